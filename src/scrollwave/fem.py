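"""Linear finite-element assembly on simplicial meshes (1D/2D/3D).

Shared by the monodomain diffusion operator, the Laplace solves used for
transmural layering and gel potentials, and the pseudo-ECG quadrature.
All operators use linear (P1) shape functions; the stiffness matrix is
the symmetric form K_ij = sum_e |e| grad(N_i) . D_e grad(N_j), so the
semi-discrete diffusion equation reads  M dV/dt = -K V  with natural
(no-flux) boundaries requiring no extra terms.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "simplex_volumes",
    "shape_gradients",
    "assemble_stiffness",
    "assemble_mass",
    "boundary_faces",
    "solve_laplace",
]


def _geometry(nodes: np.ndarray, elems: np.ndarray):
    """Edge matrices T (m, dim, d) with columns x_i - x_0."""
    x = nodes[elems]                      # (m, d+1, dim)
    return np.swapaxes(x[:, 1:, :] - x[:, :1, :], 1, 2)   # (m, dim, d)


def simplex_volumes(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Unsigned measures (length/area/volume) of each simplex."""
    T = _geometry(nodes, elems)
    m, dim, d = T.shape
    if dim == d:
        return np.abs(np.linalg.det(T)) / _factorial(d)
    # lower-dimensional simplex embedded in higher dim (surface elements)
    G = np.einsum("mki,mkj->mij", T, T)
    return np.sqrt(np.abs(np.linalg.det(G))) / _factorial(d)


def _factorial(d: int) -> float:
    out = 1.0
    for k in range(2, d + 1):
        out *= k
    return out


def shape_gradients(nodes: np.ndarray, elems: np.ndarray):
    """Gradients of the P1 shape functions.

    Returns (grads, vols): grads has shape (m, d+1, dim) with
    grads[e, i] = grad N_i on element e (constant for P1).
    """
    T = _geometry(nodes, elems)           # (m, dim, d)
    m, dim, d = T.shape
    if dim != d:
        raise ValueError("shape_gradients requires full-dimensional simplices")
    Tinv = np.linalg.inv(T)               # (m, d, dim)
    grads = np.empty((m, d + 1, dim))
    grads[:, 1:, :] = Tinv
    grads[:, 0, :] = -Tinv.sum(axis=1)
    vols = np.abs(np.linalg.det(T)) / _factorial(d)
    return grads, vols


def assemble_stiffness(nodes: np.ndarray, elems: np.ndarray,
                       tensors: np.ndarray) -> sp.csr_matrix:
    """Assemble K_ij = sum_e |e| grad(N_i) . D_e grad(N_j).

    ``tensors``: per-element symmetric (dim, dim) conductivity, shape
    (m, dim, dim) or a scalar array (m,) meaning isotropic D_e * I.
    """
    n = nodes.shape[0]
    grads, vols = shape_gradients(nodes, elems)
    m, nloc, dim = grads.shape
    tensors = np.asarray(tensors, dtype=np.float64)
    if tensors.ndim == 1:
        Dg = tensors[:, None, None] * grads
    else:
        Dg = np.einsum("mij,mkj->mki", tensors, grads)
    Ke = np.einsum("mki,mli->mkl", grads, Dg) * vols[:, None, None]
    rows = np.repeat(elems, nloc, axis=1).ravel()
    cols = np.tile(elems, (1, nloc)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def assemble_mass(nodes: np.ndarray, elems: np.ndarray,
                  lumped: bool = False) -> sp.csr_matrix:
    """Consistent or row-sum-lumped P1 mass matrix."""
    n = nodes.shape[0]
    vols = simplex_volumes(nodes, elems)
    m, nloc = elems.shape
    if lumped:
        diag = np.zeros(n)
        np.add.at(diag, elems.ravel(), np.repeat(vols / nloc, nloc))
        return sp.diags(diag).tocsr()
    Me = (np.ones((nloc, nloc)) + np.eye(nloc)) / ((nloc) * (nloc + 1))
    Ke = vols[:, None, None] * Me[None, :, :]
    rows = np.repeat(elems, nloc, axis=1).ravel()
    cols = np.tile(elems, (1, nloc)).ravel()
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def boundary_faces(elems: np.ndarray) -> np.ndarray:
    """Faces belonging to exactly one element (the mesh boundary)."""
    m, nloc = elems.shape
    faces = []
    for drop in range(nloc):
        keep = [k for k in range(nloc) if k != drop]
        faces.append(elems[:, keep])
    faces = np.concatenate(faces, axis=0)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def solve_laplace(nodes: np.ndarray, elems: np.ndarray,
                  dirichlet_nodes: np.ndarray, dirichlet_values: np.ndarray,
                  tensors: np.ndarray | None = None,
                  rtol: float = 1e-8) -> np.ndarray:
    """Solve div(D grad(phi)) = 0 with Dirichlet data, no-flux elsewhere."""
    n = nodes.shape[0]
    dirichlet_nodes = np.asarray(dirichlet_nodes, dtype=np.int64)
    dirichlet_values = np.asarray(dirichlet_values, dtype=np.float64)
    if dirichlet_nodes.size == 0:
        raise ValueError("Laplace solve requires Dirichlet boundary nodes")
    if tensors is None:
        tensors = np.ones(elems.shape[0])
    K = assemble_stiffness(nodes, elems, tensors)
    phi = np.zeros(n)
    phi[dirichlet_nodes] = dirichlet_values
    free = np.ones(n, dtype=bool)
    free[dirichlet_nodes] = False
    rhs = -K[:, dirichlet_nodes] @ dirichlet_values
    Kff = K[free][:, free].tocsc()
    sol = spla.spsolve(Kff, rhs[free])
    phi[free] = sol
    return phi
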