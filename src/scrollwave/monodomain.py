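"""Monodomain reaction-diffusion propagation on labeled meshes.

The transmembrane potential obeys  dV/dt = div(D grad V) + I_ion, with a
transversely isotropic conductivity modulated by the healthy-volume
fraction h(x):

    D = h(x) [ d_perp I + (d_par - d_perp) f (x) f(x)^T ]        (tissue)
    D = c d_perp I                                               (gel)

no-flux boundaries, and TP06 reaction kinetics per node with its
transmural layer's parameter set.  Gel inclusions carry no reaction
term: with c > 0 they act as passive isotropic conductors folded into
the global diffusion operator; with c = 0 they are excluded from the
conductive domain so their interface carries the no-flux condition.

Time integration is first-order operator splitting (reaction then
diffusion).  The reaction sub-step is the hybrid Rush-Larsen scheme of
:mod:`scrollwave.tp06`; the diffusion sub-step is either backward Euler
with the consistent P1 mass matrix (default; matches a Galerkin
finite-element treatment) or forward Euler with the lumped mass matrix
(cheaper, conditionally stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem, tp06
from .geometry import LabeledMesh, LAYER_NAMES

__all__ = [
    "ConductivitySpec",
    "ConductivityField",
    "SimulationConfig",
    "SnapshotSeries",
    "StimulusEvent",
    "MonodomainModel",
    "assemble_conductivity",
    "step_monodomain",
    "solve_gel_potential",
    "run_simulation",
]

V_DIVERGE = 500.0  # |V| beyond this aborts with a diagnostic (mV)


class SimulationDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class ConductivitySpec:
    """Tissue conductivities (mm^2/ms) and gel conductivity ratio c."""

    d_par: float = 0.1
    d_perp: float = 0.025
    gel_ratio: float = 0.0

    def __post_init__(self):
        if not (self.d_par >= self.d_perp > 0):
            raise ValueError("require d_par >= d_perp > 0")
        if self.gel_ratio < 0:
            raise ValueError("gel conductivity ratio c must be >= 0")


@dataclass
class ConductivityField:
    """Per-element symmetric conductivity tensors (mm^2/ms)."""

    tensors: np.ndarray          # (m, dim, dim)
    gel: np.ndarray              # (m,) bool
    spec: ConductivitySpec


def assemble_conductivity(mesh: LabeledMesh,
                          spec: ConductivitySpec) -> ConductivityField:
    """Per-element tensors D = h [d_perp I + (d_par - d_perp) f f^T].

    h and f are averaged from the element's nodes (f re-normalized).
    Gel elements get the isotropic c * d_perp * I instead; h = 0 tissue
    gets the zero tensor.  Fibers must be unit vectors wherever h > 0.
    """
    dim = mesh.dim
    h_n = mesh.h
    norms = np.linalg.norm(mesh.fibers, axis=1)
    bad = (h_n > 0) & (np.abs(norms - 1.0) > 1e-6)
    if np.any(bad):
        if np.any((h_n > 0) & (norms < 1e-12)):
            raise ValueError("missing fiber vector on conductive node")
        raise ValueError("non-unit fiber vector on conductive node")

    h_e = mesh.element_h()
    f_e = mesh.fibers[mesh.elements].mean(axis=1)
    nrm = np.linalg.norm(f_e, axis=1, keepdims=True)
    f_e = np.where(nrm > 1e-12, f_e / np.maximum(nrm, 1e-12), f_e)

    eye = np.eye(dim)
    D = (spec.d_perp * eye[None, :, :]
         + (spec.d_par - spec.d_perp) * np.einsum("mi,mj->mij", f_e, f_e))
    D = h_e[:, None, None] * D
    if np.any(mesh.gel):
        D[mesh.gel] = spec.gel_ratio * spec.d_perp * eye[None, :, :]
    return ConductivityField(tensors=D, gel=mesh.gel.copy(), spec=spec)


@dataclass
class SimulationConfig:
    """Numerical and recording parameters for a monodomain run.

    ``reaction`` selects where the ionic state lives: "quadrature"
    (one TP06 state per element centroid, the default, matching a
    Galerkin treatment with gate ODEs at quadrature points) or "nodal"
    (one state per mesh node).  ``theta`` is the implicitness of the
    diffusion sub-step (0.5 = Crank-Nicolson default, 1.0 = backward
    Euler); the "explicit" solver uses lumped mass and forward Euler.
    """

    dt: float = 0.1               # ms, operator-splitting step
    T: float = 1000.0             # ms, total simulated time
    snapshot_every: float = 5.0   # ms, voltage snapshot cadence
    analysis_every: float = 0.5   # ms, online AT/RT cadence (dt* = 5 dt)
    diffusion_solver: str = "implicit"   # "implicit" | "explicit"
    theta: float = 0.5                   # implicit-scheme parameter
    reaction: str = "quadrature"         # "quadrature" | "nodal"
    cell_mode: str = "restitution"       # TP06 parameter mode
    store_dvdt: bool = False
    abort_on_divergence: bool = True
    seed: int = 0
    linear_rtol: float = 1e-8

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("snapshot_every", "analysis_every"):
            cad = getattr(self, name)
            k = cad / self.dt
            if cad <= 0 or abs(k - round(k)) > 1e-9:
                raise ValueError(f"{name} must be a positive multiple of dt")
        if self.diffusion_solver not in ("implicit", "explicit"):
            raise ValueError("diffusion_solver must be 'implicit' or 'explicit'")
        if self.reaction not in ("quadrature", "nodal"):
            raise ValueError("reaction must be 'quadrature' or 'nodal'")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


@dataclass
class SnapshotSeries:
    """Time-stamped nodal voltage fields (and optional dV/dt) on a mesh."""

    mesh: LabeledMesh
    times: np.ndarray             # (nt,) ms, strictly increasing
    V: np.ndarray                 # (nt, n) mV, float32
    dVdt: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if self.V.shape != (self.times.size, self.mesh.n_nodes):
            raise ValueError("V shape must be (n_times, n_nodes)")

    def save(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["n_nodes"] = self.mesh.n_nodes
            f.create_dataset("times", data=self.times)
            f.create_dataset("V", data=self.V, chunks=(1, self.mesh.n_nodes),
                             compression="gzip", compression_opts=1)
            if self.dVdt is not None:
                f.create_dataset("dVdt", data=self.dVdt,
                                 chunks=(1, self.mesh.n_nodes),
                                 compression="gzip", compression_opts=1)

    @classmethod
    def load(cls, path, mesh: LabeledMesh) -> "SnapshotSeries":
        import h5py
        with h5py.File(path, "r") as f:
            times = f["times"][:]
            V = f["V"][:]
            dvdt = f["dVdt"][:] if "dVdt" in f else None
        return cls(mesh=mesh, times=times, V=V, dVdt=dvdt)


@dataclass(frozen=True)
class StimulusEvent:
    """A square stimulus applied over a spatial node mask."""

    stimulus: tp06.StimulusSpec
    node_mask: np.ndarray         # (n,) bool

    def current_at(self, t: float) -> float:
        return self.stimulus.value_at(t)


class MonodomainModel:
    """Assembled operators + TP06 states for one labeled mesh.

    The ionic state array lives either at mesh nodes or at element
    centroids (quadrature points) per ``config.reaction``; the voltage
    field ``V`` is always nodal.
    """

    def __init__(self, mesh: LabeledMesh, spec: ConductivitySpec,
                 config: SimulationConfig):
        self.mesh = mesh
        self.spec = spec
        self.config = config
        self.field = assemble_conductivity(mesh, spec)

        n = mesh.n_nodes
        elems = mesh.elements
        self._quad = config.reaction == "quadrature"

        # conductive elements: gel excluded when c = 0
        if spec.gel_ratio == 0.0 and np.any(mesh.gel):
            cond = ~mesh.gel
        else:
            cond = np.ones(mesh.n_elements, dtype=bool)
        self._cond_elems = elems[cond]
        self.K = fem.assemble_stiffness(mesh.nodes, self._cond_elems,
                                        self.field.tensors[cond])
        lumped = config.diffusion_solver == "explicit"
        self.M = fem.assemble_mass(mesh.nodes, self._cond_elems, lumped=lumped)
        # nodes outside the conductive domain (gel interior when c = 0)
        # get identity mass rows so the system stays nonsingular and their
        # voltage is simply held constant by the diffusion solve
        decoupled = np.asarray(self.M.diagonal() == 0.0)
        self._decoupled = decoupled
        if decoupled.any():
            self.M = (self.M + sp.diags(decoupled.astype(np.float64))).tocsr()
        if lumped:
            self._minv = 1.0 / np.maximum(self.M.diagonal(), 1e-300)
            # CFL guard for the explicit diffusion sub-step
            lam = (np.abs(self.K) @ np.ones(n)) * self._minv
            dt_max = 2.0 / max(lam.max(), 1e-30)
            if config.dt > dt_max:
                raise ValueError(
                    f"explicit diffusion unstable: dt={config.dt} > {dt_max:.3g}")
            self._solve = None
            self._B = None
            self._mass_solve = lambda b: self._minv * b
        else:
            th = config.theta
            A = (self.M + th * config.dt * self.K).tocsc()
            self._lu = spla.splu(A)
            self._solve = self._lu.solve
            self._B = (self.M - (1.0 - th) * config.dt * self.K).tocsr()
            self._mass_lu = spla.splu(self.M.tocsc())
            self._mass_solve = self._mass_lu.solve

        # reaction sites: nodes of non-gel elements, or non-gel elements
        params = {i: tp06.make_cell_params(ct, config.cell_mode)
                  for i, ct in enumerate(
                      ("endocardial", "mid-myocardial", "epicardial"))}
        self.cell_params = params
        if self._quad:
            site_layer = mesh.element_layer()
            self.active = ~mesh.gel & (mesh.element_h() > 0)
            n_sites = mesh.n_elements
        else:
            site_layer = mesh.layer
            tissue_nodes = np.unique(elems[~mesh.gel])
            self.active = np.zeros(n, dtype=bool)
            self.active[tissue_nodes] = True
            n_sites = n

        def arr(attr):
            vals = np.array([getattr(params[i], attr) for i in range(3)])
            return vals[site_layer]
        self._g = (arr("G_Kr"), arr("G_Ks"), arr("G_to"),
                   arr("G_pCa"), arr("G_pK"), arr("tau_f_scale"))
        self._endo_s = np.array(
            [params[i].endo_s_gate for i in range(3)])[site_layer]

        # projection weights for quadrature reaction: node i gains
        # vol_e / nloc of each owning element's voltage increment
        if self._quad:
            self._vols = mesh.element_volumes()
            self._nloc = elems.shape[1]

        y0 = tp06.default_initial_state().as_array()
        self.states = np.tile(y0, (n_sites, 1))
        self.V = np.full(n, y0[0])
        self.t = 0.0
        self._stim = np.zeros(n_sites)

    def node_stimulus_to_sites(self, stim_nodal: np.ndarray) -> np.ndarray:
        """Interpolate a nodal stimulus field to the reaction sites."""
        if self._quad:
            return stim_nodal[self.mesh.elements].mean(axis=1)
        return stim_nodal

    def total_voltage_integral(self) -> float:
        """∫ V dΩ over the conductive domain (consistent with M)."""
        total = float(np.ones(self.mesh.n_nodes) @ (self.M @ self.V))
        if self._decoupled.any():
            total -= float(self.V[self._decoupled].sum())
        return total

    def diffusion_step(self, dt: float | None = None) -> None:
        """One diffusion sub-step (no reaction)."""
        if dt is not None and dt != self.config.dt and self._solve is not None:
            th = self.config.theta
            A = (self.M + th * dt * self.K).tocsc()
            B = (self.M - (1.0 - th) * dt * self.K).tocsr()
            self.V = spla.splu(A).solve(B @ self.V)
            return
        if self._solve is None:
            dt = self.config.dt if dt is None else dt
            self.V = self.V - dt * (self._minv * (self.K @ self.V))
        else:
            self.V = self._solve(self._B @ self.V)

    def reaction_step(self, dt: float, stim_sites: np.ndarray) -> None:
        """Advance ionic states; apply the voltage increment to V."""
        Y = self.states
        if self._quad:
            elems = self.mesh.elements
            Y[:, 0] = self.V[elems].mean(axis=1)
            v_before = Y[:, 0].copy()
            tp06._rl_step_kernel(Y, dt, stim_sites, *self._g, self._endo_s,
                                 self.active)
            rhs = np.zeros(self.mesh.n_nodes)
            np.add.at(rhs, elems.ravel(),
                      np.repeat(self._vols * (Y[:, 0] - v_before) / self._nloc,
                                self._nloc))
            self.V = self.V + self._mass_solve(rhs)
        else:
            Y[:, 0] = self.V
            tp06._rl_step_kernel(Y, dt, stim_sites, *self._g, self._endo_s,
                                 self.active)
            self.V = Y[:, 0].copy()

    def step(self, events: Sequence[StimulusEvent] = ()) -> None:
        """One operator-splitting step (reaction then diffusion)."""
        dt = self.config.dt
        stim_nodal = None
        for ev in events:
            amp = ev.current_at(self.t)
            if amp:
                if stim_nodal is None:
                    stim_nodal = np.zeros(self.mesh.n_nodes)
                stim_nodal[ev.node_mask] += amp
        stim = self._stim
        if stim_nodal is None:
            stim[:] = 0.0
        else:
            stim[:] = self.node_stimulus_to_sites(stim_nodal)
        self.reaction_step(dt, stim)
        self.diffusion_step(dt)
        self.t += dt
        if self.config.abort_on_divergence:
            vmax = np.abs(self.V).max()
            if vmax > V_DIVERGE or not np.isfinite(vmax):
                raise SimulationDiverged(
                    f"|V| = {vmax:.1f} mV at t = {self.t:.2f} ms "
                    "(> 500 mV instability guard)")


def step_monodomain(model: MonodomainModel,
                    events: Sequence[StimulusEvent] = ()) -> np.ndarray:
    """Advance a model one operator-splitting step; returns the V field."""
    model.step(events)
    return model.V


def solve_gel_potential(mesh: LabeledMesh, spec: ConductivitySpec,
                        interface_values: dict | tuple) -> np.ndarray:
    """Steady Laplace potential inside the gel region.

    ``interface_values`` maps gel-interface node index -> potential (or
    is an ``(indices, values)`` pair).  Requires c > 0; for c = 0 the
    gel is excluded from the conductive domain and carries a no-flux
    interface instead, and this operation is inapplicable.

    Returns the potential on the gel submesh nodes as a full-length
    array (NaN outside the gel).  Under the sign convention adopted for
    gel coupling, the field solved here is the negated transmembrane
    potential continued into the gel; for spatially uniform interface
    data the interior equals that constant either way.
    """
    if spec.gel_ratio <= 0:
        raise ValueError("gel potential undefined for c = 0 (insulating gel)")
    if not np.any(mesh.gel):
        raise ValueError("mesh has no gel elements")
    if isinstance(interface_values, dict):
        idx = np.array(sorted(interface_values), dtype=np.int64)
        vals = np.array([interface_values[i] for i in idx])
    else:
        idx, vals = (np.asarray(interface_values[0], dtype=np.int64),
                     np.asarray(interface_values[1], dtype=np.float64))
    gel_elems = mesh.elements[mesh.gel]
    gel_nodes = np.unique(gel_elems)
    if not np.all(np.isin(idx, gel_nodes)):
        raise ValueError("interface nodes must belong to gel elements")
    # solve on the compacted gel submesh (the rest of the mesh does not
    # enter the Laplace problem)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[gel_nodes] = np.arange(gel_nodes.size)
    sub_elems = remap[gel_elems]
    sub_nodes = mesh.nodes[gel_nodes]
    sol = fem.solve_laplace(sub_nodes, sub_elems, remap[idx], vals)
    phi = np.full(mesh.n_nodes, np.nan)
    phi[gel_nodes] = sol
    return phi


@dataclass
class RunResult:
    series: SnapshotSeries
    events_log: list
    model: MonodomainModel
    analysis: object | None = None   # online AT/RT accumulator, if attached


def run_simulation(mesh: LabeledMesh, spec: ConductivitySpec,
                   config: SimulationConfig,
                   protocol: Sequence[StimulusEvent],
                   analysis_nodes: np.ndarray | None = None,
                   at_threshold: float = -70.0,
                   progress: Callable[[float], None] | None = None) -> RunResult:
    """Run a monodomain simulation under a stimulation protocol.

    Voltage snapshots are stored at ``config.snapshot_every``; activation
    and repolarization times are accumulated online at the analysis
    cadence dt* on ``analysis_nodes`` (all active nodes by default).
    """
    from .metrics import OnlineActivationTracker

    model = MonodomainModel(mesh, spec, config)
    n_steps = int(round(config.T / config.dt))
    snap_stride = int(round(config.snapshot_every / config.dt))
    ana_stride = int(round(config.analysis_every / config.dt))

    if analysis_nodes is None:
        analysis_nodes = np.unique(mesh.elements[~mesh.gel])
    tracker = OnlineActivationTracker(analysis_nodes, threshold=at_threshold)
    tracker.observe(0.0, model.V[analysis_nodes])

    times = [0.0]
    snaps = [model.V.astype(np.float32).copy()]
    # dV/dt at snapshot instants by backward difference over one dt
    dvdts = [np.zeros(mesh.n_nodes, dtype=np.float32)] if config.store_dvdt else None
    log = [{"event": "start", "t": 0.0, "n_nodes": mesh.n_nodes}]

    v_before = None
    for i in range(n_steps):
        if config.store_dvdt and (i + 1) % snap_stride == 0:
            v_before = model.V.copy()
        model.step(protocol)
        k = i + 1
        if k % ana_stride == 0:
            tracker.observe(model.t, model.V[analysis_nodes])
        if k % snap_stride == 0:
            times.append(model.t)
            snaps.append(model.V.astype(np.float32).copy())
            if config.store_dvdt:
                dvdts.append(((model.V - v_before) / config.dt)
                             .astype(np.float32))
        if progress is not None and k % 1000 == 0:
            progress(model.t)

    series = SnapshotSeries(mesh=mesh, times=np.array(times),
                            V=np.stack(snaps),
                            dVdt=np.stack(dvdts) if dvdts else None)
    log.append({"event": "end", "t": model.t})
    return RunResult(series=series, events_log=log, model=model,
                     analysis=tracker)
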