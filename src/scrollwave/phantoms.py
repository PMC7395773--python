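"""Analytic voltage phantoms with known singularity structure.

Used to validate the filament detection/clustering pipeline against
ground truth: a rigidly rotating spiral has exactly one phase
singularity at its core (a vertical filament line when extruded to
3D); a planar wave has none; superposed cores give known counts.
"""

from __future__ import annotations

import numpy as np

from .geometry import LabeledMesh
from .monodomain import SnapshotSeries

__all__ = [
    "rotating_spiral_fields",
    "planar_wave_fields",
    "spiral_series",
    "planar_series",
]


def rotating_spiral_fields(mesh: LabeledMesh, t: float,
                           cores=((0.0, 0.0),),
                           amplitude: float = 40.0,
                           offset: float = -45.0,
                           omega: float = 2 * np.pi / 150.0,
                           wavenumber: float = 2 * np.pi / 30.0,
                           decay: float = 6.0):
    """V and dV/dt of rigidly rotating Archimedean spiral(s).

    Around each core:  V = offset + A cos(theta - omega t + k r) e^(-r/L).
    The phase singularity sits at the core, where the -70 mV isoline
    (requiring local amplitude > |offset - (-70)|) meets the dV/dt = 0
    line at all times.  The exponential envelope (decay length ``L`` =
    ``decay``) localizes each rotor so superposed cores keep exactly
    one singularity apiece when separated by a few decay lengths.
    """
    x = mesh.nodes[:, 0]
    y = mesh.nodes[:, 1] if mesh.dim >= 2 else np.zeros_like(x)
    cores = np.asarray(cores, dtype=np.float64)
    V = np.full(mesh.n_nodes, offset)
    dVdt = np.zeros(mesh.n_nodes)
    for cx, cy in cores:
        r = np.hypot(x - cx, y - cy)
        th = np.arctan2(y - cy, x - cx)
        phase = th - omega * t + wavenumber * r
        env = amplitude * np.exp(-r / decay)
        V += env * np.cos(phase)
        dVdt += env * omega * np.sin(phase)
    return V, dVdt


def planar_wave_fields(mesh: LabeledMesh, t: float,
                       speed: float = 0.5,
                       front_width: float = 2.0,
                       apd: float = 200.0,
                       tail_width: float = 20.0,
                       rest: float = -85.0,
                       plateau: float = 15.0):
    """Rightward-travelling planar wave: front and tail never co-locate.

    The upstroke sits at x = speed * t and the (slow) repolarization
    tail trails it by speed * apd; dV/dt is large and positive only at
    the front, moderately negative only at the tail.
    """
    x = mesh.nodes[:, 0]
    xf = speed * t
    xt = speed * (t - apd)
    up = 0.5 * (1 + np.tanh((xf - x) / front_width))
    down = 0.5 * (1 + np.tanh((xt - x) / tail_width))
    V = rest + (plateau - rest) * (up - down)
    dv_up = (plateau - rest) * 0.5 * speed / front_width \
        / np.cosh((xf - x) / front_width) ** 2
    dv_down = (plateau - rest) * 0.5 * speed / tail_width \
        / np.cosh((xt - x) / tail_width) ** 2
    return V, dv_up - dv_down


def _series(mesh, fields, times):
    V = np.empty((len(times), mesh.n_nodes), dtype=np.float32)
    D = np.empty_like(V)
    for k, t in enumerate(times):
        v, d = fields(t)
        V[k] = v
        D[k] = d
    return SnapshotSeries(mesh=mesh, times=np.asarray(times, dtype=np.float64),
                         V=V, dVdt=D)


def spiral_series(mesh: LabeledMesh, times, **kw) -> SnapshotSeries:
    """Snapshot series of the rotating-spiral phantom."""
    return _series(mesh, lambda t: rotating_spiral_fields(mesh, t, **kw), times)


def planar_series(mesh: LabeledMesh, times, **kw) -> SnapshotSeries:
    """Snapshot series of the planar-wave phantom."""
    return _series(mesh, lambda t: planar_wave_fields(mesh, t, **kw), times)
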