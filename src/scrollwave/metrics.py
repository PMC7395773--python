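"""Post-processing of monodomain simulations.

Activation/repolarization/APD extraction, regional APD-restitution
distributions via Gaussian kernel density estimation, scroll-wave
filament detection (isopotential crossing intersected with the
dV/dt = 0 waveback) with DBSCAN clustering and counting, and the
pseudo-ECG volume integral with fundamental-frequency extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import periodogram
from scipy.stats import gaussian_kde
from sklearn.cluster import DBSCAN

from . import fem
from .geometry import LabeledMesh, Surface
from .monodomain import SnapshotSeries

__all__ = [
    "ActivationMap",
    "OnlineActivationTracker",
    "compute_at_rt",
    "RestitutionDistribution",
    "regional_restitution_pdf",
    "detect_singular_elements",
    "cluster_filaments",
    "FilamentTimeSeries",
    "filament_timeseries",
    "PseudoECG",
    "pseudo_ecg",
    "fundamental_frequency",
]

DEFAULT_AT_THRESHOLD = -70.0   # mV, upstroke crossing
DEFAULT_ISO = -70.0            # mV, filament isopotential
DEFAULT_DVDT_TOL = 0.1         # mV/ms minimum rate magnitude on each side


# ---------------------------------------------------------------------------
# Activation / repolarization / APD
# ---------------------------------------------------------------------------

@dataclass
class ActivationMap:
    """Per-node, per-beat activation and repolarization times (ms).

    ``at[b][i]`` / ``rt[b][i]`` are NaN where no crossing occurred
    (conduction block); ``apd = rt - at``.
    """

    at: np.ndarray               # (n_beats, n_nodes)
    rt: np.ndarray               # (n_beats, n_nodes)
    threshold: float
    repolarization_rule: str     # "apd90" or "fixed:<mV>"
    node_indices: np.ndarray

    @property
    def apd(self) -> np.ndarray:
        return self.rt - self.at

    @property
    def n_beats(self) -> int:
        return self.at.shape[0]

    def missing_count(self) -> int:
        return int(np.isnan(self.at).sum())


class OnlineActivationTracker:
    """Streaming AT/RT accumulation at the analysis cadence dt*.

    Feed (t, V) samples on a node subset; upward threshold crossings
    open a beat (AT by linear interpolation), and repolarization closes
    it.  The repolarization rule is APD90 by default: recovery through
    V_rest + 0.1 (V_peak - V_rest), with V_rest the pre-upstroke value
    of the same beat; a fixed-voltage rule ("fixed:-70") is available.
    """

    def __init__(self, node_indices: np.ndarray, threshold: float = DEFAULT_AT_THRESHOLD,
                 repolarization_rule: str = "apd90"):
        self.node_indices = np.asarray(node_indices, dtype=np.int64)
        self.threshold = float(threshold)
        self.rule = repolarization_rule
        if repolarization_rule != "apd90" and not repolarization_rule.startswith("fixed:"):
            raise ValueError("repolarization_rule must be 'apd90' or 'fixed:<mV>'")
        n = self.node_indices.size
        self._t_prev = None
        self._v_prev = None
        self._in_ap = np.zeros(n, dtype=bool)
        self._at = np.full(n, np.nan)
        self._rest = np.full(n, np.nan)
        self._peak = np.full(n, -np.inf)
        # _events[i] holds completed (at, rt) pairs per node
        self._events: list[list[tuple[float, float]]] = [[] for _ in range(n)]

    def observe(self, t: float, v: np.ndarray) -> None:
        v = np.asarray(v, dtype=np.float64)
        if self._t_prev is None:
            self._t_prev = t
            self._v_prev = v.copy()
            return
        t0, v0 = self._t_prev, self._v_prev
        dt = t - t0
        thr = self.threshold

        up = (~self._in_ap) & (v0 < thr) & (v >= thr)
        if np.any(up):
            frac = (thr - v0[up]) / (v[up] - v0[up])
            self._at[up] = t0 + frac * dt
            self._rest[up] = v0[up]
            self._peak[up] = v[up]
            self._in_ap[up] = True

        act = self._in_ap & ~up
        np.maximum(self._peak, np.where(act, v, -np.inf), out=self._peak)

        if self.rule == "apd90":
            level = self._rest + 0.1 * (self._peak - self._rest)
        else:
            level = np.full_like(v, float(self.rule.split(":")[1]))
        down = self._in_ap & (v0 > level) & (v <= level) & (self._peak > thr)
        if np.any(down):
            idxs = np.where(down)[0]
            frac = (v0[idxs] - level[idxs]) / (v0[idxs] - v[idxs])
            rts = t0 + frac * dt
            for i, r in zip(idxs, rts):
                self._events[i].append((self._at[i], float(r)))
            self._in_ap[down] = False
        self._t_prev = t
        self._v_prev = v.copy()

    def activation_map(self) -> ActivationMap:
        n = self.node_indices.size
        # include open beats (activated, not yet repolarized) with NaN RT
        events = [list(e) for e in self._events]
        for i in range(n):
            if self._in_ap[i] and np.isfinite(self._at[i]):
                events[i].append((self._at[i], np.nan))
        n_beats = max((len(e) for e in events), default=0)
        at = np.full((n_beats, n), np.nan)
        rt = np.full((n_beats, n), np.nan)
        for i, ev in enumerate(events):
            for b, (a, r) in enumerate(ev):
                at[b, i] = a
                rt[b, i] = r
        return ActivationMap(at=at, rt=rt, threshold=self.threshold,
                             repolarization_rule=self.rule,
                             node_indices=self.node_indices)


def compute_at_rt(times: np.ndarray, V: np.ndarray,
                  threshold: float = DEFAULT_AT_THRESHOLD,
                  repolarization_rule: str = "apd90") -> ActivationMap:
    """AT/RT/APD per beat from a sampled trace or field series.

    ``V`` is (nt,) for a single trace or (nt, n) for a field series
    sampled at the analysis cadence or finer.  AT is the first upward
    threshold crossing of each beat; RT follows the configured rule
    (APD90 default); crossing times are linearly interpolated between
    samples.  Nodes with no crossing get NaN entries.
    """
    times = np.asarray(times, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if V.ndim == 1:
        V = V[:, None]
    tracker = OnlineActivationTracker(np.arange(V.shape[1]), threshold,
                                      repolarization_rule)
    for t, v in zip(times, V):
        tracker.observe(t, v)
    return tracker.activation_map()


# ---------------------------------------------------------------------------
# Regional restitution distributions
# ---------------------------------------------------------------------------

@dataclass
class RestitutionDistribution:
    """Gaussian-KDE summary of regional APD samples at one cycle length."""

    region: str
    cl: float
    samples: np.ndarray
    kde: gaussian_kde | None
    bandwidth: float | None
    median: float
    std: float
    n_modes: int

    def pdf(self, x: np.ndarray) -> np.ndarray:
        if self.kde is None:
            raise ValueError("fewer than 2 samples: no PDF available")
        return self.kde(x)


def regional_restitution_pdf(samples: np.ndarray, region: str, cl: float,
                             bandwidth: str | float = "scott") -> RestitutionDistribution:
    """Gaussian KDE over APD samples at a fixed CL, with summaries.

    Reports the sample median, standard deviation and the number of KDE
    modes (local maxima of the density; > 1 flags bimodality).  With
    fewer than 2 valid samples only the summaries are returned.
    """
    samples = np.asarray(samples, dtype=np.float64)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError("no valid APD samples")
    med = float(np.median(samples))
    std = float(np.std(samples))
    if samples.size < 2 or np.ptp(samples) == 0:
        return RestitutionDistribution(region, cl, samples, None, None,
                                       med, std, 1 if samples.size else 0)
    kde = gaussian_kde(samples, bw_method=bandwidth)
    bw = float(kde.factor * samples.std(ddof=1))
    lo, hi = samples.min() - 4 * bw, samples.max() + 4 * bw
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    prominence = dens[1:-1] > 1e-3 * dens.max()
    n_modes = int(np.count_nonzero(interior & prominence))
    return RestitutionDistribution(region, cl, samples, kde, bw, med, std,
                                   max(n_modes, 1))


# ---------------------------------------------------------------------------
# Filament detection and clustering
# ---------------------------------------------------------------------------

def detect_singular_elements(mesh: LabeledMesh, V: np.ndarray,
                             dVdt: np.ndarray,
                             iso: float = DEFAULT_ISO,
                             dvdt_tol: float = DEFAULT_DVDT_TOL) -> np.ndarray:
    """Centroids of elements where the wavefront meets the waveback.

    A phase singularity is the intersection of the isopotential line
    with the dV/dt = 0 line.  Per element, dV/dt is linearly
    interpolated onto the points where the element's edges cross the
    isopotential; the element is singular when those on-isoline rates
    bracket zero within ``dvdt_tol``.  On a wavefront the isoline is
    crossed while depolarizing (all rates positive), on a waveback
    while repolarizing (all negative), so plane waves yield no flags;
    only where front and back meet does the on-isoline rate pass
    through zero.
    """
    V = np.asarray(V, dtype=np.float64)
    dVdt = np.asarray(dVdt, dtype=np.float64)
    if V.shape[0] != mesh.n_nodes or dVdt.shape[0] != mesh.n_nodes:
        raise ValueError("fields must be nodal on the same mesh")
    elems = mesh.elements
    ve = V[elems]
    de = dVdt[elems]
    straddle_iso = (ve.min(axis=1) < iso) & (ve.max(axis=1) > iso)
    m, nloc = elems.shape
    lo = np.full(m, np.inf)
    hi = np.full(m, -np.inf)
    for a in range(nloc - 1):
        for b in range(a + 1, nloc):
            va, vb = ve[:, a], ve[:, b]
            cross = (np.minimum(va, vb) < iso) & (np.maximum(va, vb) > iso)
            if not np.any(cross):
                continue
            w = (iso - va[cross]) / (vb[cross] - va[cross])
            dc = de[cross, a] + w * (de[cross, b] - de[cross, a])
            lo[cross] = np.minimum(lo[cross], dc)
            hi[cross] = np.maximum(hi[cross], dc)
    on_waveback_zero = (lo <= dvdt_tol) & (hi >= -dvdt_tol)
    flags = straddle_iso & on_waveback_zero & ~mesh.gel & (mesh.element_h() > 0)
    return mesh.element_centroids()[flags]


def cluster_filaments(centroids: np.ndarray, eps: float,
                      min_points: int = 1):
    """Group singular-element centroids into filaments with DBSCAN.

    Returns ``(labels, count)``: cluster labels per centroid (noise
    points, only possible for min_points > 1, get -1) and the number of
    clusters, i.e. the filament count.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.size == 0:
        return np.empty(0, dtype=np.int64), 0
    labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(centroids)
    count = int(labels.max() + 1) if np.any(labels >= 0) else 0
    return labels, count


@dataclass
class FilamentTimeSeries:
    """Per-instant clustered filament sets and counts."""

    times: np.ndarray                       # ms, counting cadence
    counts: np.ndarray                      # int per instant
    centroids: list                         # per-time (k, dim) arrays
    labels: list                            # per-time cluster labels
    burn_in: float
    mean_count: float                       # NaN when series ends at burn-in

    def stabilized(self) -> bool:
        return np.isfinite(self.mean_count)


def filament_timeseries(series: SnapshotSeries, cadence: float = 10.0,
                        burn_in: float = 2500.0,
                        eps: float | None = None,
                        min_points: int = 1,
                        iso: float = DEFAULT_ISO,
                        dvdt_tol: float = DEFAULT_DVDT_TOL) -> FilamentTimeSeries:
    """Detect, cluster and count filaments every ``cadence`` ms.

    The time-averaged count is taken over t > ``burn_in`` (the initial
    transient after induction).  dV/dt comes from the stored field when
    present, otherwise from finite differences of consecutive snapshots.
    ``eps`` defaults to twice the characteristic element size.
    """
    times = series.times
    if len(times) < 2:
        raise ValueError("need at least 2 snapshots")
    snap_dt = float(np.median(np.diff(times)))
    stride = max(1, int(round(cadence / snap_dt)))
    if abs(stride * snap_dt - cadence) > 1e-6 * max(cadence, 1.0):
        raise ValueError("cadence must be a multiple of the snapshot cadence")
    mesh = series.mesh
    if eps is None:
        eps = 2.0 * mesh.characteristic_spacing()

    out_t, out_c, out_pts, out_lab = [], [], [], []
    for k in range(stride, len(times), stride):
        V = series.V[k].astype(np.float64)
        if series.dVdt is not None:
            dvdt = series.dVdt[k].astype(np.float64)
        else:
            dvdt = (series.V[k].astype(np.float64)
                    - series.V[k - 1].astype(np.float64)) / (times[k] - times[k - 1])
        pts = detect_singular_elements(mesh, V, dvdt, iso, dvdt_tol)
        labels, count = cluster_filaments(pts, eps=eps, min_points=min_points)
        out_t.append(times[k])
        out_c.append(count)
        out_pts.append(pts)
        out_lab.append(labels)

    out_t = np.array(out_t)
    out_c = np.array(out_c, dtype=np.int64)
    after = out_t > burn_in
    mean_count = float(out_c[after].mean()) if np.any(after) else np.nan
    return FilamentTimeSeries(times=out_t, counts=out_c, centroids=out_pts,
                              labels=out_lab, burn_in=burn_in,
                              mean_count=mean_count)


# ---------------------------------------------------------------------------
# Pseudo-ECG
# ---------------------------------------------------------------------------

@dataclass
class PseudoECG:
    """Far-field potential trace at one electrode with its spectrum."""

    electrode: np.ndarray
    times: np.ndarray
    Ve: np.ndarray
    freqs: np.ndarray | None = None
    power: np.ndarray | None = None
    fundamental_hz: float = np.nan


def _lead_field_gradients(mesh: LabeledMesh, electrode: np.ndarray,
                          quad: str = "centroid"):
    """grad(1/rho) per element, rho = |x_e - x|, at centroid quadrature."""
    xc = mesh.element_centroids()
    d = electrode[None, : mesh.dim] - xc
    rho = np.linalg.norm(d, axis=1)
    if np.any(rho < 1e-9):
        raise ValueError("electrode coincides with an element centroid")
    return d / rho[:, None] ** 3


def pseudo_ecg(series_or_fields, electrode: np.ndarray,
               mesh: LabeledMesh | None = None) -> PseudoECG:
    """Pseudo-ECG  V_e(t) = - ∫ grad(V_m) . grad(1/rho) dΩ.

    ``series_or_fields`` is a :class:`SnapshotSeries`, or a (times, V)
    pair together with ``mesh``.  The integral is evaluated per element
    with the P1 gradient of V_m and centroid quadrature of the
    lead-field gradient.  The electrode must lie outside the conductive
    domain (the kernel is singular inside).
    """
    if isinstance(series_or_fields, SnapshotSeries):
        mesh = series_or_fields.mesh
        times = series_or_fields.times
        V = series_or_fields.V
    else:
        times, V = series_or_fields
        if mesh is None:
            raise ValueError("mesh required when passing raw fields")
    electrode = np.asarray(electrode, dtype=np.float64)

    # electrode inside the domain -> singular kernel -> reject
    xc = mesh.element_centroids()
    r = np.linalg.norm(electrode[None, : mesh.dim] - xc, axis=1)
    if r.min() < 1.5 * mesh.characteristic_spacing():
        raise ValueError("electrode lies inside or too close to the domain")

    grads, vols = fem.shape_gradients(mesh.nodes, mesh.elements)
    lead = _lead_field_gradients(mesh, electrode)
    keep = (~mesh.gel) & (mesh.element_h() > 0)
    w = np.where(keep, vols, 0.0)
    elems = mesh.elements
    V = np.asarray(V, dtype=np.float64)
    single = V.ndim == 1
    if single:
        V = V[None, :]
    # per element: grad V = sum_i V_i grad N_i
    ve = np.empty(V.shape[0])
    contrib = np.einsum("mid,md,m->mi", grads, lead, w)   # (m, nloc)
    for k in range(V.shape[0]):
        gv = V[k][elems]                                  # (m, nloc)
        ve[k] = -np.sum(contrib * gv)
    times = np.atleast_1d(np.asarray(times, dtype=np.float64))
    return PseudoECG(electrode=electrode, times=times,
                     Ve=ve[0:1] if single else ve)


def fundamental_frequency(ecg: PseudoECG | tuple,
                          dc_floor_hz: float = 0.5) -> PseudoECG | float:
    """Dominant power-spectrum peak of a pseudo-ECG trace.

    Mean is removed and a Hann taper applied before the periodogram;
    peaks at or below ``dc_floor_hz`` are excluded.  Requires a
    uniformly sampled trace of at least 1 s.  An (all-)zero trace
    yields NaN (flagged undefined).

    Accepts a PseudoECG (returns it with spectrum fields filled) or a
    ``(times_ms, values)`` pair (returns the frequency in Hz).
    """
    if isinstance(ecg, PseudoECG):
        t, x = ecg.times, ecg.Ve
    else:
        t, x = ecg
        t = np.asarray(t, dtype=np.float64)
        x = np.asarray(x, dtype=np.float64)
    if t.size < 2:
        raise ValueError("trace too short")
    dts = np.diff(t)
    if np.ptp(dts) > 1e-6 * dts.mean():
        raise ValueError("trace must be uniformly sampled")
    if t[-1] - t[0] < 1000.0:
        raise ValueError("trace must span at least 1 s")
    fs = 1000.0 / dts.mean()          # Hz (times are ms)
    xd = x - x.mean()
    if np.allclose(xd, 0.0):
        f0 = np.nan
        freqs = power = None
    else:
        freqs, power = periodogram(xd, fs=fs, window="hann")
        band = freqs > dc_floor_hz
        f0 = float(freqs[band][np.argmax(power[band])])
    if isinstance(ecg, PseudoECG):
        ecg.freqs, ecg.power, ecg.fundamental_hz = freqs, power, f0
        return ecg
    return f0
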