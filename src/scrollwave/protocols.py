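"""Stimulation protocols: dynamic restitution pacing and S1-S2 VF induction.

The restitution protocol paces a site (apex by default on anatomical
meshes) through a decreasing cycle-length schedule and pairs each
beat's per-node APD with the preceding CL and diastolic interval
DI = CL - previous APD.  The S1-S2 protocol delivers a premature
cross-field stimulus near the repolarization tail of a conditioning
wave to provoke wavebreak and reentry; scanning the coupling interval
yields the vulnerable window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import tp06
from .geometry import LabeledMesh
from .monodomain import (ConductivitySpec, MonodomainModel, SimulationConfig,
                         SnapshotSeries, StimulusEvent, run_simulation)

__all__ = [
    "RestitutionProtocol",
    "S1S2Protocol",
    "RestitutionSamples",
    "build_restitution_schedule",
    "run_restitution",
    "run_s1s2",
    "locate_wave_tail",
    "measure_vulnerable_window",
    "OUTCOME_NO_REENTRY",
    "OUTCOME_TRANSIENT",
    "OUTCOME_SUSTAINED",
]

OUTCOME_NO_REENTRY = "no reentry"
OUTCOME_TRANSIENT = "transient reentry"
OUTCOME_SUSTAINED = "sustained VF"


@dataclass
class RestitutionProtocol:
    """Repeated pacing through a cycle-length schedule."""

    site_mask: np.ndarray               # (n,) bool stimulus site
    schedule: np.ndarray                # ms per beat
    amplitude: float = 40.0             # mV/ms
    duration: float = 2.0               # ms
    lead_in: float = 5.0                # ms before the first beat

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=np.float64)
        if self.schedule.ndim != 1 or self.schedule.size < 1:
            raise ValueError("schedule must be a 1D array of cycle lengths")

    @property
    def beats(self) -> int:
        return int(self.schedule.size)

    def total_time(self) -> float:
        return float(self.lead_in + self.schedule.sum())

    def onsets(self) -> np.ndarray:
        return self.lead_in + np.concatenate([[0.0], np.cumsum(self.schedule[:-1])])

    def events(self) -> list[StimulusEvent]:
        return [StimulusEvent(tp06.StimulusSpec(self.amplitude, self.duration, t0),
                              self.site_mask)
                for t0 in self.onsets()]


def build_restitution_schedule(beats: int, cl_start: float, cl_end: float,
                               rule: str = "geometric-steps",
                               beats_per_cl: int = 4,
                               total_time: float | None = None) -> np.ndarray:
    """Monotone non-increasing CL schedule for dynamic restitution pacing.

    ``geometric-steps`` (default) holds ``beats_per_cl`` beats at each
    of ``beats / beats_per_cl`` cycle lengths stepping geometrically
    from ``cl_start`` down to ``cl_end``; ``linear`` decreases every
    beat.  If ``total_time`` is given, a schedule whose sum exceeds it
    is rejected with the required minimum.
    """
    if beats < 2:
        raise ValueError("need at least 2 beats")
    if not (cl_start >= cl_end > 0):
        raise ValueError("require cl_start >= cl_end > 0")
    if rule == "geometric-steps":
        if beats % beats_per_cl:
            raise ValueError("beats must be a multiple of beats_per_cl")
        n_lvl = beats // beats_per_cl
        levels = (np.geomspace(cl_start, cl_end, n_lvl) if n_lvl > 1
                  else np.array([cl_end]))
        sched = np.repeat(levels, beats_per_cl)
    elif rule == "linear":
        sched = np.linspace(cl_start, cl_end, beats)
    else:
        raise ValueError(f"unknown schedule rule {rule!r}")
    if total_time is not None and sched.sum() > total_time:
        raise ValueError(
            f"schedule needs T >= {sched.sum():.0f} ms (> {total_time:.0f})")
    return sched


@dataclass
class RestitutionSamples:
    """Per-node (beat, CL, APD, DI) restitution samples.

    ``apd`` and ``di`` are (n_beats, n_nodes); NaN marks conduction
    block (the node never activated on that beat) — missing data, not
    zeros.  The first beat carries no preceding CL and is excluded.
    """

    node_indices: np.ndarray
    cl: np.ndarray                      # (n_beats,) preceding CL per beat
    apd: np.ndarray                     # (n_beats, n_nodes)
    di: np.ndarray                      # (n_beats, n_nodes)

    def samples_at_cl(self, cl_value: float, last_beat_only: bool = True,
                      atol: float = 0.5) -> np.ndarray:
        """Valid APD samples for beats whose preceding CL matches."""
        rows = np.where(np.abs(self.cl - cl_value) <= atol)[0]
        if rows.size == 0:
            return np.empty(0)
        if last_beat_only:
            rows = rows[-1:]
        vals = self.apd[rows].ravel()
        return vals[np.isfinite(vals)]

    def n_blocked(self) -> int:
        return int(np.isnan(self.apd).sum())


def run_restitution(mesh: LabeledMesh, spec: ConductivitySpec,
                    config: SimulationConfig, protocol: RestitutionProtocol,
                    analysis_nodes: np.ndarray | None = None):
    """Run the pacing schedule and extract per-node restitution samples.

    Returns ``(samples, result)``.  For each beat after the first, the
    per-node APD is paired with the preceding cycle length and
    DI = CL - APD(previous beat).  AT/RT accumulate online at the
    analysis cadence dt* on the selected node subset.
    """
    T_need = protocol.total_time() + 50.0
    if config.T < T_need:
        raise ValueError(f"config.T = {config.T} too short; need >= {T_need:.0f}")
    result = run_simulation(mesh, spec, config, protocol.events(),
                            analysis_nodes=analysis_nodes)
    amap = result.analysis.activation_map()
    onsets = protocol.onsets()
    sched = protocol.schedule
    n = amap.node_indices.size

    # map detected beats to protocol beats via activation-time binning
    apd = np.full((protocol.beats, n), np.nan)
    edges = np.concatenate([onsets, [protocol.total_time() + 50.0]])
    for b_det in range(amap.n_beats):
        at = amap.at[b_det]
        a = amap.apd[b_det]
        which = np.searchsorted(edges, at, side="right") - 1
        ok = np.isfinite(at) & (which >= 0) & (which < protocol.beats)
        apd[which[ok], np.arange(n)[ok]] = a[ok]

    # preceding CL per beat; DI = CL - previous APD
    cl_prev = np.concatenate([[np.nan], sched[:-1]])
    di = np.full_like(apd, np.nan)
    di[1:] = cl_prev[1:, None] - apd[:-1]
    samples = RestitutionSamples(node_indices=amap.node_indices,
                                 cl=cl_prev, apd=apd, di=di)
    return samples, result


# ---------------------------------------------------------------------------
# S1-S2 induction
# ---------------------------------------------------------------------------

@dataclass
class S1S2Protocol:
    """Conditioning S1 followed by a premature cross-field S2."""

    s1_mask: np.ndarray
    s2_mask: np.ndarray
    coupling_interval: float            # ms between S1 and S2 onsets
    s1_amplitude: float = 40.0
    s2_amplitude: float = 300.0
    duration: float = 2.0
    s2_duration: float | None = None
    sustained_criterion: float = 2000.0  # ms of persistent reentry = sustained
    n_s1: int = 1
    s1_cl: float = 500.0
    lead_in: float = 5.0

    def __post_init__(self):
        if self.s1_amplitude <= 0 or self.s2_amplitude < 0:
            raise ValueError("stimulus amplitudes must be positive (S2 >= 0)")
        if self.coupling_interval <= 0:
            raise ValueError("coupling interval must be positive")

    @property
    def s2_onset(self) -> float:
        last_s1 = self.lead_in + (self.n_s1 - 1) * self.s1_cl
        return last_s1 + self.coupling_interval

    def events(self) -> list[StimulusEvent]:
        evs = [StimulusEvent(
            tp06.StimulusSpec(self.s1_amplitude, self.duration,
                              self.lead_in + k * self.s1_cl), self.s1_mask)
            for k in range(self.n_s1)]
        last_s1 = self.lead_in + (self.n_s1 - 1) * self.s1_cl
        if self.coupling_interval < self.duration:
            raise ValueError("S2 onset falls within the S1 stimulus")
        if self.s2_amplitude > 0:
            dur2 = self.s2_duration if self.s2_duration is not None else self.duration
            evs.append(StimulusEvent(
                tp06.StimulusSpec(self.s2_amplitude, dur2, self.s2_onset),
                self.s2_mask))
        return evs


def locate_wave_tail(model_or_series, at_time: float, lag: float = 40.0,
                     threshold: float = -70.0) -> np.ndarray:
    """Nodes that repolarized within ``lag`` ms before ``at_time``.

    A helper for placing S2 near the tail of the S1 wave: selects nodes
    whose voltage crossed back below the threshold in the window
    [at_time - lag, at_time], from a snapshot series.
    """
    series = model_or_series
    times = series.times
    sel = (times >= at_time - lag) & (times <= at_time)
    if sel.sum() < 2:
        raise ValueError("snapshot series does not cover the requested window")
    V = series.V[sel]
    below = V < threshold
    crossed = (~below[:-1]) & below[1:]
    return np.any(crossed, axis=0)


@dataclass
class S1S2Result:
    outcome: str
    series: SnapshotSeries
    quiescence_time: float | None       # ms after S2 when activity died, or None
    protocol: S1S2Protocol


def run_s1s2(mesh: LabeledMesh, spec: ConductivitySpec,
             config: SimulationConfig, protocol: S1S2Protocol,
             activity_threshold: float = -70.0) -> S1S2Result:
    """Run the S1-S2 protocol and classify the induction outcome.

    Outcomes: ``no reentry`` (activity dies within one AP duration of
    S2), ``transient reentry`` (reentrant activity outlasts that but
    dies before the sustained criterion), ``sustained VF`` (activity
    persists beyond ``sustained_criterion`` ms after S2).  Activity =
    any active node above the threshold.
    """
    t_end_need = protocol.s2_onset + protocol.sustained_criterion + 100.0
    if config.T < t_end_need:
        raise ValueError(f"config.T must reach {t_end_need:.0f} ms")
    result = run_simulation(mesh, spec, config, protocol.events())
    series = result.series
    t_s2 = protocol.s2_onset
    active_nodes = np.unique(mesh.elements[~mesh.gel])
    act = (series.V[:, active_nodes] > activity_threshold).any(axis=1)
    after = series.times > t_s2 + protocol.duration + 5.0
    quiet = after & ~act
    if not np.any(quiet):
        outcome = OUTCOME_SUSTAINED
        t_quiet = None
    else:
        t_quiet = float(series.times[np.argmax(quiet)])
        dt_after = t_quiet - t_s2
        if dt_after >= protocol.sustained_criterion:
            outcome = OUTCOME_SUSTAINED
        elif dt_after > 600.0:      # beyond one full APD + conduction time
            outcome = OUTCOME_TRANSIENT
        else:
            outcome = OUTCOME_NO_REENTRY
    return S1S2Result(outcome=outcome, series=series,
                      quiescence_time=t_quiet, protocol=protocol)


@dataclass
class VulnerableWindow:
    """Coupling intervals that induce sustained reentry."""

    intervals: np.ndarray               # scanned coupling intervals (ms)
    outcomes: list                      # outcome string per interval
    sustained: np.ndarray               # bool per interval

    @property
    def window(self) -> np.ndarray:
        return self.intervals[self.sustained]

    @property
    def extent(self) -> float:
        """Extent of the sustained set (ms); scan-step-limited from below."""
        w = self.window
        if w.size == 0:
            return 0.0
        if w.size == 1:
            steps = np.diff(self.intervals)
            return float(steps.min()) if steps.size else 0.0
        return float(w.max() - w.min())


def measure_vulnerable_window(mesh: LabeledMesh, spec: ConductivitySpec,
                              config: SimulationConfig,
                              protocol: S1S2Protocol,
                              coupling_intervals: Sequence[float],
                              runner: Callable | None = None) -> VulnerableWindow:
    """Scan S1-S2 coupling intervals for sustained-reentry induction.

    ``runner(protocol_variant)`` may be injected (e.g. for scaled-down
    studies); it defaults to :func:`run_s1s2` on the given mesh/config
    and must return an object with an ``outcome`` attribute.
    """
    intervals = np.asarray(list(coupling_intervals), dtype=np.float64)
    if intervals.size == 0:
        raise ValueError("empty coupling-interval scan")
    intervals = np.sort(intervals)
    if runner is None:
        def runner(proto):
            return run_s1s2(mesh, spec, config, proto)
    outcomes = []
    for ci in intervals:
        proto = S1S2Protocol(
            s1_mask=protocol.s1_mask, s2_mask=protocol.s2_mask,
            coupling_interval=float(ci),
            s1_amplitude=protocol.s1_amplitude,
            s2_amplitude=protocol.s2_amplitude,
            duration=protocol.duration, s2_duration=protocol.s2_duration,
            sustained_criterion=protocol.sustained_criterion,
            n_s1=protocol.n_s1, s1_cl=protocol.s1_cl,
            lead_in=protocol.lead_in)
        outcomes.append(runner(proto).outcome)
    sustained = np.array([o == OUTCOME_SUSTAINED for o in outcomes])
    return VulnerableWindow(intervals=intervals, outcomes=outcomes,
                            sustained=sustained)
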