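import numpy as np
import pytest

from scrollwave import geometry as geo
from scrollwave import monodomain as md
from scrollwave import tp06


def epi_only(mesh):
    """Label every node epicardial (single-cell-type fixtures)."""
    mesh.layer[:] = geo.LAYER_EPI
    return mesh


def measure_cable_cv(mesh, at, x_lo, x_hi):
    """CV between the cross-sections nearest two x planes."""
    x = mesh.nodes[:, 0]
    xs = np.unique(x)
    x1 = xs[np.argmin(np.abs(xs - x_lo))]
    x2 = xs[np.argmin(np.abs(xs - x_hi))]
    at1 = np.nanmean(at[x == x1])
    at2 = np.nanmean(at[x == x2])
    return (x2 - x1) / (at2 - at1)


def edge_stimulus(mesh, amplitude=40.0, duration=2.0, onset=5.0, width=None):
    """Stimulate the x = min face."""
    dx = width if width is not None else 2.05 * mesh.characteristic_spacing()
    mask = mesh.nodes[:, 0] <= mesh.nodes[:, 0].min() + dx
    return md.StimulusEvent(tp06.StimulusSpec(amplitude, duration, onset), mask)


@pytest.fixture(scope="session")
def paced_cable_run():
    """One paced 1D cable run shared by propagation tests (nodal reaction)."""
    mesh = epi_only(geo.make_cable(60.0, 0.2))
    cfg = md.SimulationConfig(dt=0.1, T=160.0, snapshot_every=10.0,
                              analysis_every=0.5, reaction="nodal")
    res = md.run_simulation(mesh, md.ConductivitySpec(), cfg,
                            [edge_stimulus(mesh)])
    return mesh, res
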