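"""Post-processing metrics: AT/RT, KDE distributions, filaments, ECG."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scrollwave import geometry as geo, metrics, phantoms
from scrollwave.monodomain import SnapshotSeries


def trapezoid_ap(t, rest=-85.0, peak=15.0, plateau=200.0, ramp=10.0,
                 onset=50.0):
    """Piecewise-linear action potential with known crossing times."""
    v = np.full_like(t, rest)
    up = (t >= onset) & (t < onset + ramp)
    v[up] = rest + (peak - rest) * (t[up] - onset) / ramp
    top = (t >= onset + ramp) & (t < onset + ramp + plateau)
    v[top] = peak
    down = (t >= onset + ramp + plateau) & (t < onset + 2 * ramp + plateau)
    v[down] = peak - (peak - rest) * (t[down] - onset - ramp - plateau) / ramp
    return v


class TestActivationRecovery:
    def test_trapezoid_apd90_recovers_plateau_duration(self):
        t = np.arange(0.0, 400.0, 0.5)
        amap = metrics.compute_at_rt(t, trapezoid_ap(t))
        assert amap.n_beats == 1
        # crossings of -70 up and the 90%-recovery level down are 200 ms
        # plus the two partial ramps; analytic value:
        rest, peak, ramp = -85.0, 15.0, 10.0
        at_exact = 50.0 + ramp * (-70.0 - rest) / (peak - rest)
        level = rest + 0.1 * (peak - rest)
        rt_exact = 50.0 + ramp + 200.0 + ramp * (peak - level) / (peak - rest)
        assert amap.at[0, 0] == pytest.approx(at_exact, abs=0.5)
        assert amap.apd[0, 0] == pytest.approx(rt_exact - at_exact, abs=1.0)

    def test_constant_trace_has_no_crossings(self):
        t = np.arange(0.0, 100.0, 0.5)
        amap = metrics.compute_at_rt(t, np.full_like(t, -85.0))
        assert amap.n_beats == 0
        assert amap.missing_count() == 0

    def test_beat_separation_matches_cycle_length(self):
        t = np.arange(0.0, 1500.0, 0.5)
        v = trapezoid_ap(t) + trapezoid_ap(t - 1000.0) - (-85.0)
        amap = metrics.compute_at_rt(t, v)
        assert amap.n_beats == 2
        assert amap.at[1, 0] - amap.at[0, 0] == pytest.approx(1000.0, abs=0.5)

    def test_extraction_invariant_to_time_shift(self):
        t = np.arange(0.0, 400.0, 0.5)
        v = trapezoid_ap(t)
        a0 = metrics.compute_at_rt(t, v)
        a1 = metrics.compute_at_rt(t + 137.0, v)
        assert a1.at[0, 0] - a0.at[0, 0] == pytest.approx(137.0, abs=1e-9)
        assert a1.apd[0, 0] == pytest.approx(a0.apd[0, 0], abs=1e-9)

    def test_fixed_voltage_repolarization_rule(self):
        t = np.arange(0.0, 400.0, 0.5)
        amap = metrics.compute_at_rt(t, trapezoid_ap(t),
                                     repolarization_rule="fixed:-70")
        # -70 crossings: up at onset + 0.15*ramp, down at 0.85 of the fall
        # ramp past the plateau end -> APD = 10*0.85 + 200 + 10*0.85
        assert amap.apd[0, 0] == pytest.approx(217.0, abs=1.0)

    def test_rt_exceeds_at_wherever_both_defined(self):
        t = np.arange(0.0, 1500.0, 0.5)
        v = trapezoid_ap(t) + trapezoid_ap(t - 700.0) - (-85.0)
        amap = metrics.compute_at_rt(t, v)
        both = np.isfinite(amap.at) & np.isfinite(amap.rt)
        assert np.all(amap.rt[both] > amap.at[both])


class TestRestitutionDistributions:
    def test_degenerate_samples_give_summary_only(self):
        d = metrics.regional_restitution_pdf(np.full(10, 212.0), "EPI", 370.0)
        assert d.kde is None
        assert d.median == 212.0

    def test_well_separated_mixture_is_bimodal(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate([rng.normal(200, 2, 300),
                                  rng.normal(280, 2, 300)])
        d = metrics.regional_restitution_pdf(samples, "LV", 370.0)
        assert d.n_modes == 2

    def test_unimodal_samples_flagged_unimodal(self):
        rng = np.random.default_rng(1)
        d = metrics.regional_restitution_pdf(rng.normal(240, 5, 500),
                                             "RV", 370.0)
        assert d.n_modes == 1

    def test_pdf_normalizes_to_one(self):
        rng = np.random.default_rng(2)
        d = metrics.regional_restitution_pdf(rng.normal(240, 8, 400),
                                             "LVMM", 370.0)
        grid = np.linspace(150, 330, 4000)
        integral = np.trapezoid(d.pdf(grid), grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_kde_median_close_to_sample_median(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(250, 6, 300)
        d = metrics.regional_restitution_pdf(samples, "EPI", 500.0)
        grid = np.linspace(200, 300, 2000)
        pdf = d.pdf(grid)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        kde_median = grid[np.searchsorted(cdf, 0.5)]
        assert abs(kde_median - d.median) < d.bandwidth

    def test_no_valid_samples_rejected(self):
        with pytest.raises(ValueError):
            metrics.regional_restitution_pdf(np.array([np.nan]), "EPI", 370.0)


class TestFilamentDetection:
    def test_uniform_field_yields_no_singularities(self):
        sheet = geo.make_sheet(20.0, 20.0, 1.0)
        pts = metrics.detect_singular_elements(
            sheet, np.full(sheet.n_nodes, -30.0), np.zeros(sheet.n_nodes))
        assert pts.size == 0

    def test_planar_wave_yields_no_singularities(self):
        sheet = geo.make_sheet(60.0, 60.0, 1.0)
        for t in np.arange(20.0, 300.0, 20.0):
            V, dV = phantoms.planar_wave_fields(sheet, t)
            pts = metrics.detect_singular_elements(sheet, V, dV)
            assert pts.size == 0

    def test_rotating_spiral_core_located_within_one_element(self):
        sheet = geo.make_sheet(60.0, 60.0, 1.0)
        sheet.nodes -= 30.0
        for t in np.arange(0.0, 150.0, 10.0):
            V, dV = phantoms.rotating_spiral_fields(sheet, t)
            pts = metrics.detect_singular_elements(sheet, V, dV)
            assert len(pts) > 0
            assert np.linalg.norm(pts, axis=1).min() < 1.0

    def test_extruded_scroll_filament_tracks_core_line(self):
        slab = geo.make_slab(40.0, 40.0, 8.0, 2.0)
        slab.nodes[:, :2] -= 20.0
        V, dV = phantoms.rotating_spiral_fields(slab, 30.0, decay=12.0)
        pts = metrics.detect_singular_elements(slab, V, dV)
        assert len(pts) > 0
        # flagged centroids stay near the vertical core line on every slice
        for z in np.unique(np.round(pts[:, 2], 1)):
            layer_pts = pts[np.round(pts[:, 2], 1) == z]
            assert np.linalg.norm(layer_pts[:, :2], axis=1).min() < 4.0

    def test_dvdt_missing_computed_from_snapshots(self):
        sheet = geo.make_sheet(60.0, 60.0, 1.0)
        sheet.nodes -= 30.0
        times = np.arange(0.0, 100.0, 5.0)
        series = phantoms.spiral_series(sheet, times)
        series_no_dvdt = SnapshotSeries(mesh=sheet, times=series.times,
                                        V=series.V)
        fts = metrics.filament_timeseries(series_no_dvdt, cadence=10.0,
                                          burn_in=0.0, eps=2.0)
        assert np.all(fts.counts >= 1)


class TestFilamentClustering:
    def test_two_distant_clouds_are_two_filaments(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.5, (20, 3))
        b = rng.normal(50.0, 0.5, (20, 3))
        _, count = metrics.cluster_filaments(np.vstack([a, b]), eps=5.0)
        assert count == 2

    def test_chained_cloud_is_one_filament(self):
        pts = np.column_stack([np.arange(0, 20, 0.5),
                               np.zeros(40), np.zeros(40)])
        _, count = metrics.cluster_filaments(pts, eps=1.0)
        assert count == 1

    def test_empty_input_gives_zero_filaments(self):
        labels, count = metrics.cluster_filaments(np.empty((0, 3)), eps=1.0)
        assert count == 0 and labels.size == 0

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            metrics.cluster_filaments(np.zeros((3, 3)), eps=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_count_matches_eps_ball_connected_components(self, seed):
        """DBSCAN with min_points = 1 equals graph connected components."""
        from scipy.sparse import csgraph
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 500)
        pts = rng.uniform(0.0, 60.0, (n, 3))
        eps = float(rng.uniform(1.0, 6.0))
        _, count = metrics.cluster_filaments(pts, eps=eps, min_points=1)
        adj = squareform(pdist(pts)) <= eps
        n_comp, _ = csgraph.connected_components(adj, directed=False)
        assert count == n_comp


class TestFilamentTimeSeries:
    def test_planar_series_counts_all_zero(self):
        sheet = geo.make_sheet(60.0, 60.0, 1.0)
        series = phantoms.planar_series(sheet, np.arange(0.0, 200.0, 10.0))
        fts = metrics.filament_timeseries(series, cadence=10.0, burn_in=50.0)
        assert np.all(fts.counts == 0)
        assert fts.mean_count == 0.0

    def test_stable_scroll_counts_one_nearly_everywhere(self):
        slab = geo.make_slab(40.0, 40.0, 8.0, 2.0)
        slab.nodes[:, :2] -= 20.0
        times = np.arange(0.0, 300.0, 10.0)
        series = phantoms.spiral_series(slab, times, decay=12.0)
        # eps = 2x the element diameter (2 mm lattice tets)
        fts = metrics.filament_timeseries(series, cadence=10.0, burn_in=0.0,
                                          eps=4.0 * np.sqrt(3))
        assert np.mean(fts.counts == 1) >= 0.95

    def test_series_ending_at_burn_in_flags_average_undefined(self):
        sheet = geo.make_sheet(60.0, 60.0, 1.0)
        series = phantoms.planar_series(sheet, np.arange(0.0, 100.0, 10.0))
        fts = metrics.filament_timeseries(series, cadence=10.0, burn_in=200.0)
        assert not fts.stabilized()
        assert fts.counts.size > 0


class TestPseudoECG:
    def test_uniform_potential_gives_zero_signal(self):
        sheet = geo.make_sheet(10.0, 10.0, 1.0)
        ecg = metrics.pseudo_ecg(([0.0], np.full(sheet.n_nodes, 7.0)),
                                 np.array([40.0, 5.0]), sheet)
        assert abs(ecg.Ve[0]) < 1e-12

    def test_signal_linear_in_potential_field(self):
        sheet = geo.make_sheet(10.0, 10.0, 1.0)
        e = np.array([35.0, 5.0])
        rng = np.random.default_rng(0)
        v1 = rng.normal(0, 20, sheet.n_nodes)
        v2 = rng.normal(0, 20, sheet.n_nodes)
        a, b = 0.7, -1.3
        ve = [metrics.pseudo_ecg(([0.0], v), e, sheet).Ve[0]
              for v in (v1, v2, a * v1 + b * v2)]
        assert ve[2] == pytest.approx(a * ve[0] + b * ve[1], abs=1e-12)

    def test_single_element_matches_dense_quadrature_oracle(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        elems = np.array([[0, 1, 2]])
        mesh = geo.LabeledMesh(nodes=nodes, elements=elems)
        V = np.array([0.0, 2.0, -1.0])       # grad V = (2, -1)
        electrode = np.array([30.0, 14.0])
        ve = metrics.pseudo_ecg(([0.0], V), electrode, mesh).Ve[0]
        # dense barycentric quadrature of -grad(V) . grad(1/rho)
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(3), size=200_000)
        pts = w @ nodes
        d = electrode[None, :] - pts
        rho = np.linalg.norm(d, axis=1)
        integrand = -(d / rho[:, None] ** 3) @ np.array([2.0, -1.0])
        oracle = 0.5 * integrand.mean()      # triangle area = 1/2
        assert ve == pytest.approx(oracle, rel=1e-3)

    def test_far_electrode_sees_weaker_signal(self):
        sheet = geo.make_sheet(10.0, 10.0, 0.5)
        blob = np.exp(-np.sum((sheet.nodes - 5.0) ** 2, axis=1))
        near = metrics.pseudo_ecg(([0.0], 100 * blob),
                                  np.array([30.0, 5.0]), sheet).Ve[0]
        far = metrics.pseudo_ecg(([0.0], 100 * blob),
                                 np.array([60.0, 5.0]), sheet).Ve[0]
        assert abs(far) < abs(near)

    def test_electrode_inside_domain_rejected(self):
        sheet = geo.make_sheet(10.0, 10.0, 1.0)
        with pytest.raises(ValueError, match="inside"):
            metrics.pseudo_ecg(([0.0], np.zeros(sheet.n_nodes)),
                               np.array([5.0, 5.0]), sheet)


class TestFundamentalFrequency:
    def test_pure_tone_recovered(self):
        t = np.arange(0.0, 5000.0, 1.0)
        f = metrics.fundamental_frequency((t, np.sin(2 * np.pi * 4.3 * t / 1000)))
        assert f == pytest.approx(4.3, abs=0.25)

    def test_dominant_component_wins(self):
        t = np.arange(0.0, 5000.0, 1.0)
        x = np.sin(2 * np.pi * 3.0 * t / 1000) \
            + 0.3 * np.sin(2 * np.pi * 6.0 * t / 1000)
        assert metrics.fundamental_frequency((t, x)) == pytest.approx(3.0,
                                                                      abs=0.25)

    def test_constant_trace_flagged_undefined(self):
        t = np.arange(0.0, 2000.0, 1.0)
        assert np.isnan(metrics.fundamental_frequency((t, np.zeros_like(t))))

    def test_short_or_nonuniform_traces_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            metrics.fundamental_frequency((np.arange(0, 500.0, 1.0),
                                           np.ones(500)))
        t = np.concatenate([np.arange(0, 1000.0, 1.0),
                            np.arange(1000.0, 3000.0, 2.0)])
        with pytest.raises(ValueError, match="uniform"):
            metrics.fundamental_frequency((t, np.ones_like(t)))
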