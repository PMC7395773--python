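"""Monodomain solver: conductivity assembly, diffusion, gel coupling."""

import numpy as np
import pytest

from scrollwave import fem, geometry as geo, monodomain as md, tp06
from conftest import edge_stimulus, epi_only, measure_cable_cv


class TestConductivitySpec:
    def test_defaults_give_ratio_four(self):
        spec = md.ConductivitySpec()
        assert spec.d_par / spec.d_perp == pytest.approx(4.0)

    @pytest.mark.parametrize("kw", [
        dict(d_par=0.01, d_perp=0.025),    # slower along fibers
        dict(d_par=0.1, d_perp=0.0),
        dict(gel_ratio=-0.5),
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            md.ConductivitySpec(**kw)


class TestAssembleConductivity:
    def test_healthy_tissue_tensor_is_transversely_isotropic(self):
        slab = geo.make_slab(4.0, 2.0, 2.0, 1.0)
        field = md.assemble_conductivity(slab, md.ConductivitySpec(0.1, 0.025))
        expected = np.broadcast_to(np.diag([0.1, 0.025, 0.025]),
                                   field.tensors.shape)
        np.testing.assert_allclose(field.tensors, expected, atol=1e-12)

    def test_infarct_core_tensor_vanishes(self):
        sheet = geo.make_sheet(10.0, 10.0, 1.0)
        sheet.h[:] = 0.0
        field = md.assemble_conductivity(sheet, md.ConductivitySpec())
        assert np.all(field.tensors == 0.0)

    def test_gel_elements_get_isotropic_scaled_tensor(self):
        slab = geo.make_slab(4.0, 2.0, 2.0, 1.0)
        slab.gel[:3] = True
        field = md.assemble_conductivity(
            slab, md.ConductivitySpec(0.1, 0.025, gel_ratio=1.5))
        np.testing.assert_allclose(field.tensors[0],
                                   0.0375 * np.eye(3), atol=1e-12)

    def test_eigenvalue_along_fiber_is_h_d_par(self):
        sheet = geo.make_sheet(6.0, 6.0, 1.0)
        sheet.h[:] = 0.5
        field = md.assemble_conductivity(sheet, md.ConductivitySpec())
        f = np.array([1.0, 0.0])
        lam = field.tensors[0] @ f @ f
        assert lam == pytest.approx(0.5 * 0.1)

    def test_non_unit_fiber_rejected(self):
        sheet = geo.make_sheet(4.0, 4.0, 1.0)
        sheet.fibers[:, 0] = 2.0
        with pytest.raises(ValueError, match="non-unit"):
            md.assemble_conductivity(sheet, md.ConductivitySpec())

    def test_missing_fiber_on_conductive_tissue_rejected(self):
        sheet = geo.make_sheet(4.0, 4.0, 1.0)
        sheet.fibers[:] = 0.0
        with pytest.raises(ValueError, match="fiber"):
            md.assemble_conductivity(sheet, md.ConductivitySpec())


class TestDiffusion:
    @pytest.mark.parametrize("solver", ["implicit", "explicit"])
    def test_uniform_field_is_diffusion_invariant(self, solver):
        sheet = geo.make_sheet(8.0, 8.0, 1.0)
        model = md.MonodomainModel(sheet, md.ConductivitySpec(),
                                   md.SimulationConfig(diffusion_solver=solver))
        model.V = np.full(sheet.n_nodes, -42.0)
        model.diffusion_step()
        np.testing.assert_allclose(model.V, -42.0, atol=1e-10)

    @pytest.mark.parametrize("solver", ["implicit", "explicit"])
    def test_no_flux_conserves_voltage_integral(self, solver):
        sheet = geo.make_sheet(10.0, 10.0, 1.0)
        model = md.MonodomainModel(sheet, md.ConductivitySpec(),
                                   md.SimulationConfig(diffusion_solver=solver))
        model.V = np.random.default_rng(0).normal(0.0, 20.0, sheet.n_nodes)
        before = model.total_voltage_integral()
        for _ in range(200):
            model.diffusion_step()
        after = model.total_voltage_integral()
        assert after == pytest.approx(before, rel=1e-10)

    def test_insulating_gel_conserves_tissue_integral(self):
        slab = geo.make_slab(10.0, 6.0, 6.0, 1.0)
        c = slab.element_centroids()
        slab.gel = np.linalg.norm(c - np.array([5.0, 3.0, 3.0]), axis=1) < 2.0
        assert slab.gel.any()
        model = md.MonodomainModel(slab, md.ConductivitySpec(gel_ratio=0.0),
                                   md.SimulationConfig())
        model.V = np.random.default_rng(1).normal(0.0, 20.0, slab.n_nodes)
        before = model.total_voltage_integral()
        for _ in range(100):
            model.diffusion_step()
        assert model.total_voltage_integral() == pytest.approx(before, rel=1e-10)

    def test_explicit_solver_rejects_unstable_dt(self):
        sheet = geo.make_sheet(8.0, 8.0, 0.4)
        cfg = md.SimulationConfig(dt=2.0, snapshot_every=10.0,
                                  analysis_every=10.0,
                                  diffusion_solver="explicit")
        with pytest.raises(ValueError, match="unstable"):
            md.MonodomainModel(sheet, md.ConductivitySpec(), cfg)


class TestGelPotential:
    def _gel_slab(self):
        slab = geo.make_slab(8.0, 4.0, 4.0, 1.0)
        c = slab.element_centroids()
        slab.gel = (c[:, 0] > 2.0) & (c[:, 0] < 6.0)
        return slab

    def test_uniform_interface_data_gives_constant_interior(self):
        slab = self._gel_slab()
        gel_nodes = np.unique(slab.elements[slab.gel])
        bnd = gel_nodes[np.isin(slab.nodes[gel_nodes, 0], [2.0, 6.0])]
        phi = md.solve_gel_potential(slab, md.ConductivitySpec(gel_ratio=1.0),
                                     (bnd, np.full(bnd.size, 3.5)))
        assert np.allclose(phi[gel_nodes], 3.5, atol=1e-9)

    def test_linear_boundary_data_gives_linear_interior(self):
        slab = self._gel_slab()
        gel_nodes = np.unique(slab.elements[slab.gel])
        x = slab.nodes[:, 0]
        bnd = gel_nodes[np.isin(x[gel_nodes], [2.0, 6.0])]
        phi = md.solve_gel_potential(slab, md.ConductivitySpec(gel_ratio=0.5),
                                     (bnd, 2.0 * x[bnd] - 1.0))
        assert np.allclose(phi[gel_nodes], 2.0 * x[gel_nodes] - 1.0, atol=1e-8)

    def test_small_system_matches_dense_solve(self):
        # two-triangle gel patch: FEM solution equals the dense oracle
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        elems = np.array([[0, 1, 2], [0, 2, 3]])
        mesh = geo.LabeledMesh(nodes=nodes, elements=elems)
        mesh.gel[:] = True
        bnd = np.array([0, 1, 3])
        vals = np.array([0.0, 1.0, 2.0])
        phi = md.solve_gel_potential(mesh, md.ConductivitySpec(gel_ratio=1.0),
                                     (bnd, vals))
        K = fem.assemble_stiffness(nodes, elems, np.ones(2)).toarray()
        free = [2]
        expected = np.linalg.solve(K[np.ix_(free, free)],
                                   -K[np.ix_(free, bnd)] @ vals)
        assert phi[2] == pytest.approx(expected[0])

    def test_insulating_gel_inapplicable(self):
        slab = self._gel_slab()
        with pytest.raises(ValueError, match="c = 0"):
            md.solve_gel_potential(slab, md.ConductivitySpec(gel_ratio=0.0),
                                   (np.array([0]), np.array([1.0])))


class TestPropagation:
    def test_activation_monotone_with_distance_from_stimulus(self):
        sheet = epi_only(geo.make_sheet(20.0, 20.0, 0.8))
        cfg = md.SimulationConfig(dt=0.1, T=80.0, snapshot_every=10.0,
                                  analysis_every=0.5, reaction="nodal")
        x, y = sheet.nodes[:, 0], sheet.nodes[:, 1]
        stim = md.StimulusEvent(tp06.StimulusSpec(40, 2, 2.0),
                                (x <= 1.6) & (y <= 1.6))
        res = md.run_simulation(sheet, md.ConductivitySpec(0.1, 0.1), cfg,
                                [stim])
        at = res.analysis.activation_map().at[0]
        r = np.hypot(x, y)
        order = np.argsort(r)
        # binned ATs increase with distance
        at_sorted = at[order]
        bins = np.array_split(at_sorted, 8)
        means = [np.nanmean(b) for b in bins]
        assert np.all(np.diff(means) > -0.5)

    def test_nonconductive_disc_blocks_and_detours(self):
        sheet = epi_only(geo.make_sheet(30.0, 30.0, 0.8))
        geo.make_infarct_map(sheet, ("sphere", (15.0, 15.0), 5.0), 0.0)
        cfg = md.SimulationConfig(dt=0.1, T=130.0, snapshot_every=10.0,
                                  analysis_every=0.5, reaction="nodal")
        res = md.run_simulation(sheet, md.ConductivitySpec(0.1, 0.1), cfg,
                                [edge_stimulus(sheet, onset=2.0)])
        at = res.analysis.activation_map().at[0]
        r = np.hypot(sheet.nodes[:, 0] - 15.0, sheet.nodes[:, 1] - 15.0)
        # interior means more than one element inside the core boundary:
        # boundary-straddling elements have mixed-h nodes and stay coupled
        inside = r < 5.0 - 1.5 * 0.8 * np.sqrt(2)
        outside = (r > 6.0)
        assert np.all(np.isnan(at[inside]))         # never activates
        assert np.isfinite(at[outside]).mean() > 0.97
        # detour: behind the disc activation is later than the same x at the edge
        x, y = sheet.nodes[:, 0], sheet.nodes[:, 1]
        behind = (np.abs(x - 22.0) < 0.5) & (np.abs(y - 15.0) < 1.0)
        edge = (np.abs(x - 22.0) < 0.5) & (y < 2.0)
        assert np.nanmean(at[behind]) > np.nanmean(at[edge]) + 1.0

    def test_cell_layer_changes_apd_not_conduction(self):
        results = {}
        for layer in (geo.LAYER_EPI, geo.LAYER_MID):
            cable = geo.make_cable(40.0, 0.8)
            cable.layer[:] = layer
            cfg = md.SimulationConfig(dt=0.1, T=500.0, snapshot_every=10.0,
                                      analysis_every=0.5, reaction="nodal")
            res = md.run_simulation(cable, md.ConductivitySpec(), cfg,
                                    [edge_stimulus(cable)])
            results[layer] = res.analysis.activation_map()
        at_epi = results[geo.LAYER_EPI].at[0]
        at_mid = results[geo.LAYER_MID].at[0]
        sel = np.isfinite(at_epi)
        np.testing.assert_allclose(at_epi[sel], at_mid[sel], atol=1.0)
        apd_epi = np.nanmean(results[geo.LAYER_EPI].apd[0])
        apd_mid = np.nanmean(results[geo.LAYER_MID].apd[0])
        assert apd_mid > apd_epi + 20.0

    def test_divergence_guard_aborts_with_diagnostic(self):
        sheet = geo.make_sheet(6.0, 6.0, 1.0)
        model = md.MonodomainModel(sheet, md.ConductivitySpec(),
                                   md.SimulationConfig())
        model.V[:] = 10_000.0
        model.states[:, 0] = 10_000.0
        with pytest.raises(md.SimulationDiverged):
            for _ in range(50):
                model.step()

    def test_mesh_refinement_converges_cv(self, paced_cable_run):
        mesh, res = paced_cable_run
        cv_fine = measure_cable_cv(mesh, res.analysis.activation_map().at[0],
                                   18.0, 45.0)
        coarse = epi_only(geo.make_cable(60.0, 0.4))
        cfg = md.SimulationConfig(dt=0.1, T=160.0, snapshot_every=10.0,
                                  analysis_every=0.5, reaction="nodal")
        res_c = md.run_simulation(coarse, md.ConductivitySpec(), cfg,
                                  [edge_stimulus(coarse)])
        cv_coarse = measure_cable_cv(coarse,
                                     res_c.analysis.activation_map().at[0],
                                     18.0, 45.0)
        assert abs(cv_fine - cv_coarse) / cv_coarse < 0.05


class TestConfigValidation:
    def test_cadence_must_be_multiple_of_dt(self):
        with pytest.raises(ValueError, match="multiple"):
            md.SimulationConfig(dt=0.1, snapshot_every=0.25)

    def test_bad_solver_and_theta_rejected(self):
        with pytest.raises(ValueError):
            md.SimulationConfig(diffusion_solver="spectral")
        with pytest.raises(ValueError):
            md.SimulationConfig(theta=1.5)

    def test_snapshot_series_requires_increasing_times(self):
        sheet = geo.make_sheet(4.0, 4.0, 1.0)
        V = np.zeros((2, sheet.n_nodes), dtype=np.float32)
        with pytest.raises(ValueError):
            md.SnapshotSeries(mesh=sheet, times=np.array([1.0, 1.0]), V=V)

    def test_snapshot_series_hdf5_roundtrip(self, tmp_path):
        sheet = geo.make_sheet(4.0, 4.0, 1.0)
        times = np.array([0.0, 5.0, 10.0])
        V = np.random.default_rng(0).normal(
            -80, 10, (3, sheet.n_nodes)).astype(np.float32)
        series = md.SnapshotSeries(mesh=sheet, times=times, V=V)
        path = tmp_path / "series.h5"
        series.save(path)
        back = md.SnapshotSeries.load(path, sheet)
        np.testing.assert_array_equal(back.V, V)
        np.testing.assert_array_equal(back.times, times)
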