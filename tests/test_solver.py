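import numpy as np
import pytest

import pulptherm as pt
from pulptherm.errors import InvalidParameterError, MissingTissueError
from pulptherm.solver import MATERIAL_FOR_LABEL
from pulptherm.validation import steady_state_error, transient_slab_error

from conftest import random_small_grid


class TestProtocol:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 37.0),      # body temperature at contact
        (2.5, 88.5),      # linear midpoint of the ramp
        (5.0, 140.0),     # end of ramp
        (10.0, 140.0),    # during hold
        (15.0, 140.0),    # end of protocol
        (20.0, 140.0),    # clamped beyond
    ])
    def test_ramp_hold_values(self, t, expected):
        assert pt.protocol_temperature(pt.ThermalProtocol(), t) == pytest.approx(
            expected)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            pt.protocol_temperature(pt.ThermalProtocol(), -0.1)

    def test_peak_below_initial_rejected(self):
        with pytest.raises(InvalidParameterError):
            pt.ThermalProtocol(T_initial=37.0, T_peak=20.0)


def brute_force_assembly(grid, library, config):
    """Naive face-by-face reference assembler (dense, triple loops)."""
    lab = grid.labels
    nx, ny, nz = lab.shape
    solid = [(i, j, k) for i in range(nx) for j in range(ny)
             for k in range(nz) if lab[i, j, k] != pt.BACKGROUND]
    dof = {v: n for n, v in enumerate(solid)}
    n = len(solid)
    h = grid.voxel_size * 1e-3
    K = np.zeros((n, n))
    robin = np.zeros(n)
    for (i, j, k) in solid:
        ka = library[MATERIAL_FOR_LABEL[lab[i, j, k]]].conductivity
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            inside = 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
            if inside and lab[ni, nj, nk] != pt.BACKGROUND:
                kb = library[MATERIAL_FOR_LABEL[lab[ni, nj, nk]]].conductivity
                g = pt.interface_conductivity(ka, kb) * h * h / h
                a, b = dof[(i, j, k)], dof[(ni, nj, nk)]
                K[a, a] += g
                K[a, b] -= g
            else:
                # exterior face: convective only for enamel above cervical z
                z_face = (grid.origin[2] + (k + 0.5) * grid.voxel_size
                          + dk * grid.voxel_size / 2.0)
                if (lab[i, j, k] == pt.ENAMEL
                        and z_face >= grid.cervical_z):
                    robin[dof[(i, j, k)]] += (
                        config.convection_coefficient * h * h)
    return K, robin, dof


class TestAssembly:
    def test_two_voxel_bar_coupling(self, library):
        labels = np.full((2, 1, 1), pt.DENTIN, dtype=np.int8)
        g = pt.TissueLabelGrid(labels=labels, voxel_size=0.5, origin=(0, 0, 0))
        op = pt.assemble_operator(g, library, pt.SimulationConfig(),
                                  require_source=False)
        k = library["Dentin"].conductivity
        h = 0.5e-3
        expected = k * h * h / h
        K = op.conduction.toarray()
        assert K[0, 1] == pytest.approx(-expected)
        assert K[0, 0] == pytest.approx(expected)

    def test_conduction_rows_sum_to_zero(self, coarse_restored, library):
        op = pt.assemble_operator(coarse_restored, library,
                                  pt.SimulationConfig())
        rowsums = np.abs(op.conduction.sum(axis=1)).max()
        assert rowsums < 1e-12
        # symmetry
        diff = (op.conduction - op.conduction.T)
        assert abs(diff).max() < 1e-15

    def test_capacity_is_rho_c_volume(self, library):
        labels = np.full((1, 1, 1), pt.PULP, dtype=np.int8)
        g = pt.TissueLabelGrid(labels=labels, voxel_size=0.25, origin=(0, 0, 0))
        op = pt.assemble_operator(g, library, pt.SimulationConfig(),
                                  require_source=False)
        rho_c = library["Pulp"].volumetric_heat_capacity
        assert op.capacity[0] == pytest.approx(rho_c * (0.25e-3) ** 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, library, seed):
        rng = np.random.default_rng(seed)
        g = random_small_grid(rng)
        config = pt.SimulationConfig()
        op = pt.assemble_operator(g, library, config)
        K_ref, robin_ref, dof_ref = brute_force_assembly(g, library, config)
        # the fast path uses the same dof ordering (flat scan of solids)
        assert op.n_dof == len(dof_ref)
        np.testing.assert_allclose(op.conduction.toarray(), K_ref,
                                   rtol=1e-12, atol=1e-18)
        np.testing.assert_allclose(op.robin_diag, robin_ref,
                                   rtol=1e-12, atol=1e-18)

    def test_missing_material_is_configuration_error(self, coarse_restored):
        partial = pt.MaterialLibrary({
            "Enamel": pt.default_library()["Enamel"],
        })
        with pytest.raises(pt.PulpthermError, match="material"):
            pt.assemble_operator(coarse_restored, partial,
                                 pt.SimulationConfig())


class TestRunSimulation:
    def test_equilibrium_fixed_point(self, coarse_restored, library):
        protocol = pt.ThermalProtocol(T_initial=37.0, T_peak=37.0)
        config = pt.SimulationConfig(dt=0.5, total_time=15.0,
                                     store_fields_every=10)
        hist = pt.run_simulation(coarse_restored, library, protocol, config)
        for _, field in hist.snapshots:
            np.testing.assert_allclose(field, 37.0, atol=1e-9)

    def test_maximum_principle_full_field(self, coarse_restored, library):
        config = pt.SimulationConfig(dt=0.25, store_fields_every=1)
        hist = pt.run_simulation(coarse_restored, library,
                                 pt.ThermalProtocol(), config)
        for _, field in hist.snapshots:
            assert field.min() >= 37.0 - 1e-9
            assert field.max() <= 140.0 + 1e-9

    def test_pulp_heating_is_monotone(self, coarse_restored, library):
        config = pt.SimulationConfig(dt=0.25)
        hist = pt.run_simulation(coarse_restored, library,
                                 pt.ThermalProtocol(), config)
        pulp_max = hist.traces["pulp"]["max"]
        assert (np.diff(pulp_max) >= -1e-9).all()

    def test_field_mirror_symmetric_in_y(self, coarse_restored, library):
        """The default phantom and cavity are symmetric about y = 0, so the
        temperature field must be too."""
        config = pt.SimulationConfig(dt=0.5, store_fields_every=30)
        hist = pt.run_simulation(coarse_restored, library,
                                 pt.ThermalProtocol(), config)
        _, field = hist.snapshots[-1]
        full = np.full(coarse_restored.labels.size, np.nan)
        op_vox = np.flatnonzero(coarse_restored.labels.reshape(-1)
                                != pt.BACKGROUND)
        full[op_vox] = field
        vol = full.reshape(coarse_restored.shape)
        mirrored = vol[:, ::-1, :]
        mask = np.isfinite(vol)
        assert np.array_equal(mask, np.isfinite(mirrored))
        np.testing.assert_allclose(vol[mask], mirrored[mask], atol=1e-8)

    def test_cg_agrees_with_direct(self, coarse_restored, library):
        kw = dict(dt=0.5, total_time=15.0)
        h1 = pt.run_simulation(coarse_restored, library, pt.ThermalProtocol(),
                               pt.SimulationConfig(linear_solver="direct", **kw))
        h2 = pt.run_simulation(coarse_restored, library, pt.ThermalProtocol(),
                               pt.SimulationConfig(linear_solver="cg", **kw))
        np.testing.assert_allclose(h1.traces["pulp"]["max"],
                                   h2.traces["pulp"]["max"], atol=1e-4)

    def test_crank_nicolson_close_to_backward_euler(self, coarse_restored,
                                                    library):
        kw = dict(dt=0.05, total_time=15.0)
        be = pt.run_simulation(coarse_restored, library, pt.ThermalProtocol(),
                               pt.SimulationConfig(scheme="backward_euler", **kw))
        cn = pt.run_simulation(coarse_restored, library, pt.ThermalProtocol(),
                               pt.SimulationConfig(scheme="crank_nicolson", **kw))
        assert be.traces["pulp"]["max"][-1] == pytest.approx(
            cn.traces["pulp"]["max"][-1], abs=0.5)

    def test_dt_must_divide_total_time(self, coarse_restored, library):
        with pytest.raises(InvalidParameterError, match="divide"):
            pt.run_simulation(coarse_restored, library, pt.ThermalProtocol(),
                              pt.SimulationConfig(dt=0.4, total_time=15.0))

    def test_total_time_must_cover_protocol(self, coarse_restored, library):
        with pytest.raises(InvalidParameterError, match="cover"):
            pt.run_simulation(coarse_restored, library, pt.ThermalProtocol(),
                              pt.SimulationConfig(dt=0.5, total_time=10.0))

    def test_timestep_convergence_of_pulp_trace(self, coarse_restored,
                                                library):
        """Halving dt changes the end-time pulp temperature by a shrinking
        amount (first-order accuracy of backward Euler)."""
        ends = []
        for dt in (0.5, 0.25, 0.125):
            hist = pt.run_simulation(
                coarse_restored, library, pt.ThermalProtocol(),
                pt.SimulationConfig(dt=dt, total_time=15.0))
            ends.append(hist.traces["pulp"]["max"][-1])
        d1 = abs(ends[1] - ends[0])
        d2 = abs(ends[2] - ends[1])
        assert d2 < d1


class TestSensors:
    def test_constant_history_constant_traces(self, coarse_restored, library):
        protocol = pt.ThermalProtocol(T_initial=37.0, T_peak=37.0)
        hist = pt.run_simulation(coarse_restored, library, protocol,
                                 pt.SimulationConfig(dt=1.0))
        sensors = pt.sample_sensors(hist, coarse_restored)
        for tissue in sensors:
            for mode in ("max", "probe"):
                np.testing.assert_allclose(
                    sensors[tissue][mode].temperatures, 37.0, atol=1e-9)

    def test_max_trace_dominates_probe(self, coarse_restored, library):
        hist = pt.run_simulation(coarse_restored, library,
                                 pt.ThermalProtocol(),
                                 pt.SimulationConfig(dt=0.25))
        sensors = pt.sample_sensors(hist, coarse_restored)
        for tissue in sensors:
            assert (sensors[tissue]["max"].temperatures
                    >= sensors[tissue]["probe"].temperatures - 1e-12).all()

    def test_max_trace_equals_exhaustive_scan(self, coarse_restored, library):
        config = pt.SimulationConfig(dt=1.0, store_fields_every=1)
        hist = pt.run_simulation(coarse_restored, library,
                                 pt.ThermalProtocol(), config)
        labels_of_dof = coarse_restored.labels.reshape(-1)[
            np.flatnonzero(coarse_restored.labels.reshape(-1)
                           != pt.BACKGROUND)]
        for code, name in ((pt.PULP, "pulp"), (pt.DENTIN, "dentin")):
            scan = [field[labels_of_dof == code].max()
                    for _, field in hist.snapshots]
            np.testing.assert_allclose(hist.traces[name]["max"], scan,
                                       atol=1e-12)

    def test_missing_tissue_rejected(self, coarse_restored, library):
        hist = pt.run_simulation(coarse_restored, library,
                                 pt.ThermalProtocol(),
                                 pt.SimulationConfig(dt=1.0))
        del hist.traces["pulp"]
        with pytest.raises(MissingTissueError):
            pt.sample_sensors(hist, coarse_restored)


class TestAnalyticSolutions:
    def test_halfspace_erfc_agreement(self):
        err = transient_slab_error(voxel_size=0.1, dt=0.01, t_end=1.0)
        assert err < 0.02

    def test_steady_state_linear_profile(self):
        assert steady_state_error(n_cells=40) < 1e-8
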