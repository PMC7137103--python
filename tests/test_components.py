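import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xtalscale import components as cp
from xtalscale import models as md
from xtalscale.reflection_data import SweepMetadata, normalize_coordinates
from conftest import make_table


def brute_smooth_1d(params, first_position, x, V):
    """Independent oracle: full Gaussian-weighted sum over nearest 3."""
    positions = first_position + np.arange(len(params))
    idx = np.argsort(np.abs(positions - x))[:3]
    w = np.exp(-((x - positions[idx]) ** 2) / V)
    return float(np.sum(w * np.asarray(params)[idx]) / np.sum(w))


class TestSmooth1D:
    def test_constant_field(self):
        params = np.full(6, 3.7)
        for x in [0.0, 1.3, 2.5, 4.0]:
            v, _, _ = cp.eval_smooth_1d(params, -0.5, np.array([x]), 0.5)
            assert v[0] == pytest.approx(3.7)

    def test_matches_brute_force(self):
        params = np.array([1.0, 2.0, 3.0])
        x = -0.5 + 1.0  # at the middle parameter position
        v, _, _ = cp.eval_smooth_1d(params, -0.5, np.array([x]), 0.5)
        assert v[0] == pytest.approx(brute_smooth_1d(params, -0.5, x, 0.5))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 4.0), st.integers(0, 2 ** 31 - 1))
    def test_brute_force_at_random_points(self, x, seed):
        params = np.random.default_rng(seed).uniform(0.5, 2.0, 6)
        v, w, cols = cp.eval_smooth_1d(params, -0.5, np.array([x]), 0.5)
        assert v[0] == pytest.approx(brute_smooth_1d(params, -0.5, x, 0.5))
        assert w.sum() == pytest.approx(1.0)

    def test_invalid_variance(self):
        with pytest.raises(ValueError, match="V"):
            cp.eval_smooth_1d(np.ones(4), -0.5, np.array([1.0]), 0.0)

    def test_locality(self):
        """Perturbing one parameter only moves values within ~3 spacings."""
        params = np.ones(10)
        xs = np.linspace(0.0, 8.0, 81)
        v0, _, _ = cp.eval_smooth_1d(params, -0.5, xs, 0.5)
        params2 = params.copy()
        params2[4] += 1.0
        v1, _, _ = cp.eval_smooth_1d(params2, -0.5, xs, 0.5)
        changed = np.abs(v1 - v0) > 1e-12
        positions = -0.5 + 4.0
        assert np.all(np.abs(xs[changed] - positions) <= 3.0)


class TestLayout:
    @pytest.mark.parametrize("width,spacing,expected", [
        (360.0, 15.0, 26), (360.0, 20.0, 20), (90.0, 15.0, 8),
    ])
    def test_counts(self, width, spacing, expected):
        n, _ = cp.smooth_1d_layout(width, spacing)
        assert n == expected


class TestDecay:
    def _component(self, params):
        c = cp.SmoothBComponent(len(params), -0.5, 20.0)
        c.params = np.asarray(params, dtype=float)
        return c

    def test_null_decay(self):
        c = self._component([0.0, 0.0, 0.0, 0.0])
        t = make_table([1] * 3, [0] * 3, [0] * 3, [1] * 3, [1] * 3,
                       d=[1.0, 2.0, 5.0])
        t["t"] = [0.5, 1.0, 1.5]
        v, _ = c.values_and_derivatives(c.prepare(t))
        np.testing.assert_allclose(v, 1.0)

    def test_closed_form(self):
        # B(t) = 2 everywhere, d = 1 A -> exp(2/(2*1)) = e
        c = self._component([2.0, 2.0, 2.0, 2.0])
        t = make_table([1], [0], [0], [1], [1], d=[1.0])
        t["t"] = [1.0]
        v, _ = c.values_and_derivatives(c.prepare(t))
        assert v[0] == pytest.approx(np.e)

    def test_monotone_in_d(self):
        c = self._component([3.0, 3.0, 3.0, 3.0])
        d = np.array([1.0, 1.5, 2.0, 4.0])
        t = make_table([1] * 4, [0] * 4, [0] * 4, [1] * 4, [1] * 4, d=d)
        t["t"] = np.full(4, 1.0)
        v, _ = c.values_and_derivatives(c.prepare(t))
        assert np.all(np.diff(v) < 0)


class TestSphericalHarmonics:
    @pytest.mark.parametrize("lmax,expected", [(1, 3), (2, 8), (4, 24)])
    def test_coefficient_count(self, lmax, expected):
        assert cp.n_sph_coeffs(lmax) == expected
        assert cp.SphericalHarmonicComponent(lmax).n_params == expected

    def test_null_surface(self):
        c = cp.SphericalHarmonicComponent(4)
        rng = np.random.default_rng(3)
        v = rng.standard_normal((20, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        t = make_table([1] * 20, [0] * 20, [0] * 20, [1] * 20, [1] * 20)
        t[["s0cx", "s0cy", "s0cz"]] = v
        t[["s1cx", "s1cy", "s1cz"]] = v[::-1]
        val, _ = c.values_and_derivatives(c.prepare(t))
        np.testing.assert_allclose(val, 1.0)

    def test_direction_swap_symmetry(self):
        c = cp.SphericalHarmonicComponent(3)
        c.params = np.random.default_rng(5).standard_normal(c.n_params) * 0.1
        rng = np.random.default_rng(6)
        a = rng.standard_normal((10, 3))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b = rng.standard_normal((10, 3))
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        t1 = make_table([1] * 10, [0] * 10, [0] * 10, [1] * 10, [1] * 10)
        t1[["s0cx", "s0cy", "s0cz"]] = a
        t1[["s1cx", "s1cy", "s1cz"]] = b
        t2 = t1.copy()
        t2[["s0cx", "s0cy", "s0cz"]] = b
        t2[["s1cx", "s1cy", "s1cz"]] = a
        v1, _ = c.values_and_derivatives(c.prepare(t1))
        v2, _ = c.values_and_derivatives(c.prepare(t2))
        np.testing.assert_allclose(v1, v2, rtol=1e-12)


class TestArrayComponent:
    def _table(self, phi_norm, dprime):
        n = len(phi_norm)
        t = make_table([1] * n, [0] * n, [0] * n, [1] * n, [1] * n)
        t["phi_norm"] = phi_norm
        t["dprime"] = dprime
        t["xp"] = np.full(n, 0.5)
        t["yp"] = np.full(n, 0.5)
        return t

    def test_uniform_grid(self):
        c = cp.ArrayComponent("decay", (6, 4))
        c.params = np.full(c.n_params, 2.5)
        t = self._table(np.linspace(0, 1, 9), np.linspace(0, 1, 9))
        v, D = c.values_and_derivatives(c.prepare(t))
        np.testing.assert_allclose(v, 2.5)
        np.testing.assert_allclose(np.asarray(D.sum(axis=1)).ravel(), 1.0)

    def test_node_value_matches_brute_force(self):
        c = cp.ArrayComponent("decay", (6, 4))
        rng = np.random.default_rng(8)
        c.params = rng.uniform(0.5, 2.0, c.n_params)
        grid = c.params.reshape(6, 4)
        # coordinate hitting node (2, 1) exactly: u = norm*n - 0.5
        t = self._table([(2 + 0.5) / 6.0], [(1 + 0.5) / 4.0])
        v, _ = c.values_and_derivatives(c.prepare(t))
        w_tot, acc = 0.0, 0.0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                w = np.exp(-(di ** 2 + dj ** 2) / 0.5)
                acc += w * grid[2 + di, 1 + dj]
                w_tot += w
        assert v[0] == pytest.approx(acc / w_tot)

    def test_3d_weights_normalized(self):
        c = cp.ArrayComponent("absorption", (5, 5, 4))
        n = 7
        t = make_table([1] * n, [0] * n, [0] * n, [1] * n, [1] * n)
        rng = np.random.default_rng(9)
        t["xp"], t["yp"], t["phi_norm"] = (rng.uniform(0, 1, n)
                                           for _ in range(3))
        v, D = c.values_and_derivatives(c.prepare(t))
        np.testing.assert_allclose(v, 1.0)
        np.testing.assert_allclose(np.asarray(D.sum(axis=1)).ravel(), 1.0)


class TestModelAssembly:
    def test_identity_initialization(self, sweep360, sim_single_sweep):
        table, sweeps, truth = sim_single_sweep
        for mtype in ("physical", "kb", "array"):
            model = md.build_model(mtype, sweeps["sweep0"])
            t = model.normalize(table[:50], sweeps["sweep0"])
            g = model.inverse_scales(model.prepare(t))
            np.testing.assert_allclose(g, 1.0)

    @pytest.mark.parametrize("mtype", ["physical", "kb", "array"])
    def test_jacobian_matches_finite_differences(self, mtype,
                                                 sim_single_sweep):
        table, sweeps, _ = sim_single_sweep
        meta = sweeps["sweep0"]
        model = md.build_model(mtype, meta)
        t = model.normalize(table[:10], meta)
        rng = np.random.default_rng(11)
        x0 = model.parameters + rng.uniform(-0.05, 0.05, model.n_params)
        model.parameters = x0
        cache = model.prepare(t)
        g0, J = model.inverse_scales(cache, with_jacobian=True)
        J = J.toarray()
        eps = 1e-6
        # probe a subset of parameters for speed
        cols = rng.choice(model.n_params, size=min(25, model.n_params),
                          replace=False)
        for j in cols:
            xp = x0.copy()
            xp[j] += eps
            model.parameters = xp
            gp = model.inverse_scales(cache)
            xm = x0.copy()
            xm[j] -= eps
            model.parameters = xm
            gm = model.inverse_scales(cache)
            fd = (gp - gm) / (2 * eps)
            np.testing.assert_allclose(J[:, j], fd, atol=1e-5 * max(
                1.0, np.abs(fd).max()))

    def test_unused_parameter_has_zero_jacobian_column(self,
                                                       sim_single_sweep):
        table, sweeps, _ = sim_single_sweep
        meta = sweeps["sweep0"]
        model = md.build_model("physical", meta)
        sub = table[table["phi"] < 5.0][:20]  # start of sweep only
        t = model.normalize(sub, meta)
        _, J = model.inverse_scales(model.prepare(t), with_jacobian=True)
        col_norm = np.asarray(np.abs(J).sum(axis=0)).ravel()
        sl = model.component_slices()["scale"]
        assert np.all(col_norm[sl][-2:] == 0.0)  # far-end scale parameters

    def test_serialization_round_trip(self, sim_single_sweep):
        _, sweeps, _ = sim_single_sweep
        for mtype in ("physical", "kb", "array"):
            model = md.build_model(mtype, sweeps["sweep0"])
            model.parameters = np.random.default_rng(2).uniform(
                0.5, 1.5, model.n_params)
            clone = md.ScalingModel.from_dict(model.to_dict())
            np.testing.assert_array_equal(model.parameters, clone.parameters)
            assert clone.model_type == model.model_type
            assert clone.parameter_report() == model.parameter_report()


class TestDefaults:
    def test_physical_360_parameter_split(self, sweep360):
        rep = md.build_model("physical", sweep360).parameter_report()
        assert rep == {"scale": 26, "decay": 20, "absorption": 24,
                       "total": 70}

    def test_array_360_parameter_split(self, sweep360):
        rep = md.build_model("array", sweep360).parameter_report()
        assert rep["decay"] == 240 and rep["absorption"] == 500

    def test_kb_two_parameters(self, sweep360):
        assert md.build_model("kb", sweep360).n_params == 2

    def test_narrow_sweep_spacing(self):
        meta = SweepMetadata("n", 0.0, 8.0, 0.1)
        model = md.build_model("physical", meta)
        assert model.scale_spacing == pytest.approx(1.0)  # floor
        meta2 = SweepMetadata("n", 0.0, 20.0, 0.1)
        model2 = md.build_model("physical", meta2)
        assert model2.scale_spacing == pytest.approx(2.0)
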