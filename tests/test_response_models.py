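"""Surface evaluation, derivatives, curvature tests and the quadratic
reduction of the non-structural surface."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fertresp as fr
from fertresp.response_models import NumericError, tnfm_to_quadratic

from conftest import REF_TPFM


def _random_tpfm(rng) -> fr.TPFMParams:
    return fr.TPFMParams(*rng.normal(0, 1, 10))


class TestTnfmPredict:
    def test_reference_value_at_origin(self, site1_params):
        # A * N0 * P0 * K0 for the site-1 reference parameters
        assert fr.tnfm_predict(site1_params, (0, 0, 0)) == pytest.approx(4335, abs=1)

    def test_zero_soil_supply_zero_yield(self):
        p = fr.TNFMParams(1e-3, 0.0, 100.0, 100.0, 1e-3, 1e-3, 1e-3)
        assert fr.tnfm_predict(p, (0, 40, 70)) == 0.0

    def test_zero_whenever_any_factor_vanishes(self, site1_params):
        s = site1_params
        for i, name in enumerate(("n0", "p0", "k0")):
            p = fr.TNFMParams(**{**s.to_dict(), name: 0.0})
            point = [10.0, 10.0, 10.0]
            point[i] = 0.0
            assert fr.tnfm_predict(p, point) == 0.0

    def test_vectorized_evaluation(self, site1_params, trials):
        pts = trials[1].rates()
        vals = fr.tnfm_predict(site1_params, pts)
        assert vals.shape == (14,)
        assert vals[0] == fr.tnfm_predict(site1_params, pts[0])

    def test_exponent_guard(self, site1_params):
        with pytest.raises(NumericError):
            fr.tnfm_predict(site1_params, (1e9, 0, 0))

    def test_maximum_point_beats_dense_grid(self, site1_params):
        point, ymax = fr.tnfm_max_rates(site1_params)
        ax = np.linspace(0, 250, 60)
        grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        grid_max = float(np.max(fr.tnfm_predict(site1_params, grid)))
        assert ymax >= grid_max
        assert ymax == pytest.approx(grid_max, rel=1e-3)


class TestTpfmPredictAndGradient:
    def test_degenerate_surfaces(self):
        zero = fr.TPFMParams(*[0.0] * 10)
        assert fr.tpfm_predict(zero, (10, 20, 30)) == 0.0
        flat = fr.TPFMParams(5000, *[0.0] * 9)
        assert fr.tpfm_predict(flat, (123, 4, 56)) == 5000.0

    def test_reference_intercept(self):
        p = fr.TPFMParams(*REF_TPFM[1]["b"])
        assert fr.tpfm_predict(p, (0, 0, 0)) == pytest.approx(4337, abs=0.5)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(42)
        h = 1e-5
        for _ in range(20):
            p = _random_tpfm(rng)
            x = rng.uniform(0, 200, 3)
            g = fr.tpfm_gradient(p, x)
            for i in range(3):
                e = np.zeros(3)
                e[i] = h
                fd = (fr.tpfm_predict(p, x + e) - fr.tpfm_predict(p, x - e)) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_linear_surface_has_constant_gradient(self):
        p = fr.TPFMParams(100, 1.5, -2.0, 3.0, 0, 0, 0, 0, 0, 0)
        for x in [(0, 0, 0), (50, 60, 70)]:
            np.testing.assert_allclose(fr.tpfm_gradient(p, x), [1.5, -2.0, 3.0])

    def test_gradient_vanishes_at_critical_point(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = _random_tpfm(rng)
            cp = fr.tpfm_critical_point(p)
            if cp is None:
                continue
            g = fr.tpfm_gradient(p, cp)
            scale = max(abs(p.b1), abs(p.b2), abs(p.b3), 1.0)
            assert np.max(np.abs(g)) < 1e-8 * scale


class TestHessianMinors:
    @pytest.mark.parametrize(
        ("quad", "expected"),
        [((-1, -1, -1), (-2, 4, -8)), ((1, 1, 1), (2, 4, 8))],
    )
    def test_diagonal_patterns(self, quad, expected):
        p = fr.TPFMParams(0, 0, 0, 0, *quad, 0, 0, 0)
        assert fr.tpfm_hessian_minors(p) == pytest.approx(expected)

    def test_minor_signs_match_eigenvalues(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            p = _random_tpfm(rng)
            g1, g2, g3 = fr.tpfm_hessian_minors(p)
            eig = np.linalg.eigvalsh(fr.tpfm_hessian(p))
            negdef = bool(np.all(eig < 0))
            assert (g1 < 0 and g2 > 0 and g3 < 0) == negdef


class TestCriticalPoint:
    def test_decoupled_parabolas(self):
        p = fr.TPFMParams(0, 2, 2, 2, -1, -1, -1, 0, 0, 0)
        assert fr.tpfm_critical_point(p) == pytest.approx((1, 1, 1))

    def test_no_curvature_is_singular(self):
        p = fr.TPFMParams(10, 1, 2, 3, 0, 0, 0, 0, 0, 0)
        assert fr.tpfm_critical_point(p) is None

    def test_fitted_surface_critical_point_matches_grid(self, tpfm_fits):
        p = tpfm_fits[1].params
        cp = fr.tpfm_critical_point(p)
        g = fr.tpfm_gradient(p, cp)
        assert np.max(np.abs(g)) < 1e-8
        ax = np.arange(0, 250, 2.0)
        grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        vals = fr.tpfm_predict(p, grid)
        idx = np.unravel_index(np.argmax(vals), vals.shape)
        argmax = [float(a[i]) for a, i in zip((ax, ax, ax), idx)]
        assert np.max(np.abs(np.array(argmax) - np.array(cp))) <= 2.0


class TestQuadraticReduction:
    def test_unit_parameters_reduce_exactly(self):
        p = fr.TNFMParams(1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0)
        q = tnfm_to_quadratic(p)
        assert q.b0 == 1.0
        assert (q.b1, q.b2, q.b3) == (1.0, 1.0, 1.0)
        assert (q.b4, q.b5, q.b6) == (0.0, 0.0, 0.0)
        assert (q.b7, q.b8, q.b9) == (1.0, 1.0, 1.0)

    def test_matches_independent_term_expansion(self, site1_params):
        """The reduction equals the ten-term truncated expansion written
        out independently, term by term."""
        a, n0, p0, k0, c1, c2, c3 = site1_params.as_array()
        bb, cc, dd = 1 - n0 * c1, 1 - p0 * c2, 1 - k0 * c3
        rng = np.random.default_rng(0)
        q = tnfm_to_quadratic(site1_params)
        for _ in range(20):
            n, p, k = rng.uniform(0, 200, 3)
            direct = a * (
                n0 * p0 * k0
                + bb * p0 * k0 * n + cc * n0 * k0 * p + dd * n0 * p0 * k
                - c1 * p0 * k0 * n**2 - c2 * n0 * k0 * p**2 - c3 * n0 * p0 * k**2
                + bb * cc * k0 * n * p + bb * dd * p0 * n * k + cc * dd * n0 * p * k
            )
            assert fr.tpfm_predict(q, (n, p, k)) == pytest.approx(direct, rel=1e-12)

    def test_agreement_in_small_rate_limit(self, site1_params):
        """The truncation error vanishes as rates shrink relative to 1/c."""
        q = tnfm_to_quadratic(site1_params)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 5, (50, 3))  # c*x ~ 0.02: truncation negligible
        y_full = fr.tnfm_predict(site1_params, pts)
        y_quad = fr.tpfm_predict(q, pts)
        assert np.max(np.abs(y_quad / y_full - 1)) < 1e-3

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(1e-5, 1e-2),
        n0=st.floats(10, 500), p0=st.floats(10, 500), k0=st.floats(10, 500),
        c1=st.floats(1e-4, 1e-2), c2=st.floats(1e-4, 1e-2), c3=st.floats(1e-4, 1e-2),
    )
    def test_pure_quadratic_terms_always_negative(self, a, n0, p0, k0, c1, c2, c3):
        q = tnfm_to_quadratic(fr.TNFMParams(a, n0, p0, k0, c1, c2, c3))
        assert q.b4 < 0 and q.b5 < 0 and q.b6 < 0


class TestAllPositiveSurfaceShape:
    def test_interior_maximum_dominates_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = fr.TNFMParams(
                a=rng.uniform(1e-4, 2e-3),
                n0=rng.uniform(50, 300), p0=rng.uniform(50, 300),
                k0=rng.uniform(50, 300),
                c1=rng.uniform(1e-3, 6e-3), c2=rng.uniform(1e-3, 6e-3),
                c3=rng.uniform(1e-3, 6e-3),
            )
            point, ymax = fr.tnfm_max_rates(p)
            hi = 2 / min(p.c1, p.c2, p.c3)
            ax = np.linspace(0, hi, 50)
            grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
            assert float(np.max(fr.tnfm_predict(p, grid))) <= ymax + 1e-9


def test_params_json_round_trip(site1_params):
    d = site1_params.to_dict()
    assert fr.TNFMParams.from_dict(d) == site1_params
    q = fr.TPFMParams(*REF_TPFM[2]["b"])
    assert fr.TPFMParams.from_dict(q.to_dict()) == q
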