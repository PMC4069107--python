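"""Circular statistics: regression, correlations, Rayleigh, model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridphase import circstats as cs


def brute_force_slope(x, phi, bounds=(-60.0, 60.0), step=0.01):
    """Independent oracle: exhaustive resultant maximization on a fine grid."""
    grid = np.arange(bounds[0], bounds[1] + step / 2, step)
    R = cs.resultant_length(grid, x, phi)
    best = R.max()
    cand = np.flatnonzero(R >= best - 1e-12)
    return grid[cand[np.argmin(np.abs(grid[cand]))]]


class TestCircularLinearFit:
    def test_noiseless_precession_recovered_exactly(self):
        x = np.arange(0.0, 21.0, 2.0)
        phi = (180.0 - 10.0 * x) % 360.0
        f = cs.fit_circular_linear(x, phi)
        assert f.slope == pytest.approx(-10.0, abs=1e-5)
        assert f.resultant == pytest.approx(1.0, abs=1e-9)
        assert f.offset_deg == pytest.approx(180.0, abs=1e-4)
        assert f.r == pytest.approx(-1.0, abs=1e-9)

    def test_constant_phase_gives_zero_slope(self):
        x = np.linspace(0, 30, 12)
        f = cs.fit_circular_linear(x, np.full(12, 77.0))
        assert f.slope == pytest.approx(0.0, abs=1e-6)
        assert f.resultant == pytest.approx(1.0, abs=1e-12)

    def test_tie_break_prefers_smaller_slope_magnitude(self):
        # R(m)=1 at m=0 and at m=+-60 (x spacing 6 cm aliases 360 deg)
        f = cs.fit_circular_linear(np.array([0.0, 6.0]), np.array([0.0, 0.0]))
        assert f.slope == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(5, 31)
            x = rng.uniform(0, 30, n)
            phi = rng.uniform(0, 360, n)
            f = cs.fit_circular_linear(x, phi)
            m_oracle = brute_force_slope(x, phi)
            assert abs(f.slope - m_oracle) < 0.05

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cs.fit_circular_linear([1.0], [10.0])
        with pytest.raises(ValueError):
            cs.fit_circular_linear([2.0, 2.0, 2.0], [10.0, 20.0, 30.0])

    def test_bound_hit_flagged(self):
        x = np.arange(0.0, 5.0, 0.5)
        phi = (100.0 - 59.9 * x) % 360.0
        f = cs.fit_circular_linear(x, phi, bounds=(-50.0, 50.0))
        assert f.bound_hit

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scale_equivariance(self, seed):
        """Fitting x in meters instead of cm rescales m by 100; r unchanged."""
        rng = np.random.default_rng(seed)
        n = 20
        x = rng.uniform(0, 40, n)
        phi = (300.0 - 7.0 * x + rng.normal(0, 20, n)) % 360.0
        f_cm = cs.fit_circular_linear(x, phi, bounds=(-60, 60))
        f_m = cs.fit_circular_linear(x / 100.0, phi, bounds=(-6000, 6000), grid_step=10.0)
        assert f_m.slope == pytest.approx(100.0 * f_cm.slope, abs=0.2)
        assert f_m.r == pytest.approx(f_cm.r, abs=1e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-720, 720))
    def test_rotation_invariance(self, seed, shift):
        """Adding a constant to all phases changes only the offset."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 30, 15)
        phi = (100.0 - 9.0 * x + rng.normal(0, 15, 15)) % 360.0
        f0 = cs.fit_circular_linear(x, phi)
        f1 = cs.fit_circular_linear(x, (phi + shift) % 360.0)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-3)
        assert f1.r == pytest.approx(f0.r, abs=1e-6)
        assert f1.offset_deg % 360.0 == pytest.approx(
            (f0.offset_deg + shift) % 360.0, abs=0.1
        ) or abs((f1.offset_deg - f0.offset_deg - shift) % 360.0) < 0.1


class TestCircLinearCorrelation:
    def test_perfect_association(self):
        x = np.arange(0.0, 21.0, 2.0)
        phi = (180.0 - 10.0 * x) % 360.0
        r, p = cs.circ_linear_correlation(x, phi, -10.0)
        assert r == pytest.approx(-1.0, abs=1e-9)
        assert p < 0.05

    def test_minimal_n_contract(self):
        r, p = cs.circ_linear_correlation([0.0, 1.0, 2.0], [10.0, 50.0, 90.0], 40.0)
        assert -1 <= r <= 1 and 0 <= p <= 1

    def test_degenerate_denominator_returns_zero(self):
        r, p = cs.circ_linear_correlation([0.0, 1.0, 2.0], [30.0, 30.0, 30.0], 0.0)
        assert r == 0.0 and p == 1.0

    def test_analytic_p_matches_permutation_oracle(self):
        """Under independence, analytic p within factor 2 of permutation p."""
        rng = np.random.default_rng(7)
        n = 200
        x = rng.uniform(0, 30, n)
        phi = rng.uniform(0, 360, n)
        f = cs.fit_circular_linear(x, phi)
        assert abs(f.r) < 0.15
        n_perm = 10_000
        perm_r = np.empty(n_perm)
        for i in range(n_perm):
            perm_r[i] = cs.circ_linear_correlation(
                x, rng.permutation(phi), f.slope
            )[0]
        p_perm = (np.sum(np.abs(perm_r) >= abs(f.r)) + 1) / (n_perm + 1)
        assert 0.5 * p_perm <= f.p_value <= 2.0 * p_perm

    def test_type_one_error_calibrated(self):
        """Empirical false-positive rate at nominal 0.05 stays in [0.03, 0.07].

        Calibration concerns the correlation test at a given slope mapping;
        selecting the slope by resultant maximization first is a separate
        (anti-conservative) two-stage procedure.
        """
        rng = np.random.default_rng(123)
        for n in (10, 30, 100):
            n_rep = 1500
            hits = 0
            for _ in range(n_rep):
                x = rng.uniform(0, 30, n)
                phi = rng.uniform(0, 360, n)
                _, p = cs.circ_linear_correlation(x, phi, -8.0)
                hits += p < 0.05
            assert 0.03 <= hits / n_rep <= 0.07, f"n={n}: {hits / n_rep}"


class TestLinearCircularCorrelation:
    def test_perfect_cosine_relation(self):
        a = np.linspace(0, 350, 36)
        dc = cs.linear_circular_correlation(a, np.cos(np.radians(a)))
        assert dc.correlation == pytest.approx(1.0, abs=1e-9)
        assert dc.p_value < 1e-6

    def test_constant_values_give_zero(self):
        dc = cs.linear_circular_correlation([10, 100, 250, 300], [2.0, 2.0, 2.0, 2.0])
        assert dc.correlation == 0.0

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 360, 50)
        v = np.cos(np.radians(a)) + rng.normal(0, 0.5, 50)
        dc = cs.linear_circular_correlation(a, v)
        r_pg, p_pg = pingouin.circ_corrcl(np.radians(a), v)
        assert dc.correlation == pytest.approx(r_pg, abs=1e-9)
        assert dc.p_value == pytest.approx(p_pg, rel=1e-6)

    def test_null_rate_about_five_percent(self):
        """With values independent of angles, ~5% of fields are significant."""
        rng = np.random.default_rng(11)
        n_fields = 1000
        sig = 0
        for _ in range(n_fields):
            n = rng.integers(5, 15)
            dc = cs.linear_circular_correlation(
                rng.uniform(0, 360, n), rng.normal(size=n)
            )
            sig += dc.p_value < 0.05
        # binomial 99% interval around 0.05 for n=1000
        assert 0.032 <= sig / n_fields <= 0.072


class TestRayleigh:
    def test_concentrated_and_antipodal(self):
        vs, _ = cs.rayleigh_test([42.0, 42.0, 42.0])
        assert vs == pytest.approx(1.0, abs=1e-12)
        vs0, p0 = cs.rayleigh_test([0.0, 180.0])
        assert vs0 == pytest.approx(0.0, abs=1e-12)
        assert p0 > 0.5

    def test_von_mises_vector_strength(self):
        from scipy import special

        rng = np.random.default_rng(21)
        draws = np.degrees(rng.vonmises(0.0, 1.0, 500))
        vs, p = cs.rayleigh_test(draws)
        expected = special.i1(1.0) / special.i0(1.0)  # ~0.446
        assert vs == pytest.approx(expected, abs=0.06)
        assert p < 1e-6

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        ph = rng.vonmises(1.0, 0.8, 80)
        _, p = cs.rayleigh_test(np.degrees(ph))
        _, p_pg = pingouin.circ_rayleigh(ph)
        assert p == pytest.approx(p_pg, rel=0.01)


class TestModelComparisonAnova:
    def test_detects_the_informative_predictor(self):
        rng = np.random.default_rng(2)
        n = 200
        preds = {k: rng.normal(size=n) for k in ("length", "tort", "ecc", "speed")}
        y = 2.0 * preds["length"] + rng.normal(0, 1, n)
        ps = cs.model_comparison_anova(y, preds)
        assert ps["length"] < 1e-6
        assert all(ps[k] > 0.001 for k in ("tort", "ecc", "speed"))

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            preds = {k: rng.normal(size=60) for k in "abcd"}
            y = rng.normal(size=60)
            pvals.extend(cs.model_comparison_anova(y, preds).values())
        pvals = np.asarray(pvals)
        assert 0.4 < pvals.mean() < 0.6
        assert 0.03 < np.mean(pvals < 0.05) < 0.08

    def test_constant_predictor_gives_p_one(self):
        rng = np.random.default_rng(6)
        n = 50
        preds = {"a": rng.normal(size=n), "b": np.ones(n)}
        y = preds["a"] + rng.normal(0, 0.1, n)
        with pytest.warns(UserWarning):
            ps = cs.model_comparison_anova(y, preds)
        assert ps["b"] == pytest.approx(1.0)


class TestModelFrontend:
    def test_results_object_and_summary(self):
        import pandas as pd

        x = np.arange(0.0, 25.0, 2.5)
        df = pd.DataFrame(
            {"distance_cm": x, "phase_deg": (200.0 - 8.0 * x) % 360.0}
        )
        res = cs.PhasePrecession.from_dataframe(df).fit()
        assert res.slope == pytest.approx(-8.0, abs=1e-4)
        assert "slope" in res.summary()
        pred = res.predict([0.0, 10.0])
        assert pred[0] == pytest.approx(200.0, abs=1e-3)
        assert pred[1] == pytest.approx(120.0, abs=1e-2)
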