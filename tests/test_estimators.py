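"""MR estimators: worked examples, oracle equivalences, equivariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protmr import (
    MRInput,
    cochran_q,
    ivw,
    max_likelihood,
    mr_egger,
    penalized_weighted_median,
    run_mr_suite,
    wald_ratio,
    weighted_median,
)
from protmr.reference import egger_normal_equations, ivw_wls_origin


def mk_input(bx, by, sx=None, sy=None, **kw):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, float)
    sy = np.full_like(bx, 0.01) if sy is None else np.asarray(sy, float)
    defaults = dict(protein_id="p", variant_ids=[f"rs{i}" for i in range(len(bx))],
                    n_exposure=30_000, n_outcome=500_000)
    defaults.update(kw)
    return MRInput(bx=bx, sx=sx, by=by, sy=sy, **defaults)


class TestWald:
    def test_ratio_and_delta_se(self):
        est = wald_ratio(0.5, 0.01, -0.1, 0.02)
        assert est.theta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.04)
        assert est.or_ == pytest.approx(np.exp(-0.2))
        assert est.ci_low == pytest.approx(np.exp(-0.2 - 1.959964 * 0.04), rel=1e-6)

    def test_zero_outcome_effect(self):
        est = wald_ratio(0.5, 0.01, 0.0, 0.02)
        assert est.theta == 0.0 and est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestCochranQ:
    def test_hand_computed_value(self):
        q, df, p = cochran_q([0.2, 0.4], [0.1, 0.2], 0.24)
        assert q == pytest.approx(0.8)  # 100*0.04^2*... = 0.16 + 0.64
        assert df == 1

    def test_identical_ratios_give_zero(self):
        q, _, p = cochran_q([0.3, 0.3, 0.3], [0.1, 0.2, 0.1], 0.3)
        assert q == 0.0 and p == pytest.approx(1.0)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            cochran_q([0.2], [0.1], 0.2)


class TestIVW:
    def test_weighted_mean_worked_example(self):
        # ratios 0.2 (se 0.1) and 0.4 (se 0.2): theta 0.24, se 1/sqrt(125)
        inp = mk_input([1.0, 1.0], [0.2, 0.4], sy=[0.1, 0.2])
        est = ivw(inp)
        assert est.theta == pytest.approx(0.24)
        assert est.se == pytest.approx(125**-0.5)
        assert est.model == "fixed" and est.q_stat == pytest.approx(0.8)

    def test_duplicating_instruments_shrinks_se_by_sqrt2(self):
        inp1 = mk_input([1.0, 1.0], [0.2, 0.4], sy=[0.1, 0.2])
        inp2 = mk_input([1.0] * 4, [0.2, 0.4, 0.2, 0.4], sy=[0.1, 0.2, 0.1, 0.2])
        a, b = ivw(inp1), ivw(inp2, model="fixed")
        assert b.theta == pytest.approx(a.theta)
        assert b.se == pytest.approx(a.se / np.sqrt(2))

    def test_heterogeneity_switches_to_random_and_inflates(self):
        inp = mk_input([1.0, 1.0, 1.0], [0.0, 0.5, 1.0], sy=[0.02, 0.02, 0.02])
        auto = ivw(inp, model="auto")
        fixed = ivw(inp, model="fixed")
        assert auto.q_pvalue < 0.05 and auto.model == "random"
        assert auto.se >= fixed.se
        assert auto.se == pytest.approx(fixed.se * np.sqrt(auto.q_stat / auto.q_df))

    def test_equals_wls_through_origin(self, random_mr_input):
        for seed in range(30):
            inp = random_mr_input(k=8, seed=seed)
            est = ivw(inp, model="fixed")
            theta_ref, se_ref = ivw_wls_origin(inp)
            assert abs(est.theta - theta_ref) < 1e-10
            assert abs(est.se - se_ref) < 1e-10

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError, match="wald"):
            ivw(mk_input([1.0], [0.2]))


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inp = mk_input(bx, 0.05 + 0.3 * bx, sy=[0.01, 0.02, 0.01, 0.02])
        est = mr_egger(inp)
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert est.theta == pytest.approx(0.3, abs=1e-10)
        assert est.q_stat == pytest.approx(0.0, abs=1e-16)
        assert est.q_df == 2

    def test_no_pleiotropy_zero_intercept(self):
        bx = np.array([0.1, 0.25, 0.4])
        est = mr_egger(mk_input(bx, 0.3 * bx))
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, random_mr_input):
        for seed in range(30):
            inp = random_mr_input(k=10, seed=seed)
            est = mr_egger(inp)
            i_ref, s_ref = egger_normal_equations(inp)
            assert abs(est.egger_intercept - i_ref) < 1e-10
            assert abs(est.theta - s_ref) < 1e-10

    def test_orientation_invariant_to_bx_sign_flips(self, random_mr_input):
        inp = random_mr_input(k=6, seed=0)
        flipped = mk_input(-inp.bx, -inp.by, sx=inp.sx, sy=inp.sy)
        a, b = mr_egger(inp), mr_egger(flipped)
        assert a.theta == pytest.approx(b.theta)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(mk_input([0.1, 0.2], [0.03, 0.06]))


class TestWeightedMedian:
    def test_breakpoint_interpolation_example(self):
        # equal weights, ratios {0.1, 0.2, 0.9}: s2 = 0.5 exactly -> 0.2
        est = weighted_median(mk_input([1, 1, 1], [0.1, 0.2, 0.9]), n_boot=50, seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_constant_ratios_recovered_with_small_se(self):
        est = weighted_median(mk_input([1, 1, 1, 1], [0.3, 0.3, 0.3, 0.3]),
                              n_boot=200, seed=1)
        assert est.theta == pytest.approx(0.3)
        assert est.se < 0.05

    def test_robust_to_single_wild_outlier(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.2, 0.4, 10)
        by = 0.25 * bx
        by[0] = 5.0  # wildly invalid instrument
        est = weighted_median(mk_input(bx, by, sy=np.full(10, 0.01)),
                              n_boot=500, seed=2)
        assert abs(est.theta - 0.25) < 2 * est.se

    def test_bootstrap_se_is_seed_deterministic(self):
        inp = mk_input([1, 1, 1], [0.1, 0.2, 0.9])
        a = weighted_median(inp, n_boot=100, seed=7)
        b = weighted_median(inp, n_boot=100, seed=7)
        c = weighted_median(inp, n_boot=100, seed=8)
        assert a.se == b.se and a.se != c.se


class TestPenalizedWeightedMedian:
    def test_inactive_penalty_equals_weighted_median(self):
        inp = mk_input([1, 1, 1, 1], [0.29, 0.3, 0.31, 0.3], sy=np.full(4, 0.05))
        wm = weighted_median(inp, n_boot=50, seed=3)
        pwm = penalized_weighted_median(inp, n_boot=50, seed=3)
        assert pwm.theta == pytest.approx(wm.theta)

    def test_outlier_is_downweighted(self):
        from protmr.estimators import _penalized_weights, _ratios
        inp = mk_input(np.full(6, 1.0), [0.3, 0.3, 0.3, 0.3, 0.3, 3.0],
                       sy=np.full(6, 0.01))
        ratios, rse = _ratios(inp)
        w = 1.0 / rse**2
        w_pen = _penalized_weights(ratios[None, :], w[None, :], 20.0)[0]
        assert w_pen[-1] < w[-1]
        assert np.allclose(w_pen[:3], w[:3])

    def test_matches_two_pass_reference(self, random_mr_input):
        from protmr.reference import weighted_median_two_pass
        for seed in range(20):
            inp = random_mr_input(k=9, seed=seed)
            ratios = inp.by / inp.bx
            weights = (inp.bx / inp.sy) ** 2
            est = penalized_weighted_median(inp, n_boot=2, seed=0)
            ref = weighted_median_two_pass(ratios, weights, penalty=20.0)
            assert est.theta == pytest.approx(ref, abs=1e-12)


class TestMaxLikelihood:
    def test_tiny_exposure_noise_limit_equals_ivw(self, random_mr_input):
        inp = random_mr_input(k=8, seed=5)
        inp_limit = mk_input(inp.bx, inp.by, sx=np.full(inp.k, 1e-8), sy=inp.sy)
        assert abs(max_likelihood(inp_limit).theta - ivw(inp_limit).theta) < 1e-6

    def test_single_instrument_reduces_to_wald(self):
        est = max_likelihood(mk_input([0.5], [0.1], sx=[0.01], sy=[0.02]))
        assert est.theta == pytest.approx(0.2, abs=1e-8)

    def test_noiseless_proportionality_recovered(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.4, 12)
        by = 0.27 * bx + rng.normal(0, 1e-5, 12)
        est = max_likelihood(mk_input(bx, by, sx=np.full(12, 1e-4),
                                      sy=np.full(12, 1e-4)))
        assert est.theta == pytest.approx(0.27, abs=1e-3)


class TestSuiteDispatch:
    def test_single_instrument_wald_only(self):
        out = run_mr_suite(mk_input([0.5], [0.1], sx=[0.01], sy=[0.02]))
        assert [e.method for e in out] == ["wald_ratio"]
        assert out[0].primary

    def test_two_instruments_no_egger(self):
        out = run_mr_suite(mk_input([0.5, 0.4], [0.1, 0.09], sy=[0.02, 0.02]))
        assert [e.method for e in out] == ["ivw", "max_likelihood"]

    def test_four_instruments_full_suite_primary_ivw(self, random_mr_input):
        out = run_mr_suite(random_mr_input(k=4, seed=2), n_boot=50)
        assert [e.method for e in out] == [
            "ivw", "max_likelihood", "mr_egger", "weighted_median",
            "penalized_weighted_median"]
        assert out[0].primary and not any(e.primary for e in out[1:])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_sign_equivariance(seed):
    """Negating all outcome effects negates every theta and fixes SEs/Q/p."""
    rng = np.random.default_rng(seed)
    k = 6
    bx = rng.uniform(0.1, 0.4, k)
    inp = mk_input(bx, 0.2 * bx + rng.normal(0, 0.01, k),
                   sx=rng.uniform(0.005, 0.02, k), sy=rng.uniform(0.005, 0.02, k))
    neg = mk_input(inp.bx, -inp.by, sx=inp.sx, sy=inp.sy)
    for f in (lambda i: ivw(i), lambda i: mr_egger(i), lambda i: max_likelihood(i),
              lambda i: weighted_median(i, n_boot=30, seed=1),
              lambda i: penalized_weighted_median(i, n_boot=30, seed=1)):
        a, b = f(inp), f(neg)
        assert b.theta == pytest.approx(-a.theta, abs=1e-8)
        assert b.se == pytest.approx(a.se, rel=1e-6)
        assert b.pvalue == pytest.approx(a.pvalue, rel=1e-6)
        if a.q_stat is not None:
            assert b.q_stat == pytest.approx(a.q_stat, rel=1e-8)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.floats(0.25, 4.0))
def test_scale_equivariance(seed, c):
    """Rescaling the exposure (bx, sx times c) divides theta by c."""
    rng = np.random.default_rng(seed)
    k = 5
    bx = rng.uniform(0.1, 0.4, k)
    inp = mk_input(bx, 0.2 * bx + rng.normal(0, 0.01, k),
                   sx=rng.uniform(0.005, 0.02, k), sy=rng.uniform(0.005, 0.02, k))
    scaled = mk_input(c * inp.bx, inp.by, sx=c * inp.sx, sy=inp.sy)
    for f in (lambda i: ivw(i), lambda i: max_likelihood(i),
              lambda i: weighted_median(i, n_boot=30, seed=1)):
        assert f(scaled).theta == pytest.approx(f(inp).theta / c, rel=1e-5)
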