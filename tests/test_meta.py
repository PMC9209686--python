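import math

import numpy as np
import pytest
from scipy import stats

from sjstar.meta import (
    ContinuousStudy,
    TwoByTwo,
    log_odds_ratio,
    paule_mandel_tau2,
    pool_binary,
    pool_continuous,
    q_profile_ci,
    smd_study,
)
from sjstar.metrics import hedges_correction


def _pm_grid_oracle(effects, variances, lo=0.0, hi=10.0, steps=2_000_001):
    """Independent grid-search solution of the Paule–Mandel equation."""
    y = np.asarray(effects)
    v = np.asarray(variances)
    k = len(y)
    grid = np.linspace(lo, hi, steps)
    best, best_err = 0.0, float("inf")
    for tau2 in grid:
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        err = abs((w * (y - mu) ** 2).sum() - (k - 1))
        if err < best_err:
            best, best_err = tau2, err
    return best


def test_single_study_or_and_no_heterogeneity():
    res = pool_binary([TwoByTwo(10, 20, 5, 20)])
    assert res.pooled_or == pytest.approx(3.0, rel=1e-12)
    assert res.fixed == pytest.approx(math.log(3.0), rel=1e-12)
    assert res.tau2 == 0.0
    assert res.tau2_ci is None
    assert res.weights == (1.0,)


def test_zero_cell_continuity_correction():
    y, v = log_odds_ratio(TwoByTwo(0, 10, 5, 10))
    assert math.exp(y) == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-12)
    assert math.exp(y) == pytest.approx(1 / 21, rel=1e-12)
    # correction applies only to zero-cell studies
    y2, _ = log_odds_ratio(TwoByTwo(10, 20, 5, 20))
    assert math.exp(y2) == pytest.approx(3.0, rel=1e-12)


def test_identical_studies_pool_to_single_estimate():
    study = TwoByTwo(12, 30, 6, 30)
    single = pool_binary([study])
    multi = pool_binary([study] * 4)
    assert multi.pooled == pytest.approx(single.pooled, abs=1e-10)
    assert multi.tau2 == 0.0
    assert (multi.ci_high - multi.ci_low) < (single.ci_high - single.ci_low)


def test_doubling_studies_preserves_estimate_and_narrows_ci():
    studies = [TwoByTwo(12, 30, 6, 30), TwoByTwo(20, 60, 15, 55),
               TwoByTwo(8, 25, 9, 28)]
    once = pool_binary(studies)
    twice = pool_binary(studies * 2)
    assert twice.pooled == pytest.approx(once.pooled, abs=1e-6)
    assert (twice.ci_high - twice.ci_low) < (once.ci_high - once.ci_low)


def test_pooled_estimate_within_convex_hull():
    studies = [TwoByTwo(12, 30, 6, 30), TwoByTwo(5, 40, 12, 38),
               TwoByTwo(22, 50, 14, 50)]
    res = pool_binary(studies)
    assert min(res.effects) <= res.pooled <= max(res.effects)
    assert sum(res.weights) == pytest.approx(1.0, abs=1e-12)


def test_paule_mandel_matches_grid_search_oracle():
    effects, variances = [0.0, 2.0], [1.0, 1.0]
    pm = paule_mandel_tau2(effects, variances)
    oracle = _pm_grid_oracle(effects, variances)
    assert pm.converged
    assert pm.tau2 == pytest.approx(oracle, abs=1e-5)
    # residual of the defining equation at the solution
    y, v = np.array(effects), np.array(variances)
    w = 1 / (v + pm.tau2)
    mu = (w * y).sum() / w.sum()
    assert (w * (y - mu) ** 2).sum() == pytest.approx(1.0, abs=1e-6)


def test_paule_mandel_cross_check_against_statsmodels():
    from statsmodels.stats.meta_analysis import combine_effects

    rng = np.random.default_rng(8)
    effects = rng.normal(0.4, 0.5, 6)
    variances = rng.uniform(0.05, 0.3, 6)
    pm = paule_mandel_tau2(effects, variances)
    sm = combine_effects(effects, variances, method_re="pm")
    assert pm.tau2 == pytest.approx(sm.tau2, abs=1e-6)


def test_paule_mandel_edge_cases():
    assert paule_mandel_tau2([1.0, 1.0, 1.0], [0.5, 0.5, 0.5]).tau2 == 0.0
    single = paule_mandel_tau2([1.0], [0.5])
    assert single.tau2 == 0.0 and not single.estimable
    with pytest.raises(ValueError):
        paule_mandel_tau2([0.0, 1.0], [0.0, 1.0])


def test_q_profile_bounds_satisfy_defining_equation():
    rng = np.random.default_rng(9)
    y = rng.normal(0.5, 0.8, 7)
    v = rng.uniform(0.05, 0.2, 7)
    (lo, hi), (tlo, thi) = q_profile_ci(y, v)

    def q_gen(tau2):
        w = 1 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        return (w * (y - mu) ** 2).sum()

    k = len(y)
    if lo > 0:
        assert q_gen(lo) == pytest.approx(stats.chi2.ppf(0.975, k - 1), abs=1e-6)
    assert q_gen(hi) == pytest.approx(stats.chi2.ppf(0.025, k - 1), abs=1e-6)
    assert (tlo, thi) == (math.sqrt(lo), math.sqrt(hi))


def test_q_profile_homogeneous_data_lower_bound_zero():
    y = np.full(12, 0.3)
    v = np.full(12, 0.1)
    (lo, _hi), _ = q_profile_ci(y, v)
    assert lo == 0.0


def test_continuous_single_study_closed_form():
    res = pool_continuous([ContinuousStudy(1.0, 1.0, 50, 0.0, 1.0, 50)])
    assert res.pooled == pytest.approx(hedges_correction(50, 50) * 1.0, rel=1e-12)
    assert res.scale == "smd"
    assert res.pooled_or is None


def test_smd_cross_check_against_statsmodels():
    from statsmodels.stats.meta_analysis import effectsize_smd

    g, v = smd_study(ContinuousStudy(1.2, 1.1, 40, 0.5, 0.9, 35))
    sm_g, sm_v = effectsize_smd(1.2, 1.1, 40, 0.5, 0.9, 35)
    assert g == pytest.approx(float(sm_g), rel=1e-6)
    assert v == pytest.approx(float(sm_v), rel=1e-6)


def test_continuous_identical_studies_and_fixed_random_agreement():
    study = ContinuousStudy(0.8, 1.0, 40, 0.2, 1.0, 40)
    multi = pool_continuous([study] * 5)
    single = pool_continuous([study])
    assert multi.pooled == pytest.approx(single.pooled, abs=1e-10)
    assert multi.tau2 == 0.0
    # with tau2 = 0 the random-effects estimate equals fixed inverse variance
    assert multi.pooled == pytest.approx(multi.fixed, abs=1e-10)


def test_input_validation():
    with pytest.raises(ValueError):
        TwoByTwo(5, 4, 1, 10)
    with pytest.raises(ValueError):
        TwoByTwo(1, 0, 1, 10)
    with pytest.raises(ValueError):
        ContinuousStudy(1, 0.0, 10, 0, 0.0, 10)
    with pytest.raises(ValueError):
        ContinuousStudy(1, 1.0, 1, 0, 1.0, 10)
    with pytest.raises(ValueError):
        pool_binary([])
    with pytest.raises(ValueError):
        pool_continuous([])


def test_null_coverage_of_pooled_smd_ci():
    """k = 6 null studies: the 95% CI should contain 0 in about 95% of
    replications."""
    rng = np.random.default_rng(10)
    hits = 0
    reps = 300
    for _ in range(reps):
        studies = []
        for _k in range(6):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            studies.append(ContinuousStudy(
                x.mean(), x.std(ddof=1), 40, y.mean(), y.std(ddof=1), 40))
        res = pool_continuous(studies)
        hits += res.ci_low <= 0 <= res.ci_high
    assert hits / reps == pytest.approx(0.95, abs=0.04)
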