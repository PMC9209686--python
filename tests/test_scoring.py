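import itertools

import pytest
from hypothesis import given, settings, strategies as st

from sjstar.option_space import candidate_star_spec, score_pattern
from sjstar.scoring import (
    DOMAINS,
    DOMAIN_WEIGHTS,
    Response,
    TrialValidationError,
    biological_response,
    oss_response,
    pro_response,
    schirmer_response,
    score_star,
    score_trial,
    systemic_response,
    ultrasound_response,
    uwsf_response,
)
from sjstar.simulate import SimConfig, negative_profile, simulate_trial

YES, NO, UND = Response.YES, Response.NO, Response.UNDETERMINED


@pytest.mark.parametrize(
    "rule,args,expected",
    [
        # systemic: decrease ≥3 clinESSDAI points
        (systemic_response, (8, 5), YES),
        (systemic_response, (8, 6), NO),
        (systemic_response, (None, 5), UND),
        # symptoms: ESSPRI decrease ≥1 point or ≥15%
        (pro_response, (8.0, 7.0), YES),
        (pro_response, (2.0, 1.6), YES),   # 20% relative decrease
        (pro_response, (8.0, 7.2), NO),    # 0.8 pt and 10%: both branches fail
        (pro_response, (0.0, 0.0), NO),    # zero baseline cannot improve
        # Schirmer: abnormal <5 mm; +5 mm if abnormal, stay normal otherwise
        (schirmer_response, (3, 8), YES),
        (schirmer_response, (10, 6), YES),
        (schirmer_response, (10, 3), NO),
        (schirmer_response, (3, 7), NO),
        # OSS: abnormal ≥3; −2 points if abnormal, stay normal otherwise
        (oss_response, (6, 4), YES),
        (oss_response, (2, 2), YES),
        (oss_response, (6, 5), NO),
        (oss_response, (2, 4), NO),
        # salivary flow: +25% if positive baseline, any increase from zero
        (uwsf_response, (0.20, 0.25), YES),
        (uwsf_response, (0.0, 0.01), YES),
        (uwsf_response, (0.0, 0.0), NO),
        (uwsf_response, (0.20, 0.24), NO),
        # ultrasound: −25% of total score; zero baseline cannot respond
        (ultrasound_response, (20, 15), YES),
        (ultrasound_response, (20, 16), NO),
        (ultrasound_response, (0, 0), NO),
        # biology: IgG −10% or RF −25%
        (biological_response, (15.0, 13.5, None, None), YES),
        (biological_response, (None, None, 40, 30), YES),
        (biological_response, (None, None, None, None), UND),
        (biological_response, (15.0, 14.0, 40, 35), NO),
        (biological_response, (15.0, 14.0, 40, 30), YES),  # RF path rescues
    ],
)
def test_instrument_rules(rule, args, expected):
    assert rule(*args) is expected


@pytest.mark.parametrize(
    "rule,args",
    [
        (systemic_response, (-1, 5)),
        (pro_response, (11.0, 5.0)),
        (uwsf_response, (-0.1, 0.2)),
        (ultrasound_response, (50, 10)),
        (biological_response, (0.0, 10.0, None, None)),
    ],
)
def test_rule_input_validation(rule, args):
    with pytest.raises(TrialValidationError):
        rule(*args)


def _all_patterns():
    for bits in itertools.product([False, True], repeat=5):
        yield dict(zip(DOMAINS, bits))


def test_responder_patterns_exhaustively():
    """All 32 domain patterns: min responder total is 5, responders always
    include a major domain, and the flag is monotone in domain flips."""
    spec = candidate_star_spec()
    totals = {}
    for pattern in _all_patterns():
        points = sum(DOMAIN_WEIGHTS[d] for d in DOMAINS if pattern[d])
        responder = score_pattern(pattern, spec)
        totals[tuple(pattern.values())] = (points, responder)
        if responder:
            assert pattern["systemic"] or pattern["pro"]
        # monotonicity: upgrading any single domain never breaks response
        for d in DOMAINS:
            if not pattern[d]:
                upgraded = dict(pattern, **{d: True})
                assert score_pattern(upgraded, spec) >= responder
    responder_totals = [p for p, r in totals.values() if r]
    assert min(responder_totals) == 5
    non_responder_totals = [p for p, r in totals.values() if not r]
    assert max(non_responder_totals) == 4


def test_score_star_composition(record_factory):
    # systemic + lachrymal + salivary = 3+1+1 = 5 → responder
    rec = record_factory(
        clin_essdai=(8, 5), esspri=(6.0, 5.5), schirmer_mm=(3, 8),
        uwsf_ml_min=(0.2, 0.25), igg_g_l=(15.0, 15.0),
    )
    res = score_star(rec)
    assert (res.total_points, res.responder, res.n_undetermined) == (5, True, 0)

    # three minors only → 3 points, non-responder
    rec = record_factory(
        clin_essdai=(8, 8), esspri=(6.0, 6.0), schirmer_mm=(3, 8),
        uwsf_ml_min=(0.2, 0.3), igg_g_l=(15.0, 13.0),
    )
    res = score_star(rec)
    assert (res.total_points, res.responder) == (3, False)

    # all five domains → 9 points
    rec = record_factory(
        clin_essdai=(8, 5), esspri=(6.0, 4.0), schirmer_mm=(3, 9),
        uwsf_ml_min=(0.2, 0.3), igg_g_l=(15.0, 13.0),
    )
    assert score_star(rec).total_points == 9


def test_undetermined_domains_earn_zero_and_are_counted(record_factory):
    rec = record_factory(clin_essdai=(8, 4), esspri=(6.0, 4.0))
    res = score_star(rec)
    assert res.total_points == 6
    assert res.responder
    assert res.n_undetermined == 3
    for d in ("lachrymal", "salivary", "biological"):
        assert res.domains[d].response is Response.UNDETERMINED
        assert res.domains[d].points_earned == 0


def test_instrument_alternative_symmetry(record_factory):
    """A domain responds the same way whichever instrument qualifies."""
    via_schirmer = record_factory(schirmer_mm=(3, 8))
    via_oss = record_factory(oss=(6, 3))
    assert score_star(via_schirmer).domains["lachrymal"].response is YES
    assert score_star(via_oss).domains["lachrymal"].response is YES


def test_score_trial_counts_are_conserved(small_trial):
    rates = score_trial(small_trial)
    n_t = len(small_trial.arm_records("treatment"))
    n_p = len(small_trial.arm_records("placebo"))
    assert rates.n_t + rates.excluded_t == n_t
    assert rates.n_p + rates.excluded_p == n_p
    assert 0.0 <= rates.rate_t <= 1.0
    assert 0.0 <= rates.rate_p <= 1.0


def test_score_trial_null_simulation_rates_close():
    trial = simulate_trial(
        SimConfig(trial_id="null", n=4000, profile=negative_profile(), seed=11)
    )
    rates = score_trial(trial)
    assert abs(rates.rate_t - rates.rate_p) < 0.05


@settings(max_examples=200, derandomize=True)
@given(
    base=st.floats(0, 10).map(lambda x: round(x, 1)),
    fu=st.floats(0, 10).map(lambda x: round(x, 1)),
)
def test_pro_rule_monotone_in_followup(base, fu):
    """If a follow-up qualifies, any lower follow-up also qualifies."""
    if pro_response(base, fu) is YES and fu >= 0.1:
        assert pro_response(base, round(fu - 0.1, 1)) is YES


@settings(max_examples=200, derandomize=True)
@given(
    base=st.floats(0, 40).map(lambda x: round(x, 1)),
    fu=st.floats(0, 40).map(lambda x: round(x, 1)),
)
def test_schirmer_yes_iff_gain_or_kept_normal(base, fu):
    out = schirmer_response(base, fu)
    if base < 5:
        assert (out is YES) == (fu - base >= 5 - 1e-9)
    else:
        assert (out is YES) == (fu >= 5)
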