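import itertools

import pytest

from sjstar.option_space import (
    DomainRule,
    OptionConfigError,
    OptionSpec,
    candidate_star_spec,
    cress_like_spec,
    enumerate_options,
    responder_status,
    score_option,
    score_pattern,
)
from sjstar.scoring import DOMAINS, Response, score_star
from sjstar.simulate import SimConfig, in_between_profile, simulate_trial


def _pattern(*yes):
    return {d: d in yes for d in DOMAINS}


@pytest.mark.parametrize(
    "spec,yes_domains,expected",
    [
        # 3A: ≥3 of 5 including ≥1 major
        (OptionSpec("a", "design_3a"), ("pro", "lachrymal", "salivary"), True),
        (OptionSpec("a", "design_3a"), ("lachrymal", "salivary", "biological"), False),
        (OptionSpec("a", "design_3a"), ("systemic", "pro"), False),
        # CRESS-like: ≥3 of 5, no major constraint
        (cress_like_spec(), ("lachrymal", "salivary", "biological"), True),
        (cress_like_spec(), ("lachrymal", "salivary"), False),
        # 3B binary: weighted sum vs threshold
        (OptionSpec("b", "design_3b_binary", response_threshold=6),
         ("systemic", "pro"), True),
        (OptionSpec("b", "design_3b_binary", response_threshold=7),
         ("systemic", "pro"), False),
        # SRI-like without worsening: any improved major suffices
        (OptionSpec("s", "sri_two_major"), ("pro",), True),
        (OptionSpec("s", "sri_two_major"), ("lachrymal",), False),
        (OptionSpec("s1", "sri_one_major", major_domains=("systemic",)),
         ("pro",), False),
        (OptionSpec("s1", "sri_one_major", major_domains=("systemic",)),
         ("systemic",), True),
    ],
)
def test_design_classification_from_patterns(spec, yes_domains, expected):
    assert score_pattern(_pattern(*yes_domains), spec) == expected


def test_continuous_design_returns_point_sum():
    spec = OptionSpec("c", "design_3b_continuous")
    assert score_pattern(_pattern("systemic", "salivary"), spec) == 4.0
    assert score_pattern(_pattern(), spec) == 0.0


def test_candidate_star_spec_fields():
    spec = candidate_star_spec()
    assert spec.design == "design_3b_binary"
    assert spec.response_threshold == 5
    # no worsening clause: no domain rule carries a worsening threshold
    assert all(r.worsening_threshold is None for r in spec.rules.values())


def test_candidate_star_spec_equals_score_star_on_simulated_records():
    trial = simulate_trial(
        SimConfig(trial_id="eq", n=600, profile=in_between_profile(), seed=21)
    )
    spec = candidate_star_spec()
    for record in trial.records:
        assert score_option(record, spec) == score_star(record).responder


def test_3b_responder_set_shrinks_with_threshold():
    trial = simulate_trial(
        SimConfig(trial_id="mono", n=300, profile=in_between_profile(), seed=5)
    )
    sets = []
    for t in range(4, 10):
        spec = OptionSpec(f"t{t}", "design_3b_binary", response_threshold=t)
        sets.append({r.patient_id for r in trial.records if score_option(r, spec)})
    for bigger, smaller in zip(sets, sets[1:]):
        assert smaller <= bigger


def test_design_3a_implies_cress():
    trial = simulate_trial(
        SimConfig(trial_id="imp", n=300, profile=in_between_profile(), seed=6)
    )
    a = OptionSpec("a", "design_3a")
    cress = cress_like_spec()
    for record in trial.records:
        if score_option(record, a):
            assert score_option(record, cress)


def test_worsening_clause_blocks_sri_response(record_factory):
    # symptoms improve but systemic activity worsens by ≥3 points
    rec = record_factory(esspri=(6.0, 4.0), clin_essdai=(5, 9))
    sri = OptionSpec("s", "sri_two_major")
    assert score_option(rec, sri) is False
    # identical improvement without the worsening → responder
    rec2 = record_factory(esspri=(6.0, 4.0), clin_essdai=(5, 6))
    assert score_option(rec2, sri) is True


def test_acr_like_uses_uniform_percent_threshold(record_factory):
    # 30% ESSPRI + 30% clinESSDAI + 30% UWSF improvements
    rec = record_factory(
        clin_essdai=(10, 7), esspri=(6.0, 4.2), uwsf_ml_min=(0.2, 0.26),
    )
    assert score_option(rec, OptionSpec("a30", "acr_like", acr_percent=30))
    # at 50% none of the three domains qualifies
    assert not score_option(rec, OptionSpec("a50", "acr_like", acr_percent=50))


def test_domain_rule_override_changes_threshold(record_factory):
    rec = record_factory(clin_essdai=(8, 6))  # decrease of 2
    loose = OptionSpec(
        "loose", "design_3b_binary", response_threshold=4,
        rules={"systemic": DomainRule(
            "systemic", improvement_threshold=2, improvement_kind="absolute")},
    )
    strict = candidate_star_spec()
    assert score_star(rec).domains["systemic"].response is Response.NO
    # with the override the systemic domain responds (3 pts), still < 4
    assert score_option(rec, strict) is False
    rec2 = record_factory(clin_essdai=(8, 6), uwsf_ml_min=(0.2, 0.3))
    assert score_option(rec2, loose) is True


def test_responder_status_flags_ambiguous_missingness(record_factory):
    spec = candidate_star_spec()
    # 4 determinate points + an undetermined major → could be 4 or 7
    rec = record_factory(
        clin_essdai=(8, 4), schirmer_mm=(3, 9),
        uwsf_ml_min=(0.0, 0.0), igg_g_l=(15.0, 15.0),
    )
    assert responder_status(rec, spec) is Response.UNDETERMINED
    # 6 determinate points: responder regardless of the missing minors
    rec2 = record_factory(clin_essdai=(8, 4), esspri=(6.0, 4.0))
    assert responder_status(rec2, spec) is Response.YES


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(design="design_3b_binary"),  # missing threshold
        dict(design="design_3b_binary", response_threshold=3),
        dict(design="acr_like"),  # missing percent
        dict(design="acr_like", acr_percent=80),
        dict(design="design_3a", acr_percent=30),  # percent on wrong design
        dict(design="sri_one_major"),  # needs a single major
        dict(design="no_such_design"),
    ],
)
def test_invalid_option_specs_rejected(kwargs):
    with pytest.raises(OptionConfigError):
        OptionSpec("bad", **kwargs)


def test_enumerate_option_grids():
    assert len(enumerate_options({"designs": ["design_3b_binary"]})) == 6
    assert len(enumerate_options({"designs": ["acr_like"]})) == 7
    assert len(enumerate_options({"designs": ["sri_one_major"]})) == 2
    combined = enumerate_options(
        {"designs": ["design_3b_binary", "acr_like", "cress_like"]}
    )
    assert len(combined) == 6 + 7 + 1
    ids = [o.option_id for o in combined]
    assert len(set(ids)) == len(ids)


def test_enumerate_empty_grid_rejected():
    with pytest.raises(OptionConfigError):
        enumerate_options({"designs": []})
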