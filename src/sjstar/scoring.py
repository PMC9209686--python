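"""Candidate STAR responder index: per-instrument rules, domain scores, totals.

The index covers five domains — systemic activity (clinESSDAI), patient
symptoms (ESSPRI), lachrymal gland function (Schirmer's test or ocular
staining score), salivary gland function (unstimulated whole salivary flow
or Hocevar ultrasound score) and biology (serum IgG or RF).  The two
"major" domains (systemic, symptoms) weigh 3 points each, the three minor
domains 1 point each, and a patient is a responder at ≥5 points — which
forces at least one major-domain response, since the minors sum to 3.

Instrument rules (all thresholds inclusive):

* systemic — decrease of ≥3 clinESSDAI points;
* symptoms — decrease of ≥1 ESSPRI point or ≥15% from baseline;
* Schirmer — abnormal (<5 mm) at baseline: increase ≥5 mm; normal at
  baseline: remaining normal counts as response;
* OSS — abnormal (≥3) at baseline: decrease ≥2 points; normal at baseline:
  remaining normal counts as response;
* UWSF — positive baseline: increase ≥25%; zero baseline: any increase;
* ultrasound — decrease ≥25% in total Hocevar score;
* biology — IgG decrease ≥10% or RF decrease ≥25%.

Within a domain, instruments are alternatives joined by "or": the domain
responds if ANY instrument with both visits available meets its rule.  A
domain with no usable instrument pair is *undetermined* and earns 0 points
(a conservative choice that biases against response); the number of
undetermined domains is surfaced on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping

from .trial_data import PatientRecord, TrialDataset, TrialValidationError

__all__ = [
    "Response",
    "DomainScore",
    "StarResult",
    "DOMAINS",
    "MAJOR_DOMAINS",
    "DOMAIN_WEIGHTS",
    "RESPONDER_THRESHOLD",
    "SCHIRMER_ABNORMAL_MM",
    "OSS_ABNORMAL",
    "systemic_response",
    "pro_response",
    "schirmer_response",
    "oss_response",
    "uwsf_response",
    "ultrasound_response",
    "biological_response",
    "score_star",
    "score_trial",
    "TrialResponseRates",
]


class Response(Enum):
    """Tri-state outcome of a response rule."""

    YES = "yes"
    NO = "no"
    UNDETERMINED = "undetermined"


DOMAINS = ("systemic", "pro", "lachrymal", "salivary", "biological")
MAJOR_DOMAINS = ("systemic", "pro")
DOMAIN_WEIGHTS = {
    "systemic": 3,
    "pro": 3,
    "lachrymal": 1,
    "salivary": 1,
    "biological": 1,
}
RESPONDER_THRESHOLD = 5

SCHIRMER_ABNORMAL_MM = 5.0  # abnormal if strictly below
OSS_ABNORMAL = 3.0  # abnormal if at or above

# Inclusive decimal thresholds (e.g. "≥25%") must hold for values that are
# exact in decimal but not in binary: 0.25/0.20 - 1 evaluates below 0.25 in
# doubles.  All threshold comparisons therefore use a 1e-9 tolerance.
_TOL = 1e-9


def _ge(x: float, threshold: float) -> bool:
    return x >= threshold - _TOL * max(1.0, abs(threshold))


def _validate(name: str, value: float | None, low: float, high: float | None,
              strict_low: bool = False) -> None:
    if value is None:
        return
    if strict_low:
        if value <= low:
            raise TrialValidationError(f"{name} must be > {low}, got {value}")
    elif value < low:
        raise TrialValidationError(f"{name} must be ≥ {low}, got {value}")
    if high is not None and value > high:
        raise TrialValidationError(f"{name} must be ≤ {high}, got {value}")


def systemic_response(baseline: float | None, followup: float | None) -> Response:
    """Systemic activity: decrease of ≥3 clinESSDAI points."""
    _validate("clinESSDAI", baseline, 0, None)
    _validate("clinESSDAI", followup, 0, None)
    if baseline is None or followup is None:
        return Response.UNDETERMINED
    return Response.YES if _ge(baseline - followup, 3.0) else Response.NO


def pro_response(baseline: float | None, followup: float | None) -> Response:
    """Patient symptoms: ESSPRI decrease of ≥1 point or ≥15% of baseline."""
    _validate("ESSPRI", baseline, 0, 10)
    _validate("ESSPRI", followup, 0, 10)
    if baseline is None or followup is None:
        return Response.UNDETERMINED
    decrease = baseline - followup
    if _ge(decrease, 1.0):
        return Response.YES
    if baseline > 0 and _ge(decrease / baseline, 0.15):
        return Response.YES
    return Response.NO


def schirmer_response(baseline: float | None, followup: float | None) -> Response:
    """Schirmer's test; abnormal below 5 mm.

    Abnormal baseline: increase of ≥5 mm.  Normal baseline: response means
    staying normal (no change to abnormal).
    """
    _validate("Schirmer", baseline, 0, None)
    _validate("Schirmer", followup, 0, None)
    if baseline is None or followup is None:
        return Response.UNDETERMINED
    if baseline < SCHIRMER_ABNORMAL_MM:
        return Response.YES if _ge(followup - baseline, 5.0) else Response.NO
    return Response.YES if followup >= SCHIRMER_ABNORMAL_MM else Response.NO


def oss_response(baseline: float | None, followup: float | None) -> Response:
    """Ocular staining score; abnormal at ≥3.

    Abnormal baseline: decrease of ≥2 points.  Normal baseline: response
    means staying below 3.
    """
    _validate("OSS", baseline, 0, 12)
    _validate("OSS", followup, 0, 12)
    if baseline is None or followup is None:
        return Response.UNDETERMINED
    if baseline >= OSS_ABNORMAL:
        return Response.YES if _ge(baseline - followup, 2.0) else Response.NO
    return Response.YES if followup < OSS_ABNORMAL else Response.NO


def uwsf_response(baseline: float | None, followup: float | None) -> Response:
    """Unstimulated whole salivary flow.

    Positive baseline: increase of ≥25% from baseline.  Zero baseline: any
    increase counts.
    """
    _validate("UWSF", baseline, 0, None)
    _validate("UWSF", followup, 0, None)
    if baseline is None or followup is None:
        return Response.UNDETERMINED
    if baseline > 0:
        return Response.YES if _ge((followup - baseline) / baseline, 0.25) else Response.NO
    return Response.YES if followup > 0 else Response.NO


def ultrasound_response(baseline: float | None, followup: float | None) -> Response:
    """Salivary ultrasound: decrease of ≥25% in total Hocevar score.

    A zero baseline cannot decrease by 25% and scores "no".
    """
    _validate("Hocevar", baseline, 0, 48)
    _validate("Hocevar", followup, 0, 48)
    if baseline is None or followup is None:
        return Response.UNDETERMINED
    if baseline <= 0:
        return Response.NO
    return Response.YES if _ge((baseline - followup) / baseline, 0.25) else Response.NO


def biological_response(
    igg_base: float | None,
    igg_fu: float | None,
    rf_base: float | None,
    rf_fu: float | None,
) -> Response:
    """Biology: serum IgG decrease ≥10% or RF decrease ≥25%."""
    _validate("IgG", igg_base, 0, None, strict_low=True)
    _validate("IgG", igg_fu, 0, None, strict_low=True)
    _validate("RF", rf_base, 0, None)
    _validate("RF", rf_fu, 0, None)
    igg_ok = igg_base is not None and igg_fu is not None
    rf_ok = rf_base is not None and rf_fu is not None
    if not igg_ok and not rf_ok:
        return Response.UNDETERMINED
    if igg_ok and _ge((igg_base - igg_fu) / igg_base, 0.10):
        return Response.YES
    if rf_ok and rf_base > 0 and _ge((rf_base - rf_fu) / rf_base, 0.25):
        return Response.YES
    return Response.NO


@dataclass(frozen=True)
class DomainScore:
    domain: str
    available: bool
    response: Response
    points_earned: int
    instruments_used: tuple[str, ...]


@dataclass(frozen=True)
class StarResult:
    """Per-domain scores, point total and responder classification."""

    domains: Mapping[str, DomainScore]
    total_points: int
    responder: bool
    n_undetermined: int


# (instrument label, callable(record) -> Response) per domain.
_DOMAIN_INSTRUMENTS: dict[str, tuple[tuple[str, Callable[[PatientRecord], Response]], ...]] = {
    "systemic": (
        ("clin_essdai", lambda r: systemic_response(r.baseline.clin_essdai, r.followup.clin_essdai)),
    ),
    "pro": (
        ("esspri", lambda r: pro_response(r.baseline.esspri, r.followup.esspri)),
    ),
    "lachrymal": (
        ("schirmer_mm", lambda r: schirmer_response(r.baseline.schirmer_mm, r.followup.schirmer_mm)),
        ("oss", lambda r: oss_response(r.baseline.oss, r.followup.oss)),
    ),
    "salivary": (
        ("uwsf_ml_min", lambda r: uwsf_response(r.baseline.uwsf_ml_min, r.followup.uwsf_ml_min)),
        ("hocevar", lambda r: ultrasound_response(r.baseline.hocevar, r.followup.hocevar)),
    ),
    "biological": (
        ("igg_rf", lambda r: biological_response(
            r.baseline.igg_g_l, r.followup.igg_g_l,
            r.baseline.rf_iu_ml, r.followup.rf_iu_ml)),
    ),
}


def domain_response(record: PatientRecord, domain: str) -> tuple[Response, tuple[str, ...]]:
    """Tri-state response of one domain and the instruments that decided it.

    Any available instrument meeting its rule makes the domain respond;
    with every instrument pair missing the domain is undetermined.
    """
    results = []
    used = []
    for name, rule in _DOMAIN_INSTRUMENTS[domain]:
        outcome = rule(record)
        if outcome is not Response.UNDETERMINED:
            results.append(outcome)
            used.append(name)
    if not results:
        return Response.UNDETERMINED, ()
    if Response.YES in results:
        return Response.YES, tuple(used)
    return Response.NO, tuple(used)


def score_star(record: PatientRecord) -> StarResult:
    """Score one patient with the candidate STAR (responder at ≥5 points)."""
    domains: dict[str, DomainScore] = {}
    total = 0
    undetermined = 0
    for domain in DOMAINS:
        response, used = domain_response(record, domain)
        points = DOMAIN_WEIGHTS[domain] if response is Response.YES else 0
        if response is Response.UNDETERMINED:
            undetermined += 1
        domains[domain] = DomainScore(
            domain=domain,
            available=response is not Response.UNDETERMINED,
            response=response,
            points_earned=points,
            instruments_used=used,
        )
        total += points
    return StarResult(
        domains=domains,
        total_points=total,
        responder=total >= RESPONDER_THRESHOLD,
        n_undetermined=undetermined,
    )


@dataclass(frozen=True)
class TrialResponseRates:
    """Per-arm responder counts for one responder definition on one trial."""

    trial_id: str
    responders_t: int
    n_t: int
    responders_p: int
    n_p: int
    excluded_t: int = 0
    excluded_p: int = 0

    @property
    def rate_t(self) -> float:
        return self.responders_t / self.n_t

    @property
    def rate_p(self) -> float:
        return self.responders_p / self.n_p


def score_trial(
    dataset: TrialDataset,
    scorer: Callable[[PatientRecord], bool | None] | None = None,
) -> TrialResponseRates:
    """Per-arm responder counts and rates for a responder definition.

    ``scorer`` maps a record to True/False, or None for patients whose
    status cannot be determined; those are excluded from the denominator
    and counted in ``excluded_*``.  Default scorer: candidate STAR.
    """
    if scorer is None:
        scorer = lambda r: score_star(r).responder  # noqa: E731
    counts = {"treatment": [0, 0, 0], "placebo": [0, 0, 0]}  # yes, n, excluded
    for record in dataset.records:
        outcome = scorer(record)
        slot = counts[record.arm]
        if outcome is None:
            slot[2] += 1
        else:
            slot[1] += 1
            slot[0] += int(bool(outcome))
    for arm in ("treatment", "placebo"):
        if counts[arm][1] == 0:
            raise TrialValidationError(
                f"no determinate patients in {arm} arm of {dataset.trial_id}"
            )
    return TrialResponseRates(
        trial_id=dataset.trial_id,
        responders_t=counts["treatment"][0],
        n_t=counts["treatment"][1],
        responders_p=counts["placebo"][0],
        n_p=counts["placebo"][1],
        excluded_t=counts["treatment"][2],
        excluded_p=counts["placebo"][2],
    )
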