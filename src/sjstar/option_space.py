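"""Parameterised composite-endpoint definitions (candidate-option families).

Seven design families are supported, mirroring the endpoint architectures
considered during the index development:

* ``sri_two_major`` — response = improvement of one of the two major
  domains (systemic, symptoms) with no worsening of the other domains;
* ``sri_one_major`` — as above with a single pre-declared target major;
* ``design_3a`` — improvement in ≥3 of 5 domains including ≥1 major;
* ``design_3b_binary`` — weighted point sum (3/3/1/1/1) dichotomised at a
  threshold tested from 4 to 9;
* ``design_3b_continuous`` — the raw 0–9 point sum, compared between arms;
* ``acr_like`` — percent improvement (a single x% from 10 to 70 applied to
  every instrument) in ≥3 of 5 domains including ≥1 major;
* ``cress_like`` — improvement in ≥3 of 5 domains, no major constraint.

Per-domain improvement defaults to the candidate STAR instrument rules;
a :class:`DomainRule` can override the instruments used and the threshold
(absolute or percent).  Worsening — needed by the SRI-like designs and for
which no consensual published definition exists — defaults to the mirror
image of each improvement rule (e.g. clinESSDAI increase ≥3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .scoring import (
    DOMAINS,
    DOMAIN_WEIGHTS,
    MAJOR_DOMAINS,
    OSS_ABNORMAL,
    RESPONDER_THRESHOLD,
    SCHIRMER_ABNORMAL_MM,
    Response,
    _DOMAIN_INSTRUMENTS,
    _ge,
)
from .trial_data import PatientRecord

__all__ = [
    "DESIGNS",
    "DomainRule",
    "OptionSpec",
    "OptionConfigError",
    "score_option",
    "responder_status",
    "score_pattern",
    "candidate_star_spec",
    "enumerate_options",
]

DESIGNS = (
    "sri_two_major",
    "sri_one_major",
    "design_3a",
    "design_3b_binary",
    "design_3b_continuous",
    "acr_like",
    "cress_like",
)

# Direction of improvement per instrument: -1 decrease is good, +1 increase.
_DIRECTION = {
    "clin_essdai": -1,
    "esspri": -1,
    "schirmer_mm": +1,
    "oss": -1,
    "uwsf_ml_min": +1,
    "hocevar": -1,
    "igg_g_l": -1,
    "rf_iu_ml": -1,
}

_DOMAIN_OF = {
    "clin_essdai": "systemic",
    "esspri": "pro",
    "schirmer_mm": "lachrymal",
    "oss": "lachrymal",
    "uwsf_ml_min": "salivary",
    "hocevar": "salivary",
    "igg_g_l": "biological",
    "rf_iu_ml": "biological",
}


class OptionConfigError(ValueError):
    """An OptionSpec or option grid is internally inconsistent."""


@dataclass(frozen=True)
class DomainRule:
    """Override of one domain's response rule.

    ``improvement_threshold`` of ``None`` keeps the candidate STAR rule for
    each instrument.  Percent thresholds are expressed on 0–100 and applied
    in the instrument's improvement direction.
    """

    domain: str
    instruments: tuple[str, ...] | None = None
    improvement_threshold: float | None = None
    improvement_kind: str = "absolute"
    worsening_threshold: float | None = None
    worsening_kind: str = "absolute"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise OptionConfigError(f"unknown domain {self.domain!r}")
        if self.instruments is not None:
            bad = [i for i in self.instruments if _DOMAIN_OF.get(i) != self.domain]
            if bad:
                raise OptionConfigError(
                    f"instruments {bad} do not belong to domain {self.domain}"
                )
        for value, kind in (
            (self.improvement_threshold, self.improvement_kind),
            (self.worsening_threshold, self.worsening_kind),
        ):
            if value is not None:
                if value <= 0:
                    raise OptionConfigError("thresholds must be strictly positive")
                if kind == "percent" and value > 100:
                    raise OptionConfigError("percent thresholds must be ≤ 100")
                if kind not in ("absolute", "percent"):
                    raise OptionConfigError(f"unknown threshold kind {kind!r}")


@dataclass(frozen=True)
class OptionSpec:
    """One fully parameterised composite endpoint."""

    option_id: str
    design: str
    rules: Mapping[str, DomainRule] = field(default_factory=dict)
    major_domains: tuple[str, ...] = MAJOR_DOMAINS
    response_threshold: int | None = None
    acr_percent: int | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise OptionConfigError(f"unknown design {self.design!r}")
        if self.design == "sri_one_major":
            if len(self.major_domains) != 1 or self.major_domains[0] not in MAJOR_DOMAINS:
                raise OptionConfigError(
                    "sri_one_major requires exactly one major domain"
                )
        elif tuple(self.major_domains) != MAJOR_DOMAINS:
            raise OptionConfigError(
                f"{self.design} uses both major domains {MAJOR_DOMAINS}"
            )
        if self.design == "design_3b_binary":
            if self.response_threshold is None or not 4 <= self.response_threshold <= 9:
                raise OptionConfigError(
                    "design_3b_binary needs response_threshold in [4, 9]"
                )
        if self.design == "acr_like":
            if self.acr_percent is None or not 10 <= self.acr_percent <= 70:
                raise OptionConfigError("acr_like needs acr_percent in [10, 70]")
        elif self.acr_percent is not None:
            raise OptionConfigError(
                f"acr_percent is only meaningful for acr_like, not {self.design}"
            )
        for domain, rule in self.rules.items():
            if rule.domain != domain:
                raise OptionConfigError(
                    f"rule for {rule.domain!r} filed under {domain!r}"
                )

    @property
    def domain_count_threshold(self) -> int:
        """Improved-domain count needed by the counting designs (default 3)."""
        if self.design in ("design_3a", "acr_like", "cress_like"):
            return self.response_threshold if self.response_threshold else 3
        raise OptionConfigError(f"{self.design} has no domain-count threshold")


# ----------------------------------------------------------------------
# Instrument-level evaluation
# ----------------------------------------------------------------------

def _relative_change(base: float, fu: float, direction: int) -> float | None:
    """Signed relative improvement; None when a percent change is undefined."""
    if base <= 0:
        return None
    return direction * (fu - base) / base


def _custom_improvement(
    base: float | None, fu: float | None, instrument: str,
    threshold: float, kind: str,
) -> Response:
    if base is None or fu is None:
        return Response.UNDETERMINED
    direction = _DIRECTION[instrument]
    if kind == "absolute":
        return Response.YES if _ge(direction * (fu - base), threshold) else Response.NO
    rel = _relative_change(base, fu, direction)
    if rel is None:
        # zero baseline: an increase-is-good instrument counts any gain
        if direction > 0:
            return Response.YES if fu > base else Response.NO
        return Response.NO
    return Response.YES if _ge(rel, threshold / 100.0) else Response.NO


def _default_worsening(base: float | None, fu: float | None, instrument: str) -> Response:
    """Mirror image of the candidate STAR improvement rules."""
    if base is None or fu is None:
        return Response.UNDETERMINED
    if instrument == "clin_essdai":
        return Response.YES if _ge(fu - base, 3.0) else Response.NO
    if instrument == "esspri":
        worse = _ge(fu - base, 1.0) or (base > 0 and _ge((fu - base) / base, 0.15))
        return Response.YES if worse else Response.NO
    if instrument == "schirmer_mm":
        worse = _ge(base - fu, 5.0) or (base >= SCHIRMER_ABNORMAL_MM > fu)
        return Response.YES if worse else Response.NO
    if instrument == "oss":
        worse = _ge(fu - base, 2.0) or (base < OSS_ABNORMAL <= fu)
        return Response.YES if worse else Response.NO
    # percent instruments: mirrored relative change; a zero baseline worsens
    # on any move in the bad direction (infinite relative change)
    direction = _DIRECTION[instrument]
    thresholds = {"uwsf_ml_min": 0.25, "hocevar": 0.25, "igg_g_l": 0.10, "rf_iu_ml": 0.25}
    rel = _relative_change(base, fu, -direction)
    if rel is None:
        return Response.YES if direction < 0 and fu > base else Response.NO
    return Response.YES if _ge(rel, thresholds[instrument]) else Response.NO


def _domain_tristate(
    record: PatientRecord, domain: str, spec: OptionSpec, mode: str,
) -> Response:
    """Tri-state improvement or worsening of one domain under a spec."""
    rule = spec.rules.get(domain)
    instruments = _DOMAIN_INSTRUMENTS[domain]
    if rule is not None and rule.instruments is not None:
        keep = set(rule.instruments)
        if domain == "biological":
            # the combined IgG/RF rule stands in for both instruments
            keep.add("igg_rf")
        instruments = tuple(
            (name, fn) for name, fn in instruments if name in keep or name == "igg_rf"
        )
    results: list[Response] = []
    for name, default_fn in instruments:
        if mode == "improve":
            percent = spec.acr_percent if spec.design == "acr_like" else None
            if percent is not None or (rule is not None and rule.improvement_threshold is not None):
                threshold = float(percent) if percent is not None else rule.improvement_threshold
                kind = "percent" if percent is not None else rule.improvement_kind
                if name == "igg_rf":
                    out = _pair_custom(record, threshold, kind)
                else:
                    out = _custom_improvement(
                        record.baseline.get(name), record.followup.get(name),
                        name, threshold, kind,
                    )
            else:
                out = default_fn(record)
        else:  # worsening
            if rule is not None and rule.worsening_threshold is not None:
                if name == "igg_rf":
                    out = _pair_custom_worse(record, rule.worsening_threshold, rule.worsening_kind)
                else:
                    out = _custom_improvement(
                        record.followup.get(name), record.baseline.get(name),
                        name, rule.worsening_threshold, rule.worsening_kind,
                    )
            elif name == "igg_rf":
                igg = _default_worsening(record.baseline.igg_g_l, record.followup.igg_g_l, "igg_g_l")
                rf = _default_worsening(record.baseline.rf_iu_ml, record.followup.rf_iu_ml, "rf_iu_ml")
                out = _combine_or(igg, rf)
            else:
                out = _default_worsening(record.baseline.get(name), record.followup.get(name), name)
        results.append(out)
    determinate = [r for r in results if r is not Response.UNDETERMINED]
    if not determinate:
        return Response.UNDETERMINED
    return Response.YES if Response.YES in determinate else Response.NO


def _combine_or(*outcomes: Response) -> Response:
    determinate = [o for o in outcomes if o is not Response.UNDETERMINED]
    if not determinate:
        return Response.UNDETERMINED
    return Response.YES if Response.YES in determinate else Response.NO


def _pair_custom(record: PatientRecord, threshold: float, kind: str) -> Response:
    igg = _custom_improvement(record.baseline.igg_g_l, record.followup.igg_g_l,
                              "igg_g_l", threshold, kind)
    rf = _custom_improvement(record.baseline.rf_iu_ml, record.followup.rf_iu_ml,
                             "rf_iu_ml", threshold, kind)
    return _combine_or(igg, rf)


def _pair_custom_worse(record: PatientRecord, threshold: float, kind: str) -> Response:
    igg = _custom_improvement(record.followup.igg_g_l, record.baseline.igg_g_l,
                              "igg_g_l", threshold, kind)
    rf = _custom_improvement(record.followup.rf_iu_ml, record.baseline.rf_iu_ml,
                             "rf_iu_ml", threshold, kind)
    return _combine_or(igg, rf)


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------

def _classify(
    spec: OptionSpec,
    improved: Mapping[str, bool],
    worsened: Mapping[str, bool],
) -> bool | float:
    design = spec.design
    if design in ("sri_two_major", "sri_one_major"):
        majors = spec.major_domains
        for m in majors:
            others_ok = not any(worsened[d] for d in DOMAINS if d != m)
            if improved[m] and others_ok:
                return True
        return False
    n_improved = sum(improved[d] for d in DOMAINS)
    if design in ("design_3a", "acr_like"):
        return (n_improved >= spec.domain_count_threshold
                and any(improved[m] for m in MAJOR_DOMAINS))
    if design == "cress_like":
        return n_improved >= spec.domain_count_threshold
    points = sum(DOMAIN_WEIGHTS[d] for d in DOMAINS if improved[d])
    if design == "design_3b_continuous":
        return float(points)
    return points >= spec.response_threshold


def score_option(record: PatientRecord, spec: OptionSpec) -> bool | float:
    """Classify one patient under an option spec.

    Binary designs return the responder flag; ``design_3b_continuous``
    returns the 0–9 point sum.  Undetermined domains are resolved
    conservatively (no improvement, no worsening), matching the candidate
    STAR convention.
    """
    improved = {d: _domain_tristate(record, d, spec, "improve") is Response.YES
                for d in DOMAINS}
    needs_worsening = spec.design in ("sri_two_major", "sri_one_major")
    worsened = {
        d: (needs_worsening
            and _domain_tristate(record, d, spec, "worsen") is Response.YES)
        for d in DOMAINS
    }
    return _classify(spec, improved, worsened)


def responder_status(record: PatientRecord, spec: OptionSpec) -> Response:
    """Tri-state classification acknowledging missing data.

    The patient is ``UNDETERMINED`` iff resolving their undetermined
    domains optimistically versus pessimistically flips the binary
    classification; otherwise the unambiguous flag is returned.
    """
    if spec.design == "design_3b_continuous":
        raise OptionConfigError("responder_status applies to binary designs")
    improve = {d: _domain_tristate(record, d, spec, "improve") for d in DOMAINS}
    needs_worsening = spec.design in ("sri_two_major", "sri_one_major")
    worsen = {
        d: (_domain_tristate(record, d, spec, "worsen")
            if needs_worsening else Response.NO)
        for d in DOMAINS
    }

    def resolve(optimistic: bool) -> bool:
        imp = {d: (improve[d] is Response.YES
                   or (optimistic and improve[d] is Response.UNDETERMINED))
               for d in DOMAINS}
        wor = {d: (worsen[d] is Response.YES
                   or (not optimistic and worsen[d] is Response.UNDETERMINED))
               for d in DOMAINS}
        return bool(_classify(spec, imp, wor))

    best, worst = resolve(True), resolve(False)
    if best == worst:
        return Response.YES if best else Response.NO
    return Response.UNDETERMINED


def score_pattern(pattern: Mapping[str, bool], spec: OptionSpec) -> bool | float:
    """Classify a bare domain-response pattern (no worsening) under a spec.

    Used for exhaustive enumeration over the 2^5 yes/no patterns.
    """
    improved = {d: bool(pattern[d]) for d in DOMAINS}
    worsened = {d: False for d in DOMAINS}
    return _classify(spec, improved, worsened)


# ----------------------------------------------------------------------
# Presets and grids
# ----------------------------------------------------------------------

def candidate_star_spec() -> OptionSpec:
    """The candidate STAR as an option: point-sum design, threshold 5,
    no worsening clause."""
    return OptionSpec(
        option_id="candidate_star",
        design="design_3b_binary",
        response_threshold=RESPONDER_THRESHOLD,
    )


def cress_like_spec() -> OptionSpec:
    """CRESS-like preset: improvement in ≥3 of 5 domains, no majors."""
    return OptionSpec(option_id="cress_like", design="cress_like")


_DEFAULT_3B_THRESHOLDS = tuple(range(4, 10))
_DEFAULT_ACR_PERCENTS = tuple(range(10, 71, 10))


def enumerate_options(grid_config: Mapping[str, object]) -> list[OptionSpec]:
    """Expand a grid configuration into a list of unique OptionSpecs.

    ``grid_config`` keys: ``designs`` (required, non-empty list);
    ``thresholds_3b`` (default 4..9); ``acr_percents`` (default 10..70 by
    10); ``rule_sets`` — list of ``(name, {domain: DomainRule})`` pairs,
    default a single empty rule-set using the candidate STAR rules.
    """
    designs = list(grid_config.get("designs", ()))
    if not designs:
        raise OptionConfigError("grid lists no designs")
    unknown = [d for d in designs if d not in DESIGNS]
    if unknown:
        raise OptionConfigError(f"unknown designs {unknown}")
    thresholds = tuple(grid_config.get("thresholds_3b", _DEFAULT_3B_THRESHOLDS))
    percents = tuple(grid_config.get("acr_percents", _DEFAULT_ACR_PERCENTS))
    rule_sets: Sequence[tuple[str, Mapping[str, DomainRule]]] = list(
        grid_config.get("rule_sets", [("rs0", {})])
    )

    options: list[OptionSpec] = []
    for (rs_name, rules), design in itertools.product(rule_sets, designs):
        if design == "design_3b_binary":
            for t in thresholds:
                options.append(OptionSpec(
                    option_id=f"3b_bin_th{t}_{rs_name}",
                    design=design, rules=dict(rules), response_threshold=t))
        elif design == "acr_like":
            for p in percents:
                options.append(OptionSpec(
                    option_id=f"acr{p}_{rs_name}",
                    design=design, rules=dict(rules), acr_percent=int(p)))
        elif design == "sri_one_major":
            for major in MAJOR_DOMAINS:
                options.append(OptionSpec(
                    option_id=f"sri1_{major}_{rs_name}",
                    design=design, rules=dict(rules), major_domains=(major,)))
        else:
            options.append(OptionSpec(
                option_id=f"{design}_{rs_name}", design=design, rules=dict(rules)))
    ids = [o.option_id for o in options]
    if len(set(ids)) != len(ids):
        raise OptionConfigError("option ids are not unique; rename rule sets")
    return options
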