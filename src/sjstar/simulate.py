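"""Synthetic primary Sjögren's syndrome RCT generator.

Patient-level trial data for this indication are not publicly available,
so evaluation of responder definitions runs on simulated trials.  The
generator emulates two-visit parallel-arm RCTs of the sizes used during
the index development (n = 80, 52, 120, 29, 27, 32, 133, 120 and 110),
each labelled with an expert verdict: three trials with convincing
treatment effect ("positive"), three with signal confined to secondary
endpoints ("in_between") and three without between-arm differences
("negative").

Baseline severity is induced by a single latent Gaussian factor shared
across instruments (a Gaussian copula): severer patients have higher
clinESSDAI/ESSPRI/OSS/ultrasound/IgG/RF and lower Schirmer/salivary flow.
Marginals are range-respecting defaults (documented in the methods note):
truncated negative binomial for clinESSDAI, truncated normals for ESSPRI
and the ultrasound score, zero-inflated gammas for Schirmer and salivary
flow, a binomial-type integer for the staining score, lognormals for IgG
and (zero-inflated) RF.

Follow-up = baseline + arm-dependent mean change + Gaussian noise, additive
for the scored-in-points instruments and relative (fractional) for the
flow/ultrasound/serology instruments, then truncated and rounded to the
instrument's granularity.  A "negative" effect profile fixes treatment
parameters equal to placebo parameters, making the null exact by
construction.  Optionally a planted subgroup (a covariate rule) receives
an extra treatment benefit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import PatientRecord, TrialDataset, VisitMeasurements

__all__ = [
    "EffectProfile",
    "SubgroupSpec",
    "SimConfig",
    "positive_profile",
    "in_between_profile",
    "negative_profile",
    "simulate_trial",
    "simulate_suite",
    "default_suite_configs",
    "simulate_binary_trial",
    "DEFAULT_TRIAL_PLAN",
]

# additive-change instruments (instrument units) vs relative-change ones
_ADDITIVE = ("clin_essdai", "esspri", "schirmer_mm", "oss")
_RELATIVE = ("uwsf_ml_min", "hocevar", "igg_g_l", "rf_iu_ml")
_ALL = _ADDITIVE + _RELATIVE

# latent severity loading sign: +1 where severer disease raises the value
_SEVERITY_SIGN = {
    "clin_essdai": +1, "esspri": +1, "schirmer_mm": -1, "oss": +1,
    "uwsf_ml_min": -1, "hocevar": +1, "igg_g_l": +1, "rf_iu_ml": +1,
}

# follow-up noise SD: instrument units for additive, fraction for relative
_NOISE_SD = {
    "clin_essdai": 2.5, "esspri": 1.0, "schirmer_mm": 2.5, "oss": 1.2,
    "uwsf_ml_min": 0.30, "hocevar": 0.15, "igg_g_l": 0.05, "rf_iu_ml": 0.20,
}

# typical scale used when a relative change meets a zero baseline
_TYPICAL = {"uwsf_ml_min": 0.15, "hocevar": 18.0, "igg_g_l": 14.0, "rf_iu_ml": 40.0}

# (granularity, low clip, high clip)
_ROUNDING = {
    "clin_essdai": (1.0, 0.0, 40.0),
    "esspri": (0.1, 0.0, 10.0),
    "schirmer_mm": (1.0, 0.0, 40.0),
    "oss": (1.0, 0.0, 12.0),
    "uwsf_ml_min": (0.01, 0.0, None),
    "hocevar": (1.0, 0.0, 48.0),
    "igg_g_l": (0.1, 0.1, None),
    "rf_iu_ml": (1.0, 0.0, None),
}

# default per-instrument probability that the instrument is unavailable for
# a patient (both visits missing); ultrasound, staining and RF were absent
# from most historical trials, so they default high
DEFAULT_MISSINGNESS = {
    "clin_essdai": 0.02, "esspri": 0.02, "schirmer_mm": 0.05, "oss": 0.25,
    "uwsf_ml_min": 0.05, "hocevar": 0.50, "igg_g_l": 0.05, "rf_iu_ml": 0.30,
}


@dataclass(frozen=True)
class EffectProfile:
    """Mean follow-up change per instrument for each arm.

    ``changes[name] = (treatment, placebo)`` — instrument units for the
    additive instruments, fractional change for the relative ones.  A
    ``negative`` profile must have identical arm parameters.
    """

    label: str
    changes: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.label not in ("positive", "in_between", "negative"):
            raise ValueError(f"unknown profile label {self.label!r}")
        missing = [k for k in _ALL if k not in self.changes]
        if missing:
            raise ValueError(f"profile lacks change parameters for {missing}")
        if self.label == "negative":
            for name, (t, p) in self.changes.items():
                if t != p:
                    raise ValueError(
                        f"negative profile requires equal arm parameters; "
                        f"{name} has {t} vs {p}"
                    )


_PLACEBO_CHANGES = {
    "clin_essdai": -1.0, "esspri": -0.4, "schirmer_mm": +0.5, "oss": -0.3,
    "uwsf_ml_min": +0.05, "hocevar": -0.05, "igg_g_l": -0.01, "rf_iu_ml": -0.02,
}


def positive_profile() -> EffectProfile:
    """Strong treatment effect across all five domains."""
    t = {
        "clin_essdai": -3.5, "esspri": -1.3, "schirmer_mm": +2.5, "oss": -1.5,
        "uwsf_ml_min": +0.35, "hocevar": -0.30, "igg_g_l": -0.12, "rf_iu_ml": -0.30,
    }
    return EffectProfile(
        "positive", {k: (t[k], _PLACEBO_CHANGES[k]) for k in _ALL}
    )


def in_between_profile() -> EffectProfile:
    """Signal mostly in glandular/biological measures, weak on the majors —
    the pattern of trials that missed their primary endpoint but showed
    benefit on secondary endpoints."""
    t = {
        "clin_essdai": -1.5, "esspri": -0.55, "schirmer_mm": +0.8, "oss": -0.5,
        "uwsf_ml_min": +0.20, "hocevar": -0.12, "igg_g_l": -0.08, "rf_iu_ml": -0.25,
    }
    return EffectProfile(
        "in_between", {k: (t[k], _PLACEBO_CHANGES[k]) for k in _ALL}
    )


def negative_profile() -> EffectProfile:
    """No treatment effect: both arms share the placebo change parameters."""
    return EffectProfile(
        "negative", {k: (_PLACEBO_CHANGES[k], _PLACEBO_CHANGES[k]) for k in _ALL}
    )


_PROFILES = {
    "positive": positive_profile,
    "in_between": in_between_profile,
    "negative": negative_profile,
}


@dataclass(frozen=True)
class SubgroupSpec:
    """A planted covariate-defined subgroup with extra treatment benefit.

    Patients with ``covariate > threshold`` in the treatment arm receive
    ``extra[name]`` additional mean change per instrument.
    """

    covariate: str
    threshold: float = 0.0
    extra: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated trial."""

    trial_id: str
    n: int
    profile: EffectProfile
    seed: int
    rho: float = 0.4
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    subgroup: SubgroupSpec | None = None
    evaluation_week: int = 24
    n_noise_covariates: int = 3

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need n ≥ 4 (at least 2 patients per arm)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        for name, rate in self.missingness.items():
            if name not in _ALL:
                raise ValueError(f"unknown instrument {name!r} in missingness")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missingness rates must be probabilities")


# ----------------------------------------------------------------------
# Baseline marginals (range-respecting defaults)
# ----------------------------------------------------------------------

def _baseline_from_uniform(name: str, u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 1e-9, 1 - 1e-9)
    if name == "clin_essdai":
        x = stats.nbinom.ppf(u, 3, 3 / 13.0)  # mean 10
        return np.clip(x, 0, 40)
    if name == "esspri":
        a, b = (0 - 6) / 2.0, (10 - 6) / 2.0
        return np.round(stats.truncnorm.ppf(u, a, b, loc=6, scale=2), 1)
    if name == "schirmer_mm":
        pi0 = 0.10
        x = np.where(u < pi0, 0.0,
                     stats.gamma.ppf((u - pi0) / (1 - pi0), 1.5, scale=4.0))
        return np.clip(np.round(x), 0, 40)
    if name == "oss":
        return stats.binom.ppf(u, 12, 0.35)
    if name == "uwsf_ml_min":
        pi0 = 0.15
        x = np.where(u < pi0, 0.0,
                     stats.gamma.ppf((u - pi0) / (1 - pi0), 1.2, scale=0.15))
        return np.round(x, 2)
    if name == "hocevar":
        a, b = (0 - 18) / 8.0, (48 - 18) / 8.0
        return np.round(stats.truncnorm.ppf(u, a, b, loc=18, scale=8))
    if name == "igg_g_l":
        return np.round(stats.lognorm.ppf(u, 0.3, scale=14.0), 1)
    if name == "rf_iu_ml":
        pi0 = 0.30
        x = np.where(u < pi0, 0.0,
                     stats.lognorm.ppf((u - pi0) / (1 - pi0), 0.8, scale=40.0))
        return np.round(x)
    raise KeyError(name)


def _finalise(name: str, x: np.ndarray) -> np.ndarray:
    step, low, high = _ROUNDING[name]
    x = np.round(x / step) * step
    x = np.maximum(x, low)
    if high is not None:
        x = np.minimum(x, high)
    return x


def simulate_trial(config: SimConfig) -> TrialDataset:
    """Generate one two-visit trial; identical config ⇒ identical dataset."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    n_t = n - n // 2
    arm = np.array(["treatment"] * n_t + ["placebo"] * (n // 2))
    rng.shuffle(arm)
    treated = arm == "treatment"

    # covariates
    covs: dict[str, np.ndarray] = {
        "age": np.round(rng.normal(55, 12, n)),
        "disease_duration": np.round(rng.gamma(2.0, 4.0, n), 1),
    }
    for j in range(1, config.n_noise_covariates + 1):
        covs[f"x{j}"] = np.round(rng.standard_normal(n), 3)

    # correlated baselines through a single latent severity factor
    severity = rng.standard_normal(n)
    baseline: dict[str, np.ndarray] = {}
    for name in _ALL:
        sign = _SEVERITY_SIGN[name]
        z = (np.sqrt(config.rho) * sign * severity
             + np.sqrt(1 - config.rho) * rng.standard_normal(n))
        baseline[name] = _baseline_from_uniform(name, stats.norm.cdf(z))

    # subgroup membership (treatment-arm extra benefit)
    in_subgroup = np.zeros(n, dtype=bool)
    if config.subgroup is not None:
        sg = config.subgroup
        if sg.covariate not in covs:
            raise ValueError(f"subgroup covariate {sg.covariate!r} not generated")
        in_subgroup = covs[sg.covariate] > sg.threshold

    followup: dict[str, np.ndarray] = {}
    for name in _ALL:
        t_delta, p_delta = config.profile.changes[name]
        delta = np.where(treated, t_delta, p_delta).astype(float)
        if config.subgroup is not None:
            extra = config.subgroup.extra.get(name, 0.0)
            delta = delta + np.where(treated & in_subgroup, extra, 0.0)
        noise = rng.normal(0.0, _NOISE_SD[name], n)
        base = baseline[name]
        if name in _ADDITIVE:
            fu = base + delta + noise
        else:
            fu = np.where(
                base > 0,
                base * (1.0 + delta + noise),
                np.maximum(0.0, (delta + noise) * _TYPICAL[name]),
            )
        followup[name] = _finalise(name, fu)

    # instrument-level availability: a missing instrument is missing at
    # both visits (emulating trials that did not collect it)
    available = {
        name: rng.random(n) >= config.missingness.get(name, 0.0)
        for name in _ALL
    }

    records = []
    width = len(str(n))
    for i in range(n):
        base_vals = {
            name: float(baseline[name][i]) if available[name][i] else None
            for name in _ALL
        }
        fu_vals = {
            name: float(followup[name][i]) if available[name][i] else None
            for name in _ALL
        }
        records.append(PatientRecord(
            patient_id=f"{config.trial_id}-{i + 1:0{width}d}",
            arm=str(arm[i]),
            baseline=VisitMeasurements(**base_vals),
            followup=VisitMeasurements(**fu_vals),
            covariates={k: float(v[i]) for k, v in covs.items()},
        ))
    return TrialDataset(
        trial_id=config.trial_id,
        expert_class=config.profile.label,
        records=tuple(records),
        evaluation_week=config.evaluation_week,
    )


#: (size, expert class) per trial, in source-table order.
DEFAULT_TRIAL_PLAN = (
    (80, "in_between"),
    (52, "negative"),
    (120, "negative"),
    (29, "positive"),
    (27, "positive"),
    (32, "positive"),
    (133, "in_between"),
    (120, "in_between"),
    (110, "negative"),
)


def default_suite_configs(master_seed: int, rho: float = 0.4,
                          missingness: Mapping[str, float] | None = None,
                          ) -> list[SimConfig]:
    """SimConfigs for the default nine-trial suite, with per-trial child
    seeds derived reproducibly from ``master_seed``."""
    children = np.random.SeedSequence(master_seed).spawn(len(DEFAULT_TRIAL_PLAN))
    configs = []
    for i, ((size, label), child) in enumerate(zip(DEFAULT_TRIAL_PLAN, children), 1):
        cfg = SimConfig(
            trial_id=f"T{i}",
            n=size,
            profile=_PROFILES[label](),
            seed=int(child.generate_state(1)[0]),
            rho=rho,
        )
        if missingness is not None:
            cfg = dataclasses.replace(cfg, missingness=dict(missingness))
        configs.append(cfg)
    return configs


def simulate_suite(
    suite: Sequence[SimConfig] | None = None,
    master_seed: int = 0,
) -> list[TrialDataset]:
    """Simulate a list of trials; default is the nine-trial suite."""
    if suite is None:
        suite = default_suite_configs(master_seed)
    if not suite:
        raise ValueError("suite is empty")
    return [simulate_trial(cfg) for cfg in suite]


def simulate_binary_trial(
    n: int = 400,
    seed: int = 0,
    p_placebo: float = 0.25,
    effect: float = 0.0,
    subgroup_effect: float = 0.4,
    subgroup_covariate: int = 1,
    subgroup_threshold: float = 0.0,
    n_covariates: int = 5,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Directly simulated binary-response trial for subgroup-discovery work.

    Returns (covariates ``x1..xk``, arm indicator, binary response).  The
    response probability is ``p_placebo`` plus, in the treatment arm,
    ``effect`` everywhere and ``subgroup_effect`` where the chosen
    covariate exceeds ``subgroup_threshold``.  Probabilities are clipped
    to [0.01, 0.99].
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, n_covariates)),
        columns=[f"x{j + 1}" for j in range(n_covariates)],
    )
    arm = rng.integers(0, 2, n)
    in_sub = X[f"x{subgroup_covariate}"].to_numpy() > subgroup_threshold
    p = p_placebo + arm * (effect + subgroup_effect * in_sub)
    p = np.clip(p, 0.01, 0.99)
    y = (rng.random(n) < p).astype(int)
    return X, arm, y
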