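"""Random-effects meta-analysis of per-trial treatment effects.

Binary endpoints are pooled as odds ratios: the fixed-effect estimate uses
the Mantel–Haenszel method (tolerant of zero cells, computed on the raw
counts), while the random-effects estimate uses inverse-variance weights
1/(v_i + τ²) on per-study log-ORs, with a 0.5 continuity correction added
to all four cells of any study containing a zero cell.  Continuous
endpoints are pooled as Hedges' g with the inverse-variance method.  The
between-study variance τ² is the Paule–Mandel moment estimator, and its
confidence interval comes from the Q-profile method (profiling the
generalised Cochran Q against χ²_{k−1} quantiles).

The null reference is OR = 1 for binary effects and SMD = 0 for continuous
ones; pooled CIs use the normal approximation (no Knapp–Hartung unless
requested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .metrics import hedges_correction

__all__ = [
    "TwoByTwo",
    "ContinuousStudy",
    "MetaResult",
    "PauleMandelResult",
    "pool_binary",
    "pool_continuous",
    "paule_mandel_tau2",
    "q_profile_ci",
    "log_odds_ratio",
    "forest_plot",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Responder counts for one study: events/size per arm."""

    events_t: float
    n_t: float
    events_p: float
    n_p: float

    def __post_init__(self) -> None:
        for events, n in ((self.events_t, self.n_t), (self.events_p, self.n_p)):
            if n <= 0:
                raise ValueError("arm sizes must be positive")
            if not 0 <= events <= n:
                raise ValueError(f"events {events} outside [0, {n}]")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (
            self.events_t, self.n_t - self.events_t,
            self.events_p, self.n_p - self.events_p,
        )


@dataclass(frozen=True)
class ContinuousStudy:
    """Per-arm summary statistics for a continuous endpoint."""

    mean_t: float
    sd_t: float
    n_t: int
    mean_p: float
    sd_p: float
    n_p: int

    def __post_init__(self) -> None:
        if self.sd_t < 0 or self.sd_p < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_t < 2 or self.n_p < 2:
            raise ValueError("each arm needs n ≥ 2")
        if self.sd_t == 0 and self.sd_p == 0:
            raise ValueError("both arms have zero SD; SMD undefined")


@dataclass(frozen=True)
class PauleMandelResult:
    tau2: float
    converged: bool
    n_iter: int
    estimable: bool = True


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect on the analysis scale (log-OR or SMD) with heterogeneity.

    ``pooled`` / ``ci_low`` / ``ci_high`` are the random-effects results;
    ``fixed`` is the fixed-effect estimate (Mantel–Haenszel for binary,
    inverse variance for continuous) with its own CI.  ``pooled_or`` is the
    back-transformed odds ratio for binary analyses, None otherwise.
    """

    scale: str  # "log_or" or "smd"
    pooled: float
    ci_low: float
    ci_high: float
    fixed: float
    fixed_ci_low: float
    fixed_ci_high: float
    tau2: float
    tau2_ci: tuple[float, float] | None
    tau_ci: tuple[float, float] | None
    q: float
    weights: tuple[float, ...]
    k: int
    effects: tuple[float, ...]
    variances: tuple[float, ...]

    @property
    def pooled_or(self) -> float | None:
        return math.exp(self.pooled) if self.scale == "log_or" else None

    @property
    def null_value(self) -> float:
        """Null reference on the analysis scale (log 1 = 0 either way)."""
        return 0.0


def log_odds_ratio(study: TwoByTwo, cc: float = 0.5) -> tuple[float, float]:
    """Per-study log-OR and variance; the continuity correction ``cc`` is
    added to all four cells iff the study contains a zero cell."""
    a = study.events_t
    b = study.n_t - study.events_t
    c = study.events_p
    d = study.n_p - study.events_p
    if study.has_zero_cell:
        a, b, c, d = a + cc, b + cc, c + cc, d + cc
    y = math.log((a * d) / (b * c))
    v = 1 / a + 1 / b + 1 / c + 1 / d
    return y, v


def paule_mandel_tau2(
    effects: Sequence[float],
    variances: Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PauleMandelResult:
    """Paule–Mandel between-study variance.

    Solves Σ w_i(τ²)(y_i − μ̂(τ²))² = k − 1 with w_i = 1/(v_i + τ²) by
    fixed-point iteration, truncated at zero.  With k = 1 the variance is
    not estimable and 0 is returned flagged.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if np.any(v <= 0):
        raise ValueError("within-study variances must be positive")
    k = len(y)
    if k < 2:
        return PauleMandelResult(tau2=0.0, converged=True, n_iter=0, estimable=False)

    def q_gen(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        return float(np.sum(w * (y - mu) ** 2))

    if q_gen(0.0) <= k - 1:
        return PauleMandelResult(tau2=0.0, converged=True, n_iter=0)
    tau2 = float(np.var(y, ddof=1))  # starting value
    for i in range(1, max_iter + 1):
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        num = float(np.sum(w * (y - mu) ** 2)) - (k - 1)
        den = float(np.sum(w**2 * (y - mu) ** 2))
        step = num / den
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < tol:
            return PauleMandelResult(tau2=new, converged=True, n_iter=i)
        tau2 = new
    return PauleMandelResult(tau2=tau2, converged=False, n_iter=max_iter)


def q_profile_ci(
    effects: Sequence[float],
    variances: Sequence[float],
    level: float = 0.95,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Q-profile confidence interval for τ² and τ.

    The bounds are the τ² values at which the generalised Q statistic
    equals the upper/lower χ²_{k−1} quantiles; empty intersections are
    truncated at 0 and the τ interval is the element-wise square root.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("Q-profile CI needs at least 2 studies")
    if np.any(v <= 0):
        raise ValueError("within-study variances must be positive")
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1 - alpha / 2, k - 1)
    q_lo = stats.chi2.ppf(alpha / 2, k - 1)

    def q_gen(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        return float(np.sum(w * (y - mu) ** 2))

    def solve(target: float) -> float:
        # Q(τ²) decreases monotonically in τ²
        if q_gen(0.0) <= target:
            return 0.0
        hi = 1.0
        while q_gen(hi) > target:
            hi *= 2.0
            if hi > 1e8:  # pragma: no cover - pathological inputs
                return hi
        from scipy.optimize import brentq

        return float(brentq(lambda t: q_gen(t) - target, 0.0, hi, xtol=1e-12))

    lower = solve(q_hi)
    upper = solve(q_lo)
    tau2_ci = (lower, upper)
    return tau2_ci, (math.sqrt(lower), math.sqrt(upper))


def _random_effects(
    y: np.ndarray, v: np.ndarray, level: float
) -> tuple[float, float, float, np.ndarray, PauleMandelResult]:
    pm = paule_mandel_tau2(y, v) if len(y) >= 2 else PauleMandelResult(0.0, True, 0, False)
    w = 1.0 / (v + pm.tau2)
    w = w / w.sum()
    pooled = float(np.sum(w * y))
    se = math.sqrt(1.0 / np.sum(1.0 / (v + pm.tau2)))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return pooled, pooled - z * se, pooled + z * se, w, pm


def _cochran_q(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    return float(np.sum(w * (y - mu) ** 2))


def _mantel_haenszel(
    studies: Sequence[TwoByTwo], level: float
) -> tuple[float, float, float]:
    """MH pooled log-OR with Robins–Breslow–Greenland CI (raw counts)."""
    import statsmodels.stats.contingency_tables as ct

    tables = np.empty((2, 2, len(studies)))
    for i, s in enumerate(studies):
        tables[:, :, i] = [
            [s.events_t, s.n_t - s.events_t],
            [s.events_p, s.n_p - s.events_p],
        ]
    with np.errstate(divide="ignore", invalid="ignore"):
        strat = ct.StratifiedTable(tables)
        log_or = float(strat.logodds_pooled)
        lo, hi = strat.logodds_pooled_confint(alpha=1 - level)
    if not all(math.isfinite(x) for x in (log_or, lo, hi)):
        raise ValueError("MH estimate degenerate (zero marginal)")
    return log_or, float(lo), float(hi)


def pool_binary(studies: Sequence[TwoByTwo], level: float = 0.95) -> MetaResult:
    """Pool 2×2 studies as odds ratios (MH fixed + Paule–Mandel random)."""
    if not studies:
        raise ValueError("no studies to pool")
    pairs = [log_odds_ratio(s) for s in studies]
    y = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    try:
        fixed, f_lo, f_hi = _mantel_haenszel(studies, level)
    except (ZeroDivisionError, FloatingPointError, ValueError):
        # degenerate tables (e.g. zero MH denominator): fall back to IV on
        # the continuity-corrected per-study effects
        w = 1.0 / v
        fixed = float(np.sum(w * y) / np.sum(w))
        se = math.sqrt(1.0 / np.sum(w))
        z = stats.norm.ppf(1 - (1 - level) / 2)
        f_lo, f_hi = fixed - z * se, fixed + z * se
    pooled, lo, hi, w, pm = _random_effects(y, v, level)
    k = len(studies)
    tau2_ci = tau_ci = None
    if k >= 2:
        tau2_ci, tau_ci = q_profile_ci(y, v, level)
    return MetaResult(
        scale="log_or", pooled=pooled, ci_low=lo, ci_high=hi,
        fixed=fixed, fixed_ci_low=f_lo, fixed_ci_high=f_hi,
        tau2=pm.tau2, tau2_ci=tau2_ci, tau_ci=tau_ci,
        q=_cochran_q(y, v), weights=tuple(w), k=k,
        effects=tuple(y), variances=tuple(v),
    )


def smd_study(study: ContinuousStudy) -> tuple[float, float]:
    """Hedges' g and its large-sample variance for one study."""
    n1, n2 = study.n_t, study.n_p
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * study.sd_t**2 + (n2 - 1) * study.sd_p**2) / df
    d = (study.mean_t - study.mean_p) / math.sqrt(sp2)
    g = hedges_correction(n1, n2) * d
    # Hedges–Olkin large-sample variance with the small-sample denominator
    v_g = (n1 + n2) / (n1 * n2) + g**2 / (2 * (n1 + n2 - 3.94))
    return g, v_g


def pool_continuous(
    studies: Sequence[ContinuousStudy], level: float = 0.95
) -> MetaResult:
    """Pool continuous studies as Hedges' g (inverse variance + PM random)."""
    if not studies:
        raise ValueError("no studies to pool")
    pairs = [smd_study(s) for s in studies]
    y = np.array([p[0] for p in pairs])
    v = np.array([p[1] for p in pairs])
    w_fixed = 1.0 / v
    fixed = float(np.sum(w_fixed * y) / np.sum(w_fixed))
    se = math.sqrt(1.0 / np.sum(w_fixed))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    pooled, lo, hi, w, pm = _random_effects(y, v, level)
    k = len(studies)
    tau2_ci = tau_ci = None
    if k >= 2:
        tau2_ci, tau_ci = q_profile_ci(y, v, level)
    return MetaResult(
        scale="smd", pooled=pooled, ci_low=lo, ci_high=hi,
        fixed=fixed, fixed_ci_low=fixed - z * se, fixed_ci_high=fixed + z * se,
        tau2=pm.tau2, tau2_ci=tau2_ci, tau_ci=tau_ci,
        q=_cochran_q(y, v), weights=tuple(w), k=k,
        effects=tuple(y), variances=tuple(v),
    )


def forest_plot(result: MetaResult, labels: Sequence[str] | None = None,
                path: str | None = None):
    """Minimal forest plot of per-study effects and the pooled estimate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = result.k
    labels = list(labels) if labels else [f"study {i + 1}" for i in range(k)]
    fig, ax = plt.subplots(figsize=(6, 1 + 0.4 * (k + 1)))
    z = stats.norm.ppf(0.975)
    for i, (y, v) in enumerate(zip(result.effects, result.variances)):
        se = math.sqrt(v)
        ax.errorbar(y, k - i, xerr=z * se, fmt="s", color="black", capsize=2)
    ax.errorbar(result.pooled, 0,
                xerr=[[result.pooled - result.ci_low], [result.ci_high - result.pooled]],
                fmt="D", color="firebrick", capsize=3)
    ax.axvline(result.null_value, linestyle=":", color="grey")
    ax.set_yticks(list(range(k, -1, -1)))
    ax.set_yticklabels(labels + ["pooled (RE)"])
    ax.set_xlabel("log OR" if result.scale == "log_or" else "SMD (Hedges' g)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
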