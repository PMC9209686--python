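"""Between-arm discrimination and sensitivity-to-change statistics.

Cohen's d uses the pooled-SD two-sample form; its confidence interval is
obtained by the noncentrality-parameter method — root-finding the
noncentral-t distribution's noncentrality so that the observed t statistic
sits at the desired tail probabilities, then rescaling the bounding NCPs by
sqrt(1/n1 + 1/n2).  Hedges' g applies the small-sample correction
J = 1 − 3/(4·df − 1).  The C-index is the Mann–Whitney concordance
probability (ties credited 0.5); on a binary responder indicator it equals
the AUC of responder status against arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "EffectSizeResult",
    "CIndexResult",
    "cohens_d",
    "hedges_g",
    "hedges_correction",
    "c_index",
    "classify_effect_size",
]

# Exact all-pairs counting below this pair count, rank formula above;
# both give identical concordance.
_EXACT_PAIR_LIMIT = 10**6


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    pooled_sd: float
    category: str


@dataclass(frozen=True)
class CIndexResult:
    c: float
    n1: int
    n2: int


def classify_effect_size(d: float) -> str:
    """Magnitude class: |d| > 0.8 large, 0.5–0.8 moderate, < 0.5 small."""
    if not math.isfinite(d):
        raise ValueError(f"effect size must be finite, got {d}")
    a = abs(d)
    if a > 0.8:
        return "large"
    if a >= 0.5:
        return "moderate"
    return "small"


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(s2))


def _nct_cdf(t_obs: float, df: int, ncp: float) -> float:
    """Noncentral-t CDF, mapping deep-tail NaN underflow to its limit."""
    value = stats.nct.cdf(t_obs, df, ncp)
    if math.isnan(value):
        return 0.0 if ncp > t_obs else 1.0
    return float(value)


def _ncp_bound(t_obs: float, df: int, prob: float) -> float:
    """NCP at which the noncentral-t CDF of t_obs equals ``prob``."""
    lo, hi = -abs(t_obs) - 10.0, abs(t_obs) + 10.0
    f = lambda ncp: _nct_cdf(t_obs, df, ncp) - prob  # noqa: E731
    # widen if the default bracket does not straddle the root
    while f(lo) < 0:
        lo -= 10.0
    while f(hi) > 0:
        hi += 10.0
    return float(brentq(f, lo, hi, xtol=1e-8))


def cohens_d(
    values_t: np.ndarray | list,
    values_p: np.ndarray | list,
    level: float = 0.95,
) -> EffectSizeResult:
    """Standardised mean difference with a noncentral-t confidence interval.

    d = (mean_t − mean_p) / s_pooled.  The CI searches for the NCPs whose
    noncentral-t tail probabilities bracket the observed t statistic and
    converts them back to the effect-size scale.
    """
    x = np.asarray(values_t, dtype=float)
    y = np.asarray(values_p, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs at least 2 values")
    sp = _pooled_sd(x, y)
    if sp == 0:
        raise ValueError("pooled variance is zero; effect size undefined")
    d = float((x.mean() - y.mean()) / sp)
    scale = math.sqrt(1.0 / n1 + 1.0 / n2)
    t_obs = d / scale
    df = n1 + n2 - 2
    alpha = 1.0 - level
    ncp_low = _ncp_bound(t_obs, df, 1.0 - alpha / 2.0)
    ncp_high = _ncp_bound(t_obs, df, alpha / 2.0)
    return EffectSizeResult(
        d=d,
        ci_low=ncp_low * scale,
        ci_high=ncp_high * scale,
        n1=n1,
        n2=n2,
        pooled_sd=sp,
        category=classify_effect_size(d),
    )


def hedges_correction(n1: int, n2: int) -> float:
    """Small-sample bias factor J = 1 − 3/(4·(n1+n2−2) − 1)."""
    df = n1 + n2 - 2
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(values_t: np.ndarray | list, values_p: np.ndarray | list) -> float:
    """Bias-corrected standardised mean difference g = J·d."""
    x = np.asarray(values_t, dtype=float)
    y = np.asarray(values_p, dtype=float)
    res = cohens_d(x, y)
    return hedges_correction(res.n1, res.n2) * res.d


def c_index(
    outcomes_t: np.ndarray | list, outcomes_p: np.ndarray | list
) -> CIndexResult:
    """Concordance of treatment vs placebo outcomes (higher = better).

    c = [#(t > p) + 0.5·#(t = p)] / (n1·n2) over all cross-arm pairs —
    the Mann–Whitney probability scaled to [0, 1]; 1 is perfectly
    discriminant, 0.5 no better than random, below 0.5 worse than random.
    """
    x = np.asarray(outcomes_t, dtype=float)
    y = np.asarray(outcomes_p, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both arms must be non-empty")
    if n1 * n2 <= _EXACT_PAIR_LIMIT:
        diff = x[:, None] - y[None, :]
        wins = float(np.count_nonzero(diff > 0))
        ties = float(np.count_nonzero(diff == 0))
        c = (wins + 0.5 * ties) / (n1 * n2)
    else:
        ranks = stats.rankdata(np.concatenate([x, y]))
        r1 = ranks[:n1].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        c = float(u) / (n1 * n2)
    return CIndexResult(c=float(c), n1=n1, n2=n2)
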