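"""Virtual-twins subgroup discovery for a binary response definition.

Two-stage procedure: (1) estimate each patient's response probability
under treatment (p1) and under placebo (p0) with a probabilistic learner
fit on covariates plus the arm indicator, predicting twice with the arm
toggled; predictions are cross-fitted (out-of-fold) to limit optimism.
(2) Partition the estimated individual effect z = p1 − p0 with a
regression tree; each leaf is a candidate subgroup reported with its size
and the relative risk (RR) of response, treatment vs placebo, inside it.

Because leaves are chosen where z is largest, their in-sample RR is
optimistic.  A procedure-level optimism estimate is computed by K-fold
cross-validation — rediscover the best leaf on each training split, take
the mean gap between its training and held-out log-RR — and subtracted
from every leaf's log-RR.

Subgroups are selected when the optimism-corrected RR is notably higher
than the whole-population RR (a configurable multiplier, default 1.5×)
and the subgroup holds enough patients for statistical power (default
≥60).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .trial_data import PatientRecord, TrialDataset

__all__ = [
    "TwinsSettings",
    "TwinEstimates",
    "SubgroupResult",
    "TwinsTree",
    "fit_twins",
    "fit_twins_arrays",
    "grow_tree",
    "select_subsets",
]


@dataclass(frozen=True)
class TwinsSettings:
    """Learner and cross-fitting hyperparameters (all overridable)."""

    n_estimators: int = 500
    min_samples_leaf: int = 5
    max_depth: int | None = None
    n_folds: int = 10
    seed: int = 0


@dataclass(frozen=True)
class TwinEstimates:
    """Cross-fitted per-patient response probabilities and effects."""

    p1: np.ndarray  # P(response | treatment)
    p0: np.ndarray  # P(response | placebo)
    X: pd.DataFrame  # covariates only (no arm column)
    y: np.ndarray
    arm: np.ndarray  # 1 = treatment
    settings: TwinsSettings
    n_dropped: int = 0

    @property
    def z(self) -> np.ndarray:
        return self.p1 - self.p0


@dataclass(frozen=True)
class SubgroupResult:
    """One candidate subgroup (a leaf of the effect tree)."""

    rule: str
    n: int
    mean_z: float
    rr_subgroup: float  # nan when placebo responders = 0 inside the leaf
    rr_overall: float  # nan when undefined
    optimism_corrected_rr: float
    selected: bool = False
    rr_overall_defined: bool = True
    leaf_id: int = -1


@dataclass(frozen=True)
class TwinsTree:
    """Fitted effect tree with its leaf subgroups."""

    leaves: tuple[SubgroupResult, ...]
    optimism_log_rr: float
    tree: DecisionTreeRegressor = field(repr=False, compare=False, default=None)


def _make_learner(settings: TwinsSettings) -> BaggingClassifier:
    return BaggingClassifier(
        estimator=DecisionTreeClassifier(
            min_samples_leaf=settings.min_samples_leaf,
            max_depth=settings.max_depth,
            random_state=settings.seed,
        ),
        n_estimators=settings.n_estimators,
        random_state=settings.seed,
        n_jobs=1,
    )


def fit_twins_arrays(
    y: np.ndarray,
    arm: np.ndarray,
    X: pd.DataFrame,
    settings: TwinsSettings | None = None,
) -> TwinEstimates:
    """Cross-fitted twin probabilities from raw arrays.

    ``y`` is the binary response, ``arm`` the treatment indicator, ``X``
    the baseline covariates.  Out-of-fold predictions: each patient's p1
    and p0 come from a learner that never saw them.
    """
    settings = settings or TwinsSettings()
    y = np.asarray(y, dtype=int)
    arm = np.asarray(arm, dtype=int)
    if X.shape[1] < 2:
        raise ValueError("virtual twins needs at least 2 covariates")
    if len(np.unique(y)) < 2:
        raise ValueError("response is single-class; twins cannot be fit")
    n = len(y)
    features = X.copy()
    features["__arm__"] = arm
    p1 = np.empty(n)
    p0 = np.empty(n)
    splitter = StratifiedKFold(
        n_splits=settings.n_folds, shuffle=True, random_state=settings.seed
    )
    # stratify on response x arm so every fold sees both arms and classes
    strata = y * 2 + arm
    for train_idx, test_idx in splitter.split(features, strata):
        learner = _make_learner(settings)
        learner.fit(features.iloc[train_idx], y[train_idx])
        pos = int(np.where(learner.classes_ == 1)[0][0])
        for value, target in ((1, p1), (0, p0)):
            toggled = features.iloc[test_idx].copy()
            toggled["__arm__"] = value
            target[test_idx] = learner.predict_proba(toggled)[:, pos]
    return TwinEstimates(p1=p1, p0=p0, X=X, y=y, arm=arm, settings=settings)


def fit_twins(
    dataset: TrialDataset,
    response: Callable[[PatientRecord], bool | None],
    covariates: Sequence[str],
    settings: TwinsSettings | None = None,
) -> TwinEstimates:
    """Twin estimates for a trial dataset and a responder definition.

    Records whose response is undetermined (``None``) or that lack one of
    the requested covariates are dropped and counted in ``n_dropped``.
    """
    rows, ys, arms = [], [], []
    dropped = 0
    for record in dataset.records:
        outcome = response(record)
        values = [record.covariates.get(c) for c in covariates]
        if outcome is None or any(v is None for v in values):
            dropped += 1
            continue
        rows.append(values)
        ys.append(int(bool(outcome)))
        arms.append(1 if record.arm == "treatment" else 0)
    X = pd.DataFrame(rows, columns=list(covariates))
    est = fit_twins_arrays(np.array(ys), np.array(arms), X, settings)
    return replace(est, n_dropped=dropped)


# ----------------------------------------------------------------------
# Effect tree and subgroup selection
# ----------------------------------------------------------------------

def _cc_log_rr(y: np.ndarray, arm: np.ndarray, mask: np.ndarray) -> float:
    """Continuity-corrected log relative risk inside ``mask``."""
    t = mask & (arm == 1)
    p = mask & (arm == 0)
    rate_t = (y[t].sum() + 0.5) / (t.sum() + 1.0)
    rate_p = (y[p].sum() + 0.5) / (p.sum() + 1.0)
    return math.log(rate_t / rate_p)


def _cc_log_rr_var(y: np.ndarray, arm: np.ndarray, mask: np.ndarray) -> float:
    """Sampling variance of the continuity-corrected log RR."""
    t = mask & (arm == 1)
    p = mask & (arm == 0)
    a, n1 = y[t].sum() + 0.5, t.sum() + 1.0
    c, n2 = y[p].sum() + 0.5, p.sum() + 1.0
    return max(1e-12, 1 / a - 1 / n1 + 1 / c - 1 / n2)


def _shrink_leaf_log_rrs(
    ys: np.ndarray, vs: np.ndarray, mu: float, optimism: float
) -> np.ndarray:
    """Empirical-Bayes shrinkage of leaf log-RRs toward the population value.

    The between-leaf variance τ² is a DerSimonian–Laird moment estimate;
    each leaf keeps the fraction τ²/(τ²+v_i) of its deviation from the
    overall log-RR.  When the leaves are homogeneous (no real subgroup
    structure) τ̂² ≈ 0 and every leaf collapses onto the population RR.
    The cross-validated procedure optimism is then subtracted from
    upward deviations, never pushing a leaf below the population value.
    """
    if len(ys) < 2:
        return ys.copy()
    w = 1.0 / vs
    mu_w = float(np.sum(w * ys) / np.sum(w))
    q = float(np.sum(w * (ys - mu_w) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    # homogeneity pretest: only admit between-leaf variance when the leaf
    # RRs are far more heterogeneous than sampling noise explains (α = 0.01);
    # a conservative gate keeping the screening specific under the null
    from scipy.stats import chi2

    if q <= chi2.ppf(0.99, len(ys) - 1):
        tau2 = 0.0
    else:
        tau2 = max(0.0, (q - (len(ys) - 1)) / denom)
    shrink = tau2 / (tau2 + vs)
    out = mu + shrink * (ys - mu)
    above = out > mu
    out[above] = np.maximum(mu, out[above] - optimism)
    return out


def _raw_rr(y: np.ndarray, arm: np.ndarray, mask: np.ndarray) -> float:
    t = mask & (arm == 1)
    p = mask & (arm == 0)
    if t.sum() == 0 or p.sum() == 0:
        return float("nan")
    rate_t = y[t].sum() / t.sum()
    rate_p = y[p].sum() / p.sum()
    if rate_p == 0:
        return float("nan")
    return rate_t / rate_p


def _leaf_rules(tree: DecisionTreeRegressor, columns: Sequence[str]) -> dict[int, str]:
    """Human-readable conjunction of split conditions for each leaf."""
    t = tree.tree_
    rules: dict[int, str] = {}

    def walk(node: int, conditions: list[str]) -> None:
        if t.children_left[node] == -1:
            rules[node] = " and ".join(conditions) if conditions else "(all patients)"
            return
        name = columns[t.feature[node]]
        thr = t.threshold[node]
        walk(t.children_left[node], conditions + [f"{name} <= {thr:.4g}"])
        walk(t.children_right[node], conditions + [f"{name} > {thr:.4g}"])

    walk(0, [])
    return rules


def _fit_effect_tree(
    X: pd.DataFrame, z: np.ndarray, min_leaf: int, seed: int
) -> DecisionTreeRegressor:
    """Regression tree on the estimated effect, pruned by cross-validated
    cost-complexity (1-SE rule) so that noise-only effects yield a
    root-only tree."""
    base = DecisionTreeRegressor(min_samples_leaf=max(1, min_leaf),
                                 random_state=seed)
    base.fit(X, z)
    alphas = np.unique(base.cost_complexity_pruning_path(X, z).ccp_alphas)
    if len(alphas) > 1:
        from sklearn.model_selection import KFold

        folds = KFold(n_splits=5, shuffle=True, random_state=seed)
        mse = np.zeros((len(alphas), folds.get_n_splits()))
        for j, (tr, te) in enumerate(folds.split(X)):
            for i, alpha in enumerate(alphas):
                t = DecisionTreeRegressor(
                    min_samples_leaf=max(1, min_leaf),
                    random_state=seed, ccp_alpha=alpha,
                ).fit(X.iloc[tr], z[tr])
                mse[i, j] = np.mean((t.predict(X.iloc[te]) - z[te]) ** 2)
        mean = mse.mean(axis=1)
        se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
        best = int(np.argmin(mean))
        # 1-SE rule: most heavily pruned tree within one SE of the best
        cutoff = mean[best] + se[best]
        chosen = max(a for a, m in zip(alphas, mean) if m <= cutoff)
        base = DecisionTreeRegressor(
            min_samples_leaf=max(1, min_leaf),
            random_state=seed, ccp_alpha=chosen,
        ).fit(X, z)
    return base


def _estimate_optimism(
    twins: TwinEstimates, min_leaf: int, seed: int, repeats: int = 3
) -> float:
    """Procedure-level optimism of the most enhanced leaf's log-RR.

    Repeated K-fold: rediscover the tree on each training split, take its
    leaf with the highest (continuity-corrected) RR — the quantity the
    selection step looks at — and record the gap between that leaf's
    training and held-out log-RR.  The mean gap, floored at zero, is
    subtracted from every leaf's log-RR.
    """
    X, y, arm, z = twins.X, twins.y, twins.arm, twins.z
    n = len(y)
    folds = min(twins.settings.n_folds, 5)
    gaps = []
    for r in range(repeats):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=seed + 7919 * r
        )
        for train_idx, test_idx in splitter.split(X, y * 2 + arm):
            scaled_leaf = max(2, int(round(min_leaf * len(train_idx) / n)))
            tree = _fit_effect_tree(
                X.iloc[train_idx], z[train_idx], scaled_leaf, seed
            )
            assign_train = tree.apply(X.iloc[train_idx])
            leaf_ids = np.unique(assign_train)
            if len(leaf_ids) < 2:
                gaps.append(0.0)  # root-only rediscovery: nothing to overfit
                continue

            def train_rr(leaf: int) -> float:
                mask = np.zeros(n, dtype=bool)
                mask[train_idx[assign_train == leaf]] = True
                return _cc_log_rr(y, arm, mask)

            best = max(leaf_ids, key=train_rr)
            mask_train = np.zeros(n, dtype=bool)
            mask_train[train_idx[assign_train == best]] = True
            assign_test = tree.apply(X.iloc[test_idx])
            mask_test = np.zeros(n, dtype=bool)
            mask_test[test_idx[assign_test == best]] = True
            if mask_test.sum() == 0:
                continue
            gaps.append(
                _cc_log_rr(y, arm, mask_train) - _cc_log_rr(y, arm, mask_test)
            )
    # the correction never increases an RR
    return max(0.0, float(np.mean(gaps))) if gaps else 0.0


def grow_tree(
    twins: TwinEstimates, min_leaf: int = 60, seed: int | None = None
) -> TwinsTree:
    """Partition the estimated treatment effect into candidate subgroups.

    ``min_leaf`` is the smallest allowed subgroup (default 60, the
    statistical-power floor used when screening responder subsets).  When
    fewer patients than ``min_leaf`` are available the tree is a single
    root.  Ties and randomness are pinned by the seed.
    """
    if min_leaf < 1:
        raise ValueError("min_leaf must be ≥ 1")
    seed = twins.settings.seed if seed is None else seed
    X, y, arm, z = twins.X, twins.y, twins.arm, twins.z
    tree = _fit_effect_tree(X, z, min_leaf, seed)
    assignments = tree.apply(X)
    rules = _leaf_rules(tree, list(X.columns))
    overall_rr = _raw_rr(y, arm, np.ones(len(y), dtype=bool))
    optimism = _estimate_optimism(twins, min_leaf, seed)
    all_mask = np.ones(len(y), dtype=bool)
    mu = _cc_log_rr(y, arm, all_mask)
    leaf_ids = [l for l in sorted(rules) if (assignments == l).sum() > 0]
    masks = [assignments == l for l in leaf_ids]
    ys = np.array([_cc_log_rr(y, arm, m) for m in masks])
    vs = np.array([_cc_log_rr_var(y, arm, m) for m in masks])
    corrected = _shrink_leaf_log_rrs(ys, vs, mu, optimism)
    leaves = []
    for leaf_id, mask, corr in zip(leaf_ids, masks, corrected):
        leaves.append(SubgroupResult(
            rule=rules[leaf_id],
            n=int(mask.sum()),
            mean_z=float(z[mask].mean()),
            rr_subgroup=_raw_rr(y, arm, mask),
            rr_overall=overall_rr,
            optimism_corrected_rr=math.exp(corr),
            rr_overall_defined=not math.isnan(overall_rr),
            leaf_id=int(leaf_id),
        ))
    return TwinsTree(leaves=tuple(leaves), optimism_log_rr=optimism, tree=tree)


def select_subsets(
    tree: TwinsTree,
    rr_ratio_min: float = 1.5,
    n_min: int = 60,
) -> list[SubgroupResult]:
    """Flag subgroups with notably enhanced response.

    Selected iff the optimism-corrected RR is at least ``rr_ratio_min``
    times the whole-population RR AND the subgroup holds ≥ ``n_min``
    patients.  When the overall RR is undefined (no placebo responders)
    the ratio criterion cannot be assessed and the subgroup is left
    unselected, flagged via ``rr_overall_defined``.
    """
    if not tree.leaves:
        raise ValueError("tree has no leaves")
    out = []
    for leaf in tree.leaves:
        if leaf.rr_overall_defined:
            selected = (
                leaf.optimism_corrected_rr >= rr_ratio_min * leaf.rr_overall
                and leaf.n >= n_min
            )
        else:
            selected = False
        out.append(replace(leaf, selected=selected))
    return out
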