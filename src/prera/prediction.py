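"""Baseline prediction of RA conversion and time-to-onset modelling.

Classification side: random-forest Gini importance ranks baseline
cellular (Tph %, GZMK+XCL1+ CD8 %, GZMB+CD57+ CD8 %) and clinical (age,
sex, CCP3, RF, shared-epitope dosage) features; AUROC with a stratified
bootstrap CI evaluates composite models; an rpart-style decision tree
with equal class priors (0.5/0.5), Gini splitting, depth 4, minimum
bucket 1 and complexity parameter 0 exposes interpretable risk strata.

Survival side: subjects are stratified into bottom 20% / middle 60% /
top 20% bins per feature; Cox proportional hazards (Efron ties, via
lifelines) estimates hazard ratios of the bins against the bottom bin,
and Kaplan-Meier curves with the log-rank test compare the strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .io import (DegenerateStratificationError, NoEventsError)

__all__ = ["gini_importance", "roc_auc", "fit_decision_tree", "TreeNode",
           "predict_tree", "stratify_quantiles", "fit_cox", "km_logrank",
           "SurvivalFit"]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def gini_importance(features: pd.DataFrame, outcome, n_trees: int = 500,
                    seed: int = 0) -> pd.Series:
    """Random-forest mean-decrease-in-Gini importance, ranked descending.

    Grows ``n_trees`` classification trees on bootstrap resamples with
    sqrt(p) candidate features per split and Gini splitting; deterministic
    given the seed.
    """
    y = np.asarray(outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need >=2 subjects per class")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", max_features="sqrt",
        bootstrap=True, random_state=int(seed))
    rf.fit(features.to_numpy(float), y)
    imp = pd.Series(rf.feature_importances_, index=features.columns)
    return imp.sort_values(ascending=False)


def roc_auc(scores, labels, n_boot: int = 2000,
            seed: int = 0) -> tuple[float, tuple[float, float]]:
    """AUROC by the rank (Mann-Whitney) estimator with midrank ties,
    plus a stratified-bootstrap 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    def auc(sv, yv):
        r = stats.rankdata(sv)
        n1, n0 = int(yv.sum()), int((~yv).sum())
        return (r[yv].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    point = float(auc(s, y))
    rng = np.random.default_rng(seed)
    pos, neg = np.where(y)[0], np.where(~y)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ix = np.concatenate([rng.choice(pos, len(pos)),
                             rng.choice(neg, len(neg))])
        boots[b] = auc(s[ix], y[ix])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Decision tree (rpart-style, priors-weighted Gini)
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Binary tree node; leaves have feature=None and report raw class
    fractions over the subjects reaching them."""
    n: int
    class_counts: tuple
    class_fractions: tuple
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None     # feature < threshold
    right: "TreeNode | None" = None
    depth: int = 0

    def to_dict(self) -> dict:
        d = {"n": self.n, "class_counts": list(self.class_counts),
             "class_fractions": list(self.class_fractions)}
        if self.feature is not None:
            d.update({"feature": self.feature,
                      "threshold": self.threshold,
                      "left": self.left.to_dict(),
                      "right": self.right.to_dict()})
        return d


def _prior_gini(n_by_class, root_n_by_class, priors):
    """Gini impurity of a node under prior-weighted class masses
    m_c = prior_c * n_c(node) / n_c(root); returns (impurity, total mass)."""
    m = np.array([p * n / r if r else 0.0
                  for n, r, p in zip(n_by_class, root_n_by_class, priors)])
    tot = m.sum()
    if tot == 0:
        return 0.0, 0.0
    frac = m / tot
    return float(1.0 - np.sum(frac ** 2)), float(tot)


def _best_split(X, y, feature_names, root_counts, priors, min_bucket):
    """Exhaustive scan over features and midpoint thresholds for the split
    maximizing the prior-weighted Gini decrease."""
    n_classes = len(root_counts)
    node_counts = np.bincount(y, minlength=n_classes)
    g_parent, m_parent = _prior_gini(node_counts, root_counts, priors)
    best = None
    for j, name in enumerate(feature_names):
        vals = X[:, j]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[order]
        uniq = np.unique(sv)
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2.0
            left = sv < thr
            if left.sum() < min_bucket or (~left).sum() < min_bucket:
                continue
            cl = np.bincount(sy[left], minlength=n_classes)
            cr = node_counts - cl
            gl, ml = _prior_gini(cl, root_counts, priors)
            gr, mr = _prior_gini(cr, root_counts, priors)
            gain = g_parent - (ml * gl + mr * gr) / m_parent
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, name, j, thr)
    return best


def fit_decision_tree(features: pd.DataFrame, outcome, max_depth: int = 4,
                      min_bucket: int = 1, cp: float = 0.0,
                      priors=(0.5, 0.5)) -> TreeNode:
    """Greedy classification tree with prior-weighted Gini splitting.

    Node class masses are m_c = prior_c * n_c(node) / n_c(root), so equal
    priors (the default) weight the classes equally regardless of the
    empirical class balance. Splitting stops at ``max_depth``, bucket
    size, or when no split has gain above ``cp`` (cp = 0 keeps every
    positive-gain split). Leaves report raw class fractions.
    """
    X = features.to_numpy()
    if not np.issubdtype(np.asarray(X).dtype, np.number):
        raise TypeError("non-numeric feature without encoding")
    X = X.astype(float)
    y, classes = pd.factorize(np.asarray(outcome), sort=True)
    root_counts = np.bincount(y, minlength=len(classes))
    names = list(features.columns)

    def grow(idx, depth):
        yy = y[idx]
        counts = np.bincount(yy, minlength=len(classes))
        node = TreeNode(
            n=len(idx), depth=depth,
            class_counts=tuple(int(c) for c in counts),
            class_fractions=tuple(float(c) / len(idx) for c in counts))
        if depth >= max_depth or len(np.unique(yy)) < 2:
            return node
        best = _best_split(X[idx], yy, names, root_counts, priors,
                           min_bucket)
        if best is None or best[0] <= cp:
            return node
        _, name, j, thr = best
        left_mask = X[idx, j] < thr
        node.feature, node.threshold = name, float(thr)
        node.left = grow(idx[left_mask], depth + 1)
        node.right = grow(idx[~left_mask], depth + 1)
        return node

    tree = grow(np.arange(len(y)), 0)
    tree.classes_ = list(classes)  # type: ignore[attr-defined]
    return tree


def predict_tree(tree: TreeNode, features: pd.DataFrame) -> np.ndarray:
    """Per-row class-1 fraction of the leaf each subject falls into."""
    out = np.empty(len(features))
    for i, (_, row) in enumerate(features.iterrows()):
        node = tree
        while node.feature is not None:
            node = (node.left if row[node.feature] < node.threshold
                    else node.right)
        out[i] = node.class_fractions[-1]
    return out


# ---------------------------------------------------------------------------
# Stratification and survival
# ---------------------------------------------------------------------------

def stratify_quantiles(values) -> pd.Series:
    """Bin subjects into bottom20 / middle60 / top20 by a feature.

    Thresholds are the k-th smallest and k-th largest values with
    k = floor(0.2 n) (nearest-rank 20th/80th percentiles); ties at a
    threshold go to the outer bin. Raises on a constant feature.
    """
    v = pd.Series(values).astype(float)
    if len(v) < 5:
        raise ValueError("need at least 5 subjects to stratify")
    if v.nunique() == 1:
        raise DegenerateStratificationError("feature is constant")
    srt = np.sort(v.to_numpy())
    k = int(np.floor(0.2 * len(v)))
    k = max(k, 1)
    low_thr, high_thr = srt[k - 1], srt[len(v) - k]
    labels = np.where(v <= low_thr, "bottom20",
                      np.where(v >= high_thr, "top20", "middle60"))
    return pd.Series(labels, index=v.index)


@dataclass
class SurvivalFit:
    terms: list
    log_hr: np.ndarray
    hr_ci: list                      # (low, high) per term on the HR scale
    wald_p: np.ndarray
    reference: dict                  # feature -> reference bin label
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "hr": np.exp(self.log_hr),
            "ci_low": [c[0] for c in self.hr_ci],
            "ci_high": [c[1] for c in self.hr_ci],
            "wald_p": self.wald_p,
        })


def fit_cox(survival: pd.DataFrame, terms: list,
            reference_bin: str = "bottom20") -> SurvivalFit:
    """Cox proportional hazards over binned features and covariates.

    ``survival`` needs time_to_event and event plus the term columns.
    Categorical (binned) terms are dummy-encoded against
    ``reference_bin`` (log HR = 0 by construction); numeric terms enter
    linearly. Ties are handled by the Efron approximation. A
    non-converging partial likelihood (e.g. monotone likelihood from
    separation) is flagged, never raised through.
    """
    if survival["event"].sum() == 0:
        raise NoEventsError("no observed events")
    cols = {}
    reference = {}
    for term in terms:
        col = survival[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = [lv for lv in pd.unique(col) if lv != reference_bin]
            reference[term] = reference_bin
            for lv in sorted(map(str, levels)):
                cols[f"{term}[{lv}]"] = (col.astype(str) == lv).astype(float)
        else:
            if col.astype(float).std() == 0:
                raise ValueError(f"term {term!r} is constant")
            cols[term] = col.astype(float)
    frame = pd.DataFrame(cols)
    frame["time_to_event"] = survival["time_to_event"].astype(float)
    frame["event"] = survival["event"].astype(bool)

    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time_to_event", event_col="event")
        converged = True
        log_hr = cph.params_.to_numpy()
        se = cph.standard_errors_.to_numpy()
        names = list(cph.params_.index)
        wald_p = cph.summary["p"].to_numpy()
    except ConvergenceError:
        converged = False
        names = list(frame.columns[:-2])
        log_hr = np.full(len(names), np.nan)
        se = np.full(len(names), np.nan)
        wald_p = np.full(len(names), np.nan)
    ci = [(float(np.exp(min(b - 1.96 * s, 700.0))),
           float(np.exp(min(b + 1.96 * s, 700.0))))
          for b, s in zip(log_hr, se)]
    return SurvivalFit(terms=names, log_hr=log_hr, hr_ci=ci, wald_p=wald_p,
                       reference=reference, converged=converged)


def km_logrank(survival: pd.DataFrame, groups) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Returns (curves, chi2, p) where curves maps group -> dict with the
    step function (time, survival) and the median (first time with
    survival <= 0.5; NaN when never reached).
    """
    g = pd.Series(np.asarray(groups), index=survival.index)
    if g.nunique() < 2:
        raise ValueError("need at least 2 groups")
    curves = {}
    for level, sub in survival.groupby(g):
        km = KaplanMeierFitter()
        km.fit(sub["time_to_event"], event_observed=sub["event"])
        sf = km.survival_function_
        curves[level] = {
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
            "median": float(km.median_survival_time_),
        }
    res = multivariate_logrank_test(
        survival["time_to_event"], g, survival["event"])
    return curves, float(res.test_statistic), float(res.p_value)
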