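import numpy as np
import pandas as pd
import pytest

from prera import synthetic as syn
from prera.io import (DegenerateStratificationError, NoEventsError)
from prera.prediction import (fit_cox, fit_decision_tree, gini_importance,
                              km_logrank, predict_tree, roc_auc,
                              stratify_quantiles)


class TestGiniImportance:
    def test_separating_feature_ranked_first(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.r_[np.zeros(15), np.ones(15)].astype(int)
            feats = pd.DataFrame(
                {"signal": y + r.normal(0, 0.05, 30)}
                | {f"noise{j}": r.normal(size=30) for j in range(5)})
            imp = gini_importance(feats, y, n_trees=100, seed=seed)
            hits += imp.index[0] == "signal"
        assert hits >= 19

    def test_constant_feature_zero_importance(self, rng):
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        feats = pd.DataFrame({"flat": np.ones(20),
                              "signal": y + rng.normal(0, 0.1, 20)})
        imp = gini_importance(feats, y, n_trees=50, seed=1)
        assert imp["flat"] == 0.0

    def test_deterministic_given_seed(self, rng):
        y = rng.integers(0, 2, 30)
        feats = pd.DataFrame(rng.normal(size=(30, 4)),
                             columns=list("abcd"))
        i1 = gini_importance(feats, y, n_trees=50, seed=7)
        i2 = gini_importance(feats, y, n_trees=50, seed=7)
        pd.testing.assert_series_equal(i1, i2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gini_importance(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=50)
        assert auc == 1.0

    def test_pairwise_count_oracle_with_ties(self):
        scores = np.array([0.3, 0.5, 0.5, 0.9])
        labels = np.array([0, 0, 1, 1])
        auc, _ = roc_auc(scores, labels, n_boot=50)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n)
                   for p in pos for n in neg) / (len(pos) * len(neg))
        assert auc == pytest.approx(wins)

    def test_null_auc_near_half(self, rng):
        aucs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            aucs.append(roc_auc(r.normal(size=40),
                                r.integers(0, 2, 40) if seed else
                                np.r_[np.zeros(20), np.ones(20)].astype(int),
                                n_boot=10, seed=seed)[0])
        aucs = np.array(aucs)
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se + 0.02

    def test_complement_symmetry(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        a1, _ = roc_auc(s, y, n_boot=10)
        a2, _ = roc_auc(-s, y, n_boot=10)
        assert a1 + a2 == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def _oracle_best_split(x, y, priors=(0.5, 0.5)):
    """Exhaustive threshold scan maximizing prior-weighted Gini gain for a
    single feature; independent reimplementation for the oracle."""
    root = np.bincount(y, minlength=2)

    def gini(counts):
        m = np.array([p * c / r if r else 0.0
                      for c, r, p in zip(counts, root, priors)])
        t = m.sum()
        return (1 - ((m / t) ** 2).sum() if t else 0.0), t

    g0, m0 = gini(np.bincount(y, minlength=2))
    best_gain, best_thr = -1.0, None
    for thr in np.unique(x)[:-1]:
        cut = (np.unique(x)[np.searchsorted(np.unique(x), thr) + 1] + thr) / 2
        left = x < cut
        gl, ml = gini(np.bincount(y[left], minlength=2))
        gr, mr = gini(np.bincount(y[~left], minlength=2))
        gain = g0 - (ml * gl + mr * gr) / m0
        if gain > best_gain + 1e-12:
            best_gain, best_thr = gain, cut
    return best_thr


class TestDecisionTree:
    def test_separable_depth_one(self):
        x = pd.DataFrame({"f": np.r_[np.zeros(5), np.ones(5)]})
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        tree = fit_decision_tree(x, y)
        assert tree.feature == "f"
        assert tree.left.feature is None and tree.right.feature is None
        assert tree.left.class_fractions == (1.0, 0.0)
        assert tree.right.class_fractions == (0.0, 1.0)

    def test_threshold_matches_exhaustive_scan_under_priors(self, rng):
        """Imbalanced classes with equal priors: the chosen root split
        equals the brute-force prior-weighted scan."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            n1, n0 = 8, 24   # priors != empirical frequencies
            x = np.concatenate([r.normal(1.2, 1.0, n1),
                                r.normal(-0.3, 1.0, n0)])
            y = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
            tree = fit_decision_tree(pd.DataFrame({"f": x}), y, max_depth=1)
            assert tree.threshold == pytest.approx(
                _oracle_best_split(x, y), abs=1e-9)

    def test_depth_cap(self):
        # alternating labels force one split per boundary; cap at 4
        x = pd.DataFrame({"f": np.arange(12, dtype=float)})
        y = np.array([0, 1] * 6)

        def depth(node):
            if node.feature is None:
                return node.depth
            return max(depth(node.left), depth(node.right))

        tree = fit_decision_tree(x, y, max_depth=4)
        assert depth(tree) == 4

    def test_min_bucket(self):
        x = pd.DataFrame({"f": np.arange(10, dtype=float)})
        y = np.array([0] * 9 + [1])
        tree = fit_decision_tree(x, y, min_bucket=3)
        if tree.feature is not None:
            assert tree.left.n >= 3 and tree.right.n >= 3

    def test_non_numeric_rejected(self):
        with pytest.raises(TypeError):
            fit_decision_tree(pd.DataFrame({"f": ["a", "b"]}), [0, 1])

    def test_predict_leaf_fractions(self):
        x = pd.DataFrame({"f": np.r_[np.zeros(4), np.ones(4)]})
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        tree = fit_decision_tree(x, y)
        risk = predict_tree(tree, x)
        assert risk[0] == pytest.approx(0.25)
        assert risk[-1] == pytest.approx(1.0)


class TestStratifyQuantiles:
    def test_nearest_rank_on_ten(self):
        bins = stratify_quantiles(list(range(1, 11)))
        assert list(bins[:2]) == ["bottom20", "bottom20"]
        assert list(bins[-2:]) == ["top20", "top20"]
        assert (bins[2:8] == "middle60").all()

    def test_order_invariance(self, rng):
        v = rng.normal(size=25)
        b1 = stratify_quantiles(pd.Series(v))
        perm = rng.permutation(25)
        b2 = stratify_quantiles(pd.Series(v[perm], index=perm))
        for i in range(25):
            assert b1[i] == b2[i]

    def test_ties_go_outer(self):
        v = [1, 1, 1, 2, 3, 4, 5, 6, 7, 8]
        bins = stratify_quantiles(v)
        assert (bins[:3] == "bottom20").all()

    def test_constant_raises(self):
        with pytest.raises(DegenerateStratificationError):
            stratify_quantiles([2.0] * 8)


def _exp_survival(n, rate_ratio, seed, censor=None):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.01 * rate_ratio ** x))
    event = np.ones(n, dtype=bool)
    if censor is not None:
        event = t < censor
        t = np.minimum(t, censor)
    return pd.DataFrame({"time_to_event": t, "event": event,
                         "x": x.astype(float)})


class TestCox:
    def test_hr_recovery(self):
        df = _exp_survival(200, 2.0, seed=0)
        fit = fit_cox(df, ["x"])
        hr = float(np.exp(fit.log_hr[0]))
        assert 1.6 <= hr <= 2.5
        assert fit.converged

    def test_null_coverage(self):
        covered = 0
        reps = 60
        for seed in range(reps):
            df = _exp_survival(80, 1.0, seed=seed)
            fit = fit_cox(df, ["x"])
            lo, hi = fit.hr_ci[0]
            covered += lo <= 1.0 <= hi
        assert covered / reps >= 0.88

    def test_no_events(self):
        df = _exp_survival(20, 1.0, seed=1)
        df["event"] = False
        with pytest.raises(NoEventsError):
            fit_cox(df, ["x"])

    def test_degenerate_two_subjects_flagged(self):
        df = pd.DataFrame({"time_to_event": [1.0, 2.0],
                           "event": [True, True], "x": [0.0, 1.0]})
        fit = fit_cox(df, ["x"])  # monotone likelihood: flagged, no crash
        assert isinstance(fit.converged, bool)

    def test_binned_terms_reference(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "time_to_event": rng.exponential(100, 60),
            "event": True,
            "bin": rng.choice(["bottom20", "middle60", "top20"], 60)})
        fit = fit_cox(df, ["bin"])
        assert fit.reference["bin"] == "bottom20"
        assert all("bottom20" not in t for t in fit.terms)

    def test_score_equation_near_zero(self):
        """Partial-likelihood gradient vanishes at the estimate."""
        df = _exp_survival(150, 1.8, seed=3)
        fit = fit_cox(df, ["x"])
        beta = fit.log_hr[0]
        order = np.argsort(df["time_to_event"].to_numpy())
        t = df["time_to_event"].to_numpy()[order]
        x = df["x"].to_numpy()[order]
        grad = 0.0
        for i in range(len(t)):   # no ties in continuous draws
            risk = t >= t[i]
            w = np.exp(beta * x[risk])
            grad += x[i] - float((w * x[risk]).sum() / w.sum())
        assert abs(grad) < 1e-4 * len(t)

    def test_single_binary_term_matches_grid_search(self):
        """Log-HR agrees with a brute-force partial-likelihood grid."""
        df = _exp_survival(60, 2.0, seed=4)
        fit = fit_cox(df, ["x"])
        order = np.argsort(df["time_to_event"].to_numpy())
        t = df["time_to_event"].to_numpy()[order]
        x = df["x"].to_numpy()[order]

        def pl(beta):
            ll = 0.0
            for i in range(len(t)):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return ll

        grid = np.arange(-1.0, 2.5, 0.001)
        best = grid[np.argmax([pl(b) for b in grid])]
        assert fit.log_hr[0] == pytest.approx(best, abs=1e-3)


class TestKmLogrank:
    def test_median_equals_sample_median_without_censoring(self):
        times = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        df = pd.DataFrame({"time_to_event": np.concatenate([times, [1.0]]),
                           "event": True,
                           "g": ["a"] * 5 + ["b"]})
        curves, _, _ = km_logrank(df, df["g"])
        assert curves["a"]["median"] == pytest.approx(np.median(times))

    def test_duplicated_groups_null(self):
        df = pd.DataFrame({"time_to_event": [5.0, 10.0, 15.0] * 2,
                           "event": True,
                           "g": ["a"] * 3 + ["b"] * 3})
        _, chi2, p = km_logrank(df, df["g"])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_risk_table_oracle(self):
        """Six subjects, no censoring: chi-square from a hand enumeration
        of the risk tables."""
        df = pd.DataFrame({"time_to_event": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                           "event": True,
                           "g": ["a"] * 3 + ["b"] * 3})
        _, chi2, p = km_logrank(df, df["g"])
        # hand enumeration over event times 1..6
        o_minus_e = 0.0
        var = 0.0
        t = df["time_to_event"].to_numpy()
        g = (df["g"] == "a").to_numpy()
        for ti in sorted(t):
            at_risk = t >= ti
            n = at_risk.sum()
            n_a = (at_risk & g).sum()
            d = 1  # one event at each time
            o = 1 if g[t == ti][0] else 0
            e = d * n_a / n
            o_minus_e += o - e
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected = o_minus_e ** 2 / var
        assert chi2 == pytest.approx(expected, rel=1e-6)

    def test_curve_monotone_from_one(self, small_cohort):
        clinical, _ = small_cohort
        cl = clinical.assign(feat=np.random.default_rng(3).normal(
            size=len(clinical)))
        surv = syn.generate_survival(cl, {"feat": 0.4}, seed=9)
        curves, _, _ = km_logrank(surv, surv["group"])
        for c in curves.values():
            s = c["survival"]
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"time_to_event": [1.0, 2.0], "event": True,
                           "g": ["a", "a"]})
        with pytest.raises(ValueError):
            km_logrank(df, df["g"])

    def test_cox_planted_recovery_via_generator(self, small_cohort):
        """generate_survival -> fit_cox round trip recovers the planted
        hazard ratio for a standardized feature."""
        clinical, _ = small_cohort
        big = pd.concat([clinical.assign(
            subject_id=clinical["subject_id"] + f"_{k}")
            for k in range(10)], ignore_index=True)
        rng = np.random.default_rng(12)
        big["feat"] = rng.normal(size=len(big))
        surv = syn.generate_survival(big, {"feat": np.log(2.0)}, seed=13)
        conv = surv[surv["group"] == "Converter"].copy()
        conv["feat_std"] = ((conv["feat"] - surv["feat"].mean())
                            / surv["feat"].std())
        fit = fit_cox(conv, ["feat_std"])
        hr = float(np.exp(fit.log_hr[0]))
        assert 1.5 <= hr <= 2.7
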