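"""RA-associated CDR3 risk scoring and the inference layers above it.

Scoring: a CDR3beta amino-acid sequence of length 12-17 scores the sum of
position-specific coefficients beta(length, position, residue); sequences
outside that length range score exactly 0, which together with the
sparsity of the coefficient table produces a large spike of exact zeros.

Zero-inflated Gaussian model: exact zeros are attributed to the
structural-zero component — a continuous Gaussian assigns probability 0
to the point {0} — so the likelihood factorizes exactly into a logistic
regression of the zero indicator on CDR3 length and a Gaussian model of
the non-zero scores with group x visit cell means. Directional group
hypotheses are tested by one-sided z contrasts on the conditional means.

Bayesian comparison: a hierarchical Gaussian model with group x visit
fixed effects (Normal(0,1) priors), a CDR3-length random intercept
(half-Cauchy(0,1) prior on its SD and on the residual SD), sampled by an
adaptive Metropolis-within-Gibbs scheme over 4 chains; one-sided contrast
probabilities are fractions of post-warmup draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import (AA_SET, DegenerateFitError, InvalidSequenceError,
                 RiskCoefficientTable, SCORE_MAX_LEN, SCORE_MIN_LEN)

__all__ = ["score_cdr3", "score_table", "ZIGaussianFit", "fit_zi_gaussian",
           "one_sided_contrast", "PosteriorComparison", "bayes_compare"]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_cdr3(cdr3_aa: str, coefficients: RiskCoefficientTable) -> float:
    """Risk score of one CDR3 sequence (0 outside lengths 12-17)."""
    if not cdr3_aa or not set(cdr3_aa) <= AA_SET:
        raise InvalidSequenceError(f"invalid CDR3 sequence {cdr3_aa!r}")
    length = len(cdr3_aa)
    if not SCORE_MIN_LEN <= length <= SCORE_MAX_LEN:
        return 0.0
    return float(sum(coefficients.lookup(length, pos, aa)
                     for pos, aa in enumerate(cdr3_aa, start=1)))


def score_table(clonotypes: pd.DataFrame, meta: pd.DataFrame,
                coefficients: RiskCoefficientTable,
                chain: str = "TRB") -> pd.DataFrame:
    """Score every clonotype of the given chain and attach cell metadata.

    Returns one row per scored receptor with columns score, length, and
    the grouping labels (sample_id, group, visit) from ``meta``.
    """
    sub = clonotypes[clonotypes["chain"] == chain]
    scores = [score_cdr3(s, coefficients) for s in sub["cdr3_aa"]]
    out = pd.DataFrame({
        "cell_id": sub["cell_id"].to_numpy(),
        "cdr3_aa": sub["cdr3_aa"].to_numpy(),
        "length": sub["cdr3_aa"].str.len().to_numpy(),
        "score": scores,
    })
    return out.merge(meta, on="cell_id", how="inner")


# ---------------------------------------------------------------------------
# Zero-inflated Gaussian model
# ---------------------------------------------------------------------------

@dataclass
class ZIGaussianFit:
    zero_coefs: np.ndarray            # logit(pi) = a + b * length
    mu: dict                          # (group, visit) -> conditional mean
    mu_var: dict                      # (group, visit) -> variance of mean
    sigma: float
    loglik: float
    n_zero: int
    n_nonzero: int
    boundary_zero_model: bool = False
    random_effects: object = None     # MixedLM result when requested

    def pi(self, length) -> np.ndarray:
        """Fitted structural-zero probability at the given length(s)."""
        eta = self.zero_coefs[0] + self.zero_coefs[1] * np.asarray(
            length, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_zi_gaussian(scores: pd.DataFrame,
                    random_intercepts: bool = False) -> ZIGaussianFit:
    """Maximum-likelihood zero-inflated Gaussian fit of per-cell scores.

    ``scores`` needs columns score, length, group, visit (and sample_id if
    ``random_intercepts``). Exact zeros are structural, so the likelihood
    splits into (i) a logistic regression of the zero indicator on CDR3
    length and (ii) a Gaussian model of the non-zero scores with a cell
    mean per group x visit; the reported log-likelihood is their sum.
    Optional per-sample random intercepts in the conditional model are
    fitted by REML via statsmodels MixedLM.
    """
    z = (scores["score"] == 0.0).to_numpy()
    if z.all():
        raise DegenerateFitError("all scores are zero")
    boundary = False
    if not z.any():
        # no zeros: pi -> 0 at every length, logit coefficients at the
        # boundary; flagged rather than fitted
        zero_coefs = np.array([-np.inf, 0.0])
        zero_ll = 0.0
        boundary = True
    else:
        X = sm.add_constant(scores["length"].astype(float).to_numpy())
        try:
            zfit = sm.Logit(z.astype(float), X).fit(disp=0, maxiter=200)
            zero_coefs = np.asarray(zfit.params, dtype=float)
            zero_ll = float(zfit.llf)
        except Exception:  # perfect separation in tiny fixtures
            boundary = True
            p0 = z.mean()
            zero_coefs = np.array([np.log(p0 / (1 - p0)), 0.0])
            zero_ll = float(np.sum(z * np.log(p0) + (~z) * np.log1p(-p0)))

    nz = scores.loc[~z]
    mu, mu_var, resid = {}, {}, []
    for key, sub in nz.groupby(["group", "visit"]):
        vals = sub["score"].to_numpy(float)
        mu[key] = float(vals.mean())
        resid.append(vals - vals.mean())
    resid = np.concatenate(resid)
    sigma = float(np.sqrt(np.mean(resid ** 2)))  # ML, not n-1
    for key, sub in nz.groupby(["group", "visit"]):
        mu_var[key] = sigma ** 2 / len(sub)
    gauss_ll = float(np.sum(stats.norm.logpdf(resid, scale=sigma)))

    re_result = None
    if random_intercepts:
        cond = nz.assign(gv=nz["group"] + ":" + nz["visit"])
        re_result = sm.MixedLM.from_formula(
            "score ~ 0 + C(gv)", groups="sample_id", data=cond).fit(reml=True)

    return ZIGaussianFit(zero_coefs=zero_coefs, mu=mu, mu_var=mu_var,
                         sigma=sigma, loglik=zero_ll + gauss_ll,
                         n_zero=int(z.sum()), n_nonzero=int((~z).sum()),
                         boundary_zero_model=boundary,
                         random_effects=re_result)


def one_sided_contrast(fit: ZIGaussianFit, contrast) -> float:
    """One-sided p-value that the first (group, visit) cell mean exceeds
    the second, from the conditional (non-zero) model."""
    first, second = tuple(contrast[0]), tuple(contrast[1])
    for level in (first, second):
        if level not in fit.mu:
            raise ValueError(f"level {level} absent from fit")
    se = float(np.sqrt(fit.mu_var[first] + fit.mu_var[second]))
    zstat = (fit.mu[first] - fit.mu[second]) / se
    return float(stats.norm.sf(zstat))


# ---------------------------------------------------------------------------
# Bayesian hierarchical comparison
# ---------------------------------------------------------------------------

@dataclass
class PosteriorComparison:
    contrast: tuple                   # ((group, visit), (group, visit))
    prob_greater: float
    mean_diff: float
    ci_low: float
    ci_high: float
    converged: bool
    rhat_max: float


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat over chains x draws for one scalar parameter."""
    m, n = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]])
    k, length = segs.shape
    means = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    b = length * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (length - 1) / length * w + b / length
    return float(np.sqrt(var_hat / w))


def _log_half_cauchy(x):
    return -np.log1p(x * x)  # up to a constant, support x > 0


def bayes_compare(scores: pd.DataFrame, level: str = "cell",
                  contrasts=None, chains: int = 4, iterations: int = 2000,
                  seed: int = 0, keep_zeros: bool = True):
    """Posterior group comparisons of CDR3 risk scores.

    Model: score ~ Normal(b[group:visit] + a[length], sigma^2) with
    Normal(0,1) priors on the fixed effects b, a length random intercept
    a ~ Normal(0, tau^2), and half-Cauchy(0,1) priors on tau and sigma.
    ``level='cell'`` uses individual receptors restricted to CDR3 lengths
    12-17 (exact zeros retained by default); ``level='sample'`` first
    averages scores per (sample, visit, length). Sampling: ``chains``
    adaptive Metropolis-within-Gibbs chains of ``iterations`` draws each,
    first half discarded as warmup; conjugate Gibbs updates for b, a and
    random-walk Metropolis on log tau, log sigma. Convergence is judged
    by split-Rhat < 1.05 over all parameters.

    Returns (list of PosteriorComparison, diagnostics dict).
    """
    if level not in ("cell", "sample"):
        raise ValueError("level must be 'cell' or 'sample'")
    df = scores[(scores["length"] >= SCORE_MIN_LEN)
                & (scores["length"] <= SCORE_MAX_LEN)].copy()
    if not keep_zeros:
        df = df[df["score"] != 0.0]
    if level == "sample":
        df = (df.groupby(["sample_id", "group", "visit", "length"])
              ["score"].mean().reset_index())
    if df.empty:
        # no data: the posterior is the prior. Draw the fixed effects from
        # Normal(0,1) for the requested contrast levels.
        if not contrasts:
            raise DegenerateFitError("no observations and no contrasts")
        levels = sorted({tuple(lv) for pair in contrasts for lv in pair})
        rng = np.random.default_rng(seed)
        flat = rng.normal(0.0, 1.0, size=(chains * (iterations // 2),
                                          len(levels)))
        ix = {lv: k for k, lv in enumerate(levels)}
        results = []
        for first, second in contrasts:
            diff = flat[:, ix[tuple(first)]] - flat[:, ix[tuple(second)]]
            lo, hi = np.percentile(diff, [2.5, 97.5])
            results.append(PosteriorComparison(
                contrast=(tuple(first), tuple(second)),
                prob_greater=float(np.mean(diff > 0)),
                mean_diff=float(diff.mean()), ci_low=float(lo),
                ci_high=float(hi), converged=True, rhat_max=1.0))
        return results, {"rhat": {}, "posterior_sd_b": flat.std(axis=0),
                         "levels": [f"{g}:{v}" for g, v in levels],
                         "seed": int(seed)}

    y = df["score"].to_numpy(float)
    gv_labels = (df["group"] + ":" + df["visit"]).to_numpy()
    gv_codes, gv_levels = pd.factorize(gv_labels, sort=True)
    l_codes, l_levels = pd.factorize(df["length"].to_numpy(), sort=True)
    n_gv, n_len = len(gv_levels), len(l_levels)
    use_length_re = n_len > 1
    if not use_length_re:
        import warnings
        warnings.warn("single CDR3 length level: length random effect "
                      "dropped", stacklevel=2)

    n = len(y)
    counts_gv = np.bincount(gv_codes, minlength=n_gv).astype(float)
    counts_l = np.bincount(l_codes, minlength=n_len).astype(float)
    half = iterations // 2
    rng_master = np.random.default_rng(seed)
    child_seeds = rng_master.integers(0, 2 ** 31 - 1, size=chains)

    b_draws = np.empty((chains, half, n_gv))
    scale_draws = np.empty((chains, half, 2))  # sigma, tau

    for c in range(chains):
        rng = np.random.default_rng(child_seeds[c])
        b = rng.normal(0.0, 0.1, size=n_gv)
        a_raw = np.zeros(n_len)        # non-centered: a = tau * a_raw
        sigma = max(float(y.std()), 0.1)
        tau = 0.5 if use_length_re else 0.0
        step_sigma = step_tau = 0.2
        acc_sigma = acc_tau = 0
        for it in range(iterations):
            a = tau * a_raw
            # b | rest: conjugate normal, prior N(0, 1)
            r = y - a[l_codes]
            sum_r = np.bincount(gv_codes, weights=r, minlength=n_gv)
            prec = counts_gv / sigma ** 2 + 1.0
            mean = (sum_r / sigma ** 2) / prec
            b = mean + rng.normal(size=n_gv) / np.sqrt(prec)
            if use_length_re:
                # a_raw | rest: conjugate normal (non-centered, prior
                # N(0,1)); the non-centered form keeps the chain mobile
                # when tau sits near zero
                r = y - b[gv_codes]
                sum_r = np.bincount(l_codes, weights=r, minlength=n_len)
                prec = tau ** 2 * counts_l / sigma ** 2 + 1.0
                mean = (tau * sum_r / sigma ** 2) / prec
                a_raw = mean + rng.normal(size=n_len) / np.sqrt(prec)
                # tau | rest: RW Metropolis on log tau; likelihood enters
                # through sum (r - tau*a_raw)^2
                s_rr = float(r @ r)
                ra = np.bincount(l_codes, weights=r, minlength=n_len)
                s_ra = float(ra @ a_raw)
                s_aa = float((counts_l * a_raw ** 2).sum())

                def tau_logpost(t):
                    rss_t = s_rr - 2.0 * t * s_ra + t * t * s_aa
                    return (-0.5 * rss_t / sigma ** 2
                            + _log_half_cauchy(t) + np.log(t))  # + Jacobian

                t_new = float(np.exp(np.log(tau) + step_tau * rng.normal()))
                if np.log(rng.random()) < tau_logpost(t_new) - tau_logpost(tau):
                    tau = t_new
                    acc_tau += 1
                # interweaved centered-parametrization tau update (ASIS):
                # holding a = tau * a_raw fixed, tau^2 | a is inverse
                # gamma up to the half-Cauchy prior, so an independence
                # proposal from that factor is accepted with the (near
                # unity) prior ratio; alternating both forms mixes tau
                # whether the posterior sits near zero or away from it
                a_cent = tau * a_raw
                s_aa_c = float(a_cent @ a_cent)
                alpha = (n_len - 1) / 2.0
                phi_new = (0.5 * s_aa_c) / rng.gamma(alpha) \
                    if s_aa_c > 0 else tau ** 2
                if np.log(rng.random()) < np.log1p(tau ** 2) - np.log1p(phi_new):
                    tau = float(np.sqrt(phi_new))
                a_raw = a_cent / tau
                # recentering sweep: the likelihood is invariant to
                # (b + delta, a_raw - delta/tau); drawing delta from its
                # prior conditional moves the common level, which the
                # one-at-a-time conjugate updates explore only slowly
                prec_d = n_gv + n_len / tau ** 2
                mean_d = (-b.sum() + a_raw.sum() / tau) / prec_d
                delta = mean_d + rng.normal() / np.sqrt(prec_d)
                b = b + delta
                a_raw = a_raw - delta / tau
            # sigma | rest: RW Metropolis on log sigma
            resid = y - b[gv_codes] - tau * a_raw[l_codes]
            rss = float(resid @ resid)

            def sigma_logpost(s):
                return (-n * np.log(s) - 0.5 * rss / s ** 2
                        + _log_half_cauchy(s) + np.log(s))

            s_new = float(np.exp(np.log(sigma) + step_sigma * rng.normal()))
            if np.log(rng.random()) < sigma_logpost(s_new) - sigma_logpost(sigma):
                sigma = s_new
                acc_sigma += 1
            # adapt proposal scales during warmup toward ~44% acceptance
            if it < half and (it + 1) % 50 == 0:
                step_sigma *= np.exp(acc_sigma / 50.0 - 0.44)
                acc_sigma = 0
                if use_length_re:
                    step_tau *= np.exp(acc_tau / 50.0 - 0.44)
                    acc_tau = 0
            if it >= iterations - half:
                j = it - (iterations - half)
                b_draws[c, j] = b
                scale_draws[c, j] = (sigma, tau)

    rhat = {}
    for k, name in enumerate(gv_levels):
        rhat[f"b[{name}]"] = _split_rhat(b_draws[:, :, k])
    rhat["sigma"] = _split_rhat(scale_draws[:, :, 0])
    if use_length_re:
        rhat["tau"] = _split_rhat(scale_draws[:, :, 1])
    rhat_max = max(rhat.values())
    converged = rhat_max < 1.05

    level_ix = {}
    for k, name in enumerate(gv_levels):
        g, v = name.split(":")
        level_ix[(g, v)] = k
    if contrasts is None:
        contrasts = [(gv1, gv2) for gv1 in level_ix for gv2 in level_ix
                     if gv1 != gv2]

    flat = b_draws.reshape(-1, n_gv)
    results = []
    for first, second in contrasts:
        first, second = tuple(first), tuple(second)
        if first not in level_ix or second not in level_ix:
            raise ValueError(f"contrast level missing: {first} vs {second}")
        diff = flat[:, level_ix[first]] - flat[:, level_ix[second]]
        lo, hi = np.percentile(diff, [2.5, 97.5])
        results.append(PosteriorComparison(
            contrast=(first, second),
            prob_greater=float(np.mean(diff > 0)),
            mean_diff=float(diff.mean()),
            ci_low=float(lo), ci_high=float(hi),
            converged=converged, rhat_max=float(rhat_max)))
    diagnostics = {"rhat": rhat, "posterior_sd_b": flat.std(axis=0),
                   "levels": list(gv_levels), "seed": int(seed)}
    return results, diagnostics
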