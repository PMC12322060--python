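"""Cross-context effect sharing and beta-binomial allelic imbalance.

The sharing model is an empirical-Bayes mixture over canonical covariance
patterns (null, context-singletons, independent, equal-across-contexts on a
scale grid), fit on a random effect subset and applied to the strong (top
eVariant) subset — the strong/random workflow used for multi-context eQTL
sharing.  The sharing-by-magnitude statistic calls a pair of contexts
"shared" when the two effects agree in sign and within a magnitude factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("sceqtl")

__all__ = [
    "EbModel",
    "canonical_covariances",
    "eb_shrink",
    "pairwise_sharing",
    "allelic_imbalance",
    "betabinom_two_sided_p",
]


# ---------------------------------------------------------------------------
# empirical-Bayes shrinkage over canonical covariances (mash-style)
# ---------------------------------------------------------------------------

@dataclass
class EbModel:
    contexts: list[str]
    cov_names: list[str]
    covariances: list[np.ndarray]
    weights: np.ndarray                 # mixture weights, sum to 1
    posterior_mean: pd.DataFrame        # estimate_subset effects x contexts
    lfsr: pd.DataFrame                  # same shape
    converged: bool
    n_iter: int


def canonical_covariances(
    n_contexts: int,
    scales: np.ndarray | None = None,
) -> tuple[list[str], list[np.ndarray]]:
    """Null, identity, per-context singleton and equal-effects covariances,
    each on a geometric scale grid."""
    if scales is None:
        scales = 2.0 ** np.arange(-2, 4)
    base = [("identity", np.eye(n_contexts)), ("equal", np.ones((n_contexts, n_contexts)))]
    for i in range(n_contexts):
        U = np.zeros((n_contexts, n_contexts))
        U[i, i] = 1.0
        base.append((f"singleton_{i}", U))
    names, covs = ["null"], [np.zeros((n_contexts, n_contexts))]
    for w in scales:
        for nm, U in base:
            names.append(f"{nm}_x{w:g}")
            covs.append(w * U)
    return names, covs


def _component_loglik(B: np.ndarray, S: np.ndarray, covs: list[np.ndarray]) -> np.ndarray:
    """log N(b_j; 0, U_k + diag(s_j^2)) for every effect j and component k."""
    n, R = B.shape
    out = np.empty((n, len(covs)))
    for k, U in enumerate(covs):
        for j in range(n):
            V = U + np.diag(S[j] ** 2) + 1e-8 * np.eye(R)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                V = V + 1e-6 * np.eye(R)
                L = np.linalg.cholesky(V)
            sol = np.linalg.solve(L, B[j])
            out[j, k] = (
                -0.5 * R * np.log(2 * np.pi)
                - np.log(np.diag(L)).sum()
                - 0.5 * float(sol @ sol)
            )
    return out


def eb_shrink(
    effects: pd.DataFrame,
    ses: pd.DataFrame,
    fit_subset: np.ndarray | None = None,
    estimate_subset: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EbModel:
    """Fit mixture weights by EM on the fit subset; shrink the estimate subset.

    ``effects``/``ses`` are effects x contexts.  ``fit_subset`` indexes the
    random rows used for the weight EM, ``estimate_subset`` the strong rows
    for which posterior means and local false sign rates are returned
    (defaults: all rows for both).
    """
    B = effects.to_numpy(float)
    S = ses.to_numpy(float)
    if B.shape != S.shape:
        raise ValueError("effects and ses must be aligned")
    contexts = list(effects.columns)
    n, R = B.shape
    fit_idx = np.arange(n) if fit_subset is None else np.asarray(fit_subset)
    est_idx = np.arange(n) if estimate_subset is None else np.asarray(estimate_subset)

    names, covs = canonical_covariances(R)
    K = len(covs)
    ll_fit = _component_loglik(B[fit_idx], S[fit_idx], covs)

    w = np.full(K, 1.0 / K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logr = ll_fit + np.log(np.clip(w, 1e-300, None))
        logr -= logsumexp(logr, axis=1, keepdims=True)
        w_new = np.exp(logr).mean(axis=0)
        w_new /= w_new.sum()
        delta = np.abs(w_new - w).max() / max(w.max(), 1e-12)
        w = w_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("eb_shrink: EM not converged after %d iterations (delta %.2g)", it, delta)

    ll_est = _component_loglik(B[est_idx], S[est_idx], covs)
    logr = ll_est + np.log(np.clip(w, 1e-300, None))
    logr -= logsumexp(logr, axis=1, keepdims=True)
    resp = np.exp(logr)

    pm = np.zeros((len(est_idx), R))
    p_nonneg = np.zeros((len(est_idx), R))  # P(b >= 0), point mass at 0 included
    p_nonpos = np.zeros((len(est_idx), R))
    for j, row in enumerate(est_idx):
        Vj = np.diag(S[row] ** 2)
        for k, U in enumerate(covs):
            if resp[j, k] < 1e-12:
                continue
            if not U.any():  # null component: point mass at zero
                p_nonneg[j] += resp[j, k]
                p_nonpos[j] += resp[j, k]
                continue
            A = U @ np.linalg.inv(U + Vj + 1e-10 * np.eye(R))
            mu = A @ B[row]
            cov = U - A @ U
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            pm[j] += resp[j, k] * mu
            p_pos = np.empty(R)
            degenerate = sd <= 0
            p_pos[~degenerate] = stats.norm.cdf(mu[~degenerate] / sd[~degenerate])
            # a zero-variance posterior is a point mass at mu
            p_pos[degenerate] = np.where(mu[degenerate] > 0, 1.0,
                                         np.where(mu[degenerate] < 0, 0.0, 0.5))
            both_zero = degenerate & (mu == 0)
            p_nonneg[j] += resp[j, k] * np.where(both_zero, 1.0, p_pos)
            p_nonpos[j] += resp[j, k] * np.where(both_zero, 1.0, 1 - p_pos)

    index = effects.index[est_idx]
    lfsr = np.minimum(p_nonneg, p_nonpos)
    # guard: probabilities of the two (closed) signs overlap only in the mass at 0
    lfsr = np.clip(lfsr, 0.0, 1.0)
    return EbModel(
        contexts=contexts,
        cov_names=names,
        covariances=covs,
        weights=w,
        posterior_mean=pd.DataFrame(pm, index=index, columns=contexts),
        lfsr=pd.DataFrame(lfsr, index=index, columns=contexts),
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# sharing by sign and magnitude
# ---------------------------------------------------------------------------

def pairwise_sharing(
    effects: pd.DataFrame,
    significant: pd.DataFrame | None = None,
    factor: float = 0.6,
    sig_threshold: float = 0.05,
) -> pd.DataFrame:
    """Proportion of effects shared by magnitude between context pairs.

    For each pair, over effects significant in at least one of the two
    contexts (``significant``: lfsr or q values; None means all effects):
    shared iff same sign and min(|b1|,|b2|)/max(|b1|,|b2|) >= ``factor``.
    Pairs with no significant effects get NaN; the diagonal is 1.
    """
    contexts = list(effects.columns)
    if len(contexts) < 2:
        raise ValueError("need >= 2 contexts")
    B = effects.to_numpy(float)
    if significant is not None:
        sig = significant.to_numpy(float) < sig_threshold
    else:
        sig = np.ones_like(B, dtype=bool)
    R = len(contexts)
    out = np.full((R, R), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(R):
        for j in range(i + 1, R):
            use = sig[:, i] | sig[:, j]
            if not use.any():
                continue
            b1, b2 = B[use, i], B[use, j]
            same_sign = np.sign(b1) * np.sign(b2) > 0
            lo = np.minimum(np.abs(b1), np.abs(b2))
            hi = np.maximum(np.abs(b1), np.abs(b2))
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(hi > 0, lo / hi, 0.0)
            shared = same_sign & (ratio >= factor)
            out[i, j] = out[j, i] = float(shared.mean())
    return pd.DataFrame(out, index=contexts, columns=contexts)


# ---------------------------------------------------------------------------
# beta-binomial allelic imbalance
# ---------------------------------------------------------------------------

def betabinom_two_sided_p(k: int, n: int, mu: float, rho: float) -> float:
    """Two-sided tail-doubling p under BetaBinomial(n, mu, rho); rho=0 is
    exact binomial."""
    if rho < 1e-12:  # shape parameters overflow; the limit is exact binomial
        lo = stats.binom.cdf(k, n, mu)
        hi = stats.binom.sf(k - 1, n, mu)
    else:
        a = mu * (1 / rho - 1)
        b = (1 - mu) * (1 / rho - 1)
        lo = stats.betabinom.cdf(k, n, a, b)
        hi = stats.betabinom.sf(k - 1, n, a, b)
    return float(min(1.0, 2 * min(lo, hi)))


def _pooled_rho_mle(k: np.ndarray, n: np.ndarray, mu: float) -> float:
    """Maximum-likelihood overdispersion with the mean fixed at mu."""

    def neg_ll(logit_rho):
        rho = 1 / (1 + np.exp(-logit_rho))
        a = mu * (1 / rho - 1)
        b = (1 - mu) * (1 / rho - 1)
        return -stats.betabinom.logpmf(k, n, a, b).sum()

    # binomial (rho -> 0) log-likelihood as the boundary reference
    ll_binom = stats.binom.logpmf(k, n, mu).sum()
    res = optimize.minimize_scalar(neg_ll, bounds=(-12, 6), method="bounded")
    if -res.fun <= ll_binom + 1e-9:
        return 0.0
    return float(1 / (1 + np.exp(-res.x)))


def allelic_imbalance(
    counts: pd.DataFrame,
    mu0: float = 0.5,
    min_depth: int = 10,
    rho_sites: str = "all",
) -> pd.DataFrame:
    """Two-sided beta-binomial test of allelic imbalance per site.

    A single overdispersion rho is estimated by maximum likelihood pooled
    across sites (``rho_sites``: 'all', or 'central-tertile' to restrict the
    fit to the sites whose reference fraction is closest to ``mu0``); each
    site with total >= ``min_depth`` is then tested against
    BetaBinomial(n, mu0, rho) with tail doubling, and BH-adjusted.
    """
    use = counts[counts["total"] >= min_depth].copy()
    if use.empty:
        raise ValueError(f"no sites with depth >= {min_depth}")
    k = use["ref_count"].to_numpy(int)
    n = use["total"].to_numpy(int)

    if rho_sites == "central-tertile":
        dev = np.abs(k / n - mu0)
        cut = np.quantile(dev, 1 / 3)
        mask = dev <= cut
        rho = _pooled_rho_mle(k[mask], n[mask], mu0)
    elif rho_sites == "all":
        rho = _pooled_rho_mle(k, n, mu0)
    else:
        raise ValueError(f"unknown rho_sites {rho_sites!r}")

    p = np.array([betabinom_two_sided_p(ki, ni, mu0, rho) for ki, ni in zip(k, n)])
    use["rho"] = rho
    use["p"] = p
    use["p_adj"] = multipletests(p, method="fdr_bh")[1]
    return use.reset_index(drop=True)
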