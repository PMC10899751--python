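"""Logistic regression machinery: single fits with a Firth fallback, and
Newton solvers vectorised across variants for genome-scale screening.

The single-model path is plain maximum likelihood via iteratively
reweighted least squares (IRLS).  When the optimiser walks off to a
separated solution (non-convergence with a coefficient beyond +/-15 on the
log-odds scale) the model is refit with Firth's penalised likelihood, which
always has a finite maximiser; the result records which method produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, special, stats

__all__ = ["LogisticFit", "fit_logistic", "batch_logistic_slope", "batch_interaction_test"]

_SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """Fitted logistic model on the log-odds scale."""

    params: np.ndarray
    cov: np.ndarray
    names: list
    converged: bool
    n_used: int
    separation_flag: bool
    method: str  # "ml" or "firth"
    loglik: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - q * self.se, self.params + q * self.se])

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "beta": self.params[i],
            "se": self.se[i],
            "z": self.zvalues[i],
            "p": self.pvalues[i],
        }


def _loglik(X, y, beta):
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _check_design(X, names):
    """Raise naming the offending columns when X is rank deficient."""
    n, k = X.shape
    if n < k:
        raise ValueError(f"design matrix has more columns ({k}) than rows ({n})")
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < k:
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def fit_logistic(
    X,
    y,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    allow_firth: bool = True,
) -> LogisticFit:
    """Fit P(y=1|x) = expit(x'beta) by maximum likelihood.

    Rows with any non-finite entry in X or y are dropped (complete-case).
    Convergence is |change in log-likelihood| < ``tol`` within ``max_iter``
    Newton steps (with step halving).  Separation triggers a Firth refit
    when ``allow_firth``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    n_used = int(keep.sum())
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError(f"outcome must be binary 0/1; found values {uniq[:5]}")
    if uniq.size < 2:
        raise ValueError("constant outcome: all responses identical")
    _check_design(X, names)

    beta = np.zeros(X.shape[1])
    ll = _loglik(X, y, beta)
    converged = False
    for _ in range(max_iter):
        p = special.expit(X @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - p)
        try:
            delta = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _loglik(X, y, cand)
            if ll_new >= ll - 1e-14:
                break
            step /= 2.0
        beta = beta + step * delta
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    # under separation the likelihood plateaus while coefficients diverge,
    # so the coefficient bound is the operative signal
    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND)
    if separation and allow_firth:
        beta, cov, conv_f, pll = _firth_fit(X, y)
        return LogisticFit(beta, cov, names, conv_f, n_used, True, "firth", pll)

    p = special.expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = linalg.inv(info)
    return LogisticFit(beta, cov, names, converged, n_used, separation, "ml", ll)


def _firth_fit(X, y, max_iter: int = 200, tol: float = 1e-10):
    """Firth bias-reduced logistic fit (Jeffreys-prior penalised likelihood)."""

    def penalised(beta):
        p = special.expit(X @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        return _loglik(X, y, beta) + 0.5 * logdet, info, p, w

    beta = np.zeros(X.shape[1])
    pll, info, p, w = penalised(beta)
    converged = False
    for _ in range(max_iter):
        cho = linalg.cho_factor(info)
        # hat diagonal h_i = w_i x_i' I^{-1} x_i
        h = w * np.einsum("ij,ji->i", X, linalg.cho_solve(cho, X.T))
        score = X.T @ (y - p + h * (0.5 - p))
        delta = linalg.cho_solve(cho, score)
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            pll_new, info_new, p_new, w_new = penalised(cand)
            if pll_new >= pll - 1e-14:
                break
            step /= 2.0
        beta, info, p, w = cand, info_new, p_new, w_new
        if abs(pll_new - pll) < tol:
            pll = pll_new
            converged = True
            break
        pll = pll_new
    cov = linalg.inv(info)
    return beta, cov, converged, pll


# ------------------------------------------------------------------
# vectorised per-variant fits


def batch_logistic_slope(G, y, max_iter: int = 40, tol: float = 1e-10):
    """Per-variant logistic regression ``y ~ 1 + g`` vectorised over variants.

    Parameters
    ----------
    G : (n, M) dosage array, NaN allowed (complete-case per variant).
    y : (n,) binary outcome shared across variants.

    Returns
    -------
    dict with per-variant arrays: ``beta`` (slope), ``se``, ``p`` (two-sided
    Wald), ``n_used``, ``ok`` (False for variants monomorphic on their
    complete cases or with a singular fit).
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, M = G.shape
    mask = np.isfinite(G)
    Gz = np.where(mask, G, 0.0)
    n_used = mask.sum(axis=0)
    # variance of dosage on complete cases: monomorphic -> not estimable
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_g = Gz.sum(axis=0) / np.maximum(n_used, 1)
        var_g = (mask * (Gz - mean_g) ** 2).sum(axis=0) / np.maximum(n_used, 1)
    ok = (n_used >= 4) & (var_g > 0)

    b0 = np.zeros(M)
    b1 = np.zeros(M)
    ym = mask * y[:, None]
    for _ in range(max_iter):
        eta = b0[None, :] + b1[None, :] * Gz
        p = special.expit(eta)
        w = mask * p * (1.0 - p)
        resid = ym - mask * p
        s0 = resid.sum(axis=0)
        s1 = (resid * Gz).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * Gz).sum(axis=0)
        i11 = (w * Gz * Gz).sum(axis=0)
        det = i00 * i11 - i01 * i01
        good = ok & (det > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = np.where(good, (i11 * s0 - i01 * s1) / det, 0.0)
            d1 = np.where(good, (i00 * s1 - i01 * s0) / det, 0.0)
        # damp very large Newton steps (separated variants)
        norm = np.maximum(np.abs(d0), np.abs(d1))
        scale = np.where(norm > 5.0, 5.0 / np.maximum(norm, 1e-30), 1.0)
        b0 += d0 * scale
        b1 += d1 * scale
        if np.max(norm * scale, initial=0.0) < 1e-8:
            break
    eta = b0[None, :] + b1[None, :] * Gz
    p = special.expit(eta)
    w = mask * p * (1.0 - p)
    i00 = w.sum(axis=0)
    i01 = (w * Gz).sum(axis=0)
    i11 = (w * Gz * Gz).sum(axis=0)
    det = i00 * i11 - i01 * i01
    ok = ok & (det > 1e-12) & (np.abs(b1) < 2 * _SEPARATION_BOUND)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, np.sqrt(np.abs(i00 / det)), np.nan)
    beta = np.where(ok, b1, np.nan)
    pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(beta / se)), np.nan)
    return {"beta": beta, "se": se, "p": pval, "n_used": n_used, "ok": ok}


def batch_interaction_test(G, e, y, max_iter: int = 40):
    """Per-variant logistic fit ``y ~ 1 + e + g + e:g`` vectorised over variants.

    Used as the one-step (exhaustive) interaction benchmark.  ``e`` and
    ``y`` are shared binary vectors; rows with missing ``e`` must be removed
    beforehand; NaN dosages are handled per variant.  Returns Wald
    statistics for the interaction coefficient.
    """
    G = np.asarray(G, dtype=float)
    e = np.asarray(e, dtype=float)
    y = np.asarray(y, dtype=float)
    n, M = G.shape
    mask = np.isfinite(G)
    Gz = np.where(mask, G, 0.0)
    GE = Gz * e[:, None]
    n_used = mask.sum(axis=0)

    beta = np.zeros((4, M))  # rows: const, e, g, ge
    ym = mask * y[:, None]
    ok = np.ones(M, dtype=bool)
    for _ in range(max_iter):
        eta = beta[0] + beta[1] * e[:, None] + beta[2] * Gz + beta[3] * GE
        p = special.expit(eta)
        w = mask * p * (1.0 - p)
        resid = ym - mask * p
        # score components
        s = np.empty((4, M))
        s[0] = resid.sum(axis=0)
        s[1] = (resid * e[:, None]).sum(axis=0)
        s[2] = (resid * Gz).sum(axis=0)
        s[3] = (resid * GE).sum(axis=0)
        # information entries; e is 0/1 so e*e == e
        we = w * e[:, None]
        wg = w * Gz
        weg = we * Gz
        I = np.empty((M, 4, 4))
        I[:, 0, 0] = w.sum(axis=0)
        I[:, 0, 1] = I[:, 1, 0] = we.sum(axis=0)
        I[:, 0, 2] = I[:, 2, 0] = wg.sum(axis=0)
        I[:, 0, 3] = I[:, 3, 0] = weg.sum(axis=0)
        I[:, 1, 1] = I[:, 0, 1]
        I[:, 1, 2] = I[:, 2, 1] = I[:, 0, 3]
        I[:, 1, 3] = I[:, 3, 1] = I[:, 0, 3]
        I[:, 2, 2] = (wg * Gz).sum(axis=0)
        I[:, 2, 3] = I[:, 3, 2] = (weg * Gz).sum(axis=0)
        I[:, 3, 3] = I[:, 2, 3]
        dets = np.linalg.det(I)
        ok = ok & np.isfinite(dets) & (dets > 1e-10)
        delta = np.zeros((M, 4))
        if ok.any():
            delta[ok] = np.linalg.solve(I[ok], s.T[ok, :, None])[:, :, 0]
        norm = np.abs(delta).max(axis=1)
        scale = np.where(norm > 5.0, 5.0 / np.maximum(norm, 1e-30), 1.0)
        beta += (delta * scale[:, None]).T
        if np.max(norm * scale, initial=0.0) < 1e-8:
            break
    # final covariance for the interaction coefficient
    eta = beta[0] + beta[1] * e[:, None] + beta[2] * Gz + beta[3] * GE
    p = special.expit(eta)
    w = mask * p * (1.0 - p)
    se = np.full(M, np.nan)
    if ok.any():
        we = w * e[:, None]
        wg = w * Gz
        weg = we * Gz
        I = np.empty((M, 4, 4))
        I[:, 0, 0] = w.sum(axis=0)
        I[:, 0, 1] = I[:, 1, 0] = we.sum(axis=0)
        I[:, 0, 2] = I[:, 2, 0] = wg.sum(axis=0)
        I[:, 0, 3] = I[:, 3, 0] = weg.sum(axis=0)
        I[:, 1, 1] = I[:, 0, 1]
        I[:, 1, 2] = I[:, 2, 1] = I[:, 0, 3]
        I[:, 1, 3] = I[:, 3, 1] = I[:, 0, 3]
        I[:, 2, 2] = (wg * Gz).sum(axis=0)
        I[:, 2, 3] = I[:, 3, 2] = (weg * Gz).sum(axis=0)
        I[:, 3, 3] = I[:, 2, 3]
        try:
            covs = np.linalg.inv(I[ok])
            se_ok = np.sqrt(np.abs(covs[:, 3, 3]))
            se[ok] = se_ok
        except np.linalg.LinAlgError:
            ok = ok & False
    ok = ok & np.isfinite(se) & (np.abs(beta[3]) < 2 * _SEPARATION_BOUND)
    b_ge = np.where(ok, beta[3], np.nan)
    se = np.where(ok, se, np.nan)
    pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(b_ge / se)), np.nan)
    return {"beta_ge": b_ge, "se_ge": se, "p_ge": pval, "n_used": n_used, "ok": ok}
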