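"""Parametric empirical-Bayes ComBat harmonization.

The model per subject i, feature v, site l = site(i):

    Y[i,v] = alpha[v] + X_signal[i,:] @ beta[:,v] + gamma[l,v] + delta[l,v] * eps[i,v]

gamma/delta are additive/multiplicative site effects.  Fitting proceeds in
the classical way: feature-wise least squares with the weighted
site-sum-to-zero constraint, standardization by the pooled residual
variance, then empirical-Bayes shrinkage of the per-site location (normal
prior) and scale (inverse-gamma prior) estimates, hyperparameters by method
of moments across features, iterated to a fixed point.  Harmonized data has
the shrunken site effects removed in standardized space and the intercept
and signal effects restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CovariateTable, DesignMatrix, FeatureMatrix, RANK_RTOL

__all__ = ["CombatModel", "combat_fit", "combat_apply", "combat_harmonize"]


@dataclass
class CombatModel:
    """Fitted ComBat parameters (all per feature, site effects per site × feature)."""

    site_levels: list
    n_per_site: np.ndarray
    alpha: np.ndarray
    beta_signal: np.ndarray        # (p, V) coefficients of the signal design (no intercept)
    signal_columns: list[str]
    gamma_hat: np.ndarray          # (L, V) naive additive site effects (standardized space)
    delta_hat: np.ndarray          # (L, V) naive variance scale per site (standardized space)
    gamma_star: np.ndarray         # (L, V) EB-shrunk additive effects
    delta_star: np.ndarray         # (L, V) EB-shrunk variance scales
    prior_params: dict = field(default_factory=dict)
    pooled_var: np.ndarray | None = None
    n_iter: np.ndarray | None = None


def _design_parts(cov: CovariateTable, X_signal: DesignMatrix):
    """Site one-hot block and the signal design stripped of any intercept."""
    sites = cov.site_indicators()
    keep = [c for c in X_signal.columns if c != "intercept"]
    Xs = X_signal.frame[keep].to_numpy(dtype=float) if keep else np.empty((cov.n_subjects, 0))
    return sites, Xs, keep


def combat_fit(
    fm: FeatureMatrix,
    cov: CovariateTable,
    X_signal: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 500,
    eb: bool = True,
) -> CombatModel:
    """Fit the ComBat model on a multi-site feature matrix.

    Requires >= 2 subjects per site and a non-confounded design (no site may
    be a linear combination of the signal covariates).  ``eb=False`` skips
    the shrinkage and uses the naive per-site estimates (useful for oracles).
    """
    cov.check_alignment(fm)
    Y = fm.values
    n, V = Y.shape
    sites, Xs, sig_cols = _design_parts(cov, X_signal)
    L = sites.shape[1]
    n_per = sites.sum(axis=0)
    if np.any(n_per < 2):
        bad = [cov.site_levels[l] for l in np.flatnonzero(n_per < 2)]
        raise ValueError(f"every site needs >=2 subjects to fit ComBat; offending: {bad}")

    X = np.column_stack([sites, Xs])
    smax = np.linalg.norm(X, 2)
    if np.linalg.matrix_rank(X, tol=RANK_RTOL * max(1.0, smax)) < X.shape[1]:
        raise ValueError(
            "confounded design: the site indicators and signal covariates "
            f"{sig_cols} are collinear (a site perfectly predicts a covariate)"
        )

    B = np.linalg.lstsq(X, Y, rcond=None)[0]          # (L + p) x V
    w = n_per / n
    alpha = w @ B[:L]                                  # grand (weighted) intercept
    beta = B[L:]
    stand_mean = alpha[None, :] + Xs @ beta            # n x V
    resid = Y - X @ B
    pooled_var = np.mean(resid**2, axis=0)             # per-feature pooled variance
    if np.any(pooled_var <= 0):
        raise ValueError("zero pooled variance: a feature is perfectly fit by the design")
    sd = np.sqrt(pooled_var)

    Z = (Y - stand_mean) / sd                          # standardized data, site effects kept
    gamma_hat = np.stack([Z[sites[:, l] == 1].mean(axis=0) for l in range(L)])
    delta_hat = np.stack([Z[sites[:, l] == 1].var(axis=0, ddof=1) for l in range(L)])

    if eb:
        gamma_star, delta_star, priors, iters = _eb_shrink(
            Z, sites, gamma_hat, delta_hat, tol=tol, max_iter=max_iter
        )
    else:
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        priors, iters = {}, np.zeros(L, dtype=int)

    return CombatModel(
        site_levels=list(cov.site_levels),
        n_per_site=n_per,
        alpha=alpha,
        beta_signal=beta,
        signal_columns=sig_cols,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        prior_params=priors,
        pooled_var=pooled_var,
        n_iter=iters,
    )


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_shrink(Z, sites, gamma_hat, delta_hat, tol, max_iter):
    """Fixed-point EB posterior estimates per site (normal / inverse-gamma priors)."""
    L, V = gamma_hat.shape
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    a = np.array([_aprior(delta_hat[l]) for l in range(L)])
    b = np.array([_bprior(delta_hat[l]) for l in range(L)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    iters = np.zeros(L, dtype=int)
    for l in range(L):
        Zl = Z[sites[:, l] == 1]
        n_l = Zl.shape[0]
        g_old, d_old = gamma_hat[l].copy(), delta_hat[l].copy()
        for it in range(1, max_iter + 1):
            g_new = (n_l * tau2[l] * gamma_hat[l] + d_old * gamma_bar[l]) / (
                n_l * tau2[l] + d_old
            )
            sum2 = ((Zl - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b[l]) / (n_l / 2.0 + a[l] - 1.0)
            change = max(
                float(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-300))),
                float(np.max(np.abs(d_new - d_old) / d_old)),
            )
            g_old, d_old = g_new, d_new
            if change <= tol:
                break
        gamma_star[l], delta_star[l] = g_old, d_old
        iters[l] = it
    priors = {"gamma_bar": gamma_bar, "tau2": tau2, "a": a, "b": b}
    return gamma_star, delta_star, priors, iters


def combat_apply(
    fm: FeatureMatrix,
    model: CombatModel,
    cov: CovariateTable,
    X_signal: DesignMatrix,
) -> FeatureMatrix:
    """Remove the fitted site effects and restore intercept + signal effects.

    In standardized space the shrunken additive effect is subtracted and the
    result divided by the shrunken scale; then the pooled scale, intercept
    and signal effects are restored.  Subjects from a site unseen at fit
    time are an error.
    """
    cov.check_alignment(fm)
    if list(cov.site_levels) != model.site_levels:
        unseen = [s for s in cov.site_levels if s not in model.site_levels]
        raise ValueError(f"site labels differ from the fitted model; unseen: {unseen}")
    sites, Xs, sig_cols = _design_parts(cov, X_signal)
    if sig_cols != model.signal_columns:
        raise ValueError(
            f"signal design columns {sig_cols} differ from fitted {model.signal_columns}"
        )
    Y = fm.values
    sd = np.sqrt(model.pooled_var)
    stand_mean = model.alpha[None, :] + Xs @ model.beta_signal
    Z = (Y - stand_mean) / sd
    codes = np.argmax(sites, axis=1)
    Zadj = (Z - model.gamma_star[codes]) / np.sqrt(model.delta_star[codes])
    out = Zadj * sd + stand_mean
    return fm.with_values(out)


def combat_harmonize(
    fm: FeatureMatrix,
    cov: CovariateTable,
    X_signal: DesignMatrix,
    **fit_kwargs,
) -> tuple[FeatureMatrix, CombatModel]:
    """Fit-and-apply convenience wrapper on a single cohort."""
    model = combat_fit(fm, cov, X_signal, **fit_kwargs)
    return combat_apply(fm, model, cov, X_signal), model
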