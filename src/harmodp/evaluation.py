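"""Before/after harmonization diagnostics.

Three families of checks:

* mass-univariate GLM partial F-tests per feature — the site test asks
  whether site explains variance beyond the signal covariates; the signal
  tests ask the same for age, sex or diagnosis, with a signed direction from
  the coefficient so positive/negative association maps can be drawn;
* a 2-D t-SNE embedding scored by silhouette against the site / sex /
  diagnosis labellings (does the point cloud still cluster by site?);
* the whole-brain summary: per-subject median over each ROI of a
  parcellation, median across ROIs, correlated with age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .io import CovariateTable, FeatureMatrix, RANK_RTOL, build_design

__all__ = [
    "MassUnivariateResult",
    "EmbeddingResult",
    "site_effect_test",
    "signal_association_test",
    "embed_and_score",
    "make_parcellation",
    "median_roi_correlation",
]


@dataclass
class MassUnivariateResult:
    """Per-feature partial-F results for one tested factor."""

    f: np.ndarray
    df_num: int
    df_den: int
    p: np.ndarray
    p_fwe: np.ndarray
    factor: str
    covariates: tuple[str, ...]
    alpha: float
    n_significant: int
    sign: np.ndarray | None = None
    fwe_method: str = "bonferroni"

    @property
    def significant(self) -> np.ndarray:
        return self.p_fwe < self.alpha


@dataclass
class EmbeddingResult:
    """2-D embedding coordinates with clustering scores per labelling."""

    coordinates: np.ndarray
    seed: int
    perplexity: float
    silhouette: dict[str, float] = field(default_factory=dict)
    age_correlation: tuple[float, float] = (0.0, 0.0)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    smax = np.linalg.norm(X, 2) if X.size else 0.0
    r = np.linalg.matrix_rank(X, tol=RANK_RTOL * max(1.0, smax))
    if r < X.shape[1]:
        from .io import _dependent_columns

        raise ValueError(
            f"rank-deficient test design; confounded columns: {_dependent_columns(X, names)}"
        )


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    r = Y - X @ coef
    return np.einsum("ij,ij->j", r, r)


def _partial_f(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    names_full: list[str],
) -> tuple[np.ndarray, int, int, np.ndarray]:
    """Extra-sum-of-squares F comparing nested OLS fits, vectorized over features."""
    _check_full_rank(X_full, names_full)
    n = Y.shape[0]
    df_num = X_full.shape[1] - X_reduced.shape[1]
    df_den = n - X_full.shape[1]
    if df_num < 1 or df_den < 1:
        raise ValueError("degenerate degrees of freedom for the partial F-test")
    rss_f = _rss(X_full, Y)
    rss_r = _rss(X_reduced, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    f = np.where(np.isfinite(f), np.maximum(f, 0.0), np.inf)
    p = stats.f.sf(f, df_num, df_den)
    return f, df_num, df_den, p


def _fwe_adjust(
    p: np.ndarray,
    method: str,
    Y: np.ndarray,
    fit_factor,
    n_perm: int,
    seed: int,
    f_obs: np.ndarray,
) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        n = Y.shape[0]
        maxf = np.empty(n_perm)
        for b in range(n_perm):
            maxf[b] = fit_factor(rng.permutation(n)).max()
        return (1.0 + (maxf[None, :] >= f_obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    raise ValueError(f"unknown FWE method '{method}'")


def site_effect_test(
    fm: FeatureMatrix,
    cov: CovariateTable,
    covariate_vars: tuple[str, ...] = ("age", "sex", "diagnosis"),
    alpha: float = 0.05,
    fwe: str = "bonferroni",
    n_perm: int = 1000,
    seed: int = 0,
) -> MassUnivariateResult:
    """Per-feature partial F-test of the site factor, adjusting for covariates.

    Full model: intercept + covariates + site indicators (reference-coded);
    reduced model drops the site block.  FWE correction is Bonferroni across
    features by default, or a max-F permutation distribution with
    ``fwe='permutation'``.
    """
    cov.check_alignment(fm)
    Y = fm.values
    Xr = build_design(cov, covariate_vars, include_intercept=True).values
    sites = cov.site_indicators()[:, 1:]  # treatment coding vs first site
    Xf = np.column_stack([Xr, sites])
    names = ["intercept", *covariate_vars] + [f"site[{s}]" for s in cov.site_levels[1:]]
    f, d1, d2, p = _partial_f(Y, Xf, Xr, names)

    def fit_perm(perm):
        Xp = np.column_stack([Xr, sites[perm]])
        return _partial_f(Y, Xp, Xr, names)[0]

    p_fwe = _fwe_adjust(p, fwe, Y, fit_perm, n_perm, seed, f)
    return MassUnivariateResult(
        f=f, df_num=d1, df_den=d2, p=p, p_fwe=p_fwe, factor="site",
        covariates=tuple(covariate_vars), alpha=alpha,
        n_significant=int((p_fwe < alpha).sum()), fwe_method=fwe,
    )


def signal_association_test(
    fm: FeatureMatrix,
    cov: CovariateTable,
    factor: str,
    covariates: tuple[str, ...] = (),
    alpha: float = 0.05,
    fwe: str = "bonferroni",
    hc_only: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
) -> MassUnivariateResult:
    """Per-feature partial F-test of one signal variable, with direction.

    ``factor`` is ``age``, ``sex`` or ``diagnosis`` (one numerator df; a
    continuous factor enters as a linear term).  ``hc_only`` restricts the
    analysis to healthy controls, the convention for age effects when a
    diagnosis group is present.  ``sign`` holds the sign of the factor's
    coefficient in the full model (positive/negative association maps).
    """
    cov.check_alignment(fm)
    Y = fm.values
    keep = np.ones(cov.n_subjects, bool)
    if hc_only:
        keep = cov.frame["diagnosis"].to_numpy() == 0
        Y = Y[keep]
    sub = cov.frame.loc[keep]
    if factor in covariates:
        raise ValueError(f"factor '{factor}' also appears among the covariates")

    def col(name):
        return sub[name].to_numpy(dtype=float)

    Xr = np.column_stack([np.ones(keep.sum())] + [col(c) for c in covariates])
    Xf = np.column_stack([Xr, col(factor)])
    names = ["intercept", *covariates, factor]
    f, d1, d2, p = _partial_f(Y, Xf, Xr, names)
    coef, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    sign = np.sign(coef[-1])

    def fit_perm(perm):
        Xp = np.column_stack([Xr, col(factor)[perm]])
        return _partial_f(Y, Xp, Xr, names)[0]

    p_fwe = _fwe_adjust(p, fwe, Y, fit_perm, n_perm, seed, f)
    return MassUnivariateResult(
        f=f, df_num=d1, df_den=d2, p=p, p_fwe=p_fwe, factor=factor,
        covariates=tuple(covariates), alpha=alpha,
        n_significant=int((p_fwe < alpha).sum()), sign=sign, fwe_method=fwe,
    )


def embed_and_score(
    fm: FeatureMatrix,
    cov: CovariateTable,
    seed: int = 0,
    perplexity: float = 30.0,
) -> EmbeddingResult:
    """Deterministic-given-seed t-SNE embedding scored against the labellings."""
    cov.check_alignment(fm)
    Y = fm.values
    if fm.n_subjects < 3 * perplexity:
        raise ValueError(f"need >= 3*perplexity subjects, got {fm.n_subjects}")
    if np.allclose(Y, Y[0]):
        raise ValueError("degenerate input: all subject rows identical")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        max_iter=1000,
    ).fit_transform(Y)
    sil = {}
    for name in ("site", "sex", "diagnosis"):
        labels = cov.frame[name].to_numpy()
        if len(np.unique(labels)) > 1:
            sil[name] = float(silhouette_score(coords, labels))
    age = cov.frame["age"].to_numpy(dtype=float)
    r = max(
        (stats.pearsonr(coords[:, k], age) for k in range(2)),
        key=lambda res: abs(res.statistic),
    )
    return EmbeddingResult(
        coordinates=coords, seed=seed, perplexity=perplexity,
        silhouette=sil, age_correlation=(float(r.statistic), float(r.pvalue)),
    )


def make_parcellation(n_features: int, n_rois: int = 100) -> np.ndarray:
    """Contiguous equal-size blocks over the feature index (synthetic atlas)."""
    if not 1 <= n_rois <= n_features:
        raise ValueError("need 1 <= n_rois <= n_features")
    return np.minimum((np.arange(n_features) * n_rois) // n_features, n_rois - 1)


def median_roi_correlation(
    fm: FeatureMatrix,
    parcellation: np.ndarray,
    cov: CovariateTable,
    summary: str = "median_of_medians",
) -> tuple[np.ndarray, float, float]:
    """Whole-brain per-subject summary and its Pearson correlation with age.

    Default: median within each ROI, then median across the ROI medians
    (``summary='pooled'`` takes one median over all features instead).
    Returns (per-subject summary, r, p).
    """
    cov.check_alignment(fm)
    parcellation = np.asarray(parcellation)
    if parcellation.shape != (fm.n_features,):
        raise ValueError("parcellation does not cover the features")
    counts = np.bincount(parcellation)
    if np.any(counts == 0):
        raise ValueError(
            f"ROIs with zero features: {np.flatnonzero(counts == 0).tolist()}"
        )
    rois = np.arange(counts.size)
    Y = fm.values
    if summary == "median_of_medians":
        roi_medians = np.column_stack([np.median(Y[:, parcellation == r], axis=1) for r in rois])
        subj = np.median(roi_medians, axis=1)
    elif summary == "pooled":
        subj = np.median(Y, axis=1)
    else:
        raise ValueError(f"unknown summary '{summary}'")
    res = stats.pearsonr(subj, cov.frame["age"].to_numpy(dtype=float))
    return subj, float(res.statistic), float(res.pvalue)
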