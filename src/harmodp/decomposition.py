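"""Spatial ICA of the pooled subjects × features matrix, and component labelling.

The pooled feature matrix is modelled as Y − mean = A·S: S holds spatially
independent maps (components × features) and A the per-subject mixing
courses (subjects × components).  Each course is then tested against the
covariates — Pearson correlation for the signal variables (age, sex,
diagnosis; point-biserial for the binary ones), one-way ANOVA across sites
for the noise variable — and the component is labelled

    signal        significant for signal variables only
    noise         significant for site only
    mixed         significant for both
    unclassified  significant for neither (always retained downstream)

with Bonferroni correction over one family of components × tested variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import fastica

from .io import CovariateTable, FeatureMatrix, RANK_RTOL

logger = logging.getLogger("harmodp")

__all__ = ["ICAModel", "ComponentLabels", "run_ica", "classify_components", "select_courses"]

DEFAULT_SIGNAL_VARS = ("age", "sex", "diagnosis")


@dataclass
class ICAModel:
    """Result of one spatial ICA run.

    ``A`` (n_subjects × C) mixing courses, ``S`` (C × n_features) spatial
    maps with unit variance across features, components ordered by explained
    variance (descending).  ``center`` is the per-feature mean removed before
    decomposition, so Y ≈ center + A·S.
    """

    A: np.ndarray
    S: np.ndarray
    center: np.ndarray
    n_components: int
    seed: int
    n_iter: int
    converged: bool
    residual: float = 0.0

    def reconstruct(self) -> np.ndarray:
        return self.center + self.A @ self.S


@dataclass
class ComponentLabels:
    """Per-component labels with the raw/adjusted p-values behind them."""

    labels: list[str]
    p_values: pd.DataFrame = field(repr=False)
    p_adjusted: pd.DataFrame = field(repr=False)
    correction: dict = field(default_factory=dict)

    def which(self, kinds: set[str] | str) -> list[int]:
        kinds = {kinds} if isinstance(kinds, str) else set(kinds)
        return [c for c, lab in enumerate(self.labels) if lab in kinds]


def run_ica(
    fm: FeatureMatrix | np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ICAModel:
    """Fixed-point spatial ICA (logcosh contrast, symmetric decorrelation).

    Whitening is done here (feature-wise centering, then SVD-based projection
    to ``n_components`` principal directions scaled to unit variance across
    features); the seeded FastICA rotation then maximizes non-Gaussianity of
    the spatial maps.  Non-convergence within ``max_iter`` is a warning and a
    ``converged=False`` flag, never an exception.
    """
    Y = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    n, V = Y.shape
    if n_components < 2:
        raise ValueError("need at least 2 components")
    center = Y.mean(axis=0)
    Yc = Y - center

    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    rank = int(np.sum(s > RANK_RTOL * s[0] * max(n, V)))
    # centering removes one dimension at most; cap at n-1 as well
    rank = min(rank, n - 1)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the rank of the centered data; "
            f"achievable maximum is {rank}"
        )

    Xw = np.sqrt(V) * Vt[:n_components]  # C x V, unit variance across features
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _, W, ST, n_iter = fastica(
            Xw.T,
            n_components=n_components,
            algorithm="parallel",
            whiten=False,
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
            return_n_iter=True,
        )
    converged = n_iter < max_iter
    if not converged:
        logger.warning("run_ica: FastICA did not converge within %d iterations", max_iter)
        warnings.warn("FastICA did not converge; result flagged", stacklevel=2)

    S = ST.T  # C x V
    # mixing courses by least squares: Yc^T = S^T A^T
    A = np.linalg.lstsq(S.T, Yc.T, rcond=None)[0].T

    # order by explained variance, fix signs deterministically
    ev = np.einsum("ij,ij->j", A, A) * np.einsum("ij,ij->i", S, S)
    order = np.argsort(ev)[::-1]
    A, S = A[:, order], S[order]
    for c in range(n_components):
        j = int(np.argmax(np.abs(S[c])))
        if S[c, j] < 0:
            S[c] *= -1.0
            A[:, c] *= -1.0

    resid = float(np.linalg.norm(Yc - A @ S) / max(np.linalg.norm(Yc), 1e-300))
    return ICAModel(
        A=A, S=S, center=center, n_components=n_components,
        seed=seed, n_iter=int(n_iter), converged=converged, residual=resid,
    )


def classify_components(
    model: ICAModel,
    cov: CovariateTable,
    signal_vars: tuple[str, ...] = DEFAULT_SIGNAL_VARS,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> ComponentLabels:
    """Label each component from its course's covariate associations.

    The Bonferroni family is one ICA run: C components × (len(signal_vars)
    site tests + 1), i.e. every (component, variable) test shares one family.
    Constant courses are untestable and labelled unclassified with a warning.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is implemented")
    if model.A.shape[0] != cov.n_subjects:
        raise ValueError("covariate table not aligned with the mixing courses")
    C = model.n_components
    codes = cov.site_codes()
    groups_idx = [np.flatnonzero(codes == l) for l in range(len(cov.site_levels))]
    variables = list(signal_vars) + ["site"]
    family = C * len(variables)

    praw = np.ones((C, len(variables)))
    labels: list[str] = []
    for c in range(C):
        course = model.A[:, c]
        if np.std(course) < 1e-12 * max(1.0, np.abs(course).max()):
            warnings.warn(f"component {c}: constant course, labelled unclassified", stacklevel=2)
            labels.append("unclassified")
            continue
        for j, var in enumerate(signal_vars):
            x = cov.frame[var].to_numpy(dtype=float)
            if np.std(x) == 0:
                praw[c, j] = 1.0
            else:
                praw[c, j] = stats.pearsonr(course, x).pvalue
        praw[c, -1] = stats.f_oneway(*[course[g] for g in groups_idx]).pvalue
        padj_row = np.minimum(1.0, praw[c] * family)
        sig_signal = bool(np.any(padj_row[:-1] < alpha))
        sig_site = bool(padj_row[-1] < alpha)
        if sig_signal and sig_site:
            labels.append("mixed")
        elif sig_signal:
            labels.append("signal")
        elif sig_site:
            labels.append("noise")
        else:
            labels.append("unclassified")

    p_values = pd.DataFrame(praw, columns=variables)
    p_adjusted = np.minimum(1.0, p_values * family)
    n_unclassified = labels.count("unclassified")
    if n_unclassified:
        logger.info(
            "classify_components: %d/%d components unclassified; they are retained "
            "(never removed) by both SP and DP denoising", n_unclassified, C,
        )
    return ComponentLabels(
        labels=labels,
        p_values=p_values,
        p_adjusted=p_adjusted,
        correction={"method": "bonferroni", "family_size": family, "alpha": alpha},
    )


def select_courses(
    model: ICAModel,
    labels: ComponentLabels,
    which: set[str] | str,
) -> np.ndarray:
    """Column submatrix of A for the requested label kinds, in original order."""
    if len(labels.labels) != model.n_components:
        raise ValueError("labels not aligned with the model")
    idx = labels.which(which)
    return model.A[:, idx] if idx else np.empty((model.A.shape[0], 0))
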