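"""Projection-based site-effect removal: single- and dual-projection ICA.

Single projection (SP) removes only the pure site-related mixing courses:

    Y_sp = Y - A_sites pinv(A_sites) Y

Dual projection (DP) additionally rescues the mixed components: each mixed
course is first purged of its signal content by regressing the signal
design out of it,

    A'_sites = A_mixed - X pinv(X) A_mixed

and the purged courses join the pure site courses in a second projection:

    Y_dp = Y - [A_sites A'_sites] pinv([A_sites A'_sites]) Y

Both projections are pure linear operations in subject space; they remove
additive site structure but (unlike ComBat) leave multiplicative site
effects untouched.

By default every projection basis is augmented with the all-ones column and
the per-feature means are restored afterwards, so harmonized data keeps the
original grand mean (comparable to ComBat's restore step); ``raw_eq=True``
reproduces the bare equations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .combat import combat_harmonize
from .decomposition import ComponentLabels, ICAModel, classify_components, run_ica, select_courses
from .io import CovariateTable, DesignMatrix, FeatureMatrix, build_design

logger = logging.getLogger("harmodp")

__all__ = [
    "ProjectionSet",
    "sp_denoise",
    "purge_signal",
    "dp_denoise",
    "build_projection_set",
    "site_signal_canonical_correlation",
    "harmonize",
]

#: relative singular-value cutoff of the projection pseudo-inverse
PINV_RTOL = 1e-10

#: canonical-correlation level above which site and signal variables are
#: declared near-confounded (the documented failure mode of the dual projection)
CONFOUND_WARN_LEVEL = 0.95


@dataclass
class ProjectionSet:
    """The course bases of the dual projection, from one ICA run."""

    a_sites: np.ndarray         # pure-noise courses, n x k1
    a_mixed: np.ndarray         # mixed courses, n x k2
    a_sites_prime: np.ndarray   # signal-purged mixed courses, n x k2

    @property
    def basis(self) -> np.ndarray:
        return np.column_stack([self.a_sites, self.a_sites_prime])


def _project_out(Y: np.ndarray, basis: np.ndarray, augment_intercept: bool) -> np.ndarray:
    """Y minus its least-squares projection onto span(basis [, ones])."""
    n = Y.shape[0]
    if basis.shape[1] == 0:
        # nothing to remove: exact identity (the intercept would cancel anyway)
        return Y.copy()
    if augment_intercept:
        basis = np.column_stack([np.ones((n, 1)), basis])
    coef, *_ = np.linalg.lstsq(basis, Y, rcond=PINV_RTOL)
    out = Y - basis @ coef
    if augment_intercept:
        out = out + Y.mean(axis=0, keepdims=True)
    return out


def sp_denoise(
    fm: FeatureMatrix,
    a_sites: np.ndarray,
    raw_eq: bool = False,
) -> FeatureMatrix:
    """Single projection: remove the pure site-related courses from Y.

    Rank-deficient (e.g. duplicated) course columns are handled by the
    minimum-norm pseudo-inverse; the residual is orthogonal to the basis.
    With zero courses the operation is the identity.
    """
    a_sites = np.asarray(a_sites, float)
    if a_sites.ndim == 1:
        a_sites = a_sites[:, None]
    if a_sites.size and a_sites.shape[0] != fm.n_subjects:
        raise ValueError("course rows not aligned with the feature matrix")
    if a_sites.size == 0:
        a_sites = np.empty((fm.n_subjects, 0))
    out = _project_out(fm.values, a_sites, augment_intercept=not raw_eq)
    return fm.with_values(out)


def purge_signal(a_mixed: np.ndarray, var_signal: DesignMatrix) -> np.ndarray:
    """Residual of each mixed course after regression on the signal design.

    The signal design is used with its intercept (added if absent), so a
    mixed course's mean cannot leak into the purged site courses.  The
    result is orthogonal to every signal-design column.
    """
    a_mixed = np.asarray(a_mixed, float)
    if a_mixed.ndim == 1:
        a_mixed = a_mixed[:, None]
    if a_mixed.shape[1] == 0:
        return a_mixed.copy()
    X = var_signal.values
    if "intercept" not in var_signal.columns:
        X = np.column_stack([np.ones((X.shape[0], 1)), X])
    if X.shape[0] != a_mixed.shape[0]:
        raise ValueError("signal design rows not aligned with the mixed courses")
    coef, *_ = np.linalg.lstsq(X, a_mixed, rcond=PINV_RTOL)
    return a_mixed - X @ coef


def dp_denoise(
    fm: FeatureMatrix,
    proj: ProjectionSet,
    raw_eq: bool = False,
) -> FeatureMatrix:
    """Dual projection: remove pure site courses and signal-purged mixed courses."""
    basis = proj.basis
    if basis.size and basis.shape[0] != fm.n_subjects:
        raise ValueError("projection basis not aligned with the feature matrix")
    out = _project_out(fm.values, basis, augment_intercept=not raw_eq)
    return fm.with_values(out)


def build_projection_set(
    model: ICAModel,
    labels: ComponentLabels,
    var_signal: DesignMatrix,
) -> ProjectionSet:
    """Assemble the dual-projection bases from a classified ICA model."""
    a_sites = select_courses(model, labels, "noise")
    a_mixed = select_courses(model, labels, "mixed")
    a_prime = purge_signal(a_mixed, var_signal) if a_mixed.shape[1] else a_mixed.copy()
    return ProjectionSet(a_sites=a_sites, a_mixed=a_mixed, a_sites_prime=a_prime)


def site_signal_canonical_correlation(cov: CovariateTable, var_signal: DesignMatrix) -> float:
    """Largest canonical correlation between site indicators and signal design.

    Values near 1 mean a signal variable is almost perfectly predictable
    from site membership; in that regime the dual projection cannot separate
    the intersection effects (they are removed together with the site
    variance).
    """
    S = cov.site_indicators()[:, 1:]  # drop one to avoid the shared intercept
    X = var_signal.frame[[c for c in var_signal.columns if c != "intercept"]].to_numpy(float)
    S = S - S.mean(axis=0)
    X = X - X.mean(axis=0)
    if S.size == 0 or X.size == 0:
        return 0.0
    Qs, _ = np.linalg.qr(S)
    Qx, _ = np.linalg.qr(X)
    sv = np.linalg.svd(Qs.T @ Qx, compute_uv=False)
    return float(min(1.0, sv[0])) if sv.size else 0.0


def harmonize(
    fm: FeatureMatrix,
    cov: CovariateTable,
    method: str = "ica-dp",
    signal_vars: tuple[str, ...] = ("age", "sex", "diagnosis"),
    n_components: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    raw_eq: bool = False,
    ica_model: ICAModel | None = None,
) -> tuple[FeatureMatrix, dict]:
    """End-to-end harmonization of a feature matrix by the chosen method.

    ``method`` is one of ``"ica-dp"``, ``"ica-sp"`` or ``"combat"``.  For the
    ICA routes the pooled matrix is decomposed (or a precomputed model
    reused), components are classified against the covariates, and the
    matching projection applied.  Returns the harmonized matrix plus a
    details dict (ICA model, labels, projection set or ComBat model).

    Emits a warning when the site/signal canonical correlation exceeds
    0.95 — near-confounded designs are the documented failure regime in
    which no method can separate intersection effects from site effects.
    """
    cov.check_alignment(fm)
    design = build_design(cov, signal_vars, include_intercept=True)
    cc = site_signal_canonical_correlation(cov, design)
    if cc > CONFOUND_WARN_LEVEL:
        warnings.warn(
            f"site and signal variables are nearly confounded (canonical correlation "
            f"{cc:.3f} > {CONFOUND_WARN_LEVEL}); harmonization cannot separate their "
            "intersection effects",
            stacklevel=2,
        )
    details: dict = {"canonical_correlation": cc, "design": design}

    method = method.lower()
    if method == "combat":
        out, model = combat_harmonize(fm, cov, design)
        details["combat_model"] = model
        return out, details

    if method not in ("ica-sp", "ica-dp"):
        raise ValueError(f"unknown method '{method}'")
    model = ica_model if ica_model is not None else run_ica(fm, n_components, seed=seed)
    labels = classify_components(model, cov, signal_vars=signal_vars, alpha=alpha)
    details["ica_model"] = model
    details["labels"] = labels
    proj = build_projection_set(model, labels, design)
    details["projection_set"] = proj
    if method == "ica-sp":
        out = sp_denoise(fm, proj.a_sites, raw_eq=raw_eq)
    else:
        out = dp_denoise(fm, proj, raw_eq=raw_eq)
    return out, details
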