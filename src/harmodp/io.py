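"""Core containers and I/O: feature matrices, covariate tables, design matrices.

A *feature matrix* is the subjects × features array every harmonization method
operates on — one row per subject, one column per in-mask voxel (or per
arbitrary feature when loaded from a delimited file).  A *covariate table*
carries the per-subject non-imaging variables: the site label (the noise
variable) and the signal variables diagnosis, sex, and age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("harmodp")

__all__ = [
    "FeatureMatrix",
    "CovariateTable",
    "DesignMatrix",
    "load_feature_matrix",
    "write_feature_matrix",
    "load_covariates",
    "build_design",
    "mask_voxel_indices",
]

#: relative tolerance for affine comparison across NIfTI maps
AFFINE_ATOL = 1e-4
#: relative singular-value cutoff used by every rank check / pseudo-inverse
RANK_RTOL = 1e-10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Subjects × features real matrix with row identities and optional mask.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_features)
        Feature values; must be finite.
    subject_ids : sequence of str
        Unique row identifiers, aligned with ``values``.
    mask_shape : tuple of int, optional
        3-D grid shape when the features are in-mask voxels.
    mask_indices : ndarray of int, shape (n_features, 3), optional
        Voxel coordinate of each feature, in the fixed x-fastest
        (Fortran-order) linearization.
    modality : str
        Free-text tag, e.g. ``"ALFF"`` or ``"ReHo"``.
    """

    values: np.ndarray
    subject_ids: Sequence[str]
    mask_shape: tuple | None = None
    mask_indices: np.ndarray | None = None
    modality: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x features)")
        n, v = self.values.shape
        if n < 2 or v < 1:
            raise ValueError(f"need >=2 subjects and >=1 feature, got {n}x{v}")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.count_nonzero(~np.isfinite(self.values)))
            raise ValueError(f"feature matrix contains {bad} non-finite values")
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if self.mask_indices is not None:
            self.mask_indices = np.asarray(self.mask_indices, dtype=np.intp)
            if self.mask_indices.shape != (v, 3):
                raise ValueError(
                    f"mask_indices shape {self.mask_indices.shape} "
                    f"inconsistent with {v} features"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "FeatureMatrix":
        """Copy of this matrix with replaced values (same subjects/mask)."""
        return FeatureMatrix(
            values=np.asarray(values, dtype=np.float64),
            subject_ids=list(self.subject_ids),
            mask_shape=self.mask_shape,
            mask_indices=None if self.mask_indices is None else self.mask_indices.copy(),
            modality=self.modality if modality is None else modality,
        )


@dataclass
class CovariateTable:
    """Per-subject site label and signal variables (diagnosis, sex, age)."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "site", "diagnosis", "sex", "age")

    def __post_init__(self):
        df = self.frame
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"covariate table is missing column '{col}'")
        if df[list(self.REQUIRED)].isna().any().any():
            raise ValueError("covariate table has missing values in a used column")
        if not isinstance(df["site"].dtype, pd.CategoricalDtype):
            levels = pd.unique(df["site"])
            df["site"] = pd.Categorical(df["site"], categories=levels)
        counts = df["site"].value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 site levels")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                "every site level needs >=2 subjects; offending sites: "
                + ", ".join(map(str, small.index))
            )
        df["age"] = df["age"].astype(float)
        for b in ("diagnosis", "sex"):
            vals = set(pd.unique(df[b]))
            if not vals <= {0, 1}:
                raise ValueError(f"column '{b}' must be coded 0/1, found {sorted(vals)}")

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame["subject_id"]]

    @property
    def site(self) -> pd.Categorical:
        return self.frame["site"].array

    @property
    def site_levels(self) -> list:
        return list(self.frame["site"].cat.categories)

    def site_codes(self) -> np.ndarray:
        """Integer site code per subject, in first-appearance level order."""
        return np.asarray(self.frame["site"].cat.codes)

    def site_indicators(self) -> np.ndarray:
        """One-hot (n_subjects × n_sites) site indicator matrix."""
        codes = self.site_codes()
        out = np.zeros((len(codes), len(self.site_levels)))
        out[np.arange(len(codes)), codes] = 1.0
        return out

    def check_alignment(self, fm: FeatureMatrix) -> None:
        if self.subject_ids != list(fm.subject_ids):
            raise ValueError("covariate table and feature matrix subject ids differ")


@dataclass
class DesignMatrix:
    """Named-column real design matrix with a recorded categorical coding."""

    frame: pd.DataFrame = field(repr=False)
    coding: dict = field(default_factory=dict)

    def __post_init__(self):
        X = self.frame.to_numpy(dtype=float)
        r = np.linalg.matrix_rank(X, tol=RANK_RTOL * max(1.0, _spectral_norm(X)))
        if r < X.shape[1]:
            dep = _dependent_columns(X, list(self.frame.columns))
            raise ValueError(
                f"design matrix is rank deficient (rank {r} < {X.shape[1]} columns); "
                f"dependent column set: {dep}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def _spectral_norm(X: np.ndarray) -> float:
    if X.size == 0:
        return 0.0
    return float(np.linalg.norm(X, 2))


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy identification of columns linearly dependent on earlier ones."""
    dep, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand, tol=RANK_RTOL * max(1.0, _spectral_norm(cand))) == kept.shape[1]:
            dep.append(name)
        else:
            kept = cand
    return dep


# ---------------------------------------------------------------------------
# voxel linearization
# ---------------------------------------------------------------------------

def mask_voxel_indices(mask: np.ndarray) -> np.ndarray:
    """In-mask voxel coordinates in the package's fixed linearization.

    The linearization is 0-based and x-fastest (Fortran order over the grid),
    so the feature ordering of a given mask is stable across loads.
    """
    mask = np.asarray(mask).astype(bool)
    flat = np.flatnonzero(mask.ravel(order="F"))
    coords = np.array(np.unravel_index(flat, mask.shape, order="F")).T
    return coords.astype(np.intp)


def _extract_masked(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return vol.ravel(order="F")[np.flatnonzero(mask.ravel(order="F"))]


# ---------------------------------------------------------------------------
# feature-matrix I/O
# ---------------------------------------------------------------------------

def load_feature_matrix(
    source: Sequence[str | Path] | str | Path,
    mask: str | Path | np.ndarray | None = None,
    subject_ids: Sequence[str] | None = None,
    modality: str = "",
) -> FeatureMatrix:
    """Load a feature matrix from 3-D NIfTI maps or one delimited file.

    Parameters
    ----------
    source : list of NIfTI paths, or a single CSV path
        NIfTI maps must share grid shape and affine (within 1e-4). A CSV must
        have a header row and a first ``subject_id`` column.
    mask : NIfTI path or boolean array, optional
        Binary mask selecting in-mask voxels; required meaning only for the
        NIfTI route. Without a mask every voxel is a feature.
    """
    if isinstance(source, (str, Path)):
        return _load_feature_csv(Path(source), modality=modality)
    return _load_feature_niftis(list(source), mask, subject_ids, modality)


def _load_feature_csv(path: Path, modality: str = "") -> FeatureMatrix:
    # round_trip parsing so write -> load is bit-identical on 64-bit values
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id'")
    ids = [str(s) for s in df["subject_id"]]
    values = df.drop(columns="subject_id").to_numpy(dtype=float)
    return FeatureMatrix(values=values, subject_ids=ids, modality=modality)


def _load_feature_niftis(paths, mask, subject_ids, modality) -> FeatureMatrix:
    import nibabel as nib

    if not paths:
        raise ValueError("no NIfTI paths given")
    vols, ref_shape, ref_affine = [], None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{p}: expected a 3-D map, got shape {data.shape}")
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, img.affine
        else:
            if data.shape != ref_shape:
                raise ValueError(
                    f"{p}: grid shape {data.shape} differs from first map {ref_shape}"
                )
            if not np.allclose(img.affine, ref_affine, atol=AFFINE_ATOL):
                raise ValueError(f"{p}: affine differs from first map beyond {AFFINE_ATOL}")
        vols.append(data)

    if mask is None:
        mask_arr = np.ones(ref_shape, dtype=bool)
    elif isinstance(mask, (str, Path)):
        mimg = nib.load(str(mask))
        mask_arr = np.asanyarray(mimg.dataobj) != 0
        if mask_arr.shape != ref_shape:
            raise ValueError(f"mask shape {mask_arr.shape} differs from maps {ref_shape}")
    else:
        mask_arr = np.asarray(mask).astype(bool)
        if mask_arr.shape != ref_shape:
            raise ValueError(f"mask shape {mask_arr.shape} differs from maps {ref_shape}")

    rows = []
    for p, v in zip(paths, vols):
        row = _extract_masked(v, mask_arr)
        bad = np.flatnonzero(~np.isfinite(row))
        if bad.size:
            raise ValueError(
                f"{p}: {bad.size} non-finite in-mask voxels (first at feature index {bad[0]})"
            )
        rows.append(row)

    ids = list(subject_ids) if subject_ids is not None else [str(Path(p).name) for p in paths]
    return FeatureMatrix(
        values=np.vstack(rows),
        subject_ids=ids,
        mask_shape=tuple(ref_shape),
        mask_indices=mask_voxel_indices(mask_arr),
        modality=modality,
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix to CSV with full 64-bit precision (%.17g)."""
    df = pd.DataFrame(fm.values, columns=[f"f{j}" for j in range(fm.n_features)])
    df.insert(0, "subject_id", fm.subject_ids)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# covariates and design
# ---------------------------------------------------------------------------

def load_covariates(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    diagnosis_positive: str = "ASD",
) -> CovariateTable:
    """Load a per-subject covariate table from a delimited file.

    ``column_spec`` maps the canonical names (subject_id, site, diagnosis,
    sex, age) to the file's column names. Diagnosis and sex may be 0/1 or
    string-labelled; for strings, ``diagnosis_positive`` (default ``"ASD"``)
    codes 1, and sex 'M'/'male' codes 1.
    """
    df = pd.read_csv(path)
    spec = dict(column_spec or {})
    rename = {}
    for canon in CovariateTable.REQUIRED:
        src = spec.get(canon, canon)
        if src not in df.columns:
            raise ValueError(f"{path}: missing required column '{src}' (for '{canon}')")
        rename[src] = canon
    extra = [c for c in df.columns if c not in rename]
    if extra:
        logger.info("load_covariates: ignoring extra columns %s", extra)
    df = df.rename(columns=rename)[list(CovariateTable.REQUIRED)]

    bad_age = pd.to_numeric(df["age"], errors="coerce").isna() & df["age"].notna()
    if bad_age.any():
        row = int(np.flatnonzero(bad_age)[0])
        raise ValueError(f"{path}: non-numeric age at data row {row} ({df['age'].iloc[row]!r})")
    df["age"] = pd.to_numeric(df["age"])

    df["diagnosis"] = _coerce_binary(df["diagnosis"], positive=diagnosis_positive)
    df["sex"] = _coerce_binary(df["sex"], positive=("M", "m", "male", "Male"))
    levels = pd.unique(df["site"])
    df["site"] = pd.Categorical(df["site"], categories=levels)
    return CovariateTable(frame=df)


def _coerce_binary(col: pd.Series, positive) -> pd.Series:
    vals = set(pd.unique(col))
    if vals <= {0, 1}:
        return col.astype(int)
    pos = {positive} if isinstance(positive, str) else set(positive)
    mapped = col.map(lambda x: 1 if x in pos else 0)
    return mapped.astype(int)


def build_design(
    cov: CovariateTable,
    variables: Sequence[str] = (),
    include_intercept: bool = True,
) -> DesignMatrix:
    """Build a full-rank design matrix from named covariate columns.

    Categorical columns get treatment coding against the first-appearance
    level; binary columns stay {0,1}; the intercept column of ones comes
    first when requested.
    """
    cols: dict[str, np.ndarray] = {}
    coding: dict[str, str] = {}
    n = cov.n_subjects
    if include_intercept:
        cols["intercept"] = np.ones(n)
    for name in variables:
        if name not in cov.frame.columns:
            raise ValueError(f"unknown covariate '{name}'")
        col = cov.frame[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
            coding[name] = f"treatment(reference={levels[0]!r})"
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col == lev).to_numpy(dtype=float)
        else:
            coding[name] = "numeric"
            key = name if name not in cols else f"{name}.dup"
            cols[key] = col.to_numpy(dtype=float)
    frame = pd.DataFrame(cols)
    return DesignMatrix(frame=frame, coding=coding)
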