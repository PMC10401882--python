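"""Voxelwise resting-state feature measures: ALFF and ReHo.

ALFF (amplitude of low-frequency fluctuations) is the total one-sided
spectral amplitude of a voxel's time series inside a low-frequency band,
0.01–0.1 Hz by convention.  ReHo (regional homogeneity) is Kendall's
coefficient of concordance W between a voxel's series and its nearest
neighbors, measuring local temporal synchrony.

Smoothing-order convention: spatial smoothing is applied to the 4-D series
*before* ALFF but to the 3-D map *after* ReHo (``feature_pipeline``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .io import FeatureMatrix, mask_voxel_indices

logger = logging.getLogger("harmodp")

__all__ = [
    "BandSpec",
    "compute_alff",
    "compute_reho",
    "kendalls_w",
    "smooth_gaussian",
    "feature_pipeline",
    "stack_feature_maps",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_NEIGHBORHOODS = {
    7: lambda d: d <= 1,        # faces + self
    19: lambda d: d <= 2,       # faces + edges + self
    27: lambda d: d <= 3,       # full 3x3x3 cube
}


@dataclass(frozen=True)
class BandSpec:
    """Frequency band in Hz; must sit inside (0, Nyquist] for the given TR."""

    low: float
    high: float

    def __post_init__(self):
        if not 0.0 <= self.low < self.high:
            raise ValueError(f"need 0 <= low < high, got [{self.low}, {self.high}]")

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.high > nyquist + 1e-12:
            raise ValueError(
                f"band upper edge {self.high} Hz exceeds Nyquist {nyquist} Hz at TR={tr}s"
            )


def _check_ts(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D (x, y, z, t) data, got shape {data.shape}")
    if data.shape[-1] < 64:
        raise ValueError(f"need at least 64 timepoints, got {data.shape[-1]}")
    return data


def compute_alff(
    data: np.ndarray,
    tr: float,
    band: BandSpec = BandSpec(0.01, 0.1),
    mask: np.ndarray | None = None,
    stat: str = "sum_amplitude",
    detrend: bool = True,
    closed: str = "both",
) -> np.ndarray:
    """Low-frequency spectral amplitude per voxel.

    Per voxel: linear detrend, real FFT, one-sided amplitude 2|F_k|/t at each
    positive-frequency bin, then sum (or mean, or sum of squared amplitudes
    for ``stat='sum_power'``) over the bins whose frequency lies in the band.
    The DC bin is always excluded, even when ``band.low == 0``.

    ``closed`` controls band-edge inclusivity: 'both' (default), 'left',
    'right' or 'neither' — the bin-assignment rule that makes ALFF additive
    over abutting bands (use 'left' on the upper band).
    """
    data = _check_ts(data)
    band.validate(tr)
    t = data.shape[-1]
    if detrend:
        data = signal.detrend(data, axis=-1, type="linear")
    spec = np.abs(np.fft.rfft(data, axis=-1)) * (2.0 / t)
    freqs = np.fft.rfftfreq(t, d=tr)

    tol = 1e-12
    lo = freqs >= band.low - tol if closed in ("both", "left") else freqs > band.low + tol
    hi = freqs <= band.high + tol if closed in ("both", "right") else freqs < band.high - tol
    sel = lo & hi
    sel[0] = False  # DC excluded unconditionally
    amp = spec[..., sel]
    if stat == "sum_amplitude":
        out = amp.sum(axis=-1)
    elif stat == "mean_amplitude":
        out = amp.mean(axis=-1) if amp.shape[-1] else np.zeros(data.shape[:3])
    elif stat == "sum_power":
        out = (amp**2).sum(axis=-1)
    else:
        raise ValueError(f"unknown stat '{stat}'")
    if mask is not None:
        out = out * np.asarray(mask, dtype=bool)
    return out


def _tie_term(series_block: np.ndarray) -> np.ndarray:
    """Per-voxel Kendall tie correction sum(tau^3 - tau) over tie groups."""
    x = np.sort(series_block, axis=-1)
    # run lengths of equal consecutive values along t
    t = x.shape[-1]
    out = np.zeros(x.shape[:-1])
    boundaries = np.concatenate(
        [np.ones(x.shape[:-1] + (1,), bool), np.diff(x, axis=-1) != 0], axis=-1
    )
    # for each run of equal values of length tau, add tau^3 - tau
    flatb = boundaries.reshape(-1, t)
    flat_out = out.reshape(-1)
    for i in range(flatb.shape[0]):
        starts = np.flatnonzero(flatb[i])
        lengths = np.diff(np.append(starts, t))
        flat_out[i] = float(np.sum(lengths.astype(np.float64) ** 3 - lengths))
    return out


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance W for K series of length t.

    Mid-ranks for ties and the tie-corrected denominator:

        W = 12 * sum_j (R_j - mean R)^2 / (K^2 (t^3 - t) - K * sum T)

    where R_j is the rank sum across series at timepoint j and
    T_i = sum(tau^3 - tau) over the tie groups of series i.  Returns 0 when
    the denominator vanishes (every series constant).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D (K series x t timepoints) array with K >= 2")
    K, t = x.shape
    ranks = stats.rankdata(x, axis=-1)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    sum_T = float(_tie_term(x).sum())
    denom = K**2 * (t**3 - t) - K * sum_T
    if denom <= 0:
        return 0.0
    return min(1.0, 12.0 * S / denom)


def compute_reho(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    neighborhood: int = 27,
) -> np.ndarray:
    """Kendall's W between each voxel's series and its in-mask neighbors.

    Series are rank-transformed over time (mid-ranks for ties); for a voxel
    with K available in-mask neighbor series (itself included),

        W = 12 * sum_j (R_j - mean R)^2 / (K^2 (t^3 - t) - K * sum T)

    with R_j the rank sum across the K series at timepoint j and T the tie
    correction of each series.  Boundary/masked-out neighbors are simply
    dropped (variable K).  Voxels with K == 1 get W = 0 and are counted in a
    log line; W is clipped to [0, 1] against rounding.
    """
    data = _check_ts(data)
    if neighborhood not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")
    if any(d < 3 for d in data.shape[:3]):
        raise ValueError(f"every spatial dimension must be >=3, got {data.shape[:3]}")
    shape, t = data.shape[:3], data.shape[-1]
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    if np.any(~np.isfinite(data[mask])):
        raise ValueError("non-finite values inside the mask")

    # 3x3x3 footprint selected by Chebyshev/Manhattan distance from center
    off = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1], indexing="ij"))
    manh = np.abs(off).sum(axis=0)
    foot = _NEIGHBORHOODS[neighborhood](manh)

    ranks = np.zeros_like(data)
    ranks[mask] = stats.rankdata(data[mask], axis=-1)
    ties = np.zeros(shape)
    ties[mask] = _tie_term(data[mask])

    m = mask.astype(np.float64)
    K = ndimage.correlate(m, foot.astype(np.float64), mode="constant")
    sum_T = ndimage.correlate(ties * m, foot.astype(np.float64), mode="constant")
    # rank sums across neighbor series, per timepoint
    R = np.empty_like(data)
    for j in range(t):
        R[..., j] = ndimage.correlate(ranks[..., j] * m, foot.astype(np.float64), mode="constant")
    S = ((R - R.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)

    denom = K**2 * (t**3 - t) - K * sum_T
    W = np.zeros(shape)
    ok = mask & (K >= 2) & (denom > 0)
    W[ok] = 12.0 * S[ok] / denom[ok]
    isolated = int(np.count_nonzero(mask & (K < 2)))
    if isolated:
        logger.warning("compute_reho: %d isolated in-mask voxels emitted as W=0", isolated)
    return np.clip(W, 0.0, 1.0) * mask


def smooth_gaussian(
    vol: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | tuple[float, float, float] = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Separable Gaussian smoothing with mask-aware renormalization.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel units.
    With a mask, smooths ``vol*mask`` and ``mask`` and divides, so values
    near the mask edge are not diluted by outside zeros.  ``fwhm_mm == 0``
    is the identity.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    if np.any(vs <= 0):
        raise ValueError("voxel size must be positive")
    if fwhm_mm == 0:
        return vol.copy()
    sigma = FWHM_TO_SIGMA * fwhm_mm / vs
    if mask is None:
        return ndimage.gaussian_filter(vol, sigma=sigma)
    m = np.asarray(mask, bool).astype(np.float64)
    num = ndimage.gaussian_filter(vol * m, sigma=sigma)
    den = ndimage.gaussian_filter(m, sigma=sigma)
    out = np.zeros_like(vol)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    return out * m if mask is not None else out


def feature_pipeline(
    data: np.ndarray,
    tr: float,
    modality: str,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float | tuple[float, float, float] = 3.0,
    mask: np.ndarray | None = None,
    band: BandSpec = BandSpec(0.01, 0.1),
    neighborhood: int = 27,
) -> np.ndarray:
    """One subject's feature map with the standard smoothing order.

    ALFF: smooth every 3-D frame of the series first, then compute ALFF.
    ReHo: compute ReHo on the unsmoothed series, then smooth the map.
    """
    data = _check_ts(data)
    if modality.lower() == "alff":
        if fwhm_mm > 0:
            sm = np.empty_like(data)
            for j in range(data.shape[-1]):
                sm[..., j] = smooth_gaussian(data[..., j], fwhm_mm, voxel_size_mm, mask)
            data = sm
        return compute_alff(data, tr, band=band, mask=mask)
    if modality.lower() == "reho":
        m = compute_reho(data, mask=mask, neighborhood=neighborhood)
        return smooth_gaussian(m, fwhm_mm, voxel_size_mm, mask)
    raise ValueError(f"unknown modality '{modality}' (expected ALFF or ReHo)")


def stack_feature_maps(
    maps: list[np.ndarray],
    mask: np.ndarray,
    subject_ids: list[str],
    modality: str = "",
) -> FeatureMatrix:
    """Stack per-subject 3-D maps into a FeatureMatrix over the in-mask voxels."""
    mask = np.asarray(mask, bool)
    flat = np.flatnonzero(mask.ravel(order="F"))
    rows = [np.asarray(m, np.float64).ravel(order="F")[flat] for m in maps]
    return FeatureMatrix(
        values=np.vstack(rows),
        subject_ids=subject_ids,
        mask_shape=mask.shape,
        mask_indices=mask_voxel_indices(mask),
        modality=modality,
    )
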