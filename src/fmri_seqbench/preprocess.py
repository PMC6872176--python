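"""Temporal SNR, Gaussian smoothing, grey-matter banding, DCT high-pass.

These are the in-scope preprocessing stages of the analysis pipeline;
spatial registration steps (realignment, distortion correction, template
normalization) are out of scope and meaningless on the phantom.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import StatMap, Volume4D

__all__ = [
    "compute_tsnr",
    "gaussian_smooth",
    "grey_band_mask",
    "dct_highpass_basis",
    "highpass_project",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors below the cut-off frequency.

    Returns ``K = floor(2 * n_volumes * TR / cutoff)`` orthonormal DCT-II
    columns (the constant term excluded), the drift basis convention of
    the standard SPM-style high-pass filter with a 128 s default period.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if cutoff <= 2 * tr:
        raise ValueError(
            f"cut-off period {cutoff}s must exceed 2*TR = {2 * tr}s"
        )
    n = n_volumes
    k_max = int(np.floor(2.0 * n * tr / cutoff))
    if k_max == 0:
        return np.empty((n, 0))
    t = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols)


def highpass_project(series: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the drift-basis component from series along the last axis.

    The basis columns are orthonormal, so projection is a single matrix
    product; applying it twice equals applying it once.
    """
    if basis.shape[1] == 0:
        return np.asarray(series, dtype=np.float64)
    series = np.asarray(series, dtype=np.float64)
    coeffs = series @ basis  # (..., K)
    return series - coeffs @ basis.T


def compute_tsnr(vol: Volume4D, detrend_cutoff: float | None = None) -> StatMap:
    """Temporal SNR map: mean / sample sd of the (detrended) series.

    With ``detrend_cutoff`` the series is first projected orthogonal to
    the DCT high-pass basis of that cut-off period (the temporal mean is
    unaffected).  Voxels with zero temporal variance are returned NaN.
    """
    if vol.n_volumes < 3:
        raise ValueError("tSNR needs at least 3 volumes")
    data = vol.data
    mean = data.mean(axis=-1)
    if detrend_cutoff is not None:
        basis = dct_highpass_basis(vol.n_volumes, vol.tr, detrend_cutoff)
        data = highpass_project(data, basis)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.abs(mean) / sd
    tsnr = np.where(sd > 0, tsnr, np.nan)
    if vol.mask is not None:
        tsnr = np.where(vol.mask, tsnr, np.nan)
    return StatMap(tsnr, kind="tsnr", voxel_size_mm=vol.voxel_size_mm)


def gaussian_smooth(obj: Volume4D | StatMap, fwhm_mm: float):
    """Separable spatial Gaussian smoothing with the given FWHM in mm.

    ``sigma = FWHM / (2 sqrt(2 ln 2))`` per axis, converted to voxels
    through the isotropic voxel size.  FWHM 0 is the identity.  Boundary
    handling is zero-padded convolution.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return obj
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / obj.voxel_size_mm
    if isinstance(obj, Volume4D):
        out = ndimage.gaussian_filter(
            obj.data, sigma=(sigma_vox,) * 3 + (0.0,), mode="constant", cval=0.0
        )
        return Volume4D(out, tr=obj.tr, voxel_size_mm=obj.voxel_size_mm,
                        mask=obj.mask)
    if isinstance(obj, StatMap):
        data = obj.data.copy()
        nan = ~np.isfinite(data)
        data[nan] = 0.0
        out = ndimage.gaussian_filter(
            data, sigma=sigma_vox, mode="constant", cval=0.0
        )
        out[nan] = np.nan
        return StatMap(out, kind=obj.kind, voxel_size_mm=obj.voxel_size_mm,
                       dof=obj.dof)
    raise TypeError(f"cannot smooth object of type {type(obj).__name__}")


def grey_band_mask(gm_probability: np.ndarray | StatMap,
                   threshold: float = 0.05) -> np.ndarray:
    """Voxels with grey-matter probability of at least *threshold*.

    The default 5% band is deliberately permissive: it keeps the partial
    volume halo that spatial smoothing spreads activation into.
    """
    prob = gm_probability.data if isinstance(gm_probability, StatMap) \
        else np.asarray(gm_probability)
    finite = prob[np.isfinite(prob)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    return prob >= threshold
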