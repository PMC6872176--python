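"""Mass-univariate GLM with prewhitening, plus CompCor nuisance extraction.

The per-voxel model is the standard task-fMRI GLM: each condition's onset
train is convolved with a canonical double-gamma hemodynamic response
function and its temporal derivative (to absorb response latency), drift
is modelled with a discrete-cosine high-pass set, and optional nuisance
columns (motion, physiological components) enter unchanged.  Temporal
autocorrelation of the noise is handled by prewhitening: an AR(1) model
with a single pooled coefficient, or an extended pooled AR(p) covariance
(default p = 3) for noise with higher-order temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import signal as ssig
from scipy import stats as sstats

from .events import CONDITIONS, EventTable
from .volume import StatMap, Volume4D

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "GLMFit",
    "ContrastSpec",
    "CONTRAST_DEFINITIONS",
    "SENSORIMOTOR_CONTRASTS",
    "canonical_hrf",
    "hrf_derivative",
    "build_design_matrix",
    "compcor_regressors",
    "estimate_ar1",
    "fit_glm",
    "contrast_tmap",
    "make_contrast",
]


# --------------------------------------------------------------------------
# hemodynamic response function
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma canonical HRF parameters.

    Defaults are the de-facto canonical values: response peaking ~5 s
    after stimulus onset, an undershoot peaking ~15 s, undershoot
    amplitude one sixth of the peak, 32 s kernel, 0.1 s sampling.
    """

    dt: float = 0.1
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("dt", "peak_delay", "undershoot_delay",
                     "peak_dispersion", "undershoot_dispersion",
                     "ratio", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.length < self.undershoot_delay:
            raise ValueError("kernel length must cover the undershoot")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.length + self.dt / 2, self.dt)


def canonical_hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sampled canonical HRF: peak gamma minus ratio-scaled undershoot gamma,
    peak-normalized to a maximum of 1."""
    t = spec.times
    peak = sstats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = sstats.gamma.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.ratio * under
    return h / np.max(h)


def hrf_derivative(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Finite-difference time derivative of the canonical HRF (same length)."""
    return np.gradient(canonical_hrf(spec), spec.dt)


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Predictor side of the GLM: ``(n_volumes, n_regressors)`` with labels."""

    matrix: np.ndarray
    labels: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count does not match columns")
        if self.labels.count("constant") != 1:
            raise ValueError("design must contain exactly one constant column")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def _check_full_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the most collinear column pair to aid diagnosis
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Xn = X / norms
    gram = np.abs(Xn.T @ Xn)
    np.fill_diagonal(gram, 0.0)
    i, j = np.unravel_index(np.argmax(gram), gram.shape)
    raise ValueError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"most collinear columns: {labels[i]!r} and {labels[j]!r}"
    )


def condition_regressors(
    events: EventTable,
    condition: str,
    n_volumes: int,
    tr: float,
    spec: HRFSpec = HRFSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved regressor and its derivative for one condition.

    The onset boxcar is built on the HRF's fine grid, convolved as a
    continuous-time integral (Riemann sum, step ``spec.dt``), then sampled
    at volume acquisition times ``i * TR``.
    """
    dt = spec.dt
    n_fine = int(np.ceil(n_volumes * tr / dt)) + 1
    u = np.zeros(n_fine)
    fine_t = np.arange(n_fine) * dt
    for onset, dur in zip(events.onsets(condition), events.durations(condition)):
        u[(fine_t >= onset) & (fine_t < onset + dur)] = 1.0
    h = canonical_hrf(spec)
    hd = hrf_derivative(spec)
    x = np.convolve(u, h)[:n_fine] * dt
    xd = np.convolve(u, hd)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return x[vol_idx], xd[vol_idx]


def build_design_matrix(
    events: EventTable,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec = HRFSpec(),
    drift: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble [task | task-derivative | drift | nuisance | constant].

    One convolved regressor plus one derivative regressor is created per
    condition present in *events* (catalogue order).  Raises on events
    extending past the run and on rank deficiency.
    """
    if tr <= 0 or n_volumes < 2:
        raise ValueError("need TR > 0 and at least 2 volumes")
    if len(events) and events.end_time > n_volumes * tr + 1e-9:
        raise ValueError(
            f"events end at {events.end_time:.1f}s but the run covers "
            f"{n_volumes * tr:.1f}s"
        )
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for cond in events.conditions:
        x, xd = condition_regressors(events, cond, n_volumes, tr, hrf)
        cols += [x, xd]
        labels += [cond, f"{cond}_derivative"]
    if drift is not None:
        drift = np.asarray(drift, dtype=np.float64)
        if drift.shape[0] != n_volumes:
            raise ValueError("drift rows must equal n_volumes")
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            labels.append(f"drift_{k + 1}")
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=np.float64)
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance rows must equal n_volumes")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            labels.append(f"nuisance_{k + 1}")
    cols.append(np.ones(n_volumes))
    labels.append("constant")
    X = np.column_stack(cols)
    _check_full_rank(X, labels)
    return DesignMatrix(X, labels, tr)


# --------------------------------------------------------------------------
# contrasts
# --------------------------------------------------------------------------

#: positive / negative condition sets for the localizer's six contrasts
CONTRAST_DEFINITIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "video_minus_audio": (
        ("visual_sentence", "visual_computation",
         "visual_left_press", "visual_right_press"),
        ("auditory_sentence", "auditory_computation",
         "auditory_left_press", "auditory_right_press"),
    ),
    "audio_minus_video": (
        ("auditory_sentence", "auditory_computation",
         "auditory_left_press", "auditory_right_press"),
        ("visual_sentence", "visual_computation",
         "visual_left_press", "visual_right_press"),
    ),
    "left_minus_right": (
        ("visual_left_press", "auditory_left_press"),
        ("visual_right_press", "auditory_right_press"),
    ),
    "right_minus_left": (
        ("visual_right_press", "auditory_right_press"),
        ("visual_left_press", "auditory_left_press"),
    ),
    "sentences_minus_checkerboard": (
        ("visual_sentence",),
        ("horizontal_checkerboard", "vertical_checkerboard"),
    ),
    "computation_minus_sentences": (
        ("visual_computation", "auditory_computation"),
        ("visual_sentence", "auditory_sentence"),
    ),
}

#: the four contrasts robust enough to benchmark against reference ROIs
SENSORIMOTOR_CONTRASTS: tuple[str, ...] = (
    "video_minus_audio",
    "audio_minus_video",
    "left_minus_right",
    "right_minus_left",
)


@dataclass(frozen=True)
class ContrastSpec:
    """Named weight vector over design columns."""

    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or not np.any(w != 0):
            raise ValueError("contrast needs at least one nonzero weight")


def make_contrast(name: str, design: DesignMatrix) -> ContrastSpec:
    """Build a contrast vector for *name* against a concrete design.

    Task contrasts weight the (non-derivative) condition columns with
    +1/n_positive and -1/n_negative; ``mean_signal`` is the indicator of
    the constant column.
    """
    w = np.zeros(design.n_regressors)
    if name == "mean_signal":
        w[design.labels.index("constant")] = 1.0
        return ContrastSpec(name, w)
    if name not in CONTRAST_DEFINITIONS:
        raise ValueError(f"unknown contrast {name!r}")
    pos, neg = CONTRAST_DEFINITIONS[name]
    pos = [c for c in pos if c in design.labels]
    neg = [c for c in neg if c in design.labels]
    if not pos or not neg:
        raise ValueError(
            f"contrast {name!r} references conditions absent from the design"
        )
    for c in pos:
        w[design.labels.index(c)] = 1.0 / len(pos)
    for c in neg:
        w[design.labels.index(c)] = -1.0 / len(neg)
    return ContrastSpec(name, w)


# --------------------------------------------------------------------------
# CompCor
# --------------------------------------------------------------------------

def compcor_regressors(
    vol: Volume4D | np.ndarray,
    mask: np.ndarray,
    n_components: int,
    drift: np.ndarray | None = None,
) -> np.ndarray:
    """Top temporal principal components of noise-tissue voxels.

    Voxel series inside *mask* are projected orthogonal to the drift
    columns plus a constant, variance-normalized, and decomposed by SVD;
    the leading ``n_components`` left temporal singular vectors are
    returned as an ``(n_volumes, n_components)`` matrix of zero-mean,
    mutually orthogonal, unit-norm columns.
    """
    if isinstance(vol, Volume4D):
        series = vol.data[np.asarray(mask, dtype=bool)].T  # (t, n_vox)
    else:
        series = np.asarray(vol, dtype=np.float64)[np.asarray(mask, dtype=bool)].T
    if series.size == 0:
        raise ValueError("empty noise mask")
    n_t, n_vox = series.shape
    if n_components > min(n_t - 1, n_vox):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_volumes-1, mask size)"
        )
    if n_components == 0:
        return np.empty((n_t, 0))

    const = np.ones((n_t, 1))
    proj_basis = const if drift is None else np.column_stack([drift, const])
    q, _ = np.linalg.qr(proj_basis)
    series = series - q @ (q.T @ series)

    sd = series.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("all noise-mask series are constant after detrending")
    series = series[:, keep] / sd[keep]

    u, s, _ = np.linalg.svd(series, full_matrices=False)
    return u[:, :n_components]


# --------------------------------------------------------------------------
# prewhitened fitting
# --------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Per-voxel estimates plus whitening metadata.

    ``beta`` has shape ``spatial_shape + (n_regressors,)``; ``resid_var``
    is the whitened-residual variance per voxel; ``xtx_inv`` is
    ``(Xw' Xw)^-1`` under the whitening transform used at fit time, the
    matrix contrast variances are computed from.
    """

    beta: np.ndarray
    resid_var: np.ndarray
    dof: int
    whitening: str
    xtx_inv: np.ndarray
    rho: float | None = None
    ar_coefficients: np.ndarray | None = None
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("degrees of freedom must be positive")


def estimate_ar1(residuals: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pooled lag-1 autoregression coefficient of GLM residuals.

    ``rho = sum_v sum_t r_t r_{t+1} / sum_v sum_t r_t^2`` over the masked
    voxels, clipped to [0, 0.99].  Raises on all-zero residual variance.
    """
    r = np.asarray(residuals, dtype=np.float64)
    if mask is not None:
        r = r[np.asarray(mask, dtype=bool)]
    r = r.reshape(-1, r.shape[-1])
    if r.shape[-1] < 3:
        raise ValueError("need at least 3 time points")
    denom = np.sum(r * r)
    if denom <= 0:
        raise ValueError("zero-variance residuals")
    num = np.sum(r[:, :-1] * r[:, 1:])
    return float(np.clip(num / denom, 0.0, 0.99))


def _pooled_autocorr(residuals: np.ndarray, max_lag: int) -> np.ndarray:
    r = residuals.reshape(-1, residuals.shape[-1])
    denom = np.sum(r * r)
    if denom <= 0:
        raise ValueError("zero-variance residuals")
    return np.array(
        [np.sum(r[:, :-k] * r[:, k:]) / denom for k in range(1, max_lag + 1)]
    )


def _projection_corrected_acf(
    residuals: np.ndarray, X: np.ndarray, order: int
) -> np.ndarray:
    """Autocorrelation of the noise, corrected for the OLS projection.

    Residuals are ``r = M y`` with ``M = I - X (X'X)^-1 X'``; their raw
    autocorrelation underestimates that of the noise because the
    projection absorbs autocorrelated (low-frequency) power.  This solves
    the moment equations: find an AR(order) model whose *implied residual*
    autocorrelation ``tr(U_k M S M) / tr(M S M)`` (S the model covariance,
    U_k the lag-k shift) matches the observed one, by damped fixed-point
    iteration starting from the raw estimate.
    """
    n = X.shape[0]
    obs = _pooled_autocorr(residuals, order)
    q, _ = np.linalg.qr(X)

    def predicted(acf_model: np.ndarray) -> np.ndarray:
        a = _yule_walker(acf_model)
        roots_poly = np.concatenate([[1.0], -a])
        for _ in range(50):
            r = np.roots(roots_poly)
            if len(r) == 0 or np.max(np.abs(r)) < 0.999:
                break
            roots_poly[1:] *= 0.95
        impulse = np.zeros(n + 200)
        impulse[0] = 1.0
        psi = ssig.lfilter([1.0], roots_poly, impulse)
        gamma = np.array(
            [np.dot(psi[: len(psi) - k], psi[k:]) for k in range(n)]
        )
        S = sla.toeplitz(gamma / gamma[0])
        # M S M with M = I - QQ'
        QS = q.T @ S
        MSM = S - q @ QS - QS.T @ q.T + q @ (QS @ q) @ q.T
        denom = np.trace(MSM)
        return np.array(
            [np.trace(MSM, offset=k) for k in range(1, order + 1)]
        ) / denom

    acf = obs.copy()
    for _ in range(25):
        acf_clipped = np.clip(acf, -0.98, 0.98)
        delta = obs - predicted(acf_clipped)
        if np.max(np.abs(delta)) < 1e-4:
            break
        acf = acf_clipped + 0.8 * delta
    return np.clip(acf, -0.98, 0.98)


def _yule_walker(acf: np.ndarray) -> np.ndarray:
    p = len(acf)
    if p == 1:
        return acf.copy()
    R = sla.toeplitz(np.concatenate([[1.0], acf[: p - 1]]))
    return np.linalg.solve(R, acf)


def _ar1_whitener(rho: float, n: int) -> np.ndarray:
    """Inverse Cholesky factor of the AR(1) covariance (unit innovations).

    First row scales by sqrt(1 - rho^2); subsequent rows take first
    differences ``y_t - rho * y_{t-1}``.
    """
    w = np.eye(n)
    w[0, 0] = np.sqrt(max(1.0 - rho**2, 1e-12))
    idx = np.arange(1, n)
    w[idx, idx - 1] = -rho
    return w


def _arp_whitener(coeffs: np.ndarray, n: int) -> np.ndarray:
    """Whitening matrix for a stationary AR(p) correlation structure.

    Builds the theoretical autocorrelation from the AR coefficients (via
    the impulse response), forms the Toeplitz correlation matrix and
    returns the inverse of its Cholesky factor.
    """
    p = len(coeffs)
    if p == 0:
        return np.eye(n)
    # enforce stationarity: shrink towards zero until roots are inside
    a = np.asarray(coeffs, dtype=np.float64).copy()
    for _ in range(50):
        roots = np.roots(np.concatenate([[1.0], -a]))
        if len(roots) == 0 or np.max(np.abs(roots)) < 0.999:
            break
        a *= 0.95
    impulse = np.zeros(n + 10 * p + 200)
    impulse[0] = 1.0
    psi = ssig.lfilter([1.0], np.concatenate([[1.0], -a]), impulse)
    gamma = np.array([np.dot(psi[: len(psi) - k], psi[k:]) for k in range(n)])
    corr = sla.toeplitz(gamma / gamma[0])
    chol = np.linalg.cholesky(corr)
    return sla.solve_triangular(chol, np.eye(n), lower=True)


def fit_glm(
    vol: Volume4D | np.ndarray,
    design: DesignMatrix,
    whitening: str = "ar1",
    *,
    ar_order: int = 3,
    mask: np.ndarray | None = None,
) -> GLMFit:
    """Estimate the GLM per voxel with optional prewhitening.

    ``ols`` fits by ordinary least squares.  ``ar1`` and ``extended`` use
    a two-pass scheme: OLS residuals give a pooled AR(1) coefficient or a
    pooled AR(p) model (default p = 3), data and design are premultiplied
    by the corresponding whitening transform, and OLS is re-run on the
    whitened system.  Degrees of freedom are ``n_volumes - rank(X)``.
    """
    if whitening not in ("ols", "ar1", "extended"):
        raise ValueError(f"unknown whitening model {whitening!r}")
    if isinstance(vol, Volume4D):
        data = vol.data
        voxel_size = vol.voxel_size_mm
        if mask is None:
            mask = vol.mask
    else:
        data = np.asarray(vol, dtype=np.float64)
        voxel_size = 2.0
    spatial_shape = data.shape[:-1]
    n_t = data.shape[-1]
    X = design.matrix
    if X.shape[0] != n_t:
        raise ValueError("design rows do not match number of volumes")
    _check_full_rank(X, design.labels)
    rank = X.shape[1]
    dof = n_t - rank
    if dof <= 0:
        raise ValueError("more regressors than volumes")

    Y = data.reshape(-1, n_t).T  # (t, n_vox)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).reshape(-1)
        Y_fit = Y[:, flat_mask]
    else:
        flat_mask = None
        Y_fit = Y

    def _ols(Xw: np.ndarray, Yw: np.ndarray):
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid = Yw - Xw @ beta
        return beta, resid

    rho: float | None = None
    ar_coeffs: np.ndarray | None = None
    if whitening == "ols":
        Xw = X
        beta, resid = _ols(X, Y_fit)
    else:
        _, resid0 = _ols(X, Y_fit)
        if whitening == "ar1":
            acf = _projection_corrected_acf(resid0.T, X, 1)
            rho = float(np.clip(acf[0], 0.0, 0.99))
            W = _ar1_whitener(rho, n_t)
            ar_coeffs = np.array([rho])
        else:
            acf = _projection_corrected_acf(resid0.T, X, ar_order)
            ar_coeffs = _yule_walker(acf)
            W = _arp_whitener(ar_coeffs, n_t)
        Xw = W @ X
        beta, resid = _ols(Xw, W @ Y_fit)

    resid_var = np.sum(resid**2, axis=0) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)

    n_vox_total = int(np.prod(spatial_shape))
    if flat_mask is not None:
        beta_full = np.full((n_vox_total, rank), np.nan)
        var_full = np.full(n_vox_total, np.nan)
        beta_full[flat_mask] = beta.T
        var_full[flat_mask] = resid_var
    else:
        beta_full = beta.T
        var_full = resid_var

    return GLMFit(
        beta=beta_full.reshape(spatial_shape + (rank,)),
        resid_var=var_full.reshape(spatial_shape),
        dof=dof,
        whitening=whitening,
        xtx_inv=xtx_inv,
        rho=rho,
        ar_coefficients=ar_coeffs,
        voxel_size_mm=voxel_size,
    )


def contrast_tmap(
    fit: GLMFit, design: DesignMatrix, contrast: ContrastSpec | str
) -> StatMap:
    """Voxel-wise t-statistic for a contrast of GLM coefficients.

    ``t = c' beta / sqrt(sigma^2 * c' (Xw' Xw)^-1 c)`` with the whitening
    transform applied at fit time.  Voxels with zero residual variance
    are returned as NaN.
    """
    if isinstance(contrast, str):
        contrast = make_contrast(contrast, design)
    c = contrast.weights
    if c.shape[0] != design.n_regressors:
        raise ValueError("contrast length does not match design columns")
    effect = fit.beta @ c
    var_factor = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.resid_var * var_factor)
    t = np.where(fit.resid_var > 0, t, np.nan)
    return StatMap(t, kind="t", dof=fit.dof, voxel_size_mm=fit.voxel_size_mm)
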