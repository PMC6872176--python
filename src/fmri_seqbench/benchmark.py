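"""Detection-theory scoring of activation maps against reference ROIs.

A voxel is "activated" at significance threshold alpha when its p-value
is strictly below alpha.  Sensitivity is the activated fraction of the
reference ROI; specificity is one minus the activated fraction of the
analysis mask outside the ROI.  Sweeping alpha yields the ROC curve,
whose trapezoidal area (AUC) equals 1 for perfect separation and 0.5 for
a random map; d' = Z(sensitivity) - Z(1 - specificity) summarizes
performance at one fixed threshold (conventionally p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .volume import StatMap

__all__ = [
    "DetectionPoint",
    "ROCResult",
    "DPrimeResult",
    "BenchmarkResult",
    "default_alpha_grid",
    "pmap_from_tmap",
    "sens_spec",
    "roc_curve",
    "dprime",
    "aggregate",
]


@dataclass(frozen=True)
class DetectionPoint:
    """Sensitivity/specificity and raw counts at one threshold."""

    alpha: float
    sensitivity: float
    specificity: float
    true_positives: int
    false_positives: int
    roi_size: int
    non_roi_size: int

    def __post_init__(self) -> None:
        if not np.isclose(self.sensitivity, self.true_positives / self.roi_size):
            raise ValueError("sensitivity inconsistent with counts")
        if not np.isclose(
            self.specificity, 1.0 - self.false_positives / self.non_roi_size
        ):
            raise ValueError("specificity inconsistent with counts")


@dataclass
class ROCResult:
    """Detection points over an ascending alpha grid, with trapezoidal AUC."""

    points: list[DetectionPoint]
    auc: float

    @property
    def alphas(self) -> np.ndarray:
        return np.array([p.alpha for p in self.points])

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([p.sensitivity for p in self.points])

    @property
    def specificities(self) -> np.ndarray:
        return np.array([p.specificity for p in self.points])


@dataclass(frozen=True)
class DPrimeResult:
    value: float
    alpha: float
    clipped: bool


@dataclass
class BenchmarkResult:
    """Per-(subject, contrast) detection results plus the aggregation the
    benchmarking protocol prescribes: sensitivity/specificity averaged
    across contrasts within subject, AUC/d' per subject, then mean +/- sd
    over subjects."""

    cells: dict[tuple[str, str], dict]
    subject_auc: dict[str, float]
    subject_dprime: dict[str, float]
    auc_mean: float
    auc_sd: float
    dprime_mean: float
    dprime_sd: float
    pooled_curve: dict


def default_alpha_grid(n_low: int = 100, n_high: int = 100) -> np.ndarray:
    """Significance thresholds spanning (0, 0.5]: geometric from 1e-6 to
    0.01 for dense low-alpha sampling, then linear up to 0.5."""
    low = np.geomspace(1e-6, 0.01, n_low, endpoint=False)
    high = np.linspace(0.01, 0.5, n_high)
    return np.concatenate([low, high])


def pmap_from_tmap(t: StatMap, dof: float | None = None,
                   sided: str = "one") -> StatMap:
    """Convert a t-map to a p-map under the Student t(dof) null.

    One-sided (default) returns the upper-tail probability, matching
    directional contrasts; two-sided doubles the tail of |t|.  Undefined
    t voxels propagate as undefined p.
    """
    if dof is None:
        dof = t.dof
    if dof is None or dof < 1:
        raise ValueError("degrees of freedom >= 1 required")
    vals = t.data
    with np.errstate(invalid="ignore"):
        if sided == "one":
            p = sstats.t.sf(vals, dof)
        elif sided == "two":
            p = 2.0 * sstats.t.sf(np.abs(vals), dof)
        else:
            raise ValueError("sided must be 'one' or 'two'")
    p = np.where(np.isfinite(vals), p, np.nan)
    return StatMap(p, kind="p", dof=dof, voxel_size_mm=t.voxel_size_mm)


def _validate_masks(roi_ref: np.ndarray, analysis_mask: np.ndarray) -> None:
    if not roi_ref.any():
        raise ValueError("reference ROI is empty")
    if (roi_ref & ~analysis_mask).any():
        raise ValueError("reference ROI extends outside the analysis mask")
    if not (analysis_mask & ~roi_ref).any():
        raise ValueError("analysis mask has no voxels outside the ROI")


def sens_spec(p: StatMap | np.ndarray, roi_ref: np.ndarray,
              analysis_mask: np.ndarray, alpha: float) -> DetectionPoint:
    """Detection counts at one threshold (activation is ``p < alpha``)."""
    pvals = p.data if isinstance(p, StatMap) else np.asarray(p)
    roi_ref = np.asarray(roi_ref, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    _validate_masks(roi_ref, analysis_mask)
    activated = analysis_mask & (pvals < alpha)
    roi_size = int(roi_ref.sum())
    non_roi_size = int((analysis_mask & ~roi_ref).sum())
    tp = int((activated & roi_ref).sum())
    fp = int((activated & ~roi_ref).sum())
    return DetectionPoint(
        alpha=float(alpha),
        sensitivity=tp / roi_size,
        specificity=1.0 - fp / non_roi_size,
        true_positives=tp,
        false_positives=fp,
        roi_size=roi_size,
        non_roi_size=non_roi_size,
    )


def roc_curve(p: StatMap | np.ndarray, roi_ref: np.ndarray,
              analysis_mask: np.ndarray,
              alpha_grid: np.ndarray | None = None) -> ROCResult:
    """ROC over an ascending alpha grid in (0, 0.5], with trapezoidal AUC.

    Anchor points (0,0) and (1,1) are appended in (1-specificity,
    sensitivity) space before integration, so a grid that never reaches
    full detection still yields a proper curve.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.ndim != 1 or len(alpha_grid) == 0:
        raise ValueError("alpha grid must be a non-empty 1D array")
    if np.any(np.diff(alpha_grid) <= 0):
        raise ValueError("alpha grid must be strictly ascending")
    if alpha_grid[0] <= 0 or alpha_grid[-1] > 0.5:
        raise ValueError("alpha grid must lie in (0, 0.5]")

    pvals = p.data if isinstance(p, StatMap) else np.asarray(p)
    roi_ref = np.asarray(roi_ref, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    _validate_masks(roi_ref, analysis_mask)

    # vectorized sweep: searchsorted of sorted p-values against the grid
    p_roi = np.sort(pvals[roi_ref])
    p_out = np.sort(pvals[analysis_mask & ~roi_ref])
    roi_size, non_roi_size = len(p_roi), len(p_out)
    tp = np.searchsorted(p_roi, alpha_grid, side="left")
    fp = np.searchsorted(p_out, alpha_grid, side="left")

    points = [
        DetectionPoint(
            alpha=float(a),
            sensitivity=int(tpi) / roi_size,
            specificity=1.0 - int(fpi) / non_roi_size,
            true_positives=int(tpi),
            false_positives=int(fpi),
            roi_size=roi_size,
            non_roi_size=non_roi_size,
        )
        for a, tpi, fpi in zip(alpha_grid, tp, fp)
    ]
    auc = _trapezoid_auc(
        fpr=fp / non_roi_size, tpr=tp / roi_size
    )
    return ROCResult(points=points, auc=auc)


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    x = np.concatenate([[0.0], fpr, [1.0]])
    y = np.concatenate([[0.0], tpr, [1.0]])
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


def dprime(point: DetectionPoint, clip_counts: bool = True) -> DPrimeResult:
    """d' = Z(sensitivity) - Z(1 - specificity) at the point's threshold.

    Degenerate rates of exactly 0 or 1 are replaced by ``1/(2n)`` and
    ``1 - 1/(2n)`` (n the relevant voxel count) when ``clip_counts``;
    otherwise an infinite d' is rejected.
    """
    sens = point.sensitivity
    fpr = 1.0 - point.specificity
    clipped = False
    if clip_counts:
        if sens <= 0.0:
            sens, clipped = 1.0 / (2 * point.roi_size), True
        elif sens >= 1.0:
            sens, clipped = 1.0 - 1.0 / (2 * point.roi_size), True
        if fpr <= 0.0:
            fpr, clipped = 1.0 / (2 * point.non_roi_size), True
        elif fpr >= 1.0:
            fpr, clipped = 1.0 - 1.0 / (2 * point.non_roi_size), True
    elif sens in (0.0, 1.0) or fpr in (0.0, 1.0):
        raise ValueError(
            "degenerate detection rate gives infinite d'; "
            "use clip_counts=True"
        )
    value = float(sstats.norm.ppf(sens) - sstats.norm.ppf(fpr))
    return DPrimeResult(value=value, alpha=point.alpha, clipped=clipped)


def aggregate(cells: dict[tuple[str, str], ROCResult],
              dprime_alpha: float = 0.001) -> BenchmarkResult:
    """Aggregate per-(subject, contrast) ROC results the protocol's way.

    Within each subject, sensitivity and specificity are averaged across
    contrasts at every grid alpha; the per-subject mean curve gives a
    per-subject AUC and a per-subject d' at ``dprime_alpha`` (rates
    clipped by total counts when degenerate).  AUC and d' are then
    summarized as mean +/- sample sd over subjects, and the pooled mean
    curve across all cells is emitted for plotting.
    """
    if not cells:
        raise ValueError("no cells to aggregate")
    first = next(iter(cells.values()))
    ref_alphas = first.alphas
    for (subj, con), roc in cells.items():
        if not np.array_equal(roc.alphas, ref_alphas):
            raise ValueError(
                f"cell ({subj}, {con}) uses a different alpha grid"
            )

    subjects = sorted({s for s, _ in cells})
    subject_auc: dict[str, float] = {}
    subject_dprime: dict[str, float] = {}
    per_subject_curves = []
    for subj in subjects:
        rocs = [roc for (s, _), roc in cells.items() if s == subj]
        sens = np.mean([r.sensitivities for r in rocs], axis=0)
        spec = np.mean([r.specificities for r in rocs], axis=0)
        per_subject_curves.append((sens, spec))
        subject_auc[subj] = _trapezoid_auc(fpr=1.0 - spec, tpr=sens)

        i = int(np.searchsorted(ref_alphas, dprime_alpha, side="right") - 1)
        if i < 0:
            raise ValueError("dprime_alpha below the alpha grid")
        roi_n = sum(r.points[i].roi_size for r in rocs)
        out_n = sum(r.points[i].non_roi_size for r in rocs)
        pseudo = _point_from_rates(
            float(ref_alphas[i]), float(sens[i]), float(spec[i]), roi_n, out_n
        )
        subject_dprime[subj] = dprime(pseudo, clip_counts=True).value

    auc_vals = np.array([subject_auc[s] for s in subjects])
    dp_vals = np.array([subject_dprime[s] for s in subjects])
    ddof = 1 if len(subjects) > 1 else 0
    pooled_sens = np.mean([c[0] for c in per_subject_curves], axis=0)
    pooled_spec = np.mean([c[1] for c in per_subject_curves], axis=0)

    return BenchmarkResult(
        cells={k: {"auc": v.auc} for k, v in cells.items()},
        subject_auc=subject_auc,
        subject_dprime=subject_dprime,
        auc_mean=float(auc_vals.mean()),
        auc_sd=float(auc_vals.std(ddof=ddof)),
        dprime_mean=float(dp_vals.mean()),
        dprime_sd=float(dp_vals.std(ddof=ddof)),
        pooled_curve={
            "alpha": ref_alphas.tolist(),
            "sensitivity": pooled_sens.tolist(),
            "specificity": pooled_spec.tolist(),
        },
    )


def _point_from_rates(alpha: float, sens: float, spec: float,
                      roi_n: int, out_n: int) -> DetectionPoint:
    """Detection point from contrast-averaged rates; the (fractional)
    implied counts only feed the d' clipping rule."""
    tp = sens * roi_n
    fp = (1.0 - spec) * out_n
    return DetectionPoint(
        alpha=alpha,
        sensitivity=tp / roi_n,
        specificity=1.0 - fp / out_n,
        true_positives=tp,
        false_positives=fp,
        roi_size=roi_n,
        non_roi_size=out_n,
    )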