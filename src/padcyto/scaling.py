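"""Scale-free size-number fits for chromocenter (PAD) populations.

When a cell redistributes a conserved amount of pericentric heterochromatin
by fusing and splitting its chromocenters, the per-cell mean chromocenter
area obeys mean = A/n, so count against mean area follows a power law with
exponent -1 and the reciprocal count 1/n grows linearly with the linear
size proxy √(mean area).  This module fits those relationships, the
exponentially decreasing individual-size spectrum, and the linear
centromere-clustering relation, each with its R² on the fitted scale.

Power-law fits regress log10(y) on log10(x) over the raw points;
exponential size spectra regress ln(count) on bin centre over non-empty
histogram bins.  R² is always reported on the transformed scale, matching
how regression packages report it for linearised fits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import CellPADSummary, FitResult, PADRecord

logger = logging.getLogger(__name__)


def _ols(x: np.ndarray, y: np.ndarray, model: str) -> FitResult:
    """Ordinary least squares of y on x with intercept, via lstsq."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(resid**2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return FitResult(
        model=model,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=float(r2),
        n_points=int(x.size),
        residual_sd=float(np.sqrt(ssr / max(x.size - 2, 1))),
    )


def fit_reciprocal_sqrt(cells: Sequence[CellPADSummary]) -> FitResult:
    """Linear fit of 1/n on √(mean area) across cells.

    Cells with zero PADs (or non-finite mean area) are excluded with a
    logged count.  A positive slope with high R² is the signature of
    fusion/splitting of a conserved heterochromatin amount.
    """
    pts = [(c.sqrt_mean_area, 1.0 / c.n_pads) for c in cells if c.valid_for_fits]
    n_excluded = len(cells) - len(pts)
    if n_excluded:
        logger.info("fit_reciprocal_sqrt: excluded %d cell(s) without PADs", n_excluded)
    if len(pts) < 3:
        raise ValueError("need at least 3 cells with PADs")
    x, y = np.array(pts).T
    fit = _ols(x, y, model="linear")
    fit.n_excluded = n_excluded
    return fit


def fit_power_law(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Power-law fit y = a·x^k by OLS of log10(y) on log10(x).

    Non-positive values (in either coordinate) are excluded with a logged
    count, following the zero-removal rule used for the size spectra.  The
    exponent is the slope of the log-log fit and is invariant under
    rescaling x or y by positive constants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    n_excluded = int(x.size - keep.sum())
    if n_excluded:
        logger.info("fit_power_law: excluded %d non-positive point(s)", n_excluded)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 positive points for the power-law fit")
    fit = _ols(np.log10(x[keep]), np.log10(y[keep]), model="power")
    fit.exponent = fit.slope
    fit.n_excluded = n_excluded
    return fit


def fit_exponential(
    areas: Sequence[float],
    n_bins: int = 20,
    max_area_um2: float = 6.0,
) -> FitResult:
    """Exponential fit of the individual-PAD size spectrum.

    Histograms the areas in equal-width bins on (0, ``max_area_um2``] — the
    cap reflects that the spectrum is dominated by PADs below 5-6 µm² —
    then regresses ln(count) on bin centre over the non-empty bins.  A
    negative slope (rate) corresponds to the exponentially decreasing size
    spectrum; values above the cap are excluded with a logged count.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size < 30:
        raise ValueError("need at least 30 PAD areas")
    kept = areas[(areas > 0) & (areas <= max_area_um2)]
    n_excluded = int(areas.size - kept.size)
    if n_excluded:
        logger.info("fit_exponential: excluded %d area(s) outside (0, %.1f]",
                    n_excluded, max_area_um2)
    counts, edges = np.histogram(kept, bins=n_bins, range=(0.0, max_area_um2))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nz = counts > 0
    if nz.sum() < 3:
        raise ValueError("fewer than 3 non-empty bins")
    fit = _ols(centers[nz], np.log(counts[nz]), model="exponential")
    fit.n_excluded = n_excluded
    return fit


def fit_centromere_clustering(
    pads: Sequence[PADRecord],
) -> tuple[FitResult, FitResult]:
    """Centromere count vs individual PAD area: linear and exponential fits.

    Both models are fitted to PADs with at least one centromere (zero-count
    PADs are excluded, as for all log fits): a linear OLS of count on area,
    and an exponential fit of ln(count) on area.  Reporting both R² values
    supports the model comparison between plain clustering
    (count ∝ area) and super-linear clustering toward large PAD clusters.
    When every count is equal the exponential fit is degenerate and flagged.
    """
    kept = [p for p in pads if p.centromere_count >= 1]
    if len(kept) < 10:
        raise ValueError("need at least 10 PADs with centromere_count >= 1")
    area = np.array([p.area_um2 for p in kept], dtype=float)
    count = np.array([p.centromere_count for p in kept], dtype=float)
    linear = _ols(area, count, model="linear")
    if np.ptp(count) == 0:
        logger.warning("fit_centromere_clustering: all counts equal; "
                       "exponential fit degenerate")
        exponential = FitResult(
            model="exponential", slope=0.0,
            intercept=float(np.log(count[0])), r2=0.0,
            n_points=len(kept), degenerate=True,
        )
    else:
        exponential = _ols(area, np.log(count), model="exponential")
    n_excluded = len(pads) - len(kept)
    linear.n_excluded = exponential.n_excluded = n_excluded
    return linear, exponential


@dataclass
class ConditionReport:
    """Control-vs-treated comparison of per-cell PAD statistics."""

    control_fit: Optional[FitResult]
    treated_fit: Optional[FitResult]
    control_median_area: float
    treated_median_area: float
    t_statistic: float
    df: float
    p_value: float
    boxplot: dict = field(default_factory=dict)

    @property
    def r2_drop(self) -> float:
        if self.control_fit is None or self.treated_fit is None:
            return float("nan")
        return self.control_fit.r2 - self.treated_fit.r2

    def to_dict(self) -> dict:
        return {
            "control_fit": self.control_fit.to_dict() if self.control_fit else None,
            "treated_fit": self.treated_fit.to_dict() if self.treated_fit else None,
            "control_median_area": self.control_median_area,
            "treated_median_area": self.treated_median_area,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "r2_drop": self.r2_drop,
            "boxplot": self.boxplot,
        }


def _box_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "n": int(values.size),
    }


def compare_conditions(
    control_cells: Sequence[CellPADSummary],
    treated_cells: Sequence[CellPADSummary],
) -> ConditionReport:
    """Compare PAD size-number structure between two cohorts.

    Fits the count-vs-mean-area power law per cohort (a treated cohort whose
    PADs have unravelled to uniform small units loses the fit — reported as
    an R² drop), compares the per-cell mean PAD areas by a two-tailed Welch
    test, and returns box-plot-ready five-number summaries.
    """
    ctrl = [c for c in control_cells if c.valid_for_fits]
    trt = [c for c in treated_cells if c.valid_for_fits]
    if not ctrl or not trt:
        raise ValueError("both cohorts must contain cells with PADs")

    def cohort_fit(cells, label):
        try:
            return fit_power_law(
                np.array([c.mean_area_um2 for c in cells]),
                np.array([c.n_pads for c in cells], dtype=float),
            )
        except ValueError as exc:
            logger.warning("compare_conditions: %s cohort fit failed (%s)", label, exc)
            return None

    ctrl_fit = cohort_fit(ctrl, "control")
    trt_fit = cohort_fit(trt, "treated")
    a = np.array([c.mean_area_um2 for c in ctrl])
    b = np.array([c.mean_area_um2 for c in trt])
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        t, p, df = (0.0, 1.0, float(a.size + b.size - 2)) if a.mean() == b.mean() else (
            float("inf"), 0.0, float(a.size + b.size - 2))
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return ConditionReport(
        control_fit=ctrl_fit,
        treated_fit=trt_fit,
        control_median_area=float(np.median(a)),
        treated_median_area=float(np.median(b)),
        t_statistic=t,
        df=df,
        p_value=p,
        boxplot={"control": _box_summary(a), "treated": _box_summary(b)},
    )
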