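"""Acridine-orange R/G DNA-conformation index.

After RNA removal and acid pretreatment, acridine orange reports chromatin
packing state through the ratio of red (dimer, ~640 nm) to green (monomer,
~530 nm) emission.  Per nucleus the index is the ratio of the integrated
fluorescence intensities of the two planes, R/G = IFI_red / IFI_green; a
higher value means a more unfolded DNA conformation.  Population shifts are
expressed on a control-normalised scale where the starving-control mean is
exactly 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stats import TestResult, welch_t
from .types import NucleusImage

logger = logging.getLogger(__name__)


@dataclass
class RGMeasurement:
    """Per-nucleus red/green index; ``valid`` is False when IFI_green = 0."""

    nucleus_id: int
    ifi_red: float
    ifi_green: float
    rg_raw: float
    valid: bool = True
    rg_norm: float = float("nan")


@dataclass
class PopulationRG:
    """Control-normalised R/G values and group summaries."""

    treated_norm: np.ndarray
    control_norm: np.ndarray
    control_mean_raw: float
    treated_mean: float
    treated_sd: float
    control_mean: float
    control_sd: float


def rg_index(
    image: NucleusImage, nucleus_mask: np.ndarray, nucleus_id: int = 0
) -> RGMeasurement:
    """R/G of one nucleus: per-plane IFI summed over the mask, then ratioed."""
    if image.red is None or image.green is None:
        raise ValueError("red and green planes required for the AO index")
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    ifi_red = float(np.asarray(image.red, dtype=float)[mask].sum())
    ifi_green = float(np.asarray(image.green, dtype=float)[mask].sum())
    if ifi_green == 0:
        logger.warning("rg_index[nucleus %d]: IFI_green = 0, measurement invalid",
                       nucleus_id)
        return RGMeasurement(nucleus_id, ifi_red, ifi_green, float("nan"), valid=False)
    return RGMeasurement(nucleus_id, ifi_red, ifi_green, ifi_red / ifi_green)


def measure_population(images: Sequence[NucleusImage]) -> list[RGMeasurement]:
    """R/G for a list of single-nucleus AO fields (whole field above zero)."""
    out = []
    for i, img in enumerate(images):
        mask = (np.asarray(img.green, dtype=float) > 0) | (
            np.asarray(img.red, dtype=float) > 0
        )
        out.append(rg_index(img, mask, nucleus_id=i))
    return out


def normalize_population(
    treated: Sequence[RGMeasurement], control: Sequence[RGMeasurement]
) -> PopulationRG:
    """Normalise raw R/G to the control-group mean (control mean becomes 1).

    Invalid measurements (zero green IFI) are excluded with a logged count.
    """
    ctrl = np.array([m.rg_raw for m in control if m.valid], dtype=float)
    trt = np.array([m.rg_raw for m in treated if m.valid], dtype=float)
    n_invalid = (len(control) - ctrl.size) + (len(treated) - trt.size)
    if n_invalid:
        logger.warning("normalize_population: excluded %d invalid measurement(s)",
                       n_invalid)
    if ctrl.size == 0:
        raise ValueError("control group is empty (or all invalid)")
    cmean = float(ctrl.mean())
    ctrl_norm = ctrl / cmean
    trt_norm = trt / cmean
    for m, v in zip([m for m in control if m.valid], ctrl_norm):
        m.rg_norm = float(v)
    for m, v in zip([m for m in treated if m.valid], trt_norm):
        m.rg_norm = float(v)
    return PopulationRG(
        treated_norm=trt_norm,
        control_norm=ctrl_norm,
        control_mean_raw=cmean,
        treated_mean=float(trt_norm.mean()) if trt_norm.size else float("nan"),
        treated_sd=float(trt_norm.std(ddof=1)) if trt_norm.size > 1 else float("nan"),
        control_mean=float(ctrl_norm.mean()),
        control_sd=float(ctrl_norm.std(ddof=1)) if ctrl_norm.size > 1 else float("nan"),
    )


def shift_test(group_a: np.ndarray, group_b: np.ndarray, label: str = "") -> TestResult:
    """Two-tailed Welch test on normalised R/G values (delegates to stats)."""
    return welch_t(np.asarray(group_a, float), np.asarray(group_b, float), label=label)


def detect_bimodality(
    values: np.ndarray, min_separation_sd: float = 2.0
) -> dict:
    """Report (not test) bimodal structure in a normalised R/G population.

    Finds local maxima of a Gaussian KDE; reports the two tallest modes and
    whether their separation exceeds ``min_separation_sd`` pooled standard
    deviations — the situation where a treated population has split into a
    lagging and a promoted subpopulation.
    """
    from scipy.signal import argrelmax
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    if values.size < 10 or np.ptp(values) == 0:
        return {"n_modes": 1, "modes": [float(np.mean(values))], "bimodal": False,
                "separation_sd": 0.0}
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 1024)
    dens = kde(grid)
    peaks = argrelmax(dens)[0]
    if grid.size and dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if grid.size and dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [grid.size - 1]])
    modes = grid[peaks][np.argsort(dens[peaks])[::-1]]
    if modes.size < 2:
        return {"n_modes": int(modes.size), "modes": modes.tolist(),
                "bimodal": False, "separation_sd": 0.0}
    top2 = np.sort(modes[:2])
    # pooled SD of the two half-populations split at the density minimum
    cut = 0.5 * (top2[0] + top2[1])
    left, right = values[values <= cut], values[values > cut]
    sds = [g.std(ddof=1) for g in (left, right) if g.size > 1]
    pooled = float(np.sqrt(np.mean(np.square(sds)))) if sds else float("nan")
    sep = float((top2[1] - top2[0]) / pooled) if pooled and np.isfinite(pooled) else 0.0
    return {
        "n_modes": int(modes.size),
        "modes": modes.tolist(),
        "bimodal": sep > min_separation_sd,
        "separation_sd": sep,
    }
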