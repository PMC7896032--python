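"""Shared container types for the PAD cytometry pipeline.

Conventions used throughout the package: images are 2-D ``float64`` arrays in
row-major order with pixel-centred, 0-based coordinates; areas are converted
between pixels and square micrometres via ``px_per_um ** 2``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class NucleusImage:
    """One registered multi-channel field.

    Channel roles follow the staining scheme: ``blue`` = DAPI (DNA),
    ``red`` = H3K9me3 (chromocenters / PADs) or the AO red plane,
    ``green`` = CENPA foci or H3K4me3 texture, or the AO green plane.
    Any channel may be ``None`` when the assay does not produce it
    (AO fields have no blue plane).
    """

    blue: Optional[np.ndarray]
    red: Optional[np.ndarray]
    green: Optional[np.ndarray]
    px_per_um: float
    field_id: str = ""

    def __post_init__(self) -> None:
        shapes = {c.shape for c in (self.blue, self.red, self.green) if c is not None}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if not shapes:
            raise ValueError("at least one channel must be present")
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        for c in (self.blue, self.red, self.green):
            if c is not None:
                return c.shape
        raise AssertionError("unreachable")


@dataclass
class NucleusRecord:
    """One segmented nucleus: mask, area, integrated DAPI intensity, gate."""

    nucleus_id: int
    mask: np.ndarray  # boolean, full-field shape
    area_px: int
    area_um2: float
    dapi_ifi: float
    gate: str = "unassigned"  # one of {"2C", "S-G2", "preapoptotic", "unassigned"}
    oversized: bool = False  # flagged probable under-segmentation
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("nucleus mask must be non-empty")
        if self.dapi_ifi < 0:
            raise ValueError("dapi_ifi must be >= 0")


@dataclass
class PADRecord:
    """One H3K9me3-positive chromocenter (PAD) inside a parent nucleus."""

    pad_id: int
    nucleus_id: int
    mask: np.ndarray
    area_px: int
    area_um2: float
    centromere_count: int = 0

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("PAD mask must be non-empty")
        if self.centromere_count < 0:
            raise ValueError("centromere_count must be >= 0")


@dataclass
class CellPADSummary:
    """Per-cell aggregate of chromocenter count and size.

    ``sqrt_mean_area`` (µm) is the linear-size proxy used by the
    reciprocal-count scaling analysis; ``heterogeneity`` is the fraction of
    in-nucleus pixels deviating more than the tolerance from the mean green
    intensity.
    """

    nucleus_id: int
    n_pads: int
    mean_area_um2: float
    total_area_um2: float
    sqrt_mean_area: float
    heterogeneity: float = float("nan")
    gate: str = "unassigned"

    @property
    def valid_for_fits(self) -> bool:
        return self.n_pads >= 1 and np.isfinite(self.mean_area_um2)


@dataclass
class FitResult:
    """Result of one least-squares model fit.

    ``model`` is ``"linear"``, ``"power"`` or ``"exponential"``; slope and
    intercept live on the fitted scale (log-log for power, log-linear for
    exponential).  ``exponent`` duplicates the slope for power-law fits, where
    it is the scaling exponent.  ``r2`` is the coefficient of determination on
    the fitted scale.
    """

    model: str
    slope: float
    intercept: float
    r2: float
    n_points: int
    exponent: Optional[float] = None
    residual_sd: float = float("nan")
    n_excluded: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "slope": self.slope,
            "intercept": self.intercept,
            "exponent": self.exponent,
            "r2": self.r2,
            "n_points": self.n_points,
            "residual_sd": self.residual_sd,
            "n_excluded": self.n_excluded,
            "degenerate": self.degenerate,
        }


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    cell_id: int
    dna_class: str  # "2C", "S-G2" or "preapoptotic"
    n_pads: int
    pad_areas_um2: np.ndarray
    centromere_counts: np.ndarray
    total_pad_area_um2: float
    dapi_base: float
    nucleus_area_um2: float
    ao_rg: float = float("nan")
    heterogeneity: float = float("nan")


@dataclass
class GroundTruth:
    """Ground truth accompanying a simulated dataset.

    Only the sections produced by the generator that built it are populated:
    ``cells`` for multi-channel nucleus fields, ``ao_rg`` for AO two-plane
    populations, ``fold_changes`` for qPCR plates.
    """

    cells: list[CellTruth] = field(default_factory=list)
    ao_rg: Optional[np.ndarray] = None
    fold_changes: Optional[dict] = None
    clipped_pixels: int = 0

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.cells:
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "dna_class": c.dna_class,
                    "n_pads": c.n_pads,
                    "total_pad_area_um2": c.total_pad_area_um2,
                    "mean_pad_area_um2": float(np.mean(c.pad_areas_um2))
                    if c.n_pads
                    else float("nan"),
                    "total_centromeres": int(np.sum(c.centromere_counts)),
                    "dapi_base": c.dapi_base,
                    "nucleus_area_um2": c.nucleus_area_um2,
                }
            )
        return pd.DataFrame(rows)
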