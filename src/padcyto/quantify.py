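"""Nucleus and chromocenter cytometry.

Segments DAPI-stained nuclei, measures integrated DAPI fluorescence (IFI)
for DNA-content gating, segments H3K9me3-positive chromocenters (PADs)
inside each nucleus, counts CENPA-positive centromere foci nested in PADs,
and computes the euchromatin heterogeneity statistic on the green channel.

The original measurements were made on interactively drawn contours; this
module replaces them with reproducible automatic thresholds (Otsu on the
smoothed DAPI channel for nuclei, a configurable fraction-of-maximum or
percentile threshold for the red/green foci channels), all exposed in
:class:`QuantConfig`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation

from .types import CellPADSummary, NucleusImage, NucleusRecord, PADRecord

logger = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    """Thresholds and windows of the cytometry pipeline.

    * ``smooth_sigma_um`` — Gaussian presmoothing of the DAPI channel before
      Otsu thresholding.
    * ``min_nucleus_area_um2`` / ``max_nucleus_area_um2`` — objects below the
      minimum are dropped (counted in the log); above the maximum they are
      kept but flagged as probable under-segmentation.
    * ``pad_threshold`` / ``foci_threshold`` — ``("fraction_of_max", f)``
      thresholds at ``f`` times the in-nucleus channel maximum (matches soft
      Gaussian-profile foci at ``f = 0.5``), or ``("percentile", q)`` at the
      q-th percentile of in-nucleus intensity.
    * ``min_pad_area_um2`` — components below this are discarded; the default
      0.2 µm² is the finest unit resolvable in the confocal data the size
      spectra are built from.
    * ``gate_window`` — half-width of the 2C gate around the modal IFI.
    * ``heterogeneity_tolerance`` — relative deviation above which a pixel
      counts as heterogeneous (strictly greater than).
    """

    smooth_sigma_um: float = 0.25
    min_nucleus_area_um2: float = 20.0
    max_nucleus_area_um2: float = 400.0
    pad_threshold: tuple[str, float] = ("fraction_of_max", 0.5)
    foci_threshold: tuple[str, float] = ("fraction_of_max", 0.5)
    min_pad_area_um2: float = 0.2
    min_focus_area_px: int = 2
    gate_window: float = 0.25
    heterogeneity_tolerance: float = 0.10

    def __post_init__(self) -> None:
        for name in ("pad_threshold", "foci_threshold"):
            kind, value = getattr(self, name)
            if kind not in ("fraction_of_max", "percentile"):
                raise ValueError(f"{name}: unknown method {kind!r}")
            if kind == "fraction_of_max" and not 0 < value < 1:
                raise ValueError(f"{name}: fraction must be in (0, 1)")
            if kind == "percentile" and not 0 < value < 100:
                raise ValueError(f"{name}: percentile must be in (0, 100)")
        if not 0 < self.gate_window < 1:
            raise ValueError("gate_window must be in (0, 1)")
        if self.heterogeneity_tolerance < 0:
            raise ValueError("heterogeneity_tolerance must be >= 0")


@dataclass
class GateReport:
    """Cell-cycle gating outcome: modal IFI and class fractions."""

    mode_ifi: float
    fractions: dict[str, float]
    n_cells: int
    assigned: bool = True


def _resolve_threshold(values: np.ndarray, spec: tuple[str, float]) -> float:
    kind, v = spec
    if kind == "fraction_of_max":
        return v * float(values.max())
    return float(np.percentile(values, v))


# ---------------------------------------------------------------------------


def segment_nuclei(
    image: NucleusImage, config: QuantConfig = QuantConfig()
) -> list[NucleusRecord]:
    """Segment nuclei on the DAPI (blue) channel.

    Smooth + Otsu + hole filling; connected components touching the image
    border or smaller than ``min_nucleus_area_um2`` are dropped (counts
    logged); components above ``max_nucleus_area_um2`` are flagged as
    probable under-segmentation.  An empty blue channel yields an empty
    list, not an error.
    """
    if image.blue is None:
        raise ValueError("blue (DAPI) channel required for nucleus segmentation")
    blue = np.asarray(image.blue, dtype=float)
    if blue.max() <= 0:
        return []
    sigma = config.smooth_sigma_um * image.px_per_um
    smoothed = filters.gaussian(blue, sigma=sigma, preserve_range=True)
    try:
        thr = filters.threshold_otsu(smoothed)
    except ValueError:  # constant image
        return []
    binary = ndi.binary_fill_holes(smoothed > thr)
    n_border_before = measure.label(binary, connectivity=2).max()
    binary = segmentation.clear_border(binary)
    labels = measure.label(binary, connectivity=2)
    n_dropped_border = n_border_before - labels.max()
    if n_dropped_border:
        logger.info("segment_nuclei[%s]: dropped %d border-touching object(s)",
                    image.field_id, n_dropped_border)
    px2 = image.px_per_um**2
    records: list[NucleusRecord] = []
    n_dropped_small = 0
    for region in measure.regionprops(labels):
        area_um2 = region.area / px2
        if area_um2 < config.min_nucleus_area_um2:
            n_dropped_small += 1
            continue
        mask = labels == region.label
        records.append(
            NucleusRecord(
                nucleus_id=len(records),
                mask=mask,
                area_px=int(region.area),
                area_um2=area_um2,
                dapi_ifi=measure_dna_content_mask(blue, mask),
                oversized=area_um2 > config.max_nucleus_area_um2,
                field_id=image.field_id,
            )
        )
    if n_dropped_small:
        logger.info("segment_nuclei[%s]: dropped %d object(s) below %.1f um^2",
                    image.field_id, n_dropped_small, config.min_nucleus_area_um2)
    n_over = sum(r.oversized for r in records)
    if n_over:
        logger.warning("segment_nuclei[%s]: %d object(s) exceed max_nucleus_area "
                       "(possible under-segmentation)", image.field_id, n_over)
    return records


def measure_dna_content_mask(blue: np.ndarray, mask: np.ndarray) -> float:
    """Integrated DAPI fluorescence intensity (IFI): sum of blue over the mask."""
    return float(np.asarray(blue, dtype=float)[mask].sum())


def measure_dna_content(nucleus: NucleusRecord, image: NucleusImage) -> float:
    """IFI of one nucleus; additive over any partition of its mask."""
    if image.blue is None:
        raise ValueError("blue (DAPI) channel required")
    return measure_dna_content_mask(image.blue, nucleus.mask)


def gate_cells(
    records: Sequence[NucleusRecord],
    mode_window: float = 0.25,
    pad_summaries: Optional[dict[int, "CellPADSummary"]] = None,
    min_cells: int = 20,
) -> GateReport:
    """Gate DNA-content classes around the modal IFI (in place).

    The modal IFI is the tallest peak of a Gaussian kernel density estimate
    over per-nucleus IFI.  Cells within ``mode x [1-w, 1+w]`` are gated 2C;
    above the window S-G2; below the window preapoptotic.  When per-cell PAD
    summaries are supplied, the preapoptotic label additionally requires a
    top-quartile mean PAD area (chromocenter aggregation with DNA loss);
    low-IFI cells failing that stay unassigned.  With fewer than
    ``min_cells`` records everything stays unassigned.
    """
    records = list(records)
    n = len(records)
    if n < min_cells:
        logger.warning("gate_cells: only %d records (< %d); all left unassigned", n, min_cells)
        for r in records:
            r.gate = "unassigned"
        return GateReport(mode_ifi=float("nan"), fractions={}, n_cells=n, assigned=False)
    ifi = np.array([r.dapi_ifi for r in records], dtype=float)
    mode = _modal_value(ifi)
    lo, hi = mode * (1.0 - mode_window), mode * (1.0 + mode_window)

    big_pads = None
    if pad_summaries:
        mean_areas = np.array(
            [pad_summaries[r.nucleus_id].mean_area_um2
             if r.nucleus_id in pad_summaries else np.nan
             for r in records]
        )
        with np.errstate(invalid="ignore"):
            q75 = np.nanpercentile(mean_areas, 75)
        big_pads = mean_areas >= q75

    for i, r in enumerate(records):
        if lo <= r.dapi_ifi <= hi:
            r.gate = "2C"
        elif r.dapi_ifi > hi:
            r.gate = "S-G2"
        else:
            if big_pads is None or big_pads[i]:
                r.gate = "preapoptotic"
            else:
                r.gate = "unassigned"
    fractions = {
        g: sum(r.gate == g for r in records) / n
        for g in ("2C", "S-G2", "preapoptotic", "unassigned")
    }
    return GateReport(mode_ifi=mode, fractions=fractions, n_cells=n)


def _modal_value(values: np.ndarray) -> float:
    """Tallest-peak estimate via Gaussian KDE (falls back for degenerate input)."""
    from scipy.stats import gaussian_kde

    if np.ptp(values) == 0:
        return float(values[0])
    try:
        kde = gaussian_kde(values)
    except np.linalg.LinAlgError:
        return float(np.median(values))
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def segment_pads(
    image: NucleusImage,
    nucleus: NucleusRecord,
    config: QuantConfig = QuantConfig(),
) -> list[PADRecord]:
    """Segment H3K9me3-positive chromocenters inside one nucleus.

    Connected components (8-connectivity) of the thresholded red channel
    restricted to the nucleus mask; components below ``min_pad_area_um2``
    are discarded (counted in the log).  A nucleus with no red signal gives
    an empty list.
    """
    if image.red is None:
        raise ValueError("red channel required for PAD segmentation")
    red = np.asarray(image.red, dtype=float)
    inside = red[nucleus.mask]
    if inside.size == 0 or inside.max() <= 0:
        return []
    thr = _resolve_threshold(inside, config.pad_threshold)
    binary = (red > thr) & nucleus.mask
    labels = measure.label(binary, connectivity=2)
    px2 = image.px_per_um**2
    pads: list[PADRecord] = []
    n_small = 0
    for region in measure.regionprops(labels):
        area_um2 = region.area / px2
        if area_um2 < config.min_pad_area_um2:
            n_small += 1
            continue
        pads.append(
            PADRecord(
                pad_id=len(pads),
                nucleus_id=nucleus.nucleus_id,
                mask=labels == region.label,
                area_px=int(region.area),
                area_um2=area_um2,
            )
        )
    if n_small:
        logger.info("segment_pads[nucleus %d]: dropped %d component(s) below %.2f um^2",
                    nucleus.nucleus_id, n_small, config.min_pad_area_um2)
    return pads


def count_centromeres(
    image: NucleusImage,
    pads: Sequence[PADRecord],
    nucleus: Optional[NucleusRecord] = None,
    config: QuantConfig = QuantConfig(),
) -> list[PADRecord]:
    """Count CENPA-positive foci per PAD (in place; also returns the list).

    Green connected components (8-connectivity) are assigned to the PAD
    whose mask contains their centroid; components whose centroid falls in
    no PAD are ignored.
    """
    if image.green is None:
        raise ValueError("green channel required for centromere counting")
    green = np.asarray(image.green, dtype=float)
    domain = nucleus.mask if nucleus is not None else np.ones_like(green, dtype=bool)
    inside = green[domain]
    for pad in pads:
        pad.centromere_count = 0
    if inside.size == 0 or inside.max() <= 0:
        return list(pads)
    thr = _resolve_threshold(inside, config.foci_threshold)
    labels = measure.label((green > thr) & domain, connectivity=2)
    for region in measure.regionprops(labels):
        if region.area < config.min_focus_area_px:
            continue
        cy, cx = region.centroid
        iy, ix = int(round(cy)), int(round(cx))
        for pad in pads:
            if pad.mask[iy, ix]:
                pad.centromere_count += 1
                break
    return list(pads)


def heterogeneity(
    image: NucleusImage,
    nucleus: NucleusRecord,
    tolerance: float = 0.10,
) -> float:
    """Fraction of in-nucleus green pixels deviating more than ``tolerance``.

    With ``m`` the mean green intensity over the nucleus mask, returns
    ``|{p : |I(p) - m| > tolerance * m}| / |mask|``.  The inequality is
    strict, so pixels deviating exactly 10% do not count.  Invariant under
    multiplying all intensities by a positive constant.  A uniformly zero
    field has mean 0 and is defined as perfectly homogeneous (0, logged).
    """
    if image.green is None:
        raise ValueError("green channel required for heterogeneity")
    values = np.asarray(image.green, dtype=float)[nucleus.mask]
    if values.size == 0:
        raise ValueError("nucleus mask is empty")
    m = values.mean()
    if m == 0:
        logger.info("heterogeneity[nucleus %d]: zero-mean field, returning 0",
                    nucleus.nucleus_id)
        return 0.0
    return float((np.abs(values - m) > tolerance * m).sum() / values.size)


def summarize_cell(
    nucleus: NucleusRecord,
    pads: Sequence[PADRecord],
    het: float = float("nan"),
) -> CellPADSummary:
    """Aggregate one cell: PAD count, mean/total area, √(mean area), heterogeneity.

    A cell with zero PADs gets NaN mean/sqrt areas and is excluded from fits
    downstream (``valid_for_fits`` is False).
    """
    for p in pads:
        if p.nucleus_id != nucleus.nucleus_id:
            raise ValueError("PAD/nucleus linkage inconsistent")
    n = len(pads)
    if n == 0:
        logger.info("summarize_cell[nucleus %d]: zero PADs, excluded from fits",
                    nucleus.nucleus_id)
        return CellPADSummary(
            nucleus_id=nucleus.nucleus_id,
            n_pads=0,
            mean_area_um2=float("nan"),
            total_area_um2=0.0,
            sqrt_mean_area=float("nan"),
            heterogeneity=het,
            gate=nucleus.gate,
        )
    total = float(sum(p.area_um2 for p in pads))
    mean = total / n
    return CellPADSummary(
        nucleus_id=nucleus.nucleus_id,
        n_pads=n,
        mean_area_um2=mean,
        total_area_um2=total,
        sqrt_mean_area=float(np.sqrt(mean)),
        heterogeneity=het,
        gate=nucleus.gate,
    )


def quantify_field(
    image: NucleusImage, config: QuantConfig = QuantConfig()
) -> tuple[list[NucleusRecord], list[PADRecord], list[CellPADSummary]]:
    """Run segmentation + PAD counting + heterogeneity on one field."""
    nuclei = segment_nuclei(image, config)
    all_pads: list[PADRecord] = []
    summaries: list[CellPADSummary] = []
    for nuc in nuclei:
        pads = segment_pads(image, nuc, config)
        count_centromeres(image, pads, nucleus=nuc, config=config)
        het = heterogeneity(image, nuc, tolerance=config.heterogeneity_tolerance)
        summaries.append(summarize_cell(nuc, pads, het))
        all_pads.extend(pads)
    return nuclei, all_pads, summaries
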