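"""Seeded generators of synthetic microscopy fields and qPCR plates.

The generators emulate the statistical structure the downstream analysis
assumes, with full ground truth for recovery tests:

* nuclei whose chromocenters (PADs) share a conserved per-cell total area
  while their count varies — the fusion/splitting regime that produces the
  1/n size-number scaling;
* CENPA-like centromere foci nested inside PADs, with counts proportional to
  PAD area (centromere clustering);
* acridine-orange two-plane populations with a controllable red/green shift;
* euchromatin-like textures with a controllable pixel-deviation
  heterogeneity;
* qPCR CT tables with specified fold changes and reference-gene stability.

All randomness descends from one root seed: a ``numpy.random.SeedSequence``
is built from it and spawned once per cell (or per plate section), so adding
cells never perturbs earlier ones and identical parameters give bit-identical
output.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import CellTruth, GroundTruth, NucleusImage

logger = logging.getLogger(__name__)

# Rendering constants.  Blobs are Gaussian-profile discs whose half-maximum
# contour matches the true radius; profiles are truncated at TRUNC_FACTOR
# times that radius, and placement keeps centres at least
# SEP_FACTOR*(r_i+r_j) + SEP_GAP_PX apart, which together guarantee that no
# blob's tail can lift a pixel outside another blob above half maximum — the
# half-max threshold then recovers every disc as a separate component.
PAD_AMPLITUDE = 200.0
FOCUS_AMPLITUDE = 180.0
DAPI_2C = 100.0
DAPI_SG2 = 200.0
DAPI_PREAPO = 65.0
DAPI_PAD_EXCESS = 0.1  # chromocenter excess in the blue channel, x red
HALF_MAX_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))  # sigma = r * this
TRUNC_FACTOR = 1.4
SEP_FACTOR = 1.25
SEP_GAP_PX = 2.0
FOCUS_RADIUS_UM = 0.2
MAX_PLACEMENT_RETRIES = 500


class PlacementError(RuntimeError):
    """Raised when a blob cannot be placed without overlap within the retry budget."""


CountLaw = Union[tuple[int, int], dict[int, float]]


@dataclass
class PopulationParams:
    """Parameters of a simulated nucleus population.

    ``total_pad_area`` is the conserved per-cell amount of constitutive
    pericentric heterochromatin (µm²); ``area_cv`` is the cell-to-cell
    coefficient of variation around it (0 = exact conservation).
    ``count_law`` is either an inclusive integer range ``(low, high)`` drawn
    uniformly, or a ``{count: probability}`` categorical law; the default
    range 6–16 matches the bulk of chromocenter counts seen in serum-starved
    controls.  ``centromere_density`` is centromeres per µm² of PAD.
    """

    n_cells: int = 100
    total_pad_area: float = 16.0
    area_cv: float = 0.1
    count_law: CountLaw = (6, 16)
    centromere_density: float = 1.0
    dirichlet_alpha: float = 1.0
    image_size: int = 192
    px_per_um: float = 8.0
    noise_sd: float = 2.0
    nucleus_radius_um: float = 5.5
    dna_class_probs: tuple[float, float, float] = (0.85, 0.10, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.total_pad_area <= 0:
            raise ValueError("total_pad_area must be positive")
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        if self.area_cv < 0 or self.noise_sd < 0:
            raise ValueError("area_cv and noise_sd must be >= 0")
        if abs(sum(self.dna_class_probs) - 1.0) > 1e-9:
            raise ValueError("dna_class_probs must sum to 1")
        for n in self._count_support():
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ValueError("count_law support must be positive integers")

    def _count_support(self) -> Sequence[int]:
        if isinstance(self.count_law, dict):
            return list(self.count_law)
        lo, hi = self.count_law
        return [lo, hi]

    def draw_count(self, rng: np.random.Generator) -> int:
        if isinstance(self.count_law, dict):
            ns = np.array(sorted(self.count_law))
            ps = np.array([self.count_law[n] for n in ns], dtype=float)
            return int(rng.choice(ns, p=ps / ps.sum()))
        lo, hi = self.count_law
        return int(rng.integers(lo, hi + 1))


@dataclass
class QPCRSimParams:
    """Design of a simulated qPCR plate.

    ``genes`` maps target gene -> {sample: true fold change vs the control
    sample}; ``ref_genes`` maps reference gene -> stability (SD of its log2
    expression across samples; 0 = perfectly stable).  CT noise is per-well,
    in cycles.
    """

    genes: dict[str, dict[str, float]]
    ref_genes: dict[str, float] = field(
        default_factory=lambda: {"GAPDH": 0.0, "B2M": 0.0}
    )
    replicates: int = 4
    ct_noise_sd: float = 0.2
    control_sample: str = "ST"
    baseline_ct: float = 24.0
    ref_baseline_ct: float = 19.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if len(self.ref_genes) < 1:
            raise ValueError("at least one reference gene required")

    @property
    def samples(self) -> list[str]:
        names: list[str] = [self.control_sample]
        for fold_map in self.genes.values():
            for s in fold_map:
                if s not in names:
                    names.append(s)
        return names


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_mask(shape, center, axes, theta):
    """Boolean mask of a rotated ellipse (pixel-centred coordinates)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    y = rr - center[0]
    x = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _render_blob(channel, center, r_px, amplitude):
    """Add a truncated Gaussian-profile disc; half-maximum contour at r_px."""
    sigma = max(r_px, 0.5) * HALF_MAX_SIGMA
    cut = max(TRUNC_FACTOR * r_px, 1.5)
    r0, r1 = int(max(0, center[0] - cut - 1)), int(min(channel.shape[0], center[0] + cut + 2))
    c0, c1 = int(max(0, center[1] - cut - 1)), int(min(channel.shape[1], center[1] + cut + 2))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    prof = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    prof[d2 > cut**2] = 0.0
    channel[r0:r1, c0:c1] += prof


def _place_disjoint(
    rng: np.random.Generator,
    radii_px: np.ndarray,
    center,
    axes,
    theta,
    what: str,
    sep_factor: float = SEP_FACTOR,
    gap_px: float = SEP_GAP_PX,
    margin_factor: float = 1.05,
):
    """Rejection-sample non-overlapping disc centres inside an ellipse.

    Largest discs are placed first; each centre must keep its half-maximum
    disc inside the ellipse (scaled by ``margin_factor``) and respect the
    separation rule against all previously placed discs.  Raises
    :class:`PlacementError` after ``MAX_PLACEMENT_RETRIES`` failed draws for
    any single disc.
    """
    order = np.argsort(radii_px)[::-1]
    ct, st = math.cos(theta), math.sin(theta)
    n_restarts = 20
    for restart in range(n_restarts):
        centers = np.zeros((len(radii_px), 2))
        placed: list[int] = []
        failed = False
        for idx in order:
            r = radii_px[idx]
            margin = margin_factor * r + 1.0
            ay = max(axes[0] - margin, 0.5)
            ax = max(axes[1] - margin, 0.5)
            for attempt in range(MAX_PLACEMENT_RETRIES):
                # uniform point in the shrunken ellipse
                u = math.sqrt(rng.uniform())
                phi = rng.uniform(0.0, 2.0 * math.pi)
                ex = u * ax * math.cos(phi)
                ey = u * ay * math.sin(phi)
                cy = center[0] + ex * st + ey * ct
                cx = center[1] + ex * ct - ey * st
                ok = True
                for j in placed:
                    sep = sep_factor * (r + radii_px[j]) + gap_px
                    if (cy - centers[j, 0]) ** 2 + (cx - centers[j, 1]) ** 2 < sep**2:
                        ok = False
                        break
                if ok:
                    centers[idx] = (cy, cx)
                    placed.append(idx)
                    break
            else:  # this disc failed; restart the whole set with fresh draws
                failed = True
                break
        if not failed:
            return centers
    raise PlacementError(
        f"could not place {what} set of {len(radii_px)} disc(s) after "
        f"{n_restarts} restarts x {MAX_PLACEMENT_RETRIES} retries"
    )


def _stick_break(rng: np.random.Generator, total: float, n: int, alpha: float) -> np.ndarray:
    """Split ``total`` into ``n`` fragments by symmetric Dirichlet stick-breaking."""
    if n == 1:
        return np.array([total])
    w = rng.dirichlet(np.full(n, alpha))
    return total * w


# ---------------------------------------------------------------------------
# population generator


def sample_population_truth(params: PopulationParams) -> GroundTruth:
    """Draw the per-cell ground truth (no rendering).

    Useful for analyses that only need the fragment statistics — e.g. the
    conserved-area scaling study — where rendering and re-segmenting the
    fields would only add discretisation error.
    """
    root = np.random.SeedSequence(params.seed)
    truth = GroundTruth()
    for cell_id, child in enumerate(root.spawn(params.n_cells)):
        rng = np.random.Generator(np.random.PCG64(child))
        truth.cells.append(_sample_cell(params, cell_id, rng))
    return truth


def _sample_cell(params: PopulationParams, cell_id: int, rng: np.random.Generator) -> CellTruth:
    classes = ("2C", "S-G2", "preapoptotic")
    dna_class = classes[rng.choice(3, p=np.asarray(params.dna_class_probs))]
    if dna_class == "preapoptotic":
        # aggregated chromocenters with some DNA loss
        n = int(rng.integers(1, 4))
        base = DAPI_PREAPO
    else:
        n = params.draw_count(rng)
        base = DAPI_SG2 if dna_class == "S-G2" else DAPI_2C
    if params.area_cv > 0:
        mult = max(0.2, 1.0 + params.area_cv * rng.standard_normal())
    else:
        mult = 1.0
    total = params.total_pad_area * mult
    areas = _stick_break(rng, total, n, params.dirichlet_alpha)
    counts = np.maximum(1, np.round(params.centromere_density * areas)).astype(int)
    ax_jitter = rng.uniform(0.9, 1.1, size=2)
    nucleus_area = math.pi * params.nucleus_radius_um**2 * ax_jitter[0] * ax_jitter[1]
    cell = CellTruth(
        cell_id=cell_id,
        dna_class=dna_class,
        n_pads=n,
        pad_areas_um2=areas,
        centromere_counts=counts,
        total_pad_area_um2=float(areas.sum()),
        dapi_base=base,
        nucleus_area_um2=nucleus_area,
    )
    cell._ax_jitter = ax_jitter  # reused by the renderer
    return cell


def simulate_population(params: PopulationParams) -> tuple[list[NucleusImage], GroundTruth]:
    """Render one nucleus field per cell with full ground truth.

    Each field carries a DAPI (blue), H3K9me3 (red) and CENPA (green)
    channel.  Per-cell total PAD area follows the conservation law set by
    ``total_pad_area``/``area_cv``; fragment counts follow ``count_law``;
    centromere foci are nested inside PAD discs with counts
    ``max(1, round(density * area))``.  Raises :class:`PlacementError` when a
    blob cannot be placed without overlap.
    """
    root = np.random.SeedSequence(params.seed)
    size = params.image_size
    truth = GroundTruth()
    images: list[NucleusImage] = []
    for cell_id, child in enumerate(root.spawn(params.n_cells)):
        rng = np.random.Generator(np.random.PCG64(child))
        cell = _sample_cell(params, cell_id, rng)

        center = (
            size / 2.0 + rng.uniform(-3, 3),
            size / 2.0 + rng.uniform(-3, 3),
        )
        r_nuc = params.nucleus_radius_um * params.px_per_um
        axes = (r_nuc * cell._ax_jitter[0], r_nuc * cell._ax_jitter[1])
        theta = rng.uniform(0.0, math.pi)
        nuc_mask = _ellipse_mask((size, size), center, axes, theta)

        radii_px = np.sqrt(cell.pad_areas_um2 / math.pi) * params.px_per_um
        pad_centers = _place_disjoint(
            rng, radii_px, center, axes, theta, what=f"PAD (cell {cell_id})"
        )

        red = np.zeros((size, size))
        green = np.zeros((size, size))
        for (cy, cx), r in zip(pad_centers, radii_px):
            _render_blob(red, (cy, cx), r, PAD_AMPLITUDE)
        focus_r = FOCUS_RADIUS_UM * params.px_per_um
        for (cy, cx), r, c in zip(pad_centers, radii_px, cell.centromere_counts):
            foci = _place_disjoint(
                rng,
                np.full(c, focus_r),
                (cy, cx),
                (max(0.9 * r, 0.5), max(0.9 * r, 0.5)),
                0.0,
                what=f"centromere focus (cell {cell_id})",
                sep_factor=1.5,
                gap_px=0.5,
                margin_factor=0.0,
            )
            for fy, fx in foci:
                _render_blob(green, (fy, fx), focus_r, FOCUS_AMPLITUDE)

        blue = cell.dapi_base * nuc_mask.astype(float) + DAPI_PAD_EXCESS * red
        if params.noise_sd > 0:
            blue = blue + rng.normal(0.0, params.noise_sd, blue.shape)
            red = red + rng.normal(0.0, params.noise_sd, red.shape)
            green = green + rng.normal(0.0, params.noise_sd, green.shape)
            for ch in (blue, red, green):
                np.clip(ch, 0.0, None, out=ch)

        cell._pad_centers_px = pad_centers
        cell._pad_radii_px = radii_px
        truth.cells.append(cell)
        images.append(
            NucleusImage(
                blue=blue,
                red=red,
                green=green,
                px_per_um=params.px_per_um,
                field_id=f"cell_{cell_id:04d}",
            )
        )
    return images, truth


# ---------------------------------------------------------------------------
# AO populations


def simulate_ao_population(
    n_cells: int,
    control_rg: float,
    shift_factor: float,
    noise_sd: float,
    seed: int,
    image_size: int = 96,
    px_per_um: float = 4.0,
) -> tuple[list[NucleusImage], GroundTruth]:
    """Two-plane acridine-orange fields with a controllable population R/G shift.

    Per-nucleus ``IFI_red / IFI_green`` is lognormally distributed with mean
    ``control_rg * shift_factor`` and standard deviation
    ``control_rg * noise_sd`` (``noise_sd`` is the spread on the
    control-normalised scale, matching how population SDs are reported);
    ``noise_sd = 0`` makes every nucleus exactly ``control_rg * shift_factor``.
    """
    if control_rg <= 0 or shift_factor <= 0:
        raise ValueError("control_rg and shift_factor must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    root = np.random.SeedSequence([int(seed), 0xA0])
    mean_norm = shift_factor
    truth = GroundTruth()
    images: list[NucleusImage] = []
    rgs = np.empty(n_cells)
    clipped = 0
    for i, child in enumerate(root.spawn(n_cells)):
        rng = np.random.Generator(np.random.PCG64(child))
        if noise_sd == 0:
            r_norm = mean_norm
        else:
            s2 = math.log1p((noise_sd / mean_norm) ** 2)
            mu = math.log(mean_norm) - s2 / 2.0
            r_norm = float(rng.lognormal(mu, math.sqrt(s2)))
        rg = control_rg * r_norm
        rgs[i] = rg

        center = (image_size / 2.0, image_size / 2.0)
        ax = image_size * 0.3 * rng.uniform(0.9, 1.1)
        ay = image_size * 0.3 * rng.uniform(0.9, 1.1)
        mask = _ellipse_mask((image_size, image_size), center, (ay, ax), 0.0)
        green_level = 150.0
        green = green_level * mask.astype(float)
        red = green_level * rg * mask.astype(float)
        neg = int((green < 0).sum() + (red < 0).sum())
        if neg:
            clipped += neg
            np.clip(green, 0.0, None, out=green)
            np.clip(red, 0.0, None, out=red)
        images.append(
            NucleusImage(
                blue=None,
                red=red,
                green=green,
                px_per_um=px_per_um,
                field_id=f"ao_{i:04d}",
            )
        )
    if clipped:
        logger.warning("clipped %d negative pixels in AO simulation", clipped)
    truth.ao_rg = rgs
    truth.clipped_pixels = clipped
    return images, truth


# ---------------------------------------------------------------------------
# heterogeneity texture


def simulate_heterogeneity_field(
    mask: np.ndarray, target_fraction: float, seed: int, mean_level: float = 100.0
) -> np.ndarray:
    """Texture whose >10%-deviation pixel fraction equals ``target_fraction``.

    A fraction ``target_fraction`` of in-mask pixels is displaced ±25% from
    the mean level (balanced up/down so the mask mean stays at
    ``mean_level``); the rest sit exactly at the mean.  The measured
    heterogeneity then matches the target to within one pixel's weight.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E]))
    k = int(round(target_fraction * n))
    k_up = k // 2
    k_down = k - k_up
    values = np.full(n, mean_level)
    idx = rng.permutation(n)
    dev = 0.25 * mean_level
    values[idx[:k_up]] += dev
    values[idx[k_up : k_up + k_down]] -= dev
    img = np.zeros(mask.shape)
    img[mask] = values
    return img


# ---------------------------------------------------------------------------
# qPCR plates


def simulate_qpcr_plate(params: QPCRSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one qPCR plate as a tidy CT table.

    Per well, ``CT = baseline - log2(expression) + N(0, ct_noise_sd²)``.
    Target-gene expression is the specified fold change vs the control
    sample; reference-gene expression varies across samples with the stated
    stability (SD of log2 expression; 0 = constant).
    Returns a DataFrame with columns ``sample, gene, replicate, ct`` plus the
    ground-truth fold changes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0x9C]))
    rows = []
    samples = params.samples
    for gene, fold_map in params.genes.items():
        for sample in samples:
            fold = 1.0 if sample == params.control_sample else fold_map.get(sample, 1.0)
            if fold <= 0:
                raise ValueError(f"fold change must be positive ({gene}, {sample})")
            base_ct = params.baseline_ct - math.log2(fold)
            for rep in range(1, params.replicates + 1):
                ct = base_ct + rng.normal(0.0, params.ct_noise_sd)
                rows.append((sample, gene, rep, ct))
    for ref, stability in params.ref_genes.items():
        for sample in samples:
            log2_expr = rng.normal(0.0, stability) if stability > 0 else 0.0
            base_ct = params.ref_baseline_ct - log2_expr
            for rep in range(1, params.replicates + 1):
                ct = base_ct + rng.normal(0.0, params.ct_noise_sd)
                rows.append((sample, ref, rep, ct))
    table = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    truth = GroundTruth(
        fold_changes={g: dict(m) for g, m in params.genes.items()}
    )
    return table, truth
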