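"""Relative quantification of qPCR CT tables.

Implements the comparative-CT scheme with an assumed amplification
efficiency of 2:

    ΔCT  = CT(target) - CT(reference)
    ΔΔCT = ΔCT - ΔCT(control sample)
    RQ   = 2^(-ΔΔCT)

with either a single reference gene or a two-gene scheme in which relative
quantities are normalised by the geometric mean of the pair — equivalent,
on the CT scale, to subtracting the arithmetic mean of the two reference
CTs.  Reference-gene stability is scored with the pairwise-variation
measure M (the geNorm definition, reimplemented here): for candidate j,
M(j) is the mean over the other candidates k of the standard deviation
across samples of log2(Q_j / Q_k), where Q = 2^(-CT) is the relative
quantity.

CT tables are tidy DataFrames with columns ``sample, gene, replicate, ct``;
replicates are averaged (arithmetic mean of CT) before any ΔCT.
"""
from __future__ import annotations

import logging
from typing import Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample", "gene", "replicate", "ct")

Reference = Union[str, Sequence[str]]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CT table lacks column(s): {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return table


def mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged CT per (sample, gene), with replicate SD and count."""
    _validate_table(table)
    out = (
        table.groupby(["sample", "gene"], sort=False)["ct"]
        .agg(ct="mean", ct_sd="std", n_replicates="count")
        .reset_index()
    )
    return out


def _reference_ct(means: pd.DataFrame, ref: Reference) -> pd.Series:
    """Per-sample reference CT: single gene, or the mean CT of a gene pair.

    Averaging CTs of the pair is identical to normalising relative
    quantities by their geometric mean, since log2 Q = -CT.
    """
    refs = [ref] if isinstance(ref, str) else list(ref)
    pivot = means.pivot(index="sample", columns="gene", values="ct")
    for r in refs:
        missing = pivot.index[pivot[r].isna()].tolist() if r in pivot else list(pivot.index)
        if r not in pivot.columns or missing:
            raise ValueError(
                f"reference gene {r!r} missing in sample(s): "
                f"{missing if r in pivot.columns else 'all'}"
            )
    return pivot[refs].mean(axis=1)


def delta_ct(table: pd.DataFrame, target_gene: str, ref: Reference) -> pd.Series:
    """ΔCT per sample: mean CT(target) - reference CT.

    ``ref`` is a reference gene name or a pair of names (two-gene geometric
    averaging scheme).  Raises if the target or a reference is missing from
    any sample, naming it.
    """
    means = mean_ct(table)
    pivot = means.pivot(index="sample", columns="gene", values="ct")
    if target_gene not in pivot.columns:
        raise ValueError(f"target gene {target_gene!r} absent from the table")
    missing = pivot.index[pivot[target_gene].isna()].tolist()
    if missing:
        raise ValueError(f"target gene {target_gene!r} missing in sample(s): {missing}")
    ref_ct = _reference_ct(means, ref)
    return (pivot[target_gene] - ref_ct).rename("delta_ct")


def rq(
    table: pd.DataFrame,
    target_gene: str,
    ref: Reference,
    control_sample: str,
) -> pd.DataFrame:
    """Relative quantification of one target within one plate.

    Returns a per-sample frame with ΔCT, ΔΔCT and RQ = 2^(-ΔΔCT); RQ of the
    control sample is exactly 1 and log2(RQ) = -ΔΔCT by construction.  All
    quantities are computed inside the given table (one plate); no
    cross-plate pooling.
    """
    dct = delta_ct(table, target_gene, ref)
    if control_sample not in dct.index:
        raise ValueError(f"control sample {control_sample!r} absent from the table")
    ddct = dct - dct.loc[control_sample]
    out = pd.DataFrame(
        {
            "gene": target_gene,
            "delta_ct": dct,
            "delta_delta_ct": ddct,
            "rq": np.power(2.0, -ddct),
        }
    )
    out.index.name = "sample"
    return out.reset_index()


def genorm_m(table: pd.DataFrame, candidate_refs: Sequence[str]) -> pd.Series:
    """Reference-gene stability M per candidate (pairwise-variation measure).

    M(j) = mean over k != j of SD across samples of log2(Q_j / Q_k) with
    Q = 2^(-CT).  Lower is more stable; perfectly covarying candidates give
    M = 0, and M is invariant under per-sample CT offsets (plate effects
    cancel in the ratio).  Requires >= 2 candidates and >= 2 samples.
    """
    candidates = list(candidate_refs)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate reference genes")
    means = mean_ct(table)
    pivot = means.pivot(index="sample", columns="gene", values="ct")
    for g in candidates:
        if g not in pivot.columns or pivot[g].isna().any():
            raise ValueError(f"candidate {g!r} missing in some sample(s)")
    if len(pivot.index) < 2:
        raise ValueError("need at least 2 samples to estimate stability")
    # log2(Qj/Qk) = CT_k - CT_j
    m = {}
    for j in candidates:
        sds = [
            float((pivot[k] - pivot[j]).std(ddof=1))
            for k in candidates
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="genorm_m")


def normalize_biphasic_report(
    rq_results: pd.DataFrame,
    genes: Sequence[str] | None = None,
    sample_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalise a time-course RQ table per gene to its maximal mean value.

    ``rq_results`` holds columns ``sample, gene, rq`` (several plates may be
    concatenated; values are averaged per (gene, sample) first).  Each
    gene's series is divided by its maximum mean RQ, so the peak of every
    gene sits at 1 — the display convention for comparing biphasic
    early-response kinetics across genes.
    """
    if genes is not None:
        rq_results = rq_results[rq_results["gene"].isin(list(genes))]
    means = rq_results.groupby(["gene", "sample"], sort=False)["rq"].mean().reset_index()
    out_parts = []
    for gene, sub in means.groupby("gene", sort=False):
        if len(sub) < 2:
            raise ValueError(f"gene {gene!r} has fewer than 2 time points")
        peak = sub["rq"].max()
        part = sub.copy()
        part["rq_norm"] = part["rq"] / peak
        out_parts.append(part)
    out = pd.concat(out_parts, ignore_index=True)
    if sample_order is not None:
        order = {s: i for i, s in enumerate(sample_order)}
        out = out.sort_values(
            ["gene", "sample"], key=lambda s: s.map(order) if s.name == "sample" else s
        ).reset_index(drop=True)
    return out
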