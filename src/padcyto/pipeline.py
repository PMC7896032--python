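"""End-to-end runners: generation -> quantification -> fits -> statistics.

Each runner takes a :class:`RunConfig` (usually parsed from YAML), writes
its tables and fit summaries under ``outdir``, and returns the in-memory
results.  Given the same config and seed the written CSV/JSON files are
byte-identical across reruns.

Config layout (all sections optional; missing values fall back to the
simulation defaults)::

    seed: 1
    outdir: runs/demo
    pads:
      simulate: {n_cells: 100, total_pad_area: 16.0, count_law: [6, 16], ...}
      treated_simulate: {n_cells: 100, count_law: [14, 30], ...}   # optional
      images: [field1.tif, ...]          # alternative to simulate
      px_per_um: 8.0                     # for images without metadata
      save_images: false
      quant: {min_pad_area_um2: 0.2, gate_window: 0.25, ...}
    ao:
      control: {n_cells: 300, control_rg: 1.2, noise_sd: 0.15}
      time_points:
        - {label: HRG20, shift_factor: 1.16}
        - {label: HRG60, shift_factor: 1.49}
    qpcr:
      simulate: {genes: {HS3-9: {HRG20: 0.8, HRG60: 1.5}}, replicates: 4, ...}
      table: ct.csv                      # alternative to simulate
      targets: [HS3-9]
      ref: GAPDH                         # or [GAPDH, B2M]
      control_sample: ST
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import ao as ao_mod
from . import io as pio
from . import qpcr as qpcr_mod
from . import scaling
from .quantify import QuantConfig, gate_cells, quantify_field
from .stats import GroupSummary, bh_adjust, welch_t
from .synthetic import (
    PopulationParams,
    QPCRSimParams,
    simulate_ao_population,
    simulate_population,
    simulate_qpcr_plate,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parsed run configuration; see the module docstring for the layout."""

    seed: int = 0
    outdir: Path = Path("padcyto_run")
    pads: dict = field(default_factory=dict)
    ao: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def resolved_outdir(self) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def setup_run_logging(outdir: Path, level: str = "INFO") -> logging.Handler:
    """Attach a per-run log file capturing dropped-object counts and warnings."""
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("padcyto")
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def _population_params(spec: dict, seed: int) -> PopulationParams:
    spec = dict(spec or {})
    if "count_law" in spec and isinstance(spec["count_law"], list):
        spec["count_law"] = tuple(spec["count_law"])
    spec.setdefault("seed", seed)
    return PopulationParams(**spec)


def _quant_config(spec: dict) -> QuantConfig:
    spec = dict(spec or {})
    for key in ("pad_threshold", "foci_threshold"):
        if key in spec and isinstance(spec[key], list):
            spec[key] = tuple(spec[key])
    return QuantConfig(**spec)


def _load_fields(cfg: dict) -> list:
    images = []
    for p in cfg.get("images", []):
        try:
            images.append(pio.read_field(p, px_per_um=cfg.get("px_per_um")))
        except (OSError, ValueError) as exc:
            logger.error("run_pads: skipping unreadable image %s (%s)", p, exc)
    return images


def _quantify_cohort(images, qconfig: QuantConfig, cohort: str):
    nuclei, pads, summaries = [], [], []
    offset = 0
    for img in images:
        nuc, pad, summ = quantify_field(img, qconfig)
        for n in nuc:
            n.nucleus_id += offset
        for p in pad:
            p.nucleus_id += offset
        for s in summ:
            s.nucleus_id += offset
        offset += len(nuc)
        nuclei.extend(nuc)
        pads.extend(pad)
        summaries.extend(summ)
    if not nuclei:
        raise RuntimeError(f"run_pads: zero segmented cells in the {cohort} cohort")
    report = gate_cells(
        nuclei,
        pad_summaries={s.nucleus_id: s for s in summaries},
    )
    for n, s in zip(nuclei, summaries):
        s.gate = n.gate
    return nuclei, pads, summaries, report


def _cells_frame(nuclei, summaries, cohort: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cohort": cohort,
            "field_id": [n.field_id for n in nuclei],
            "nucleus_id": [n.nucleus_id for n in nuclei],
            "nucleus_area_um2": [n.area_um2 for n in nuclei],
            "dapi_ifi": [n.dapi_ifi for n in nuclei],
            "gate": [n.gate for n in nuclei],
            "n_pads": [s.n_pads for s in summaries],
            "mean_pad_area_um2": [s.mean_area_um2 for s in summaries],
            "total_pad_area_um2": [s.total_area_um2 for s in summaries],
            "sqrt_mean_area_um": [s.sqrt_mean_area for s in summaries],
            "heterogeneity": [s.heterogeneity for s in summaries],
        }
    )


def _fit_or_none(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (ValueError, RuntimeError) as exc:
        logger.warning("fit skipped: %s", exc)
        return None


def run_pads(config: RunConfig) -> dict:
    """Chromocenter pipeline: segment, gate, count, summarise, fit, compare."""
    outdir = config.resolved_outdir()
    cfg = config.pads or {}
    qconfig = _quant_config(cfg.get("quant", {}))

    if "images" in cfg:
        images = _load_fields(cfg)
    else:
        params = _population_params(cfg.get("simulate", {}), config.seed)
        images, truth = simulate_population(params)
        pio.write_ground_truth(truth, outdir, stem="pads_truth")
        pio.write_params_yaml(params, outdir / "pads_params.yaml")
        if cfg.get("save_images"):
            img_dir = outdir / "fields"
            img_dir.mkdir(exist_ok=True)
            for img in images:
                pio.write_field_tiff(img, img_dir / f"{img.field_id}.tif")

    nuclei, pads, summaries, gate_report = _quantify_cohort(images, qconfig, "control")
    cells = _cells_frame(nuclei, summaries, "control")

    pads_frame = pd.DataFrame(
        {
            "nucleus_id": [p.nucleus_id for p in pads],
            "pad_id": [p.pad_id for p in pads],
            "area_px": [p.area_px for p in pads],
            "area_um2": [p.area_um2 for p in pads],
            "centromere_count": [p.centromere_count for p in pads],
        }
    )

    valid = [s for s in summaries if s.valid_for_fits]
    fits = {
        "reciprocal_sqrt": _fit_or_none(scaling.fit_reciprocal_sqrt, summaries),
        "count_vs_mean_area_power": _fit_or_none(
            scaling.fit_power_law,
            np.array([s.mean_area_um2 for s in valid]),
            np.array([s.n_pads for s in valid], dtype=float),
        ),
        "individual_size_exponential": _fit_or_none(
            scaling.fit_exponential, [p.area_um2 for p in pads]
        ),
    }
    clustering = _fit_or_none(scaling.fit_centromere_clustering, pads)
    if clustering is not None:
        fits["centromere_linear"], fits["centromere_exponential"] = clustering

    result: dict[str, Any] = {
        "cells": cells,
        "pads": pads_frame,
        "gate_report": gate_report,
        "fits": fits,
    }

    if "treated_simulate" in cfg:
        tparams = _population_params(cfg["treated_simulate"], config.seed + 1)
        timages, ttruth = simulate_population(tparams)
        pio.write_ground_truth(ttruth, outdir, stem="pads_truth_treated")
        tnuclei, tpads, tsummaries, _ = _quantify_cohort(timages, qconfig, "treated")
        tcells = _cells_frame(tnuclei, tsummaries, "treated")
        cells = pd.concat([cells, tcells], ignore_index=True)
        result["cells"] = cells
        result["comparison"] = scaling.compare_conditions(summaries, tsummaries)

    cells.to_csv(outdir / "pads_cells.csv", index=False)
    pads_frame.to_csv(outdir / "pads_individual.csv", index=False)
    summary_json = {
        "gate": {
            "mode_ifi": gate_report.mode_ifi,
            "fractions": gate_report.fractions,
            "n_cells": gate_report.n_cells,
        },
        "fits": {k: (v.to_dict() if v is not None else None) for k, v in fits.items()},
    }
    if "comparison" in result:
        summary_json["comparison"] = result["comparison"].to_dict()
    (outdir / "pads_summary.json").write_text(json.dumps(summary_json, indent=1))
    return result


def run_ao(config: RunConfig) -> dict:
    """AO pipeline: per-cell R/G, control normalisation, shift table."""
    outdir = config.resolved_outdir()
    cfg = config.ao or {}
    control_spec = dict(cfg.get("control", {}))
    control_spec.setdefault("n_cells", 300)
    control_spec.setdefault("control_rg", 1.2)
    control_spec.setdefault("noise_sd", 0.15)
    time_points = cfg.get(
        "time_points",
        [{"label": "HRG20", "shift_factor": 1.16}, {"label": "HRG60", "shift_factor": 1.49}],
    )

    control_images, _ = simulate_ao_population(
        n_cells=int(control_spec["n_cells"]),
        control_rg=float(control_spec["control_rg"]),
        shift_factor=1.0,
        noise_sd=float(control_spec["noise_sd"]),
        seed=config.seed,
    )
    control_meas = ao_mod.measure_population(control_images)

    groups: dict[str, np.ndarray] = {}
    rows = []
    pop0 = ao_mod.normalize_population([], control_meas)
    groups["ST"] = pop0.control_norm
    for m in control_meas:
        rows.append(("ST", m.nucleus_id, m.ifi_red, m.ifi_green, m.rg_raw, m.rg_norm))
    for i, tp in enumerate(time_points):
        images, _ = simulate_ao_population(
            n_cells=int(tp.get("n_cells", control_spec["n_cells"])),
            control_rg=float(control_spec["control_rg"]),
            shift_factor=float(tp["shift_factor"]),
            noise_sd=float(tp.get("noise_sd", control_spec["noise_sd"])),
            seed=config.seed + 101 + i,
        )
        meas = ao_mod.measure_population(images)
        pop = ao_mod.normalize_population(meas, control_meas)
        groups[str(tp["label"])] = pop.treated_norm
        for m in meas:
            rows.append((tp["label"], m.nucleus_id, m.ifi_red, m.ifi_green,
                         m.rg_raw, m.rg_norm))

    per_cell = pd.DataFrame(
        rows, columns=["group", "nucleus_id", "ifi_red", "ifi_green", "rg_raw", "rg_norm"]
    )
    labels = list(groups)
    comparisons = [("ST", lab) for lab in labels if lab != "ST"]
    comparisons += [
        (labels[i], labels[i + 1]) for i in range(1, len(labels) - 1)
    ]
    tests = [
        ao_mod.shift_test(groups[a], groups[b], label=f"{a} vs {b}")
        for a, b in comparisons
    ]
    if tests:
        for t, q in zip(tests, bh_adjust([t.p_raw for t in tests])):
            t.p_adjusted = float(q)

    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [groups[g].size for g in labels],
            "rg_mean_norm": [float(groups[g].mean()) for g in labels],
            "rg_sd_norm": [float(groups[g].std(ddof=1)) for g in labels],
        }
    )
    bimodal = {g: ao_mod.detect_bimodality(groups[g]) for g in labels}

    per_cell.to_csv(outdir / "ao_cells.csv", index=False)
    summary.to_csv(outdir / "ao_summary.csv", index=False)
    (outdir / "ao_tests.json").write_text(
        json.dumps(
            {
                "tests": [
                    {
                        "comparison": t.comparison,
                        "t": t.statistic,
                        "df": t.df,
                        "p_raw": t.p_raw,
                        "p_adjusted": t.p_adjusted,
                    }
                    for t in tests
                ],
                "bimodality": bimodal,
            },
            indent=1,
        )
    )
    return {"per_cell": per_cell, "summary": summary, "tests": tests,
            "bimodality": bimodal}


def run_qpcr(config: RunConfig) -> dict:
    """qPCR pipeline: CT table -> RQ per target, reference stability, biphasic report."""
    outdir = config.resolved_outdir()
    cfg = config.qpcr or {}
    control_sample = cfg.get("control_sample", "ST")
    ref = cfg.get("ref", "GAPDH")
    if isinstance(ref, list):
        ref = tuple(ref)

    if "table" in cfg:
        table = pio.read_ct_table(cfg["table"])
        targets = cfg.get("targets")
        if not targets:
            ref_set = {ref} if isinstance(ref, str) else set(ref)
            targets = [g for g in table["gene"].unique() if g not in ref_set]
    else:
        sim = dict(cfg.get("simulate", {}))
        sim.setdefault(
            "genes",
            {
                "HS3-9": {"HRG20": 0.8, "HRG60": 1.5},
                "HS3-1": {"HRG20": 0.8, "HRG60": 1.5},
            },
        )
        sim.setdefault("seed", config.seed)
        sim.setdefault("control_sample", control_sample)
        params = QPCRSimParams(**sim)
        table, truth = simulate_qpcr_plate(params)
        table.to_csv(outdir / "qpcr_ct.csv", index=False)
        (outdir / "qpcr_truth.json").write_text(json.dumps(truth.fold_changes, indent=1))
        targets = cfg.get("targets", list(params.genes))
        if isinstance(ref, str) and ref not in set(table["gene"]):
            ref = list(params.ref_genes)[0]
        if cfg.get("ref_candidates") is None and len(params.ref_genes) >= 2:
            cfg = {**cfg, "ref_candidates": list(params.ref_genes)}

    rq_frames = [
        qpcr_mod.rq(table, target, ref, control_sample) for target in targets
    ]
    rq_table = pd.concat(rq_frames, ignore_index=True)

    ref_candidates = cfg.get("ref_candidates")
    if ref_candidates is None:
        ref_candidates = list(ref) if not isinstance(ref, str) else None
    stability = (
        qpcr_mod.genorm_m(table, ref_candidates) if ref_candidates else None
    )

    biphasic = None
    if cfg.get("biphasic", True) and rq_table["sample"].nunique() >= 2:
        biphasic = qpcr_mod.normalize_biphasic_report(rq_table)
        biphasic.to_csv(outdir / "qpcr_biphasic.csv", index=False)

    rq_table.to_csv(outdir / "qpcr_rq.csv", index=False)
    if stability is not None:
        stability.to_frame().to_csv(outdir / "qpcr_genorm_m.csv")
    return {"ct_table": table, "rq": rq_table, "genorm_m": stability,
            "biphasic": biphasic}


def run_report(config: RunConfig) -> dict:
    """Run all three pipelines and write a combined summary JSON."""
    outdir = config.resolved_outdir()
    results = {
        "pads": run_pads(config),
        "ao": run_ao(config),
        "qpcr": run_qpcr(config),
    }
    combined = {
        "pads_fits": {
            k: (v.to_dict() if v is not None else None)
            for k, v in results["pads"]["fits"].items()
        },
        "gate_fractions": results["pads"]["gate_report"].fractions,
        "ao_groups": results["ao"]["summary"].to_dict(orient="records"),
        "qpcr_rq": results["qpcr"]["rq"].to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(combined, indent=1))
    return results
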