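"""File I/O: multi-channel TIFF/PNG fields, ground-truth sidecars, CT tables."""
from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import GroundTruth, NucleusImage

CHANNEL_ORDER = ("blue", "red", "green")


def write_field_tiff(image: NucleusImage, path: str | Path) -> Path:
    """Write a field as a 16-bit multi-page TIFF (page order blue, red, green).

    Missing channels are written as zero pages so the page order stays
    fixed; the channel order and pixel calibration are recorded in the
    image description.  Intensities are clipped to [0, 65535] and rounded.
    """
    path = Path(path)
    shape = image.shape
    pages = []
    present = []
    for name in CHANNEL_ORDER:
        ch = getattr(image, name)
        if ch is None:
            pages.append(np.zeros(shape, dtype=np.uint16))
        else:
            pages.append(np.clip(np.round(ch), 0, 65535).astype(np.uint16))
            present.append(name)
    meta = {
        "channel_order": list(CHANNEL_ORDER),
        "channels_present": present,
        "px_per_um": image.px_per_um,
        "field_id": image.field_id,
    }
    tifffile.imwrite(
        path,
        np.stack(pages),
        description=json.dumps(meta),
        software="padcyto",
        photometric="minisblack",
    )
    return path


def read_field(
    path: str | Path,
    px_per_um: Optional[float] = None,
    channel_roles: Optional[dict[str, int]] = None,
) -> NucleusImage:
    """Read a field from TIFF or PNG.

    TIFFs written by :func:`write_field_tiff` carry their own metadata;
    other files need ``px_per_um`` and, for multi-page/multi-channel data,
    a ``channel_roles`` map of role -> page index (roles: blue/red/green,
    or the AO aliases ao_red/ao_green which map onto red/green).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        meta = None
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = None
        if meta and "channel_order" in meta:
            present = set(meta.get("channels_present", CHANNEL_ORDER))
            channels = {
                name: arr[i].astype(float) if name in present else None
                for i, name in enumerate(meta["channel_order"])
            }
            return NucleusImage(
                blue=channels.get("blue"),
                red=channels.get("red"),
                green=channels.get("green"),
                px_per_um=float(meta["px_per_um"]),
                field_id=str(meta.get("field_id", path.stem)),
            )
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) PNG
            arr = np.moveaxis(arr[..., :3], -1, 0)[[2, 0, 1]]  # to blue,red,green
            channel_roles = channel_roles or {"blue": 0, "red": 1, "green": 2}
    if px_per_um is None:
        raise ValueError(f"{path}: px_per_um required for files without metadata")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    roles = channel_roles or {name: i for i, name in enumerate(CHANNEL_ORDER[: len(arr)])}
    alias = {"ao_red": "red", "ao_green": "green", "dapi": "blue",
             "h3k9me3": "red", "cenpa_or_h3k4me3": "green"}
    picked: dict[str, Optional[np.ndarray]] = {"blue": None, "red": None, "green": None}
    for role, idx in roles.items():
        picked[alias.get(role, role)] = arr[idx]
    return NucleusImage(
        blue=picked["blue"], red=picked["red"], green=picked["green"],
        px_per_um=float(px_per_um), field_id=path.stem,
    )


def write_ground_truth(truth: GroundTruth, outdir: str | Path, stem: str = "truth") -> tuple[Path, Path]:
    """Write ground truth as a per-cell CSV plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    json_path = outdir / f"{stem}.json"
    frame = truth.to_frame()
    frame.to_csv(csv_path, index=False)
    sidecar = {
        "n_cells": len(truth.cells),
        "clipped_pixels": truth.clipped_pixels,
        "fold_changes": truth.fold_changes,
        "ao_rg": truth.ao_rg.tolist() if truth.ao_rg is not None else None,
        "pad_areas_um2": [c.pad_areas_um2.tolist() for c in truth.cells],
        "centromere_counts": [c.centromere_counts.tolist() for c in truth.cells],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def write_params_yaml(params, path: str | Path) -> Path:
    """Dump a parameter dataclass (or dict) as YAML."""
    path = Path(path)
    payload = asdict(params) if is_dataclass(params) else dict(params)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a CT table CSV with columns sample,gene,replicate,ct."""
    table = pd.read_csv(path)
    missing = [c for c in ("sample", "gene", "replicate", "ct") if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: CT table lacks column(s) {missing}")
    return table


def read_group_summaries(path: str | Path):
    """Read group summaries (label,mean,sd,n) into GroupSummary objects."""
    from .stats import GroupSummary

    frame = pd.read_csv(path)
    missing = [c for c in ("label", "mean", "sd", "n") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: summary table lacks column(s) {missing}")
    return [
        GroupSummary(label=str(r.label), mean=float(r.mean), sd=float(r.sd), n=int(r.n))
        for r in frame.itertuples()
    ]
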