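"""File formats: multi-page TIFF stacks with voxel-size sidecars, GMT gene
sets, expression/annotation TSVs, truth and manifest JSON.

Images are written as one 16-bit multi-page TIFF per nucleus per channel
with the physical voxel size in a JSON sidecar next to the TIFF, avoiding
any proprietary metadata dialect.  All tables use '.' decimals and UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic_microscopy import CHANNELS, GroundTruthTable, VoxelGrid

__all__ = [
    "GmtParseError",
    "save_stack",
    "load_stack",
    "save_dataset",
    "load_dataset",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_classes",
    "write_classes",
    "read_gene_map",
    "write_gene_map",
]


class GmtParseError(ValueError):
    """A malformed GMT line (fewer than 3 tab-separated fields)."""


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def save_stack(grid: VoxelGrid, path) -> None:
    """Write a stack as 16-bit multi-page TIFF plus a JSON voxel-size sidecar."""
    path = Path(path)
    data = np.clip(np.rint(grid.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "voxel_size_um": list(grid.voxel_size),
        "channel": grid.channel,
        "axes": "ZYX",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def load_stack(path) -> VoxelGrid:
    """Read a TIFF stack and its voxel-size sidecar back into a VoxelGrid."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return VoxelGrid(
        data.astype(np.float32),
        tuple(meta["voxel_size_um"]),
        channel=meta.get("channel", ""),
    )


def save_dataset(stacks, truth: GroundTruthTable, config, outdir) -> list[Path]:
    """Write a generated dataset: per-nucleus TIFFs, truth.json, dataset.yaml.

    Returns the list of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, channels in enumerate(stacks):
        nucdir = outdir / f"nucleus_{i:04d}"
        nucdir.mkdir(exist_ok=True)
        for ch, grid in channels.items():
            p = nucdir / f"{ch}.tif"
            save_stack(grid, p)
            written += [p, p.with_suffix(".json")]
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), sort_keys=True))
    written.append(truth_path)
    cfg_path = outdir / "dataset.yaml"
    cfg_path.write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))
    written.append(cfg_path)
    return written


def _config_to_dict(config) -> dict:
    import dataclasses

    if dataclasses.is_dataclass(config):
        d = dataclasses.asdict(config)
    else:
        d = dict(config)
    return {
        k: list(v) if isinstance(v, tuple) else v for k, v in d.items()
    }


def load_dataset(outdir):
    """Read back a dataset directory written by :func:`save_dataset`.

    Returns (stacks, truth) in the same structure as
    :func:`nucleoscape.synthetic_microscopy.generate_nuclei_dataset`.
    """
    outdir = Path(outdir)
    truth = GroundTruthTable.from_dict(json.loads((outdir / "truth.json").read_text()))
    stacks = []
    for nucdir in sorted(outdir.glob("nucleus_*")):
        channels = {}
        for ch in CHANNELS:
            p = nucdir / f"{ch}.tif"
            if p.exists():
                channels[ch] = load_stack(p)
        stacks.append(channels)
    return stacks, truth


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into (name, description, genes) triples.

    Raises :class:`GmtParseError` naming the offending line when a line has
    fewer than three tab-separated fields.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            sets.append((name, desc, genes))
    return sets


def write_gmt(sets, path) -> None:
    """Write (name, description, genes) triples as a GMT file."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_classes(classes: pd.Series, path) -> None:
    classes.rename("class").to_csv(path, sep="\t", index_label="sample")


def read_classes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return df["class"]


def write_gene_map(mapping: pd.Series, path, value_name: str = "value") -> None:
    mapping.rename(value_name).to_csv(path, sep="\t", index_label="gene")


def read_gene_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return df[df.columns[0]]
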