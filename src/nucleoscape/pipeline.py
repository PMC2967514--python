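"""End-to-end orchestration: simulate -> quantify -> radial/compare and
simulate-expression -> enrich, with one root seed feeding every stage.

Each stage draws its seed from the root seed and its own name (a CRC32
substream key), so adding or reordering stages never perturbs another
stage's random draws.  A manifest records every stage's parameters, seed
and outputs; reruns with the same config are bit-identical for
deterministic stages.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .geneset_permutation import (
    chromosome_ratio,
    gene_de_test,
    go_enrichment,
    heatmap_table,
    permutation_heat_value,
)
from .nuclear_architecture_stats import (
    OutsideNucleus,
    compare_counts,
    compare_means,
    radial_fraction,
    shell_histogram,
    shell_index,
)
from .object_quantification import (
    NoNucleusFound,
    detect_objects,
    nuclei_to_frame,
    objects_to_frame,
    segment_nuclei,
)
from .synthetic_expression import PlantedSet, generate_expression
from .synthetic_microscopy import GenerationConfig, generate_nuclei_dataset

__all__ = [
    "RunConfig",
    "StageError",
    "stage_seed",
    "quantify_stacks",
    "radial_stacks",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def stage_seed(root_seed: int, stage_name: str) -> int:
    """Deterministic per-stage seed derived from the root seed and stage name."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage_name.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class RunConfig:
    """A validated pipeline run: ordered stages, root seed, output directory."""

    stages: list = field(default_factory=list)
    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            stages=d.get("stages", []),
            seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", ".")),
            log_level=str(d.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for st in self.stages:
            name = st.get("stage")
            if name not in _STAGES:
                raise ValueError(
                    f"unknown stage {name!r}; available: {sorted(_STAGES)}"
                )


# ---------------------------------------------------------------------------
# in-memory pipeline cores (shared by stages, CLI and tests)
# ---------------------------------------------------------------------------

def quantify_stacks(
    stacks,
    channels=("centromere",),
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_size: int = 8,
    min_nuclear_volume: float = 50.0,
):
    """Segment nuclei and detect objects across a list of per-nucleus stacks.

    Returns (objects, nuclei) DataFrames with globally unique nucleus ids.
    Fields in which no nucleus is found are skipped with a log message.
    """
    obj_frames, nuc_frames = [], []
    next_id = 0
    for i, channel_dict in enumerate(stacks):
        try:
            masks = segment_nuclei(channel_dict["dapi"], min_nuclear_volume)
        except NoNucleusFound:
            log.warning("field %d: no nucleus found", i)
            continue
        for mask in masks:
            mask.nucleus_id = next_id
            objs = []
            for ch in channels:
                objs.extend(
                    detect_objects(
                        channel_dict[ch],
                        mask,
                        threshold_method=threshold_method,
                        threshold_value=threshold_value,
                        min_size=min_size,
                    )
                )
            of = objects_to_frame(objs)
            of["field"] = i
            obj_frames.append(of)
            nf = nuclei_to_frame([mask])
            nf["field"] = i
            nuc_frames.append(nf)
            next_id += 1
    objects = (
        pd.concat(obj_frames, ignore_index=True) if obj_frames else objects_to_frame([])
    )
    nuclei = (
        pd.concat(nuc_frames, ignore_index=True) if nuc_frames else nuclei_to_frame([])
    )
    return objects, nuclei


def radial_stacks(
    stacks,
    channel: str = "locus",
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_size: int = 8,
    min_nuclear_volume: float = 50.0,
):
    """Measure normalized radial positions of signals across stacks.

    Segments each field's nuclei, detects signals in ``channel`` and casts a
    ray through each signal's centre of mass.  Returns a DataFrame with one
    row per accepted signal (nucleus id, signal id, fraction, shell) and the
    count of signals rejected because their centre fell outside the mask.
    """
    rows = []
    rejected = 0
    next_id = 0
    for i, channel_dict in enumerate(stacks):
        try:
            masks = segment_nuclei(channel_dict["dapi"], min_nuclear_volume)
        except NoNucleusFound:
            continue
        for mask in masks:
            mask.nucleus_id = next_id
            objs = detect_objects(
                channel_dict[channel],
                mask,
                threshold_method=threshold_method,
                threshold_value=threshold_value,
                min_size=min_size,
            )
            for o in objs:
                try:
                    f = radial_fraction(o.center_um, mask)
                except OutsideNucleus:
                    rejected += 1
                    continue
                rows.append(
                    {
                        "nucleus_id": next_id,
                        "signal_id": o.object_id,
                        "fraction": f,
                        "shell": shell_index(f),
                        "field": i,
                    }
                )
            next_id += 1
    radial = pd.DataFrame(
        rows, columns=["nucleus_id", "signal_id", "fraction", "shell", "field"]
    )
    return radial, rejected


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate_images(params: dict, seed: int, outdir: Path) -> list[str]:
    params = dict(params)
    sub = params.pop("out", "images")
    params.setdefault("seed", seed)
    # YAML lists -> tuples for law/geometry fields
    for key in (
        "nucleus_semiaxes", "voxel_size", "chromocenter_count_law",
        "chromocenter_volume_law", "focus_channel_offset", "locus_radial_law",
        "psf_sigma", "noise_model",
    ):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    config = GenerationConfig(**params)
    stacks, truth = generate_nuclei_dataset(config)
    written = nio.save_dataset(stacks, truth, config, outdir / sub)
    return [str(p.relative_to(outdir)) for p in written]


def _stage_quantify(params: dict, seed: int, outdir: Path) -> list[str]:
    images = outdir / params.get("images", "images")
    stacks, _truth = nio.load_dataset(images)
    channels = params.get("channels", ["centromere"])
    if isinstance(channels, str):
        channels = [channels]
    objects, nuclei = quantify_stacks(
        stacks,
        channels=channels,
        threshold_method=params.get("threshold_method", "otsu"),
        threshold_value=params.get("threshold_value"),
        min_size=int(params.get("min_size", 8)),
        min_nuclear_volume=float(params.get("min_nuclear_volume", 50.0)),
    )
    if "condition" in params:
        objects["condition"] = params["condition"]
        nuclei["condition"] = params["condition"]
    obj_path = outdir / params.get("objects_out", "objects.csv")
    nuc_path = outdir / params.get("nuclei_out", "nuclei.csv")
    objects.to_csv(obj_path, index=False)
    nuclei.to_csv(nuc_path, index=False)
    return [str(obj_path.relative_to(outdir)), str(nuc_path.relative_to(outdir))]


def _stage_radial(params: dict, seed: int, outdir: Path) -> list[str]:
    images = outdir / params.get("images", "images")
    stacks, _truth = nio.load_dataset(images)
    radial, rejected = radial_stacks(
        stacks,
        channel=params.get("channel", "locus"),
        threshold_method=params.get("threshold_method", "otsu"),
        threshold_value=params.get("threshold_value"),
        min_size=int(params.get("min_size", 8)),
    )
    if rejected:
        log.warning("%d signals rejected (outside nucleus mask)", rejected)
    if "condition" in params:
        radial["condition"] = params["condition"]
    out = outdir / params.get("out", "radial.csv")
    radial.to_csv(out, index=False)
    counts, cumulative = shell_histogram(radial["fraction"].to_numpy())
    hist_path = outdir / params.get("histogram_out", "shell_histogram.csv")
    pd.DataFrame(
        {
            "shell": [1, 2, 3, 4, 5],
            "lower_edge": [0.0, 0.2, 0.4, 0.6, 0.8],
            "count": counts,
        }
    ).to_csv(hist_path, index=False)
    cum_path = outdir / params.get("cumulative_out", "cumulative.csv")
    cumulative.to_csv(cum_path, index=False)
    return [str(p.relative_to(outdir)) for p in (out, hist_path, cum_path)]


def _stage_compare(params: dict, seed: int, outdir: Path) -> list[str]:
    objects = pd.read_csv(outdir / params.get("objects", "objects.csv"))
    nuclei = pd.read_csv(outdir / params.get("nuclei", "nuclei.csv"))
    cond_a, cond_b = params["a"], params["b"]
    metric = params.get("metric", "volume")
    oa = objects[objects["condition"] == cond_a]
    ob = objects[objects["condition"] == cond_b]
    na = nuclei[nuclei["condition"] == cond_a]
    nb = nuclei[nuclei["condition"] == cond_b]
    if metric == "count":
        ca = oa.groupby("nucleus_id").size().reindex(na["nucleus_id"], fill_value=0)
        cb = ob.groupby("nucleus_id").size().reindex(nb["nucleus_id"], fill_value=0)
        stat, p = compare_counts(ca.to_numpy(), cb.to_numpy())
        test = "pooled-rate z"
    elif metric in ("volume", "intensity"):
        col = "volume_um3" if metric == "volume" else "mean_intensity"
        stat, p = compare_means(oa[col].to_numpy(), ob[col].to_numpy())
        test = "welch t"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = outdir / params.get("out", "stats.json")
    out.write_text(
        json.dumps(
            {"a": cond_a, "b": cond_b, "metric": metric, "test": test,
             "statistic": stat, "p_value": p},
            sort_keys=True,
        )
    )
    return [str(out.relative_to(outdir))]


def _stage_simulate_expression(params: dict, seed: int, outdir: Path) -> list[str]:
    params = dict(params)
    sub = outdir / params.pop("out", "expression")
    sub.mkdir(parents=True, exist_ok=True)
    sets = tuple(
        PlantedSet(**s) if isinstance(s, dict) else PlantedSet(*s)
        for s in params.pop("sets", [])
    )
    params.setdefault("seed", seed)
    matrix, truth, gmt_sets = generate_expression(sets=sets, **params)
    nio.write_expression(matrix.values, sub / "expr.tsv")
    nio.write_classes(matrix.classes, sub / "classes.tsv")
    nio.write_gene_map(matrix.gene2chrom, sub / "gene2chrom.tsv", "chromosome")
    nio.write_gmt(gmt_sets, sub / "sets.gmt")
    (sub / "truth.json").write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "sets": truth.sets.to_dict(orient="list"),
                "genes": truth.genes.to_dict(orient="list"),
            },
            sort_keys=True,
        )
    )
    return [
        str((sub / f).relative_to(outdir))
        for f in ("expr.tsv", "classes.tsv", "gene2chrom.tsv", "sets.gmt", "truth.json")
    ]


def _stage_enrich(params: dict, seed: int, outdir: Path) -> list[str]:
    from .synthetic_expression import ExpressionMatrix

    expr_dir = outdir / params.get("expression", "expression")
    values = nio.read_expression(expr_dir / "expr.tsv")
    classes = nio.read_classes(expr_dir / "classes.tsv")
    gene2chrom = nio.read_gene_map(expr_dir / "gene2chrom.tsv")
    matrix = ExpressionMatrix(values=values, classes=classes, gene2chrom=gene2chrom)
    sets = nio.read_gmt(expr_dir / params.get("sets", "sets.gmt"))
    klasses = params.get("classes") or sorted(classes.unique())
    n_perm = int(params.get("n_permutations", 10000))
    results = []
    for name, _desc, genes in sets:
        for kl in klasses:
            results.append(
                permutation_heat_value(
                    matrix, genes, kl, n_permutations=n_perm,
                    seed=stage_seed(seed, f"enrich:{name}:{kl}"), set_name=name,
                )
            )
    perm_path = outdir / params.get("permutation_out", "permutation.tsv")
    pd.DataFrame(
        [
            {
                "set": r.set_name, "class": r.klass, "score": r.observed_score,
                "N": r.n_permutations, "n_up": r.n_up, "n_down": r.n_down,
                "heat_value": r.heat_value, "exhaustive": r.exhaustive,
                "significant": r.significant,
            }
            for r in results
        ]
    ).to_csv(perm_path, sep="\t", index=False)
    values_t, _sig = heatmap_table(results)
    heat_path = outdir / params.get("heatmap_out", "heatmap.tsv")
    values_t.to_csv(heat_path, sep="\t")
    written = [perm_path, heat_path]

    de_classes = params.get("de_classes")
    if de_classes:
        table, de_genes = gene_de_test(matrix, de_classes[0], de_classes[1])
        de_path = outdir / params.get("de_out", "de.tsv")
        table.to_csv(de_path, sep="\t")
        written.append(de_path)
        ratios, unmapped = chromosome_ratio(de_genes, matrix.gene2chrom)
        ratio_path = outdir / params.get("chrom_ratio_out", "chrom_ratio.tsv")
        ratios.to_csv(ratio_path, sep="\t")
        written.append(ratio_path)
        go_path = expr_dir / "gene2go.tsv"
        if go_path.exists():
            g2g = pd.read_csv(go_path, sep="\t")
            enr = go_enrichment(de_genes, list(matrix.genes), g2g)
            enr_path = outdir / params.get("enrichment_out", "enrichment.tsv")
            pd.DataFrame(
                [
                    {
                        "category": e.category, "n_array": e.category_size,
                        "n_degs": e.de_in_category, "p_raw": e.p_raw,
                        "p_holm": e.p_holm,
                    }
                    for e in enr
                ]
            ).to_csv(enr_path, sep="\t", index=False)
            written.append(enr_path)
    return [str(p.relative_to(outdir)) for p in written]


_STAGES = {
    "simulate-images": _stage_simulate_images,
    "quantify": _stage_quantify,
    "radial": _stage_radial,
    "compare": _stage_compare,
    "simulate-expression": _stage_simulate_expression,
    "enrich": _stage_enrich,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order and write a manifest.

    Returns the manifest dict.  A stage failure raises :class:`StageError`
    after writing the partial manifest, preserving earlier outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}
    manifest_path = outdir / "manifest.json"
    for st in config.stages:
        st = dict(st)
        name = st.pop("stage")
        seed = stage_seed(config.seed, name)
        try:
            outputs = _STAGES[name](st, seed, outdir)
        except Exception as exc:
            manifest["stages"].append(
                {"stage": name, "seed": seed, "params": st, "error": str(exc)}
            )
            manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"stage": name, "seed": seed, "params": st, "outputs": sorted(outputs)}
        )
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
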