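"""Synthetic expression matrices with planted gene-set regulation.

Emulates the downstream product of an RMA-normalized three-condition
microarray experiment — untreated control, integrin-blocking antibody, and
HGF/SF1 stimulation, three replicates each — on the log2 scale.  Chosen gene
sets are shifted up or down by a known effect size in one condition so the
permutation and enrichment statistics can be validated against planted
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLASSES",
    "MOUSE_CHROMOSOMES",
    "PlantedSet",
    "ExpressionMatrix",
    "PlantedTruth",
    "generate_expression",
]

DEFAULT_CLASSES = ("control", "antibody", "hgf")

#: mouse autosomes + X, the karyotype of the emulated arrays
MOUSE_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX",)


@dataclass(frozen=True)
class PlantedSet:
    """One gene set with a planted regulation direction.

    ``direction`` is "up", "down" or "null"; ``delta`` is the log2 shift
    applied to member genes in class ``klass`` (ignored for null sets).
    """

    name: str
    size: int
    direction: str = "null"
    delta: float = 0.0
    klass: str = "antibody"


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with condition labels and annotation."""

    values: pd.DataFrame            # genes x samples
    classes: pd.Series              # sample id -> class label
    gene2chrom: pd.Series           # gene id -> chromosome
    gene2go: pd.DataFrame | None = None   # columns: gene, go

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not set(self.values.columns) == set(self.classes.index):
            raise ValueError("classes must label exactly the matrix samples")
        counts = self.classes.value_counts()
        if (counts < 2).any():
            raise ValueError("every class needs at least two samples")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def class_members(self, klass: str) -> list[str]:
        return list(self.classes.index[self.classes == klass])


@dataclass
class PlantedTruth:
    """Ground truth of the planted design."""

    sets: pd.DataFrame    # name, size, direction, delta, klass
    genes: pd.DataFrame   # gene, de_status (bool), shift, klass, set_name
    seed: int = 0
    extras: dict = field(default_factory=dict)


def generate_expression(
    n_genes: int = 10000,
    sets: tuple[PlantedSet, ...] = (),
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    class_labels: tuple[str, ...] = DEFAULT_CLASSES,
    chromosomes: tuple[str, ...] = MOUSE_CHROMOSOMES,
    chromosome_weights=None,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth, list]:
    """Generate a synthetic log2 expression matrix with planted gene sets.

    Baseline per-gene means are drawn once from N(baseline_mean, baseline_sd);
    each planted set's member genes are shifted by ±delta in the affected
    class; i.i.d. Gaussian noise of ``noise_sd`` is added per cell.
    Chromosome labels are assigned per gene from ``chromosomes`` with
    probabilities ``chromosome_weights`` (uniform when None).

    Returns
    -------
    (matrix, truth, gmt_sets) where ``gmt_sets`` is a list of
    ``(name, description, genes)`` triples ready for GMT writing.

    Raises
    ------
    ValueError
        If the regulated (up/down) sets cannot be planted on disjoint genes,
        a set exceeds the gene universe, or ``noise_sd`` is not positive.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_replicates < 2:
        raise ValueError("need at least two replicates per class")
    for s in sets:
        if s.size > n_genes:
            raise ValueError(f"set {s.name!r} larger than the gene universe")
        if s.direction not in ("up", "down", "null"):
            raise ValueError(f"set {s.name!r}: unknown direction {s.direction!r}")
        if s.klass not in class_labels:
            raise ValueError(f"set {s.name!r}: unknown class {s.klass!r}")

    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    samples = [f"{c}_{r + 1}" for c in class_labels for r in range(n_replicates)]
    classes = pd.Series(
        [c for c in class_labels for _ in range(n_replicates)],
        index=pd.Index(samples, name="sample"),
        name="class",
    )

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    shifts = np.zeros((n_genes, len(samples)))

    # non-null sets receive disjoint member genes (a gene cannot carry two
    # conflicting planted directions); null sets may overlap anything
    n_regulated = sum(s.size for s in sets if s.direction != "null")
    if n_regulated > n_genes:
        raise ValueError(
            "overlapping regulated sets are not representable: planted "
            f"up/down sets need {n_regulated} disjoint genes but the universe "
            f"has only {n_genes}"
        )
    pool = list(rng.permutation(n_genes))
    member_rows = []
    gmt_sets = []
    for s in sets:
        if s.direction == "null":
            members = rng.choice(n_genes, size=s.size, replace=False)
        else:
            members, pool = pool[: s.size], pool[s.size :]
        signed = {"up": 1.0, "down": -1.0, "null": 0.0}[s.direction]
        for g in members:
            member_rows.append(
                {
                    "gene": genes[g],
                    "de_status": s.direction != "null" and s.delta != 0,
                    "shift": signed * s.delta,
                    "klass": s.klass,
                    "set_name": s.name,
                }
            )
        if s.direction != "null" and s.delta != 0:
            cols = np.array([classes.iloc[j] == s.klass for j in range(len(samples))])
            shifts[np.ix_(members, cols)] += signed * s.delta
        gmt_sets.append((s.name, f"planted {s.direction} delta={s.delta}",
                         [genes[g] for g in members]))

    values = baseline[:, None] + shifts + rng.normal(0.0, noise_sd,
                                                     size=(n_genes, len(samples)))
    if chromosome_weights is None:
        probs = None
    else:
        w = np.asarray(chromosome_weights, dtype=float)
        probs = w / w.sum()
    chrom = rng.choice(len(chromosomes), size=n_genes, p=probs)
    gene2chrom = pd.Series(
        [chromosomes[i] for i in chrom], index=genes, name="chromosome"
    )

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        classes=classes,
        gene2chrom=gene2chrom,
    )
    truth = PlantedTruth(
        sets=pd.DataFrame(
            [
                {"name": s.name, "size": s.size, "direction": s.direction,
                 "delta": s.delta, "klass": s.klass}
                for s in sets
            ],
            columns=["name", "size", "direction", "delta", "klass"],
        ),
        genes=pd.DataFrame(
            member_rows, columns=["gene", "de_status", "shift", "klass", "set_name"]
        ),
        seed=seed,
    )
    return matrix, truth, gmt_sets
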