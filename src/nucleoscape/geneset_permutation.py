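"""Permutation gene-set statistics, chromosome DE density and GO enrichment.

The central statistic is the permutation heat-plot value for a gene set in a
one-class-versus-rest comparison.  The observed set score is the mean, over
set genes, of (mean expression in the tested class - mean expression in all
other classes).  Class-versus-rest membership is permuted N times (default
10000, or exhaustively when the number of distinct splits is smaller);
``n_up`` counts permuted scores at least as large as the observed one and
``n_down`` those at least as small, ties falling in both tails.  The
reported heat value is ``1 - n_up/N`` for up-regulated sets (near 1 means
significant up-regulation) and ``n_down/N`` for down-regulated sets (near 0
means significant down-regulation), so both directions share one [0, 1]
colour scale; values with 0.05 < p < 0.95 are conventionally flagged as not
significant.

Around it: a per-gene two-sample t test (a stand-in for a moderated array
fit, applied to an already-normalized matrix), the per-chromosome
ratio of differentially expressed genes to genes mapped to the chromosome,
and hypergeometric GO over-representation with Holm correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_expression import ExpressionMatrix

__all__ = [
    "EmptySetError",
    "PermutationResult",
    "EnrichmentResult",
    "gene_de_test",
    "chromosome_ratio",
    "set_score",
    "permutation_heat_value",
    "hypergeometric_pvalue",
    "go_enrichment",
    "heatmap_table",
]

log = logging.getLogger(__name__)

#: heat values in this open interval are flagged as not significant
SIGNIFICANCE_BAND = (0.05, 0.95)


class EmptySetError(ValueError):
    """None of a gene set's members are present in the expression matrix."""


@dataclass
class PermutationResult:
    """Permutation statistic for one (gene set, class) pair."""

    set_name: str
    klass: str
    observed_score: float
    n_permutations: int
    n_up: int
    n_down: int
    heat_value: float
    exhaustive: bool
    n_genes_used: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        lo, hi = SIGNIFICANCE_BAND
        return not (lo < self.heat_value < hi)


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of DE genes in one GO category."""

    category: str
    category_size: int      # genes of the category on the array ("# array")
    de_in_category: int     # DE genes in the category ("#DEGs")
    p_raw: float
    p_holm: float


# ---------------------------------------------------------------------------
# per-gene differential test
# ---------------------------------------------------------------------------

def gene_de_test(
    matrix: ExpressionMatrix,
    class_a: str,
    class_b: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene pooled two-sample t test between two classes.

    The pooled (equal-variance) form is used because with three replicates
    per class the Welch approximation is noticeably conservative, while the
    pooled test holds its nominal size under the homoscedastic noise these
    matrices carry.

    Returns a table with columns ``p``, ``t``, ``mean_diff`` (class_a minus
    class_b) and ``flagged`` (True for genes with zero within-class variance
    in both classes, whose p is set to 1), plus the list of genes with
    uncorrected p < ``alpha``.
    """
    sa = matrix.class_members(class_a)
    sb = matrix.class_members(class_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each class needs at least two samples")
    A = matrix.values[sa].to_numpy(float)
    B = matrix.values[sb].to_numpy(float)
    res = stats.ttest_ind(A, B, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    flagged = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    flagged |= np.isnan(p)
    if flagged.any():
        log.info("%d genes with zero within-class variance: p set to 1",
                 int(flagged.sum()))
    p[flagged] = 1.0
    t[np.isnan(t)] = 0.0
    table = pd.DataFrame(
        {
            "p": p,
            "t": t,
            "mean_diff": A.mean(axis=1) - B.mean(axis=1),
            "flagged": flagged,
        },
        index=matrix.genes,
    )
    de_genes = list(table.index[table["p"] < alpha])
    return table, de_genes


# ---------------------------------------------------------------------------
# chromosome DE density
# ---------------------------------------------------------------------------

def chromosome_ratio(
    de_genes, gene2chrom: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Ratio of DE genes to all mapped genes, per chromosome.

    Returns (table, unmapped) where the table has one row per chromosome with
    columns ``n_de``, ``n_total`` and ``ratio``; DE genes absent from the
    map are returned in ``unmapped`` rather than silently dropped.
    """
    de = pd.Index(de_genes)
    unmapped = list(de.difference(gene2chrom.index))
    mapped_de = de.intersection(gene2chrom.index)
    total = gene2chrom.value_counts()
    de_counts = gene2chrom.loc[mapped_de].value_counts()
    table = pd.DataFrame(
        {
            "n_de": de_counts.reindex(total.index, fill_value=0).astype(int),
            "n_total": total.astype(int),
        }
    )
    table["ratio"] = table["n_de"] / table["n_total"]
    table.index.name = "chromosome"
    return table.sort_index(), unmapped


# ---------------------------------------------------------------------------
# set score and permutation statistic
# ---------------------------------------------------------------------------

def _set_sample_means(matrix: ExpressionMatrix, gene_set) -> np.ndarray:
    present = [g for g in gene_set if g in matrix.genes]
    missing = len(list(gene_set)) - len(present)
    if not present:
        raise EmptySetError("no gene of the set is present in the matrix")
    if missing:
        log.info("%d set genes absent from the matrix were dropped", missing)
    return matrix.values.loc[present].to_numpy(float).mean(axis=0)


def set_score(matrix: ExpressionMatrix, gene_set, klass: str) -> float:
    """Observed class-versus-rest score of a gene set.

    Mean over set genes of (mean expression in ``klass`` - mean expression
    in all other classes), in log2 units.  Set genes absent from the matrix
    are dropped (logged); an entirely absent set raises :class:`EmptySetError`.
    """
    m = _set_sample_means(matrix, gene_set)
    in_class = (matrix.classes == klass).to_numpy()
    if in_class.sum() == 0 or (~in_class).sum() == 0:
        raise ValueError(f"class {klass!r} must leave samples on both sides")
    return float(m[in_class].mean() - m[~in_class].mean())


def permutation_heat_value(
    matrix: ExpressionMatrix,
    gene_set,
    klass: str,
    n_permutations: int = 10000,
    seed: int | None = 0,
    set_name: str = "",
    mode: str = "auto",
) -> PermutationResult:
    """Permutation heat-plot statistic for one gene set in one class.

    Class-versus-rest membership labels are permuted uniformly; when the
    number of distinct splits ``C(S, k)`` does not exceed ``n_permutations``
    the splits are enumerated exhaustively instead of sampled.  Ties between
    permuted and observed scores count in both tails.  The heat value is
    ``1 - n_up/N`` when the observed score is non-negative (up-regulation,
    values near 1 significant) and ``n_down/N`` otherwise (down-regulation,
    values near 0 significant).

    ``mode`` is "auto" (exhaustive when cheap), "exhaustive", or "sample"
    (force Monte-Carlo even when enumeration would be possible, e.g. to
    check sampling convergence against the exhaustive value).
    """
    present = [g for g in gene_set if g in matrix.genes]
    m = _set_sample_means(matrix, gene_set)
    in_class = (matrix.classes == klass).to_numpy()
    k = int(in_class.sum())
    S = len(m)
    if k < 2 or S - k < 2:
        raise ValueError("need at least two samples inside and outside the class")
    observed = float(m[in_class].mean() - m[~in_class].mean())

    total = m.sum()

    def scores_from_insums(in_sums: np.ndarray) -> np.ndarray:
        return in_sums / k - (total - in_sums) / (S - k)

    if mode not in ("auto", "exhaustive", "sample"):
        raise ValueError(f"unknown mode {mode!r}")
    n_splits = math.comb(S, k)
    if mode == "exhaustive" or (mode == "auto" and n_splits <= n_permutations):
        idx = np.fromiter(
            (i for combo in combinations(range(S), k) for i in combo),
            dtype=np.intp,
        ).reshape(n_splits, k)
        exhaustive = True
        N = n_splits
    else:
        rng = np.random.default_rng(seed)
        # uniform random k-subsets via argsort of i.i.d. uniforms
        idx = np.argsort(rng.random((n_permutations, S)), axis=1)[:, :k]
        exhaustive = False
        N = n_permutations
    perm_scores = scores_from_insums(m[idx].sum(axis=1))

    tol = 1e-9 * max(1.0, abs(observed))
    n_up = int(np.sum(perm_scores >= observed - tol))
    n_down = int(np.sum(perm_scores <= observed + tol))
    heat = 1.0 - n_up / N if observed >= 0 else n_down / N
    return PermutationResult(
        set_name=set_name,
        klass=klass,
        observed_score=observed,
        n_permutations=N,
        n_up=n_up,
        n_down=n_down,
        heat_value=float(min(max(heat, 0.0), 1.0)),
        exhaustive=exhaustive,
        n_genes_used=len(present),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def hypergeometric_pvalue(M: int, m: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for overlap X between a
    category of size ``m`` and ``n`` draws from a universe of size ``M``."""
    if not (0 <= m <= M and 0 <= n <= M and 0 <= k):
        raise ValueError("need 0 <= m, n <= M and k >= 0")
    return float(min(stats.hypergeom.sf(k - 1, M, m, n), 1.0))


def go_enrichment(de_genes, universe, gene2go: pd.DataFrame) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of DE genes in GO categories.

    ``gene2go`` has columns ``gene`` and ``go``.  Genes without any GO
    annotation are excluded from both the universe and the DE list (logged).
    The raw p-value for a category of size m in a universe of size M with n
    DE genes and overlap k is the upper tail P(X >= k) of the hypergeometric
    distribution; Holm's step-down adjustment is applied across all tested
    categories.
    """
    universe = pd.Index(universe).unique()
    de = pd.Index(de_genes).unique()
    if not de.isin(universe).all():
        raise ValueError("DE genes must be a subset of the universe")
    covered = pd.Index(gene2go["gene"]).unique()
    dropped = len(universe.difference(covered))
    if dropped:
        log.info("%d universe genes without GO annotation excluded", dropped)
    universe = universe.intersection(covered)
    de = de.intersection(universe)
    M = len(universe)
    if M == 0:
        raise ValueError("empty universe after GO coverage filtering")
    n = len(de)
    ann = gene2go[gene2go["gene"].isin(universe)]
    de_set = set(de)
    rows = []
    for cat, grp in ann.groupby("go"):
        members = set(grp["gene"])
        m = len(members)
        k = len(members & de_set)
        rows.append((str(cat), m, k, hypergeometric_pvalue(M, m, n, k)))
    if not rows:
        return []
    praw = np.array([r[3] for r in rows])
    pholm = multipletests(praw, method="holm")[1]
    return [
        EnrichmentResult(category=c, category_size=m, de_in_category=k,
                         p_raw=p, p_holm=float(ph))
        for (c, m, k, p), ph in zip(rows, pholm)
    ]


# ---------------------------------------------------------------------------
# heat-plot assembly
# ---------------------------------------------------------------------------

def heatmap_table(
    results: list[PermutationResult],
    sets: list[str] | None = None,
    classes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble permutation results into a sets x classes heat table.

    Returns (values, significant): rectangular frames indexed by set name
    with one column per class.  Cells without a result are NaN (missing);
    cells with heat value in the open band (0.05, 0.95) are flagged not
    significant.
    """
    if sets is None:
        sets = list(dict.fromkeys(r.set_name for r in results))
    if classes is None:
        classes = list(dict.fromkeys(r.klass for r in results))
    values = pd.DataFrame(np.nan, index=pd.Index(sets, name="set"),
                          columns=pd.Index(classes, name="class"))
    seen = set()
    for r in results:
        key = (r.set_name, r.klass)
        if key in seen:
            raise ValueError(f"duplicate result for {key}")
        seen.add(key)
        if r.set_name in values.index and r.klass in values.columns:
            values.loc[r.set_name, r.klass] = r.heat_value
    lo, hi = SIGNIFICANCE_BAND
    significant = values.map(
        lambda v: (not math.isnan(v)) and not (lo < v < hi)
    )
    return values, significant
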