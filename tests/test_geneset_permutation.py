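"""Permutation statistic, DE stand-in, chromosome ratios, GO enrichment."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nucleoscape.geneset_permutation import (
    EmptySetError,
    chromosome_ratio,
    gene_de_test,
    go_enrichment,
    heatmap_table,
    hypergeometric_pvalue,
    permutation_heat_value,
    set_score,
)
from nucleoscape.synthetic_expression import (
    ExpressionMatrix,
    PlantedSet,
    generate_expression,
)


def manual_matrix(values: dict, classes: dict, chrom=None) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    cl = pd.Series(classes)
    cl.index.name = "sample"
    df.index.name = "gene"
    df.columns = cl.index
    if chrom is None:
        chrom = pd.Series("chr1", index=df.index)
    return ExpressionMatrix(values=df, classes=cl, gene2chrom=chrom)


CLASSES9 = {f"{c}_{r}": c for c in ("control", "antibody", "hgf")
            for r in (1, 2, 3)}


class TestGeneDeTest:
    def test_constant_gene_flagged_with_p_one(self):
        vals = {"G1": [1, 2, 3, 4, 5, 6], "G2": [2.0] * 6}
        classes = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        m = manual_matrix(vals, classes)
        table, de = gene_de_test(m, "a", "b")
        assert bool(table.loc["G2", "flagged"])
        assert table.loc["G2", "p"] == 1.0

    def test_planted_genes_detected_with_high_power(self):
        sets = (PlantedSet("UP", 50, "up", 1.0, "antibody"),)
        m, truth, _ = generate_expression(n_genes=2000, sets=sets,
                                          noise_sd=0.25, seed=4)
        _, de = gene_de_test(m, "antibody", "control")
        planted = set(truth.genes.gene)
        rate = len(planted & set(de)) / len(planted)
        assert rate >= 0.90


class TestChromosomeRatio:
    def test_hand_counted_ratios(self):
        g2c = pd.Series(
            ["chr1"] * 20 + ["chr2"] * 10,
            index=[f"g{i}" for i in range(30)],
        )
        de = [f"g{i}" for i in range(4)] + ["g25"]
        table, unmapped = chromosome_ratio(de, g2c)
        assert table.loc["chr1", "ratio"] == pytest.approx(0.2)
        assert table.loc["chr2", "ratio"] == pytest.approx(0.1)
        assert unmapped == []

    def test_all_or_none_de(self):
        g2c = pd.Series(["chr1", "chr2"], index=["a", "b"])
        all_de, _ = chromosome_ratio(["a", "b"], g2c)
        none_de, _ = chromosome_ratio([], g2c)
        assert (all_de.ratio == 1).all()
        assert (none_de.ratio == 0).all()

    def test_unmapped_reported_and_totals_conserved(self):
        g2c = pd.Series(["chr1"] * 5, index=[f"g{i}" for i in range(5)])
        table, unmapped = chromosome_ratio(["g0", "g1", "phantom"], g2c)
        assert unmapped == ["phantom"]
        assert table.n_de.sum() == 2


class TestSetScore:
    def test_constant_matrix_scores_zero(self):
        vals = {f"G{i}": [5.0] * 9 for i in range(3)}
        m = manual_matrix(vals, CLASSES9)
        assert set_score(m, ["G0", "G1"], "antibody") == 0.0

    def test_noiseless_shift_recovered_exactly(self):
        delta = 0.75
        vals = {
            f"G{i}": [5.0 + (delta if c == "antibody" else 0.0)
                      for c in CLASSES9.values()]
            for i in range(4)
        }
        m = manual_matrix(vals, CLASSES9)
        assert set_score(m, [f"G{i}" for i in range(4)], "antibody") == (
            pytest.approx(delta)
        )

    def test_hand_computed_mean_difference(self):
        vals = {
            "G1": [1.0, 2.0, 3.0, 4.0],
            "G2": [2.0, 2.0, 6.0, 6.0],
            "G3": [0.0, 1.0, 1.0, 2.0],
        }
        classes = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        m = manual_matrix(vals, classes)
        # per-gene class-a minus rest: (1.5-3.5), (2-6), (0.5-1.5) -> mean -7/3
        assert set_score(m, ["G1", "G2", "G3"], "a") == pytest.approx(-7 / 3)

    def test_absent_set_rejected(self):
        m = manual_matrix({"G1": [1.0] * 9}, CLASSES9)
        with pytest.raises(EmptySetError):
            set_score(m, ["missing"], "antibody")


class TestPermutation:
    def test_unique_maximum_gives_one_minus_one_over_84(self):
        # noiseless planted shift: the observed 3-vs-6 split is the unique
        # maximiser over all C(9,3)=84 splits
        vals = {
            f"G{i}": [4.0 + (1.0 if c == "antibody" else 0.0)
                      for c in CLASSES9.values()]
            for i in range(3)
        }
        m = manual_matrix(vals, CLASSES9)
        r = permutation_heat_value(m, [f"G{i}" for i in range(3)], "antibody")
        assert r.exhaustive
        assert r.n_permutations == 84
        assert r.n_up == 1
        assert r.heat_value == pytest.approx(1 - 1 / 84)

    def test_tie_counting_in_both_tails(self):
        vals = {"G0": [1.0] * 9}
        m = manual_matrix(vals, CLASSES9)
        r = permutation_heat_value(m, ["G0"], "antibody")
        # all permuted scores tie with the observed zero score
        assert r.n_up == 84 and r.n_down == 84
        assert r.heat_value == 0.0

    def test_sampled_converges_to_exhaustive(self):
        m, _, gmt = generate_expression(
            n_genes=300, sets=(PlantedSet("S", 25, "null"),), seed=6
        )
        genes = gmt[0][2]
        ex = permutation_heat_value(m, genes, "antibody", mode="exhaustive")
        for n_perm in (100, 1000, 10000):
            sampled = permutation_heat_value(
                m, genes, "antibody", n_permutations=n_perm, seed=3,
                mode="sample",
            )
            band = max(0.02, 4 * math.sqrt(0.25 / n_perm))
            assert abs(sampled.heat_value - ex.heat_value) < band

    def test_null_sets_heat_values_roughly_uniform(self):
        heats = []
        for seed in range(40):
            m, _, gmt = generate_expression(
                n_genes=120, sets=(PlantedSet("S", 15, "null"),), seed=seed
            )
            heats.append(
                permutation_heat_value(m, gmt[0][2], "antibody").heat_value
            )
        heats = np.asarray(heats)
        assert 0.3 < heats.mean() < 0.7
        assert heats.min() < 0.3 and heats.max() > 0.7

    def test_degenerate_class_rejected(self):
        vals = {"G0": [1.0, 2.0, 3.0]}
        m_classes = {"a1": "a", "a2": "a", "b1": "b"}
        df = pd.DataFrame(vals).T
        cl = pd.Series(m_classes)
        df.columns = cl.index
        with pytest.raises(ValueError):
            matrix = ExpressionMatrix(
                values=df, classes=cl,
                gene2chrom=pd.Series("chr1", index=df.index),
            )
            permutation_heat_value(matrix, ["G0"], "b")


class TestHypergeometric:
    def test_worked_example_10_choose_2(self):
        # universe 10, DEGs 5, category 2, overlap 2:
        # C(5,2)C(5,0)/C(10,2) = 10/45
        assert hypergeometric_pvalue(10, 2, 5, 2) == pytest.approx(10 / 45)

    def test_zero_overlap_size_one_category(self):
        for M, n in [(10, 4), (7, 3), (12, 5)]:
            # P(X >= 0) = 1; P(X >= 1) for m=1 is n/M
            assert hypergeometric_pvalue(M, 1, n, 0) == 1.0
            assert hypergeometric_pvalue(M, 1, n, 1) == pytest.approx(n / M)

    def test_single_category_holm_is_raw(self):
        g2g = pd.DataFrame({"gene": ["a", "b", "c"], "go": ["GO:X"] * 3})
        res = go_enrichment(["a"], ["a", "b", "c", "d"], g2g)
        assert len(res) == 1
        assert res[0].p_holm == pytest.approx(res[0].p_raw)

    def test_holm_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        rows = [{"gene": g, "go": f"GO:{i % 7}"} for i, g in enumerate(genes)]
        g2g = pd.DataFrame(rows)
        de = list(rng.choice(genes, 12, replace=False))
        res = go_enrichment(de, genes, g2g)
        res_sorted = sorted(res, key=lambda e: e.p_raw)
        for e in res:
            assert e.p_holm >= e.p_raw
            assert e.p_holm <= 1.0
        adj = [e.p_holm for e in res_sorted]
        assert adj == sorted(adj)

    def test_de_outside_universe_rejected(self):
        g2g = pd.DataFrame({"gene": ["a"], "go": ["GO:X"]})
        with pytest.raises(ValueError):
            go_enrichment(["z"], ["a"], g2g)


class TestHeatmapTable:
    def test_single_cell(self):
        vals = {f"G{i}": [4.0 + (1.0 if c == "antibody" else 0.0)
                          for c in CLASSES9.values()] for i in range(2)}
        m = manual_matrix(vals, CLASSES9)
        r = permutation_heat_value(m, ["G0", "G1"], "antibody", set_name="S")
        table, sig = heatmap_table([r])
        assert table.shape == (1, 1)
        assert table.loc["S", "antibody"] == r.heat_value

    def test_planted_up_and_down_sets_flagged_in_affected_class(self):
        sets = (
            PlantedSet("UP1", 25, "up", 1.5, "antibody"),
            PlantedSet("UP2", 25, "up", 1.5, "antibody"),
            PlantedSet("DN1", 25, "down", 1.5, "antibody"),
            PlantedSet("DN2", 25, "down", 1.5, "antibody"),
        )
        m, _, gmt = generate_expression(n_genes=2000, sets=sets, seed=11)
        results = [
            permutation_heat_value(m, genes, "antibody", set_name=name)
            for name, _, genes in gmt
        ]
        table, sig = heatmap_table(results)
        assert sig["antibody"].sum() == 4
        assert (table.loc[["UP1", "UP2"], "antibody"] >= 0.95).all()
        assert (table.loc[["DN1", "DN2"], "antibody"] <= 0.05).all()

    def test_missing_pair_is_nan_cell(self):
        vals = {"G0": [float(i) for i in range(9)]}
        m = manual_matrix(vals, CLASSES9)
        r = permutation_heat_value(m, ["G0"], "antibody", set_name="S")
        table, sig = heatmap_table([r], sets=["S"],
                                   classes=["antibody", "hgf"])
        assert math.isnan(table.loc["S", "hgf"])
        assert not sig.loc["S", "hgf"]
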