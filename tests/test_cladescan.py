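"""Clade enrichment scan, unique-gene extraction, term enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from gutstrain import (clade_unique_genes, infant_oriented, scan_tree,
                       term_enrichment)
from gutstrain.cladescan import chi_square_node, scan_table
from gutstrain.tables import DistanceMatrix
from gutstrain.trees import build_tree, read_newick


def balanced_tree(n_leaves, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_leaves, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return build_tree(DistanceMatrix([f"L{i:03d}" for i in range(n_leaves)], d))


def labels_for(leaves, n_case, infants=None):
    groups = ["case"] * n_case + ["control"] * (len(leaves) - n_case)
    return pd.DataFrame({
        "infant_id": infants or [f"I{i}" for i in range(len(leaves))],
        "group": groups}, index=list(leaves))


class TestChiSquareNode:
    def test_pure_case_node_of_ten(self):
        stat, p = chi_square_node(10, 0, 0.5)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(chi2.sf(10, 1), rel=1e-12)
        assert p == pytest.approx(0.00157, abs=5e-5)

    def test_balanced_node(self):
        stat, p = chi_square_node(3, 3, 0.5)
        assert stat == 0.0 and p == 1.0

    def test_pure_case_node_of_six_significant(self):
        stat, p = chi_square_node(6, 0, 0.5)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(0.0143, abs=5e-4)
        assert p < 0.05


class TestScanTree:
    def test_counts_consistent_with_children(self, small_strain):
        from gutstrain.trees import gene_content_distance
        sd = small_strain.clade
        tree = build_tree(gene_content_distance(sd.gene_presence))
        tree.annotate(sd.genome_map.set_index("genome_id"))
        results = scan_tree(tree, expected_case_fraction=0.5)
        by_leaves = {r.leaves: r for r in results}
        for node in tree.tree.preorder():
            if node.is_tip():
                continue
            r = by_leaves[tuple(t.name for t in node.tips())]
            child_case = child_ctrl = 0
            for ch in node.children:
                if ch.is_tip():
                    grp = sd.genome_map.set_index("genome_id").loc[ch.name,
                                                                   "group"]
                    child_case += grp == "case"
                    child_ctrl += grp == "control"
                else:
                    cr = by_leaves[tuple(t.name for t in ch.tips())]
                    child_case += cr.n_case
                    child_ctrl += cr.n_control
            assert (child_case, child_ctrl) == (r.n_case, r.n_control)

    def test_min_leaves_below_two_rejected(self):
        tree = balanced_tree(8)
        with pytest.raises(ValueError):
            scan_tree(tree, labels_for(tree.leaf_names, 4), min_leaves=1)

    def test_unlabelled_leaf_rejected(self):
        tree = balanced_tree(8)
        labels = labels_for(tree.leaf_names[:-1], 4)
        with pytest.raises(ValueError, match="unlabelled"):
            scan_tree(tree, labels)

    def test_expected_fraction_defaults_to_observed(self):
        tree = balanced_tree(10)
        labels = labels_for(tree.leaf_names, 3)  # 30% cases
        results = scan_tree(tree, labels)
        assert results[0].expected_case_fraction == pytest.approx(0.3)

    def test_calibration_under_label_permutation(self):
        """On permuted balanced labels ~5% (+-3 points) of tested nodes
        reach p < 0.05 (the chi-square is approximate at small n)."""
        tree = balanced_tree(96, seed=3)
        leaves = tree.leaf_names
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(60):
            perm = rng.permutation(leaves)
            labels = labels_for(perm, len(leaves) // 2)
            for r in scan_tree(tree, labels, expected_case_fraction=0.5):
                if not np.isnan(r.p):
                    ps.append(r.p)
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) <= 0.03

    def test_sorted_by_p(self, small_strain):
        from gutstrain.trees import gene_content_distance
        sd = small_strain.clade
        tree = build_tree(gene_content_distance(sd.gene_presence))
        results = scan_tree(tree, sd.genome_map.set_index("genome_id"),
                            expected_case_fraction=0.5)
        ps = [r.p for r in results if not np.isnan(r.p)]
        assert ps == sorted(ps)
        df = scan_table(results)
        assert (df["n_case"] + df["n_control"] == df["n_leaves"]).all()


class TestInfantOriented:
    def test_single_infant(self):
        assert infant_oriented(["I1", "I1", "I1"])

    def test_two_infants(self):
        assert not infant_oriented(["I1", "I2"])

    def test_single_leaf(self):
        assert infant_oriented(["I1"])

    def test_flagged_in_scan(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        labels = pd.DataFrame({"infant_id": ["I1", "I1", "I2", "I3"],
                               "group": ["case", "case", "control", "control"]},
                              index=list("ABCD"))
        results = scan_tree(tree, labels, min_leaves=2)
        flags = {r.leaves: r.infant_oriented for r in results}
        assert flags[("A", "B")] is True
        assert flags[("C", "D")] is False


class TestCladeUniqueGenes:
    def _gpm(self):
        genomes = [f"g{i}" for i in range(10)]
        data = {"always": [1] * 10,
                "clade_only": [1] * 4 + [0] * 6,
                "outside_only": [0] * 4 + [1] * 6,
                "mostly_clade": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]}
        return pd.DataFrame(data, index=genomes).T

    def test_unique_gene_included_core_excluded(self):
        res = clade_unique_genes(self._gpm(), [f"g{i}" for i in range(4)])
        assert "clade_only" in res.genes
        assert "always" not in res.genes
        assert "outside_only" not in res.genes

    def test_thresholds(self):
        # mostly_clade present in 75% of clade < default 95%
        res = clade_unique_genes(self._gpm(), [f"g{i}" for i in range(4)])
        assert "mostly_clade" not in res.genes
        relaxed = clade_unique_genes(self._gpm(), [f"g{i}" for i in range(4)],
                                     in_min=0.7)
        assert "mostly_clade" in relaxed.genes

    def test_full_clade_rejected(self):
        with pytest.raises(ValueError):
            clade_unique_genes(self._gpm(), [f"g{i}" for i in range(10)])

    def test_planted_genes_recovered_exactly(self, small_strain):
        sd = small_strain.clade
        res = clade_unique_genes(sd.gene_presence, sd.planted_clade_genomes)
        assert sorted(res.genes) == sorted(sd.planted_genes)
        assert len(res) == 223


class TestTermEnrichment:
    def test_extreme_enrichment_tops_ranking(self):
        background = [f"gene{i}" for i in range(100)]
        annotation = {g: ["adhesion"] for g in background[:10]}
        annotation.update({g: ["other"] for g in background[10:]})
        res = term_enrichment(background[:10], annotation, background)
        assert res.iloc[0]["term"] == "adhesion"
        assert res.iloc[0]["p"] < 1e-6

    def test_zero_overlap_p_one(self):
        background = [f"gene{i}" for i in range(20)]
        annotation = {g: ["t1"] for g in background[:10]}
        annotation.update({g: ["t2"] for g in background[10:]})
        res = term_enrichment(background[:5], annotation, background)
        assert res.set_index("term").loc["t2", "p"] == 1.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(["a"], {"a": ["t"]}, [])

    def test_uncovered_query_rejected(self):
        with pytest.raises(ValueError, match="covers no query"):
            term_enrichment(["zz"], {"a": ["t"]}, ["a", "zz"])

    def test_random_queries_roughly_uniform(self):
        rng = np.random.default_rng(5)
        background = [f"gene{i}" for i in range(200)]
        annotation = {g: [f"T{rng.integers(0, 20)}"] for g in background}
        ps = []
        for _ in range(40):
            query = rng.choice(background, size=30, replace=False)
            res = term_enrichment(list(query), annotation, background)
            ps.extend(res["p"].tolist())
        # one-sided discrete p-values are stochastically >= uniform
        assert kstest(ps, "uniform", alternative="greater").pvalue > 0.01
        assert np.mean(ps) > 0.4
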