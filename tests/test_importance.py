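"""Shapley attributions, k-mer/domain→gene mapping, and consensus reporting."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

import acidforest as af
from acidforest._treeshap import forest_shap_values, tree_shap_values
from acidforest.features import reverse_complement
from acidforest.importance import (
    ImportanceTable,
    build_consensus,
    map_domain_to_genes,
    map_kmer_to_genes,
)


def path_dependent_expectation(t, x, S, node=0):
    """Oracle: expected tree output when only features in S are fixed to x."""
    if t.children_left[node] < 0:
        return t.value[node, 0, 0]
    d = t.feature[node]
    left, right = t.children_left[node], t.children_right[node]
    if d in S:
        nxt = left if x[d] <= t.threshold[node] else right
        return path_dependent_expectation(t, x, S, nxt)
    w = t.weighted_n_node_samples
    return (
        w[left] * path_dependent_expectation(t, x, S, left)
        + w[right] * path_dependent_expectation(t, x, S, right)
    ) / w[node]


def brute_force_shapley(t, x, n_features):
    """Oracle: exhaustive coalition enumeration of the Shapley value."""
    phi = np.zeros(n_features)
    for i in range(n_features):
        rest = [j for j in range(n_features) if j != i]
        for size in range(n_features):
            coef = factorial(size) * factorial(n_features - size - 1) / factorial(n_features)
            for S in combinations(rest, size):
                phi[i] += coef * (
                    path_dependent_expectation(t, x, set(S) | {i})
                    - path_dependent_expectation(t, x, set(S))
                )
    return phi


class TestTreeShapley:
    @pytest.mark.parametrize("depth", [2, 4, None])
    def test_matches_bruteforce_coalition_enumeration(self, depth):
        rng = np.random.default_rng(0)
        M = 6
        X = rng.normal(size=(60, M))
        y = X @ rng.normal(size=M) + 0.3 * rng.normal(size=60)
        tree = DecisionTreeRegressor(max_depth=depth, random_state=0).fit(X, y)
        phi, base = tree_shap_values(tree, X[:8])
        for r in range(8):
            expected = brute_force_shapley(tree.tree_, X[r], M)
            assert np.allclose(phi[r], expected, atol=1e-9)

    def test_additivity_for_single_tree_and_forest(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 10))
        y = X[:, 0] * 2 - X[:, 3] + rng.normal(size=80)
        forest = RandomForestRegressor(n_estimators=40, random_state=0).fit(X, y)
        phi, base = forest_shap_values(forest, X[:30])
        assert np.allclose(base + phi.sum(axis=1), forest.predict(X[:30]), atol=1e-8)

    def test_irrelevant_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 3))
        y = X[:, 0] * 2.0  # feature 2 never used
        tree = DecisionTreeRegressor(max_depth=3, random_state=0).fit(X, y)
        phi, _ = tree_shap_values(tree, X[:20])
        assert np.allclose(phi[:, 2], 0.0, atol=1e-12)


class TestComputeImportances:
    def test_additivity_and_ranking_on_pipeline(self, default_pipeline_report):
        objs = default_pipeline_report["_objects"]
        imp = objs["importances"]["gene"]
        bundle = objs["bundles"]["gene"]
        shap = imp.shap_values
        pred = bundle.regressor.predict(
            objs["datasets"]["gene"][1].X.loc[shap.index].to_numpy()
        )
        total = imp.base_value + shap.sum(axis=1).to_numpy()
        assert np.allclose(total, pred, atol=1e-6)
        ranked = imp.table["mean_abs_shap"].to_numpy()
        assert np.all(np.diff(ranked) <= 1e-12)
        assert list(imp.table["rank"]) == list(range(1, len(ranked) + 1))

    def test_planted_blocks_and_conditions_in_top_ten(self, default_pipeline_report):
        top10 = default_pipeline_report["_objects"]["importances"]["gene"].top_features(10)
        truth = default_pipeline_report["_objects"]["truth"]
        for block, genes in truth.causal_genes.items():
            assert any(
                set(genes) <= set(feat.split(",")) for feat in top10
            ), f"causal block {block} missing from top-10"
        for cond in ("Yeast", "Temperature", "Volume"):
            assert cond in top10

    def test_planted_direction_is_faster(self, default_pipeline_report):
        imp = default_pipeline_report["_objects"]["importances"]["gene"]
        truth = default_pipeline_report["_objects"]["truth"]
        table = imp.table.set_index("feature")
        for genes in truth.causal_genes.values():
            for feat in table.index:
                if set(genes) <= set(feat.split(",")):
                    assert table.at[feat, "direction"] == "faster"

    def test_mismatched_data_rejected(self, default_pipeline_report):
        objs = default_pipeline_report["_objects"]
        with pytest.raises(ValueError, match="do not match"):
            af.compute_importances(objs["bundles"]["gene"], objs["datasets"]["pfam"][1])


class TestKmerGeneMap:
    def test_absent_kmer_empty_hits(self):
        seqs = {"gA": {"s1": "ACGTACGTAAA"}}
        assert map_kmer_to_genes("GGGGGGGGG", seqs).hits == {}

    def test_reverse_strand_hit_reported(self):
        kmer = "ACGGTCACT"
        seqs = {"gA": {"s1": "TTTT" + reverse_complement(kmer) + "CCCC"}}
        assert map_kmer_to_genes(kmer, seqs).hits == {"gA": 1}

    def test_matches_bruteforce_scan_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(4, 10))
            kmer = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
            seqs = {
                f"g{j}": {
                    f"s{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
                    for i in range(rng.integers(1, 5))
                }
                for j in range(4)
            }
            got = map_kmer_to_genes(kmer, seqs).hits
            rc = reverse_complement(kmer)
            expected = {}
            for g, copies in seqs.items():
                n = sum(1 for s in copies.values() if kmer in s or rc in s)
                if n:
                    expected[g] = n
            assert got == expected

    def test_synthetic_tag_maps_to_planted_family_only(self, small_pop):
        _, truth, _ = small_pop
        for block, tag in truth.tag_kmers.items():
            result = map_kmer_to_genes(tag, truth.gene_sequences)
            assert set(result.hits) == set(truth.causal_genes[block])
            carriers = int(truth.block_presence(block).sum())
            for gene, n in result.hits.items():
                assert n == carriers

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            map_kmer_to_genes("ACGTN", {})

    def test_min_strains_threshold(self):
        seqs = {
            "common": {f"s{i}": "AAACCCGGG" for i in range(45)},
            "rare": {"s0": "AAACCCGGG"},
        }
        result = map_kmer_to_genes("AAACCCGGG", seqs)
        assert result.genes(min_strains=40) == ["common"]


class TestDomainGeneMap:
    def make_table(self):
        return pd.DataFrame(
            {
                "seq_id": ["s1|gA", "s2|gA", "s1|gB", "s3|gC"],
                "hmm_acc": ["PF1.1", "PF1.1", "PF1.1", "PF2.1"],
            }
        )

    def test_absent_accession_empty(self):
        assert map_domain_to_genes("PF9.9", self.make_table()) == {}

    def test_counts_conserved_over_genes(self):
        table = self.make_table()
        seq_to_gene = {s: s.split("|")[1] for s in table["seq_id"]}
        hits = map_domain_to_genes("PF1.1", table, seq_to_gene)
        assert hits == {"gA": 2, "gB": 1}
        assert sum(hits.values()) == int((table["hmm_acc"] == "PF1.1").sum())

    def test_synthetic_assignment_recovered(self, small_pop):
        _, truth, _ = small_pop
        rows = []
        for g, accs in truth.domain_assignment.items():
            for s in truth.presence.index:
                if truth.presence.at[s, g]:
                    rows.extend((f"{s}|{g}", a) for a in accs)
        table = pd.DataFrame(rows, columns=["seq_id", "hmm_acc"])
        seq_to_gene = {s: s.split("|")[1] for s in table["seq_id"].unique()}
        # a dedicated causal accession maps to exactly its planted family
        block_gene = truth.causal_genes["cau1"][0]
        acc = truth.domain_assignment[block_gene][0]
        assert set(map_domain_to_genes(acc, table, seq_to_gene)) == {block_gene}


def make_importance(rep, features):
    table = pd.DataFrame(
        {
            "feature": features,
            "mean_abs_shap": np.linspace(1, 0.1, len(features)),
            "direction": ["faster"] * len(features),
            "rank": range(1, len(features) + 1),
        }
    )
    return ImportanceTable(representation=rep, table=table, base_value=0.0)


class TestConsensus:
    def test_gene_and_kmer_agreement_flagged(self):
        importances = {
            "gene": make_importance("gene", ["geneX", "geneY"]),
            "kmer9": make_importance("kmer9", ["ACGGTCACT", "AAAAAAAAA"]),
        }
        kmer_maps = {"ACGGTCACT": af.KmerGeneMap("ACGGTCACT", {"geneX": 25})}
        report = build_consensus(importances, kmer_maps=kmer_maps)
        assert "geneX" in report.consensus_labels()
        geneY = next(e for e in report.entries if e.label == "geneY")
        assert not geneY.consensus

    def test_single_representation_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_consensus({"gene": make_importance("gene", ["g"])})

    def test_empty_tables_give_empty_report(self):
        importances = {
            "gene": make_importance("gene", []),
            "pfam": make_importance("pfam", []),
        }
        assert build_consensus(importances).entries == []

    def test_collapsed_ids_expanded(self):
        importances = {
            "gene": make_importance("gene", ["gA,gB"]),
            "pfam": make_importance("pfam", ["PF1.1"]),
        }
        domain_maps = {"PF1.1": {"gB": 12}}
        report = build_consensus(importances, domain_maps=domain_maps)
        assert "gB" in report.consensus_labels()

    def test_pipeline_consensus_contains_causal_genes(self, default_pipeline_report):
        truth = default_pipeline_report["_objects"]["truth"]
        labels = {
            e["label"] for e in default_pipeline_report["consensus"] if e["consensus"]
        }
        for genes in truth.causal_genes.values():
            assert set(genes) <= labels
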