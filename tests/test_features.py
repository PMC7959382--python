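"""Canonical k-mer counting, matrix building, pruning, collapsing, pangenome."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import acidforest as af
from acidforest.features import (
    FeatureMatrix,
    assemble_dataset,
    build_domain_matrix,
    build_gene_matrix,
    canonical_kmer,
    collapse_identical,
    count_canonical_kmers,
    pangenome_summary,
    prune_features,
    reverse_complement,
)
from acidforest.kinetics import ALL_CONDITIONS, PhenotypeTable

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


def naive_canonical_counts(seqs, k):
    """Brute-force oracle: enumerate every window and canonicalize by string."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= set("ACGT"):
                c = min(w, reverse_complement(w))
                counts[c] = counts.get(c, 0) + 1
    return counts


class TestCanonicalKmers:
    def test_poly_a_counts_under_canonical_form(self):
        assert count_canonical_kmers(["AAAAAAAAAA"], 9) == {"AAAAAAAAA": 2}

    def test_ambiguous_bases_skipped_and_contig_boundaries_respected(self):
        # windows containing N are dropped; windows never span contigs
        counts = count_canonical_kmers(["ACGTN", "ACGT"], 4)
        assert counts == {"ACGT": 2}

    def test_matches_naive_oracle_on_random_contig(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        assert count_canonical_kmers([seq], 9) == naive_canonical_counts([seq], 9)

    @given(seq=dna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_strand_symmetry(self, seq):
        k = 5
        assert count_canonical_kmers([seq], k) == count_canonical_kmers(
            [reverse_complement(seq)], k
        )

    def test_canonical_space_sizes_by_exhaustive_enumeration(self):
        # count distinct canonical k-mers over the full 4^k space
        for k, expected in ((8, 32896), (9, 131072)):
            codes = np.arange(4**k, dtype=np.int64)
            digits = np.empty((len(codes), k), dtype=np.int64)
            c = codes.copy()
            for pos in range(k - 1, -1, -1):
                digits[:, pos] = c & 3
                c >>= 2
            rc = ((3 - digits)[:, ::-1] * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1)
            assert len(np.unique(np.minimum(codes, rc))) == expected

    def test_total_count_conservation(self):
        rng = np.random.default_rng(6)
        contigs = ["".join("ACGT"[i] for i in rng.integers(0, 4, L)) for L in (50, 9, 8, 200)]
        k = 9
        total = sum(count_canonical_kmers(contigs, k).values())
        assert total == sum(max(0, len(s) - k + 1) for s in contigs)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            count_canonical_kmers(["ACGT"], 0)
        assert count_canonical_kmers(["ACG"], 9) == {}

    def test_canonical_kmer_helper(self):
        assert canonical_kmer("TTT") == "AAA"
        assert canonical_kmer("ACG") == "ACG"  # revcomp CGT is later


class TestGeneMatrix:
    def make_roary(self):
        return pd.DataFrame(
            {
                "Gene": ["g1", "g2", "g3", "g4"],
                "Annotation": ["a"] * 4,
                "s1": ["s1|g1", "s1|g2", "s1|g3", "s1|g4"],
                "s2": ["s2|g1", "", "s2|g3", "s2|g4"],
                "s3": ["s3|g1", "s3|g2", "", "s3|g4\ts3|g4b"],
            }
        )

    def test_toy_counting_and_paralogs(self):
        m = build_gene_matrix(self.make_roary())
        assert m.values.to_numpy().sum() == 10
        assert set(np.unique(m.values.to_numpy())) <= {0, 1}
        # the tab-joined paralog cell still scores presence 1
        assert m.values.at["s3", "g4"] == 1

    def test_duplicate_gene_names_rejected(self):
        bad = self.make_roary()
        bad.loc[1, "Gene"] = "g1"
        with pytest.raises(ValueError, match="duplicated"):
            build_gene_matrix(bad)


class TestDomainMatrix:
    def test_copy_number_semantics(self):
        table = pd.DataFrame(
            {"seq_id": ["s1|gA", "s1|gB", "s2|gA"], "hmm_acc": ["PF00001.1"] * 3}
        )
        g2s = {"s1|gA": "s1", "s1|gB": "s1", "s2|gA": "s2"}
        m = build_domain_matrix(table, g2s)
        assert m.values.at["s1", "PF00001.1"] == 2
        assert m.values.at["s2", "PF00001.1"] == 1

    def test_empty_table_gives_zero_columns_after_pruning(self):
        m = build_domain_matrix(
            pd.DataFrame(columns=["seq_id", "hmm_acc"]), {"s1|g": "s1", "s2|g": "s2"}
        )
        assert prune_features(m).n_features == 0

    def test_unmapped_sequence_rejected(self):
        table = pd.DataFrame({"seq_id": ["sX|g"], "hmm_acc": ["PF1.1"]})
        with pytest.raises(ValueError, match="not mapped"):
            build_domain_matrix(table, {"s1|g": "s1"})


def binary_matrix(present_counts: dict[str, int], n: int) -> FeatureMatrix:
    cols = {}
    for name, npresent in present_counts.items():
        v = np.zeros(n, dtype=np.int64)
        v[:npresent] = 1
        cols[name] = v
    df = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return FeatureMatrix("gene", df, pd.Series("x", index=df.index))


class TestPruning:
    def test_boundary_behaviour_at_98_percent(self):
        # strict '>' at the threshold: presence (or absence) must exceed 0.98
        m = binary_matrix({"all": 100, "p99": 99, "p98": 98, "p50": 50, "p2": 2, "p1": 1, "none": 0}, 100)
        kept = prune_features(m).feature_ids
        assert kept == ["p98", "p50", "p2"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 3, (40, 30)), index=[f"s{i}" for i in range(40)])
        df.columns = [f"f{j}" for j in range(30)]
        m = FeatureMatrix("pfam", df, pd.Series("x", index=df.index))
        once = prune_features(m)
        twice = prune_features(once)
        assert once.feature_ids == twice.feature_ids

    def test_count_features_use_presence_notion(self):
        # a count column that is nonzero everywhere is 'present' everywhere
        df = pd.DataFrame({"f": np.arange(1, 101)}, index=[f"s{i}" for i in range(100)])
        m = FeatureMatrix("kmer9", df, pd.Series("x", index=df.index))
        assert prune_features(m).n_features == 0


class TestCollapse:
    def test_two_identical_columns_merge(self):
        df = pd.DataFrame(
            {"A": [1, 0, 1], "B": [1, 0, 1], "C": [0, 1, 1]},
            index=["s1", "s2", "s3"],
        )
        m = collapse_identical(FeatureMatrix("gene", df, pd.Series("x", index=df.index)))
        assert m.feature_ids == ["A,B", "C"]
        assert m.collapse_map == {"A,B": ["A", "B"]}
        assert list(m.values["A,B"]) == [1, 0, 1]

    def test_all_distinct_unchanged(self):
        df = pd.DataFrame({"A": [1, 0], "B": [0, 1]}, index=["s1", "s2"])
        m = collapse_identical(FeatureMatrix("gene", df, pd.Series("x", index=df.index)))
        assert m.feature_ids == ["A", "B"]
        assert m.collapse_map == {}

    def test_partition_against_set_partition_oracle(self):
        rng = np.random.default_rng(17)
        base = rng.integers(0, 2, (25, 8))
        # plant duplicate groups by repeating columns
        assignment = rng.integers(0, 8, 30)
        df = pd.DataFrame(
            base[:, assignment], index=[f"s{i}" for i in range(25)],
            columns=[f"f{j:02d}" for j in range(30)],
        )
        m = collapse_identical(FeatureMatrix("gene", df, pd.Series("x", index=df.index)))
        # oracle: set partition of columns by exact profile
        profiles = {}
        for c in df.columns:
            profiles.setdefault(tuple(df[c]), []).append(c)
        assert m.n_features == len(profiles)
        seen = [orig for name in m.feature_ids for orig in name.split(",")]
        assert sorted(seen) == sorted(df.columns)
        for name in m.feature_ids:
            members = name.split(",")
            assert profiles[tuple(m.values[name])] == members

    def test_prune_collapse_commute_on_binary(self):
        rng = np.random.default_rng(23)
        base = rng.integers(0, 2, (100, 12))
        cols = rng.integers(0, 12, 40)
        df = pd.DataFrame(
            base[:, cols], index=[f"s{i}" for i in range(100)],
            columns=[f"f{j:02d}" for j in range(40)],
        )
        # add extreme columns so pruning has something to remove
        df["rare"] = 0
        df.loc["s0", "rare"] = 1
        df["ubiq"] = 1
        m = FeatureMatrix("gene", df, pd.Series("x", index=df.index))
        a = collapse_identical(prune_features(m))
        b = prune_features(collapse_identical(m))
        assert a.feature_ids == b.feature_ids
        assert a.values.equals(b.values)


class TestAssemble:
    def make_inputs(self):
        df = pd.DataFrame(
            {"gB": [1, 0], "gA": [0, 1]}, index=["s1", "s2"]
        )
        matrix = FeatureMatrix("gene", df, pd.Series("x", index=df.index))
        vals = pd.DataFrame(
            -0.3, index=["s1", "s2"], columns=[c.label for c in ALL_CONDITIONS]
        )
        vals.iloc[1, 0] = np.nan
        return matrix, PhenotypeTable(vals)

    def test_row_and_predictor_counts(self):
        matrix, phen = self.make_inputs()
        data = assemble_dataset(matrix, phen)
        assert data.n_rows == 23
        assert len(data.feature_names) == 2 + 3
        # genomic columns sorted by name, condition features last
        assert data.feature_names == ["gA", "gB", "Temperature", "Volume", "Yeast"]

    def test_genomic_values_broadcast_per_strain(self):
        matrix, phen = self.make_inputs()
        data = assemble_dataset(matrix, phen)
        s1_rows = data.X[data.strain_of_row == "s1"]
        assert s1_rows["gB"].nunique() == 1

    def test_strain_order_invariance(self):
        matrix, phen = self.make_inputs()
        flipped = FeatureMatrix(
            "gene", matrix.values.iloc[::-1], matrix.subspecies.iloc[::-1]
        )
        a = assemble_dataset(matrix, phen)
        b = assemble_dataset(flipped, phen)
        assert a.X.sort_index().equals(b.X.sort_index())

    def test_missing_strain_rejected(self):
        matrix, phen = self.make_inputs()
        short = FeatureMatrix(
            "gene", matrix.values.iloc[:1], matrix.subspecies.iloc[:1]
        )
        with pytest.raises(ValueError, match="absent"):
            assemble_dataset(short, phen)


class TestPangenomeSummary:
    def test_threshold_assignment(self):
        m = binary_matrix({"core": 10, "shell": 9, "cloud": 1}, 10)
        s = pangenome_summary(m)
        assert (s.core, s.soft_core, s.shell, s.cloud) == (1, 0, 1, 1)

    def test_random_matrix_against_bruteforce(self):
        rng = np.random.default_rng(9)
        n = 200
        df = pd.DataFrame(
            (rng.random((n, 60)) < rng.uniform(0, 1, 60)).astype(int),
            index=[f"s{i}" for i in range(n)],
            columns=[f"g{j}" for j in range(60)],
        )
        m = FeatureMatrix("gene", df, pd.Series("x", index=df.index))
        s = pangenome_summary(m)
        brute = {"core": 0, "soft": 0, "shell": 0, "cloud": 0}
        for c in df.columns:
            p = df[c].mean()
            if p >= 0.99:
                brute["core"] += 1
            elif p >= 0.95:
                brute["soft"] += 1
            elif p >= 0.15:
                brute["shell"] += 1
            else:
                brute["cloud"] += 1
        assert (s.core, s.soft_core, s.shell, s.cloud) == tuple(brute.values())
        assert s.total == 60
        assert abs(sum(s.percentages().values()) - 100) < 0.01

    def test_nonbinary_rejected(self):
        df = pd.DataFrame({"f": [0, 2]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="binary"):
            pangenome_summary(FeatureMatrix("gene", df, pd.Series("x", index=df.index)))
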