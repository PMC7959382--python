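"""Genomic feature representations for strain collections.

Four representations of a strain's genome are supported: presence/absence of
pangenome gene families (Roary output), copy numbers of Pfam domains
(pfam_scan output), and counts of canonical 8-mers and 9-mers of the genomic
DNA.  Because assemblies are strand-agnostic, a k-mer and its reverse
complement are the same feature, represented by whichever of the pair comes
alphabetically first.

Feature matrices are pruned (features present, or absent, in more than 98% of
strains are dropped) and collapsed (features with identical strain profiles
are merged into one comma-named column) before model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import ALL_CONDITIONS, Condition, PhenotypeTable

Representation = Literal["gene", "pfam", "kmer8", "kmer9"]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype="S1")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet, case preserved as upper)."""
    comp = str.maketrans("ACGTacgt", "TGCATGCA")
    return seq.translate(comp)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The alphabetically first of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer.upper())
    k = kmer.upper()
    return k if k <= rc else rc


def _encode_seq(seq: str) -> np.ndarray:
    """Map a sequence to base codes A=0,C=1,G=2,T=3; non-ACGT become -1."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    """Base-4 decode integer k-mer codes back to strings."""
    digits = np.empty((len(codes), k), dtype=np.int64)
    c = codes.copy()
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = c & 3
        c >>= 2
    chars = _CODE_TO_BASE[digits]
    return [b"".join(row).decode("ascii") for row in chars]


def count_canonical_kmers(
    records: Sequence, k: int, as_codes: bool = False
) -> dict:
    """Count canonical k-mers over the contigs of one genome.

    Parameters
    ----------
    records
        An iterable of contigs; each element may be a plain string or any
        object with a ``seq`` attribute (e.g. a Bio.SeqRecord).
    k
        k-mer length; windows never span contig boundaries and windows
        containing non-ACGT characters are skipped.
    as_codes
        If true, keys are base-4 integer codes of the canonical k-mer
        (A=0..T=3) instead of strings — much faster when building matrices
        over many strains.

    Since lexicographic order of equal-length DNA strings coincides with
    numeric order of their base-4 codes, the canonical representative is
    simply ``min(code, revcomp_code)``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts: dict = {}
    all_codes = []
    for rec in records:
        seq = rec if isinstance(rec, str) else str(getattr(rec, "seq", rec))
        if len(seq) < k:
            continue
        codes = _encode_seq(seq)
        n_win = len(codes) - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        pw_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        fwd = windows @ pw_f
        # reverse complement: complement each base (3 - c), reverse the order
        pw_r = 4 ** np.arange(k, dtype=np.int64)
        rev = (3 - windows) @ pw_r
        canon = np.minimum(fwd, rev)[valid]
        all_codes.append(canon)
    if not all_codes:
        return counts
    canon = np.concatenate(all_codes)
    uniq, cnt = np.unique(canon, return_counts=True)
    if as_codes:
        return dict(zip(uniq.tolist(), cnt.tolist()))
    return dict(zip(_decode_codes(uniq, k), cnt.tolist()))


def kmer_count_matrix(
    genomes: Mapping[str, Sequence], k: int, subspecies: Mapping[str, str] | None = None
) -> "FeatureMatrix":
    """Canonical k-mer count matrix over a strain collection.

    ``genomes`` maps strain id to its contigs (strings or SeqRecords).
    """
    per_strain = {s: count_canonical_kmers(recs, k, as_codes=True) for s, recs in genomes.items()}
    all_codes = sorted(set().union(*per_strain.values())) if per_strain else []
    code_index = {c: i for i, c in enumerate(all_codes)}
    mat = np.zeros((len(per_strain), len(all_codes)), dtype=np.int64)
    strains = list(per_strain)
    for i, s in enumerate(strains):
        d = per_strain[s]
        if d:
            idx = np.fromiter((code_index[c] for c in d), dtype=np.int64, count=len(d))
            mat[i, idx] = np.fromiter(d.values(), dtype=np.int64, count=len(d))
    cols = _decode_codes(np.asarray(all_codes, dtype=np.int64), k) if all_codes else []
    df = pd.DataFrame(mat, index=strains, columns=cols)
    df.index.name = "strain"
    rep: Representation = "kmer8" if k == 8 else "kmer9" if k == 9 else f"kmer{k}"  # type: ignore[assignment]
    return FeatureMatrix(representation=rep, values=df, subspecies=_subspecies_series(strains, subspecies))


def _subspecies_series(strains: Sequence[str], subspecies: Mapping[str, str] | None) -> pd.Series:
    if subspecies is None:
        return pd.Series("unknown", index=list(strains), name="subspecies")
    return pd.Series({s: subspecies.get(s, "unknown") for s in strains}, name="subspecies")


@dataclass
class FeatureMatrix:
    """Strains × genomic features for one representation.

    ``values`` holds 0/1 presence (gene) or non-negative counts (pfam, kmer);
    ``collapse_map`` records, after :func:`collapse_identical`, which original
    feature ids each comma-joined column stands for.
    """

    representation: Representation
    values: pd.DataFrame
    subspecies: pd.Series
    collapse_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate strain ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        self.subspecies = self.subspecies.reindex(self.values.index).fillna("unknown")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# Roary's gene_presence_absence.csv carries these metadata columns before the
# per-strain locus-tag columns; a minimal dialect with just Gene/Annotation is
# also accepted.
ROARY_META_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
)


def build_gene_matrix(
    roary_table: pd.DataFrame, subspecies: Mapping[str, str] | None = None
) -> FeatureMatrix:
    """Binary gene-family presence/absence from a Roary-style table.

    Rows are gene groups, the ``Gene`` column names the group, and each
    per-strain column holds the locus tag(s) of that strain's copies (empty
    if absent).  A cell with several tab-joined locus tags (paralogs) still
    scores presence 1.
    """
    if "Gene" not in roary_table.columns:
        raise ValueError("Roary table must have a 'Gene' column")
    genes = roary_table["Gene"].astype(str)
    if genes.duplicated().any():
        dupes = genes[genes.duplicated()].tolist()
        raise ValueError(f"duplicated gene-group names: {dupes[:5]}")
    strain_cols = [c for c in roary_table.columns if c not in ROARY_META_COLUMNS]
    if not strain_cols:
        raise ValueError("no strain columns found in Roary table")
    cells = roary_table[strain_cols]
    present = cells.notna() & (cells.astype(str).apply(lambda s: s.str.strip()) != "")
    mat = present.astype(np.int64).T
    mat.columns = list(genes)
    mat.index.name = "strain"
    return FeatureMatrix(
        representation="gene",
        values=mat,
        subspecies=_subspecies_series(list(mat.index), subspecies),
    )


def build_domain_matrix(
    pfamscan_table: pd.DataFrame,
    gene_to_strain: Mapping[str, str],
    subspecies: Mapping[str, str] | None = None,
) -> FeatureMatrix:
    """Pfam-domain copy-number matrix from pfam_scan hits.

    ``pfamscan_table`` needs columns ``seq_id`` and ``hmm_acc`` (versioned
    accession, e.g. ``PF02502.13``); ``gene_to_strain`` maps each sequence id
    to its strain.  The cell for (strain, accession) is the total number of
    hits of that domain across all the strain's genes.
    """
    required = {"seq_id", "hmm_acc"}
    if not required <= set(pfamscan_table.columns):
        raise ValueError(f"pfam_scan table must have columns {sorted(required)}")
    strains = sorted(set(gene_to_strain.values()))
    unmapped = set(pfamscan_table["seq_id"]) - set(gene_to_strain)
    if unmapped:
        raise ValueError(f"sequence ids not mapped to any strain: {sorted(unmapped)[:5]}")
    if len(pfamscan_table):
        tbl = pfamscan_table.assign(strain=pfamscan_table["seq_id"].map(gene_to_strain))
        counts = tbl.groupby(["strain", "hmm_acc"]).size().unstack(fill_value=0)
        counts = counts.reindex(strains, fill_value=0)
    else:
        counts = pd.DataFrame(index=strains)
    counts = counts.astype(np.int64)
    counts.index.name = "strain"
    counts.columns.name = None
    return FeatureMatrix(
        representation="pfam",
        values=counts,
        subspecies=_subspecies_series(strains, subspecies),
    )


def prune_features(matrix: FeatureMatrix, threshold: float = 0.98) -> FeatureMatrix:
    """Drop near-constant features.

    A feature is removed iff the fraction of strains in which it is present
    (value > 0) is strictly greater than ``threshold``, or the fraction in
    which it is absent (value == 0) is strictly greater than ``threshold``.
    Idempotent by construction.
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    present_frac = (matrix.values > 0).mean(axis=0)
    keep = ~((present_frac > threshold) | ((1 - present_frac) > threshold))
    kept = matrix.values.loc[:, keep.to_numpy()]
    return FeatureMatrix(
        representation=matrix.representation,
        values=kept.copy(),
        subspecies=matrix.subspecies.copy(),
        collapse_map=dict(matrix.collapse_map),
    )


def collapse_identical(matrix: FeatureMatrix) -> FeatureMatrix:
    """Merge features with identical strain profiles into comma-named columns.

    Column order follows the first occurrence of each distinct profile;
    members are joined in original column order with no spaces.  The merged
    column keeps the shared value vector unchanged, and ``collapse_map``
    records membership for multi-member columns.
    """
    vals = matrix.values
    if vals.shape[1] == 0:
        return FeatureMatrix(matrix.representation, vals.copy(), matrix.subspecies.copy())
    arr = vals.to_numpy()
    # group columns by exact value profile, preserving first-seen order
    groups: dict[bytes, list[int]] = {}
    for j in range(arr.shape[1]):
        groups.setdefault(arr[:, j].tobytes(), []).append(j)
    new_cols, new_names, collapse_map = [], [], {}
    cols = list(vals.columns)
    for key, members in groups.items():
        name = ",".join(cols[j] for j in members)
        new_names.append(name)
        new_cols.append(arr[:, members[0]])
        if len(members) > 1:
            collapse_map[name] = [cols[j] for j in members]
    out = pd.DataFrame(
        np.column_stack(new_cols), index=vals.index, columns=new_names
    )
    out.index.name = vals.index.name
    return FeatureMatrix(
        representation=matrix.representation,
        values=out,
        subspecies=matrix.subspecies.copy(),
        collapse_map=collapse_map,
    )


#: names of the three condition predictors appended to every model dataset
CONDITION_FEATURES = ("Temperature", "Volume", "Yeast")


@dataclass
class AssembledDataset:
    """Model-ready rows: one per (strain, condition) with an observed V_max.

    Predictors are the genomic features (sorted by name, so that column order
    never depends on input order) followed by Temperature (numeric °C),
    Volume (deepwell=1) and Yeast (yeast extract=1).  ``strain_of_row`` maps
    each row back to its strain for strain-level splitting and permutation.
    """

    representation: Representation
    X: pd.DataFrame
    y: pd.Series  # V_max, h⁻¹
    strain_of_row: pd.Series
    genomic_features: list[str]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def subset_strains(self, strains: Sequence[str]) -> "AssembledDataset":
        mask = self.strain_of_row.isin(set(strains)).to_numpy()
        return AssembledDataset(
            representation=self.representation,
            X=self.X.iloc[mask].copy(),
            y=self.y.iloc[mask].copy(),
            strain_of_row=self.strain_of_row.iloc[mask].copy(),
            genomic_features=list(self.genomic_features),
        )


def assemble_dataset(matrix: FeatureMatrix, phenotypes: PhenotypeTable) -> AssembledDataset:
    """Join a feature matrix with the phenotype table into model rows.

    Each strain's genomic feature values are broadcast across its observed
    conditions; rows with missing V_max are dropped.
    """
    missing = set(phenotypes.strain_ids) - set(matrix.strain_ids)
    if missing:
        raise ValueError(f"strains in phenotypes absent from feature matrix: {sorted(missing)[:5]}")
    genomic = sorted(matrix.values.columns)
    long = phenotypes.values.stack()  # (strain, condition_label) -> vmax
    strains = long.index.get_level_values(0)
    labels = long.index.get_level_values(1)
    conds = [Condition.from_label(l) for l in labels]
    Xg = matrix.values.loc[strains, genomic].reset_index(drop=True)
    Xc = pd.DataFrame(
        {
            "Temperature": [c.temperature_C for c in conds],
            "Volume": [1 if c.volume == "DW" else 0 for c in conds],
            "Yeast": [1 if c.yeast == "YE" else 0 for c in conds],
        }
    )
    X = pd.concat([Xg, Xc], axis=1).astype(float)
    row_index = pd.Index([f"{s}@{l}" for s, l in zip(strains, labels)], name="row")
    X.index = row_index
    y = pd.Series(long.to_numpy(), index=row_index, name="vmax")
    return AssembledDataset(
        representation=matrix.representation,
        X=X,
        y=y,
        strain_of_row=pd.Series(list(strains), index=row_index, name="strain"),
        genomic_features=genomic,
    )


@dataclass
class PangenomeSummary:
    """Gene counts per pangenome category.

    Categories by presence fraction p: core p ≥ 0.99, soft core
    0.95 ≤ p < 0.99, shell 0.15 ≤ p < 0.95, cloud p < 0.15.
    """

    core: int
    soft_core: int
    shell: int
    cloud: int

    @property
    def total(self) -> int:
        return self.core + self.soft_core + self.shell + self.cloud

    def percentages(self) -> dict[str, float]:
        t = self.total
        return {
            "core": 100 * self.core / t,
            "soft_core": 100 * self.soft_core / t,
            "shell": 100 * self.shell / t,
            "cloud": 100 * self.cloud / t,
        }


def pangenome_summary(presence: FeatureMatrix) -> PangenomeSummary:
    """Classify gene families into core / soft core / shell / cloud."""
    vals = presence.values.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("pangenome summary requires a binary presence matrix")
    p = vals.mean(axis=0)
    return PangenomeSummary(
        core=int((p >= 0.99).sum()),
        soft_core=int(((p >= 0.95) & (p < 0.99)).sum()),
        shell=int(((p >= 0.15) & (p < 0.95)).sum()),
        cloud=int((p < 0.15).sum()),
    )
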