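"""Feature-importance analysis and cross-representation consensus.

Per-prediction Shapley attributions (see :mod:`acidforest._treeshap`) rank the
features of each fitted model.  Because V_max is negative for acidifying
cultures, a *negative* attribution pushes the prediction toward *faster*
acidification; importance tables therefore carry an explicit
``direction`` column ("faster"/"slower") instead of a bare sign.

Features of the k-mer and Pfam models do not correspond one-to-one to genes:
a domain occurs in several genes and a k-mer can sit in several genes (or
outside genes entirely).  The mapping helpers resolve k-mers and domain
accessions to the genes that carry them, so that high-importance features
from different representations can be grouped into a consensus report of the
biological entities they implicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._treeshap import forest_shap_values
from .features import AssembledDataset, CONDITION_FEATURES, reverse_complement
from .model import ModelBundle


@dataclass
class ImportanceTable:
    """Features ranked by mean |Shapley value| over the explained rows."""

    representation: str
    table: pd.DataFrame  # columns: feature, mean_abs_shap, direction, rank
    base_value: float
    shap_values: pd.DataFrame | None = None  # rows × features, optional

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.table.head(n)

    def top_features(self, n: int = 20) -> list[str]:
        return list(self.table["feature"].head(n))


def compute_importances(
    model: ModelBundle,
    data: AssembledDataset,
    top_n: int = 20,
    keep_shap: bool = True,
) -> ImportanceTable:
    """Shapley attributions of every prediction, ranked by mean |value|.

    ``direction`` summarises, per feature, whether a *higher* feature value
    pushes predictions toward faster acidification (more negative V_max,
    negative attribution) or slower; features whose value never varies over
    the explained rows get direction "n/a".
    """
    if model.feature_names != data.feature_names:
        raise ValueError("model and data predictors do not match")
    if data.n_rows < 1:
        raise ValueError("need at least one row to explain")
    X = data.X.to_numpy()
    phi, base = forest_shap_values(model.regressor, X)
    mean_abs = np.abs(phi).mean(axis=0)
    directions = []
    for j, name in enumerate(data.feature_names):
        xj = X[:, j]
        if np.ptp(xj) == 0 or np.ptp(phi[:, j]) == 0:
            directions.append("n/a")
        else:
            # sign of the value↔attribution relationship
            corr = np.corrcoef(xj, phi[:, j])[0, 1]
            directions.append("faster" if corr < 0 else "slower")
    order = np.argsort(-mean_abs, kind="stable")
    table = pd.DataFrame(
        {
            "feature": [data.feature_names[j] for j in order],
            "mean_abs_shap": mean_abs[order],
            "direction": [directions[j] for j in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    shap_df = (
        pd.DataFrame(phi, index=data.X.index, columns=data.feature_names)
        if keep_shap
        else None
    )
    return ImportanceTable(
        representation=model.representation,
        table=table,
        base_value=base,
        shap_values=shap_df,
    )


@dataclass
class KmerGeneMap:
    """Genes carrying a k-mer (or its reverse complement), with strain counts."""

    kmer: str
    hits: dict[str, int]  # gene id -> number of strains whose copy contains it

    def genes(self, min_strains: int = 0) -> list[str]:
        return [g for g, n in sorted(self.hits.items(), key=lambda kv: -kv[1]) if n >= min_strains]


def map_kmer_to_genes(
    kmer: str,
    gene_sequences: Mapping[str, Mapping[str, str]],
    min_strains: int = 0,
) -> KmerGeneMap:
    """Locate a k-mer in per-strain gene sequences.

    ``gene_sequences`` maps gene id → {strain id → that strain's copy of the
    gene}.  Both the k-mer and its reverse complement are searched, since
    assemblies are strand-agnostic.  ``min_strains`` drops genes supported by
    fewer strains (a reporting threshold of 40 strains is used for the
    published tables; 0 keeps everything).
    """
    kmer = kmer.upper()
    if not set(kmer) <= set("ACGT"):
        raise ValueError("k-mer must be over the ACGT alphabet")
    rc = reverse_complement(kmer)
    hits: dict[str, int] = {}
    for gene, copies in gene_sequences.items():
        n = sum(1 for seq in copies.values() if kmer in seq.upper() or rc in seq.upper())
        if n > 0:
            hits[gene] = n
    if min_strains:
        hits = {g: n for g, n in hits.items() if n >= min_strains}
    return KmerGeneMap(kmer=kmer, hits=hits)


def map_domain_to_genes(
    domain_accession: str,
    pfamscan_table: pd.DataFrame,
    seq_to_gene: Mapping[str, str] | None = None,
    min_occurrences: int = 0,
) -> dict[str, int]:
    """Genes carrying a Pfam domain, with occurrence counts.

    ``seq_to_gene`` maps the table's sequence ids to gene labels (identity if
    omitted).  ``min_occurrences`` drops genes accounting for few hits (the
    published tables use a threshold of 10 occurrences; 0 keeps everything).
    Counts conserve the table: summed over genes they equal the accession's
    total number of hits.
    """
    rows = pfamscan_table[pfamscan_table["hmm_acc"] == domain_accession]
    if not len(rows):
        return {}
    genes = rows["seq_id"].map(lambda s: seq_to_gene.get(s, s) if seq_to_gene else s)
    counts = genes.value_counts().to_dict()
    if min_occurrences:
        counts = {g: int(n) for g, n in counts.items() if n >= min_occurrences}
    return {g: int(n) for g, n in counts.items()}


@dataclass
class ConsensusEntry:
    """One biological entity and the representations whose top features implicate it."""

    label: str
    representations: set[str] = field(default_factory=set)
    features: dict[str, list[str]] = field(default_factory=dict)  # representation -> feature ids

    @property
    def consensus(self) -> bool:
        return len(self.representations) >= 2


@dataclass
class ConsensusReport:
    entries: list[ConsensusEntry]

    def consensus_labels(self) -> list[str]:
        return [e.label for e in self.entries if e.consensus]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [e.label for e in self.entries],
                "representations": [",".join(sorted(e.representations)) for e in self.entries],
                "consensus": [e.consensus for e in self.entries],
                "features": [
                    "; ".join(f"{r}:{'|'.join(f)}" for r, f in sorted(e.features.items()))
                    for e in self.entries
                ],
            }
        )


def _expand_feature(feature: str, collapse_map: Mapping[str, list[str]] | None) -> list[str]:
    if collapse_map and feature in collapse_map:
        return list(collapse_map[feature])
    return feature.split(",") if "," in feature else [feature]


def build_consensus(
    importances: Mapping[str, ImportanceTable],
    kmer_maps: Mapping[str, KmerGeneMap] | None = None,
    domain_maps: Mapping[str, Mapping[str, int]] | None = None,
    collapse_maps: Mapping[str, Mapping[str, list[str]]] | None = None,
    top_n: int = 20,
    include_conditions: bool = False,
) -> ConsensusReport:
    """Group the top features of ≥2 representations by the genes they implicate.

    Gene-model features resolve to themselves (after expanding collapsed
    columns); Pfam accessions resolve through ``domain_maps`` and k-mers
    through ``kmer_maps``.  A label supported by two or more representations
    is flagged as consensus.
    """
    if len(importances) < 2:
        raise ValueError("consensus requires importances from at least 2 representations")
    kmer_maps = kmer_maps or {}
    domain_maps = domain_maps or {}
    collapse_maps = collapse_maps or {}
    entries: dict[str, ConsensusEntry] = {}

    def add(label: str, rep: str, feature: str) -> None:
        e = entries.setdefault(label, ConsensusEntry(label=label))
        e.representations.add(rep)
        e.features.setdefault(rep, [])
        if feature not in e.features[rep]:
            e.features[rep].append(feature)

    for rep, imp in importances.items():
        cmap = collapse_maps.get(rep)
        for feature in imp.top_features(top_n):
            if feature in CONDITION_FEATURES:
                if include_conditions:
                    add(feature, rep, feature)
                continue
            for part in _expand_feature(feature, cmap):
                if rep == "gene":
                    add(part, rep, feature)
                elif rep == "pfam":
                    genes = domain_maps.get(part, {})
                    for g in genes:
                        add(g, rep, feature)
                elif rep in ("kmer8", "kmer9"):
                    km = kmer_maps.get(part)
                    if km is not None:
                        for g in km.hits:
                            add(g, rep, feature)
    ordered = sorted(entries.values(), key=lambda e: (-len(e.representations), e.label))
    return ConsensusReport(entries=ordered)
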