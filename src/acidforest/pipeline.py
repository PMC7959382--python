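"""End-to-end pipeline: featurize → split → train → evaluate → signal tests → importance.

A single :class:`PipelineConfig` names either a synthetic population
(``sim``) or input files, the representations to run, and every seed, so two
runs with identical configuration produce identical reports.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as afio
from .features import (
    AssembledDataset,
    FeatureMatrix,
    assemble_dataset,
    build_domain_matrix,
    build_gene_matrix,
    collapse_identical,
    kmer_count_matrix,
    prune_features,
)
from .importance import build_consensus, compute_importances, map_domain_to_genes, map_kmer_to_genes
from .kinetics import PhenotypeTable
from .model import PRESETS, HyperparameterGrid, evaluate, split_by_strain, train_model, tune_hyperparameters
from .signal_tests import feature_permutation_test, profile_switch_test
from .synthetic import SimConfig, SyntheticTruth, generate_phenotypes, generate_population

#: default forest settings for synthetic populations (the published presets
#: were tuned on the real 342-strain data and are available via params="preset")
SYNTHETIC_PARAMS: dict = {
    "n_estimators": 200,
    "max_depth": None,
    "min_samples_split": 4,
    "min_samples_leaf": 2,
    "oob_score": False,
}

REPRESENTATIONS = ("gene", "pfam", "kmer8", "kmer9")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    # either a synthetic population ...
    sim: SimConfig | None = None
    # ... or input files
    fasta_dir: str | None = None
    roary_path: str | None = None
    pfam_path: str | None = None
    phenotype_path: str | None = None
    subspecies: Mapping[str, str] | None = None

    representations: tuple[str, ...] = REPRESENTATIONS
    prune_threshold: float = 0.98
    params: str | Mapping = "default"  # "default" | "preset" | "search" | explicit dict
    grid: HyperparameterGrid | None = None
    split_fraction: float = 0.75
    split_seed: int = 1
    forest_seed: int = 1
    run_signal_tests: tuple[str, ...] = ("gene", "pfam")
    perm_reps: int = 200
    run_importance: bool = True
    importance_top_n: int = 20
    importance_max_rows: int | None = 300  # cap on explained test rows
    consensus: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.representations) - set(REPRESENTATIONS)
        if unknown:
            raise ValueError(f"unknown representations: {sorted(unknown)}")


def _log(msg: str) -> None:
    print(f"[acidforest] {msg}", file=sys.stderr, flush=True)


def build_matrices(
    config: PipelineConfig,
) -> tuple[dict[str, FeatureMatrix], PhenotypeTable, SyntheticTruth | None, dict]:
    """Stage 1: obtain raw (unpruned) feature matrices and phenotypes."""
    truth = None
    extras: dict = {}
    if config.sim is not None:
        _log(f"simulating population (n_strains={config.sim.n_strains}, seed={config.sim.seed})")
        genomes, truth = generate_population(config.sim)
        phenotypes = generate_phenotypes(truth, config.sim)
        subspecies = truth.subspecies
        roary = None
        pfam_table = None
        gene_to_strain = None
        extras["gene_sequences"] = truth.gene_sequences
        if "gene" in config.representations:
            genes = list(truth.presence.columns)
            cols = {"Gene": genes, "Annotation": [""] * len(genes)}
            for s in truth.presence.index:
                pres = truth.presence.loc[s]
                cols[s] = [f"{s}|{g}" if pres[g] else "" for g in genes]
            roary = pd.DataFrame(cols)
        if "pfam" in config.representations:
            rows = []
            for g, accs in truth.domain_assignment.items():
                for s in truth.presence.index:
                    if truth.presence.at[s, g]:
                        rows.extend((f"{s}|{g}", acc) for acc in accs)
            pfam_table = pd.DataFrame(rows, columns=["seq_id", "hmm_acc"])
            gene_to_strain = {sid: sid.split("|")[0] for sid in pfam_table["seq_id"].unique()}
            extras["pfam_table"] = pfam_table
    else:
        if config.phenotype_path is None:
            raise FileNotFoundError("stage featurize: no phenotype file configured")
        phenotypes = afio.read_phenotypes(config.phenotype_path)
        subspecies = dict(config.subspecies or {})
        genomes = None
        roary = None
        pfam_table = None
        gene_to_strain = None
        if {"kmer8", "kmer9"} & set(config.representations):
            if config.fasta_dir is None:
                raise FileNotFoundError("stage featurize: k-mer representations need --fasta-dir")
            genomes = afio.read_fasta_dir(config.fasta_dir)
            extras["gene_sequences"] = _gene_sequences_from_records(genomes)
        if "gene" in config.representations:
            if config.roary_path is None:
                raise FileNotFoundError("stage featurize: gene representation needs --roary")
            roary = afio.read_roary(config.roary_path)
        if "pfam" in config.representations:
            if config.pfam_path is None:
                raise FileNotFoundError("stage featurize: pfam representation needs --pfam")
            pfam_table = afio.read_pfamscan(config.pfam_path)
            gene_to_strain = {sid: sid.split("|")[0] for sid in pfam_table["seq_id"].unique()}
            extras["pfam_table"] = pfam_table

    matrices: dict[str, FeatureMatrix] = {}
    for rep in config.representations:
        t0 = time.time()
        if rep == "gene":
            matrices[rep] = build_gene_matrix(roary, subspecies=subspecies)
        elif rep == "pfam":
            matrices[rep] = build_domain_matrix(pfam_table, gene_to_strain, subspecies=subspecies)
        elif rep in ("kmer8", "kmer9"):
            matrices[rep] = kmer_count_matrix(genomes, k=int(rep[-1]), subspecies=subspecies)
        _log(f"built {rep} matrix: {matrices[rep].values.shape} ({time.time()-t0:.1f}s)")
    return matrices, phenotypes, truth, extras


def _gene_sequences_from_records(genomes: Mapping[str, list]) -> dict[str, dict[str, str]]:
    """Recover gene→strain→sequence when record ids follow 'strain|gene'."""
    out: dict[str, dict[str, str]] = {}
    for strain, recs in genomes.items():
        for rec in recs:
            if "|" not in rec.id:
                return {}
            gene = rec.id.split("|", 1)[1]
            out.setdefault(gene, {})[strain] = str(rec.seq)
    return out


def preprocess(matrix: FeatureMatrix, threshold: float = 0.98) -> FeatureMatrix:
    """Prune near-constant features, then collapse identical profiles."""
    return collapse_identical(prune_features(matrix, threshold=threshold))


def _subsample_rows(data: AssembledDataset, max_rows: int | None, seed: int) -> AssembledDataset:
    """Deterministic row subsample used to bound the attribution runtime."""
    if max_rows is None or data.n_rows <= max_rows:
        return data
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(data.n_rows, size=max_rows, replace=False))
    return AssembledDataset(
        representation=data.representation,
        X=data.X.iloc[idx].copy(),
        y=data.y.iloc[idx].copy(),
        strain_of_row=data.strain_of_row.iloc[idx].copy(),
        genomic_features=list(data.genomic_features),
    )


def _resolve_params(config: PipelineConfig, rep: str, train_data: AssembledDataset) -> dict:
    if isinstance(config.params, Mapping):
        p = config.params.get(rep, config.params) if rep in config.params else config.params
        return dict(p)
    if config.params == "preset":
        return dict(PRESETS[rep])
    if config.params == "search":
        return tune_hyperparameters(train_data, config.grid, seed=config.forest_seed)
    if config.params == "default":
        return dict(SYNTHETIC_PARAMS)
    raise ValueError(f"unknown params mode {config.params!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; return a JSON-serialisable report."""
    report: dict = {
        "config": {
            "representations": list(config.representations),
            "prune_threshold": config.prune_threshold,
            "split_fraction": config.split_fraction,
            "split_seed": config.split_seed,
            "forest_seed": config.forest_seed,
            "perm_reps": config.perm_reps,
            "params_mode": config.params if isinstance(config.params, str) else "explicit",
            "simulated": config.sim is not None,
        },
        "representations": {},
    }
    if config.sim is not None:
        report["config"]["sim_seed"] = config.sim.seed
        report["config"]["n_strains"] = config.sim.n_strains

    matrices, phenotypes, truth, extras = build_matrices(config)
    strains = phenotypes.strain_ids
    split = split_by_strain(strains, fraction=config.split_fraction, seed=config.split_seed)
    report["split"] = {"n_train": len(split.train), "n_test": len(split.test)}

    importances = {}
    collapse_maps = {}
    bundles = {}
    datasets = {}
    for rep in config.representations:
        stage = f"representation {rep}"
        t0 = time.time()
        mat = preprocess(matrices[rep], threshold=config.prune_threshold)
        collapse_maps[rep] = mat.collapse_map
        data = assemble_dataset(mat, phenotypes)
        train_data = data.subset_strains(split.train)
        test_data = data.subset_strains(split.test)
        params = _resolve_params(config, rep, train_data)
        bundle = train_model(train_data, params, seed=config.forest_seed, split=split)
        scores = evaluate(bundle, test_data)
        rep_report = {
            "n_features_raw": matrices[rep].n_features,
            "n_features_model": mat.n_features,
            "n_train_rows": train_data.n_rows,
            "n_test_rows": test_data.n_rows,
            "params": {k: v for k, v in params.items()},
            "scores": {
                "pearson": scores.pearson,
                "explained_variance": scores.explained_variance,
                "rmse": scores.rmse,
            },
        }
        _log(f"{stage}: {mat.n_features} features, test {scores} ({time.time()-t0:.1f}s)")
        if rep in config.run_signal_tests and config.perm_reps > 0:
            fp = feature_permutation_test(bundle, test_data, n_reps=config.perm_reps, seed=config.forest_seed)
            ps = profile_switch_test(bundle, test_data, n_reps=config.perm_reps, seed=config.forest_seed)
            rep_report["signal_tests"] = {
                "feature_permute": fp.summary(),
                "profile_switch": ps.summary(),
            }
            _log(
                f"{stage}: permutation nulls "
                f"feature_permute outside_95={fp.outside_95}, profile_switch outside_95={ps.outside_95}"
            )
        if config.run_importance:
            explain_data = _subsample_rows(test_data, config.importance_max_rows, config.forest_seed)
            imp = compute_importances(bundle, explain_data, top_n=config.importance_top_n)
            importances[rep] = imp
            rep_report["top_features"] = [
                {
                    "feature": r.feature,
                    "mean_abs_shap": float(r.mean_abs_shap),
                    "direction": r.direction,
                }
                for r in imp.top(config.importance_top_n).itertuples()
            ]
        bundles[rep] = bundle
        datasets[rep] = (train_data, test_data)
        report["representations"][rep] = rep_report

    if config.consensus and len(importances) >= 2:
        gene_seqs = extras.get("gene_sequences") or {}
        kmer_maps = {}
        domain_maps = {}
        for rep, imp in importances.items():
            for feature in imp.top_features(config.importance_top_n):
                for part in feature.split(","):
                    if rep in ("kmer8", "kmer9") and gene_seqs and set(part) <= set("ACGT"):
                        kmer_maps[part] = map_kmer_to_genes(part, gene_seqs)
                    elif rep == "pfam" and "pfam_table" in extras:
                        domain_maps[part] = map_domain_to_genes(
                            part,
                            extras["pfam_table"],
                            seq_to_gene={
                                sid: sid.split("|", 1)[1]
                                for sid in extras["pfam_table"]["seq_id"].unique()
                            },
                        )
        consensus = build_consensus(
            importances,
            kmer_maps=kmer_maps,
            domain_maps=domain_maps,
            collapse_maps=collapse_maps,
            top_n=config.importance_top_n,
        )
        report["consensus"] = consensus.as_frame().to_dict(orient="records")

    report["_objects"] = {
        "bundles": bundles,
        "datasets": datasets,
        "importances": importances,
        "truth": truth,
        "split": split,
    }
    return report
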