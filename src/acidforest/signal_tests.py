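"""Permutation tests of genomic-signal reliance, and learning curves.

A model could predict V_max from the condition features alone (temperature,
volume, yeast extract), ignoring the genome.  Two permutation nulls probe
this: *feature permutation* independently shuffles every genomic feature
column across test strains (destroying both genome–phenotype and
feature–feature structure), while the *profile switch* reassigns whole
genomic profiles among test strains (destroying genome–phenotype links but
keeping within-genome feature correlations intact).  Both act at the strain
level — a strain keeps one (shuffled) genome across all its condition rows —
and never touch the target values or the condition features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .features import AssembledDataset
from .model import EvaluationScores, ModelBundle, evaluate, score_predictions, train_model


@dataclass
class PermutationTestResult:
    """Outcome of one permutation null against the original test PC."""

    mode: Literal["feature_permute", "profile_switch"]
    original_pc: float
    null_pcs: np.ndarray
    seed: int

    @property
    def null_low(self) -> float:
        """2.5th percentile of the null PCs."""
        return float(np.percentile(self.null_pcs, 2.5))

    @property
    def null_high(self) -> float:
        """97.5th percentile of the null PCs."""
        return float(np.percentile(self.null_pcs, 97.5))

    @property
    def outside_95(self) -> bool:
        """Whether the original PC lies outside the null's 95% interval."""
        return self.original_pc > self.null_high or self.original_pc < self.null_low

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "original_pc": self.original_pc,
            "null_pc_2.5": self.null_low,
            "null_pc_97.5": self.null_high,
            "outside_95": self.outside_95,
            "n_reps": int(len(self.null_pcs)),
            "seed": self.seed,
        }


def _strain_level_genome(test: AssembledDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """One genomic-feature row per test strain, plus each row's strain index."""
    strains = list(dict.fromkeys(test.strain_of_row))  # stable order
    strain_pos = {s: i for i, s in enumerate(strains)}
    row_strain_idx = np.array([strain_pos[s] for s in test.strain_of_row], dtype=np.intp)
    genomic = test.X[test.genomic_features]
    per_strain = genomic.groupby(test.strain_of_row.to_numpy(), sort=False).first()
    per_strain = per_strain.loc[strains]
    # every row of a strain must carry the same genome for strain-level
    # permutation to be meaningful
    if not np.array_equal(per_strain.to_numpy()[row_strain_idx], genomic.to_numpy()):
        raise ValueError("genomic features differ across a strain's rows")
    return per_strain, row_strain_idx


def make_null_genome(
    G: np.ndarray,
    mode: Literal["feature_permute", "profile_switch"],
    rng: np.random.Generator,
) -> np.ndarray:
    """One null draw of the strain-level genomic matrix.

    ``feature_permute`` permutes every column independently across strains
    (each column keeps its multiset of values); ``profile_switch`` applies a
    single row permutation (each whole genomic profile survives, reassigned
    to a different strain).
    """
    if mode == "feature_permute":
        Gp = np.empty_like(G)
        for j in range(G.shape[1]):
            Gp[:, j] = G[rng.permutation(G.shape[0]), j]
        return Gp
    if mode == "profile_switch":
        return G[rng.permutation(G.shape[0]), :]
    raise ValueError(f"unknown mode {mode!r}")


def _permutation_test(
    model: ModelBundle,
    test: AssembledDataset,
    mode: Literal["feature_permute", "profile_switch"],
    n_reps: int,
    seed: int,
) -> PermutationTestResult:
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if model.feature_names != test.feature_names:
        raise ValueError("model and test predictors do not match")
    y = test.y.to_numpy()
    per_strain, row_idx = _strain_level_genome(test)
    G = per_strain.to_numpy()  # strains × genomic features
    n_strains = G.shape[0]
    X_full = test.X.to_numpy().copy()
    gen_cols = np.array([test.feature_names.index(c) for c in test.genomic_features], dtype=np.intp)

    original_pc = float(pearsonr(y, model.regressor.predict(test.X.to_numpy())).statistic)

    rng = np.random.default_rng(seed)
    null_pcs = np.empty(n_reps, dtype=float)
    # batch replicates into one predict call per chunk; per-call overhead of a
    # several-hundred-tree forest would otherwise dominate the runtime
    n_rows, n_feat = X_full.shape
    chunk = max(1, min(n_reps, int(2e7 // (n_rows * n_feat)) or 1))
    for start in range(0, n_reps, chunk):
        reps = range(start, min(start + chunk, n_reps))
        Xb = np.repeat(X_full[None, :, :], len(reps), axis=0)
        for b, _ in enumerate(reps):
            Gp = make_null_genome(G, mode, rng)
            Xb[b, :, gen_cols] = Gp[row_idx, :].T
        pred = model.regressor.predict(Xb.reshape(-1, n_feat)).reshape(len(reps), n_rows)
        for b, r in enumerate(reps):
            null_pcs[r] = pearsonr(y, pred[b]).statistic
    return PermutationTestResult(mode=mode, original_pc=original_pc, null_pcs=null_pcs, seed=seed)


def feature_permutation_test(
    model: ModelBundle, test: AssembledDataset, n_reps: int = 1000, seed: int = 1
) -> PermutationTestResult:
    """Null that independently permutes each genomic feature across strains."""
    return _permutation_test(model, test, "feature_permute", n_reps, seed)


def profile_switch_test(
    model: ModelBundle, test: AssembledDataset, n_reps: int = 1000, seed: int = 1
) -> PermutationTestResult:
    """Null that reassigns whole genomic profiles among strains."""
    return _permutation_test(model, test, "profile_switch", n_reps, seed)


@dataclass
class LearningCurveResult:
    """Test scores as a function of training-set size (strains)."""

    sizes: list[int]
    scores: list[EvaluationScores]  # mean over repetitions, per size
    reps_per_size: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_strains": self.sizes,
                "pearson": [s.pearson for s in self.scores],
                "explained_variance": [s.explained_variance for s in self.scores],
                "rmse": [s.rmse for s in self.scores],
            }
        )


def learning_curve(
    train: AssembledDataset,
    test: AssembledDataset,
    sizes: Sequence[int],
    params: Mapping,
    reps_per_size: int = 5,
    seed: int = 1,
) -> LearningCurveResult:
    """Retrain on random strain subsets of each size; evaluate on the fixed test set."""
    sizes = sorted(sizes)
    train_strains = list(dict.fromkeys(train.strain_of_row))
    if sizes and sizes[-1] > len(train_strains):
        raise ValueError(
            f"requested size {sizes[-1]} exceeds the {len(train_strains)} training strains"
        )
    if reps_per_size < 1:
        raise ValueError("reps_per_size must be >= 1")
    rng = np.random.default_rng(seed)
    mean_scores = []
    y_test = test.y.to_numpy()
    for size in sizes:
        reps = []
        for _ in range(reps_per_size):
            if size == len(train_strains):
                chosen = train_strains
            else:
                chosen = [train_strains[i] for i in rng.choice(len(train_strains), size, replace=False)]
            sub = train.subset_strains(chosen)
            bundle = train_model(sub, params, seed=seed)
            reps.append(score_predictions(y_test, bundle.predict(test.X)))
        mean_scores.append(
            EvaluationScores(
                pearson=float(np.mean([s.pearson for s in reps])),
                explained_variance=float(np.mean([s.explained_variance for s in reps])),
                rmse=float(np.mean([s.rmse for s in reps])),
            )
        )
    return LearningCurveResult(sizes=list(sizes), scores=mean_scores, reps_per_size=reps_per_size, seed=seed)
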