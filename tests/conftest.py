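"""Shared fixtures: small synthetic populations and one full pipeline run.

The expensive fixtures are session-scoped so the planted-signal pipeline is
executed once and reused by the signal-test, importance and acceptance
suites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import acidforest as af


@pytest.fixture(scope="session")
def small_cfg() -> af.SimConfig:
    return af.SimConfig(
        n_strains=30,
        n_core_genes=8,
        n_accessory_genes=25,
        gene_length_bp=(150, 300),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    genomes, truth = af.generate_population(small_cfg)
    phenotypes = af.generate_phenotypes(truth, small_cfg)
    return genomes, truth, phenotypes


@pytest.fixture(scope="session")
def default_pipeline_report():
    """Planted-signal pipeline at the reference study conditions (n=200)."""
    config = af.PipelineConfig(
        sim=af.SimConfig(seed=1),
        representations=("gene", "pfam"),
        perm_reps=200,
        split_seed=1,
        forest_seed=1,
    )
    return af.run_pipeline(config)


def sliding_window_slopes(times: np.ndarray, values: np.ndarray, w: int) -> list[float]:
    """Independent brute-force oracle: least-squares slope of every window."""
    slopes = []
    for start in range(len(times) - w + 1):
        t = times[start : start + w]
        y = values[start : start + w]
        tbar, ybar = t.mean(), y.mean()
        slopes.append(float(((t - tbar) * (y - ybar)).sum() / ((t - tbar) ** 2).sum()))
    return slopes
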