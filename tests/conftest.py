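"""Shared fixtures: tiny hand-built matrices plus session-scoped
simulation runs used by the slower recovery tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from trajrank.core_io import CountForm, CountMatrix
from trajrank.pipeline import PipelineConfig, run_pipeline
from trajrank.ranking import top_candidates
from trajrank.simulate import SimConfig, simulate_lineage, tiny_config
from trajrank.trajectory import TrajectorySet


def make_count_matrix(array, barcodes=None, genes=None) -> CountMatrix:
    array = np.asarray(array)
    n, m = array.shape
    barcodes = barcodes or [f"c{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(m)]
    return CountMatrix(barcodes, genes, sp.csr_matrix(array))


def make_trajectory_set(norm: pd.DataFrame, log: pd.DataFrame | None = None) -> TrajectorySet:
    """TrajectorySet from an explicit gene x bin NORM matrix."""
    from trajrank.core_io import make_count_forms

    if log is None:
        log = np.log1p(norm)
    forms, zero = make_count_forms(norm, log)
    B = norm.shape[1]
    return TrajectorySet(
        n_bins=B,
        edges=np.linspace(0.0, 1.0, B + 1),
        occupancy=np.ones(B, dtype=int),
        forms=forms,
        interpolated=np.zeros(B, dtype=bool),
        zero_genes=zero,
    )


@pytest.fixture
def small_counts() -> CountMatrix:
    return make_count_matrix(
        [[5, 5, 0, 1], [0, 2, 3, 0], [1, 0, 0, 4]],
        genes=["mt-Nd1", "GeneA", "GeneB", "Malat1"],
    )


@pytest.fixture(scope="session")
def tiny_sim():
    cm, meta, truth = simulate_lineage(tiny_config(seed=0))
    return cm, meta, truth


@pytest.fixture(scope="session")
def tiny_run(tiny_sim):
    cm, meta, truth = tiny_sim
    cfg = PipelineConfig(seed=0, n_bins=20, n_pcs=20, n_hvg=150, n_comps=10)
    return run_pipeline(cfg, cm, meta), truth


def _one_default_run(seed: int, shuffled: bool) -> dict:
    cm, meta, truth = simulate_lineage(SimConfig(seed=seed), shuffle_planted=shuffled)
    result = run_pipeline(PipelineConfig(seed=seed), cm, meta)
    planted = set(truth.loc[truth["is_coreg"], "gene"])
    top50 = set(top_candidates(result.rank_table, 50))
    rho = spearmanr(
        result.meta["pseudotime"], result.meta["true_time"]
    ).statistic
    return {
        "seed": seed,
        "shuffled": shuffled,
        "result": result,
        "truth": truth,
        "planted": planted,
        "top50": top50,
        "recovered": len(top50 & planted),
        "pseudotime_spearman": float(rho),
    }


@pytest.fixture(scope="session")
def default_runs() -> list[dict]:
    """Full pipeline on the default simulator, three seeds."""
    return [_one_default_run(seed, False) for seed in (1, 2, 3)]


@pytest.fixture(scope="session")
def shuffled_runs() -> list[dict]:
    """Negative control: planted genes decoupled from the reference."""
    return [_one_default_run(seed, True) for seed in (1, 2, 3)]
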