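"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from mbcontinuum.core import LabeledMatrix, assign_quantile
from mbcontinuum.synthetic import ScConfig, SimulationConfig, generate_bulk, generate_methylation


@pytest.fixture(scope="session")
def small_bulk():
    """120-sample / 600-gene noisy cohort with four planted programs."""
    cfg = SimulationConfig(
        n_samples=120, n_genes=600, program_size=60, n_cpgs=600,
        n_switch_cpgs=60, n_block_cpgs=30, seed=42,
        sc=ScConfig(cells_per_patient=25, depth=2000),
    )
    return cfg, generate_bulk(cfg)


@pytest.fixture(scope="session")
def noiseless_bulk():
    """Same structure without count noise (exact mean model)."""
    cfg = SimulationConfig(
        n_samples=120, n_genes=600, program_size=60, count_noise=False, seed=42,
    )
    return cfg, generate_bulk(cfg)


@pytest.fixture(scope="session")
def methylation_cohort():
    """100 samples with uniform-ish scores and switch/block/null CpGs."""
    rng = np.random.default_rng(7)
    scores = {f"S{i:03d}": float(u) for i, u in enumerate(rng.uniform(0, 1, 100))}
    cfg = SimulationConfig(
        n_cpgs=800, n_switch_cpgs=80, n_block_cpgs=40, seed=7
    )
    beta, truth = generate_methylation(cfg, scores)
    quantiles = {s: assign_quantile(v) for s, v in scores.items()}
    return beta, truth, scores, quantiles


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 5, size=(30, 12))
    return LabeledMatrix(
        X, [f"g{i}" for i in range(30)], [f"s{j}" for j in range(12)]
    )
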