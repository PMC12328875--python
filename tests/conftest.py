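"""Shared fixtures: tiny synthetic cohorts and pipeline runs.

Everything is generated programmatically at test time; nothing is read from
outside the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from neoquant.pipeline import run
from neoquant.simulate import SimulationConfig, simulate_cohort

AA = "ACDEFGHIKLMNPQRSTVWY"

TINY_PIPELINE_CONFIG = {
    "simulate": {
        "n_patients": 8,
        "seed": 5,
        "burden_median": 8,
        "burden_sigma": 0.5,
        "n_genes": 12,
        "gene_length_range": [60, 120],
        "oncogene_frac": 0.2,
        "tcr_n_clones": 50,
        "tcr_total_templates": 600,
    },
    "predict": {"predictor": "mock"},
    "features": {"score_quality": True},
    "riskmodel": {"horizon_months": 36},
}


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = SimulationConfig(
        n_patients=10, seed=11, burden_median=10, burden_sigma=0.5,
        n_genes=15, gene_length_range=(60, 150), tcr_n_clones=40,
        tcr_total_templates=500,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """The tiny pipeline run end-to-end, twice with the same seed."""
    d1 = tmp_path_factory.mktemp("run_a")
    d2 = tmp_path_factory.mktemp("run_b")
    run("all", TINY_PIPELINE_CONFIG, d1, seed=5)
    run("all", TINY_PIPELINE_CONFIG, d2, seed=5)
    return d1, d2
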