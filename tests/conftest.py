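import warnings

import numpy as np
import pandas as pd
import pytest

import xsc
from xsc.pipeline import axis_divergence_analysis, score_accessibility, score_expression
from xsc.simulate import SimConfig

# The default synthetic study: 3 species, 10 cell types, 6 donors/species,
# 2,000 genes, 5,000 regions. Generated once per session and shared by the
# recovery and calibration tests.
STUDY_SEED = 1
TAU_SEED = 7


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast config for structural (non-recovery) tests."""
    return SimConfig(seed=STUDY_SEED, n_genes=300, n_regions=400, n_donors=4,
                     cells_per_type_donor=10, axis_module_size=15, n_leaves=8)


@pytest.fixture(scope="session")
def sim_expression(default_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xsc.simulate_expression(default_config)


@pytest.fixture(scope="session")
def sim_small_expression(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xsc.simulate_expression(small_config)


@pytest.fixture(scope="session")
def gene_conservation(sim_expression) -> pd.DataFrame:
    """Expressolog + tau + regime table for the default synthetic study."""
    counts, omap, _ = sim_expression
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return score_expression(counts, omap, tau_seed=TAU_SEED)


@pytest.fixture(scope="session")
def sim_accessibility(default_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return xsc.simulate_accessibility(default_config)


@pytest.fixture(scope="session")
def region_conservation(sim_accessibility) -> pd.DataFrame:
    access, region_map, _, _ = sim_accessibility
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return score_accessibility(access, region_map, n_candidates=1000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def axis_results(sim_expression):
    """Axis divergence with planted axis-module sets and an HVG background."""
    counts, omap, truth = sim_expression
    planted = {
        "d1_vs_d2": set(truth.genes.index[truth.genes["axis_module"] == "pathway"]),
        "striosome_vs_matrix": set(truth.genes.index[truth.genes["axis_module"] == "compartment"]),
        "dv_gradient": set(truth.genes.index[truth.genes["axis_module"] == "gradient"]),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return axis_divergence_analysis(counts, omap, anchor_gene=truth.anchor_gene,
                                        use_planted_sets=planted)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
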