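import numpy as np
import pytest

from genosem import (
    FactorArchitecture,
    GeneticCovariance,
    LDSCOptions,
    build_S_V,
    implied_genetic_correlation,
    make_ld_panel,
    preset_architecture,
    simulate_zscores,
    standardize,
    vech_indices,
)

#: LDSC settings for synthetic desk-scale panels (no outlier filter, no
#: genome-scale variance weights) — see docs/methods.md.
SYNTH_OPTS = LDSCOptions(weights="unit", max_chisq=None)


@pytest.fixture(scope="session")
def small_panel():
    return make_ld_panel(M_panel=2000, n_blocks=20, ld_mean=30.0, seed=7)


@pytest.fixture(scope="session")
def k2_arch():
    """Two traits, h2 = 0.4 each, genetic correlation 0.5 (cov_g = 0.2),
    fully overlapping cohorts with phenotypic correlation 0.5."""
    return FactorArchitecture(
        trait_names=["t1", "t2"],
        loadings=np.zeros((2, 1)),
        factor_cov=np.eye(1),
        residual_cov=np.array([[1.0, 0.5], [0.5, 1.0]]),
        h2=np.array([0.4, 0.4]),
        N=np.array([50_000, 50_000]),
        N_overlap=np.full((2, 2), 50_000.0),
        pheno_corr=np.array([[1.0, 0.5], [0.5, 1.0]]),
    )


@pytest.fixture(scope="session")
def triad_gc():
    """Exact single-factor correlation structure with loadings .8/.6/.5."""
    S = np.array([[1.0, 0.48, 0.40], [0.48, 1.0, 0.30], [0.40, 0.30, 1.0]])
    return GeneticCovariance(["a", "b", "c"], S, np.eye(6), np.zeros((3, 3)),
                             "correlation", 4)


def truth_gc(arch, v_scale: float = 1.0) -> GeneticCovariance:
    """Noise-free correlation-metric (S, V): S is the architecture's implied
    genetic correlation matrix and V the identity (unit DWLS weights)."""
    R = implied_genetic_correlation(arch)
    k = len(arch.trait_names)
    c = k * (k + 1) // 2
    return GeneticCovariance(list(arch.trait_names), R, v_scale * np.eye(c),
                             np.eye(k), "correlation", 0)


@pytest.fixture(scope="session")
def preset_truth_gc():
    return truth_gc(preset_architecture())


@pytest.fixture(scope="session")
def preset_sim_gc():
    """One simulated 16-trait (S, V) at moderate scale for structure tests."""
    arch = preset_architecture()
    panel = make_ld_panel(8000, 500, 50.0, seed=31)
    ss = simulate_zscores(panel, arch, seed=32)
    return standardize(build_S_V(ss, panel, SYNTH_OPTS))
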