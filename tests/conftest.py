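"""Shared fixtures: study-like synthetic cage experiments."""

import numpy as np
import pytest

from casfit.cage_synth import CageSimConfig, simulate_experiment
from casfit.core_model import CutRates, FitnessParams

# starting construct frequencies spanning the low-to-high range of the cage
# study (two cages started high, the rest low to intermediate)
STUDY_STARTS = (0.2, 0.25, 0.3, 0.35, 0.4, 0.55, 0.6)

# published ML estimates for the Cas9+gRNAs construct (full viability model)
TRUE_NE = 175.0
TRUE_W_DIRECT = 0.98
TRUE_W_OFFTARGET = 0.84


def full_model_configs(n_gens: int = 12, census: float = 3000.0):
    """Seven cage configs under the full viability model at the published
    ML estimates."""
    params = FitnessParams(TRUE_W_DIRECT, TRUE_W_OFFTARGET, "viability")
    return [
        CageSimConfig(
            Ne=TRUE_NE, census=census, initial_freq=f, params=params,
            cut=CutRates(1.0, 1.0), n_gens=n_gens,
        )
        for f in STUDY_STARTS
    ]


def neutral_configs(n_gens: int = 12, census: float = 3000.0):
    params = FitnessParams(selection_mode="none")
    return [
        CageSimConfig(
            Ne=TRUE_NE, census=census, initial_freq=f, params=params,
            cut=CutRates(0.0, 0.0), ancestral_construct_cut=False,
            n_gens=n_gens,
        )
        for f in STUDY_STARTS
    ]


@pytest.fixture(scope="session")
def cas9_like_cages():
    """Synthetic stand-in for the seven-cage experiment (seed 42)."""
    return simulate_experiment(full_model_configs(), master_seed=42)


@pytest.fixture(scope="session")
def neutral_cages():
    """Seven cages simulated without any fitness costs (seed 7)."""
    return simulate_experiment(neutral_configs(), master_seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


def mc_next_generation(state, params, cut, n, rng):
    """Monte-Carlo oracle for one model generation: explicit parents,
    gametes, cutting and selection by rejection sampling, independent of
    the enumeration code path in the package."""
    from casfit.core_model import GENOTYPES, genotype_fitness

    probs = state.probs
    fit = np.array([genotype_fitness(g, params) for g in GENOTYPES])
    if params.selection_mode == "fecundity_mate_choice":
        pw = probs * fit
        pw = pw / pw.sum()
    else:
        pw = probs
    mothers = rng.choice(9, size=n, p=pw)
    fathers = rng.choice(9, size=n, p=pw)

    def gamete(parent_idx):
        cc, xc = parent_idx // 3, parent_idx % 3
        c = rng.random(n) < cc / 2
        x = rng.random(n) < xc / 2
        x |= (cc >= 1) & (rng.random(n) < cut.germline)
        return c, x

    cm, xm = gamete(mothers)
    cf, xf = gamete(fathers)
    mother_carrier = mothers // 3 >= 1
    xm |= mother_carrier & (rng.random(n) < cut.embryo)
    xf |= mother_carrier & (rng.random(n) < cut.embryo)
    idx = 3 * (cm.astype(int) + cf.astype(int)) + xm.astype(int) + xf.astype(int)
    if params.selection_mode == "viability":
        keep = rng.random(n) < fit[idx] / fit.max()
        idx = idx[keep]
    # realized size matters: viability rejection shrinks the sample
    return np.bincount(idx, minlength=9) / idx.size, idx.size
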