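"""Stochastic forward simulation of cage trajectories and assay outcomes.

The cage generator draws drift on the full nine-genotype vector: each
generation the deterministic two-locus expectation is resampled as a single
multinomial draw of size ``round(Ne)``, then rescaled to the reported
census size.  This is deliberately richer than the inference model's
deterministic latent dynamics — the observable classes drift exactly as the
likelihood assumes, but the latent cut-copy composition drifts too, so
parameter-recovery studies probe that mismatch.

Also provides binomial generators for the mate-choice and viability single
-cross assays, and an overdispersed (negative-binomial) egg-count option
for fecundity-style data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from casfit.core_model import (
    CutRates,
    FitnessParams,
    GenotypeState,
    next_generation,
    phenotype_marginal,
    state_from_phenotypes,
)
from casfit.inference import CageCounts, effective_counts

__all__ = [
    "CageSimConfig",
    "simulate_cage",
    "simulate_ensemble",
    "simulate_experiment",
    "simulate_mate_choice",
    "simulate_viability_assay",
    "simulate_fecundity_counts",
    "subseed",
]


def subseed(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-stream: reproducible and order-independent."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass
class CageSimConfig:
    """Configuration of one simulated cage population.

    ``Ne`` is the drift (multinomial) size; ``census`` the reported total
    count per generation (a constant or one value per generation, emulating
    the few-thousand-fly censuses of real cages).  ``initial_freq`` is the
    construct allele frequency at generation 0; with
    ``three_genotype_start`` the ancestral generation is at Hardy-Weinberg
    proportions, otherwise it contains only the two homozygote classes.
    ``ancestral_construct_cut`` assigns cut/cut off-target genotypes to
    generation-0 construct carriers.
    """

    Ne: float = 175.0
    census: float | Sequence[float] = 3000.0
    initial_freq: float = 0.5
    three_genotype_start: bool = False
    params: FitnessParams = field(
        default_factory=lambda: FitnessParams(0.98, 0.84, "viability")
    )
    cut: CutRates = field(default_factory=CutRates)
    ancestral_construct_cut: bool = True
    n_gens: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.n_gens < 1:
            raise ValueError("n_gens must be >= 1")
        if not (0.0 <= self.initial_freq <= 1.0):
            raise ValueError("initial_freq must be in [0, 1]")

    def census_at(self, gen: int) -> float:
        if np.isscalar(self.census):
            return float(self.census)
        return float(self.census[gen])

    def initial_state(self) -> GenotypeState:
        p = self.initial_freq
        if self.three_genotype_start:
            classes = (p * p, 2 * p * (1 - p), (1 - p) ** 2)
        else:
            classes = (p, 0.0, 1.0 - p)
        return state_from_phenotypes(classes, self.ancestral_construct_cut)


def simulate_cage(cfg: CageSimConfig, replicate_id: str = "sim") -> CageCounts:
    """One stochastic cage trajectory as reported phenotype counts.

    Per generation: propagate the current nine-genotype frequencies through
    the deterministic expectation, resample them as one multinomial draw of
    size ``round(Ne)`` (drift), and report class counts as the class
    frequencies rescaled to the census by largest-remainder rounding.
    """
    rng = np.random.default_rng(cfg.seed)
    return _simulate_cage_rng(cfg, rng, replicate_id)


def _simulate_cage_rng(
    cfg: CageSimConfig, rng: np.random.Generator, replicate_id: str
) -> CageCounts:
    n_drift = int(round(cfg.Ne))
    state = cfg.initial_state()
    rows = [effective_counts(phenotype_marginal(state), cfg.census_at(0))]
    for gen in range(1, cfg.n_gens + 1):
        expected = next_generation(state, cfg.params, cfg.cut)
        draw = rng.multinomial(n_drift, expected.probs)
        state = GenotypeState(draw / n_drift)
        rows.append(effective_counts(phenotype_marginal(state), cfg.census_at(gen)))
    return CageCounts(
        replicate_id=replicate_id,
        generations=list(range(cfg.n_gens + 1)),
        counts=np.array(rows, dtype=float),
    )


def simulate_experiment(
    cfgs: Sequence[CageSimConfig], master_seed: int
) -> list[CageCounts]:
    """Independent replicate cages with counter-derived sub-seeds."""
    out = []
    for i, cfg in enumerate(cfgs):
        rng = subseed(master_seed, i)
        out.append(_simulate_cage_rng(cfg, rng, replicate_id=f"rep{i + 1}"))
    return out


def simulate_ensemble(cfg: CageSimConfig, n_reps: int) -> np.ndarray:
    """Per-generation percentile band of the construct allele frequency.

    Runs ``n_reps`` independent trajectories with sub-seeds derived from
    ``cfg.seed`` and returns an array of shape ``(n_gens + 1, 3)`` holding
    the 2.5, 50 and 97.5 percentiles per generation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    freqs = np.empty((n_reps, cfg.n_gens + 1))
    for r in range(n_reps):
        cage = _simulate_cage_rng(cfg, subseed(cfg.seed, r), f"ens{r}")
        freqs[r] = cage.construct_frequency()
    return np.percentile(freqs, [2.5, 50.0, 97.5], axis=0).T


def simulate_mate_choice(
    n_females: int, p_choose_egfp: float, seed: int
) -> tuple[int, int]:
    """Binomial mate-choice outcome: females choosing the EGFP male vs the
    construct male.  Returns ``(k_egfp, k_construct)`` summing to
    ``n_females``."""
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    k = int(np.random.default_rng(seed).binomial(n_females, p_choose_egfp))
    return k, n_females - k


def simulate_viability_assay(
    n_crosses: int, offspring_per_cross: int, p_het: float, seed: int
) -> np.ndarray:
    """Per-cross heterozygous-offspring fractions from binomial sampling."""
    if n_crosses < 1 or offspring_per_cross < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    k = rng.binomial(offspring_per_cross, p_het, size=n_crosses)
    return k / offspring_per_cross


def simulate_fecundity_counts(
    n_females: int, mean_eggs: float, seed: int, dispersion: float = 10.0
) -> np.ndarray:
    """Overdispersed per-female egg counts (negative binomial).

    ``dispersion`` is the NB size parameter; variance is
    ``mean + mean^2 / dispersion``.
    """
    if n_females < 1 or mean_eggs <= 0 or dispersion <= 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    p = dispersion / (dispersion + mean_eggs)
    return rng.negative_binomial(dispersion, p, size=n_females)
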