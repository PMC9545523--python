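"""Individual-based homing gene-drive simulation with off-target costs.

Simulates discrete, non-overlapping generations of a diploid population
with a homing drive locus (alleles: wild-type W, drive D, nonfunctional
resistance R2) and an optional set of unlinked off-target cut sites whose
cut alleles impose multiplicative viability costs.  Drive conversion and
resistance-allele formation occur in the germline of drive/wild-type
heterozygotes; maternally deposited Cas9 converts wild-type zygote alleles
to R2; off-target cutting happens exclusively in the germline of drive
carriers.

Two drive architectures are supported.  A *modification* drive rescues an
essential haplosufficient target, so only R2/R2 individuals are nonviable.
A *suppression* drive disrupts a haplosufficient female-fertility gene, so
females carrying any two drive/R2 alleles are sterile; a successful
suppression ends with an empty population.

Reproduction is density-dependent: each fertile female mates one uniformly
random male and bears a Poisson number of offspring with mean
``2*beta / ((beta - 1) * N / K + 1)`` (replacement at carrying capacity K,
mean ``2*beta`` per female at low density).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "W",
    "D",
    "R2",
    "DriveParams",
    "OffTargetConfig",
    "PopParams",
    "Individual",
    "DrivePopulation",
    "calibrate_offtarget_multiplier",
    "germline_gamete",
    "embryo_effects",
    "viability_and_fertility",
    "step_generation",
    "run_drive_sim",
]

# drive-locus allele codes
W, D, R2 = 0, 1, 2


@dataclass(frozen=True)
class OffTargetConfig:
    """Unlinked off-target cut sites with a calibrated viability cost.

    ``homozygous_cut_fitness`` (F) is the viability of the calibration
    genotype: both alleles cut for a single site, or half of all ``2 *
    n_sites`` alleles cut for multiple sites.  Canonical settings are one
    site always cut in the germline (``n_sites=1, cut_prob=1``) or twenty
    rarely cut sites (``n_sites=20, cut_prob=0.05``).
    """

    n_sites: int = 1
    cut_prob: float = 1.0
    homozygous_cut_fitness: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0.0 <= self.cut_prob <= 1.0):
            raise ValueError("cut_prob must be in [0, 1]")
        if not (0.0 < self.homozygous_cut_fitness <= 1.0):
            raise ValueError("homozygous_cut_fitness must be in (0, 1]")


def calibrate_offtarget_multiplier(cfg: OffTargetConfig) -> float:
    """Per-cut-allele viability multiplier m.

    Calibrated so an individual with both alleles cut at a single site
    (``m**2 = F``) has the same fitness as one with half of all site
    alleles cut in the multi-site model (``m**n_sites = F``).
    """
    F = cfg.homozygous_cut_fitness
    if cfg.n_sites == 1:
        return float(F**0.5)
    return float(F ** (1.0 / cfg.n_sites))


@dataclass(frozen=True)
class DriveParams:
    """Homing-drive genetics and fitness parameters.

    The printed germline rates are absolute per-W-allele outcome
    probabilities in drive/wild-type heterozygotes: conversion to D with
    ``conversion``, to R2 with ``germline_resistance``, unchanged otherwise.
    ``direct_fitness`` is the viability of drive homozygotes relative to
    wild-type (per-allele multiplier is its square root).
    """

    drive_type: str = "modification"
    conversion: float = 0.8
    germline_resistance: float = 0.1
    embryo_resistance: float = 0.05
    direct_fitness: float = 1.0
    offtarget: OffTargetConfig | None = None

    def __post_init__(self) -> None:
        if self.drive_type not in ("modification", "suppression"):
            raise ValueError("drive_type must be 'modification' or 'suppression'")
        for name in ("conversion", "germline_resistance", "embryo_resistance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.conversion + self.germline_resistance > 1.0 + 1e-12:
            raise ValueError("conversion + germline_resistance must be <= 1")
        if not (0.0 < self.direct_fitness <= 1.0):
            raise ValueError("direct_fitness must be in (0, 1]")

    @property
    def n_sites(self) -> int:
        return self.offtarget.n_sites if self.offtarget is not None else 0

    @property
    def cut_multiplier(self) -> float:
        if self.offtarget is None:
            return 1.0
        return calibrate_offtarget_multiplier(self.offtarget)


@dataclass(frozen=True)
class PopParams:
    """Population-level simulation parameters."""

    K: int = 20_000
    beta: float = 10.0
    release_fraction: float = 0.01
    n_gens: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.beta <= 1.0:
            raise ValueError("beta must be > 1")
        if not (0.0 <= self.release_fraction <= 1.0):
            raise ValueError("release_fraction must be in [0, 1]")


class Individual(NamedTuple):
    """Single diploid individual (convenience view for the per-individual API)."""

    sex: str  # 'F' or 'M'
    drive_locus: tuple[int, int]
    offtarget_bits: np.ndarray  # (n_sites, 2) cut flags


@dataclass
class DrivePopulation:
    """Array-of-individuals population state.

    ``drive`` has shape (N, 2) with allele codes W/D/R2; ``ot`` has shape
    (N, n_sites, 2) with cut flags (n_sites may be 0).
    """

    female: np.ndarray
    drive: np.ndarray
    ot: np.ndarray

    @property
    def size(self) -> int:
        return self.drive.shape[0]

    def allele_frequency(self, allele: int) -> float:
        if self.size == 0:
            return float("nan")
        return float((self.drive == allele).sum()) / (2 * self.size)

    def mean_cut_alleles(self) -> float:
        if self.size == 0:
            return float("nan")
        return float(self.ot.sum()) / self.size

    @classmethod
    def release(cls, pp: PopParams, dp: DriveParams, rng: np.random.Generator
                ) -> "DrivePopulation":
        """K wild-type adults plus a release of drive/wild-type heterozygotes
        (no cut off-target alleles in either group), half each sex."""
        n_wild = pp.K
        n_rel = int(round(pp.release_fraction * pp.K))
        n = n_wild + n_rel
        drive = np.zeros((n, 2), dtype=np.int8)
        drive[n_wild:, 0] = D
        female = np.zeros(n, dtype=bool)
        female[: n_wild // 2] = True
        female[n_wild : n_wild + n_rel // 2] = True
        ot = np.zeros((n, dp.n_sites, 2), dtype=bool)
        return cls(female=female, drive=drive, ot=ot)


# ---------------------------------------------------------------------------
# vectorized genetics
# ---------------------------------------------------------------------------

def _germline_gametes(
    drive: np.ndarray,
    ot: np.ndarray,
    parents: np.ndarray,
    dp: DriveParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per entry of ``parents``: drive allele + off-target bits.

    A transmitted W allele from a drive-carrying parent is converted to D
    with probability ``conversion``, to R2 with ``germline_resistance``.
    Transmitted uncut off-target alleles are cut with ``cut_prob`` iff the
    parent carries at least one drive allele.  Sites are unlinked: an
    independent Mendelian pick per site.
    """
    m = parents.shape[0]
    pick = rng.integers(2, size=m)
    alleles = drive[parents, pick].copy()
    has_d = (drive[parents] == D).any(axis=1)
    cuttable = has_d & (alleles == W)
    u = rng.random(m)
    alleles[cuttable & (u < dp.conversion)] = D
    alleles[
        cuttable
        & (u >= dp.conversion)
        & (u < dp.conversion + dp.germline_resistance)
    ] = R2
    n_sites = ot.shape[1]
    if n_sites == 0:
        return alleles, np.zeros((m, 0), dtype=bool)
    site_pick = rng.integers(2, size=(m, n_sites))
    bits = np.take_along_axis(ot[parents], site_pick[:, :, None], axis=2)[:, :, 0]
    cut = has_d[:, None] & (rng.random((m, n_sites)) < dp.offtarget.cut_prob)
    return alleles, bits | cut


def _embryo_effects(
    zygote_drive: np.ndarray,
    mother_has_d: np.ndarray,
    dp: DriveParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Maternal-Cas9 conversion of zygote W alleles to R2 (in place)."""
    if dp.embryo_resistance > 0.0:
        hit = (
            mother_has_d[:, None]
            & (zygote_drive == W)
            & (rng.random(zygote_drive.shape) < dp.embryo_resistance)
        )
        zygote_drive[hit] = R2
    return zygote_drive


def _viability(drive: np.ndarray, ot: np.ndarray, dp: DriveParams) -> np.ndarray:
    n_d = (drive == D).sum(axis=1)
    v = (dp.direct_fitness**0.5) ** n_d
    if dp.n_sites > 0:
        v = v * dp.cut_multiplier ** ot.sum(axis=(1, 2))
    if dp.drive_type == "modification":
        v = np.where((drive == R2).all(axis=1), 0.0, v)
    return v


def _female_sterile(drive: np.ndarray, dp: DriveParams) -> np.ndarray:
    if dp.drive_type != "suppression":
        return np.zeros(drive.shape[0], dtype=bool)
    return (drive != W).all(axis=1)


# ---------------------------------------------------------------------------
# per-individual API
# ---------------------------------------------------------------------------

def _as_arrays(ind: Individual, n_sites: int):
    drive = np.array([list(ind.drive_locus)], dtype=np.int8)
    ot = np.asarray(ind.offtarget_bits, dtype=bool).reshape(1, n_sites, 2)
    return drive, ot


def germline_gamete(
    parent: Individual, dp: DriveParams, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Sample one gamete (drive allele, off-target cut bits) from a parent."""
    drive, ot = _as_arrays(parent, dp.n_sites)
    alleles, bits = _germline_gametes(drive, ot, np.zeros(1, dtype=int), dp, rng)
    return int(alleles[0]), bits[0]


def embryo_effects(
    zygote: Individual, mother: Individual, dp: DriveParams,
    rng: np.random.Generator,
) -> Individual:
    """Apply maternal-Cas9 embryo resistance-allele formation to a zygote."""
    drive = np.array([list(zygote.drive_locus)], dtype=np.int8)
    mother_has_d = np.array([D in mother.drive_locus])
    drive = _embryo_effects(drive, mother_has_d, dp, rng)
    return Individual(zygote.sex, (int(drive[0, 0]), int(drive[0, 1])),
                      zygote.offtarget_bits)


def viability_and_fertility(
    ind: Individual, dp: DriveParams
) -> tuple[float, bool]:
    """Viability weight in [0, 1] and fertility flag for one individual."""
    drive, ot = _as_arrays(ind, dp.n_sites)
    v = float(_viability(drive, ot, dp)[0])
    sterile = bool(_female_sterile(drive, dp)[0]) and ind.sex == "F"
    return v, not sterile


# ---------------------------------------------------------------------------
# generation cycle
# ---------------------------------------------------------------------------

def step_generation(
    pop: DrivePopulation,
    dp: DriveParams,
    pp: PopParams,
    rng: np.random.Generator,
) -> DrivePopulation:
    """Advance one generation; returns the (possibly empty) next adults."""
    n = pop.size
    empty = DrivePopulation(
        female=np.zeros(0, dtype=bool),
        drive=np.zeros((0, 2), dtype=np.int8),
        ot=np.zeros((0, dp.n_sites, 2), dtype=bool),
    )
    if n == 0:
        return empty
    females = np.flatnonzero(pop.female & ~_female_sterile(pop.drive, dp))
    males = np.flatnonzero(~pop.female)
    if females.size == 0 or males.size == 0:
        return empty
    mean_offspring = 2.0 * pp.beta / ((pp.beta - 1.0) * n / pp.K + 1.0)
    brood = rng.poisson(mean_offspring, size=females.size)
    mothers = np.repeat(females, brood)
    fathers = np.repeat(males[rng.integers(males.size, size=females.size)], brood)
    m = mothers.size
    if m == 0:
        return empty
    a_m, ot_m = _germline_gametes(pop.drive, pop.ot, mothers, dp, rng)
    a_f, ot_f = _germline_gametes(pop.drive, pop.ot, fathers, dp, rng)
    drive = np.stack([a_m, a_f], axis=1)
    ot = np.stack([ot_m, ot_f], axis=2)
    mother_has_d = (pop.drive[mothers] == D).any(axis=1)
    drive = _embryo_effects(drive, mother_has_d, dp, rng)
    survive = rng.random(m) < _viability(drive, ot, dp)
    return DrivePopulation(
        female=rng.random(m)[survive] < 0.5,
        drive=drive[survive],
        ot=ot[survive],
    )


def run_drive_sim(dp: DriveParams, pp: PopParams) -> pd.DataFrame:
    """Release-and-track simulation of one drive in one population.

    Starts from ``K`` wild-type adults plus a release of
    ``release_fraction * K`` drive/wild-type heterozygotes and runs
    ``n_gens`` generations or until extinction.  Returns one record per
    generation: drive and R2 allele frequencies, population size, and the
    mean number of cut off-target alleles per individual.
    """
    rng = np.random.default_rng(pp.seed)
    pop = DrivePopulation.release(pp, dp, rng)
    records = []

    def record(gen: int) -> None:
        records.append(
            {
                "generation": gen,
                "drive_freq": pop.allele_frequency(D),
                "r2_freq": pop.allele_frequency(R2),
                "pop_size": pop.size,
                "mean_cut_alleles": pop.mean_cut_alleles(),
            }
        )

    record(0)
    for gen in range(1, pp.n_gens + 1):
        pop = step_generation(pop, dp, pp, rng)
        record(gen)
        if pop.size == 0:
            break
    return pd.DataFrame.from_records(records)
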