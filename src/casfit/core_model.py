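"""Deterministic two-locus genotype-frequency dynamics.

The model tracks an autosomal biallelic construct locus (EGFP / construct,
observable through dominant fluorescent markers) and a single unlinked,
idealized off-target locus (uncut / cut, unobservable).  An individual's
genotype is the pair of allele counts at the two loci, giving nine possible
genotypes.  Generations are discrete and non-overlapping; genotype
frequencies are assumed identical in both sexes.

One generation consists of: gamete formation with germline cutting in
construct carriers, random mating (optionally weighted by fecundity /
mating success), cutting of uncut zygote alleles by maternally deposited
Cas9 when the mother carries a construct allele, and (in the viability
mode) viability selection on the offspring.  Fitness is multiplicative
across loci and across the two alleles at each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Genotype",
    "GenotypeState",
    "FitnessParams",
    "CutRates",
    "GENOTYPES",
    "NORM_TOL",
    "genotype_fitness",
    "fitness_vector",
    "gamete_distribution",
    "mating_tensor",
    "next_generation",
    "phenotype_marginal",
    "expected_trajectory",
    "construct_allele_frequency",
    "state_from_phenotypes",
]

#: absolute tolerance for normalization checks on genotype states
NORM_TOL = 1e-12

VALID_SELECTION_MODES = ("viability", "fecundity_mate_choice", "none")


class Genotype(NamedTuple):
    """Two-locus genotype: allele counts at the construct and off-target locus."""

    construct_copies: int  # number of construct alleles, 0 = EGFP homozygote
    cut_copies: int  # number of cut alleles at the idealized off-target locus

    @property
    def index(self) -> int:
        return 3 * self.construct_copies + self.cut_copies


#: the nine genotypes in canonical (construct-major) order
GENOTYPES: tuple[Genotype, ...] = tuple(
    Genotype(c, x) for c in (0, 1, 2) for x in (0, 1, 2)
)

# allele-count lookup arrays aligned with GENOTYPES
_CONSTRUCT_COPIES = np.array([g.construct_copies for g in GENOTYPES])
_CUT_COPIES = np.array([g.cut_copies for g in GENOTYPES])


@dataclass(frozen=True)
class FitnessParams:
    """Relative fitness per construct allele and per cut off-target allele.

    ``w_direct`` is the fitness of construct/EGFP heterozygotes relative to
    EGFP homozygotes; ``w_offtarget`` the fitness of cut/uncut heterozygotes
    relative to uncut homozygotes.  ``selection_mode`` chooses whether the
    weights act on offspring viability or on parental fecundity and mating
    success (equally); ``"none"`` disables selection entirely.
    """

    w_direct: float = 1.0
    w_offtarget: float = 1.0
    selection_mode: str = "viability"

    def __post_init__(self) -> None:
        if self.selection_mode not in VALID_SELECTION_MODES:
            raise ValueError(
                f"selection_mode must be one of {VALID_SELECTION_MODES}, "
                f"got {self.selection_mode!r}"
            )
        if not (self.w_direct > 0 and self.w_offtarget > 0):
            raise ValueError("fitness parameters must be positive")


@dataclass(frozen=True)
class CutRates:
    """Germline and embryo cut probabilities at the off-target locus.

    ``germline``: probability that a transmitted uncut allele is cut in the
    germline of a construct carrier.  ``embryo``: probability that an uncut
    zygote allele is cut by maternally deposited Cas9/gRNA when the mother
    carries at least one construct allele.
    """

    germline: float = 1.0
    embryo: float = 1.0

    def __post_init__(self) -> None:
        for name in ("germline", "embryo"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} cut rate must be in [0, 1], got {v}")


@dataclass
class GenotypeState:
    """Probability distribution over the nine two-locus genotypes."""

    probs: np.ndarray = field(
        default_factory=lambda: np.array([1.0] + [0.0] * 8)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (9,):
            raise ValueError("GenotypeState requires 9 genotype weights")
        if np.any(self.probs < -NORM_TOL):
            raise ValueError("genotype weights must be non-negative")
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("degenerate all-zero genotype state")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype weights must sum to 1, got {total}")
        # absorb round-off
        self.probs = np.clip(self.probs, 0.0, None)
        self.probs = self.probs / self.probs.sum()

    def __getitem__(self, g: Genotype) -> float:
        return float(self.probs[Genotype(*g).index])

    @classmethod
    def from_dict(cls, weights: dict[Genotype, float]) -> "GenotypeState":
        probs = np.zeros(9)
        for g, w in weights.items():
            probs[Genotype(*g).index] = w
        return cls(probs)


def genotype_fitness(g: Genotype, params: FitnessParams) -> float:
    """Multiplicative fitness weight of a genotype.

    Returns ``w_direct**construct_copies * w_offtarget**cut_copies``, or 1
    when ``selection_mode`` is ``"none"``.
    """
    g = Genotype(*g)
    if params.selection_mode == "none":
        return 1.0
    return params.w_direct**g.construct_copies * params.w_offtarget**g.cut_copies


def fitness_vector(params: FitnessParams) -> np.ndarray:
    """Fitness weights of all nine genotypes in canonical order."""
    if params.selection_mode == "none":
        return np.ones(9)
    return params.w_direct**_CONSTRUCT_COPIES * params.w_offtarget**_CUT_COPIES


def gamete_distribution(parent: Genotype, cut: CutRates) -> np.ndarray:
    """Distribution over the four gamete types produced by ``parent``.

    Returns a 2x2 array ``p[c, x]`` where ``c`` is 1 if the gamete carries
    the construct allele (else EGFP) and ``x`` is 1 if it carries a cut
    off-target allele (else uncut).  Transmission is Mendelian at both
    (unlinked) loci; a transmitted uncut allele is converted to cut with
    probability ``cut.germline`` iff the parent carries at least one
    construct allele.
    """
    parent = Genotype(*parent)
    p_construct = parent.construct_copies / 2.0
    p_cut = parent.cut_copies / 2.0
    if parent.construct_copies >= 1:
        p_cut = p_cut + (1.0 - p_cut) * cut.germline
    return np.array(
        [
            [(1 - p_construct) * (1 - p_cut), (1 - p_construct) * p_cut],
            [p_construct * (1 - p_cut), p_construct * p_cut],
        ]
    )


def _embryo_adjust(gamete: np.ndarray, embryo_rate: float) -> np.ndarray:
    """Convert an uncut transmitted allele to cut with the embryo cut rate."""
    if embryo_rate == 0.0:
        return gamete
    out = gamete.copy()
    moved = out[:, 0] * embryo_rate
    out[:, 0] -= moved
    out[:, 1] += moved
    return out


@lru_cache(maxsize=64)
def mating_tensor(germline: float, embryo: float) -> np.ndarray:
    """Offspring kernel ``T[i, j, k] = P(offspring k | mother i, father j)``.

    Includes germline cutting in both parents and embryo cutting of uncut
    zygote alleles (both maternal and paternal) when the mother carries at
    least one construct allele.  Depends only on the cut rates; selection is
    applied separately, so the tensor can be cached across likelihood
    evaluations.
    """
    cut = CutRates(germline=germline, embryo=embryo)
    base = [gamete_distribution(g, cut) for g in GENOTYPES]
    T = np.zeros((9, 9, 9))
    for i, mother in enumerate(GENOTYPES):
        e = embryo if mother.construct_copies >= 1 else 0.0
        gm = _embryo_adjust(base[i], e)
        for j in range(9):
            gf = _embryo_adjust(base[j], e)
            for cm in (0, 1):
                for xm in (0, 1):
                    for cf in (0, 1):
                        for xf in (0, 1):
                            k = 3 * (cm + cf) + (xm + xf)
                            T[i, j, k] += gm[cm, xm] * gf[cf, xf]
    return T


def next_generation(
    state: GenotypeState, params: FitnessParams, cut: CutRates
) -> GenotypeState:
    """Exact expected genotype distribution after one generation.

    Enumerates all mother x father genotype pairs.  In the
    ``fecundity_mate_choice`` mode parental weights (maternal fecundity and
    paternal mating success, of equal magnitude) multiply the pair
    probability; in the ``viability`` mode offspring weights multiply the
    zygote distribution, which is then renormalized.
    """
    probs = next_generation_probs(
        state.probs, fitness_vector(params), params.selection_mode,
        mating_tensor(cut.germline, cut.embryo),
    )
    return GenotypeState(probs)


def next_generation_probs(
    s: np.ndarray, fit: np.ndarray, selection_mode: str, T: np.ndarray
) -> np.ndarray:
    """Array core of :func:`next_generation` (no wrapper objects)."""
    if selection_mode == "fecundity_mate_choice":
        sw = s * fit
        sw = sw / sw.sum()
        sm = sf = sw
    else:
        sm = sf = s
    # q[k] = sum_ij sm[i] sf[j] T[i,j,k]
    q = np.einsum("i,ijk,j->k", sm, T, sf)
    if selection_mode == "viability":
        q = q * fit
    total = q.sum()
    if total <= 0:
        raise ValueError("offspring distribution vanished (lethal parameters)")
    return q / total


def phenotype_marginal(state: GenotypeState) -> np.ndarray:
    """Observable 3-class marginal (construct homozygote, heterozygote,
    EGFP homozygote), summing the unobserved off-target dimension."""
    p = state.probs
    return np.array([p[6:9].sum(), p[3:6].sum(), p[0:3].sum()])


def construct_allele_frequency(state: GenotypeState) -> float:
    """Frequency of the construct allele implied by the genotype state."""
    return float(np.dot(state.probs, _CONSTRUCT_COPIES)) / 2.0


def expected_trajectory(
    initial: GenotypeState,
    params: FitnessParams,
    cut: CutRates,
    n_gens: int,
) -> list[GenotypeState]:
    """Deterministic trajectory: ``n_gens + 1`` states starting at ``initial``."""
    if n_gens < 0:
        raise ValueError("n_gens must be non-negative")
    states = [initial]
    for _ in range(n_gens):
        states.append(next_generation(states[-1], params, cut))
    return states


def state_from_phenotypes(
    class_freqs: Iterable[float], construct_carriers_cut: bool
) -> GenotypeState:
    """Build a genotype state from observed phenotype-class frequencies.

    ``class_freqs`` are (construct homozygote, heterozygote, EGFP
    homozygote) frequencies.  Construct carriers are assigned cut/cut
    off-target genotypes when ``construct_carriers_cut`` is true (the
    default assumption for the ancestral generation of constructs with
    active cutting), otherwise uncut/uncut.  EGFP homozygotes are always
    uncut/uncut.
    """
    f_hom, f_het, f_egfp = (float(v) for v in class_freqs)
    probs = np.zeros(9)
    x = 2 if construct_carriers_cut else 0
    probs[Genotype(0, 0).index] = f_egfp
    probs[Genotype(1, x).index] = f_het
    probs[Genotype(2, x).index] = f_hom
    return GenotypeState(probs)
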