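"""Multinomial maximum-likelihood inference of fitness costs from cage counts.

Replicated per-generation phenotype counts (construct homozygote /
heterozygote / EGFP homozygote) are modeled as a chain of multinomial
transitions: the two-locus model predicts the next generation's expected
phenotype-class frequencies, and drift enters through a multinomial draw of
size ``Ne`` on the three observable classes.  Each transition contributes
the drift multinomial evaluated as a *density* over observed class
frequencies: the log-gamma multinomial term at continuous pseudo-counts
``f_c * Ne`` (smooth in Ne, equal to the ordinary log-mass at integers)
plus the lattice-to-density Jacobian ``d * log(Ne)``, where ``d`` is the
number of free class dimensions (2 generically, 0 for degenerate certain
transitions).  The Jacobian term is what makes Ne identifiable —
the interior optimum balances the drift-variance penalty against it — and
is why fitted log-likelihoods are positive.  Sampling noise is not added
on top of drift because whole populations are phenotyped.

The latent off-target dimension propagates deterministically; after each
observation the state is conditioned on the data by replacing the
construct-locus marginal with the observed class frequencies while
retaining the conditional cut-copy distribution within each class.

Five model variants are supported (full, construct-only, off-target-only,
initial-off-target, neutral), compared via the corrected Akaike information
criterion, with 95% profile-likelihood confidence intervals from a
likelihood-ratio cutoff with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import qmc

from casfit.core_model import (
    CutRates,
    FitnessParams,
    GenotypeState,
    fitness_vector,
    mating_tensor,
    next_generation,
    phenotype_marginal,
    state_from_phenotypes,
)

__all__ = [
    "CageCounts",
    "ModelSpec",
    "FitResult",
    "MODEL_NAMES",
    "aicc",
    "effective_counts",
    "transition_loglik",
    "trajectory_loglik",
    "fit_model",
    "profile_ci",
    "model_selection_table",
    "format_table",
]

#: lnL drop defining a 95% profile-likelihood bound (chi2(1) cutoff / 2)
PROFILE_DROP = 1.9207293090798535

#: optimizer search box
NE_BOUNDS = (10.0, 5000.0)
W_BOUNDS = (0.3, 2.0)

MODEL_NAMES = ("full", "construct", "off_target", "initial_off_target", "neutral")


@dataclass
class CageCounts:
    """Observed per-generation phenotype-class counts for one replicate cage.

    ``counts`` has one row per retained generation in the order
    (construct homozygote, heterozygote, EGFP homozygote).
    """

    replicate_id: str
    generations: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must be a (generations, 3) array")
        if len(self.generations) != self.counts.shape[0]:
            raise ValueError("generation index / counts length mismatch")
        if len(self.generations) < 2:
            raise ValueError("a cage needs at least 2 generations (1 transition)")
        if any(b <= a for a, b in zip(self.generations, self.generations[1:])):
            raise ValueError("generation indices must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("each generation needs a positive total count")

    @property
    def census(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    @property
    def n_transitions(self) -> int:
        return len(self.generations) - 1

    def construct_frequency(self) -> np.ndarray:
        """Construct allele frequency per generation."""
        f = self.freqs
        return f[:, 0] + 0.5 * f[:, 1]


@dataclass(frozen=True)
class ModelSpec:
    """One of the five selection-model variants.

    ``name`` fixes which parameters are free: the full model frees Ne and
    both fitness parameters; ``construct`` fixes the off-target parameter at
    1; ``off_target`` and ``initial_off_target`` fix the direct parameter at
    1; ``neutral`` fixes both.  Cut rates default to 1 for models with
    cutting during the experiment and to 0 for the initial-off-target and
    neutral models, overridable for constructs that cannot cut.
    ``ancestral_construct_cut`` controls whether generation-0 construct
    carriers are assigned cut/cut off-target genotypes.
    """

    name: str
    selection_mode: str = "viability"
    cut: CutRates | None = None
    ancestral_construct_cut: bool | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.name == "neutral":
            object.__setattr__(self, "selection_mode", "none")
        if self.cut is None:
            default = 1.0 if self.name in ("full", "construct", "off_target") else 0.0
            object.__setattr__(self, "cut", CutRates(default, default))
        if self.ancestral_construct_cut is None:
            object.__setattr__(
                self, "ancestral_construct_cut", self.name != "neutral"
            )

    @property
    def free_params(self) -> tuple[str, ...]:
        return {
            "full": ("Ne", "w_direct", "w_offtarget"),
            "construct": ("Ne", "w_direct"),
            "off_target": ("Ne", "w_offtarget"),
            "initial_off_target": ("Ne", "w_offtarget"),
            "neutral": ("Ne",),
        }[self.name]

    def fitness_params(self, w_direct: float, w_offtarget: float) -> FitnessParams:
        wd = w_direct if "w_direct" in self.free_params else 1.0
        wo = w_offtarget if "w_offtarget" in self.free_params else 1.0
        return FitnessParams(wd, wo, self.selection_mode)


@dataclass
class FitResult:
    """Point estimates, log-likelihood, AICc and profile CIs for one model."""

    spec: ModelSpec
    Ne_hat: float
    w_direct_hat: float | None
    w_offtarget_hat: float | None
    lnL_hat: float
    p: int
    n_transitions: int
    aicc: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    converged: bool = True


def aicc(lnL: float, p: int, n: int) -> float:
    """Corrected Akaike information criterion.

    ``AICc = 2p - 2 lnL + (2p^2 + 2p) / (n - p - 1)`` with ``n`` the number
    of generation transitions and ``p`` the number of free parameters.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if n <= p + 1:
        raise ValueError("AICc requires n > p + 1")
    return 2.0 * p - 2.0 * lnL + (2.0 * p * p + 2.0 * p) / (n - p - 1.0)


def effective_counts(freqs: Sequence[float], Ne: float) -> np.ndarray:
    """Integer pseudo-counts of the three classes at drift size ``round(Ne)``.

    Largest-remainder rounding of ``freqs * round(Ne)``; the result sums to
    exactly ``round(Ne)``.
    """
    if Ne < 2:
        raise ValueError("Ne must be >= 2")
    f = np.asarray(freqs, dtype=float)
    n = int(round(Ne))
    raw = f * n
    base = np.floor(raw).astype(np.int64)
    short = n - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# numba likelihood kernel
# ---------------------------------------------------------------------------

_MODE_CODE = {"viability": 0, "fecundity_mate_choice": 1, "none": 2}


@njit(cache=True)
def _chain_loglik(T, fit9, mode, init_state, obs, ne):
    """Log-likelihood of one cage's transition chain.

    ``obs`` holds observed class frequencies for generations 1..G (class
    order: construct hom, het, EGFP hom).  Drift acts through a multinomial
    of size ``ne`` on the observable classes, evaluated as a density over
    class frequencies; after each transition the state is conditioned on
    the observation.
    """
    s = init_state.copy()
    lnl = 0.0
    for t in range(obs.shape[0]):
        # expected offspring distribution under the two-locus model
        if mode == 1:
            sm = s * fit9
            sm = sm / sm.sum()
        else:
            sm = s
        q = np.zeros(9)
        for i in range(9):
            if sm[i] == 0.0:
                continue
            for j in range(9):
                w = sm[i] * sm[j]
                if w == 0.0:
                    continue
                for k in range(9):
                    q[k] += w * T[i, j, k]
        if mode == 0:
            q = q * fit9
        q = q / q.sum()
        # observable marginal: classes (construct hom, het, EGFP hom)
        m = np.empty(3)
        m[0] = q[6] + q[7] + q[8]
        m[1] = q[3] + q[4] + q[5]
        m[2] = q[0] + q[1] + q[2]
        # continuous multinomial term at counts f_c * Ne: smooth in Ne so
        # the optimizer and profile bisection see no lattice jitter
        term = math.lgamma(ne + 1.0)
        dims = -1
        for c in range(3):
            x = obs[t, c] * ne
            term -= math.lgamma(x + 1.0)
            if m[c] > 0.0:
                dims += 1
            if x > 0.0:
                if m[c] <= 0.0:
                    return -np.inf
                term += x * math.log(m[c])
        # lattice-to-density Jacobian: likelihood of the observed class
        # frequencies, not of the Ne-dependent count lattice
        if dims > 0:
            term += dims * math.log(ne)
        lnl += term
        # condition the latent state on the observed class frequencies
        s = np.zeros(9)
        for c in range(3):
            cc = 2 - c  # construct copies of class c
            if m[c] > 0.0:
                for x in range(3):
                    s[3 * cc + x] = obs[t, c] * q[3 * cc + x] / m[c]
            elif obs[t, c] > 0.0:
                return -np.inf
    return lnl


def _prepare_cage(cage: CageCounts, spec: ModelSpec):
    f = cage.freqs
    init = state_from_phenotypes(
        (f[0, 0], f[0, 1], f[0, 2]), spec.ancestral_construct_cut
    )
    return init.probs, f[1:]


def _pooled_loglik(
    cages: Sequence[CageCounts],
    spec: ModelSpec,
    Ne: float,
    w_direct: float,
    w_offtarget: float,
) -> float:
    T = mating_tensor(spec.cut.germline, spec.cut.embryo)
    params = spec.fitness_params(w_direct, w_offtarget)
    fit9 = fitness_vector(params)
    mode = _MODE_CODE[params.selection_mode]
    lnl = 0.0
    for cage in cages:
        init, obs = _prepare_cage(cage, spec)
        lnl += _chain_loglik(T, fit9, mode, init, np.ascontiguousarray(obs), Ne)
        if not np.isfinite(lnl):
            return -np.inf
    return lnl


# ---------------------------------------------------------------------------
# public likelihood API
# ---------------------------------------------------------------------------

def transition_loglik(
    state_t: GenotypeState,
    obs_t1: Sequence[float],
    Ne: float,
    params: FitnessParams,
    cut: CutRates,
) -> tuple[float, GenotypeState | None]:
    """One drift-transition term and the data-conditioned next state.

    The expected class frequencies come from propagating ``state_t`` one
    generation; the observation contributes the drift multinomial evaluated
    as a density over class frequencies — the log-gamma multinomial term at
    continuous pseudo-counts ``f_c * Ne`` plus the lattice-to-density
    Jacobian ``d * log(Ne)`` (``d`` = free class dimensions, so a
    degenerate certain transition still contributes 0).
    The returned state carries the observed construct-locus marginal with
    the model's conditional cut-copy distribution within each class; it is
    ``None`` when the observation has zero model probability (term
    ``-inf``).
    """
    obs = np.asarray(obs_t1, dtype=float)
    nxt = next_generation(state_t, params, cut)
    m = phenotype_marginal(nxt)
    term = math.lgamma(Ne + 1.0)
    dims = -1
    for c in range(3):
        x = obs[c] * Ne
        term -= math.lgamma(x + 1.0)
        if m[c] > 0:
            dims += 1
        if x > 0:
            if m[c] <= 0:
                return -np.inf, None
            term += x * math.log(m[c])
    if dims > 0:
        term += dims * math.log(Ne)
    probs = np.zeros(9)
    for c in range(3):
        cc = 2 - c
        block = nxt.probs[3 * cc : 3 * cc + 3]
        if m[c] > 0:
            probs[3 * cc : 3 * cc + 3] = obs[c] * block / m[c]
        elif obs[c] > 0:
            return -np.inf, None
    return term, GenotypeState(probs)


def trajectory_loglik(
    cage: CageCounts,
    spec: ModelSpec,
    Ne: float,
    w_direct: float = 1.0,
    w_offtarget: float = 1.0,
) -> float:
    """Pooled log-likelihood of one cage's chained transitions."""
    return _pooled_loglik([cage], spec, Ne, w_direct, w_offtarget)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, free: tuple[str, ...]) -> tuple[float, float, float]:
    ne = math.exp(theta[0])
    wd = wo = 1.0
    i = 1
    if "w_direct" in free:
        wd = theta[i]
        i += 1
    if "w_offtarget" in free:
        wo = theta[i]
    return ne, wd, wo


def _bounds(free: tuple[str, ...]) -> list[tuple[float, float]]:
    b = [(math.log(NE_BOUNDS[0]), math.log(NE_BOUNDS[1]))]
    b += [W_BOUNDS] * (len(free) - 1)
    return b


def fit_model(
    cages: Sequence[CageCounts],
    spec: ModelSpec,
    n_starts: int = 8,
    seed: int = 0,
    compute_ci: bool = True,
) -> FitResult:
    """Maximize the pooled log-likelihood over the model's free parameters.

    All replicates share one Ne and one set of fitness parameters.  The
    optimizer is bounded Nelder-Mead (Ne on a log scale in [10, 5000],
    fitness weights in [0.3, 2.0]) restarted from a Latin-hypercube of
    ``n_starts`` points; 95% CIs come from :func:`profile_ci`.
    """
    cages = list(cages)
    if not cages:
        raise ValueError("need at least one cage")
    free = spec.free_params
    p = len(free)
    bounds = _bounds(free)

    def negloglik(theta: np.ndarray) -> float:
        ne, wd, wo = _unpack(theta, free)
        return -_pooled_loglik(cages, spec, ne, wd, wo)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = lo + qmc.LatinHypercube(d=p, seed=seed).random(n_starts) * (hi - lo)
    best = None
    for x0 in starts:
        res = minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"fatol": 1e-6, "xatol": 1e-5, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ne, wd, wo = _unpack(best.x, free)
    n_trans = sum(c.n_transitions for c in cages)
    result = FitResult(
        spec=spec,
        Ne_hat=ne,
        w_direct_hat=wd if "w_direct" in free else None,
        w_offtarget_hat=wo if "w_offtarget" in free else None,
        lnL_hat=-best.fun,
        p=p,
        n_transitions=n_trans,
        # AICc is undefined for n <= p + 1 (tiny datasets); flag with NaN
        aicc=aicc(-best.fun, p, n_trans) if n_trans > p + 1 else math.nan,
        converged=bool(best.success and np.isfinite(best.fun)),
    )
    if compute_ci:
        for name in free:
            result.ci[name], result.ci_flags[name] = profile_ci(
                cages, spec, result, name
            )
    return result


def _profile_bound(
    profile: Callable[[float], float],
    x_hat: float,
    target: float,
    edge: float,
    tol: float,
) -> tuple[float, bool]:
    """Bisection for the point where a profile log-likelihood crosses
    ``target`` between ``x_hat`` and ``edge``; flags a clipped bound."""
    if profile(edge) >= target:
        return edge, True
    a, b = x_hat, edge  # profile(a) >= target > profile(b)
    while abs(b - a) > tol:
        mid = 0.5 * (a + b)
        if profile(mid) >= target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b), False


def profile_ci(
    cages: Sequence[CageCounts],
    spec: ModelSpec,
    fit: FitResult,
    param_name: str,
    tol: float = 1e-3,
) -> tuple[tuple[float, float], str]:
    """95% profile-likelihood interval for one free parameter.

    The bound is where the profile log-likelihood (re-optimizing the other
    free parameters, warm-started at the MLE) drops ``PROFILE_DROP`` nats
    below the maximum.  Ne is profiled on a log scale.  Returns the interval
    and a flag string ('' or a comma-separated list of 'lower_clipped' /
    'upper_clipped' when a bound hits the search box).
    """
    free = spec.free_params
    if param_name not in free:
        raise ValueError(f"{param_name} is not free in model {spec.name!r}")
    idx = free.index(param_name)
    bounds = _bounds(free)
    x_hat_full = np.empty(len(free))
    x_hat_full[0] = math.log(fit.Ne_hat)
    i = 1
    if "w_direct" in free:
        x_hat_full[i] = fit.w_direct_hat
        i += 1
    if "w_offtarget" in free:
        x_hat_full[i] = fit.w_offtarget_hat
    others = [i for i in range(len(free)) if i != idx]

    def profile(v: float) -> float:
        if not others:
            theta = np.array([v])
            ne, wd, wo = _unpack(theta, free)
            return _pooled_loglik(cages, spec, ne, wd, wo)

        def obj(sub: np.ndarray) -> float:
            theta = np.empty(len(free))
            theta[idx] = v
            theta[others] = sub
            ne, wd, wo = _unpack(theta, free)
            return -_pooled_loglik(cages, spec, ne, wd, wo)

        res = minimize(
            obj,
            x_hat_full[others],
            method="Nelder-Mead",
            bounds=[bounds[i] for i in others],
            options={"fatol": 1e-6, "xatol": 1e-5, "maxiter": 2000},
        )
        return -res.fun

    target = fit.lnL_hat - PROFILE_DROP
    x_hat = x_hat_full[idx]
    lo_bound, lo_clip = _profile_bound(profile, x_hat, target, bounds[idx][0], tol)
    hi_bound, hi_clip = _profile_bound(profile, x_hat, target, bounds[idx][1], tol)
    if param_name == "Ne":
        lo_bound, hi_bound = math.exp(lo_bound), math.exp(hi_bound)
    flags = []
    if lo_clip:
        flags.append("lower_clipped")
    if hi_clip:
        flags.append("upper_clipped")
    return (lo_bound, hi_bound), ",".join(flags)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def model_selection_table(
    cages: Sequence[CageCounts],
    specs: Iterable[ModelSpec],
    n_starts: int = 8,
    seed: int = 0,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Fit every spec and tabulate estimates, CIs, lnL, p, AICc (ascending)."""
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 model specs to compare")
    rows = []
    for spec in specs:
        fit = fit_model(cages, spec, n_starts=n_starts, seed=seed,
                        compute_ci=compute_ci)
        rows.append(
            {
                "model": spec.name,
                "selection": spec.selection_mode,
                "Ne": fit.Ne_hat,
                "Ne_ci_low": fit.ci.get("Ne", (np.nan, np.nan))[0],
                "Ne_ci_high": fit.ci.get("Ne", (np.nan, np.nan))[1],
                "w_direct": fit.w_direct_hat,
                "w_direct_ci_low": fit.ci.get("w_direct", (np.nan, np.nan))[0],
                "w_direct_ci_high": fit.ci.get("w_direct", (np.nan, np.nan))[1],
                "w_offtarget": fit.w_offtarget_hat,
                "w_offtarget_ci_low": fit.ci.get("w_offtarget", (np.nan, np.nan))[0],
                "w_offtarget_ci_high": fit.ci.get("w_offtarget", (np.nan, np.nan))[1],
                "lnL": fit.lnL_hat,
                "p": fit.p,
                "n_transitions": fit.n_transitions,
                "AICc": fit.aicc,
                "converged": fit.converged,
            }
        )
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    return df


def format_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a model-selection table.

    Fitness estimates are rounded to 2 decimals, Ne to integer, AICc to
    integer (half away from zero); fixed parameters render as '1*'.
    """
    out_rows = []
    for _, r in df.iterrows():
        def w_fmt(value, lo, hi):
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return "1*"
            if np.isfinite(lo):
                return f"{value:.2f}[{lo:.2f}-{hi:.2f}]"
            return f"{value:.2f}"

        ne = f"{_round_half_away(r['Ne'])}"
        if np.isfinite(r["Ne_ci_low"]):
            ne += f"[{_round_half_away(r['Ne_ci_low'])}-{_round_half_away(r['Ne_ci_high'])}]"
        out_rows.append(
            {
                "Model": r["model"],
                "Selection": r["selection"],
                "Ne": ne,
                "Direct fitness": w_fmt(
                    r["w_direct"], r["w_direct_ci_low"], r["w_direct_ci_high"]
                ),
                "Off-target fitness": w_fmt(
                    r["w_offtarget"],
                    r["w_offtarget_ci_low"],
                    r["w_offtarget_ci_high"],
                ),
                "lnL": f"{r['lnL']:.1f}",
                "p": str(int(r["p"])),
                "AICc": str(_round_half_away(r["AICc"])),
            }
        )
    tbl = pd.DataFrame(out_rows)
    widths = {c: max(len(c), tbl[c].map(len).max()) for c in tbl.columns}
    lines = ["  ".join(c.ljust(widths[c]) for c in tbl.columns)]
    for _, r in tbl.iterrows():
        lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in tbl.columns))
    return "\n".join(lines)
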