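"""Tests for the multinomial likelihood, fitting, CIs and model selection."""

import math

import numpy as np
import pytest
from scipy.stats import multinomial

from conftest import TRUE_NE, TRUE_W_DIRECT, TRUE_W_OFFTARGET, full_model_configs

from casfit.cage_synth import simulate_cage, simulate_experiment
from casfit.core_model import CutRates, FitnessParams, GenotypeState
from casfit.inference import (
    CageCounts,
    ModelSpec,
    PROFILE_DROP,
    _profile_bound,
    aicc,
    effective_counts,
    fit_model,
    format_table,
    model_selection_table,
    profile_ci,
    trajectory_loglik,
    transition_loglik,
)


class TestCageCounts:
    def test_validation(self):
        with pytest.raises(ValueError):
            CageCounts("r", [0], np.array([[1, 2, 3]]))  # single generation
        with pytest.raises(ValueError):
            CageCounts("r", [0, 0], np.array([[1, 2, 3], [1, 2, 3]]))
        with pytest.raises(ValueError):
            CageCounts("r", [0, 1], np.array([[1, 2, 3], [0, 0, 0]]))

    def test_construct_frequency(self):
        cage = CageCounts("r", [0, 1], np.array([[25, 50, 25], [0, 50, 50]]))
        assert np.allclose(cage.construct_frequency(), [0.5, 0.25])


class TestEffectiveCounts:
    @pytest.mark.parametrize(
        "freqs, ne, expected",
        [
            ((0.5, 0.5, 0.0), 100, (50, 50, 0)),
            ((0.255, 0.5, 0.245), 175, (45, 87, 43)),
        ],
    )
    def test_largest_remainder_examples(self, freqs, ne, expected):
        assert tuple(effective_counts(freqs, ne)) == expected

    def test_thirds_split_evenly(self):
        c = effective_counts((1 / 3, 1 / 3, 1 / 3), 100)
        assert c.sum() == 100 and c.max() - c.min() <= 1

    def test_rejects_tiny_ne(self):
        with pytest.raises(ValueError):
            effective_counts((1, 0, 0), 1.5)


class TestAicc:
    @pytest.mark.parametrize(
        "lnl, p, n, rounded",
        [
            # printed model-comparison values for the Cas9+gRNAs construct
            (373.6, 1, 87, -745),
            (383.6, 2, 87, -763),
            (384.7, 3, 87, -763),
            (0.0, 1, 3, 6),
        ],
    )
    def test_formula(self, lnl, p, n, rounded):
        assert round(aicc(lnl, p, n)) == rounded

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            aicc(0.0, 2, 3)
        with pytest.raises(ValueError):
            aicc(0.0, 0, 10)


class TestTransitionLoglik:
    def test_certain_outcome_contributes_zero(self):
        state = GenotypeState()  # 100% EGFP homozygote
        term, nxt = transition_loglik(
            state, (0, 0, 1), 200, FitnessParams(selection_mode="none"),
            CutRates(0, 0),
        )
        assert term == pytest.approx(0.0, abs=1e-9)
        assert nxt[(0, 0)] == pytest.approx(1.0)

    def test_matches_independent_multinomial_density(self):
        # oracle: scipy multinomial pmf at the pseudo-counts plus the
        # 2-dimensional frequency-lattice Jacobian
        state = GenotypeState.from_dict({(2, 2): 0.5, (0, 0): 0.5})
        params = FitnessParams(selection_mode="none")
        cut = CutRates(1.0, 1.0)
        ne = 2.0
        obs = (0.5, 0.5, 0.0)
        # expected classes are (0.25, 0.5, 0.25) by hand enumeration
        oracle = multinomial(2, [0.25, 0.5, 0.25]).logpmf([1, 1, 0])
        oracle += 2 * math.log(2)
        term, _ = transition_loglik(state, obs, ne, params, cut)
        assert term == pytest.approx(oracle)

    def test_impossible_observation_flags_minus_inf(self):
        state = GenotypeState()  # EGFP only: construct classes unreachable
        term, nxt = transition_loglik(
            state, (0.5, 0.0, 0.5), 100, FitnessParams(selection_mode="none"),
            CutRates(0, 0),
        )
        assert term == -np.inf and nxt is None

    def test_conditioning_preserves_cut_distribution_within_classes(self):
        state = GenotypeState.from_dict({(2, 2): 0.5, (0, 0): 0.5})
        params = FitnessParams(selection_mode="none")
        _, nxt = transition_loglik(state, (0.1, 0.4, 0.5), 100, params,
                                   CutRates(1.0, 1.0))
        # construct marginal replaced by the observation...
        from casfit.core_model import phenotype_marginal

        assert np.allclose(phenotype_marginal(nxt), [0.1, 0.4, 0.5])
        # ...while the model's within-class cut composition is retained:
        # hand enumeration puts the het class at half (1,2), half (1,1)
        assert nxt[(1, 2)] == pytest.approx(0.2)
        assert nxt[(1, 1)] == pytest.approx(0.2)


class TestTrajectoryLoglik:
    def test_all_egfp_cage_has_zero_loglik(self):
        cage = CageCounts(
            "r", [0, 1, 2], np.array([[0, 0, 500]] * 3, dtype=float)
        )
        for name in ("full", "neutral"):
            assert trajectory_loglik(cage, ModelSpec(name), 175, 1, 1) == 0.0

    def test_true_parameters_beat_perturbed_on_average(self):
        spec = ModelSpec("full", "viability")
        cfg = full_model_configs(n_gens=12)[3]
        diffs = []
        for seed in range(200):
            cfg2 = type(cfg)(**{**cfg.__dict__, "seed": seed})
            cage = simulate_cage(cfg2)
            at_truth = trajectory_loglik(
                cage, spec, TRUE_NE, TRUE_W_DIRECT, TRUE_W_OFFTARGET
            )
            perturbed = trajectory_loglik(cage, spec, TRUE_NE, 1.05, 0.70)
            diffs.append(at_truth - perturbed)
        assert np.mean(diffs) > 0


class TestModelSpec:
    def test_free_parameters_by_variant(self):
        assert ModelSpec("full").free_params == ("Ne", "w_direct", "w_offtarget")
        assert ModelSpec("construct").free_params == ("Ne", "w_direct")
        assert ModelSpec("off_target").free_params == ("Ne", "w_offtarget")
        assert ModelSpec("neutral").free_params == ("Ne",)

    def test_default_cut_rates(self):
        assert ModelSpec("full").cut == CutRates(1.0, 1.0)
        assert ModelSpec("initial_off_target").cut == CutRates(0.0, 0.0)
        assert ModelSpec("neutral").cut == CutRates(0.0, 0.0)

    def test_neutral_forces_no_selection(self):
        assert ModelSpec("neutral", "viability").selection_mode == "none"


class TestFitModel:
    def test_full_fit_recovers_generating_parameters(self, cas9_like_cages):
        fit = fit_model(cas9_like_cages, ModelSpec("full", "viability"),
                        compute_ci=True, seed=0)
        assert fit.converged
        lo, hi = fit.ci["w_offtarget"]
        assert lo <= TRUE_W_OFFTARGET <= hi
        lo, hi = fit.ci["Ne"]
        assert lo <= TRUE_NE <= hi
        assert fit.n_transitions == 7 * 12
        assert fit.aicc == pytest.approx(
            aicc(fit.lnL_hat, 3, fit.n_transitions)
        )

    def test_neutral_fit_recovers_ne(self, neutral_cages):
        fit = fit_model(neutral_cages, ModelSpec("neutral"), compute_ci=True,
                        seed=0)
        assert fit.w_direct_hat is None and fit.w_offtarget_hat is None
        lo, hi = fit.ci["Ne"]
        assert lo <= TRUE_NE <= hi

    def test_neutral_ne_coverage_over_replicate_experiments(self):
        from conftest import neutral_configs

        hits = 0
        n_exp = 40
        for seed in range(n_exp):
            cages = simulate_experiment(neutral_configs(), master_seed=1000 + seed)
            fit = fit_model(cages, ModelSpec("neutral"), n_starts=3, seed=0)
            lo, hi = fit.ci["Ne"]
            hits += lo <= TRUE_NE <= hi
        # nominal 95% coverage; conservative bound for 40 replicates
        assert hits >= 0.85 * n_exp

    def test_requires_cages(self):
        with pytest.raises(ValueError):
            fit_model([], ModelSpec("neutral"))


class TestProfileCI:
    def test_quadratic_profile_half_width_closed_form(self):
        # Gaussian log-likelihood with curvature c: the 1.9207-nat drop is
        # at half-width sqrt(2 * 1.9207 / c)
        for c in (0.5, 4.0, 80.0):
            profile = lambda x: -0.5 * c * x**2
            target = -PROFILE_DROP
            bound, clipped = _profile_bound(profile, 0.0, target, 50.0, 1e-5)
            assert not clipped
            assert bound == pytest.approx(math.sqrt(2 * PROFILE_DROP / c),
                                          rel=1e-2)

    def test_clipped_bound_is_flagged(self):
        profile = lambda x: 0.0  # flat likelihood
        bound, clipped = _profile_bound(profile, 0.0, -PROFILE_DROP, 2.0, 1e-4)
        assert clipped and bound == 2.0

    def test_point_estimate_inside_interval(self, cas9_like_cages):
        spec = ModelSpec("off_target", "viability")
        fit = fit_model(cas9_like_cages, spec, compute_ci=False, seed=0)
        (lo, hi), _ = profile_ci(cas9_like_cages, spec, fit, "w_offtarget")
        assert lo <= fit.w_offtarget_hat <= hi

    def test_short_single_cage_gives_wide_fitness_intervals(self):
        # documented non-identifiability: one cage, few transitions
        cfg = full_model_configs(n_gens=4)[2]
        cage = simulate_cage(type(cfg)(**{**cfg.__dict__, "seed": 5}))
        spec = ModelSpec("full", "viability")
        fit = fit_model([cage], spec, compute_ci=True, seed=0)
        for name in ("w_direct", "w_offtarget"):
            lo, hi = fit.ci[name]
            assert hi - lo > 0.1

    def test_unknown_parameter_rejected(self, cas9_like_cages):
        spec = ModelSpec("neutral")
        fit = fit_model(cas9_like_cages, spec, compute_ci=False, seed=0)
        with pytest.raises(ValueError):
            profile_ci(cas9_like_cages, spec, fit, "w_direct")


class TestModelSelection:
    def test_table_is_sorted_and_internally_consistent(self, cas9_like_cages):
        specs = [
            ModelSpec("full", "viability"),
            ModelSpec("off_target", "viability"),
            ModelSpec("construct", "viability"),
            ModelSpec("neutral"),
        ]
        df = model_selection_table(cas9_like_cages, specs, n_starts=4,
                                   seed=0, compute_ci=False)
        assert list(df["AICc"]) == sorted(df["AICc"])
        for _, r in df.iterrows():
            assert r["AICc"] == pytest.approx(
                aicc(r["lnL"], int(r["p"]), int(r["n_transitions"]))
            )
        # nested maximization: the full model dominates its submodels
        lnl = df.set_index("model")["lnL"]
        assert lnl["full"] >= lnl["off_target"] - 1e-4
        assert lnl["full"] >= lnl["construct"] - 1e-4
        assert min(lnl["off_target"], lnl["construct"]) >= lnl["neutral"] - 1e-4

    def test_neutral_data_prefer_neutral_model(self):
        from conftest import neutral_configs

        specs = [
            ModelSpec("full", "viability"),
            ModelSpec("construct", "viability"),
            ModelSpec("off_target", "viability"),
            ModelSpec("neutral"),
        ]
        wins = 0
        n_exp = 10
        for seed in range(n_exp):
            cages = simulate_experiment(neutral_configs(), master_seed=3000 + seed)
            df = model_selection_table(cages, specs, n_starts=3, seed=0,
                                       compute_ci=False)
            wins += df.iloc[0]["model"] == "neutral"
        assert wins >= 6

    def test_requires_two_specs(self, cas9_like_cages):
        with pytest.raises(ValueError):
            model_selection_table(cas9_like_cages, [ModelSpec("neutral")])

    def test_formatting_marks_fixed_parameters(self, cas9_like_cages):
        df = model_selection_table(
            cas9_like_cages,
            [ModelSpec("off_target", "viability"), ModelSpec("neutral")],
            n_starts=2, seed=0, compute_ci=False,
        )
        text = format_table(df)
        assert "1*" in text and "AICc" in text
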