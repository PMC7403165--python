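import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcmix import (
    CorpusProbabilityTable,
    StudyDesign,
    fit_all_participants,
    fit_weights,
    model_fit_correlation,
    observed_proportions,
    predict_probabilities,
)
from gpcmix.mixture import aggregate_weights

from conftest import simplex_grid


def exact_observed(beta, probs, design):
    """Observed proportions generated exactly by the mixture equation."""
    obs = {}
    for cond in design.conditions:
        pred = predict_probabilities(beta, probs, cond, design)
        for cat, p in pred.items():
            obs[(cond, cat)] = p
    return obs


def grid_min_loss(obs, probs, design, step=0.01):
    """Brute-force minimum of the loss over a simplex grid."""
    rows, y = [], []
    for cond in design.conditions:
        mat = probs.rule_matrix(design, cond)
        for i, cat in enumerate(design.response_categories):
            rows.append(mat[i])
            y.append(obs[(cond, cat)])
    A, y = np.array(rows), np.array(y)
    pts = simplex_grid(step)
    losses = ((pts @ A.T - y) ** 2).sum(axis=1)
    return float(losses.min())


class TestPredict:
    def test_identity_weighting_returns_rule_distribution(self, english):
        design, probs = english
        pred = predict_probabilities((1, 0, 0), probs, "CS_O+CS_B+", design)
        assert pred["ae"] == pytest.approx(
            probs.probability("CS_O+CS_B+", "simpleGPC", "ae")
        )

    def test_hand_evaluated_weighted_sum(self):
        design = StudyDesign(
            language_mode="english_style",
            conditions=("c1", "c2", "c3", "c4"),
            response_categories=("ae",),
            rule_types=("simpleGPC", "CS_O", "CS_B"),
        )
        entries = {c: {"simpleGPC": {"ae": 0.9}, "CS_O": {"ae": 0.1},
                       "CS_B": {"ae": 0.5}} for c in design.conditions}
        probs = CorpusProbabilityTable(entries=entries)
        pred = predict_probabilities((0.5, 0.5, 0), probs, "c1", design)
        assert pred["ae"] == pytest.approx(0.5 * 0.9 + 0.5 * 0.1)

    def test_predictions_sum_to_one_for_complete_distributions(self, german):
        design, probs = german
        for cond in design.conditions:
            pred = predict_probabilities((0.2, 0.5, 0.3), probs, cond, design)
            assert sum(pred.values()) == pytest.approx(1.0)

    def test_missing_condition_entry_names_gap(self, english):
        design, probs = english
        with pytest.raises(KeyError, match="nonexistent"):
            predict_probabilities((1, 0, 0), probs, "nonexistent", design)


class TestObservedProportions:
    def test_all_same_category(self, english, make_records):
        design, _ = english
        rows = [("p1", 2, f"i{t}", "CS_O+CS_B+", "ae", True, False) for t in range(16)]
        obs, dropped = observed_proportions(make_records(rows), "p1", design)
        assert obs[("CS_O+CS_B+", "ae")] == 1.0
        assert dropped == ["CS_O-CS_B+", "CS_O+CS_B-", "CS_O-CS_B-"]

    def test_other_vowel_in_denominator_by_default(self, english, make_records):
        design, _ = english
        cats = ["ae"] * 6 + ["open_o"] * 3 + ["other_vowel"]
        rows = [("p1", 2, f"i{t}", "CS_O+CS_B+", c, True, False)
                for t, c in enumerate(cats)]
        df = make_records(rows)
        obs, _ = observed_proportions(df, "p1", design)
        assert obs[("CS_O+CS_B+", "ae")] == pytest.approx(0.6)
        assert obs[("CS_O+CS_B+", "open_o")] == pytest.approx(0.3)
        # the auditable switch: renormalise over modeled categories only
        obs2, _ = observed_proportions(df, "p1", design, renormalize_modeled=True)
        assert obs2[("CS_O+CS_B+", "ae")] == pytest.approx(6 / 9)

    def test_all_error_condition_dropped(self, english, make_records):
        design, _ = english
        rows = [("p1", 2, f"i{t}", "CS_O+CS_B+", "consonant_error", False, True)
                for t in range(5)]
        rows += [("p1", 2, f"j{t}", "CS_O-CS_B+", "ae", True, False) for t in range(5)]
        obs, dropped = observed_proportions(make_records(rows), "p1", design)
        assert "CS_O+CS_B+" in dropped
        assert ("CS_O+CS_B+", "ae") not in obs


class TestFitWeights:
    def test_recovers_exact_mixture_and_beats_grid(self, english):
        design, probs = english
        beta_true = np.array([0.2, 0.7, 0.1])
        obs = exact_observed(beta_true, probs, design)
        fit = fit_weights(obs, probs, design, constrained=True)
        assert fit.converged and fit.identifiable
        assert np.abs(fit.beta - beta_true).max() < 1e-3
        assert fit.loss < 1e-10
        assert fit.loss <= grid_min_loss(obs, probs, design) + 1e-9

    def test_identity_case(self, english):
        design, probs = english
        obs = exact_observed(np.array([1.0, 0.0, 0.0]), probs, design)
        fit = fit_weights(obs, probs, design)
        assert np.abs(fit.beta - np.array([1.0, 0.0, 0.0])).max() < 1e-4

    def test_degenerate_rules_flagged_unidentifiable(self):
        design = StudyDesign(
            language_mode="english_style",
            conditions=("c1", "c2", "c3", "c4"),
            response_categories=("ae", "open_o"),
            rule_types=("simpleGPC", "CS_O", "CS_B"),
        )
        cell = {"ae": 0.6, "open_o": 0.3}
        entries = {c: {r: dict(cell) for r in design.rule_types}
                   for c in design.conditions}
        probs = CorpusProbabilityTable(entries=entries)
        obs = exact_observed(np.array([1 / 3] * 3), probs, design)
        fit = fit_weights(obs, probs, design)
        assert not fit.identifiable

    def test_fewer_than_two_conditions_fatal(self, english):
        design, probs = english
        obs = {("CS_O+CS_B+", c): 0.3 for c in design.response_categories}
        with pytest.raises(ValueError, match="at least 2 conditions"):
            fit_weights(obs, probs, design)

    def test_simplex_constraints_hold(self, english):
        design, probs = english
        rng = np.random.default_rng(5)
        obs = {(c, cat): rng.uniform(0, 0.4)
               for c in design.conditions for cat in design.response_categories}
        fit = fit_weights(obs, probs, design, constrained=True)
        assert fit.beta.min() >= -1e-6 and fit.beta.max() <= 1 + 1e-6
        assert fit.beta.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constrained_beats_random_simplex_points(self, english):
        design, probs = english
        rng = np.random.default_rng(17)
        obs = {(c, cat): rng.uniform(0, 0.5)
               for c in design.conditions for cat in design.response_categories}
        fit = fit_weights(obs, probs, design, constrained=True)
        rows, y = [], []
        for cond in design.conditions:
            mat = probs.rule_matrix(design, cond)
            for i, cat in enumerate(design.response_categories):
                rows.append(mat[i]); y.append(obs[(cond, cat)])
        A, y = np.array(rows), np.array(y)
        pts = rng.dirichlet(np.ones(3), size=1000)
        losses = ((pts @ A.T - y) ** 2).sum(axis=1)
        assert fit.loss <= losses.min() + 1e-9

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_relaxed_loss_never_exceeds_constrained(self, english, seed):
        design, probs = english
        rng = np.random.default_rng(seed)
        obs = {(c, cat): rng.uniform(0, 0.6)
               for c in design.conditions for cat in design.response_categories}
        con = fit_weights(obs, probs, design, constrained=True)
        rel = fit_weights(obs, probs, design, constrained=False)
        assert rel.loss <= con.loss + 1e-9

    def test_relaxed_allows_negative_weights(self):
        # a target outside the simplex span forces a negative coefficient
        design = StudyDesign(
            language_mode="english_style",
            conditions=("c1", "c2", "c3", "c4"),
            response_categories=("ae", "open_o"),
            rule_types=("simpleGPC", "CS_O", "CS_B"),
        )
        entries = {
            "c1": {"simpleGPC": {"ae": 0.9, "open_o": 0.05},
                   "CS_O": {"ae": 0.1, "open_o": 0.8},
                   "CS_B": {"ae": 0.5, "open_o": 0.3}},
            "c2": {"simpleGPC": {"ae": 0.8, "open_o": 0.1},
                   "CS_O": {"ae": 0.2, "open_o": 0.7},
                   "CS_B": {"ae": 0.4, "open_o": 0.5}},
            "c3": {"simpleGPC": {"ae": 0.7, "open_o": 0.2},
                   "CS_O": {"ae": 0.3, "open_o": 0.6},
                   "CS_B": {"ae": 0.6, "open_o": 0.2}},
            "c4": {"simpleGPC": {"ae": 0.85, "open_o": 0.1},
                   "CS_O": {"ae": 0.15, "open_o": 0.75},
                   "CS_B": {"ae": 0.55, "open_o": 0.35}},
        }
        probs = CorpusProbabilityTable(entries=entries)
        A = np.vstack([probs.rule_matrix(design, c) for c in design.conditions])
        beta_out = np.array([1.4, -0.3, -0.1])
        y = A @ beta_out
        obs = {}
        i = 0
        for cond in design.conditions:
            for cat in design.response_categories:
                obs[(cond, cat)] = float(y[i]); i += 1
        rel = fit_weights(obs, probs, design, constrained=False)
        assert rel.beta.min() < 0
        assert np.abs(rel.beta - beta_out).max() < 1e-6

    def test_permutation_equivariance(self, english):
        design, probs = english
        beta_true = np.array([0.2, 0.7, 0.1])
        obs = exact_observed(beta_true, probs, design)
        fit = fit_weights(obs, probs, design)

        perm_design = StudyDesign(
            language_mode=design.language_mode,
            conditions=design.conditions,
            response_categories=design.response_categories,
            rule_types=(design.rule_types[2], design.rule_types[0],
                        design.rule_types[1]),
            items_per_condition=design.items_per_condition,
        )
        fit_p = fit_weights(obs, probs, perm_design)
        assert np.allclose(fit_p.beta, fit.beta[[2, 0, 1]], atol=1e-4)

    def test_scale_consistency_percentages_vs_proportions(self, english):
        design, probs = english
        rng = np.random.default_rng(3)
        obs = {(c, cat): rng.uniform(0, 0.5)
               for c in design.conditions for cat in design.response_categories}
        obs_pct = {k: 100 * v for k, v in obs.items()}
        probs_pct = CorpusProbabilityTable(entries={
            c: {r: {cat: 100 * p for cat, p in cell.items()}
                for r, cell in rules.items()}
            for c, rules in probs.entries.items()
        })
        f1 = fit_weights(obs, probs, design)
        f2 = fit_weights(obs_pct, probs_pct, design)
        assert np.allclose(f1.beta, f2.beta, atol=1e-5)


class TestModelFitAndAggregation:
    def test_perfect_prediction_gives_r_one(self, simulated_english, english):
        design, probs = english
        df, beta_true = simulated_english
        fits = fit_all_participants(df, probs, design)
        rs = model_fit_correlation(fits, df, probs, design, group_by="grade")
        assert set(rs) == {2, 3}
        assert all(r > 0.97 for r in rs.values())

    def test_hand_computed_pearson(self):
        obs = np.array([10.0, 20.0, 30.0, 40.0])
        pred = np.array([12.0, 18.0, 33.0, 37.0])
        # direct evaluation of the Pearson formula
        r_hand = (((obs - obs.mean()) * (pred - pred.mean())).sum()
                  / np.sqrt(((obs - obs.mean()) ** 2).sum()
                            * ((pred - pred.mean()) ** 2).sum()))
        assert np.corrcoef(obs, pred)[0, 1] == pytest.approx(r_hand)

    def test_zero_variance_reported_as_nan(self, english, make_records):
        # one trial of each modeled category per condition: every observed
        # cell is 1/3, so the observed vector is constant and r is undefined
        design, probs = english
        rows = [("p1", 2, f"{c}_i{i}", c, cat, True, False)
                for c in design.conditions
                for i, cat in enumerate(design.response_categories)]
        df = make_records(rows)
        fits = fit_all_participants(df, probs, design)
        rs = model_fit_correlation(fits, df, probs, design, group_by="grade")
        assert np.isnan(rs[2])

    def test_aggregate_means_and_simplex_preservation(self, english):
        design, probs = english
        fits = []
        for pid, beta in [("a", (0.2, 0.7, 0.1)), ("b", (0.4, 0.5, 0.1))]:
            obs = exact_observed(np.array(beta), probs, design)
            fits.append(fit_weights(obs, probs, design, participant_id=pid))
        tab = aggregate_weights(fits, {"a": 2, "b": 2})
        row = tab[tab.grade == 2].iloc[0]
        assert row["simpleGPC_mean"] == pytest.approx(0.3, abs=1e-3)
        assert row["CS_O_mean"] == pytest.approx(0.6, abs=1e-3)
        assert row["CS_B_mean"] == pytest.approx(0.1, abs=1e-3)
        # constrained fits: mean betas still sum to 1
        total = sum(row[f"{r}_mean"] for r in design.rule_types)
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_single_fit_sd_is_nan(self, english):
        design, probs = english
        obs = exact_observed(np.array([0.2, 0.7, 0.1]), probs, design)
        tab = aggregate_weights([fit_weights(obs, probs, design,
                                             participant_id="solo")], {"solo": 4})
        assert np.isnan(tab[tab.grade == 4]["simpleGPC_sd"].iloc[0])
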