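import numpy as np
import pandas as pd
import pytest

from domcert.health_models import (
    HYPOTHESIS_TERMS,
    ModelSpec,
    candidate_set,
    fit_outcome_model,
    fold_change,
    selection_from_aicc,
    selection_from_deltas,
)
from domcert.reference_tables import COEFFICIENTS, SELECTION_DELTAS


class TestModelSpecs:
    def test_hypothesis_set_is_complete(self):
        assert set(HYPOTHESIS_TERMS) == {
            "H0", "H1", "H2", "H3", "H4", "H5", "H6", "H7a", "H7b", "H8"}

    def test_crp_controls_include_il6_and_order(self):
        rhs = ModelSpec("H3", "crp").formula_rhs
        assert "il6" in rhs and "sampling_order" in rhs

    def test_null_model_keeps_controls_only(self):
        assert ModelSpec("H0", "diarrhea").formula_rhs == "1"
        assert "rank" not in ModelSpec("H0", "il6").formula_rhs

    def test_interaction_terms_present_for_h8(self):
        rhs = ModelSpec("H8", "tnfa").formula_rhs
        assert "rank:dc" in rhs
        assert rhs.count(":") >= 4  # three two-way + one three-way

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("H9", "crp")
        with pytest.raises(ValueError):
            ModelSpec("H1", "cortisol")


class TestSelectionArithmetic:
    def test_best_model_likelihood_is_one(self):
        table = selection_from_deltas({"A": 0.0, "B": 2.0})
        assert table.loc["A", "likelihood"] == pytest.approx(1.0)
        assert table.loc["A", "evidence_ratio"] == pytest.approx(1.0)

    def test_published_likelihood_value(self):
        # dAICc of 6.84 corresponds to a model likelihood of 0.033
        table = selection_from_deltas(SELECTION_DELTAS["crp"])
        assert table.loc["H5", "likelihood"] == pytest.approx(0.033, abs=5e-4)

    def test_equal_aicc_splits_weight(self):
        table = selection_from_aicc({"A": 100.0, "B": 100.0})
        assert np.allclose(table["weight"], 0.5)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            aicc = {f"M{i}": 500 + 30 * rng.random() for i in range(8)}
            table = selection_from_aicc(aicc)
            assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_evidence_ratio_identity(self):
        # ratio of weights equals exp(dAICc/2) algebraically
        table = selection_from_deltas(SELECTION_DELTAS["il6"])
        for h, row in table.iterrows():
            assert row["evidence_ratio"] == pytest.approx(
                np.exp(row["delta_aicc"] / 2), rel=1e-12)

    def test_sorted_ascending(self):
        table = selection_from_deltas(SELECTION_DELTAS["diarrhea"])
        assert table["delta_aicc"].is_monotonic_increasing

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            selection_from_deltas({"A": -0.5, "B": 0.0})


class TestCandidateSet:
    def test_dominant_best_model_is_singleton(self):
        table = selection_from_deltas(SELECTION_DELTAS["crp"])
        assert table["weight"].iloc[0] > 0.90
        assert candidate_set(table) == ["H8"]

    def test_spread_weight_keeps_delta_window(self):
        table = selection_from_deltas(SELECTION_DELTAS["il6"])
        assert candidate_set(table) == ["H5", "H8", "H3", "H1"]

    def test_null_model_excluded(self):
        table = selection_from_deltas(SELECTION_DELTAS["diarrhea"])
        cand = candidate_set(table)
        assert "H0" not in cand
        assert cand == ["H4", "H3", "H7b", "H2", "H5", "H7a"]

    def test_synthetic_dominant_weight(self):
        table = selection_from_deltas({"A": 0.0, "B": 8.0, "C": 12.0})
        assert table["weight"].iloc[0] > 0.95
        assert candidate_set(table) == ["A"]


class TestFoldChange:
    def test_zero_delta_is_neutral(self):
        es = fold_change({"dc": -2.46}, "dc", 0.0)
        assert es.fold_change == pytest.approx(1.0)
        assert es.direction == "no change"

    def test_reciprocity(self):
        up = fold_change({"rank": 1.3}, "rank", 0.25)
        down = fold_change({"rank": 1.3}, "rank", -0.25)
        assert up.fold_change * down.fold_change == pytest.approx(1.0)

    def test_published_il6_certainty_effect(self):
        # +0.10 certainty at the published H3 coefficient: 1.28x lower IL-6
        es = fold_change(COEFFICIENTS[("il6", "H3")], "dc", 0.10)
        assert es.direction == "decrease"
        assert es.magnitude == pytest.approx(1.28, abs=0.01)

    def test_published_diarrhea_certainty_effect(self):
        es = fold_change(COEFFICIENTS[("diarrhea", "H3")], "dc", -0.10)
        assert es.direction == "increase"
        assert es.magnitude == pytest.approx(2.44, abs=0.01)

    def test_interaction_slope_uses_moderators(self):
        coefs = {"rank": 2.0, "dc": 1.0, "rank:dc": -4.0}
        es = fold_change(coefs, "rank", 0.5, {"dc": 0.75})
        # effective slope = 2.0 - 4.0 * 0.75 = -1.0
        assert es.effective_slope == pytest.approx(-1.0)
        assert es.fold_change == pytest.approx(np.exp(-0.5))

    def test_missing_moderator_is_error(self):
        with pytest.raises(ValueError, match="dc"):
            fold_change({"rank": 1.0, "rank:dc": -2.0}, "rank", 0.25)

    def test_unknown_predictor_is_error(self):
        with pytest.raises(ValueError):
            fold_change({"rank": 1.0}, "dc", 0.1)


class TestAiccLimit:
    def test_aicc_approaches_aic_for_large_n(self):
        k, n = 5, 10 ** 5 + 7
        correction = 2 * k * (k + 1) / (n - k - 1)
        assert correction < 0.01


def synthetic_outcome_table(rng, n_per_group=90):
    rows = []
    for g in "ABC":
        for i in range(n_per_group):
            rows.append({
                "animal_id": f"{g}{i}", "group_id": g,
                "sex": "M" if rng.random() < 0.3 else "F",
                "age_cat": rng.choice(["3", "4-5", "6-12", "13+"]),
                "rank": rng.random(),
                "dc": 0.5 + 0.5 * rng.random(),
                "sampling_order": rng.integers(1, 9),
                "observation_days": 12,
            })
    df = pd.DataFrame(rows)
    eta = -0.5 + 1.2 * df["rank"] + 0.8 * df["dc"]
    mu = np.exp(eta)
    r = 1 / 0.5
    df["il6"] = rng.negative_binomial(r, r / (r + mu))
    df["tnfa"] = df["il6"]
    df["crp"] = rng.gamma(2.0, np.exp(0.2 + 0.5 * df["rank"]) / 2.0)
    df["diarrhea_bouts"] = rng.poisson(0.4, len(df))
    return df


class TestFitOutcomeModel:
    def test_recovers_generating_slopes(self):
        rng = np.random.default_rng(77)
        df = synthetic_outcome_table(rng)
        fit = fit_outcome_model(df, ModelSpec("H4", "il6"))
        assert fit.coef("rank") == pytest.approx(1.2, abs=2.5 * fit.se[
            fit.param_names.index("rank")])
        assert fit.coef("dc") == pytest.approx(0.8, abs=2.5 * fit.se[
            fit.param_names.index("dc")])

    def test_diarrhea_uses_observation_offset(self):
        rng = np.random.default_rng(78)
        df = synthetic_outcome_table(rng)
        fit12 = fit_outcome_model(df, ModelSpec("H0", "diarrhea"))
        df2 = df.copy()
        df2["observation_days"] = 24  # doubling exposure halves the rate
        fit24 = fit_outcome_model(df2, ModelSpec("H0", "diarrhea"))
        assert fit24.params[0] == pytest.approx(
            fit12.params[0] - np.log(2), abs=0.05)

    def test_referent_levels_are_males_and_adults(self):
        rng = np.random.default_rng(79)
        df = synthetic_outcome_table(rng)
        fit = fit_outcome_model(df, ModelSpec("H1", "il6"))
        assert "sex[F]" in fit.param_names
        assert "age_cat[6-12]" not in " ".join(fit.param_names)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(80)
        df = synthetic_outcome_table(rng)
        df["group_id"] = "A"
        with pytest.raises(ValueError):
            fit_outcome_model(df, ModelSpec("H1", "il6"))
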