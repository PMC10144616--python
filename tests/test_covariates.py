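import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pvaff import (
    DesignSpec,
    LogisticRiskModel,
    encode_design,
    features_from_records,
    univariate_tests,
)


def make_features(rng, n, beta0=-2.0, betas=None):
    """Simulate a flat feature frame from a known logistic model."""
    betas = betas or {}
    df = pd.DataFrame({
        "female": rng.integers(0, 2, n).astype(float),
        "exposed": rng.integers(0, 2, n).astype(float),
        "age_years": rng.normal(60, 15, n),
    })
    eta = beta0 + sum(b * df[k] for k, b in betas.items())
    df["is_case"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return df


class TestUnivariate:
    def test_symmetry_under_group_swap(self):
        df = pd.DataFrame({
            "v": [1.0, 2, 3, 4, 10, 11, 12, 13],
            "is_case": [1, 1, 1, 1, 0, 0, 0, 0],
        })
        flipped = df.assign(is_case=1 - df["is_case"])
        _, p1 = univariate_tests(df, "v", "continuous")
        _, p2 = univariate_tests(flipped, "v", "continuous")
        assert p1 == pytest.approx(p2)

    def test_rank_sum_matches_exhaustive_permutation(self):
        case = [1.3, 2.1, 7.4, 9.0]
        ctrl = [0.5, 3.3, 4.2, 5.1]
        df = pd.DataFrame({"v": case + ctrl, "is_case": [1] * 4 + [0] * 4})
        _, p = univariate_tests(df, "v", "continuous")
        # oracle: exact permutation distribution of the rank-sum statistic
        pooled = np.array(case + ctrl)
        ranks = pooled.argsort().argsort() + 1
        n1 = len(case)
        obs = ranks[:n1].sum()
        mu = n1 * (len(pooled) + 1) / 2
        stats = [sum(c) for c in itertools.combinations(ranks, n1)]
        p_exact = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in stats])
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_right_tail_smaller_for_enriched_flag(self):
        df = pd.DataFrame({
            "flag": [1] * 9 + [0] * 1 + [1] * 2 + [0] * 8,
            "is_case": [1] * 10 + [0] * 10,
        })
        _, p_two = univariate_tests(df, "flag", "binary_two_sided")
        _, p_right = univariate_tests(df, "flag", "binary_right_tailed")
        assert p_right < p_two

    def test_empty_group_yields_missing_p(self):
        df = pd.DataFrame({"v": [np.nan, np.nan, 3.0],
                           "is_case": [1, 1, 0]})
        _, p = univariate_tests(df, "v", "continuous")
        assert math.isnan(p)


class TestEncodeDesign:
    def test_effect_coding_values(self):
        df = pd.DataFrame({"exposed": [1.0, 0.0, 1.0],
                           "is_case": [1.0, 0.0, 0.0]})
        spec = DesignSpec(binary_predictors=["exposed"])
        X, y, _ = encode_design(df, spec)
        assert X["exposed"].tolist() == [1.0, -1.0, 1.0]
        assert y.tolist() == [1.0, 0.0, 0.0]

    def test_complete_case_dropping_and_dimensions(self):
        df = pd.DataFrame({
            "exposed": [1.0, 0, 1, 0, np.nan],
            "bmi": [20.0, 22, np.nan, 25, 24],
            "is_case": [1.0, 0, 0, 1, 0],
        })
        spec = DesignSpec(binary_predictors=["exposed"],
                          continuous_predictors=["bmi"])
        X, y, ranges = encode_design(df, spec)
        assert X.shape == (3, 3)  # const + 2 predictors, complete rows only
        assert ranges["bmi"] == (20.0, 25.0)

    def test_constant_column_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"exposed": [1.0, 1, 1, 1],
                           "is_case": [1.0, 0, 1, 0]})
        spec = DesignSpec(binary_predictors=["exposed"])
        with caplog.at_level("WARNING"):
            X, _, _ = encode_design(df, spec)
        assert "exposed" not in X.columns
        assert any("constant" in r.message for r in caplog.records)

    def test_duplicate_predictor_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            DesignSpec(binary_predictors=["x"], continuous_predictors=["x"])

    def test_features_from_records_encodes_exposure(self, tiny_records):
        feats = features_from_records(tiny_records, drugs=["drug X"],
                                      event="atypical femoral fracture")
        assert feats["drug_drug X"].sum() == 4
        assert feats["is_case"].sum() == 3


class TestLogisticFit:
    def test_null_model_recovers_no_effect(self):
        rng = np.random.default_rng(7)
        df = make_features(rng, 10_000, beta0=-1.0)
        spec = DesignSpec(binary_predictors=["female", "exposed"],
                          continuous_predictors=["age_years"])
        X, y, ranges = encode_design(df, spec)
        res = LogisticRiskModel(X, y, spec, ranges).fit()
        for name in ("female", "exposed"):
            assert abs(res.params[name]) < 0.1
            assert res.level_or[name] == pytest.approx(1.0, abs=0.25)

    def test_planted_coefficients_recovered_within_three_se(self):
        rng = np.random.default_rng(50_001)
        truth = {"female": 0.8, "exposed": 1.2, "age_years": 0.02}
        df = make_features(rng, 50_000, beta0=-4.0, betas=truth)
        spec = DesignSpec(binary_predictors=["female", "exposed"],
                          continuous_predictors=["age_years"],
                          binary_coding=(0.0, 1.0))
        X, y, ranges = encode_design(df, spec)
        res = LogisticRiskModel(X, y, spec, ranges).fit()
        for name, b in truth.items():
            assert abs(res.params[name] - b) < 3 * res.bse[name]

    def test_effect_and_dummy_coding_are_equivalent(self):
        rng = np.random.default_rng(12)
        df = make_features(rng, 4000, beta0=-1.5,
                           betas={"female": 0.7, "exposed": -0.4})
        names = ["female", "exposed"]
        fits = {}
        for coding in [(-1.0, 1.0), (0.0, 1.0)]:
            spec = DesignSpec(binary_predictors=names, binary_coding=coding)
            X, y, ranges = encode_design(df, spec)
            fits[coding] = LogisticRiskModel(X, y, spec, ranges).fit()
        eff, dum = fits[(-1.0, 1.0)], fits[(0.0, 1.0)]
        for name in names:
            assert dum.params[name] == pytest.approx(2 * eff.params[name],
                                                     rel=1e-6)
            assert eff.level_or[name] == pytest.approx(dum.level_or[name],
                                                       rel=1e-6)
        np.testing.assert_allclose(eff.predict(), dum.predict(), atol=1e-8)

    def test_fit_improves_on_null_loglik(self):
        rng = np.random.default_rng(3)
        df = make_features(rng, 5000, beta0=-1.0, betas={"exposed": 1.0})
        spec = DesignSpec(binary_predictors=["exposed"])
        X, y, ranges = encode_design(df, spec)
        res = LogisticRiskModel(X, y, spec, ranges).fit()
        assert res.llf >= res.llnull

    def test_complete_separation_names_predictor(self):
        df = pd.DataFrame({"exposed": [1.0, 1, 1, 0, 0, 0],
                           "is_case": [1.0, 1, 1, 0, 0, 0]})
        spec = DesignSpec(binary_predictors=["exposed"])
        X, y, _ = encode_design(df, spec)
        with pytest.raises((ValueError, RuntimeError), match="exposed|separ"):
            LogisticRiskModel(X, y, spec).fit()

    def test_requires_both_outcomes(self):
        df = pd.DataFrame({"exposed": [1.0, 0.0], "is_case": [0.0, 0.0]})
        spec = DesignSpec(binary_predictors=["exposed"])
        X, y, _ = encode_design(df, spec)
        with pytest.raises(ValueError, match="at least one event"):
            LogisticRiskModel(X, y, spec)

    def test_wald_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(99)
        b_true = 0.9
        hits = reps = 0
        spec = DesignSpec(binary_predictors=["exposed"])
        for _ in range(200):
            df = make_features(rng, 1500, beta0=-1.0,
                               betas={"exposed": b_true})
            X, y, _ = encode_design(df, spec)
            try:
                res = LogisticRiskModel(X, y, spec).fit()
            except (ValueError, RuntimeError):
                continue
            lo, hi = res.conf_int.loc["exposed"]
            reps += 1
            hits += lo <= b_true / 2 <= hi  # +-1 coding halves the slope
        assert reps > 180
        assert 0.90 <= hits / reps <= 0.99

    def test_summary_and_table_shape(self):
        rng = np.random.default_rng(4)
        df = make_features(rng, 3000, beta0=-1.0, betas={"exposed": 0.8})
        spec = DesignSpec(binary_predictors=["exposed"],
                          continuous_predictors=["age_years"])
        X, y, ranges = encode_design(df, spec)
        res = LogisticRiskModel(X, y, spec, ranges).fit()
        frame = res.odds_ratio_frame()
        assert list(frame["predictor"]) == [
            "exposed", "age_years (unit)", "age_years (range)"]
        assert "Logistic risk model" in res.summary()
        row = frame.set_index("predictor").loc["exposed"]
        assert row["ci_low"] <= row["or"] <= row["ci_high"]
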