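"""Verification sampling, IPW screening estimates, weighted AUC, kappa."""

import numpy as np
import pandas as pd
import pytest

from phenorisk.evaluation import (
    SamplingDesign,
    bootstrap_ci,
    cohens_kappa,
    draw_review_sample,
    ipw_estimates,
    prevalence_by_stratum,
    simulate_chart_review,
    weighted_auc,
)
from phenorisk.model import score_percentiles


def make_frame(n=10_000, seed=0):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=n)
    return pd.DataFrame({
        "patient_id": [f"v{i}" for i in range(n)],
        "score": scores,
        "percentile": score_percentiles(scores, scores),
    })


def reviewed_toy():
    """Hand-built two-stratum review set with known weighted 2x2 table."""
    rows = [
        # stratum, pi, score, label
        ("a", 0.5, 10.0, "probable"),
        ("a", 0.5, 10.0, "possible"),
        ("a", 0.5, 1.0, "possible"),   # weighted fn = 2
        ("a", 0.5, 1.0, "none"),       # weighted tn = 2
        ("b", 1.0, 2.0, "probable"),   # tp += 1
        ("b", 1.0, 2.0, "none"),       # fp = 1
        ("b", 1.0, 0.5, "none"),
        ("b", 1.0, 0.5, "none"),
        ("b", 1.0, 0.5, "none"),
    ]
    df = pd.DataFrame(rows, columns=["stratum", "pi", "score", "review_label"])
    df["patient_id"] = [f"t{i}" for i in range(len(df))]
    df["percentile"] = score_percentiles(df["score"].to_numpy(),
                                         df["score"].to_numpy())
    return df


class TestSamplingDesign:
    def test_default_design_draws_600_with_valid_pi(self):
        frame = make_frame()
        reviewed = draw_review_sample(frame, SamplingDesign(seed=3))
        assert len(reviewed) == 600
        assert reviewed["patient_id"].is_unique
        assert (reviewed["pi"] > 0).all() and (reviewed["pi"] <= 1).all()
        counts = reviewed["stratum"].value_counts()
        assert counts["srs"] == 200 and counts["mid"] == 100
        assert all(counts[f"band_{b}_{b + 1}"] == 30 for b in range(90, 100))

    def test_census_design_gives_pi_one(self):
        frame = make_frame(n=50)
        design = SamplingDesign(n_srs=50, n_mid=0, band_start=100.0, seed=0)
        reviewed = draw_review_sample(frame, design)
        assert len(reviewed) == 50
        np.testing.assert_allclose(reviewed["pi"], 1.0)

    def test_two_stratum_toy_pi_matches_hand_computation(self):
        frame = make_frame(n=20, seed=5)
        design = SamplingDesign(n_srs=0, mid_stratum=(0.0, 50.0), n_mid=5,
                                band_start=50.0, band_width=50.0,
                                n_per_band=5, seed=2)
        reviewed = draw_review_sample(frame, design)
        assert len(reviewed) == 10
        np.testing.assert_allclose(reviewed["pi"], 0.5)

    def test_deterministic_given_seed(self):
        frame = make_frame(n=2000, seed=1)
        design = SamplingDesign(n_srs=40, n_mid=20, n_per_band=2, seed=8)
        r1 = draw_review_sample(frame, design)
        r2 = draw_review_sample(frame, design)
        pd.testing.assert_frame_equal(r1, r2)

    def test_infeasible_stratum_raises(self):
        frame = make_frame(n=100)
        with pytest.raises(ValueError):
            draw_review_sample(frame, SamplingDesign(seed=0))  # needs 30/band

    def test_bands_must_partition(self):
        with pytest.raises(ValueError):
            SamplingDesign(band_start=90.0, band_width=3.0)


class TestIpwEstimates:
    def test_equal_weights_reduce_to_sample_proportions(self):
        rng = np.random.default_rng(4)
        n = 200
        df = pd.DataFrame({
            "patient_id": [f"x{i}" for i in range(n)],
            "stratum": ["srs"] * n,
            "pi": [0.37] * n,
            "score": rng.normal(size=n),
            "review_label": rng.choice(["none", "possible", "probable"], n),
        })
        est = ipw_estimates(df, df["score"].to_numpy(), 50.0)
        pos = df["review_label"].isin(["possible", "probable"])
        assert est.prevalence == pytest.approx(pos.mean())

    def test_hand_built_weighted_table(self):
        df = reviewed_toy()
        est = ipw_estimates(df, np.array([1.5]), 50.0)  # cutoff value 1.5
        assert est.prevalence == pytest.approx(7 / 13)
        assert est.sensitivity == pytest.approx(5 / 7)
        assert est.specificity == pytest.approx(5 / 6)
        assert est.ppv == pytest.approx(5 / 6)
        assert est.npv == pytest.approx(5 / 7)
        assert est.accuracy == pytest.approx(10 / 13)

    def test_ppv_satisfies_bayes_identity(self):
        df = reviewed_toy()
        est = ipw_estimates(df, np.array([1.5]), 50.0)
        p, se, sp = est.prevalence, est.sensitivity, est.specificity
        assert est.ppv == pytest.approx(
            se * p / (se * p + (1 - sp) * (1 - p)), abs=1e-12)

    def test_perfect_score_all_rates_one(self):
        df = reviewed_toy().copy()
        df["score"] = np.where(df["review_label"] == "none", -1.0, 1.0)
        est = ipw_estimates(df, df["score"].to_numpy(), 50.0)
        assert est.sensitivity == 1.0 and est.specificity == 1.0
        assert est.accuracy == 1.0

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame({
            "patient_id": [f"x{i}" for i in range(n)],
            "stratum": ["srs"] * n,
            "pi": [0.5] * n,
            "score": rng.normal(size=n),
        })
        df["review_label"] = np.where(
            rng.random(n) < 1 / (1 + np.exp(-df["score"])), "possible", "none")
        full = df["score"].to_numpy()
        ests = [ipw_estimates(df, full, c) for c in (10, 30, 50, 70, 90)]
        sens = [e.sensitivity for e in ests]
        spec = [e.specificity for e in ests]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_zero_margin_gives_missing(self):
        df = reviewed_toy()
        df["review_label"] = "none"
        est = ipw_estimates(df, np.array([1.5]), 50.0)
        assert np.isnan(est.sensitivity)  # zero weighted positives
        assert est.prevalence == 0.0 and est.ppv == 0.0
        assert est.specificity == pytest.approx(est.accuracy)


def auc_oracle(scores, pos, w):
    """O(n^2) weighted pairwise-concordance probability."""
    num = den = 0.0
    for i in np.flatnonzero(pos):
        for j in np.flatnonzero(~pos):
            pair = w[i] * w[j]
            den += pair
            if scores[i] > scores[j]:
                num += pair
            elif scores[i] == scores[j]:
                num += 0.5 * pair
    return num / den


class TestWeightedAuc:
    def _df(self, scores, pos, w):
        return pd.DataFrame({
            "score": scores, "pi": 1.0 / np.asarray(w),
            "review_label": np.where(pos, "possible", "none"),
        })

    def test_all_tied_scores_give_half(self):
        df = self._df(np.ones(10), np.arange(10) < 4, np.ones(10))
        assert weighted_auc(df) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        pos = np.arange(10) < 4
        df = self._df(np.where(pos, 2.0, 1.0), pos, np.ones(10))
        assert weighted_auc(df) == pytest.approx(1.0)

    def test_single_class_is_missing(self):
        df = self._df(np.arange(5.0), np.ones(5, bool), np.ones(5))
        assert np.isnan(weighted_auc(df))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
        pos = rng.random(n) < 0.4
        if pos.all() or not pos.any():
            pos[0] = ~pos[0]
        w = rng.uniform(0.5, 5.0, size=n)
        df = self._df(scores, pos, w)
        assert weighted_auc(df) == pytest.approx(auc_oracle(scores, pos, w),
                                                 abs=1e-12)


class TestBootstrap:
    def test_same_seed_identical_interval(self):
        df = reviewed_toy()

        def stat(d):
            w = 1.0 / d["pi"]
            return float((w * d["review_label"].isin(["possible", "probable"])).sum()
                         / w.sum())

        ci1 = bootstrap_ci(stat, df, B=200, seed=5)
        ci2 = bootstrap_ci(stat, df, B=200, seed=5)
        assert ci1 == ci2
        assert ci1[0] <= stat(df) <= ci1[1]

    def test_constant_statistic_zero_width(self):
        df = reviewed_toy()
        ci = bootstrap_ci(lambda d: 0.42, df, B=100, seed=0)
        assert ci == (0.42, 0.42)

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: 0.0, reviewed_toy(), B=50, seed=0)


class TestKappa:
    def test_identical_ratings_give_one(self):
        a = ["none", "possible", "probable", "none", "possible"]
        kappa, se = cohens_kappa(a, a)
        assert kappa == 1.0

    def test_independent_ratings_give_null(self):
        rng = np.random.default_rng(0)
        a = rng.choice(["x", "y", "z"], 10_000)
        b = rng.choice(["x", "y", "z"], 10_000)
        kappa, _ = cohens_kappa(a, b)
        assert abs(kappa) < 0.05

    def test_two_by_two_agreement_table(self):
        # 40 agree/10 disagree per class of 100 -> kappa = 0.6
        a = ["p"] * 50 + ["n"] * 50
        b = ["p"] * 40 + ["n"] * 10 + ["p"] * 10 + ["n"] * 40
        kappa, se = cohens_kappa(a, b)
        assert kappa == pytest.approx(0.6)
        assert se == pytest.approx(np.sqrt(0.8 * 0.2 / (100 * 0.25)))

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        a = rng.choice(["none", "possible", "probable"], 500, p=[0.7, 0.2, 0.1])
        b = np.where(rng.random(500) < 0.7, a,
                     rng.choice(["none", "possible", "probable"], 500))
        kappa, _ = cohens_kappa(a, b)
        assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_constant_equal_raters_convention(self):
        kappa, se = cohens_kappa(["none"] * 5, ["none"] * 5)
        assert kappa == 1.0 and se == 0.0


class TestPrevalenceByStratum:
    def test_uniform_labels_flat_profile(self):
        df = reviewed_toy()
        df["review_label"] = "possible"
        table = prevalence_by_stratum(df)
        present = table.dropna(subset=["prevalence"])
        np.testing.assert_allclose(present["prevalence"], 1.0)

    def test_single_band_equals_overall(self):
        df = reviewed_toy()
        table = prevalence_by_stratum(df, bands=[(0, 100)])
        overall = ipw_estimates(df, np.array([1.5]), 50.0).prevalence
        assert table["prevalence"].iloc[0] == pytest.approx(overall)

    def test_monotone_risk_gives_increasing_profile(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(2)
        n = 2000
        scores = rng.normal(size=n)
        p_pos = 1 / (1 + np.exp(-2.0 * scores))
        df = pd.DataFrame({
            "patient_id": [f"x{i}" for i in range(n)],
            "stratum": ["srs"] * n, "pi": [0.3] * n, "score": scores,
            "percentile": score_percentiles(scores, scores),
            "review_label": np.where(rng.random(n) < p_pos, "possible", "none"),
        })
        bands = [(i, i + 10) for i in range(0, 100, 10)]
        table = prevalence_by_stratum(df, bands=bands)
        rho = spearmanr(np.arange(len(table)), table["prevalence"]).statistic
        assert rho > 0

    def test_empty_band_reported_missing(self):
        df = reviewed_toy()
        table = prevalence_by_stratum(df, bands=[(-10, -5), (0, 100)])
        assert np.isnan(table["prevalence"].iloc[0])
        assert table["n_reviewed"].iloc[0] == 0


class TestSimulatedReview:
    def test_perfect_reviewer_matches_truth(self):
        frame = make_frame(n=1000, seed=9)
        truth = pd.DataFrame({
            "patient_id": frame["patient_id"],
            "latent_truth": np.where(np.arange(1000) % 10 == 0,
                                     "possible_probable", "none"),
        })
        design = SamplingDesign(n_srs=50, n_mid=10, n_per_band=2, seed=1)
        reviewed = draw_review_sample(frame, design)
        reviewed = simulate_chart_review(reviewed, truth, seed=2)
        lut = truth.set_index("patient_id")["latent_truth"]
        for row in reviewed.itertuples():
            if lut.loc[row.patient_id] == "possible_probable":
                assert row.review_label in ("possible", "probable")
            else:
                assert row.review_label == "none"

    def test_blind_reviewer_misses_everything(self):
        frame = make_frame(n=100, seed=9)
        truth = pd.DataFrame({"patient_id": frame["patient_id"],
                              "latent_truth": ["possible_probable"] * 100})
        design = SamplingDesign(n_srs=20, n_mid=0, band_start=100.0, seed=1)
        reviewed = simulate_chart_review(
            draw_review_sample(frame, design), truth,
            reviewer_sensitivity=0.0, seed=3)
        assert (reviewed["review_label"] == "none").all()
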