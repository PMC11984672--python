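"""Reference model, Mahalanobis BioAge, clocks, age acceleration, EML."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from omicage.bioage import (
    age_acceleration,
    apply_linear_clock,
    clr_transform,
    compute_all_bioages,
    epigenetic_mutation_load,
    fit_linear_clock,
    fit_reference,
    mahalanobis_bioage,
    preprocess_layer,
    standardize_bioage,
    ClockSpec,
)


def _matrix(rng, n=20, p=5, prefix="f"):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(p)],
    )


class TestReferenceModel:
    def test_diagonal_mode_is_column_mean_and_sd(self, rng):
        X = _matrix(rng, n=6, p=4)
        model = fit_reference(X, X.index, mode="diagonal")
        pd.testing.assert_series_equal(model.mu, X.mean())
        pd.testing.assert_series_equal(model.sigma, X.std(ddof=1))

    def test_identical_reference_rows_error(self):
        X = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        with pytest.raises(ValueError, match="zero variance"):
            fit_reference(X, X.index)

    def test_zero_variance_features_dropped(self, rng):
        X = _matrix(rng, n=8, p=4)
        X["const"] = 1.0
        model = fit_reference(X, X.index)
        assert model.dropped_features == ["const"]
        assert "const" not in model.features

    def test_too_few_reference_samples(self, rng):
        X = _matrix(rng)
        with pytest.raises(ValueError, match="at least 2"):
            fit_reference(X, X.index[:1])

    def test_shrinkage_lambda_one_equals_diagonal(self, rng):
        X = _matrix(rng, n=10, p=4)
        diag = fit_reference(X, X.index, mode="diagonal")
        shr = fit_reference(X, X.index, mode="shrinkage", shrinkage_lambda=1.0)
        x = X.iloc[3] + rng.normal(size=4)
        assert mahalanobis_bioage(diag, x) == pytest.approx(mahalanobis_bioage(shr, x), abs=1e-10)


class TestMahalanobis:
    def test_distance_zero_at_reference_mean(self, rng):
        X = _matrix(rng)
        model = fit_reference(X, X.index)
        assert mahalanobis_bioage(model, model.mu) == 0.0

    def test_pythagorean_case(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        X = (X - X.mean()) / X.std(ddof=1)  # unit reference variances
        model = fit_reference(X, X.index)
        x = model.mu.copy()
        x["a"] += 3 * model.sigma["a"]
        x["b"] += 4 * model.sigma["b"]
        assert mahalanobis_bioage(model, x) == pytest.approx(5.0, abs=1e-12)

    def test_matches_dense_inverse_oracle(self, rng):
        X = _matrix(rng, n=20, p=5)
        model = fit_reference(X, X.index, mode="shrinkage", shrinkage_lambda=0.3)
        S = np.cov(X.to_numpy(), rowvar=False, ddof=1)
        sigma = 0.7 * S + 0.3 * np.diag(np.diag(S))
        inv = linalg.inv(sigma)
        for _ in range(5):
            x = pd.Series(rng.normal(size=5), index=X.columns)
            d = x.to_numpy() - model.mu.to_numpy()
            expected = np.sqrt(d @ inv @ d)
            assert mahalanobis_bioage(model, x) == pytest.approx(expected, abs=1e-8)

    def test_affine_invariance_full_covariance(self, rng):
        X = _matrix(rng, n=20, p=4)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4)
        XT = pd.DataFrame(X.to_numpy() @ A.T + b, index=X.index, columns=X.columns)
        m1 = fit_reference(X, X.index, mode="shrinkage", shrinkage_lambda=0.0)
        m2 = fit_reference(XT, XT.index, mode="shrinkage", shrinkage_lambda=0.0)
        x = pd.Series(rng.normal(size=4), index=X.columns)
        xt = pd.Series(A @ x.to_numpy() + b, index=X.columns)
        assert mahalanobis_bioage(m1, x) == pytest.approx(mahalanobis_bioage(m2, xt), abs=1e-8)

    def test_missing_feature_policy(self, rng):
        X = _matrix(rng)
        model = fit_reference(X, X.index)
        x = pd.Series({"f0": 1.0})
        with pytest.raises(ValueError, match="missing"):
            mahalanobis_bioage(model, x)
        assert np.isfinite(mahalanobis_bioage(model, x, impute_missing=True))

    def test_chi_square_moment(self):
        """Reference-distributed samples give mean D^2 ~= p (diagonal mode)."""
        rng = np.random.default_rng(3)
        p = 8
        ref = pd.DataFrame(rng.normal(size=(5000, p)))
        model = fit_reference(ref, ref.index)
        draws = pd.DataFrame(rng.normal(size=(10_000, p)))
        D = mahalanobis_bioage(model, draws)
        assert abs((D**2).mean() / p - 1.0) < 0.1


class TestStandardize:
    def test_arithmetic(self):
        assert standardize_bioage(0.0, 9) == 0.0
        assert standardize_bioage(6.0, 4) == 3.0
        with pytest.raises(ValueError):
            standardize_bioage(1.0, 0)

    def test_score_comparable_across_feature_counts(self):
        """E[D^2] = p under the reference distribution, so D/sqrt(p) has
        mean ~1 whether the layer has 10 or 1000 features."""
        rng = np.random.default_rng(8)
        means = []
        for p in (10, 1000):
            ref = pd.DataFrame(rng.normal(size=(2000, p)))
            model = fit_reference(ref, ref.index)
            draws = pd.DataFrame(rng.normal(size=(2000, p)))
            means.append(standardize_bioage(mahalanobis_bioage(model, draws), p).mean())
        assert abs(means[0] - means[1]) / means[1] < 0.10


class TestComputeAllBioages:
    def test_adults_older_than_reference_everywhere(self, subset_cohort):
        _, dataset, _ = subset_cohort
        table, models = compute_all_bioages(dataset)
        assert table.shape == (len(dataset.metadata), 6)
        m = table.groupby(dataset.metadata["group"]).mean()
        assert (m.loc["WD"] > m.loc["yWD"]).all()

    def test_deterministic(self, subset_cohort):
        _, dataset, _ = subset_cohort
        t1, _ = compute_all_bioages(dataset)
        t2, _ = compute_all_bioages(dataset)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_layer_warns_and_skips(self, subset_cohort):
        _, dataset, _ = subset_cohort
        partial = type(dataset)(
            layers={k: v for k, v in dataset.layers.items() if k != "hormones"},
            metadata=dataset.metadata,
        )
        with pytest.warns(UserWarning, match="hormones"):
            table, _ = compute_all_bioages(partial, layers=list(dataset.layers))
        assert table.shape[1] == 5

    def test_recovery_ordering_full_scale(self):
        """Planted intervention effects: WD scores above CR and EX in every
        layer for nearly all seeds at the full cohort size."""
        from omicage import CohortConfig, simulate_cohort

        ok = 0
        n_seeds = 12
        for seed in range(n_seeds):
            dataset, _ = simulate_cohort(CohortConfig(seed=seed))
            table, _ = compute_all_bioages(dataset)
            m = table.groupby(dataset.metadata["group"]).mean()
            ok += int(((m.loc["WD"] > m.loc["CR"]) & (m.loc["WD"] > m.loc["EX"])).all())
        assert ok >= n_seeds - 1


class TestPreprocess:
    def test_clr_rows_sum_to_zero(self, subset_cohort):
        _, dataset, _ = subset_cohort
        clr = clr_transform(dataset.layers["microbiome"])
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)

    def test_unknown_layer_rejected(self, rng):
        with pytest.raises(ValueError, match="no preprocessing"):
            preprocess_layer(_matrix(rng), "proteome")


class TestClocks:
    def test_constant_clock(self, rng):
        X = _matrix(rng)
        clock = ClockSpec("flat", intercept=50.0, coefficients={})
        assert (apply_linear_clock(clock, X) == 50.0).all()

    def test_single_feature_clock(self, rng):
        X = _matrix(rng)
        clock = ClockSpec("one", intercept=2.0, coefficients={"f1": 1.0})
        pd.testing.assert_series_equal(
            apply_linear_clock(clock, X), 2.0 + X["f1"], check_names=False
        )

    def test_missing_feature_policies(self, rng):
        X = _matrix(rng)
        clock = ClockSpec("c", intercept=0.0, coefficients={"f0": 1.0, "nope": 2.0})
        with pytest.raises(ValueError, match="missing"):
            apply_linear_clock(clock, X)
        pred = apply_linear_clock(clock, X, missing="zero")
        pd.testing.assert_series_equal(pred, X["f0"] + 0.0, check_names=False)

    def test_fit_then_apply_recovers_age(self, full_cohort):
        _, dataset, _ = full_cohort
        mvals = preprocess_layer(dataset.layers["dnam"], "dnam")
        age = dataset.metadata["age"]
        train = dataset.metadata.index[::2]
        test = dataset.metadata.index[1::2]
        clock = fit_linear_clock(mvals.loc[train], age.loc[train], n_features=50)
        pred = apply_linear_clock(clock, mvals.loc[test])
        r = np.corrcoef(pred, age.loc[test])[0, 1]
        assert r > 0.8


class TestAgeAcceleration:
    def test_affine_predictions_have_zero_residuals(self, rng):
        age = pd.Series(rng.uniform(30, 80, size=30))
        np.testing.assert_allclose(age_acceleration(age, age), 0.0, atol=1e-10)
        np.testing.assert_allclose(age_acceleration(2 * age + 7, age), 0.0, atol=1e-10)

    def test_residual_properties(self, rng):
        age = pd.Series(rng.uniform(30, 80, size=50))
        pred = age + rng.normal(0, 5, size=50)
        res = age_acceleration(pred, age)
        assert abs(res.mean()) < 1e-9
        assert abs(np.corrcoef(res, age)[0, 1]) < 1e-8

    def test_group_shift_recovered(self, rng):
        age = pd.Series(rng.uniform(30, 80, size=60))
        shift = pd.Series([3.0] * 30 + [0.0] * 30)
        res = age_acceleration(age + shift, age)
        assert res[:30].mean() - res[30:].mean() == pytest.approx(3.0, abs=0.5)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_acceleration(pd.Series([1.0, 2.0, 3.0]), pd.Series([5.0, 5.0, 5.0]))


class TestEML:
    def test_reference_median_sample_has_zero_count(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(20, 50)))
        median_row = beta.median()
        beta.iloc[0] = median_row
        res = epigenetic_mutation_load(beta, reference_ids=beta.index[1:])
        assert res.counts.iloc[0] == 0

    def test_forced_outlier_increments_count_by_one(self, rng):
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(20, 50)))
        ref = beta.index[4:]
        base = epigenetic_mutation_load(beta, reference_ids=ref)
        q1, q3 = beta.loc[ref, 7].quantile([0.25, 0.75])
        bumped = beta.copy()
        bumped.iloc[0, 7] = q3 + 4 * (q3 - q1)
        res = epigenetic_mutation_load(bumped, reference_ids=ref)
        assert res.counts.iloc[0] == base.counts.iloc[0] + 1

    def test_counts_match_bruteforce_recount(self, rng):
        """Planted ~1% outliers: per-sample counts equal an independent
        per-site recount."""
        n, p = 15, 400
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, size=(n, p)))
        mask = rng.random((n, p)) < 0.01
        vals = beta.to_numpy()
        vals[mask] = 0.999
        beta = pd.DataFrame(vals)
        ref = beta.index[5:]
        res = epigenetic_mutation_load(beta, reference_ids=ref, k=3)
        refvals = beta.loc[ref].to_numpy()
        q1 = np.percentile(refvals, 25, axis=0)
        q3 = np.percentile(refvals, 75, axis=0)
        iqr = q3 - q1
        ok = iqr > 0
        brute = (
            ((vals < q1 - 3 * iqr) | (vals > q3 + 3 * iqr)) & ok[None, :]
        ).sum(axis=1)
        np.testing.assert_array_equal(res.counts.to_numpy(), brute)

    def test_eml_aa_zero_mean(self, rng):
        beta = pd.DataFrame(rng.uniform(0.1, 0.9, size=(25, 100)))
        age = pd.Series(rng.uniform(30, 80, size=25))
        res = epigenetic_mutation_load(beta, age=age)
        assert abs(res.eml_aa.mean()) < 1e-9

    def test_reference_too_small(self, rng):
        beta = pd.DataFrame(rng.uniform(size=(6, 10)))
        with pytest.raises(ValueError, match="at least 4"):
            epigenetic_mutation_load(beta, reference_ids=beta.index[:3])
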