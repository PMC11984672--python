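"""Sparse multi-block discriminant analysis: thresholding, fitting,
prediction, CV tuning, signatures and overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicage.multiblock import (
    BlockData,
    CVResult,
    balanced_error_rate,
    default_design,
    default_keepx_grid,
    extract_signature,
    fit_multiblock_splsda,
    predict_multiblock,
    preprocess_block,
    signature_overlap_test,
    soft_threshold_topk,
    tune_keepx_cv,
)


class TestSoftThresholdTopK:
    def test_top1_support_and_sign(self):
        out = soft_threshold_topk(np.array([3.0, -2.0, 1.0]), 1)
        assert out[0] == pytest.approx(1.0)
        assert out[1] == out[2] == 0.0

    def test_k_equals_dim_keeps_support(self):
        v = np.array([3.0, -2.0, 1.0])
        out = soft_threshold_topk(v, 3)
        np.testing.assert_allclose(out, v / np.linalg.norm(v))

    def test_boundary_tie_keeps_lower_index(self):
        out = soft_threshold_topk(np.array([2.0, 2.0, 1.0]), 1)
        assert out[0] != 0.0 and out[1] == 0.0 and out[2] == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            soft_threshold_topk(np.zeros(3), 1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=20),
        st.integers(min_value=1, max_value=25),
    )
    def test_unit_norm_and_support_bound(self, values, k):
        v = np.asarray(values)
        if not np.any(v != 0):
            return
        out = soft_threshold_topk(v, k)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-8)
        assert np.count_nonzero(out) <= min(k, np.count_nonzero(v))


class TestPreprocessBlock:
    def test_columns_standardized(self, rng):
        X = pd.DataFrame(rng.normal(3, 2, size=(20, 6)))
        out = preprocess_block(X)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-10)

    def test_already_standardized_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        X = (X - X.mean()) / X.std(ddof=1)
        pd.testing.assert_frame_equal(preprocess_block(X), X, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        X["c"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = preprocess_block(X)
        assert list(out.columns) == ["a", "b"]

    def test_clr_rows_sum_zero_before_standardization(self, subset_cohort):
        from omicage.bioage import clr_transform

        _, dataset, _ = subset_cohort
        clr = clr_transform(dataset.layers["microbiome"])
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)


def _block_data(blocks, labels, **kw):
    blocks = {k: preprocess_block(v) for k, v in blocks.items()}
    return BlockData(blocks=blocks, labels=labels, **kw)


class TestFit:
    def test_single_informative_feature_selected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            idx = [f"S{i}" for i in range(30)]
            labels = pd.Series(["A"] * 15 + ["B"] * 15, index=idx)
            Z = rng.normal(size=(30, 20))
            Z[:15, 0] += 3.0
            data = _block_data({"x": pd.DataFrame(Z, index=idx)}, labels)
            model = fit_multiblock_splsda(data, {"x": 1})
            hits += int(model.loadings["x"].iloc[0, 0] != 0)
        assert hits >= 48

    def test_dense_limit_matches_svd_oracle(self, rng):
        """keepX = p with outcome-only design: each block's loading is the
        leading left singular vector of X_bT Y (independent oracle)."""
        idx = [f"S{i}" for i in range(24)]
        labels = pd.Series(["A"] * 12 + ["B"] * 12, index=idx)
        blocks = {
            "x1": pd.DataFrame(rng.normal(size=(24, 8)), index=idx),
            "x2": pd.DataFrame(rng.normal(size=(24, 6)), index=idx),
        }
        design = default_design(["x1", "x2"], block_weight=0.0)
        data = _block_data(blocks, labels, design=design)
        model = fit_multiblock_splsda(data, {"x1": 8, "x2": 6})
        from omicage.multiblock import _outcome_matrix

        Y = _outcome_matrix(labels, ["A", "B"])
        for b in ("x1", "x2"):
            M = data.blocks[b].to_numpy().T @ Y
            # power iteration on M M^T — independent of the fit path
            u = np.ones(M.shape[0])
            for _ in range(500):
                u = M @ (M.T @ u)
                u /= np.linalg.norm(u)
            a = model.loadings[b].to_numpy()[:, 0]
            if a @ u < 0:
                u = -u
            np.testing.assert_allclose(a, u, atol=1e-6)

    def test_identical_blocks_agree_up_to_sign(self, rng):
        idx = [f"S{i}" for i in range(20)]
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
        X = pd.DataFrame(rng.normal(size=(20, 10)), index=idx)
        X.iloc[:10, 0] += 2
        data = _block_data({"x1": X, "x2": X.copy()}, labels)
        model = fit_multiblock_splsda(data, {"x1": 4, "x2": 4})
        a1 = model.loadings["x1"].to_numpy()[:, 0]
        a2 = model.loadings["x2"].to_numpy()[:, 0]
        assert min(np.abs(a1 - a2).max(), np.abs(a1 + a2).max()) < 1e-6

    def test_loading_unit_norm_and_support(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels)
        model = fit_multiblock_splsda(data, {"x1": 5, "x2": 7}, n_components=2)
        for b, keep in (("x1", 5), ("x2", 7)):
            L = model.loadings[b].to_numpy()
            for h in range(2):
                assert np.linalg.norm(L[:, h]) == pytest.approx(1.0, abs=1e-8)
                assert np.count_nonzero(L[:, h]) <= keep


class TestPredict:
    def test_training_data_perfectly_separated(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels)
        model = fit_multiblock_splsda(data, {"x1": 5, "x2": 5})
        pred = predict_multiblock(model, data.blocks)
        assert (pred == labels).all()

    def test_single_block_reduces_to_nearest_centroid(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data({"x1": blocks["x1"]}, labels)
        model = fit_multiblock_splsda(data, {"x1": 5})
        pred = predict_multiblock(model, data.blocks)
        T = data.blocks["x1"].to_numpy() @ model.loadings["x1"].to_numpy()
        cents = model.centroids["x1"]
        manual = [
            cents.index[np.argmin([np.linalg.norm(t - cents.loc[c]) for c in cents.index])]
            for t in T
        ]
        assert list(pred) == manual

    def test_majority_vote_overrides_noise_block(self, rng):
        idx = [f"S{i}" for i in range(30)]
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=idx)
        sig = rng.normal(size=(30, 10))
        sig[:15] += 2.5
        blocks = {
            "good1": pd.DataFrame(sig, index=idx),
            "good2": pd.DataFrame(sig + rng.normal(0, 0.3, size=sig.shape), index=idx),
            "noise": pd.DataFrame(rng.normal(size=(30, 10)), index=idx),
        }
        data = _block_data(blocks, labels)
        model = fit_multiblock_splsda(data, {b: 5 for b in blocks})
        pred = predict_multiblock(model, data.blocks)
        assert (pred == labels).mean() == 1.0

    def test_sign_flip_leaves_predictions_unchanged(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels)
        model = fit_multiblock_splsda(data, {"x1": 5, "x2": 5})
        baseline = predict_multiblock(model, data.blocks)
        for b in model.block_names:
            model.loadings[b] *= -1
            model.scores[b] *= -1
            model.centroids[b] *= -1
        flipped = predict_multiblock(model, data.blocks)
        assert (baseline == flipped).all()


class TestBER:
    @pytest.mark.parametrize(
        "true,pred,expected",
        [
            (list("AABB"), list("AABB"), 0.0),
            (list("AABB"), list("AAAA"), 0.5),
            (["A"] * 10 + ["B"] * 10, ["A"] * 8 + ["B"] * 2 + ["B"] * 6 + ["A"] * 4, 0.3),
        ],
    )
    def test_confusion_arithmetic(self, true, pred, expected):
        assert balanced_error_rate(true, pred) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            balanced_error_rate(["A"], ["A", "B"])


class TestTuneCV:
    def test_deterministic_given_seed(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels)
        grid = [{"x1": 2, "x2": 2}, {"x1": 5, "x2": 5}]
        cv1 = tune_keepx_cv(data, grid, folds=5, repeats=3, seed=9)
        cv2 = tune_keepx_cv(data, grid, folds=5, repeats=3, seed=9)
        np.testing.assert_array_equal(cv1.ber_mean, cv2.ber_mean)
        assert cv1.chosen == cv2.chosen

    def test_planted_signal_recovered(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels)
        grid = [{"x1": k, "x2": k} for k in (2, 5, 10, 20)]
        cv = tune_keepx_cv(data, grid, folds=5, repeats=20, seed=0)
        assert cv.ber_mean.min() < 0.1
        assert sum(cv.chosen.values()) <= 2 * 2 * 5  # within 2x planted size

    def test_null_data_ber_near_half(self):
        """Label-permuted CV: mean BER within [0.4, 0.6].  A single noise
        dataset has CV-mean SD ~0.06-0.09, so the check averages several
        fresh datasets with permuted labels."""
        idx = [f"S{i}" for i in range(40)]
        bers = []
        for d in range(6):
            r = np.random.default_rng(500 + d)
            X = pd.DataFrame(r.normal(size=(40, 30)), index=idx)
            labels = pd.Series(r.permutation(["A"] * 20 + ["B"] * 20), index=idx)
            data = _block_data({"x": X}, labels)
            cv = tune_keepx_cv(data, [{"x": 5}], folds=5, repeats=10, seed=d)
            bers.append(cv.ber_mean[0])
        assert 0.4 <= np.mean(bers) <= 0.6

    def test_small_class_reduces_folds(self, rng):
        idx = [f"S{i}" for i in range(12)]
        labels = pd.Series(["A"] * 3 + ["B"] * 9, index=idx)
        data = _block_data({"x": pd.DataFrame(rng.normal(size=(12, 5)), index=idx)}, labels)
        with pytest.warns(UserWarning, match="reducing folds"):
            cv = tune_keepx_cv(data, [{"x": 2}], folds=5, repeats=2, seed=0)
        assert cv.folds == 3

    def test_default_grid_shape(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels)
        grid = default_keepx_grid(data)
        assert all(set(point) == set(data.blocks) for point in grid)
        assert all(point["x1"] <= 30 for point in grid)


class TestSignature:
    def test_sizes_match_nonzero_loading_recount(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels, positive_class="A")
        model = fit_multiblock_splsda(data, {"x1": 5, "x2": 7}, n_components=2)
        sig = extract_signature(model)
        for b in ("x1", "x2"):
            nonzero = (model.loadings[b] != 0).any(axis=1).sum()
            assert sig.size(b) == nonzero

    def test_direction_tags(self, two_group_blocks):
        blocks, labels = two_group_blocks
        data = _block_data(blocks, labels, positive_class="A")
        model = fit_multiblock_splsda(data, {"x1": 5, "x2": 5})
        sig = extract_signature(model)
        for b, feats in sig.features.items():
            for f in feats:
                diff = (
                    data.blocks[b].loc[labels == "A", f].mean()
                    - data.blocks[b].loc[labels == "B", f].mean()
                )
                assert sig.direction[b][f] == ("higher" if diff > 0 else "lower")

    def test_disjoint_components_union(self, rng):
        idx = [f"S{i}" for i in range(30)]
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=idx)
        Z = rng.normal(size=(30, 20))
        Z[:15, 0] += 3
        Z[:15, 1] += 1.5
        data = _block_data({"x": pd.DataFrame(Z, index=idx)}, labels)
        model = fit_multiblock_splsda(data, {"x": 1}, n_components=2)
        sig = extract_signature(model)
        assert sig.size("x") == 2


class TestOverlap:
    def test_zero_overlap_p_one(self):
        out = signature_overlap_test(
            {"l": ["a", "b"]}, {"l": ["c", "d"]}, {"l": 100}
        )
        assert out["per_layer"]["p"].iloc[0] == 1.0

    def test_enumeration_case(self):
        out = signature_overlap_test(
            {"l": list("abcd")}, {"l": list("abcxy")}, {"l": 10}
        )
        assert out["per_layer"]["p"].iloc[0] == pytest.approx(66 / 252, abs=1e-12)

    def test_study_dnam_counts_significant(self):
        """Overlap of 71 CpGs between 1363- and 2883-CpG signatures in a
        346,699-CpG universe is far beyond chance."""
        sig_a = {"dnam": [f"a{i}" for i in range(1363 - 71)] + [f"s{i}" for i in range(71)]}
        sig_b = {"dnam": [f"b{i}" for i in range(2883 - 71)] + [f"s{i}" for i in range(71)]}
        out = signature_overlap_test(sig_a, sig_b, {"dnam": 346_699})
        p = out["per_layer"]["p"].iloc[0]
        assert 0 < p < 1e-4

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            signature_overlap_test({"l": list("ab")}, {"l": list("ab")}, {"l": 1})
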