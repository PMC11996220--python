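"""Variant encoding, imputation, splitting, SMOTE, scaling and targets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathwaynet import (
    KNNImputerMixed,
    drop_sparse_features,
    encode_snps,
    minmax_scale,
    one_hot_labels,
    parse_plink_text,
    preprocess_cohort,
    smote_balance,
    split_stratified,
)
from pathwaynet.cohort import CLASS_ORDER


class TestEncodeSnps:
    def test_additive_sum_per_gene(self):
        calls = pd.DataFrame([[1, 2, 0]], index=["s1"], columns=["v1", "v2", "v3"])
        agg, report = encode_snps(calls, {"v1": "G1", "v2": "G1", "v3": "G1"})
        assert agg.loc["s1", "G1"] == 3
        assert report["dropped_variants"] == []

    def test_all_zero_codes(self):
        calls = pd.DataFrame(np.zeros((3, 4)), columns=[f"v{i}" for i in range(4)])
        agg, _ = encode_snps(calls, {f"v{i}": "G1" for i in range(4)})
        assert (agg.to_numpy() == 0).all()

    def test_missing_contributes_zero_and_unmapped_dropped(self):
        calls = pd.DataFrame([[1, np.nan, 2]], index=["s1"], columns=["v1", "v2", "v3"])
        agg, report = encode_snps(calls, {"v1": "G1", "v2": "G1"})
        assert agg.loc["s1", "G1"] == 1  # nan -> 0; v3 unmapped
        assert report["dropped_variants"] == ["v3"]

    def test_invalid_code_names_sample_and_variant(self):
        calls = pd.DataFrame([[3]], index=["s9"], columns=["vX"])
        with pytest.raises(ValueError, match="s9.*vX"):
            encode_snps(calls, {"vX": "G1"})

    def test_random_calls_match_loop_oracle(self):
        rng = np.random.default_rng(0)
        calls = pd.DataFrame(
            rng.integers(0, 3, size=(20, 50)).astype(float),
            index=[f"s{i}" for i in range(20)],
            columns=[f"v{i}" for i in range(50)],
        )
        vmap = {f"v{i}": f"G{i % 7}" for i in range(50)}
        agg, _ = encode_snps(calls, vmap)
        for s in calls.index:
            for gene in agg.columns:
                expected = sum(
                    calls.loc[s, v] for v in calls.columns if vmap[v] == gene
                )
                assert agg.loc[s, gene] == expected


class TestParsePlinkText:
    def test_three_line_bim(self, tmp_path):
        bim = tmp_path / "x.bim"
        bim.write_text("1 rs1 0 1000 A G\n1 rs2 0 2000 C T\n2 rs3 0 500 G A\n")
        fam = tmp_path / "x.fam"
        fam.write_text("F1 I1 0 0 1 -9\n")
        variants, samples = parse_plink_text(bim, fam)
        assert list(variants["variant_id"]) == ["rs1", "rs2", "rs3"]
        assert list(variants["position"]) == [1000, 2000, 500]
        assert list(samples["individual_id"]) == ["I1"]

    def test_empty_files(self, tmp_path):
        bim = tmp_path / "e.bim"; bim.write_text("")
        fam = tmp_path / "e.fam"; fam.write_text("")
        variants, samples = parse_plink_text(bim, fam)
        assert len(variants) == 0 and len(samples) == 0

    def test_wrong_column_count_names_line(self, tmp_path):
        bim = tmp_path / "b.bim"
        bim.write_text("1 rs1 0 1000 A G\n1 rs2 0 2000 C\n")
        fam = tmp_path / "b.fam"; fam.write_text("")
        with pytest.raises(ValueError, match="line 2"):
            parse_plink_text(bim, fam)

    def test_generated_bim_matches_manifest(self, tmp_path):
        rng = np.random.default_rng(4)
        ids = [f"rs{i}" for i in rng.permutation(1000)]
        lines = [f"{rng.integers(1, 23)} {v} 0 {rng.integers(1, 10**6)} A G" for v in ids]
        bim = tmp_path / "big.bim"
        bim.write_text("\n".join(lines) + "\n")
        fam = tmp_path / "big.fam"; fam.write_text("")
        variants, _ = parse_plink_text(bim, fam)
        assert len(variants) == 1000
        assert set(variants["variant_id"]) == set(ids)


class TestClinicalPreprocessing:
    def test_sparse_feature_dropped_at_threshold(self):
        df = pd.DataFrame({
            "mostly_missing": [np.nan] * 7 + [1.0] * 3,
            "complete": range(10),
        }, index=[f"s{i}" for i in range(10)])
        kept, dropped = drop_sparse_features(df, df.index, max_missing=0.60)
        assert dropped == ["mostly_missing"]
        assert list(kept.columns) == ["complete"]

    def test_missingness_computed_on_training_rows_only(self):
        df = pd.DataFrame({
            "f": [np.nan, np.nan, np.nan, 1.0, 1.0, 1.0],
        }, index=[f"s{i}" for i in range(6)])
        # 100% missing on the training subset, 50% overall
        _, dropped = drop_sparse_features(df.assign(g=1.0), ["s0", "s1", "s2"])
        assert dropped == ["f"]

    def test_random_pattern_matches_fraction_oracle(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(40, 12)),
                          columns=[f"f{i}" for i in range(12)])
        mask = rng.uniform(size=df.shape) < rng.uniform(0.2, 0.9, size=12)
        df = df.mask(mask)
        kept, dropped = drop_sparse_features(df, df.index, max_missing=0.60)
        for c in df.columns:
            frac = df[c].isna().mean()
            assert (c in dropped) == (frac >= 0.60)

    def test_impute_identity_when_complete(self):
        df = pd.DataFrame(np.arange(24, dtype=float).reshape(6, 4))
        df.columns = [f"f{i}" for i in range(4)]
        imp = KNNImputerMixed(n_neighbors=3).fit(df)
        pd.testing.assert_frame_equal(imp.transform(df), df)

    def test_impute_equidistant_neighbors_mean(self):
        # target row shares feature "a" with all 5 donors, so all are
        # equidistant; the donated values (1,1,1,3,4) average to 2
        df = pd.DataFrame({
            "a": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            "b": [np.nan, 1.0, 1.0, 1.0, 3.0, 4.0],
        }, index=[f"s{i}" for i in range(6)])
        imp = KNNImputerMixed(n_neighbors=5).fit(df)
        out = imp.transform(df)
        assert out.loc["s0", "b"] == pytest.approx(2.0)

    def test_impute_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(50, 8))
        miss = rng.uniform(size=data.shape) < 0.10
        df = pd.DataFrame(np.where(miss, np.nan, data),
                          columns=[f"f{i}" for i in range(8)],
                          index=[f"s{i}" for i in range(50)])
        df = df.dropna(how="all")
        k = 5
        imp = KNNImputerMixed(n_neighbors=k, weights="distance").fit(df)
        out = imp.transform(df)
        # brute-force oracle: explicit partial-distance computation
        vals = df.to_numpy()
        center = np.nanmean(vals, axis=0)
        scale = np.nanstd(vals, axis=0)
        scale[scale == 0] = 1.0
        Z = (vals - center) / scale
        n, p = Z.shape
        for i in range(n):
            for j in range(p):
                if not np.isnan(vals[i, j]):
                    assert out.iloc[i, j] == vals[i, j]
                    continue
                dists = np.full(n, np.inf)
                for t in range(n):
                    if t == i or np.isnan(vals[t, j]):
                        continue
                    both = ~np.isnan(Z[i]) & ~np.isnan(Z[t])
                    if not both.any():
                        continue
                    sq = ((Z[i, both] - Z[t, both]) ** 2).sum()
                    dists[t] = np.sqrt(sq * p / both.sum())
                order = np.argsort(dists, kind="stable")[:k]
                w = 1.0 / (dists[order] + 1e-12)
                expected = np.average(vals[order, j], weights=w)
                assert out.iloc[i, j] == pytest.approx(expected, rel=1e-9)

    def test_impute_all_missing_row_is_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        imp = KNNImputerMixed(n_neighbors=2).fit(df)
        bad = pd.DataFrame({"a": [np.nan], "b": [np.nan]}, index=["sX"])
        with pytest.raises(ValueError, match="sX"):
            imp.transform(bad)

    def test_categorical_imputes_mode(self):
        df = pd.DataFrame({
            "a": [0.0] * 6,
            "cat": [np.nan, 1.0, 1.0, 1.0, 2.0, 0.0],
        })
        imp = KNNImputerMixed(n_neighbors=5, feature_types={"cat": "categorical"}).fit(df)
        assert imp.transform(df).loc[0, "cat"] == 1.0


class TestSplitStratified:
    def test_divisible_cohort_splits_exactly(self):
        labels = pd.Series(np.repeat(CLASS_ORDER, 100))
        split = split_stratified(labels, seed=0)
        counts = split.value_counts()
        assert counts["train"] == 168 and counts["validation"] == 42 and counts["test"] == 90
        for cls in CLASS_ORDER:
            sub = split[labels.values == cls].value_counts()
            assert sub["train"] == 56 and sub["validation"] == 14 and sub["test"] == 30

    def test_reference_cohort_sizes(self):
        labels = pd.Series(np.repeat(CLASS_ORDER, (212, 317, 97)))
        split = split_stratified(labels, seed=3)
        counts = split.value_counts()
        assert abs(counts["train"] - 350) <= 1
        assert abs(counts["validation"] - 88) <= 1
        assert abs(counts["test"] - 188) <= 1

    def test_deterministic_under_seed(self):
        labels = pd.Series(np.repeat(CLASS_ORDER, (40, 30, 20)))
        a = split_stratified(labels, seed=5)
        b = split_stratified(labels, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_small_class_rejected(self):
        labels = pd.Series(["CN"] * 10 + ["MCI"] * 10 + ["AD"] * 2)
        with pytest.raises(ValueError, match="AD"):
            split_stratified(labels)


class TestSmote:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1, 2], 10)
        Xr, yr = smote_balance(X, y, seed=0)
        assert Xr.shape == X.shape
        np.testing.assert_array_equal(Xr, X)

    def test_output_counts_equal_majority(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = np.repeat([0, 1, 2], (30, 20, 10))
        Xr, yr = smote_balance(X, y, seed=1)
        assert [int((yr == c).sum()) for c in (0, 1, 2)] == [30, 30, 30]

    def test_synthetic_rows_are_convex_combinations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = np.repeat([0, 1], (20, 10))
        Xr, yr = smote_balance(X, y, k_neighbors=5, seed=2)
        synth = Xr[len(X):]
        klass = yr[len(X):]
        originals = {c: X[y == c] for c in (0, 1)}
        for row, c in zip(synth, klass):
            rows = originals[c]
            on_segment = False
            for i in range(len(rows)):
                for j in range(len(rows)):
                    if i == j:
                        continue
                    d = rows[j] - rows[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((row - rows[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(rows[i] + u * d, row, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_tiny_class_shrinks_k_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(13, 2))
        y = np.array([0] * 10 + [1] * 3)
        with pytest.warns(UserWarning, match="reduced"):
            Xr, yr = smote_balance(X, y, k_neighbors=5, seed=3)
        assert (yr == 1).sum() == 10


class TestScalingAndTargets:
    def test_minmax_basic(self):
        Xt, (Xo,), _ = minmax_scale(np.array([[2.0], [4.0], [6.0]]), [np.array([[8.0]])])
        np.testing.assert_allclose(Xt.ravel(), [0.0, 0.5, 1.0])
        assert Xo[0, 0] == pytest.approx(1.5)  # unclipped extrapolation

    def test_constant_feature_maps_to_zero(self):
        Xt, _, _ = minmax_scale(np.full((4, 1), 7.0), [])
        assert (Xt == 0).all()

    def test_one_hot_order_and_round_trip(self):
        Y = one_hot_labels(["AD", "CN", "MCI", "CN"])
        np.testing.assert_array_equal(Y[0], [0, 0, 1])
        np.testing.assert_array_equal(Y[1], [1, 0, 0])
        decoded = np.array(CLASS_ORDER)[Y.argmax(axis=1)]
        np.testing.assert_array_equal(decoded, ["AD", "CN", "MCI", "CN"])

    def test_one_hot_unknown_label(self):
        with pytest.raises(ValueError, match="unknown"):
            one_hot_labels(["CN", "???"])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(CLASS_ORDER), min_size=1, max_size=40))
    def test_one_hot_rows_sum_to_one_and_round_trip(self, labels):
        Y = one_hot_labels(labels)
        assert (Y.sum(axis=1) == 1).all()
        decoded = np.array(CLASS_ORDER)[Y.argmax(axis=1)]
        np.testing.assert_array_equal(decoded, labels)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_minmax_train_block_always_in_unit_interval(self, seed, width):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, width)) * rng.uniform(0.1, 100, size=width)
        Xt, _, _ = minmax_scale(X, [])
        assert Xt.min() >= -1e-12 and Xt.max() <= 1 + 1e-12


class TestPipeline:
    def test_full_chain_no_leak_and_alignment(self, small_cohort):
        processed = preprocess_cohort(small_cohort, seed=4)
        # training block scaled into [0,1]
        assert processed.X_train.min() >= -1e-12
        assert processed.X_train.max() <= 1 + 1e-12
        # no-leak: refitting the scaler on the training block reproduces it
        lo = processed.X_train.min(axis=0)
        hi = processed.X_train.max(axis=0)
        varying = hi > lo
        np.testing.assert_allclose(lo[varying], 0.0, atol=1e-12)
        np.testing.assert_allclose(hi[varying], 1.0, atol=1e-12)
        # all classes in every split
        for y in (processed.y_train, processed.y_val, processed.y_test):
            assert set(np.unique(y)) == {0, 1, 2}
        # SMOTE balanced the training labels
        counts = np.bincount(processed.y_train)
        assert counts.min() == counts.max()
        # feature axis consistent
        assert processed.X_val.shape[1] == processed.X_train.shape[1] == processed.n_features
        assert len(processed.modality) == processed.n_features

    def test_pipeline_deterministic(self, small_cohort):
        a = preprocess_cohort(small_cohort, seed=9)
        b = preprocess_cohort(small_cohort, seed=9)
        np.testing.assert_array_equal(a.X_train, b.X_train)
        np.testing.assert_array_equal(a.y_test, b.y_test)
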