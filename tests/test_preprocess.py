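"""Loading, binarization, imputation, encoding, scaling and splitting."""

import numpy as np
import pandas as pd
import pytest

from gradvote import (
    FeatureTable,
    binarize_target,
    encode_and_impute,
    impute_invalid_zeros,
    load_table,
    normalize,
    save_table,
    stratified_split,
)


def _write_csv(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadTable:
    def test_two_class_string_target_maps_to_codes(self, tmp_path):
        path = _write_csv(
            tmp_path, "t.csv",
            "a,b,diagnosis\n1,2,M\n3,4,B\n5,6,M\n7,8,B\n",
        )
        table = load_table(path, "diagnosis", positive_label="M")
        assert table.n_instances == 4
        assert table.y.tolist() == [1, 0, 1, 0]
        assert set(np.unique(table.y)) == {0, 1}

    def test_missing_target_column_raises(self, tmp_path):
        path = _write_csv(tmp_path, "t.csv", "a,b\n1,2\n")
        with pytest.raises(KeyError, match="outcome"):
            load_table(path, "outcome", positive_label=1)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_table(tmp_path / "absent.csv", "y")

    def test_multiclass_without_map_raises(self, tmp_path):
        path = _write_csv(tmp_path, "t.csv", "a,level\n1,low\n2,mid\n3,high\n")
        with pytest.raises(ValueError, match="positive_classes"):
            load_table(path, "level", positive_label="high")

    def test_roundtrip_through_save(self, tmp_path):
        table = FeatureTable(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]))
        save_table(table, tmp_path / "out.csv")
        back = load_table(tmp_path / "out.csv", "target")
        assert back.y.tolist() == [0, 1]
        assert back.X["a"].tolist() == [1.0, 2.0]


class TestBinarizeTarget:
    @pytest.mark.parametrize(
        "positives, expected",
        [
            ({"ObeseI", "ObeseII"}, [0, 0, 1, 1]),
            ({"Normal", "Overweight", "ObeseI", "ObeseII"}, [1, 1, 1, 1]),
            (set(), [0, 0, 0, 0]),
        ],
    )
    def test_positive_set_defines_class_one(self, positives, expected):
        labels = np.array(["Normal", "Overweight", "ObeseI", "ObeseII"])
        table = FeatureTable(pd.DataFrame({"a": [1, 2, 3, 4]}), labels)
        out = binarize_target(table, positives)
        assert out.y.tolist() == expected


class TestImputeInvalidZeros:
    def test_median_of_nonzero_values(self):
        table = FeatureTable(
            pd.DataFrame({"x": [0.0, 2.0, 4.0, 6.0], "other": [0.0, 0.0, 1.0, 1.0]}),
            np.array([0, 1, 0, 1]),
        )
        out = impute_invalid_zeros(table, ["x"], "median")
        assert out.X["x"].tolist() == [4.0, 2.0, 4.0, 6.0]
        # untargeted column untouched, including its zeros
        assert out.X["other"].tolist() == table.X["other"].tolist()

    def test_min_strategy(self):
        table = FeatureTable(pd.DataFrame({"x": [0.0, 5.0, 9.0]}), np.array([0, 1, 1]))
        out = impute_invalid_zeros(table, ["x"], "min")
        assert out.X["x"].tolist() == [5.0, 5.0, 9.0]

    def test_column_without_zeros_unchanged(self):
        table = FeatureTable(pd.DataFrame({"x": [1.0, 2.0]}), np.array([0, 1]))
        out = impute_invalid_zeros(table, ["x"], "median")
        assert out.X["x"].tolist() == [1.0, 2.0]

    def test_all_zero_column_warns_and_is_left_alone(self):
        table = FeatureTable(pd.DataFrame({"x": [0.0, 0.0]}), np.array([0, 1]))
        with pytest.warns(UserWarning, match="entirely zero"):
            out = impute_invalid_zeros(table, ["x"], "median")
        assert out.X["x"].tolist() == [0.0, 0.0]

    def test_non_numeric_column_rejected(self):
        table = FeatureTable(pd.DataFrame({"x": ["a", "b"]}), np.array([0, 1]))
        with pytest.raises(TypeError):
            impute_invalid_zeros(table, ["x"], "median")


class TestEncodeAndImpute:
    def test_one_hot_uses_training_vocabulary(self):
        train = FeatureTable(
            pd.DataFrame({"c": ["yes", "no", "yes"]}), np.array([1, 0, 1])
        )
        out = encode_and_impute(train, fit_on=train)
        assert sorted(out.X.columns) == ["c=no", "c=yes"]
        assert out.X.sum(axis=1).tolist() == [1.0, 1.0, 1.0]  # exactly one hot

    def test_unseen_category_is_all_zero(self):
        train = FeatureTable(pd.DataFrame({"c": ["yes", "no"]}), np.array([1, 0]))
        test = FeatureTable(pd.DataFrame({"c": ["maybe"]}), np.array([0]))
        out = encode_and_impute(test, fit_on=train)
        assert out.X.iloc[0].tolist() == [0.0, 0.0]

    def test_numeric_missing_filled_with_training_median(self):
        train = FeatureTable(pd.DataFrame({"x": [1.0, 3.0, 4.0, 6.0]}), np.zeros(4))
        test = FeatureTable(pd.DataFrame({"x": [np.nan]}), np.array([0]))
        out = encode_and_impute(test, fit_on=train)
        assert out.X["x"].iloc[0] == 3.5

    def test_categorical_missing_filled_with_training_mode(self):
        train = FeatureTable(
            pd.DataFrame({"c": ["a", "a", "b"]}), np.array([0, 1, 0])
        )
        test = FeatureTable(pd.DataFrame({"c": [None]}), np.array([1]))
        out = encode_and_impute(test, fit_on=train)
        assert out.X["c=a"].iloc[0] == 1.0

    def test_no_missing_values_after_transform(self, balanced_table):
        out = encode_and_impute(balanced_table, fit_on=balanced_table)
        assert np.isfinite(out.X.to_numpy(dtype=float)).all()


class TestNormalize:
    def test_min_max_closed_form(self):
        fit = FeatureTable(pd.DataFrame({"x": [0.0, 10.0]}), np.array([0, 1]))
        table = FeatureTable(pd.DataFrame({"x": [5.0]}), np.array([1]))
        assert normalize(table, fit).X["x"].iloc[0] == 0.5

    def test_constant_column_maps_to_zero(self):
        fit = FeatureTable(pd.DataFrame({"x": [3.0, 3.0]}), np.array([0, 1]))
        out = normalize(fit, fit)
        assert out.X["x"].tolist() == [0.0, 0.0]

    def test_out_of_range_values_clip(self):
        fit = FeatureTable(pd.DataFrame({"x": [0.0, 10.0]}), np.array([0, 1]))
        table = FeatureTable(pd.DataFrame({"x": [12.0, -3.0]}), np.array([1, 0]))
        assert normalize(table, fit).X["x"].tolist() == [1.0, 0.0]

    def test_idempotent_with_same_fit_table(self, balanced_table):
        from gradvote import encode_and_impute

        enc = encode_and_impute(balanced_table, fit_on=balanced_table)
        once = normalize(enc, enc)
        fit_scaled = normalize(enc, enc)
        twice = normalize(once, fit_scaled)
        pd.testing.assert_frame_equal(once.X, twice.X)


class TestStratifiedSplit:
    def test_exact_stratified_counts(self):
        y = np.array([0, 1] * 50)
        table = FeatureTable(pd.DataFrame({"x": np.arange(100.0)}), y)
        split = stratified_split(table, (0.6, 0.2, 0.2), seed=0)
        sizes = {k: v.n_instances for k, v in split.parts().items()}
        assert sizes == {"train": 60, "val": 20, "test": 20}
        assert [int(p.y.sum()) for p in split.parts().values()] == [30, 10, 10]

    def test_partition_is_disjoint_and_exhaustive(self, balanced_table):
        split = stratified_split(balanced_table, (0.6, 0.2, 0.2), seed=3)
        all_idx = np.concatenate([split.indices[k] for k in ("train", "val", "test")])
        assert sorted(all_idx.tolist()) == list(range(balanced_table.n_instances))

    def test_stratification_within_two_points(self, balanced_table):
        split = stratified_split(balanced_table, (0.6, 0.2, 0.2), seed=3)
        whole = balanced_table.positive_fraction
        for part in split.parts().values():
            assert abs(part.positive_fraction - whole) <= 0.02

    def test_same_seed_reproduces_partition(self, balanced_table):
        a = stratified_split(balanced_table, (0.6, 0.2, 0.2), seed=11)
        b = stratified_split(balanced_table, (0.6, 0.2, 0.2), seed=11)
        for k in ("train", "val", "test"):
            assert a.indices[k].tolist() == b.indices[k].tolist()
            pd.testing.assert_frame_equal(a.parts()[k].X, b.parts()[k].X)

    def test_minority_too_small_raises(self):
        table = FeatureTable(
            pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), np.array([1, 0, 0, 0])
        )
        with pytest.raises(ValueError):
            stratified_split(table, (0.6, 0.2, 0.2), seed=0)

    @pytest.mark.parametrize("fractions", [(0.5, 0.5, 0.0), (0.6, 0.2, 0.1)])
    def test_bad_fractions_rejected(self, balanced_table, fractions):
        with pytest.raises(ValueError):
            stratified_split(balanced_table, fractions, seed=0)
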