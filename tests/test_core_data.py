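"""Dataset container, CSV round trips, splitting, discretization, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesboost.core_data import (
    CATEGORICAL,
    NUMERIC,
    Schema,
    SchemaError,
    TabularDataset,
    Variable,
    discretize,
    distribution_distance,
    read_csv,
    stratified_split,
    total_variation,
    undiscretize,
    write_csv,
)


def test_csv_round_trip_preserves_dataset(tiny_dataset, tmp_path):
    path = tmp_path / "d.csv"
    write_csv(tiny_dataset, path)
    back = read_csv(path, tiny_dataset.schema)
    assert back.n_rows == tiny_dataset.n_rows
    pd.testing.assert_series_equal(back.frame["gender"], tiny_dataset.frame["gender"])
    np.testing.assert_allclose(back.frame["age"], tiny_dataset.frame["age"])
    assert (back.labels() == tiny_dataset.labels()).all()


def test_csv_write_line_count_and_provenance_flag(tiny_dataset, tmp_path):
    one = tiny_dataset.subset([0])
    path = tmp_path / "one.csv"
    write_csv(one, path)
    assert len(path.read_text().strip().splitlines()) == 2
    tagged = TabularDataset(
        tiny_dataset.schema,
        tiny_dataset.frame,
        provenance=np.full(tiny_dataset.n_rows, "original", dtype=object),
    )
    write_csv(tagged, path)
    assert "provenance" not in path.read_text().splitlines()[0]
    write_csv(tagged, path, include_provenance=True)
    assert "provenance" in path.read_text().splitlines()[0]


def test_undeclared_level_raises_naming_column_and_value(tiny_schema, tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("gender,age,stroke\nX,44.0,0\n")
    with pytest.raises(SchemaError, match="gender.*X"):
        read_csv(path, tiny_schema)


def test_missing_target_raises(tiny_schema, tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("gender,age,stroke\nF,44.0,\n")
    with pytest.raises(SchemaError, match="target"):
        read_csv(path, tiny_schema)


def test_stratified_split_per_level_counts(tiny_schema):
    # 1000 rows with level shares (0.5, 0.3, 0.2); fraction 0.3 -> (150, 90, 60)
    schema = Schema(
        variables=(
            Variable("grp", CATEGORICAL, ("a", "b", "c")),
            Variable("stroke", CATEGORICAL, ("0", "1")),
        ),
        target_name="stroke",
        protected_name="grp",
    )
    frame = pd.DataFrame(
        {"grp": ["a"] * 500 + ["b"] * 300 + ["c"] * 200, "stroke": ["0", "1"] * 500}
    )
    ds = TabularDataset(schema, frame)
    part_a, part_b = stratified_split(ds, "grp", 0.3, seed=7)
    counts = part_a.frame["grp"].value_counts()
    assert (counts["a"], counts["b"], counts["c"]) == (150, 90, 60)
    assert part_a.n_rows + part_b.n_rows == 1000


def test_stratified_split_70_30_on_target(tiny_dataset):
    train, test = stratified_split(tiny_dataset, "stroke", 0.7, seed=1)
    assert train.n_rows == pytest.approx(0.7 * tiny_dataset.n_rows, abs=1)
    # deterministic under the seed
    train2, _ = stratified_split(tiny_dataset, "stroke", 0.7, seed=1)
    pd.testing.assert_frame_equal(train.frame, train2.frame)


def test_discretize_quartile_boundaries():
    rng = np.random.default_rng(0)
    ages = rng.uniform(20, 80, size=4000)
    schema = Schema(
        variables=(
            Variable("age", NUMERIC),
            Variable("g", CATEGORICAL, ("x", "y")),
            Variable("t", CATEGORICAL, ("0", "1")),
        ),
        target_name="t",
        protected_name="g",
    )
    frame = pd.DataFrame({"age": ages, "g": ["x", "y"] * 2000, "t": ["0", "1"] * 2000})
    ds = TabularDataset(schema, frame)
    disc, bmap = discretize(ds, n_bins=4)
    np.testing.assert_allclose(
        bmap.cutpoints("age"), np.quantile(ages, [0.25, 0.5, 0.75])
    )
    # categorical columns pass through unchanged
    pd.testing.assert_series_equal(disc.frame["g"], ds.frame["g"])


def test_discretize_round_trip_bin_membership(tiny_dataset):
    disc, bmap = discretize(tiny_dataset, n_bins=5)
    back = undiscretize(disc, bmap, seed=3, numeric_schema=tiny_dataset.schema)
    orig_bins = bmap.assign("age", tiny_dataset.frame["age"].to_numpy())
    new_bins = bmap.assign("age", back.frame["age"].to_numpy())
    assert (orig_bins == disc.frame["age"].to_numpy()).all()
    assert (new_bins == disc.frame["age"].to_numpy()).all()


def test_undiscretize_uniform_within_bin(tiny_schema):
    # one wide bin: inverted values are uniform, so the mean sits mid-bin
    rng = np.random.default_rng(1)
    n = 10_000
    frame = pd.DataFrame(
        {"gender": ["F"] * n, "age": rng.uniform(40, 50, n), "stroke": ["0", "1"] * (n // 2)}
    )
    ds = TabularDataset(tiny_schema, frame)
    disc, bmap = discretize(ds, n_bins=2)
    back = undiscretize(disc, bmap, seed=9, numeric_schema=tiny_schema)
    lo, hi = bmap.interval("age", disc.frame["age"].iloc[0])
    first_bin = back.frame["age"][disc.frame["age"] == disc.frame["age"].iloc[0]]
    assert first_bin.between(lo, hi).all()
    assert abs(first_bin.mean() - (lo + hi) / 2) < 0.1
    back2 = undiscretize(disc, bmap, seed=9, numeric_schema=tiny_schema)
    np.testing.assert_array_equal(back.frame["age"], back2.frame["age"])


def test_constant_numeric_column_single_bin(tiny_schema):
    frame = pd.DataFrame({"gender": ["F", "M"], "age": [50.0, 50.0], "stroke": ["0", "1"]})
    ds = TabularDataset(tiny_schema, frame)
    with pytest.warns(UserWarning, match="constant"):
        disc, bmap = discretize(ds)
    assert len(bmap.bins["age"]) == 1


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (["x"] * 5 + ["y"] * 5, ["x"] * 5 + ["y"] * 5, 0.0),
        (["x"] * 5 + ["y"] * 5, ["x"] * 9 + ["y"] * 1, 0.4),
        (["x"] * 4, ["y"] * 6, 1.0),
    ],
)
def test_total_variation_examples(a, b, expected):
    assert total_variation(a, b) == pytest.approx(expected)


def test_ks_distance_for_numeric_columns():
    a = pd.Series(np.linspace(0, 1, 200))
    assert distribution_distance(a, a, NUMERIC) == pytest.approx(0.0, abs=1e-12)
    b = pd.Series(np.linspace(10, 11, 200))
    assert distribution_distance(a, b, NUMERIC) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        distribution_distance(a.iloc[:0], b, NUMERIC)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.sampled_from("abc"), min_size=1, max_size=30),
    st.lists(st.sampled_from("abc"), min_size=1, max_size=30),
    st.lists(st.sampled_from("abc"), min_size=1, max_size=30),
)
def test_total_variation_metric_properties(a, b, c):
    dab = total_variation(a, b)
    assert 0.0 <= dab <= 1.0
    assert dab == pytest.approx(total_variation(b, a))
    assert dab <= total_variation(a, c) + total_variation(c, b) + 1e-12
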