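"""Score model: rank statistics, grouping, weighting algebra, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redoxpair import (
    compare_groups,
    descriptor_comparison_table,
    fit_score_model,
    group_descriptors,
    score_dataset,
    spearman_r,
)
from redoxpair.config import RunConfig
from helpers import mwu_oracle, spearman_oracle, welch_oracle


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_r(x, x) == pytest.approx(1.0)
        assert spearman_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_binary_labels_match_rank_pearson_oracle(self):
        y = [0, 0, 1, 1]
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_r(x, y) == pytest.approx(spearman_oracle(x, y))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        y = rng.integers(0, 2, size=30).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert spearman_r(x, y) == pytest.approx(spearman_oracle(x, y))

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGrouping:
    def test_duplicated_column_shares_group(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        df = pd.DataFrame({"a": a, "a_copy": a, "b": rng.normal(size=40)})
        groups, _ = group_descriptors(df, threshold=0.8)
        by_member = {m: tuple(g) for g in groups for m in g}
        assert by_member["a"] == by_member["a_copy"]
        assert by_member["b"] != by_member["a"]

    def test_uncorrelated_descriptors_stay_singletons(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        groups, _ = group_descriptors(df, threshold=0.8)
        assert sorted(map(len, groups)) == [1, 1, 1, 1]

    def test_chained_correlation_forms_one_component(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=200)
        a = z + 0.55 * rng.normal(size=200)
        b = z
        c = z + 0.55 * rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        from scipy.stats import spearmanr

        r_ab = abs(spearmanr(a, b).statistic)
        r_bc = abs(spearmanr(b, c).statistic)
        r_ac = abs(spearmanr(a, c).statistic)
        assert r_ab >= 0.8 and r_bc >= 0.8 and r_ac < 0.8  # chain, not clique
        groups, _ = group_descriptors(df, threshold=0.8)
        assert groups == [["a", "b", "c"]]

    def test_constant_column_is_flagged_singleton(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=30), "k": np.ones(30)})
        groups, constants = group_descriptors(df, threshold=0.8)
        assert ["k"] in groups and constants == ["k"]


def _training_frame(n=24, seed=0, informative="d1"):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    df = pd.DataFrame(
        {
            "d1": rng.normal(size=n),
            "d2": rng.normal(size=n),
            "d3": rng.normal(size=n),
        }
    )
    # informative descriptor perfectly ordered with the class
    df[informative] = np.concatenate(
        [np.linspace(5, 6, n // 2), np.linspace(1, 2, n // 2)]
    )
    df["label"] = y
    return df


class TestFitAndScore:
    def test_informative_descriptor_separates_classes(self):
        df = _training_frame(seed=4)
        model = fit_score_model(df)
        scored = score_dataset(model, df.drop(columns="label"))
        pos = scored.loc[df["label"] == 1, "redox_score"]
        neg = scored.loc[df["label"] == 0, "redox_score"]
        assert pos.min() > neg.max()

    def test_single_class_raises(self):
        df = _training_frame()
        df["label"] = 1
        with pytest.raises(ValueError, match="positive and negative"):
            fit_score_model(df)

    def test_too_few_examples_raises(self):
        df = _training_frame().head(2)
        with pytest.raises(ValueError):
            fit_score_model(df)

    def test_identical_examples_raise_degenerate_error(self):
        df = pd.DataFrame(
            {"d1": [2.0] * 6, "d2": [3.0] * 6, "label": [1, 1, 1, 0, 0, 0]}
        )
        with pytest.raises(ValueError, match="S_max == S_min|degenerate"):
            fit_score_model(df)

    def test_missing_values_imputed_with_training_median(self):
        df = _training_frame(seed=5)
        df.loc[3, "d2"] = np.nan
        model = fit_score_model(df)
        assert model.impute_values["d2"] == pytest.approx(
            df["d2"].dropna().median()
        )
        scored = score_dataset(model, df.drop(columns="label"))
        assert np.isfinite(scored["raw_score"]).all()

    def test_score_endpoints_and_midpoint(self):
        train = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "label": [0, 0, 1, 1]})
        model = fit_score_model(train)
        scored = score_dataset(model, pd.DataFrame({"x": [0.0, 1.5, 3.0]}))
        assert list(scored["redox_score"]) == pytest.approx([0.0, 50.0, 100.0])

    def test_scored_set_spans_zero_to_hundred(self, strong_training_set):
        df = strong_training_set["training"]
        feats = ["sg_distance", "pct_buried", "hse_total", "min_pka", "avg_b"]
        model = fit_score_model(df[feats + ["label"]])
        scored = score_dataset(model, df[feats])
        assert scored["redox_score"].min() == pytest.approx(0.0)
        assert scored["redox_score"].max() == pytest.approx(100.0)

    def test_frozen_model_clamps_out_of_range(self):
        train = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "label": [0, 0, 1, 1]})
        model = fit_score_model(train)
        score_dataset(model, pd.DataFrame({"x": [0.0, 3.0]}))  # freezes bounds
        scored = score_dataset(model, pd.DataFrame({"x": [10.0, -5.0]}), freeze=True)
        assert list(scored["redox_score"]) == [100.0, 0.0]

    def test_unknown_descriptor_is_schema_error(self):
        train = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "label": [0, 0, 1, 1]})
        model = fit_score_model(train)
        with pytest.raises(ValueError, match="descriptor"):
            score_dataset(model, pd.DataFrame({"y": [1.0, 2.0]}))

    def test_model_json_round_trip(self, strong_training_set, tmp_path):
        df = strong_training_set["training"]
        feats = ["sg_distance", "pct_buried", "hse_total", "min_pka", "avg_b"]
        model = fit_score_model(df[feats + ["label"]])
        path = tmp_path / "model.json"
        model.save(path)
        from redoxpair import ScoreModel

        back = ScoreModel.load(path)
        assert back.to_json() == model.to_json()
        s1 = score_dataset(model, df[feats])
        s2 = score_dataset(back, df[feats])
        assert np.allclose(s1["redox_score"], s2["redox_score"])


@st.composite
def training_tables(draw):
    n = draw(st.integers(min_value=8, max_value=24))
    n_desc = draw(st.integers(min_value=2, max_value=4))
    rng = np.random.default_rng(draw(st.integers(0, 10_000)))
    data = rng.normal(size=(n, n_desc)).round(3)
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    df = pd.DataFrame(data, columns=[f"d{i}" for i in range(n_desc)])
    df["label"] = labels
    return df


class TestScoreAlgebra:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(table=training_tables(), dup_index=st.integers(0, 3))
    def test_duplicating_any_descriptor_leaves_scores_unchanged(
        self, table, dup_index
    ):
        feats = [c for c in table.columns if c != "label"]
        name = feats[dup_index % len(feats)]
        try:
            base_model = fit_score_model(table)
        except ValueError:
            return  # degenerate random table
        base = score_dataset(base_model, table[feats])
        dup = table.copy()
        dup[f"{name}_copy"] = dup[name]
        dup_model = fit_score_model(dup)
        scored = score_dataset(dup_model, dup.drop(columns="label"))
        assert np.allclose(base["raw_score"], scored["raw_score"], atol=1e-10)
        assert np.allclose(base["redox_score"], scored["redox_score"], atol=1e-8)

    def test_monotone_in_positively_weighted_descriptor(self):
        df = _training_frame(seed=6)
        model = fit_score_model(df)
        name = max(model.descriptor_names, key=lambda k: model.w[k] * model.r[k])
        assert model.w[name] * model.r[name] > 0
        row = df.drop(columns="label").iloc[[0]].copy()
        bumped = row.copy()
        bumped[name] += 2.5
        both = pd.concat([row, bumped], ignore_index=True)
        scored = score_dataset(model, both, freeze=True)
        assert scored["raw_score"].iloc[1] >= scored["raw_score"].iloc[0]

    @pytest.mark.parametrize("slope,intercept", [(3.0, -7.0), (-2.0, 11.0), (0.25, 0.0)])
    def test_affine_rescaling_of_a_column_is_absorbed(self, slope, intercept):
        df = _training_frame(seed=7)
        feats = [c for c in df.columns if c != "label"]
        model = fit_score_model(df)
        base = score_dataset(model, df[feats])
        rescaled = df.copy()
        rescaled["d2"] = slope * rescaled["d2"] + intercept
        model2 = fit_score_model(rescaled)
        scored = score_dataset(model2, rescaled[feats])
        assert np.allclose(base["redox_score"], scored["redox_score"], atol=1e-8)


class TestGroupComparisons:
    def test_identical_groups_welch(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "welch_t")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_separated_mwu_u_zero(self):
        u, _ = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], "mann_whitney_u")
        assert u == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_welch_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=rng.integers(4, 15))
        b = rng.normal(0.7, 2, size=rng.integers(4, 15))
        t, p = compare_groups(a, b, "welch_t")
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0)
        assert p == pytest.approx(p0)

    @pytest.mark.parametrize("seed", range(20))
    def test_mwu_matches_textbook_formula_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, size=rng.integers(5, 20)).astype(float)
        b = rng.integers(2, 10, size=rng.integers(5, 20)).astype(float)
        u, p = compare_groups(a, b, "mann_whitney_u")
        u0, p0 = mwu_oracle(a, b)
        assert u == pytest.approx(u0)
        assert p == pytest.approx(p0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0], "mann_whitney_u")

    def test_descriptor_comparison_table_shape(self, strong_training_set):
        df = strong_training_set["training"]
        stats = descriptor_comparison_table(df, df["label"])
        assert set(stats["descriptor"]) == {
            "sg_distance", "pct_buried", "hse_total", "min_pka", "avg_b"
        }
        assert ((stats["p_value"] >= 0) & (stats["p_value"] <= 1)).all()
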