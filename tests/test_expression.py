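"""Probe collapsing, imputation and the two-group t-test."""

import numpy as np
import pandas as pd
import pytest

from modmir.exceptions import ConfigurationError, InputError
from modmir.expression import (
    ExpressionMatrix,
    collapse_probes,
    differential_test,
    impute_missing,
)
from oracles import pooled_t


def make_matrix(values, groups):
    df = pd.DataFrame(values)
    return ExpressionMatrix(values=df, groups=pd.Series(groups, index=df.columns))


TWO_GROUPS_4 = {"a": "case", "b": "case", "c": "control", "d": "control"}


class TestCollapseProbes:
    def test_probe_rows_are_averaged(self):
        m = make_matrix(
            {"a": [1.0, 3.0], "b": [3.0, 5.0], "c": [0.0, 0.0], "d": [0.0, 0.0]},
            TWO_GROUPS_4,
        )
        m.values.index = ["p1", "p2"]
        out = collapse_probes(m, {"p1": "G", "p2": "G"})
        assert list(out.values.loc["G", ["a", "b"]]) == [2.0, 4.0]

    def test_one_probe_per_feature_is_identity(self):
        m = make_matrix(
            {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0], "d": [7.0, 8.0]},
            TWO_GROUPS_4,
        )
        m.values.index = ["p1", "p2"]
        out = collapse_probes(m, {"p1": "G1", "p2": "G2"})
        assert np.allclose(out.values.loc[["G1", "G2"]].to_numpy(), m.values.to_numpy())

    def test_means_match_direct_recomputation(self, rng):
        probes = [f"p{i}" for i in range(5)]
        mapping = {"p0": "G1", "p1": "G1", "p2": "G2", "p3": "G2", "p4": "G2"}
        X = rng.normal(size=(5, 4))
        m = make_matrix(
            {s: X[:, j] for j, s in enumerate(["a", "b", "c", "d"])}, TWO_GROUPS_4
        )
        m.values.index = probes
        out = collapse_probes(m, mapping)
        assert np.allclose(out.values.loc["G1"], X[:2].mean(axis=0))
        assert np.allclose(out.values.loc["G2"], X[2:].mean(axis=0))

    def test_unmapped_probes_dropped_and_empty_map_rejected(self):
        m = make_matrix(
            {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0], "d": [7.0, 8.0]},
            TWO_GROUPS_4,
        )
        m.values.index = ["p1", "p2"]
        out = collapse_probes(m, {"p1": "G1", "zzz": "G9"})
        assert list(out.values.index) == ["G1"]
        with pytest.raises(InputError):
            collapse_probes(m, {"q": "G"})


class TestImputeMissing:
    def test_mean_fills_row_mean(self):
        m = make_matrix(
            {"a": [1.0], "b": [np.nan], "c": [3.0], "d": [2.0]}, TWO_GROUPS_4
        )
        out = impute_missing(m, method="mean")
        assert out.values.iloc[0, 1] == pytest.approx(2.0)

    def test_complete_matrix_unchanged(self, toy_matrix):
        out = impute_missing(toy_matrix, method="mean")
        pd.testing.assert_frame_equal(out.values, toy_matrix.values)

    def test_knn_k1_matches_exhaustive_nearest_row(self):
        # row 0 missing at column b; rows 1 and 2 observed everywhere
        values = pd.DataFrame(
            {
                "a": [1.0, 1.1, 9.0],
                "b": [np.nan, 4.0, 7.0],
                "c": [2.0, 2.1, 8.0],
                "d": [3.0, 3.2, 9.5],
            },
            index=["r0", "r1", "r2"],
        )
        m = ExpressionMatrix(values=values, groups=pd.Series(TWO_GROUPS_4))
        # exhaustive distances on co-observed columns (a, c, d):
        d1 = np.mean((values.loc["r0", ["a", "c", "d"]] - values.loc["r1", ["a", "c", "d"]]) ** 2)
        d2 = np.mean((values.loc["r0", ["a", "c", "d"]] - values.loc["r2", ["a", "c", "d"]]) ** 2)
        assert d1 < d2
        out = impute_missing(m, method="knn", k=1)
        assert out.values.loc["r0", "b"] == pytest.approx(4.0)

    def test_fully_missing_row_is_an_error(self):
        values = pd.DataFrame(
            {"a": [np.nan, 1.0], "b": [np.nan, 2.0], "c": [np.nan, 3.0], "d": [np.nan, 4.0]},
            index=["bad", "ok"],
        )
        m = ExpressionMatrix(values=values, groups=pd.Series(TWO_GROUPS_4))
        with pytest.raises(InputError, match="bad"):
            impute_missing(m)


class TestDifferentialTest:
    def test_identical_group_means_give_t0_p1(self, toy_matrix):
        de = differential_test(toy_matrix, "case", "control")
        assert de.loc["B", "t_score"] == pytest.approx(0.0)
        assert de.loc["B", "p_value"] == pytest.approx(1.0)

    def test_closed_form_pooled_example(self):
        m = make_matrix(
            {"a": [1.0], "b": [2.0], "c": [3.0], "x": [4.0], "y": [5.0], "z": [6.0]},
            {"a": "case", "b": "case", "c": "case", "x": "control", "y": "control", "z": "control"},
        )
        de = differential_test(m, "case", "control")
        assert de["t_score"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert de["p_value"].iloc[0] == pytest.approx(0.0214, abs=1e-3)
        assert de["direction"].iloc[0] == "down"

    def test_matches_textbook_pooled_formula(self, rng):
        n1, n2 = 7, 9
        X = rng.normal(size=(30, n1 + n2))
        samples = [f"s{i}" for i in range(n1 + n2)]
        groups = {s: ("case" if i < n1 else "control") for i, s in enumerate(samples)}
        m = make_matrix({s: X[:, i] for i, s in enumerate(samples)}, groups)
        de = differential_test(m, "case", "control")
        for i in range(30):
            t_ref, p_ref = pooled_t(X[i, :n1], X[i, n1:])
            assert de["t_score"].iloc[i] == pytest.approx(t_ref, rel=1e-10)
            assert de["p_value"].iloc[i] == pytest.approx(p_ref, rel=1e-10)

    def test_swapping_group_labels_negates_t_keeps_p(self, rng):
        X = rng.normal(size=(20, 10))
        samples = [f"s{i}" for i in range(10)]
        groups = {s: ("case" if i < 5 else "control") for i, s in enumerate(samples)}
        m = make_matrix({s: X[:, i] for i, s in enumerate(samples)}, groups)
        de = differential_test(m, "case", "control")
        de_swapped = differential_test(m, "control", "case")
        assert np.allclose(de["t_score"], -de_swapped["t_score"])
        assert np.allclose(de["p_value"], de_swapped["p_value"])

    def test_zero_variance_conventions(self):
        m = make_matrix(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [3.0, 2.0], "d": [3.0, 2.0]},
            TWO_GROUPS_4,
        )
        de = differential_test(m, "case", "control")
        assert de["t_score"].iloc[0] == -np.inf
        assert de["p_value"].iloc[0] == 0.0
        assert bool(de["degenerate"].iloc[0])
        assert de["t_score"].iloc[1] == 0.0
        assert de["p_value"].iloc[1] == 1.0

    def test_welch_flag_and_bad_arguments(self, toy_matrix):
        de = differential_test(toy_matrix, "case", "control", variant="welch")
        assert set(de.columns) >= {"t_score", "p_value", "direction", "is_significant"}
        with pytest.raises(ConfigurationError):
            differential_test(toy_matrix, "case", "control", variant="median")
        with pytest.raises(ConfigurationError):
            differential_test(toy_matrix, "case", "control", alpha=1.5)

    def test_bh_correction_flag(self, rng):
        X = rng.normal(size=(50, 10))
        samples = [f"s{i}" for i in range(10)]
        groups = {s: ("case" if i < 5 else "control") for i, s in enumerate(samples)}
        m = make_matrix({s: X[:, i] for i, s in enumerate(samples)}, groups)
        de = differential_test(m, "case", "control", correction="bh")
        assert "q_value" in de.columns
        assert (de["q_value"] >= de["p_value"] - 1e-12).all()
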