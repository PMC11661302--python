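"""Bound-set algebra, Wilcoxon DE with exact enumeration, and target gating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intraseq import (
    BoundSetSpec,
    NormalizedMatrix,
    ValidationError,
    build_bound_set,
    intersect_targets,
    wilcoxon_de,
)
from intraseq.tf_targets import _exact_ranksum_p


class TestBuildBoundSet:
    def test_union_minus_exclusions(self):
        spec = BoundSetSpec(
            include_sets={"t16": {"A", "B", "C"}, "t48": {"B", "C", "D"}},
            exclude_sets={"ctrl": {"C"}, "ko": {"D"}},
        )
        assert build_bound_set(spec) == {"A", "B"}

    def test_no_exclusions_is_plain_union(self):
        spec = BoundSetSpec(include_sets={"a": {"X"}, "b": {"Y"}})
        assert build_bound_set(spec) == {"X", "Y"}

    def test_disjoint_exclusions_leave_union_unchanged(self):
        spec = BoundSetSpec(include_sets={"a": {"X", "Y"}},
                            exclude_sets={"c": {"Z"}})
        assert build_bound_set(spec) == {"X", "Y"}

    def test_intersection_mode(self):
        spec = BoundSetSpec(include_sets={"a": {"X", "Y"}, "b": {"Y", "Z"}},
                            mode="intersection")
        assert build_bound_set(spec) == {"Y"}

    def test_case_fold_option(self):
        spec = BoundSetSpec(include_sets={"a": {"Stat3"}},
                            exclude_sets={"b": {"STAT3"}})
        assert build_bound_set(spec) == {"Stat3"}
        assert build_bound_set(spec, case_fold=True) == set()

    def test_empty_union_warns(self):
        spec = BoundSetSpec(include_sets={"a": set()})
        with pytest.warns(UserWarning):
            assert build_bound_set(spec) == set()

    def test_no_include_sets_rejected(self):
        with pytest.raises(ValidationError):
            build_bound_set(BoundSetSpec(include_sets={}))


def _norm(values, genes=None):
    values = np.asarray(values, float)
    return NormalizedMatrix(
        cells=[f"c{i}" for i in range(values.shape[0])],
        features=genes or [f"g{j}" for j in range(values.shape[1])],
        values=values, method="rna_lognorm",
    )


class TestWilcoxonDE:
    def test_identical_groups_null_result(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        m = _norm(vals)
        out = wilcoxon_de(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert out["log2_fc"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_p_for_three_vs_three(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 assignments are as extreme -> p = 0.1."""
        m = _norm(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]))
        out = wilcoxon_de(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert out["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_log2_fc_formula(self):
        """Back-transformed means 3 vs 1 with pseudo-count 1 -> log2(4/2) = 1."""
        a = np.log1p(np.full((3, 1), 3.0))
        b = np.log1p(np.full((3, 1), 1.0))
        m = _norm(np.vstack([a, b]))
        out = wilcoxon_de(m, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert out["log2_fc"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_asymptotic_close_to_exact_for_small_groups(self):
        rng = np.random.default_rng(21)
        worst = 0.0
        for _ in range(100):
            na, nb = rng.integers(5, 9, size=2)
            a = rng.normal(size=na)
            b = rng.normal(rng.uniform(-1, 1), size=nb)
            exact = _exact_ranksum_p(a, b)
            asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
            worst = max(worst, abs(exact - asym))
        assert worst < 0.02

    def test_group_constraints(self):
        m = _norm(np.zeros((6, 1)))
        with pytest.raises(ValidationError):
            wilcoxon_de(m, ["c0", "c1"], ["c2", "c3", "c4"])
        with pytest.raises(ValidationError):
            wilcoxon_de(m, ["c0", "c1", "c2"], ["c2", "c3", "c4"])

    def test_null_data_rarely_passes_joint_gate(self):
        """No group difference: <= 1% of genes pass FDR < 0.05 and FC > 1.5."""
        rng = np.random.default_rng(33)
        n_genes = 1000
        values = np.log1p(rng.gamma(2.0, 1.0, size=(60, n_genes)))
        m = _norm(values)
        out = wilcoxon_de(m, m.cells[:30], m.cells[30:])
        passed = (out["fdr"] < 0.05) & (out["log2_fc"].abs() > np.log2(1.5))
        assert passed.mean() <= 0.01


class TestIntersectTargets:
    def _de(self, rows, tp):
        frame = pd.DataFrame(rows, columns=["gene", "log2_fc", "fdr"])
        frame["p"] = frame["fdr"]
        frame["time_point"] = tp
        return frame

    def test_empty_bound_set_gives_empty_table(self):
        de = {"t1": self._de([("A", 2.0, 0.001)], "t1")}
        targets, counts = intersect_targets(set(), de)
        assert targets.empty
        assert counts["n_up"].sum() == 0

    def test_fold_change_gate_is_strict(self):
        de = {"t1": self._de([("A", np.log2(1.4), 0.04)], "t1")}
        targets, _ = intersect_targets({"A"}, de)
        assert not targets.loc[0, "de_any_timepoint"]

    def test_toy_counts_two_up_one_down(self):
        rows = [
            ("A", 1.5, 0.01),   # up
            ("B", 2.0, 0.001),  # up
            ("C", -1.2, 0.02),  # down
            ("D", 0.1, 0.001),  # fails FC gate
            ("E", 3.0, 0.20),   # fails FDR gate
        ]
        de = {"t1": self._de(rows, "t1")}
        targets, counts = intersect_targets({"A", "B", "C", "D", "E"}, de)
        c = counts.set_index("time_point").loc["t1"]
        assert (c["n_up"], c["n_down"]) == (2, 1)
        t = targets.set_index("gene")
        assert t.loc["A", "direction"] == "up"
        assert t.loc["C", "direction"] == "down"
        assert t.loc["D", "direction"] == "none"

    def test_direction_from_most_significant_time_point_with_conflict_flag(self):
        de = {
            "t1": self._de([("A", 2.0, 0.04)], "t1"),
            "t2": self._de([("A", -2.0, 0.001)], "t2"),
        }
        targets, _ = intersect_targets({"A"}, de)
        assert targets.loc[0, "direction"] == "down"
        assert targets.loc[0, "direction_conflict"]

    def test_counts_match_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(40)]
        de = {}
        for tp in ("t1", "t2", "t3"):
            rows = [(g, rng.normal(0, 1.5), rng.random()) for g in genes]
            de[tp] = self._de(rows, tp)
        bound = set(rng.choice(genes, size=25, replace=False))
        targets, counts = intersect_targets(bound, de)
        gate = np.log2(1.5)
        for tp in de:
            f = de[tp].set_index("gene")
            up = sum(1 for g in bound
                     if f.loc[g, "fdr"] < 0.05 and f.loc[g, "log2_fc"] > gate)
            down = sum(1 for g in bound
                       if f.loc[g, "fdr"] < 0.05 and f.loc[g, "log2_fc"] < -gate)
            row = counts.set_index("time_point").loc[tp]
            assert (row["n_up"], row["n_down"]) == (up, down)
        expected_de = {
            g for g in bound
            if any((de[tp].set_index("gene").loc[g, "fdr"] < 0.05)
                   and (abs(de[tp].set_index("gene").loc[g, "log2_fc"]) > gate)
                   for tp in de)
        }
        assert set(targets.loc[targets["de_any_timepoint"], "gene"]) == expected_de
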