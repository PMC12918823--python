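"""Cell-cycle gating, feature models, marker contrasts, proportion models
and representative-cell selection."""

import numpy as np
import pandas as pd
import pytest

from tglow import simulate as sim
from tglow.features import FeatureTable
from tglow.phenotyping import (GateSet, assign_cell_cycle, find_markers,
                               fit_feature_model, proportion_model,
                               representative_cells_categorical,
                               representative_cells_continuous)


def ray_casting_inside(poly, px, py):
    """Independent even-odd point-in-polygon oracle (boundary-exclusive)."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def feature_table(values: pd.DataFrame, meta: pd.DataFrame) -> FeatureTable:
    meta = meta.copy()
    for col, val in (("plate", "p1"), ("well", "w1"), ("field", 1)):
        if col not in meta:
            meta[col] = val
    return FeatureTable(values, meta)


class TestGateSet:
    def _gates(self):
        return GateSet.from_vertices(
            sim.DEFAULT_GATES,
            x_column="nucleus_intensity_integrated_dna",
            y_column="nucleus_intensity_integrated_ki67")

    def test_point_inside_gate(self):
        gates = self._gates()
        assert gates.assign(np.array([100.0]), np.array([1.0]))[0] == "G0"

    def test_point_outside_all_gates_is_other(self):
        gates = self._gates()
        assert gates.assign(np.array([500.0]), np.array([10.0]))[0] == "Other"

    def test_matches_ray_casting_oracle_on_grid(self):
        gates = self._gates()
        gx, gy = np.meshgrid(np.linspace(30, 300, 40), np.linspace(-1, 5, 25))
        labels = gates.assign(gx.ravel(), gy.ravel())
        for x, y, lab in zip(gx.ravel(), gy.ravel(), labels):
            expected = "Other"
            for name, poly in sim.DEFAULT_GATES.items():
                on_edge = any(
                    np.isclose(x, vx) or np.isclose(y, vy) for vx, vy in poly)
                if ray_casting_inside(poly, x, y) or (
                        on_edge and lab == name):
                    expected = name
                    break
            assert lab == expected, (x, y)

    def test_boundary_points_count_inside(self):
        gates = self._gates()
        # (60, 1.0) lies on the left edge of the G0 rectangle
        assert gates.assign(np.array([60.0]), np.array([1.0]))[0] == "G0"

    def test_first_wins_on_overlap(self):
        gates = GateSet.from_vertices(
            {"first": [(0, 0), (2, 0), (2, 2), (0, 2)],
             "second": [(1, 1), (3, 1), (3, 3), (1, 3)]},
            x_column="x", y_column="y", log10_y=False)
        assert gates.assign(np.array([1.5]), np.array([1.5]))[0] == "first"

    def test_invalid_polygon_rejected(self):
        bowtie = [(0, 0), (2, 2), (2, 0), (0, 2)]
        with pytest.raises(ValueError, match="not simple"):
            GateSet.from_vertices({"bad": bowtie})

    def test_json_round_trip(self, tmp_path):
        gates = self._gates()
        path = gates.to_json(tmp_path / "gates.json")
        back = GateSet.from_json(path)
        assert list(back.gates) == list(gates.gates)
        assert back.x_column == gates.x_column


class TestAssignCellCycle:
    def test_recovers_simulated_phase_fractions(self, feature_fixture):
        table, man = feature_fixture
        gates = GateSet.from_vertices(
            man.truth["gate_vertices"],
            x_column="nucleus_intensity_integrated_dna",
            y_column="nucleus_intensity_integrated_ki67")
        labels, frac = assign_cell_cycle(table, gates)
        observed = labels.value_counts(normalize=True) * 100
        for phase, target in man.truth["phase_fractions"].items():
            assert observed.get(phase, 0.0) == pytest.approx(target * 100, abs=2.0)

    def test_labels_invariant_to_row_order(self, feature_fixture):
        table, man = feature_fixture
        gates = GateSet.from_vertices(
            man.truth["gate_vertices"],
            x_column="nucleus_intensity_integrated_dna",
            y_column="nucleus_intensity_integrated_ki67")
        labels, _ = assign_cell_cycle(table, gates)
        perm = np.random.default_rng(1).permutation(table.n_cells)
        shuffled = FeatureTable(table.values.iloc[perm],
                                table.cell_meta.iloc[perm])
        labels2, _ = assign_cell_cycle(shuffled, gates)
        assert (labels2.loc[labels.index] == labels).all()

    def test_fractions_sum_to_100(self, feature_fixture):
        table, man = feature_fixture
        gates = GateSet.from_vertices(
            man.truth["gate_vertices"],
            x_column="nucleus_intensity_integrated_dna",
            y_column="nucleus_intensity_integrated_ki67")
        _, frac = assign_cell_cycle(table, gates)
        np.testing.assert_allclose(frac.sum(axis=1), 100.0)

    def test_missing_column_rejected(self, rng):
        values = pd.DataFrame({"cell_intensity_a_dna": rng.normal(size=10)})
        table = feature_table(values, pd.DataFrame(index=values.index))
        gates = GateSet.from_vertices(sim.DEFAULT_GATES)
        with pytest.raises(KeyError):
            assign_cell_cycle(table, gates)


class TestFitFeatureModel:
    def _table(self, beta, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        group = np.where(rng.random(n) < 0.5, "treated", "control")
        y = rng.normal(0, 1, n) + beta * (group == "treated")
        values = pd.DataFrame({"cell_intensity_a_dna": y})
        meta = pd.DataFrame({"group": group}, index=values.index)
        return feature_table(values, meta)

    def test_null_effect_small_coefficient(self):
        res = fit_feature_model(self._table(0.0), term="group")
        assert abs(res["coef"].iloc[0]) < 0.1

    def test_beta_recovery_matches_closed_form(self):
        table = self._table(0.5)
        res = fit_feature_model(table, term="group")
        # closed-form two-group OLS: difference of group means
        y = table.values.iloc[:, 0]
        g = table.cell_meta["group"] == "treated"
        expected = y[g].mean() - y[~g].mean()
        assert res["coef"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert 0.4 < res["coef"].iloc[0] < 0.6

    def test_identical_models_lrt_zero(self, rng):
        # term explains nothing that covariates do not: compare to itself
        table = self._table(0.3)
        res = fit_feature_model(table, term="group")
        assert res["lrt_stat"].iloc[0] > 0
        # degenerate check: a constant-effect term against itself
        y = table.values.iloc[:, 0].to_numpy()
        import statsmodels.api as smapi
        X = np.column_stack([np.ones_like(y)])
        fit = smapi.OLS(y, X).fit()
        assert 2 * (fit.llf - fit.llf) == 0.0

    def test_p_values_approximately_uniform_under_null(self):
        rng = np.random.default_rng(3)
        n, n_feat = 400, 60
        group = np.where(rng.random(n) < 0.5, "a", "b")
        values = pd.DataFrame(
            rng.normal(size=(n, n_feat)),
            columns=[f"cell_intensity_f{i}_dna" for i in range(n_feat)])
        table = feature_table(values, pd.DataFrame({"group": group},
                                                   index=values.index))
        res = fit_feature_model(table, term="group")
        assert 0.3 < res["p"].mean() < 0.7
        assert (res["p"] < 0.05).mean() < 0.15

    def test_constant_term_rejected(self):
        table = self._table(0.0)
        table.cell_meta["const"] = "x"
        with pytest.raises(ValueError, match="distinct"):
            fit_feature_model(table, term="const")


class TestFindMarkers:
    def _table(self, rng, shift_features=(), k=3, n_per=120):
        classes = [f"c{i}" for i in range(k)]
        labels = np.repeat(classes, n_per)
        values = pd.DataFrame(
            rng.normal(size=(k * n_per, 12)),
            columns=[f"cell_intensity_f{i}_dna" for i in range(12)])
        for f in shift_features:
            values.iloc[labels == "c0", f] += 1.0
        meta = pd.DataFrame({"cluster": labels}, index=values.index)
        return feature_table(values, meta)

    def test_two_class_vs_rest_equals_group_difference(self, rng):
        table = self._table(rng, k=2)
        res = find_markers(table, "cluster", mode="vs-rest")
        f0 = res[(res["class"] == "c0") & (res["feature"] ==
                                           "cell_intensity_f0_dna")]
        y = table.values["cell_intensity_f0_dna"]
        g = table.cell_meta["cluster"] == "c0"
        assert f0["coef"].iloc[0] == pytest.approx(y[g].mean() - y[~g].mean(),
                                                   abs=1e-9)

    def test_null_classes_control_fdr(self, rng):
        table = self._table(rng, k=3)
        res = find_markers(table, "cluster", mode="vs-rest")
        assert (res["p_adj"] < 0.05).mean() <= 0.07

    def test_constructed_markers_rank_first(self, rng):
        table = self._table(rng, shift_features=(0, 1, 2), k=3)
        res = find_markers(table, "cluster", mode="vs-rest")
        top = (res[res["class"] == "c0"].sort_values("p_adj")
               .head(3)["feature"].tolist())
        assert set(top) == {"cell_intensity_f0_dna", "cell_intensity_f1_dna",
                            "cell_intensity_f2_dna"}

    def test_vs_reference_contrast(self, rng):
        table = self._table(rng, shift_features=(0,), k=3)
        res = find_markers(table, "cluster", mode="vs-reference", reference="c1")
        f0 = res[(res["class"] == "c0") & (res["feature"] ==
                                           "cell_intensity_f0_dna")]
        y = table.values["cell_intensity_f0_dna"]
        lab = table.cell_meta["cluster"]
        expected = y[lab == "c0"].mean() - y[lab == "c1"].mean()
        assert f0["coef"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert not (res["class"] == "c1").any()

    def test_balanced_vs_rest_coefficients_sum_to_zero(self, rng):
        table = self._table(rng, k=3)
        res = find_markers(table, "cluster", mode="vs-rest")
        sums = res.groupby("feature")["coef"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestProportionModel:
    def test_constant_composition_zero_slope(self):
        frac = pd.DataFrame({"G0": [40.0] * 6, "G1": [60.0] * 6},
                            index=[f"d{i}" for i in range(6)])
        design = pd.Series([0, 1, 2, 3, 4, 5], index=frac.index, name="dose")
        res = proportion_model(frac, design)
        assert np.allclose(res["coef"], 0.0, atol=1e-9)

    def test_dose_trend_recovery(self):
        rng = np.random.default_rng(4)
        doses = np.repeat([0.0, 0.5, 1.0], 6)
        g0 = 30 + 16 * doses + rng.normal(0, 2, len(doses))
        g1 = 100 - g0
        frac = pd.DataFrame({"G0": g0, "G1": g1},
                            index=[f"d{i}" for i in range(len(doses))])
        res = proportion_model(frac, pd.Series(doses, index=frac.index,
                                               name="dose"))
        b = res.set_index("category")["coef"]
        assert b["G0"] == pytest.approx(16.0, abs=3.0)

    def test_category_slopes_sum_to_zero(self):
        rng = np.random.default_rng(5)
        doses = np.repeat([0, 1, 2], 5)
        a = 20 + 5 * doses + rng.normal(0, 1, 15)
        b = 30 - 2 * doses + rng.normal(0, 1, 15)
        c = 100 - a - b
        frac = pd.DataFrame({"A": a, "B": b, "C": c},
                            index=[f"s{i}" for i in range(15)])
        res = proportion_model(frac, pd.Series(doses.astype(float),
                                               index=frac.index, name="dose"))
        assert res["coef"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_underdetermined_rejected(self):
        frac = pd.DataFrame({"A": [50.0, 50.0]}, index=["s1", "s2"])
        design = pd.DataFrame({"d1": [0.0, 1.0], "d2": [1.0, 0.0]},
                              index=frac.index)
        with pytest.raises(ValueError, match="fewer samples"):
            proportion_model(frac, design)


class TestRepresentativeCells:
    def test_group_of_one_is_its_own_index(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 3)),
                              index=[f"c{i}" for i in range(5)])
        labels = pd.Series(["a"] * 4 + ["b"], index=scores.index)
        out = representative_cells_categorical(scores, labels, k=2)
        assert out["b"]["index_cell"] == "c4"
        assert out["b"]["neighbours"] == []

    def test_index_matches_brute_force(self, rng):
        scores = pd.DataFrame(rng.normal(size=(200, 2)),
                              index=[f"c{i}" for i in range(200)])
        labels = pd.Series("g", index=scores.index)
        out = representative_cells_categorical(scores, labels, k=5)
        S = scores.to_numpy()
        d2 = ((S - S.mean(axis=0)) ** 2).sum(axis=1)
        assert out["g"]["index_cell"] == scores.index[np.argmin(d2)]
        assert len(out["g"]["neighbours"]) == 5

    def test_quantile_index_ranks(self, rng):
        values = pd.Series(rng.permutation(1000).astype(float),
                           index=[f"c{i}" for i in range(1000)])
        out = representative_cells_continuous(values, [0.05, 0.5, 0.95], k=3)
        for q, expected in zip([0.05, 0.5, 0.95], [50, 500, 950]):
            assert abs(out[q]["rank"] - expected) <= 1
            assert len(out[q]["neighbours"]) == 6

    def test_invalid_quantile_rejected(self, rng):
        values = pd.Series(rng.normal(size=10))
        with pytest.raises(ValueError, match="quantiles"):
            representative_cells_continuous(values, [0.0])
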