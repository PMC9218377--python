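import numpy as np
import pandas as pd
import pytest

from augtrial.augmented_design import (
    AdjustedMeansTable,
    DesignError,
    adjust_test_entries,
    adjusted_means,
    anova_single_location,
    combined_anova,
    compute_block_adjustments,
)
from augtrial.trial_data import TraitSpec, TrialDataset

from conftest import ls_genotype_means, make_long


class TestBlockAdjustments:
    def test_hand_example(self, toy_dataset):
        adj = {a.block: a.adjustment for a in compute_block_adjustments(toy_dataset, "LOC", "Y")}
        assert adj == pytest.approx({"B1": -1.0, "B2": 1.0})

    def test_identical_checks_give_zero(self, toy_dataset):
        obs = toy_dataset.observations.copy()
        obs.loc[obs["role"] == "check", "value"] = 13.0
        data = TrialDataset(obs, dict(toy_dataset.traits), toy_dataset.checks)
        adjs = compute_block_adjustments(data, "LOC", "Y")
        assert all(a.adjustment == pytest.approx(0.0) for a in adjs)

    def test_single_block_zero(self):
        rows = [
            ("C1", "check", "L", "B1", "Y", 10.0),
            ("C2", "check", "L", "B1", "Y", 14.0),
        ]
        data = TrialDataset(make_long(rows), {"Y": TraitSpec("Y", "quantitative")}, ("C1", "C2"))
        (adj,) = compute_block_adjustments(data, "L", "Y")
        assert adj.adjustment == pytest.approx(0.0)
        assert adj.n_checks_used == 2

    def test_block_without_checks_warns_zero(self, toy_dataset):
        obs = toy_dataset.observations.copy()
        obs = obs[~((obs["role"] == "check") & (obs["block"] == "B2"))]
        data = TrialDataset(obs.reset_index(drop=True), dict(toy_dataset.traits), toy_dataset.checks)
        with pytest.warns(UserWarning, match="no check values"):
            adjs = compute_block_adjustments(data, "LOC", "Y")
        by_block = {a.block: a for a in adjs}
        assert by_block["B2"].adjustment == 0.0
        assert by_block["B2"].n_checks_used == 0

    def test_fewer_than_two_checks_raises(self):
        rows = [("C1", "check", "L", "B1", "Y", 10.0)]
        data = TrialDataset(make_long(rows), {"Y": TraitSpec("Y", "quantitative")}, ("C1",))
        with pytest.raises(DesignError):
            compute_block_adjustments(data, "L", "Y")

    def test_adjustments_sum_to_zero_with_complete_checks(self, paper_scale_dataset):
        adjs = compute_block_adjustments(paper_scale_dataset, "L1", "YLD")
        assert sum(a.adjustment for a in adjs) == pytest.approx(0.0, abs=1e-8)


class TestAdjustTestEntries:
    def test_hand_example(self, toy_dataset):
        table = adjust_test_entries(toy_dataset, "LOC")
        assert table.loc["T1", "Y"] == pytest.approx(21.0)
        assert table.loc["T2", "Y"] == pytest.approx(19.0)

    def test_checks_reported_as_raw_means(self, toy_dataset):
        table = adjust_test_entries(toy_dataset, "LOC")
        assert table.loc["C1", "Y"] == pytest.approx(11.0)
        assert table.loc["C2", "Y"] == pytest.approx(15.0)

    def test_identical_check_blocks_leave_tests_unchanged(self, toy_dataset):
        obs = toy_dataset.observations.copy()
        obs.loc[obs["role"] == "check", "value"] = 13.0
        data = TrialDataset(obs, dict(toy_dataset.traits), toy_dataset.checks)
        table = adjust_test_entries(data, "LOC")
        assert table.loc["T1", "Y"] == pytest.approx(20.0)
        assert table.loc["T2", "Y"] == pytest.approx(20.0)

    def test_least_squares_oracle_equivalence(self, toy_dataset):
        table = adjust_test_entries(toy_dataset, "LOC")
        oracle = ls_genotype_means(toy_dataset.numeric_slice("Y", "LOC"))
        for geno in ["T1", "T2", "C1", "C2"]:
            assert table.loc[geno, "Y"] == pytest.approx(oracle[geno], abs=1e-9)

    def test_least_squares_oracle_on_random_complete_design(self):
        rng = np.random.default_rng(42)
        rows = []
        blocks = [f"B{j}" for j in range(4)]
        for j, block in enumerate(blocks):
            for check in ["C1", "C2", "C3"]:
                rows.append((check, "check", "L", block, "Y", float(rng.normal(50, 5))))
            for t in range(3):
                rows.append((f"T{j}{t}", "test", "L", block, "Y", float(rng.normal(55, 5))))
        data = TrialDataset(make_long(rows), {"Y": TraitSpec("Y", "quantitative")}, ("C1", "C2", "C3"))
        table = adjust_test_entries(data, "L")
        oracle = ls_genotype_means(data.numeric_slice("Y", "L"))
        tests = [g for g in table.index if g.startswith("T")]
        for geno in tests:
            assert table.loc[geno, "Y"] == pytest.approx(oracle[geno], abs=1e-9)

    def test_constant_shift_equivariance(self, toy_dataset):
        base = adjust_test_entries(toy_dataset, "LOC")
        obs = toy_dataset.observations.copy()
        obs["value"] = obs["value"] + 7.5
        shifted = adjust_test_entries(
            TrialDataset(obs, dict(toy_dataset.traits), toy_dataset.checks), "LOC"
        )
        pd.testing.assert_frame_equal(shifted, base + 7.5)

    def test_missing_observation_propagates(self, toy_dataset):
        obs = toy_dataset.observations.copy()
        obs.loc[obs["genotype"] == "T1", "value"] = np.nan
        data = TrialDataset(obs, dict(toy_dataset.traits), toy_dataset.checks)
        table = adjust_test_entries(data, "LOC")
        assert np.isnan(table.loc["T1", "Y"])


class TestAnovaSingleLocation:
    def test_df_bookkeeping_paper_dimensions(self, paper_scale_dataset):
        table = anova_single_location(paper_scale_dataset, "L1", "YLD")
        dfs = {row["source"]: row["df"] for _, row in table.rows.iterrows()}
        assert dfs["Genotypes"] == 344
        assert dfs["Checks"] == 3
        assert dfs["Tests"] == 340
        assert dfs["Tests-vs-Checks"] == 1
        assert dfs["Block"] == 21
        assert dfs["Error"] == 63  # (4-1)(22-1)

    def test_df_additivity(self, paper_scale_dataset):
        table = anova_single_location(paper_scale_dataset, "L1", "Fe")
        assert table.df("Checks") + table.df("Tests") + table.df("Tests-vs-Checks") == table.df("Genotypes")

    def test_ss_matches_sequential_least_squares(self, toy_dataset):
        table = anova_single_location(toy_dataset, "LOC", "Y")
        obs = toy_dataset.numeric_slice("Y", "LOC")
        y = obs["value"].to_numpy()
        ones = np.ones((len(y), 1))
        blocks = pd.get_dummies(obs["block"], dtype=float).to_numpy()
        genos = pd.get_dummies(obs["genotype"], dtype=float).to_numpy()

        def sse(design):
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            r = y - design @ coef
            return float(r @ r)

        ss_total = float(((y - y.mean()) ** 2).sum())
        ss_block = ss_total - sse(np.hstack([ones, blocks]))
        ss_geno = sse(np.hstack([ones, blocks])) - sse(np.hstack([ones, blocks, genos]))
        assert table["Block"]["SS"] == pytest.approx(ss_block, abs=1e-9)
        assert table["Genotypes"]["SS"] == pytest.approx(ss_geno, abs=1e-9)

    def test_partition_sums_to_genotype_ss(self, paper_scale_dataset):
        table = anova_single_location(paper_scale_dataset, "L2", "Zn")
        parts = table["Checks"]["SS"] + table["Tests"]["SS"] + table["Tests-vs-Checks"]["SS"]
        assert parts == pytest.approx(table["Genotypes"]["SS"], rel=1e-9)

    def test_constant_shift_leaves_ss_unchanged(self, paper_scale_dataset):
        base = anova_single_location(paper_scale_dataset, "L1", "Zn")
        obs = paper_scale_dataset.observations.copy()
        mask = obs["trait"] == "Zn"
        obs.loc[mask, "value"] = pd.to_numeric(obs.loc[mask, "value"]) + 100.0
        shifted_data = TrialDataset(
            obs, dict(paper_scale_dataset.traits), paper_scale_dataset.checks
        )
        shifted = anova_single_location(shifted_data, "L1", "Zn")
        for source in ["Block", "Genotypes", "Checks", "Tests", "Error"]:
            assert shifted[source]["SS"] == pytest.approx(base[source]["SS"], rel=1e-9)

    def test_fewer_than_two_checks_unsupported(self, toy_dataset):
        obs = toy_dataset.observations
        obs = obs[obs["genotype"] != "C2"].reset_index(drop=True)
        data = TrialDataset(obs, dict(toy_dataset.traits), ("C1",))
        with pytest.raises(DesignError, match=">=2 checks"):
            anova_single_location(data, "LOC", "Y")


def hand_adjusted_table(values: dict) -> AdjustedMeansTable:
    """Build an AdjustedMeansTable from {genotype: {location: value}}."""
    per_loc = pd.DataFrame(
        [
            {"genotype": g, "location": loc, "Y": v}
            for g, locs in values.items()
            for loc, v in locs.items()
        ]
    ).set_index(["genotype", "location"])
    pooled = per_loc.groupby(level="genotype").mean()
    roles = pd.Series("test", index=pooled.index)
    return AdjustedMeansTable(per_loc, pooled, roles)


class TestCombinedAnova:
    def test_df_bookkeeping_paper_dimensions(self, paper_scale_dataset):
        adj = adjusted_means(paper_scale_dataset, traits=["YLD"])
        table = combined_anova(adj, [], "YLD")
        dfs = {row["source"]: row["df"] for _, row in table.rows.iterrows()}
        assert dfs == {"Genotype": 340, "Environment": 1, "Genotype x Environment": 340}

    def test_identical_locations_zero_interaction(self):
        adj = hand_adjusted_table(
            {g: {"L1": v, "L2": v} for g, v in [("A", 1.0), ("B", 2.0), ("C", 5.0)]}
        )
        table = combined_anova(adj, [], "Y")
        assert table["Environment"]["SS"] == pytest.approx(0.0, abs=1e-12)
        assert table["Genotype x Environment"]["SS"] == pytest.approx(0.0, abs=1e-12)

    def test_two_way_decomposition_identity(self):
        values = {
            "A": {"L1": 10.0, "L2": 14.0},
            "B": {"L1": 12.0, "L2": 18.0},
            "C": {"L1": 9.0, "L2": 11.0},
            "D": {"L1": 15.0, "L2": 13.0},
        }
        adj = hand_adjusted_table(values)
        table = combined_anova(adj, [], "Y")
        mat = np.array([[v["L1"], v["L2"]] for v in values.values()])
        ss_total = ((mat - mat.mean()) ** 2).sum()
        parts = (
            table["Genotype"]["SS"]
            + table["Environment"]["SS"]
            + table["Genotype x Environment"]["SS"]
        )
        assert parts == pytest.approx(ss_total, rel=1e-12)

    def test_single_location_unsupported(self):
        adj = hand_adjusted_table({"A": {"L1": 1.0}, "B": {"L1": 2.0}})
        with pytest.raises(DesignError, match=">=2 locations"):
            combined_anova(adj, [], "Y")

    def test_incomplete_genotypes_dropped_with_warning(self):
        adj = hand_adjusted_table(
            {
                "A": {"L1": 1.0, "L2": 2.0},
                "B": {"L1": 3.0, "L2": 4.0},
                "C": {"L1": 5.0},  # missing at L2
            }
        )
        with pytest.warns(UserWarning, match="dropped"):
            table = combined_anova(adj, [], "Y")
        assert table.metadata["dropped_genotypes"] == ["C"]
        assert table.df("Genotype") == 1

    def test_gxe_tested_against_pooled_error(self, paper_scale_dataset):
        per_loc = [
            anova_single_location(paper_scale_dataset, loc, "Zn")
            for loc in paper_scale_dataset.locations
        ]
        adj = adjusted_means(paper_scale_dataset, traits=["Zn"])
        table = combined_anova(adj, per_loc, "Zn")
        pooled_ms = sum(t["Error"]["SS"] for t in per_loc) / sum(t["Error"]["df"] for t in per_loc)
        assert table.metadata["pooled_error_ms"] == pytest.approx(pooled_ms)
        expected_f = table.ms("Genotype x Environment") / pooled_ms
        assert table["Genotype x Environment"]["F"] == pytest.approx(expected_f)


class TestAdjustedMeansTable:
    def test_pooled_is_mean_of_locations(self, small_dataset):
        adj = adjusted_means(small_dataset, traits=["YLD", "Fe"])
        manual = adj.per_location.groupby(level="genotype").mean()
        pd.testing.assert_frame_equal(adj.pooled, manual.sort_index())

    def test_method_tag(self, small_dataset):
        adj = adjusted_means(small_dataset, traits=["YLD"])
        assert "augmented" in adj.method
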