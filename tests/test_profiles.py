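"""Normalization, summary matrices, Welch tests and compact letters."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy
import scipy.stats

from floromics import (
    StageProfileTable,
    compact_letters,
    generate_metabolite_table,
    log2_stage_means,
    normalize,
    pairwise_stage_ttests,
    relative_to_reference,
    ttest_from_summary,
)
from floromics.reference import c13_accumulation


class TestNormalize:
    def test_unit_factors_identity(self, small_table):
        out = normalize(small_table)
        # fixture fw is 30 mg everywhere, so values scale by 1/30 uniformly
        assert out.values.to_numpy() == pytest.approx(small_table.values.to_numpy() / 30.0)
        assert out.normalized

    def test_doubling_fw_halves_values(self, small_table):
        doubled = StageProfileTable(
            small_table.values.copy(),
            classes=small_table.classes,
            fw_mg=small_table.fw_mg * 2,
            istd=small_table.istd,
        )
        assert normalize(doubled).values.to_numpy() == pytest.approx(
            normalize(small_table).values.to_numpy() / 2
        )

    def test_known_factors_recovered(self, rng):
        table, truth = generate_metabolite_table(10, noise_cv=0.0, seed=4)
        out = normalize(table)
        expected = table.values / (table.fw_mg * table.istd)
        assert out.values.to_numpy() == pytest.approx(expected.to_numpy())


class TestLog2StageMeans:
    def test_log_identity(self):
        cols = pd.MultiIndex.from_product(
            [["S9", "S13", "S16"], ["r1"]], names=["stage", "replicate"]
        )
        values = pd.DataFrame([[1.0, 2.0, 4.0]], index=["x", ], columns=cols)
        # need >= 2 replicates for means; single replicate mean = value
        out = log2_stage_means(StageProfileTable(values))
        assert out.loc["x"].tolist() == pytest.approx([0.0, 1.0, 2.0])

    def test_scaled_rows_are_zscores(self, small_table):
        out = log2_stage_means(normalize(small_table), scale_rows=True)
        ok = out.dropna(how="all")
        assert ok.mean(axis=1).to_numpy() == pytest.approx(0.0, abs=1e-9)
        assert ok.std(axis=1, ddof=1).to_numpy() == pytest.approx(1.0, abs=1e-9)

    def test_constant_compound_flagged(self):
        cols = pd.MultiIndex.from_product(
            [["S9", "S13"], ["r1", "r2"]], names=["stage", "replicate"]
        )
        values = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["flat"], columns=cols)
        with pytest.warns(UserWarning, match="zero variance"):
            out = log2_stage_means(StageProfileTable(values), scale_rows=True)
        assert out.loc["flat"].isna().all()

    def test_zero_mean_becomes_missing(self):
        cols = pd.MultiIndex.from_product(
            [["S9", "S13"], ["r1", "r2"]], names=["stage", "replicate"]
        )
        values = pd.DataFrame([[0.0, 0.0, 2.0, 2.0]], index=["x"], columns=cols)
        with pytest.warns(UserWarning, match="zero/negative"):
            out = log2_stage_means(StageProfileTable(values))
        assert np.isnan(out.loc["x", "S9"]) and out.loc["x", "S13"] == 1.0

    def test_two_archetype_clustering_splits_groups(self):
        table, truth = generate_metabolite_table(40, noise_cv=0.05, seed=7)
        trends = truth.compound_trends
        keep = trends["archetype"].isin(["up", "down"])
        sub = StageProfileTable(
            table.values.loc[keep], classes=table.classes[keep],
            fw_mg=table.fw_mg, istd=table.istd,
        )
        mat = log2_stage_means(sub, scale_rows=True)
        link = scipy.cluster.hierarchy.linkage(mat.to_numpy(), method="complete", metric="euclidean")
        cut = scipy.cluster.hierarchy.fcluster(link, 2, criterion="maxclust")
        labels = trends.loc[keep, "archetype"].to_numpy()
        # the 2-cluster cut separates rising from falling compounds
        assert len(set(cut[labels == "up"])) == 1
        assert len(set(cut[labels == "down"])) == 1
        assert set(cut[labels == "up"]) != set(cut[labels == "down"])


class TestRelativeToReference:
    def test_reference_stage_ratio_mean_one(self, small_table):
        out = relative_to_reference(small_table, "S9")
        s9 = out.values.xs("S9", axis=1, level="stage")
        assert s9.mean(axis=1).to_numpy() == pytest.approx(1.0)

    def test_doubling_series(self):
        cols = pd.MultiIndex.from_product(
            [["S9", "S12", "S13"], ["r1"]], names=["stage", "replicate"]
        )
        values = pd.DataFrame([[1.0, 2.0, 4.0]], index=["x"], columns=cols)
        out = relative_to_reference(StageProfileTable(values), "S9")
        assert out.values.loc["x"].tolist() == pytest.approx([1.0, 2.0, 4.0])

    def test_global_rescale_invariance(self, small_table):
        scaled = StageProfileTable(
            small_table.values * 7.3, classes=small_table.classes,
            fw_mg=small_table.fw_mg, istd=small_table.istd,
        )
        a = relative_to_reference(small_table, "S9").values.to_numpy()
        b = relative_to_reference(scaled, "S9").values.to_numpy()
        assert b == pytest.approx(a)

    def test_zero_reference_dropped(self):
        cols = pd.MultiIndex.from_product(
            [["S9", "S13"], ["r1", "r2"]], names=["stage", "replicate"]
        )
        values = pd.DataFrame(
            [[0.0, 0.0, 1.0, 1.0], [1.0, 1.0, 2.0, 2.0]], index=["z", "x"], columns=cols
        )
        with pytest.warns(UserWarning, match="reference mean"):
            out = relative_to_reference(StageProfileTable(values), "S9")
        assert list(out.values.index) == ["x"]


class TestTTestFromSummary:
    def test_identical_groups(self):
        t, df, p = ttest_from_summary(5.0, 1.0, 3, 5.0, 1.0, 3)
        assert t == 0.0 and p == 1.0

    def test_zero_variance_equal_and_unequal(self):
        assert ttest_from_summary(2.0, 0.0, 3, 2.0, 0.0, 3)[2] == 1.0
        with pytest.warns(UserWarning):
            assert ttest_from_summary(2.0, 0.0, 3, 3.0, 0.0, 3)[2] == 0.0

    def test_published_fru_pairs(self):
        # anthesis vs postanthesis share a letter; pre vs anthesis do not
        _, _, p_shared = ttest_from_summary(2378.80, 25.09, 3, 2418.67, 212.58, 3)
        assert p_shared > 0.05
        _, _, p_diff = ttest_from_summary(437.16, 103.16, 3, 2378.80, 25.09, 3)
        assert p_diff < 0.05

    def test_matches_scipy_on_replicate_data(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 7)
        t_ref, p_ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        t, _, p = ttest_from_summary(
            a.mean(), a.std(ddof=1) / np.sqrt(5), 5, b.mean(), b.std(ddof=1) / np.sqrt(7), 7
        )
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)


class TestCompactLetters:
    def test_three_separated_groups(self):
        letters = compact_letters([(0.0, 0.1, 3), (10.0, 0.1, 3), (20.0, 0.1, 3)])
        assert letters == ["a", "b", "c"]

    def test_published_succinate_pattern(self):
        letters = compact_letters(
            [(137.83, 14.18, 3), (431.74, 27.73, 3), (155.27, 6.66, 3)]
        )
        assert letters == ["a", "b", "a"]

    def test_identical_groups_share_letter(self):
        letters = compact_letters([(1.0, 0.5, 3)] * 3)
        assert letters == ["a", "a", "a"]

    def test_letter_semantics_hold_on_reference_rows(self):
        # groups share a letter iff their pairwise test is not significant
        ref = c13_accumulation()
        phases = ("preanthesis", "anthesis", "postanthesis")
        for _, row in ref.iterrows():
            groups = [(row[f"{ph}_mean"], row[f"{ph}_se"], 3) for ph in phases]
            letters = compact_letters(groups)
            for i in range(3):
                for j in range(i + 1, 3):
                    _, _, p = ttest_from_summary(*groups[i], *groups[j])
                    share = bool(set(letters[i]) & set(letters[j]))
                    assert share == (p >= 0.05)


class TestPairwiseStageTTests:
    def _table(self, rows, stages=("S9", "S13", "S16")):
        cols = pd.MultiIndex.from_product(
            [list(stages), ["r1", "r2", "r3"]], names=["stage", "replicate"]
        )
        return StageProfileTable(
            pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))], columns=cols)
        )

    def test_identical_groups_single_letter(self):
        t = self._table([[5.0, 5.1, 4.9] * 3])
        out = pairwise_stage_ttests(t, grouping="phase")
        assert set("".join(out.letters.loc["c0"])) == {"a"}
        assert not out.bold.loc["c0"]

    def test_separated_groups_three_letters_bold(self):
        t = self._table([[1.0, 1.01, 0.99, 50.0, 50.5, 49.5, 200.0, 201.0, 199.0]])
        out = pairwise_stage_ttests(t, grouping="phase")
        assert list(out.letters.loc["c0"]) == ["a", "b", "c"]
        assert out.bold.loc["c0"]

    def test_agrees_with_summary_path(self, rng):
        values = rng.lognormal(0, 0.4, (4, 9))
        t = self._table(values.tolist())
        out = pairwise_stage_ttests(t, grouping="phase")
        for comp in out.means.index:
            groups = [
                (out.means.loc[comp, g], out.se.loc[comp, g], int(out.n.loc[comp, g]))
                for g in out.means.columns
            ]
            assert compact_letters(groups) == list(out.letters.loc[comp])

    def test_single_replicate_group_skipped(self):
        cols = pd.MultiIndex.from_tuples(
            [("S9", "r1"), ("S9", "r2"), ("S13", "r1")], names=["stage", "replicate"]
        )
        t = StageProfileTable(pd.DataFrame([[1.0, 2.0, 3.0]], index=["c0"], columns=cols))
        with pytest.warns(UserWarning, match="<2 replicates"):
            out = pairwise_stage_ttests(t, grouping="stage")
        assert out.means.empty
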