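"""The RNA-seq count funnel: filtering, normalization, trend test, clustering."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from floromics import (
    CountMatrix,
    filter_low_counts,
    generate_count_matrix,
    kmeans_profiles,
    normalize_logcpm,
    stage_contrasts,
    trend_filter,
)
from floromics.stages import CANONICAL_STAGES

AGES = np.repeat([s.age_days for s in CANONICAL_STAGES], 3)


def tiny_counts(values, n_samples=6):
    genes = [f"g{i}" for i in range(len(values))]
    cols = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "stage": ["S9"] * (n_samples // 2) + ["S13"] * (n_samples - n_samples // 2),
            "age_days": [7.25] * (n_samples // 2) + [11.5] * (n_samples - n_samples // 2),
            "replicate": [f"r{i}" for i in range(n_samples)],
        },
        index=cols,
    )
    return CountMatrix(pd.DataFrame(values, index=genes, columns=cols), samples)


class TestFilterLowCounts:
    def test_boundary_strictly_less_than(self):
        cm = tiny_counts([[1, 2, 2, 2, 1, 1], [2, 2, 2, 2, 1, 1]])  # totals 9 and 10
        kept = filter_low_counts(cm, 10)
        assert list(kept.counts.index) == ["g1"]

    def test_zero_threshold_identity(self):
        cm = tiny_counts([[0] * 6, [1] * 6])
        assert filter_low_counts(cm, 0).counts.shape == cm.counts.shape

    def test_planted_low_fraction_removed(self):
        cm, truth = generate_count_matrix(1000, frac_low=0.05, seed=9)
        kept = filter_low_counts(cm, 10)
        removed = set(cm.counts.index) - set(kept.counts.index)
        low = set(truth.gene_coefficients.index[truth.gene_coefficients["low"]])
        # essentially all planted low-expression genes are removed
        assert len(low & removed) / len(low) > 0.9


class TestNormalizeLogcpm:
    def test_closed_form_zero_count(self):
        cm = tiny_counts([[0] * 6])
        cm.counts.iloc[0, 0] = 0
        # library of 1e6: add a high-count gene to set the library size
        cm2 = tiny_counts([[0] * 6, [10**6] * 6])
        out = normalize_logcpm(cm2, prior=0.5)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=0.01)

    def test_scale_invariance(self):
        cm1 = tiny_counts([[10, 20, 30, 5, 5, 5], [90, 80, 70, 95, 95, 95]])
        cm2 = tiny_counts([[20, 40, 60, 10, 10, 10], [180, 160, 140, 190, 190, 190]])
        a, b = normalize_logcpm(cm1), normalize_logcpm(cm2)
        assert a.to_numpy() == pytest.approx(b.to_numpy(), abs=1e-4)

    def test_monotone_in_count(self):
        cm = tiny_counts([[1, 2, 3, 4, 5, 6], [100] * 6])
        out = normalize_logcpm(cm)
        assert (np.diff(out.iloc[0].to_numpy()[:3]) > 0).all()

    def test_integer_validation(self):
        with pytest.raises(ValueError, match="integer"):
            tiny_counts([[0.5] * 6])


class TestTrendFilter:
    def test_noiseless_quadratic_kept(self):
        z = (AGES - AGES.mean()) / AGES.std()
        y = pd.DataFrame([5 + z**2, 3 + 0 * z])
        fit = trend_filter(y, AGES)
        assert bool(fit.keep.iloc[0])
        assert np.isinf(fit.f_statistic.iloc[0])

    def test_flat_gene_pvalues_uniform(self, rng):
        y = pd.DataFrame(rng.normal(5, 0.3, size=(2000, len(AGES))))
        fit = trend_filter(y, AGES)
        assert abs((fit.p < 0.05).mean() - 0.05) < 0.02
        # uniformity beyond the 0.05 tail
        assert abs((fit.p < 0.5).mean() - 0.5) < 0.05

    def test_power_at_stated_conditions(self, rng):
        z = (AGES - AGES.mean()) / AGES.std()
        quad = z**2 - (z**2).mean()
        quad = quad / (quad.max() - quad.min())  # 2-fold swing in log2 units
        sd = np.log2(np.e) * np.sqrt(np.log1p(0.2**2))  # CV 20%
        y = pd.DataFrame(5 + 1.0 * quad + rng.normal(0, sd, size=(500, len(AGES))))
        fit = trend_filter(y, AGES)
        assert (fit.p < 0.05).mean() > 0.9

    def test_constant_ages_rejected(self):
        y = pd.DataFrame(np.ones((2, 6)))
        with pytest.raises(ValueError):
            trend_filter(y, np.full(6, 10.0))

    def test_bh_step_up_hand_example(self):
        # classic 5-value worked example of the step-up procedure
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        q = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx([0.05, 0.05, 0.05, 0.05, 0.05])
        p2 = np.array([0.005, 0.011, 0.02, 0.04, 0.3])
        q2 = multipletests(p2, method="fdr_bh")[1]
        assert q2 == pytest.approx([0.025, 0.0275, 0.03333333, 0.05, 0.3])


class TestStageContrasts:
    def test_null_contrast_controlled(self, rng):
        cols = [f"s{i}" for i in range(6)]
        samples = pd.DataFrame(
            {"stage": ["S9"] * 3 + ["S10"] * 3, "age_days": [7.25] * 3 + [9.25] * 3,
             "replicate": ["r1", "r2", "r3"] * 2},
            index=cols,
        )
        y = pd.DataFrame(rng.normal(5, 0.5, (2000, 6)), columns=cols)
        out = stage_contrasts(y, samples["stage"], [("S9", "S10")])
        tab = out[("S9", "S10")]
        assert abs((tab["p"] < 0.05).mean() - 0.05) < 0.03
        assert tab["significant"].mean() < 0.01

    def test_planted_degs_recalled(self, rng):
        n, n_deg = 2000, 200
        sd = np.log2(np.e) * np.sqrt(np.log1p(0.2**2))
        a = rng.normal(5, sd, (n, 3))
        b = rng.normal(5, sd, (n, 3))
        b[:n_deg] += 2.0  # 4-fold
        y = pd.DataFrame(np.hstack([a, b]))
        stages = ["S9"] * 3 + ["S13"] * 3
        tab = stage_contrasts(y, stages, [("S13", "S9")])[("S13", "S9")]
        # raw-p recall is essentially complete; BH recall is limited by the
        # noisy per-gene variance estimate at n = 3 without moderation
        assert (tab["p"][:n_deg] < 0.05).mean() > 0.95
        assert tab["significant"][:n_deg].mean() > 0.4
        assert tab["significant"][n_deg:].mean() < 0.01

    def test_swapping_contrast_flips_sign_only(self, rng):
        y = pd.DataFrame(rng.normal(0, 1, (50, 6)))
        stages = ["S9"] * 3 + ["S13"] * 3
        ab = stage_contrasts(y, stages, [("S9", "S13")])[("S9", "S13")]
        ba = stage_contrasts(y, stages, [("S13", "S9")])[("S13", "S9")]
        assert ab["t"].to_numpy() == pytest.approx(-ba["t"].to_numpy())
        assert ab["p"].to_numpy() == pytest.approx(ba["p"].to_numpy())


class TestKmeansProfiles:
    def test_planted_step_archetypes_separated(self, rng):
        stages = [s.stage_label for s in CANONICAL_STAGES]
        up = np.array([0, 0, 0, 1.0, 1, 1, 1, 1])
        down = 1.0 - up
        rows = [up + 0.01 * rng.normal(size=8) for _ in range(20)] + [
            down + 0.01 * rng.normal(size=8) for _ in range(20)
        ]
        sm = pd.DataFrame(rows, columns=stages)
        out = kmeans_profiles(sm, k=2, seed=0)
        labels = out.assignment.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]
        steps = out.anthesis_step
        assert steps.iloc[labels[0]] * steps.iloc[labels[20]] < 0  # opposite signs

    def test_k1_centroid_is_global_mean(self, rng):
        sm = pd.DataFrame(rng.normal(size=(10, 8)),
                          columns=[s.stage_label for s in CANONICAL_STAGES])
        out = kmeans_profiles(sm, k=1, seed=0)
        x = sm.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        assert out.centroids.iloc[0].to_numpy() == pytest.approx(z.mean(0))

    def test_seeded_determinism(self, rng):
        sm = pd.DataFrame(rng.normal(size=(30, 8)),
                          columns=[s.stage_label for s in CANONICAL_STAGES])
        a = kmeans_profiles(sm, k=3, seed=5)
        b = kmeans_profiles(sm, k=3, seed=5)
        assert (a.assignment == b.assignment).all()

    def test_k_exceeding_genes_rejected(self, rng):
        sm = pd.DataFrame(rng.normal(size=(3, 8)),
                          columns=[s.stage_label for s in CANONICAL_STAGES])
        with pytest.raises(ValueError):
            kmeans_profiles(sm, k=5, seed=0)


class TestFunnelOrderStability:
    def test_planted_structure_survives_funnel(self):
        cm, truth = generate_count_matrix(
            600, frac_null=0.5, dispersion=0.05, seed=21
        )
        kept = filter_low_counts(cm, 10)
        # normalize by the nominal sequencing depth: with half the genes
        # strongly trending, column sums carry a composition trend that CPM
        # would transfer onto flat genes
        logcpm = normalize_logcpm(kept, lib_sizes=np.full(kept.counts.shape[1], 1e6))
        fit = trend_filter(logcpm, kept.ages, fdr=0.05)
        coef = truth.gene_coefficients.loc[fit.keep.index]
        null_kept = fit.keep[coef["null"]].mean()
        trend_kept = fit.keep[~coef["null"] & ~coef["low"]].mean()
        assert trend_kept > 0.9
        assert null_kept < 0.08  # FDR-level leakage only
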