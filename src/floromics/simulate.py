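"""Synthetic data generators with known ground truth.

Every analysis stage in this package has a generator here producing inputs
with the statistical structure that stage assumes, plus the ground truth it
was generated from, so the whole pipeline is testable end to end with no
external data.  At zero noise each generator is the exact inverse of its
analysis counterpart.

The generators' defaults emulate the anthesis study design: 8 developmental
stages (ages 7.25–15.25 days, anthesis at 11.50 d) × 3 replicates and ~130
compounds for the metabolite table; negative-binomial counts with smooth
quadratic age trends plus null genes for the RNA-seq matrix; label
partitions over nine compound classes with n = 5 replicates for the ¹⁴C
experiment.  Multiplicative lognormal noise is used for abundances and
radioactivities (the metabolomics convention); the default abundance CV of
0.2 reflects typical between-replicate variation of GC–MS floret pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .flux import COMPOUND_CLASSES_14C, LabelPartition
from .io import COMPOUND_CLASSES, StageProfileTable
from .isotopes import ElementalFormula, MIDRecord, correction_matrix
from .reference import (
    C14_FEEDING_HOURS,
    C14_FEEDING_SA,
    C14_REDISTRIBUTION_PCT,
    C14_TOTALS,
)
from .stages import CANONICAL_STAGES
from .transcripts import CountMatrix

__all__ = [
    "SimulationTruth",
    "TREND_ARCHETYPES",
    "default_true_fluxes",
    "generate_metabolite_table",
    "generate_count_matrix",
    "generate_mid_data",
    "generate_14c_experiment",
]

TREND_ARCHETYPES = ("up", "down", "peak_at_anthesis", "flat")


@dataclass
class SimulationTruth:
    """Ground truth behind a batch of simulated data.

    Only the fields relevant to the generator that produced it are filled.
    """

    compound_trends: pd.DataFrame | None = None  # archetype, log2_fold, baseline
    gene_coefficients: pd.DataFrame | None = None  # beta0..beta2, null flag
    enrichments: pd.Series | None = None  # metabolite -> E* in [0, 1]
    true_fluxes: dict[str, float] | None = None  # class -> nmol gFW^-1 h^-1

    def __post_init__(self) -> None:
        if self.enrichments is not None:
            e = self.enrichments
            if ((e < 0) | (e > 1)).any():
                raise ValueError("true enrichments must lie in [0, 1]")
        if self.true_fluxes is not None and any(v < 0 for v in self.true_fluxes.values()):
            raise ValueError("true fluxes must be non-negative")
        if self.compound_trends is not None:
            flat = self.compound_trends["archetype"] == "flat"
            if (self.compound_trends.loc[flat, "log2_fold"] != 0).any():
                raise ValueError("flat compounds must have zero trend effect")


def default_true_fluxes(
    specific_activity: float = C14_FEEDING_SA, duration_h: float = C14_FEEDING_HOURS
) -> dict[str, float]:
    """Per-class fluxes implied by the reference redistribution summary.

    These serve as realistic defaults for the ¹⁴C generator: the published
    mean class percentages applied to the published mean metabolized label
    at the feeding-solution specific activity.
    """
    met = C14_TOTALS["metabolized radioactivity"][0]
    return {
        c: pct / 100.0 * met / (specific_activity * duration_h)
        for c, (pct, _) in C14_REDISTRIBUTION_PCT.items()
    }


def _sigma_from_cv(cv: float) -> float:
    # lognormal(mu=-sigma^2/2, sigma) has mean 1 and CV sqrt(exp(sigma^2)-1)
    return float(np.sqrt(np.log1p(cv**2)))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s = _sigma_from_cv(cv)
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=size)


def _trend_log_abundance(archetype: str, log2_fold: float, ages: np.ndarray) -> np.ndarray:
    """Natural-log abundance trend over age for one compound."""
    a0, a1 = ages.min(), ages.max()
    rel = (ages - a0) / (a1 - a0)
    if archetype == "up":
        shape = rel
    elif archetype == "down":
        shape = 1.0 - rel
    elif archetype == "peak_at_anthesis":
        shape = np.exp(-0.5 * ((ages - 11.50) / 1.0) ** 2)  # 1-day-sd bump
    elif archetype == "flat":
        shape = np.zeros_like(ages)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return np.log(2.0) * log2_fold * shape


def generate_metabolite_table(
    n_compounds: int = 130,
    truth: SimulationTruth | None = None,
    noise_cv: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
) -> tuple[StageProfileTable, SimulationTruth]:
    """Simulate a stage-resolved metabolite abundance table.

    8 stages × ``n_replicates`` samples; abundance = baseline ×
    exp(trend(age)) × lognormal noise at the given CV.  Fresh weight and
    internal standard are drawn with 10% CV around 30 mg and 1.0.  If
    ``truth`` is given its ``compound_trends`` are honoured; otherwise
    archetypes are assigned round-robin with log₂ fold ranges drawn from
    U(1, 3) (flat compounds get 0).
    """
    if n_compounds < 2:
        raise ValueError("need at least two compounds")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    ages = np.array([s.age_days for s in CANONICAL_STAGES])
    stage_labels = [s.stage_label for s in CANONICAL_STAGES]

    if truth is None or truth.compound_trends is None:
        archetypes = [TREND_ARCHETYPES[i % len(TREND_ARCHETYPES)] for i in range(n_compounds)]
        log2_fold = np.where(
            np.array(archetypes) == "flat", 0.0, rng.uniform(1.0, 3.0, n_compounds)
        )
        baseline = 10.0 ** rng.uniform(0.0, 3.0, n_compounds)
        classes = rng.choice(COMPOUND_CLASSES, size=n_compounds)
        trends = pd.DataFrame(
            {
                "archetype": archetypes,
                "log2_fold": log2_fold,
                "baseline": baseline,
                "class": classes,
            },
            index=[f"compound_{i:03d}" for i in range(n_compounds)],
        )
        truth = SimulationTruth(compound_trends=trends)
    trends = truth.compound_trends

    columns = pd.MultiIndex.from_product(
        [stage_labels, [f"r{i + 1}" for i in range(n_replicates)]],
        names=["stage", "replicate"],
    )
    values = np.empty((len(trends), len(columns)))
    for k, (cid, row) in enumerate(trends.iterrows()):
        mean_per_stage = row["baseline"] * np.exp(
            _trend_log_abundance(row["archetype"], row["log2_fold"], ages)
        )
        per_sample = np.repeat(mean_per_stage, n_replicates)
        values[k] = per_sample * _lognormal_noise(rng, noise_cv, len(columns))

    fw = pd.Series(30.0 * _lognormal_noise(rng, 0.10, len(columns)), index=columns)
    istd = pd.Series(1.0 * _lognormal_noise(rng, 0.10, len(columns)), index=columns)
    table = StageProfileTable(
        pd.DataFrame(values, index=trends.index, columns=columns),
        classes=trends["class"] if "class" in trends else None,
        fw_mg=fw,
        istd=istd,
    )
    return table, truth


def generate_count_matrix(
    n_genes: int = 2000,
    frac_null: float = 0.5,
    dispersion: float = 0.1,
    lib_sizes: Sequence[float] | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    frac_low: float = 0.05,
    log2_swing: tuple[float, float] = (1.0, 3.0),
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate an RNA-seq count matrix with quadratic stage trends.

    Counts are negative-binomial with mean ``lib_size × exp(quadratic(age))``
    and variance ``mean + dispersion·mean²``.  ``frac_null`` of genes are
    flat (zero trend coefficients); ``frac_low`` of genes have expression so
    low that their expected total count falls below the usual 10-count
    filter.
    """
    if not 0.0 <= frac_null <= 1.0:
        raise ValueError("frac_null must lie in [0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    ages_stage = np.array([s.age_days for s in CANONICAL_STAGES])
    stage_labels = [s.stage_label for s in CANONICAL_STAGES]
    ages = np.repeat(ages_stage, n_replicates)
    n_samples = len(ages)
    if lib_sizes is None:
        lib_sizes = np.full(n_samples, 1.0e6)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.shape != (n_samples,):
        raise ValueError(f"lib_sizes must have length {n_samples}")

    null = rng.random(n_genes) < frac_null
    low = rng.random(n_genes) < frac_low
    # relative expression (fraction of the library at the mean age)
    log_rel = rng.normal(np.log(3e-5), 1.0, n_genes)
    log_rel[low] = np.log(0.1 / lib_sizes.mean() / n_samples)  # ~0.1 expected total
    z = (ages - ages.mean()) / ages.std()
    swing = rng.uniform(*log2_swing, n_genes) * np.log(2.0)
    b1 = rng.normal(0.0, 1.0, n_genes)
    b2 = rng.normal(0.0, 1.0, n_genes)
    norm = np.sqrt(b1**2 + b2**2)
    norm[norm == 0] = 1.0
    b1, b2 = swing * b1 / norm, swing * b2 / norm
    b1[null] = b2[null] = 0.0

    trend = np.outer(b1, z) + np.outer(b2, z**2 - (z**2).mean())
    mean = lib_sizes * np.exp(log_rel[:, None] + trend)
    if dispersion < 1e-8:
        counts = rng.poisson(mean)
    else:
        n_param = 1.0 / dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mean))

    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    sample_ids = [
        f"{s}_r{r + 1}" for s in stage_labels for r in range(n_replicates)
    ]
    samples = pd.DataFrame(
        {
            "stage": np.repeat(stage_labels, n_replicates),
            "age_days": ages,
            "replicate": [f"r{r + 1}" for _ in stage_labels for r in range(n_replicates)],
        },
        index=sample_ids,
    )
    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), samples)
    truth = SimulationTruth(
        gene_coefficients=pd.DataFrame(
            {"beta0": log_rel, "beta1": b1, "beta2": b2, "null": null, "low": low},
            index=genes,
        )
    )
    return matrix, truth


def generate_mid_data(
    formulas: Mapping[str, ElementalFormula],
    enrichments: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[MIDRecord], SimulationTruth]:
    """Simulate measured MIDs at known fractional enrichments.

    Labelling is binomial and independent per tracer carbon at enrichment
    E*; the labelled distribution is convolved with the natural-abundance
    signature of the full formula (via the forward correction matrix), then
    perturbed with truncated-normal noise of the given sd and renormalized
    to sum to one.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if enrichments is None:
        enrichments = {name: rng.uniform(0.0, 0.8) for name in formulas}
    records = []
    for name, formula in formulas.items():
        e_star = float(enrichments[name])
        if not 0.0 <= e_star <= 1.0:
            raise ValueError(f"enrichment for {name!r} outside [0, 1]")
        n = formula.n_tracer_carbons
        labelled = scipy.stats.binom.pmf(np.arange(n + 1), n, e_star)
        measured = correction_matrix(formula) @ labelled
        if noise_sd > 0:
            measured = np.clip(measured + rng.normal(0.0, noise_sd, n + 1), 0.0, None)
        total = measured.sum()
        if total <= 0:
            raise ArithmeticError(f"simulated MID for {name!r} vanished")
        records.append(MIDRecord(name, formula, measured / total))
    truth = SimulationTruth(enrichments=pd.Series(dict(enrichments), dtype=float))
    return records, truth


def generate_14c_experiment(
    true_fluxes: Mapping[str, float] | None = None,
    specific_activity: float = C14_FEEDING_SA,
    duration_h: float = C14_FEEDING_HOURS,
    n_replicates: int = 5,
    noise_cv: float = 0.3,
    seed: int = 0,
    uptake_fraction: float = 0.95,
    recovery: tuple[float, float] = (0.58, 0.04),
) -> tuple[list[LabelPartition], SimulationTruth]:
    """Simulate a whole-inflorescence ¹⁴C feeding experiment.

    Per replicate and class, incorporated label is
    ``J* × SA × duration × lognormal(noise_cv)``; metabolized label is the
    class total; uptake is metabolized divided by ``uptake_fraction`` (the
    observed metabolized-to-uptake ratio); the fractionation recovery is an
    independent pass-through draw.  At ``noise_cv = 0`` the flux estimator
    recovers the true fluxes exactly.
    """
    if specific_activity <= 0 or duration_h <= 0:
        raise ValueError("specific_activity and duration_h must be positive")
    if not 0 < uptake_fraction <= 1:
        raise ValueError("uptake_fraction must lie in (0, 1]")
    if true_fluxes is None:
        true_fluxes = default_true_fluxes(specific_activity, duration_h)
    if any(v < 0 for v in true_fluxes.values()):
        raise ValueError("true fluxes must be non-negative")
    rng = np.random.default_rng(seed)
    partitions = []
    for i in range(n_replicates):
        bq = {
            c: j * specific_activity * duration_h * float(_lognormal_noise(rng, noise_cv, ()))
            for c, j in true_fluxes.items()
        }
        metabolized = sum(bq.values())
        rec = float(np.clip(rng.normal(*recovery), 0.0, 1.0))
        partitions.append(
            LabelPartition(
                replicate=f"r{i + 1}",
                bq_per_class=bq,
                total_uptake=metabolized / uptake_fraction,
                metabolized=metabolized,
                recovery=rec,
            )
        )
    return partitions, SimulationTruth(true_fluxes=dict(true_fluxes))
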