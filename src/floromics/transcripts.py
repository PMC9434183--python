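"""RNA-seq count funnel for stage-resolved expression profiles.

The funnel mirrors a standard developmental RNA-seq workflow: drop genes
with fewer than a minimum total count, normalize to log₂ counts-per-million
with a pseudo-count, keep genes whose expression follows a smooth trend in
floret age (an F-test of a 3-df polynomial basis against the intercept-only
model, Benjamini–Hochberg corrected), call per-contrast differential genes
with Welch t-tests, and cluster the surviving z-scored stage profiles with
k-means.  Empirical-Bayes variance moderation is deliberately not layered
on top of the Welch tests: the funnel's structure, not a particular
moderation scheme, is what this module implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "TrendFit",
    "filter_low_counts",
    "normalize_logcpm",
    "trend_filter",
    "stage_contrasts",
    "kmeans_profiles",
]

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene × sample integer counts with stage annotation.

    ``samples`` must carry columns ``stage``, ``age_days`` and ``replicate``
    indexed like the count columns.  Library sizes are the column sums.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples table lacks annotation for: {sorted(missing)}")
        for col in ("stage", "age_days", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing column {col!r}")
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def ages(self) -> pd.Series:
        return self.samples["age_days"].astype(float)


@dataclass
class TrendFit:
    """Per-gene smooth-trend test results."""

    coefficients: pd.DataFrame  # gene x basis column
    f_statistic: pd.Series
    p: pd.Series
    q: pd.Series  # Benjamini-Hochberg adjusted
    keep: pd.Series  # q <= fdr


def filter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with total count across all samples below ``min_total``.

    A gene with exactly ``min_total`` counts is kept ("fewer than" is
    strict).  The removal is logged.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_total
    logger.info(
        "low-count filter: kept %d of %d genes (min_total=%d)",
        int(keep.sum()),
        len(keep),
        min_total,
    )
    return CountMatrix(counts.counts.loc[keep], counts.samples)


def normalize_logcpm(
    counts: CountMatrix,
    prior: float = 0.5,
    lib_sizes: Sequence[float] | None = None,
) -> pd.DataFrame:
    """log₂ counts-per-million with a pseudo-count.

    ``log2((count + prior_j) / (library_size_j + 2*prior_j) * 1e6)`` where
    ``prior_j = prior * library_size_j / 1e6`` — the pseudo-count is
    ``prior`` counts per million, so jointly rescaling counts and libraries
    leaves the result exactly unchanged; monotone in the count.
    ``lib_sizes`` overrides the column-sum library sizes, e.g. with nominal
    sequencing depths.
    """
    if lib_sizes is None:
        lib = counts.library_sizes.to_numpy(dtype=float)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
        if lib.shape != (counts.counts.shape[1],):
            raise ValueError("lib_sizes must have one entry per sample")
    if (lib <= 0).any():
        bad = counts.counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    prior_j = prior * lib / 1e6
    cpm = (counts.counts.to_numpy() + prior_j) / (lib + 2.0 * prior_j) * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.counts.index, columns=counts.counts.columns)


def _smooth_basis(ages: np.ndarray, df: int = 3) -> np.ndarray:
    """Orthonormal polynomial basis of the ages (df columns, no intercept)."""
    uniq = np.unique(ages)
    if len(uniq) < df + 2:
        raise ValueError(f"need at least df+2={df + 2} distinct ages, got {len(uniq)}")
    # Vandermonde on centred/scaled ages, orthogonalized against the intercept
    z = (ages - ages.mean()) / ages.std()
    v = np.column_stack([z**k for k in range(df + 1)])
    q, _ = np.linalg.qr(v)
    return q[:, 1:]


def trend_filter(
    logcpm: pd.DataFrame,
    ages: Sequence[float],
    df: int = 3,
    fdr: float = 0.05,
) -> TrendFit:
    """Keep genes whose profile fits a smooth df-degree polynomial in age.

    Per gene, least squares on ``[1, basis(age)]`` is compared with the
    intercept-only model by an F-test on (df, n-df-1) degrees of freedom;
    p-values are Benjamini–Hochberg corrected across genes and genes with
    ``q <= fdr`` are flagged for keeping.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.std() == 0:
        raise ValueError("ages are constant; trend is unidentifiable")
    if logcpm.shape[1] != len(ages):
        raise ValueError("ages must match the sample columns")
    basis = _smooth_basis(ages, df=df)
    X = np.column_stack([np.ones(len(ages)), basis])
    y = logcpm.to_numpy(dtype=float).T  # samples x genes
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    df_resid = len(ages) - df - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df) / (rss1 / df_resid)
    # numerically perfect fits -> infinite F; constant genes -> no evidence
    f = np.where(rss1 <= 1e-12 * np.maximum(rss0, 1e-300), np.inf, f)
    f = np.where(rss0 == 0, 0.0, f)
    p = scipy.stats.f.sf(f, df, df_resid)
    q = multipletests(p, method="fdr_bh")[1]
    genes = logcpm.index
    return TrendFit(
        coefficients=pd.DataFrame(beta.T, index=genes),
        f_statistic=pd.Series(f, index=genes),
        p=pd.Series(p, index=genes),
        q=pd.Series(q, index=genes),
        keep=pd.Series(q <= fdr, index=genes),
    )


def stage_contrasts(
    logcpm: pd.DataFrame,
    stages: Sequence,
    contrasts: Sequence[tuple],
    fdr: float = 0.05,
) -> dict[tuple, pd.DataFrame]:
    """Welch t-tests per gene for each requested stage contrast.

    Returns, per contrast ``(a, b)``, a DataFrame with columns ``log_fc``
    (mean(a) − mean(b)), ``t``, ``p``, ``q`` (BH within the contrast) and
    ``significant``.
    """
    stages = pd.Index(stages)
    out: dict[tuple, pd.DataFrame] = {}
    x = logcpm.to_numpy(dtype=float)
    for a, b in contrasts:
        ia, ib = np.asarray(stages == a), np.asarray(stages == b)
        if ia.sum() < 2 or ib.sum() < 2:
            raise ValueError(f"contrast ({a}, {b}) needs >=2 replicates per side")
        t, p = scipy.stats.ttest_ind(x[:, ia], x[:, ib], axis=1, equal_var=False)
        q = multipletests(p, method="fdr_bh")[1]
        out[(a, b)] = pd.DataFrame(
            {
                "log_fc": x[:, ia].mean(axis=1) - x[:, ib].mean(axis=1),
                "t": t,
                "p": p,
                "q": q,
                "significant": q <= fdr,
            },
            index=logcpm.index,
        )
    return out


@dataclass
class ProfileClusters:
    """k-means clustering of z-scored stage profiles."""

    assignment: pd.Series  # gene -> cluster id
    centroids: pd.DataFrame  # cluster x stage
    anthesis_step: pd.Series  # cluster -> centroid change across the anthesis boundary


def kmeans_profiles(
    stage_means: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    anthesis_boundary: tuple | None = None,
    n_init: int = 10,
) -> ProfileClusters:
    """Cluster z-scored stage profiles with k-means.

    ``stage_means`` is genes × stages (column order = developmental order).
    ``anthesis_boundary`` names the (pre, post) stage columns across which
    the per-cluster step is summarised; default is the S12→S13 transition
    when present, else the middle column pair.  The step sign says whether a
    cluster switches up (+) or down (−) at flower opening.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > stage_means.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({stage_means.shape[0]})")
    x = stage_means.to_numpy(dtype=float)
    mu, sd = x.mean(axis=1, keepdims=True), x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0  # constant profiles stay at zero after centering
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
    centroids = pd.DataFrame(km.cluster_centers_, columns=stage_means.columns)
    cols = list(stage_means.columns)
    if anthesis_boundary is None:
        pre, post = ("S12", "S13") if {"S12", "S13"} <= set(cols) else (
            cols[len(cols) // 2 - 1],
            cols[len(cols) // 2],
        )
    else:
        pre, post = anthesis_boundary
    step = centroids[post] - centroids[pre]
    return ProfileClusters(
        assignment=pd.Series(km.labels_, index=stage_means.index, name="cluster"),
        centroids=centroids,
        anthesis_step=step,
    )
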