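"""Stage-resolved profile statistics: normalization, summary matrices, and
pairwise-stage significance with compact letter display.

Abundances are normalized per sample by fresh weight and internal-standard
response.  Heatmap matrices take the log₂ of the per-stage replicate mean
(log of the mean, not mean of logs), optionally z-scored per compound.
Group differences use Welch (unpooled-variance) two-sample t-tests — the
unequal standard errors visible across phases make a pooled test
inappropriate — and are summarised as a compact letter display: groups that
are not significantly different share at least one letter; significantly
different pairs share none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import StageProfileTable
from .stages import stage_phase

__all__ = [
    "StageSummary",
    "normalize",
    "log2_stage_means",
    "relative_to_reference",
    "ttest_from_summary",
    "compact_letters",
    "pairwise_stage_ttests",
]


@dataclass
class StageSummary:
    """Per-compound group summaries with significance letters.

    ``letters`` uses 'a', 'b', ... within each compound; ``bold`` marks
    compounds significant at the stricter level in at least one pairwise
    comparison.
    """

    means: pd.DataFrame  # compound x group
    se: pd.DataFrame
    n: pd.DataFrame
    letters: pd.DataFrame  # compound x group, strings
    bold: pd.Series  # compound -> bool


def normalize(table: StageProfileTable) -> StageProfileTable:
    """Divide every cell by its sample's fresh weight × internal standard."""
    if table.normalized:
        warnings.warn("table is already normalized; normalizing again", stacklevel=2)
    factors = table.fw_mg * table.istd
    values = table.values.div(factors, axis=1)
    return StageProfileTable(
        values, classes=table.classes, fw_mg=table.fw_mg, istd=table.istd, normalized=True
    )


def log2_stage_means(table: StageProfileTable, scale_rows: bool = False) -> pd.DataFrame:
    """Compound × stage matrix of log₂ replicate means.

    Cells whose stage mean is zero or negative become NaN with a warning.
    With ``scale_rows`` each row is centred and scaled to unit variance
    (standard heatmap convention); constant rows are flagged and left NaN.
    """
    means = table.values.T.groupby(level="stage", sort=False).mean().T
    nonpos = means <= 0
    if nonpos.to_numpy().any():
        warnings.warn(
            f"{int(nonpos.to_numpy().sum())} stage means are zero/negative; set to missing",
            stacklevel=2,
        )
    log2 = np.log2(means.where(~nonpos))
    if scale_rows:
        mu = log2.mean(axis=1)
        sd = log2.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"compounds with zero variance left unscaled as missing: {list(log2.index[flat])}",
                stacklevel=2,
            )
        log2 = log2.sub(mu, axis=0).div(sd.where(~flat), axis=0)
    return log2


def relative_to_reference(table: StageProfileTable, reference_stage: str) -> StageProfileTable:
    """Express every replicate value relative to the reference-stage mean.

    Compounds whose reference mean is zero (or entirely missing) are dropped
    with a warning — their ratios are undefined.
    """
    stages = table.values.columns.get_level_values("stage")
    if reference_stage not in set(stages):
        raise KeyError(f"reference stage {reference_stage!r} not present")
    ref_mean = table.values.loc[:, stages == reference_stage].mean(axis=1)
    bad = ref_mean.isna() | (ref_mean == 0)
    if bad.any():
        warnings.warn(
            f"dropping compounds with zero/missing reference mean: {list(table.values.index[bad])}",
            stacklevel=2,
        )
    values = table.values.loc[~bad].div(ref_mean[~bad], axis=0)
    return StageProfileTable(
        values,
        classes=table.classes[~bad],
        fw_mg=table.fw_mg,
        istd=table.istd,
        normalized=table.normalized,
    )


def ttest_from_summary(
    m1: float, se1: float, n1: int, m2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t-test from group summaries (mean, standard error, n).

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    Degenerate zero-variance inputs return p = 1 for equal means and p = 0
    (with a warning) otherwise.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled = se1**2 + se2**2
    if pooled == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        warnings.warn("zero variance with unequal means; p set to 0", stacklevel=2)
        return float("inf"), float(n1 + n2 - 2), 0.0
    t = (m1 - m2) / np.sqrt(pooled)
    df = pooled**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def compact_letters(
    groups: Sequence[tuple[float, float, int]], alpha: float = 0.05
) -> list[str]:
    """Compact letter display from (mean, se, n) summaries.

    Uses the insert-and-absorb algorithm on the pairwise Welch-test
    significance matrix: every non-significant pair shares at least one
    letter and every significant pair shares none.  Letters are consecutive
    starting at 'a'.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    signif = np.zeros((k, k), dtype=bool)
    for i, j in combinations(range(k), 2):
        _, _, p = ttest_from_summary(*groups[i], *groups[j])
        signif[i, j] = signif[j, i] = p < alpha
    return _insert_absorb(signif)


def _insert_absorb(signif: np.ndarray) -> list[str]:
    """Letter columns from a boolean significance matrix (insert–absorb)."""
    k = signif.shape[0]
    columns: list[set[int]] = [set(range(k))]
    for i, j in combinations(range(k), 2):
        if not signif[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            ci, cj = col - {j}, col - {i}
            # keep only maximal new columns (absorb duplicates/subsets)
            for new in (ci, cj):
                if not any(new <= other for other in columns):
                    columns.append(new)
            columns = [c for c in columns if not any(c < other for other in columns)]
    # order letters by first group membership for a stable a, b, c ... layout
    columns.sort(key=lambda c: min(c))
    letters = [""] * k
    for letter_idx, col in enumerate(columns):
        for g in sorted(col):
            letters[g] += chr(ord("a") + letter_idx)
    return letters


def pairwise_stage_ttests(
    table: StageProfileTable,
    grouping: str = "phase",
    alpha: float = 0.05,
    alpha_strict: float = 0.01,
) -> StageSummary:
    """All pairwise Welch tests per compound, with letters and a bold flag.

    ``grouping`` is ``"stage"`` (one group per stage) or ``"phase"``
    (preanthesis / anthesis / postanthesis, pooling stages).  Compounds with
    any group holding fewer than two replicates are skipped with a warning.
    The bold flag records significance at ``alpha_strict`` in at least one
    pairwise comparison.
    """
    if grouping == "stage":
        group_of = {s: s for s in table.stages}
    elif grouping == "phase":
        group_of = {s: stage_phase(s) for s in table.stages}
    else:
        raise ValueError("grouping must be 'stage' or 'phase'")
    stages = table.values.columns.get_level_values("stage")
    sample_groups = pd.Index([group_of[s] for s in stages], name="group")
    group_names = list(dict.fromkeys(sample_groups))

    means, ses, ns, letters_rows, bold = {}, {}, {}, {}, {}
    for compound, row in table.values.iterrows():
        by_group = {
            g: row.to_numpy()[np.asarray(sample_groups == g)] for g in group_names
        }
        by_group = {g: v[~np.isnan(v)] for g, v in by_group.items()}
        if any(len(v) < 2 for v in by_group.values()):
            warnings.warn(
                f"compound {compound!r}: a group has <2 replicates; skipped", stacklevel=2
            )
            continue
        summ = [
            (float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))), len(v))
            for v in by_group.values()
        ]
        means[compound] = [s[0] for s in summ]
        ses[compound] = [s[1] for s in summ]
        ns[compound] = [s[2] for s in summ]
        letters_rows[compound] = compact_letters(summ, alpha=alpha)
        pvals = [
            ttest_from_summary(*summ[i], *summ[j])[2]
            for i, j in combinations(range(len(summ)), 2)
        ]
        bold[compound] = bool(min(pvals) < alpha_strict)

    idx = list(means)
    return StageSummary(
        means=pd.DataFrame.from_dict(means, orient="index", columns=group_names).loc[idx],
        se=pd.DataFrame.from_dict(ses, orient="index", columns=group_names).loc[idx],
        n=pd.DataFrame.from_dict(ns, orient="index", columns=group_names).loc[idx],
        letters=pd.DataFrame.from_dict(letters_rows, orient="index", columns=group_names).loc[idx],
        bold=pd.Series(bold).loc[idx] if idx else pd.Series(dtype=bool),
    )
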