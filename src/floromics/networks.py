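"""All-pairs Pearson correlation, threshold edge selection, and network
statistics.

Correlations are computed over pairwise-complete observations; two-sided
p-values come from the exact t transform ``t = r * sqrt(n-2) / sqrt(1-r²)``
on ``n-2`` degrees of freedom.  Edges enter a network when the raw p-value
passes the significance cutoff and |r| strictly exceeds the threshold (ties
at the threshold are excluded); no multiple-testing correction is applied by
default, matching the raw-P convention of threshold correlation networks,
with an optional Benjamini–Hochberg mode.  Node importance is summarised by
degree and unnormalized shortest-path betweenness centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "CorrelationNetwork",
    "pairwise_pearson",
    "count_summary",
    "build_network",
    "transcript_metabolite_network",
]


@dataclass
class CorrelationResult:
    """Symmetric correlation matrices with significance and pair counts."""

    r: pd.DataFrame  # variables x variables, diagonal 1
    p: pd.DataFrame
    n_used: pd.DataFrame  # pairwise-complete sample counts

    @property
    def variables(self) -> list:
        return list(self.r.index)


@dataclass
class CorrelationNetwork:
    """Thresholded correlation network.

    ``graph`` is an undirected networkx graph whose nodes carry ``class``
    (or ``kind``), ``degree`` and ``betweenness`` attributes and whose edges
    carry ``r``, ``p`` and ``sign``.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": n, **d} for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"])


def pairwise_pearson(matrix: pd.DataFrame, min_pairs: int = 3) -> CorrelationResult:
    """All-pairs Pearson r with p-values, variables in rows.

    Parameters
    ----------
    matrix
        variables × samples; NaN allowed (pairwise-complete observations).
    min_pairs
        Pairs observed together in fewer samples than this get NaN r and p.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3 for a defined p-value")
    x = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    n_used = obs.astype(int) @ obs.astype(int).T

    zero_var = np.nanstd(x, axis=1) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance variables (r undefined): {list(matrix.index[zero_var])}",
            stacklevel=2,
        )

    # pairwise-complete Pearson; the transpose puts variables in columns
    r = pd.DataFrame(x.T, columns=matrix.index).corr(min_periods=min_pairs).to_numpy()
    np.fill_diagonal(r, 1.0)
    r[n_used < min_pairs] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        df = n_used - 2
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = 2.0 * scipy.stats.t.sf(np.abs(t), np.maximum(df, 1))
        p[np.isinf(t)] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)

    idx = matrix.index
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_used=pd.DataFrame(n_used, index=idx, columns=idx),
    )


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def count_summary(
    result: CorrelationResult,
    p_max: float = 0.05,
    r_hi: float = 0.65,
    r_lo: float = -0.65,
) -> dict[str, int]:
    """Counts of possible / significant / strong correlations.

    Returns ``n_possible`` (pairs with a defined correlation),
    ``n_significant`` (p <= p_max), and among the significant pairs the
    strong positive (r > r_hi) and strong negative (r < r_lo) counts.
    """
    if not 0 < p_max <= 1 or not -1 <= r_lo <= r_hi <= 1:
        raise ValueError("invalid thresholds")
    r, p = _upper(result.r.to_numpy()), _upper(result.p.to_numpy())
    defined = ~np.isnan(r)
    sig = defined & (p <= p_max)
    return {
        "n_possible": int(defined.sum()),
        "n_significant": int(sig.sum()),
        "n_strong_pos": int((sig & (r > r_hi)).sum()),
        "n_strong_neg": int((sig & (r < r_lo)).sum()),
    }


def build_network(
    result: CorrelationResult,
    r_min: float = 0.65,
    p_max: float = 0.05,
    sign: str = "positive",
    node_class: Mapping | None = None,
    bh_correct: bool = False,
) -> CorrelationNetwork:
    """Threshold a correlation result into a network.

    An edge is kept iff its p-value passes ``p_max`` (after optional BH
    correction across all pairs) and r strictly exceeds ``r_min`` (positive
    sign), is strictly below ``-r_min`` (negative), or either (both).
    Isolated nodes are dropped; degree and unnormalized shortest-path
    betweenness are attached to the surviving nodes.
    """
    if sign not in ("positive", "negative", "both"):
        raise ValueError("sign must be 'positive', 'negative' or 'both'")
    if not 0.0 <= r_min <= 1.0:
        raise ValueError("r_min must lie in [0, 1]")
    variables = result.variables
    rmat, pmat = result.r.to_numpy(), result.p.to_numpy()
    iu = np.triu_indices(len(variables), k=1)
    pvals = pmat[iu]
    if bh_correct:
        ok = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        pvals = adj

    g = nx.Graph()
    for (i, j), pv in zip(zip(*iu), pvals):
        rv = rmat[i, j]
        if np.isnan(rv) or np.isnan(pv) or pv > p_max:
            continue
        keep_pos = sign in ("positive", "both") and rv > r_min
        keep_neg = sign in ("negative", "both") and rv < -r_min
        if keep_pos or keep_neg:
            g.add_edge(
                variables[i],
                variables[j],
                r=float(rv),
                p=float(pv),
                sign=1 if rv > 0 else -1,
            )

    betw = nx.betweenness_centrality(g, normalized=False)
    for node in g.nodes:
        g.nodes[node]["class"] = str(node_class.get(node, "other")) if node_class else "other"
        g.nodes[node]["degree"] = int(g.degree(node))
        g.nodes[node]["betweenness"] = float(betw[node])
    return CorrelationNetwork(g)


def transcript_metabolite_network(
    transcripts: pd.DataFrame,
    metabolites: pd.DataFrame,
    sample_phase: pd.Series,
    phase_filter: str,
    r_min: float = 0.80,
    p_max: float = 0.05,
    min_samples: int = 3,
) -> CorrelationNetwork:
    """Joint transcript/metabolite correlation network within one phase.

    Both matrices are variables × samples and must share sample labels.
    Samples whose phase matches ``phase_filter`` are selected; correlations
    are computed over the combined variable set (gene–gene, gene–compound,
    compound–compound pairs alike) on that subset, and the positive edges
    above ``r_min`` are kept.  Node attribute ``kind`` records gene vs
    metabolite.
    """
    shared = transcripts.columns.intersection(metabolites.columns)
    if len(shared) == 0:
        raise ValueError("transcripts and metabolites share no samples")
    keep = [s for s in shared if sample_phase.get(s) == phase_filter]
    if len(keep) < min_samples:
        raise ValueError(
            f"phase {phase_filter!r} has only {len(keep)} samples (< {min_samples})"
        )
    overlap = transcripts.index.intersection(metabolites.index)
    if len(overlap):
        raise ValueError(f"variable ids appear in both matrices: {list(overlap)[:5]}")
    combined = pd.concat([transcripts[keep], metabolites[keep]])
    result = pairwise_pearson(combined, min_pairs=min_samples)
    kinds = {v: "gene" for v in transcripts.index}
    kinds.update({v: "metabolite" for v in metabolites.index})
    network = build_network(result, r_min=r_min, p_max=p_max, sign="positive")
    for node in network.graph.nodes:
        network.graph.nodes[node]["kind"] = kinds[node]
    return network
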