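"""Centrality indices, significance filtering, and descriptive statistics.

In-strength of a node is the sum of the absolute incoming temporal edge
weights, out-strength the sum of the absolute outgoing ones (self-loops
excluded by default), and strength the sum of the absolute contemporaneous
partial correlations involving the node. Centralities are computed on the
full estimated matrices by default; a filtered variant (non-significant edges
zeroed first) is available.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .mlvar import ContemporaneousNetwork, TemporalNetwork
from .synthetic import ITEM_COLUMNS

__all__ = [
    "edge_significance_filter",
    "temporal_centrality",
    "contemporaneous_strength",
    "centrality_table",
    "descriptives",
]


def edge_significance_filter(network, alpha: float = 0.05, bonferroni: bool = False):
    """Display copy of a network with edges at p >= alpha zeroed.

    The estimation copy is untouched. Strict inequality: an edge at exactly
    p = alpha is dropped. With ``bonferroni=True`` alpha is divided by the
    number of off-diagonal tests first.
    """
    k = len(network.node_names)
    if bonferroni:
        alpha = alpha / (k * (k - 1))
    if isinstance(network, TemporalNetwork):
        keep = network.p < alpha
        return replace(network, beta=np.where(keep, network.beta, 0.0),
                       meta={**network.meta, "filtered_alpha": alpha})
    if isinstance(network, ContemporaneousNetwork):
        keep = network.p < alpha
        np.fill_diagonal(keep, True)
        return replace(network, pcor=np.where(keep, network.pcor, 0.0),
                       meta={**network.meta, "filtered_alpha": alpha})
    raise TypeError(f"unsupported network type {type(network).__name__}")


def temporal_centrality(tn: TemporalNetwork,
                        include_self_loops: bool = False) -> pd.DataFrame:
    """In-strength and out-strength per node from the directed beta matrix.

    IS(j) = sum_k |beta[k, j]|, OS(j) = sum_k |beta[j, k]|, excluding the
    autoregressive self-loop unless requested.
    """
    absb = np.abs(tn.beta).astype(float)
    if not include_self_loops:
        absb = absb.copy()
        np.fill_diagonal(absb, 0.0)
    return pd.DataFrame(
        {"node": tn.node_names,
         "in_strength": absb.sum(axis=0),
         "out_strength": absb.sum(axis=1)}
    ).set_index("node")


def contemporaneous_strength(cn: ContemporaneousNetwork) -> pd.Series:
    """Strength per node: sum of absolute off-diagonal partial correlations."""
    absp = np.abs(cn.pcor).astype(float).copy()
    np.fill_diagonal(absp, 0.0)
    return pd.Series(absp.sum(axis=1), index=cn.node_names, name="strength")


def centrality_table(tn: TemporalNetwork, cn: ContemporaneousNetwork,
                     include_self_loops: bool = False,
                     on_filtered: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Combined IS/OS/S table (one row per node).

    With ``on_filtered=True`` the indices are computed after zeroing
    non-significant edges at ``alpha``.
    """
    if on_filtered:
        tn = edge_significance_filter(tn, alpha)
        cn = edge_significance_filter(cn, alpha)
    tab = temporal_centrality(tn, include_self_loops=include_self_loops)
    tab["strength"] = contemporaneous_strength(cn)
    return tab


def descriptives(ds: pd.DataFrame, redundancy_r: float = 0.80
                 ) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str, float]]]:
    """Pooled per-item summary statistics and the zero-order correlation screen.

    Statistics (mean, SD, 25/50/75th percentiles; linear-interpolation
    percentile rule) pool all answered prompts of the included persons. Item
    pairs whose absolute Pearson correlation reaches ``redundancy_r`` are
    flagged as potentially redundant nodes.

    Returns (summary table, correlation matrix, redundant pairs).
    """
    answered = ds[ITEM_COLUMNS].dropna()
    summary = pd.DataFrame(
        {
            "mean": answered.mean(),
            "sd": answered.std(ddof=1),
            "p25": answered.quantile(0.25),
            "p50": answered.quantile(0.50),
            "p75": answered.quantile(0.75),
        }
    )
    corr = answered.corr(method="pearson")
    flagged = []
    for i, a in enumerate(ITEM_COLUMNS):
        for b in ITEM_COLUMNS[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= redundancy_r:
                flagged.append((a, b, r))
    return summary, corr, flagged
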