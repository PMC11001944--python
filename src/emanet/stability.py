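"""Case-drop bootstrap for centrality rank stability.

Repeatedly drops a fraction of the participants at random, refits the whole
two-step multilevel VAR on the remainder, recomputes the centrality indices,
and records how often each node ranks strictly first per index. Exact ties
credit no node, so the per-index frequencies sum to at most 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mlvar import FitConfig, MultilevelVAR, _cfg_kwargs
from .networks import centrality_table
from .preprocess import LAG_PREFIX, build_lagged_table
from .synthetic import ITEM_COLUMNS

__all__ = ["StabilityResult", "case_drop_bootstrap", "rank_first_frequencies"]

INDICES = ["in_strength", "out_strength", "strength"]


@dataclass
class StabilityResult:
    n_reps: int
    n_failed: int
    drop_fraction: float
    frequencies: pd.DataFrame  # index: centrality index, columns: nodes
    archive: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.frequencies.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("rank-first frequencies must be in [0, 1]")
        if np.any(vals.sum(axis=1) > 1.0 + 1e-12):
            raise ValueError("per-index frequencies must sum to <= 1")


def rank_first_frequencies(archive: pd.DataFrame) -> pd.DataFrame:
    """Per index and node: fraction of reps in which the node is the strict
    maximum. Reps where the maximum is tied credit no node."""
    if archive.empty:
        raise ValueError("no successful bootstrap replications")
    counts = pd.DataFrame(0.0, index=INDICES, columns=ITEM_COLUMNS)
    n_reps = archive["rep"].nunique()
    for _, rep_tab in archive.groupby("rep"):
        for index_name in INDICES:
            vals = rep_tab.set_index("node")[index_name]
            top = vals.max()
            winners = vals.index[vals == top]
            if len(winners) == 1:
                counts.loc[index_name, winners[0]] += 1
    return counts / n_reps


def case_drop_bootstrap(data: pd.DataFrame, cfg: FitConfig | None = None,
                        n_reps: int = 1000, drop_fraction: float = 0.20,
                        seed: int | None = None, keep_archive: bool = True,
                        include_self_loops: bool = False,
                        max_failure_fraction: float = 0.05) -> StabilityResult:
    """Case-drop bootstrap of the centrality ranking.

    Each replication removes ``round(drop_fraction * N)`` persons sampled
    without replacement, refits the two-step model on the remaining lag rows
    with the inherited fit configuration, and records the centrality table.
    Deterministic given ``seed``. Replications whose fit fails are skipped and
    counted; the run aborts if more than ``max_failure_fraction`` fail.
    """
    cfg = cfg or FitConfig()
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    lagged = data
    if not any(c.startswith(LAG_PREFIX) for c in lagged.columns):
        lagged = build_lagged_table(lagged)
    persons = np.array(sorted(lagged["person_id"].unique()))
    n = persons.size
    if n < 5:
        raise ValueError("case-drop bootstrap requires at least 5 persons")
    n_drop = int(round(drop_fraction * n))

    rng = np.random.default_rng(seed)
    groups = {pid: idx for pid, idx in lagged.groupby("person_id").groups.items()}
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        dropped = set(rng.choice(persons, size=n_drop, replace=False)) if n_drop else set()
        keep_idx = np.concatenate(
            [np.asarray(groups[p]) for p in persons if p not in dropped]
        )
        sub = lagged.loc[keep_idx]
        try:
            est = MultilevelVAR(**_cfg_kwargs(cfg)).fit(sub)
            tab = centrality_table(est.temporal_, est.contemporaneous_,
                                   include_self_loops=include_self_loops)
        except Exception:
            n_failed += 1
            if n_failed > max_failure_fraction * n_reps:
                raise RuntimeError(
                    f"case-drop bootstrap aborted: {n_failed} of {rep + 1} "
                    f"replications failed (> {max_failure_fraction:.0%} allowed)"
                )
            continue
        tab = tab.reset_index()
        tab.insert(0, "rep", rep)
        rows.append(tab)

    archive = pd.concat(rows, ignore_index=True)
    freqs = rank_first_frequencies(archive)
    return StabilityResult(
        n_reps=n_reps,
        n_failed=n_failed,
        drop_fraction=drop_fraction,
        frequencies=freqs,
        archive=archive if keep_archive else None,
        meta={"n_persons": int(n), "n_dropped_per_rep": n_drop, "seed": seed},
    )
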