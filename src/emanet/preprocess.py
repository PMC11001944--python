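"""Data-quality filtering, detrending, and lag-1 table construction.

The filters mirror common EMA practice: participants need at least
``min_count`` completed prompts (70% of the 105 scheduled, i.e. 73), prompts
completed implausibly fast relative to the participant's own median are
dropped via the relative speed index (RSI), and externally flagged
participants (careless responding, failed verification item) are excluded.
Each person-item series is then detrended — significant linear day trends and
occasion-of-day effects are regressed out per series — before lag-1 pairs are
formed within person-days.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import ITEM_COLUMNS

__all__ = [
    "compute_compliance",
    "compute_rsi",
    "apply_inclusion_filters",
    "Detrender",
    "detrend",
    "build_lagged_table",
]

LAG_PREFIX = "lag_"


def _answered_mask(ds: pd.DataFrame) -> pd.Series:
    return ds[ITEM_COLUMNS].notna().all(axis=1)


def compute_compliance(ds: pd.DataFrame) -> pd.Series:
    """Per-person fraction of scheduled prompts answered, in [0, 1]."""
    if ds.empty:
        raise ValueError("dataset has no scheduled rows")
    answered = _answered_mask(ds)
    counts = ds.assign(_answered=answered).groupby("person_id")["_answered"]
    return counts.mean().rename("compliance")


def compute_rsi(ds: pd.DataFrame, convention: str = "speed") -> pd.DataFrame:
    """Relative speed index per answered prompt.

    ``convention="speed"`` (default): rsi = person_median / duration, so large
    values flag fast (potentially careless) completion. ``"literal"``:
    rsi = duration / person_median. Under either convention prompts with
    rsi <= 2 are retained.
    """
    if convention not in ("speed", "literal"):
        raise ValueError(f"unknown rsi convention {convention!r}")
    has_dur = ds["completion_seconds"].notna()
    q = ds.loc[has_dur, ["person_id", "day", "occasion", "completion_seconds"]].copy()
    bad = q["completion_seconds"] <= 0
    if bad.any():
        row = q[bad].iloc[0]
        raise ValueError(
            f"non-positive completion duration for person {row['person_id']} "
            f"day {int(row['day'])} occasion {int(row['occasion'])}"
        )
    med = q.groupby("person_id")["completion_seconds"].transform("median")
    if convention == "speed":
        q["rsi"] = med / q["completion_seconds"]
    else:
        q["rsi"] = q["completion_seconds"] / med
    q["retained"] = q["rsi"] <= 2.0
    return q.reset_index(drop=True)


def apply_inclusion_filters(
    ds: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    exclusion_flags: dict[str, str] | None = None,
    min_count: int = 73,
    rsi_max: float = 2.0,
    rsi_convention: str = "speed",
) -> tuple[pd.DataFrame, dict]:
    """Apply person- and prompt-level inclusion filters.

    Order: (1) drop persons flagged externally (careless / failed
    verification); (2) turn prompts failing the RSI criterion into missed
    prompts (their completion duration is kept so the person median — and
    hence the filter — is unchanged on reapplication, making the operation
    idempotent); (3) drop persons with fewer than ``min_count`` retained
    completed prompts. Returns the filtered dataset and an audit log counting
    each exclusion reason.
    """
    exclusion_flags = exclusion_flags or {}
    out = ds.copy()
    audit: dict = {
        "persons_input": int(out["person_id"].nunique()),
        "persons_flagged": 0,
        "flag_reasons": {},
        "prompts_rsi_excluded": 0,
        "persons_low_compliance": 0,
    }

    flagged = [p for p in exclusion_flags if p in set(out["person_id"])]
    audit["persons_flagged"] = len(flagged)
    for p in flagged:
        reason = exclusion_flags[p]
        audit["flag_reasons"][reason] = audit["flag_reasons"].get(reason, 0) + 1
    out = out[~out["person_id"].isin(flagged)]

    if quality is None:
        quality = compute_rsi(out, convention=rsi_convention)
    failing = quality.loc[quality["rsi"] > rsi_max, ["person_id", "day", "occasion"]]
    key = ["person_id", "day", "occasion"]
    idx = out.set_index(key).index
    fail_idx = pd.MultiIndex.from_frame(failing)
    to_null = idx.isin(fail_idx) & _answered_mask(out).to_numpy()
    audit["prompts_rsi_excluded"] = int(to_null.sum())
    out.loc[to_null, ITEM_COLUMNS] = np.nan

    answered_counts = _answered_mask(out).groupby(out["person_id"]).sum()
    low = answered_counts[answered_counts < min_count].index
    audit["persons_low_compliance"] = int(len(low))
    out = out[~out["person_id"].isin(low)]

    audit["persons_retained"] = int(out["person_id"].nunique())
    audit["prompts_retained"] = int(_answered_mask(out).sum())
    return out.reset_index(drop=True), audit


def _term_pvalues(y: np.ndarray, day: np.ndarray, occ: np.ndarray):
    """Per-series OLS of score on day (linear) + occasion (categorical).

    Returns (day_slope, day_p, occasion_p, day_component, occ_component) where
    the components are mean-centred fitted contributions of each term from the
    full model. Degenerate cases: a zero-residual exact trend gets p = 0; a
    coefficient that is exactly zero with zero residual variance gets p = 1.
    """
    n = y.size
    if np.ptp(y) == 0.0:  # constant series: nothing to test or remove
        return 0.0, 1.0, 1.0, np.zeros(n), np.zeros(n)
    levels = np.unique(occ)
    dummies = [(occ == lv).astype(float) for lv in levels[1:]]
    X_full = np.column_stack([np.ones(n), day] + dummies)
    q_full = X_full.shape[1]

    beta, _, rank, _ = np.linalg.lstsq(X_full, y, rcond=None)
    fitted = X_full @ beta
    rss_full = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss_full <= 1e-12 * max(tss, 1e-30):
        rss_full = 0.0  # exact (noise-free) fit
    dof = n - rank
    scale = rss_full / dof if dof > 0 else np.nan

    day_centered = day - day.mean()
    day_slope = float(beta[1]) if rank == q_full else 0.0
    if rank < q_full or not np.any(day_centered):
        day_p = 1.0
        day_slope = 0.0
    else:
        xtx_inv = np.linalg.pinv(X_full.T @ X_full)
        se = np.sqrt(max(scale, 0.0) * xtx_inv[1, 1]) if dof > 0 else 0.0
        if se == 0.0:
            day_p = 0.0 if abs(day_slope) > 1e-12 else 1.0
        else:
            t = day_slope / se
            day_p = 2.0 * stats.t.sf(abs(t), dof)

    # occasion block: F test of the full model against day-only
    if len(dummies) == 0 or rank < q_full:
        occ_p = 1.0
    else:
        X_red = np.column_stack([np.ones(n), day])
        beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_red = float(np.sum((y - X_red @ beta_r) ** 2))
        df_num = len(dummies)
        if dof <= 0 or rss_full <= 1e-12 * max(rss_red, 1.0):
            occ_p = 0.0 if rss_red - rss_full > 1e-10 * max(rss_red, 1.0) else 1.0
        else:
            f = ((rss_red - rss_full) / df_num) / (rss_full / dof)
            occ_p = float(stats.f.sf(f, df_num, dof))

    day_comp = day_slope * day_centered
    occ_part = np.zeros(n)
    for j, d in enumerate(dummies):
        occ_part += beta[2 + j] * d
    occ_comp = occ_part - occ_part.mean()
    return day_slope, float(day_p), float(occ_p), day_comp, occ_comp


class Detrender(BaseEstimator, TransformerMixin):
    """Per-person, per-item removal of significant trends.

    For every person-item series, an ordinary least-squares model with a
    linear day term and categorical occasion-of-day effects is fitted; each
    term whose test rejects at ``alpha`` is subtracted out (mean-centred, so
    the person's grand mean is preserved). Non-significant terms leave the
    series unchanged. Series with fewer than ``min_points`` answered prompts
    are passed through with a warning.

    Attributes
    ----------
    report_ : pandas.DataFrame
        One row per (person, item): slope estimate, term p-values, and which
        terms were removed.
    """

    def __init__(self, alpha: float = 0.05, min_points: int = 10):
        self.alpha = alpha
        self.min_points = min_points

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self._fit_transform(X, record_only=True)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self._fit_transform(X, record_only=False)

    def fit_transform(self, X: pd.DataFrame, y=None, **kw) -> pd.DataFrame:
        out = self._fit_transform(X, record_only=False)
        return out

    def _fit_transform(self, ds: pd.DataFrame, record_only: bool) -> pd.DataFrame:
        out = ds.copy()
        answered = _answered_mask(out)
        rows = []
        for pid, sub_idx in out.groupby("person_id").groups.items():
            sub = out.loc[sub_idx]
            mask = answered.loc[sub_idx]
            ans = sub[mask]
            day = ans["day"].to_numpy(dtype=float)
            occ = ans["occasion"].to_numpy()
            for item in ITEM_COLUMNS:
                yv = ans[item].to_numpy(dtype=float)
                if yv.size < self.min_points:
                    warnings.warn(
                        f"person {pid} item {item}: only {yv.size} answered "
                        f"prompts (<{self.min_points}); skipped detrending"
                    )
                    rows.append((pid, item, np.nan, np.nan, np.nan, False, False, True))
                    continue
                slope, day_p, occ_p, day_comp, occ_comp = _term_pvalues(yv, day, occ)
                rm_day = day_p < self.alpha
                rm_occ = occ_p < self.alpha
                if not record_only:
                    adj = np.zeros_like(yv)
                    if rm_day:
                        adj += day_comp
                    if rm_occ:
                        adj += occ_comp
                    if rm_day or rm_occ:
                        out.loc[ans.index, item] = yv - adj
                rows.append((pid, item, slope, day_p, occ_p, rm_day, rm_occ, False))
        self.report_ = pd.DataFrame(
            rows,
            columns=["person_id", "item", "day_slope", "day_p", "occasion_p",
                     "removed_day", "removed_occasion", "skipped"],
        )
        return out


def detrend(ds: pd.DataFrame, alpha: float = 0.05,
            min_points: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`Detrender`; returns (dataset, report)."""
    d = Detrender(alpha=alpha, min_points=min_points)
    out = d.fit_transform(ds)
    return out, d.report_


def build_lagged_table(ds: pd.DataFrame) -> pd.DataFrame:
    """Pair each answered prompt with the immediately preceding answered
    prompt of the same person-day.

    A pair is formed only for adjacent occasions (occasion difference of
    exactly 1) that are both answered: a missed prompt breaks the chain and
    the first prompt of a day never has a lag row. Overnight lags are thereby
    excluded by construction.

    Returns columns person_id, day, occasion (of the outcome), the six current
    scores, and the six lagged scores prefixed ``lag_``.
    """
    ds = ds.sort_values(["person_id", "day", "occasion"], kind="mergesort")
    answered = _answered_mask(ds)
    cur = ds[answered]
    prev = cur.groupby(["person_id", "day"], sort=False).shift(1)
    ok = prev["occasion"].notna() & (cur["occasion"] - prev["occasion"] == 1)
    lagged = cur.loc[ok, ["person_id", "day", "occasion", *ITEM_COLUMNS]].copy()
    for item in ITEM_COLUMNS:
        lagged[LAG_PREFIX + item] = prev.loc[ok, item].to_numpy()
    return lagged.reset_index(drop=True)
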