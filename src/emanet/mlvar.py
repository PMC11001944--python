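"""Two-step multilevel VAR(1) estimation of group-level dynamic networks.

Step 1 (temporal network): for each node k, the score at prompt t is regressed
on the within-person-centered scores of all six nodes at prompt t-1, with the
person means of the lagged predictors as between-person covariates and — under
the mixed random-effects options — a random intercept and random lagged slopes
per person. The fixed lagged coefficients form the directed temporal matrix
beta, whose (j, k) entry is the partial regression effect of node j at t-1 on
node k at t controlling for all other nodes.

Step 2 (contemporaneous network): the step-1 residuals are regressed node-wise
on the other five same-prompt residuals; each unordered pair's two directed
coefficients are combined into a partial correlation by a sign-consistent
geometric mean, giving the undirected contemporaneous network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator

from .preprocess import LAG_PREFIX, build_lagged_table
from .synthetic import ITEM_COLUMNS

__all__ = [
    "FitConfig",
    "TemporalNetwork",
    "ContemporaneousNetwork",
    "MultilevelVAR",
    "fit_temporal",
    "fit_contemporaneous",
    "fit_mlvar",
]

_RE_OPTIONS = ("fixed", "orthogonal", "correlated")
_LADDER = {"correlated": "orthogonal", "orthogonal": "fixed"}


@dataclass
class FitConfig:
    """Estimation options for the two-step procedure.

    random_effects: "fixed" = pooled node-wise least squares (fixed part
    only); "orthogonal" = random intercept plus uncorrelated random lagged
    slopes; "correlated" = full random-effect covariance. Non-converging mixed
    fits are downgraded one rung at a time (correlated -> orthogonal ->
    fixed) and the downgrade is logged.
    """

    random_effects: str = "correlated"
    alpha: float = 0.05
    include_between_covariates: bool = True
    symmetrization: str = "and"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.random_effects not in _RE_OPTIONS:
            raise ValueError(f"random_effects must be one of {_RE_OPTIONS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.symmetrization not in ("and", "or"):
            raise ValueError("symmetrization must be 'and' or 'or'")


@dataclass
class TemporalNetwork:
    """Directed lag-1 network: beta[j, k] = fixed effect of node j at t-1 on
    node k at t, with matching standard errors and Wald p-values."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    node_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.node_names)
        for name in ("beta", "se", "p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            setattr(self, name, arr)
        if np.any(self.se < 0):
            raise ValueError("standard errors must be non-negative")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class ContemporaneousNetwork:
    """Undirected partial-correlation network of same-prompt residuals."""

    pcor: np.ndarray
    p: np.ndarray
    node_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.node_names)
        self.pcor = np.asarray(self.pcor, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.pcor.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError(f"pcor and p must be {k}x{k}")
        if not np.allclose(self.pcor, self.pcor.T, atol=1e-10):
            raise ValueError("pcor must be symmetric")
        if not np.allclose(np.diag(self.pcor), 1.0):
            raise ValueError("pcor diagonal must be 1")
        off = self.pcor[~np.eye(k, dtype=bool)]
        if np.any(np.abs(off) > 1.0 + 1e-12):
            raise ValueError("off-diagonal partial correlations must be in [-1, 1]")


def _design_frame(lagged: pd.DataFrame, node_names: list[str],
                  include_between: bool) -> pd.DataFrame:
    """Within-person-centered lagged predictors plus person-mean covariates."""
    df = pd.DataFrame({"person": lagged["person_id"].to_numpy()})
    g = lagged.groupby("person_id")
    for j, node in enumerate(node_names):
        lag_col = LAG_PREFIX + node
        pm = g[lag_col].transform("mean")
        df[f"c{j}"] = (lagged[lag_col] - pm).to_numpy()
        if include_between:
            df[f"pm{j}"] = pm.to_numpy()
    for j, node in enumerate(node_names):
        df[f"y{j}"] = lagged[node].to_numpy()
    return df


def _fit_one_node(df: pd.DataFrame, k: int, n_nodes: int, cfg: FitConfig,
                  downgrades: list[str]):
    """Fit one node-wise regression; returns (coefs, ses, ps, residuals)."""
    c_cols = [f"c{j}" for j in range(n_nodes)]
    pm_cols = [f"pm{j}" for j in range(n_nodes)] if cfg.include_between_covariates else []
    y = df[f"y{k}"].to_numpy(dtype=float)

    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in c_cols + pm_cols])
    # The between block (intercept + person means) may be internally collinear
    # when there are few persons; that does not affect the within (lagged)
    # coefficients. Singularity only matters if the centered lag columns fail
    # to add a full set of independent directions.
    base = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in pm_cols])
    if np.linalg.matrix_rank(X) < np.linalg.matrix_rank(base) + n_nodes:
        raise ValueError(f"singular design matrix for node index {k}")

    level = cfg.random_effects
    while level != "fixed":
        result = _try_mixed(df, k, c_cols, pm_cols, level)
        if result is not None:
            fe, se, p, resid = result
            return fe, se, p, resid
        downgrades.append(f"node {k}: {level} -> {_LADDER[level]}")
        level = _LADDER[level]

    res = sm.OLS(y, X).fit()
    idx = slice(1, 1 + n_nodes)
    resid = y - res.fittedvalues
    return (np.asarray(res.params[idx]), np.asarray(res.bse[idx]),
            np.asarray(res.pvalues[idx]), resid)


def _try_mixed(df: pd.DataFrame, k: int, c_cols: list[str], pm_cols: list[str],
               level: str):
    rhs = " + ".join(c_cols + pm_cols) or "1"
    formula = f"y{k} ~ {rhs}"
    if level == "correlated":
        re_formula = "1 + " + " + ".join(c_cols)
        vc = None
    else:  # orthogonal
        re_formula = "1"
        vc = {c: f"0 + {c}" for c in c_cols}
    model = smf.mixedlm(formula, df, groups=df["person"],
                        re_formula=re_formula, vc_formula=vc)
    res = _fit_mixed_model(model, lambda r: np.array([r.bse_fe[c] for c in c_cols]))
    if res is None:
        return None
    fe = np.array([res.fe_params[c] for c in c_cols])
    se = np.array([res.bse_fe[c] for c in c_cols])
    p = np.array([res.pvalues[c] for c in c_cols])
    resid = df[f"y{k}"].to_numpy(dtype=float) - np.asarray(res.fittedvalues)
    return fe, se, p, resid


def _fit_mixed_model(model, bse_of_interest):
    """REML fit with an optimizer cascade; None when no optimizer converges
    with finite standard errors for the coefficients of interest."""
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, maxiter=200, method=method)
                ok = res.converged and np.all(np.isfinite(bse_of_interest(res)))
            if ok:
                return res
        except (np.linalg.LinAlgError, ValueError):
            continue
    return None


class MultilevelVAR(BaseEstimator):
    """Two-step multilevel VAR(1) network estimator.

    Parameters mirror :class:`FitConfig`. ``fit`` accepts either a lag-1 table
    (from :func:`emanet.preprocess.build_lagged_table`) or a beep-level
    dataset, in which case the lag table is built first.

    Attributes
    ----------
    temporal_ : TemporalNetwork
        Directed lag-1 fixed-effect network (beta, SEs, p-values).
    contemporaneous_ : ContemporaneousNetwork
        Undirected residual partial-correlation network.
    residuals_ : pandas.DataFrame
        Step-1 residuals per lag row (person_id plus one column per node).
    downgrades_ : list of str
        Random-effects downgrades applied on non-convergence.
    """

    def __init__(self, random_effects: str = "correlated", alpha: float = 0.05,
                 include_between_covariates: bool = True,
                 symmetrization: str = "and", seed: int | None = None):
        self.random_effects = random_effects
        self.alpha = alpha
        self.include_between_covariates = include_between_covariates
        self.symmetrization = symmetrization
        self.seed = seed

    def _config(self) -> FitConfig:
        return FitConfig(
            random_effects=self.random_effects,
            alpha=self.alpha,
            include_between_covariates=self.include_between_covariates,
            symmetrization=self.symmetrization,
            seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y=None):
        cfg = self._config()
        lagged = X
        if not any(c.startswith(LAG_PREFIX) for c in lagged.columns):
            lagged = build_lagged_table(lagged)
        if lagged.empty:
            raise ValueError("no lag-1 rows available")
        if lagged["person_id"].nunique() < 2:
            raise ValueError("at least two persons are required")

        node_names = list(ITEM_COLUMNS)
        n = len(node_names)
        df = _design_frame(lagged, node_names, cfg.include_between_covariates)
        self.downgrades_ = []

        beta = np.zeros((n, n))
        se = np.zeros((n, n))
        p = np.ones((n, n))
        resid = {}
        for k in range(n):
            fe, ses, ps, r = _fit_one_node(df, k, n, cfg, self.downgrades_)
            beta[:, k] = fe
            se[:, k] = ses
            p[:, k] = np.clip(ps, 0.0, 1.0)
            resid[node_names[k]] = r

        meta = {
            "config": {
                "random_effects": cfg.random_effects,
                "alpha": cfg.alpha,
                "include_between_covariates": cfg.include_between_covariates,
                "symmetrization": cfg.symmetrization,
                "seed": cfg.seed,
            },
            "n_persons": int(lagged["person_id"].nunique()),
            "n_lag_rows": int(len(lagged)),
            "downgrades": list(self.downgrades_),
        }
        self.temporal_ = TemporalNetwork(beta=beta, se=se, p=p,
                                         node_names=node_names, meta=dict(meta))
        self.residuals_ = pd.DataFrame(
            {"person_id": lagged["person_id"].to_numpy(), **resid}
        )
        self.contemporaneous_ = _contemporaneous_from_residuals(
            self.residuals_, node_names, cfg, meta
        )
        self.n_persons_ = meta["n_persons"]
        self.n_obs_ = meta["n_lag_rows"]
        return self


def combine_partial_pair(b_jk: float, b_kj: float, label: str = "") -> float:
    """Sign-consistent geometric mean of the two directed coefficients of a
    pair: sign(b) * sqrt(b_jk * b_kj) when the signs agree, 0 otherwise.
    Values outside [-1, 1] (numerical) are clamped with a warning."""
    prod = b_jk * b_kj
    if prod <= 0 or b_jk == 0:
        return 0.0
    val = float(np.sign(b_jk) * np.sqrt(prod))
    if abs(val) > 1.0:
        warnings.warn(f"partial correlation {label} = {val:.3f} clamped to +/-1")
        val = float(np.sign(val))
    return val


def _contemporaneous_from_residuals(residuals: pd.DataFrame,
                                    node_names: list[str], cfg: FitConfig,
                                    meta: dict) -> ContemporaneousNetwork:
    n = len(node_names)
    b = np.zeros((n, n))
    praw = np.ones((n, n))
    use_mixed = cfg.random_effects != "fixed"
    df = residuals.rename(columns={name: f"r{j}" for j, name in enumerate(node_names)})
    for j in range(n):
        others = [f"r{m}" for m in range(n) if m != j]
        if use_mixed:
            coefs, ps = _mixed_residual_fit(df, j, others)
        else:
            coefs, ps = None, None
        if coefs is None:
            y = df[f"r{j}"].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in others])
            res = sm.OLS(y, X).fit()
            coefs = np.asarray(res.params[1:])
            ps = np.asarray(res.pvalues[1:])
        for idx, col in enumerate(others):
            m = int(col[1:])
            b[j, m] = coefs[idx]
            praw[j, m] = min(max(ps[idx], 0.0), 1.0)

    pcor = np.eye(n)
    p = np.zeros((n, n))
    for j in range(n):
        for m in range(j + 1, n):
            val = combine_partial_pair(b[j, m], b[m, j],
                                       label=f"{node_names[j]}-{node_names[m]}")
            pcor[j, m] = pcor[m, j] = val
            if cfg.symmetrization == "and":
                pv = max(praw[j, m], praw[m, j])
            else:
                pv = min(praw[j, m], praw[m, j])
            p[j, m] = p[m, j] = pv
    return ContemporaneousNetwork(pcor=pcor, p=p, node_names=list(node_names),
                                  meta=dict(meta))


def _mixed_residual_fit(df: pd.DataFrame, j: int, others: list[str]):
    """Random-intercept regression of residual j on the other residuals."""
    formula = f"r{j} ~ " + " + ".join(others)
    model = smf.mixedlm(formula, df, groups=df["person_id"])
    res = _fit_mixed_model(model, lambda r: np.array([r.bse_fe[c] for c in others]))
    if res is None:
        return None, None
    coefs = np.array([res.fe_params[c] for c in others])
    ps = np.array([res.pvalues[c] for c in others])
    return coefs, ps


def fit_temporal(lagged: pd.DataFrame,
                 cfg: FitConfig | None = None) -> tuple[TemporalNetwork, pd.DataFrame]:
    """Step 1 only: temporal network plus per-row residual table."""
    cfg = cfg or FitConfig()
    est = MultilevelVAR(**_cfg_kwargs(cfg)).fit(lagged)
    return est.temporal_, est.residuals_


def fit_contemporaneous(residuals: pd.DataFrame,
                        cfg: FitConfig | None = None) -> ContemporaneousNetwork:
    """Step 2 only: contemporaneous network from step-1 residuals."""
    cfg = cfg or FitConfig()
    return _contemporaneous_from_residuals(residuals, list(ITEM_COLUMNS), cfg, {})


def fit_mlvar(data: pd.DataFrame, cfg: FitConfig | None = None
              ) -> tuple[TemporalNetwork, ContemporaneousNetwork]:
    """Full two-step procedure on a beep-level dataset or lag table."""
    cfg = cfg or FitConfig()
    est = MultilevelVAR(**_cfg_kwargs(cfg)).fit(data)
    return est.temporal_, est.contemporaneous_


def _cfg_kwargs(cfg: FitConfig) -> dict:
    return {
        "random_effects": cfg.random_effects,
        "alpha": cfg.alpha,
        "include_between_covariates": cfg.include_between_covariates,
        "symmetrization": cfg.symmetrization,
        "seed": cfg.seed,
    }
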