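"""Synthetic EMA study generator.

Emulates a smartphone experience-sampling study: participants receive five
semi-random prompts per day over three weeks and rate six psychological-process
items (negative/positive affect, negative/positive cognition, rigidity,
variation) on a 0-100 slider. The latent data-generating process is a
person-specific VAR(1) with random effects around a population model, plus
person-level linear day trends and occasion-of-day offsets, so that the
downstream multilevel-VAR estimator can be tested against known ground truth.

The VAR chain is re-initialised from its stationary distribution at the start
of each day: there is no carry-over of dynamics across the night gap, matching
the estimator's convention of never forming lag pairs across days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

__all__ = [
    "NODE_NAMES",
    "PopulationVarModel",
    "PersonVarModel",
    "StudyDesign",
    "default_population_model",
    "draw_population_model",
    "draw_person_models",
    "simulate_schedule",
    "simulate_responses",
    "simulate_study",
]

#: The six analyzed process items, in canonical order.
NODE_NAMES = [
    "neg_affect",
    "pos_affect",
    "neg_cognition",
    "pos_cognition",
    "rigidity",
    "variation",
]

ITEM_COLUMNS = list(NODE_NAMES)

#: Spectral radius the coefficient matrix is rescaled to when it is explosive.
STATIONARITY_TARGET = 0.9

_BASE_DATE = pd.Timestamp("2022-09-14")


def spectral_radius(m: np.ndarray) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(m, dtype=float)))))


def _enforce_stationarity(B: np.ndarray, target: float = STATIONARITY_TARGET) -> np.ndarray:
    """Rescale B to spectral radius `target` if it is >= 1.

    Scaling the whole matrix preserves the sign pattern and relative edge
    strengths while guaranteeing a well-defined stationary process.
    """
    r = spectral_radius(B)
    if r >= 1.0:
        return B * (target / r)
    return B


@dataclass
class StudyDesign:
    """Sampling scheme of the EMA protocol.

    Five prompts per day at 3-hour anchors inside the waking window, each
    jittered by a normal deviate (SD 0.63 h), with a 30-minute minimum gap
    and a 120-minute expiry window.
    """

    n_participants: int = 114
    n_days: int = 21
    prompts_per_day: int = 5
    prompt_spacing_h: float = 3.0
    jitter_sd_h: float = 0.63
    min_gap_min: float = 30.0
    expiry_min: float = 120.0
    waking_start: float = 8.0
    waking_end: float = 23.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1 or self.prompts_per_day < 1:
            raise ValueError("n_participants, n_days and prompts_per_day must be >= 1")
        span = (self.prompts_per_day - 1) * self.prompt_spacing_h
        window = self.waking_end - self.waking_start
        if window < span:
            raise ValueError(
                f"waking window of {window:g} h cannot fit {self.prompts_per_day} "
                f"anchors spaced {self.prompt_spacing_h:g} h apart; at least "
                f"{span:g} h are required"
            )

    @property
    def scheduled_per_person(self) -> int:
        return self.n_days * self.prompts_per_day


@dataclass
class PopulationVarModel:
    """Population-level parameters of the generative VAR(1).

    ``B[j, k]`` is the effect of node j at the previous prompt on node k at the
    current prompt (the ground-truth temporal edge j -> k); ``Sigma`` is the
    innovation covariance whose standardized negative inverse is the
    ground-truth contemporaneous partial-correlation network.
    """

    node_names: list[str] = field(default_factory=lambda: list(NODE_NAMES))
    mu: np.ndarray = field(default_factory=lambda: np.zeros(6))
    B: np.ndarray = field(default_factory=lambda: np.zeros((6, 6)))
    tau_B: np.ndarray = field(default_factory=lambda: np.zeros((6, 6)))
    Sigma: np.ndarray = field(default_factory=lambda: np.eye(6))
    tau_mu: np.ndarray = field(default_factory=lambda: np.zeros(6))
    trend_sd: float = 0.0
    occasion_effects: np.ndarray = field(default_factory=lambda: np.zeros(5))
    # Observation-process parameters (not part of the VAR itself).
    compliance_mean: float = 0.93
    compliance_sd: float = 0.08
    duration_median_s: float = 210.0
    duration_sigma_between: float = 0.25
    duration_sigma_within: float = 0.35
    speeder_fraction: float = 0.0
    speeder_factor: float = 8.0

    def __post_init__(self) -> None:
        k = len(self.node_names)
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.tau_B = np.broadcast_to(np.asarray(self.tau_B, dtype=float), (k, k)).copy()
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.tau_mu = np.broadcast_to(np.asarray(self.tau_mu, dtype=float), (k,)).copy()
        self.occasion_effects = np.asarray(self.occasion_effects, dtype=float)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def validate(self) -> None:
        k = self.n_nodes
        if self.mu.shape != (k,) or self.B.shape != (k, k) or self.Sigma.shape != (k, k):
            raise ValueError("mu/B/Sigma shapes inconsistent with node_names")
        r = spectral_radius(self.B)
        if r >= 1.0:
            raise ValueError(f"B is non-stationary (spectral radius {r:.3f} >= 1)")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        eigmin = float(np.min(np.linalg.eigvalsh(self.Sigma)))
        if eigmin <= 0.0:
            raise ValueError(
                f"Sigma is not positive definite (smallest eigenvalue {eigmin:.6g})"
            )
        if np.any(self.tau_B < 0) or np.any(self.tau_mu < 0) or self.trend_sd < 0:
            raise ValueError("tau_B, tau_mu and trend_sd must be non-negative")
        if not (0.0 < self.compliance_mean <= 1.0):
            raise ValueError("compliance_mean must be in (0, 1]")


@dataclass
class PersonVarModel:
    """Person-level realisation of the population model."""

    person_id: str
    B_i: np.ndarray
    mu_i: np.ndarray
    trend_i: np.ndarray
    compliance_i: float

    def __post_init__(self) -> None:
        if spectral_radius(self.B_i) >= 1.0:
            raise ValueError(f"person {self.person_id}: B_i non-stationary")
        if not (0.0 <= self.compliance_i <= 1.0):
            raise ValueError(f"person {self.person_id}: compliance outside [0, 1]")


def default_population_model() -> PopulationVarModel:
    """Population model calibrated to the reported study.

    Means follow the published per-item descriptives; the temporal matrix makes
    rigidity the strongest out-going node (positively driving negative
    processes, negatively driving positive ones) and the innovation correlation
    groups positive and negative processes with opposite-sign cross links —
    the qualitative structure the group-level networks exhibited.
    """
    mu = np.array([24.50, 72.51, 29.26, 61.50, 28.20, 63.01])
    B = np.array(
        [
            # na     pa     nc     pc     rig    var
            [0.20, -0.04, 0.08, -0.03, 0.06, -0.02],  # neg_affect ->
            [-0.03, 0.18, -0.03, 0.06, -0.04, 0.03],  # pos_affect ->
            [0.08, -0.03, 0.22, -0.04, 0.07, -0.03],  # neg_cognition ->
            [-0.03, 0.06, -0.04, 0.20, -0.05, 0.05],  # pos_cognition ->
            [0.10, -0.07, 0.10, -0.08, 0.25, -0.07],  # rigidity ->
            [-0.02, 0.04, -0.03, 0.05, -0.05, 0.15],  # variation ->
        ]
    )
    # Innovation correlations: same-valence positive, cross-valence negative,
    # rigidity tied more strongly to the negative block.
    R = np.array(
        [
            [1.00, -0.20, 0.25, -0.15, 0.25, -0.10],
            [-0.20, 1.00, -0.15, 0.25, -0.20, 0.20],
            [0.25, -0.15, 1.00, -0.20, 0.28, -0.12],
            [-0.15, 0.25, -0.20, 1.00, -0.22, 0.22],
            [0.25, -0.20, 0.28, -0.22, 1.00, -0.18],
            [-0.10, 0.20, -0.12, 0.22, -0.18, 1.00],
        ]
    )
    sd = np.array([19.0, 16.0, 19.0, 17.0, 20.0, 16.5])
    Sigma = np.outer(sd, sd) * R
    return PopulationVarModel(
        mu=mu,
        B=B,
        tau_B=np.full((6, 6), 0.05),
        Sigma=Sigma,
        tau_mu=np.full(6, 12.0),
        trend_sd=0.15,
        occasion_effects=np.array([-1.0, 0.0, 0.5, 0.5, 0.0]),
        speeder_fraction=0.03,
    )


def draw_population_model(config: dict | PopulationVarModel | None = None,
                          seed: int | None = None) -> PopulationVarModel:
    """Build a validated population model from a config mapping.

    Any field of :class:`PopulationVarModel` may be overridden; a requested B
    with spectral radius >= 1 is rescaled to radius 0.9 rather than rejected,
    preserving its sign pattern. A user-supplied non-positive-definite Sigma is
    rejected with the offending eigenvalue named. Deterministic: the same
    config (and seed) always produces the identical model.
    """
    del seed  # construction is deterministic in the config; kept for API symmetry
    if isinstance(config, PopulationVarModel):
        model = replace(config)
    else:
        base = default_population_model()
        cfg = dict(config or {})
        known = set(base.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown population-model fields: {sorted(unknown)}")
        for key, value in cfg.items():
            setattr(base, key, value)
        base.B = _enforce_stationarity(np.asarray(base.B, dtype=float))
        model = PopulationVarModel(**{f: getattr(base, f) for f in known})
    model.validate()
    return model


def draw_person_models(pop: PopulationVarModel, n: int, seed: int | None = None,
                       rng: np.random.Generator | None = None) -> list[PersonVarModel]:
    """Draw n person-specific models around the population model.

    B_i = B + elementwise N(0, tau_B) deviations, rescaled to spectral radius
    0.9 if explosive; mu_i ~ N(mu, tau_mu); trend_i ~ N(0, trend_sd) per node;
    compliance_i from a Beta with the configured mean/SD, clipped to [0.4, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = pop.n_nodes
    persons = []
    width = max(3, len(str(n)))
    for i in range(n):
        B_i = pop.B + rng.standard_normal((k, k)) * pop.tau_B
        B_i = _enforce_stationarity(B_i)
        mu_i = pop.mu + rng.standard_normal(k) * pop.tau_mu
        trend_i = rng.standard_normal(k) * pop.trend_sd
        compliance_i = _draw_compliance(rng, pop.compliance_mean, pop.compliance_sd)
        persons.append(
            PersonVarModel(
                person_id=f"P{i + 1:0{width}d}",
                B_i=B_i,
                mu_i=mu_i,
                trend_i=trend_i,
                compliance_i=compliance_i,
            )
        )
    return persons


def _draw_compliance(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0 or mean >= 1.0:
        return min(mean, 1.0)
    var = sd * sd
    max_var = mean * (1 - mean)
    if var >= max_var:
        var = 0.95 * max_var
    nu = mean * (1 - mean) / var - 1.0
    a, b = mean * nu, (1 - mean) * nu
    return float(np.clip(rng.beta(a, b), 0.4, 1.0))


def simulate_schedule(design: StudyDesign, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the semi-random prompt schedule.

    Anchors are equally spaced (`prompt_spacing_h`) and centred in the waking
    window; each is jittered with a normal deviate of SD `jitter_sd_h`. A day
    whose jittered times violate the minimum gap, ordering, or the waking
    window is re-jittered wholesale.

    Returns a long table (person_id, day, occasion, scheduled_time).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = design.prompts_per_day
    span = (p - 1) * design.prompt_spacing_h
    margin = (design.waking_end - design.waking_start - span) / 2.0
    anchors = design.waking_start + margin + np.arange(p) * design.prompt_spacing_h
    min_gap_h = design.min_gap_min / 60.0

    width = max(3, len(str(design.n_participants)))
    records: list[tuple[str, int, int, pd.Timestamp]] = []
    for i in range(design.n_participants):
        pid = f"P{i + 1:0{width}d}"
        for day in range(1, design.n_days + 1):
            times = _jitter_day(rng, anchors, design, min_gap_h)
            base = _BASE_DATE + pd.Timedelta(days=day - 1)
            for occ, t in enumerate(times, start=1):
                ts = (base + pd.Timedelta(hours=float(t))).floor("s")
                records.append((pid, day, occ, ts))
    return pd.DataFrame(
        records, columns=["person_id", "day", "occasion", "scheduled_time"]
    )


def _jitter_day(rng: np.random.Generator, anchors: np.ndarray,
                design: StudyDesign, min_gap_h: float,
                max_tries: int = 1000) -> np.ndarray:
    if design.jitter_sd_h == 0:
        return anchors.copy()
    for _ in range(max_tries):
        t = anchors + rng.standard_normal(anchors.size) * design.jitter_sd_h
        if t[0] < design.waking_start or t[-1] > design.waking_end:
            continue
        gaps = np.diff(t)
        if np.all(gaps >= min_gap_h):
            return t
    raise RuntimeError(
        "could not draw a legal prompt schedule; jitter SD too large for the "
        "minimum-gap constraint"
    )


def simulate_responses(persons: list[PersonVarModel], schedule: pd.DataFrame,
                       pop: PopulationVarModel, seed: int | None = None,
                       clip: bool = False,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate item responses for every scheduled prompt.

    The latent score vector at prompt t of a day is
    ``y_t = mu_i + trend_i * day + occasion_effect + x_t`` where the VAR part
    follows ``x_t = B_i' x_{t-1} + eps_t``, ``eps_t ~ N(0, Sigma)``, and x is
    drawn fresh from the stationary distribution at the first prompt of each
    day. Each prompt is answered with probability ``compliance_i``; answered
    prompts receive a log-normal completion duration (with optional "speeder"
    contamination) and a response timestamp within the expiry window.

    With clip=True scores are truncated to the 0-100 response scale; the
    default leaves the latent scale untouched so linear-model recovery tests
    are unbiased.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    by_person = {p.person_id: p for p in persons}
    missing = set(schedule["person_id"].unique()) - set(by_person)
    if missing:
        raise ValueError(f"schedule contains persons without models: {sorted(missing)}")

    chol_sigma = np.linalg.cholesky(pop.Sigma)
    k = pop.n_nodes
    occ_fx = pop.occasion_effects

    out_rows = []
    schedule = schedule.sort_values(["person_id", "day", "occasion"], kind="mergesort")
    for pid, sub in schedule.groupby("person_id", sort=True):
        person = by_person[pid]
        A = person.B_i.T  # transition matrix acting on column vectors
        V = solve_discrete_lyapunov(A, pop.Sigma)
        # numerical symmetrization before Cholesky
        chol_v = np.linalg.cholesky((V + V.T) / 2.0)
        log_dur_mu = math.log(pop.duration_median_s) + (
            rng.standard_normal() * pop.duration_sigma_between
        )
        for day, day_rows in sub.groupby("day", sort=True):
            x = chol_v @ rng.standard_normal(k)
            first = True
            for row in day_rows.itertuples(index=False):
                if not first:
                    x = A @ x + chol_sigma @ rng.standard_normal(k)
                first = False
                y = (
                    person.mu_i
                    + person.trend_i * day
                    + occ_fx[row.occasion - 1]
                    + x
                )
                if clip:
                    y = np.clip(y, 0.0, 100.0)
                answered = rng.random() < person.compliance_i
                if answered:
                    dur = math.exp(log_dur_mu + rng.standard_normal() * pop.duration_sigma_within)
                    if pop.speeder_fraction > 0 and rng.random() < pop.speeder_fraction:
                        dur /= pop.speeder_factor
                    dur = round(dur, 1)
                    delay_min = min(float(rng.exponential(15.0)), 119.0)
                    resp = (row.scheduled_time + pd.Timedelta(minutes=delay_min)).floor("s")
                    scores = np.round(y, 4)
                else:
                    dur, resp, scores = np.nan, pd.NaT, np.full(k, np.nan)
                out_rows.append(
                    (pid, day, row.occasion, row.scheduled_time, resp, dur, *scores)
                )
    cols = ["person_id", "day", "occasion", "scheduled_time", "response_time",
            "completion_seconds", *pop.node_names]
    ds = pd.DataFrame(out_rows, columns=cols)
    if clip:
        vals = ds[pop.node_names].to_numpy()
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=100.0) > 100:
            warnings.warn("clipping failed to bound scores")  # pragma: no cover
    return ds


def simulate_study(design: StudyDesign | None = None,
                   pop: PopulationVarModel | None = None,
                   seed: int = 0, clip: bool = False) -> pd.DataFrame:
    """Convenience wrapper: persons + schedule + responses with one root seed.

    The root seed is split into independent streams per stage (persons,
    schedule, responses) via `numpy.random.SeedSequence.spawn`, so each stage
    is independently reproducible.
    """
    design = design or StudyDesign()
    pop = pop or default_population_model()
    ss = np.random.SeedSequence(seed).spawn(3)
    persons = draw_person_models(pop, design.n_participants,
                                 rng=np.random.default_rng(ss[0]))
    schedule = simulate_schedule(design, rng=np.random.default_rng(ss[1]))
    return simulate_responses(persons, schedule, pop, clip=clip,
                              rng=np.random.default_rng(ss[2]))
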