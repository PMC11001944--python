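"""End-to-end pipeline: raw beep-level CSV -> filtered data -> detrended
series -> lag-1 table -> temporal & contemporaneous networks -> centralities
-> case-drop bootstrap -> report bundle with a provenance-stamped manifest.

All randomness flows from a single root seed, split into independent
per-stage streams with ``numpy.random.SeedSequence(root).spawn`` in stage
order (simulate, bootstrap), so each stage is independently reproducible.
Every output carries the SHA-256 hash of the canonical JSON form of the
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ema_io
from .mlvar import ContemporaneousNetwork, FitConfig, MultilevelVAR, TemporalNetwork, _cfg_kwargs
from .networks import centrality_table, descriptives, edge_significance_filter
from .preprocess import apply_inclusion_filters, build_lagged_table, detrend
from .stability import case_drop_bootstrap
from .synthetic import (PopulationVarModel, StudyDesign, default_population_model,
                        draw_person_models, draw_population_model,
                        simulate_responses, simulate_schedule)

__all__ = ["PipelineConfig", "run_pipeline", "export_networks", "config_hash",
           "simulate_from_config"]

EXPORT_FORMATS = ("edgelist", "matrix", "graphml")


@dataclass
class PipelineConfig:
    """Serializable configuration of a full analysis run."""

    input: str | None = None            # beep-level CSV; None => simulate
    output_dir: str = "emanet_out"
    simulate: dict = field(default_factory=dict)   # StudyDesign / model overrides
    exclusion_flags: dict = field(default_factory=dict)
    min_count: int = 73
    rsi_max: float = 2.0
    rsi_convention: str = "speed"
    detrend_alpha: float = 0.05
    fit: dict = field(default_factory=dict)        # FitConfig overrides
    alpha: float = 0.05                            # edge display threshold
    n_reps: int = 1000
    drop_fraction: float = 0.20
    seed: int = 0
    export_graphml: bool = False
    clip: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: PipelineConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, PipelineConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate_from_config(sim_cfg: dict, seed: int, clip: bool = True) -> pd.DataFrame:
    """Generate a synthetic study from config overrides and a stage seed."""
    design_keys = set(StudyDesign.__dataclass_fields__)
    design = StudyDesign(**{k: v for k, v in sim_cfg.items() if k in design_keys})
    pop_cfg = {k: v for k, v in sim_cfg.items() if k not in design_keys}
    pop = draw_population_model(pop_cfg or None)
    ss = np.random.SeedSequence(seed).spawn(3)
    persons = draw_person_models(pop, design.n_participants,
                                 rng=np.random.default_rng(ss[0]))
    schedule = simulate_schedule(design, rng=np.random.default_rng(ss[1]))
    return simulate_responses(persons, schedule, pop, clip=clip,
                              rng=np.random.default_rng(ss[2]))


def _matrix_csv(mat: np.ndarray, names: list[str], path: Path) -> None:
    pd.DataFrame(mat, index=names, columns=names).to_csv(path, float_format="%.10g")


def export_networks(tn: TemporalNetwork, cn: ContemporaneousNetwork,
                    out_dir: str | Path, formats=("edgelist", "matrix"),
                    alpha: float = 0.05) -> list[Path]:
    """Write network outputs; returns the list of files written.

    ``edgelist``: one CSV with columns from,to,type,weight,se,p,significant.
    ``matrix``: one CSV per network. ``graphml``: directed graph for the
    temporal network, undirected for the contemporaneous one, with edge sign
    stored as an attribute.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - set(EXPORT_FORMATS)
    if unknown:
        raise ValueError(
            f"unknown export format(s) {sorted(unknown)}; supported: {EXPORT_FORMATS}"
        )
    written: list[Path] = []
    names = tn.node_names
    if "edgelist" in formats:
        rows = []
        for j, a in enumerate(names):
            for k, b in enumerate(names):
                rows.append((a, b, "temporal", tn.beta[j, k], tn.se[j, k],
                             tn.p[j, k], tn.p[j, k] < alpha))
        for j, a in enumerate(names):
            for k in range(j + 1, len(names)):
                rows.append((a, names[k], "contemporaneous", cn.pcor[j, k],
                             np.nan, cn.p[j, k], cn.p[j, k] < alpha))
        path = out_dir / "edges.csv"
        pd.DataFrame(rows, columns=["from", "to", "type", "weight", "se", "p",
                                    "significant"]).to_csv(path, index=False,
                                                           float_format="%.10g")
        written.append(path)
    if "matrix" in formats:
        p1 = out_dir / "temporal_matrix.csv"
        p2 = out_dir / "contemporaneous_matrix.csv"
        _matrix_csv(tn.beta, names, p1)
        _matrix_csv(cn.pcor, names, p2)
        written += [p1, p2]
    if "graphml" in formats:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(names)
        for j, a in enumerate(names):
            for k, b in enumerate(names):
                w = float(tn.beta[j, k])
                if w != 0.0:
                    g.add_edge(a, b, weight=w, p=float(tn.p[j, k]),
                               sign="positive" if w > 0 else "negative")
        u = nx.Graph()
        u.add_nodes_from(names)
        for j, a in enumerate(names):
            for k in range(j + 1, len(names)):
                w = float(cn.pcor[j, k])
                if w != 0.0:
                    u.add_edge(a, names[k], weight=w, p=float(cn.p[j, k]),
                               sign="positive" if w > 0 else "negative")
        p1 = out_dir / "temporal.graphml"
        p2 = out_dir / "contemporaneous.graphml"
        nx.write_graphml(g, p1)
        nx.write_graphml(u, p2)
        written += [p1, p2]
    return written


def read_edgelist_matrix(path: str | Path, kind: str,
                         node_names: list[str]) -> np.ndarray:
    """Rebuild a weight matrix from an exported edge list (round-trip check)."""
    edges = pd.read_csv(path)
    n = len(node_names)
    idx = {name: i for i, name in enumerate(node_names)}
    mat = np.zeros((n, n)) if kind == "temporal" else np.eye(n)
    sub = edges[edges["type"] == kind]
    for a, b, w in zip(sub["from"], sub["to"], sub["weight"]):
        j, k = idx[a], idx[b]
        mat[j, k] = w
        if kind == "contemporaneous":
            mat[k, j] = w
    return mat


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    Stages: load-or-simulate, inclusion filters, descriptives (on filtered,
    un-detrended data), detrending, lag-table, two-step network fit,
    centrality, optional bootstrap (skipped when n_reps = 0), exports.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest: dict = {"config": config.to_dict(), "config_hash": chash,
                      "stages": {}, "outputs": {}}
    seeds = np.random.SeedSequence(config.seed).spawn(2)

    if config.input:
        ds = ema_io.read_dataset(config.input)
        manifest["stages"]["input"] = {"path": str(config.input), "rows": len(ds)}
    else:
        ds = simulate_from_config(config.simulate, seed=_seed_int(seeds[0]),
                                  clip=config.clip)
        sim_path = out_dir / "simulated_dataset.csv"
        ema_io.write_dataset(ds, sim_path)
        manifest["stages"]["simulate"] = {"rows": len(ds), "path": str(sim_path)}
        manifest["outputs"]["simulated_dataset"] = str(sim_path)

    filtered, audit = apply_inclusion_filters(
        ds, exclusion_flags=config.exclusion_flags, min_count=config.min_count,
        rsi_max=config.rsi_max, rsi_convention=config.rsi_convention,
    )
    (out_dir / "audit.json").write_text(json.dumps(audit, indent=2))
    manifest["stages"]["filters"] = audit
    manifest["outputs"]["audit"] = str(out_dir / "audit.json")

    summary, corr, flagged = descriptives(filtered)
    summary.to_csv(out_dir / "descriptives.csv", float_format="%.10g")
    corr.to_csv(out_dir / "correlations.csv", float_format="%.10g")
    manifest["stages"]["descriptives"] = {"redundant_pairs": [
        [a, b, float(r)] for a, b, r in flagged]}
    manifest["outputs"]["descriptives"] = str(out_dir / "descriptives.csv")
    manifest["outputs"]["correlations"] = str(out_dir / "correlations.csv")

    detrended, report = detrend(filtered, alpha=config.detrend_alpha)
    report.to_csv(out_dir / "detrend_report.csv", index=False, float_format="%.10g")
    manifest["stages"]["detrend"] = {
        "removed_day_terms": int(report["removed_day"].sum()),
        "removed_occasion_terms": int(report["removed_occasion"].sum()),
        "skipped_series": int(report["skipped"].sum()),
    }
    manifest["outputs"]["detrend_report"] = str(out_dir / "detrend_report.csv")

    lagged = build_lagged_table(detrended)
    fit_cfg = FitConfig(**config.fit)
    est = MultilevelVAR(**_cfg_kwargs(fit_cfg)).fit(lagged)
    tn, cn = est.temporal_, est.contemporaneous_
    formats = ["edgelist", "matrix"] + (["graphml"] if config.export_graphml else [])
    files = export_networks(tn, cn, out_dir, formats=formats, alpha=config.alpha)
    manifest["stages"]["fit"] = dict(tn.meta)
    manifest["outputs"]["networks"] = [str(f) for f in files]

    cents = centrality_table(tn, cn)
    cents.to_csv(out_dir / "centrality.csv", float_format="%.10g")
    manifest["outputs"]["centrality"] = str(out_dir / "centrality.csv")

    if config.n_reps > 0:
        stab = case_drop_bootstrap(
            lagged, fit_cfg, n_reps=config.n_reps,
            drop_fraction=config.drop_fraction, seed=_seed_int(seeds[1]),
            keep_archive=False,
        )
        stab_rows = [
            {"index": idx, "node": node,
             "rank_first_freq": float(stab.frequencies.loc[idx, node]),
             "n_reps": stab.n_reps, "n_failed": stab.n_failed}
            for idx in stab.frequencies.index for node in stab.frequencies.columns
        ]
        pd.DataFrame(stab_rows).to_csv(out_dir / "stability.csv", index=False)
        manifest["stages"]["bootstrap"] = {
            "n_reps": stab.n_reps, "n_failed": stab.n_failed,
            "drop_fraction": stab.drop_fraction, **stab.meta,
        }
        manifest["outputs"]["stability"] = str(out_dir / "stability.csv")
    else:
        manifest["stages"]["bootstrap"] = {"skipped": True}

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))
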