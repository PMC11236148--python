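"""End-to-end orchestration: load tables, run every stage, write per-stage
TSVs plus one machine-readable results JSON.

The run is deterministic given the config: every stochastic stage receives
an explicit seed derived from the config's master seed, and the results
JSON contains no timestamps, so identical configs produce byte-identical
reports. Every number in the JSON is read back from (or written alongside)
a stage output file; nothing is computed only for the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import drivers as drivers_mod
from . import ncm as ncm_mod
from . import network as network_mod
from . import keystone as keystone_mod
from .tables import (
    AbundanceTable,
    EnvTable,
    TaxonomyTable,
    ValidationError,
    read_abundance,
    read_env,
    read_metadata,
    read_taxonomy,
)

logger = logging.getLogger(__name__)

STAGES = ("tables", "alpha", "beta", "network", "keystone", "drivers", "ncm")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    abundance: str
    metadata: str
    taxonomy: str | None = None
    env: str | None = None
    outdir: str = "results"
    group_by: tuple[str, ...] = ("ecosystem", "season")
    factors: tuple[str, ...] = ("SWC", "pH", "TN", "SOM", "AP", "RAK", "ST")
    network_method: str = "spearman"
    network_min_abs_r: float = 0.6
    network_max_p: float = 0.05
    network_correction: str = "BH"
    n_perm: int = 999
    seed: int | None = 0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict and self.seed is None:
            raise ValidationError("strict mode requires an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"unknown config keys {sorted(unknown)}; expected a subset of {sorted(known)}"
            )
        for key in ("group_by", "factors"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"invalid config: {exc}") from exc


def _group_scopes(ab: AbundanceTable, group_by) -> list[tuple[str, str, pd.Index]]:
    scopes = []
    for col in group_by:
        labels = ab.groups(col)
        for val in sorted(labels.unique()):
            scopes.append((col, str(val), labels[labels == val].index))
    return scopes


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``<outdir>/results.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(config).items()}, "stages": {}}
    seed = config.seed if config.seed is not None else 0

    stage = "tables"
    try:
        t0 = time.perf_counter()
        metadata = read_metadata(config.metadata)
        ab = read_abundance(config.abundance, metadata=metadata)
        tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
        env = read_env(config.env) if config.env else None
        logger.info("stage %s: %d samples x %d species (%.2fs)",
                    stage, len(ab.samples), len(ab.species), time.perf_counter() - t0)
        report["stages"]["tables"] = {
            "n_samples": len(ab.samples),
            "n_species": len(ab.species),
            "has_taxonomy": tax is not None,
            "has_env": env is not None,
        }
    except Exception as exc:
        _abort(report, out, stage, exc)

    stage = "alpha"
    try:
        per_sample = alpha_mod.alpha_table(ab)
        per_sample.to_csv(out / "alpha.tsv", sep="\t")
        alpha_report = {}
        for col in config.group_by:
            gm = alpha_mod.group_alpha(ab, col)
            gm.to_csv(out / f"alpha_{col}.tsv", sep="\t")
            comp = alpha_mod.compare_groups(
                per_sample["H"], ab.groups(col), method="permutation",
                n_perm=config.n_perm, seed=seed + 11,
            )
            alpha_report[col] = {
                "group_means_H": {k: round(v, 6) for k, v in gm["H"].items()},
                "group_means_D": {k: round(v, 6) for k, v in gm["D"].items()},
                "H_omnibus_p": comp["p"],
            }
        cp_rows = []
        if tax is not None:
            cp_rows.append(alpha_mod.cp_quotient(ab, tax))
            for col, val, _ in _group_scopes(ab, config.group_by):
                cp_rows.append(alpha_mod.cp_quotient(ab, tax, scope={col: val}))
            pd.DataFrame(cp_rows).to_csv(out / "cp.tsv", sep="\t", index=False)
            alpha_report["cp"] = {
                r["scope"]: r["quotient"] for r in cp_rows if r["defined"]
            }
        report["stages"]["alpha"] = alpha_report
    except Exception as exc:
        _abort(report, out, stage, exc)

    stage = "beta"
    try:
        d = beta_mod.bray_curtis(ab)
        d.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        ord_ = beta_mod.nmds(d, k=2, restarts=20, seed=seed + 23)
        ord_.coordinates.to_csv(out / "nmds.tsv", sep="\t")
        beta_report = {"nmds_stress": round(ord_.stress, 6), "nmds_converged": ord_.converged}
        for col in config.group_by:
            res = beta_mod.permanova(
                d, ab.groups(col).to_numpy(), n_perm=config.n_perm, seed=seed + 31
            )
            beta_report[f"permanova_{col}"] = {
                "pseudo_F": round(res["pseudo_F"], 6), "p": res["p"],
            }
        report["stages"]["beta"] = beta_report
    except Exception as exc:
        _abort(report, out, stage, exc)

    stage = "network"
    nets: dict[str, network_mod.CooccurrenceNetwork] = {}
    try:
        topo_rows, net_report = [], {}
        for col, val, idx in _group_scopes(ab, config.group_by):
            scope_name = f"{col}:{val}"
            try:
                net = network_mod.build_network(
                    ab.subset(idx),
                    method=config.network_method,
                    min_abs_r=config.network_min_abs_r,
                    max_p=config.network_max_p,
                    correction=config.network_correction,
                )
                if net.n_edges == 0:
                    logger.warning("network %s: no edges at thresholds", scope_name)
                    continue
                network_mod.detect_modules(net, seed=seed + 41)
                topo = network_mod.topology(net)
                topo["scope"] = scope_name
                topo_rows.append(topo)
                nets[scope_name] = net
                net.edge_list().to_csv(
                    out / f"network_{col}_{val}.edges.tsv", sep="\t", index=False
                )
            except ValidationError as exc:
                logger.warning("network %s skipped: %s", scope_name, exc)
        if topo_rows:
            cols = ["scope", "n_nodes", "n_edges", "average_degree", "modularity",
                    "density", "clustering_coefficient", "mean_path_length",
                    "positive_ratio", "negative_ratio"]
            pd.DataFrame(topo_rows)[cols].to_csv(out / "topology.tsv", sep="\t", index=False)
            for row in topo_rows:
                net_report[row["scope"]] = {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in row.items() if k != "scope"
                }
        report["stages"]["network"] = net_report
    except Exception as exc:
        _abort(report, out, stage, exc)

    stage = "keystone"
    try:
        key_rows = []
        for scope_name, net in nets.items():
            roles = keystone_mod.zi_pi(net)
            for r in keystone_mod.classify_keystones(roles):
                key_rows.append(
                    {"scope": scope_name, "node": r.node, "module": r.module,
                     "Zi": r.zi, "Pi": r.pi, "role": r.role}
                )
        keys_df = pd.DataFrame(
            key_rows, columns=["scope", "node", "module", "Zi", "Pi", "role"]
        )
        keys_df.to_csv(out / "keystones.tsv", sep="\t", index=False)
        report["stages"]["keystone"] = {
            "n_keystones": int(len(keys_df)),
            "by_scope": keys_df.groupby("scope").size().to_dict() if len(keys_df) else {},
        }
    except Exception as exc:
        _abort(report, out, stage, exc)

    stage = "drivers"
    if env is None:
        logger.warning("no environmental table; drivers stage skipped")
        report["stages"]["drivers"] = {"skipped": "no environmental table"}
    else:
        try:
            d = beta_mod.bray_curtis(ab)
            factors = [f for f in config.factors if f in env.factors.columns]
            panel = drivers_mod.mantel_panel(
                d, env, factors, n_perm=config.n_perm, seed=seed + 53
            )
            panel.to_csv(out / "mantel.tsv", sep="\t", index=False)
            decay_rows = []
            if {"latitude", "longitude"}.issubset(ab.metadata.columns):
                d_geo = drivers_mod.geo_distance(ab.metadata)
                fit = drivers_mod.distance_decay(
                    d, d_geo, n_perm=config.n_perm, seed=seed + 61, predictor="geo_km"
                )
                decay_rows.append(fit)
            for f in factors:
                d_env = drivers_mod.env_distance(env, f, samples=ab.samples)
                decay_rows.append(
                    drivers_mod.distance_decay(
                        d, d_env, n_perm=config.n_perm, seed=seed + 67, predictor=f
                    )
                )
            decay_df = pd.DataFrame([asdict(f) for f in decay_rows])
            decay_df.to_csv(out / "decay.tsv", sep="\t", index=False)
            report["stages"]["drivers"] = {
                "mantel": {
                    r["factor"]: {"r": round(r["r"], 6), "p": r["p"]}
                    for _, r in panel.iterrows()
                },
                "decay": {
                    r.predictor: {"slope": r.slope, "r": r.r, "p": r.p}
                    for r in decay_rows if r.defined
                },
            }
        except Exception as exc:
            _abort(report, out, stage, exc)

    stage = "ncm"
    try:
        fits = [ncm_mod.fit_ncm(ab)]
        for col, val, _ in _group_scopes(ab, config.group_by):
            try:
                fits.append(ncm_mod.fit_ncm(ab, scope={col: val}))
            except ValidationError as exc:
                logger.warning("ncm scope %s=%s skipped: %s", col, val, exc)
        table = ncm_mod.compare_scopes(fits) if len(fits) > 1 else pd.DataFrame()
        if len(table):
            table.to_csv(out / "ncm_fits.tsv", sep="\t", index=False)
        fits[0].species.to_csv(out / "ncm_species.tsv", sep="\t")
        report["stages"]["ncm"] = {
            f.scope: {
                "m": round(f.m, 6), "Nm": round(f.Nm, 3),
                "R2": round(f.R2, 6) if f.R2_defined else None,
                "fraction_within": round(f.fraction_within, 6),
            }
            for f in fits
        }
    except Exception as exc:
        _abort(report, out, stage, exc)

    report["complete"] = True
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _abort(report: dict, out: Path, stage: str, exc: Exception):
    report["complete"] = False
    report["failed_stage"] = stage
    report["error"] = str(exc)
    _write_report(report, out)
    raise PipelineError(stage, exc)
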