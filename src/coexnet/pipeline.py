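"""End-to-end orchestration: ingest -> screen x2 -> meta -> netbuild.

RunConfig is a flat, human-editable YAML mapping; CLI flags override config
values. cmd-level wrappers live in cli.py; this module holds the library
path the CLI, analysis drivers, and tests all share.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import UsageError, ValidationError
from .ingest import (
    FeatureAnnotation,
    read_annotation,
    read_edge_list,
    read_expression_tsv,
    read_series_matrix,
)
from .meta import CandidateSet, intersect_screens, rank_candidates, write_candidate_table
from .netbuild import (
    NetworkConfig,
    build_networks,
    hub_rank,
    score_network,
    unconnected_focus,
    write_network,
)
from .screen import ScreenConfig, run_screen, write_screen_tsv

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "expression_1", "expression_2", "annotation_1", "annotation_2",
    "evidence", "evidence_dialect", "format_1", "format_2", "log2",
    "seed", "r_threshold", "p_method", "n_permutations", "min_pairs",
    "rng_seed", "matching_level", "max_nodes", "background_size",
    "allow_connectors", "rank_method", "output_dir", "log_level",
}


@dataclass
class RunConfig:
    expression_1: str
    expression_2: str
    evidence: str
    seed: str
    annotation_1: str | None = None
    annotation_2: str | None = None
    evidence_dialect: str = "tsv"
    format_1: str = "tsv"  # tsv | series_matrix
    format_2: str = "tsv"
    log2: bool = False
    r_threshold: float = 0.55
    p_method: str = "analytic"
    n_permutations: int = 10_000
    min_pairs: int = 10
    rng_seed: int = 0
    matching_level: str = "feature"
    max_nodes: int = 35
    background_size: int | None = None
    allow_connectors: bool = True
    rank_method: str = "min_abs_r"
    output_dir: str = "coexnet_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(str(path), encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise UsageError(f"{path}: run config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise UsageError(f"{path}: unknown config keys: {sorted(unknown)}")
        missing = {"expression_1", "expression_2", "evidence", "seed"} - set(raw)
        if missing:
            raise UsageError(f"{path}: missing required keys: {sorted(missing)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for key in ("expression_1", "expression_2", "evidence",
                    "annotation_1", "annotation_2"):
            value = getattr(self, key)
            if value is not None and not Path(value).is_file():
                raise FileNotFoundError(f"{key}: no such file: {value}")

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            seed=self.seed,
            r_threshold=self.r_threshold,
            p_method=self.p_method,
            n_permutations=self.n_permutations,
            min_pairs=self.min_pairs,
            rng_seed=self.rng_seed,
        )

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            max_nodes=self.max_nodes,
            background_size=self.background_size,
            allow_connectors=self.allow_connectors,
        )


def load_expression(path, fmt: str, dataset_id: str, log2: bool = False):
    if fmt == "tsv":
        return read_expression_tsv(path, dataset_id=dataset_id, log2=log2)
    if fmt == "series_matrix":
        return read_series_matrix(path, dataset_id=dataset_id, log2=log2)
    raise UsageError(f"unknown expression format {fmt!r}")


def _load_annotation(path, expr) -> FeatureAnnotation:
    if path is None:
        return FeatureAnnotation.identity(expr.feature_ids)
    return read_annotation(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, write artifacts, return the run summary."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "config": {k: getattr(config, k) for k in _KNOWN_KEYS}}
    logger.info("run config: %s", json.dumps(summary["config"], sort_keys=True, default=str))

    def stage(name):
        t0 = time.perf_counter()
        def done():
            summary["stages"][name] = round(time.perf_counter() - t0, 3)
        return done

    done = stage("ingest")
    expr1 = load_expression(config.expression_1, config.format_1, "ds1", config.log2)
    expr2 = load_expression(config.expression_2, config.format_2, "ds2", config.log2)
    ann1 = _load_annotation(config.annotation_1, expr1)
    ann2 = _load_annotation(config.annotation_2, expr2)
    evidence = read_edge_list(config.evidence, dialect=config.evidence_dialect)
    done()
    summary["datasets"] = {
        "ds1": {"features": expr1.n_features, "samples": expr1.n_samples},
        "ds2": {"features": expr2.n_features, "samples": expr2.n_samples},
    }

    done = stage("screen")
    scfg = config.screen_config()
    screen1 = run_screen(expr1, ann1, scfg)
    screen2 = run_screen(expr2, ann2, scfg)
    write_screen_tsv(screen1, outdir / "screen_ds1.tsv")
    write_screen_tsv(screen2, outdir / "screen_ds2.tsv")
    done()

    done = stage("meta")
    cs = intersect_screens(screen1, screen2, ann1, ann2, level=config.matching_level)
    write_candidate_table(cs, outdir / "candidates.tsv", method=config.rank_method)
    done()
    summary["counts"] = cs.counts()
    summary["concordance_defined"] = cs.concordance_defined

    done = stage("netbuild")
    ranked = rank_candidates(cs, config.rank_method) if cs.records else []
    focus_symbols = {}
    for rec in ranked:
        key = rec.symbol or rec.match_key
        focus_symbols.setdefault(key, int((rec.r1 > 0) - (rec.r1 < 0)))
    ncfg = config.network_config()
    networks = []
    if focus_symbols:
        networks = build_networks(
            focus_symbols, evidence, ncfg, correlation_sign=focus_symbols
        )
        n_focus_total = len({k.upper() for k in focus_symbols})
        for i, net in enumerate(networks, start=1):
            score_network(net, n_focus_total, ncfg, evidence)
            write_network(net, outdir / f"network_{i:02d}.graphml", "graphml")
            write_network(net, outdir / f"network_{i:02d}.sif", "sif")
    done()

    summary["networks"] = []
    for i, net in enumerate(networks, start=1):
        report = hub_rank(net)
        summary["networks"].append(
            {
                "index": i,
                "n_nodes": len(net.nodes),
                "n_focus": len(net.focus),
                "n_edges": net.n_internal_edges,
                "fisher_p": net.fisher_p,
                "score": net.score,
                "top_hub": report.top_hub,
            }
        )
    summary["singleton_focus"] = unconnected_focus(set(focus_symbols), evidence) if focus_symbols else []
    summary["networks"].sort(key=lambda n: (-n["score"], n["index"]))

    counts = summary["counts"]
    assert counts["union"] == counts["passing_1"] + counts["passing_2"] - counts["intersection"]
    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    logger.info("artifacts written to %s", outdir)
    return summary


def best_network(summary: dict) -> dict | None:
    return summary["networks"][0] if summary["networks"] else None
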