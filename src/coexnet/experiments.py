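"""Replicated end-to-end experiments on planted-module data.

These helpers run the full screen -> intersect -> network pipeline on
synthetic cohorts drawn under the study conditions (two independent
datasets of 166 and 76 samples, a 20-gene module plus seed and hub among
5000 background genes) and measure recovery of the planted truth. They are
shared by the test suite, the analysis drivers, and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ingest import FeatureAnnotation
from .meta import CandidateSet, intersect_screens
from .netbuild import NetworkConfig, build_networks, hub_rank, score_network
from .screen import ScreenConfig, run_screen
from .synthetic import SynthSpec, TruthTable, simulate_evidence, simulate_pair


@dataclass
class RecoveryMetrics:
    recall: float  # fraction of planted module genes (excl. seed) recovered
    n_module: int
    n_recovered: int
    n_false_positive: int  # background genes in the intersection
    concordance_fraction: float
    n_passing_1: int
    n_passing_2: int
    n_intersection: int
    n_union: int


def screen_pair(
    spec: SynthSpec, r_threshold: float = 0.55
) -> tuple[CandidateSet, TruthTable]:
    """Simulate a cohort pair, screen both against the seed, intersect."""
    expr1, expr2, truth = simulate_pair(spec)
    ann = FeatureAnnotation.identity(spec.gene_ids)
    config = ScreenConfig(seed=spec.seed_gene, r_threshold=r_threshold)
    s1 = run_screen(expr1, ann, config)
    s2 = run_screen(expr2, ann, config)
    cs = intersect_screens(s1, s2, ann, ann, level="feature")
    return cs, truth


def recovery_metrics(spec: SynthSpec, r_threshold: float = 0.55) -> RecoveryMetrics:
    """Module recovery and false positives of the cross-dataset intersection."""
    cs, truth = screen_pair(spec, r_threshold)
    module = set(truth.module_genes())
    recovered = {rec.match_key for rec in cs.records}
    hits = recovered & module
    return RecoveryMetrics(
        recall=len(hits) / len(module),
        n_module=len(module),
        n_recovered=len(hits),
        n_false_positive=len(recovered - module),
        concordance_fraction=cs.concordance_fraction,
        n_passing_1=cs.n_passing_1,
        n_passing_2=cs.n_passing_2,
        n_intersection=cs.n_intersection,
        n_union=cs.n_union,
    )


def single_cohort_recall(
    spec: SynthSpec, n_samples: int, stream_label: str = "B",
    r_threshold: float = 0.55,
) -> float:
    """Module recall of one screen at a given cohort size."""
    from .synthetic import simulate_dataset

    expr, truth = simulate_dataset(spec, n_samples, stream_label)
    ann = FeatureAnnotation.identity(spec.gene_ids)
    res = run_screen(expr, ann, ScreenConfig(seed=spec.seed_gene, r_threshold=r_threshold))
    module = set(truth.module_genes())
    return len(set(res.passing_ids) & module) / len(module)


def hub_recovery(
    spec: SynthSpec, r_threshold: float = 0.55, max_nodes: int = 35
) -> tuple[str, str, float]:
    """End-to-end run returning (top hub of the best-scoring network,
    planted hub, best network score)."""
    cs, truth = screen_pair(spec, r_threshold)
    evidence = simulate_evidence(spec)
    focus = {rec.match_key for rec in cs.records}
    config = NetworkConfig(max_nodes=max_nodes)
    networks = build_networks(focus, evidence, config)
    for net in networks:
        score_network(net, len(focus), config, evidence)
    best = max(networks, key=lambda n: n.score)
    return hub_rank(best).top_hub, truth.hub_gene, best.score
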