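"""Size-capped interaction-network construction and Fisher scoring.

Candidate ("focus") genes from the cross-dataset screen are grown into
limited networks (default cap 35 nodes) over a gene-gene interaction
evidence graph. Construction is greedy: each network is seeded with the
unassigned focus gene best connected to other unassigned focus genes and
extended one gene at a time by whichever admissible gene adds the most
evidence edges to the current node set (focus genes preferred over
connectors; ties lexicographic). Each focus gene belongs to exactly one
network; connector genes may recur across networks. A network's edges are
the evidence subgraph induced on its nodes.

Networks are scored by a right-tailed Fisher's exact test on the 2x2 table
(focus membership x network membership over a declared background universe):
the probability that at least the observed number of focus genes lands in a
node set of that size under random assignment. The tail sum is computed in
log space so scores stay finite for extreme enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .ingest import InteractionEvidence

logger = logging.getLogger(__name__)

LOG10 = float(np.log(10.0))


@dataclass
class NetworkConfig:
    max_nodes: int = 35
    background_size: int | None = None  # default: distinct genes in evidence
    allow_connectors: bool = True

    def __post_init__(self) -> None:
        if self.max_nodes < 2:
            raise ValidationError("max_nodes must be >= 2")


@dataclass
class Network:
    nodes: list[str]  # sorted
    focus: set[str]  # focus genes among nodes
    edges: dict[tuple[str, str], str]  # sorted endpoint pair -> relation
    correlation_sign: dict[str, int] = field(default_factory=dict)
    fisher_p: float = float("nan")
    log10_fisher_p: float = float("nan")

    @property
    def n_internal_edges(self) -> int:
        return len(self.edges)

    @property
    def score(self) -> float:
        """-log10 of the Fisher p-value (0 for an unenriched network)."""
        return -self.log10_fisher_p

    def degree(self, gene: str) -> int:
        return sum(1 for (a, b) in self.edges if gene in (a, b))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node,
                focus=node in self.focus,
                correlation_sign=self.correlation_sign.get(node, 0),
            )
        for (a, b), rel in sorted(self.edges.items()):
            g.add_edge(a, b, relation=rel)
        return g


@dataclass
class HubReport:
    ranking: list[str]
    degree: dict[str, int]
    betweenness: dict[str, float]

    @property
    def top_hub(self) -> str:
        return self.ranking[0]


def log_fisher_exact_right(a: int, b: int, c: int, d: int) -> float:
    """Natural-log right-tail Fisher p for the 2x2 table [[a, b], [c, d]].

    With margins fixed, the right tail sums hypergeometric probabilities of
    tables with >= a counts in the (focus, in-network) cell:

        P(X >= a), X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b).

    Each term is evaluated via log-binomials (gammaln) and combined with
    logsumexp, so the result is usable far below float underflow.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("contingency cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0:
        return 0.0  # empty table: p = 1

    def log_comb(m: int, k: int) -> float:
        return float(gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1))

    k_hi = min(K, n)
    ks = np.arange(a, k_hi + 1)
    if ks.size == 0:
        return float("-inf")  # a exceeds the support: p = 0 (cannot happen with valid cells)
    terms = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - (n - ks) + 1)
        - log_comb(N, n)
    )
    return float(min(0.0, logsumexp(terms)))


def fisher_exact_right(a: int, b: int, c: int, d: int) -> float:
    """Right-tailed Fisher's exact test p-value (may underflow to 0.0 for
    extreme tables; use log_fisher_exact_right for scoring)."""
    return float(np.exp(log_fisher_exact_right(a, b, c, d)))


def _induced_edges(
    nodes: set[str], evidence: InteractionEvidence
) -> dict[tuple[str, str], str]:
    return {
        (a, b): rel
        for (a, b), rel in evidence.relations.items()
        if a in nodes and b in nodes
    }


def unconnected_focus(focus, evidence: InteractionEvidence) -> list[str]:
    """Focus genes with no evidence edges at all — reported as singletons."""
    genes = evidence.genes()
    return sorted(g for g in {f.upper() for f in focus} if g not in genes)


def build_networks(
    focus,
    evidence: InteractionEvidence,
    config: NetworkConfig | None = None,
    correlation_sign: dict[str, int] | None = None,
) -> list[Network]:
    """Grow size-capped networks from the focus set over the evidence graph.

    Returns networks in construction order; each focus gene with at least one
    evidence edge appears in exactly one network. Focus genes absent from the
    evidence are left out (see unconnected_focus) and logged.
    """
    config = config or NetworkConfig()
    focus_set = {f.upper() for f in focus}
    if not focus_set:
        raise ValidationError("focus set is empty")
    if len(evidence) == 0:
        raise ValidationError("interaction evidence is empty")
    correlation_sign = {
        g.upper(): int(np.sign(s)) for g, s in (correlation_sign or {}).items()
    }

    adj: dict[str, set[str]] = {}
    for a, b in evidence.relations:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    singles = unconnected_focus(focus_set, evidence)
    if singles:
        logger.info("%d focus genes without evidence edges: %s", len(singles), singles[:10])

    unassigned = {g for g in focus_set if g in adj}
    networks: list[Network] = []
    while unassigned:
        # Seed: unassigned focus gene with most edges to other unassigned focus genes.
        seed = min(
            unassigned,
            key=lambda g: (-len(adj[g] & (unassigned - {g})), g),
        )
        nodes = {seed}
        while len(nodes) < config.max_nodes:
            frontier: set[str] = set()
            for node in nodes:
                frontier |= adj[node]
            frontier -= nodes
            candidates = []
            for gene in frontier:
                is_focus = gene in unassigned
                if not is_focus:
                    if not config.allow_connectors or gene in focus_set:
                        # focus genes already assigned elsewhere are closed
                        continue
                added = len(adj[gene] & nodes)
                if added >= 1:
                    candidates.append((0 if is_focus else 1, -added, gene))
            if not candidates:
                break
            nodes.add(min(candidates)[2])
        unassigned -= nodes
        net_focus = nodes & focus_set
        networks.append(
            Network(
                nodes=sorted(nodes),
                focus=net_focus,
                edges=_induced_edges(nodes, evidence),
                correlation_sign={
                    g: correlation_sign[g] for g in nodes if g in correlation_sign
                },
            )
        )
    return networks


def score_network(
    net: Network, n_focus_total: int, config: NetworkConfig, evidence: InteractionEvidence | None = None
) -> Network:
    """Attach the right-tailed Fisher p (and its log10) to a network.

    Contingency: a = focus nodes in the network, b = connector nodes in the
    network, c = remaining focus genes, d = remaining background genes, over
    a background universe of config.background_size genes (default: distinct
    genes in the evidence).
    """
    background = config.background_size
    if background is None:
        if evidence is None:
            raise ValidationError(
                "background_size unset and no evidence given to derive it"
            )
        background = len(evidence.genes())
    a = len(net.focus)
    b = len(net.nodes) - a
    c = n_focus_total - a
    d = background - a - b - c
    if c < 0:
        raise ValidationError(
            f"network holds {a} focus genes but n_focus_total={n_focus_total}"
        )
    if d < 0:
        raise ValidationError(
            f"background_size={background} smaller than focus+network union"
        )
    logp = log_fisher_exact_right(a, b, c, d)
    # keep fisher_p in (0, 1] even when the exact tail underflows float range
    net.fisher_p = max(float(np.exp(logp)), 5e-324)
    net.log10_fisher_p = logp / LOG10
    return net


def hub_rank(net: Network) -> HubReport:
    """Rank network nodes by degree, then betweenness, then name."""
    if not net.nodes:
        raise ValidationError("cannot rank hubs of an empty network")
    g = net.to_graph()
    degree = {n: d for n, d in g.degree()}
    betweenness = nx.betweenness_centrality(g, normalized=True)
    ranking = sorted(
        net.nodes, key=lambda n: (-degree[n], -betweenness[n], n)
    )
    return HubReport(ranking=ranking, degree=degree, betweenness=betweenness)


def write_network(net: Network, path, format: str = "graphml") -> None:
    """Write a network as GraphML, SIF, or TSV attribute tables.

    Nodes carry focus and correlation-sign attributes; edges carry the
    direct/indirect relation. Element order is deterministic. The tsv format
    writes edges at ``path`` and node attributes at ``path + ".nodes.tsv"``.
    """
    path = str(path)
    if format == "graphml":
        nx.write_graphml(net.to_graph(), path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            connected = set()
            for (a, b), rel in sorted(net.edges.items()):
                fh.write(f"{a}\t{rel}\t{b}\n")
                connected |= {a, b}
            for node in sorted(set(net.nodes) - connected):
                fh.write(f"{node}\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_a\tgene_b\trelation\n")
            for (a, b), rel in sorted(net.edges.items()):
                fh.write(f"{a}\t{b}\t{rel}\n")
        with open(path + ".nodes.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\tfocus\tcorrelation_sign\tdegree\n")
            for node in net.nodes:
                fh.write(
                    f"{node}\t{int(node in net.focus)}"
                    f"\t{net.correlation_sign.get(node, 0)}\t{net.degree(node)}\n"
                )
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_sif(path) -> InteractionEvidence:
    """Read a SIF file back into interaction evidence (isolated nodes kept
    out, matching InteractionEvidence's edge-only model)."""
    ev = InteractionEvidence()
    with open(str(path), encoding="utf-8", newline="") as fh:
        for line in fh:
            toks = line.rstrip("\r\n").split("\t")
            if len(toks) == 3:
                ev.add(toks[0], toks[2], toks[1])
    return ev
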