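"""Driver prioritization by weighted semi-local centrality (the eccDriver score).

Given a set of candidate genes (EDGs), a reference protein–protein
interaction network, and a set of differentially expressed genes (DEGs),
each candidate is scored by how central it is in the PPI and how strongly
its two-hop neighborhood is enriched for transcriptional change:

* ``K(v)`` — degree of the candidate in the full reference PPI.
* A depth-2 *local network* per candidate: the candidate (source), DEGs
  within two hops (targets), and one-hop bridges to two-hop DEGs
  (intermediates).
* ``N(v)`` — number of direct DEG neighbors of ``v``.
* ``Q(v) = sum over u in Gamma(v) of N(u)`` — second-shell DEG influence.
* ``alpha = sum(N(v)^2) / sum(Q(v))`` over the candidate set — a single
  weighting coefficient discounting next-nearest relative to nearest
  neighbors (0 when the denominator vanishes).
* ``C_WL(v) = N(v) + alpha * Q(v)`` — weighted semi-local centrality.
* ``EGIS(v) = (K(v) + 1) * (C_WL(v) + 1)`` — the ranking statistic; the
  top-``m`` genes (default 100) are the candidate eccDNA-driven drivers.

Unlike the classical four-hop semi-local centrality, the neighborhood stops
at two hops and the two shells are weighted unequally through ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .types import CentralityRecord

logger = logging.getLogger(__name__)

DEFAULT_TOP_M = 100
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_Q_THRESHOLD = 0.01
LOCAL_NETWORK_DEPTH = 2  # fixed by the method definition


@dataclass
class LocalNetwork:
    """Depth-2 subnetwork around one source gene.

    Roles: ``source`` (the candidate itself), ``target`` (a DEG one or two
    hops away), ``intermediate`` (a one-hop bridge to a two-hop DEG); a
    one-hop DEG that also bridges is ``intermediate+target``.
    """

    source: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    roles: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)


def degree_K(ppi: nx.Graph, gene: str) -> int:
    """Degree of ``gene`` in the full thresholded reference PPI."""
    if gene not in ppi:
        raise KeyError(
            f"{gene!r} is not in the PPI network; candidates not covered by the "
            "network must be removed before scoring"
        )
    return ppi.degree(gene)


def build_local_network(
    ppi: nx.Graph, source: str, deg_set: set, max_depth: int = LOCAL_NETWORK_DEPTH
) -> LocalNetwork:
    """Construct the depth-2 DEG-based local network around ``source``.

    Included nodes: the source; DEGs at hop distance 1 or 2; and non-source
    hop-1 nodes adjacent to at least one hop-2 DEG. Hop-1 non-DEG neighbors
    with no DEG behind them are excluded. Edges are the PPI subgraph induced
    on the included nodes.
    """
    if source not in ppi:
        raise KeyError(f"source {source!r} not in PPI network")
    if max_depth != 2:
        raise ValueError("the local network is defined at depth 2")

    hop1 = set(ppi.neighbors(source)) - {source}
    hop2 = set()
    for u in hop1:
        hop2 |= set(ppi.neighbors(u))
    hop2 -= hop1 | {source}

    hop1_degs = hop1 & deg_set
    hop2_degs = hop2 & deg_set
    bridges = {u for u in hop1 if set(ppi.neighbors(u)) & hop2_degs}

    nodes = {source} | hop1_degs | hop2_degs | bridges
    net = LocalNetwork(source=source, graph=ppi.subgraph(nodes).copy())
    for node in nodes:
        if node == source:
            net.roles[node] = "source"
            continue
        is_target = node in hop1_degs or node in hop2_degs
        is_intermediate = node in bridges
        if is_target and is_intermediate:
            net.roles[node] = "intermediate+target"
        elif is_target:
            net.roles[node] = "target"
        else:
            net.roles[node] = "intermediate"
    return net


def nearest_deg_count(
    graph: nx.Graph, node: str, deg_set: set, restrict_to_local: bool = True
) -> int:
    """``N(node)``: number of direct DEG neighbors.

    With ``restrict_to_local`` the neighbor set is taken in ``graph`` (a
    local network); pass the full PPI and ``restrict_to_local=False``
    semantics by handing in the full graph instead.
    """
    if node not in graph:
        return 0
    return sum(1 for u in graph.neighbors(node) if u in deg_set)


def q_value(graph: nx.Graph, node: str, deg_set: set) -> int:
    """``Q(node)``: sum of N(u) over the direct neighbors u of ``node``."""
    if node not in graph:
        return 0
    return sum(nearest_deg_count(graph, u, deg_set) for u in graph.neighbors(node))


def alpha(per_edg_N: list, per_edg_Q: list) -> float:
    """The shared weighting coefficient over the candidate set.

    ``alpha = sum(N^2) / sum(Q)``, with the convention that a zero
    denominator yields 0 (then C_WL reduces to N).
    """
    if not per_edg_N:
        raise ValueError("alpha requires a non-empty candidate set")
    if len(per_edg_N) != len(per_edg_Q):
        raise ValueError("N and Q vectors must align")
    denom = float(sum(per_edg_Q))
    if denom == 0.0:
        return 0.0
    return float(sum(n * n for n in per_edg_N)) / denom


def c_wl(N: float, Q: float, alpha_coef: float) -> float:
    """Weighted semi-local centrality ``C_WL = N + alpha * Q``."""
    return float(N) + alpha_coef * float(Q)


def egis(K: float, c_wl_value: float) -> float:
    """Impact score ``EGIS = (K + 1) * (C_WL + 1)``."""
    return (float(K) + 1.0) * (c_wl_value + 1.0)


def filter_degs(
    deg_table: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> set:
    """Apply the strict DEG filters ``|log2FC| > lfc`` and ``q < q_threshold``."""
    mask = (deg_table["log2fc"].abs() > lfc_threshold) & (
        deg_table["q_value"] < q_threshold
    )
    return set(deg_table.loc[mask, "gene_id"])


def rank_drivers(
    edg_genes,
    ppi: nx.Graph,
    deg_table,
    top_m: int = DEFAULT_TOP_M,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    restrict_to_local: bool = True,
) -> list[CentralityRecord]:
    """Score and rank candidate genes by EGIS.

    Parameters
    ----------
    edg_genes : iterable of str
        Candidate genes (typically the coding EDGs of one dataset).
        Candidates absent from the PPI are dropped.
    ppi : networkx.Graph
        Reference interaction network (thresholded, undirected).
    deg_table : pandas.DataFrame or set
        Either a ``gene_id/log2fc/q_value`` table (filtered here with strict
        thresholds) or a precomputed set of DEG ids.
    top_m : int
        Number of top-ranked genes flagged as candidate drivers.
    restrict_to_local : bool
        Count DEG neighbors within the local network (default, the method's
        definition) or in the full PPI (sensitivity analysis).

    Returns
    -------
    list of CentralityRecord
        All surviving candidates sorted by EGIS descending (ties: K
        descending, then gene id ascending), ranks 1..n. The caller takes
        ``records[:top_m]`` as the candidate drivers; :func:`top_candidates`
        does exactly that.
    """
    if isinstance(deg_table, pd.DataFrame):
        deg_set = filter_degs(deg_table, lfc_threshold, q_threshold)
        if not deg_set and len(deg_table):
            logger.warning(
                "no gene passes the DEG filters (|log2FC| > %s, q < %s); "
                "all N and Q will be 0",
                lfc_threshold,
                q_threshold,
            )
    else:
        deg_set = set(deg_table)

    candidates = sorted(set(edg_genes))
    surviving = [g for g in candidates if g in ppi]
    dropped = len(candidates) - len(surviving)
    if dropped:
        logger.info("%d candidate(s) not covered by the PPI were removed", dropped)
    if not surviving:
        raise ValueError("no candidate gene is covered by the PPI network")

    per_gene = {}
    for gene in surviving:
        local = build_local_network(ppi, gene, deg_set)
        count_graph = local.graph if restrict_to_local else ppi
        N = nearest_deg_count(count_graph, gene, deg_set)
        Q = q_value(count_graph, gene, deg_set)
        per_gene[gene] = (degree_K(ppi, gene), N, Q)

    a = alpha([v[1] for v in per_gene.values()], [v[2] for v in per_gene.values()])

    scored = []
    for gene, (K, N, Q) in per_gene.items():
        cw = c_wl(N, Q, a)
        scored.append((gene, K, N, Q, cw, egis(K, cw)))
    scored.sort(key=lambda t: (-t[5], -t[1], t[0]))

    records = [
        CentralityRecord(
            gene_id=gene, K=K, N=N, Q=Q, alpha_used=a, c_wl=cw, egis=score,
            rank=i + 1,
        )
        for i, (gene, K, N, Q, cw, score) in enumerate(scored)
    ]
    return records


def top_candidates(records: list[CentralityRecord], top_m: int = DEFAULT_TOP_M):
    """The first ``min(top_m, n)`` records: the candidate driver set."""
    return records[: max(0, top_m)]
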