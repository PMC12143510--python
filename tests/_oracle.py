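"""Independent brute-force re-evaluation of the centrality definitions.

Deliberately written from scratch over plain adjacency sets (no networkx,
no imports from the package's ranking module) so it can serve as an oracle
for the pipeline implementation.
"""

from collections import defaultdict


def adjacency(edges):
    adj = defaultdict(set)
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def local_nodes(adj, source, degs):
    """Depth-2 local network node set, re-derived from the definition."""
    hop1 = set(adj[source])
    hop2 = set()
    for u in hop1:
        hop2 |= adj[u]
    hop2 -= hop1 | {source}
    hop1_degs = hop1 & degs
    hop2_degs = hop2 & degs
    bridges = {u for u in hop1 if adj[u] & hop2_degs}
    return {source} | hop1_degs | hop2_degs | bridges


def oracle_scores(edges, degs, edg_set, nodes=None):
    """N, Q, alpha, C_WL and EGIS for every candidate, by direct evaluation.

    Returns ``(per_gene, alpha)`` with
    ``per_gene[g] = (K, N, Q, c_wl, egis)``. ``nodes`` defaults to the edge
    list's endpoints; pass it explicitly when the graph has isolated nodes.
    Candidates outside ``nodes`` are skipped (the PPI-coverage filter).
    """
    adj = adjacency(edges)
    nodes = set(adj) if nodes is None else set(nodes)
    degs = set(degs)
    surviving = sorted(g for g in edg_set if g in nodes)

    raw = {}
    for s in surviving:
        local = local_nodes(adj, s, degs)
        n_of = lambda v: len(adj[v] & local & degs)  # noqa: E731
        N = n_of(s)
        Q = sum(n_of(u) for u in adj[s] & local)
        raw[s] = (len(adj[s]), N, Q)

    sum_q = sum(v[2] for v in raw.values())
    a = (sum(v[1] ** 2 for v in raw.values()) / sum_q) if sum_q else 0.0

    per_gene = {}
    for s, (K, N, Q) in raw.items():
        cwl = N + a * Q
        per_gene[s] = (K, N, Q, cwl, (K + 1) * (cwl + 1))
    return per_gene, a
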