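"""Independent brute-force oracles for the graph stage.

Deliberately implemented with plain sets, dicts and loops over edge lists —
no networkx, no imports from the package — so they constitute an
independent route to the same answers.
"""

from __future__ import annotations


def norm(u, v):
    return (u, v) if u <= v else (v, u)


def bf_extract(edges, genes):
    """Induced node/edge sets of `genes`, dropping isolated members."""
    genes = set(genes)
    induced = {norm(u, v) for u, v in edges if u in genes and v in genes and u != v}
    nodes = {n for e in induced for n in e}
    return nodes, induced


def bf_neighbors(edges):
    adj = {}
    for u, v in edges:
        if u == v:
            continue
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def bf_extend(core_nodes, edges, dereg, threshold):
    """One-pass MoA extension: non-core genes passing the threshold that
    touch a deregulated core gene; returns (final nodes, final edges,
    deregulated-core set, extension set)."""
    adj = bf_neighbors(edges)
    passing = {g for g, fc in dereg.items() if abs(fc) >= threshold}
    dereg_core = {g for g in passing if g in core_nodes}
    ext = {
        g
        for g in passing
        if g not in core_nodes and adj.get(g, set()) & dereg_core
    }
    nodes = set(core_nodes) | ext
    final_edges = {norm(u, v) for u, v in edges if u in nodes and v in nodes and u != v}
    return nodes, final_edges, dereg_core, ext


def bf_interference(a_nodes, a_edges, b_nodes, b_edges):
    return set(a_nodes) & set(b_nodes), {norm(*e) for e in a_edges} & {norm(*e) for e in b_edges}


def bf_distances(edges, sources, cutoff):
    """Breadth-first shortest-path hop counts from a source set."""
    adj = bf_neighbors(edges)
    dist = {s: 0 for s in sources}
    frontier = set(sources)
    d = 0
    while frontier and d < cutoff:
        d += 1
        nxt = set()
        for u in frontier:
            for v in adj.get(u, set()):
                if v not in dist:
                    dist[v] = d
                    nxt.add(v)
        frontier = nxt
    return dist


def bf_rank(sig_nodes, edges, all_nodes, evidence, proximity_max):
    """Candidate rows ordered by (tier, distance, -evidence, gene)."""
    dist = bf_distances(edges, set(sig_nodes) & set(all_nodes), proximity_max)
    rows = []
    for g, cnt in evidence.items():
        if g not in all_nodes or g not in dist:
            continue
        tier = "in_signature" if dist[g] == 0 else "proximal"
        rows.append((0 if tier == "in_signature" else 1, dist[g], -cnt, g, tier))
    rows.sort()
    return [(g, tier, d, -negcnt) for _, d, negcnt, g, tier in rows]
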