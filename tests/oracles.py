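"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the package's own code paths: the genetic code is
taken from biopython, chain search is exhaustive DFS, tandem clustering is
a networkx connected-components computation, and additive trees are grown
by random leaf attachment with BFS path sums.
"""

import collections
import itertools
import math

import networkx as nx
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

GENETIC_CODE = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
NTS = "ACGT"


def oracle_sites(codon):
    """(synonymous sites, total sites) by direct neighbor enumeration;
    stop neighbors excluded from denominators."""
    s = 0.0
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NTS:
            if nt == codon[pos]:
                continue
            neighbor = codon[:pos] + nt + codon[pos + 1:]
            if neighbor in STOPS:
                continue
            valid += 1
            if GENETIC_CODE[neighbor] == GENETIC_CODE[codon]:
                syn += 1
        if valid:
            s += syn / valid
            total += 1.0
    return s, total


def oracle_differences(ca, cb):
    """Pathway-averaged (syn, nonsyn) differences; NaN when all pathways
    pass through a stop codon."""
    positions = [p for p in range(3) if ca[p] != cb[p]]
    if not positions:
        return 0.0, 0.0
    outcomes = []
    for order in itertools.permutations(positions):
        cur, syn, nonsyn, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            outcomes.append((syn, nonsyn))
    if not outcomes:
        return math.nan, math.nan
    return (float(np.mean([o[0] for o in outcomes])),
            float(np.mean([o[1] for o in outcomes])))


def oracle_tandem(genes, window):
    """Connected components of the same-chromosome within-window pair graph."""
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in genes)
    for a, b in itertools.combinations(genes, 2):
        if a.chromosome == b.chromosome and abs(a.start - b.start) <= window:
            graph.add_edge(a.gene_id, b.gene_id)
    return sorted(
        tuple(sorted(c)) for c in nx.connected_components(graph) if len(c) >= 2
    )


def oracle_best_chain(points, gap):
    """Length of the longest gap-respecting strictly increasing chain."""
    best = 0
    order = sorted(range(len(points)), key=lambda k: points[k])

    def extend(last, count, remaining):
        nonlocal best
        best = max(best, count)
        for k in remaining:
            pa, pb = points[k]
            la, lb = points[last]
            if pa > la and pb > lb and pa - la - 1 <= gap and pb - lb - 1 <= gap:
                extend(k, count + 1, [r for r in remaining if r != k])

    for k in order:
        extend(k, 1, [r for r in order if r != k])
    return best


def random_additive_tree(n_leaves, rng):
    """Random binary unrooted tree; returns its exact leaf path metric."""
    nodes = {i: {} for i in range(n_leaves)}

    def add_edge(u, v, w):
        nodes.setdefault(u, {})[v] = w
        nodes.setdefault(v, {})[u] = w

    next_internal = n_leaves
    add_edge(0, 1, float(rng.uniform(0.1, 1.0)))
    edges = [(0, 1)]
    for leaf in range(2, n_leaves):
        u, v = edges[rng.integers(len(edges))]
        w = nodes[u].pop(v)
        nodes[v].pop(u)
        mid = next_internal
        next_internal += 1
        split = float(rng.uniform(0.25, 0.75))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, float(rng.uniform(0.1, 1.0)))
        edges.remove((u, v))
        edges += [(u, mid), (mid, v), (mid, leaf)]

    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, w in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    return (D + D.T) / 2.0  # exact float symmetry
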