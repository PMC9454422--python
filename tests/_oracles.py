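"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: the ROH
oracle enumerates every (i, j) window and checks each criterion directly;
the tree oracle builds random additive distance matrices by summing path
lengths over an explicit random tree; the overlap oracle is an all-pairs
intersection test.
"""

from __future__ import annotations

import numpy as np


def brute_force_roh(pos, dosages, criteria):
    """Exhaustive ROH search for one individual on one chromosome.

    Enumerates every window (i, j), keeps those satisfying all five
    criteria (with homozygous boundary SNPs), then greedily selects
    non-overlapping windows left to right: repeatedly take the
    earliest-start window disjoint from prior selections, breaking ties by
    the longest (largest end).  Returns (i, j) index pairs.
    """
    pos = np.asarray(pos)
    d = np.asarray(dosages)
    n = len(pos)
    hom = (d == 0) | (d == 2)
    het = d == 1
    miss = d < 0

    qualifying = []
    for i in range(n):
        if not hom[i]:
            continue
        n_het = 0
        n_miss = 0
        max_gap = 0
        for j in range(i, n):
            if j > i:
                max_gap = max(max_gap, pos[j] - pos[j - 1])
                if het[j]:
                    n_het += 1
                if miss[j]:
                    n_miss += 1
            if n_het > criteria.max_het or n_miss > criteria.max_missing:
                break
            if max_gap > criteria.max_gap_bp:
                break
            if not hom[j]:
                continue
            n_snps = j - i + 1
            length = int(pos[j] - pos[i]) + 1
            if (
                n_snps >= criteria.min_snps
                and length >= criteria.min_length_bp
                and length <= criteria.min_density_bp_per_snp * n_snps
            ):
                qualifying.append((i, j))

    selected = []
    cursor = -1
    while True:
        candidates = [(i, j) for i, j in qualifying if i > cursor]
        if not candidates:
            break
        best = min(candidates, key=lambda w: (pos[w[0]], -(pos[w[1]] - pos[w[0]]), pos[w[1]]))
        selected.append(best)
        cursor = best[1]
    return selected


def random_roh_instance(rng, n_snps=500, het_rate=0.05, miss_rate=0.02,
                        mean_spacing=5_000):
    """A random single-chromosome genotype row for oracle comparison."""
    gaps = rng.geometric(1.0 / mean_spacing, size=n_snps)
    pos = np.cumsum(gaps) + 1
    u = rng.random(n_snps)
    d = np.where(u < het_rate, 1, np.where(rng.random(n_snps) < 0.5, 0, 2))
    d = np.where(rng.random(n_snps) < miss_rate, -1, d).astype(np.int8)
    return pos.astype(np.int64), d


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree; returns (taxa, dist_matrix, edge map).

    Grown by sequential taxon attachment; distances are path-length sums
    (hence exactly additive).  ``edges`` maps each non-trivial bipartition
    (canonical side excluding taxon 0's name) to its branch length, and
    each leaf name to its pendant edge length.
    """

    class _N:
        __slots__ = ("name", "nbrs")

        def __init__(self, name=None):
            self.name = name
            self.nbrs = {}  # node -> branch length

    def link(a, b, L):
        a.nbrs[b] = L
        b.nbrs[a] = L

    def unlink(a, b):
        del a.nbrs[b]
        del b.nbrs[a]

    taxa = [f"t{i}" for i in range(n_taxa)]
    leaves = [_N(t) for t in taxa]
    rlen = lambda: float(rng.uniform(0.1, 2.0))
    if n_taxa == 2:
        link(leaves[0], leaves[1], rlen())
    else:
        center = _N()
        for leaf in leaves[:3]:
            link(center, leaf, rlen())
        for leaf in leaves[3:]:
            # pick a random existing edge, split it, hang the new leaf
            edges = []
            seen = set()
            stack = [leaves[0]]
            while stack:
                node = stack.pop()
                seen.add(id(node))
                for nbr in node.nbrs:
                    if id(nbr) not in seen:
                        edges.append((node, nbr))
                        stack.append(nbr)
            a, b = edges[rng.integers(0, len(edges))]
            L = a.nbrs[b]
            cut = float(rng.uniform(0.05, 0.95)) * L
            mid = _N()
            unlink(a, b)
            link(a, mid, cut)
            link(mid, b, L - cut)
            link(mid, leaf, rlen())

    name_to_leaf = {l.name: l for l in leaves}

    def path_length(src, dst):
        stack = [(src, 0.0, None)]
        while stack:
            node, acc, prev = stack.pop()
            if node is dst:
                return acc
            for nbr, L in node.nbrs.items():
                if nbr is not prev:
                    stack.append((nbr, acc + L, node))
        raise AssertionError("disconnected tree")

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = path_length(name_to_leaf[taxa[i]], name_to_leaf[taxa[j]])

    # edge -> bipartition map
    all_taxa = frozenset(taxa)
    edges = {}
    seen = set()
    stack = [leaves[0]]
    order = []
    while stack:
        node = stack.pop()
        seen.add(id(node))
        order.append(node)
        for nbr in node.nbrs:
            if id(nbr) not in seen:
                stack.append(nbr)

    def tips_under(node, prev):
        out = set()
        stack2 = [(node, prev)]
        while stack2:
            cur, par = stack2.pop()
            if cur.name is not None:
                out.add(cur.name)
            for nbr in cur.nbrs:
                if nbr is not par:
                    stack2.append((nbr, cur))
        return out

    done = set()
    for node in order:
        for nbr, L in node.nbrs.items():
            key_ids = frozenset((id(node), id(nbr)))
            if key_ids in done:
                continue
            done.add(key_ids)
            side = frozenset(tips_under(nbr, node))
            if len(side) == 1:
                edges[next(iter(side))] = L
            elif len(side) == n_taxa - 1:
                other = all_taxa - side
                edges[next(iter(other))] = L
            elif 2 <= len(side) <= n_taxa - 2:
                canon = side if taxa[0] not in side else all_taxa - side
                edges[canon] = L
    return taxa, D, edges


def brute_force_overlaps(islands, genes):
    """All-pairs 1-bp-overlap test; returns a list of gene-id sets per island."""
    out = []
    for isl in islands:
        hits = {
            g.gene_id
            for g in genes
            if g.chrom == isl.chrom and g.start <= isl.end and g.end >= isl.start
        }
        out.append(hits)
    return out
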