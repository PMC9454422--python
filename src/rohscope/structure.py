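"""Population structure: genetic distances, neighbor-joining tree with
bootstrap support, and Patterson-normalised PCA.

Two pairwise distances over samples are provided:

* allele-sharing (IBS) distance, the genotype-native default:
  ``d(i, j) = 1 - shared_alleles / (2 * co-typed sites)`` with the shared
  count at one site equal to ``2 - |dosage_i - dosage_j|``;
* Kimura two-parameter (K2P) distance on per-sample consensus
  pseudo-sequences (dosage 0 -> ref, 2 -> alt, heterozygote -> a seeded
  random allele), ``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))`` with P
  and Q the transition and transversion difference fractions.  K2P is
  defined on sequences, so the genotype -> sequence conversion is a
  documented convention, not part of the model.

The neighbor-joining implementation follows Saitou–Nei with the standard
Q-criterion and is exact on additive distance matrices; ties in the
Q-matrix are broken by the first pair in row-major order (lexicographic in
the current node ordering), making the output deterministic.  Negative
branch lengths are clamped to zero by default for presentation; the raw
value is kept on each node as ``raw_length``.

Bootstrap support resamples site columns with replacement, rebuilds the
tree, and reports for each internal bipartition of the full-data tree the
fraction of replicates containing it.

PCA uses the smartpca-style normalisation ``(d - 2*p) / sqrt(p * (1 - p))``
with p the observed alternate-allele frequency; missing cells are set to
zero after centring, monomorphic sites are skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _abs_diff_sums(dosages: np.ndarray, weights: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (sum |d_i - d_j|, co-typed count) over sites, via indicator
    matrix products; ``weights`` are per-site multiplicities (bootstrap)."""
    w = np.ones(dosages.shape[1]) if weights is None else np.asarray(weights, float)
    ind = [(dosages == v).astype(np.float64) for v in (0, 1, 2)]
    obs = (dosages != MISSING).astype(np.float64)
    n_pair = (obs * w) @ obs.T
    s = np.zeros_like(n_pair)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            s += abs(a - b) * ((ind[a] * w) @ ind[b].T)
    return s, n_pair


def ibs_distance(
    gm: GenotypeMatrix, weights: np.ndarray | None = None
) -> DistanceMatrix:
    """Allele-sharing distance matrix over all samples.

    Raises ``ValueError`` naming the first pair with zero co-typed sites.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    s, n_pair = _abs_diff_sums(gm.dosages, weights)
    bad = np.argwhere((n_pair == 0) & ~np.eye(gm.n_samples, dtype=bool))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no co-typed sites"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = s / (2.0 * n_pair)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float jitter
    return DistanceMatrix(d, ids=gm.samples)


def pseudo_sequences(gm: GenotypeMatrix, seed: int | None = 0) -> np.ndarray:
    """Consensus allele calls (samples x sites): 0 = ref, 1 = alt, -1 missing.

    Heterozygotes take a random allele under the given seed — a necessary
    invention to apply a sequence-distance model to genotypes.
    """
    rng = np.random.default_rng(seed)
    d = gm.dosages
    calls = np.full(d.shape, -1, dtype=np.int8)
    calls[d == 0] = 0
    calls[d == 2] = 1
    het = d == 1
    calls[het] = rng.integers(0, 2, size=int(het.sum()))
    return calls


def transition_mask(gm: GenotypeMatrix) -> np.ndarray:
    """True at sites whose ref/alt pair is a transition (A<->G, C<->T)."""
    return np.array(
        [frozenset((str(r), str(a))) in _TRANSITIONS for r, a in zip(gm.ref, gm.alt)]
    )


def k2p_from_fractions(P: float | np.ndarray, Q: float | np.ndarray) -> float | np.ndarray:
    """Kimura two-parameter distance from transition/transversion fractions.

    Saturated inputs (log argument <= 0) give ``inf``.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = (1.0 - 2.0 * np.asarray(P) - np.asarray(Q)) * np.sqrt(
            np.maximum(1.0 - 2.0 * np.asarray(Q), 0.0)
        )
        d = np.where(arg > 0.0, -0.5 * np.log(np.maximum(arg, 1e-300)), np.inf)
    return float(d) if np.ndim(d) == 0 else d


def k2p_distance(
    gm: GenotypeMatrix,
    seed: int | None = 0,
    weights: np.ndarray | None = None,
    calls: np.ndarray | None = None,
) -> DistanceMatrix:
    """K2P distance matrix on consensus pseudo-sequences.

    Saturated pairs are reported as ``inf`` with a warning.  ``calls`` lets
    a caller reuse pseudo-sequences across bootstrap replicates.
    """
    if calls is None:
        calls = pseudo_sequences(gm, seed)
    w = np.ones(gm.n_sites) if weights is None else np.asarray(weights, float)
    ts = transition_mask(gm)
    obs = (calls != -1).astype(np.float64)
    ref_is = (calls == 0).astype(np.float64)
    alt_is = (calls == 1).astype(np.float64)
    n_pair = (obs * w) @ obs.T
    diff_ts = ((ref_is * (w * ts)) @ alt_is.T) + ((alt_is * (w * ts)) @ ref_is.T)
    diff_tv = ((ref_is * (w * ~ts)) @ alt_is.T) + ((alt_is * (w * ~ts)) @ ref_is.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = diff_ts / n_pair
        Q = diff_tv / n_pair
    d = np.asarray(k2p_from_fractions(P, Q))
    np.fill_diagonal(d, 0.0)
    n_sat = int(np.sum(np.isinf(d)) // 2)
    if n_sat:
        # saturation sentinel stays +inf; callers building trees must
        # substitute a finite ceiling first
        warnings.warn(f"{n_sat} sample pairs at K2P saturation (distance=inf)", stacklevel=2)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=gm.samples)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _edge_length(node: TreeNode, raw: float, clamp: bool) -> None:
    node.raw_length = float(raw)
    node.length = max(0.0, float(raw)) if clamp else float(raw)


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou–Nei neighbor joining; unrooted (trifurcating root) TreeNode.

    Exact on additive matrices: the generating topology and branch lengths
    are recovered.  Tie-break at each agglomeration step: the row-major
    first minimum of the Q-matrix in the current node order (initially the
    distance-matrix id order).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    D = dm.data.astype(np.float64).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        _edge_length(nodes[i], li, clamp_negative)
        _edge_length(nodes[j], lj, clamp_negative)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [x for x in range(k) if x != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    root = TreeNode()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = [
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ]
        for node, L in zip(nodes, lengths):
            _edge_length(node, L, clamp_negative)
            root.append(node)
    else:  # two taxa: a single edge, split evenly
        for node in nodes:
            _edge_length(node, D[0, 1] / 2.0, clamp_negative)
            root.append(node)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, one canonical side each.

    The side not containing the lexicographically smallest taxon is kept;
    splits separating fewer than two taxa are dropped.
    """
    taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if ref in side:
            side = taxa - side
        splits.add(side)
    return splits


def _distance_for(
    gm: GenotypeMatrix, kind: str, weights: np.ndarray | None, seed: int | None,
    calls: np.ndarray | None = None,
) -> DistanceMatrix:
    if kind == "ibs":
        return ibs_distance(gm, weights=weights)
    if kind == "k2p":
        return k2p_distance(gm, seed=seed, weights=weights, calls=calls)
    raise ValueError(f"unknown distance kind {kind!r}; use 'ibs' or 'k2p'")


def bootstrap_support(
    gm: GenotypeMatrix,
    distance_kind: str = "ibs",
    n_reps: int = 1000,
    seed: int | None = 0,
    clamp_negative: bool = True,
) -> TreeNode:
    """NJ tree with per-internal-edge bootstrap support in [0, 1].

    Site columns are resampled with replacement ``n_reps`` times; the
    support of each internal bipartition of the full-data tree is the
    fraction of replicate trees containing it, written both to
    ``node.support`` and, in the conventional style, to the internal node
    name.  Reproducible under a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    calls = pseudo_sequences(gm, seed) if distance_kind == "k2p" else None
    main = nj_tree(_distance_for(gm, distance_kind, None, seed, calls), clamp_negative)
    ref_splits = bipartitions(main)
    hits = {s: 0 for s in ref_splits}
    m = gm.n_sites
    p = np.full(m, 1.0 / m)
    for _ in range(n_reps):
        w = rng.multinomial(m, p).astype(np.float64)
        rep = nj_tree(_distance_for(gm, distance_kind, w, seed, calls), clamp_negative)
        for s in bipartitions(rep):
            if s in hits:
                hits[s] += 1
    taxa = frozenset(gm.samples)
    ref = min(taxa)
    for node in main.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = side if ref not in side else taxa - side
        support = hits[key] / n_reps
        node.support = support
        node.name = f"{support:.3f}"
    return main


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Top-k principal-component scores with the full eigenvalue spectrum."""

    samples: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # descending, full spectrum
    variance_explained: np.ndarray  # fractions aligned with eigenvalues


def pca(gm: GenotypeMatrix, k: int = 10) -> PCAResult:
    """Patterson-normalised PCA of the dosage matrix.

    Normalised dosage: ``(d - 2*p) / sqrt(p*(1 - p))`` with p the observed
    alternate-allele frequency at the site; missing cells are zero after
    centring; monomorphic (or all-missing) sites are skipped.  Eigenvalues
    come from the sample covariance ``Z Z^T / m``; coordinates are the
    projections ``U * sqrt(m * eigenvalue)``.
    """
    from .genotype_io import allele_frequencies

    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least two samples for PCA")
    if k > n - 1:
        warnings.warn(f"k={k} clipped to n_samples-1={n - 1}", stacklevel=2)
        k = n - 1
    freq = allele_frequencies(gm)
    poly = np.isfinite(freq) & (freq > 0.0) & (freq < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    d = gm.dosages[:, poly].astype(np.float64)
    p = freq[poly]
    Z = (d - 2.0 * p) / np.sqrt(p * (1.0 - p))
    Z[gm.dosages[:, poly] == MISSING] = 0.0
    m = Z.shape[1]
    C = (Z @ Z.T) / m
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    coords = evecs[:, :k] * np.sqrt(m * evals[:k])
    total = evals.sum()
    var_frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(
        samples=list(gm.samples),
        coordinates=coords,
        eigenvalues=evals,
        variance_explained=var_frac,
    )
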