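"""Telomere phylogenetics: alignment, K2P distances, NJ, bootstrap, congruence.

Telomere sequences evolve fast and are occasionally exchanged wholesale
between replicons; comparing a neighbor-joining tree of telomeres with the
strain (genome) tree exposes such swaps as topological incongruence.  The
chain implemented here mirrors the classical MEGA-style workflow: progressive
multiple alignment, removal of low-coverage columns, Kimura two-parameter
distances with pairwise deletion, Saitou-Nei neighbor joining, nonparametric
bootstrap over columns, and Robinson-Foulds-style bipartition comparison
against a user-supplied genome tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from linearends._seq import revcomp  # noqa: F401  (re-exported convenience)

GAP = "-"

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -5.0, -1.0


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class TelomereAlignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def site_coverage(self) -> np.ndarray:
        mat = np.array([list(r) for r in self.rows])
        return (mat != GAP).mean(axis=0)

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _pair_align(a: str, b: str) -> tuple[str, str, float]:
    """Global Needleman-Wunsch with affine gaps, deterministic traceback."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def _profile_cols(rows: Sequence[str]) -> list[str]:
    return ["".join(r[j] for r in rows) for j in range(len(rows[0]))]


def _col_score(ca: str, cb: str) -> float:
    s = 0.0
    n = 0
    for x in ca:
        for y in cb:
            if x == GAP or y == GAP:
                continue
            s += MATCH if x == y else MISMATCH
            n += 1
    return s / n if n else 0.0


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap profile-profile alignment (sum-of-pairs column scores)."""
    ca, cb = _profile_cols(rows_a), _profile_cols(rows_b)
    n, m = len(ca), len(cb)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in B (consume A column)
    Y = np.full((n + 1, m + 1), NEG)   # gap in A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    S = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = _col_score(ca[i], cb[j])
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)
    # deterministic traceback, preferring M, then X, then Y on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(ca[i - 1])
            out_b.append(cb[j - 1])
            i, j = i - 1, j - 1
            if i > 0 or j > 0:
                state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
        elif state == 1:
            out_a.append(ca[i - 1])
            out_b.append(GAP * len(cb[0]))
            state = 0 if M[i - 1, j] + GAP_OPEN >= X[i - 1, j] + GAP_EXTEND \
                else 1
            i -= 1
        else:
            out_a.append(GAP * len(ca[0]))
            out_b.append(cb[j - 1])
            state = 0 if M[i, j - 1] + GAP_OPEN >= Y[i, j - 1] + GAP_EXTEND \
                else 2
            j -= 1
    out_a.reverse()
    out_b.reverse()
    rows_a2 = ["".join(c[r] for c in out_a) for r in range(len(rows_a))]
    rows_b2 = ["".join(c[r] for c in out_b) for r in range(len(rows_b))]
    return rows_a2, rows_b2


def align_telomeres(seqs: Sequence[tuple[str, str]]) -> TelomereAlignment:
    """Progressive multiple alignment.

    All-pairs global alignment (+1/-1, gap -5/-1) gives p-distances; a UPGMA
    guide tree orders profile-profile merges.  Fully deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    names = [n for n, _ in seqs]
    raw = [s for _, s in seqs]
    k = len(raw)
    pd = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ra, rb, _ = _pair_align(raw[i], raw[j])
            ident = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
            pd[i, j] = pd[j, i] = 1.0 - ident / len(ra)
    cond = pd[np.triu_indices(k, 1)]
    Z = linkage(cond, method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(k)}
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        ids_a, rows_a = clusters.pop(ia)
        ids_b, rows_b = clusters.pop(ib)
        rows_a2, rows_b2 = _profile_align(rows_a, rows_b)
        clusters[k + step] = (ids_a + ids_b, rows_a2 + rows_b2)
    ids, rows = clusters.popitem()[1]
    order = np.argsort(ids)
    return TelomereAlignment(taxa=[names[ids[i]] for i in order],
                             rows=[rows[i] for i in order])


def filter_sites(aln: TelomereAlignment,
                 min_coverage: float = 0.80) -> TelomereAlignment:
    """Drop columns with non-gap fraction strictly below ``min_coverage``."""
    cov = aln.site_coverage
    keep = np.flatnonzero(cov >= min_coverage)
    if keep.size == 0:
        raise ValueError("all columns removed by the coverage filter")
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return TelomereAlignment(taxa=list(aln.taxa), rows=rows)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

TRANSITIONS = {frozenset("AG"), frozenset("CT")}

SATURATED = np.inf


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out


def k2p_distance(aln: TelomereAlignment) -> DistanceMatrix:
    """Kimura two-parameter distances with pairwise deletion of gaps.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the transition and
    transversion proportions over mutually ungapped sites.  Pairs whose log
    arguments are <= 0 are flagged saturated (d = inf).
    """
    n = len(aln.taxa)
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = aln.rows[i], aln.rows[j]
            tot = ts = tv = 0
            for x, y in zip(ri, rj):
                if x == GAP or y == GAP:
                    continue
                tot += 1
                if x != y:
                    if frozenset((x, y)) in TRANSITIONS:
                        ts += 1
                    else:
                        tv += 1
            if tot == 0:
                d[i, j] = d[j, i] = SATURATED
                continue
            p, q = ts / tot, tv / tot
            P[i, j] = P[j, i] = p
            Q[i, j] = Q[j, i] = q
            a1, a2 = 1 - 2 * p - q, 1 - 2 * q
            if a1 <= 0 or a2 <= 0:
                d[i, j] = d[j, i] = SATURATED
            else:
                d[i, j] = d[j, i] = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    return DistanceMatrix(taxa=list(aln.taxa), d=d, P=P, Q=Q)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    newick: str
    taxa: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def dendropy_tree(self, namespace: dendropy.TaxonNamespace | None = None
                      ) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 taxon_namespace=namespace)

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.newick, self.taxa)


def _bipartitions(newick: str, taxa: Sequence[str],
                  min_branch: float = 1e-8) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the side excluding taxa[0].

    Internal edges of (near-)zero length are collapsed first: identical
    sequences produce zero-length edges whose resolution is a tie-break
    artifact, not signal, and must not count as topology.
    """
    t = dendropy.Tree.get(data=newick, schema="newick")
    all_taxa = frozenset(taxa)
    ref = sorted(all_taxa)[0]
    out: set[frozenset] = set()
    for edge in t.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        if edge.length is not None and edge.length <= min_branch:
            continue
        leaves = frozenset(lf.taxon.label for lf in
                           edge.head_node.leaf_iter())
        if len(leaves) <= 1 or len(leaves) >= len(all_taxa) - 1:
            continue
        side = leaves if ref not in leaves else all_taxa - leaves
        out.add(side)
    return out


def nj_tree(dm: DistanceMatrix, allow_saturated: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion break on the lexicographically smallest taxon
    pair (using the smallest leaf label of each cluster).  Negative branch
    lengths are clamped to zero, the deficit moved to the sister branch.
    """
    taxa = list(dm.taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.d.copy()
    if not np.isfinite(D).all():
        if not allow_saturated:
            raise ValueError(f"saturated pairs: {dm.saturated_pairs}")
        finite = D[np.isfinite(D)]
        cap = 2 * finite.max() if finite.size else 10.0
        D[~np.isfinite(D)] = cap
    labels = [t for t in taxa]          # smallest leaf label per cluster
    nodes = [t for t in taxa]           # newick fragments
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = tuple(sorted((labels[active[ai]], labels[active[aj]])))
                cand = (q, key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2)) if m > 2 else dij / 2
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_label = min(labels[i], labels[j])
        li, lj = abs(li), abs(lj)   # normalize -0.0
        new_node = f"({nodes[i]}:{li:.10f},{nodes[j]}:{lj:.10f})"
        # distances to the new node
        dk = np.zeros(D.shape[0] + 1)
        for a in active:
            if a in (i, j):
                continue
            dk[a] = (D[i, a] + D[j, a] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dk[:-1]
        D[:-1, -1] = dk[:-1]
        labels.append(new_label)
        nodes.append(new_node)
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]

    i, j = active
    dij = max(D[i, j], 0.0)
    newick = f"({nodes[i]}:{dij/2:.10f},{nodes[j]}:{dij/2:.10f});"
    return PhyloTree(newick=newick, taxa=taxa)


def bootstrap_support(aln: TelomereAlignment, n_reps: int = 100,
                      seed: int = 0) -> PhyloTree:
    """NJ tree with column-bootstrap support percentages on internal edges."""
    if len(aln.taxa) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    main = nj_tree(k2p_distance(aln), allow_saturated=True)
    target = main.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    L = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep = TelomereAlignment(taxa=list(aln.taxa), rows=rows)
        try:
            t = nj_tree(k2p_distance(rep), allow_saturated=True)
        except ValueError:
            continue
        found = t.bipartitions()
        for b in target:
            if b in found:
                counts[b] += 1
    main.support = {b: 100.0 * c / n_reps for b, c in counts.items()}
    return main


# ---------------------------------------------------------------------------
# congruence
# ---------------------------------------------------------------------------

@dataclass
class IncongruenceReport:
    shared_bipartitions: set[frozenset]
    conflicts_genome: set[frozenset]    # in genome tree only
    conflicts_telomere: set[frozenset]  # in telomere tree only
    moved_pairs: list[tuple[str, str, str]]  # (leaf, partner_genome, partner_telo)
    incongruent_leaves: list[str]

    @property
    def rf_distance(self) -> int:
        return len(self.conflicts_genome) + len(self.conflicts_telomere)


def _cherry_partners(newick: str) -> dict[str, str]:
    t = dendropy.Tree.get(data=newick, schema="newick")
    out: dict[str, str] = {}
    for node in t.preorder_node_iter():
        kids = node.child_nodes()
        leaves = [c for c in kids if c.is_leaf()]
        if len(leaves) == 2 and len(kids) == 2:
            a, b = (lf.taxon.label for lf in leaves)
            out[a] = b
            out[b] = a
    return out


def compare_topologies(genome_tree: PhyloTree | str,
                       telomere_tree: PhyloTree | str,
                       taxa: Sequence[str] | None = None) -> IncongruenceReport:
    """Bipartition-level congruence test between genome and telomere trees.

    Conflicting bipartitions (the Robinson-Foulds components) plus leaves
    whose sister ("cherry partner") differs between the trees — the
    operational telomere-exchange signal.
    """
    if isinstance(genome_tree, str):
        gt_newick = genome_tree
        gt_taxa = _leaf_labels(genome_tree)
    else:
        gt_newick, gt_taxa = genome_tree.newick, genome_tree.taxa
    if isinstance(telomere_tree, str):
        tt_newick = telomere_tree
        tt_taxa = _leaf_labels(telomere_tree)
    else:
        tt_newick, tt_taxa = telomere_tree.newick, telomere_tree.taxa
    if set(gt_taxa) != set(tt_taxa):
        raise ValueError("leaf sets differ between trees")
    taxa = sorted(gt_taxa)
    bg = _bipartitions(gt_newick, taxa)
    bt = _bipartitions(tt_newick, taxa)
    pg = _cherry_partners(gt_newick)
    pt = _cherry_partners(tt_newick)
    moved = []
    for leaf in taxa:
        a, b = pg.get(leaf), pt.get(leaf)
        if a is not None and b is not None and a != b:
            moved.append((leaf, a, b))
    # a leaf is incongruently placed if pruning it strictly reduces the
    # number of conflicting bipartitions
    base_rf = len(bg - bt) + len(bt - bg)
    bad = []
    if base_rf:
        for leaf in taxa:
            rest = [t for t in taxa if t != leaf]
            g2 = _prune_bipartitions(bg, leaf, rest)
            t2 = _prune_bipartitions(bt, leaf, rest)
            if len(g2 - t2) + len(t2 - g2) < base_rf:
                bad.append(leaf)
    return IncongruenceReport(
        shared_bipartitions=bg & bt,
        conflicts_genome=bg - bt,
        conflicts_telomere=bt - bg,
        moved_pairs=moved,
        incongruent_leaves=bad,
    )


def _prune_bipartitions(bips: set[frozenset], leaf: str,
                        rest: Sequence[str]) -> set[frozenset]:
    """Bipartitions of the tree restricted to ``rest`` (leaf removed)."""
    ref = sorted(rest)[0]
    out: set[frozenset] = set()
    n = len(rest)
    for b in bips:
        side = frozenset(x for x in b if x != leaf)
        if ref in side:
            side = frozenset(rest) - side
        if 1 < len(side) < n - 1:
            out.add(side)
    return out


def _leaf_labels(newick: str) -> list[str]:
    t = dendropy.Tree.get(data=newick, schema="newick")
    return [lf.taxon.label for lf in t.leaf_node_iter()]


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment, terminal gap runs excluded.

    Telomeres differ in recovered length, so the denominator uses only the
    aligned overlap (local-overlap convention).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    ra, rb, _ = _pair_align(a, b)
    cols = len(ra)
    start = 0
    while start < cols and (ra[start] == GAP or rb[start] == GAP):
        start += 1
    end = cols
    while end > start and (ra[end - 1] == GAP or rb[end - 1] == GAP):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(ra[start:end], rb[start:end])
                  if x == y and x != GAP)
    return 100.0 * matches / (end - start)
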