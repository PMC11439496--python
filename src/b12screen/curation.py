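"""Tree-based curation of candidate homologue sets.

After reciprocal validation, each family's candidates are aligned, screened
by neighbour-joining trees, and curated by the protocol's rules:

* terminal branches longer than 1.0 calculated substitutions/site are
  removed iteratively, one worst offender per iteration, with the full
  align/distance/tree cycle recomputed after each removal;
* alignment columns with a non-gap fraction below 0.5 are trimmed;
* bipartition support comes from neighbour-joining bootstrap replicates;
* eukaryotic tips that resolve with bacterial homologues are classified as
  contaminants (a single library nested among prokaryotes, or near-identity
  to a bacterial sequence) or as horizontal gene transfers (the same
  bacterial-nested signal shared by two or more distinct strains of the
  same lineage group);
* tips are assigned to anchored isoform clades (e.g. the two METE isoform
  families) by the smallest bipartition side spanning the anchors.

Distances are Poisson-corrected p-distances, d = -ln(1 - p), so that branch
lengths are in substitutions/site and the 1.0 pruning threshold is
meaningful; p is capped at 0.95 to keep distances finite.

Maximum-likelihood tree inference is out of scope: every rule here operates
on any tree with branch lengths, so externally computed trees can be
supplied in newick through :class:`PhyloTree`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .registry import PipelineConfig, SequenceRecord
from .search import ScoringScheme, align_score, encode

logger = logging.getLogger("b12screen")

#: p-distances at or above this mismatch fraction are capped
P_CAP = 0.95
D_CAP = -math.log(1.0 - P_CAP)

TIP_FLAGS = ("clean", "contaminant", "hgt")
PROKARYOTE_DOMAINS = ("bacteria", "archaea")


class CurationError(ValueError):
    """Raised when an alignment or tree violates a curation precondition."""


# ---------------------------------------------------------------------------
# multiple alignment container
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise CurationError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise CurationError("an alignment needs at least 2 rows")
        ncols = len(self.rows[0])
        if any(len(r) != ncols for r in self.rows):
            raise CurationError("alignment rows differ in length")
        for i, r in enumerate(self.rows):
            if set(r) == {"-"}:
                raise CurationError(f"row {self.ids[i]!r} is all gaps")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def ungapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace("-", "")

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


def pairwise_identity(msa: MultipleAlignment) -> dict[frozenset, float]:
    """Fraction of identical residues over mutually ungapped columns."""
    arr = msa.to_array()
    gap = arr == "-"
    out: dict[frozenset, float] = {}
    for i in range(msa.n_rows):
        for j in range(i + 1, msa.n_rows):
            both = ~gap[i] & ~gap[j]
            n = int(both.sum())
            ident = float((arr[i][both] == arr[j][both]).sum() / n) if n else 0.0
            out[frozenset((msa.ids[i], msa.ids[j]))] = ident
    return out


# ---------------------------------------------------------------------------
# centre-star progressive alignment
# ---------------------------------------------------------------------------

def _profile_columns(rows: list[str], scheme: ScoringScheme) -> np.ndarray:
    """Mean substitution score of each profile column against each residue."""
    from .search import _INDEX

    S = scheme.substitution_matrix.astype(np.float64)
    cols = np.zeros((len(rows[0]), 21))
    for r in rows:
        # gap cells are encoded as X: the X row of the matrix is all zero,
        # so gaps contribute nothing to the column score
        enc = np.fromiter((_INDEX.get(c, 20) for c in r), dtype=np.intp,
                          count=len(r))
        cols += S[enc]
    return cols / len(rows)


def _global_profile_seq(rows: list[str], seq: str, scheme: ScoringScheme
                        ) -> list[tuple[Optional[int], Optional[int]]]:
    """Global affine alignment of a profile (list of gapped rows) to a
    sequence; returns the column path as (profile_col, seq_pos) pairs with
    ``None`` marking a gap on that side."""
    cols = _profile_columns(rows, scheme)
    eseq = encode(seq)
    na, nb = cols.shape[0], len(eseq)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    NEG = -1e12
    M = np.full((na + 1, nb + 1), NEG)
    Ix = np.full((na + 1, nb + 1), NEG)
    Iy = np.full((na + 1, nb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        Ix[i, 0] = -go - ge * (i - 1)
    j_idx = np.arange(nb + 1, dtype=np.float64)
    Iy[0, 1:] = -go - ge * (j_idx[1:] - 1)
    for i in range(1, na + 1):
        srow = cols[i - 1][eseq]
        prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev[:-1] + srow
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        t = M[i] + ge * j_idx
        cm = np.maximum.accumulate(t)
        Iy[i, 1:] = cm[:-1] - go - ge * (j_idx[1:] - 1)
    # traceback; tie-break prefers diagonal, then vertical, then horizontal
    i, j = na, nb
    state = max(("M", "Ix", "Iy"),
                key=lambda s: {"M": M, "Ix": Ix, "Iy": Iy}[s][i, j] -
                {"M": 0.0, "Ix": 1e-9, "Iy": 2e-9}[s])
    eps = 1e-6
    path: list[tuple[Optional[int], Optional[int]]] = []
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            target = M[i, j] - cols[i - 1][eseq[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - target) < eps:
                state = "M"
            elif abs(Ix[i, j] - target) < eps:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":  # profile column against gap
            path.append((i - 1, None))
            opened = abs(M[i - 1, j] - go - Ix[i, j]) < eps
            i -= 1
            state = "M" if opened else "Ix"
        else:  # sequence residue against gap
            path.append((None, j - 1))
            opened = abs(M[i, j - 1] - go - Iy[i, j]) < eps
            j -= 1
            state = "M" if opened else "Iy"
    path.reverse()
    return path


def profile_align(seqs: Sequence[SequenceRecord],
                  scheme: Optional[ScoringScheme] = None,
                  pairwise_scores: Optional[np.ndarray] = None
                  ) -> MultipleAlignment:
    """Centre-star progressive multiple alignment.

    The centre is the sequence maximizing its summed pairwise local
    alignment score against all others (ties go to the earliest input);
    the remaining sequences are merged one by one, most-similar first, by
    global affine DP against the growing profile, with existing gaps
    propagated ("once a gap, always a gap").  ``pairwise_scores`` may carry
    a precomputed square score matrix to skip the centre-selection sweeps.
    Output rows are returned in input order; ungapping any row reproduces
    its input sequence.
    """
    scheme = scheme or ScoringScheme()
    if len(seqs) < 2:
        raise CurationError("profile_align needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise CurationError("duplicate sequence ids in alignment input")
    if pairwise_scores is None:
        from .search import score_many
        n = len(seqs)
        pairwise_scores = np.zeros((n, n))
        enc = [encode(s.sequence) for s in seqs]
        for i in range(n):
            pairwise_scores[i] = score_many(enc[i], enc, scheme)
    sums = pairwise_scores.sum(axis=1) - np.diag(pairwise_scores)
    centre = int(np.argmax(sums))  # argmax takes the first on ties
    order = sorted((k for k in range(len(seqs)) if k != centre),
                   key=lambda k: (-pairwise_scores[centre, k], k))
    aligned_rows = [seqs[centre].sequence]
    aligned_idx = [centre]
    for k in order:
        path = _global_profile_seq(aligned_rows, seqs[k].sequence, scheme)
        new_rows = ["" for _ in aligned_rows]
        new_row = ""
        for pcol, spos in path:
            for r, row in enumerate(aligned_rows):
                new_rows[r] += row[pcol] if pcol is not None else "-"
            new_row += seqs[k].sequence[spos] if spos is not None else "-"
        aligned_rows = new_rows + [new_row]
        aligned_idx.append(k)
    by_idx = dict(zip(aligned_idx, aligned_rows))
    return MultipleAlignment(ids=list(ids),
                             rows=[by_idx[i] for i in range(len(seqs))])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances in substitutions/site."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise CurationError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise CurationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise CurationError("distance matrix has a non-zero diagonal")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise CurationError("distances must be finite and non-negative")
        self.matrix = m


#: pairs already warned about (complementary split gene models keep
#: producing the same capped distance in every pruning/bootstrap round)
_warned_pairs: set[frozenset] = set()


def poisson_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Poisson-corrected pairwise distances, d = -ln(1 - p).

    p is the mismatch fraction over columns where both rows are ungapped
    (columns where either residue is the ambiguity code X are also
    excluded).  Pairs with p >= 0.95, or with no mutually ungapped columns
    at all, are set to the cap d = -ln(0.05) ~ 3.0.
    """
    arr = msa.to_array()
    usable = (arr != "-") & (arr != "X")
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = usable[i] & usable[j]
            m = int(both.sum())
            if m == 0:
                pair = frozenset((msa.ids[i], msa.ids[j]))
                if pair not in _warned_pairs:
                    _warned_pairs.add(pair)
                    logger.warning(
                        "rows %s and %s share no ungapped columns; distance "
                        "capped", msa.ids[i], msa.ids[j])
                dij = D_CAP
            else:
                p = float((arr[i][both] != arr[j][both]).sum() / m)
                dij = D_CAP if p >= P_CAP else -math.log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(msa.ids), matrix=d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children", "length")

    def __init__(self, label: Optional[str] = None,
                 length: float = 0.0) -> None:
        self.label = label
        self.children: list["_Node"] = []
        self.length = length  # length of the edge above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An unrooted tree with branch lengths, tip annotations and support.

    Internally the topology is stored rooted at an arbitrary internal node
    (with three children for a fully unrooted binary tree); every rule in
    this module is phrased in terms of bipartitions, so the storage rooting
    carries no meaning.
    """

    def __init__(self, root: _Node,
                 annotations: Optional[dict[str, dict]] = None,
                 support: Optional[dict[frozenset, float]] = None) -> None:
        self.root = root
        self.annotations = annotations or {}
        self.support = support or {}
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise CurationError("tip labels are not unique")
        if len(labels) < 3:
            raise CurationError("a tree needs at least 3 tips")

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, **kw) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
        return cls.from_dendropy(dtree, **kw)

    @classmethod
    def from_dendropy(cls, dtree, **kw) -> "PhyloTree":
        def build(dnode) -> _Node:
            node = _Node(
                label=dnode.taxon.label if dnode.taxon else None,
                length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.children.append(build(child))
            return node

        return cls(build(dtree.seed_node), **kw)

    def to_newick(self, with_support: bool = False) -> str:
        all_tips = frozenset(self.tip_labels())
        anchor = min(all_tips)

        def fmt(node: _Node, top: bool) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(fmt(c, False) for c in node.children)
            sup = ""
            if with_support and not top:
                side = self._tipset(node)
                canon = side if anchor in side else all_tips - side
                if canon in self.support:
                    sup = f"{self.support[canon]:.2f}"
            if top:
                return f"({inner}){sup};"
            return f"({inner}){sup}:{node.length:.6f}"

        return fmt(self.root, True)

    # -- basic queries -------------------------------------------------------
    def _tipset(self, node: _Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        out: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.add(cur.label)
            else:
                stack.extend(cur.children)
        return frozenset(out)

    def tip_labels(self) -> list[str]:
        out = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                out.append(node.label)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def terminal_branch_lengths(self) -> dict[str, float]:
        out = {}

        def walk(node: _Node) -> None:
            if node.is_leaf:
                out[node.label] = node.length
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def edge_sides(self) -> list[frozenset]:
        """One tip set per edge: the tips on the child side of the edge."""
        sides = []

        def walk(node: _Node) -> None:
            for c in node.children:
                sides.append(self._tipset(c))
                walk(c)

        walk(self.root)
        return sides

    def has_bipartition(self, tipset: frozenset) -> bool:
        all_tips = frozenset(self.tip_labels())
        target = frozenset(tipset)
        for side in self.edge_sides():
            if side == target or all_tips - side == target:
                return True
        return False

    def smallest_side_containing(self, tip: str, min_size: int = 3
                                 ) -> frozenset:
        """The smallest bipartition side containing ``tip`` with at least
        ``min_size`` tips; ties resolved by sorted tip labels."""
        all_tips = frozenset(self.tip_labels())
        candidates = []
        for side in self.edge_sides():
            for oriented in (side, all_tips - side):
                if tip in oriented and len(oriented) >= min_size:
                    candidates.append(oriented)
        if not candidates:
            raise CurationError(f"no bipartition side of size >= {min_size} "
                                f"contains tip {tip!r}")
        return min(candidates, key=lambda s: (len(s), tuple(sorted(s))))

    def path_length_matrix(self) -> DistanceMatrix:
        """Patristic distances between all tip pairs."""
        labels = sorted(self.tip_labels())
        index = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: _Node) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.label]: 0.0}
            below: dict[int, float] = {}
            for child in node.children:
                sub = {k: v + child.length for k, v in walk(child).items()}
                for k1, v1 in below.items():
                    for k2, v2 in sub.items():
                        d[k1, k2] = d[k2, k1] = v1 + v2
                below.update(sub)
            return below

        walk(self.root)
        return DistanceMatrix(labels=labels, matrix=d)

def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbour joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of cluster representative labels (a cluster is represented by its
    smallest tip label).  Negative branch-length estimates are clamped to
    zero with the deficit transferred to the sibling branch, preserving the
    joined pair's distance.
    """
    n = len(D.labels)
    if n < 3:
        raise CurationError("neighbour joining needs at least 3 labels")
    d = D.matrix.astype(float).copy()
    nodes = [_Node(label=lab) for lab in D.labels]
    reps = list(D.labels)
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-10)
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        if vi < 0:
            vi, vj = 0.0, d[i, j]
        elif vj < 0:
            vi, vj = d[i, j], 0.0
        parent = _Node()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.children = [nodes[i], nodes[j]]
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = np.maximum(dnew[keep], 0.0)
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        d = d2
    root = _Node()
    if len(nodes) == 3:
        (a, b, c) = nodes
        da, db, dc = d[0, 1], d[0, 2], d[1, 2]
        a.length = max(0.0, 0.5 * (da + db - dc))
        b.length = max(0.0, 0.5 * (da + dc - db))
        c.length = max(0.0, 0.5 * (db + dc - da))
        root.children = [a, b, c]
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# iterative long-branch pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneResult:
    retained: list[SequenceRecord]
    removed_log: list[dict]
    unalignable: bool = False
    msa: Optional[MultipleAlignment] = None
    tree: Optional[PhyloTree] = None


def prune_divergent(seqs: Sequence[SequenceRecord],
                    config: Optional[PipelineConfig] = None,
                    scheme: Optional[ScoringScheme] = None) -> PruneResult:
    """Iteratively remove tips whose terminal branch exceeds the threshold.

    Each iteration realigns the remaining sequences, rebuilds the
    neighbour-joining tree and removes the single worst offender whose
    terminal branch is strictly greater than ``branch_length_threshold``
    (1.0 substitutions/site by default); a branch of exactly the threshold
    is retained.  Removal stops when no offender remains or when another
    removal would leave fewer than 4 sequences, in which case the set is
    flagged unalignable.
    """
    config = config or PipelineConfig()
    scheme = scheme or ScoringScheme()
    if len(seqs) < 4:
        raise CurationError("prune_divergent needs at least 4 sequences")
    from .search import score_many

    enc = [encode(s.sequence) for s in seqs]
    full_scores = np.zeros((len(seqs), len(seqs)))
    for i in range(len(seqs)):
        full_scores[i] = score_many(enc[i], enc, scheme)
    current = list(seqs)
    idx = list(range(len(seqs)))
    removed_log: list[dict] = []
    iteration = 0
    while True:
        iteration += 1
        msa = profile_align(current, scheme,
                            pairwise_scores=full_scores[np.ix_(idx, idx)])
        tree = nj_tree(poisson_distance(msa))
        lengths = tree.terminal_branch_lengths()
        offenders = {lab: ln for lab, ln in lengths.items()
                     if ln > config.branch_length_threshold}
        if not offenders:
            return PruneResult(current, removed_log, False, msa, tree)
        if len(current) <= 4:
            logger.warning("long branches remain but only %d sequences left; "
                           "flagging set as unalignable", len(current))
            return PruneResult(current, removed_log, True, msa, tree)
        worst = max(offenders, key=lambda lab: (offenders[lab], lab))
        removed_log.append({"id": worst, "branch_length": offenders[worst],
                            "iteration": iteration})
        pos = next(k for k, s in enumerate(current) if s.id == worst)
        current.pop(pos)
        idx.pop(pos)


# ---------------------------------------------------------------------------
# column trimming
# ---------------------------------------------------------------------------

def trim_columns(msa: MultipleAlignment,
                 config: Optional[PipelineConfig] = None) -> MultipleAlignment:
    """Keep columns whose non-gap fraction is >= the gap threshold.

    A column at exactly the threshold is kept.  Rows that become all-gap
    are dropped with a warning; a result with zero columns is an error.
    """
    config = config or PipelineConfig()
    arr = msa.to_array()
    nongap_frac = (arr != "-").mean(axis=0)
    keep = nongap_frac >= config.gap_threshold
    if not keep.any():
        raise CurationError("column trimming removed every column")
    trimmed = arr[:, keep]
    ids, rows = [], []
    for rid, row in zip(msa.ids, trimmed):
        joined = "".join(row)
        if set(joined) == {"-"}:
            logger.warning("row %s became all-gap after trimming; dropped",
                           rid)
            continue
        ids.append(rid)
        rows.append(joined)
    return MultipleAlignment(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def _canonical_sides(tree: PhyloTree) -> set[frozenset]:
    all_tips = frozenset(tree.tip_labels())
    anchor = min(all_tips)
    out = set()
    for side in tree.edge_sides():
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side if anchor in side else all_tips - side)
    return out


def bootstrap_support(msa: MultipleAlignment, n_reps: int, seed: int,
                      config: Optional[PipelineConfig] = None) -> PhyloTree:
    """Neighbour-joining bootstrap: resample columns with replacement,
    rebuild the tree per replicate, and attach to each internal bipartition
    of the point-estimate tree the fraction of replicates containing it."""
    if n_reps < 1:
        raise CurationError("n_reps must be >= 1")
    tree = nj_tree(poisson_distance(msa))
    counts: dict[frozenset, int] = {side: 0 for side in _canonical_sides(tree)}
    rng = np.random.default_rng(seed)
    arr = msa.to_array()
    for _ in range(n_reps):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep = MultipleAlignment(
            ids=list(msa.ids),
            rows=["".join(r) for r in arr[:, cols]])
        rep_sides = _canonical_sides(nj_tree(poisson_distance(rep)))
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    tree.support = {side: c / n_reps for side, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# contaminant / HGT discrimination
# ---------------------------------------------------------------------------

def flag_contaminants(tree: PhyloTree,
                      identities: Mapping[frozenset, float] |
                      Callable[[str, str], float],
                      config: Optional[PipelineConfig] = None
                      ) -> dict[str, str]:
    """Classify each eukaryotic tip as clean, contaminant or hgt.

    A eukaryotic tip is a contaminant if (a) its pairwise identity to any
    prokaryotic tip reaches the contaminant identity threshold (99% by
    default), or (b) the smallest clade containing it and at least two
    other tips consists otherwise entirely of prokaryotic tips and it is
    the only library from its lineage group there.  If the bacterial-nested
    signal of (b) is instead shared by two or more distinct strains of the
    same lineage group, those tips are flagged as horizontal gene transfers,
    not contaminants.

    Tips must carry ``domain`` (bacteria/archaea/eukaryote) annotations;
    eukaryotic tips additionally ``lineage_group`` and ``strain`` (or
    ``library_id``).  Prokaryotic tips are reported as clean.
    """
    config = config or PipelineConfig()
    if callable(identities):
        ident = identities
    else:
        lookup = dict(identities)

        def ident(a: str, b: str) -> float:
            return lookup.get(frozenset((a, b)), 0.0)

    tips = tree.tip_labels()
    missing = [t for t in tips if t not in tree.annotations
               or "domain" not in tree.annotations[t]]
    if missing:
        raise CurationError(f"tips without domain annotation: {sorted(missing)}")

    def domain(t: str) -> str:
        return tree.annotations[t]["domain"]

    def group(t: str) -> str:
        return tree.annotations[t].get("lineage_group", "")

    def strain(t: str) -> str:
        ann = tree.annotations[t]
        return ann.get("strain") or ann.get("library_id") or t

    prokaryotes = [t for t in tips if domain(t) in PROKARYOTE_DOMAINS]
    flags: dict[str, str] = {t: "clean" for t in tips}
    # pass 1: per-tip conditions.  (a) near-identity to a prokaryote;
    # (b) the smallest clade around the tip holds at least one prokaryote
    # and no eukaryote from any other lineage group (the tip "resolves
    # with bacterial homologues").
    nested: dict[str, list[str]] = {}  # tip -> same-group companions
    for t in tips:
        if domain(t) in PROKARYOTE_DOMAINS:
            continue
        if any(ident(t, p) >= config.contaminant_identity_threshold
               for p in prokaryotes):
            flags[t] = "contaminant"
            continue
        clade = tree.smallest_side_containing(t, min_size=3)
        others = clade - {t}
        euk_others = [o for o in others if domain(o) not in PROKARYOTE_DOMAINS]
        if len(euk_others) == len(others):
            continue  # no prokaryote in the neighbourhood: vertical signal
        if any(group(o) != group(t) for o in euk_others):
            continue  # mixed eukaryotic company: rule not triggered
        nested[t] = euk_others
    # pass 2: the transfer exemption.  A bacterial-nested signal shared by
    # two or more distinct strains of one lineage group marks an ancestral
    # acquisition, not contamination; a single strain (however many of its
    # libraries) is called a contaminant.
    by_group: dict[str, set[str]] = {}
    for t, companions in nested.items():
        by_group.setdefault(group(t), set()).update(
            strain(s) for s in [t] + companions)
    for t in nested:
        if len(by_group[group(t)]) >= 2:
            flags[t] = "hgt"
        else:
            flags[t] = "contaminant"
    return flags


# ---------------------------------------------------------------------------
# anchored clade assignment
# ---------------------------------------------------------------------------

def assign_isoform_clade(tree: PhyloTree,
                         anchors: Mapping[str, set[str]]) -> dict[str, str]:
    """Assign each tip to the anchored clade it falls in, or 'unassigned'.

    For each label the smallest bipartition side spanning all of its anchor
    tips is taken as the anchored clade; it must contain no anchor of any
    other label, otherwise the anchor sets are not separable by any edge
    and an error is raised.
    """
    all_tips = frozenset(tree.tip_labels())
    for label, tipset in anchors.items():
        missing = set(tipset) - all_tips
        if missing:
            raise CurationError(
                f"anchor tips of {label!r} absent from tree: {sorted(missing)}")
    sides = set()
    for side in tree.edge_sides():
        sides.add(side)
        sides.add(all_tips - side)
    clades: dict[str, frozenset] = {}
    for label, tipset in anchors.items():
        containing = [s for s in sides if set(tipset) <= s]
        clade = min(containing, key=len)  # whole tip set always qualifies
        other_anchors = {a for lab, t in anchors.items() if lab != label
                         for a in t}
        if clade & other_anchors:
            raise CurationError(
                f"anchors of {label!r} cannot be separated from other "
                "anchor sets by any edge")
        clades[label] = clade
    assignment = {t: "unassigned" for t in all_tips}
    for label, clade in clades.items():
        for t in clade:
            if assignment[t] == "unassigned":
                assignment[t] = label
            elif assignment[t] != label:  # claimed by two labels
                assignment[t] = "unassigned"
    return assignment
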