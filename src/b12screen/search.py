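"""Forward homologue search and reciprocal best-hit validation.

The search stage is a native dynamic-programming local aligner (optimal
Smith-Waterman under affine gaps, BLOSUM62 by default) with a closed-form
Karlin-Altschul E-value, E = K * m * n * exp(-lambda * S).  Compared with a
heuristic seeded search this is strictly more sensitive and fully
deterministic, which matters because downstream curation thresholds act on
the exact hit set.  At desk scale (libraries of tens to hundreds of
proteins) the exact DP is affordable; a heuristic external search could be
slotted in behind the same operation signatures.

Candidate acceptance mirrors the screening protocol: a library sequence is a
candidate for a family if its best alignment to any family seed has
E <= 1e-5; a candidate is validated only if its best-scoring match in the
validation database (a decoy proteome representing a METE-only genome,
supplemented with all registry queries) is a query of the same family.  For
METE only, a best match to one of the three characterized Arabidopsis
methionine synthases also validates, because the decoy proteome itself
encodes METE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .registry import AA20, PipelineConfig, QueryFamily, SequenceRecord

#: residue order used for encoding; X is the last row/column and scores 0
_RESIDUES = AA20 + "X"
_INDEX = {aa: i for i, aa in enumerate(_RESIDUES)}

HIT_STATUSES = ("candidate", "validated", "rejected_reciprocal",
                "rejected_contaminant", "rejected_divergent")

VALIDATION_ROLES = ("decoy_proteome", "registry_query",
                    "arabidopsis_met_synthase")


def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            mat[i, j] = int(blosum[a, b])
    # X scores 0 against everything, including itself
    return mat


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap and Karlin-Altschul parameters.

    The gap model charges ``gap_open`` for the first residue of a gap run and
    ``gap_extend`` for each further residue, and forbids a deletion run
    immediately adjacent to an insertion run (the canonical-alignment
    convention; under protein scoring such adjacent runs are never optimal).
    """

    substitution_matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041

    def __post_init__(self) -> None:
        m = np.asarray(self.substitution_matrix)
        if m.shape not in ((20, 20), (21, 21)):
            raise ValueError("substitution matrix must be 20x20 or 21x21")
        if m.shape == (20, 20):  # pad with an all-zero X row/column
            full = np.zeros((21, 21), dtype=m.dtype)
            full[:20, :20] = m
            m = full
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin parameters must be positive")
        self.substitution_matrix = m


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into the scoring matrix."""
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:  # pragma: no cover - records are pre-validated
        raise ValueError(f"residue {exc} outside the protein alphabet") from exc


@dataclass
class LocalAlignment:
    """An optimal local alignment between two sequences.

    Spans are half-open, 0-based intervals on the unaligned sequences.
    ``identity`` is the fraction of identical residue pairs over aligned
    columns, excluding gap columns from the denominator.
    """

    score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str

    @property
    def identity(self) -> float:
        pairs = [(a, b) for a, b in zip(self.aligned_query, self.aligned_subject)
                 if a != "-" and b != "-"]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)


def _dp_matrices(a: np.ndarray, b: np.ndarray, scheme: ScoringScheme):
    """Fill the three Gotoh state matrices, row-vectorized over ``b``.

    M[i, j]  best local alignment ending with a[i-1] aligned to b[j-1]
    Ix[i, j] best ending with a[i-1] aligned to a gap (gap in subject)
    Iy[i, j] best ending with b[j-1] aligned to a gap (gap in query)
    """
    na, nb = len(a), len(b)
    S = scheme.substitution_matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    NEG = np.int64(-(10 ** 12))
    M = np.full((na + 1, nb + 1), 0, dtype=np.int64)
    Ix = np.full((na + 1, nb + 1), NEG, dtype=np.int64)
    Iy = np.full((na + 1, nb + 1), NEG, dtype=np.int64)
    j_idx = np.arange(nb + 1, dtype=np.int64)
    for i in range(1, na + 1):
        srow = S[a[i - 1], b]  # length nb
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = np.maximum(0, prev_best[:-1] + srow)
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        # Iy depends on M of the same row only: unrolled gap-run recurrence
        t = M[i] + ge * j_idx
        cm = np.maximum.accumulate(t)
        Iy[i, 1:] = cm[:-1] - go - ge * (j_idx[1:] - 1)
    return M, Ix, Iy


def align_score(a: str | np.ndarray, b: str | np.ndarray,
                scheme: ScoringScheme) -> int:
    """Optimal Smith-Waterman score only (no traceback)."""
    if isinstance(a, str):
        a = encode(a)
    if isinstance(b, str):
        b = encode(b)
    if len(a) == 0 or len(b) == 0:
        return 0
    M, _, _ = _dp_matrices(a, b, scheme)
    return int(M.max())


def score_many(query: str | np.ndarray, subjects: Sequence[str | np.ndarray],
               scheme: ScoringScheme) -> np.ndarray:
    """Optimal local alignment scores of one query against many subjects.

    All subjects are scored in a single DP sweep (the subject axis is padded
    to the longest sequence with a neutral sentinel); this is the throughput
    path used by candidate search and reciprocal validation.
    """
    if len(subjects) == 0:
        return np.zeros(0, dtype=np.int64)
    q = encode(query) if isinstance(query, str) else query
    enc = [encode(s) if isinstance(s, str) else s for s in subjects]
    if len(q) == 0:
        return np.zeros(len(enc), dtype=np.int64)
    maxlen = max(len(e) for e in enc)
    nseq = len(enc)
    B = np.full((nseq, maxlen), 20, dtype=np.intp)  # pad with X (scores 0)
    pad_mask = np.ones((nseq, maxlen), dtype=bool)
    for k, e in enumerate(enc):
        B[k, :len(e)] = e
        pad_mask[k, :len(e)] = False

    S = scheme.substitution_matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    NEG = np.int64(-(10 ** 12))
    ncol = maxlen + 1
    M = np.zeros((nseq, ncol), dtype=np.int64)
    Ix = np.full((nseq, ncol), NEG, dtype=np.int64)
    Iy = np.full((nseq, ncol), NEG, dtype=np.int64)
    j_idx = np.arange(ncol, dtype=np.int64)
    best = np.zeros(nseq, dtype=np.int64)
    for i in range(len(q)):
        srow = S[q[i]][B]          # (nseq, maxlen)
        srow[pad_mask] = NEG       # padding can never be aligned
        prev_best = np.maximum(np.maximum(M, Ix), Iy)
        newM = np.empty_like(M)
        newM[:, 0] = 0
        newM[:, 1:] = np.maximum(0, prev_best[:, :-1] + srow)
        newIx = np.empty_like(Ix)
        newIx[:, 0] = NEG
        newIx[:, 1:] = np.maximum(M[:, 1:] - go, Ix[:, 1:] - ge)
        t = newM + ge * j_idx
        cm = np.maximum.accumulate(t, axis=1)
        newIy = np.empty_like(Iy)
        newIy[:, 0] = NEG
        newIy[:, 1:] = cm[:, :-1] - go - ge * (j_idx[1:] - 1)
        M, Ix, Iy = newM, newIx, newIy
        np.maximum(best, M.max(axis=1), out=best)
    return best


def align_local(a: str, b: str, scheme: Optional[ScoringScheme] = None
                ) -> LocalAlignment:
    """Optimal local alignment with deterministic traceback.

    Tie-break during traceback prefers the diagonal move, then the vertical
    (gap in subject), then the horizontal (gap in query); among equal-scoring
    end cells the one with the smallest (query, subject) end coordinates is
    chosen.  An empty input yields the empty alignment with score 0.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        return LocalAlignment(0, (0, 0), (0, 0), "", "")
    ea, eb = encode(a), encode(b)
    M, Ix, Iy = _dp_matrices(ea, eb, scheme)
    best = int(M.max())
    if best <= 0:
        return LocalAlignment(0, (0, 0), (0, 0), "", "")
    ends = np.argwhere(M == best)
    i, j = map(int, ends[np.lexsort((ends[:, 1], ends[:, 0]))][0])
    end_i, end_j = i, j
    S = scheme.substitution_matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    out_a: list[str] = []
    out_b: list[str] = []
    state = "M"
    while True:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i, j] - S[ea[i - 1], eb[j - 1]]
            i, j = i - 1, j - 1
            if prev == 0:
                break
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":  # gap in subject, consume a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            opened = M[i - 1, j] - go == Ix[i, j]
            i -= 1
            state = "M" if opened else "Ix"
        else:  # Iy: gap in query, consume b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            opened = M[i, j - 1] - go == Iy[i, j]
            j -= 1
            state = "M" if opened else "Iy"
    return LocalAlignment(
        score=best,
        query_span=(i, end_i),
        subject_span=(j, end_j),
        aligned_query="".join(reversed(out_a)),
        aligned_subject="".join(reversed(out_b)),
    )


def estimate_evalue(score: float, m: int, n: int,
                    scheme: Optional[ScoringScheme] = None,
                    karlin_lambda: Optional[float] = None,
                    karlin_K: Optional[float] = None) -> float:
    """Karlin-Altschul expected number of chance hits: K*m*n*exp(-lambda*S)."""
    scheme = scheme or ScoringScheme()
    lam = scheme.karlin_lambda if karlin_lambda is None else karlin_lambda
    K = scheme.karlin_K if karlin_K is None else karlin_K
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    with np.errstate(under="ignore"):
        return float(K * m * n * np.exp(-lam * float(score)))


# ---------------------------------------------------------------------------
# candidate search and reciprocal validation
# ---------------------------------------------------------------------------

@dataclass
class CandidateHit:
    """A library sequence with forward-search evidence for one family.

    The status transitions append-only through ``history`` so that every
    exclusion downstream remains auditable.
    """

    record: SequenceRecord
    family: str
    best_forward: LocalAlignment
    evalue: float
    seed_id: str
    status: str = "candidate"
    history: list[str] = field(default_factory=list)

    def set_status(self, status: str) -> None:
        if status not in HIT_STATUSES:
            raise ValueError(f"unknown hit status {status!r}")
        self.history.append(self.status)
        self.status = status


@dataclass
class ValidationSequence:
    """A validation-database entry: sequence plus role tag.

    Roles: ``decoy_proteome`` (background proteome), ``registry_query``
    (a family seed; ``family`` set), ``arabidopsis_met_synthase`` (one of
    the three characterized Arabidopsis METE proteins).
    """

    record: SequenceRecord
    role: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.role not in VALIDATION_ROLES:
            raise ValueError(f"unknown validation role {self.role!r}")


@dataclass
class ValidationResult:
    hit: CandidateHit
    matched_id: str
    matched_role: str
    matched_family: str
    validated: bool


def find_candidates(family: QueryFamily, library: Sequence[SequenceRecord],
                    config: Optional[PipelineConfig] = None,
                    scheme: Optional[ScoringScheme] = None,
                    db_residues: Optional[int] = None) -> list[CandidateHit]:
    """Forward search of one family's seeds against one library.

    Every record whose best alignment to any seed reaches
    E <= forward_evalue_threshold is returned, carrying the alignment to its
    best seed (highest score; ties go to the first seed in registry order).
    ``db_residues`` is the effective database size for the E-value (defaults
    to the total residue count of the library).
    """
    config = config or PipelineConfig()
    scheme = scheme or ScoringScheme()
    if not library:
        return []
    n_db = db_residues if db_residues is not None else \
        sum(len(r.sequence) for r in library)
    enc_lib = [encode(r.sequence) for r in library]
    best_scores = np.zeros(len(library), dtype=np.int64)
    best_seed = np.zeros(len(library), dtype=np.intp)
    for s_idx, seed in enumerate(family.seed_sequences):
        scores = score_many(seed.sequence, enc_lib, scheme)
        better = scores > best_scores  # strict: ties keep the earlier seed
        best_seed[better] = s_idx
        np.maximum(best_scores, scores, out=best_scores)
    hits: list[CandidateHit] = []
    for k, rec in enumerate(library):
        seed = family.seed_sequences[int(best_seed[k])]
        ev = estimate_evalue(int(best_scores[k]), len(seed.sequence), n_db,
                             scheme)
        if ev <= config.forward_evalue_threshold:
            aln = align_local(seed.sequence, rec.sequence, scheme)
            hits.append(CandidateHit(
                record=rec, family=family.name, best_forward=aln,
                evalue=ev, seed_id=seed.id))
    return hits


def reciprocal_validate(hit: CandidateHit,
                        validation_db: Sequence[ValidationSequence],
                        config: Optional[PipelineConfig] = None,
                        scheme: Optional[ScoringScheme] = None
                        ) -> ValidationResult:
    """Reciprocal best-hit test of one candidate against the validation DB.

    The candidate is validated iff its best-scoring match (ties resolved in
    favour of registry queries over decoys, then by database order) is a
    registry query of the same family -- or, for METE only, one of the
    Arabidopsis methionine synthases.  No E-value threshold is applied to
    the reciprocal search; only the identity of the best match matters.
    """
    scheme = scheme or ScoringScheme()
    if not validation_db:
        raise ValueError("validation_db is empty; the reciprocal search "
                         "requires the decoy proteome plus registry queries")
    scores = score_many(hit.record.sequence,
                        [v.record.sequence for v in validation_db], scheme)
    top = int(scores.max())
    tied = [validation_db[i] for i in np.flatnonzero(scores == top)]
    prefer = {"registry_query": 0, "arabidopsis_met_synthase": 1,
              "decoy_proteome": 2}
    best = min(tied, key=lambda v: prefer[v.role])
    ok = (best.role == "registry_query" and best.family == hit.family) or (
        hit.family == "METE" and best.role == "arabidopsis_met_synthase")
    hit.set_status("validated" if ok else "rejected_reciprocal")
    return ValidationResult(
        hit=hit, matched_id=best.record.id, matched_role=best.role,
        matched_family=best.family, validated=ok)
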