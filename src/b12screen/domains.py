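"""Domain-architecture validation of candidate homologues.

Each query family carries a list of required protein-domain models; a
candidate only counts as a complete homologue if every required domain is
detected at E <= 1e-5.  Domain models here are lightweight position-specific
scoring matrices (PSSMs) built from seed alignments with additive
pseudocounts: presence/absence at a coarse E-value threshold is all the
downstream calls depend on, so full profile HMMs are not required, and an
external scanner's tabular output can be ingested through the same
:class:`DomainHit` contract.

PSSM entries are natural-log odds, so the Karlin-Altschul scale parameter
of the hit statistics is 1 by construction and E = K * m * n * exp(-S).

Two special behaviours mirror the screening protocol:

* genomes (never transcriptomes) may carry a single gene split across
  several gene models; when the models lie on the same scaffold their
  domain complements are merged into a single ``complete_split`` call;
* the CBA1 family has no shared domain model and is validated against a
  consensus profile built from its two characterized seed proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .registry import AA20, PipelineConfig, QueryFamily, SequenceRecord
from .search import _INDEX, ScoringScheme, align_local
from .curation import MultipleAlignment

logger = logging.getLogger("b12screen")

#: Karlin K for the log-odds profile statistics (lambda = 1 by construction)
PROFILE_K = 0.1

COMPLETENESS_STATUSES = ("complete", "partial", "absent", "complete_split")


class DomainError(ValueError):
    pass


@dataclass
class ProfileModel:
    """A position-specific log-odds scoring profile for one domain."""

    id: str
    scores: np.ndarray  # (length, 20) natural-log odds
    background: np.ndarray  # (20,) residue frequencies, sums to 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise DomainError("profile scores must have shape (length, 20)")
        if self.length < 5:
            raise DomainError(
                f"profile {self.id!r}: length {self.length} < 5")
        if not np.all(np.isfinite(self.scores)):
            raise DomainError(f"profile {self.id!r}: non-finite scores")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise DomainError(f"profile {self.id!r}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class DomainHit:
    """One profile match on a sequence (0-based half-open span)."""

    profile_id: str
    span: tuple[int, int]
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise DomainError("E-value must be >= 0")
        if self.span[0] < 0 or self.span[1] < self.span[0]:
            raise DomainError(f"invalid span {self.span}")


@dataclass
class CompletenessCall:
    """Domain-completeness verdict for one family on one record (or, after
    split-model rescue, on a set of records sharing a scaffold)."""

    family: str
    status: str
    missing_domains: list[str] = field(default_factory=list)
    contributing_records: list[str] = field(default_factory=list)
    found_domains: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in COMPLETENESS_STATUSES:
            raise DomainError(f"unknown completeness status {self.status!r}")
        if self.status in ("complete", "complete_split") and self.missing_domains:
            raise DomainError("complete call cannot list missing domains")


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profile(seed_msa: MultipleAlignment, pseudocount: float = 0.5,
                  profile_id: str = "",
                  background: Optional[np.ndarray] = None) -> ProfileModel:
    """Position-specific log-odds profile from a seed alignment.

    score[c, a] = ln( (count[c, a] + alpha) / (n[c] + 20 * alpha)
                      / background[a] )

    where n[c] counts the non-gap residues in column c; the ambiguity code X
    is treated as missing.  Columns with more than 50% gaps are excluded
    from the model.  The default background is uniform.
    """
    if pseudocount <= 0:
        raise DomainError("pseudocount must be > 0")
    bg = (np.full(20, 0.05) if background is None
          else np.asarray(background, dtype=float))
    arr = seed_msa.to_array()
    keep = (arr == "-").mean(axis=0) <= 0.5
    if not keep.any():
        raise DomainError("every column of the seed alignment is gappy")
    arr = arr[:, keep]
    ncols = arr.shape[1]
    counts = np.zeros((ncols, 20))
    for c in range(ncols):
        for ch in arr[:, c]:
            if ch not in ("-", "X"):
                counts[c, _INDEX[ch]] += 1
    n = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        scores = np.log((counts + pseudocount) / (n + 20.0 * pseudocount) / bg)
    return ProfileModel(id=profile_id or "profile", scores=scores,
                        background=bg)


def single_sequence_profile(seq: str, profile_id: str,
                            pseudocount: float = 0.5) -> ProfileModel:
    """PSSM from a single consensus sequence (a degenerate seed alignment)."""
    bg = np.full(20, 0.05)
    counts = np.zeros((len(seq), 20))
    for c, ch in enumerate(seq):
        if ch != "X":
            counts[c, _INDEX[ch]] += 1
    n = counts.sum(axis=1, keepdims=True)
    scores = np.log((counts + pseudocount) / (n + 20.0 * pseudocount) / bg)
    return ProfileModel(id=profile_id, scores=scores, background=bg)


def consensus_profile(seq_a: SequenceRecord, seq_b: SequenceRecord,
                      scheme: Optional[ScoringScheme] = None,
                      pseudocount: float = 0.5,
                      profile_id: str = "consensus") -> ProfileModel:
    """Two-sequence consensus profile (the CBA1 validation model).

    The sequences are aligned pairwise (optimal local alignment, globalized
    by extending both ends), and the resulting 2-row alignment is turned
    into a PSSM.  A warning is logged when the pair aligns at under 10%
    identity, as the profile is then weakly informative.
    """
    scheme = scheme or ScoringScheme()
    aln = align_local(seq_a.sequence, seq_b.sequence, scheme)
    if aln.identity < 0.1:
        logger.warning(
            "consensus profile %s: parents align at %.1f%% identity; "
            "profile is weakly informative", profile_id, 100 * aln.identity)
    a, b = seq_a.sequence, seq_b.sequence
    (qs, qe), (ss, se) = aln.query_span, aln.subject_span
    # globalize: unaligned prefixes/suffixes become opposing gap runs
    row_a = (a[:qs] + "-" * ss + aln.aligned_query
             + a[qe:] + "-" * (len(b) - se))
    row_b = ("-" * qs + b[:ss] + aln.aligned_subject
             + "-" * (len(a) - qe) + b[se:])
    msa = MultipleAlignment(ids=[seq_a.id, seq_b.id], rows=[row_a, row_b])
    return build_profile(msa, pseudocount=pseudocount, profile_id=profile_id)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _best_segment(profile: ProfileModel, enc: np.ndarray
                  ) -> tuple[float, tuple[int, int]]:
    """Best-scoring gapless local match of the profile on the sequence.

    Maximum-sum contiguous segment over every profile/sequence diagonal;
    X residues score 0 at every position.
    """
    L, S = profile.length, len(enc)
    scores = np.hstack([profile.scores, np.zeros((L, 1))])  # X column
    best, best_span = 0.0, (0, 0)
    for d in range(-(L - 1), S):
        i0, j0 = (-d, 0) if d < 0 else (0, d)
        n = min(L - i0, S - j0)
        if n <= 0:
            continue
        diag = scores[np.arange(i0, i0 + n), enc[j0:j0 + n]]
        csum = np.concatenate([[0.0], np.cumsum(diag)])
        run_min = np.minimum.accumulate(csum[:-1])
        gains = csum[1:] - run_min
        k = int(np.argmax(gains))
        if gains[k] > best:
            start = int(np.argmin(csum[:k + 1]))
            best = float(gains[k])
            best_span = (j0 + start, j0 + k + 1)
    return best, best_span


def scan_domains(seq: str | SequenceRecord,
                 profiles: Sequence[ProfileModel],
                 config: Optional[PipelineConfig] = None) -> list[DomainHit]:
    """Scan a sequence with a set of profiles; hits at E <= threshold are
    returned sorted by sequence position."""
    config = config or PipelineConfig()
    if isinstance(seq, SequenceRecord):
        seq = seq.sequence
    if not seq:
        raise DomainError("cannot scan an empty sequence")
    enc = np.fromiter((_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    hits: list[DomainHit] = []
    for prof in profiles:
        score, span = _best_segment(prof, enc)
        evalue = PROFILE_K * prof.length * len(seq) * math.exp(-score)
        if evalue <= config.domain_evalue_threshold:
            hits.append(DomainHit(profile_id=prof.id, span=span,
                                  score=score, evalue=evalue))
    hits.sort(key=lambda h: (h.span, h.profile_id))
    return hits


def assess_completeness(hits: Sequence[DomainHit],
                        family: QueryFamily,
                        record_id: str = "") -> CompletenessCall:
    """Completeness of one record's domain architecture for one family.

    complete: every required domain hit at least once; partial: some but
    not all; absent: none.  Missing domains are listed in registry order.
    Architecture order is recorded through the hit spans but not enforced.
    """
    found = {h.profile_id for h in hits}
    required = list(family.required_domains)
    missing = [d for d in required if d not in found]
    present = [d for d in required if d in found]
    if not required:  # consensus-validated family: one hit suffices
        status = "complete" if hits else "absent"
    elif not missing:
        status = "complete"
    elif present:
        status = "partial"
    else:
        status = "absent"
    return CompletenessCall(
        family=family.name, status=status, missing_domains=missing,
        found_domains=present,
        contributing_records=[record_id] if record_id else [])


def rescue_split_models(calls: Sequence[CompletenessCall],
                        records: Sequence[SequenceRecord],
                        family: QueryFamily) -> CompletenessCall:
    """Merge split gene models of one family within one genome library.

    If no single record is complete but the union of domains over records
    sharing a scaffold covers every required domain, the family is called
    ``complete_split`` with those records as contributors.  A union that
    only works across different scaffolds stays partial, with an explicit
    note.  Records without a scaffold id cannot take part in the rescue.
    Transcriptome libraries must never be passed here.
    """
    if not calls:
        raise DomainError("rescue needs at least one completeness call")
    for call in calls:
        if call.status in ("complete", "complete_split"):
            return call
    by_id = {r.id: r for r in records}
    per_scaffold: dict[str, set[str]] = {}
    contributors: dict[str, list[str]] = {}
    union_all: set[str] = set()
    for call in calls:
        for rid in call.contributing_records:
            rec = by_id.get(rid)
            union_all.update(call.found_domains)
            if rec is None or rec.scaffold_id is None:
                if rec is not None:
                    logger.warning(
                        "record %s lacks a scaffold id; excluded from "
                        "split-model rescue", rid)
                continue
            per_scaffold.setdefault(rec.scaffold_id, set()).update(
                call.found_domains)
            contributors.setdefault(rec.scaffold_id, []).append(rid)
    required = set(family.required_domains)
    for scaffold, domains in sorted(per_scaffold.items()):
        if required <= domains:
            return CompletenessCall(
                family=family.name, status="complete_split",
                contributing_records=sorted(set(contributors[scaffold])),
                found_domains=[d for d in family.required_domains],
                note=f"split gene models merged on scaffold {scaffold}")
    best = max(calls, key=lambda c: len(c.found_domains))
    note = best.note
    if required <= union_all:
        note = (note + "; " if note else "") + "possible split (multi-scaffold)"
    return CompletenessCall(
        family=family.name, status=best.status,
        missing_domains=list(best.missing_domains),
        contributing_records=list(best.contributing_records),
        found_domains=list(best.found_domains), note=note)


def family_profiles(family: QueryFamily, domain_models: dict[str, str],
                    scheme: Optional[ScoringScheme] = None
                    ) -> list[ProfileModel]:
    """Scoring profiles for one family.

    Families with required domains get one single-consensus PSSM per domain
    model; a cba1_consensus family gets the two-seed consensus profile.
    """
    if family.special_rule == "cba1_consensus" and not family.required_domains:
        if len(family.seed_sequences) < 2:
            raise DomainError(
                f"family {family.name!r}: consensus validation needs 2 seeds")
        a, b = family.seed_sequences[:2]
        return [consensus_profile(a, b, scheme,
                                  profile_id=f"{family.name}-consensus")]
    profiles = []
    for dom in family.required_domains:
        if dom not in domain_models:
            raise DomainError(f"no domain model for {dom!r}")
        profiles.append(single_sequence_profile(domain_models[dom], dom))
    return profiles
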