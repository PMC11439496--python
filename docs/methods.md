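# Methods

This note records the models, rules and numerical choices behind
`b12screen`, in the order the pipeline applies them, together with what
the synthetic benchmark does and does not demonstrate.

## Homologue search

The forward search is an exact Smith–Waterman local alignment under affine
gaps rather than a seeded heuristic: at the library sizes this package
targets (tens to a few hundred proteins per library) the full dynamic
programme is affordable, strictly more sensitive, and deterministic, which
matters because downstream curation acts on the exact candidate set. The
recurrences are the three-state Gotoh form, vectorized along the subject
axis so that one query is scored against an entire library in a single
sweep. Scoring defaults are BLOSUM62 with gap open 11 / extend 1 (the
protein defaults of the standard search tools); a gap run of length *L*
costs `open + (L−1)·extend`, adjacent opposite gap runs are disallowed
(the canonical-alignment convention; with these penalties such alignments
are never optimal anyway), and the ambiguity residue X scores 0 against
everything. Traceback tie-breaks prefer the diagonal move, then the
vertical, then the horizontal, making alignments reproducible bit for bit.

E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with fixed
λ = 0.267, K = 0.041 (ungapped protein defaults). No per-query
recalibration is attempted: the screen only uses a coarse `E ≤ 10⁻⁵`
cutoff, two orders of magnitude away from any decision boundary observed
in the benchmark.

Reciprocal validation applies no second E-value threshold — only the
identity of the best-scoring match in the validation database matters, with
ties resolved in favour of registry queries so that borderline candidates
survive to the tree stage where the stronger filters act. The METE
exception (acceptance of the three *Arabidopsis* methionine synthases as
reciprocal matches) exists because the validation proteome itself encodes
METE, so a genuine algal METE may retrieve the proteome's own copy rather
than the query.

## Alignment and distances

Multiple alignments are centre-star progressive: the centre is the
sequence with the highest summed pairwise local score, and the remaining
sequences are merged most-similar-first by a global affine
profile-to-sequence DP (column scores are the mean substitution score over
the column's residues), with existing gaps propagated. End gaps are
penalized; free end gaps would mis-place single-residue indels near
sequence ends, and truncated transcripts still align correctly because
their core match dominates. The aligner's contract is narrow — ungapping
any row must reproduce its input — so an external aligner can be
substituted behind the same signature.

Distances are Poisson-corrected p-distances, `d = −ln(1−p)`, with *p* the
mismatch fraction over columns where both rows are ungapped and neither is
X. The model is chosen for its units: branch lengths must be in
substitutions per site for the 1.0 pruning threshold to be meaningful.
*p* is capped at 0.95 (`d ≈ 3.0`) to keep distances finite; pairs sharing
no columns at all (for example the two halves of a split gene model) get
the cap, with a warning emitted once per pair.

Neighbour joining is the canonical Saitou–Nei algorithm. Ties in the Q
criterion are broken by the lexicographically smallest pair of cluster
representative labels; negative branch-length estimates are clamped to
zero with the deficit moved to the sibling branch so the joined pair's
distance is preserved. On additive matrices the reconstruction is exact
(property-tested against independently generated random trees up to eight
tips, and cross-checked against scikit-bio's implementation).

## Curation rules

* **Long-branch pruning** removes one worst offender per iteration —
  terminal branch strictly greater than 1.0 substitutions/site — and
  recomputes the alignment, distances and tree before looking again.
  One-at-a-time removal is deliberate: a single rogue inflates its
  neighbours' terminal branches, and batch removal would overshoot.
  Internal branches above the threshold are logged but never trigger
  removal; pruning stops (and flags the set) rather than dropping below
  four sequences.
* **Column trimming** keeps a column iff its non-gap fraction is ≥ 0.5 —
  a column at exactly the boundary is kept, matching the documented
  behaviour of the standard trimming tool.
* **Bootstrap support** resamples alignment columns with replacement
  (100 replicates by default, seeded per family from the run seed) and
  reports, for each internal bipartition of the point-estimate tree, the
  fraction of replicate NJ trees containing it.
* **Contaminant vs HGT.** Curation trees contain, besides the library
  candidates, the family's query seeds and a set of prokaryotic reference
  homologues. A eukaryotic tip is *bacterial-nested* when the smallest
  bipartition side holding it and at least two other tips contains a
  prokaryote and no eukaryote from any other lineage group. Nested tips
  are contaminants, with two exceptions: near-identity (≥ 99%) to a
  prokaryotic tip is always contamination, and a nested signal shared by
  two or more distinct strains of the same lineage group anywhere in the
  tree marks an ancestral transfer (`hgt`), which keeps its presence
  call. Several libraries of one strain are not independent evidence.
  Including the query seeds in the tree is essential: without a
  eukaryotic anchor, a vertically inherited singleton in a
  bacteria-dominated tree is topologically indistinguishable from a
  contaminant.
* **Isoform clades** are assigned by anchors: a tip belongs to a labelled
  clade iff it lies in the smallest bipartition side spanning all of that
  label's anchor tips; that side must contain no anchor of another label,
  otherwise the anchor sets are reported as inseparable. Tips outside
  every anchored clade (outgroups) stay unassigned.

## Domain validation

Domain models are position-specific log-odds profiles with additive
pseudocounts (α = 0.5, uniform background): the downstream calls depend
only on presence/absence at `E ≤ 10⁻⁵`, not on fine HMM scores, and the
tabular output of an external scanner can be ingested through the same
`DomainHit` type. Profile entries are natural-log odds, so the scale
parameter of the hit statistics is 1 by construction and `E =
K·m·n·e^(−S)` with K = 0.1. Scanning is gapless (best-scoring
profile/sequence diagonal segment): indels inside a 36-residue domain
segment are not part of the generator's model, and for real data the
external-scanner route is the appropriate one.

Completeness requires every registered domain; hit order is recorded but
not enforced. A genome library with no complete record triggers the
split-model rescue: if the union of domains over gene models sharing one
scaffold covers the family, the library is called `complete_split`;
unions across different scaffolds stay partial with an explicit note,
because co-residence on one chromosomal element is the evidence that two
models are fragments of one gene. Transcriptome records are never
rescued. CBA1 has no shared domain; its validation profile is built from
the pairwise alignment of its two characterized seed proteins (globalized
by end extension), which by construction sit near 28% mutual identity —
low, hence the profile-quality warning below 10%.

## Classification

Partial presences (for example a METE missing its N-terminal domain, the
dinoflagellate configuration) count as absent for status but are kept in
the matrix and reports. Absence calls are genome-gated at strain level:
a transcriptome-only strain with METH is recorded as dependent with a
low-confidence flag, and its loss-of-B12 verdict is indeterminate,
because METE can be transcriptionally repressed in B12-replete cultures.
MTRR does not gate the METH presence call itself; it enters only the
loss rule (METE retained; METH, MTRR, MCM, RNR-II absent; genome
available). Strains whose only detected families are accessory
(Cbl*/CBA1) are classed unknown with an explanatory note rather than
given a fifth class.

## The synthetic benchmark

The generator emulates a mixed genome/transcriptome corpus at desk scale.
Defaults: 30 species on a pure-birth tree (λ = 1); six families (METE,
METH, MTRR, MCM, RNR-II, CblB); per-branch loss probability 0.3;
per-branch HGT probability 0.05 on METE, MCM and RNR-II only — the
families for which bacterial transfers into algae are actually
documented — and 0 elsewhere; per-library contamination 0.05 (a verbatim
copy of a bacterial reference); per-transcript truncation 0.2 (a uniform
20–60% prefix or suffix removed) and dropout 0.2; 30% of species are
transcriptome-only and 10% of genome species also have a transcriptome
library, exercising strain deduplication. Substitution is per-site
Poisson with uniform replacement among the 19 alternatives, so the
proportion of differing sites after distance *d* has the closed form
`p(d) = (19/20)(1 − e^(−20d/19))` used by the tests; domain segments
evolve at 0.3× the background rate of 0.1 substitutions/site per unit
branch length, keeping domain hits detectable at realistic divergence.
The bacterial pool is a radiation of 20 lineages from a stem 0.5
substitutions/site off the family root; eight pool tips double as the
prokaryotic reference homologues and as contamination/HGT donors. All
randomness derives from the single cohort seed; output is byte-identical
across runs.

What passing the benchmark shows: the search/validation chain recovers
planted homologues with perfect precision, planted contaminants never
produce a presence call, multi-strain transfers are recognized as such,
and no vertically inherited sequence is ever flagged (vertical
false-positive rate 0 across tested seeds). What it does not show: the
generator has no indel process inside genes, no compositional
heterogeneity, no paralogy, and its transcriptomes are cleanly translated
proteins — real transcriptome noise is messier. Two error channels are
inherent rather than implementation artefacts, and dominate the residual
status-accuracy gap (25/30 at seed 1; 29/30 and 28/30 at seeds 2 and 3):
a transfer received by a *single* strain is, by the screening rules
themselves, indistinguishable from contamination and is deliberately
suppressed; and transcriptome-only strains genuinely under-report
(dropout, or truncation leaving a partial architecture), which is exactly
why the classifier genome-gates its absence calls.

## Problem sizes

The shipped configuration — 30 species, 6 families, ~32 libraries of
~15 proteins each — was chosen so that a full simulate-run-score cycle
completes in seconds on one CPU while still exercising every rule
(losses, transfers, contaminants, split models, truncation, dual
libraries). All thresholds are configuration, not constants, so the same
code runs unchanged on larger inputs.
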