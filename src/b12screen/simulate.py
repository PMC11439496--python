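"""Synthetic sequence libraries with known evolutionary truth.

The generator emulates, at desk scale, the kind of mixed genome and
transcriptome corpus the screen is designed for: homologues of B12-pathway
protein families planted along a birth-death species tree, with

* irreversible gene losses and bacterial horizontal gene transfers (HGT)
  drawn per branch;
* per-site substitution with conserved domain segments evolving at a
  fraction of the background rate, so that domain scanning stays realistic
  under divergence;
* a bacterial sequence pool (deep lineages radiating from an independent
  stem) that acts both as the HGT donor set and as the reference
  prokaryotic homologues included in curation trees;
* transcriptome libraries that truncate transcripts, drop genes entirely
  (under-reporting), or carry verbatim bacterial contaminants;
* shuffled composition-matched decoy proteins padding every library;
* occasional genome genes emitted as two gene models on one scaffold
  (split gene models).

Everything is deterministic given the simulation seed, and every emitted
sequence carries exactly one truth label, so each pipeline stage can be
scored against ground truth without external data.

The substitution model is deliberately simple -- Poisson numbers of
substitution events per site, each replacing the residue uniformly among
the 19 alternatives -- so that the expected proportion of differing sites
after distance d has the closed form  p(d) = (19/20) * (1 - exp(-20 d / 19)).
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import PhyloTree
from .registry import (AA20, REQUIRED_DOMAINS, CollectionSite, LibraryManifest,
                       PipelineConfig, QueryFamily, Registry, SequenceRecord,
                       domain_consensus, normalize_strain_name, save_registry,
                       write_fasta, write_manifest)
from .search import ValidationSequence

_AA = np.array(list(AA20))
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

PRESENCE_STATES = ("retained", "lost", "hgt_acquired")
SEQUENCE_ORIGINS = ("vertical", "hgt", "contaminant", "decoy")

LINEAGE_GROUP_NAMES = (
    "chlorophytes", "streptophytes", "hornworts", "red algae",
    "haptophytes", "diatoms", "cryptomonads", "dinoflagellates",
    "chrysophytes", "glaucophytes", "mosses", "liverworts",
    "euglenids", "chlorarachniophytes",
)

HABITATS = ("marine", "freshwater", "terrestrial", "symbiotic", "other")


@dataclass
class FamilySpec:
    """Evolutionary parameters of one simulated query family.

    The root protein is a chain of linkers and domain segments (one segment
    per required domain, in order); the segment for a given domain
    identifier is always the same consensus, shared with registry
    generation.  Rates are in substitutions per site per unit of tree
    branch length.
    """

    name: str
    required_domains: tuple[str, ...]
    substitution_rate: float = 0.1
    domain_rate_factor: float = 0.3
    loss_prob: float = 0.3
    hgt_prob: float = 0.0
    domain_len: int = 36
    linker_len: int = 24

    def __post_init__(self) -> None:
        if not self.required_domains:
            raise ValueError(f"family {self.name!r} needs >= 1 domain segment")
        for p in (self.loss_prob, self.hgt_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def root_sequence(self) -> tuple[str, list[tuple[int, int]]]:
        """Deterministic root protein and its domain spans."""
        rng = np.random.default_rng(
            zlib.crc32(f"root:{self.name}".encode()) & 0x7FFFFFFF)
        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        for dom in self.required_domains:
            linker = "".join(rng.choice(_AA, size=self.linker_len))
            parts.append(linker)
            pos += self.linker_len
            seg = domain_consensus(dom, self.domain_len)
            parts.append(seg)
            spans.append((pos, pos + self.domain_len))
            pos += self.domain_len
        parts.append("".join(rng.choice(_AA, size=self.linker_len)))
        return "".join(parts), spans

    def site_rates(self) -> np.ndarray:
        seq, spans = self.root_sequence()
        rates = np.full(len(seq), self.substitution_rate)
        for a, b in spans:
            rates[a:b] = self.substitution_rate * self.domain_rate_factor
        return rates


def default_families() -> list[FamilySpec]:
    """The six families of the default cohort.

    HGT is enabled for the families in which bacterial transfers into algae
    have actually been observed (METE into red algae and chrysophytes, MCM
    and RNR-II into green algae); the methionine synthase support proteins
    evolve strictly vertically.
    """
    hgt_families = {"METE", "MCM", "RNR-II"}
    return [
        FamilySpec(name=n, required_domains=REQUIRED_DOMAINS[n],
                   hgt_prob=0.05 if n in hgt_families else 0.0)
        for n in ("METE", "METH", "MTRR", "MCM", "RNR-II", "CblB")
    ]


@dataclass
class SimulationSpec:
    """Cohort-level parameters of one simulation."""

    n_species: int = 30
    birth_rate: float = 1.0
    families: list[FamilySpec] = field(default_factory=default_families)
    contamination_rate: float = 0.05  # per library
    truncation_prob: float = 0.2      # per emitted transcript
    transcriptome_fraction: float = 0.3  # species with transcriptome only
    dual_library_fraction: float = 0.1   # genome species with a transcriptome too
    dropout_prob: float = 0.2         # per transcriptome gene
    split_gene_prob: float = 0.05     # per genome gene (>= 2 domains)
    n_decoys: int = 8                 # decoy proteins per library
    n_decoy_proteome: int = 40        # background size of the validation DB
    n_bacterial_lineages: int = 20
    n_bacterial_refs: int = 8         # pool tips used as tree references
    seed_divergence: float = 0.15     # registry seeds vs family root
    bacterial_stem: float = 0.5       # family root -> bacterial pool root
    bacterial_crown: float = 0.5      # depth of the bacterial pool radiation
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        for p in (self.contamination_rate, self.truncation_prob,
                  self.transcriptome_fraction, self.dropout_prob,
                  self.split_gene_prob, self.dual_library_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(spec: SimulationSpec) -> "dendropy.Tree":
    """Pure-birth (Yule) species tree with ``n_species`` extant tips.

    Tips are labelled sp01..spNN in leaf traversal order; the tree is
    ultrametric and deterministic given the simulation seed.
    """
    import dendropy
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=spec.birth_rate, death_rate=0.0,
        num_extant_tips=spec.n_species,
        rng=random.Random(spec.seed))
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{k:02d}"
    return tree


def species_tree_as_phylo(tree) -> PhyloTree:
    return PhyloTree.from_dendropy(tree)


def yule_expected_depth(n: int, birth_rate: float) -> float:
    """Expected root-to-tip depth of a pure-birth tree grown from a single
    lineage until it has n extant tips: sum_{k=1}^{n-1} 1/(birth_rate*k)."""
    return sum(1.0 / k for k in range(1, n)) / birth_rate


def _assign_lineage_groups(tree, n_groups: int = 6) -> dict[str, str]:
    """Chunk the leaf traversal order into contiguous lineage groups, so
    that groups are (approximately) clades of the species tree."""
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    size = -(-len(leaves) // n_groups)
    groups = {}
    for i, label in enumerate(leaves):
        groups[label] = LINEAGE_GROUP_NAMES[min(i // size,
                                                n_groups - 1)]
    return groups


# ---------------------------------------------------------------------------
# gene presence and sequence evolution
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    """Ground truth for one family: per-species presence state, the
    evolved sequences, and the bacterial pool."""

    spec: FamilySpec
    presence: dict[str, str]              # species -> presence state
    sequences: dict[str, str]             # species -> protein (if present)
    origins: dict[str, str]               # species -> vertical | hgt
    pool: list[SequenceRecord]            # bacterial pool tips
    reference_ids: list[str]              # subset used as tree references


def _mutate(seq: np.ndarray, distance: np.ndarray | float,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site Poisson substitution; each event draws uniformly from the
    19 alternative residues."""
    d = np.broadcast_to(np.asarray(distance, dtype=float), seq.shape)
    events = rng.poisson(d)
    out = seq.copy()
    for pos in np.flatnonzero(events):
        cur = out[pos]
        for _ in range(events[pos]):
            step = rng.integers(0, 19)
            cur = step if step < cur else step + 1
        out[pos] = cur
    return out


def _encode_aa(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64,
                       count=len(seq))


def _decode_aa(arr: np.ndarray) -> str:
    return "".join(_AA[arr])


#: attribute name used to annotate per-node presence states on the tree
_STATE_ATTR = "b12_presence_state"


def evolve_presence(tree, family: FamilySpec, seed: int
                    ) -> tuple[dict[str, str], dict[int, list[str]]]:
    """Evolve presence root-to-tips.

    On every branch the vertical copy is lost with ``loss_prob``
    (irreversibly, although a later transfer can re-introduce the gene) and
    replaced by a bacterial acquisition with ``hgt_prob``; an acquisition is
    shared by all descendants of the transfer branch.  Each tree node is
    annotated with its (kind, event) state so that sequence evolution can
    replay exactly the same history.  Returns the per-species states and
    the HGT events (event id -> recipient species).
    """
    rng = np.random.default_rng(seed)
    states: dict[str, str] = {}
    events: dict[int, list[str]] = {}
    counter = 0
    kind_name = {"retained": "retained", "lost": "lost",
                 "hgt": "hgt_acquired"}

    setattr(tree.seed_node, _STATE_ATTR, ("retained", None))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        kind, ev = getattr(node.parent_node, _STATE_ATTR)
        if rng.random() < family.loss_prob:
            kind, ev = "lost", None
        if rng.random() < family.hgt_prob:
            counter += 1
            kind, ev = "hgt", counter
        setattr(node, _STATE_ATTR, (kind, ev))
        if node.is_leaf():
            label = node.taxon.label
            states[label] = kind_name[kind]
            if kind == "hgt":
                events.setdefault(ev, []).append(label)
    return states, events


def _simulate_pool(family: FamilySpec, root_enc: np.ndarray,
                   rates: np.ndarray, spec: SimulationSpec,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Bacterial pool: a star-like radiation of deep lineages from a stem
    diverged off the family root."""
    pool_root = _mutate(root_enc, rates * spec.bacterial_stem, rng)
    tips = []
    for _ in range(spec.n_bacterial_lineages):
        depth = spec.bacterial_crown * (0.5 + rng.random())
        tips.append(_mutate(pool_root, rates * depth, rng))
    return tips


def evolve_sequences(tree, family: FamilySpec, presence: dict[str, str],
                     hgt_events: dict[int, list[str]], spec: SimulationSpec,
                     seed: int) -> FamilyTruth:
    """Evolve the family's protein along the annotated species tree.

    Vertical copies descend from the family root; an HGT copy descends from
    a randomly chosen bacterial pool tip starting at the transfer branch,
    then keeps evolving down the tree like any other gene.  Domain segments
    evolve at ``domain_rate_factor`` times the background rate throughout.
    Requires the node states recorded by :func:`evolve_presence`.
    """
    rng = np.random.default_rng(seed)
    root_seq, _ = family.root_sequence()
    root_enc = _encode_aa(root_seq)
    rates = family.site_rates()
    pool = _simulate_pool(family, root_enc, rates, spec, rng)
    # every event id recorded on the tree needs a donor, including
    # acquisitions later overwritten by loss or by a more recent transfer
    all_events = sorted({
        getattr(node, _STATE_ATTR)[1]
        for node in tree.preorder_node_iter()
        if hasattr(node, _STATE_ATTR)
        and getattr(node, _STATE_ATTR)[1] is not None})
    donor_of_event = {
        ev: int(rng.integers(0, spec.n_bacterial_refs))
        for ev in all_events
    }
    sequences: dict[str, str] = {}
    origins: dict[str, str] = {}
    seq_at: dict[int, Optional[np.ndarray]] = {id(tree.seed_node): root_enc}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if not hasattr(node, _STATE_ATTR):
            raise ValueError("tree is missing presence annotations; run "
                             "evolve_presence first")
        kind, ev = getattr(node, _STATE_ATTR)
        pkind, pev = getattr(node.parent_node, _STATE_ATTR)
        blen = node.edge.length or 0.0
        parent_seq = seq_at[id(node.parent_node)]
        if kind == "lost":
            seq: Optional[np.ndarray] = None
        elif kind == "hgt" and ev != pev:
            donor = pool[donor_of_event[ev]]
            seq = _mutate(donor, rates * max(blen, 0.05), rng)
        else:
            seq = None if parent_seq is None else \
                _mutate(parent_seq, rates * blen, rng)
        seq_at[id(node)] = seq
        if node.is_leaf() and seq is not None:
            label = node.taxon.label
            sequences[label] = _decode_aa(seq)
            origins[label] = "hgt" if kind == "hgt" else "vertical"
    pool_records = [
        SequenceRecord(id=f"bact{k:02d}_{family.name}",
                       sequence=_decode_aa(tip_seq),
                       library_id=f"bacteria_{family.name}")
        for k, tip_seq in enumerate(pool)
    ]
    return FamilyTruth(
        spec=family, presence=presence, sequences=sequences,
        origins=origins, pool=pool_records,
        reference_ids=[r.id for r in pool_records[:spec.n_bacterial_refs]])


# ---------------------------------------------------------------------------
# library emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything one simulation produces: inputs for the pipeline plus the
    ground truth needed to score it."""

    spec: SimulationSpec
    species_tree: PhyloTree
    registry: Registry
    libraries: dict[str, list[SequenceRecord]]
    manifests: list[LibraryManifest]
    validation_db: list[ValidationSequence]
    bacterial_refs: dict[str, list[SequenceRecord]]
    presence_truth: pd.DataFrame   # species x family -> presence state
    sequence_truth: pd.DataFrame   # one row per emitted sequence
    strain_of_species: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        """Write the cohort in the pipeline's input formats (FASTA + TSV +
        YAML), plus the truth tables."""
        outdir = Path(outdir)
        (outdir / "libraries").mkdir(parents=True, exist_ok=True)
        for lib_id, records in sorted(self.libraries.items()):
            write_fasta(records, outdir / "libraries" / f"{lib_id}.fasta")
        write_manifest(self.manifests, outdir / "manifest.tsv")
        save_registry(self.registry, outdir / "registry.yaml")
        write_fasta([v.record for v in self.validation_db],
                    outdir / "validation_db.fasta")
        pd.DataFrame(
            [{"id": v.record.id, "role": v.role, "family": v.family}
             for v in self.validation_db]
        ).to_csv(outdir / "validation_roles.tsv", sep="\t", index=False)
        (outdir / "references").mkdir(exist_ok=True)
        for fam, records in sorted(self.bacterial_refs.items()):
            write_fasta(records, outdir / "references" / f"{fam}.fasta")
        self.presence_truth.to_csv(outdir / "presence_truth.tsv", sep="\t",
                                   index_label="species")
        self.sequence_truth.to_csv(outdir / "sequence_truth.tsv", sep="\t",
                                   index=False)
        with open(outdir / "species_tree.nwk", "w") as fh:
            fh.write(self.species_tree.to_newick() + "\n")


def _shuffled_decoy(source: str, rng: np.random.Generator) -> str:
    """Composition-matched decoy: a permutation of an existing protein."""
    chars = np.array(list(source))
    rng.shuffle(chars)
    return "".join(chars)


def _truncate(seq: str, rng: np.random.Generator) -> str:
    """Remove a uniform 20-60% prefix or suffix (transcript truncation)."""
    frac = 0.2 + 0.4 * rng.random()
    cut = max(1, int(round(frac * len(seq))))
    if rng.random() < 0.5:
        return seq[cut:]
    return seq[:len(seq) - cut]


def emit_libraries(spec: SimulationSpec, tree,
                   truths: dict[str, FamilyTruth],
                   groups: dict[str, str], seed: int
                   ) -> tuple[dict[str, list[SequenceRecord]],
                              list[LibraryManifest], pd.DataFrame,
                              dict[str, str]]:
    """Emit per-species libraries with decoys, truncation, dropout,
    split gene models and contamination.

    Genome libraries carry every present gene unmodified (occasionally as
    two gene models on one scaffold); transcriptome libraries drop each
    gene with the dropout probability and truncate surviving transcripts
    with the truncation probability.  Contaminants are verbatim copies of
    bacterial reference sequences.  Returns libraries, manifests, the
    per-sequence truth table and the species -> strain-name map.
    """
    rng = np.random.default_rng(seed)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(species)
    n_trans_only = int(round(spec.transcriptome_fraction * n))
    order = rng.permutation(n)
    trans_only = {species[i] for i in order[:n_trans_only]}
    genome_species = [s for s in species if s not in trans_only]
    n_dual = int(round(spec.dual_library_fraction * len(genome_species)))
    dual = set(s for s in genome_species[:n_dual])
    family_names = list(truths)

    libraries: dict[str, list[SequenceRecord]] = {}
    manifests: list[LibraryManifest] = []
    truth_rows: list[dict] = []
    strain_of_species: dict[str, str] = {}

    for sp in species:
        strain = f"{groups[sp].split()[0].capitalize()} sp. {sp.upper()}"
        strain_of_species[sp] = strain
        site = CollectionSite(
            latitude=float(np.round(rng.uniform(-80, 80), 1)),
            longitude=float(np.round(rng.uniform(-179, 179), 1)),
            habitat=str(rng.choice(HABITATS)))
        lib_types = (["transcriptome"] if sp in trans_only
                     else ["genome", "transcriptome"] if sp in dual
                     else ["genome"])
        for lib_type in lib_types:
            lib_id = f"{sp}_{'txm' if lib_type == 'transcriptome' else 'gen'}"
            records: list[SequenceRecord] = []
            for fam in family_names:
                truth = truths[fam]
                if sp not in truth.sequences:
                    continue
                seq = truth.sequences[sp]
                origin = truth.origins[sp]
                if lib_type == "transcriptome":
                    if rng.random() < spec.dropout_prob:
                        continue  # under-reported transcript
                    truncated = rng.random() < spec.truncation_prob
                    out_seq = _truncate(seq, rng) if truncated else seq
                    records.append(SequenceRecord(
                        id=f"{lib_id}_{fam}_t1", sequence=out_seq,
                        library_id=lib_id))
                    truth_rows.append({
                        "library_id": lib_id, "record_id": f"{lib_id}_{fam}_t1",
                        "species": sp, "family": fam, "origin": origin,
                        "truncated": truncated})
                else:
                    scaffold = f"scaf{int(rng.integers(0, 1000)):04d}"
                    n_domains = len(truth.spec.required_domains)
                    split = (n_domains >= 2
                             and rng.random() < spec.split_gene_prob)
                    if split:
                        _, spans = truth.spec.root_sequence()
                        cut_after = n_domains // 2  # split between domains
                        cut = (spans[cut_after - 1][1]
                               + spans[cut_after][0]) // 2
                        pieces = [seq[:cut], seq[cut:]]
                    else:
                        pieces = [seq]
                    for k, piece in enumerate(pieces, start=1):
                        rid = f"{lib_id}_{fam}_g{k}"
                        records.append(SequenceRecord(
                            id=rid, sequence=piece, library_id=lib_id,
                            scaffold_id=scaffold))
                        truth_rows.append({
                            "library_id": lib_id, "record_id": rid,
                            "species": sp, "family": fam, "origin": origin,
                            "truncated": split})
            if rng.random() < spec.contamination_rate:
                fam = family_names[int(rng.integers(0, len(family_names)))]
                refs = truths[fam].pool[:spec.n_bacterial_refs]
                donor = refs[int(rng.integers(0, len(refs)))]
                rid = f"{lib_id}_contam1"
                records.append(SequenceRecord(
                    id=rid, sequence=donor.sequence, library_id=lib_id))
                truth_rows.append({
                    "library_id": lib_id, "record_id": rid, "species": sp,
                    "family": fam, "origin": "contaminant",
                    "truncated": False})
            pool_all = [t.sequences[s] for t in truths.values()
                        for s in sorted(t.sequences)]
            for k in range(spec.n_decoys):
                src = pool_all[int(rng.integers(0, len(pool_all)))]
                rid = f"{lib_id}_decoy{k:02d}"
                records.append(SequenceRecord(
                    id=rid, sequence=_shuffled_decoy(src, rng),
                    library_id=lib_id))
                truth_rows.append({
                    "library_id": lib_id, "record_id": rid, "species": sp,
                    "family": "", "origin": "decoy", "truncated": False})
            libraries[lib_id] = records
            manifests.append(LibraryManifest(
                library_id=lib_id, strain_name=strain,
                library_type=lib_type, lineage_group=groups[sp],
                collection_site=site,
                source_collection="synthetic"))
    sequence_truth = pd.DataFrame(truth_rows)
    return libraries, manifests, sequence_truth, strain_of_species


def _build_registry(spec: SimulationSpec,
                    truths: dict[str, FamilyTruth], seed: int) -> Registry:
    """Registry for the simulated families: two independently diverged
    seeds per family plus the shared domain consensus models."""
    rng = np.random.default_rng(seed)
    families = []
    domain_models: dict[str, str] = {}
    for fam, truth in truths.items():
        root_seq, _ = truth.spec.root_sequence()
        enc = _encode_aa(root_seq)
        rates = truth.spec.site_rates()
        seeds = [
            SequenceRecord(
                id=f"{fam}_seed{k}",
                sequence=_decode_aa(
                    _mutate(enc, rates * spec.seed_divergence, rng)),
                library_id="registry")
            for k in (1, 2)
        ]
        families.append(QueryFamily(
            name=fam, seed_sequences=seeds,
            required_domains=list(truth.spec.required_domains),
            special_rule="mete_arabidopsis" if fam == "METE" else "none"))
        for dom in truth.spec.required_domains:
            domain_models[dom] = domain_consensus(dom, truth.spec.domain_len)
    return Registry(families, domain_models, version="synthetic")


def _build_validation_db(spec: SimulationSpec, registry: Registry,
                         truths: dict[str, FamilyTruth],
                         seed: int) -> list[ValidationSequence]:
    """Validation database: a decoy proteome (the stand-in for a METE-only
    reference genome), the registry queries, and three Arabidopsis-style
    METE homologues (synthetic stand-ins carrying the conventional
    locus identifiers)."""
    rng = np.random.default_rng(seed)
    db: list[ValidationSequence] = []
    sources = [s.sequence for fam in registry for s in fam.seed_sequences]
    for k in range(spec.n_decoy_proteome):
        src = sources[int(rng.integers(0, len(sources)))]
        db.append(ValidationSequence(
            record=SequenceRecord(id=f"At_decoy{k:03d}",
                                  sequence=_shuffled_decoy(src, rng),
                                  library_id="validation"),
            role="decoy_proteome"))
    for fam in registry:
        for seed_rec in fam.seed_sequences:
            db.append(ValidationSequence(
                record=SequenceRecord(id=seed_rec.id,
                                      sequence=seed_rec.sequence,
                                      library_id="validation"),
                role="registry_query", family=fam.name))
    if "METE" in registry:
        mete = truths["METE"]
        root_enc = _encode_aa(mete.spec.root_sequence()[0])
        rates = mete.spec.site_rates()
        for locus in ("At5g17920", "At3g03780", "At5g20980"):
            db.append(ValidationSequence(
                record=SequenceRecord(
                    id=locus,
                    sequence=_decode_aa(_mutate(root_enc, rates * 0.2, rng)),
                    library_id="validation"),
                role="arabidopsis_met_synthase"))
    return db


def simulate_cohort(spec: Optional[SimulationSpec] = None) -> SyntheticCohort:
    """Run the full generator: species tree, per-family presence and
    sequence evolution, library emission, registry and validation DB."""
    spec = spec or SimulationSpec()
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(4 + 2 * len(spec.families))]
    tree = simulate_species_tree(spec)
    groups = _assign_lineage_groups(tree)
    truths: dict[str, FamilyTruth] = {}
    for k, fam in enumerate(spec.families):
        presence, events = evolve_presence(tree, fam, child_seeds[4 + 2 * k])
        truths[fam.name] = evolve_sequences(
            tree, fam, presence, events, spec, child_seeds[5 + 2 * k])
    libraries, manifests, sequence_truth, strain_of_species = emit_libraries(
        spec, tree, truths, groups, child_seeds[0])
    registry = _build_registry(spec, truths, child_seeds[1])
    validation_db = _build_validation_db(spec, registry, truths,
                                         child_seeds[2])
    presence_truth = pd.DataFrame(
        {fam: truths[fam].presence for fam in truths},
        index=[lf.taxon.label for lf in tree.leaf_node_iter()])
    bacterial_refs = {
        fam: [r for r in truth.pool if r.id in set(truth.reference_ids)]
        for fam, truth in truths.items()
    }
    return SyntheticCohort(
        spec=spec, species_tree=species_tree_as_phylo(tree),
        registry=registry, libraries=libraries, manifests=manifests,
        validation_db=validation_db, bacterial_refs=bacterial_refs,
        presence_truth=presence_truth, sequence_truth=sequence_truth,
        strain_of_species=strain_of_species)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def true_statuses(cohort: SyntheticCohort) -> dict[str, "B12Status"]:
    """Ground-truth B12 statuses: the classification rule applied to the
    true presence states with the true genome availability."""
    from .classify import classify_b12_status

    has_genome = {}
    for m in cohort.manifests:
        key = normalize_strain_name(m.strain_name)
        has_genome[key] = has_genome.get(key, False) or \
            m.library_type == "genome"
    out = {}
    for sp in cohort.presence_truth.index:
        strain = cohort.strain_of_species[sp]
        key = normalize_strain_name(strain)
        row = {
            fam: ("present"
                  if cohort.presence_truth.at[sp, fam] in
                  ("retained", "hgt_acquired") else "absent")
            for fam in cohort.presence_truth.columns
        }
        out[key] = classify_b12_status(row, has_genome[key], strain=strain)
    return out


def score_pipeline(cohort: SyntheticCohort, matrix, statuses
                   ) -> dict[str, object]:
    """Score pipeline output against the simulation truth.

    Reports per-family presence precision/recall, overall methionine-status
    accuracy, the number of contaminant-driven false presences, contaminant
    suppression recall, and (separately) the accuracy of genome-gated METE
    absence calls.
    """
    truth_status = true_statuses(cohort)
    pred_keys = set(matrix.table.index)
    truth_keys = set(truth_status)
    if pred_keys != truth_keys:
        raise ValueError(
            "strain sets differ between truth and prediction: "
            f"{sorted(pred_keys ^ truth_keys)[:5]} ...")

    key_of_species = {
        sp: normalize_strain_name(cohort.strain_of_species[sp])
        for sp in cohort.presence_truth.index
    }
    families = list(cohort.presence_truth.columns)
    per_family = {}
    tp = fp = fn = 0
    for fam in families:
        ftp = ffp = ffn = 0
        for sp in cohort.presence_truth.index:
            key = key_of_species[sp]
            truth_present = cohort.presence_truth.at[sp, fam] in \
                ("retained", "hgt_acquired")
            pred_present = matrix.table.at[key, fam] in \
                ("present", "present_split")
            ftp += truth_present and pred_present
            ffp += pred_present and not truth_present
            ffn += truth_present and not pred_present
        per_family[fam] = {
            "precision": ftp / (ftp + ffp) if ftp + ffp else 1.0,
            "recall": ftp / (ftp + ffn) if ftp + ffn else 1.0,
        }
        tp, fp, fn = tp + ftp, fp + ffp, fn + ffn

    status_hits = sum(
        statuses[k].methionine_status == truth_status[k].methionine_status
        for k in truth_keys)
    status_accuracy = status_hits / len(truth_keys)

    # contaminant insertions that nevertheless produced a presence call
    contam = cohort.sequence_truth[
        cohort.sequence_truth["origin"] == "contaminant"]
    contam_false = 0
    for _, row in contam.iterrows():
        key = key_of_species[row["species"]]
        fam = row["family"]
        truth_present = cohort.presence_truth.at[row["species"], fam] in \
            ("retained", "hgt_acquired")
        pred_present = matrix.table.at[key, fam] in \
            ("present", "present_split")
        if pred_present and not truth_present:
            contam_false += 1
    contam_recall = (1.0 - contam_false / len(contam)) if len(contam) else 1.0

    # genome-gated METE absence: among genome-bearing strains, agreement of
    # the METE presence/absence call with truth
    gated_total = gated_hits = 0
    for sp in cohort.presence_truth.index:
        key = key_of_species[sp]
        if not matrix.strains[key].has_genome or "METE" not in families:
            continue
        gated_total += 1
        truth_present = cohort.presence_truth.at[sp, "METE"] in \
            ("retained", "hgt_acquired")
        pred_present = matrix.table.at[key, "METE"] in \
            ("present", "present_split")
        gated_hits += truth_present == pred_present
    return {
        "per_family": per_family,
        "presence_precision": tp / (tp + fp) if tp + fp else 1.0,
        "presence_recall": tp / (tp + fn) if tp + fn else 1.0,
        "status_accuracy": status_accuracy,
        "n_strains": len(truth_keys),
        "contaminant_insertions": int(len(contam)),
        "contaminant_false_presences": contam_false,
        "contaminant_recall": contam_recall,
        "mete_genome_gated_accuracy":
            gated_hits / gated_total if gated_total else 1.0,
    }
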