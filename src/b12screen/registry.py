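"""Data model and I/O for query registries, sequence libraries and manifests.

The screen starts from a registry of query protein families involved in
cobalamin (vitamin B12) metabolism: the two methionine synthase isoforms
(B12-dependent METH, B12-independent METE), the METH reactivator MTRR, the
adenosylcobalamin-dependent enzymes MCM and RNR-II, the uptake/trafficking
proteins CblA-D/F/J, the epistatic regulators CblX and epi-CblC, and the
B12-acquisition protein CBA1.  Each family carries seed query sequences and
the set of protein-domain models its members are expected to contain.

The default registry shipped with the package uses synthetic stand-in seed
sequences (generated deterministically, with the expected domain segments
embedded) so that the whole pipeline is runnable and testable without any
external database; the domain accessions are carried as opaque identifiers.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger("b12screen")

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA20)
#: residues accepted in stored sequences (standard 20 + ambiguity X)
ALPHABET = frozenset(AA20 + "X")

#: canonical family names of the screen (13 families plus CBA1)
FAMILY_NAMES = (
    "METE", "METH", "MTRR", "MCM", "RNR-II",
    "CblA", "CblB", "CblC", "CblD", "CblF", "CblJ", "CblX", "epi-CblC",
    "CBA1",
)

SPECIAL_RULES = ("none", "mete_arabidopsis", "cba1_consensus")

#: required domain models per family.  The METH, METE and MTRR rows follow
#: the domain complements documented for those proteins (homocysteine
#: S-methyltransferase, pterin-binding, two B12-binding and activation
#: domains for METH; the N- and C-terminal catalytic domains for METE;
#: flavodoxin, FAD-binding and oxidoreductase domains for MTRR).  The
#: remaining accessions are carried as opaque identifiers; CBA1 has no
#: shared domain and is validated by a two-seed consensus profile.
REQUIRED_DOMAINS: dict[str, tuple[str, ...]] = {
    "METE": ("PF08267", "PF01717"),
    "METH": ("PF02574", "PF00809", "PF02607", "PF02310", "PF02965"),
    "MTRR": ("PF00258", "PF00667", "PF00175"),
    "MCM": ("PF01642", "PF02310"),
    "RNR-II": ("PF00317", "PF02867"),
    "CblA": ("PF03308",),
    "CblB": ("PF01923",),
    "CblC": ("PF16882",),
    "CblD": ("PF11775",),
    "CblF": ("PF04791",),
    "CblJ": ("PF04791",),
    "CblX": ("PF01344",),
    "epi-CblC": ("PF16882",),
    "CBA1": (),
}

HABITAT_CLASSES = ("marine", "freshwater", "terrestrial", "symbiotic", "other")


class RegistryError(ValueError):
    """Raised when a registry, manifest or config file violates its schema."""


# ---------------------------------------------------------------------------
# core records
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A single amino-acid sequence from one library.

    ``scaffold_id`` is only meaningful for genome-derived gene models and is
    what allows split gene models on the same chromosomal element to be
    merged during domain-completeness rescue.
    """

    id: str
    sequence: str
    library_id: str = ""
    scaffold_id: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise RegistryError("SequenceRecord.id must be non-empty")
        if not self.sequence:
            raise RegistryError(f"sequence of record {self.id!r} is empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise RegistryError(
                f"record {self.id!r} contains residues outside the alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QueryFamily:
    """One query protein family: seed sequences plus required domain models."""

    name: str
    seed_sequences: list[SequenceRecord]
    required_domains: list[str]
    special_rule: str = "none"

    def __post_init__(self) -> None:
        if self.special_rule not in SPECIAL_RULES:
            raise RegistryError(
                f"family {self.name!r}: unknown special_rule "
                f"{self.special_rule!r} (expected one of {SPECIAL_RULES})"
            )
        if not self.seed_sequences:
            raise RegistryError(f"family {self.name!r}: seed_sequences is empty")
        if not self.required_domains and self.special_rule != "cba1_consensus":
            raise RegistryError(
                f"family {self.name!r}: required_domains is empty but "
                "special_rule is not cba1_consensus"
            )


@dataclass
class CollectionSite:
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    habitat: Optional[str] = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise RegistryError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise RegistryError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class LibraryManifest:
    """Provenance of one sequence library (a genome or a transcriptome)."""

    library_id: str
    strain_name: str
    library_type: str  # "genome" | "transcriptome"
    lineage_group: str
    collection_site: Optional[CollectionSite] = None
    source_collection: str = ""

    def __post_init__(self) -> None:
        if self.library_type not in ("genome", "transcriptome"):
            raise RegistryError(
                f"library {self.library_id!r}: library_type must be genome or "
                f"transcriptome, got {self.library_type!r}"
            )


@dataclass
class PipelineConfig:
    """Thresholds and replicate counts steering every pipeline stage.

    Defaults follow the screening protocol: a 1e-5 E-value cutoff for both
    the forward homologue search and the domain scan, iterative removal of
    terminal branches longer than 1.0 substitutions/site, a 0.5 gap-fraction
    column trim, 100 neighbour-joining bootstrap replicates and a 99%
    identity rule for flagging bacterial contaminants.
    """

    forward_evalue_threshold: float = 1e-5
    domain_evalue_threshold: float = 1e-5
    branch_length_threshold: float = 1.0
    gap_threshold: float = 0.5
    nj_replicates: int = 100
    bootstrap_replicates: int = 100
    contaminant_identity_threshold: float = 0.99
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("forward_evalue_threshold", "domain_evalue_threshold",
                     "branch_length_threshold", "gap_threshold",
                     "contaminant_identity_threshold"):
            if getattr(self, name) <= 0:
                raise RegistryError(f"config field {name} must be > 0")
        if not 0.0 < self.gap_threshold <= 1.0:
            raise RegistryError("gap_threshold must lie in (0, 1]")
        if not 0.0 < self.contaminant_identity_threshold <= 1.0:
            raise RegistryError("contaminant_identity_threshold must lie in (0, 1]")
        for name in ("nj_replicates", "bootstrap_replicates"):
            if getattr(self, name) < 1:
                raise RegistryError(f"config field {name} must be >= 1")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise RegistryError(f"config file {path} does not parse to a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise RegistryError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# registry container + I/O
# ---------------------------------------------------------------------------

class Registry:
    """An ordered collection of :class:`QueryFamily` plus shared domain models.

    ``domain_models`` maps a domain identifier to its consensus segment
    (an ungapped amino-acid string) from which a scoring profile is built.
    Families with ``special_rule = cba1_consensus`` have no shared domain
    model; their members are validated against a two-sequence consensus
    profile built from the family seeds instead.
    """

    def __init__(self, families: Sequence[QueryFamily],
                 domain_models: Optional[dict[str, str]] = None,
                 version: str = "0"):
        names = [f.name for f in families]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate family names in registry: {sorted(dupes)}")
        self.families: list[QueryFamily] = list(families)
        self.domain_models: dict[str, str] = dict(domain_models or {})
        self.version = version
        missing = {
            d for f in self.families for d in f.required_domains
            if d not in self.domain_models
        }
        if missing:
            raise RegistryError(
                f"required domains without a domain model: {sorted(missing)}"
            )

    def __iter__(self) -> Iterator[QueryFamily]:
        return iter(self.families)

    def __len__(self) -> int:
        return len(self.families)

    def __getitem__(self, name: str) -> QueryFamily:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.families)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return (
            self.domain_models == other.domain_models
            and len(self.families) == len(other.families)
            and all(a == b for a, b in zip(self.families, other.families))
        )


def load_registry(path: str | Path) -> Registry:
    """Load a registry from its YAML serialization, validating invariants."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "families" not in raw:
        raise RegistryError(f"registry file {path}: missing top-level 'families'")
    families = []
    for i, fam in enumerate(raw["families"]):
        for key in ("name", "seeds", "required_domains"):
            if key not in fam:
                raise RegistryError(
                    f"registry file {path}: family #{i} is missing field {key!r}"
                )
        seeds = [
            SequenceRecord(id=s["id"], sequence=s["sequence"],
                           library_id="registry")
            for s in fam["seeds"]
        ]
        families.append(QueryFamily(
            name=fam["name"],
            seed_sequences=seeds,
            required_domains=list(fam["required_domains"]),
            special_rule=fam.get("special_rule", "none"),
        ))
    return Registry(families, raw.get("domain_models", {}),
                    version=str(raw.get("version", "0")))


def save_registry(registry: Registry, path: str | Path) -> None:
    data = {
        "version": registry.version,
        "domain_models": dict(registry.domain_models),
        "families": [
            {
                "name": f.name,
                "special_rule": f.special_rule,
                "required_domains": list(f.required_domains),
                "seeds": [{"id": s.id, "sequence": s.sequence}
                          for s in f.seed_sequences],
            }
            for f in registry.families
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_registry() -> Registry:
    """The registry shipped with the package: 13 families plus CBA1."""
    with resources.as_file(
        resources.files("b12screen").joinpath("data/registry.yaml")
    ) as p:
        return load_registry(p)


def domain_consensus(domain_id: str, length: int = 36) -> str:
    """Deterministic synthetic consensus segment for a domain identifier.

    Used when generating registries and simulated proteins so that the same
    domain identifier always maps to the same consensus, independent of any
    run-time seed.
    """
    seed = zlib.crc32(domain_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA20), size=length))


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, library_id: str = "",
               scaffold_from_description: bool = False) -> list[SequenceRecord]:
    """Read a protein FASTA into :class:`SequenceRecord` objects.

    Trailing ``*`` stop characters are stripped; any residue outside the
    declared alphabet is mapped to ``X`` with a logged warning; records with
    an empty sequence are skipped with a warning.  The id is the first
    whitespace-delimited token of the header; the remainder is retained as
    the description.  If ``scaffold_from_description`` is set, a
    ``scaffold=<id>`` token in the description populates ``scaffold_id``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        logger.warning("FASTA file %s contains no records", path)
        return records
    seen: set[str] = set()
    for rec in parsed:
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            logger.warning("skipping record %s: empty sequence", rec.id)
            continue
        if set(seq) - ALPHABET:
            cleaned = re.sub(f"[^{AA20}X]", "X", seq)
            logger.warning(
                "record %s: %d non-alphabet residue(s) mapped to X",
                rec.id, sum(a != b for a, b in zip(seq, cleaned)))
            seq = cleaned
        if rec.id in seen:
            raise RegistryError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        scaffold = None
        if scaffold_from_description:
            m = re.search(r"scaffold=(\S+)", rec.description)
            if m:
                scaffold = m.group(1)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(
            id=rec.id, sequence=seq, library_id=library_id,
            scaffold_id=scaffold, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    bio = []
    for r in records:
        desc = r.description
        if r.scaffold_id:
            desc = (desc + f" scaffold={r.scaffold_id}").strip()
        bio.append(BioSeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# manifests and strain deduplication
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[LibraryManifest]:
    """Read a tab-separated library manifest.

    Expected columns: library_id, strain_name, library_type, lineage_group,
    source_collection, latitude, longitude, habitat (empty fields allowed in
    the last four).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    manifests = []
    for _, row in df.iterrows():
        site = None
        if row.get("latitude", "") or row.get("habitat", ""):
            site = CollectionSite(
                latitude=float(row["latitude"]) if row.get("latitude") else None,
                longitude=float(row["longitude"]) if row.get("longitude") else None,
                habitat=row.get("habitat") or None,
            )
        manifests.append(LibraryManifest(
            library_id=row["library_id"], strain_name=row["strain_name"],
            library_type=row["library_type"], lineage_group=row["lineage_group"],
            collection_site=site, source_collection=row.get("source_collection", ""),
        ))
    return manifests


def write_manifest(manifests: Sequence[LibraryManifest], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for m in manifests:
        site = m.collection_site
        rows.append({
            "library_id": m.library_id, "strain_name": m.strain_name,
            "library_type": m.library_type, "lineage_group": m.lineage_group,
            "source_collection": m.source_collection,
            "latitude": "" if site is None or site.latitude is None else site.latitude,
            "longitude": "" if site is None or site.longitude is None else site.longitude,
            "habitat": "" if site is None or site.habitat is None else site.habitat,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class Strain:
    """One unique strain after manifest deduplication."""

    name: str
    libraries: list[LibraryManifest] = field(default_factory=list)
    has_genome: bool = False
    lineage_group: str = ""
    collection_site: Optional[CollectionSite] = None

    @property
    def library_ids(self) -> list[str]:
        return [m.library_id for m in self.libraries]


def normalize_strain_name(name: str,
                          synonyms: Optional[dict[str, str]] = None) -> str:
    """Case-insensitive, whitespace-collapsed strain key, through synonyms."""
    key = re.sub(r"\s+", " ", name.strip()).casefold()
    if synonyms:
        folded = {re.sub(r"\s+", " ", k.strip()).casefold(): v
                  for k, v in synonyms.items()}
        key = re.sub(r"\s+", " ", folded.get(key, key).strip()).casefold()
    return key


def dedupe_strains(manifests: Sequence[LibraryManifest],
                   synonyms: Optional[dict[str, str]] = None) -> dict[str, Strain]:
    """Merge manifest rows into unique strains.

    Strains are matched case-insensitively on the normalized strain name
    (whitespace collapsed, culture-collection synonyms resolved through an
    explicit, user-supplied table).  A strain observed in several libraries
    carries the union of them; any genome library sets ``has_genome``.
    Conflicting lineage groups between merged rows raise an error.
    """
    strains: dict[str, Strain] = {}
    for m in manifests:
        key = normalize_strain_name(m.strain_name, synonyms)
        strain = strains.setdefault(key, Strain(name=m.strain_name))
        if strain.lineage_group and m.lineage_group and \
                strain.lineage_group != m.lineage_group:
            raise RegistryError(
                f"strain {m.strain_name!r}: conflicting lineage groups "
                f"{strain.lineage_group!r} vs {m.lineage_group!r}"
            )
        strain.libraries.append(m)
        strain.lineage_group = strain.lineage_group or m.lineage_group
        strain.has_genome = strain.has_genome or m.library_type == "genome"
        if strain.collection_site is None:
            strain.collection_site = m.collection_site
    return strains
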