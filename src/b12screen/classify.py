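"""Presence/absence aggregation and B12 metabolic status classification.

Validated, tree-curated, domain-complete calls are collapsed into a
strain x family presence matrix; each strain is then classified by the
joint presence of the two methionine synthase isoforms:

* METH and METE          -> facultative B12 user
* METH only              -> B12-dependent
* METE only              -> B12-independent
* neither                -> unknown

Because transcriptomes may under-report METE (it can be transcriptionally
repressed in B12-replete cultures), a METE absence only supports a
confident call when the strain has at least one sequenced genome; without
one, a METH-only strain is recorded as dependent with a low-confidence
flag, and the loss-of-B12 verdict is indeterminate.

A strain has lost all known B12-associated metabolism when it retains METE
but lacks METH, MTRR, MCM and RNR-II with a genome available.  Partial
presences (e.g. a METE missing its N-terminal domain) never count towards
status but are preserved in the matrix and reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .registry import (HABITAT_CLASSES, LibraryManifest, Registry, Strain,
                       dedupe_strains)

logger = logging.getLogger("b12screen")

#: cell values of the presence matrix, strongest first
CELL_RANK = ("present", "present_split", "present_partial",
             "contaminant_only", "absent")

METHIONINE_STATUSES = ("dependent_only", "facultative", "independent_only",
                       "unknown")

#: families whose absence (with METE present) defines loss of known
#: B12-associated metabolism
LOSS_RULE_FAMILIES = ("METH", "MTRR", "MCM", "RNR-II")

ADENOSYL_FAMILIES = ("MCM", "RNR-II")

#: families counted as accessory when only they are present
ACCESSORY_FAMILIES = ("CblA", "CblB", "CblC", "CblD", "CblF", "CblJ",
                      "CblX", "epi-CblC", "CBA1")

COMPARTMENTS = ("secretory", "mitochondrion", "plastid", "endomembrane",
                "other/none")


class ClassifyError(ValueError):
    pass


@dataclass
class FamilyCall:
    """One curated, completeness-assessed call feeding the matrix."""

    library_id: str
    family: str
    completeness_status: str  # complete | complete_split | partial | absent
    curation_flag: str = "clean"  # clean | contaminant | hgt
    record_ids: list[str] = field(default_factory=list)

    @property
    def cell_value(self) -> str:
        if self.curation_flag == "contaminant":
            return "contaminant_only"
        return {
            "complete": "present",
            "complete_split": "present_split",
            "partial": "present_partial",
            "absent": "absent",
        }[self.completeness_status]


@dataclass
class PresenceMatrix:
    """Strain x family matrix of validated presence calls."""

    table: pd.DataFrame  # index: strain keys; columns: families; cells: str
    strains: dict[str, Strain]
    audit: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    low_coverage: set[str] = field(default_factory=set)

    def has_genome(self, strain_key: str) -> bool:
        return self.strains[strain_key].has_genome

    def row(self, strain_key: str) -> pd.Series:
        return self.table.loc[strain_key]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "has_genome",
                   [self.strains[k].has_genome for k in out.index])
        out.insert(0, "strain",
                   [self.strains[k].name for k in out.index])
        out.to_csv(path, sep="\t", index_label="strain_key")


@dataclass
class B12Status:
    """Per-strain classification of B12-associated metabolism."""

    strain: str
    methionine_status: str
    adenosyl_users: list[str] = field(default_factory=list)
    lost_known_b12: bool | str = False  # True / False / "indeterminate"
    low_confidence: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.methionine_status not in METHIONINE_STATUSES:
            raise ClassifyError(
                f"unknown methionine status {self.methionine_status!r}")
        if self.lost_known_b12 is True:
            if self.methionine_status != "independent_only" or self.adenosyl_users:
                raise ClassifyError(
                    "lost_known_b12 requires independent-only methionine "
                    "status and no adenosylcobalamin users")

    @property
    def status_class(self) -> str:
        """Display class: red dependent, purple facultative, light-blue
        independent, grey unknown."""
        return {
            "dependent_only": "red",
            "facultative": "purple",
            "independent_only": "light-blue",
            "unknown": "grey",
        }[self.methionine_status]


@dataclass
class TargetingCall:
    """Consensus subcellular targeting over several predictor tools."""

    record_id: str
    per_tool: dict[str, str]
    consensus: str  # compartment or "ambiguous"
    note: str = ""


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_presence_matrix(validated_calls: Sequence[FamilyCall],
                          manifests: Sequence[LibraryManifest],
                          registry: Registry | Sequence[str],
                          synonyms: Optional[dict[str, str]] = None
                          ) -> PresenceMatrix:
    """Collapse per-library calls into one row per unique strain.

    Per strain and family the strongest cell value across the strain's
    libraries wins (present > present_split > present_partial >
    contaminant_only > absent); contaminant-flagged hits can never produce
    a presence.  Strains with no call at all are all-absent rows flagged
    low-coverage.
    """
    families = ([f.name for f in registry] if isinstance(registry, Registry)
                else list(registry))
    strains = dedupe_strains(manifests, synonyms)
    lib_to_strain = {m.library_id: key for key, s in strains.items()
                     for m in s.libraries}
    rank = {v: i for i, v in enumerate(CELL_RANK)}
    table = pd.DataFrame("absent", index=sorted(strains), columns=families)
    audit: dict[tuple[str, str], list[str]] = {}
    covered: set[str] = set()
    for call in validated_calls:
        if call.library_id not in lib_to_strain:
            raise ClassifyError(
                f"call references unknown library {call.library_id!r}")
        if call.family not in families:
            raise ClassifyError(f"call references unknown family "
                                f"{call.family!r}")
        key = lib_to_strain[call.library_id]
        covered.add(key)
        value = call.cell_value
        if rank[value] < rank[table.at[key, call.family]]:
            table.at[key, call.family] = value
        audit.setdefault((key, call.family), []).extend(call.record_ids)
    low_coverage = set(table.index) - covered
    return PresenceMatrix(table=table, strains=strains, audit=audit,
                          low_coverage=low_coverage)


def _present(value: str) -> bool:
    # partial presences never count towards status
    return value in ("present", "present_split")


def classify_b12_status(row: Mapping[str, str], has_genome: bool,
                        strain: str = "") -> B12Status:
    """Classify one strain's B12 metabolic status from its matrix row."""
    get = lambda fam: row.get(fam, "absent")
    meth, mete = _present(get("METH")), _present(get("METE"))
    adenosyl = [f for f in ADENOSYL_FAMILIES if _present(get(f))]
    low_confidence = False
    if meth and mete:
        status = "facultative"
    elif meth:
        status = "dependent_only"
        # a transcriptome-only strain may simply under-report METE
        low_confidence = not has_genome
    elif mete:
        status = "independent_only"
    else:
        status = "unknown"
    lost: bool | str = False
    if status == "independent_only" and \
            not any(_present(get(f)) for f in LOSS_RULE_FAMILIES):
        lost = True if has_genome else "indeterminate"
    note = ""
    accessory = [f for f in ACCESSORY_FAMILIES if _present(get(f))]
    if status == "unknown" and accessory:
        note = "accessory B12 proteins only: " + ", ".join(accessory)
    return B12Status(strain=strain, methionine_status=status,
                     adenosyl_users=adenosyl, lost_known_b12=lost,
                     low_confidence=low_confidence, note=note)


def classify_all(matrix: PresenceMatrix) -> dict[str, B12Status]:
    return {
        key: classify_b12_status(matrix.table.loc[key].to_dict(),
                                 matrix.has_genome(key),
                                 strain=matrix.strains[key].name)
        for key in matrix.table.index
    }


# ---------------------------------------------------------------------------
# targeting consensus
# ---------------------------------------------------------------------------

def targeting_consensus(per_tool: Mapping[str, str],
                        record_id: str = "") -> TargetingCall:
    """Strict-majority consensus over per-tool targeting predictions.

    Fewer than 3 predictions are insufficient for a consensus; with 3 or
    more, a compartment predicted by a strict majority of the supplied
    tools wins, otherwise the call is ambiguous.
    """
    if not per_tool:
        raise ClassifyError("at least one tool prediction is required")
    bad = {v for v in per_tool.values() if v not in COMPARTMENTS}
    if bad:
        raise ClassifyError(
            f"unknown compartment(s) {sorted(bad)}; accepted terms: "
            f"{COMPARTMENTS}")
    if len(per_tool) < 3:
        return TargetingCall(record_id, dict(per_tool), "ambiguous",
                             note="fewer than 3 tool predictions")
    counts = pd.Series(list(per_tool.values())).value_counts()
    if counts.iloc[0] * 2 > len(per_tool):
        return TargetingCall(record_id, dict(per_tool), str(counts.index[0]))
    return TargetingCall(record_id, dict(per_tool), "ambiguous")


# ---------------------------------------------------------------------------
# tabulations
# ---------------------------------------------------------------------------

def tabulate_groups(matrix: PresenceMatrix,
                    statuses: Mapping[str, B12Status]) -> pd.DataFrame:
    """Per-lineage-group counts of methionine synthase repertoires.

    Counts are over unique strains: how many carry METH only, METE only or
    both; how many are assessable at all; and, among strains with at least
    one B12 enzyme detected, per-family occurrence counts.
    """
    families = list(matrix.table.columns)
    rows = []
    groups = sorted({s.lineage_group for s in matrix.strains.values()})
    for grp in groups:
        keys = [k for k, s in matrix.strains.items()
                if s.lineage_group == grp]
        meth = {k for k in keys if _present(matrix.table.at[k, "METH"])} \
            if "METH" in families else set()
        mete = {k for k in keys if _present(matrix.table.at[k, "METE"])} \
            if "METE" in families else set()
        with_enzyme = [k for k in keys
                       if any(_present(matrix.table.at[k, f])
                              for f in families)]
        row = {
            "lineage_group": grp,
            "n_meth_only": len(meth - mete),
            "n_mete_only": len(mete - meth),
            "n_both": len(meth & mete),
            "n_assessable": len(keys),
        }
        for fam in families:
            row[f"n_{fam}"] = sum(
                _present(matrix.table.at[k, fam]) for k in with_enzyme)
        rows.append(row)
    return pd.DataFrame(rows).set_index("lineage_group")


def habitat_crosstab(statuses: Mapping[str, B12Status],
                     matrix: PresenceMatrix) -> tuple[pd.DataFrame, int]:
    """Habitat class x loss-of-known-B12 contingency table.

    Strains without a habitat tag, and strains whose loss verdict is
    indeterminate, are excluded; the number excluded is returned alongside
    the table.
    """
    counts = pd.DataFrame(0, index=list(HABITAT_CLASSES),
                          columns=[True, False])
    excluded = 0
    for key, status in statuses.items():
        strain = matrix.strains[key]
        site = strain.collection_site
        habitat = site.habitat if site else None
        if habitat not in HABITAT_CLASSES or \
                status.lost_known_b12 == "indeterminate":
            excluded += 1
            continue
        counts.at[habitat, bool(status.lost_known_b12)] += 1
    counts.columns = ["lost_known_b12", "retains_known_b12"]
    return counts, excluded
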