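"""End-to-end orchestration of the screening pipeline.

Stage order, per family: forward search -> reciprocal best-hit validation
-> alignment, iterative long-branch pruning, column trimming,
neighbour-joining with bootstrap -> contaminant/HGT flagging -> domain scan
and completeness assessment (with split-gene-model rescue on genomes) ->
presence matrix -> B12 status classification -> per-lineage and habitat
tabulations.

Every sequence that drops out of the presence chain appears in exactly one
exclusion log entry with a reason code (below_evalue is implicit in never
becoming a candidate; the recorded codes are reciprocal_fail,
divergent_branch, contaminant and incomplete_domains).  Runs are
single-process and deterministic: rerunning with the same inputs, seed and
configuration reproduces every artefact byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .classify import (B12Status, ClassifyError, FamilyCall, PresenceMatrix,
                       build_presence_matrix, classify_all, habitat_crosstab,
                       tabulate_groups)
from .curation import (CurationError, PhyloTree, bootstrap_support,
                       pairwise_identity, prune_divergent, trim_columns)
from .domains import (assess_completeness, family_profiles,
                      rescue_split_models, scan_domains)
from .registry import (LibraryManifest, PipelineConfig, Registry,
                       SequenceRecord, dedupe_strains)
from .search import (CandidateHit, ScoringScheme, ValidationSequence,
                     find_candidates, reciprocal_validate)

logger = logging.getLogger("b12screen")

REASON_CODES = ("below_evalue", "reciprocal_fail", "divergent_branch",
                "contaminant", "incomplete_domains", "low_coverage")

STAGES = ("candidates", "validated", "post_curation", "complete")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and family it occurred in."""

    def __init__(self, stage: str, family: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for family {family!r}: "
                         f"{cause}")
        self.stage, self.family, self.cause = stage, family, cause


@dataclass
class ExclusionRecord:
    record_id: str
    library_id: str
    family: str
    stage: str
    reason: str
    detail: str = ""


@dataclass
class RunReport:
    """Everything a pipeline run produces, plus its audit trail."""

    config: PipelineConfig
    config_hash: str
    stage_counts: pd.DataFrame          # families x stages
    matrix: PresenceMatrix
    statuses: dict[str, B12Status]
    group_counts: pd.DataFrame
    habitat_table: pd.DataFrame
    habitat_excluded: int
    exclusions: list[ExclusionRecord]
    family_calls: list[FamilyCall]
    trees: dict[str, PhyloTree]
    tip_flags: dict[str, dict[str, str]]
    isoform_assignments: dict[str, dict[str, str]]
    warnings: list[str]
    timings: dict[str, float]

    def status_table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.statuses):
            s = self.statuses[key]
            audit = sorted({rid for (k, _), rids in self.matrix.audit.items()
                            if k == key for rid in rids})
            rows.append({
                "strain_key": key, "strain": s.strain,
                "methionine_status": s.methionine_status,
                "status_class": s.status_class,
                "adenosyl_users": ",".join(s.adenosyl_users),
                "lost_known_b12": s.lost_known_b12,
                "low_confidence": s.low_confidence,
                "note": s.note,
                "audit_records": ";".join(audit),
            })
        return pd.DataFrame(rows)

    def exclusion_table(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.exclusions],
                            columns=["record_id", "library_id", "family",
                                     "stage", "reason", "detail"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.write_tsv(outdir / "presence_matrix.tsv")
        self.status_table().to_csv(outdir / "statuses.tsv", sep="\t",
                                   index=False)
        self.group_counts.to_csv(outdir / "group_counts.tsv", sep="\t")
        self.habitat_table.to_csv(outdir / "habitat_crosstab.tsv", sep="\t")
        self.stage_counts.to_csv(outdir / "stage_counts.tsv", sep="\t")
        self.exclusion_table().to_csv(outdir / "exclusions.tsv", sep="\t",
                                      index=False)
        for fam, tree in self.trees.items():
            with open(outdir / f"tree_{fam}.nwk", "w") as fh:
                fh.write(tree.to_newick(with_support=True) + "\n")
        meta = {"config_hash": self.config_hash,
                "config": self.config.__dict__,
                "warnings": self.warnings,
                "timings": {k: round(v, 3) for k, v in self.timings.items()}}
        (outdir / "run_meta.yaml").write_text(yaml.safe_dump(meta))


def config_hash(config: PipelineConfig) -> str:
    payload = yaml.safe_dump(config.__dict__, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _family_seed(config: PipelineConfig, family: str) -> int:
    return (config.random_seed * 1_000_003
            + zlib.crc32(family.encode())) % (2 ** 31)


def run_pipeline(config: PipelineConfig, registry: Registry,
                 libraries: dict[str, Sequence[SequenceRecord]],
                 manifests: Sequence[LibraryManifest],
                 validation_db: Sequence[ValidationSequence],
                 reference_homologues: Optional[
                     dict[str, Sequence[SequenceRecord]]] = None,
                 synonyms: Optional[dict[str, str]] = None,
                 isoform_anchors: Optional[dict[str, dict[str, set]]] = None,
                 scheme: Optional[ScoringScheme] = None) -> RunReport:
    """Run the full screen over a set of libraries.

    ``reference_homologues`` supplies, per family, prokaryotic (or other
    outgroup) homologues to be included in the curation trees; without them
    the bacterial-nesting contaminant rule cannot fire.  ``isoform_anchors``
    optionally maps a family to anchor tip sets for isoform-clade
    assignment (e.g. the Arabidopsis methionine synthases for METE).
    """
    scheme = scheme or ScoringScheme()
    reference_homologues = reference_homologues or {}
    manifest_by_lib = {m.library_id: m for m in manifests}
    unknown = set(libraries) - set(manifest_by_lib)
    if unknown:
        raise ClassifyError(f"libraries without manifest rows: "
                            f"{sorted(unknown)}")
    strains = dedupe_strains(manifests, synonyms)
    strain_of_lib = {m.library_id: key for key, s in strains.items()
                     for m in s.libraries}

    counts = pd.DataFrame(0, index=[f.name for f in registry],
                          columns=list(STAGES))
    exclusions: list[ExclusionRecord] = []
    family_calls: list[FamilyCall] = []
    trees: dict[str, PhyloTree] = {}
    tip_flags: dict[str, dict[str, str]] = {}
    isoform_assignments: dict[str, dict[str, str]] = {}
    warnings: list[str] = []
    timings: dict[str, float] = {}

    total_residues = sum(len(r.sequence) for recs in libraries.values()
                         for r in recs)
    for family in registry:
        fam = family.name
        t0 = time.perf_counter()
        # ---- forward search -------------------------------------------------
        try:
            candidates: list[CandidateHit] = []
            for lib_id in sorted(libraries):
                candidates.extend(find_candidates(
                    family, list(libraries[lib_id]), config, scheme,
                    db_residues=total_residues))
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("find_candidates", fam, exc)
        counts.at[fam, "candidates"] = len(candidates)
        timings[f"{fam}:search"] = time.perf_counter() - t0

        # ---- reciprocal validation -----------------------------------------
        t0 = time.perf_counter()
        validated: list[CandidateHit] = []
        for hit in candidates:
            result = reciprocal_validate(hit, validation_db, config, scheme)
            if result.validated:
                validated.append(hit)
            else:
                exclusions.append(ExclusionRecord(
                    hit.record.id, hit.record.library_id, fam,
                    "reciprocal", "reciprocal_fail",
                    f"best match {result.matched_id} ({result.matched_role})"))
        counts.at[fam, "validated"] = len(validated)
        timings[f"{fam}:reciprocal"] = time.perf_counter() - t0

        # ---- tree curation --------------------------------------------------
        t0 = time.perf_counter()
        refs = list(reference_homologues.get(fam, []))
        # the query seeds are aligned in with the homologues, exactly as in
        # the screening protocol: they anchor vertical homologues away from
        # the prokaryotic reference clade during contaminant inspection
        seed_ids = {s.id for s in family.seed_sequences}
        flags: dict[str, str] = {}
        surviving = list(validated)
        if len(validated) + len(refs) >= 4 and len(validated) >= 1:
            try:
                prune = prune_divergent(
                    [h.record for h in validated]
                    + list(family.seed_sequences) + refs, config, scheme)
            except CurationError as exc:
                raise PipelineError("prune_divergent", fam, exc)
            removed_ids = {e["id"] for e in prune.removed_log}
            if prune.unalignable:
                warnings.append(f"family {fam}: flagged unalignable "
                                "(long branches remain at 4 sequences)")
            still: list[CandidateHit] = []
            for hit in validated:
                if hit.record.id in removed_ids:
                    entry = next(e for e in prune.removed_log
                                 if e["id"] == hit.record.id)
                    hit.set_status("rejected_divergent")
                    exclusions.append(ExclusionRecord(
                        hit.record.id, hit.record.library_id, fam,
                        "curation", "divergent_branch",
                        f"terminal branch {entry['branch_length']:.2f} "
                        f"subst/site (iteration {entry['iteration']})"))
                else:
                    still.append(hit)
            surviving = still
            if prune.msa is not None and prune.msa.n_rows >= 3:
                try:
                    trimmed = trim_columns(prune.msa, config)
                except CurationError as exc:
                    raise PipelineError("trim_columns", fam, exc)
                if trimmed.n_rows >= 3:
                    tree = bootstrap_support(
                        trimmed, config.nj_replicates,
                        _family_seed(config, fam), config)
                    for tip in tree.tip_labels():
                        hit = next((h for h in surviving
                                    if h.record.id == tip), None)
                        if hit is None:
                            if tip in seed_ids:
                                tree.annotations[tip] = {
                                    "domain": "eukaryote",
                                    "lineage_group": "query reference",
                                    "strain": tip,
                                }
                            else:
                                tree.annotations[tip] = {"domain": "bacteria"}
                        else:
                            man = manifest_by_lib[hit.record.library_id]
                            tree.annotations[tip] = {
                                "domain": "eukaryote",
                                "lineage_group": man.lineage_group,
                                "library_id": man.library_id,
                                "strain": strain_of_lib[man.library_id],
                            }
                    flags = flag_contaminants_safe(tree, trimmed, config,
                                                   warnings, fam)
                    trees[fam] = tree
                    tip_flags[fam] = flags
                    if isoform_anchors and fam in isoform_anchors:
                        from .curation import assign_isoform_clade
                        isoform_assignments[fam] = assign_isoform_clade(
                            tree, isoform_anchors[fam])
        elif validated:
            warnings.append(f"family {fam}: too few sequences for tree "
                            "curation; hits pass through unflagged")
        timings[f"{fam}:curation"] = time.perf_counter() - t0

        # ---- contaminant bookkeeping ---------------------------------------
        clean_hits: list[CandidateHit] = []
        contaminant_hits: list[CandidateHit] = []
        hgt_ids: set[str] = set()
        for hit in surviving:
            flag = flags.get(hit.record.id, "clean")
            if flag == "contaminant":
                hit.set_status("rejected_contaminant")
                contaminant_hits.append(hit)
                exclusions.append(ExclusionRecord(
                    hit.record.id, hit.record.library_id, fam,
                    "curation", "contaminant",
                    "resolved with prokaryotic homologues"))
            else:
                if flag == "hgt":
                    hgt_ids.add(hit.record.id)
                clean_hits.append(hit)
        counts.at[fam, "post_curation"] = len(clean_hits)

        # ---- domain completeness -------------------------------------------
        t0 = time.perf_counter()
        profiles = family_profiles(family, registry.domain_models, scheme)
        by_library: dict[str, list[CandidateHit]] = {}
        for hit in clean_hits:
            by_library.setdefault(hit.record.library_id, []).append(hit)
        n_complete = 0
        for lib_id in sorted(by_library):
            hits_here = by_library[lib_id]
            calls = []
            for hit in hits_here:
                dom_hits = scan_domains(hit.record.sequence, profiles, config)
                calls.append(assess_completeness(dom_hits, family,
                                                 hit.record.id))
            manifest = manifest_by_lib[lib_id]
            if manifest.library_type == "genome" and not any(
                    c.status == "complete" for c in calls):
                call = rescue_split_models(
                    calls, [h.record for h in hits_here], family)
            else:
                call = max(calls, key=lambda c: (
                    {"complete": 3, "complete_split": 2, "partial": 1,
                     "absent": 0}[c.status], len(c.found_domains)))
            if call.status in ("complete", "complete_split"):
                n_complete += 1
            else:
                for c in calls:
                    for rid in c.contributing_records:
                        exclusions.append(ExclusionRecord(
                            rid, lib_id, fam, "domains",
                            "incomplete_domains",
                            "missing: " + ",".join(c.missing_domains)))
            contributing = call.contributing_records or \
                [h.record.id for h in hits_here]
            family_calls.append(FamilyCall(
                library_id=lib_id, family=fam,
                completeness_status=call.status,
                curation_flag="hgt" if any(
                    h.record.id in hgt_ids for h in hits_here) else "clean",
                record_ids=contributing))
        counts.at[fam, "complete"] = n_complete
        for hit in contaminant_hits:
            family_calls.append(FamilyCall(
                library_id=hit.record.library_id, family=fam,
                completeness_status="complete", curation_flag="contaminant",
                record_ids=[hit.record.id]))
        timings[f"{fam}:domains"] = time.perf_counter() - t0

    # ---- aggregation --------------------------------------------------------
    t0 = time.perf_counter()
    matrix = build_presence_matrix(family_calls, manifests, registry,
                                   synonyms)
    for key in matrix.low_coverage:
        exclusions.append(ExclusionRecord(
            "", "", "", "aggregation", "low_coverage",
            f"strain {matrix.strains[key].name!r} has no validated hit"))
    statuses = classify_all(matrix)
    group_counts = tabulate_groups(matrix, statuses)
    habitat_table, habitat_excluded = habitat_crosstab(statuses, matrix)
    timings["aggregate"] = time.perf_counter() - t0

    return RunReport(
        config=config, config_hash=config_hash(config),
        stage_counts=counts, matrix=matrix, statuses=statuses,
        group_counts=group_counts, habitat_table=habitat_table,
        habitat_excluded=habitat_excluded, exclusions=exclusions,
        family_calls=family_calls, trees=trees, tip_flags=tip_flags,
        isoform_assignments=isoform_assignments, warnings=warnings,
        timings=timings)


def flag_contaminants_safe(tree: PhyloTree, msa, config: PipelineConfig,
                           warnings: list[str], fam: str) -> dict[str, str]:
    from .curation import flag_contaminants

    try:
        return flag_contaminants(tree, pairwise_identity(msa), config)
    except CurationError as exc:
        warnings.append(f"family {fam}: contaminant flagging skipped: {exc}")
        return {}


# ---------------------------------------------------------------------------
# summary rendering
# ---------------------------------------------------------------------------

def render_summaries(report: RunReport,
                     species_tree: Optional[PhyloTree] = None,
                     strain_of_tip: Optional[dict[str, str]] = None
                     ) -> dict[str, object]:
    """Produce the summary artefacts of a run.

    * ``group_counts``: per-lineage counts of METH/METE repertoires and
      per-family occurrences;
    * ``loss_table``: strains retaining METE but lacking METH and MTRR,
      with collection metadata and notes listing any retained accessory
      families (strains with an adenosylcobalamin enzyme stay in the table
      but are excluded from the strict no-known-B12 subset);
    * ``status_newick`` (when a species tree and tip-to-strain map are
      given): the tree with each tip annotated by its status class.
    """
    matrix = report.matrix
    rows = []
    for key in sorted(matrix.table.index):
        row = matrix.table.loc[key]
        present = lambda f: row.get(f, "absent") in ("present",
                                                     "present_split")
        if not (present("METE") and not present("METH")
                and not present("MTRR")):
            continue
        strain = matrix.strains[key]
        others = [f for f in matrix.table.columns
                  if f != "METE" and present(f)]
        site = strain.collection_site
        status = report.statuses[key]
        rows.append({
            "species": strain.name,
            "lineage": strain.lineage_group,
            "strain": strain.name,
            "ecological_context":
                site.habitat if site and site.habitat else "N/A",
            "collection_latitude":
                site.latitude if site and site.latitude is not None else "N/A",
            "collection_longitude":
                site.longitude if site and site.longitude is not None else "N/A",
            "notes": ("encodes " + ", ".join(others)) if others else "",
            "lost_known_b12": status.lost_known_b12,
        })
    loss_table = pd.DataFrame(
        rows, columns=["species", "lineage", "strain", "ecological_context",
                       "collection_latitude", "collection_longitude",
                       "notes", "lost_known_b12"])
    out: dict[str, object] = {
        "group_counts": report.group_counts,
        "loss_table": loss_table,
    }
    if species_tree is not None and strain_of_tip is not None:
        from .registry import normalize_strain_name

        labelled = []
        for tip in species_tree.tip_labels():
            key = normalize_strain_name(strain_of_tip.get(tip, ""))
            cls = (report.statuses[key].status_class
                   if key in report.statuses else "grey")
            labelled.append((tip, f"{tip}|{cls}"))
        newick = species_tree.to_newick()
        for tip, new in labelled:
            newick = newick.replace(f"{tip}:", f"{new}:")
        out["status_newick"] = newick
    return out


# ---------------------------------------------------------------------------
# directory-based input loading (the on-disk layout written by
# SyntheticCohort.write and expected by the command-line interface)
# ---------------------------------------------------------------------------

def load_run_inputs(indir: str | Path):
    """Load registry, libraries, manifests, validation DB and reference
    homologues from a run directory."""
    from .registry import load_registry, read_fasta, read_manifest

    indir = Path(indir)
    registry = load_registry(indir / "registry.yaml")
    manifests = read_manifest(indir / "manifest.tsv")
    libraries = {}
    for fasta in sorted((indir / "libraries").glob("*.fasta")):
        lib_id = fasta.stem
        libraries[lib_id] = read_fasta(fasta, library_id=lib_id,
                                       scaffold_from_description=True)
    roles = pd.read_csv(indir / "validation_roles.tsv", sep="\t").fillna("")
    role_of = {row["id"]: (row["role"], row["family"])
               for _, row in roles.iterrows()}
    validation_db = []
    for rec in read_fasta(indir / "validation_db.fasta",
                          library_id="validation"):
        role, family = role_of[rec.id]
        validation_db.append(ValidationSequence(record=rec, role=role,
                                                family=family))
    references = {}
    ref_dir = indir / "references"
    if ref_dir.is_dir():
        for fasta in sorted(ref_dir.glob("*.fasta")):
            references[fasta.stem] = read_fasta(fasta,
                                                library_id=fasta.stem)
    return registry, libraries, manifests, validation_db, references
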