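import numpy as np
import pytest

from b12screen.classify import (B12Status, ClassifyError, FamilyCall,
                                build_presence_matrix, classify_all,
                                classify_b12_status, habitat_crosstab,
                                tabulate_groups, targeting_consensus)
from b12screen.registry import (CollectionSite, LibraryManifest,
                                normalize_strain_name)

FAMILIES = ["METE", "METH", "MTRR", "MCM", "RNR-II", "CblB"]


def manifest(lib, strain, lib_type="genome", group="hornworts",
             habitat=None):
    site = CollectionSite(habitat=habitat) if habitat else None
    return LibraryManifest(library_id=lib, strain_name=strain,
                           library_type=lib_type, lineage_group=group,
                           collection_site=site)


def fcall(lib, family, status="complete", flag="clean", records=None):
    return FamilyCall(library_id=lib, family=family,
                      completeness_status=status, curation_flag=flag,
                      record_ids=records or [f"{lib}_{family}_r1"])


class TestPresenceMatrix:
    def test_strongest_evidence_across_libraries_wins(self):
        manifests = [manifest("g1", "Anthoceros agrestis", "genome"),
                     manifest("t1", "Anthoceros agrestis", "transcriptome")]
        matrix = build_presence_matrix(
            [fcall("g1", "METH", "complete_split"),
             fcall("t1", "METH", "complete")],
            manifests, FAMILIES)
        key = normalize_strain_name("Anthoceros agrestis")
        assert matrix.table.at[key, "METH"] == "present"
        assert matrix.has_genome(key)
        assert len(matrix.audit[(key, "METH")]) == 2

    def test_contaminant_flagged_hits_never_yield_presence(self):
        manifests = [manifest("t1", "Blasia sp.", "transcriptome",
                              group="liverworts")]
        matrix = build_presence_matrix(
            [fcall("t1", "METH", "complete", flag="contaminant")],
            manifests, FAMILIES)
        key = normalize_strain_name("Blasia sp.")
        assert matrix.table.at[key, "METH"] == "contaminant_only"

    def test_empty_call_set_gives_all_absent_low_coverage(self):
        manifests = [manifest("g1", "S1"), manifest("g2", "S2")]
        matrix = build_presence_matrix([], manifests, FAMILIES)
        assert (matrix.table == "absent").all().all()
        assert len(matrix.low_coverage) == 2

    def test_unknown_library_raises(self):
        with pytest.raises(ClassifyError, match="unknown library"):
            build_presence_matrix([fcall("nope", "METH")],
                                  [manifest("g1", "S1")], FAMILIES)


def row(**kw):
    base = {f: "absent" for f in FAMILIES}
    base.update(kw)
    return base


class TestB12Status:
    def test_hornwort_like_row_is_facultative(self):
        status = classify_b12_status(
            row(METH="present", METE="present", MTRR="present"), True)
        assert status.methionine_status == "facultative"
        assert status.status_class == "purple"
        assert status.lost_known_b12 is False

    def test_mete_only_with_genome_has_lost_known_b12(self):
        status = classify_b12_status(row(METE="present"), True)
        assert status.methionine_status == "independent_only"
        assert status.lost_known_b12 is True
        assert status.status_class == "light-blue"

    def test_galdieria_like_row_keeps_adenosyl_metabolism(self):
        status = classify_b12_status(row(METE="present", MCM="present"), True)
        assert status.methionine_status == "independent_only"
        assert status.lost_known_b12 is False
        assert status.adenosyl_users == ["MCM"]

    def test_mete_only_without_genome_is_indeterminate_loss(self):
        status = classify_b12_status(row(METE="present"), False)
        assert status.lost_known_b12 == "indeterminate"

    def test_transcriptome_only_meth_is_low_confidence_dependent(self):
        status = classify_b12_status(row(METH="present"), False)
        assert status.methionine_status == "dependent_only"
        assert status.low_confidence
        genome = classify_b12_status(row(METH="present"), True)
        assert genome.methionine_status == "dependent_only"
        assert not genome.low_confidence

    def test_partial_presence_counts_as_absent_for_status(self):
        status = classify_b12_status(
            row(METE="present_partial", METH="present"), True)
        assert status.methionine_status == "dependent_only"

    def test_split_presence_counts_as_present(self):
        status = classify_b12_status(
            row(METH="present_split", METE="present"), True)
        assert status.methionine_status == "facultative"

    def test_neither_synthase_is_unknown_with_accessory_note(self):
        status = classify_b12_status(row(CblB="present"), True)
        assert status.methionine_status == "unknown"
        assert "CblB" in status.note

    def test_loss_flag_invariant_enforced(self):
        with pytest.raises(ClassifyError):
            B12Status(strain="x", methionine_status="facultative",
                      lost_known_b12=True)

    def test_pure_function_of_row_and_genome_flag(self):
        r = row(METE="present", MCM="present")
        a = classify_b12_status(dict(r), True)
        b = classify_b12_status(dict(reversed(list(r.items()))), True)
        assert (a.methionine_status, a.lost_known_b12) == \
            (b.methionine_status, b.lost_known_b12)


class TestTargetingConsensus:
    def test_four_of_five_majority(self):
        call = targeting_consensus(
            {"WolfPSort": "mitochondrion", "SignalP": "mitochondrion",
             "ASAFind": "mitochondrion", "TargetP": "mitochondrion",
             "HECTAR": "secretory"})
        assert call.consensus == "mitochondrion"

    def test_split_vote_is_ambiguous(self):
        call = targeting_consensus(
            {"a": "plastid", "b": "plastid", "c": "secretory",
             "d": "secretory", "e": "other/none"})
        assert call.consensus == "ambiguous"

    def test_fewer_than_three_tools_is_ambiguous(self):
        call = targeting_consensus({"a": "plastid"})
        assert call.consensus == "ambiguous" and "fewer than 3" in call.note

    def test_unknown_compartment_raises_with_vocabulary(self):
        with pytest.raises(ClassifyError, match="accepted terms"):
            targeting_consensus({"a": "nucleus", "b": "plastid",
                                 "c": "plastid"})


class TestTabulations:
    def _cohort(self):
        manifests = [
            manifest("g1", "Horn 1", group="hornworts"),
            manifest("g2", "Horn 2", group="hornworts"),
            manifest("g3", "Alga 1", group="chlorophytes"),
            manifest("g4", "Alga 2", group="chlorophytes"),
            manifest("g5", "Alga 3", group="chlorophytes"),
        ]
        calls = [
            fcall("g1", "METH"), fcall("g1", "METE"),   # both
            fcall("g2", "METE"),                        # METE only
            fcall("g3", "METH"),                        # METH only
            fcall("g4", "METE"), fcall("g4", "MCM"),    # METE + MCM
        ]
        matrix = build_presence_matrix(calls, manifests, FAMILIES)
        return matrix, classify_all(matrix)

    def test_counts_match_constructed_truth(self):
        matrix, statuses = self._cohort()
        table = tabulate_groups(matrix, statuses)
        horn = table.loc["hornworts"]
        assert (horn["n_both"], horn["n_mete_only"], horn["n_meth_only"],
                horn["n_assessable"]) == (1, 1, 0, 2)
        chloro = table.loc["chlorophytes"]
        assert (chloro["n_both"], chloro["n_mete_only"],
                chloro["n_meth_only"], chloro["n_assessable"]) == (0, 1, 1, 3)
        assert chloro["n_MCM"] == 1

    def test_repertoire_partition_bounded_by_assessable(self):
        matrix, statuses = self._cohort()
        table = tabulate_groups(matrix, statuses)
        partition = (table["n_meth_only"] + table["n_mete_only"]
                     + table["n_both"])
        assert (partition <= table["n_assessable"]).all()

    def test_counts_are_over_strains_not_libraries(self):
        manifests = [manifest("g1", "Same strain", "genome"),
                     manifest("t1", "Same strain", "transcriptome")]
        matrix = build_presence_matrix(
            [fcall("g1", "METE"), fcall("t1", "METE")], manifests, FAMILIES)
        table = tabulate_groups(matrix, classify_all(matrix))
        assert table.loc["hornworts", "n_mete_only"] == 1


class TestHabitatCrosstab:
    #: loss-table analogue: 15 strains, habitat class and whether the strict
    #: no-known-B12 rule applies (4 of the 15 retain MCM/RNR-II or similar)
    TABLE_ROWS = [
        ("Blastophysa cf. rhizopus", "marine", True),
        ("Botryococcus braunii", "freshwater", True),
        ("Brandtodinium nutriculum", "symbiotic", True),
        ("Cephaleuros virescens", "symbiotic", True),
        ("Coccomyxa pringsheimii", "freshwater", True),
        ("Cyanidioschyzon merolae", "terrestrial", True),
        ("Galdieria sulphuraria", "terrestrial", False),
        ("Geminigera cryophila", "marine", True),
        ("Ignatius tetrasporus", "freshwater", False),
        ("Leptosira obovata", "freshwater", True),
        ("Porphyridium cruentum", "freshwater", False),
        ("Poteriospumella JBC07", "freshwater", True),
        ("Pseudoscourfieldia marina", "marine", False),
        ("Trentepohlia annulata", "freshwater", True),
        ("Vitrella brassicaformis", "symbiotic", True),
    ]

    def _matrix(self, rows):
        manifests = [
            manifest(f"g{i}", name, habitat=habitat)
            for i, (name, habitat, _) in enumerate(rows)
        ]
        calls = []
        for i, (name, _, lost) in enumerate(rows):
            calls.append(fcall(f"g{i}", "METE"))
            if not lost:
                calls.append(fcall(f"g{i}", "MCM"))
        matrix = build_presence_matrix(calls, manifests, FAMILIES)
        return matrix, classify_all(matrix)

    def test_encoded_loss_table_row_sums_match_species_counts(self):
        matrix, statuses = self._matrix(self.TABLE_ROWS)
        table, excluded = habitat_crosstab(statuses, matrix)
        assert excluded == 0
        assert int(table.to_numpy().sum()) == 15
        assert int(table["lost_known_b12"].sum()) == 11
        # freshwater strict losses encoded above: Botryococcus, Coccomyxa,
        # Leptosira, Poteriospumella, Trentepohlia
        assert table.at["freshwater", "lost_known_b12"] == 5

    def test_all_losses_freshwater_gives_clean_margins(self):
        rows = [("S1", "freshwater", True), ("S2", "freshwater", True),
                ("S3", "marine", False)]
        matrix, statuses = self._matrix(rows)
        table, _ = habitat_crosstab(statuses, matrix)
        assert table.at["freshwater", "lost_known_b12"] == 2
        assert table.at["marine", "lost_known_b12"] == 0

    def test_missing_habitat_excluded_with_count(self):
        manifests = [manifest("g1", "S1", habitat="freshwater"),
                     manifest("g2", "S2")]  # no collection site
        matrix = build_presence_matrix(
            [fcall("g1", "METE"), fcall("g2", "METE")], manifests, FAMILIES)
        table, excluded = habitat_crosstab(classify_all(matrix), matrix)
        assert excluded == 1
        assert int(table.to_numpy().sum()) == 1
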