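import math

import numpy as np
import pytest

from oracles import random_additive_matrix

from b12screen.curation import (D_CAP, CurationError, DistanceMatrix,
                                MultipleAlignment, PhyloTree,
                                assign_isoform_clade, bootstrap_support,
                                flag_contaminants, nj_tree, pairwise_identity,
                                poisson_distance, profile_align,
                                prune_divergent, trim_columns)
from b12screen.registry import AA20, PipelineConfig, SequenceRecord
from b12screen.simulate import _decode_aa, _encode_aa, _mutate


def rec(id, sequence):
    return SequenceRecord(id=id, sequence=sequence, library_id="lib")


def related_family(rng, n, length=120, divergence=0.15):
    """n sequences independently diverged from one random ancestor."""
    root = _encode_aa("".join(rng.choice(list(AA20), size=length)))
    return [rec(f"s{i:02d}", _decode_aa(_mutate(root, divergence, rng)))
            for i in range(n)]


class TestProfileAlign:
    def test_identical_pair_aligns_gapless(self):
        msa = profile_align([rec("a", "ACDEFGHIKL"), rec("b", "ACDEFGHIKL")])
        assert msa.rows == ["ACDEFGHIKL", "ACDEFGHIKL"]

    def test_single_deletion_opens_gap_opposite_missing_residue(self):
        msa = profile_align([rec("a", "ACDE"), rec("b", "ACE")])
        assert msa.rows == ["ACDE", "AC-E"]

    def test_ungapping_rows_recovers_inputs(self):
        rng = np.random.default_rng(21)
        seqs = related_family(rng, 6, divergence=0.3)
        # one truncated sequence exercises end-gap handling
        seqs.append(rec("trunc", seqs[0].sequence[40:]))
        msa = profile_align(seqs)
        for s in seqs:
            assert msa.ungapped(s.id) == s.sequence

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(CurationError):
            profile_align([rec("a", "ACDE")])


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        d = poisson_distance(MultipleAlignment(["a", "b"],
                                               ["ACDEF", "ACDEF"]))
        assert d.matrix[0, 1] == 0.0

    def test_half_mismatch_gives_ln_two(self):
        d = poisson_distance(MultipleAlignment(["a", "b"],
                                               ["AAAA", "AACC"]))
        assert d.matrix[0, 1] == pytest.approx(math.log(2))

    def test_saturated_pairs_capped(self):
        row_a = "A" * 100
        row_b = "A" * 4 + "C" * 96  # p = 0.96 >= cap
        d = poisson_distance(MultipleAlignment(["a", "b"], [row_a, row_b]))
        assert d.matrix[0, 1] == pytest.approx(D_CAP)
        worse = poisson_distance(MultipleAlignment(["a", "b"],
                                                   [row_a, "C" * 100]))
        assert worse.matrix[0, 1] == pytest.approx(D_CAP)  # no increase

    def test_disjoint_rows_capped_not_infinite(self):
        d = poisson_distance(MultipleAlignment(
            ["a", "b", "c"], ["AAAA----", "----CCCC", "AAAACCCC"]))
        assert d.matrix[0, 1] == pytest.approx(D_CAP)

    def test_gap_columns_excluded_from_denominator(self):
        d = poisson_distance(MultipleAlignment(["a", "b"],
                                               ["AA--AA", "AACCAC"]))
        # 4 shared columns, 1 mismatch
        assert d.matrix[0, 1] == pytest.approx(-math.log(1 - 0.25))


class TestNeighbourJoining:
    def test_recovers_known_quartet_exactly(self):
        # additive matrix of ((A:1,B:1):1,(C:2,D:3))
        d = DistanceMatrix(["A", "B", "C", "D"], np.array(
            [[0, 2, 4, 5], [2, 0, 4, 5], [4, 4, 0, 5], [5, 5, 5, 0]], float))
        tree = nj_tree(d)
        assert tree.has_bipartition(frozenset(["A", "B"]))
        pl = tree.path_length_matrix()
        assert np.allclose(pl.matrix, d.matrix)
        assert tree.terminal_branch_lengths() == pytest.approx(
            {"A": 1.0, "B": 1.0, "C": 2.0, "D": 3.0})

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        lengths = nj_tree(d).terminal_branch_lengths()
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    @pytest.mark.parametrize("n_tips", [4, 5, 6, 7, 8])
    def test_exact_on_random_additive_matrices(self, n_tips):
        rng = np.random.default_rng(100 + n_tips)
        for _ in range(20):
            labels, d = random_additive_matrix(rng, n_tips)
            tree = nj_tree(DistanceMatrix(labels, d))
            pl = tree.path_length_matrix()
            order = [pl.labels.index(l) for l in labels]
            assert np.allclose(pl.matrix[np.ix_(order, order)], d,
                               atol=1e-8)

    def test_agrees_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(77)
        labels, d = random_additive_matrix(rng, 7)
        ours = nj_tree(DistanceMatrix(labels, d))
        theirs = PhyloTree.from_newick(
            str(skbio_nj(SkbioDM(d, ids=labels)).root_at_midpoint()))
        all_tips = frozenset(labels)
        ours_sides = {s if "t0" in s else all_tips - s
                      for s in ours.edge_sides() if 1 < len(s) < len(labels) - 1}
        theirs_sides = {s if "t0" in s else all_tips - s
                        for s in theirs.edge_sides()
                        if 1 < len(s) < len(labels) - 1}
        assert ours_sides == theirs_sides

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(CurationError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


class TestPruneDivergent:
    def test_conserved_family_fully_retained(self):
        rng = np.random.default_rng(31)
        seqs = related_family(rng, 8, divergence=0.1)
        result = prune_divergent(seqs)
        assert [s.id for s in result.retained] == [s.id for s in seqs]
        assert result.removed_log == []

    def test_random_rogue_removed_in_first_iteration(self):
        rng = np.random.default_rng(32)
        seqs = related_family(rng, 9, divergence=0.1)
        rogue = rec("rogue", "".join(rng.choice(list(AA20), size=120)))
        result = prune_divergent(seqs + [rogue])
        assert [e["id"] for e in result.removed_log] == ["rogue"]
        assert result.removed_log[0]["iteration"] == 1
        assert result.removed_log[0]["branch_length"] > 1.0

    def test_branch_exactly_at_threshold_is_retained(self):
        rng = np.random.default_rng(33)
        seqs = related_family(rng, 6, divergence=0.05)
        outlier = rec("far", _decode_aa(
            _mutate(_encode_aa(seqs[0].sequence), 1.6, rng)))
        pool = seqs + [outlier]
        baseline = prune_divergent(pool)
        assert [e["id"] for e in baseline.removed_log] == ["far"]
        branch = baseline.removed_log[0]["branch_length"]
        # the rule is strictly greater-than: a branch of exactly the
        # threshold length survives
        at_threshold = prune_divergent(
            pool, PipelineConfig(branch_length_threshold=branch))
        assert at_threshold.removed_log == []
        just_below = prune_divergent(
            pool, PipelineConfig(branch_length_threshold=branch * 0.999))
        assert [e["id"] for e in just_below.removed_log] == ["far"]

    def test_idempotent(self):
        rng = np.random.default_rng(34)
        seqs = related_family(rng, 9, divergence=0.1)
        rogue = rec("rogue", "".join(rng.choice(list(AA20), size=120)))
        first = prune_divergent(seqs + [rogue])
        second = prune_divergent(first.retained)
        assert second.removed_log == []

    def test_never_drops_below_four_sequences(self):
        rng = np.random.default_rng(35)
        root = _encode_aa("".join(rng.choice(list(AA20), size=100)))
        seqs = [rec(f"x{i}", _decode_aa(_mutate(root, 2.5, rng)))
                for i in range(5)]
        result = prune_divergent(seqs)
        assert len(result.retained) >= 4

    def test_requires_four_sequences(self):
        rng = np.random.default_rng(36)
        with pytest.raises(CurationError):
            prune_divergent(related_family(rng, 3))


class TestTrimColumns:
    def test_gapless_alignment_unchanged(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        assert trim_columns(msa).rows == msa.rows

    def test_six_of_ten_gaps_removed_five_kept(self):
        ids = [f"r{i}" for i in range(10)]
        col_6gap = ["A"] * 4 + ["-"] * 6   # non-gap fraction 0.4 < 0.5
        col_5gap = ["C"] * 5 + ["-"] * 5   # exactly 0.5: kept
        col_full = ["D"] * 10
        rows = ["".join(t) for t in zip(col_full, col_6gap, col_5gap)]
        trimmed = trim_columns(MultipleAlignment(ids, rows))
        assert trimmed.n_cols == 2
        assert trimmed.rows[0] == "D-"[0] + ("C" if True else "")  # r0: D + C
        assert trimmed.rows[0] == "DC"
        assert trimmed.rows[9] == "D-"

    def test_idempotent_and_never_wider(self):
        rng = np.random.default_rng(41)
        seqs = related_family(rng, 6, divergence=0.2)
        seqs.append(rec("trunc", seqs[0].sequence[60:]))
        msa = profile_align(seqs)
        once = trim_columns(msa)
        twice = trim_columns(once)
        assert once.n_cols <= msa.n_cols
        assert twice.rows == once.rows

    def test_all_columns_removed_is_an_error(self):
        msa = MultipleAlignment(["a", "b", "c"],
                                ["A--", "-C-", "--D"])
        with pytest.raises(CurationError):
            trim_columns(msa)


class TestBootstrap:
    def _two_clades(self):
        rng = np.random.default_rng(51)
        left_root = _encode_aa("".join(rng.choice(list(AA20), size=150)))
        right_root = _mutate(left_root, 1.0, rng)  # deep split
        seqs = [rec(f"L{i}", _decode_aa(_mutate(left_root, 0.05, rng)))
                for i in range(4)]
        seqs += [rec(f"R{i}", _decode_aa(_mutate(right_root, 0.05, rng)))
                 for i in range(4)]
        return profile_align(seqs)

    def test_deep_split_has_high_support(self):
        tree = bootstrap_support(self._two_clades(), n_reps=100, seed=1)
        split = frozenset(["L0", "L1", "L2", "L3"])
        assert tree.has_bipartition(split)
        canon = {s if "L0" in s else frozenset(tree.tip_labels()) - s: v
                 for s, v in tree.support.items()}
        assert canon[split] >= 0.95

    def test_support_values_bounded_and_reproducible(self):
        msa = self._two_clades()
        t1 = bootstrap_support(msa, n_reps=20, seed=9)
        t2 = bootstrap_support(msa, n_reps=20, seed=9)
        assert t1.support == t2.support
        assert all(0.0 <= v <= 1.0 for v in t1.support.values())

    def test_single_replicate_yields_binary_support(self):
        tree = bootstrap_support(self._two_clades(), n_reps=1, seed=2)
        assert set(tree.support.values()) <= {0.0, 1.0}


def annotated_tree(newick, annotations):
    tree = PhyloTree.from_newick(newick)
    tree.annotations = annotations
    return tree


def euk(group, strain=None):
    return {"domain": "eukaryote", "lineage_group": group,
            "strain": strain or group}


BACT = {"domain": "bacteria"}


class TestFlagContaminants:
    def test_near_identity_to_bacterial_tip_is_contaminant(self):
        # a liverwort sequence at 99.5% identity to a bacterial METH
        tree = annotated_tree(
            "((liv1:0.01,b1:0.01):0.5,(b2:0.3,b3:0.3):0.2,euk1:0.6);",
            {"liv1": euk("liverworts", "Blasia sp."), "b1": BACT, "b2": BACT,
             "b3": BACT, "euk1": euk("hornworts")})
        flags = flag_contaminants(tree, {frozenset(("liv1", "b1")): 0.995})
        assert flags["liv1"] == "contaminant"

    def test_single_library_nested_in_bacteria_is_contaminant(self):
        tree = annotated_tree(
            "(((hap1:0.2,b1:0.2):0.1,b2:0.3):0.2,b3:0.4,"
            "((euk1:0.2,euk2:0.2):0.1,euk3:0.3):0.8);",
            {"hap1": euk("haptophytes", "Pavlova lutheri"), "b1": BACT,
             "b2": BACT, "b3": BACT, "euk1": euk("chlorophytes", "c1"),
             "euk2": euk("chlorophytes", "c2"),
             "euk3": euk("streptophytes", "s1")})
        flags = flag_contaminants(tree, {})
        assert flags["hap1"] == "contaminant"
        assert flags["euk1"] == flags["euk2"] == flags["euk3"] == "clean"

    def test_two_strains_of_one_group_in_bacterial_clade_are_hgt(self):
        tree = annotated_tree(
            "(((redA:0.1,redB:0.1):0.1,b1:0.2):0.1,b2:0.3,"
            "(euk1:0.2,euk2:0.2):0.8);",
            {"redA": euk("red algae", "Porphyridium"), "b1": BACT,
             "redB": euk("red algae", "Cyanidioschyzon"), "b2": BACT,
             "euk1": euk("chlorophytes", "c1"),
             "euk2": euk("chlorophytes", "c2")})
        flags = flag_contaminants(tree, {})
        assert flags["redA"] == flags["redB"] == "hgt"

    def test_two_libraries_of_one_strain_are_not_independent_evidence(self):
        tree = annotated_tree(
            "(((redA:0.1,redB:0.1):0.1,b1:0.2):0.1,b2:0.3,"
            "(euk1:0.2,euk2:0.2):0.8);",
            {"redA": euk("red algae", "Porphyridium"), "b1": BACT,
             "redB": euk("red algae", "Porphyridium"), "b2": BACT,
             "euk1": euk("chlorophytes", "c1"),
             "euk2": euk("chlorophytes", "c2")})
        flags = flag_contaminants(tree, {})
        assert flags["redA"] == flags["redB"] == "contaminant"

    def test_tip_among_own_kingdom_is_clean(self):
        tree = annotated_tree(
            "((horn1:0.1,strep1:0.1):0.2,strep2:0.2,(b1:0.3,b2:0.3):0.5);",
            {"horn1": euk("hornworts"), "strep1": euk("streptophytes", "s1"),
             "strep2": euk("streptophytes", "s2"), "b1": BACT, "b2": BACT})
        assert flag_contaminants(tree, {})["horn1"] == "clean"

    def test_unannotated_tips_raise(self):
        tree = annotated_tree("(a:1,b:1,c:1);", {"a": BACT, "b": BACT})
        with pytest.raises(CurationError, match="c"):
            flag_contaminants(tree, {})


class TestIsoformClades:
    NEWICK = ("(((At1:0.1,At2:0.1):0.1,(At3:0.1,plant1:0.1):0.1):0.3,"
              "((c1:0.1,c2:0.1):0.2,plant2:0.3):0.3,out:0.6);")

    def test_anchored_clade_assignment(self):
        tree = PhyloTree.from_newick(self.NEWICK)
        labels = assign_isoform_clade(
            tree, {"Clade I": {"At1", "At2", "At3"}, "Clade II": {"c1", "c2"}})
        assert labels["plant1"] == "Clade I"
        assert labels["At1"] == "Clade I"
        assert labels["c1"] == "Clade II"
        # the outgroup sits outside both anchored clades
        assert labels["out"] == "unassigned"
        assert labels["plant2"] == "unassigned"

    def test_inseparable_anchor_sets_raise(self):
        tree = PhyloTree.from_newick(self.NEWICK)
        with pytest.raises(CurationError, match="separated"):
            assign_isoform_clade(
                tree, {"Clade I": {"At1", "c1"}, "Clade II": {"At2", "c2"}})

    def test_missing_anchor_tip_raises(self):
        tree = PhyloTree.from_newick(self.NEWICK)
        with pytest.raises(CurationError, match="absent"):
            assign_isoform_clade(tree, {"Clade I": {"At1", "nope"}})


class TestPairwiseIdentity:
    def test_counts_only_mutually_ungapped_columns(self):
        # columns where either row is gapped never enter the denominator
        msa = MultipleAlignment(["a", "b"], ["ACD-EF", "ACDC-F"])
        ident = pairwise_identity(msa)
        assert ident[frozenset(("a", "b"))] == pytest.approx(1.0)
        msa2 = MultipleAlignment(["a", "b"], ["ACDEF", "AQDEF"])
        assert pairwise_identity(msa2)[frozenset(("a", "b"))] == \
            pytest.approx(4 / 5)


class TestAlignmentProperties:
    from hypothesis import given, settings, strategies as st

    aa_text = st.text(alphabet=AA20, min_size=1, max_size=25)

    @given(st.lists(aa_text, min_size=2, max_size=5, unique=True))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_alignment_conserves_sequences_and_distances_stay_bounded(
            self, sequences):
        seqs = [rec(f"h{i}", s) for i, s in enumerate(sequences)]
        msa = profile_align(seqs)
        for s in seqs:
            assert msa.ungapped(s.id) == s.sequence
        d = poisson_distance(msa).matrix
        assert d.max() <= D_CAP + 1e-9
        assert (np.diag(d) == 0).all()
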