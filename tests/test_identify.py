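import numpy as np
import pytest

from elasmobarcode.distances import DistanceMatrix
from elasmobarcode.identify import (
    ConfigurationError,
    CurationOverride,
    Hit,
    IdentifyConfig,
    MatchFlag,
    Status,
    TreeAssignment,
    UsageError,
    apply_overrides,
    assign_match_flag,
    consensus_identify,
    flag_from_tabulated,
    rank_hits,
    tree_assign,
)
from elasmobarcode.io import BarcodeSequence, ReferenceRecord
from elasmobarcode.taxonomy import ELASMOBRANCHII, Lineage, SELACHII
from elasmobarcode.tree import read_newick


def make_ref(accession, label, seq):
    lin = Lineage(
        species=label if " " in label else label + " sp",
        genus=label.split()[0], family="Famidae", order="Ordiformes",
        infraclass=SELACHII, class_=ELASMOBRANCHII)
    return ReferenceRecord(accession=accession, label=label, lineage=lin,
                           seq=BarcodeSequence(id=accession, seq=seq))


def hit(label, pct, acc="R1"):
    return Hit(reference=make_ref(acc, label, "ACGT"), identity_pct=pct)


class TestRankHits:
    def test_identical_reference_is_a_perfect_top_hit(self):
        rng = np.random.default_rng(0)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 654))
        refs = [make_ref("R1", "Aus bus", s),
                make_ref("R2", "Cus dus", s[:-1] + ("A" if s[-1] != "A"
                                                    else "C"))]
        hits = rank_hits(BarcodeSequence(id="q", seq=s), refs)
        assert hits[0].reference.accession == "R1"
        assert hits[0].identity_pct == pytest.approx(100.0)

    def test_three_mismatches_over_barcode_length(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 4, 654)
        s = "".join("ACGT"[i] for i in codes)
        mutated = codes.copy()
        mutated[:3] = (mutated[:3] + 1) % 4
        q = "".join("ACGT"[i] for i in mutated)
        hits = rank_hits(BarcodeSequence(id="q", seq=q),
                         [make_ref("R1", "Aus bus", s)])
        assert hits[0].identity_pct == pytest.approx(651 / 654 * 100,
                                                     abs=1e-6)

    def test_reverse_complement_matches_with_orientation_check(self):
        rng = np.random.default_rng(2)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(s))
        cfg = IdentifyConfig(check_orientation=True)
        hits = rank_hits(BarcodeSequence(id="q", seq=rc),
                         [make_ref("R1", "Aus bus", s)], cfg=cfg)
        assert hits[0].identity_pct == pytest.approx(100.0)

    def test_unequal_lengths_use_end_gap_free_alignment(self):
        rng = np.random.default_rng(3)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        # query is a clean interior window of the reference
        hits = rank_hits(BarcodeSequence(id="q", seq=s[30:370]),
                         [make_ref("R1", "Aus bus", s)])
        assert hits[0].identity_pct == pytest.approx(100.0)

    def test_empty_library_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            rank_hits(BarcodeSequence(id="q", seq="ACGT"), [])


class TestMatchFlag:
    def test_low_similarity(self):
        # deep-water ray with no close reference: best hit far below 99
        flag = assign_match_flag(
            "Urogymnus lobistoma", [hit("Himantura chaophraya", 88.01)])
        assert flag is MatchFlag.LS

    def test_different_species(self):
        flag = assign_match_flag(
            "Squalus altipinnis", [hit("Squalus edmundsi", 99.54)])
        assert flag is MatchFlag.DS

    def test_uncertain_species(self):
        flag = assign_match_flag(
            "Narcine maculata", [hit("Narcine sp.", 99.35)])
        assert flag is MatchFlag.MU

    def test_multiple_species_within_window(self):
        flag = assign_match_flag(
            "Carcharhinus limbatus",
            [hit("Carcharhinus limbatus", 99.54, "R1"),
             hit("Carcharhinus amblyrhynchoides", 99.50, "R2")])
        assert flag is MatchFlag.MM

    def test_second_species_outside_window_is_ignored(self):
        flag = assign_match_flag(
            "Carcharhinus limbatus",
            [hit("Carcharhinus limbatus", 99.85, "R1"),
             hit("Carcharhinus amblyrhynchoides", 99.00, "R2")])
        assert flag is MatchFlag.OK

    def test_boundary_identity_counts_as_strong(self):
        # matches at exactly 99.0x carry no low-similarity annotation
        flag = assign_match_flag(
            "Himantura leoparda", [hit("Himantura leoparda", 99.08)])
        assert flag is MatchFlag.OK

    def test_strong_match_to_field_species(self):
        flag = assign_match_flag(
            "Heterodontus zebra", [hit("Heterodontus zebra", 99.54)])
        assert flag is MatchFlag.OK


class TestTabulatedFlags:
    def test_printed_mm_and_mu_sets_reproduced(self, sample_table):
        flags = {r.sample: flag_from_tabulated(r) for r in sample_table}
        mm = {s for s, f in flags.items() if f is MatchFlag.MM}
        mu = {s for s, f in flags.items() if f is MatchFlag.MU}
        printed_mm = {r.sample for r in sample_table if r.marker == "MM"}
        printed_mu = {r.sample for r in sample_table if r.marker == "MU"}
        assert mm == printed_mm and len(mm) == 17
        assert mu == printed_mu == {"2-874"}

    def test_low_similarity_cohort_matches_reported_range(
            self, sample_table):
        ls = [r for r in sample_table
              if flag_from_tabulated(r) is MatchFlag.LS]
        assert len(ls) == 15
        pcts = sorted(r.ncbi_pct for r in ls)
        assert pcts[0] == pytest.approx(88.01)
        assert pcts[-1] == pytest.approx(98.93)

    def test_revised_reference_marker_is_not_a_conflict(self, sample_table):
        t7 = next(r for r in sample_table if r.sample == "T7")
        assert flag_from_tabulated(t7) is MatchFlag.OK


class TestTreeAssign:
    @staticmethod
    def _setup(d_query_ref):
        tree = read_newick(
            "((q:{0},R1:{0}):0.02,(R2:0.002,R3:0.002):0.02);".format(
                d_query_ref / 2))
        refs = [make_ref("R1", "Aus bus", "ACGT"),
                make_ref("R2", "Aus cus", "ACGT"),
                make_ref("R3", "Aus cus", "ACGT")]
        ids = ["q", "R1", "R2", "R3"]
        v = np.zeros((4, 4))
        tips = {t.name: t for t in tree.tips()}
        for i in range(4):
            for j in range(i + 1, 4):
                v[i, j] = v[j, i] = tips[ids[i]].distance(tips[ids[j]])
        return tree, refs, DistanceMatrix(ids=ids, values=v)

    def test_conspecific_distance_assigns_species(self):
        tree, refs, dm = self._setup(0.002)
        ta = tree_assign("q", tree, refs, dm)
        assert ta.species == "Aus bus"
        assert not ta.cryptic_split

    def test_deep_intraspecific_distance_flags_cryptic_split(self):
        tree, refs, dm = self._setup(0.037)
        ta = tree_assign("q", tree, refs, dm)
        assert ta.species == "Aus bus"
        assert ta.cryptic_split

    def test_beyond_cryptic_threshold_withholds_assignment(self):
        tree, refs, dm = self._setup(0.052)
        ta = tree_assign("q", tree, refs, dm)
        assert ta.species is None

    def test_mixed_species_clade_withholds_assignment(self):
        tree = read_newick(
            "((q:0.002,R1:0.002,R2:0.002):0.02,R3:0.02);")
        refs = [make_ref("R1", "Aus bus", "ACGT"),
                make_ref("R2", "Aus cus", "ACGT"),
                make_ref("R3", "Aus dus", "ACGT")]
        ids = ["q", "R1", "R2", "R3"]
        tips = {t.name: t for t in tree.tips()}
        v = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                v[i, j] = v[j, i] = tips[ids[i]].distance(tips[ids[j]])
        ta = tree_assign("q", tree, refs, DistanceMatrix(ids=ids, values=v))
        assert ta.species is None

    def test_missing_query_is_a_usage_error(self):
        tree, refs, dm = self._setup(0.002)
        with pytest.raises(UsageError):
            tree_assign("nope", tree, refs, dm)


class TestConsensus:
    LIB = {"Squalus edmundsi", "Carcharhinus amboinensis",
           "Carcharhinus leucas", "Hemitrygon parvonigra"}

    def test_verified_when_both_approaches_agree(self):
        res = consensus_identify(
            "Carcharhinus leucas", MatchFlag.OK,
            [hit("Carcharhinus leucas", 100.0)],
            TreeAssignment("Carcharhinus leucas", 0.002),
            library_species=self.LIB)
        assert res.status is Status.VERIFIED
        assert res.final_name == "Carcharhinus leucas"
        assert not res.inconclusive

    def test_field_misidentification_reassigned(self):
        res = consensus_identify(
            "Carcharhinus leucas", MatchFlag.DS,
            [hit("Carcharhinus amboinensis", 99.69)],
            TreeAssignment("Carcharhinus amboinensis", 0.003),
            library_species=self.LIB)
        assert res.status is Status.REASSIGNED
        assert res.final_name == "Carcharhinus amboinensis"

    def test_low_similarity_without_reference_keeps_field_name(self):
        res = consensus_identify(
            "Urogymnus lobistoma", MatchFlag.LS,
            [hit("Himantura chaophraya", 88.01)],
            TreeAssignment(None, 0.13),
            library_species=self.LIB)
        assert res.status is Status.RETAINED
        assert res.final_name == "Urogymnus lobistoma"
        assert res.inconclusive

    def test_low_similarity_with_reference_becomes_cf_form(self):
        res = consensus_identify(
            "Hemitrygon parvonigra", MatchFlag.LS,
            [hit("Hemitrygon parvonigra", 94.78)],
            TreeAssignment(None, 0.052),
            library_species=self.LIB)
        assert res.status is Status.INCONCLUSIVE
        assert res.final_name == "Hemitrygon cf. parvonigra"

    def test_multiple_match_resolved_by_tree_is_cautiously_verified(self):
        res = consensus_identify(
            "Carcharhinus limbatus", MatchFlag.MM,
            [hit("Carcharhinus limbatus", 99.54)],
            TreeAssignment("Carcharhinus limbatus", 0.004),
            library_species=self.LIB)
        assert res.status is Status.VERIFIED
        assert res.notes

    def test_multiple_match_unresolved_is_retained(self):
        res = consensus_identify(
            "Maculabatis gerrardi", MatchFlag.MM,
            [hit("Maculabatis macrura", 99.85)],
            TreeAssignment(None, 0.01),
            library_species=self.LIB)
        assert res.status is Status.RETAINED
        assert res.inconclusive

    def test_uncertain_match_becomes_cf_form(self):
        res = consensus_identify(
            "Narcine maculata", MatchFlag.MU,
            [hit("Narcine sp.", 99.35)],
            TreeAssignment(None, 0.02),
            library_species=self.LIB)
        assert res.status is Status.INCONCLUSIVE
        assert res.final_name.startswith("Narcine cf.")

    def test_morphology_override_retains_field_identity(self):
        ovr = [CurationOverride(
            target="Cephaloscyllium sarawakense",
            corrected_species="", kind="retain",
            reason="morphology conflicts with the deposited sequence")]
        res = consensus_identify(
            "Cephaloscyllium sarawakense", MatchFlag.DS,
            [hit("Cephaloscyllium umbratile", 99.85)],
            TreeAssignment("Cephaloscyllium umbratile", 0.008),
            overrides=ovr, library_species=self.LIB)
        assert res.status is Status.RETAINED
        assert res.final_name == "Cephaloscyllium sarawakense"


class TestOverrides:
    def test_rename_relabels_reference(self):
        refs = [make_ref("EU398924", "Myliobatis tobijei", "ACGT")]
        out = apply_overrides(refs, [CurationOverride(
            target="EU398924", corrected_species="Myliobatis hamlyni")])
        assert out[0].label == "Myliobatis hamlyni"

    def test_rename_by_label(self):
        refs = [make_ref("X1", "Neotrygon kuhlii", "ACGT")]
        out = apply_overrides(refs, [CurationOverride(
            target="Neotrygon kuhlii",
            corrected_species="Neotrygon varidens")])
        assert out[0].label == "Neotrygon varidens"
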