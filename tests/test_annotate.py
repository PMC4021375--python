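import pytest

from indelrules.annotate import (
    ANNOTATION_SCHEMA,
    annotate_variant,
    disorder_category,
    length_category,
    local_sequences,
    overlap_flags,
    perturbation,
    perturbation_value,
    pro_gly_flags,
    rip_category,
    rsa_category,
    ss_category,
)
from indelrules.datamodel import AnnotationError, IndelVariant
from indelrules.properties import MODES, PROPERTIES

from conftest import make_context


class TestLocalSequences:
    def test_deletion_site_environment_region(self, toy_context):
        v = IndelVariant("P1", 5, "deletion", "N")
        local = local_sequences(v, toy_context)
        assert local.site == "Q"
        assert local.site_span == (6, 6)
        assert local.environment == "AQ"
        assert local.region == "VAQW"

    def test_insertion_site_is_reference_at_position(self):
        ctx = make_context("MKVAN")
        v = IndelVariant("P1", 3, "insertion", "GG")
        assert local_sequences(v, ctx).site == "VA"

    def test_deletion_of_last_residue_falls_back_upstream(self):
        ctx = make_context("MKVANQW")
        v = IndelVariant("P1", 7, "deletion", "W")
        local = local_sequences(v, ctx)
        assert local.site == "Q"
        assert local.site_span == (6, 6)

    def test_flanks_truncated_at_protein_ends(self):
        ctx = make_context("MKVANQW")
        v = IndelVariant("P1", 1, "deletion", "M")
        local = local_sequences(v, ctx)
        assert local.site == "K"
        assert local.environment == "K"  # no left flank at the N-terminus
        assert local.region == "KV"

    def test_deletion_covering_whole_protein_is_an_error(self):
        ctx = make_context("MKVAN")
        v = IndelVariant("P1", 1, "deletion", "MKVAN")
        with pytest.raises(AnnotationError):
            local_sequences(v, ctx)


class TestPerturbation:
    def test_identical_site_gives_equal_everywhere(self):
        # deleting "AA" at 1 of "AAAA..." leaves a site of two alanines
        ctx = make_context("A" * 12)
        v = IndelVariant("P1", 1, "deletion", "AA")
        for prop in PROPERTIES:
            for mode in MODES:
                assert perturbation(v, ctx, "site", prop, mode) == "equal"

    def test_large_volume_difference_clamps_to_two_more(self):
        # deletion G (volume 1) with site W (volume 5): d = +4 -> two_more
        ctx = make_context("MKGWANQ")
        v = IndelVariant("P1", 3, "deletion", "G")
        assert perturbation_value(v, ctx, "site", "volume", "total") == 4
        assert perturbation(v, ctx, "site", "volume", "total") == "two_more"

    def test_symmetric_case_is_two_less(self):
        ctx = make_context("MKWGANQ")
        v = IndelVariant("P1", 3, "deletion", "W")
        assert perturbation(v, ctx, "site", "volume", "total") == "two_less"

    @pytest.mark.parametrize("a,b", [("G", "W"), ("AN", "KD"), ("PGS", "WYF")])
    def test_antisymmetry_of_numeric_perturbation(self, a, b):
        # swapping the indel residues with the site residues negates d
        pad = "Q" * 8
        ctx_ab = make_context(a + b + pad)
        ctx_ba = make_context(b + a + pad)
        v_ab = IndelVariant("P1", 1, "deletion", a)
        v_ba = IndelVariant("P1", 1, "deletion", b)
        for prop in PROPERTIES:
            for mode in MODES:
                d1 = perturbation_value(v_ab, ctx_ab, "site", prop, mode)
                d2 = perturbation_value(v_ba, ctx_ba, "site", prop, mode)
                assert d1 == pytest.approx(-d2)


class TestStructuralCategories:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.1, "structured"),
            (0.39, "structured"),
            (0.4, "semi_disorder"),
            (0.55, "semi_disorder"),
            (0.7, "semi_disorder"),
            (0.71, "disorder"),
            (0.9, "disorder"),
        ],
    )
    def test_disorder_bins(self, p, expected):
        ctx = make_context("MKVANQW", disorder=p)
        v = IndelVariant("P1", 5, "deletion", "N")
        assert disorder_category(v, ctx) == expected

    @pytest.mark.parametrize(
        "rv,expected",
        [
            (10, "fully_buried"),
            (30, "buried"),
            (59.9, "buried"),
            (60, "intermediate"),
            (90, "exposed"),
            (120, "fully_exposed"),
            (150, "fully_exposed"),
        ],
    )
    def test_rsa_bins_left_closed(self, rv, expected):
        ctx = make_context("MKVANQW", rsa=float(rv))
        v = IndelVariant("P1", 5, "deletion", "N")
        assert rsa_category(v, ctx) == expected

    def test_ss_homogeneous_windows(self):
        for state in ("helix", "strand", "coil"):
            ctx = make_context("MKVANQW", ss=state)
            v = IndelVariant("P1", 3, "deletion", "V")
            assert ss_category(v, ctx) == state

    def test_ss_transition_zone_is_two(self):
        # window (positions 3-5) mixes strand and coil
        ss = ["coil", "coil", "coil", "strand", "coil", "coil", "coil"]
        ctx = make_context("MKVANQW", ss=ss)
        v = IndelVariant("P1", 3, "deletion", "V")  # site span (4,4), window 3-5
        assert ss_category(v, ctx) == "two"

    def test_ss_mixed_window_majority_and_tie_to_strand(self):
        # window 3-5: helix, strand, coil -> tie between helix and strand
        ss = ["coil", "coil", "helix", "strand", "coil", "coil", "coil"]
        ctx = make_context("MKVANQW", ss=ss)
        v = IndelVariant("P1", 3, "deletion", "V")
        assert ss_category(v, ctx) == "strand"
        ss = ["coil", "coil", "helix", "helix", "strand", "coil", "coil"]
        ctx = make_context("MKVANQW", ss=ss)
        assert ss_category(v, ctx) == "helix"


class TestPositionLengthComposition:
    @pytest.mark.parametrize(
        "position,expected",
        [(5, "n_terminal"), (10, "n_terminal"), (11, "middle"),
         (50, "middle"), (89, "middle"), (90, "c_terminal"), (95, "c_terminal")],
    )
    def test_rip_bins_on_length_100(self, position, expected):
        seq = "A" * 100
        ctx = make_context(seq)
        v = IndelVariant("P1", position, "deletion", "A")
        assert rip_category(v, ctx) == expected

    def test_rip_uses_span_midpoint_for_multiresidue_deletions(self):
        ctx = make_context("A" * 100)
        # span [9, 12] -> midpoint 10.5 -> middle
        v = IndelVariant("P1", 9, "deletion", "AAAA")
        assert rip_category(v, ctx) == "middle"

    def test_length_and_pro_gly(self):
        assert length_category(IndelVariant("P1", 1, "insertion", "N")) == "one"
        assert (
            length_category(IndelVariant("P1", 1, "insertion", "GPA"))
            == "more_than_one"
        )
        assert pro_gly_flags(IndelVariant("P1", 1, "insertion", "N")) == (False, False)
        assert pro_gly_flags(IndelVariant("P1", 1, "insertion", "GPA")) == (True, True)
        assert pro_gly_flags(IndelVariant("P1", 1, "insertion", "GG")) == (False, True)


class TestOverlapFlags:
    def test_site_span_interval_intersection(self):
        seq = "A" * 25
        # deletion of length 2 at position 8 -> site span (10, 11)
        v = IndelVariant("P1", 8, "deletion", "AA")
        ctx = make_context(seq, pfam=[(5, 20)], block=[(12, 20)])
        flags = overlap_flags(v, ctx)
        assert flags["pfam"] is True
        assert flags["block"] is False
        assert flags["prosite"] is False

    def test_conserved_site_residue_sets_flag(self):
        seq = "A" * 25
        conserved = [False] * 25
        conserved[9] = True  # residue 10, inside site span (10, 11)
        v = IndelVariant("P1", 8, "deletion", "AA")
        ctx = make_context(seq, conserved=conserved)
        assert overlap_flags(v, ctx)["conserved_residue"] is True


class TestAnnotateVariant:
    def test_forced_categories_and_determinism(self):
        seq = "A" * 40
        ss = ["coil"] * 40
        for i in range(14, 26):
            ss[i] = "strand"
        conserved = [False] * 40
        for i in range(14, 26):
            conserved[i] = True
        ctx = make_context(
            seq,
            disorder=0.1,
            rsa=20.0,
            ss=ss,
            conserved=conserved,
            pfam=[(10, 30)],
            block=[(10, 30)],
        )
        v = IndelVariant("P1", 18, "deletion", "AA", "deleterious")
        features = annotate_variant(v, ctx)
        assert features["probability_of_disorder"] == "structured"
        assert features["rsa"] == "fully_buried"
        assert features["secondary_structure"] == "strand"
        assert features["block"] == "true"
        assert features["pfam"] == "true"
        assert features["conserved_residue"] == "true"
        assert features["relative_indel_position"] == "middle"
        assert features == annotate_variant(v, ctx)  # purity
        ANNOTATION_SCHEMA.validate_features(features)

    def test_every_parameter_populated(self, toy_context):
        v = IndelVariant("P1", 5, "deletion", "N")
        features = annotate_variant(v, toy_context)
        assert set(features) == set(ANNOTATION_SCHEMA.names)
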