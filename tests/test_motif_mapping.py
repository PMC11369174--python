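"""Motif-position classification of mutations and the Grantham distance."""

import itertools

import pytest

from mutprop.motif_mapping import (
    CATEGORY_FLANKING,
    CATEGORY_KEY,
    CATEGORY_MOTIF_CREATED,
    CATEGORY_NO_MOTIF,
    CATEGORY_WILDCARD,
    MotifModel,
    classify_mutation,
    extract_window,
    grantham,
    grantham_class,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestExtractWindow:
    def test_interior_window_arithmetic(self):
        seq = "A" * 781
        wt, mut, offset = extract_window(seq, 33, "F")
        assert offset == 13 and len(wt) == 41  # residues 13..53
        assert mut[33 - offset] == "F"

    def test_left_truncation(self):
        wt, mut, offset = extract_window("A" * 100, 5, "G")
        assert offset == 1 and len(wt) == 25  # residues 1..25

    def test_right_truncation_at_terminus(self):
        wt, mut, offset = extract_window("A" * 50, 50, "G")
        assert offset == 30 and len(wt) == 21

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            extract_window("AAAA", 5, "G")


class TestClassification:
    def test_beta_catenin_phospho_degron_site_creates_g3bp_motif(self):
        # S33F introduces the fixed F of [FILV]xFG only in the mutant window
        motif = MotifModel("G3BP1_NTF2", "[FILV]xFG")
        wt, mut = "QQSYLDSGIHSGATTT", "QQSYLDFGIHSGATTT"
        ann = classify_mutation(wt, mut, 6, motif)
        assert ann.category == CATEGORY_MOTIF_CREATED

    def test_ppxy_tyrosine_is_key(self):
        motif = MotifModel("WW", "PPxY")
        ann = classify_mutation("AAAPPSYAAAA", "AAAPPSCAAAA", 6, motif)
        assert ann.category == CATEGORY_KEY
        assert ann.distance_to_motif == 0

    def test_wildcard_position_of_dxxlv(self):
        motif = MotifModel("GGA1_VHS", "DxxLV")
        ann = classify_mutation("QQELDDLLVDLDHQR", "QQELDHLLVDLDHQR", 5, motif)
        assert ann.category == CATEGORY_WILDCARD

    def test_one_past_motif_is_flanking_distance_one(self):
        motif = MotifModel("WW", "PPxY")
        ann = classify_mutation("AAAPPSYDAAA", "AAAPPSYAAAA", 7, motif)
        assert ann.category == CATEGORY_FLANKING
        assert ann.distance_to_motif == 1

    def test_no_match_in_window_is_no_motif(self):
        motif = MotifModel("WW", "PPxY")
        ann = classify_mutation("AAAAGSYAAAA", "AAAAGSWAAAA", 6, motif)
        assert ann.category == CATEGORY_NO_MOTIF
        assert ann.motif_span is None

    def test_destruction_and_creation_are_symmetric(self):
        motif = MotifModel("WW", "PPxY")
        wt, mut = "AAAPPSYAAAA", "AAAPPSEAAAA"  # Y -> E destroys the only match
        assert classify_mutation(wt, mut, 6, motif).category == CATEGORY_KEY
        assert classify_mutation(mut, wt, 6, motif).category == CATEGORY_MOTIF_CREATED

    def test_known_spans_take_precedence_over_scanning(self):
        motif = MotifModel("WW", "PPxY")
        # curated instance far from the site forces a flanking call
        ann = classify_mutation("AAAPPSYAAGA", "AAAPPSYAAEA", 9, motif,
                                known_spans=[(3, 6)])
        assert ann.category == CATEGORY_FLANKING
        assert ann.distance_to_motif == 3

    def test_motif_span_reported_in_protein_coordinates(self):
        motif = MotifModel("WW", "PPxY")
        ann = classify_mutation("AAAPPSYAAAA", "AAAPPSCAAAA", 6, motif, window_offset=101)
        assert ann.motif_span == (104, 107)


def _grantham_formula_oracle():
    """Independent recomputation from the composition/polarity/volume data."""
    props = {
        "S": (1.42, 9.2, 32), "R": (0.65, 10.5, 124), "L": (0, 4.9, 111),
        "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61), "A": (0, 8.1, 31),
        "V": (0, 5.9, 84), "G": (0.74, 9.0, 3), "I": (0, 5.2, 111),
        "F": (0, 5.2, 132), "Y": (0.20, 6.2, 136), "C": (2.75, 5.5, 55),
        "H": (0.58, 10.4, 96), "Q": (0.89, 10.5, 85), "N": (1.33, 11.6, 56),
        "K": (0.33, 11.3, 119), "D": (1.38, 13.0, 54), "E": (0.92, 12.3, 83),
        "M": (0, 5.7, 105), "W": (0.13, 5.4, 170),
    }

    def raw(a, b):
        (c1, p1, v1), (c2, p2, v2) = props[a], props[b]
        return (1.833 * (c1 - c2) ** 2 + 0.1018 * (p1 - p2) ** 2
                + 0.000399 * (v1 - v2) ** 2) ** 0.5

    pairs = list(itertools.combinations(props, 2))
    rho = 100.0 * len(pairs) / sum(raw(a, b) for a, b in pairs)
    return {frozenset(p): round(rho * raw(*p)) for p in pairs}


class TestGrantham:
    def test_known_distances(self):
        assert grantham("R", "C") == 180
        assert grantham("L", "I") == 5
        assert grantham("A", "A") == 0

    def test_symmetric_and_zero_iff_identical(self):
        for a in AA:
            for b in AA:
                assert grantham(a, b) == grantham(b, a)
                assert (grantham(a, b) == 0) == (a == b)

    def test_matches_formula_oracle_for_all_190_pairs(self):
        oracle = _grantham_formula_oracle()
        assert len(oracle) == 190
        for pair, expected in oracle.items():
            a, b = tuple(pair)
            assert grantham(a, b) == expected

    def test_noncanonical_pair_is_error(self):
        with pytest.raises(ValueError):
            grantham("A", "X")

    @pytest.mark.parametrize("score,expected", [
        (0, "conservative"), (50, "conservative"),
        (51, "moderately_conservative"), (100, "moderately_conservative"),
        (101, "moderately_radical"), (150, "moderately_radical"),
        (151, "radical"), (215, "radical"),
    ])
    def test_class_boundaries(self, score, expected):
        assert grantham_class(score) == expected

    def test_classification_attaches_grantham(self):
        motif = MotifModel("WW", "PPxY")
        ann = classify_mutation("AAAPPSYAAAA", "AAAPPSCAAAA", 6, motif)
        assert ann.grantham == grantham("Y", "C")
        assert ann.grantham_class == grantham_class(ann.grantham)
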