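"""Variant application, re-splicing, translation, NMD, protein diffs."""

import numpy as np
import pytest

from caverelax.synthetic_data import (
    FixtureSpec,
    make_ptc_fixture,
    make_splice_fixture,
    mitfa_like_fixture,
    tyrp1a_like_fixture,
)
from caverelax.variant_consequences import (
    GeneModel,
    Variant,
    apply_variants,
    call_nmd,
    predict_consequences,
    protein_diff,
    resplice,
    translate_cds,
)


# -- apply_variants --------------------------------------------------------


def _toy_gene():
    #           exon1          intron         exon2
    genome = "ACGT" + "ATGGCTAAA" + "GTACAG" + "GCCTAA" + "TTTT"
    model = GeneModel(
        gene_id="toy", strand="+", exons=((4, 13), (19, 25)), cds_start=0
    )
    return genome, model


def test_empty_variant_list_is_identity():
    genome, model = _toy_gene()
    mg, mm = apply_variants(genome, model, [])
    assert mg == genome
    assert mm == model


def test_insertion_at_intron_start_shifts_downstream_exon():
    genome, model = _toy_gene()
    v = Variant(position=13, ref="GTA", alt="GTATAT")  # +3 inside the intron
    mg, mm = apply_variants(genome, model, [v])
    assert mm.exons[0] == (4, 13)
    assert mm.exons[1] == (22, 28)
    assert mg[22:28] == "GCCTAA"


def test_non_overlapping_variants_commute():
    genome, model = _toy_gene()
    v1 = Variant(position=5, ref="TG", alt="TT")
    v2 = Variant(position=20, ref="CC", alt="GGGG")
    a = apply_variants(genome, model, [v1, v2])
    b = apply_variants(genome, model, [v2, v1])
    assert a == b


def test_reference_mismatch_rejected():
    genome, model = _toy_gene()
    with pytest.raises(ValueError, match="reference mismatch"):
        apply_variants(genome, model, [Variant(position=0, ref="GG", alt="AA")])


def test_overlapping_variants_rejected():
    genome, model = _toy_gene()
    with pytest.raises(ValueError, match="overlapping"):
        apply_variants(
            genome,
            model,
            [Variant(4, "ATG", "A"), Variant(6, "GG", "TT")],
        )


# -- resplice --------------------------------------------------------------


def test_unmutated_gene_reproduces_reference_transcript():
    genome, model = _toy_gene()
    out = resplice(genome, model)
    assert out.transcript == "ATGGCTAAA" + "GCCTAA"
    assert out.nt_delta == 0
    assert not out.rescue_applied
    assert all(canonical for _, _, canonical in out.donor_sites_used)


def test_transcript_length_equals_sum_of_segments():
    genome, model, variants = mitfa_like_fixture()
    mg, mm = apply_variants(genome, model, variants)
    out = resplice(mg, mm)
    assert len(out.transcript) == sum(out.segment_lengths)


def test_broken_donor_rescued_by_upstream_gt():
    genome, model, variants = mitfa_like_fixture()
    mg, mm = apply_variants(genome, model, variants)
    out = resplice(mg, mm)
    assert out.rescue_applied
    assert out.nt_delta == -63


def test_nearest_of_two_candidate_donors_wins():
    # two in-exon GTs at -30 and -63 from the broken donor: -30 is chosen
    exon = ["C", "A"] * 50
    exon = exon[:100]
    for off in (30, 63):
        exon[100 - off] = "G"
        exon[100 - off + 1] = "T"
    genome = "".join(exon) + "CCACAG" + "AAATTT"
    model = GeneModel(gene_id="two_gt", strand="+",
                      exons=((0, 100), (106, 112)), cds_start=0)
    out = resplice(genome, model)
    assert out.rescue_applied
    assert out.nt_delta == -30


def test_gt_preferred_over_closer_gc():
    exon = ["C", "A"] * 50
    exon = exon[:100]
    exon[90], exon[91] = "G", "C"  # GC at -10
    exon[37], exon[38] = "G", "T"  # GT at -63
    genome = "".join(exon) + "CCACAG" + "AAATTT"
    model = GeneModel(gene_id="gt_vs_gc", strand="+",
                      exons=((0, 100), (106, 112)), cds_start=0)
    out = resplice(genome, model)
    assert out.nt_delta == -63
    pos, dinuc, canonical = out.donor_sites_used[0]
    assert dinuc == "GT" and not canonical


def test_no_candidate_donor_retains_intron_and_flags():
    exon = "CA" * 50
    genome = exon + "CCACAG" + "AAATTT"
    model = GeneModel(gene_id="none", strand="+",
                      exons=((0, 100), (106, 112)), cds_start=0)
    out = resplice(genome, model)
    assert out.unresolved_introns == (0,)
    assert not out.resolved
    assert out.nt_delta == 6  # the retained intron stays in the transcript
    assert "CCACAG" in out.transcript


# -- translate -------------------------------------------------------------


def test_translation_stops_at_first_stop():
    assert translate_cds("ATGGCTTAA", 0) == ("MA", 2)


def test_translation_without_stop_is_flagged_none():
    protein, stop = translate_cds("ATGGCTGCT", 0)
    assert protein == "MAA"
    assert stop is None


def test_frameshifted_translation_detected_against_direct_translation():
    genome, model, _ = make_splice_fixture(FixtureSpec(alt_donor_offset=64))
    ref = resplice(genome, model)
    assert translate_cds(ref.transcript, 0)[1] is not None


# -- NMD -------------------------------------------------------------------


def test_ptc_in_last_exon_is_not_an_nmd_substrate():
    nmd, _ = call_nmd(ptc_codon_index=40, cds_start=0,
                      segment_lengths=(60, 120))
    assert not nmd


@pytest.mark.parametrize("distance,expected", [(0, False), (50, False),
                                               (51, True), (100, True)])
def test_fifty_nt_rule_boundary_is_sharp(distance, expected):
    # build a two-exon transcript where the PTC ends exactly `distance`
    # nt upstream of the final junction
    first_len = 3 * 40 + distance  # PTC occupies codons 39; junction after
    nmd, d = call_nmd(ptc_codon_index=39, cds_start=0,
                      segment_lengths=(first_len, 90))
    assert d == distance
    assert nmd is expected


def test_single_exon_transcript_never_nmd():
    nmd, _ = call_nmd(ptc_codon_index=3, cds_start=0, segment_lengths=(300,))
    assert not nmd


# -- protein diff ----------------------------------------------------------


def test_identical_proteins_classified_none():
    assert protein_diff("MAVK", "MAVK").kind == "none"


@pytest.mark.parametrize("k", [1, 5, 21, 50])
def test_single_block_deletions_detected_with_correct_length(k, rng):
    ref = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    start = int(rng.integers(1, len(ref) - k - 1))
    alt = ref[:start] + ref[start + k :]
    out = protein_diff(ref, alt, nt_delta=-3 * k)
    assert out.kind == "in_frame_deletion"
    assert out.aa_deleted == k


def test_truncated_protein_classified_premature_stop():
    out = protein_diff("MAVKLY", "MAV", nt_delta=0)
    assert out.kind == "premature_stop"
    assert out.ptc_codon_index == 3


def test_frame_breaking_delta_classified_frameshift():
    out = protein_diff("MAVKLY", "MAVTPW", nt_delta=-1)
    assert out.kind == "frameshift"


# -- end to end ------------------------------------------------------------


def test_mitfa_archetype_yields_63nt_loss_and_21aa_deletion():
    genome, model, variants = mitfa_like_fixture()
    splice, cons = predict_consequences(genome, model, variants)
    assert splice.rescue_applied
    assert splice.nt_delta == -63
    assert cons.kind == "in_frame_deletion"
    assert cons.aa_deleted == 21


def test_three_nt_offset_removes_single_residue():
    genome, model, variants = make_splice_fixture(FixtureSpec(alt_donor_offset=3))
    splice, cons = predict_consequences(genome, model, variants)
    assert splice.nt_delta == -3
    assert cons.kind == "in_frame_deletion"
    assert cons.aa_deleted == 1


def test_non_multiple_of_three_offset_causes_frameshift():
    genome, model, variants = make_splice_fixture(FixtureSpec(alt_donor_offset=64))
    splice, cons = predict_consequences(genome, model, variants)
    assert splice.nt_delta == -64
    assert cons.kind == "frameshift"


def test_offsets_one_and_two_are_impossible():
    with pytest.raises(ValueError, match="impossible"):
        make_splice_fixture(FixtureSpec(alt_donor_offset=2))


def test_tyrp1a_archetype_triggers_nmd():
    genome, model, variants = tyrp1a_like_fixture()
    _, cons = predict_consequences(genome, model, variants)
    assert cons.kind == "premature_stop"
    assert cons.nmd_predicted
    assert cons.distance_to_last_junction > 50


def test_ptc_moved_to_last_exon_flips_nmd_call():
    genome, model, variants = tyrp1a_like_fixture(ptc_exon_index=7)
    _, cons = predict_consequences(genome, model, variants)
    assert cons.kind == "premature_stop"
    assert not cons.nmd_predicted


def test_no_variants_is_consequence_none():
    genome, model, _ = tyrp1a_like_fixture()
    _, cons = predict_consequences(genome, model, [])
    assert cons.kind == "none"


def test_nonstop_change_rejected_by_ptc_fixture():
    spec = FixtureSpec(
        exon_lengths=(90, 120, 96, 150, 108, 135, 120, 99),
        intron_lengths=(80, 76, 84, 88, 92, 78, 86),
        ptc_codon_change=("TAT", "TAC"),
    )
    with pytest.raises(ValueError, match="stop"):
        make_ptc_fixture(spec)
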