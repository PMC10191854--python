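"""Insertion validation, VAF, classification, mechanisms and variant filters."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1mosaic.retro_calls import (
    SegmentMapping,
    SoL1REvent,
    SourceRecord,
    VariantCall,
    annotate_mechanism,
    attribute_source,
    call_clonal_in_cancer,
    cell_fraction,
    class_fractions,
    classify_insertion,
    filter_variants,
    insertion_vaf,
    validate_insertion,
)


def make_event(**kwargs) -> SoL1REvent:
    base = dict(
        sample_id="cl1",
        chrom="chr1",
        target_pos=1000,
        polyA_len=30,
        tsd_len=12,
        supporting_pairs=10,
        reference_pairs=10,
    )
    base.update(kwargs)
    return SoL1REvent(**base)


REGISTRY = [
    SourceRecord("srcA", "chr2", 100_000, 106_000, "+"),
    SourceRecord("srcB", "chr2", 150_000, 156_000, "-"),
]


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def make_call(vafs, depth=100, **kwargs):
    support = {f"s{i}": (depth, int(round(v * depth))) for i, v in enumerate(vafs)}
    base = dict(chrom="chr1", pos=100, ref="A", alt="T", support=support)
    base.update(kwargs)
    return VariantCall(**base)


@pytest.mark.parametrize(
    "call, expected_rule",
    [
        (make_call([0.24, 0.20, 0.10]), "max_vaf_below_threshold"),
        (make_call([0.5, 0.5], depth=4), "min_depth_all_samples"),
        (make_call([0.5, 0.5], panel_vaf=0.01), "panel_of_normals"),
        (make_call([0.5, 0.5], clip_indel_proportion=0.71), "clipping_or_indel_proportion"),
        (make_call([0.5, 0.5], variant_read_mismatches=3), "variant_read_mismatches"),
        (VariantCall("chr1", 100, "A", "T", support={}), "insufficient_coverage_data"),
    ],
)
def test_filter_rejects_with_first_violated_rule(call, expected_rule):
    retained, rejected = filter_variants([call])
    assert retained == []
    assert rejected[0][1] == expected_rule


def test_clean_heterozygous_call_retained():
    call = make_call([0.5, 0.5, 0.5])
    retained, rejected = filter_variants([call])
    assert retained == [call] and rejected == []


def test_boundary_values_exactly_at_thresholds():
    # clipping proportion exactly 70% passes ("over 70%" rejects)
    retained, _ = filter_variants([make_call([0.5], clip_indel_proportion=0.70)])
    assert retained
    # exactly 5 reads everywhere passes
    retained, _ = filter_variants([make_call([0.6, 0.6], depth=5)])
    assert retained
    # VAF exactly 0.25 in one sample passes ("VAF < 0.25 in all" rejects)
    retained, _ = filter_variants([make_call([0.25, 0.0], depth=20)])
    assert retained
    # 2 mismatches pass, panel VAF just under 1% passes
    retained, _ = filter_variants(
        [make_call([0.5], variant_read_mismatches=2, panel_vaf=0.0099)]
    )
    assert retained


def test_filter_is_order_independent():
    calls = [make_call([0.5]), make_call([0.1]), make_call([0.3]), make_call([0.05])]
    fwd_kept, fwd_rej = filter_variants(calls)
    rev_kept, rev_rej = filter_variants(calls[::-1])
    assert set(map(id, fwd_kept)) == set(map(id, rev_kept))
    assert {id(c) for c, _ in fwd_rej} == {id(c) for c, _ in rev_rej}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_low_supporting_fraction_fails():
    ok, reasons = validate_insertion(make_event(supporting_pairs=2, reference_pairs=38))
    assert not ok and "low_supporting_fraction" in reasons  # 2/40 = 5% < 10%


def test_supported_event_with_hallmarks_passes():
    ok, reasons = validate_insertion(make_event(supporting_pairs=10, reference_pairs=10))
    assert ok and reasons == []


def test_missing_polyA_fails_with_named_reason():
    ok, reasons = validate_insertion(make_event(polyA_len=0))
    assert not ok and "no_polyA" in reasons


def test_tsd_absent_exception_flag():
    event = make_event(tsd_len=0)
    assert not validate_insertion(event)[0]
    assert validate_insertion(event, allow_tsd_absent=True)[0]


# ---------------------------------------------------------------------------
# VAF
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "s, r, expected",
    [(10, 0, 1.0), (10, 10, Fraction(10, 30)), (20, 20, Fraction(20, 60))],
)
def test_insertion_vaf_formula(s, r, expected):
    assert insertion_vaf(s, r) == pytest.approx(float(expected))


def test_vaf_undefined_without_informative_pairs():
    with pytest.raises(ValueError, match="undefined"):
        insertion_vaf(0, 0)


@settings(derandomize=True, max_examples=200)
@given(s=st.integers(1, 500), r=st.integers(1, 500))
def test_vaf_monotone_in_support_and_reference(s, r):
    v = insertion_vaf(s, r)
    assert 0 < v < 1
    assert insertion_vaf(s + 1, r) > v
    assert insertion_vaf(s, r + 1) < v
    assert insertion_vaf(2 * s, 2 * r) == pytest.approx(v)  # scale invariance


# ---------------------------------------------------------------------------
# classification and attribution
# ---------------------------------------------------------------------------

def test_solo_when_insert_maps_only_to_repeat():
    event = make_event(
        insert_5p_map=SegmentMapping("L1HS", 3000, 6000, "+", is_repeat=True),
        insert_3p_map=SegmentMapping("L1HS", 5500, 6000, "+", is_repeat=True),
    )
    classify_insertion(event, REGISTRY)
    assert event.insertion_class == "solo" and event.source_id is None


def test_orphan_attributed_within_15kb_downstream():
    segment = SegmentMapping("chr2", 114_000, 115_500, "+", is_repeat=False)
    event = make_event(unique_segment=segment)  # 8 kb past srcA's 3' end
    classify_insertion(event, REGISTRY)
    assert event.insertion_class == "orphan" and event.source_id == "srcA"


def test_partnered_keeps_l1_plus_unique_segment():
    event = make_event(
        insert_5p_map=SegmentMapping("L1HS", 3000, 6000, "+", is_repeat=True),
        unique_segment=SegmentMapping("chr2", 107_000, 108_000, "+", is_repeat=False),
    )
    classify_insertion(event, REGISTRY)
    assert event.insertion_class == "partnered" and event.source_id == "srcA"


def test_opposite_strand_ends_mark_inversion():
    event = make_event(
        insert_5p_map=SegmentMapping("L1HS", 3000, 4500, "+", is_repeat=True),
        insert_3p_map=SegmentMapping("L1HS", 4500, 6000, "-", is_repeat=True),
    )
    classify_insertion(event, REGISTRY)
    assert event.inverted


def test_minus_strand_source_downstream_sense():
    # srcB is on '-': transduced sequence lies at coordinates BELOW its start
    segment = SegmentMapping("chr2", 145_000, 146_000, "-", is_repeat=False)
    source_id, warnings = attribute_source(segment, REGISTRY)
    assert source_id == "srcB" and not warnings


def test_attribution_refused_inside_repeat_and_outside_window():
    inside_repeat = SegmentMapping("chr2", 114_000, 115_000, "+", is_repeat=True)
    sid, warn = attribute_source(inside_repeat, REGISTRY)
    assert sid is None and any("repeat" in w for w in warn)
    far = SegmentMapping("chr2", 126_001, 127_000, "+", is_repeat=False)  # 20 kb away
    assert attribute_source(far, REGISTRY)[0] is None


def test_nearest_source_wins_on_ties_with_ambiguity_logged():
    registry = [
        SourceRecord("near", "chr3", 10_000, 16_000, "+"),
        SourceRecord("farther", "chr3", 3_000, 9_000, "+"),
    ]
    segment = SegmentMapping("chr3", 18_000, 19_000, "+", is_repeat=False)
    sid, warnings = attribute_source(segment, registry)
    assert sid == "near"
    assert any("ambiguous" in w for w in warnings)


def test_classification_is_a_partition():
    events = [
        make_event(insert_5p_map=SegmentMapping("L1HS", 0, 100, "+", is_repeat=True)),
        make_event(unique_segment=SegmentMapping("chr2", 114_000, 115_000, "+", is_repeat=False)),
        make_event(),
    ]
    for ev in events:
        classify_insertion(ev, REGISTRY)
    fractions = class_fractions(events)
    assert sum(fractions.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# mechanisms
# ---------------------------------------------------------------------------

def test_canonical_event_has_no_mechanism_flags():
    event = annotate_mechanism(make_event(
        insert_5p_map=SegmentMapping("L1HS", 3000, 6000, "+", is_repeat=True),
        insert_3p_map=SegmentMapping("L1HS", 5500, 6000, "+", is_repeat=True),
    ))
    assert not event.twin_priming and not event.foldback
    assert event.extra_synthesis_len == 0


def test_intra_insert_inversion_flags_twin_priming():
    event = annotate_mechanism(make_event(
        insert_5p_map=SegmentMapping("L1HS", 3000, 4500, "-", is_repeat=True),
        insert_3p_map=SegmentMapping("L1HS", 4500, 6000, "+", is_repeat=True),
    ))
    assert event.twin_priming and not event.foldback


def test_target_flank_inverted_duplication_flags_foldback():
    event = annotate_mechanism(make_event(
        chrom="chr5",
        insert_5p_map=SegmentMapping("chr5", 900, 980, "-", is_repeat=False),
        insert_3p_map=SegmentMapping("chr5", 980, 1000, "+", is_repeat=False),
    ))
    assert event.foldback and not event.twin_priming


def test_extra_synthesis_by_exact_length_accounting():
    event = annotate_mechanism(
        make_event(), insert_length=1100, template_matched_length=1000
    )
    assert event.extra_synthesis_len == 100
    assert 52 <= event.extra_synthesis_len <= 220  # observed band for this mechanism


# ---------------------------------------------------------------------------
# clonality in cancer
# ---------------------------------------------------------------------------

def test_cutoff_is_minimum_shared_cell_fraction():
    events = [
        make_event(supporting_pairs=18, reference_pairs=2),  # VAF 18/22, CF capped 1
        make_event(supporting_pairs=3, reference_pairs=17),  # VAF 3/37, CF 0.162
    ]
    flags = call_clonal_in_cancer(
        events, shared_normal_cell_fractions=[0.7, 0.85, 0.9]
    )
    assert [f for _, f in flags] == [True, False]


def test_cell_fraction_doubles_vaf_and_caps():
    assert cell_fraction(0.3) == pytest.approx(0.6)
    assert cell_fraction(0.9) == 1.0
    assert cell_fraction(0.3, purity=0.75) == pytest.approx(0.8)


def test_missing_cutoff_and_reference_set_rejected():
    with pytest.raises(ValueError, match="cutoff"):
        call_clonal_in_cancer([make_event()])
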