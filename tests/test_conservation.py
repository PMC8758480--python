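import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicecons.conservation import (
    CONSERVED,
    LOST,
    NOT_ALIGNABLE,
    ConservationConfig,
    classify_site,
    classify_transcript,
    reverse_complement,
)
from splicecons.gene_models import SpliceSite
from splicecons.maf_io import MappedColumn


def donor(strand="+"):
    return SpliceSite("tx", "donor", "chr1", 200, strand, "GT")


def mapped(context, offset, species="mm10", aligned=True):
    char = context[offset] if aligned and 0 <= offset < len(context) else ""
    return MappedColumn(species, aligned, char, context, offset)


def brute_force_best_shift(context, offset, allowed, max_shift):
    """Independent oracle: scan every placement of an allowed dinucleotide."""
    hits = [
        i - offset
        for i in range(len(context) - 1)
        if context[i : i + 2] in allowed and abs(i - offset) <= max_shift
    ]
    if not hits:
        return None
    return min(hits, key=lambda s: (abs(s), s > 0))


def test_exact_donor_is_conserved_with_zero_shift():
    call = classify_site(donor(), mapped("CCGTAAG", 2))
    assert call.status == CONSERVED and call.shift == 0


def test_species_absent_is_not_alignable():
    call = classify_site(donor(), MappedColumn("mm10", False))
    assert call.status == NOT_ALIGNABLE and call.shift is None


def test_no_dinucleotide_with_zero_shift_is_lost():
    call = classify_site(donor(), mapped("AGCCA", 0), max_shift=0)
    assert call.status == LOST


def test_shifted_dinucleotide_found_and_matches_brute_force():
    # GT only at +3 within a +/-6 window
    context = "CCCCCCCAAACCGTAAACCC"
    offset = 9
    assert context[offset + 3 : offset + 5] == "GT"
    call = classify_site(donor(), mapped(context, offset), max_shift=6)
    assert call.status == CONSERVED
    assert call.shift == brute_force_best_shift(context, offset, ("GT",), 6) == 3


def test_tied_shifts_resolve_to_negative():
    context = "AAGTAAAGTAA"  # GT at indices 2 and 7; offset 5 gives shifts -3/+2?
    offset = 4  # GT at -2 and +3 -> smallest |shift| is... check both directions
    call = classify_site(donor(), mapped(context, offset), max_shift=6)
    assert call.shift == brute_force_best_shift(context, offset, ("GT",), 6)
    # explicit symmetric tie
    context = "GTAAGT"
    offset = 2  # GT at -2 and +2
    call = classify_site(donor(), mapped(context, offset), max_shift=6)
    assert call.shift == -2


def test_minus_strand_context_reverse_complemented():
    # alignment orientation holds "AC" (revcomp of donor GT) at the boundary
    site = SpliceSite("tx", "donor", "chr1", 200, "-", "GT")
    call = classify_site(site, mapped("CCACCC", 2), max_shift=0)
    assert call.status == CONSERVED and call.shift == 0
    call = classify_site(site, mapped("CCGTCC", 2), max_shift=0)
    assert call.status == LOST


def test_all_gap_context_is_not_alignable():
    call = classify_site(donor(), MappedColumn("mm10", True, "", "", -1))
    assert call.status == NOT_ALIGNABLE


@given(
    context=st.text(alphabet="ACGT", min_size=4, max_size=30),
    offset=st.integers(min_value=0, max_value=29),
    max_shift=st.integers(min_value=0, max_value=8),
    strand=st.sampled_from("+-"),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_shift_search_agrees_with_brute_force_scan(context, offset, max_shift, strand):
    offset = min(offset, len(context) - 1)
    site = SpliceSite("tx", "donor", "chr1", 200, strand, "GT")
    call = classify_site(site, mapped(context, offset), max_shift=max_shift)
    ctx, off = context, offset
    if strand == "-":
        ctx, off = reverse_complement(context), len(context) - offset - 2
    expected = brute_force_best_shift(ctx, off, ("GT",), max_shift)
    if expected is None:
        assert call.status == LOST
    else:
        assert call.status == CONSERVED and call.shift == expected


@given(
    context=st.text(alphabet="ACGT", min_size=4, max_size=30),
    offset=st.integers(min_value=0, max_value=25),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_widening_shift_window_never_loses_conservation(context, offset):
    offset = min(offset, len(context) - 1)
    statuses = [
        classify_site(donor(), mapped(context, offset), max_shift=s).status
        for s in range(0, 9)
    ]
    conserved = [s == CONSERVED for s in statuses]
    assert conserved == sorted(conserved)  # once conserved, stays conserved


def _call(status, tid="tx", species="mm10", kind="donor", pos=100):
    from splicecons.conservation import SiteConservationCall

    return SiteConservationCall(tid, kind, "chr1", pos, species, status,
                                0 if status == CONSERVED else None)


def test_all_sites_conserved_is_complete():
    calls = [_call(CONSERVED, pos=p) for p in (1, 2, 3, 4)]
    r = classify_transcript(calls)
    assert r.complete and r.present and r.fraction_conserved == 1.0
    assert all(r.intermediate.values())


def test_half_conserved_hits_intermediate_but_not_complete():
    calls = [_call(CONSERVED, pos=1), _call(CONSERVED, pos=2),
             _call(LOST, pos=3), _call(LOST, pos=4)]
    r = classify_transcript(calls)
    assert r.fraction_conserved == 0.5
    assert r.present and not r.complete
    assert r.intermediate[0.5] and r.intermediate[0.25] and not r.intermediate[0.75]


def test_nothing_conserved_nothing_alignable():
    calls = [_call(NOT_ALIGNABLE, pos=p) for p in (1, 2, 3, 4)]
    r = classify_transcript(calls)
    assert not r.present and not r.complete
    assert not any(r.intermediate.values())
    assert r.n_alignable == 0


def test_mixed_species_calls_rejected():
    calls = [_call(CONSERVED, species="mm10"), _call(CONSERVED, species="rn6")]
    with pytest.raises(ValueError, match="one \\(transcript, species\\)"):
        classify_transcript(calls)


def test_missing_sites_listed_in_error():
    sites = [SpliceSite("tx", "donor", "chr1", 100, "+", "GT"),
             SpliceSite("tx", "acceptor", "chr1", 150, "+", "AG")]
    calls = [_call(CONSERVED, pos=100)]
    with pytest.raises(ValueError, match="150"):
        classify_transcript(calls, expected_sites=sites)


def test_level_flags_nest_on_pipeline_output(small_sim):
    table = pd.read_csv(small_sim["outdir"] / "transcript_conservation.tsv", sep="\t")
    inter = [c for c in table.columns if c.startswith("frac_ge_")]
    for col in inter:
        assert not (table["complete"] & ~table[col]).any()
        assert not (table[col] & ~table["present"]).any()


def test_reference_species_fully_conserved(small_sim):
    """Self-conservation: every site maps onto its own canonical dinucleotide."""
    from splicecons.conservation import run_conservation
    from splicecons.gene_models import read_annotation
    from splicecons.maf_io import MafIndex

    transcripts = read_annotation(small_sim["paths"]["bed"], "bed12")[:10]
    index = MafIndex(small_sim["paths"]["maf"], "hg38")
    cfg = ConservationConfig(species=("hg38", "spA"))
    _, records = run_conservation(transcripts, index, cfg)
    ref_rows = [r for r in records if r.species == "hg38"]
    assert ref_rows and all(r.fraction_conserved == 1.0 for r in ref_rows)


def test_unseen_species_warns_and_calls_not_alignable(small_sim, caplog):
    from splicecons.conservation import run_conservation
    from splicecons.gene_models import read_annotation
    from splicecons.maf_io import MafIndex

    transcripts = read_annotation(small_sim["paths"]["bed"], "bed12")[:2]
    index = MafIndex(small_sim["paths"]["maf"], "hg38")
    with caplog.at_level("WARNING"):
        calls, records = run_conservation(
            transcripts, index, ConservationConfig(species=("noSuchSpecies",))
        )
    assert "never observed" in caplog.text
    assert all(c.status == NOT_ALIGNABLE for c in calls)
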