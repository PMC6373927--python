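"""Base quality score recalibration: tabulation, empirical quality,
deltas, application, and the .recal report."""

import io

import numpy as np
import pytest

from samprep.aux_formats import KnownSites, ReferenceMap
from samprep.bqsr import (
    RecalTable,
    apply_bqsr,
    compute_deltas,
    covariates_for_read,
    empirical_quality,
    read_recal_table,
    recalibrate_record,
    serialize_recal_table,
    tabulate,
    write_recal_table,
)
from samprep.sam_model import SamFile

from conftest import make_header, make_record
from oracles import scan_empirical_quality


REF = ReferenceMap({"chr1": "ACGTACGTACGTACGTACGT", "chr2": "GGGGCCCCAAAATTTT"})
NO_SITES = KnownSites()


def _read(seq, pos=1, flag=0, qual=None, cigar=None, rg="rg0", mapq=60):
    n = len(seq)
    return make_record(
        qname="r", flag=flag, rname="chr1", pos=pos, mapq=mapq,
        cigar=cigar or ((n, "M"),), seq=seq, qual=qual or chr(30 + 33) * n,
        tags=[("RG", "Z", rg)],
    )


def _sam(*records):
    return SamFile(make_header(), list(records))


# -- empirical quality ------------------------------------------------------

@pytest.mark.parametrize(
    "obs,err,prior",
    [
        (0, 0, 30),
        (1000, 1, 30),
        (1000, 0, 30),
        (100, 100, 10),
        (10**6, 10**3, 30),  # err/obs == 10^-3 exactly: peak at the prior
        (50000, 500, 25),
        (10, 3, 40),
    ],
)
def test_empirical_quality_matches_exhaustive_scan(obs, err, prior):
    assert empirical_quality(obs, err, prior) == scan_empirical_quality(obs, err, prior)


def test_empirical_quality_zero_observations_returns_prior():
    assert empirical_quality(0, 0, 30) == 30
    assert empirical_quality(0, 0, 27.6) == 28


def test_huge_matched_error_rate_keeps_reported_quality():
    assert empirical_quality(10**6, 10**3, 30) == 30


# -- covariates -------------------------------------------------------------

def test_forward_cycles_and_contexts():
    rec = _read("ACGTA")
    covs = covariates_for_read(rec, 2)
    assert [c for c, _ in covs] == [1, 2, 3, 4, 5]
    assert [x for _, x in covs] == [None, None, "AC", "CG", "GT"]


def test_reverse_read_counts_cycles_from_stored_end():
    # stored seq ACGTA; sequencing orientation is its reverse complement TACGT
    rec = _read("ACGTA", flag=0x10)
    covs = covariates_for_read(rec, 2)
    assert [c for c, _ in covs] == [5, 4, 3, 2, 1]
    # context precedes in sequencing orientation: for stored index 0 (cycle 5)
    # the two preceding sequencing bases are revcomp(seq[1:3]) = revcomp("CG")
    assert covs[0][1] == "CG"
    assert covs[4][1] is None  # sequencing cycle 1 has no context


def test_second_of_pair_cycles_are_negative():
    rec = _read("ACGTA", flag=0x1 | 0x80)
    assert [c for c, _ in covariates_for_read(rec, 2)] == [-1, -2, -3, -4, -5]


# -- tabulation -------------------------------------------------------------

def test_perfect_read_counts_every_base_with_context():
    rec = _read("ACGT")  # matches reference exactly
    table = tabulate(_sam(rec), REF, NO_SITES, context_length=0)
    assert table.rg["rg0"][:2] == [4, 0]
    # with the default 2-base context the first two cycles carry no context
    table2 = tabulate(_sam(rec), REF, NO_SITES, context_length=2)
    assert table2.rg["rg0"][:2] == [2, 0]


def test_mismatch_at_known_site_is_masked():
    rec = _read("AGGT")  # mismatch at position 2
    masked = KnownSites.from_sites({"chr1": [(2, 1)]})
    table = tabulate(_sam(rec), REF, masked, context_length=0)
    assert table.rg["rg0"][:2] == [3, 0]
    unmasked = tabulate(_sam(rec), REF, NO_SITES, context_length=0)
    assert unmasked.rg["rg0"][:2] == [4, 1]


def test_excluded_records_are_skipped():
    for flag, mapq in [(0x400, 60), (0x100, 60), (0x800, 60), (0x4, 60), (0, 0)]:
        rec = _read("ACGT", flag=flag, mapq=mapq)
        if flag == 0x4:
            rec.rname, rec.pos, rec.cigar = "*", 0, []
        table = tabulate(_sam(rec), REF, NO_SITES, context_length=0)
        assert table.rg == {}


def test_insertions_deletions_clips_contribute_nothing():
    # 2M1I1M: read ACGG-> positions 1,2 then insertion G then ref pos 3 (G)
    rec = _read("ACGG", cigar=((2, "M"), (1, "I"), (1, "M")))
    table = tabulate(_sam(rec), REF, NO_SITES, context_length=0)
    assert table.rg["rg0"][:2] == [3, 0]
    rec2 = _read("CGTA", pos=2, cigar=((1, "S"), (3, "M")))  # clip excluded
    # aligned part GTA vs ref pos 2..4 = CGT: mismatches at 2 of 3
    table2 = tabulate(_sam(rec2), REF, NO_SITES, context_length=0)
    assert table2.rg["rg0"][0] == 3


def test_missing_contig_raises():
    rec = _read("ACGT")
    rec.rname = "chrZ"
    with pytest.raises(ValueError, match="chrZ"):
        tabulate(_sam(rec), REF, NO_SITES)


def test_star_qual_skipped_by_policy():
    rec = _read("ACGT", qual="x")
    rec.qual = "*"
    assert tabulate(_sam(rec), REF, NO_SITES).rg == {}
    with pytest.raises(ValueError):
        tabulate(_sam(rec), REF, NO_SITES, skip_missing_qual=False)


def test_counts_conserved_across_levels():
    rng = np.random.default_rng(8)
    bases = "ACGT"
    records = []
    for i in range(60):
        n = int(rng.integers(5, 15))
        seq = "".join(rng.choice(list(bases), size=n))
        qual = "".join(chr(int(q) + 33) for q in rng.integers(20, 35, size=n))
        flag = 0x10 if rng.random() < 0.5 else 0
        records.append(_read(seq, pos=int(rng.integers(1, 5)), flag=flag, qual=qual,
                             rg=f"rg{int(rng.integers(0, 2))}"))
    table = tabulate(SamFile(make_header(read_groups=(("rg0", "l0"), ("rg1", "l1"))), records),
                     REF, NO_SITES)
    for rg, (obs, err, _) in table.rg.items():
        q_obs = sum(v[0] for (g, q), v in table.qual.items() if g == rg)
        q_err = sum(v[1] for (g, q), v in table.qual.items() if g == rg)
        assert (obs, err) == (q_obs, q_err)
    for (rg, q), (obs, err) in table.qual.items():
        for name in ("Cycle", "Context"):
            sub_obs = sum(v[0] for (g, qq, nm, _), v in table.cov.items()
                          if (g, qq, nm) == (rg, q, name))
            sub_err = sum(v[1] for (g, qq, nm, _), v in table.cov.items()
                          if (g, qq, nm) == (rg, q, name))
            assert (obs, err) == (sub_obs, sub_err)


def test_tabulation_is_input_order_invariant():
    rng = np.random.default_rng(9)
    records = [
        _read("ACGTACGT", pos=int(rng.integers(1, 8)),
              qual="".join(chr(int(q) + 33) for q in rng.integers(25, 35, size=8)))
        for _ in range(30)
    ]
    sam = _sam(*records)
    t1 = tabulate(sam, REF, NO_SITES)
    shuffled = SamFile(sam.header, [records[i] for i in rng.permutation(len(records))])
    t2 = tabulate(shuffled, REF, NO_SITES)
    assert t1 == t2


# -- deltas and application -------------------------------------------------

def test_empty_table_application_is_identity():
    table = compute_deltas(RecalTable())
    rec = _read("ACGT")
    before = rec.qual
    recalibrate_record(rec, table)
    assert rec.qual == before


def test_zero_delta_table_leaves_qualities_unchanged():
    rec = _read("ACGTACGT")
    table = tabulate(_sam(_read("ACGTACGT")), REF, NO_SITES)
    compute_deltas(table)
    # error-free tabulation at high prior weight: deltas may still shift;
    # instead pin deltas to zero explicitly and check pure arithmetic
    for key in table.delta_global:
        table.delta_global[key] = 0.0
    for key in table.delta_reported:
        table.delta_reported[key] = 0.0
    for key in table.delta_cov:
        table.delta_cov[key] = 0.0
    before = rec.qual
    recalibrate_record(rec, table)
    assert rec.qual == before


def test_delta_sum_arithmetic_and_clamp():
    table = RecalTable()
    table.delta_global = {"rg0": -1.0}
    table.delta_reported = {("rg0", 30): -1.0}
    table.delta_cov = {}
    table._deltas_ready = True
    rec = _read("ACGT")
    recalibrate_record(rec, table)
    assert rec.qual == chr(28 + 33) * 4  # 30 - 2


def test_preserve_below_threshold():
    table = RecalTable()
    table.delta_global = {"rg0": 10.0}
    table._deltas_ready = True
    rec = _read("ACGT", qual=chr(2 + 33) * 4)
    recalibrate_record(rec, table, preserve_below=6)
    assert rec.qual == chr(2 + 33) * 4


def test_apply_changes_only_qual():
    rng = np.random.default_rng(10)
    records = [
        _read("ACGTACGT", pos=1,
              qual="".join(chr(int(q) + 33) for q in rng.integers(20, 35, size=8)),
              flag=0x10 if i % 2 else 0)
        for i in range(20)
    ]
    sam = _sam(*records)
    table = compute_deltas(tabulate(sam, REF, NO_SITES))
    before = [(r.qname, r.flag, r.pos, list(r.cigar), r.seq, list(r.tags)) for r in sam.alignments]
    apply_bqsr(sam, table)
    after = [(r.qname, r.flag, r.pos, list(r.cigar), r.seq, list(r.tags)) for r in sam.alignments]
    assert before == after


def test_apply_rewrites_duplicates_and_unmapped_too():
    table = RecalTable()
    table.delta_global = {"rg0": -3.0}
    table._deltas_ready = True
    dup = _read("ACGT", flag=0x400)
    unmapped = _read("ACGT", flag=0x4)
    unmapped.rname, unmapped.pos, unmapped.cigar = "*", 0, []
    sam = _sam(dup, unmapped)
    apply_bqsr(sam, table)
    assert dup.qual == chr(27 + 33) * 4
    assert unmapped.qual == chr(27 + 33) * 4


# -- .recal report ----------------------------------------------------------

def _example_table():
    rng = np.random.default_rng(2)
    records = [
        _read("ACGTACGT",
              qual="".join(chr(int(q) + 33) for q in rng.integers(25, 35, size=8)))
        for _ in range(25)
    ]
    return compute_deltas(tabulate(_sam(*records), REF, NO_SITES))


def test_recal_write_read_round_trip():
    table = _example_table()
    text = serialize_recal_table(table)
    back = read_recal_table(io.StringIO(text))
    assert back == table
    assert serialize_recal_table(back) == text


def test_recal_serialization_is_deterministic():
    t1, t2 = _example_table(), _example_table()
    assert serialize_recal_table(t1) == serialize_recal_table(t2)


def test_empty_table_serializes_header_only_report():
    text = serialize_recal_table(RecalTable())
    lines = text.strip().split("\n")
    assert lines[0].startswith("#:samprep.recal")
    assert all(l.startswith("#:") or "\t" in l for l in lines)
    assert read_recal_table(io.StringIO(text)).rg == {}


def test_recal_rejects_foreign_text():
    with pytest.raises(ValueError):
        read_recal_table(io.StringIO("not a recal file\n"))
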