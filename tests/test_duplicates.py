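"""Duplicate marking, optical clustering, library-size estimation."""

import math

import numpy as np
import pytest

from samprep.duplicates import (
    estimate_library_size,
    mark_duplicates,
    mark_optical_duplicates,
    parse_physical_location,
    record_score,
    unclipped_position,
)
from samprep.sam_model import SamFile

from conftest import make_header, make_record, random_duplicate_file
from oracles import (
    bisect_library_size,
    brute_force_duplicates,
    brute_force_optical_clusters,
    marked_set,
)


# -- unclipped position -----------------------------------------------------

@pytest.mark.parametrize(
    "flag,pos,cigar,expected",
    [
        (0, 100, ((10, "M"),), 100),
        (0, 100, ((3, "S"), (7, "M")), 97),
        (0x10, 100, ((5, "M"), (2, "S")), 106),  # 100 + 5 - 1 + 2
        (0, 100, ((2, "H"), (1, "S"), (7, "M")), 97),
        (0x10, 100, ((10, "M"), (5, "D"), (3, "M"), (4, "S")), 121),  # ref len 18
    ],
)
def test_unclipped_position(flag, pos, cigar, expected):
    rec = make_record(flag=flag, pos=pos, cigar=cigar)
    assert unclipped_position(rec) == expected


def test_unclipped_position_rejects_unmapped():
    with pytest.raises(ValueError):
        unclipped_position(make_record(flag=0x4, rname="*", pos=0, cigar=[]))


# -- scores -----------------------------------------------------------------

def test_score_sums_qualities_at_or_above_15():
    rec = make_record(cigar=((3, "M"),), qual="".join(chr(q + 33) for q in (20, 20, 10)))
    assert record_score(rec) == 40


def test_score_all_below_threshold_is_zero():
    rec = make_record(cigar=((4, "M"),), qual=chr(14 + 33) * 4)
    assert record_score(rec) == 0


def test_missing_qual_scores_zero():
    rec = make_record(qual="*")
    assert record_score(rec) == 0


# -- marking: explicit small cases ------------------------------------------

def _pair(qname, pos1, pos2, q1=30, q2=30, fi=0, contig="chr1", lib="rg0",
          clip1=0):
    cig1 = ([(clip1, "S")] if clip1 else []) + [(20 - clip1, "M")]
    r1 = make_record(qname=qname, flag=0x1 | 0x40 | 0x20, rname=contig,
                     pos=pos1 + clip1, cigar=cig1, rnext="=", pnext=pos2,
                     qual=chr(q1 + 33) * 20, tags=[("RG", "Z", lib)], file_index=fi)
    r2 = make_record(qname=qname, flag=0x1 | 0x80 | 0x10, rname=contig,
                     pos=pos2, cigar=((20, "M"),), rnext="=", pnext=pos1 + clip1,
                     qual=chr(q2 + 33) * 20, tags=[("RG", "Z", lib)], file_index=fi + 1)
    return [r1, r2]


def test_lower_scoring_identical_fragment_is_marked():
    recs = [
        make_record(qname="hi", qual=chr(30 + 33) * 10, file_index=0),
        make_record(qname="lo", qual=chr(25 + 33) * 10, file_index=1),
    ]
    sam = SamFile(make_header(), recs)
    mark_duplicates(sam, deterministic=True)
    assert not recs[0].is_duplicate
    assert recs[1].is_duplicate


def test_pairs_beat_fragments_even_with_higher_score():
    recs = _pair("p", 100, 400, q1=20, q2=20)
    frag = make_record(qname="f", pos=100, cigar=((20, "M"),),
                       qual=chr(40 + 33) * 20, tags=[("RG", "Z", "rg0")], file_index=2)
    sam = SamFile(make_header(), recs + [frag])
    mark_duplicates(sam, deterministic=True)
    assert frag.is_duplicate
    assert not recs[0].is_duplicate and not recs[1].is_duplicate


def test_equal_score_pair_tie_breaks_by_file_index():
    a = _pair("a", 100, 400, fi=2)
    b = _pair("b", 100, 400, fi=0)
    sam = SamFile(make_header(), a + b)
    mark_duplicates(sam, deterministic=True)
    assert a[0].is_duplicate and a[1].is_duplicate
    assert not b[0].is_duplicate and not b[1].is_duplicate


def test_clipping_does_not_change_the_key():
    a = _pair("a", 100, 400, fi=0, q1=30)
    b = _pair("b", 100, 400, fi=2, q1=25, clip1=3)  # raw POS differs, key matches
    assert b[0].pos != a[0].pos
    sam = SamFile(make_header(), a + b)
    mark_duplicates(sam, deterministic=True)
    assert b[0].is_duplicate and b[1].is_duplicate


def test_pair_key_is_mate_swap_invariant():
    a = _pair("a", 100, 400, fi=0)
    b = _pair("b", 100, 400, fi=2)
    # swap which mate is first-of-pair in b: strands travel with position
    b[0].flag, b[1].flag = 0x1 | 0x80 | 0x20, 0x1 | 0x40 | 0x10
    sam = SamFile(make_header(), a + b)
    mark_duplicates(sam, deterministic=True)
    assert b[0].is_duplicate and b[1].is_duplicate


def test_secondary_supplementary_unmapped_never_examined():
    recs = [
        make_record(qname="sec", flag=0x100 | 0x400, file_index=0),
        make_record(qname="sup", flag=0x800, file_index=1),
        make_record(qname="unm", flag=0x4, rname="*", pos=0, cigar=[], file_index=2),
        make_record(qname="frag", file_index=3),
    ]
    sam = SamFile(make_header(), recs)
    mark_duplicates(sam, deterministic=True)
    assert recs[0].is_duplicate  # untouched: pre-existing flag survives
    assert not recs[1].is_duplicate and not recs[2].is_duplicate
    assert not recs[3].is_duplicate


def test_orphan_pair_member_treated_as_fragment_with_warning():
    r1 = _pair("orphan", 100, 400)[0]  # mate never added
    frag = make_record(qname="f", pos=100, cigar=((20, "M"),),
                       qual=chr(20 + 33) * 20, tags=[("RG", "Z", "rg0")], file_index=5)
    sam = SamFile(make_header(), [r1, frag])
    result = mark_duplicates(sam, deterministic=True)
    assert result.orphan_warnings == 1
    # both are fragments at the same key now; higher score survives
    assert frag.is_duplicate and not r1.is_duplicate


def test_marking_only_touches_the_duplicate_bit():
    sam = random_duplicate_file(np.random.default_rng(0), 60)
    before = [(r.qname, r.flag & ~0x400, r.pos, r.qual) for r in sam.alignments]
    mark_duplicates(sam, deterministic=True)
    after = [(r.qname, r.flag & ~0x400, r.pos, r.qual) for r in sam.alignments]
    assert before == after


def test_agreement_with_brute_force_oracle_small_batch():
    for seed in range(10):
        sam = random_duplicate_file(np.random.default_rng(seed), 80)
        mark_duplicates(sam, deterministic=True)
        assert marked_set(sam) == brute_force_duplicates(sam), f"seed {seed}"


def test_input_order_invariance():
    rng = np.random.default_rng(42)
    sam = random_duplicate_file(rng, 100)
    mark_duplicates(sam, deterministic=True)
    expected = marked_set(sam)
    shuffled = SamFile(sam.header, [sam.alignments[i] for i in rng.permutation(len(sam.alignments))])
    mark_duplicates(shuffled, deterministic=True)
    assert marked_set(shuffled) == expected


# -- physical locations and optical clustering ------------------------------

@pytest.mark.parametrize(
    "qname,expected",
    [
        ("M:1:FC:1:2101:1000:2000", (2101, 1000, 2000)),
        ("read1", None),
        ("a:b:c:d:1:2:3", (1, 2, 3)),
        ("a:b:1:x:3", None),  # x not an integer
    ],
)
def test_parse_physical_location(qname, expected):
    loc = parse_physical_location(qname)
    if expected is None:
        assert loc is None
    else:
        assert (loc.tile, loc.x, loc.y) == expected


def _optical_file(coords, tiles=None, contig="chr1"):
    """One duplicate class: n identical pairs with given pixel coords."""
    records = []
    for i, (x, y) in enumerate(coords):
        tile = 1 if tiles is None else tiles[i]
        qname = f"m{i}:1:{tile}:{x}:{y}"
        r = _pair(qname, 100, 400, q1=30 - i, fi=2 * i)  # distinct scores: i=0 survives
        for rec in r:
            rec.qname = qname
        records.extend(r)
    return SamFile(make_header(), records)


def test_two_members_within_distance_are_optical():
    sam = _optical_file([(10, 10), (60, 50)])
    result = mark_duplicates(sam, deterministic=True)
    counts = mark_optical_duplicates(result.classes, max_distance=100)
    assert counts == {"lib1": 1}


def test_different_tiles_never_link():
    sam = _optical_file([(10, 10), (10, 10)], tiles=[1, 2])
    result = mark_duplicates(sam, deterministic=True)
    assert mark_optical_duplicates(result.classes, max_distance=100) == {}


def test_transitive_chain_forms_one_cluster():
    # a-b and b-c within 100, a-c not: one cluster of 3, 2 optical
    sam = _optical_file([(0, 0), (90, 0), (180, 0)])
    result = mark_duplicates(sam, deterministic=True)
    assert mark_optical_duplicates(result.classes, max_distance=100) == {"lib1": 2}


def test_members_without_location_never_link():
    sam = _optical_file([(10, 10), (20, 20)])
    for rec in sam.alignments:
        rec.qname = rec.qname.split(":")[0]  # drop coordinates from all names
    result = mark_duplicates(sam, deterministic=True)
    assert mark_optical_duplicates(result.classes, max_distance=100) == {}


def test_optical_counts_match_brute_force_closure():
    rng = np.random.default_rng(3)
    for trial in range(50):
        n = int(rng.integers(2, 10))
        coords = [(int(rng.integers(0, 300)), int(rng.integers(0, 300))) for _ in range(n)]
        tiles = [int(rng.integers(1, 3)) for _ in range(n)]
        sam = _optical_file(coords, tiles=tiles)
        result = mark_duplicates(sam, deterministic=True)
        counts = mark_optical_duplicates(result.classes, max_distance=100)
        points = [(0, tiles[i], x, y) for i, (x, y) in enumerate(coords)]
        clusters = brute_force_optical_clusters(points, 100)
        expected = sum(len(c) - 1 for c in clusters)
        got = counts.get("lib1", 0)
        assert got == expected, f"trial {trial}"
        # optical never exceeds the class's pair duplicates
        assert got <= n - 1


# -- library size -----------------------------------------------------------

def test_library_size_degenerate_cases():
    assert estimate_library_size(100, 100) is None
    assert estimate_library_size(100, 0) is None
    with pytest.raises(ValueError):
        estimate_library_size(10, 11)


def test_library_size_residual_and_oracle():
    for n, u in [(100, 50), (1000, 900), (10**6, 10**5), (7, 3)]:
        x = estimate_library_size(n, u)
        assert abs(x * (1 - math.exp(-n / x)) - u) < 1e-6 * x
        assert x == pytest.approx(bisect_library_size(n, u), rel=1e-6)


def test_library_size_monotone_in_unique_pairs():
    xs = [estimate_library_size(1000, u) for u in (200, 400, 600, 800)]
    assert xs == sorted(xs)
    assert estimate_library_size(1000, 800) > estimate_library_size(1000, 400)
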