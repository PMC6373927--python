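"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from samprep.sam_model import AlignmentRecord, SamFile, SamHeader, parse_sam


TINY_SAM = """\
@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chr1\tLN:10000
@SQ\tSN:chr2\tLN:8000
@RG\tID:rg0\tLB:lib1\tPU:unit0\tSM:s1
r1\t0\tchr1\t100\t60\t4M\t*\t0\t0\tACGT\tIIII\tNM:i:2\tRG:Z:rg0
r2\t16\tchr1\t200\t60\t3M1S\t*\t0\t0\tACGT\tIIII\tRG:Z:rg0
r3\t4\t*\t0\t0\t*\t*\t0\t0\tTTTT\tIIII
"""


@pytest.fixture
def tiny_sam_text() -> str:
    return TINY_SAM


@pytest.fixture
def tiny_sam(tiny_sam_text) -> SamFile:
    import io

    return parse_sam(io.StringIO(tiny_sam_text))


def make_record(
    qname="r",
    flag=0,
    rname="chr1",
    pos=100,
    mapq=60,
    cigar=((10, "M"),),
    rnext="*",
    pnext=0,
    tlen=0,
    seq=None,
    qual=None,
    tags=(),
    file_index=0,
) -> AlignmentRecord:
    length = sum(n for n, op in cigar if op in "MIS=X") if cigar else 10
    if seq is None:
        seq = "A" * length
    if qual is None:
        qual = chr(30 + 33) * length
    return AlignmentRecord(
        qname, flag, rname, pos, mapq, list(cigar), rnext, pnext, tlen,
        seq, qual, list(tags), file_index,
    )


def make_header(contigs=(("chr1", 10000), ("chr2", 8000)), read_groups=(("rg0", "lib1"),)) -> SamHeader:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    lines += [f"@SQ\tSN:{n}\tLN:{l}" for n, l in contigs]
    lines += [f"@RG\tID:{rg}\tLB:{lb}\tPU:unit\tSM:s1" for rg, lb in read_groups]
    return SamHeader(lines=lines)


def random_duplicate_file(rng: np.random.Generator, n_records: int = 80) -> SamFile:
    """Adversarial random SAM files for duplicate-marking oracle checks:
    few loci (forced key collisions), random clips, strands, libraries,
    pairs/fragments, deliberate score ties, unmapped and secondary reads."""
    header = make_header(
        contigs=(("chr1", 100000), ("chr2", 100000)),
        read_groups=(("rg0", "libA"), ("rg1", "libB"), ("rg2", "libA")),
    )
    loci = [int(p) for p in rng.integers(1000, 1030, size=6)]  # heavy collisions
    contigs = ["chr1", "chr1", "chr2"]
    records: list[AlignmentRecord] = []
    uid = 0
    n = 0
    while n < n_records:
        uid += 1
        kind = rng.random()
        lib_tag = [("RG", "Z", f"rg{int(rng.integers(0, 3))}")]
        if rng.random() < 0.1:
            lib_tag = []  # falls into "Unknown Library"
        contig = contigs[int(rng.integers(0, 3))]
        pos = loci[int(rng.integers(0, len(loci)))]
        clip = int(rng.integers(0, 4))
        read_len = 20
        q = int(rng.choice([20, 20, 25, 30]))  # repeated values force ties
        qual = chr(q + 33) * read_len
        if kind < 0.12:  # unmapped record
            records.append(
                make_record(qname=f"u{uid}", flag=0x4, rname="*", pos=0, mapq=0,
                            cigar=[], seq="A" * read_len, qual=qual, tags=lib_tag)
            )
            n += 1
        elif kind < 0.2:  # secondary record at a colliding locus
            records.append(
                make_record(qname=f"s{uid}", flag=0x100, rname=contig, pos=pos,
                            cigar=[(read_len, "M")], qual=qual, tags=lib_tag)
            )
            n += 1
        elif kind < 0.55:  # fragment, possibly clipped, random strand
            reverse = bool(rng.random() < 0.5)
            if reverse:
                cig = [(read_len - clip, "M")] + ([(clip, "S")] if clip else [])
                flag = 0x10
            else:
                cig = ([(clip, "S")] if clip else []) + [(read_len - clip, "M")]
                flag = 0
            records.append(
                make_record(qname=f"f{uid}", flag=flag, rname=contig, pos=pos + clip if not reverse else pos,
                            cigar=cig, qual=qual, tags=lib_tag)
            )
            n += 1
        elif kind < 0.62 and n + 1 <= n_records:  # paired read with unmapped mate
            records.append(
                make_record(qname=f"m{uid}", flag=0x1 | 0x8 | 0x40, rname=contig,
                            pos=pos, cigar=[(read_len, "M")], rnext="=", pnext=pos,
                            qual=qual, tags=lib_tag)
            )
            n += 1
        else:  # proper pair (sometimes cross-contig)
            if n + 2 > n_records:
                n = n_records
                continue
            mate_contig = contig if rng.random() < 0.8 else contigs[int(rng.integers(0, 3))]
            mate_pos = loci[int(rng.integers(0, len(loci)))] + 300
            c1 = ([(clip, "S")] if clip else []) + [(read_len - clip, "M")]
            c2 = [(read_len, "M")]
            rnext1 = "=" if mate_contig == contig else mate_contig
            rnext2 = "=" if mate_contig == contig else contig
            records.append(
                make_record(qname=f"p{uid}", flag=0x1 | 0x40 | 0x20, rname=contig,
                            pos=pos + clip, cigar=c1, rnext=rnext1, pnext=mate_pos,
                            qual=qual, tags=lib_tag)
            )
            records.append(
                make_record(qname=f"p{uid}", flag=0x1 | 0x80 | 0x10, rname=mate_contig,
                            pos=mate_pos, cigar=c2, rnext=rnext2, pnext=pos + clip,
                            qual=chr(int(rng.choice([20, 25, 30])) + 33) * read_len,
                            tags=lib_tag)
            )
            n += 2
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    for i, rec in enumerate(records):
        rec.file_index = i
    return SamFile(header, records)
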