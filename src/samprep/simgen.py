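"""Synthetic fixture generator with ground truth.

Emits pre-aligned paired-end (plus optional single-end) reads over a
random reference, with planted features whose truth is recorded alongside:

* PCR-duplicate groups — pairs sharing adapted (unclipped) 5' keys but
  with varied soft clipping, so raw POS differs while the duplicate key
  matches; per group one intended survivor (strictly highest quality sum).
* optical duplicates — read names carry tile/x/y pixel coordinates at
  controlled offsets from the survivor; copies within the pixel threshold
  are true optical duplicates, far copies are PCR-only.
* sequencing errors — mismatches injected per cycle at
  rate(c) = base_rate * multiplier(c), with base_rate defaulting to the
  Phred-matched 10^(-Q/10) of the constant reported quality.
* known sites — planted "variant" positions where every covering read
  carries the alternate base; emitted as a VCF so masking can exclude them
  from error tabulation.

Alignment itself is out of scope: reads are emitted with consistent
POS/CIGAR directly. Everything is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .aux_formats import ReferenceMap
from .sam_model import AlignmentRecord, SamFile, SamHeader

__all__ = [
    "DupProfile",
    "ErrorProfile",
    "OpticalProfile",
    "SimTruth",
    "gen_reference",
    "reference_fasta",
    "gen_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass
class DupProfile:
    """Planted PCR-duplicate structure: ``n_groups`` loci each receive
    ``group_size`` pairs (one survivor + duplicates), clipped variably."""

    n_groups: int = 8
    group_size: int = 3
    max_clip: int = 3


@dataclass
class OpticalProfile:
    """Pixel geometry of duplicate copies relative to the group survivor.

    The first ``n_optical`` duplicates of each group sit ``near_offset``
    pixels away (within the threshold), the rest ``far_offset`` away.
    """

    n_optical: int = 1
    near_offset: int = 50
    far_offset: int = 5000


@dataclass
class ErrorProfile:
    base_quality: int = 30
    base_rate: Optional[float] = None  # None -> 10^(-Q/10)
    cycle_multipliers: dict[int, float] = field(default_factory=dict)
    n_known_sites: int = 0

    def rate_at(self, cycle: int) -> float:
        rate = self.base_rate
        if rate is None:
            rate = 10.0 ** (-self.base_quality / 10.0)
        return min(1.0, rate * self.cycle_multipliers.get(abs(cycle), 1.0))


@dataclass
class SimTruth:
    duplicate_qnames: set[str] = field(default_factory=set)  # non-survivor pairs
    survivor_qnames: set[str] = field(default_factory=set)  # dup-group survivors
    optical_per_library: dict[str, int] = field(default_factory=dict)
    known_sites: dict[str, list[int]] = field(default_factory=dict)
    vcf_text: str = ""
    per_cycle_rate: dict[int, float] = field(default_factory=dict)
    base_rate: float = 0.0
    base_quality: int = 30


def gen_reference(
    contigs: list[tuple[str, int]], seed: int = 0
) -> ReferenceMap:
    """Reproducible uniform-ACGT reference."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, length in contigs:
        if length <= 0:
            raise ValueError(f"contig {name!r}: non-positive length")
        out[name] = "".join(rng.choice(_BASES, size=length))
    return ReferenceMap(out)


def reference_fasta(ref: ReferenceMap, width: int = 70) -> str:
    lines = []
    for name, seq in ref.contigs.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


def _make_header(ref: ReferenceMap, libraries: list[str]) -> SamHeader:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    lines += [f"@SQ\tSN:{name}\tLN:{len(seq)}" for name, seq in ref.contigs.items()]
    lines += [
        f"@RG\tID:rg{i}\tLB:{lib}\tPU:unit{i}\tSM:sample1"
        for i, lib in enumerate(libraries)
    ]
    return SamHeader(lines=lines)


def gen_reads(
    reference: ReferenceMap,
    n_pairs: int = 300,
    read_len: int = 50,
    frag_len: Optional[int] = None,
    dup_profile: Optional[DupProfile] = None,
    optical_profile: Optional[OpticalProfile] = None,
    error_profile: Optional[ErrorProfile] = None,
    n_fragments: int = 0,
    libraries: tuple[str, ...] = ("lib1",),
    shuffle: bool = True,
    seed: int = 0,
) -> tuple[SamFile, SimTruth]:
    """Generate an aligned synthetic SAM file plus its ground truth."""
    rng = np.random.default_rng(seed)
    if frag_len is None:
        frag_len = 3 * read_len
    dup = dup_profile or DupProfile(n_groups=0)
    opt = optical_profile or OpticalProfile()
    err = error_profile or ErrorProfile()
    truth = SimTruth(
        base_rate=err.rate_at(10**9),  # unmodified cycles
        base_quality=err.base_quality,
    )
    truth.per_cycle_rate = {
        c: err.rate_at(c) for c in range(1, read_len + 1)
    }

    # distinct fragment slots so distinct loci never collide on keys
    slot_w = frag_len + 2 * dup.max_clip + 4
    slots: list[tuple[str, int]] = []
    for name, seq in reference.contigs.items():
        n_slots = (len(seq) - 2 * dup.max_clip - 2) // slot_w
        slots.extend((name, 1 + dup.max_clip + i * slot_w) for i in range(n_slots))
    needed = n_pairs + n_fragments
    if needed > len(slots):
        raise ValueError(
            f"reference too small: {needed} loci needed, {len(slots)} slots available"
        )
    order = rng.permutation(len(slots))[:needed]
    loci = [slots[i] for i in order]

    # plant known sites (one alt base each, inside the covered range)
    contigs = list(reference.contigs)
    mutable_ref = {name: list(seq) for name, seq in reference.contigs.items()}
    vcf_lines = [
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    alt_of: dict[tuple[str, int], str] = {}
    if err.n_known_sites:
        for _ in range(err.n_known_sites):
            contig = contigs[int(rng.integers(len(contigs)))]
            pos = int(rng.integers(1, len(reference.contigs[contig]) + 1))
            ref_base = reference.contigs[contig][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            if (contig, pos) in alt_of:
                continue
            alt_of[(contig, pos)] = alt
            truth.known_sites.setdefault(contig, []).append(pos)
            vcf_lines.append(f"{contig}\t{pos}\t.\t{ref_base}\t{alt}\t.\t.\t.")
        for positions in truth.known_sites.values():
            positions.sort()
    truth.vcf_text = "\n".join(vcf_lines) + "\n"

    header = _make_header(reference, list(libraries))
    records: list[AlignmentRecord] = []
    uid = 0

    def read_seq(contig: str, start: int, length: int, cycles: np.ndarray) -> str:
        """Reference bases start..start+length-1 with variants + errors.

        ``cycles`` gives each base's sequencing cycle (1-based, unsigned),
        used for the per-cycle error rate.
        """
        seq = list(reference.contigs[contig][start - 1 : start - 1 + length])
        for off in range(length):
            alt = alt_of.get((contig, start + off))
            if alt is not None:
                seq[off] = alt
        rates = np.array([err.rate_at(int(c)) for c in cycles])
        flips = rng.random(length) < rates
        for off in np.nonzero(flips)[0]:
            cur = seq[off]
            seq[off] = str(rng.choice([b for b in "ACGT" if b != cur]))
        return "".join(seq)

    def random_bases(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n)) if n else ""

    def qual_string(penalty_bases: int) -> str:
        q = chr(err.base_quality + 33)
        if penalty_bases == 0:
            return q * read_len
        low = chr(max(2, err.base_quality - 2) + 33)
        return q * (read_len - penalty_bases) + low * penalty_bases

    def emit_pair(
        contig: str,
        start: int,
        lib_idx: int,
        clip: int,
        tile: int,
        x: int,
        y: int,
        penalty: int,
    ) -> str:
        nonlocal uid
        qname = f"sim{uid}:1:{tile}:{x}:{y}"
        uid += 1
        rg = f"rg{lib_idx}"
        end = start + frag_len - 1
        # read 1: forward; leading soft clip, unclipped 5' stays at start
        pos1 = start + clip
        aligned1 = read_len - clip
        cig1 = ([(clip, "S")] if clip else []) + [(aligned1, "M")]
        cycles1 = np.arange(1, read_len + 1)
        seq1 = random_bases(clip) + read_seq(contig, pos1, aligned1, cycles1[clip:])
        # read 2: reverse; trailing soft clip, unclipped 3'-anchor stays at end
        aligned2 = read_len - clip
        pos2 = end - read_len + 1
        cig2 = [(aligned2, "M")] + ([(clip, "S")] if clip else [])
        # stored index j has sequencing cycle read_len - j
        cycles2 = read_len - np.arange(read_len)
        seq2 = read_seq(contig, pos2, aligned2, cycles2[:aligned2]) + random_bases(clip)
        q1, q2 = qual_string(penalty), qual_string(penalty)
        tlen = frag_len
        records.append(
            AlignmentRecord(qname, 0x63, contig, pos1, 60, cig1, "=", pos2, tlen,
                            seq1, q1, [("RG", "Z", rg)])
        )
        records.append(
            AlignmentRecord(qname, 0x93, contig, pos2, 60, cig2, "=", pos1, -tlen,
                            seq2, q2, [("RG", "Z", rg)])
        )
        return qname

    n_dup_pairs = dup.n_groups * dup.group_size
    if n_dup_pairs > n_pairs:
        raise ValueError("duplicate profile needs more pairs than requested")

    locus_i = 0
    pair_budget = n_pairs
    tile_base = 1101
    for g in range(dup.n_groups):
        contig, start = loci[locus_i]
        locus_i += 1
        lib_idx = g % len(libraries)
        tile = tile_base + g
        x0, y0 = 10000 + 37 * g, 20000 + 53 * g
        survivor = emit_pair(contig, start, lib_idx, clip=0, tile=tile, x=x0, y=y0, penalty=0)
        truth.survivor_qnames.add(survivor)
        for j in range(1, dup.group_size):
            clip = j % (dup.max_clip + 1)
            if j <= opt.n_optical:
                x, y = x0 + opt.near_offset, y0
                lib = libraries[lib_idx]
                truth.optical_per_library[lib] = truth.optical_per_library.get(lib, 0) + 1
            else:
                # distinct far offsets so far copies never link to each other
                x, y = x0 + opt.far_offset * j, y0
            qname = emit_pair(contig, start, lib_idx, clip, tile, x, y, penalty=j)
            truth.duplicate_qnames.add(qname)
        pair_budget -= dup.group_size

    for p in range(pair_budget):
        contig, start = loci[locus_i]
        locus_i += 1
        lib_idx = p % len(libraries)
        tile = 2000 + (p % 16)
        emit_pair(contig, start, lib_idx, clip=0, tile=tile,
                  x=int(rng.integers(0, 30000)), y=int(rng.integers(0, 30000)), penalty=0)

    for f in range(n_fragments):
        contig, start = loci[locus_i]
        locus_i += 1
        lib_idx = f % len(libraries)
        qname = f"sim{uid}:1:{3000 + f}:{int(rng.integers(0, 30000))}:{int(rng.integers(0, 30000))}"
        uid += 1
        cycles = np.arange(1, read_len + 1)
        seq = read_seq(contig, start, read_len, cycles)
        records.append(
            AlignmentRecord(qname, 0x0, contig, start, 60, [(read_len, "M")], "*", 0, 0,
                            seq, qual_string(0), [("RG", "Z", f"rg{lib_idx}")])
        )

    if shuffle:
        perm = rng.permutation(len(records))
        records = [records[i] for i in perm]
    for idx, rec in enumerate(records):
        rec.file_index = idx
    return SamFile(header, records), truth
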