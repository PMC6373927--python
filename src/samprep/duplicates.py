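"""Duplicate marking with Picard/GATK-4 semantics, optical duplicate
clustering, and duplication metrics.

Reads sharing an *adapted* (unclipped) 5' position key are PCR or optical
copies of one source fragment. Marking proceeds in two tiers:

* **pairs** — primary records with both ends mapped and the mate present.
  The pair key combines library and both ends' (contig, unclipped 5' pos,
  strand), with the two ends ordered canonically so the key is invariant
  under swapping mate roles. The highest-scoring pair in a class survives;
  all other members get flag 0x400.
* **fragments** — remaining mapped primary records (unpaired, mate
  unmapped, or mate absent). A fragment whose single-end key matches any
  pair's end key is always a duplicate (pairs beat fragments); otherwise
  the best fragment in its class survives.

Scores sum base qualities >= 15 (a pair's score is the sum over both
mates). Ties are broken by the original file order (``file_index``) in
deterministic mode, making repeated runs byte-identical.

Optical duplicates are class members whose flow-cell coordinates (tile, x,
y parsed from the read name) lie within a pixel threshold of another
member; clusters are the transitive closure of that relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import brentq

from .sam_model import AlignmentRecord, SamFile, SamHeader

__all__ = [
    "PhysicalLocation",
    "DuplicateClass",
    "DuplicationMetrics",
    "MarkResult",
    "unclipped_position",
    "record_score",
    "mark_duplicates",
    "parse_physical_location",
    "mark_optical_duplicates",
    "estimate_library_size",
    "collect_duplication_metrics",
    "library_of",
]

UNKNOWN_LIBRARY = "Unknown Library"

#: minimum base quality included in the duplicate score sum (Picard default)
SCORE_MIN_QUALITY = 15
#: default optical pixel distance (Picard OPTICAL_DUPLICATE_PIXEL_DISTANCE)
DEFAULT_PIXEL_DISTANCE = 100


def unclipped_position(rec: AlignmentRecord) -> int:
    """Adapted 5' mapping position (1-based), undoing soft/hard clips.

    Forward strand: pos minus leading S/H clip lengths. Reverse strand:
    alignment end (pos + reference_length - 1) plus trailing S/H clips.
    """
    if rec.is_unmapped or rec.pos == 0:
        raise ValueError(f"record {rec.qname!r} is unmapped; no unclipped position")
    cigar = rec.cigar
    if rec.is_reverse:
        trailing = 0
        for n, op in reversed(cigar):
            if op in ("S", "H"):
                trailing += n
            else:
                break
        return rec.pos + rec.reference_length() - 1 + trailing
    leading = 0
    for n, op in cigar:
        if op in ("S", "H"):
            leading += n
        else:
            break
    return rec.pos - leading


def record_score(rec: AlignmentRecord) -> int:
    """Sum of base qualities >= 15; 0 for a '*' quality string."""
    if rec.qual == "*":
        return 0
    return sum(q - 33 for q in map(ord, rec.qual) if q - 33 >= SCORE_MIN_QUALITY)


def library_of(rec: AlignmentRecord, header: SamHeader, rg_library: dict[str, str] | None = None) -> str:
    if rg_library is None:
        rg_library = header.rg_library
    rg = rec.get_tag("RG")
    if rg is None:
        return UNKNOWN_LIBRARY
    return rg_library.get(rg, UNKNOWN_LIBRARY)


def _end_key(rec: AlignmentRecord) -> tuple[str, int, str]:
    return (rec.rname, unclipped_position(rec), "R" if rec.is_reverse else "F")


@dataclass
class _Member:
    """One class member: a whole pair (two records) or a single fragment."""

    records: tuple[AlignmentRecord, ...]
    score: int
    file_index: int  # min over records: the deterministic tie-break key

    @property
    def qname(self) -> str:
        return self.records[0].qname


@dataclass
class DuplicateClass:
    library: str
    key: tuple
    is_pair: bool
    members: list[_Member]
    survivor: Optional[_Member] = None


@dataclass
class MarkResult:
    classes: list[DuplicateClass]
    pair_end_keys: set  # (library, contig, unclipped pos, strand)
    orphan_warnings: int  # paired records whose mate was absent


def mark_duplicates(
    sam: SamFile,
    deterministic: bool = True,
    external_pair_end_keys: set | None = None,
) -> MarkResult:
    """Mark PCR duplicates in place (flag 0x400 only; no records added or
    removed). Secondary, supplementary and unmapped records are never
    examined and never chosen as survivors.

    ``external_pair_end_keys`` extends the pairs-beat-fragments rule with
    pair end keys discovered elsewhere (used by the split-by-region mode,
    where cross-contig pairs live in a different chunk than fragments that
    may share their key).
    """
    rg_library = sam.header.rg_library
    eligible: list[AlignmentRecord] = []
    for rec in sam.alignments:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.pos == 0:
            continue
        eligible.append(rec)

    # pair formation: primary mapped, paired, mate mapped, mate present
    by_qname: dict[str, list[AlignmentRecord]] = {}
    for rec in eligible:
        if rec.is_paired and not rec.mate_unmapped:
            by_qname.setdefault(rec.qname, []).append(rec)

    pairs: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    orphans = 0
    paired_records: set[int] = set()
    for qname, recs in by_qname.items():
        if len(recs) == 2:
            pairs.append((recs[0], recs[1]))
            paired_records.add(id(recs[0]))
            paired_records.add(id(recs[1]))
        else:
            orphans += len(recs)  # mate absent: fall through to fragments

    pair_end_keys: set = set()
    pair_classes: dict[tuple, DuplicateClass] = {}
    for a, b in pairs:
        lib = library_of(a, sam.header, rg_library)
        ka, kb = _end_key(a), _end_key(b)
        key = (lib,) + tuple(sorted([ka, kb]))
        pair_end_keys.add((lib,) + ka)
        pair_end_keys.add((lib,) + kb)
        member = _Member(
            records=(a, b),
            score=record_score(a) + record_score(b),
            file_index=min(a.file_index, b.file_index),
        )
        cls = pair_classes.get(key)
        if cls is None:
            pair_classes[key] = cls = DuplicateClass(lib, key, True, [])
        cls.members.append(member)

    all_pair_end_keys = pair_end_keys | (external_pair_end_keys or set())

    frag_classes: dict[tuple, DuplicateClass] = {}
    for rec in eligible:
        if id(rec) in paired_records:
            continue
        lib = library_of(rec, sam.header, rg_library)
        key = (lib,) + _end_key(rec)
        member = _Member(records=(rec,), score=record_score(rec), file_index=rec.file_index)
        cls = frag_classes.get(key)
        if cls is None:
            frag_classes[key] = cls = DuplicateClass(lib, key, False, [])
        cls.members.append(member)

    def pick_survivor(members: list[_Member]) -> _Member:
        if deterministic:
            return min(members, key=lambda m: (-m.score, m.file_index))
        best = members[0]
        for m in members[1:]:
            if m.score > best.score:
                best = m
        return best

    # only flag bit 0x400 changes, and only on examined records
    for rec in eligible:
        rec.set_duplicate(False)

    classes: list[DuplicateClass] = []
    for cls in pair_classes.values():
        cls.survivor = pick_survivor(cls.members)
        for m in cls.members:
            if m is not cls.survivor:
                for r in m.records:
                    r.set_duplicate(True)
        classes.append(cls)

    for cls in frag_classes.values():
        lib_key = cls.key  # (lib, contig, pos, strand)
        if lib_key in all_pair_end_keys:
            # pairs beat fragments: every fragment here is a duplicate
            cls.survivor = None
            for m in cls.members:
                m.records[0].set_duplicate(True)
        else:
            cls.survivor = pick_survivor(cls.members)
            for m in cls.members:
                if m is not cls.survivor:
                    m.records[0].set_duplicate(True)
        classes.append(cls)

    return MarkResult(classes=classes, pair_end_keys=pair_end_keys, orphan_warnings=orphans)


# ---------------------------------------------------------------------------
# optical duplicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalLocation:
    tile: int
    x: int
    y: int


def parse_physical_location(qname: str) -> Optional[PhysicalLocation]:
    """Illumina-style read names: if the name has >= 5 ':'-separated fields
    and the last three parse as integers, they are (tile, x, y)."""
    parts = qname.split(":")
    if len(parts) < 5:
        return None
    try:
        tile, x, y = int(parts[-3]), int(parts[-2]), int(parts[-1])
    except ValueError:
        return None
    return PhysicalLocation(tile, x, y)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def mark_optical_duplicates(
    classes: list[DuplicateClass],
    max_distance: int = DEFAULT_PIXEL_DISTANCE,
    euclidean: bool = False,
) -> dict[str, int]:
    """Count optical duplicates per library among pair-duplicate classes.

    Two members of the same class are optically linked iff they share read
    group and tile and their pixel offsets are within ``max_distance`` on
    each axis (or within Euclidean distance if requested). Per transitive
    cluster, every member except the class survivor (or except one, in
    survivor-free clusters) counts as optical.
    """
    counts: dict[str, int] = {}
    for cls in classes:
        if not cls.is_pair or len(cls.members) < 2:
            continue
        located = []
        for m in cls.members:
            loc = parse_physical_location(m.qname)
            if loc is not None:
                rg = m.records[0].get_tag("RG")
                located.append((m, rg, loc))
        if len(located) < 2:
            continue
        uf = _UnionFind(len(located))
        for i in range(len(located)):
            _, rgi, li = located[i]
            for j in range(i + 1, len(located)):
                _, rgj, lj = located[j]
                if rgi != rgj or li.tile != lj.tile:
                    continue
                dx, dy = li.x - lj.x, li.y - lj.y
                if euclidean:
                    close = dx * dx + dy * dy <= max_distance * max_distance
                else:
                    close = abs(dx) <= max_distance and abs(dy) <= max_distance
                if close:
                    uf.union(i, j)
        clusters: dict[int, list[_Member]] = {}
        for idx, (m, _, _) in enumerate(located):
            clusters.setdefault(uf.find(idx), []).append(m)
        n_optical = sum(len(members) - 1 for members in clusters.values())
        if n_optical:
            counts[cls.library] = counts.get(cls.library, 0) + n_optical
    return counts


# ---------------------------------------------------------------------------
# library size estimate (Lander-Waterman)
# ---------------------------------------------------------------------------

def estimate_library_size(read_pairs: int, unique_pairs: int) -> Optional[float]:
    """Solve U = X * (1 - exp(-N/X)) for the library size X.

    Returns None when no duplication was observed (U == N) or nothing was
    observed (U == 0); raises for U > N. The root is unique because the
    left side is strictly increasing in X with range (0, N).
    """
    n, u = read_pairs, unique_pairs
    if u > n:
        raise ValueError(f"unique pairs ({u}) exceed total pairs ({n})")
    if u == n or u == 0:
        return None

    def f(x: float) -> float:
        return x * (1.0 - math.exp(-n / x)) - u

    lo = float(u)
    hi = float(u)
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - u < n guarantees a bracket
            raise RuntimeError("library size bracket expansion failed")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# duplication metrics
# ---------------------------------------------------------------------------

@dataclass
class DuplicationMetrics:
    """Picard-style per-library duplication counters.

    Pair counters are kept at read granularity (``*_reads``) so metrics
    from split chunks can be summed exactly; ``finalize`` halves them into
    pair units and derives PERCENT_DUPLICATION and ESTIMATED_LIBRARY_SIZE.
    """

    library: str
    unpaired_reads_examined: int = 0
    paired_reads_examined: int = 0
    secondary_or_supplementary: int = 0
    unmapped_reads: int = 0
    unpaired_duplicates: int = 0
    paired_duplicate_reads: int = 0
    optical_duplicate_pairs: int = 0

    # derived
    read_pairs_examined: int = 0
    read_pair_duplicates: int = 0
    percent_duplication: float = 0.0
    estimated_library_size: Optional[float] = None

    def add(self, other: "DuplicationMetrics") -> None:
        self.unpaired_reads_examined += other.unpaired_reads_examined
        self.paired_reads_examined += other.paired_reads_examined
        self.secondary_or_supplementary += other.secondary_or_supplementary
        self.unmapped_reads += other.unmapped_reads
        self.unpaired_duplicates += other.unpaired_duplicates
        self.paired_duplicate_reads += other.paired_duplicate_reads
        self.optical_duplicate_pairs += other.optical_duplicate_pairs

    def finalize(self) -> None:
        self.read_pairs_examined = self.paired_reads_examined // 2
        self.read_pair_duplicates = self.paired_duplicate_reads // 2
        denom = self.unpaired_reads_examined + 2 * self.read_pairs_examined
        numer = self.unpaired_duplicates + 2 * self.read_pair_duplicates
        self.percent_duplication = (numer / denom) if denom else 0.0
        n = self.read_pairs_examined - self.optical_duplicate_pairs
        u = self.read_pairs_examined - self.read_pair_duplicates
        self.estimated_library_size = (
            estimate_library_size(n, u) if 0 <= u <= n else None
        )


def collect_duplication_metrics(
    sam: SamFile, optical_counts: dict[str, int] | None = None
) -> dict[str, DuplicationMetrics]:
    """Tally duplication metrics by scanning final flag bits.

    Counting is flag-driven (0x400, 0x4, 0x100|0x800, pairing bits), so a
    brute-force recount over the output file reproduces these numbers.
    """
    rg_library = sam.header.rg_library
    out: dict[str, DuplicationMetrics] = {}

    def get(lib: str) -> DuplicationMetrics:
        m = out.get(lib)
        if m is None:
            out[lib] = m = DuplicationMetrics(lib)
        return m

    for rec in sam.alignments:
        lib = library_of(rec, sam.header, rg_library)
        m = get(lib)
        if rec.is_secondary or rec.is_supplementary:
            m.secondary_or_supplementary += 1
        elif rec.is_unmapped:
            m.unmapped_reads += 1
        elif rec.is_paired and not rec.mate_unmapped:
            m.paired_reads_examined += 1
            if rec.is_duplicate:
                m.paired_duplicate_reads += 1
        else:
            m.unpaired_reads_examined += 1
            if rec.is_duplicate:
                m.unpaired_duplicates += 1

    for lib, count in (optical_counts or {}).items():
        get(lib).optical_duplicate_pairs += count
    return out
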