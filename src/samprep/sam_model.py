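"""In-memory SAM model and lossless SAM text I/O.

The whole pipeline operates on a :class:`SamFile`: a header plus an ordered
list of :class:`AlignmentRecord`. Each record remembers the 0-based ordinal
of its alignment line in the original input (``file_index``), which serves
as the stable tie-break key everywhere determinism matters (coordinate-sort
ties, duplicate-survivor ties).

Only the SAM v1 *text* dialect is supported; qualities are Phred+33.
Coordinates follow the SAM convention: 1-based inclusive, ``pos == 0``
meaning unavailable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "AlignmentRecord",
    "SamHeader",
    "SamFile",
    "SamParseError",
    "parse_sam",
    "parse_sam_records",
    "write_sam",
    "reference_length",
    "CIGAR_OPS",
    "CONSUMES_REFERENCE",
]

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QC_FAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

CIGAR_OPS = set("MIDNSHP=X")
#: CIGAR operations that consume reference bases.
CONSUMES_REFERENCE = set("MDN=X")
#: CIGAR operations that consume read (query) bases.
CONSUMES_QUERY = set("MIS=X")

_CIGAR_RE = re.compile(r"(\d+)([A-Za-z=])")


class SamParseError(ValueError):
    """Raised for malformed SAM/VCF-adjacent text with a line reference."""


@dataclass
class AlignmentRecord:
    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: list[tuple[int, str]]  # empty list encodes "*"
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[tuple[str, str, object]] = field(default_factory=list)
    file_index: int = -1

    # -- flag predicates (each reads exactly one documented SAM flag bit) --
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_first_of_pair(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    @property
    def is_second_of_pair(self) -> bool:
        return bool(self.flag & FLAG_SECOND)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    def set_duplicate(self, value: bool) -> None:
        if value:
            self.flag |= FLAG_DUPLICATE
        else:
            self.flag &= ~FLAG_DUPLICATE

    def get_tag(self, name: str):
        """Return the tag value or None if absent."""
        for tag, _, value in self.tags:
            if tag == name:
                return value
        return None

    def reference_length(self) -> int:
        return reference_length(self.cigar)

    def reference_end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        return self.pos + reference_length(self.cigar) - 1

    def to_line(self) -> str:
        return format_record(self)


def reference_length(cigar: list[tuple[int, str]]) -> int:
    """Number of reference bases consumed by a CIGAR (M/D/N/=/X)."""
    return sum(n for n, op in cigar if op in CONSUMES_REFERENCE)


@dataclass
class SamHeader:
    """Parsed SAM header retaining the original line text for fidelity.

    ``lines`` keeps every header line verbatim (in order); the structured
    views (@SQ names/lengths, @RG id->library) are derived on parse and kept
    in sync by the mutation helpers used in the pipeline (set_sort_order,
    append_pg, strip_pg).
    """

    lines: list[str] = field(default_factory=list)

    # -- derived views -------------------------------------------------
    @staticmethod
    def _fields(line: str) -> dict[str, str]:
        out = {}
        for part in line.split("\t")[1:]:
            if ":" in part:
                key, _, value = part.partition(":")
                out[key] = value
        return out

    @property
    def sq_names(self) -> list[str]:
        return [self._fields(l)["SN"] for l in self.lines if l.startswith("@SQ")]

    @property
    def sq_lengths(self) -> dict[str, int]:
        return {
            self._fields(l)["SN"]: int(self._fields(l)["LN"])
            for l in self.lines
            if l.startswith("@SQ")
        }

    @property
    def rg_library(self) -> dict[str, str]:
        """@RG ID -> LB (library) mapping; IDs without LB are omitted."""
        out = {}
        for l in self.lines:
            if l.startswith("@RG"):
                f = self._fields(l)
                if "ID" in f and "LB" in f:
                    out[f["ID"]] = f["LB"]
        return out

    @property
    def rg_ids(self) -> list[str]:
        return [
            self._fields(l)["ID"]
            for l in self.lines
            if l.startswith("@RG") and "ID" in self._fields(l)
        ]

    @property
    def sort_order(self) -> str:
        for l in self.lines:
            if l.startswith("@HD"):
                return self._fields(l).get("SO", "unknown")
        return "unknown"

    # -- mutation helpers ----------------------------------------------
    def set_sort_order(self, order: str) -> None:
        for i, l in enumerate(self.lines):
            if l.startswith("@HD"):
                parts = l.split("\t")
                found = False
                for j, p in enumerate(parts[1:], start=1):
                    if p.startswith("SO:"):
                        parts[j] = f"SO:{order}"
                        found = True
                if not found:
                    parts.append(f"SO:{order}")
                self.lines[i] = "\t".join(parts)
                return
        self.lines.insert(0, f"@HD\tVN:1.6\tSO:{order}")

    def append_pg(self, pg_id: str, name: str, version: str) -> None:
        # No CL field: output must not depend on the invocation spelling.
        self.lines.append(f"@PG\tID:{pg_id}\tPN:{name}\tVN:{version}")

    def strip_pg(self) -> None:
        self.lines = [l for l in self.lines if not l.startswith("@PG")]

    def validate(self) -> None:
        names = self.sq_names
        if len(names) != len(set(names)):
            raise SamParseError("duplicate @SQ SN names in header")
        ids = self.rg_ids
        if len(ids) != len(set(ids)):
            raise SamParseError("duplicate @RG IDs in header")

    def copy(self) -> "SamHeader":
        return SamHeader(lines=list(self.lines))


@dataclass
class SamFile:
    header: SamHeader
    alignments: list[AlignmentRecord] = field(default_factory=list)

    def copy(self) -> "SamFile":
        import copy as _copy

        return SamFile(self.header.copy(), [_copy.deepcopy(a) for a in self.alignments])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_cigar(text: str, lineno: int) -> list[tuple[int, str]]:
    if text == "*":
        return []
    out = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise SamParseError(f"line {lineno}: malformed CIGAR {text!r}")
        n, op = int(m.group(1)), m.group(2)
        if op not in CIGAR_OPS:
            raise SamParseError(f"line {lineno}: unknown CIGAR operation {op!r} in {text!r}")
        if n <= 0:
            raise SamParseError(f"line {lineno}: non-positive CIGAR length in {text!r}")
        out.append((n, op))
        pos = m.end()
    if pos != len(text):
        raise SamParseError(f"line {lineno}: malformed CIGAR {text!r}")
    return out


def _parse_tag(text: str, lineno: int) -> tuple[str, str, object]:
    parts = text.split(":", 2)
    if len(parts) != 3 or len(parts[0]) != 2 or len(parts[1]) != 1:
        raise SamParseError(f"line {lineno}: malformed optional field {text!r}")
    tag, typ, raw = parts
    if typ == "i":
        try:
            value: object = int(raw)
        except ValueError as exc:
            raise SamParseError(f"line {lineno}: bad integer tag {text!r}") from exc
    elif typ == "f":
        try:
            value = float(raw)
        except ValueError as exc:
            raise SamParseError(f"line {lineno}: bad float tag {text!r}") from exc
    elif typ in ("A", "Z", "H", "B"):
        value = raw  # H/B kept verbatim: pass-through fidelity only
    else:
        raise SamParseError(f"line {lineno}: unknown tag type {typ!r} in {text!r}")
    return tag, typ, value


def parse_alignment_line(line: str, lineno: int, file_index: int) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(
            f"line {lineno}: alignment line has {len(fields)} fields, expected >= 11"
        )
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        mapq = int(fields[4])
        pnext = int(fields[7])
        tlen = int(fields[8])
    except ValueError as exc:
        raise SamParseError(f"line {lineno}: non-integer numeric field") from exc
    if pos < 0:
        raise SamParseError(f"line {lineno}: negative POS")
    cigar = _parse_cigar(fields[5], lineno)
    tags = [_parse_tag(f, lineno) for f in fields[11:]]
    seen = set()
    for tag, _, _ in tags:
        if tag in seen:
            raise SamParseError(f"line {lineno}: duplicate tag {tag!r}")
        seen.add(tag)
    rec = AlignmentRecord(
        qname=fields[0],
        flag=flag,
        rname=fields[2],
        pos=pos,
        mapq=mapq,
        cigar=cigar,
        rnext=fields[6],
        pnext=pnext,
        tlen=tlen,
        seq=fields[9],
        qual=fields[10],
        tags=tags,
        file_index=file_index,
    )
    if rec.seq != "*" and rec.qual != "*" and len(rec.seq) != len(rec.qual):
        raise SamParseError(f"line {lineno}: SEQ and QUAL lengths differ")
    return rec


def parse_sam_records(
    stream: IO[str] | Iterable[str],
) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    """Parse a SAM stream lazily: header eagerly, records as a generator.

    This is the phase-1 entry point: callers can apply filters record by
    record while parsing, so the input is traversed exactly once.
    """
    it = iter(stream)
    header = SamHeader()
    first_alignment: str | None = None
    lineno = 0
    for line in it:
        lineno += 1
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            header.lines.append(line)
        else:
            first_alignment = line
            break
    header.validate()

    first_lineno = lineno

    def records() -> Iterator[AlignmentRecord]:
        n = lineno
        idx = 0
        if first_alignment is not None:
            yield parse_alignment_line(first_alignment, first_lineno, 0)
            idx = 1
        for raw in it:
            n += 1
            raw = raw.rstrip("\n")
            if not raw:
                continue
            if raw.startswith("@"):
                raise SamParseError(f"line {n}: header line after alignment lines")
            yield parse_alignment_line(raw, n, idx)
            idx += 1

    return header, records()


def parse_sam(stream: IO[str] | Iterable[str]) -> SamFile:
    header, records = parse_sam_records(stream)
    return SamFile(header, list(records))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_tag_value(typ: str, value: object) -> str:
    if typ == "f":
        # repr-minimal float text; canonical inputs round-trip byte-exactly
        text = repr(float(value))
        return text
    return str(value)


def format_record(rec: AlignmentRecord) -> str:
    cigar = "*" if not rec.cigar else "".join(f"{n}{op}" for n, op in rec.cigar)
    fields = [
        rec.qname,
        str(rec.flag),
        rec.rname,
        str(rec.pos),
        str(rec.mapq),
        cigar,
        rec.rnext,
        str(rec.pnext),
        str(rec.tlen),
        rec.seq,
        rec.qual,
    ]
    fields.extend(f"{t}:{y}:{_format_tag_value(y, v)}" for t, y, v in rec.tags)
    return "\t".join(fields)


def write_sam(sam: SamFile, stream: IO[str]) -> None:
    for line in sam.header.lines:
        stream.write(line)
        stream.write("\n")
    for rec in sam.alignments:
        stream.write(format_record(rec))
        stream.write("\n")
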