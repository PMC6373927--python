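"""Output-comparison recipe for byte-exact equivalence checks.

Two SAM files produced by different tools (or runs) can differ in ways
that carry no information: @PG provenance lines, PG record tags, the
order of optional fields within a record, and record order among
coordinate ties. Normalization removes exactly those differences: strip
@PG lines and PG tags, sort each record's optional fields by tag name,
then sort the alignment lines by (query name, full line). Two files are
equivalent iff their normalized forms are identical.
"""

from __future__ import annotations

from typing import IO, Optional

from .sam_model import format_record, parse_sam

__all__ = ["normalize_sam", "compare_sams"]


def normalize_sam(stream: IO[str]) -> list[str]:
    sam = parse_sam(stream)
    header_lines = sorted(l for l in sam.header.lines if not l.startswith("@PG"))
    record_lines = []
    for rec in sam.alignments:
        rec.tags = sorted(
            (t for t in rec.tags if t[0] != "PG"), key=lambda t: t[0]
        )
        record_lines.append(format_record(rec))
    record_lines.sort(key=lambda line: (line.split("\t", 1)[0], line))
    return header_lines + record_lines


def compare_sams(a: IO[str], b: IO[str]) -> tuple[bool, Optional[str]]:
    """Return (equal, first differing line description or None)."""
    la, lb = normalize_sam(a), normalize_sam(b)
    for i, (x, y) in enumerate(zip(la, lb)):
        if x != y:
            return False, f"line {i + 1}:\n< {x}\n> {y}"
    if len(la) != len(lb):
        longer = la if len(la) > len(lb) else lb
        which = "first" if len(la) > len(lb) else "second"
        return False, (
            f"line {min(len(la), len(lb)) + 1}: extra line in {which} file:\n"
            f"  {longer[min(len(la), len(lb))]}"
        )
    return True, None
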