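"""Whole-set sorting by coordinate or query name.

Both sorts are stable by construction: the explicit ``file_index`` key
breaks every tie, so repeated runs order identically regardless of the
underlying sort's stability.
"""

from __future__ import annotations

from .sam_model import AlignmentRecord, SamFile

__all__ = ["sort_coordinate", "sort_queryname", "coordinate_key", "queryname_key"]


def coordinate_key(rec: AlignmentRecord, sq_index: dict[str, int]):
    """(reference rank, pos, file_index); unmapped/'*' records rank last."""
    if rec.rname == "*" or rec.is_unmapped and rec.rname == "*":
        rank = len(sq_index)
    else:
        rank = sq_index.get(rec.rname)
        if rank is None:
            raise ValueError(f"record {rec.qname!r}: rname {rec.rname!r} not in @SQ header")
    return (rank, rec.pos, rec.file_index)


def queryname_key(rec: AlignmentRecord):
    return (rec.qname, rec.file_index)


def sort_coordinate(sam: SamFile) -> None:
    """Order by (@SQ rank, pos); rname '*' after all mapped; stable."""
    sq_index = {name: i for i, name in enumerate(sam.header.sq_names)}
    sam.alignments.sort(key=lambda r: coordinate_key(r, sq_index))
    sam.header.set_sort_order("coordinate")


def sort_queryname(sam: SamFile) -> None:
    """Group and order by qname (byte-lexicographic), stable."""
    sam.alignments.sort(key=queryname_key)
    sam.header.set_sort_order("queryname")
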