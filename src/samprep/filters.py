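"""Per-record filters pluggable into the parsing and writing phases.

A :class:`Filter` is a two-level closure, the shape the whole engine is
built around: the header stage runs once and may rewrite the header; it
returns the per-record function that decides keep (True) / remove (False)
and may mutate the record in place. Per-record functions must not depend on
neighbouring records — that contract is what lets the engine merge filters
into a single pass and apply them in any record order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .aux_formats import RegionSet
from .sam_model import AlignmentRecord, SamHeader

__all__ = [
    "Filter",
    "compose_filters",
    "filter_unmapped",
    "filter_regions",
    "filter_remove_duplicates",
]

RecordFn = Callable[[AlignmentRecord], bool]
HeaderStage = Callable[[SamHeader], Optional[RecordFn]]


@dataclass
class Filter:
    name: str
    header_stage: HeaderStage


def compose_filters(filters: list[Filter]) -> Filter:
    """Left-to-right composition; the record function short-circuits on
    the first removal (conjunction of keeps)."""

    def header_stage(header: SamHeader) -> Optional[RecordFn]:
        fns = [fn for f in filters if (fn := f.header_stage(header)) is not None]
        if not fns:
            return None

        def record_fn(rec: AlignmentRecord) -> bool:
            for fn in fns:
                if not fn(rec):
                    return False
            return True

        return record_fn

    return Filter(name="+".join(f.name for f in filters) or "identity", header_stage=header_stage)


def filter_unmapped() -> Filter:
    def header_stage(header: SamHeader) -> RecordFn:
        return lambda rec: not rec.is_unmapped

    return Filter("filter-unmapped", header_stage)


def filter_regions(regions: RegionSet) -> Filter:
    """Keep a mapped record iff its reference span (pos .. pos+reflen-1,
    clips excluded) overlaps a target interval of its contig; unmapped
    records and records on contigs absent from the set are removed.

    Mate rescue (keeping a read because its mate overlaps) is deliberately
    not performed.
    """

    def header_stage(header: SamHeader) -> RecordFn:
        def record_fn(rec: AlignmentRecord) -> bool:
            if rec.is_unmapped or rec.pos == 0:
                return False
            return regions.overlaps(rec.rname, rec.pos, rec.reference_end())

        return record_fn

    return Filter("filter-regions", header_stage)


def filter_remove_duplicates() -> Filter:
    def header_stage(header: SamHeader) -> RecordFn:
        return lambda rec: not rec.is_duplicate

    return Filter("remove-duplicates", header_stage)
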