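"""Split-filter-merge (sfm) execution mode.

The input is scattered into one chunk per contig group (default: one
contig per group) plus an overflow chunk, each chunk is run through the
same pipeline phases as the in-memory (filter) mode, and the processed
chunks are k-way merged into the final output. Outputs — SAM, metrics and
.recal — are byte-identical to filter mode in deterministic mode.

Routing rule: a mapped record goes to its own contig's chunk iff its mate
(when mapped) is in the same group; records of cross-group pairs and all
unmapped records go to the overflow chunk. Every record lands in exactly
one chunk, and every duplicate class is wholly contained in one chunk —
except that a fragment in a contig chunk may share a single-end key with a
cross-contig pair living in the overflow chunk. The overflow chunk is
therefore processed first and its pair end keys are injected into every
contig chunk's duplicate marking, preserving the pairs-beat-fragments rule
globally.

Per-chunk BQSR tables are integer-count tables; they are summed into one
global table before deltas are computed, so the .recal output equals the
filter-mode one exactly. Quality rewriting happens on the merge pass.

Original file order survives the round trip through chunk files via a
scratch tag (``zi:i:<file_index>``) that is stripped before the final
output, so deterministic tie-breaks behave exactly as in filter mode.
"""

from __future__ import annotations

import heapq
import os
import shutil
import tempfile
from dataclasses import dataclass
from typing import IO, Iterator, Optional

from .bqsr import (
    RecalTable,
    compute_deltas,
    levels_from_histogram,
    quality_histogram,
    recalibrate_record,
    serialize_recal_table,
    tabulate,
)
from .duplicates import (
    collect_duplication_metrics,
    mark_duplicates,
    mark_optical_duplicates,
)
from .engine import PG_ID, PipelineOptions, RunReport, build_plan
from .filters import filter_remove_duplicates
from .metrics_io import serialize_metrics
from .sam_model import (
    AlignmentRecord,
    SamFile,
    SamHeader,
    format_record,
    parse_sam_records,
)
from .sort_ops import sort_coordinate, sort_queryname
from . import __version__

__all__ = ["split_by_region", "merge_chunks", "run_sfm", "OVERFLOW_CHUNK"]

OVERFLOW_CHUNK = "overflow"
_INDEX_TAG = "zi"


def _chunk_record_line(rec: AlignmentRecord) -> str:
    """Serialize with the scratch file-index tag appended."""
    saved = rec.tags
    rec.tags = saved + [(_INDEX_TAG, "i", rec.file_index)]
    try:
        return format_record(rec)
    finally:
        rec.tags = saved


def _restore_index(rec: AlignmentRecord) -> AlignmentRecord:
    for i, (tag, _, value) in enumerate(rec.tags):
        if tag == _INDEX_TAG:
            rec.file_index = int(value)
            del rec.tags[i]
            return rec
    return rec


def contig_groups(header: SamHeader, contigs_per_group: int = 1) -> list[list[str]]:
    names = header.sq_names
    return [names[i : i + contigs_per_group] for i in range(0, len(names), contigs_per_group)]


@dataclass
class SplitResult:
    header: SamHeader
    chunk_paths: dict[str, str]  # group label -> path (includes overflow)
    group_labels: list[str]  # contig group labels in @SQ order
    records_total: int


def split_by_region(
    input_stream, workdir: str, contigs_per_group: int = 1
) -> SplitResult:
    """Scatter a SAM stream into per-contig-group chunk files plus an
    overflow chunk (cross-group pairs and unmapped records)."""
    header, records = parse_sam_records(input_stream)
    groups = contig_groups(header, contigs_per_group)
    group_of: dict[str, str] = {}
    labels: list[str] = []
    for grp in groups:
        label = grp[0]
        labels.append(label)
        for name in grp:
            group_of[name] = label

    paths: dict[str, str] = {}
    handles: dict[str, IO[str]] = {}

    def handle(label: str) -> IO[str]:
        fh = handles.get(label)
        if fh is None:
            path = os.path.join(workdir, f"chunk-{len(paths):04d}-{label}.sam")
            paths[label] = path
            handles[label] = fh = open(path, "w")
            for line in header.lines:
                fh.write(line)
                fh.write("\n")
        return fh

    total = 0
    try:
        for rec in records:
            total += 1
            if rec.is_unmapped or rec.rname == "*" or rec.rname not in group_of:
                label = OVERFLOW_CHUNK
            else:
                label = group_of[rec.rname]
                if rec.is_paired and not rec.mate_unmapped:
                    mate_rname = rec.rname if rec.rnext in ("=", "*") else rec.rnext
                    if group_of.get(mate_rname) != label:
                        label = OVERFLOW_CHUNK
            fh = handle(label)
            fh.write(_chunk_record_line(rec))
            fh.write("\n")
    finally:
        for fh in handles.values():
            fh.close()
    return SplitResult(header=header, chunk_paths=paths, group_labels=labels, records_total=total)


def _load_chunk(path: str) -> SamFile:
    with open(path) as fh:
        header, records = parse_sam_records(fh)
        alignments = [_restore_index(rec) for rec in records]
    return SamFile(header, alignments)


def _merge_key_fn(sorting_order: str, sq_index: dict[str, int]):
    n_sq = len(sq_index)
    if sorting_order == "coordinate":
        return lambda rec: (
            sq_index.get(rec.rname, n_sq) if rec.rname != "*" else n_sq,
            rec.pos,
            rec.file_index,
        )
    if sorting_order == "queryname":
        return lambda rec: (rec.qname, rec.file_index)
    return lambda rec: rec.file_index


def merge_chunks(
    chunk_paths: list[str],
    output_stream: IO[str],
    final_header: SamHeader,
    sorting_order: str,
    per_record=None,
) -> int:
    """K-way merge of processed chunk files into the final output.

    Chunks must already be ordered by the merge key. ``per_record`` is an
    optional callable(record) -> bool applied while writing (mutation plus
    keep/remove): the phase-3 hook of this mode.
    """
    sq_index = {name: i for i, name in enumerate(final_header.sq_names)}
    key_fn = _merge_key_fn(sorting_order, sq_index)

    for line in final_header.lines:
        output_stream.write(line)
        output_stream.write("\n")

    def chunk_iter(path: str) -> Iterator[tuple[tuple, AlignmentRecord]]:
        with open(path) as fh:
            chunk_header, records = parse_sam_records(fh)
            if chunk_header.sq_names != final_header.sq_names:
                raise ValueError(f"chunk {path}: @SQ list differs from output header")
            for rec in records:
                _restore_index(rec)
                yield key_fn(rec), rec

    written = 0
    for _, rec in heapq.merge(*(chunk_iter(p) for p in chunk_paths), key=lambda kv: kv[0]):
        if per_record is not None and not per_record(rec):
            continue
        output_stream.write(format_record(rec))
        output_stream.write("\n")
        written += 1
    return written


def run_sfm(
    options: PipelineOptions,
    input_path: str,
    output_path: str,
    workdir: Optional[str] = None,
    contigs_per_group: int = 1,
    metrics_stream: Optional[IO[str]] = None,
    recal_stream: Optional[IO[str]] = None,
) -> RunReport:
    """Execute a pipeline in split-filter-merge mode."""
    plan = build_plan(options)
    report = RunReport()
    tmpdir = tempfile.mkdtemp(prefix="samprep-sfm-", dir=workdir)
    try:
        with open(input_path) as fh:
            split = split_by_region(fh, tmpdir, contigs_per_group)
        report.records_read = split.records_total

        # final header: same rewrites, in the same order, as filter mode
        final_header = split.header.copy()
        if not options.no_pg:
            final_header.append_pg(PG_ID, PG_ID, __version__)
        if options.sorting_order != "keep":
            final_header.set_sort_order(options.sorting_order)

        # overflow first: its pair end keys feed the contig chunks
        order = [OVERFLOW_CHUNK] + [l for l in split.group_labels if l in split.chunk_paths]
        if OVERFLOW_CHUNK not in split.chunk_paths:
            order = order[1:]

        global_table: Optional[RecalTable] = None
        metrics_acc: dict = {}
        optical_acc: dict[str, int] = {}
        external_keys: set = set()
        processed: list[str] = []
        qual_hist = None

        for label in order:
            path = split.chunk_paths[label]
            chunk = _load_chunk(path)
            chunk.header = final_header.copy()

            # phase 1 filters
            fns = []
            for f in plan.phase1:
                fn = f.header_stage(chunk.header)
                if fn is not None:
                    fns.append((f.name, fn))
                    report.removed.setdefault(f.name, 0)
            kept = []
            for rec in chunk.alignments:
                keep = True
                for name, fn in fns:
                    if not fn(rec):
                        report.removed[name] += 1
                        keep = False
                        break
                if keep:
                    kept.append(rec)
            chunk.alignments = kept

            # phase 2
            if options.sorting_order == "coordinate":
                sort_coordinate(chunk)
            elif options.sorting_order == "queryname":
                sort_queryname(chunk)
            if options.mark_duplicates:
                result = mark_duplicates(
                    chunk,
                    deterministic=options.deterministic,
                    external_pair_end_keys=external_keys if label != OVERFLOW_CHUNK else None,
                )
                if label == OVERFLOW_CHUNK:
                    external_keys = result.pair_end_keys
                report.orphan_warnings += result.orphan_warnings
                if options.mark_optical_duplicates:
                    for lib, n in mark_optical_duplicates(
                        result.classes, max_distance=options.optical_pixel_distance
                    ).items():
                        optical_acc[lib] = optical_acc.get(lib, 0) + n
                for lib, m in collect_duplication_metrics(chunk).items():
                    if lib in metrics_acc:
                        metrics_acc[lib].add(m)
                    else:
                        metrics_acc[lib] = m
            if options.bqsr:
                table = tabulate(
                    chunk,
                    plan.reference,
                    plan.known,
                    context_length=options.context_length,
                    sigma=options.sigma,
                )
                if global_table is None:
                    global_table = table
                else:
                    global_table.merge(table)
                if options.quantization_levels:
                    h = quality_histogram(chunk)
                    qual_hist = h if qual_hist is None else qual_hist + h

            out_path = path + ".processed"
            with open(out_path, "w") as fh:
                for line in chunk.header.lines:
                    fh.write(line)
                    fh.write("\n")
                for rec in chunk.alignments:
                    fh.write(_chunk_record_line(rec))
                    fh.write("\n")
            processed.append(out_path)

        # reduce + merge pass
        levels = None
        if global_table is not None:
            compute_deltas(global_table)
            report.recal_table = global_table
            if options.quantization_levels and qual_hist is not None:
                levels = levels_from_histogram(qual_hist, options.quantization_levels)

        remove_fn = None
        if options.remove_duplicates:
            remove_fn = filter_remove_duplicates().header_stage(final_header)
            report.removed.setdefault("remove-duplicates", 0)

        def per_record(rec: AlignmentRecord) -> bool:
            if global_table is not None:
                recalibrate_record(rec, global_table, levels, options.preserve_below)
            if remove_fn is not None and not remove_fn(rec):
                report.removed["remove-duplicates"] += 1
                return False
            return True

        with open(output_path, "w") as out:
            report.records_written = merge_chunks(
                processed, out, final_header, options.sorting_order, per_record
            )

        if metrics_acc:
            from .duplicates import DuplicationMetrics

            for lib, n in optical_acc.items():
                if lib not in metrics_acc:
                    metrics_acc[lib] = DuplicationMetrics(lib)
                metrics_acc[lib].optical_duplicate_pairs += n
            report.metrics = metrics_acc
            report.optical_counts = optical_acc
            if metrics_stream is not None or options.mark_optical_duplicates:
                text = serialize_metrics(metrics_acc, final_header)
                if metrics_stream is not None:
                    metrics_stream.write(text)
                else:
                    with open(options.mark_optical_duplicates, "w") as fh:
                        fh.write(text)
        if report.recal_table is not None and (recal_stream or options.bqsr):
            text = serialize_recal_table(report.recal_table)
            if recal_stream is not None:
                recal_stream.write(text)
            else:
                with open(options.bqsr, "w") as fh:
                    fh.write(text)
    finally:
        shutil.rmtree(tmpdir, ignore_errors=True)
    return report
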