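"""Three-phase, single-pass execution core.

A pipeline run makes exactly one traversal of the input:

* **phase 1** — parse records from the stream, applying the parse-time
  filters (region filter, unmapped filter) record by record; survivors are
  collected into an in-memory :class:`SamFile`. Header rewrites (sort
  order, @PG provenance line) happen here.
* **phase 2** — whole-set operations over the collected records, in the
  canonical order sort -> duplicate marking (+ optical) -> BQSR
  tabulation. Tabulation runs after marking because it must see duplicate
  flags.
* **phase 3** — output-time work: BQSR application, the remove-duplicates
  filter, and metrics emission.

The plan built from a set of options is a pure function of that set — the
order in which options are supplied never changes the plan, and hence
never changes the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

from . import __version__
from .aux_formats import (
    KnownSites,
    ReferenceMap,
    RegionSet,
    load_reference,
    load_sites,
    read_bed,
)
from .bqsr import (
    RecalTable,
    apply_bqsr,
    compute_deltas,
    learn_quantization_levels,
    serialize_recal_table,
    tabulate,
)
from .duplicates import (
    DuplicationMetrics,
    MarkResult,
    collect_duplication_metrics,
    mark_duplicates,
    mark_optical_duplicates,
)
from .filters import (
    Filter,
    compose_filters,
    filter_regions,
    filter_remove_duplicates,
    filter_unmapped,
)
from .metrics_io import serialize_metrics
from .sam_model import SamFile, format_record, parse_sam_records
from .sort_ops import sort_coordinate, sort_queryname

__all__ = [
    "PipelineOptions",
    "PipelinePlan",
    "ConfigurationError",
    "RunReport",
    "build_plan",
    "run_pipeline",
    "run_filter_file",
    "compose_filters",
]

PG_ID = "samprep"


class ConfigurationError(ValueError):
    """Invalid option combination."""


@dataclass(frozen=True)
class PipelineOptions:
    """The full option surface of a pipeline invocation.

    Paths may be None when the corresponding step is off. ``sorting_order``
    is one of keep/coordinate/queryname.
    """

    mark_duplicates: bool = False
    mark_optical_duplicates: Optional[str] = None  # metrics output path
    optical_pixel_distance: int = 100
    sorting_order: str = "keep"
    bqsr: Optional[str] = None  # .recal output path
    known_sites: Optional[str] = None
    bqsr_reference: Optional[str] = None
    filter_unmapped_reads: bool = False
    target_regions: Optional[str] = None
    remove_duplicates: bool = False
    deterministic: bool = False
    no_pg: bool = False
    preserve_below: int = 6
    context_length: int = 2
    sigma: float = 0.5
    quantization_levels: Optional[int] = None
    known_sites_full_span: bool = True


@dataclass
class PipelinePlan:
    options: PipelineOptions
    phase1: list[Filter] = field(default_factory=list)
    phase2: list[str] = field(default_factory=list)  # canonical stage names
    phase3: list[str] = field(default_factory=list)
    regions: Optional[RegionSet] = None
    reference: Optional[ReferenceMap] = None
    known: Optional[KnownSites] = None

    @property
    def stages(self) -> tuple[tuple[str, ...], ...]:
        return (
            tuple(f.name for f in self.phase1),
            tuple(self.phase2),
            tuple(self.phase3),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PipelinePlan):
            return NotImplemented
        return self.options == other.options and self.stages == other.stages


def build_plan(
    options: PipelineOptions,
    regions: Optional[RegionSet] = None,
    reference: Optional[ReferenceMap] = None,
    known: Optional[KnownSites] = None,
) -> PipelinePlan:
    """Validate options and lay out the canonical stage order.

    Resource objects may be injected directly (tests, in-process callers);
    otherwise they are loaded from the paths in ``options``.
    """
    if options.sorting_order not in ("keep", "coordinate", "queryname"):
        raise ConfigurationError(f"unknown sorting order {options.sorting_order!r}")
    if options.mark_optical_duplicates and not options.mark_duplicates:
        raise ConfigurationError(
            "--mark-optical-duplicates requires --mark-duplicates"
        )
    if options.bqsr:
        if not options.bqsr_reference:
            raise ConfigurationError("--bqsr requires --bqsr-reference")
        if not options.known_sites:
            raise ConfigurationError("--bqsr requires --known-sites")

    plan = PipelinePlan(options=options)

    if options.target_regions:
        if regions is None:
            with open(options.target_regions) as fh:
                regions = read_bed(fh)
        plan.regions = regions
        plan.phase1.append(filter_regions(regions))
    if options.filter_unmapped_reads:
        plan.phase1.append(filter_unmapped())

    if options.sorting_order != "keep":
        plan.phase2.append(f"sort:{options.sorting_order}")
    if options.mark_duplicates:
        plan.phase2.append("mark-duplicates")
        if options.mark_optical_duplicates:
            plan.phase2.append("mark-optical-duplicates")
    if options.bqsr:
        if reference is None:
            reference = load_reference(options.bqsr_reference)
        if known is None:
            known = load_sites(options.known_sites, full_span=options.known_sites_full_span)
        plan.reference = reference
        plan.known = known
        plan.phase2.append("bqsr-tabulate")
        plan.phase3.append("bqsr-apply")
    if options.remove_duplicates:
        plan.phase3.append("remove-duplicates")
    if options.mark_optical_duplicates:
        plan.phase3.append("write-metrics")
    return plan


@dataclass
class RunReport:
    records_read: int = 0
    records_written: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    orphan_warnings: int = 0
    metrics: Optional[dict[str, DuplicationMetrics]] = None
    recal_table: Optional[RecalTable] = None
    mark_result: Optional[MarkResult] = None
    optical_counts: Optional[dict[str, int]] = None


def _read_phase1(
    plan: PipelinePlan, input_stream: IO[str] | Iterable[str], report: RunReport
) -> SamFile:
    header, records = parse_sam_records(input_stream)
    if not plan.options.no_pg:
        header.append_pg(PG_ID, PG_ID, __version__)
    if plan.options.sorting_order == "keep" and header.sort_order == "unknown":
        pass  # leave the header's @HD untouched
    filter_fns = []
    for f in plan.phase1:
        fn = f.header_stage(header)
        if fn is not None:
            filter_fns.append((f.name, fn))
            report.removed.setdefault(f.name, 0)
    kept = []
    for rec in records:
        report.records_read += 1
        keep = True
        for name, fn in filter_fns:
            if not fn(rec):
                report.removed[name] += 1
                keep = False
                break
        if keep:
            kept.append(rec)
    return SamFile(header, kept)


def _run_phase2(plan: PipelinePlan, sam: SamFile, report: RunReport) -> None:
    opts = plan.options
    for stage in plan.phase2:
        if stage == "sort:coordinate":
            sort_coordinate(sam)
        elif stage == "sort:queryname":
            sort_queryname(sam)
        elif stage == "mark-duplicates":
            result = mark_duplicates(sam, deterministic=opts.deterministic)
            report.mark_result = result
            report.orphan_warnings = result.orphan_warnings
        elif stage == "mark-optical-duplicates":
            report.optical_counts = mark_optical_duplicates(
                report.mark_result.classes, max_distance=opts.optical_pixel_distance
            )
        elif stage == "bqsr-tabulate":
            table = tabulate(
                sam,
                plan.reference,
                plan.known,
                context_length=opts.context_length,
                sigma=opts.sigma,
            )
            compute_deltas(table)
            report.recal_table = table
    if report.mark_result is not None:
        report.metrics = collect_duplication_metrics(sam, report.optical_counts)


def _write_phase3(
    plan: PipelinePlan,
    sam: SamFile,
    output_stream: IO[str],
    report: RunReport,
) -> None:
    opts = plan.options
    if "bqsr-apply" in plan.phase3 and report.recal_table is not None:
        levels = None
        if opts.quantization_levels:
            levels = learn_quantization_levels(sam, opts.quantization_levels)
        apply_bqsr(
            sam,
            report.recal_table,
            quantization_levels=levels,
            preserve_below=opts.preserve_below,
        )
    filter_fns = []
    if "remove-duplicates" in plan.phase3:
        f = filter_remove_duplicates()
        fn = f.header_stage(sam.header)
        filter_fns.append((f.name, fn))
        report.removed.setdefault(f.name, 0)
    for line in sam.header.lines:
        output_stream.write(line)
        output_stream.write("\n")
    for rec in sam.alignments:
        keep = True
        for name, fn in filter_fns:
            if not fn(rec):
                report.removed[name] += 1
                keep = False
                break
        if keep:
            output_stream.write(format_record(rec))
            output_stream.write("\n")
            report.records_written += 1


def run_pipeline(
    plan: PipelinePlan,
    input_stream: IO[str] | Iterable[str],
    output_stream: IO[str],
    metrics_stream: Optional[IO[str]] = None,
    recal_stream: Optional[IO[str]] = None,
) -> RunReport:
    """Execute a plan in filter (whole-file in-memory) mode.

    Side outputs (metrics, .recal) go to the given streams, or to the
    paths named in the options when streams are not supplied.
    """
    report = RunReport()
    sam = _read_phase1(plan, input_stream, report)
    _run_phase2(plan, sam, report)
    _write_phase3(plan, sam, output_stream, report)

    opts = plan.options
    if report.metrics is not None and (metrics_stream or opts.mark_optical_duplicates):
        text = serialize_metrics(report.metrics, sam.header)
        if metrics_stream is not None:
            metrics_stream.write(text)
        else:
            with open(opts.mark_optical_duplicates, "w") as fh:
                fh.write(text)
    if report.recal_table is not None and (recal_stream or opts.bqsr):
        text = serialize_recal_table(report.recal_table)
        if recal_stream is not None:
            recal_stream.write(text)
        else:
            with open(opts.bqsr, "w") as fh:
                fh.write(text)
    return report


def run_filter_file(
    options: PipelineOptions, input_path: str, output_path: str
) -> RunReport:
    """Convenience wrapper: build a plan and run it on file paths."""
    plan = build_plan(options)
    with open(input_path) as inp, open(output_path, "w") as out:
        return run_pipeline(plan, inp, out)
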