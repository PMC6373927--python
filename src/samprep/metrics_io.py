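"""Picard-style duplication metrics report (MultiQC-readable).

One "## METRICS CLASS" section, a tab-separated header row with the fixed
field order below, and one row per library. PERCENT_DUPLICATION is printed
with 6 decimals; ESTIMATED_LIBRARY_SIZE is blank when undefined.
"""

from __future__ import annotations

from typing import IO

from .duplicates import DuplicationMetrics
from .sam_model import SamHeader

__all__ = ["write_metrics", "serialize_metrics", "METRICS_FIELDS"]

METRICS_FIELDS = [
    "LIBRARY",
    "UNPAIRED_READS_EXAMINED",
    "READ_PAIRS_EXAMINED",
    "SECONDARY_OR_SUPPLEMENTARY_RDS",
    "UNMAPPED_READS",
    "UNPAIRED_READ_DUPLICATES",
    "READ_PAIR_DUPLICATES",
    "READ_PAIR_OPTICAL_DUPLICATES",
    "PERCENT_DUPLICATION",
    "ESTIMATED_LIBRARY_SIZE",
]


def _library_order(metrics: dict[str, DuplicationMetrics], header: SamHeader) -> list[str]:
    """Libraries in order of first appearance in the @RG header lines;
    libraries seen only in records (e.g. "Unknown Library") follow, sorted."""
    ordered: list[str] = []
    for lib in header.rg_library.values():
        if lib in metrics and lib not in ordered:
            ordered.append(lib)
    for lib in sorted(metrics):
        if lib not in ordered:
            ordered.append(lib)
    return ordered


def serialize_metrics(metrics: dict[str, DuplicationMetrics], header: SamHeader) -> str:
    lines = [
        "## samprep.metrics",
        "# samprep mark-duplicates",
        "",
        "## METRICS CLASS\tsamprep.DuplicationMetrics",
        "\t".join(METRICS_FIELDS),
    ]
    for lib in _library_order(metrics, header):
        m = metrics[lib]
        m.finalize()
        size = "" if m.estimated_library_size is None else str(int(m.estimated_library_size))
        lines.append(
            "\t".join(
                [
                    m.library,
                    str(m.unpaired_reads_examined),
                    str(m.read_pairs_examined),
                    str(m.secondary_or_supplementary),
                    str(m.unmapped_reads),
                    str(m.unpaired_duplicates),
                    str(m.read_pair_duplicates),
                    str(m.optical_duplicate_pairs),
                    f"{m.percent_duplication:.6f}",
                    size,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_metrics(metrics: dict[str, DuplicationMetrics], header: SamHeader, stream: IO[str]) -> None:
    stream.write(serialize_metrics(metrics, header))
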