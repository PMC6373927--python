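"""Base quality score recalibration (BQSR): tabulation and application.

Sequencers misreport per-base quality. BQSR tabulates, per covariate bin,
how often aligned bases mismatch the reference at positions *not* known to
be polymorphic, converts the observed error rates to empirical Phred
qualities, and rewrites base qualities by a hierarchy of deltas:

    Q_new = round(Q_reported + dQ_global + dQ_reported + dQ_cycle + dQ_context)

The covariate set is the GATK-4 standard one: read group; reported
quality; machine cycle (1-based in sequencing order, negated for the
second read of a pair); and the k preceding bases in sequencing
orientation (k = 2 by default). Reverse-strand reads are mapped back to
sequencing orientation (reverse complement) before cycle/context are read
off.

Empirical quality per bin is the integer argmax over Q in [0, 93] of a
Gaussian log-prior centred on the parent bin's estimate (width sigma, 0.5
by default on the Phred scale) plus the binomial log-likelihood of the
observed (errors, observations) at error rate 10^(-Q/10).

A base enters the table only when it has a full-length ACGT context (and
an unambiguous base and reference base), so every tabulated base counts at
every level of the table and parent counts equal the sum of their
children's exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Optional

import numpy as np
from scipy.stats import binom

from .aux_formats import KnownSites, ReferenceMap
from .sam_model import AlignmentRecord, SamFile

__all__ = [
    "RecalTable",
    "tabulate",
    "empirical_quality",
    "compute_deltas",
    "apply_bqsr",
    "write_recal_table",
    "read_recal_table",
    "learn_quantization_levels",
]

MAX_QUALITY = 93
DEFAULT_SIGMA = 0.5
DEFAULT_CONTEXT_LENGTH = 2
DEFAULT_PRESERVE_BELOW = 6
NO_READ_GROUP = "NA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACGT = frozenset("ACGT")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class RecalTable:
    """Hierarchical (observations, errors) counts per covariate bin.

    Levels: read group -> reported quality -> {cycle, context}. Counts are
    integers (including the reported-quality weight sum), so tables from
    split chunks merge exactly and tabulation order never matters.
    """

    context_length: int = DEFAULT_CONTEXT_LENGTH
    sigma: float = DEFAULT_SIGMA
    # read group -> [observations, errors, sum of reported Q over observations]
    rg: dict[str, list[int]] = field(default_factory=dict)
    # (read group, q) -> [observations, errors]
    qual: dict[tuple[str, int], list[int]] = field(default_factory=dict)
    # (read group, q, covariate name, covariate value) -> [observations, errors]
    cov: dict[tuple[str, int, str, str], list[int]] = field(default_factory=dict)

    # filled by compute_deltas
    est_reported: dict[str, float] = field(default_factory=dict)
    emp_rg: dict[str, int] = field(default_factory=dict)
    delta_global: dict[str, float] = field(default_factory=dict)
    emp_qual: dict[tuple[str, int], int] = field(default_factory=dict)
    delta_reported: dict[tuple[str, int], float] = field(default_factory=dict)
    emp_cov: dict[tuple[str, int, str, str], int] = field(default_factory=dict)
    delta_cov: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    _deltas_ready: bool = False

    # -- accumulation ---------------------------------------------------
    def record_base(self, rg: str, q: int, cycle: int, context: str, error: bool) -> None:
        e = 1 if error else 0
        bin0 = self.rg.get(rg)
        if bin0 is None:
            self.rg[rg] = bin0 = [0, 0, 0]
        bin0[0] += 1
        bin0[1] += e
        bin0[2] += q
        k1 = (rg, q)
        bin1 = self.qual.get(k1)
        if bin1 is None:
            self.qual[k1] = bin1 = [0, 0]
        bin1[0] += 1
        bin1[1] += e
        for name, value in (("Cycle", str(cycle)), ("Context", context)):
            k2 = (rg, q, name, value)
            bin2 = self.cov.get(k2)
            if bin2 is None:
                self.cov[k2] = bin2 = [0, 0]
            bin2[0] += 1
            bin2[1] += e

    def merge(self, other: "RecalTable") -> None:
        """Sum another table's counts into this one (chunked tabulation)."""
        if other.context_length != self.context_length:
            raise ValueError("context lengths differ; tables are incompatible")
        for rg, (o, e, sq) in other.rg.items():
            bin0 = self.rg.setdefault(rg, [0, 0, 0])
            bin0[0] += o
            bin0[1] += e
            bin0[2] += sq
        for key, (o, e) in other.qual.items():
            bin1 = self.qual.setdefault(key, [0, 0])
            bin1[0] += o
            bin1[1] += e
        for key, (o, e) in other.cov.items():
            bin2 = self.cov.setdefault(key, [0, 0])
            bin2[0] += o
            bin2[1] += e
        self._deltas_ready = False

    def total_observations(self) -> int:
        return sum(v[0] for v in self.rg.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecalTable):
            return NotImplemented
        return serialize_recal_table(self) == serialize_recal_table(other)


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def _is_excluded(rec: AlignmentRecord) -> bool:
    return (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
        or rec.mapq == 0
        or rec.pos == 0
    )


def covariates_for_read(
    rec: AlignmentRecord, context_length: int
) -> list[tuple[int, str | None]]:
    """Per stored base: (signed cycle, context or None when incomplete).

    Cycle is the 1-based position in sequencing order (reverse-strand reads
    are numbered from the stored 3' end), negated for second-of-pair reads.
    Context is the ``context_length`` preceding bases in sequencing
    orientation, or None when truncated or containing non-ACGT letters.
    """
    seq = rec.seq
    n = len(seq)
    k = context_length
    out: list[tuple[int, str | None]] = []
    if rec.is_reverse:
        rc = _revcomp(seq)  # sequencing orientation
        for i in range(n):
            j = n - 1 - i  # position in sequencing orientation
            cycle = j + 1
            ctx = rc[j - k : j] if j >= k else None
            if ctx is not None and (len(ctx) != k or not _ACGT.issuperset(ctx)):
                ctx = None
            out.append((-cycle if rec.is_second_of_pair else cycle, ctx))
    else:
        for i in range(n):
            cycle = i + 1
            ctx = seq[i - k : i] if i >= k else None
            if ctx is not None and (len(ctx) != k or not _ACGT.issuperset(ctx)):
                ctx = None
            out.append((-cycle if rec.is_second_of_pair else cycle, ctx))
    return out


def tabulate(
    sam: SamFile,
    reference: ReferenceMap,
    known: KnownSites,
    context_length: int = DEFAULT_CONTEXT_LENGTH,
    sigma: float = DEFAULT_SIGMA,
    skip_missing_qual: bool = True,
) -> RecalTable:
    """Tally (observations, errors) per covariate bin over aligned bases.

    Duplicate-flagged, secondary, supplementary, unmapped and mapq-0
    records are skipped; so are bases at known polymorphic positions,
    ambiguous bases, and bases without a full ACGT context. Only CIGAR
    M/=/X bases are observed.
    """
    table = RecalTable(context_length=context_length, sigma=sigma)
    for rec in sam.alignments:
        if _is_excluded(rec):
            continue
        if rec.qual == "*" or rec.seq == "*":
            if skip_missing_qual:
                continue
            raise ValueError(f"record {rec.qname!r} lacks base qualities")
        if rec.rname not in reference:
            raise ValueError(f"contig {rec.rname!r} missing from reference")
        ref_seq = reference[rec.rname]
        rg = rec.get_tag("RG") or NO_READ_GROUP
        covs = covariates_for_read(rec, context_length)
        seq, qual = rec.seq, rec.qual
        read_i = 0
        ref_pos = rec.pos  # 1-based
        for length, op in rec.cigar:
            if op in ("M", "=", "X"):
                for off in range(length):
                    i = read_i + off
                    p = ref_pos + off
                    base = seq[i]
                    if p > len(ref_seq):
                        continue
                    ref_base = ref_seq[p - 1]
                    if base not in _ACGT or ref_base not in _ACGT:
                        continue
                    if known.is_masked(rec.rname, p):
                        continue
                    cycle, ctx = covs[i]
                    if ctx is None:
                        continue
                    table.record_base(rg, ord(qual[i]) - 33, cycle, ctx, base != ref_base)
                read_i += length
                ref_pos += length
            elif op in ("I", "S"):
                read_i += length
            elif op in ("D", "N"):
                ref_pos += length
            # H and P consume nothing
    return table


# ---------------------------------------------------------------------------
# empirical quality and deltas
# ---------------------------------------------------------------------------

_Q_GRID = np.arange(MAX_QUALITY + 1)
_P_GRID = np.power(10.0, -_Q_GRID / 10.0)


def empirical_quality(
    observations: int, errors: int, prior_center: float, sigma: float = DEFAULT_SIGMA
) -> int:
    """Integer argmax over Q in [0, 93] of Gaussian log-prior (centre
    ``prior_center``, width ``sigma``) plus binomial log-likelihood of
    ``errors`` out of ``observations`` at rate 10^(-Q/10).

    With zero observations the prior wins: returns round(prior_center).
    """
    if observations == 0:
        return int(round(prior_center))
    log_prior = -0.5 * ((_Q_GRID - prior_center) / sigma) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = binom.logpmf(errors, observations, _P_GRID)
    log_lik = np.where(np.isnan(log_lik), -np.inf, log_lik)
    return int(np.argmax(log_prior + log_lik))


def compute_deltas(table: RecalTable) -> RecalTable:
    """Fill the empirical qualities and hierarchical quality deltas.

    dQ_global       = Qemp(read group)    - weighted mean reported Q
    dQ_reported(q)  = Qemp(q bin)         - q - dQ_global
    dQ_cycle/ctx    = Qemp(sub bin)       - q - dQ_global - dQ_reported(q)

    Each bin's empirical quality uses its parent's estimate as the prior
    centre.
    """
    sigma = table.sigma
    table.est_reported.clear()
    table.emp_rg.clear()
    table.delta_global.clear()
    table.emp_qual.clear()
    table.delta_reported.clear()
    table.emp_cov.clear()
    table.delta_cov.clear()
    for rg, (obs, err, sum_q) in table.rg.items():
        est = sum_q / obs if obs else 0.0
        q_emp = empirical_quality(obs, err, est, sigma)
        table.est_reported[rg] = est
        table.emp_rg[rg] = q_emp
        table.delta_global[rg] = q_emp - est
    for (rg, q), (obs, err) in table.qual.items():
        prior = q + table.delta_global[rg]
        q_emp = empirical_quality(obs, err, prior, sigma)
        table.emp_qual[(rg, q)] = q_emp
        table.delta_reported[(rg, q)] = q_emp - prior
    for (rg, q, name, value), (obs, err) in table.cov.items():
        prior = q + table.delta_global[rg] + table.delta_reported[(rg, q)]
        q_emp = empirical_quality(obs, err, prior, sigma)
        table.emp_cov[(rg, q, name, value)] = q_emp
        table.delta_cov[(rg, q, name, value)] = q_emp - prior
    table._deltas_ready = True
    return table


def _ensure_deltas(table: RecalTable) -> None:
    if not table._deltas_ready:
        compute_deltas(table)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def recalibrate_record(
    rec: AlignmentRecord,
    table: RecalTable,
    quantization_levels: Optional[list[int]] = None,
    preserve_below: int = DEFAULT_PRESERVE_BELOW,
) -> None:
    """Rewrite one record's QUAL string in place (see :func:`apply_bqsr`)."""
    if rec.qual == "*" or rec.seq == "*":
        return
    k = table.context_length
    covs = covariates_for_read(rec, k)
    qual = rec.qual
    out = []
    rg = rec.get_tag("RG") or NO_READ_GROUP
    d_global = table.delta_global.get(rg)
    for i, ch in enumerate(qual):
        q = ord(ch) - 33
        if q < preserve_below or d_global is None:
            out.append(ch)
            continue
        total = d_global
        key1 = (rg, q)
        if key1 in table.delta_reported:
            total += table.delta_reported[key1]
            cycle, ctx = covs[i]
            c_key = (rg, q, "Cycle", str(cycle))
            if c_key in table.delta_cov:
                total += table.delta_cov[c_key]
            if ctx is not None:
                x_key = (rg, q, "Context", ctx)
                if x_key in table.delta_cov:
                    total += table.delta_cov[x_key]
        new_q = math.floor(q + total + 0.5)
        new_q = max(1, min(MAX_QUALITY, new_q))
        if quantization_levels:
            new_q = min(quantization_levels, key=lambda lvl: (abs(lvl - new_q), lvl))
        out.append(chr(new_q + 33))
    rec.qual = "".join(out)


def apply_bqsr(
    sam: SamFile,
    table: RecalTable,
    quantization_levels: Optional[list[int]] = None,
    preserve_below: int = DEFAULT_PRESERVE_BELOW,
) -> None:
    """Rewrite base qualities in place on *all* records (skipping rules
    apply to tabulation only). Only the QUAL field changes. Bases below
    ``preserve_below`` pass through unchanged. Missing covariate bins fall
    back to the deepest available ancestor's deltas.
    """
    _ensure_deltas(table)
    for rec in sam.alignments:
        recalibrate_record(rec, table, quantization_levels, preserve_below)


def quality_histogram(sam: SamFile) -> np.ndarray:
    """Counts of reported base qualities 0..93 over all records."""
    hist = np.zeros(MAX_QUALITY + 1, dtype=np.int64)
    for rec in sam.alignments:
        if rec.qual == "*":
            continue
        for ch in rec.qual:
            hist[ord(ch) - 33] += 1
    return hist


def learn_quantization_levels(sam: SamFile, n_levels: int, max_iter: int = 30) -> list[int]:
    """1-D k-means on the observed quality histogram; deterministic
    quantile initialisation. Returns sorted integer levels."""
    return levels_from_histogram(quality_histogram(sam), n_levels, max_iter)


def levels_from_histogram(hist: np.ndarray, n_levels: int, max_iter: int = 30) -> list[int]:
    present = np.nonzero(hist)[0]
    if len(present) <= n_levels:
        return [int(q) for q in present]
    total = hist.sum()
    cdf = np.cumsum(hist) / total
    centers = np.array(
        [present[np.searchsorted(cdf[present], (i + 0.5) / n_levels)] for i in range(n_levels)],
        dtype=float,
    )
    centers = np.unique(centers)
    qs = np.arange(MAX_QUALITY + 1, dtype=float)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(qs[:, None] - centers[None, :]), axis=1)
        new_centers = centers.copy()
        for j in range(len(centers)):
            w = hist[assign == j]
            if w.sum():
                new_centers[j] = np.average(qs[assign == j], weights=w)
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    return sorted({int(round(c)) for c in centers})


# ---------------------------------------------------------------------------
# .recal report (this tool's stable text dialect)
# ---------------------------------------------------------------------------

_HEADER = "#:samprep.recal:v1"


def serialize_recal_table(table: RecalTable) -> str:
    _ensure_deltas(table)
    lines = [_HEADER]
    lines.append("#:Parameters")
    lines.append("ContextLength\tSigma")
    lines.append(f"{table.context_length}\t{table.sigma:.4f}")
    lines.append("#:ReadGroupTable")
    lines.append(
        "ReadGroup\tEstimatedQReported\tEmpiricalQuality\tDeltaQGlobal\tObservations\tErrors"
    )
    for rg in sorted(table.rg):
        obs, err, _ = table.rg[rg]
        lines.append(
            f"{rg}\t{table.est_reported[rg]:.4f}\t{table.emp_rg[rg]}\t"
            f"{table.delta_global[rg]:.4f}\t{obs}\t{err}"
        )
    lines.append("#:QualityScoreTable")
    lines.append(
        "ReadGroup\tQualityScore\tEmpiricalQuality\tDeltaQReported\tObservations\tErrors"
    )
    for rg, q in sorted(table.qual):
        obs, err = table.qual[(rg, q)]
        lines.append(
            f"{rg}\t{q}\t{table.emp_qual[(rg, q)]}\t"
            f"{table.delta_reported[(rg, q)]:.4f}\t{obs}\t{err}"
        )
    lines.append("#:CovariateTable")
    lines.append(
        "ReadGroup\tQualityScore\tCovariateName\tCovariateValue\t"
        "EmpiricalQuality\tDeltaQ\tObservations\tErrors"
    )
    for key in sorted(table.cov):
        rg, q, name, value = key
        obs, err = table.cov[key]
        lines.append(
            f"{rg}\t{q}\t{name}\t{value}\t{table.emp_cov[key]}\t"
            f"{table.delta_cov[key]:.4f}\t{obs}\t{err}"
        )
    return "\n".join(lines) + "\n"


def write_recal_table(table: RecalTable, stream: IO[str]) -> None:
    stream.write(serialize_recal_table(table))


def read_recal_table(stream: IO[str]) -> RecalTable:
    lines = [l.rstrip("\n") for l in stream]
    if not lines or lines[0] != _HEADER:
        raise ValueError("not a samprep .recal report")
    table = RecalTable()
    section = None
    header_pending = False
    for line in lines[1:]:
        if line.startswith("#:"):
            section = line[2:]
            header_pending = True
            continue
        if header_pending:  # the column-header row of the section
            header_pending = False
            continue
        if section == "Parameters":
            ctx_s, sigma_s = line.split("\t")
            table.context_length = int(ctx_s)
            table.sigma = float(sigma_s)
        elif section == "ReadGroupTable":
            rg, est, emp, dq, obs, err = line.split("\t")
            o, e = int(obs), int(err)
            est_f = float(est)
            table.rg[rg] = [o, e, int(round(est_f * o))]
            table.est_reported[rg] = est_f
            table.emp_rg[rg] = int(emp)
            table.delta_global[rg] = float(dq)
        elif section == "QualityScoreTable":
            rg, q_s, emp, dq, obs, err = line.split("\t")
            key = (rg, int(q_s))
            table.qual[key] = [int(obs), int(err)]
            table.emp_qual[key] = int(emp)
            table.delta_reported[key] = float(dq)
        elif section == "CovariateTable":
            rg, q_s, name, value, emp, dq, obs, err = line.split("\t")
            key = (rg, int(q_s), name, value)
            table.cov[key] = [int(obs), int(err)]
            table.emp_cov[key] = int(emp)
            table.delta_cov[key] = float(dq)
        else:
            raise ValueError(f"malformed .recal section content: {line!r}")
    table._deltas_ready = True
    return table
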