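# Methods

This note documents the models and procedures implemented in `samprep`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter for
reproducing outputs byte for byte.

## Pipeline model

A pipeline is executed in three phases over exactly one traversal of the
input SAM stream:

1. **Parse + filter.** Records are parsed one at a time; parse-time
   filters (target-region filter, unmapped filter) decide keep/remove per
   record. Filters are two-level closures: a header stage (run once, may
   rewrite the header) returning the per-record function. Per-record
   functions must not depend on neighbouring records; that contract is
   what allows fusing all requested steps into one pass and applying them
   in any record order. Survivors are collected into an in-memory file.
2. **Whole-set operations**, in a fixed canonical order: sort →
   duplicate marking (→ optical clustering) → BQSR tabulation. Tabulation
   runs after marking because duplicate-flagged reads must be excluded
   from recalibration statistics. The order is derived from the option
   set only — permuting command-line flags cannot change it.
3. **Filter + write.** BQSR application (a pure per-record transform),
   the remove-duplicates filter, and metrics emission happen while
   writing.

A `@PG` line (ID/PN/VN, deliberately no command line) is appended to the
header unless `--no-pg`; omitting the CL field keeps the two execution
modes byte-identical and keeps reruns diff-able.

## Duplicate marking

Key: library (RG tag → @RG LB; otherwise "Unknown Library"), reference
name, *unclipped* 5' position, strand. The unclipped position undoes
soft/hard clipping: forward reads subtract leading clip lengths from POS;
reverse reads add trailing clips to the alignment end (POS +
reference-consumed length − 1). Pair keys use both ends sorted by
(contig, position, strand), making them invariant under swapping which
mate is "first"; fragments (unpaired reads, mate-unmapped reads, and
paired reads whose mate is absent — counted as warnings) use their single
end.

Survivor selection: highest sum of base qualities ≥ 15 (pair score = sum
of both mates), the Picard scoring rule. A fragment whose key equals any
pair end key is marked regardless of score (pairs beat fragments). In
deterministic mode ties break by smallest original record index
(`file_index`); otherwise any tied member may survive but the class-level
invariants (exactly one survivor, only bit 0x400 changes) still hold.
Secondary, supplementary and unmapped records are never examined and
never survive on behalf of a class; their pre-existing flags are left
untouched.

Optical clustering runs within each pair-duplicate class: members are
linked when they share read group and tile and their pixel offsets are
within the threshold on **each axis** (rectangle comparison, the Picard
convention; Euclidean is available as an option), with the default
threshold of 100 px. Clusters are the transitive closure of links. In a
cluster containing the class survivor all other members count as optical;
in survivor-free clusters all but one count. Locations are parsed from
read names with ≥ 5 colon-separated fields whose last three are integers
(tile, x, y).

Library size solves `U = X·(1 − exp(−N/X))` (Lander–Waterman) with
`N` = pairs examined − optical pairs and `U` = pairs examined − duplicate
pairs, by bracketed root finding (`scipy.optimize.brentq`, relative
tolerance 1e−12; the left side is strictly increasing in `X` with range
(0, N), so the root is unique). Undefined when `U == N` (no duplication)
or `U == 0`; the metrics column is left blank.

## BQSR

Covariates: read group, reported quality, signed cycle, 2-base context.
Cycle is the 1-based position in **sequencing order** — reverse-strand
records are numbered from the stored 3' end — and negated for
second-of-pair reads. Context is the `k = 2` preceding bases in
sequencing orientation (reverse-complemented for reverse-strand records).
`k` and the Gaussian prior width are configurable.

A base enters the table only if: the record is not duplicate-flagged,
secondary, supplementary, unmapped or MAPQ 0; the base is aligned (CIGAR
M/=/X); neither base nor reference base is ambiguous; the reference
position is not masked by a known site; and the base has a full-length
ACGT context. The last rule is a deliberate design choice: a base either
contributes to *every* level of the table or to none, which makes the
hierarchy exactly conservative (parent observations/errors equal the sum
over either covariate family of children). The alternative — counting
short-context bases at upper levels only — would break that invariant.

Known-site masking spans the full REF length of each VCF record by
default (a deletion allele masks its whole span; multi-allelic sites mask
the longest REF), with a POS-only switch, since the authoritative
behaviour is not documented; full-span is the conservative choice for
excluding true variation from error counts.

Empirical quality of a bin with `n` observations and `k` errors, prior
centre `c` (the parent's estimate: the observation-weighted mean reported
quality for read-group bins; `q + ΔQ_global` for quality bins;
`q + ΔQ_global + ΔQ_reported` for cycle/context bins):

```
Qemp = argmax_{Q ∈ 0..93} [ −(Q − c)² / (2σ²) + log Binom(k | n, 10^(−Q/10)) ]
```

with σ = 0.5 on the Phred scale. Deltas follow the hierarchy:
`ΔQ_global = Qemp(rg) − mean reported`, `ΔQ_reported = Qemp(q) − q −
ΔQ_global`, and `ΔQ_cycle/context = Qemp(sub) − q − ΔQ_global −
ΔQ_reported`. The exact objective and σ are this package's documented
choice (verified against an independent exhaustive-scan oracle in the
tests), selected for compatibility with the GATK-4 default behaviour.

Application rewrites all records — the exclusion rules above apply to
tabulation only. `Q_new = floor(q + Σ deltas + 0.5)` clamped to [1, 93];
bases with `q < 6` (`preserve_below`) pass through; missing bins fall
back to the deepest available ancestor's deltas. Optional quantization
learns L levels by deterministic 1-D k-means on the quality histogram
(quantile initialisation) and maps each output quality to the nearest
level (ties to the lower level); off by default.

All table counts are integers (including the reported-quality weight
sum), so tabulation is exactly order-invariant and per-chunk tables sum
to the whole-file table without floating-point drift.

### Statistical power of the recovery checks

With σ = 0.5 the prior is strong: for a bin whose true quality is `d`
Phred away from its prior centre, the posterior argmax is shifted toward
the prior by roughly `(d/σ²) / (n·p·(ln10/10)²)` Phred (prior gradient
over binomial Fisher information), where `p` is the bin's error rate.
Recovering a planted 10× per-cycle error rate (d ≈ 8.4, p ≈ 7e−3) to
within ±1 Phred therefore needs on the order of 2×10⁵ observations per
signed-cycle bin; the recovery test and the acceptance script simulate
200 000 read pairs of length 20 (8×10⁶ aligned bases) with the mean error
rate matched to the reported quality so the read-group delta stays at
zero. Smaller simulations would measure the prior, not the data.

## Split-filter-merge mode

The input is scattered into one chunk per contig group (default one
contig each) plus an overflow chunk holding unmapped records and both
mates of cross-group pairs; every record lands in exactly one chunk. Each
chunk runs phases 1–2 independently; chunk outputs are k-way merged under
the final sort key with BQSR application and phase-3 filters applied
during the merge.

Correctness across chunks: pair-duplicate classes are wholly contained in
one chunk by construction. The one cross-chunk interaction is a fragment
sharing a single-end key with a cross-contig pair (which lives in the
overflow chunk); the overflow chunk is processed first and its pair end
keys are injected into every contig chunk's marking, so the
pairs-beat-fragments rule holds globally. Per-chunk metrics counters are
kept at read granularity and summed before derived quantities are
computed; per-chunk BQSR tables are summed before deltas. Original record
order survives the round trip through chunk files via a scratch `zi:i:`
tag stripped at merge time, so deterministic tie-breaks are identical to
filter mode. These choices make the two modes byte-identical on every
input, which the test suite verifies on planted datasets and an
adversarial cross-contig construction.

Temporary chunks live in a per-run unique directory removed on success;
debris from an interrupted run never affects a rerun.

## Synthetic data generator

`simgen` emits pre-aligned paired-end (and optionally single-end) reads
over a uniform-ACGT reference, with ground truth recorded for every
planted feature: PCR-duplicate groups (shared unclipped keys under varied
soft clipping, strictly ordered scores so the intended survivor is
unambiguous), optical copies at controlled pixel offsets, per-cycle
mismatch rates, and known "variant" sites carried by every covering read
and emitted as a VCF. Distinct loci are laid out on a non-overlapping
slot grid so unrelated reads can never collide on a duplicate key.

What it does **not** emulate: alignment itself (reads are written with
consistent POS/CIGAR directly, so aligner artefacts like soft-clip
asymmetries near indels are absent), indels within reads, quality-score
heterogeneity along realistic profiles, chimeric/supplementary
alignments, GC bias, and coverage fluctuations. Passing tests on this
data therefore demonstrate the *semantics* of marking/recalibration
(keys, survivor selection, masking, covariate accounting, mode
equivalence) — not robustness to every artefact of real libraries.
Adversarial small inputs (clips, ties, orphans, cross-contig pairs,
secondary/unmapped records) are exercised separately by the randomized
oracle tests.

## Numerical and formatting choices

* Qualities are Phred+33 throughout; coordinates are SAM 1-based
  inclusive (`pos = 0` = unavailable); BED input is converted to 0-based
  half-open internally.
* Sorting is made stable by keying on `file_index` explicitly, so any
  unstable sort algorithm underneath would still give identical output.
  Queryname order is plain byte-lexicographic (not Picard's
  numeric-aware "natural" order); the comparison recipe uses this
  package's own sort on both sides, so the choice cancels out.
* The `.recal` report is this package's stable text dialect
  (GATKReport-inspired): fixed section and column order, keys sorted,
  deltas and weighted means printed to 4 decimals. Equal tables serialize
  byte-identically; read∘write is the identity. Byte-level GATKReport
  compatibility is not claimed, since it could not be verified against
  the original tool here.
* Metrics formatting: `PERCENT_DUPLICATION` to 6 decimals,
  `ESTIMATED_LIBRARY_SIZE` truncated to an integer and blank when
  undefined; libraries ordered by first appearance among the header's
  @RG lines.
* Float-typed (`f`) SAM tags are stored as Python floats and written
  back in repr-minimal form; canonical spellings round-trip byte-exactly.
* `*` quality strings score 0 for duplicate selection and are skipped by
  BQSR tabulation (a policy switch can make them an error instead);
  application leaves them untouched.
* Unknown CIGAR operations are a parse error (fail fast) because
  silently skipping them would corrupt duplicate keys.

## Limitations

* SAM text only; BAM/CRAM/BGZF and tabix-indexed inputs are out of scope.
* Indel BQSR (insertion/deletion qualities) is not implemented.
* Duplicate marking does not inspect secondary/supplementary alignments
  (they are passed through with flags unchanged).
* The region filter does not perform mate rescue (keeping a read whose
  mate overlaps a target); this mirrors `-L`-style semantics.
* Everything runs single-threaded; the engine's contribution is the
  single-pass fusion and the order-independence contracts, not a
  concurrency implementation. Deterministic mode guarantees byte-stable
  output across runs and chunking granularities.
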