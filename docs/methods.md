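# Methods

## The selection problem

A BLAST search reports, per query sequence, a list of subject *hits*,
each containing one or more *HSPs* (local alignments) with an e-value,
bit score and alignment counts. Limiting output with `-max_target_seqs`
acts inside the search heuristic — before the final gapped alignment
stage — so it can change which alignments exist at all and is not a
reliable "give me the best hit" switch. `blastqc` treats selection as a
pure post-processing problem over the complete result file: every
decision below operates on records that BLAST already produced, and the
engine never mutates a field value — output is always a sub-multiset of
the parsed input.

## Record model and parsing

Both dialects are flattened to per-HSP records. A hit with several HSPs
yields one record per HSP, all sharing the hit's accession and
definition; community parsers that keep only the first HSP lose real
alignments (a query hitting two distinct regions of the same subject is
the common case). The XML parser also round-trips `Hsp_query-frame`
verbatim — a field a pair of widely circulated parser scripts reset to
0 — and the tests pin this as a regression.

XML is parsed with an incremental pull parser: each `<Iteration>`
subtree is converted and then discarded, so peak memory tracks the
largest single query, not the file (checked coarsely in the suite: a
10× longer file stays under 2× the peak). Tabular rows are grouped into
queries by maximal contiguous runs of equal `qseqid`, matching how
BLAST emits them; a qseqid that re-appears later is treated as a new
query and logged rather than merged, which would require unbounded
buffering. `#`-comment lines are skipped so `-outfmt 7` headers pass
through.

Two textual conventions matter for faithful output. Raw e-value and
bit-score strings are kept alongside the parsed floats and written back
as-is (`1e-05` never becomes `0.00001`); comparisons always use the
floats. Fields a dialect lacks (query length, subject length, frame and
percent conserved in tabular input; mismatch/gapopen in XML) are
`None`, printed `NA`, and never fabricated. Alignment coordinates are
passed through 1-based inclusive, exactly as BLAST reports them.

Derived percentages, computed for XML input only (tabular already
carries `pident`):

    pident     = 100 · Hsp_identity / Hsp_align-len
    pconserved = 100 · Hsp_positive / Hsp_align-len

For "accession number" the parser uses `Hit_accession`, falling back to
`Hit_id` for databases without accessions; the query identifier is the
first whitespace token of `Iteration_query-def`, which is the same
`qseqid` convention tabular output uses, so the two renderings of one
search agree.

## The QC pipeline

Per query: thresholds → ordering → optional range refinement → top-N.

**Thresholds** are conjunctive and inclusive: `evalue ≤ evalue_max`,
`bitscore ≥ bitscore_min`, `pident ≥ pident_min`,
`taxids(hit_def) ≥ taxid_min`, where `taxids` counts non-empty
`;`-separated fields of the subject definition. The semicolon rule fits
lineage-style definitions (`Bacteria;Proteobacteria;…` scores one per
rank) while a free-text annotation like `protein of unknown function
DUF1680` scores 1 — correctly flagged as low-information. A record
missing a field a set threshold needs is excluded (QC fails safe) with
a once-per-run warning; when the dialect makes the field impossible —
a taxid threshold on 12-column tabular input, which has no definitions
at all — the run is rejected up front as a configuration error instead
of silently emptying the output.

**Ordering** keys: e-value ascending, bit score descending, percent
identity descending, or definition (taxid count) descending. Ties break
by e-value ascending, then bit score descending, then percent identity
descending, then original file position, making every sort total,
stable and deterministic — a requirement for the parallel byte-identity
guarantee. The tie-break chain is this package's choice (nothing forces
one); it mirrors how BLAST itself ranks hits.

**Range refinement** takes one additive, inclusive window anchored at
the best record: e-value ≤ best + δ, or bit score / percent identity
≥ best − δ. Records inside the window are re-ranked by taxid count
(descending, ties by the ordering key), records outside keep their
order after the window. The window is intentionally inclusive at the
boundary so "δ more than the top hit" qualifies. Refinement runs before
top-N slicing, so `-n 3` with a range returns the three most
informative in-window records, a natural generalisation of the n=1
use case. With δ = 0 and no taxid ties the ranking is unchanged.

**Top-N** keeps the first `min(n, available)` records; unset `n`
returns everything ordered, which is the tool's default mode.

## Parallel execution

The parent process alone reads the input (a pipe cannot be shared),
groups whole queries into chunks (default 500 — large enough that
process start-up and IPC do not dominate for realistic inputs), and a
`multiprocessing` pool QC's chunks independently. Results are written
in chunk-ordinal order, so parallel output is byte-identical to
sequential output; the suite asserts this for 1/2/4/8 processes. With
one process no pool is constructed at all. A worker exception aborts
the whole run — no partial output is silently kept.

## Synthetic searches

The generator emulates the statistical *shape* of metagenomic search
output without any database: log-uniform e-values over 10⁻¹⁸⁰–10¹
(roughly what a nucleotide search against a large rRNA database spans),
bit scores anti-correlated with log e-value plus ±15 bits of noise (so
the ordering keys genuinely disagree on some inputs, exercising
tie-breaks and refinement), alignment lengths 80–900, 1–8 hits per
query with 1–3 HSPs each, semicolon-joined lineage definitions of depth
2–7 drawn from a small bundled vocabulary, and a 20% fraction of
single-field uninformative definitions. Identity/positive counts are
drawn as integers so the XML-derived `pident` and the tabular `pident`
(printed at 3 decimals, BLAST's convention) agree within 0.0005 by
construction. Generation is a pure function of the seed; the same seed
gives byte-identical files.

What the generator does **not** model: actual sequences or alignments
(scores are sampled, not computed), compositional biases, duplicate
accessions across queries, or BLAST's occasional exponent-free e-value
formats. Passing tests therefore demonstrate correct *selection logic*
on well-formed files, not robustness to every artefact of real
databases.

Two constructed cases target specific behaviours: a *truncation case*
places the global minimum-e-value hit anywhere but first in file order
and pairs the file with a variant cut to the first-listed hit — the
failure mode of capping the search — and a *range case* puts a more
informative definition within δ of an uninformative best hit. A fixed
two-hit *threshold demo* (32.40 bits at e-value 0.0015 vs 66.5 bits at
0.005) shows a 60-bit threshold flipping the selection.

## Numerical and interface choices

* Threshold and window comparisons are float comparisons on parsed
  values; no epsilon is added. Boundary behaviour is inclusive and
  documented rather than fuzzed.
* Report rendering: raw score text when available, otherwise scientific
  notation with 3 significant digits; percentages at 2 decimals; `NA`
  for missing fields; exactly 14 columns.
* Degenerate inputs: an empty stream parses to zero queries and writes
  a header-only report with zero counts; an empty `<Iteration_hits>` is
  a query with no records; `n` larger than the surviving set returns
  the whole set.
* Format auto-detection reads a bounded prefix (never consuming the
  stream) and keys on the XML declaration/root or the tab-field count
  of the first data line; ambiguous prefixes raise rather than guess.
* CLI flags use the short forms users of this tool class expect
  (`-or`, `-n`, `-e`, `-b`, `-i`, `-t`, `-er`, `-br`, `-ir`, `-p`,
  `-sa`, `-f`, `-o`) with long aliases; a range flag that does not
  match the order key is a usage error naming both flags. Exit codes:
  0 success, 1 usage/configuration, 2 parse/format, 3 I/O.

## Problem sizes in the checks

The acceptance checks run at sizes chosen to finish comfortably on one
CPU while still being adversarial: 300 random queries × 20 random
configurations against a brute-force reference (≈6000 pipeline runs),
50 truncation cases, 30 range cases, a 1000-query search for
cross-format concordance, and five 1000-query searches for parallel
byte-identity. The paper-scale runtime benchmarks (10³–10⁷ queries on
specific hardware) are out of scope; nothing in the selection logic
depends on input size.

## Known limitations

* Only `-outfmt 5` and `-outfmt 6` are supported — no pairwise text,
  ASN.1 or archive formats.
* No alignment statistics are recomputed beyond the two percentage
  formulas; no re-scoring or composition-based corrections.
* Tabular input without `salltitles` cannot support definition-based
  features (taxid thresholds, definition ordering is degenerate at
  count 0, range refinement cannot promote anything).
* The taxid count is a string heuristic; definitions that encode detail
  without semicolons are under-scored.
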