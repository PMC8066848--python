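# blastqc

Post-search quality control for NCBI BLAST result files.

Condensing a large BLAST search into "the hits that matter" is usually
done in one of two risky ways: capping the search itself with
`-max_target_seqs` — which is applied *during* the heuristic search, can
change which alignments are computed and their statistics, and famously
does **not** guarantee the best-scoring hit — or with ad-hoc sort
commands and one-off parser scripts, several of which silently drop
secondary HSPs or zero out the query frame. `blastqc` replaces both: run
BLAST unconstrained, then filter the result file afterwards, where
selection is exact and reproducible.

It is aimed at bioinformatics and genomics pipelines (metagenomic read
annotation against SILVA-style databases is the motivating case) that
need a dependency-free, streaming, parallelisable step between `blastn`/
`blastp`/`blastx` and downstream analysis.

## What it computes

Both BLAST output dialects are read — XML (`-outfmt 5`) and 12/13-column
tabular (`-outfmt 6`, optionally with `salltitles`) — and flattened into
one record per high-scoring pair (HSP). A hit with *k* HSPs contributes
*k* records, each keeping the hit's accession and definition, so no
alignment is lost. For XML input the two percentage fields are derived
from the HSP counts:

    percent identity  = 100 · Hsp_identity / Hsp_align-len
    percent conserved = 100 · Hsp_positive / Hsp_align-len

Per query, the QC pipeline is then

1. **thresholds** — keep records with `evalue ≤ E`, `bitscore ≥ B`,
   `pident ≥ I`, and/or at least `T` "taxids" (non-empty `;`-separated
   fields of the subject definition — a proxy for how informative the
   annotation is: a SILVA lineage scores 4–7, `hypothetical protein`
   scores 1);
2. **ordering** — by e-value ascending, or bit score / percent identity /
   taxid count descending, with deterministic tie-breaking;
3. **range refinement** (optional) — within an additive window of the
   best value (e.g. `-er .0005`: e-value ≤ best + 0.0005), re-rank by
   taxid count so the most informative hit in the window comes first;
4. **top-N** — keep the first `n` records.

Ordering by e-value with `-n 1` reproduces what `-max_target_seqs 1` is
commonly (and wrongly) assumed to do — as a safe post-hoc filter.
Parallel processing (`-p`, default = CPU count) chunks whole queries
across worker processes and merges results so output is byte-identical
to a sequential run (`-p 1`).

## Worked example

The bundled generator writes realistic paired fixtures, so the example
is fully reproducible:

```sh
python - <<'EOF' > example.xml
from blastqc.synth import *
print(to_xml(build_search(SyntheticSearchSpec(
    n_queries=2, seed=42, hits_per_query=(3,3), hsps_per_hit=(1,1)))), end="")
EOF
blast-qc -p 1 -or e -n 1 example.xml
```

prints

```
query_name	query_length	accession_number	subject_length	subject_description	e-value	bit_score	query_frame	query_start	query_end	hit_start	hit_end	percent_identity	percent_conserved
query00000	917	SYN00000.2	541	Eukaryota;Actinobacteria	1.38608e-152	356.2	-1	195	618	50	473	42.22	47.64
query00001	1051	SYN00001.2	920	Bacteria;Proteobacteria	4.77879e-84	194.7	3	474	1026	328	880	64.92	77.40
```

one row per query: the single best hit by e-value, with the derived
percent identity/conserved in the last two columns and the query frame
(here −1 and +3) carried through from the XML. Fields a dialect does not
provide are printed `NA`. Input may also be piped:
`cat example.xml | blast-qc -n 1`.

Library use mirrors the CLI exactly:

```python
from blastqc import QcConfig, parse_xml, qc_query

cfg = QcConfig(order_key="evalue", n_hits=1, evalue_range=5e-4)
with open("example.xml", "rb") as fh:
    best = [qc_query(q, cfg).records for q in parse_xml(fh)]
```

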