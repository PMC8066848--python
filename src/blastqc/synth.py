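"""Synthetic BLAST search generator.

Emulates the shape of real search output — SILVA-style semicolon-joined
lineage definitions, log-uniform e-values with anti-correlated bit scores,
multi-HSP hits, translated-search query frames — and renders the same
simulated search as both an XML (``-outfmt 5``) and a tabular
(``-outfmt 6``) report, plus a truth table of the intended best record per
query under each ordering key.  Scores are sampled, not computed from
sequences; generation is a pure function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, NamedTuple, Optional, Sequence, Tuple
from xml.sax.saxutils import escape

__all__ = [
    "SyntheticSearchSpec",
    "SynHsp", "SynHit", "SynQuery", "SynSearch",
    "build_search", "to_xml", "to_tabular", "truth_table",
    "generate_search", "GeneratedSearch",
    "generate_truncation_case", "TruncationCase",
    "generate_range_case", "RangeCase",
    "generate_threshold_demo",
]

# small bundled vocabulary of lineage tokens, deepest-last (SILVA-like)
_LINEAGE_LEVELS = (
    ("Bacteria", "Archaea", "Eukaryota"),
    ("Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria"),
    ("Gammaproteobacteria", "Alphaproteobacteria", "Bacilli", "Clostridia"),
    ("Vibrionales", "Enterobacterales", "Pseudomonadales", "Lactobacillales"),
    ("Vibrionaceae", "Enterobacteriaceae", "Pseudomonadaceae", "Shewanellaceae"),
    ("Vibrio", "Escherichia", "Pseudomonas", "Shewanella"),
    ("Vibrio cholerae", "Escherichia coli", "Pseudomonas putida",
     "Shewanella oneidensis"),
)

_UNINFORMATIVE_DEFS = (
    "hypothetical protein",
    "protein of unknown function DUF1680",
    "uncharacterized protein",
    "predicted protein",
)


@dataclass(frozen=True)
class SyntheticSearchSpec:
    """Parameters of one simulated search (all ranges inclusive)."""

    n_queries: int = 50
    hits_per_query: Tuple[int, int] = (1, 8)
    hsps_per_hit: Tuple[int, int] = (1, 3)
    evalue_log10_range: Tuple[float, float] = (-180.0, 1.0)
    bitscore_range: Tuple[float, float] = (30.0, 400.0)
    align_len_range: Tuple[int, int] = (80, 900)
    lineage_depth_range: Tuple[int, int] = (2, 7)
    uninformative_fraction: float = 0.2
    frame_values: Tuple[int, ...] = (-3, -2, -1, 1, 2, 3)
    seed: int = 0

    def validate(self) -> None:
        for name in ("hits_per_query", "hsps_per_hit", "align_len_range",
                     "lineage_depth_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is empty: {lo}..{hi}")
        if not 0.0 <= self.uninformative_fraction <= 1.0:
            raise ValueError("uninformative_fraction must lie in [0, 1]")
        if self.n_queries < 0:
            raise ValueError("n_queries must be >= 0")
        if not self.frame_values:
            raise ValueError("frame_values must be non-empty")


@dataclass
class SynHsp:
    evalue_text: str
    bitscore_text: str
    align_len: int
    identity: int
    positive: int
    q_start: int
    q_end: int
    h_start: int
    h_end: int
    frame: int
    mismatch: int
    gapopen: int

    @property
    def evalue(self) -> float:
        return float(self.evalue_text)

    @property
    def bitscore(self) -> float:
        return float(self.bitscore_text)

    @property
    def pident(self) -> float:
        return 100.0 * self.identity / self.align_len

    @property
    def pident_text(self) -> str:
        # BLAST prints tabular pident at 3 decimals
        return f"{self.pident:.3f}"


@dataclass
class SynHit:
    hit_id: str
    accession: str
    definition: str
    length: int
    hsps: List[SynHsp]


@dataclass
class SynQuery:
    qseqid: str
    query_def: str
    length: int
    hits: List[SynHit]


@dataclass
class SynSearch:
    queries: List[SynQuery]


def _taxid_count(definition: str) -> int:
    return sum(1 for part in definition.split(";") if part.strip())


def _make_definition(rng: random.Random, spec: SyntheticSearchSpec) -> str:
    if rng.random() < spec.uninformative_fraction:
        return rng.choice(_UNINFORMATIVE_DEFS)
    lo, hi = spec.lineage_depth_range
    depth = min(rng.randint(lo, hi), len(_LINEAGE_LEVELS))
    return ";".join(rng.choice(level) for level in _LINEAGE_LEVELS[:depth])


def _make_hsp(rng: random.Random, spec: SyntheticSearchSpec) -> SynHsp:
    lo_e, hi_e = spec.evalue_log10_range
    log_e = rng.uniform(lo_e, hi_e)
    evalue_text = f"{10.0 ** log_e:.6g}"
    # bit score anti-correlated with e-value plus noise, clipped to range
    lo_b, hi_b = spec.bitscore_range
    frac = (log_e - lo_e) / (hi_e - lo_e) if hi_e > lo_e else 0.5
    raw_bits = hi_b - frac * (hi_b - lo_b) + rng.uniform(-15.0, 15.0)
    bitscore_text = f"{min(max(raw_bits, lo_b), hi_b):.1f}"
    align_len = rng.randint(*spec.align_len_range)
    identity = rng.randint(max(0, int(0.3 * align_len)), align_len)
    positive = rng.randint(identity, align_len)
    q_start = rng.randint(1, 500)
    h_start = rng.randint(1, 500)
    return SynHsp(
        evalue_text=evalue_text,
        bitscore_text=bitscore_text,
        align_len=align_len,
        identity=identity,
        positive=positive,
        q_start=q_start,
        q_end=q_start + align_len - 1,
        h_start=h_start,
        h_end=h_start + align_len - 1,
        frame=rng.choice(spec.frame_values),
        mismatch=align_len - identity,
        gapopen=rng.randint(0, 3),
    )


def build_search(spec: SyntheticSearchSpec) -> SynSearch:
    """Sample the in-memory model of one simulated search."""
    spec.validate()
    rng = random.Random(spec.seed)
    queries: List[SynQuery] = []
    for qi in range(spec.n_queries):
        qseqid = f"query{qi:05d}"
        hits: List[SynHit] = []
        for hi in range(rng.randint(*spec.hits_per_query)):
            hsps = [_make_hsp(rng, spec)
                    for _ in range(rng.randint(*spec.hsps_per_hit))]
            accession = f"SYN{qi:05d}.{hi}"
            hits.append(SynHit(
                hit_id=f"gnl|synthdb|{accession}",
                accession=accession,
                definition=_make_definition(rng, spec),
                length=max(h.h_end for h in hsps) + rng.randint(0, 100),
                hsps=hsps,
            ))
        q_end_max = max((h.q_end for hit in hits for h in hit.hsps), default=100)
        queries.append(SynQuery(
            qseqid=qseqid,
            query_def=f"{qseqid} synthetic metagenomic read",
            length=q_end_max + rng.randint(0, 50),
            hits=hits,
        ))
    return SynSearch(queries=queries)


# ---------------------------------------------------------------------------
# Rendering

def _xml_iteration(out: List[str], index: int, query: SynQuery) -> None:
    a = out.append
    a("    <Iteration>\n")
    a(f"      <Iteration_iter-num>{index + 1}</Iteration_iter-num>\n")
    a(f"      <Iteration_query-ID>Query_{index + 1}</Iteration_query-ID>\n")
    a(f"      <Iteration_query-def>{escape(query.query_def)}</Iteration_query-def>\n")
    a(f"      <Iteration_query-len>{query.length}</Iteration_query-len>\n")
    if not query.hits:
        a("      <Iteration_hits></Iteration_hits>\n")
    else:
        a("      <Iteration_hits>\n")
        for hi, hit in enumerate(query.hits):
            a("        <Hit>\n")
            a(f"          <Hit_num>{hi + 1}</Hit_num>\n")
            a(f"          <Hit_id>{escape(hit.hit_id)}</Hit_id>\n")
            a(f"          <Hit_def>{escape(hit.definition)}</Hit_def>\n")
            a(f"          <Hit_accession>{escape(hit.accession)}</Hit_accession>\n")
            a(f"          <Hit_len>{hit.length}</Hit_len>\n")
            a("          <Hit_hsps>\n")
            for si, hsp in enumerate(hit.hsps):
                a("            <Hsp>\n")
                a(f"              <Hsp_num>{si + 1}</Hsp_num>\n")
                a(f"              <Hsp_bit-score>{hsp.bitscore_text}</Hsp_bit-score>\n")
                a(f"              <Hsp_score>{int(round(hsp.bitscore * 2))}</Hsp_score>\n")
                a(f"              <Hsp_evalue>{hsp.evalue_text}</Hsp_evalue>\n")
                a(f"              <Hsp_query-from>{hsp.q_start}</Hsp_query-from>\n")
                a(f"              <Hsp_query-to>{hsp.q_end}</Hsp_query-to>\n")
                a(f"              <Hsp_hit-from>{hsp.h_start}</Hsp_hit-from>\n")
                a(f"              <Hsp_hit-to>{hsp.h_end}</Hsp_hit-to>\n")
                a(f"              <Hsp_query-frame>{hsp.frame}</Hsp_query-frame>\n")
                a("              <Hsp_hit-frame>1</Hsp_hit-frame>\n")
                a(f"              <Hsp_identity>{hsp.identity}</Hsp_identity>\n")
                a(f"              <Hsp_positive>{hsp.positive}</Hsp_positive>\n")
                a("              <Hsp_gaps>0</Hsp_gaps>\n")
                a(f"              <Hsp_align-len>{hsp.align_len}</Hsp_align-len>\n")
                a("            </Hsp>\n")
            a("          </Hit_hsps>\n")
            a("        </Hit>\n")
        a("      </Iteration_hits>\n")
    a("      <Iteration_stat>\n        <Statistics>\n")
    a("          <Statistics_db-num>1000</Statistics_db-num>\n")
    a("          <Statistics_db-len>1000000</Statistics_db-len>\n")
    a("          <Statistics_hsp-len>0</Statistics_hsp-len>\n")
    a("          <Statistics_eff-space>0</Statistics_eff-space>\n")
    a("          <Statistics_kappa>0.41</Statistics_kappa>\n")
    a("          <Statistics_lambda>0.625</Statistics_lambda>\n")
    a("          <Statistics_entropy>0.78</Statistics_entropy>\n")
    a("        </Statistics>\n      </Iteration_stat>\n")
    a("    </Iteration>\n")


def to_xml(search: SynSearch) -> str:
    """Render the search as a well-formed ``-outfmt 5`` XML report."""
    first = search.queries[0] if search.queries else None
    out: List[str] = []
    a = out.append
    a('<?xml version="1.0"?>\n')
    a('<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" '
      '"http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">\n')
    a("<BlastOutput>\n")
    a("  <BlastOutput_program>blastn</BlastOutput_program>\n")
    a("  <BlastOutput_version>BLASTN 2.10.0+</BlastOutput_version>\n")
    a("  <BlastOutput_reference>Synthetic search output for testing"
      "</BlastOutput_reference>\n")
    a("  <BlastOutput_db>synthetic_db</BlastOutput_db>\n")
    a("  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>\n")
    a(f"  <BlastOutput_query-def>"
      f"{escape(first.query_def) if first else 'none'}</BlastOutput_query-def>\n")
    a(f"  <BlastOutput_query-len>{first.length if first else 0}"
      "</BlastOutput_query-len>\n")
    a("  <BlastOutput_param>\n    <Parameters>\n")
    a("      <Parameters_expect>10</Parameters_expect>\n")
    a("      <Parameters_sc-match>1</Parameters_sc-match>\n")
    a("      <Parameters_sc-mismatch>-2</Parameters_sc-mismatch>\n")
    a("      <Parameters_gap-open>0</Parameters_gap-open>\n")
    a("      <Parameters_gap-extend>0</Parameters_gap-extend>\n")
    a("      <Parameters_filter>L;m;</Parameters_filter>\n")
    a("    </Parameters>\n  </BlastOutput_param>\n")
    a("  <BlastOutput_iterations>\n")
    for index, query in enumerate(search.queries):
        _xml_iteration(out, index, query)
    a("  </BlastOutput_iterations>\n")
    a("</BlastOutput>\n")
    return "".join(out)


def to_tabular(search: SynSearch, salltitles: bool = False) -> str:
    """Render the same search as a 12- or 13-column tabular report."""
    rows: List[str] = []
    for query in search.queries:
        for hit in query.hits:
            for hsp in hit.hsps:
                fields = [
                    query.qseqid, hit.accession, hsp.pident_text,
                    str(hsp.align_len), str(hsp.mismatch), str(hsp.gapopen),
                    str(hsp.q_start), str(hsp.q_end),
                    str(hsp.h_start), str(hsp.h_end),
                    hsp.evalue_text, hsp.bitscore_text,
                ]
                if salltitles:
                    fields.append(hit.definition)
                rows.append("\t".join(fields))
    return "".join(row + "\n" for row in rows)


def truth_table(search: SynSearch) -> str:
    """TSV of the intended best record per query for every order key:
    ``query_id <TAB> order_key <TAB> accession <TAB> source_rank``."""
    lines = ["query_id\torder_key\taccession\tsource_rank"]
    for query in search.queries:
        flat: List[Tuple[SynHit, SynHsp, int]] = []
        rank = 0
        for hit in query.hits:
            for hsp in hit.hsps:
                flat.append((hit, hsp, rank))
                rank += 1
        if not flat:
            continue
        keyed = {
            "evalue": lambda h, s: s.evalue,
            "bitscore": lambda h, s: -s.bitscore,
            "pident": lambda h, s: -s.pident,
            "definition": lambda h, s: -_taxid_count(h.definition),
        }
        for name, primary in keyed.items():
            best = min(flat, key=lambda t: (primary(t[0], t[1]), t[1].evalue,
                                            -t[1].bitscore, -t[1].pident, t[2]))
            lines.append(f"{query.qseqid}\t{name}\t{best[0].accession}\t{best[2]}")
    return "".join(line + "\n" for line in lines)


class GeneratedSearch(NamedTuple):
    search: SynSearch
    xml_path: Path
    tabular_path: Path
    tabular_salltitles_path: Path
    truth_path: Path


def generate_search(spec: SyntheticSearchSpec, directory) -> GeneratedSearch:
    """Write the paired renderings and truth table into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    search = build_search(spec)
    paths = GeneratedSearch(
        search=search,
        xml_path=directory / "search.xml",
        tabular_path=directory / "search.tsv",
        tabular_salltitles_path=directory / "search_salltitles.tsv",
        truth_path=directory / "truth.tsv",
    )
    paths.xml_path.write_text(to_xml(search))
    paths.tabular_path.write_text(to_tabular(search, salltitles=False))
    paths.tabular_salltitles_path.write_text(to_tabular(search, salltitles=True))
    paths.truth_path.write_text(truth_table(search))
    return paths


# ---------------------------------------------------------------------------
# Targeted cases

class TruncationCase(NamedTuple):
    full_xml: str
    truncated_xml: str
    best_accession: str
    best_evalue: float


def generate_truncation_case(seed: int) -> TruncationCase:
    """A search whose globally best-e-value hit is *not* the first-listed
    hit, plus a variant truncated to the first-listed hit only — the
    classic ``-max_target_seqs 1`` failure mode.  QC on the full file must
    recover the best hit; the truncated file cannot contain it."""
    rng = random.Random(seed)
    spec = SyntheticSearchSpec(n_queries=0, seed=seed)
    n_hits = rng.randint(4, 8)
    log_evalues = sorted(rng.uniform(-60.0, -2.0) for _ in range(n_hits))
    texts = [f"{10.0 ** lg:.6g}" for lg in log_evalues]
    while len(set(texts)) != len(texts):  # extremely unlikely; keep distinct
        log_evalues = sorted(rng.uniform(-60.0, -2.0) for _ in range(n_hits))
        texts = [f"{10.0 ** lg:.6g}" for lg in log_evalues]

    # place the minimum e-value anywhere but first
    best_position = rng.randint(1, n_hits - 1)
    order = list(range(1, n_hits))
    rng.shuffle(order)
    positions = [None] * n_hits
    positions[best_position] = 0
    spill = iter(order)
    for i in range(n_hits):
        if positions[i] is None:
            positions[i] = next(spill)

    hits: List[SynHit] = []
    for i in range(n_hits):
        hsp = _make_hsp(rng, spec)
        hsp.evalue_text = texts[positions[i]]
        accession = f"TRC{seed:06d}.{i}"
        hits.append(SynHit(
            hit_id=f"gnl|synthdb|{accession}",
            accession=accession,
            definition=_make_definition(rng, spec),
            length=hsp.h_end + 10,
            hsps=[hsp],
        ))
    query = SynQuery(qseqid="query00000",
                     query_def="query00000 truncation test read",
                     length=max(h.hsps[0].q_end for h in hits) + 10,
                     hits=hits)
    full = SynSearch(queries=[query])
    truncated = SynSearch(queries=[SynQuery(
        qseqid=query.qseqid, query_def=query.query_def,
        length=query.length, hits=[hits[0]])])
    best_hit = hits[best_position]
    return TruncationCase(
        full_xml=to_xml(full),
        truncated_xml=to_xml(truncated),
        best_accession=best_hit.accession,
        best_evalue=best_hit.hsps[0].evalue,
    )


class RangeCase(NamedTuple):
    xml: str
    delta: float
    baseline_accession: str   # top hit under plain e-value ordering
    informative_accession: str  # in-window hit with strictly more taxids


def generate_range_case(seed: int, delta: float = 5e-4) -> RangeCase:
    """A search where the second-best e-value hit lies within ``delta`` of
    the best but carries a strictly more informative definition, so range
    refinement (``-er delta``) must promote it to the top."""
    rng = random.Random(seed)
    spec = SyntheticSearchSpec(n_queries=0, seed=seed)

    e_best = 10.0 ** rng.uniform(-5.0, -3.2)
    # keep the runner-up inside the window after float round-trip through text
    e_second = e_best + delta * rng.uniform(0.2, 0.8)

    hsp_a = _make_hsp(rng, spec)
    hsp_a.evalue_text = f"{e_best:.17g}"
    hit_a = SynHit(hit_id="gnl|synthdb|RNG.A", accession=f"RNG{seed:06d}.A",
                   definition=rng.choice(_UNINFORMATIVE_DEFS),
                   length=hsp_a.h_end + 10, hsps=[hsp_a])

    hsp_b = _make_hsp(rng, spec)
    hsp_b.evalue_text = f"{e_second:.17g}"
    depth = rng.randint(4, len(_LINEAGE_LEVELS))
    hit_b = SynHit(hit_id="gnl|synthdb|RNG.B", accession=f"RNG{seed:06d}.B",
                   definition=";".join(rng.choice(level)
                                       for level in _LINEAGE_LEVELS[:depth]),
                   length=hsp_b.h_end + 10, hsps=[hsp_b])

    # one clearly out-of-window hit to exercise the window partition
    hsp_c = _make_hsp(rng, spec)
    hsp_c.evalue_text = f"{e_best + 10.0 * delta:.17g}"
    hit_c = SynHit(hit_id="gnl|synthdb|RNG.C", accession=f"RNG{seed:06d}.C",
                   definition=";".join(level[0] for level in _LINEAGE_LEVELS),
                   length=hsp_c.h_end + 10, hsps=[hsp_c])

    query = SynQuery(qseqid="query00000",
                     query_def="query00000 range refinement test read",
                     length=max(h.hsps[0].q_end for h in (hit_a, hit_b, hit_c)) + 10,
                     hits=[hit_a, hit_b, hit_c])
    return RangeCase(xml=to_xml(SynSearch(queries=[query])), delta=delta,
                     baseline_accession=hit_a.accession,
                     informative_accession=hit_b.accession)


def generate_threshold_demo() -> str:
    """Fixed two-hit search for the threshold demonstration: the better
    e-value hit (0.0015) scores only 32.40 bits while the 0.005 hit scores
    66.5 bits, so a 60-bit threshold flips the top selection."""
    def hit(tag: str, evalue: str, bitscore: str, definition: str) -> SynHit:
        return SynHit(
            hit_id=f"gnl|synthdb|DEMO.{tag}",
            accession=f"DEMO.{tag}",
            definition=definition,
            length=400,
            hsps=[SynHsp(evalue_text=evalue, bitscore_text=bitscore,
                         align_len=120, identity=96, positive=108,
                         q_start=1, q_end=120, h_start=31, h_end=150,
                         frame=1, mismatch=24, gapopen=0)],
        )

    query = SynQuery(
        qseqid="query00000",
        query_def="query00000 threshold demo read",
        length=150,
        hits=[hit("A", "0.0015", "32.40",
                  "Bacteria;Proteobacteria;Gammaproteobacteria"),
              hit("B", "0.005", "66.5",
                  "Bacteria;Firmicutes;Bacilli;Lactobacillales")],
    )
    return to_xml(SynSearch(queries=[query]))
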