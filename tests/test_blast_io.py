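"""Parsing, derived percentages, format detection and report writing."""

import io
import math
import random
import tracemalloc
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from blastqc.blast_io import (
    BlastParseError,
    FormatTag,
    HEADER_LINE,
    HspRecord,
    QueryResult,
    UnrecognizedFormatError,
    compute_percent_conserved,
    compute_percent_identity,
    detect_format,
    format_record,
    parse_tabular,
    parse_xml,
    write_tabular,
)
from blastqc.synth import SyntheticSearchSpec, build_search, to_tabular, to_xml

# ---------------------------------------------------------------------------
# Percentage formulas


@pytest.mark.parametrize("func", [compute_percent_identity,
                                  compute_percent_conserved])
@pytest.mark.parametrize("count,length,expected", [
    (30, 60, 50.0),
    (60, 60, 100.0),
    (0, 17, 0.0),
    (45, 60, 75.0),
    (1, 3, 100.0 / 3.0),
])
def test_percentage_formula_examples(func, count, length, expected):
    assert func(count, length) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("func", [compute_percent_identity,
                                  compute_percent_conserved])
def test_percentage_formula_domain_errors(func):
    with pytest.raises(ValueError):
        func(5, 0)
    with pytest.raises(ValueError):
        func(10, 5)
    with pytest.raises(ValueError):
        func(-1, 5)


@given(st.integers(min_value=1, max_value=10**6), st.data())
def test_percentage_formula_matches_exact_rational(length, data):
    count = data.draw(st.integers(min_value=0, max_value=length))
    expected = float(Fraction(100 * count, length))
    got = compute_percent_identity(count, length)
    assert abs(got - expected) <= math.ulp(expected)
    assert 0.0 <= got <= 100.0


# ---------------------------------------------------------------------------
# XML parsing


def _one_query_xml(hits):
    """Minimal hand-rolled iteration: hits is a list of (accession, hsp-xml)."""
    hit_blocks = "".join(
        f"<Hit><Hit_num>{i+1}</Hit_num><Hit_id>gi|{i}</Hit_id>"
        f"<Hit_def>def {acc}</Hit_def><Hit_accession>{acc}</Hit_accession>"
        f"<Hit_len>500</Hit_len><Hit_hsps>{hsps}</Hit_hsps></Hit>"
        for i, (acc, hsps) in enumerate(hits))
    return (
        '<?xml version="1.0"?><BlastOutput><BlastOutput_iterations>'
        "<Iteration><Iteration_iter-num>1</Iteration_iter-num>"
        "<Iteration_query-def>seq1 some description</Iteration_query-def>"
        "<Iteration_query-len>900</Iteration_query-len>"
        f"<Iteration_hits>{hit_blocks}</Iteration_hits></Iteration>"
        "</BlastOutput_iterations></BlastOutput>")


def _hsp(evalue="1e-05", bits="200.1", frame="1", identity=80, length=100,
         drop=()):
    parts = {
        "Hsp_num": "1", "Hsp_bit-score": bits, "Hsp_evalue": evalue,
        "Hsp_query-from": "1", "Hsp_query-to": str(length),
        "Hsp_hit-from": "11", "Hsp_hit-to": str(10 + length),
        "Hsp_query-frame": frame, "Hsp_identity": str(identity),
        "Hsp_positive": str(identity + 5), "Hsp_align-len": str(length),
    }
    body = "".join(f"<{k}>{v}</{k}>" for k, v in parts.items() if k not in drop)
    return f"<Hsp>{body}</Hsp>"


def test_multi_hsp_hit_expands_to_one_record_per_hsp():
    xml = _one_query_xml([("ACC1", _hsp() + _hsp(evalue="2e-07")
                           + _hsp(evalue="3e-03"))])
    (query,) = parse_xml(io.StringIO(xml))
    assert len(query.records) == 3
    assert {r.hit_accession for r in query.records} == {"ACC1"}
    assert {r.hit_def for r in query.records} == {"def ACC1"}
    assert [r.source_rank for r in query.records] == [0, 1, 2]


def test_query_id_is_first_token_of_query_def():
    xml = _one_query_xml([("A", _hsp())])
    (query,) = parse_xml(io.StringIO(xml))
    assert query.query_id == "seq1"
    assert query.query_len == 900


def test_empty_hits_element_yields_query_with_no_records():
    xml = ('<?xml version="1.0"?><BlastOutput><BlastOutput_iterations>'
           "<Iteration><Iteration_query-def>q</Iteration_query-def>"
           "<Iteration_hits></Iteration_hits></Iteration>"
           "</BlastOutput_iterations></BlastOutput>")
    (query,) = parse_xml(io.StringIO(xml))
    assert query.records == []


def test_negative_query_frame_round_trips():
    xml = _one_query_xml([("A", _hsp(frame="-2"))])
    (query,) = parse_xml(io.StringIO(xml))
    assert query.records[0].query_frame == -2


def test_xml_pident_derived_from_identity_over_align_len():
    xml = _one_query_xml([("A", _hsp(identity=30, length=60))])
    (query,) = parse_xml(io.StringIO(xml))
    record = query.records[0]
    assert record.pident == 50.0
    assert record.pconserved == pytest.approx(100.0 * 35 / 60)


def test_missing_required_element_names_query_and_hit():
    xml = _one_query_xml([("ACCX", _hsp(drop={"Hsp_evalue"}))])
    with pytest.raises(BlastParseError, match="seq1.*ACCX.*Hsp_evalue"):
        list(parse_xml(io.StringIO(xml)))


def test_malformed_xml_reports_byte_offset():
    with pytest.raises(BlastParseError, match="byte offset"):
        list(parse_xml(io.StringIO("<BlastOutput><oops</BlastOutput>")))


def test_truncated_xml_is_an_error():
    xml = _one_query_xml([("A", _hsp())])
    with pytest.raises(BlastParseError):
        list(parse_xml(io.StringIO(xml[:-20])))


def test_empty_xml_stream_yields_nothing():
    assert list(parse_xml(io.StringIO(""))) == []
    assert list(parse_xml(io.BytesIO(b""))) == []


def test_parse_xml_accepts_bytes_stream():
    xml = _one_query_xml([("A", _hsp())])
    (query,) = parse_xml(io.BytesIO(xml.encode()))
    assert query.records[0].evalue == 1e-05


def test_hit_accession_falls_back_to_hit_id():
    xml = ('<?xml version="1.0"?><BlastOutput><BlastOutput_iterations>'
           "<Iteration><Iteration_query-def>q</Iteration_query-def>"
           "<Iteration_hits><Hit><Hit_id>gi|777</Hit_id>"
           f"<Hit_hsps>{_hsp()}</Hit_hsps></Hit></Iteration_hits>"
           "</Iteration></BlastOutput_iterations></BlastOutput>")
    (query,) = parse_xml(io.StringIO(xml))
    assert query.records[0].hit_accession == "gi|777"


def test_parse_xml_memory_stays_bounded_as_file_grows():
    """Peak memory on a 10x larger file grows far less than 10x (the
    parser discards each query's subtree after yielding it)."""
    def peak(n_queries):
        spec = SyntheticSearchSpec(n_queries=n_queries, seed=9,
                                   hits_per_query=(3, 3), hsps_per_hit=(2, 2))
        data = to_xml(build_search(spec)).encode()
        tracemalloc.start()
        count = sum(len(q.records) for q in parse_xml(io.BytesIO(data)))
        _, peak_bytes = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert count == n_queries * 6
        return peak_bytes

    assert peak(300) < 2 * peak(30)


# ---------------------------------------------------------------------------
# Tabular parsing


def _row(qseqid, extra=None, evalue="1e-10", bitscore="200.5"):
    fields = [qseqid, "subj1", "98.765", "120", "2", "1", "1", "120",
              "31", "150", evalue, bitscore]
    if extra is not None:
        fields.append(extra)
    return "\t".join(fields)


def test_tabular_groups_only_contiguous_runs():
    text = "\n".join([_row("A"), _row("A"), _row("B"), _row("A"), _row("A")]) + "\n"
    queries = list(parse_tabular(io.StringIO(text)))
    assert [(q.query_id, len(q.records)) for q in queries] == [
        ("A", 2), ("B", 1), ("A", 2)]
    assert [q.file_index for q in queries] == [0, 1, 2]
    for q in queries:
        assert [r.source_rank for r in q.records] == list(range(len(q.records)))


def test_tabular_fields_map_to_record():
    (query,) = parse_tabular(io.StringIO(_row("A") + "\n"))
    r = query.records[0]
    assert (r.pident, r.align_len, r.mismatch, r.gapopen) == (98.765, 120, 2, 1)
    assert (r.q_start, r.q_end, r.h_start, r.h_end) == (1, 120, 31, 150)
    assert (r.evalue, r.bitscore) == (1e-10, 200.5)
    # fields the tabular dialect does not carry stay missing
    assert r.query_len is None and r.hit_len is None
    assert r.query_frame is None and r.pconserved is None
    assert r.hit_def is None


def test_tabular_salltitles_column_populates_hit_def():
    text = _row("A", extra="Bacteria;Proteobacteria") + "\n"
    (query,) = parse_tabular(io.StringIO(text), has_salltitles=True)
    assert query.records[0].hit_def == "Bacteria;Proteobacteria"


def test_tabular_empty_stream_yields_nothing():
    assert list(parse_tabular(io.StringIO(""))) == []


def test_tabular_comment_lines_are_skipped():
    text = "# BLASTN 2.10.0+\n# Fields: ...\n" + _row("A") + "\n"
    (query,) = parse_tabular(io.StringIO(text))
    assert len(query.records) == 1


def test_tabular_wrong_column_count_names_line():
    text = _row("A") + "\n" + _row("B", extra="unexpected") + "\n"
    with pytest.raises(BlastParseError, match="line 2.*expected 12.*13"):
        list(parse_tabular(io.StringIO(text)))


def test_tabular_non_numeric_value_names_line_and_column():
    bad = _row("A").replace("1e-10", "not-a-number")
    with pytest.raises(BlastParseError, match="line 1.*evalue"):
        list(parse_tabular(io.StringIO(bad + "\n")))


def test_tabular_grouping_matches_run_length_oracle(rng):
    """Grouping equals an independent run-length encoding of the qseqid
    column, for random query orderings."""
    import itertools
    ids = [rng.choice("ABCDE") for _ in range(200)]
    text = "".join(_row(q) + "\n" for q in ids)
    queries = list(parse_tabular(io.StringIO(text)))
    expected = [(k, len(list(g))) for k, g in itertools.groupby(ids)]
    assert [(q.query_id, len(q.records)) for q in queries] == expected


# ---------------------------------------------------------------------------
# Format detection


@pytest.mark.parametrize("payload,expected", [
    ('<?xml version="1.0"?>\n<BlastOutput>', FormatTag.XML),
    ("  \n<BlastOutput>", FormatTag.XML),
    (_row("A") + "\n", FormatTag.TABULAR),
    (_row("A", extra="some;def") + "\n", FormatTag.TABULAR_SALLTITLES),
    ("# comment\n" + _row("A") + "\n", FormatTag.TABULAR),
])
def test_detect_format_recognises_dialects(payload, expected):
    assert detect_format(io.StringIO(payload)) is expected
    assert detect_format(io.BytesIO(payload.encode())) is expected


def test_detect_format_rejects_unknown_field_count():
    with pytest.raises(UnrecognizedFormatError, match="11"):
        detect_format(io.StringIO("\t".join("x" * 1 for _ in range(11)) + "\n"))


def test_detect_format_does_not_consume_the_stream():
    stream = io.StringIO(_row("A") + "\n")
    detect_format(stream)
    assert stream.read() == _row("A") + "\n"


# ---------------------------------------------------------------------------
# Report writing


def test_write_tabular_empty_input_writes_header_only():
    out = io.StringIO()
    write_tabular([], out)
    assert out.getvalue() == HEADER_LINE + "\n"
    assert HEADER_LINE.split("\t") == [
        "query_name", "query_length", "accession_number", "subject_length",
        "subject_description", "e-value", "bit_score", "query_frame",
        "query_start", "query_end", "hit_start", "hit_end",
        "percent_identity", "percent_conserved"]


def test_write_tabular_renders_missing_fields_as_na():
    (query,) = parse_tabular(io.StringIO(_row("A") + "\n"))
    out = io.StringIO()
    write_tabular([query], out)
    row = out.getvalue().splitlines()[1].split("\t")
    assert row[1] == "NA"        # query_length unknown in tabular input
    assert row[3] == "NA"        # subject_length
    assert row[4] == "NA"        # subject_description
    assert row[7] == "NA"        # query_frame
    assert row[13] == "NA"       # percent_conserved
    assert row[12] == "98.77"    # pident at 2 decimals


def test_write_tabular_preserves_raw_evalue_text():
    xml = _one_query_xml([("A", _hsp(evalue="1e-05"))])
    (query,) = parse_xml(io.StringIO(xml))
    out = io.StringIO()
    write_tabular([query], out)
    assert out.getvalue().splitlines()[1].split("\t")[5] == "1e-05"


def test_format_record_falls_back_to_scientific_notation():
    record = HspRecord(query_id="q", hit_accession="a", evalue=1.2345e-7,
                       bitscore=66.5, align_len=10, q_start=1, q_end=10,
                       h_start=1, h_end=10, source_rank=0)
    row = format_record(record).split("\t")
    assert row[5] == "1.23e-07"


# ---------------------------------------------------------------------------
# Cross-dialect and cross-parser concordance on generated searches


def _fixture_search(seed, n_queries=40):
    return build_search(SyntheticSearchSpec(n_queries=n_queries, seed=seed))


def test_xml_parse_round_trips_generated_values():
    search = _fixture_search(2)
    xml_queries = list(parse_xml(io.StringIO(to_xml(search))))
    assert len(xml_queries) == len(search.queries)
    for syn_q, parsed in zip(search.queries, xml_queries):
        flat = [(hit, hsp) for hit in syn_q.hits for hsp in hit.hsps]
        assert len(parsed.records) == len(flat)
        for (hit, hsp), record in zip(flat, parsed.records):
            assert record.hit_accession == hit.accession
            assert record.hit_def == hit.definition
            assert record.evalue == hsp.evalue
            assert record.query_frame == hsp.frame
            assert record.pident == 100.0 * hsp.identity / hsp.align_len


def test_hsp_conservation_record_count_equals_hsp_element_count():
    search = _fixture_search(4)
    xml = to_xml(search)
    total = sum(len(q.records) for q in parse_xml(io.StringIO(xml)))
    assert total == xml.count("<Hsp>")


def test_query_frame_multiset_preserved():
    search = _fixture_search(6)
    parsed = parse_xml(io.StringIO(to_xml(search)))
    got = sorted(r.query_frame for q in parsed for r in q.records)
    written = sorted(h.frame for q in search.queries
                     for hit in q.hits for h in hit.hsps)
    assert got == written
    assert 0 not in got  # never coerced to zero


def test_xml_and_tabular_renderings_agree_per_query():
    search = _fixture_search(8)
    xml_queries = list(parse_xml(io.StringIO(to_xml(search))))
    tab_queries = list(parse_tabular(
        io.StringIO(to_tabular(search, salltitles=True)), has_salltitles=True))
    xml_map = {q.query_id: q for q in xml_queries}
    for tq in tab_queries:
        xq = xml_map[tq.query_id]
        key = lambda r: (r.hit_accession, r.evalue, r.bitscore, r.align_len,
                         r.q_start, r.q_end, r.h_start, r.h_end)
        assert sorted(map(key, xq.records)) == sorted(map(key, tq.records))
        for xr, tr in zip(xq.records, tq.records):
            assert abs(xr.pident - tr.pident) < 0.005


def test_parser_agrees_with_biopython_ncbixml():
    """Independent oracle: Bio.Blast NCBIXML on the same file must see the
    same per-HSP e-values, scores, frames and identity counts."""
    from Bio.Blast import NCBIXML

    search = _fixture_search(12, n_queries=15)
    xml = to_xml(search)
    ours = list(parse_xml(io.StringIO(xml)))
    theirs = list(NCBIXML.parse(io.StringIO(xml)))
    assert len(ours) == len(theirs)
    for mine, ref in zip(ours, theirs):
        ref_rows = [(aln.accession, h.expect, h.bits, h.identities,
                     h.positives, h.align_length, h.frame[0])
                    for aln in ref.alignments for h in aln.hsps]
        my_rows = [(r.hit_accession, r.evalue, r.bitscore, r.identity_count,
                    r.positive_count, r.align_len, r.query_frame)
                   for r in mine.records]
        assert my_rows == ref_rows
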