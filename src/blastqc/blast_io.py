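"""Reading and writing NCBI BLAST result files.

Supports the XML report (``-outfmt 5``, NCBI_BlastOutput DTD) and the
12/13-column tabular report (``-outfmt 6``, optionally carrying a 13th
``salltitles`` column).  Both dialects are flattened into one record per
high-scoring pair (HSP): a hit carrying several HSPs contributes one
record per HSP, each retaining the hit's accession and definition, so no
alignment is lost downstream.

XML parsing is incremental — memory stays proportional to one query's
subtree, not the whole file — so multi-gigabyte search outputs stream
through without being loaded at once.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union
from xml.etree import ElementTree as ET

logger = logging.getLogger("blastqc")

__all__ = [
    "BlastQcError",
    "BlastParseError",
    "UnrecognizedFormatError",
    "FormatTag",
    "HspRecord",
    "QueryResult",
    "REPORT_COLUMNS",
    "HEADER_LINE",
    "parse_xml",
    "parse_tabular",
    "detect_format",
    "compute_percent_identity",
    "compute_percent_conserved",
    "format_record",
    "write_tabular",
]


# ---------------------------------------------------------------------------
# Errors

class BlastQcError(Exception):
    """Base class for every error raised by this package."""


class BlastParseError(BlastQcError):
    """The input is not a readable BLAST report: malformed syntax, a bad
    column count or numeric field, or a required XML element is absent."""


class UnrecognizedFormatError(BlastQcError):
    """The input prefix matches neither BLAST XML nor tabular output."""


# ---------------------------------------------------------------------------
# Record model

class FormatTag(enum.Enum):
    """Input dialect of a BLAST result stream."""

    XML = "xml"
    TABULAR = "tabular"
    TABULAR_SALLTITLES = "tabular_salltitles"


@dataclass(slots=True)
class HspRecord:
    """One flattened hit/HSP candidate row.

    Fields absent from a dialect (e.g. query length or percent conserved
    in tabular input) are ``None`` and rendered ``NA`` on output; they are
    never fabricated.  ``evalue_text``/``bitscore_text`` retain the raw
    strings seen at parse time so output reproduces the input formatting
    (``1e-05`` is not rewritten as ``0.00001``); all comparisons use the
    parsed floats.
    """

    query_id: str
    hit_accession: str
    evalue: float
    bitscore: float
    align_len: int
    q_start: int
    q_end: int
    h_start: int
    h_end: int
    source_rank: int
    query_len: Optional[int] = None
    hit_len: Optional[int] = None
    hit_def: Optional[str] = None
    query_frame: Optional[int] = None
    identity_count: Optional[int] = None
    positive_count: Optional[int] = None
    pident: Optional[float] = None
    pconserved: Optional[float] = None
    mismatch: Optional[int] = None
    gapopen: Optional[int] = None
    evalue_text: Optional[str] = None
    bitscore_text: Optional[str] = None


@dataclass(slots=True)
class QueryResult:
    """All candidate records for one query, in input-file order."""

    query_id: str
    query_len: Optional[int]
    records: list
    file_index: int


# ---------------------------------------------------------------------------
# Derived percentages

def compute_percent_identity(identity_count: int, align_len: int) -> float:
    """Percent of alignment positions with identical residues,
    ``100 * identity_count / align_len``."""
    if align_len < 1:
        raise ValueError(f"align_len must be >= 1, got {align_len}")
    if not 0 <= identity_count <= align_len:
        raise ValueError(
            f"identity_count must lie in [0, align_len]; "
            f"got {identity_count} with align_len {align_len}"
        )
    return 100.0 * identity_count / align_len


def compute_percent_conserved(positive_count: int, align_len: int) -> float:
    """Percent of alignment positions with chemically similar ("positive")
    residues, ``100 * positive_count / align_len``."""
    if align_len < 1:
        raise ValueError(f"align_len must be >= 1, got {align_len}")
    if not 0 <= positive_count <= align_len:
        raise ValueError(
            f"positive_count must lie in [0, align_len]; "
            f"got {positive_count} with align_len {align_len}"
        )
    return 100.0 * positive_count / align_len


# ---------------------------------------------------------------------------
# XML parsing (-outfmt 5)

_XML_CHUNK_SIZE = 1 << 16


def _req_text(elem: ET.Element, tag: str, context: str) -> str:
    node = elem.find(tag)
    if node is None or node.text is None:
        raise BlastParseError(f"{context}: missing required element <{tag}>")
    return node.text


def _opt_int(elem: ET.Element, tag: str) -> Optional[int]:
    text = elem.findtext(tag)
    if text is None or not text.strip():
        return None
    return int(text)


def _iteration_to_query(iteration: ET.Element, file_index: int) -> QueryResult:
    # qseqid convention: first whitespace token of the query definition,
    # falling back to the internal Query_N id when no definition is given.
    qdef = iteration.findtext("Iteration_query-def")
    if qdef is None or not qdef.strip():
        qdef = iteration.findtext("Iteration_query-ID") or f"Query_{file_index + 1}"
    query_id = qdef.split()[0]
    query_len = _opt_int(iteration, "Iteration_query-len")

    records: list = []
    rank = 0
    for hit in iteration.findall("Iteration_hits/Hit"):
        accession = hit.findtext("Hit_accession") or hit.findtext("Hit_id") or ""
        hit_def = hit.findtext("Hit_def")
        hit_len = _opt_int(hit, "Hit_len")
        context = f"query {query_id!r}, hit {accession!r}"
        for hsp in hit.findall("Hit_hsps/Hsp"):
            evalue_text = _req_text(hsp, "Hsp_evalue", context).strip()
            bitscore_text = _req_text(hsp, "Hsp_bit-score", context).strip()
            align_len = int(_req_text(hsp, "Hsp_align-len", context))
            identity = _opt_int(hsp, "Hsp_identity")
            positive = _opt_int(hsp, "Hsp_positive")
            frame = _opt_int(hsp, "Hsp_query-frame")
            try:
                records.append(HspRecord(
                    query_id=query_id,
                    hit_accession=accession,
                    evalue=float(evalue_text),
                    bitscore=float(bitscore_text),
                    align_len=align_len,
                    q_start=int(_req_text(hsp, "Hsp_query-from", context)),
                    q_end=int(_req_text(hsp, "Hsp_query-to", context)),
                    h_start=int(_req_text(hsp, "Hsp_hit-from", context)),
                    h_end=int(_req_text(hsp, "Hsp_hit-to", context)),
                    source_rank=rank,
                    query_len=query_len,
                    hit_len=hit_len,
                    hit_def=hit_def,
                    query_frame=frame,
                    identity_count=identity,
                    positive_count=positive,
                    pident=(compute_percent_identity(identity, align_len)
                            if identity is not None else None),
                    pconserved=(compute_percent_conserved(positive, align_len)
                                if positive is not None else None),
                    evalue_text=evalue_text,
                    bitscore_text=bitscore_text,
                ))
            except ValueError as exc:
                raise BlastParseError(f"{context}: {exc}") from exc
            rank += 1
    return QueryResult(query_id=query_id, query_len=query_len,
                       records=records, file_index=file_index)


def parse_xml(stream: Union[IO[bytes], IO[str]]) -> Iterator[QueryResult]:
    """Stream QueryResults out of a BLAST XML report (``-outfmt 5``).

    Yields one :class:`QueryResult` per ``<Iteration>`` in file order;
    every ``(Hit, Hsp)`` pair becomes one :class:`HspRecord`.  An empty
    stream yields nothing; malformed XML raises :class:`BlastParseError`
    naming the offending byte range.
    """
    parser = ET.XMLPullParser(events=("start", "end"))
    offset = 0
    seen_content = False
    file_index = 0
    container: Optional[ET.Element] = None

    def drain() -> Iterator[QueryResult]:
        nonlocal file_index, container
        events = parser.read_events()
        while True:
            try:
                event, elem = next(events)
            except StopIteration:
                return
            except ET.ParseError as exc:
                line, col = exc.position
                raise BlastParseError(
                    f"malformed XML near byte offset {offset}"
                    f" (line {line}, column {col}): {exc}"
                ) from exc
            if event == "start":
                if elem.tag == "BlastOutput_iterations":
                    container = elem
            elif elem.tag == "Iteration":
                yield _iteration_to_query(elem, file_index)
                file_index += 1
                # drop the processed subtree so memory stays bounded
                if container is not None:
                    container.clear()

    while True:
        chunk = stream.read(_XML_CHUNK_SIZE)
        if not chunk:
            break
        if not seen_content and chunk.strip():
            seen_content = True
        try:
            parser.feed(chunk)
        except ET.ParseError as exc:
            line, col = exc.position
            raise BlastParseError(
                f"malformed XML within byte offset {offset}-{offset + len(chunk)}"
                f" (line {line}, column {col}): {exc}"
            ) from exc
        offset += len(chunk)
        yield from drain()

    if not seen_content:
        return
    try:
        parser.close()
    except ET.ParseError as exc:
        line, col = exc.position
        raise BlastParseError(
            f"malformed XML at end of input, byte offset {offset}"
            f" (line {line}, column {col}): {exc}"
        ) from exc
    yield from drain()


# ---------------------------------------------------------------------------
# Tabular parsing (-outfmt 6)

# (column index, report name, converter) for the numeric standard columns
_TABULAR_NUMERIC = (
    (2, "pident", float),
    (3, "length", int),
    (4, "mismatch", int),
    (5, "gapopen", int),
    (6, "qstart", int),
    (7, "qend", int),
    (8, "sstart", int),
    (9, "send", int),
    (10, "evalue", float),
    (11, "bitscore", float),
)


def parse_tabular(stream: Union[IO[bytes], IO[str]],
                  has_salltitles: bool = False) -> Iterator[QueryResult]:
    """Stream QueryResults out of a BLAST tabular report (``-outfmt 6``).

    Rows are grouped into one :class:`QueryResult` per maximal contiguous
    run of equal ``qseqid`` (BLAST emits queries contiguously); a qseqid
    that re-appears non-contiguously is treated as a new query and logged.
    Lines starting with ``#`` (``-outfmt 7`` style headers) are skipped.
    """
    if isinstance(stream.read(0), bytes):
        stream = io.TextIOWrapper(stream, encoding="utf-8")
    expected = 13 if has_salltitles else 12

    current_id: Optional[str] = None
    current_records: list = []
    file_index = 0
    seen_ids: set = set()
    warned_comment = False

    def flush() -> QueryResult:
        nonlocal file_index
        result = QueryResult(query_id=current_id,
                             query_len=None,
                             records=current_records,
                             file_index=file_index)
        file_index += 1
        return result

    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\r\n")
        if not line:
            continue
        if line.startswith("#"):
            if not warned_comment:
                logger.debug("skipping comment lines ('#') in tabular input")
                warned_comment = True
            continue
        fields = line.split("\t")
        if len(fields) != expected:
            raise BlastParseError(
                f"line {lineno}: expected {expected} tab-separated columns, "
                f"found {len(fields)}"
            )
        values = {}
        for idx, name, conv in _TABULAR_NUMERIC:
            try:
                values[name] = conv(fields[idx])
            except ValueError as exc:
                raise BlastParseError(
                    f"line {lineno}, column {idx + 1} ({name}): "
                    f"non-numeric value {fields[idx]!r}"
                ) from exc

        qseqid = fields[0]
        if qseqid != current_id:
            if current_id is not None:
                yield flush()
            if qseqid in seen_ids:
                logger.warning(
                    "qseqid %r re-appears non-contiguously at line %d; "
                    "treated as a distinct query", qseqid, lineno)
            seen_ids.add(qseqid)
            current_id = qseqid
            current_records = []

        current_records.append(HspRecord(
            query_id=qseqid,
            hit_accession=fields[1],
            evalue=values["evalue"],
            bitscore=values["bitscore"],
            align_len=values["length"],
            q_start=values["qstart"],
            q_end=values["qend"],
            h_start=values["sstart"],
            h_end=values["send"],
            source_rank=len(current_records),
            hit_def=fields[12] if has_salltitles else None,
            pident=values["pident"],
            mismatch=values["mismatch"],
            gapopen=values["gapopen"],
            evalue_text=fields[10],
            bitscore_text=fields[11],
        ))

    if current_id is not None:
        yield flush()


# ---------------------------------------------------------------------------
# Format detection

_PEEK_SIZE = 1 << 16


def _peek_prefix(stream) -> Union[bytes, str]:
    if getattr(stream, "seekable", None) and stream.seekable():
        pos = stream.tell()
        data = stream.read(_PEEK_SIZE)
        stream.seek(pos)
        return data
    peek = getattr(stream, "peek", None)
    if peek is not None:
        return peek(_PEEK_SIZE)[:_PEEK_SIZE]
    raise UnrecognizedFormatError(
        "stream supports neither seeking nor peeking; "
        "pass an explicit format instead of auto-detecting")


def detect_format(stream) -> FormatTag:
    """Decide the input dialect from a bounded, non-consuming prefix read.

    XML is recognised by its declaration/root tag; otherwise the first
    non-comment line's tab-field count picks the tabular dialect.
    """
    prefix = _peek_prefix(stream)
    text = prefix.decode("utf-8", "replace") if isinstance(prefix, bytes) else prefix
    stripped = text.lstrip()
    if stripped.startswith(("<?xml", "<!DOCTYPE BlastOutput", "<BlastOutput")):
        return FormatTag.XML

    truncated = len(text) >= _PEEK_SIZE and not text.endswith(("\n", "\r"))
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#"):
            continue
        if truncated and i == len(lines) - 1:
            break  # line may be cut short; cannot judge its field count
        n_fields = len(line.split("\t"))
        if n_fields == 12:
            return FormatTag.TABULAR
        if n_fields == 13:
            return FormatTag.TABULAR_SALLTITLES
        raise UnrecognizedFormatError(
            f"first data line has {n_fields} tab-separated fields; "
            f"expected 12 or 13 (or BLAST XML)")
    raise UnrecognizedFormatError(
        "input prefix matches neither BLAST XML nor tabular output")


# ---------------------------------------------------------------------------
# Report writing

REPORT_COLUMNS = (
    "query_name", "query_length", "accession_number", "subject_length",
    "subject_description", "e-value", "bit_score", "query_frame",
    "query_start", "query_end", "hit_start", "hit_end",
    "percent_identity", "percent_conserved",
)

HEADER_LINE = "\t".join(REPORT_COLUMNS)


def _fmt_scored(value: float, raw: Optional[str]) -> str:
    return raw if raw is not None else f"{value:.2e}"


def _fmt_pct(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.2f}"


def _fmt_opt(value) -> str:
    return "NA" if value is None else str(value)


def format_record(r: HspRecord) -> str:
    """Render one report row (no trailing newline)."""
    return "\t".join((
        r.query_id,
        _fmt_opt(r.query_len),
        r.hit_accession,
        _fmt_opt(r.hit_len),
        r.hit_def if r.hit_def is not None else "NA",
        _fmt_scored(r.evalue, r.evalue_text),
        _fmt_scored(r.bitscore, r.bitscore_text),
        _fmt_opt(r.query_frame),
        str(r.q_start),
        str(r.q_end),
        str(r.h_start),
        str(r.h_end),
        _fmt_pct(r.pident),
        _fmt_pct(r.pconserved),
    ))


def write_tabular(queries: Iterable[QueryResult], stream: IO[str]) -> None:
    """Write the 14-column QC report: one header line, then one row per
    record in the given query order."""
    stream.write(HEADER_LINE + "\n")
    for query in queries:
        for record in query.records:
            stream.write(format_record(record) + "\n")
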