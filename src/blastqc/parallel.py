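"""Parallel execution: partition queries across worker processes and merge
results so that parallel output is byte-identical to a sequential run.

The parent alone reads the input stream (a pipe cannot be shared safely),
chunks whole queries into fixed-size work units to amortise inter-process
overhead, and writes worker results back in chunk order.  ``-p 1`` takes a
pure sequential path with no pool at all.
"""

from __future__ import annotations

import logging
import multiprocessing
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Optional, Tuple

from . import blast_io
from .blast_io import FormatTag, QueryResult
from .qc import ConfigurationError, QcConfig, qc_query, reset_warning_state

logger = logging.getLogger("blastqc")

__all__ = ["ParallelPlan", "RunSummary", "chunk_queries", "run", "run_parallel"]

DEFAULT_CHUNK_SIZE = 500


@dataclass
class ParallelPlan:
    """Worker-pool shape: ``n_processes=None`` means the detected CPU
    count; ``chunk_size`` is the number of whole queries per work unit."""

    n_processes: Optional[int] = None
    chunk_size: int = DEFAULT_CHUNK_SIZE

    def resolved_processes(self) -> int:
        if self.n_processes is None:
            return os.cpu_count() or 1
        return self.n_processes

    def validate(self) -> None:
        if self.n_processes is not None and self.n_processes < 1:
            raise ConfigurationError(
                f"number of processes must be >= 1, got {self.n_processes}")
        if self.chunk_size < 1:
            raise ConfigurationError(
                f"chunk_size must be >= 1, got {self.chunk_size}")


@dataclass
class RunSummary:
    queries: int = 0
    records_in: int = 0
    records_out: int = 0


def chunk_queries(queries: Iterable[QueryResult],
                  chunk_size: int) -> Iterator[Tuple[int, List[QueryResult]]]:
    """Partition the query stream into consecutive chunks of at most
    ``chunk_size`` whole queries, tagged with their ordinal."""
    if chunk_size < 1:
        raise ConfigurationError(f"chunk_size must be >= 1, got {chunk_size}")
    ordinal = 0
    buffer: List[QueryResult] = []
    for query in queries:
        buffer.append(query)
        if len(buffer) == chunk_size:
            yield ordinal, buffer
            ordinal += 1
            buffer = []
    if buffer:
        yield ordinal, buffer


def _qc_chunk(payload: Tuple[int, List[QueryResult], QcConfig]
              ) -> Tuple[int, List[QueryResult]]:
    ordinal, queries, config = payload
    return ordinal, [qc_query(q, config) for q in queries]


def run(input_stream, config: QcConfig, output: IO[str],
        plan: Optional[ParallelPlan] = None,
        format_tag: Optional[FormatTag] = None) -> RunSummary:
    """Detect/parse the input, QC every query, and write the report.

    With more than one process, chunks of queries are QC'd by a
    ``multiprocessing`` pool and written back in ordinal order, so output
    is byte-identical to a sequential run.  A worker failure fails the
    whole run; no partial output is silently kept.
    """
    plan = plan or ParallelPlan()
    plan.validate()
    config.validate()
    reset_warning_state()

    tag = format_tag or blast_io.detect_format(input_stream)
    if config.taxid_min is not None and tag is FormatTag.TABULAR:
        raise ConfigurationError(
            "a taxid threshold needs subject definitions, but plain "
            "12-column tabular input has none — use XML or tabular with "
            "salltitles")

    if tag is FormatTag.XML:
        queries = blast_io.parse_xml(input_stream)
    else:
        queries = blast_io.parse_tabular(
            input_stream,
            has_salltitles=(tag is FormatTag.TABULAR_SALLTITLES))

    summary = RunSummary()

    def counted(source: Iterable[QueryResult]) -> Iterator[QueryResult]:
        for query in source:
            summary.queries += 1
            summary.records_in += len(query.records)
            yield query

    def emit(result: QueryResult) -> None:
        summary.records_out += len(result.records)
        for record in result.records:
            output.write(blast_io.format_record(record) + "\n")

    output.write(blast_io.HEADER_LINE + "\n")
    n_processes = plan.resolved_processes()
    if n_processes == 1:
        for query in counted(queries):
            emit(qc_query(query, config))
    else:
        payloads = ((ordinal, chunk, config) for ordinal, chunk
                    in chunk_queries(counted(queries), plan.chunk_size))
        with multiprocessing.Pool(n_processes) as pool:
            for _ordinal, done in pool.imap(_qc_chunk, payloads):
                for result in done:
                    emit(result)
    logger.debug("run complete: %d queries, %d records in, %d records out",
                 summary.queries, summary.records_in, summary.records_out)
    return summary


run_parallel = run
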