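"""Quality-control engine: thresholds, ordering, range refinement, top-N.

This is the post-search replacement for ``-max_target_seqs``: instead of
limiting subjects *during* the BLAST search (which alters the heuristic
and the statistics), the full result file is filtered afterwards.  Per
query the pipeline is

    thresholds -> order by key -> optional range refinement -> top-N

where the informativeness of a hit is measured by its "taxid count": the
number of non-empty semicolon-separated fields in the subject definition
(SILVA-style lineages score high, "hypothetical protein" scores 1).
Range refinement keeps the familiar score ordering but, within an
additive window of the best score, prefers the most informative
definitions — trading a sliver of score for a usable annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .blast_io import BlastQcError, HspRecord, QueryResult

logger = logging.getLogger("blastqc")

__all__ = [
    "ConfigurationError",
    "QcConfig",
    "ORDER_KEYS",
    "count_taxids",
    "apply_thresholds",
    "order_hits",
    "apply_range_refinement",
    "select_top_n",
    "qc_query",
    "reset_warning_state",
]


class ConfigurationError(BlastQcError):
    """A QC configuration is internally inconsistent or out of range."""


ORDER_KEYS = ("evalue", "bitscore", "pident", "definition")

# warn once per run when a set threshold meets a record lacking the field
_warned_missing: set = set()


def reset_warning_state() -> None:
    _warned_missing.clear()


def _warn_missing_once(field: str) -> None:
    if field not in _warned_missing:
        _warned_missing.add(field)
        logger.warning(
            "threshold on %s set but some records lack the field; "
            "those records are excluded", field)


def count_taxids(hit_def: Optional[str]) -> int:
    """Number of non-empty ';'-separated fields in a subject definition —
    the informativeness proxy (taxonomic or functional level of detail)."""
    if not hit_def:
        return 0
    return sum(1 for part in hit_def.split(";") if part.strip())


@dataclass
class QcConfig:
    """User-facing QC settings.

    Thresholds are inclusive (``evalue <= evalue_max``, minima via ``>=``)
    and conjunctive; an unset threshold filters nothing.  ``n_hits=None``
    returns all surviving records, ordered — the tool's default mode.  At
    most one range delta may be set, and only together with the matching
    ``order_key``.
    """

    evalue_max: Optional[float] = None
    bitscore_min: Optional[float] = None
    pident_min: Optional[float] = None
    taxid_min: Optional[int] = None
    order_key: str = "evalue"
    n_hits: Optional[int] = None
    evalue_range: Optional[float] = None
    bitscore_range: Optional[float] = None
    pident_range: Optional[float] = None

    def range_delta(self) -> Optional[float]:
        for delta in (self.evalue_range, self.bitscore_range, self.pident_range):
            if delta is not None:
                return delta
        return None

    def validate(self) -> None:
        if self.order_key not in ORDER_KEYS:
            raise ConfigurationError(
                f"unknown order key {self.order_key!r}; expected one of {ORDER_KEYS}")
        if self.n_hits is not None and self.n_hits < 1:
            raise ConfigurationError(f"n_hits must be >= 1, got {self.n_hits}")
        if self.evalue_max is not None and self.evalue_max < 0:
            raise ConfigurationError("evalue_max must be non-negative")
        if self.pident_min is not None and not 0 <= self.pident_min <= 100:
            raise ConfigurationError("pident_min must lie in [0, 100]")
        if self.taxid_min is not None and self.taxid_min < 0:
            raise ConfigurationError("taxid_min must be non-negative")
        ranges = [("evalue_range", self.evalue_range, "evalue"),
                  ("bitscore_range", self.bitscore_range, "bitscore"),
                  ("pident_range", self.pident_range, "pident")]
        set_ranges = [(name, delta, key) for name, delta, key in ranges
                      if delta is not None]
        if len(set_ranges) > 1:
            names = ", ".join(name for name, _, _ in set_ranges)
            raise ConfigurationError(f"at most one range may be set; got {names}")
        for name, delta, key in set_ranges:
            if delta < 0:
                raise ConfigurationError(f"{name} must be non-negative")
            if self.order_key != key:
                raise ConfigurationError(
                    f"{name} requires order_key={key!r}, got {self.order_key!r}")


# ---------------------------------------------------------------------------
# Thresholds

def _record_passes(record: HspRecord, config: QcConfig) -> bool:
    if config.evalue_max is not None and record.evalue > config.evalue_max:
        return False
    if config.bitscore_min is not None and record.bitscore < config.bitscore_min:
        return False
    if config.pident_min is not None:
        if record.pident is None:
            _warn_missing_once("percent identity")
            return False
        if record.pident < config.pident_min:
            return False
    if config.taxid_min is not None:
        if record.hit_def is None:
            _warn_missing_once("hit definition (taxids)")
            return False
        if count_taxids(record.hit_def) < config.taxid_min:
            return False
    return True


def apply_thresholds(query: QueryResult, config: QcConfig) -> QueryResult:
    """Keep the records satisfying every set threshold, in input order.

    A record missing a field a set threshold needs fails that threshold
    (QC fails safe) and a warning is logged once per run.
    """
    kept = [r for r in query.records if _record_passes(r, config)]
    return QueryResult(query_id=query.query_id, query_len=query.query_len,
                       records=kept, file_index=query.file_index)


# ---------------------------------------------------------------------------
# Ordering

def _primary_metric(record: HspRecord, order_key: str) -> float:
    if order_key == "evalue":
        return record.evalue
    if order_key == "bitscore":
        return -record.bitscore
    if order_key == "pident":
        return -(record.pident if record.pident is not None else 0.0)
    if order_key == "definition":
        return -count_taxids(record.hit_def)
    raise ConfigurationError(
        f"unknown order key {order_key!r}; expected one of {ORDER_KEYS}")


def composite_key(record: HspRecord, order_key: str) -> Tuple:
    """Total deterministic sort key: the primary metric, then e-value
    ascending, bit score descending, percent identity descending, and
    finally original file position."""
    pident = record.pident if record.pident is not None else 0.0
    return (_primary_metric(record, order_key),
            record.evalue, -record.bitscore, -pident, record.source_rank)


def order_hits(records: Sequence[HspRecord], order_key: str) -> List[HspRecord]:
    """Sort records by the chosen key (e-value ascending; bit score,
    percent identity and definition taxid count descending)."""
    if order_key not in ORDER_KEYS:
        raise ConfigurationError(
            f"unknown order key {order_key!r}; expected one of {ORDER_KEYS}")
    return sorted(records, key=lambda r: composite_key(r, order_key))


# ---------------------------------------------------------------------------
# Range refinement

def apply_range_refinement(ordered: Sequence[HspRecord], order_key: str,
                           delta: float) -> List[HspRecord]:
    """Within ``delta`` of the best record's key value (inclusive, additive:
    best + delta for e-value, best - delta for bit score / percent
    identity), re-rank by definition informativeness — most taxids first,
    ties broken by the ordering composite key.  Records outside the window
    keep their existing order after the window."""
    if delta < 0:
        raise ConfigurationError(f"range delta must be non-negative, got {delta}")
    if order_key not in ("evalue", "bitscore", "pident"):
        raise ConfigurationError(
            f"range refinement applies to evalue/bitscore/pident, not {order_key!r}")
    ordered = list(ordered)
    if not ordered:
        return ordered

    def metric(r: HspRecord) -> float:
        if order_key == "evalue":
            return r.evalue
        if order_key == "bitscore":
            return r.bitscore
        return r.pident if r.pident is not None else 0.0

    best = metric(ordered[0])
    if order_key == "evalue":
        within = lambda r: metric(r) <= best + delta
    else:
        within = lambda r: metric(r) >= best - delta
    in_window = [r for r in ordered if within(r)]
    outside = [r for r in ordered if not within(r)]
    in_window.sort(key=lambda r: (-count_taxids(r.hit_def),)
                   + composite_key(r, order_key))
    return in_window + outside


# ---------------------------------------------------------------------------
# Top-N and composition

def select_top_n(ordered: Sequence[HspRecord],
                 n: Optional[int]) -> List[HspRecord]:
    """First ``min(n, len)`` records of the final ranking; ``n=None``
    keeps everything."""
    if n is None:
        return list(ordered)
    if n < 1:
        raise ConfigurationError(f"n_hits must be >= 1, got {n}")
    return list(ordered[:n])


def qc_query(query: QueryResult, config: QcConfig) -> QueryResult:
    """Run the full QC pipeline on one query's candidate records."""
    config.validate()
    kept = apply_thresholds(query, config)
    ranked = order_hits(kept.records, config.order_key)
    delta = config.range_delta()
    if delta is not None:
        ranked = apply_range_refinement(ranked, config.order_key, delta)
    ranked = select_top_n(ranked, config.n_hits)
    return QueryResult(query_id=query.query_id, query_len=query.query_len,
                       records=ranked, file_index=query.file_index)
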