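import random

import pytest
from hypothesis import HealthCheck, settings

from blastqc.blast_io import HspRecord, QueryResult
from blastqc.qc import QcConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

_DEFS = [
    None,
    "",
    "hypothetical protein",
    "protein of unknown function DUF1680",
    "Bacteria;Proteobacteria",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Vibrionales",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus",
]


def random_record(rng: random.Random, source_rank: int,
                  query_id: str = "q") -> HspRecord:
    """One random candidate row; fields deliberately collide often so that
    tie-breaking paths are exercised."""
    align_len = rng.randint(50, 500)
    identity = rng.randint(10, align_len)
    return HspRecord(
        query_id=query_id,
        hit_accession=f"acc{source_rank}",
        evalue=rng.choice([10.0 ** rng.uniform(-50, 1),
                           rng.choice([1e-10, 1e-5, 0.001])]),
        bitscore=rng.choice([rng.uniform(20, 400), rng.choice([60.0, 100.0])]),
        align_len=align_len,
        q_start=1, q_end=align_len, h_start=1, h_end=align_len,
        source_rank=source_rank,
        hit_def=rng.choice(_DEFS),
        pident=rng.choice([100.0 * identity / align_len, None]),
        identity_count=identity,
    )


def random_query(rng: random.Random, max_records: int = 100,
                 file_index: int = 0) -> QueryResult:
    n = rng.randint(0, max_records)
    return QueryResult(query_id=f"q{file_index}", query_len=None,
                       records=[random_record(rng, i, f"q{file_index}")
                                for i in range(n)],
                       file_index=file_index)


def random_config(rng: random.Random) -> QcConfig:
    order_key = rng.choice(["evalue", "bitscore", "pident", "definition"])
    cfg = QcConfig(
        evalue_max=rng.choice([None, 1e-20, 1e-5, 0.01, 10.0]),
        bitscore_min=rng.choice([None, 50.0, 100.0, 250.0]),
        pident_min=rng.choice([None, 30.0, 60.0, 90.0]),
        taxid_min=rng.choice([None, 1, 2, 4]),
        order_key=order_key,
        n_hits=rng.choice([None, 1, 3, 10]),
    )
    if order_key != "definition" and rng.random() < 0.5:
        delta = rng.choice([0.0, 1e-6, 1e-3, 5.0, 20.0])
        if order_key == "evalue":
            cfg.evalue_range = delta
        elif order_key == "bitscore":
            cfg.bitscore_range = delta
        else:
            cfg.pident_range = delta
    return cfg


@pytest.fixture
def rng():
    return random.Random(20260930)
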