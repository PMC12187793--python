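"""Shared fixtures: hand-built site tables, toy transcript models, and
random-model generators used by the brute-force geometry oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from m5cscope.io_model import (
    SITE_COLUMNS,
    SiteTable,
    TranscriptCatalog,
    TranscriptModel,
)


def make_site_table(rows, sample_id="S"):
    """rows: iterable of (transcript_id, position, kmer9, coverage,
    stoichiometry, probability)."""
    df = pd.DataFrame(
        [(sample_id, *r) for r in rows], columns=list(SITE_COLUMNS)
    )
    df["position"] = df["position"].astype(np.int64)
    df["coverage"] = df["coverage"].astype(np.int64)
    return SiteTable(df, provenance=("fixture",))


def random_transcript_model(rng: np.random.Generator, tid: str = "tx",
                            coding: bool = True) -> TranscriptModel:
    """A random valid multi-exon transcript model."""
    n_ex = int(rng.integers(1, 6))
    pos = int(rng.integers(0, 10_000))
    exons = []
    for _ in range(n_ex):
        length = int(rng.integers(20, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(50, 500))
    strand = "+" if rng.random() < 0.5 else "-"
    order = tuple(exons) if strand == "+" else tuple(exons[::-1])
    total = sum(e - s for s, e in exons)
    cds_start = cds_end = None
    if coding and total >= 30:
        cds_start = int(rng.integers(1, total // 3))
        cds_end = int(rng.integers(cds_start + 1, total))
    return TranscriptModel(tid, f"g_{tid}", "chr1", strand, order, cds_start, cds_end)


def walk_genomic_bases(model: TranscriptModel) -> list[int]:
    """Brute-force oracle: genomic base under every transcript position,
    enumerated one base at a time in transcription order."""
    bases: list[int] = []
    for s, e in model.exons:
        if model.strand == "+":
            bases.extend(range(s, e))
        else:
            bases.extend(range(e - 1, s - 1, -1))
    return bases


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def toy_gtf(tmp_path):
    """Three transcripts: plus-strand two-exon coding, minus-strand
    two-exon coding, single-exon non-coding."""
    text = "\n".join([
        'chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        'chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        'chr1\ttest\tCDS\t151\t200\t.\t+\t0\tgene_id "gA"; transcript_id "tA";',
        'chr1\ttest\tCDS\t301\t350\t.\t+\t0\tgene_id "gA"; transcript_id "tA";',
        'chr2\ttest\texon\t101\t200\t.\t-\t.\tgene_id "gB"; transcript_id "tB";',
        'chr2\ttest\texon\t301\t400\t.\t-\t.\tgene_id "gB"; transcript_id "tB";',
        'chr2\ttest\tCDS\t121\t200\t.\t-\t0\tgene_id "gB"; transcript_id "tB";',
        'chr2\ttest\tCDS\t351\t400\t.\t-\t0\tgene_id "gB"; transcript_id "tB";',
        'chr1\ttest\texon\t1001\t1500\t.\t+\t.\tgene_id "gC"; transcript_id "tC";',
    ]) + "\n"
    path = tmp_path / "toy.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def simple_catalog():
    """In-memory catalog: one 600-nt coding transcript (5'UTR 100, CDS
    300, 3'UTR 200) over three exons of 300/200/100 plus a single-exon
    non-coding transcript."""
    coding = TranscriptModel(
        "tx1", "g1", "chr1", "+",
        ((1000, 1300), (2000, 2200), (3000, 3100)),
        cds_start_t=100, cds_end_t=400,
    )
    nc = TranscriptModel("tx2", "g2", "chr1", "+", ((5000, 5400),))
    return TranscriptCatalog({"tx1": coding, "tx2": nc})
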