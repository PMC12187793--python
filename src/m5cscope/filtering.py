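"""Site-selection funnel and set summaries.

A per-site caller reports every tested cytosine with a prediction
probability.  Downstream analysis keeps only high-confidence sites:
coverage of at least eight reads and probability strictly above 0.9999
(a cutoff at which the caller's benchmarked false-discovery rate is
essentially zero).  The funnel report tracks how many cytosines survive
each tier: tested -> called (probability above a softer "called" bound)
-> high confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import SiteTable, TranscriptCatalog, ValidationError

__all__ = [
    "FunnelReport",
    "filter_sites",
    "replicate_consensus",
    "sites_per_gene",
    "shared_site_sets",
]


@dataclass(frozen=True)
class FunnelReport:
    """Counts of cytosines surviving each selection tier."""

    n_tested: int
    n_called: int
    n_high_confidence: int

    def __post_init__(self) -> None:
        if not self.n_high_confidence <= self.n_called <= self.n_tested:
            raise ValidationError(
                f"funnel counts not nested: {self.n_high_confidence} <= "
                f"{self.n_called} <= {self.n_tested} violated"
            )

    @property
    def fraction_called(self) -> float:
        return self.n_called / self.n_tested if self.n_tested else float("nan")

    @property
    def fraction_high_confidence(self) -> float:
        return self.n_high_confidence / self.n_tested if self.n_tested else float("nan")


def filter_sites(
    table: SiteTable,
    min_coverage: int = 8,
    min_probability: float = 0.9999,
    called_probability: float = 0.5,
) -> tuple[SiteTable, FunnelReport]:
    """Apply the coverage floor and the high-confidence probability cutoff.

    A row is retained iff ``coverage >= min_coverage`` and
    ``probability > min_probability`` (strictly greater).  The middle
    "called" tier of the funnel counts rows meeting the coverage floor
    with ``probability > called_probability``.
    """
    if min_coverage < 1:
        raise ValidationError(f"min_coverage must be >= 1, got {min_coverage}")
    df = table.df
    covered = df["coverage"] >= min_coverage
    # the "called" tier is the softer of the two bounds so the funnel nests
    called = covered & (df["probability"] > min(called_probability, min_probability))
    high = covered & (df["probability"] > min_probability)
    report = FunnelReport(len(df), int(called.sum()), int(high.sum()))
    out = SiteTable(
        df[high].reset_index(drop=True),
        provenance=table.provenance
        + (f"filter coverage>={min_coverage} probability>{min_probability}",),
    )
    return out, report


def replicate_consensus(
    rep1: SiteTable,
    rep2: SiteTable,
    max_stoich_delta: float = 0.1,
) -> SiteTable:
    """Keep sites called consistently in both replicates.

    A site survives iff it is present in both replicates and the two
    stoichiometry estimates differ by at most ``max_stoich_delta``.  The
    consensus stoichiometry (and probability) is the coverage-weighted
    mean; consensus coverage is the sum.
    """
    key = ["transcript_id", "position"]
    merged = rep1.df.merge(rep2.df, on=key, suffixes=("_1", "_2"))
    keep = (merged["stoichiometry_1"] - merged["stoichiometry_2"]).abs() <= max_stoich_delta
    merged = merged[keep]
    cov = merged["coverage_1"] + merged["coverage_2"]
    w1 = merged["coverage_1"] / cov
    w2 = merged["coverage_2"] / cov
    df = pd.DataFrame(
        {
            "sample_id": merged["sample_id_1"],
            "transcript_id": merged["transcript_id"],
            "position": merged["position"],
            "kmer9": merged["kmer9_1"],
            "coverage": cov,
            "stoichiometry": w1 * merged["stoichiometry_1"] + w2 * merged["stoichiometry_2"],
            "probability": w1 * merged["probability_1"] + w2 * merged["probability_2"],
        }
    ).reset_index(drop=True)
    return SiteTable(
        df,
        provenance=rep1.provenance
        + (f"replicate consensus |d stoichiometry|<={max_stoich_delta}, "
           "coverage-weighted merge",),
    )


def sites_per_gene(
    table: SiteTable,
    catalog: TranscriptCatalog,
    by_genomic_position: bool = True,
    warn: list[str] | None = None,
) -> tuple[pd.Series, float]:
    """Distinct m5C sites per gene, pooled over that gene's transcripts.

    With ``by_genomic_position`` (default) sites shared by splice variants
    at the same genomic base count once; otherwise each (transcript,
    position) pair counts.  Returns (per-gene counts, median over genes).
    Sites on transcripts absent from the catalog are tallied in ``warn``.
    """
    keys: set[tuple[str, object]] = set()
    unresolved = 0
    for row in table.df.itertuples(index=False):
        model = catalog.get(row.transcript_id)
        if model is None:
            unresolved += 1
            continue
        if by_genomic_position:
            chrom, g, _ = model.transcript_to_genome(int(row.position))
            keys.add((model.gene_id, (chrom, g)))
        else:
            keys.add((model.gene_id, (row.transcript_id, int(row.position))))
    if unresolved and warn is not None:
        warn.append(f"{unresolved} site(s) on transcripts absent from the catalog")
    counts = pd.Series(
        [g for g, _ in keys], dtype="object", name="gene_id"
    ).value_counts().sort_index()
    counts.name = "n_sites"
    median = float(np.median(counts.values)) if len(counts) else float("nan")
    return counts, median


def shared_site_sets(
    tables: Mapping[str, SiteTable],
    catalog: TranscriptCatalog | None = None,
    by_gene: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Presence/absence of site keys across samples (Venn-cell counts).

    Keys are (transcript_id, position) by default, or gene_id when
    ``by_gene`` (requires a catalog to resolve transcripts to genes).
    Returns the boolean membership matrix (rows = keys, columns = sample
    names) and a mapping from each non-empty sample subset to its count
    of keys present in exactly that subset.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValidationError("need at least 2 tables")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate sample names")
    member: dict[object, dict[str, bool]] = {}
    for name, table in tables.items():
        if by_gene:
            if catalog is None:
                raise ValidationError("by_gene requires a catalog")
            keys = {
                catalog[tid].gene_id
                for tid in table.df["transcript_id"]
                if tid in catalog
            }
        else:
            keys = table.site_keys()
        for k in keys:
            member.setdefault(k, {})[name] = True
    matrix = pd.DataFrame(
        [[bool(member[k].get(n)) for n in names] for k in member],
        index=pd.Index(list(member), tupleize_cols=False, name="key"),
        columns=names,
    )
    cells: dict[tuple[str, ...], int] = {}
    for _, row in matrix.iterrows():
        subset = tuple(n for n in names if row[n])
        cells[subset] = cells.get(subset, 0) + 1
    return matrix, cells
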