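"""Transcript-coordinate geometry: genomic projection, metatranscript
(5'UTR/CDS/3'UTR) scaling, splice-junction distances and chromosome
window densities.

The metatranscript axis maps each of the three mRNA regions linearly onto
a unit interval: 5'UTR -> [0, 1), CDS -> [1, 2), 3'UTR -> [2, 3).  The
start codon sits at 1.0 and the stop codon boundary at 2.0, so profiles
from transcripts with different region lengths are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import SiteTable, TranscriptCatalog, TranscriptModel, ValidationError

__all__ = [
    "MetageneProfile",
    "JunctionDistanceHistogram",
    "transcript_to_genome",
    "genome_to_transcript",
    "metagene_coordinate",
    "metagene_profile",
    "junction_distance",
    "junction_distance_histogram",
    "junction_zone_classification",
    "genomic_window_density",
    "project_sites",
]


def transcript_to_genome(model: TranscriptModel, position: int) -> tuple[str, int, str]:
    """Genomic (chromosome, base, strand) under a transcript coordinate."""
    return model.transcript_to_genome(position)


def genome_to_transcript(model: TranscriptModel, genomic_position: int) -> int:
    """Inverse of :func:`transcript_to_genome`; raises for non-exonic bases."""
    return model.genome_to_transcript(genomic_position)


def metagene_coordinate(model: TranscriptModel, position: int) -> float | None:
    """Scaled metatranscript coordinate in [0, 3) of a transcript position.

    Returns None for non-coding transcripts (they carry no UTR/CDS
    partition and are tallied separately by :func:`metagene_profile`).
    Region boundaries follow the half-open convention: the first CDS base
    maps to exactly 1.0 and the first 3'UTR base to exactly 2.0.
    """
    if not model.is_coding:
        return None
    if not 0 <= position < model.length:
        raise ValidationError(
            f"{model.transcript_id}: position {position} outside [0, {model.length})"
        )
    u5, c, u3 = model.region_lengths()
    if position < u5:
        return position / u5
    if position < u5 + c:
        return 1.0 + (position - u5) / c
    return 2.0 + (position - u5 - c) / u3


@dataclass(frozen=True)
class MetageneProfile:
    """Binned site density over the scaled [0, 3) metatranscript axis."""

    edges: np.ndarray          # bin edges, length n_bins + 1
    density: np.ndarray        # per-bin fraction of mapped sites
    n_mapped: int
    n_noncoding: int           # sites on non-coding transcripts (skipped)
    n_unresolved: int          # sites on transcripts absent from the catalog

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.edges[:-1],
                "bin_end": self.edges[1:],
                "density": self.density,
            }
        )


def metagene_profile(
    table: SiteTable,
    catalog: TranscriptCatalog,
    n_bins: int = 90,
) -> MetageneProfile:
    """Metatranscript density profile of a site table.

    ``n_bins`` spans the full [0, 3) axis (a multiple of 3 keeps region
    boundaries on bin edges; the default gives 30 bins per region).
    Densities sum to 1 over mapped sites.
    """
    coords: list[float] = []
    n_noncoding = n_unresolved = 0
    for row in table.df.itertuples(index=False):
        model = catalog.get(row.transcript_id)
        if model is None:
            n_unresolved += 1
            continue
        x = metagene_coordinate(model, int(row.position))
        if x is None:
            n_noncoding += 1
        else:
            coords.append(x)
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    counts, _ = np.histogram(coords, bins=edges)
    total = counts.sum()
    density = counts / total if total else counts.astype(float)
    return MetageneProfile(edges, density, int(total), n_noncoding, n_unresolved)


def junction_distance(model: TranscriptModel, position: int) -> int | None:
    """Distance (nt) from a transcript position to the nearest splice
    junction; None for single-exon transcripts.

    Junctions sit at cumulative exon lengths (a junction coordinate names
    the first base of the downstream exon), so ``distance == 0`` iff the
    position is the first base of a non-first exon.
    """
    if not 0 <= position < model.length:
        raise ValidationError(
            f"{model.transcript_id}: position {position} outside [0, {model.length})"
        )
    junctions = model.junctions()
    if not junctions:
        return None
    return min(abs(position - j) for j in junctions)


def signed_junction_distance(model: TranscriptModel, position: int) -> int | None:
    """Signed distance to the nearest junction: negative = upstream (5')
    of the junction, non-negative = at/downstream."""
    if not 0 <= position < model.length:
        raise ValidationError(
            f"{model.transcript_id}: position {position} outside [0, {model.length})"
        )
    junctions = model.junctions()
    if not junctions:
        return None
    return min((position - j for j in junctions), key=abs)


@dataclass(frozen=True)
class JunctionDistanceHistogram:
    """Histogram of site-to-junction distances."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_undefined: int  # single-exon (no junction) sites
    n_unresolved: int
    signed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def junction_distance_histogram(
    table: SiteTable,
    catalog: TranscriptCatalog,
    bin_width: int = 50,
    max_distance: int = 1000,
    signed: bool = False,
) -> JunctionDistanceHistogram:
    """Histogram of distances from sites to their nearest splice junction.

    Distances beyond ``max_distance`` are clamped into the last (or, when
    signed, outermost) bin so the histogram mass equals the number of
    sites with a defined distance.
    """
    dists: list[int] = []
    n_undefined = n_unresolved = 0
    for row in table.df.itertuples(index=False):
        model = catalog.get(row.transcript_id)
        if model is None:
            n_unresolved += 1
            continue
        d = (signed_junction_distance if signed else junction_distance)(
            model, int(row.position)
        )
        if d is None:
            n_undefined += 1
        else:
            dists.append(d)
    if signed:
        edges = np.arange(-max_distance, max_distance + bin_width, bin_width)
        clipped = np.clip(dists, -max_distance, max_distance - 1)
    else:
        edges = np.arange(0, max_distance + bin_width, bin_width)
        clipped = np.clip(dists, 0, max_distance - 1)
    counts, _ = np.histogram(clipped, bins=edges)
    return JunctionDistanceHistogram(edges, counts, n_undefined, n_unresolved, signed)


def junction_zone_classification(
    table: SiteTable,
    catalog: TranscriptCatalog,
    proximal: int = 100,
    flank_max: int = 400,
) -> pd.DataFrame:
    """Classify sites by distance to the nearest splice junction.

    Zones: ``proximal`` = distance in [0, proximal] (closed), ``flank`` =
    (proximal, flank_max], ``distal`` = > flank_max, ``undefined`` =
    single-exon transcript, ``unresolved`` = transcript not in catalog.
    """
    zones = {"proximal": 0, "flank": 0, "distal": 0, "undefined": 0, "unresolved": 0}
    for row in table.df.itertuples(index=False):
        model = catalog.get(row.transcript_id)
        if model is None:
            zones["unresolved"] += 1
            continue
        d = junction_distance(model, int(row.position))
        if d is None:
            zones["undefined"] += 1
        elif d <= proximal:
            zones["proximal"] += 1
        elif d <= flank_max:
            zones["flank"] += 1
        else:
            zones["distal"] += 1
    total = sum(zones.values())
    return pd.DataFrame(
        {
            "zone": list(zones),
            "count": list(zones.values()),
            "fraction": [v / total if total else float("nan") for v in zones.values()],
        }
    )


def project_sites(
    table: SiteTable,
    catalog: TranscriptCatalog,
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """Genomic projection of every resolvable site.

    Returns a frame with chromosome, genomic_position (0-based), strand
    plus the original transcript key.  Unresolvable transcripts are
    tallied in ``warn``.
    """
    rows = []
    unresolved = 0
    for row in table.df.itertuples(index=False):
        model = catalog.get(row.transcript_id)
        if model is None:
            unresolved += 1
            continue
        chrom, g, strand = model.transcript_to_genome(int(row.position))
        rows.append((row.transcript_id, int(row.position), chrom, g, strand))
    if unresolved and warn is not None:
        warn.append(f"{unresolved} site(s) on transcripts absent from the catalog")
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "position", "chromosome", "genomic_position", "strand"],
    )


def genomic_window_density(
    table: SiteTable,
    catalog: TranscriptCatalog,
    window: int = 27_000_000,
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """Count distinct genomic m5C bases per fixed chromosome window.

    Windows tile each chromosome half-open: [0, W), [W, 2W), ...  Sites
    sharing a genomic base (splice variants) count once.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    proj = project_sites(table, catalog, warn=warn)
    dedup = proj.drop_duplicates(subset=["chromosome", "genomic_position"])
    if dedup.empty:
        return pd.DataFrame(columns=["chromosome", "window_index", "count"])
    out = (
        dedup.assign(window_index=dedup["genomic_position"] // window)
        .groupby(["chromosome", "window_index"])
        .size()
        .reset_index(name="count")
        .sort_values(["chromosome", "window_index"])
        .reset_index(drop=True)
    )
    return out
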