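"""Domain types and readers/writers for per-site m5C call tables, transcript
annotation, expression tables and qPCR Ct tables.

The central record is one called cytosine in one sample: its transcript,
its 0-based position on the spliced transcript, the 9-mer sequence context
centered on the C, read coverage, methylation stoichiometry (fraction of
reads carrying the modification) and the caller's prediction probability.
Tables of such records are the input to every downstream stage.

Coordinate conventions
----------------------
* Site positions are 0-based on the spliced transcript and point at the C
  itself.  Callers that index the start of a k-mer window can be adapted at
  parse time with ``position_offset``.
* GTF annotation (1-based, closed intervals) is converted on read to
  0-based half-open intervals.  Exons are stored in transcription order,
  i.e. reversed for minus-strand transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "M5CSite",
    "SiteTable",
    "TranscriptModel",
    "TranscriptCatalog",
    "ExpressionTable",
    "CtTable",
    "SITE_COLUMNS",
    "read_site_table",
    "read_annotation",
    "read_expression",
    "read_ct_table",
    "read_fasta",
    "write_table",
    "write_gtf",
    "write_fasta",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


#: Canonical column order of the site-table TSV dialect.
SITE_COLUMNS = (
    "sample_id",
    "transcript_id",
    "position",
    "kmer9",
    "coverage",
    "stoichiometry",
    "probability",
)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class M5CSite:
    """One called cytosine in one sample."""

    sample_id: str
    transcript_id: str
    position: int
    kmer9: str
    coverage: int
    stoichiometry: float
    probability: float

    def problems(self) -> list[str]:
        """Return invariant violations as human-readable messages."""
        out: list[str] = []
        if len(self.kmer9) != 9 or not set(self.kmer9) <= _BASES:
            out.append(f"kmer9 {self.kmer9!r} is not a 9-mer over ACGT")
        elif self.kmer9[4] != "C":
            out.append(f"kmer9 {self.kmer9!r} center base is not C")
        if self.position < 0:
            out.append(f"position {self.position} is negative")
        if self.coverage < 0:
            out.append(f"coverage {self.coverage} is negative")
        if not 0.0 <= self.stoichiometry <= 1.0:
            out.append(f"stoichiometry {self.stoichiometry} outside [0, 1]")
        if not 0.0 <= self.probability <= 1.0:
            out.append(f"probability {self.probability} outside [0, 1]")
        return out


@dataclass(frozen=True)
class SiteTable:
    """An ordered collection of m5C sites with provenance.

    ``df`` always carries the canonical :data:`SITE_COLUMNS`.  ``provenance``
    records the source and every filter applied, in order.  ``rejected``
    carries row-numbered diagnostics for rows dropped in lenient parsing.
    """

    df: pd.DataFrame
    provenance: tuple[str, ...] = ()
    rejected: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterable[M5CSite]:
        for row in self.df.itertuples(index=False):
            yield M5CSite(
                row.sample_id, row.transcript_id, int(row.position), row.kmer9,
                int(row.coverage), float(row.stoichiometry), float(row.probability),
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df["sample_id"].unique())

    def with_provenance(self, note: str) -> "SiteTable":
        return replace(self, provenance=self.provenance + (note,))

    def site_keys(self) -> set[tuple[str, int]]:
        return set(zip(self.df["transcript_id"], self.df["position"].astype(int)))

    @classmethod
    def from_sites(cls, sites: Sequence[M5CSite], provenance: tuple[str, ...] = ()) -> "SiteTable":
        df = pd.DataFrame([s.__dict__ for s in sites], columns=list(SITE_COLUMNS))
        return cls(_coerce_site_frame(df), provenance)


def _coerce_site_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df[list(SITE_COLUMNS)].copy()
    df["position"] = df["position"].astype(np.int64)
    df["coverage"] = df["coverage"].astype(np.int64)
    df["stoichiometry"] = df["stoichiometry"].astype(float)
    df["probability"] = df["probability"].astype(float)
    return df.reset_index(drop=True)


def _validate_site_frame(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Row-numbered invariant diagnostics (0-based data row numbers)."""
    bad: list[tuple[int, str]] = []
    kmers = df["kmer9"].astype(str)
    ok_kmer = kmers.str.len().eq(9) & kmers.str.fullmatch("[ACGT]{9}", na=False)
    for i in df.index[~ok_kmer]:
        bad.append((i, f"kmer9 {df.at[i, 'kmer9']!r} is not a 9-mer over ACGT"))
    center_bad = ok_kmer & (kmers.str[4] != "C")
    for i in df.index[center_bad]:
        bad.append((i, f"kmer9 {df.at[i, 'kmer9']!r} center base is not C"))
    for i in df.index[df["position"] < 0]:
        bad.append((i, f"position {df.at[i, 'position']} is negative"))
    for i in df.index[df["coverage"] < 0]:
        bad.append((i, f"coverage {df.at[i, 'coverage']} is negative"))
    s = df["stoichiometry"]
    for i in df.index[(s < 0) | (s > 1) | s.isna()]:
        bad.append((i, f"stoichiometry {df.at[i, 'stoichiometry']} outside [0, 1]"))
    p = df["probability"]
    for i in df.index[(p < 0) | (p > 1) | p.isna()]:
        bad.append((i, f"probability {df.at[i, 'probability']} outside [0, 1]"))
    dup = df.duplicated(subset=["sample_id", "transcript_id", "position"], keep="first")
    for i in df.index[dup]:
        bad.append((i, f"duplicate site ({df.at[i, 'transcript_id']}, {df.at[i, 'position']})"))
    return sorted(set(bad))


#: Default column names of the CHEUI-solo style per-site output dialect.
DEFAULT_COLUMN_MAP = {
    "transcript_id": "transcript_id",
    "position": "position",
    "kmer9": "kmer9",
    "coverage": "coverage",
    "stoichiometry": "stoichiometry",
    "probability": "probability",
}


def read_site_table(
    path: str | Path,
    sample_id: str,
    column_map: Mapping[str, str] | None = None,
    position_offset: int = 0,
    strict: bool = True,
) -> SiteTable:
    """Read a tab-separated per-site m5C call table.

    Parameters
    ----------
    path
        TSV file with a header row.
    sample_id
        Sample label attached to every row (the file itself need not carry
        one).  If the file has a ``sample_id`` column it must agree.
    column_map
        Maps canonical field names (``transcript_id``, ``position``,
        ``kmer9``, ``coverage``, ``stoichiometry``, ``probability``) to the
        column names used in the file.
    position_offset
        Added to the parsed position, for callers that report the start of
        the 9-mer window rather than the C itself (offset 4 in that case).
    strict
        If True (default) any invariant violation raises
        :class:`ValidationError`.  If False, offending rows are dropped and
        reported in ``SiteTable.rejected``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype={cmap["kmer9"]: str})
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = pd.DataFrame({k: raw[v] for k, v in cmap.items()})
    df["sample_id"] = sample_id
    df["position"] = df["position"].astype(np.int64) + position_offset
    df = _coerce_site_frame(df)
    problems = _validate_site_frame(df)
    if problems and strict:
        detail = "; ".join(f"row {i + 1}: {msg}" for i, msg in problems[:20])
        raise ValidationError(f"{path}: {len(problems)} invalid row(s): {detail}")
    bad_rows = sorted({i for i, _ in problems})
    rejected = tuple(f"row {i + 1}: {msg}" for i, msg in problems)
    df = df.drop(index=bad_rows).reset_index(drop=True)
    return SiteTable(df, provenance=(f"read {Path(path)}",), rejected=rejected)


# ---------------------------------------------------------------------------
# Transcript annotation


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS span of one transcript.

    ``exons`` are genomic half-open ``[start, end)`` intervals listed in
    transcription (5'->3') order; for minus-strand transcripts this is
    descending genomic order.  ``cds_start_t``/``cds_end_t`` are a 0-based
    half-open span in spliced-transcript coordinates, or None for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_t: int | None = None
    cds_end_t: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        if (self.cds_start_t is None) != (self.cds_end_t is None):
            raise ValidationError(f"{self.transcript_id}: half-specified CDS span")
        if self.cds_start_t is not None:
            if not (0 <= self.cds_start_t < self.cds_end_t <= self.length):
                raise ValidationError(
                    f"{self.transcript_id}: CDS [{self.cds_start_t}, {self.cds_end_t}) "
                    f"outside transcript of length {self.length}"
                )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_t is not None

    def transcript_to_genome(self, position: int) -> tuple[str, int, str]:
        """Genomic base under transcript base ``position`` (0-based)."""
        if not 0 <= position < self.length:
            raise ValidationError(
                f"{self.transcript_id}: position {position} outside [0, {self.length})"
            )
        off = position
        for s, e in self.exons:
            n = e - s
            if off < n:
                g = s + off if self.strand == "+" else e - 1 - off
                return self.chromosome, g, self.strand
            off -= n
        raise AssertionError("unreachable")

    def genome_to_transcript(self, genomic_position: int) -> int:
        """Transcript coordinate of a genomic base; raises if not exonic."""
        off = 0
        for s, e in self.exons:
            if s <= genomic_position < e:
                within = (genomic_position - s) if self.strand == "+" else (e - 1 - genomic_position)
                return off + within
            off += e - s
        raise ValidationError(
            f"{self.transcript_id}: genomic position {genomic_position} not exonic"
        )

    def junctions(self) -> tuple[int, ...]:
        """Splice-junction transcript coordinates: cumulative exon lengths
        excluding the total.  A junction coordinate names the first base of
        the downstream exon."""
        acc, out = 0, []
        for s, e in self.exons[:-1]:
            acc += e - s
            out.append(acc)
        return tuple(out)

    def region_lengths(self) -> tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths; raises for non-coding transcripts."""
        if not self.is_coding:
            raise ValidationError(f"{self.transcript_id}: non-coding transcript")
        return (
            self.cds_start_t,
            self.cds_end_t - self.cds_start_t,
            self.length - self.cds_end_t,
        )


@dataclass(frozen=True)
class TranscriptCatalog:
    """Mapping transcript_id -> model, with a gene index."""

    models: Mapping[str, TranscriptModel]

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.models

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.models[transcript_id]

    def get(self, transcript_id: str) -> TranscriptModel | None:
        return self.models.get(transcript_id)

    @property
    def gene_index(self) -> dict[str, tuple[str, ...]]:
        idx: dict[str, list[str]] = {}
        for tid, m in self.models.items():
            idx.setdefault(m.gene_id, []).append(tid)
        return {g: tuple(sorted(ts)) for g, ts in idx.items()}


def read_annotation(path: str | Path, warn: list[str] | None = None) -> TranscriptCatalog:
    """Read a GTF (Ensembl/GENCODE dialect) into a :class:`TranscriptCatalog`.

    Parsing is delegated to :mod:`gffutils` (in-memory database).  Only
    ``exon`` and ``CDS`` features are used; both must carry ``transcript_id``
    and ``gene_id`` attributes.  GTF 1-based closed coordinates become
    0-based half-open.  Transcripts whose CDS is not contained in their
    exons raise; transcripts with no exon feature are skipped with a
    warning appended to ``warn``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise FormatError(f"{path}: {feat.featuretype} without transcript_id")
        tid = tids[0]
        gid = (feat.attributes.get("gene_id") or [""])[0]
        iv = (feat.start - 1, feat.end)  # 1-based closed -> 0-based half-open
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models: dict[str, TranscriptModel] = {}
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in exons:
            if warn is not None:
                warn.append(f"transcript {tid} has no exon features; skipped")
            continue
        ex = sorted(exons[tid])
        if strand == "-":
            ex = ex[::-1]
        model = TranscriptModel(tid, gid, chrom, strand, tuple(ex))
        if tid in cds:
            tcoords: list[int] = []
            for s, e in cds[tid]:
                try:
                    tcoords.append(model.genome_to_transcript(s))
                    tcoords.append(model.genome_to_transcript(e - 1))
                except ValidationError as err:
                    raise ValidationError(
                        f"transcript {tid}: CDS interval [{s}, {e}) not contained in exons"
                    ) from err
            model = replace(model, cds_start_t=min(tcoords), cds_end_t=max(tcoords) + 1)
        models[tid] = model
    return TranscriptCatalog(models)


# ---------------------------------------------------------------------------
# Expression and Ct tables


@dataclass(frozen=True)
class ExpressionTable:
    """Per-transcript TPM, keyed by (sample_id, transcript_id)."""

    df: pd.DataFrame  # columns: sample_id, transcript_id, tpm

    def __len__(self) -> int:
        return len(self.df)

    def validate(self, check_sum: bool = False) -> None:
        if (self.df["tpm"] < 0).any():
            bad = self.df[self.df["tpm"] < 0].iloc[0]
            raise ValidationError(
                f"negative TPM {bad.tpm} for ({bad.sample_id}, {bad.transcript_id})"
            )
        dup = self.df.duplicated(subset=["sample_id", "transcript_id"])
        if dup.any():
            bad = self.df[dup].iloc[0]
            raise ValidationError(
                f"duplicate entry ({bad.sample_id}, {bad.transcript_id})"
            )
        if check_sum:
            sums = self.df.groupby("sample_id")["tpm"].sum()
            off = sums[(sums - 1e6).abs() > 1e4]
            if len(off):
                raise ValidationError(
                    f"TPM sums deviate from 1e6 by >1%: {off.to_dict()}"
                )

    def tpm_map(self, sample_id: str | None = None) -> pd.Series:
        """transcript_id -> tpm for one sample (or for the only sample)."""
        df = self.df
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        elif df["sample_id"].nunique() > 1:
            raise ValidationError("multiple samples present; pass sample_id")
        return df.set_index("transcript_id")["tpm"]


@dataclass(frozen=True)
class CtTable:
    """qPCR Ct values: gene x condition x timepoint x replicate, with the
    target and the internal reference gene measured in the same well set."""

    df: pd.DataFrame  # gene, condition, timepoint_h, replicate, ct_target, ct_reference

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        key = ["gene", "condition", "timepoint_h", "replicate"]
        dup = self.df.duplicated(subset=key)
        if dup.any():
            bad = self.df[dup].iloc[0]
            raise ValidationError(
                f"duplicate Ct record ({bad.gene}, {bad.condition}, "
                f"{bad.timepoint_h}, {bad.replicate})"
            )
        for col in ("ct_target", "ct_reference"):
            if not np.isfinite(self.df[col]).all():
                raise ValidationError(f"non-finite values in {col}")
        for (gene, cond), grp in self.df.groupby(["gene", "condition"]):
            if not (grp["timepoint_h"] == 0).any():
                raise ValidationError(
                    f"gene {gene} condition {cond} has no timepoint 0"
                )


_EXPR_COLUMNS = ["sample_id", "transcript_id", "tpm"]
_CT_COLUMNS = ["gene", "condition", "timepoint_h", "replicate", "ct_target", "ct_reference"]


def read_expression(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[_EXPR_COLUMNS].copy()
    df["tpm"] = df["tpm"].astype(float)
    table = ExpressionTable(df.reset_index(drop=True))
    table.validate()
    return table


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[_CT_COLUMNS].copy()
    df["timepoint_h"] = df["timepoint_h"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["ct_target"] = df["ct_target"].astype(float)
    df["ct_reference"] = df["ct_reference"].astype(float)
    table = CtTable(df.reset_index(drop=True))
    table.validate()
    return table


def write_table(obj, path: str | Path) -> None:
    """Write a SiteTable / ExpressionTable / CtTable / DataFrame as TSV.

    Writers emit ``repr``-faithful floats so read(write(x)) == x
    field-for-field and write(read(write(x))) is byte-identical.
    """
    if isinstance(obj, SiteTable):
        df = obj.df[list(SITE_COLUMNS)]
    elif isinstance(obj, (ExpressionTable, CtTable)):
        df = obj.df
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_gtf(catalog: TranscriptCatalog, path: str | Path, source: str = "m5cscope") -> None:
    """Write a catalog back to GTF (exon + CDS features, 1-based closed)."""
    lines: list[str] = []
    for tid in sorted(catalog.models):
        m = catalog.models[tid]
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        for s, e in sorted(m.exons):
            lines.append(
                f"{m.chromosome}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}"
            )
        if m.is_coding:
            # project the transcript CDS span back to genomic intervals
            gpos = sorted(
                m.transcript_to_genome(t)[1] for t in range(m.cds_start_t, m.cds_end_t)
            )
            runs: list[tuple[int, int]] = []
            start = prev = gpos[0]
            for g in gpos[1:]:
                if g == prev + 1:
                    prev = g
                    continue
                runs.append((start, prev + 1))
                start = prev = g
            runs.append((start, prev + 1))
            for s, e in runs:
                lines.append(
                    f"{m.chromosome}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
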