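"""Sequence-context (k-mer) analyses of m5C sites.

Each called site carries the 9-mer centered on the modified C.  Two
derived views are used downstream:

* the 5-mer starting at the C (the C plus four downstream bases), the
  unit of motif-abundance heatmaps and of motif-conditioned comparisons
  such as the NSUN2-dependent 5'-CNGGG-3' (Type I) context;
* the full 9-mer position frequency matrix (positions -4..+4), the input
  to sequence-logo rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import SiteTable, ValidationError

__all__ = [
    "extract_5mer",
    "iupac_match",
    "motif_abundance_matrix",
    "PositionFrequencyMatrix",
    "position_frequency_matrix",
    "MotifTestResult",
    "motif_stoichiometry_test",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASES = ("A", "C", "G", "T")


def extract_5mer(kmer9: str) -> str:
    """5-mer with the modified C at its first position: characters 4..8 of
    the C-centered 9-mer."""
    if len(kmer9) != 9 or kmer9[4] != "C":
        raise ValidationError(f"not a C-centered 9-mer: {kmer9!r}")
    return kmer9[4:9]


def iupac_match(sequence: str, pattern: str) -> bool:
    """True if ``sequence`` matches the IUPAC degenerate ``pattern``."""
    if len(sequence) != len(pattern):
        return False
    for base, code in zip(sequence, pattern.upper()):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValidationError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        if base not in allowed:
            return False
    return True


def motif_abundance_matrix(tables: dict[str, SiteTable]) -> pd.DataFrame:
    """Relative abundance (%) of each 5-mer motif per sample.

    Rows are samples (input order), columns the union of observed 5-mers
    in lexicographic order; each row sums to 100 when the sample has at
    least one site (empty samples yield NaN rows).
    """
    per_sample: dict[str, pd.Series] = {}
    for name, table in tables.items():
        motifs = table.df["kmer9"].map(extract_5mer)
        per_sample[name] = motifs.value_counts()
    columns = sorted(set().union(*(set(s.index) for s in per_sample.values())) if per_sample else [])
    rows = []
    for name, counts in per_sample.items():
        total = counts.sum()
        if total == 0:
            rows.append([np.nan] * len(columns))
        else:
            rows.append([100.0 * counts.get(m, 0) / total for m in columns])
    return pd.DataFrame(rows, index=list(per_sample), columns=columns)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base frequencies at 9-mer positions -4..+4 plus per-position
    information content (2 - Shannon entropy in bits, uniform background)."""

    frequencies: pd.DataFrame      # index -4..4, columns A C G T
    information_content: pd.Series  # index -4..4, bits in [0, 2]


def position_frequency_matrix(table: SiteTable) -> PositionFrequencyMatrix:
    """PFM over the 9-mers of a site table; position 0 is the modified C
    (frequency 1 by construction)."""
    kmers = table.df["kmer9"].astype(str)
    if len(kmers) == 0:
        raise ValidationError("cannot build a PFM from an empty table")
    positions = list(range(-4, 5))
    counts = np.zeros((9, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for kmer in kmers:
        for i, base in enumerate(kmer):
            counts[i, base_idx[base]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    ic = 2.0 - entropy
    freq_df = pd.DataFrame(freqs, index=pd.Index(positions, name="offset"), columns=_BASES)
    return PositionFrequencyMatrix(freq_df, pd.Series(ic, index=freq_df.index, name="bits"))


@dataclass(frozen=True)
class MotifTestResult:
    """Two-sample comparison of stoichiometry at pattern-matched sites."""

    pattern: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    pvalue: float
    underpowered: bool
    paired: bool


def _pattern_sites(table: SiteTable, pattern: str) -> pd.DataFrame:
    motifs = table.df["kmer9"].map(extract_5mer)
    mask = motifs.map(lambda m: iupac_match(m, pattern))
    return table.df[mask]


def motif_stoichiometry_test(
    table_a: SiteTable,
    table_b: SiteTable,
    pattern: str = "CNGGG",
    paired: bool = False,
    min_n: int = 3,
) -> MotifTestResult:
    """Compare stoichiometry distributions at sites matching an IUPAC
    5-mer pattern (the pattern must start with C, the modified base).

    Unpaired mode (default) uses the two-sided Wilcoxon rank-sum /
    Mann-Whitney U test: exact null enumeration when the pooled sample is
    small (n_a + n_b <= 12, no ties), normal approximation with tie
    correction otherwise.  Paired mode joins sites present in both tables
    by (transcript, position) and applies the Wilcoxon signed-rank test.
    With fewer than ``min_n`` observations on either side the result is
    flagged underpowered and the p-value is NaN.
    """
    if len(pattern) != 5 or pattern.upper()[0] != "C":
        raise ValidationError(f"pattern must be a 5-mer starting with C, got {pattern!r}")
    sel_a = _pattern_sites(table_a, pattern)
    sel_b = _pattern_sites(table_b, pattern)
    if paired:
        merged = sel_a.merge(
            sel_b, on=["transcript_id", "position"], suffixes=("_a", "_b")
        )
        a = merged["stoichiometry_a"].to_numpy()
        b = merged["stoichiometry_b"].to_numpy()
    else:
        a = sel_a["stoichiometry"].to_numpy()
        b = sel_b["stoichiometry"].to_numpy()
    n_a, n_b = len(a), len(b)
    med_a = float(np.median(a)) if n_a else float("nan")
    med_b = float(np.median(b)) if n_b else float("nan")
    if n_a < min_n or n_b < min_n:
        return MotifTestResult(pattern, n_a, n_b, med_a, med_b,
                               float("nan"), float("nan"), True, paired)
    if paired:
        diffs = a - b
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < n_a + n_b
        method = "exact" if (n_a + n_b <= 12 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    return MotifTestResult(pattern, n_a, n_b, med_a, med_b,
                           float(stat), min(float(p), 1.0), False, paired)
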