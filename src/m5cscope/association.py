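"""Methylation-expression association.

Two complementary views: (i) transcript abundance (TPM) compared between
conditions within stoichiometry strata (five bins spanning [0, 1]); and
(ii) the global correlation between per-site methylation change and
transcript expression change, with sites classified into the four
quadrants (hyper+over, hypo+under, hypo+over, hyper+under).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import DiffTable
from .io_model import ExpressionTable, SiteTable, ValidationError

__all__ = [
    "BIN_LABELS",
    "assign_bin",
    "bin_expression_compare",
    "CorrelationResult",
    "methylation_expression_correlation",
]

#: Stoichiometry strata; left-closed right-open, last bin closed.
BIN_LABELS = ("0.0-0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1.0")
_BIN_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


def assign_bin(stoichiometry: float) -> str:
    """Stratum label of a stoichiometry in [0, 1]."""
    if not 0.0 <= stoichiometry <= 1.0:
        raise ValidationError(f"stoichiometry {stoichiometry} outside [0, 1]")
    idx = int(np.searchsorted(_BIN_EDGES, stoichiometry, side="right")) - 1
    return BIN_LABELS[min(idx, len(BIN_LABELS) - 1)]


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples,
    normal approximation with tie and continuity correction otherwise."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = len(a) <= 8 and len(b) <= 8 and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), min(float(res.pvalue), 1.0)


def _tier(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def bin_expression_compare(
    sites_a: SiteTable,
    sites_b: SiteTable,
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    sample_a: str | None = None,
    sample_b: str | None = None,
) -> pd.DataFrame:
    """Compare TPM between conditions within each stoichiometry stratum.

    Each site contributes its transcript's TPM in its own condition to
    the stratum given by its stoichiometry.  Per stratum a two-sided
    Mann-Whitney U test compares the two TPM distributions; significance
    tiers: ``**`` p < 0.01, ``*`` p < 0.05, ``ns`` otherwise.  Strata
    empty on either side are flagged with NaN p.
    """
    tpm_a = expr_a.tpm_map(sample_a)
    tpm_b = expr_b.tpm_map(sample_b)

    def site_tpms(sites: SiteTable, tpm: pd.Series) -> pd.DataFrame:
        df = sites.df[["transcript_id", "stoichiometry"]].copy()
        df["tpm"] = df["transcript_id"].map(tpm)
        df = df.dropna(subset=["tpm"])
        df["bin"] = df["stoichiometry"].map(assign_bin)
        return df

    da = site_tpms(sites_a, tpm_a)
    db = site_tpms(sites_b, tpm_b)
    rows = []
    for lab in BIN_LABELS:
        va = da.loc[da["bin"] == lab, "tpm"].to_numpy()
        vb = db.loc[db["bin"] == lab, "tpm"].to_numpy()
        if len(va) == 0 or len(vb) == 0:
            u = p = float("nan")
        else:
            u, p = _mwu(va, vb)
        rows.append(
            {
                "bin": lab,
                "n_a": len(va),
                "n_b": len(vb),
                "median_tpm_a": float(np.median(va)) if len(va) else float("nan"),
                "median_tpm_b": float(np.median(vb)) if len(vb) else float("nan"),
                "U": u,
                "p": p,
                "tier": _tier(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    """Global methylation-change vs expression-change association."""

    r: float
    p: float
    n: int
    quadrants: dict[str, int]   # hyper_over, hypo_under, hypo_over, hyper_under
    n_on_axis: int              # points with zero methylation or expression change
    points: pd.DataFrame        # per-site x (meth log2FC), y (expr log2FC), quadrant


def methylation_expression_correlation(
    diff: DiffTable,
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    eps_tpm: float = 0.01,
    sample_a: str | None = None,
    sample_b: str | None = None,
    level: str = "site",
) -> CorrelationResult:
    """Pearson correlation between per-site methylation log2FC and the
    transcript expression log2FC, with quadrant classification.

    x = methylation log2FC from the differential table; y = log2((tpm_a +
    eps) / (tpm_b + eps)).  ``level='transcript'`` first averages x over
    the sites of each transcript.  Points with x == 0 or y == 0 sit on a
    quadrant axis and are excluded from quadrant counts (reported in
    ``n_on_axis``).  Requires at least 3 points; otherwise r is NaN.
    """
    tpm_a = expr_a.tpm_map(sample_a)
    tpm_b = expr_b.tpm_map(sample_b)
    df = diff.df[["transcript_id", "position", "log2fc"]].copy()
    if level == "transcript":
        df = df.groupby("transcript_id", as_index=False)["log2fc"].mean()
        df["position"] = -1
    elif level != "site":
        raise ValidationError(f"level must be 'site' or 'transcript', got {level!r}")
    df["tpm_a"] = df["transcript_id"].map(tpm_a)
    df["tpm_b"] = df["transcript_id"].map(tpm_b)
    df = df.dropna(subset=["tpm_a", "tpm_b"]).reset_index(drop=True)
    x = df["log2fc"].to_numpy()
    y = np.log2((df["tpm_a"] + eps_tpm) / (df["tpm_b"] + eps_tpm))
    quadrant = np.select(
        [(x > 0) & (y > 0), (x < 0) & (y < 0), (x < 0) & (y > 0), (x > 0) & (y < 0)],
        ["hyper_over", "hypo_under", "hypo_over", "hyper_under"],
        default="axis",
    )
    points = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "position": df["position"],
            "meth_log2fc": x,
            "expr_log2fc": y,
            "quadrant": quadrant,
        }
    )
    quads = {
        q: int((quadrant == q).sum())
        for q in ("hyper_over", "hypo_under", "hypo_over", "hyper_under")
    }
    n = len(df)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, quads,
                             int((quadrant == "axis").sum()), points)
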