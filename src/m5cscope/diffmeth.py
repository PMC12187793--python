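"""Per-site differential methylation between two conditions.

For every site observed in both conditions, modified/unmodified read
counts are reconstructed from stoichiometry and coverage, a two-sided
exact test on the resulting 2x2 table gives a per-site p-value, and the
log2 fold change of stoichiometry (with a small pseudocount guarding
zeros) quantifies the direction.  p-values are adjusted across all joined
sites (Benjamini-Hochberg by default) and each site is labeled
hypermethylated, hypomethylated, or not significant using the standard
cutoffs |log2FC| >= 1 and adjusted p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .io_model import SiteTable, ValidationError

__all__ = [
    "DiffTable",
    "to_read_counts",
    "site_diff_test",
    "log2fc_methylation",
    "differential_table",
    "top_k_sites",
    "pairwise_concordance",
]


def to_read_counts(stoichiometry: float, coverage: int) -> tuple[int, int]:
    """Reconstruct (modified, unmodified) read counts from a stoichiometry
    and a coverage, rounding half to even."""
    if coverage < 1:
        raise ValidationError(f"coverage must be >= 1, got {coverage}")
    modified = int(np.rint(stoichiometry * coverage))
    return modified, coverage - modified


def site_diff_test(
    mod_a: int, unmod_a: int, mod_b: int, unmod_b: int, method: str = "fisher"
) -> float:
    """Two-sided p-value for a difference in modification fraction.

    ``fisher`` (default): exact hypergeometric test on the 2x2 table
    [[mod_a, unmod_a], [mod_b, unmod_b]].  ``ztest``: two-proportion
    z-test, an asymptotic alternative for large counts.
    """
    cov_a, cov_b = mod_a + unmod_a, mod_b + unmod_b
    if cov_a == 0 or cov_b == 0:
        raise ValidationError("zero coverage in one condition")
    if method == "fisher":
        _, p = stats.fisher_exact([[mod_a, unmod_a], [mod_b, unmod_b]], alternative="two-sided")
    elif method == "ztest":
        if mod_a + mod_b in (0, cov_a + cov_b):  # degenerate margins: no evidence
            return 1.0
        _, p = proportions_ztest([mod_a, mod_b], [cov_a, cov_b])
    else:
        raise ValidationError(f"unknown test method {method!r}")
    return float(min(p, 1.0))


def log2fc_methylation(stoich_a: float, stoich_b: float, eps: float = 0.01) -> float:
    """log2((stoich_a + eps) / (stoich_b + eps)); antisymmetric under
    condition swap.  The pseudocount guards fully unmethylated sites."""
    return float(np.log2((stoich_a + eps) / (stoich_b + eps)))


@dataclass(frozen=True)
class DiffTable:
    """Per-site statistics for one paired-condition comparison."""

    df: pd.DataFrame
    name_a: str
    name_b: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def label_counts(self) -> dict[str, int]:
        counts = self.df["label"].value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in ("hyper", "hypo", "ns")}


def differential_table(
    table_a: SiteTable,
    table_b: SiteTable,
    name_a: str = "A",
    name_b: str = "B",
    min_cov: int = 8,
    lfc_cut: float = 1.0,
    p_cut: float = 0.001,
    eps: float = 0.01,
    test: str = "fisher",
    adjust: str = "fdr_bh",
) -> DiffTable:
    """Differential methylation over sites shared by two conditions.

    Sites are inner-joined on (transcript, position) and kept when both
    conditions meet ``min_cov``.  Labels: ``hyper`` when condition A is
    more methylated than B (log2FC >= lfc_cut) at adjusted p < p_cut,
    ``hypo`` for the mirror image, ``ns`` otherwise.  ``adjust`` is any
    statsmodels multiple-testing method name (default Benjamini-Hochberg;
    ``bonferroni`` available).
    """
    key = ["transcript_id", "position"]
    merged = table_a.df.merge(table_b.df, on=key, suffixes=("_a", "_b"))
    merged = merged[(merged["coverage_a"] >= min_cov) & (merged["coverage_b"] >= min_cov)]
    if merged.empty:
        empty = pd.DataFrame(
            columns=key + ["kmer9", "stoich_a", "stoich_b", "cov_a", "cov_b",
                           "mod_a", "unmod_a", "mod_b", "unmod_b",
                           "log2fc", "log2fc_counts", "p", "p_adj", "label"]
        )
        return DiffTable(empty, name_a, name_b,
                         {"min_cov": min_cov, "lfc_cut": lfc_cut, "p_cut": p_cut,
                          "eps": eps, "test": test, "adjust": adjust, "empty_join": True})
    counts_a = [to_read_counts(s, c) for s, c in zip(merged["stoichiometry_a"], merged["coverage_a"])]
    counts_b = [to_read_counts(s, c) for s, c in zip(merged["stoichiometry_b"], merged["coverage_b"])]
    mod_a = np.array([m for m, _ in counts_a])
    unmod_a = np.array([u for _, u in counts_a])
    mod_b = np.array([m for m, _ in counts_b])
    unmod_b = np.array([u for _, u in counts_b])
    p = np.array([
        site_diff_test(int(ma), int(ua), int(mb), int(ub), method=test)
        for ma, ua, mb, ub in zip(mod_a, unmod_a, mod_b, unmod_b)
    ])
    p_adj = multipletests(p, method=adjust)[1]
    lfc = np.log2((merged["stoichiometry_a"] + eps) / (merged["stoichiometry_b"] + eps))
    # counts-based variant of the fold change (same pseudocount on the fractions)
    lfc_counts = np.log2((mod_a / (mod_a + unmod_a) + eps) / (mod_b / (mod_b + unmod_b) + eps))
    significant = (np.abs(lfc) >= lfc_cut) & (p_adj < p_cut)
    label = np.where(significant & (lfc > 0), "hyper", np.where(significant, "hypo", "ns"))
    df = pd.DataFrame(
        {
            "transcript_id": merged["transcript_id"].to_numpy(),
            "position": merged["position"].to_numpy(),
            "kmer9": merged["kmer9_a"].to_numpy(),
            "stoich_a": merged["stoichiometry_a"].to_numpy(),
            "stoich_b": merged["stoichiometry_b"].to_numpy(),
            "cov_a": merged["coverage_a"].to_numpy(),
            "cov_b": merged["coverage_b"].to_numpy(),
            "mod_a": mod_a, "unmod_a": unmod_a, "mod_b": mod_b, "unmod_b": unmod_b,
            "log2fc": lfc.to_numpy(),
            "log2fc_counts": lfc_counts,
            "p": p,
            "p_adj": p_adj,
            "label": label,
        }
    ).reset_index(drop=True)
    return DiffTable(df, name_a, name_b,
                     {"min_cov": min_cov, "lfc_cut": lfc_cut, "p_cut": p_cut,
                      "eps": eps, "test": test, "adjust": adjust})


def top_k_sites(diff: DiffTable, k: int = 20) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, bool]]:
    """Top-k hyper- and hypomethylated sites.

    Within each label, sites rank by adjusted p ascending, then |log2FC|
    descending, then (transcript, position) lexicographically for
    determinism.  When fewer than k sites carry a label the short side is
    flagged in the returned dict.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    out: dict[str, pd.DataFrame] = {}
    flags: dict[str, bool] = {}
    for lab in ("hyper", "hypo"):
        sub = diff.df[diff.df["label"] == lab].copy()
        sub["_abs_lfc"] = sub["log2fc"].abs()
        sub = sub.sort_values(
            by=["p_adj", "_abs_lfc", "transcript_id", "position"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).drop(columns="_abs_lfc")
        flags[lab] = len(sub) < k
        out[lab] = sub.head(k).reset_index(drop=True)
    return out["hyper"], out["hypo"], flags


def pairwise_concordance(
    diffs: Mapping[str, DiffTable],
    min_shared: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson concordance of log2 fold changes across comparisons.

    For each pair of comparisons, sites shared by both are matched on
    (transcript, position); returns (r matrix, n matrix, discordant-sign
    count matrix).  Pairs with fewer than ``min_shared`` shared sites get
    NaN r.
    """
    names = list(diffs)
    if len(names) < 2:
        raise ValidationError("need at least 2 comparisons")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names)
    disc = pd.DataFrame(0, index=names, columns=names)
    key = ["transcript_id", "position"]
    for name in names:
        n.loc[name, name] = len(diffs[name].df)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            merged = diffs[na].df[key + ["log2fc"]].merge(
                diffs[nb].df[key + ["log2fc"]], on=key, suffixes=("_x", "_y")
            )
            n.loc[na, nb] = n.loc[nb, na] = len(merged)
            d = int(((merged["log2fc_x"] * merged["log2fc_y"]) < 0).sum())
            disc.loc[na, nb] = disc.loc[nb, na] = d
            if len(merged) < min_shared:
                rv = float("nan")
            else:
                rv = float(stats.pearsonr(merged["log2fc_x"], merged["log2fc_y"])[0])
            r.loc[na, nb] = r.loc[nb, na] = rv
    return r, n, disc
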