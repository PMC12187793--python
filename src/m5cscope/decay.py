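"""mRNA decay kinetics from transcription-shutoff qPCR time courses.

After actinomycin-D transcription shutoff, remaining mRNA is quantified
by qPCR at successive timepoints and normalized with the 2^-ddCt method
against an internal reference gene and the t = 0 calibrator.  Assuming
first-order decay, ln(remaining fraction) is linear in time; ordinary
least squares yields the decay rate k (per hour) and the half-life
ln(2)/k.  Condition differences in decay rate are tested with a pooled
regression carrying a condition x time interaction term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_model import CtTable, ValidationError

__all__ = [
    "relative_quantity",
    "rq_series",
    "remaining_fraction",
    "DecayFit",
    "fit_decay",
    "fit_gene_decay",
    "DecayComparison",
    "compare_decay",
    "compare_gene_decay",
    "per_timepoint_tests",
]

LN2 = math.log(2.0)


def relative_quantity(
    ct_target_t: float, ct_ref_t: float, ct_target_0: float, ct_ref_0: float
) -> float:
    """2^-ddCt relative quantity of a target at time t versus time 0,
    normalized to the reference gene; RQ at t = 0 is 1 by construction."""
    ddct = (ct_target_t - ct_ref_t) - (ct_target_0 - ct_ref_0)
    return float(2.0 ** (-ddct))


def rq_series(
    ct: CtTable,
    gene: str,
    condition: str,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Relative quantities over the time course of one gene/condition.

    Replicate Ct values are averaged on the Ct scale before ddCt (the
    calibrator dCt at t = 0 is always the replicate mean).  With
    ``average_replicates=False`` each replicate keeps its own RQ against
    the common t = 0 calibrator, for pooled regression.
    """
    sub = ct.df[(ct.df["gene"] == gene) & (ct.df["condition"] == condition)]
    if sub.empty:
        raise ValidationError(f"no Ct records for gene {gene!r} condition {condition!r}")
    t0 = sub[sub["timepoint_h"] == 0]
    if t0.empty:
        raise ValidationError(f"gene {gene!r} condition {condition!r} has no timepoint 0")
    dct0 = float((t0["ct_target"] - t0["ct_reference"]).mean())
    if average_replicates:
        grouped = sub.groupby("timepoint_h")[["ct_target", "ct_reference"]].mean()
        dct = grouped["ct_target"] - grouped["ct_reference"]
        return pd.DataFrame(
            {
                "timepoint_h": grouped.index.to_numpy(float),
                "rq": (2.0 ** (-(dct - dct0))).to_numpy(),
            }
        ).reset_index(drop=True)
    dct = sub["ct_target"] - sub["ct_reference"]
    return pd.DataFrame(
        {
            "timepoint_h": sub["timepoint_h"].to_numpy(float),
            "replicate": sub["replicate"].to_numpy(),
            "rq": (2.0 ** (-(dct - dct0))).to_numpy(),
        }
    ).reset_index(drop=True)


def remaining_fraction(rq: pd.DataFrame) -> pd.DataFrame:
    """Remaining-mRNA fractions relative to t = 0.

    Input is a frame with ``timepoint_h`` and ``rq`` columns; the output
    carries ``fraction`` = rq / rq(t=0).  Under the 2^-ddCt convention
    rq(0) == 1 when replicates were averaged, so the fractions coincide
    with the RQ values; the explicit division makes the series invariant
    to any common rescaling of the RQs.
    """
    at0 = rq[rq["timepoint_h"] == 0]
    if at0.empty:
        raise ValidationError("series has no timepoint 0")
    rq0 = float(at0["rq"].mean())
    out = rq.copy()
    out["fraction"] = out["rq"] / rq0
    return out


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit of one gene/condition."""

    gene: str
    condition: str
    k: float                 # decay rate, per hour (= -slope of ln fraction vs t)
    half_life_h: float       # ln(2)/k for k > 0, NaN otherwise
    r2: float
    slope_se: float
    n: int
    stable: bool             # k <= 0: no measurable decay
    n_dropped: int = 0       # points with fraction <= 0 (log undefined)


def fit_decay(
    times: np.ndarray,
    fractions: np.ndarray,
    gene: str = "",
    condition: str = "",
    pin_intercept: bool = False,
) -> DecayFit:
    """OLS fit of ln(fraction) on time.

    The intercept is free by default (absorbing plating offsets);
    ``pin_intercept`` forces the fit through ln(1) = 0 at t = 0.  Points
    with fraction <= 0 are dropped with a tally (their log is undefined).
    Requires >= 3 usable timepoints.
    """
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    ok = fractions > 0
    n_dropped = int((~ok).sum())
    times, fractions = times[ok], fractions[ok]
    if len(np.unique(times)) < 3:
        raise ValidationError("need fractions at >= 3 distinct timepoints")
    y = np.log(fractions)
    X = times[:, None] if pin_intercept else sm.add_constant(times)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[-1])
    se = float(fit.bse[-1])
    ss_res = float(np.sum(fit.resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (1.0 - ss_res / ss_tot if ss_tot else float("nan"))
    k = -slope
    stable = k <= 0
    half_life = LN2 / k if k > 0 else float("nan")
    return DecayFit(gene, condition, k, half_life, r2, se, len(y), stable, n_dropped)


def fit_gene_decay(
    ct: CtTable,
    gene: str,
    condition: str,
    pooled_replicates: bool = True,
    pin_intercept: bool = False,
) -> DecayFit:
    """Fit decay for one gene/condition straight from a Ct table.

    With ``pooled_replicates`` (default) each replicate contributes its
    own point at each timepoint; otherwise replicates are averaged on the
    Ct scale first.
    """
    rq = rq_series(ct, gene, condition, average_replicates=not pooled_replicates)
    frac = remaining_fraction(rq)
    return fit_decay(
        frac["timepoint_h"].to_numpy(),
        frac["fraction"].to_numpy(),
        gene=gene,
        condition=condition,
        pin_intercept=pin_intercept,
    )


@dataclass(frozen=True)
class DecayComparison:
    """Condition difference in decay rate via interaction regression."""

    gene: str
    k_a: float
    k_b: float
    delta_k: float           # k_b - k_a
    p: float                 # two-sided t-test on the condition x time term
    n_a: int
    n_b: int


def compare_decay(
    times_a: np.ndarray,
    fractions_a: np.ndarray,
    times_b: np.ndarray,
    fractions_b: np.ndarray,
    gene: str = "",
) -> DecayComparison:
    """Test whether two conditions decay at different rates.

    Pools ln(fraction) points of both conditions into one regression with
    condition, time and condition x time terms; the two-sided t-test on
    the interaction coefficient is the slope-difference test.  Degenerate
    zero-residual designs return p = 1 when the slopes agree exactly and
    p = 0 when they differ.
    """
    ta = np.asarray(times_a, float)
    fa = np.asarray(fractions_a, float)
    tb = np.asarray(times_b, float)
    fb = np.asarray(fractions_b, float)
    for t, f in ((ta, fa), (tb, fb)):
        if (f <= 0).any():
            raise ValidationError("fractions must be positive for log-linear comparison")
        if len(np.unique(t)) < 3:
            raise ValidationError("need >= 3 distinct timepoints per condition")
    y = np.concatenate([np.log(fa), np.log(fb)])
    t = np.concatenate([ta, tb])
    cond = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    X = sm.add_constant(np.column_stack([t, cond, t * cond]))
    fit = sm.OLS(y, X).fit()
    slope_a = float(fit.params[1])
    delta_slope = float(fit.params[3])
    k_a, k_b = -slope_a, -(slope_a + delta_slope)
    p = float(fit.pvalues[3])
    ss_res = float(np.sum(fit.resid**2))
    if not np.isfinite(p) or ss_res < 1e-18:  # (near-)zero residual variance
        p = 1.0 if abs(delta_slope) < 1e-10 else 0.0
    return DecayComparison(gene, k_a, k_b, k_b - k_a, p, len(ta), len(tb))


def compare_gene_decay(
    ct: CtTable, gene: str, condition_a: str, condition_b: str
) -> DecayComparison:
    """Slope comparison for one gene between two conditions, with
    replicates pooled as points."""
    fr_a = remaining_fraction(rq_series(ct, gene, condition_a, average_replicates=False))
    fr_b = remaining_fraction(rq_series(ct, gene, condition_b, average_replicates=False))
    return compare_decay(
        fr_a["timepoint_h"].to_numpy(), fr_a["fraction"].to_numpy(),
        fr_b["timepoint_h"].to_numpy(), fr_b["fraction"].to_numpy(),
        gene=gene,
    )


def per_timepoint_tests(
    ct: CtTable, gene: str, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Welch t-tests on per-replicate remaining fractions at each shared
    nonzero timepoint (descriptive companion to the slope test)."""
    from scipy import stats

    fr_a = remaining_fraction(rq_series(ct, gene, condition_a, average_replicates=False))
    fr_b = remaining_fraction(rq_series(ct, gene, condition_b, average_replicates=False))
    rows = []
    shared = sorted(set(fr_a["timepoint_h"]) & set(fr_b["timepoint_h"]) - {0.0})
    for t in shared:
        va = fr_a.loc[fr_a["timepoint_h"] == t, "fraction"].to_numpy()
        vb = fr_b.loc[fr_b["timepoint_h"] == t, "fraction"].to_numpy()
        if len(va) < 2 or len(vb) < 2 or (np.std(va) == 0 and np.std(vb) == 0):
            p = float("nan")
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        rows.append({"timepoint_h": t, "mean_a": va.mean(), "mean_b": vb.mean(), "p": p})
    return pd.DataFrame(rows)
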