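"""Normalization and differential-expression screening.

FPKM for length-bearing transcripts, RPM/CPM depth normalization, a
pluggable two-group count test (default: exact conditional binomial on
pooled, library-size-weighted counts — the dispersion-zero limit of the
negative-binomial exact test), BH-FDR, Z-scoring, and 2^-ddCt relative
quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as _st

from .matrix import ExpressionMatrix, SampleDesign
from .stats import bh_adjust

__all__ = [
    "fpkm", "cpm", "DEThresholds", "de_screen", "summarize_de",
    "zscore_rows", "ddct", "binomial_exact_test", "nb_exact_test",
    "expression_tier", "hclust_order",
]


def fpkm(counts: pd.DataFrame, feature_lengths: pd.Series,
         library_totals: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * total)."""
    lengths = feature_lengths.reindex(counts.index)
    bad = lengths.index[lengths.isna() | (lengths <= 0)].tolist()
    if bad:
        raise ValueError(f"non-positive or missing length for feature(s): {bad[:10]}")
    totals = library_totals.reindex(counts.columns)
    badt = totals.index[totals.isna() | (totals <= 0)].tolist()
    if badt:
        raise ValueError(f"non-positive or missing library total for sample(s): {badt}")
    return counts.astype(float).mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def cpm(counts: pd.DataFrame, library_totals: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads (the length-free normalization)."""
    totals = counts.sum(axis=0) if library_totals is None else library_totals
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.astype(float).mul(1e6).div(totals, axis=1)


def expression_tier(fpkm_values: pd.DataFrame, high_cutoff: float = 50.0) -> pd.Series:
    """Annotate features as 'medium_high' (mean FPKM >= cutoff) or 'low'.

    An annotation, not a filter: the screen itself does not require it.
    """
    mean = fpkm_values.mean(axis=1)
    return pd.Series(np.where(mean >= high_cutoff, "medium_high", "low"),
                     index=fpkm_values.index, name="expression_tier")


# ---------------------------------------------------------------- count tests

def binomial_exact_test(counts1: np.ndarray, counts2: np.ndarray,
                        lib1: float, lib2: float) -> float:
    """Exact conditional binomial test on pooled counts.

    Conditional on the pooled total t = s1 + s2, s1 ~ Binomial(t, lib1/(lib1+lib2))
    under the null of equal relative abundance; two-sided p by the
    minimum-likelihood method. This is the dispersion-zero limit of the
    negative-binomial exact test.
    """
    s1, s2 = int(np.sum(counts1)), int(np.sum(counts2))
    t = s1 + s2
    if t == 0:
        return 1.0
    pr = lib1 / (lib1 + lib2)
    return float(_st.binomtest(s1, t, pr, alternative="two-sided").pvalue)


def nb_exact_test(counts1: np.ndarray, counts2: np.ndarray,
                  lib1: float, lib2: float, dispersion: float) -> float:
    """Exact negative-binomial test with a supplied common dispersion.

    Counts are scaled to a common depth, group sums S1, S2 are treated as
    NB with means proportional to group size and variance mu + phi*mu^2;
    the two-sided p sums P(S1 = s | S1 + S2 = t) over outcomes no more
    likely than the observed split. Falls back to the binomial test when
    dispersion is ~0.
    """
    if dispersion <= 1e-12:
        return binomial_exact_test(counts1, counts2, lib1, lib2)
    n1, n2 = len(counts1), len(counts2)
    mean_lib = (lib1 / n1 + lib2 / n2) / 2.0
    s1 = float(np.sum(counts1)) * (mean_lib * n1) / lib1
    s2 = float(np.sum(counts2)) * (mean_lib * n2) / lib2
    t = int(round(s1 + s2))
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    r = 1.0 / dispersion  # per-sample NB size
    s = np.arange(t + 1)
    logp1 = _st.nbinom.logpmf(s, n1 * r, r / (r + mu))
    logp2 = _st.nbinom.logpmf(t - s, n2 * r, r / (r + mu))
    logjoint = logp1 + logp2
    logjoint -= logjoint.max()
    prob = np.exp(logjoint)
    prob /= prob.sum()
    obs = int(round(s1))
    p = prob[prob <= prob[obs] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def estimate_common_dispersion(counts: pd.DataFrame, design: SampleDesign) -> float:
    """Method-of-moments common dispersion phi from within-group residuals.

    phi solves var = mu + phi*mu^2 averaged over features on depth-scaled
    counts; clipped at 0.
    """
    scaled = cpm(counts) * counts.sum(axis=0).mean() / 1e6
    num, den = 0.0, 0.0
    for g in design.groups:
        sub = scaled[design.samples_in(g)]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        keep = mu > 0
        num += float(((var - mu) * keep).sum())
        den += float((mu[keep] ** 2).sum())
    return max(0.0, num / den) if den > 0 else 0.0


# ------------------------------------------------------------------ screening

@dataclass
class DEThresholds:
    """Screening rule: significance field ('fdr' or 'p'), alpha, and |log2FC| floor."""

    significance_field: str = "fdr"
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0

    def __post_init__(self):
        if self.significance_field not in {"fdr", "p"}:
            raise ValueError("significance_field must be 'fdr' or 'p'")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


def de_screen(matrix: ExpressionMatrix, design: SampleDesign,
              comparison: tuple[str, str],
              thresholds: DEThresholds | None = None,
              test: Callable[..., float] | None = None,
              pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-group differential-expression screen.

    log2FC = log2((mean2 + c) / (mean1 + c)) on library-size-equalized
    counts, with pseudocount c of one raw count at the common depth; the
    p-value comes from ``test`` (default exact conditional binomial); FDR is
    BH over all features of the comparison. A feature is 'up'/'down' only
    when the significance field beats alpha AND |log2FC| exceeds the floor.

    Returns one row per feature: feature_id, comparison, log2FC, p_value,
    fdr, direction.
    """
    if matrix.unit != "counts":
        raise ValueError("de_screen expects raw counts")
    thresholds = thresholds or DEThresholds()
    test = test or binomial_exact_test
    g1, g2 = comparison
    s1 = design.samples_in(g1)
    s2 = design.samples_in(g2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each comparison group needs >= 2 samples")
    counts = matrix.values
    libs = counts.sum(axis=0).astype(float)
    mean_lib = float(libs.mean())
    # equalize depth: scale each sample to the mean library size
    scaled = counts.astype(float).mul(mean_lib / libs, axis=1)
    m1 = scaled[s1].mean(axis=1)
    m2 = scaled[s2].mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    lib1, lib2 = float(libs[s1].sum()), float(libs[s2].sum())
    pvals = np.array([
        test(counts.loc[f, s1].to_numpy(), counts.loc[f, s2].to_numpy(), lib1, lib2)
        for f in counts.index
    ])
    fdr = bh_adjust(pvals)
    sig = fdr if thresholds.significance_field == "fdr" else pvals
    passed = (sig < thresholds.alpha) & (np.abs(log2fc) > thresholds.min_abs_log2fc)
    direction = np.where(~passed, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame({
        "feature_id": counts.index,
        "comparison": f"{g1}_vs_{g2}",
        "log2FC": log2fc.to_numpy(),
        "p_value": pvals,
        "fdr": fdr,
        "direction": direction,
    }).reset_index(drop=True)


def summarize_de(results: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison up/down/total counts ('ns' rows excluded).

    n_total = n_up + n_down by construction.
    """
    if len(results) == 0:
        return pd.DataFrame(columns=["comparison", "n_up", "n_down", "n_total"])
    rows = []
    for comp, sub in results.groupby("comparison", sort=True):
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        rows.append({"comparison": comp, "n_up": n_up, "n_down": n_down,
                     "n_total": n_up + n_down})
    return pd.DataFrame(rows)


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise standardization to mean 0, sample sd 1 (n-1 denominator).

    Constant rows cannot be standardized and are dropped with a warning.
    """
    vals = matrix.values.astype(float)
    sd = vals.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant row(s): {constant[:5]}...",
                      stacklevel=2)
        vals = vals.drop(index=constant)
        sd = sd.drop(index=constant)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, unit="zscore", feature_kind=matrix.feature_kind)


def ddct(ct_target_case: float, ct_ref_case: float,
         ct_target_control: float, ct_ref_control: float) -> float:
    """Relative quantity by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,control - Ct_ref,control).
    """
    for v in (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("CT values must be finite")
    dd = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-dd))


def hclust_order(matrix: ExpressionMatrix) -> list[str]:
    """Dendrogram leaf order of rows (Euclidean distance, complete linkage).

    Display ordering for heatmaps only; not a tested statistic.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    vals = matrix.values.to_numpy(dtype=float)
    if len(vals) < 2:
        return matrix.feature_ids
    link = hierarchy.linkage(pdist(vals, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(link)
    return [matrix.feature_ids[i] for i in order]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """log2FC vs -log10(p) table for a volcano plot export."""
    out = results[["feature_id", "comparison", "log2FC", "p_value", "direction"]].copy()
    out["neg_log10_p"] = -np.log10(np.clip(out["p_value"], 1e-300, None))
    return out


def plot_volcano(results: pd.DataFrame, path: str) -> None:
    """Write a basic volcano plot (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = volcano_table(results)
    colors = tab["direction"].map({"up": "tab:red", "down": "tab:green", "ns": "0.7"})
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(tab["log2FC"], tab["neg_log10_p"], s=8, c=colors)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
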