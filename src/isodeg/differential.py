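"""Replicate averaging, differential stability, and the Isoform Decay Range.

Per-replicate log(kdeg) estimates are averaged with inverse-variance weights,
and the replicate-to-replicate variance is shrunk toward a genome-wide trend
of log-variance versus log read depth (a precision-weighted compromise
between the observed variance, at n_reps - 1 degrees of freedom, and the
trend, at a fixed prior df).  Differential stability is a z-test on
L2FC(kdeg) = log2(kdeg_B / kdeg_A); the Isoform Decay Range (IDR) of a gene
is the spread max - min of its isoforms' replicate-average log(kdeg), tested
as range / total uncertainty against a standard normal.  All p-values are
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))

PRIOR_DF = 5.0
_VAR_FLOOR = 1e-10


def bh_adjust(pvals: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate as NaN."""
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def average_and_regularize(
    replicates: pd.DataFrame,
    prior_df: float = PRIOR_DF,
) -> pd.DataFrame:
    """Average per-replicate log(kdeg) with trend-shrunk replicate variance.

    ``replicates`` needs columns condition, gene, transcript, log_kdeg,
    se_log_kdeg, n_reads (read depth used for the trend).  Returns one row
    per (condition, transcript) with mean_log_kdeg, se_mean, n_reps and a
    ``trend_only`` flag for single-replicate entries.
    """
    need = {"condition", "gene", "transcript", "log_kdeg", "se_log_kdeg", "n_reads"}
    missing = need - set(replicates.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")

    rows = []
    for (cond, tx), grp in replicates.groupby(["condition", "transcript"], sort=True):
        w = 1.0 / np.clip(grp["se_log_kdeg"].to_numpy(float) ** 2, _VAR_FLOOR, None)
        x = grp["log_kdeg"].to_numpy(float)
        mean = float((w * x).sum() / w.sum())
        n_reps = len(grp)
        obs_var = float(np.var(x, ddof=1)) if n_reps > 1 else np.nan
        rows.append(
            {
                "condition": cond,
                "gene": grp["gene"].iloc[0],
                "transcript": tx,
                "mean_log_kdeg": mean,
                "obs_var": obs_var,
                "n_reps": n_reps,
                "mean_reads": float(grp["n_reads"].mean()),
            }
        )
    out = pd.DataFrame(rows)

    # trend: log replicate variance vs log read depth, over multi-replicate rows
    fit_rows = out[(out["n_reps"] > 1) & (out["obs_var"] > 0)]
    if len(fit_rows) >= 2 and fit_rows["mean_reads"].nunique() > 1:
        slope, intercept = np.polyfit(
            np.log(fit_rows["mean_reads"]), np.log(fit_rows["obs_var"]), deg=1
        )
    elif len(fit_rows) >= 1:
        slope, intercept = 0.0, float(np.log(fit_rows["obs_var"]).mean())
    else:
        warnings.warn(
            "no multi-replicate rows; variance trend unavailable, using unit variance",
            stacklevel=2,
        )
        slope, intercept = 0.0, 0.0

    trend_logvar = slope * np.log(out["mean_reads"].to_numpy(float)) + intercept
    obs_logvar = np.log(np.clip(out["obs_var"].to_numpy(float), _VAR_FLOOR, None))
    obs_df = out["n_reps"].to_numpy(float) - 1.0
    trend_only = obs_df < 1
    shrunk_logvar = np.where(
        trend_only,
        trend_logvar,
        (obs_df * obs_logvar + prior_df * trend_logvar) / (obs_df + prior_df),
    )
    shrunk_var = np.exp(shrunk_logvar)
    out["shrunk_var"] = shrunk_var
    out["se_mean"] = np.sqrt(shrunk_var / out["n_reps"].to_numpy(float))
    out["trend_only"] = trend_only
    return out.drop(columns=["obs_var"])


def compare_kdeg(
    a: pd.DataFrame,
    b: pd.DataFrame,
    padj_cutoff: float = 0.01,
    l2fc_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Differential stability between two conditions (B relative to A).

    Inputs are :func:`average_and_regularize` outputs.  L2FC(kdeg) =
    (mean_log_kdeg_B - mean_log_kdeg_A) / ln 2; z uses the quadrature sum of
    the two log2-scale standard errors.  ``significant`` applies the default
    gate padj < 0.01 and |L2FC| > 1.
    """
    cols = ["transcript", "gene", "mean_log_kdeg", "se_mean"]
    merged = a[cols].merge(
        b[cols], on=["transcript", "gene"], suffixes=("_A", "_B"), how="inner"
    )
    n_skipped = len(set(a["transcript"]) ^ set(b["transcript"]))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} transcript(s) present in only one condition were skipped",
            stacklevel=2,
        )
    l2fc = (merged["mean_log_kdeg_B"] - merged["mean_log_kdeg_A"]) / LN2
    se = np.sqrt(merged["se_mean_A"] ** 2 + merged["se_mean_B"] ** 2) / LN2
    z = l2fc / se
    p = 2.0 * norm.sf(np.abs(z))
    merged["L2FC_kdeg"] = l2fc
    merged["se_L2FC"] = se
    merged["z"] = z
    merged["p"] = p
    merged["padj"] = bh_adjust(p)
    merged["significant"] = (merged["padj"] < padj_cutoff) & (
        merged["L2FC_kdeg"].abs() > l2fc_cutoff
    )
    return merged


def compute_idr(averaged: pd.DataFrame) -> pd.DataFrame:
    """Isoform Decay Range per gene within one condition.

    For genes with >= 2 isoforms: idr = max - min of mean_log_kdeg; the
    uncertainty is the quadrature sum of the two extreme isoforms' SEs.
    """
    rows = []
    for gene, grp in averaged.groupby("gene", sort=True):
        if len(grp) < 2:
            continue
        i_max = grp["mean_log_kdeg"].idxmax()
        i_min = grp["mean_log_kdeg"].idxmin()
        idr = float(grp.loc[i_max, "mean_log_kdeg"] - grp.loc[i_min, "mean_log_kdeg"])
        se = float(
            np.sqrt(grp.loc[i_max, "se_mean"] ** 2 + grp.loc[i_min, "se_mean"] ** 2)
        )
        z = idr / se if se > 0 else np.inf
        rows.append(
            {
                "gene": gene,
                "condition": grp["condition"].iloc[0],
                "idr": idr,
                "se_idr": se,
                "z": z,
                "p": 2.0 * float(norm.sf(abs(z))),
                "least_stable": grp.loc[i_max, "transcript"],
                "most_stable": grp.loc[i_min, "transcript"],
                "n_isoforms": len(grp),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"])
    return out


def compare_idr(
    idr_a: pd.DataFrame,
    idr_b: pd.DataFrame,
    min_fraction: float = 0.10,
) -> pd.DataFrame:
    """IDR change between conditions (A - B, e.g. DMSO minus NMD-inhibited).

    ``fraction_attributable`` = delta_idr / idr_A estimates the share of the
    gene's isoform stability spread removed by the treatment; it is NA when
    idr_A is zero, and ``attributable`` marks genes at or above
    ``min_fraction`` (default: a 10% or larger decrease).
    """
    merged = idr_a.merge(idr_b, on="gene", suffixes=("_A", "_B"), how="inner")
    delta = merged["idr_A"] - merged["idr_B"]
    se = np.sqrt(merged["se_idr_A"] ** 2 + merged["se_idr_B"] ** 2)
    z = delta / se
    p = 2.0 * norm.sf(np.abs(z))
    frac = np.where(merged["idr_A"] > 0, delta / merged["idr_A"], np.nan)
    out = merged[["gene", "idr_A", "idr_B", "se_idr_A", "se_idr_B"]].copy()
    out["delta_idr"] = delta
    out["z"] = z
    out["p"] = p
    out["padj"] = bh_adjust(p)
    out["fraction_attributable"] = np.minimum(frac, 1.0)
    out["attributable"] = out["fraction_attributable"] >= min_fraction
    return out


__all__ = [
    "bh_adjust",
    "average_and_regularize",
    "compare_kdeg",
    "compute_idr",
    "compare_idr",
]
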