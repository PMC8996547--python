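"""Phylogeny-matching correlation analysis of per-species prediction summaries.

A model that has learned a conserved regulatory code should, when applied to
orthologs of a reference species' OCRs across a clade, produce mean
predictions that fall off with divergence time from the reference (and
prediction standard deviations that rise).  The mean-vs-divergence
relationship is summarized with Pearson/Spearman correlations and a fitted
exponential decay y = a * exp(b * x), x in millions of years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


def filter_sparse_rows(matrix: pd.DataFrame, min_frac: float = 0.25) -> pd.DataFrame:
    """Drop OCR rows with usable orthologs in less than ``min_frac`` of species.

    Boundary is inclusive: a row present in exactly one quarter of species is
    retained.  Raises if nothing survives.
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix needs >= 1 species column")
    frac = matrix.notna().mean(axis=1)
    out = matrix.loc[frac >= min_frac]
    if out.empty:
        raise ValueError("all rows removed by sparsity filter")
    return out


def per_species_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean/sd/n over non-missing entries (sample sd, ddof=1)."""
    return pd.DataFrame(
        {
            "mean": matrix.mean(axis=0, skipna=True),
            "sd": matrix.std(axis=0, skipna=True, ddof=1),
            "n": matrix.notna().sum(axis=0),
        }
    )


@dataclass
class PhyloFit:
    pearson_r_mean: float
    pearson_p_mean: float
    spearman_r_mean: float
    spearman_p_mean: float
    pearson_r_sd: float
    pearson_p_sd: float
    spearman_r_sd: float
    spearman_p_sd: float
    a: float = math.nan
    b: float = math.nan


def phylogeny_correlation(
    summaries: pd.DataFrame, divergence_table: Mapping[str, float]
) -> PhyloFit:
    """Correlations of per-species prediction mean and sd with divergence (MYA).

    P-values are two-sided.  Zero-variance inputs give NaN correlations.
    Also fits the exponential decay of mean prediction vs divergence.
    """
    species = [s for s in summaries.index if s in divergence_table]
    if len(species) < 3:
        raise ValueError("need >= 3 species with divergence times")
    mya = np.array([divergence_table[s] for s in species], dtype=float)
    means = summaries.loc[species, "mean"].to_numpy(dtype=float)
    sds = summaries.loc[species, "sd"].to_numpy(dtype=float)

    def corr(fn, x, y):
        if np.nanstd(x) == 0 or np.nanstd(y) == 0:
            return math.nan, math.nan
        r, p = fn(x, y)
        return float(r), float(p)

    pr_m, pp_m = corr(stats.pearsonr, means, mya)
    sr_m, sp_m = corr(stats.spearmanr, means, mya)
    pr_s, pp_s = corr(stats.pearsonr, sds, mya)
    sr_s, sp_s = corr(stats.spearmanr, sds, mya)
    a = b = math.nan
    if np.all(means > 0):
        fit = fit_exponential(mya, means)
        a, b = fit.a, fit.b
    return PhyloFit(pr_m, pp_m, sr_m, sp_m, pr_s, pp_s, sr_s, sp_s, a=a, b=b)


@dataclass
class ExponentialFit:
    a: float
    b: float
    residual_norm: float
    converged: bool


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> ExponentialFit:
    """Least-squares fit of y = a * exp(b * x) on the original scale.

    Initialized from ordinary least squares on (x, log y), which requires
    y > 0.  If the nonlinear refinement fails to converge, the log-linear
    initialization is returned with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.any(y <= 0):
        raise ValueError("y must be positive for log-linear initialization")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t), x, y, p0=(a0, b0), maxfev=10000
        )
        a, b = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        a, b = a0, b0
        converged = False
    resid = float(np.linalg.norm(y - a * np.exp(b * x)))
    return ExponentialFit(a=a, b=b, residual_norm=resid, converged=converged)


def negative_reference_level(test_negative_scores: Sequence[float]) -> float:
    """Average prediction across test-set negatives (plotting reference line)."""
    return float(np.mean(np.asarray(test_negative_scores, dtype=float)))
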