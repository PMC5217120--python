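"""Negative-binomial differential expression between cells and exosomes.

A deliberately simple NB Wald engine: median-of-ratios size factors,
per-transcript method-of-moments dispersion (no empirical-Bayes shrinkage,
no independent filtering), a log-link NB GLM with size-factor offsets, a
Wald test on the compartment coefficient, and Benjamini-Hochberg FDR
control across the tested transcripts.  Fold changes are oriented exosome
over cell: positive log2FC means relatively more abundant in exosomes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._data import CELL, EXOSOME, CountMatrix

DISPERSION_FLOOR = 1e-8


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalised to geometric mean 1.

    s_j = median over transcripts t (restricted to those with a positive
    geometric mean across samples) of count_tj / geomean_t.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_x = np.log(x)
    finite = np.isfinite(log_x).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no transcript has positive counts in every sample; "
            "size factors need a pseudo-reference fallback"
        )
    log_geo = log_x[finite].mean(axis=1)
    ratios = log_x[finite] - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=mat.columns, name="size_factor")


def normalized_counts(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.counts / factors


def _mom_dispersion(norm: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over condition groups.

    For each group: alpha_g = (s^2 - mean) / mean^2 on normalized counts;
    pooled by degrees of freedom and floored at :data:`DISPERSION_FLOOR`.
    """
    num = 0.0
    den = 0
    for g in np.unique(groups):
        v = norm[groups == g]
        if len(v) < 2:
            continue
        mu = v.mean()
        if mu <= 0:
            continue
        alpha = (v.var(ddof=1) - mu) / mu**2
        num += alpha * (len(v) - 1)
        den += len(v) - 1
    alpha = num / den if den else 0.0
    return max(DISPERSION_FLOOR, alpha)


def nb_differential_test(
    counts: CountMatrix,
    condition: str = "compartment",
    covariates: list[str] | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-transcript NB Wald test of the exosome-vs-cell contrast.

    Transcripts with all-zero counts are excluded from testing and from
    the BH denominator.  An optional categorical covariate (e.g. the
    sequencing run) is added to the design; a covariate confounded with
    the condition is rejected.
    """
    meta = counts.samples
    cond = meta[condition]
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two {condition} levels, got {levels}")
    # orient the contrast exosome over cell when applicable
    if set(levels) == {CELL, EXOSOME}:
        levels = [CELL, EXOSOME]
    x_cond = (cond == levels[1]).to_numpy(dtype=float)

    design = [np.ones_like(x_cond), x_cond]
    names = ["intercept", "condition"]
    for cov in covariates or []:
        dummies = pd.get_dummies(meta[cov], drop_first=True, dtype=float)
        for col in dummies.columns:
            d = dummies[col].to_numpy()
            if len(np.unique(d + 2 * x_cond)) <= 2:
                raise ValueError(f"covariate {cov!r} is confounded with {condition}")
            design.append(d)
            names.append(f"{cov}[{col}]")
    X = np.column_stack(design)

    if factors is None:
        factors = size_factors(counts)
    sf = factors.loc[counts.sample_ids].to_numpy()
    offset = np.log(sf)
    norm = counts.counts.to_numpy(dtype=float) / sf

    rows = []
    for i, transcript in enumerate(counts.transcripts):
        y = counts.counts.iloc[i].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        alpha = _mom_dispersion(norm[i], x_cond)
        try:
            fit = sm.GLM(
                y,
                X,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            ).fit(maxiter=100)
            beta = fit.params[1]
            se = fit.bse[1]
        except Exception:
            beta, se = np.nan, np.nan
        if not np.isfinite(se) or se == 0:
            wald, p = np.nan, np.nan
        else:
            wald = beta / se
            p = 2 * stats.norm.sf(abs(wald))
        rows.append(
            {
                "transcript": transcript,
                "baseMean": norm[i].mean(),
                "log2FoldChange": beta / np.log(2) if np.isfinite(beta) else np.nan,
                "lfcSE": se / np.log(2) if np.isfinite(se) else np.nan,
                "stat": wald,
                "pvalue": p,
                "dispersion": alpha,
            }
        )
    res = pd.DataFrame(rows).set_index("transcript")
    tested = res["pvalue"].notna()
    res["padj"] = np.nan
    if tested.any():
        res.loc[tested, "padj"] = bh_adjust(res.loc[tested, "pvalue"].to_numpy())
    res["direction"] = np.where(
        res["log2FoldChange"] > 0, f"up_in_{levels[1]}", f"up_in_{levels[0]}"
    )
    return res


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def ma_table(results: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """MA-plot table: mean normalized expression, log2FC, significance flag."""
    if results.empty:
        raise ValueError("empty differential expression results")
    out = results[["baseMean", "log2FoldChange", "padj"]].copy()
    out["significant"] = out["padj"] < fdr
    return out
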