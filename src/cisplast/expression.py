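"""Parental differential expression and plasticity contrasts.

The model is a negative-binomial GLM with log link over the nested design
``genotype + genotype:timepoint`` (time as a categorical factor within
genotype) with the log size factor as offset.  Because that design is
saturated — one free mean per genotype x timepoint cell — the fit reduces to
independent one-parameter NB maximum-likelihood problems per cell, solved by
Newton iteration, with per-gene dispersion estimated by method of moments
from a Poisson pilot fit (floored at 1e-8).  Wald contrasts of log cell
means give:

* the plastic slope  s_t = log2(expr_t / expr_0) within a species,
* the basal difference  b = log2(derived_0 / outgroup_0),
* the plasticity difference  Delta_t = s_t(derived) - s_t(outgroup),

each with a t reference on the residual degrees of freedom and
Benjamini-Hochberg FDR within each (test x timepoint x pair) family.
Genes with mean count below ``min_mean_count`` are flagged excluded and
never tested.  Reported ratios always come from fitted means, never raw
counts, so zeros need no pseudocounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = np.log(2.0)

PARENTS = ("outgroup", "derived1", "derived2")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def estimate_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Only genes with nonzero counts in every sample enter the reference.  If
    no such gene exists, falls back to total-count factors (sample total /
    median of totals) with a warning.
    """
    if hasattr(counts, "counts"):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        warnings.warn(
            "no gene is nonzero in all samples; falling back to total-count "
            "size factors",
            RuntimeWarning,
        )
        totals = mat.sum(axis=0)
        factors = totals / np.median(totals)
    else:
        ref = np.exp(np.mean(np.log(mat[allpos]), axis=1))
        factors = np.median(mat[allpos] / ref[:, None], axis=0)
        factors = factors / np.median(factors)  # anchor typical sample at 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class ExpressionFit:
    """Per-gene fitted cell means of the nested NB model.

    ``log_mean``/``var_log``: (genes, genotypes, timepoints) natural-log cell
    means (size-factor normalized) and their Wald variances; ``dispersion``:
    per-gene NB dispersion; ``excluded``: mean count < min_mean_count or a
    non-converged fit.
    """

    genes: pd.Index
    genotypes: tuple
    timepoints: tuple
    log_mean: np.ndarray
    var_log: np.ndarray
    dispersion: np.ndarray
    df_resid: int
    mean_count: np.ndarray
    excluded: np.ndarray
    converged: np.ndarray
    size_factors: pd.Series

    def _gidx(self, genotype: str) -> int:
        return self.genotypes.index(genotype)

    def _tidx(self, t: float) -> int:
        return self.timepoints.index(float(t))


def fit_nested_model(
    matrix,
    genotype_set=PARENTS,
    min_mean_count: float = 10.0,
    dispersion_floor: float = 1e-8,
) -> ExpressionFit:
    """Fit the nested NB model to every gene over ``genotype_set`` samples."""
    sub = matrix.subset_genotypes(genotype_set)
    rna = sub.samples.index[sub.samples["material"] == "RNA"]
    samples = sub.samples.loc[rna]
    counts = sub.counts[list(rna)]
    timepoints = tuple(sorted(samples["timepoint_h"].unique()))
    genotypes = tuple(g for g in genotype_set)

    cell_sizes = samples.groupby(["genotype", "timepoint_h"]).size()
    if (cell_sizes < 2).any():
        raise ValueError("each genotype x timepoint cell needs >= 2 replicates")

    sf = estimate_size_factors(counts)
    y = counts.to_numpy(dtype=float)
    s = sf.to_numpy()
    n_genes, n_samp = y.shape
    n_geno, n_tp = len(genotypes), len(timepoints)
    cell_of = np.array(
        [
            genotypes.index(samples.loc[sid, "genotype"]) * n_tp
            + timepoints.index(float(samples.loc[sid, "timepoint_h"]))
            for sid in counts.columns
        ]
    )
    n_cells = n_geno * n_tp

    # Poisson pilot: closed-form cell means sum(y)/sum(s)
    sum_y = np.zeros((n_genes, n_cells))
    sum_s = np.zeros(n_cells)
    for c in range(n_cells):
        cols = cell_of == c
        sum_y[:, c] = y[:, cols].sum(axis=1)
        sum_s[c] = s[cols].sum()
    m = sum_y / sum_s  # pilot cell means

    mu = m[:, cell_of] * s  # fitted values per sample
    df_resid = n_samp - n_cells
    # method-of-moments dispersion: solve the Pearson equation
    # sum (y - mu)^2 / (mu + alpha mu^2) = n - p for alpha, per gene
    r2 = (y - mu) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        crude = np.nan_to_num(((r2 - mu) / mu**2), nan=0.0, posinf=0.0)
    alpha = np.maximum(crude.sum(axis=1) / df_resid, dispersion_floor)
    for _ in range(25):
        denom = mu + alpha[:, None] * mu**2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.nan_to_num(r2 / denom, nan=0.0).sum(axis=1) - df_resid
            fp = -np.nan_to_num(r2 * mu**2 / denom**2, nan=0.0).sum(axis=1)
        step = np.where(fp < 0, f / fp, 0.0)
        alpha_new = np.maximum(alpha - step, dispersion_floor)
        if np.max(np.abs(alpha_new - alpha)) < 1e-12:
            alpha = alpha_new
            break
        alpha = alpha_new

    # NB refit per cell: solve sum (y - s m) / (1 + alpha s m) = 0 by Newton
    m_nb = np.maximum(m, 1e-10)
    converged = np.ones(n_genes, dtype=bool)
    a = alpha[:, None]
    for _ in range(50):
        g = np.zeros_like(m_nb)
        h = np.zeros_like(m_nb)
        mu = m_nb[:, cell_of] * s
        denom = 1.0 + a * mu
        resid = (y - mu) / denom
        hess = s * (1.0 + a * y) / denom**2
        for c in range(n_cells):
            cols = cell_of == c
            g[:, c] = resid[:, cols].sum(axis=1)
            h[:, c] = hess[:, cols].sum(axis=1)
        step = g / np.maximum(h, 1e-300)
        m_new = np.maximum(m_nb + step, 1e-10)
        if np.max(np.abs(m_new - m_nb) / (m_nb + 1e-10)) < 1e-10:
            m_nb = m_new
            break
        m_nb = m_new
    else:
        moved = np.abs(step / np.maximum(m_nb, 1e-10)).max(axis=1) > 1e-6
        converged &= ~moved

    mu = m_nb[:, cell_of] * s
    info = np.zeros_like(m_nb)
    w = mu / (1.0 + a * mu)
    for c in range(n_cells):
        info[:, c] = w[:, cell_of == c].sum(axis=1)
    with np.errstate(divide="ignore"):
        var_log = 1.0 / info
        log_mean = np.log(m_nb)

    mean_count = y.mean(axis=1)
    excluded = (mean_count < min_mean_count) | ~converged

    return ExpressionFit(
        genes=counts.index,
        genotypes=genotypes,
        timepoints=timepoints,
        log_mean=log_mean.reshape(n_genes, n_geno, n_tp),
        var_log=var_log.reshape(n_genes, n_geno, n_tp),
        dispersion=alpha,
        df_resid=df_resid,
        mean_count=mean_count,
        excluded=excluded,
        converged=converged,
        size_factors=sf,
    )


def _wald_frame(fit: ExpressionFit, est, var, alpha: float) -> pd.DataFrame:
    """Shared Wald-contrast machinery: t reference, BH across genes."""
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = est / se
    p = 2.0 * stats.t.sf(np.abs(tstat), fit.df_resid)
    p[~np.isfinite(tstat)] = np.nan
    p[fit.excluded] = np.nan
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "estimate": est / LN2,
            "se": se / LN2,
            "stat": tstat,
            "p": p,
            "q": q,
            "excluded": fit.excluded,
        },
        index=fit.genes,
    )


def test_plasticity(fit: ExpressionFit, species: str, t: float,
                    alpha_plast: float = 0.05) -> pd.DataFrame:
    """Wald contrast of timepoint ``t`` vs 0 h within one species.

    Returns per-gene log2 slope ``s_t``, p, BH q and the plastic direction
    (up/down/none; q <= alpha counts as significant).  At t = 0 the slope is
    identically zero.
    """
    gi = fit._gidx(species)
    ti, t0 = fit._tidx(t), fit._tidx(0.0)
    if ti == t0:
        est = np.zeros(len(fit.genes))
        out = _wald_frame(fit, est, np.full_like(est, np.inf), alpha_plast)
        out["se"] = 0.0
        out["p"] = np.where(fit.excluded, np.nan, 1.0)
        out["q"] = out["p"]
        out["direction"] = "none"
        return out
    est = fit.log_mean[:, gi, ti] - fit.log_mean[:, gi, t0]
    var = fit.var_log[:, gi, ti] + fit.var_log[:, gi, t0]
    out = _wald_frame(fit, est, var, alpha_plast)
    sig = out["q"] <= alpha_plast
    out["direction"] = np.where(
        sig & (out["estimate"] > 0), "up", np.where(sig & (out["estimate"] < 0), "down", "none")
    )
    return out


def test_basal_difference(fit: ExpressionFit, pair=("derived1", "outgroup"),
                          alpha_basal: float = 0.05) -> pd.DataFrame:
    """Wald contrast of basal (0 h) expression, log2(first / second)."""
    g1, g2 = fit._gidx(pair[0]), fit._gidx(pair[1])
    t0 = fit._tidx(0.0)
    est = fit.log_mean[:, g1, t0] - fit.log_mean[:, g2, t0]
    var = fit.var_log[:, g1, t0] + fit.var_log[:, g2, t0]
    out = _wald_frame(fit, est, var, alpha_basal)
    out["significant"] = out["q"] <= alpha_basal
    return out


def test_plasticity_difference(fit: ExpressionFit, pair=("derived1", "outgroup"),
                               t: float = 6.0, alpha_delta: float = 0.1) -> pd.DataFrame:
    """Interspecific plasticity difference Delta_t, log2 slope ratio.

    Delta_t = log2[(first_t / first_0) / (second_t / second_0)]; negative
    values mean a weaker (or reversed) response in the first species.
    """
    g1, g2 = fit._gidx(pair[0]), fit._gidx(pair[1])
    ti, t0 = fit._tidx(t), fit._tidx(0.0)
    if ti == t0:
        est = np.zeros(len(fit.genes))
        out = _wald_frame(fit, est, np.full_like(est, np.inf), alpha_delta)
        out["se"] = 0.0
        out["p"] = np.where(fit.excluded, np.nan, 1.0)
        out["q"] = out["p"]
        out["significant"] = False
        return out
    est = (fit.log_mean[:, g1, ti] - fit.log_mean[:, g1, t0]) - (
        fit.log_mean[:, g2, ti] - fit.log_mean[:, g2, t0]
    )
    var = (
        fit.var_log[:, g1, ti]
        + fit.var_log[:, g1, t0]
        + fit.var_log[:, g2, ti]
        + fit.var_log[:, g2, t0]
    )
    out = _wald_frame(fit, est, var, alpha_delta)
    out["significant"] = out["q"] <= alpha_delta
    return out
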