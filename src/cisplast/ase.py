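"""Allele-specific expression against the DNA baseline.

Per gene and hybrid, the two allele counts over the seven sample types
(DNA, RNA 0 h, RNA 1.5 h, ... RNA 24 h) are modeled with a quasi-binomial
GLM (logit link).  The sample-type factor is saturated, so the fitted
allele-B proportion of each type is the pooled fraction across replicates
and the quasi-likelihood dispersion is the Pearson chi-square over residual
degrees of freedom, floored at 1 (never deflated below binomial).  The two
contrasts of interest are tested with t statistics on the residual df:

* basal ASE:  allelic log2 ratio at RNA 0 h minus at DNA — the DNA control
  absorbs per-gene mapping bias;
* plastic ASE:  allelic log2 ratio at RNA t minus at RNA 0 h.

BH-FDR is applied across genes separately per contrast; basal calls use
q <= 0.05, plastic calls q <= 0.1.

Upstream of the test, per-SNP counts are filtered (distance to the nearest
intron > 50 bp, at most 10 SNPs per 200 bp window, DNA coverage >= 5),
aggregated to gene level using the median per-SNP allele-B fraction applied
to the summed total (rounded half-even, totals conserved exactly), and
normalized by ortholog-total size factors.  The raw-count filters run
before normalization; the mean-count >= 10 filter applies to final counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .io_formats import AlleleCountTable

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# SNP filtering and aggregation


def filter_snps(
    snps: pd.DataFrame,
    min_dna_coverage: float = 5,
    min_intron_dist_bp: float = 50,
    max_snps_per_window: int = 10,
    window_bp: int = 200,
):
    """Apply the mapping-bias SNP filters; returns (kept, dropped).

    A SNP is retained if it lies more than ``min_intron_dist_bp`` from the
    nearest intron, its DNA coverage is at least ``min_dna_coverage``, and no
    ``window_bp`` window containing it holds more than
    ``max_snps_per_window`` SNPs of the same gene (dense windows flag every
    SNP they contain).  ``dropped`` carries one reason code per removed SNP.
    """
    for col in ("gene_id", "pos", "dist_to_intron_bp", "dna_coverage"):
        if col not in snps.columns:
            raise KeyError(f"SNP table missing metadata column {col!r}")
    snps = snps.copy()
    reason = pd.Series("", index=snps.index, dtype=object)

    near = snps["dist_to_intron_bp"] <= min_intron_dist_bp
    reason[near] = "near_intron"
    lowcov = (snps["dna_coverage"] < min_dna_coverage) & (reason == "")
    reason[lowcov] = "low_dna_coverage"

    dense = pd.Series(False, index=snps.index)
    for _, grp in snps.groupby("gene_id"):
        pos = grp["pos"].sort_values()
        idx = pos.index.to_numpy()
        arr = pos.to_numpy(dtype=float)
        k = max_snps_per_window
        for i in range(len(arr) - k):
            if arr[i + k] - arr[i] <= window_bp:  # k+1 SNPs within the window
                dense[idx[i : i + k + 1]] = True
    reason[dense & (reason == "")] = "dense_region"

    kept = snps[reason == ""]
    dropped = snps[reason != ""].assign(reason=reason[reason != ""])
    return kept, dropped


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(np.asarray(x, dtype=float))


def aggregate_gene_alleles(snp_counts: pd.DataFrame):
    """Collapse per-SNP counts to per-(gene, sample) allele counts.

    The gene total is the sum of SNP totals; the allele-B share is the
    median across SNPs of the per-SNP allele-B fraction (SNPs with zero
    total are uninformative and skipped), applied to the total with
    half-even rounding so totals are conserved exactly.  (gene, sample)
    pairs where every SNP has zero total are returned as unquantifiable.
    """
    for col in ("gene_id", "sample_id", "count_a", "count_b"):
        if col not in snp_counts.columns:
            raise KeyError(f"SNP count table missing column {col!r}")
    df = snp_counts.copy()
    df["total"] = df["count_a"] + df["count_b"]
    rows, unquantifiable = [], []
    for (gene, sample), grp in df.groupby(["gene_id", "sample_id"], sort=True):
        total = grp["total"].sum()
        informative = grp[grp["total"] > 0]
        if len(informative) == 0:
            unquantifiable.append((gene, sample))
            continue
        frac_b = float(np.median(informative["count_b"] / informative["total"]))
        b = float(_round_half_even(frac_b * total))
        rows.append((gene, sample, total - b, b))
    counts = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "count_a", "count_b"]
    ).set_index(["gene_id", "sample_id"])
    return counts, pd.DataFrame(unquantifiable, columns=["gene_id", "sample_id"])


def normalize_alleles(table: AlleleCountTable):
    """Size-factor normalize gene-level allele counts.

    The factor of a sample is its total read count over retained orthologs
    divided by the median of those totals across samples.  Both allele
    columns are divided by the factor, so within-sample allele fractions are
    preserved exactly.  Returns (normalized table, factors).
    """
    totals = table.totals().groupby(level="sample_id").sum()
    factors = totals / np.median(totals.to_numpy())
    norm = table.counts.div(
        factors.reindex(table.counts.index.get_level_values("sample_id")).to_numpy(),
        axis=0,
    )
    return AlleleCountTable(norm, table.samples, table.snps), factors


# ---------------------------------------------------------------------------
# quasi-binomial test


@dataclass
class AseResult:
    """Per-gene ASE statistics for one hybrid.

    ``basal``: per-gene DataFrame with r0 (log2 allelic ratio at 0 h minus
    DNA), se, p, q, basal_cis.  ``plastic``: per (gene, timepoint) DataFrame
    with delta (allelic log2 ratio at t minus at 0 h), se, p, q,
    plastic_cis.  ``excluded``: genes not tested, with reason codes.
    """

    hybrid: str
    basal: pd.DataFrame
    plastic: pd.DataFrame
    excluded: pd.DataFrame
    dispersion: pd.Series


def _sample_types(samples: pd.DataFrame) -> pd.Series:
    types = pd.Series(index=samples.index, dtype=object)
    dna = samples["material"] == "DNA"
    types[dna] = "DNA"
    types[~dna] = [f"RNA_{t:g}" for t in samples.loc[~dna, "timepoint_h"]]
    return types


def test_ase(
    table: AlleleCountTable,
    hybrid: str,
    alpha_basal: float = 0.05,
    alpha_plastic: float = 0.1,
    min_mean_count: float = 10.0,
    dispersion_floor: float = 1.0,
) -> AseResult:
    """Quasi-binomial ASE test for one hybrid, all genes at once."""
    samples = table.samples[table.samples["genotype"] == hybrid]
    if (samples["material"] == "DNA").sum() == 0:
        raise ValueError(f"no DNA control samples for {hybrid}")
    types = _sample_types(samples)
    type_levels = ["DNA"] + [
        f"RNA_{t:g}" for t in sorted(samples["timepoint_h"].dropna().unique())
    ]
    timepoints = sorted(samples["timepoint_h"].dropna().unique())
    reps_per_type = types.value_counts()
    if (reps_per_type < 2).any():
        raise ValueError("each sample type needs >= 2 replicates")

    counts = table.counts[
        table.counts.index.get_level_values("sample_id").isin(samples.index)
    ]
    wide_a = counts["count_a"].unstack("sample_id")
    wide_b = counts["count_b"].unstack("sample_id")
    cols = [s for s in samples.index if s in wide_a.columns]
    wide_a, wide_b = wide_a[cols].fillna(0.0), wide_b[cols].fillna(0.0)
    type_of = types[cols].to_numpy()
    a = wide_a.to_numpy(dtype=float)
    b = wide_b.to_numpy(dtype=float)
    genes = wide_a.index
    n_genes = len(genes)
    n_types = len(type_levels)

    pooled_a = np.zeros((n_genes, n_types))
    pooled_b = np.zeros((n_genes, n_types))
    for j, lev in enumerate(type_levels):
        cols_j = type_of == lev
        pooled_a[:, j] = a[:, cols_j].sum(axis=1)
        pooled_b[:, j] = b[:, cols_j].sum(axis=1)
    pooled_n = pooled_a + pooled_b

    mean_count = (a + b).mean(axis=1)
    zero_type = (pooled_n == 0).any(axis=1)
    low = mean_count < min_mean_count
    excluded = zero_type | low
    reasons = np.where(zero_type, "zero_total_in_sample_type", "")
    reasons = np.where(low & (reasons == ""), "low_mean_count", reasons)

    # saturated fit: pooled fraction per type; continuity correction for
    # boundary estimates (a zero allele within a type)
    adj_a = pooled_a + np.where((pooled_a == 0) | (pooled_b == 0), 0.5, 0.0)
    adj_b = pooled_b + np.where((pooled_a == 0) | (pooled_b == 0), 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.log(adj_b / adj_a)  # logit of allele-B fraction per type
        p_hat = pooled_b / np.where(pooled_n > 0, pooled_n, np.nan)

    # Pearson dispersion over replicate observations
    p_rep = np.zeros_like(a)
    for j, lev in enumerate(type_levels):
        p_rep[:, type_of == lev] = p_hat[:, [j]]
    n_rep_tot = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = (b - n_rep_tot * p_rep) ** 2 / (
            n_rep_tot * p_rep * (1.0 - p_rep)
        )
    pearson[~np.isfinite(pearson)] = 0.0
    df_resid = (n_rep_tot > 0).sum(axis=1) - n_types
    df_resid = np.maximum(df_resid, 1)
    phi = np.maximum(pearson.sum(axis=1) / df_resid, dispersion_floor)

    # Wald variance of each type's logit under the saturated fit
    with np.errstate(divide="ignore", invalid="ignore"):
        info = pooled_n * p_hat * (1.0 - p_hat)
        info = np.where(info > 0, info, pooled_n * 0.25 * 0.1)  # boundary guard
        var_eta = phi[:, None] / info

    def _contrast(j1: int, j0: int, alpha: float, flag: str) -> pd.DataFrame:
        est = (eta[:, j1] - eta[:, j0]) / LN2
        se = np.sqrt(var_eta[:, j1] + var_eta[:, j0]) / LN2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = est / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        p[excluded] = np.nan
        q = bh_adjust(p)
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "stat": tstat,
                "p": p,
                "q": q,
                flag: np.where(np.isnan(q), False, q <= alpha),
                "excluded": excluded,
            },
            index=genes,
        )

    j_dna = type_levels.index("DNA")
    j_rna0 = type_levels.index("RNA_0")
    basal = _contrast(j_rna0, j_dna, alpha_basal, "basal_cis")
    basal = basal.rename(columns={"estimate": "r0"})

    plastic_frames = []
    for t in timepoints:
        if t == 0:
            continue
        j_t = type_levels.index(f"RNA_{t:g}")
        frame = _contrast(j_t, j_rna0, alpha_plastic, "plastic_cis")
        frame = frame.rename(columns={"estimate": "delta"})
        frame["timepoint_h"] = t
        plastic_frames.append(frame.reset_index(names="gene_id"))
    plastic = (
        pd.concat(plastic_frames, ignore_index=True).set_index(
            ["gene_id", "timepoint_h"]
        )
        if plastic_frames
        else pd.DataFrame()
    )

    excluded_df = pd.DataFrame(
        {"reason": reasons[excluded]}, index=genes[excluded]
    )
    return AseResult(
        hybrid=hybrid,
        basal=basal,
        plastic=plastic,
        excluded=excluded_df,
        dispersion=pd.Series(phi, index=genes, name="dispersion"),
    )
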