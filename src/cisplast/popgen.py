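"""Population-genetic summaries and the gene-resampling bootstrap.

Per-gene statistics: segregating sites, the average number of pairwise
differences per gene (pi; a per-site variant is exposed as an option),
Tajima's D at synonymous and nonsynonymous sites, and Ka/Ks divergence from
pairwise codon alignments.  Group comparisons resample genes with
replacement (B replicates, default 1000), recompute the group statistic,
and derive a two-sided p-value from the bootstrap distribution of the
difference, floored at 2/B.

Ka/Ks uses degenerate-site counting in the Li (1993) / Pamilo-Bianchi
style: codon positions are binned as 0-, 2- or 4-fold degenerate,
transitional and transversional differences are accumulated per class
(averaged over substitution pathways for multi-hit codons), and distances
are Kimura two-parameter corrected.  NG86 is available as an option.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from . import _codons
from .io_formats import PopulationData


# ---------------------------------------------------------------------------
# variant filtering


def filter_population(
    pop: PopulationData,
    min_depth: float = 10,
    min_gq: float = 20,
    min_qual: float = 30,
    max_missing: float = 0.8,
    downsample: bool = True,
    seed: int | None = 0,
):
    """Apply the variant filters, in order, then down-sample alleles.

    Order: indels out, multiallelic sites out, site quality < ``min_qual``
    out; genotypes with depth < ``min_depth`` or GQ < ``min_gq`` are set
    missing; sites where more than ``max_missing`` of individuals are
    missing are dropped.  Finally each remaining site is randomly
    down-sampled (seeded) to the minimum observed allele number across
    sites, so all sites share one sample size.

    Returns (sites DataFrame with ``alt_count``/``n_alleles``, dropped log).
    """
    sites = pop.sites.reset_index(drop=True)
    alleles = pop.alleles.copy()
    dropped = []

    def drop(mask, reason):
        for _, row in sites[mask].iterrows():
            dropped.append((row["chrom"], row["pos"], reason))

    keep = np.ones(len(sites), dtype=bool)
    m = keep & ~sites["is_snp"].to_numpy()
    drop(m, "indel")
    keep &= ~m
    m = keep & (sites["n_alt_alleles"].to_numpy() > 1)
    drop(m, "multiallelic")
    keep &= ~m
    qual = sites["qual"].to_numpy()
    m = keep & (np.nan_to_num(qual, nan=np.inf) < min_qual)
    drop(m, "low_site_quality")
    keep &= ~m

    # genotype-level masking: both alleles of a low-quality genotype go missing
    n_ind = pop.n_individuals
    bad_geno = np.zeros((len(sites), n_ind), dtype=bool)
    if pop.depth.size:
        bad_geno |= np.nan_to_num(pop.depth, nan=np.inf) < min_depth
    if pop.gq.size:
        bad_geno |= np.nan_to_num(pop.gq, nan=np.inf) < min_gq
    mask2 = np.repeat(bad_geno, 2, axis=1)
    alleles = np.where(mask2, -1, alleles)

    ind_missing = (
        (alleles.reshape(len(sites), n_ind, 2) < 0).any(axis=2).mean(axis=1)
        if len(sites)
        else np.zeros(0)
    )
    m = keep & (ind_missing > max_missing)
    drop(m, "excess_missing")
    keep &= ~m

    sites = sites[keep].reset_index(drop=True)
    alleles = alleles[keep]
    observed = [row[row >= 0] for row in alleles]
    n_obs = np.array([len(o) for o in observed], dtype=int)

    if len(sites) == 0:
        out = sites.assign(alt_count=[], n_alleles=[])
        return out, pd.DataFrame(dropped, columns=["chrom", "pos", "reason"])

    if downsample:
        target = int(n_obs.min())
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        alt_count = np.empty(len(sites), dtype=int)
        for i, obs in enumerate(observed):
            pick = (
                obs
                if len(obs) == target
                else obs[rng.choice(len(obs), size=target, replace=False)]
            )
            alt_count[i] = int((pick > 0).sum())
        n_alleles = np.full(len(sites), target)
    else:
        alt_count = np.array([int((o > 0).sum()) for o in observed])
        n_alleles = n_obs

    out = sites.assign(alt_count=alt_count, n_alleles=n_alleles)
    return out, pd.DataFrame(dropped, columns=["chrom", "pos", "reason"])


# ---------------------------------------------------------------------------
# SFS / diversity


def fold_sfs(alt_counts, n: int) -> np.ndarray:
    """Folded site frequency spectrum, classes 1 .. floor(n/2).

    ``alt_counts`` are derived/alt allele counts in a sample of ``n``
    alleles; monomorphic entries (0 or n) are ignored.
    """
    counts = np.asarray(alt_counts, dtype=int)
    counts = counts[(counts > 0) & (counts < n)]
    folded = np.minimum(counts, n - counts)
    out = np.zeros(n // 2, dtype=int)
    for c in folded:
        out[c - 1] += 1
    return out


def pi_from_counts(alt_counts, n: int, per_site: bool = False, n_sites: int | None = None) -> float:
    """Average number of pairwise differences from per-site allele counts.

    Per-gene total by default (the sum over sites of 2c(n-c)/(n(n-1)));
    ``per_site=True`` divides by ``n_sites`` (defaults to the number of
    supplied sites).
    """
    c = np.asarray(alt_counts, dtype=float)
    if n < 2:
        raise ValueError("need n >= 2 alleles")
    tot = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    if per_site:
        denom = n_sites if n_sites is not None else len(c)
        return tot / denom if denom else np.nan
    return tot


def pi_pairwise(haplotypes) -> float:
    """Mean pairwise difference across haplotypes (direct double loop)."""
    hap = np.asarray(haplotypes)
    n = hap.shape[1]
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    diffs = [
        (hap[:, i] != hap[:, j]).sum() for i, j in combinations(range(n), 2)
    ]
    return float(np.mean(diffs))


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites, pi and the sample size.

    Uses the 1989 constants a1, a2, b1, b2, c1, c2, e1, e2.  Undefined
    (NaN) when S = 0.
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return np.nan
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi - S / a1) / np.sqrt(var))


def gene_stats(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary statistics from a filtered site table.

    ``sites`` needs columns gene_id, site_class, alt_count, n_alleles (one
    shared n).  Returns per gene S_syn, S_nonsyn, pi, pi_n, pi_s, D_syn,
    D_nonsyn.
    """
    rows = []
    for gene, grp in sites.groupby("gene_id"):
        n = int(grp["n_alleles"].iloc[0])
        seg = grp[(grp["alt_count"] > 0) & (grp["alt_count"] < n)]
        syn = seg[seg["site_class"] == "synonymous"]
        non = seg[seg["site_class"] == "nonsynonymous"]
        pi_all = pi_from_counts(seg["alt_count"], n)
        pi_s = pi_from_counts(syn["alt_count"], n)
        pi_n = pi_from_counts(non["alt_count"], n)
        rows.append(
            {
                "gene_id": gene,
                "n_alleles": n,
                "S_syn": len(syn),
                "S_nonsyn": len(non),
                "pi": pi_all,
                "pi_s": pi_s,
                "pi_n": pi_n,
                "D_syn": tajimas_d(len(syn), pi_s, n),
                "D_nonsyn": tajimas_d(len(non), pi_n, n),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Ka/Ks


def _k2p(P: float, Q: float):
    """Kimura two-parameter transition (A) and transversion (B) distances."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return np.nan, np.nan
    A = 0.5 * np.log(1.0 / w1) - 0.25 * np.log(1.0 / w2)
    B = 0.5 * np.log(1.0 / w2)
    return A, B


def kaks(seq1: str, seq2: str, method: str = "li93"):
    """Pairwise Ka and Ks by degenerate-site counting.

    ``method="li93"`` (default): Li (1993) / Pamilo-Bianchi weighting of
    K2P distances over 0-/2-/4-fold degenerate sites.  ``method="ng86"``:
    Nei-Gojobori fractional site counting with Jukes-Cantor correction.
    Codons containing gaps, ambiguity codes or stops are skipped.
    Returns (Ka, Ks); components are NaN when undefined (saturation, or no
    sites of the needed class).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq1) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    seq1, seq2 = seq1.upper(), seq2.upper()

    L = np.zeros(3)  # L0, L2, L4 averaged over the two sequences
    ts = np.zeros(3)  # transitional differences per class
    tv = np.zeros(3)  # transversional differences per class
    ng_sites = np.zeros(2)  # syn, nonsyn fractional sites (both sequences)
    ng_diffs = np.zeros(2)  # syn, nonsyn fractional differences

    cls_idx = {0: 0, 2: 1, 4: 2}
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if (
            c1 not in _codons.CODON_TO_AA
            or c2 not in _codons.CODON_TO_AA
        ):
            continue  # gap, ambiguity or stop codon
        n_codons += 1
        for codon in (c1, c2):
            l0, l2, l4 = _codons.codon_site_counts(codon)
            L += 0.5 * np.array([l0, l2, l4])
            s, ns = _codons.fractional_site_counts(codon)
            ng_sites += 0.5 * np.array([s, ns])
        for deg, is_ts, syn, w in _codons.pathway_events(c1, c2):
            j = cls_idx[deg]
            if is_ts:
                ts[j] += w
            else:
                tv[j] += w
            ng_diffs[0 if syn else 1] += w
    if n_codons == 0:
        return np.nan, np.nan

    if method == "li93":
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(L > 0, ts / L, 0.0)
            Q = np.where(L > 0, tv / L, 0.0)
        AB = [_k2p(P[j], Q[j]) for j in range(3)]
        A = np.array([ab[0] for ab in AB])
        B = np.array([ab[1] for ab in AB])
        L0, L2, L4 = L
        ks = (
            (L2 * A[1] + L4 * A[2]) / (L2 + L4) + B[2]
            if (L2 + L4) > 0
            else np.nan
        )
        ka = (
            A[0] + (L0 * B[0] + L2 * B[1]) / (L0 + L2)
            if (L0 + L2) > 0
            else np.nan
        )
        return float(ka), float(ks)
    if method == "ng86":
        with np.errstate(invalid="ignore", divide="ignore"):
            ps = ng_diffs / ng_sites
        out = []
        for p in ps[::-1]:  # (nonsyn, syn) -> return (Ka, Ks)
            if not np.isfinite(p) or p >= 0.75:
                out.append(np.nan)
            else:
                out.append(float(-0.75 * np.log(1.0 - 4.0 * p / 3.0)))
        return out[0], out[1]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# bootstrap comparison


def bootstrap_compare(
    groups: dict,
    B: int = 1000,
    seed: int = 0,
    statistic=np.nanmean,
    min_group_size: int = 30,
):
    """Gene-resampling bootstrap comparison of per-gene statistics.

    ``groups`` maps group label -> array of per-gene values (NaNs allowed;
    the statistic must tolerate them, as ``nanmean`` does).  For each group,
    B bootstrap replicates resample genes with replacement and recompute
    the statistic.  For each pair, the p-value is the proportion of the
    pooled bootstrap differences on the minority side of zero, doubled
    (one-sided construction made two-sided), floored at 2/B and capped at 1.
    """
    labels = list(groups)
    for lab in labels:
        if len(np.asarray(groups[lab])) < min_group_size:
            warnings.warn(
                f"group {lab!r} has fewer than {min_group_size} genes; "
                "bootstrap variance will be high",
                RuntimeWarning,
            )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    boots = {}
    means = {}
    for lab in labels:
        vals = np.asarray(groups[lab], dtype=float)
        idx = rng.integers(0, len(vals), size=(B, len(vals)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boots[lab] = statistic(vals[idx], axis=1)
            means[lab] = float(statistic(vals))
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            delta = boots[g1] - boots[g2]
            delta = delta[np.isfinite(delta)]
            if len(delta) == 0:
                rows.append((g1, g2, np.nan, np.nan))
                continue
            lo = int((delta <= 0).sum())
            hi = int((delta >= 0).sum())
            p = 2.0 * min(lo, hi) / len(delta)
            p = min(max(p, 2.0 / B), 1.0)
            rows.append((g1, g2, float(np.mean(delta)), p))
    pairs = pd.DataFrame(
        rows, columns=["group1", "group2", "mean_difference", "p"]
    )
    return {
        "means": pd.Series(means),
        "bootstrap": pd.DataFrame(boots),
        "pairwise": pairs,
    }


def d_index(d1, d2):
    """Interspecific Tajima's D index (d1 + 2) / (d2 + 2).

    Tajima's D cannot reach -2 in practice; a denominator at or below zero
    is flagged (NaN with a warning) rather than guessed at.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    denom = d2 + 2.0
    bad = denom <= 0
    if np.any(bad):
        warnings.warn("d_index undefined where the denominator D + 2 <= 0",
                      RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (d1 + 2.0) / denom)
    return out if out.ndim else float(out)
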