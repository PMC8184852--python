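"""Diversity statistics, Ka/Ks, VCF filtering and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisplast import io_formats, popgen
from cisplast.popgen import (
    bootstrap_compare,
    d_index,
    filter_population,
    fold_sfs,
    kaks,
    pi_from_counts,
    pi_pairwise,
    tajimas_d,
)


def _textbook_tajimas_d(hap: np.ndarray) -> float:
    """Independent re-derivation straight from the 1989 definitions."""
    n = hap.shape[1]
    sums = hap.sum(axis=1)
    S = int(((sums > 0) & (sums < n)).sum())
    if S == 0:
        return np.nan
    # pi as the average over all pairs of haplotypes
    diffs, pairs = 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((hap[:, i] != hap[:, j]).sum())
            pairs += 1
    pi = diffs / pairs
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# folded SFS and pi


def test_fold_sfs_trivial_bins():
    assert fold_sfs([3], 4).tolist() == [1, 0]
    assert fold_sfs([2], 4).tolist() == [0, 1]
    assert fold_sfs([1, 3, 2], 4).tolist() == [2, 1]


@settings(deadline=None, derandomize=True)
@given(
    st.integers(4, 20).flatmap(
        lambda n: st.tuples(
            st.just(n), st.lists(st.integers(0, n), min_size=0, max_size=60)
        )
    )
)
def test_fold_sfs_matches_brute_force(n_counts):
    n, counts = n_counts
    sfs = fold_sfs(counts, n)
    brute = np.zeros(n // 2, dtype=int)
    for c in counts:
        if 0 < c < n:
            brute[min(c, n - c) - 1] += 1
    assert np.array_equal(sfs, brute)
    assert sfs.sum() == sum(1 for c in counts if 0 < c < n)


def test_pi_two_haplotypes_three_differences():
    hap = np.zeros((3, 2), dtype=int)
    hap[:, 1] = 1
    assert pi_pairwise(hap) == 3.0
    assert pi_from_counts(hap.sum(axis=1), 2) == pytest.approx(3.0)


def test_pi_routes_agree():
    """pi from allele counts equals pi from explicit pairwise comparison."""
    rng = np.random.default_rng(20)
    for _ in range(20):
        n = int(rng.integers(4, 24))
        hap = (rng.random((rng.integers(1, 80), n)) < rng.uniform(0.05, 0.5)).astype(int)
        assert pi_from_counts(hap.sum(axis=1), n) == pytest.approx(
            pi_pairwise(hap), abs=1e-9
        )


# ---------------------------------------------------------------------------
# Tajima's D


def test_tajimas_d_zero_when_pi_equals_watterson():
    # n=4: a1 = 1 + 1/2 + 1/3, S=11 gives theta_W = 6, so pi=6 -> D = 0
    assert tajimas_d(11, 6.0, 4) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_undefined_without_segregating_sites():
    assert np.isnan(tajimas_d(0, 0.0, 10))


def test_tajimas_d_matches_textbook_oracle():
    rng = np.random.default_rng(21)
    for _ in range(100):
        hap = (rng.random((200, 20)) < 0.1).astype(int)
        counts = hap.sum(axis=1)
        seg = counts[(counts > 0) & (counts < 20)]
        mine = tajimas_d(len(seg), pi_from_counts(seg, 20), 20)
        assert mine == pytest.approx(_textbook_tajimas_d(hap), abs=1e-10)


# ---------------------------------------------------------------------------
# Ka/Ks


def test_kaks_identical_sequences_zero():
    seq = "ATGGCTAAAGGT" * 30
    assert kaks(seq, seq) == (0.0, 0.0)
    assert kaks(seq, seq, method="ng86") == (0.0, 0.0)


def test_kaks_single_fourfold_transition_hand_computed():
    """100 GGT codons with one third-position transition (T->C): all third
    positions are 4-fold, so Ks = A4 = 0.5 ln(1/(1 - 2/100)) and Ka = 0."""
    s1 = "GGT" * 100
    s2 = "GGC" + "GGT" * 99
    ka, ks = kaks(s1, s2)
    assert ka == pytest.approx(0.0, abs=1e-12)
    assert ks == pytest.approx(0.5 * np.log(1 / 0.98), rel=1e-9)


def test_kaks_skips_gapped_codons():
    s1 = "ATG" + "GGT" * 50
    s2 = "AT-" + "GGT" * 50
    assert kaks(s1, s2) == (0.0, 0.0)


def test_kaks_alignment_validation():
    with pytest.raises(ValueError):
        kaks("ATG", "ATGGGT")
    with pytest.raises(ValueError):
        kaks("ATGC", "ATGC")


# ---------------------------------------------------------------------------
# population filtering


def _toy_population(tmp_path):
    """Six records: one indel, one triallelic, one where every genotype has
    low GQ (hence >80% missing), three clean SNPs."""
    vcf = tmp_path / "pop.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tind1\tind2",
        "1\t10\t.\tA\tT\t60\tPASS\t.\tGT:DP:GQ\t0/1:30:99\t0/0:30:99",
        "1\t20\t.\tA\tAT\t60\tPASS\t.\tGT:DP:GQ\t0/1:30:99\t0/0:30:99",
        "1\t30\t.\tG\tC,T\t60\tPASS\t.\tGT:DP:GQ\t0/1:30:99\t0/2:30:99",
        "1\t40\t.\tC\tG\t60\tPASS\t.\tGT:DP:GQ\t0/1:30:5\t1/1:30:5",
        "1\t50\t.\tT\tA\t60\tPASS\t.\tGT:DP:GQ\t1/1:30:99\t0/0:30:99",
        "1\t60\t.\tT\tG\t60\tPASS\t.\tGT:DP:GQ\t0/0:30:99\t0/1:30:99",
    ]
    vcf.write_text("\n".join(lines) + "\n")
    ann = tmp_path / "ann.tsv"
    pd.DataFrame(
        {
            "chrom": "1",
            "pos": [10, 20, 30, 40, 50, 60],
            "site_class": ["synonymous", "other", "nonsynonymous", "synonymous",
                           "nonsynonymous", "synonymous"],
            "gene_id": "g1",
        }
    ).to_csv(ann, sep="\t", index=False)
    return vcf, ann


def test_filter_population_hand_counted_toy(tmp_path):
    vcf, ann = _toy_population(tmp_path)
    pop = io_formats.read_population(vcf, ann)
    assert len(pop.sites) == 6
    sites, dropped = filter_population(pop)
    assert len(sites) == 3
    reasons = dropped.set_index("pos")["reason"]
    assert reasons.loc[20] == "indel"
    assert reasons.loc[30] == "multiallelic"
    assert reasons.loc[40] == "excess_missing"
    # all remaining sites share the down-sampled allele number
    assert sites["n_alleles"].nunique() == 1


def test_downsampling_identity_when_complete(tmp_path):
    vcf, ann = _toy_population(tmp_path)
    pop = io_formats.read_population(vcf, ann)
    sites, _ = filter_population(pop)
    # two diploid individuals, no missing genotypes at retained sites -> 4
    assert (sites["n_alleles"] == 4).all()
    assert sites.set_index("pos")["alt_count"].loc[50] == 2


def test_downsampling_preserves_frequencies():
    """Random down-sampling must not shift expected allele frequencies."""
    rng = np.random.default_rng(22)
    n_sites = 10_000
    freqs = rng.uniform(0.05, 0.95, n_sites)
    full = (rng.random((n_sites, 20)) < freqs[:, None]).astype(np.int16)
    # site 0 has two missing alleles, so the target is 18
    full[0, :2] = -1
    pop = io_formats.PopulationData(
        sites=pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, n_sites + 1),
                "ref": "A",
                "alt": "T",
                "qual": 60.0,
                "n_alt_alleles": 1,
                "is_snp": True,
                "site_class": "synonymous",
                "gene_id": "g1",
            }
        ),
        alleles=full,
        depth=np.empty((0, 0)),
        gq=np.empty((0, 0)),
    )
    sites, _ = filter_population(pop, seed=1)
    assert (sites["n_alleles"] == 18).all()
    before = np.where(full < 0, np.nan, full)
    f_before = np.nanmean(before, axis=1)
    f_after = sites["alt_count"].to_numpy() / 18
    assert abs(np.mean(f_after - f_before)) < 0.01


def test_gene_stats_flags(tmp_path):
    vcf, ann = _toy_population(tmp_path)
    pop = io_formats.read_population(vcf, ann)
    sites, _ = filter_population(pop)
    stats_df = popgen.gene_stats(sites)
    row = stats_df.loc["g1"]
    assert row["S_syn"] + row["S_nonsyn"] == 3
    assert row["pi"] > 0


# ---------------------------------------------------------------------------
# bootstrap and the D index


def test_bootstrap_identical_groups_large_p():
    vals = np.random.default_rng(23).normal(size=200)
    res = bootstrap_compare({"a": vals, "b": vals.copy()}, B=1000, seed=5)
    assert res["pairwise"]["p"].iloc[0] > 0.3


def test_bootstrap_separated_groups_floor_p():
    rng = np.random.default_rng(24)
    a = rng.normal(0.0, 1.0, 100)
    b = rng.normal(5.0, 1.0, 100)
    res = bootstrap_compare({"a": a, "b": b}, B=1000, seed=6)
    assert res["pairwise"]["p"].iloc[0] == pytest.approx(2 / 1000)


def test_bootstrap_seed_reproducible():
    rng = np.random.default_rng(25)
    groups = {"a": rng.normal(size=80), "b": rng.normal(size=90)}
    r1 = bootstrap_compare(groups, B=500, seed=9)
    r2 = bootstrap_compare(groups, B=500, seed=9)
    pd.testing.assert_frame_equal(r1["pairwise"], r2["pairwise"])
    assert not r1["pairwise"].equals(
        bootstrap_compare(groups, B=500, seed=10)["pairwise"]
    )


def test_bootstrap_small_group_warns():
    with pytest.warns(RuntimeWarning, match="fewer than"):
        bootstrap_compare({"a": np.arange(5), "b": np.arange(40)}, B=100, seed=1)


def test_bootstrap_null_rejection_rate():
    """Two groups drawn from one distribution reject at 5% no more than 7%
    of the time over 500 trials."""
    rng = np.random.default_rng(26)
    rejections = 0
    n_trials = 500
    for trial in range(n_trials):
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        res = bootstrap_compare({"a": a, "b": b}, B=200, seed=trial)
        if res["pairwise"]["p"].iloc[0] < 0.05:
            rejections += 1
    assert rejections / n_trials <= 0.07


def test_d_index_values():
    assert d_index(0.5, 0.5) == pytest.approx(1.0)
    assert d_index(-2.0, 0.0) == pytest.approx(0.0)
    assert d_index(0.5, -0.5) == pytest.approx(2.5 / 1.5)
    with pytest.warns(RuntimeWarning, match="denominator"):
        assert np.isnan(d_index(0.5, -2.5))
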