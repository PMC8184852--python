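"""SNP filters, aggregation, normalization and the quasi-binomial ASE test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisplast import ase
from cisplast.io_formats import AlleleCountTable


def _snp_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "pos", "dist_to_intron_bp", "dna_coverage"]
    )


@pytest.mark.parametrize(
    "dist, cov, kept",
    [
        (30, 50, False),   # too close to an intron
        (50, 50, False),   # boundary: "more than 50 bp" means 50 is out
        (51, 50, True),
        (100, 4, False),   # DNA coverage below 5
        (100, 5, True),    # coverage exactly 5 is kept
    ],
)
def test_filter_snps_boundaries(dist, cov, kept):
    snps = _snp_frame([("g1", 100, dist, cov)])
    retained, dropped = ase.filter_snps(snps)
    assert (len(retained) == 1) is kept
    assert (len(dropped) == 1) is (not kept)


def test_filter_snps_dense_window():
    """Eleven SNPs inside one 200 bp window are all removed; a sparser gene
    at the same positions spread out survives."""
    dense = _snp_frame([("g1", 1000 + 10 * i, 100, 50) for i in range(11)])
    retained, dropped = ase.filter_snps(dense)
    assert len(retained) == 0
    assert (dropped["reason"] == "dense_region").all()
    sparse = _snp_frame([("g2", 1000 + 50 * i, 100, 50) for i in range(11)])
    retained, _ = ase.filter_snps(sparse)
    assert len(retained) == 11


def test_filter_snps_ten_in_window_kept():
    snps = _snp_frame([("g1", 1000 + 20 * i, 100, 50) for i in range(10)])
    retained, _ = ase.filter_snps(snps)
    assert len(retained) == 10


def test_filter_snps_missing_column():
    with pytest.raises(KeyError, match="dna_coverage"):
        ase.filter_snps(pd.DataFrame({"gene_id": [], "pos": [], "dist_to_intron_bp": []}))


# ---------------------------------------------------------------------------
# aggregation and normalization


def test_aggregate_single_snp_identity():
    snp = pd.DataFrame(
        {"gene_id": ["g1"], "sample_id": ["s1"], "count_a": [30.0], "count_b": [70.0]}
    )
    counts, unq = ase.aggregate_gene_alleles(snp)
    assert counts.loc[("g1", "s1"), "count_a"] == 30
    assert counts.loc[("g1", "s1"), "count_b"] == 70
    assert len(unq) == 0


def test_aggregate_median_fraction():
    """Three SNPs with B-fractions 0.2/0.5/0.9 and totals 100 each: the
    median fraction 0.5 applied to the total 300 gives (150, 150)."""
    snp = pd.DataFrame(
        {
            "gene_id": "g1",
            "sample_id": "s1",
            "count_a": [80.0, 50.0, 10.0],
            "count_b": [20.0, 50.0, 90.0],
        }
    )
    counts, _ = ase.aggregate_gene_alleles(snp)
    assert counts.loc[("g1", "s1"), "count_a"] == 150
    assert counts.loc[("g1", "s1"), "count_b"] == 150


def test_aggregate_conserves_totals():
    rng = np.random.default_rng(4)
    snp = pd.DataFrame(
        {
            "gene_id": rng.choice(["g1", "g2", "g3"], 60),
            "sample_id": rng.choice(["s1", "s2"], 60),
            "count_a": rng.poisson(40, 60).astype(float),
            "count_b": rng.poisson(60, 60).astype(float),
        }
    )
    counts, _ = ase.aggregate_gene_alleles(snp)
    got = counts.sum(axis=1).groupby("gene_id").sum().sort_index()
    want = (snp["count_a"] + snp["count_b"]).groupby(snp["gene_id"]).sum().sort_index()
    assert np.allclose(got, want)


def test_aggregate_all_zero_unquantifiable():
    snp = pd.DataFrame(
        {"gene_id": ["g1"], "sample_id": ["s1"], "count_a": [0.0], "count_b": [0.0]}
    )
    counts, unq = ase.aggregate_gene_alleles(snp)
    assert len(counts) == 0
    assert unq.iloc[0].tolist() == ["g1", "s1"]


def _table(counts_by_sample, types):
    """Build an AlleleCountTable from {sample: (a, b)} and type labels."""
    rows, sheet = [], []
    for (sid, (a, b)), (mat, t, rep) in zip(counts_by_sample.items(), types):
        rows.append(("g1", sid, float(a), float(b)))
        sheet.append((sid, "hybrid1", mat, t, rep))
    counts = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "count_a", "count_b"]
    ).set_index(["gene_id", "sample_id"])
    samples = pd.DataFrame(
        sheet, columns=["sample_id", "genotype", "material", "timepoint_h", "replicate"]
    ).set_index("sample_id")
    return AlleleCountTable(counts, samples)


def test_normalize_equal_totals_unit_factors(sim_null):
    _, act, _ = sim_null
    norm, factors = ase.normalize_alleles(act)
    totals = act.totals().groupby(level="sample_id").sum()
    brute = totals / np.median(totals)
    assert np.allclose(factors.sort_index(), brute.sort_index())
    # allele fractions preserved exactly
    before = act.counts["count_b"] / act.totals().replace(0, np.nan)
    after = norm.counts["count_b"] / norm.totals().replace(0, np.nan)
    pd.testing.assert_series_equal(before, after)


def test_normalize_scaled_sample():
    tab = _table(
        {"s1": (50, 50), "s2": (150, 150), "s3": (50, 50)},
        [("RNA", 0.0, 1), ("RNA", 0.0, 2), ("RNA", 0.0, 3)],
    )
    _, factors = ase.normalize_alleles(tab)
    assert factors["s2"] == pytest.approx(3.0)
    assert factors["s1"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# the quasi-binomial test


def _full_design(dna, rna0, rna_other=None, n_rep=4):
    """Seven sample types x n_rep with per-type (a, b) tuples."""
    rna_other = rna_other or rna0
    counts, types = {}, []
    for rep in range(1, n_rep + 1):
        counts[f"dna_r{rep}"] = dna
        types.append(("DNA", np.nan, rep))
    for t in (0.0, 1.5, 3.0, 6.0, 12.0, 24.0):
        for rep in range(1, n_rep + 1):
            counts[f"rna{t:g}_r{rep}"] = rna0 if t == 0 else rna_other
            types.append(("RNA", t, rep))
    return _table(counts, types)


def test_ase_null_no_call():
    tab = _full_design(dna=(100, 100), rna0=(100, 100))
    res = ase.test_ase(tab, "hybrid1")
    assert res.basal["r0"].iloc[0] == pytest.approx(0.0)
    assert not res.basal["basal_cis"].iloc[0]
    assert res.basal["q"].iloc[0] > 0.9


def test_ase_strong_basal_signal():
    """DNA 50:50, RNA 0 h 150:50: the pooled exact-binomial oracle gives
    p << 1e-6, and the quasi-binomial test must also reject."""
    oracle = stats.binomtest(600, 800, 0.5).pvalue
    assert oracle < 1e-6
    tab = _full_design(dna=(200, 200), rna0=(50, 150))
    res = ase.test_ase(tab, "hybrid1")
    assert res.basal["basal_cis"].iloc[0]
    assert res.basal["q"].iloc[0] <= 0.05
    assert res.basal["r0"].iloc[0] == pytest.approx(np.log2(3), abs=1e-6)


def test_ase_mapping_bias_absorbed_by_dna():
    """A 60:40 bias present in both DNA and RNA is not called as ASE."""
    tab = _full_design(dna=(80, 120), rna0=(80, 120))
    res = ase.test_ase(tab, "hybrid1")
    assert not res.basal["basal_cis"].iloc[0]
    assert abs(res.basal["r0"].iloc[0]) < 1e-9


def test_ase_plastic_contrast():
    tab = _full_design(dna=(100, 100), rna0=(100, 100), rna_other=(50, 150))
    res = ase.test_ase(tab, "hybrid1")
    row = res.plastic.loc[("g1", 6.0)]
    assert row["delta"] == pytest.approx(np.log2(3), abs=1e-6)
    assert row["plastic_cis"]
    # the 0 h reference never appears as its own plastic contrast
    assert ("g1", 0.0) not in res.plastic.index


def test_ase_zero_sample_type_excluded():
    tab = _full_design(dna=(0, 0), rna0=(100, 100))
    res = ase.test_ase(tab, "hybrid1")
    assert res.excluded.loc["g1", "reason"] == "zero_total_in_sample_type"
    assert np.isnan(res.basal["p"].iloc[0])


def test_ase_matches_statsmodels_quasibinomial():
    """The closed-form saturated fit must agree with a statsmodels GLM
    (binomial family, Pearson-X2 scale) on the same contrast."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(8)
    # beta-binomial replicates: real overdispersion, so the floor at 1 is
    # inactive and the Pearson scales must match
    tab_counts, types = {}, []
    labels = [("DNA", np.nan)] + [("RNA", t) for t in (0.0, 1.5, 3.0, 6.0, 12.0, 24.0)]
    frac, trials, groups = [], [], []
    rho = 0.05
    for j, (mat, t) in enumerate(labels):
        m = rng.uniform(0.3, 0.7)
        conc = (1 - rho) / rho
        for rep in range(1, 5):
            n = 400
            b = rng.binomial(n, rng.beta(m * conc, (1 - m) * conc))
            tab_counts[f"{mat}{t}_r{rep}"] = (n - b, b)
            types.append((mat, t, rep))
            frac.append(b / n)
            trials.append(n)
            groups.append(j)
    tab = _table(tab_counts, types)
    res = ase.test_ase(tab, "hybrid1", min_mean_count=0)

    X = np.zeros((len(groups), len(labels)))
    X[np.arange(len(groups)), groups] = 1.0
    fit = sm.GLM(
        np.asarray(frac),
        X,
        family=sm.families.Binomial(),
        var_weights=np.asarray(trials, float),
    ).fit(scale="X2")
    assert fit.df_resid == 21  # same residual df as the closed form
    assert res.dispersion.iloc[0] == pytest.approx(float(fit.scale), rel=1e-6)
    contrast = np.zeros(len(labels))
    contrast[1], contrast[0] = 1.0, -1.0  # RNA 0h vs DNA
    tres = fit.t_test(contrast)
    assert res.basal["r0"].iloc[0] == pytest.approx(
        float(np.ravel(tres.effect)[0]) / np.log(2), rel=1e-6
    )
    assert res.basal["se"].iloc[0] == pytest.approx(
        float(np.ravel(tres.sd)[0]) / np.log(2), rel=1e-6
    )


def test_ase_type_one_error_controlled(null_ase):
    assert (null_ase.basal["q"] <= 0.05).mean() <= 0.07


def test_ase_bias_immunity(null_ase, bias_ase):
    """Planted mapping bias up to +-0.5 log2 must not inflate ASE calls."""
    k1 = int((null_ase.basal["q"] <= 0.05).sum())
    k2 = int((bias_ase.basal["q"] <= 0.05).sum())
    n1, n2 = len(null_ase.basal), len(bias_ase.basal)
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if min(k1, k2) == 0:
        p = stats.fisher_exact(table)[1]
    else:
        p = stats.chi2_contingency(table, correction=False)[1]
    assert p > 0.01
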