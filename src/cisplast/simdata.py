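"""Synthetic data with planted ground truth.

The generator emulates the statistical structure the inference chain assumes:

* parental read counts are negative-binomial over a stress time course
  (six timepoints, four replicates by default), with a per-gene baseline and
  a plastic slope shared across species except where a planted basal or
  slope effect separates a derived lineage from the outgroup;
* hybrid allele counts are beta-binomial around the cis log-odds, so that
  planted *cis* effects show up both in the parental contrast and in the
  hybrid allelic ratio, while *trans* effects move both hybrid alleles
  together and therefore only appear in the parental contrast;
* every gene carries a Gaussian mapping-bias shift on the allelic log-odds
  that is shared between the DNA control and all RNA samples of that gene,
  which is exactly what the DNA-baseline contrast is there to absorb;
* population fixtures draw site frequencies from the neutral spectrum
  (P(i) proportional to 1/i) and codon-alignment fixtures plant synonymous /
  nonsynonymous substitutions at requested per-site rates.

Seeding uses one master seed; each gene gets its own substream derived by
counter-based hashing (``SeedSequence(seed, spawn_key=(gene,))``), so
enlarging ``n_genes`` never reshuffles earlier genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlleleCountTable, ExpressionMatrix

LN2 = np.log(2.0)

#: the nine planted modes: basal class (none/ortho/para) x plastic class
#: (none/magnified/mitigated), excluding the fully-invariant cell which is
#: simply "none".
MODES = (
    "none",
    "Only-Ortho",
    "Only-Para",
    "Only-Mag",
    "Only-Mit",
    "Ortho-Mag",
    "Ortho-Mit",
    "Para-Mag",
    "Para-Mit",
)

_MODE_COMPONENTS = {
    "none": (0, 0),
    "Only-Ortho": (+1, 0),
    "Only-Para": (-1, 0),
    "Only-Mag": (0, +1),
    "Only-Mit": (0, -1),
    "Ortho-Mag": (+1, +1),
    "Ortho-Mit": (+1, -1),
    "Para-Mag": (-1, +1),
    "Para-Mit": (-1, -1),
}


class SimConfigError(ValueError):
    """An invalid field in a :class:`SimConfig`; the message names it."""


@dataclass
class SimConfig:
    """Parameters of the synthetic F1-hybrid time-course experiment.

    ``mean_depth`` is the expected read count per gene per sample;
    ``nb_dispersion`` is the negative-binomial dispersion (variance =
    mu + dispersion * mu^2); ``bb_overdispersion`` the beta-binomial
    intraclass correlation rho; ``effect_log2`` the magnitude of planted
    basal/slope effects; ``plastic_slope_log2`` the outgroup response slope
    at the reference timepoint (6 h); ``mapping_bias_sd`` the SD (log2
    odds) of the per-gene mapping bias shared by DNA and RNA samples.
    """

    n_genes: int = 1000
    timepoints_h: tuple = (0.0, 1.5, 3.0, 6.0, 12.0, 24.0)
    n_replicates: int = 4
    mean_depth: float = 200.0
    nb_dispersion: float = 0.01
    bb_overdispersion: float = 0.01
    mode_proportions: dict = field(
        default_factory=lambda: {
            "none": 0.36,
            "Only-Ortho": 0.08,
            "Only-Para": 0.08,
            "Only-Mag": 0.08,
            "Only-Mit": 0.08,
            "Ortho-Mag": 0.08,
            "Ortho-Mit": 0.08,
            "Para-Mag": 0.08,
            "Para-Mit": 0.08,
        }
    )
    cis_fraction: float = 0.5
    effect_log2: float = 1.5
    plastic_slope_log2: float = 2.0
    mapping_bias_sd: float = 0.2
    origin_proportions: tuple = (0.4, 0.4, 0.2)  # derived1, derived2, shared
    gene_mean_log2_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_genes) < 1:
            raise SimConfigError("n_genes must be a positive integer")
        self.timepoints_h = tuple(float(t) for t in self.timepoints_h)
        if len(self.timepoints_h) < 2 or self.timepoints_h[0] != 0.0:
            raise SimConfigError("timepoints_h must start at 0 with >= 2 points")
        if sorted(self.timepoints_h) != list(self.timepoints_h):
            raise SimConfigError("timepoints_h must be ordered")
        if int(self.n_replicates) < 1:
            raise SimConfigError("n_replicates must be a positive integer")
        if self.mean_depth <= 0:
            raise SimConfigError("mean_depth must be strictly positive")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if not (0.0 <= self.bb_overdispersion < 1.0):
            raise SimConfigError("bb_overdispersion must be in [0, 1)")
        props = self.mode_proportions
        if set(props) != set(MODES):
            raise SimConfigError("mode_proportions must cover exactly the 9 modes")
        if any(v < 0 for v in props.values()):
            raise SimConfigError("mode_proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise SimConfigError("mode_proportions must sum to 1 (within 1e-9)")
        if not (0.0 <= self.cis_fraction <= 1.0):
            raise SimConfigError("cis_fraction must be in [0, 1]")
        if self.effect_log2 < 0:
            raise SimConfigError("effect_log2 must be >= 0")
        if self.mapping_bias_sd < 0:
            raise SimConfigError("mapping_bias_sd must be >= 0")
        if abs(sum(self.origin_proportions) - 1.0) > 1e-9:
            raise SimConfigError("origin_proportions must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints_h"] = list(self.timepoints_h)
        d["origin_proportions"] = list(self.origin_proportions)
        return d


def time_profile(timepoints_h, peak_h: float = 6.0) -> np.ndarray:
    """Shape of the stress response over time, scaled to 1 at ``peak_h``.

    Linear rise to the peak, then linear relaxation to half the peak by 24 h
    — the qualitative shape of an acute-dehydration response that is
    strongest a few hours into the stress.
    """
    t = np.asarray(timepoints_h, dtype=float)
    rise = np.clip(t / peak_h, 0.0, 1.0)
    decay = np.clip(1.0 - 0.5 * (t - peak_h) / (24.0 - peak_h), 0.5, 1.0)
    return np.where(t <= peak_h, rise, decay)


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))


def _bb_draw(rng, n, p, rho):
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - rho) / rho
    a = np.maximum(p * conc, 1e-12)
    b = np.maximum((1.0 - p) * conc, 1e-12)
    return rng.binomial(n, rng.beta(a, b))


def _sample_frame(timepoints_h, n_replicates):
    """Sample sheet for the full design (3 parents, 2 hybrids, DNA controls)."""
    rows = []
    for geno in ("outgroup", "derived1", "derived2", "hybrid1", "hybrid2"):
        for t in timepoints_h:
            for rep in range(1, n_replicates + 1):
                sid = f"{geno}_t{t:g}_r{rep}"
                rows.append((sid, geno, "RNA", t, rep))
    for geno in ("hybrid1", "hybrid2"):
        for rep in range(1, n_replicates + 1):
            rows.append((f"{geno}_DNA_r{rep}", geno, "DNA", np.nan, rep))
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "material", "timepoint_h", "replicate"]
    ).set_index("sample_id")
    return sheet


def simulate_experiment(config: SimConfig):
    """Simulate the full experiment with planted truth.

    Returns ``(ExpressionMatrix, AlleleCountTable, truth)`` where ``truth``
    is a DataFrame indexed by gene with the planted mode, direction, origin
    and per-lineage cis/trans basal and slope effects (log2).
    """
    cfg = config
    tps = np.asarray(cfg.timepoints_h)
    prof = time_profile(tps)
    n_rep = cfg.n_replicates
    sheet = _sample_frame(cfg.timepoints_h, n_rep)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    mode_labels = list(cfg.mode_proportions)
    mode_probs = np.array([cfg.mode_proportions[m] for m in mode_labels])
    origins = ("derived1", "derived2", "shared")

    rna_samples = sheet[sheet["material"] == "RNA"]
    counts = np.zeros((cfg.n_genes, len(sheet)), dtype=np.int64)
    allele_rows = {"count_a": [], "count_b": []}
    truth_rows = []
    col_of = {s: i for i, s in enumerate(sheet.index)}

    hybrid_cols = {}  # (geno, kind) -> column indices aligned with tps x reps
    for geno in ("hybrid1", "hybrid2"):
        rna_cols = [
            col_of[f"{geno}_t{t:g}_r{r}"] for t in tps for r in range(1, n_rep + 1)
        ]
        dna_cols = [col_of[f"{geno}_DNA_r{r}"] for r in range(1, n_rep + 1)]
        hybrid_cols[geno] = (rna_cols, dna_cols)

    allele_index = []
    allele_a = []
    allele_b = []

    for gi, gene in enumerate(genes):
        rng = _gene_rng(cfg.seed, gi)
        b0 = np.log2(cfg.mean_depth) + rng.normal(0.0, cfg.gene_mean_log2_sd)
        mode = mode_labels[rng.choice(len(mode_labels), p=mode_probs)]
        basal_c, plast_c = _MODE_COMPONENTS[mode]
        if mode == "none":
            direction = "none"
            dir_sign = 0.0
            origin = "none"
        else:
            dir_sign = 1.0 if rng.random() < 0.5 else -1.0
            direction = "up" if dir_sign > 0 else "down"
            origin = origins[rng.choice(3, p=np.asarray(cfg.origin_proportions))]
        out_slope = dir_sign * cfg.plastic_slope_log2

        basal_eff = basal_c * dir_sign * cfg.effect_log2
        slope_eff = plast_c * dir_sign * cfg.effect_log2
        cis_basal = bool(basal_eff) and rng.random() < cfg.cis_fraction
        cis_plastic = bool(slope_eff) and rng.random() < cfg.cis_fraction
        bias = rng.normal(0.0, cfg.mapping_bias_sd) if cfg.mapping_bias_sd > 0 else 0.0

        lineages = {"derived1": origin in ("derived1", "shared"),
                    "derived2": origin in ("derived2", "shared")}
        eff = {}
        for lin, carries in lineages.items():
            b = basal_eff if carries else 0.0
            s = slope_eff if carries else 0.0
            eff[lin] = {
                "cis_basal": b if cis_basal else 0.0,
                "trans_basal": b if not cis_basal else 0.0,
                "cis_slope": s if cis_plastic else 0.0,
                "trans_slope": s if not cis_plastic else 0.0,
            }

        # parents
        for geno in ("outgroup", "derived1", "derived2"):
            if geno == "outgroup":
                log2mu = b0 + out_slope * prof
            else:
                e = eff[geno]
                b_tot = e["cis_basal"] + e["trans_basal"]
                s_tot = e["cis_slope"] + e["trans_slope"]
                log2mu = b0 + b_tot + (out_slope + s_tot) * prof
            mu = np.repeat(2.0 ** log2mu, n_rep)
            cols = [
                col_of[f"{geno}_t{t:g}_r{r}"] for t in tps for r in range(1, n_rep + 1)
            ]
            counts[gi, cols] = _nb_draw(rng, mu, cfg.nb_dispersion)

        # hybrids: totals NB, allele split beta-binomial around cis log-odds
        for geno, lin in (("hybrid1", "derived1"), ("hybrid2", "derived2")):
            e = eff[lin]
            trans_shift = e["trans_basal"] + e["trans_slope"] * prof
            r_cis = e["cis_basal"] + e["cis_slope"] * prof  # log2 B/A
            mu_a = 2.0 ** (b0 - 1.0 + trans_shift + out_slope * prof)
            mu_b = mu_a * 2.0 ** r_cis
            mu_tot = np.repeat(mu_a + mu_b, n_rep)
            rna_cols, dna_cols = hybrid_cols[geno]
            tot = _nb_draw(rng, mu_tot, cfg.nb_dispersion)
            p_b = 1.0 / (1.0 + 2.0 ** -(np.repeat(r_cis, n_rep) + bias))
            b_cnt = _bb_draw(rng, tot, p_b, cfg.bb_overdispersion)
            counts[gi, rna_cols] = tot
            dna_tot = _nb_draw(rng, np.full(n_rep, cfg.mean_depth), cfg.nb_dispersion)
            p_dna = 1.0 / (1.0 + 2.0 ** -bias)
            dna_b = _bb_draw(rng, dna_tot, np.full(n_rep, p_dna), cfg.bb_overdispersion)
            counts[gi, dna_cols] = dna_tot
            for cols, totals, bs in ((rna_cols, tot, b_cnt), (dna_cols, dna_tot, dna_b)):
                for c, n_tot, nb in zip(cols, totals, bs):
                    allele_index.append((gene, sheet.index[c]))
                    allele_a.append(int(n_tot - nb))
                    allele_b.append(int(nb))

        truth_rows.append(
            {
                "gene_id": gene,
                "planted_mode": mode,
                "planted_direction": direction,
                "origin": origin,
                "outgroup_slope_log2": out_slope,
                "mapping_bias_log2": bias,
                **{
                    f"{kind}_{layer}_effect_log2_{lin[-1]}": eff[lin][f"{kind}_{layer}"]
                    for lin in ("derived1", "derived2")
                    for kind in ("cis", "trans")
                    for layer in ("basal", "slope")
                },
            }
        )

    em = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sheet.index),
        sheet,
    )
    allele_counts = pd.DataFrame(
        {"count_a": np.array(allele_a, dtype=float), "count_b": np.array(allele_b, dtype=float)},
        index=pd.MultiIndex.from_tuples(allele_index, names=["gene_id", "sample_id"]),
    )
    hyb_sheet = sheet[sheet["genotype"].isin(["hybrid1", "hybrid2"])]
    act = AlleleCountTable(allele_counts, hyb_sheet)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return em, act, truth


# ---------------------------------------------------------------------------
# population fixtures


def simulate_population(
    n_haplotypes: int,
    n_sites: int,
    theta_per_site: float,
    seed: int,
    nonsyn_fraction: float = 0.7,
):
    """Draw a 0/1 haplotype matrix from the neutral frequency spectrum.

    Each site is segregating with probability ``theta * a1`` (Watterson) and
    its minor/derived allele count i in 1..n-1 is drawn with P(i) ~ 1/i;
    carriers are a uniform random subset.  Sites are labeled synonymous or
    nonsynonymous by ``nonsyn_fraction``.  Returns a dict with keys
    ``haplotypes`` (S x n), ``positions`` (1-based), ``site_class`` and
    ``n_sites`` (the number of simulated, mostly monomorphic, sites).
    """
    if n_haplotypes < 4:
        raise ValueError("n_haplotypes must be >= 4")
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be >= 0")
    if theta_per_site == 0:
        return {
            "haplotypes": np.zeros((0, n_haplotypes), dtype=np.int8),
            "positions": np.array([], dtype=int),
            "site_class": np.array([], dtype=object),
            "n_sites": n_sites,
        }
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n = n_haplotypes
    a1 = np.sum(1.0 / np.arange(1, n))
    p_seg = min(1.0, theta_per_site * a1)
    seg = rng.random(n_sites) < p_seg
    positions = np.flatnonzero(seg) + 1
    s = len(positions)
    freq_probs = (1.0 / np.arange(1, n)) / a1
    counts = rng.choice(np.arange(1, n), size=s, p=freq_probs)
    hap = np.zeros((s, n), dtype=np.int8)
    for i, c in enumerate(counts):
        hap[i, rng.choice(n, size=c, replace=False)] = 1
    site_class = np.where(
        rng.random(s) < nonsyn_fraction, "nonsynonymous", "synonymous"
    ).astype(object)
    return {
        "haplotypes": hap,
        "positions": positions,
        "site_class": site_class,
        "n_sites": n_sites,
    }


def population_to_vcf(pop: dict, path, chrom: str = "1", qual: float = 60.0,
                      depth: int = 30, gq: int = 99) -> None:
    """Write a simulated population as a minimal diploid VCF.

    Haplotypes are paired in order into diploid genotypes.
    """
    from .io_formats import write_vcf

    hap = pop["haplotypes"]
    s, n = hap.shape
    if n % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    geno = hap.reshape(s, n // 2, 2)
    ref = np.full(s, "A")
    alt = np.full(s, "T")
    write_vcf(
        path,
        chrom,
        pop["positions"],
        ref,
        alt,
        geno,
        quals=np.full(s, qual),
        depth=np.full((s, n // 2), depth),
        gq=np.full((s, n // 2), gq),
    )


def population_annotation(pop: dict, path, chrom: str = "1",
                          gene_id: str = "gene1") -> None:
    pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pop["positions"],
            "site_class": pop["site_class"],
            "gene_id": gene_id,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# codon-alignment fixtures


def simulate_codon_pair(n_codons: int, ka: float, ks: float, seed: int):
    """Generate two aligned coding sequences at requested per-site rates.

    Starting from a random stop-free sequence, each codon position of the
    second copy is substituted with probability ka * (nonsynonymous site
    fraction) + ks * (synonymous site fraction); the substitution is chosen
    synonymous or nonsynonymous accordingly and never creates a stop codon.
    Realized counts therefore match the requested per-site rates in
    expectation (before multiple-hit correction).
    """
    from . import _codons

    if not (0.0 <= ka <= 0.5 and 0.0 <= ks <= 0.5):
        raise ValueError("ka and ks must be in [0, 0.5]")
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    codons1 = [
        _codons.SENSE_CODONS[i]
        for i in rng.choice(len(_codons.SENSE_CODONS), size=n_codons)
    ]
    codons2 = []
    for codon in codons1:
        cur = codon
        for pos in range(3):
            fs = _codons.syn_fraction(cur, pos)
            p_syn = ks * fs
            p_non = ka * (1.0 - fs)
            u = rng.random()
            if u < p_syn + p_non:
                want = "syn" if u < p_syn else "nonsyn"
                options = [c for c, k in _codons.neighbors(cur, pos) if k == want]
                if options:
                    cur = options[rng.choice(len(options))]
        codons2.append(cur)
    return "".join(codons1), "".join(codons2)


def write_codon_pair_fasta(seq1: str, seq2: str, path, names=("seqA", "seqB")) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, (seq1, seq2)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
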