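# Methods

## The inference problem

In an F1 hybrid the two parental alleles share one nucleus, hence one
trans-regulatory environment: any reproducible imbalance between the alleles'
transcripts must be caused by variation linked to the alleles themselves
(cis-acting). Comparing two hybrids that share one parent (the outgroup)
polarizes those variants: a cis signal seen in only one hybrid arose, by
parsimony, on the corresponding sister lineage; a signal seen in both either
predates the sister-species split or arose in the outgroup and cannot be
polarized ("undetermined").

`cisplast` implements this chain for a stress time course: parental
differential expression and plasticity, allele-specific expression (ASE)
tested against a genomic-DNA baseline, classification of each gene's mode of
plasticity evolution, parsimony assignment of variant origin, and
population-genetic comparisons of the resulting gene groups.

## Expression model

Counts are modeled per gene with a negative-binomial GLM, log link, design
`genotype + genotype:timepoint` (time categorical, nested within genotype) and
log size factor as offset. Size factors are median-of-ratios with a
geometric-mean reference over genes nonzero in every sample, anchored so the
median factor is 1; if no such gene exists the total-count fallback is used
with a warning.

Because the nested design is saturated (one free mean per genotype×timepoint
cell), the fit reduces to independent one-parameter NB likelihoods per cell,
solved by Newton iteration from the closed-form Poisson means Σy/Σs. The
per-gene dispersion α (variance μ+αμ²) solves the Pearson moment equation
Σ(y−μ)²/(μ+αμ²) = n−p, floored at 1e-8; this choice is calibrated — on
fully-null simulations the Wald p-values are uniform (KS p ≈ 0.4) where the
cruder residual-ratio estimator was visibly anti-conservative. Contrasts of
log cell means use a t reference on the residual df (54 for three genotypes,
six timepoints, four replicates):

* plastic slope `s_t = log2(expr_t / expr_0)` per species (s_0 ≡ 0),
* basal difference `b = log2(derived_0 / outgroup_0)`,
* plasticity difference `Δ_t = s_t(derived) − s_t(outgroup)` (antisymmetric
  under pair swap, Δ_0 ≡ 0).

BH-FDR runs within each (test × timepoint × pair) family across genes.
Defaults: α_plast = α_basal = 0.05, α_Δ = 0.1; a q exactly at the threshold
counts as significant. Genes with mean count < 10 are flagged and excluded
from every test. Reported ratios always come from fitted means, so zero
counts need no pseudocounts. Hybrids are not included in the parental fit.

## ASE model

Per-SNP counts are filtered before any normalization: SNPs within 50 bp of an
intron, SNPs in any 200-bp window holding more than 10 SNPs of the same gene,
and SNPs with DNA coverage below 5 are removed, each with a reason code.
Gene-level counts take the summed SNP total and split it by the median
per-SNP allele-B fraction (half-even rounding; totals conserved exactly).
Samples are then scaled by total-count size factors (sample total over
retained orthologs / median of those totals), which preserves within-sample
allele fractions exactly.

The test is a quasi-binomial GLM (logit link) of the two allele counts over
the seven sample types (DNA, RNA 0–24 h) per gene and hybrid. The type factor
is saturated, so the fitted proportion per type is the pooled fraction and
the dispersion is Pearson χ²/df, floored at 1 (never deflated below
binomial). Contrasts — basal: RNA 0 h vs DNA; plastic: RNA t vs RNA 0 h — use
t statistics on the residual df (21 with four replicates). The DNA baseline
absorbs per-gene mapping bias by construction; planted biases up to ±0.5
log2-odds produce no excess calls in simulation. Thresholds: basal q ≤ 0.05,
plastic q ≤ 0.1. A per-gene, per-hybrid fit is used rather than one model
nesting both hybrids: all contrasts are within-hybrid and this isolates
failures. Types with a zero pooled allele get a 0.5 continuity correction for
the point estimate; genes with a zero *total* in any required type, or mean
count < 10, are excluded with a reason.

## Classification

The outgroup's plastic direction at the reference timepoint (default 6 h, the
peak of the simulated response) proxies the ancestral response. A significant
basal difference with the same sign is **orthoplastic**, opposite
**paraplastic**; a significant Δ with the sign of the outgroup slope is a
**magnified** response, opposite sign (weakening or reversal) **mitigated**.
The sign convention generalizes "positive Δ = magnification" so it holds for
down-regulated genes too. The basal × plastic cross yields the eight modes
(Only-Ortho … Para-Mit) plus "none"; every gene receives exactly one mode.

Cis/trans architecture per layer: **cis** needs parental and allelic
significance with concordant signs; parental-only is **trans_only**;
allelic-only and sign-discordant cases are excluded from cis/trans calling
(the hybrid has more power than the parental contrast, and a preferred allele
from the lower-expressing parent is uninterpretable). A gene with basal and
plastic cis signals counts once for origin assignment.

Quadrant tests default to the 1-df goodness-of-fit of ortho vs para against
1:1, χ² = (2k−n)²/n; a conditional 2×2 independence variant (direction ×
side) is available. Within-group odds are k/(n−k). Lineage-rate comparisons
use the 2×8 homogeneity χ² (df 7) plus a per-mode 1-df decomposition
(expected counts from lineage marginals); a variant scoring one lineage
against marginal expectations is exposed, and modes with expected counts
below 1 fall back to an exact binomial with a warning.

## Population genetics

VCF filters run in order: indels, multiallelic sites, site QUAL < 30;
genotypes with DP < 10 or GQ < 20 set missing; sites with > 80% of
individuals missing dropped; finally every site is randomly down-sampled
(seeded) to the minimum observed allele count so all sites share one sample
size (verified not to shift expected frequencies). π is reported per gene as
the average number of pairwise differences (a per-site option exists);
Tajima's D uses the 1989 constants and is NaN (not 0) when S = 0. Ka/Ks uses
Li (1993)/Pamilo–Bianchi degenerate-site counting with Kimura two-parameter
correction, averaging multi-hit codons over stop-free substitution pathways;
NG86 is an option. Note an intrinsic property of the degenerate-site method:
synonymous transversions at 2-fold(-binned) sites count toward Ka, so Ka is
slightly positive even for purely synonymous divergence; NG86 gives exactly 0
there.

Group comparisons resample genes with replacement (B = 1000 by default),
recompute the group statistic, and take p = 2·min(#Δ*≤0, #Δ*≥0)/B, floored at
2/B and capped at 1. Groups under 30 genes warn about bootstrap variance. The
interspecific index (D₁+2)/(D₂+2) is taken literally; a denominator ≤ 0
(impossible for real Tajima's D) yields NaN with a warning.

## Synthetic data

The generator emulates the study design: three "species" (outgroup + two
derived) and two hybrids, six timepoints (0–24 h) × four replicates, NB totals
(dispersion 0.01), beta-binomial allele splits (ρ = 0.01; 0.02 in the
calibration runs), DNA controls, and a per-gene Gaussian mapping bias
(default SD 0.2 log2-odds) shared by DNA and RNA — which is what makes the
DNA baseline necessary. Planted truth: each gene draws one of the nine modes
(default 36% none, 8% each mode), a direction (up/down), an origin
(derived1/derived2/shared at 0.4/0.4/0.2), and cis vs trans placement per
layer (cis fraction 0.5). The outgroup response ramps linearly to its peak at
6 h (slope 2.0 log2 by default) and relaxes to half by 24 h; basal and slope
effects have magnitude `effect_log2` (default 1.5). Cis effects appear in
both the parental contrast and the hybrid allelic ratio; trans effects move
both hybrid alleles together and appear only in the parental contrast.
Population fixtures draw site frequencies from the neutral spectrum
(P(i) ∝ 1/i), which matches Watterson/π expectations exactly (mean D ≈ 0);
codon pairs plant synonymous/nonsynonymous substitutions at requested
per-site rates without creating stops.

Seeding: one master seed; per-gene substreams via
`SeedSequence(seed, spawn_key=(gene,))`, so increasing `n_genes` extends the
gene set without reshuffling earlier genes; all outputs are byte-identical
given the seed.

What the generator does **not** emulate: read-level artifacts (mapping,
reassignment across parental genomes), gene-gene correlation, library-size
variation beyond size factors, linkage between SNPs of a gene, and coalescent
genealogies (the frequency-draw model has independent sites). Passing tests
therefore show the inference chain is correct and calibrated under its own
assumptions — not that those assumptions hold in any particular RNA-seq
experiment.

## Problem sizes and measured behavior

The calibration and recovery suites use 2000 genes at depth 200 with four
replicates, 50 replicate neutral populations of 16 haplotypes × 10⁴ sites, 20
codon alignments of 5000 codons, and 500 bootstrap trials; these sizes give
stable Monte-Carlo estimates while keeping the whole suite under a minute of
simulation time. Measured on synthetic data (seeds in the test suite): null
ASE calls at q<0.05 ≈ 0%; exact-mode recovery ≈ 98–99% with ≈1–2% spurious
modes on null genes; origin polarity ≈ 98% correct among detected cis
variants; neutral mean D within ±0.02 of 0; Ka/Ks ratio recovery within a few
percent of the generating 0.5.

## Known limitations

No dispersion shrinkage or outlier handling (by design — the contrasts, not
shrinkage details, are the contract); per-gene GLMs assume independence
across genes, so family-level FDR leniency from many true effects slightly
inflates per-null-gene call rates in effect-rich simulations; the parsimony
origin rule cannot see variants whose parental contrast is masked (they are
excluded, not misassigned); Ka/Ks is a counting method and saturates for
divergences well beyond the regime tested here.
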