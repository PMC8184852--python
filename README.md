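# cisplast

Detecting **cis-acting regulatory variants** from allele-specific expression
(ASE) in F1 hybrids over a stress time course, and asking whether the
direction of pre-existing expression **plasticity** shaped which regulatory
changes accumulated in each lineage.

In an F1 hybrid both parental alleles sit in one nucleus and share every
trans-acting factor, so a reproducible allelic imbalance in the transcripts —
tested against the genomic-DNA allelic ratio to absorb mapping bias — reveals
a cis-regulatory difference at that locus. With two hybrids that share one
outgroup parent, hybrid-specific cis signals can be polarized by parsimony to
the corresponding sister lineage, giving per-lineage *rates* of regulatory
evolution across thousands of genes. `cisplast` implements the full chain:

1. **expression** — per-gene negative-binomial GLM over the nested design
   `genotype + genotype:timepoint`; Wald contrasts give the plastic slope
   `s_t = log2(expr_t/expr_0)`, the basal difference
   `b = log2(derived_0/outgroup_0)` and the plasticity difference
   `Δ_t = s_t^derived − s_t^outgroup`, each with BH-FDR across genes;
2. **ase** — SNP filtering, gene-level aggregation (median SNP ratio),
   size-factor normalization, and a quasi-binomial GLM of the two allele
   counts over the seven sample types (DNA, RNA 0–24 h), contrasting RNA 0 h
   vs DNA (basal ASE, q ≤ 0.05) and RNA t vs RNA 0 h (plastic ASE, q ≤ 0.1);
3. **classify** — orthoplastic/paraplastic basal change and
   magnified/mitigated response relative to the outgroup's plastic direction;
   the basal × plastic cross defines eight modes of plasticity evolution;
   cis/trans architecture per layer; quadrant χ² tests and odds ratios;
4. **lineage** — parsimony origin (derived in one lineage vs undetermined)
   and 2×8 / per-mode 1-df χ² comparisons of variant accumulation rates;
5. **popgen** — folded SFS, π, Tajima's D (synonymous/nonsynonymous), Ka/Ks
   (Li93/Pamilo–Bianchi counting, K2P-corrected), compared across gene groups
   with a gene-resampling bootstrap (p = 2·min-tail/B, floored at 2/B) and
   the interspecific index (D₁+2)/(D₂+2);
6. **simdata** — a first-class synthetic-data generator that emulates the
   whole design (NB totals, beta-binomial allele splits, DNA controls with
   shared mapping bias, neutral-SFS populations, codon alignments) with
   planted ground truth, used by every calibration and recovery test.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate 500 genes with planted effects and run the whole chain:

```python
from cisplast import pipeline
from cisplast.simdata import SimConfig

bundle = pipeline.run_synthetic(SimConfig(n_genes=500, seed=42))
print(pipeline.format_report(pipeline.report(bundle)))
```

Output (abridged):

```
== derived1 ==
  basal: n_total=150, n_ortho=85, percent_ortho=56.7, chi2=2.67, df=1,
         p=0.102, odds_ratio=1.31, n_cis=66, n_cis_ortho=45,
         percent_cis_ortho=68.2, cis_chi2=8.73, cis_p=0.0031, cis_odds_ratio=2.14
  ...
== mode_table ==
              derived1  derived2
  Only-Ortho        12        12
  Only-Para          4        12
  ...
mode_rate_test: {'chi2': 6.95, 'df': 7, 'p': 0.434}
```

Reading it: of the 150 genes with a significant basal difference between
derived1 and the outgroup, 85 (56.7%) shifted in the direction of the
outgroup's plastic response (orthoplastic); 66 of the 150 carry a concordant
allelic imbalance in the hybrid, i.e. a basal cis-acting variant, and among
those the orthoplastic excess is stronger (68.2%, within-group odds 2.14,
quadrant χ² p = 0.0031). The mode table counts derived cis variants per
lineage across the eight modes; here the generator planted symmetric rates,
and the 7-df homogeneity test correctly finds no lineage difference
(p = 0.43). The same machinery applied to counts with a planted 3× enrichment
flags the enriched mode through the per-mode 1-df decomposition.

The CLI exposes the stages (`cisplast simulate/run/ase/popgen`); e.g.

```sh
cisplast simulate --out sim/ --seed 3
cisplast run --counts sim/counts.tsv --samples sim/samples.csv \
             --alleles sim/alleles.tsv --hybrid-samples sim/hybrid_samples.csv \
             --out report.json
```

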