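# hybridexpr

Analysis of gene expression inheritance and cis/trans regulatory
divergence from RNA-seq of two closely related species and their F1
hybrids, across multiple tissues.

When two species hybridize, the way a gene's expression behaves in the
F1 — matching one parent, sitting between them, or falling outside the
parental range (misexpression) — carries information about the
regulatory changes that separated the species.  A *cis*-regulatory
change is linked to the allele it regulates and produces allelic
imbalance in hybrids; a *trans* change acts on both alleles equally and
does not.  Opposing *cis* and *trans* changes can cancel in each parent
(compensatory evolution) yet collide in the hybrid, producing
misexpression together with allele-specific expression (ASE) at genes
whose parental expression is conserved — a signature of
Dobzhansky–Muller incompatibility between regulatory elements.

`hybridexpr` implements the full inference chain from a gene × sample
count matrix and a phased per-SNP allelic count table to:

* **Differential expression** — a self-contained negative-binomial
  engine: median-of-ratios size factors, gene-wise dispersions shrunk
  toward a fitted mean–dispersion trend, per-gene Wald tests
  (log2 fold changes, BH-adjusted p), and MAP-shrunken fold changes
  under a zero-centred normal prior.
* **Expression structure** — TPM, the expressed-gene census
  (mean TPM > 1), the Yanai tissue-specificity index
  τ = Σᵢ(1 − x̂ᵢ)/(n − 1) with a cross-species consensus, PCA with
  projection of hybrid samples onto the parental axes, and
  between-groups PCA with a Monte-Carlo permutation test on explained
  inertia (optionally conditioned on a second factor).
* **Inheritance modes** — each gene × tissue is classified from the
  shrunken fold changes x = LFC(hybrid/collared), y = LFC(hybrid/pied)
  into conserved / additive / pied-dominant / collared-dominant /
  overdominant / underdominant using a fold-change threshold of 1.125,
  plus type II (major-axis) regression and misexpression calls.
* **Allele-specific expression** — per (gene, individual) beta-binomial
  likelihood-ratio tests aggregating phased SNPs (coverage ≥ 10, allelic
  depth > 2, ≥ 2 SNPs), with genome-wide per-individual overdispersion,
  BH adjustment within individual × tissue, and a population rule
  (ASE when ≥ 2 individuals reach adjusted p < 0.05).
* **Regulatory inference** — Mann–Whitney associations between
  |LFC| and ASE or CNE fixed-difference flags, the continuity-corrected
  χ² compensation test (misexpression × ASE), the hypergeometric fast-Z
  enrichment test with Holm adjustment, and GLM/MLR analyses of the
  determinants of expression divergence (PPI, τ, ϕ, πN/πS, dN/dS, FST).

A seeded synthetic-data generator (`hybridexpr.simulate`) emulates the
study design — 5 + 5 parental and 3 hybrid males across five tissues,
NB counts with gene-wise dispersion, phased allelic counts under
cis / trans / compensatory / null regimes — so the entire chain runs
and is tested without any external data.

## Worked example

The numbered scripts under `analysis/` run the chain end to end on a
synthetic data set (800 genes, five tissues, seed 1):

```
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_expression_structure.py
python analysis/04_inheritance.py
python analysis/05_ase.py
python analysis/06_regulatory_inference.py
```

`03_expression_structure.py` prints

```
between-groups PCA: tissue explains 91.2% (p = 0.01); species given tissue 10.44% (p = 0.01)
```

— tissue identity dominates expression variation while species identity
is detectable only after conditioning on tissue, the qualitative pattern
expected for recently diverged species.  `06_regulatory_inference.py`
prints the association battery; with the generator's default mixed
architecture the strongest signals are the compensation tests (planted
compensatory genes are misexpressed *and* show hybrid ASE) and the
hybrid-specific ASE × DE associations (planted cis divergence), e.g.

```
         test tissue            p  direction
 compensation  heart 1.440882e-51          1
ase_de_hybrid  brain 3.416210e-21          1
```

Equivalent functionality is exposed as a CLI
(`hybridexpr simulate|de|structure|inherit|ase|infer|run|report`).

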