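"""Generate the synthetic study data set.

Emulates the sampling design: 5 collared + 5 pied + 3 F1 hybrid males,
five tissues, NB counts with gene-wise dispersion, phased allelic counts
and gene annotation.  Writes data tables under results/data/.
"""

from pathlib import Path

from hybridexpr import SimConfig, simulate_allele_counts, \
    simulate_annotation, simulate_counts
from hybridexpr import io as io_mod

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

config = SimConfig(
    n_genes=800,
    n_tissues=5,
    mode_fractions={"additive": 0.05, "pied_dominant": 0.05,
                    "collared_dominant": 0.05, "overdominant": 0.03,
                    "underdominant": 0.03},
    snp_coverage_mean=40.0,
    seed=1,
)

counts, samples, truth = simulate_counts(config)
alleles = simulate_allele_counts(truth)
annotation = simulate_annotation(truth)

io_mod.write_counts(counts, OUT / "counts.tsv")
io_mod.write_table(samples, OUT / "samples.tsv")
io_mod.write_table(alleles, OUT / "allele_counts.tsv")
io_mod.write_table(annotation, OUT / "annotation.tsv")
io_mod.write_table(truth.gene_tissue, OUT / "truth_gene_tissue.tsv")
io_mod.write_table(truth.genes, OUT / "truth_genes.tsv")

n_div = (truth.gene_tissue["mode"] != "conserved").sum()
print(f"wrote {config.n_genes} genes x {len(samples)} samples to {OUT}")
print(f"{n_div} divergent gene x tissue combinations "
      f"({n_div / len(truth.gene_tissue):.1%})")
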