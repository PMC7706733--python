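"""Regulatory inference: the association battery on the full run.

Links expression divergence to hybrid/parental ASE (Mann-Whitney),
tests misexpression x ASE compensation (Yates chi-square), fast-Z DE
enrichment (hypergeometric + Holm), the CNE fixed-difference
association, and the GLM / MLR determinants of expression divergence.
"""

from pathlib import Path

import pandas as pd

from hybridexpr import ase as ase_mod
from hybridexpr import inference as inf
from hybridexpr import io as io_mod
from hybridexpr.config import PipelineConfig
from hybridexpr.pipeline import run_de_stage, run_inference_stage, \
    run_inheritance_stage

BASE = Path(__file__).resolve().parent.parent / "results"

counts = io_mod.read_counts(BASE / "data" / "counts.tsv")
samples = io_mod.read_samples(BASE / "data" / "samples.tsv", counts)
alleles = io_mod.read_allele_counts(BASE / "data" / "allele_counts.tsv")
annotation = io_mod.read_annotation(BASE / "data" / "annotation.tsv")

config = PipelineConfig()
de_results = run_de_stage(counts, samples, config)
_, mis_calls = run_inheritance_stage(de_results, config)
species_of = samples.drop_duplicates("individual") \
    .set_index("individual")["species"]
_, population = ase_mod.run_ase(alleles, species_of)

assoc = run_inference_stage(de_results, mis_calls, population, annotation,
                            config)
out = BASE / "inference"
io_mod.write_table(assoc, out / "associations.tsv")

sig = assoc[assoc["p"] < 0.05]
print(f"{len(sig)} of {assoc['p'].notna().sum()} testable associations "
      "significant at p < 0.05:")
print(sig[["test", "tissue", "p", "direction"]]
      .sort_values("p").head(12).to_string(index=False))

# determinants of parental expression divergence, pooled example (brain)
tissue = sorted(de_results)[0]
cp = de_results[tissue]["CP"]
ann = annotation.set_index("gene")
auto = ann["chrom_class"] == "autosome"
covariates = ann.loc[auto, ["ppi", "tau", "phi", "pin_pis", "dn_ds", "fst"]]
response = (cp["status"] == "DE").astype(float).reindex(covariates.index)
response[cp["status"].reindex(covariates.index) == "untested"] = pd.NA
glm = inf.glm_determinants(response, covariates)
io_mod.write_table(glm, out / f"glm_determinants_{tissue}.tsv")
print(f"\nGLM determinants of DE in {tissue}:")
print(glm.round(4).to_string(index=False))
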