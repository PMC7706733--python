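"""Pairwise differential expression per tissue.

Fits the NB Wald test for the three contrasts (collared/pied,
hybrid/collared, hybrid/pied) in every tissue, adds shrunken fold
changes, and prints the DE gene counts per tissue and contrast together
with the cross-tissue overlap of parental DE genes.
"""

from pathlib import Path

import pandas as pd

from hybridexpr import de as de_mod
from hybridexpr import io as io_mod
from hybridexpr.config import PipelineConfig
from hybridexpr.pipeline import run_de_stage

BASE = Path(__file__).resolve().parent.parent / "results"

counts = io_mod.read_counts(BASE / "data" / "counts.tsv")
samples = io_mod.read_samples(BASE / "data" / "samples.tsv", counts)

results = run_de_stage(counts, samples, PipelineConfig())

rows = []
for tissue, contrasts in results.items():
    for name, res in contrasts.items():
        io_mod.write_table(res.reset_index(names="gene"),
                           BASE / "de" / f"{tissue}_{name}.tsv")
        rows.append((tissue, name, int((res["status"] == "DE").sum())))
table = pd.DataFrame(rows, columns=["tissue", "contrast", "n_de"]) \
    .pivot(index="tissue", columns="contrast", values="n_de")
io_mod.write_table(table.reset_index(), BASE / "de" / "de_counts.tsv")
print("DE gene counts per tissue and contrast:")
print(table.to_string())

cp_sets = {t: set(c["CP"].index[c["CP"]["status"] == "DE"])
           for t, c in results.items()}
cells = de_mod.de_overlap(cp_sets, list(counts.index))
shared_all = cells[frozenset(cp_sets)]
print(f"\nparental DE genes shared by all {len(cp_sets)} tissues: "
      f"{shared_all}; DE in no tissue: {cells[frozenset()]}")
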