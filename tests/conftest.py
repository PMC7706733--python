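import numpy as np
import pandas as pd
import pytest

from hybridexpr import SimConfig, simulate_counts
from hybridexpr import de as de_mod


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-tissue simulated study shared across read-only tests."""
    cfg = SimConfig(n_genes=400, n_tissues=2, seed=42)
    counts, samples, truth = simulate_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def parent_de():
    """One-tissue parental DE run with moderate planted divergence."""
    cfg = SimConfig(n_genes=800, n_tissues=1, base_log2_range=(6, 10),
                    mode_fractions={"additive": 0.2}, effect_size_log2=1.5,
                    seed=9)
    counts, samples, truth = simulate_counts(cfg)
    block = samples[samples["species"] != "hybrid"]
    sub = counts[block["sample"]]
    design = block.set_index("sample")["species"]
    sf = de_mod.size_factors(sub)
    phi = de_mod.estimate_dispersions(sub, sf, design)
    res = de_mod.wald_test(sub, sf, phi, design, ("collared", "pied"))
    return {"counts": sub, "design": design, "sf": sf, "phi": phi,
            "result": res, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
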