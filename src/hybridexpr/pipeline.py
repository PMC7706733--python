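"""End-to-end orchestration of the analysis chain.

``run_pipeline`` executes, per tissue: the three pairwise DE contrasts
(CP, HC, HP) with shrunken fold changes; expression structure (TPM,
expressed-gene census, PCA with hybrid projection, conditional bgPCA);
inheritance-mode classification and misexpression calls; the ASE chain;
and the regulatory-inference battery.  Every run writes a manifest with
a config hash and seed; deterministic stages are bit-identical on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import de as de_mod
from . import inference as inf_mod
from . import inheritance as inh_mod
from . import structure as st_mod
from .config import PipelineConfig
from .io import write_table

logger = logging.getLogger(__name__)

CONTRASTS = {"CP": ("collared", "pied"),
             "HC": ("hybrid", "collared"),
             "HP": ("hybrid", "pied")}


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_de_stage(counts: pd.DataFrame, samples: pd.DataFrame,
                 config: PipelineConfig) -> dict:
    """Per-tissue pairwise DE results: {tissue: {contrast: DataFrame}}."""
    results: dict = {}
    for tissue, block in samples.groupby("tissue"):
        sub = counts[block["sample"]]
        design = block.set_index("sample")["species"]
        sf = de_mod.size_factors(sub, pseudo_reference=True)
        phi = de_mod.estimate_dispersions(
            sub, sf, design, prior_var=config.dispersion_prior_var)
        results[tissue] = {}
        for name, contrast in CONTRASTS.items():
            res = de_mod.wald_test(sub, sf, phi, design, contrast,
                                   alpha=config.alpha)
            res["shrunkenLfc"] = de_mod.shrink_lfc(
                sub, sf, phi, design, contrast, res,
                prior_var=config.lfc_prior_var)
            results[tissue][name] = res
    return results


def run_inheritance_stage(de_results: dict, config: PipelineConfig
                          ) -> tuple[pd.DataFrame, dict]:
    """Mode calls per gene x tissue plus misexpression calls per tissue."""
    call_rows, mis = [], {}
    for tissue, contrasts in de_results.items():
        hc, hp = contrasts["HC"], contrasts["HP"]
        modes = inh_mod.classify_inheritance(
            hc["shrunkenLfc"].to_numpy(), hp["shrunkenLfc"].to_numpy(),
            fold_threshold=config.fold_threshold)
        call_rows.append(pd.DataFrame({
            "gene": hc.index, "tissue": tissue,
            "x": hc["shrunkenLfc"].to_numpy(),
            "y": hp["shrunkenLfc"].to_numpy(),
            "mode": modes,
        }))
        mis[tissue] = inh_mod.call_misexpression(
            contrasts["CP"], hc, hp,
            require_sign_consistency=config.require_sign_consistency)
    return pd.concat(call_rows, ignore_index=True), mis


def run_structure_stage(counts: pd.DataFrame, samples: pd.DataFrame,
                        annotation: pd.DataFrame, config: PipelineConfig
                        ) -> dict:
    lengths = annotation.set_index("gene")["effective_length"]
    tpm_matrix = st_mod.tpm(counts, lengths)
    meta = samples.set_index("sample")
    census = {}
    tau_by_species = {}
    for species, block in meta.groupby("species"):
        labels = pd.Series(block["species"] + "/" + block["tissue"],
                           index=block.index)
        census[species] = st_mod.count_expressed(
            tpm_matrix[block.index], labels, threshold=config.tpm_threshold)
        mean_by_tissue = pd.DataFrame({
            tissue: tpm_matrix[tis_block.index].mean(axis=1)
            for tissue, tis_block in block.groupby("tissue")})
        tau_by_species[species] = st_mod.tau(
            mean_by_tissue, log_transform=config.tau_log_transform)
    tau_frame = pd.DataFrame(tau_by_species)
    consensus = st_mod.consensus_tau(tau_frame)

    # ordination on the log-normalized matrix, parents define the axes
    sf = de_mod.size_factors(counts, pseudo_reference=True)
    logmat = de_mod.rlog_like_transform(counts, sf).T  # samples x genes
    parents = meta.index[meta["species"] != "hybrid"]
    hybrids = meta.index[meta["species"] == "hybrid"]
    pca_by_tissue = {}
    for tissue, block in meta.groupby("tissue"):
        train = [s for s in block.index if s in set(parents)]
        held = [s for s in block.index if s in set(hybrids)]
        model = st_mod.pca(logmat.loc[train])
        pca_by_tissue[tissue] = {
            "model": model,
            "hybrid_scores": st_mod.project_samples(model, logmat.loc[held]),
        }
    bg_tissue = st_mod.between_group_pca(
        logmat.loc[parents], meta.loc[parents, "tissue"],
        n_perm=config.n_perm, seed=config.seed)
    bg_species = st_mod.between_group_pca(
        logmat.loc[parents], meta.loc[parents, "species"],
        n_perm=config.n_perm, condition_on=meta.loc[parents, "tissue"],
        seed=config.seed)
    return {"tpm": tpm_matrix, "census": census, "tau": tau_frame,
            "consensus_tau": consensus, "pca_by_tissue": pca_by_tissue,
            "bg_tissue": bg_tissue, "bg_species": bg_species}


def run_inference_stage(de_results: dict, mis_calls: dict,
                        ase_population: dict, annotation: pd.DataFrame,
                        config: PipelineConfig) -> pd.DataFrame:
    chrom = annotation.set_index("gene")["chrom_class"]
    results = []
    fastz_counts = {}
    for tissue, contrasts in de_results.items():
        cp = contrasts["CP"]
        tested = cp["status"] != "untested"
        de_flag = cp["status"] == "DE"
        z = chrom.reindex(cp.index) == "Z"
        auto = chrom.reindex(cp.index) == "autosome"
        fastz_counts[tissue] = (
            int((de_flag & z & tested).sum()),
            int((~de_flag & z & tested).sum()),
            int((de_flag & auto & tested).sum()),
            int((~de_flag & auto & tested).sum()))

        status_by_source = {}
        for source, pop in ase_population.items():
            block = pop[pop["tissue"] == tissue]
            status_by_source[source] = block.set_index("gene")["status"]
        if status_by_source:
            results.extend(inf_mod.ase_de_association(
                cp, cp["shrunkenLfc"], status_by_source, chrom, tissue=tissue))
        if "cne_flag" in annotation.columns:
            flags = annotation.set_index("gene")["cne_flag"] \
                .reindex(cp.index).fillna(False)
            use = (chrom.reindex(cp.index) == "autosome") & tested
            results.append(inf_mod.mwu_association(
                cp.loc[use, "shrunkenLfc"].abs(), flags[use].to_numpy(),
                test="cne_de", tissue=tissue))
        if "hybrid" in ase_population:
            hybrid_status = ase_population["hybrid"]
            block = hybrid_status[hybrid_status["tissue"] == tissue]
            results.append(inf_mod.compensation_test(
                mis_calls[tissue], block.set_index("gene")["status"],
                chrom, tissue=tissue))
    fastz = inf_mod.fast_z_test(fastz_counts)
    assoc = inf_mod.association_table(results)
    fastz_rows = fastz.assign(test="fast_z", statistic=np.nan, direction=0,
                              note="")
    fastz_rows["n1"] = fastz_rows["de_z"] + fastz_rows["nde_z"]
    fastz_rows["n0"] = fastz_rows["de_a"] + fastz_rows["nde_a"]
    assoc["p_holm"] = assoc["p_holm"].astype(float)
    return pd.concat([assoc, fastz_rows[assoc.columns]], ignore_index=True)


def run_pipeline(counts: pd.DataFrame, samples: pd.DataFrame,
                 allele_counts: pd.DataFrame, annotation: pd.DataFrame,
                 config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and persist results under ``out_dir``.

    Returns the in-memory result bundle (also written as TSV/JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "de"
    try:
        de_results = run_de_stage(counts, samples, config)
        stage = "structure"
        structure = run_structure_stage(counts, samples, annotation, config)
        stage = "inheritance"
        calls, mis_calls = run_inheritance_stage(de_results, config)
        stage = "ase"
        species_of = samples.drop_duplicates("individual") \
            .set_index("individual")["species"]
        indiv_ase, ase_population = ase_mod.run_ase(
            allele_counts, species_of,
            min_coverage=config.min_coverage,
            min_allelic_depth=config.min_allelic_depth,
            min_snps=config.min_snps, alpha=config.alpha,
            fallback_rho=config.ase_fallback_rho)
        stage = "inference"
        assoc = run_inference_stage(de_results, mis_calls, ase_population,
                                    annotation, config)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for tissue, contrasts in de_results.items():
        for name, res in contrasts.items():
            write_table(res.reset_index(names="gene"),
                        out / "de" / f"{tissue}_{name}.tsv")
    write_table(calls, out / "inheritance" / "calls.tsv")
    chrom = annotation.set_index("gene")["chrom_class"]
    write_table(inh_mod.inheritance_frequencies(calls, chrom),
                out / "inheritance" / "frequencies.tsv")
    for tissue, m in mis_calls.items():
        write_table(m.reset_index(names="gene"),
                    out / "inheritance" / f"misexpression_{tissue}.tsv")
    write_table(indiv_ase, out / "ase" / "individual.tsv")
    for source, pop in ase_population.items():
        write_table(pop, out / "ase" / f"population_{source}.tsv")
    write_table(assoc, out / "inference" / "associations.tsv")
    write_table(structure["tau"].reset_index(names="gene"),
                out / "structure" / "tau.tsv")
    census_rows = [(sp, grp, n) for sp, ser in structure["census"].items()
                   for grp, n in ser.items()]
    write_table(pd.DataFrame(census_rows,
                             columns=["species", "group", "n_expressed"]),
                out / "structure" / "census.tsv")
    summary = {
        "bg_tissue": {"inertia_pct": structure["bg_tissue"].inertia_pct,
                      "p": structure["bg_tissue"].p_value,
                      "n_perm": structure["bg_tissue"].n_perm},
        "bg_species_given_tissue": {
            "inertia_pct": structure["bg_species"].inertia_pct,
            "p": structure["bg_species"].p_value,
            "n_perm": structure["bg_species"].n_perm},
    }
    (out / "structure" / "bgpca.json").write_text(json.dumps(summary, indent=2))
    manifest = {
        "config_hash": _config_hash(config), "seed": config.seed,
        "config": config.to_dict(),
        "n_genes": int(counts.shape[0]), "n_samples": int(counts.shape[1]),
        "stages": ["de", "structure", "inheritance", "ase", "inference"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {"de": de_results, "structure": structure, "calls": calls,
            "misexpression": mis_calls, "ase_individual": indiv_ase,
            "ase_population": ase_population, "associations": assoc,
            "manifest": manifest}
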