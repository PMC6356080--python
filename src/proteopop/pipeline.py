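"""End-to-end pipeline driver over the synthetic generator.

Runs simulate -> quantify/QC -> concordance -> networks -> subtypes ->
SOM -> QTL -> enrichment in dependency order, writing TSV/JSON artifacts
per stage. Stage toggles and all stage parameters live in
:class:`PipelineConfig`; one global seed is streamed into per-stage seeds
and recorded in the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as cc
from . import enrichment as en
from . import network as nw
from . import qtl as q
from . import simulate as sim
from . import som as so
from . import subtypes as st
from .containers import ExpressionMatrix
from .quantitation import filter_by_detection, per_line_distribution, replicate_concordance

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "qc", "concordance", "network", "subtype", "som", "qtl", "enrich"
    )
    population: sim.PopulationConfig = field(default_factory=sim.PopulationConfig)
    architecture: sim.ExpressionArchitecture = field(default_factory=sim.ExpressionArchitecture)
    network: nw.NetworkConfig = field(default_factory=nw.NetworkConfig)
    som: so.SOMConfig = field(default_factory=so.SOMConfig)
    n_effects_per_class: int = 50
    mad_frac: float = 0.5
    k_range: tuple[int, int] = (2, 8)
    consensus_reps: int = 100
    n_perm_preservation: int = 200
    n_perm_qc: int = 10_000
    bh_alpha: float = 0.05


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a summary dict (also written
    to ``outdir/summary.json``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}

    pop = sim.PopulationConfig(**{**cfg.population.__dict__, "seed": _stage_seed(cfg.seed, "geno")})
    arch = sim.ExpressionArchitecture(
        **{**cfg.architecture.__dict__, "seed": _stage_seed(cfg.seed, "expr")}
    )
    geno, truth0 = sim.simulate_genotypes(pop)
    gene_models = sim.make_gene_models(arch.n_genes, geno.snp_meta)
    if not arch.cis_effects:
        n_each = min(cfg.n_effects_per_class, arch.n_genes // 6)
        arch.cis_effects = sim.plant_cis_effects(
            geno,
            gene_models,
            n_direct=n_each,
            n_mediated=n_each,
            n_mrna=n_each,
            seed=_stage_seed(cfg.seed, "effects"),
        )
    mrna, protein, truth = sim.simulate_expression(geno, truth0, arch)
    labels = protein.line_meta["subpop"]
    if "simulate" in cfg.stages:
        cats = sim.make_category_map(mrna.genes, seed=_stage_seed(cfg.seed, "cats"))
        sim.write_fixture_bundle(out / "fixtures", geno, mrna, protein, truth, gene_models, cats)
        summary["simulate"] = {"n_lines": geno.n_lines, "n_snps": geno.n_snps,
                               "n_genes": mrna.n_genes}

    protein_f = filter_by_detection(protein)
    if "qc" in cfg.stages:
        dist = per_line_distribution(protein_f)
        dist.to_csv(out / "per_line_distribution.tsv", sep="\t")
        qc = replicate_concordance(
            protein_f, truth.replicate_pairs, n_perm=cfg.n_perm_qc,
            seed=_stage_seed(cfg.seed, "qc"),
        )
        summary["qc"] = {
            "replicate_mean_r": qc.replicate_mean_r,
            "nonreplicate_mean_r": qc.nonreplicate_mean_r,
            "permutation_p": qc.permutation_p,
        }

    if "concordance" in cfg.stages:
        corrs, csum = cc.gene_correlations(mrna, protein_f)
        corrs.to_csv(out / "gene_correlations.tsv", sep="\t")
        summary["concordance"] = {
            "fraction_positive": csum.fraction_positive,
            "fraction_significant": csum.fraction_significant,
            "n_tested": csum.n_tested,
        }

    modules = None
    if "network" in cfg.stages:
        # restrict to module-bearing + a slice of background genes for speed
        adj_prot = nw.adjust_population(protein_f, labels)
        adj_mrna = nw.adjust_population(
            ExpressionMatrix(mrna.values.loc[mrna.genes], mrna.line_meta), labels
        )
        modules = nw.detect_modules(adj_prot, cfg.network)
        modules.primary.to_frame().to_csv(out / "modules_protein.tsv", sep="\t")
        pres = nw.module_preservation(
            adj_prot, adj_mrna, modules, n_perm=cfg.n_perm_preservation,
            seed=_stage_seed(cfg.seed, "preservation"),
        )
        pd.DataFrame(
            {"z_summary": pres.z_summary, "median_rank": pres.median_rank}
        ).to_csv(out / "module_preservation.tsv", sep="\t")
        summary["network"] = {
            "n_modules": len(modules.modules),
            "z_summary": pres.z_summary.to_dict(),
        }

    subtype_labels = None
    if "subtype" in cfg.stages:
        top = cc.mad_top_fraction(protein_f, cfg.mad_frac)
        cons = st.consensus_cluster(
            protein_f.subset_genes(top),
            k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
            reps=cfg.consensus_reps,
            seed=_stage_seed(cfg.seed, "consensus"),
        )
        subtype_labels = cons.labels
        cons.labels.to_frame().join(cons.silhouette).join(cons.core).to_csv(
            out / "subtypes.tsv", sep="\t"
        )
        core_lab = cons.labels[cons.core]
        assoc = st.subtype_vs_subpopulation(core_lab, labels)
        assoc.to_csv(out / "subtype_vs_subpop.tsv", sep="\t", index=False)
        err, _preds = st.nsc_loocv(protein_f.subset_genes(top), cons.labels)
        summary["subtype"] = {"chosen_k": cons.chosen_k, "loocv_error": err}

    if "som" in cfg.stages:
        six = so.subpopulation_gene_summary(mrna, protein_f, labels)
        pct = so.to_percentiles(six)
        som_cfg = so.SOMConfig(**{**cfg.som.__dict__, "seed": _stage_seed(cfg.seed, "som")})
        model = so.train_som(pct, som_cfg)
        model = so.cluster_codebook(model, q=som_cfg.ap_q)
        gc = so.gene_clusters(model)
        gc.to_frame().join(model.bmu).to_csv(out / "som_gene_clusters.tsv", sep="\t")
        summary["som"] = {
            "quantization_error": model.quantization_error,
            "n_clusters": int(model.unit_clusters.nunique()),
        }

    if "qtl" in cfg.stages:
        K = q.kinship_matrix(geno)
        Qcov = pd.get_dummies(labels.loc[geno.lines], dtype=float).iloc[:, 1:]
        eig_cache: dict = {}
        planted = {e.gene for e in truth.cis_effects}
        records = []
        pvals = {"protein": [], "mrna": []}
        scans = {}
        for gene in sorted(planted):
            gm = gene_models.loc[gene]
            snps = q.cis_snps(geno, gm["start"], gm["end"], gm["chrom"])
            if len(snps) == 0:
                continue
            sub = geno.subset_snps(snps)
            for level, mat in (("protein", protein_f), ("mrna", mrna)):
                if gene not in mat.genes:
                    continue
                trait = mat.values.loc[gene, geno.lines]
                try:
                    scan = q.mlm_scan(trait, sub, K, Qcov, scope="cis",
                                      trait_name=gene, level=level, _eig_cache=eig_cache)
                except ValueError:
                    continue
                scans[(gene, level)] = scan
                pvals[level].append(scan.results["p"])
        for level in ("protein", "mrna"):
            if not pvals[level]:
                continue
            pooled = pd.concat(pvals[level])
            thr, _flags = q.bh_threshold(pooled.to_numpy(), alpha=cfg.bh_alpha)
            summary.setdefault("qtl", {})[f"bh_threshold_{level}"] = thr
            for (gene, lv), scan in scans.items():
                if lv != level:
                    continue
                records += q.clump_qtls(scan, geno.subset_snps(scan.results.index), thr)
        rows = [r.__dict__ | {"clump": ",".join(r.clump)} for r in records]
        pd.DataFrame(rows).to_csv(out / "qtl_records.tsv", sep="\t", index=False)
        summary.setdefault("qtl", {})["n_qtls"] = len(records)

    if "enrich" in cfg.stages:
        cats = sim.make_category_map(mrna.genes, seed=_stage_seed(cfg.seed, "cats"))
        tm = cats.rename(columns={"category": "term_id"})
        query = list(tm.loc[tm["term_id"] == tm["term_id"].iloc[0], "gene_id"])
        res = en.enrich(query, list(mrna.genes), tm,
                        seed=_stage_seed(cfg.seed, "enrich"))
        res.to_csv(out / "enrichment.tsv", sep="\t")
        summary["enrich"] = {"n_significant": int(res["significant"].sum())}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
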