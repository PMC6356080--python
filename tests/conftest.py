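import numpy as np
import pandas as pd
import pytest

from proteopop import simulate as sim
from proteopop.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_panel():
    """98-line panel with structure, LD blocks, and planted cis effects."""
    cfg = sim.PopulationConfig(n_lines=98, n_snps=2000, fst=0.2, seed=42)
    geno, truth = sim.simulate_genotypes(cfg)
    gene_models = sim.make_gene_models(400, geno.snp_meta)
    effects = sim.plant_cis_effects(
        geno, gene_models, n_direct=15, n_mediated=15, n_mrna=15, seed=43
    )
    arch = sim.ExpressionArchitecture(
        n_genes=400,
        module_sizes=(60, 50, 40),
        coupling_rho=0.6,
        cis_effects=effects,
        missing_rate_protein=0.15,
        n_replicate_lines=5,
        seed=44,
    )
    mrna, protein, truth = sim.simulate_expression(geno, truth, arch)
    return {
        "geno": geno,
        "mrna": mrna,
        "protein": protein,
        "truth": truth,
        "gene_models": gene_models,
        "arch": arch,
    }


@pytest.fixture()
def planted_module_expr():
    """Three latent-factor modules (60/50/40, within r ~ 0.7) + 100 noise genes."""
    n = 150
    rng = np.random.default_rng(7)
    rows, labels = [], []
    for mi, size in enumerate([60, 50, 40]):
        f = rng.standard_normal(n)
        for _ in range(size):
            rows.append(np.sqrt(0.7) * f + np.sqrt(0.3) * rng.standard_normal(n))
            labels.append(f"T{mi}")
    for _ in range(100):
        rows.append(rng.standard_normal(n))
        labels.append("noise")
    genes = [f"g{i:04d}" for i in range(len(rows))]
    expr = ExpressionMatrix(pd.DataFrame(rows, index=genes))
    return expr, pd.Series(labels, index=genes)
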