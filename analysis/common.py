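"""Shared dataset builder for the numbered analysis scripts.

Generates (once, deterministically) the synthetic maize-like panel used by
every downstream script: 98 inbred lines in three subpopulations, 5,000
SNPs with LD blocks, 2,000 genes with five planted coexpression modules,
mRNA-protein coupling 0.6, planted cis effects (direct / mediated /
mRNA-only), 20% missing protein cells, and 7 replicate line pairs. The
fixture bundle is written under results/data/ and reloaded on later runs.
"""

from __future__ import annotations

from pathlib import Path

from proteopop import io as ppio
from proteopop import simulate as sim

SEED = 11
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def build_dataset(force: bool = False):
    """Generate or reload the shared synthetic panel."""
    DATA.mkdir(parents=True, exist_ok=True)
    truth_path = DATA / "truth.json"
    if truth_path.exists() and not force:
        geno = ppio.read_genotypes(DATA / "genotypes.vcf")
        mrna = ppio.read_expression(DATA / "mrna.tsv")
        protein = ppio.read_expression(DATA / "protein.tsv")
        truth = sim.load_truth(truth_path)
        gene_models = _gene_models_from(geno)
        for m in (mrna, protein):
            m.line_meta["subpop"] = [
                truth.subpop_labels.get(ln.replace("_rep", ""), "NA") for ln in m.lines
            ]
        return geno, mrna, protein, truth, gene_models

    pop = sim.PopulationConfig(n_lines=98, n_snps=5000, fst=0.2, seed=SEED)
    geno, truth0 = sim.simulate_genotypes(pop)
    gene_models = _gene_models_from(geno)
    effects = sim.plant_cis_effects(
        geno, gene_models, n_direct=50, n_mediated=50, n_mrna=50, seed=SEED + 1
    )
    arch = sim.ExpressionArchitecture(
        n_genes=2000,
        module_sizes=(80, 70, 60, 50, 40),
        coupling_rho=0.6,
        cis_effects=effects,
        missing_rate_protein=0.2,
        n_replicate_lines=7,
        seed=SEED + 2,
    )
    mrna, protein, truth = sim.simulate_expression(geno, truth0, arch)
    cats = sim.make_category_map(mrna.genes, seed=SEED + 3)
    sim.write_fixture_bundle(DATA, geno, mrna, protein, truth, gene_models, cats)
    return geno, mrna, protein, truth, gene_models


def _gene_models_from(geno):
    return sim.make_gene_models(2000, geno.snp_meta)


if __name__ == "__main__":
    build_dataset(force=True)
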