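"""SOM integration of mRNA and protein medians across subpopulations.

Builds the six-measurement per-gene table (median mRNA and protein in
NSS/SS/TST), converts each column to ECDF percentiles, trains the
toroidal hexagonal SOM over restarts, and clusters the codebook vectors
with affinity propagation into expression archetypes.
"""

import pandas as pd

from common import RESULTS, SEED, build_dataset
from proteopop import som as so
from proteopop.quantitation import filter_by_detection

geno, mrna, protein, truth, _ = build_dataset()
labels = protein.line_meta["subpop"]
protein_f = filter_by_detection(protein, 0.5)

six = so.subpopulation_gene_summary(mrna, protein_f, labels)
print(f"genes with all six measurements: {len(six)}")
pct = so.to_percentiles(six)

cfg = so.SOMConfig(grid_x=11, grid_y=8, restarts=50, presentations=100, seed=SEED)
model = so.train_som(pct, cfg)
spread = (model.restart_errors.mean() - model.quantization_error) / model.restart_errors.mean()
print(
    f"best of {cfg.restarts} restarts: quantization error "
    f"{model.quantization_error:.4f} ({100 * spread:.2f}% below the restart mean)"
)

model = so.cluster_codebook(model, q=cfg.ap_q)
gc = so.gene_clusters(model)
pd.DataFrame({"unit": model.bmu, "cluster": gc}).to_csv(
    RESULTS / "som_gene_clusters.tsv", sep="\t"
)
pd.DataFrame(model.codebook).to_csv(RESULTS / "som_codebook.tsv", sep="\t")
print(f"affinity propagation found {model.unit_clusters.nunique()} codebook clusters")
profiles = pct.groupby(gc).mean()
profiles.to_csv(RESULTS / "som_cluster_profiles.tsv", sep="\t")
print("per-cluster mean percentile profiles written; cluster sizes:",
      gc.value_counts().to_dict())
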