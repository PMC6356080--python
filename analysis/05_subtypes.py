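"""Subtype discovery on the protein matrix and comparison with the
genomic subpopulations.

Consensus clustering on MAD-top-50% proteins, silhouette core-sample
selection, Wilcoxon signatures, nearest-shrunken-centroid LOOCV, Fisher
association of subtypes with subpopulations, and the Mantel correlation
of expression distance with genetic distance.
"""

import numpy as np
import pandas as pd

from common import RESULTS, SEED, build_dataset
from proteopop import qtl as q
from proteopop import subtypes as st
from proteopop.concordance import mad_top_fraction
from proteopop.quantitation import filter_by_detection

geno, mrna, protein, truth, _ = build_dataset()
labels = protein.line_meta["subpop"]
protein_f = filter_by_detection(protein, 0.5)

top = mad_top_fraction(protein_f, 0.5)
mat = protein_f.subset_genes(top)
cons = st.consensus_cluster(mat, k_range=range(2, 9), reps=250, seed=SEED)
print(f"consensus clustering chose k = {cons.chosen_k}")
print("subtype sizes:", cons.labels.value_counts().to_dict())
n_core = int(cons.core.sum())
print(f"core samples (positive silhouette): {n_core}/{len(cons.core)}")
cons.labels.to_frame().join(cons.silhouette).join(cons.core).to_csv(
    RESULTS / "subtypes.tsv", sep="\t"
)

sigs = st.subtype_signatures(mat, cons.labels)
sigs.to_csv(RESULTS / "subtype_signatures.tsv", sep="\t")
print(f"signature tests: {len(sigs)}; Bonferroni-significant: {int(sigs['significant'].sum())}")

err, preds = st.nsc_loocv(mat, cons.labels)
print(f"nearest-shrunken-centroid LOOCV error: {100 * err:.1f}%")

core_labels = cons.labels[cons.core]
assoc = st.subtype_vs_subpopulation(core_labels, labels)
assoc.to_csv(RESULTS / "subtype_vs_subpopulation.tsv", sep="\t", index=False)
best = assoc.sort_values("p").iloc[0]
print(
    f"strongest subtype/subpopulation association: subtype {best.subtype} with "
    f"{best.subpop}, p = {best.p:.2e}"
)

# expression distance vs genetic distance (Mantel)
lines = [ln for ln in protein_f.lines if not ln.endswith("_rep")]
expr = protein_f.subset_lines(lines).values
vals = expr.fillna(expr.mean(axis=1).mean()).to_numpy()
edist = 1.0 - np.corrcoef(vals.T)
np.fill_diagonal(edist, 0.0)
K = q.kinship_matrix(geno.subset_lines(lines))
kd = K.to_numpy()
gdist = np.sqrt(np.maximum(np.add.outer(np.diag(kd), np.diag(kd)) - 2 * kd, 0.0))
np.fill_diagonal(gdist, 0.0)
edm = pd.DataFrame(edist, index=lines, columns=lines)
gdm = pd.DataFrame(gdist, index=lines, columns=lines)
r, p = st.expression_vs_genetic_distance(edm, gdm, n_perm=999, seed=SEED)
print(f"Mantel r(expression distance, genetic distance) = {r:.3f}, p = {p:.3g}")
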