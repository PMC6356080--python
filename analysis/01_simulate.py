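"""Generate the synthetic panel: genotypes, mRNA, protein, ground truth.

Writes the fixture bundle (VCF, expression TSVs, GFF3 gene models,
category map, truth JSON) under results/data/ and prints the headline
dimensions and realized structure (subpopulation sizes, missing-protein
fraction, planted-effect counts).
"""

import numpy as np

from common import build_dataset

geno, mrna, protein, truth, gene_models = build_dataset(force=True)

print(f"lines: {geno.n_lines} (+{len(truth.replicate_pairs)} replicate columns)")
print("subpopulations:", truth.subpop_labels.value_counts().to_dict())
print(f"SNPs: {geno.n_snps}; mean MAF {geno.maf().mean():.3f}")
print(f"genes: {mrna.n_genes}")
modules = {m: sum(1 for v in truth.module_of_gene.values() if v == m)
           for m in sorted(set(truth.module_of_gene.values()))}
print("planted modules:", modules)
effects = {}
for e in truth.cis_effects:
    effects[e.effect_on] = effects.get(e.effect_on, 0) + 1
print("planted cis effects:", effects)
print(f"protein missing fraction: {np.mean(np.isnan(protein.values.to_numpy())):.3f}")
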