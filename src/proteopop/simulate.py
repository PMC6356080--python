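"""Synthetic genotype + mRNA + protein generator with known ground truth.

Emulates the statistical structure of a population proteogenomics panel of
fully inbred maize lines drawn from three subpopulations (NSS/SS/TST-like):

* genotypes — biallelic homozygous SNPs (dosage 0/2) with Balding-Nichols
  subpopulation differentiation controlled by ``fst`` and simple LD blocks
  built by copying a block-founder SNP with a small per-line flip
  probability;
* expression — genes organised into coexpression modules via shared latent
  factors, a tunable per-gene mRNA-protein coupling, planted cis effects
  (on mRNA, protein, both, or protein-only-through-mRNA "mediated"),
  missing protein cells, and biological-replicate line pairs.

Every random draw flows from the config seeds, so identical configs give
identical datasets, and the returned :class:`SyntheticTruth` records what
was planted for downstream recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix

SUBPOP_NAMES = ("NSS", "SS", "TST")

EffectTarget = Literal["mrna", "protein", "both", "mediated"]


@dataclass
class PopulationConfig:
    """Panel design: lines, subpopulations, SNPs, differentiation, LD."""

    n_lines: int = 98
    subpop_proportions: tuple[float, float, float] = (0.2, 0.1, 0.7)
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.2
    ld_block_size: int = 5
    ld_flip_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 6:
            raise ValueError("n_lines must be >= 6")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-12:
            raise ValueError("subpop_proportions must sum to 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class CisEffect:
    """A planted SNP effect on one gene's expression."""

    gene: str
    snp: str
    effect_on: EffectTarget
    beta: float  # in per-genotype-SD units; trait shift of beta/2 per allele copy


@dataclass
class ExpressionArchitecture:
    """Gene-level architecture: modules, coupling, planted effects, noise."""

    n_genes: int = 2000
    module_sizes: Sequence[int] = (80, 70, 60, 50, 40)
    module_strength: float = 0.55  # shared-variance fraction of module latent factor
    coupling_rho: float | np.ndarray = 0.6
    cis_effects: list[CisEffect] = field(default_factory=list)
    noise_sd_mrna: float = 0.3
    noise_sd_protein: float = 0.3
    # SD of per-gene subpopulation mean shifts (differential expression
    # between NSS/SS/TST); applied to the mRNA signal and, independently,
    # to the protein-specific component, so the proteome tracks the
    # subpopulations at least as strongly as the transcriptome
    subpop_de_sd: float = 0.3
    missing_rate_protein: float = 0.2
    n_replicate_lines: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) must be <= n_genes")
        if not (0.0 <= self.missing_rate_protein < 0.5):
            raise ValueError("missing_rate_protein must be in [0, 0.5)")
        rho = np.asarray(self.coupling_rho, dtype=float)
        if np.any(np.abs(rho) > 1.0):
            raise ValueError("coupling_rho must lie in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    subpop_labels: pd.Series | None = None
    module_of_gene: dict[str, str] = field(default_factory=dict)
    cis_effects: list[CisEffect] = field(default_factory=list)
    coupling_of_gene: dict[str, float] = field(default_factory=dict)
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(cfg: PopulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw inbred genotypes with Balding-Nichols subpopulation structure.

    Ancestral allele frequencies are uniform over ``maf_range``; when
    ``fst`` > 0 each subpopulation's frequency is drawn from the
    Balding-Nichols Beta distribution
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` so that Var(p_s) = F p (1-p).
    Inbred lines carry a single allele duplicated (dosage 0 or 2). SNPs are
    grouped into LD blocks of ``ld_block_size``: non-founder SNPs copy the
    founder's alleles and flip per line with ``ld_flip_prob``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _subpop_counts(cfg.n_lines, cfg.subpop_proportions)
    labels = np.repeat(np.arange(3), counts)
    line_ids = [f"L{i:03d}" for i in range(cfg.n_lines)]

    n_blocks = -(-cfg.n_snps // cfg.ld_block_size)
    lo, hi = cfg.maf_range
    anc = rng.uniform(lo, hi, size=n_blocks)

    if cfg.fst > 0:
        a = anc * (1 - cfg.fst) / cfg.fst
        b = (1 - anc) * (1 - cfg.fst) / cfg.fst
        # subpop frequencies, clipped away from fixation
        sub_freq = np.clip(rng.beta(a[:, None], b[:, None], size=(n_blocks, 3)), 1e-6, 1 - 1e-6)
    else:
        sub_freq = np.repeat(anc[:, None], 3, axis=1)

    # founder allele per (block, line): Bernoulli(freq of that line's subpop)
    p_line = sub_freq[:, labels]  # n_blocks x n_lines
    founder = (rng.random((n_blocks, cfg.n_lines)) < p_line).astype(np.int8)

    alleles = np.empty((cfg.n_snps, cfg.n_lines), dtype=np.int8)
    block_of_snp = np.arange(cfg.n_snps) // cfg.ld_block_size
    for s in range(cfg.n_snps):
        b = block_of_snp[s]
        if s % cfg.ld_block_size == 0:
            alleles[s] = founder[b]
        else:
            flips = rng.random(cfg.n_lines) < cfg.ld_flip_prob
            alleles[s] = founder[b] ^ flips

    dosages = (2 * alleles).astype(float)
    snp_ids = [f"snp{i:05d}" for i in range(cfg.n_snps)]
    snp_meta = _place_snps(snp_ids, rng)
    geno = GenotypeMatrix(
        pd.DataFrame(dosages, index=snp_ids, columns=line_ids),
        snp_meta,
    )
    truth = SyntheticTruth(
        subpop_labels=pd.Series([SUBPOP_NAMES[g] for g in labels], index=line_ids, name="subpop")
    )
    return geno, truth


def _subpop_counts(n_lines: int, props: Sequence[float]) -> np.ndarray:
    counts = np.floor(np.asarray(props) * n_lines).astype(int)
    counts[np.argmax(props)] += n_lines - counts.sum()
    return counts


# Two chromosomes; genes are spaced every GENE_SPACING bp so that the
# +-200 kb cis window of a gene covers a handful of neighbouring SNPs.
GENE_SPACING = 50_000
GENE_LENGTH = 3_000
CIS_WINDOW = 200_000


def _place_snps(snp_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    n = len(snp_ids)
    half = n - n // 2
    chroms = np.array(["chr1"] * half + ["chr2"] * (n - half))
    pos = np.empty(n, dtype=int)
    for chrom in ("chr1", "chr2"):
        m = chroms == chrom
        k = int(m.sum())
        length = max(k * 1000, GENE_SPACING * 10)
        pos[m] = np.sort(rng.choice(np.arange(1, length), size=k, replace=False))
    refalt = rng.choice(list("ACGT"), size=(n, 2))
    same = refalt[:, 0] == refalt[:, 1]
    refalt[same, 1] = np.where(refalt[same, 0] == "A", "G", "A")
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": refalt[:, 0], "alt": refalt[:, 1]},
        index=pd.Index(snp_ids, name="snp"),
    )


def make_gene_models(n_genes: int, snp_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Lay out ``n_genes`` two-exon gene models over the simulated chromosomes.

    Returns a frame indexed by gene ID with ``chrom``, ``start``, ``end``
    (1-based inclusive) plus exon/CDS/UTR sub-interval columns used by the
    GFF3 writer and the SNP annotator. Genes alternate between chromosomes
    in positional order so cis windows overlap the SNP coordinate space.
    """
    rows = []
    per_chrom = -(-n_genes // 2)
    if snp_meta is not None:
        extent = {
            c: int(snp_meta.loc[snp_meta["chrom"] == c, "pos"].max())
            for c in ("chr1", "chr2")
            if (snp_meta["chrom"] == c).any()
        }
    else:
        extent = {}
    spacing = {
        c: max((extent.get(c, per_chrom * GENE_SPACING) - 20_000) // max(per_chrom, 1), GENE_LENGTH + 100)
        for c in ("chr1", "chr2")
    }
    for i in range(n_genes):
        chrom = "chr1" if i < per_chrom else "chr2"
        j = i if i < per_chrom else i - per_chrom
        start = spacing[chrom] * j + 10_000
        end = start + GENE_LENGTH - 1
        # exon1: 5'UTR (200) + CDS part; intron 800; exon2: CDS + 3'UTR (300)
        exon1 = (start, start + 999)
        exon2 = (start + 1800, end)
        rows.append(
            {
                "gene": f"g{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+",
                "exon1_start": exon1[0],
                "exon1_end": exon1[1],
                "exon2_start": exon2[0],
                "exon2_end": exon2[1],
                "utr5_start": start,
                "utr5_end": start + 199,
                "cds1_start": start + 200,
                "cds1_end": exon1[1],
                "cds2_start": exon2[0],
                "cds2_end": end - 300,
                "utr3_start": end - 299,
                "utr3_end": end,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def plant_cis_effects(
    geno: GenotypeMatrix,
    gene_models: pd.DataFrame,
    n_direct: int = 50,
    n_mediated: int = 50,
    n_mrna: int = 50,
    n_both: int = 0,
    beta: float = 2.0,
    seed: int = 0,
    min_maf: float = 0.1,
) -> list[CisEffect]:
    """Pick SNP-gene pairs inside cis windows and assign planted effects.

    Each chosen gene gets one cis SNP (MAF >= ``min_maf``) within
    +-200 kb; genes are disjoint across effect classes.
    """
    rng = np.random.default_rng(seed)
    maf = geno.maf()
    usable = geno.snp_meta[maf >= min_maf]
    candidates: list[tuple[str, str]] = []
    by_chrom = {c: sub.sort_values("pos") for c, sub in usable.groupby("chrom")}
    for gene, gm in gene_models.iterrows():
        sub = by_chrom.get(gm["chrom"])
        if sub is None:
            continue
        lo, hi = gm["start"] - CIS_WINDOW, gm["end"] + CIS_WINDOW
        hits = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
        if len(hits):
            candidates.append((gene, str(rng.choice(hits.index))))
    total = n_direct + n_mediated + n_mrna + n_both
    if total > len(candidates):
        raise ValueError(f"only {len(candidates)} cis-eligible genes for {total} effects")
    chosen = rng.permutation(len(candidates))[:total]
    kinds = ["protein"] * n_direct + ["mediated"] * n_mediated + ["mrna"] * n_mrna + ["both"] * n_both
    return [
        CisEffect(gene=candidates[i][0], snp=candidates[i][1], effect_on=k, beta=beta)
        for i, k in zip(chosen, kinds)
    ]


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    geno: GenotypeMatrix,
    truth: SyntheticTruth,
    arch: ExpressionArchitecture,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate coupled mRNA and protein matrices on top of the genotypes.

    mRNA(g) = module latent factor + cis effects on mRNA (including
    "mediated" and "both") + Gaussian noise. Protein(g) combines the mRNA
    *signal* with weight ``coupling_rho`` and an independent component with
    weight sqrt(1 - rho^2), then adds direct protein effects ("protein",
    "both"), noise, missingness, and replicate columns. "Mediated" effects
    therefore reach the protein only through the mRNA term.
    """
    rng = np.random.default_rng(arch.seed)
    n_lines = geno.n_lines
    line_ids = list(geno.lines)
    genes = [f"g{i:04d}" for i in range(arch.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    for eff in arch.cis_effects:
        if eff.gene not in gene_pos:
            raise ValueError(f"cis effect references unknown gene {eff.gene}")
        if eff.snp not in geno.snps:
            raise ValueError(f"cis effect references unknown SNP {eff.snp}")

    rho = np.broadcast_to(np.asarray(arch.coupling_rho, dtype=float), (arch.n_genes,)).copy()

    # module latent structure
    module_of: dict[str, str] = {}
    mrna_sig = np.empty((arch.n_genes, n_lines))
    v = arch.module_strength
    gi = 0
    for m, size in enumerate(arch.module_sizes):
        factor = rng.standard_normal(n_lines)
        for _ in range(size):
            mrna_sig[gi] = np.sqrt(v) * factor + np.sqrt(1 - v) * rng.standard_normal(n_lines)
            module_of[genes[gi]] = f"M{m + 1}"
            gi += 1
    for _ in range(gi, arch.n_genes):
        mrna_sig[gi] = rng.standard_normal(n_lines)
        module_of[genes[gi]] = "none"
        gi += 1

    # per-gene subpopulation differential expression on the mRNA signal
    labels0 = truth.subpop_labels
    pop_idx = None
    if labels0 is not None and arch.subpop_de_sd > 0:
        name_to_i = {n: i for i, n in enumerate(SUBPOP_NAMES)}
        pop_idx = np.array([name_to_i.get(labels0.get(ln), 0) for ln in line_ids])
        de_mrna = rng.normal(0.0, arch.subpop_de_sd, size=(arch.n_genes, 3))
        mrna_sig += de_mrna[:, pop_idx]

    # planted genotype effects on the mRNA signal
    dos = geno.dosages.to_numpy()
    snp_pos = {s: i for i, s in enumerate(geno.snps)}
    for eff in arch.cis_effects:
        if eff.effect_on in ("mrna", "both", "mediated"):
            d = dos[snp_pos[eff.snp]]
            mrna_sig[gene_pos[eff.gene]] += eff.beta * (d - d.mean()) / 2.0

    # protein signal: coupling-weighted mRNA + independent part + direct effects.
    # The independent component carries the same module memberships driven by
    # new per-module factors, so protein coexpression modules exist in their
    # own right (protein complexes co-vary beyond transcriptional coupling).
    indep = np.empty((arch.n_genes, n_lines))
    gi = 0
    for size in arch.module_sizes:
        factor = rng.standard_normal(n_lines)
        for _ in range(size):
            indep[gi] = np.sqrt(v) * factor + np.sqrt(1 - v) * rng.standard_normal(n_lines)
            gi += 1
    for _ in range(gi, arch.n_genes):
        indep[gi] = rng.standard_normal(n_lines)
        gi += 1
    prot_sig = rho[:, None] * mrna_sig + np.sqrt(1 - rho**2)[:, None] * indep
    if pop_idx is not None:
        de_prot = rng.normal(0.0, arch.subpop_de_sd, size=(arch.n_genes, 3))
        prot_sig += de_prot[:, pop_idx]
    for eff in arch.cis_effects:
        if eff.effect_on in ("protein", "both"):
            d = dos[snp_pos[eff.snp]]
            prot_sig[gene_pos[eff.gene]] += eff.beta * (d - d.mean()) / 2.0

    mrna_vals = mrna_sig + arch.noise_sd_mrna * rng.standard_normal(mrna_sig.shape)
    prot_vals = prot_sig + arch.noise_sd_protein * rng.standard_normal(prot_sig.shape)

    # replicate columns: same signal, fresh noise
    rep_pairs: list[tuple[str, str]] = []
    rep_cols_m, rep_cols_p, rep_ids = [], [], []
    n_rep = min(arch.n_replicate_lines, n_lines)
    for idx in rng.choice(n_lines, size=n_rep, replace=False):
        rid = f"{line_ids[idx]}_rep"
        rep_ids.append(rid)
        rep_pairs.append((line_ids[idx], rid))
        rep_cols_m.append(mrna_sig[:, idx] + arch.noise_sd_mrna * rng.standard_normal(arch.n_genes))
        rep_cols_p.append(prot_sig[:, idx] + arch.noise_sd_protein * rng.standard_normal(arch.n_genes))

    all_ids = line_ids + rep_ids
    mrna_full = np.column_stack([mrna_vals] + [c[:, None] for c in rep_cols_m]) if rep_ids else mrna_vals
    prot_full = np.column_stack([prot_vals] + [c[:, None] for c in rep_cols_p]) if rep_ids else prot_vals

    if arch.missing_rate_protein > 0:
        mask = rng.random(prot_full.shape) < arch.missing_rate_protein
        prot_full = prot_full.copy()
        prot_full[mask] = np.nan

    labels = truth.subpop_labels
    meta = pd.DataFrame(index=pd.Index(all_ids, name="line"))
    if labels is not None:
        meta["subpop"] = [labels.get(i.replace("_rep", ""), "NA") for i in all_ids]

    mrna = ExpressionMatrix(pd.DataFrame(mrna_full, index=genes, columns=all_ids), meta)
    protein = ExpressionMatrix(pd.DataFrame(prot_full, index=genes, columns=all_ids), meta)

    out_truth = SyntheticTruth(
        subpop_labels=labels,
        module_of_gene=module_of,
        cis_effects=list(arch.cis_effects),
        coupling_of_gene={g: float(r) for g, r in zip(genes, rho)},
        replicate_pairs=rep_pairs,
    )
    return mrna, protein, out_truth


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(
    outdir: str | Path,
    geno: GenotypeMatrix,
    mrna: ExpressionMatrix,
    protein: ExpressionMatrix,
    truth: SyntheticTruth,
    gene_models: pd.DataFrame | None = None,
    category_map: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the generated objects to standard on-disk formats.

    Produces genotypes.vcf (VCF 4.2 sites+GT), mrna.tsv / protein.tsv
    expression tables, genes.gff3, categories.tsv, and truth.json. Files
    round-trip losslessly through :mod:`proteopop.io`.
    """
    from . import io as ppio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "mrna": outdir / "mrna.tsv",
        "protein": outdir / "protein.tsv",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
    }
    ppio.write_vcf(paths["vcf"], geno)
    ppio.write_expression(paths["mrna"], mrna)
    ppio.write_expression(paths["protein"], protein)
    if gene_models is None:
        gene_models = make_gene_models(mrna.n_genes)
    ppio.write_gff3(paths["gff3"], gene_models)
    if category_map is not None:
        paths["categories"] = outdir / "categories.tsv"
        category_map.to_csv(paths["categories"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1)
    return paths


def _truth_to_json(truth: SyntheticTruth) -> dict:
    return {
        "subpop_labels": truth.subpop_labels.to_dict() if truth.subpop_labels is not None else None,
        "module_of_gene": truth.module_of_gene,
        "cis_effects": [asdict(e) for e in truth.cis_effects],
        "coupling_of_gene": truth.coupling_of_gene,
        "replicate_pairs": [list(p) for p in truth.replicate_pairs],
    }


def load_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        subpop_labels=pd.Series(d["subpop_labels"]) if d["subpop_labels"] else None,
        module_of_gene=d["module_of_gene"],
        cis_effects=[CisEffect(**e) for e in d["cis_effects"]],
        coupling_of_gene=d["coupling_of_gene"],
        replicate_pairs=[tuple(p) for p in d["replicate_pairs"]],
    )


def peptide_table_from_protein(
    protein: ExpressionMatrix,
    peptides_per_gene: int = 3,
    shared_fraction: float = 0.15,
    noise_sd_log2: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand a gene-level log2-ratio matrix into a peptide-level ratio table.

    Each gene gets ``peptides_per_gene`` unique peptides whose linear
    ratios scatter around 2^(gene log2 ratio) with log-normal measurement
    noise; a ``shared_fraction`` of peptides is flagged non-unique (mapped
    to two genes) and must be ignored by quantitation. Missing gene cells
    yield missing peptide ratios.
    """
    rng = np.random.default_rng(seed)
    lines = list(protein.lines)
    rows = []
    pep_i = 0
    genes = list(protein.genes)
    for g in genes:
        base = protein.values.loc[g]
        for _ in range(peptides_per_gene):
            ratios = 2.0 ** (base + noise_sd_log2 * rng.standard_normal(len(lines)))
            rec = {"peptide": f"PEP{pep_i:06d}", "gene_id": g, "unique": True}
            rec.update(dict(zip(lines, ratios)))
            rows.append(rec)
            pep_i += 1
        if rng.random() < shared_fraction:
            other = genes[int(rng.integers(len(genes)))]
            ratios = 2.0 ** (base + 2.0 + noise_sd_log2 * rng.standard_normal(len(lines)))
            for mapped in (g, other):
                rec = {"peptide": f"PEP{pep_i:06d}", "gene_id": mapped, "unique": False}
                rec.update(dict(zip(lines, ratios)))
                rows.append(rec)
            pep_i += 1
    return pd.DataFrame(rows)


def make_category_map(
    genes: Sequence[str],
    n_categories: int = 20,
    genes_per_category: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> category map standing in for MapMan/GO-like terms."""
    rng = np.random.default_rng(seed)
    rows = []
    genes = list(genes)
    for c in range(n_categories):
        members = rng.choice(genes, size=min(genes_per_category, len(genes)), replace=False)
        rows += [{"gene_id": g, "category": f"cat{c:02d}"} for g in members]
    return pd.DataFrame(rows)
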