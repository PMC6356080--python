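"""Readers and writers for the on-disk formats the pipeline consumes.

Expression matrices are TSV (first column gene ID, header = line IDs,
empty cell = missing). Genotypes are VCF 4.2 (sites + GT, read through
cyvcf2) or a plain dosage TSV. Gene models are GFF3 parsed with gffutils.
All writes are atomic (write to a temp file in the same directory, then
rename).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# expression TSV


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x lines TSV; empty cells become NaN (missing, not zero)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    df = df.astype("Float64").astype(float)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dups[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(path: str | Path, m: ExpressionMatrix) -> None:
    text = m.values.to_csv(sep="\t", index_label="gene_id", na_rep="")
    _atomic_write(Path(path), text)


# ---------------------------------------------------------------------------
# genotypes


def write_vcf(path: str | Path, geno: GenotypeMatrix) -> None:
    """Write sites + GT calls as VCF 4.2 (dosage 0 -> 0/0, 2 -> 1/1)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=proteopop",
    ]
    for chrom in pd.unique(geno.snp_meta["chrom"]):
        length = int(geno.snp_meta.loc[geno.snp_meta["chrom"] == chrom, "pos"].max()) + 10_000
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.lines))
    meta = geno.snp_meta
    order = meta.sort_values(["chrom", "pos"]).index
    dos = geno.dosages
    code = {0.0: "0/0", 2.0: "1/1", 1.0: "0/1"}
    for snp in order:
        row = meta.loc[snp]
        gts = [code.get(d, "./.") if np.isfinite(d) else "./." for d in dos.loc[snp]]
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_genotypes(path: str | Path, het_policy: str = "drop") -> GenotypeMatrix:
    """Read genotypes from VCF (via cyvcf2) or dosage TSV.

    Heterozygous calls are dropped (set missing) under the default policy,
    or coded as dosage 1 with ``het_policy="dose"``. Multi-allelic sites
    are skipped.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, het_policy)
    return _read_dosage_tsv(path)


def _read_vcf(path: Path, het_policy: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_het = 0
    last = {}
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if last.get(var.CHROM, -1) > var.POS:
            raise ValueError(f"VCF not sorted at {var.CHROM}:{var.POS}")
        last[var.CHROM] = var.POS
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.full_like(gt, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 3] = 2.0
        het = gt == 1
        n_het += int(het.sum())
        if het_policy == "dose":
            dos[het] = 1.0
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="snp"),
    )
    return GenotypeMatrix(pd.DataFrame(np.array(rows), index=meta.index, columns=samples), meta)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp", "chrom", "pos", "ref", "alt"]
    meta = df[meta_cols].set_index("snp")
    dos = df.drop(columns=meta_cols[1:]).set_index("snp").astype(float)
    return GenotypeMatrix(dos, meta)


def write_dosage_tsv(path: str | Path, geno: GenotypeMatrix) -> None:
    out = geno.snp_meta.join(geno.dosages)
    _atomic_write(Path(path), out.to_csv(sep="\t", index_label="snp"))


# ---------------------------------------------------------------------------
# gene models (GFF3)


@dataclass
class TranscriptModel:
    """Interval set of one transcript (1-based inclusive coordinates)."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


def write_gff3(path: str | Path, gene_models: pd.DataFrame) -> None:
    """Write the generator's two-exon gene models as GFF3."""
    out = ["##gff-version 3"]
    for gene, r in gene_models.iterrows():
        c, s, e = r["chrom"], int(r["start"]), int(r["end"])
        tid = f"{gene}_T001"
        out.append(f"{c}\t.\tgene\t{s}\t{e}\t.\t{r['strand']}\t.\tID={gene}")
        out.append(f"{c}\t.\tmRNA\t{s}\t{e}\t.\t{r['strand']}\t.\tID={tid};Parent={gene}")
        feats = [
            ("exon", r["exon1_start"], r["exon1_end"]),
            ("exon", r["exon2_start"], r["exon2_end"]),
            ("five_prime_UTR", r["utr5_start"], r["utr5_end"]),
            ("CDS", r["cds1_start"], r["cds1_end"]),
            ("CDS", r["cds2_start"], r["cds2_end"]),
            ("three_prime_UTR", r["utr3_start"], r["utr3_end"]),
        ]
        for k, (ftype, fs, fe) in enumerate(feats):
            phase = "0" if ftype == "CDS" else "."
            out.append(
                f"{c}\t.\t{ftype}\t{int(fs)}\t{int(fe)}\t.\t{r['strand']}\t{phase}"
                f"\tID={tid}.{ftype}.{k};Parent={tid}"
            )
    _atomic_write(Path(path), "\n".join(out) + "\n")


def read_gene_models(path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Parse a GFF3 into per-gene transcript models using gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, list[TranscriptModel]] = {}
    for gene in db.features_of_type("gene"):
        txs = []
        for tx in db.children(gene, featuretype="mRNA"):
            model = TranscriptModel(
                transcript_id=tx.id,
                gene_id=gene.id,
                chrom=tx.seqid,
                start=tx.start,
                end=tx.end,
            )
            for child in db.children(tx):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    model.exons.append(iv)
                elif child.featuretype == "CDS":
                    model.cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    model.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    model.utr3.append(iv)
            txs.append(model)
        models[gene.id] = txs
    return models


# ---------------------------------------------------------------------------
# misc tables


def read_category_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty category map: {path}")
    return df


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Peptide TSV: peptide, gene_id, unique, then one column per line."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "gene_id", "unique"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df
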