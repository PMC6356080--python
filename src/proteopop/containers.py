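"""Core in-memory containers shared by every analysis stage.

Expression data live in an :class:`ExpressionMatrix` (genes x lines, NaN =
missing), genotypes in a :class:`GenotypeMatrix` (biallelic SNPs x lines,
allele dosage coded 0/2 for fully inbred homozygotes). Both are thin
dataclasses around pandas objects so that downstream code can use ordinary
DataFrame operations while line/SNP metadata travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x lines numeric matrix (log2 protein ratio or FPKM).

    Missing cells are NaN. ``line_meta`` is indexed by line ID and may carry
    a ``subpop`` column and replicate pairing information.
    """

    values: pd.DataFrame
    line_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.line_meta.empty:
            self.line_meta = pd.DataFrame(index=self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.line_meta)

    def subset_lines(self, lines) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(lines)], self.line_meta.loc[list(lines)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.line_meta.copy())


@dataclass
class GenotypeMatrix:
    """Biallelic SNPs x lines allele-dosage matrix for inbred lines.

    ``dosages`` holds values in {0, 2} (NaN = missing call); ``snp_meta`` is
    indexed by SNP ID with columns ``chrom``, ``pos`` (1-based), ``ref``,
    ``alt``.
    """

    dosages: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.snp_meta.index):
            raise ValueError("dosage rows and snp_meta index must match")

    @property
    def snps(self) -> pd.Index:
        return self.dosages.index

    @property
    def lines(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP, ignoring missing calls."""
        freq = self.dosages.mean(axis=1, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, snps) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[snps], self.snp_meta.loc[snps])

    def subset_lines(self, lines) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[list(lines)], self.snp_meta)
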