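"""Expression matrix container, TPM computation and the expression filter.

The pipeline works on raw gene-by-sample count matrices with per-gene lengths.
TPM (transcripts per million) divides counts by gene length and rescales each
sample to sum to 1e6; the recurring eligibility rule keeps genes whose median
TPM over a stated sample subset is at least 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Raw counts for one tissue.

    Attributes
    ----------
    counts
        Integer gene x sample DataFrame (genes in rows).
    gene_lengths
        Per-gene length in bases, indexed like ``counts.index``.
    sample_donor
        Sample id -> donor id mapping covering every column.
    tissue
        Tissue name.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_donor: pd.Series
    tissue: str = "tissue"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in counts")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("every gene needs a length")
        missing = self.counts.columns.difference(self.sample_donor.index)
        if len(missing):
            raise ValueError(f"samples without a donor mapping: {list(missing)[:5]}")
        self.sample_donor = self.sample_donor.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        return ExpressionMatrix(
            counts=self.counts.loc[:, samples],
            gene_lengths=self.gene_lengths,
            sample_donor=self.sample_donor.loc[samples],
            tissue=self.tissue,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(
            counts=self.counts.loc[genes],
            gene_lengths=self.gene_lengths.loc[genes],
            sample_donor=self.sample_donor,
            tissue=self.tissue,
        )


def compute_tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Length-normalized counts rescaled so every sample sums to 1e6.

    ``tpm[g, s] = (count[g, s] / length[g]) / sum_g'(count[g', s] / length[g']) * 1e6``

    An all-zero sample yields an all-zero column and a warning rather than an
    error, so sparse synthetic tissues do not abort the pipeline.
    """
    lengths = matrix.gene_lengths.to_numpy(dtype=float)
    if (lengths <= 0).any():
        bad = matrix.genes[lengths <= 0]
        raise ValueError(f"non-positive gene lengths for: {list(bad)[:5]}")
    rate = matrix.counts.to_numpy(dtype=float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample(s) produce all-zero TPM columns",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.where(zero, 1.0, colsum)
    tpm = rate / denom[None, :] * 1e6
    return pd.DataFrame(tpm, index=matrix.genes, columns=matrix.samples)


def filter_expressed(tpm: pd.DataFrame, sample_subset: Sequence[str], min_median: float = 1.0) -> pd.Index:
    """Genes whose median TPM over ``sample_subset`` is >= ``min_median``.

    The median over an even number of samples is the midpoint mean, so a gene
    at exactly the threshold is kept (the removal rule is strict ``<``).
    The result depends only on the listed subset.
    """
    subset = pd.Index(sample_subset)
    if len(subset) == 0:
        raise ValueError("sample subset must be non-empty")
    med = tpm.loc[:, subset].median(axis=1)
    return tpm.index[med >= min_median]
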