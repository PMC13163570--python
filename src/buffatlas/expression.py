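"""Expression-matrix I/O, filtering, replicate averaging and correlation.

The central container is :class:`ExpressionMatrix`: a gene x sample table of
TPM (transcripts per million) values together with per-sample metadata
(tissue, optional lactation stage, data source).  All downstream screening
steps (housekeeping-gene and tissue-specific-gene calling) operate either on
this container or on the replicate-averaged :class:`TissueProfile` derived
from it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

VALID_STAGES = {"dry", "early", "peak", "mid", "late"}

__all__ = [
    "ExpressionMatrix",
    "TissueProfile",
    "CorrelationMatrix",
    "load_expression_matrix",
    "write_expression_matrix",
    "filter_expressed",
    "average_replicates",
    "correlate_profiles",
    "expressed_gene_counts",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id; entries
        are finite, non-negative TPM values.
    metadata
        DataFrame indexed by sample id with columns ``tissue`` (required),
        ``stage`` (optional label among dry/early/peak/mid/late, else NA)
        and ``source``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite expression values")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in v.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        md = self.metadata.loc[list(v.columns)]
        if "tissue" not in md.columns or md["tissue"].isna().any():
            raise ValueError("every sample requires a tissue label")
        bad = md["stage"].dropna()[~md["stage"].dropna().isin(VALID_STAGES)] if "stage" in md.columns else pd.Series(dtype=object)
        if len(bad):
            raise ValueError(f"invalid stage labels: {sorted(bad.unique())}")
        self.metadata = md

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.metadata.loc[sample_ids])


@dataclass
class TissueProfile:
    """Gene x group matrix of replicate-averaged TPM (groups are tissues or stages)."""

    means: pd.DataFrame
    by: str = "tissue"

    @property
    def gene_ids(self) -> list:
        return list(self.means.index)

    @property
    def tissue_ids(self) -> list:
        return list(self.means.columns)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise correlation coefficients with two-sided p-values."""

    rho: pd.DataFrame
    pvals: pd.DataFrame
    method: str = "pearson"
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(self.rho.columns)


def load_expression_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows) plus a TSV metadata table.

    The matrix file's first column holds gene ids and the header row holds
    sample ids; the metadata file needs columns ``sample_id``, ``tissue``,
    ``stage``, ``source``.  Samples present in the matrix but absent from the
    metadata raise a :class:`ValueError` naming the offending sample.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index.name = None
    values.columns.name = None
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "tissue"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    for col in ("stage", "source"):
        if col not in meta.columns:
            meta[col] = pd.NA
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    meta = meta.set_index("sample_id")
    m = ExpressionMatrix(values, meta)
    logger.info("loaded expression matrix: %d genes x %d samples", *m.shape)
    return m


def write_expression_matrix(m: ExpressionMatrix, matrix_path, metadata_path=None) -> None:
    """Write the matrix (and optionally its metadata) as TSV."""
    m.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        m.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")
    logger.info("wrote expression matrix: %d genes x %d samples", *m.shape)


def filter_expressed(m: ExpressionMatrix, min_tpm: float = 1.0, min_samples: int = 1) -> ExpressionMatrix:
    """Keep genes with TPM strictly above ``min_tpm`` in >= ``min_samples`` samples.

    The default (TPM > 1 in at least one sample) is the detection filter used
    before any downstream screening.  The sample set is unchanged; an empty
    gene result is permitted with a warning.
    """
    if min_tpm < 0:
        raise ValueError("min_tpm must be >= 0")
    n_samples = m.shape[1]
    if not 1 <= min_samples <= n_samples:
        raise ValueError(f"min_samples must be in [1, {n_samples}]")
    keep = (m.values.to_numpy() > min_tpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    out = ExpressionMatrix(m.values.loc[keep], m.metadata)
    logger.info("filter_expressed: %d -> %d genes (min_tpm=%g, min_samples=%d)",
                m.shape[0], out.shape[0], min_tpm, min_samples)
    return out


def average_replicates(m: ExpressionMatrix, by: str = "tissue") -> TissueProfile:
    """Arithmetic mean of TPM over replicate samples per tissue (or stage).

    With ``by='stage'`` only samples carrying a stage label contribute; a
    group with zero samples is an error.
    """
    if by not in ("tissue", "stage"):
        raise ValueError("by must be 'tissue' or 'stage'")
    labels = m.metadata[by]
    if by == "stage":
        labels = labels.dropna()
        if labels.empty:
            raise ValueError("no samples carry a stage label")
    groups = labels.groupby(labels).groups
    cols = {}
    for g, samples in groups.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"group {g!r} has zero samples")
        cols[g] = m.values[samples].mean(axis=1)
    means = pd.DataFrame(cols)
    return TissueProfile(means=means, by=by)


def _pairwise_corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return np.nan, np.nan
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance column in correlation; reported as missing", stacklevel=3)
        return np.nan, np.nan
    if method == "pearson":
        r, p = _stats.pearsonr(x, y)
    else:
        r, p = _stats.spearmanr(x, y)
    return float(r), float(p)


def correlate_profiles(data, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise column correlations with two-sided p-values.

    Accepts a :class:`TissueProfile` or any DataFrame whose columns are the
    variables to correlate (e.g. a trait table).  Missing values are dropped
    pairwise; p-values come from the t-approximation on n-2 degrees of
    freedom and Spearman uses tie-corrected average ranks.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = data.means if isinstance(data, TissueProfile) else pd.DataFrame(data)
    cols = list(df.columns)
    n = len(cols)
    rho = np.eye(n)
    pvals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, p = _pairwise_corr(df[cols[i]].to_numpy(float), df[cols[j]].to_numpy(float), method)
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        pvals=pd.DataFrame(pvals, index=cols, columns=cols),
        method=method,
    )


def expressed_gene_counts(m: ExpressionMatrix, min_tpm: float = 0.0) -> pd.Series:
    """Number of genes detected (TPM > min_tpm in >= 1 replicate) per tissue."""
    counts = {}
    for tissue, samples in m.metadata.groupby("tissue").groups.items():
        sub = m.values[list(samples)]
        counts[tissue] = int(((sub > min_tpm).any(axis=1)).sum())
    return pd.Series(counts, name="n_expressed")
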