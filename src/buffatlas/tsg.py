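"""Tissue-specific and stage-specific gene calling after smooth quantile
normalization.

Smooth quantile normalization ("qsmooth") generalizes quantile
normalization to grouped designs: at each rank it blends the global
reference quantile with the group-specific quantile, weighting toward the
reference when between-group differences at that rank are small relative to
total variation.  Tissue-specific genes (TSGs) are then called on the
replicate-averaged profile by a fold rule — a gene is specific to the
tissue whose mean is at least ``fold`` (default 3) times every other
tissue's mean — and marker genes are the stricter case of exclusive
expression in a single tissue.  The same fold rule transfers to lactation
stages for stage-specific screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, TissueProfile, average_replicates

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "TsgCall",
    "qsmooth_normalize",
    "call_tsgs",
    "call_markers",
    "call_stage_specific",
    "fold_sensitivity",
]


@dataclass
class NormalizedMatrix:
    """Result of smooth quantile normalization.

    ``values`` has the shape of the input matrix; ``weights`` holds the
    per-rank blending weight in [0, 1] (1 = pure reference quantile,
    0 = pure group quantile).
    """

    values: pd.DataFrame
    group_factor: pd.Series
    weights: np.ndarray

    def as_expression_matrix(self, metadata: pd.DataFrame) -> ExpressionMatrix:
        return ExpressionMatrix(self.values, metadata)


@dataclass(frozen=True)
class TsgCall:
    gene_id: str
    tissue: str
    fold_ratio: float
    is_marker: bool = False


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with shrinking windows at the edges."""
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def qsmooth_normalize(m: ExpressionMatrix, group_factor=None, window_frac: float = 0.05) -> NormalizedMatrix:
    """Smooth quantile normalization of a gene x sample matrix.

    For each sample the values are sorted; the reference quantile at each
    rank is the across-sample mean and the group quantile is the group-wise
    mean.  The per-rank weight is the within-group share of total variance
    (median-smoothed over a window of ``window_frac`` x n_genes ranks,
    forced odd), so ranks where the groups genuinely differ lean on the
    group quantile.  Each sample's normalized sorted values are mapped back
    to its original order; tied input values receive the mean of their
    normalized values, so within-sample rank order is preserved.

    With a single group the weights are all 1 and the result is ordinary
    quantile normalization.
    """
    X = m.values.to_numpy(float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples to normalize")
    if group_factor is None:
        groups = m.metadata["tissue"]
    else:
        groups = pd.Series(group_factor, index=m.values.columns) if not isinstance(group_factor, pd.Series) else group_factor
    groups = groups.loc[m.values.columns]
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    uniq = groups.unique()
    if len(uniq) == 0:
        raise ValueError("no groups")

    order = np.argsort(X, axis=0, kind="stable")
    Xsort = np.take_along_axis(X, order, axis=0)          # rank x sample
    qref = Xsort.mean(axis=1)                              # reference quantiles
    qhat = np.empty_like(Xsort)                            # group-wise quantiles
    for g in uniq:
        cols = np.flatnonzero((groups == g).to_numpy())
        qhat[:, cols] = Xsort[:, cols].mean(axis=1, keepdims=True)

    sst = ((Xsort - qref[:, None]) ** 2).sum(axis=1)
    ssb = ((qhat - qref[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sst > 0, 1.0 - ssb / sst, 1.0)
    w = np.clip(w, 0.0, 1.0)
    window = max(1, int(window_frac * n_genes))
    if window % 2 == 0:
        window += 1
    w = np.clip(_running_median(w, window), 0.0, 1.0)

    norm_sorted = w[:, None] * qref[:, None] + (1.0 - w[:, None]) * qhat
    # rank-varying weights can locally invert the blend when group and
    # reference quantiles diverge strongly; clamp to restore monotonicity
    # along ranks so within-sample order is always preserved
    norm_sorted = np.maximum.accumulate(norm_sorted, axis=0)
    out = np.empty_like(X)
    for s in range(n_samples):
        out[order[:, s], s] = norm_sorted[:, s]
        # ties in the input share the mean of their normalized values
        col = X[:, s]
        vals, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=out[:, s])
            out[:, s] = (sums / counts)[inv]
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    logger.info("qsmooth: %d genes x %d samples, %d groups, mean weight %.3f",
                n_genes, n_samples, len(uniq), float(w.mean()))
    return NormalizedMatrix(values=values, group_factor=groups, weights=w)


def _fold_calls(means: pd.DataFrame, fold: float, min_tpm: float) -> list[TsgCall]:
    """Fold-rule specificity calls on a gene x group mean matrix."""
    M = means.to_numpy(float)
    groups = list(means.columns)
    calls: list[TsgCall] = []
    top_idx = M.argmax(axis=1)
    for i, gene in enumerate(means.index):
        t = top_idx[i]
        target = M[i, t]
        others = np.delete(M[i], t)
        max_other = others.max() if len(others) else 0.0
        if max_other == 0.0:
            if target >= min_tpm:
                calls.append(TsgCall(str(gene), str(groups[t]), np.inf))
        elif target >= fold * max_other:
            calls.append(TsgCall(str(gene), str(groups[t]), float(target / max_other)))
    return calls


def call_tsgs(p: TissueProfile, fold: float = 3.0, min_tpm: float = 1.0) -> list[TsgCall]:
    """Tissue-specific genes: mean in one tissue >= fold x every other tissue.

    Genes below ``min_tpm`` in all tissues are excluded first.  When every
    other tissue's mean is zero the fold ratio is +inf and the call is made
    provided the target tissue reaches ``min_tpm`` (so exclusive markers stay
    inside the TSG universe).  With ``fold`` > 1 a gene can be specific to at
    most one tissue.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if p.means.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    means = p.means[p.means.max(axis=1) >= min_tpm]
    calls = _fold_calls(means, fold, min_tpm)
    logger.info("call_tsgs: %d TSGs at fold %g from %d genes", len(calls), fold, len(means))
    return calls


def call_markers(p: TissueProfile, expressed_threshold: float = 1.0) -> list[TsgCall]:
    """Marker genes: expressed (>= threshold) in exactly one tissue."""
    M = p.means.to_numpy(float)
    expressed = M >= expressed_threshold
    calls = []
    for i, gene in enumerate(p.means.index):
        hits = np.flatnonzero(expressed[i])
        if len(hits) == 1:
            t = hits[0]
            others = np.delete(M[i], t)
            max_other = others.max() if len(others) else 0.0
            ratio = np.inf if max_other == 0 else float(M[i, t] / max_other)
            calls.append(TsgCall(str(gene), str(p.means.columns[t]), ratio, is_marker=True))
    return calls


def call_stage_specific(m: ExpressionMatrix, stages=("early", "peak", "mid", "late"),
                        fold: float = 3.0, min_tpm: float = 1.0) -> dict[str, list[str]]:
    """Stage-specific genes across lactation phases by the TSG fold rule.

    Stage means are computed per gene over the samples carrying each stage
    label; the fold rule then runs with stages in place of tissues.  Returns
    a mapping stage -> gene list.
    """
    present = set(m.metadata["stage"].dropna())
    missing = [s for s in stages if s not in present]
    if missing:
        raise ValueError(f"stages absent from metadata: {missing}")
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    prof = average_replicates(m, by="stage")
    means = prof.means[list(stages)]
    means = means[means.max(axis=1) >= min_tpm]
    calls = _fold_calls(means, fold, min_tpm)
    out: dict[str, list[str]] = {s: [] for s in stages}
    for c in calls:
        out[c.tissue].append(c.gene_id)
    return out


def fold_sensitivity(p: TissueProfile, folds=(3.0, 4.0, 5.0), min_tpm: float = 1.0) -> dict:
    """TSG calls at ascending fold thresholds plus pairwise retention.

    Call sets at higher folds are nested inside those at lower folds;
    ``retention[(f_low, f_high)]`` is the fraction of f_low calls kept at
    f_high.
    """
    folds = list(folds)
    if folds != sorted(folds) or any(f <= 1 for f in folds):
        raise ValueError("folds must be ascending and > 1")
    sets = {f: {(c.gene_id, c.tissue) for c in call_tsgs(p, fold=f, min_tpm=min_tpm)} for f in folds}
    retention = {}
    for i, fl in enumerate(folds):
        for fh in folds[i + 1:]:
            denom = len(sets[fl])
            retention[(fl, fh)] = len(sets[fh] & sets[fl]) / denom if denom else float("nan")
    return {"folds": folds, "calls": sets, "retention": retention}
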