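"""qPCR reference-gene stability ranking: geNorm, NormFinder, BestKeeper,
RefFinder.

All four algorithms rank a panel of candidate reference genes measured by
qPCR across tissue cDNA samples, from most to least stably expressed:

* **geNorm** scores each gene by M, the average across partners of the
  standard deviation of the pairwise log2 expression ratio; stepwise
  exclusion of the highest-M gene yields a ranking whose final two genes
  are inseparable (the ratio-based measure cannot order a pair).
* **NormFinder** fits an additive gene + sample model to log2 relative
  quantities and scores each gene by the dispersion of its residuals
  (optionally adding an intergroup term when sample groups are supplied).
* **BestKeeper** works on raw Cq values: per-gene dispersion (sample SD by
  default, mean absolute deviation as an option), percent CV, and the
  Pearson correlation of each gene with the BestKeeper index (the
  per-sample geometric mean of all genes' Cq).
* **RefFinder** aggregates the three rankings (plus geNorm's) as the
  geometric mean of each gene's ranks.

Cq (quantification cycle) is the PCR cycle at which fluorescence crosses
threshold; lower Cq means higher abundance.  Relative quantities assume a
common amplification efficiency E (default 2, i.e. perfect doubling):
Q = E^(Cq_min - Cq), so each gene's best-expressed sample has Q = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CqTable",
    "GenormResult",
    "cq_to_relative_quantity",
    "genorm",
    "normfinder",
    "bestkeeper",
    "reffinder",
    "stability_report",
]


@dataclass
class CqTable:
    """Candidate-gene x sample matrix of qPCR quantification-cycle values."""

    cq: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cq.index.has_duplicates or self.cq.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids")
        if not np.isfinite(self.cq.to_numpy(float)).all():
            raise ValueError("Cq table contains missing or non-finite values")

    @property
    def gene_ids(self) -> list:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list:
        return list(self.cq.columns)


def _as_cq_frame(cq) -> pd.DataFrame:
    return cq.cq if isinstance(cq, CqTable) else pd.DataFrame(cq)


def cq_to_relative_quantity(cq, efficiency: float = 2.0) -> pd.DataFrame:
    """Relative quantities Q = efficiency^(min Cq - Cq), per-gene max = 1."""
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    df = _as_cq_frame(cq)
    delta = df.min(axis=1).to_numpy()[:, None] - df.to_numpy(float)
    return pd.DataFrame(efficiency ** delta, index=df.index, columns=df.columns)


@dataclass
class GenormResult:
    m_values: pd.Series                 # M on the full gene set
    ranking: list = field(default_factory=list)   # most to least stable
    ranks: pd.Series = None             # 1..n by M (ties: gene id)
    exclusion_order: list = field(default_factory=list)
    pairwise_variation: pd.DataFrame = None       # V_{n/n+1} for NF_n vs NF_{n+1}


def _genorm_m(logq: pd.DataFrame) -> pd.Series:
    genes = list(logq.index)
    A = logq.to_numpy(float)
    n = len(genes)
    M = np.zeros(n)
    for j in range(n):
        sds = [np.std(A[j] - A[k], ddof=1) for k in range(n) if k != j]
        M[j] = float(np.mean(sds))
    return pd.Series(M, index=genes, name="genorm_m")


def genorm(cq, efficiency: float = 2.0) -> GenormResult:
    """geNorm stability measure M with stepwise exclusion.

    V[j,k] is the sample SD over samples of log2(Q_j / Q_k); M_j is the mean
    of V[j,k] over partners k.  The gene with the highest M is repeatedly
    excluded (ties broken by gene id); the last two genes share rank 1 in
    the stepwise ranking.  The pairwise-variation table reports
    V_{n/n+1} = SD of log2(NF_n / NF_{n+1}) for normalization factors built
    from the top n genes.
    """
    df = _as_cq_frame(cq)
    if df.shape[0] < 2:
        raise ValueError("geNorm needs >= 2 genes")
    logq = np.log2(cq_to_relative_quantity(df, efficiency))
    m_full = _genorm_m(logq)

    remaining = logq.copy()
    exclusion = []
    while remaining.shape[0] > 2:
        m = _genorm_m(remaining)
        worst = m.sort_values(kind="mergesort").index[-1]
        # deterministic tie-break: among max-M genes pick lexicographically last
        worst_m = m.max()
        cands = sorted(str(g) for g in m.index[m == worst_m])
        worst = cands[-1]
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    last_two = sorted(str(g) for g in remaining.index)
    ranking = last_two + list(reversed(exclusion))

    order = sorted(m_full.index, key=lambda g: (m_full[g], str(g)))
    ranks = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="genorm_rank")

    # pairwise variation V_{n/n+1} over the stepwise ranking
    pv = []
    for n in range(2, len(ranking)):
        nf_n = logq.loc[ranking[:n]].mean(axis=0)
        nf_n1 = logq.loc[ranking[:n + 1]].mean(axis=0)
        pv.append({"n": n, "v": float(np.std(nf_n - nf_n1, ddof=1))})
    pv_df = pd.DataFrame(pv) if pv else pd.DataFrame(columns=["n", "v"])
    return GenormResult(m_values=m_full, ranking=ranking, ranks=ranks,
                        exclusion_order=exclusion, pairwise_variation=pv_df)


def normfinder(cq, groups=None, efficiency: float = 2.0) -> pd.Series:
    """NormFinder-style stability values on log2 relative quantities.

    Ungrouped (default): fit the additive model x[g,s] = gene + sample +
    residual by two-way centering and score each gene by the sample SD of
    its residuals.  Grouped: per group, the same within-group residual SD is
    combined with the magnitude of the gene x group interaction (the
    intergroup variation of the published model):
    stability_g = mean over groups (|d_ga| + se_ga), where d_ga is the
    centered group effect for gene g and se_ga the within-group residual
    standard error.
    """
    df = _as_cq_frame(cq)
    if df.shape[0] < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    x = np.log2(cq_to_relative_quantity(df, efficiency)).to_numpy(float)
    genes = list(df.index)

    if groups is None:
        resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
        stab = resid.std(axis=1, ddof=1)
        return pd.Series(stab, index=genes, name="normfinder_stability")

    groups = pd.Series(groups, index=df.columns) if not isinstance(groups, pd.Series) else groups.loc[df.columns]
    labels = groups.unique()
    if any((groups == a).sum() < 2 for a in labels):
        raise ValueError("grouped NormFinder needs >= 2 samples per group")
    gene_mean = x.mean(axis=1, keepdims=True)
    grand = x.mean()
    stab = np.zeros(len(genes))
    for a in labels:
        cols = np.flatnonzero((groups == a).to_numpy())
        xa = x[:, cols]
        na = len(cols)
        # gene x group interaction: group-gene mean minus gene and group effects
        d = xa.mean(axis=1) - gene_mean[:, 0] - xa.mean() + grand
        resid = xa - xa.mean(axis=1, keepdims=True) - xa.mean(axis=0, keepdims=True) + xa.mean()
        se = resid.std(axis=1, ddof=1) / np.sqrt(na)
        stab += np.abs(d) + se
    return pd.Series(stab / len(labels), index=genes, name="normfinder_stability")


def bestkeeper(cq, dispersion: str = "sd") -> pd.DataFrame:
    """BestKeeper descriptive stability on raw Cq values.

    Returns per gene: ``sd`` (sample SD of Cq, or mean absolute deviation
    with ``dispersion='mad'``), ``cv_pct`` (100 x dispersion / mean Cq) and
    ``r`` (Pearson correlation with the BestKeeper index, the per-sample
    geometric mean of all genes' Cq).  Genes rank by ascending dispersion.
    The index is attached as ``result.attrs['index']``.
    """
    if dispersion not in ("sd", "mad"):
        raise ValueError("dispersion must be 'sd' or 'mad'")
    df = _as_cq_frame(cq)
    if df.shape[0] < 1:
        raise ValueError("empty Cq table")
    A = df.to_numpy(float)
    if dispersion == "sd":
        disp = A.std(axis=1, ddof=1)
    else:
        disp = np.abs(A - A.mean(axis=1, keepdims=True)).mean(axis=1)
    cv_pct = 100.0 * disp / A.mean(axis=1)
    index = np.exp(np.log(A).mean(axis=0))  # per-sample geometric mean of Cq
    r = np.ones(len(df))
    if df.shape[0] > 1 and np.std(index) > 0:
        for i in range(len(df)):
            gi = A[i]
            r[i] = np.corrcoef(gi, index)[0, 1] if np.std(gi) > 0 else np.nan
    out = pd.DataFrame({"sd": disp, "cv_pct": cv_pct, "r": r}, index=df.index)
    out.attrs["index"] = pd.Series(index, index=df.columns, name="bestkeeper_index")
    return out


def _rank_ascending(scores: pd.Series) -> pd.Series:
    """Ranks 1..n by ascending score, deterministic gene-id tie-break."""
    order = sorted(scores.index, key=lambda g: (scores[g], str(g)))
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype=int)


def reffinder(rank_lists: dict[str, pd.Series]) -> pd.DataFrame:
    """Aggregate per-algorithm rankings by the geometric mean of ranks.

    Each entry of ``rank_lists`` must be a permutation of 1..n over the same
    gene set.  The final ranking ascends by geometric mean; ties break by
    the gene's best single-algorithm rank, then gene id.
    """
    frames = list(rank_lists.values())
    genes = set(frames[0].index)
    n = len(genes)
    for s in frames:
        if set(s.index) != genes:
            raise ValueError("rank vectors cover different gene sets")
        if sorted(s.values) != list(range(1, n + 1)):
            raise ValueError("rank vector is not a permutation of 1..n")
    R = pd.DataFrame(rank_lists)
    geo = R.prod(axis=1) ** (1.0 / R.shape[1])
    best = R.min(axis=1)
    order = sorted(geo.index, key=lambda g: (geo[g], best[g], str(g)))
    final = pd.Series({g: i + 1 for i, g in enumerate(order)}, dtype=int)
    out = pd.DataFrame({"reffinder_geomean": geo, "final_rank": final.loc[geo.index]})
    return out


def stability_report(cq, efficiency: float = 2.0, groups=None,
                     bestkeeper_dispersion: str = "sd") -> pd.DataFrame:
    """Run all four algorithms and aggregate with RefFinder.

    Returns one row per candidate gene with each algorithm's stability
    measure and rank plus the RefFinder geometric mean and final rank.
    """
    table = cq if isinstance(cq, CqTable) else CqTable(_as_cq_frame(cq))
    df = table.cq
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise ValueError("stability ranking needs >= 3 genes and >= 3 samples")
    gn = genorm(table, efficiency)
    nf = normfinder(table, groups=groups, efficiency=efficiency)
    bk = bestkeeper(table, dispersion=bestkeeper_dispersion)
    ranks = {
        "genorm": gn.ranks,
        "normfinder": _rank_ascending(nf),
        "bestkeeper": _rank_ascending(bk["sd"]),
    }
    # RefFinder aggregates four rankings; the fourth is the comparative
    # delta-Ct method (mean over partners of the SD of pairwise Cq
    # differences), computed on raw Cq values.
    A = df.to_numpy(float)
    dct = pd.Series(
        [np.mean([np.std(A[j] - A[k], ddof=1) for k in range(len(df)) if k != j])
         for j in range(len(df))],
        index=df.index, name="delta_ct",
    )
    ranks["delta_ct"] = _rank_ascending(dct)
    rf = reffinder(ranks)
    report = pd.DataFrame({
        "genorm_m": gn.m_values,
        "genorm_rank": ranks["genorm"],
        "normfinder_stability": nf,
        "normfinder_rank": ranks["normfinder"],
        "bestkeeper_sd": bk["sd"],
        "bestkeeper_r": bk["r"],
        "bestkeeper_rank": ranks["bestkeeper"],
        "reffinder_geomean": rf["reffinder_geomean"],
        "final_rank": rf["final_rank"],
    })
    logger.info("stability_report: %d genes ranked; best = %s",
                len(report), report["final_rank"].idxmin())
    return report.sort_values("final_rank")
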