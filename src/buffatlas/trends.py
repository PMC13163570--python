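"""Fuzzy c-means clustering of lactation-stage expression trends.

Genes' per-stage mean expression profiles are z-scored (so only the shape
of the trajectory matters) and grouped by fuzzy c-means: soft clustering
that minimizes sum_{g,k} u_{gk}^m ||z_g - v_k||^2 subject to each gene's
memberships summing to 1, with fuzzifier m > 1 controlling how soft the
partition is.  Cluster centroids are then matched against a lactation-trait
trajectory (e.g. milk yield across stages) by Pearson correlation to find
the cluster whose expression trend tracks the trait.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TrendClustering", "standardize_stage_profiles", "fuzzy_cmeans", "match_trait_trend"]


@dataclass
class TrendClustering:
    memberships: pd.DataFrame      # gene x cluster, rows sum to 1
    centroids: pd.DataFrame        # cluster x stage (z-score units)
    objective: float
    objective_trace: list
    n_iter: int
    fuzzifier: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def hard_assignments(self) -> pd.Series:
        """Cluster of maximal membership per gene; ties go to the lower index."""
        return pd.Series(self.memberships.to_numpy().argmax(axis=1),
                         index=self.memberships.index, name="cluster")


def standardize_stage_profiles(stage_means: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each gene's stage profile (row mean 0, SD 1).

    Rows with zero SD (flat profiles) carry no trend information and are
    dropped with a warning.
    """
    if stage_means.shape[1] < 2:
        raise ValueError("need >= 2 stages")
    sd = stage_means.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} constant-profile genes", stacklevel=2)
        stage_means = stage_means.loc[~flat]
        sd = sd[~flat]
    z = stage_means.sub(stage_means.mean(axis=1), axis=0).div(sd, axis=0)
    return z


def fuzzy_cmeans(z: pd.DataFrame, c: int, m: float = 2.0, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 300) -> TrendClustering:
    """Fuzzy c-means by alternating optimization from a seeded random start.

    Memberships are initialized uniformly at random (rows normalized to 1);
    each iteration recomputes centroids as membership^m-weighted means and
    memberships from inverse-distance ratios.  Converged when the largest
    membership change falls below ``tol``.  A point coinciding with one or
    more centroids gets its membership split evenly among them.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    n, p = z.shape
    if c > n:
        raise ValueError("more clusters than genes")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = z.to_numpy(float)
    cluster_ids = [f"cluster_{k + 1}" for k in range(c)]

    if c == 1:
        U = np.ones((n, 1))
        V = X.mean(axis=0, keepdims=True)
        obj = float((((X - V) ** 2).sum(axis=1)).sum())
        return TrendClustering(
            memberships=pd.DataFrame(U, index=z.index, columns=cluster_ids),
            centroids=pd.DataFrame(V, index=cluster_ids, columns=z.columns),
            objective=obj, objective_trace=[obj], n_iter=0, fuzzifier=m, seed=seed,
        )

    rng = np.random.default_rng(seed)
    U = rng.random((n, c))
    U /= U.sum(axis=1, keepdims=True)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Um = U ** m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((Um * d2).sum()))
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            inv = (1.0 / d2) ** (1.0 / (m - 1.0))
        U_new = np.where(zero.any(axis=1, keepdims=True),
                         zero / np.maximum(zero.sum(axis=1, keepdims=True), 1),
                         inv / inv.sum(axis=1, keepdims=True))
        shift = float(np.abs(U_new - U).max())
        U = U_new
        if shift < tol:
            break
    Um = U ** m
    V = (Um.T @ X) / Um.sum(axis=0)[:, None]
    d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
    trace.append(float((Um * d2).sum()))
    logger.info("fuzzy_cmeans: c=%d m=%g converged in %d iters, objective %.4g",
                c, m, n_iter, trace[-1])
    return TrendClustering(
        memberships=pd.DataFrame(U, index=z.index, columns=cluster_ids),
        centroids=pd.DataFrame(V, index=cluster_ids, columns=z.columns),
        objective=trace[-1], objective_trace=trace, n_iter=n_iter, fuzzifier=m, seed=seed,
    )


def match_trait_trend(tc: TrendClustering, trait) -> dict:
    """Match cluster centroids to a per-stage trait trajectory.

    The trait vector is z-scored and each centroid's Pearson correlation
    with it is computed; the best-matching cluster is the argmax.  Returns
    the best cluster id, per-cluster correlations, and hard cluster sizes.
    """
    trait = np.asarray(trait, float)
    if len(trait) != tc.centroids.shape[1]:
        raise ValueError("trait vector length must equal the number of stages")
    if np.std(trait) == 0:
        raise ValueError("constant trait vector")
    tz = (trait - trait.mean()) / trait.std()
    corr = {}
    for cid, centroid in tc.centroids.iterrows():
        v = centroid.to_numpy()
        corr[cid] = float(np.corrcoef(v, tz)[0, 1]) if np.std(v) > 0 else np.nan
    corr_s = pd.Series(corr, name="trait_correlation")
    best = corr_s.idxmax()
    sizes = tc.hard_assignments().value_counts().sort_index()
    return {"best_cluster": best, "correlations": corr_s,
            "cluster_sizes": {tc.centroids.index[k]: int(v) for k, v in sizes.items()}}
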