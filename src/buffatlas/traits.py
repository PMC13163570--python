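"""Lactation-trait tables: stage representatives, Spearman correlations,
pairwise stage comparisons.

A trait table records, per animal and day of lactation, daily milk yield
(kg/day) and milk composition (protein, fat and lactose as percentages).
Stage-representative days — 7 (early), 85 (peak), 145 (mid), 285 (late) —
summarize the lactation curve; Spearman rank correlation across all time
points quantifies the dilution effect (yield vs. solids concentrations);
Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment compare traits
between stages.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .expression import CorrelationMatrix, correlate_profiles

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["milk_yield", "protein_pct", "fat_pct", "lactose_pct"]
DEFAULT_STAGE_DAYS = {"early": 7, "peak": 85, "mid": 145, "late": 285}

__all__ = [
    "TRAIT_COLUMNS",
    "DEFAULT_STAGE_DAYS",
    "load_trait_table",
    "validate_trait_table",
    "stage_representatives",
    "stage_observations",
    "trait_correlations",
    "pairwise_stage_tests",
    "significance_stars",
]


def validate_trait_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ["day"] + TRAIT_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if not np.isfinite(t[TRAIT_COLUMNS + ["day"]].to_numpy(float)).all():
        raise ValueError("trait table contains non-finite values")
    if (t["day"] < 1).any():
        raise ValueError("days must be >= 1")
    for c in ("protein_pct", "fat_pct", "lactose_pct"):
        if ((t[c] < 0) | (t[c] > 100)).any():
            raise ValueError(f"{c} outside [0, 100]")
    if (t["milk_yield"] < 0).any():
        raise ValueError("negative milk yield")
    return t


def load_trait_table(path) -> pd.DataFrame:
    """Read a CSV trait table (day, milk_yield, protein_pct, fat_pct, lactose_pct [, animal_id])."""
    t = pd.read_csv(path)
    return validate_trait_table(t)


def stage_observations(t: pd.DataFrame, stage_days: dict | None = None,
                       window: int = 5) -> dict[str, pd.DataFrame]:
    """Per-stage observations: for each animal, the record nearest the
    stage-representative day (within +/- ``window`` days)."""
    stage_days = stage_days or DEFAULT_STAGE_DAYS
    t = validate_trait_table(pd.DataFrame(t))
    if "animal_id" not in t.columns:
        t = t.assign(animal_id="animal_1")
    out = {}
    for stage, day in stage_days.items():
        rows = []
        for animal, sub in t.groupby("animal_id"):
            dist = (sub["day"] - day).abs()
            if dist.min() <= window:
                rows.append(sub.loc[dist.idxmin()])
        if not rows:
            raise ValueError(f"no record within {window} days of day {day} for stage {stage!r}")
        out[stage] = pd.DataFrame(rows)
    return out


def stage_representatives(t: pd.DataFrame, stage_days: dict | None = None,
                          window: int = 5) -> pd.DataFrame:
    """Per-stage mean of each trait across animals at the representative day."""
    obs = stage_observations(t, stage_days, window)
    return pd.DataFrame({stage: sub[TRAIT_COLUMNS].mean() for stage, sub in obs.items()}).T


def trait_correlations(t: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlations among the four traits across all time points."""
    t = validate_trait_table(pd.DataFrame(t))
    if len(t) < 3:
        raise ValueError("need >= 3 records")
    return correlate_profiles(t[TRAIT_COLUMNS], method="spearman")


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0  # identical values: no evidence of a difference
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def pairwise_stage_tests(t: pd.DataFrame, trait: str = "milk_yield",
                         stage_days: dict | None = None, window: int = 5,
                         test: str = "ranksum") -> pd.DataFrame:
    """Two-sided stage-pair comparisons of one trait with BH adjustment.

    Default test is the Wilcoxon rank-sum (Mann-Whitney); ``test='ttest'``
    switches to Welch's t.  Stages with fewer than two observations are
    skipped with a warning; p-values are Benjamini-Hochberg adjusted across
    the tested pairs and annotated with the star scheme
    (*** p<0.001, * p<0.05, ns otherwise).
    """
    if trait not in TRAIT_COLUMNS:
        raise ValueError(f"unknown trait {trait!r}")
    if test not in ("ranksum", "ttest"):
        raise ValueError("test must be 'ranksum' or 'ttest'")
    obs = stage_observations(t, stage_days, window)
    rows = []
    for s1, s2 in combinations(obs.keys(), 2):
        a = obs[s1][trait].to_numpy(float)
        b = obs[s2][trait].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"skipping pair ({s1}, {s2}): a stage has < 2 observations",
                          stacklevel=2)
            continue
        if test == "ranksum":
            stat, p = _rank_sum_p(a, b)
        else:
            stat, p = _stats.ttest_ind(a, b, equal_var=False)
        rows.append({"stage_a": s1, "stage_b": s2, "statistic": float(stat), "pvalue": float(p)})
    result = pd.DataFrame(rows)
    if len(result):
        result["pvalue_adj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
        result["significance"] = result["pvalue_adj"].map(significance_stars)
    logger.info("pairwise_stage_tests(%s): %d pairs tested", trait, len(result))
    return result


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"
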