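"""Housekeeping-gene screening by coefficient-of-variation quartiles.

Candidate housekeeping genes (HKGs) are genes with mean TPM > 1 across
tissues.  Each candidate's coefficient of variation (CV = SD / mean of its
tissue-level means) is computed and the CV distribution is split at its
quartiles: low variability (CV <= Q1), medium (Q1 < CV < Q3), high
(CV >= Q3).  Crossing the low-variability group with expression-abundance
bins (1 < TPM <= 10, 10 < TPM <= 50, TPM > 50) yields the core HKG set:
low CV and mean TPM above a high-expression threshold (default 50), with
robustness rescreening at stricter thresholds (70, 100).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .expression import TissueProfile

logger = logging.getLogger(__name__)

__all__ = [
    "compute_cv",
    "classify_variability",
    "select_core_hkgs",
    "rank_top_stable",
    "threshold_robustness",
]


def compute_cv(profile: TissueProfile, min_mean_tpm: float = 1.0, ddof: int = 1) -> pd.DataFrame:
    """Per-gene mean TPM and coefficient of variation over tissue means.

    Genes at or below ``min_mean_tpm`` (default 1, the candidate-HKG
    pre-filter) are excluded first.  CV uses the sample (n-1) standard
    deviation by default; ``ddof=0`` gives the population variant.
    """
    means = profile.means
    if means.shape[1] < 2:
        raise ValueError("need >= 2 tissues to compute a CV")
    mean_tpm = means.mean(axis=1)
    kept = mean_tpm > min_mean_tpm
    means = means.loc[kept]
    mean_tpm = mean_tpm[kept]
    if (mean_tpm == 0).any():
        raise ValueError("zero mean expression after filtering")
    sd = means.std(axis=1, ddof=ddof)
    stats = pd.DataFrame({"mean_tpm": mean_tpm, "cv": sd / mean_tpm})
    logger.info("compute_cv: %d candidate genes (mean TPM > %g)", len(stats), min_mean_tpm)
    return stats


def _expression_bin(mean_tpm: float) -> str:
    if mean_tpm > 50:
        return "high"
    if mean_tpm > 10:
        return "medium"
    return "low"


def classify_variability(stats: pd.DataFrame) -> pd.DataFrame:
    """Assign variability groups by CV quartiles and expression bins by mean TPM.

    Quartiles are computed by linear interpolation (numpy's default, type-7).
    Group rule: low iff CV <= Q1, high iff CV >= Q3, medium otherwise; when
    Q1 == Q3 a CV sitting on both boundaries is resolved low before high.
    Adds columns ``variability_group``, ``expression_bin`` and ``is_core``
    (low variability AND TPM > 50).
    """
    if len(stats) < 4:
        raise ValueError("need >= 4 genes for quartile classification")
    cv = stats["cv"].to_numpy(float)
    q1, q3 = np.quantile(cv, [0.25, 0.75])
    group = np.where(cv <= q1, "low", np.where(cv >= q3, "high", "medium"))
    out = stats.copy()
    out["variability_group"] = group
    out["expression_bin"] = out["mean_tpm"].map(_expression_bin)
    out["is_core"] = (out["variability_group"] == "low") & (out["expression_bin"] == "high")
    logger.info(
        "classify_variability: Q1=%.4g Q3=%.4g; low=%d medium=%d high=%d; core=%d",
        q1, q3, (group == "low").sum(), (group == "medium").sum(),
        (group == "high").sum(), int(out["is_core"].sum()),
    )
    return out


def select_core_hkgs(classes: pd.DataFrame, expr_threshold: float = 50.0) -> list:
    """Genes with low variability and mean TPM above ``expr_threshold``.

    Raising the threshold can only shrink the set, so selections at 50, 70
    and 100 are nested — the robustness rescreen exploits this.
    """
    sel = classes[(classes["variability_group"] == "low") & (classes["mean_tpm"] > expr_threshold)]
    return list(sel.index)


def threshold_robustness(classes: pd.DataFrame, thresholds=(50.0, 70.0, 100.0)) -> dict:
    """Core-HKG sets at successively stricter high-expression thresholds."""
    return {t: select_core_hkgs(classes, t) for t in thresholds}


def rank_top_stable(classes: pd.DataFrame, n: int) -> list:
    """Top ``n`` core HKGs by ascending CV.

    Ties break by descending mean TPM, then lexicographic gene id.  If fewer
    than ``n`` core HKGs exist, all are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    core = classes[classes["is_core"]].copy()
    # index is the gene id; lexicographic tie-break on it after cv and mean_tpm
    core = core.assign(_gid=core.index.astype(str)).sort_values(
        by=["cv", "mean_tpm", "_gid"], ascending=[True, False, True], kind="mergesort"
    )
    if n > len(core):
        warnings.warn(f"requested top {n} but only {len(core)} core HKGs exist", stacklevel=2)
        n = len(core)
    return list(core.index[:n])
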