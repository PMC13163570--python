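"""Seeded synthetic-data generators with planted ground truth.

Three generators stand in for the study's measured data so every pipeline
stage can be exercised and scored against known truth:

* :func:`simulate_atlas` — a multi-tissue TPM atlas (default 20 tissues,
  2-4 replicates each) with planted housekeeping genes (low cross-tissue
  CV, high expression), fold-enriched tissue-specific genes, exclusive
  markers, and lactation-stage-specific genes in the mammary samples, over
  a log-normal background with tissue-level heterogeneity and
  multiplicative replicate noise.
* :func:`simulate_cq` — a qPCR Cq table whose genes differ only in their
  per-gene technical noise SD (plus shared per-sample offsets), so the
  true stability order is the ascending noise order.
* :func:`simulate_lactation` — per-animal lactation trajectories following
  a rise / plateau / decline yield curve with composition traits coupled
  to yield through a tunable dilution effect, plus a companion stage
  expression matrix containing one gene cluster that tracks the yield
  curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .stability import CqTable
from .traits import TRAIT_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = [
    "mammary", "liver", "rumen", "duodenum", "muscle", "heart", "lung",
    "kidney", "spleen", "brain", "skin", "ovary", "uterus", "jejunum",
    "ileum", "abomasum", "adipose", "lymph_node", "pituitary", "tongue",
]
LACTATION_STAGES = ["early", "peak", "mid", "late"]

# milk sampling schedule: dense during the first 25 days, then every 10 days
DEFAULT_SAMPLING_DAYS = [1, 2, 3, 4, 5, 6, 7, 11, 18, 25] + list(range(35, 305, 10))

__all__ = [
    "AtlasTruth", "CqTruth", "DEFAULT_TISSUES", "LACTATION_STAGES",
    "DEFAULT_SAMPLING_DAYS", "simulate_atlas", "simulate_cq", "simulate_lactation",
]


@dataclass
class AtlasTruth:
    planted_hkg: set = field(default_factory=set)
    planted_tsg: dict = field(default_factory=dict)      # gene -> tissue
    planted_marker: dict = field(default_factory=dict)   # gene -> tissue
    planted_stage: dict = field(default_factory=dict)    # gene -> stage
    background: set = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "class": "hkg", "target": ""} for g in sorted(self.planted_hkg)]
        rows += [{"gene_id": g, "class": "tsg", "target": t} for g, t in sorted(self.planted_tsg.items())]
        rows += [{"gene_id": g, "class": "marker", "target": t} for g, t in sorted(self.planted_marker.items())]
        rows += [{"gene_id": g, "class": "stage", "target": s} for g, s in sorted(self.planted_stage.items())]
        rows += [{"gene_id": g, "class": "background", "target": ""} for g in sorted(self.background)]
        return pd.DataFrame(rows)


@dataclass
class CqTruth:
    noise_sd: pd.Series            # per-gene noise SD (cycles)
    sample_offset: pd.Series       # per-sample offset (cycles)

    @property
    def stability_order(self) -> list:
        return list(self.noise_sd.sort_values(kind="mergesort").index)


def simulate_atlas(n_genes: int = 5000, tissues=None, reps_range=(2, 4),
                   hkg_frac: float = 0.10, tsg_frac: float = 0.10,
                   marker_frac: float = 0.005, stage_frac: float = 0.02,
                   tsg_fold: float = 8.0, stage_fold: float = 8.0,
                   replicate_log_sd: float = 0.2, tissue_log_sd: float = 0.5,
                   bg_median_tpm: float = 3.0, bg_log_sd: float = 1.2,
                   seed: int = 0) -> tuple[ExpressionMatrix, AtlasTruth]:
    """Simulate a multi-tissue TPM atlas with planted gene classes.

    Background genes get log-normal baselines (median TPM ~= 3, log-sd 1.2)
    with tissue-level multiplicative heterogeneity (log-sd
    ``tissue_log_sd``), making their cross-tissue CV sit well above planted
    housekeeping genes' (log-sd 0.03).  Planted classes:

    * HKGs: baseline uniform in [60, 500] TPM, near-zero tissue
      heterogeneity — low CV and mean TPM > 50 by construction.
    * TSGs: one tissue's mean is ``tsg_fold`` x the basal level.
    * markers: 5-50 TPM in exactly one tissue, zero elsewhere.
    * stage genes: elevated ``stage_fold`` x in one lactation stage of the
      mammary samples (the mammary tissue carries one replicate set per
      stage; other tissues have 2-4 unstaged replicates).

    The four planted sets are disjoint.  Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    tissues = list(tissues) if tissues is not None else list(DEFAULT_TISSUES)
    fracs = (hkg_frac, tsg_frac, marker_frac, stage_frac)
    if any(f < 0 for f in fracs) or sum(fracs) > 1:
        raise ValueError("planted fractions must be non-negative and sum to <= 1")
    lo, hi = reps_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid replicate range")

    n_hkg = int(round(hkg_frac * n_genes))
    n_tsg = int(round(tsg_frac * n_genes))
    n_marker = int(round(marker_frac * n_genes))
    n_stage = int(round(stage_frac * n_genes))
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    idx = rng.permutation(n_genes)
    hkg_idx = idx[:n_hkg]
    tsg_idx = idx[n_hkg:n_hkg + n_tsg]
    marker_idx = idx[n_hkg + n_tsg:n_hkg + n_tsg + n_marker]
    stage_idx = idx[n_hkg + n_tsg + n_marker:n_hkg + n_tsg + n_marker + n_stage]
    bg_idx = idx[n_hkg + n_tsg + n_marker + n_stage:]

    # samples: mammary has one replicate pair per lactation stage; others 2-4 reps
    sample_ids, sample_tissue, sample_stage = [], [], []
    for t in tissues:
        if t == "mammary":
            for s in LACTATION_STAGES:
                for r in range(2):
                    sample_ids.append(f"{t}_{s}_r{r + 1}")
                    sample_tissue.append(t)
                    sample_stage.append(s)
        else:
            for r in range(int(rng.integers(lo, hi + 1))):
                sample_ids.append(f"{t}_r{r + 1}")
                sample_tissue.append(t)
                sample_stage.append(None)
    n_samples = len(sample_ids)
    tissue_arr = np.array(sample_tissue)
    stage_arr = np.array([s if s is not None else "" for s in sample_stage])

    # per-gene per-tissue mean TPM
    mean_tpm = np.zeros((n_genes, len(tissues)))
    baseline = np.exp(rng.normal(np.log(bg_median_tpm), bg_log_sd, n_genes))
    for j, t in enumerate(tissues):
        tissue_eff = np.exp(rng.normal(0.0, tissue_log_sd, n_genes))
        mean_tpm[:, j] = baseline * tissue_eff
    # planted HKGs: high, flat expression
    hkg_base = rng.uniform(60.0, 500.0, n_hkg)
    mean_tpm[hkg_idx, :] = hkg_base[:, None] * np.exp(
        rng.normal(0.0, 0.03, (n_hkg, len(tissues))))
    # planted TSGs: basal level everywhere, one enriched tissue
    tsg_tissue = rng.integers(0, len(tissues), n_tsg)
    tsg_base = np.exp(rng.normal(np.log(5.0), 0.5, n_tsg))
    mean_tpm[tsg_idx, :] = tsg_base[:, None] * np.exp(
        rng.normal(0.0, 0.1, (n_tsg, len(tissues))))
    mean_tpm[tsg_idx, tsg_tissue] = tsg_base * tsg_fold
    # markers: expressed in exactly one tissue
    marker_tissue = rng.integers(0, len(tissues), n_marker)
    mean_tpm[marker_idx, :] = 0.0
    mean_tpm[marker_idx, marker_tissue] = rng.uniform(5.0, 50.0, n_marker)
    # stage genes: moderate, near-flat expression across tissues; their stage
    # modulation is applied to the mammary replicates below
    stage_basal = np.exp(rng.normal(np.log(5.0), 0.5, n_stage))
    mean_tpm[stage_idx, :] = stage_basal[:, None] * np.exp(
        rng.normal(0.0, 0.1, (n_stage, len(tissues))))

    # expand to replicates with multiplicative log-normal noise
    tissue_col = {t: j for j, t in enumerate(tissues)}
    col_of = np.array([tissue_col[t] for t in sample_tissue])
    X = mean_tpm[:, col_of] * np.exp(rng.normal(0.0, replicate_log_sd, (n_genes, n_samples)))

    # stage-specific genes: one lactation stage enriched in the mammary samples
    stage_gene_stage = rng.integers(0, len(LACTATION_STAGES), n_stage)
    mam_cols = np.flatnonzero(tissue_arr == "mammary")
    for k in range(n_stage):
        g = stage_idx[k]
        target = LACTATION_STAGES[stage_gene_stage[k]]
        for c in mam_cols:
            level = stage_basal[k] * (stage_fold if stage_arr[c] == target else 1.0)
            X[g, c] = level * np.exp(rng.normal(0.0, replicate_log_sd))

    values = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    metadata = pd.DataFrame({
        "tissue": sample_tissue,
        "stage": [s if s else pd.NA for s in stage_arr],
        "source": "synthetic",
    }, index=pd.Index(sample_ids, name="sample_id"))
    truth = AtlasTruth(
        planted_hkg={gene_ids[i] for i in hkg_idx},
        planted_tsg={gene_ids[tsg_idx[k]]: tissues[tsg_tissue[k]] for k in range(n_tsg)},
        planted_marker={gene_ids[marker_idx[k]]: tissues[marker_tissue[k]] for k in range(n_marker)},
        planted_stage={gene_ids[stage_idx[k]]: LACTATION_STAGES[stage_gene_stage[k]] for k in range(n_stage)},
        background={gene_ids[i] for i in bg_idx},
    )
    logger.info("simulate_atlas: %d genes x %d samples (%d tissues); planted %d/%d/%d/%d",
                n_genes, n_samples, len(tissues), n_hkg, n_tsg, n_marker, n_stage)
    return ExpressionMatrix(values, metadata), truth


def simulate_cq(n_genes: int = 6, n_samples: int = 5, noise_sds=None,
                sample_offset_sd: float = 0.2, seed: int = 0) -> tuple[CqTable, CqTruth]:
    """Simulate a qPCR Cq table with planted per-gene noise levels.

    Cq[g, s] = gene baseline + sample offset_s + Normal(0, noise_sd_g).
    Sample offsets model shared cDNA-input differences; geNorm and
    NormFinder cancel them exactly, while BestKeeper (raw-Cq dispersion)
    does not, so the default offset SD models well-normalized cDNA input
    (0.2 cycles).  Per-gene noise determines the true stability order.
    """
    if noise_sds is None:
        noise_sds = np.linspace(0.05, 1.0, n_genes)
    noise_sds = np.asarray(noise_sds, float)
    if len(noise_sds) != n_genes:
        raise ValueError("noise_sds length must equal n_genes")
    if (noise_sds < 0).any():
        raise ValueError("negative noise SD")
    rng = np.random.default_rng(seed)
    gene_ids = [f"REF{g + 1}" for g in range(n_genes)]
    sample_ids = [f"S{s + 1}" for s in range(n_samples)]
    baseline = rng.uniform(18.0, 30.0, n_genes)
    offsets = rng.normal(0.0, sample_offset_sd, n_samples)
    cq = baseline[:, None] + offsets[None, :] + rng.normal(0.0, 1.0, (n_genes, n_samples)) * noise_sds[:, None]
    table = CqTable(pd.DataFrame(cq, index=gene_ids, columns=sample_ids))
    truth = CqTruth(
        noise_sd=pd.Series(noise_sds, index=gene_ids, name="noise_sd"),
        sample_offset=pd.Series(offsets, index=sample_ids, name="offset"),
    )
    return table, truth


def _yield_curve(day: np.ndarray, peak_yield: float = 10.0, late_yield: float = 4.42) -> np.ndarray:
    """Rise / plateau / decline lactation curve (kg/day).

    Wood-type rise reaching ``peak_yield`` by day ~35, a plateau through
    day ~115, then exponential decline to ``late_yield`` at day 285.
    """
    day = np.asarray(day, float)
    rise = peak_yield * (1.0 - np.exp(-day / 8.0))
    decline_rate = np.log(peak_yield / late_yield) / (285.0 - 115.0)
    decline = peak_yield * np.exp(-decline_rate * np.maximum(day - 115.0, 0.0))
    return np.where(day <= 115.0, rise, decline)


def simulate_lactation(n_animals: int = 6, days=None, peak_yield: float = 10.0,
                       late_yield: float = 4.42, dilution_strength: float = 0.9,
                       n_genes: int = 200, seed: int = 0):
    """Simulate lactation trait trajectories and a stage expression matrix.

    Milk yield follows the rise-plateau-decline curve with animal-level and
    day-level multiplicative noise.  Composition traits couple to the
    (standardized) yield with strength ``dilution_strength`` in [0, 1]:
    protein and fat negatively (the dilution effect), lactose positively
    (osmotic driver); at strength 0 the traits are independent noise.

    Returns ``(trait_table, stage_matrix, truth)`` where ``stage_matrix``
    is an :class:`ExpressionMatrix` of mammary samples across the four
    lactation stages containing one planted gene cluster whose stage
    profile tracks the yield curve, and ``truth`` maps genes to their
    planted trend ('yield_like', 'inverse', 'flat').
    """
    if not 0.0 <= dilution_strength <= 1.0:
        raise ValueError("dilution_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    days = np.asarray(days if days is not None else DEFAULT_SAMPLING_DAYS, int)

    base = {"protein_pct": 4.5, "fat_pct": 7.5, "lactose_pct": 5.0}
    coupling = {"protein_pct": -0.6, "fat_pct": -0.9, "lactose_pct": 0.35}
    curve = _yield_curve(days, peak_yield, late_yield)
    frames = []
    for a in range(n_animals):
        animal_scale = np.exp(rng.normal(0.0, 0.08))
        y = curve * animal_scale * np.exp(rng.normal(0.0, 0.05, len(days)))
        yz = (y - y.mean()) / y.std()
        data = {"animal_id": f"B{a + 1}", "day": days, "milk_yield": y}
        for c, slope in coupling.items():
            noise_sd = 0.45 if c == "fat_pct" else 0.25
            vals = (base[c] + dilution_strength * slope * yz
                    + rng.normal(0.0, noise_sd * (1.0 - 0.6 * dilution_strength), len(days)))
            data[c] = np.clip(vals, 0.1, 100.0)
        frames.append(pd.DataFrame(data))
    trait_table = pd.concat(frames, ignore_index=True)[["animal_id", "day"] + TRAIT_COLUMNS]

    # companion mammary stage expression: one cluster tracks the yield curve
    stage_days = np.array([7, 85, 145, 285])
    stage_yield = _yield_curve(stage_days, peak_yield, late_yield)
    yz = (stage_yield - stage_yield.mean()) / stage_yield.std()
    n_like = n_genes // 4
    n_inv = n_genes // 4
    trends = (["yield_like"] * n_like + ["inverse"] * n_inv
              + ["flat"] * (n_genes - n_like - n_inv))
    gene_ids = [f"MG{i:04d}" for i in range(n_genes)]
    reps = 2
    cols, tissue, stage = [], [], []
    for s in LACTATION_STAGES:
        for r in range(reps):
            cols.append(f"mammary_{s}_r{r + 1}")
            tissue.append("mammary")
            stage.append(s)
    X = np.zeros((n_genes, len(cols)))
    base_expr = np.exp(rng.normal(np.log(20.0), 0.5, n_genes))
    for i, tr in enumerate(trends):
        shape = {"yield_like": yz, "inverse": -yz, "flat": np.zeros(4)}[tr]
        profile = base_expr[i] * np.exp(0.8 * shape)
        for j in range(len(cols)):
            s_idx = LACTATION_STAGES.index(stage[j])
            X[i, j] = profile[s_idx] * np.exp(rng.normal(0.0, 0.15))
    stage_matrix = ExpressionMatrix(
        pd.DataFrame(X, index=gene_ids, columns=cols),
        pd.DataFrame({"tissue": tissue, "stage": stage, "source": "synthetic"},
                     index=pd.Index(cols, name="sample_id")),
    )
    truth = pd.Series(trends, index=gene_ids, name="planted_trend")
    logger.info("simulate_lactation: %d animals x %d days; %d stage genes",
                n_animals, len(days), n_genes)
    return trait_table, stage_matrix, truth
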