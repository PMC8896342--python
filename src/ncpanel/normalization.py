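"""Three-stage normalization for targeted counting panels.

Stage 1 — background: per sample, a detection threshold is set at the mean
of the negative-control probes plus ``k`` standard deviations (default 2).
The threshold drives detectability only; counts are never background
subtracted, but sub-threshold values are floored at the sample threshold so
that downstream geometric means and log-ratios stay finite.

Stage 2 — technical: per-sample positive-control factors correct for
hybridization/lane efficiency.  With ``G_s`` the geometric mean of sample
``s``'s positive-control counts, the factor is ``f_s = mean_s(G) / G_s`` and
every count of sample ``s`` is multiplied by ``f_s``.

Stage 3 — content: reference genes are chosen among the housekeeping
candidates by the geNorm stability algorithm (pairwise log2-ratio SDs ->
stability M; stepwise exclusion of the least stable gene; pairwise variation
V(n, n+1) decides how many genes are enough), and a per-sample content
factor is computed from their geometric mean exactly as in stage 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .rcc_io import CodeClass, CohortMatrix, Group

__all__ = [
    "BackgroundModel",
    "GeNormResult",
    "NormalizationFactors",
    "NormalizedMatrix",
    "NormalizationError",
    "background_threshold",
    "detectability_mask",
    "positive_factors",
    "genorm_rank",
    "content_factors",
    "normalize_cohort",
]

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised by a normalization stage; the message names the stage."""


@dataclass(frozen=True)
class BackgroundModel:
    """Per-sample negative-control background: threshold = mean + k_sd * SD."""

    per_sample_threshold: dict[str, float]
    neg_mean: dict[str, float]
    neg_sd: dict[str, float]
    k_sd: float = 2.0


@dataclass(frozen=True)
class GeNormResult:
    """Outcome of geNorm reference-gene ranking.

    ``ranking`` lists candidates most-stable first; ``exclusion_order`` lists
    the stepwise-removed genes least-stable first (length n_candidates - 2);
    ``m_values`` holds each gene's stability M at the step it was ranked;
    ``v_curve[i]`` is the pairwise variation V(i+2, i+3).
    """

    m_values: dict[str, float]
    exclusion_order: list[str]
    ranking: list[str]
    v_curve: list[float]
    n_selected: int

    @property
    def selected_genes(self) -> list[str]:
        return self.ranking[: self.n_selected]


@dataclass(frozen=True)
class NormalizationFactors:
    positive_factor: dict[str, float]
    content_factor: dict[str, float]
    reference_genes: list[str]


@dataclass
class NormalizedMatrix:
    """Fully normalized expression values plus full provenance.

    ``values`` covers Endogenous and Housekeeping genes (rows) for every
    sample (columns); ``detectable`` flags Endogenous genes whose raw counts
    cleared background in enough samples.
    """

    values: pd.DataFrame
    detectable: dict[str, bool]
    groups: dict[str, Group]
    background: BackgroundModel
    factors: NormalizationFactors
    genorm: GeNormResult
    endogenous_genes: list[str]

    @property
    def detectable_genes(self) -> list[str]:
        return [g for g in self.endogenous_genes if self.detectable.get(g, False)]

    def detectable_values(self) -> pd.DataFrame:
        return self.values.loc[self.detectable_genes]

    def sample_ids_in(self, group: Group) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) is group]


def background_threshold(neg_counts: Sequence[float], k_sd: float = 2.0) -> float:
    """Background threshold of one sample: mean + k_sd * sample SD of negatives."""
    arr = np.asarray(list(neg_counts), dtype=float)
    if arr.size < 2:
        raise NormalizationError(
            f"background_threshold: need >=2 negative probes, got {arr.size}"
        )
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        log.warning("background_threshold: zero variance among negative probes")
    return float(arr.mean()) + k_sd * sd


def _background_model(matrix: CohortMatrix, k_sd: float) -> BackgroundModel:
    neg = matrix.class_frame(CodeClass.NEGATIVE)
    thresholds, means, sds = {}, {}, {}
    for sid in neg.columns:
        vals = neg[sid].to_numpy(dtype=float)
        thresholds[sid] = background_threshold(vals, k_sd)
        means[sid] = float(vals.mean())
        sds[sid] = float(vals.std(ddof=1))
    return BackgroundModel(thresholds, means, sds, k_sd)


def detectability_mask(
    matrix: CohortMatrix, bg: BackgroundModel, min_fraction: float = 0.5
) -> dict[str, bool]:
    """Endogenous gene -> detectable?

    A gene is detectable iff its raw count strictly exceeds its sample's
    background threshold in at least ``min_fraction`` of all samples.
    """
    endo = matrix.class_frame(CodeClass.ENDOGENOUS)
    thr = np.array([bg.per_sample_threshold[s] for s in endo.columns])
    above = endo.to_numpy(dtype=float) > thr[None, :]
    frac = above.mean(axis=1)
    return {gene: bool(f >= min_fraction) for gene, f in zip(endo.index, frac)}


def _geomean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.log(values).mean(axis=axis))


def positive_factors(matrix: CohortMatrix) -> dict[str, float]:
    """Per-sample technical factor from the positive-control titration."""
    pos = matrix.class_frame(CodeClass.POSITIVE)
    if pos.shape[0] < 2:
        raise NormalizationError(
            f"positive_factors: need >=2 positive probes, got {pos.shape[0]}"
        )
    vals = pos.to_numpy(dtype=float)
    if np.any(vals <= 0):
        bad = pos.columns[np.any(vals <= 0, axis=0)].tolist()
        raise NormalizationError(
            f"positive_factors: zero positive-control count in sample(s) {bad}"
        )
    g = _geomean(vals, axis=0)
    mean_g = g.mean()
    return {sid: float(mean_g / gs) for sid, gs in zip(pos.columns, g)}


def genorm_rank(hk: pd.DataFrame, v_cutoff: float = 0.15, min_genes: int = 2) -> GeNormResult:
    """Rank housekeeping candidates by geNorm stability.

    ``hk`` is a genes x samples frame of positive-normalized values, all > 0.
    For genes j, k the pairwise variation ``V_jk`` is the SD over samples of
    ``log2(x_j / x_k)``; the stability ``M_j`` is the mean of ``V_jk`` over
    k != j.  The gene with the highest M is removed and M recomputed until
    two genes remain (ties broken by gene name).  ``V(n, n+1)`` is the SD
    over samples of ``log2(NF_n / NF_{n+1})`` with ``NF_n`` the per-sample
    geometric mean of the n most stable genes; the number of reference genes
    selected is the smallest ``n >= min_genes`` with ``V(n, n+1) < v_cutoff``,
    or all candidates if the curve never drops below the cutoff.
    """
    if hk.shape[0] < 3:
        raise NormalizationError(f"genorm_rank: need >=3 housekeeping genes, got {hk.shape[0]}")
    vals = hk.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise NormalizationError("genorm_rank: all housekeeping values must be > 0")

    logv = pd.DataFrame(np.log2(vals), index=hk.index, columns=hk.columns)
    remaining = list(hk.index)
    exclusion: list[str] = []
    m_values: dict[str, float] = {}
    while len(remaining) > 2:
        m = _stability_m(logv.loc[remaining])
        worst = max(remaining, key=lambda g: (m[g], g))
        m_values[worst] = m[worst]
        exclusion.append(worst)
        remaining.remove(worst)
    final_m = _stability_m(logv.loc[remaining])
    for g in remaining:
        m_values[g] = final_m[g]
    # most stable first; the final two share one M value, order them by name
    ranking = sorted(remaining) + exclusion[::-1]

    v_curve: list[float] = []
    n_total = len(ranking)
    for n in range(2, n_total):
        nf_n = logv.loc[ranking[:n]].mean(axis=0)
        nf_n1 = logv.loc[ranking[: n + 1]].mean(axis=0)
        v_curve.append(float((nf_n - nf_n1).std(ddof=1)))

    n_selected = n_total
    for i, v in enumerate(v_curve):
        if v < v_cutoff and i + 2 >= min_genes:
            n_selected = i + 2
            break
    return GeNormResult(
        m_values=m_values,
        exclusion_order=exclusion,
        ranking=ranking,
        v_curve=v_curve,
        n_selected=n_selected,
    )


def _stability_m(logv: pd.DataFrame) -> dict[str, float]:
    """M_j = mean over k != j of SD_samples(log2 x_j - log2 x_k)."""
    arr = logv.to_numpy()
    n = arr.shape[0]
    sds = np.zeros((n, n))
    for j in range(n):
        diffs = arr[j][None, :] - arr  # (n, samples)
        sds[j] = diffs.std(axis=1, ddof=1)
    m = sds.sum(axis=1) / (n - 1)  # diagonal contributes 0
    return {g: float(v) for g, v in zip(logv.index, m)}


def content_factors(
    values: pd.DataFrame, reference_genes: Sequence[str]
) -> dict[str, float]:
    """Per-sample RNA-content factor from the reference-gene geometric mean."""
    missing = [g for g in reference_genes if g not in values.index]
    if missing:
        raise NormalizationError(f"content_factors: reference genes missing: {missing}")
    ref = values.loc[list(reference_genes)].to_numpy(dtype=float)
    if np.any(ref <= 0):
        raise NormalizationError("content_factors: zero reference-gene value")
    h = _geomean(ref, axis=0)
    mean_h = h.mean()
    return {sid: float(mean_h / hs) for sid, hs in zip(values.columns, h)}


def normalize_cohort(
    matrix: CohortMatrix, config: PipelineConfig | None = None
) -> NormalizedMatrix:
    """Run the full normalization chain on a raw cohort.

    background model -> detectability mask -> positive-control factors ->
    geNorm reference selection -> content factors.  Endogenous and
    housekeeping counts are floored at the per-sample background threshold
    before any geometric-mean computation, and the output values are the
    floored counts scaled by both factors.
    """
    cfg = config or PipelineConfig()
    classes = {p.code_class for p in matrix.probes}
    missing = set(CodeClass) - classes
    if missing:
        raise NormalizationError(
            f"normalize_cohort: cohort lacks probe classes {sorted(c.value for c in missing)}"
        )

    bg = _background_model(matrix, cfg.background_k_sd)
    detectable = detectability_mask(matrix, bg, cfg.detect_min_fraction)
    pos_f = positive_factors(matrix)

    endo = matrix.class_frame(CodeClass.ENDOGENOUS)
    hk = matrix.class_frame(CodeClass.HOUSEKEEPING)
    work = pd.concat([endo, hk]).astype(float)
    thr = np.array([bg.per_sample_threshold[s] for s in work.columns])
    floored = np.maximum(work.to_numpy(), thr[None, :])
    if np.any(floored <= 0):
        # all-zero negatives give threshold 0; keep logs finite
        floored = np.maximum(floored, 1.0)
    work = pd.DataFrame(floored, index=work.index, columns=work.columns)

    fvec = np.array([pos_f[s] for s in work.columns])
    pos_norm = work * fvec[None, :]

    genorm = genorm_rank(
        pos_norm.loc[hk.index], cfg.genorm_v_cutoff, cfg.genorm_min_genes
    )
    refs = genorm.selected_genes
    cont_f = content_factors(pos_norm, refs)
    cvec = np.array([cont_f[s] for s in work.columns])
    values = pos_norm * cvec[None, :]

    return NormalizedMatrix(
        values=values,
        detectable=detectable,
        groups=matrix.groups,
        background=bg,
        factors=NormalizationFactors(pos_f, cont_f, list(refs)),
        genorm=genorm,
        endogenous_genes=list(endo.index),
    )
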