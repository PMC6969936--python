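"""Group and single-subject inference for decoding timecourses.

Group level: a one-sample sign-flip Monte-Carlo test on subject accuracy
curves.  Per time point the one-sample t statistic of (accuracy - chance)
across subjects is enhanced with TFCE (threshold-free cluster enhancement,
E = 0.5, H = 2 over the time axis); the null distribution of the *maximum*
enhanced score is built by randomly negating each subject's whole curve,
which is exchangeable under the null hypothesis that accuracy is symmetric
about chance.  Corrected p-values compare the observed score at each time
point against that max-statistic null, controlling the family-wise error
over time.  A cluster-mass alternative (fixed t threshold) is available
behind the config.

Single-subject level: the decoding procedure is re-run under label
permutations; per time point the p-value is the smoothed rank of the
observed accuracy in the permutation distribution, corrected across time
with Benjamini-Hochberg FDR.

A two-sample variant of the Monte-Carlo test compares subjects split into
high/low imagery-vividness groups at the median of their eyes-open VVIQ
scores (subjects exactly at the median are excluded).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .decoding import (
    ClassifierSpec,
    DecodingTimecourse,
    PreparedCV,
    SchemeSpec,
)
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "StatsConfig",
    "ClusterResult",
    "SubjectPermutationResult",
    "tfce_scores",
    "cluster_mass_scores",
    "group_cluster_test",
    "subject_permutation_test",
    "fdr_adjust",
    "vividness_split_comparison",
    "decoding_summary",
]


@dataclass(frozen=True)
class StatsConfig:
    """Inference parameters.

    10,000 Monte-Carlo sign flips / group-label permutations at the group
    level, 1000 label shuffles per subject, all tests one-sided (above
    chance / difference > 0) at alpha 0.05.
    """

    n_montecarlo: int = 10_000
    n_subject_perms: int = 1000
    alpha: float = 0.05
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh: float = 0.1
    fdr_q: float = 0.05
    cluster_stat: str = "tfce"  # or "mass"
    cluster_t_thresh: float = 1.645
    stat_clip: float = 20.0

    def __post_init__(self) -> None:
        if self.n_montecarlo < 1 or self.n_subject_perms < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ClusterResult:
    """Corrected significance per time point from a max-statistic null."""

    times_ms: np.ndarray
    stat: np.ndarray  # observed enhanced score per time point
    p_corrected: np.ndarray
    mask: np.ndarray
    alpha: float


@dataclass
class SubjectPermutationResult:
    """Per-time-point permutation p-values for one subject, FDR-corrected."""

    times_ms: np.ndarray
    observed: DecodingTimecourse
    p_raw: np.ndarray
    p_fdr: np.ndarray
    mask: np.ndarray


def tfce_scores(
    stat: np.ndarray, dh: float = 0.1, e: float = 0.5, h: float = 2.0
) -> np.ndarray:
    """Threshold-free cluster enhancement of 1-D statistic curves.

    For every time point, integrates ``extent(h)^E * h^H dh`` over all
    thresholds ``h`` below the point's statistic, where extent is the
    length of the contiguous supra-threshold run containing it.  Only
    positive statistics are enhanced (one-sided).  Accepts a single curve
    or a stack of curves (rows enhanced independently).
    """
    x = np.asarray(stat, dtype=np.float64)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    pos = np.clip(x2, 0.0, None)
    out = np.zeros_like(pos)
    hmax = pos.max()
    if hmax <= 0:
        return out[0] if single else out
    n_rows, n_t = pos.shape
    row_off = np.arange(n_rows)[:, None]
    for height in np.arange(dh, hmax + dh, dh):
        mask = pos >= height
        if not mask.any():
            break
        starts = mask.copy()
        starts[:, 1:] &= ~mask[:, :-1]
        cid = np.cumsum(starts, axis=1) * mask  # per-row cluster ids, 1-based
        width = cid.max() + 1
        flat = (cid + row_off * width).ravel()
        counts = np.bincount(flat[mask.ravel()], minlength=n_rows * width)
        extent = counts[flat].reshape(n_rows, n_t) * mask
        out += (extent ** e) * (height ** h) * dh
    return out[0] if single else out


def cluster_mass_scores(stat: np.ndarray, t_thresh: float) -> np.ndarray:
    """Cluster-mass score per time point: summed statistic of the
    supra-threshold run containing it (0 below threshold)."""
    x = np.asarray(stat, dtype=np.float64)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    mask = x2 >= t_thresh
    out = np.zeros_like(x2)
    n_rows, n_t = x2.shape
    starts = mask.copy()
    starts[:, 1:] &= ~mask[:, :-1]
    cid = np.cumsum(starts, axis=1) * mask
    width = cid.max() + 1
    row_off = np.arange(n_rows)[:, None]
    flat = (cid + row_off * width).ravel()
    sums = np.bincount(
        flat[mask.ravel()], weights=x2.ravel()[mask.ravel()],
        minlength=n_rows * width,
    )
    out = sums[flat].reshape(n_rows, n_t) * mask
    return out[0] if single else out


def _enhance(stat: np.ndarray, cfg: StatsConfig) -> np.ndarray:
    # t values are clipped before enhancement: with few subjects a
    # near-zero sample variance yields astronomically large t.  The clip is
    # a fixed monotone transform applied to observed and null curves alike,
    # so permutation p-values remain exact; it only flattens the ranking
    # among already-extreme points.
    stat = np.clip(stat, -cfg.stat_clip, cfg.stat_clip)
    if cfg.cluster_stat == "tfce":
        return tfce_scores(stat, cfg.tfce_dh, cfg.tfce_e, cfg.tfce_h)
    if cfg.cluster_stat == "mass":
        return cluster_mass_scores(stat, cfg.cluster_t_thresh)
    raise ValueError(f"unknown cluster statistic {cfg.cluster_stat!r}")


def _one_sample_t(effects: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t across subjects for each sign-flip row.

    ``effects`` is (n_subjects, n_times); ``signs`` is (n_perms,
    n_subjects) of +/-1.  Uses the flip-invariance of per-subject squares
    so the whole stack is two matrix products.  Zero-variance time points
    score t = 0.
    """
    n = effects.shape[0]
    mean = signs @ effects / n
    sumsq = (effects ** 2).sum(axis=0)  # invariant under sign flips
    var = (sumsq[None, :] - n * mean ** 2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            "zero-variance time points encountered; their t scores are set to 0",
            stacklevel=3,
        )
        t[bad] = 0.0
    return t


def _stack_timecourses(
    timecourses: Sequence[DecodingTimecourse] | np.ndarray,
    times_ms: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(timecourses, np.ndarray):
        if times_ms is None:
            raise ValueError("times_ms required when passing a raw array")
        return np.asarray(timecourses, dtype=np.float64), np.asarray(times_ms)
    times = timecourses[0].times_ms
    for tc in timecourses[1:]:
        if len(tc.times_ms) != len(times) or not np.allclose(tc.times_ms, times):
            raise ValueError("subjects must share a common time grid")
    return np.stack([tc.accuracy for tc in timecourses]), times


def group_cluster_test(
    timecourses: Sequence[DecodingTimecourse] | np.ndarray,
    chance: float = 0.5,
    cfg: StatsConfig | None = None,
    rng: np.random.Generator | None = None,
    times_ms: np.ndarray | None = None,
    exact: bool = False,
) -> ClusterResult:
    """One-sample sign-flip Monte-Carlo cluster test above chance.

    With ``exact=True`` all ``2^n`` sign assignments are enumerated instead
    of sampling (feasible for small groups) and p-values are exact
    fractions; otherwise ``cfg.n_montecarlo`` random flips are drawn and
    p-values use the ``(1 + b) / (1 + n)`` smoothing.
    """
    cfg = cfg or StatsConfig()
    data, times = _stack_timecourses(timecourses, times_ms)
    n_sub = data.shape[0]
    if n_sub < 2:
        raise ValueError("group test needs at least 2 subjects")
    effects = data - chance
    obs_t = _one_sample_t(effects, np.ones((1, n_sub)))[0]
    obs_score = _enhance(obs_t, cfg)
    if exact:
        codes = np.arange(2 ** n_sub)
        signs = ((codes[:, None] >> np.arange(n_sub)) & 1) * 2 - 1
    else:
        rng = rng or np.random.default_rng()
        signs = rng.choice([-1, 1], size=(cfg.n_montecarlo, n_sub))
    null_t = _one_sample_t(effects, signs)
    null_max = _enhance(null_t, cfg).max(axis=1)
    ge = (null_max[:, None] >= obs_score[None, :]).sum(axis=0)
    if exact:
        p = ge / len(signs)
    else:
        p = (1 + ge) / (1 + len(signs))
    return ClusterResult(
        times_ms=times, stat=obs_score, p_corrected=p,
        mask=p < cfg.alpha, alpha=cfg.alpha,
    )


def subject_permutation_test(
    epochs: EpochSet,
    scheme: SchemeSpec,
    cfg: StatsConfig | None = None,
    rng: np.random.Generator | None = None,
    spec: ClassifierSpec | None = None,
) -> SubjectPermutationResult:
    """Single-subject label-permutation test with FDR across time.

    The decoding procedure is run once with the true labels and
    ``cfg.n_subject_perms`` times with labels randomly reassigned to
    epochs (fold/chunk structure untouched).  The per-time-point p-value
    is the smoothed fraction of permutations at or above the observed
    accuracy; Benjamini-Hochberg is applied across time points.
    """
    cfg = cfg or StatsConfig()
    rng = rng or np.random.default_rng()
    prepared = PreparedCV(epochs, scheme, spec)
    observed = prepared.run()
    n = len(prepared.y)
    n1 = int(prepared.y.sum())
    n_distinct = math.comb(n, n1)
    if n_distinct < cfg.n_subject_perms:
        logger.info(
            "only %d distinct label arrangements (< %d permutations); "
            "sampling with replacement", n_distinct, cfg.n_subject_perms,
        )
    count = np.zeros_like(observed.accuracy)
    for _ in range(cfg.n_subject_perms):
        acc = prepared.run(rng.permutation(prepared.y)).accuracy
        count += acc >= observed.accuracy
    p_raw = (1 + count) / (1 + cfg.n_subject_perms)
    p_fdr, mask = fdr_adjust(p_raw, cfg.fdr_q)
    return SubjectPermutationResult(
        times_ms=observed.times_ms, observed=observed,
        p_raw=p_raw, p_fdr=p_fdr, mask=mask,
    )


def fdr_adjust(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and the rejection mask."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy(), np.zeros_like(p, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _two_sample_t(
    data: np.ndarray, is_high: np.ndarray
) -> np.ndarray:
    """Pooled-variance two-sample t (high minus low) per time point."""
    a, b = data[is_high], data[~is_high]
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + (
        (b - b.mean(axis=0)) ** 2
    ).sum(axis=0)
    sp2 = ss / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[~np.isfinite(t)] = 0.0
    return t


def vividness_split_comparison(
    timecourses: Sequence[DecodingTimecourse] | np.ndarray,
    vviq_eyes_open: Sequence[float],
    cfg: StatsConfig | None = None,
    rng: np.random.Generator | None = None,
    times_ms: np.ndarray | None = None,
) -> ClusterResult:
    """High-vs-low vividness group difference, Monte-Carlo cluster-corrected.

    Subjects are split at the median of their eyes-open VVIQ scores;
    subjects exactly at the median are excluded.  Tests where the
    high-minus-low accuracy difference exceeds zero, using
    ``cfg.n_montecarlo`` random reassignments of subjects to groups to
    build the max-statistic null.
    """
    cfg = cfg or StatsConfig()
    rng = rng or np.random.default_rng()
    data, times = _stack_timecourses(timecourses, times_ms)
    scores = np.asarray(vviq_eyes_open, dtype=np.float64)
    if len(scores) != data.shape[0]:
        raise ValueError("one VVIQ score per subject required")
    med = np.median(scores)
    keep = scores != med
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d subject(s) at the median VVIQ score", n_excluded)
    data = data[keep]
    is_high = scores[keep] > med
    if is_high.sum() < 2 or (~is_high).sum() < 2:
        raise ValueError(
            "need at least 2 subjects per vividness group after excluding "
            f"median-tied subjects (got {int(is_high.sum())} high / "
            f"{int((~is_high).sum())} low)"
        )
    obs_score = _enhance(_two_sample_t(data, is_high), cfg)
    null_max = np.empty(cfg.n_montecarlo)
    for i in range(cfg.n_montecarlo):
        perm = rng.permutation(is_high)
        null_max[i] = _enhance(_two_sample_t(data, perm), cfg).max()
    ge = (null_max[:, None] >= obs_score[None, :]).sum(axis=0)
    p = (1 + ge) / (1 + cfg.n_montecarlo)
    return ClusterResult(
        times_ms=times, stat=obs_score, p_corrected=p,
        mask=p < cfg.alpha, alpha=cfg.alpha,
    )


def decoding_summary(
    times_ms: np.ndarray, mean_accuracy: np.ndarray, mask: np.ndarray
) -> dict:
    """Onset (first significant time) and peak latency/accuracy."""
    times_ms = np.asarray(times_ms)
    mean_accuracy = np.asarray(mean_accuracy)
    mask = np.asarray(mask, dtype=bool)
    peak_i = int(np.argmax(mean_accuracy))
    return {
        "onset_ms": float(times_ms[mask][0]) if mask.any() else None,
        "n_significant": int(mask.sum()),
        "peak_ms": float(times_ms[peak_i]),
        "peak_accuracy": float(mean_accuracy[peak_i]),
    }
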