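"""Surrogate null distributions and the Monte Carlo area-difference test.

The null model is built without any parametric assumption: the analysis is
re-run on the *same* recordings with pseudo-stimulus onsets placed uniformly
at random, so every Sync1 curve in the surrogate pool reflects what the
method reports when no stimulus-locked structure exists. The group statistic
is the signed area between the experimental group-average Sync1 curve and the
pool mean over an analysis window; its null distribution comes from repeatedly
averaging random groups of surrogate curves and computing the same area.

Because filtering, normalization and the sliding correlations do not depend
on the stimulus schedule, the surrogate reruns share one pair-correlation
array per recording and only the epoch averaging is repeated — numerically
identical to rerunning the full pipeline per pseudo-schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    GW6Config,
    compute_baseline,
    gw6_epoch_average,
    pair_correlations,
    sync_arrays,
)
from .io import EEGRecording, StimulusSchedule
from .preprocess import dft_bandpass, normalize

__all__ = [
    "SurrogatePool",
    "AreaStats",
    "MCResult",
    "analyze_with_surrogates",
    "bootstrap_surrogates",
    "pool_mean",
    "area_difference",
    "monte_carlo_test",
    "default_area_window",
]


@dataclass
class SurrogatePool:
    """Sync1 curves from pseudo-stimulus reruns; the bootstrap null."""

    curves: np.ndarray            # (n_curves, n_epoch_samples)
    source_file_ids: list[str]
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if len(self.source_file_ids) != self.curves.shape[0]:
            raise ValueError("source_file_ids must parallel the curves")

    @property
    def size(self) -> int:
        return self.curves.shape[0]

    def extend(self, other: "SurrogatePool") -> "SurrogatePool":
        if self.curves.shape[1] != other.curves.shape[1]:
            raise ValueError("cannot merge pools with different curve lengths")
        return SurrogatePool(
            np.vstack([self.curves, other.curves]),
            self.source_file_ids + other.source_file_ids,
            self.rng_seed,
        )


@dataclass
class AreaStats:
    """Signed area (raw sample-sum) and maximum of an excess-correlation curve.

    ``area`` is the plain sum over the window of (experimental − null mean);
    ``area_per_s`` divides by the sampling rate when a rate is supplied, for
    a duration-free correlation·seconds reading of the same number.
    """

    area: float
    max_value: float
    area_per_s: float | None = None

    def __iter__(self):
        return iter((self.area, self.max_value))


@dataclass
class MCResult:
    """Monte Carlo exceedance test outcome for one observed area."""

    observed_area: float
    observed_max: float
    null_areas: np.ndarray
    exceed_count: int
    n_cycles: int

    @property
    def p_estimate(self) -> float:
        return self.exceed_count / self.n_cycles

    @property
    def p_label(self) -> str:
        if self.exceed_count == 0:
            return f"p < {1.0 / self.n_cycles:g}"
        return f"p = {self.p_estimate:g}"


def _pseudo_schedule(
    rng: np.random.Generator,
    n_samples: int,
    n_stimuli: int,
    cfg: GW6Config,
    rate: float,
) -> StimulusSchedule:
    """Uniformly random pseudo-onsets whose epochs all fit in the recording."""
    pre = cfg.epoch.pre_samples(rate)
    length = cfg.epoch.n_samples(rate)
    lo = pre
    hi = n_samples - (length - pre)   # inclusive upper bound for a valid onset
    if hi - lo + 1 < n_stimuli:
        raise ValueError(
            f"recording of {n_samples} samples too short for {n_stimuli} pseudo-stimuli"
        )
    onsets = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_stimuli, replace=False))
    return StimulusSchedule(onsets, cfg.epoch.stim_samples(rate))


def bootstrap_surrogates(
    rec: EEGRecording,
    cfg: GW6Config,
    n_stimuli: int,
    n_reps: int = 20,
    rng_seed: int | np.random.SeedSequence | None = None,
    file_id: str = "",
    min_gap: int = 0,
) -> SurrogatePool:
    """``n_reps`` Sync1 curves from random pseudo-stimulus schedules on ``rec``.

    Pseudo-onsets are drawn uniformly (independently per repetition) from the
    range in which a full analysis epoch fits; overlap between pseudo-epochs
    is allowed unless ``min_gap`` (samples between successive onsets) says
    otherwise. Deterministic under ``rng_seed``.
    """
    cfg.validate_for(rec.sampling_rate)
    rng = np.random.default_rng(rng_seed)
    rate = rec.sampling_rate
    filtered = normalize(dft_bandpass(rec, cfg.band))
    corrs, pairs = pair_correlations(filtered.data, cfg.window_len)
    curves = []
    for _ in range(n_reps):
        sched = _pseudo_schedule(rng, rec.n_samples, n_stimuli, cfg, rate)
        if min_gap > 0:
            while np.any(np.diff(sched.onsets) < min_gap):
                sched = _pseudo_schedule(rng, rec.n_samples, n_stimuli, cfg, rate)
        r_avg = gw6_epoch_average(corrs, sched, cfg.epoch, rate)
        baseline = compute_baseline(r_avg, cfg.epoch, rate)
        curves.append(sync_arrays(r_avg, baseline, pairs, rate, cfg.epoch).sync1)
    seed_repr = rng_seed if isinstance(rng_seed, (int, type(None))) else None
    return SurrogatePool(np.array(curves), [file_id] * n_reps, seed_repr)


def analyze_with_surrogates(
    rec: EEGRecording,
    sched: StimulusSchedule,
    cfg: GW6Config,
    n_reps: int = 20,
    rng_seed: int | np.random.SeedSequence | None = None,
    file_id: str = "",
):
    """Experimental Sync curves plus a surrogate pool from one shared analysis pass.

    Returns ``(SyncCurves, SurrogatePool)``. Identical to running
    :func:`gw6.core.gw6_pipeline` and :func:`bootstrap_surrogates`
    separately, but the filter / z-score / sliding-correlation stage — which
    does not depend on any schedule — is computed once.
    """
    cfg.validate_for(rec.sampling_rate)
    rng = np.random.default_rng(rng_seed)
    rate = rec.sampling_rate
    filtered = normalize(dft_bandpass(rec, cfg.band))
    corrs, pairs = pair_correlations(filtered.data, cfg.window_len)

    def sync1_for(schedule: StimulusSchedule):
        r_avg = gw6_epoch_average(corrs, schedule, cfg.epoch, rate)
        baseline = compute_baseline(r_avg, cfg.epoch, rate)
        return sync_arrays(r_avg, baseline, pairs, rate, cfg.epoch)

    observed = sync1_for(sched)
    curves = []
    for _ in range(n_reps):
        pseudo = _pseudo_schedule(rng, rec.n_samples, sched.n_stimuli, cfg, rate)
        curves.append(sync1_for(pseudo).sync1)
    seed_repr = rng_seed if isinstance(rng_seed, (int, type(None))) else None
    return observed, SurrogatePool(np.array(curves), [file_id] * n_reps, seed_repr)


def pool_mean(pool: SurrogatePool) -> np.ndarray:
    """Elementwise mean over all surrogate curves (the 'bootstrap curve')."""
    if pool.size == 0:
        raise ValueError("empty surrogate pool")
    return pool.curves.mean(axis=0)


def default_area_window(cfg: GW6Config, rate: float) -> tuple[int, int]:
    """Default analysis window: stimulus onset to the end of the epoch."""
    return cfg.epoch.pre_samples(rate), cfg.epoch.n_samples(rate)


def area_difference(
    expt: np.ndarray,
    null_mean: np.ndarray,
    window: tuple[int, int] | None = None,
    rate: float | None = None,
) -> AreaStats:
    """Signed area and maximum of (experimental − null) over a sample window.

    Both can be negative; the area is the raw sum over window samples (the
    statistic used for exceedance counting), with a per-second version
    attached when ``rate`` is given.
    """
    expt = np.asarray(expt, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    if expt.shape != null_mean.shape:
        raise ValueError(f"curve length mismatch: {expt.shape} vs {null_mean.shape}")
    if window is None:
        window = (0, expt.size)
    lo, hi = window
    if not (0 <= lo < hi <= expt.size):
        raise ValueError(f"window {window} outside curve of {expt.size} samples")
    diff = expt[lo:hi] - null_mean[lo:hi]
    area = float(diff.sum())
    return AreaStats(
        area=area,
        max_value=float(diff.max()),
        area_per_s=area / rate if rate else None,
    )


def monte_carlo_test(
    pool: SurrogatePool,
    group_size: int,
    n_cycles: int,
    observed_area: float,
    window: tuple[int, int] | None = None,
    rng_seed: int | np.random.SeedSequence | None = None,
    observed_max: float = float("nan"),
    with_replacement: bool = False,
) -> MCResult:
    """Exceedance test of ``observed_area`` against random surrogate groups.

    Each cycle draws ``group_size`` curves from the pool (without replacement
    by default, mirroring a group of distinct files), averages them, and
    computes the same signed area against the full-pool mean; the counter is
    incremented whenever the null area exceeds the observed one. The p
    estimate is ``exceed_count / n_cycles`` with a reporting floor of
    ``1/n_cycles`` when the count is zero.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not with_replacement and group_size > pool.size:
        raise ValueError(
            f"group_size {group_size} exceeds pool of {pool.size} curves"
        )
    rng = np.random.default_rng(rng_seed)
    null_curve = pool_mean(pool)
    if window is None:
        window = (0, null_curve.size)
    lo, hi = window
    centered = pool.curves[:, lo:hi] - null_curve[lo:hi]
    null_areas = np.empty(n_cycles)
    for i in range(n_cycles):
        idx = rng.choice(pool.size, size=group_size, replace=with_replacement)
        null_areas[i] = centered[idx].mean(axis=0).sum()
    exceed = int(np.count_nonzero(null_areas > observed_area))
    return MCResult(
        observed_area=float(observed_area),
        observed_max=float(observed_max),
        null_areas=null_areas,
        exceed_count=exceed,
        n_cycles=n_cycles,
    )
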