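"""The GW6 event-related inter-channel correlation algorithm.

The method quantifies transient changes in synchronization between EEG
channels that are time-locked to a stimulus but not necessarily phase-locked
to it (and therefore invisible to classical ERP averaging):

1. A window of length ``L`` slides sample-by-sample along every pair of
   (filtered, z-scored) channels; the Pearson correlation of the two windows
   is recorded at the window centre, giving ``R(x)`` per pair — ``Nt =
   NC(NC-1)/2`` traces (91 for a 14-channel montage).
2. ``R`` traces are epoched around each stimulus onset and averaged over
   stimuli, giving ``R'(I, X)`` (pair I, epoch sample X).
3. Per pair, a scalar baseline — the mean of ``R'`` over the pre- and
   post-stimulus samples — is subtracted and the result rectified:
   ``Sync(I, X) = |R'(I, X) - baseline(I)|``.
4. ``Sync1(X)`` averages ``Sync`` over all pairs; ``Sync2(C, X)`` averages
   over the ``NC - 1`` pairs containing channel ``C``.

Because Pearson correlation is invariant to affine rescaling of either
channel, the curves respond to phase alignment rather than amplitude — the
property that makes the method robust to amplitude artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io import EEGRecording, StimulusSchedule
from .preprocess import BandSpec, EpochSpec, dft_bandpass, extract_epochs, normalize

__all__ = [
    "GW6Config",
    "PairIndex",
    "SyncCurves",
    "channel_pairs",
    "sliding_correlation",
    "pair_correlations",
    "gw6_epoch_average",
    "compute_baseline",
    "sync_arrays",
    "gw6_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GW6Config:
    """Analysis parameters: correlation window, filter band, epoch geometry.

    ``window_len`` defaults to 64 samples (0.5 s at 128/s): about five cycles
    of the 9–10 Hz band of interest, yet short against the 1 s stimulus.
    """

    window_len: int = 64
    band: BandSpec = field(default_factory=lambda: BandSpec(9.0, 10.0))
    epoch: EpochSpec = field(default_factory=EpochSpec)

    def __post_init__(self) -> None:
        if self.window_len < 4:
            raise ValueError(f"window_len must be >= 4 samples, got {self.window_len}")

    def validate_for(self, rate: float) -> None:
        if self.window_len > self.epoch.n_samples(rate):
            raise ValueError(
                f"window_len {self.window_len} exceeds the "
                f"{self.epoch.n_samples(rate)}-sample epoch"
            )


@dataclass(frozen=True)
class PairIndex:
    """All unordered channel pairs (a < b), lexicographically ordered."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pairs_with(self, channel: int) -> list[int]:
        """Row indices of the pairs containing ``channel``."""
        return [i for i, (a, b) in enumerate(self.pairs) if channel in (a, b)]


def channel_pairs(nc: int) -> PairIndex:
    """Enumerate the ``nc*(nc-1)/2`` unordered channel pairs (91 for nc=14)."""
    if nc < 2:
        raise ValueError(f"need at least 2 channels to form pairs, got {nc}")
    return PairIndex(tuple((a, b) for a in range(nc) for b in range(a + 1, nc)))


def _window_sums(x: np.ndarray, length: int) -> np.ndarray:
    """Sums over every contiguous window of ``length`` along the last axis."""
    cs = np.cumsum(x, axis=-1, dtype=float)
    pad = np.zeros(x.shape[:-1] + (1,))
    cs = np.concatenate([pad, cs], axis=-1)
    return cs[..., length:] - cs[..., :-length]


def _edge_extend(valid: np.ndarray, n: int, length: int) -> np.ndarray:
    """Place window-start values at window centres and copy ends outward."""
    half = length // 2
    out = np.empty(valid.shape[:-1] + (n,))
    out[..., half:half + valid.shape[-1]] = valid
    out[..., :half] = valid[..., :1]
    out[..., half + valid.shape[-1]:] = valid[..., -1:]
    return out


def sliding_correlation(a: np.ndarray, b: np.ndarray, window_len: int) -> np.ndarray:
    """Pearson correlation of length-``window_len`` windows centred at every sample.

    The output has the same length as the inputs: positions closer than half a
    window to an edge copy the nearest fully defined value, so downstream
    epoch indexing stays uniform. Windows in which either channel is constant
    yield 0 (with a logged warning) rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D vectors, got {a.shape} and {b.shape}")
    n = a.size
    if window_len > n:
        raise ValueError(f"window of {window_len} samples exceeds series length {n}")
    L = window_len
    sa, sb = _window_sums(a, L), _window_sums(b, L)
    qa, qb = _window_sums(a * a, L), _window_sums(b * b, L)
    sab = _window_sums(a * b, L)
    var_a = qa - sa * sa / L
    var_b = qb - sb * sb / L
    cov = sab - sa * sb / L
    denom = var_a * var_b
    degenerate = denom <= 0
    if np.any(degenerate):
        logger.warning(
            "%d sliding window(s) with zero variance; correlation set to 0 there",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, cov / np.sqrt(np.where(degenerate, 1.0, denom)))
    np.clip(r, -1.0, 1.0, out=r)
    return _edge_extend(r, n, L)


def pair_correlations(
    data: np.ndarray, window_len: int, pairs: PairIndex | None = None
) -> tuple[np.ndarray, PairIndex]:
    """Sliding correlation for every channel pair of a (nc, n) array at once.

    Vectorized equivalent of calling :func:`sliding_correlation` per pair;
    returns (``R`` matrix of shape (n_pairs, n), pair index).
    """
    data = np.ascontiguousarray(data, dtype=float)
    nc, n = data.shape
    if pairs is None:
        pairs = channel_pairs(nc)
    if window_len > n:
        raise ValueError(f"window of {window_len} samples exceeds series length {n}")
    L = window_len
    ia = np.array([p[0] for p in pairs.pairs], dtype=np.int64)
    ib = np.array([p[1] for p in pairs.pairs], dtype=np.int64)
    if _kernels.HAVE_NUMBA:
        r, ndegen = _kernels.pair_corr_kernel(data, ia, ib, L)
        if ndegen:
            logger.warning(
                "%d sliding window(s) with zero variance; correlation set to 0 there",
                int(ndegen),
            )
        return r, pairs
    s = _window_sums(data, L)
    q = _window_sums(data * data, L)
    var = q - s * s / L
    sab = _window_sums(data[ia] * data[ib], L)
    cov = sab - s[ia] * s[ib] / L
    denom = var[ia] * var[ib]
    degenerate = denom <= 0
    if np.any(degenerate):
        logger.warning(
            "%d sliding window(s) with zero variance; correlation set to 0 there",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, cov / np.sqrt(np.where(degenerate, 1.0, denom)))
    np.clip(r, -1.0, 1.0, out=r)
    return _edge_extend(r, n, L), pairs


def gw6_epoch_average(
    pair_corrs: np.ndarray,
    sched: StimulusSchedule,
    epoch: EpochSpec,
    rate: float,
) -> np.ndarray:
    """Average the epoched ``R`` traces over stimuli: ``R'(I, X)``."""
    pair_corrs = np.atleast_2d(np.asarray(pair_corrs, dtype=float))
    if _kernels.HAVE_NUMBA:
        n = pair_corrs.shape[1]
        pre = epoch.pre_samples(rate)
        length = epoch.n_samples(rate)
        starts = sched.onsets - pre
        bad = (starts < 0) | (starts + length > n)
        if np.any(bad):
            raise ValueError(
                f"epoch window out of bounds for onset(s) {sched.onsets[bad].tolist()} "
                f"(series length {n})"
            )
        return _kernels.epoch_mean_kernel(
            np.ascontiguousarray(pair_corrs), starts.astype(np.int64), length
        )
    epochs = extract_epochs(pair_corrs, sched, epoch, rate)
    return epochs.mean(axis=0)


def compute_baseline(r_avg: np.ndarray, epoch: EpochSpec, rate: float) -> np.ndarray:
    """Per-pair mean of ``R'`` over every epoch sample outside the stimulus interval."""
    if epoch.pre_s == 0 and epoch.post_s == 0:
        raise ValueError("baseline undefined: epoch has no pre- or post-stimulus region")
    start, stop = epoch.stimulus_slice(rate)
    n = r_avg.shape[-1]
    mask = np.ones(n, dtype=bool)
    mask[start:stop] = False
    return r_avg[..., mask].mean(axis=-1)


@dataclass
class SyncCurves:
    """All GW6 output curves for one recording.

    ``r_avg`` is ``R'(I, X)``; ``sync_pair`` is the rectified, baseline-
    subtracted ``Sync(I, X)``; ``sync1`` its mean over pairs; ``sync2`` the
    per-channel mean over the pairs containing that channel.
    """

    r_avg: np.ndarray
    baseline: np.ndarray
    sync_pair: np.ndarray
    sync1: np.ndarray
    sync2: np.ndarray
    pairs: PairIndex
    rate: float
    epoch: EpochSpec

    def times_ms(self) -> np.ndarray:
        pre = self.epoch.pre_samples(self.rate)
        return (np.arange(self.sync1.size) - pre) / self.rate * 1000.0


def sync_arrays(
    r_avg: np.ndarray,
    baseline: np.ndarray,
    pairs: PairIndex,
    rate: float,
    epoch: EpochSpec,
) -> SyncCurves:
    """Rectified baseline-subtracted curves and their pair/channel aggregates."""
    r_avg = np.asarray(r_avg, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if r_avg.shape[0] != pairs.n_pairs or baseline.shape != (pairs.n_pairs,):
        raise ValueError(
            f"shape mismatch: r_avg {r_avg.shape}, baseline {baseline.shape}, "
            f"{pairs.n_pairs} pairs"
        )
    sync_pair = np.abs(r_avg - baseline[:, None])
    sync1 = sync_pair.mean(axis=0)
    nc = max(b for _, b in pairs.pairs) + 1
    sync2 = np.empty((nc, r_avg.shape[1]))
    for c in range(nc):
        sync2[c] = sync_pair[pairs.pairs_with(c)].mean(axis=0)
    return SyncCurves(r_avg, baseline, sync_pair, sync1, sync2, pairs, rate, epoch)


def gw6_pipeline(rec: EEGRecording, sched: StimulusSchedule, cfg: GW6Config) -> SyncCurves:
    """Full GW6 analysis of one recording: filter → z-score → correlate → epoch → Sync.

    Deterministic; same input always yields bit-identical curves.
    """
    cfg.validate_for(rec.sampling_rate)
    filtered = normalize(dft_bandpass(rec, cfg.band))
    corrs, pairs = pair_correlations(filtered.data, cfg.window_len)
    r_avg = gw6_epoch_average(corrs, sched, cfg.epoch, rec.sampling_rate)
    baseline = compute_baseline(r_avg, cfg.epoch, rec.sampling_rate)
    return sync_arrays(r_avg, baseline, pairs, rec.sampling_rate, cfg.epoch)
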