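"""Classical stimulus-locked ERP averaging and group evoked-power summation.

This is the baseline analysis against which the correlation method is judged:
time- and phase-locked epochs are averaged per channel, channel-averaged for
the grand waveform, and across subjects the per-sample evoked *power* (mean
over channels of the squared ERP amplitude) is summed. Power summation
sidesteps the latency-jitter cancellation that plagues cross-subject
amplitude averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import EpochSpec

__all__ = [
    "ERPWaveform",
    "erp_average",
    "grand_channel_average",
    "erp_power",
    "group_power_sum",
]


@dataclass
class ERPWaveform:
    """Stimulus-locked average, shape (n_channels, n_epoch_samples)."""

    values: np.ndarray
    rate: float
    epoch_spec: EpochSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.epoch_spec.n_samples(self.rate)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"waveform shape {self.values.shape} inconsistent with epoch of {expected} samples"
            )

    def times_ms(self) -> np.ndarray:
        """Epoch sample times in milliseconds relative to stimulus onset."""
        pre = self.epoch_spec.pre_samples(self.rate)
        return (np.arange(self.values.shape[1]) - pre) / self.rate * 1000.0


def erp_average(epochs: np.ndarray, rate: float, epoch_spec: EpochSpec) -> ERPWaveform:
    """Mean over epochs of a (n_epochs, n_channels, n_samples) tensor."""
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] == 0:
        raise ValueError("epochs must be a non-empty (n_epochs, n_channels, n_samples) tensor")
    return ERPWaveform(epochs.mean(axis=0), rate, epoch_spec)


def grand_channel_average(erp: ERPWaveform) -> np.ndarray:
    """Mean across channels at each epoch sample."""
    return erp.values.mean(axis=0)


def erp_power(erp: ERPWaveform) -> np.ndarray:
    """Per-sample evoked power: mean over channels of the squared ERP amplitude."""
    return (erp.values ** 2).mean(axis=0)


def group_power_sum(powers: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise sum of per-subject evoked-power curves."""
    powers = [np.asarray(p, dtype=float) for p in powers]
    if not powers:
        raise ValueError("need at least one power curve")
    lengths = {p.shape for p in powers}
    if len(lengths) != 1:
        raise ValueError(f"mismatched power curve shapes: {sorted(lengths)}")
    return np.sum(powers, axis=0)
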