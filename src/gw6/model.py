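"""Model/Results surface over the GW6 pipeline.

Two estimator-style entry points, in the spirit of statsmodels:

* :class:`GW6Model` — one recording plus its stimulus schedule; ``fit()``
  runs the full analysis (optionally with bootstrap surrogates) and returns a
  :class:`GW6SessionResults`.
* :class:`GW6Study` — a cohort of recordings (e.g. the 25 receiver files of
  a study); ``fit()`` runs every file, builds the pooled surrogate null,
  computes the group area statistic and its Monte Carlo p, and returns a
  :class:`GW6Results` with a ``summary()`` table and plotting helpers.

The functional modules (:mod:`gw6.core`, :mod:`gw6.resampling`) remain the
computational layer; these classes only orchestrate and hold results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GW6Config, SyncCurves, gw6_pipeline
from .io import EEGRecording, SessionPair, StimulusSchedule
from .resampling import (
    AreaStats,
    MCResult,
    SurrogatePool,
    analyze_with_surrogates,
    area_difference,
    default_area_window,
    monte_carlo_test,
    pool_mean,
)

__all__ = ["GW6Model", "GW6SessionResults", "GW6Study", "GW6Results"]


def _shade_stimulus(ax, cfg: GW6Config, rate: float) -> None:
    lo, hi = cfg.epoch.stimulus_slice(rate)
    pre = cfg.epoch.pre_samples(rate)
    ax.axvspan((lo - pre) / rate * 1000, (hi - pre) / rate * 1000,
               color="0.9", zorder=0, label="stimulus")


class GW6Model:
    """Event-related inter-channel correlation analysis of one recording."""

    def __init__(
        self,
        recording: EEGRecording,
        schedule: StimulusSchedule,
        config: GW6Config | None = None,
    ) -> None:
        self.recording = recording
        self.schedule = schedule
        self.config = config if config is not None else GW6Config()
        self.config.validate_for(recording.sampling_rate)

    @classmethod
    def from_files(
        cls,
        recording_path,
        schedule_path,
        format: str = "delimited",
        config: GW6Config | None = None,
    ) -> "GW6Model":
        from .io import read_recording, read_schedule

        return cls(read_recording(recording_path, format), read_schedule(schedule_path), config)

    def fit(self, n_surrogates: int = 0, seed=None) -> "GW6SessionResults":
        """Run the pipeline; with ``n_surrogates > 0`` also build a surrogate pool."""
        if n_surrogates > 0:
            curves, pool = analyze_with_surrogates(
                self.recording, self.schedule, self.config,
                n_reps=n_surrogates, rng_seed=seed,
            )
        else:
            curves, pool = gw6_pipeline(self.recording, self.schedule, self.config), None
        return GW6SessionResults(self, curves, pool)


@dataclass
class GW6SessionResults:
    """Sync curves (and optional surrogate pool) for one recording."""

    model: GW6Model
    curves: SyncCurves
    pool: SurrogatePool | None = None

    @property
    def sync1(self) -> np.ndarray:
        return self.curves.sync1

    def to_frame(self) -> pd.DataFrame:
        """Sync1/Sync2 curves as a tidy table indexed by epoch time in ms."""
        labels = self.model.recording.channel_labels
        data = {"sync1": self.curves.sync1}
        for c, label in enumerate(labels):
            data[f"sync2_{label}"] = self.curves.sync2[c]
        return pd.DataFrame(data, index=pd.Index(self.curves.times_ms(), name="time_ms"))

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cfg = self.model.config
        rate = self.model.recording.sampling_rate
        ax.plot(self.curves.times_ms(), self.curves.sync1 * 100, color="crimson",
                label="Sync1")
        if self.pool is not None:
            ax.plot(self.curves.times_ms(), pool_mean(self.pool) * 100, color="royalblue",
                    label="surrogate mean")
        _shade_stimulus(ax, cfg, rate)
        ax.set_xlabel("time from stimulus onset (ms)")
        ax.set_ylabel("correlation × 100")
        ax.legend()
        return ax


class GW6Study:
    """Group-level GW6 analysis of a cohort of recordings.

    ``sessions`` is a sequence of ``(recording, schedule)`` tuples; use
    :meth:`from_session_pairs` to analyse the sender or receiver side of
    simultaneously recorded pairs.
    """

    def __init__(
        self,
        sessions: Sequence[tuple[EEGRecording, StimulusSchedule]],
        config: GW6Config | None = None,
        file_ids: Sequence[str] | None = None,
    ) -> None:
        if not sessions:
            raise ValueError("need at least one session")
        self.sessions = list(sessions)
        self.config = config if config is not None else GW6Config()
        for rec, _ in self.sessions:
            self.config.validate_for(rec.sampling_rate)
        self.file_ids = (
            list(file_ids) if file_ids is not None
            else [f"file{i}" for i in range(len(sessions))]
        )
        if len(self.file_ids) != len(self.sessions):
            raise ValueError("file_ids must parallel sessions")

    @classmethod
    def from_session_pairs(
        cls,
        pairs: Sequence[SessionPair],
        role: str = "receiver",
        config: GW6Config | None = None,
    ) -> "GW6Study":
        if role not in ("sender", "receiver"):
            raise ValueError(f"role must be 'sender' or 'receiver', got {role!r}")
        sessions = [(getattr(p, role), p.schedule) for p in pairs]
        return cls(sessions, config, [p.pair_id for p in pairs])

    def fit(
        self,
        n_boot_reps: int = 20,
        n_cycles: int = 2000,
        group_size: int | None = None,
        area_window: tuple[int, int] | None = None,
        seed=None,
    ) -> "GW6Results":
        """Per-file analysis, pooled surrogate null, group area and Monte Carlo p.

        ``group_size`` defaults to the number of files so null groups match
        the experimental group's averaging; the classic design compares 25
        real files against random groups of 25 surrogate curves.
        """
        rate = self.sessions[0][0].sampling_rate
        root = np.random.SeedSequence(seed if seed is not None else 0)
        file_seeds = root.spawn(len(self.sessions) + 1)
        per_file = []
        pool: SurrogatePool | None = None
        for (rec, sched), fid, fseed in zip(self.sessions, self.file_ids, file_seeds):
            curves, fpool = analyze_with_surrogates(
                rec, sched, self.config, n_reps=n_boot_reps, rng_seed=fseed, file_id=fid
            )
            per_file.append(curves.sync1)
            pool = fpool if pool is None else pool.extend(fpool)
        per_file = np.array(per_file)
        group_curve = per_file.mean(axis=0)
        window = area_window if area_window is not None else default_area_window(self.config, rate)
        null_curve = pool_mean(pool)
        stats = area_difference(group_curve, null_curve, window, rate=rate)
        gsize = group_size if group_size is not None else len(self.sessions)
        mc = monte_carlo_test(
            pool, group_size=gsize, n_cycles=n_cycles,
            observed_area=stats.area, window=window,
            rng_seed=file_seeds[-1], observed_max=stats.max_value,
        )
        return GW6Results(
            study=self, per_file_sync1=per_file, group_sync1=group_curve,
            pool=pool, null_mean=null_curve, area=stats, mc=mc,
            area_window=window, seed=seed,
        )


@dataclass
class GW6Results:
    """Group-level estimates, their surrogate null and the exceedance test."""

    study: GW6Study
    per_file_sync1: np.ndarray
    group_sync1: np.ndarray
    pool: SurrogatePool
    null_mean: np.ndarray
    area: AreaStats
    mc: MCResult
    area_window: tuple[int, int]
    seed: object = None

    @property
    def pvalue(self) -> float:
        return self.mc.p_estimate

    def times_ms(self) -> np.ndarray:
        cfg = self.study.config
        rate = self.study.sessions[0][0].sampling_rate
        pre = cfg.epoch.pre_samples(rate)
        return (np.arange(self.group_sync1.size) - pre) / rate * 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_sync1": self.group_sync1,
                "surrogate_mean": self.null_mean,
                "excess": self.group_sync1 - self.null_mean,
            },
            index=pd.Index(self.times_ms(), name="time_ms"),
        )

    def summary(self) -> str:
        cfg = self.study.config
        rate = self.study.sessions[0][0].sampling_rate
        lo, hi = self.area_window
        lines = [
            "GW6 group analysis",
            "==================",
            f"files:                {len(self.study.sessions)}",
            f"band (Hz):            {cfg.band.label()}",
            f"epoch (s):            {cfg.epoch.pre_s}/{cfg.epoch.stim_s}/{cfg.epoch.post_s}"
            f"  ({cfg.epoch.n_samples(rate)} samples)",
            f"corr window (samples):{cfg.window_len:>5}",
            f"surrogate pool:       {self.pool.size} curves",
            f"area window (samples):[{lo}, {hi})",
            "",
            f"area difference:      {self.area.area:.4f}",
            f"maximum value:        {self.area.max_value:.4f}",
            f"Monte Carlo cycles:   {self.mc.n_cycles}",
            f"exceedances:          {self.mc.exceed_count}",
            f"probability:          {self.mc.p_label}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Group Sync1 (red) vs surrogate-pool mean (blue), correlation × 100."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.times_ms()
        ax.plot(t, self.group_sync1 * 100, color="crimson", label="group Sync1")
        ax.plot(t, self.null_mean * 100, color="royalblue", label="surrogate mean")
        _shade_stimulus(ax, self.study.config, self.study.sessions[0][0].sampling_rate)
        ax.set_xlabel("time from stimulus onset (ms)")
        ax.set_ylabel("correlation × 100")
        ax.legend()
        return ax

    def plot_null(self, ax=None):
        """Histogram of null areas with the observed area marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.mc.null_areas, bins=40, color="steelblue")
        ax.axvline(self.area.area, color="red", label=f"observed ({self.mc.p_label})")
        ax.set_xlabel("null area difference")
        ax.set_ylabel("count")
        ax.legend()
        return ax
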