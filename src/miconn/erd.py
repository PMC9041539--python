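"""Event-related desynchronisation / synchronisation (ERD/ERS) quantification.

ERD% = 100 * (A - R) / R, where R is the mean band power over the pre-event
baseline (fixation, -2-0 s) and A the band power after the event. The time
course follows the classic four steps: band-pass each trial, square the
samples, average power across trials, smooth over time. Negative values are
desynchronisation (power suppression), positive values synchronisation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from . import stats as _stats
from .preprocess import ALPHA, BandDefinition, TrialSet, filter_band


@dataclass
class ERDTimeCourse:
    """Percent band-power change per channel and time point."""

    values: np.ndarray  # (n_channels, n_samples), percent
    time_axis: np.ndarray
    channel_labels: list[str]
    band: BandDefinition
    baseline_window: tuple[float, float]
    smoothing_len: float

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]


def erd_timecourse(
    trials: TrialSet,
    band: BandDefinition = ALPHA,
    baseline: tuple[float, float] = (-2.0, 0.0),
    smoothing_len: float = 0.25,
) -> ERDTimeCourse:
    """ERD/ERS time course of one (condition, hand) trial set.

    Parameters
    ----------
    trials
        Epoched trials; the baseline window must lie inside the epoch.
    band
        Frequency band; alpha (8-13 Hz) is the canonical MI index.
    baseline
        Reference window in seconds relative to MI onset.
    smoothing_len
        Moving-average length in seconds (0.25 s: shorter than ERD dynamics,
        longer than one alpha cycle).
    """
    if trials.n_trials < 2:
        raise ValueError("need at least 2 trials for a power average")
    t = trials.time_axis
    base_mask = (t >= baseline[0] - 1e-9) & (t < baseline[1] - 1e-9)
    if not base_mask.any():
        raise ValueError(f"baseline window {baseline} lies outside the epoch")
    filtered = filter_band(trials.epochs, trials.fs, band)
    power = np.mean(filtered**2, axis=0)  # (channels, samples)
    size = max(1, int(round(smoothing_len * trials.fs)))
    smoothed = uniform_filter1d(power, size=size, axis=-1, mode="nearest")
    r = smoothed[:, base_mask].mean(axis=1, keepdims=True)
    if np.any(r <= 0):
        bad = [trials.channel_labels[i] for i in np.where(r[:, 0] <= 0)[0]]
        raise ZeroDivisionError(f"zero baseline power on channels {bad}")
    values = 100.0 * (smoothed - r) / r
    return ERDTimeCourse(
        values=values,
        time_axis=t.copy(),
        channel_labels=list(trials.channel_labels),
        band=band,
        baseline_window=baseline,
        smoothing_len=smoothing_len,
    )


def erd_summary(tc: ERDTimeCourse, window: tuple[float, float] = (0.0, 5.0)) -> pd.Series:
    """Time-average ERD% per channel over ``window`` (default 0-5 s of MI)."""
    mask = (tc.time_axis >= window[0] - 1e-9) & (tc.time_axis < window[1] - 1e-9)
    if not mask.any():
        raise ValueError(f"summary window {window} contains no samples")
    return pd.Series(tc.values[:, mask].mean(axis=1), index=tc.channel_labels, name="erd_percent")


def lateralization_test(
    contralateral: np.ndarray, ipsilateral: np.ndarray
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of per-subject contralateral vs
    ipsilateral ERD summaries (two-sided). Returns (statistic, p)."""
    contralateral = np.asarray(contralateral, dtype=float)
    ipsilateral = np.asarray(ipsilateral, dtype=float)
    if contralateral.shape != ipsilateral.shape or contralateral.ndim != 1:
        raise ValueError("need two equal-length 1-D per-subject vectors")
    if contralateral.size < 5:
        raise ValueError("need >= 5 paired subject values")
    res = _stats.wilcoxon_signed_rank(contralateral, ipsilateral)
    return res.statistic, res.pvalue
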