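"""Synthetic motor-imagery EEG with planted, parameterised ground truth.

Each session follows the three-condition MI paradigm: trials of fixation
(-2-0 s), motor imagery (0-10 s) and rest (10-13 s); three conditions
(tMI, rmMI, bcMI) x two hands x 20 trials = 120 trials per session.

Signal model per trial and channel:

* background: broadband Gaussian noise plus a weak 1/f component, giving an
  EEG-like spectrum without modelling artifacts;
* an alpha-band (8-13 Hz) oscillation on the motor channels C3/C4, realised
  as narrowband-filtered noise (nonzero bandwidth, so event-related
  desynchronisation estimation faces realistic envelope variability); its
  amplitude is multiplied by ``erd_depth`` on the hand-contralateral channel
  during the MI stage only — the planted ERD;
* optional directed couplings: the sink channel receives the band-limited
  source signal delayed by ``lag`` samples and scaled by ``strength``,
  restricted to the MI stage and to the coupling's conditions — the planted
  effective-connectivity ground truth.

A single session seed deterministically spawns independent per-trial streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import (
    ALPHA,
    BandDefinition,
    ConfigError,
    EEGRecording,
    Event,
    filter_band,
)

#: The nine analysis channels of the frontal/central/parietal montage.
NINE_CHANNELS = ["F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4"]

#: Contralateral mapping: imagining a hand suppresses alpha on the opposite
#: motor channel (C3 is contralateral to the right hand).
CONTRALATERAL = {"left": "C4", "right": "C3"}


@dataclass(frozen=True)
class Coupling:
    """Planted directed interaction source -> sink.

    lag is in native samples; strength scales the band-limited source signal
    added into the sink during the MI stage of trials whose condition is in
    ``conditions``.
    """

    source: str
    sink: str
    conditions: tuple[str, ...]
    lag: int
    strength: float
    band: BandDefinition

    def as_record(self) -> dict:
        rec = asdict(self)
        rec["conditions"] = list(self.conditions)
        rec["band"] = {"name": self.band.name, "lo": self.band.lo, "hi": self.band.hi}
        return rec


@dataclass
class SynthConfig:
    """Parameters of one synthetic session; defaults are the study paradigm."""

    channels: list[str] = field(default_factory=lambda: list(NINE_CHANNELS))
    fs_native: float = 1000.0
    n_trials_per_hand: int = 20
    conditions: tuple[str, ...] = ("tMI", "rmMI", "bcMI")
    hands: tuple[str, ...] = ("left", "right")
    stage_durations: tuple[float, float, float] = (2.0, 10.0, 3.0)  # fixation, MI, rest (s)
    erd_channels: dict = field(default_factory=lambda: dict(CONTRALATERAL))
    erd_depth: float = 0.5
    alpha_band: BandDefinition = ALPHA
    alpha_amp: float = 1.0
    couplings: tuple[Coupling, ...] = ()
    noise_sd: float = 1.0
    pink_weight: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channels: labels must be unique")
        if self.fs_native <= 0:
            raise ConfigError(f"fs_native: must be positive, got {self.fs_native}")
        if self.n_trials_per_hand < 1:
            raise ConfigError("n_trials_per_hand: must be >= 1")
        if len(self.stage_durations) != 3 or any(d < 0 for d in self.stage_durations):
            raise ConfigError("stage_durations: need three nonnegative durations")
        if not (0 < self.erd_depth <= 1):
            raise ConfigError(f"erd_depth: must be in (0, 1], got {self.erd_depth}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be nonnegative")
        for hand in self.hands:
            ch = self.erd_channels.get(hand)
            if ch is not None and ch not in self.channels:
                raise ConfigError(f"erd_channels: {ch!r} (hand {hand!r}) not in channels")
        for c in self.couplings:
            if c.source not in self.channels or c.sink not in self.channels:
                raise ConfigError(f"couplings: {c.source}->{c.sink} uses unknown channel")
            if c.lag < 1:
                raise ConfigError(f"couplings: lag must be >= 1, got {c.lag}")
            unknown = set(c.conditions) - set(self.conditions)
            if unknown:
                raise ConfigError(f"couplings: unknown conditions {sorted(unknown)}")

    @property
    def trial_duration(self) -> float:
        return float(sum(self.stage_durations))

    @property
    def n_trials(self) -> int:
        return len(self.conditions) * len(self.hands) * self.n_trials_per_hand


@dataclass
class GroundTruth:
    """What was planted: trial labels, ERD factors, directed edges per condition."""

    trials: list[dict]
    erd_factors: dict  # hand -> {channel: amplitude factor during MI}
    edges: dict  # condition -> list of coupling records

    def to_json_dict(self) -> dict:
        return {"trials": self.trials, "erd_factors": self.erd_factors, "edges": self.edges}

    def planted_pairs(self, condition: str) -> set[tuple[str, str]]:
        return {(e["source"], e["sink"]) for e in self.edges.get(condition, [])}


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _narrowband(rng: np.random.Generator, n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Unit-RMS narrowband noise carrier (naturally amplitude-modulated)."""
    carrier = filter_band(rng.standard_normal(n), fs, band)
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / rms if rms > 0 else carrier


def _stage_mask(n: int, fs: float, start_s: float, stop_s: float) -> np.ndarray:
    mask = np.zeros(n)
    i0, i1 = int(round(start_s * fs)), int(round(stop_s * fs))
    mask[i0:i1] = 1.0
    return mask


def generate_session(config: SynthConfig) -> tuple[EEGRecording, list[Event], GroundTruth]:
    """Generate one continuous session with events and ground-truth record.

    Trials are concatenated in a seed-determined shuffled order; each event
    marks the MI onset (end of the fixation stage). Same config + same seed
    gives identical samples.
    """
    config.validate()
    fs = config.fs_native
    fix_d, mi_d, rest_d = config.stage_durations
    n_trial = int(round(config.trial_duration * fs))
    mi_mask = _stage_mask(n_trial, fs, fix_d, fix_d + mi_d)
    ch_idx = {ch: i for i, ch in enumerate(config.channels)}
    motor_channels = sorted(set(config.erd_channels.values()))

    cells = [
        (cond, hand)
        for cond in config.conditions
        for hand in config.hands
        for _ in range(config.n_trials_per_hand)
    ]
    ss = np.random.SeedSequence(config.seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    order = order_rng.permutation(len(cells))
    trial_seeds = ss.spawn(len(cells) + 1)[1:]

    data = np.empty((len(config.channels), n_trial * len(cells)))
    events: list[Event] = []
    trial_records: list[dict] = []
    for slot, cell_i in enumerate(order):
        cond, hand = cells[cell_i]
        rng = np.random.default_rng(trial_seeds[slot])
        trial = np.zeros((len(config.channels), n_trial))
        for ch in config.channels:
            bg = rng.standard_normal(n_trial) + config.pink_weight * _pink_noise(rng, n_trial)
            trial[ch_idx[ch]] = config.noise_sd * bg
        erd_target = config.erd_channels.get(hand)
        for ch in motor_channels:
            carrier = config.alpha_amp * _narrowband(rng, n_trial, fs, config.alpha_band)
            envelope = np.ones(n_trial)
            if ch == erd_target:
                envelope -= (1.0 - config.erd_depth) * mi_mask
            trial[ch_idx[ch]] += carrier * envelope
        base = trial.copy()  # couplings read pre-coupling signals: order-independent
        for c in config.couplings:
            if cond not in c.conditions:
                continue
            src = filter_band(base[ch_idx[c.source]], fs, c.band)
            shifted = np.zeros(n_trial)
            shifted[c.lag :] = src[: -c.lag]
            trial[ch_idx[c.sink]] += c.strength * shifted * mi_mask
        start = slot * n_trial
        data[:, start : start + n_trial] = trial
        events.append(Event(sample=start + int(round(fix_d * fs)), condition=cond, hand=hand))
        trial_records.append({"index": slot, "condition": cond, "hand": hand})

    erd_factors = {
        hand: {ch: (config.erd_depth if ch == config.erd_channels.get(hand) else 1.0)
               for ch in motor_channels}
        for hand in config.hands
    }
    edges = {
        cond: [c.as_record() for c in config.couplings if cond in c.conditions]
        for cond in config.conditions
    }
    gt = GroundTruth(trials=trial_records, erd_factors=erd_factors, edges=edges)
    rec = EEGRecording(data=data, fs=fs, channel_labels=list(config.channels), events=events)
    return rec, events, gt


@dataclass(frozen=True)
class CoupledPair:
    """Lagged linear coupling X -> Y with the generating parameters attached.

    X is white Gaussian; Y_t = c * X_{t-lag} + eps_t, eps ~ N(0, sd_noise^2).
    The population transfer entropy X->Y is 0.5 * ln(1 + c^2 / sd_noise^2)
    nats; Y->X is exactly zero.
    """

    x: np.ndarray
    y: np.ndarray
    c: float
    lag: int
    sd_noise: float
    seed: int

    @property
    def population_te(self) -> float:
        return 0.5 * np.log1p(self.c**2 / self.sd_noise**2)


def generate_coupled_ar(
    n: int, c: float, lag: int = 1, sd_noise: float = 1.0, seed: int = 0
) -> CoupledPair:
    """Reference pair with analytically known transfer entropy."""
    if n < 100:
        raise ValueError(f"n must be >= 100, got {n}")
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if sd_noise <= 0:
        raise ValueError(f"sd_noise must be positive, got {sd_noise}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.normal(0.0, sd_noise, n)
    y[lag:] += c * x[:-lag]
    return CoupledPair(x=x, y=y, c=c, lag=lag, sd_noise=sd_noise, seed=seed)
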