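"""Experiment orchestration: synth -> preprocess -> {erd, cspclf, te} -> stats.

One ``ExperimentConfig`` describes a whole synthetic cohort study; a master
seed deterministically spawns per-subject and per-stage streams
(``np.random.SeedSequence(master, spawn_key=...)``), so the same config
reproduces identical numeric tables. Every output table carries the config
hash and seed in the provenance record.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import erd as erd_mod
from . import io as io_mod
from . import stats as stats_mod
from .cspclf import cross_validate
from .preprocess import (
    ALPHA,
    BETA_CLF,
    BETA_TE,
    GAMMA,
    BROADBAND,
    BandDefinition,
    EEGRecording,
    TrialSet,
    bandpass,
    downsample,
    epoch,
)
from .synth import CONTRALATERAL, Coupling, GroundTruth, SynthConfig, generate_session
from .te import EmbeddingParams, TEMatrix, relative_te, te_matrix


def subject_seed(master: int, subject: int, stage: int = 0) -> int:
    """Stable per-subject/per-stage seed below 2**31."""
    ss = np.random.SeedSequence(master, spawn_key=(subject, stage))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ExperimentConfig:
    """Full study description; defaults mirror the MI paradigm."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    n_subjects: int = 14
    fs_target: float = 250.0
    epoch_window: tuple[float, float] = (-2.0, 13.0)
    erd_band: BandDefinition = ALPHA
    erd_summary_window: tuple[float, float] = (0.0, 5.0)
    clf_bands: tuple[BandDefinition, ...] = (ALPHA, BETA_CLF)
    clf_m: int = 5
    cv_k: int = 10
    cv_repeats: int = 100
    te_bands: tuple[BandDefinition, ...] = (BETA_TE,)
    mi_window: tuple[float, float] = (0.0, 10.0)
    baseline_window: tuple[float, float] = (-2.0, 0.0)
    te_params: EmbeddingParams | None = None
    te_max_points: int = 2000
    te_channels: list[str] | None = None
    contrasts: tuple[tuple[str, str], ...] = (("rmMI", "tMI"), ("bcMI", "rmMI"))
    alpha: float = 0.05
    seed: int = 0
    stages: tuple[str, ...] = ("erd", "classify", "te")

    def validate(self) -> None:
        self.synth.validate()
        for a, b in self.contrasts:
            for cond in (a, b):
                if cond not in self.synth.conditions:
                    raise ValueError(f"contrast condition {cond!r} not generated by synth config")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    erd: pd.DataFrame | None
    lateralization: pd.DataFrame | None
    accuracy: pd.DataFrame | None
    contrasts: dict
    provenance: dict
    log: list = field(default_factory=list)

    def write_outputs(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("erd_summary.csv", self.erd),
            ("lateralization.csv", self.lateralization),
            ("accuracy.csv", self.accuracy),
        ]:
            if df is not None:
                path = outdir / name
                df.to_csv(path, index=False, float_format="%.10g")
                written.append(path)
        if self.contrasts:
            frames = []
            for (band, hand, name), contrast in sorted(self.contrasts.items()):
                t = contrast.table.copy()
                t.insert(0, "contrast", name)
                t.insert(0, "hand", hand)
                t.insert(0, "band", band)
                frames.append(t)
            path = outdir / "contrasts.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
            written.append(path)
        path = outdir / "provenance.json"
        path.write_text(json.dumps(self.provenance, indent=1, sort_keys=True))
        written.append(path)
        return written


def preprocess_session(
    rec: EEGRecording,
    fs_target: float = 250.0,
    epoch_window: tuple[float, float] = (-2.0, 13.0),
    subject_id: str | None = None,
) -> dict[tuple[str, str], TrialSet]:
    """Standard conditioning chain: broadband filter, decimate, epoch."""
    filtered = bandpass(rec, BROADBAND)
    decimated = downsample(filtered, fs_target)
    trial_sets = epoch(decimated, epoch_window, subject_id=subject_id)
    return {(ts.condition, ts.hand): ts for ts in trial_sets}


def generate_subject(cfg: ExperimentConfig, subject: int):
    """Generate and preprocess one subject's session."""
    sc = replace(cfg.synth, seed=subject_seed(cfg.seed, subject))
    rec, _, gt = generate_session(sc)
    trials = preprocess_session(
        rec, cfg.fs_target, cfg.epoch_window, subject_id=f"sub-{subject:02d}"
    )
    return trials, gt


def run_experiment(cfg: ExperimentConfig, outdir: str | Path | None = None) -> ExperimentResult:
    """Run the configured cohort study and return (optionally write) tables."""
    cfg.validate()
    t_start = time.time()
    log: list[str] = []
    subjects = list(range(cfg.n_subjects))
    all_trials: dict[int, dict] = {}
    gt: GroundTruth | None = None
    for s in subjects:
        all_trials[s], gt = generate_subject(cfg, s)
    log.append(f"synth+preprocess: {cfg.n_subjects} subjects in {time.time() - t_start:.1f}s")

    erd_df = None
    lat_df = None
    if "erd" in cfg.stages:
        t0 = time.time()
        rows = []
        for s in subjects:
            for (cond, hand), ts in all_trials[s].items():
                tc = erd_mod.erd_timecourse(ts, band=cfg.erd_band,
                                            baseline=cfg.baseline_window)
                summary = erd_mod.erd_summary(tc, cfg.erd_summary_window)
                for ch, val in summary.items():
                    rows.append((s, cond, hand, ch, val))
        erd_df = pd.DataFrame(rows, columns=["subject", "condition", "hand", "channel",
                                             "erd_percent"])
        lat_rows = []
        for cond in cfg.synth.conditions:
            for hand in cfg.synth.hands:
                contra_ch = CONTRALATERAL[hand]
                ipsi_ch = CONTRALATERAL["left" if hand == "right" else "right"]
                sub = erd_df[(erd_df.condition == cond) & (erd_df.hand == hand)]
                contra = sub[sub.channel == contra_ch].sort_values("subject").erd_percent.values
                ipsi = sub[sub.channel == ipsi_ch].sort_values("subject").erd_percent.values
                if contra.size >= 5:
                    stat, p = erd_mod.lateralization_test(contra, ipsi)
                    lat_rows.append((cond, hand, contra_ch, ipsi_ch, stat, p))
        if lat_rows:
            lat_df = pd.DataFrame(lat_rows, columns=["condition", "hand", "contra", "ipsi",
                                                     "statistic", "p"])
            lat_df["p_adj"] = stats_mod.fdr_adjust(lat_df["p"].values)
        log.append(f"erd: {time.time() - t0:.1f}s")

    acc_df = None
    if "classify" in cfg.stages:
        t0 = time.time()
        rows = []
        for s in subjects:
            for cond in cfg.synth.conditions:
                left = all_trials[s][(cond, "left")].crop(cfg.mi_window)
                right = all_trials[s][(cond, "right")].crop(cfg.mi_window)
                res = cross_validate(
                    left, right, cfg.clf_bands, m=cfg.clf_m, k=cfg.cv_k,
                    repeats=cfg.cv_repeats, seed=subject_seed(cfg.seed, s, stage=1),
                )
                rows.append((s, cond, 100 * res.mean, 100 * res.sd))
        acc_df = pd.DataFrame(rows, columns=["subject", "condition", "accuracy_percent",
                                             "sd_percent"])
        log.append(f"classify: {time.time() - t0:.1f}s")

    contrasts: dict = {}
    if "te" in cfg.stages:
        t0 = time.time()
        needed = sorted({c for pair in cfg.contrasts for c in pair})
        rel: dict[tuple[int, str, str, str], TEMatrix] = {}
        for s in subjects:
            for cond in needed:
                for hand in cfg.synth.hands:
                    ts = all_trials[s][(cond, hand)]
                    for band in cfg.te_bands:
                        mi = te_matrix(ts, band, cfg.mi_window, channels=cfg.te_channels,
                                       params=cfg.te_params, window_label="mi",
                                       max_points=cfg.te_max_points)
                        base = te_matrix(ts, band, cfg.baseline_window,
                                         channels=cfg.te_channels, params=cfg.te_params,
                                         window_label="baseline",
                                         max_points=cfg.te_max_points)
                        rel[(s, cond, hand, band.name)] = relative_te(mi, base)
        for band in cfg.te_bands:
            for hand in cfg.synth.hands:
                for (a, b) in cfg.contrasts:
                    te_a = [rel[(s, a, hand, band.name)] for s in subjects]
                    te_b = [rel[(s, b, hand, band.name)] for s in subjects]
                    contrast = stats_mod.contrast_conditions(te_a, te_b, alpha=cfg.alpha)
                    contrast.contrast = f"{a}-{b}"
                    contrasts[(band.name, hand, f"{a}-{b}")] = contrast
        log.append(f"te+contrasts: {time.time() - t0:.1f}s")

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "stages": list(cfg.stages),
        "planted_edges": gt.edges if gt is not None else {},
    }
    result = ExperimentResult(erd=erd_df, lateralization=lat_df, accuracy=acc_df,
                              contrasts=contrasts, provenance=provenance)
    result.log = log
    if outdir is not None:
        result.write_outputs(outdir)
        (Path(outdir) / "run.log").write_text("\n".join(log) + "\n")
    return result


def tiny_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Down-scaled study used by tests and fixtures: 2 s MI stage, 4 trials
    per condition, fixed TE embedding. Structure matches the full paradigm."""
    synth = SynthConfig(
        n_trials_per_hand=2,
        stage_durations=(2.0, 2.0, 1.0),
        seed=seed,
    )
    defaults = dict(
        synth=synth,
        n_subjects=2,
        epoch_window=(-2.0, 3.0),
        erd_summary_window=(0.0, 2.0),
        mi_window=(0.0, 2.0),
        cv_k=2,
        cv_repeats=2,
        clf_m=1,
        te_params=EmbeddingParams(d=1, tau=1, u=1, K=4, theiler=1),
        te_max_points=400,
        contrasts=(("bcMI", "tMI"),),
        seed=seed,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


def planted_contrast_study(
    seed: int,
    n_subjects: int = 14,
    couplings: tuple[Coupling, ...] | None = None,
    plant_condition: str = "bcMI",
    reference_condition: str = "tMI",
    hand: str = "right",
    band: BandDefinition = BETA_TE,
    n_trials_per_hand: int = 4,
    strength: float = 1.0,
    alpha: float = 0.05,
    te_max_points: int = 400,
) -> dict:
    """One end-to-end recovery replicate at the down-scaled study size.

    Plants directed couplings in one condition only (or none, for a null
    replicate when ``couplings=()``), runs the full pipeline for one hand and
    band, and scores the retained-edge mask against the plant. Returns recall
    (fraction of planted edges retained) and the fraction of the 72-pair
    family retained overall.
    """
    if couplings is None:
        couplings = (
            Coupling("Pz", "Cz", (plant_condition,), lag=4, strength=strength, band=band),
            Coupling("P3", "F4", (plant_condition,), lag=4, strength=strength, band=band),
        )
    synth = SynthConfig(
        n_trials_per_hand=n_trials_per_hand,
        conditions=(reference_condition, plant_condition),
        hands=(hand,),
        stage_durations=(2.0, 2.0, 1.0),
        couplings=couplings,
        seed=seed,
    )
    cfg = ExperimentConfig(
        synth=synth,
        n_subjects=n_subjects,
        epoch_window=(-2.0, 3.0),
        mi_window=(0.0, 2.0),
        te_bands=(band,),
        te_params=EmbeddingParams(d=1, tau=1, u=1, K=4, theiler=1),
        te_max_points=te_max_points,
        contrasts=((plant_condition, reference_condition),),
        alpha=alpha,
        seed=seed,
        stages=("te",),
    )
    result = run_experiment(cfg)
    contrast = result.contrasts[(band.name, hand, f"{plant_condition}-{reference_condition}")]
    planted = {(c.source, c.sink) for c in couplings}
    retained = set(contrast.retained_edges)
    # a planted edge counts as recovered only if its direction matches the plant
    correct_dir = {
        (r.source, r.sink)
        for r in contrast.table.itertuples()
        if r.retained and r.direction == "A"
    }
    recall = len(planted & correct_dir) / len(planted) if planted else float("nan")
    return {
        "contrast": contrast,
        "planted": planted,
        "retained": retained,
        "recall": recall,
        "retained_fraction": len(retained) / len(contrast.table),
    }


def make_fixtures(outdir: str | Path, size: str = "tiny") -> list[Path]:
    """Write deterministic delimited-format sessions for file-based tests.

    ``tiny``: 2 subjects, 4 trials per condition (2 per hand), 2 s MI stage.
    ``default``: 1 subject at the full paradigm (large; runtime use only).
    """
    outdir = Path(outdir)
    if size == "tiny":
        template = SynthConfig(n_trials_per_hand=4, stage_durations=(2.0, 2.0, 1.0))
        n_subjects = 2
    elif size == "default":
        template = SynthConfig()
        n_subjects = 1
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    paths = []
    for s in range(n_subjects):
        sc = replace(template, seed=subject_seed(1234, s))
        rec, _, gt = generate_session(sc)
        paths.append(io_mod.save_session(outdir / f"sub-{s:02d}", rec, gt))
    return paths
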