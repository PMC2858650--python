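"""End-to-end orchestration: simulate -> preprocess -> peaks -> PLS ->
ANOVAs -> behavior, with YAML configuration and deterministic seeding.

A run writes, under its output directory: the resolved configuration, a
rejection log, the evoked container, the peak table, PLS result JSON +
salience TSVs (mean-centered per stimulus; non-rotated per group x
stimulus), ANOVA tables, and the behavioral d'/t-test/correlation
outputs.  One master seed deterministically derives every module seed;
re-running the same configuration reproduces all payloads bit-exactly
(wall-clock metadata goes only to the log stream).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import peaks as pk
from . import pls as pls_mod
from . import preprocess as pp
from .anova import RepeatedMeasuresAnova
from .containers import StudyDataset, write_evokeds
from .errors import ConfigError
from .montage import Montage, default_montage
from .simulate import (EffectPlan, SimConfig, default_effect_plan,
                       iter_study_blocks, _simulate_study_behavior)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("aepstats")


@dataclass
class RunConfig:
    """Resolved run configuration; nested blocks mirror the pipeline."""

    seed: int = 0
    # simulation block
    n_subjects_per_group: int = 10
    sessions: tuple[int, ...] = (1, 2, 3, 4)
    trials_per_block: int = 400
    noise_sd: float = 15.0
    artifact_rate: float = 0.05
    p2_gain: dict = field(default_factory=lambda: {
        "1": {"2": 0.5, "3": 1.0}, "2": {"2": 1.0, "3": 2.0}})
    gain_region: tuple[str, ...] = ("TP9", "IZ", "TP10")
    retention_decay: dict = field(default_factory=lambda: {"1": 0.1, "2": 0.8})
    # preprocessing block
    baseline: tuple[float, float] = (-100.0, 0.0)
    reject_threshold: float = 70.0
    hp_hz: float = 1.0
    lp_hz: float = 20.0
    # analysis block
    peak_windows: dict = field(default_factory=lambda: {
        "P1": [80.0, 160.0], "N1": [120.0, 220.0], "P2": [190.0, 320.0]})
    pls_window: tuple[float, float] = (0.0, 300.0)
    n_perm: int = 500
    n_boot: int = 500
    bsr_threshold: float = 3.0
    nr_contrast: tuple[float, ...] = (-1.0, 0.0, 1.0)
    save_epochs: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigError("resample counts must be >= 1")

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_subjects_per_group=self.n_subjects_per_group,
            sessions=tuple(self.sessions),
            trials_per_block=self.trials_per_block,
            noise_sd=self.noise_sd, artifact_rate=self.artifact_rate,
            seed=self.seed)

    def effect_plan(self) -> EffectPlan:
        gains = {(int(g), int(s)): float(v)
                 for g, by_s in self.p2_gain.items()
                 for s, v in by_s.items()}
        return EffectPlan(p2_gain=gains, region=tuple(self.gain_region),
                          retention_decay={int(g): float(v)
                                           for g, v in self.retention_decay.items()})

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        for key in ("sessions", "gain_region", "nr_contrast", "baseline",
                    "pls_window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())


def _tsv(df: pd.DataFrame, path: Path, header_meta: dict) -> None:
    with open(path, "w") as f:
        for k, v in sorted(header_meta.items()):
            f.write(f"# {k}={v}\n")
        df.to_csv(f, sep="\t", index=False)


def preprocess_study(study_blocks, montage: Montage, cfg: RunConfig):
    """Preprocess streamed (key, EpochSet) blocks into evokeds + log."""
    evokeds, logs = {}, []
    for key, ep in study_blocks:
        ev, rej = pp.preprocess_block(
            ep, montage, baseline=tuple(cfg.baseline),
            threshold=cfg.reject_threshold, hp=cfg.hp_hz, lp=cfg.lp_hz)
        evokeds[key] = ev
        logs.append(rej)
    rejection_log = (pd.concat(logs, ignore_index=True) if logs
                     else pd.DataFrame())
    return evokeds, rejection_log


def _pls_stage(evokeds, montage, cfg: RunConfig, meta, outdir: Path) -> dict:
    """Mean-centered PLS per stimulus (sessions 1-3) and non-rotated PLS
    per group x stimulus with the linear session contrast."""
    out = {}
    pls_dir = outdir / "pls"
    pls_dir.mkdir(exist_ok=True)
    sessions123 = sorted({k[2] for k in evokeds} & {1, 2, 3})
    stimuli = sorted({k[3] for k in evokeds})
    if len(sessions123) < 2:
        log.warning("PLS skipped: fewer than 2 sessions in 1..3")
        (pls_dir / "SKIPPED.txt").write_text(
            "PLS skipped: fewer than 2 sessions available\n")
        return out
    seed_mc, seed_nr = np.random.SeedSequence(cfg.seed).generate_state(2) >> 1
    for stim in stimuli:
        sel = {k: v for k, v in evokeds.items()
               if k[3] == stim and k[2] in sessions123}
        dm = pls_mod.assemble_data_matrix(sel, montage,
                                          window=tuple(cfg.pls_window))
        res = pls_mod.fit_mc_pls(dm, n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                                 seed=int(seed_mc),
                                 bsr_threshold=cfg.bsr_threshold)
        res.save_json(pls_dir / f"mc_{stim}.json")
        _tsv(res.salience_table(0), pls_dir / f"mc_{stim}_lv1_salience.tsv", meta)
        out[("mc", stim)] = res
        if len(sessions123) == len(cfg.nr_contrast):
            for g in sorted({k[1] for k in sel}):
                sub = {k: v for k, v in sel.items() if k[1] == g}
                dmg = pls_mod.assemble_data_matrix(sub, montage,
                                                   window=tuple(cfg.pls_window))
                rng = pls_mod.fit_nr_pls(dmg, contrast=cfg.nr_contrast,
                                         n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                                         seed=int(seed_nr),
                                         bsr_threshold=cfg.bsr_threshold)
                rng.save_json(pls_dir / f"nr_g{g}_{stim}.json")
                out[("nr", g, stim)] = rng
    return out


def _anova_stage(peak_table: pd.DataFrame, cfg: RunConfig, meta,
                 outdir: Path) -> dict:
    """P2 amplitude/latency ANOVAs at Cz and the two electrode ROIs over
    sessions 1-3, plus the session-4 retention contrasts at the
    temporal-occipital electrodes."""
    adir = outdir / "anova"
    adir.mkdir(exist_ok=True)
    out = {}
    p2 = peak_table[peak_table["component"] == "P2"]
    sessions = sorted(p2["session"].unique())
    s123 = [s for s in sessions if s in (1, 2, 3)]
    if len(s123) < 2:
        log.warning("session ANOVAs skipped: fewer than 2 sessions")
        (adir / "SKIPPED.txt").write_text(
            "session ANOVAs skipped: fewer than 2 sessions available\n")
        return out
    base = p2[p2["session"].isin(s123)]
    designs = {
        "cz": (base[base["electrode"] == "CZ"], ["stimulus", "session"]),
        "anterior_central": (
            base[base["electrode"].isin(pk.ROIS["anterior-central"].electrodes)],
            ["stimulus", "session", "electrode"]),
        "temporal_occipital": (
            base[base["electrode"].isin(pk.ROIS["temporal-occipital"].electrodes)],
            ["stimulus", "session", "electrode"]),
    }
    for name, (df, within) in designs.items():
        for dv in ("amplitude", "latency"):
            model = RepeatedMeasuresAnova(df, dv=dv, subject="subject",
                                          within=within, between="group")
            res = model.fit()
            out[(name, dv)] = res
            _tsv(res.anova_table, adir / f"{name}_{dv}.tsv", meta)
    # retention: temporal-occipital electrodes, session pairs (1,4), (3,4)
    if 4 in sessions:
        to_el = pk.ROIS["temporal-occipital"].electrodes
        for s_ref in (1, 3):
            df = p2[(p2["electrode"].isin(to_el))
                    & (p2["session"].isin([s_ref, 4]))]
            model = RepeatedMeasuresAnova(
                df, dv="amplitude", subject="subject",
                within=["stimulus", "session", "electrode"], between="group")
            res = model.fit()
            out[(f"retention_{s_ref}v4", "amplitude")] = res
            _tsv(res.anova_table, adir / f"retention_{s_ref}v4.tsv", meta)
    return out


def _behavior_stage(behavior: pd.DataFrame, evokeds, cfg: RunConfig, meta,
                    outdir: Path) -> dict:
    bdir = outdir / "behavior"
    bdir.mkdir(exist_ok=True)
    out = {}
    if behavior.empty:
        (bdir / "SKIPPED.txt").write_text("no behavioral logs in dataset\n")
        return out
    dp = beh.dprime_table(behavior)
    _tsv(dp, bdir / "dprime.tsv", meta)
    out["dprime"] = dp
    tests = {}
    g2 = dp[dp["group"] == 2].pivot(index="subject", columns="session",
                                    values="dprime")
    if {1, 2, 3} <= set(g2.columns):
        long = dp[(dp["group"] == 2) & (dp["session"].isin([1, 2, 3]))]
        res = RepeatedMeasuresAnova(long, dv="dprime", subject="subject",
                                    within=["session"]).fit()
        out["dprime_anova"] = res
        _tsv(res.anova_table, bdir / "dprime_anova.tsv", meta)
    if {1, 2} <= set(g2.columns):
        tests["s2_vs_s1_one_tailed"] = beh.paired_t(
            g2[2].to_numpy(), g2[1].to_numpy(), tail="greater")
    if {1, 4} <= set(g2.columns):
        tests["s1_vs_s4"] = beh.paired_t(g2[1].to_numpy(), g2[4].to_numpy())
    if {3, 4} <= set(g2.columns):
        tests["s3_vs_s4"] = beh.paired_t(g2[3].to_numpy(), g2[4].to_numpy())
    g1s4 = dp[(dp["group"] == 1) & (dp["session"] == 4)]["dprime"]
    g2s4 = dp[(dp["group"] == 2) & (dp["session"] == 4)]["dprime"]
    if len(g1s4) >= 2 and len(g2s4) >= 2:
        tests["group1_vs_group2_s4"] = beh.independent_t(
            g1s4.to_numpy(), g2s4.to_numpy())
    out["t_tests"] = tests
    with open(bdir / "t_tests.json", "w") as f:
        json.dump(tests, f, sort_keys=True, indent=1)
    # brain-behavior correlations: mean 190-290 ms P2 at CZ and TO ROI
    p2_rows = []
    for key, ev in evokeds.items():
        subject, group, session, stim = key
        if group != 2 or stim != "mba":
            continue
        for loc, where in (("CZ", "CZ"),
                           ("temporal-occipital",
                            pk.ROIS["temporal-occipital"])):
            p2_rows.append(dict(
                subject=subject, session=session, location=loc,
                amplitude=pk.mean_window_amplitude(ev, where)))
    if p2_rows and not dp.empty:
        corr = beh.correlate_dprime_p2(dp[dp["group"] == 2],
                                       pd.DataFrame(p2_rows))
        out["correlations"] = corr
        _tsv(corr, bdir / "dprime_p2_correlations.tsv", meta)
    return out


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the full analysis flow on a simulated study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    try:
        meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
        log.info("run %s (seed=%d)", meta["config_hash"], cfg.seed)
        (outdir / "config_resolved.yaml").write_text(cfg.to_yaml())

        montage = default_montage()
        montage.to_tsv(outdir / "montage.tsv")
        sim_cfg = cfg.sim_config()
        plan = cfg.effect_plan()

        truth_holder = {}

        def blocks():
            for key, ep, truth in iter_study_blocks(sim_cfg, plan, montage):
                truth_holder["truth"] = truth
                yield key, ep

        evokeds, rejection_log = preprocess_study(blocks(), montage, cfg)
        truth = truth_holder.get("truth")
        _tsv(rejection_log, outdir / "rejection_log.tsv", meta)
        write_evokeds(outdir / "evokeds.h5", evokeds)
        if truth is not None:
            with open(outdir / "sim_truth.json", "w") as f:
                json.dump({
                    "seed": truth.seed,
                    "dprime": truth.dprime.to_dict("records"),
                    "n_artifact_trials": int(len(truth.artifacts)),
                    "config": truth.config,
                }, f, sort_keys=True, indent=1)

        electrodes = sorted({e for roi in pk.ROIS.values()
                             for e in roi.electrodes})
        windows = {k: tuple(v) for k, v in cfg.peak_windows.items()}
        peak_table = pk.build_peak_table(evokeds, electrodes=electrodes,
                                         windows=windows)
        _tsv(peak_table, outdir / "peaks.tsv",
             {**meta, **{f"window_{k}": v for k, v in windows.items()}})

        bundle = {
            "evokeds": evokeds,
            "rejection_log": rejection_log,
            "peak_table": peak_table,
            "pls": _pls_stage(evokeds, montage, cfg, meta, outdir),
            "anova": _anova_stage(peak_table, cfg, meta, outdir),
            "behavior": _behavior_stage(
                _simulate_study_behavior(sim_cfg), evokeds, cfg, meta, outdir),
            "truth": truth,
            "meta": meta,
        }
        log.info("run %s complete", meta["config_hash"])
        return bundle
    finally:
        log.removeHandler(handler)
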