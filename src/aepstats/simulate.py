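"""Synthetic auditory-ERP study generator.

Emulates the structure the downstream analyses assume: a P1-N1-P2 evoked
complex whose latency is delayed by the stimulus-internal silence
(~50 ms for "mba", ~60 ms for "ba"), a session-wise P2 amplitude gain
that is largest at temporal-occipital electrodes and larger for the task
group, a stable N1, spatially correlated Gaussian noise, occasional
epochs exceeding the +/-70 µV artifact screen, four periocular channels
carrying blink transients, and an equal-variance Gaussian 2AFC observer
for the behavioral identification task.

Everything is seeded; identical configuration + seed reproduce the study
bit-exactly.  Ground truth (realized component parameters, planted d',
artifact trial indices) is returned alongside the data so recovery tests
have an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import EpochSet, Evoked, SimTruth, StudyDataset, default_times
from .errors import ConfigError, DimensionError
from .montage import Montage, default_montage

__all__ = [
    "ComponentSpec", "EffectPlan", "SimConfig", "SubjectParams",
    "component_kernel", "default_components", "default_effect_plan",
    "simulate_evoked_truth", "simulate_study", "simulate_study_evoked",
    "simulate_behavior", "evoked_noise_equivalent",
]

#: silence preceding the acoustic onset of each stimulus token (ms)
STIMULUS_SILENCE = {"mba": 50.0, "ba": 60.0}

#: voltage threshold that defines an artifact trial (µV)
ARTIFACT_THRESHOLD = 70.0

#: kernel support is truncated beyond this many half-widths from the peak
_KERNEL_SUPPORT = 3.5


# ---------------------------------------------------------------------------
# component and plan types
# ---------------------------------------------------------------------------

@dataclass
class ComponentSpec:
    """One deflection of the evoked complex.

    latency is ms after the *acoustic* onset (the stimulus silence is added
    separately); width is the half-width at half maximum of the Gaussian
    kernel; amplitude is the signed peak voltage at the peak-weighted
    electrode; topography holds one weight in [-1, 1] per scalp electrode.
    """

    name: str
    latency: float
    width: float
    amplitude: float
    topography: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in ("P1", "N1", "P2"):
            raise ConfigError(f"unknown component {self.name!r}")
        if self.width <= 0:
            raise ConfigError("component width must be > 0")
        self.topography = np.asarray(self.topography, dtype=float)
        if np.any(np.abs(self.topography) > 1 + 1e-12):
            raise ConfigError("topography weights must lie in [-1, 1]")
        if self.name in ("P1", "P2") and self.amplitude < 0:
            raise ConfigError(f"{self.name} amplitude must be >= 0")
        if self.name == "N1" and self.amplitude > 0:
            raise ConfigError("N1 amplitude must be <= 0")


@dataclass
class EffectPlan:
    """Session/group dependent amplitude gains planted on top of the base
    components.

    p2_gain / n1_gain map (group, session) -> µV added at the electrodes in
    ``region`` (full weight, no spatial falloff, so recovery tests have an
    exact footprint).  Session-4 gains are the session-3 gain scaled by
    ``retention_decay`` (a scalar, or a per-group mapping).
    """

    p2_gain: dict[tuple[int, int], float] = field(default_factory=dict)
    n1_gain: dict[tuple[int, int], float] = field(default_factory=dict)
    region: tuple[str, ...] = ("TP9", "IZ", "TP10")
    retention_decay: float | dict[int, float] = 0.5

    def __post_init__(self) -> None:
        for d in (self.p2_gain, self.n1_gain):
            if any(not math.isfinite(v) for v in d.values()):
                raise ConfigError("gains must be finite")

    def _decay(self, group: int) -> float:
        if isinstance(self.retention_decay, dict):
            return float(self.retention_decay.get(group, 0.0))
        return float(self.retention_decay)

    def gain(self, which: str, group: int, session: int) -> float:
        table = self.p2_gain if which == "P2" else self.n1_gain
        if session == 4:
            return table.get((group, 3), 0.0) * self._decay(group)
        return table.get((group, session), 0.0)


@dataclass
class SimConfig:
    """Study-level simulation configuration (the defaults are the study
    conditions: 10 subjects per group, four sessions, two 400-trial
    blocks per session, 1 kHz epochs from -100 to 500 ms)."""

    n_subjects_per_group: int = 10
    sessions: tuple[int, ...] = (1, 2, 3)
    trials_per_block: int = 400
    noise_sd: float = 15.0                 # single-trial µV
    spatial_noise_corr: float = 0.6        # exp(-d/scale) amplitude at d=scale
    artifact_rate: float = 0.05
    stimulus_silence: dict[str, float] = field(
        default_factory=lambda: dict(STIMULUS_SILENCE))
    stimuli: tuple[str, ...] = ("mba", "ba")
    seed: int = 0
    subject_amp_sd: float = 0.05           # multiplicative component variability
    subject_lat_sd: float = 2.0            # per-subject latency jitter, ms
    dprime_plan: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(2, 1): 0.2, (2, 2): 0.5, (2, 3): 0.4,
                                 (2, 4): 0.3, (1, 4): 0.35})

    def __post_init__(self) -> None:
        if self.n_subjects_per_group <= 0 or self.trials_per_block <= 0:
            raise ConfigError("counts must be > 0")
        if not set(self.sessions) <= {1, 2, 3, 4}:
            raise ConfigError(f"sessions must lie in 1..4, got {self.sessions}")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ConfigError("artifact_rate must lie in [0, 1)")
        if not (0.0 <= self.spatial_noise_corr < 1.0):
            raise ConfigError("spatial_noise_corr must lie in [0, 1)")


@dataclass
class SubjectParams:
    """Realized per-subject component parameters for one session/stimulus."""

    subject: str
    group: int
    components: list[ComponentSpec]


# ---------------------------------------------------------------------------
# kernels and noiseless truth
# ---------------------------------------------------------------------------

def component_kernel(spec: ComponentSpec, times: np.ndarray) -> np.ndarray:
    """Gaussian deflection peaking at spec.latency with value
    spec.amplitude; support truncated to ±3.5 half-widths so pre-stimulus
    samples are exactly zero."""
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    if len(times) >= 2 and not np.allclose(dt, 1.0):
        raise ConfigError("time axis must be uniform at 1 kHz")
    if spec.width <= 0:
        raise ConfigError("component width must be > 0")
    # half-width at half maximum -> Gaussian sigma
    sigma = spec.width / math.sqrt(2.0 * math.log(2.0))
    x = times - spec.latency
    w = spec.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
    w[np.abs(x) > _KERNEL_SUPPORT * spec.width] = 0.0
    return w


def _vertex_topography(montage: Montage, scale: float = 0.8) -> np.ndarray:
    """Vertex-maximal weight map, decaying with schematic distance from CZ."""
    d = montage.distance_matrix(montage.scalp_labels)
    cz = montage.scalp_labels.index("CZ")
    return np.exp(-0.5 * (d[cz] / scale) ** 2)


def default_components(montage: Montage) -> list[ComponentSpec]:
    """Canonical P1-N1-P2 morphology (latencies after acoustic onset)."""
    topo = _vertex_topography(montage)
    return [
        ComponentSpec("P1", latency=60.0, width=12.0, amplitude=1.0,
                      topography=topo),
        ComponentSpec("N1", latency=110.0, width=22.0, amplitude=-4.0,
                      topography=topo),
        ComponentSpec("P2", latency=180.0, width=30.0, amplitude=3.0,
                      topography=topo),
    ]


def default_effect_plan() -> EffectPlan:
    """Session-wise P2 gain at the temporal-occipital electrodes:
    +0.5 / +1.0 µV for sessions 2 / 3, doubled in the task group; most of
    the gain is retained at session 4 in the task group only."""
    return EffectPlan(
        p2_gain={(1, 2): 0.5, (1, 3): 1.0, (2, 2): 1.0, (2, 3): 2.0},
        region=("TP9", "IZ", "TP10"),
        retention_decay={1: 0.1, 2: 0.8},
    )


def _region_topography(montage: Montage, region: tuple[str, ...]) -> np.ndarray:
    topo = np.zeros(montage.n_scalp)
    scalp = montage.scalp_labels
    for lab in region:
        topo[scalp.index(lab)] = 1.0
    return topo


def realize_subject(montage: Montage, cfg: SimConfig, plan: EffectPlan,
                    subject: str, group: int, session: int,
                    amp_scale: dict[str, float], lat_shift: float,
                    ) -> list[ComponentSpec]:
    """Per-subject/session component list = base morphology x subject
    scaling + planted session gain on the plan's electrode region."""
    base = default_components(montage)
    region_topo = _region_topography(montage, plan.region)
    out: list[ComponentSpec] = []
    for spec in base:
        amp = spec.amplitude * amp_scale[spec.name]
        out.append(ComponentSpec(spec.name, spec.latency + lat_shift,
                                 spec.width, amp, spec.topography))
        gain = plan.gain(spec.name, group, session) if spec.name in ("P2", "N1") else 0.0
        if gain:
            # additive regional component, same temporal kernel
            out.append(ComponentSpec(
                spec.name, spec.latency + lat_shift, spec.width,
                gain, region_topo))
    return out


def simulate_evoked_truth(params: SubjectParams, stimulus: str,
                          montage: Montage, session: int,
                          silence: dict[str, float] | None = None,
                          times: np.ndarray | None = None) -> Evoked:
    """Noiseless evoked = sum over components of kernel x topography,
    latencies shifted by the stimulus-internal silence.  Eye channels are
    zero.  Exactly zero in the pre-stimulus window."""
    silence = silence if silence is not None else STIMULUS_SILENCE
    times = times if times is not None else default_times()
    delay = silence[stimulus]
    n_scalp = montage.n_scalp
    data = np.zeros((len(montage.labels), len(times)))
    for spec in params.components:
        if len(spec.topography) != n_scalp:
            raise DimensionError(
                f"topography length {len(spec.topography)} != {n_scalp} scalp electrodes")
        shifted = ComponentSpec(spec.name, spec.latency + delay, spec.width,
                                spec.amplitude, spec.topography)
        data[:n_scalp] += np.outer(spec.topography, component_kernel(shifted, times))
    return Evoked(data=data, times=times, channels=montage.labels,
                  subject=params.subject, group=params.group, session=session,
                  stimulus=stimulus, n_trials_included=0,
                  provenance={"noiseless": True})


# ---------------------------------------------------------------------------
# noise machinery
# ---------------------------------------------------------------------------

def _spatial_cholesky(montage: Montage, corr: float) -> np.ndarray:
    """Cholesky factor of an exponential-decay channel correlation matrix;
    ``corr`` is the correlation at one unit of schematic distance."""
    n = len(montage.labels)
    if corr <= 0:
        return np.eye(n)
    d = montage.distance_matrix()
    scale = -1.0 / math.log(corr)
    cov = np.exp(-d / scale)
    cov += 1e-9 * np.eye(n)
    return np.linalg.cholesky(cov)


def _temporal_kernel(sd_ms: float = 8.0) -> np.ndarray:
    t = np.arange(-3 * sd_ms, 3 * sd_ms + 1)
    k = np.exp(-0.5 * (t / sd_ms) ** 2)
    # normalized so white noise keeps unit variance after smoothing
    return k / np.sqrt((k ** 2).sum())


def correlated_noise(rng: np.random.Generator, chol: np.ndarray,
                     n_samples: int, sd: float) -> np.ndarray:
    """Spatially correlated, temporally smoothed Gaussian noise with
    per-channel standard deviation ``sd`` µV."""
    from scipy.signal import fftconvolve

    n_ch = chol.shape[0]
    kern = _temporal_kernel()
    pad = len(kern) - 1
    white = rng.standard_normal((n_ch, n_samples + pad))
    smooth = fftconvolve(white, kern[None, :], mode="valid", axes=1)
    return sd * (chol @ smooth)


def _blink(times: np.ndarray, rng: np.random.Generator,
           amplitude: float) -> np.ndarray:
    center = rng.uniform(times[0] + 60, times[-1] - 60)
    return amplitude * np.exp(-0.5 * ((times - center) / 25.0) ** 2)


# ---------------------------------------------------------------------------
# full study simulation
# ---------------------------------------------------------------------------

def _subject_ids(cfg: SimConfig) -> list[tuple[str, int]]:
    out = []
    for group in (1, 2):
        for i in range(cfg.n_subjects_per_group):
            out.append((f"S{group}{i:02d}", group))
    return out


def _subject_effects(rng: np.random.Generator, cfg: SimConfig):
    amp_scale = {name: max(0.2, 1.0 + cfg.subject_amp_sd * rng.standard_normal())
                 for name in ("P1", "N1", "P2")}
    lat_shift = cfg.subject_lat_sd * rng.standard_normal()
    return amp_scale, lat_shift


def simulate_trial_block(rng: np.random.Generator, truth_ev: Evoked,
                         montage: Montage, cfg: SimConfig) -> np.ndarray:
    """One block of epochs = noiseless evoked + correlated noise + eye
    blinks + occasional large artifact transients."""
    n_trials = cfg.trials_per_block
    chol = _spatial_cholesky(montage, cfg.spatial_noise_corr)
    times = truth_ev.times
    n_ch, n_samp = truth_ev.data.shape
    eye_idx = [montage.labels.index(l) for l in montage.eye_labels]
    frontal = np.array([max(0.0, y) for y in montage.table["y"]])
    data = np.empty((n_trials, n_ch, n_samp))
    for t in range(n_trials):
        trial = truth_ev.data + correlated_noise(rng, chol, n_samp, cfg.noise_sd)
        # small routine blinks on the eye channels (part of the stochastic
        # noise model: disabled in noiseless simulations)
        if cfg.noise_sd > 0 and rng.random() < 0.15:
            b = _blink(times, rng, rng.uniform(20, 50))
            trial[eye_idx] += b
        if cfg.artifact_rate and rng.random() < cfg.artifact_rate:
            # large blink: dominates eye channels, decays over frontal scalp
            b = _blink(times, rng, rng.uniform(90, 150))
            trial += np.outer(0.4 * frontal, b)
            trial[eye_idx] += b
        data[t] = trial
    return data


def simulate_study(cfg: SimConfig, plan: EffectPlan | None = None,
                   montage: Montage | None = None) -> tuple[StudyDataset, SimTruth]:
    """Trial-level study simulation.

    Memory scales with n_subjects x sessions x stimuli x trials; use a
    reduced ``trials_per_block`` for in-memory analysis, or
    :func:`iter_study_blocks` to stream block-by-block.
    """
    plan = plan if plan is not None else default_effect_plan()
    montage = montage if montage is not None else default_montage()
    epochs: dict[tuple, EpochSet] = {}
    truth = None
    for key, ep, truth in iter_study_blocks(cfg, plan, montage):
        epochs[key] = ep
    behavior = _simulate_study_behavior(cfg)
    study = StudyDataset(epochs=epochs, behavior=behavior, montage=montage,
                         truth=truth, seed=cfg.seed)
    return study, truth


def iter_study_blocks(cfg: SimConfig, plan: EffectPlan | None = None,
                      montage: Montage | None = None):
    """Yield (key, EpochSet, SimTruth-so-far) per subject/session/stimulus.

    The SimTruth object yielded is shared and grows as blocks are
    generated; after exhaustion it is complete.
    """
    plan = plan if plan is not None else default_effect_plan()
    montage = montage if montage is not None else default_montage()
    root = np.random.SeedSequence(cfg.seed)
    times = default_times()
    comp_rows, artifact_rows = [], []
    truth = SimTruth(components=pd.DataFrame(), dprime=_dprime_table(cfg),
                     artifacts=pd.DataFrame(), seed=cfg.seed,
                     config=_config_record(cfg))
    subj_seq, block_seq = root.spawn(2)
    subj_rngs = {sid: np.random.default_rng(s)
                 for (sid, _g), s in zip(_subject_ids(cfg),
                                         subj_seq.spawn(2 * cfg.n_subjects_per_group))}
    block_children = iter(block_seq.spawn(
        2 * cfg.n_subjects_per_group * len(cfg.sessions) * len(cfg.stimuli)))
    for subject, group in _subject_ids(cfg):
        amp_scale, lat_shift = _subject_effects(subj_rngs[subject], cfg)
        for session in sorted(cfg.sessions):
            comps = realize_subject(montage, cfg, plan, subject, group,
                                    session, amp_scale, lat_shift)
            params = SubjectParams(subject, group, comps)
            for stimulus in cfg.stimuli:
                rng = np.random.default_rng(next(block_children))
                truth_ev = simulate_evoked_truth(
                    params, stimulus, montage, session,
                    silence=cfg.stimulus_silence, times=times)
                data = simulate_trial_block(rng, truth_ev, montage, cfg)
                ep = EpochSet(data=data, times=times, channels=montage.labels,
                              subject=subject, group=group, session=session,
                              stimulus=stimulus,
                              provenance={"seed": cfg.seed})
                # ground-truth artifact marking: the rejection rule itself,
                # applied at the stage the screen runs (after baseline
                # correction)
                bl = data[:, :, times <= 0].mean(axis=2, keepdims=True)
                bad = np.where(np.abs(data - bl).max(axis=(1, 2))
                               > ARTIFACT_THRESHOLD)[0]
                for t in bad:
                    artifact_rows.append(dict(subject=subject, group=group,
                                              session=session, stimulus=stimulus,
                                              trial=int(t)))
                for spec in comps:
                    comp_rows.append(dict(
                        subject=subject, group=group, session=session,
                        stimulus=stimulus, component=spec.name,
                        latency=spec.latency + cfg.stimulus_silence[stimulus],
                        amplitude=spec.amplitude,
                        regional=bool(np.array_equal(
                            spec.topography, _region_topography(montage, plan.region)))))
                truth.components = pd.DataFrame(comp_rows)
                truth.artifacts = pd.DataFrame(
                    artifact_rows, columns=["subject", "group", "session",
                                            "stimulus", "trial"])
                yield ep.key, ep, truth


def _config_record(cfg: SimConfig) -> dict:
    rec = asdict(cfg)
    rec["dprime_plan"] = {f"{g}|{s}": v for (g, s), v in cfg.dprime_plan.items()}
    return rec


def _dprime_table(cfg: SimConfig) -> pd.DataFrame:
    rows = [dict(group=g, session=s, dprime=v)
            for (g, s), v in sorted(cfg.dprime_plan.items())]
    return pd.DataFrame(rows, columns=["group", "session", "dprime"])


def _simulate_study_behavior(cfg: SimConfig) -> pd.DataFrame:
    """2AFC logs for every (group, session) with a planted d'."""
    root = np.random.SeedSequence((cfg.seed, 777))
    rows = []
    items = sorted(cfg.dprime_plan.items())
    children = iter(root.spawn(len(items) * 2 * cfg.n_subjects_per_group))
    for (group, session), dp in items:
        if session not in cfg.sessions:
            continue
        for subject, g in _subject_ids(cfg):
            if g != group:
                continue
            rng = np.random.default_rng(next(children))
            log = simulate_behavior(dp, rng=rng)
            log.insert(0, "session", session)
            log.insert(0, "group", group)
            log.insert(0, "subject", subject)
            rows.append(log)
    if not rows:
        return pd.DataFrame(columns=["subject", "group", "session",
                                     "trial", "stimulus", "response"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# evoked-level simulation (for statistical recovery / calibration studies)
# ---------------------------------------------------------------------------

def evoked_noise_equivalent(cfg: SimConfig) -> float:
    """Evoked-level noise standard deviation matching the trial-level
    conditions: single-trial noise averaged over the expected number of
    retained trials."""
    retained = cfg.trials_per_block * (1.0 - cfg.artifact_rate)
    return cfg.noise_sd / math.sqrt(retained)


def simulate_study_evoked(cfg: SimConfig, plan: EffectPlan | None = None,
                          montage: Montage | None = None,
                          evoked_noise_sd: float | None = None,
                          stimulus: str = "mba",
                          seed: int | None = None,
                          ) -> tuple[dict[tuple, Evoked], SimTruth]:
    """Simulate subject-level *averaged* evokeds directly: noiseless truth
    plus spatially correlated noise with standard deviation
    ``evoked_noise_sd`` µV at the average level.  This is the input for
    permutation/bootstrap recovery and null-calibration experiments, where
    single-trial resolution is irrelevant.  The default noise level is the
    trial-level equivalent :func:`evoked_noise_equivalent`."""
    if evoked_noise_sd is None:
        evoked_noise_sd = evoked_noise_equivalent(cfg)
    plan = plan if plan is not None else default_effect_plan()
    montage = montage if montage is not None else default_montage()
    root = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    times = default_times()
    chol = _spatial_cholesky(montage, cfg.spatial_noise_corr)
    n_scalp = montage.n_scalp
    evokeds: dict[tuple, Evoked] = {}
    comp_rows = []
    ids = _subject_ids(cfg)
    children = iter(root.spawn(len(ids)))
    for subject, group in ids:
        rng = np.random.default_rng(next(children))
        amp_scale, lat_shift = _subject_effects(rng, cfg)
        for session in sorted(cfg.sessions):
            comps = realize_subject(montage, cfg, plan, subject, group,
                                    session, amp_scale, lat_shift)
            params = SubjectParams(subject, group, comps)
            ev = simulate_evoked_truth(params, stimulus, montage, session,
                                       silence=cfg.stimulus_silence, times=times)
            noise = correlated_noise(rng, chol, len(times), evoked_noise_sd)
            data = ev.data.copy()
            data[:n_scalp] += noise[:n_scalp]
            evokeds[ev.key] = ev.copy_with(
                data=data, n_trials_included=1,
                provenance={"evoked_level_sim": True})
            for spec in comps:
                comp_rows.append(dict(subject=subject, group=group,
                                      session=session, stimulus=stimulus,
                                      component=spec.name,
                                      amplitude=spec.amplitude))
    truth = SimTruth(components=pd.DataFrame(comp_rows),
                     dprime=_dprime_table(cfg),
                     artifacts=pd.DataFrame(columns=["subject", "group",
                                                     "session", "stimulus",
                                                     "trial"]),
                     seed=cfg.seed, config=_config_record(cfg))
    return evokeds, truth


# ---------------------------------------------------------------------------
# behavioral observer
# ---------------------------------------------------------------------------

def simulate_behavior(dprime_true: float, criterion: float | None = None,
                      n_trials: int = 50, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Equal-variance Gaussian 2AFC observer.

    Half the trials are "mba" (signal, internal response ~ N(d', 1)), half
    "ba" (noise, ~ N(0, 1)); the observer answers "mba" when the internal
    response exceeds the criterion (default d'/2, i.e. unbiased).
    ``dprime_true = inf`` yields a deterministic observer.
    """
    if n_trials % 2:
        raise ConfigError("n_trials must be even (equal stimulus counts)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_each = n_trials // 2
    stimuli = np.array(["mba"] * n_each + ["ba"] * n_each)
    rng.shuffle(stimuli)
    if math.isinf(dprime_true):
        responses = stimuli.copy()
    else:
        c = criterion if criterion is not None else dprime_true / 2.0
        signal = stimuli == "mba"
        x = rng.standard_normal(n_trials) + np.where(signal, dprime_true, 0.0)
        responses = np.where(x > c, "mba", "ba")
    return pd.DataFrame({"trial": np.arange(n_trials),
                         "stimulus": stimuli, "response": responses})
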