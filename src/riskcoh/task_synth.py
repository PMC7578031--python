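"""Synthetic session generator for the reward-uncertainty task.

The task shows one of nine reward cues on each trial. Each cue is a discrete
reward distribution on an 11-point scale whose expected value (EV: 3, 6 or 9
points) and variance (0, 1 or 4 points^2) are orthogonal by construction
(mean-preserving spreads around deterministic anchors). The generator emits
complete sessions -- trial metadata, opponent-coded spiking populations with
shared gain latents, oscillatory LFPs with condition-dependent band power, and
direction-asymmetric, variance-dependent spike-field phase coupling -- together
with the ground truth needed to verify every downstream analysis by parameter
recovery.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt, hilbert

__all__ = [
    "RewardCue",
    "GroundTruth",
    "SessionConfig",
    "SessionBundle",
    "UnitRecord",
    "build_cue_set",
    "simulate_session",
    "inject_artifacts",
    "generate_phase_locked_spikes",
]

POINT_SCALE = (1, 11)
EV_LEVELS = (3, 6, 9)

#: trial epoch markers, ms relative to cue onset
CUE_ON, CUE_OFF, TARGET_ON = 0.0, 400.0, 800.0
TRIAL_SPAN = (-1200.0, 2000.0)

ARTIFACT_KINDS = ("broadband-power", "line-noise", "saturation", "transient")


@dataclass(frozen=True)
class RewardCue:
    """One reward distribution: outcome magnitudes (points) and probabilities."""

    cue_id: int
    outcomes: tuple[tuple[int, float], ...]

    @property
    def ev(self) -> float:
        return float(sum(m * p for m, p in self.outcomes))

    @property
    def variance(self) -> float:
        mu = self.ev
        return float(sum(p * (m - mu) ** 2 for m, p in self.outcomes))

    def validate(self) -> None:
        probs = [p for _, p in self.outcomes]
        mags = [m for m, _ in self.outcomes]
        if not np.isclose(sum(probs), 1.0):
            raise ValueError(f"cue {self.cue_id}: probabilities sum to {sum(probs)}")
        for m in mags:
            if not (POINT_SCALE[0] <= m <= POINT_SCALE[1]) or m != int(m):
                raise ValueError(f"cue {self.cue_id}: magnitude {m} outside 1-11 integer scale")


def build_cue_set() -> list[RewardCue]:
    """Build the nine-cue schedule: 3 EV levels x 3 variance levels.

    For each deterministic anchor EV in {3, 6, 9} there is a point-mass cue and
    two equiprobable two-point spreads at integer offsets +-k. The larger
    offset is the maximum integer k that keeps every outcome within the 1-11
    scale for *every* EV level (so the variance levels are shared across EVs);
    the smaller offset is 1. This yields variances {0, 1, 4} and a cue set in
    which EV and variance are exactly uncorrelated.
    """
    lo, hi = POINT_SCALE
    k_max = min(min(ev - lo, hi - ev) for ev in EV_LEVELS)
    offsets = (1, k_max)
    cues: list[RewardCue] = []
    cue_id = 1
    for ev in EV_LEVELS:
        cues.append(RewardCue(cue_id, ((ev, 1.0),)))
        cue_id += 1
        for k in offsets:
            cues.append(RewardCue(cue_id, ((ev - k, 0.5), (ev + k, 0.5))))
            cue_id += 1
    for cue in cues:
        cue.validate()
    return cues


# ---------------------------------------------------------------------------
# ground truth + configuration


@dataclass
class UnitGroundTruth:
    unit_id: int
    area: str
    factor: str | None          # "ev", "variance" or None
    polarity: int               # +1 / -1 (ignored when factor is None)
    effect: float               # spikes/s change per factor unit during cue+delay
    base_rate: float            # spikes/s
    subnetwork: str | None      # latent-sharing group, e.g. "frontal/ev"
    coupled: bool = False       # spike phases locked to the other area's field
    coupling_electrode: int = -1


@dataclass
class GroundTruth:
    """Everything injected by the generator, for downstream parameter recovery."""

    lick_coeffs: dict[str, float]
    unit_coding: list[UnitGroundTruth]
    shared_latents: dict[str, float]
    lfp_band_effects: dict[str, dict[str, tuple[float, float]]]
    coupling: dict[str, dict[str, object]]
    artifact_labels: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_kinds: dict[str, np.ndarray] = field(default_factory=dict)
    rt_coeffs: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for d in self.coupling.values():
            for k in d.get("kappa", {}).values():
                if k < 0:
                    raise ValueError("von Mises concentration kappa must be >= 0")
        for u in self.unit_coding:
            if not np.isfinite(u.effect):
                raise ValueError("non-finite unit effect size")


_BANDS = {"alpha_beta": (8.0, 18.0), "beta_gamma": (18.0, 43.0)}
_BAND_CENTER = {"alpha_beta": 12.0, "beta_gamma": 30.0}


@dataclass
class SessionConfig:
    """Scenario parameters for one synthetic session.

    Defaults reflect the task's published statistical structure: licking
    log-odds slopes of 0.24 per EV point and 0.03 per variance point^2,
    opponent-coded minority populations, alpha/low-beta suppression by both
    factors with area-specific beta/gamma effects, and variance-dependent
    coupling that is enhanced parietal->frontal and suppressed frontal->parietal.
    """

    n_trials: int = 540
    areas: tuple[str, str] = ("frontal", "parietal")
    n_units: dict[str, int] | int = 24
    n_electrodes: dict[str, int] | int = 8
    sampling_rate: float = 1000.0
    min_trials_per_condition: int = 5

    # behavior
    lick_coeffs: dict[str, float] = field(default_factory=lambda: {
        "intercept": -2.0, "ev": 0.24, "variance": 0.03,
        "location": 0.0, "ev_x_variance": 0.0,
    })
    lick_mode: str = "binary"        # "binary" or "fraction"
    rt_mean: float = 250.0           # ms
    rt_sd: float = 40.0
    rt_coeffs: dict[str, float] = field(default_factory=lambda: {"ev": 0.0, "variance": 0.0})
    p_correct: float = 0.82

    # spiking
    coding_mixture: dict[str, float] = field(default_factory=lambda: {
        "ev+": 0.09, "ev-": 0.06, "variance+": 0.10, "variance-": 0.08,
    })
    ev_effect: float = 1.2           # spikes/s per EV point in coding units
    variance_effect: float = 1.0     # spikes/s per variance point^2
    base_rate_mean: float = 8.0      # spikes/s, lognormal across units
    base_rate_sd: float = 3.0
    rate_link: str = "linear"        # "linear" (rate = base + beta*x, floored) or "log"
    gain_latent_sd: float = 0.25     # multiplicative shared gain SD per subnetwork

    # LFP
    lfp_band_effects: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            # band -> (fractional power change per EV point, per variance point^2)
            "frontal": {"alpha_beta": (-0.02, -0.05), "beta_gamma": (-0.02, 0.05)},
            "parietal": {"alpha_beta": (-0.02, -0.05), "beta_gamma": (0.02, -0.05)},
        }
    )
    oscillation_amplitude: float = 1.0
    background_sd: float = 1.0

    # spike-field coupling: direction name -> schedule
    coupling: dict[str, dict[str, object]] = field(default_factory=lambda: {
        "parietal->frontal": {"band": (8.0, 18.0), "kappa": {0: 0.1, 1: 0.4, 4: 1.0},
                              "preferred_phase": 0.0, "fraction": 1.0},
        "frontal->parietal": {"band": (8.0, 18.0), "kappa": {0: 1.0, 1: 0.4, 4: 0.1},
                              "preferred_phase": 0.0, "fraction": 1.0},
    })

    # artifacts
    artifact_rate: float = 0.0
    artifact_kinds: tuple[str, ...] = ARTIFACT_KINDS

    make_lfp: bool = True
    lick_trace: bool = False

    def n_units_for(self, area: str) -> int:
        return self.n_units[area] if isinstance(self.n_units, dict) else self.n_units

    def n_electrodes_for(self, area: str) -> int:
        return self.n_electrodes[area] if isinstance(self.n_electrodes, dict) else self.n_electrodes


@dataclass
class UnitRecord:
    unit_id: int
    area: str
    spike_times: list[np.ndarray]    # one array (ms, cue-aligned) per trial
    quality: str = "good"


@dataclass
class SessionBundle:
    """One session: trial table + spike trains + LFP traces + ground truth."""

    trials: "object"                  # pandas DataFrame
    units: list[UnitRecord]
    lfps: dict[str, np.ndarray]       # area -> (electrodes, trials, samples)
    sampling_rate: float
    t0: float = TRIAL_SPAN[0]
    epoch_markers: tuple[float, float, float] = (CUE_ON, CUE_OFF, TARGET_ON)
    ground_truth: GroundTruth | None = None

    def lfp_times(self) -> np.ndarray:
        n = next(iter(self.lfps.values())).shape[-1] if self.lfps else 0
        return self.t0 + np.arange(n) * 1000.0 / self.sampling_rate


# ---------------------------------------------------------------------------
# simulation


def _named_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_trials(cfg: SessionConfig, rng: np.random.Generator):
    import pandas as pd

    cues = build_cue_set()
    for attempt in range(200):
        cue_idx = rng.integers(0, 9, size=cfg.n_trials)
        cue_loc = rng.integers(0, 2, size=cfg.n_trials)
        ev = np.array([cues[i].ev for i in cue_idx])
        var = np.array([cues[i].variance for i in cue_idx])
        cells = {}
        for e, v, c in zip(ev, var, cue_loc):
            cells[(e, v, c)] = cells.get((e, v, c), 0) + 1
        if len(cells) == 18 and min(cells.values()) >= cfg.min_trials_per_condition:
            break
    else:
        raise ValueError(
            f"could not satisfy >= {cfg.min_trials_per_condition} trials per "
            f"(ev, variance, location) cell with n_trials={cfg.n_trials}"
        )
    target_loc = rng.integers(0, 2, size=cfg.n_trials)

    lc = cfg.lick_coeffs
    logit = (lc["intercept"] + lc["ev"] * ev + lc["variance"] * var
             + lc["location"] * cue_loc + lc["ev_x_variance"] * ev * var)
    p_lick = 1.0 / (1.0 + np.exp(-logit))
    if cfg.lick_mode == "binary":
        lick = rng.random(cfg.n_trials) < p_lick
        lick = lick.astype(float)
    else:
        lick = np.clip(rng.beta(1 + 8 * p_lick, 1 + 8 * (1 - p_lick)), 0, 1)

    rc = cfg.rt_coeffs
    rt = rng.normal(cfg.rt_mean + rc.get("ev", 0.0) * ev + rc.get("variance", 0.0) * var,
                    cfg.rt_sd)
    rt = np.maximum(rt, 100.0)
    correct = rng.random(cfg.n_trials) < cfg.p_correct

    return pd.DataFrame({
        "trial_id": np.arange(cfg.n_trials),
        "cue_id": [cues[i].cue_id for i in cue_idx],
        "ev": ev, "variance": var,
        "cue_location": cue_loc, "target_location": target_loc,
        "rt_ms": rt, "correct": correct, "lick": lick,
    })


def _assign_unit_coding(cfg: SessionConfig, rng: np.random.Generator) -> list[UnitGroundTruth]:
    coding: list[UnitGroundTruth] = []
    uid = 0
    for area in cfg.areas:
        n = cfg.n_units_for(area)
        labels = list(cfg.coding_mixture.items())
        pool: list[str] = []
        for lab, frac in labels:
            pool += [lab] * int(round(frac * n))
        pool += ["none"] * (n - len(pool))
        rng.shuffle(pool)
        for lab in pool[:n]:
            base = float(np.exp(rng.normal(np.log(cfg.base_rate_mean), cfg.base_rate_sd / cfg.base_rate_mean)))
            if lab == "none":
                coding.append(UnitGroundTruth(uid, area, None, +1, 0.0, base, None))
            else:
                factor = "ev" if lab.startswith("ev") else "variance"
                pol = +1 if lab.endswith("+") else -1
                eff = cfg.ev_effect if factor == "ev" else cfg.variance_effect
                coding.append(UnitGroundTruth(
                    uid, area, factor, pol, eff, base, f"{area}/{factor}"))
            uid += 1
    return coding


def _piecewise_spike_times(rate_pre: float, rate_task: float, rate_post: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Homogeneous-Poisson spikes on [-1200,0), [0,800), [800,2000] ms."""
    segs = [(-1200.0, 0.0, rate_pre), (0.0, 800.0, rate_task), (800.0, 2000.0, rate_post)]
    times = []
    for a, b, r in segs:
        n = rng.poisson(max(r, 0.0) * (b - a) / 1000.0)
        times.append(rng.uniform(a, b, size=n))
    return np.sort(np.concatenate(times))


def _simulate_units(cfg: SessionConfig, trials, coding: list[UnitGroundTruth],
                    rng: np.random.Generator) -> list[UnitRecord]:
    n_trials = len(trials)
    ev = trials["ev"].to_numpy(float)
    var = trials["variance"].to_numpy(float)
    # shared trial-wise gain latents per subnetwork (area/factor)
    subnets = sorted({u.subnetwork for u in coding if u.subnetwork})
    latents = {s: rng.standard_normal(n_trials) for s in subnets}

    units = []
    for u in coding:
        x = ev if u.factor == "ev" else var if u.factor == "variance" else np.zeros(n_trials)
        if cfg.rate_link == "log":
            task_rate = u.base_rate * np.exp(u.polarity * u.effect / u.base_rate * x)
        else:
            task_rate = np.maximum(u.base_rate + u.polarity * u.effect * x, 0.0)
        gain = np.ones(n_trials)
        if u.subnetwork is not None and cfg.gain_latent_sd > 0:
            gain = np.maximum(1.0 + u.polarity * cfg.gain_latent_sd * latents[u.subnetwork], 0.0)
        spike_lists = [
            _piecewise_spike_times(u.base_rate * gain[t], task_rate[t] * gain[t],
                                   u.base_rate * gain[t], rng)
            for t in range(n_trials)
        ]
        units.append(UnitRecord(u.unit_id, u.area, spike_lists))
    return units


def _one_over_f_background(n_samples: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^2 (integrated white) background plus white noise, unit-SD scaled."""
    w = rng.standard_normal(n_samples)
    brown = np.cumsum(w)
    brown = brown - np.mean(brown)
    s = np.std(brown)
    if s > 0:
        brown = brown / s
    return sd * (brown + 0.5 * rng.standard_normal(n_samples))


def _simulate_lfp(cfg: SessionConfig, trials, rng: np.random.Generator) -> dict[str, np.ndarray]:
    fs = cfg.sampling_rate
    if fs < 2 * 100.0:
        raise ValueError("sampling rate below 2x the 100 Hz analysis band ceiling")
    t = np.arange(TRIAL_SPAN[0], TRIAL_SPAN[1], 1000.0 / fs) / 1000.0  # seconds
    n_samples = t.size
    task = (t >= 0) & (t < TARGET_ON / 1000.0)
    ev = trials["ev"].to_numpy(float)
    var = trials["variance"].to_numpy(float)
    n_trials = len(trials)

    lfps = {}
    for area in cfg.areas:
        n_el = cfg.n_electrodes_for(area)
        traces = np.empty((n_el, n_trials, n_samples))
        effects = cfg.lfp_band_effects.get(area, {})
        # band oscillations are coherent across an array's electrodes: one
        # phase per (trial, band) shared by all electrodes of the area
        shared_phase = {band: rng.uniform(0, 2 * np.pi, size=n_trials)
                        for band in effects}
        for e in range(n_el):
            for tr in range(n_trials):
                x = _one_over_f_background(n_samples, cfg.background_sd, rng)
                for band, (b_ev, b_var) in effects.items():
                    f0 = _BAND_CENTER.get(band, np.mean(_BANDS.get(band, (10, 20))))
                    osc = np.cos(2 * np.pi * f0 * t + shared_phase[band][tr])
                    mult = np.ones(n_samples)
                    pw = max(1.0 + b_ev * ev[tr] + b_var * var[tr], 0.05)
                    mult[task] = np.sqrt(pw)
                    x = x + cfg.oscillation_amplitude * mult * osc
                traces[e, tr] = x
        lfps[area] = traces
    return lfps


def bandpass_phase(samples: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous phase of the band-filtered analytic signal (0 = peak)."""
    nyq = fs / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist limit {nyq} Hz")
    sos = butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    filt = sosfiltfilt(sos, samples, axis=-1)
    return np.angle(hilbert(filt, axis=-1))


def generate_phase_locked_spikes(lfp: np.ndarray, fs: float, t0: float,
                                 band: tuple[float, float], kappa: float,
                                 preferred_phase: float, n_spikes: int,
                                 rng: np.random.Generator | int,
                                 window: tuple[float, float] | None = None) -> np.ndarray:
    """Spike times whose phases on the band-filtered LFP are von Mises.

    Each spike's target phase is drawn von Mises(preferred_phase, kappa); the
    spike is placed at a uniformly chosen crossing of that phase by the
    analytic-signal phase of the band-filtered trace (within ``window`` if
    given). Exactly ``n_spikes`` times (ms, trace clock) are returned.
    """
    if np.ndim(lfp) != 1 or lfp.size == 0:
        raise ValueError("lfp must be a non-empty 1-D trace")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    phase = bandpass_phase(lfp, fs, band)
    times = t0 + np.arange(lfp.size) * 1000.0 / fs
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        phase, times = phase[sel], times[sel]
        if phase.size < 2:
            raise ValueError("window too short for phase mapping")
    unwrapped = np.unwrap(phase)
    if kappa == 0:
        targets = rng.uniform(-np.pi, np.pi, size=n_spikes)
    else:
        targets = rng.vonmises(preferred_phase, kappa, size=n_spikes)
    return _map_phases_to_times(unwrapped, phase, times, targets, rng)


def _map_phases_to_times(unwrapped: np.ndarray, phase: np.ndarray,
                         times: np.ndarray, targets: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Place each target phase at a uniformly chosen matching-phase crossing."""
    out = np.empty(targets.size)
    dt = times[1] - times[0]
    for i, th in enumerate(targets):
        # crossing times of unwrapped phase through th + 2*pi*k
        u = (unwrapped - th) / (2 * np.pi)
        k = np.floor(u)
        cross = np.nonzero(np.diff(k) > 0)[0]
        if cross.size == 0:
            out[i] = times[int(np.argmin(np.abs(((phase - th) + np.pi) % (2 * np.pi) - np.pi)))]
            continue
        j = int(rng.choice(cross))
        # linear interpolation between samples j and j+1
        lvl = (k[j] + 1) * 2 * np.pi + th
        frac = (lvl - unwrapped[j]) / (unwrapped[j + 1] - unwrapped[j])
        out[i] = times[j] + np.clip(frac, 0, 1) * dt
    return np.sort(out)


def _apply_coupling(cfg: SessionConfig, bundle: SessionBundle,
                    coding: list[UnitGroundTruth], rng: np.random.Generator) -> None:
    var = bundle.trials["variance"].to_numpy(float)
    times_full = bundle.lfp_times()
    win_sel = (times_full >= CUE_ON) & (times_full <= TARGET_ON)
    times = times_full[win_sel]
    for direction, sched in cfg.coupling.items():
        spike_area, field_area = direction.split("->")
        if field_area not in bundle.lfps:
            continue
        band = tuple(sched["band"])
        kappas = {float(k): float(v) for k, v in sched["kappa"].items()}
        mu = float(sched.get("preferred_phase", 0.0))
        frac = float(sched.get("fraction", 1.0))
        n_el = bundle.lfps[field_area].shape[0]
        area_units = [u for u in coding if u.area == spike_area]
        n_coupled = int(round(frac * len(area_units)))
        # band-filtered phase per (electrode, trial), computed once
        phase_cache: dict[int, np.ndarray] = {}
        for u in area_units[:n_coupled]:
            u.coupled = True
            e = int(rng.integers(0, n_el))
            u.coupling_electrode = e
            if e not in phase_cache:
                phase_cache[e] = bandpass_phase(
                    bundle.lfps[field_area][e], cfg.sampling_rate, band)[:, win_sel]
            phases = phase_cache[e]
            rec = next(r for r in bundle.units if r.unit_id == u.unit_id)
            for tr in range(len(var)):
                st = rec.spike_times[tr]
                in_win = (st >= CUE_ON) & (st < TARGET_ON)
                n_move = int(np.sum(in_win))
                if n_move == 0:
                    continue
                kap = kappas[var[tr]]
                targets = (rng.uniform(-np.pi, np.pi, n_move) if kap == 0
                           else rng.vonmises(mu, kap, n_move))
                new = _map_phases_to_times(np.unwrap(phases[tr]), phases[tr],
                                           times, targets, rng)
                rec.spike_times[tr] = np.sort(np.concatenate([st[~in_win], new]))


def simulate_session(config: SessionConfig | None = None, seed: int = 0) -> SessionBundle:
    """Generate one complete synthetic session with fully populated ground truth."""
    cfg = copy.deepcopy(config) if config is not None else SessionConfig()
    if cfg.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    for area in cfg.areas:
        if cfg.n_units_for(area) <= 0:
            raise ValueError("unit count must be positive")
    rngs = _named_rngs(int(seed), ["trials", "spikes", "lfp", "coupling", "artifacts"])

    trials = _draw_trials(cfg, rngs["trials"])
    coding = _assign_unit_coding(cfg, rngs["spikes"])
    units = _simulate_units(cfg, trials, coding, rngs["spikes"])
    lfps = _simulate_lfp(cfg, trials, rngs["lfp"]) if cfg.make_lfp else {}

    gt = GroundTruth(
        lick_coeffs=dict(cfg.lick_coeffs),
        unit_coding=coding,
        shared_latents={s: cfg.gain_latent_sd
                        for s in sorted({u.subnetwork for u in coding if u.subnetwork})},
        lfp_band_effects=copy.deepcopy(cfg.lfp_band_effects) if cfg.make_lfp else {},
        coupling=copy.deepcopy(cfg.coupling) if cfg.make_lfp else {},
        rt_coeffs=dict(cfg.rt_coeffs),
    )
    bundle = SessionBundle(trials=trials, units=units, lfps=lfps,
                           sampling_rate=cfg.sampling_rate, ground_truth=gt)
    if cfg.make_lfp and cfg.coupling:
        _apply_coupling(cfg, bundle, coding, rngs["coupling"])
    for area, traces in bundle.lfps.items():
        gt.artifact_labels[area] = np.zeros(traces.shape[:2], dtype=bool)
        gt.artifact_kinds[area] = np.full(traces.shape[:2], "", dtype=object)
    if cfg.artifact_rate > 0:
        bundle = inject_artifacts(bundle, cfg.artifact_rate, cfg.artifact_kinds,
                                  rng=rngs["artifacts"])
    gt.validate()
    return bundle


def inject_artifacts(bundle: SessionBundle, rate: float,
                     kinds: Sequence[str] = ARTIFACT_KINDS,
                     rng: np.random.Generator | int = 0) -> SessionBundle:
    """Corrupt a fraction of trial x electrode LFP traces, updating labels.

    Kinds: ``broadband-power`` (amplitude x sqrt(10), i.e. 10x power),
    ``line-noise`` (large 60 Hz sinusoid), ``saturation`` (rail-clamped
    segment), ``transient`` (brief 10x-SD pulse).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    for k in kinds:
        if k not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind: {k}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    out = copy.deepcopy(bundle)
    fs = out.sampling_rate
    for area, traces in out.lfps.items():
        n_el, n_tr, n_s = traces.shape
        labels = np.zeros((n_el, n_tr), dtype=bool)
        kind_arr = np.full((n_el, n_tr), "", dtype=object)
        mask = rng.random((n_el, n_tr)) < rate
        for e, tr in zip(*np.nonzero(mask)):
            kind = kinds[int(rng.integers(0, len(kinds)))]
            x = traces[e, tr]
            sd = np.std(x) or 1.0
            if kind == "broadband-power":
                traces[e, tr] = x * np.sqrt(10.0)
            elif kind == "line-noise":
                t = np.arange(n_s) / fs
                traces[e, tr] = x + 6.0 * sd * np.sin(2 * np.pi * 60.0 * t)
            elif kind == "saturation":
                i0 = int(rng.integers(0, n_s - n_s // 4))
                rail = 8.0 * sd * (1 if rng.random() < 0.5 else -1)
                traces[e, tr, i0:i0 + n_s // 4] = rail
            elif kind == "transient":
                i0 = int(rng.integers(0, n_s - int(0.05 * fs)))
                traces[e, tr, i0:i0 + int(0.05 * fs)] += 10.0 * sd
            labels[e, tr] = True
            kind_arr[e, tr] = kind
        if out.ground_truth is not None:
            out.ground_truth.artifact_labels[area] = labels
            out.ground_truth.artifact_kinds[area] = kind_arr
    return out


def ground_truth_dict(gt: GroundTruth) -> dict:
    """JSON-serializable view of the ground truth (arrays as lists)."""
    d = asdict(gt)
    d["artifact_labels"] = {a: v.tolist() for a, v in gt.artifact_labels.items()}
    d["artifact_kinds"] = {a: v.tolist() for a, v in gt.artifact_kinds.items()}
    return d
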