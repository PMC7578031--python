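"""Directional spike-field coherence (PPC) and field-field coherence (WPLI).

Spike-field coherence quantifies how strongly spike times concentrate at a
consistent phase of an LFP oscillation. When the spikes and the field come
from different areas it is a directional measure: coherence between area A
spikes and area B fields indexes transmission from A to B. The estimator is
the across-trial pairwise phase consistency: the average cosine of the phase
difference over all spike pairs drawn from *different* trials, with every
trial pair weighted equally regardless of its spike counts. This controls
the upward bias of naive spike-pair averaging at low spike counts and the
dependence between spikes of the same trial. The naive pooled-pair variant
(ppc_pooled) is kept for bias comparisons.

Field-field coupling uses the weighted phase lag index (WPLI), built from the
imaginary cross-spectrum only, and therefore insensitive to the zero-lag
correlations produced by volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lfp import wavelet_power, _morlet_scales
from .task_synth import UnitRecord

__all__ = [
    "PhaseSampleSet",
    "spike_triggered_phase",
    "ppc",
    "ppc_pooled",
    "ppc_bruteforce",
    "wpli",
    "session_sfc",
    "condition_stats",
    "directional_contrast",
]

SFC_FREQS = np.arange(4.0, 48.0)      # 4-47 Hz, 1 Hz step
DEFAULT_BINS = ((0.0, 200.0), (200.0, 400.0), (400.0, 600.0), (600.0, 800.0))


@dataclass
class PhaseSampleSet:
    """Per-spike LFP phases on a frequency grid.

    ``phases`` is (n_spikes, n_freqs), radians in (-pi, pi], phase 0 at the
    oscillation peak. ``trial_ids`` and ``bin_ids`` align with the spike axis.
    """

    unit_id: int
    electrode_id: int
    freqs: np.ndarray
    phases: np.ndarray
    trial_ids: np.ndarray
    bin_ids: np.ndarray
    n_dropped_edge: int = 0


def spike_triggered_phase(unit: UnitRecord, lfp_trials: np.ndarray, fs: float,
                          t0: float, freqs: np.ndarray = SFC_FREQS,
                          bins: tuple = DEFAULT_BINS, win_ms: float = 200.0,
                          electrode_id: int = 0) -> PhaseSampleSet:
    """Phase of the LFP at each spike time, per frequency.

    Each spike contributes the phase of a Hann-tapered ``win_ms`` window of
    the simultaneously recorded LFP centered on the spike, evaluated at each
    frequency of the 4-47 Hz grid. A spike at the peak of a pure sinusoid
    yields phase 0. Spikes too close to the trace edge are dropped (counted),
    and spikes are assigned to 200 ms task-epoch bins.
    """
    lfp_trials = np.atleast_2d(lfp_trials)
    n_samples = lfp_trials.shape[-1]
    half = int(round(win_ms / 2 * fs / 1000.0))
    win_len = 2 * half + 1
    taper = np.hanning(win_len + 2)[1:-1]
    dt = np.arange(-half, half + 1) / fs
    # (win_len, n_freqs): e^{-i 2 pi f dt}; angle(sum) = phase at window center
    basis = taper[:, None] * np.exp(-2j * np.pi * dt[:, None] * np.asarray(freqs)[None, :])

    segs, trial_ids, bin_ids = [], [], []
    dropped = 0
    for tr, st in enumerate(unit.spike_times):
        for t_spike in np.atleast_1d(st):
            b = next((bi for bi, (lo, hi) in enumerate(bins) if lo <= t_spike < hi), None)
            if b is None:
                continue
            c = int(round((t_spike - t0) * fs / 1000.0))
            if c - half < 0 or c + half + 1 > n_samples:
                dropped += 1
                continue
            segs.append(lfp_trials[tr, c - half:c + half + 1])
            trial_ids.append(tr)
            bin_ids.append(b)
    if segs:
        phases = np.angle(np.asarray(segs) @ basis)
    else:
        phases = np.empty((0, len(freqs)))
    return PhaseSampleSet(unit.unit_id, electrode_id, np.asarray(freqs, float),
                          phases, np.asarray(trial_ids, int), np.asarray(bin_ids, int),
                          dropped)


def ppc(phases: np.ndarray, trial_ids: np.ndarray) -> float:
    """Across-trial pairwise phase consistency with equal trial-pair weights.

    For each trial m let r_m be the mean phasor of its spikes. The statistic
    is the average over all trial pairs (m != n) of Re(r_m conj(r_n)) -- the
    mean pairwise cosine between the trials' spikes, with each trial pair
    contributing once. Returns NaN when fewer than two trials have spikes.
    """
    phases = np.asarray(phases, float)
    trial_ids = np.asarray(trial_ids)
    trials = np.unique(trial_ids)
    if trials.size < 2:
        return float("nan")
    r = np.array([np.exp(1j * phases[trial_ids == m]).mean() for m in trials])
    M = r.size
    total = np.abs(r.sum()) ** 2 - np.sum(np.abs(r) ** 2)
    return float(total / (M * (M - 1)))


def ppc_pooled(phases: np.ndarray) -> float:
    """Naive PPC over all spike pairs pooled across trials (bias-prone)."""
    phases = np.asarray(phases, float)
    N = phases.size
    if N < 2:
        return float("nan")
    s = np.exp(1j * phases).sum()
    return float((np.abs(s) ** 2 - N) / (N * (N - 1)))


def ppc_bruteforce(phases: np.ndarray, trial_ids: np.ndarray) -> float:
    """Independent oracle: explicit double loop over cross-trial spike pairs."""
    phases = np.asarray(phases, float)
    trial_ids = np.asarray(trial_ids)
    trials = np.unique(trial_ids)
    if trials.size < 2:
        return float("nan")
    vals = []
    for i, m in enumerate(trials):
        for n in trials[i + 1:]:
            pm, pn = phases[trial_ids == m], phases[trial_ids == n]
            pair_cos = [np.cos(a - b) for a in pm for b in pn]
            vals.append(np.mean(pair_cos))
    return float(np.mean(vals))


def ppc_by_condition(ps: PhaseSampleSet, trials: pd.DataFrame,
                     condition: str = "variance",
                     by_bin: bool = False) -> pd.DataFrame:
    """Tidy PPC per condition level (x bin) x frequency for one pair."""
    rows = []
    cond = trials[condition].to_numpy()
    bins = np.unique(ps.bin_ids) if by_bin else [None]
    for lvl in np.unique(cond):
        in_lvl = np.isin(ps.trial_ids, np.nonzero(cond == lvl)[0])
        for b in bins:
            sel = in_lvl if b is None else (in_lvl & (ps.bin_ids == b))
            tid = ps.trial_ids[sel]
            n_trials = np.unique(tid).size
            for fi, f in enumerate(ps.freqs):
                val = ppc(ps.phases[sel, fi], tid) if n_trials >= 2 else np.nan
                rows.append({"unit_id": ps.unit_id, "electrode_id": ps.electrode_id,
                             "condition": lvl, "bin": -1 if b is None else int(b),
                             "freq": float(f), "ppc": val,
                             "n_spikes": int(sel.sum()), "n_trials": int(n_trials)})
    return pd.DataFrame(rows)


def wpli(lfp_a: np.ndarray, lfp_b: np.ndarray, fs: float,
         freqs: np.ndarray, t0: float = -1200.0,
         decim: int = 10) -> "object":
    """Weighted phase lag index per time-frequency cell across trials.

    WPLI = |sum_trials Im(X)| / sum_trials |Im(X)| with X the Morlet
    cross-spectrum of the two electrodes. Cells where the denominator is 0
    (e.g. identical signals, pure volume conduction) are NaN-flagged.
    Requires >= 2 trials. Invariant to amplitude scaling of either signal.
    """
    lfp_a, lfp_b = np.atleast_2d(lfp_a), np.atleast_2d(lfp_b)
    if lfp_a.shape[0] < 2:
        raise ValueError("WPLI requires at least two trials")
    wavelet, scales = _morlet_scales(np.asarray(freqs, float), fs, 7.0)
    import pywt
    ca, _ = pywt.cwt(lfp_a, scales, wavelet, sampling_period=1.0 / fs,
                     method="fft", axis=-1)
    cb, _ = pywt.cwt(lfp_b, scales, wavelet, sampling_period=1.0 / fs,
                     method="fft", axis=-1)
    # (freqs, trials, samples) -> decimate time
    x = (ca * np.conj(cb))[..., ::decim]
    imx = np.imag(x)
    num = np.abs(imx.sum(axis=1))
    den = np.abs(imx).sum(axis=1)
    # cells where Im(X) is numerically zero (pure zero-lag coupling) are undefined
    floor = 1e-12 * np.abs(x).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > floor, num / den, np.nan)
    times = t0 + np.arange(lfp_a.shape[-1]) * 1000.0 / fs
    from .lfp import TimeFrequencyMap
    return TimeFrequencyMap(w, np.asarray(freqs, float), times[::decim], "WPLI")


def session_sfc(bundle, spike_area: str, field_area: str,
                freqs: np.ndarray = SFC_FREQS, bins: tuple = DEFAULT_BINS,
                condition: str = "variance", by_bin: bool = False,
                max_units: int | None = None,
                max_electrodes: int | None = None) -> pd.DataFrame:
    """Directional SFC for all unit x electrode pairs between two areas.

    Pairs in which the unit fired no spikes are excluded. Returns tidy rows
    (pair, condition, bin, frequency, PPC, counts) with a ``direction``
    column ``spike_area->field_area``.
    """
    fields = bundle.lfps[field_area]
    n_el = fields.shape[0] if max_electrodes is None else min(max_electrodes, fields.shape[0])
    units = [u for u in bundle.units if u.area == spike_area]
    if max_units is not None:
        units = units[:max_units]
    frames = []
    for u in units:
        if sum(st.size for st in u.spike_times) == 0:
            continue
        for e in range(n_el):
            ps = spike_triggered_phase(u, fields[e], bundle.sampling_rate,
                                       bundle.t0, freqs, bins, electrode_id=e)
            if ps.phases.shape[0] == 0:
                continue
            frames.append(ppc_by_condition(ps, bundle.trials, condition, by_bin))
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    out["direction"] = f"{spike_area}->{field_area}"
    return out


def condition_stats(results: pd.DataFrame, value_col: str = "ppc",
                    alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis across condition levels per frequency, FDR-corrected.

    ``results`` is tidy SFC/WPLI output with columns condition, freq and the
    value column; samples are pairs. The modulation direction per frequency is
    the sign of the least-squares slope of the condition-level means.
    """
    rows = []
    for (b, f), sub in results.groupby(["bin", "freq"]):
        levels = sorted(sub["condition"].unique())
        groups = [sub.loc[sub["condition"] == lvl, value_col].dropna().to_numpy()
                  for lvl in levels]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        try:
            kw = stats.kruskal(*groups)
            p = float(kw.pvalue)
        except ValueError:      # all values identical
            p = 1.0
        means = [g.mean() for g in groups]
        x = np.array(levels[:len(groups)], dtype=float)
        slope = float(np.polyfit(x, means, 1)[0]) if len(means) >= 2 else np.nan
        rows.append({"bin": b, "freq": f, "p_raw": p, "slope": slope,
                     "direction": "increase" if slope > 0 else "decrease"})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_fdr"] = np.nan
        for b, sub in table.groupby("bin"):
            adj = multipletests(sub["p_raw"].to_numpy(), alpha=alpha, method="fdr_bh")[1]
            table.loc[sub.index, "p_fdr"] = adj
        table["significant"] = table["p_fdr"] < alpha
    return table


def _variance_slopes_per_pair(sfc: pd.DataFrame, band: tuple[float, float],
                              bin_id: int | None = None) -> np.ndarray:
    sel = (sfc["freq"] >= band[0]) & (sfc["freq"] <= band[1])
    if bin_id is not None:
        sel &= sfc["bin"] == bin_id
    sub = sfc[sel].dropna(subset=["ppc"])
    slopes = []
    for (u, e), g in sub.groupby(["unit_id", "electrode_id"]):
        means = g.groupby("condition")["ppc"].mean()
        if len(means) >= 2:
            slopes.append(np.polyfit(means.index.to_numpy(float),
                                     means.to_numpy(), 1)[0])
    return np.asarray(slopes)


def directional_contrast(sfc_ab: pd.DataFrame, sfc_ba: pd.DataFrame,
                         band: tuple[float, float] = (8.0, 18.0),
                         bin_id: int | None = None, n_boot: int = 1000,
                         seed: int = 0) -> dict:
    """Difference in variance-modulation of SFC between the two directions.

    Per pair, the slope of mean PPC vs variance level is computed within the
    band (and epoch bin if given); the asymmetry is the difference of the
    directions' mean slopes, with a bootstrap-over-pairs 95% CI.
    """
    for df in (sfc_ab, sfc_ba):
        if df.empty:
            raise ValueError("mismatched grids: a direction has no SFC values")
    if set(sfc_ab["freq"]) != set(sfc_ba["freq"]):
        raise ValueError("mismatched frequency grids between directions")
    s_ab = _variance_slopes_per_pair(sfc_ab, band, bin_id)
    s_ba = _variance_slopes_per_pair(sfc_ba, band, bin_id)
    if s_ab.size == 0 or s_ba.size == 0:
        raise ValueError("no pairs with defined slopes in a direction")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (rng.choice(s_ab, s_ab.size).mean()
                    - rng.choice(s_ba, s_ba.size).mean())
    return {
        "slope_ab": float(s_ab.mean()), "slope_ba": float(s_ba.mean()),
        "asymmetry": float(s_ab.mean() - s_ba.mean()),
        "ci": (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
        "n_pairs": (int(s_ab.size), int(s_ba.size)),
    }
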