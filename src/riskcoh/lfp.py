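"""LFP preprocessing, artifact rejection, time-frequency power, and GLM maps.

Preprocessing is a zero-phase 60 Hz notch, zero-phase 100 Hz low-pass, and
linear detrend. Artifact rejection is a two-step, condition-blind procedure:

1. *Frequency domain.* Each trial is summarized by the sum of log multitaper
   power in five bands (0.5-4, 4-8, 8-12, 12-30, 30-90 Hz), projected to two
   principal components and clustered with a Gaussian mixture (K chosen by
   BIC). Trials in sparse clusters are discarded, as are trials within dense
   clusters whose Mahalanobis distance to the cluster exceeds the 90th
   percentile.
2. *Time domain.* Peak-to-peak amplitudes of the surviving trials are
   z-scored and trials with |z| > 0.5 are removed. This is deliberately
   conservative (it would remove ~62% of trials from a clean Gaussian
   peak-to-peak distribution).

Power uses Morlet wavelets (1 Hz bins, 7 cycles) and is normalized per trial
and frequency as relative power change against the trial's own 300 ms pre-cue
baseline: (power_tf - baseline_f) / baseline_f. Coefficient maps come from a
per-pixel GLM (normal identity) with EV, variance, EV x variance, and cue
location; regions of interest are epoch x frequency cells whose coefficients
are significant (FDR across frequencies) with the same sign in all subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess_lfp",
    "band_power_features",
    "clean_frequency_domain",
    "clean_time_domain",
    "clean_session",
    "wavelet_power",
    "normalize_power",
    "fit_pixel_glm",
    "detect_rois",
    "ROI",
    "TimeFrequencyMap",
]

LOG_POWER_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 30.0), (30.0, 90.0))
ANALYSIS_EPOCHS = ((0.0, 200.0), (200.0, 400.0), (400.0, 600.0), (600.0, 800.0))
BASELINE_WINDOW = (-300.0, 0.0)


@dataclass
class TimeFrequencyMap:
    """Values on a (frequency x time) grid with axis metadata."""

    values: np.ndarray          # (..., n_freqs, n_times)
    freqs: np.ndarray           # Hz
    times: np.ndarray           # ms relative to cue onset
    content: str = "raw power"  # | "relative power change" | "GLM coefficient" | "p-value"


@dataclass
class ROI:
    factor: str
    band: tuple[float, float]
    epoch: tuple[float, float]
    sign: int
    p_values: list[float]       # per subject, FDR-adjusted


def preprocess_lfp(traces: np.ndarray, fs: float,
                   notch_hz: float = 60.0, lowpass_hz: float = 100.0) -> np.ndarray:
    """Zero-phase 60 Hz notch + 100 Hz low-pass + linear detrend (last axis)."""
    if fs < 250.0:
        raise ValueError("sampling rate must be >= 250 Hz")
    traces = np.asarray(traces, dtype=float)
    if not np.all(np.isfinite(traces)):
        raise ValueError("NaN or infinite samples in LFP")
    b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
    out = signal.filtfilt(b, a, traces, axis=-1)
    sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, out, axis=-1)
    return signal.detrend(out, axis=-1, type="linear")


def band_power_features(traces: np.ndarray, fs: float, n_tapers: int = 4,
                        fmax: float = 90.0) -> np.ndarray:
    """Per-trial 5-vector: sum of log multitaper power in the five bands."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[-1]
    if n < 64:
        raise ValueError("trial too short for multitaper estimation")
    nw = (n_tapers + 1) / 2.0
    tapers = signal.windows.dpss(n, nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # (tapers, trials, freqs)
    spec = np.fft.rfft(tapers[:, None, :] * traces[None, :, :], axis=-1)
    psd = np.mean(np.abs(spec) ** 2, axis=0)
    feats = np.empty((traces.shape[0], len(LOG_POWER_BANDS)))
    for bi, (lo, hi) in enumerate(LOG_POWER_BANDS):
        sel = (freqs >= lo) & (freqs < min(hi, fmax))
        feats[:, bi] = np.sum(np.log(psd[:, sel] + 1e-300), axis=-1)
    return feats


def clean_frequency_domain(features: np.ndarray, k_range: tuple[int, ...] = (2, 3, 4),
                           dense_fraction: float = 0.8, mahal_percentile: float = 90.0,
                           seed: int = 0) -> tuple[np.ndarray, dict]:
    """GMM-based outlier rejection in the band-power feature space.

    Returns a boolean keep mask over trials and an audit dict. Dense clusters
    are the largest clusters jointly holding >= ``dense_fraction`` of trials;
    sparse-cluster trials are discarded, and within dense clusters trials with
    Mahalanobis distance to the cluster (mean, covariance) above the
    ``mahal_percentile`` percentile are discarded.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 50:
        raise ValueError("need >= 50 trials for frequency-domain cleaning")
    Z = (features - features.mean(0)) / np.where(features.std(0) > 0, features.std(0), 1.0)
    pcs = PCA(n_components=2).fit_transform(Z)

    best, best_bic = None, np.inf
    for k in k_range:
        gm = GaussianMixture(k, covariance_type="full", n_init=3, random_state=seed,
                             reg_covar=1e-6).fit(pcs)
        bic = gm.bic(pcs)
        if bic < best_bic:
            best, best_bic = gm, bic
    labels = best.predict(pcs)
    sizes = np.bincount(labels, minlength=best.n_components)
    order = np.argsort(sizes)[::-1]
    # dense clusters: largest-first until they jointly hold >= dense_fraction
    # of trials; a cluster under half the largest is sparse outright, so an
    # outlier cluster near the coverage boundary is never absorbed as dense
    dense, cum = [], 0
    for c in order:
        if dense and sizes[c] < 0.5 * sizes[order[0]]:
            break
        dense.append(c)
        cum += sizes[c]
        if cum >= dense_fraction * n:
            break
    keep = np.isin(labels, dense)
    audit = {"n_in": int(n), "k": int(best.n_components), "bic": float(best_bic),
             "n_sparse_removed": int(np.sum(~keep)), "regularized": False}

    for c in dense:
        idx = np.nonzero(labels == c)[0]
        if idx.size < 3:
            continue
        x = pcs[idx]
        mu = x.mean(0)
        cov = np.cov(x.T)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            cov_inv = np.linalg.inv(cov + 1e-6 * np.eye(2))
            audit["regularized"] = True
        d2 = np.einsum("ij,jk,ik->i", x - mu, cov_inv, x - mu)
        thresh = np.percentile(d2, mahal_percentile)
        keep[idx[d2 > thresh]] = False
    audit["n_mahalanobis_removed"] = int(n - np.sum(keep) - audit["n_sparse_removed"])
    audit["n_kept"] = int(np.sum(keep))
    return keep, audit


def clean_time_domain(traces: np.ndarray, keep: np.ndarray,
                      z_threshold: float = 0.5) -> tuple[np.ndarray, dict]:
    """Remove surviving trials whose peak-to-peak amplitude has |z| > 0.5."""
    keep = np.asarray(keep, dtype=bool).copy()
    idx = np.nonzero(keep)[0]
    ptp = np.ptp(np.asarray(traces)[idx], axis=-1)
    sd = ptp.std()
    audit = {"n_in": int(idx.size), "sd_zero": bool(sd == 0)}
    if sd == 0:
        audit.update(n_removed=0, n_kept=int(idx.size), exclusion_fraction=0.0)
        return keep, audit
    z = (ptp - ptp.mean()) / sd
    bad = np.abs(z) > z_threshold
    keep[idx[bad]] = False
    audit.update(n_removed=int(bad.sum()), n_kept=int(np.sum(keep)),
                 exclusion_fraction=float(bad.sum() / idx.size))
    return keep, audit


def clean_session(traces: np.ndarray, fs: float, seed: int = 0,
                  **freq_kwargs) -> tuple[np.ndarray, dict]:
    """Both cleaning steps on one session's (trials x samples) traces."""
    feats = band_power_features(traces, fs)
    keep1, audit1 = clean_frequency_domain(feats, seed=seed, **freq_kwargs)
    keep2, audit2 = clean_time_domain(traces, keep1)
    n = traces.shape[0]
    return keep2, {"frequency_domain": audit1, "time_domain": audit2,
                   "n_in": int(n), "n_kept": int(keep2.sum()),
                   "exclusion_fraction": float(1 - keep2.sum() / n)}


def _morlet_scales(freqs: np.ndarray, fs: float, n_cycles: float) -> tuple[str, np.ndarray]:
    # complex Morlet 'cmorB-C': time SD at scale a is a*sqrt(B/2)/fs and the
    # center frequency is C*fs/a; choose B so the envelope spans n_cycles.
    C = 1.0
    B = 2.0 * (n_cycles / (2 * np.pi)) ** 2
    scales = C * fs / np.asarray(freqs, dtype=float)
    return f"cmor{B:.6f}-{C:.6f}", scales


def wavelet_power(traces: np.ndarray, fs: float,
                  freqs: np.ndarray | None = None, n_cycles: float = 7.0,
                  t0: float = -1200.0, decim: int = 1) -> TimeFrequencyMap:
    """Morlet wavelet power in 1 Hz bins (or a custom frequency grid).

    ``traces`` may be (samples,) or (trials, samples); the output grid is
    (freqs x times), decimated in time by ``decim``.
    """
    traces = np.asarray(traces, dtype=float)
    freqs = np.arange(1.0, 101.0) if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.max() > fs / 2:
        raise ValueError("frequency above Nyquist")
    wavelet, scales = _morlet_scales(freqs, fs, n_cycles)
    coef, _ = pywt.cwt(traces, scales, wavelet, sampling_period=1.0 / fs,
                       method="fft", axis=-1)
    # pywt puts scales first: (n_freqs, [n_trials,] n_samples)
    power = np.abs(coef) ** 2
    if power.ndim == 3:
        power = np.moveaxis(power, 0, 1)   # (trials, freqs, samples)
    times = t0 + np.arange(traces.shape[-1]) * 1000.0 / fs
    return TimeFrequencyMap(power[..., ::decim], freqs, times[::decim], "raw power")


def normalize_power(tfmap: TimeFrequencyMap, mode: str = "safe",
                    baseline_window: tuple[float, float] = BASELINE_WINDOW) -> TimeFrequencyMap:
    """Relative power change vs the trial's own pre-cue baseline.

    relative power change(t, f) = (power_tf - baseline_f) / baseline_f, with
    baseline_f the mean over the 300 ms before cue onset of the same trial.
    ``safe`` applies this to raw (positive) power. ``paper`` first z-scores
    power per frequency over all trials and time points, then applies the
    same ratio to the z-scored values; near-zero baselines are flagged as NaN
    (this ordering is numerically fragile, which is why it is not the
    default).
    """
    vals = tfmap.values.astype(float)
    sel = (tfmap.times >= baseline_window[0]) & (tfmap.times < baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window outside the map's time axis")
    if mode == "paper":
        ax = tuple(i for i in range(vals.ndim) if i != vals.ndim - 2)
        mu = vals.mean(axis=ax, keepdims=True)
        sd = vals.std(axis=ax, keepdims=True)
        vals = (vals - mu) / np.where(sd > 0, sd, 1.0)
        base = vals[..., sel].mean(axis=-1, keepdims=True)
        out = np.where(np.abs(base) > 1e-6, (vals - base) / base, np.nan)
    elif mode == "safe":
        if np.any(vals[..., sel] <= 0):
            raise ValueError("non-positive baseline power in safe mode")
        base = vals[..., sel].mean(axis=-1, keepdims=True)
        out = (vals - base) / base
    else:
        raise ValueError(f"unknown normalization mode: {mode}")
    return TimeFrequencyMap(out, tfmap.freqs, tfmap.times, "relative power change")


_PIXEL_FACTORS = ("ev", "variance", "ev_x_variance", "cue_location")


def fit_pixel_glm(maps: np.ndarray, trials: pd.DataFrame,
                  freqs: np.ndarray, times: np.ndarray) -> dict[str, dict[str, TimeFrequencyMap]]:
    """Per-pixel GLM (normal identity) of normalized power on the task factors.

    ``maps`` is (n_obs, n_freqs, n_times), with observations = trials pooled
    across an array's electrodes; ``trials`` has one row per observation. The
    identity-link normal GLM is ordinary least squares, solved in closed form
    for all pixels at once. Returns per-factor coefficient and p-value maps;
    pixels with any non-finite observation are marked missing.
    """
    n_obs = maps.shape[0]
    if len(trials) != n_obs:
        raise ValueError("one metadata row per observation required")
    X = np.column_stack([
        np.ones(n_obs),
        trials["ev"].to_numpy(float),
        trials["variance"].to_numpy(float),
        (trials["ev"] * trials["variance"]).to_numpy(float),
        trials["cue_location"].to_numpy(float),
    ])
    Y = maps.reshape(n_obs, -1)
    finite = np.all(np.isfinite(Y), axis=0)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = np.full((X.shape[1], Y.shape[1]), np.nan)
    pvals = np.full_like(beta, np.nan)
    if finite.any():
        Yf = Y[:, finite]
        b = XtX_inv @ (X.T @ Yf)
        resid = Yf - X @ b
        dof = n_obs - X.shape[1]
        s2 = np.sum(resid**2, axis=0) / dof
        se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = b / se
        p = 2 * stats.t.sf(np.abs(tstat), dof)
        beta[:, finite] = b
        pvals[:, finite] = p
    shape = maps.shape[1:]
    out: dict[str, dict[str, TimeFrequencyMap]] = {}
    for i, fac in enumerate(_PIXEL_FACTORS):
        out[fac] = {
            "coef": TimeFrequencyMap(beta[i + 1].reshape(shape), freqs, times, "GLM coefficient"),
            "p": TimeFrequencyMap(pvals[i + 1].reshape(shape), freqs, times, "p-value"),
        }
    return out


def electrode_coefficient_maps(maps_by_electrode: list[np.ndarray],
                               trials: pd.DataFrame, freqs: np.ndarray,
                               times: np.ndarray) -> dict[str, np.ndarray]:
    """Per-electrode GLM coefficient maps: factor -> (n_electrodes, f, t)."""
    out: dict[str, list[np.ndarray]] = {f: [] for f in _PIXEL_FACTORS}
    for m in maps_by_electrode:
        res = fit_pixel_glm(m, trials, freqs, times)
        for f in _PIXEL_FACTORS:
            out[f].append(res[f]["coef"].values)
    return {f: np.stack(v) for f, v in out.items()}


def detect_rois(subject_maps: list[dict[str, np.ndarray]], freqs: np.ndarray,
                times: np.ndarray, factors: tuple[str, ...] = ("ev", "variance"),
                epochs: tuple[tuple[float, float], ...] = ANALYSIS_EPOCHS,
                alpha: float = 0.05) -> list[ROI]:
    """Cross-subject ROI detection on per-electrode coefficient maps.

    For each subject, factor, 200 ms epoch and frequency, the coefficients are
    averaged over the epoch's time pixels per electrode and tested against 0
    across electrodes (Wilcoxon signed-rank, the one-sample rank analog of the
    across-group Kruskal-Wallis), with Benjamini-Hochberg FDR correction
    across frequencies. Cells significant with the same sign in all subjects
    are merged over contiguous frequencies into band x epoch ROIs.
    """
    if len(subject_maps) < 1:
        raise ValueError("need at least one subject")
    rois: list[ROI] = []
    n_f = freqs.size
    for factor in factors:
        for (e_lo, e_hi) in epochs:
            tsel = (times >= e_lo) & (times < e_hi)
            if not tsel.any():
                continue
            sig = np.ones(n_f, dtype=bool)
            signs = np.zeros((len(subject_maps), n_f))
            padj_all = np.ones((len(subject_maps), n_f))
            for si, smap in enumerate(subject_maps):
                coefs = smap[factor][..., tsel].mean(axis=-1)  # (electrodes, freqs)
                praw = np.ones(n_f)
                for fi in range(n_f):
                    x = coefs[:, fi]
                    x = x[np.isfinite(x)]
                    if x.size >= 5 and np.any(x != 0):
                        praw[fi] = stats.wilcoxon(x).pvalue
                    signs[si, fi] = np.sign(np.median(x)) if x.size else 0
                padj = multipletests(praw, alpha=alpha, method="fdr_bh")[1]
                padj_all[si] = padj
                sig &= padj < alpha
            same_sign = np.all(signs == signs[0], axis=0) & (signs[0] != 0)
            cells = sig & same_sign
            # merge contiguous significant frequencies into bands
            fi = 0
            while fi < n_f:
                if cells[fi]:
                    fj = fi
                    while fj + 1 < n_f and cells[fj + 1]:
                        fj += 1
                    rois.append(ROI(
                        factor=factor, band=(float(freqs[fi]), float(freqs[fj])),
                        epoch=(float(e_lo), float(e_hi)), sign=int(signs[0, fi]),
                        p_values=[float(padj_all[si, fi:fj + 1].max())
                                  for si in range(len(subject_maps))],
                    ))
                    fi = fj + 1
                else:
                    fi += 1
    return rois
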