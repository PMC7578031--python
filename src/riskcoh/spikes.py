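"""Single-unit and pairwise spiking analyses.

Selectivity is measured with a trial-by-trial GLM of the 0-800 ms spike count
on EV, variance, their interaction, and cue location (normal distribution,
identity link). Units are labeled by which factors reach significance and by
the sign of the significant coefficient -- the opponent-coding convention in
which distinct subsets of neurons increase (+) or decrease (-) firing with the
same variable. Noise correlations use a 600 ms pre-cue epoch, which carries no
stimulus structure, and are grouped by the pair's selectivity classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import norm

from .task_synth import UnitRecord, CUE_ON, TARGET_ON

__all__ = [
    "SelectivityResult",
    "PairCorrelation",
    "spike_counts",
    "select_units",
    "fit_unit_glm",
    "spike_density",
    "fano_factor",
    "noise_correlations",
]

FACTORS = ("ev", "variance", "ev_x_variance", "cue_location")


@dataclass
class SelectivityResult:
    unit_id: int
    area: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    factor: str                   # "ev" | "variance" | "both" | "interaction-only" | "none"
    polarity: dict[str, int]      # per significant main factor: +1 / -1
    alpha: float = 0.05
    diagnostics: str = ""

    def significant(self, name: str) -> bool:
        p = self.p_values.get(name, np.nan)
        return bool(np.isfinite(p) and p < self.alpha)


@dataclass
class PairCorrelation:
    unit_a: int
    unit_b: int
    area: str
    r: float
    pair_class: str   # "within-same" | "within-opposite" | "across-same" | "across-opposite"


def spike_counts(unit: UnitRecord, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return np.array([np.sum((st >= lo) & (st < hi)) for st in unit.spike_times], dtype=float)


def select_units(units: list[UnitRecord], trials: pd.DataFrame,
                 min_trials: int = 5, min_mean_spikes: float = 5.0,
                 window: tuple[float, float] = (-500.0, 1000.0),
                 condition_cols: tuple[str, ...] = ("ev", "variance")) -> tuple[list[UnitRecord], dict]:
    """Apply the unit inclusion criteria.

    A unit is kept if every condition cell (the 9 EV x variance cells by
    default) has at least ``min_trials`` trials with that unit recorded, and
    the unit fired at least ``min_mean_spikes`` spikes on average in
    ``window``. Returns the included units and per-criterion exclusion counts.
    """
    cell_counts = trials.groupby(list(condition_cols)).size()
    enough_trials = (len(cell_counts) > 0) and (cell_counts.min() >= min_trials)
    kept, audit = [], {"n_in": len(units), "excluded_trials": 0, "excluded_rate": 0}
    for u in units:
        ok_trials = enough_trials and len(u.spike_times) == len(trials)
        mean_count = float(np.mean(spike_counts(u, window))) if len(u.spike_times) else 0.0
        ok_rate = mean_count >= min_mean_spikes
        if not ok_trials:
            audit["excluded_trials"] += 1
        elif not ok_rate:
            audit["excluded_rate"] += 1
        else:
            kept.append(u)
    audit["n_kept"] = len(kept)
    return kept, audit


def fit_unit_glm(unit: UnitRecord, trials: pd.DataFrame,
                 window: tuple[float, float] = (CUE_ON, TARGET_ON),
                 alpha: float = 0.05) -> SelectivityResult:
    """GLM of the windowed spike count on EV, variance, EV x variance, location."""
    y = spike_counts(unit, window)
    if np.var(y) == 0:
        zeros = {f: 0.0 for f in FACTORS}
        return SelectivityResult(unit.unit_id, unit.area, zeros,
                                 {f: np.nan for f in FACTORS}, "none", {}, alpha,
                                 diagnostics="zero-variance spike counts")
    X = pd.DataFrame({
        "ev": trials["ev"].astype(float).to_numpy(),
        "variance": trials["variance"].astype(float).to_numpy(),
        "ev_x_variance": (trials["ev"] * trials["variance"]).astype(float).to_numpy(),
        "cue_location": trials["cue_location"].astype(float).to_numpy(),
    })
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coef = {f: float(fit.params[f]) for f in FACTORS}
    pval = {f: float(fit.pvalues[f]) for f in FACTORS}
    sig_ev, sig_var = pval["ev"] < alpha, pval["variance"] < alpha
    if sig_ev and sig_var:
        factor = "both"
    elif sig_ev:
        factor = "ev"
    elif sig_var:
        factor = "variance"
    elif pval["ev_x_variance"] < alpha:
        factor = "interaction-only"
    else:
        factor = "none"
    polarity = {f: int(np.sign(coef[f])) for f, s in
                (("ev", sig_ev), ("variance", sig_var)) if s}
    return SelectivityResult(unit.unit_id, unit.area, coef, pval, factor, polarity, alpha)


def spike_density(unit: UnitRecord, trials: pd.DataFrame,
                  kernel_sd: float = 50.0,
                  window: tuple[float, float] = (-500.0, 1500.0),
                  group_by: str | None = None, zscore: bool = True) -> dict:
    """Gaussian-smoothed, optionally z-scored spike density per condition.

    Spike trains are binned at 1 ms, convolved with a Gaussian kernel
    (``kernel_sd`` ms SD), averaged over trials (per level of ``group_by`` if
    given), and z-scored using the cell's mean/SD over the cue+delay epoch
    (0-800 ms).
    """
    t = np.arange(window[0], window[1], 1.0)
    pad = int(4 * kernel_sd)
    edges = np.arange(window[0] - pad, window[1] + pad + 1.0, 1.0)
    kern_t = np.arange(-pad, pad + 1.0)
    kernel = norm.pdf(kern_t, 0, kernel_sd) * 1000.0  # spikes/s per 1 ms bin

    def smooth(trial_idx: np.ndarray) -> np.ndarray:
        if trial_idx.size == 0:
            raise ValueError("empty condition")
        counts = np.zeros(edges.size - 1)
        for i in trial_idx:
            counts += np.histogram(unit.spike_times[i], bins=edges)[0]
        rate = np.convolve(counts / trial_idx.size, kernel, mode="same")
        centers = edges[:-1] + 0.5
        return np.interp(t, centers, rate)

    all_idx = np.arange(len(trials))
    overall = smooth(all_idx)
    epoch = (t >= CUE_ON) & (t < TARGET_ON)
    mu, sd = overall[epoch].mean(), overall[epoch].std()

    def maybe_z(x: np.ndarray) -> np.ndarray:
        return (x - mu) / sd if (zscore and sd > 0) else x

    out = {"time_ms": t, "overall": maybe_z(overall)}
    if group_by is not None:
        out["conditions"] = {
            lvl: maybe_z(smooth(np.nonzero((trials[group_by] == lvl).to_numpy())[0]))
            for lvl in sorted(trials[group_by].unique())
        }
    return out


def fano_factor(unit: UnitRecord, trials: pd.DataFrame,
                window: tuple[float, float] = (CUE_ON, TARGET_ON),
                group_by: tuple[str, ...] = ("ev", "variance")) -> dict:
    """Across-trial spike-count variance / mean, overall and per condition."""
    y = spike_counts(unit, window)
    def ff(v: np.ndarray) -> float:
        m = v.mean()
        return float(v.var(ddof=1) / m) if m > 0 and v.size > 1 else float("nan")
    out = {"overall": ff(y), "conditions": {}}
    for key, sub in trials.groupby(list(group_by)):
        out["conditions"][key] = ff(y[sub.index.to_numpy()])
    return out


_CLASS_NAMES = {
    (True, True): "within-same", (True, False): "within-opposite",
    (False, True): "across-same", (False, False): "across-opposite",
}


def noise_correlations(units: list[UnitRecord], trials: pd.DataFrame,
                       selectivity: dict[int, SelectivityResult],
                       window: tuple[float, float] = (-600.0, 0.0),
                       zscore: bool = False) -> tuple[list[PairCorrelation], dict]:
    """Pearson noise correlations of pre-cue counts, grouped by selectivity.

    Pairs are same-area, simultaneously recorded units whose selectivity label
    is a single main factor (or "both", contributing through each significant
    factor's polarity). Classes: within-factor (both units code the same
    factor) vs across-factor, crossed with same vs opposite polarity.
    Group-level statistics: Kruskal-Wallis across the four classes and a
    Wilcoxon signed-rank test vs 0 per class.
    """
    counts = {}
    for u in units:
        c = spike_counts(u, window)
        if zscore and c.std() > 0:
            c = (c - c.mean()) / c.std()
        counts[u.unit_id] = c

    def unit_factors(res: SelectivityResult) -> list[tuple[str, int]]:
        return [(f, res.polarity[f]) for f in ("ev", "variance") if f in res.polarity]

    pairs: list[PairCorrelation] = []
    skipped = 0
    by_area: dict[str, list[UnitRecord]] = {}
    for u in units:
        by_area.setdefault(u.area, []).append(u)
    for area, area_units in by_area.items():
        for ua, ub in combinations(area_units, 2):
            ra, rb = selectivity.get(ua.unit_id), selectivity.get(ub.unit_id)
            if ra is None or rb is None:
                continue
            fa, fb = unit_factors(ra), unit_factors(rb)
            if not fa or not fb:
                continue
            ca, cb = counts[ua.unit_id], counts[ub.unit_id]
            if ca.std() == 0 or cb.std() == 0:
                skipped += 1
                continue
            r = float(np.corrcoef(ca, cb)[0, 1])
            # a unit significant for both factors contributes to each class
            for (f1, p1) in fa:
                for (f2, p2) in fb:
                    cls = _CLASS_NAMES[(f1 == f2, p1 == p2)]
                    pairs.append(PairCorrelation(ua.unit_id, ub.unit_id, area, r, cls))

    groups = {name: np.array([p.r for p in pairs if p.pair_class == name])
              for name in set(_CLASS_NAMES.values())}
    stats_out: dict = {"n_pairs": len(pairs), "n_skipped_zero_variance": skipped,
                       "group_means": {k: (float(v.mean()) if v.size else np.nan)
                                       for k, v in groups.items()},
                       "group_n": {k: int(v.size) for k, v in groups.items()}}
    nonempty = [v for v in groups.values() if v.size >= 2]
    if len(nonempty) >= 2:
        kw = stats.kruskal(*nonempty)
        stats_out["kruskal_wallis"] = {"statistic": float(kw.statistic),
                                       "p": float(kw.pvalue)}
    sign_tests = {}
    for k, v in groups.items():
        if v.size >= 5 and np.any(v != 0):
            sign_tests[k] = float(stats.wilcoxon(v).pvalue)
    stats_out["signed_rank_vs_zero"] = sign_tests
    return pairs, stats_out
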