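"""Pseudopopulation SVM decoding of EV and variance.

Units need not be simultaneously recorded for this analysis: on each
bootstrap repetition, m trials per unit and condition (m = the minimum trial
count over the units and the conditions being discriminated) are drawn and
stacked into pseudotrials. A linear max-margin classifier is scored with
stratified five-fold cross-validation, and the reported quantity is *excess
accuracy*: real-label accuracy minus label-shuffled accuracy per repetition,
summarized by its bootstrap distribution and 95% CI. Incongruent regimes
train on one factor's levels and test on the other's, mapped by rank
(low <-> low, high <-> high); chance-level incongruent transfer indicates
separated representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .task_synth import UnitRecord, CUE_ON, TARGET_ON

__all__ = [
    "DecodingConfig",
    "DecodingResult",
    "windowed_rates",
    "build_pseudopopulation",
    "decode_pairwise",
    "excess_accuracy",
    "cross_decode",
]


@dataclass
class DecodingConfig:
    window: tuple[float, float] = (CUE_ON, TARGET_ON)
    kernel_sd: float = 50.0
    folds: int = 5
    repetitions: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class DecodingResult:
    excess: np.ndarray            # per-repetition excess accuracy
    real: np.ndarray
    shuffled: np.ndarray
    mean: float = field(init=False)
    ci: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.excess))
        self.ci = (float(np.percentile(self.excess, 2.5)),
                   float(np.percentile(self.excess, 97.5)))


def windowed_rates(unit: UnitRecord, window: tuple[float, float],
                   kernel_sd: float = 50.0) -> np.ndarray:
    """Per-trial mean Gaussian-smoothed firing rate (spikes/s) in a window.

    The time average over the window of a kernel-smoothed spike train has the
    closed form (1/T) * sum_spikes [Phi((hi-t_s)/sd) - Phi((lo-t_s)/sd)],
    which avoids gridding entirely.
    """
    lo, hi = window
    T = (hi - lo) / 1000.0
    out = np.empty(len(unit.spike_times))
    for i, st in enumerate(unit.spike_times):
        if st.size == 0:
            out[i] = 0.0
        else:
            out[i] = np.sum(norm.cdf((hi - st) / kernel_sd)
                            - norm.cdf((lo - st) / kernel_sd)) / T
    return out


def _condition_pools(trials: pd.DataFrame, factor: str,
                     levels: tuple) -> dict:
    return {lvl: np.nonzero((trials[factor] == lvl).to_numpy())[0] for lvl in levels}


def balanced_trial_count(trials: pd.DataFrame, factor: str, levels: tuple) -> int:
    """m = minimum trial count over the discriminated conditions."""
    return min(len(v) for v in _condition_pools(trials, factor, levels).values())


def build_pseudopopulation(rates: dict[int, np.ndarray], pools: dict,
                           m: int, rng: np.random.Generator,
                           exclude: dict | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Stack m randomly chosen trials per unit and condition into pseudotrials.

    ``rates`` maps unit_id -> per-trial response; ``pools`` maps condition
    level -> trial indices. Rows are pseudotrials (condition-aligned across
    units, trial order randomized per unit), columns are units. Returns the
    matrix, labels, and the per-unit-condition trial indices used (so a
    disjoint test set can be drawn).
    """
    unit_ids = sorted(rates)
    n_cond = len(pools)
    X = np.empty((m * n_cond, len(unit_ids)))
    y = np.empty(m * n_cond, dtype=object)
    used: dict = {u: {} for u in unit_ids}
    for ci, (lvl, pool) in enumerate(sorted(pools.items(), key=lambda kv: str(kv[0]))):
        rows = slice(ci * m, (ci + 1) * m)
        y[rows] = lvl
        for uj, u in enumerate(unit_ids):
            avail = pool
            if exclude is not None and lvl in exclude.get(u, {}):
                avail = np.setdiff1d(pool, exclude[u][lvl])
            if len(avail) < m:
                raise ValueError(f"unit {u}, condition {lvl}: only {len(avail)} trials for m={m}")
            pick = rng.choice(avail, size=m, replace=False)
            used[u][lvl] = pick
            X[rows, uj] = rates[u][pick]
    return X, y, used


def _classifier():
    # linear kernel, unit regularization; features z-scored on training folds only
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def decode_pairwise(X: np.ndarray, y: np.ndarray, config: DecodingConfig,
                    rng: np.random.Generator | None = None) -> float:
    """Stratified k-fold cross-validated accuracy of a linear SVM."""
    levels = np.unique(y.astype(str))
    if levels.size != 2:
        raise ValueError("decode_pairwise requires exactly two label values")
    if np.all(X.std(axis=0) == 0):
        return 0.5
    seed = int(rng.integers(2**31)) if rng is not None else config.seed
    cv = StratifiedKFold(config.folds, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(_classifier(), X, y.astype(str), cv=cv)))


def excess_accuracy(units: list[UnitRecord], trials: pd.DataFrame, factor: str,
                    levels: tuple, config: DecodingConfig | None = None) -> DecodingResult:
    """Bootstrap distribution of real-minus-shuffled decoding accuracy."""
    config = config or DecodingConfig()
    rng = np.random.default_rng(config.seed)
    rates = {u.unit_id: windowed_rates(u, config.window, config.kernel_sd) for u in units}
    pools = _condition_pools(trials, factor, levels)
    m = min(len(p) for p in pools.values())
    if m < config.folds:
        raise ValueError(f"m={m} < folds={config.folds}")
    real = np.empty(config.repetitions)
    shuf = np.empty(config.repetitions)
    for rep in range(config.repetitions):
        X, y, _ = build_pseudopopulation(rates, pools, m, rng)
        real[rep] = decode_pairwise(X, y, config, rng)
        y_perm = rng.permutation(y)
        shuf[rep] = decode_pairwise(X, y_perm, config, rng)
    return DecodingResult(excess=real - shuf, real=real, shuffled=shuf)


def cross_decode(units: list[UnitRecord], trials: pd.DataFrame,
                 train_factor: str, train_levels: tuple,
                 test_factor: str, test_levels: tuple,
                 config: DecodingConfig | None = None) -> DecodingResult:
    """Train on one factor's levels, test on the other's, mapped by rank.

    Train and test pseudotrials are disjoint: test draws exclude the trials
    used for training wherever the condition pools overlap. The shuffled
    baseline permutes the training labels and evaluates on the same test set.
    """
    config = config or DecodingConfig()
    if len(train_levels) != 2 or len(test_levels) != 2:
        raise ValueError("train and test label sets must each be binary")
    rng = np.random.default_rng(config.seed)
    rates = {u.unit_id: windowed_rates(u, config.window, config.kernel_sd) for u in units}
    train_pools = _condition_pools(trials, train_factor, train_levels)
    test_pools = _condition_pools(trials, test_factor, test_levels)
    # rank mapping low<->low, high<->high: test labels expressed as train labels
    mapping = dict(zip(sorted(test_levels), sorted(train_levels)))

    m_tr = min(len(p) for p in train_pools.values())
    overlap = any(np.intersect1d(tp, trp).size
                  for tp in test_pools.values() for trp in train_pools.values())
    if overlap:
        m_tr = max(m_tr // 2, config.folds)  # reserve disjoint test trials
    real = np.empty(config.repetitions)
    shuf = np.empty(config.repetitions)
    for rep in range(config.repetitions):
        Xtr, ytr, used = build_pseudopopulation(rates, train_pools, m_tr, rng)
        # test pools exclude train-used trials per unit where they overlap
        excl = {u: {lvl: np.concatenate(list(d.values())) for lvl in test_levels}
                for u, d in used.items()}
        m_te = min(
            min(len(np.setdiff1d(pool, np.concatenate(list(used[u].values()))))
                for u in rates)
            for pool in test_pools.values())
        if m_te < 2:
            raise ValueError("not enough disjoint test trials")
        Xte, yte, _ = build_pseudopopulation(rates, test_pools, m_te, rng, exclude=excl)
        yte_mapped = np.array([mapping.get(lvl, lvl) for lvl in yte], dtype=object)
        clf = _classifier().fit(Xtr, ytr.astype(str))
        real[rep] = float(np.mean(clf.predict(Xte) == yte_mapped.astype(str)))
        clf_s = _classifier().fit(Xtr, rng.permutation(ytr).astype(str))
        shuf[rep] = float(np.mean(clf_s.predict(Xte) == yte_mapped.astype(str)))
    return DecodingResult(excess=real - shuf, real=real, shuffled=shuf)
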