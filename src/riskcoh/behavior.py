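"""Behavioral analyses: trial filtering and GLMs for licking and reaction time.

Anticipatory licking is the behavioral readout of reward expectation: its
log-odds are modeled as a linear function of the cue's expected value (EV,
points) and variance (points^2), with cue location and the EV x variance
interaction as nuisance regressors. EV and variance enter on their natural
scales (3/6/9 and 0/1/4), so coefficients are per point and per point^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GLMResult",
    "filter_trials",
    "compute_lick_response",
    "fit_behavior_glm",
    "compare_uncertainty_models",
]

#: per-subject lick measurement windows (ms after cue onset)
LICK_WINDOW_PRESETS = {"monkey1": (400, 800), "monkey2": (800, 1100)}


@dataclass
class GLMResult:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    family: str
    link: str
    n_obs: int
    log_likelihood: float
    aic: float
    diagnostics: list[str] = field(default_factory=list)

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        b, se = self.coefficients[name], self.std_errors[name]
        return (b - z * se, b + z * se)


def filter_trials(trials: pd.DataFrame, n_sd: float = 2.0) -> pd.DataFrame:
    """Keep correct trials with RT within mean +- ``n_sd`` SD of correct trials.

    The RT mean/SD are computed over the session's correct trials. A
    zero-spread RT distribution keeps all correct trials. Kept/removed counts
    are recorded in ``result.attrs["filter_audit"]``.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = trials[trials["correct"].astype(bool)]
    if len(correct) == 0:
        raise ValueError("no correct trials in session")
    # RT bounds belong to the session's original correct-trial distribution;
    # reusing stored bounds makes the filter idempotent
    bounds = trials.attrs.get("rt_bounds")
    if bounds is None:
        mu, sd = correct["rt_ms"].mean(), correct["rt_ms"].std(ddof=1)
        bounds = ((-np.inf, np.inf) if not np.isfinite(sd) or sd == 0
                  else (mu - n_sd * sd, mu + n_sd * sd))
    kept = correct[correct["rt_ms"].between(*bounds)]
    kept = kept.copy()
    kept.attrs["rt_bounds"] = bounds
    kept.attrs["filter_audit"] = {
        "n_in": int(len(trials)),
        "n_kept": int(len(kept)),
        "n_removed_incorrect": int(len(trials) - len(correct)),
        "n_removed_rt": int(len(correct) - len(kept)),
    }
    return kept


def compute_lick_response(trace: np.ndarray, window: tuple[float, float],
                          fs: float = 1000.0, t0: float = 0.0,
                          mode: str = "fraction") -> float:
    """Lick response in a window of a 1 ms-resolution contact trace.

    ``fraction`` returns the fraction of window samples with tongue contact;
    ``binary`` returns 1.0 if any contact occurred.
    """
    trace = np.asarray(trace)
    times = t0 + np.arange(trace.size) * 1000.0 / fs
    lo, hi = window
    if lo < times[0] or hi > times[-1] + 1000.0 / fs:
        raise ValueError(f"window {window} outside trace extent [{times[0]}, {times[-1]}]")
    sel = (times >= lo) & (times < hi)
    vals = trace[sel]
    if mode == "binary":
        return float(np.any(vals > 0))
    return float(np.mean(vals > 0))


def _design(trials: pd.DataFrame, variance_col: str = "variance") -> pd.DataFrame:
    X = pd.DataFrame({
        "ev": trials["ev"].astype(float),
        variance_col: trials[variance_col].astype(float),
        "ev_x_variance": trials["ev"].astype(float) * trials["variance"].astype(float),
        "cue_location": trials["cue_location"].astype(float),
    })
    return sm.add_constant(X, has_constant="add")


def fit_behavior_glm(trials: pd.DataFrame, response: str = "lick",
                     family: str = "binomial-logit") -> GLMResult:
    """Fit response ~ EV + variance + EV x variance + cue location.

    ``family`` is ``binomial-logit`` (licking) or ``normal-identity``
    (saccade RT). Degenerate responses (all 0 or all 1 licks) are reported as
    a diagnostic rather than raised.
    """
    for col in ("ev", "variance"):
        if trials[col].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {col}")
    y = trials[response if response != "rt" else "rt_ms"].astype(float)
    X = _design(trials)
    diagnostics = []
    if family == "binomial-logit":
        fam = sm.families.Binomial()
        if y.nunique() < 2:
            diagnostics.append("degenerate response: no variation in lick")
    elif family == "normal-identity":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unknown family: {family}")
    try:
        fit = sm.GLM(y, X, family=fam).fit()
    except Exception as err:  # separation etc.
        diagnostics.append(f"fit failure: {err}")
        nan = {c: float("nan") for c in X.columns}
        return GLMResult(nan, dict(nan), dict(nan), family.split("-")[0],
                         family.split("-")[1], len(y), float("nan"), float("nan"),
                         diagnostics)
    return GLMResult(
        coefficients=dict(fit.params),
        std_errors=dict(fit.bse),
        p_values=dict(fit.pvalues),
        family=family.split("-")[0], link=family.split("-")[1],
        n_obs=int(fit.nobs), log_likelihood=float(fit.llf), aic=float(fit.aic),
        diagnostics=diagnostics,
    )


def compare_uncertainty_models(trials: pd.DataFrame, response: str = "lick",
                               family: str = "binomial-logit") -> dict:
    """Parametric-variance model vs binary probabilistic-vs-deterministic model.

    Fits the standard model (variance as 0/1/4) and a variant replacing the
    variance regressor with a binary indicator of a probabilistic cue, and
    compares them by AIC (log-likelihood and BIC reported too).
    """
    if not ((trials["variance"] > 0).any() and (trials["variance"] == 0).any()):
        raise ValueError("need both probabilistic and deterministic cues")
    parametric = fit_behavior_glm(trials, response, family)
    t2 = trials.copy()
    t2["variance"] = (t2["variance"] > 0).astype(float) * 1.0
    binary = fit_behavior_glm(t2, response, family)
    d_aic = parametric.aic - binary.aic
    preferred = "parametric" if d_aic < 0 else ("binary" if d_aic > 0 else "tie")

    def _bic(r: GLMResult) -> float:
        k = len(r.coefficients)
        return k * np.log(r.n_obs) - 2 * r.log_likelihood

    return {
        "parametric": parametric, "binary": binary,
        "log_likelihoods": {"parametric": parametric.log_likelihood,
                            "binary": binary.log_likelihood},
        "aic": {"parametric": parametric.aic, "binary": binary.aic},
        "bic": {"parametric": _bic(parametric), "binary": _bic(binary)},
        "delta_aic": float(d_aic),
        "preferred": preferred,
    }
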