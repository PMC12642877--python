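"""Temperature-response model fitting and comparison.

Two candidate shapes for the response of a volumetric rate to incubation
temperature:

* exponential (Q10): r(T) = r_ref * Q10**((T - T_ref)/10), fitted by
  log-linear least squares, appropriate for processes that accelerate
  monotonically over the tested range (dark DIC fixation, ammonia
  assimilation);
* unimodal: a Gaussian in temperature, r(T) = r_opt * exp(-(T-T_opt)^2 /
  (2 w^2)), fitted by bounded nonlinear least squares, appropriate for
  processes with an optimum inside the range (ammonia oxidation, which
  peaks near 10 degC in cold hypolimnion water).

Model choice is by small-sample-corrected AIC on residuals in rate space;
|dAICc| < 2 is reported as indistinguishable. The assimilation:fixation
ratio profile is computed per replicate pair before averaging, which is what
gives the ratio its replicate spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class TemperatureExperiment:
    """Replicated rates of one process across a temperature gradient."""

    process: str  # "oxidation", "dic_fixation" or "n_assimilation"
    temperatures: np.ndarray  # degC, one entry per record
    replicates: np.ndarray  # replicate ids, aligned
    rates: np.ndarray  # nmol l^-1 d^-1, aligned

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.replicates = np.asarray(self.replicates)
        self.rates = np.asarray(self.rates, dtype=float)
        if not self.temperatures.size == self.replicates.size == self.rates.size:
            raise ValueError("records must align")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, process: str) -> "TemperatureExperiment":
        sub = df[df["process"] == process]
        if sub.empty:
            raise ValueError(f"no records for process {process!r}")
        return cls(
            process=process,
            temperatures=sub["temperature_c"].to_numpy(),
            replicates=sub["replicate"].to_numpy(),
            rates=sub["rate"].to_numpy(),
        )

    def n_distinct_temperatures(self) -> int:
        return np.unique(self.temperatures).size


@dataclass
class FitResult:
    """Fitted temperature-response model with goodness-of-fit metadata."""

    model: str  # "exponential" or "unimodal"
    parameters: dict
    rss: float
    aicc: float
    n: int
    converged: bool
    boundary: bool = False

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.parameters
        if self.model == "exponential":
            return p["r_ref"] * p["q10"] ** ((t - p["t_ref"]) / 10.0)
        return p["r_opt"] * np.exp(-((t - p["t_opt"]) ** 2) / (2.0 * p["width"] ** 2))


def _aicc(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AICc; k counts model parameters plus the variance.

    NaN when the small-sample correction is undefined (n <= k + 1); the fit
    itself is still valid, only model selection becomes impossible.
    """
    if n - k - 1 <= 0:
        return math.nan
    rss = max(rss, 1e-300)  # guard log(0) on perfect fits
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_exponential(exp: TemperatureExperiment, t_ref: float = 5.0) -> FitResult:
    """Q10 fit by log-linear least squares: ln r = ln r_ref + (ln Q10 / 10)(T - T_ref).

    Exact on noiseless exponential data. Rates must be strictly positive
    (pre-floor upstream if needed); RSS and AICc are computed on residuals
    in rate space so exponential and unimodal fits are comparable.
    """
    if exp.n_distinct_temperatures() < 3:
        raise ValueError("need >= 3 distinct temperatures")
    if np.any(exp.rates <= 0):
        raise ValueError("exponential fit requires positive rates (log undefined)")
    x = exp.temperatures - t_ref
    coeffs = np.polyfit(x, np.log(exp.rates), 1)
    q10 = float(np.exp(10.0 * coeffs[0]))
    r_ref = float(np.exp(coeffs[1]))
    fitted = r_ref * q10 ** (x / 10.0)
    rss = float(np.sum((exp.rates - fitted) ** 2))
    n = exp.rates.size
    return FitResult(
        model="exponential",
        parameters={"r_ref": r_ref, "q10": q10, "t_ref": t_ref},
        rss=rss,
        aicc=_aicc(rss, n, k=3),
        n=n,
        converged=True,
    )


def _gaussian(t, r_opt, t_opt, width):
    return r_opt * np.exp(-((t - t_opt) ** 2) / (2.0 * width**2))


def fit_unimodal(exp: TemperatureExperiment) -> FitResult:
    """Gaussian-in-temperature fit by bounded nonlinear least squares.

    Initialized at the argmax temperature with half the temperature range as
    width; T_opt is constrained to [min T - 5, max T + 5] so monotone data
    pin the optimum at a boundary (flagged) instead of diverging.
    Non-convergence is flagged on the result, never raised.
    """
    if exp.n_distinct_temperatures() < 4:
        raise ValueError("need >= 4 distinct temperatures for a 3-parameter fit")
    t, r = exp.temperatures, exp.rates
    t_lo, t_hi = float(t.min()) - 5.0, float(t.max()) + 5.0
    p0 = [max(float(r.max()), 1e-12), float(t[np.argmax(r)]), max(np.ptp(t) / 2.0, 1.0)]
    n = r.size
    try:
        popt, _ = curve_fit(
            _gaussian,
            t,
            r,
            p0=p0,
            bounds=([0.0, t_lo, 1e-6], [np.inf, t_hi, np.inf]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    r_opt, t_opt, width = (float(v) for v in popt)
    fitted = _gaussian(t, r_opt, t_opt, width)
    rss = float(np.sum((r - fitted) ** 2))
    boundary = converged and (abs(t_opt - t_lo) < 1e-6 or abs(t_opt - t_hi) < 1e-6)
    return FitResult(
        model="unimodal",
        parameters={"r_opt": r_opt, "t_opt": t_opt, "width": width},
        rss=rss,
        aicc=_aicc(rss, n, k=4) if converged else math.inf,
        n=n,
        converged=converged,
        boundary=boundary,
    )


@dataclass
class ModelSelection:
    """AICc comparison between an exponential and a unimodal fit."""

    preferred: str
    delta_aicc: float  # AICc(other) - AICc(preferred), >= 0
    indistinguishable: bool


def select_model(fit_a: FitResult, fit_b: FitResult) -> ModelSelection:
    """Pick the smaller-AICc model; |dAICc| < 2 is flagged indistinguishable."""
    if fit_a.n != fit_b.n:
        raise ValueError("fits must be on identical data")
    if math.isnan(fit_a.aicc) or math.isnan(fit_b.aicc):
        raise ValueError("AICc undefined: too few observations for the parameter count")
    best, other = (fit_a, fit_b) if fit_a.aicc <= fit_b.aicc else (fit_b, fit_a)
    delta = other.aicc - best.aicc
    return ModelSelection(
        preferred=best.model, delta_aicc=delta, indistinguishable=bool(delta < 2.0)
    )


def ratio_profile(
    assim: TemperatureExperiment, fix: TemperatureExperiment
) -> pd.DataFrame:
    """Assimilation:fixation ratio per temperature, mean +/- SD over replicates.

    Ratios are formed per (temperature, replicate) pair before averaging;
    pairs with zero fixation are dropped (reducing n at that temperature)
    rather than propagating an infinity.
    """
    a = pd.DataFrame(
        {"temperature_c": assim.temperatures, "replicate": assim.replicates, "assim": assim.rates}
    )
    f = pd.DataFrame(
        {"temperature_c": fix.temperatures, "replicate": fix.replicates, "fix": fix.rates}
    )
    merged = a.merge(f, on=["temperature_c", "replicate"], how="inner")
    if merged.empty:
        raise ValueError("no matching (temperature, replicate) pairs")
    merged = merged[merged["fix"] > 0].copy()
    merged["ratio"] = merged["assim"] / merged["fix"]
    out = (
        merged.groupby("temperature_c", sort=True)["ratio"]
        .agg(mean_ratio="mean", sd_ratio=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return out
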