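"""Synthetic incubation data with the statistical structure the estimators assume.

Every pipeline input can be generated here from explicit ground truth and a
seed: 15N-nitrite accumulation series, endpoint biomass enrichment, per-cell
ion counts with Poisson noise, and temperature-gradient rate tables. The
defaults are calibrated to the measured study conditions of a deep
oligotrophic lake hypolimnion (85 m, ~5 degC): volumetric rates of
7.5 nmol N l-1 d-1 oxidized, 1.3 nmol C l-1 d-1 fixed and 5.5 nmol N l-1 d-1
assimilated; single-cell rate distributions parameterized by the printed
medians/IQRs of ammonia-oxidizing archaea (AOA) and the remaining
picoplankton; a unimodal temperature response for ammonia oxidation
(optimum 10 degC, rates doubling from 5 to 10 degC) versus exponential (Q10)
responses for fixation and assimilation whose ratio runs from 2.9 at 5 degC
to 6.5 at 20 degC.

Noise is multiplicative Gaussian (CV-parameterized) on concentrations and
atom fractions — instrument error scales with signal — and Poisson on ion
counts. Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import X_NAT_C, X_NAT_N
from .bulk import EndpointPair, IncubationSeries

#: z-score of the 75th percentile; the IQR of a lognormal(mu, sigma) is
#: median * (exp(z*sigma) - exp(-z*sigma)).
_Z75 = 0.6744897501960817


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Lognormal (location, scale) matching a given median and IQR.

    Solves iqr = median * (exp(z*sigma) - exp(-z*sigma)) = 2*median*sinh(z*sigma)
    with z the 75th-percentile normal score; the solution is
    sigma = asinh(iqr / (2*median)) / z, exact for any iqr >= 0.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if iqr < 0:
        raise ValueError("iqr must be non-negative")
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75
    return math.log(median), sigma


@dataclass
class TruthConfig:
    """Ground truth for one bulk incubation condition.

    Rates are in nmol (N or C) l^-1 d^-1; pools in nmol l^-1 (ammonium) or
    umol l^-1 (DIC, POC, PON); times in days. Defaults are the hypolimnion
    (85 m) condition: 5 uM 15NH4Cl amendment on ~0.32 uM ambient ammonium
    (F ~ 0.93) and 1.3 mM NaH13CO3 on 1.6 mM ambient DIC (F ~ 0.43), 48 h.
    """

    true_ox_rate: float = 7.5
    true_dic_rate: float = 1.3
    true_n_assim_rate: float = 5.5
    f15n: float = 0.93
    f13c: float = 0.43
    nh4_pool: float = 5324.0  # nmol l^-1, amendment + ambient
    dic_pool: float = 1600.0  # umol l^-1
    poc: float = 10.0  # umol C l^-1
    pon: float = 1.5  # umol N l^-1
    duration: float = 2.0  # days
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    noise_cv: float = 0.05
    depletion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.true_ox_rate, self.true_dic_rate, self.true_n_assim_rate) < 0:
            raise ValueError("true rates must be non-negative")
        if not X_NAT_N < self.f15n <= 1.0:
            raise ValueError("f15n must exceed natural abundance and be <= 1")
        if not X_NAT_C < self.f13c <= 1.0:
            raise ValueError("f13c must exceed natural abundance and be <= 1")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must start at 0 and increase strictly")
        if tp[-1] != self.duration:
            raise ValueError("duration must equal the last timepoint")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if min(self.nh4_pool, self.dic_pool, self.poc, self.pon) <= 0:
            raise ValueError("pools must be positive")


def simulate_oxidation_series(
    truth: TruthConfig,
    replicates: int = 3,
    *,
    sample_id: str = "sim",
    depth: float = 85.0,
    temperature: float = 5.0,
    rng: np.random.Generator | None = None,
) -> list[IncubationSeries]:
    """15N-nitrite accumulation series for ``replicates`` bottles.

    Mean accumulation is true_ox_rate * f15n * t (conservative product pool);
    multiplicative Gaussian noise of CV ``noise_cv`` is applied per
    measurement and negative draws are clipped to zero. In depletion mode the
    ammonium pool is finite: oxidation removing 15N and 14N in proportion to
    the current labeling fraction leaves that fraction unchanged, so the
    accumulation stays linear, but a truth whose consumption would exhaust
    the pool within the incubation is rejected and cumulative labeled nitrite
    can never exceed the initial labeled ammonium.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if truth.depletion and truth.true_ox_rate * truth.duration > truth.nh4_pool:
        raise ValueError(
            "oxidation would exhaust the ammonium pool within the incubation"
        )
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    t = np.asarray(truth.timepoints, dtype=float)
    mean = truth.true_ox_rate * truth.f15n * t
    if truth.depletion:
        mean = np.minimum(mean, truth.f15n * truth.nh4_pool)
    out = []
    for r in range(replicates):
        noise = 1.0 + truth.noise_cv * rng.standard_normal(t.size)
        conc = np.clip(mean * noise, 0.0, None)
        out.append(
            IncubationSeries(
                sample_id=sample_id,
                depth=depth,
                temperature=temperature,
                replicate=f"r{r + 1}",
                times=t,
                n15_nitrite=conc,
                f15n=truth.f15n,
            )
        )
    return out


def simulate_endpoint(
    truth: TruthConfig,
    element: str,
    *,
    sample_id: str = "sim",
    replicate: str = "r1",
    rng: np.random.Generator | None = None,
) -> EndpointPair:
    """Endpoint biomass enrichment implied by the true volumetric rate.

    T0 atom fraction is natural abundance; the endpoint fraction is
    x_nat + (rate * duration / pool) * (F - x_nat) with the rate in
    nmol l^-1 d^-1 and the particulate pool in umol l^-1 (hence the implicit
    factor 1000). Multiplicative noise (CV ``noise_cv``) acts on the excess.
    """
    if element == "C":
        rate, pool, f_label, x_nat = truth.true_dic_rate, truth.poc, truth.f13c, X_NAT_C
    elif element == "N":
        rate, pool, f_label, x_nat = truth.true_n_assim_rate, truth.pon, truth.f15n, X_NAT_N
    else:
        raise ValueError("element must be 'C' or 'N'")
    new_frac = rate * truth.duration / (pool * 1000.0)
    if new_frac > 1.0:
        raise ValueError("implied newly fixed fraction exceeds 1 (unphysical truth)")
    excess = new_frac * (f_label - x_nat)
    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed) if rng is None else rng
        excess = max(excess * (1.0 + truth.noise_cv * rng.standard_normal()), 0.0)
    return EndpointPair(
        sample_id=sample_id,
        element=element,
        replicate=replicate,
        pool=pool,
        x0=x_nat,
        x_end=x_nat + excess,
        f_label=f_label,
        duration=truth.duration,
    )


@dataclass
class CellGroupTruth:
    """Lognormal per-cell rate truth for one taxon group."""

    n_cells: int
    median_c: float  # mol C cell^-1 d^-1
    iqr_c: float
    median_n: float  # mol N cell^-1 d^-1
    iqr_n: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.median_c, self.median_n) <= 0 or min(self.iqr_c, self.iqr_n) < 0:
            raise ValueError("medians must be positive and IQRs non-negative")


def default_cell_groups() -> dict[str, CellGroupTruth]:
    """Study-condition cell truths: AOA versus remaining picoplankton."""
    return {
        "AOA": CellGroupTruth(25, 2.17e-18, 3.8e-18, 8.14e-18, 23.4e-18),
        "other": CellGroupTruth(427, 0.36e-18, 1.51e-18, 1.67e-18, 7.19e-18),
    }


@dataclass
class CellTruth:
    """Ground truth for a single-cell nanoSIMS dataset."""

    groups: Mapping[str, CellGroupTruth] = field(default_factory=default_cell_groups)
    cell_c_content: float = 1.75e-15  # mol C cell^-1
    cell_n_content: float = 3.1e-16  # mol N cell^-1
    total_ion_counts: float = 1e5  # expected major-isotope counts per cell
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cell_c_content, self.cell_n_content) <= 0:
            raise ValueError("cell contents must be positive")
        if self.total_ion_counts <= 0:
            raise ValueError("total_ion_counts must be positive")


def simulate_cells(
    cells: CellTruth,
    f13c: float = 0.43,
    f15n: float = 0.93,
    x_nat_c: float = X_NAT_C,
    x_nat_n: float = X_NAT_N,
    duration: float = 2.0,
    *,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell ion-count table with lognormal rate truth and Poisson noise.

    For each cell a true rate is drawn from the lognormal defined by the
    group's (median, IQR); the implied true atom fraction is
    x = x_nat + (rate * duration / content) * (F - x_nat), with the newly
    synthesized fraction saturating at 1 (a cell cannot exceed the labeling
    of its substrate pool); major counts are Poisson(total_ion_counts) and
    minor counts Poisson(major_expectation * x / (1 - x)). Columns
    ``true_rate_c``/``true_rate_n`` carry the drawn truths for round-trip
    checks.
    """
    rng = np.random.default_rng(cells.seed) if rng is None else rng
    frames = []
    for group, gt in sorted(cells.groups.items()):
        n = gt.n_cells
        mu_c, sig_c = lognormal_from_median_iqr(gt.median_c, gt.iqr_c)
        mu_n, sig_n = lognormal_from_median_iqr(gt.median_n, gt.iqr_n)
        rate_c = np.exp(mu_c + sig_c * rng.standard_normal(n))
        rate_n = np.exp(mu_n + sig_n * rng.standard_normal(n))
        # newly synthesized fraction saturates at 1: a cell cannot become
        # more enriched than the labeled substrate pool itself
        new_c = np.minimum(rate_c * duration / cells.cell_c_content, 1.0)
        new_n = np.minimum(rate_n * duration / cells.cell_n_content, 1.0)
        x_c = x_nat_c + new_c * (f13c - x_nat_c)
        x_n = x_nat_n + new_n * (f15n - x_nat_n)
        major_c = rng.poisson(cells.total_ion_counts, n)
        minor_c = rng.poisson(cells.total_ion_counts * x_c / (1.0 - x_c))
        major_n = rng.poisson(cells.total_ion_counts, n)
        minor_n = rng.poisson(cells.total_ion_counts * x_n / (1.0 - x_n))
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{group}_{i + 1:04d}" for i in range(n)],
                    "sample_id": sample_id,
                    "group": group,
                    "counts_major_c": major_c,
                    "counts_minor_c": minor_c,
                    "counts_major_n": major_n,
                    "counts_minor_n": minor_n,
                    "true_rate_c": rate_c,
                    "true_rate_n": rate_n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class UnimodalModel:
    """Gaussian-in-temperature response: r(T) = r_opt * exp(-(T-T_opt)^2 / (2 w^2))."""

    t_opt: float  # degC
    r_opt: float  # nmol l^-1 d^-1
    width: float  # degC

    def __post_init__(self) -> None:
        if self.width <= 0 or self.r_opt < 0:
            raise ValueError("width must be positive and r_opt non-negative")

    def rate(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return self.r_opt * np.exp(-((t - self.t_opt) ** 2) / (2.0 * self.width**2))


@dataclass
class ExponentialModel:
    """Q10 response: r(T) = r_ref * Q10 ** ((T - t_ref) / 10)."""

    r_ref: float
    q10: float
    t_ref: float = 5.0

    def __post_init__(self) -> None:
        if self.q10 <= 0 or self.r_ref < 0:
            raise ValueError("Q10 must be positive and r_ref non-negative")

    def rate(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return self.r_ref * self.q10 ** ((t - self.t_ref) / 10.0)


# Ratio-profile calibration: assimilation:fixation of 2.9 at 5 degC rising to
# 6.5 at 20 degC fixes Q10_assim / Q10_fix = (6.5/2.9)**(2/3) and the
# reference-rate ratio at 2.9.
_RATIO_5C = 2.9
_RATIO_20C = 6.5
_Q10_FIX = 2.0
_Q10_ASSIM = _Q10_FIX * (_RATIO_20C / _RATIO_5C) ** (2.0 / 3.0)


@dataclass
class TemperatureTruth:
    """Ground truth for a temperature-gradient experiment.

    Oxidation is unimodal with its optimum at 10 degC and a width chosen so
    rates double from 5 to 10 degC; fixation and assimilation are exponential
    with the assimilation:fixation ratio running from 2.9 (5 degC) to 6.5
    (20 degC).
    """

    model_ox: UnimodalModel = field(
        default_factory=lambda: UnimodalModel(
            t_opt=10.0, r_opt=15.0, width=math.sqrt(25.0 / (2.0 * math.log(2.0)))
        )
    )
    model_fix: ExponentialModel = field(
        default_factory=lambda: ExponentialModel(r_ref=1.3, q10=_Q10_FIX, t_ref=5.0)
    )
    model_assim: ExponentialModel = field(
        default_factory=lambda: ExponentialModel(
            r_ref=_RATIO_5C * 1.3, q10=_Q10_ASSIM, t_ref=5.0
        )
    )
    temperatures: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    oxidation_temperatures: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 28.0)
    replicates: int = 3
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (*self.temperatures, *self.oxidation_temperatures):
            if not 0.0 <= t <= 40.0:
                raise ValueError("temperatures must lie within [0, 40] degC")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def simulate_temperature(
    truth: TemperatureTruth, *, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Replicated rate table across the temperature gradient.

    Returns a tidy frame (process, temperature_c, replicate, rate) with
    multiplicative Gaussian replicate noise; the oxidation process may use a
    wider temperature grid than fixation/assimilation.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    rows = []
    grids = {
        "oxidation": (truth.oxidation_temperatures, truth.model_ox),
        "dic_fixation": (truth.temperatures, truth.model_fix),
        "n_assimilation": (truth.temperatures, truth.model_assim),
    }
    for process, (temps, model) in grids.items():
        for t in temps:
            mean = float(model.rate(t))
            for r in range(truth.replicates):
                noise = 1.0 + truth.noise_cv * rng.standard_normal()
                rows.append(
                    {
                        "process": process,
                        "temperature_c": t,
                        "replicate": f"r{r + 1}",
                        "rate": max(mean * noise, 0.0),
                    }
                )
    return pd.DataFrame(rows)
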