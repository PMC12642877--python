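"""Stoichiometric partitioning of dark DIC fixation among nitrifier guilds.

Chemolithoautotrophic nitrifiers fix a predictable amount of carbon per mole
of nitrogen oxidized: cultured ammonia-oxidizing archaea oxidize roughly
10-11 mol N per mol C fixed, nitrite oxidizers about 28 mol N per mol C.
Dividing a measured oxidation rate by this yield gives the guild's expected
DIC fixation, and its ratio to total measured dark fixation is the expected
guild share. Measured single-cell shares are conservative because the
CARD-FISH staining that precedes nanoSIMS dilutes isotopic signals (reported
range 16%-77%); an upper bound corrects the measured share for the largest
reported dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class YieldModel:
    """mol N oxidized per mol C fixed, as a [low, high] interval per guild."""

    guild: str  # "AOA" or "NOB"
    n_per_c_low: float
    n_per_c_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.n_per_c_low <= self.n_per_c_high:
            raise ValueError("need 0 < low <= high yield")


#: Culture-derived yields: AOA ~10-11 N per C, NOB ~28 N per C.
AOA_YIELD = YieldModel("AOA", 10.0, 11.0)
NOB_YIELD = YieldModel("NOB", 28.0, 28.0)


@dataclass
class ShareInterval:
    """Expected guild share of total dark DIC fixation, as an interval."""

    low: float
    high: float
    flag: str | None = None

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


def expected_share(
    oxidation_rate: float, yield_model: YieldModel, total_fixation: float
) -> ShareInterval:
    """Expected share of total DIC fixation implied by an oxidation rate.

    Guild fixation = oxidation_rate / yield (high yield -> low fixation), so
    the share interval is [ox / (yield_high * total), ox / (yield_low * total)].
    A share above 1 is flagged, not raised: it signals mutually inconsistent
    rate inputs.
    """
    if total_fixation <= 0:
        raise ValueError("total fixation must be positive")
    if oxidation_rate < 0:
        raise ValueError("oxidation rate must be non-negative")
    low = oxidation_rate / yield_model.n_per_c_high / total_fixation
    high = oxidation_rate / yield_model.n_per_c_low / total_fixation
    flag = "share_exceeds_1" if high > 1.0 else None
    return ShareInterval(low=low, high=high, flag=flag)


@dataclass
class DilutionBound:
    """Fractional isotope-signal dilution caused by staining, as a range."""

    d_low: float = 0.16
    d_high: float = 0.77

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_low <= self.d_high < 1.0:
            raise ValueError("need 0 <= d_low <= d_high < 1")


def dilution_corrected_share(
    measured_share: float, d: float, convention: str = "multiplicative"
) -> float:
    """Upper-bound a measured share given a fractional isotope dilution d.

    The default ``multiplicative`` convention scales the measured share by
    (1 + d), reading "diluted by d" as a fractional signal loss of size d
    relative to the measured value. The alternative ``rescale`` convention
    divides by (1 - d), reading d as the lost fraction of the true signal;
    it is stricter and available behind the flag. Results above 1 are
    clipped.
    """
    if not 0.0 <= measured_share <= 1.0:
        raise ValueError("measured share must lie in [0, 1]")
    if not 0.0 <= d < 1.0:
        raise ValueError("dilution must lie in [0, 1)")
    if convention == "multiplicative":
        corrected = measured_share * (1.0 + d)
    elif convention == "rescale":
        corrected = measured_share / (1.0 - d)
    else:
        raise ValueError(f"unknown dilution convention {convention!r}")
    return min(corrected, 1.0)


@dataclass
class ObservedVsExpected:
    """Comparison of a measured share against its stoichiometric expectation."""

    expected: ShareInterval
    observed: float
    ratio: float  # observed / expected midpoint
    verdict: str  # "consistent", "lower" or "higher"


def observed_vs_expected(expected: ShareInterval, observed: float) -> ObservedVsExpected:
    """Classify an observed share against the expected interval."""
    if observed < 0:
        raise ValueError("observed share must be non-negative")
    if expected.low <= observed <= expected.high:
        verdict = "consistent"
    elif observed < expected.low:
        verdict = "lower"
    else:
        verdict = "higher"
    mid = expected.midpoint
    ratio = observed / mid if mid > 0 else math.inf if observed > 0 else 0.0
    return ObservedVsExpected(expected=expected, observed=observed, ratio=ratio, verdict=verdict)
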