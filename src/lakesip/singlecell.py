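"""Single-cell rate inference from nanoSIMS ion counts.

Each cell contributes independent Poisson-distributed major- and
minor-isotope ion counts per element; the measured atom fraction is
minor / (minor + major) and its relative standard error under independent
Poisson counting is sqrt(1/minor + 1/major). Measurements above the counting
error threshold (default 5%) are excluded. Decoded excess enrichment is
converted to a per-cell element-fixation rate through the cell's element
content, distributions are summarized with median/IQR/skewness (right-skewed
in these data), groups are compared with a two-sided Mann-Whitney U test
(Benjamini-Hochberg corrected), and group means are extrapolated to
volumetric population rates via the cell census.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Config


def poisson_relative_error(minor, major):
    """Relative standard error of an isotope ratio from Poisson counts.

    sqrt(1/minor + 1/major); infinite when the minor count is zero (the
    measurement is then filtered, not rejected with an exception). Accepts
    scalars or arrays.
    """
    minor = np.asarray(minor, dtype=float)
    major = np.asarray(major, dtype=float)
    if np.any(major <= 0):
        raise ValueError("major counts must be positive")
    if np.any(minor < 0):
        raise ValueError("minor counts must be non-negative")
    with np.errstate(divide="ignore"):
        err = np.sqrt(1.0 / minor + 1.0 / major)
    return float(err) if err.ndim == 0 else err


def cell_rate(
    x_measured,
    x_nat: float,
    f_label: float,
    cell_content: float,
    duration: float,
    *,
    clip: bool = True,
):
    """Per-cell element fixation rate (mol cell^-1 d^-1) from enrichment.

    The newly synthesized biomass fraction is
    f_new = (x_measured - x_nat) / (f_label - x_nat); the rate is
    f_new * cell_content / duration. Negative excess is clipped to zero by
    default (pass ``clip=False`` for the raw diagnostic value).
    """
    if f_label <= x_nat:
        raise ValueError("labeling fraction must exceed natural abundance")
    if cell_content <= 0 or duration <= 0:
        raise ValueError("cell_content and duration must be positive")
    x = np.asarray(x_measured, dtype=float)
    rate = (x - x_nat) / (f_label - x_nat) * cell_content / duration
    if clip:
        rate = np.maximum(rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def decode_cells(
    cells: pd.DataFrame,
    config: Config,
    f13c: float,
    f15n: float,
    duration: float,
) -> pd.DataFrame:
    """Derive atom fractions, counting errors, filters and rates per cell.

    Expects the cells table schema (counts_major_c, counts_minor_c,
    counts_major_n, counts_minor_n, group, ...). Adds, per element: the atom
    fraction ``x``, the Poisson relative error ``rel_err``, the filter flag
    ``passed_filter`` (rel_err < config.poisson_threshold) and the clipped
    rate ``rate`` plus the unclipped ``rate_raw`` diagnostic.
    """
    out = cells.copy()
    channels = {
        "c": (f13c, config.x_nat_c, config.cell_c_content),
        "n": (f15n, config.x_nat_n, config.cell_n_content),
    }
    for el, (f_label, x_nat, content) in channels.items():
        minor = out[f"counts_minor_{el}"].to_numpy(dtype=float)
        major = out[f"counts_major_{el}"].to_numpy(dtype=float)
        out[f"x_{el}"] = minor / (minor + major)
        out[f"rel_err_{el}"] = poisson_relative_error(minor, major)
        out[f"passed_filter_{el}"] = out[f"rel_err_{el}"] < config.poisson_threshold
        out[f"rate_{el}_raw"] = cell_rate(
            out[f"x_{el}"], x_nat, f_label, content, duration, clip=False
        )
        out[f"rate_{el}"] = np.maximum(out[f"rate_{el}_raw"], 0.0)
    return out


@dataclass
class DistributionSummary:
    """Five-number-style summary of a (typically right-skewed) rate sample."""

    n: int
    median: float
    iqr: float
    mean: float
    skewness: float | None
    zero_variance: bool = False


def summarize_distribution(rates: Sequence[float] | np.ndarray) -> DistributionSummary:
    """Median, IQR (type-7 quartiles), mean and adjusted skewness.

    Skewness is the adjusted Fisher-Pearson coefficient
    g1 * sqrt(n (n-1)) / (n - 2); it needs n >= 3 and is reported as 0 with a
    flag for zero-variance samples.
    """
    x = np.asarray(rates, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one rate")
    q25, q75 = np.percentile(x, [25, 75], method="linear")
    zero_var = bool(np.all(x == x[0]))
    if x.size < 3:
        skew = None
    elif zero_var:
        skew = 0.0
    else:
        skew = float(stats.skew(x, bias=False))
    return DistributionSummary(
        n=int(x.size),
        median=float(np.median(x)),
        iqr=float(q75 - q25),
        mean=float(np.mean(x)),
        skewness=skew,
        zero_variance=zero_var,
    )


@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney U comparison between two groups."""

    groups: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    method: str = "exact"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a, computed from midranks (handles ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_permutation_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating every group assignment.

    The permutation distribution of U is symmetric about n_a*n_b/2, so the
    two-sided p is P(U <= u_min) + P(U >= n_a*n_b - u_min), capped at 1.
    Feasible for small groups only (C(n_a+n_b, n_a) assignments).
    """
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum() - offset)
    total = n_a * n_b
    u_min = min(u_obs, total - u_obs)
    us = np.array(
        [sum(c) - offset for c in itertools.combinations(ranks, n_a)]
    )
    eps = 1e-9
    p = (np.sum(us <= u_min + eps) + np.sum(us >= total - u_min - eps)) / us.size
    return float(min(p, 1.0))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two rate samples.

    The U statistic always uses midranks. The p-value is exact by full
    enumeration for small groups (both n <= 8, valid with ties), exact via
    the tie-free null distribution for moderate tie-free samples (n <= 20),
    and a tie-corrected normal approximation otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    u = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= 8 and y.size <= 8:
        p = _exact_permutation_p(x, y)
        method = "exact-enumeration"
    elif not has_ties and max(x.size, y.size) <= 20:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "asymptotic"
    return GroupComparison(groups=labels, statistic=u, p_raw=p, method=method)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_comparisons(comparisons: Sequence[GroupComparison]) -> list[GroupComparison]:
    """Attach BH-adjusted p-values across a family of group comparisons."""
    adj = bh_adjust([c.p_raw for c in comparisons])
    for c, pa in zip(comparisons, adj):
        c.p_adjusted = float(pa)
    return list(comparisons)


@dataclass
class CellCensus:
    """Cell densities from microscopy counts (cells per ml)."""

    sample_id: str
    dapi_density: float  # total picoplankton, cells ml^-1
    aoa_density: float  # AOA subset, cells ml^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.aoa_density <= self.dapi_density:
            raise ValueError("need 0 <= AOA density <= DAPI density")

    def group_densities_per_liter(self) -> dict[str, float]:
        return {
            "AOA": self.aoa_density * 1000.0,
            "other": (self.dapi_density - self.aoa_density) * 1000.0,
        }


def extrapolate_population(
    group_means: Mapping[str, float], census: CellCensus
) -> dict:
    """Volumetric population rates from mean single-cell rates and densities.

    Per group: mean rate (mol cell^-1 d^-1, from filter-passing cells) times
    density (cells l^-1), reported in nmol l^-1 d^-1; the combined rate is
    the sum over groups and shares are group/combined. Means (not medians)
    are used because mean x density is the only statistic that conserves
    mass under aggregation.
    """
    densities = census.group_densities_per_liter()
    unknown = set(group_means) - set(densities)
    if unknown:
        raise ValueError(f"no census density for groups: {sorted(unknown)}")
    volumetric = {
        g: group_means[g] * densities[g] * 1e9 for g in group_means  # mol -> nmol
    }
    combined = sum(volumetric.values())
    if combined > 0:
        shares = {g: v / combined for g, v in volumetric.items()}
        flag = None
    else:
        shares = {g: math.nan for g in volumetric}
        flag = "zero_combined_rate"
    return {
        "volumetric_nmol_l_d": volumetric,
        "combined_nmol_l_d": combined,
        "shares": shares,
        "flag": flag,
    }
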