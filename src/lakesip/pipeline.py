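"""Stage orchestration: simulate -> bulk rates -> single cell -> partition -> temperature.

Each stage is a plain function reading/writing CSV or JSON under an output
directory, so the numbered analysis drivers, the CLI subcommands and the
tests all share one code path. Per-stage random streams are spawned from the
master seed, so one seed fixes the whole bundle bit-for-bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .bulk import endpoint_rate, fit_oxidation_rate, summarize_rates
from .config import Config
from .partition import (
    AOA_YIELD,
    NOB_YIELD,
    DilutionBound,
    dilution_corrected_share,
    expected_share,
    observed_vs_expected,
)
from .singlecell import (
    adjust_comparisons,
    compare_groups,
    decode_cells,
    extrapolate_population,
    summarize_distribution,
)
from .synthetic import (
    CellTruth,
    TemperatureTruth,
    TruthConfig,
    simulate_cells,
    simulate_endpoint,
    simulate_oxidation_series,
    simulate_temperature,
)
from .temperature import (
    TemperatureExperiment,
    fit_exponential,
    fit_unimodal,
    ratio_profile,
    select_model,
)

log = logging.getLogger("lakesip")

STAGES = ("simulate", "oxidation", "assimilation", "singlecell", "partition", "temperature")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """One independent 31-bit stream seed per stage, spawned from the master."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def run_simulate(config: Config, out_dir: Path, seed: int) -> dict:
    """Generate every pipeline input table from the study-condition truth."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    truth = TruthConfig(seed=seed)
    cell_truth = CellTruth(
        cell_c_content=config.cell_c_content,
        cell_n_content=config.cell_n_content,
        seed=seed,
    )
    temp_truth = TemperatureTruth(seed=seed)

    series = simulate_oxidation_series(truth, replicates=3, rng=rng)
    rows = []
    for s in series:
        for t, c in zip(s.times, s.n15_nitrite):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "depth_m": s.depth,
                    "temperature_c": s.temperature,
                    "replicate": s.replicate,
                    "time": t,
                    "time_unit": "d",
                    "n15_no2": c,
                    "conc_unit": "nmol/l",
                    "f15n": s.f15n,
                }
            )
    io.write_table(pd.DataFrame(rows), out_dir / "incubation_series.csv")

    ep_rows = []
    for element in ("C", "N"):
        for r in range(3):
            pair = simulate_endpoint(truth, element, replicate=f"r{r + 1}", rng=rng)
            ep_rows.append(
                {
                    "sample_id": pair.sample_id,
                    "element": pair.element,
                    "replicate": pair.replicate,
                    "pool_umol_l": pair.pool,
                    "x0": pair.x0,
                    "x_end": pair.x_end,
                    "f_label": pair.f_label,
                    "duration_d": pair.duration,
                }
            )
    io.write_table(pd.DataFrame(ep_rows), out_dir / "endpoint.csv")

    cells = simulate_cells(
        cell_truth,
        f13c=truth.f13c,
        f15n=truth.f15n,
        x_nat_c=config.x_nat_c,
        x_nat_n=config.x_nat_n,
        duration=truth.duration,
        rng=rng,
    )
    io.write_table(cells, out_dir / "cells.csv")

    census = pd.DataFrame(
        {
            "sample_id": ["sim", "sim"],
            "group": ["dapi", "aoa"],
            "cells_per_ml": [2.96e5, 0.24e5],
        }
    )
    io.write_table(census, out_dir / "census.csv")

    io.write_table(simulate_temperature(temp_truth, rng=rng), out_dir / "temperature.csv")

    truth_record = {
        "bulk": {
            "true_ox_rate": truth.true_ox_rate,
            "true_dic_rate": truth.true_dic_rate,
            "true_n_assim_rate": truth.true_n_assim_rate,
            "f15n": truth.f15n,
            "f13c": truth.f13c,
            "nh4_pool": truth.nh4_pool,
            "dic_pool": truth.dic_pool,
            "poc": truth.poc,
            "pon": truth.pon,
            "duration": truth.duration,
            "timepoints": list(truth.timepoints),
            "noise_cv": truth.noise_cv,
        },
        "cells": {
            g: {
                "n_cells": gt.n_cells,
                "median_c": gt.median_c,
                "iqr_c": gt.iqr_c,
                "median_n": gt.median_n,
                "iqr_n": gt.iqr_n,
            }
            for g, gt in cell_truth.groups.items()
        },
        "cell_constants": {
            "cell_c_content": cell_truth.cell_c_content,
            "cell_n_content": cell_truth.cell_n_content,
            "total_ion_counts": cell_truth.total_ion_counts,
        },
        "temperature": {
            "model_ox": vars(temp_truth.model_ox),
            "model_fix": vars(temp_truth.model_fix),
            "model_assim": vars(temp_truth.model_assim),
            "temperatures": list(temp_truth.temperatures),
            "oxidation_temperatures": list(temp_truth.oxidation_temperatures),
            "replicates": temp_truth.replicates,
            "noise_cv": temp_truth.noise_cv,
        },
        "seed": seed,
    }
    io.write_json(truth_record, out_dir / "truth.json")
    log.info("simulate: wrote 5 input tables + truth.json to %s", out_dir)
    return truth_record


def run_oxidation(config: Config, out_dir: Path) -> pd.DataFrame:
    """Fit per-bottle oxidation rates and summarize significant ones."""
    out_dir = Path(out_dir)
    table = io.read_table(out_dir / "incubation_series.csv", "incubation_series")
    rows = []
    for s in io.series_from_table(table):
        est = fit_oxidation_rate(s, alpha=config.alpha)
        rows.append(
            {
                "sample_id": s.sample_id,
                "replicate": s.replicate,
                "process": "oxidation",
                "rate": est.rate,
                "std_error": est.std_error,
                "p_value": est.p_value,
                "n": est.n,
                "significant": est.significant,
                "method": est.method,
            }
        )
    rates = pd.DataFrame(rows)
    io.write_table(rates, out_dir / "rates_oxidation.csv")
    summary = summarize_rates(rates, ["sample_id", "process"])
    io.write_table(summary, out_dir / "rates_oxidation_summary.csv")
    log.info("oxidation: %d bottles, %d significant", len(rates), int(rates["significant"].sum()))
    return rates


def run_assimilation(config: Config, out_dir: Path) -> pd.DataFrame:
    """Endpoint DIC-fixation (C) and ammonia-assimilation (N) rates."""
    out_dir = Path(out_dir)
    table = io.read_table(out_dir / "endpoint.csv", "endpoint")
    rows = []
    for pair in io.endpoints_from_table(table):
        est = endpoint_rate(pair)
        rows.append(
            {
                "sample_id": pair.sample_id,
                "replicate": pair.replicate,
                "process": "dic_fixation" if pair.element == "C" else "n_assimilation",
                "rate": est.rate,
                "std_error": est.std_error,
                "p_value": est.p_value,
                "n": est.n,
                "significant": est.significant,
                "method": est.method,
                "flag": est.flag or "",
            }
        )
    rates = pd.DataFrame(rows)
    io.write_table(rates, out_dir / "rates_endpoint.csv")
    summary = summarize_rates(rates, ["sample_id", "process"])
    io.write_table(summary, out_dir / "rates_endpoint_summary.csv")
    log.info("assimilation: %d endpoint rates", len(rates))
    return rates


def run_singlecell(config: Config, out_dir: Path) -> dict:
    """Decode, filter, summarize, compare and extrapolate single-cell rates."""
    import json

    out_dir = Path(out_dir)
    cells = io.read_table(out_dir / "cells.csv", "cells")
    census = io.census_from_table(io.read_table(out_dir / "census.csv", "census"))
    f13c, f15n, duration = 0.43, 0.93, 2.0
    truth_path = out_dir / "truth.json"
    if truth_path.exists():
        bulk_truth = json.loads(truth_path.read_text())["bulk"]
        f13c, f15n, duration = bulk_truth["f13c"], bulk_truth["f15n"], bulk_truth["duration"]
    decoded = decode_cells(cells, config, f13c=f13c, f15n=f15n, duration=duration)
    io.write_table(decoded, out_dir / "cell_rates.csv")

    summaries, comparisons, group_means = [], [], {"c": {}, "n": {}}
    for el in ("c", "n"):
        kept = decoded[decoded[f"passed_filter_{el}"]]
        by_group: dict[str, pd.DataFrame] = {}
        for group, sub in kept.groupby("group"):
            s = summarize_distribution(sub[f"rate_{el}"].to_numpy())
            by_group[str(group)] = sub
            group_means[el][group] = s.mean
            summaries.append(
                {
                    "element": el.upper(),
                    "group": group,
                    "n": s.n,
                    "median": s.median,
                    "iqr": s.iqr,
                    "mean": s.mean,
                    "skewness": s.skewness,
                }
            )
        if {"AOA", "other"} <= set(by_group):
            # BH family: C and N x (rate, enrichment) within one sample
            for quantity, column in (("rate", f"rate_{el}"), ("enrichment", f"x_{el}")):
                comp = compare_groups(
                    by_group["AOA"][column].to_numpy(),
                    by_group["other"][column].to_numpy(),
                    ("AOA", "other"),
                )
                comparisons.append((f"{el.upper()}_{quantity}", comp))
    adjusted = adjust_comparisons([c for _, c in comparisons])
    comp_rows = [
        {
            "comparison": name,
            "groups": "AOA_vs_other",
            "u_statistic": c.statistic,
            "p_raw": c.p_raw,
            "p_adjusted": c.p_adjusted,
            "method": c.method,
        }
        for (name, _), c in zip(comparisons, adjusted)
    ]
    io.write_table(pd.DataFrame(summaries), out_dir / "cell_distributions.csv")
    io.write_table(pd.DataFrame(comp_rows), out_dir / "cell_comparisons.csv")

    extrapolation = {
        el.upper(): extrapolate_population(group_means[el], census) for el in ("c", "n")
    }
    io.write_json(extrapolation, out_dir / "extrapolation.json")
    log.info(
        "singlecell: combined C %.3f nmol/l/d, AOA share %.1f%%",
        extrapolation["C"]["combined_nmol_l_d"],
        100 * extrapolation["C"]["shares"].get("AOA", float("nan")),
    )
    return extrapolation


def run_partition(config: Config, out_dir: Path) -> dict:
    """Stoichiometric expectation versus measured single-cell AOA share."""
    import json

    out_dir = Path(out_dir)
    ox = pd.read_csv(out_dir / "rates_oxidation_summary.csv")
    ep = pd.read_csv(out_dir / "rates_endpoint_summary.csv")
    extrap = json.loads((out_dir / "extrapolation.json").read_text())

    ox_rate = float(ox.loc[ox["process"] == "oxidation", "mean_rate"].iloc[0])
    total_fix = float(ep.loc[ep["process"] == "dic_fixation", "mean_rate"].iloc[0])
    expected = expected_share(ox_rate, AOA_YIELD, total_fix)
    # steady-state nitrite: NOB nitrite flux defaults to the oxidation rate
    nob = expected_share(ox_rate, NOB_YIELD, total_fix)
    observed = float(extrap["C"]["shares"].get("AOA", float("nan")))
    report_ove = observed_vs_expected(expected, observed)
    bound = DilutionBound()
    upper = dilution_corrected_share(observed, bound.d_high, config.dilution_convention)
    report = {
        "oxidation_rate_nmol_l_d": ox_rate,
        "total_fixation_nmol_l_d": total_fix,
        "aoa_expected_share": {"low": expected.low, "high": expected.high, "flag": expected.flag},
        "nob_expected_share": {"low": nob.low, "high": nob.high},
        "aoa_observed_share": observed,
        "verdict": report_ove.verdict,
        "observed_over_expected_midpoint": report_ove.ratio,
        "dilution": {"d_low": bound.d_low, "d_high": bound.d_high},
        "aoa_share_upper_bound": upper,
        "dilution_convention": config.dilution_convention,
    }
    io.write_json(report, out_dir / "partition.json")
    log.info(
        "partition: expected %.1f-%.1f%%, observed %.1f%%, upper bound %.1f%%",
        100 * expected.low,
        100 * expected.high,
        100 * observed,
        100 * upper,
    )
    return report


def run_temperature(config: Config, out_dir: Path) -> dict:
    """Fit response models per process and the assimilation:fixation ratio."""
    out_dir = Path(out_dir)
    table = io.read_table(out_dir / "temperature.csv", "temperature")
    fits, selections = [], []
    experiments = {}
    for process in ("oxidation", "dic_fixation", "n_assimilation"):
        exp = TemperatureExperiment.from_frame(table, process)
        experiments[process] = exp
        positive = exp.rates > 0
        exp_pos = TemperatureExperiment(
            exp.process, exp.temperatures[positive], exp.replicates[positive], exp.rates[positive]
        )
        f_exp = fit_exponential(exp_pos)
        f_uni = fit_unimodal(exp)
        sel = select_model(f_exp, f_uni)
        selections.append(
            {
                "process": process,
                "preferred": sel.preferred,
                "delta_aicc": sel.delta_aicc,
                "indistinguishable": sel.indistinguishable,
            }
        )
        for f in (f_exp, f_uni):
            fits.append(
                {
                    "process": process,
                    "model": f.model,
                    **{f"param_{k}": v for k, v in f.parameters.items()},
                    "rss": f.rss,
                    "aicc": f.aicc,
                    "n": f.n,
                    "converged": f.converged,
                    "boundary": f.boundary,
                }
            )
    ratio = ratio_profile(experiments["n_assimilation"], experiments["dic_fixation"])
    io.write_table(pd.DataFrame(fits), out_dir / "temperature_fits.csv")
    io.write_table(pd.DataFrame(selections), out_dir / "temperature_selection.csv")
    io.write_table(ratio, out_dir / "temperature_ratio.csv")
    log.info("temperature: fitted %d models over 3 processes", len(fits))
    return {"fits": fits, "selections": selections, "ratio": ratio.to_dict("records")}


def run_pipeline(
    config: Config,
    stages: tuple[str, ...] | list[str],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the selected stages in dependency order, with provenance.

    ``stages`` may contain ``"all"``. The master seed defaults to the
    config's; per-stage streams are spawned from it so any stage subset is
    reproducible independently of the others.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = config.master_seed if seed is None else seed
    seeds = stage_seeds(master)
    selected = list(STAGES) if "all" in stages else [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES) - {"all"}
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    results: dict = {}
    runners = {
        "simulate": lambda: run_simulate(config, out_dir, seeds["simulate"]),
        "oxidation": lambda: run_oxidation(config, out_dir),
        "assimilation": lambda: run_assimilation(config, out_dir),
        "singlecell": lambda: run_singlecell(config, out_dir),
        "partition": lambda: run_partition(config, out_dir),
        "temperature": lambda: run_temperature(config, out_dir),
    }
    for stage in selected:
        try:
            results[stage] = runners[stage]()
        except FileNotFoundError as err:
            raise FileNotFoundError(f"stage {stage!r}: {err}") from err
    inputs = {
        p.name: p
        for p in sorted(out_dir.glob("*.csv"))
        if p.name in {"incubation_series.csv", "endpoint.csv", "cells.csv", "census.csv", "temperature.csv"}
    }
    io.write_json(make_provenance_record(config, inputs, seeds), out_dir / "provenance.json")
    return results


def make_provenance_record(config, inputs, seeds) -> dict:
    return io.make_provenance(config, inputs, seeds)
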