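"""Configuration, orchestration and reporting for reproducible runs.

A run is described by a versioned JSON document; `run_pipeline` executes the
requested stages in dependency order (synthetic cohorts → survival analysis;
demography; chemotaxis) with all randomness derived from the single top-level
seed, and returns a report whose numeric payload is byte-identical across
re-runs of the same config. No records are silently dropped: per-stage counts
of analyzed and excluded records are part of the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np

from androdyn import __version__
from androdyn.chemotaxis import aggregate_ci, compare_ci
from androdyn.demography import (
    BenchmarkResult, MatingSystemParams, PopulationState,
    compare_to_benchmark, generations_to_threshold, male_fraction_trajectory,
    simulate_sex_ratio,
)
from androdyn.errors import ConfigError
from androdyn.survival import (
    km_estimate, logrank_test, mean_lifespan, percent_reduction,
)
from androdyn.synthetic import (
    CohortSpec, calibrate_hazard, gen_chemotaxis_plate, gen_survival_cohort,
)

__all__ = ["SCHEMA_VERSION", "default_config", "validate_config",
           "run_pipeline"]

SCHEMA_VERSION = 1

log = logging.getLogger("androdyn.pipeline")


def default_config() -> dict[str, Any]:
    """A complete runnable configuration emulating the study's designs."""
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": 1,
        "stages": {
            "synth_cohorts": {
                # per-cohort Gompertz aging rates chosen so the simulated
                # SE of the mean matches the printed legend SEs
                # (12.0 ± 0.4 d at n=40; 7.7 ± 0.2 d at n=80)
                "cohorts": [
                    {"group": "solitary_males", "n": 40,
                     "target_mean": 12.0, "aging_rate": 0.5},
                    {"group": "grouped_males_8", "n": 80,
                     "target_mean": 7.7, "aging_rate": 0.7},
                ],
            },
            "survival": {"control_group": "solitary_males"},
            "demography": {
                "relative_progeny_factor": 0.768,
                "initial_male_fraction": 0.5,
                "threshold": 0.01,
                "generations": 20,
                "days_per_generation": 3.0,
            },
            "chemotaxis": {
                "n_plates": 12,
                "n_worms": 15,
                "groups": [
                    {"group": "female_supernatant",
                     "p_super": 0.55, "p_ctrl": 0.15, "p_origin": 0.2},
                    {"group": "buffer_only",
                     "p_super": 0.35, "p_ctrl": 0.35, "p_origin": 0.2},
                ],
                "compare": ["female_supernatant", "buffer_only"],
                "method": "t",
            },
        },
    }


_KNOWN_STAGES = ("synth_cohorts", "survival", "demography", "chemotaxis")


def validate_config(config: dict[str, Any]) -> list[str]:
    """Return every schema/range violation found (empty list = valid)."""
    issues: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a JSON object"]
    if config.get("schema_version") != SCHEMA_VERSION:
        issues.append(f"schema_version must be {SCHEMA_VERSION}")
    seed = config.get("seed")
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        issues.append("seed must be a non-negative integer")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        issues.append("stages must be a non-empty object")
        return issues
    for name in stages:
        if name not in _KNOWN_STAGES:
            issues.append(f"unknown stage {name!r}")

    synth = stages.get("synth_cohorts")
    if synth is not None:
        for i, c in enumerate(synth.get("cohorts", [])):
            if c.get("n", 1) < 1:
                issues.append(f"synth_cohorts.cohorts[{i}].n must be >= 1")
            if c.get("target_mean", 1.0) <= 0:
                issues.append(
                    f"synth_cohorts.cohorts[{i}].target_mean must be > 0")
            if c.get("aging_rate", 0.0) < 0:
                issues.append(
                    f"synth_cohorts.cohorts[{i}].aging_rate must be >= 0")
        if synth.get("aging_rate", 0.0) < 0:
            issues.append("synth_cohorts.aging_rate must be >= 0")
    surv = stages.get("survival")
    if surv is not None and synth is None:
        issues.append("survival stage requires synth_cohorts")

    demo = stages.get("demography")
    if demo is not None:
        r = demo.get("relative_progeny_factor", 0.768)
        if not 0.0 < r <= 1.0:
            issues.append("demography.relative_progeny_factor must be in (0, 1]")
        for key in ("initial_male_fraction", "selfing_male_rate",
                    "cross_male_rate"):
            if key in demo and not 0.0 <= demo[key] <= 1.0:
                issues.append(f"demography.{key} must be in [0, 1]")
        if demo.get("generations", 1) < 0:
            issues.append("demography.generations must be >= 0")
        th = demo.get("threshold", 0.01)
        if not 0.0 < th < 1.0:
            issues.append("demography.threshold must be in (0, 1)")

    chem = stages.get("chemotaxis")
    if chem is not None:
        if chem.get("n_plates", 1) < 1:
            issues.append("chemotaxis.n_plates must be >= 1")
        if chem.get("n_worms", 1) < 0:
            issues.append("chemotaxis.n_worms must be >= 0")
        for i, g in enumerate(chem.get("groups", [])):
            psum = g.get("p_super", 0) + g.get("p_ctrl", 0) + g.get("p_origin", 0)
            for key in ("p_super", "p_ctrl", "p_origin"):
                if key in g and not 0.0 <= g[key] <= 1.0:
                    issues.append(
                        f"chemotaxis.groups[{i}].{key} must be in [0, 1]")
            if psum > 1.0 + 1e-12:
                issues.append(
                    f"chemotaxis.groups[{i}] probabilities sum above 1")
    return issues


def _config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def _sub_seeds(seed: int, n: int) -> list[int]:
    # one reproducible 31-bit sub-seed per stochastic call site
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _run_synth_and_survival(stages: dict, seeds: list[int],
                            report: dict, warnings: list[str]) -> None:
    synth = stages["synth_cohorts"]
    default_aging = float(synth.get("aging_rate", 0.5))
    cohorts = {}
    stage_out: dict[str, Any] = {"cohorts": {}}
    for c, sub_seed in zip(synth["cohorts"], seeds):
        hazard = calibrate_hazard(float(c["target_mean"]),
                                  float(c.get("aging_rate", default_aging)))
        spec = CohortSpec(group_label=c["group"], n=int(c["n"]),
                          hazard=hazard, seed=sub_seed,
                          censor_day=c.get("censor_day"))
        records = gen_survival_cohort(spec)
        cohorts[c["group"]] = records
        stage_out["cohorts"][c["group"]] = {
            "n": len(records),
            "target_mean": c["target_mean"],
            "baseline_rate": hazard.baseline_rate,
            "aging_rate": hazard.aging_rate,
        }
        log.info("generated cohort %s (n=%d)", c["group"], len(records))
    report["stages"]["synth_cohorts"] = stage_out

    surv = stages.get("survival")
    if surv is None:
        return
    all_records = [r for recs in cohorts.values() for r in recs]
    summaries = {g: mean_lifespan(recs) for g, recs in cohorts.items()}
    curves = {g: km_estimate(recs) for g, recs in cohorts.items()}
    out: dict[str, Any] = {
        "n_input": len(all_records),
        "n_analyzed": len(all_records),
        "n_excluded": 0,
        "summaries": {g: {"mean": s.mean, "se": s.se, "n": s.n}
                      for g, s in summaries.items()},
        "km": {g: {"times": c.times.tolist(),
                   "survival": c.survival.tolist()}
               for g, c in curves.items()},
    }
    if len(cohorts) >= 2:
        lr = logrank_test(all_records)
        out["logrank"] = {"chi_square": lr.chi_square, "df": lr.df,
                          "p_value": lr.p_value}
    control = surv.get("control_group")
    if control is not None:
        if control not in summaries:
            raise ConfigError(f"survival.control_group {control!r} is not a "
                              "generated cohort")
        out["percent_reduction"] = {
            g: percent_reduction(summaries[control], s)
            for g, s in summaries.items() if g != control}
    report["stages"]["survival"] = out


def _run_demography(demo: dict, seeds: list[int], report: dict) -> None:
    params = MatingSystemParams(
        relative_progeny_factor=float(
            demo.get("relative_progeny_factor", 0.768)),
        selfing_male_rate=float(demo.get("selfing_male_rate", 0.002)),
        cross_male_rate=float(demo.get("cross_male_rate", 0.5)),
        encounter_efficacy=float(demo.get("encounter_efficacy", 10.0)),
        initial_male_fraction=float(demo.get("initial_male_fraction", 0.5)),
    )
    generations = int(demo.get("generations", 20))
    threshold = float(demo.get("threshold", 0.01))
    dpg = float(demo.get("days_per_generation", 3.0))

    treated = male_fraction_trajectory(params, generations)
    control = male_fraction_trajectory(
        MatingSystemParams(relative_progeny_factor=1.0,
                           initial_male_fraction=params.initial_male_fraction),
        generations)
    out: dict[str, Any] = {
        "params": {"relative_progeny_factor": params.relative_progeny_factor,
                   "initial_male_fraction": params.initial_male_fraction,
                   "threshold": threshold,
                   "days_per_generation": dpg},
        "control_male_fraction": control.male_fraction.tolist(),
        "treated_male_fraction": treated.male_fraction.tolist(),
    }
    if params.relative_progeny_factor < 1.0:
        gens = generations_to_threshold(params, threshold)
        bench: BenchmarkResult = compare_to_benchmark(
            male_fraction_trajectory(params, max(generations, gens)),
            threshold, dpg)
        out["generations_to_threshold"] = gens
        out["days_to_threshold"] = bench.days
    stoch = demo.get("stochastic")
    if stoch is not None:
        init = PopulationState(
            n_hermaphrodites=int(stoch.get("n_hermaphrodites", 5000)),
            n_males=int(stoch.get("n_males", 5000)))
        traj = simulate_sex_ratio(
            params, init, generations=generations, seed=seeds[0],
            cap=int(stoch.get("cap", 20000)),
            brood_size=int(stoch.get("brood_size", 238)))
        out["stochastic"] = {
            "generation": traj.generation.tolist(),
            "male_fraction": traj.male_fraction.tolist(),
            "extinct": traj.extinct,
        }
    report["stages"]["demography"] = out


def _run_chemotaxis(chem: dict, seeds: list[int], report: dict,
                    warnings: list[str]) -> None:
    n_plates = int(chem.get("n_plates", 12))
    n_worms = int(chem.get("n_worms", 15))
    plate_groups = {}
    seed_iter = iter(seeds)
    for g in chem["groups"]:
        plate_groups[g["group"]] = [
            gen_chemotaxis_plate(n_worms, g.get("p_super", 0.0),
                                 g.get("p_ctrl", 0.0), g.get("p_origin", 0.0),
                                 seed=next(seed_iter))
            for _ in range(n_plates)]
    out: dict[str, Any] = {"ci": {}}
    for g, plates in plate_groups.items():
        res = aggregate_ci(plates)
        out["ci"][g] = {"mean": res.mean_ci, "sem": res.sem,
                        "n_plates": res.n_plates}
    pair = chem.get("compare")
    if pair:
        a, b = pair
        out["comparison"] = {
            "groups": [a, b],
            "method": chem.get("method", "t"),
            "p_value": compare_ci(plate_groups[a], plate_groups[b],
                                  method=chem.get("method", "t"),
                                  seed=next(seed_iter)),
        }
    report["stages"]["chemotaxis"] = out


def run_pipeline(config: dict[str, Any],
                 output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured stages; identical config+seed ⇒ identical report.

    Returns the report dict; if ``output_dir`` is given, also writes it there
    as ``report.json``.
    """
    issues = validate_config(config)
    if issues:
        raise ConfigError("invalid config: " + "; ".join(issues))
    seed = int(config["seed"])
    stages = config["stages"]
    warnings: list[str] = []
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "stages": {},
        "warnings": warnings,
    }
    # fixed-size seed pool so adding a stage never reshuffles earlier seeds
    pool = _sub_seeds(seed, 64)
    if "synth_cohorts" in stages:
        _run_synth_and_survival(stages, pool[:16], report, warnings)
    if "demography" in stages:
        _run_demography(stages["demography"], pool[16:32], report)
    if "chemotaxis" in stages:
        _run_chemotaxis(stages["chemotaxis"], pool[32:], report, warnings)

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def setup_logging(verbose: bool = False, json_lines: bool = False) -> None:
    """Configure stderr logging; JSON-lines format for machine consumption."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _JsonFormatter(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps({"level": record.levelname,
                                   "name": record.name,
                                   "message": record.getMessage()})
        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                               "%(message)s"))
    root = logging.getLogger("androdyn")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
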