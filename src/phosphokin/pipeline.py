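"""End-to-end pipeline: evidence -> site groups -> differential -> kinases.

Stages run in the order the quantification workflow prescribes: outlier
screen, site-group conversion, median-equalization normalization, median
polish summarization, Student's t / BH differential testing, kinase z-score
inference. In ``simulate`` mode the inputs are generated by
:mod:`phosphokin.synthetic` with planted activities and a recovery report
is written alongside the results. Every stage's row counts go into a JSON
run log so filtering is auditable; a fixed seed makes simulate-mode output
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .errors import ConfigError, PhosphokinError
from .kinase import infer_kinase_activities, load_kinase_substrate_map, sitewise_ztest
from .site_quant import (
    differential_sites,
    flag_sample_outliers,
    normalize_median_equalization,
    summarize_site_groups,
    to_site_groups,
)
from .synthetic import evaluate_recovery, simulate_experiment, simulate_kinase_substrate_map

__all__ = ["PipelineConfig", "SimulationParams", "validate_config", "run_pipeline"]


@dataclass
class SimulationParams:
    """Simulation scenario for simulate-mode runs (log2 units throughout)."""

    n_kinases: int = 120
    substrates_per_kinase: int = 10
    n_active_kinases: int = 20
    activity_log2: float = 1.0
    replicates: int = 3
    n_null_sites: int = 0
    fragments_per_group: int = 2
    noise_sd: float = 0.5
    sample_offset_sd: float = 0.1
    missing_rate: float = 0.05
    allow_shared: bool = False


@dataclass
class PipelineConfig:
    output_dir: str = "phosphokin_out"
    mode: str = "real"  # "real" | "simulate"
    evidence: str | None = None
    design: str | None = None
    kinase_map: str | None = None
    contrast: tuple[str, str] | None = None
    alpha: float = 0.05
    min_substrates: int = 3
    match_rule: str = "any-site"
    outlier_threshold: float = 3.0
    exclude_outliers: bool = True
    polish_tol: float = 1e-6
    polish_max_iter: int = 50
    seed: int | None = None
    simulation: SimulationParams = field(default_factory=SimulationParams)


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}
_CFG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(path) -> tuple[PipelineConfig, list[str]]:
    """Load and validate a YAML config file.

    Returns (config, warnings). All violations are collected and raised
    together in a single :class:`ConfigError`; unknown keys produce warnings
    rather than errors so configs stay forward compatible.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config must be a key-value mapping, got {type(raw).__name__}"])
    return resolve_config(raw, base_dir=path.parent)


def resolve_config(raw: dict, base_dir: Path | None = None) -> tuple[PipelineConfig, list[str]]:
    """Validate a config mapping, fill defaults, collect every violation."""
    violations: list[str] = []
    warnings: list[str] = []

    known = dict(raw)
    for key in list(known):
        if key not in _CFG_FIELDS:
            warnings.append(f"unknown config key {key!r} ignored")
            known.pop(key)

    sim_raw = known.pop("simulation", {}) or {}
    if not isinstance(sim_raw, dict):
        violations.append("simulation: must be a mapping")
        sim_raw = {}
    for key in list(sim_raw):
        if key not in _SIM_FIELDS:
            warnings.append(f"unknown simulation key {key!r} ignored")
            sim_raw.pop(key)

    contrast = known.get("contrast")
    if contrast is not None:
        if not (isinstance(contrast, (list, tuple)) and len(contrast) == 2):
            violations.append("contrast: must be a pair [condition_A, condition_B]")
            known.pop("contrast")
        else:
            known["contrast"] = (str(contrast[0]), str(contrast[1]))

    cfg = PipelineConfig(**{**known, "simulation": SimulationParams(**sim_raw)})

    if cfg.mode not in ("real", "simulate"):
        violations.append(f"mode: must be 'real' or 'simulate', got {cfg.mode!r}")
    if cfg.contrast is None:
        violations.append("contrast: required (pair of condition labels)")
    if not 0 < cfg.alpha < 1:
        violations.append(f"alpha: must lie in (0, 1), got {cfg.alpha}")
    if cfg.min_substrates < 1:
        violations.append("min_substrates: must be >= 1")
    if cfg.match_rule not in ("any-site", "exact-singleton"):
        violations.append(f"match_rule: unknown rule {cfg.match_rule!r}")
    if cfg.polish_tol <= 0:
        violations.append("polish_tol: must be positive")
    if cfg.polish_max_iter < 1:
        violations.append("polish_max_iter: must be >= 1")
    if cfg.mode == "simulate":
        if cfg.seed is None:
            violations.append("seed: required in simulate mode")
        sim = cfg.simulation
        if sim.replicates < 1:
            violations.append("simulation.replicates: must be >= 1")
        if not 0 <= sim.missing_rate < 1:
            violations.append(f"simulation.missing_rate: must be in [0, 1), got {sim.missing_rate}")
        if sim.noise_sd < 0:
            violations.append("simulation.noise_sd: must be >= 0")
        if sim.n_active_kinases > sim.n_kinases:
            violations.append("simulation.n_active_kinases: cannot exceed n_kinases")
    else:
        for name in ("evidence", "design", "kinase_map"):
            value = getattr(cfg, name)
            if value is None:
                violations.append(f"{name}: required in real mode")
            else:
                p = Path(value)
                if base_dir is not None and not p.is_absolute():
                    p = base_dir / p
                    setattr(cfg, name, str(p))
                if not p.exists():
                    violations.append(f"{name}: file not found: {p}")

    if violations:
        raise ConfigError(violations)
    return cfg, warnings


def _simulation_inputs(cfg: PipelineConfig):
    sim = cfg.simulation
    rng = np.random.default_rng(cfg.seed)
    n_sites = sim.n_kinases * sim.substrates_per_kinase if not sim.allow_shared else max(
        sim.n_kinases * sim.substrates_per_kinase, sim.substrates_per_kinase
    )
    ksmap = simulate_kinase_substrate_map(
        sim.n_kinases, n_sites, sim.substrates_per_kinase,
        seed=int(rng.integers(2**31)), allow_shared=sim.allow_shared,
    )
    cond_a, cond_b = cfg.contrast
    design = {}
    for cond in (cond_a, cond_b):
        for r in range(sim.replicates):
            design[f"{cond}_{r + 1}"] = cond
    # alternate planted signs so the fold-change distribution stays centred
    activities = {}
    for i in range(sim.n_active_kinases):
        sign = 1.0 if i % 2 == 0 else -1.0
        activities[f"K{i + 1}"] = {cond_a: sign * sim.activity_log2, cond_b: 0.0}
    evidence, truth = simulate_experiment(
        ksmap, design, activities,
        fragments_per_group=sim.fragments_per_group,
        noise_sd=sim.noise_sd,
        sample_offset_sd=sim.sample_offset_sd,
        missing_rate=sim.missing_rate,
        seed=int(rng.integers(2**31)),
        n_null_sites=sim.n_null_sites,
    )
    return ksmap, design, evidence, truth


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Writes evidence (simulate mode), the site-group matrix, the differential
    table, the kinase-activity table, a recovery report (simulate mode) and
    ``run_log.json``. On a stage failure, partial outputs are retained and a
    ``FAILED`` marker file records the error before the exception
    propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _config_dict(config), "stages": {}, "versions": _versions()}
    try:
        if config.mode == "simulate":
            ksmap, design, evidence, truth = _simulation_inputs(config)
            design = pd.Series(design)
            pio.write_evidence(evidence, out / "evidence.tsv")
            ksmap.to_tsv(out / "kinase_map.tsv")
            pio.write_design(design, out / "design.tsv")
            truth.to_dir(out / "truth")
        else:
            evidence = pio.read_evidence(config.evidence)
            design = pio.read_design(config.design)
            ksmap = load_kinase_substrate_map(config.kinase_map)
            truth = None
        log["stages"]["evidence_rows"] = int(len(evidence))
        log["stages"]["samples"] = int(evidence["sample"].nunique())

        flagged = flag_sample_outliers(evidence, threshold=config.outlier_threshold)
        log["stages"]["outlier_samples_flagged"] = flagged
        if flagged and config.exclude_outliers:
            before = len(evidence)
            evidence = evidence[~evidence["sample"].isin(flagged)].reset_index(drop=True)
            log["stages"]["evidence_rows_dropped_as_outliers"] = before - int(len(evidence))
        log["stages"]["evidence_rows_retained"] = int(len(evidence))

        grouped = to_site_groups(evidence)
        grouped["log2_intensity"] = pio.log2_intensities(grouped)
        observed = grouped.dropna(subset=["log2_intensity"])
        log["stages"]["observed_rows"] = int(len(observed))
        log["stages"]["missing_rows"] = int(len(grouped) - len(observed))

        normalized = normalize_median_equalization(observed)
        matrix = summarize_site_groups(
            normalized, tol=config.polish_tol, max_iter=config.polish_max_iter
        )
        log["stages"]["site_groups"] = int(len(matrix))
        pio.write_matrix(matrix, out / "site_group_matrix.tsv")

        diff = differential_sites(matrix, design, config.contrast)
        log["stages"]["site_groups_tested"] = int(diff["pvalue"].notna().sum())
        fold_changes = diff.set_index("site_group")["log2FC"]
        site_p = sitewise_ztest(fold_changes)
        diff = diff.merge(
            site_p.rename("ztest_pvalue"), left_on="site_group", right_index=True, how="left"
        )
        pio.write_table(diff, out / "differential.tsv")

        kin = infer_kinase_activities(
            fold_changes, ksmap,
            min_substrates=config.min_substrates,
            alpha=config.alpha,
            rule=config.match_rule,
        )
        log["stages"]["kinases_tested"] = int(kin["pvalue"].notna().sum())
        pio.write_table(kin, out / "kinase_activity.tsv")

        if truth is not None:
            report = evaluate_recovery(truth, kin, config.contrast, alpha=config.alpha)
            (out / "recovery.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
            log["stages"]["recovery"] = report.to_dict()
    except PhosphokinError as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
        raise
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return out


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("contrast") is not None:
        d["contrast"] = list(d["contrast"])
    return d


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "phosphokin": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
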