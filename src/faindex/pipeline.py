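"""Reproducible simulate -> score -> analyze -> report pipeline.

Each stage writes tidy CSV/JSON artifacts plus a run manifest (config hash,
seed, package version, SHA-256 checksums of every output) so that two runs
with equal config and seed produce equal checksums. Complete-case
exclusions are logged at every stage, mirroring the shifting denominators
of questionnaire studies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .descriptive import class_profile_table, spearman, transition_summary
from .questionnaire import read_questionnaire_csv, score_cohort
from .simulate import CohortTable, SimulationConfig, events_table, generate_cohort
from .survival import class_factor_lr_test, kaplan_meier, log_rank_test

__all__ = [
    "ConfigError",
    "load_config",
    "run_simulate",
    "run_score",
    "run_analyze",
    "run_selftest",
    "write_manifest",
]

logger = logging.getLogger("faindex.pipeline")


class ConfigError(ValueError):
    """Simulation config failed schema validation."""


def load_config(path, seed_override: Optional[int] = None) -> SimulationConfig:
    """Load and validate a YAML/JSON simulation config.

    Unknown keys and invalid values raise :class:`ConfigError` naming the
    offending key. ``seed_override`` replaces the config's seed.
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if raw is None:
        raw = {}
    if seed_override is not None:
        raw["seed"] = seed_override
    if "seed" not in raw:
        raise ConfigError("config must set 'seed' (no default randomness)")
    try:
        cfg = SimulationConfig(**raw)
    except ValidationError as exc:
        keys = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid config key(s): {keys}\n{exc}") from exc
    return SimulationConfig.defaults(**cfg.model_dump()) if cfg.item_model is None else cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: SimulationConfig) -> str:
    canon = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(out_dir: Path, config: Optional[SimulationConfig], outputs) -> Path:
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def run_simulate(config: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Generate a cohort and write cohort.csv, events.csv and the manifest.

    Partial outputs are removed if generation fails midway.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        cohort = generate_cohort(config)
        cohort_path = out_dir / "cohort.csv"
        cohort.to_csv(cohort_path)
        written.append(cohort_path)
        events_path = out_dir / "events.csv"
        events_table(cohort).to_csv(events_path, index=False)
        written.append(events_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    manifest = write_manifest(out_dir, config, written)
    logger.info("simulated cohort n=%d -> %s", config.n, out_dir)
    return {"cohort": written[0], "events": written[1], "manifest": manifest}


def run_score(cohort_csv, out_dir) -> Dict[str, Path]:
    """Score a raw questionnaire CSV: per-respondent scores + class summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = read_questionnaire_csv(cohort_csv)
    scores = score_cohort(df)
    n_excluded = scores.n_total - scores.n_scorable
    logger.info(
        "scored %d records; %d unscorable excluded (complete-case)",
        scores.n_total, n_excluded,
    )
    scored_path = out_dir / "scored.csv"
    scores.table.to_csv(scored_path, index=False)
    summary_path = out_dir / "class_summary.csv"
    scores.summary().to_csv(summary_path)
    manifest = write_manifest(out_dir, None, [scored_path, summary_path])
    return {"scored": scored_path, "class_summary": summary_path, "manifest": manifest}


_REQUIRED_ANALYZE_COLS = [
    "fa_class", "pooled_class", "age", "sex",
    "observed_death_time", "death_event",
    "observed_nursing_time", "nursing_event",
    "wave2_outcome",
]


def run_analyze(cohort_path, out_dir, horizon_months: float = 93.0) -> Dict[str, Path]:
    """Full report bundle from a scored cohort CSV.

    Emits class shares, the per-class profile, attrition and wave-2 outcome
    tables, KM curve data per class and endpoint, log-rank and adjusted PH
    results, the pooled transition summary and rank correlations. Every
    percentage is traceable to numerator/denominator columns; exclusions
    are logged. A single-class cohort skips the group tests with a notice.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(cohort_path)
    missing = [c for c in _REQUIRED_ANALYZE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {missing}")
    log_lines = []
    scored = df[df["fa_class"].notna()].copy()
    log_lines.append(
        f"records: {len(df)} total, {len(df) - len(scored)} unscorable excluded"
    )
    outputs: Dict[str, Path] = {}

    # class shares (grid-table analogue)
    counts = scored["fa_class"].value_counts()
    order = ["Robust", "postRobust", "preFrail", "Frail"]
    counts = counts.reindex(order, fill_value=0)
    from ._rounding import percent

    shares = pd.DataFrame(
        {"count": counts, "n": len(scored),
         "percent": [percent(c, len(scored)) for c in counts]}
    )
    outputs["class_shares"] = out_dir / "class_shares.csv"
    shares.to_csv(outputs["class_shares"])

    # per-class covariate/age profile
    profile = class_profile_table(scored)
    outputs["class_profile"] = out_dir / "class_profile.csv"
    profile.to_csv(outputs["class_profile"], index=False)

    # attrition by class (deaths / lost / refusals between waves)
    att_rows = []
    for cls in order:
        sub = scored[scored["fa_class"] == cls]
        n = len(sub)
        for what in ("dead", "lost", "refused"):
            cases = int((sub["wave2_outcome"] == what).sum())
            att_rows.append(
                {"fa_class": cls, "outcome": what, "cases": cases, "n": n,
                 "percent": percent(cases, n)}
            )
    outputs["attrition"] = out_dir / "attrition.csv"
    pd.DataFrame(att_rows).to_csv(outputs["attrition"], index=False)

    # survival analyses per endpoint
    classes_present = [c for c in order if (scored["fa_class"] == c).any()]
    survival_results = {}
    km_frames = []
    for endpoint, tcol, ecol in (
        ("death", "observed_death_time", "death_event"),
        ("nursing_care", "observed_nursing_time", "nursing_event"),
    ):
        for cls in classes_present:
            sub = scored[scored["fa_class"] == cls]
            km = kaplan_meier(sub[tcol], sub[ecol])
            frame = km.as_frame()
            frame.insert(0, "endpoint", endpoint)
            frame.insert(1, "fa_class", cls)
            km_frames.append(frame)
        if len(classes_present) < 2:
            log_lines.append(
                f"{endpoint}: single class present; log-rank and PH skipped"
            )
            survival_results[endpoint] = {"skipped": "single class"}
            continue
        if int(scored[ecol].sum()) == 0:
            log_lines.append(f"{endpoint}: no events; log-rank and PH skipped")
            survival_results[endpoint] = {"skipped": "no events"}
            continue
        lr = log_rank_test(scored[tcol], scored[ecol], scored["fa_class"])
        adjust = ["age", "is_female"]
        scored["is_female"] = (scored["sex"] == "female").astype(float)
        if "fair_poor_health" in scored.columns:
            scored["fair_poor_health_f"] = scored["fair_poor_health"].astype(float)
            adjust.append("fair_poor_health_f")
        ph = class_factor_lr_test(
            scored, tcol, ecol, "fa_class", adjust_cols=adjust
        )
        survival_results[endpoint] = {
            "log_rank": {
                "statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value,
                "observed": dict(zip(lr.groups, lr.observed.tolist())),
                "expected": dict(zip(lr.groups, lr.expected.tolist())),
            },
            "ph_adjusted": {
                "log_hazard_ratios": ph.params.to_dict(),
                "standard_errors": ph.standard_errors.to_dict(),
                "lr_statistic": ph.lr_statistic,
                "lr_df": ph.lr_df,
                "lr_p": ph.lr_p,
                "adjusted_for": adjust,
            },
        }
    outputs["km_curves"] = out_dir / "km_curves.csv"
    pd.concat(km_frames, ignore_index=True).to_csv(outputs["km_curves"], index=False)
    outputs["survival"] = out_dir / "survival_results.json"
    outputs["survival"].write_text(json.dumps(survival_results, indent=2) + "\n")

    # transitions (pooled classes)
    trans = transition_summary(scored["pooled_class"], scored["wave2_outcome"])
    outputs["transition_counts"] = out_dir / "transition_counts.csv"
    trans.counts.to_csv(outputs["transition_counts"])
    outputs["transition_percent"] = out_dir / "transition_percent.csv"
    trans.row_percent.to_csv(outputs["transition_percent"])

    # rank correlations of the ordinal class with age / health measures
    ordinal = scored["fa_class"].map(
        {"Robust": 0, "postRobust": 1, "preFrail": 2, "Frail": 3}
    ).astype(float)
    corr_rows = []
    for name in ("age", "fair_poor_health", "chronic_pain", "depressed"):
        if name not in scored.columns:
            continue
        vec = scored[name]
        vec = vec.astype(float) if vec.dtype != object else vec.map(
            {True: 1.0, False: 0.0, "True": 1.0, "False": 0.0}
        ).astype(float)
        res = spearman(ordinal, vec)
        corr_rows.append(
            {"variable": name, "rho": res.rho, "p_value": res.p_value, "n": res.n}
        )
        log_lines.append(f"spearman fa_class~{name}: complete-case n={res.n}")
    if corr_rows:
        outputs["correlations"] = out_dir / "correlations.csv"
        pd.DataFrame(corr_rows).to_csv(outputs["correlations"], index=False)

    log_path = out_dir / "analysis_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    manifest = write_manifest(out_dir, None, sorted(outputs.values()))
    outputs["manifest"] = manifest
    for line in log_lines:
        logger.info("%s", line)
    return outputs


def run_selftest() -> Dict[str, bool]:
    """Internal consistency sweep: classification oracle + small stat oracles."""
    from itertools import product

    from .descriptive import fisher_exact, welch_t
    from .questionnaire import classify

    results = {}
    # exhaustive classification sweep over reachable score pairs
    ok = True
    for risk, resource in product(range(7), range(7)):
        if risk + resource > 11:
            continue
        label = classify(risk, resource).value
        expect = {
            (True, True): "Robust", (False, True): "postRobust",
            (True, False): "preFrail", (False, False): "Frail",
        }[(risk <= 2, resource >= 3)]
        ok &= label == expect
    results["classification_grid"] = ok
    results["fisher_5_0_0_5"] = abs(
        fisher_exact([[5, 0], [0, 5]]).p_value - 1 / 126
    ) < 1e-12
    results["welch_identical"] = abs(welch_t([1, 2, 3], [1, 2, 3]).t) < 1e-12
    km = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 0, 0, 0])
    results["km_hand"] = bool(np.allclose(km.survival, [1.0, 0.8, 0.6]))
    return results
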