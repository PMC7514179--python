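"""End-to-end orchestration: raw or synthetic trials -> statistics tables.

``run_pipeline`` executes the fixed stage order (preprocess -> posture
matrix -> kinematic PCA -> PM selection -> score differentiation ->
control measures -> split-plot ANOVA) from a single ``RunConfig``, and
writes every artifact plus a provenance JSON echoing all parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import measures, pma, preprocessing, stats
from .io import MarkerFrameSeries, load_marker_config, read_trial, write_trial_csv
from .synthetic import SyntheticCohort, SyntheticCohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run (YAML round-trippable)."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    trial_paths: list[str] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)  # SyntheticCohortSpec overrides
    cut_s: float = 10.0
    target_rate_hz: float = 120.0
    marker_config: str | None = None  # YAML path; None = packaged default
    gap_components: int = 5
    entropy_m: int = 2
    entropy_r_coeff: float = 0.2
    entropy_tau: int = 12
    filter_cutoff_hz: float = 7.0
    filter_order: int = 6
    detrend_window: int = 501
    selection_threshold: float | None = None  # None = 1/n_columns
    loo_angle_limit_deg: float = 15.0
    run_loo: bool = True
    alpha: float = 0.05
    correction_rule_threshold: float = 0.75
    always_correct: bool = False
    out_dir: str = "pmsway_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    """Artifact bundle of one run."""

    basis: pma.PrincipalMovementBasis
    retained: np.ndarray
    pm_series: list[pma.PMTimeSeries]
    measure_table: pd.DataFrame
    effects: pd.DataFrame
    posthoc: pd.DataFrame
    loo: dict | None
    provenance: dict
    cohort: SyntheticCohort | None = None


def _load_trials(config: RunConfig) -> tuple[list[MarkerFrameSeries], SyntheticCohort | None]:
    if config.mode == "synthetic":
        spec = SyntheticCohortSpec(**{**config.synthetic, "seed": config.seed})
        cohort = generate_cohort(spec)
        return cohort.trials, cohort
    if config.mode == "files":
        if not config.trial_paths:
            raise ValueError("files mode requires trial_paths")
        trials = []
        for p in config.trial_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
            trials.append(read_trial(p))
        return trials, None
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute all stages; deterministic given ``config.seed``."""
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("load")
    trials, cohort = _load_trials(config)

    _stage("preprocess")
    mcfg = (preprocessing.default_marker_config() if config.marker_config is None
            else load_marker_config(config.marker_config))
    X = preprocessing.preprocess_cohort(
        trials, config=mcfg, cut_s=config.cut_s, target_rate=config.target_rate_hz,
        gap_components=config.gap_components,
    )

    _stage("pca")
    basis = pma.fit_pma(X)
    threshold = (1.0 / X.n_columns if config.selection_threshold is None
                 else config.selection_threshold)
    retained = np.flatnonzero(basis.rel_ev > threshold)

    loo = None
    if config.run_loo and len({s for _, _, s, _ in X.row_ledger}) >= 3:
        _stage("leave-one-out")
        loo = pma.loo_crossvalidate(X, basis, k=len(retained),
                                    angle_limit_deg=config.loo_angle_limit_deg)

    _stage("scores")
    series = pma.pm_series_for_matrix(X, basis, retained)

    _stage("measures")
    eparams = measures.EntropyParams(config.entropy_m, config.entropy_r_coeff,
                                     config.entropy_tau, config.target_rate_hz)
    table = measures.compute_measures_table(
        series, retained, eparams, cutoff_hz=config.filter_cutoff_hz,
        filter_order=config.filter_order, detrend_window=config.detrend_window,
    )

    _stage("statistics")
    effects, posthoc = stats.analyze_measures(
        table, alpha=config.alpha, rule_threshold=config.correction_rule_threshold,
        always_correct=config.always_correct,
    )

    provenance = {
        "config": dataclasses.asdict(config),
        "n_trials": len(trials),
        "n_rows": int(X.data.shape[0]),
        "n_columns": int(X.n_columns),
        "selection_threshold_pct": 100.0 * threshold,
        "retained_pms": [int(i) + 1 for i in retained],
        "rel_ev_pct": basis.rel_ev_pct[: max(10, len(retained))].round(4).tolist(),
        "entropy": dataclasses.asdict(eparams),
    }
    if loo is not None:
        provenance["loo_max_angle_deg"] = np.round(loo["max_angle_deg"], 3).tolist()
        provenance["loo_robust"] = [bool(b) for b in loo["robust"]]

    if write_outputs:
        basis.to_json(out / "pm_basis.json")
        table.to_csv(out / "measures.csv", index=False)
        effects.to_csv(out / "anova_effects.csv", index=False)
        posthoc.to_csv(out / "posthoc.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        for ts in series:
            fname = out / f"pm_scores_{ts.subject_id}_{ts.condition}.csv"
            cols = {}
            for j, pm_idx in enumerate(retained):
                cols[f"pp_{pm_idx + 1}"] = ts.pp[:, j]
                cols[f"pv_{pm_idx + 1}"] = ts.pv[:, j]
                cols[f"pa_{pm_idx + 1}"] = ts.pa[:, j]
            pd.DataFrame(cols).to_csv(fname, index=False, float_format="%.9g")
        if cohort is not None:
            (out / "ground_truth.json").write_text(json.dumps(cohort.ledger(), indent=2))

    return PipelineResult(basis, retained, series, table, effects, posthoc, loo,
                          provenance, cohort)


def export_cohort_csv(cohort: SyntheticCohort, out_dir: str | Path) -> list[Path]:
    """Write every synthetic trial as wide CSV + JSON sidecar; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in cohort.trials:
        p = out / f"{tr.meta.subject_id}_{tr.meta.condition}.csv"
        write_trial_csv(tr, p)
        paths.append(p)
    (out / "ground_truth.json").write_text(json.dumps(cohort.ledger(), indent=2))
    return paths
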