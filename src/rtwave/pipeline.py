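"""Per-dataset and study-level orchestration.

A :class:`DatasetConfig` names its input (a delimited trial file or a
synthetic specification), the preprocessing variant, and the analysis
parameters.  :func:`run_dataset` executes the fixed stage order

    read/generate -> filter_errors -> filter_outliers -> assign_differential
    -> build_profile -> arm_symmetry (normalize + split + resample + r)
    -> null_probability

and returns a report with full stage accounting.  :func:`run_study`
aggregates dataset reports, summarizes each group, and runs the pooled
two-sample t-test on the per-dataset null probabilities between groups.
All randomness flows from the configured seeds, so re-running a study with
the same configuration reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dispersion_profile, group_inference, null_model, symmetry_analysis, trial_io
from .errors import ConfigError, RTWaveError
from .synthetic_data import DesignConfig, WaveParams, generate_trials
from .trial_io import FilterSpec

__all__ = ["DatasetConfig", "DatasetReport", "StudyReport",
           "run_dataset", "run_study", "write_report", "read_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to analyze one dataset.

    Exactly one of ``input_path`` / ``synthetic`` must be present.
    ``synthetic`` is a mapping with keys ``design`` (DesignConfig fields),
    ``wave`` (WaveParams fields) and ``seed``.  ``null`` holds overrides
    for the Monte Carlo null (``mu``, ``sigma``, ``reps``, ``seed``).
    """

    name: str
    group: str = "default"
    input_path: str | None = None
    column_map: Mapping[str, str] | None = None
    synthetic: Mapping[str, Any] | None = None
    filter: FilterSpec = field(default_factory=lambda: FilterSpec(outlier_k=None))
    differential_mode: str = "vs_estimate"
    min_count: int = 5
    axis: float = 0.0
    K: int = 100
    smoothing: float | None = None
    null: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError(
                f"dataset {self.name!r}: exactly one of input_path / synthetic required")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DatasetConfig":
        d = dict(d)
        # YAML parses an unquoted `null:` key as None; accept that and the
        # `null_model:` alias for the Monte Carlo overrides
        for alias in (None, "null_model"):
            if alias in d:
                d["null"] = {**(d.pop(alias) or {}), **(d.get("null") or {})}
        if d.get("null") is None:
            d["null"] = {}
        if "filter" in d and not isinstance(d["filter"], FilterSpec):
            d["filter"] = FilterSpec(**d["filter"])
        return cls(**d)


@dataclass
class DatasetReport:
    """Per-dataset analysis outcome with stage accounting."""

    name: str
    group: str
    config: dict
    n_input: int
    n_errors_removed: int
    n_outliers_removed: int
    n_retained: int
    dropped_bins: list
    profile: list[dict]
    r: float
    axis: float
    K: int
    smoothing: float
    p_hat: float
    null_reps: int
    null_mu: float
    null_sigma: float
    null_seed: int | None
    r_sim_mean: float
    r_sim_sd: float


@dataclass
class StudyReport:
    """Study-level aggregation over datasets and groups."""

    datasets: list[DatasetReport]
    group_summaries: dict[str, dict[str, dict]]
    ttest: dict | None
    ttest_groups: list[str] | None
    notes: list[str]


def _load_table(cfg: DatasetConfig) -> pd.DataFrame:
    if cfg.input_path is not None:
        return trial_io.read_trials(cfg.input_path, column_map=cfg.column_map)
    spec = dict(cfg.synthetic)
    design = spec.get("design", {})
    if not isinstance(design, DesignConfig):
        design = DesignConfig(**design)
    wave = spec.get("wave", {})
    if not isinstance(wave, WaveParams):
        wave = WaveParams(**wave)
    return generate_trials(design, wave, seed=spec.get("seed", 0))


def _config_echo(cfg: DatasetConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["filter"] = dataclasses.asdict(cfg.filter)
    for key in ("synthetic", "null", "column_map"):
        if d.get(key) is not None:
            d[key] = {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                      for k, v in dict(d[key]).items()}
    return d


def run_dataset(cfg: DatasetConfig) -> DatasetReport:
    """Run the full per-dataset analysis chain.

    Any stage failure is re-raised with a stage-tagged message so study
    runs can report which dataset and step broke.
    """
    stage = "load"
    try:
        table = _load_table(cfg)
        n_input = len(table)

        stage = "filter_errors"
        table = trial_io.filter_errors(table, cfg.filter)
        n_err = table.attrs.get("n_errors_removed", 0)

        stage = "filter_outliers"
        table = trial_io.filter_outliers(table, cfg.filter)
        n_out = table.attrs.get("n_outliers_removed", 0)

        stage = "assign_differential"
        table = trial_io.assign_differential(table, cfg.differential_mode)

        stage = "build_profile"
        profile = dispersion_profile.build_profile(table, min_count=cfg.min_count)

        stage = "arm_symmetry"
        sym = symmetry_analysis.arm_symmetry(
            profile, axis=cfg.axis, K=cfg.K, smoothing=cfg.smoothing)

        stage = "null_probability"
        null_opts = dict(cfg.null)
        ncfg = null_model.NullConfig(
            abscissae=profile["differential"].tolist(),
            mu=null_opts.get("mu", 0.44),
            sigma=null_opts.get("sigma", 0.27),
            reps=null_opts.get("reps", 10_000),
            axis=cfg.axis,
            K=cfg.K,
            smoothing=cfg.smoothing,
            seed=null_opts.get("seed"),
        )
        null = null_model.null_probability(sym.r, ncfg)
    except RTWaveError as exc:
        raise type(exc)(f"[{cfg.name} / {stage}] {exc}") from exc

    return DatasetReport(
        name=cfg.name,
        group=cfg.group,
        config=_config_echo(cfg),
        n_input=n_input,
        n_errors_removed=int(n_err),
        n_outliers_removed=int(n_out),
        n_retained=len(table),
        dropped_bins=list(profile.attrs.get("dropped_bins", [])),
        profile=profile.to_dict(orient="records"),
        r=sym.r,
        axis=sym.axis,
        K=sym.K,
        smoothing=sym.smoothing,
        p_hat=null.p_hat,
        null_reps=null.reps,
        null_mu=ncfg.mu,
        null_sigma=ncfg.sigma,
        null_seed=ncfg.seed,
        r_sim_mean=null.r_sim_mean,
        r_sim_sd=null.r_sim_sd,
    )


def run_study(cfgs: Sequence[DatasetConfig]) -> StudyReport:
    """Analyze every dataset, summarize groups, and test p_hat between
    the two group labels (in first-appearance order).

    With fewer than two groups, or fewer than two datasets in a group,
    the t-test block is omitted with a note.
    """
    reports = [run_dataset(c) for c in cfgs]
    notes: list[str] = []

    groups: dict[str, list[DatasetReport]] = {}
    for rep in reports:
        groups.setdefault(rep.group, []).append(rep)

    summaries = {
        label: {
            "r": dataclasses.asdict(group_inference.summarize([r.r for r in reps])),
            "p_hat": dataclasses.asdict(group_inference.summarize([r.p_hat for r in reps])),
        }
        for label, reps in groups.items()
    }

    ttest = None
    ttest_groups = None
    labels = list(groups)
    if len(labels) != 2:
        notes.append(f"t-test omitted: need exactly 2 group labels, got {len(labels)}")
        log.warning(notes[-1])
    elif any(len(groups[lb]) < 2 for lb in labels):
        notes.append("t-test omitted: each group needs >= 2 datasets")
        log.warning(notes[-1])
    else:
        res = group_inference.two_sample_t(
            [r.p_hat for r in groups[labels[0]]],
            [r.p_hat for r in groups[labels[1]]],
        )
        ttest = dataclasses.asdict(res)
        ttest["significant"] = res.significant
        ttest_groups = labels

    return StudyReport(datasets=reports, group_summaries=summaries,
                       ttest=ttest, ttest_groups=ttest_groups, notes=notes)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _human_summary(d: dict) -> str:
    lines = []
    if "datasets" in d:  # study report
        lines.append(f"Study report: {len(d['datasets'])} dataset(s)")
        for rep in d["datasets"]:
            lines.append(
                f"  {rep['name']} [{rep['group']}]: r={rep['r']:.3f}, "
                f"p_hat={rep['p_hat']:.5f} ({rep['null_reps']} reps)")
        if d.get("ttest"):
            t = d["ttest"]
            g = d.get("ttest_groups") or []
            lines.append(
                f"  t-test ({' vs '.join(g)}): t({t['df']}) = {t['t']:.3f}, "
                f"p = {t['p']:.3f}")
        for note in d.get("notes", []):
            lines.append(f"  note: {note}")
    else:
        lines.append(
            f"Dataset {d['name']} [{d['group']}]: {d['n_input']} trials in, "
            f"{d['n_retained']} retained "
            f"({d['n_errors_removed']} errors, {d['n_outliers_removed']} outliers removed)")
        lines.append(f"  arm correlation r = {d['r']:.3f} (axis {d['axis']}, K={d['K']})")
        lines.append(f"  null p_hat = {d['p_hat']:.5f} over {d['null_reps']} reps")
    return "\n".join(lines) + "\n"


def write_report(report: DatasetReport | StudyReport, path,
                 format: str = "json") -> None:
    """Serialize a report: ``json`` (machine-readable, round-trips through
    :func:`read_report`) or ``text`` (human-readable summary)."""
    d = dataclasses.asdict(report)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, cls=_ReportEncoder)
            fh.write("\n")
    elif format == "text":
        with open(path, "w") as fh:
            fh.write(_human_summary(d))
    else:
        raise ConfigError(f"unknown report format {format!r}")


def read_report(path) -> DatasetReport | StudyReport:
    """Load a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        d = json.load(fh)
    if "datasets" in d:
        d["datasets"] = [DatasetReport(**rep) for rep in d["datasets"]]
        return StudyReport(**d)
    return DatasetReport(**d)
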