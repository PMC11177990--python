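"""End-to-end orchestration: simulate -> preprocess -> segment -> featurize -> analyze.

Usable in two ways: in-memory (``cohort_feature_table`` on a generated
cohort, the path the tests take) and file-based (``run_simulate`` /
``run_extract`` / ``run_analyze``, the CLI path, with plain CSV/JSON
artifacts between stages so any stage can be inspected or replaced).
Every stage logs counts in/out; a single top-level seed reproduces every
artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import models as mdl
from . import stats as st
from .preprocess import PreprocessConfig, preprocess_recording, wear_compliance
from .segmentation import WindowGrid, label_windows_heuristic, label_windows_oracle
from .synthetic import (
    DEFAULT_GROUP_SIZES,
    AccelRecording,
    CohortMember,
    generate_cohort,
    read_intervals,
    write_cohort,
)

log = logging.getLogger("gdmkin.pipeline")

SCORE_COLS = ("uhdrs_motor", "uhdrs_functional", "tfc", "uhdrs_ul")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    group_sizes: tuple[int, int, int] = DEFAULT_GROUP_SIZES
    n_days: int = 7
    day_length_hours: float = 12.0
    sample_rate: float = 50.0
    detector: str = "oracle"  # or "heuristic"
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    grid: WindowGrid = dataclasses.field(default_factory=WindowGrid)
    features: feat.FeatureConfig = dataclasses.field(default_factory=feat.FeatureConfig)
    model: mdl.ModelConfig = dataclasses.field(default_factory=mdl.ModelConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict = {}
        nested = {
            "preprocess": PreprocessConfig,
            "grid": WindowGrid,
            "features": feat.FeatureConfig,
            "model": mdl.ModelConfig,
        }
        for key, sub_cls in nested.items():
            if key in raw:
                sub = raw.pop(key)
                unknown = set(sub) - {f.name for f in dataclasses.fields(sub_cls)}
                if unknown:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                kwargs[key] = sub_cls(**sub)
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_sizes" in raw:
            raw["group_sizes"] = tuple(raw["group_sizes"])
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _label(recording: AccelRecording, signals, config: PipelineConfig) -> np.ndarray:
    if config.detector == "oracle":
        return label_windows_oracle(recording, config.grid)
    if config.detector == "heuristic":
        return label_windows_heuristic(signals, config.grid)
    raise ValueError(f"unknown detector {config.detector!r}")


def recording_day_features(recording: AccelRecording, config: PipelineConfig):
    signals = preprocess_recording(recording, config.preprocess)
    labels = _label(recording, signals, config)
    return feat.extract_day_features(signals, labels, config.grid, config.features)


def cohort_feature_table(
    cohort: list[CohortMember], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Subject-level table: 22 GDM features + group, severity, scores, compliance."""
    config = config or PipelineConfig()
    rows = []
    for member in cohort:
        day_results = [recording_day_features(rec, config) for rec in member.recordings]
        n_windows = sum(len(df) for df, _ in day_results)
        log.info(
            "subject %s: %d days, %d GDM windows",
            member.profile.subject_id,
            len(day_results),
            n_windows,
        )
        if n_windows == 0:
            log.warning("subject %s dropped: no GDM windows", member.profile.subject_id)
            continue
        row = feat.subject_feature_row(day_results)
        _, mean_compliance = wear_compliance(recordings=member.recordings)
        row["compliance"] = mean_compliance
        row["subject_id"] = member.profile.subject_id
        row["group"] = member.profile.group
        row["severity"] = member.profile.severity
        for key, val in member.scores.as_dict().items():
            row[key] = val
        rows.append(row)
    table = pd.DataFrame(rows).reset_index(drop=True)
    meta = ["subject_id", "group", "severity", "n_days", "compliance", *SCORE_COLS]
    ordered = meta + [c for c in feat.FEATURE_COLUMNS if c in table.columns]
    return table[ordered]


# ---------------------------------------------------------------------------
# File-based stages (the CLI surface)
# ---------------------------------------------------------------------------


def _check_outdir(outdir: Path, force: bool) -> None:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True/--force to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)


def run_simulate(config: PipelineConfig, outdir: Path, force: bool = False) -> Path:
    """Generate the cohort and write recordings + manifest CSVs."""
    _check_outdir(outdir, force)
    cohort = generate_cohort(
        group_sizes=config.group_sizes,
        seed=config.seed,
        n_days=config.n_days,
        day_length_hours=config.day_length_hours,
        sample_rate=config.sample_rate,
    )
    manifest = write_cohort(cohort, Path(outdir))
    log.info("simulate: %d subjects, %d recordings", len(cohort), sum(len(m.recordings) for m in cohort))
    return manifest


def _load_recording_row(row: pd.Series, basedir: Path) -> AccelRecording:
    data = np.loadtxt(basedir / row["recording_file"], delimiter=",", skiprows=1)
    intervals = read_intervals(basedir / row["intervals_file"])
    return AccelRecording(
        subject_id=row["subject_id"],
        day_index=int(row["day_index"]),
        sample_rate=float(row["sample_rate"]),
        accel=data[:, 1:4],
        true_gdm_intervals=intervals,
    )


def run_extract(config: PipelineConfig, datadir: Path, out_csv: Path) -> Path:
    """Read a cohort manifest and write the subject feature table CSV."""
    datadir = Path(datadir)
    manifest = pd.read_csv(datadir / "manifest.csv")
    rows = []
    for subject_id, sub in manifest.groupby("subject_id", sort=True):
        day_results = []
        recordings = []
        for _, rec_row in sub.sort_values("day_index").iterrows():
            try:
                rec = _load_recording_row(rec_row, datadir)
            except OSError as exc:
                log.warning("subject %s: unreadable recording (%s), skipped", subject_id, exc)
                continue
            recordings.append(rec)
            day_results.append(recording_day_features(rec, config))
        if not day_results or sum(len(df) for df, _ in day_results) == 0:
            log.warning("subject %s dropped: no usable days", subject_id)
            continue
        row = feat.subject_feature_row(day_results)
        _, row["compliance"] = wear_compliance(recordings=recordings)
        row["subject_id"] = subject_id
        first = sub.iloc[0]
        row["group"] = first["group"]
        row["severity"] = first["severity"]
        for col in SCORE_COLS:
            if col in sub.columns:
                row[col] = first[col]
        rows.append(row)
        log.info(
            "extract: subject %s -> %d days, %d windows",
            subject_id,
            len(day_results),
            sum(len(df) for df, _ in day_results),
        )
    table = pd.DataFrame(rows).reset_index(drop=True)
    meta = ["subject_id", "group", "severity", "n_days", "compliance"]
    meta += [c for c in SCORE_COLS if c in table.columns]
    ordered = meta + [c for c in feat.FEATURE_COLUMNS if c in table.columns]
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    table[ordered].to_csv(out_csv, index=False)
    return out_csv


def run_analyze(config: PipelineConfig, feature_csv: Path, outdir: Path) -> dict[str, Path]:
    """Group stats, clinical correlations and LOSO models from a feature table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(feature_csv)
    feature_cols = [c for c in feat.FEATURE_COLUMNS if c in table.columns]
    outputs: dict[str, Path] = {}

    group_counts = table["group"].value_counts()
    usable = set(group_counts[group_counts >= 2].index)  # t-test needs n >= 2 per group
    groups_present = table["group"].nunique()
    if len(usable) >= 2:
        contrasts = tuple((a, b) for a, b in st.DEFAULT_CONTRASTS if {a, b} <= usable)
        stats_df = st.group_stats_table(table, feature_cols, contrasts=contrasts)
        outputs["stats"] = outdir / "group_stats.csv"
        stats_df.to_csv(outputs["stats"], index=False)
        log.info("analyze: %d stats rows", len(stats_df))
    else:
        log.warning("analyze: fewer than 2 groups present, stats skipped")

    report: dict = {"seed": config.seed}
    have_scores = all(c in table.columns and table[c].notna().all() for c in SCORE_COLS)
    if have_scores:
        corr = st.correlation_table(table, feature_cols, list(SCORE_COLS))
        outputs["correlations"] = outdir / "correlations.csv"
        corr.to_csv(outputs["correlations"], index=False)

    if groups_present >= 2:
        preds, clf_report = mdl.loso_evaluate(
            table, feature_cols, "group", "classification", config=config.model
        )
        outputs["class_predictions"] = outdir / "classification_predictions.csv"
        preds.to_csv(outputs["class_predictions"], index=False)
        report["classification"] = clf_report.as_dict()

    if have_scores:
        report["regression"] = {}
        for score in SCORE_COLS:
            preds, reg_report = mdl.loso_evaluate(
                table, feature_cols, score, "regression", config=config.model
            )
            preds.to_csv(outdir / f"regression_predictions_{score}.csv", index=False)
            report["regression"][score] = reg_report.as_dict()
    else:
        log.warning("analyze: clinical scores missing, correlation/regression skipped")

    outputs["model_report"] = outdir / "model_report.json"
    with open(outputs["model_report"], "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return outputs
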