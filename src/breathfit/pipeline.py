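"""End-to-end orchestration: simulate → preprocess → segment → featurize →
evaluate, as one reproducible run driven by a flat YAML config.

A single global seed is expanded into per-stage substreams (simulation,
fold shuffling, SMOTE, model fitting) so one knob reproduces a full run;
every resolved parameter lands in the run manifest alongside software
versions, and re-running from the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .features import build_feature_table
from .io import (
    BreathRecording,
    read_labels,
    read_recording,
    sample_labels,
    write_feature_table,
    write_labels,
    write_recording,
    write_report,
    EvaluationReport,
)
from .modeling import MODEL_FAMILIES, FoldPlan, ModelSpec, evaluate
from .preprocess import PreprocessParams, preprocess_recording
from .segmentation import (
    SegmentationParams,
    WindowParams,
    label_cycles,
    segment_cycles,
    sliding_windows,
)
from .synth import PlanBlock, SynthConfig, SynthDataset, default_session_plan, simulate_cohort

log = logging.getLogger("breathfit")


def _substreams(seed: int, n: int = 4) -> list[int]:
    """Derive n independent 31-bit stage seeds from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source (synthetic XOR files),
    parameter blocks for every stage, a global seed, and an output dir."""

    outdir: str = "breathfit_run"
    seed: int = 0
    synth: SynthConfig | None = None
    recordings: list[str] | None = None  # file paths
    labels_file: str | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    windows: WindowParams = field(default_factory=WindowParams)
    mode: str = "cycles"  # "cycles" | "windows"
    cycle_label_purity: float = 0.8
    model_family: str = "gradient_boosted_trees"
    scheme: str = "loso"
    k: int = 5
    smote: bool = True
    smote_k_neighbors: int = 5
    grid_search: bool = False
    write_recordings: bool = False

    def __post_init__(self) -> None:
        has_files = self.recordings is not None or self.labels_file is not None
        if (self.synth is not None) == has_files:
            raise ConfigError(
                "exactly one input source required: synthetic config XOR input files"
            )
        if has_files and (self.recordings is None or self.labels_file is None):
            raise ConfigError("file input needs both recordings and labels_file")
        if self.mode not in ("cycles", "windows"):
            raise ConfigError(f"mode must be 'cycles' or 'windows', got {self.mode!r}")
        if self.model_family not in MODEL_FAMILIES:
            raise ConfigError(f"model_family must be one of {MODEL_FAMILIES}")
        if self.scheme not in ("kfold", "loso"):
            raise ConfigError(f"scheme must be 'kfold' or 'loso', got {self.scheme!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synth" in kwargs and kwargs["synth"] is not None:
            synth = dict(kwargs["synth"])
            if "session_plan" in synth:
                synth["session_plan"] = tuple(
                    PlanBlock(**blk) for blk in synth["session_plan"]
                )
            kwargs["synth"] = SynthConfig(**synth)
        for key, typ in (
            ("preprocess", PreprocessParams),
            ("segmentation", SegmentationParams),
            ("windows", WindowParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def resolved_dict(self) -> dict:
        """Every tunable parameter, JSON-serializable, for the manifest."""
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "mode": self.mode,
            "cycle_label_purity": self.cycle_label_purity,
            "model_family": self.model_family,
            "scheme": self.scheme,
            "k": self.k,
            "smote": self.smote,
            "smote_k_neighbors": self.smote_k_neighbors,
            "grid_search": self.grid_search,
            "preprocess": asdict(self.preprocess),
            "segmentation": asdict(self.segmentation),
            "windows": asdict(self.windows),
        }
        if self.synth is not None:
            s = asdict(self.synth)
            s["session_plan"] = [asdict(b) for b in self.synth.session_plan]
            s["drift_sd"] = dict(self.synth.drift_sd)
            s["noise_sd"] = dict(self.synth.noise_sd)
            d["synth"] = s
        else:
            d["recordings"] = list(self.recordings)
            d["labels_file"] = self.labels_file
        return d


def _load_dataset(cfg: RunConfig, sim_seed: int) -> SynthDataset | tuple:
    if cfg.synth is not None:
        synth = SynthConfig(**{**_synth_kwargs(cfg.synth), "seed": sim_seed})
        log.info("simulating %d subjects (%.0f s sessions)", synth.n_subjects,
                 synth.total_duration_s)
        return simulate_cohort(synth)
    recs = [read_recording(p) for p in cfg.recordings]
    all_labels = read_labels(cfg.labels_file)
    labels = []
    for rec in recs:
        labels.append(
            [s for s in all_labels if s.session_id == rec.session_id
             and s.subject_id == rec.subject_id]
        )
    return SynthDataset(recordings=recs, labels=labels, truths=[], config=None)


def _synth_kwargs(synth: SynthConfig) -> dict:
    return {
        "n_subjects": synth.n_subjects,
        "session_plan": synth.session_plan,
        "fs": synth.fs,
        "rate_range_bpm": synth.rate_range_bpm,
        "insp_fraction_mean": synth.insp_fraction_mean,
        "insp_fraction_sd": synth.insp_fraction_sd,
        "cycle_jitter_cv": synth.cycle_jitter_cv,
        "pressure_amp_hpa": synth.pressure_amp_hpa,
        "pressure_baseline_hpa": synth.pressure_baseline_hpa,
        "temp_baseline_c": synth.temp_baseline_c,
        "temp_exhale_c": synth.temp_exhale_c,
        "rh_baseline": synth.rh_baseline,
        "rh_exhale": synth.rh_exhale,
        "microclimate_tau_s": synth.microclimate_tau_s,
        "drift_sd": dict(synth.drift_sd),
        "noise_sd": dict(synth.noise_sd),
        "phase_noise_sd_s": synth.phase_noise_sd_s,
        "amp_subject_cv": synth.amp_subject_cv,
        "seed": synth.seed,
    }


def build_table(dataset: SynthDataset, cfg: RunConfig, mode: str) -> pd.DataFrame:
    """Preprocess, segment and featurize every session of a dataset."""
    segments = []
    for rec, segs in zip(dataset.recordings, dataset.labels):
        track = sample_labels(rec, segs)
        pp = preprocess_recording(rec, cfg.preprocess)
        if mode == "cycles":
            cycles = segment_cycles(pp, cfg.segmentation)
            segments.extend(label_cycles(cycles, track, purity=cfg.cycle_label_purity))
        else:
            segments.extend(sliding_windows(pp, track, cfg.windows))
    log.info("%s mode: %d labelled segments", mode, len(segments))
    window_samples = int(round(cfg.windows.window_s * dataset.recordings[0].fs))
    return build_feature_table(segments, mode, window_samples=window_samples)


def run_pipeline(cfg: RunConfig) -> tuple[EvaluationReport, dict[str, Path]]:
    """Execute one full run; returns the report and the artifact paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed, fold_seed, model_seed, _ = _substreams(cfg.seed)

    dataset = _load_dataset(cfg, sim_seed)
    artifacts: dict[str, Path] = {}

    if cfg.synth is not None and cfg.write_recordings:
        rec_dir = outdir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec, segs in zip(dataset.recordings, dataset.labels):
            write_recording(rec, rec_dir / f"{rec.subject_id}.csv")
        flat = [s for segs in dataset.labels for s in segs]
        write_labels(flat, outdir / "labels.csv")
        artifacts["recordings"] = rec_dir
        artifacts["labels"] = outdir / "labels.csv"

    table = build_table(dataset, cfg, cfg.mode)
    log.info("feature table: %d rows x %d columns", *table.shape)
    features_path = outdir / "features.csv"
    write_feature_table(table, features_path)
    artifacts["features"] = features_path

    spec = ModelSpec(family=cfg.model_family, seed=model_seed)
    plan = FoldPlan(scheme=cfg.scheme, k=cfg.k, seed=fold_seed)
    report = evaluate(
        table,
        spec,
        plan,
        smote=cfg.smote,
        k_neighbors=cfg.smote_k_neighbors,
        search=cfg.grid_search,
        segmentation_mode=cfg.mode,
    )
    log.info(
        "%s/%s/%s: F1 = %.4f ± %.4f over %d folds",
        cfg.model_family, cfg.scheme, cfg.mode,
        report.f1_mean, report.f1_sd, len(report.folds),
    )
    report_path = outdir / "report.json"
    write_report(report, report_path)
    artifacts["report"] = report_path

    manifest = {
        "config": cfg.resolved_dict(),
        "stage_seeds": {
            "simulate": sim_seed,
            "folds": fold_seed,
            "model": model_seed,
        },
        "versions": _versions(),
        "n_feature_rows": int(len(table)),
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = manifest_path
    return report, artifacts


def _versions() -> dict:
    import scipy
    import sklearn
    import xgboost

    return {
        "breathfit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def compare_strategies(cfg: RunConfig) -> pd.DataFrame:
    """The full model × segmentation × scheme comparison grid.

    Evaluates all three model families under both segmentation strategies
    and both validation schemes on one dataset (12 cells), reporting mean ±
    SD of per-fold F1 per cell and flagging any cell where the cycle-based
    mean falls below its sliding-window counterpart.
    """
    sim_seed, fold_seed, model_seed, _ = _substreams(cfg.seed)
    dataset = _load_dataset(cfg, sim_seed)
    tables = {mode: build_table(dataset, cfg, mode) for mode in ("cycles", "windows")}
    rows = []
    for family in MODEL_FAMILIES:
        for scheme in ("kfold", "loso"):
            cell = {"model": family, "scheme": scheme}
            for mode in ("cycles", "windows"):
                rep = evaluate(
                    tables[mode],
                    ModelSpec(family=family, seed=model_seed),
                    FoldPlan(scheme=scheme, k=cfg.k, seed=fold_seed),
                    smote=cfg.smote,
                    k_neighbors=cfg.smote_k_neighbors,
                    search=cfg.grid_search,
                    segmentation_mode=mode,
                )
                cell[f"{mode}_f1_mean"] = rep.f1_mean
                cell[f"{mode}_f1_sd"] = rep.f1_sd
            cell["cycle_below_window"] = cell["cycles_f1_mean"] < cell["windows_f1_mean"]
            log.info(
                "%s/%s: cycles %.4f±%.4f  windows %.4f±%.4f",
                family, scheme,
                cell["cycles_f1_mean"], cell["cycles_f1_sd"],
                cell["windows_f1_mean"], cell["windows_f1_sd"],
            )
            rows.append(cell)
    return pd.DataFrame(rows)


def format_comparison(df: pd.DataFrame) -> str:
    """Human-readable comparison table (percent F1, mean ± SD)."""
    lines = [f"{'Model':<24}{'Validation':<12}{'Sliding Window':>20}{'Cycle-Based':>20}"]
    for row in df.itertuples():
        sw = f"{100 * row.windows_f1_mean:.2f} ± {100 * row.windows_f1_sd:.2f}"
        cb = f"{100 * row.cycles_f1_mean:.2f} ± {100 * row.cycles_f1_sd:.2f}"
        flag = "  (!)" if row.cycle_below_window else ""
        lines.append(f"{row.model:<24}{row.scheme:<12}{sw:>20}{cb:>20}{flag}")
    return "\n".join(lines)
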