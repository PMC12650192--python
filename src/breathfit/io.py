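"""Data model and delimited-text I/O for intra-mask breathing data.

A recording is one session's synchronized pressure / temperature / relative
humidity series sampled at a fixed rate (10 Hz on the target hardware).
Label segments tag half-open time intervals ``[start_s, end_s)`` with a fit
condition drawn from the closed vocabulary ``{fit, poor_fit, other}``.

All on-disk formats are plain CSV (UTF-8, "." decimal, LF):

* recording:      ``time_s,pressure_hpa,temperature_c,humidity_rh``
* labels:         ``subject_id,session_id,start_s,end_s,label,condition``
* feature table:  ``subject_id,session_id,provenance,label,<feature columns>``
* report:         JSON document holding the :class:`EvaluationReport` fields
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DataError,
    FormatError,
    IntervalError,
    SchemaError,
    VocabularyError,
)

#: Closed label vocabulary.
LABELS = ("fit", "poor_fit", "other")

#: Canonical recording CSV columns, in order.
RECORDING_COLUMNS = ("time_s", "pressure_hpa", "temperature_c", "humidity_rh")

#: Canonical labels CSV columns, in order.
LABEL_COLUMNS = ("subject_id", "session_id", "start_s", "end_s", "label", "condition")

#: Channel names in canonical order (matches the sensor's reporting order).
CHANNELS = ("pressure", "humidity", "temperature")


@dataclass
class BreathRecording:
    """One session's synchronized tri-channel series at a fixed sampling rate.

    Parameters
    ----------
    subject_id, session_id
        Provenance identifiers.
    fs
        Sampling rate in Hz (10 for the target hardware).
    t0
        Session start time in seconds; sample ``i`` covers time ``t0 + i/fs``.
    pressure, temperature, humidity
        Equal-length series in hPa, °C and %RH respectively.
    preprocessed
        Set by the preprocessing stage; downstream stages that require
        filtered/standardized input check this flag.
    """

    subject_id: str
    session_id: str
    pressure: np.ndarray
    temperature: np.ndarray
    humidity: np.ndarray
    fs: float = 10.0
    t0: float = 0.0
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.humidity = np.asarray(self.humidity, dtype=float)
        n = len(self.pressure)
        if n < 1 or len(self.temperature) != n or len(self.humidity) != n:
            raise DataError(
                "pressure/temperature/humidity must have equal length >= 1 "
                f"(got {len(self.pressure)}/{len(self.temperature)}/{len(self.humidity)})"
            )
        if not self.fs > 0:
            raise DataError(f"fs must be positive, got {self.fs}")
        for name in CHANNELS:
            if not np.all(np.isfinite(self.channel(name))):
                raise DataError(f"channel {name!r} contains NaN/inf values")

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's series by name ('pressure'|'humidity'|'temperature')."""
        if name not in CHANNELS:
            raise SchemaError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return len(self.pressure)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from ``t0``."""
        return np.arange(self.n_samples) / self.fs

    def with_channels(self, pressure, temperature, humidity, *, preprocessed=None):
        """Copy with replaced series (used by the preprocessing stage)."""
        return replace(
            self,
            pressure=np.asarray(pressure, dtype=float),
            temperature=np.asarray(temperature, dtype=float),
            humidity=np.asarray(humidity, dtype=float),
            preprocessed=self.preprocessed if preprocessed is None else preprocessed,
        )


@dataclass(frozen=True)
class LabelSegment:
    """A half-open labelled time interval ``[start_s, end_s)`` within a session."""

    start_s: float
    end_s: float
    label: str
    condition: str = ""
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise VocabularyError(
                f"label {self.label!r} not in closed vocabulary {LABELS}"
            )
        if not (0 <= self.start_s < self.end_s):
            raise IntervalError(
                f"require 0 <= start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _check_no_overlap(segments: Sequence[LabelSegment]) -> None:
    by_session: dict[tuple[str, str], list[LabelSegment]] = {}
    for seg in segments:
        by_session.setdefault((seg.subject_id, seg.session_id), []).append(seg)
    for key, segs in by_session.items():
        segs = sorted(segs, key=lambda s: s.start_s)
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ConsistencyError(
                    f"overlapping segments in session {key}: "
                    f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )


def read_recording(
    path,
    schema: Mapping[str, str] | None = None,
    declared_fs: float | None = None,
) -> BreathRecording:
    """Read a recording CSV, validating time-base uniformity.

    Parameters
    ----------
    path
        Delimited text file with a header naming time, pressure, temperature
        and humidity columns.
    schema
        Optional map from canonical column names (``time_s`` etc.) to the
        file's column names, for foreign files.
    declared_fs
        If given, the sampling rate inferred from the median time step must
        agree with it within 1%.

    Raises
    ------
    SchemaError
        A required column is missing.
    FormatError
        Time steps deviate from the median step by more than 1%, or the
        inferred rate disagrees with ``declared_fs``.
    DataError
        NaN cells.
    """
    colmap = {c: c for c in RECORDING_COLUMNS}
    if schema:
        colmap.update(schema)
    # round_trip parsing: repr-written floats must come back bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [colmap[c] for c in RECORDING_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    sub = df[[colmap[c] for c in RECORDING_COLUMNS]]
    if sub.isna().any().any():
        raise DataError(f"{path}: NaN cells present; gaps are an error")
    t = sub[colmap["time_s"]].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise FormatError(f"{path}: time column must be strictly increasing")
    if np.any(np.abs(dt - step) > 0.01 * step):
        raise FormatError(
            f"{path}: non-uniform time step (median {step:g} s, "
            f"max deviation {np.max(np.abs(dt - step)):g} s > 1%)"
        )
    fs = 1.0 / step
    if declared_fs is not None and abs(fs - declared_fs) > 0.01 * declared_fs:
        raise FormatError(
            f"{path}: inferred fs {fs:g} Hz disagrees with declared {declared_fs:g} Hz"
        )
    name = str(path)
    stem = name.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return BreathRecording(
        subject_id=stem,
        session_id=stem,
        pressure=sub[colmap["pressure_hpa"]].to_numpy(dtype=float),
        temperature=sub[colmap["temperature_c"]].to_numpy(dtype=float),
        humidity=sub[colmap["humidity_rh"]].to_numpy(dtype=float),
        fs=fs,
        t0=float(t[0]),
    )


def write_recording(rec: BreathRecording, path) -> None:
    """Write a recording to canonical CSV at full float precision (round-trip exact)."""
    df = pd.DataFrame(
        {
            "time_s": rec.t0 + rec.times(),
            "pressure_hpa": rec.pressure,
            "temperature_c": rec.temperature,
            "humidity_rh": rec.humidity,
        }
    )
    # pandas writes repr(float): shortest exact round-trip representation
    df.to_csv(path, index=False, lineterminator="\n")


def read_labels(path) -> list[LabelSegment]:
    """Read a labels CSV; returns segments sorted by (subject, session, start_s).

    Raises
    ------
    VocabularyError / IntervalError
        Propagated from segment validation.
    ConsistencyError
        Overlapping segments within one session.
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    segments = [
        LabelSegment(
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            label=str(row.label),
            condition=str(row.condition),
            subject_id=str(row.subject_id),
            session_id=str(row.session_id),
        )
        for row in df.itertuples()
    ]
    _check_no_overlap(segments)
    segments.sort(key=lambda s: (s.subject_id, s.session_id, s.start_s))
    return segments


def write_labels(segments: Sequence[LabelSegment], path) -> None:
    """Write label segments to canonical CSV."""
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "session_id": s.session_id,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "label": s.label,
                "condition": s.condition,
            }
            for s in segments
        ],
        columns=list(LABEL_COLUMNS),
    )
    df.to_csv(path, index=False, lineterminator="\n")


def sample_labels(rec: BreathRecording, segments: Sequence[LabelSegment]) -> np.ndarray:
    """Per-sample label track for a recording.

    Sample ``i`` (at time ``i/fs`` from session start) takes the label of the
    enclosing half-open segment ``[start_s, end_s)``, or ``"other"`` where no
    segment covers it.
    """
    _check_no_overlap(segments)
    track = np.full(rec.n_samples, "other", dtype=object)
    for seg in segments:
        i0 = int(np.ceil(seg.start_s * rec.fs - 1e-9))
        i1 = int(np.ceil(seg.end_s * rec.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, rec.n_samples)
        if i1 > i0:
            track[i0:i1] = seg.label
    return track


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

#: Non-feature metadata columns of a feature table, in order.
META_COLUMNS = ("subject_id", "session_id", "provenance", "label")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV (metadata columns first, features after)."""
    table.to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV, validating the schema.

    The table must carry the four metadata columns followed by exactly the
    22-name cycle schema or the 18-name window schema, and no ``other`` rows.
    """
    from .features import CYCLE_FEATURE_NAMES, WINDOW_FEATURE_NAMES

    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing metadata column(s) {missing}")
    feats = [c for c in df.columns if c not in META_COLUMNS]
    if feats != list(CYCLE_FEATURE_NAMES) and feats != list(WINDOW_FEATURE_NAMES):
        raise SchemaError(
            f"{path}: feature columns match neither the 22-name cycle schema "
            f"nor the 18-name window schema (got {len(feats)} columns)"
        )
    if (df["label"] == "other").any():
        raise VocabularyError(f"{path}: feature tables must not contain 'other' rows")
    for c in feats:
        df[c] = pd.to_numeric(df[c])
    return df


# ---------------------------------------------------------------------------
# Evaluation reports
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    """Metrics for one cross-validation fold.

    ``confusion`` is a 2×2 integer matrix with rows = true (poor_fit, fit)
    and columns = predicted (poor_fit, fit).  ``roc_auc`` is None when the
    test fold contains a single class (AUC undefined).
    """

    fold_id: str
    test_subjects: list[str]
    test_size: int
    f1: float
    roc_auc: float | None
    confusion: list[list[int]]

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion)
        if cm.shape != (2, 2) or np.any(cm < 0):
            raise DataError("confusion matrix must be 2x2 non-negative")
        if int(cm.sum()) != self.test_size:
            raise DataError(
                f"confusion entries sum to {int(cm.sum())} != test size {self.test_size}"
            )
        if not (0.0 <= self.f1 <= 1.0):
            raise DataError(f"F1 out of range: {self.f1}")
        if self.roc_auc is not None and not (0.0 <= self.roc_auc <= 1.0):
            raise DataError(f"ROC-AUC out of range: {self.roc_auc}")


@dataclass
class EvaluationReport:
    """Cross-validated evaluation of one model/segmentation configuration."""

    scheme: str  # "kfold" | "loso"
    folds: list[FoldResult]
    f1_mean: float
    f1_sd: float
    pooled_confusion: list[list[int]]
    model_family: str
    hyperparameters: dict
    seed: int
    segmentation_mode: str = ""

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "segmentation_mode": self.segmentation_mode,
            "model_family": self.model_family,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "summary": {"f1_mean": self.f1_mean, "f1_sd": self.f1_sd},
            "pooled_confusion": self.pooled_confusion,
            "folds": [
                {
                    "fold_id": f.fold_id,
                    "test_subjects": f.test_subjects,
                    "test_size": f.test_size,
                    "f1": f.f1,
                    "roc_auc": f.roc_auc,
                    "confusion": f.confusion,
                }
                for f in self.folds
            ],
        }


def write_report(report: EvaluationReport, path) -> None:
    """Write an evaluation report as a JSON document."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> EvaluationReport:
    """Read an evaluation report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return EvaluationReport(
        scheme=d["scheme"],
        folds=[
            FoldResult(
                fold_id=f["fold_id"],
                test_subjects=list(f["test_subjects"]),
                test_size=f["test_size"],
                f1=f["f1"],
                roc_auc=f["roc_auc"],
                confusion=f["confusion"],
            )
            for f in d["folds"]
        ],
        f1_mean=d["summary"]["f1_mean"],
        f1_sd=d["summary"]["f1_sd"],
        pooled_confusion=d["pooled_confusion"],
        model_family=d["model_family"],
        hyperparameters=d["hyperparameters"],
        seed=d["seed"],
        segmentation_mode=d.get("segmentation_mode", ""),
    )
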