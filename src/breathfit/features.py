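"""Per-cycle and per-window feature extraction from tri-channel segments.

The cycle schema holds 22 named features per breathing cycle:

* 1 temporal ratio — the inspiratory time proportion ``delta_insp`` (stored
  as a fraction in (0, 1); the expiratory proportion is its complement and
  is deliberately not stored — it would be perfectly collinear);
* 3 peak-to-peak amplitudes (max − min over the cycle, per channel);
* 6 per-phase means (inspiratory and expiratory mean per channel);
* 3 standard deviations, 3 skewnesses, 3 excess kurtoses, 3 medians.

Channels are ordered pressure, humidity, temperature throughout.  Moment
conventions are fixed for reproducibility: population SD, Fisher–Pearson
standardized third moment for skewness, excess kurtosis (normal → 0), both
bias-uncorrected.

The window schema (18 features) drops the phase-based quantities — an
arbitrary 5 s window has no reliable phase boundary — and keeps per-channel
peak-to-peak, whole-window mean, SD, skewness, kurtosis and median.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, EmptyTableError, LengthError
from .io import CHANNELS, META_COLUMNS
from .segmentation import BreathCycle, CycleSegment, WindowSegment


def _schema(prefixes: Sequence[str]) -> tuple[str, ...]:
    return tuple(f"{p}_{c}" for p in prefixes for c in CHANNELS)


#: Canonical ordered 22-name cycle feature schema.
CYCLE_FEATURE_NAMES: tuple[str, ...] = (
    ("insp_time_prop",)
    + _schema(("ptp",))
    + _schema(("mean_insp", "mean_exp"))
    + _schema(("sd", "skew", "kurt", "median"))
)

#: Canonical ordered 18-name window feature schema.
WINDOW_FEATURE_NAMES: tuple[str, ...] = _schema(
    ("ptp", "mean", "sd", "skew", "kurt", "median")
)

assert len(CYCLE_FEATURE_NAMES) == 22
assert len(WINDOW_FEATURE_NAMES) == 18


def _channel_stats(x: np.ndarray, name: str) -> dict[str, float]:
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError(
            f"constant-valued {name} slice: skewness/kurtosis undefined"
        )
    return {
        "ptp": float(np.ptp(x)),
        "sd": float(np.std(x)),
        "skew": float(stats.skew(x, bias=True)),
        "kurt": float(stats.kurtosis(x, fisher=True, bias=True)),
        "median": float(np.median(x)),
    }


def extract_cycle_features(
    cycle: BreathCycle,
    slices: Mapping[str, np.ndarray],
    swap_phases: bool = False,
) -> dict[str, float]:
    """Compute the 22 named cycle features from aligned tri-channel slices.

    ``slices`` maps channel name to the inclusive ``[p_initial, p_final]``
    slice; the inspiratory sub-slice is ``[p_initial, v]`` and the
    expiratory sub-slice ``[v, p_final]`` (both inclusive, sharing the
    valley sample), flipped when ``swap_phases`` is set.

    Raises
    ------
    LengthError
        Any slice shorter than 3 samples or mismatched with the cycle span.
    DegenerateSignalError
        A constant-valued slice (higher moments undefined).
    """
    span = cycle.p_final - cycle.p_initial + 1
    v_rel = cycle.v - cycle.p_initial
    for name in CHANNELS:
        x = np.asarray(slices[name], dtype=float)
        if len(x) < 3:
            raise LengthError(f"degenerate cycle: {name} slice has {len(x)} samples")
        if len(x) != span:
            raise LengthError(
                f"{name} slice length {len(x)} does not match cycle span {span}"
            )

    delta = cycle.delta_exp if swap_phases else cycle.delta_insp
    out: dict[str, float] = {"insp_time_prop": float(delta)}

    per_channel = {}
    for name in CHANNELS:
        x = np.asarray(slices[name], dtype=float)
        per_channel[name] = _channel_stats(x, name)
        first, second = x[: v_rel + 1], x[v_rel:]
        insp, exp = (second, first) if swap_phases else (first, second)
        per_channel[name]["mean_insp"] = float(np.mean(insp))
        per_channel[name]["mean_exp"] = float(np.mean(exp))

    for feat in ("ptp",):
        for name in CHANNELS:
            out[f"{feat}_{name}"] = per_channel[name][feat]
    for feat in ("mean_insp", "mean_exp"):
        for name in CHANNELS:
            out[f"{feat}_{name}"] = per_channel[name][feat]
    for feat in ("sd", "skew", "kurt", "median"):
        for name in CHANNELS:
            out[f"{feat}_{name}"] = per_channel[name][feat]
    assert tuple(out) == CYCLE_FEATURE_NAMES
    return out


def extract_window_features(
    slices: Mapping[str, np.ndarray], n_samples: int = 50
) -> dict[str, float]:
    """Compute the 18 named window features from a fixed-length tri-channel
    window (default 50 samples = 5 s at 10 Hz).

    Raises
    ------
    LengthError
        A slice whose length differs from ``n_samples``.
    DegenerateSignalError
        A constant-valued slice.
    """
    per_channel = {}
    for name in CHANNELS:
        x = np.asarray(slices[name], dtype=float)
        if len(x) != n_samples:
            raise LengthError(
                f"{name} window has {len(x)} samples, expected {n_samples}"
            )
        per_channel[name] = _channel_stats(x, name)
        per_channel[name]["mean"] = float(np.mean(x))

    out: dict[str, float] = {}
    for feat in ("ptp", "mean", "sd", "skew", "kurt", "median"):
        for name in CHANNELS:
            out[f"{feat}_{name}"] = per_channel[name][feat]
    assert tuple(out) == WINDOW_FEATURE_NAMES
    return out


def build_feature_table(
    segments: Sequence[CycleSegment | WindowSegment],
    mode: str,
    window_samples: int = 50,
) -> pd.DataFrame:
    """Assemble labelled segments into the canonical feature table.

    One row per retained segment, carrying subject/session provenance;
    unlabelled and ``other``-labelled segments are excluded, and segments
    with degenerate (constant) slices are skipped.

    Raises
    ------
    EmptyTableError
        No rows survive filtering.
    """
    if mode not in ("cycles", "windows"):
        raise ValueError(f"mode must be 'cycles' or 'windows', got {mode!r}")
    rows = []
    for seg in segments:
        if seg.label is None or seg.label == "other":
            continue
        try:
            if mode == "cycles":
                feats = extract_cycle_features(
                    seg.cycle, seg.slices, swap_phases=getattr(seg, "swap_phases", False)
                )
            else:
                feats = extract_window_features(seg.slices, n_samples=window_samples)
        except DegenerateSignalError:
            continue
        rows.append(
            {
                "subject_id": seg.subject_id,
                "session_id": seg.session_id,
                "provenance": seg.provenance,
                "label": seg.label,
                **feats,
            }
        )
    if not rows:
        raise EmptyTableError("no labelled, non-degenerate segments to tabulate")
    names = CYCLE_FEATURE_NAMES if mode == "cycles" else WINDOW_FEATURE_NAMES
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(names))


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature table into (X, y, subjects) arrays for modeling."""
    names = [c for c in table.columns if c not in META_COLUMNS]
    X = table[names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=object)
    subjects = table["subject_id"].to_numpy(dtype=object)
    return X, y, subjects
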