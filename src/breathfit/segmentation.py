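"""Breathing-cycle segmentation and the fixed-length sliding-window alternative.

A breathing cycle is a validated peak–valley–peak triplet detected on the
preprocessed temperature channel (the anchor): the dead-space temperature
peaks at the end of each exhalation, decays while cool ambient air is drawn
in, and bottoms out at the inspiration→expiration turn.  The triplet
``[p_initial, v, p_final]`` gives

    t_cycle   = (p_final - p_initial) / fs
    delta_insp = (v - p_initial) / (p_final - p_initial)
    delta_exp  = (p_final - v) / (p_final - p_initial)

so ``delta_insp + delta_exp == 1`` identically.  The same index bounds are
applied to the pressure and humidity channels, keeping the three modalities
aligned per cycle.

Extremum detection enforces a minimum peak distance (mpd, default 23 samples
= 2.3 s at 10 Hz, i.e. a 26 BPM ceiling): strict local extrema are found
(plateaus resolve to their first index) and then greedily thinned
highest-amplitude-first so that any two retained extrema are >= mpd samples
apart, ties broken toward the earlier index.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError, LengthError
from .io import CHANNELS, BreathRecording


@dataclass(frozen=True)
class BreathCycle:
    """A validated peak–valley–peak index triplet with derived timing fields."""

    p_initial: int
    v: int
    p_final: int
    fs: float

    def __post_init__(self) -> None:
        if not (self.p_initial < self.v < self.p_final):
            raise ConfigError(
                f"require p_initial < v < p_final, got "
                f"({self.p_initial}, {self.v}, {self.p_final})"
            )
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")

    @property
    def t_cycle_s(self) -> float:
        return (self.p_final - self.p_initial) / self.fs

    @property
    def delta_insp(self) -> float:
        return (self.v - self.p_initial) / (self.p_final - self.p_initial)

    @property
    def delta_exp(self) -> float:
        return (self.p_final - self.v) / (self.p_final - self.p_initial)


@dataclass(frozen=True)
class SegmentationParams:
    """Cycle-detection parameters: minimum peak distance (samples) and anchor
    channel.  ``per_segment_zscore`` re-standardizes each extracted slice
    (off by default — the session-level z-score is canonical).
    ``swap_phases`` flips the inspiration/expiration reading of the triplet."""

    mpd: int = 23
    anchor_channel: str = "temperature"
    per_segment_zscore: bool = False
    swap_phases: bool = False

    def __post_init__(self) -> None:
        if self.mpd < 1:
            raise ConfigError(f"mpd must be >= 1, got {self.mpd}")
        if self.anchor_channel not in CHANNELS:
            raise ConfigError(f"anchor_channel must be one of {CHANNELS}")


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window parameters: 5 s windows with 2 s overlap by default
    (50 samples / step 30 at 10 Hz); a window keeps the majority label only
    if its purity is >= ``label_purity``."""

    window_s: float = 5.0
    overlap_s: float = 2.0
    label_purity: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.window_s):
            raise ConfigError(
                f"require 0 <= overlap_s < window_s, got "
                f"({self.overlap_s}, {self.window_s})"
            )
        if not (0 < self.label_purity <= 1):
            raise ConfigError(f"label_purity must be in (0, 1], got {self.label_purity}")


@dataclass
class CycleSegment:
    """A detected cycle with its aligned tri-channel slices (inclusive bounds)."""

    cycle: BreathCycle
    slices: dict[str, np.ndarray]
    label: str | None = None
    subject_id: str = ""
    session_id: str = ""
    #: when True the valley→p_final limb is read as inspiration
    swap_phases: bool = False

    @property
    def provenance(self) -> str:
        c = self.cycle
        return f"cycle[{c.p_initial}:{c.v}:{c.p_final}]"


@dataclass
class WindowSegment:
    """A fixed-length window with its tri-channel slices and majority label."""

    start: int
    length: int
    slices: dict[str, np.ndarray]
    label: str | None = None
    subject_id: str = ""
    session_id: str = ""

    @property
    def provenance(self) -> str:
        return f"window[{self.start}:{self.start + self.length}]"


# ---------------------------------------------------------------------------
# Extremum detection
# ---------------------------------------------------------------------------


def _strict_local_maxima(x: np.ndarray) -> np.ndarray:
    """First indices of strict local maxima (plateaus resolve to their first
    sample; endpoints never qualify)."""
    if len(x) < 3:
        return np.asarray([], dtype=int)
    _, props = find_peaks(x, plateau_size=(1, None))
    return props["left_edges"].astype(int)


def _greedy_mpd(candidates: np.ndarray, heights: np.ndarray, mpd: int) -> np.ndarray:
    """Greedy minimum-distance thinning: largest amplitude first, ties to the
    earlier index; a candidate is kept iff it is >= mpd samples from every
    already-kept extremum.  Returns kept indices sorted ascending."""
    order = np.lexsort((candidates, -heights))  # by (-height, index)
    kept: list[int] = []
    for j in order:
        idx = int(candidates[j])
        if all(abs(idx - k) >= mpd for k in kept):
            kept.append(idx)
    return np.asarray(sorted(kept), dtype=int)


def detect_extrema(x: np.ndarray, mpd: int) -> tuple[np.ndarray, np.ndarray]:
    """Locate local maxima and minima separated by at least ``mpd`` samples.

    Returns ``(peak_indices, valley_indices)``, each sorted ascending; either
    may be empty (e.g. on monotonic input).  Valleys are detected on the
    inverted signal with the same mpd.
    """
    x = np.asarray(x, dtype=float)
    if mpd < 1:
        raise ConfigError(f"mpd must be >= 1, got {mpd}")
    peaks = _strict_local_maxima(x)
    valleys = _strict_local_maxima(-x)
    peaks = _greedy_mpd(peaks, x[peaks], mpd) if len(peaks) else peaks
    valleys = _greedy_mpd(valleys, -x[valleys], mpd) if len(valleys) else valleys
    return peaks, valleys


# ---------------------------------------------------------------------------
# Cycle construction
# ---------------------------------------------------------------------------


def build_cycles(
    peaks: Sequence[int], valleys: Sequence[int], fs: float
) -> list[BreathCycle]:
    """Assemble validated peak–valley–peak cycles.

    Valleys outside the span of the detected peaks are dropped; a cycle is
    emitted for a consecutive peak pair iff exactly one retained valley lies
    strictly between them (intervals with zero or multiple valleys are
    discarded as artefacts or incomplete cycles).  Adjacent cycles share
    their boundary peak.
    """
    peaks = np.asarray(peaks, dtype=int)
    valleys = np.asarray(valleys, dtype=int)
    if len(peaks) < 2:
        return []
    valleys = valleys[(valleys > peaks[0]) & (valleys < peaks[-1])]
    cycles = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        inside = valleys[(valleys > p0) & (valleys < p1)]
        if len(inside) == 1:
            cycles.append(BreathCycle(int(p0), int(inside[0]), int(p1), fs))
    return cycles


def segment_cycles(
    rec: BreathRecording, p: SegmentationParams = SegmentationParams()
) -> list[CycleSegment]:
    """Detect cycles on the anchor channel and slice all three channels at the
    same inclusive ``[p_initial, p_final]`` bounds."""
    anchor = rec.channel(p.anchor_channel)
    peaks, valleys = detect_extrema(anchor, p.mpd)
    cycles = build_cycles(peaks, valleys, rec.fs)
    segments = []
    for cyc in cycles:
        sl = {
            name: rec.channel(name)[cyc.p_initial : cyc.p_final + 1].copy()
            for name in CHANNELS
        }
        if p.per_segment_zscore:
            from .preprocess import zscore

            sl = {name: zscore(v) for name, v in sl.items()}
        segments.append(
            CycleSegment(
                cycle=cyc,
                slices=sl,
                subject_id=rec.subject_id,
                session_id=rec.session_id,
                swap_phases=p.swap_phases,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------


def _majority(track_slice: np.ndarray) -> tuple[str, float]:
    counts = Counter(track_slice.tolist())
    label, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return label, n / len(track_slice)


def label_cycles(
    segments: Sequence[CycleSegment],
    label_track: np.ndarray,
    purity: float = 0.8,
) -> list[CycleSegment]:
    """Assign each cycle the majority label over its inclusive span; cycles
    whose purity falls below ``purity`` or whose majority is ``other`` are
    discarded (transition spans have no defensible single label)."""
    kept = []
    for seg in segments:
        c = seg.cycle
        label, frac = _majority(label_track[c.p_initial : c.p_final + 1])
        if label != "other" and frac >= purity:
            seg.label = label
            kept.append(seg)
    return kept


def sliding_windows(
    rec: BreathRecording,
    label_track: np.ndarray,
    p: WindowParams = WindowParams(),
) -> list[WindowSegment]:
    """Fixed-length overlapping windows with purity-filtered majority labels.

    Step = ``window_s - overlap_s`` (3 s = 30 samples by default), so a
    series of N samples yields ``floor((N - W)/S) + 1`` candidate windows;
    windows with purity below threshold or majority ``other`` are discarded.
    """
    w = int(round(p.window_s * rec.fs))
    s = int(round((p.window_s - p.overlap_s) * rec.fs))
    n = rec.n_samples
    if w > n:
        raise LengthError(f"window of {w} samples exceeds series length {n}")
    if len(label_track) != n:
        raise LengthError("label track length must equal series length")
    out = []
    for start in range(0, n - w + 1, s):
        label, frac = _majority(np.asarray(label_track[start : start + w]))
        if label == "other" or frac < p.label_purity:
            continue
        out.append(
            WindowSegment(
                start=start,
                length=w,
                slices={
                    name: rec.channel(name)[start : start + w].copy()
                    for name in CHANNELS
                },
                label=label,
                subject_id=rec.subject_id,
                session_id=rec.session_id,
            )
        )
    return out
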