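"""Physics-informed synthetic intra-mask recordings.

The generator emulates the mechanistic signal structure of breathing inside a
tight-fitting half-facepiece respirator carrying a pressure/temperature/
humidity sensor in its dead space:

* **Pressure** — sub-ambient during inhalation (flow drawn through the
  filter), supra-ambient during exhalation; modelled as raised-cosine humps
  of amplitude ``A = pressure_amp_hpa * (1 - leak)`` around an ambient
  baseline.  A leak vents flow through unintended paths and attenuates the
  oscillation multiplicatively.
* **Temperature / humidity** — exhaled air is warm (≈31–35 °C) and nearly
  saturated, so the dead-space microclimate relaxes first-order toward the
  exhalation targets during expiration and back toward ambient during
  inspiration.  A leak scales the exhalation increment by ``(1 - leak)`` and
  adds inter-channel timing jitter (decorrelation).
* Cycles run at a subject-specific rate drawn from ``rate_range_bpm`` with
  per-cycle period jitter; the inspiratory fraction of each cycle is drawn
  from a truncated normal.  Slow random-walk drift and white sensor noise are
  added per channel.

Each cycle starts at inspiration onset, which is where the temperature trace
peaks (end of the previous exhalation) — the anchor-channel geometry the
segmentation stage relies on.  Ground-truth cycle boundaries and inspiratory
fractions are returned alongside every simulated session so downstream
detectors can be tested against the generator's own truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .io import BreathRecording, LabelSegment

#: Per-channel default white-noise SDs (hPa, °C, %RH).
DEFAULT_NOISE_SD = {"pressure": 0.02, "temperature": 0.05, "humidity": 0.5}
#: Per-channel default random-walk step SDs per sample.
DEFAULT_DRIFT_SD = {"pressure": 0.002, "temperature": 0.003, "humidity": 0.02}


@dataclass(frozen=True)
class PlanBlock:
    """One protocol block: ``duration_s`` of condition ``condition`` labelled
    ``label``, simulated with leak severity ``leak`` in [0, 1]."""

    duration_s: float
    label: str
    condition: str
    leak: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError(f"block duration must be positive, got {self.duration_s}")
        if not (0.0 <= self.leak <= 1.0):
            raise ConfigError(f"leak severity must be in [0, 1], got {self.leak}")
        if self.label not in ("fit", "poor_fit", "other"):
            raise ConfigError(f"unknown block label {self.label!r}")


def default_session_plan(scale: float = 1.0) -> tuple[PlanBlock, ...]:
    """The default 50-min protocol: ~21 min fit, ~16 min poor-fit, ~13 min
    unlabelled transitions/calibration, mirroring the standard fit-test
    session structure (proper fit 6+3 min, reading aloud 2 min, passed seal
    test 10 min; simulated tube leak / loose / displaced 2 min each, failed
    seal test 10 min).

    ``scale`` shrinks every block proportionally for desk-scale runs.
    """
    if scale <= 0:
        raise ConfigError(f"scale must be positive, got {scale}")

    def b(dur, label, cond, leak=0.0):
        return PlanBlock(round(dur * scale, 3), label, cond, leak)

    return (
        b(360, "fit", "proper_fit"),
        b(60, "other", "transition"),
        b(180, "fit", "proper_fit"),
        b(60, "other", "transition"),
        b(120, "fit", "reading_aloud"),
        b(60, "other", "transition"),
        b(600, "fit", "seal_test_pass"),
        b(120, "other", "transition"),
        b(120, "poor_fit", "tube_leak", 0.6),
        b(60, "other", "transition"),
        b(120, "poor_fit", "loose", 0.7),
        b(60, "other", "transition"),
        b(120, "poor_fit", "displaced", 0.8),
        b(60, "other", "transition"),
        b(600, "poor_fit", "seal_test_fail", 0.7),
        b(300, "other", "rest"),
    )


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    Defaults encode the study conditions the generator emulates: 10 Hz
    sampling, 12–16 breaths/min, inspiratory fraction 0.40 ± 0.03, exhaled
    air at ≈33 °C / 98 %RH against a 24 °C / 55 %RH ambient, ±0.6 hPa
    pressure oscillation, and a 0.4 s microclimate time constant.
    """

    n_subjects: int = 20
    session_plan: tuple[PlanBlock, ...] = field(default_factory=default_session_plan)
    fs: float = 10.0
    rate_range_bpm: tuple[float, float] = (12.0, 16.0)
    insp_fraction_mean: float = 0.40
    insp_fraction_sd: float = 0.03
    cycle_jitter_cv: float = 0.05
    pressure_amp_hpa: float = 0.6
    pressure_baseline_hpa: float = 1013.0
    temp_baseline_c: float = 24.0
    temp_exhale_c: float = 33.0
    rh_baseline: float = 55.0
    rh_exhale: float = 98.0
    microclimate_tau_s: float = 0.4
    drift_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT_SD))
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    phase_noise_sd_s: float = 0.15
    amp_subject_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rate_range_bpm
        if not (6.0 < lo <= hi < 26.0):
            raise ConfigError(
                f"rate_range_bpm must lie within (6, 26) so cycles stay detectable "
                f"under the default minimum peak distance; got {self.rate_range_bpm}"
            )
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not self.session_plan:
            raise ConfigError("session_plan must contain at least one block")
        for sd in (self.cycle_jitter_cv, self.insp_fraction_sd, self.phase_noise_sd_s):
            if sd < 0:
                raise ConfigError("all SDs must be >= 0")
        for m in (self.drift_sd, self.noise_sd):
            if any(v < 0 for v in m.values()):
                raise ConfigError("all SDs must be >= 0")
        if self.microclimate_tau_s <= 0:
            raise ConfigError("microclimate_tau_s must be positive")

    @property
    def total_duration_s(self) -> float:
        return sum(b.duration_s for b in self.session_plan)

    def label_segments(self, subject_id: str, session_id: str) -> list[LabelSegment]:
        """Labelled intervals implied by the session plan ('other' blocks are
        left uncovered — they fall back to 'other' at sampling time)."""
        segs = []
        t = 0.0
        for blk in self.session_plan:
            if blk.label != "other":
                segs.append(
                    LabelSegment(
                        start_s=round(t, 6),
                        end_s=round(t + blk.duration_s, 6),
                        label=blk.label,
                        condition=blk.condition,
                        subject_id=subject_id,
                        session_id=session_id,
                    )
                )
            t += blk.duration_s
        return segs


@dataclass
class GroundTruth:
    """Generator-side truth for one session.

    ``boundaries_s`` holds the n_cycles+1 cycle boundary times (inspiration
    onsets, plus the final boundary); ``insp_fraction`` and ``leak`` are
    per-cycle.
    """

    boundaries_s: np.ndarray
    insp_fraction: np.ndarray
    leak: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.insp_fraction)

    def cycle_periods_s(self) -> np.ndarray:
        return np.diff(self.boundaries_s)


@dataclass
class SynthDataset:
    """A simulated cohort: per-session recordings, label segments and truth."""

    recordings: list[BreathRecording]
    labels: list[list[LabelSegment]]
    truths: list[GroundTruth]
    config: SynthConfig


def _leak_at(plan: Sequence[PlanBlock], t: float) -> float:
    acc = 0.0
    for blk in plan:
        acc += blk.duration_s
        if t < acc:
            return blk.leak
    return plan[-1].leak


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth unit hump on [0, 1]: 0 at both ends, 1 at the centre."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _first_order_relax(target: np.ndarray, x0: float, alpha: float) -> np.ndarray:
    """x[n] = (1-alpha) x[n-1] + alpha * target[n], x[-1] = x0 (vectorized)."""
    b = [alpha]
    a = [1.0, -(1.0 - alpha)]
    zi = np.asarray([(1.0 - alpha) * x0])
    y, _ = lfilter(b, a, target, zi=zi)
    return y


def simulate_subject(
    cfg: SynthConfig, subject_index: int
) -> tuple[BreathRecording, list[LabelSegment], GroundTruth]:
    """Simulate one subject's session.

    Randomness is drawn from a deterministic substream keyed by
    ``(cfg.seed, subject_index)``: the same index always reproduces the same
    session, and distinct indices are statistically independent.
    """
    if subject_index < 0:
        raise ConfigError(f"subject_index must be >= 0, got {subject_index}")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index)))
    fs = cfg.fs
    dt = 1.0 / fs
    total = cfg.total_duration_s
    n = int(round(total * fs))
    if n < 2:
        raise ConfigError("session plan too short to produce a recording")

    rate = rng.uniform(*cfg.rate_range_bpm)
    amp = cfg.pressure_amp_hpa * (1.0 + cfg.amp_subject_cv * rng.standard_normal())
    amp = max(amp, 0.1 * cfg.pressure_amp_hpa)

    # --- draw the cycle train -------------------------------------------------
    boundaries = [0.0]
    fractions: list[float] = []
    leaks: list[float] = []
    t = 0.0
    base_period = 60.0 / rate
    while t < total:
        jitter = np.clip(cfg.cycle_jitter_cv * rng.standard_normal(), -0.3, 0.3)
        period = base_period * (1.0 + jitter)
        delta = rng.normal(cfg.insp_fraction_mean, cfg.insp_fraction_sd)
        while not (0.2 <= delta <= 0.6):
            delta = rng.normal(cfg.insp_fraction_mean, cfg.insp_fraction_sd)
        leaks.append(_leak_at(cfg.session_plan, t))
        fractions.append(float(delta))
        t += period
        boundaries.append(t)

    # --- pressure: per-cycle raised-cosine humps ------------------------------
    times = np.arange(n) * dt
    pressure = np.full(n, cfg.pressure_baseline_hpa, dtype=float)
    # phase targets for the microclimate channels (per-channel, leak-jittered)
    temp_target = np.full(n, cfg.temp_baseline_c, dtype=float)
    rh_target = np.full(n, cfg.rh_baseline, dtype=float)

    for k in range(len(fractions)):
        c0, c1 = boundaries[k], boundaries[k + 1]
        period = c1 - c0
        split = c0 + fractions[k] * period  # inspiration -> expiration
        lam = leaks[k]
        a = amp * (1.0 - lam)

        i0 = int(np.ceil(c0 * fs - 1e-9))
        im = int(np.ceil(split * fs - 1e-9))
        i1 = int(np.ceil(c1 * fs - 1e-9))
        i0, im, i1 = max(i0, 0), min(max(im, 0), n), min(max(i1, 0), n)
        if im > i0:  # inspiration: sub-ambient hump
            u = (times[i0:im] - c0) / (split - c0)
            pressure[i0:im] -= a * _raised_cosine(u)
        if i1 > im:  # expiration: supra-ambient hump
            u = (times[im:i1] - split) / (c1 - split)
            pressure[im:i1] += a * _raised_cosine(u)

        # microclimate targets during expiration, scaled by (1 - leak); the
        # channel-relative split/end times jitter by phase_noise_sd_s * leak
        for target, exhale, base in (
            (temp_target, cfg.temp_exhale_c, cfg.temp_baseline_c),
            (rh_target, cfg.rh_exhale, cfg.rh_baseline),
        ):
            eps = rng.normal(0.0, cfg.phase_noise_sd_s * lam) if lam > 0 else 0.0
            j0 = int(np.ceil((split + eps) * fs - 1e-9))
            j1 = int(np.ceil((c1 + eps) * fs - 1e-9))
            j0, j1 = min(max(j0, 0), n), min(max(j1, 0), n)
            if j1 > j0:
                target[j0:j1] = base + (exhale - base) * (1.0 - lam)

    alpha = min(dt / cfg.microclimate_tau_s, 1.0)
    temperature = _first_order_relax(temp_target, cfg.temp_baseline_c, alpha)
    humidity = _first_order_relax(rh_target, cfg.rh_baseline, alpha)

    # --- drift + sensor noise -------------------------------------------------
    channels = {"pressure": pressure, "temperature": temperature, "humidity": humidity}
    for name, series in channels.items():
        drift_sd = float(cfg.drift_sd.get(name, 0.0))
        noise_sd = float(cfg.noise_sd.get(name, 0.0))
        if drift_sd > 0:
            series += np.cumsum(rng.normal(0.0, drift_sd, n))
        if noise_sd > 0:
            series += rng.normal(0.0, noise_sd, n)

    subject_id = f"S{subject_index + 1:02d}"
    session_id = "sess01"
    rec = BreathRecording(
        subject_id=subject_id,
        session_id=session_id,
        pressure=channels["pressure"],
        temperature=channels["temperature"],
        humidity=channels["humidity"],
        fs=fs,
    )
    truth = GroundTruth(
        boundaries_s=np.asarray(boundaries),
        insp_fraction=np.asarray(fractions),
        leak=np.asarray(leaks),
    )
    return rec, cfg.label_segments(subject_id, session_id), truth


def simulate_cohort(cfg: SynthConfig) -> SynthDataset:
    """Simulate ``cfg.n_subjects`` independent sessions (see :func:`simulate_subject`)."""
    recordings, labels, truths = [], [], []
    for idx in range(cfg.n_subjects):
        rec, segs, truth = simulate_subject(cfg, idx)
        recordings.append(rec)
        labels.append(segs)
        truths.append(truth)
    return SynthDataset(recordings=recordings, labels=labels, truths=truths, config=cfg)
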