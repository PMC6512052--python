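"""Synthetic five-class annotated ECG records.

Each beat is a sum of Gaussian-shaped P/Q/R/S/T waves placed relative to
its R-peak; the five study classes differ in morphology and in R–R timing
structure:

* **NSR** — reference template: normal P, narrow QRS, upright T.
* **LBBB** — broad R wave and a deep, wide, late S deflection; small P.
* **RBBB** — narrow R followed by a prominent R' bump and an early wide S.
* **APC** — premature beat (preceding R–R shortened by a configurable
  fraction, default 0.25) with an altered, earlier P wave.
* **PVC** — wide bizarre QRS, no P wave, inverted T, and a compensatory
  pause (the following R–R lengthened, default factor 1.5).

Annotations are placed at the true R-peak samples with the correct MIT-BIH
symbols; Gaussian amplitude noise is added on top.  All randomness flows
from the config seed.  An APC drawn immediately after a PVC is replaced by
NSR, since one interval cannot be both a compensatory pause and a
premature coupling; this keeps both timing signatures unconditional.

This generator aims at structural fidelity (R-peaks, timing, separable
morphology classes), not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotatedRecord, BeatAnnotation, CLASS_ORDER, ClassLabel

__all__ = ["SyntheticConfig", "generate_record", "generate_dataset", "WAVE_PARAMS"]

#: per class: list of (center offset s relative to R, width sigma s, amplitude mV)
WAVE_PARAMS: dict[ClassLabel, tuple[tuple[float, float, float], ...]] = {
    ClassLabel.NSR: (
        (-0.200, 0.025, 0.15),   # P
        (-0.048, 0.012, -0.10),  # Q
        (0.000, 0.022, 1.00),    # R
        (0.048, 0.015, -0.25),   # S
        (0.300, 0.080, 0.30),    # T
    ),
    ClassLabel.LBBB: (
        (-0.210, 0.030, 0.06),   # diminished P
        (0.000, 0.055, 0.90),    # broad R
        (0.130, 0.050, -0.55),   # deep wide late S
        (0.340, 0.090, -0.20),   # discordant T
    ),
    ClassLabel.RBBB: (
        (-0.200, 0.025, 0.14),   # P
        (0.000, 0.020, 0.85),    # R
        (0.042, 0.025, -0.45),   # early wide S
        (0.085, 0.028, 0.55),    # R' bump
        (0.300, 0.080, 0.18),    # T
    ),
    ClassLabel.APC: (
        (-0.140, 0.040, 0.28),   # altered, earlier/taller P
        (-0.048, 0.012, -0.10),
        (0.000, 0.022, 0.95),
        (0.048, 0.015, -0.22),
        (0.290, 0.075, 0.28),
    ),
    ClassLabel.PVC: (
        (0.000, 0.070, 1.20),    # wide bizarre R, no P
        (0.150, 0.055, -0.50),
        (0.330, 0.090, -0.40),   # inverted T
    ),
}

#: default beat-class proportions, matching the study's training-count mix
_DEFAULT_MIX = (0.351, 0.211, 0.201, 0.065, 0.172)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults give an MIT-BIH-like 360 Hz record."""

    fs: float = 360.0
    n_beats: int = 200
    class_mix: tuple[float, ...] = _DEFAULT_MIX
    mean_rr: float = 0.8
    rr_jitter: float = 0.05
    noise_sd: float = 0.02
    apc_prematurity: float = 0.25
    pvc_pause_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        mix = tuple(float(p) for p in self.class_mix)
        object.__setattr__(self, "class_mix", mix)
        if len(mix) != len(CLASS_ORDER):
            raise ValueError("class_mix needs one proportion per class")
        if any(p < 0 for p in mix):
            raise ValueError("class_mix entries must be non-negative")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.fs <= 0 or self.mean_rr <= 0:
            raise ValueError("fs and mean_rr must be positive")
        if self.rr_jitter < 0 or self.noise_sd < 0:
            raise ValueError("rr_jitter and noise_sd must be non-negative")
        if not 0 < self.apc_prematurity < 1:
            raise ValueError("apc_prematurity must be in (0, 1)")
        if self.pvc_pause_factor <= 1:
            raise ValueError("pvc_pause_factor must exceed 1")


_CLASS_SYMBOL = {
    ClassLabel.NSR: "N",
    ClassLabel.LBBB: "L",
    ClassLabel.RBBB: "R",
    ClassLabel.APC: "A",
    ClassLabel.PVC: "V",
}


def draw_classes(config: SyntheticConfig, rng: np.random.Generator) -> list[ClassLabel]:
    """The seeded class-assignment stream, including the PVC→APC rule."""
    idx = rng.choice(len(CLASS_ORDER), size=config.n_beats, p=config.class_mix)
    classes = [CLASS_ORDER[i] for i in idx]
    for i in range(1, len(classes)):
        if classes[i] is ClassLabel.APC and classes[i - 1] is ClassLabel.PVC:
            classes[i] = ClassLabel.NSR
    return classes


def _r_times(
    config: SyntheticConfig, classes: list[ClassLabel], rng: np.random.Generator
) -> np.ndarray:
    """R-peak times in seconds, with class-specific timing deformations."""
    n = len(classes)
    base = config.mean_rr * (
        1.0 + config.rr_jitter * rng.standard_normal(n)
    )
    base = np.clip(base, 0.3 * config.mean_rr, 2.0 * config.mean_rr)
    intervals = base.copy()
    for i in range(n):
        # interval[i] separates beat i-1 (or the record start) from beat i
        if classes[i] is ClassLabel.APC and i > 0:
            intervals[i] *= 1.0 - config.apc_prematurity
        if i > 0 and classes[i - 1] is ClassLabel.PVC:
            intervals[i] *= config.pvc_pause_factor
    start = 0.5 * config.mean_rr
    return start + np.cumsum(intervals)


def generate_record(
    config: SyntheticConfig, record_id: str = "synth-000"
) -> AnnotatedRecord:
    """Render one annotated record from the config's seeded streams."""
    rng = np.random.default_rng(config.seed)
    classes = draw_classes(config, rng)
    if not classes:
        return AnnotatedRecord(
            record_id=record_id,
            signal=np.zeros(int(config.fs)),
            fs=config.fs,
            annotations=[],
        )
    r_times = _r_times(config, classes, rng)
    duration = r_times[-1] + 0.6
    n_samples = int(round(duration * config.fs)) + 1
    t = np.arange(n_samples) / config.fs
    signal = np.zeros(n_samples)
    for r_t, label in zip(r_times, classes):
        lo = max(0, int((r_t - 0.5) * config.fs))
        hi = min(n_samples, int((r_t + 0.6) * config.fs))
        seg_t = t[lo:hi]
        for center, sigma, amp in WAVE_PARAMS[label]:
            signal[lo:hi] += amp * np.exp(
                -0.5 * ((seg_t - r_t - center) / sigma) ** 2
            )
    if config.noise_sd > 0:
        signal += config.noise_sd * rng.standard_normal(n_samples)
    annotations = [
        BeatAnnotation(sample_index=int(round(r_t * config.fs)), symbol=_CLASS_SYMBOL[c])
        for r_t, c in zip(r_times, classes)
    ]
    return AnnotatedRecord(
        record_id=record_id, signal=signal, fs=config.fs, annotations=annotations
    )


def generate_dataset(
    config: SyntheticConfig, n_records: int
) -> list[AnnotatedRecord]:
    """Independent records with per-record seeds derived from the master seed."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    seed_rng = np.random.default_rng(config.seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=n_records)
    records = []
    for i, child in enumerate(child_seeds):
        cfg = SyntheticConfig(
            fs=config.fs,
            n_beats=config.n_beats,
            class_mix=config.class_mix,
            mean_rr=config.mean_rr,
            rr_jitter=config.rr_jitter,
            noise_sd=config.noise_sd,
            apc_prematurity=config.apc_prematurity,
            pvc_pause_factor=config.pvc_pause_factor,
            seed=int(child),
        )
        records.append(generate_record(cfg, record_id=f"synth-{i:03d}"))
    return records
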