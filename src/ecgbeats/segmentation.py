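"""R-peak-anchored beat windows and fixed-length normalization.

A window for reference beat :math:`R_n` with segment count *k* spans from
the midpoint of the :math:`R_{n-k+1}` / :math:`R_{n-k+2}` peak positions to
the midpoint of :math:`R_{n+1}` / :math:`R_{n+2}` positions, i.e. roughly
*k* consecutive R–R intervals centred on the reference beat.  Because
window duration varies with heart rate, each raw window is resampled to a
fixed ``(k - 1) * 100`` samples (200 for k=3 up to 600 for k=7) with an
anti-aliasing polyphase filter, then amplitude-standardized per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from .io import AnnotatedRecord, ClassLabel, symbol_to_class

__all__ = [
    "SegmentConfig",
    "SegmentWindow",
    "NormalizedBeat",
    "boundary_samples",
    "extract_windows",
    "normalize_window",
]

_STD_GUARD = 1e-12


@dataclass(frozen=True)
class SegmentConfig:
    """Segment count *k* (R-peaks of context, 3–7) and per-interval samples.

    The normalized window length is ``(k - 1) * samples_per_interval`` —
    a pure function of the config, never of heart rate or sampling rate.
    """

    k: int = 3
    samples_per_interval: int = 100

    def __post_init__(self) -> None:
        if not 3 <= self.k <= 7:
            raise ValueError(f"k must be in [3, 7], got {self.k}")
        if self.samples_per_interval < 2:
            raise ValueError("samples_per_interval must be >= 2")

    @property
    def normalized_length(self) -> int:
        return (self.k - 1) * self.samples_per_interval


@dataclass(frozen=True)
class SegmentWindow:
    """One reference beat's raw extraction window (half-open sample range)."""

    record_id: str
    reference_index: int
    first_sample: int
    end_sample: int
    label: ClassLabel
    raw: np.ndarray


@dataclass(frozen=True)
class NormalizedBeat:
    """Fixed-length, amplitude-standardized window — the network input unit."""

    values: np.ndarray
    label: ClassLabel
    record_id: str
    reference_index: int


def boundary_samples(
    record: AnnotatedRecord, n: int, k: int
) -> tuple[int, int] | None:
    """Window boundaries for reference annotation position ``n``.

    Returns ``(first_sample, end_sample)`` with
    ``first = floor((pos[n-k+1] + pos[n-k+2]) / 2)`` and
    ``end = floor((pos[n+1] + pos[n+2]) / 2)``, or ``None`` when the
    annotation list lacks the required context peaks (the beat is skipped,
    not an error).
    """
    lo = n - k + 1
    if lo < 0 or n + 2 >= len(record.annotations):
        return None
    pos = record.annotation_samples
    first = (int(pos[lo]) + int(pos[lo + 1])) // 2
    end = (int(pos[n + 1]) + int(pos[n + 2])) // 2
    return first, end


def extract_windows(
    record: AnnotatedRecord, config: SegmentConfig
) -> list[SegmentWindow]:
    """One window per annotation with a study-class symbol and enough context.

    Context peaks may be any annotated beat (class-mapped or not); only the
    reference beat's own symbol decides the label.  Beats with insufficient
    context at either end of the record are skipped.
    """
    windows: list[SegmentWindow] = []
    for n, ann in enumerate(record.annotations):
        label = symbol_to_class(ann.symbol)
        if label is None:
            continue
        bounds = boundary_samples(record, n, config.k)
        if bounds is None:
            continue
        first, end = bounds
        if first < 0 or end > record.signal.size or end - first < 2:
            continue
        windows.append(
            SegmentWindow(
                record_id=record.record_id,
                reference_index=n,
                first_sample=first,
                end_sample=end,
                label=label,
                raw=record.signal[first:end].copy(),
            )
        )
    return windows


def normalize_window(window: SegmentWindow, config: SegmentConfig) -> NormalizedBeat:
    """Resample a raw window to ``(k-1) * samples_per_interval`` samples.

    Polyphase resampling with an FIR anti-aliasing low-pass (cutoff at the
    target Nyquist) guards against aliasing when decimating.  Amplitude is
    then z-scored per window; a (near-)constant window standardizes to
    zeros rather than dividing by ~0.
    """
    target = config.normalized_length
    raw = np.asarray(window.raw, dtype=float)
    if raw.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if raw.std() < _STD_GUARD:  # constant window: no shape to resample
        return NormalizedBeat(
            values=np.zeros(target),
            label=window.label,
            record_id=window.record_id,
            reference_index=window.reference_index,
        )
    values = resample_poly(raw, target, raw.size) if raw.size != target else raw.copy()
    values = values[:target]
    sd = values.std()
    if sd < _STD_GUARD:
        values = np.zeros(target)
    else:
        values = (values - values.mean()) / sd
    return NormalizedBeat(
        values=values,
        label=window.label,
        record_id=window.record_id,
        reference_index=window.reference_index,
    )


def record_to_beats(
    record: AnnotatedRecord, config: SegmentConfig
) -> list[NormalizedBeat]:
    """Convenience: extract and normalize every eligible beat of a record."""
    return [normalize_window(w, config) for w in extract_windows(record, config)]
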