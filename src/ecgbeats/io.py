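"""Annotated single-lead ECG records: in-memory container and on-disk dialects.

Two dialects are supported:

``fixture``
    A plain-text pair ``<record_id>.csv`` (one column of decimal millivolt
    samples) plus ``<record_id>.json`` (record id, sampling rate, beat
    annotations).  Round-trips bit-exactly, diffable, and is what the
    synthetic generator emits.

``wfdb``
    The PhysioNet waveform-database layout: ``.hea`` header, ``.dat`` signal
    (format 212 or 16) and ``.atr`` MIT annotation stream.  A compact reader
    is included so MIT-BIH-style records can be loaded directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "ClassLabel",
    "CLASS_ORDER",
    "BeatAnnotation",
    "AnnotatedRecord",
    "FormatError",
    "symbol_to_class",
    "read_record",
    "write_record",
    "PACED_RECORDS",
]


class FormatError(ValueError):
    """Raised when a record violates a structural invariant."""


class ClassLabel(str, Enum):
    """The five beat classes of the study, in fixed reporting order.

    The order NSR, LBBB, RBBB, APC, PVC fixes confusion-matrix row and
    column order everywhere in the package.
    """

    NSR = "NSR"
    LBBB = "LBBB"
    RBBB = "RBBB"
    APC = "APC"
    PVC = "PVC"


CLASS_ORDER: tuple[ClassLabel, ...] = (
    ClassLabel.NSR,
    ClassLabel.LBBB,
    ClassLabel.RBBB,
    ClassLabel.APC,
    ClassLabel.PVC,
)

#: MIT-BIH beat symbol -> study class.  Every other symbol is excluded.
_SYMBOL_MAP: dict[str, ClassLabel] = {
    "N": ClassLabel.NSR,
    "L": ClassLabel.LBBB,
    "R": ClassLabel.RBBB,
    "A": ClassLabel.APC,
    "V": ClassLabel.PVC,
}

#: MIT-BIH records whose rhythm is paced; excluded from study datasets.
PACED_RECORDS: tuple[str, ...] = ("102", "104", "107", "217")


def symbol_to_class(symbol: str) -> ClassLabel | None:
    """Map a single-character beat annotation symbol to a study class.

    N→NSR, L→LBBB, R→RBBB, A→APC, V→PVC; any other symbol (paced beats,
    fusion beats, non-beat annotations, ...) returns ``None`` and the beat
    is excluded from training and testing.
    """
    return _SYMBOL_MAP.get(symbol)


@dataclass(frozen=True, order=True)
class BeatAnnotation:
    """One annotated R-peak: 0-based sample index plus beat symbol."""

    sample_index: int
    symbol: str


@dataclass
class AnnotatedRecord:
    """A sampled single-lead ECG with beat annotations.

    Invariants (checked on construction): ``fs`` positive, annotations
    strictly increasing by sample index and inside ``[0, len(signal))``.
    Signal amplitudes are physical units (millivolts).
    """

    record_id: str
    signal: np.ndarray
    fs: float
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise FormatError("signal must be one-dimensional (single lead)")
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        n = self.signal.size
        prev = -1
        for ann in self.annotations:
            if not 0 <= ann.sample_index < n:
                raise FormatError(
                    f"annotation at sample {ann.sample_index} outside signal "
                    f"of length {n}"
                )
            if ann.sample_index <= prev:
                raise FormatError("annotations must be strictly increasing")
            prev = ann.sample_index

    @property
    def annotation_samples(self) -> np.ndarray:
        return np.array([a.sample_index for a in self.annotations], dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.fs == other.fs
            and self.annotations == other.annotations
            and self.signal.shape == other.signal.shape
            and bool(np.all(self.signal == other.signal))
        )


# ---------------------------------------------------------------------------
# fixture dialect
# ---------------------------------------------------------------------------

def _fixture_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix in {".csv", ".json"} else path
    return base.with_suffix(".csv"), base.with_suffix(".json")


def _read_fixture(path: Path) -> AnnotatedRecord:
    csv_path, json_path = _fixture_paths(path)
    for p in (csv_path, json_path):
        if not p.exists():
            raise FileNotFoundError(p)
    meta = json.loads(json_path.read_text())
    signal = np.array(
        [float(line) for line in csv_path.read_text().splitlines() if line.strip()],
        dtype=float,
    )
    annotations = [
        BeatAnnotation(int(a["sample"]), str(a["symbol"]))
        for a in meta["annotations"]
    ]
    return AnnotatedRecord(
        record_id=str(meta["record_id"]),
        signal=signal,
        fs=float(meta["fs"]),
        annotations=annotations,
    )


def _write_fixture(record: AnnotatedRecord, path: Path) -> None:
    csv_path, json_path = _fixture_paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    # repr() round-trips every float exactly -> bit-exact read-back
    csv_path.write_text("\n".join(repr(float(x)) for x in record.signal) + "\n")
    meta = {
        "record_id": record.record_id,
        "fs": record.fs,
        "annotations": [
            {"sample": a.sample_index, "symbol": a.symbol}
            for a in record.annotations
        ],
    }
    json_path.write_text(json.dumps(meta, indent=1) + "\n")


# ---------------------------------------------------------------------------
# WFDB dialect (reader only)
# ---------------------------------------------------------------------------

#: MIT annotation type code -> symbol, for the codes that occur in practice.
_ATR_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}


def _parse_header(hea_path: Path) -> dict:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_id = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain_s, base_s = gain_str.rstrip(")").split("(")
            gain, baseline = float(gain_s), int(base_s)
        else:
            gain = float(gain_str)
            baseline = int(parts[4]) if len(parts) > 4 else 0
        if gain == 0:
            gain = 200.0
        signals.append(
            {"file": parts[0], "fmt": int(fmt), "gain": gain, "baseline": baseline}
        )
    return {
        "record_id": record_id,
        "n_sig": n_sig,
        "fs": fs,
        "n_samp": n_samp,
        "signals": signals,
    }


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def _read_dat(dat_path: Path, header: dict, channel: int) -> np.ndarray:
    sig = header["signals"][channel]
    n_sig = header["n_sig"]
    raw = dat_path.read_bytes()
    fmt = sig["fmt"]
    if fmt == 212:
        total = header["n_samp"] * n_sig if header["n_samp"] else (len(raw) // 3) * 2
        adc = _decode_212(raw, total)
    elif fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt}")
    adc = adc[: (len(adc) // n_sig) * n_sig].reshape(-1, n_sig)
    return (adc[:, channel] - sig["baseline"]) / sig["gain"]


def _read_atr(atr_path: Path) -> list[BeatAnnotation]:
    data = atr_path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        val = word & 0x3FF
        if code == 0 and val == 0:  # end of stream
            break
        if code == 59:  # SKIP: 4-byte offset, high 16-bit word first (PDP-11)
            if i + 3 >= len(data):
                break
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            t += (high << 16) | low
            i += 4
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers: ignored
            continue
        elif code == 63:  # AUX: skip the string payload (padded to even)
            i += val + (val & 1)
        else:
            t += val
            symbol = _ATR_CODE_TO_SYMBOL.get(code, "?")
            anns.append(BeatAnnotation(sample_index=t, symbol=symbol))
    return anns


def _read_wfdb(path: Path, channel: int) -> AnnotatedRecord:
    base = path.with_suffix("") if path.suffix in {".hea", ".dat", ".atr"} else path
    hea_path = base.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(hea_path)
    header = _parse_header(hea_path)
    dat_path = base.parent / header["signals"][channel]["file"]
    if not dat_path.exists():
        raise FileNotFoundError(dat_path)
    signal = _read_dat(dat_path, header, channel)
    atr_path = base.with_suffix(".atr")
    annotations = _read_atr(atr_path) if atr_path.exists() else []
    # keep only annotations that land inside the signal
    annotations = [a for a in annotations if 0 <= a.sample_index < signal.size]
    return AnnotatedRecord(
        record_id=header["record_id"],
        signal=signal,
        fs=header["fs"],
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path, dialect: str = "fixture", channel: int = 0
) -> AnnotatedRecord:
    """Read an annotated record from disk.

    Parameters
    ----------
    path
        Record base path (extension optional).
    dialect
        ``"fixture"`` (CSV + JSON sidecar) or ``"wfdb"``.
    channel
        Signal channel for multi-lead WFDB records; the first lead by
        default, matching the single-lead method.
    """
    path = Path(path)
    if dialect == "fixture":
        return _read_fixture(path)
    if dialect == "wfdb":
        return _read_wfdb(path, channel)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_record(
    record: AnnotatedRecord, path: str | Path, dialect: str = "fixture"
) -> None:
    """Write a record; only the fixture dialect is writable.

    ``read_record`` inverts this bit-exactly (signal values, annotation
    indices and symbols).
    """
    if dialect != "fixture":
        raise ValueError("only the fixture dialect is writable")
    _write_fixture(record, Path(path))
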