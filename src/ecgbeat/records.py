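"""Reading ECG records and beat annotations.

Two on-disk representations are supported through one interface:

* **WFDB** — the PhysioNet waveform-database layout used by the MIT-BIH
  arrhythmia database: a ``<record>.hea`` header, a format-212 ``.dat``
  signal file (two 12-bit samples packed into three bytes) and a ``.atr``
  beat-annotation file.  Only the subset of the format needed for these
  records is implemented (format 212, single segment, no skew/offset).
* **Delimited text** — a fixture-friendly fallback: ``<record>.txt`` holding
  a two-line header (``fs <Hz>`` then comma-separated channel names)
  followed by one comma-separated sample row per time point, and
  ``<record>.ann.csv`` with columns ``sample_index,symbol``.

Both paths yield the same :class:`ECGRecord` / :class:`BeatAnnotation`
objects, so synthetic fixtures and real database files are interchangeable
downstream.

Beat classes
------------
Eight beat types are classified, indexed in a fixed order::

    0 N      normal
    1 LBBB   left bundle branch block
    2 RBBB   right bundle branch block
    3 APC    atrial premature contraction
    4 NESC   nodal (junctional) escape
    5 ABERR  aberrated atrial premature
    6 NPC    nodal (junctional) premature
    7 AESC   atrial escape

:func:`map_symbol` converts the standard PhysioNet annotation symbols
(``N L R A j a J e``) to these labels; every other symbol (ventricular
beats, rhythm markers, noise flags, ...) maps to ``None`` and the beat is
excluded from the dataset.
"""

from __future__ import annotations

import struct
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "N_CLASSES",
    "SYMBOL_TO_CLASS",
    "ClassLabel",
    "ECGRecord",
    "BeatAnnotation",
    "map_symbol",
    "class_counts",
    "load_record",
    "load_annotations",
    "write_text_record",
    "write_text_annotations",
    "write_wfdb_record",
    "write_wfdb_annotations",
]

#: Class names in label order.
CLASS_NAMES: tuple[str, ...] = (
    "N", "LBBB", "RBBB", "APC", "NESC", "ABERR", "NPC", "AESC",
)

N_CLASSES = len(CLASS_NAMES)

#: PhysioNet beat-annotation symbol -> class index.  These are the standard
#: MIT-BIH symbols for the eight beat types above; all other symbols are
#: intentionally absent (their beats are excluded).
SYMBOL_TO_CLASS: dict[str, int] = {
    "N": 0,  # normal
    "L": 1,  # left bundle branch block
    "R": 2,  # right bundle branch block
    "A": 3,  # atrial premature contraction
    "j": 4,  # nodal (junctional) escape
    "a": 5,  # aberrated atrial premature
    "J": 6,  # nodal (junctional) premature
    "e": 7,  # atrial escape
}


@dataclass(frozen=True)
class ClassLabel:
    """One of the eight beat classes (index and canonical name)."""

    index: int
    name: str

    @classmethod
    def from_index(cls, index: int) -> "ClassLabel":
        if not 0 <= index < N_CLASSES:
            raise ValueError(f"class index {index} out of range [0, {N_CLASSES})")
        return cls(index, CLASS_NAMES[index])


@dataclass
class ECGRecord:
    """A multichannel ECG signal in physical units (mV)."""

    record_id: str
    fs: float
    signals: np.ndarray  # shape (n_samples, n_channels)
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (n_samples, n_channels) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.signals.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signals.shape[1]} signal channels"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    def channel(self, index: int = 0) -> np.ndarray:
        """Return one channel as a 1-D array (channel 0 by default)."""
        return self.signals[:, index]


@dataclass(frozen=True)
class BeatAnnotation:
    """An annotated event: 0-based sample index of the R-peak plus symbol."""

    sample_index: int
    symbol: str


def map_symbol(symbol: str) -> ClassLabel | None:
    """Map an annotation symbol to its beat class, or ``None`` if excluded.

    Total and deterministic: exactly the eight PhysioNet beat symbols
    ``N L R A j a J e`` map to labels; everything else (including
    ventricular beats and non-beat markers such as ``+`` or ``~``) returns
    ``None``.
    """
    idx = SYMBOL_TO_CLASS.get(symbol)
    if idx is None:
        return None
    return ClassLabel(idx, CLASS_NAMES[idx])


def class_counts(annotations: Iterable[BeatAnnotation]) -> dict[int, int]:
    """Count annotations per class index, ignoring unmapped symbols.

    Returns a dict with all eight class indices as keys (zero where a class
    is absent), so tables line up across records.
    """
    counter: Counter[int] = Counter()
    for ann in annotations:
        label = map_symbol(ann.symbol)
        if label is not None:
            counter[label.index] += 1
    return {c: counter.get(c, 0) for c in range(N_CLASSES)}


# ---------------------------------------------------------------------------
# WFDB reading (header + format-212 signal + MIT annotation files)
# ---------------------------------------------------------------------------

# Annotation-code -> symbol table from the WFDB specification.  Codes not
# listed are read as '?' (they never map to a beat class anyway).
_ANN_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_ANN_CODE = {s: c for c, s in _ANN_CODE_TO_SYMBOL.items()}


def _parse_header(path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header: {path}")
    head = lines[0].split()
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    if len(lines) - 1 < nsig:
        raise ValueError(
            f"WFDB header {path} declares {nsig} signals but lists {len(lines) - 1}"
        )
    specs = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_s, base_s = gain_part.rstrip(")").split("(")
            baseline = int(base_s)
        else:
            gain_s, baseline = gain_part, None
        gain = float(gain_s)
        if gain == 0:
            gain = 200.0
        adczero = int(tok[4]) if len(tok) > 4 else 0
        specs.append(
            {
                "filename": tok[0],
                "format": fmt,
                "gain": gain,
                "baseline": baseline if baseline is not None else adczero,
                "description": " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(specs)}",
            }
        )
    return name, nsig, fs, nsamp, specs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format-212 bytes into ``n_values`` 12-bit signed integers."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = (n_values + 1) // 2
    if b.size < 3 * n_pairs:
        raise ValueError("format-212 signal file truncated")
    b = b[: 3 * n_pairs].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    vals = np.empty(2 * n_pairs, dtype=np.int32)
    vals[0::2] = first
    vals[1::2] = second
    vals[vals > 2047] -= 4096
    return vals[:n_values]


def _load_wfdb_record(directory: Path, record_id: str) -> ECGRecord:
    header = directory / f"{record_id}.hea"
    _, nsig, fs, nsamp, specs = _parse_header(header)
    fnames = {s["filename"] for s in specs}
    if len(fnames) != 1:
        raise ValueError(f"multi-file signals not supported in {header}")
    fmts = {s["format"] for s in specs}
    if fmts != {"212"}:
        raise ValueError(f"unsupported WFDB signal format(s) {fmts} in {header}")
    dat = directory / specs[0]["filename"]
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    raw = dat.read_bytes()
    if nsamp == 0:
        nsamp = (len(raw) * 2 // 3) // nsig
    digital = _decode_212(raw, nsamp * nsig).reshape(nsamp, nsig)
    physical = np.empty(digital.shape, dtype=float)
    for ch, s in enumerate(specs):
        physical[:, ch] = (digital[:, ch] - s["baseline"]) / s["gain"]
    return ECGRecord(
        record_id=record_id,
        fs=fs,
        signals=physical,
        channel_names=[s["description"] for s in specs],
    )


def _load_wfdb_annotations(path: Path) -> list[BeatAnnotation]:
    raw = path.read_bytes()
    out: list[BeatAnnotation] = []
    t = 0
    pos = 0
    n = len(raw)
    while pos + 1 < n:
        word = raw[pos] | (raw[pos + 1] << 8)
        pos += 2
        code = word >> 10
        data = word & 0x3FF
        if word == 0:  # EOF marker
            break
        if code == 59:  # SKIP: 4-byte interval follows, high word first
            if pos + 3 >= n:
                raise ValueError(f"truncated SKIP in annotation file {path}")
            hi = raw[pos] | (raw[pos + 1] << 8)
            lo = raw[pos + 2] | (raw[pos + 3] << 8)
            pos += 4
            t += struct.unpack("<i", struct.pack("<I", (hi << 16) | lo))[0]
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers: no time advance
            continue
        elif code == 63:  # AUX: data = byte count, padded to even
            pos += data + (data & 1)
        else:
            t += data
            out.append(BeatAnnotation(t, _ANN_CODE_TO_SYMBOL.get(code, "?")))
    out.sort(key=lambda a: a.sample_index)
    return out


# ---------------------------------------------------------------------------
# Delimited-text fallback
# ---------------------------------------------------------------------------


def _load_text_record(directory: Path, record_id: str) -> ECGRecord:
    path = directory / f"{record_id}.txt"
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"text record {path} missing header lines")
    head = lines[0].split()
    if len(head) != 2 or head[0] != "fs":
        raise ValueError(f"text record {path}: first line must be 'fs <Hz>'")
    fs = float(head[1])
    names = [c.strip() for c in lines[1].split(",")]
    rows = [ln for ln in lines[2:] if ln.strip()]
    data = np.array([[float(v) for v in ln.split(",")] for ln in rows], dtype=float)
    if data.size == 0:
        data = np.empty((0, len(names)))
    if data.shape[1] != len(names):
        raise ValueError(
            f"text record {path}: {data.shape[1]} columns for {len(names)} channels"
        )
    return ECGRecord(record_id=record_id, fs=fs, signals=data, channel_names=names)


def _load_text_annotations(path: Path) -> list[BeatAnnotation]:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    out: list[BeatAnnotation] = []
    for ln in lines:
        if ln.lower().startswith("sample_index"):
            continue
        idx_s, sym = ln.split(",", 1)
        out.append(BeatAnnotation(int(idx_s), sym.strip()))
    out.sort(key=lambda a: a.sample_index)
    return out


# ---------------------------------------------------------------------------
# Public loaders (auto-detect format) and fixture writers
# ---------------------------------------------------------------------------


def load_record(directory: str | Path, record_id: str) -> ECGRecord:
    """Load a record by id, preferring WFDB files over the text fallback."""
    directory = Path(directory)
    if (directory / f"{record_id}.hea").exists():
        return _load_wfdb_record(directory, record_id)
    if (directory / f"{record_id}.txt").exists():
        return _load_text_record(directory, record_id)
    raise FileNotFoundError(
        f"no record '{record_id}' in {directory} "
        f"(looked for {record_id}.hea and {record_id}.txt)"
    )


def load_annotations(directory: str | Path, record_id: str) -> list[BeatAnnotation]:
    """Load beat annotations for a record, sorted by sample index.

    Non-beat annotations are retained with their symbols; filtering to the
    eight beat classes happens later via :func:`map_symbol`.
    """
    directory = Path(directory)
    if (directory / f"{record_id}.atr").exists():
        return _load_wfdb_annotations(directory / f"{record_id}.atr")
    if (directory / f"{record_id}.ann.csv").exists():
        return _load_text_annotations(directory / f"{record_id}.ann.csv")
    raise FileNotFoundError(
        f"no annotations for '{record_id}' in {directory} "
        f"(looked for {record_id}.atr and {record_id}.ann.csv)"
    )


def write_text_record(directory: str | Path, record: ECGRecord) -> Path:
    """Write a record in the delimited-text layout (one row per sample)."""
    directory = Path(directory)
    path = directory / f"{record.record_id}.txt"
    with path.open("w") as fh:
        fh.write(f"fs {record.fs:g}\n")
        fh.write(",".join(record.channel_names) + "\n")
        for row in record.signals:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    return path


def write_text_annotations(
    directory: str | Path, record_id: str, annotations: Sequence[BeatAnnotation]
) -> Path:
    directory = Path(directory)
    path = directory / f"{record_id}.ann.csv"
    with path.open("w") as fh:
        fh.write("sample_index,symbol\n")
        for ann in annotations:
            fh.write(f"{ann.sample_index},{ann.symbol}\n")
    return path


def write_wfdb_record(
    directory: str | Path,
    record: ECGRecord,
    gain: float = 200.0,
    baseline: int = 1024,
) -> Path:
    """Write a record as a WFDB header + format-212 signal pair.

    Used for round-trip fixtures; amplitudes are quantized to 12 bits with
    the given gain (ADC units per mV), so the round-trip is exact to
    ``1/(2*gain)`` mV.
    """
    directory = Path(directory)
    digital = np.round(record.signals * gain + baseline).astype(np.int32)
    if digital.min() < -2048 or digital.max() > 2047:
        raise ValueError("signal out of 12-bit range for format 212 at this gain")
    flat = digital.reshape(-1)  # interleaved channel-major per frame
    if flat.size % 2:
        flat = np.append(flat, 0)
    first = flat[0::2] & 0xFFF
    second = flat[1::2] & 0xFFF
    packed = np.empty((first.size, 3), dtype=np.uint8)
    packed[:, 0] = first & 0xFF
    packed[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
    packed[:, 2] = second & 0xFF
    dat = directory / f"{record.record_id}.dat"
    dat.write_bytes(packed.tobytes())
    hea = directory / f"{record.record_id}.hea"
    with hea.open("w") as fh:
        fh.write(
            f"{record.record_id} {record.n_channels} {record.fs:g} "
            f"{record.n_samples}\n"
        )
        for name in record.channel_names:
            fh.write(
                f"{record.record_id}.dat 212 {gain:g}({baseline})/mV 12 "
                f"{baseline} 0 0 0 {name}\n"
            )
    return hea


def write_wfdb_annotations(
    directory: str | Path, record_id: str, annotations: Sequence[BeatAnnotation]
) -> Path:
    """Write annotations in the MIT binary format (for round-trip fixtures)."""
    directory = Path(directory)
    path = directory / f"{record_id}.atr"
    anns = sorted(annotations, key=lambda a: a.sample_index)
    words = bytearray()
    t = 0
    for ann in anns:
        code = _SYMBOL_TO_ANN_CODE.get(ann.symbol)
        if code is None:
            raise ValueError(f"symbol {ann.symbol!r} has no WFDB annotation code")
        dt = ann.sample_index - t
        if dt > 0x3FF or dt < 0:
            # SKIP escape: code 59 with a 4-byte interval, high word first
            words += struct.pack("<H", (59 << 10))
            iv = struct.unpack("<I", struct.pack("<i", dt))[0]
            words += struct.pack("<HH", (iv >> 16) & 0xFFFF, iv & 0xFFFF)
            dt = 0
        words += struct.pack("<H", (code << 10) | dt)
        t = ann.sample_index
    words += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(words))
    return path
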