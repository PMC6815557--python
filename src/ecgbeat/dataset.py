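"""Beat datasets: the in-memory container and its two-file text serialization.

A dataset is the collection ``{(x_i, y_i)}`` of fixed-length beats with
class labels.  On disk it is a pair of plain-text files sharing a stem:

* ``<stem>.beats.tsv`` — one beat per row, ``beat_length`` tab-separated
  columns, written at 17 significant digits so the round-trip is bit-exact
  for double precision;
* ``<stem>.manifest.csv`` — one row per beat with columns
  ``row_id,record_id,r_index,label_index,label_name,split``.

The ``split`` column is empty until :func:`ecgbeat.preprocess.split_dataset`
assigns ``train``/``val``/``test``.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .records import CLASS_NAMES, N_CLASSES

BEAT_LENGTH = 250  # samples per beat (about 0.7 s at 360 Hz)
R_POSITION = 125  # within-beat index of the annotated R-peak

__all__ = [
    "BEAT_LENGTH",
    "R_POSITION",
    "Beat",
    "BeatDataset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class Beat:
    """One fixed-length beat window with its label and provenance."""

    samples: np.ndarray  # length BEAT_LENGTH (by default)
    label: int  # class index 0..7
    source_record: str = ""
    r_index: int = -1  # R-peak sample index in the source record

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("beat samples must be 1-D")
        if not 0 <= self.label < N_CLASSES:
            raise ValueError(f"label {self.label} out of range [0, {N_CLASSES})")

    @property
    def label_name(self) -> str:
        return CLASS_NAMES[self.label]


@dataclass
class BeatDataset:
    """An ordered collection of labelled beats."""

    beats: list[Beat] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.beats)

    @property
    def class_distribution(self) -> dict[int, int]:
        counter = Counter(b.label for b in self.beats)
        return {c: counter.get(c, 0) for c in range(N_CLASSES)}

    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.beats], dtype=int)

    def matrix(self) -> np.ndarray:
        """Stack beats into an (n, beat_length) array."""
        if not self.beats:
            return np.empty((0, BEAT_LENGTH))
        return np.stack([b.samples for b in self.beats])

    def subset(self, indices: Iterable[int]) -> "BeatDataset":
        return BeatDataset([self.beats[i] for i in indices])

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.beats)


def save_dataset(
    stem: str | Path,
    dataset: BeatDataset,
    splits: Sequence[str] | None = None,
) -> tuple[Path, Path]:
    """Write a dataset as ``<stem>.beats.tsv`` + ``<stem>.manifest.csv``."""
    stem = Path(stem)
    if splits is not None and len(splits) != dataset.n:
        raise ValueError("splits must have one entry per beat")
    beats_path = stem.with_name(stem.name + ".beats.tsv")
    manifest_path = stem.with_name(stem.name + ".manifest.csv")
    with beats_path.open("w") as fh:
        for beat in dataset.beats:
            fh.write("\t".join(f"{v:.17g}" for v in beat.samples) + "\n")
    with manifest_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["row_id", "record_id", "r_index", "label_index", "label_name", "split"]
        )
        for i, beat in enumerate(dataset.beats):
            writer.writerow(
                [
                    i,
                    beat.source_record,
                    beat.r_index,
                    beat.label,
                    beat.label_name,
                    splits[i] if splits is not None else "",
                ]
            )
    return beats_path, manifest_path


def load_dataset(stem: str | Path) -> tuple[BeatDataset, list[str]]:
    """Read a dataset pair written by :func:`save_dataset`.

    Returns the dataset and the per-beat split assignment (empty strings
    where no split was recorded).
    """
    stem = Path(stem)
    beats_path = stem.with_name(stem.name + ".beats.tsv")
    manifest_path = stem.with_name(stem.name + ".manifest.csv")
    for p in (beats_path, manifest_path):
        if not p.exists():
            raise FileNotFoundError(f"dataset file not found: {p}")
    rows = []
    with beats_path.open() as fh:
        for ln in fh:
            if ln.strip():
                rows.append(np.array([float(v) for v in ln.split("\t")]))
    beats: list[Beat] = []
    splits: list[str] = []
    with manifest_path.open(newline="") as fh:
        for rec in csv.DictReader(fh):
            i = int(rec["row_id"])
            beats.append(
                Beat(
                    samples=rows[i],
                    label=int(rec["label_index"]),
                    source_record=rec["record_id"],
                    r_index=int(rec["r_index"]),
                )
            )
            splits.append(rec.get("split", "") or "")
    if len(beats) != len(rows):
        raise ValueError(
            f"manifest lists {len(beats)} beats but matrix has {len(rows)} rows"
        )
    return BeatDataset(beats), splits
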