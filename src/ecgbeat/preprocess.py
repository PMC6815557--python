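"""Signal preprocessing: wavelet denoising, beat segmentation, normalization.

The preprocessing chain applied to each record is

1. :func:`denoise_db6` — multilevel Daubechies-6 discrete wavelet transform;
   the deepest approximation band is zeroed when it lies below ~1 Hz
   (removes baseline wander) and the two finest detail bands are
   soft-thresholded with the universal threshold (removes high-frequency
   noise);
2. :func:`segment_beats` — fixed 250-sample windows centered on the
   annotated R-peaks (125 samples before, 124 after), skipping beats whose
   window would cross a record boundary;
3. :func:`zscore` — per-beat standardization to zero mean / unit sample
   standard deviation, making beats amplitude-invariant.

:func:`split_dataset` then partitions the pooled beats into train /
validation / test sets with per-class stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pywt

from .dataset import BEAT_LENGTH, R_POSITION, Beat, BeatDataset
from .records import BeatAnnotation, ECGRecord, map_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "DenoiseConfig",
    "denoise_db6",
    "segment_beats",
    "zscore",
    "build_dataset",
    "split_dataset",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Tunables of the db6 denoiser.

    ``level`` is the requested decomposition depth (capped at the maximum
    the signal length supports).  The approximation band is zeroed only when
    its upper edge ``fs / 2**(level+1)`` falls at or below
    ``baseline_max_hz`` — at 360 Hz and level 9 that band is 0–0.35 Hz,
    squarely the baseline-wander range; on short segments where the
    achievable depth leaves a band that still contains signal, the
    approximation is kept.  ``threshold_levels`` are the detail levels
    (1 = finest) soft-thresholded with the universal threshold
    ``sigma * sqrt(2 ln N)``, sigma estimated from the finest detail band as
    ``median(|d1|) / 0.6745``.  Setting ``remove_baseline=False`` and
    ``threshold_levels=()`` makes the transform a perfect reconstruction.
    """

    wavelet: str = "db6"
    level: int = 9
    remove_baseline: bool = True
    baseline_max_hz: float = 1.0
    threshold_levels: tuple[int, ...] = (1, 2)
    fixed_threshold: float | None = None  # overrides the universal estimate
    mode: str = "symmetric"


def denoise_db6(
    signal: np.ndarray, fs: float, config: DenoiseConfig = DenoiseConfig()
) -> np.ndarray:
    """Denoise a 1-D signal with the multilevel db6 wavelet transform.

    Output has the same length as the input.  Requires at least 64 samples
    (shorter windows leave no meaningful decomposition depth).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("denoise_db6 expects a 1-D signal")
    if signal.size < 64:
        raise ValueError(f"signal too short to denoise ({signal.size} < 64 samples)")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    wavelet = pywt.Wavelet(config.wavelet)
    max_level = pywt.dwt_max_level(signal.size, wavelet.dec_len)
    level = max(1, min(config.level, max_level))
    coeffs = pywt.wavedec(signal, wavelet, mode=config.mode, level=level)
    # coeffs = [a_L, d_L, ..., d_1]
    if config.remove_baseline and fs / 2 ** (level + 1) <= config.baseline_max_hz:
        coeffs[0] = np.zeros_like(coeffs[0])
    if config.threshold_levels:
        if config.fixed_threshold is not None:
            thr = config.fixed_threshold
        else:
            d1 = coeffs[-1]
            sigma = np.median(np.abs(d1)) / 0.6745 if d1.size else 0.0
            thr = sigma * np.sqrt(2.0 * np.log(signal.size))
        for lv in config.threshold_levels:
            if 1 <= lv <= level:
                coeffs[-lv] = pywt.threshold(coeffs[-lv], thr, mode="soft")
    out = pywt.waverec(coeffs, wavelet, mode=config.mode)
    return out[: signal.size]


def segment_beats(
    signal: np.ndarray,
    annotations: Sequence[BeatAnnotation],
    beat_length: int = BEAT_LENGTH,
    record_id: str = "",
) -> list[Beat]:
    """Cut fixed windows centered on annotated R-peaks.

    For each annotation whose symbol maps to one of the eight beat classes,
    the window ``[r - beat_length//2, r + beat_length//2 - 1]`` (inclusive)
    is emitted — for the default length 250 that is 125 samples before the
    R-peak and 124 after, with the R-peak at within-beat position 125.
    Annotations whose window crosses either record boundary are skipped
    (counted and logged), as are unmapped symbols.  Output order follows
    annotation order.
    """
    signal = np.asarray(signal, dtype=float)
    if beat_length % 2:
        raise ValueError(f"beat_length must be even, got {beat_length}")
    half = beat_length // 2
    beats: list[Beat] = []
    n_boundary = 0
    for ann in annotations:
        label = map_symbol(ann.symbol)
        if label is None:
            continue
        start = ann.sample_index - half
        stop = ann.sample_index + half  # exclusive
        if start < 0 or stop > signal.size:
            n_boundary += 1
            continue
        beats.append(
            Beat(
                samples=signal[start:stop].copy(),
                label=label.index,
                source_record=record_id,
                r_index=ann.sample_index,
            )
        )
    if n_boundary:
        logger.info(
            "record %s: skipped %d beat(s) whose window crossed a boundary",
            record_id or "<unnamed>",
            n_boundary,
        )
    return beats


def zscore(beat: Beat) -> Beat:
    """Standardize one beat to zero mean and unit sample standard deviation.

    A (near-)constant beat — sample std below 1e-12 — becomes the zero
    sequence rather than dividing by noise.
    """
    x = beat.samples
    mu = x.mean()
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd < 1e-12:
        samples = np.zeros_like(x)
    else:
        samples = (x - mu) / sd
    return replace(beat, samples=samples)


def build_dataset(
    records: Sequence[tuple[ECGRecord, Sequence[BeatAnnotation]]],
    denoise: bool = True,
    denoise_config: DenoiseConfig = DenoiseConfig(),
    beat_length: int = BEAT_LENGTH,
    channel: int = 0,
) -> BeatDataset:
    """Run denoise → segment → z-score over records and pool the beats.

    Channel 0 (MLII for most MIT-BIH records) is used by default.
    """
    beats: list[Beat] = []
    for record, annotations in records:
        sig = record.channel(channel)
        if denoise:
            sig = denoise_db6(sig, record.fs, denoise_config)
        segs = segment_beats(sig, annotations, beat_length, record.record_id)
        beats.extend(zscore(b) for b in segs)
    return BeatDataset(beats)


def _stratified_take(
    rng: np.random.Generator,
    pools: list[list[int]],
    total: int,
    fraction: float,
) -> list[int]:
    """Draw ``total`` indices from per-class pools, ~``fraction`` per class.

    Largest-remainder rounding hits the exact total; every nonempty class
    keeps at least one member in the residual pool, so small classes are
    never emptied by the draw.
    """
    sizes = np.array([len(p) for p in pools], dtype=float)
    quota = sizes * fraction
    base = np.floor(quota).astype(int)
    # cap: leave at least one member behind in each nonempty class
    cap = np.maximum(sizes.astype(int) - 1, 0)
    base = np.minimum(base, cap)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        for c in list(order) + list(range(len(pools))):
            if short == 0:
                break
            if base[c] < cap[c]:
                base[c] += 1
                short -= 1
    elif short < 0:
        order = np.argsort(quota - np.floor(quota), kind="stable")
        for c in order:
            if short == 0:
                break
            take = min(base[c], -short)
            base[c] -= take
            short += take
    taken: list[int] = []
    for c, pool in enumerate(pools):
        k = int(base[c])
        if k:
            taken.extend(pool[:k])
            del pool[:k]
    return taken


def split_dataset(
    dataset: BeatDataset,
    test_fraction: float = 0.10,
    val_fraction_of_rest: float = 0.10,
    seed: int = 0,
) -> tuple[BeatDataset, BeatDataset, BeatDataset]:
    """Partition beats into (train, validation, test), stratified per class.

    Test takes ``round(n * test_fraction)`` beats, validation
    ``round(remainder * val_fraction_of_rest)``; allocation across classes
    is proportional with largest-remainder rounding, and each class always
    retains at least one member in the training set.  Deterministic given
    the seed.
    """
    for name, frac in (("test_fraction", test_fraction),
                       ("val_fraction_of_rest", val_fraction_of_rest)):
        if not 0.0 < frac < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {frac}")
    n = dataset.n
    if n < 10:
        raise ValueError(f"dataset too small to split (n={n} < 10)")
    rng = np.random.default_rng(seed)
    labels = dataset.labels()
    pools: list[list[int]] = []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        pools.append(idx.tolist())
    n_test = int(round(n * test_fraction))
    test_idx = _stratified_take(rng, pools, n_test, test_fraction)
    n_rest = n - len(test_idx)
    n_val = int(round(n_rest * val_fraction_of_rest))
    val_idx = _stratified_take(rng, pools, n_val, val_fraction_of_rest)
    train_idx = [i for pool in pools for i in pool]
    return (
        dataset.subset(sorted(train_idx)),
        dataset.subset(sorted(val_idx)),
        dataset.subset(sorted(test_idx)),
    )
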