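"""Seeded synthetic ECG beats for testing the pipeline without any download.

Each beat class is a sum of Gaussian waves (a McSharry-style morphology):
P, Q, R, S, T bumps with per-class centers, widths and amplitudes chosen as
deliberate caricatures of the eight beat types — e.g. a widened QRS for the
bundle-branch-block classes, an absent P wave for the junctional escape
class, an inverted (retrograde) P for the nodal premature class.  The
caricatures make class separability provable by construction; they are not
clinically faithful morphologies.

Per-beat variation is jitter on wave centers (±3 samples) and amplitudes
(±10%), then additive noise: baseline-wander and powerline sinusoids with
random phase plus white Gaussian noise (:class:`NoiseSpec`).

A convenience preset scales the MIT-BIH eight-class beat counts
(75,020 / 8,072 / 7,255 / 2,546 / 229 / 150 / 83 / 16) to any total, so
generated datasets carry the same heavy imbalance as the real database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import BEAT_LENGTH, R_POSITION, Beat, BeatDataset
from .records import N_CLASSES

__all__ = [
    "Wave",
    "NoiseSpec",
    "TEMPLATES",
    "MITBIH_CLASS_COUNTS",
    "template_signal",
    "gen_beat",
    "gen_dataset",
    "add_noise",
    "scale_counts",
    "nearest_template_class",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: center offset in samples relative to the R-peak
    position (125), width (Gaussian sigma, samples), amplitude (mV)."""

    center: float
    width: float
    amplitude: float


#: Per-class wave tables.  Index order: N, LBBB, RBBB, APC, NESC, ABERR,
#: NPC, AESC.  Distinctions (all caricatures):
#:   LBBB/ABERR — widened R and deep S;  LBBB also discordant (negative) T
#:   RBBB       — secondary R' deflection after the QRS
#:   APC        — early, peaked P close to the QRS
#:   NESC       — no P wave, late rounded T
#:   NPC        — inverted (retrograde) P immediately before the QRS
#:   AESC       — low, slow P far from a low-amplitude QRS
TEMPLATES: dict[int, tuple[Wave, ...]] = {
    0: (  # N
        Wave(-45, 5, 0.15), Wave(-10, 2, -0.15), Wave(0, 3, 1.0),
        Wave(10, 2, -0.25), Wave(55, 12, 0.35),
    ),
    1: (  # LBBB
        Wave(-45, 5, 0.12), Wave(0, 9, 0.9), Wave(20, 7, -0.5),
        Wave(60, 12, -0.35),
    ),
    2: (  # RBBB
        Wave(-45, 5, 0.15), Wave(0, 3, 0.8), Wave(8, 2, -0.35),
        Wave(16, 4, 0.6), Wave(60, 12, -0.25),
    ),
    3: (  # APC
        Wave(-28, 3, 0.28), Wave(-10, 2, -0.12), Wave(0, 3, 1.0),
        Wave(10, 2, -0.2), Wave(50, 10, 0.3),
    ),
    4: (  # NESC
        Wave(-10, 2, -0.15), Wave(0, 3, 1.0), Wave(10, 2, -0.25),
        Wave(70, 12, 0.4),
    ),
    5: (  # ABERR
        Wave(-30, 4, 0.2), Wave(0, 7, 0.85), Wave(17, 5, -0.45),
        Wave(58, 11, 0.25),
    ),
    6: (  # NPC
        Wave(-18, 3, -0.22), Wave(0, 3, 1.0), Wave(10, 2, -0.25),
        Wave(55, 12, 0.3),
    ),
    7: (  # AESC
        Wave(-58, 7, 0.1), Wave(0, 4, 0.7), Wave(11, 2, -0.15),
        Wave(45, 9, 0.18),
    ),
}

#: Eight-class beat counts of the MIT-BIH arrhythmia database (N, LBBB,
#: RBBB, APC, NESC, ABERR, NPC, AESC); total 93,371.
MITBIH_CLASS_COUNTS: dict[int, int] = {
    0: 75020, 1: 8072, 2: 7255, 3: 2546, 4: 229, 5: 150, 6: 83, 7: 16,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise: baseline-wander and powerline sinusoids (random
    phase) plus white Gaussian noise.  All amplitudes in mV; defaults are
    zero (clean beats)."""

    baseline_amp: float = 0.0
    baseline_hz: float = 0.3
    powerline_amp: float = 0.0
    powerline_hz: float = 60.0
    white_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    @classmethod
    def mild(cls) -> "NoiseSpec":
        """Mild contamination: 0.10 mV baseline wander at 0.3 Hz, 0.05 mV
        powerline at 60 Hz, 0.05 mV white noise — small relative to the
        1 mV R-peak but visible on the trace."""
        return cls(
            baseline_amp=0.10, baseline_hz=0.3,
            powerline_amp=0.05, powerline_hz=60.0,
            white_sd=0.05,
        )


def template_signal(
    class_id: int,
    templates: Mapping[int, tuple[Wave, ...]] = TEMPLATES,
    length: int = BEAT_LENGTH,
    r_position: int = R_POSITION,
) -> np.ndarray:
    """The noiseless, jitter-free Gaussian-sum template for one class."""
    if class_id not in templates:
        raise ValueError(f"unknown class id {class_id}")
    t = np.arange(length, dtype=float)
    out = np.zeros(length)
    for w in templates[class_id]:
        out += w.amplitude * np.exp(
            -((t - (r_position + w.center)) ** 2) / (2.0 * w.width**2)
        )
    return out


def add_noise(
    signal: np.ndarray,
    noise: NoiseSpec,
    rng: np.random.Generator,
    fs: float = 360.0,
) -> np.ndarray:
    """Add baseline + powerline + white noise to a signal (seeded)."""
    signal = np.asarray(signal, dtype=float)
    t = np.arange(signal.size) / fs
    out = signal.copy()
    if noise.baseline_amp > 0:
        out += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp > 0:
        out += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.white_sd > 0:
        out += rng.normal(0.0, noise.white_sd, size=signal.size)
    return out


def gen_beat(
    class_id: int,
    templates: Mapping[int, tuple[Wave, ...]] = TEMPLATES,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
    jitter: bool = True,
    center_jitter: float = 3.0,
    amplitude_jitter: float = 0.10,
    fs: float = 360.0,
) -> Beat:
    """Generate one beat: jittered Gaussian-sum template plus noise.

    Jitter draws a uniform offset in ±``center_jitter`` samples per wave
    center and a uniform relative factor in ±``amplitude_jitter`` per wave
    amplitude.  With ``jitter=False`` and zero noise the beat equals the
    closed-form template exactly.
    """
    if class_id not in templates:
        raise ValueError(f"unknown class id {class_id}")
    if rng is None:
        rng = np.random.default_rng()
    t = np.arange(BEAT_LENGTH, dtype=float)
    out = np.zeros(BEAT_LENGTH)
    for w in templates[class_id]:
        center = w.center
        amp = w.amplitude
        if jitter:
            center = center + rng.uniform(-center_jitter, center_jitter)
            amp = amp * (1.0 + rng.uniform(-amplitude_jitter, amplitude_jitter))
        out += amp * np.exp(
            -((t - (R_POSITION + center)) ** 2) / (2.0 * w.width**2)
        )
    out = add_noise(out, noise, rng, fs=fs)
    return Beat(samples=out, label=class_id, source_record="synthetic",
                r_index=R_POSITION)


def scale_counts(total: int, proportions: Mapping[int, int] | None = None) -> dict[int, int]:
    """Scale a count table (MIT-BIH eight-class by default) to a new total
    with largest-remainder rounding.  Very rare classes may round to zero
    at small totals, exactly as a small draw from the real distribution
    would."""
    if total < 1:
        raise ValueError("total must be >= 1")
    props = dict(proportions or MITBIH_CLASS_COUNTS)
    grand = sum(props.values())
    quota = {c: total * v / grand for c, v in props.items()}
    base = {c: int(np.floor(q)) for c, q in quota.items()}
    short = total - sum(base.values())
    order = sorted(props, key=lambda c: (-(quota[c] - base[c]), c))
    for c in order[:short]:
        base[c] += 1
    return base


def gen_dataset(
    class_counts: Mapping[int, int],
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    templates: Mapping[int, tuple[Wave, ...]] = TEMPLATES,
    jitter: bool = True,
) -> BeatDataset:
    """Generate a dataset with exactly the requested per-class counts,
    deterministically shuffled."""
    counts = {c: int(n) for c, n in class_counts.items() if n}
    if any(n < 0 for n in counts.values()):
        raise ValueError("class counts must be nonnegative")
    if not counts:
        raise ValueError("all class counts are zero")
    rng = np.random.default_rng(seed)
    beats: list[Beat] = []
    for c in sorted(counts):
        for _ in range(counts[c]):
            beats.append(gen_beat(c, templates, noise, rng, jitter=jitter))
    order = rng.permutation(len(beats))
    return BeatDataset([beats[i] for i in order])


def nearest_template_class(
    samples: np.ndarray,
    templates: Mapping[int, tuple[Wave, ...]] = TEMPLATES,
) -> int:
    """Classify a beat by correlation with the noiseless class templates.

    An independent check that the generator's classes are separable: a
    beat should correlate best with its own class template.
    """
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    best_c, best_r = -1, -np.inf
    for c in sorted(templates):
        tmpl = template_signal(c, templates)
        tmpl = tmpl - tmpl.mean()
        r = float(np.dot(x, tmpl) / (np.linalg.norm(x) * np.linalg.norm(tmpl) + 1e-30))
        if r > best_r:
            best_c, best_r = c, r
    return best_c
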