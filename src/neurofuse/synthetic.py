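"""Seeded generators of paired EEG/video sequences with planted class signal.

Four regimes control where the class signal lives:

* ``eeg_only`` — class k sets the EEG oscillation frequency; the video blob
  moves in a random direction.
* ``video_only`` — class k sets the blob heading; EEG frequency is random.
* ``redundant`` — both modalities carry k.
* ``interaction_only`` — a bit ``a`` is planted in EEG, an independent bit
  ``b`` in video, and the label is ``a XOR b``; neither stream alone is
  predictive (binary labels only).

EEG channels are ``snr * sin(2 pi f t + phase)`` plus unit-variance white
noise; frequencies come from an evenly spaced 4-30 Hz grid. Video frames show
a bright Gaussian blob drifting along a class-conditional heading
(``2 pi k / |C|``) over a dark background plus pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import EEGSequence, LabelSequence, ValidationError, VideoSequence

__all__ = [
    "SynthSpec",
    "SynthDataset",
    "generate",
    "holdout_split",
    "class_frequencies",
]

REGIMES = ("eeg_only", "video_only", "redundant", "interaction_only")

_F_LO, _F_HI = 4.0, 30.0


@dataclass
class SynthSpec:
    n_sequences: int = 100
    T: int = 32
    d: int = 4
    frame_shape: tuple[int, int, int] = (16, 16, 1)
    n_classes: int = 2
    regime: str = "redundant"
    snr: float = 1.0
    seed: int = 0
    sampling_rate: float = 128.0

    def __post_init__(self):
        self.frame_shape = tuple(self.frame_shape)
        if self.regime not in REGIMES:
            raise ValidationError(f"regime must be one of {REGIMES}")
        if self.snr <= 0:
            raise ValidationError("snr must be positive")
        if self.n_classes < 2:
            raise ValidationError("need at least two classes")
        if self.n_sequences < self.n_classes:
            raise ValidationError("need at least one sequence per class")
        if self.regime == "interaction_only" and self.n_classes != 2:
            raise ValidationError("interaction_only is a binary (XOR) construction")
        if len(self.frame_shape) != 3 or min(self.frame_shape) < 1:
            raise ValidationError("frame_shape must be (h, w, c) with all >= 1")
        if self.T < 2 or self.d < 1:
            raise ValidationError("need T >= 2 and d >= 1")


def class_frequencies(n_classes: int) -> np.ndarray:
    """Evenly spaced oscillation frequencies on [4, 30] Hz, one per class."""
    return np.linspace(_F_LO, _F_HI, n_classes)


@dataclass
class SynthDataset(Sequence):
    """Sequence of (EEGSequence, VideoSequence, LabelSequence) triples plus
    the planted codes, exposed for leakage checks."""

    triples: list[tuple[EEGSequence, VideoSequence, LabelSequence]]
    sequence_labels: np.ndarray  # (N,)
    eeg_code: np.ndarray  # (N,) class/bit planted in the EEG stream
    video_code: np.ndarray  # (N,) class/bit planted in the video stream
    subject_ids: np.ndarray  # (N,) for future grouped splitting
    spec: SynthSpec

    def __len__(self) -> int:
        return len(self.triples)

    def __getitem__(self, i):
        return self.triples[i]

    def __iter__(self) -> Iterator:
        return iter(self.triples)


def _blob_video(
    rng: np.random.Generator,
    T: int,
    shape: tuple[int, int, int],
    heading: float,
    snr: float,
) -> np.ndarray:
    h, w, c = shape
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = max(h, w) / 8.0
    # near-centered start: the trajectory, not the offset, carries the class
    start = np.array(
        [rng.uniform(0.45 * h, 0.55 * h), rng.uniform(0.45 * w, 0.55 * w)]
    )
    # traverse about half the frame over the sequence
    vel = (max(h, w) / 2.0 / max(T - 1, 1)) * np.array(
        [np.sin(heading), np.cos(heading)]
    )
    frames = rng.standard_normal((T, h, w, c))
    amp = 2.0 * snr
    for t in range(T):
        cy, cx = np.clip(start + vel * t, [0, 0], [h - 1, w - 1])
        blob = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        frames[t] += blob[:, :, None]
    return frames


def _eeg_signal(
    rng: np.random.Generator,
    T: int,
    d: int,
    freq: float,
    snr: float,
    fs: float,
) -> np.ndarray:
    t = np.arange(T) / fs
    phases = rng.uniform(0, 2 * np.pi, size=d)
    signal = snr * np.sin(2 * np.pi * freq * t[:, None] + phases[None, :])
    return signal + rng.standard_normal((T, d))


def generate(spec: SynthSpec) -> SynthDataset:
    """Draw ``spec.n_sequences`` paired trials, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n_sequences, spec.n_classes
    freqs = class_frequencies(C)

    if spec.regime == "interaction_only":
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        labels = a ^ b
        eeg_code, video_code = a, b
    else:
        labels = rng.permutation(np.resize(np.arange(C), n))
        if spec.regime == "eeg_only":
            eeg_code = labels
            video_code = rng.integers(0, C, size=n)
        elif spec.regime == "video_only":
            eeg_code = rng.integers(0, C, size=n)
            video_code = labels
        else:  # redundant
            eeg_code = labels
            video_code = labels

    triples = []
    for i in range(n):
        if spec.regime == "video_only":
            freq = rng.uniform(_F_LO, _F_HI)
        else:
            freq = freqs[eeg_code[i]]
        if spec.regime == "eeg_only":
            heading = rng.uniform(0, 2 * np.pi)
        else:
            heading = 2 * np.pi * video_code[i] / C
        eeg = EEGSequence(
            _eeg_signal(rng, spec.T, spec.d, freq, spec.snr, spec.sampling_rate),
            sampling_rate=spec.sampling_rate,
        )
        video = VideoSequence(
            frames=_blob_video(rng, spec.T, spec.frame_shape, heading, spec.snr)
        )
        lab = LabelSequence(np.full(spec.T, labels[i]), n_classes=C)
        triples.append((eeg, video, lab))

    return SynthDataset(
        triples=triples,
        sequence_labels=np.asarray(labels, dtype=np.int64),
        eeg_code=np.asarray(eeg_code, dtype=np.int64),
        video_code=np.asarray(video_code, dtype=np.int64),
        subject_ids=np.arange(n, dtype=np.int64),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    ideal = total * fractions
    base = np.floor(ideal).astype(int)
    rem = ideal - base
    for idx in np.argsort(-rem, kind="stable")[: total - base.sum()]:
        base[idx] += 1
    return base


def holdout_split(
    dataset,
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, label-stratified train/val/test index sets.

    ``dataset`` may be a :class:`SynthDataset`, a list of triples, or a plain
    per-sequence label vector. Global split sizes follow the fractions by
    largest remainder exactly; per-class allocations are as proportional as
    integer seats allow.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.shape != (3,) or np.any(fractions <= 0):
        raise ValidationError("need three positive fractions")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")

    if isinstance(dataset, SynthDataset):
        labels = dataset.sequence_labels
    elif isinstance(dataset, np.ndarray):
        labels = dataset.astype(np.int64)
    else:
        labels = np.array([t[2].labels[0] for t in dataset], dtype=np.int64)
    n = labels.shape[0]
    targets = _largest_remainder(n, fractions)

    classes = np.unique(labels)
    rng = np.random.default_rng(seed)

    floors: dict[int, np.ndarray] = {}
    frac_parts: list[tuple[float, int, int]] = []
    for cls in classes:
        n_c = int((labels == cls).sum())
        if n_c < 3:
            raise ValidationError(
                f"class {cls} has {n_c} sequences, fewer than the 3 splits"
            )
        ideal = n_c * fractions
        floors[cls] = np.floor(ideal).astype(int)
        for s in range(3):
            frac_parts.append((float(ideal[s] - floors[cls][s]), int(cls), s))

    # distribute remaining per-class seats to the columns still short globally
    seats = {int(c): int((labels == c).sum() - floors[c].sum()) for c in classes}
    deficit = targets - np.sum([floors[c] for c in classes], axis=0)
    for _, cls, s in sorted(frac_parts, key=lambda x: -x[0]):
        if seats[cls] > 0 and deficit[s] > 0:
            floors[cls][s] += 1
            seats[cls] -= 1
            deficit[s] -= 1
    for cls in classes:  # fallback, cannot trigger unless ties exhausted a column
        while seats[int(cls)] > 0:
            s = int(np.argmax(deficit))
            floors[cls][s] += 1
            seats[int(cls)] -= 1
            deficit[s] -= 1

    parts: list[list[int]] = [[], [], []]
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        a, b = floors[cls][0], floors[cls][0] + floors[cls][1]
        parts[0].extend(idx[:a])
        parts[1].extend(idx[a:b])
        parts[2].extend(idx[b:])
    return tuple(np.sort(np.array(p, dtype=np.int64)) for p in parts)
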