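"""Readers and writers: EDF (European Data Format) for EEG, dense ``.npy``
containers for arrays, CSV for labels and training records, YAML for configs
and run manifests, ``.npz`` archives for checkpoints.

The EDF codec implements the plain 16-bit EDF layout (256-byte fixed header,
256 bytes per signal header, one data record here). Physical values are
quantized to the 16-bit digital range on write, so EDF round trips are exact
only to quantization; the dense container round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .model import EEGSequence, FusionModel, ModelConfig, ValidationError
from .synthetic import SynthDataset

__all__ = [
    "ParseError",
    "write_edf",
    "read_edf",
    "read_eeg",
    "write_dataset",
    "read_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "RunManifest",
    "sha256_file",
]


class ParseError(ValidationError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(eeg: EEGSequence, path) -> None:
    """Write one EEG trial as a single-record EDF file (channels as signals)."""
    samples = eeg.samples
    T, d = samples.shape
    fs = eeg.sampling_rate or 1.0
    duration = T / fs

    phys_min = samples.min(axis=0)
    phys_max = samples.max(axis=0)
    # avoid a zero physical span on constant channels
    flat = phys_max - phys_min < 1e-9
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((samples - phys_min) / scale + _EDF_DIG_MIN).astype("<i2")

    header_bytes = 256 + 256 * d
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad("1", 8))  # one data record
        fh.write(_pad(f"{duration:.6g}", 8))
        fh.write(_pad(str(d), 4))
        for i in range(d):
            fh.write(_pad(f"ch{i}", 16))
        for _ in range(d):
            fh.write(_pad("", 80))  # transducer
        for _ in range(d):
            fh.write(_pad("uV", 8))
        for i in range(d):
            fh.write(_pad(f"{phys_min[i]:.6g}", 8))
        for i in range(d):
            fh.write(_pad(f"{phys_max[i]:.6g}", 8))
        for _ in range(d):
            fh.write(_pad(str(_EDF_DIG_MIN), 8))
        for _ in range(d):
            fh.write(_pad(str(_EDF_DIG_MAX), 8))
        for _ in range(d):
            fh.write(_pad("", 80))  # prefiltering
        for _ in range(d):
            fh.write(_pad(str(T), 8))
        for _ in range(d):
            fh.write(_pad("", 32))
        fh.write(digital.T.tobytes())  # signal-major within the record


def read_edf(path) -> EEGSequence:
    """Read an EDF file written by :func:`write_edf` (or any plain 16-bit EDF
    whose signals share one sample count per record)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ParseError("EDF header truncated")

    def fld(off, width):
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        header_bytes = int(fld(184, 8))
        n_records = int(fld(236, 8))
        duration = float(fld(244, 8))
        d = int(fld(252, 4))
    except ValueError as exc:
        raise ParseError(f"malformed EDF header: {exc}") from exc
    if len(raw) < 256 + 256 * d:
        raise ParseError("EDF signal headers truncated")

    base = 256

    def sig_fld(block_index, width, i):
        off = base + block_index + width * i
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    # per-signal blocks in order: label16 transducer80 dim8 pmin8 pmax8
    # dmin8 dmax8 prefilter80 nsamples8 reserved32
    offs = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    starts = np.cumsum([0] + offs[:-1]) * d
    try:
        phys_min = np.array([float(sig_fld(starts[3], 8, i)) for i in range(d)])
        phys_max = np.array([float(sig_fld(starts[4], 8, i)) for i in range(d)])
        dig_min = np.array([int(sig_fld(starts[5], 8, i)) for i in range(d)])
        dig_max = np.array([int(sig_fld(starts[6], 8, i)) for i in range(d)])
        n_samples = np.array([int(sig_fld(starts[8], 8, i)) for i in range(d)])
    except ValueError as exc:
        raise ParseError(f"malformed EDF signal header: {exc}") from exc
    if len(set(n_samples.tolist())) != 1:
        raise ParseError("channels disagree on samples per record")
    T = int(n_samples[0]) * n_records
    expected = header_bytes + 2 * T * d
    if len(raw) < expected:
        raise ParseError("EDF data shorter than header promises")

    data = np.frombuffer(raw[header_bytes : header_bytes + 2 * T * d], dtype="<i2")
    per_rec = int(n_samples[0])
    out = np.empty((T, d))
    for r in range(n_records):
        block = data[r * per_rec * d : (r + 1) * per_rec * d].reshape(d, per_rec)
        scale = (phys_max - phys_min) / (dig_max - dig_min)
        out[r * per_rec : (r + 1) * per_rec] = (
            (block.T - dig_min) * scale + phys_min
        )
    fs = T / (duration * n_records) if duration > 0 else None
    return EEGSequence(out, sampling_rate=fs)


def read_eeg(path, format: str = "dense_array") -> EEGSequence:
    """Load one EEG trial; ``format`` is ``edf`` or ``dense_array`` (.npy).

    Non-finite samples are rejected (the documented NaN policy).
    """
    if format == "edf":
        return read_edf(path)
    if format == "dense_array":
        arr = np.load(path)
        if not np.all(np.isfinite(arr)):
            raise ParseError("dense array contains non-finite samples")
        return EEGSequence(arr)
    raise ValidationError(f"unknown EEG format {format!r}")


# ---------------------------------------------------------------------------
# Dataset directories
# ---------------------------------------------------------------------------


def write_dataset(dataset: SynthDataset, out_dir) -> None:
    """Dense array + CSV layout: eeg.npy, frames.npy/features.npy,
    labels.csv (sequence,step,label) and meta.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eeg = np.stack([t[0].samples for t in dataset])
    np.save(out / "eeg.npy", eeg)
    if dataset.triples[0][1].frames is not None:
        np.save(out / "frames.npy", np.stack([t[1].frames for t in dataset]))
    else:
        np.save(out / "features.npy", np.stack([t[1].features for t in dataset]))
    labels = np.stack([t[2].labels for t in dataset])
    n, T = labels.shape
    df = pd.DataFrame(
        {
            "sequence": np.repeat(np.arange(n), T),
            "step": np.tile(np.arange(T), n),
            "label": labels.ravel(),
        }
    )
    df.to_csv(out / "labels.csv", index=False)
    meta = {
        "spec": {**asdict(dataset.spec), "frame_shape": list(dataset.spec.frame_shape)},
        "n_classes": int(dataset.spec.n_classes),
        "subject_ids": dataset.subject_ids.tolist(),
        "eeg_code": dataset.eeg_code.tolist(),
        "video_code": dataset.video_code.tolist(),
    }
    (out / "meta.yaml").write_text(yaml.safe_dump(meta))


def read_dataset(in_dir):
    """Load a dataset directory back into stacked arrays.

    Returns ``(eeg, frames, features, labels, meta)`` with ``labels`` (N, T).
    """
    src = Path(in_dir)
    eeg_path = src / "eeg.npy"
    if not eeg_path.exists():
        raise ParseError(f"missing {eeg_path}")
    eeg = np.load(eeg_path)
    frames = features = None
    if (src / "frames.npy").exists():
        frames = np.load(src / "frames.npy")
    elif (src / "features.npy").exists():
        features = np.load(src / "features.npy")
    else:
        raise ParseError("dataset has neither frames.npy nor features.npy")
    df = pd.read_csv(src / "labels.csv")
    for col in ("sequence", "step", "label"):
        if col not in df.columns:
            raise ParseError(f"labels.csv missing column {col!r}")
    n = int(df["sequence"].max()) + 1
    T = int(df["step"].max()) + 1
    labels = np.full((n, T), -1, dtype=np.int64)
    labels[df["sequence"].to_numpy(), df["step"].to_numpy()] = df["label"].to_numpy()
    if (labels < 0).any():
        raise ParseError("labels.csv does not cover every (sequence, step)")
    meta = {}
    if (src / "meta.yaml").exists():
        meta = yaml.safe_load((src / "meta.yaml").read_text())
    for name, arr in (("eeg", eeg), ("frames", frames), ("features", features)):
        if arr is not None and not np.all(np.isfinite(arr)):
            raise ParseError(f"{name} array contains non-finite values")
    return eeg, frames, features, labels, meta


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: FusionModel, path) -> None:
    """Single .npz archive: all parameter arrays + config/variant/seed JSON."""
    meta = json.dumps(
        {"config": asdict(model.cfg), "variant": model.variant, "seed": model.seed}
    )
    np.savez(path, __meta__=np.array(meta), **model.state_arrays())


def load_checkpoint(path) -> FusionModel:
    with np.load(path) as archive:
        if "__meta__" not in archive:
            raise ParseError("checkpoint missing metadata entry")
        meta = json.loads(str(archive["__meta__"]))
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    model = FusionModel(cfg, seed=meta["seed"], variant=meta["variant"])
    model.load_state_arrays(arrays)
    return model


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte (timestamp aside)."""

    config: dict
    seed: int
    input_hashes: dict[str, str] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, config: dict, seed: int, inputs: dict[str, str]) -> "RunManifest":
        from . import __version__

        return cls(
            config=config,
            seed=seed,
            input_hashes=inputs,
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))
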