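"""Two-stream EEG + video sequence classifier with attention fusion.

The model maps a paired sequence ``(X, V)`` — ``X`` a ``T x d`` EEG sample
matrix and ``V`` a ``T x h x w x c`` frame stack (or ``T x h_v`` precomputed
frame features) — to per-time-step (or per-sequence) class probabilities.

Architecture
------------
1. **EEG stream** — temporal 1-D convolution (same padding, GELU) produces
   hidden states ``H^eeg (T x d_h)``; adaptive temporal attention with learned
   query/key projections pools them into context vectors.
2. **Video stream** — per-frame spatial attention scores every pixel
   embedding and pools each frame to an ``h_v`` vector; temporal attention
   then mirrors the EEG stream.
3. **Cross-modal fusion** — both context streams are projected to a shared
   width ``d_f``; attention weights ``softmax_j(ctx_eeg[t] . ctx_video[j])``
   mix the summed streams into the fused context.
4. **Head** — a linear layer + softmax, either per time step or on the
   time-mean of the fused context.

All learnable parameters live in ``FusionModel.params`` as autodiff tensors;
pure-numpy functional primitives (``attention``, ``knn_mask_attention``,
``predict``, ``sequence_cross_entropy``) are exposed for direct use and
verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor, constant, parameter

__all__ = [
    "ValidationError",
    "EEGSequence",
    "VideoSequence",
    "LabelSequence",
    "HiddenStates",
    "AttentionMatrix",
    "ContextBundle",
    "ModelConfig",
    "PredictionHead",
    "attention",
    "knn_mask_attention",
    "predict",
    "sequence_cross_entropy",
    "FusionModel",
    "count_parameters",
    "parameter_shapes",
    "estimate_flops",
    "flops_breakdown",
    "VARIANTS",
]

VARIANTS = ("full", "no_cross_modal", "no_adaptive_attention", "no_eeg_stream")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _require_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EEGSequence:
    """T x d matrix of EEG samples; ``sampling_rate`` is metadata only."""

    samples: np.ndarray
    sampling_rate: Optional[float] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or min(self.samples.shape) < 1:
            raise ValidationError("EEG samples must be a T x d matrix with T,d >= 1")
        _require_finite("EEG samples", self.samples)

    @property
    def n_steps(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class VideoSequence:
    """Either raw frames (T x h x w x c) or precomputed features (T x h_v)."""

    frames: Optional[np.ndarray] = None
    features: Optional[np.ndarray] = None

    def __post_init__(self):
        if (self.frames is None) == (self.features is None):
            raise ValidationError("provide exactly one of frames or features")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=np.float64)
            if self.frames.ndim != 4 or min(self.frames.shape) < 1:
                raise ValidationError("frames must be T x h x w x c")
            _require_finite("video frames", self.frames)
        else:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.ndim != 2 or min(self.features.shape) < 1:
                raise ValidationError("features must be T x h_v")
            _require_finite("video features", self.features)

    @property
    def n_steps(self) -> int:
        arr = self.frames if self.frames is not None else self.features
        return arr.shape[0]


@dataclass
class LabelSequence:
    """Length-T integer labels in {0, ..., n_classes-1}."""

    labels: np.ndarray
    n_classes: int
    class_names: Optional[list[str]] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D integer vector")
        if self.n_classes < 2:
            raise ValidationError("need at least two classes")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValidationError("labels out of range")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValidationError("class_names length must equal n_classes")


@dataclass
class HiddenStates:
    values: np.ndarray  # T x dim
    modality: str  # "eeg" | "video"

    def __post_init__(self):
        if self.modality not in ("eeg", "video"):
            raise ValidationError("modality must be 'eeg' or 'video'")
        self.values = np.asarray(self.values, dtype=np.float64)
        _require_finite("hidden states", self.values)


@dataclass
class AttentionMatrix:
    """Row-stochastic weight matrix (query step t rows, key step j cols);
    square T x T in the temporal/cross uses, rectangular for masked rows."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValidationError("attention weights must be a 2-D matrix")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise ValidationError("attention weights must lie in [0, 1]")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("attention rows must sum to 1")


@dataclass
class ContextBundle:
    """Per-step context vectors and attention maps from one forward pass."""

    eeg_context: Optional[np.ndarray]
    video_context: np.ndarray
    cross_context: np.ndarray
    attn_eeg: Optional[AttentionMatrix]
    attn_video: AttentionMatrix
    attn_cross: Optional[AttentionMatrix]


@dataclass
class ModelConfig:
    d: int = 4  # EEG channels
    h: int = 16  # frame height
    w: int = 16  # frame width
    c: int = 1  # frame color channels
    h_v: int = 8  # video hidden width
    d_h: int = 8  # EEG hidden width
    d_f: int = 8  # shared fusion width
    n_classes: int = 2
    conv_kernel: int = 3
    dropout_p: float = 0.5
    use_knn_attention: bool = False
    knn_k: int = 1
    use_positional_encoding: bool = True
    scale_by_sqrt_dim: bool = True
    head_mode: str = "per_step"  # or "per_sequence"
    max_time: int = 256  # capacity of the learned positional table

    def __post_init__(self):
        for name in ("d", "h", "w", "c", "h_v", "d_h", "d_f", "max_time"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            raise ValidationError("conv_kernel must be odd and positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValidationError("dropout_p must be in [0, 1)")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.head_mode not in ("per_step", "per_sequence"):
            raise ValidationError("head_mode must be per_step or per_sequence")


@dataclass
class PredictionHead:
    weight: np.ndarray  # d_f x n_classes
    bias: np.ndarray  # n_classes

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weight.ndim != 2 or self.bias.ndim != 1:
            raise ValidationError("head weight must be 2-D and bias 1-D")
        if self.weight.shape[1] != self.bias.shape[0]:
            raise ValidationError("head weight/bias class dimensions disagree")


# ---------------------------------------------------------------------------
# Functional primitives (pure numpy)
# ---------------------------------------------------------------------------


def _row_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def attention(
    queries: np.ndarray,
    keys: np.ndarray,
    values: np.ndarray,
    scale_by_sqrt_dim: bool = True,
) -> tuple[np.ndarray, AttentionMatrix]:
    """Scaled dot-product attention over one sequence.

    ``weights[t, j] = softmax_j(s * q_t . k_j)`` with ``s = 1/sqrt(k_width)``
    when ``scale_by_sqrt_dim`` else 1; ``context[t] = sum_j weights[t,j] v_j``.
    """
    queries = np.asarray(queries, dtype=np.float64)
    keys = np.asarray(keys, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    for name, arr in (("queries", queries), ("keys", keys), ("values", values)):
        if arr.ndim != 2:
            raise ValidationError(f"{name} must be 2-D")
        _require_finite(name, arr)
    if queries.shape[0] < 1:
        raise ValidationError("need at least one time step")
    if queries.shape[1] != keys.shape[1]:
        raise ValidationError("queries and keys must share their width")
    if keys.shape[0] != values.shape[0]:
        raise ValidationError("keys and values must share their length")
    scale = 1.0 / np.sqrt(queries.shape[1]) if scale_by_sqrt_dim else 1.0
    logits = scale * (queries @ keys.T)
    weights = _row_softmax(logits)
    return weights @ values, AttentionMatrix(weights)


def knn_mask_attention(logit_matrix: np.ndarray, k: int) -> AttentionMatrix:
    """Row-softmax after keeping only each row's k largest logits.

    Ties are broken toward the lower column index. ``k == T`` reproduces the
    plain softmax exactly.
    """
    logits = np.asarray(logit_matrix, dtype=np.float64)
    if logits.ndim != 2:
        raise ValidationError("logit matrix must be 2-D")
    _require_finite("logits", logits)
    T = logits.shape[1]
    if not (1 <= k <= T):
        raise ValidationError(f"k must satisfy 1 <= k <= {T}")
    mask = _topk_mask(logits, k)
    masked = np.where(mask, logits, -np.inf)
    return AttentionMatrix(_row_softmax(masked))


def _topk_mask(logits: np.ndarray, k: int) -> np.ndarray:
    """Boolean keep-mask of each row's k largest entries, ties to lower index."""
    # stable argsort on -logits puts equal logits in column order
    order = np.argsort(-logits, axis=-1, kind="stable")
    mask = np.zeros(logits.shape, dtype=bool)
    np.put_along_axis(mask, order[..., :k], True, axis=-1)
    return mask


def predict(cross: np.ndarray, head: PredictionHead) -> np.ndarray:
    """Linear layer + softmax: row t gives class probabilities for step t."""
    cross = np.asarray(cross, dtype=np.float64)
    if cross.ndim != 2 or cross.shape[1] != head.weight.shape[0]:
        raise ValidationError("fused context width does not match head")
    return _row_softmax(cross @ head.weight + head.bias)


def sequence_cross_entropy(
    class_probs: np.ndarray, y: LabelSequence, clamp: float = 1e-12
) -> float:
    """``-sum_t log p(y_t)`` with probabilities clamped at ``clamp``.

    The clamp bounds the loss at ``-T log(clamp)`` instead of returning inf
    when a true class receives zero probability.
    """
    probs = np.asarray(class_probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValidationError("class_probs must be T x n_classes")
    if probs.shape[0] != y.labels.shape[0]:
        raise ValidationError("probs and labels disagree on sequence length")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1")
    picked = probs[np.arange(probs.shape[0]), y.labels]
    return float(-np.sum(np.log(np.maximum(picked, clamp))))


# ---------------------------------------------------------------------------
# The assembled model
# ---------------------------------------------------------------------------


def parameter_shapes(cfg: ModelConfig, variant: str = "full") -> dict[str, tuple[int, ...]]:
    """Shapes of every learned array the model allocates for ``variant``."""
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    shapes: dict[str, tuple[int, ...]] = {}
    if variant != "no_eeg_stream":
        shapes["eeg.conv_w"] = (cfg.conv_kernel, cfg.d, cfg.d_h)
        shapes["eeg.conv_b"] = (cfg.d_h,)
        shapes["eeg.wq"] = (cfg.d_h, cfg.d_h)
        shapes["eeg.wk"] = (cfg.d_h, cfg.d_h)
        if cfg.use_positional_encoding:
            shapes["eeg.pos"] = (cfg.max_time, cfg.d_h)
        shapes["fuse.proj_eeg_w"] = (cfg.d_h, cfg.d_f)
        shapes["fuse.proj_eeg_b"] = (cfg.d_f,)
    shapes["video.embed_w"] = (cfg.c, cfg.h_v)
    shapes["video.embed_b"] = (cfg.h_v,)
    if cfg.use_positional_encoding:
        # per-pixel embedding so pooled frames can encode *where* the mass is
        shapes["video.pix_pos"] = (cfg.h * cfg.w, cfg.h_v)
    shapes["video.score"] = (cfg.h_v, 1)
    shapes["video.wq"] = (cfg.h_v, cfg.h_v)
    shapes["video.wk"] = (cfg.h_v, cfg.h_v)
    if cfg.use_positional_encoding:
        shapes["video.pos"] = (cfg.max_time, cfg.h_v)
    shapes["fuse.proj_video_w"] = (cfg.h_v, cfg.d_f)
    shapes["fuse.proj_video_b"] = (cfg.d_f,)
    shapes["head.w"] = (cfg.d_f, cfg.n_classes)
    shapes["head.b"] = (cfg.n_classes,)
    return shapes


def count_parameters(cfg: ModelConfig, variant: str = "full") -> int:
    """Exact number of learned scalars in the assembled model."""
    return int(
        sum(int(np.prod(s)) for s in parameter_shapes(cfg, variant).values())
    )


def flops_breakdown(cfg: ModelConfig, T: int, variant: str = "full") -> dict[str, int]:
    """Documented per-layer multiply-accumulate counts for one forward pass.

    conv: ``T*d*d_h*kernel``; each attention use: ``T^2*k + T^2*m`` (logits
    plus weighted sum, k = query/key width, m = value width); q/k projections
    and spatial embedding as plain matrix products; head: ``T*d_f*|C|``.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    P = cfg.h * cfg.w
    out: dict[str, int] = {}
    adaptive = variant != "no_adaptive_attention"
    if variant != "no_eeg_stream":
        out["eeg_conv"] = T * cfg.d * cfg.d_h * cfg.conv_kernel
        if adaptive:
            out["eeg_qk_proj"] = 2 * T * cfg.d_h * cfg.d_h
            out["eeg_attention"] = T * T * cfg.d_h + T * T * cfg.d_h
        out["eeg_fuse_proj"] = T * cfg.d_h * cfg.d_f
    out["video_spatial"] = T * P * cfg.c * cfg.h_v + 2 * T * P * cfg.h_v
    if adaptive:
        out["video_qk_proj"] = 2 * T * cfg.h_v * cfg.h_v
        out["video_attention"] = T * T * cfg.h_v + T * T * cfg.h_v
    out["video_fuse_proj"] = T * cfg.h_v * cfg.d_f
    if variant == "full" or (variant == "no_adaptive_attention"):
        if variant == "full":
            out["cross_attention"] = T * T * cfg.d_f + T * T * cfg.d_f
        else:  # uniform cross mixing is still a T^2 weighted sum
            out["cross_attention"] = T * T * cfg.d_f
    out["head"] = T * cfg.d_f * cfg.n_classes
    return out


def estimate_flops(cfg: ModelConfig, T: int, variant: str = "full") -> int:
    return int(sum(flops_breakdown(cfg, T, variant).values()))


def _filterbank_conv_init(
    shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Frequency-selective conv init: alternating low-pass / high-pass
    temporal filters with random channel mixes, so hidden dims start out
    spectrally diverse (filterbank-style, as in EEG conv front-ends)."""
    K, d, d_h = shape
    taps = np.hanning(K + 2)[1:-1]
    taps = taps / np.linalg.norm(taps)
    alt = taps * (-1.0) ** np.arange(K)  # high-pass mirror
    data = np.empty(shape)
    for o in range(d_h):
        base = taps if o % 2 == 0 else alt
        mix = rng.uniform(-1.0, 1.0, size=d)
        mix = mix / max(np.linalg.norm(mix), 1e-12)
        data[:, :, o] = np.outer(base, mix)
    data += 0.05 * rng.standard_normal(shape)
    return data


def _video_pos_init(max_time: int, dim: int) -> np.ndarray:
    """Temporal code for the video stream: when width allows, the last four
    dims hold a banding sin/cos pair (period ``max_time/2``) and a slow
    ramp pair (period ``max_time``); low dims are left free for spatial
    content. Falls back to a plain sinusoid table for narrow widths."""
    if dim < 7:
        return 0.5 * _sinusoid_table(max_time, dim)
    t = np.arange(max_time)
    pos = np.zeros((max_time, dim))
    band = dim - 4
    pos[:, band] = 2.0 * np.sin(2 * np.pi * t / (max_time / 2))
    pos[:, band + 1] = 2.0 * np.cos(2 * np.pi * t / (max_time / 2))
    pos[:, band + 2] = 2.0 * np.sin(2 * np.pi * t / max_time)
    pos[:, band + 3] = 2.0 * np.cos(2 * np.pi * t / max_time)
    return pos


def _sinusoid_table(n: int, dim: int) -> np.ndarray:
    """Transformer-style fixed sinusoid table (used as an init, then learned)."""
    pos = np.arange(n)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


def _coordinate_table(
    h: int, w: int, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-pixel embedding init: centered y/x ramps in the first two columns
    plus small noise, so spatial position starts out linearly decodable."""
    yy, xx = np.mgrid[0:h, 0:w]
    table = 0.05 * rng.standard_normal((h * w, dim))
    table[:, 0] += ((yy.ravel() - (h - 1) / 2) / max(h, 1)) * 2.0
    if dim > 1:
        table[:, 1] += ((xx.ravel() - (w - 1) / 2) / max(w, 1)) * 2.0
    return table


class FusionModel:
    """The assembled two-stream classifier.

    Parameters are initialized uniformly scaled by fan-in from a seeded
    generator; all stochastic behavior (init, dropout) flows from ``seed``.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0, variant: str = "full"):
        if variant not in VARIANTS:
            raise ValidationError(f"unknown variant {variant!r}")
        self.cfg = cfg
        self.variant = variant
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        for name, shape in parameter_shapes(cfg, variant).items():
            fan_in = shape[0] if len(shape) == 1 else int(np.prod(shape[:-1]))
            bound = 1.0 / np.sqrt(fan_in)
            if name.endswith((".conv_b", ".embed_b", "_b", ".b")):
                data = np.zeros(shape)
            elif name == "eeg.conv_w":
                data = _filterbank_conv_init(shape, rng)
            elif name == "video.pos":
                # multi-scale pairs: a banding pair (period max_time/2) for
                # near-local temporal attention plus a slow ramp pair
                # (period max_time) giving a monotone time code
                data = _video_pos_init(cfg.max_time, cfg.h_v)
            elif name == "eeg.pos":
                # smooth (sinusoidal) start so nearby steps get nearby codes
                data = 0.5 * _sinusoid_table(*shape)
            elif name == "video.pix_pos":
                # coordinate ramps: position becomes a locally linear code
                data = _coordinate_table(cfg.h, cfg.w, cfg.h_v, rng)
            elif name in ("video.wq", "video.wk") and cfg.h_v >= 7:
                # project onto the banding posenc pair: attention starts out
                # banded around the diagonal, preserving temporal trends
                sel = np.zeros(shape)
                band = cfg.h_v - 4
                sel[band, band] = sel[band + 1, band + 1] = 1.0
                data = 1.5 * sel + 0.1 * rng.standard_normal(shape)
            elif name.endswith((".wq", ".wk")):
                # identity component keeps attention near-local at init
                data = rng.uniform(-bound, bound, size=shape) + 0.5 * np.eye(shape[0])
            elif name == "video.embed_w" and cfg.h_v >= 4:
                # dedicate one axis to mean pixel intensity; positional ramps
                # occupy dims 0-1 and the temporal codes the trailing dims
                data = np.zeros(shape)
                data[:, 2] = 1.0 / np.sqrt(shape[0])
                data += 0.02 * rng.standard_normal(shape)
            else:
                data = rng.uniform(-bound, bound, size=shape)
            self.params[name] = parameter(data)
        if "video.score" in self.params:
            # align the spatial score with the intensity embedding so bright
            # pixels drive the pooling from the start (saliency-aligned init)
            w = self.params["video.embed_w"].data
            direction = w.sum(axis=0)
            norm2 = float(direction @ direction)
            if norm2 > 1e-12:
                self.params["video.score"].data = (
                    3.0 * direction[:, None] / norm2
                )
        self._dropout_rng = np.random.default_rng(rng.integers(2**63))

    # -- bookkeeping ---------------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        if set(arrays) != set(self.params):
            raise ValidationError("checkpoint parameter names do not match model")
        for k, v in arrays.items():
            if v.shape != self.params[k].data.shape:
                raise ValidationError(f"shape mismatch for parameter {k}")
            self.params[k].data = np.array(v, dtype=np.float64)

    # -- internal attention helper -------------------------------------------
    def _temporal_attention(
        self, h: Tensor, wq: Tensor, wk: Tensor, width: int
    ) -> tuple[Tensor, Tensor]:
        """Returns (context, attention weights); shapes (..., T, m), (..., T, T)."""
        T = h.shape[-2]
        if self.variant == "no_adaptive_attention":
            shape = h.shape[:-2] + (T, T)
            attn = constant(np.full(shape, 1.0 / T))
            return attn @ h, attn
        q = h @ wq
        k = h @ wk
        scale = 1.0 / np.sqrt(width) if self.cfg.scale_by_sqrt_dim else 1.0
        logits = (q @ k.swapaxes(-1, -2)) * scale
        if self.cfg.use_knn_attention:
            kk = min(self.cfg.knn_k, T)
            keep = _topk_mask(logits.data, kk)
            logits = logits.masked_fill(~keep, -1e30)
        attn = logits.softmax(axis=-1)
        return attn @ h, attn

    # -- stream encoders -------------------------------------------------------
    def _eeg_hidden(self, x: Tensor) -> Tensor:
        h = x.conv1d_same(self.params["eeg.conv_w"], self.params["eeg.conv_b"]).gelu()
        if self.cfg.use_positional_encoding:
            T = h.shape[-2]
            if T > self.cfg.max_time:
                raise ValidationError("sequence longer than positional table")
            h = h + self.params["eeg.pos"][:T]
        return h

    def _video_hidden(self, frames: Tensor | None, features: Tensor | None) -> Tensor:
        if (frames is None) == (features is None):
            raise ValidationError("provide exactly one of frames or features")
        if features is not None:
            h = features
        else:
            B_shape = frames.shape[:-3]
            P = frames.shape[-3] * frames.shape[-2]
            pix = frames.reshape(B_shape + (P, frames.shape[-1]))
            W, b = self.params["video.embed_w"], self.params["video.embed_b"]
            u = self.params["video.score"]
            # emb_p = pix_p @ W + b (+ pix_pos_p); pooling is linear in emb,
            # so compute scores and the pooled vector without materializing
            # the (..., P, h_v) embedding tensor:
            #   score_p = pix_p @ (W u) + (b + pix_pos_p) @ u
            #   pooled  = (sum_p a_p pix_p) @ W + b + sum_p a_p pix_pos_p
            scores = pix @ (W @ u) + b.reshape(1, -1) @ u
            if self.cfg.use_positional_encoding:
                pos = self.params["video.pix_pos"]
                scores = scores + (pos @ u).reshape(P, 1)
            alpha = scores.softmax(axis=-2)  # (..., P, 1)
            h = (alpha * pix).sum(axis=-2) @ W + b
            if self.cfg.use_positional_encoding:
                posmix = alpha.swapaxes(-1, -2) @ pos  # (..., 1, h_v)
                h = h + posmix.reshape(B_shape + (pos.shape[-1],))
        if self.cfg.use_positional_encoding:
            T = h.shape[-2]
            if T > self.cfg.max_time:
                raise ValidationError("sequence longer than positional table")
            h = h + self.params["video.pos"][:T]
        return h

    # -- forward ---------------------------------------------------------------
    def forward(
        self,
        eeg: np.ndarray | None,
        video_frames: np.ndarray | None = None,
        video_features: np.ndarray | None = None,
        train: bool = False,
    ) -> Tensor:
        """Batched forward pass.

        ``eeg``: (B, T, d); ``video_frames``: (B, T, h, w, c) or
        ``video_features``: (B, T, h_v). Returns class-probability tensor of
        shape (B, T, C) in ``per_step`` mode or (B, C) in ``per_sequence``.
        """
        cfg = self.cfg
        p_drop = cfg.dropout_p if train else 0.0

        pv = self._video_stream(video_frames, video_features, p_drop)
        if self.variant == "no_eeg_stream":
            cross = pv
        else:
            if eeg is None:
                raise ValidationError("this variant requires EEG input")
            pe = self._eeg_stream(np.asarray(eeg, dtype=np.float64), p_drop)
            cross = self._fuse(pe, pv)
        return self._head(cross)

    def _eeg_stream(self, eeg: np.ndarray, p_drop: float) -> Tensor:
        h = self._eeg_hidden(constant(eeg))
        ctx, _ = self._temporal_attention(
            h, self.params["eeg.wq"], self.params["eeg.wk"], self.cfg.d_h
        )
        if p_drop > 0:
            ctx = ctx.dropout(p_drop, self._dropout_rng)
        return ctx @ self.params["fuse.proj_eeg_w"] + self.params["fuse.proj_eeg_b"]

    def _video_stream(
        self,
        frames: np.ndarray | None,
        features: np.ndarray | None,
        p_drop: float,
    ) -> Tensor:
        ft = constant(np.asarray(frames, dtype=np.float64)) if frames is not None else None
        fe = (
            constant(np.asarray(features, dtype=np.float64))
            if features is not None
            else None
        )
        h = self._video_hidden(ft, fe)
        ctx, _ = self._temporal_attention(
            h, self.params["video.wq"], self.params["video.wk"], self.cfg.h_v
        )
        if p_drop > 0:
            ctx = ctx.dropout(p_drop, self._dropout_rng)
        return ctx @ self.params["fuse.proj_video_w"] + self.params["fuse.proj_video_b"]

    def _fuse(self, pe: Tensor, pv: Tensor) -> Tensor:
        """Cross-modal mixing of the two projected context streams."""
        T = pe.shape[-2]
        if self.variant == "no_cross_modal":
            return pe + pv
        if self.variant == "no_adaptive_attention":
            attn = constant(np.full(pe.shape[:-2] + (T, T), 1.0 / T))
            return attn @ (pe + pv)
        scale = 1.0 / np.sqrt(self.cfg.d_f) if self.cfg.scale_by_sqrt_dim else 1.0
        logits = (pe @ pv.swapaxes(-1, -2)) * scale
        attn = logits.softmax(axis=-1)
        return attn @ (pe + pv)

    def _head(self, cross: Tensor) -> Tensor:
        if self.cfg.head_mode == "per_sequence":
            cross = cross.mean(axis=-2)
        logits = cross @ self.params["head.w"] + self.params["head.b"]
        return logits.softmax(axis=-1)

    # -- single-sequence inspection API ---------------------------------------
    def encode_eeg(
        self, x: EEGSequence
    ) -> tuple[HiddenStates, np.ndarray, AttentionMatrix]:
        """Hidden states, attention-pooled context and weights for one EEG trial."""
        if self.variant == "no_eeg_stream":
            raise ValidationError("variant has no EEG stream")
        if x.samples.shape[1] != self.cfg.d:
            raise ValidationError("EEG channel count does not match config")
        h = self._eeg_hidden(constant(x.samples))
        ctx, attn = self._temporal_attention(
            h, self.params["eeg.wq"], self.params["eeg.wk"], self.cfg.d_h
        )
        return (
            HiddenStates(h.data, "eeg"),
            ctx.data,
            AttentionMatrix(attn.data),
        )

    def encode_video(
        self, v: VideoSequence
    ) -> tuple[HiddenStates, np.ndarray, AttentionMatrix]:
        ft = constant(v.frames) if v.frames is not None else None
        fe = constant(v.features) if v.features is not None else None
        h = self._video_hidden(ft, fe)
        ctx, attn = self._temporal_attention(
            h, self.params["video.wq"], self.params["video.wk"], self.cfg.h_v
        )
        return (
            HiddenStates(h.data, "video"),
            ctx.data,
            AttentionMatrix(attn.data),
        )

    def cross_modal_fuse(
        self, ctx_eeg: np.ndarray, ctx_video: np.ndarray
    ) -> tuple[np.ndarray, AttentionMatrix]:
        """Fuse already-projected context streams (both T x d_f)."""
        ctx_eeg = np.asarray(ctx_eeg, dtype=np.float64)
        ctx_video = np.asarray(ctx_video, dtype=np.float64)
        if ctx_eeg.shape != ctx_video.shape:
            raise ValidationError("context streams must share shape T x d_f")
        if ctx_eeg.shape[1] != self.cfg.d_f:
            raise ValidationError("context width must equal d_f")
        out = self._fuse(constant(ctx_eeg), constant(ctx_video))
        T = ctx_eeg.shape[0]
        if self.variant in ("no_cross_modal",):
            attn = AttentionMatrix(np.eye(T))
        elif self.variant == "no_adaptive_attention":
            attn = AttentionMatrix(np.full((T, T), 1.0 / T))
        else:
            scale = 1.0 / np.sqrt(self.cfg.d_f) if self.cfg.scale_by_sqrt_dim else 1.0
            attn = AttentionMatrix(_row_softmax(scale * (ctx_eeg @ ctx_video.T)))
        return out.data, attn

    def describe(
        self, x: EEGSequence | None, v: VideoSequence
    ) -> ContextBundle:
        """Full inspection pass for one paired trial (no dropout)."""
        hv, ctx_v, attn_v = self.encode_video(v)
        pv = (
            ctx_v @ self.params["fuse.proj_video_w"].data
            + self.params["fuse.proj_video_b"].data
        )
        if self.variant == "no_eeg_stream":
            return ContextBundle(None, ctx_v, pv, None, attn_v, None)
        if x is None:
            raise ValidationError("this variant requires EEG input")
        he, ctx_e, attn_e = self.encode_eeg(x)
        pe = (
            ctx_e @ self.params["fuse.proj_eeg_w"].data
            + self.params["fuse.proj_eeg_b"].data
        )
        cross, attn_c = self.cross_modal_fuse(pe, pv)
        return ContextBundle(ctx_e, ctx_v, cross, attn_e, attn_v, attn_c)

    def prediction_head(self) -> PredictionHead:
        return PredictionHead(self.params["head.w"].data, self.params["head.b"].data)

    # -- loss ------------------------------------------------------------------
    def loss(
        self,
        probs: Tensor,
        labels: np.ndarray,
        clamp: float = 1e-12,
    ) -> Tensor:
        """Mean-over-batch cross-entropy; labels (B, T) or (B,) to match probs."""
        labels = np.asarray(labels, dtype=np.int64)
        picked_idx = tuple(np.indices(labels.shape)) + (labels,)
        picked = probs[picked_idx].clamp_min(clamp)
        per_item = -picked.log()
        if labels.ndim == 2:  # sum over time as the loss prescribes
            per_item = per_item.sum(axis=-1)
        return per_item.mean()
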