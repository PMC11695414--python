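# neurofuse

Two-stream EEG + video sequence classification with adaptive temporal
attention, per-frame spatial attention, and cross-modal attention fusion —
plus the training strategy (cosine-cyclic learning rate with warm restarts,
global gradient-norm clipping, Adam with decoupled weight decay, early
stopping), a synthetic paired-data generator with controllable unimodal and
cross-modal class signal, a metric suite, and an ablation harness.

The model maps a paired trial `(X, V)` — `X` a `T x d` EEG sample matrix and
`V` a `T x h x w x c` frame stack (or `T x h_v` precomputed features) — to
per-time-step or per-sequence class probabilities:

1. **EEG stream**: temporal 1-D convolution (same padding, GELU) then
   adaptive scaled dot-product attention over time.
2. **Video stream**: spatial attention pools pixel embeddings per frame,
   then temporal attention as in the EEG stream.
3. **Fusion**: both context streams are projected to a shared width; cross
   attention `softmax_j(ctx_eeg[t] . ctx_video[j])` mixes the summed streams.
4. **Head**: linear + softmax.

Ablation variants: `full`, `no_cross_modal` (per-step sum instead of cross
attention), `no_adaptive_attention` (uniform 1/T pooling), `no_eeg_stream`
(video-only path). Optional top-k attention masking and learned positional
encodings (temporal and per-pixel) are available via `ModelConfig` flags.

Everything runs on numpy with a small built-in reverse-mode autodiff engine
(`neurofuse.autodiff`) — no deep-learning framework required. All runs are
bit-reproducible from a single seed.

## CLI

```bash
# write a config (see tests/test_cli.py for a full example), then:
neurofuse simulate --spec config.yaml --out data/           # synthetic dataset
neurofuse train    --data data/ --config config.yaml --out run/
neurofuse train    --data data/ --config config.yaml --out run2/ --ablate no_cross_modal
neurofuse evaluate --checkpoint run/checkpoint.npz --data data/ --out eval/
neurofuse ablate   --spec config.yaml --config config.yaml --seeds 5 --out abl/
```

The config file has `synth:`, `model:`, `train:` and `data:` sections
mirroring `SynthSpec`, `ModelConfig`, `TrainConfig` and the split fractions;
flags override file values and the merged effective config is written next
to every output. Each `train` run emits `checkpoint.npz`, `record.csv` and a
`manifest.yaml` whose output hashes are identical across reruns with the
same inputs and seed.

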