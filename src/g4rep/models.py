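"""The five sequence-classifier architectures.

All five map a padded batch of per-residue feature matrices to one binding
probability per sequence:

1. two stacked LSTM layers -> two position-wise FC+sigmoid layers -> masked
   mean pooling;
2. as 1, with an additive (Bahdanau-style) attention recombination between
   the LSTM layers;
3. a 1-D convolution + ReLU in front of architecture 1;
4. a 1-D convolution + ReLU in front of architecture 2;
5. convolution + ReLU followed directly by the two FC+sigmoid layers and
   pooling (no recurrence).

Recurrence is unidirectional; the convolution uses same-padding and masked
positions are re-zeroed after it so padding can never leak into valid
positions; pooling averages over valid positions only.  Consequently the
score of a sequence is invariant to how much padding its batch carries.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encode import EncodedBatch

ARCHS_WITH_CONV = {3, 4, 5}
ARCHS_WITH_LSTM = {1, 2, 3, 4}
ARCHS_WITH_ATTENTION = {2, 4}


@dataclass(frozen=True)
class ModelConfig:
    architecture: int = 1
    input_dim: int = 20
    lstm_hidden: int = 128
    lstm_layers_stacked: int = 2  # fixed where recurrence is present
    conv_filters: int = 64
    conv_kernel: int = 7
    fc_hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in {1, 2, 3, 4, 5}:
            raise ValueError("architecture must be one of 1..5")
        if self.conv_kernel % 2 != 1 or self.conv_kernel < 1:
            raise ValueError("conv_kernel must be odd and positive")
        if min(self.lstm_hidden, self.conv_filters, self.fc_hidden, self.input_dim) < 1:
            raise ValueError("layer sizes must be positive")
        if self.lstm_layers_stacked != 2:
            raise ValueError("the stacked-LSTM depth is fixed at 2")

    @property
    def attention(self) -> bool:
        return self.architecture in ARCHS_WITH_ATTENTION


@dataclass(frozen=True)
class BindingPrediction:
    """Per-sequence binding probability B in [0, 1]."""

    seq_id: str
    score_B: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_B <= 1.0):
            raise ValueError(f"score_B out of [0,1]: {self.score_B}")


def _param_shapes(cfg: ModelConfig) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}
    d = cfg.input_dim
    if cfg.architecture in ARCHS_WITH_CONV:
        shapes["conv.W"] = (cfg.conv_kernel, d, cfg.conv_filters)
        shapes["conv.b"] = (cfg.conv_filters,)
        d = cfg.conv_filters
    if cfg.architecture in ARCHS_WITH_LSTM:
        h = cfg.lstm_hidden
        shapes["lstm1.Wx"] = (d, 4 * h)
        shapes["lstm1.Wh"] = (h, 4 * h)
        shapes["lstm1.b"] = (4 * h,)
        if cfg.attention:
            shapes["attn.W"] = (h, h)
            shapes["attn.b"] = (h,)
            shapes["attn.v"] = (h, 1)
        shapes["lstm2.Wx"] = (h, 4 * h)
        shapes["lstm2.Wh"] = (h, 4 * h)
        shapes["lstm2.b"] = (4 * h,)
        d = h
    shapes["fc1.W"] = (d, cfg.fc_hidden)
    shapes["fc1.b"] = (cfg.fc_hidden,)
    shapes["fc2.W"] = (cfg.fc_hidden, 1)
    shapes["fc2.b"] = (1,)
    return shapes


def init_params(cfg: ModelConfig) -> dict[str, Tensor]:
    """Uniform fan-in initialisation, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    params: dict[str, Tensor] = {}
    for name, shape in _param_shapes(cfg).items():
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        if name.startswith("conv."):
            fan_in = cfg.conv_kernel * cfg.input_dim
        bound = 1.0 / np.sqrt(fan_in)
        params[name] = Tensor(rng.uniform(-bound, bound, size=shape))
    return params


def validate_params(cfg: ModelConfig, params: dict[str, Tensor]) -> None:
    expected = _param_shapes(cfg)
    if set(params) != set(expected):
        raise ValueError(
            f"parameter names mismatch: missing {sorted(set(expected) - set(params))}, "
            f"unexpected {sorted(set(params) - set(expected))}"
        )
    for name, shape in expected.items():
        if params[name].data.shape != shape:
            raise ValueError(
                f"{name}: shape {params[name].data.shape}, expected {shape}"
            )


def _lstm_layer(x: Tensor, mask: np.ndarray, Wx: Tensor, Wh: Tensor, b: Tensor) -> Tensor:
    """Unidirectional LSTM over axis 1 of ``x`` (B, T, D) -> (B, T, H)."""
    B, T, _ = x.data.shape
    H = Wh.data.shape[0]
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    hs: list[Tensor] = []
    sl = slice(None)
    for t in range(T):
        x_t = x[sl, t, sl]
        z = ad.add(ad.add(ad.matmul(x_t, Wx), ad.matmul(h, Wh)), b)
        i = ad.sigmoid(z[sl, 0 * H : 1 * H])
        f = ad.sigmoid(z[sl, 1 * H : 2 * H])
        g = ad.tanh(z[sl, 2 * H : 3 * H])
        o = ad.sigmoid(z[sl, 3 * H : 4 * H])
        c = ad.add(ad.mul(f, c), ad.mul(i, g))
        h = ad.mul(o, ad.tanh(c))
        hs.append(h)
    return ad.stack(hs, axis=1)


def _conv1d_same(x: Tensor, mask: np.ndarray, W: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution over the residue axis, then ReLU, then
    re-zeroing of masked positions so pad rows stay exactly zero."""
    K = W.data.shape[0]
    half = K // 2
    B, T, D = x.data.shape
    pad = np.zeros((B, half, D))
    xp_data = np.concatenate([pad, x.data, pad], axis=1)
    xp = Tensor(xp_data, (x,))

    def bw(g):
        x.grad += g[:, half : half + T, :]

    xp._backward = bw

    acc = None
    for k in range(K):
        term = ad.matmul(xp[:, k : k + T, :], W[k])
        acc = term if acc is None else ad.add(acc, term)
    out = ad.relu(ad.add(acc, b))
    return ad.mul(out, Tensor(mask[:, :, None].astype(float)))


def _attention_block(
    h: Tensor, mask: np.ndarray, W: Tensor, b: Tensor, v: Tensor
) -> tuple[Tensor, Tensor]:
    """Additive attention: e_i = v^T tanh(W h_i + b); masked softmax; each
    position is recombined as h_i + context (residual sum keeps the width).

    Returns (recombined states (B,T,H), weights (B,T,1))."""
    if not np.asarray(mask).any(axis=-1).all():
        raise ValueError("attention requires at least one valid position per sequence")
    scores = ad.matmul(ad.tanh(ad.add(ad.matmul(h, W), b)), v)  # (B, T, 1)
    alpha = ad.softmax_masked(scores, np.asarray(mask)[:, :, None], axis=1)
    context = ad.tsum(ad.mul(alpha, h), axis=1, keepdims=True)  # (B, 1, H)
    return ad.add(h, context), alpha


def attention_recombine(
    states: np.ndarray, mask: np.ndarray, W: np.ndarray, b: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Public (non-autodiff) view of the attention block for a single sequence
    or batch; returns (recombined states, attention weights)."""
    states = np.asarray(states, dtype=float)
    squeeze = states.ndim == 2
    if squeeze:
        states = states[None]
        mask = np.asarray(mask)[None]
    out, alpha = _attention_block(
        Tensor(states), np.asarray(mask, dtype=bool), Tensor(W), Tensor(b),
        Tensor(np.asarray(v).reshape(-1, 1)),
    )
    o, a = out.data, alpha.data[..., 0]
    return (o[0], a[0]) if squeeze else (o, a)


def masked_mean_pool(values: np.ndarray, mask: np.ndarray) -> float | np.ndarray:
    """Arithmetic mean of ``values`` over positions where ``mask`` is True."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=-1)
    if np.any(counts == 0):
        raise ValueError("masked_mean_pool: no valid positions")
    out = (values * mask).sum(axis=-1) / counts
    return float(out) if out.ndim == 0 else out


def forward_scores(cfg: ModelConfig, params: dict[str, Tensor], batch: EncodedBatch) -> Tensor:
    """Run the architecture on a batch; returns the (B,) score tensor on the
    autodiff tape (for training).  Use :func:`forward` for plain predictions."""
    validate_params(cfg, params)
    if batch.features.shape[2] != cfg.input_dim:
        raise ValueError(
            f"batch feature dim {batch.features.shape[2]} != cfg.input_dim {cfg.input_dim}"
        )
    mask = batch.mask
    x = Tensor(batch.features)

    if cfg.architecture in ARCHS_WITH_CONV:
        x = _conv1d_same(x, mask, params["conv.W"], params["conv.b"])
    if cfg.architecture in ARCHS_WITH_LSTM:
        x = _lstm_layer(x, mask, params["lstm1.Wx"], params["lstm1.Wh"], params["lstm1.b"])
        if cfg.attention:
            x, _ = _attention_block(
                x, mask, params["attn.W"], params["attn.b"], params["attn.v"]
            )
        x = _lstm_layer(x, mask, params["lstm2.Wx"], params["lstm2.Wh"], params["lstm2.b"])

    x = ad.sigmoid(ad.add(ad.matmul(x, params["fc1.W"]), params["fc1.b"]))
    x = ad.sigmoid(ad.add(ad.matmul(x, params["fc2.W"]), params["fc2.b"]))  # (B,T,1)
    per_pos = x[:, :, 0]

    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("batch contains a sequence with no valid positions")
    masked = ad.mul(per_pos, Tensor(mask.astype(float)))
    return ad.mul(ad.tsum(masked, axis=1), Tensor(1.0 / counts))


def forward(
    cfg: ModelConfig, params: dict[str, Tensor], batch: EncodedBatch
) -> list[BindingPrediction]:
    scores = forward_scores(cfg, params, batch).data
    return [BindingPrediction(sid, float(s)) for sid, s in zip(batch.seq_ids, scores)]


def save_checkpoint(path, cfg: ModelConfig, params: dict[str, Tensor]) -> None:
    """Serialize parameters + config to a keyed .npz archive."""
    arrays = {f"param/{k}": v.data for k, v in params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ModelConfig, dict[str, Tensor]]:
    archive = np.load(path)
    cfg = ModelConfig(**json.loads(bytes(archive["config_json"]).decode()))
    params = {
        k[len("param/"):]: Tensor(archive[k]) for k in archive.files if k.startswith("param/")
    }
    validate_params(cfg, params)
    return cfg, params
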