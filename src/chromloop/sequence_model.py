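"""Stage 1: the convolutional anchor-sequence feature extractor.

Each anchor sequence is one-hot encoded and passed through a small
convolutional network — convolution / ReLU / max-pool stacks followed by
global max pooling — so that every last-layer kernel contributes one feature:
its maximal activation anywhere on the sequence. A pair of anchors is
represented by four blocks of such features (left-forward, left-reverse-
complement, right-forward, right-reverse-complement), which makes motif
orientation visible to the downstream classifier: a motif on the forward
strand of the left anchor and its reverse complement on the right anchor (the
convergent geometry of CTCF loops) lights up the same kernel in the left-F
and right-RC blocks.

The extractor is pretrained end-to-end with a small dense head on the
distance-matched dataset (binary cross-entropy on interaction labels), then
frozen; later stages train gradient-boosted trees on its output. The network
is implemented directly on NumPy (forward and backward passes, Adam), which
keeps it dependency-light and bit-reproducible under a fixed seed at the
problem sizes this package targets.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import reverse_complement
from .evaluation import auprc

__all__ = [
    "ExtractorConfig",
    "OneHotSequence",
    "one_hot_encode",
    "ConvFeatureExtractor",
    "DenseHead",
    "build_extractor",
    "extract_pair_features",
    "extract_feature_matrix",
    "feature_names",
    "feature_blocks",
    "train_stage1",
    "freeze",
    "save_checkpoint",
    "load_checkpoint",
]

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

BLOCKS = ("left_F", "left_RC", "right_F", "right_RC")


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture of the sequence feature extractor.

    Defaults: 64 kernels of width 19 bp, max-pool width 10, then 32 kernels
    of width 11 (DeepBind-scale sizes); two convolutional layers so that both
    first-layer kernels (motif discovery) and last-layer kernels (feature
    attribution) are interpretable. ``input_length`` is the window, centered
    on the anchor midpoint, that the network sees.
    """

    input_length: int = 1000
    conv_channels: tuple[int, ...] = (64, 32)
    conv_widths: tuple[int, ...] = (19, 11)
    pool_width: int = 10
    dense_units: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) < 2 or len(self.conv_channels) != len(self.conv_widths):
            raise ValueError("need >= 2 convolutional layers with matching widths")
        if min(self.conv_channels) < 1 or min(self.conv_widths) < 1:
            raise ValueError("layer sizes must be positive")
        if self.pool_width < 1 or self.input_length < 1 or self.dense_units < 1:
            raise ValueError("sizes must be positive")
        # walk spatial sizes: pool after every conv layer except the last,
        # which is globally max-pooled
        size = self.input_length
        for i, w in enumerate(self.conv_widths):
            size = size - w + 1
            if size <= 0:
                raise ValueError(f"conv layer {i} leaves non-positive spatial size")
            if i < len(self.conv_widths) - 1:
                size = size // self.pool_width
                if size <= 0:
                    raise ValueError(f"pooling after layer {i} leaves no positions")

    @property
    def n_kernels_last(self) -> int:
        return self.conv_channels[-1]

    @property
    def pair_feature_dim(self) -> int:
        return 4 * self.n_kernels_last


OneHotSequence = np.ndarray  # (L, 4) over channel order A,C,G,T; N rows all-zero


def one_hot_encode(seq: str, L: int) -> OneHotSequence:
    """One-hot encode ``seq`` centered in a window of length ``L``.

    Shorter sequences are zero-padded symmetrically; longer ones are
    center-cropped. N (or any non-ACGT character) becomes an all-zero row.
    """
    n = len(seq)
    if n > L:
        off = (n - L) // 2
        seq = seq[off : off + L]
        n = L
    codes = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    out = np.zeros((L, 4), dtype=np.float32)
    pad = (L - n) // 2
    valid = codes >= 0
    rows = np.nonzero(valid)[0] + pad
    out[rows, codes[valid]] = 1.0
    return out


def _encode_batch(seqs: Sequence[str], L: int) -> np.ndarray:
    out = np.zeros((len(seqs), L, 4), dtype=np.float32)
    for i, s in enumerate(seqs):
        out[i] = one_hot_encode(s, L)
    return out


# ---------------------------------------------------------------------------
# layers


class _Conv1D:
    """Valid-mode cross-correlation: y[b,t,k] = sum_{o,c} x[b,t+o,c] W[o,c,k]."""

    def __init__(self, width: int, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (width * c_in))
        self.W = (rng.standard_normal((width, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        w, _, K = self.W.shape
        Lp = L - w + 1
        win = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)  # (B,Lp,C,w)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * Lp, w * C)
        y = cols @ self.W.reshape(w * C, K)
        return y.reshape(B, Lp, K) + self.b

    def backward(self, x: np.ndarray, dy: np.ndarray):
        B, L, C = x.shape
        w, _, K = self.W.shape
        Lp = dy.shape[1]
        dW = np.empty_like(self.W)
        dyf = dy.reshape(-1, K)
        for o in range(w):
            dW[o] = x[:, o : o + Lp, :].reshape(-1, C).T @ dyf
        db = dyf.sum(axis=0)
        dx = np.zeros_like(x)
        for o in range(w):
            dx[:, o : o + Lp, :] += dy @ self.W[o].T
        return dx, dW, db


def _maxpool(x: np.ndarray, p: int):
    B, L, K = x.shape
    P = L // p
    xr = x[:, : P * p, :].reshape(B, P, p, K)
    arg = xr.argmax(axis=2)
    y = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return y, (arg, x.shape)


def _maxpool_backward(dy: np.ndarray, cache, p: int) -> np.ndarray:
    arg, shape = cache
    B, L, K = shape
    P = dy.shape[1]
    dxr = np.zeros((B, P, p, K), dtype=dy.dtype)
    np.put_along_axis(dxr, arg[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(shape, dtype=dy.dtype)
    dx[:, : P * p, :] = dxr.reshape(B, P * p, K)
    return dx


class ConvFeatureExtractor:
    """The stage-1 feature extractor (see module docstring).

    Per sequence the output is the global-max-pooled activation of every
    last-layer kernel (one value per kernel). First-layer kernel weights are
    exposed (``conv_layers[0].W``) for motif analysis.
    """

    def __init__(self, config: ExtractorConfig):
        self.config = config
        self.frozen = False
        rng = np.random.default_rng(config.seed)
        self.conv_layers: list[_Conv1D] = []
        c_in = 4
        for width, c_out in zip(config.conv_widths, config.conv_channels):
            self.conv_layers.append(_Conv1D(width, c_in, c_out, rng))
            c_in = c_out

    @property
    def n_features(self) -> int:
        return self.config.n_kernels_last

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers:
            out.extend([layer.W, layer.b])
        return out

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, L, 4) → features (B, K_last); optionally a backprop cache."""
        cache = []
        p = self.config.pool_width
        n = len(self.conv_layers)
        for i, layer in enumerate(self.conv_layers):
            z = layer.forward(x)
            a = np.maximum(z, 0.0)
            if i < n - 1:
                y, pc = _maxpool(a, p)
            else:
                # global max pool
                arg = a.argmax(axis=1)
                y = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
                pc = (arg, a.shape)
            if want_cache:
                cache.append((x, z, pc))
            x = y
        return (x, cache) if want_cache else x

    def backward(self, cache, dfeat: np.ndarray):
        """Gradients of all conv parameters given d(features); returns list
        aligned with :meth:`parameters`."""
        grads: list[np.ndarray] = [None] * (2 * len(self.conv_layers))
        dy = dfeat
        p = self.config.pool_width
        n = len(self.conv_layers)
        for i in range(n - 1, -1, -1):
            x, z, pc = cache[i]
            if i == n - 1:
                arg, shape = pc
                da = np.zeros(shape, dtype=dy.dtype)
                np.put_along_axis(da, arg[:, None, :], dy[:, None, :], axis=1)
            else:
                da = _maxpool_backward(dy, pc, p)
            dz = da * (z > 0)
            dx, dW, db = self.conv_layers[i].backward(x, dz)
            grads[2 * i] = dW
            grads[2 * i + 1] = db
            dy = dx
        return grads

    def kernel_activations(self, x: np.ndarray, layer: int = 0) -> np.ndarray:
        """Pre-activation maps of the given conv layer for probe sequences;
        shape (B, positions, kernels)."""
        p = self.config.pool_width
        for i, lyr in enumerate(self.conv_layers):
            z = lyr.forward(x)
            if i == layer:
                return z
            a = np.maximum(z, 0.0)
            if i < len(self.conv_layers) - 1:
                x, _ = _maxpool(a, p)
        raise ValueError(f"layer {layer} out of range")


def build_extractor(config: ExtractorConfig) -> ConvFeatureExtractor:
    """Deterministically initialized extractor for the given config."""
    return ConvFeatureExtractor(config)


class DenseHead:
    """Two dense layers (hidden ReLU → 1 logit); the stage-1 pretraining
    classifier, discarded after the extractor is frozen."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.W1 = (rng.standard_normal((in_dim, hidden)) * np.sqrt(2.0 / in_dim)).astype(
            np.float32
        )
        self.b1 = np.zeros(hidden, dtype=np.float32)
        self.W2 = (rng.standard_normal((hidden, 1)) * np.sqrt(2.0 / hidden)).astype(
            np.float32
        )
        self.b2 = np.zeros(1, dtype=np.float32)

    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, f: np.ndarray, want_cache: bool = False):
        z1 = f @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        logit = (a1 @ self.W2 + self.b2)[:, 0]
        if want_cache:
            return logit, (f, z1, a1)
        return logit

    def backward(self, cache, dlogit: np.ndarray):
        f, z1, a1 = cache
        dl = dlogit[:, None]
        dW2 = a1.T @ dl
        db2 = dl.sum(axis=0)
        da1 = dl @ self.W2.T
        dz1 = da1 * (z1 > 0)
        dW1 = f.T @ dz1
        db1 = dz1.sum(axis=0)
        df = dz1 @ self.W1.T
        return df, [dW1, db1, dW2, db2]


# ---------------------------------------------------------------------------
# pair featurization


def feature_blocks(config: ExtractorConfig) -> dict[str, slice]:
    """Block-name → slice of the pair feature vector (fixed order:
    left_F, left_RC, right_F, right_RC)."""
    K = config.n_kernels_last
    return {name: slice(i * K, (i + 1) * K) for i, name in enumerate(BLOCKS)}


def feature_names(config: ExtractorConfig, include_distance: bool = False) -> list[str]:
    K = config.n_kernels_last
    names = [f"{block}_k{k:03d}" for block in BLOCKS for k in range(K)]
    if include_distance:
        names.append("distance")
    return names


def _pair_orientation_batch(
    left_seqs: Sequence[str], right_seqs: Sequence[str], L: int
) -> np.ndarray:
    """Stack the four oriented sequences of each pair: returns (4B, L, 4) with
    orientation-major layout [all left-F | all left-RC | all right-F | all
    right-RC]."""
    seqs: list[str] = []
    seqs.extend(left_seqs)
    seqs.extend(reverse_complement(s) for s in left_seqs)
    seqs.extend(right_seqs)
    seqs.extend(reverse_complement(s) for s in right_seqs)
    return _encode_batch(seqs, L)


def extract_feature_matrix(
    extractor: ConvFeatureExtractor,
    left_seqs: Sequence[str],
    right_seqs: Sequence[str],
    batch_size: int = 128,
) -> np.ndarray:
    """Pair feature matrix (n, 4K): four forward passes per pair, blocks
    concatenated in the fixed left-F / left-RC / right-F / right-RC order."""
    n = len(left_seqs)
    K = extractor.n_features
    out = np.empty((n, 4 * K), dtype=np.float32)
    L = extractor.config.input_length
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        x = _pair_orientation_batch(left_seqs[lo:hi], right_seqs[lo:hi], L)
        feats = extractor.forward(x)  # (4m, K)
        m = hi - lo
        out[lo:hi] = feats.reshape(4, m, K).transpose(1, 0, 2).reshape(m, 4 * K)
    return out


def extract_pair_features(
    extractor: ConvFeatureExtractor,
    left_seq: str,
    right_seq: str,
    distance: int | None = None,
) -> np.ndarray:
    """Feature vector of one pair; appends raw distance (bp) if given."""
    v = extract_feature_matrix(extractor, [left_seq], [right_seq])[0]
    if distance is not None:
        v = np.concatenate([v, np.array([distance], dtype=np.float32)])
    return v


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[np.ndarray], lrs: list[float]):
        self.params = params
        self.lrs = list(lrs)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, g, m, v, lr in zip(self.params, grads, self.m, self.v, self.lrs):
            g = g.astype(p.dtype)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


def _score_pairs(
    extractor: ConvFeatureExtractor,
    head: DenseHead,
    left_seqs: Sequence[str],
    right_seqs: Sequence[str],
    batch_size: int = 256,
) -> np.ndarray:
    feats = extract_feature_matrix(extractor, left_seqs, right_seqs, batch_size)
    logits = head.forward(feats)
    return 1.0 / (1.0 + np.exp(-logits))


def train_stage1(
    extractor: ConvFeatureExtractor,
    train_pairs: Sequence[tuple[str, str, int]],
    val_pairs: Sequence[tuple[str, str, int]],
    epochs: int = 30,
    learning_rate: float = 1e-3,
    batch_size: int = 128,
    patience: int = 5,
    seed: int = 0,
    head: DenseHead | None = None,
    first_layer_lr_multiplier: float = 10.0,
    verbose: bool = False,
):
    """Pretrain the extractor with a dense head on (left_seq, right_seq, label)
    triples.

    Weighted binary cross-entropy (negatives down-weighted to an effective 1:1
    class balance), Adam, early stopping on validation auPRC with the given
    patience; the extractor is returned with its best-validation parameters.
    Fully reproducible given ``seed``.

    The first convolutional layer trains at ``first_layer_lr_multiplier`` x
    the base learning rate: randomly initialized motif kernels spend a long
    plateau drifting into alignment with the informative subsequences, and a
    larger first-layer step shortens that plateau substantially without
    destabilizing the head.

    Returns ``(head, log)`` where ``log`` is a list of per-epoch dicts with
    ``train_loss`` and ``val_auprc``.
    """
    if extractor.frozen:
        raise RuntimeError("extractor is frozen; stage-1 training is not allowed")
    labels = np.array([int(p[2]) for p in train_pairs])
    if labels.min() == labels.max():
        raise ValueError("stage-1 training set contains a single class")
    rng = np.random.default_rng(seed)
    cfg = extractor.config
    if head is None:
        head = DenseHead(cfg.pair_feature_dim, cfg.dense_units, rng)

    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    w_neg = n_pos / n_neg if n_neg else 1.0
    weights = np.where(labels == 1, 1.0, w_neg).astype(np.float32)
    weights *= len(weights) / weights.sum()

    left = [p[0] for p in train_pairs]
    right = [p[1] for p in train_pairs]
    vleft = [p[0] for p in val_pairs]
    vright = [p[1] for p in val_pairs]
    vlabels = np.array([int(p[2]) for p in val_pairs])

    params = extractor.parameters() + head.parameters()
    lrs = [learning_rate] * len(params)
    lrs[0] = lrs[1] = learning_rate * first_layer_lr_multiplier
    opt = _Adam(params, lrs)
    K = extractor.n_features
    L = cfg.input_length

    best_auprc = -np.inf
    best_state = None
    best_epoch = -1
    log: list[dict] = []
    since_best = 0

    for epoch in range(epochs):
        order = rng.permutation(len(train_pairs))
        total_loss = 0.0
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            m = len(idx)
            x = _pair_orientation_batch(
                [left[i] for i in idx], [right[i] for i in idx], L
            )
            feats4, cache = extractor.forward(x, want_cache=True)  # (4m, K)
            feats = feats4.reshape(4, m, K).transpose(1, 0, 2).reshape(m, 4 * K)
            logit, hcache = head.forward(feats, want_cache=True)
            y = labels[idx].astype(np.float32)
            w = weights[idx]
            prob = 1.0 / (1.0 + np.exp(-logit))
            eps = 1e-7
            loss = -np.mean(
                w * (y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
            )
            total_loss += loss * m
            dlogit = (w * (prob - y) / m).astype(np.float32)
            dfeats, hgrads = head.backward(hcache, dlogit)
            dfeat4 = (
                dfeats.reshape(m, 4, K).transpose(1, 0, 2).reshape(4 * m, K)
            ).astype(np.float32)
            cgrads = extractor.backward(cache, dfeat4)
            opt.step(cgrads + hgrads)

        val_scores = _score_pairs(extractor, head, vleft, vright)
        val_auprc = auprc(val_scores, vlabels)[0] if len(set(vlabels)) > 1 else np.nan
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(total_loss / len(order)),
                "val_auprc": float(val_auprc),
            }
        )
        if verbose:
            print(f"epoch {epoch}: loss {log[-1]['train_loss']:.4f} "
                  f"val auPRC {val_auprc:.4f}")
        if np.isnan(val_auprc) or val_auprc > best_auprc:
            best_auprc = val_auprc
            best_state = [p.copy() for p in params]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break

    if best_state is not None:
        for p, b in zip(params, best_state):
            p[...] = b
    return head, log


def freeze(extractor: ConvFeatureExtractor) -> ConvFeatureExtractor:
    """Mark the extractor immutable; subsequent training attempts raise."""
    extractor.frozen = True
    return extractor


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    extractor: ConvFeatureExtractor, path: str | Path, head: DenseHead | None = None
) -> None:
    """Self-describing checkpoint: config JSON + all parameter arrays."""
    arrays = {}
    for i, layer in enumerate(extractor.conv_layers):
        arrays[f"conv{i}_W"] = layer.W
        arrays[f"conv{i}_b"] = layer.b
    if head is not None:
        arrays.update(
            head_W1=head.W1, head_b1=head.b1, head_W2=head.W2, head_b2=head.b2
        )
    cfg = asdict(extractor.config)
    cfg["conv_channels"] = list(cfg["conv_channels"])
    cfg["conv_widths"] = list(cfg["conv_widths"])
    np.savez(
        path,
        config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        frozen=np.array([extractor.frozen]),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> ConvFeatureExtractor:
    data = np.load(path)
    cfg = json.loads(bytes(data["config"]).decode())
    cfg["conv_channels"] = tuple(cfg["conv_channels"])
    cfg["conv_widths"] = tuple(cfg["conv_widths"])
    extractor = ConvFeatureExtractor(ExtractorConfig(**cfg))
    for i, layer in enumerate(extractor.conv_layers):
        layer.W = data[f"conv{i}_W"]
        layer.b = data[f"conv{i}_b"]
    extractor.frozen = bool(data["frozen"][0])
    return extractor
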