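"""Sequence-to-accessibility model with probability-sparse self-attention.

The model maps an L-bp one-hot DNA sequence to per-cell accessibility
probabilities.  A convolutional stem produces motif-level token embeddings
(with alternating convolution/pooling for long inputs); fixed sinusoidal
position embeddings are added (``X0 = alpha * u + PE``); a stack of
encoder layers applies sparse multi-head self-attention in which only the
top-u queries — ranked by how far their attention distribution deviates
from uniform — attend to the keys, followed by a position-wise
feed-forward block and convolution + max-pooling over the token axis.
A final convolution and dense layer produce a low-dimensional sequence
embedding Z, and a per-cell linear read-out gives
``y = sigmoid(Z W_p + b_p)``.  The columns of ``W_p`` are reusable cell
embeddings and ``b_p`` acts as a per-cell sequencing-depth intercept.

Training minimises cell-averaged binary cross-entropy with Adam and
patience-based early stopping on a validation peak set.  Everything runs
on the NumPy autodiff engine in :mod:`probatac.autodiff`.

The module follows the statsmodels convention: build an
:class:`AccessibilityModel` from data, call :meth:`~AccessibilityModel.fit`,
and work with the returned :class:`AccessibilityResults`.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from . import autodiff as ad
from .autodiff import Tensor
from .sequence_io import OneHotBatch, PeakCellMatrix

__all__ = [
    "ModelConfig",
    "CellEmbedding",
    "AccessibilityModel",
    "AccessibilityResults",
    "position_embedding",
    "uniform_input",
    "sparsity_measurement",
    "sparse_attention",
    "dense_attention_oracle",
    "predict_accessibility",
    "bce_loss",
    "mean_auroc",
    "desk_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyper-parameters of the encoder and its training protocol.

    ``input_length`` is the sequence length L in bp.  ``d`` is the token
    embedding width (must be even for sin/cos pairing and divisible by
    ``n_heads``).  Sequences longer than ``stem_threshold`` pass through
    alternating convolution/pooling stem stages until the token count drops
    below the threshold; shorter ones through a single convolution.
    ``alpha`` balances motif against position embeddings in
    ``X0 = alpha * u + PE``; ``c`` is the attention sampling factor with
    ``u = ceil(c * ln L_Q)`` selected queries.
    """

    input_length: int
    n_cells: int
    d: int = 128
    n_heads: int = 8
    n_layers: int = 2
    c: float = 5.0
    attention_mode: str = "sampled"      # "sampled" | "exact"
    stem_threshold: int = 5000
    stem_kernel: int = 15
    enc_kernel: int = 5
    pool_width: int = 2
    ffw_width: int | None = None         # default 2 * d
    seq_channels: int = 8
    seq_kernel: int = 5
    embedding_size: int = 32
    pe_mode: str = "fixed_absolute"      # "fixed_absolute" | "none"
    pe_base: float = 10000.0
    alpha: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 16
    patience: int = 5
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.ffw_width is None:
            self.ffw_width = 2 * self.d
        if self.d % 2 != 0:
            raise ValueError("d must be even (sin/cos pairing)")
        if self.d % self.n_heads != 0:
            raise ValueError("n_heads must divide d")
        if self.c < 1:
            raise ValueError("sampling factor c must be >= 1")
        if self.input_length < self.stem_kernel:
            raise ValueError("input length shorter than the stem kernel")
        if self.pe_mode not in ("fixed_absolute", "none"):
            raise ValueError(f"unknown position-embedding mode {self.pe_mode!r}")
        if self.attention_mode not in ("sampled", "exact"):
            raise ValueError(f"unknown attention mode {self.attention_mode!r}")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads

    def stem_plan(self) -> tuple[int, int]:
        """(number of conv+pool stem stages, resulting token count)."""
        L = self.input_length
        stages = 0
        while L > self.stem_threshold:
            L //= self.pool_width
            stages += 1
        return stages, L

    def token_counts(self) -> list[int]:
        """Token count entering each encoder layer and the final count."""
        _, L = self.stem_plan()
        counts = [L]
        for k in range(self.n_layers):
            if k < self.n_layers - 1:   # last layer skips pooling
                L //= self.pool_width
            counts.append(L)
        return counts


def desk_config(n_cells: int, input_length: int = 300, seed: int = 0,
                **overrides) -> ModelConfig:
    """Reference desk-scale (single CPU) configuration used for the bundled
    synthetic study: a narrower 2-layer encoder with a pooled stem."""
    defaults = dict(d=48, n_heads=4, n_layers=2, ffw_width=96,
                    stem_threshold=160, max_epochs=30)
    defaults.update(overrides)
    return ModelConfig(input_length=input_length, n_cells=n_cells, seed=seed,
                       **defaults)


# ---------------------------------------------------------------------------
# stateless operations
# ---------------------------------------------------------------------------


def position_embedding(L_tok: int, d: int, base: float = 10000.0) -> np.ndarray:
    """Fixed sinusoidal embedding: PE[pos, 2i] = sin(pos / base^(2i/d)),
    PE[pos, 2i+1] = cos(pos / base^(2i/d))."""
    if d % 2 != 0:
        raise ValueError("embedding width must be even")
    pos = np.arange(L_tok)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(base, 2.0 * i / d)
    pe = np.empty((L_tok, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def uniform_input(u: np.ndarray, pe: np.ndarray | None, alpha: float) -> np.ndarray:
    """X0 = alpha * u + PE (PE omitted in the no-position-embedding ablation)."""
    if pe is None:
        return alpha * u
    if u.shape[-2:] != pe.shape:
        raise ValueError(f"shape mismatch: motif {u.shape} vs position {pe.shape}")
    return alpha * u + pe


def _measurement_exact(scores: np.ndarray) -> np.ndarray:
    """M = LSE(scores) - mean(scores) along the key axis."""
    return logsumexp(scores, axis=-1) - scores.mean(axis=-1)


def _measurement_sampled(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Max-minus-mean surrogate over ~L_K * ln(L_Q) sampled query-key pairs,
    balanced as ceil(L_K * ln(L_Q) / L_Q) keys per query."""
    *lead, L_Q, L_K = scores.shape
    s = max(1, math.ceil(L_K * max(math.log(L_Q), 0.0) / L_Q))
    s = min(s, L_K)
    # rank-based sampling without replacement, per query
    r = rng.random(scores.shape)
    keep = np.argpartition(r, s - 1, axis=-1)[..., :s]
    sub = np.take_along_axis(scores, keep, axis=-1)
    return sub.max(axis=-1) - sub.mean(axis=-1)


def sparsity_measurement(Q: np.ndarray, K: np.ndarray, mode: str = "exact",
                         seed: int = 0) -> np.ndarray:
    """Per-query long-range dependency score.

    ``exact`` evaluates the log-sum-exp-minus-mean form on all keys; with
    identical scores it equals ln L_K.  ``sampled`` uses the max-minus-mean
    surrogate on a random subset of query-key pairs, so identical scores
    give exactly 0.  Scores are scaled by 1/sqrt(d_h).
    """
    Q, K = np.asarray(Q, float), np.asarray(K, float)
    if K.shape[-2] == 0:
        raise ValueError("empty key matrix")
    d_h = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d_h)
    if mode == "exact":
        return _measurement_exact(scores)
    if mode == "sampled":
        return _measurement_sampled(scores, np.random.default_rng(seed))
    raise ValueError(f"unknown measurement mode {mode!r}")


def _top_u_indices(measure: np.ndarray, u: int) -> np.ndarray:
    """Indices of the u largest measurements; ties broken by lowest index."""
    order = np.argsort(-measure, axis=-1, kind="stable")
    return np.sort(order[..., :u], axis=-1)


def _sparse_attention_core(q: Tensor, k: Tensor, v: Tensor, c: float, mode: str,
                  seed: int) -> Tensor:
    """Differentiable sparse attention on (..., L, d_h) tensors."""
    L_Q = q.shape[-2]
    if L_Q == 0:
        raise ValueError("no queries")
    d_h = q.shape[-1]
    u = min(max(1, math.ceil(c * math.log(L_Q))) if L_Q > 1 else 1, L_Q)
    scores_np = q.data @ np.swapaxes(k.data, -1, -2) / math.sqrt(d_h)
    if mode == "exact":
        measure = _measurement_exact(scores_np)
    else:
        measure = _measurement_sampled(scores_np, np.random.default_rng(seed))
    idx = _top_u_indices(measure, u)
    q_bar = ad.gather_tokens(q, idx)
    kt = k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
    att = ad.softmax(ad.matmul(q_bar, kt) * (1.0 / math.sqrt(d_h)), axis=-1)
    rows = ad.matmul(att, v)
    # non-selected queries: softmax of all-zero scores is uniform -> mean of V
    base = v.mean(axis=-2, keepdims=True) + ad.tensor(np.zeros_like(q.data))
    return ad.scatter_tokens(base, idx, rows)


def sparse_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                      c: float = 5.0, mode: str = "exact", seed: int = 0
                      ) -> np.ndarray:
    """Sparse attention: the top-u queries under the dependency measurement
    attend to all keys; the remaining query rows receive the key-wise mean
    of V.  Accepts (L, d_h) or batched (..., L, d_h) arrays."""
    if np.asarray(K).shape[-2] != np.asarray(V).shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    out = _sparse_attention_core(ad.tensor(Q), ad.tensor(K), ad.tensor(V), c, mode, seed)
    return out.data


def dense_attention_oracle(Q: np.ndarray, K: np.ndarray, V: np.ndarray
                           ) -> np.ndarray:
    """Exact softmax(Q K^T / sqrt(d_h)) V with no sparsity (test oracle)."""
    Q, K, V = (np.asarray(a, float) for a in (Q, K, V))
    d_h = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d_h)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


def predict_accessibility(Z: np.ndarray, W_p: np.ndarray, b_p: np.ndarray
                          ) -> np.ndarray:
    """y = sigmoid(Z W_p + b_p), elementwise over cells."""
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[-1] != W_p.shape[0]:
        raise ValueError("embedding size does not match W_p rows")
    logits = Z @ W_p + b_p
    return 0.5 * (np.tanh(0.5 * logits) + 1.0)


_BCE_EPS = 1e-7


def bce_loss(y: np.ndarray, labels: np.ndarray, eps: float = _BCE_EPS) -> float:
    """Cell-averaged negated binary cross-entropy, probabilities clipped to
    [eps, 1-eps]; non-negative by construction."""
    y = np.asarray(y, float)
    labels = np.asarray(labels, float)
    if y.shape != labels.shape:
        raise ValueError("prediction / label length mismatch")
    yc = np.clip(y, eps, 1.0 - eps)
    return float(-(labels * np.log(yc) + (1 - labels) * np.log(1 - yc)).mean())


def mean_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney auROC per cell (column), averaged over cells that have at
    least one positive and one negative label.  ``scores`` and ``labels`` are
    (peaks, cells)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    aucs = []
    for j in range(scores.shape[1]):
        lab = labels[:, j] > 0
        n_pos = int(lab.sum())
        n_neg = lab.size - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(scores[:, j])
        auc = (ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("no cell has both positive and negative labels")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = shape[-1]
    std = math.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, shape)


class _Network:
    """Parameter container + forward graph (internal)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, K = config.d, config.stem_kernel
        self.stem_stages, self.L_tok = config.stem_plan()
        p: dict[str, Tensor] = {}
        n_convs = max(1, self.stem_stages)
        for s in range(n_convs):
            cin = 4 if s == 0 else d
            p[f"stem{s}_w"] = ad.parameter(_glorot(rng, K, cin, d))
            p[f"stem{s}_b"] = ad.parameter(np.zeros(d))
        for k in range(config.n_layers):
            for nm in ("q", "k", "v", "o"):
                p[f"enc{k}_w{nm}"] = ad.parameter(_glorot(rng, d, d))
            p[f"enc{k}_bo"] = ad.parameter(np.zeros(d))
            p[f"enc{k}_ff1_w"] = ad.parameter(_glorot(rng, d, config.ffw_width))
            p[f"enc{k}_ff1_b"] = ad.parameter(np.zeros(config.ffw_width))
            p[f"enc{k}_ff2_w"] = ad.parameter(_glorot(rng, config.ffw_width, d))
            p[f"enc{k}_ff2_b"] = ad.parameter(np.zeros(d))
            p[f"enc{k}_conv_w"] = ad.parameter(
                _glorot(rng, config.enc_kernel, d, d))
            p[f"enc{k}_conv_b"] = ad.parameter(np.zeros(d))
        p["seq_conv_w"] = ad.parameter(
            _glorot(rng, config.seq_kernel, d, config.seq_channels))
        p["seq_conv_b"] = ad.parameter(np.zeros(config.seq_channels))
        flat = config.token_counts()[-1] * config.seq_channels
        p["seq_w"] = ad.parameter(_glorot(rng, flat, config.embedding_size))
        p["seq_b"] = ad.parameter(np.zeros(config.embedding_size))
        p["pred_w"] = ad.parameter(
            _glorot(rng, config.embedding_size, config.n_cells))
        p["pred_b"] = ad.parameter(np.zeros(config.n_cells))
        self.params = p
        self.pe = (position_embedding(self.L_tok, d, config.pe_base)
                   if config.pe_mode == "fixed_absolute" else None)

    # -- pieces (also the public op surface, via AccessibilityResults) ------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def motif_embedding(self, x: Tensor) -> Tensor:
        """One-hot (B, L, 4) -> token embedding u of width d; long inputs go
        through alternating convolution + max-pooling stages."""
        cfg = self.config
        if self.stem_stages == 0:
            return ad.elu(ad.conv1d(x, self.params["stem0_w"],
                                    self.params["stem0_b"]))
        h = x
        for s in range(self.stem_stages):
            h = ad.elu(ad.conv1d(h, self.params[f"stem{s}_w"],
                                 self.params[f"stem{s}_b"]))
            h = ad.maxpool1d(h, cfg.pool_width)
        return h

    def uniform_input(self, u: Tensor) -> Tensor:
        cfg = self.config
        x0 = u * cfg.alpha
        if self.pe is not None:
            x0 = x0 + ad.tensor(self.pe)
        return x0

    def _split_heads(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        h = self.config.n_heads
        return x.reshape(B, L, h, d // h).transpose(0, 2, 1, 3)

    def _merge_heads(self, x: Tensor) -> Tensor:
        B, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, h * dh)

    def encoder_layer(self, x: Tensor, k: int, seed: int, pool: bool) -> Tensor:
        """Sparse multi-head attention + residual, position-wise feed-forward
        + residual, then Conv1d (+ELU) and, unless ``pool`` is off, MaxPool."""
        cfg = self.config
        p = self.params
        q = self._split_heads(ad.matmul(x, p[f"enc{k}_wq"]))
        kk = self._split_heads(ad.matmul(x, p[f"enc{k}_wk"]))
        v = self._split_heads(ad.matmul(x, p[f"enc{k}_wv"]))
        att = _sparse_attention_core(q, kk, v, cfg.c, cfg.attention_mode, seed)
        att = ad.matmul(self._merge_heads(att), p[f"enc{k}_wo"]) + p[f"enc{k}_bo"]
        x = x + att
        ff = ad.matmul(ad.elu(ad.matmul(x, p[f"enc{k}_ff1_w"]) + p[f"enc{k}_ff1_b"]),
                       p[f"enc{k}_ff2_w"]) + p[f"enc{k}_ff2_b"]
        x = x + ff
        x = ad.elu(ad.conv1d(x, p[f"enc{k}_conv_w"], p[f"enc{k}_conv_b"]))
        if pool:
            x = ad.maxpool1d(x, cfg.pool_width)
        return x

    def sequence_embedding(self, x: Tensor) -> Tensor:
        """Z = ELU(W_f flatten(ELU(Conv1d(X))) + b_f)."""
        p = self.params
        h = ad.elu(ad.conv1d(x, p["seq_conv_w"], p["seq_conv_b"]))
        B = h.shape[0]
        h = h.reshape(B, h.shape[1] * h.shape[2])
        return ad.elu(ad.matmul(h, p["seq_w"]) + p["seq_b"])

    def forward(self, x: np.ndarray, seed: int = 0,
                return_embedding: bool = False):
        cfg = self.config
        xt = ad.tensor(x)
        u = self.motif_embedding(xt)
        h = self.uniform_input(u)
        for k in range(cfg.n_layers):
            pool = k < cfg.n_layers - 1
            h = self.encoder_layer(h, k, seed + 7919 * (k + 1), pool)
        z = self.sequence_embedding(h)
        y = ad.sigmoid(ad.matmul(z, self.params["pred_w"]) + self.params["pred_b"])
        if return_embedding:
            return y, z
        return y

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, float).copy()


def _bce_tensor(y: Tensor, labels: np.ndarray, eps: float = _BCE_EPS) -> Tensor:
    yc = ad.clip(y, eps, 1.0 - eps)
    lab = ad.tensor(labels)
    one = ad.tensor(np.ones_like(labels))
    ll = lab * ad.log(yc) + (one - lab) * ad.log(one - yc)
    return -ll.mean()


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


@dataclass
class CellEmbedding:
    """Per-cell embedding (rows of W_p^T) and depth intercepts (b_p)."""

    matrix: np.ndarray           # (n_cells, embedding_size)
    depth: np.ndarray            # (n_cells,)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)) or not np.all(np.isfinite(self.depth)):
            raise ValueError("cell embedding contains non-finite values")


class AccessibilityModel:
    """Accessibility model bound to a dataset (sequences + binary labels).

    Parameters
    ----------
    batch : OneHotBatch
        All peak sequences, one-hot encoded.
    labels : PeakCellMatrix
        Binarized cells x peaks accessibility indicators.
    config : ModelConfig
    splits : optional (train, val, test) index arrays over peaks; by default
        an 0.8/0.1/0.1 split drawn from ``config.seed``.
    """

    def __init__(self, batch: OneHotBatch, labels: PeakCellMatrix,
                 config: ModelConfig,
                 splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None):
        if batch.length != config.input_length:
            raise ValueError("batch length does not match config.input_length")
        if labels.n_cells != config.n_cells:
            raise ValueError("label matrix cell count does not match config")
        if labels.n_peaks != batch.n:
            raise ValueError("label matrix peak count does not match batch")
        lab = labels.dense()
        if not np.all(np.isin(lab, (0.0, 1.0))):
            raise ValueError("labels must be binarized first")
        self.batch = batch
        self.labels = lab                      # cells x peaks
        self.cell_ids = list(labels.cell_ids)
        self.config = config
        if splits is None:
            rng = np.random.default_rng(config.seed)
            order = rng.permutation(batch.n)
            n_tr = int(round(0.8 * batch.n))
            n_va = int(round(0.1 * batch.n))
            splits = (order[:n_tr], order[n_tr:n_tr + n_va],
                      order[n_tr + n_va:])
        self.splits = tuple(np.asarray(s) for s in splits)
        if len(self.splits[0]) == 0:
            raise ValueError("empty training set")

    @classmethod
    def from_dataset(cls, dataset, config: ModelConfig | None = None,
                     **config_overrides) -> "AccessibilityModel":
        """Build from a :class:`probatac.synthetic.SyntheticDataset`."""
        from .sequence_io import binarize

        batch = dataset.one_hot()
        labels = binarize(dataset.observed)
        if config is None:
            config = desk_config(labels.n_cells, batch.length,
                                 seed=dataset.design.seed, **config_overrides)
        return cls(batch, labels, config)

    def _epoch_loss(self, net: _Network, idx: np.ndarray, seed: int) -> float:
        """Forward-only loss over peaks ``idx`` (deterministic for fixed seed)."""
        bs = max(self.config.batch_size, 64)
        total, n = 0.0, 0
        for start in range(0, len(idx), bs):
            sel = idx[start:start + bs]
            y = net.forward(self.batch.tensor[sel], seed=seed)
            total += bce_loss(y.data, self.labels[:, sel].T) * len(sel)
            n += len(sel)
        return total / n

    def fit(self, verbose: bool = False) -> "AccessibilityResults":
        """Adam + early stopping (patience epochs without a validation-loss
        improvement); the best-validation weights are restored."""
        cfg = self.config
        net = _Network(cfg)
        opt = ad.Adam(net.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        train_idx, val_idx, _ = self.splits
        history = {"train_loss": [], "val_loss": []}
        best_val = math.inf
        best_state = net.state_dict()
        best_epoch = -1
        t0 = time.time()
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                y = net.forward(self.batch.tensor[sel],
                                seed=int(rng.integers(2 ** 31)))
                loss = _bce_tensor(y, self.labels[:, sel].T)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            train_loss = float(np.mean(losses))
            val_loss = (self._epoch_loss(net, val_idx, seed=0)
                        if len(val_idx) else train_loss)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch + 1:3d}  train {train_loss:.4f}  "
                      f"val {val_loss:.4f}  ({time.time() - t0:.0f}s)")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = net.state_dict()
                best_epoch = epoch
            elif epoch - best_epoch >= cfg.patience:
                break
        net.load_state_dict(best_state)
        return AccessibilityResults(self, net, history, best_epoch, best_val)


class AccessibilityResults:
    """Fitted model: predictions, embeddings, diagnostics."""

    def __init__(self, model: AccessibilityModel | None, net: _Network,
                 history: dict, best_epoch: int, best_val_loss: float,
                 cell_ids: list[str] | None = None):
        self.model = model
        self._net = net
        self.config = net.config
        self.history = history
        self.best_epoch = best_epoch
        self.best_val_loss = best_val_loss
        if cell_ids is not None:
            self.cell_ids = list(cell_ids)
        elif model is not None:
            self.cell_ids = list(model.cell_ids)
        else:
            self.cell_ids = [f"cell{i}" for i in range(net.config.n_cells)]

    # -- inference ----------------------------------------------------------
    def predict(self, batch: OneHotBatch | np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Per-cell accessibility probabilities, shape (sequences, cells)."""
        x = batch.tensor if isinstance(batch, OneHotBatch) else np.asarray(batch)
        if x.ndim == 2:
            x = x[None]
        out = []
        for start in range(0, x.shape[0], batch_size):
            y = self._net.forward(x[start:start + batch_size], seed=0)
            out.append(y.data)
        return np.vstack(out)

    def embed_sequences(self, batch: OneHotBatch | np.ndarray,
                        batch_size: int = 64) -> np.ndarray:
        x = batch.tensor if isinstance(batch, OneHotBatch) else np.asarray(batch)
        out = []
        for start in range(0, x.shape[0], batch_size):
            _, z = self._net.forward(x[start:start + batch_size], seed=0,
                                     return_embedding=True)
            out.append(z.data)
        return np.vstack(out)

    def cell_embeddings(self) -> CellEmbedding:
        """The read-out weights, transposed to (cells, embedding_size), plus
        the per-cell depth intercept b_p."""
        W_p = self._net.params["pred_w"].data
        b_p = self._net.params["pred_b"].data
        ids = self.cell_ids or [f"cell{i}" for i in range(len(b_p))]
        return CellEmbedding(W_p.T.copy(), b_p.copy(), list(ids))

    def evaluate_auroc(self, subset: str = "test",
                       labels: np.ndarray | None = None) -> float:
        """Mean per-cell auROC on a held-out peak subset of the bound dataset;
        ``labels`` (cells x peaks) overrides the training labels."""
        if self.model is None:
            raise ValueError("results not bound to a dataset")
        idx = {"train": 0, "val": 1, "test": 2}[subset]
        sel = self.model.splits[idx]
        scores = self.predict(self.model.batch.tensor[sel])
        lab = self.model.labels if labels is None else np.asarray(labels)
        return mean_auroc(scores, lab[:, sel].T)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Accessibility model (probability-sparse attention encoder)",
            "=" * 58,
            f"cells: {cfg.n_cells}    input length: {cfg.input_length} bp",
            f"embedding width d: {cfg.d}   heads: {cfg.n_heads}   "
            f"layers: {cfg.n_layers}",
            f"tokens per stage: {cfg.token_counts()}",
            f"parameters: {self._net.n_parameters():,}",
            f"epochs run: {len(self.history['train_loss'])}   "
            f"best epoch: {self.best_epoch + 1}",
            f"best validation BCE: {self.best_val_loss:.4f}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Per-epoch train/validation loss curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        epochs = np.arange(1, len(self.history["train_loss"]) + 1)
        ax.plot(epochs, self.history["train_loss"], label="train")
        ax.plot(epochs, self.history["val_loss"], label="validation")
        ax.axvline(self.best_epoch + 1, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("binary cross-entropy")
        ax.legend(frameon=False)
        return ax

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        """Single ``.npz`` checkpoint + JSON sidecar of config and history."""
        state = self._net.state_dict()
        np.savez_compressed(path, **state)
        meta = {"config": asdict(self.config), "history": self.history,
                "best_epoch": self.best_epoch,
                "best_val_loss": self.best_val_loss,
                "cell_ids": list(self.cell_ids or [])}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path: str) -> "AccessibilityResults":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        config = ModelConfig(**meta["config"])
        net = _Network(config)
        with np.load(path if str(path).endswith(".npz") else str(path)) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return cls(None, net, meta["history"], meta["best_epoch"],
                   meta["best_val_loss"], cell_ids=meta["cell_ids"] or None)
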