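"""Neural building blocks: peephole LSTM, BLSTM autoencoder, residual TCN.

The pieces implemented here, in the order they compose:

* an LSTM memory cell with the three peephole connections (the input and
  forget gates peek at the previous cell state, the output gate at the
  current one), tanh cell input/output and logistic gates;
* a bidirectional wrapper running independent forward and backward passes
  over a window and concatenating the per-step outputs;
* the autoencoder reconstruction error RE = 1/2 * sum_i ||z_i - zhat_i||^2
  used as the change/anomaly score (a literal difference-of-norms variant,
  1/2 * sum_i (||z_i|| - ||zhat_i||)^2, is available behind a flag for
  auditability — it is degenerate as a loss, being blind to rotations of the
  reconstruction, and is never used for training);
* dilated causal convolution y_i = sum_j g_j * x_{i-d*j} and the receptive
  field D = (S-1)(2^K - 1) + 1 of a K-layer stack with doubling dilations;
* residual TCN blocks (two equal-dilation convolutions with ReLU + dropout,
  identity or 1x1-projection skip) with a global-average-pool softmax head
  for supervised pretraining.

Two frozen architecture configurations ship as defaults — the standalone
autoencoder (BLSTM hidden sizes [16, 256, 16], fully-connected sizes
[500, 50, 500], middle-block dropout 0.7810), the five-block TCN (256
filters, kernel sizes [8, 6, 19, 8, 7]) and the joint-use autoencoder
(hidden [256, 128, 256], fully-connected [200, 100, 200]) — together with
``scaled()`` variants (hidden sizes / 8) for desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, dropout  # noqa: F401  (Adam re-export)
from .preprocess import ValidationError


# ---------------------------------------------------------------------------
# LSTM memory cell with peepholes

@dataclass
class LSTMCellParams:
    """Weights of one peephole LSTM cell (hidden size M, input size N).

    ``W`` maps the input, ``R`` the recurrent output, ``b`` is the bias, for
    each of the cell input ``I`` and the input/forget/output gates
    ``i``/``f``/``o``; ``p_i``/``p_f``/``p_o`` are the peephole vectors.
    """

    W: dict[str, Tensor]
    R: dict[str, Tensor]
    b: dict[str, Tensor]
    p: dict[str, Tensor]
    M: int
    N: int

    KEYS = ("I", "i", "f", "o")

    @classmethod
    def init(cls, N: int, M: int, rng: np.random.Generator,
             zero: bool = False) -> "LSTMCellParams":
        """Glorot-uniform weights; biases and peepholes start at zero."""
        def mat(rows, cols):
            if zero:
                return Tensor(np.zeros((rows, cols)), requires_grad=True)
            lim = np.sqrt(6.0 / (rows + cols))
            return Tensor(rng.uniform(-lim, lim, (rows, cols)),
                          requires_grad=True)

        W = {k: mat(M, N) for k in cls.KEYS}
        R = {k: mat(M, M) for k in cls.KEYS}
        b = {k: Tensor(np.zeros(M), requires_grad=True) for k in cls.KEYS}
        p = {k: Tensor(np.zeros(M), requires_grad=True) for k in ("i", "f", "o")}
        return cls(W=W, R=R, b=b, p=p, M=M, N=N)

    def parameters(self) -> list[Tensor]:
        return [*self.W.values(), *self.R.values(), *self.b.values(),
                *self.p.values()]


def lstm_step(params: LSTMCellParams, x, O_prev, c_prev):
    """One peephole-LSTM transition.

    ``x`` may be (N,) or batched (B, N); ``O_prev``/``c_prev`` match with M
    in place of N.  Returns ``(O, c)`` as autodiff tensors (use ``.data``
    for the arrays).  Gate equations: cell input I = tanh(Wx + RO + b);
    input/forget gates peek at c_prev, the output gate at the current c;
    c = i*I + f*c_prev; O = o*tanh(c).
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    O_prev = O_prev if isinstance(O_prev, Tensor) else Tensor(O_prev)
    c_prev = c_prev if isinstance(c_prev, Tensor) else Tensor(c_prev)
    if x.shape[-1] != params.N or O_prev.shape[-1] != params.M \
            or c_prev.shape[-1] != params.M:
        raise ValidationError("lstm_step shape mismatch")

    def lin(k):
        return x @ params.W[k].transpose() + O_prev @ params.R[k].transpose() \
            + params.b[k]

    I = lin("I").tanh()
    i = (lin("i") + params.p["i"] * c_prev).sigmoid()
    f = (lin("f") + params.p["f"] * c_prev).sigmoid()
    c = i * I + f * c_prev
    o = (lin("o") + params.p["o"] * c).sigmoid()
    O = o * c.tanh()
    return O, c


class LSTMLayer:
    """Unidirectional LSTM over a sequence (T, B, N) -> (T, B, M)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.cell = LSTMCellParams.init(n_in, n_hidden, rng)

    def forward(self, seq: Tensor) -> list[Tensor]:
        T, B = seq.shape[0], seq.shape[1]
        O = Tensor(np.zeros((B, self.cell.M)))
        c = Tensor(np.zeros((B, self.cell.M)))
        outs = []
        for t in range(T):
            O, c = lstm_step(self.cell, seq[t], O, c)
            outs.append(O)
        return outs

    def parameters(self) -> list[Tensor]:
        return self.cell.parameters()


class BLSTMLayer:
    """Bidirectional LSTM: independent forward and backward passes,
    per-step outputs concatenated -> (T, B, 2M)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fwd = LSTMLayer(n_in, n_hidden, rng)
        self.bwd = LSTMLayer(n_in, n_hidden, rng)
        self.n_out = 2 * n_hidden

    def forward(self, seq: Tensor) -> Tensor:
        if seq.shape[0] == 0:
            raise ValidationError("empty sequence")
        T = seq.shape[0]
        f_outs = self.fwd.forward(seq)
        rev = seq[::-1]
        b_outs = self.bwd.forward(rev)[::-1]
        steps = [concat([f_outs[t], b_outs[t]], axis=-1) for t in range(T)]
        return concat([s.reshape(1, *s.shape) for s in steps], axis=0)

    def parameters(self) -> list[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters()


def blstm_forward(layer: BLSTMLayer, sequence) -> np.ndarray:
    """Run a BLSTM layer over a (T, N) or (T, B, N) sequence; numpy out."""
    seq = sequence if isinstance(sequence, Tensor) else Tensor(sequence)
    squeeze = False
    if len(seq.shape) == 2:
        seq = seq.reshape(seq.shape[0], 1, seq.shape[1])
        squeeze = True
    out = layer.forward(seq).data
    return out[:, 0, :] if squeeze else out


# ---------------------------------------------------------------------------
# reconstruction error

def reconstruction_error(z, zhat, literal: bool = False) -> float:
    """RE(z, zhat) = 1/2 * sum_i ||z_i - zhat_i||^2 over rows.

    ``literal=True`` computes the difference-of-norms variant
    1/2 * sum_i (||z_i|| - ||zhat_i||)^2 (audit only; rotation-blind).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    zh = np.atleast_2d(np.asarray(zhat, dtype=float))
    if z.shape != zh.shape:
        raise ValidationError("reconstruction_error shape mismatch")
    if literal:
        return float(0.5 * np.sum((np.linalg.norm(z, axis=1)
                                   - np.linalg.norm(zh, axis=1)) ** 2))
    return float(0.5 * np.sum((z - zh) ** 2))


# ---------------------------------------------------------------------------
# dilated causal convolution

def dcc(x: np.ndarray, g: np.ndarray, d: int) -> np.ndarray:
    """Dilated causal convolution: y_i = sum_{j<S} g_j * x_{i-d*j}.

    Left zero-padding keeps the output length equal to the input length and
    guarantees causality (y_i never references samples after i).  For d = 1
    this is the classical causal convolution.  Requires N > S > d as the
    size ordering of the definition.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    N, S = len(x), len(g)
    if not (N > S > d >= 1):
        raise ValidationError(
            f"size ordering N > S > d >= 1 violated (N={N}, S={S}, d={d})")
    xp = np.pad(x, ((S - 1) * d, 0))
    y = np.zeros(N)
    for j in range(S):
        y += g[j] * xp[(S - 1 - j) * d: (S - 1 - j) * d + N]
    return y


def receptive_field(S: int, K: int) -> int:
    """Receptive field D = (S-1)(2^K - 1) + 1 of K layers with kernel S and
    doubling dilations d_k = 2^(k-1)."""
    if S < 1 or K < 1:
        raise ValidationError("S and K must be >= 1")
    return (S - 1) * (2 ** K - 1) + 1


class DCCLayer:
    """Multichannel dilated causal convolution (B, Cin, T) -> (B, Cout, T)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        lim = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.W = Tensor(rng.uniform(-lim, lim, (kernel, c_in, c_out)),
                        requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel, self.dilation = kernel, dilation

    def forward(self, x: Tensor) -> Tensor:
        S, d = self.kernel, self.dilation
        T = x.shape[-1]
        xp = x.pad_left((S - 1) * d, axis=-1)
        terms = None
        for j in range(S):
            a = (S - 1 - j) * d
            sl = xp[:, :, a:a + T]                      # (B, Cin, T)
            term = (sl.transpose(0, 2, 1) @ self.W[j])  # (B, T, Cout)
            terms = term if terms is None else terms + term
        return (terms + self.bias).transpose(0, 2, 1)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.bias]


class ResidualBlock:
    """Two equal-dilation causal convolutions with ReLU + dropout, plus an
    identity (or 1x1-projection) skip connection."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 p_drop: float, rng: np.random.Generator):
        self.conv1 = DCCLayer(c_in, c_out, kernel, dilation, rng)
        self.conv2 = DCCLayer(c_out, c_out, kernel, dilation, rng)
        self.proj = DCCLayer(c_in, c_out, 1, 1, rng) if c_in != c_out else None
        self.p_drop = p_drop

    def forward(self, x: Tensor, rng: np.random.Generator,
                train: bool) -> Tensor:
        h = dropout(self.conv1.forward(x).relu(), self.p_drop, rng, train)
        h = dropout(self.conv2.forward(h).relu(), self.p_drop, rng, train)
        skip = self.proj.forward(x) if self.proj is not None else x
        return (h + skip).relu()

    def parameters(self) -> list[Tensor]:
        ps = self.conv1.parameters() + self.conv2.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps


# ---------------------------------------------------------------------------
# configurations (frozen defaults + scaled desk variants)

@dataclass(frozen=True)
class TCNConfig:
    """Residual-TCN architecture: per-block filters/kernels/dropout;
    dilations double per block (d_k = 2^(k-1))."""

    n_filters: tuple[int, ...] = (256, 256, 256, 256, 256)
    kernel_sizes: tuple[int, ...] = (8, 6, 19, 8, 7)
    dropouts: tuple[float, ...] = (0.6116, 0.6391, 0.0438, 0.6323, 0.5121)
    n_classes: int = 4

    def __post_init__(self) -> None:
        K = len(self.n_filters)
        if K < 1 or len(self.kernel_sizes) != K or len(self.dropouts) != K:
            raise ValidationError("per-block parameter lists must align, K >= 1")
        if any(s < 1 for s in self.kernel_sizes):
            raise ValidationError("kernel sizes must be >= 1")
        if any(not (0 <= p < 1) for p in self.dropouts):
            raise ValidationError("dropout probabilities must be in [0, 1)")

    @property
    def K(self) -> int:
        return len(self.n_filters)

    @property
    def dilations(self) -> tuple[int, ...]:
        return tuple(2 ** k for k in range(self.K))

    def scaled(self, hidden_div: int = 8) -> "TCNConfig":
        """Desk-scale variant: filter counts divided by ``hidden_div``."""
        return TCNConfig(
            n_filters=tuple(max(4, n // hidden_div) for n in self.n_filters),
            kernel_sizes=self.kernel_sizes, dropouts=self.dropouts,
            n_classes=self.n_classes)


@dataclass(frozen=True)
class BLSTMAEBlock:
    units: int
    fc_out: int
    relu: bool = False
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        if self.units < 1 or self.fc_out < 1:
            raise ValidationError("block sizes must be >= 1")


@dataclass(frozen=True)
class BLSTMAEConfig:
    """Encoder-bottleneck-decoder block stack; the middle block's
    fully-connected output is the latent size N'."""

    blocks: tuple[BLSTMAEBlock, ...] = (
        BLSTMAEBlock(16, 500),
        BLSTMAEBlock(256, 50, relu=True, dropout=0.7810),
        BLSTMAEBlock(16, 500),
    )

    def __post_init__(self) -> None:
        if len(self.blocks) < 3:
            raise ValidationError("need at least 3 blocks")

    @property
    def latent_size(self) -> int:
        return self.blocks[len(self.blocks) // 2].fc_out

    @classmethod
    def standalone(cls) -> "BLSTMAEConfig":
        """The standalone change-detector autoencoder configuration."""
        return cls()

    @classmethod
    def joint(cls) -> "BLSTMAEConfig":
        """The configuration optimized for use on TCN activations."""
        return cls(blocks=(
            BLSTMAEBlock(256, 200, dropout=0.0083),
            BLSTMAEBlock(128, 100, relu=True, dropout=0.2875),
            BLSTMAEBlock(256, 200, dropout=0.0095),
        ))

    def scaled(self, hidden_div: int = 8) -> "BLSTMAEConfig":
        return BLSTMAEConfig(blocks=tuple(
            BLSTMAEBlock(max(2, b.units // hidden_div),
                         max(2, b.fc_out // hidden_div),
                         b.relu, b.dropout)
            for b in self.blocks))


# ---------------------------------------------------------------------------
# model objects

class FCLayer:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-lim, lim, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BLSTMAutoencoder:
    """Sequence autoencoder with BLSTM+FC blocks and a bottleneck.

    Operates on windows shaped (batch, n_channels, seq_len), internally
    (T, B, C).  Each block applies a BLSTM then a per-step fully-connected
    map (optionally ReLU + dropout); a final linear projection restores the
    input channel count so the output reconstructs the input sequence.
    """

    def __init__(self, config: BLSTMAEConfig, n_in: int, seq_len: int,
                 seed: int = 0):
        total_in = n_in * seq_len
        if config.latent_size >= total_in:
            raise ValidationError(
                f"bottleneck violated: latent size {config.latent_size} must "
                f"be smaller than the input size {total_in}")
        rng = np.random.default_rng(seed)
        self.config = config
        self.n_in, self.seq_len = n_in, seq_len
        self.blocks = []
        dim = n_in
        for blk in config.blocks:
            bl = BLSTMLayer(dim, blk.units, rng)
            fc = FCLayer(bl.n_out, blk.fc_out, rng)
            self.blocks.append((bl, fc, blk))
            dim = blk.fc_out
        self.out_proj = FCLayer(dim, n_in, rng)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None,
                train: bool = False) -> Tensor:
        """(B, C, T) -> reconstruction (B, C, T)."""
        if rng is None:
            rng = np.random.default_rng(0)
        h = x.transpose(2, 0, 1)                    # (T, B, C)
        for bl, fc, blk in self.blocks:
            h = fc.forward(bl.forward(h))
            if blk.relu:
                h = h.relu()
            h = dropout(h, blk.dropout, rng, train)
        return self.out_proj.forward(h).transpose(1, 2, 0)

    def parameters(self) -> list[Tensor]:
        ps = []
        for bl, fc, _ in self.blocks:
            ps += bl.parameters() + fc.parameters()
        return ps + self.out_proj.parameters()

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def window_re(self, windows: np.ndarray) -> np.ndarray:
        """Per-window reconstruction error of (B, C, T) windows."""
        recon = self.forward(Tensor(windows)).data
        return 0.5 * np.sum((windows - recon) ** 2, axis=(1, 2))


class TCN:
    """Residual TCN with doubling dilations and a 4-way softmax head.

    ``forward`` yields class logits via global average pooling over time;
    ``activations`` yields the time-pooled output of the last residual
    block (the learned feature vector fed to the joint autoencoder).
    """

    def __init__(self, config: TCNConfig, n_in: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.n_in = n_in
        self.blocks = []
        c = n_in
        for k in range(config.K):
            self.blocks.append(ResidualBlock(
                c, config.n_filters[k], config.kernel_sizes[k],
                config.dilations[k], config.dropouts[k], rng))
            c = config.n_filters[k]
        self.head = FCLayer(c, config.n_classes, rng)

    def _features(self, x: Tensor, rng, train: bool) -> Tensor:
        h = x
        for blk in self.blocks:
            h = blk.forward(h, rng, train)
        return h.mean(axis=2)                       # (B, C_last) time pool

    def forward(self, x: Tensor, rng: np.random.Generator | None = None,
                train: bool = False) -> Tensor:
        """(B, C, T) -> logits (B, n_classes)."""
        if rng is None:
            rng = np.random.default_rng(0)
        return self.head.forward(self._features(x, rng, train))

    def activations(self, windows: np.ndarray) -> np.ndarray:
        """Learned features: time-pooled last-block output, (B, C_last)."""
        return self._features(Tensor(windows), np.random.default_rng(0),
                              train=False).data

    def parameters(self) -> list[Tensor]:
        ps = []
        for blk in self.blocks:
            ps += blk.parameters()
        return ps + self.head.parameters()

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_blstm_ae(config: BLSTMAEConfig, n_in: int, seq_len: int,
                   seed: int = 0) -> BLSTMAutoencoder:
    """Construct the BLSTM autoencoder for (n_in x seq_len) windows."""
    return BLSTMAutoencoder(config, n_in, seq_len, seed)


def build_tcn(config: TCNConfig, n_in: int, seed: int = 0) -> TCN:
    """Construct the residual TCN feature learner."""
    return TCN(config, n_in, seed)


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(model, path) -> None:
    """Persist model weights + config to one .npz checkpoint."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    if isinstance(model, BLSTMAutoencoder):
        meta = {"kind": "blstm_ae", "n_in": model.n_in,
                "seq_len": model.seq_len,
                "blocks": [[b.units, b.fc_out, b.relu, b.dropout]
                           for b in model.config.blocks]}
    elif isinstance(model, TCN):
        meta = {"kind": "tcn", "n_in": model.n_in,
                "n_filters": list(model.config.n_filters),
                "kernel_sizes": list(model.config.kernel_sizes),
                "dropouts": list(model.config.dropouts),
                "n_classes": model.config.n_classes}
    else:
        raise ValidationError(f"cannot checkpoint {type(model).__name__}")
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint written by save_checkpoint."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    if meta["kind"] == "blstm_ae":
        cfg = BLSTMAEConfig(blocks=tuple(
            BLSTMAEBlock(u, f, bool(r), d) for u, f, r, d in meta["blocks"]))
        model = BLSTMAutoencoder(cfg, meta["n_in"], meta["seq_len"])
    else:
        cfg = TCNConfig(n_filters=tuple(meta["n_filters"]),
                        kernel_sizes=tuple(meta["kernel_sizes"]),
                        dropouts=tuple(meta["dropouts"]),
                        n_classes=meta["n_classes"])
        model = TCN(cfg, meta["n_in"])
    for i, p in enumerate(model.parameters()):
        p.data[...] = arrays[f"p{i}"]
    return model
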