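"""The hybrid tabular classifier: CNN → LSTM → topology refinement → softmax.

The preprocessed feature vector is treated as a length-F single-channel 1-D
signal.  Convolutional layers extract local feature patterns; the feature map
is chunked into ordered segments that form the sequence consumed by a gated
recurrent stage (LSTM by default, GRU selectable); a dense layer produces the
final feature vector x_L.  The topology-refinement stage builds a
feature-by-feature adjacency matrix

    a_ij = ReLU(w_ij · x_L)

(one learnable weight vector per feature pair), multiplies it onto x_L and
concatenates the refined features with x_L before the softmax head:

    y = softmax(W_out · concat(A x_L, x_L) + b_out)

Ablation variants toggle the three stages independently; the MLP-only variant
keeps only dense layers.  All shapes derive from :func:`param_specs` so that
initialization, training and serialization stay consistent.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from ._autograd import Tensor

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "ModelState",
    "build_variant",
    "param_specs",
    "forward",
    "predict_proba",
    "predict",
    "conv1d_forward",
    "activate",
    "recurrent_forward",
    "topology_adjacency",
    "classify",
    "save_model",
    "load_model",
]

# Table of ablation variants: name -> (use_cnn, use_lstm, use_topology)
VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    "full":         (True, True, True),
    "cnn_only":     (True, False, False),
    "cnn_lstm":     (True, True, False),
    "cnn_topology": (True, False, True),
    "lstm_only":    (False, True, False),
    "mlp_only":     (False, False, False),
}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    n_features: int
    n_classes: int
    use_cnn: bool = True
    use_lstm: bool = True
    use_topology: bool = True
    n_layers: int = 5               # total depth: conv stack + recurrent + dense + head
    kernel_size: int = 3
    channels: tuple[int, ...] = (8, 16)
    lstm_hidden: int = 32
    feat_dim: int = 32              # size of the final feature vector x_L
    mlp_hidden: tuple[int, ...] = (64, 32)
    n_segments: int = 5             # sequence length fed to the recurrent stage
    dropout: float = 0.5
    activation: str = "relu"
    topology_mode: str = "learned"  # learned | correlation
    recurrent_cell: str = "lstm"    # lstm | gru
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same padding)")
        if self.activation not in ("relu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.topology_mode not in ("learned", "correlation"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")
        if self.recurrent_cell not in ("lstm", "gru"):
            raise ValueError(f"unknown recurrent_cell {self.recurrent_cell!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d) -> "ModelConfig":
        d = dict(d)
        for k in ("channels", "mlp_hidden"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def build_variant(
    name: str, n_features: int, n_classes: int, **overrides
) -> ModelConfig:
    """Config for one of the six ablation variants; other hyperparameters are
    shared across variants unless overridden."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    cnn, lstm, topo = VARIANTS[name]
    return ModelConfig(
        n_features=n_features, n_classes=n_classes,
        use_cnn=cnn, use_lstm=lstm, use_topology=topo, **overrides,
    )


@dataclasses.dataclass
class ModelState:
    """All learnable parameters plus the config and init seed that shaped them."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    init_seed: int

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            init_seed=self.init_seed,
        )


def _chunk_len(cfg: ModelConfig) -> int:
    return -(-cfg.n_features // cfg.n_segments)  # ceil division


def param_specs(cfg: ModelConfig) -> list[tuple[str, tuple[int, ...], int, int]]:
    """(name, shape, fan_in, fan_out) for every learnable tensor.

    Names containing ``.b`` are biases (zero-initialized, exempt from L2).
    """
    specs: list[tuple[str, tuple[int, ...], int, int]] = []
    chunk = _chunk_len(cfg)
    if cfg.use_cnn:
        c_in = 1
        for i, c_out in enumerate(cfg.channels):
            k = cfg.kernel_size
            specs.append((f"conv{i}.W", (c_out, c_in, k), c_in * k, c_out * k))
            specs.append((f"conv{i}.b", (c_out,), 0, 0))
            c_in = c_out
        map_channels = cfg.channels[-1]
    else:
        map_channels = 1

    if cfg.use_lstm:
        step_in = map_channels * chunk
        H = cfg.lstm_hidden
        gates = 4 if cfg.recurrent_cell == "lstm" else 3
        specs.append(("rnn.Wx", (step_in, gates * H), step_in, H))
        specs.append(("rnn.Wh", (H, gates * H), H, H))
        specs.append(("rnn.b", (gates * H,), 0, 0))
        feat_in = H
    elif cfg.use_cnn:
        feat_in = map_channels * cfg.n_features
    else:
        d_in = cfg.n_features
        for i, h in enumerate(cfg.mlp_hidden):
            specs.append((f"mlp{i}.W", (d_in, h), d_in, h))
            specs.append((f"mlp{i}.b", (h,), 0, 0))
            d_in = h
        feat_in = d_in

    D = cfg.feat_dim
    specs.append(("feat.W", (feat_in, D), feat_in, D))
    specs.append(("feat.b", (D,), 0, 0))

    if cfg.use_topology and cfg.topology_mode == "learned":
        specs.append(("topo.W", (D, D, D), D, 1))

    head_in = 2 * D if cfg.use_topology else D
    specs.append(("out.W", (head_in, cfg.n_classes), head_in, cfg.n_classes))
    specs.append(("out.b", (cfg.n_classes,), 0, 0))
    return specs


# ---------------------------------------------------------------------------
# forward computation (autograd path used for both training and inference)
# ---------------------------------------------------------------------------

def _apply_activation(t: Tensor, kind: str) -> Tensor:
    return {"relu": t.relu, "sigmoid": t.sigmoid, "tanh": t.tanh}[kind]()


def _rnn_steps(cfg: ModelConfig, x: Tensor, channels: int) -> list[Tensor]:
    """Chunk a (B, channels, F) map — or (B, F) vector — into S ordered steps."""
    chunk = _chunk_len(cfg)
    total = chunk * cfg.n_segments
    if x.data.ndim == 2:
        B = x.data.shape[0]
        x = x.reshape(B, 1, cfg.n_features)
    B = x.data.shape[0]
    pad = total - cfg.n_features
    if pad:
        zeros = Tensor(np.zeros((B, channels, pad)))
        x = Tensor.concat([x, zeros], axis=-1)
    steps = []
    for s in range(cfg.n_segments):
        seg = x.slice_cols(s * chunk, (s + 1) * chunk)
        steps.append(seg.reshape(B, channels * chunk))
    return steps


def _lstm_scan(steps, Wx: Tensor, Wh: Tensor, b: Tensor, H: int) -> Tensor:
    B = steps[0].data.shape[0]
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    for x_t in steps:
        z = x_t.matmul(Wx) + h.matmul(Wh) + b
        i = z.slice_cols(0, H).sigmoid()
        f = z.slice_cols(H, 2 * H).sigmoid()
        g = z.slice_cols(2 * H, 3 * H).tanh()
        o = z.slice_cols(3 * H, 4 * H).sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
    return h


def _gru_scan(steps, Wx: Tensor, Wh: Tensor, b: Tensor, H: int) -> Tensor:
    B = steps[0].data.shape[0]
    h = Tensor(np.zeros((B, H)))
    one = Tensor(np.ones((B, H)))
    neg = Tensor(-np.ones((B, H)))
    for x_t in steps:
        zx = x_t.matmul(Wx) + b
        zh = h.matmul(Wh)
        z = (zx.slice_cols(0, H) + zh.slice_cols(0, H)).sigmoid()
        r = (zx.slice_cols(H, 2 * H) + zh.slice_cols(H, 2 * H)).sigmoid()
        n = (zx.slice_cols(2 * H, 3 * H) + r * zh.slice_cols(2 * H, 3 * H)).tanh()
        h = (one + neg * z) * n + z * h
    return h


def forward(
    params: dict[str, Tensor],
    cfg: ModelConfig,
    X: np.ndarray,
    rng: np.random.Generator | None = None,
    return_extras: bool = False,
):
    """Compute class logits for a batch.

    ``rng`` enables dropout (training mode); ``None`` disables it, making the
    forward pass deterministic.  With ``return_extras`` the final feature
    vector x_L and the adjacency tensor A are also returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = X.shape[0]
    p = cfg.dropout
    act = cfg.activation

    if cfg.use_cnn:
        h = Tensor(X.reshape(B, 1, cfg.n_features))
        for i in range(len(cfg.channels)):
            h = h.conv1d_same(params[f"conv{i}.W"], params[f"conv{i}.b"])
            h = _apply_activation(h, act)
        cmap, channels = h, cfg.channels[-1]
    else:
        cmap, channels = Tensor(X), 1

    if cfg.use_lstm:
        steps = _rnn_steps(cfg, cmap, channels)
        H = cfg.lstm_hidden
        scan = _lstm_scan if cfg.recurrent_cell == "lstm" else _gru_scan
        feat_in = scan(steps, params["rnn.Wx"], params["rnn.Wh"], params["rnn.b"], H)
    elif cfg.use_cnn:
        feat_in = cmap.reshape(B, channels * cfg.n_features)
    else:
        feat_in = Tensor(X)
        for i in range(len(cfg.mlp_hidden)):
            feat_in = feat_in.matmul(params[f"mlp{i}.W"]) + params[f"mlp{i}.b"]
            feat_in = _apply_activation(feat_in, act).dropout(p, rng)

    x_L = feat_in.matmul(params["feat.W"]) + params["feat.b"]
    x_L = _apply_activation(x_L, act)

    A = None
    if cfg.use_topology:
        if cfg.topology_mode == "learned":
            A = x_L.pair_bilinear(params["topo.W"]).relu()
            # 1/D normalization keeps the refined features on the same scale
            # as x_L (the row sums of A grow with the feature count)
            refined = A.bmm_vec(x_L).scale(1.0 / cfg.feat_dim)
        else:
            # batch-level correlation adjacency, treated as a constant:
            # gradients flow through x_L but not through A itself
            A_np = topology_adjacency(x_L.data, mode="correlation")
            A = Tensor(np.broadcast_to(A_np, (B,) + A_np.shape))
            refined = x_L.matmul(Tensor(A_np.T))
        z = Tensor.concat([refined, x_L], axis=-1)
    else:
        z = x_L

    # dropout regularizes the classifier head, downstream of the (quadratic)
    # topology map, so the adjacency is built from clean activations
    logits = z.dropout(p, rng).matmul(params["out.W"]) + params["out.b"]
    if return_extras:
        return logits, x_L, A
    return logits


def _tensors(state: ModelState) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in state.params.items()}


def predict_proba(state: ModelState, X: np.ndarray, batch: int = 1024) -> np.ndarray:
    """Class probabilities with dropout disabled, computed in batches."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = []
    params = _tensors(state)
    for start in range(0, X.shape[0], batch):
        logits = forward(params, state.config, X[start : start + batch]).data
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        out.append(ez / ez.sum(axis=1, keepdims=True))
    return np.vstack(out)


def predict(state: ModelState, X: np.ndarray) -> np.ndarray:
    return predict_proba(state, X).argmax(axis=1)


# ---------------------------------------------------------------------------
# standalone building-block operations (plain numpy, no tape)
# ---------------------------------------------------------------------------

def conv1d_forward(
    X: np.ndarray, W: np.ndarray, b: np.ndarray | float = 0.0,
    padding: str = "same",
) -> np.ndarray:
    """1-D cross-correlation of a (C_in, F) signal with (C_out, C_in, k)
    kernels, stride 1.  ``padding`` is 'same' (zero padding, output length F)
    or 'valid'.  A 1-D input/kernel is treated as single-channel."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if W.ndim == 1:
        W = W[None, None, :]
    elif W.ndim == 2:
        W = W[:, None, :]
    C_in, F = X.shape
    C_out, C_in_w, k = W.shape
    if C_in_w != C_in:
        raise ValueError(
            f"kernel expects {C_in_w} input channels, signal has {C_in}"
        )
    if padding == "same":
        pad = (k - 1) // 2
        Xp = np.pad(X, ((0, 0), (pad, k - 1 - pad)))
        out_len = F
    elif padding == "valid":
        if k > F:
            raise ValueError(f"kernel length {k} exceeds input length {F}")
        Xp, out_len = X, F - k + 1
    else:
        raise ValueError(f"unknown padding {padding!r}")
    b = np.broadcast_to(np.asarray(b, dtype=float), (C_out,))
    out = np.empty((C_out, out_len))
    for o in range(C_out):
        for t in range(out_len):
            out[o, t] = np.sum(Xp[:, t : t + k] * W[o]) + b[o]
    return out


def activate(Z: np.ndarray, kind: str) -> np.ndarray:
    """Element-wise activation; one of relu / sigmoid / tanh."""
    Z = np.asarray(Z, dtype=float)
    if kind == "relu":
        return np.maximum(Z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-Z))
    if kind == "tanh":
        return np.tanh(Z)
    raise ValueError(f"unknown activation {kind!r}")


def recurrent_forward(
    sequence: np.ndarray, params: dict[str, np.ndarray], cell: str = "lstm"
) -> np.ndarray:
    """Run a gated recurrence over a (T, d) sequence; return the final hidden
    state.  ``params`` holds Wx (d, G·H), Wh (H, G·H), b (G·H,) with G = 4
    for LSTM (gate order i, f, g, o) and G = 3 for GRU (z, r, n)."""
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    if seq.shape[0] == 0:
        raise ValueError("empty sequence")
    gates = 4 if cell == "lstm" else 3
    H = params["Wh"].shape[0]
    if params["Wx"].shape[1] != gates * H:
        raise ValueError("parameter shapes inconsistent with cell type")
    steps = [Tensor(seq[t : t + 1]) for t in range(seq.shape[0])]
    Wx, Wh, b = (Tensor(params[k]) for k in ("Wx", "Wh", "b"))
    scan = _lstm_scan if cell == "lstm" else _gru_scan
    return scan(steps, Wx, Wh, b, H).data[0]


def topology_adjacency(
    X: np.ndarray, W: np.ndarray | None = None, mode: str = "learned"
) -> np.ndarray:
    """Feature-by-feature adjacency.

    learned:      a_ij = ReLU(W[i, j, :] · x) for a single feature vector x.
    correlation:  a_ij = |Pearson correlation of features i, j| across the
                  rows of X, diagonal 1; zero-variance features get zero rows
                  and columns (diagonal kept at 1) with a warning.
    """
    X = np.asarray(X, dtype=float)
    if mode == "learned":
        if W is None:
            raise ValueError("learned mode needs the pair-weight tensor W")
        x = X.ravel()
        return np.maximum(np.einsum("ijd,d->ij", W, x), 0.0)
    if mode == "correlation":
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("correlation mode needs >= 2 rows of activations")
        sd = X.std(axis=0)
        dead = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
        A = np.abs(np.nan_to_num(C, nan=0.0))
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} zero-variance feature(s) in correlation "
                "adjacency; rows/columns zeroed"
            )
            A[dead, :] = 0.0
            A[:, dead] = 0.0
        np.fill_diagonal(A, 1.0)
        return A
    raise ValueError(f"unknown mode {mode!r}")


def classify(
    X_L: np.ndarray, A: np.ndarray | None, W_out: np.ndarray, b_out: np.ndarray
) -> np.ndarray:
    """Softmax head: concat(A·x_L/D, x_L) when an adjacency is given, else
    x_L, then an affine map and softmax.  Returns a probability vector.  The
    refined features carry the same 1/D normalization as the trained network
    so the two code paths agree."""
    x = np.asarray(X_L, dtype=float).ravel()
    if A is not None:
        z = np.concatenate([np.asarray(A, float) @ x / x.size, x])
    else:
        z = x
    if W_out.shape[0] != z.size:
        raise ValueError(
            f"W_out expects input of length {W_out.shape[0]}, got {z.size}"
        )
    logits = z @ W_out + np.asarray(b_out, float)
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(state: ModelState, path) -> None:
    """Write parameters as .npz beside a JSON manifest of config and shapes."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **state.params)
    manifest = {
        "config": state.config.to_dict(),
        "init_seed": state.init_seed,
        "shapes": {k: list(v.shape) for k, v in state.params.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> ModelState:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k] for k in data.files}
    cfg = ModelConfig.from_dict(manifest["config"])
    for k, shape in manifest["shapes"].items():
        if list(params[k].shape) != shape:
            raise ValueError(f"archive/manifest shape mismatch for {k}")
    return ModelState(config=cfg, params=params, init_seed=manifest["init_seed"])
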