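"""Branched neural network over the three protein encodings.

Topology: a stack of 1-D convolutions (over the residue axis) for each of
the two length-dependent ``L x 20`` encodings (one-hot and PSSM), global
pooling to erase the length dependence, a fully-connected branch for the
fixed-length domain-presence vector, concatenation of the three branch
outputs, and a fully-connected classifier head ending in Q per-class
logistic outputs in (0, 1). Per-class logistic (not softmax) squashing is
used because the labels are not mutually exclusive.

Training is end-to-end by backpropagation with an Adam-style adaptive
optimizer, with either the pairwise rank-exponential loss (``bpmll``, the
multi-label level) or class-weighted binary cross-entropy
(``weighted-binary``, the imbalanced mono/multi level).

The implementation is pure NumPy: models at this scale are small enough
that vectorized batch linear algebra on one CPU covers the training budgets
used here, and it keeps runs bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from mlenz.rank_loss import DegenerateLabelSetError, LabelSet, bpmll_gradient, bpmll_loss
from mlenz.seq_encoding import EncodedProtein

_SCORE_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the branched network and its training run.

    ``conv_filters`` lists (window length, channel count) pairs applied in
    order to both L x 20 branches. ``fc_widths`` holds the domain-branch
    hidden width first, then the classifier-head hidden widths.
    ``class_weights`` (length Q) weights the positive term of the binary
    cross-entropy per class; when omitted under ``weighted-binary`` loss,
    balanced weights are derived from the training label frequencies.
    """

    q_classes: int = 6
    conv_filters: tuple[tuple[int, int], ...] = ((4, 32), (8, 32))
    pool: str = "global-max"
    fc_widths: tuple[int, ...] = (64, 128)
    dropout: float = 0.3
    max_len: int | None = None
    seed: int = 0
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    class_weights: tuple[float, ...] | None = None

    def validate(self) -> None:
        problems = []
        if self.q_classes < 1:
            problems.append(f"q_classes must be >= 1 (got {self.q_classes})")
        for w, c in self.conv_filters:
            if w < 1 or c < 1:
                problems.append(f"conv filter ({w}, {c}) must have positive window and channels")
        if self.pool not in ("global-max", "global-average"):
            problems.append(f"pool must be 'global-max' or 'global-average' (got {self.pool!r})")
        if len(self.fc_widths) < 2 or any(w < 1 for w in self.fc_widths):
            problems.append("fc_widths needs a domain-branch width and >= 1 head width, all >= 1")
        if not (0 <= self.dropout < 1):
            problems.append(f"dropout must be in [0, 1) (got {self.dropout})")
        if self.epochs < 1 or self.batch_size < 1:
            problems.append("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            problems.append(f"learning_rate must be > 0 (got {self.learning_rate})")
        if self.class_weights is not None and (
            len(self.class_weights) != self.q_classes
            or any(w <= 0 for w in self.class_weights)
        ):
            problems.append("class_weights must be q_classes positive reals")
        if problems:
            raise ValueError("invalid model config: " + "; ".join(problems))

    @property
    def receptive_field(self) -> int:
        return sum(w - 1 for w, _ in self.conv_filters) + 1


@dataclass
class TrainedModel:
    """Network weights plus everything needed to rebuild its input space."""

    parameters: dict[str, np.ndarray]
    config: ModelConfig
    domain_vocabulary: tuple[str, ...]
    history: list[float] = field(default_factory=list)

    def forward(self, x: EncodedProtein) -> np.ndarray:
        return forward(self, x)


# ---------------------------------------------------------------------------
# initialization


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def build_model(config: ModelConfig, domain_dim: int,
                domain_vocabulary: Sequence[str] | None = None) -> TrainedModel:
    """Initialize an untrained model deterministically from ``config.seed``."""
    config.validate()
    if domain_dim < 1:
        raise ValueError(f"domain_dim must be >= 1 (got {domain_dim})")
    if domain_vocabulary is None:
        domain_vocabulary = tuple(f"D{i:04d}" for i in range(domain_dim))
    if len(domain_vocabulary) != domain_dim:
        raise ValueError("domain_vocabulary length must equal domain_dim")
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    for branch in ("onehot", "pssm"):
        c_in = 20
        for i, (w, c_out) in enumerate(config.conv_filters):
            params[f"{branch}_conv{i}_W"] = _he_init(rng, (w, c_in, c_out), w * c_in)
            params[f"{branch}_conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
    dom_w = config.fc_widths[0]
    params["dom_W"] = _he_init(rng, (domain_dim, dom_w), domain_dim)
    params["dom_b"] = np.zeros(dom_w)
    concat_dim = 2 * config.conv_filters[-1][1] + dom_w
    prev = concat_dim
    for i, width in enumerate(config.fc_widths[1:]):
        params[f"head{i}_W"] = _he_init(rng, (prev, width), prev)
        params[f"head{i}_b"] = np.zeros(width)
        prev = width
    params["out_W"] = _he_init(rng, (prev, config.q_classes), prev)
    params["out_b"] = np.zeros(config.q_classes)
    return TrainedModel(
        parameters=params,
        config=config,
        domain_vocabulary=tuple(domain_vocabulary),
    )


# ---------------------------------------------------------------------------
# forward / backward


def _pack_batch(
    xs: Sequence[EncodedProtein], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad a batch to a common length.

    Sequences shorter than the conv stack's receptive field are zero-padded
    up to it (deterministically, independent of batch composition), and
    ``max_len`` truncates long ones. Returns (one-hot, pssm, domain, lengths).
    """
    r = config.receptive_field
    lengths = []
    for x in xs:
        length = x.length
        if config.max_len is not None:
            length = min(length, config.max_len)
        lengths.append(max(length, r))
    lengths = np.array(lengths, dtype=int)
    l_max = int(lengths.max())
    b = len(xs)
    onehot = np.zeros((b, l_max, 20))
    pssm = np.zeros((b, l_max, 20))
    for i, x in enumerate(xs):
        take = min(x.length, lengths[i])
        onehot[i, :take] = x.one_hot.values[:take]
        pssm[i, :take] = x.pssm.values[:take]
    dom = np.stack([x.domains.values for x in xs])
    return onehot, pssm, dom, lengths


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution: (B, L, Cin) x (w, Cin, Cout) -> (B, L-w+1, Cout)."""
    win = w.shape[0]
    n_batch, length, c_in = x.shape
    l_out = length - win + 1
    y = np.zeros((n_batch, l_out, w.shape[2])) + b
    flat = x.reshape(-1, c_in)
    for k in range(win):
        # full-length contiguous GEMM, then shift-and-sum the valid slice
        y += (flat @ w[k]).reshape(n_batch, length, -1)[:, k : k + l_out, :]
    return y


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    win = w.shape[0]
    l_out = dy.shape[1]
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for k in range(win):
        dx[:, k : k + l_out, :] += dy @ w[k].T
        dw[k] = np.tensordot(x[:, k : k + l_out, :], dy, axes=([0, 1], [0, 1]))
    db = dy.sum(axis=(0, 1))
    return dx, dw, db


def _branch_forward(
    x: np.ndarray, lengths: np.ndarray, params: dict, branch: str, config: ModelConfig
) -> tuple[np.ndarray, list]:
    """Conv stack + ReLU per layer + masked global pooling. Returns the
    pooled (B, C) vector and the caches needed for backprop."""
    caches = []
    cur = x
    cur_len = lengths.copy()
    for i, (win, _) in enumerate(config.conv_filters):
        w = params[f"{branch}_conv{i}_W"]
        z = _conv_forward(cur, w, params[f"{branch}_conv{i}_b"])
        a = np.maximum(z, 0.0)
        caches.append((cur, w, z))
        cur = a
        cur_len = cur_len - win + 1
    b, l_out, c = cur.shape
    pos = np.arange(l_out)[None, :, None]
    valid = pos < cur_len[:, None, None]
    if config.pool == "global-max":
        masked = np.where(valid, cur, -np.inf)
        arg = masked.argmax(axis=1)  # (B, C)
        pooled = np.take_along_axis(cur, arg[:, None, :], axis=1)[:, 0, :]
        caches.append(("max", arg, cur.shape))
    else:
        pooled = (cur * valid).sum(axis=1) / cur_len[:, None]
        caches.append(("avg", valid, cur_len))
    return pooled, caches


def _branch_backward(
    dpooled: np.ndarray, caches: list, params: dict, branch: str,
    grads: dict, config: ModelConfig,
) -> None:
    pool_cache = caches[-1]
    if pool_cache[0] == "max":
        _, arg, shape = pool_cache
        da = np.zeros(shape)
        np.put_along_axis(da, arg[:, None, :], dpooled[:, None, :], axis=1)
    else:
        _, valid, cur_len = pool_cache
        da = (dpooled[:, None, :] / cur_len[:, None, None]) * valid
    for i in reversed(range(len(config.conv_filters))):
        x_in, w, z = caches[i]
        dz = da * (z > 0)
        dx, dw, db = _conv_backward(x_in, w, dz)
        grads[f"{branch}_conv{i}_W"] = grads.get(f"{branch}_conv{i}_W", 0) + dw
        grads[f"{branch}_conv{i}_b"] = grads.get(f"{branch}_conv{i}_b", 0) + db
        da = dx


def _forward_batch(
    model: TrainedModel,
    xs: Sequence[EncodedProtein],
    train_mode: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Score a batch; returns (B, Q) scores in (0,1) and the backprop cache."""
    config = model.config
    params = model.parameters
    onehot, pssm, dom, lengths = _pack_batch(xs, config)
    for x in xs:
        if x.domains.values.size != params["dom_W"].shape[0]:
            raise ValueError(
                f"domain vector length {x.domains.values.size} does not match "
                f"model domain dimension {params['dom_W'].shape[0]}"
            )
    pooled_oh, cache_oh = _branch_forward(onehot, lengths, params, "onehot", config)
    pooled_ps, cache_ps = _branch_forward(pssm, lengths, params, "pssm", config)
    dom_z = dom @ params["dom_W"] + params["dom_b"]
    dom_a = np.maximum(dom_z, 0.0)
    concat = np.concatenate([pooled_oh, pooled_ps, dom_a], axis=1)
    cur = concat
    head_caches = []
    n_head = len(config.fc_widths) - 1
    for i in range(n_head):
        z = cur @ params[f"head{i}_W"] + params[f"head{i}_b"]
        a = np.maximum(z, 0.0)
        if train_mode and config.dropout > 0:
            keep = (dropout_rng.random(a.shape) >= config.dropout) / (1 - config.dropout)
            a = a * keep
        else:
            keep = None
        head_caches.append((cur, z, keep))
        cur = a
    logits = cur @ params["out_W"] + params["out_b"]
    scores = 1.0 / (1.0 + np.exp(-logits))
    scores = np.clip(scores, _SCORE_EPS, 1.0 - _SCORE_EPS)
    cache = {
        "onehot": (onehot, cache_oh),
        "pssm": (pssm, cache_ps),
        "dom": (dom, dom_z),
        "concat": concat,
        "heads": head_caches,
        "last_hidden": cur,
        "scores": scores,
    }
    return scores, cache


def _backward_batch(model: TrainedModel, cache: dict, dscores: np.ndarray) -> dict:
    """Gradients of a scalar loss wrt every parameter, given dLoss/dscores."""
    config = model.config
    params = model.parameters
    grads: dict[str, np.ndarray] = {}
    scores = cache["scores"]
    dlogits = dscores * scores * (1.0 - scores)
    grads["out_W"] = cache["last_hidden"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    da = dlogits @ params["out_W"].T
    for i in reversed(range(len(cache["heads"]))):
        x_in, z, keep = cache["heads"][i]
        if keep is not None:
            da = da * keep
        dz = da * (z > 0)
        grads[f"head{i}_W"] = x_in.T @ dz
        grads[f"head{i}_b"] = dz.sum(axis=0)
        da = dz @ params[f"head{i}_W"].T
    c = config.conv_filters[-1][1]
    d_oh, d_ps, d_dom_a = da[:, :c], da[:, c : 2 * c], da[:, 2 * c :]
    dom, dom_z = cache["dom"]
    d_dom_z = d_dom_a * (dom_z > 0)
    grads["dom_W"] = dom.T @ d_dom_z
    grads["dom_b"] = d_dom_z.sum(axis=0)
    _branch_backward(d_oh, cache["onehot"][1], params, "onehot", grads, config)
    _branch_backward(d_ps, cache["pssm"][1], params, "pssm", grads, config)
    return grads


def forward(model: TrainedModel, x: EncodedProtein) -> np.ndarray:
    """Score one encoded protein: length-Q vector in (0, 1)^Q.

    Pure and batch-invariant: the same instance scores identically whether
    evaluated alone or inside any batch (padding is masked out).
    """
    scores, _ = _forward_batch(model, [x], train_mode=False)
    return scores[0]


def forward_many(model: TrainedModel, xs: Sequence[EncodedProtein]) -> np.ndarray:
    """Score a list of encoded proteins as an (n, Q) matrix."""
    if not xs:
        return np.zeros((0, model.config.q_classes))
    scores, _ = _forward_batch(model, list(xs), train_mode=False)
    return scores


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _weighted_bce(
    scores: np.ndarray, d: np.ndarray, pos_w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy, summed over classes, mean over
    the batch handled by the caller. Returns (sum over batch, dLoss/dscores)."""
    loss = -(pos_w * d * np.log(scores) + (1 - d) * np.log(1 - scores)).sum()
    dscores = -(pos_w * d / scores) + (1 - d) / (1 - scores)
    return float(loss), dscores


def balanced_class_weights(labels: Sequence[LabelSet], q: int) -> tuple[float, ...]:
    """Positive-class weights inversely proportional to positive frequency:
    w_j = (# negatives of class j) / (# positives of class j)."""
    pos = np.zeros(q)
    for lab in labels:
        pos += lab.indicator()
    n = len(labels)
    neg = n - pos
    with np.errstate(divide="ignore"):
        w = np.where(pos > 0, neg / np.maximum(pos, 1), 1.0)
    return tuple(float(x) for x in w)


def train(
    model: TrainedModel,
    data: Sequence[tuple[EncodedProtein, LabelSet]],
    loss: str = "bpmll",
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train in place by mini-batch backpropagation; returns the model.

    ``loss='bpmll'`` uses the pairwise rank-exponential loss (every label
    set must leave both itself and its complement non-empty);
    ``loss='weighted-binary'`` uses class-weighted binary cross-entropy with
    balanced weights derived from the data unless ``config.class_weights``
    is set. The recorded history is the mean per-instance loss per epoch;
    optimizing the mean rather than the sum rescales the objective by a
    positive constant and leaves the optimum unchanged.

    Fully deterministic given (seed, data, config) on one thread.
    """
    if config is None:
        config = model.config
    config.validate()
    if len(data) == 0:
        raise ValueError("training data is empty")
    q = config.q_classes
    if loss not in ("bpmll", "weighted-binary"):
        raise ValueError(f"unknown loss spec {loss!r}")
    for i, (_, lab) in enumerate(data):
        if lab.q != q:
            raise ValueError(f"instance {i}: label set over Q={lab.q}, model has Q={q}")
        if loss == "bpmll" and (len(lab) == 0 or len(lab) == q):
            raise DegenerateLabelSetError(
                f"instance {i}: rank loss undefined for empty or full label set"
            )
    if loss == "weighted-binary":
        if config.class_weights is not None:
            pos_w = np.asarray(config.class_weights, dtype=float)
        else:
            pos_w = np.asarray(balanced_class_weights([lab for _, lab in data], q))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB9]))
    optimizer = _Adam(model.parameters, config.learning_rate)
    n = len(data)
    indicators = np.stack([lab.indicator() for _, lab in data])
    model.history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs = [data[i][0] for i in idx]
            scores, cache = _forward_batch(model, xs, train_mode=True, dropout_rng=rng)
            if loss == "bpmll":
                batch_total = 0.0
                dscores = np.zeros_like(scores)
                for row, i in enumerate(idx):
                    lab = data[i][1]
                    batch_total += bpmll_loss(scores[row], lab)
                    dscores[row] = bpmll_gradient(scores[row], lab)
            else:
                batch_total, dscores = _weighted_bce(scores, indicators[idx], pos_w)
            grads = _backward_batch(model, cache, dscores / len(idx))
            optimizer.step(model.parameters, grads)
            epoch_loss += batch_total
        model.history.append(epoch_loss / n)
    return model


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path,
               threshold: "object | None" = None) -> None:
    """Serialize weights, config, vocabulary, history (and optionally the
    fitted threshold function) into one ``.npz`` checkpoint.

    float64 arrays round-trip bit-exactly.
    """
    meta = {
        "config": {
            **{k: getattr(model.config, k) for k in (
                "q_classes", "pool", "dropout", "max_len", "seed", "epochs",
                "batch_size", "learning_rate",
            )},
            "conv_filters": [list(f) for f in model.config.conv_filters],
            "fc_widths": list(model.config.fc_widths),
            "class_weights": (
                list(model.config.class_weights)
                if model.config.class_weights is not None else None
            ),
        },
        "domain_vocabulary": list(model.domain_vocabulary),
        "history": list(model.history),
        "alphabet": "ACDEFGHIKLMNPQRSTVWY",
    }
    arrays = {f"param__{k}": v for k, v in model.parameters.items()}
    if threshold is not None:
        arrays["threshold_w"] = np.asarray(threshold.w, dtype=float)
        arrays["threshold_b"] = np.array([threshold.b, threshold.residual_rms])
    np.savez(str(path), meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> tuple[TrainedModel, "object | None"]:
    """Load a checkpoint written by :func:`save_model`.

    Returns ``(model, threshold_model_or_None)``.
    """
    from mlenz.threshold_calibration import ThresholdModel

    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = {
            k[len("param__"):]: data[k] for k in data.files if k.startswith("param__")
        }
        threshold = None
        if "threshold_w" in data.files:
            tb = data["threshold_b"]
            threshold = ThresholdModel(
                w=data["threshold_w"], b=float(tb[0]), residual_rms=float(tb[1])
            )
    cfg_d = meta["config"]
    config = ModelConfig(
        q_classes=cfg_d["q_classes"],
        conv_filters=tuple((int(w), int(c)) for w, c in cfg_d["conv_filters"]),
        pool=cfg_d["pool"],
        fc_widths=tuple(int(w) for w in cfg_d["fc_widths"]),
        dropout=cfg_d["dropout"],
        max_len=cfg_d["max_len"],
        seed=cfg_d["seed"],
        epochs=cfg_d["epochs"],
        batch_size=cfg_d["batch_size"],
        learning_rate=cfg_d["learning_rate"],
        class_weights=(
            tuple(cfg_d["class_weights"]) if cfg_d["class_weights"] is not None else None
        ),
    )
    model = TrainedModel(
        parameters=params,
        config=config,
        domain_vocabulary=tuple(meta["domain_vocabulary"]),
        history=list(meta["history"]),
    )
    return model, threshold


def with_config(model: TrainedModel, **overrides) -> ModelConfig:
    """Convenience: derive a modified copy of the model's config."""
    return replace(model.config, **overrides)
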