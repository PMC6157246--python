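"""The deep architecture and its training loop.

The network maps one siRNA record to a predicted efficacy in (0, 1):

1. the flanked target window is one-hot encoded into an L×4 matrix,
   L = 21 + 2n;
2. a bank of m×4 convolution kernels (motif detectors, 2 ≤ m ≤ 20) slides
   over the matrix, each kernel carrying a learnable scale δ; a kernel of
   height m yields a feature map of length L − m + 1;
3. an elementwise activation (ReLU by default) is applied, then global max
   and average pooling compress each map to a (y_max, y_avg) pair — with d
   kernels the pooled block is 2d-dimensional;
4. the pooled block is concatenated with the 20 thermodynamic descriptors,
   batch-normalized, passed through one hidden layer (25 sigmoid units by
   default) and through a final sigmoid over a weighted sum.

Training is plain full-batch gradient descent on mean-squared error with a
fixed learning rate, stopping when the iteration count exceeds
``max_iterations`` or the training error drops below ``error_tolerance``.
All arithmetic is numpy; gradients are analytic and are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from sirnadeep.encoding import EncodedSequence, encode_window
from sirnadeep.records_io import GUIDE_LEN, SiRNARecord, extract_window
from sirnadeep.thermo import N_FEATURES as N_THERMO
from sirnadeep.thermo import NNParameterTable, featurize_thermo

_BN_EPS = 1e-5

KERNEL_HEIGHT_MIN = 2
KERNEL_HEIGHT_MAX = 20


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    kernel_heights: Sequence[int] = tuple(range(6, 21))
    kernels_per_height: int = 1
    flank_n: int = 20
    dnn_units: int = 25
    conv_activation: str = "relu"
    dnn_activation: str = "sigmoid"
    learning_rate: float = 0.1
    max_iterations: int = 1000
    error_tolerance: float = 0.001
    seed: int = 0
    batch_size: Optional[int] = None  # None = full batch
    end_window: int = 1  # width of the thermo end-differential window

    def __post_init__(self) -> None:
        self.kernel_heights = tuple(int(m) for m in self.kernel_heights)
        for m in self.kernel_heights:
            if not (KERNEL_HEIGHT_MIN <= m <= KERNEL_HEIGHT_MAX):
                raise ValueError(
                    f"kernel height {m} outside [{KERNEL_HEIGHT_MIN}, {KERNEL_HEIGHT_MAX}]"
                )
        if not self.kernel_heights:
            raise ValueError("at least one kernel height required")
        if self.kernels_per_height < 1:
            raise ValueError("kernels_per_height must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.conv_activation not in ("relu", "sigmoid"):
            raise ValueError(f"unknown conv_activation {self.conv_activation!r}")
        if self.dnn_activation not in ("relu", "sigmoid"):
            raise ValueError(f"unknown dnn_activation {self.dnn_activation!r}")

    @property
    def n_kernels(self) -> int:
        return len(self.kernel_heights) * self.kernels_per_height

    @property
    def pooled_dim(self) -> int:
        """2d: one (max, avg) pair per kernel."""
        return 2 * self.n_kernels

    @property
    def merged_dim(self) -> int:
        return self.pooled_dim + N_THERMO

    @property
    def input_length(self) -> int:
        return GUIDE_LEN + 2 * self.flank_n


def reference_config(**overrides) -> ModelConfig:
    """The selected architecture: one kernel per height 6–20 (15 kernels),
    ReLU convolutions, sigmoid hidden layer, learning rate 0.1, n = 20,
    25 hidden units."""
    return ModelConfig(**overrides)


# ---------------------------------------------------------------------------
# elementary operations (also exposed for direct use and oracle testing)


def convolve(encoded: EncodedSequence, kernel: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Sliding dot product of an m×4 kernel over the L×4 encoded matrix.

    Output length is L − m + 1; with n = 0 (L = 21) this is the classic
    22 − m feature-map length.
    """
    kernel = np.asarray(kernel, dtype=float)
    m = kernel.shape[0]
    L = encoded.length
    if kernel.shape != (m, 4) or m < 1:
        raise ValueError(f"kernel must be m×4, got shape {kernel.shape}")
    if m > L:
        raise ValueError(f"kernel height {m} exceeds input length {L}")
    S = encoded.matrix
    out = np.empty(L - m + 1)
    for p in range(L - m + 1):
        out[p] = scale * float(np.sum(S[p : p + m] * kernel))
    return out


def activate(x: np.ndarray, fn: str) -> np.ndarray:
    """Elementwise ReLU max(0, x) or logistic sigmoid 1/(1+e^-x)."""
    x = np.asarray(x, dtype=float)
    if fn == "relu":
        return np.maximum(0.0, x)
    if fn == "sigmoid":
        return _sigmoid(x)
    raise ValueError(f"unknown activation {fn!r}")


def pool(feature_map: np.ndarray) -> tuple[float, float]:
    """Global (y_max, y_avg) over one feature map; the pool spans the map."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.size == 0:
        raise ValueError("cannot pool an empty feature map")
    return float(fm.max()), float(fm.mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# input preparation


def _prepare_inputs(records, config: ModelConfig, params: NNParameterTable):
    """Encode all records: per-height im2col blocks + thermo matrix + labels."""
    N = len(records)
    L = config.input_length
    S = np.empty((N, L, 4))
    thermo = np.empty((N, N_THERMO))
    for r, rec in enumerate(records):
        S[r] = encode_window(extract_window(rec, config.flank_n), config.flank_n).matrix
        thermo[r] = featurize_thermo(rec, params, end_window=config.end_window).flatten()
    heights = sorted(set(config.kernel_heights))
    windows = {}
    for m in heights:
        if m > L:
            raise ValueError(f"kernel height {m} exceeds input length {L}")
        P = L - m + 1
        # im2col: row (r, p) holds the flattened m×4 patch S[r, p:p+m]
        w = np.lib.stride_tricks.sliding_window_view(S, (m, 4), axis=(1, 2))
        windows[m] = np.ascontiguousarray(w.reshape(N, P, 4 * m))
    return windows, thermo


def _labels(records) -> np.ndarray:
    y = [r.efficacy for r in records]
    if any(v is None for v in y):
        raise ValueError("all training records must carry an efficacy")
    return np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# the network


class _Network:
    """Parameter container with vectorized forward/backward passes.

    Kernels are grouped by height so that all kernels of one height share
    a single im2col matrix multiply.  Parameter keys: ``M{m}`` (4m × K_m
    kernel stack), ``delta{m}`` (per-kernel scales), ``gamma``/``beta``
    (batch-norm), ``W1``/``b1`` (hidden layer), ``w2`` (output weights).
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.heights = sorted(set(config.kernel_heights))
        counts = {}
        for m in config.kernel_heights:
            counts[m] = counts.get(m, 0) + config.kernels_per_height
        self.kernel_counts = {m: counts[m] for m in self.heights}
        D = 2 * sum(self.kernel_counts.values()) + N_THERMO
        H = config.dnn_units
        self.params = {}
        for m in self.heights:
            r = 1.0 / np.sqrt(4 * m)
            self.params[f"M{m}"] = rng.uniform(-r, r, size=(4 * m, self.kernel_counts[m]))
            self.params[f"delta{m}"] = np.ones(self.kernel_counts[m])
        self.params["gamma"] = np.ones(D)
        self.params["beta"] = np.zeros(D)
        r = 1.0 / np.sqrt(D)
        self.params["W1"] = rng.uniform(-r, r, size=(D, H))
        self.params["b1"] = rng.uniform(-r, r, size=H)
        r = 1.0 / np.sqrt(H)
        self.params["w2"] = rng.uniform(-r, r, size=H)
        self.merged_dim = D
        # inference-time batch-norm statistics, frozen after training
        self.bn_mean = np.zeros(D)
        self.bn_var = np.ones(D)

    # -- forward ----------------------------------------------------------

    def _merged(self, windows, thermo):
        """Conv → activation → pooling → concat with thermo.  Returns the
        merged matrix plus the per-height caches needed for backprop."""
        N = thermo.shape[0]
        caches = {}
        pooled_blocks = []
        for m in self.heights:
            X = windows[m]  # (N, P, 4m)
            P = X.shape[1]
            K = self.kernel_counts[m]
            raw = (X.reshape(N * P, 4 * m) @ self.params[f"M{m}"]).reshape(N, P, K)
            x = raw * self.params[f"delta{m}"]
            a = activate(x, self.config.conv_activation)
            amax = np.argmax(a, axis=1)  # (N, K)
            u = np.take_along_axis(a, amax[:, None, :], axis=1)[:, 0, :]
            v = a.mean(axis=1)
            caches[m] = (X, raw, x, a, amax, P, K)
            pooled_blocks.append(np.concatenate([u, v], axis=1))
        merged = np.concatenate(pooled_blocks + [thermo], axis=1)
        return merged, caches

    def _head(self, merged, mu, var):
        xhat = (merged - mu) / np.sqrt(var + _BN_EPS)
        zbn = self.params["gamma"] * xhat + self.params["beta"]
        h_pre = zbn @ self.params["W1"] + self.params["b1"]
        h = activate(h_pre, self.config.dnn_activation)
        o = h @ self.params["w2"]
        yhat = _sigmoid(o)
        return yhat, (xhat, zbn, h_pre, h)

    def predict(self, windows, thermo) -> np.ndarray:
        """Inference with frozen batch-norm statistics."""
        merged, _ = self._merged(windows, thermo)
        yhat, _ = self._head(merged, self.bn_mean, self.bn_var)
        return yhat

    # -- backward ---------------------------------------------------------

    def loss_and_grads(self, windows, thermo, y):
        """Mean-squared-error loss and analytic gradients for one batch.

        Batch normalization uses the batch's own statistics here, as during
        training; gradients flow through the statistics.
        """
        N = y.shape[0]
        merged, caches = self._merged(windows, thermo)
        mu = merged.mean(axis=0)
        var = merged.var(axis=0)
        yhat, (xhat, zbn, h_pre, h) = self._head(merged, mu, var)

        loss = float(np.mean((yhat - y) ** 2))
        grads = {}

        do = (2.0 / N) * (yhat - y) * yhat * (1.0 - yhat)
        grads["w2"] = h.T @ do
        dh = do[:, None] * self.params["w2"][None, :]
        if self.config.dnn_activation == "sigmoid":
            dh_pre = dh * h * (1.0 - h)
        else:
            dh_pre = dh * (h_pre > 0)
        grads["W1"] = zbn.T @ dh_pre
        grads["b1"] = dh_pre.sum(axis=0)
        dzbn = dh_pre @ self.params["W1"].T

        grads["gamma"] = (dzbn * xhat).sum(axis=0)
        grads["beta"] = dzbn.sum(axis=0)
        dxhat = dzbn * self.params["gamma"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        dmerged = (inv_std / N) * (
            N * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

        col = 0
        for m in self.heights:
            X, raw, x, a, amax, P, K = caches[m]
            du = dmerged[:, col : col + K]
            dv = dmerged[:, col + K : col + 2 * K]
            col += 2 * K
            da = np.repeat(dv[:, None, :] / P, P, axis=1)
            np.put_along_axis(
                da, amax[:, None, :], np.take_along_axis(da, amax[:, None, :], axis=1) + du[:, None, :], axis=1
            )
            if self.config.conv_activation == "relu":
                dx = da * (x > 0)
            else:
                dx = da * a * (1.0 - a)
            grads[f"delta{m}"] = (dx * raw).sum(axis=(0, 1))
            draw = dx * self.params[f"delta{m}"]
            grads[f"M{m}"] = X.reshape(N * P, 4 * m).T @ draw.reshape(N * P, K)
        return loss, grads

    def step(self, grads, lr: float) -> None:
        for k, g in grads.items():
            self.params[k] -= lr * g

    def freeze_bn(self, windows, thermo) -> None:
        merged, _ = self._merged(windows, thermo)
        self.bn_mean = merged.mean(axis=0)
        self.bn_var = merged.var(axis=0)


# ---------------------------------------------------------------------------
# trained model and public API


@dataclass
class TrainedModel:
    config: ModelConfig
    network: _Network
    training_log: list = field(default_factory=list)

    @property
    def pooled_dim(self) -> int:
        return self.config.pooled_dim

    @property
    def merged_dim(self) -> int:
        return self.config.merged_dim

    def save(self, path) -> None:
        """Serialize config (JSON) plus weight arrays to one .npz archive."""
        cfg = asdict(self.config)
        cfg["kernel_heights"] = list(cfg["kernel_heights"])
        arrays = {f"param_{k}": v for k, v in self.network.params.items()}
        arrays["bn_mean"] = self.network.bn_mean
        arrays["bn_var"] = self.network.bn_var
        arrays["training_log"] = np.asarray(self.training_log)
        np.savez(
            path,
            schema_version=np.asarray(1),
            config_json=np.asarray(json.dumps(cfg)),
            base_order=np.asarray("AUGC"),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["config_json"]))
            config = ModelConfig(**cfg)
            net = _Network(config, np.random.default_rng(config.seed))
            for k in net.params:
                net.params[k] = z[f"param_{k}"]
            net.bn_mean = z["bn_mean"]
            net.bn_var = z["bn_var"]
            log = list(z["training_log"])
        return cls(config=config, network=net, training_log=log)


def train(records, config: ModelConfig, params: NNParameterTable) -> TrainedModel:
    """Fit the architecture to labeled records by gradient descent on MSE.

    Deterministic given ``config.seed``.  Stops when the iteration count
    exceeds ``config.max_iterations`` or the mean-squared training error
    falls below ``config.error_tolerance``.  Raises on unlabeled records
    or a non-finite loss (naming the iteration).
    """
    y = _labels(records)
    if len(records) < 2:
        raise ValueError("need at least 2 labeled records to train")
    windows, thermo = _prepare_inputs(records, config, params)
    rng = np.random.default_rng(config.seed)
    net = _Network(config, rng)
    N = len(records)
    bs = config.batch_size or N
    log = []
    for it in range(1, config.max_iterations + 1):
        if bs >= N:
            loss, grads = net.loss_and_grads(windows, thermo, y)
            net.step(grads, config.learning_rate)
        else:
            order = rng.permutation(N)
            losses = []
            for start in range(0, N, bs):
                idx = order[start : start + bs]
                wb = {m: w[idx] for m, w in windows.items()}
                loss_b, grads = net.loss_and_grads(wb, thermo[idx], y[idx])
                net.step(grads, config.learning_rate)
                losses.append(loss_b)
            loss = float(np.mean(losses))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        log.append(loss)
        if loss < config.error_tolerance:
            break
    net.freeze_bn(windows, thermo)
    return TrainedModel(config=config, network=net, training_log=log)


def predict(records, model: TrainedModel, params: NNParameterTable) -> np.ndarray:
    """Predicted efficacies, strictly in (0, 1), one per record."""
    windows, thermo = _prepare_inputs(records, model.config, params)
    return model.network.predict(windows, thermo)


def forward(record: SiRNARecord, model: TrainedModel, params: NNParameterTable) -> float:
    """Predicted efficacy for a single record (inference mode)."""
    return float(predict([record], model, params)[0])


def select_kernel_set(
    records,
    candidate_heights: Sequence[int],
    params: NNParameterTable,
    threshold: float = 0.6,
    base_config: Optional[ModelConfig] = None,
    k: int = 10,
    seed: int = 0,
):
    """Pick kernel heights whose single-height networks exceed a CV PCC bar.

    For each candidate height m one network with 22 − m kernels of height m
    is cross-validated; heights whose mean CV PCC is higher than
    ``threshold`` are returned (sorted).
    """
    from sirnadeep.evaluation import cross_validate

    candidate_heights = list(candidate_heights)
    if not candidate_heights:
        raise ValueError("candidate_heights must not be empty")
    base = base_config or reference_config()
    selected = []
    for m in sorted(candidate_heights):
        cfg_kwargs = asdict(base)
        cfg_kwargs.update(kernel_heights=[m], kernels_per_height=22 - m)
        cfg = ModelConfig(**cfg_kwargs)
        report = cross_validate(records, cfg, params, k=k, seed=seed)
        if report.mean_pcc > threshold:
            selected.append(m)
    return selected
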