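"""Feed-forward base learners on thresholded SNP sets.

Each base model is a small fully connected network over the dosage columns
passing one GWAS p-value threshold.  Hidden layers apply an affine map, then
optional batch normalisation, a Leaky ReLU activation, and optional dropout
(rate 0.5); the output head is a single unit with a logistic link for binary
traits (binary cross-entropy loss) or an identity link for quantitative
traits (mean-squared-error loss).  Hidden widths follow an integer-division
chain: layer k's width is the previous width divided by that layer's divisor
(1–4); a chain that reaches width < 1 makes the architecture invalid.

Training uses Adam (initial learning rate 1e-3) with early stopping on the
validation loss (patience in epochs, minimum improvement delta, best-epoch
weights restored).  Everything — initialisation, dropout masks, minibatch
shuffles — is driven by one seed, so a fixed spec retrains to bit-identical
weights.

The forward/backward passes, batch-norm, dropout and Adam are implemented
directly in numpy; the networks here are tiny (tens to hundreds of inputs)
and full-batch or 256-sample minibatch updates on such sizes are fast in
pure array code.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BaseModelSpec",
    "BaseModel",
    "leaky_relu",
    "logistic",
    "bce_loss",
    "mse_loss",
    "hidden_widths",
    "build_network",
    "train_base",
    "grid_search",
    "predict",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def leaky_relu(x: np.ndarray | float, alpha: float = 0.01) -> np.ndarray | float:
    """x for x >= 0, alpha*x otherwise, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, x, alpha * x)
    return out if out.ndim else float(out)


def logistic(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable sigmoid 1/(1+exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0.0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy, -(1/N) sum[y log p + (1-y) log(1-p)]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def mse_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.mean((y - yhat) ** 2))


# ---------------------------------------------------------------------------
# specs and models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseModelSpec:
    """Architecture and training hyperparameters of one base network.

    ``depth`` counts hidden layers (0 = purely affine model, the degenerate
    logistic/linear-regression case); ``width_divisors`` gives, per hidden
    layer, the integer divisor applied to the previous layer's output count.
    """

    depth: int = 1
    width_divisors: tuple[int, ...] = (2,)
    use_dropout: bool = True
    dropout_rate: float = 0.5
    use_batchnorm: bool = True
    learning_rate: float = 1e-3
    max_epochs: int = 500
    early_stop_patience: int = 10
    min_delta: float = 1e-5
    batch_size: int = 256
    full_batch_below: int = 512
    seed: int = 0
    leaky_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.depth <= 4):
            raise ValueError(f"depth must be in 0..4, got {self.depth}")
        if len(self.width_divisors) != self.depth:
            raise ValueError("one width divisor per hidden layer required")
        if any(d < 1 or d > 4 for d in self.width_divisors):
            raise ValueError("width divisors must be in 1..4")


def hidden_widths(spec: BaseModelSpec, n_inputs: int) -> list[int]:
    """Integer-division width chain; raises if any width falls below 1."""
    widths = []
    w = n_inputs
    for div in spec.width_divisors:
        w = w // div
        if w < 1:
            raise ValueError(
                f"width chain {spec.width_divisors} from {n_inputs} inputs reaches width {w}"
            )
        widths.append(w)
    return widths


class Network:
    """Weights and batch-norm state of one feed-forward network."""

    def __init__(self, spec: BaseModelSpec, n_inputs: int, trait_type: str):
        if trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        self.spec = spec
        self.n_inputs = n_inputs
        self.trait_type = trait_type
        widths = hidden_widths(spec, n_inputs)
        rng = np.random.default_rng(spec.seed)
        self.layers: list[dict] = []
        fan_in = n_inputs
        for w in widths:
            layer = {
                # He-style init suits the (leaky) ReLU nonlinearity
                "W": rng.standard_normal((fan_in, w)) * np.sqrt(2.0 / fan_in),
                "b": np.zeros(w),
            }
            if spec.use_batchnorm:
                layer.update(
                    gamma=np.ones(w), beta=np.zeros(w),
                    run_mean=np.zeros(w), run_var=np.ones(w),
                )
            self.layers.append(layer)
            fan_in = w
        self.out_W = rng.standard_normal((fan_in, 1)) * np.sqrt(1.0 / fan_in)
        self.out_b = np.zeros(1)
        self._init_rng = rng  # carried on for dropout/shuffling during training

    # -- parameter bookkeeping -------------------------------------------

    def parameters(self) -> list[tuple[dict | "Network", str]]:
        params: list[tuple[dict | Network, str]] = []
        for layer in self.layers:
            params.append((layer, "W"))
            params.append((layer, "b"))
            if self.spec.use_batchnorm:
                params.append((layer, "gamma"))
                params.append((layer, "beta"))
        params.append((self, "out_W"))
        params.append((self, "out_b"))
        return params

    def n_parameters(self) -> int:
        total = 0
        for holder, name in self.parameters():
            total += int(np.asarray(_get(holder, name)).size)
        return total

    def state(self) -> dict:
        return copy.deepcopy(
            {
                "layers": self.layers,
                "out_W": self.out_W,
                "out_b": self.out_b,
            }
        )

    def load_state(self, state: dict) -> None:
        st = copy.deepcopy(state)
        self.layers = st["layers"]
        self.out_W = st["out_W"]
        self.out_b = st["out_b"]

    # -- forward / backward ----------------------------------------------

    def forward(self, X: np.ndarray, training: bool, rng: np.random.Generator | None = None):
        """Returns (output, cache).  ``output`` is the probability for binary
        traits, the raw prediction for quantitative ones."""
        spec = self.spec
        a = np.asarray(X, dtype=float)
        cache = {"a": [a], "z": [], "xhat": [], "std": [], "zact": [], "mask": []}
        for layer in self.layers:
            z = a @ layer["W"] + layer["b"]
            cache["z"].append(z)
            if spec.use_batchnorm:
                if training:
                    mean = z.mean(axis=0)
                    var = z.var(axis=0)
                    layer["run_mean"] = (1 - _BN_MOMENTUM) * layer["run_mean"] + _BN_MOMENTUM * mean
                    layer["run_var"] = (1 - _BN_MOMENTUM) * layer["run_var"] + _BN_MOMENTUM * var
                else:
                    mean, var = layer["run_mean"], layer["run_var"]
                std = np.sqrt(var + _BN_EPS)
                xhat = (z - mean) / std
                zact = layer["gamma"] * xhat + layer["beta"]
            else:
                std = xhat = None
                zact = z
            cache["xhat"].append(xhat)
            cache["std"].append(std)
            cache["zact"].append(zact)
            h = np.where(zact >= 0.0, zact, spec.leaky_alpha * zact)
            if spec.use_dropout and training:
                mask = (rng.random(h.shape) >= spec.dropout_rate).astype(float)
                h = h * mask / (1.0 - spec.dropout_rate)
            else:
                mask = None
            cache["mask"].append(mask)
            cache["a"].append(h)
            a = h
        o = (a @ self.out_W + self.out_b)[:, 0]
        cache["o"] = o
        if self.trait_type == "binary":
            return logistic(o), cache
        return o, cache

    def backward(self, cache: dict, y: np.ndarray) -> dict:
        """Gradients of the mean loss wrt every parameter."""
        spec = self.spec
        n = len(y)
        out = cache["o"]
        if self.trait_type == "binary":
            p = logistic(out)
            do = (p - y) / n  # BCE through the logistic head
        else:
            do = 2.0 * (out - y) / n
        grads: dict[int, dict] = {}
        a_last = cache["a"][-1]
        grads["out_W"] = a_last.T @ do[:, None]
        grads["out_b"] = np.array([do.sum()])
        da = do[:, None] @ self.out_W.T
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            g: dict[str, np.ndarray] = {}
            if spec.use_dropout and cache["mask"][li] is not None:
                da = da * cache["mask"][li] / (1.0 - spec.dropout_rate)
            zact = cache["zact"][li]
            dz_act = da * np.where(zact >= 0.0, 1.0, spec.leaky_alpha)
            if spec.use_batchnorm:
                xhat = cache["xhat"][li]
                std = cache["std"][li]
                g["gamma"] = (dz_act * xhat).sum(axis=0)
                g["beta"] = dz_act.sum(axis=0)
                dxhat = dz_act * layer["gamma"]
                m = dz_act.shape[0]
                dz = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
                if m == 1:  # batch of one: batch stats have no gradient flow
                    dz = dxhat / std
            else:
                dz = dz_act
            a_prev = cache["a"][li]
            g["W"] = a_prev.T @ dz
            g["b"] = dz.sum(axis=0)
            da = dz @ layer["W"].T
            grads[li] = g
        return grads


def _get(holder, name):
    return holder[name] if isinstance(holder, dict) else getattr(holder, name)


def _set(holder, name, value):
    if isinstance(holder, dict):
        holder[name] = value
    else:
        setattr(holder, name, value)


class _Adam:
    def __init__(self, net: Network, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(np.asarray(_get(h, n), dtype=float)) for h, n in net.parameters()]
        self.v = [np.zeros_like(x) for x in self.m]

    def step(self, grads: dict) -> None:
        self.t += 1
        flat: list[np.ndarray] = []
        for li in range(len(self.net.layers)):
            flat.append(grads[li]["W"])
            flat.append(grads[li]["b"])
            if self.net.spec.use_batchnorm:
                flat.append(grads[li]["gamma"])
                flat.append(grads[li]["beta"])
        flat.append(np.asarray(grads["out_W"]).reshape(self.net.out_W.shape))
        flat.append(grads["out_b"])
        for k, ((holder, name), grad) in enumerate(zip(self.net.parameters(), flat)):
            g = np.asarray(grad, dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            new = _get(holder, name) - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            _set(holder, name, new)


@dataclass
class BaseModel:
    """A trained base network bound to its p-value threshold and SNP set."""

    spec: BaseModelSpec
    trait_type: str
    threshold: float | None
    vids: list[str]
    input_mean: np.ndarray
    input_sd: np.ndarray
    network: Network = field(repr=False)
    val_loss: float = float("nan")
    val_metric: float = float("nan")
    epochs_run: int = 0

    def standardise(self, Z: np.ndarray) -> np.ndarray:
        return (np.asarray(Z, dtype=float) - self.input_mean) / self.input_sd


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def build_network(spec: BaseModelSpec, n_inputs: int, trait_type: str = "binary") -> Network:
    """Untrained network: affine -> [batch-norm] -> Leaky ReLU -> [dropout]
    per hidden layer, then a single output unit."""
    return Network(spec, n_inputs, trait_type)


def _loss_fn(trait_type: str):
    return bce_loss if trait_type == "binary" else mse_loss


def train_base(
    Z_train: np.ndarray,
    y_train: np.ndarray,
    Z_val: np.ndarray,
    y_val: np.ndarray,
    spec: BaseModelSpec,
    trait_type: str,
    threshold: float | None = None,
    vids: Sequence[str] | None = None,
) -> BaseModel:
    """Train one base network with Adam and validation early stopping.

    Inputs are standardised per column by the training mean and standard
    deviation (constants stored on the returned model).  Training stops when
    the validation loss has not improved by at least ``min_delta`` for
    ``early_stop_patience`` consecutive epochs; the best-validation weights
    are restored.
    """
    Z_train = np.asarray(Z_train, dtype=float)
    Z_val = np.asarray(Z_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)

    mean = Z_train.mean(axis=0)
    sd = Z_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr = (Z_train - mean) / sd
    Xva = (Z_val - mean) / sd

    net = build_network(spec, Xtr.shape[1], trait_type)
    rng = net._init_rng
    opt = _Adam(net, spec.learning_rate)
    loss_fn = _loss_fn(trait_type)

    n = len(y_train)
    full_batch = n < spec.full_batch_below

    best_state = net.state()
    best_loss = float("inf")
    best_epoch = 0
    since_improve = 0
    epochs_run = 0

    for epoch in range(spec.max_epochs):
        if full_batch:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = [perm[i:i + spec.batch_size] for i in range(0, n, spec.batch_size)]
        for b in batches:
            _, cache = net.forward(Xtr[b], training=True, rng=rng)
            if not np.all(np.isfinite(cache["o"])):
                raise FloatingPointError(
                    f"non-finite training output at epoch {epoch} (spec {spec})"
                )
            grads = net.backward(cache, y_train[b])
            opt.step(grads)
        epochs_run = epoch + 1
        pred_val, _ = net.forward(Xva, training=False)
        val_loss = loss_fn(y_val, pred_val)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_loss - spec.min_delta:
            best_loss = val_loss
            best_state = net.state()
            best_epoch = epochs_run
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= spec.early_stop_patience:
                break

    net.load_state(best_state)
    if best_loss == float("inf"):  # zero-epoch budget: keep initial weights
        pred_val, _ = net.forward(Xva, training=False)
        best_loss = loss_fn(y_val, pred_val)
        best_epoch = 0
    return BaseModel(
        spec=spec,
        trait_type=trait_type,
        threshold=threshold,
        vids=list(vids) if vids is not None else [],
        input_mean=mean,
        input_sd=sd,
        network=net,
        val_loss=best_loss,
        epochs_run=best_epoch,
    )


def predict(model: BaseModel, Z: np.ndarray) -> np.ndarray:
    """Inference-mode predictions: dropout off, batch-norm running stats.

    Probabilities in (0, 1) for binary traits, raw values for quantitative.
    """
    X = model.standardise(Z)
    out, _ = model.network.forward(X, training=False)
    if model.trait_type == "binary":
        out = np.clip(out, 1e-12, 1.0 - 1e-12)
    return out


def _val_metric(y_val: np.ndarray, pred: np.ndarray, trait_type: str) -> float:
    from .metrics import nagelkerke_r2, r_squared

    if np.std(pred) == 0.0:
        return 0.0
    if trait_type == "binary":
        return nagelkerke_r2(y_val, pred)
    return r_squared(y_val, pred)


def grid_search(
    Z_train: np.ndarray,
    y_train: np.ndarray,
    Z_val: np.ndarray,
    y_val: np.ndarray,
    specs: Sequence[BaseModelSpec],
    trait_type: str,
    threshold: float | None = None,
    vids: Sequence[str] | None = None,
) -> tuple[BaseModel, pd.DataFrame]:
    """Train every valid spec; return the best model and the results table.

    The selection metric is Nagelkerke R² (binary) or R² (quantitative) on
    the validation predictions.  Ties break toward fewer parameters, then
    earlier grid order.  Specs whose width chain collapses below one unit are
    skipped.
    """
    rows = []
    best: BaseModel | None = None
    best_key: tuple[float, int, int] | None = None
    for order, spec in enumerate(specs):
        try:
            hidden_widths(spec, Z_train.shape[1])
        except ValueError:
            rows.append({"grid_order": order, "spec": spec, "skipped": True,
                         "val_metric": float("nan"), "val_loss": float("nan"),
                         "n_parameters": 0, "epochs_run": 0})
            continue
        model = train_base(Z_train, y_train, Z_val, y_val, spec, trait_type,
                           threshold=threshold, vids=vids)
        pred = predict(model, Z_val)
        metric = _val_metric(y_val, pred, trait_type)
        model.val_metric = metric
        n_par = model.network.n_parameters()
        rows.append({"grid_order": order, "spec": spec, "skipped": False,
                     "val_metric": metric, "val_loss": model.val_loss,
                     "n_parameters": n_par, "epochs_run": model.epochs_run})
        key = (-metric, n_par, order)  # smaller is better
        if best_key is None or key < best_key:
            best, best_key = model, key
    if best is None:
        raise ValueError("every spec in the grid was invalid for this input width")
    return best, pd.DataFrame(rows)
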