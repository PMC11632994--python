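"""Feed-forward Cox log-risk network, implemented directly in NumPy.

The model is the neural extension of the Cox proportional-hazards model:
a multilayer perceptron maps a one-hot encoded covariate-and-treatment
vector x to a single scalar h(x), the log-risk, and is trained on the
Breslow-form negative log partial likelihood

    L(h) = -(1/D) * sum_{i: event} [ h_i - log sum_{j: t_j >= t_i} exp(h_j) ]

which is free of the baseline hazard. Training is full batch (risk sets are
global, so a mini-batch partial likelihood would be biased) with ReLU
activations, optional batch normalization and dropout, Adam with decoupled
weight decay, global-norm gradient clipping, and a step or
reduce-on-plateau learning-rate schedule. All weights, the dropout stream
and the validation split derive from the config seed, so training is
exactly reproducible.

Backpropagation is hand-written; a finite-difference check lives in the
test-suite.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .survival import concordance

__all__ = [
    "NetworkConfig",
    "EncodingMap",
    "RiskModel",
    "SearchSpace",
    "encode_features",
    "neg_log_partial_likelihood",
    "partial_likelihood_grad",
    "train",
    "predict_log_risk",
    "random_search",
    "save_model",
    "load_model",
]

MAX_EPOCH_BUDGET = 1000


@dataclass
class NetworkConfig:
    n_hidden_layers: int = 2
    nodes_per_layer: int = 50
    dropout: float = 0.0
    weight_decay: float = 0.0
    learning_rate: float = 0.01
    lr_schedule: str = "plateau"      # none | step | plateau
    lr_step_size: int = 200           # step schedule: epochs between decays
    lr_factor: float = 0.5
    lr_patience: int = 20             # plateau schedule: epochs without val improvement
    grad_clip_norm: float | None = 2.0
    batch_norm: bool = True
    max_epochs: int = 500
    early_stop_patience: int = 50
    checkpoint: str = "best_val"      # best_val | final
    seed: int = 0

    def __post_init__(self) -> None:
        if self.checkpoint not in ("best_val", "final"):
            raise ValueError(f"unknown checkpoint policy {self.checkpoint!r}")
        if self.max_epochs > MAX_EPOCH_BUDGET:
            raise ValueError(f"max_epochs exceeds the {MAX_EPOCH_BUDGET}-epoch budget")
        if self.n_hidden_layers >= 1 and self.nodes_per_layer < 1:
            raise ValueError("nodes_per_layer must be >= 1 when hidden layers exist")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.lr_schedule not in ("none", "step", "plateau"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.grad_clip_norm is not None and self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be > 0 or None")


@dataclass
class EncodingMap:
    """Deterministic full-rank one-hot layout; treatment columns are flagged
    so counterfactual arm-switching can toggle exactly those columns."""

    feature_levels: dict          # factor -> tuple of levels (first = reference)
    treatment_levels: tuple       # first = reference
    columns: list[str] = field(default_factory=list)
    treatment_cols: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            cols = []
            for f, levels in self.feature_levels.items():
                cols.extend(f"{f}={lv}" for lv in levels[1:])
            t0 = len(cols)
            cols.extend(f"treatment={lv}" for lv in self.treatment_levels[1:])
            self.columns = cols
            self.treatment_cols = list(range(t0, len(cols)))

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def transform(self, df: pd.DataFrame, treatment_values) -> np.ndarray:
        """Encode a cohort table plus a per-subject treatment label vector."""
        n = len(df)
        x = np.zeros((n, self.n_columns))
        j = 0
        for f, levels in self.feature_levels.items():
            vals = df[f].to_numpy()
            unseen = ~np.isin(vals, levels)
            if unseen.any():
                raise ValueError(
                    f"unseen level(s) {sorted(set(vals[unseen]))} of factor {f!r}"
                )
            for lv in levels[1:]:
                x[:, j] = vals == lv
                j += 1
        tv = np.asarray(treatment_values, dtype=object)
        if tv.shape == ():  # single arm label for the whole table
            tv = np.full(n, treatment_values, dtype=object)
        unseen = ~np.isin(tv, self.treatment_levels)
        if unseen.any():
            raise ValueError(f"unseen treatment level(s) {sorted(set(tv[unseen]))}")
        for lv in self.treatment_levels[1:]:
            x[:, j] = tv == lv
            j += 1
        return x


def encode_features(
    df: pd.DataFrame,
    feature_factors: list[str],
    treatment_values,
    treatment_levels: tuple,
    scheme=None,
) -> tuple[np.ndarray, EncodingMap]:
    """One-hot encode features plus a treatment label column.

    Level order (hence the reference level, which is dropped) comes from the
    cohort scheme when given, otherwise from sorted observed values.
    """
    feature_levels = {}
    for f in feature_factors:
        if scheme is not None:
            feature_levels[f] = tuple(scheme.levels(f))
        else:
            feature_levels[f] = tuple(sorted(pd.unique(df[f].astype(str))))
    enc = EncodingMap(feature_levels=feature_levels, treatment_levels=tuple(treatment_levels))
    return enc.transform(df, treatment_values), enc


# --------------------------------------------------------------------------
# Partial-likelihood loss
# --------------------------------------------------------------------------

def _risk_group_bounds(t_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    stops = np.r_[starts[1:], t_sorted.size]
    return starts, stops


def neg_log_partial_likelihood(log_risks, times, events) -> float:
    """Breslow negative log partial likelihood, normalized by event count."""
    h = np.asarray(log_risks, float).ravel()
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    d = int(e.sum())
    if d == 0:
        raise ValueError("no events: partial likelihood is undefined")
    order = np.argsort(t, kind="stable")
    h, t, e = h[order], t[order], e[order]
    shift = h.max()
    w = np.exp(h - shift)
    # suffix sums: S0 at group g = sum of w over all t_j >= t_g
    rev_cum = np.cumsum(w[::-1])[::-1]
    starts, _ = _risk_group_bounds(t)
    ll = 0.0
    with np.errstate(divide="ignore"):
        for g, s in enumerate(starts):
            stop = starts[g + 1] if g + 1 < starts.size else t.size
            dg = e[s:stop].sum()
            if dg:
                ll += h[s:stop][e[s:stop] == 1].sum() - dg * (np.log(rev_cum[s]) + shift)
    return float(-ll / d)


def partial_likelihood_grad(log_risks, times, events) -> np.ndarray:
    """d loss / d h for the Breslow loss above (same normalization)."""
    h = np.asarray(log_risks, float).ravel()
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    d = int(e.sum())
    if d == 0:
        raise ValueError("no events: partial likelihood is undefined")
    n = h.size
    order = np.argsort(t, kind="stable")
    inv = np.empty(n, int)
    inv[order] = np.arange(n)
    hs, ts, es = h[order], t[order], e[order]
    shift = hs.max()
    w = np.exp(hs - shift)
    rev_cum = np.cumsum(w[::-1])[::-1]
    starts, stops = _risk_group_bounds(ts)
    # A_k = sum over event groups with t_g <= t_k of d_g / S0_g
    per_group = np.array(
        [es[s:stop].sum() / rev_cum[s] for s, stop in zip(starts, stops)]
    )
    cum = np.cumsum(per_group)
    group_of = np.repeat(np.arange(starts.size), stops - starts)
    a = cum[group_of]
    grad_sorted = (w * a - es) / d
    return grad_sorted[inv]


# --------------------------------------------------------------------------
# MLP with manual backprop
# --------------------------------------------------------------------------

_BN_EPS = 1e-5


def _init_params(n_in: int, config: NetworkConfig, rng: np.random.Generator) -> list[dict]:
    """He-style uniform fan-in init; one dict per layer, output layer last."""
    sizes = [n_in] + [config.nodes_per_layer] * config.n_hidden_layers + [1]
    layers = []
    for li in range(len(sizes) - 1):
        fan_in, fan_out = sizes[li], sizes[li + 1]
        bound = np.sqrt(6.0 / fan_in)
        layer = {
            "W": rng.uniform(-bound, bound, size=(fan_in, fan_out)),
            "b": np.zeros(fan_out),
        }
        hidden = li < len(sizes) - 2
        if hidden and config.batch_norm:
            layer["gamma"] = np.ones(fan_out)
            layer["beta"] = np.zeros(fan_out)
            layer["mean"] = np.zeros(fan_out)   # inference statistics
            layer["var"] = np.ones(fan_out)
        layers.append(layer)
    return layers


def _forward(
    layers: list[dict],
    x: np.ndarray,
    config: NetworkConfig,
    train_mode: bool,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns (h, cache) where cache feeds backprop."""
    a = x
    cache = []
    n_layers = len(layers)
    for li, layer in enumerate(layers):
        hidden = li < n_layers - 1
        z = a @ layer["W"] + layer["b"]
        step = {"a_in": a, "z": z}
        if hidden and config.batch_norm:
            if train_mode:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
            else:
                mu, var = layer["mean"], layer["var"]
            z_hat = (z - mu) / np.sqrt(var + _BN_EPS)
            y = layer["gamma"] * z_hat + layer["beta"]
            step.update(mu=mu, var=var, z_hat=z_hat)
        else:
            y = z
        if hidden:
            y = np.maximum(y, 0.0)
            step["relu_mask"] = y > 0
            if train_mode and config.dropout > 0:
                keep = 1.0 - config.dropout
                mask = (rng.random(y.shape) < keep) / keep
                y = y * mask
                step["drop_mask"] = mask
        cache.append(step)
        a = y
    return a.ravel(), cache


def _backward(
    layers: list[dict],
    cache: list[dict],
    grad_h: np.ndarray,
    config: NetworkConfig,
) -> list[dict]:
    """Backprop d loss / d params from d loss / d h."""
    grads = [dict() for _ in layers]
    da = grad_h[:, None]
    n_layers = len(layers)
    for li in range(n_layers - 1, -1, -1):
        layer, step = layers[li], cache[li]
        hidden = li < n_layers - 1
        if hidden:
            if "drop_mask" in step:
                da = da * step["drop_mask"]
            da = da * step["relu_mask"]
        if hidden and config.batch_norm:
            m = da.shape[0]
            z_hat = step["z_hat"]
            grads[li]["gamma"] = (da * z_hat).sum(axis=0)
            grads[li]["beta"] = da.sum(axis=0)
            dz_hat = da * layer["gamma"]
            inv_std = 1.0 / np.sqrt(step["var"] + _BN_EPS)
            dz = (inv_std / m) * (
                m * dz_hat
                - dz_hat.sum(axis=0)
                - z_hat * (dz_hat * z_hat).sum(axis=0)
            )
        else:
            dz = da
        grads[li]["W"] = step["a_in"].T @ dz
        grads[li]["b"] = dz.sum(axis=0)
        da = dz @ layer["W"].T
    return grads


def _clip_grads(grads: list[dict], max_norm: float | None) -> None:
    if max_norm is None:
        return
    total = np.sqrt(sum(float((g ** 2).sum()) for gd in grads for g in gd.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for gd in grads:
            for k in gd:
                gd[k] = gd[k] * scale


def _inference_bn_stats(layers: list[dict], x: np.ndarray, config: NetworkConfig) -> None:
    """Set BN inference statistics to the full-training-set activations.

    With full-batch training this makes evaluation-mode predictions exact
    and invariant to batch composition.
    """
    if not config.batch_norm:
        return
    a = x
    for li, layer in enumerate(layers[:-1]):
        z = a @ layer["W"] + layer["b"]
        layer["mean"] = z.mean(axis=0)
        layer["var"] = z.var(axis=0)
        z_hat = (z - layer["mean"]) / np.sqrt(layer["var"] + _BN_EPS)
        a = np.maximum(layer["gamma"] * z_hat + layer["beta"], 0.0)
    # output layer has no BN


@dataclass
class RiskModel:
    """A trained log-risk network plus its input encoding and history."""

    config: NetworkConfig
    encoding: EncodingMap | None
    layers: list[dict]
    history: pd.DataFrame | None = None
    train_idx: np.ndarray | None = None   # rows used for gradient steps
    val_idx: np.ndarray | None = None     # rows used for early stopping

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode log-risk, one scalar per row."""
        h, _ = _forward(self.layers, np.asarray(x, float), self.config, train_mode=False)
        return h

    def predict_for_arm(self, df: pd.DataFrame, arm) -> np.ndarray:
        """Counterfactual log-risk with every subject's treatment set to ``arm``."""
        if self.encoding is None:
            raise ValueError("model has no encoding map attached")
        return self.predict(self.encoding.transform(df, arm))


def predict_log_risk(model: RiskModel, df: pd.DataFrame, treatment_values) -> np.ndarray:
    """Log-risk for a cohort table under its (or a supplied) treatment column."""
    if model.encoding is None:
        raise ValueError("model has no encoding map attached")
    return model.predict(model.encoding.transform(df, treatment_values))


def _stratified_split(events: np.ndarray, val_fraction: float, rng: np.random.Generator):
    idx = np.arange(events.size)
    val = []
    for flag in (0, 1):
        pool = idx[events == flag]
        pool = rng.permutation(pool)
        val.append(pool[: max(1, int(round(val_fraction * pool.size)))] if pool.size else pool)
    val_idx = np.sort(np.concatenate(val))
    train_idx = np.setdiff1d(idx, val_idx)
    return train_idx, val_idx


def train(
    x: np.ndarray,
    times,
    events,
    config: NetworkConfig,
    val_fraction: float = 0.2,
    encoding: EncodingMap | None = None,
) -> RiskModel:
    """Full-batch Adam training with early stopping on validation loss.

    Returns the best-validation-loss checkpoint (batch-norm inference
    statistics frozen over the full training portion at that checkpoint).
    """
    x = np.asarray(x, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    rng = np.random.default_rng(config.seed)
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    tr, va = _stratified_split(e, val_fraction, rng)
    if e[tr].sum() < 2:
        raise ValueError("training portion has fewer than 2 events")
    if e[va].sum() < 1:
        raise ValueError("validation portion has no events")
    xtr, ttr, etr = x[tr], t[tr], e[tr]
    xva, tva, eva = x[va], t[va], e[va]

    layers = _init_params(x.shape[1], config, rng)
    adam_m = [{k: np.zeros_like(v) for k, v in ly.items() if k in ("W", "b", "gamma", "beta")}
              for ly in layers]
    adam_v = copy.deepcopy(adam_m)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step_count = 0

    best_val = np.inf
    best_layers = None
    since_best = 0
    plateau_since = 0
    hist = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(config.max_epochs):
        h, cache = _forward(layers, xtr, config, train_mode=True, rng=rng)
        loss = neg_log_partial_likelihood(h, ttr, etr)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={loss!r}; "
                "reduce the learning rate or enable gradient clipping"
            )
        grad_h = partial_likelihood_grad(h, ttr, etr)
        grads = _backward(layers, cache, grad_h, config)
        _clip_grads(grads, config.grad_clip_norm)

        step_count += 1
        for ly, gd, m, v in zip(layers, grads, adam_m, adam_v):
            for k, g in gd.items():
                if config.weight_decay > 0 and k == "W":
                    ly[k] = ly[k] * (1.0 - lr * config.weight_decay)
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                m_hat = m[k] / (1 - b1 ** step_count)
                v_hat = v[k] / (1 - b2 ** step_count)
                ly[k] = ly[k] - lr * m_hat / (np.sqrt(v_hat) + eps)

        _inference_bn_stats(layers, xtr, config)
        val_loss = neg_log_partial_likelihood(
            _forward(layers, xva, config, train_mode=False)[0], tva, eva
        )
        hist["epoch"].append(epoch)
        hist["train_loss"].append(loss)
        hist["val_loss"].append(float(val_loss))
        hist["lr"].append(lr)

        if val_loss < best_val - 1e-12:
            best_val = float(val_loss)
            best_layers = copy.deepcopy(layers)
            since_best = 0
            plateau_since = 0
        else:
            since_best += 1
            plateau_since += 1

        if config.lr_schedule == "step" and (epoch + 1) % config.lr_step_size == 0:
            lr *= config.lr_factor
        elif config.lr_schedule == "plateau" and plateau_since >= config.lr_patience:
            lr *= config.lr_factor
            plateau_since = 0
        if config.early_stop_patience and since_best >= config.early_stop_patience:
            break

    if best_layers is None or config.checkpoint == "final":
        best_layers = copy.deepcopy(layers)
    return RiskModel(
        config=config,
        encoding=encoding,
        layers=best_layers,
        history=pd.DataFrame(hist),
        train_idx=tr,
        val_idx=va,
    )


# --------------------------------------------------------------------------
# Random hyperparameter search
# --------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Uniform random search over explicit per-field choice lists."""

    choices: dict               # NetworkConfig field -> list of values
    n_draws: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        valid = set(NetworkConfig.__dataclass_fields__)
        unknown = set(self.choices) - valid
        if unknown:
            raise ValueError(f"unknown NetworkConfig fields {sorted(unknown)}")

    def draw(self, rng: np.random.Generator) -> dict:
        return {k: v[rng.integers(len(v))] for k, v in self.choices.items()}


def random_search(
    x: np.ndarray,
    times,
    events,
    space: SearchSpace,
    val_fraction: float = 0.2,
    seed: int = 0,
    encoding: EncodingMap | None = None,
) -> tuple[NetworkConfig, RiskModel, pd.DataFrame]:
    """Draw configs uniformly from the space, train each, select by
    validation C statistic (ties broken by lower validation loss)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    rows = []
    best = None
    for draw in range(space.n_draws):
        overrides = space.draw(rng)
        overrides.setdefault("seed", int(rng.integers(2 ** 31 - 1)))
        config = NetworkConfig(**overrides)
        try:
            model = train(x, t, e, config, val_fraction=val_fraction, encoding=encoding)
        except RuntimeError:
            rows.append({"draw": draw, "val_c": np.nan, "val_loss": np.nan,
                         **{k: overrides[k] for k in space.choices}})
            continue
        # evaluate on the model's own validation split (recreated from its seed)
        split_rng = np.random.default_rng(config.seed)
        _, va = _stratified_split(e, val_fraction, split_rng)
        h_va = model.predict(x[va])
        val_c = concordance(t[va], e[va], h_va).c
        val_loss = neg_log_partial_likelihood(h_va, t[va], e[va])
        rows.append({"draw": draw, "val_c": val_c, "val_loss": val_loss,
                     **{k: overrides[k] for k in space.choices}})
        key = (-val_c, val_loss)
        if best is None or key < best[0]:
            best = (key, config, model)
    leaderboard = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every random-search draw diverged")
    return best[1], best[2], leaderboard


# --------------------------------------------------------------------------
# Persistence (portable JSON: config + encoding + weights)
# --------------------------------------------------------------------------

def save_model(model: RiskModel, path) -> None:
    payload = {
        "config": asdict(model.config),
        "encoding": None,
        "layers": [
            {k: np.asarray(v).tolist() for k, v in ly.items()} for ly in model.layers
        ],
    }
    if model.encoding is not None:
        payload["encoding"] = {
            "feature_levels": {k: list(v) for k, v in model.encoding.feature_levels.items()},
            "treatment_levels": list(model.encoding.treatment_levels),
            "columns": list(model.encoding.columns),
            "treatment_cols": list(model.encoding.treatment_cols),
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> RiskModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    config = NetworkConfig(**payload["config"])
    encoding = None
    if payload["encoding"] is not None:
        enc = payload["encoding"]
        encoding = EncodingMap(
            feature_levels={k: tuple(v) for k, v in enc["feature_levels"].items()},
            treatment_levels=tuple(enc["treatment_levels"]),
            columns=list(enc["columns"]),
            treatment_cols=list(enc["treatment_cols"]),
        )
    layers = [
        {k: np.asarray(v, float) for k, v in ly.items()} for ly in payload["layers"]
    ]
    return RiskModel(config=config, encoding=encoding, layers=layers)
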