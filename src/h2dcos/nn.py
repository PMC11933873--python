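"""CNN-LSTM regression of SOD activity from spectra, in pure numpy.

The network design: the spectrum enters as a
1 x B "2D data matrix"; three convolution blocks, each a 1x2 kernel with
stride 2 followed by 1x2 max pooling, produce 32, 64 and 128 feature maps;
the conv output, read as a sequence over the reduced band axis with the
filter dimension as features, feeds an LSTM; a dense layer and a single
linear regression output complete the model.  Training minimizes mean
squared error with Adam.

Because the convolution is a 1x2 kernel at stride 2, receptive fields never
overlap, so both convolution and pooling are reshapes plus small matrix
products — which keeps a from-scratch implementation exact, fast at the
problem sizes involved (hundreds of samples, a few hundred bands), and
bit-deterministic under a fixed seed.  Inputs and targets are standardized
internally (per-band z-scores fitted on the training data); predictions are
returned in the original units (U/mg).

Blocks whose input would become shorter than 4 positions are dropped
automatically (recorded in the model summary), so the same architecture runs
on full spectra and on 10-band sensitive-wavelength subsets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import SpectrumSet


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Architecture parameters.

    conv_filters: feature-map counts per block (kernel 1x2, stride 2, max
    pooling are fixed unless overridden); lstm_units/dense_units size the
    recurrent and dense layers; seed fixes the weight initialization.
    """

    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel: int = 2
    stride: int = 2
    lstm_units: int = 64
    dense_units: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lstm_units < 1 or self.dense_units < 1:
            raise ValueError("lstm_units and dense_units must be >= 1")
        if self.kernel != 2 or self.stride != 2:
            raise ValueError(
                "only the 1x2 kernel with stride 2 is supported"
            )
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("filter counts must be >= 1")


@dataclass
class TrainConfig:
    """Optimization settings: standard small-data defaults, all overridable."""

    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    split_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only adam is implemented")


@dataclass
class EvalMetrics:
    """Pearson R and RMSE between predictions and reference values."""

    r: float
    rmse: float
    n: int
    split: str = ""
    r_defined: bool = True


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class CNNLSTMRegressor:
    """Spectral CNN-LSTM regressor; see module docstring for the architecture."""

    def __init__(self, spec: ModelSpec, input_bands: int):
        if input_bands < 8:
            raise ValueError(
                f"input_bands={input_bands} < 8: too short for a conv block "
                "stack; reduce conv_blocks or supply more bands"
            )
        self.spec = spec
        self.input_bands = int(input_bands)

        # plan the conv stack: each block needs >= 4 positions coming in
        plan: list[tuple[int, int, int]] = []  # (c_in, filters, t_in)
        t, c = self.input_bands, 1
        for f in spec.conv_filters:
            if t < 4:
                break
            plan.append((c, f, t))
            t = (t // 2) // 2  # conv then pool, both halving
            c = f
        self.block_plan = plan
        self.seq_len = t
        self.feat_dim = c
        self.depth_reduced = len(plan) < len(spec.conv_filters)

        rng = np.random.default_rng(spec.seed)
        H, D = spec.lstm_units, spec.dense_units
        self.params: dict[str, np.ndarray] = {}
        for i, (cin, f, _) in enumerate(plan):
            self.params[f"conv{i}_W"] = _glorot(rng, (2, cin, f), 2 * cin, f)
            self.params[f"conv{i}_b"] = np.zeros(f)
        F = self.feat_dim
        self.params["lstm_W"] = _glorot(rng, (F + H, 4 * H), F + H, 4 * H)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.params["lstm_b"] = b
        self.params["dense_W"] = _glorot(rng, (H, D), H, D)
        self.params["dense_b"] = np.zeros(D)
        self.params["out_W"] = _glorot(rng, (D, 1), D, 1)
        self.params["out_b"] = np.zeros(1)

        # standardization, fitted in fit()
        self.x_mean = np.zeros(input_bands)
        self.x_std = np.ones(input_bands)
        self.y_mean = 0.0
        self.y_std = 1.0
        self.fitted = False

    # -- bookkeeping --------------------------------------------------------

    def summary(self) -> dict:
        return {
            "input_bands": self.input_bands,
            "conv_blocks": [
                {"in_channels": c, "filters": f, "in_length": t}
                for c, f, t in self.block_plan
            ],
            "depth_reduced": self.depth_reduced,
            "requested_blocks": len(self.spec.conv_filters),
            "lstm_sequence_length": self.seq_len,
            "lstm_feature_dim": self.feat_dim,
            "lstm_units": self.spec.lstm_units,
            "dense_units": self.spec.dense_units,
            "n_parameters": int(sum(p.size for p in self.params.values())),
        }

    def conv_param_names(self) -> list[str]:
        return [k for k in self.params if k.startswith("conv")]

    # -- forward / backward -------------------------------------------------

    def _forward(self, Xs: np.ndarray, cache: bool = False):
        """Xs: standardized (batch, B). Returns standardized predictions."""
        caches = []
        a = Xs[:, :, None]  # (batch, T, C=1)
        for i, _ in enumerate(self.block_plan):
            W, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            t = a.shape[1]
            tc = t // 2
            pairs = a[:, : 2 * tc].reshape(a.shape[0], tc, 2, a.shape[2])
            pre = np.tensordot(pairs, W, axes=([2, 3], [0, 1])) + b
            relu = np.maximum(pre, 0.0)
            tp = tc // 2
            pool_in = relu[:, : 2 * tp].reshape(relu.shape[0], tp, 2, relu.shape[2])
            arg = pool_in.argmax(axis=2)
            pooled = np.take_along_axis(pool_in, arg[:, :, None, :], axis=2)[:, :, 0, :]
            if cache:
                caches.append((a.shape, pairs, pre > 0, relu.shape, arg, tc, tp))
            a = pooled

        # LSTM over the reduced band axis
        B_, T, F = a.shape
        H = self.spec.lstm_units
        W, b = self.params["lstm_W"], self.params["lstm_b"]
        h = np.zeros((B_, H))
        c = np.zeros((B_, H))
        steps = []
        for t_ in range(T):
            xh = np.concatenate([a[:, t_, :], h], axis=1)
            z = xh @ W + b
            i_g = _sigmoid(z[:, :H])
            f_g = _sigmoid(z[:, H : 2 * H])
            g_g = np.tanh(z[:, 2 * H : 3 * H])
            o_g = _sigmoid(z[:, 3 * H :])
            c_new = f_g * c + i_g * g_g
            tc_ = np.tanh(c_new)
            h_new = o_g * tc_
            if cache:
                steps.append((xh, i_g, f_g, g_g, o_g, c, c_new, tc_))
            h, c = h_new, c_new

        d_pre = h @ self.params["dense_W"] + self.params["dense_b"]
        d_act = np.maximum(d_pre, 0.0)
        y = (d_act @ self.params["out_W"] + self.params["out_b"])[:, 0]
        if cache:
            return y, caches, (a, steps, h, d_pre > 0, d_act)
        return y

    def _backward(self, Xs, caches_conv, cache_head, dy) -> dict[str, np.ndarray]:
        a_conv, steps, h, d_mask, d_act = cache_head
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        B_ = Xs.shape[0]
        H = self.spec.lstm_units

        grads["out_W"] = d_act.T @ dy[:, None]
        grads["out_b"] = np.array([dy.sum()])
        dd = (dy[:, None] @ self.params["out_W"].T) * d_mask
        grads["dense_W"] = h.T @ dd
        grads["dense_b"] = dd.sum(axis=0)
        dh = dd @ self.params["dense_W"].T
        dc = np.zeros_like(dh)

        W = self.params["lstm_W"]
        T = a_conv.shape[1]
        F = a_conv.shape[2]
        da = np.zeros_like(a_conv)
        for t_ in range(T - 1, -1, -1):
            xh, i_g, f_g, g_g, o_g, c_prev, c_new, tc_ = steps[t_]
            do = dh * tc_
            dc = dc + dh * o_g * (1.0 - tc_ * tc_)
            di = dc * g_g
            dg = dc * i_g
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i_g * (1.0 - i_g),
                    df * f_g * (1.0 - f_g),
                    dg * (1.0 - g_g * g_g),
                    do * o_g * (1.0 - o_g),
                ],
                axis=1,
            )
            grads["lstm_W"] += xh.T @ dz
            grads["lstm_b"] += dz.sum(axis=0)
            dxh = dz @ W.T
            da[:, t_, :] = dxh[:, :F]
            dh = dxh[:, F:]
            dc = dc * f_g

        # conv blocks, reversed
        d_out = da
        for i in range(len(self.block_plan) - 1, -1, -1):
            in_shape, pairs, relu_mask, relu_shape, arg, tc, tp = caches_conv[i]
            Wc = self.params[f"conv{i}_W"]
            d_relu = np.zeros(relu_shape)
            d_pool_in = np.zeros((B_, tp, 2, relu_shape[2]))
            np.put_along_axis(d_pool_in, arg[:, :, None, :], d_out[:, :, None, :], axis=2)
            d_relu[:, : 2 * tp] = d_pool_in.reshape(B_, 2 * tp, relu_shape[2])
            d_pre = d_relu * relu_mask
            grads[f"conv{i}_W"] = np.tensordot(pairs, d_pre, axes=([0, 1], [0, 1]))
            grads[f"conv{i}_b"] = d_pre.sum(axis=(0, 1))
            d_pairs = np.tensordot(d_pre, Wc, axes=([2], [2]))  # (B, tc, 2, cin)
            d_in = np.zeros(in_shape)
            d_in[:, : 2 * tc] = d_pairs.reshape(B_, 2 * tc, in_shape[2])
            d_out = d_in
        return grads

    # -- training -----------------------------------------------------------

    def fit(
        self,
        spectra: SpectrumSet,
        cfg: TrainConfig | None = None,
        trainable: set[str] | None = None,
        refit_scalers: bool = True,
    ) -> list[float]:
        """Train on a calibration SpectrumSet; returns per-epoch MSE history.

        ``trainable`` restricts updates to a subset of parameter names (used
        by transfer learning to freeze the convolutional feature extractor);
        ``refit_scalers=False`` keeps previously fitted standardization.
        """
        cfg = cfg or TrainConfig()
        X = spectra.X
        y = spectra.perturbation
        if X.shape[1] != self.input_bands:
            raise ValueError(
                f"model expects {self.input_bands} bands, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in training data")
        if np.ptp(y) == 0:
            raise ValueError("zero-variance targets: refusing degenerate fit")
        if refit_scalers or not self.fitted:
            self.x_mean = X.mean(axis=0)
            self.x_std = np.maximum(X.std(axis=0), 1e-12)
            self.y_mean = float(y.mean())
            self.y_std = float(max(y.std(), 1e-12))
        Xs = (X - self.x_mean) / self.x_std
        ys = (y - self.y_mean) / self.y_std

        names = sorted(self.params) if trainable is None else sorted(trainable)
        unknown = set(names) - set(self.params)
        if unknown:
            raise ValueError(f"unknown trainable parameters: {sorted(unknown)}")
        m = {k: np.zeros_like(self.params[k]) for k in names}
        v = {k: np.zeros_like(self.params[k]) for k in names}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        rng = np.random.default_rng(cfg.seed)
        n = X.shape[0]
        history: list[float] = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xs[idx], ys[idx]
                pred, conv_caches, head_cache = self._forward(xb, cache=True)
                err = pred - yb
                loss = float(np.mean(err**2))
                losses.append(loss)
                dy = 2.0 * err / err.size
                grads = self._backward(xb, conv_caches, head_cache, dy)
                step += 1
                lr = cfg.learning_rate
                for k in names:
                    g = grads[k]
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                last_good = history[-1] if history else float("nan")
                raise TrainingDivergenceError(
                    f"NaN/inf loss at epoch {epoch}; last good epoch loss "
                    f"{last_good:.6g}"
                )
            history.append(epoch_loss)
        self.fitted = True
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict activities (original units) for an (n, B) matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_bands:
            raise ValueError(
                f"model expects {self.input_bands} bands, got {X.shape[1]}"
            )
        Xs = (X - self.x_mean) / self.x_std
        ys = self._forward(Xs, cache=False)
        return ys * self.y_std + self.y_mean

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arch = {
            "spec": {
                "conv_filters": list(self.spec.conv_filters),
                "kernel": self.spec.kernel,
                "stride": self.spec.stride,
                "lstm_units": self.spec.lstm_units,
                "dense_units": self.spec.dense_units,
                "seed": self.spec.seed,
            },
            "input_bands": self.input_bands,
            "summary": self.summary(),
        }
        (directory / "architecture.json").write_text(json.dumps(arch, indent=2))
        np.savez(
            directory / "weights.npz",
            x_mean=self.x_mean,
            x_std=self.x_std,
            y_scale=np.array([self.y_mean, self.y_std]),
            fitted=np.array([int(self.fitted)]),
            **self.params,
        )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CNNLSTMRegressor":
        directory = Path(directory)
        arch = json.loads((directory / "architecture.json").read_text())
        spec = ModelSpec(
            conv_filters=tuple(arch["spec"]["conv_filters"]),
            kernel=arch["spec"]["kernel"],
            stride=arch["spec"]["stride"],
            lstm_units=arch["spec"]["lstm_units"],
            dense_units=arch["spec"]["dense_units"],
            seed=arch["spec"]["seed"],
        )
        model = cls(spec, arch["input_bands"])
        data = np.load(directory / "weights.npz")
        for k in model.params:
            model.params[k] = data[k]
        model.x_mean = data["x_mean"]
        model.x_std = data["x_std"]
        model.y_mean, model.y_std = data["y_scale"]
        model.fitted = bool(data["fitted"][0])
        return model

    def copy(self) -> "CNNLSTMRegressor":
        clone = CNNLSTMRegressor(self.spec, self.input_bands)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone.x_mean = self.x_mean.copy()
        clone.x_std = self.x_std.copy()
        clone.y_mean, clone.y_std = self.y_mean, self.y_std
        clone.fitted = self.fitted
        return clone


def build_model(spec: ModelSpec, input_bands: int) -> CNNLSTMRegressor:
    """Construct a CNN-LSTM regressor for spectra of ``input_bands`` bands."""
    return CNNLSTMRegressor(spec, input_bands)


def split_dataset(
    spectra: SpectrumSet, cfg: TrainConfig | None = None
) -> tuple[SpectrumSet, SpectrumSet]:
    """Calibration/prediction split, stratified by treatment x stage.

    The total calibration size is ``floor(split_fraction * N)``; it is
    apportioned to strata by the largest-remainder rule so the global count
    is exact (e.g. 0.75 of 108 gives 81/27).  Strata smaller than 2 samples
    trigger a warning and a plain random split.  Reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    n = spectra.n_samples
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    rng = np.random.default_rng(cfg.seed)
    n_cal = int(np.floor(cfg.split_fraction * n))

    strata: list[np.ndarray]
    if (
        spectra.meta is not None
        and {"treatment_g_per_l", "stage"} <= set(spectra.meta.columns)
    ):
        keys = (
            spectra.meta["treatment_g_per_l"].astype(str)
            + "|"
            + spectra.meta["stage"].astype(str)
        ).to_numpy()
        uniq = sorted(set(keys))
        strata = [np.nonzero(keys == k)[0] for k in uniq]
        if min(len(s) for s in strata) < 2:
            warnings.warn(
                "stratum with fewer than 2 samples; falling back to a random split",
                stacklevel=2,
            )
            strata = [np.arange(n)]
    else:
        strata = [np.arange(n)]

    quotas = np.array([cfg.split_fraction * len(s) for s in strata])
    base = np.floor(quotas).astype(int)
    short = n_cal - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for j in order[: max(short, 0)]:
        base[j] += 1
    cal_idx: list[int] = []
    for s, k in zip(strata, base):
        perm = rng.permutation(len(s))
        cal_idx.extend(s[perm[:k]])
    cal_mask = np.zeros(n, dtype=bool)
    cal_mask[cal_idx] = True
    return spectra.take(np.nonzero(cal_mask)[0]), spectra.take(np.nonzero(~cal_mask)[0])


def train(
    model: CNNLSTMRegressor, calibration: SpectrumSet, cfg: TrainConfig | None = None
) -> tuple[CNNLSTMRegressor, list[float]]:
    """Fit the model on the calibration set; returns (model, loss history)."""
    history = model.fit(calibration, cfg)
    return model, history


def pearson_r(pred: np.ndarray, ref: np.ndarray) -> float:
    return float(np.corrcoef(pred, ref)[0, 1])


def evaluate(
    model: CNNLSTMRegressor, spectra: SpectrumSet, split: str = ""
) -> EvalMetrics:
    """Pearson R and RMSE of model predictions against the set's labels."""
    pred = model.predict(spectra.X)
    ref = spectra.perturbation
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(ref) == 0:
        return EvalMetrics(r=float("nan"), rmse=rmse, n=ref.size, split=split, r_defined=False)
    return EvalMetrics(r=pearson_r(pred, ref), rmse=rmse, n=ref.size, split=split)
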