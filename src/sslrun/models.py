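"""The five stance-load estimators, implemented directly in NumPy.

Each model maps a running step to the 100-sample time-normalized load curve
of one musculoskeletal structure:

* ``hybrid_lstm`` -- two bidirectional LSTM layers (20 units each) over the
  multivariate IMU time series; the recurrent summary (final hidden states of
  the second layer, 40 values) is concatenated with the tabular features,
  batch-normalized, passed through dropout (0.2), a 20-unit ReLU dense layer,
  dropout (0.2) and a linear 100-unit output layer.
* ``ts_lstm`` -- the same architecture without the concatenation step (time
  series only).
* ``f_nn`` -- tabular features only: dense 20 ReLU, dropout 0.2, dense 20
  ReLU, dropout 0.2, linear dense 100.
* ``linear_l1`` -- a multi-output linear map on the tabular features with an
  L1 penalty, trained with the same optimizer/early-stopping protocol; the
  regularization strength is selected on validation MSE over a log grid in
  [1e-4, 100].
* ``mean`` -- the pointwise mean training curve (constant prediction).

Training uses Adam (default initial learning rate 1e-4, staircase-decayed by
0.90 every 10,000 optimizer steps), MSE loss, batch size 64, at most 500
epochs and early stopping on validation MSE with patience 30, restoring the
best-epoch parameters.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

MODEL_TYPES = ("hybrid_lstm", "ts_lstm", "f_nn", "linear_l1", "mean")
N_OUT = 100
DTYPE = np.float32

#: log-spaced L1 strength grid spanning the tuning range [1e-4, 100]
L1_LAMBDA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


@dataclass
class ModelSpec:
    model_type: str
    sensors: str = "dual"  # dual | pelvis | foot
    structure: str = "achilles"
    recurrent_units: int = 20
    dense_units: int = 20
    dropout: float = 0.2
    learning_rate: float = 1e-4
    decay_factor: float = 0.90
    decay_steps: int = 10_000
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 30
    l1_lambda: float = 1e-4  # linear_l1 only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model_type {self.model_type!r}")


@dataclass
class ModelData:
    """Standardized inputs for a set of steps plus their target curves (BW)."""

    x_ts: np.ndarray | None  # (n, T, C) or None for tabular-only models
    x_tab: np.ndarray | None  # (n, F) or None for time-series-only models
    y: np.ndarray  # (n, N_OUT)

    @property
    def n(self) -> int:
        return self.y.shape[0]


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(DTYPE)
        self.g = np.zeros_like(self.v)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += self._x.T @ dy
        self.b.g += dy.sum(axis=0)
        return dy @ self.W.v.T


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    """Inverted dropout; active in training mode and during MC inference."""

    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class BatchNorm:
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._xhat = (x - mu) / np.sqrt(var + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._train = train
        return self.gamma.v * self._xhat + self.beta.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        self.gamma.g += (dy * xhat).sum(axis=0)
        self.beta.g += dy.sum(axis=0)
        if not self._train:
            return dy * self.gamma.v * istd
        n = dy.shape[0]
        dxhat = dy * self.gamma.v
        return (istd / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class LSTMDirection:
    """One direction of an LSTM layer with full backpropagation through time."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, reverse: bool):
        u = units
        self.units = u
        self.reverse = reverse
        self.Wx = Param(_glorot(rng, (d_in, 4 * u)))
        self.Wh = Param(_glorot(rng, (u, 4 * u)))
        b = np.zeros(4 * u)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.b = Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, return_sequences: bool) -> np.ndarray:
        if self.reverse:
            x = x[:, ::-1]
        B, T, D = x.shape
        u = self.units
        pre = (x.reshape(B * T, D) @ self.Wx.v).reshape(B, T, 4 * u)
        h = np.zeros((B, u), dtype=DTYPE)
        c = np.zeros((B, u), dtype=DTYPE)
        gi = np.empty((T, B, u), dtype=DTYPE)
        gf = np.empty_like(gi)
        gg = np.empty_like(gi)
        go = np.empty_like(gi)
        tc = np.empty_like(gi)
        cprev = np.empty_like(gi)
        hprev = np.empty_like(gi)
        hs = np.empty_like(gi)
        for t in range(T):
            a = pre[:, t] + h @ self.Wh.v + self.b.v
            i = _sigmoid(a[:, :u])
            f = _sigmoid(a[:, u : 2 * u])
            g = np.tanh(a[:, 2 * u : 3 * u])
            o = _sigmoid(a[:, 3 * u :])
            cprev[t] = c
            hprev[t] = h
            c = f * c + i * g
            t_c = np.tanh(c)
            h = o * t_c
            gi[t], gf[t], gg[t], go[t], tc[t], hs[t] = i, f, g, o, t_c, h
        self._cache = (x, gi, gf, gg, go, tc, cprev, hprev)
        self._seq = return_sequences
        if return_sequences:
            out = np.swapaxes(hs, 0, 1)  # (B, T, u)
            return out[:, ::-1] if self.reverse else out
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, gi, gf, gg, go, tc, cprev, hprev = self._cache
        B, T, D = x.shape
        u = self.units
        if self._seq:
            dh_seq = dout[:, ::-1] if self.reverse else dout
        dh_next = np.zeros((B, u), dtype=DTYPE)
        dc = np.zeros((B, u), dtype=DTYPE)
        dA = np.empty((B, T, 4 * u), dtype=DTYPE)
        WhT = self.Wh.v.T
        dWh = np.zeros_like(self.Wh.v)
        for t in range(T - 1, -1, -1):
            dh = dh_next.copy()
            if self._seq:
                dh += dh_seq[:, t]
            elif t == T - 1:
                dh += dout
            i, f, g, o, t_c = gi[t], gf[t], gg[t], go[t], tc[t]
            do = dh * t_c
            dct = dc + dh * o * (1.0 - t_c * t_c)
            di = dct * g
            dg = dct * i
            df = dct * cprev[t]
            dc = dct * f
            da = dA[:, t]
            da[:, :u] = di * i * (1.0 - i)
            da[:, u : 2 * u] = df * f * (1.0 - f)
            da[:, 2 * u : 3 * u] = dg * (1.0 - g * g)
            da[:, 3 * u :] = do * o * (1.0 - o)
            dh_next = da @ WhT
            dWh += hprev[t].T @ da
        self.Wh.g += dWh
        flat = dA.reshape(B * T, 4 * u)
        self.Wx.g += x.reshape(B * T, D).T @ flat
        self.b.g += flat.sum(axis=0)
        dx = (flat @ self.Wx.v.T).reshape(B, T, D)
        return dx[:, ::-1] if self.reverse else dx


class BiLSTM:
    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.fwd = LSTMDirection(d_in, units, rng, reverse=False)
        self.bwd = LSTMDirection(d_in, units, rng, reverse=True)
        self.units = units

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, return_sequences: bool) -> np.ndarray:
        a = self.fwd.forward(x, return_sequences)
        b = self.bwd.forward(x, return_sequences)
        return np.concatenate([a, b], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u = self.units
        da, db = dy[..., :u], dy[..., u:]
        return self.fwd.backward(np.ascontiguousarray(da)) + self.bwd.backward(
            np.ascontiguousarray(db)
        )


class Adam:
    def __init__(self, params: list, spec: ModelSpec):
        self.params = params
        self.spec = spec
        self.m = [np.zeros_like(p.v) for p in params]
        self.vv = [np.zeros_like(p.v) for p in params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    @property
    def lr(self) -> float:
        # staircase exponential decay
        return self.spec.learning_rate * self.spec.decay_factor ** (
            self.t // self.spec.decay_steps
        )

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.vv):
            m *= b1
            m += (1 - b1) * p.g
            v *= b2
            v += (1 - b2) * p.g * p.g
            p.v -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
            p.g[:] = 0.0


class _BaseModel:
    """Shared training loop: Adam, MSE, early stopping with best-epoch restore."""

    spec: ModelSpec

    def params(self) -> list:
        raise NotImplementedError

    def _forward(self, data: ModelData, sl: slice | np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def _backward(self, dy: np.ndarray) -> None:
        raise NotImplementedError

    def _loss_grad(self, pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        err = pred - y
        loss = float(np.mean(err**2))
        return loss, (2.0 / err.size) * err

    def _penalty_grad(self) -> None:
        return None

    def evaluate_mse(self, data: ModelData) -> float:
        pred = self._forward(data, slice(None), train=False, rng=None)
        return float(np.mean((pred - data.y) ** 2))

    def _init_output_bias(self, train: ModelData) -> None:
        """Start the output layer at the pointwise mean training curve so the
        optimizer only has to learn deviations from the base rate."""
        out = getattr(self, "out", None) or getattr(self, "lin", None)
        if out is not None:
            out.b.v[:] = train.y.mean(axis=0).astype(DTYPE)

    def fit(self, train: ModelData, val: ModelData | None) -> "_BaseModel":
        if train.n == 0:
            raise ValueError("empty training set")
        self._init_output_bias(train)
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        opt = Adam(self.params(), spec)
        best_val = np.inf
        best_state = None
        best_epoch = -1
        history = {"train_mse": [], "val_mse": []}
        n = train.n
        for epoch in range(spec.max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                pred = self._forward(train, idx, train=True, rng=rng)
                loss, dy = self._loss_grad(pred, train.y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(f"NaN/inf training loss at epoch {epoch}")
                self._backward(dy.astype(DTYPE))
                self._penalty_grad()
                opt.step()
                ep_loss += loss * idx.size
            history["train_mse"].append(ep_loss / n)
            if val is not None and val.n:
                v = self.evaluate_mse(val)
                history["val_mse"].append(v)
                if v < best_val - 1e-12:
                    best_val, best_epoch = v, epoch
                    best_state = [p.v.copy() for p in self.params()]
                elif epoch - best_epoch >= spec.patience:
                    break
        if best_state is not None:
            for p, s in zip(self.params(), best_state):
                p.v[:] = s
        self.history = history
        self.best_epoch = best_epoch if best_epoch >= 0 else len(history["train_mse"]) - 1
        return self

    def predict(self, data: ModelData) -> np.ndarray:
        """Predicted 100-sample curves, clipped to be non-negative."""
        pred = self._forward(data, slice(None), train=False, rng=None)
        return np.clip(pred.astype(float), 0.0, None)

    def mc_forward(self, data: ModelData, rng: np.random.Generator) -> np.ndarray:
        """One stochastic forward pass: dropout active, batch-norm in
        inference mode (Monte Carlo dropout)."""
        pred = self._forward(data, slice(None), train=False, rng=rng, mc=True)
        return np.clip(pred.astype(float), 0.0, None)

    @property
    def has_dropout(self) -> bool:
        """True when the architecture contains dropout layers (even at rate
        0, where MC passes are deterministic and every SD is exactly zero)."""
        return any(isinstance(v, Dropout) for v in vars(self).values())


class RecurrentCurveModel(_BaseModel):
    """hybrid_lstm (time series + tabular) and ts_lstm (time series only)."""

    def __init__(self, spec: ModelSpec, ts_channels: int, n_tab: int | None):
        self.spec = spec
        self.use_tab = spec.model_type == "hybrid_lstm"
        if self.use_tab and not n_tab:
            raise ValueError("hybrid_lstm requires tabular features")
        rng = np.random.default_rng(spec.seed)
        u = spec.recurrent_units
        self.lstm1 = BiLSTM(ts_channels, u, rng)
        self.lstm2 = BiLSTM(2 * u, u, rng)
        width = 2 * u + (n_tab if self.use_tab else 0)
        self.bn = BatchNorm(width)
        self.drop1 = Dropout(spec.dropout)
        self.dense1 = Dense(width, spec.dense_units, rng)
        self.relu = ReLU()
        self.drop2 = Dropout(spec.dropout)
        self.out = Dense(spec.dense_units, N_OUT, rng)
        self.ts_channels = ts_channels
        self.n_tab = n_tab if self.use_tab else 0

    def params(self):
        return (
            self.lstm1.params()
            + self.lstm2.params()
            + self.bn.params()
            + self.dense1.params()
            + self.out.params()
        )

    def _forward(self, data, sl, train, rng, mc=False, bypass_batchnorm=False):
        x = np.ascontiguousarray(data.x_ts[sl], dtype=DTYPE)
        if x.shape[2] != self.ts_channels:
            raise ValueError(
                f"expected {self.ts_channels} time-series channels, got {x.shape[2]}"
            )
        h = self.lstm1.forward(x, return_sequences=True)
        h = self.lstm2.forward(h, return_sequences=False)
        if self.use_tab:
            tab = np.asarray(data.x_tab[sl], dtype=DTYPE)
            if tab.shape[1] != self.n_tab:
                raise ValueError(f"expected {self.n_tab} tabular features, got {tab.shape[1]}")
            h = np.concatenate([h, tab], axis=1)
        self._concat_width = h.shape[1]
        if not bypass_batchnorm:
            h = self.bn.forward(h, train=train)
        else:
            self._bn_bypassed = True
        drop_active = train or mc
        h = self.drop1.forward(h, drop_active, rng)
        h = self.relu.forward(self.dense1.forward(h))
        h = self.drop2.forward(h, drop_active, rng)
        return self.out.forward(h)

    def _backward(self, dy):
        d = self.out.backward(dy)
        d = self.drop2.backward(d)
        d = self.dense1.backward(self.relu.backward(d))
        d = self.drop1.backward(d)
        d = self.bn.backward(d)
        if self.use_tab:
            d = d[:, : 2 * self.spec.recurrent_units]
        d = self.lstm2.backward(np.ascontiguousarray(d))
        self.lstm1.backward(d)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))


class FeedForwardCurveModel(_BaseModel):
    """f_nn: tabular features -> dense 20 ReLU -> dropout -> dense 20 ReLU ->
    dropout -> linear dense 100."""

    def __init__(self, spec: ModelSpec, n_tab: int):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.dense1 = Dense(n_tab, spec.dense_units, rng)
        self.relu1 = ReLU()
        self.drop1 = Dropout(spec.dropout)
        self.dense2 = Dense(spec.dense_units, spec.dense_units, rng)
        self.relu2 = ReLU()
        self.drop2 = Dropout(spec.dropout)
        self.out = Dense(spec.dense_units, N_OUT, rng)
        self.n_tab = n_tab

    def params(self):
        return self.dense1.params() + self.dense2.params() + self.out.params()

    def _forward(self, data, sl, train, rng, mc=False):
        x = np.asarray(data.x_tab[sl], dtype=DTYPE)
        if x.shape[1] != self.n_tab:
            raise ValueError(f"expected {self.n_tab} tabular features, got {x.shape[1]}")
        drop_active = train or mc
        h = self.relu1.forward(self.dense1.forward(x))
        h = self.drop1.forward(h, drop_active, rng)
        h = self.relu2.forward(self.dense2.forward(h))
        h = self.drop2.forward(h, drop_active, rng)
        return self.out.forward(h)

    def _backward(self, dy):
        d = self.out.backward(dy)
        d = self.drop2.backward(d)
        d = self.dense2.backward(self.relu2.backward(d))
        d = self.drop1.backward(d)
        self.dense1.backward(self.relu1.backward(d))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))


class LinearL1Model(_BaseModel):
    """Multi-output linear map with an L1 coefficient penalty (intercept free)."""

    def __init__(self, spec: ModelSpec, n_tab: int):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.lin = Dense(n_tab, N_OUT, rng)
        self.lin.W.v[:] = 0.0  # start from the intercept-only model
        self.n_tab = n_tab

    def params(self):
        return self.lin.params()

    def _forward(self, data, sl, train, rng, mc=False):
        return self.lin.forward(np.asarray(data.x_tab[sl], dtype=DTYPE))

    def _backward(self, dy):
        self.lin.backward(dy)

    def _penalty_grad(self):
        # subgradient of lambda * ||W||_1, scaled like the mean loss
        lam = self.spec.l1_lambda / self.lin.W.v.size
        self.lin.W.g += lam * np.sign(self.lin.W.v)

    @property
    def has_dropout(self) -> bool:
        return False


class MeanRegressor:
    """Constant prediction: the pointwise mean training curve."""

    def __init__(self, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec(model_type="mean")
        self.mean_curve: np.ndarray | None = None

    def fit(self, train: ModelData, val: ModelData | None = None) -> "MeanRegressor":
        if train.n == 0:
            raise ValueError("empty training set")
        self.mean_curve = train.y.mean(axis=0)
        self.history = {"train_mse": [float(np.mean((train.y - self.mean_curve) ** 2))]}
        return self

    def predict(self, data: ModelData) -> np.ndarray:
        if self.mean_curve is None:
            raise RuntimeError("model not fitted")
        return np.clip(np.tile(self.mean_curve, (data.n, 1)), 0.0, None)

    def evaluate_mse(self, data: ModelData) -> float:
        return float(np.mean((self.predict(data) - data.y) ** 2))

    @property
    def has_dropout(self) -> bool:
        return False


def build(spec: ModelSpec, ts_channels: int | None = None, n_tab: int | None = None):
    """Instantiate an untrained model matching ``spec`` and the input shapes."""
    if spec.model_type in ("hybrid_lstm", "ts_lstm"):
        if not ts_channels:
            raise ValueError(f"{spec.model_type} requires time-series input")
        return RecurrentCurveModel(spec, ts_channels, n_tab)
    if spec.model_type == "f_nn":
        if not n_tab:
            raise ValueError("f_nn requires tabular input")
        return FeedForwardCurveModel(spec, n_tab)
    if spec.model_type == "linear_l1":
        if not n_tab:
            raise ValueError("linear_l1 requires tabular input")
        return LinearL1Model(spec, n_tab)
    return MeanRegressor(spec)


def fit_mean_regressor(train: ModelData) -> MeanRegressor:
    return MeanRegressor().fit(train)


def fit_linear_l1(
    train: ModelData,
    val: ModelData,
    spec: ModelSpec | None = None,
    lambda_grid: tuple[float, ...] = L1_LAMBDA_GRID,
) -> tuple[LinearL1Model, float, dict]:
    """Train one linear model per grid point; keep the validation-MSE winner."""
    if not lambda_grid or any(not 1e-4 <= lam <= 100.0 for lam in lambda_grid):
        raise ValueError("lambda_grid must lie within [1e-4, 100]")
    base = spec or ModelSpec(model_type="linear_l1")
    best = None
    val_mses = {}
    for lam in lambda_grid:
        s = dc_replace(base, l1_lambda=lam)
        model = LinearL1Model(s, train.x_tab.shape[1]).fit(train, val)
        v = model.evaluate_mse(val)
        val_mses[lam] = v
        if best is None or v < best[1]:
            best = (model, v, lam)
    return best[0], best[2], val_mses


def predict_curves(model, data: ModelData) -> np.ndarray:
    """Model-agnostic predict contract: one non-negative 100-value curve/step."""
    return model.predict(data)
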