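"""Shank-angle regression from thigh motion with an LSTM network.

The regressor maps a four-component input per frame — left/right thigh
angle and angular speed — to the angles of both shanks.  A single hidden
layer of LSTM cells implements the standard gate equations

    f_t = sigmoid(W_f [v_t, h_{t-1}] + b_f)        forget gate
    i_t = sigmoid(W_i [v_t, h_{t-1}] + b_i)        input gate
    g_t = tanh   (W_g [v_t, h_{t-1}] + b_g)        input modulation
    c_t = f_t * c_{t-1} + i_t * g_t                long-term state
    o_t = sigmoid(W_o [v_t, h_{t-1}] + b_o)        output gate
    h_t = o_t * tanh(c_t)                          hidden state
    y_t = tanh(W_y h_t + b_y)                      emission

Training minimizes the squared error between y_t and the scaled true shank
angles over non-overlapping fixed-length chunks, by backpropagation through
time with the Adam update rule.  Prediction is strictly causal: one output
per input frame, hidden state carried across calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_HIDDEN = 50
DEFAULT_CHUNK = 15


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LstmParams:
    """All weights of the cell, per gate, acting on [v_t, h_{t-1}]."""

    W_f: np.ndarray  # (H, D+H)
    W_i: np.ndarray
    W_g: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray  # (H,)
    b_i: np.ndarray
    b_g: np.ndarray
    b_o: np.ndarray
    W_y: np.ndarray  # (O, H)
    b_y: np.ndarray  # (O,)

    def __post_init__(self) -> None:
        H, DH = self.W_f.shape
        O = self.W_y.shape[0]
        for name in ("W_i", "W_g", "W_o"):
            if getattr(self, name).shape != (H, DH):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_f", "b_i", "b_g", "b_o"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} shape mismatch")
        if self.W_y.shape != (O, H) or self.b_y.shape != (O,):
            raise ValueError("output map shape mismatch")
        for name in ("W_f", "W_i", "W_g", "W_o", "b_f", "b_i", "b_g", "b_o", "W_y", "b_y"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1] - self.hidden_size

    @property
    def output_dim(self) -> int:
        return self.W_y.shape[0]


def init_params(
    input_dim: int, hidden_size: int, output_dim: int, rng: np.random.Generator
) -> LstmParams:
    """Small uniform initialization; forget bias starts at 1 (a common
    choice that keeps the long-term state open early in training)."""
    DH = input_dim + hidden_size
    scale = 1.0 / np.sqrt(DH)

    def w(shape):
        return rng.uniform(-scale, scale, size=shape)

    return LstmParams(
        W_f=w((hidden_size, DH)),
        W_i=w((hidden_size, DH)),
        W_g=w((hidden_size, DH)),
        W_o=w((hidden_size, DH)),
        b_f=np.ones(hidden_size),
        b_i=np.zeros(hidden_size),
        b_g=np.zeros(hidden_size),
        b_o=np.zeros(hidden_size),
        W_y=rng.uniform(-1.0 / np.sqrt(hidden_size), 1.0 / np.sqrt(hidden_size),
                        size=(output_dim, hidden_size)),
        b_y=np.zeros(output_dim),
    )


def lstm_cell_step(
    params: LstmParams, x: np.ndarray, h: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One evaluation of the cell equations; returns (h_next, c_next, y)."""
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != (params.input_dim,) or h.shape != (params.hidden_size,):
        raise ValueError("input/hidden dimension mismatch")
    vh = np.concatenate([x, h])
    f = _sigmoid(params.W_f @ vh + params.b_f)
    i = _sigmoid(params.W_i @ vh + params.b_i)
    g = np.tanh(params.W_g @ vh + params.b_g)
    c_next = f * c + i * g
    o = _sigmoid(params.W_o @ vh + params.b_o)
    h_next = o * np.tanh(c_next)
    y = np.tanh(params.W_y @ h_next + params.b_y)
    return h_next, c_next, y


# ---------------------------------------------------------------------------
# Packed batched forward/backward used for training.  Gate order: f, i, g, o.


def _pack(params: LstmParams) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    D, H = params.input_dim, params.hidden_size
    W = np.concatenate([params.W_f, params.W_i, params.W_g, params.W_o], axis=0)  # (4H, D+H)
    Wx = W[:, :D].T.copy()  # (D, 4H)
    Wh = W[:, D:].T.copy()  # (H, 4H)
    b = np.concatenate([params.b_f, params.b_i, params.b_g, params.b_o])
    return Wx, Wh, b, W


def _unpack(Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray, Wy: np.ndarray,
            by: np.ndarray) -> LstmParams:
    H = Wh.shape[0]
    W = np.concatenate([Wx, Wh], axis=0).T  # (4H, D+H)
    return LstmParams(
        W_f=W[:H].copy(), W_i=W[H:2 * H].copy(), W_g=W[2 * H:3 * H].copy(), W_o=W[3 * H:].copy(),
        b_f=b[:H].copy(), b_i=b[H:2 * H].copy(), b_g=b[2 * H:3 * H].copy(), b_o=b[3 * H:].copy(),
        W_y=Wy.copy(), b_y=by.copy(),
    )


def _forward_batch(theta: dict, X: np.ndarray):
    """Forward pass over chunks X (B, T, D) from zero initial state."""
    Wx, Wh, b, Wy, by = theta["Wx"], theta["Wh"], theta["b"], theta["Wy"], theta["by"]
    B, T, D = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = {"X": X, "f": [], "i": [], "g": [], "o": [], "c": [], "tc": [], "h_prev": [],
             "c_prev": [], "h": [], "y": []}
    for t in range(T):
        z = X[:, t] @ Wx + h @ Wh + b
        f = _sigmoid(z[:, :H])
        i = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        cache["h_prev"].append(h)
        cache["c_prev"].append(c)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        y = np.tanh(h @ Wy.T + by)
        for key, val in (("f", f), ("i", i), ("g", g), ("o", o), ("c", c), ("tc", tc),
                         ("h", h), ("y", y)):
            cache[key].append(val)
    Y = np.stack(cache["y"], axis=1)  # (B, T, O)
    return Y, cache


def _backward_batch(theta: dict, cache: dict, dY: np.ndarray):
    """Gradients of a scalar loss wrt packed parameters, given dL/dY."""
    Wx, Wh, Wy = theta["Wx"], theta["Wh"], theta["Wy"]
    X = cache["X"]
    B, T, D = X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros_like(theta["b"])
    dWy = np.zeros_like(Wy)
    dby = np.zeros_like(theta["by"])
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        y = cache["y"][t]
        dpy = dY[:, t] * (1.0 - y**2)
        dWy += dpy.T @ cache["h"][t]
        dby += dpy.sum(axis=0)
        dh = dh + dpy @ Wy
        o, tc, f, i, g = (cache[k][t] for k in ("o", "tc", "f", "i", "g"))
        c_prev, h_prev = cache["c_prev"][t], cache["h_prev"][t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dz = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), dg * (1.0 - g**2), do * o * (1 - o)], axis=1
        )
        dWx += X[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
        dc = dc * f
    return {"Wx": dWx, "Wh": dWh, "b": db, "Wy": dWy, "by": dby}


@dataclass
class _LinearScale:
    """Invertible per-output linear map degrees <-> (-1, 1)."""

    center: np.ndarray
    half_range: np.ndarray

    def to_scaled(self, y: np.ndarray) -> np.ndarray:
        return (y - self.center) / self.half_range

    def to_degrees(self, s: np.ndarray) -> np.ndarray:
        return s * self.half_range + self.center


class GaitLstmRegressor(BaseEstimator, RegressorMixin):
    """LSTM regressor from thigh features (degrees) to shank angles (degrees).

    Parameters
    ----------
    hidden_size : LSTM units in the single hidden layer.
    chunk_length : training segment length in frames; sequences are cut
        into non-overlapping chunks with the state reset per chunk.
    learning_rate, max_epochs, patience, batch_size : Adam optimization
        settings; early stopping watches one held-out training participant
        (the last group) when groups are supplied.
    scale_margin : fractional widening of the training target range before
        mapping to (-1, 1), so the tanh output can reach observed extremes.
    """

    def __init__(
        self,
        hidden_size: int = DEFAULT_HIDDEN,
        chunk_length: int = DEFAULT_CHUNK,
        learning_rate: float = 3e-3,
        max_epochs: int = 300,
        patience: int = 25,
        batch_size: int = 64,
        scale_margin: float = 0.1,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.chunk_length = chunk_length
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.scale_margin = scale_margin
        self.random_state = random_state

    # -- data plumbing ------------------------------------------------------

    def _chunk(self, X: np.ndarray, y: np.ndarray, lengths) -> tuple[np.ndarray, np.ndarray]:
        L = self.chunk_length
        xs, ys = [], []
        start = 0
        for n in lengths:
            for s in range(start, start + n - L + 1, L):
                xs.append(X[s : s + L])
                ys.append(y[s : s + L])
            start += n
        if not xs:
            raise ValueError(f"no sequence of length >= chunk_length={L}")
        return np.stack(xs), np.stack(ys)

    def fit(self, X, y, lengths=None, groups=None):
        """Fit on concatenated sequences.

        ``lengths`` gives per-sequence frame counts (one sequence assumed
        if omitted); ``groups`` gives a participant id per sequence, the
        last distinct one being held out for early stopping.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if lengths is None:
            lengths = [len(X)]
        lengths = list(map(int, lengths))
        self.n_features_in_ = X.shape[1]
        out_dim = y.shape[1]

        # feature min-max -> [0, 1]; target linear map -> (-1, 1) with margin
        self.x_bounds_ = np.stack([X.min(axis=0), X.max(axis=0)])
        span = np.where(self.x_bounds_[1] > self.x_bounds_[0],
                        self.x_bounds_[1] - self.x_bounds_[0], 1.0)
        Xs = (X - self.x_bounds_[0]) / span
        lo, hi = y.min(axis=0), y.max(axis=0)
        half = (hi - lo) / 2.0 * (1.0 + self.scale_margin)
        half = np.where(half > 0, half, 1.0)
        self.y_scale_ = _LinearScale(center=(lo + hi) / 2.0, half_range=half)
        ys = self.y_scale_.to_scaled(y)

        # split off the validation participant (last group) if possible
        if groups is not None:
            groups = list(groups)
            if len(groups) != len(lengths):
                raise ValueError("groups must give one id per sequence")
            val_group = sorted(set(groups))[-1] if len(set(groups)) > 1 else None
        else:
            groups, val_group = [None] * len(lengths), None
        tr_x, tr_y, va_x, va_y = [], [], [], []
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        tr_lengths, va_lengths = [], []
        for k, g in enumerate(groups):
            seg = slice(offsets[k], offsets[k + 1])
            target = (va_x, va_y, va_lengths) if g == val_group and val_group is not None \
                else (tr_x, tr_y, tr_lengths)
            target[0].append(Xs[seg])
            target[1].append(ys[seg])
            target[2].append(lengths[k])
        Xtr = np.concatenate(tr_x)
        ytr = np.concatenate(tr_y)
        cx, cy = self._chunk(Xtr, ytr, tr_lengths)
        if va_x:
            vx, vy = self._chunk(np.concatenate(va_x), np.concatenate(va_y), va_lengths)
        else:
            vx, vy = cx, cy

        rng = np.random.default_rng(self.random_state)
        params = init_params(self.n_features_in_, self.hidden_size, out_dim, rng)
        Wx, Wh, b, _ = _pack(params)
        theta = {"Wx": Wx, "Wh": Wh, "b": b, "Wy": params.W_y.copy(), "by": params.b_y.copy()}
        m = {k: np.zeros_like(v) for k, v in theta.items()}
        v_adam = {k: np.zeros_like(v) for k, v in theta.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        self.loss_trace_ = []
        self.val_trace_ = []
        best_val = np.inf
        best_theta = {k: v.copy() for k, v in theta.items()}
        bad_epochs = 0
        n_chunks = len(cx)
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n_chunks)
            epoch_loss = 0.0
            for s in range(0, n_chunks, self.batch_size):
                idx = order[s : s + self.batch_size]
                Xb, yb = cx[idx], cy[idx]
                Y, cache = _forward_batch(theta, Xb)
                err = Y - yb
                loss = float(np.mean(err**2))
                dY = 2.0 * err / err.size
                grads = _backward_batch(theta, cache, dY)
                step += 1
                for k in theta:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v_adam[k] / (1 - beta2**step)
                    theta[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                epoch_loss += loss * len(idx)
            self.loss_trace_.append(epoch_loss / n_chunks)
            Yv, _ = _forward_batch(theta, vx)
            val_loss = float(np.mean((Yv - vy) ** 2))
            self.val_trace_.append(val_loss)
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_theta = {k: v.copy() for k, v in theta.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        self.params_ = _unpack(best_theta["Wx"], best_theta["Wh"], best_theta["b"],
                               best_theta["Wy"], best_theta["by"])
        self.reset_state()
        return self

    # -- prediction ---------------------------------------------------------

    def reset_state(self) -> None:
        """Zero the carried hidden and long-term state."""
        H = self.params_.hidden_size
        self._h = np.zeros(H)
        self._c = np.zeros(H)

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.x_bounds_
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.asarray(X, dtype=float) - lo) / span

    def predict(self, X, degrees: bool = True) -> np.ndarray:
        """Causal frame-by-frame prediction; state carries across calls.

        Feeding a sequence whole or frame-by-frame yields identical
        outputs.  Call :meth:`reset_state` between independent streams.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = self._scale_x(X)
        out = np.empty((len(X), self.params_.output_dim))
        for t in range(len(X)):
            self._h, self._c, y = lstm_cell_step(self.params_, Xs[t], self._h, self._c)
            out[t] = y
        return self.y_scale_.to_degrees(out) if degrees else out


def predict_stream(model: GaitLstmRegressor, frames: np.ndarray) -> np.ndarray:
    """Streaming prediction of both shank angles in degrees."""
    return model.predict(frames)


def train_gait_model(series_list, config: dict | None = None, seed: int = 0) -> GaitLstmRegressor:
    """Fit a gait model from per-participant :class:`~gain.features.AngularSeries`.

    ``series_list`` is a list of ``(participant_id, AngularSeries)`` pairs;
    inputs are the four thigh features, targets the two shank angles.
    """
    config = dict(config or {})
    X, y, lengths, groups = [], [], [], []
    for pid, ang in series_list:
        X.append(np.column_stack([ang.theta_L, ang.theta_R, ang.omega_TL, ang.omega_TR]))
        y.append(np.column_stack([ang.phi_L, ang.phi_R]))
        lengths.append(len(ang))
        groups.append(pid)
    model = GaitLstmRegressor(random_state=seed, **config)
    model.fit(np.concatenate(X), np.concatenate(y), lengths=lengths, groups=groups)
    return model


# -- serialization ----------------------------------------------------------


def save_gait_model(model: GaitLstmRegressor, path: str | Path) -> None:
    p = model.params_
    payload = {
        "hyperparams": model.get_params(),
        "x_bounds": model.x_bounds_.tolist(),
        "y_center": model.y_scale_.center.tolist(),
        "y_half_range": model.y_scale_.half_range.tolist(),
        "n_features_in": model.n_features_in_,
        "weights": {
            name: getattr(p, name).tolist()
            for name in ("W_f", "W_i", "W_g", "W_o", "b_f", "b_i", "b_g", "b_o", "W_y", "b_y")
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_gait_model(path: str | Path) -> GaitLstmRegressor:
    payload = json.loads(Path(path).read_text())
    model = GaitLstmRegressor(**payload["hyperparams"])
    model.params_ = LstmParams(
        **{name: np.array(w) for name, w in payload["weights"].items()}
    )
    model.x_bounds_ = np.array(payload["x_bounds"])
    model.y_scale_ = _LinearScale(
        center=np.array(payload["y_center"]), half_range=np.array(payload["y_half_range"])
    )
    model.n_features_in_ = int(payload["n_features_in"])
    model.reset_state()
    return model
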