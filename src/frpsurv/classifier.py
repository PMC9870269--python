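"""Sequence classifiers for fuzzy recurrence plots.

An M x M FRP is read as a time series: row i is the vector of M feature
values at time step i.  A bidirectional LSTM consumes the sequence in both
directions, the final hidden states of the two directions are concatenated
and mapped through a fully-connected layer with softmax to two class
scores (<5-year vs >5-year survival).

The LSTM cell follows the standard gating:

    u_t = sigmoid(i_u z_t + r_u h_{t-1} + b_u)     input gate
    f_t = sigmoid(i_f z_t + r_f h_{t-1} + b_f)     forget gate
    w_t = tanh   (i_w z_t + r_w h_{t-1} + b_w)     cell candidate
    e_t = sigmoid(i_e z_t + r_e h_{t-1} + b_e)     output gate
    c_t = f_t o c_{t-1} + u_t o w_t
    h_t = e_t o tanh(c_t)

``lstm_cell_step`` is a deliberately plain, per-gate reference of this
arithmetic; the trainer uses an independent vectorised implementation with
analytic backpropagation through time, and the two are pinned against each
other (and against finite differences) in the test suite.

Training uses Adam with the configured learning rate, gradient clipping by
global L2 norm at the configured threshold, and full-batch updates when the
configured batch size exceeds the training-set size.

A linear SVM over raw feature vectors (deep or GLCM) is provided as the
baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrainConfig",
    "LSTMCellWeights",
    "LSTMState",
    "lstm_cell_step",
    "BiLSTMClassifier",
    "train_lstm",
    "predict_lstm",
    "train_svm",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class TrainConfig:
    """LSTM training hyperparameters.

    Pipeline defaults: at most 300 epochs,
    batch size 150 (clamped to the training-set size, i.e. full-batch for
    small cohorts), learning rate 0.01, gradient threshold 1, bidirectional
    processing.  Hidden size 100 is a package default.  ``loss_tol`` stops
    training early once the mean cross-entropy falls below it.
    """

    max_epochs: int = 300
    batch_size: int = 150
    learning_rate: float = 0.01
    gradient_threshold: float = 1.0
    bidirectional: bool = True
    hidden_size: int = 100
    seed: int = 0
    loss_tol: float = 1e-3
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        for name in ("max_epochs", "batch_size", "hidden_size"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("learning_rate", "gradient_threshold", "loss_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LSTMCellWeights:
    """One LSTM cell's parameters, gates stacked in order (u, f, w, e).

    ``input_weights`` is (4H, D), ``recurrent_weights`` (4H, H), ``biases``
    (4H,).  Per-gate blocks are exposed as ``i_u``/``r_u``/``b_u`` etc.
    """

    input_weights: np.ndarray
    recurrent_weights: np.ndarray
    biases: np.ndarray
    hidden_size: int

    def __post_init__(self) -> None:
        H = self.hidden_size
        self.input_weights = np.atleast_2d(np.asarray(self.input_weights, dtype=float))
        self.recurrent_weights = np.atleast_2d(np.asarray(self.recurrent_weights, dtype=float))
        self.biases = np.asarray(self.biases, dtype=float).ravel()
        if self.input_weights.shape[0] != 4 * H:
            raise ValueError("input_weights must have 4*hidden_size rows")
        if self.recurrent_weights.shape != (4 * H, H):
            raise ValueError("recurrent_weights must be (4*hidden_size, hidden_size)")
        if self.biases.shape != (4 * H,):
            raise ValueError("biases must have length 4*hidden_size")

    def _block(self, which: np.ndarray, g: int) -> np.ndarray:
        H = self.hidden_size
        return which[g * H:(g + 1) * H]

    @property
    def i_u(self): return self._block(self.input_weights, 0)
    @property
    def i_f(self): return self._block(self.input_weights, 1)
    @property
    def i_w(self): return self._block(self.input_weights, 2)
    @property
    def i_e(self): return self._block(self.input_weights, 3)
    @property
    def r_u(self): return self._block(self.recurrent_weights, 0)
    @property
    def r_f(self): return self._block(self.recurrent_weights, 1)
    @property
    def r_w(self): return self._block(self.recurrent_weights, 2)
    @property
    def r_e(self): return self._block(self.recurrent_weights, 3)
    @property
    def b_u(self): return self._block(self.biases, 0)
    @property
    def b_f(self): return self._block(self.biases, 1)
    @property
    def b_w(self): return self._block(self.biases, 2)
    @property
    def b_e(self): return self._block(self.biases, 3)


@dataclass
class LSTMState:
    """Hidden state h and cell state c of one LSTM cell."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.h.shape != self.c.shape:
            raise ValueError("h and c must have the same length")
        if not (np.isfinite(self.h).all() and np.isfinite(self.c).all()):
            raise ValueError("non-finite LSTM state")


def lstm_cell_step(weights: LSTMCellWeights, z_t, prev: LSTMState) -> LSTMState:
    """One LSTM time step, written gate by gate (reference implementation)."""
    z = np.asarray(z_t, dtype=float).ravel()
    if weights.input_weights.shape[1] != z.size:
        raise ValueError(
            f"input dimension mismatch: weights expect {weights.input_weights.shape[1]}, "
            f"got {z.size}"
        )
    if prev.h.size != weights.hidden_size:
        raise ValueError("state size does not match hidden_size")
    u = _sigmoid(weights.i_u @ z + weights.r_u @ prev.h + weights.b_u)
    f = _sigmoid(weights.i_f @ z + weights.r_f @ prev.h + weights.b_f)
    w = np.tanh(weights.i_w @ z + weights.r_w @ prev.h + weights.b_w)
    e = _sigmoid(weights.i_e @ z + weights.r_e @ prev.h + weights.b_e)
    c_t = f * prev.c + u * w
    h_t = e * np.tanh(c_t)
    return LSTMState(h=h_t, c=c_t)


# ---------------------------------------------------------------------------
# vectorised bidirectional LSTM trainer
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_direction(rng, D: int, H: int) -> dict[str, np.ndarray]:
    b = np.zeros(4 * H)
    b[H:2 * H] = 1.0  # forget-gate bias 1: remember by default
    return {
        "Wi": _glorot(rng, (4 * H, D)),
        "Wr": _glorot(rng, (4 * H, H)),
        "b": b,
    }


def _lstm_forward(params, X):
    """Run one direction over X (B, T, D); returns last hidden state + caches."""
    B, T, D = X.shape
    H = params["Wr"].shape[1]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    for t in range(T):
        x_t = X[:, t, :]
        A = x_t @ params["Wi"].T + h @ params["Wr"].T + params["b"]
        U = _sigmoid(A[:, :H])
        F = _sigmoid(A[:, H:2 * H])
        W = np.tanh(A[:, 2 * H:3 * H])
        E = _sigmoid(A[:, 3 * H:])
        c_new = F * c + U * W
        tc = np.tanh(c_new)
        h_new = E * tc
        caches.append((x_t, h, c, U, F, W, E, tc))
        h, c = h_new, c_new
    return h, caches


def _lstm_backward(params, caches, dh_last):
    """BPTT for one direction given the gradient at the last hidden state."""
    H = params["Wr"].shape[1]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for t in range(len(caches) - 1, -1, -1):
        x_t, h_prev, c_prev, U, F, W, E, tc = caches[t]
        dE = dh * tc
        dc = dc + dh * E * (1.0 - tc * tc)
        dU = dc * W
        dW = dc * U
        dF = dc * c_prev
        dc = dc * F
        dA = np.concatenate([
            dU * U * (1.0 - U),
            dF * F * (1.0 - F),
            dW * (1.0 - W * W),
            dE * E * (1.0 - E),
        ], axis=1)
        grads["Wi"] += dA.T @ x_t
        grads["Wr"] += dA.T @ h_prev
        grads["b"] += dA.sum(axis=0)
        dh = dA @ params["Wr"]
    return grads


class BiLSTMClassifier:
    """Bidirectional LSTM -> fully-connected(2) -> softmax classifier.

    Input examples are M x M FRP matrices read as M time steps of M
    features.  ``fit`` returns self; ``predict_scores`` yields softmax
    scores per example (column 1 = positive class, the >5-year label);
    exact 0.5/0.5 ties resolve to the positive class.
    """

    POSITIVE = 1

    def __init__(self, config: TrainConfig = TrainConfig()):
        self.config = config
        self.params_: dict | None = None
        self.loss_history_: list[float] = []
        self.M_: int | None = None

    # -- internals ---------------------------------------------------------
    def _init_params(self, D: int) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden_size
        n_dir = 2 if cfg.bidirectional else 1
        params = {"fwd": _init_direction(rng, D, H)}
        if cfg.bidirectional:
            params["bwd"] = _init_direction(rng, D, H)
        params["fc"] = {
            "W": _glorot(rng, (2, n_dir * H)),
            "b": np.zeros(2),
        }
        return params

    def _forward(self, X, with_caches=False):
        p = self.params_
        h_f, caches_f = _lstm_forward(p["fwd"], X)
        if self.config.bidirectional:
            h_b, caches_b = _lstm_forward(p["bwd"], X[:, ::-1, :])
            h_cat = np.concatenate([h_f, h_b], axis=1)
        else:
            h_b, caches_b = None, None
            h_cat = h_f
        logits = h_cat @ p["fc"]["W"].T + p["fc"]["b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        if with_caches:
            return probs, h_cat, caches_f, caches_b
        return probs

    def _loss_and_grads(self, X, Y, sample_weight):
        p = self.params_
        B = X.shape[0]
        probs, h_cat, caches_f, caches_b = self._forward(X, with_caches=True)
        eps = 1e-12
        loss = float(-(sample_weight * np.log(probs[np.arange(B), Y] + eps)).sum()
                     / sample_weight.sum())
        dlogits = probs.copy()
        dlogits[np.arange(B), Y] -= 1.0
        dlogits *= (sample_weight / sample_weight.sum())[:, None]
        grads = {"fc": {
            "W": dlogits.T @ h_cat,
            "b": dlogits.sum(axis=0),
        }}
        dh_cat = dlogits @ p["fc"]["W"]
        H = self.config.hidden_size
        grads["fwd"] = _lstm_backward(p["fwd"], caches_f, dh_cat[:, :H])
        if self.config.bidirectional:
            grads["bwd"] = _lstm_backward(p["bwd"], caches_b, dh_cat[:, H:])
        return loss, grads

    @staticmethod
    def _flatten(tree):
        out = []
        for key in sorted(tree):
            sub = tree[key]
            for name in sorted(sub):
                out.append((f"{key}.{name}", sub[name]))
        return out

    def _clip(self, grads):
        """Global L2-norm gradient clipping at the configured threshold."""
        arrs = [a for _, a in self._flatten(grads)]
        norm = np.sqrt(sum(float((a * a).sum()) for a in arrs))
        thr = self.config.gradient_threshold
        if norm > thr:
            scale = thr / norm
            for a in arrs:
                a *= scale
        return grads

    # -- public API --------------------------------------------------------
    def fit(self, frps, labels) -> "BiLSTMClassifier":
        X, y = _stack_frps(frps, labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.M_ = X.shape[1]
        cfg = self.config
        self.params_ = self._init_params(X.shape[2])
        B_total = X.shape[0]
        batch = min(cfg.batch_size, B_total)

        if cfg.class_weight == "balanced":
            counts = np.bincount(y, minlength=2)
            w_class = B_total / (2.0 * counts)
            weights = w_class[y]
        else:
            weights = np.ones(B_total)

        flat = self._flatten(self.params_)
        mom = {k: np.zeros_like(v) for k, v in flat}
        vel = {k: np.zeros_like(v) for k, v in flat}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        rng = np.random.default_rng(cfg.seed + 1)
        self.loss_history_ = []
        for _epoch in range(cfg.max_epochs):
            if batch < B_total:
                order = rng.permutation(B_total)
            else:
                order = np.arange(B_total)
            epoch_loss = 0.0
            n_seen = 0
            for start in range(0, B_total, batch):
                idx = order[start:start + batch]
                loss, grads = self._loss_and_grads(X[idx], y[idx], weights[idx])
                grads = self._clip(grads)
                step += 1
                for (key, param), (_, grad) in zip(self._flatten(self.params_),
                                                   self._flatten(grads)):
                    mom[key] = beta1 * mom[key] + (1 - beta1) * grad
                    vel[key] = beta2 * vel[key] + (1 - beta2) * grad * grad
                    m_hat = mom[key] / (1 - beta1 ** step)
                    v_hat = vel[key] / (1 - beta2 ** step)
                    param -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                epoch_loss += loss * len(idx)
                n_seen += len(idx)
            epoch_loss /= n_seen
            self.loss_history_.append(epoch_loss)
            if epoch_loss < cfg.loss_tol:
                break
        return self

    def predict_scores(self, frps) -> np.ndarray:
        """Softmax class scores, shape (n, 2); columns (negative, positive)."""
        if self.params_ is None:
            raise RuntimeError("model is not trained")
        X, _ = _stack_frps(frps, None)
        if X.shape[1] != self.M_:
            raise ValueError(f"FRP size {X.shape[1]} != training size {self.M_}")
        return self._forward(X)

    def predict(self, frps) -> np.ndarray:
        """Predicted labels; an exact tie goes to the positive (>5-year) class."""
        scores = self.predict_scores(frps)
        return (scores[:, self.POSITIVE] >= scores[:, 1 - self.POSITIVE]).astype(int)


def _stack_frps(frps, labels):
    """Stack FRPMatrix objects / arrays into (n, M, M); validate labels."""
    from .frp import FRPMatrix

    mats = []
    for f in frps:
        arr = f.values if isinstance(f, FRPMatrix) else np.asarray(f, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"FRP must be square, got shape {arr.shape}")
        mats.append(arr)
    if not mats:
        raise ValueError("no examples")
    M = mats[0].shape[0]
    if any(m.shape[0] != M for m in mats):
        raise ValueError("all FRPs must share the same size M")
    X = np.stack(mats)
    if labels is None:
        return X, None
    y = np.asarray(labels).astype(int).ravel()
    if y.size != X.shape[0]:
        raise ValueError("labels length does not match number of examples")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return X, y


def train_lstm(frps, labels, config: TrainConfig = TrainConfig()) -> BiLSTMClassifier:
    """Train a (bidirectional) LSTM classifier on FRPs; returns the model."""
    return BiLSTMClassifier(config).fit(frps, labels)


def predict_lstm(model: BiLSTMClassifier, frps):
    """Class scores and hard labels for a trained model."""
    scores = model.predict_scores(frps)
    labels = model.predict(frps)
    return scores, labels


# ---------------------------------------------------------------------------
# linear SVM baseline
# ---------------------------------------------------------------------------

def _stack_features(features) -> np.ndarray:
    rows = []
    for f in features:
        values = getattr(f, "values", f)
        rows.append(np.asarray(values, dtype=float).ravel())
    X = np.stack(rows)
    return X


def train_svm(features, labels, seed: int = 0):
    """Linear-kernel SVM over standardized feature vectors.

    Accepts FeatureVector/GLCMFeatures objects or plain arrays.  Returns a
    fitted sklearn pipeline (StandardScaler + linear SVC) exposing
    ``predict`` / ``decision_function``.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = _stack_features(features)
    y = np.asarray(labels).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = make_pipeline(StandardScaler(), SVC(kernel="linear", random_state=seed))
    model.fit(X, y)
    return model
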