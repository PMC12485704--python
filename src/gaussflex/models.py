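"""Model architectures for flexibility prediction from 30-component GI vectors.

Four families, mirroring the study design: a 1-D CNN with additive attention
pooling (the primary model), the same CNN with mean pooling, a gated
recurrent network that reads the 30 components as a sequence of scalars, and
an RBF-kernel SVM baseline.  Each supports a classification head (sigmoid
probability) and a regression head (identity).

The CNN treats a descriptor vector as a single-channel series of length 30:
four convolution blocks (kernel 3, padding 1, stride 1, ReLU) map
1 -> 32 -> 64 -> 64 -> 128 channels while preserving the positional axis,
an additive attention layer scores each of the 30 positions from its 128-dim
feature (tanh projection then scalar score, plus a learned per-position bias
that breaks the convolution stack's translation symmetry, softmax over
positions), and the attention-weighted sum yields a single 128-dimensional
vector which a dense layer maps to one logit.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.svm import SVC, SVR

from .autodiff import Adam, Tensor, conv1d
from .errors import CapabilityError, ParameterError, ShapeError

N_FEATURES = 30

ARCHITECTURES = ("cnn_attention", "cnn", "rnn", "svm_rbf")
TASKS = ("classification", "regression")


@dataclass
class ModelSpec:
    """Hyperparameters of one model instance."""

    architecture: str = "cnn_attention"
    task: str = "classification"
    conv_channels: tuple = (32, 64, 64, 128)
    kernel_size: int = 3
    padding: int = 1
    attention_dim: int = 64
    rnn_hidden: int = 64
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ParameterError(f"unknown architecture {self.architecture!r}")
        if self.task not in TASKS:
            raise ParameterError(f"unknown task {self.task!r}")
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        if len(self.conv_channels) != 4 or self.conv_channels[-1] != 128:
            raise ParameterError("conv_channels must be 4 widths ending at 128")
        if self.kernel_size != 3 or self.padding != 1:
            raise ParameterError("kernel_size=3 and padding=1 are fixed")
        if self.attention_dim < 1 or self.rnn_hidden < 1:
            raise ParameterError("attention_dim and rnn_hidden must be >= 1")


@dataclass
class PredictionBatch:
    """Scores (probabilities or regression values) plus optional attention weights."""

    scores: np.ndarray
    attention: np.ndarray | None = None


def _check_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ShapeError(f"features must be (n, {N_FEATURES}), got {X.shape}")
    return X


def _uniform(rng, fan_in, *shape):
    k = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)


class _NeuralModel:
    """Shared machinery: parameters, forward, predict, (de)serialization."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.params: list[Tensor] = []
        self._build(np.random.default_rng(spec.seed))

    def _build(self, rng):
        raise NotImplementedError

    def _register(self, tensor: Tensor) -> Tensor:
        self.params.append(tensor)
        return tensor

    # -- interface used by training and evaluation ------------------------

    def forward(self, x: Tensor) -> Tensor:
        """Raw head output (logit for classification, value for regression)."""
        raise NotImplementedError

    def output(self, x: Tensor) -> Tensor:
        """Task-scaled output: sigmoid probability or identity."""
        out = self.forward(x)
        return out.sigmoid() if self.spec.task == "classification" else out

    def predict(self, X) -> PredictionBatch:
        X = _check_features(X)
        out = self.output(Tensor(X)).data.ravel()
        if self.spec.task == "classification":
            out = np.clip(out, 1e-12, 1.0 - 1e-12)
        att = self.attention_weights(X) if hasattr(self, "_attention") else None
        return PredictionBatch(scores=out, attention=att)

    def attention_weights(self, X) -> np.ndarray:
        raise CapabilityError(
            f"{self.spec.architecture} has no attention mechanism"
        )

    def state_arrays(self) -> list:
        return [p.data.copy() for p in self.params]

    def load_state_arrays(self, arrays):
        if len(arrays) != len(self.params):
            raise ParameterError("checkpoint parameter count mismatch")
        for p, a in zip(self.params, arrays):
            if p.data.shape != a.shape:
                raise ParameterError("checkpoint parameter shape mismatch")
            p.data = a.copy()

    def make_optimizer(self, lr: float, weight_decay: float) -> Adam:
        return Adam(self.params, lr=lr, weight_decay=weight_decay)


class _ConvBackbone(_NeuralModel):
    def _build_conv(self, rng):
        chans = (1,) + self.spec.conv_channels
        K = self.spec.kernel_size
        self.conv_w, self.conv_b = [], []
        for cin, cout in zip(chans[:-1], chans[1:]):
            self.conv_w.append(self._register(_uniform(rng, cin * K, cout, cin, K)))
            self.conv_b.append(self._register(_uniform(rng, cin * K, cout)))

    def _features(self, x: Tensor) -> Tensor:
        """(B, 30) -> (B, 30, C_final); positional axis preserved by pad 1."""
        h = x.reshape(x.shape[0], 1, N_FEATURES)
        for w, b in zip(self.conv_w, self.conv_b):
            h = conv1d(h, w, b, padding=self.spec.padding).relu()
        return h.swapaxes(1, 2)


class AttentionCNN(_ConvBackbone):
    """1-D CNN with additive attention pooling over the 30 positions."""

    _attention = True

    def _build(self, rng):
        self._build_conv(rng)
        C = self.spec.conv_channels[-1]
        A = self.spec.attention_dim
        self.att_w = self._register(_uniform(rng, C, C, A))
        self.att_b = self._register(_uniform(rng, C, A))
        self.att_v = self._register(_uniform(rng, A, A, 1))
        # learned per-position score bias: breaks the translation symmetry of
        # the convolution stack so attention can prefer specific positions
        self.att_pos = self._register(Tensor(np.zeros(N_FEATURES), requires_grad=True))
        self.fc_w = self._register(_uniform(rng, C, C, 1))
        self.fc_b = self._register(_uniform(rng, C, 1))

    def _attention_alpha(self, feat: Tensor) -> Tensor:
        scores = ((feat @ self.att_w + self.att_b).tanh() @ self.att_v)
        scores = scores.reshape(feat.shape[0], N_FEATURES) + self.att_pos
        return scores.softmax(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        feat = self._features(x)                       # (B, 30, C)
        alpha = self._attention_alpha(feat)            # (B, 30)
        pooled = (feat * alpha.reshape(alpha.shape[0], N_FEATURES, 1)).sum(axis=1)
        return (pooled @ self.fc_w + self.fc_b).reshape(x.shape[0])

    def attention_weights(self, X) -> np.ndarray:
        X = _check_features(X)
        return self._attention_alpha(self._features(Tensor(X))).data


class PlainCNN(_ConvBackbone):
    """Same convolutional stack with mean pooling instead of attention."""

    def _build(self, rng):
        self._build_conv(rng)
        C = self.spec.conv_channels[-1]
        self.fc_w = self._register(_uniform(rng, C, C, 1))
        self.fc_b = self._register(_uniform(rng, C, 1))

    def forward(self, x: Tensor) -> Tensor:
        pooled = self._features(x).mean(axis=1)
        return (pooled @ self.fc_w + self.fc_b).reshape(x.shape[0])


class GRUNet(_NeuralModel):
    """Single-layer gated recurrent network over the 30 positions (1 feature each)."""

    def _build(self, rng):
        H = self.spec.rnn_hidden
        def mk(fan, *shape):
            return self._register(_uniform(rng, fan, *shape))
        self.w_z, self.u_z, self.b_z = mk(H, 1, H), mk(H, H, H), mk(H, H)
        # bias the update gate toward carrying state so early positions
        # survive the 30-step read (memory-friendly gate initialization)
        self.b_z.data = self.b_z.data - 1.0
        self.w_r, self.u_r, self.b_r = mk(H, 1, H), mk(H, H, H), mk(H, H)
        self.w_h, self.u_h, self.b_h = mk(H, 1, H), mk(H, H, H), mk(H, H)
        self.fc_w = mk(H, H, 1)
        self.fc_b = mk(H, 1)

    def forward(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        h = Tensor(np.zeros((B, self.spec.rnn_hidden)))
        for t in range(N_FEATURES):
            xt = x[:, t].reshape(B, 1)
            z = (xt @ self.w_z + h @ self.u_z + self.b_z).sigmoid()
            r = (xt @ self.w_r + h @ self.u_r + self.b_r).sigmoid()
            h_cand = (xt @ self.w_h + (r * h) @ self.u_h + self.b_h).tanh()
            h = (1.0 - z) * h + z * h_cand
        return (h @ self.fc_w + self.fc_b).reshape(B)


class SVMModel:
    """RBF-kernel support vector machine baseline (scikit-learn)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        if spec.task == "classification":
            self.estimator = SVC(
                C=spec.svm_C,
                gamma=spec.svm_gamma,
                kernel="rbf",
                probability=True,
                random_state=spec.seed,
            )
        else:
            self.estimator = SVR(C=spec.svm_C, gamma=spec.svm_gamma, kernel="rbf")
        self.fitted = False

    def fit(self, X, y):
        self.estimator.fit(_check_features(X), np.asarray(y).ravel())
        self.fitted = True
        return self

    def predict(self, X) -> PredictionBatch:
        X = _check_features(X)
        if not self.fitted:
            raise ParameterError("SVM model must be fitted before predicting")
        if self.spec.task == "classification":
            scores = self.estimator.predict_proba(X)[:, 1]
            scores = np.clip(scores, 1e-12, 1.0 - 1e-12)
        else:
            scores = self.estimator.predict(X)
        return PredictionBatch(scores=scores, attention=None)

    def attention_weights(self, X):
        raise CapabilityError("svm_rbf has no attention mechanism")


def build_model(spec: ModelSpec):
    """Instantiate a model from its spec; parameter init is seeded by spec.seed."""
    cls = {
        "cnn_attention": AttentionCNN,
        "cnn": PlainCNN,
        "rnn": GRUNet,
        "svm_rbf": SVMModel,
    }[spec.architecture]
    return cls(spec)


def predict(model, features) -> PredictionBatch:
    """Deterministic batch prediction; batched equals one-by-one to 1e-6."""
    return model.predict(features)


def attention_map(model, features) -> np.ndarray:
    """The exact softmax weights the attention model used for aggregation."""
    if not hasattr(model, "_attention"):
        raise CapabilityError(
            f"{model.spec.architecture} does not expose attention weights"
        )
    return model.attention_weights(features)


def save_model(model, path) -> None:
    """Single-file checkpoint: spec JSON plus weight arrays (npz archive)."""
    path = Path(path)
    spec_json = json.dumps(asdict(model.spec))
    payload = {"spec": np.frombuffer(spec_json.encode(), dtype=np.uint8)}
    if isinstance(model, SVMModel):
        blob = pickle.dumps(model.estimator)
        payload["svm"] = np.frombuffer(blob, dtype=np.uint8)
    else:
        for i, arr in enumerate(model.state_arrays()):
            payload[f"param_{i}"] = arr
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path):
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        spec_dict = json.loads(bytes(data["spec"]).decode())
        spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
        spec = ModelSpec(**spec_dict)
        model = build_model(spec)
        if isinstance(model, SVMModel):
            model.estimator = pickle.loads(bytes(data["svm"]))
            model.fitted = True
        else:
            arrays = [data[f"param_{i}"] for i in range(len(model.params))]
            model.load_state_arrays(arrays)
    return model
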