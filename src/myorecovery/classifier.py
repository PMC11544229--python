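"""Recovery-phase classifier trained from day-level class proportions.

The classifier F: R^D -> simplex^K is a 3-layer perceptron
(linear -> ReLU -> linear -> ReLU -> linear -> softmax).  No instance has
a class label; the only supervision is the class-proportion vector p_j of
the day j each instance came from (learning from label proportions, LLP).

Training groups same-day instances into bags of N; the bag's predicted
proportion is the mean of its members' confidences,

    p_hat_k = (1/|B|) * sum_{x in B} F(x)_k,

and the proportion loss is the KL divergence of the day's true proportion
from the bag prediction,

    L_prop = D_KL(p_j || p_hat) = sum_k p_k * ln(p_k / p_hat_k),

minimized by seeded mini-batch gradient descent.  The pseudo-label
baseline instead draws a random one-hot label y per instance with
P(y_k = 1) = p_k and minimizes ordinary cross-entropy -sum_k y_k ln F(x)_k.

The module is organised statsmodels-style: build a
:class:`RecoveryPhaseClassifier` from data, call :meth:`fit`, and work
with the returned :class:`RecoveryPhaseResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .scheme import ClassScheme, DEFAULT_SCHEME

KL_EPS = 1e-8


# ---------------------------------------------------------------------------
# parameters and forward pass

@dataclass
class MLPParams:
    """Weights of the 3-layer perceptron F: R^D -> simplex^K."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (self.W1.shape[0], self.W1.shape[1], self.W2.shape[1], self.W3.shape[1])

    def copy(self) -> "MLPParams":
        return MLPParams(*(a.copy() for a in
                           (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3)))

    def to_json(self) -> str:
        return json.dumps({k: np.asarray(v).tolist() for k, v in asdict(self).items()})

    @classmethod
    def from_json(cls, text: str) -> "MLPParams":
        data = json.loads(text)
        return cls(**{k: np.asarray(v, dtype=np.float64) for k, v in data.items()})


def init_params(
    D: int, hidden1: int, hidden2: int, K: int, seed: int = 0
) -> MLPParams:
    """He-style seeded initialization (ReLU gain), zero biases."""
    rng = np.random.default_rng(seed)
    def he(n_in, n_out):
        return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
    return MLPParams(
        W1=he(D, hidden1), b1=np.zeros(hidden1),
        W2=he(hidden1, hidden2), b2=np.zeros(hidden2),
        W3=he(hidden2, K), b3=np.zeros(K),
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """Confidence vector(s) F(x) on the open probability simplex."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(f"feature dim {X.shape[1]} != model dim {params.W1.shape[0]}")
    h1 = np.maximum(X @ params.W1 + params.b1, 0.0)
    h2 = np.maximum(h1 @ params.W2 + params.b2, 0.0)
    probs = _softmax(h2 @ params.W3 + params.b3)
    return probs[0] if single else probs


def predict_class(params: MLPParams, x: np.ndarray) -> int | np.ndarray:
    """Class with the highest confidence; ties go to the lowest index."""
    conf = forward(params, x)
    return np.argmax(conf, axis=-1) if conf.ndim > 1 else int(np.argmax(conf))


# ---------------------------------------------------------------------------
# bags and losses

@dataclass(frozen=True)
class Bag:
    """N same-day instances whose mean confidence is trained against p_j."""

    day_label: int
    instance_indices: np.ndarray

    @property
    def N(self) -> int:
        return len(self.instance_indices)


def make_bags(day_labels, N: int, seed: int = 0) -> list[Bag]:
    """Partition instances into same-day bags of exactly N.

    Instances are shuffled within each day (seeded), then chunked into
    consecutive bags of N; each day's trailing remainder (< N instances)
    is dropped, so the bag count is M = sum_j floor(n_j / N).
    """
    if N < 1:
        raise ValueError("bag size N must be >= 1")
    day_labels = np.asarray(day_labels)
    rng = np.random.default_rng(seed)
    bags: list[Bag] = []
    for day in np.unique(day_labels):
        idx = np.flatnonzero(day_labels == day)
        idx = rng.permutation(idx)
        for start in range(0, len(idx) - N + 1, N):
            bags.append(Bag(int(day), idx[start : start + N]))
    return bags


def predicted_proportion(params: MLPParams, bag: Bag, features: np.ndarray) -> np.ndarray:
    """Bag-level predicted proportion: mean of member confidences."""
    if bag.N == 0:
        raise ValueError("empty bag has no predicted proportion")
    return forward(params, np.asarray(features)[bag.instance_indices]).mean(axis=0)


def _smooth(p_hat: np.ndarray, eps: float) -> np.ndarray:
    p_hat = np.asarray(p_hat, dtype=np.float64)
    return (p_hat + eps) / (p_hat.sum() + eps * len(p_hat))


def proportion_loss(p_true, p_hat, eps: float = KL_EPS) -> float:
    """KL divergence D_KL(p_true || p_hat) with eps-smoothed predictions.

    Zero-probability true entries contribute nothing; the prediction is
    shifted by ``eps`` and renormalized so the loss is finite even when
    the classifier puts zero mass on a supported class.
    """
    p = np.asarray(p_true, dtype=np.float64)
    q = _smooth(p_hat, eps)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def pseudo_label_sample(p, n: int, seed: int = 0) -> np.ndarray:
    """Draw n one-hot labels with P(y_k = 1) = p_k (seeded)."""
    p = np.asarray(p, dtype=np.float64)
    rng = np.random.default_rng(seed)
    classes = rng.choice(len(p), size=n, p=p / p.sum())
    y = np.zeros((n, len(p)))
    if n:
        y[np.arange(n), classes] = 1.0
    return y


def cross_entropy_loss(confidences: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy -sum_k y_k ln F(x)_k over a batch."""
    conf = np.atleast_2d(np.asarray(confidences, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    return float(-(y * np.log(conf)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Training regime for :meth:`RecoveryPhaseClassifier.fit`.

    ``loss_mode`` selects the LLP proportion loss ("llp") or the
    pseudo-label cross-entropy baseline ("pseudo").  Bags are resampled
    every epoch; each gradient step averages the loss over
    ``bags_per_step`` bags (llp) or over ``batch_size`` instances
    (pseudo).  All randomness derives from ``seed``.
    """

    loss_mode: str = "llp"
    bag_size: int = 64
    bags_per_step: int = 16
    bags_per_epoch: int | None = None  # None: every full bag once per epoch
    batch_size: int = 128
    epochs: int = 300
    step_size: float | None = None  # None: 1.0 for llp, 0.1 for pseudo
    weight_decay: float = 1e-3
    seed: int = 0
    eps: float = KL_EPS

    def __post_init__(self) -> None:
        if self.loss_mode not in ("llp", "pseudo"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")

    @property
    def effective_step(self) -> float:
        if self.step_size is not None:
            return self.step_size
        return 1.0 if self.loss_mode == "llp" else 0.1


class RecoveryPhaseClassifier:
    """LLP model for per-cell recovery-phase classification.

    Parameters
    ----------
    features : (N, D) array
        Instance feature matrix (one row per cell image).
    day_labels : length-N int array
        Day j of each instance (days after injury; day 0 = pre-injury).
    day_proportions : mapping day -> length-K proportion vector
        Ground-truth class proportions per day, from rough annotations.
    scheme : ClassScheme
        Class names/colors; fixes K.
    hidden1, hidden2 : int
        Perceptron widths; ``hidden1=None`` keeps the input dimension
        (FC1 preserves dimension, FC2 compresses to ``hidden2``).
    standardize : bool
        Standardize features to zero mean / unit variance before the
        perceptron (stored and re-applied at prediction time).
    """

    def __init__(
        self,
        features,
        day_labels,
        day_proportions,
        scheme: ClassScheme = DEFAULT_SCHEME,
        hidden1: int | None = None,
        hidden2: int = 256,
        standardize: bool = True,
    ) -> None:
        self.features = np.asarray(features, dtype=np.float64)
        self.day_labels = np.asarray(day_labels)
        if self.features.ndim != 2 or len(self.day_labels) != len(self.features):
            raise ValueError("features must be (N, D) with one day label per row")
        self.scheme = scheme
        self.day_proportions = {
            int(j): np.asarray(p, dtype=np.float64) for j, p in dict(day_proportions).items()
        }
        for j in np.unique(self.day_labels):
            if int(j) not in self.day_proportions:
                raise ValueError(f"day {j} has no ground-truth proportion")
        for j, p in self.day_proportions.items():
            if len(p) != scheme.K or p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"day {j} proportion is not on the {scheme.K}-simplex")
        self.D = self.features.shape[1]
        self.hidden1 = hidden1 or self.D
        self.hidden2 = hidden2
        self.standardize = standardize
        if standardize:
            self._mu = self.features.mean(axis=0)
            sd = self.features.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        else:
            self._mu = np.zeros(self.D)
            self._sd = np.ones(self.D)

    # -- internals ---------------------------------------------------------

    def _X(self) -> np.ndarray:
        return (self.features - self._mu) / self._sd

    def _forward_cache(self, params: MLPParams, X: np.ndarray):
        h1 = np.maximum(X @ params.W1 + params.b1, 0.0)
        h2 = np.maximum(h1 @ params.W2 + params.b2, 0.0)
        S = _softmax(h2 @ params.W3 + params.b3)
        return h1, h2, S

    @staticmethod
    def _apply_update(params: MLPParams, grads: MLPParams, lr: float, wd: float) -> None:
        # L2 weight decay on the weight matrices only, not the biases
        for name in ("W1", "W2", "W3"):
            w = getattr(params, name)
            w -= lr * (getattr(grads, name) + wd * w)
        for name in ("b1", "b2", "b3"):
            getattr(params, name)[...] -= lr * getattr(grads, name)

    @staticmethod
    def _backprop(params: MLPParams, X, h1, h2, dZ) -> MLPParams:
        gW3 = h2.T @ dZ
        gb3 = dZ.sum(axis=0)
        dh2 = (dZ @ params.W3.T) * (h2 > 0)
        gW2 = h1.T @ dh2
        gb2 = dh2.sum(axis=0)
        dh1 = (dh2 @ params.W2.T) * (h1 > 0)
        gW1 = X.T @ dh1
        gb1 = dh1.sum(axis=0)
        return MLPParams(gW1, gb1, gW2, gb2, gW3, gb3)

    def _llp_step_grad(self, params: MLPParams, X, bags: list, eps: float):
        """Mean proportion loss over a batch of bags, and its gradient."""
        grads = None
        total = 0.0
        for bag in bags:
            Xb = X[bag.instance_indices]
            h1, h2, S = self._forward_cache(params, Xb)
            p_hat = S.mean(axis=0)
            scale = p_hat.sum() + eps * len(p_hat)
            q = (p_hat + eps) / scale
            p = self.day_proportions[bag.day_label]
            mask = p > 0
            total += float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
            # dL/dq = -p/q on supported entries; q = (p_hat + eps)/scale
            dLdq = np.where(mask, -p / q, 0.0)
            dLdphat = (dLdq - (dLdq * q).sum()) / scale  # through renormalization
            g = dLdphat / bag.N
            dZ = S * (g - (S * g).sum(axis=1, keepdims=True))
            gb = self._backprop(params, Xb, h1, h2, dZ)
            if grads is None:
                grads = gb
            else:
                for a, b in zip(vars(grads).values(), vars(gb).values()):
                    a += b
        n = len(bags)
        for a in vars(grads).values():
            a /= n
        return total / n, grads

    # -- public API --------------------------------------------------------

    def fit(self, config: TrainConfig | None = None, **kwargs) -> "RecoveryPhaseResults":
        """Train with seeded mini-batch SGD and return a results object.

        Keyword arguments override :class:`TrainConfig` fields, e.g.
        ``fit(loss_mode="pseudo", epochs=100, seed=3)``.
        """
        if config is None:
            config = TrainConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a TrainConfig or keyword overrides, not both")

        ss = np.random.SeedSequence(config.seed)
        init_seed, loop_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        params = init_params(self.D, self.hidden1, self.hidden2, self.scheme.K, init_seed)
        X = self._X()
        lr = config.effective_step
        rng = np.random.default_rng(loop_seed)
        trace: list[float] = []

        for epoch in range(config.epochs):
            if config.loss_mode == "llp":
                bags = make_bags(self.day_labels, config.bag_size,
                                 seed=int(rng.integers(2**31)))
                order = rng.permutation(len(bags))
                if config.bags_per_epoch is not None:
                    order = order[: config.bags_per_epoch]
                losses = []
                for start in range(0, len(order), config.bags_per_step):
                    batch = [bags[i] for i in order[start : start + config.bags_per_step]]
                    loss, grads = self._llp_step_grad(params, X, batch, config.eps)
                    losses.append(loss)
                    self._apply_update(params, grads, lr, config.weight_decay)
                trace.append(float(np.mean(losses)) if losses else np.nan)
            else:  # pseudo-label baseline
                Y = np.zeros((len(X), self.scheme.K))
                for day in np.unique(self.day_labels):
                    idx = np.flatnonzero(self.day_labels == day)
                    Y[idx] = pseudo_label_sample(
                        self.day_proportions[int(day)], len(idx),
                        seed=int(rng.integers(2**31)))
                order = rng.permutation(len(X))
                losses = []
                for start in range(0, len(order), config.batch_size):
                    sel = order[start : start + config.batch_size]
                    Xb, Yb = X[sel], Y[sel]
                    h1, h2, S = self._forward_cache(params, Xb)
                    losses.append(float(-(Yb * np.log(np.clip(S, 1e-300, None)))
                                        .sum(axis=1).mean()))
                    dZ = (S - Yb) / len(sel)
                    grads = self._backprop(params, Xb, h1, h2, dZ)
                    self._apply_update(params, grads, lr, config.weight_decay)
                trace.append(float(np.mean(losses)) if losses else np.nan)

        return RecoveryPhaseResults(self, params, config, np.asarray(trace))


class RecoveryPhaseResults:
    """Fitted recovery-phase classifier.

    Carries the perceptron weights, the training configuration and the
    per-epoch mean loss trace; provides instance prediction, bag-level
    proportion prediction and held-out diagnostics.
    """

    def __init__(self, model: RecoveryPhaseClassifier, params: MLPParams,
                 config: TrainConfig, loss_trace: np.ndarray) -> None:
        self.model = model
        self.params = params
        self.config = config
        self.loss_trace = loss_trace

    def _transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.model._mu) / self.model._sd

    def predict_proba(self, features) -> np.ndarray:
        """Per-instance confidence vectors F(x) on the simplex."""
        return forward(self.params, self._transform(features))

    def predict(self, features) -> np.ndarray:
        """Argmax class per instance (ties to the lowest index)."""
        return np.argmax(self.predict_proba(features), axis=1)

    def predict_day_proportions(self, features, day_labels) -> dict[int, np.ndarray]:
        """Mean confidence per day: the inferred day-level proportions."""
        probs = self.predict_proba(features)
        day_labels = np.asarray(day_labels)
        return {int(d): probs[day_labels == d].mean(axis=0)
                for d in np.unique(day_labels)}

    def bag_kl(self, features, day_labels, day_proportions=None,
               bag_size: int | None = None, seed: int = 0) -> float:
        """Mean proportion loss over freshly drawn bags of held-out data."""
        day_proportions = ({int(j): np.asarray(p) for j, p in dict(day_proportions).items()}
                           if day_proportions is not None else self.model.day_proportions)
        bags = make_bags(day_labels, bag_size or self.config.bag_size, seed=seed)
        X = self._transform(features)
        vals = [proportion_loss(day_proportions[b.day_label],
                                forward(self.params, X[b.instance_indices]).mean(axis=0),
                                self.config.eps)
                for b in bags]
        return float(np.mean(vals))

    def day_kl(self, features, day_labels, day_proportions=None) -> float:
        """Mean day-level KL(true || inferred proportion) on held-out data.

        The inferred proportion of a day is the mean confidence over all
        its instances (one large bag per day), mirroring the per-test-image
        proportion comparison used in cross-validation; bag-size-64
        evaluation (see :meth:`bag_kl`) carries a multinomial sampling
        floor of roughly (K-1)/(2N) per bag that this metric does not.
        """
        day_proportions = ({int(j): np.asarray(p) for j, p in dict(day_proportions).items()}
                           if day_proportions is not None else self.model.day_proportions)
        inferred = self.predict_day_proportions(features, day_labels)
        vals = [proportion_loss(day_proportions[d], p_hat, self.config.eps)
                for d, p_hat in inferred.items()]
        return float(np.mean(vals))

    def summary(self) -> str:
        m, c = self.model, self.config
        lines = [
            "Recovery-phase classifier (learning from label proportions)",
            "=" * 60,
            f"instances: {len(m.features)}    feature dim D: {m.D}",
            f"perceptron: {m.D} -> {m.hidden1} -> {m.hidden2} -> {m.scheme.K} (softmax)",
            f"classes: {', '.join(m.scheme.names)}",
            f"loss mode: {c.loss_mode}    bag size N: {c.bag_size}",
            f"epochs: {c.epochs}    step size: {c.effective_step}    seed: {c.seed}",
            f"final mean {'bag KL' if c.loss_mode == 'llp' else 'cross-entropy'} loss: "
            f"{self.loss_trace[-1]:.6f}" if len(self.loss_trace) else "not trained",
            "day proportions (truth):",
        ]
        for j in sorted(m.day_proportions):
            p = m.day_proportions[j]
            lines.append(f"  day {j:>3}: " + "  ".join(f"{v:.3f}" for v in p))
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize weights + dims + scheme + config as a JSON file."""
        blob = {
            "params": json.loads(self.params.to_json()),
            "dims": self.params.dims,
            "scheme": {"names": self.model.scheme.names,
                       "colors": self.model.scheme.colors},
            "standardize": {"mu": self.model._mu.tolist(),
                            "sd": self.model._sd.tolist()},
            "config": asdict(self.config),
            "loss_trace": self.loss_trace.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path, features=None, day_labels=None, day_proportions=None):
        """Rebuild a results object (model context optional, for inference)."""
        with open(path) as fh:
            blob = json.load(fh)
        params = MLPParams(**{k: np.asarray(v, dtype=np.float64)
                              for k, v in blob["params"].items()})
        scheme = ClassScheme(tuple(blob["scheme"]["names"]),
                             tuple(tuple(c) for c in blob["scheme"]["colors"]))
        D = params.dims[0]
        if features is None:
            features = np.zeros((1, D))
            day_labels = [0]
            day_proportions = {0: np.full(scheme.K, 1.0 / scheme.K)}
        model = RecoveryPhaseClassifier(features, day_labels, day_proportions,
                                        scheme=scheme, standardize=False)
        model._mu = np.asarray(blob["standardize"]["mu"])
        model._sd = np.asarray(blob["standardize"]["sd"])
        config = TrainConfig(**blob["config"])
        return cls(model, params, config, np.asarray(blob["loss_trace"]))
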