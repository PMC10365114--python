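"""The two players: a binary AD classifier and a conditional counterfactual
generator, with their pre-training.

Both are small fully-connected networks written directly in NumPy with
analytic backpropagation.  Besides parameter gradients, each exposes the
gradients the adversarial game needs:

* the classifier returns the gradient of its per-sample cross-entropy with
  respect to the *input image* (:meth:`MLPClassifier.input_gradient`), and
* the generator returns the gradient of its *output image* with respect to
  the target age, chained through the Fourier conditioning encoder
  (:meth:`MLPGenerator.generate_with_age_grad`).

The simulator's :class:`~cfaug.toyworld.OracleGenerator` satisfies the same
generator contract exactly; the neural generator here is trained by
regressing onto the oracle's counterfactuals at random target ages, which
gives a frozen, differentiable stand-in for a pre-trained conditional
generative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import conditioning as cond
from .toyworld import ImageSample, ToyDataset, images_of, labels_of

__all__ = [
    "TrainConfig",
    "MLPClassifier",
    "MLPGenerator",
    "pretrain_classifier",
    "per_sample_errors",
    "train_neural_generator",
    "TrainingDivergedError",
    "bce_from_logits",
]


@dataclass
class TrainConfig:
    epochs: int = 40
    learning_rate: float = 3e-4
    batch_size: int = 32
    seed: int = 0
    hidden: int = 48
    # generator-specific
    n_pairs_per_sample: int = 4     # (source, target-age) pairs per train sample
    patience: int = 10              # divergence check window, epochs

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, learning_rate and batch_size must be positive")


class TrainingDivergedError(RuntimeError):
    pass


def bce_from_logits(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Numerically stable per-sample binary cross-entropy."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=float)
    return np.maximum(logits, 0.0) - logits * labels + np.log1p(np.exp(-np.abs(logits)))


class _Adam:
    """Minimal Adam state over a list of parameter arrays."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, sign=-1.0, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p += sign * lr * mhat / (np.sqrt(vhat) + self.eps)


class MLPClassifier:
    """One-hidden-layer tanh network with a sigmoid output: p(AD | image).

    Satisfies the classifier contract: ``predict_proba``, ``per_sample_loss``
    (binary cross-entropy of ``predict_proba``), and ``input_gradient``
    (gradient of each sample's loss with respect to its own pixels, through
    which the adversarial ascent reaches the target age).
    """

    def __init__(self, n_inputs: int, hidden: int = 48, seed: int = 0):
        rng = np.random.default_rng(seed)
        sc1 = 1.0 / np.sqrt(n_inputs)
        self.W1 = rng.normal(0.0, sc1, size=(hidden, n_inputs))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.w_skip = np.zeros(n_inputs)   # linear pixel->logit path; keeps
        self.b2 = 0.0                      # gradients alive if tanh saturates
        self.n_inputs = n_inputs
        self._adam = None
        self.loss_curve_ = []

    # -- plumbing
    def _params(self):
        return [self.W1, self.b1, self.W2, self.w_skip,
                np.atleast_1d(np.float64(self.b2))]

    def parameter_snapshot(self):
        return [self.W1.copy(), self.b1.copy(), self.W2.copy(),
                self.w_skip.copy(), float(self.b2)]

    def _flat(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        return images.reshape(images.shape[0], -1)

    def _forward(self, X):
        H = np.tanh(X @ self.W1.T + self.b1)
        logits = H @ self.W2 + X @ self.w_skip + self.b2
        return H, logits

    # -- contract surface
    def decision_logits(self, images) -> np.ndarray:
        _, logits = self._forward(self._flat(images))
        return logits

    def predict_proba(self, images) -> np.ndarray:
        return expit(self.decision_logits(images))

    def per_sample_loss(self, images, labels) -> np.ndarray:
        return bce_from_logits(self.decision_logits(images), labels)

    def input_gradient(self, images, labels) -> np.ndarray:
        """d(loss_i)/d(image_i), shape like ``images``."""
        images = np.asarray(images, dtype=float)
        X = self._flat(images)
        H, logits = self._forward(X)
        dlogit = expit(logits) - np.asarray(labels, dtype=float)   # (n,)
        dH = dlogit[:, None] * self.W2[None, :] * (1.0 - H**2)     # (n, h)
        dX = dH @ self.W1 + dlogit[:, None] * self.w_skip[None, :]
        return dX.reshape(images.shape)

    # -- training
    def fit_epoch(self, images, labels, lr: float, rng: np.random.Generator,
                  batch_size: int = 32) -> float:
        """One epoch of minibatch Adam on binary cross-entropy; returns mean loss."""
        X = self._flat(images)
        y = np.asarray(labels, dtype=float)
        if self._adam is None:
            self._adam = _Adam(self._params(), lr)
        order = rng.permutation(len(X))
        total = 0.0
        bs = batch_size
        for start in range(0, len(X), bs):
            idx = order[start:start + bs]
            Xb, yb = X[idx], y[idx]
            H, logits = self._forward(Xb)
            total += float(np.sum(bce_from_logits(logits, yb)))
            dlogit = (expit(logits) - yb) / len(idx)
            gW2 = dlogit @ H
            gskip = dlogit @ Xb
            gb2 = float(np.sum(dlogit))
            dH = np.outer(dlogit, self.W2) * (1.0 - H**2)
            gW1 = dH.T @ Xb
            gb1 = dH.sum(axis=0)
            b2arr = np.atleast_1d(np.float64(self.b2))
            self._adam.step([self.W1, self.b1, self.W2, self.w_skip, b2arr],
                            [gW1, gb1, gW2, gskip, np.atleast_1d(gb2)], lr=lr)
            self.b2 = float(b2arr[0])
        return total / len(X)

    # -- persistence
    def save(self, path) -> None:
        np.savez_compressed(path, W1=self.W1, b1=self.b1, W2=self.W2,
                            w_skip=self.w_skip, b2=np.float64(self.b2))

    @classmethod
    def load(cls, path) -> "MLPClassifier":
        data = np.load(path)
        obj = cls.__new__(cls)
        obj.W1 = data["W1"]
        obj.b1 = data["b1"]
        obj.W2 = data["W2"]
        obj.w_skip = data["w_skip"]
        obj.b2 = float(data["b2"])
        obj.n_inputs = obj.W1.shape[1]
        obj._adam = None
        obj.loss_curve_ = []
        return obj


def pretrain_classifier(dataset: ToyDataset, cfg: TrainConfig) -> MLPClassifier:
    """Minimise mean binary cross-entropy on the train split.

    Deterministic given ``cfg.seed``; the per-epoch loss curve is attached
    as ``classifier.loss_curve_``.
    """
    train = dataset.split("train")
    if not train:
        raise ValueError("train split is empty")
    y = labels_of(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    X = images_of(train)
    clf = MLPClassifier(n_inputs=X[0].size, hidden=cfg.hidden, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(cfg.epochs):
        clf.loss_curve_.append(
            clf.fit_epoch(X, y, cfg.learning_rate, rng, cfg.batch_size))
    return clf


def per_sample_errors(classifier, samples) -> np.ndarray:
    """Binary cross-entropy of each sample, order-aligned with the input."""
    if len(samples) == 0:
        return np.empty(0)
    return classifier.per_sample_loss(images_of(samples), labels_of(samples))


# ---------------------------------------------------------------------------
# neural counterfactual generator


class MLPGenerator:
    """Conditional encoder-decoder: (image, gamma(target conditions)) -> image.

    A single tanh hidden layer maps the concatenation of the flattened source
    image and the Fourier-encoded target conditions to the output image
    (tanh-bounded into (-1, 1)).  The age path is differentiable end to end:
    target age -> normalised conditions -> Fourier features -> output pixels.
    """

    trainable = True

    def __init__(self, image_shape, spec: cond.EncodingSpec | None = None,
                 hidden: int = 256, seed: int = 0,
                 age_range=cond.AGE_RANGE):
        self.image_shape = tuple(image_shape)
        self.spec = spec or cond.make_encoding_spec(seed=seed)
        self.age_range = age_range
        D = int(np.prod(image_shape))
        E = self.spec.out_dim
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(D + E), size=(hidden, D + E))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(D, hidden))
        self.b2 = np.zeros(D)
        self.D, self.E = D, E
        self._adam = None
        self.loss_curve_ = []

    def parameter_snapshot(self):
        return [self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy()]

    def _encode_conditions(self, samples, target_ages) -> np.ndarray:
        ages = np.clip(np.asarray(target_ages, dtype=float),
                       self.age_range[0], self.age_range[1])
        V = np.stack([cond.normalize_conditions(a, s.diagnosis, self.age_range)
                      for s, a in zip(samples, ages)])
        return cond.fourier_encode_batch(V, self.spec)

    def _forward(self, samples, target_ages):
        X = np.stack([s.image.ravel() for s in samples])
        G = self._encode_conditions(samples, target_ages)
        Z = np.concatenate([X, G], axis=1)
        H = np.tanh(Z @ self.W1.T + self.b1)
        out = np.tanh(H @ self.W2.T + self.b2)
        return Z, H, out

    def generate(self, samples, target_ages) -> np.ndarray:
        _, _, out = self._forward(samples, target_ages)
        return out.reshape((len(samples),) + self.image_shape)

    def generate_with_age_grad(self, samples, target_ages):
        """Outputs plus per-sample d(output)/d(target age), chain rule through
        the Fourier encoder."""
        _, H, out = self._forward(samples, target_ages)
        dv_da = np.array([cond.age_norm_derivative(self.age_range), 0.0])
        n = len(samples)
        grads = np.empty((n, self.D))
        ages = np.asarray(target_ages, dtype=float)
        W1_enc = self.W1[:, self.D:]                      # (h, E)
        for i in range(n):
            v = cond.normalize_conditions(
                float(np.clip(ages[i], *self.age_range)),
                samples[i].diagnosis, self.age_range)
            J = cond.fourier_jacobian(v, self.spec)        # (E, d)
            dgamma_da = J @ dv_da                          # (E,)
            dz1 = W1_enc @ dgamma_da                       # (h,)
            dh = (1.0 - H[i] ** 2) * dz1
            grads[i] = (1.0 - out[i] ** 2) * (self.W2 @ dh)
        return (out.reshape((n,) + self.image_shape),
                grads.reshape((n,) + self.image_shape))

    # -- backprop shared by regression training and adversarial ascent
    def _backprop(self, Z, H, out, dout):
        """Parameter gradients given d(loss)/d(pre-tanh output activations)'s
        upstream d(loss)/d(out)."""
        dz2 = dout * (1.0 - out**2)                        # (n, D)
        gW2 = dz2.T @ H
        gb2 = dz2.sum(axis=0)
        dH = dz2 @ self.W2 * (1.0 - H**2)
        gW1 = dH.T @ Z
        gb1 = dH.sum(axis=0)
        return [gW1, gb1, gW2, gb2]

    def fit_epoch(self, samples, target_ages, targets, lr, rng,
                  batch_size: int = 32) -> float:
        """One epoch of minibatch Adam on mean squared pixel error against
        ``targets`` (oracle counterfactuals); returns mean loss."""
        n = len(samples)
        if self._adam is None:
            self._adam = _Adam([self.W1, self.b1, self.W2, self.b2], lr)
        order = rng.permutation(n)
        total = 0.0
        bs = batch_size
        T = targets.reshape(n, -1)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            batch = [samples[j] for j in idx]
            Z, H, out = self._forward(batch, np.asarray(target_ages)[idx])
            err = out - T[idx]
            total += float(np.mean(err**2) * len(idx))
            dout = 2.0 * err / err.size
            grads = self._backprop(Z, H, out, dout)
            self._adam.step([self.W1, self.b1, self.W2, self.b2], grads, lr=lr)
        return total / n

    def ascent_step(self, samples, target_ages, dloss_dout, lr: float) -> None:
        """Gradient *ascent* on the generator parameters given the upstream
        gradient of the (to-be-maximised) classifier loss w.r.t. the output
        images.  Plain SGD: the cautionary mode needs no momentum."""
        Z, H, out = self._forward(samples, target_ages)
        grads = self._backprop(Z, H, out, dloss_dout.reshape(len(samples), -1))
        for p, g in zip([self.W1, self.b1, self.W2, self.b2], grads):
            p += lr * g

    def save(self, path) -> None:
        np.savez_compressed(path, W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
                            image_shape=np.array(self.image_shape),
                            enc_m=self.spec.m, enc_mu=self.spec.mu_scale,
                            enc_seed=self.spec.seed, enc_d=self.spec.d,
                            age_lo=self.age_range[0], age_hi=self.age_range[1])

    @classmethod
    def load(cls, path) -> "MLPGenerator":
        d = np.load(path)
        spec = cond.EncodingSpec(m=int(d["enc_m"]), mu_scale=float(d["enc_mu"]),
                                 seed=int(d["enc_seed"]), d=int(d["enc_d"]))
        obj = cls(tuple(d["image_shape"]), spec=spec, hidden=d["W1"].shape[0],
                  age_range=(float(d["age_lo"]), float(d["age_hi"])))
        obj.W1, obj.b1 = d["W1"], d["b1"]
        obj.W2, obj.b2 = d["W2"], d["b2"]
        return obj


def train_neural_generator(dataset: ToyDataset, oracle, cfg: TrainConfig,
                           spec: cond.EncodingSpec | None = None,
                           hidden: int = 256) -> MLPGenerator:
    """Fit the conditional generator by regressing onto oracle counterfactuals.

    For every training sample we draw ``cfg.n_pairs_per_sample`` random target
    ages and supervise the generator with the oracle's noiseless
    counterfactual at those ages (mean squared pixel error).  Raises
    :class:`TrainingDivergedError` if the loss stops decreasing over the
    patience window.
    """
    train = dataset.split("train")
    if not train:
        raise ValueError("train split is empty")
    rng = np.random.default_rng(cfg.seed)
    pairs_samples, pairs_ages = [], []
    for s in train:
        for _ in range(cfg.n_pairs_per_sample):
            pairs_samples.append(s)
            pairs_ages.append(float(rng.uniform(*cond.AGE_RANGE)))
        # include the identity counterfactual so "same age" is anchored
        pairs_samples.append(s)
        pairs_ages.append(s.age)
    pairs_ages = np.asarray(pairs_ages)
    targets = oracle.generate(pairs_samples, pairs_ages)

    gen = MLPGenerator(train[0].image.shape, spec=spec, hidden=hidden, seed=cfg.seed)
    best = np.inf
    stale = 0
    for _ in range(cfg.epochs):
        loss = gen.fit_epoch(pairs_samples, pairs_ages, targets,
                             cfg.learning_rate, rng, cfg.batch_size)
        gen.loss_curve_.append(loss)
        if loss < best - 1e-6:
            best, stale = loss, 0
        else:
            stale += 1
            if stale > cfg.patience:
                raise TrainingDivergedError(
                    f"generator loss not decreasing for {stale} epochs; "
                    f"curve tail {gen.loss_curve_[-5:]}")
    return gen
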