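"""Adversarial counterfactual augmentation.

The game: a frozen conditional generator G(x, a) and a classifier C play over
the *conditional factor* a (the target age) of a fixed set of hard training
samples.  The target ages are repeatedly pushed by gradient ascent in the
direction that maximises C's cross-entropy on the counterfactuals
G(x, a) (labels are preserved: changing the target age does not change the
diagnosis), and C is then retrained for one epoch on the union of the real
training data and the current counterfactuals.  Ascending a rather than G's
parameters keeps the counterfactuals on the generator's manifold; the
G-vs-C variant (:func:`train_generator_adversarially`) exists to demonstrate
why the alternative degrades.

A continual-learning variant replays only a memory buffer of M% of the
training data, and the synthetic hard counterfactuals act against
catastrophic forgetting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .models import per_sample_errors
from .toyworld import ImageSample, ToyDataset, images_of, labels_of, ages_of

log = logging.getLogger("cfaug.adversarial")

__all__ = [
    "AugmentConfig",
    "RunHistory",
    "select_hard_samples",
    "init_target_ages",
    "ascend_target_ages",
    "synthesize_counterfactuals",
    "classifier_update",
    "adversarial_augment",
    "continual_adversarial_augment",
    "train_generator_adversarially",
]


@dataclass
class AugmentConfig:
    """Hyperparameters of the adversarial loops.

    ``n_hard`` and ``k`` default to the reference setting (N=100 hard
    samples, k=5 outer iterations).  ``gamma_a`` is the ascent step size on
    the *year* scale (gradients are taken through the normalisation); it is
    large because a well-fit desk-scale classifier leaves per-sample loss
    gradients of order 0.01 per year, and the ascent must be able to move
    target ages by whole years per step.  ``n_ascent`` inner ascent steps
    run per outer iteration.  Target ages
    are clipped into ``clip_range`` after every update.
    ``memory_fraction`` is the M% buffer of the continual variant.
    """

    n_hard: int = 100
    k: int = 5
    gamma_a: float = 50.0
    n_ascent: int = 1
    clip_range: tuple[float, float] = (60.0, 90.0)
    classifier_lr: float = 1e-4
    memory_fraction: float = 100.0
    seed: int = 0
    init_mode: str = "uniform_to_max"
    selection: str = "hard"            # "hard" | "random" (random = RSAT)
    reselect_hard: bool = False        # selection happens once by default
    # G-vs-C cautionary mode
    generator_lr: float = 1e-2
    gvc_epochs: int = 10
    gvc_n_syn: int = 100

    def __post_init__(self):
        if self.gamma_a <= 0:
            raise ValueError("gamma_a must be positive")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range must be ordered")
        if not 0 < self.memory_fraction <= 100:
            raise ValueError("memory_fraction must be in (0, 100]")
        if self.init_mode not in ("uniform_to_max", "real_age"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.selection not in ("hard", "random"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass
class RunHistory:
    """Per-iteration log of an adversarial run; length equals k."""

    records: list = field(default_factory=list)
    sub_seeds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {k: v for k, v in r.items()
                   if not isinstance(v, np.ndarray) and v is not None}
            rows.append(row)
        return pd.DataFrame(rows)

    def age_snapshots(self) -> np.ndarray:
        return np.stack([r["target_ages"] for r in self.records])

    def initial_ages(self) -> np.ndarray:
        return self.records[0]["initial_ages"]

    def hard_labels(self) -> np.ndarray:
        return self.records[0]["hard_labels"]

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for r in self.records:
                out = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in r.items()}
                fh.write(json.dumps(out) + "\n")


def _sub_seeds(master_seed: int) -> dict:
    """Fan one master seed out into named component seeds (all < 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    names = ["selection", "init", "data_order", "store"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)}


def select_hard_samples(classifier, samples, n_hard: int) -> list:
    """The ``n_hard`` samples with the highest per-sample cross-entropy.

    "Error" is the continuous BCE loss, which gives a total ranking; ties
    break by ascending sample_id.  The returned subset is ordered by
    sample_id.
    """
    if n_hard > len(samples):
        raise ValueError(f"n_hard={n_hard} exceeds split size {len(samples)}")
    losses = per_sample_errors(classifier, samples)
    order = sorted(range(len(samples)),
                   key=lambda i: (-losses[i], samples[i].sample_id))
    chosen = sorted(order[:n_hard], key=lambda i: samples[i].sample_id)
    return [samples[i] for i in chosen]


def init_target_ages(d_hard, mode: str, seed: int,
                     clip_range=(60.0, 90.0)) -> np.ndarray:
    """Initial target ages: uniform between each real age and the maximum
    age (``uniform_to_max``) or the real ages themselves (``real_age``)."""
    ages = ages_of(d_hard)
    if mode == "real_age":
        return ages.copy()
    if mode == "uniform_to_max":
        rng = np.random.default_rng(seed)
        return rng.uniform(ages, clip_range[1])
    raise ValueError(f"unknown init mode {mode!r}")


def ascend_target_ages(a: np.ndarray, d_hard, G, C, cfg: AugmentConfig) -> np.ndarray:
    """``n_ascent`` steps of a <- clip(a + gamma_a * d(loss_i)/d(a_i)).

    The per-sample classifier loss is the BCE of C on G(x_i, a_i) against the
    *source* label; its age-gradient is the pixelwise product of C's input
    gradient with G's age-Jacobian.  Neither C nor G parameters are touched.
    """
    a = np.asarray(a, dtype=float).copy()
    labels = labels_of(d_hard)
    for _ in range(cfg.n_ascent):
        imgs, dimg_da = G.generate_with_age_grad(d_hard, a)
        dloss_dimg = C.input_gradient(imgs, labels)
        grad = np.sum(dloss_dimg.reshape(len(a), -1)
                      * dimg_da.reshape(len(a), -1), axis=1)
        if not np.all(np.isfinite(grad)):
            bad = np.flatnonzero(~np.isfinite(grad))
            log.error("non-finite age gradient at hard indices %s", bad[:10])
            raise FloatingPointError("non-finite gradient in target-age ascent")
        a = np.clip(a + cfg.gamma_a * grad, cfg.clip_range[0], cfg.clip_range[1])
    return a


def synthesize_counterfactuals(d_hard, a: np.ndarray, G) -> list:
    """Counterfactual set D_syn: G(x_i, a_i) carrying the source label.

    Each synthetic sample keeps its source's diagnosis (label preservation)
    and records the target age as its age; images carry no gradient state.
    """
    if len(a) != len(d_hard):
        raise ValueError("target ages not aligned with hard set")
    imgs = G.generate(d_hard, a)
    return [ImageSample(np.array(imgs[i]), float(a[i]), s.diagnosis,
                        s.subject, "syn", s.sample_id)
            for i, s in enumerate(d_hard)]


def classifier_update(C, train_samples, d_syn, cfg: AugmentConfig,
                      rng: np.random.Generator) -> float:
    """One epoch of BCE minimisation over the union of real and synthetic
    samples; returns the epoch's mean loss."""
    combined = list(train_samples) + list(d_syn)
    X = images_of(combined)
    y = labels_of(combined)
    return C.fit_epoch(X, y, cfg.classifier_lr, rng)


def _run_adversarial_loop(C, G, real_samples, val_samples, cfg: AugmentConfig,
                          seeds: dict) -> RunHistory:
    history = RunHistory(sub_seeds=dict(seeds))
    if cfg.selection == "hard":
        d_hard = select_hard_samples(C, real_samples, cfg.n_hard)
    else:
        rng_sel = np.random.default_rng(seeds["selection"])
        idx = rng_sel.choice(len(real_samples), size=cfg.n_hard, replace=False)
        d_hard = [real_samples[i] for i in sorted(idx)]
    a = init_target_ages(d_hard, cfg.init_mode, seeds["init"], cfg.clip_range)
    a0 = a.copy()
    rng_data = np.random.default_rng(seeds["data_order"])
    labels = labels_of(d_hard)
    for it in range(cfg.k):
        if cfg.reselect_hard and it > 0:
            d_hard = select_hard_samples(C, real_samples, cfg.n_hard)
            labels = labels_of(d_hard)
        loss_before = float(np.mean(C.per_sample_loss(G.generate(d_hard, a), labels)))
        a = ascend_target_ages(a, d_hard, G, C, cfg)
        d_syn = synthesize_counterfactuals(d_hard, a, G)
        loss_after = float(np.mean(per_sample_errors(C, d_syn)))
        train_loss = classifier_update(C, real_samples, d_syn, cfg, rng_data)
        rec = dict(iteration=it, hard_loss_before=loss_before,
                   hard_loss_after=loss_after, train_loss=train_loss,
                   target_ages=a.copy(),
                   initial_ages=a0 if it == 0 else None,
                   hard_labels=labels.copy() if it == 0 else None)
        if val_samples:
            p = C.predict_proba(images_of(val_samples))
            rec["val_accuracy"] = float(np.mean((p > 0.5) == labels_of(val_samples)))
        history.records.append(rec)
    return history


def adversarial_augment(C, G, dataset: ToyDataset, cfg: AugmentConfig):
    """The main loop with a frozen generator.

    Hard samples are selected once from the train split, target ages are
    initialised, then k iterations of ascend -> synthesize -> one-epoch
    classifier update on D_train U D_syn.  G's parameters are never touched.
    """
    seeds = _sub_seeds(cfg.seed)
    history = _run_adversarial_loop(C, G, dataset.split("train"),
                                    dataset.split("val"), cfg, seeds)
    return C, history


def continual_adversarial_augment(C, G, dataset: ToyDataset, cfg: AugmentConfig):
    """Memory-buffer variant: everything is restricted to D_store U D_syn.

    D_store is a uniformly random M% of the train split (the whole split, in
    order, when M=100, so that trajectory coincides bitwise with
    :func:`adversarial_augment` at the same seed).  If the buffer is smaller
    than ``n_hard``, ``n_hard`` is lowered with a warning.
    """
    seeds = _sub_seeds(cfg.seed)
    train = dataset.split("train")
    if cfg.memory_fraction >= 100.0:
        d_store = list(train)
    else:
        n_store = int(round(cfg.memory_fraction / 100.0 * len(train)))
        rng = np.random.default_rng(seeds["store"])
        idx = rng.choice(len(train), size=max(n_store, 1), replace=False)
        d_store = [train[i] for i in sorted(idx)]
    run_cfg = cfg
    if cfg.n_hard > len(d_store):
        warnings.warn(f"n_hard={cfg.n_hard} exceeds memory buffer size "
                      f"{len(d_store)}; lowering n_hard")
        run_cfg = replace(cfg, n_hard=len(d_store))
    history = _run_adversarial_loop(C, G, d_store, dataset.split("val"),
                                    run_cfg, seeds)
    history.sub_seeds["store_size"] = len(d_store)
    return C, history


def train_generator_adversarially(G, C, dataset: ToyDataset, cfg: AugmentConfig):
    """Cautionary mode: ascend the *generator parameters* against C.

    Alternates gradient ascent of G's parameters on the classifier loss over
    synthetic data with one-epoch classifier updates on D_train U D_syn.
    Nothing constrains G's outputs to remain realistic, and the per-epoch
    fidelity log (mean pixel distance of G's counterfactuals to the
    simulator's) measures the damage.  Requires a trainable generator.
    """
    if not getattr(G, "trainable", False):
        raise TypeError("train_generator_adversarially requires a trainable "
                        "neural generator, not the frozen oracle")
    seeds = _sub_seeds(cfg.seed)
    train = dataset.split("train")
    oracle = dataset.oracle()
    rng = np.random.default_rng(seeds["data_order"])
    history = RunHistory(sub_seeds=dict(seeds))
    # fixed probe set for the fidelity log
    probe_idx = rng.choice(len(train), size=min(32, len(train)), replace=False)
    probe = [train[i] for i in probe_idx]
    probe_ages = rng.uniform(cfg.clip_range[0], cfg.clip_range[1], size=len(probe))
    oracle_probe = oracle.generate(probe, probe_ages)

    for epoch in range(cfg.gvc_epochs):
        idx = rng.choice(len(train), size=min(cfg.gvc_n_syn, len(train)),
                         replace=False)
        batch = [train[i] for i in idx]
        ages = rng.uniform(cfg.clip_range[0], cfg.clip_range[1], size=len(batch))
        # ascend G on the classifier loss of the synthetic batch
        imgs = G.generate(batch, ages)
        dloss = C.input_gradient(imgs, labels_of(batch)) / len(batch)
        G.ascent_step(batch, ages, dloss, cfg.generator_lr)
        d_syn = synthesize_counterfactuals(batch, ages, G)
        train_loss = classifier_update(C, train, d_syn, cfg, rng)
        fidelity = float(np.mean(np.abs(G.generate(probe, probe_ages)
                                        - oracle_probe)))
        history.records.append(dict(iteration=epoch, train_loss=train_loss,
                                    fidelity_to_oracle=fidelity,
                                    target_ages=ages.copy()))
    return G, C, history
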