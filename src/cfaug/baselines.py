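"""Comparison strategies under the same classifier/generator contracts.

* RSRS — random selection + random synthesis (the typical "generate and
  merge" augmentation strategy).
* HSRS — hard selection + random synthesis.
* RSAT — random selection + adversarial target-age training (the proposed
  loop minus hard selection).
* JTT — "just train twice": oversample the misclassified training samples
  ``lambda_up`` times and retrain; no generator involved.

All baselines mutate and return the classifier they are given, so a single
runner can execute {naive, rsrs, hsrs, rsat, jtt, proposed} from one config
and emit one comparison table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .adversarial import (AugmentConfig, adversarial_augment, classifier_update,
                          select_hard_samples, synthesize_counterfactuals)
from .toyworld import ToyDataset, images_of, labels_of

__all__ = ["BaselineConfig", "rsrs", "hsrs", "rsat", "jtt"]


@dataclass
class BaselineConfig:
    """Shared baseline knobs: N selected samples, 5 syntheses each (500
    synthetic total in the reference setting), k one-epoch retraining passes,
    and the JTT oversampling factor lambda_up=2."""

    n_select: int = 100
    n_synthesis_per_sample: int = 5
    k: int = 5
    lambda_up: int = 2
    classifier_lr: float = 1e-4
    clip_range: tuple[float, float] = (60.0, 90.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_select", "n_synthesis_per_sample", "k", "lambda_up"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _random_synthesis(C, G, dataset, cfg: BaselineConfig, selection: str):
    train = dataset.split("train")
    rng = np.random.default_rng(cfg.seed)
    if selection == "random":
        idx = rng.choice(len(train), size=cfg.n_select, replace=False)
        chosen = [train[i] for i in sorted(idx)]
    else:
        chosen = select_hard_samples(C, train, cfg.n_select)
    sources, ages = [], []
    for s in chosen:
        for _ in range(cfg.n_synthesis_per_sample):
            sources.append(s)
            ages.append(rng.uniform(*cfg.clip_range))
    d_syn = synthesize_counterfactuals(sources, np.asarray(ages), G)
    up_cfg = AugmentConfig(n_hard=1, classifier_lr=cfg.classifier_lr, seed=cfg.seed)
    for _ in range(cfg.k):
        classifier_update(C, train, d_syn, up_cfg, rng)
    return C


def rsrs(C, G, dataset: ToyDataset, cfg: BaselineConfig):
    """Random selection + random synthesis: uniform random target ages over
    the clip range, k one-epoch passes on the combined set."""
    return _random_synthesis(C, G, dataset, cfg, selection="random")


def hsrs(C, G, dataset: ToyDataset, cfg: BaselineConfig):
    """Hard selection + random synthesis."""
    return _random_synthesis(C, G, dataset, cfg, selection="hard")


def rsat(C, G, dataset: ToyDataset, cfg: AugmentConfig):
    """Random selection + adversarial training: the proposed loop with the
    hard-sample selection replaced by a uniform random draw."""
    return adversarial_augment(C, G, dataset, replace(cfg, selection="random"))


def jtt(C, dataset: ToyDataset, cfg: BaselineConfig):
    """Just Train Twice: oversample 0/1-misclassified training samples
    ``lambda_up`` times and retrain for k one-epoch passes."""
    train = dataset.split("train")
    pred = (C.predict_proba(images_of(train)) > 0.5).astype(int)
    y = labels_of(train)
    errors = [s for s, p, t in zip(train, pred, y) if p != t]
    if not errors:
        warnings.warn("JTT error set is empty; plain retraining")
    d_up = list(train) + [s for s in errors for _ in range(cfg.lambda_up - 1)]
    X, yy = images_of(d_up), labels_of(d_up)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.k):
        C.fit_epoch(X, yy, cfg.classifier_lr, rng)
    return C
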