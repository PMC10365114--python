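"""Differentiable synthetic ageing-brain simulator.

A stylised 2D "brain slice" phantom: an elliptic tissue shell containing two
dark lateral-ventricle lobes that enlarge with age (atrophy), plus two small
dark temporal-horn spots that are essentially absent in controls and
pronounced in AD.  Diagnosis additionally adds a fixed offset ``beta_ad`` to
the effective atrophy, so an AD brain resembles a control roughly nine years
older — advanced age and disease are visually confusable, which is exactly
the ambiguity the adversarial augmentation method exploits.

All region edges are sigmoid-smoothed, and every age-dependent quantity is
linear in age, so the map ``age -> image`` is smooth and its derivative is
available in closed form (:func:`render_with_age_grad`).  This makes the
built-in :class:`OracleGenerator` a counterfactual generator that is exactly
differentiable in the target age, standing in for a pre-trained conditional
generative model.

Geometry lives in normalised [-1, 1]^2 coordinates; the pixel size is purely
a resolution knob.  Intensities lie in [-1, +1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

log = logging.getLogger("cfaug.toyworld")

__all__ = [
    "RenderConfig",
    "SubjectParams",
    "ImageSample",
    "ToyDataset",
    "render",
    "render_with_age_grad",
    "dark_interior_area",
    "sample_dataset",
    "make_spurious_dataset",
    "oracle_generator",
    "OracleGenerator",
    "images_of",
    "labels_of",
    "ages_of",
    "load_nifti_slices",
]

AGE_LO, AGE_HI = 60.0, 90.0
_AGE_SPAN = AGE_HI - AGE_LO


@dataclass(frozen=True)
class RenderConfig:
    """Knobs of the phantom renderer.

    ``beta_ad`` is the diagnosis offset on the effective-atrophy axis in
    units of the full age range (0.3 ~ +9 years).  ``tau`` is the sigmoid
    edge temperature in squared-elliptic-radius units; ``sigma_noise`` is
    additive Gaussian pixel noise applied once at dataset creation (the
    gradient path is always noise-free).
    """

    size: int = 64
    tau: float = 0.02
    beta_ad: float = 0.3
    sigma_noise: float = 0.02
    outer_axes: tuple[float, float] = (0.80, 0.88)
    outer_shrink: float = 0.14            # fractional shrink per unit *age*
    vent_centers: tuple = ((-0.14, 0.05), (0.14, 0.05))
    vent_axes: tuple[float, float] = (0.06, 0.16)
    vent_growth: tuple[float, float] = (0.14, 0.08)
    horn_base: float = 0.025
    horn_ad: float = 0.05                 # extra horn radius when AD
    horn_age_gain: float = 0.02           # mild horn growth with age (AD only)
    tissue: float = 0.35
    texture_amp: float = 0.10
    dark: float = -0.75
    background: float = -1.0


# module-wide default
DEFAULT_RENDER = RenderConfig()


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject anatomy: small multiplicative jitter on the base geometry,
    plus the subject's (mirrored) temporal-horn position.

    Horn position varies across subjects, so the AD signature is not tied to
    fixed pixels and is genuinely harder to learn than global shell size.
    Identical subject_id (same sampling seed) yields identical parameters;
    counterfactual generation re-renders the same subject, so identity is
    preserved by construction.
    """

    subject_id: int
    base_outer_axes: tuple[float, float]
    base_ventricle_axes: tuple[float, float]
    texture_seed: int
    horn_pos: tuple[float, float] = (0.47, 0.18)


@dataclass
class ImageSample:
    image: np.ndarray          # (S, S) grayscale in [-1, +1]
    age: float
    diagnosis: int             # CN=0, AD=1
    subject: SubjectParams
    split: str                 # train / val / test / syn
    sample_id: int


@dataclass
class ToyDataset:
    samples: list
    age_bins: list = field(default_factory=lambda: [(60.0, 70.0), (70.0, 80.0), (80.0, 90.0)])
    provenance: dict = field(default_factory=dict)

    def split(self, name: str) -> list:
        return [s for s in self.samples if s.split == name]

    @property
    def render_config(self) -> RenderConfig:
        cfg = self.provenance.get("render", {})
        if not cfg:
            return DEFAULT_RENDER
        # YAML round-trips tuples as (nested) lists
        def detuple(v):
            if isinstance(v, (list, tuple)):
                return tuple(detuple(x) for x in v)
            return v
        return RenderConfig(**{k: detuple(v) for k, v in cfg.items()})

    def oracle(self) -> "OracleGenerator":
        return OracleGenerator(self.render_config)

    # -- persistence: compressed array container + delimited metadata table
    def save(self, outdir) -> None:
        import pathlib, yaml

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(outdir / "images.npz",
                            images=np.stack([s.image for s in self.samples]))
        rows = []
        for s in self.samples:
            rows.append(dict(sample_id=s.sample_id, subject_id=s.subject.subject_id,
                             age=s.age, diagnosis=s.diagnosis, split=s.split,
                             outer_ax=s.subject.base_outer_axes[0],
                             outer_ay=s.subject.base_outer_axes[1],
                             vent_ax=s.subject.base_ventricle_axes[0],
                             vent_ay=s.subject.base_ventricle_axes[1],
                             horn_x=s.subject.horn_pos[0],
                             horn_y=s.subject.horn_pos[1],
                             texture_seed=s.subject.texture_seed))
        pd.DataFrame(rows).to_csv(outdir / "meta.csv", index=False,
                                  float_format="%.17g")
        with open(outdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump({"age_bins": [list(b) for b in self.age_bins],
                            **self.provenance}, fh)

    @classmethod
    def load(cls, outdir) -> "ToyDataset":
        import pathlib, yaml

        outdir = pathlib.Path(outdir)
        images = np.load(outdir / "images.npz")["images"]
        meta = pd.read_csv(outdir / "meta.csv", float_precision="round_trip")
        with open(outdir / "provenance.yaml") as fh:
            prov = yaml.safe_load(fh)
        age_bins = [tuple(b) for b in prov.pop("age_bins")]
        samples = []
        for i, row in meta.iterrows():
            subj = SubjectParams(int(row.subject_id),
                                 (row.outer_ax, row.outer_ay),
                                 (row.vent_ax, row.vent_ay),
                                 int(row.texture_seed),
                                 horn_pos=(row.horn_x, row.horn_y))
            samples.append(ImageSample(images[i], float(row.age), int(row.diagnosis),
                                       subj, str(row.split), int(row.sample_id)))
        return cls(samples, age_bins=age_bins, provenance=prov)


def images_of(samples) -> np.ndarray:
    return np.stack([s.image for s in samples])


def labels_of(samples) -> np.ndarray:
    return np.array([s.diagnosis for s in samples])


def ages_of(samples) -> np.ndarray:
    return np.array([s.age for s in samples], dtype=float)


# ---------------------------------------------------------------------------
# rendering


def _texture(subject: SubjectParams, X: np.ndarray, Y: np.ndarray,
             cfg: RenderConfig) -> np.ndarray:
    """Smooth per-subject intensity field, independent of age."""
    rng = np.random.default_rng(subject.texture_seed)
    field_ = np.zeros_like(X)
    for _ in range(4):
        fx, fy = rng.uniform(0.4, 1.6, size=2)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = cfg.texture_amp / 4.0 * rng.uniform(0.5, 1.0)
        field_ += amp * np.sin(2.0 * np.pi * (fx * X + fy * Y) + phase)
    return field_


def _region(X, Y, cx, cy, ax, ay, dax, day, tau):
    """Soft elliptic indicator s and its age-derivative ds.

    s = sigmoid((1 - u)/tau) with u the squared elliptic radius; dax/day are
    d(semi-axis)/d(age) in years^-1.
    """
    dx2 = (X - cx) ** 2
    dy2 = (Y - cy) ** 2
    u = dx2 / ax**2 + dy2 / ay**2
    s = expit((1.0 - u) / tau)
    du = -2.0 * dx2 / ax**3 * dax - 2.0 * dy2 / ay**3 * day
    ds = s * (1.0 - s) * (-du) / tau
    return s, ds


def _render_core(subject: SubjectParams, age: float, diagnosis: int,
                 size: int, cfg: RenderConfig):
    """Noiseless render plus analytic d(image)/d(age)."""
    t_age = (age - AGE_LO) / _AGE_SPAN
    t = t_age + cfg.beta_ad * diagnosis           # effective atrophy
    dt = 1.0 / _AGE_SPAN                          # d t / d age (years^-1)

    coords = np.linspace(-1.0, 1.0, size)
    X, Y = np.meshgrid(coords, coords)

    # outer tissue shell: global shrinkage is driven by age alone, so shell
    # size is a diagnosis-independent ageing signature; disease-sensitive
    # atrophy lives in the interior (ventricles, horns)
    oax = subject.base_outer_axes[0] * (1.0 - cfg.outer_shrink * t_age)
    oay = subject.base_outer_axes[1] * (1.0 - cfg.outer_shrink * t_age)
    doax = -subject.base_outer_axes[0] * cfg.outer_shrink * dt
    doay = -subject.base_outer_axes[1] * cfg.outer_shrink * dt

    tissue = cfg.tissue + _texture(subject, X, Y, cfg)

    s, ds = _region(X, Y, 0.0, 0.0, oax, oay, doax, doay, cfg.tau)
    img = cfg.background + s * (tissue - cfg.background)
    dimg = ds * (tissue - cfg.background)

    # dark interior regions painted over sequentially
    regions = []
    vax = subject.base_ventricle_axes[0] + cfg.vent_growth[0] * t
    vay = subject.base_ventricle_axes[1] + cfg.vent_growth[1] * t
    # degenerate-geometry guard: ventricles must stay inside the shell
    max_vax, max_vay = 0.55 * oax, 0.55 * oay
    dvax, dvay = cfg.vent_growth[0] * dt, cfg.vent_growth[1] * dt
    if vax > max_vax or vay > max_vay:
        log.warning("ventricle axes (%.3f, %.3f) exceed shell; clamped", vax, vay)
        vax, vay = min(vax, max_vax), min(vay, max_vay)
        dvax = dvay = 0.0
    for (cx, cy) in cfg.vent_centers:
        regions.append((cx, cy, vax, vay, dvax, dvay))

    rh = cfg.horn_base + diagnosis * (cfg.horn_ad + cfg.horn_age_gain * t_age)
    drh = diagnosis * cfg.horn_age_gain * dt
    hx, hy = subject.horn_pos
    for cx in (-hx, hx):
        regions.append((cx, hy, rh, rh, drh, drh))

    for (cx, cy, ax, ay, dax, day) in regions:
        r, dr = _region(X, Y, cx, cy, ax, ay, dax, day, cfg.tau)
        dimg = (1.0 - r) * dimg + dr * (cfg.dark - img)
        img = img + r * (cfg.dark - img)

    return img, dimg


def render(subject: SubjectParams, age: float, diagnosis: int,
           size: int = 64, render_cfg: RenderConfig | None = None,
           noise_seed: int | None = None) -> np.ndarray:
    """Render one phantom slice; deterministic given all arguments.

    ``noise_seed`` adds frozen Gaussian pixel noise (sigma from the config)
    and clips back into [-1, 1]; pass None for a noiseless image.
    """
    cfg = render_cfg or DEFAULT_RENDER
    if size < 32:
        raise ValueError("size must be >= 32")
    img, _ = _render_core(subject, age, diagnosis, size, cfg)
    if noise_seed is not None and cfg.sigma_noise > 0:
        rng = np.random.default_rng(noise_seed)
        img = img + rng.normal(0.0, cfg.sigma_noise, size=img.shape)
    return np.clip(img, -1.0, 1.0)


def render_with_age_grad(subject: SubjectParams, age: float, diagnosis: int,
                         size: int = 64,
                         render_cfg: RenderConfig | None = None):
    """Noiseless render and analytic d(image)/d(age), both (S, S)."""
    cfg = render_cfg or DEFAULT_RENDER
    return _render_core(subject, age, diagnosis, size, cfg)


def dark_interior_area(image: np.ndarray, lo: float = -0.92, hi: float = -0.4) -> float:
    """Soft count of dark pixels strictly inside tissue (ventricles + horns)."""
    return float(np.sum((image > lo) & (image < hi)))


# ---------------------------------------------------------------------------
# dataset sampling


def _make_subject(subject_id: int, rng: np.random.Generator,
                  cfg: RenderConfig) -> SubjectParams:
    jo = rng.uniform(0.95, 1.05, size=2)
    jv = rng.uniform(0.95, 1.05, size=2)
    horn = (float(rng.uniform(0.35, 0.55)), float(rng.uniform(0.0, 0.35)))
    return SubjectParams(
        subject_id=subject_id,
        base_outer_axes=(cfg.outer_axes[0] * jo[0], cfg.outer_axes[1] * jo[1]),
        base_ventricle_axes=(cfg.vent_axes[0] * jv[0], cfg.vent_axes[1] * jv[1]),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        horn_pos=horn,
    )


def _partition(n: int, fracs) -> list:
    """Largest-remainder split of n into len(fracs) integer counts."""
    fracs = np.asarray(fracs, dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError(f"split fractions must sum to 1, got {fracs}")
    raw = fracs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def _draw_age(rng: np.random.Generator, age_law: dict) -> float:
    kind = age_law.get("kind", "uniform")
    lo = float(age_law.get("lo", AGE_LO))
    hi = float(age_law.get("hi", AGE_HI))
    if kind == "uniform":
        return float(rng.uniform(lo, hi))
    if kind == "normal":
        # truncated by rejection; the toy range is narrow so this is cheap
        while True:
            a = rng.normal(float(age_law["mean"]), float(age_law["sd"]))
            if lo <= a <= hi:
                return float(a)
    raise ValueError(f"unknown age law kind {kind!r}")


def sample_dataset(n_subjects: int, age_law: dict | None = None,
                   ad_fraction: float = 0.5, seed: int = 0,
                   split_fracs=(0.7, 0.1, 0.2), size: int = 64,
                   render_cfg: RenderConfig | None = None) -> ToyDataset:
    """Balanced, uncoupled cohort: one slice per subject, diagnosis independent of age."""
    cfg = render_cfg or DEFAULT_RENDER
    cfg = replace(cfg, size=size)
    age_law = age_law or {"kind": "uniform"}
    counts = _partition(n_subjects, split_fracs)
    if any(c == 0 for c in counts):
        raise ValueError(f"empty split with n_subjects={n_subjects}, fracs={split_fracs}")
    rng = np.random.default_rng(seed)
    split_names = ["train", "val", "test"]
    splits = sum([[nm] * c for nm, c in zip(split_names, counts)], [])
    samples = []
    for sid in range(n_subjects):
        subj = _make_subject(sid, rng, cfg)
        age = _draw_age(rng, age_law)
        diag = int(rng.random() < ad_fraction)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        img = render(subj, age, diag, size=size, render_cfg=cfg, noise_seed=noise_seed)
        samples.append(ImageSample(img, age, diag, subj, splits[sid], sid))
    prov = {"generator": "sample_dataset", "n_subjects": n_subjects,
            "ad_fraction": ad_fraction, "seed": seed,
            "split_fracs": list(split_fracs), "age_law": age_law,
            "render": cfg.__dict__.copy()}
    return ToyDataset(samples, provenance=prov)


def make_spurious_dataset(n: int, age_split: float = 75.0, seed: int = 0,
                          split_fracs=(0.6, 0.15, 0.25), size: int = 64,
                          render_cfg: RenderConfig | None = None) -> ToyDataset:
    """Cohort with an age/diagnosis confound in train and val.

    Training (and validation) couple the label to the age group: every AD
    subject is younger than ``age_split`` and every CN subject is at least
    ``age_split`` (young->AD, old->CN).  The test split is uncoupled, so all
    four (diagnosis x age-group) cells are populated and the two cells absent
    from training measure how badly the classifier absorbed the confound.
    """
    if not AGE_LO < age_split < AGE_HI:
        raise ValueError(f"age_split must lie inside ({AGE_LO}, {AGE_HI})")
    cfg = replace(render_cfg or DEFAULT_RENDER, size=size)
    counts = _partition(n, split_fracs)
    if any(c == 0 for c in counts):
        raise ValueError("n too small to populate all splits")
    rng = np.random.default_rng(seed)
    split_names = ["train", "val", "test"]
    splits = sum([[nm] * c for nm, c in zip(split_names, counts)], [])
    samples = []
    for sid in range(n):
        subj = _make_subject(sid, rng, cfg)
        diag = int(rng.random() < 0.5)
        if splits[sid] == "test":
            age = float(rng.uniform(AGE_LO, AGE_HI))
        elif diag == 1:  # AD -> young
            age = float(rng.uniform(AGE_LO, age_split))
        else:            # CN -> old
            age = float(rng.uniform(age_split, AGE_HI))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        img = render(subj, age, diag, size=size, render_cfg=cfg, noise_seed=noise_seed)
        samples.append(ImageSample(img, age, diag, subj, splits[sid], sid))
    ds = ToyDataset(samples,
                    age_bins=[(AGE_LO, age_split), (age_split, AGE_HI)],
                    provenance={"generator": "make_spurious_dataset", "n": n,
                                "age_split": age_split, "seed": seed,
                                "split_fracs": list(split_fracs),
                                "render": cfg.__dict__.copy()})
    test = ds.split("test")
    for d in (0, 1):
        for young in (True, False):
            k = sum(1 for s in test
                    if s.diagnosis == d and (s.age < age_split) == young)
            if k == 0:
                raise ValueError("n too small: empty diagnosis x age-group test cell")
    return ds


# ---------------------------------------------------------------------------
# oracle counterfactual generator


def oracle_generator(sample: ImageSample, target_age: float,
                     render_cfg: RenderConfig | None = None) -> np.ndarray:
    """Counterfactual of one sample at ``target_age``.

    Same subject and diagnosis, noiseless; target ages above the sample's age
    yield ageing, below it rejuvenation — one mechanism covers both
    directions.
    """
    cfg = render_cfg or DEFAULT_RENDER
    size = sample.image.shape[0]
    img, _ = _render_core(sample.subject, float(target_age), sample.diagnosis, size, cfg)
    return np.clip(img, -1.0, 1.0)


class OracleGenerator:
    """GeneratorContract view of the simulator itself.

    ``generate`` re-renders each sample's subject at the requested target
    age; ``generate_with_age_grad`` additionally returns the analytic
    per-sample d(image)/d(target age).  It has no trainable parameters.
    """

    trainable = False

    def __init__(self, render_cfg: RenderConfig | None = None):
        self.render_cfg = render_cfg or DEFAULT_RENDER

    def generate(self, samples, target_ages) -> np.ndarray:
        target_ages = np.asarray(target_ages, dtype=float)
        return np.stack([oracle_generator(s, a, self.render_cfg)
                         for s, a in zip(samples, target_ages)])

    def generate_with_age_grad(self, samples, target_ages):
        imgs, grads = [], []
        for s, a in zip(samples, np.asarray(target_ages, dtype=float)):
            img, dimg = _render_core(s.subject, float(a), s.diagnosis,
                                     s.image.shape[0], self.render_cfg)
            imgs.append(img)
            grads.append(dimg)
        return np.stack(imgs), np.stack(grads)


# ---------------------------------------------------------------------------
# optional real-data ingestion (untested against real cohorts)


def load_nifti_slices(meta_table, root=".", axial_index: int | None = None,
                      size: int | None = None) -> ToyDataset:
    """Read pre-registered 2D slices from NIfTI volumes plus a metadata table.

    ``meta_table`` is a CSV path or DataFrame with columns
    (path, subject_id, age, diagnosis, split).  The middle axial slice (or
    ``axial_index``) is extracted, intensities are clipped at the 99.5th
    percentile and rescaled to [-1, +1].  Subjects get placeholder anatomy
    parameters; the oracle generator does not apply to real data.
    """
    import pathlib

    import nibabel as nib

    meta = pd.read_csv(meta_table) if not isinstance(meta_table, pd.DataFrame) else meta_table
    samples = []
    for i, row in meta.iterrows():
        vol = np.asanyarray(nib.load(pathlib.Path(root) / row["path"]).dataobj)
        z = axial_index if axial_index is not None else vol.shape[2] // 2
        sl = np.asarray(vol[:, :, z], dtype=float)
        v995 = np.percentile(sl, 99.5)
        sl = np.clip(sl, 0, v995) / max(v995, 1e-12) * 2.0 - 1.0
        subj = SubjectParams(int(row["subject_id"]), DEFAULT_RENDER.outer_axes,
                             DEFAULT_RENDER.vent_axes, 0)
        samples.append(ImageSample(sl, float(row["age"]), int(row["diagnosis"]),
                                   subj, str(row["split"]), int(i)))
    return ToyDataset(samples, provenance={"generator": "load_nifti_slices"})
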