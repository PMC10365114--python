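"""Differentiable conditioning of the counterfactual generator.

The generator is conditioned on a vector ``v = (age, diagnosis)``.  A naive
ordinal encoding of age (``3 -> [1,1,1,0,0]``) is discrete: adding a gradient
step to it produces a vector that is no longer ordinal, so gradients cannot
flow back into the conditioning factor.  This module instead normalises the
factors into the unit interval and maps them through a random Fourier feature
basis

    gamma(v) = [p_1 cos(2*pi*b_1.v), p_1 sin(2*pi*b_1.v), ...,
                p_m cos(2*pi*b_m.v), p_m sin(2*pi*b_m.v)]

which is infinitely differentiable in ``v`` and therefore in the target age.
Frequencies ``b_j`` are drawn i.i.d. from N(0, mu_scale^2) and frozen; the
coefficients satisfy ``p_j^2 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AGE_RANGE",
    "C_AD",
    "EPS",
    "ConditionVector",
    "EncodingSpec",
    "normalize_conditions",
    "denormalize_age",
    "age_norm_derivative",
    "make_encoding_spec",
    "fourier_encode",
    "fourier_encode_batch",
    "fourier_jacobian",
    "ordinal_encode",
]

#: Default closed age range, in years.
AGE_RANGE = (60.0, 90.0)

#: Normalised value of an AD diagnosis (CN maps to 0).  Both classes lie in
#: [0, 1) and are well separated.
C_AD = 0.5

#: Slack in the normalisation denominator so the upper age bound maps
#: strictly below 1 (the encoding domain is the half-open unit interval).
EPS = 1e-6


@dataclass(frozen=True)
class ConditionVector:
    """Target age (years) plus binary diagnosis (CN=0, AD=1)."""

    age: float
    diagnosis: int

    def normalized(self, age_range: tuple[float, float] = AGE_RANGE) -> np.ndarray:
        return normalize_conditions(self.age, self.diagnosis, age_range)


def normalize_conditions(
    age: float,
    diagnosis: int,
    age_range: tuple[float, float] = AGE_RANGE,
) -> np.ndarray:
    """Map (age, diagnosis) into the half-open unit square.

    Component 0 is ``(age - lo) / (hi - lo + EPS)``; component 1 is 0 for CN
    and :data:`C_AD` for AD.  Differentiable in age with constant derivative
    :func:`age_norm_derivative`.  Ages outside the configured range raise
    ``ValueError`` — clipping is the caller's responsibility.
    """
    lo, hi = float(age_range[0]), float(age_range[1])
    if not hi > lo:
        raise ValueError(f"age_range must be increasing, got {age_range}")
    age = float(age)
    if age < lo or age > hi:
        raise ValueError(f"age {age} outside configured range [{lo}, {hi}]")
    if diagnosis not in (0, 1):
        raise ValueError(f"diagnosis must be 0 (CN) or 1 (AD), got {diagnosis}")
    return np.array([(age - lo) / (hi - lo + EPS), C_AD * diagnosis])


def denormalize_age(v0: float, age_range: tuple[float, float] = AGE_RANGE) -> float:
    """Inverse of the age component of :func:`normalize_conditions`."""
    lo, hi = float(age_range[0]), float(age_range[1])
    return lo + float(v0) * (hi - lo + EPS)


def age_norm_derivative(age_range: tuple[float, float] = AGE_RANGE) -> float:
    """d(normalised age)/d(age in years)."""
    lo, hi = float(age_range[0]), float(age_range[1])
    return 1.0 / (hi - lo + EPS)


@dataclass
class EncodingSpec:
    """Frozen random Fourier basis.

    ``b`` has shape (d, m) with entries ~ N(0, mu_scale^2); ``p`` holds the m
    coefficients (all 1 by default, so p_j^2 = 1).  The basis is regenerated
    from ``seed`` on construction and never stored on disk.
    """

    m: int
    mu_scale: float
    seed: int
    d: int = 2
    p: np.ndarray = field(init=False, repr=False)
    b: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.m < 1 or self.d < 1:
            raise ValueError("m and d must be positive integers")
        if self.mu_scale <= 0:
            raise ValueError("mu_scale must be positive")
        rng = np.random.default_rng(self.seed)
        self.b = rng.normal(0.0, self.mu_scale, size=(self.d, self.m))
        self.p = np.ones(self.m)

    # -- serialization: config only, the basis is reproducible from the seed.
    def to_config(self) -> dict:
        return {"m": self.m, "mu_scale": self.mu_scale, "seed": self.seed, "d": self.d}

    @classmethod
    def from_config(cls, cfg: dict) -> "EncodingSpec":
        return cls(m=int(cfg["m"]), mu_scale=float(cfg["mu_scale"]),
                   seed=int(cfg["seed"]), d=int(cfg.get("d", 2)))

    @property
    def out_dim(self) -> int:
        return 2 * self.m


def make_encoding_spec(
    m: int = 100, mu_scale: float = 10.0, seed: int = 0, d: int = 2
) -> EncodingSpec:
    """Construct the default encoding basis (m=100, mu_scale=10, d=2 -> 200-dim)."""
    return EncodingSpec(m=m, mu_scale=mu_scale, seed=seed, d=d)


def _check_v(v: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != spec.d:
        raise ValueError(f"condition vector has length {v.shape[-1]}, spec expects d={spec.d}")
    return v


def fourier_encode(v: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Encode one condition vector; output length 2m, cos/sin interleaved per frequency."""
    v = _check_v(v, spec)
    phase = 2.0 * np.pi * (v @ spec.b)          # (m,)
    out = np.empty(2 * spec.m)
    out[0::2] = spec.p * np.cos(phase)
    out[1::2] = spec.p * np.sin(phase)
    return out


def fourier_encode_batch(V: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Encode a batch of condition vectors, shape (n, d) -> (n, 2m)."""
    V = _check_v(np.atleast_2d(V), spec)
    phase = 2.0 * np.pi * (V @ spec.b)          # (n, m)
    out = np.empty((V.shape[0], 2 * spec.m))
    out[:, 0::2] = spec.p * np.cos(phase)
    out[:, 1::2] = spec.p * np.sin(phase)
    return out


def fourier_jacobian(v: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Analytic Jacobian d(gamma)/d(v), shape (2m, d).

    Row 2j   : d/dv of p_j cos(2*pi*b_j.v) = -2*pi*p_j sin(2*pi*b_j.v) b_j
    Row 2j+1 : d/dv of p_j sin(2*pi*b_j.v) =  2*pi*p_j cos(2*pi*b_j.v) b_j
    """
    v = _check_v(v, spec)
    phase = 2.0 * np.pi * (v @ spec.b)          # (m,)
    J = np.empty((2 * spec.m, spec.d))
    J[0::2, :] = (-2.0 * np.pi * spec.p * np.sin(phase))[:, None] * spec.b.T
    J[1::2, :] = (2.0 * np.pi * spec.p * np.cos(phase))[:, None] * spec.b.T
    return J


def ordinal_encode(value: int, n_bins: int) -> np.ndarray:
    """Thermometer/ordinal encoding: first ``value`` entries 1, rest 0.

    Kept as the non-differentiable foil: adding a real-valued gradient step to
    an ordinal vector breaks its 1..1,0..0 structure, which is why the Fourier
    encoding above exists.
    """
    value = int(value)
    if not 0 <= value <= n_bins:
        raise ValueError(f"value {value} outside [0, {n_bins}]")
    out = np.zeros(n_bins)
    out[:value] = 1.0
    return out
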