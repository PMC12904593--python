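"""Synthetic functional data with a known magnitude-based ground truth.

Curves follow f_i(t) = s_i * t + sin(2*pi*(t + p_i)) on a uniform grid in
[0, 1], with slopes s_i ~ U(3.5, 4.5) and phases p_i ~ U(0, 0.2).  Because
the sine integrates to zero over the full period, the true integral of curve
i is exactly s_i / 2, so the ground-truth ranking is the descending slope
order.  Five noise schemes (Gaussian, spike, amplitude, Poisson, Laplace),
three missingness mechanisms (MCAR / MAR / MNAR) and whole-curve Gaussian
outlier contamination reproduce the disturbance designs of the Monte-Carlo
study; every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from .curves import RawCurveSet, TimeGrid
from .exceptions import InvalidArgumentError

__all__ = [
    "SimulationSpec",
    "NoiseSpec",
    "MissingSpec",
    "OutlierSpec",
    "generate_truth",
    "add_noise",
    "apply_missingness",
    "inject_outliers",
]

NOISE_KINDS = ("gaussian", "spike", "amplitude", "poisson", "laplace")
MISSING_MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass(frozen=True)
class SimulationSpec:
    n_curves: int = 100
    n_times: int = 30
    slope_low: float = 3.5
    slope_high: float = 4.5
    phase_low: float = 0.0
    phase_high: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_curves < 2 or self.n_times < 4:
            raise InvalidArgumentError("need at least 2 curves and 4 time points")
        if self.slope_low >= self.slope_high or self.phase_low >= self.phase_high:
            raise InvalidArgumentError("parameter bounds must be ordered")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NoiseSpec:
    """kind: gaussian|spike|amplitude|poisson|laplace; ``level`` is the sd,
    point fraction, rate or scale of the scheme."""

    kind: str
    level: float
    spike_factor: float = 5.0
    amplitude_factor: float = 2.0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise InvalidArgumentError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise InvalidArgumentError("noise level must be nonnegative")
        if self.kind in ("spike", "amplitude") and self.level > 1:
            raise InvalidArgumentError("point fractions cannot exceed 1")


@dataclass(frozen=True)
class MissingSpec:
    mechanism: str
    rate: float

    def __post_init__(self):
        if self.mechanism not in MISSING_MECHANISMS:
            raise InvalidArgumentError(f"unknown mechanism {self.mechanism!r}")
        if not (0 <= self.rate < 0.5):
            raise InvalidArgumentError("missing rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class OutlierSpec:
    proportion: float
    magnitude_mult: int = 1
    delta: float | None = None  # default: sd of the clean values

    def __post_init__(self):
        if not (0 <= self.proportion <= 0.3):
            raise InvalidArgumentError("outlier proportion must lie in [0, 0.3]")
        if self.magnitude_mult not in (1, 2, 3):
            raise InvalidArgumentError("magnitude multiplier must be 1, 2 or 3")


def generate_truth(spec: SimulationSpec):
    """Noise-free curves plus the exact integrals and the true ranking
    (1 = largest integral)."""
    rng = np.random.default_rng(spec.seed)
    s = rng.uniform(spec.slope_low, spec.slope_high, spec.n_curves)
    p = rng.uniform(spec.phase_low, spec.phase_high, spec.n_curves)
    t = np.linspace(0.0, 1.0, spec.n_times)
    values = s[:, None] * t[None, :] + np.sin(2 * np.pi * (t[None, :] + p[:, None]))
    raw = RawCurveSet(grid=TimeGrid(t), values=values)
    # closed form: int_0^1 (s t + sin(2 pi (t+p))) dt = s/2 (full sine period)
    true_integrals = s / 2.0
    true_ranking = rankdata(-true_integrals, method="average")
    return raw, true_integrals, true_ranking


def add_noise(raw: RawCurveSet, noise: NoiseSpec, seed: int = 0) -> RawCurveSet:
    """Apply one of the five disturbance schemes (identity at level 0)."""
    rng = np.random.default_rng(seed)
    N, T = raw.values.shape
    vals = raw.values.copy()
    if noise.level == 0:
        return raw.with_values(vals)
    if noise.kind == "gaussian":
        vals += rng.normal(0.0, noise.level, size=vals.shape)
    elif noise.kind == "laplace":
        vals += rng.laplace(0.0, noise.level, size=vals.shape)
    elif noise.kind == "poisson":
        # centred so the perturbation has mean zero
        vals += rng.poisson(noise.level, size=vals.shape) - noise.level
    elif noise.kind in ("spike", "amplitude"):
        # the affected sampling points are drawn once and shared by all
        # curves, so every curve is perturbed at the same times
        n_pts = math.ceil(noise.level * T)
        factor = noise.spike_factor if noise.kind == "spike" else noise.amplitude_factor
        cols = rng.choice(T, size=n_pts, replace=False)
        vals[:, cols] *= factor
    return raw.with_values(vals)


def apply_missingness(raw: RawCurveSet, spec: MissingSpec, seed: int = 0) -> RawCurveSet:
    """Mask entries by MCAR / MAR / MNAR, keeping >= 4 observed per curve.

    MAR drives the masking probability of (i, j) by the within-curve
    quantile of the previous observed value (the first point is never
    masked); MNAR by the quantile of |value - curve median|, so extreme
    values are more likely to go missing.
    """
    rng = np.random.default_rng(seed)
    N, T = raw.values.shape
    if spec.rate == 0:
        return raw.with_values(raw.values.copy())
    if spec.mechanism == "MCAR":
        probs = np.full((N, T), spec.rate)
    else:
        if spec.mechanism == "MAR":
            prev = raw.values[:, :-1]
            q = (rankdata(prev, method="average", axis=1)) / prev.shape[1]
            probs = np.zeros((N, T))
            probs[:, 1:] = _scaled_probs_rows(q, spec.rate * T / (T - 1))
        else:  # MNAR
            dev = np.abs(raw.values - np.median(raw.values, axis=1, keepdims=True))
            q = rankdata(dev, method="average", axis=1) / T
            probs = _scaled_probs_rows(q, spec.rate)
    mask = rng.random((N, T)) >= probs  # True = observed
    # per-curve floor: unmask the lowest-probability picks until >= 4 observed
    for i in range(N):
        short = 4 - int(mask[i].sum())
        if short > 0:
            hidden = np.flatnonzero(~mask[i])
            order = hidden[np.argsort(probs[i, hidden], kind="stable")]
            mask[i, order[:short]] = True
    return RawCurveSet(grid=raw.grid, values=raw.values.copy(),
                       observed_mask=mask, unit_names=list(raw.unit_names))


def _scaled_probs_rows(weight: np.ndarray, rate: float) -> np.ndarray:
    mean = weight.mean(axis=1, keepdims=True)
    out = np.where(mean > 0, weight * (rate / np.where(mean > 0, mean, 1.0)), rate)
    return np.clip(out, 0.0, 0.999)


def inject_outliers(raw: RawCurveSet, spec: OutlierSpec, seed: int = 0):
    """Contaminate ceil(proportion * N) whole curves with Gaussian noise of
    sd magnitude_mult * delta; returns (contaminated set, index set)."""
    rng = np.random.default_rng(seed)
    N = raw.n_curves
    n_out = math.ceil(spec.proportion * N)
    if n_out == 0:
        return raw.with_values(raw.values.copy()), np.asarray([], dtype=int)
    delta = spec.delta if spec.delta is not None else float(raw.values.std())
    idx = rng.choice(N, size=n_out, replace=False)
    vals = raw.values.copy()
    vals[idx] += rng.normal(0.0, spec.magnitude_mult * delta, size=(n_out, raw.n_times))
    return raw.with_values(vals), np.sort(idx)
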