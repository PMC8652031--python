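"""Synthetic benchmark generator.

Eleven base waveform families (7 cyclic, 4 non-cyclic) across a full
factorial grid of replicates (1, 2, 3), sampling intervals (1, 2, 4 h),
durations (36, 48, 72, 96 h) and noise levels (10-40% of waveform
amplitude) -- 144 sampling conditions in total -- plus missingness and
outlier degradation.  Parameter distributions below are declared,
reproducible substitutes for the original benchmark generator; they are
exposed via :func:`default_parameter_ranges` so runs can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from timecycle.types import ExpressionSet

__all__ = [
    "SamplingSpec",
    "WaveformSpec",
    "CYCLIC_SHAPES",
    "NONCYCLIC_SHAPES",
    "SHAPES",
    "waveform_value",
    "draw_waveform",
    "simulate_dataset",
    "grid_specs",
    "simulate_grid",
    "degrade_missing",
    "inject_outliers",
    "default_parameter_ranges",
]

CYCLIC_SHAPES = ("sine", "peak", "sawtooth", "linear_trend", "damped",
                 "amplified", "contractile")
NONCYCLIC_SHAPES = ("flat", "linear", "sigmoid", "exponential")
SHAPES = CYCLIC_SHAPES + NONCYCLIC_SHAPES

GRID_REPLICATES = (1, 2, 3)
GRID_INTERVALS_H = (1.0, 2.0, 4.0)
GRID_LENGTHS_H = (36.0, 48.0, 72.0, 96.0)
GRID_NOISE_FRACS = (0.1, 0.2, 0.3, 0.4)

_BASE_PERIOD_H = 24.0


@dataclass(frozen=True)
class SamplingSpec:
    """One cell of the benchmark grid."""

    interval_h: float
    length_h: float
    replicates: int
    noise_frac: float

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.length_h, self.interval_h)


@dataclass
class WaveformSpec:
    """A single simulated gene's noiseless expression curve."""

    shape: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def is_cyclic(self) -> bool:
        return self.shape in CYCLIC_SHAPES


def default_parameter_ranges() -> dict:
    """Documented parameter distributions used by :func:`draw_waveform`.

    ``amplitude`` is log-uniform over a 4-fold range and also sets the
    noise scale (sd = noise_frac * amplitude); phases are uniform over
    a full period; shape rates are uniform over the stated intervals.
    """
    return {
        "amplitude": ("log-uniform", 1.0, 4.0),
        "baseline": ("uniform", 6.0, 12.0),
        "phase_rad": ("uniform", 0.0, 2 * math.pi),
        "period_h": ("fixed", _BASE_PERIOD_H),
        "peak_sharpness": ("uniform", 2.0, 4.0),
        "sawtooth_asymmetry": ("uniform", 0.1, 0.9),
        "trend_slope_per_h": ("uniform times amplitude", 1 / 96.0, 1 / 24.0),
        "envelope_rate_per_h": ("uniform", math.log(2) / 48.0,
                                math.log(2) / 24.0),
        "contractile_shrink_per_h": ("uniform", 4.0 / 96.0, 10.0 / 96.0),
        "sigmoid_steepness_per_h": ("uniform", 0.15, 0.6),
        "sigmoid_midpoint_h": ("uniform", 12.0, 36.0),
        "exponential_rate_per_h": ("signed uniform", 0.01, 0.035),
    }


def waveform_value(w: WaveformSpec, t) -> np.ndarray:
    """Noiseless value(s) of waveform ``w`` at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    p = w.parameters
    a = p.get("amplitude", 1.0)
    b = p.get("baseline", 0.0)
    phi = p.get("phase_rad", 0.0)
    P = p.get("period_h", _BASE_PERIOD_H)
    w0 = 2 * np.pi / P
    shape = w.shape
    if shape == "sine":
        return a * np.sin(w0 * t + phi) + b
    if shape == "peak":
        kappa = p["sharpness"]
        return a * np.exp(kappa * (np.cos(w0 * t + phi) - 1.0)) + b
    if shape == "sawtooth":
        rho = p["asymmetry"]
        u = (t / P + phi / (2 * np.pi)) % 1.0
        tri = np.where(u < rho, u / rho, (1.0 - u) / (1.0 - rho))
        return b + 2 * a * (tri - 0.5)
    if shape == "linear_trend":
        c = p["trend_slope"]
        return a * np.sin(w0 * t + phi) + c * t + b
    if shape == "damped":
        lam = p["envelope_rate"]
        return a * np.exp(-lam * t) * np.sin(w0 * t + phi) + b
    if shape == "amplified":
        lam = p["envelope_rate"]
        return a * np.exp(lam * t) * np.sin(w0 * t + phi) + b
    if shape == "contractile":
        r = p["shrink_rate"]  # period P(t) = P - r t, linearly shrinking
        theta = -(2 * np.pi / r) * np.log1p(-r * t / P)
        return a * np.sin(theta + phi) + b
    if shape == "flat":
        return np.full_like(t, b)
    if shape == "linear":
        return b + p["slope"] * t
    if shape == "sigmoid":
        k = p["steepness"]
        t0 = p["midpoint"]
        return a / (1.0 + np.exp(-k * (t - t0))) + b
    if shape == "exponential":
        return a * np.exp(p["rate"] * t) + b
    raise ValueError(f"unknown shape {shape!r}")  # pragma: no cover


def draw_waveform(shape: str, rng: np.random.Generator) -> WaveformSpec:
    """Draw shape parameters from the documented ranges."""
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}")
    a = float(np.exp(rng.uniform(np.log(1.0), np.log(4.0))))
    params = {
        "amplitude": a,
        "baseline": float(rng.uniform(6.0, 12.0)),
        "phase_rad": float(rng.uniform(0.0, 2 * np.pi)),
        "period_h": _BASE_PERIOD_H,
    }
    if shape == "peak":
        params["sharpness"] = float(rng.uniform(2.0, 4.0))
    elif shape == "sawtooth":
        params["asymmetry"] = float(rng.uniform(0.1, 0.9))
    elif shape == "linear_trend":
        params["trend_slope"] = a * float(rng.uniform(1 / 96.0, 1 / 24.0))
    elif shape in ("damped", "amplified"):
        params["envelope_rate"] = float(
            rng.uniform(math.log(2) / 48.0, math.log(2) / 24.0))
    elif shape == "contractile":
        params["shrink_rate"] = float(rng.uniform(4.0 / 96.0, 10.0 / 96.0))
    elif shape == "linear":
        sign = rng.choice([-1.0, 1.0])
        params["slope"] = sign * a * float(rng.uniform(1 / 96.0, 1 / 24.0))
    elif shape == "sigmoid":
        params["steepness"] = float(rng.uniform(0.15, 0.6))
        params["midpoint"] = float(rng.uniform(12.0, 36.0))
    elif shape == "exponential":
        sign = rng.choice([-1.0, 1.0])
        params["rate"] = sign * float(rng.uniform(0.01, 0.035))
    return WaveformSpec(shape, params)


def simulate_dataset(
    spec: SamplingSpec,
    n_per_shape: int,
    rng: np.random.Generator,
) -> tuple[ExpressionSet, pd.DataFrame]:
    """Simulate 11 * n_per_shape genes under one sampling condition.

    Replicate columns are independent Gaussian noise draws
    (sd = noise_frac * amplitude) around a shared base curve.  Returns
    the expression set and a labels table (gene, shape, is_cyclic).
    """
    if n_per_shape < 1:
        raise ValueError("n_per_shape must be >= 1")
    times = spec.times()
    n_t = len(times)
    sample_times = np.tile(times, spec.replicates)
    rep_labels = np.repeat(np.arange(1, spec.replicates + 1), n_t)

    n_genes = len(SHAPES) * n_per_shape
    values = np.empty((n_genes, n_t * spec.replicates))
    gene_ids, shapes_col, cyclic_col, amp_col = [], [], [], []
    g = 0
    for shape in SHAPES:
        for i in range(n_per_shape):
            w = draw_waveform(shape, rng)
            base = waveform_value(w, times)
            sd = spec.noise_frac * w.parameters["amplitude"]
            noisy = base[None, :] + rng.normal(
                0.0, sd, size=(spec.replicates, n_t))
            values[g] = noisy.ravel()
            gene_ids.append(f"{shape}_{i:05d}")
            shapes_col.append(shape)
            cyclic_col.append(w.is_cyclic)
            amp_col.append(w.parameters["amplitude"])
            g += 1
    es = ExpressionSet(gene_ids, values, sample_times, rep_labels)
    labels = pd.DataFrame(
        {"gene": gene_ids, "shape": shapes_col, "is_cyclic": cyclic_col,
         "amplitude": amp_col})
    return es, labels


def grid_specs() -> list[SamplingSpec]:
    """The 144 sampling specifications of the full factorial grid."""
    return [
        SamplingSpec(interval_h=i, length_h=l, replicates=r, noise_frac=nf)
        for r in GRID_REPLICATES
        for i in GRID_INTERVALS_H
        for l in GRID_LENGTHS_H
        for nf in GRID_NOISE_FRACS
    ]


def simulate_grid(
    n_per_shape: int,
    seed: int = 0,
) -> Iterator[tuple[SamplingSpec, ExpressionSet, pd.DataFrame]]:
    """Lazily realize all 144 grid datasets.

    Each dataset gets an independent child generator derived from
    ``seed`` and its grid position, so any subset can be regenerated
    reproducibly and in any order.
    """
    specs = grid_specs()
    children = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, ss in zip(specs, children):
        es, labels = simulate_dataset(spec, n_per_shape,
                                      np.random.default_rng(ss))
        yield spec, es, labels


def degrade_missing(
    es: ExpressionSet,
    frac_missing: float,
    rng: np.random.Generator,
) -> ExpressionSet:
    """Mask floor(frac * n_samples) entries per gene, leaving >= 2 observed."""
    if not (0.0 <= frac_missing < 1.0):
        raise ValueError("frac_missing must be in [0, 1)")
    values = es.values.copy()
    n_s = es.n_samples
    n_mask = min(int(np.floor(frac_missing * n_s)), n_s - 2)
    if n_mask > 0:
        for g in range(es.n_genes):
            idx = rng.choice(n_s, size=n_mask, replace=False)
            values[g, idx] = np.nan
    return ExpressionSet(list(es.gene_ids), values, es.sample_times.copy(),
                         es.replicate_labels.copy())


def inject_outliers(
    es: ExpressionSet,
    rate: float,
    rng: np.random.Generator,
) -> ExpressionSet:
    """Replace cells (Bernoulli ``rate``) with outliers 3-4 sd from the mean.

    Outliers are uniform on [mu - 4 sigma, mu - 3 sigma] or
    [mu + 3 sigma, mu + 4 sigma] (side chosen with probability 1/2),
    where mu and sigma are the gene's observed mean and standard
    deviation before injection.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    values = es.values.copy()
    if rate == 0.0:
        return ExpressionSet(list(es.gene_ids), values,
                             es.sample_times.copy(),
                             es.replicate_labels.copy())
    for g in range(es.n_genes):
        row = values[g]
        obs = ~np.isnan(row)
        if obs.sum() < 2:
            continue
        mu = float(np.nanmean(row))
        sigma = float(np.nanstd(row, ddof=1))
        hit = obs & (rng.random(len(row)) < rate)
        n_hit = int(hit.sum())
        if n_hit == 0:
            continue
        side = rng.choice([-1.0, 1.0], size=n_hit)
        mag = rng.uniform(3.0 * sigma, 4.0 * sigma, size=n_hit)
        row[hit] = mu + side * mag
    return ExpressionSet(list(es.gene_ids), values, es.sample_times.copy(),
                         es.replicate_labels.copy())
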