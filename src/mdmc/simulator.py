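"""Seeded Monte-Carlo simulation of the superimposed diffusion process.

The decision process is integrated by an Euler scheme with step ``dt``:

    X(t + dt) = X(t) + mu(t) * dt + sigma * sqrt(dt) * Z,   Z ~ N(0, 1)

where ``mu(t)`` is the controlled drift plus the signed automatic drifts of
all task-irrelevant modalities.  The process starts at a beta-distributed
point on (-b, b) and is absorbed at +b (correct response) or -b (error);
decision time is the first crossing time.  The observable response time adds
a normally distributed residual (non-decision) duration, redrawn until
positive.

Noise is applied once to the superimposed process (a single diffusion
constant ``sigma``), and the first Euler step evaluates the automatic drift
at t = dt, so the 1/t singularity of the drift formula at t = 0 is never
touched.

Trials that fail to absorb within ``time_cap`` ms are flagged censored; at
realistic parameter values this is vanishingly rare.

The per-trial integration loop is JIT-compiled (numba).  The kernel can
either draw its Gaussian increments internally from a seeded stream, or read
them from a pre-generated per-trial noise matrix — the latter is what the
fitting module uses to hold common random numbers fixed across objective
evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .model_core import (
    NEUTRAL,
    CongruencyCondition,
    ModelParameters,
    automatic_drift,
)

__all__ = [
    "DEFAULT_TIME_CAP",
    "DecisionBatch",
    "sample_start_point",
    "drift_schedule",
    "simulate_decisions",
    "simulate_decision",
    "simulate_trial",
    "simulate_experiment",
]

DEFAULT_TIME_CAP = 5000.0  # ms

_EMPTY_NOISE = np.empty((0, 0), dtype=np.float32)


@njit(cache=True)
def _first_passage_kernel(x0, drift, dt, sigma_sqrt_dt, boundary, max_steps, noise, seed):
    n = x0.shape[0]
    steps = np.zeros(n, dtype=np.int64)
    correct = np.zeros(n, dtype=np.bool_)
    censored = np.zeros(n, dtype=np.bool_)
    np.random.seed(seed)
    n_pre = noise.shape[1]
    for i in range(n):
        x = x0[i]
        absorbed = False
        for k in range(max_steps):
            if k < n_pre:
                z = np.float64(noise[i, k])
            else:
                z = np.random.normal(0.0, 1.0)
            x += drift[k] * dt + sigma_sqrt_dt * z
            if x >= boundary:
                steps[i] = k + 1
                correct[i] = True
                absorbed = True
                break
            elif x <= -boundary:
                steps[i] = k + 1
                correct[i] = False
                absorbed = True
                break
        if not absorbed:
            steps[i] = max_steps
            censored[i] = True
    return steps, correct, censored


@dataclass
class DecisionBatch:
    """Raw output of the diffusion stage for a batch of trials."""

    decision_time: np.ndarray  # ms
    correct: np.ndarray  # bool
    censored: np.ndarray  # bool


def sample_start_point(
    start_shape: float, boundary: float, rng: np.random.Generator, size=None
):
    """Draw starting points 2b * Beta(alpha, alpha) - b on (-b, b).

    The symmetric beta has mean 0 and variance b^2 / (2 alpha + 1); large
    ``alpha`` concentrates the start at 0, ``alpha = 1`` is uniform.
    """
    if not start_shape > 0:
        raise ValueError(f"start_shape must be positive, got {start_shape}")
    if not boundary > 0:
        raise ValueError(f"boundary must be positive, got {boundary}")
    return (2.0 * rng.beta(start_shape, start_shape, size=size) - 1.0) * boundary


def drift_schedule(
    params: ModelParameters,
    condition: CongruencyCondition,
    time_cap: float = DEFAULT_TIME_CAP,
) -> np.ndarray:
    """Deterministic per-step drift mu(t) evaluated at t = dt, 2*dt, ...

    Step k of the Euler scheme uses the drift at the end of the step,
    t = (k + 1) * dt, which keeps the evaluation away from t = 0.
    """
    max_steps = int(np.ceil(time_cap / params.dt))
    t = (np.arange(max_steps, dtype=float) + 1.0) * params.dt
    mu = np.full(max_steps, params.mu_c, dtype=float)
    for modality, spec in params.automatic.items():
        s = condition.sign(modality)
        if s != 0:
            mu += automatic_drift(t, spec, s)
    return mu


def simulate_decisions(
    params: ModelParameters,
    condition: CongruencyCondition,
    n: int,
    rng: np.random.Generator,
    time_cap: float = DEFAULT_TIME_CAP,
    start_points: np.ndarray | None = None,
    noise: np.ndarray | None = None,
) -> DecisionBatch:
    """Simulate ``n`` first-passage times of the superimposed diffusion.

    ``start_points`` and ``noise`` override the internally drawn starting
    points / Gaussian increments; the fitting machinery uses them to pin
    common random numbers.  ``noise`` holds one row of N(0, 1) increments per
    trial; steps beyond its width fall back to the kernel's seeded stream.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    drift = drift_schedule(params, condition, time_cap)
    if start_points is None:
        start_points = sample_start_point(
            params.start_shape, params.boundary, rng, size=n
        )
    x0 = np.ascontiguousarray(start_points, dtype=np.float64)
    if x0.shape != (n,):
        raise ValueError("start_points must have shape (n,)")
    noise_mat = _EMPTY_NOISE if noise is None else np.ascontiguousarray(
        noise, dtype=np.float32
    )
    # Seed for the kernel's fallback stream; kept below 2**31 for numba.
    seed = int(rng.integers(0, 2**31 - 1))
    steps, correct, censored = _first_passage_kernel(
        x0,
        drift,
        params.dt,
        params.sigma * np.sqrt(params.dt),
        params.boundary,
        len(drift),
        noise_mat,
        seed,
    )
    return DecisionBatch(
        decision_time=steps.astype(float) * params.dt,
        correct=correct,
        censored=censored,
    )


def simulate_decision(
    params: ModelParameters,
    condition: CongruencyCondition,
    rng: np.random.Generator,
    time_cap: float = DEFAULT_TIME_CAP,
) -> tuple[float, bool, bool]:
    """Single-trial convenience wrapper; returns (decision_time, correct, censored)."""
    batch = simulate_decisions(params, condition, 1, rng, time_cap=time_cap)
    return (
        float(batch.decision_time[0]),
        bool(batch.correct[0]),
        bool(batch.censored[0]),
    )


def residual_mean(
    params: ModelParameters, condition: CongruencyCondition, variant: str
) -> float:
    """Mean residual time for a condition under the given variant.

    The faster-neutral variant uses ``mu_rn`` when the visual stimulus is at
    the central (neutral) position, reflecting the foveal processing-speed
    advantage; otherwise, and always in the base variant, ``mu_r`` applies.
    """
    variant = normalize_variant(variant)
    if variant == "fn-mdmc":
        if params.mu_rn is None:
            raise ValueError("variant 'fn-mdmc' requires mu_rn to be set")
        visual = condition.modalities[0]
        if condition.labels[visual] == NEUTRAL:
            return params.mu_rn
    return params.mu_r


def normalize_variant(variant: str) -> str:
    v = variant.strip().lower().replace("_", "-")
    if v not in ("mdmc", "fn-mdmc"):
        raise ValueError(f"unknown variant {variant!r}; expected 'mdmc' or 'fn-mdmc'")
    return v


def sample_residual(
    mean: float, sigma_r: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sigma_r) residual durations, redrawn until positive."""
    r = rng.normal(mean, sigma_r, size=n)
    bad = r <= 0
    while np.any(bad):
        r[bad] = rng.normal(mean, sigma_r, size=int(bad.sum()))
        bad = r <= 0
    return r


def simulate_trial(
    params: ModelParameters,
    condition: CongruencyCondition,
    variant: str,
    rng: np.random.Generator,
    participant: str | int = "sim",
    time_cap: float = DEFAULT_TIME_CAP,
) -> dict:
    """Simulate one full trial: decision time plus residual duration."""
    table = simulate_condition(
        params, condition, 1, variant, rng, participant=participant, time_cap=time_cap
    )
    return table.iloc[0].to_dict()


def simulate_condition(
    params: ModelParameters,
    condition: CongruencyCondition,
    n: int,
    variant: str,
    rng: np.random.Generator,
    participant: str | int = "sim",
    time_cap: float = DEFAULT_TIME_CAP,
) -> pd.DataFrame:
    """Simulate ``n`` trials of one congruency condition as a trial table."""
    variant = normalize_variant(variant)
    batch = simulate_decisions(params, condition, n, rng, time_cap=time_cap)
    residual = sample_residual(
        residual_mean(params, condition, variant), params.sigma_r, n, rng
    )
    rt = batch.decision_time + residual
    rt[batch.censored] = np.nan
    data = {"participant": participant}
    for modality, label in condition.labels.items():
        data[f"{modality}_congruency"] = label
    data.update(
        rt_ms=rt,
        accuracy=batch.correct.astype(np.int64),
        censored=batch.censored,
        decision_time_ms=batch.decision_time,
    )
    return pd.DataFrame(data)


def simulate_experiment(
    params: ModelParameters,
    conditions: list[CongruencyCondition],
    n_per_condition: int,
    variant: str,
    rng: np.random.Generator | int | np.random.SeedSequence,
    participant: str | int = "sim",
    time_cap: float = DEFAULT_TIME_CAP,
) -> pd.DataFrame:
    """Simulate a full factorial experiment: ``n_per_condition`` trials per cell.

    Each condition gets its own child random stream derived deterministically
    from the root seed, so changing one condition's trial count cannot
    reshuffle the others.
    """
    if not conditions:
        raise ValueError("condition list must not be empty")
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be at least 1")
    if isinstance(rng, np.random.Generator):
        streams = rng.spawn(len(conditions))
    else:
        root = (
            rng
            if isinstance(rng, np.random.SeedSequence)
            else np.random.SeedSequence(rng)
        )
        streams = [np.random.default_rng(c) for c in root.spawn(len(conditions))]
    frames = []
    for condition, stream in zip(conditions, streams):
        frames.append(
            simulate_condition(
                params,
                condition,
                n_per_condition,
                variant,
                stream,
                participant=participant,
                time_cap=time_cap,
            )
        )
    return pd.concat(frames, ignore_index=True)
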