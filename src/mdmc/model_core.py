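"""Parameter types and the deterministic mathematical core of the model.

The decision process in a conflict task (e.g. the Simon task) is modelled as
a Wiener diffusion with constant drift ``mu_c`` (the controlled process, which
accumulates task-relevant evidence) onto which one pulse-like automatic
process per task-irrelevant modality is superimposed.  The expected time
course of one automatic process is a rescaled Gamma density,

    E[X_a(t)] = A * exp(-t / tau) * (t * e / ((a - 1) * tau)) ** (a - 1),

whose time-dependent drift is its first derivative

    mu_a(t) = A * exp(-t / tau) * (t * e / ((a - 1) * tau)) ** (a - 1)
                * ((a - 1) / t - 1 / tau).

``A`` is the signed peak of the pulse (positive for a congruent stimulus
location, negative for incongruent, zero effect for neutral), ``tau`` the
time scale in ms, and ``a`` the Gamma shape, fixed to 2 throughout the
conflict-task literature.  The pulse attains its extremum |A| at
``t = (a - 1) * tau``.

All times are in milliseconds; drift rates are activation units per ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "CONGRUENT",
    "NEUTRAL",
    "INCONGRUENT",
    "LABELS",
    "AutomaticProcessSpec",
    "ModelParameters",
    "CongruencyCondition",
    "condition_sign",
    "expected_automatic_activation",
    "automatic_drift",
    "expected_decision_path",
]

CONGRUENT = "congruent"
NEUTRAL = "neutral"
INCONGRUENT = "incongruent"
LABELS = (CONGRUENT, NEUTRAL, INCONGRUENT)

_SIGNS = {CONGRUENT: 1, NEUTRAL: 0, INCONGRUENT: -1}


@dataclass(frozen=True)
class AutomaticProcessSpec:
    """Amplitude and time scale of one modality's automatic activation pulse.

    Parameters
    ----------
    amplitude_magnitude
        |A|, the peak activation reached by the pulse (activation units).
        The sign carried by the congruency condition is applied separately.
    tau
        Scale parameter of the rescaled Gamma pulse, in ms.
    shape
        Gamma shape parameter ``a``.  Structural constant: 2 everywhere in
        this model family; kept as a field to make the Gamma family explicit.
        It is never a free fitting parameter.
    """

    amplitude_magnitude: float
    tau: float
    shape: float = 2.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.amplitude_magnitude < 0:
            raise ValueError(
                f"amplitude_magnitude must be >= 0, got {self.amplitude_magnitude}"
            )
        if not self.shape > 1:
            raise ValueError(f"shape must exceed 1, got {self.shape}")

    @property
    def peak_time(self) -> float:
        """Time (ms) at which the expected pulse attains its extremum."""
        return (self.shape - 1.0) * self.tau


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of one model variant.

    ``mu_rn`` is present exactly for the faster-neutral variant (FN), which
    grants the visual-neutral condition its own mean residual time; the base
    variant uses ``mu_r`` for every condition.

    Fields
    ------
    mu_c : drift rate of the controlled process (activation units / ms)
    boundary : decision boundary b > 0; absorption at +b (correct) / -b (error)
    start_shape : shape alpha of the symmetric beta starting-point distribution
    mu_r, sigma_r : mean and SD of the residual (non-decision) time, ms
    mu_rn : mean residual time in the visual-neutral condition (FN variant only)
    automatic : ordered mapping modality name -> AutomaticProcessSpec
    sigma : diffusion constant of the superimposed process (default 4)
    dt : Euler step of the simulation, ms (default 1)
    """

    mu_c: float
    boundary: float
    start_shape: float
    mu_r: float
    sigma_r: float
    automatic: Mapping[str, AutomaticProcessSpec]
    mu_rn: float | None = None
    sigma: float = 4.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.boundary > 0:
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        if not self.sigma_r > 0:
            raise ValueError(f"sigma_r must be positive, got {self.sigma_r}")
        if not self.start_shape > 0:
            raise ValueError(f"start_shape must be positive, got {self.start_shape}")
        if self.sigma < 0:
            # sigma == 0 is admitted for the noiseless deterministic path,
            # which is useful for analytic checks.
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.automatic:
            raise ValueError("at least one automatic process is required")
        object.__setattr__(self, "automatic", dict(self.automatic))

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.automatic)

    @property
    def is_faster_neutral(self) -> bool:
        return self.mu_rn is not None

    def with_(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class CongruencyCondition:
    """Per-modality congruency labels: one cell of the factorial design."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for modality, label in self.labels.items():
            if label not in LABELS:
                raise ValueError(
                    f"unknown congruency label {label!r} for modality {modality!r}"
                )
        object.__setattr__(self, "labels", dict(self.labels))

    def __hash__(self) -> int:
        return hash(tuple(self.labels.items()))

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.labels)

    @property
    def name(self) -> str:
        """Compact label, e.g. 'CVIT' for congruent-visual incongruent-tactile."""
        return "".join(
            f"{label[0].upper()}{modality[0].upper()}"
            for modality, label in self.labels.items()
        )

    def sign(self, modality: str) -> int:
        return condition_sign(self.labels[modality])


def condition_sign(label: str) -> int:
    """Map a congruency label to the sign of its automatic pulse.

    A congruent stimulus location pushes toward the correct boundary (+1),
    an incongruent one toward the error boundary (-1), and a neutral
    (central) location does not engage the automatic process (0).
    """
    try:
        return _SIGNS[label]
    except KeyError:
        raise ValueError(
            f"unknown congruency label {label!r}; expected one of {LABELS}"
        ) from None


def expected_automatic_activation(
    t: float | np.ndarray, spec: AutomaticProcessSpec, sign: int = 1
):
    """Expected automatic activation at time ``t`` (ms).

    Vectorised over ``t``.  Zero at t = 0, peaks at |A| when
    t = (a - 1) * tau, and decays to zero afterwards.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    a, tau = spec.shape, spec.tau
    out = (
        sign
        * spec.amplitude_magnitude
        * np.exp(-t / tau)
        * (t * math.e / ((a - 1.0) * tau)) ** (a - 1.0)
    )
    return out if out.ndim else float(out)


def automatic_drift(t: float | np.ndarray, spec: AutomaticProcessSpec, sign: int = 1):
    """Time-dependent drift of the automatic process: d/dt of the expected pulse.

    Positive before the pulse peak at (a - 1) * tau, zero exactly there,
    negative after (for sign = +1).  The expression carries a 1/t factor and
    is therefore only defined for t > 0; the simulator's first Euler step
    evaluates it at t = dt, never at 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be strictly positive (the drift has a 1/t factor)")
    a, tau = spec.shape, spec.tau
    out = (
        sign
        * spec.amplitude_magnitude
        * np.exp(-t / tau)
        * (t * math.e / ((a - 1.0) * tau)) ** (a - 1.0)
        * ((a - 1.0) / t - 1.0 / tau)
    )
    return out if out.ndim else float(out)


def _check_modalities(params: ModelParameters, condition: CongruencyCondition) -> None:
    if set(params.modalities) != set(condition.modalities):
        raise ValueError(
            "modality mismatch between parameters "
            f"{params.modalities} and condition {condition.modalities}"
        )


def expected_decision_path(
    t: float | np.ndarray, params: ModelParameters, condition: CongruencyCondition
):
    """Expected superimposed decision path: linear controlled ramp plus pulses.

    With every modality neutral this reduces to the straight line mu_c * t.
    """
    _check_modalities(params, condition)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = params.mu_c * t
    for modality, spec in params.automatic.items():
        s = condition.sign(modality)
        if s != 0:
            out = out + expected_automatic_activation(t, spec, s)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def total_drift(
    t: np.ndarray, params: ModelParameters, condition: CongruencyCondition
) -> np.ndarray:
    """Superimposed drift mu(t) = mu_c + sum of signed automatic drifts."""
    _check_modalities(params, condition)
    out = np.full_like(np.asarray(t, dtype=float), params.mu_c)
    for modality, spec in params.automatic.items():
        s = condition.sign(modality)
        if s != 0:
            out = out + automatic_drift(t, spec, s)
    return out
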