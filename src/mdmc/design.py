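"""Factorial experiment design and synthetic dataset generation.

The emulated task is a visual letter-identification (Simon) task with a
second, task-irrelevant modality (tactile or auditory).  A letter (H or S)
appears left, center, or right of fixation while the second modality is
stimulated left, center, or right; participants respond left or right to
letter identity.  Crossing 3 visual positions x 3 secondary positions x 2
letters yields 18 trial types; relative to the correct response side each
modality's position is congruent (same side), incongruent (opposite side),
or neutral (center), so the 18 types collapse onto a 3 x 3 grid of nine
congruency conditions.

With 5 repetitions per trial type per block and 6 blocks, every participant
contributes 540 trials: each of the nine congruency cells exactly 60 times.
The letter-to-response mapping is counterbalanced across participants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    CONGRUENT,
    INCONGRUENT,
    LABELS,
    NEUTRAL,
    CongruencyCondition,
    ModelParameters,
)
from . import simulator

__all__ = [
    "POSITIONS",
    "DesignSpec",
    "congruency_of",
    "build_design",
    "nine_conditions",
    "generate_dataset",
]

POSITIONS = ("left", "center", "right")
SIDES = ("left", "right")
_OPPOSITE = {"left": "right", "right": "left"}


@dataclass(frozen=True)
class DesignSpec:
    """Layout of one synthetic experiment."""

    secondary_modality: str = "tactile"
    positions: tuple = POSITIONS
    letters: tuple = ("H", "S")
    reps_per_block: int = 5
    n_blocks: int = 6
    n_participants: int = 30

    @property
    def n_trial_types(self) -> int:
        return len(self.positions) ** 2 * len(self.letters)

    @property
    def trials_per_participant(self) -> int:
        return self.n_trial_types * self.reps_per_block * self.n_blocks

    def letter_mapping(self, participant: int) -> dict:
        """Letter -> response side; counterbalanced by participant parity."""
        a, b = self.letters
        if participant % 2 == 0:
            return {a: "left", b: "right"}
        return {a: "right", b: "left"}


def congruency_of(stimulus_position: str, correct_response_side: str) -> str:
    """Congruency of a stimulus position relative to the required response.

    Same side -> congruent; opposite side -> incongruent; central -> neutral.
    """
    if stimulus_position not in POSITIONS:
        raise ValueError(f"unknown stimulus position {stimulus_position!r}")
    if correct_response_side not in SIDES:
        raise ValueError(f"unknown response side {correct_response_side!r}")
    if stimulus_position == "center":
        return NEUTRAL
    if stimulus_position == correct_response_side:
        return CONGRUENT
    return INCONGRUENT


def nine_conditions(secondary_modality: str = "tactile") -> list[CongruencyCondition]:
    """The 3 x 3 grid of congruency conditions, visual label varying slowest."""
    return [
        CongruencyCondition({"visual": v, secondary_modality: s})
        for v, s in itertools.product(LABELS, LABELS)
    ]


def build_design(
    spec: DesignSpec, participant: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Ordered trial list for one participant, shuffled within each block."""
    mapping = spec.letter_mapping(participant)
    types = list(
        itertools.product(spec.positions, spec.positions, spec.letters)
    )
    rows = []
    for block in range(spec.n_blocks):
        block_trials = types * spec.reps_per_block
        perm = rng.permutation(len(block_trials))
        for idx in perm:
            vpos, spos, letter = block_trials[idx]
            side = mapping[letter]
            rows.append(
                {
                    "participant": participant,
                    "block": block,
                    "visual_position": vpos,
                    "secondary_position": spos,
                    "letter": letter,
                    "correct_side": side,
                    "visual_congruency": congruency_of(vpos, side),
                    f"{spec.secondary_modality}_congruency": congruency_of(spos, side),
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(
    params: ModelParameters,
    spec: DesignSpec,
    variant: str,
    rng: np.random.Generator | int | np.random.SeedSequence,
    residual_jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate the full synthetic experiment: every participant, every trial.

    All participants share one parameter set (the fitting target is the
    aggregate).  ``residual_jitter_sd`` optionally applies multiplicative
    lognormal-free jitter (1 + sd * z, clipped at 0.5) to each participant's
    mean residual time for robustness exercises; it is off by default.
    """
    if isinstance(rng, np.random.Generator):
        root = rng
    else:
        root = np.random.default_rng(rng)
    sec = spec.secondary_modality
    cond_cols = ["visual_congruency", f"{sec}_congruency"]
    frames = []
    for participant in range(spec.n_participants):
        design_rng, sim_rng, jitter_rng = root.spawn(3)
        design = build_design(spec, participant, design_rng)
        p_params = params
        if residual_jitter_sd > 0:
            factor = max(0.5, 1.0 + residual_jitter_sd * jitter_rng.standard_normal())
            p_params = params.with_(mu_r=params.mu_r * factor)
        # Simulate per congruency cell in one batch, then scatter back into
        # the designed trial order.
        rt = np.empty(len(design))
        acc = np.empty(len(design), dtype=np.int64)
        cens = np.zeros(len(design), dtype=bool)
        dtime = np.empty(len(design))
        for (vlab, slab), idx in design.groupby(cond_cols, sort=True).groups.items():
            condition = CongruencyCondition({"visual": vlab, sec: slab})
            cell = simulator.simulate_condition(
                p_params,
                condition,
                len(idx),
                variant,
                sim_rng,
                participant=participant,
            )
            rt[idx] = cell["rt_ms"].to_numpy()
            acc[idx] = cell["accuracy"].to_numpy()
            cens[idx] = cell["censored"].to_numpy()
            dtime[idx] = cell["decision_time_ms"].to_numpy()
        out = design[["participant"] + cond_cols].copy()
        out["rt_ms"] = rt
        out["accuracy"] = acc
        out["censored"] = cens
        out["decision_time_ms"] = dtime
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
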