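"""Simulation-based fitting: binned proportions, G², multi-start simplex, BIC.

The model is fitted to ten proportions per congruency condition: five derived
from the CDF of correct-response RTs and five from the conditional accuracy
function.  Writing ``q_p`` for the observed correct-RT quantiles at
p = .1, .3, .5, .7, .9, the CDF slots are the fractions of trials that are
correct with RT in (-inf, q.1], (q.1, q.3], (q.3, q.5], (q.5, q.7],
(q.7, q.9] — for the observed data these are (0.1, 0.2, 0.2, 0.2, 0.2)
times the condition's accuracy up to the granularity of the sample.  The CAF
slots are the fractions of trials that are errors within each observed RT
quintile bin.  Model predictions are scored in the *observed* bins, so all
shape information enters through the predicted vector.  The discrepancy is

    G2 = 2 * sum_c N_c * sum_i |p_ci * log(p_ci / pi_ci)|

with 0 * log(0/pi) = 0 and predicted proportions floored at 1e-5.  The
absolute value is part of the printed objective this toolkit reproduces; the
classical signed form is available behind a flag for sensitivity analysis.

The objective is a Monte-Carlo estimate, so the minimizer (multi-start
Nelder-Mead, run in unit-box-normalized parameter space) sees a *fixed*
noise realization per fit: starting-point uniforms, Gaussian increments, and
residual-time normals are pre-generated once from the fit seed and reused
across every objective evaluation (common random numbers).  The best of
``n_starts`` restarts is returned.

Model comparison simulates ``n_sims`` independent G² (and BIC) values per
model at its fitted parameters against the fixed observed proportions and
applies a paired sign-flip permutation test to the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaincinv

from .model_core import (
    LABELS,
    AutomaticProcessSpec,
    CongruencyCondition,
    ModelParameters,
)
from . import simulator
from .simulator import DEFAULT_TIME_CAP, normalize_variant
from .summaries import DEFAULT_PROBS, caf_bin_counts

__all__ = [
    "PROPORTION_FLOOR",
    "DEFAULT_RANGES",
    "ProportionVector",
    "ConditionBins",
    "FitConfig",
    "FitResult",
    "observed_proportions",
    "score_proportions",
    "predicted_proportions",
    "g_squared",
    "bic",
    "fit_model",
    "compare_models",
    "permutation_pvalue",
]

PROPORTION_FLOOR = 1e-5

#: Plausible ranges bracketing published estimates; used both as optimizer
#: bounds and as the default sampling ranges for multi-start initial values.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mu_r": (200.0, 450.0),
    "sigma_r": (10.0, 80.0),
    "start_shape": (1.0, 6.0),
    "boundary": (30.0, 100.0),
    "mu_c": (0.2, 1.2),
    "amplitude": (1.0, 40.0),
    "tau": (10.0, 120.0),
    "mu_rn": (200.0, 450.0),
}


@dataclass(frozen=True)
class ProportionVector:
    """Ten response proportions (5 CDF + 5 CAF slots) for one condition."""

    values: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (10,):
            raise ValueError(f"expected 10 proportions, got shape {v.shape}")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ConditionBins:
    """Observed bin edges a prediction is scored against.

    ``quantile_edges`` are the five correct-RT quantiles; ``caf_edges`` the
    four interior RT boundaries of the observed quintile bins.
    """

    quantile_edges: np.ndarray
    caf_edges: np.ndarray


def score_proportions(
    rt: np.ndarray, correct: np.ndarray, bins: ConditionBins
) -> np.ndarray:
    """Score trials into the ten observed slots; fractions of all trials.

    CDF slots count correct responses in the half-open intervals delimited by
    the quantile edges; CAF slots count errors per RT quintile bin.
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    n = rt.size
    if n == 0:
        raise ValueError("cannot score an empty trial set")
    out = np.empty(10)
    crt = rt[correct]
    idx = np.searchsorted(bins.quantile_edges, crt, side="left")
    out[:5] = np.bincount(idx, minlength=6)[:5] / n
    ert = rt[~correct]
    idx = np.searchsorted(bins.caf_edges, ert, side="left")
    out[5:] = np.bincount(idx, minlength=5)[:5] / n
    return out


def observed_proportions(
    table: pd.DataFrame, label: str = ""
) -> tuple[ProportionVector, ConditionBins]:
    """Observed proportion vector of one condition plus its scoring bins."""
    n = len(table)
    if n < 10:
        raise ValueError(f"too few trials ({n}) in condition {label or '<unnamed>'}")
    rt = table["rt_ms"].to_numpy(dtype=float)
    correct = table["accuracy"].to_numpy(dtype=float) > 0.5
    if not correct.any():
        raise ValueError(
            f"no correct responses in condition {label or '<unnamed>'}; "
            "cannot anchor the CDF quantiles"
        )
    quantile_edges = np.quantile(rt[correct], list(DEFAULT_PROBS), method="linear")
    order = np.argsort(rt, kind="stable")
    stops = np.cumsum(caf_bin_counts(n, 5))
    caf_edges = rt[order][stops[:-1] - 1]
    bins = ConditionBins(quantile_edges=quantile_edges, caf_edges=caf_edges)
    return ProportionVector(score_proportions(rt, correct, bins), n), bins


class CommonRandomNumbers:
    """Pre-generated randomness reused across objective evaluations of a fit.

    One block serves every condition: a (n_sim, width) matrix of float32
    Gaussian increments, per-trial starting-point uniforms, per-trial
    residual-time normals, and an integer seed for the kernel's fallback
    stream (trials outstripping the matrix width).  Because the randomness
    is fixed, the objective surface is deterministic for the optimizer.
    """

    def __init__(self, n_sim: int, seed_seq: np.random.SeedSequence, width: int = 768):
        rng = np.random.default_rng(seed_seq)
        self.n_sim = int(n_sim)
        self.noise = rng.standard_normal((self.n_sim, width), dtype=np.float32)
        self.start_u = rng.random(self.n_sim)
        self.resid_z = rng.standard_normal(self.n_sim)
        self.kernel_seed = int(rng.integers(0, 2**31 - 1))
        self._beta_cache: tuple[float, np.ndarray] | None = None

    def start_points(self, start_shape: float, boundary: float) -> np.ndarray:
        # The beta inverse CDF dominates the per-evaluation cost; every
        # condition of one evaluation shares the same shape, so memoize it.
        if self._beta_cache is None or self._beta_cache[0] != start_shape:
            base = 2.0 * betaincinv(start_shape, start_shape, self.start_u) - 1.0
            self._beta_cache = (start_shape, base)
        return self._beta_cache[1] * boundary

    def residuals(self, mean: float, sigma_r: float) -> np.ndarray:
        r = mean + sigma_r * self.resid_z
        bad = r <= 0
        if bad.any():  # ~9 SDs from 0 at published scales; essentially never
            rng = np.random.default_rng(self.kernel_seed)
            while bad.any():
                r[bad] = rng.normal(mean, sigma_r, size=int(bad.sum()))
                bad = r <= 0
        return r


def _simulate_rts(
    params: ModelParameters,
    condition: CongruencyCondition,
    variant: str,
    crn: CommonRandomNumbers,
    time_cap: float = DEFAULT_TIME_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """CRN-driven simulation of one condition; censored trials dropped."""
    x0 = crn.start_points(params.start_shape, params.boundary)
    drift = simulator.drift_schedule(params, condition, time_cap)
    steps, correct, censored = simulator._first_passage_kernel(
        x0,
        drift,
        params.dt,
        params.sigma * math.sqrt(params.dt),
        params.boundary,
        len(drift),
        crn.noise,
        crn.kernel_seed,
    )
    resid = crn.residuals(
        simulator.residual_mean(params, condition, variant), params.sigma_r
    )
    rt = steps.astype(float) * params.dt + resid
    keep = ~censored
    return rt[keep], correct[keep]


def predicted_proportions(
    params: ModelParameters,
    condition: CongruencyCondition,
    bins: ConditionBins,
    variant: str,
    n_sim: int = 50_000,
    rng: np.random.Generator | int | None = None,
    crn: CommonRandomNumbers | None = None,
    rt_filter: tuple[float, float] | None = (150.0, 1200.0),
) -> ProportionVector:
    """Model-predicted proportions scored in the observed bins.

    Simulated trials pass through the same RT filter as the data before
    scoring (disable with ``rt_filter=None``).  Supply ``crn`` to reuse a
    fit's fixed noise; otherwise randomness derives from ``rng``.
    """
    if crn is None:
        if rng is None:
            raise ValueError("either rng or crn must be provided")
        seed_seq = (
            rng.bit_generator.seed_seq
            if isinstance(rng, np.random.Generator)
            else np.random.SeedSequence(rng)
        )
        crn = CommonRandomNumbers(n_sim, seed_seq)
    rt, correct = _simulate_rts(params, condition, variant, crn)
    if rt_filter is not None:
        lo, hi = rt_filter
        keep = (rt >= lo) & (rt <= hi)
        rt, correct = rt[keep], correct[keep]
    if rt.size == 0:
        # Degenerate parameter region: nothing survives the filter.
        return ProportionVector(np.zeros(10), 0)
    return ProportionVector(score_proportions(rt, correct, bins), int(rt.size))


def g_squared(
    observed: Sequence[ProportionVector],
    predicted: Sequence[ProportionVector],
    absolute: bool = True,
    floor: float = PROPORTION_FLOOR,
) -> float:
    """Binned discrepancy statistic between observed and predicted proportions.

    ``absolute=True`` applies the absolute value to each term as printed in
    the objective this package reproduces; ``absolute=False`` gives the
    classical signed likelihood-ratio form.
    """
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted must cover the same conditions")
    total = 0.0
    for obs, pred in zip(observed, predicted):
        p = obs.values
        pi = np.maximum(pred.values, floor)
        if np.any(pi <= 0):
            raise RuntimeError("predicted proportions must be positive after flooring")
        mask = p > 0
        terms = p[mask] * np.log(p[mask] / pi[mask])
        if absolute:
            terms = np.abs(terms)
        total += obs.n_trials * float(terms.sum())
    return 2.0 * total


def bic(g2: float, n_free: int, n_total: int) -> float:
    """Penalized fit statistic: G² + f · ln(N)."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    return g2 + n_free * math.log(n_total)


# ---------------------------------------------------------------------------
# Parameter vector layout


def _free_parameter_names(variant: str, secondary: str) -> list[str]:
    names = [
        "mu_r",
        "sigma_r",
        "start_shape",
        "boundary",
        "mu_c",
        "A_visual",
        "tau_visual",
        f"A_{secondary}",
        f"tau_{secondary}",
    ]
    if variant == "fn-mdmc":
        names.append("mu_rn")
    return names


def _range_key(name: str) -> str:
    if name.startswith("A_"):
        return "amplitude"
    if name.startswith("tau_"):
        return "tau"
    return name


def _vector_to_params(
    x: np.ndarray, names: list[str], secondary: str, sigma: float, dt: float
) -> ModelParameters:
    d = dict(zip(names, (float(v) for v in x)))
    return ModelParameters(
        mu_c=d["mu_c"],
        boundary=d["boundary"],
        start_shape=d["start_shape"],
        mu_r=d["mu_r"],
        sigma_r=d["sigma_r"],
        mu_rn=d.get("mu_rn"),
        automatic={
            "visual": AutomaticProcessSpec(d["A_visual"], d["tau_visual"]),
            secondary: AutomaticProcessSpec(d[f"A_{secondary}"], d[f"tau_{secondary}"]),
        },
        sigma=sigma,
        dt=dt,
    )


def params_to_vector(params: ModelParameters, variant: str) -> np.ndarray:
    """Flatten a parameter set into the free-parameter vector of a variant."""
    variant = normalize_variant(variant)
    modalities = params.modalities
    secondary = modalities[1]
    specs = params.automatic
    x = [
        params.mu_r,
        params.sigma_r,
        params.start_shape,
        params.boundary,
        params.mu_c,
        specs["visual"].amplitude_magnitude,
        specs["visual"].tau,
        specs[secondary].amplitude_magnitude,
        specs[secondary].tau,
    ]
    if variant == "fn-mdmc":
        if params.mu_rn is None:
            raise ValueError("fn-mdmc vector requires mu_rn")
        x.append(params.mu_rn)
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitConfig:
    """Tunable settings of one fit.

    ``n_sim`` trials are simulated per condition per objective evaluation;
    ``n_starts`` simplex restarts are drawn uniformly from ``start_ranges``
    (default: the shared ``DEFAULT_RANGES``), each capped at ``maxfev``
    evaluations, after which the best endpoint is refined by one longer
    restarted simplex run (``polish_maxfev`` evaluations; 0 disables).
    ``bic_n`` overrides the sample size entering the BIC penalty; by default
    the number of trials entering the fit is used.
    """

    n_starts: int = 10
    n_sim: int = 50_000
    seed: int = 0
    maxfev: int = 800
    polish_maxfev: int = 3000
    xatol: float = 0.005
    fatol: float = 0.5
    rt_filter: tuple[float, float] | None = (150.0, 1200.0)
    start_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    bic_n: int | None = None
    sigma: float = 4.0
    dt: float = 1.0
    initial_vectors: Sequence[np.ndarray] | None = None


@dataclass
class FitResult:
    """Outcome of a multi-start fit of one model variant."""

    variant: str
    params: ModelParameters
    g2: float
    bic: float
    n_free: int
    n_total: int
    starts: list[dict]
    seed: int
    n_sim_per_condition: int
    parameter_names: list[str]

    def __post_init__(self) -> None:
        if self.g2 < 0:
            raise ValueError("g2 must be non-negative")

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "g2": self.g2,
            "bic": self.bic,
            "n_free": self.n_free,
            "n_total": self.n_total,
            "seed": self.seed,
            "n_sim_per_condition": self.n_sim_per_condition,
            "parameters": dict(
                zip(
                    self.parameter_names,
                    (float(v) for v in params_to_vector(self.params, self.variant)),
                )
            ),
            "starts": self.starts,
        }


def condition_tables(table: pd.DataFrame) -> tuple[str, dict]:
    """Split a trial table into its nine congruency cells.

    Returns the secondary modality name and an ordered mapping
    CongruencyCondition -> sub-table.  Raises if any of the nine cells is
    missing.
    """
    cols = [c for c in table.columns if c.endswith("_congruency")]
    modalities = [c[: -len("_congruency")] for c in cols]
    if "visual" not in modalities or len(modalities) != 2:
        raise ValueError(
            f"expected a visual and one secondary *_congruency column, got {cols}"
        )
    secondary = next(m for m in modalities if m != "visual")
    groups = {}
    missing = []
    for v in LABELS:
        for s in LABELS:
            cond = CongruencyCondition({"visual": v, secondary: s})
            sub = table[
                (table["visual_congruency"] == v)
                & (table[f"{secondary}_congruency"] == s)
            ]
            if len(sub) == 0:
                missing.append(cond.name)
            groups[cond] = sub
    if missing:
        raise ValueError(f"conditions missing from the data: {missing}")
    return secondary, groups


def fit_model(
    table: pd.DataFrame, variant: str, config: FitConfig | None = None
) -> FitResult:
    """Fit one model variant to a (filtered, pooled) trial table.

    The G² objective is minimized by Nelder-Mead restarted from
    ``config.n_starts`` initial vectors; the search runs in unit-box
    normalized space with ``DEFAULT_RANGES`` as hard bounds, and the
    simulation noise is frozen per fit (common random numbers).
    """
    variant = normalize_variant(variant)
    config = config or FitConfig()
    secondary, groups = condition_tables(table)
    observed, bins_by_cond = [], []
    for cond, sub in groups.items():
        vec, bins = observed_proportions(sub, label=cond.name)
        observed.append(vec)
        bins_by_cond.append((cond, bins))
    n_total = sum(o.n_trials for o in observed)

    names = _free_parameter_names(variant, secondary)
    ranges = {**DEFAULT_RANGES, **dict(config.start_ranges)}
    lo = np.array([ranges[_range_key(n)][0] for n in names])
    hi = np.array([ranges[_range_key(n)][1] for n in names])

    root = np.random.SeedSequence(config.seed)
    crn_seq, start_seq = root.spawn(2)
    crn = CommonRandomNumbers(config.n_sim, crn_seq)
    start_rng = np.random.default_rng(start_seq)

    def objective(z: np.ndarray) -> float:
        x = lo + np.clip(z, 0.0, 1.0) * (hi - lo)
        params = _vector_to_params(x, names, secondary, config.sigma, config.dt)
        predicted = [
            predicted_proportions(
                params,
                cond,
                bins,
                variant,
                n_sim=config.n_sim,
                crn=crn,
                rt_filter=config.rt_filter,
            )
            for cond, bins in bins_by_cond
        ]
        if any(p.n_trials == 0 for p in predicted):
            return 1e12
        return g_squared(observed, predicted)

    if config.initial_vectors is not None:
        z0s = [
            (np.asarray(x0, dtype=float) - lo) / (hi - lo)
            for x0 in config.initial_vectors
        ]
    else:
        z0s = [start_rng.random(len(names)) for _ in range(config.n_starts)]

    starts: list[dict] = []
    best = None
    for z0 in z0s:
        res = minimize(
            objective,
            np.clip(z0, 0.0, 1.0),
            method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(names),
            options={
                "maxfev": config.maxfev,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "adaptive": True,
            },
        )
        x0_phys = lo + np.clip(z0, 0.0, 1.0) * (hi - lo)
        starts.append(
            {
                "initial": dict(zip(names, (float(v) for v in x0_phys))),
                "g2": float(res.fun),
                "n_evals": int(res.nfev),
            }
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"all {len(z0s)} starts failed to produce a finite objective; "
            f"trace: {starts}"
        )
    if config.polish_maxfev > 0:
        # Fresh simplex from the best endpoint: a restart escapes the
        # degenerate simplexes short exploration runs tend to end in.
        res = minimize(
            objective,
            best.x,
            method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(names),
            options={
                "maxfev": config.polish_maxfev,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "adaptive": True,
            },
        )
        starts.append(
            {
                "initial": dict(
                    zip(
                        names,
                        (float(v) for v in lo + np.clip(best.x, 0, 1) * (hi - lo)),
                    )
                ),
                "g2": float(res.fun),
                "n_evals": int(res.nfev),
                "polish": True,
            }
        )
        if res.fun < best.fun:
            best = res
    x_best = lo + np.clip(best.x, 0.0, 1.0) * (hi - lo)
    params = _vector_to_params(x_best, names, secondary, config.sigma, config.dt)
    g2 = float(best.fun)
    n_for_bic = config.bic_n if config.bic_n is not None else n_total
    return FitResult(
        variant=variant,
        params=params,
        g2=g2,
        bic=bic(g2, len(names), n_for_bic),
        n_free=len(names),
        n_total=n_total,
        starts=starts,
        seed=config.seed,
        n_sim_per_condition=config.n_sim,
        parameter_names=names,
    )


# ---------------------------------------------------------------------------
# Model comparison


def permutation_pvalue(
    diffs: np.ndarray, n_perms: int, rng: np.random.Generator
) -> float:
    """Two-sided paired sign-flip permutation p-value for mean(diffs) = 0."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    stat = abs(diffs.mean())
    count = 0
    chunk = max(1, min(n_perms, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_perms:
        m = min(chunk, n_perms - done)
        signs = rng.integers(0, 2, size=(m, n)) * 2 - 1
        perm_stats = np.abs(signs @ diffs) / n
        count += int((perm_stats >= stat - 1e-12).sum())
        done += m
    return (1 + count) / (1 + n_perms)


def simulated_statistics(
    fit: FitResult,
    observed: Sequence[ProportionVector],
    bins_by_cond: Sequence[tuple[CongruencyCondition, ConditionBins]],
    n_sim_per_condition: int,
    seed_seqs: Sequence[np.random.SeedSequence],
    rt_filter,
) -> np.ndarray:
    """Independent G² replicates at a fit's best parameters."""
    out = np.empty(len(seed_seqs))
    for k, child in enumerate(seed_seqs):
        crn = CommonRandomNumbers(n_sim_per_condition, child)
        predicted = [
            predicted_proportions(
                fit.params,
                cond,
                bins,
                fit.variant,
                crn=crn,
                rt_filter=rt_filter,
            )
            for cond, bins in bins_by_cond
        ]
        out[k] = g_squared(observed, predicted)
    return out


def compare_models(
    fit_a: FitResult,
    fit_b: FitResult,
    table: pd.DataFrame,
    n_sims: int = 1000,
    n_perms: int = 50_000,
    rng: np.random.Generator | int | None = 0,
    n_sim_per_condition: int | None = None,
    rt_filter: tuple[float, float] | None = (150.0, 1200.0),
) -> dict:
    """Paired permutation comparison of two fitted variants on the same data.

    Simulates ``n_sims`` independent G² (and BIC) values per model against
    the fixed observed proportions and tests the paired differences with a
    sign-flip permutation test.  Returns two-sided p-values and the mean
    simulated statistics per model.
    """
    if fit_a.n_total != fit_b.n_total:
        raise ValueError("fits do not come from the same dataset (n_total differs)")
    _, groups = condition_tables(table)
    observed, bins_by_cond = [], []
    for cond, sub in groups.items():
        vec, bins = observed_proportions(sub, label=cond.name)
        observed.append(vec)
        bins_by_cond.append((cond, bins))
    n_total = sum(o.n_trials for o in observed)
    if n_total != fit_a.n_total:
        raise ValueError("table does not match the dataset the fits were made on")
    seed_seq = (
        rng.bit_generator.seed_seq
        if isinstance(rng, np.random.Generator)
        else np.random.SeedSequence(rng)
    )
    seq_sim, seq_perm = seed_seq.spawn(2)
    n_sim_pc = n_sim_per_condition or fit_a.n_sim_per_condition
    # Both models see the same simulation streams (common random numbers):
    # the k-th pair shares its noise, so the paired differences isolate the
    # model effect, and comparing a model with itself ties exactly.
    sim_children = seq_sim.spawn(n_sims)
    g2_a = simulated_statistics(
        fit_a, observed, bins_by_cond, n_sim_pc, sim_children, rt_filter
    )
    g2_b = simulated_statistics(
        fit_b, observed, bins_by_cond, n_sim_pc, sim_children, rt_filter
    )
    pen_a = fit_a.bic - fit_a.g2
    pen_b = fit_b.bic - fit_b.g2
    perm_rng = np.random.default_rng(seq_perm)
    p_g2 = permutation_pvalue(g2_a - g2_b, n_perms, perm_rng)
    p_bic = permutation_pvalue((g2_a + pen_a) - (g2_b + pen_b), n_perms, perm_rng)
    return {
        "p_g2": p_g2,
        "p_bic": p_bic,
        "mean_g2": (float(g2_a.mean()), float(g2_b.mean())),
        "mean_bic": (float(g2_a.mean() + pen_a), float(g2_b.mean() + pen_b)),
        "n_sims": n_sims,
        "n_perms": n_perms,
    }
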