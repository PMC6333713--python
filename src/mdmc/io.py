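"""Trial-table and parameter-set readers/writers.

Trial tables travel as comma-separated UTF-8 text with a header row:
``participant``, one ``<modality>_congruency`` column per modality,
``rt_ms``, ``accuracy``, ``censored`` (and optionally ``decision_time_ms``
for simulated data).  Parameter sets travel as YAML, nested by modality;
the four reference parameter sets shipped with the package
(``vt_mdmc``, ``vt_fnmdmc``, ``va_mdmc``, ``va_fnmdmc``) use the same format.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import LABELS, AutomaticProcessSpec, ModelParameters

__all__ = [
    "read_trials",
    "write_trials",
    "read_params",
    "write_params",
    "load_fixture",
    "fixture_names",
]

_REQUIRED = ("participant", "rt_ms", "accuracy")


class TrialTableError(ValueError):
    """Raised when a trial-table file violates the documented schema."""


def write_trials(table: pd.DataFrame, path) -> None:
    out = table.copy()
    if "censored" in out.columns:
        out["censored"] = out["censored"].astype(int)
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; malformed rows are reported by line."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required columns {missing}")
    modality_cols = [c for c in table.columns if c.endswith("_congruency")]
    if not modality_cols:
        raise TrialTableError(f"{path}: no <modality>_congruency column found")
    problems = []
    # header is line 1, first data row line 2
    lines = table.index.to_numpy() + 2
    rt = pd.to_numeric(table["rt_ms"], errors="coerce")
    censored = (
        table["censored"].astype(bool)
        if "censored" in table.columns
        else pd.Series(False, index=table.index)
    )
    bad_rt = (rt.isna() | (rt <= 0)) & ~censored
    for ln in lines[bad_rt.to_numpy()]:
        problems.append(f"line {ln}: rt_ms is not a positive number")
    acc = pd.to_numeric(table["accuracy"], errors="coerce")
    bad_acc = ~acc.isin([0, 1])
    for ln in lines[bad_acc.to_numpy()]:
        problems.append(f"line {ln}: accuracy must be 0 or 1")
    for col in modality_cols:
        bad = ~table[col].isin(LABELS)
        for ln in lines[bad.to_numpy()]:
            problems.append(f"line {ln}: {col} must be one of {LABELS}")
    if problems:
        raise TrialTableError(f"{path}: " + "; ".join(problems[:20]))
    table["rt_ms"] = rt
    table["accuracy"] = acc.astype(np.int64)
    table["censored"] = censored.to_numpy()
    return table


def write_params(params: ModelParameters, path, variant: str | None = None) -> None:
    doc: dict = {
        "mu_c": params.mu_c,
        "boundary": params.boundary,
        "start_shape": params.start_shape,
        "mu_r": params.mu_r,
        "sigma_r": params.sigma_r,
        "sigma": params.sigma,
        "dt": params.dt,
        "automatic": {
            m: {
                "amplitude_magnitude": s.amplitude_magnitude,
                "tau": s.tau,
                "shape": s.shape,
            }
            for m, s in params.automatic.items()
        },
    }
    if params.mu_rn is not None:
        doc["mu_rn"] = params.mu_rn
    if variant is not None:
        doc["variant"] = variant
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _params_from_doc(doc: dict) -> ModelParameters:
    automatic = {
        m: AutomaticProcessSpec(
            amplitude_magnitude=float(s["amplitude_magnitude"]),
            tau=float(s["tau"]),
            shape=float(s.get("shape", 2.0)),
        )
        for m, s in doc["automatic"].items()
    }
    return ModelParameters(
        mu_c=float(doc["mu_c"]),
        boundary=float(doc["boundary"]),
        start_shape=float(doc["start_shape"]),
        mu_r=float(doc["mu_r"]),
        sigma_r=float(doc["sigma_r"]),
        mu_rn=float(doc["mu_rn"]) if doc.get("mu_rn") is not None else None,
        automatic=automatic,
        sigma=float(doc.get("sigma", 4.0)),
        dt=float(doc.get("dt", 1.0)),
    )


def read_params(path) -> ModelParameters:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _params_from_doc(doc)


def fixture_names() -> list[str]:
    root = resources.files("mdmc") / "fixtures"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_fixture(name: str, with_meta: bool = False):
    """Load one of the shipped reference parameter sets by name.

    With ``with_meta=True`` also returns the fixture's metadata block
    (variant, secondary modality, reference fit statistics).
    """
    ref = resources.files("mdmc") / "fixtures" / f"{name}.yaml"
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {fixture_names()}"
        ) from None
    doc = yaml.safe_load(text)
    params = _params_from_doc(doc)
    if with_meta:
        meta = {k: doc.get(k) for k in ("variant", "task", "reference")}
        return params, meta
    return params
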