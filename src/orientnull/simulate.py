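"""Synthetic trial cohorts with known movement processes.

Generators for the movement archetypes the analysis assumes or probes:

* ``crw_vm`` / ``crw_wc`` — correlated random walk: zero-centred turning
  angles from a von Mises (concentration ``kappa``) or wrapped Cauchy
  (``rho``) distribution.  The internally-cued null.
* ``brw`` — biased random walk: bearings drawn i.i.d. around a fixed goal
  direction (concentration ``kappa_bias``).  The externally-cued signature.
* ``bcrw`` — biased-correlated walk: turn toward the goal with weight
  ``w`` in [0, 1] (w = 0 reduces to CRW) with turn concentration ``kappa``.
* ``one_sided`` — constant turning bias: turns centred on ``delta`` != 0;
  consistent turning that curls the path, lowering straightness below the
  CRW expectation.
* ``zigzag`` — alternating-sign turns centred on +/- ``delta``
  (deterministic alternation; ``random_sign=True`` for a random-sign
  variant).
* ``composite_crw`` — turn concentration switches between ``kappa1`` and
  ``kappa2`` by a symmetric two-state Markov chain (switch probability
  ``p_switch``).

Every walk starts from a uniform random initial bearing.  Cohorts written
by :func:`generate_study` round-trip through :func:`orientnull.trials.read_trials`
and come with a manifest of true generating parameters for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circular import (
    InvalidParameterError,
    cumulate_bearings,
    sample_von_mises,
    sample_wrapped_cauchy,
    wrap_turning,
)
from .trials import Trial, trials_to_frame

__all__ = ["MODELS", "MovementSpec", "generate_trial", "generate_cohort", "generate_study"]

MODELS = ("crw_vm", "crw_wc", "brw", "bcrw", "zigzag", "composite_crw", "one_sided")


@dataclass(frozen=True)
class MovementSpec:
    """One species-level cohort specification."""

    model: str
    nobs: int
    n_trials: int
    species_label: str
    method_label: str = "scuba_following"
    family: str = "synthetic"
    location: str = "synthetic"
    is_group: bool = False
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in MODELS:
            raise InvalidParameterError(f"unknown movement model {self.model!r}")
        if self.nobs < 5:
            raise InvalidParameterError("nobs must be >= 5")
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")
        _validate_params(self.model, self.parameters)


def _require(params: dict, keys: Sequence[str], model: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise InvalidParameterError(f"{model} requires parameter(s): {', '.join(missing)}")


def _validate_params(model: str, p: dict) -> None:
    if model == "crw_vm":
        _require(p, ["kappa"], model)
        if p["kappa"] < 0:
            raise InvalidParameterError("kappa must be >= 0")
    elif model == "crw_wc":
        _require(p, ["rho"], model)
        if not 0 <= p["rho"] < 1:
            raise InvalidParameterError("rho must lie in [0, 1)")
    elif model == "brw":
        _require(p, ["goal", "kappa_bias"], model)
        if p["kappa_bias"] < 0:
            raise InvalidParameterError("kappa_bias must be >= 0")
    elif model == "bcrw":
        _require(p, ["goal", "kappa", "w"], model)
        if not 0 <= p["w"] <= 1:
            raise InvalidParameterError("w must lie in [0, 1]")
    elif model == "zigzag":
        _require(p, ["delta", "kappa"], model)
    elif model == "composite_crw":
        _require(p, ["kappa1", "kappa2", "p_switch"], model)
        if not 0 < p["p_switch"] < 1:
            raise InvalidParameterError("p_switch must lie in (0, 1)")
    elif model == "one_sided":
        _require(p, ["delta", "kappa"], model)
        if p["delta"] == 0:
            raise InvalidParameterError("one_sided requires a nonzero mean turn delta")


def _simulate_bearings(model: str, nobs: int, p: dict, rng: np.random.Generator) -> np.ndarray:
    theta0 = rng.uniform(0.0, 360.0)
    n_turn = nobs - 1
    if model == "crw_vm":
        dth = sample_von_mises(0.0, p["kappa"], n_turn, rng)
    elif model == "crw_wc":
        dth = sample_wrapped_cauchy(0.0, p["rho"], n_turn, rng)
    elif model == "brw":
        return sample_von_mises(p["goal"], p["kappa_bias"], nobs, rng)
    elif model == "bcrw":
        theta = np.empty(nobs)
        theta[0] = theta0
        for t in range(1, nobs):
            pull = p["w"] * wrap_turning(p["goal"] - theta[t - 1])
            step = sample_von_mises(pull, p["kappa"], 1, rng)[0]
            theta[t] = np.mod(theta[t - 1] + wrap_turning(step), 360.0)
        return theta
    elif model == "zigzag":
        signs = (
            rng.choice([-1.0, 1.0], size=n_turn)
            if p.get("random_sign", False)
            else (-1.0) ** np.arange(1, n_turn + 1)
        )
        dth = wrap_turning(
            signs * p["delta"] + sample_von_mises(0.0, p["kappa"], n_turn, rng)
        )
    elif model == "composite_crw":
        state = np.empty(n_turn, dtype=int)
        state[0] = rng.integers(2)
        switches = rng.random(n_turn - 1) < p["p_switch"]
        state[1:] = (state[0] + np.cumsum(switches)) % 2
        kappas = np.where(state == 0, p["kappa1"], p["kappa2"])
        dth = np.array([sample_von_mises(0.0, k, 1, rng)[0] for k in kappas])
    elif model == "one_sided":
        dth = sample_von_mises(p["delta"], p["kappa"], n_turn, rng)
    else:  # pragma: no cover - guarded by MovementSpec
        raise InvalidParameterError(model)
    return cumulate_bearings(theta0, wrap_turning(dth))


def generate_trial(spec: MovementSpec, rng: np.random.Generator, trial_id: str | None = None) -> Trial:
    """One synthetic trial drawn from the spec's movement process."""
    return Trial(
        trial_id=trial_id or f"{spec.species_label}_t1",
        species=spec.species_label,
        abbreviation=spec.species_label[:8],
        family=spec.family,
        method=spec.method_label,
        location=spec.location,
        is_group=spec.is_group,
        nominal_nobs=spec.nobs,
        bearings=_simulate_bearings(spec.model, spec.nobs, spec.parameters, rng),
    )


def generate_cohort(spec: MovementSpec, rng: np.random.Generator) -> list[Trial]:
    """All trials of one cohort specification."""
    return [
        generate_trial(spec, rng, trial_id=f"{spec.species_label}_t{i + 1}")
        for i in range(spec.n_trials)
    ]


def generate_study(
    specs: Iterable[MovementSpec],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    out_path=None,
    manifest_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a multi-species study; returns (trial table, truth manifest).

    The trial table follows the on-disk schema of
    :mod:`orientnull.trials`; the manifest records each cohort's true
    generating model and parameters.  Deterministic under a fixed seed.
    """
    specs = list(specs)
    if len({s.species_label for s in specs}) != len(specs):
        raise InvalidParameterError("species labels must be unique across specs")
    if rng is None:
        rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    manifest_rows = []
    for spec in specs:
        trials.extend(generate_cohort(spec, rng))
        manifest_rows.append(
            {
                "species": spec.species_label,
                "model": spec.model,
                "nobs": spec.nobs,
                "n_trials": spec.n_trials,
                "method": spec.method_label,
                "is_group": int(spec.is_group),
                **{f"param_{k}": v for k, v in spec.parameters.items()},
            }
        )
    table = trials_to_frame(trials)
    manifest = pd.DataFrame(manifest_rows)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, index=False)
    return table, manifest
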