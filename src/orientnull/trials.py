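"""Reading, writing and selection of orientation trials.

A trial is one animal's ordered sequence of compass bearings plus the
metadata needed by the meta-analysis (species, observation method, whether
the animal was tracked alone or in a group, and the nominal number of
observations for its study design).

Selection mirrors the study designs the package targets: drifting-chamber
(DISC) deployments with a nominal 90, 180 or 300 observations per trial and
diver-followed (scuba-following) releases with a nominal 21 observations.
A trial is retained only if it has more than 90% of the nominal count
(strictly more than 20 for scuba-following); over-long records are trimmed
to the nominal count keeping the later-in-time observations; and only
trials whose bearings reject circular uniformity (Rayleigh test, p < alpha)
enter the quantitative analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circular import rayleigh_test, wrap_bearing

__all__ = [
    "Trial",
    "FilterReport",
    "SchemaError",
    "ParseError",
    "DuplicateRecordError",
    "METHODS",
    "read_trials",
    "trials_to_frame",
    "write_trials",
    "apply_nobs_filter",
    "filter_directional",
    "subsample_trial",
]

METHODS = ("DISC", "scuba_following")
VALID_NOMINAL = (21, 90, 180, 300)

REQUIRED_COLUMNS = (
    "trial_id",
    "species",
    "abbreviation",
    "family",
    "method",
    "location",
    "is_group",
    "nominal_nobs",
    "time_index",
    "bearing_deg",
)


class SchemaError(ValueError):
    """Input table does not match the trial schema."""


class ParseError(ValueError):
    """A cell could not be parsed; message carries the offending row."""


class DuplicateRecordError(ValueError):
    """Duplicate (trial_id, time_index) record."""


@dataclass(frozen=True, eq=False)
class Trial:
    """One trial: an ordered bearing sequence plus its metadata."""

    trial_id: str
    species: str
    abbreviation: str
    family: str
    method: str
    location: str
    is_group: bool
    nominal_nobs: int
    bearings: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.method not in METHODS:
            raise SchemaError(f"unknown method {self.method!r}")
        if int(self.nominal_nobs) not in VALID_NOMINAL:
            raise SchemaError(
                f"nominal_nobs must be one of {VALID_NOMINAL}, got {self.nominal_nobs}"
            )
        object.__setattr__(self, "bearings", wrap_bearing(np.asarray(self.bearings, float)))

    @property
    def n_obs(self) -> int:
        return int(self.bearings.size)


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of the trial-selection chain.

    Conservation: ``n_input = n_rejected_short + n_nondirectional + n_retained``
    (trimming changes a trial, it never removes one).
    """

    n_input: int
    n_rejected_short: int
    n_trimmed: int
    n_nondirectional: int
    n_retained: int

    def __post_init__(self):
        if self.n_input != self.n_rejected_short + self.n_nondirectional + self.n_retained:
            raise ValueError("FilterReport counts do not conserve n_input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def read_trials(path) -> list[Trial]:
    """Read a long-format trial table (CSV, one bearing per row).

    Columns: trial_id, species, abbreviation, family, method, location,
    is_group, nominal_nobs, time_index (1-based, strictly increasing within
    a trial), bearing_deg.  Bearings are wrapped to [0, 360) on ingest.
    """
    if isinstance(path, (str, Path)):
        df = pd.read_csv(path, dtype={"trial_id": str})
    else:  # file-like
        df = pd.read_csv(path, dtype={"trial_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bearings = pd.to_numeric(df["bearing_deg"], errors="coerce")
    bad = df.index[bearings.isna()]
    if len(bad):
        raise ParseError(f"non-numeric bearing_deg at file row {int(bad[0]) + 2}")
    df = df.assign(bearing_deg=bearings)

    dup = df.duplicated(subset=["trial_id", "time_index"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicate (trial_id={row['trial_id']!r}, time_index={row['time_index']})"
        )

    out: list[Trial] = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("time_index")
        meta = grp.iloc[0]
        out.append(
            Trial(
                trial_id=str(trial_id),
                species=str(meta["species"]),
                abbreviation=str(meta["abbreviation"]),
                family=str(meta["family"]),
                method=str(meta["method"]),
                location=str(meta["location"]),
                is_group=bool(int(meta["is_group"])),
                nominal_nobs=int(meta["nominal_nobs"]),
                bearings=grp["bearing_deg"].to_numpy(),
            )
        )
    return out


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Long-format DataFrame in the on-disk schema."""
    rows = []
    for t in trials:
        for i, b in enumerate(t.bearings, start=1):
            rows.append(
                (t.trial_id, t.species, t.abbreviation, t.family, t.method,
                 t.location, int(t.is_group), t.nominal_nobs, i, float(b))
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[:8]) + ["time_index", "bearing_deg"])


def write_trials(trials: Iterable[Trial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def apply_nobs_filter(trial: Trial) -> Trial | None:
    """Apply the observation-count rule; ``None`` means the trial is rejected.

    DISC: reject when n <= 0.9 * nominal; trim to the last ``nominal``
    bearings when over-long.  Scuba-following: reject when n < 21, trim to
    the last 21 when longer.
    """
    n, nominal = trial.n_obs, trial.nominal_nobs
    if trial.method == "scuba_following":
        if n < 21:
            return None
        if n > 21:
            return replace(trial, bearings=trial.bearings[-21:])
        return trial
    if n <= 0.9 * nominal:
        return None
    if n > nominal:
        return replace(trial, bearings=trial.bearings[-nominal:])
    return trial


def filter_directional(
    trials: Sequence[Trial], alpha: float = 0.05, apply_nobs: bool = True
) -> tuple[list[Trial], FilterReport]:
    """Full selection chain: observation-count rule then Rayleigh filter.

    Returns the retained trials (those whose bearings reject uniformity at
    ``alpha``) and a :class:`FilterReport` tallying every category.
    """
    n_input = len(trials)
    n_short = n_trimmed = n_nondir = 0
    retained: list[Trial] = []
    for t in trials:
        if apply_nobs:
            kept = apply_nobs_filter(t)
            if kept is None:
                n_short += 1
                continue
            if kept.n_obs != t.n_obs:
                n_trimmed += 1
            t = kept
        if rayleigh_test(t.bearings).p < alpha:
            retained.append(t)
        else:
            n_nondir += 1
    report = FilterReport(
        n_input=n_input,
        n_rejected_short=n_short,
        n_trimmed=n_trimmed,
        n_nondirectional=n_nondir,
        n_retained=len(retained),
    )
    return retained, report


def subsample_trial(trial: Trial, target_nobs: int = 21) -> Trial:
    """Deterministic even-in-time subsample of a trial to ``target_nobs``.

    Picks indices ``round(1 + k*(n-1)/(target-1))`` (1-based, k = 0..target-1),
    so both endpoints are always included — the coarser cadence a diver
    following the same track would have recorded.  The subsampled trial is
    relabelled ``nominal_nobs = target_nobs`` and must be re-filtered before
    analysis.
    """
    from .circular import InsufficientLengthError

    n = trial.n_obs
    if n < target_nobs:
        raise InsufficientLengthError(
            f"cannot subsample {n} bearings to {target_nobs}"
        )
    if n == target_nobs and trial.nominal_nobs == target_nobs:
        return trial
    k = np.arange(target_nobs, dtype=float)
    idx = np.floor(1.0 + k * (n - 1) / (target_nobs - 1) + 0.5).astype(int) - 1
    return replace(
        trial,
        bearings=trial.bearings[idx],
        nominal_nobs=target_nobs,
        trial_id=f"{trial.trial_id}_s{target_nobs}",
    )
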