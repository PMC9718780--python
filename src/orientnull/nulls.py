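"""Null models of internally cued (correlated-random-walk) movement.

Two complementary nulls for the straightness of a bearing sequence:

* **Theoretical phase diagrams** (:func:`build_phase_diagram`): simulate
  correlated random walks whose turning angles are drawn from a zero-centred
  von Mises (concentration grid kappa = 0..399) or wrapped Cauchy
  (400 rho values in [0, 0.999]) distribution, 1000 walks per grid point,
  and summarise the joint behaviour of the turn consistency R_dtheta and
  the path straightness R_theta as quantile contours (5th, 10th, 20th, ...,
  90th, 95th) plus a mean curve over the R_dtheta axis.

* **Per-trial permutation null** (:func:`crw_resampling_null`): permute the
  observed turning angles without replacement, rebuild the bearing
  sequence, and record the straightness each permutation achieves.

A trial whose observed R_theta sits high in either null is straighter than
its own turn consistency can explain under a correlated random walk —
the signature of steering by an external cue.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .circular import (
    InvalidParameterError,
    resultant_lengths,
    sample_von_mises,
    sample_wrapped_cauchy,
    turning_angles,
)

__all__ = [
    "QUANTILE_LEVELS",
    "NullPhaseDiagram",
    "ResamplingNull",
    "default_concentration_grid",
    "simulate_crw_pairs",
    "build_phase_diagram",
    "crw_resampling_null",
]

QUANTILE_LEVELS = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95)
_FORMAT_VERSION = 1
_N_FINE = 512

DIST_KINDS = ("von_mises", "wrapped_cauchy")


def default_concentration_grid(dist_kind: str) -> np.ndarray:
    """The standard concentration grid: kappa = 0..399 or 400 rho in [0, 0.999]."""
    if dist_kind == "von_mises":
        return np.arange(400, dtype=float)
    if dist_kind == "wrapped_cauchy":
        return np.linspace(0.0, 0.999, 400)
    raise InvalidParameterError(f"unknown dist_kind {dist_kind!r}")


def _sample_dthetas(dist_kind, conc, size, rng):
    if dist_kind == "von_mises":
        return sample_von_mises(0.0, conc, 0, rng, size=size)
    if dist_kind == "wrapped_cauchy":
        return sample_wrapped_cauchy(0.0, conc, 0, rng, size=size)
    raise InvalidParameterError(f"unknown dist_kind {dist_kind!r}")


def _cumulate_rows(theta0: np.ndarray, dthetas: np.ndarray) -> np.ndarray:
    """Row-wise bearing reconstruction: theta[:,0]=theta0, cumulative sums wrapped."""
    out = np.empty((dthetas.shape[0], dthetas.shape[1] + 1))
    out[:, 0] = theta0
    out[:, 1:] = theta0[:, None] + np.cumsum(dthetas, axis=1)
    return np.mod(out, 360.0)


def simulate_crw_pairs(
    dist_kind: str, conc: float, nobs: int, n_rep: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_rep`` CRW walks; return the (R_dtheta, R_theta) pairs.

    Each replicate draws a uniform initial bearing and ``nobs - 1`` i.i.d.
    zero-centred turning angles from the fundamental distribution, rebuilds
    the bearings, and records the mean vector lengths of both sequences.
    """
    if nobs < 5:
        raise InvalidParameterError("nobs must be >= 5")
    dth = _sample_dthetas(dist_kind, conc, (n_rep, nobs - 1), rng)
    theta0 = rng.uniform(0.0, 360.0, size=n_rep)
    theta = _cumulate_rows(theta0, dth)
    return resultant_lengths(dth, axis=1), resultant_lengths(theta, axis=1)


def _fit_contour(x: np.ndarray, y: np.ndarray, x_fine: np.ndarray) -> np.ndarray:
    """GCV smoothing spline through (x, y), evaluated on x_fine, made monotone.

    The grid points crowd together near R_dtheta = 1 (high concentration),
    which makes a spline in x ill-conditioned; instead both coordinates are
    smoothed over the (uniformly spaced) grid index and the parametric
    curve is resampled onto x_fine.
    """
    u = np.arange(x.size, dtype=float)
    u_fine = np.linspace(0.0, u[-1], 4 * x.size)
    x_u = make_smoothing_spline(u, x)(u_fine)
    y_u = make_smoothing_spline(u, y)(u_fine)
    x_u = np.maximum.accumulate(x_u)  # concentration raises turn consistency
    vals = np.interp(x_fine, x_u, y_u)
    vals = np.maximum.accumulate(vals)  # isotonic in R_dtheta
    return np.clip(vals, 0.0, 1.0)


@dataclass
class NullPhaseDiagram:
    """CRW-expected quantile-contour surface for one distribution and N_obs.

    ``contour_values(x)`` returns the 11 contour heights (R_theta at each
    quantile level) at turn consistency ``x``; ``mean_curve(x)`` the
    CRW-expected mean straightness.  Both are linear interpolations of the
    smoothed contours sampled on a dense grid over the diagram's support.
    """

    dist_kind: str
    nobs: int
    n_rep: int
    seed: int | None
    conc_grid: np.ndarray = field(repr=False)
    x_mean: np.ndarray = field(repr=False)
    r_theta_mean: np.ndarray = field(repr=False)
    r_theta_quantiles: np.ndarray = field(repr=False)  # (grid, levels)
    x_fine: np.ndarray = field(repr=False)
    contours_fine: np.ndarray = field(repr=False)  # (levels, fine)
    mean_fine: np.ndarray = field(repr=False)
    quantile_levels: tuple = QUANTILE_LEVELS

    @property
    def support(self) -> tuple[float, float]:
        return float(self.x_fine[0]), float(self.x_fine[-1])

    def clamp(self, x: float) -> float:
        lo, hi = self.support
        if x < lo or x > hi:
            warnings.warn(
                f"R_dtheta={x:.4f} outside diagram support [{lo:.4f}, {hi:.4f}]; clamped",
                stacklevel=2,
            )
        return float(np.clip(x, lo, hi))

    def contour_values(self, x: float) -> np.ndarray:
        x = self.clamp(x)
        vals = np.array([np.interp(x, self.x_fine, c) for c in self.contours_fine])
        return np.maximum.accumulate(vals)  # keep levels ordered at every x

    def mean_curve(self, x: float) -> float:
        return float(np.interp(self.clamp(x), self.x_fine, self.mean_fine))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "dist_kind": self.dist_kind,
            "nobs": self.nobs,
            "n_rep": self.n_rep,
            "seed": self.seed,
            "quantile_levels": list(self.quantile_levels),
            "conc_grid": self.conc_grid.tolist(),
            "x_mean": self.x_mean.tolist(),
            "r_theta_mean": self.r_theta_mean.tolist(),
            "r_theta_quantiles": self.r_theta_quantiles.tolist(),
            "x_fine": self.x_fine.tolist(),
            "contours_fine": self.contours_fine.tolist(),
            "mean_fine": self.mean_fine.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "NullPhaseDiagram":
        return cls(
            dist_kind=d["dist_kind"],
            nobs=int(d["nobs"]),
            n_rep=int(d["n_rep"]),
            seed=d.get("seed"),
            conc_grid=np.asarray(d["conc_grid"]),
            x_mean=np.asarray(d["x_mean"]),
            r_theta_mean=np.asarray(d["r_theta_mean"]),
            r_theta_quantiles=np.asarray(d["r_theta_quantiles"]),
            x_fine=np.asarray(d["x_fine"]),
            contours_fine=np.asarray(d["contours_fine"]),
            mean_fine=np.asarray(d["mean_fine"]),
            quantile_levels=tuple(d["quantile_levels"]),
        )

    @classmethod
    def load(cls, path) -> "NullPhaseDiagram":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_phase_diagram(
    dist_kind: str,
    nobs: int,
    n_rep: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    conc_grid: np.ndarray | None = None,
) -> NullPhaseDiagram:
    """Build the CRW phase diagram for one fundamental distribution and N_obs.

    At each of the 400 concentrations, ``n_rep`` walks are simulated; the
    per-grid-point mean R_dtheta is the abscissa, and the 11 quantile levels
    plus the mean of R_theta are smoothed over it with GCV splines and an
    isotonic projection (contours must be non-decreasing for quantile
    inversion to be well defined).
    """
    if dist_kind not in DIST_KINDS:
        raise InvalidParameterError(f"unknown dist_kind {dist_kind!r}")
    if n_rep < 100:
        raise InvalidParameterError("n_rep < 100 gives unstable contours; refusing")
    if nobs not in (21, 90, 180, 300):
        warnings.warn(f"nobs={nobs} differs from the standard study designs")
    if rng is None:
        rng = np.random.default_rng(seed)
    if conc_grid is None:
        conc_grid = default_concentration_grid(dist_kind)
    conc_grid = np.asarray(conc_grid, dtype=float)

    levels = np.asarray(QUANTILE_LEVELS, dtype=float)
    x_mean = np.empty(conc_grid.size)
    r_mean = np.empty(conc_grid.size)
    r_q = np.empty((conc_grid.size, levels.size))
    for i, conc in enumerate(conc_grid):
        r_dth, r_th = simulate_crw_pairs(dist_kind, conc, nobs, n_rep, rng)
        x_mean[i] = r_dth.mean()
        r_mean[i] = r_th.mean()
        r_q[i] = np.quantile(r_th, levels / 100.0)

    x_fine = np.linspace(x_mean.min(), x_mean.max(), _N_FINE)
    contours = np.vstack([_fit_contour(x_mean, r_q[:, j], x_fine) for j in range(levels.size)])
    contours = np.maximum.accumulate(contours, axis=0)  # order across levels
    mean_fine = _fit_contour(x_mean, r_mean, x_fine)

    return NullPhaseDiagram(
        dist_kind=dist_kind,
        nobs=int(nobs),
        n_rep=int(n_rep),
        seed=seed,
        conc_grid=conc_grid,
        x_mean=x_mean,
        r_theta_mean=r_mean,
        r_theta_quantiles=r_q,
        x_fine=x_fine,
        contours_fine=contours,
        mean_fine=mean_fine,
    )


@dataclass
class ResamplingNull:
    """Per-trial permutation null of path straightness.

    ``values`` holds the R_theta of each reconstruction of the trial from a
    random permutation (without replacement) of its observed turning angles.
    """

    trial_id: str
    values: np.ndarray = field(repr=False)
    n_rep: int = 100

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_rep:
            raise ValueError("ResamplingNull: values count must equal n_rep")


def crw_resampling_null(
    trial, n_rep: int = 100, rng: np.random.Generator | None = None
) -> ResamplingNull:
    """Permutation (CRW-r) null for one trial.

    Each replicate shuffles the observed turning angles, rebuilds the
    bearing sequence from the observed initial bearing (R_theta is
    rotation-invariant, so this choice cannot affect the null), and stores
    the resulting straightness.  Duplicate permutations are allowed.
    """
    if rng is None:
        rng = np.random.default_rng()
    bearings = np.asarray(trial.bearings, dtype=float)
    if bearings.size < 5:
        raise InvalidParameterError("resampling null requires at least 5 bearings")
    dth = turning_angles(bearings)
    if np.allclose(dth, dth[0]):
        warnings.warn(
            f"trial {trial.trial_id}: constant turning angles; degenerate null",
            stacklevel=2,
        )
    perms = rng.permuted(np.broadcast_to(dth, (n_rep, dth.size)).copy(), axis=1)
    theta = _cumulate_rows(np.full(n_rep, bearings[0]), perms)
    return ResamplingNull(trial_id=trial.trial_id, values=resultant_lengths(theta, axis=1), n_rep=n_rep)
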