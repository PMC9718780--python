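"""Circular-statistics primitives for bearing sequences.

All public functions take and return angles in compass **degrees** (the unit
in which field bearings are recorded); computations are carried out in
radians internally.  Bearings are wrapped to ``[0, 360)``; turning angles —
differences of consecutive bearings — are wrapped to ``(-180, 180]`` with
positive values meaning counter-clockwise turns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InsufficientLengthError",
    "InvalidAngleError",
    "InvalidParameterError",
    "RayleighResult",
    "wrap_bearing",
    "wrap_turning",
    "turning_angles",
    "mean_vector_length",
    "rayleigh_test",
    "sample_von_mises",
    "sample_wrapped_cauchy",
    "cumulate_bearings",
]


class InsufficientLengthError(ValueError):
    """Raised when an angle sequence is too short for the requested statistic."""


class InvalidAngleError(ValueError):
    """Raised on non-finite angle input."""


class InvalidParameterError(ValueError):
    """Raised on an out-of-range distribution parameter."""


def _as_angles(angles, min_n: int, what: str) -> np.ndarray:
    arr = np.asarray(angles, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < min_n:
        raise InsufficientLengthError(
            f"{what} requires at least {min_n} angles, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidAngleError(f"{what}: non-finite angle in input")
    return arr


def wrap_bearing(angle_deg):
    """Wrap an angle (scalar or array, degrees) into ``[0, 360)``."""
    arr = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidAngleError("wrap_bearing: non-finite angle")
    wrapped = np.mod(arr, 360.0)
    # -1e-18 % 360 can return 360.0 exactly under floating point
    wrapped = np.where(wrapped >= 360.0, wrapped - 360.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_turning(angle_deg):
    """Wrap an angle (degrees) into the half-open interval ``(-180, 180]``."""
    arr = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidAngleError("wrap_turning: non-finite angle")
    wrapped = np.mod(arr, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def turning_angles(bearings_deg) -> np.ndarray:
    """Turning angles of a bearing sequence.

    Element ``t`` is ``wrap(theta[t+1] - theta[t])`` in ``(-180, 180]``;
    the output has length ``n - 1``.
    """
    theta = _as_angles(bearings_deg, 2, "turning_angles")
    return wrap_turning(np.diff(theta))


def mean_vector_length(angles_deg) -> float:
    """Mean vector length ``R`` of a set of angles.

    ``R`` is the modulus of the average unit vector: 0 for a uniform spread
    of angles, 1 when all angles coincide.  Invariant under a global
    rotation of the sample.
    """
    a = np.radians(_as_angles(angles_deg, 1, "mean_vector_length"))
    return float(np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a))))


def resultant_lengths(angles_deg: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vectorised mean vector length along ``axis`` of an array of degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.hypot(np.mean(np.cos(a), axis=axis), np.mean(np.sin(a), axis=axis))


@dataclass(frozen=True)
class RayleighResult:
    """Outcome of the Rayleigh test of circular uniformity."""

    R: float
    Z: float
    p: float
    n: int

    @property
    def directional(self) -> bool:
        """Significant departure from uniformity at the 5% level."""
        return self.p < 0.05


def rayleigh_test(angles_deg) -> RayleighResult:
    """Rayleigh test of uniformity for circular data.

    Uses ``Z = n R**2`` with the second-order series approximation of the
    p-value

    ``p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``

    which is accurate for the sample sizes used here (n >= 4).
    """
    a = _as_angles(angles_deg, 4, "rayleigh_test")
    n = a.size
    R = mean_vector_length(a)
    Z = n * R * R
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return RayleighResult(R=R, Z=Z, p=float(np.clip(p, 0.0, 1.0)), n=n)


def sample_von_mises(mu_deg: float, kappa: float, n: int, rng: np.random.Generator,
                     size=None) -> np.ndarray:
    """Draw i.i.d. von Mises angles (degrees, wrapped to ``[0, 360)``).

    ``kappa = 0`` is the circular uniform distribution.  The expected mean
    vector length is the Bessel ratio ``A(kappa) = I1(kappa)/I0(kappa)``.
    """
    if not np.isfinite(kappa) or kappa < 0:
        raise InvalidParameterError(f"kappa must be >= 0, got {kappa}")
    shape = (n,) if size is None else size
    if kappa == 0.0:
        draws = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    else:
        draws = rng.vonmises(np.radians(mu_deg), kappa, size=shape)
    return wrap_bearing(np.degrees(draws))


def sample_wrapped_cauchy(mu_deg: float, rho: float, n: int, rng: np.random.Generator,
                          size=None) -> np.ndarray:
    """Draw i.i.d. wrapped Cauchy angles (degrees, wrapped to ``[0, 360)``).

    Exact inverse-CDF sampler:
    ``theta = mu + 2*atan( ((1-rho)/(1+rho)) * tan(pi*(U - 1/2)) )``,
    so the population mean resultant length equals ``rho`` exactly;
    ``rho = 0`` reduces to circular uniform.
    """
    if not np.isfinite(rho) or not (0.0 <= rho < 1.0):
        raise InvalidParameterError(f"rho must lie in [0, 1), got {rho}")
    shape = (n,) if size is None else size
    u = rng.uniform(0.0, 1.0, size=shape)
    draws = np.radians(mu_deg) + 2.0 * np.arctan(
        ((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5))
    )
    return wrap_bearing(np.degrees(draws))


def cumulate_bearings(theta0_deg: float, dthetas_deg) -> np.ndarray:
    """Rebuild a bearing sequence from an initial bearing and turning angles.

    ``theta[0] = theta0``; ``theta[t+1] = wrap(theta[t] + dtheta[t])``.
    Inverse of :func:`turning_angles` on the turning-angle side.
    """
    theta0 = wrap_bearing(theta0_deg)
    d = np.asarray(dthetas_deg, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InvalidAngleError("cumulate_bearings: non-finite turning angle")
    return wrap_bearing(theta0 + np.concatenate(([0.0], np.cumsum(d))))


def bessel_ratio(kappa: float) -> float:
    """Population mean resultant length of vM(mu, kappa): A(k)=I1(k)/I0(k).

    Uses the exponentially scaled Bessel functions so large kappa is safe.
    """
    from scipy.special import i0e, i1e

    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))
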