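"""Placing observed trials on the CRW null.

For a trial with turn consistency ``R_dtheta`` and path straightness
``R_theta``, the theoretical quantile Q is read off the phase diagram by
evaluating the 11 quantile contours at the trial's own R_dtheta and
interpolating the level piecewise-linearly in R_theta; below the 5th
contour Q falls linearly to 0 at R_theta = 0, above the 95th it rises
linearly to 100 at R_theta = 1, then clamps.  The permutation quantile is
the percentage of null straightness values strictly smaller than the
observed one.  Delta-R is the observed straightness minus the CRW-expected
mean straightness at the trial's R_dtheta; positive values mean a
straighter-than-CRW path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .circular import mean_vector_length, rayleigh_test, turning_angles
from .nulls import NullPhaseDiagram, ResamplingNull, crw_resampling_null

__all__ = [
    "trial_quantile_theoretical",
    "trial_quantile_resampling",
    "delta_r",
    "analyze_trials",
    "species_pool",
]


def trial_quantile_theoretical(
    diagram: NullPhaseDiagram, r_dtheta: float, r_theta: float
) -> float:
    """Quantile (percent) of an observed straightness within the CRW null."""
    c = diagram.contour_values(r_dtheta)
    y_knots = np.concatenate(([0.0], c, [1.0]))
    q_knots = np.concatenate(([0.0], np.asarray(diagram.quantile_levels, float), [100.0]))
    # np.interp tolerates ties in y_knots (takes the right-most level)
    return float(np.clip(np.interp(r_theta, y_knots, q_knots), 0.0, 100.0))


def trial_quantile_resampling(null: ResamplingNull, r_theta_hat: float) -> float:
    """Quantile (percent) as the proportion of null values strictly below
    the observed straightness; ties count against the trial."""
    return float(100.0 * np.count_nonzero(null.values < r_theta_hat) / null.n_rep)


def delta_r(diagram: NullPhaseDiagram, r_dtheta: float, r_theta: float) -> float:
    """Observed straightness minus the CRW-expected mean at this R_dtheta."""
    return float(r_theta - diagram.mean_curve(r_dtheta))


def analyze_trials(
    trials,
    diagrams: dict[int, NullPhaseDiagram],
    wc_diagrams: dict[int, NullPhaseDiagram] | None = None,
    n_rep_resample: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-trial quantile table.

    ``diagrams`` maps N_obs to the von Mises phase diagram used for Q_vm
    and Delta-R (the trial's native N_obs diagram is always used);
    ``wc_diagrams`` optionally adds Q_wc.  Returns one row per trial with
    r_dtheta_hat, r_theta_hat, q_vm, q_wc, q_r and delta_r.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for t in trials:
        dth = turning_angles(t.bearings)
        r_dth = mean_vector_length(dth)
        r_th = mean_vector_length(t.bearings)
        dia = diagrams[t.n_obs if t.n_obs in diagrams else t.nominal_nobs]
        q_vm = trial_quantile_theoretical(dia, r_dth, r_th)
        dr = delta_r(dia, r_dth, r_th)
        q_wc = np.nan
        if wc_diagrams is not None:
            wc = wc_diagrams[t.n_obs if t.n_obs in wc_diagrams else t.nominal_nobs]
            q_wc = trial_quantile_theoretical(wc, r_dth, r_th)
        null = crw_resampling_null(t, n_rep=n_rep_resample, rng=rng)
        q_r = trial_quantile_resampling(null, r_th)
        rows.append(
            {
                "trial_id": t.trial_id,
                "species": t.species,
                "abbreviation": t.abbreviation,
                "family": t.family,
                "method": t.method,
                "is_group": t.is_group,
                "nobs": t.n_obs,
                "nominal_nobs": t.nominal_nobs,
                "r_dtheta_hat": r_dth,
                "r_theta_hat": r_th,
                "q_vm": q_vm,
                "q_wc": q_wc,
                "q_r": q_r,
                "delta_r": dr,
                "rayleigh_p": rayleigh_test(t.bearings).p,
            }
        )
    return pd.DataFrame(rows)


def _t_ci_halfwidth(x: np.ndarray) -> float:
    """Half-width of the t-based 95% CI of the mean; NaN when n < 2."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.nan
    se = x.std(ddof=1) / np.sqrt(x.size)
    return float(stats.t.ppf(0.975, x.size - 1) * se)


def species_pool(quantile_table: pd.DataFrame) -> pd.DataFrame:
    """Pool the per-trial table by (species, method, nominal N_obs).

    Reports arithmetic means and t-based 95% CI half-widths of Delta-R,
    R_dtheta and R_theta, plus the directional-trial count per group.
    """
    rows = []
    for (sp, meth, nobs), grp in quantile_table.groupby(
        ["species", "method", "nominal_nobs"], sort=False
    ):
        row = {"species": sp, "method": meth, "nominal_nobs": nobs, "n_directional": len(grp)}
        for col, name in (
            ("delta_r", "delta_r"),
            ("r_dtheta_hat", "r_dtheta"),
            ("r_theta_hat", "r_theta"),
        ):
            row[f"mean_{name}"] = grp[col].mean()
            row[f"ci95_{name}"] = _t_ci_halfwidth(grp[col].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("mean_delta_r", ascending=False, ignore_index=True)
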