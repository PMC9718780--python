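"""Meta-analysis of trial quantiles across individuals and species.

If movement were a pure correlated random walk, each trial's quantile
within its CRW null would be uniform on [0, 100].  The meta layer tests
departures from that uniform with binned Pearson chi-square goodness-of-fit
tests (expected counts from the bin widths), summarises their strength with
Cohen's W = sqrt(X^2 / n), tests across species whether the mean W exceeds
the strong-effect benchmark of 0.5 (one-sided one-sample t-test after a
Shapiro-Wilk normality check), and cross-tabulates the theoretical and
permutation quantiles in a 20 x 20 concordance matrix (5% bins).

Two binning schemes are used, dictated by the chi-square rule of at least
five expected counts per bin: pooled across species, bins (0-50, 50-70,
70-90, 90-100] (needs n >= 50); within species, bins (0-50, 50-75, 75-100]
(needs n >= 20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChiSquareOutcome",
    "EffectSizeTest",
    "ConcordanceMatrix",
    "SampleSizeError",
    "chi_square_quantile_test",
    "effect_size_ttest",
    "concordance_matrix",
    "build_species_table",
]

SCHEMES = {
    # name -> (upper bin edges, expected proportions, minimum n)
    "pooled": (np.array([50.0, 70.0, 90.0, 100.0]), np.array([0.50, 0.20, 0.20, 0.10]), 50),
    "species": (np.array([50.0, 75.0, 100.0]), np.array([0.50, 0.25, 0.25]), 20),
}


class SampleSizeError(ValueError):
    """Too few trials for the chi-square expected-count rule."""


@dataclass(frozen=True)
class ChiSquareOutcome:
    """Binned goodness-of-fit of observed quantiles against the uniform null."""

    bins: tuple  # (lower, upper] percent intervals
    observed_counts: np.ndarray
    expected_counts: np.ndarray
    statistic: float
    dof: int
    p: float
    cohens_w: float
    n: int


@dataclass(frozen=True)
class EffectSizeTest:
    """One-sided one-sample t-test of species-level Cohen's W against 0.5."""

    species_ws: tuple  # ((species, W), ...)
    shapiro_p: float
    t_statistic: float
    p_one_sided: float
    reference: float = 0.5
    wilcoxon_p: float = field(default=np.nan)
    zero_variance: bool = False


@dataclass(frozen=True)
class ConcordanceMatrix:
    """20 x 20 cross-tabulation of theoretical vs permutation quantiles."""

    m: np.ndarray
    bin_width: float = 5.0

    @property
    def n(self) -> int:
        return int(self.m.sum())

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.m.sum(axis=1), self.m.sum(axis=0)


def _bin_counts(q: np.ndarray, upper_edges: np.ndarray) -> np.ndarray:
    # (lower, upper] bins; q == 0 falls in the first bin
    idx = np.searchsorted(upper_edges[:-1], q, side="left")
    return np.bincount(idx, minlength=upper_edges.size)


def chi_square_quantile_test(quantiles, scheme: str = "pooled") -> ChiSquareOutcome:
    """Pearson chi-square of a quantile sample against the uniform null.

    ``scheme`` selects the binning ("pooled" or "species"); expected counts
    are the bin widths times n.  Refuses (SampleSizeError) below the
    scheme's minimum n or if any expected count would fall under 5 — no
    silent continuity correction or exact-test substitution.
    """
    q = np.asarray(quantiles, dtype=float)
    if np.any((q < 0) | (q > 100)) or not np.all(np.isfinite(q)):
        raise ValueError("quantiles must lie in [0, 100]")
    try:
        upper, props, n_min = SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}") from None
    n = q.size
    if n < n_min:
        raise SampleSizeError(f"{scheme} scheme requires n >= {n_min}, got {n}")
    expected = props * n
    if np.any(expected < 5):
        raise SampleSizeError("an expected bin count falls below 5; refusing")
    observed = _bin_counts(q, upper)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    dof = upper.size - 1
    lowers = np.concatenate(([0.0], upper[:-1]))
    return ChiSquareOutcome(
        bins=tuple(zip(lowers, upper)),
        observed_counts=observed,
        expected_counts=expected,
        statistic=statistic,
        dof=dof,
        p=float(stats.chi2.sf(statistic, dof)),
        cohens_w=float(np.sqrt(statistic / n)),
        n=n,
    )


def effect_size_ttest(outcomes: dict[str, ChiSquareOutcome], reference: float = 0.5) -> EffectSizeTest:
    """Test whether species-level effect sizes are on average above ``reference``.

    Requires at least three species with a valid chi-square outcome.
    Shapiro-Wilk is reported (and warned about when p < 0.05) but does not
    abort; a one-sided Wilcoxon signed-rank p is carried alongside as a
    sensitivity line.  A zero-variance W sample yields t = 0, p = 0.5 by
    convention.
    """
    if len(outcomes) < 3:
        raise SampleSizeError("effect-size t-test requires >= 3 species")
    species = tuple(sorted(outcomes))
    ws = np.array([outcomes[s].cohens_w for s in species])
    if np.ptp(ws) == 0.0:
        # Degenerate sample: t is 0/0.  Sign-aware convention — identical W
        # at the reference is uninformative (p = 0.5); identical W away from
        # it (every species at the effect-size ceiling, say) is overwhelming
        # evidence in that direction.
        mean_w = float(ws.mean())
        if mean_w == reference:
            t_stat, p_one = 0.0, 0.5
        elif mean_w > reference:
            t_stat, p_one = np.inf, 0.0
        else:
            t_stat, p_one = -np.inf, 1.0
        return EffectSizeTest(
            species_ws=tuple(zip(species, ws)),
            shapiro_p=np.nan,
            t_statistic=t_stat,
            p_one_sided=p_one,
            reference=reference,
            zero_variance=True,
        )
    shapiro_p = float(stats.shapiro(ws).pvalue)
    if shapiro_p < 0.05:
        warnings.warn(
            f"species effect sizes fail Shapiro-Wilk normality (p={shapiro_p:.3g}); "
            "see the Wilcoxon sensitivity p",
            stacklevel=2,
        )
    t_res = stats.ttest_1samp(ws, reference, alternative="greater")
    try:
        wil_p = float(stats.wilcoxon(ws - reference, alternative="greater").pvalue)
    except ValueError:  # all differences zero
        wil_p = np.nan
    return EffectSizeTest(
        species_ws=tuple(zip(species, ws)),
        shapiro_p=shapiro_p,
        t_statistic=float(t_res.statistic),
        p_one_sided=float(t_res.pvalue),
        reference=reference,
        wilcoxon_p=wil_p,
    )


def concordance_matrix(q_pairs) -> ConcordanceMatrix:
    """Cross-tabulate (Q_vm, Q_r) pairs into 5%-wide (lower, upper] cells.

    Q = 0 is assigned to the first cell; e.g. (99, 96) lands in cell
    (20, 20) and (52, 46) in cell (11, 10) (1-based).
    """
    pairs = np.asarray(q_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        pairs = pairs.reshape(-1, 2)
    if not np.all(np.isfinite(pairs)) or np.any((pairs < 0) | (pairs > 100)):
        raise ValueError("quantiles must lie in [0, 100]")
    idx = np.clip(np.ceil(pairs / 5.0).astype(int) - 1, 0, 19)
    m = np.zeros((20, 20), dtype=int)
    np.add.at(m, (idx[:, 0], idx[:, 1]), 1)
    return ConcordanceMatrix(m=m)


def build_species_table(
    quantile_table: pd.DataFrame,
    totals: dict | None = None,
    min_n_chisq: int = 20,
) -> pd.DataFrame:
    """Study summary: one row per (species, method, nominal N_obs) group.

    Carries mean Delta-R with its 95% CI half-width, the chi-square
    statistic and Cohen's W for both the theoretical and the permutation
    analysis (NaN when the group has fewer than ``min_n_chisq`` directional
    trials), and the directional / total counts.  ``totals`` optionally
    maps (species, method, nominal_nobs) to the pre-filter trial count.
    Rows are sorted by descending mean Delta-R.
    """
    from .quantiles import _t_ci_halfwidth

    rows = []
    for (sp, meth, nobs), grp in quantile_table.groupby(
        ["species", "method", "nominal_nobs"], sort=False
    ):
        n_dir = len(grp)
        row = {
            "species": sp,
            "method": meth,
            "nominal_nobs": nobs,
            "mean_delta_r": grp["delta_r"].mean(),
            "ci95_delta_r": _t_ci_halfwidth(grp["delta_r"].to_numpy()),
            "n_directional": n_dir,
            "n_total": (totals or {}).get((sp, meth, nobs), np.nan),
        }
        for kind, col in (("vm", "q_vm"), ("r", "q_r")):
            if n_dir >= min_n_chisq:
                out = chi_square_quantile_test(grp[col].to_numpy(), scheme="species")
                row[f"chisq_{kind}"] = out.statistic
                row[f"p_{kind}"] = out.p
                row[f"cohens_w_{kind}"] = out.cohens_w
            else:
                row[f"chisq_{kind}"] = np.nan
                row[f"p_{kind}"] = np.nan
                row[f"cohens_w_{kind}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("mean_delta_r", ascending=False, ignore_index=True)
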