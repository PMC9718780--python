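"""Statsmodels-style front door: fit the full orientation analysis to a
trial table and hold the results.

``OrientationModel`` owns the data and the study configuration; ``fit``
runs the pipeline — trial selection, phase-diagram construction (one per
N_obs present, cached and reusable), per-trial quantiles against the
theoretical and permutation nulls, and the species-level meta-analysis —
and returns an ``OrientationResults`` with the estimates, their
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meta as _meta
from .nulls import NullPhaseDiagram, build_phase_diagram
from .quantiles import analyze_trials, species_pool
from .trials import Trial, filter_directional, read_trials

__all__ = ["OrientationModel", "OrientationResults"]


class OrientationModel:
    """Orientation analysis of a cohort of bearing-sequence trials.

    Parameters
    ----------
    trials : sequence of Trial
        Raw trials (selection rules are applied by ``fit``).
    alpha : float
        Rayleigh directionality threshold (default 0.05).
    include_wrapped_cauchy : bool
        Also build wrapped Cauchy diagrams and report Q_wc.
    exclude_groups : bool
        Drop group trials from the species-level effect-size test (they are
        still analysed per trial).
    """

    def __init__(
        self,
        trials,
        alpha: float = 0.05,
        include_wrapped_cauchy: bool = False,
        exclude_groups: bool = True,
    ):
        self.trials: list[Trial] = list(trials)
        self.alpha = alpha
        self.include_wrapped_cauchy = include_wrapped_cauchy
        self.exclude_groups = exclude_groups

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OrientationModel":
        return cls(read_trials(path), **kwargs)

    def fit(
        self,
        seed: int | None = 0,
        n_rep_diagram: int = 1000,
        n_rep_resample: int = 100,
        diagrams: dict[int, NullPhaseDiagram] | None = None,
        wc_diagrams: dict[int, NullPhaseDiagram] | None = None,
    ) -> "OrientationResults":
        """Run the pipeline; pre-built diagrams may be passed to skip the
        expensive null construction (they must match each N_obs present)."""
        ss = np.random.SeedSequence(seed)
        ss_diagram, ss_resample = ss.spawn(2)

        retained, report = filter_directional(self.trials, alpha=self.alpha)
        nobs_present = sorted({t.n_obs for t in retained})

        diagrams = dict(diagrams or {})
        child_seeds = ss_diagram.spawn(2 * len(nobs_present))
        for i, nobs in enumerate(nobs_present):
            if nobs not in diagrams:
                diagrams[nobs] = build_phase_diagram(
                    "von_mises", nobs, n_rep=n_rep_diagram,
                    rng=np.random.default_rng(child_seeds[2 * i]),
                )
        if self.include_wrapped_cauchy:
            wc_diagrams = dict(wc_diagrams or {})
            for i, nobs in enumerate(nobs_present):
                if nobs not in wc_diagrams:
                    wc_diagrams[nobs] = build_phase_diagram(
                        "wrapped_cauchy", nobs, n_rep=n_rep_diagram,
                        rng=np.random.default_rng(child_seeds[2 * i + 1]),
                    )
        elif wc_diagrams is None:
            wc_diagrams = None

        tq = analyze_trials(
            retained,
            diagrams,
            wc_diagrams=wc_diagrams,
            n_rep_resample=n_rep_resample,
            rng=np.random.default_rng(ss_resample),
        )

        totals = {}
        for t in self.trials:
            key = (t.species, t.method, t.nominal_nobs)
            totals[key] = totals.get(key, 0) + 1

        return OrientationResults(
            model=self,
            trial_quantiles=tq,
            filter_report=report,
            diagrams=diagrams,
            wc_diagrams=wc_diagrams,
            totals=totals,
        )


@dataclass
class OrientationResults:
    """Fitted orientation analysis: per-trial quantiles, nulls and summaries."""

    model: OrientationModel
    trial_quantiles: pd.DataFrame
    filter_report: object
    diagrams: dict
    wc_diagrams: dict | None
    totals: dict = field(default_factory=dict)

    # -- derived tables ---------------------------------------------------
    def _single_larva(self) -> pd.DataFrame:
        tq = self.trial_quantiles
        return tq[~tq["is_group"]] if self.model.exclude_groups else tq

    def species_summary(self) -> pd.DataFrame:
        return species_pool(self.trial_quantiles)

    def species_table(self) -> pd.DataFrame:
        return _meta.build_species_table(self.trial_quantiles, totals=self.totals)

    def pooled_chi_square(self, kind: str = "vm") -> _meta.ChiSquareOutcome:
        q = self._single_larva()[f"q_{kind}"].dropna().to_numpy()
        return _meta.chi_square_quantile_test(q, scheme="pooled")

    def species_chi_square(self, kind: str = "vm", min_n: int = 20) -> dict:
        """Per-species chi-square outcomes (species with >= min_n trials)."""
        out = {}
        for sp, grp in self._single_larva().groupby("species", sort=False):
            q = grp[f"q_{kind}"].dropna().to_numpy()
            if q.size >= min_n:
                out[sp] = _meta.chi_square_quantile_test(q, scheme="species")
        return out

    def effect_size_test(self, kind: str = "vm") -> _meta.EffectSizeTest:
        return _meta.effect_size_ttest(self.species_chi_square(kind=kind))

    def concordance(self) -> _meta.ConcordanceMatrix:
        tq = self.trial_quantiles
        return _meta.concordance_matrix(tq[["q_vm", "q_r"]].to_numpy())

    # -- plotting ---------------------------------------------------------
    def plot_phase_diagram(self, nobs: int | None = None, ax=None):
        from .plotting import plot_phase_diagram

        if nobs is None:
            nobs = min(self.diagrams)
        tq = self.trial_quantiles
        overlay = tq[tq["nobs"] == nobs]
        return plot_phase_diagram(self.diagrams[nobs], trials=overlay, ax=ax)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fitted analysis."""
        rep = self.filter_report
        lines = [
            "Orientation analysis against correlated-random-walk nulls",
            "=" * 62,
            f"Trials: {rep.n_input} input, {rep.n_rejected_short} too short, "
            f"{rep.n_trimmed} trimmed, {rep.n_nondirectional} non-directional, "
            f"{rep.n_retained} retained ({100 * rep.n_retained / max(rep.n_input, 1):.0f}% directional)",
            f"Phase diagrams (von Mises): N_obs = {sorted(self.diagrams)}",
            "",
            "Species summary (sorted by descending mean Delta-R):",
        ]
        tbl = self.species_table()
        with pd.option_context("display.width", 120, "display.float_format", "{:.3f}".format):
            lines.append(tbl.to_string(index=False, na_rep="--"))
        try:
            pooled = self.pooled_chi_square("vm")
            lines += [
                "",
                f"Pooled chi-square (theoretical null): X2 = {pooled.statistic:.1f}, "
                f"dof = {pooled.dof}, p = {pooled.p:.3g}, Cohen's W = {pooled.cohens_w:.2f}, "
                f"n = {pooled.n}",
            ]
        except _meta.SampleSizeError:
            lines += ["", "Pooled chi-square: too few trials (n < 50)"]
        for kind, label in (("vm", "theoretical"), ("r", "permutation")):
            try:
                es = self.effect_size_test(kind)
                lines.append(
                    f"Species Cohen's W vs 0.5 ({label}): mean W = "
                    f"{np.mean([w for _, w in es.species_ws]):.2f}, "
                    f"t = {es.t_statistic:.2f}, one-sided p = {es.p_one_sided:.3g} "
                    f"({len(es.species_ws)} species)"
                )
            except _meta.SampleSizeError:
                lines.append(
                    f"Species Cohen's W vs 0.5 ({label}): too few species with n >= 20"
                )
        return "\n".join(lines)
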