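"""Phase-diagram plotting."""

from __future__ import annotations

import numpy as np

from .nulls import NullPhaseDiagram


def plot_phase_diagram(diagram: NullPhaseDiagram, trials=None, ax=None):
    """Plot the CRW quantile contours, the mean curve and (optionally)
    observed trials on the (R_dtheta, R_theta) plane.

    ``trials`` may be a per-trial quantile table (needs columns
    ``r_dtheta_hat`` and ``r_theta_hat``).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    x = diagram.x_fine
    for level, contour in zip(diagram.quantile_levels, diagram.contours_fine):
        lw = 1.6 if level in (5, 95) else 0.7
        ax.plot(x, contour, color="grey", lw=lw)
        ax.annotate(
            f"{level}", (x[-1], contour[-1]), fontsize=7, color="grey",
            xytext=(2, 0), textcoords="offset points",
        )
    ax.plot(x, diagram.mean_fine, color="tab:blue", lw=2.5, label="CRW mean")
    if trials is not None and len(trials):
        ax.scatter(
            np.asarray(trials["r_dtheta_hat"]),
            np.asarray(trials["r_theta_hat"]),
            s=14, color="tab:red", alpha=0.6, zorder=3, label="trials",
        )
    ax.set_xlabel(r"$R_{\Delta\theta}$ (turn consistency)")
    ax.set_ylabel(r"$R_{\theta}$ (path straightness)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title(f"{diagram.dist_kind} CRW null, $N_{{obs}}$ = {diagram.nobs}")
    ax.legend(loc="upper left", fontsize=8)
    return ax
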