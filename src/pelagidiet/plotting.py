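"""Optional figure hooks (require matplotlib).

Two views mirror the study's standard displays: rarefaction/extrapolation
curves with confidence bands, and per-stratum isotope ellipses with the
Bayesian niche-width posterior.
"""

from __future__ import annotations

import numpy as np

from .diversity import RarefactionCurve
from .isotopes import EllipseFit


def plot_rarefaction(curves: dict, ax=None):
    """Rarefaction (solid) and extrapolation (dotted) curves with 95% bands.

    ``curves`` maps a label to a :class:`RarefactionCurve` (or its
    ``to_frame()`` output).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        df = curve.to_frame() if isinstance(curve, RarefactionCurve) else curve
        interp = df[df.segment == "interp"]
        extrap = df[df.segment == "extrap"]
        (line,) = ax.plot(interp["size"], interp.estimate, "-", label=str(label))
        ax.plot(extrap["size"], extrap.estimate, ":", color=line.get_color())
        ax.fill_between(df["size"], df.lower, df.upper,
                        color=line.get_color(), alpha=0.15)
        ref = df.loc[df.segment == "interp", "size"].max()
        ax.plot([ref], interp.loc[interp["size"] == ref, "estimate"], "o",
                color=line.get_color())
    ax.set_xlabel("sample size")
    ax.set_ylabel("species richness")
    ax.legend(fontsize=8)
    return ax


def plot_isotope_ellipses(fits: dict, scale: str = "SEA_C", ax=None):
    """Standard ellipses per stratum plus an inset of SEA_B posteriors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    inset = None
    for label, fit in fits.items():
        assert isinstance(fit, EllipseFit)
        r = np.sqrt(fit.radius2(scale))
        chol = np.linalg.cholesky(fit.cov)
        boundary = fit.mean + r * circle @ chol.T
        (line,) = ax.plot(boundary[:, 0], boundary[:, 1], "-",
                          label=str(label))
        ax.plot(*fit.mean, "+", color=line.get_color())
        if fit.sea_b is not None:
            if inset is None:
                inset = ax.inset_axes([0.65, 0.05, 0.33, 0.28])
                inset.set_xlabel("SEA$_B$", fontsize=7)
                inset.tick_params(labelsize=6)
                inset.set_yticks([])
            inset.hist(fit.sea_b, bins=60, density=True, alpha=0.4,
                       color=line.get_color())
    ax.set_xlabel(r"$\delta^{13}$C (permil)")
    ax.set_ylabel(r"$\delta^{15}$N (permil)")
    ax.legend(fontsize=8)
    return ax
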