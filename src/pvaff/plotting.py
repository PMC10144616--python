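"""Plot emitters: volcano scatter and onset histograms with fitted density."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .disproportionality import SignalResult  # noqa: E402
from .weibull import WeibullFit, density_series  # noqa: E402


def volcano_figure(
    results: Iterable[SignalResult],
    p_axis: str = "x",
    p_threshold: float = 0.05,
    path: str | Path | None = None,
):
    """Volcano plot of the screen: significance vs effect, coloured by volume."""
    import math

    from .disproportionality import volcano_coordinates

    pts = volcano_coordinates(results, p_axis=p_axis)
    xs, ys, cs = zip(*pts) if pts else ((), (), ())
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(xs, ys, c=cs, cmap="RdYlBu_r", s=18, edgecolors="none")
    thr = -math.log10(p_threshold)
    if p_axis == "x":
        ax.axvline(thr, ls=":", c="grey")
        ax.axhline(0.0, ls="-", c="lightgrey", lw=0.8)
        ax.set_xlabel(r"$-\log_{10}(p)$")
        ax.set_ylabel(r"$\ln(\mathrm{ROR})$")
    else:
        ax.axhline(thr, ls=":", c="grey")
        ax.axvline(0.0, ls="-", c="lightgrey", lw=0.8)
        ax.set_xlabel(r"$\ln(\mathrm{ROR})$")
        ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.colorbar(sc, ax=ax, label=r"$\log_{10}$ reports")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def onset_histogram(
    fit: WeibullFit,
    durations: Sequence[float],
    bins: int = 20,
    path: str | Path | None = None,
):
    """Onset-day histogram with the fitted Weibull density overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(durations, bins=bins, density=True, color="steelblue", alpha=0.6)
    t, f = density_series(fit)
    ax.plot(t, f, color="red", lw=1.5)
    ax.set_xlabel("days to onset")
    ax.set_ylabel("density")
    ax.set_title(f"{fit.drug} ({fit.stratum}): "
                 rf"$\alpha$={fit.alpha:.0f}, $\beta$={fit.beta:.2f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
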