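"""Plot helpers: cumulative-incidence panels and HR(t) ribbon plots."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_cumulative_incidence", "plot_hr_curve"]

_COLORS = {"twin": "#b2182b", "singleton": "#2166ac"}


def plot_cumulative_incidence(curves: pd.DataFrame, ax=None, title: str | None = None):
    """Cumulative incidence per 1000 for both pluralities with CI bands.

    ``curves`` is the stacked frame from :func:`twinppd.estimate_curves`
    (columns day, plurality, cuminc_per_1000, lo, hi).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for pl, grp in curves.groupby("plurality"):
        c = _COLORS.get(pl, None)
        ax.plot(grp["day"], grp["cuminc_per_1000"], label=pl, color=c)
        ax.fill_between(grp["day"], grp["lo"], grp["hi"], alpha=0.2, color=c)
    ax.set_xlabel("days since childbirth")
    ax.set_ylabel("cumulative incidence per 1000")
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_hr_curve(hr: pd.DataFrame, ax=None, title: str | None = None):
    """Momentary hazard ratio over time with a 95% CI ribbon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(hr["day"], hr["hr"], color="#333333")
    ax.fill_between(hr["day"], hr["lo"], hr["hi"], alpha=0.2, color="#777777")
    ax.axhline(1.0, ls="--", lw=0.8, color="black")
    ax.set_xlabel("days since childbirth")
    ax.set_ylabel("hazard ratio (twin vs singleton)")
    if title:
        ax.set_title(title)
    return ax
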