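"""Restricted cubic spline (natural spline) basis and knot selection.

A restricted cubic spline is a cubic spline constrained to be linear beyond
its boundary knots.  With K knots it contributes K-1 regression columns: the
time variable itself plus K-2 "restricted" nonlinear terms built from
truncated cubic powers (Harrell's normalized truncated-power construction).
The nonlinear terms vanish identically below the first knot and have zero
second derivative beyond both boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotSet", "rcs_basis", "select_knots", "HARRELL_PERCENTILES"]

#: Default knot-placement percentiles for 4 knots (Harrell convention).
HARRELL_PERCENTILES: tuple[float, ...] = (5.0, 35.0, 65.0, 95.0)


@dataclass(frozen=True)
class KnotSet:
    """Knot locations for the time spline and optional covariate splines.

    Parameters
    ----------
    time : knots (days since childbirth) for the time-since-birth spline.
    age : optional knots for the parental-age spline (adjusted models).
    year : optional knots for the calendar-year spline (adjusted models).
    """

    time: tuple[float, ...]
    age: tuple[float, ...] | None = None
    year: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("time", "age", "year"):
            k = getattr(self, name)
            if k is None:
                continue
            k = tuple(float(v) for v in k)
            if len(k) < 3:
                raise ValueError(f"{name} knots: need at least 3, got {len(k)}")
            if not np.all(np.diff(k) > 0):
                raise ValueError(f"{name} knots must be strictly increasing: {k}")
            object.__setattr__(self, name, k)


def rcs_basis(t: np.ndarray | float, knots: tuple[float, ...]) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at times ``t``.

    Returns an array of shape ``(len(t), K-1)`` whose first column is ``t``
    itself and whose remaining K-2 columns are the restricted nonlinear
    terms, normalized by ``(k_K - k_1)**2`` so all columns share the scale
    of ``t``.  Defined for all real ``t``; linear outside ``[k_1, k_K]``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = np.asarray(knots, dtype=float)
    n_k = len(k)
    if n_k < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    norm = (k[-1] - k[0]) ** 2
    cols = [t]
    denom = k[-1] - k[-2]

    def cube(x: np.ndarray) -> np.ndarray:
        return np.clip(x, 0.0, None) ** 3

    for j in range(n_k - 2):
        term = (
            cube(t - k[j])
            - cube(t - k[-2]) * (k[-1] - k[j]) / denom
            + cube(t - k[-1]) * (k[-2] - k[j]) / denom
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def select_knots(
    event_times: np.ndarray,
    n_knots: int = 4,
    percentiles: tuple[float, ...] | None = None,
) -> tuple[float, ...]:
    """Place knots at percentiles of the observed event times.

    Default placement is the Harrell convention: 5th/35th/65th/95th
    percentiles for 4 knots.  Raises if the event times are too few or too
    tied to yield ``n_knots`` distinct locations — supply fixed knots in
    that case.
    """
    times = np.asarray(event_times, dtype=float)
    times = times[np.isfinite(times)]
    if percentiles is None:
        if n_knots == 4:
            percentiles = HARRELL_PERCENTILES
        else:
            percentiles = tuple(np.linspace(5.0, 95.0, n_knots))
    if len(percentiles) != n_knots:
        raise ValueError("need one percentile per knot")
    if len(np.unique(times)) < n_knots:
        raise ValueError(
            f"only {len(np.unique(times))} distinct event times; "
            f"cannot place {n_knots} knots — supply fixed knots instead"
        )
    knots = np.percentile(times, percentiles)
    knots = np.unique(knots)
    if len(knots) < n_knots:
        raise ValueError(
            "event-time percentiles collapse to fewer than "
            f"{n_knots} distinct knots — supply fixed knots instead"
        )
    return tuple(float(v) for v in knots)
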