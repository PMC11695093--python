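"""Piecewise-exponential hazard model fitted by Poisson regression.

The hazard is treated as constant within each person-period row and
modelled on the log scale as a linear predictor in a restricted cubic
spline of time since childbirth, a twin indicator, twin x time-spline
interactions, and (in adjusted specifications) covariate splines and
indicators.  The Poisson likelihood with a log risk-time offset is
maximized by iteratively reweighted least squares (IRLS).  Within-parent
dependence from repeat births is handled by a cluster-robust sandwich
covariance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .splines import KnotSet, rcs_basis, select_knots

__all__ = [
    "ModelSpec",
    "SplineHazardFit",
    "build_design",
    "poisson_irls",
    "fit_piecewise_poisson",
    "cluster_robust_vcov",
    "wald_test",
    "default_knots",
]


@dataclass(frozen=True)
class ModelSpec:
    """Model specification for one parental role.

    The unadjusted spec is intercept + rcs(time) + twin + twin x rcs(time).
    The adjusted spec adds rcs(age), rcs(calendar year), ART, ART x
    rcs(year) (the contribution of assisted reproduction to twinning fell
    over the study period), cohabitation, and — for mothers only —
    primiparity.  ``time_interaction=False`` drops the twin x time terms,
    giving a proportional-hazards (single twin coefficient) variant.
    """

    role: str = "mother"
    adjusted: bool = False
    time_interaction: bool = True

    def __post_init__(self) -> None:
        if self.role not in ("mother", "father"):
            raise ValueError(f"role must be 'mother' or 'father', got {self.role!r}")


def _rcs_block(values: np.ndarray, knots: tuple[float, ...], prefix: str):
    basis = rcs_basis(values, knots)
    names = [f"{prefix}_rcs{i + 1}" for i in range(basis.shape[1])]
    return basis, names


def build_design(
    df: pd.DataFrame, spec: ModelSpec, knots: KnotSet
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for person-period rows (or prediction rows).

    ``df`` needs ``band_midpoint_day`` and ``plurality`` (strings or a
    0/1 ``twin`` column); adjusted specs additionally need ``age_years``,
    ``calendar_year``, ``art_flag``, ``cohabiting_flag`` and (mothers)
    ``primiparous_flag``.  Fractional covariate values are allowed and
    enter the linear predictor as-is (used for standardization at
    marginal means).
    """
    n = len(df)
    t = df["band_midpoint_day"].to_numpy(dtype=float)
    if "twin" in df.columns:
        twin = df["twin"].to_numpy(dtype=float)
    else:
        twin = (df["plurality"].to_numpy() == "twin").astype(float)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["const"]

    tb, tnames = _rcs_block(t, knots.time, "time")
    cols.append(tb)
    names += tnames

    cols.append(twin[:, None])
    names.append("twin")
    if spec.time_interaction:
        cols.append(twin[:, None] * tb)
        names += [f"twin:{nm}" for nm in tnames]

    if spec.adjusted:
        if knots.age is None or knots.year is None:
            raise ValueError("adjusted spec requires age and year knots")
        ab, anames = _rcs_block(df["age_years"].to_numpy(dtype=float), knots.age, "age")
        cols.append(ab)
        names += anames
        yb, ynames = _rcs_block(
            df["calendar_year"].to_numpy(dtype=float), knots.year, "year"
        )
        cols.append(yb)
        names += ynames
        art = df["art_flag"].to_numpy(dtype=float)
        cols.append(art[:, None])
        names.append("art")
        cols.append(art[:, None] * yb)
        names += [f"art:{nm}" for nm in ynames]
        cols.append(df["cohabiting_flag"].to_numpy(dtype=float)[:, None])
        names.append("cohabiting")
        if spec.role == "mother":
            primi = df["primiparous_flag"].to_numpy(dtype=float)
            if np.any(~np.isfinite(primi)):
                raise ValueError("primiparous_flag missing for mother rows")
            cols.append(primi[:, None])
            names.append("primiparous")

    X = np.column_stack(cols)
    return X, names


def default_knots(
    records: pd.DataFrame, spec: ModelSpec, time_knots: tuple[float, ...] | None = None
) -> KnotSet:
    """Knots from the data: time knots at event-time percentiles, covariate
    knots at covariate percentiles (adjusted specs)."""
    if time_knots is None:
        ev = records.loc[records["event_flag"].astype(bool), "exit_day"].to_numpy()
        time_knots = select_knots(ev)
    age = year = None
    if spec.adjusted:
        age = select_knots(records["age_years"].to_numpy())
        year = select_knots(records["calendar_year"].to_numpy())
    return KnotSet(time=time_knots, age=age, year=year)


@dataclass
class SplineHazardFit:
    """Fitted piecewise-exponential Poisson model.

    ``params`` is indexed by design-column name; ``cov_model`` is the
    inverse observed information and ``cov_cluster`` the cluster-robust
    sandwich (plain A^-1 B A^-1, no small-sample factor).
    """

    spec: ModelSpec
    knots: KnotSet
    params: pd.Series
    cov_model: pd.DataFrame
    cov_cluster: pd.DataFrame
    loglik: float
    deviance: float
    n_iter: int
    converged: bool
    n_rows: int
    n_events: int
    n_clusters: int

    @property
    def names(self) -> list[str]:
        return list(self.params.index)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spec": {
                "role": self.spec.role,
                "adjusted": self.spec.adjusted,
                "time_interaction": self.spec.time_interaction,
            },
            "knots": {
                "time": self.knots.time,
                "age": self.knots.age,
                "year": self.knots.year,
            },
            "params": {k: float(v) for k, v in self.params.items()},
            "cov_model": self.cov_model.to_numpy().tolist(),
            "cov_cluster": self.cov_cluster.to_numpy().tolist(),
            "loglik": self.loglik,
            "deviance": self.deviance,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "n_clusters": self.n_clusters,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplineHazardFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        names = list(d["params"])
        knots = KnotSet(
            time=tuple(d["knots"]["time"]),
            age=tuple(d["knots"]["age"]) if d["knots"]["age"] else None,
            year=tuple(d["knots"]["year"]) if d["knots"]["year"] else None,
        )
        return cls(
            spec=ModelSpec(**d["spec"]),
            knots=knots,
            params=pd.Series(d["params"]),
            cov_model=pd.DataFrame(d["cov_model"], index=names, columns=names),
            cov_cluster=pd.DataFrame(d["cov_cluster"], index=names, columns=names),
            loglik=d["loglik"],
            deviance=d["deviance"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            n_rows=d["n_rows"],
            n_events=d["n_events"],
            n_clusters=d["n_clusters"],
        )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    # log y! omitted (constant in the parameters)
    return float(np.sum(special.xlogy(y, mu) - mu))


def _check_rank(xtwx: np.ndarray, names: list[str]) -> None:
    # scale-normalize first: raw X'WX conditioning is dominated by the very
    # different magnitudes of the spline columns, not by collinearity
    d = np.sqrt(np.diag(xtwx))
    dead = d <= 0
    if np.any(dead):
        cols = [names[i] for i in np.flatnonzero(dead)]
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; columns involved: " + ", ".join(cols)
        )
    corr = xtwx / np.outer(d, d)
    w, v = np.linalg.eigh(corr)
    if np.min(w) < 1e-10:
        j = np.argmin(w)
        involved = [names[i] for i in np.argsort(-np.abs(v[:, j]))[:3]]
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; columns involved: "
            + ", ".join(involved)
        )


def poisson_irls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Poisson IRLS on an explicit design: mean exp(X beta + offset).

    Start values: intercept (first column, assumed constant 1) at
    log(sum y / sum exp(offset)), all else 0.  Converges when the relative
    log-likelihood change drops below ``tol``; step-halving guards against
    overshooting.  Returns (beta, cov_model, loglik, n_iter, converged)
    where ``cov_model`` is the inverse observed information.
    """
    names = names or [f"x{i}" for i in range(X.shape[1])]
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.sum() / np.exp(offset).sum())
    mu = np.exp(X @ beta + offset)
    ll = _poisson_loglik(y, mu)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        xtwx = (X * mu[:, None]).T @ X
        if it == 1:
            _check_rank(xtwx, names)
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            _check_rank(xtwx, names)
            raise
        # step-halving safeguard
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            mu_new = np.exp(X @ cand + offset)
            ll_new = _poisson_loglik(y, mu_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * (abs(ll) + 1.0):
                break
            factor *= 0.5
        else:
            raise RuntimeError(
                f"IRLS step failed to improve the likelihood at iteration {it}; "
                f"loglik trace ended at {ll:.6f}"
            )
        beta, mu = cand, mu_new
        if abs(ll_new - ll) < tol * (abs(ll) + 0.1):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations (loglik {ll:.6f})"
        )
    # one polishing Newton step: quadratic convergence makes the remaining
    # coefficient error negligible relative to the loglik stopping rule
    xtwx = (X * mu[:, None]).T @ X
    beta = beta + np.linalg.solve(xtwx, X.T @ (y - mu))
    mu = np.exp(X @ beta + offset)
    ll = _poisson_loglik(y, mu)
    cov_model = np.linalg.inv((X * mu[:, None]).T @ X)
    return beta, cov_model, ll, it, converged


def fit_piecewise_poisson(
    table: pd.DataFrame,
    spec: ModelSpec,
    knots: KnotSet,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SplineHazardFit:
    """Maximize the Poisson likelihood with log risk-time offset via IRLS.

    Mean: ``risk_days * exp(X beta)``.  Start values: intercept at
    log(total events / total person-days), all else 0.  Convergence when
    the relative log-likelihood change drops below ``tol`` (default
    1e-10) or after ``max_iter`` iterations; with an intercept the score
    equation forces fitted events to total observed events.
    """
    if len(table) == 0:
        raise ValueError("person-period table is empty")
    y = table["events"].to_numpy(dtype=float)
    risk = table["risk_days"].to_numpy(dtype=float)
    if np.any(risk <= 0):
        raise ValueError("risk_days must be positive")
    if y.sum() == 0:
        raise ValueError("no events in the person-period table; cannot fit")
    X, names = build_design(table, spec, knots)
    offset = np.log(risk)

    beta, cov_model, ll, it, converged = poisson_irls(
        X, y, offset, names, max_iter=max_iter, tol=tol
    )
    mu = np.exp(X @ beta + offset)

    clusters = (
        table["parent_id"] if "parent_id" in table.columns else pd.Series(range(len(table)))
    )
    cov_cluster, n_clusters = cluster_robust_vcov(X, y, mu, clusters, cov_model)

    sat = float(np.sum(special.xlogy(y, np.where(y > 0, y, 1.0)) - y))
    deviance = 2.0 * (sat - ll)

    return SplineHazardFit(
        spec=spec,
        knots=knots,
        params=pd.Series(beta, index=names),
        cov_model=pd.DataFrame(cov_model, index=names, columns=names),
        cov_cluster=pd.DataFrame(cov_cluster, index=names, columns=names),
        loglik=ll,
        deviance=deviance,
        n_iter=it,
        converged=converged,
        n_rows=len(table),
        n_events=int(y.sum()),
        n_clusters=n_clusters,
    )


def cluster_robust_vcov(
    X: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    clusters: pd.Series | np.ndarray,
    cov_model: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Sandwich covariance ``A^-1 B A^-1`` for within-cluster dependence.

    ``A`` is the observed information (X' diag(mu) X, equal to the expected
    information for the canonical log link) and ``B`` sums the outer
    products of per-cluster score sums.  With every row its own cluster
    this reduces to the HC0 heteroskedasticity-robust estimator.  No
    small-sample correction factor is applied.
    """
    ids, idx = np.unique(np.asarray(clusters), return_inverse=True)
    n_clusters = len(ids)
    if n_clusters < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")
    if cov_model is None:
        cov_model = np.linalg.inv((X * mu[:, None]).T @ X)
    resid = (y - mu)[:, None] * X
    S = np.zeros((n_clusters, X.shape[1]))
    np.add.at(S, idx, resid)
    B = S.T @ S
    V = cov_model @ B @ cov_model
    return 0.5 * (V + V.T), n_clusters


def wald_test(
    fit: SplineHazardFit, terms: list[str], robust: bool = True
) -> tuple[float, int, float]:
    """Joint Wald test that the named coefficients are all zero.

    Returns (statistic, df, p-value); chi-squared reference distribution.
    """
    from scipy import stats

    missing = [t for t in terms if t not in fit.names]
    if missing:
        raise ValueError(f"terms not in the model: {missing}")
    b = fit.params[terms].to_numpy()
    V = (fit.cov_cluster if robust else fit.cov_model).loc[terms, terms].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    df = len(terms)
    return stat, df, float(stats.chi2.sf(stat, df))
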