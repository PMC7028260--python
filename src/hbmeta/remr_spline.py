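"""One-stage robust-error meta-regression for nonlinear dose-response.

All category-level log risk ratios from all studies are regressed jointly
on a restricted-cubic-spline basis of dose, each study contributing its
effects relative to its own reference category (so covariates are basis
*differences* and the model has no intercept).  Weights are inverse
variances; standard errors come from a cluster-robust sandwich with
studies as clusters, which absorbs the within-study correlation induced by
the shared reference groups.  A Wald test on the nonlinear spline
coefficients assesses departure from log-linearity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effect_math import Z95, effect_from_ci
from .errors import HbmetaError, IdentifiabilityError, InsufficientDataError, NumericalError
from .study_table import StudyTable

log = logging.getLogger(__name__)


def rcs_basis(doses: Sequence[float], knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline design values (Harrell parameterisation).

    k knots give k-1 columns: the linear term plus k-2 truncated-cubic
    terms constrained to be linear beyond the boundary knots, normalised by
    the squared knot span so coefficients stay on comparable scales.
    """
    knots = np.asarray(sorted(knots), dtype=float)
    if len(knots) < 3:
        raise HbmetaError("a restricted cubic spline needs at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise HbmetaError("knots must be strictly increasing")
    x = np.atleast_1d(np.asarray(doses, dtype=float))
    if not np.all(np.isfinite(x)):
        raise HbmetaError("doses must be finite")
    k = len(knots)
    span2 = (knots[-1] - knots[0]) ** 2
    cols = [x]
    pos3 = lambda v: np.clip(v, 0, None) ** 3
    for j in range(k - 2):
        term = (
            pos3(x - knots[j])
            - pos3(x - knots[k - 2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[k - 2])
            + pos3(x - knots[-1]) * (knots[k - 2] - knots[j]) / (knots[-1] - knots[k - 2])
        ) / span2
        cols.append(term)
    return np.column_stack(cols)


def weighted_percentile_knots(doses: Sequence[float], weights: Sequence[float],
                              percentiles: Sequence[float] = (10, 50, 90)) -> np.ndarray:
    """Knots at weighted percentiles of the observed doses."""
    d = np.asarray(doses, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(d)
    d, w = d[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    knots = np.interp(np.asarray(percentiles, dtype=float) / 100.0, cum, d)
    if len(np.unique(knots)) != len(knots):
        raise HbmetaError(f"degenerate knots {knots}; supply explicit knots")
    return knots


@dataclass(frozen=True)
class SplineModel:
    """A fitted REMR restricted-cubic-spline dose-response model."""

    knots: tuple[float, ...]
    coefficients: np.ndarray
    robust_cov: np.ndarray
    ref_dose: float
    n_obs: int
    n_clusters: int
    p_nonlinear: float
    dose_span: tuple[float, float]

    def basis_diff(self, doses) -> np.ndarray:
        x = np.atleast_1d(np.asarray(doses, dtype=float))
        if not self.knots:  # linear-only model
            return (x - self.ref_dose)[:, None]
        return rcs_basis(x, self.knots) - rcs_basis([self.ref_dose], self.knots)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Predicted RR curve with pointwise 95% CI and significance threshold."""

    grid: np.ndarray
    rr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    ref_dose: float

    @property
    def threshold(self) -> Optional[float]:
        return threshold_dose(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose": self.grid, "rr": self.rr,
                             "lo": self.lo, "hi": self.hi})


def _remr_observations(table: StudyTable):
    """Collect (study, dose, log_rr, se, study_ref_dose) category rows."""
    rows = []
    for rec in table.records:
        ref = [c for c in rec.categories if c.is_reference]
        others = [c for c in rec.categories
                  if not c.is_reference and c.rr is not None
                  and c.ci_lower is not None and c.assigned_dose is not None]
        if not ref or len(others) < 1 or ref[0].assigned_dose is None:
            continue
        for c in others:
            e = effect_from_ci(c.rr, c.ci_lower, c.ci_upper)
            rows.append((rec.study_id, c.assigned_dose, e.log_rr, e.se,
                         ref[0].assigned_dose))
    return rows


def fit_remr(table: StudyTable, knots: Optional[Sequence[float]] = None,
             knot_percentiles: Sequence[float] = (10, 50, 90),
             ref_dose: Optional[float] = None, linear: bool = False) -> SplineModel:
    """Fit the one-stage spline meta-regression.

    Observations are all non-reference dosed categories (the reference is
    the zero anchor, not a data row).  The design is
    ``basis(dose) - basis(study reference dose)`` with no intercept,
    weights ``1/se^2``; the coefficient covariance is the CR1 cluster
    sandwich (clusters = studies); ``p_nonlinear`` is a Wald test of the
    nonlinear coefficients against an F(q, g-1) reference, the standard
    small-sample treatment for cluster-robust inference.
    """
    rows = _remr_observations(table)
    if not rows:
        raise InsufficientDataError("no usable category-level observations")
    groups = np.array([r[0] for r in rows])
    doses = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    se = np.array([r[3] for r in rows])
    refs = np.array([r[4] for r in rows])
    g = len(np.unique(groups))
    if g < 2:
        raise InsufficientDataError("one-stage meta-regression needs >=2 studies")

    w = 1.0 / se ** 2
    if linear:
        knots = np.array([])
        X = (doses - refs)[:, None]
    else:
        knots = (np.asarray(sorted(knots), dtype=float) if knots is not None
                 else weighted_percentile_knots(doses, w, knot_percentiles))
        X = rcs_basis(doses, knots) - rcs_basis(refs, knots)
    p = X.shape[1]
    if g < p:
        raise IdentifiabilityError(
            f"{p} spline coefficients but only {g} study clusters")
    if np.linalg.matrix_rank(np.sqrt(w)[:, None] * X) < p:
        raise NumericalError("singular spline design")

    fit = sm.WLS(y, X, weights=w).fit()
    b = np.asarray(fit.params)
    resid = y - X @ b

    # CR1 cluster sandwich: bread (X'WX)^-1, meat from per-cluster scores
    XtWX = X.T @ (w[:, None] * X)
    bread = np.linalg.inv(XtWX)
    meat = np.zeros((p, p))
    for gid in np.unique(groups):
        m = groups == gid
        s = X[m].T @ (w[m] * resid[m])
        meat += np.outer(s, s)
    V = bread @ meat @ bread * (g / (g - 1))
    V = (V + V.T) / 2

    q = p - 1  # nonlinear coefficients
    if q > 0:
        b_nl = b[1:]
        V_nl = V[1:, 1:]
        try:
            stat = float(b_nl @ np.linalg.solve(V_nl, b_nl))
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular robust covariance in Wald test") from exc
        p_nonlinear = float(stats.f.sf(stat / q, q, g - 1))
    else:
        p_nonlinear = float("nan")

    all_doses = np.concatenate([doses, refs])
    anchor = float(ref_dose) if ref_dose is not None else float(all_doses.min())
    log.debug("REMR fit: knots %s, coefs %s, p_nonlinear %.4f", knots, b, p_nonlinear)
    return SplineModel(
        knots=tuple(knots), coefficients=b, robust_cov=V, ref_dose=anchor,
        n_obs=len(y), n_clusters=g, p_nonlinear=p_nonlinear,
        dose_span=(float(all_doses.min()), float(all_doses.max())),
    )


def predict_curve(model: SplineModel, grid: Optional[Sequence[float]] = None,
                  ref_dose: Optional[float] = None, step: float = 0.01) -> DoseResponseCurve:
    """Predicted RR(d) with delta-method pointwise CI, anchored at RR=1.

    ``RR(d) = exp(b'(basis(d) - basis(ref)))``; the CI uses the robust
    coefficient covariance.  Doses outside the fitted span are flagged via
    a log warning, not an error.
    """
    anchor = float(ref_dose) if ref_dose is not None else model.ref_dose
    if grid is None:
        grid = np.arange(model.dose_span[0], model.dose_span[1] + step / 2, step)
        grid = grid[grid <= model.dose_span[1] + 1e-12]
    grid = np.asarray(grid, dtype=float)
    if anchor < model.dose_span[0] or anchor > model.dose_span[1]:
        log.warning("reference dose %.3g outside fitted span %s", anchor, model.dose_span)
    if grid.min() < model.dose_span[0] - 1e-9 or grid.max() > model.dose_span[1] + 1e-9:
        log.warning("curve grid extrapolates beyond fitted span %s", model.dose_span)
    if model.knots:
        D = rcs_basis(grid, model.knots) - rcs_basis([anchor], model.knots)
    else:
        D = (grid - anchor)[:, None]
    eta = D @ model.coefficients
    var = np.einsum("ij,jk,ik->i", D, model.robust_cov, D)
    sd = np.sqrt(np.clip(var, 0, None))
    return DoseResponseCurve(
        grid=grid, rr=np.exp(eta), lo=np.exp(eta - Z95 * sd),
        hi=np.exp(eta + Z95 * sd), ref_dose=anchor,
    )


def threshold_dose(curve: DoseResponseCurve) -> Optional[float]:
    """Smallest dose above the anchor where the lower CI exceeds RR = 1
    and stays above 1 for every larger dose on the grid (so an isolated
    crossing does not count).  None when no such dose exists."""
    above = (curve.grid > curve.ref_dose) & (curve.lo > 1.0)
    beyond = curve.grid > curve.ref_dose
    if not np.any(above):
        return None
    # persistence: from each candidate onward, lo must stay > 1
    ok = np.ones(len(curve.grid), dtype=bool)
    lo_ok = curve.lo > 1.0
    suffix_all = np.flip(np.logical_and.accumulate(np.flip(lo_ok | ~beyond)))
    cand = above & suffix_all
    if not np.any(cand):
        return None
    return float(curve.grid[np.argmax(cand)])
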