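"""Per-1%-HbA1c log-linear trend from correlated category effects.

Category-specific log risk ratios within one study all share the study's
reference group, so they are positively correlated; treating them as
independent understates the trend's precision.  The generalized
least-squares approach reconstructs fitted counts consistent with the
reported effects and the category margins, builds the induced covariance
of the log RRs from those counts, and solves the weighted regression of
log RR on dose difference through the origin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .effect_math import (
    SOURCE_GL_DERIVED, SOURCE_REPORTED, EffectEstimate, effect_from_ci,
    hamling_pseudo_counts,
)
from .errors import InsufficientDataError, NumericalError
from .study_table import StudyRecord

log = logging.getLogger(__name__)

METHOD_REPORTED = "reported"
METHOD_GL = "gl"
METHOD_TWO_POINT = "two_point"

COV_FITTED_COUNTS = "gl_fitted_counts"
COV_INDEPENDENCE = "independence"


@dataclass(frozen=True)
class TrendResult:
    """A per-1% HbA1c log-RR slope with its standard error."""

    study_id: str
    beta: float
    se_beta: float
    method: str
    cov_model: str = ""

    def as_effect(self) -> EffectEstimate:
        source = SOURCE_REPORTED if self.method == METHOD_REPORTED else SOURCE_GL_DERIVED
        return EffectEstimate(self.beta, self.se_beta, source=source)


def fit_reference_cases(totals: Sequence[float], rrs: Sequence[float],
                        total_cases: float, ref_idx: int,
                        tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Fitted per-category case counts matching margins and adjusted RRs.

    Finds cases ``a_i`` with ``sum(a_i) = total_cases`` and
    ``(a_i/n_i)/(a_ref/n_ref) = RR_i``.  The system is monotone in the
    reference cell, so a bracketed root solve converges fast; tolerance and
    iteration cap guard degenerate inputs.
    """
    totals = np.asarray(totals, dtype=float)
    rrs = np.asarray(rrs, dtype=float)

    def implied_total(a_ref):
        p_ref = a_ref / totals[ref_idx]
        return a_ref + sum(
            rrs[i] * p_ref * totals[i] for i in range(len(totals)) if i != ref_idx
        )

    lo, hi = 1e-9, totals[ref_idx] - 1e-9
    if implied_total(hi) < total_cases:
        raise NumericalError("margins incompatible with reported RRs (risks exceed 1)")
    try:
        a_ref = optimize.brentq(lambda a: implied_total(a) - total_cases, lo, hi,
                                xtol=tol, maxiter=max_iter)
    except ValueError as exc:  # pragma: no cover - degenerate margins
        raise NumericalError(f"fitted-count solve failed: {exc}") from exc
    p_ref = a_ref / totals[ref_idx]
    cases = rrs * p_ref * totals
    cases[ref_idx] = a_ref
    return cases


def gl_covariance(ses: Sequence[float], a_ref: float, n_ref: float) -> np.ndarray:
    """Approximate covariance of non-reference log RRs sharing one reference.

    Diagonal: reported variances.  Off-diagonal: the shared reference
    contribution ``1/a_ref - 1/n_ref`` from the fitted counts (cumulative
    incidence data).
    """
    ses = np.asarray(ses, dtype=float)
    C = np.full((len(ses), len(ses)), 1.0 / a_ref - 1.0 / n_ref)
    np.fill_diagonal(C, ses ** 2)
    return C


def gl_slope(record: StudyRecord, use_counts: bool = True) -> TrendResult:
    """GLS per-1% slope from a dosed record's category effects.

    ``beta = (x'C^-1 x)^-1 x'C^-1 L`` with x the dose differences from the
    reference and L the non-reference log RRs.  The covariance C uses
    fitted counts when category totals (or study margins for the
    pseudo-count route) are available; otherwise it falls back to a
    diagonal covariance, recorded in ``cov_model``.  With one non-reference
    category this is exactly ``L1/x1`` with ``se(L1)/|x1|``.
    """
    cats = record.categories
    ref = [c for c in cats if c.is_reference]
    others = [c for c in cats if not c.is_reference and c.rr is not None]
    if not ref or len(others) < 1:
        raise InsufficientDataError(
            f"{record.study_id}: need a reference and >=1 non-reference category with RR"
        )
    ref = ref[0]
    if ref.assigned_dose is None or any(c.assigned_dose is None for c in others):
        raise InsufficientDataError(f"{record.study_id}: run dose assignment first")

    x = np.array([c.assigned_dose - ref.assigned_dose for c in others])
    effects = [effect_from_ci(c.rr, c.ci_lower, c.ci_upper) for c in others]
    L = np.array([e.log_rr for e in effects])
    ses = np.array([e.se for e in effects])

    if len(others) == 1:
        return TrendResult(record.study_id, float(L[0] / x[0]),
                           float(ses[0] / abs(x[0])), METHOD_TWO_POINT,
                           COV_INDEPENDENCE)

    C = None
    cov_model = COV_INDEPENDENCE
    if use_counts:
        counts = _category_counts(record)
        if counts is not None:
            totals, cases_total, ref_idx = counts
            try:
                fitted = fit_reference_cases(
                    totals, [c.rr if c.rr is not None else 1.0 for c in cats],
                    cases_total, ref_idx)
                C = gl_covariance(ses, fitted[ref_idx], totals[ref_idx])
                cov_model = COV_FITTED_COUNTS
            except NumericalError:
                log.warning("%s: fitted-count covariance failed; using independence",
                            record.study_id)
    if C is None:
        C = np.diag(ses ** 2)

    try:
        Cinv_x = np.linalg.solve(C, x)
        Cinv_L = np.linalg.solve(C, L)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"{record.study_id}: singular GL covariance") from exc
    xtCx = float(x @ Cinv_x)
    if xtCx <= 0:
        raise NumericalError(f"{record.study_id}: non-positive GLS information")
    beta = float(x @ Cinv_L) / xtCx
    return TrendResult(record.study_id, beta, math.sqrt(1.0 / xtCx),
                       METHOD_GL, cov_model)


def _category_counts(record: StudyRecord):
    """Category totals + total cases, directly or via pseudo-counts."""
    cats = record.categories
    ref_idx = next(i for i, c in enumerate(cats) if c.is_reference)
    if all(c.total is not None for c in cats) and all(c.cases is not None for c in cats):
        return ([c.total for c in cats], sum(c.cases for c in cats), ref_idx)
    if record.study_cases is not None and record.study_total is not None:
        try:
            pc = hamling_pseudo_counts(cats, record.study_cases, record.study_total)
        except Exception:
            return None
        return (list(pc.totals), sum(pc.cases), ref_idx)
    return None


def per_unit_effect(record: StudyRecord) -> TrendResult:
    """The study's per-1% HbA1c effect, preferring the published value.

    A publication's own per-unit estimate reflects its full adjustment
    model, so it takes precedence; the GLS slope is the fallback for
    studies reporting only categorical effects.
    """
    if record.per_unit_rr is not None:
        if record.per_unit_ci_lower is None or record.per_unit_ci_upper is None:
            raise InsufficientDataError(f"{record.study_id}: per-unit RR lacks a CI")
        e = effect_from_ci(record.per_unit_rr, record.per_unit_ci_lower,
                           record.per_unit_ci_upper)
        if record.n_dosed_categories >= 2:
            try:
                gl = gl_slope(record)
                log.debug("%s: reported per-1%% beta %.4f (GL comparison %.4f)",
                          record.study_id, e.log_rr, gl.beta)
            except (InsufficientDataError, NumericalError):
                pass
        return TrendResult(record.study_id, e.log_rr, e.se, METHOD_REPORTED)
    if record.categories:
        return gl_slope(record)
    raise InsufficientDataError(
        f"{record.study_id}: no per-unit value and no category data"
    )
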