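"""Conversions between effect-reporting forms.

Risk ratios arrive as published point estimates with 95% CIs, or as raw
case counts.  Everything downstream works on the natural-log scale with a
standard error, so this module provides: RR/CI -> log-effect, RR from a
2x2 of counts, and the pseudo-count reconstruction that re-expresses a
study's category effects against a different reference category while
preserving the published CIs and the study's crude margins (the Hamling
transform).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import HbmetaError, NumericalError
from .study_table import ExposureCategory

log = logging.getLogger(__name__)

#: two-sided 97.5% normal quantile used for every 95% CI in the package
Z95 = 1.959964

SOURCE_REPORTED = "reported"
SOURCE_FROM_COUNTS = "from_counts"
SOURCE_GL_DERIVED = "gl_derived"


@dataclass(frozen=True)
class EffectEstimate:
    """A log risk ratio with its standard error (optionally dosed)."""

    log_rr: float
    se: float
    dose: Optional[float] = None
    source: str = SOURCE_REPORTED

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr)

    def ci(self, z: float = Z95) -> tuple[float, float]:
        """95% CI on the RR scale."""
        return math.exp(self.log_rr - z * self.se), math.exp(self.log_rr + z * self.se)


def effect_from_ci(rr: float, lo: float, hi: float,
                   dose: Optional[float] = None) -> EffectEstimate:
    """Log effect from a published RR and 95% CI.

    ``se = (ln hi - ln lo) / (2 * 1.959964)``: the symmetric-SE reading of
    the interval, which keeps the published point estimate intact even when
    the printed CI is not perfectly log-symmetric.
    """
    if min(rr, lo, hi) <= 0:
        raise HbmetaError(f"risk ratios must be positive, got ({rr}, {lo}, {hi})")
    if lo > hi:
        raise HbmetaError(f"CI bounds out of order: ({lo}, {hi})")
    se = (math.log(hi) - math.log(lo)) / (2 * Z95)
    return EffectEstimate(math.log(rr), se, dose=dose, source=SOURCE_REPORTED)


def rr_from_counts(cases_exp: float, total_exp: float, cases_ref: float,
                   total_ref: float, continuity: float = 0.5,
                   dose: Optional[float] = None) -> EffectEstimate:
    """Risk ratio and log-scale SE from a 2x2 of cumulative-incidence counts.

    ``RR = (a/n1)/(c/n0)``; ``se = sqrt(1/a - 1/n1 + 1/c - 1/n0)``.  If any
    cell (cases or non-cases) is zero, the continuity correction is added to
    all four cells first so the estimate stays finite.
    """
    if total_exp <= 0 or total_ref <= 0:
        raise HbmetaError("category totals must be positive")
    a, n1, c, n0 = float(cases_exp), float(total_exp), float(cases_ref), float(total_ref)
    if min(a, n1 - a, c, n0 - c) <= 0:
        a += continuity
        c += continuity
        n1 += 2 * continuity
        n0 += 2 * continuity
    log_rr = math.log((a / n1) / (c / n0))
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return EffectEstimate(log_rr, se, dose=dose, source=SOURCE_FROM_COUNTS)


@dataclass(frozen=True)
class PseudoCounts:
    """Effective cases/totals per category implied by published RRs and CIs."""

    cases: tuple[float, ...]
    totals: tuple[float, ...]
    reference_index: int

    def noncases(self) -> tuple[float, ...]:
        return tuple(n - a for a, n in zip(self.cases, self.totals))


def _cells_given_reference(a0: float, n0: float, rrs: Sequence[float],
                           variances: Sequence[float]) -> tuple[list[float], list[float]]:
    """Solve each non-reference category's (cases, total) given reference cells.

    With reference risk p0 = a0/n0, a category reporting RR and var(log RR)
    = v satisfies p = RR*p0 and 1/a - 1/n = v - (1/a0 - 1/n0) =: u, giving
    the closed forms n = (1-p)/(p*u), a = (1-p)/u.
    """
    p0 = a0 / n0
    u_ref = 1 / a0 - 1 / n0
    cases, totals = [], []
    for rr, v in zip(rrs, variances):
        p = rr * p0
        u = v - u_ref
        if p >= 1 or u <= 0:
            raise NumericalError(
                f"infeasible pseudo-count cell (risk {p:.3g}, residual variance {u:.3g})"
            )
        cases.append((1 - p) / u)
        totals.append((1 - p) / (p * u))
    return cases, totals


def hamling_pseudo_counts(categories: Sequence[ExposureCategory],
                          study_cases: float, study_total: float) -> PseudoCounts:
    """Reconstruct effective counts matching published RRs, CIs, and margins.

    Finds reference-category cells ``(a0, n0)`` such that every category's
    implied cells reproduce its published RR and CI width exactly, and the
    summed cases and summed totals equal the study's crude margins.  The
    two margin constraints determine the two reference unknowns, but the
    system can admit more than one positive root; the solver therefore
    multistarts from a grid of proportional splits and keeps the root with
    the largest smallest category size (degenerate roots have near-zero
    pseudo denominators, which would wreck downstream variances).
    """
    ref_idx = next(i for i, c in enumerate(categories) if c.is_reference)
    others = [c for i, c in enumerate(categories) if i != ref_idx]
    if any(c.rr is None or c.ci_lower is None or c.ci_upper is None for c in others):
        raise HbmetaError("every non-reference category needs an RR with CI")
    if study_cases is None or study_total is None:
        raise HbmetaError("study-level crude cases and total are required")
    rrs = [c.rr for c in others]
    variances = [effect_from_ci(c.rr, c.ci_lower, c.ci_upper).se ** 2 for c in others]
    k = len(categories)

    def residual(theta):
        with np.errstate(all="ignore"):
            a0, n0 = np.exp(theta)
            if not (np.isfinite(a0) and np.isfinite(n0)):
                return np.array([1e6, 1e6])
            try:
                cases, totals = _cells_given_reference(a0, n0, rrs, variances)
            except NumericalError:
                return np.array([1e6, 1e6])
            return np.array([
                (a0 + sum(cases)) / study_cases - 1.0,
                (n0 + sum(totals)) / study_total - 1.0,
            ])

    best = None
    fractions = (1.0 / k, 0.05, 0.1, 0.2, 0.35, 0.5, 0.7, 0.9)
    for fa in fractions:
        for fn in fractions:
            x0 = np.log([max(study_cases * fa, 0.5), max(study_total * fn, 1.0)])
            sol = optimize.root(residual, x0, method="hybr", tol=1e-12)
            if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
                continue
            a0, n0 = np.exp(sol.x)
            try:
                cases, totals = _cells_given_reference(a0, n0, rrs, variances)
            except NumericalError:
                continue
            min_cell = min(min(cases), min(totals), a0, n0)
            if best is None or min_cell > best[0]:
                best = (min_cell, a0, n0, cases, totals)
    if best is None:
        raise NumericalError("pseudo-count solver did not converge from any start")
    _, a0, n0, cases, totals = best
    cases.insert(ref_idx, a0)
    totals.insert(ref_idx, n0)
    log.debug("pseudo-counts: cases %s totals %s", cases, totals)
    return PseudoCounts(tuple(cases), tuple(totals), ref_idx)


def hamling_reref(categories: Sequence[ExposureCategory], new_reference: int,
                  study_cases: Optional[float] = None,
                  study_total: Optional[float] = None) -> list[EffectEstimate]:
    """Re-express category effects against a different reference category.

    Solves for pseudo-counts consistent with the published RRs/CIs and the
    study margins, then recomputes each category's risk ratio against
    ``new_reference`` from those counts.  The new reference maps to
    ``(log_rr=0, se=0)`` by construction.
    """
    pc = hamling_pseudo_counts(categories, study_cases, study_total)
    out = []
    ar, nr = pc.cases[new_reference], pc.totals[new_reference]
    for i, cat in enumerate(categories):
        if i == new_reference:
            out.append(EffectEstimate(0.0, 0.0, dose=cat.assigned_dose,
                                      source=SOURCE_FROM_COUNTS))
        else:
            est = rr_from_counts(pc.cases[i], pc.totals[i], ar, nr,
                                 dose=cat.assigned_dose)
            out.append(est)
    return out
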