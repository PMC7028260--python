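"""Random-effects pooling, heterogeneity, sensitivity and trim-and-fill.

The moment-based DerSimonian–Laird estimator of the between-study variance
is used throughout: it is what the mainstream meta-analysis GUIs implement
for inverse-variance random effects, and the published pooled numbers this
package reproduces were produced by such software.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_math import Z95, EffectEstimate
from .errors import EmptyInputError, HbmetaError, InsufficientDataError, NumericalError
from .gl_trend import per_unit_effect
from .study_table import StudyTable

METHOD_DL_RANDOM = "DL_random"
METHOD_FIXED = "fixed"


@dataclass(frozen=True)
class PooledResult:
    """Summary of an inverse-variance pool of k study effects."""

    k: int
    pooled_log_rr: float
    se: float
    Q: float
    tau2: float
    i2: float
    weights: tuple[float, ...]
    method: str
    labels: tuple[str, ...] = ()

    @property
    def df(self) -> int:
        return self.k - 1

    @property
    def rr(self) -> float:
        return math.exp(self.pooled_log_rr)

    @property
    def ci_lower(self) -> float:
        return math.exp(self.pooled_log_rr - Z95 * self.se)

    @property
    def ci_upper(self) -> float:
        return math.exp(self.pooled_log_rr + Z95 * self.se)

    @property
    def p_overall(self) -> float:
        if self.se == 0:
            return 0.0 if self.pooled_log_rr != 0 else 1.0
        z = self.pooled_log_rr / self.se
        return 2 * stats.norm.sf(abs(z))

    def to_dict(self) -> dict:
        return {
            "k": self.k, "rr": self.rr, "ci": [self.ci_lower, self.ci_upper],
            "Q": self.Q, "df": self.df, "i2": self.i2, "tau2": self.tau2,
            "p": self.p_overall, "weights": list(self.weights),
            "labels": list(self.labels), "method": self.method,
        }


def pool(effects: Sequence[EffectEstimate], method: str = METHOD_DL_RANDOM,
         labels: Optional[Sequence[str]] = None) -> PooledResult:
    """Inverse-variance pool of log effects.

    Fixed-effect weights ``w_i = 1/se_i^2`` give Cochran's
    ``Q = sum w_i (L_i - L_FE)^2``; DerSimonian–Laird
    ``tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))``; random-effects
    weights ``1/(se_i^2 + tau2)`` give the pooled estimate and its SE.
    ``I² = max(0, (Q - df)/Q) * 100``.
    """
    if len(effects) == 0:
        raise EmptyInputError("no effects to pool")
    L = np.array([e.log_rr for e in effects])
    se = np.array([e.se for e in effects])
    if np.any(se <= 0):
        raise HbmetaError("all standard errors must be positive")
    labels = tuple(labels) if labels is not None else tuple(f"study_{i+1}" for i in range(len(L)))

    w = 1.0 / se ** 2
    mu_fe = float(np.sum(w * L) / np.sum(w))
    Q = float(np.sum(w * (L - mu_fe) ** 2))
    df = len(L) - 1
    if df > 0 and Q > 0:
        tau2 = max(0.0, (Q - df) / (np.sum(w) - np.sum(w ** 2) / np.sum(w)))
        i2 = max(0.0, (Q - df) / Q) * 100.0
    else:
        tau2, i2 = 0.0, 0.0
    if method == METHOD_FIXED:
        tau2_used = 0.0
    elif method == METHOD_DL_RANDOM:
        tau2_used = tau2
    else:
        raise HbmetaError(f"unknown pooling method {method!r}")
    ws = 1.0 / (se ** 2 + tau2_used)
    mu = float(np.sum(ws * L) / np.sum(ws))
    se_mu = float(1.0 / math.sqrt(np.sum(ws)))
    return PooledResult(
        k=len(L), pooled_log_rr=mu, se=se_mu, Q=Q, tau2=tau2, i2=i2,
        weights=tuple(np.asarray(ws / np.sum(ws))), method=method, labels=labels,
    )


HET_LOW, HET_MODERATE, HET_HIGH = "low", "moderate", "high"


def classify_heterogeneity(i2: float) -> str:
    """Conventional I² bands: <50 low, 50–75 moderate, >75 high."""
    if not 0 <= i2 <= 100:
        raise HbmetaError(f"I² must be in [0, 100], got {i2}")
    if i2 < 50:
        return HET_LOW
    if i2 <= 75:
        return HET_MODERATE
    return HET_HIGH


def _pool_records(records, method=METHOD_DL_RANDOM) -> PooledResult:
    effects = [per_unit_effect(r).as_effect() for r in records]
    return pool(effects, method=method, labels=[r.study_id for r in records])


def subgroup_pool(table: StudyTable, grouping: str,
                  method: str = METHOD_DL_RANDOM) -> dict[str, PooledResult]:
    """One pool per level of ``grouping`` ('population', 'outcome', 'adjusted').

    Auxiliary stratum records never enter (their per-1% effect lives on the
    parent record).  Empty groups are omitted.
    """
    if grouping not in ("population", "outcome", "adjusted"):
        raise HbmetaError(f"unknown grouping {grouping!r}")
    out: dict[str, PooledResult] = {}
    records = [r for r in table.records if not r.auxiliary]
    keys = sorted({str(getattr(r, grouping)) for r in records})
    for key in keys:
        members = [r for r in records if str(getattr(r, grouping)) == key]
        if members:
            out[key] = _pool_records(members, method)
    return out


def leave_one_out(effects: Sequence[EffectEstimate],
                  labels: Sequence[str],
                  method: str = METHOD_DL_RANDOM) -> list[tuple[str, PooledResult]]:
    """Re-pool k times, excluding each effect in turn (input order kept)."""
    if len(effects) < 2:
        raise InsufficientDataError("leave-one-out needs at least two studies")
    out = []
    for i, label in enumerate(labels):
        rest = [e for j, e in enumerate(effects) if j != i]
        rest_labels = [l for j, l in enumerate(labels) if j != i]
        out.append((label, pool(rest, method=method, labels=rest_labels)))
    return out


def trim_and_fill(effects: Sequence[EffectEstimate], side: str = "left",
                  max_iter: int = 50) -> tuple[int, PooledResult]:
    """Duval–Tweedie trim-and-fill with the R0 missing-study estimator.

    ``side`` names the funnel side where suppressed studies are presumed
    missing (the convention meta-analysis packages use): their surviving
    mirror images on the opposite side are iteratively trimmed, the
    fixed-effect center re-estimated, and the R0 run statistic recomputed
    until stable; the trimmed studies are then mirrored around the final
    center and a DL pool of the filled set returned.  ``k0 = 0`` returns
    the unadjusted pool.
    """
    if len(effects) < 3:
        raise InsufficientDataError("trim-and-fill needs at least three studies")
    if side not in ("left", "right"):
        raise HbmetaError("side must be 'left' or 'right'")
    # missing on the left -> excess extremes observed on the right get trimmed
    sign = 1.0 if side == "left" else -1.0
    L = np.array([e.log_rr for e in effects]) * sign
    se = np.array([e.se for e in effects])
    k = len(L)

    k0 = 0
    for _ in range(max_iter):
        keep = np.argsort(L)[: k - k0] if k0 else np.arange(k)
        w = 1.0 / se[keep] ** 2
        center = np.sum(w * L[keep]) / np.sum(w)
        dev = L - center
        order = np.argsort(np.abs(dev))  # ascending |deviation|
        signs = np.sign(dev[order])
        # rightmost run: count of most extreme deviations that are all positive
        gamma = 0
        for s in signs[::-1]:
            if s > 0:
                gamma += 1
            else:
                break
        new_k0 = max(gamma - 1, 0)
        if new_k0 == k0:
            break
        k0 = new_k0
    else:
        raise NumericalError("trim-and-fill did not stabilise")

    if k0 == 0:
        return 0, pool(list(effects))
    trimmed_idx = np.argsort(L)[k - k0:]
    keep = np.argsort(L)[: k - k0]
    w = 1.0 / se[keep] ** 2
    center = float(np.sum(w * L[keep]) / np.sum(w))
    filled_L = list(L) + [2 * center - L[i] for i in trimmed_idx]
    filled_se = list(se) + [se[i] for i in trimmed_idx]
    filled = [EffectEstimate(l * sign, s) for l, s in zip(filled_L, filled_se)]
    return k0, pool(filled)


def export_json(result: PooledResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def forest_frame(result: PooledResult,
                 effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Forest-plot-ready table: label, rr, lo, hi, weight_pct."""
    rows = [
        {"label": lab, "rr": e.rr, "lo": e.ci()[0], "hi": e.ci()[1],
         "weight_pct": 100 * wt}
        for lab, e, wt in zip(result.labels, effects, result.weights)
    ]
    rows.append({"label": "Pooled", "rr": result.rr, "lo": result.ci_lower,
                 "hi": result.ci_upper, "weight_pct": 100.0})
    return pd.DataFrame(rows)
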