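"""Lifespan-variation measures on period life tables.

Life disparity e-dagger is the average remaining life expectancy at the ages
people die — equivalently the average life-years lost per death:

    e† = ∫ d(a) e(a) da                     (continuous form)

evaluated discretely with e interpolated at the mean age at death within each
interval.  Related measures: the threshold age a† (where a marginal mortality
improvement has zero effect on e†), Keyfitz entropy H = e†/e0, and the
life-table Gini coefficient G = 1 − (1/e0) ∫ l(x)² dx.

Also provided: the cross-population coefficient of variation and the paired
first-difference quadrant analysis of (Δe0, Δe†).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lifetable import LifeTable, _lifetable_columns, build_lifetable

__all__ = [
    "DispersionSummary",
    "QuadrantSummary",
    "e_dagger",
    "threshold_age",
    "keyfitz_entropy",
    "gini_lifetable",
    "cv_across_populations",
    "quadrant_analysis",
    "summarize",
]


def _edagger_from_columns(cols: dict, ages: np.ndarray) -> np.ndarray:
    """Vectorised e† on life-table column arrays of shape (n_ages, k)."""
    n = np.diff(ages).astype(float)[:, None]
    dx, ex, ax = cols["dx"], cols["ex"], cols["ax"]
    w = ax[:-1] / n  # weight of e(x+n) at the mean age at death
    closed = dx[:-1] * ((1.0 - w) * ex[:-1] + w * ex[1:])
    return closed.sum(axis=0) + dx[-1] * ex[-1]


def e_dagger(lt: LifeTable) -> float:
    """Life disparity: average remaining life expectancy at death, in years.

    Discrete evaluation of ∫ d(a)e(a)da; within each closed interval e is
    linearly interpolated at the mean age at death x + a(x), and the open
    interval contributes d(open) * e(open).
    """
    cols = {k: getattr(lt, k)[:, None] for k in ("dx", "ex", "ax")}
    return float(_edagger_from_columns(cols, lt.ages)[0])


def e0_edagger_matrix(mx: np.ndarray, ages: np.ndarray, a0_rule="coale-demeny"):
    """(e0, e†) for each column of a rate matrix — fast path for decomposition
    and sensitivity sweeps."""
    mx = np.asarray(mx, dtype=float)
    if mx.ndim == 1:
        mx = mx[:, None]
    cols = _lifetable_columns(mx, ages, a0_rule)
    return cols["ex"][0], _edagger_from_columns(cols, np.asarray(ages))


def keyfitz_entropy(lt: LifeTable) -> float:
    """Keyfitz life-table entropy H = (−∫ l ln l dx) / e0.

    Computed by trapezoid quadrature on the survival curve — an independent
    route from :func:`e_dagger` — with the open interval integrated in closed
    form under its constant hazard m(open):

        ∫_open l(x) Λ(x) dx = l_open (Λ_open + 1) / m_open.

    Satisfies H ≈ e†/e0 up to discretisation error.
    """
    lx = lt.lx
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(lx > 0, -lx * np.log(np.where(lx > 0, lx, 1.0)), 0.0)
    body = np.trapezoid(integrand, lt.ages.astype(float))
    l_open = lx[-1]
    if l_open > 0:
        tail = l_open * (-np.log(l_open) + 1.0) / lt.mx[-1]
    else:
        tail = 0.0
    return float((body + tail) / lt.e0)


def gini_lifetable(lt: LifeTable) -> float:
    """Life-table Gini coefficient G = 1 − (1/e0) ∫ l(x)² dx (radix 1).

    Trapezoid on the table grid; exponential tail ∫ l² = l_open² / (2 m_open)
    beyond the open age.  G lies in [0, 1): 0 for rectangular survival,
    1/2 for a constant hazard.
    """
    lsq = lt.lx**2
    body = np.trapezoid(lsq, lt.ages.astype(float))
    tail = lsq[-1] / (2.0 * lt.mx[-1])
    return float(1.0 - (body + tail) / lt.Tx[0])


def _band_factors(ages: np.ndarray, center: float, bandwidth: float, reduction: float):
    """Multiplier per interval for a proportional hazard reduction applied on
    the band [center − w/2, center + w/2], weighted by fractional overlap."""
    edges = np.append(ages.astype(float), ages[-1] + 1.0)  # open interval ~ width 1
    lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
    left = np.maximum(edges[:-1], lo)
    right = np.minimum(edges[1:], hi)
    overlap = np.clip(right - left, 0.0, None) / (edges[1:] - edges[:-1])
    return 1.0 - reduction * overlap


def threshold_age(
    lt: LifeTable,
    bandwidth: float = 1.0,
    reduction: float = 0.01,
    return_all: bool = False,
):
    """Threshold age a†: where a marginal mortality reduction leaves e† unchanged.

    Sweeps a finite-difference sensitivity s(a) = e†(rates reduced by
    ``reduction`` in a band of width ``bandwidth`` centred at a) − e†(rates)
    over the grid; reductions below a† compress lifespan variation (s < 0),
    reductions above expand it (s > 0).  Each sign change is refined by root
    finding on the continuous band position.

    Returns the oldest crossing below the open interval (and, with
    ``return_all``, the list of all crossings).

    Raises ``ValueError`` when the sensitivity never changes sign (a schedule
    without a threshold).
    """
    ages = lt.ages
    mx = lt.mx
    base = e_dagger(lt)

    def s(center: float) -> float:
        f = _band_factors(ages, center, bandwidth, reduction)
        _, ed = e0_edagger_matrix(mx * f, ages)
        return float(ed[0] - base)

    centers = ages[:-1].astype(float) + np.diff(ages) / 2.0
    vals = np.array([s(c) for c in centers])
    # ignore numerically-dead cells (no survivors left, sensitivity exactly 0)
    tol = 1e-9 * np.max(np.abs(vals))
    sig = np.nonzero(np.abs(vals) > tol)[0]
    crossings = []
    for i, j in zip(sig[:-1], sig[1:]):
        if vals[i] * vals[j] < 0:
            crossings.append(float(brentq(s, centers[i], centers[j], xtol=1e-10)))
    if not crossings:
        raise ValueError("e-dagger sensitivity has no sign change: no threshold age")
    a_dagger = crossings[-1]
    if return_all:
        return a_dagger, crossings
    return a_dagger


def cv_across_populations(values) -> float:
    """Coefficient of variation across populations: population SD / mean.

    Uses the n-denominator standard deviation (the populations are the full
    study set, not a sample).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 populations")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("mean must be positive for a coefficient of variation")
    return float(values.std(ddof=0) / mean)


@dataclass(frozen=True)
class DispersionSummary:
    """Per-year, per-population summary of location and dispersion."""

    e0: float
    e_dagger: float
    threshold_age: float
    entropy: float
    gini: float


def summarize(lt: LifeTable, bandwidth: float = 1.0) -> DispersionSummary:
    ed = e_dagger(lt)
    return DispersionSummary(
        e0=lt.e0,
        e_dagger=ed,
        threshold_age=threshold_age(lt, bandwidth=bandwidth),
        entropy=ed / lt.e0,
        gini=gini_lifetable(lt),
    )


_QUADRANTS = {
    (1, 1): "up_up",
    (1, -1): "up_down",
    (-1, 1): "down_up",
    (-1, -1): "down_down",
}


@dataclass(frozen=True)
class QuadrantSummary:
    """Counts and proportions of (sign Δe0, sign Δe†) year-pair quadrants."""

    period: str
    scale: str  # "absolute" or "relative"
    counts: dict
    n_pairs: int
    proportions: dict
    ci_low: dict
    ci_high: dict
    n_zero_excluded: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in _QUADRANTS.values():
            rows.append(
                {
                    "period": self.period,
                    "scale": self.scale,
                    "quadrant": q,
                    "count": self.counts[q],
                    "proportion": self.proportions[q],
                    "ci_low": self.ci_low[q],
                    "ci_high": self.ci_high[q],
                }
            )
        return pd.DataFrame(rows)


def quadrant_analysis(
    e0_df: pd.DataFrame,
    edagger_df: pd.DataFrame,
    periods,
    scale: str = "absolute",
    drop_zero: bool = True,
) -> list[QuadrantSummary]:
    """Classify paired yearly first differences of e0 and e† by sign quadrant.

    Parameters
    ----------
    e0_df, edagger_df : DataFrames indexed by year with one column per
        population, aligned.
    periods : iterable of (start_year, end_year, label); a year pair
        (t, t+1) belongs to the period with start <= t < end.
    scale : "absolute" (year differences) or "relative" (differences divided
        by the previous year's value).
    drop_zero : exclude exact-zero first differences from denominators
        (classified as "no change").

    95% CIs are normal-approximation binomial: p ± 1.96 sqrt(p(1−p)/n),
    truncated to [0, 1].
    """
    if scale not in ("absolute", "relative"):
        raise ValueError("scale must be 'absolute' or 'relative'")
    e0_df, edagger_df = e0_df.align(edagger_df, join="inner")
    years = e0_df.index.to_numpy()
    d_e0 = e0_df.diff().iloc[1:]
    d_ed = edagger_df.diff().iloc[1:]
    if scale == "relative":
        d_e0 = d_e0 / e0_df.shift().iloc[1:]
        d_ed = d_ed / edagger_df.shift().iloc[1:]
    base_years = years[:-1]  # pair (t, t+1) keyed by t

    out = []
    for start, end, label in periods:
        mask = (base_years >= start) & (base_years < end)
        if mask.sum() < 1:
            out.append(
                QuadrantSummary(
                    period=label,
                    scale=scale,
                    counts={q: 0 for q in _QUADRANTS.values()},
                    n_pairs=0,
                    proportions={q: np.nan for q in _QUADRANTS.values()},
                    ci_low={q: np.nan for q in _QUADRANTS.values()},
                    ci_high={q: np.nan for q in _QUADRANTS.values()},
                    n_zero_excluded=0,
                )
            )
            continue
        a = d_e0.iloc[mask].to_numpy().ravel()
        b = d_ed.iloc[mask].to_numpy().ravel()
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        zero = (a == 0) | (b == 0)
        n_zero = int(zero.sum()) if drop_zero else 0
        if drop_zero:
            a, b = a[~zero], b[~zero]
        counts = {q: 0 for q in _QUADRANTS.values()}
        for sa, sb in zip(np.sign(a), np.sign(b)):
            key = (int(sa) if sa != 0 else 1, int(sb) if sb != 0 else 1)
            counts[_QUADRANTS[key]] += 1
        n = sum(counts.values())
        props, lo, hi = {}, {}, {}
        for q, c in counts.items():
            p = c / n if n else np.nan
            props[q] = p
            if n:
                half = 1.96 * np.sqrt(p * (1 - p) / n)
                lo[q], hi[q] = max(0.0, p - half), min(1.0, p + half)
            else:
                lo[q] = hi[q] = np.nan
        out.append(
            QuadrantSummary(
                period=label,
                scale=scale,
                counts=counts,
                n_pairs=n,
                proportions=props,
                ci_low=lo,
                ci_high=hi,
                n_zero_excluded=n_zero,
            )
        )
    return out
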