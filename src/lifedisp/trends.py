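"""Mortality-trend diagnostics and period segmentation.

Three tools:

* a 2-D penalized-least-squares (Whittaker) smoother of log death rates on
  the Lexis grid, with second-order difference penalties along age and year
  and generalized cross-validation for the penalty weights;
* annual rates of mortality improvement rho(x, t) = -100 * d/dt log m(x, t)
  on the smoothed surface, categorised as improvement / worsening / little
  change at a +-0.5% band;
* divisive hierarchical multiple change-point detection on a yearly series
  (energy-distance statistic, permutation significance test), used to
  segment the cross-country coefficient-of-variation series into analysis
  periods, and a mapper from statistical breaks to the canonical period
  boundaries {1980, 1988, 1994, 2000}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lifetable import MortalitySurface

__all__ = [
    "ImprovementSurface",
    "PeriodSegmentation",
    "smooth_log_rates",
    "improvement_rates",
    "detect_changepoints",
    "assign_periods",
    "CANONICAL_BOUNDARIES",
    "CANONICAL_LABELS",
]

_LOG_FLOOR = 1e-8  # rates are floored here before logging
_RHO_BAND = 0.5  # percent; the little-change band is (-0.5, 0.5)

CANONICAL_BOUNDARIES = (1980, 1988, 1994, 2000)
CANONICAL_LABELS = (
    "stagnation",
    "improvements",
    "deterioration",
    "divergence",
    "convergence",
)


# ---------------------------------------------------------------------------
# Smoothing


def _second_diff_eig(k: int):
    """Eigendecomposition of D2'D2 for a second-order difference penalty."""
    d = np.diff(np.eye(k), n=2, axis=0)
    return np.linalg.eigh(d.T @ d)


def _fit_2d(Y, Ua, sa, Uy, sy, lam_a, lam_y):
    core = Ua.T @ Y @ Uy
    shrink = 1.0 / (1.0 + lam_a * sa[:, None] + lam_y * sy[None, :])
    return Ua @ (core * shrink) @ Uy.T, shrink


def smooth_log_rates(
    surface: MortalitySurface,
    lambda_age: float | None = None,
    lambda_year: float | None = None,
) -> MortalitySurface:
    """Smooth a mortality surface on the log scale.

    Penalized least squares with second-order difference penalties along the
    age and year directions; the penalty null space contains all bilinear
    log surfaces, which pass through unchanged.  When a penalty weight is
    ``None`` it is chosen by generalized cross-validation on a log-spaced
    grid.  Zero rates are floored at 1e-8 before logging; output rates are
    strictly positive.
    """
    if len(surface.ages) < 3 or len(surface.years) < 3:
        raise ValueError("need at least 3 ages and 3 years for second differences")
    Y = np.log(np.maximum(surface.mx, _LOG_FLOOR))
    sa, Ua = _second_diff_eig(Y.shape[0])
    sy, Uy = _second_diff_eig(Y.shape[1])
    sa, sy = np.maximum(sa, 0), np.maximum(sy, 0)

    if lambda_age is None or lambda_year is None:
        grid = 10.0 ** np.arange(-1, 6)
        best = (np.inf, grid[0], grid[0])
        N = Y.size
        for la in grid if lambda_age is None else [lambda_age]:
            for ly in grid if lambda_year is None else [lambda_year]:
                F, shrink = _fit_2d(Y, Ua, sa, Uy, sy, la, ly)
                rss = float(((Y - F) ** 2).sum())
                edf = float(shrink.sum())
                gcv = N * rss / (N - edf) ** 2
                if gcv < best[0]:
                    best = (gcv, la, ly)
        _, lambda_age, lambda_year = best

    F, _ = _fit_2d(Y, Ua, sa, Uy, sy, lambda_age, lambda_year)
    return replace(surface, mx=np.exp(F))


# ---------------------------------------------------------------------------
# Rates of improvement


@dataclass(frozen=True)
class ImprovementSurface:
    """Annual rates of mortality improvement rho(x, t), in percent.

    ``rho[x, j]`` is the improvement from ``years[j]`` to ``years[j] + 1``;
    ``category`` cells are 'improvement' (rho > 0.5), 'worsening'
    (rho < -0.5) or 'little_change'.
    """

    ages: np.ndarray
    years: np.ndarray  # year t of each (t, t+1) pair
    rho: np.ndarray
    category: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        a, y = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame(
            {
                "age": a.ravel(),
                "year": y.ravel(),
                "rho_pct": self.rho.ravel(),
                "category": self.category.ravel(),
            }
        )


def improvement_rates(surface: MortalitySurface) -> ImprovementSurface:
    """Year-over-year rates of mortality improvement on a (smoothed) surface:
    rho(x, t) = -100 [ln m(x, t+1) - ln m(x, t)]."""
    if len(surface.years) < 2:
        raise ValueError("need at least 2 years")
    logm = np.log(np.maximum(surface.mx, _LOG_FLOOR))
    rho = -100.0 * np.diff(logm, axis=1)
    category = np.where(
        rho > _RHO_BAND,
        "improvement",
        np.where(rho < -_RHO_BAND, "worsening", "little_change"),
    )
    return ImprovementSurface(
        ages=surface.ages.copy(),
        years=surface.years[:-1].copy(),
        rho=rho,
        category=category,
    )


# ---------------------------------------------------------------------------
# Divisive hierarchical change-point detection (energy statistic)


@dataclass(frozen=True)
class PeriodSegmentation:
    """Ordered break years partitioning a series into analysis periods.

    A break year is the first year of a new segment.  ``statistics`` and
    ``p_values`` align with ``breaks``; ``labels`` has one entry per segment
    (len(breaks) + 1).
    """

    start_year: int
    end_year: int
    breaks: tuple
    statistics: tuple
    p_values: tuple
    labels: tuple

    def boundaries(self) -> list:
        return [self.start_year, *self.breaks, self.end_year]

    def periods(self) -> list:
        b = self.boundaries()
        return [(b[i], b[i + 1], self.labels[i]) for i in range(len(b) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "break_year": self.breaks,
                "statistic": self.statistics,
                "p_value": self.p_values,
            }
        )


def _prefix2d(D: np.ndarray) -> np.ndarray:
    S = np.zeros((D.shape[0] + 1, D.shape[1] + 1))
    S[1:, 1:] = D.cumsum(0).cumsum(1)
    return S


def _block_sum(S, r0, r1, c0, c1):
    return S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]


def _best_split(S, lo, hi, min_seg):
    """Best split of segment [lo, hi) maximizing the scaled energy statistic
    Q = mn/(m+n) * (2*mean_between - mean_within_x - mean_within_y)."""
    best_q, best_k = -np.inf, -1
    for k in range(lo + min_seg, hi - min_seg + 1):
        m, n = k - lo, hi - k
        between = _block_sum(S, lo, k, k, hi) / (m * n)
        wx = _block_sum(S, lo, k, lo, k) / (m * m)
        wy = _block_sum(S, k, hi, k, hi) / (n * n)
        q = m * n / (m + n) * (2.0 * between - wx - wy)
        if q > best_q:
            best_q, best_k = q, k
    return best_q, best_k


def _max_stat(x, segments, min_seg):
    D = np.abs(x[:, None] - x[None, :])
    S = _prefix2d(D)
    best = (-np.inf, -1, -1)
    for si, (lo, hi) in enumerate(segments):
        if hi - lo >= 2 * min_seg:
            q, k = _best_split(S, lo, hi, min_seg)
            if q > best[0]:
                best = (q, k, si)
    return best


def detect_changepoints(
    series,
    years=None,
    min_segment: int = 5,
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int | None = 0,
) -> PeriodSegmentation:
    """Divisive hierarchical multiple change-point detection.

    At each stage the candidate split maximizing the between-segment
    energy-distance statistic (Euclidean, exponent 1) over all current
    segments is tested against a permutation null (observations permuted
    within the current segmentation, ``n_permutations`` draws, seeded);
    significant splits (p <= alpha) are accepted and the search recurses.
    The series is standardized first, making detection invariant to affine
    transforms.

    Parameters
    ----------
    series : 1-d yearly values (or a pandas Series indexed by year).
    years : explicit year labels when ``series`` is a bare array.
    """
    if isinstance(series, pd.Series):
        years = series.index.to_numpy()
        x = series.to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
        if years is None:
            years = np.arange(len(x))
        years = np.asarray(years)
    n = len(x)
    if n < 2 * min_segment:
        raise ValueError(
            f"series of length {n} is shorter than 2 * min_segment = {2 * min_segment}"
        )
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    rng = np.random.default_rng(seed)

    segments = [(0, n)]
    found = []  # (index, statistic, p_value)
    while True:
        q_obs, k, si = _max_stat(z, segments, min_segment)
        if not np.isfinite(q_obs) or k < 0:
            break
        exceed = 0
        for _ in range(n_permutations):
            zp = np.empty_like(z)
            for lo, hi in segments:
                zp[lo:hi] = rng.permutation(z[lo:hi])
            q_perm, _, _ = _max_stat(zp, segments, min_segment)
            if q_perm >= q_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        if p > alpha:
            break
        found.append((k, q_obs, p))
        lo, hi = segments.pop(si)
        segments.insert(si, (lo, k))
        segments.insert(si + 1, (k, hi))
    found.sort(key=lambda t: t[0])
    breaks = tuple(int(years[k]) for k, _, _ in found)
    return PeriodSegmentation(
        start_year=int(years[0]),
        end_year=int(years[-1]),
        breaks=breaks,
        statistics=tuple(q for _, q, _ in found),
        p_values=tuple(p for _, _, p in found),
        labels=tuple(f"period_{i + 1}" for i in range(len(breaks) + 1)),
    )


def assign_periods(
    segmentation: PeriodSegmentation,
    canonical=CANONICAL_BOUNDARIES,
    snap_within: int = 4,
) -> PeriodSegmentation:
    """Map statistical breaks to canonical analysis boundaries.

    A break within ``snap_within`` years of a canonical boundary is moved to
    it (the default 4 covers the historical 1976 -> 1980 rounding of the
    stagnation/improvements cut); other breaks are kept and their flanking
    segments labelled
    non-canonical.  When the snapped boundaries are exactly the canonical
    set the five named periods (stagnation, improvements, deterioration,
    divergence, convergence) are emitted.
    """
    snapped, noncanon = [], set()
    for b in segmentation.breaks:
        dist = [abs(b - c) for c in canonical]
        j = int(np.argmin(dist))
        if dist[j] <= snap_within:
            if canonical[j] not in snapped:
                snapped.append(canonical[j])
        else:
            snapped.append(b)
            noncanon.add(b)
    snapped = sorted(snapped)
    if tuple(snapped) == tuple(canonical):
        labels = CANONICAL_LABELS
    else:
        labels = tuple(
            "non-canonical" if (i < len(snapped) and snapped[i] in noncanon)
            or (i > 0 and snapped[i - 1] in noncanon)
            else f"period_{i + 1}"
            for i in range(len(snapped) + 1)
        )
    return replace(
        segmentation,
        breaks=tuple(snapped),
        statistics=segmentation.statistics[: len(snapped)],
        p_values=segmentation.p_values[: len(snapped)],
        labels=labels,
    )
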