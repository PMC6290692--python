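"""Period life-table construction from age-specific death rates.

The central object is the :class:`MortalitySurface` — a Lexis rectangle of
death rates m(x, t) for one population and sex — and the :class:`LifeTable`
built from one of its columns.  Tables follow the standard period closure:

    q(x) = n * m(x) / (1 + (n - a(x)) * m(x)),

with the open interval closed by q = 1, a(open) = e(open) = 1 / m(open).

The average person-years lived by decedents in the first year of life use a
Coale–Demeny-style rule a(0) = 0.07 + 1.7 * m(0), capped at 0.5; elsewhere
a(x) = n / 2.  Both single-year grids (0..109 plus 110+) and abridged 5-year
grids (0, 5, ..., 85+) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySurface",
    "LifeTable",
    "AdjustmentScenario",
    "build_lifetable",
    "apply_adjustment",
    "infant_inflation_schedule",
]

_A0_CAP = 0.5


def _validate_rates(mx: np.ndarray, ages: np.ndarray) -> None:
    bad = ~np.isfinite(mx) | (mx < 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid death rate at age {ages[idx[0]]}: "
            f"rates must be finite and non-negative"
        )
    if np.any(mx[-1] <= 0):
        raise ValueError("open-interval death rate must be strictly positive")


def _ax_values(mx0, ages: np.ndarray, a0_rule: str) -> np.ndarray:
    """Mean person-years lived in each closed interval by those dying in it.

    ``mx0`` may be a scalar m(0) or a vector of m(0) values (one per column
    when vectorising over years).
    """
    n = np.diff(ages).astype(float)
    ax = n / 2.0
    if a0_rule == "coale-demeny" and ages[0] == 0 and n[0] == 1:
        a0 = np.minimum(0.07 + 1.7 * np.asarray(mx0), _A0_CAP)
        return n, ax, a0
    return n, ax, ax[0] if np.ndim(mx0) == 0 else np.full(np.shape(mx0), ax[0])


def _lifetable_columns(mx: np.ndarray, ages: np.ndarray, a0_rule: str = "coale-demeny"):
    """Vectorised life-table kernel.

    Parameters
    ----------
    mx : array, shape (n_ages,) or (n_ages, k)
        Death rates; the last row is the open interval.

    Returns a dict of arrays with the same trailing shape as ``mx``.
    """
    mx = np.asarray(mx, dtype=float)
    squeeze = mx.ndim == 1
    if squeeze:
        mx = mx[:, None]
    n_ages = mx.shape[0]
    if n_ages != len(ages):
        raise ValueError("mx and ages length mismatch")

    n, ax_closed, a0 = _ax_values(mx[0], ages, a0_rule)
    ax = np.broadcast_to(ax_closed[:, None], mx[:-1].shape).copy()
    ax[0] = a0

    nn = n[:, None]
    qx = nn * mx[:-1] / (1.0 + (nn - ax) * mx[:-1])
    np.minimum(qx, 1.0, out=qx)

    lx = np.empty_like(mx)
    lx[0] = 1.0
    np.cumprod(1.0 - qx, axis=0, out=lx[1:])

    dx = np.empty_like(mx)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]

    m_open = mx[-1]
    e_open = 1.0 / m_open

    Lx = np.empty_like(mx)
    Lx[:-1] = nn * lx[1:] + ax * dx[:-1]
    Lx[-1] = lx[-1] * e_open

    Tx = np.cumsum(Lx[::-1], axis=0)[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    ex[-1] = np.where(lx[-1] > 0, e_open, 0.0)

    qx_full = np.concatenate([qx, np.ones((1, mx.shape[1]))], axis=0)
    ax_full = np.concatenate([ax, e_open[None, :]], axis=0)

    cols = dict(mx=mx, ax=ax_full, qx=qx_full, lx=lx, dx=dx, Lx=Lx, Tx=Tx, ex=ex)
    if squeeze:
        cols = {k: v[:, 0] for k, v in cols.items()}
    return cols


@dataclass(frozen=True)
class LifeTable:
    """Full period life table on a stated age grid with open interval.

    All columns are per unit radix (l(0) = 1).  ``n`` holds closed-interval
    widths followed by ``inf`` for the open interval.
    """

    ages: np.ndarray
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray

    @property
    def n(self) -> np.ndarray:
        return np.concatenate([np.diff(self.ages).astype(float), [np.inf]])

    @property
    def open_age(self) -> int:
        return int(self.ages[-1])

    @property
    def e0(self) -> float:
        return float(self.ex[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "mx": self.mx,
                "ax": self.ax,
                "qx": self.qx,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )


def build_lifetable(
    mx: np.ndarray, ages: np.ndarray, a0_rule: str = "coale-demeny"
) -> LifeTable:
    """Build a period life table from one year's death rates.

    Parameters
    ----------
    mx : death rates per person-year, one per age; last entry is the open
        interval (e.g. 110+).
    ages : strictly increasing integer grid (single-year or abridged).
    a0_rule : "coale-demeny" (default; a0 = 0.07 + 1.7 m0 capped at 0.5 on
        single-year grids) or "midpoint" (a = n/2 everywhere).
    """
    ages = np.asarray(ages)
    mx = np.asarray(mx, dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("age grid must be strictly increasing")
    _validate_rates(mx, ages)
    cols = _lifetable_columns(mx, ages, a0_rule)
    return LifeTable(ages=ages.copy(), **cols)


@dataclass(frozen=True)
class MortalitySurface:
    """Age x calendar-year rectangle of death rates for one population/sex."""

    population_id: str
    sex: str
    ages: np.ndarray
    years: np.ndarray
    mx: np.ndarray  # shape (n_ages, n_years)
    open_age: int = 110

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages))
        object.__setattr__(self, "years", np.asarray(self.years))
        object.__setattr__(self, "mx", np.asarray(self.mx, dtype=float))
        if self.mx.shape != (len(self.ages), len(self.years)):
            raise ValueError(
                f"mx shape {self.mx.shape} does not match "
                f"({len(self.ages)}, {len(self.years)}) grid"
            )
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if self.ages[-1] != self.open_age:
            raise ValueError("last age must equal open_age")
        _validate_rates(self.mx, self.ages)

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise KeyError(f"year {year} not on the surface")
        return int(idx[0])

    def column(self, year: int) -> np.ndarray:
        return self.mx[:, self.year_index(year)]

    def lifetable(self, year: int, a0_rule: str = "coale-demeny") -> LifeTable:
        return build_lifetable(self.column(year), self.ages, a0_rule)

    def lifetables(self, a0_rule: str = "coale-demeny") -> dict[int, LifeTable]:
        cols = _lifetable_columns(self.mx, self.ages, a0_rule)
        return {
            int(y): LifeTable(
                ages=self.ages.copy(), **{k: v[:, j] for k, v in cols.items()}
            )
            for j, y in enumerate(self.years)
        }

    def restrict_ages(self, start_age: int) -> "MortalitySurface":
        if start_age not in self.ages:
            raise ValueError(f"age {start_age} not on the grid")
        keep = self.ages >= start_age
        return replace(self, ages=self.ages[keep], mx=self.mx[keep, :])


@dataclass(frozen=True)
class AdjustmentScenario:
    """Robustness adjustment applied to a mortality surface.

    kind = "infant_inflation": multiply the age-0 rate by a per-year factor
    (``schedule`` maps year -> multiplier).  kind = "condition_on_age": drop
    ages below ``start_age`` and reset the radix there.
    """

    kind: str
    schedule: Mapping[int, float] | None = None
    start_age: int | None = None


def infant_inflation_schedule(years) -> dict[int, float]:
    """Infant-mortality inflation scenario: a doubling before 1990, linear
    decrease to 10% inflation by 2000, constant 10% thereafter."""
    out = {}
    for y in np.asarray(years):
        y = int(y)
        if y < 1990:
            out[y] = 2.0
        elif y < 2000:
            out[y] = 2.0 + (1.1 - 2.0) * (y - 1990) / 10.0
        else:
            out[y] = 1.1
    return out


def apply_adjustment(
    surface: MortalitySurface, scenario: AdjustmentScenario
) -> MortalitySurface:
    """Apply a robustness scenario, returning a new surface.

    For ``condition_on_age`` the returned surface starts at the conditioning
    age; life tables built from it have their radix at that age.
    """
    if scenario.kind == "infant_inflation":
        if scenario.schedule is None:
            raise ValueError("infant_inflation requires a year -> multiplier schedule")
        factors = np.array(
            [float(scenario.schedule.get(int(y), 1.0)) for y in surface.years]
        )
        if np.any(factors <= 0):
            raise ValueError("inflation multipliers must be positive")
        if surface.ages[0] != 0:
            raise ValueError("surface has no age-0 row to inflate")
        mx = surface.mx.copy()
        mx[0, :] = mx[0, :] * factors
        return replace(surface, mx=mx)
    if scenario.kind == "condition_on_age":
        if scenario.start_age is None:
            raise ValueError("condition_on_age requires start_age")
        return surface.restrict_ages(int(scenario.start_age))
    raise ValueError(f"unknown adjustment kind: {scenario.kind!r}")
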