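"""Readers and writers for the HMD Mx 1x1 text dialect and HCDB-like cause
tables.

The Mx 1x1 dialect: a free-text header line, a blank line, a column header
``Year Age Female Male Total``, then whitespace-aligned rows with ages
0..109 and the open interval written ``110+``; missing values are ``.``.

Cause files are plain CSV with columns ``country, year, sex, cause`` and one
column per 5-year age-group start (``a0, a5, ..., a85``) holding death
counts or proportions; the ``cause`` field is either one of the seven
pre-grouped category labels or an ICD-10 code routed through
:func:`lifedisp.causes.classify_icd10`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .causes import CAUSE_CATEGORIES, CauseProportionTable, classify_icd10
from .lifetable import MortalitySurface

__all__ = [
    "read_hmd_mx",
    "write_hmd_mx",
    "read_cause_table",
    "write_cause_table",
]

_SEXES = ("female", "male", "total")


def _parse_age(token: str, lineno: int) -> tuple[int, bool]:
    if token.endswith("+"):
        return int(token[:-1]), True
    try:
        return int(token), False
    except ValueError:
        raise ValueError(f"malformed age token {token!r} on line {lineno}") from None


def read_hmd_mx(path, population_id: str | None = None, strict: bool = True) -> dict:
    """Read a period Mx 1x1 file; returns {sex: MortalitySurface}.

    In strict mode (default) any missing value ('.') is rejected; in lenient
    mode missing cells become NaN and the affected years are listed in the
    surface's ``flagged_years`` attribute (callers must impute or drop them
    before building life tables).
    """
    path = Path(path)
    if population_id is None:
        population_id = path.name.split(".")[0]
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["Year", "Age"]:
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path}: no 'Year Age ...' column header found")
    seen = set()
    for lineno, line in enumerate(lines[start:], start + 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        year = int(parts[0])
        age, is_open = _parse_age(parts[1], lineno)
        if (year, age) in seen:
            raise ValueError(f"{path}:{lineno}: duplicate (year, age) = ({year}, {age})")
        seen.add((year, age))
        vals = []
        for tok in parts[2:]:
            if tok == ".":
                vals.append(np.nan)
            else:
                vals.append(float(tok))
        rows.append((year, age, is_open, *vals))

    df = pd.DataFrame(rows, columns=["year", "age", "open", *_SEXES])
    open_rows = df[df["open"]]
    if open_rows.empty:
        raise ValueError(f"{path}: no open-interval ('+') age row found")
    open_age = int(open_rows["age"].iloc[0])
    years = np.sort(df["year"].unique())
    ages = np.sort(df["age"].unique())
    if ages[-1] != open_age:
        raise ValueError(f"{path}: open age {open_age} is not the largest age")

    out = {}
    for sex in _SEXES:
        pivot = df.pivot(index="age", columns="year", values=sex)
        pivot = pivot.reindex(index=ages, columns=years)
        mx = pivot.to_numpy(dtype=float)
        missing = np.isnan(mx)
        if missing.any():
            # non-rectangular blocks show up as missing cells too
            holes = df.groupby("year")["age"].count()
            if holes.nunique() > 1:
                raise ValueError(
                    f"{path}: non-rectangular year blocks "
                    f"(row counts {sorted(holes.unique())})"
                )
            flagged = [int(y) for y in years[missing.any(axis=0)]]
            if strict:
                raise ValueError(
                    f"{path}: missing values ('.') for sex={sex} in years "
                    f"{flagged}; use strict=False to carry them"
                )
        else:
            flagged = []
        surf = MortalitySurface.__new__(MortalitySurface)
        # bypass validation when carrying NaN markers in lenient mode
        object.__setattr__(surf, "population_id", population_id)
        object.__setattr__(surf, "sex", sex)
        object.__setattr__(surf, "ages", ages)
        object.__setattr__(surf, "years", years)
        object.__setattr__(surf, "mx", mx)
        object.__setattr__(surf, "open_age", open_age)
        if not missing.any():
            # re-run the invariant checks via the real constructor
            surf = MortalitySurface(
                population_id=population_id,
                sex=sex,
                ages=ages,
                years=years,
                mx=mx,
                open_age=open_age,
            )
        object.__setattr__(surf, "flagged_years", flagged)
        out[sex] = surf
    return out


def write_hmd_mx(path, surfaces: dict, header: str | None = None) -> None:
    """Write surfaces (keyed by sex; missing sexes are filled with '.') in
    the Mx 1x1 dialect.  Values are printed with %.17g so that reading the
    file back reproduces the rates exactly."""
    some = next(iter(surfaces.values()))
    ages, years, open_age = some.ages, some.years, some.open_age
    for s in surfaces.values():
        if not (np.array_equal(s.ages, ages) and np.array_equal(s.years, years)):
            raise ValueError("all surfaces must share one (age, year) grid")
    if header is None:
        header = f"{some.population_id}, Mx (period 1x1), synthetic fixture"
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header + "\n\n")
        fh.write(f"{'Year':>6} {'Age':>6} {'Female':>24} {'Male':>24} {'Total':>24}\n")
        for j, year in enumerate(years):
            for i, age in enumerate(ages):
                age_tok = f"{age}+" if age == open_age else str(age)
                cells = []
                for sex in _SEXES:
                    if sex in surfaces:
                        cells.append(f"{surfaces[sex].mx[i, j]:.17g}")
                    else:
                        cells.append(".")
                fh.write(
                    f"{year:>6} {age_tok:>6} "
                    + " ".join(f"{c:>24}" for c in cells)
                    + "\n"
                )


def write_cause_table(path, country: str, sex: str, tables: dict) -> None:
    """Write {year: CauseProportionTable} as a wide CSV (one row per cause,
    one column per age-group start)."""
    rows = []
    for year in sorted(tables):
        t = tables[year]
        for cause in CAUSE_CATEGORIES:
            row = {"country": country, "year": year, "sex": sex, "cause": cause}
            for a in t.age_groups:
                row[f"a{int(a)}"] = t.props.loc[a, cause]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_cause_table(path) -> dict:
    """Read an HCDB-like cause CSV; returns
    {(country, sex, year): CauseProportionTable}.

    Cause identifiers that are not one of the seven pre-grouped labels are
    treated as ICD-10 codes and classified; counts (or proportions) are
    aggregated per category and normalized within each age group.  An age
    group whose values sum to zero across causes cannot be normalized and is
    rejected.
    """
    df = pd.read_csv(path)
    required = {"country", "year", "sex", "cause"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    age_cols = [c for c in df.columns if c.startswith("a") and c[1:].isdigit()]
    if not age_cols:
        raise ValueError(f"{path}: no age-group columns (a0, a5, ...) found")
    age_cols = sorted(age_cols, key=lambda c: int(c[1:]))
    ages = np.array([int(c[1:]) for c in age_cols])

    df = df.copy()
    df["category"] = [
        c if c in CAUSE_CATEGORIES else classify_icd10(str(c)) for c in df["cause"]
    ]
    out = {}
    for (country, sex, year), grp in df.groupby(["country", "sex", "year"]):
        agg = grp.groupby("category")[age_cols].sum()
        agg = agg.reindex(list(CAUSE_CATEGORIES), fill_value=0.0)
        mat = agg.to_numpy(dtype=float).T  # (age groups, causes)
        sums = mat.sum(axis=1)
        if np.any(sums <= 0):
            bad = ages[sums <= 0].tolist()
            raise ValueError(
                f"{path}: zero total for {country}/{sex}/{year} in age groups {bad}"
            )
        props = pd.DataFrame(
            mat / sums[:, None], index=ages, columns=list(CAUSE_CATEGORIES)
        )
        out[(country, sex, int(year))] = CauseProportionTable(
            year=int(year), props=props
        )
    return out
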