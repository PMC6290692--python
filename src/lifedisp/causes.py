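"""Cause-of-death grouping (ICD-10) and cause-splitting of death rates.

Deaths are grouped into seven broad categories chosen for their association
with hazardous alcohol consumption and with the epidemiologic transition:

1. ``alcohol``      — conditions wholly attributable to alcohol (mental and
   behavioural disorders due to alcohol, alcoholic liver disease/cirrhosis,
   alcohol poisoning): F10, K70, K74, X45.
2. ``circulatory``  — cardiovascular disease (amenable to alcohol): the
   I-chapter ranges listed below plus transient cerebral ischaemia G45.
3. ``transport``    — transport accidents V01–V99 (amenable to alcohol).
4. ``other_external`` — other external causes (fires, poisonings, suicide,
   assault, falls, drowning, undetermined intent, medical complications...).
5. ``infectious_respiratory`` — A00–B99 and J00–J99.
6. ``cancers``      — C00–C97.
7. ``rest``         — remaining conditions, and all mortality above the
   cause-truncation age (85).

Overlaps are resolved by first match in the order above (alcohol takes
precedence over the amenable groups).  The category membership of ranges 5
and 6 is a documented package assumption; the alcohol-related groups follow
the standard amenable-to-alcohol classification verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CAUSE_CATEGORIES",
    "CauseProportionTable",
    "classify_icd10",
    "split_rates_by_cause",
]

CAUSE_CATEGORIES = (
    "alcohol",
    "circulatory",
    "transport",
    "other_external",
    "infectious_respiratory",
    "cancers",
    "rest",
)

_ROW_SUM_TOL = 1e-9


def _ranges(expr: str):
    """Parse 'F10, K70, X60-X84' into (letter, lo, hi) triples."""
    out = []
    for token in expr.replace(";", ",").split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            a, b = token.split("-")
            la, na = a[0], int(a[1:])
            lb, nb = b[0], int(b[1:])
            if la != lb:
                raise ValueError(f"range spans letters: {token}")
            out.append((la, na, nb))
        else:
            letter, num = token[0], int(token[1:])
            out.append((letter, num, num))
    return out


# First-match order: alcohol > circulatory/transport > other external >
# infectious & respiratory / cancers > rest.
_CATEGORY_RANGES = [
    ("alcohol", _ranges("F10, K70, K74, X45")),
    (
        "circulatory",
        _ranges(
            "I20-I25, I60-I67, G45, I00-I09, I10, I11-I15, I26-I28, "
            "I34-I38, I46, I50, I30-I33, I40-I45, I47-I49, I51, I69, "
            "I70-I78, I80-I99"
        ),
    ),
    ("transport", _ranges("V01-V99")),
    (
        "other_external",
        _ranges(
            "X00-X09, X40-X44, X46-X49, X60-X84, X85-X99, Y00-Y09, Y35, Y36, "
            "Y10-Y34, Y40-Y84, W00-W19, W65-W74, W75-W84, W20-W64, W85-W99, "
            "X10-X39, X50-X59, Y85-Y91, Y95-Y98"
        ),
    ),
    ("infectious_respiratory", _ranges("A00-A99, B00-B99, J00-J99")),
    ("cancers", _ranges("C00-C97")),
]

_ICD_RE = re.compile(r"^([A-Z])(\d{2})(?:\.?\d{1,2})?$")


def classify_icd10(code: str) -> str:
    """Map an ICD-10 code (e.g. 'F10', 'X45', 'I21.4') to one of the seven
    broad categories; anything outside the listed ranges falls to 'rest'.

    Raises ``ValueError`` for a malformed code.
    """
    if not isinstance(code, str):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    letter, num = m.group(1), int(m.group(2))
    for category, ranges in _CATEGORY_RANGES:
        for range_letter, lo, hi in ranges:
            if letter == range_letter and lo <= num <= hi:
                return category
    return "rest"


@dataclass(frozen=True)
class CauseProportionTable:
    """Per-year cause-of-death fractions by 5-year age group.

    ``props`` is a DataFrame indexed by age-group start (0, 5, ..., 85 with
    85 the open/truncation group), columns the seven categories; every row
    sums to 1.
    """

    year: int
    props: pd.DataFrame

    def __post_init__(self):
        props = self.props
        missing = [c for c in CAUSE_CATEGORIES if c not in props.columns]
        if missing:
            raise ValueError(f"missing cause columns: {missing}")
        props = props.loc[:, list(CAUSE_CATEGORIES)].astype(float)
        if (props.to_numpy() < -_ROW_SUM_TOL).any() or (
            props.to_numpy() > 1 + _ROW_SUM_TOL
        ).any():
            raise ValueError("proportions must lie in [0, 1]")
        row_sums = props.sum(axis=1)
        bad = row_sums[(row_sums - 1.0).abs() > _ROW_SUM_TOL]
        if len(bad):
            raise ValueError(
                f"age-group rows must sum to 1; offending groups: "
                f"{list(bad.index)}"
            )
        object.__setattr__(self, "props", props)

    @property
    def age_groups(self) -> np.ndarray:
        return self.props.index.to_numpy()


def split_rates_by_cause(
    mx_5y: np.ndarray, ages: np.ndarray, props: CauseProportionTable
) -> pd.DataFrame:
    """Split abridged all-cause rates into cause-specific rates
    m(x, c) = m(x) p(x, c).

    Cause sums reproduce the all-cause rate exactly; the open (>= 85) group
    carries all its mortality in 'rest'.
    """
    ages = np.asarray(ages)
    if not np.array_equal(ages, props.age_groups):
        raise ValueError("age grids of rates and proportions do not align")
    p = props.props.copy()
    # truncation: open group entirely residual
    p.iloc[-1, :] = 0.0
    p.loc[p.index[-1], "rest"] = 1.0
    out = p.mul(np.asarray(mx_5y, dtype=float), axis=0)
    out.index.name = "age"
    return out
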