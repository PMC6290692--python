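"""Synthetic mortality surfaces and cause tables with a crisis structure.

The generator emulates the joint features the analysis assumes of Central
and Eastern European male mortality since 1960:

* a Siler baseline hazard (declining infant term + constant + Gompertz
  senescence) with a Gaussian young-adult excess hump;
* regime-driven multipliers over working ages tracing five periods —
  stagnation, improvements, deterioration (the early-1990s crisis),
  divergence, and convergence/recovery;
* seven-cause fractions by 5-year age group with plausible age profiles
  (logistic rise for circulatory disease and cancers, young-adult humps for
  alcohol-attributable and external causes, a declining infectious &
  respiratory profile), rows summing to 1, everything above 85 residual.

Deterministic rate surfaces are the primary fixtures; Poisson death counts
are optional noise for robustness work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .causes import CAUSE_CATEGORIES, CauseProportionTable
from .lifetable import MortalitySurface

__all__ = [
    "HazardParams",
    "ScenarioSchedule",
    "CauseProfileParams",
    "CEE_MALE_PARAMS",
    "make_surface",
    "sample_death_counts",
    "make_cause_table",
    "default_cause_profiles",
    "cee_crisis_schedule",
    "flat_schedule",
    "two_country_crisis",
    "write_fixture_set",
    "single_year_grid",
    "abridged_grid",
]

DEFAULT_YEARS = np.arange(1960, 2015)
DEFAULT_BOUNDARIES = (1980, 1988, 1994, 2000)
_REGIME_LABELS = (
    "stagnation",
    "improvement",
    "crisis",
    "crisis",
    "recovery",
)
_WORKING_BAND = (20, 60)


def single_year_grid() -> np.ndarray:
    """Ages 0..109 plus the 110+ open interval."""
    return np.arange(0, 111)


def abridged_grid(open_age: int = 85) -> np.ndarray:
    """5-year age groups 0, 5, ..., open_age."""
    return np.arange(0, open_age + 1, 5)


@dataclass(frozen=True)
class HazardParams:
    """Siler hazard with a young-adult Gaussian hump.

    mu(x) = a1 exp(-b1 x) + c + a2 exp(b2 x) + h exp(-(x - kappa)^2 / (2 sigma^2))
    """

    a1: float = 0.02
    b1: float = 1.1
    c: float = 0.0004
    a2: float = 2.3e-5
    b2: float = 0.105
    h: float = 0.0022
    kappa: float = 28.0
    sigma: float = 14.0

    def __post_init__(self):
        if min(self.a1, self.b1, self.c, self.a2, self.h, self.sigma) < 0:
            raise ValueError("hazard parameters must be non-negative")
        if self.b2 <= 0:
            raise ValueError("senescence slope b2 must be positive")

    def mu(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = (
            self.a1 * np.exp(-self.b1 * x)
            + self.c
            + self.a2 * np.exp(self.b2 * x)
        )
        if self.h > 0:
            out = out + self.h * np.exp(-((x - self.kappa) ** 2) / (2 * self.sigma**2))
        return out


# Calibrated so the baseline (all factors 1) gives CEE-male-like levels:
# e0 ~ 66 years, life disparity ~ 15 years.
CEE_MALE_PARAMS = HazardParams()


@dataclass(frozen=True)
class ScenarioSchedule:
    """Per-year hazard multipliers on age bands, with regime labels.

    ``factors`` maps year -> list of (age_lo, age_hi, factor); the factor
    applies multiplicatively to rates with age_lo <= x < age_hi.
    ``regimes`` maps year -> label in {stagnation, improvement, crisis,
    recovery}.
    """

    years: np.ndarray
    factors: dict
    regimes: dict

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years))
        for y, bands in self.factors.items():
            for lo, hi, f in bands:
                if f <= 0:
                    raise ValueError(f"factor must be positive (year {y})")
                if hi <= lo:
                    raise ValueError(f"empty age band (year {y})")

    def multiplier(self, ages: np.ndarray, year: int) -> np.ndarray:
        out = np.ones(len(ages), dtype=float)
        for lo, hi, f in self.factors.get(int(year), []):
            out[(ages >= lo) & (ages < hi)] *= f
        return out


def flat_schedule(years=DEFAULT_YEARS) -> ScenarioSchedule:
    years = np.asarray(years)
    return ScenarioSchedule(
        years=years,
        factors={int(y): [] for y in years},
        regimes={int(y): "stagnation" for y in years},
    )


def _regime_of(year, boundaries):
    for i, b in enumerate(boundaries):
        if year < b:
            return i
    return len(boundaries)


def cee_crisis_schedule(
    years=DEFAULT_YEARS,
    boundaries=DEFAULT_BOUNDARIES,
    band=_WORKING_BAND,
    style: str = "ramp",
    jitter_sd: float = 0.0,
    jitter_seed: int = 0,
) -> ScenarioSchedule:
    """Working-age multiplier path tracing the five mortality regimes.

    style="ramp": piecewise-linear factors — mild worsening through the
    stagnation years, improvement in the 1980s, a sharp ramp to ~1.5x over
    the deterioration years, a high plateau during divergence, decline
    during convergence.  style="step": one constant factor per regime
    (stylized level shifts, convenient for change-point work).

    ``jitter_sd`` adds small deterministic year-to-year log-normal jitter to
    the band factor (seeded; the schedule stays reproducible).
    """
    years = np.asarray(years)
    b = list(boundaries)
    # factor levels at the regime boundaries (ramp) / per regime (step)
    ramp_nodes = {years[0]: 1.0, b[0]: 1.10, b[1]: 0.95, b[2]: 1.50, b[3]: 1.40}
    end_level = 0.85
    # distinct |gap| levels so each regime boundary shifts the cross-country
    # CV of e0 (1.05 vs 0.95 would leave |e0 gap| nearly symmetric around a
    # stable partner country and hide the first boundary)
    step_levels = (1.12, 0.95, 1.50, 1.40, 1.00)

    node_years = np.array([years[0], *b, years[-1]], dtype=float)
    node_levels = np.array([*(ramp_nodes[y] for y in [years[0], *b]), end_level])

    rng = np.random.default_rng(jitter_seed)
    eps = rng.normal(0.0, 1.0, size=len(years)) if jitter_sd > 0 else np.zeros(len(years))

    factors, regimes = {}, {}
    lo, hi = band
    for j, y in enumerate(years):
        # a boundary year is the endpoint of the outgoing regime: the new
        # level applies from the following year (so the 1988-1994 period
        # spans the full 0.95 -> 1.50 deterioration)
        r = _regime_of(y - 1, b)
        if style == "ramp":
            f = float(np.interp(y, node_years, node_levels))
        elif style == "step":
            f = step_levels[r]
        else:
            raise ValueError("style must be 'ramp' or 'step'")
        f *= float(np.exp(jitter_sd * eps[j]))
        factors[int(y)] = [(lo, hi, f)]
        regimes[int(y)] = _REGIME_LABELS[r]
    return ScenarioSchedule(years=years, factors=factors, regimes=regimes)


def make_surface(
    params: HazardParams,
    schedule: ScenarioSchedule,
    ages=None,
    years=None,
    population_id: str = "synthetic",
    sex: str = "male",
) -> MortalitySurface:
    """Deterministic surface m(x, t) = mu(x) * factor(x, t).

    The hazard is evaluated at interval midpoints (x + n/2; open interval at
    its start age plus 2 years).
    """
    if ages is None:
        ages = single_year_grid()
    ages = np.asarray(ages)
    if years is None:
        years = schedule.years
    years = np.asarray(years)
    widths = np.diff(ages)
    eval_ages = np.concatenate([ages[:-1] + widths / 2.0, [ages[-1] + 2.0]])
    mu = params.mu(eval_ages)
    mx = np.empty((len(ages), len(years)))
    for j, y in enumerate(years):
        mx[:, j] = mu * schedule.multiplier(ages, int(y))
    return MortalitySurface(
        population_id=population_id,
        sex=sex,
        ages=ages,
        years=years,
        mx=mx,
        open_age=int(ages[-1]),
    )


def sample_death_counts(
    surface: MortalitySurface, exposures, seed: int
) -> np.ndarray:
    """Poisson death counts with mean m(x, t) * exposure(x, t); reproducible
    given the seed."""
    exposures = np.broadcast_to(np.asarray(exposures, dtype=float), surface.mx.shape)
    if np.any(exposures <= 0):
        raise ValueError("exposures must be strictly positive")
    rng = np.random.default_rng(seed)
    return rng.poisson(surface.mx * exposures)


# ---------------------------------------------------------------------------
# Cause profiles


def _logistic(x, amp, x0, s):
    return amp / (1.0 + np.exp(-(x - x0) / s))


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-((x - mu) ** 2) / (2 * sd**2))


@dataclass(frozen=True)
class CauseProfileParams:
    """Parametric cause-of-death age profiles and per-year mixing weights.

    ``year_effects`` maps cause -> callable(year) -> multiplier, letting
    crisis years inflate the alcohol-attributable and external-cause shares.
    Profiles are unnormalized weights; rows are normalized to proportions.
    """

    year_effects: dict = field(default_factory=dict)

    def weights(self, age_midpoints: np.ndarray, year: int) -> pd.DataFrame:
        x = np.asarray(age_midpoints, dtype=float)
        w = {
            "alcohol": _gauss(x, 0.09, 47.0, 16.0) + 0.002,
            "circulatory": _logistic(x, 0.62, 58.0, 12.0) + 0.01,
            "transport": _gauss(x, 0.08, 28.0, 14.0) + 0.003,
            "other_external": _gauss(x, 0.14, 40.0, 18.0) + 0.005,
            "infectious_respiratory": 0.28 * np.exp(-x / 25.0) + 0.02,
            "cancers": _logistic(x, 0.30, 55.0, 10.0) + 0.005,
            "rest": np.full_like(x, 0.16),
        }
        for cause, effect in self.year_effects.items():
            w[cause] = w[cause] * float(effect(year))
        return pd.DataFrame(w, index=age_midpoints)


def default_cause_profiles(boundaries=DEFAULT_BOUNDARIES) -> CauseProfileParams:
    """Default profiles with alcohol and external causes elevated during the
    deterioration regime (between the 2nd and 3rd canonical boundaries)."""
    lo, hi = boundaries[1], boundaries[2]

    def crisis_boost(year, strength):
        return 1.0 + (strength - 1.0) * (lo <= year < hi)

    return CauseProfileParams(
        year_effects={
            "alcohol": lambda y: crisis_boost(y, 1.5),
            "other_external": lambda y: crisis_boost(y, 1.35),
            "transport": lambda y: crisis_boost(y, 1.2),
        }
    )


def make_cause_table(
    profiles: CauseProfileParams, year: int, age_groups=None
) -> CauseProportionTable:
    """Normalized seven-cause proportions by 5-year age group; the open
    (>= 85) group is entirely residual."""
    if age_groups is None:
        age_groups = abridged_grid()
    age_groups = np.asarray(age_groups)
    mids = age_groups + 2.5
    w = profiles.weights(mids, int(year))
    w.index = age_groups
    sums = w.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("cause profile row sums to zero; cannot normalize")
    props = w.div(sums, axis=0)
    props.iloc[-1, :] = 0.0
    props.loc[age_groups[-1], "rest"] = 1.0
    return CauseProportionTable(year=int(year), props=props[list(CAUSE_CATEGORIES)])


# ---------------------------------------------------------------------------
# Fixture presets


def two_country_crisis(years=DEFAULT_YEARS, boundaries=DEFAULT_BOUNDARIES):
    """Two synthetic countries: 'Stablia' (no regime shocks, mild steady
    improvement trend) and 'Crisia' (step-regime working-age crisis).

    Small deterministic jitter keeps within-period variance positive so the
    permutation test of the change-point search is well defined.
    """
    years = np.asarray(years)
    stable_sched = cee_crisis_schedule(
        years, boundaries, style="ramp", jitter_sd=0.004, jitter_seed=11
    )
    # Stablia: flatten the regime path to 1.0, keep only jitter
    stable_factors = {
        y: [(lo, hi, f / _ramp_level(y, years, boundaries)) for lo, hi, f in bands]
        for y, bands in stable_sched.factors.items()
    }
    stable = ScenarioSchedule(
        years=years,
        factors=stable_factors,
        regimes={int(y): "stagnation" for y in years},
    )
    crisis = cee_crisis_schedule(
        years, boundaries, style="step", jitter_sd=0.004, jitter_seed=7
    )
    return {
        "Stablia": (CEE_MALE_PARAMS, stable),
        "Crisia": (CEE_MALE_PARAMS, crisis),
    }


def _ramp_level(year, years, boundaries):
    b = list(boundaries)
    node_years = np.array([years[0], *b, years[-1]], dtype=float)
    node_levels = np.array([1.0, 1.10, 0.95, 1.50, 1.40, 0.85])
    return float(np.interp(year, node_years, node_levels))


PRESETS = ("cee-male", "two-country-crisis")


def write_fixture_set(
    outdir, preset: str = "two-country-crisis", seed: int = 0
) -> dict:
    """Write an HMD-dialect Mx 1x1 file and an HCDB-like cause CSV per
    synthetic country, plus sampled death counts and a manifest.

    Rate files are deterministic (independent of ``seed``); only the
    sampled-count files vary with it.  Returns the manifest dict.
    """
    from .io import write_cause_table, write_hmd_mx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    years = DEFAULT_YEARS
    if preset == "two-country-crisis":
        countries = two_country_crisis(years)
    elif preset == "cee-male":
        countries = {
            "Ceemia": (CEE_MALE_PARAMS, cee_crisis_schedule(years, jitter_sd=0.004))
        }
    else:
        raise ValueError(f"unknown preset {preset!r}; available: {PRESETS}")

    profiles = default_cause_profiles()
    manifest = {"preset": preset, "seed": int(seed), "countries": {}}
    for i, (name, (params, schedule)) in enumerate(sorted(countries.items())):
        surf = make_surface(params, schedule, population_id=name)
        # stylized companion columns: female rates at 55% of male, total midway
        from dataclasses import replace as _replace

        female = _replace(surf, sex="female", mx=surf.mx * 0.55)
        total = _replace(surf, sex="total", mx=(surf.mx + female.mx) / 2.0)
        mx_path = outdir / f"{name}.Mx_1x1.txt"
        write_hmd_mx(mx_path, {"male": surf, "female": female, "total": total})
        counts = sample_death_counts(surf, 1e5, seed=seed + i)
        cdf = pd.DataFrame(counts, index=surf.ages, columns=surf.years)
        counts_path = outdir / f"{name}.deaths.csv"
        cdf.to_csv(counts_path, index_label="age")
        tables = {
            int(y): make_cause_table(profiles, int(y))
            for y in years
            if y >= 1994
        }
        cause_path = outdir / f"{name}.causes.csv"
        write_cause_table(cause_path, name, "male", tables)
        manifest["countries"][name] = {
            "mx_file": mx_path.name,
            "deaths_file": counts_path.name,
            "cause_file": cause_path.name,
            "regimes": {str(y): schedule.regimes[int(y)] for y in years.tolist()},
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
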