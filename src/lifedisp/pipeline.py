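"""End-to-end analysis pipeline.

Stages, in order: period life tables -> e0 / e-dagger / entropy / Gini /
threshold-age series -> change-point segmentation of the cross-country CV
series -> improvement surfaces -> quadrant summaries per period (absolute
and relative) -> age decompositions per period -> age x cause decompositions
for the cause-data era.  Every stage writes one delimited text file with a
units header; a JSON manifest records the configuration, seed and
decomposition residuals so any bundle can be re-run identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dispersion, synthetic, trends
from .causes import CAUSE_CATEGORIES
from .decomposition import decompose_by_age, decompose_by_age_cause
from .io import read_cause_table, read_hmd_mx
from .lifetable import MortalitySurface, build_lifetable

__all__ = ["RunConfig", "run_pipeline"]

_RESIDUAL_TOL = 1e-6


@dataclass
class RunConfig:
    """Pipeline configuration; mirrors the CLI flags."""

    output_dir: str = "lifedisp_out"
    fixture_preset: str | None = "two-country-crisis"
    mx_files: list = field(default_factory=list)
    cause_files: list = field(default_factory=list)
    sex: str = "male"
    boundaries: tuple = trends.CANONICAL_BOUNDARIES
    # regime-sized rate changes (e.g. a 0.95 -> 1.5 working-age factor) need
    # more path segments than the year-pair default of 20 to keep the
    # additivity residual under tolerance
    n_steps: int = 80
    truncation_age: int = 85
    open_age: int = 110
    seed: int = 0
    changepoint_min_segment: int = 5
    changepoint_alpha: float = 0.05
    changepoint_permutations: int = 199
    functional: str = "e_dagger"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        b = list(self.boundaries)
        if b != sorted(b):
            raise ValueError("period boundaries must be ordered")
        if self.truncation_age > self.open_age:
            raise ValueError("truncation age must not exceed the open age")
        if self.seed is None:
            raise ValueError("a seed is required (stochastic stages are seeded)")


def _abridge(surface: MortalitySurface, open_age: int) -> MortalitySurface:
    """Collapse a single-year surface to 5-year groups with open interval at
    ``open_age``, weighting rates by life-table person-years."""
    grid = synthetic.abridged_grid(open_age)
    mx = np.empty((len(grid), len(surface.years)))
    from .lifetable import _lifetable_columns

    cols = _lifetable_columns(surface.mx, surface.ages)
    Lx = cols["Lx"]
    deaths = cols["Lx"] * surface.mx  # person-year-weighted deaths
    ages = surface.ages
    for i, g in enumerate(grid):
        if g == grid[-1]:
            sel = ages >= g
        else:
            sel = (ages >= g) & (ages < g + 5)
        mx[i] = deaths[sel].sum(axis=0) / Lx[sel].sum(axis=0)
    return MortalitySurface(
        population_id=surface.population_id,
        sex=surface.sex,
        ages=grid,
        years=surface.years,
        mx=mx,
        open_age=open_age,
    )


def _write(df: pd.DataFrame, path: Path, units: dict) -> None:
    with open(path, "w") as fh:
        for col, unit in units.items():
            fh.write(f"# {col}: {unit}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _load_inputs(config: RunConfig):
    surfaces, cause_tables = {}, {}
    if config.fixture_preset:
        if config.fixture_preset == "two-country-crisis":
            countries = synthetic.two_country_crisis()
        elif config.fixture_preset == "cee-male":
            countries = {
                "Ceemia": (
                    synthetic.CEE_MALE_PARAMS,
                    synthetic.cee_crisis_schedule(jitter_sd=0.004),
                )
            }
        else:
            raise ValueError(f"unknown fixture preset {config.fixture_preset!r}")
        profiles = synthetic.default_cause_profiles()
        for name, (params, schedule) in sorted(countries.items()):
            surfaces[name] = synthetic.make_surface(
                params, schedule, population_id=name, sex=config.sex
            )
            cause_tables[name] = {
                int(y): synthetic.make_cause_table(profiles, int(y))
                for y in schedule.years
                if y >= 1994
            }
    else:
        for path in config.mx_files:
            per_sex = read_hmd_mx(path)
            surf = per_sex[config.sex]
            surfaces[surf.population_id] = surf
        for path in config.cause_files:
            for (country, sex, year), table in read_cause_table(path).items():
                if sex != config.sex:
                    continue
                cause_tables.setdefault(country, {})[year] = table
    if not surfaces:
        raise ValueError("no input surfaces (give mx_files or a fixture preset)")
    return surfaces, cause_tables


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the result bundle.

    Returns a dict with the in-memory stage results and the manifest.
    Raises with the stage name on any failure; aborts if a decomposition
    residual exceeds tolerance.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    surfaces, cause_tables = _load_inputs(config)
    years_common = sorted(
        set.intersection(*(set(s.years.tolist()) for s in surfaces.values()))
    )
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "residuals": {},
    }
    results = {}

    # --- stage: measures -------------------------------------------------
    stage = "measures"
    rows = []
    for name, surf in sorted(surfaces.items()):
        tables = surf.lifetables()
        for year in years_common:
            lt = tables[year]
            ed = dispersion.e_dagger(lt)
            rows.append(
                {
                    "population": name,
                    "year": year,
                    "e0": lt.e0,
                    "e_dagger": ed,
                    "entropy": ed / lt.e0,
                    "gini": dispersion.gini_lifetable(lt),
                    "threshold_age": dispersion.threshold_age(lt),
                }
            )
    measures = pd.DataFrame(rows)
    _write(
        measures,
        outdir / "measures.tsv",
        {
            "e0": "years",
            "e_dagger": "years",
            "entropy": "dimensionless",
            "gini": "dimensionless",
            "threshold_age": "years",
        },
    )
    results["measures"] = measures
    manifest["stages"][stage] = "measures.tsv"

    # --- stage: cross-country CV and change points -----------------------
    stage = "changepoints"
    e0_wide = measures.pivot(index="year", columns="population", values="e0")
    ed_wide = measures.pivot(index="year", columns="population", values="e_dagger")
    cv = pd.DataFrame(
        {
            "year": e0_wide.index,
            "cv_e0": [
                dispersion.cv_across_populations(r) for r in e0_wide.to_numpy()
            ]
            if e0_wide.shape[1] >= 2
            else np.nan,
            "cv_e_dagger": [
                dispersion.cv_across_populations(r) for r in ed_wide.to_numpy()
            ]
            if ed_wide.shape[1] >= 2
            else np.nan,
        }
    )
    _write(cv, outdir / "cv_series.tsv", {"cv_e0": "dimensionless"})
    results["cv_series"] = cv

    if e0_wide.shape[1] >= 2:
        seg = trends.detect_changepoints(
            pd.Series(cv["cv_e0"].to_numpy(), index=cv["year"].to_numpy()),
            min_segment=config.changepoint_min_segment,
            alpha=config.changepoint_alpha,
            n_permutations=config.changepoint_permutations,
            seed=config.seed,
        )
        seg = trends.assign_periods(seg)
    else:
        seg = trends.PeriodSegmentation(
            start_year=years_common[0],
            end_year=years_common[-1],
            breaks=tuple(config.boundaries),
            statistics=(np.nan,) * len(config.boundaries),
            p_values=(np.nan,) * len(config.boundaries),
            labels=trends.CANONICAL_LABELS,
        )
    _write(
        seg.to_frame(),
        outdir / "changepoints.tsv",
        {"break_year": "calendar year", "statistic": "energy", "p_value": "prob"},
    )
    results["segmentation"] = seg

    # analysis periods come from the configured canonical boundaries
    bounds = [years_common[0], *config.boundaries, years_common[-1] + 1]
    periods = []
    for i in range(len(bounds) - 1):
        label = (
            trends.CANONICAL_LABELS[i]
            if tuple(config.boundaries) == trends.CANONICAL_BOUNDARIES
            and len(bounds) - 1 == 5
            else f"period_{i + 1}"
        )
        periods.append((bounds[i], bounds[i + 1], label))
    results["periods"] = periods

    # --- stage: improvement surfaces --------------------------------------
    stage = "improvement"
    imp_frames = []
    for name, surf in sorted(surfaces.items()):
        smoothed = trends.smooth_log_rates(surf)
        imp = trends.improvement_rates(smoothed)
        frame = imp.to_frame()
        frame.insert(0, "population", name)
        imp_frames.append(frame)
    improvement = pd.concat(imp_frames, ignore_index=True)
    _write(
        improvement,
        outdir / "improvement_rates.tsv",
        {"rho_pct": "percent per year", "category": "improvement band (+-0.5%)"},
    )
    results["improvement"] = improvement

    # --- stage: quadrants --------------------------------------------------
    stage = "quadrants"
    quad_frames = []
    for scale in ("absolute", "relative"):
        for q in dispersion.quadrant_analysis(e0_wide, ed_wide, periods, scale=scale):
            quad_frames.append(q.to_frame())
    quadrants = pd.concat(quad_frames, ignore_index=True)
    _write(
        quadrants,
        outdir / "quadrants.tsv",
        {"proportion": "fraction of year pairs", "ci_low": "95% CI"},
    )
    results["quadrants"] = quadrants

    # --- stage: age decomposition ------------------------------------------
    stage = "decomposition_age"
    dec_rows = []
    for name, surf in sorted(surfaces.items()):
        for start, end, label in periods:
            y2 = min(end, years_common[-1])
            res = decompose_by_age(
                surf, start, y2, functional=config.functional, n_steps=config.n_steps
            )
            if res.residual > _RESIDUAL_TOL * max(1.0, abs(res.total)):
                raise RuntimeError(
                    f"stage {stage}: residual {res.residual:.2e} above tolerance "
                    f"for {name} {start}-{y2}"
                )
            manifest["residuals"][f"{name}:{label}:{config.functional}"] = res.residual
            df = res.to_frame()
            df.insert(0, "population", name)
            df.insert(1, "period", label)
            df["year_start"], df["year_end"] = start, y2
            dec_rows.append(df)
    decomp_age = pd.concat(dec_rows, ignore_index=True)
    _write(decomp_age, outdir / "decomposition_age.tsv", {"contribution": "years"})
    results["decomposition_age"] = decomp_age

    # --- stage: age x cause decomposition -----------------------------------
    stage = "decomposition_age_cause"
    cause_rows, cause_tot_rows = [], []
    for name, surf in sorted(surfaces.items()):
        tables = cause_tables.get(name, {})
        if not tables:
            continue
        abridged = _abridge(surf, config.truncation_age)
        cause_years = sorted(tables)
        for start, end, label in periods:
            y1 = max(start, cause_years[0])
            y2 = min(end, cause_years[-1])
            if y2 <= y1:
                continue
            res, totals = decompose_by_age_cause(
                abridged,
                tables[y1],
                tables[y2],
                y1,
                y2,
                functional=config.functional,
                n_steps=config.n_steps,
            )
            if res.residual > _RESIDUAL_TOL * max(1.0, abs(res.total)):
                raise RuntimeError(
                    f"stage {stage}: residual {res.residual:.2e} above tolerance "
                    f"for {name} {y1}-{y2}"
                )
            manifest["residuals"][f"{name}:{label}:cause:{config.functional}"] = (
                res.residual
            )
            df = res.to_frame()
            df.insert(0, "population", name)
            df.insert(1, "period", label)
            df["year_start"], df["year_end"] = y1, y2
            cause_rows.append(df)
            tot = totals.rename("contribution").reset_index()
            tot.insert(0, "population", name)
            tot.insert(1, "period", label)
            tot["total"] = res.total
            cause_tot_rows.append(tot)
    if cause_rows:
        decomp_cause = pd.concat(cause_rows, ignore_index=True)
        cause_totals = pd.concat(cause_tot_rows, ignore_index=True)
    else:
        decomp_cause = pd.DataFrame(
            columns=["population", "period", "age", "cause", "contribution"]
        )
        cause_totals = pd.DataFrame(
            columns=["population", "period", "cause", "contribution", "total"]
        )
    _write(
        decomp_cause, outdir / "decomposition_age_cause.tsv", {"contribution": "years"}
    )
    _write(cause_totals, outdir / "cause_totals.tsv", {"contribution": "years"})
    results["decomposition_age_cause"] = decomp_cause
    results["cause_totals"] = cause_totals

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
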