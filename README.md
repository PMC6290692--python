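# lifedisp

Lifespan variation analysis for periods of mortality crisis: period life
tables, life disparity and related inequality measures, additive
decomposition of their changes by age and cause of death, and trend
segmentation of long mortality series.

Life expectancy at birth (e₀) summarizes average survival but conceals how
unequal ages at death are. During the Central and Eastern European mortality
crises of the late twentieth century — stagnation, the Gorbachev-era
improvements, the post-Soviet deterioration, divergence, and convergence —
e₀ and lifespan inequality moved largely independently of each other,
because mortality change was concentrated at working ages. `lifedisp` is a
toolkit for studying exactly this phenomenon: it is aimed at demographers
and epidemiologists who want to track *both* moments of the age-at-death
distribution and attribute their changes to specific ages and causes of
death, without access to, or ahead of, the archival all-cause (HMD-style)
and cause-of-death (HCDB-style) series the original analyses used.

## Measures and methods

* **Life disparity**
  e† = ∫₀^ω d(a) e(a) da — the average remaining life expectancy at the
  ages people die, equivalently average life-years lost per death. Evaluated
  on the discrete table as Σ dₓ·[(1 − aₓ/n)·eₓ + (aₓ/n)·e_{x+n}] plus the
  open-interval term d(ω)·e(ω).
* **Threshold age a†** — the age at which a marginal mortality improvement
  leaves e† unchanged: saving lives below a† compresses the distribution of
  ages at death, saving lives above it expands it. Located by sweeping a
  finite-difference sensitivity (1 % hazard reduction in a sliding 1-year
  band) and root-finding its sign change.
* **Keyfitz entropy** H = e†/e₀ and the **life-table Gini**
  G = 1 − (1/e₀)∫ l(x)² dx, both computed by independent routes
  (survival-curve quadrature) and used as relative-inequality robustness
  checks.
* **Horiuchi line-integral decomposition**
  f₂ − f₁ = Σᵢ ∫ (∂f/∂xᵢ) dxᵢ = Σᵢ cᵢ — additive attribution of a change
  in e₀ or e† to every single-age death rate, or to every 5-year age-group ×
  cause-of-death rate (seven broad categories keyed to hazardous alcohol
  consumption; cause analysis truncated at 85).
* **Trend segmentation** — divisive hierarchical multiple change-point
  detection (energy-distance statistic with a seeded permutation test) on
  the cross-country coefficient of variation of e₀, with snapping of
  statistical breaks to the canonical period boundaries {1980, 1988, 1994,
  2000}; smoothed Lexis surfaces of annual rates of mortality improvement;
  and quadrant analysis of paired yearly changes (Δe₀, Δe†).
* **Synthetic mortality-crisis generator** — Siler hazard with a
  young-adult hump, regime-driven working-age multipliers, and parametric
  seven-cause profiles, written in the same HMD/HCDB text dialects the
  readers parse, so the entire pipeline runs and is tested without any
  data downloads.

## Worked example

```python
from lifedisp import (
    make_surface, cee_crisis_schedule, decompose_by_age, summarize,
)
from lifedisp.synthetic import CEE_MALE_PARAMS

surface = make_surface(CEE_MALE_PARAMS, cee_crisis_schedule())
for year in (1988, 1994):
    s = summarize(surface.lifetable(year))
    print(f"{year}: e0={s.e0:.2f}  e†={s.e_dagger:.2f}  "
          f"H={s.entropy:.3f}  G={s.gini:.3f}  a†={s.threshold_age:.1f}")

res = decompose_by_age(surface, 1988, 1994, functional="e_dagger", n_steps=80)
young = res.contributions[(res.contributions.index >= 20)
                          & (res.contributions.index < 60)].sum()
print(f"Δe† 1988→1994 = {res.total:+.3f} years (residual {res.residual:.1e})")
print(f"  contribution of ages 20-59: {young:+.3f} years")
```

prints

```
1988: e0=69.39  e†=13.63  H=0.196  G=0.147  a†=70.2
1994: e0=66.72  e†=15.12  H=0.227  G=0.168  a†=68.0
Δe† 1988→1994 = +1.492 years (residual 3.1e-07)
  contribution of ages 20-59: +1.492 years
```

Between 1988 and 1994 the simulated crisis (working-age death rates ramping
to 1.5×) cuts life expectancy by 2.7 years while life disparity *rises* by
1.5 years — the distribution of ages at death widens — and the
decomposition attributes the entire expansion to ages 20–59, all below the
threshold age of ~70. The residual shows the additivity of the
decomposition: age contributions sum to the total change up to 3×10⁻⁷
years.

A command-line interface mirrors the library
(`lifedisp simulate|lifetable|measures|decompose|trends|quadrants|pipeline`);
`lifedisp pipeline --out results --seed 1` runs every stage — life tables,
dispersion measures, change-point segmentation, improvement surfaces,
quadrant summaries, and age and age×cause decompositions — on the bundled
two-country crisis fixture and writes one delimited text file per stage
plus a manifest that makes the run exactly reproducible.

## Documentation

`docs/methods.md` describes the life-table closure, the discrete e†
evaluation and its convergence, the decomposition algorithm, the
change-point and smoothing choices, what the synthetic generator does and
does not emulate, and known limitations.
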