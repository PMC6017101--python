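# combindex

Median-effect and combination-index analysis of enzyme-inhibition
dose-effect data, in the Chou–Talalay framework.

## The problem

Screening pairs of inhibitors — here, bromelain combined with
phytochemicals (amenthoflavone, asiaticoside, diosgenin) against
phospholipase A2, a pro-inflammatory enzyme — requires a quantitative
answer to "is the mixture better than the sum of its parts?".  The
standard machinery, implemented commercially in CompuSyn/CalcuSyn, is:

1. **Median-effect equation.**  Each agent's dose-effect relation follows
   the mass-action form

   $$\frac{f_a}{f_u} = \left(\frac{D}{D_m}\right)^m, \qquad f_u = 1 - f_a$$

   where $f_a$ is the fraction affected (fractional inhibition), $D_m$
   the median-effect dose (IC50) and $m$ the sigmoidicity coefficient.
   Taking log10 linearises it, so $(D_m, m)$ come from ordinary least
   squares of $\log_{10}(f_a/f_u)$ on $\log_{10} D$; the Pearson $r$ of
   the transformed points is the goodness-of-fit statistic
   (conventionally $r \ge 0.95$ for acceptable in vitro data).

2. **Combination index.**  A fixed-ratio mixture is titrated over total
   dose and fitted as a single entity.  At any effect level $f_a$,

   $$CI = \frac{(D)_1}{(D_x)_1} + \frac{(D)_2}{(D_x)_2}$$

   with $(D)_i$ the component doses inside the mixture reaching $f_a$
   and $(D_x)_i$ the single-agent doses reaching it alone.  $CI < 1$ is
   synergism, $CI = 1$ Loewe additivity, $CI > 1$ antagonism.

3. **Dose-reduction index.**  $DRI_i = (D_x)_i / (D)_i$ is the fold dose
   sparing the combination affords agent $i$ (favorable when $> 1$);
   identically $CI = \sum_i 1/DRI_i$.

The package also covers the stage upstream (colorimetric kinetics →
enzyme activity → percent inhibition), constant-ratio design grids built
from IC50 multiples, and a seeded synthetic-data generator that can plant
a known true CI — so the whole pipeline is testable without wet-lab data.

It is intended for researchers running enzyme-inhibition combination
screens who want an open, scriptable, validated replacement for the
closed-source combination-index tools.

## Worked example

```python
import numpy as np
import combindex as cx

# synthetic bromelain series from its known truth (Dm=0.0723 mg/mL, m=0.6767)
br = cx.generate_single(cx.GeneratorSpec(
    agent_id="bromelain", dm=0.0723, m=0.6767,
    dose_min=0.005, dose_max=1.0, n_doses=10,
    noise_sd=0.05, replicates=3, seed=42))
res = cx.fit_median_effect(br)
print(res.summary())
```

```
Median-Effect Model Results
==============================================
agent:            bromelain
n (used/total):   30/30
Dm (mg/mL):       0.0721
m:                0.6864 +/- 0.0097
r:                0.9972
==============================================
```

The fit recovers the generating IC50 (0.0721 vs 0.0723 mg/mL) and slope,
with $r$ well above the 0.95 acceptability rule.  `res.dx(0.9)` then
gives the dose for 90% inhibition (1.770 mg/mL here).

Combination analysis against a second agent (asiaticoside parameters
$D_m = 0.3143$, $m = 0.5258$), with a mixture generated at true CI 0.7
and mixed at the IC50 ratio:

```python
asi = cx.MedianEffectResults(agent_id="asiaticoside", dm=0.3143, m=0.5258,
    r=1.0, m_se=0.0381, intercept=-0.5258*np.log10(0.3143),
    intercept_se=0.0, n_used=5)
ratio = 0.0723 / (0.0723 + 0.3143)
mix = cx.generate_combination(cx.ComboGeneratorSpec(
    agent_id="br+as", dm1=0.0723, m1=0.6767, dm2=0.3143, m2=0.5258,
    ratio=ratio, true_ci=0.7, total_doses=tuple(np.geomspace(0.02, 2.0, 8)),
    noise_sd=0.05, replicates=3, seed=7))
combo = cx.fit_combination(mix, ratio)
print(combo.ci_profile(res, asi, fa_grid=[0.5, 0.75, 0.9])
      .table[["fa", "total_dose", "CI", "classification"]])
```

```
  fa  total_dose       CI classification
0.50    0.141879 0.735134      synergism
0.75    0.957925 0.808223      synergism
0.90    6.467639 0.939588       additive
```

The estimated CI sits near the planted 0.7 at moderate effect levels
(drifting with noise at the extrapolated 90% level), and
`combo.dri_table(res, asi)` reports the matching dose-reduction indices
(all favorable, DRI 1.5–3.9 here).

## Command line

```sh
combindex simulate --agent-id br --dm 0.0723 --m 0.6767 \
    --dose-min 0.005 --dose-max 1 --n-doses 10 --noise-sd 0.05 --out br.csv
combindex fit br.csv
combindex design --ic50-1 0.0723 --ic50-2 0.3143 --agent-ids bromelain,asiaticoside
combindex report --input bundle.csv --agent1 a1 --agent2 a2 --mixture mix --out results/
```

`report` writes a versioned JSON report, flat Fa–CI and DRI CSVs and the
Fa–CI figure; identical inputs and config give a byte-identical JSON
report.

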