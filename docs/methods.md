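# Methods

## Model

The package rests on the median-effect principle: a dose-effect relation
of the mass-action form fa/fu = (D/Dm)^m, with fu = 1 − fa.  Its
log10-log10 transform is a straight line, so the fit is ordinary least
squares of y = log10(fa/fu) on x = log10(D); m is the slope, Dm recovers
as 10^(−intercept/m), and r is the Pearson correlation of the
transformed points.  The fit is deliberately *only* the linearisation —
no weighted or nonlinear refit — because that is the method the
combination-index framework and the tools built on it define.  The OLS
itself is delegated to `scipy.stats.linregress`, which also supplies the
slope standard error reported as `m_se`; an independent closed-form-sums
oracle in the test suite checks the delegation.

Assumptions worth stating: effects are monotone in dose with full range
(0, 1); replicate scatter on the transformed scale is roughly
homoscedastic; and for mixtures, the fixed-ratio mixture itself obeys a
median-effect relation when fitted as a single entity.  The last is the
standard (and only workable) reading of the Fa–CI curve construction:
the mixture's own (Dm, m) supply the total dose at each effect level,
the constant ratio splits it into component doses, and the single-agent
fits supply the equipotent doses.  A "pointwise" alternative — CI only
at observed (dose, fa) points — is available by passing the observed fa
values as the grid to `compute_ci`.

## Parameters and defaults

- **usability band** (fit): fa in (0.005, 0.995), configurable.  The
  log-odds transform diverges at 0 and 1; excluding boundary points is
  standard practice for this analysis.  Exclusions are recorded on the
  results object and logged in verbose mode.
- **replicate handling**: replicates enter the regression individually
  by default (preserves the error structure); `average=True` switches to
  mean-per-dose.
- **r acceptability**: r ≥ 0.95 is reported as a QC flag
  (`r_acceptable`), never enforced — a poor r should be visible, not
  fatal.
- **CI classification bands**: synergism < 0.9 ≤ additive ≤ 1.1 <
  antagonism.  A literal <1/=1/>1 trichotomy is meaningless for noisy
  estimates; the band is configurable and a `strict` mode applies the
  trichotomy for noise-free work.
- **DRI levels**: {0.50, 0.75, 0.90, 0.95} by default, the conventional
  reporting grid; favorable iff DRI > 1.
- **effect grid** for Fa–CI export: 99 points, fa = 0.01 … 0.99.
- **constant-ratio design**: IC50 multiples {2.5, 2, 1, 0.5, 0.2} by
  default; component concentration = multiplier × IC50, stored as
  nominal (pre-mix) values with a `dilution_factor` field (default 1,
  set 2 for equal-volume mixing).  CI is scale-equivariant, so the
  nominal/in-reaction choice cannot change any CI or DRI value.
- **mixing ratio**: defaults to ic50_1/(ic50_1 + ic50_2), the ratio an
  equal-IC50-multiple design produces; always overridable because
  published component splits do not always match the nominal design.
- **assay stage**: activity = (OD(0) − OD(t))/t with the kinetic window
  t a *required* argument (5- and 15-minute protocols both exist in the
  literature; silently defaulting either would be a trap).  Readings are
  matched to requested times within 0.25 min (plate-reader timestamp
  jitter).  Optional blank traces are subtracted pointwise before the
  activity computation; negative inhibition (activation) is kept and
  flagged rather than clamped.

## Synthetic data

`generate_single` draws y = m·log10(D/Dm) + ε, ε ~ N(0, noise_sd²), and
maps back to fa — i.e. noise lives on the transformed scale where the
model is linear, which keeps fa strictly inside (0, 1) and makes
noise_sd directly interpretable as scatter about the median-effect plot.
A clipped raw-fa Gaussian mode exists for robustness testing only.

`generate_combination` plants a *known* combination index: at each total
dose the noiseless fa solves d1/Dx1(fa) + d2/Dx2(fa) = true_ci by
Brent root-finding (the left side is strictly decreasing in fa, so the
root is unique); noise is then added as above.  true_ci = 1 yields an
exactly Loewe-additive mixture — with equal slopes this closes to a
median-effect curve with the same m, which the tests exploit.  The
constant-CI alternative is imposed pointwise at every dose; a
dose-varying CI profile can be supplied as a callable.

What the generator does *not* emulate: day/batch variance components,
heteroscedastic raw-OD noise, curvature of kinetic traces as substrate
depletes, or deviations from the median-effect form itself.  Passing
tests therefore demonstrate correctness of the *analysis* under its own
model assumptions, not robustness of the model to real assay pathology.

All randomness flows from one integer seed through a single
`numpy.random.default_rng`; identical spec + seed is byte-identical.

## Validation scale

The Monte-Carlo recovery study uses 200 replicates of 10 log-spaced
doses spanning 0.005–1.0 mg/mL around the bromelain truth
(Dm = 0.0723 mg/mL, m = 0.6767), at transformed-scale noise sd 0.1
(recovery) and 0.05 (QC-rate check).  These sizes give stable medians
and percentiles while keeping the whole validation in seconds; per-
replicate seeds are spawned from one `SeedSequence` so replicates are
independent but fully reproducible.

## Numerical choices

- Base-10 logs throughout; any consistent base gives identical (Dm, m),
  base 10 keeps the plot readable.
- Root-finding brackets fa in (1e-9, 1 − 1e-9) with `brentq` at machine
  tolerance; an unattainable target CI at a given dose raises an error
  reporting the attainable CI range there.
- Report tables round half-up (concentrations 4 dp, CI/DRI 2 dp) via a
  decimal rendering, so products of decimal inputs round as a hand
  calculation would; full precision is retained internally and in the
  JSON report.
- Degenerate inputs fail loudly: < 2 usable points (with the excluded
  points and reasons listed), all-identical doses, zero-activity
  control, non-physical m ≤ 0 at dose inversion.

## Known limitations

- Two-agent, constant-ratio designs only; no checkerboard designs,
  >2-agent combinations, or Bliss/HSA/ZIP reference models.
- The mixture-as-single-entity fit extrapolates the Fa–CI curve beyond
  the observed effect range; CI values at extreme fa inherit that
  extrapolation uncertainty (visible in the README example at fa = 0.9).
- DRI "bypass" mode (`dri_from_doses`) exists because published
  component-dose tables are not always internally consistent with their
  nominal design ratio; it computes DRI from whatever doses are quoted,
  and documents nothing more than that arithmetic.
- No uncertainty propagation onto CI/DRI (CompuSyn reports none
  either); the simulation module is the supported route for assessing
  estimator variability.
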