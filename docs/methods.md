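# Methods

## The quantal dose–response model

Each well exposes `n` larvae to a concentration `d` (ng/mL of
spore-and-crystal preparation) and records the number dead. Deaths are
modelled as binomial with probability

    P(death | d) = F(a + b · log10 d),

where `F` is the logistic CDF (logit link, the default) or the standard
normal CDF (probit). The dose metameter is log10 concentration: this is
the only metameter under which published (slope, intercept) pairs for
these assays reproduce their published LC50s through
`LC50 = 10^(−a/b)`. Replicate wells are pooled within concentration
before fitting; control wells (concentration 0) never enter the
regression and act only through Abbott's correction
`p' = (p − c)/(1 − c)`, applied per replicate to each well's mortality
before pooling (an exact no-op at zero control mortality, the usual case
for these assays). Corrected death counts `n·p'` may be fractional; the
likelihood machinery accepts them.

### Fitting

The binomial log-likelihood is maximised by Newton–Raphson on
(intercept, slope) with step-halving to guarantee ascent, starting from a
least-squares line through shrunk empirical link-quantiles
`F⁻¹((y+½)/(n+1))`. Convergence requires a relative deviance change
below 1e-8 or a gradient max-norm below 1e-8, within 100 iterations.
The covariance matrix is the inverse *observed* information at the
optimum (identical to expected information for the canonical logit
link). Degenerate responses — no deaths anywhere, complete mortality
everywhere, a flat response, or complete separation (every pooled dose at
0% or 100%) — are refused with a dedicated error; such treatments are
reported as censored LC50s (`> top dose` or `< bottom dose`) rather than
forced through a fit, which matches how non-active preparations are
reported in practice.

Two distinct concentrations are accepted (the fit is then saturated and
carries no goodness-of-fit information); three or more are needed for a
χ² test, and a warning is emitted below that.

### Inversion and confidence limits

`LCp = 10^((F⁻¹(p) − a)/b)`, so LC50 = `10^(−a/b)` under both links.
Limits for log10 LCp:

* **Fieller** (default; the classical fiducial interval for a ratio of
  regression coefficients): roots of
  `(a + bρ − z)² = q² · Var(a + bρ)` in ρ, with `z = F⁻¹(p)`. When the
  Fieller `g = q²·Var(b)/b² ≥ 1` the slope is not significantly positive
  and the interval is unbounded; the package raises rather than report
  fabricated limits, and report tables leave the limit cells blank with a
  warning.
* **Delta**: `ρ̂ ± q · SE(ρ̂)` by first-order propagation.

Heterogeneity follows Finney's convention: with Pearson
`χ² = Σ (y − n·p̂)²/(n·p̂(1−p̂))` over pooled doses and `df = k − 2`,
when `h = χ²/df > 1` the covariance is inflated by `h` and `q` is a
t-quantile on `df` degrees of freedom; otherwise `q` is a normal
quantile. Doses whose expected counts are numerically 0 (fitted p̂ at 0
or 1) are excluded from χ² with a warning and `df` reduced accordingly.

## Mixture interaction

For a mixture with mass fractions `rᵢ` and individual LC50s, simple
similar action (Tabashnik's null for similarly acting, parallel-slope
toxins) predicts `LC50(m) = (Σ rᵢ/LC50ᵢ)⁻¹`. The synergism factor is
`SF = expected/observed`. Components whose LC50 is censored
(`> bound`) enter the sum at their bound — the only reading under which
the published worked examples follow from their printed inputs — and the
result is flagged as a *lower bound* on the expected LC50 (hence SF is a
lower bound on the synergy). Less-than censors cannot enter the sum and
are refused.

Classification defaults: SF > 2 synergistic, SF < 0.5 antagonistic,
otherwise additive; these cutoffs are conventional, configurable, and not
part of the source analyses, which report SFs without a threshold. A
mixture whose *every* component is individually non-active (censored)
but which itself has a finite LC50 below the screening bound is classed
*enabling*. The enabling factor — active component's LC50 over the
mixture's — is computed automatically only when exactly one component is
active; for all-censored enabling mixtures there is no active-component
numerator and the factor is left absent.

A preliminary mortality screen at a single shared dose flags potential
synergy when the mixture's mortality strictly exceeds the sum of the
individual mortalities; the sum is capped at 1, so a mixture at 100%
against individuals summing past 100% is *not* flagged (the uncapped
comparison would be vacuous there).

## Synthetic bioassays

The generator emulates the standard design: `k` doses (default 6) by
1:`f` serial dilution (default 1:2, stored at full precision — printed
dose lists like "…, 62.5, 31.5" are treated as rounded 31.25), larvae
per well uniform on 10–15 (configurable), a chosen number of replicate
wells (default 3; the source protocols do not state a count), and
binomial deaths at `c + (1−c)·F(b·(log10 d − log10 LC50))` with control
mortality `c` (default 0). The design helper places the top dose C1 at
90% predicted mortality — the lower edge of the 90–100% rule. This
choice is deliberate: with a 1:2 six-dose series the dose range spans
1.5 decades, and anchoring C1 at 95% or higher pushes every dose above
the LC50 (predicted mortality ~54–95%), starving the fit of information
below the median; anchoring at 90% spans ~36–90% for a slope of 1.85
and keeps the LC50 inside the tested range.

Mixtures are simulated with a shared reference slope (the parallelism
assumption of the SSA model; differing component slopes would require an
alternative joint-action model and are out of scope) and true LC50
`LC50_SSA/s`, where the interaction multiplier `s` is 1 under the null.

Randomness: one `numpy.random.SeedSequence` per assay, with one spawned
child stream per replicate, so identical seeds give identical data and
adding replicates never perturbs earlier draws.

What the generator does *not* emulate: between-well overdispersion
beyond binomial, larval development or feeding behaviour, dose
preparation error, and time-to-death structure. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators
under the binomial model, not robustness to extra-binomial variation in
real assays.

## Validation strategy and problem sizes

Raw well-level data behind the published LC50 tables are not available,
so the published fits cannot be re-estimated; validation instead uses:

* printed-coefficient consistency — `10^(−a/b)` against each printed
  LC50 (within ~2%, reflecting 3-significant-figure coefficient
  rounding; the reference-product row at 0.019 ng/mL deviates by ~6%
  for the same rounding reason and is documented rather than asserted);
* exact mixture arithmetic against the published expected-LC50/SF table
  (two of that table's expected values, 170 and 100 ng/mL, do not follow
  from their printed inputs under equal proportions — likely computed
  from unrounded values — and are used only as SF ratio checks);
* an independent brute-force grid-search ML oracle and statsmodels GLM
  as cross-checks of the Newton fitter;
* parameter recovery: 500 simulated assays at truth LC50 171 ng/mL,
  slope 1.85, 6 doses, 12 larvae/well, 3 replicates (median estimate
  within 5%, Fieller 95% coverage within [0.90, 0.99]);
* SF calibration: 200 simulated mixture pipelines under the null
  (mean SF within 3 Monte-Carlo SEs of 1) and at s = 11.44 (median SF
  within 15%);
* a 2000-draw parametric bootstrap as an oracle for the delta-method
  limits.

These problem sizes keep the full suite under ten seconds while leaving
Monte-Carlo error well inside the asserted tolerances.

## Numerical choices

Probabilities are clipped to [1e-12, 1−1e-12] inside likelihoods;
proportions of a mixture must sum to 1 within 1e-9; the activity screen
threshold defaults to 10% corrected mortality at the top dose (the
sources report "no activity" without a numeric cutoff); reports render
3 significant figures and censored values as `>bound`, while `.meta.json`
sidecars carry full precision and the run configuration (seed, link,
CI method) needed to reproduce any output exactly.

## Known limitations

No parallelism test between dose–response lines is implemented (the SSA
model assumes it); no time-to-death or resistance-ratio analyses; no
alternative joint-action nulls (independent action, multiplicative
survival); SF uncertainty is not propagated from the component fits by
default.
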