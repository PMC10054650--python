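# btassay

Quantal dose–response analysis and mixture-synergism statistics for
*Bacillus thuringiensis* (Bt) larvicide bioassays.

Mosquito-control programmes evaluate Bt spore-and-crystal preparations by
exposing batches of larvae (here, *Aedes albopictus* L2) to serial
dilutions of toxin and counting deaths. `btassay` provides the complete
statistical chain for such assays, for toxicologists and bioassay
analysts:

* **LC50 estimation** — binomial maximum-likelihood logit (or probit)
  regression of mortality on log10 concentration:
  `P(death | d) = F(a + b·log10 d)`, with LCp = `10^((F⁻¹(p) − a)/b)`,
  Fieller (fiducial) or delta-method confidence limits, Pearson χ²
  goodness of fit with Finney's heterogeneity factor `h = max(1, χ²/df)`,
  and Abbott's control-mortality correction `(p − c)/(1 − c)`.
* **Mixture interaction** — the expected LC50 of a toxin mixture under
  Tabashnik's *simple similar action* (SSA) no-interaction null,
  `LC50(m) = (Σᵢ rᵢ/LC50ᵢ)⁻¹` for mass fractions rᵢ, the synergism factor
  `SF = expected/observed LC50`, enabling factors for mixtures whose
  partner is individually non-toxic, and interaction classification
  (synergistic / additive / antagonistic / enabling).
* **Activity screening** — censored reporting (`LC50 > top dose`) for
  preparations with no measurable response at the screening dose.
* **Synthetic bioassays** — a seeded generator for the standard design
  (6 concentrations by 1:2 serial dilution from a top dose producing
  90–100% mortality, 10–15 larvae per well, binomial deaths), including
  mixtures simulated under the SSA null or with a controlled interaction
  multiplier, so the whole pipeline is testable without laboratory data.

## Worked example

Generate a demo dataset (two active toxins, one inert protein, a
synergistic 1:1 mixture and an "enabled" mixture), fit it, and assess the
mixtures:

```sh
btassay fixtures --out demo --seed 42
btassay fit demo/demo_bioassay.csv --out demo/fits.csv
btassay mix demo/fits.csv demo/demo_mixtures.csv --out demo/interactions.csv
```

The fit report (concentrations in ng/mL, 3 significant figures):

```
         treatment   lc50 lower upper  chi2 df slope se_slope intercept
            Cyt1Aa    194   115   283 0.752  4  1.92    0.328     -4.39
           Cry11Aa    233              14.4  4  1.04    0.323     -2.45
       Cry56A-like >1e+05
    Cyt1Aa+Cry11Aa   15.8  11.7  20.5  2.93  4   2.8    0.388     -3.35
Cyt1Aa+Cry56A-like   20.7  8.14  36.8  5.25  4  1.92    0.322     -2.53
```

Each row is one treatment: the LC50 with 95% Fieller limits, Pearson χ²
on `df = k − 2` pooled doses, and the fitted slope/intercept on the logit
scale. The simulated truths here were LC50 171 (Cyt1Aa) and 228 ng/mL
(Cry11Aa); the estimates 194 and 233 reflect ordinary sampling noise at
3 replicates of 10–15 larvae. `Cry56A-like` produced no deaths, so its
LC50 is censored at the screening dose. For `Cry11Aa` this particular
draw left the slope not significantly positive (Fieller g ≥ 1), so the
limits are omitted with a warning rather than fabricated.

The interaction report:

```
         treatment observed_lc50 expected_lc50 ... synergism_factor interaction_class enabling_factor
    Cyt1Aa+Cry11Aa          15.8           212 ...             13.4       synergistic
Cyt1Aa+Cry56A-like          20.7           387 ...             18.7       synergistic            9.37
```

`expected_lc50` is the SSA combination of the fitted single-toxin LC50s
(the inert component entering at its censor bound of 1e5 ng/mL); the
synergism factor 13.4 means the observed mixture is 13.4-fold more potent
than the no-interaction null predicts. The second mixture also reports an
enabling factor: the mixture is 9.37-fold more active than its only
active component alone.

Other subcommands: `btassay screen` (high-dose activity verdicts) and
`btassay simulate` (write a synthetic assay for a chosen truth; the seed
and configuration are echoed in a `.meta.json` sidecar next to every
output).

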