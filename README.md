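# agrichoice

A discrete choice experiment (DCE) toolkit for analysing smallholder
preferences over soil-fertility management technologies. It covers the whole
stated-preference workflow:

- **Attribute schemes & choice data** (`agrichoice.data`): long-format
  choice datasets (respondent x plot x situation x alternative), CSV I/O,
  validation, design-matrix construction with a status-quo constant, scaled
  cost, binary dummies and attribute x cost interactions, plus the
  `plan_sample_size` plot-count formula (ceil of t² Cv² / d²).
- **Efficient choice designs** (`agrichoice.design`): full-factorial
  enumeration, a normalized D-efficiency score for multinomial-logit
  information, and a seeded coordinate-swap hill climb (`generate_design`)
  with support for pinned profiles.
- **Soil limitation grading** (`agrichoice.soil`): five-degree (I–V) grading
  of soil chemical parameters against configurable thresholds, with a
  two-sided pH ladder, per-plot worst degree, per-hub tallies and
  severe-limitation flags.
- **Conditional logit** (`agrichoice.mnl`): vectorized likelihood/gradient,
  BFGS MLE, observed-information covariance, McFadden pseudo-R² against the
  equal-shares base model.
- **Latent-class logit** (`agrichoice.latent`): S classes with
  covariate-driven membership (zeroed reference class), EM + quasi-Newton
  polish with multistart, AIC/BIC/CAIC class selection, posterior assignment
  and a Wald joint test.
- **Attribute non-attendance** (`agrichoice.attendance`): endogenous
  attendance mixtures over per-attribute (or joint-block) Bernoulli
  attendance, reporting ANA (ignore) probabilities.
- **Willingness to adopt** (`agrichoice.wta`): −β/δ ratios back-transformed
  to CFAF, USD conversion at a fixed rate (default 606.73 CFAF/USD),
  delta-method standard errors, within-class ranking.
- **Synthetic data** (`agrichoice.simulate`): study-shaped generators
  (962 respondents / 1,047 plots / 4 situations x 4+1 alternatives =
  20,940 rows) under latent-class or attendance-mixture truths, with per-hub
  soil chemistry and reproducible substreams per stage.

## CLI

Every subcommand writes its outputs plus a `manifest.json` (config hash,
seed, package version) into a fresh `--out` directory:

```sh
agrichoice simulate --preset small --seed 1 --out runs/sim
agrichoice design --sets 4 --alts 4 --seed 0 --out runs/design
agrichoice classify-soil --input runs/sim/population.csv --out runs/soil
agrichoice fit-mnl --data runs/sim/choices.csv --out runs/mnl
agrichoice fit-lcl --data runs/sim/choices.csv --classes 3 --starts 10 --seed 0 --out runs/lcl
agrichoice fit-eaa --data runs/sim/choices.csv --block conservation,maintenance --out runs/eaa
agrichoice wta --fit runs/lcl/lcl_fit.json --rate 606.73 --out runs/wta
agrichoice pipeline --preset small --classes 2 --seed 0 --out runs/full
```

Presets: `study` (1,047 plots), `small` (44 plots, quick smoke), `eaa`
(attendance-mixture truth). A YAML config passed with `--config` may
override the attribute scheme (`scheme:` — attributes, levels, cost_scale,
interactions), simulation overrides (`simulate:`) and the latent-class
membership covariates (`membership_covariates:`); CLI flags take precedence.

## Conventions

- Binary attribute levels are coded 0/1 exactly as defined by the scheme;
  cost enters estimation divided by `cost_scale` (default 10,000 CFAF) and
  WTA is always reported back in CFAF.
- Boundary soil measurements resolve to the better (lower) degree; pH is
  graded on both the acid and alkaline ladders and the worse side wins.
- Mixture models group situations by plot by default (`unit="respondent"`
  available); information criteria use the number of mixture units as n.
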