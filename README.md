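# accurator

**Clinical-utility calculator for polygenic risk score (PRS) guided
intervention.**

Polygenic risk scores can flag the top few percent of a population as being
at several-fold elevated risk of a disease — but whether *treating* that
group is worthwhile depends on quantities a relative risk alone does not
reveal: the precision of the call (most called positives for a rare disease
never become cases), the fraction of all cases the targeted group actually
contains, and the number needed to treat. `accurator` computes all of these
in closed form from four inputs — disease prevalence, the targeted fraction
of the population, one discrimination parameter, and treatment
effectiveness — and validates every formula with a Monte Carlo cohort
simulator. It is aimed at statistical geneticists and clinical
epidemiologists evaluating whether a risk score is ready for therapeutic
targeting.

## The model

A screening scenario is a 2×2 table determined by prevalence *p*, target
fraction *t* (everyone above a chosen PRS percentile), and sensitivity *s*.
The three interchangeable discrimination currencies are linked by

* remainder-referenced relative risk
  RR = (s·p/t) / ((1−s)·p/(1−t)), so **s = RR·t / (1 − t + RR·t)**
  (prevalence cancels);
* precision PPV = s·p/t;
* table cells tp = s·p, fp = t − tp, fn = (1−s)·p, tn = 1 − t − fn,
  from which NPV, specificity and accuracy follow.

With treatment preventing a fraction e_t of treated cases in the target and
e_r outside it:

* events prevented treating only the target: s·p·e_t
* events prevented treating everyone: p·(s·e_t + (1−s)·e_r)
* **NNT(all) = 1 / [p·(s·e_t + (1−s)·e_r)]**,
  **NNT(targeted) = 1 / (PPV·e_t)**

The percentile axis is supplied by the standard Gaussian liability threshold
model: liability L = g + e with g ~ N(0, r²), e ~ N(0, 1−r²), disease when
L > Φ⁻¹(1−K). Conditional risk at PRS percentile q is
Φ̄((T − √r²·Φ⁻¹(q))/√(1−r²)), and `calibrate_r2_to_rr` finds the variance
explained r² that makes the top tail match a stated relative risk. A cohort
simulator draws individuals from the same model and recovers every metric by
counting — the package's internal oracle.

## Worked example

Suppose a score defines the top 5% of the population with a relative risk of
8.7 for opioid use disorder (8% prevalence) and treatment prevents 80% of
treated cases:

```bash
$ accurator intervene --prevalence 0.08 --target 0.05 --rr 8.7 --effectiveness 0.8
percent_preventable     0.314079
percent_all_prevented   0.251264
nnt_all                 15.625
nnt_targeted            2.48743
nnt_all_rounded         16
nnt_targeted_rounded    2
```

Treating only that top 5% prevents 25% of all cases (31% of the cases that
are preventable at all), and within the target group fewer than three people
must be treated per case prevented — against 16 if everyone were treated.
The same algebra runs in Python:

```python
>>> from accurator import required_rr_for_precision, two_group_prevention
>>> round(required_rr_for_precision(0.5, 0.08, 0.05), 3)   # RR needed for 50% precision
8.636
>>> two_group_prevention(0.08, 2/3, 0.5, 0.5)  # negative prediction: 2/3 at half risk
0.25
```

Other subcommands: `accurator metrics` (PPV/NPV/sensitivity/specificity),
`accurator curve` (risk-by-percentile TSV from the liability model, with
optional plot), `accurator simulate` (seeded Monte Carlo cohort with counted
metrics and standard errors), and `accurator tables`, which evaluates a
whole scenario set:

```bash
$ accurator tables --preset observed_conditions | cut -f1,5
Attribute               cad_rr3.3_top5
Prevalence              2.2
Relative Risk           3.3
Target                  5%
PPV/Precision           7
...
NNT All                 182
NNT Targeted            61
```

Two presets ship with the package (`rare_vs_common`, `observed_conditions`);
custom sets are flat YAML files with one mapping per column
(`prevalence`, `target`, exactly one of `relative_risk`/`sensitivity`/`ppv`,
and an effectiveness — see `accurator tables --config`).

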