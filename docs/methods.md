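# Methods

## Scope and model

`accurator` treats risk-stratified intervention as pure 2×2-table algebra.
A scenario is (prevalence *p*, target fraction *t*, sensitivity *s*), with
*s* optionally derived from a remainder-referenced relative risk or from a
precision goal. All quantities are fractions of the whole population;
percents appear only at I/O boundaries. This avoids the classic
double-scaling bugs of mixed percent/fraction code.

**Relative risk convention.** RR here is the prevalence among the targeted
divided by the prevalence among the untargeted remainder, RR = PPV/(1−NPV).
It is *not* the cross-product odds ratio, and it is referenced to the
remainder rather than to the whole population. Sensitivity follows as
s = RR·t/(1 − t + RR·t), independent of prevalence — which is why a
published score's tail RR can be carried across diseases with different
prevalences. Texts that quote tail "odds ratios" for scores of this strength
are usually quoting this same quantity; the package exposes no cross-product
odds ratio at all.

**Intervention model.** Treatment prevents a fraction e_t of treated cases
inside the target and e_r outside (both in [0,1]; uniform means e_t = e_r).
NNT(all) takes the whole population as the treated denominator with
remainder cases preventing at e_r; NNT(targeted) = 1/(PPV·e_t) exactly.
Under uniform effectiveness the share of preventable events captured by
target-only treatment collapses to the sensitivity — a useful sanity
identity, exercised directly by the tests. NNTs are returned raw, with
nearest-integer renderings (half away from zero) alongside, because printed
tables round but downstream arithmetic must not.

**Infeasibility is an error, not a clamp.** Parameter combinations implying
PPV > 1 or NPV < 0 (e.g. a precision goal requiring more cases in the target
than exist) raise `InfeasibleScenarioError`. Clamping would silently
fabricate a different scenario.

## Liability threshold model

The percentile axis comes from the standard Gaussian liability threshold
model: liability L = g + e, g ~ N(0, r²), e ~ N(0, 1−r²), disease iff
L > T = Φ⁻¹(1−K). This is the field-standard generative mechanism for
PRS-by-percentile risk profiles; it produces the characteristic slow rise
across most of the score distribution with a sharp upswing in the top
percentiles. Parameters: population risk K in (0,1) and variance explained
on the liability scale r² in [0,1) — r² = 1 is rejected as degenerate (risk
becomes a step function). `calibrate_r2_to_rr` bridges the two worlds,
root-finding (Brent, tolerance 1e−12) the r² whose top tail above a given
percentile has a stated RR; RR = 1 maps to r² = 0, and requests above the
perfect-score supremum (1−t)/(K−t) are rejected.

**Quadrature.** Tail and bin masses ∫ risk(q) dq are evaluated by composite
Gauss–Legendre after substituting q = Φ(z): on the liability scale the
integrand Φ̄((T−√r²·z)/√(1−r²))·φ(z) is smooth everywhere, whereas in
percentile space its derivatives blow up at q → 0, 1 through Φ⁻¹ and a
fixed-order rule converges slowly. With 8 panels × 24 nodes (curve bins use
2 panels each) the law-of-total-probability defect |∫risk − K| is below
1e−10, comfortably inside the 1e−6 the tests require; integration limits are
capped at |z| = 8.5, discarding < 1e−17 of mass. Tests cross-check the tail
mass against the closed bivariate-normal form (L and the standardized score
are jointly normal with correlation √r²), an independent route that involves
no percentile quadrature.

**Risk curves.** The percentile grid uses half-open bins [i/b, (i+1)/b) on a
configurable grid (default 100). Per bin the curve reports mean conditional
risk, fold enrichment versus the mean risk of all lower percentiles
(undefined for the first bin — reported as NaN rather than a fabricated 1),
sensitivity above the bin's lower edge, and precision of targeting above it.

## Monte Carlo simulator

The simulator draws individuals from exactly the liability model above and
recomputes every metric by counting, making it a model-free oracle given the
cohort. Design choices:

* **Target by score rank, not by outcome or total liability** — the top
  round(n·t) individuals by g, matching how a PRS would be used in practice
  (ties cannot occur with continuous g; the count is exact up to integer
  rounding). With r² = 0 the "top" is an arbitrary random subset, as it
  should be.
* **Potential-outcome response draws.** Each individual receives one
  Bernoulli response draw at their group's effectiveness, so the treat-all
  and treat-target policies are compared on the same counterfactuals rather
  than on independent randomness; "prevented" counts are therefore
  consistent between arms.
* **Standard errors** are plain binomial SEs on the relevant denominator
  (target size for PPV, case count for sensitivity, …). Empty margins raise
  a degeneracy error instead of returning silent NaNs.
* **Determinism.** One `numpy.random.Generator` seeded per cohort; identical
  seeds give bit-identical cohorts.

The default validation size is n = 200,000, at which 3-SE bands are narrow
enough to distinguish adjacent integer percentages in the rendered tables.
One caveat follows from the same arithmetic: for narrowly targeted columns
(t = 5% of a 2%-prevalence condition) the relative SE of the target-group
NNT is about 3%, so fixed-seed checks tighter than ~3 SE on that quantity
can fail by ordinary sampling noise at this n even though the estimator is
unbiased; the simulator-agreement tests and their outcomes should be read
with that in mind.

## Scenario tables and configuration

Scenario sets are flat YAML: a name plus a list of column mappings, each
with `prevalence`, `target`, exactly one discrimination key
(`relative_risk` / `sensitivity` / `ppv`), and either `effectiveness` or the
`effect_target`/`effect_remainder` pair. Unknown keys are rejected, every
column is feasibility-checked at load time, and errors name the offending
column. Evaluation is a pure function; output is either raw fractions (JSON)
or the conventional integer-percent rendering (TSV), rounding halves away
from zero — the convention that matches published screening tables (e.g.
0.425 → 43).

The shipped presets encode two standard scans: `rare_vs_common` (a 2% vs 20%
prevalence condition across realistic and exceptional score strengths,
uniform 90%/50% and differential 75%/25% effectiveness) and
`observed_conditions` (opioid use disorder, cardiovascular events under
intensive blood-pressure therapy at a 2.2%/year event rate treated as an
ordinary per-period prevalence, and lifetime osteoporotic fracture risk).

### Known inconsistent cells

Three printed cells in the published versions of these scans are internally
inconsistent with their own columns and are deliberately *not* reproduced;
the engine emits the model-consistent values:

* rare-vs-common, RR = 2 / top 20% column: sensitivity and specificity print
  as 50/88 but the column's own PPV of 33 forces 33/83 (the printed
  "Percent of Preventable 33%" agrees with 33, confirming the typo);
* observed-conditions, fracture RR = 5 / top decile: "Percent of
  Preventable" prints 31% where uniform effectiveness forces it to equal the
  sensitivity, 36%;
* the first table's prevalence row begins 5/8/8 in some transcriptions while
  every other cell of those columns verifies only at 2% — the presets use 2%.

## Limitations

* The liability model is a parametric stand-in for empirical
  percentile-risk profiles: real scores show ancestry-dependent calibration,
  age structure, and non-Gaussian tails that the model does not emulate, so
  agreement here demonstrates internal consistency, not real-world
  calibration.
* No time-to-event modelling: annualized rates are treated as per-period
  prevalences. No adverse-event (NNH) modelling, no adherence, no
  cost-effectiveness.
* Effectiveness is a single Bernoulli response probability per group;
  correlation between disease risk and treatment response beyond the
  two-group split is out of scope.
* Confidence intervals on the closed-form metrics are not provided (the
  inputs are scenario parameters, not estimates with sampling error).
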