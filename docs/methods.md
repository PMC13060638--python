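# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions. It states no empirical result
that the test suite or the acceptance run does not itself compute.

## Droplet-level quantification

A ddPCR reaction partitions template randomly into `n` droplets, so the copy
number per droplet is Poisson with mean λ and the probability that a droplet
is positive is `p = 1 − e^(−λ)`. Inverting the observed positive fraction
gives the maximum-likelihood occupancy

```
λ̂ = −ln(1 − n_positive / n_total),     c = λ̂ / v   [copies/µL]
```

with `v` the droplet volume in µL. **Droplet volume** is an instrument
constant that the assay output does not carry; the default is 0.85 nL (the
QX-series convention) and every copies/µL and copies/mL figure scales as
`1/v`. It is configurable (`VolumeConfig.droplet_volume_nl`).

**Confidence intervals.** A 95% Wilson score interval is computed on the
binomial proportion `p̂` and both bounds are pushed through the monotone map
`p ↦ −ln(1−p)`. The Wilson interval is used because it behaves well at the
low counts this assay lives at (0–10 positive droplets): it never collapses
to a zero-width interval at `n_positive = 0`, and monotonicity of the
transform preserves the interval ordering. Coverage of the planted λ is
verified by simulation at λ from 0.001 to 1 (≥ 93% required). The original
assay publication cites an earlier CI construction without formulas; the
Wilson transform is this package's documented stand-in.

**Pooling.** Duplicate wells of the same reaction mix are merged by adding
droplet counts *before* quantification. Droplets from replicate wells are
exchangeable Poisson samples, so pooling is exact, whereas averaging
per-well estimates is not (the transform is nonlinear). All downstream
droplet-count thresholds (LoBs) refer to pooled counts.

**Saturated wells** (every droplet positive) have no finite point estimate;
they are flagged and reported as the Wilson lower bound with an infinite
upper CI, never as infinity in a table.

**Volume chain.** Copies measured in the analyzed wells are scaled to plasma
by dividing by the analyzed fraction of the bisulfite-converted eluate and
the plasma input volume. Defaults: duplicate 5 µL templates from a 15 µL
eluate (fraction 2/3) derived from 4 mL plasma. Every volume is
configurable; whether the original analysis pooled duplicates or averaged
per-well copies for its copies/mL is not documented, so pooling is used for
consistency with the Poisson argument above.

**Degenerate ratios.** Percent methylated (`100 × marker/ALB`) is undefined
— returned as `None`, never 0 — when the ALB reference measured zero
copies.

## Preanalytical quality control

Four single-well ddPCR assays per sample: CPP1 spike-in recovery (spiked
~36,000 copies before extraction), PBC/cfDNA ratio (B-cell IGH assay;
lymphocyte DNA contamination flagged strictly above 2%), EMC7 250 bp/65 bp
fragment ratio (high-molecular-weight contamination), and total cfDNA
(EMC7 short fragment scaled through the QC volume chain, default 5 µL
template of a 200 µL cfDNA eluate). The EMC7 flag threshold (0.35) and the
low-recovery threshold (0.42) are conventions chosen to separate the
observed outlier regime from the observed bulk; neither is an assay
constant, both are configurable, and **all flags are advisory** — no flag
excludes a sample.

## Limit of blank and combined calling rule

Per marker, the pooled positive-droplet counts of an analyte-free control
cohort and a case cohort define an empirical ROC over integer thresholds
(droplet counts are integral). The LoB is the threshold maximising Youden's
J = sensitivity + specificity − 1 over all integers from 0 to the largest
observed count; **ties break toward the higher threshold** because an LoB is
a blank limit — when J is flat, the more specific cut is the defensible one.
A marker is called positive when its pooled count is **strictly above** the
LoB ("above the limit of blank" read strictly; equality is blank-consistent;
an inclusive mode is available via `MarkerPanel(strict=False)`).

A sample is ctDNA-positive when at least `min_positive_markers` markers are
positive and the positive set is not *exactly* an exception set. The
published panel is LoB = {NPY 4, FRMD4B 3, GDAP1L1 2, CELF2 2, CLIP4 1},
k = 2, exception {NPY, GDAP1L1}.

**Rule search.** `combined_rule_search` ascends k = 1..5. At each k it
evaluates the plain k-of-5 rule on the control cohort; if specificity falls
short of the target (default ≥ 95%), it collects the exact positive-marker
sets of control false positives of size exactly k and tries each as a single
exception, most frequent first. A candidate is adopted only when it (a)
reaches the specificity target and (b) yields a strictly better
sensitivity + specificity sum than the plain rule at that k — the
combination criterion the assay's developers applied. Restricting candidates
to minimal sets (|set| = k) preserves monotonicity: a larger exception would
call a sample negative while one of its strict subsets is called positive.
Exception adoption is recorded in the calibration log, never silent. If no
k admits the target specificity, the search returns k = 5 with a warning
flag.

Two design notes: this ordering prefers a k=2 rule rescued by an exception
over a plain k=3 rule (it keeps more sensitivity at equal specificity), and
the calibration is deliberately in-sample — the published panel was derived
on the full cohorts, and cross-validating the calibration is out of scope.

## ctDNA kinetics and response classification

Each timepoint is reduced to one **aggregated ctDNA fraction**: by default
the five markers' pooled positive droplet counts are summed, the sum is
quantified as if it were one target, and the fraction is
`100 × λ_sum / λ_ALB`, with the CI given by the Wilson-transformed interval
on the summed count scaled by the ALB point estimate. Summation is monotone,
uses all signal, and keeps a count-level CI; `max` and `mean-positive`
aggregations are selectable. ALB is treated as fixed in the fraction CI —
its relative error is negligible against the marker counts (thousands vs
tens of droplets).

A change between baseline and post-treatment is **significant** when the two
95% CIs do not overlap; touching intervals count as overlap. This criterion
is conservative by construction (two independent 95% intervals overlap far
more than 95% of the time under the null), which the suite verifies
(< 5% false-change rate on null pairs).

Categories: PD = significant increase; SD = no significant change; for a
significant decrease, CR = zero positive droplets across all five markers,
NCR = ctDNA-negative but with residual sub-LoB droplets, PR = still
positive. CR/NCR as stated here are this package's documented stand-ins for
an unpublished criteria table; they are validated by count consistency
(CR + NCR + PR must equal the number of significant decreases) rather than
against the original wording.

Responder groups: **progressive** = significant increase, or a
negative→positive transition (not observed in the original cohort; defined
for completeness); **good** = ctDNA-negative after treatment regardless of
change (includes consistently-negative pairs), or consistently positive
with a significant decrease of strictly more than 75% in fraction;
**poor** = consistently positive with a ≤ 75% decrease or a stable
fraction. The 75% boundary is strict: a measured −75.0% change is poor.
Patients with an undefined baseline fraction (ALB zero) or zero baseline
signal are handled through the status-transition logic, not percent change.

## Marker discovery

Beta matrices (CpG probes × samples, values in [0,1]) with COLON/REST
labels. Probes with any missing value are removed first. A probe is a
colon-hypermethylated DMC when mean COLON beta > 0.75 and mean REST beta
< 0.25, hypomethylated under the mirrored condition; inequalities are
strict, so a probe whose group mean sits exactly on a threshold is not
selected. Feature ranking sits behind a contract
(`ranker(beta, labels, seed) → ordered probes`): the default is a
dependency-free two-group separation score (|mean difference| / pooled SD);
recursive-feature-elimination (linear SVM) and random-forest-importance
rankers, both rank-averaged over repeated stratified cross-validation
(10-fold ×5 and 10-fold ×10 by default), plug in via scikit-learn. The
candidate list is the union of the two rankers' top-10, at most 20 probes.
The downstream wet-lab triage of candidates (assay design, multiplex
compatibility) is out of scope.

## Survival

Kaplan–Meier product-limit estimation, log-rank comparison and Cox
proportional-hazards fits are delegated to lifelines behind this module's
interface. The median is the earliest time with estimated survival ≤ 0.5;
its CI inverts the Greenwood log-log band at 0.5; medians never reached
propagate as the token `"NR"`, never as infinity. Cox fits use a single
categorical covariate (the stratum) with Efron tie handling; a reference
arm without events is flagged unstable rather than rejected. Censoring is a
data-preparation responsibility (an `event` column), never inferred.

## Synthetic cohorts — the stated world

The generator emulates the cohort structure the analysis assumes: 60
controls, 59 localized and 65 metastatic patients; duplicate 20,000-droplet
wells; six co-measured targets. Droplet counts follow the occupancy model
`n_positive ~ Binomial(n, 1 − e^(−c/n))` for `c` planted copies per well.

Anchored constants (taken from the published cohort description): cohort
sizes; ALB copies per well (lognormal, medians 3470/3680/6350 from the
reported total-cfDNA medians of 2600/2760/4760 copies/mL over 4 mL plasma);
relative marker levels (the reported per-marker median percent-methylated
values in localized disease); the good/poor/progressive mix (36/21/8 of
65); and per-group progression hazards (exponential, good median 11.4
months, poor ×1.71, progressive ×4.36).

Calibrated conventions (tuned once so that default runs land in the
published operating regime of ≈ 97% specificity and ≈ 64%/89% sensitivity,
then frozen; they are not measurements): shedding is bimodal — a patient
is a non-shedder with probability 0.33 (localized) / 0.09 (metastatic),
otherwise draws a lognormal(0, 0.8) factor on the cohort median level with
metastatic levels 4× localized. Blank background is Poisson per well and
concentrated on NPY (0.35/well) and GDAP1L1 (0.25/well) — the two assays
whose published single-marker specificities are low — with near-clean
tissue-conserved assays; the control matrix additionally carries a
correlated contamination mode hitting NPY and GDAP1L1 jointly (12% of
controls, ~8 copies/well) and a rare three-marker mode (1.25%). The
contamination modes apply to the control cohort only, mirroring the
observation that the pair pattern occurred exclusively in controls (which
were collected and processed separately from the patient cohorts).
Post-treatment fractions multiply the baseline by a group-dependent fold:
good = cleared (50%) or 0.02–0.12, poor = 0.45–1.1, progressive = 2.5–8
(log-uniform). Non-shedding metastatic patients are labelled good with fold
0, because the classification itself defines consistently-negative pairs as
good responders and a patient without measurable ctDNA cannot express
planted kinetics.

What a green test does **not** establish: the generator has no
between-well or between-plate variability, no bisulfite-conversion loss, no
droplet-count variation (every well has exactly 20,000 accepted droplets),
no fluorescence-level effects (gating is upstream of this package), and
marker levels within a patient are perfectly proportional (one shedding
factor). Recovery results on synthetic cohorts therefore bound what the
method does under its own model assumptions, not assay performance on real
plasma. Patient-level published results (cohort medians, hazard-ratio point
values, exact group counts) are not reproducible without the raw patient
data; the suite verifies the machinery by parameter recovery instead.

Reproducibility: one global seed fans out through `SeedSequence.spawn` to
independent substreams (cohorts, response assignment, QC, beta matrices,
survival), so generated tables are byte-identical across runs for a fixed
seed and module-level tests can draw independent streams.

## Numerical conventions

* Strict inequalities wherever the rule text says "above"/"more than":
  marker counts vs LoB, the 2% PBC ratio, the 75% decrease, DMC thresholds.
* Youden ties → higher threshold; ranker ties → stable (mergesort/lexsort)
  order by probe identifier.
* Zero-count wells: λ̂ = 0 with CI [0, Wilson-upper]; λ̂ = 0 iff no positive
  droplets.
* Probability-scale quantities are kept as fractions internally and
  formatted as percentages (one decimal) only at reporting boundaries.
* Exit codes in the CLI: 0 success, 2 validation failure, 3 degenerate
  result escalated (e.g. specificity target unreachable).

## Known limitations

* The Wilson-transformed CI is a stand-in for the original (uncited-formula)
  interval; absolute CI widths may differ slightly, though the change-test
  conservatism property holds for any interval at the stated level.
* The exception-set search only promotes single minimal sets; worlds whose
  blank structure needs two simultaneous exceptions fall back to a higher k.
* The aggregated-fraction CI ignores ALB uncertainty (documented above).
* `copies/µL` values inherit the assumed droplet volume exactly.
* The RFE and random-forest rankers are convenience wrappers; their
  estimator choices (linear SVM, 100-tree forests) are defaults, not tuned.
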