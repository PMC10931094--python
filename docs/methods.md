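# Methods

## Data model and normalization

Mutation input is MAF-dialect TSV (GDC column names, `#` comments). Rows
without an `HGVSp_Short` protein annotation are dropped at read time
because positional pooling is impossible without it; silent mutations are
kept, since synonymous recurrence can be functional. The amino-acid
position of an event is the **first** integer in the HGVS string, so a
range deletion (`p.E746_A750del`) or a frameshift (`p.G96Wfs*12`)
contributes to its start position; this pools an exon-19-deletion cluster
with substitutions at the same residue, which is the behavior a positional
screen wants.

Patient identity is the 12-character barcode prefix, and *all* pooling and
group construction is per patient, never per sample: a patient with two
sequenced samples carrying the same hotspot is one carrier. The
sample-type whitelist defaults to primary tumor (`01`); metastatic (`06`)
can be added for melanoma-like cohorts where the primary is rarely
sequenced. Overall survival is `days_to_death` for deceased patients and
`days_to_last_follow_up` otherwise; unknown vital-status strings are
treated as censored and logged rather than dropped, because silent record
loss is worse than a conservative censoring assumption.

## Hypermutation filter

TMB is the per-sample count of SNVs (`Variant_Type == SNP`; indels do not
count). A sample is hypermutated when either

* **Rule A**: TMB > 500 *and* TMB ≥ the nearest-rank 90th percentile
  (ties at the threshold included), or
* **Rule B**: TMB > median + 4·MAD.

The MAD is unscaled (median of absolute deviations, no 1.4826 consistency
constant); the scaled variant is available as an option
(`scaled_mad=True`) since robust-statistics conventions differ. The final
flag is A ∪ B. Note a structural property of Rule B: for any unimodal
burden distribution with tails (e.g. Poisson), median + 4·MAD sits near
the ~99.6th percentile, so a fraction of order 0.3% of perfectly ordinary
samples will always be flagged. That is the intended behavior of a robust
outlier cutoff, not an artifact; the synthetic-data tests therefore require
all *planted* hypermutated samples to be flagged while allowing at most 1%
background leakage.

## Hotspot calling and the four comparisons

Mutations are pooled by (gene, transcript, amino-acid position) per cancer
type; a position is a hotspot when ≥ `min_patients` (default 4) patients
*with clinical data* carry it. Positions on different transcripts of a
gene are distinct hotspots, but comparison universes (vs Gene, vs Spots,
vs Y) are built per gene symbol.

Group construction follows one precedence rule: **carrier beats
comparison**. A patient carrying hotspot X never appears in X's
comparison group, whatever else they carry; in X vs Y, patients carrying
both are excluded from both sides. This keeps every comparison a disjoint
two-group partition, which the statistics require. The ≥4-patient
threshold applies to both sides in tests 2–4 (the comparison universes
shrink as they specialize, and a 2-patient comparison arm is
uninterpretable); for X vs All only the carrier side is thresholded,
since the complement of a called hotspot in a testable cohort is always
large. X vs Y pairs are unordered and tested once, with the hazard ratio
oriented X relative to Y. Every skip decision is logged.

Significance is called on the empirical permutation p at α = 0.05, raw.
No cross-screen multiplicity correction is applied: the null is estimated
per comparison, conditional on that comparison's group sizes and event
structure, and a global correction assuming one shared null would be
miscalibrated for exactly the unbalanced cases this package exists for.
The χ² log-rank and Cox p-values are reported for context, never used for
calling.

## The conditional permutation null of L

The null holds the observed times and censoring pattern fixed and permutes
only the minority-group labels. The implementation rests on the score
identity

```
L(g) = Σ_{i∈g} w_i,   w_i = δ_i − H(t_i),   Σ_i w_i = 0,
```

where `H` is the pooled Nelson–Aalen cumulative hazard evaluated at each
patient's own time (ties included). The identity is exact for the
multiplicity-aware tie version of L and is verified against a direct
risk-table computation in the tests; it reduces every label assignment to
a subset sum.

* **Enumeration mode** (`C(n, n1) ≤ enum_limit`, default 100 000): all
  assignments are listed; the null is exact with uniform weights.
* **Stratified mode** otherwise: conditioning on `k`, the number of events
  in the minority group, the assignment splits into a k-subset of the `d`
  event patients and an (n1−k)-subset of the censored patients, each
  uniform. Stratum weights are hypergeometric,
  `w_k = C(d,k)·C(n−d,n1−k)/C(n,n1)`, computed in closed form, so the
  rare-`k` tails that dominate small p-values carry exactly the right
  mass. Within a stratum, if the stratum's subset count is at most
  `stratum_enum_limit` (default: the per-stratum sampling budget) the
  stratum is enumerated exactly as an outer sum of event-side and
  censored-side subset sums; larger strata are estimated from
  `n_perm_per_stratum` (default 10 000) uniform draws.

The two-sided p-value is `min(1, 2·min(P(L ≤ L_obs), P(L ≥ L_obs)))`,
with support points equal to `L_obs` (within a 1e-9 relative tolerance)
counted fully in both tails — the conservative reading of "twice the tail
area" for discrete nulls. The statistic whose null is tabulated is the
signed `L` itself, not `L²/V`, because the null's asymmetry is
informative: its two tails genuinely differ when groups are unbalanced.

Reproducibility: the RNG seed is a mandatory argument. The screen derives
one sub-seed per comparison from the screen seed and the comparison's
identity (CRC32 of cancer/gene/transcript/position/test), so results are
identical across reruns and independent of hotspot iteration order.

## Cox model and Kaplan–Meier

The Cox fit is the single-binary-covariate partial likelihood with Breslow
tie handling, maximized by Newton iteration on the closed-form score and
information (steps capped at ±5, convergence at |step| < 1e-9). Wald
p-values are reported. Degenerate configurations are first-class: no
events at all (`no_events`), a group with zero events
(`no_events_in_group`), and monotone likelihoods detected as |log HR| > 15
after convergence-by-saturation (`nonconvergence`) all return a
qualitative direction `"<1"` or `">1"` instead of a meaningless numeric
hazard ratio — matching how screening tables conventionally annotate
inestimable HRs. The fit is cross-checked against an independent
implementation (lifelines) in the tests.

Kaplan–Meier estimation delegates to lifelines' product-limit fitter;
median survival is the smallest time with S(t) ≤ 0.5, absent when the
curve never reaches it.

## Synthetic cohorts

Survival is exponential with rate `baseline_hazard · HR^carrier`
(defaults: 1/1000 per day, i.e. ~700-day median survival), censored by an
independent exponential (1/2000 per day) and a 10-year administrative
cutoff — roughly one third of patients censored, times rounded to whole
days as registries record them. Exponential survival satisfies
proportional hazards exactly, so the Cox estimand has a known truth and
parameter-recovery tests are meaningful.

Mutations have two background layers. The modeled genes (default three,
mutation probability 0.05–0.15 per patient, protein lengths 600–1000)
receive sparse background mutations, so random positional recurrence is
rare, as in a real exome. The per-sample *burden* is emitted separately:
Poisson-distributed SNV counts (mean 50 background, 1000 hypermutated)
scattered over 200 background genes × 10 000 positions, a space large
enough that burden mutations essentially never recur positionally.
Hypermutated patients draw elevated counts everywhere, including the
modeled genes — which is precisely the mechanism by which unfiltered
hypermutators fabricate hotspot carriers. HGVS strings are synthesized
from a grammar covering missense, synonymous, frameshift and range
deletions, so the parser's full surface is exercised. Planted hotspots
draw carriers without replacement and add missense SNVs at the planted
position; a patient carrying several planted hotspots multiplies their
hazard ratios.

What the generator does *not* emulate: mutational signatures, copy
number, subclonality, covariate structure (age, stage, subtype), or
non-proportional hazards. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that real
cohorts satisfy that model.

## Validation battery and problem sizes

The statistical-validation suite (also recomputed by
`scripts/acceptance.py`) uses these designs, chosen to finish in minutes
on one core while keeping Monte-Carlo error well inside the asserted
margins:

* **Oracle agreement** — 20 random instances, n ≤ 12, n1 ≤ 4, mixed
  censoring: enumeration-mode null vs a direct subset iterator, total
  variation < 1e-12; empirical p equals the oracle p.
* **Sampling convergence** — n=12, n1=3: stratified null vs enumerated
  null, TV decreasing over per-stratum budgets {100, 1000, 10000}, < 0.02
  at the largest.
* **Type-I error** — n=300, n1=6, 30% censoring, 2000 replicates, 2000
  draws per sampled stratum: rejection at 0.05 within [0.035, 0.065].
* **Balanced limit** — n=200, n1=100, 100 replicates: mean
  |p_empirical − p_χ²| < 0.02 (the regime where the classical test is
  fine).
* **Unbalanced regime** — n=400, n1=4, 200 replicates: 90th percentile of
  |p_empirical − p_χ²| > 0.05 (the failure mode that motivates the
  empirical null).
* **Cox recovery** — planted HR=2, n=500, 20% censoring, 200 replicates:
  Wald 95% CI coverage ≥ 90%; zero-event and temporally separated
  fixtures exercise every degenerate path.
* **Filter and calling fixtures** — three hand-computed TMB cohorts flag
  exactly the expected samples; planted positions round-trip through the
  full pipeline; the 54-patient walkthrough cohort reproduces its design
  counts (54 patients / 34 gene-mutated / 4 hotspots) and group sizes.

## Known limitations

* The null is conditional on the observed censoring pattern; it does not
  model covariate-dependent censoring.
* Stratified sampling estimates within-stratum shapes by Monte Carlo;
  p-values below ~w_k/n_perm for the extreme stratum are resolution-
  limited (raise `n_perm_per_stratum` when chasing very small p).
* The Cox model is univariate by design — with 4–20 carriers, covariate
  adjustment destabilizes estimation faster than it removes confounding —
  so hazard ratios are unadjusted associations, not causal effects.
* Transcript-level pooling means genes annotated against multiple
  transcripts in the same file yield distinct hotspots at the same
  nominal residue.
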