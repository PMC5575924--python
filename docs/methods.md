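# Methods

This note documents the statistical models, conventions, and design
choices behind `crisprstat`, and what the synthetic-data generator does
and does not emulate.

## Data model and integration

The unit of analysis is a *replicon* (chromosome or plasmid) identified by
accession.  Arrays and operons use 1-based inclusive coordinates; all
distance arithmetic is defined against that convention.  The distance
between an operon and an array is 0 when the intervals overlap and
otherwise the gap between the nearest interval ends (operon ending at 200,
array starting at 300 → 100 bp).  Distances are linear along the replicon;
no wrap across the origin is applied.  A circular-distance alternative
would change results only for operon-array pairs spanning the sequence
origin, which the generator never produces and which real annotation
tables rarely contain.

Distance is measured to the whole operon interval rather than to the cas1
gene alone — the conservative reading when only operon bounds are known.
Each operon is associated with exactly one (closest) array; equidistant
candidates tie-break deterministically on smaller start coordinate.
Operons on replicons without any array are reported in an "unpaired"
sidecar rather than silently dropped.  Arrays on replicons without any
classified operon are exposed via `cas_less_arrays` as candidate inactive
loci.

Default filtering keeps chromosomal, non-questionable arrays and Class 1
Type I/III operons with a cas1 anchor.  Strand-specific analyses key on
the **array's** strand (not the operon's): the array is the feature whose
position and orientation are under study, and the two strands are reported
separately throughout.

## Array-size model

Spacer counts are treated as draws from a single-parameter discrete
family.  The geometric family uses the *failures* parameterization on
{0, 1, 2, …}: pmf `(1−p)^k p`, mean `(1−p)/p`, MLE `p̂ = 1/(1 + x̄)`.  This
choice (rather than the trials form on {1, 2, …}) is forced by the
estimate pair the model is meant to produce: a sample mean near 38.3 gives
`1/(1+38.277) ≈ 0.0255`, i.e. a p̂ of 0.025 alongside a Poisson λ̂ equal to
the mean.  Log-likelihoods are accumulated in log space via
`scipy.stats.*.logpmf`, which is well-conditioned at n ≈ 800 and means
≈ 38.

Quartiles use linear interpolation of order statistics at position
`1 + (n−1)p` (numpy's `method="linear"`), the default of the R environment
such summaries are conventionally produced in.

### Goodness of fit

The Kolmogorov–Smirnov statistic `D = sup|F₀ − F_data|` is computed
exactly: both CDFs are right-continuous step functions jumping only at
integers, so the supremum is attained on the integer grid 0..max(sample)
and is evaluated there in full.

Because the family parameter is estimated from the same sample and the
support is discrete, the continuous K-S null distribution is doubly
invalid (anti-conservative for estimated parameters, conservative for
discreteness).  P-values therefore come from a Lilliefors-type parametric
bootstrap: draw a same-size sample from the fitted distribution, refit,
recompute D, and report `p = (1 + #{D_boot ≥ D_obs}) / (n_boot + 1)`.  The
bootstrap is seeded and fully reproducible; 999 replicates by default
(overridable, minimum 99 so the smallest attainable p-value is ≤ 0.01).
The calibration of this test under a true geometric null and its power
against Poisson misspecification are verified in the test suite and
recomputed by `scripts/acceptance.py`.

Group comparisons use Welch's unequal-variance t-test (Satterthwaite
degrees of freedom, two-sided) between the two major types and the
Kruskal-Wallis rank test (tie-corrected, chi-square reference) across
subtypes.  All tests are two-sided and no multiple-testing correction is
applied — the analyses are few and pre-specified.

Probability plots use plotting positions `j/(n+1)` and the discrete ppf
(smallest support value whose CDF reaches the position) as the
theoretical quantile.

### Scope of the size sample

Whether "array size of a group" means one count per system (the
cas-proximal array) or every array on the group's replicons is genuinely
ambiguous in survey practice; both are supported via `size_scope`
('proximal', the default, or 'all').  Proximal scope is the default
because it keeps one observation per system, avoiding double-weighting
replicons that carry many arrays.

## Position analysis

Start coordinates map to `((start/length) × 360) mod 360 ∈ [0, 360)`; a
start equal to the replicon length wraps to 0.  Polar histograms round
half-up to integer degrees (359.5+ wraps to bin 0); rounding is for
display only.  The uniformity test uses the *unrounded* positions:
one-sample K-S of degrees/360 against Uniform(0, 1) (scipy's exact/
asymptotic two-sided p).  This statistic is anchored at the deposited
sequence start, which is biologically arbitrary; it is not invariant under
rotation of all positions, a definitional property of the K-S test rather
than a bug.  A rotation-invariant circular test (Kuiper) is a deliberate
non-goal here, since the K-S form is the one this framework standardizes
on.  Groups with fewer than `min_group_n` (default 30) positions are
flagged `underpowered`: their large p-values reflect scarce data, not
evidence of uniformity.

## Multiplicity analysis

Only replicons with exactly one cas operon enter the multiplicity stage,
making "the proximal array" unambiguous.  A proximal array that ties the
replicon maximum counts as largest (inclusive comparison).  Spearman's rho
is computed by the difference-of-ranks formula when ranks are unique and
by the rank-average Pearson generalization under ties; the output records
which path was taken.  A constant variable is defined to have rho 0 (no
monotone association) rather than NaN.

Two variants are reported because they answer different questions:

* `aggregated_proportion` (default): rho between the array count m and
  the largest-proximal proportion across the multiplicity curve.  Note
  that under i.i.d. array sizes this proportion is *intrinsically*
  decreasing in m (one particular array is the inclusive maximum of m
  with probability ≈ 1/m), so a negative aggregated rho alone does not
  demonstrate a proximity effect — its steepness does.
* `per_genome`: rho between m and the proximal array's spacer count
  across individual replicons.  This variant is null when sizes do not
  depend on multiplicity, and is therefore the right null check for an
  unbiased generator.

## Synthetic-data generator

The generator emulates annotation *tables*, not sequences.  Defaults are
the study-scale conditions: 811 genomes; replicon lengths uniform on
1.5–6 Mb; spacer counts geometric with p = 0.025 truncated below at 1
(annotated arrays have at least one spacer); operon count 1 with mass
0.82, else 2; array count per replicon with weights 0.50/0.25/0.12/0.08/
0.05 on 1–5 (most genomes carry one array, with a decreasing tail);
subtype mix 0.24/0.21/0.29/0.13/0.13 over I-B/I-C/I-E/I-F/Type III,
reflecting the relative abundance of the well-represented Class 1 groups;
5% questionable decoys and 5% plasmid replicons to exercise the filters;
strands equiprobable.

Truncation uses memorylessness (`X | X ≥ m ~ m + X`), which is exact and
vectorized.  Truncation at 1 raises the mean from `(1−p)/p = 39` to 40 at
p = 0.025, biasing p̂ recovery downward by ≈ 0.0006 — quantified and well
inside the recovery tolerance; `min_spacers=0` gives the untruncated mode
for calibration work.

Positions follow either a uniform model or a clustered one: a fraction
`cluster_mass` of points lands uniformly within `cluster_width_deg` of
`cluster_center_deg` (wrapping across 0/360), the rest uniformly on the
circle.  The uniform-window mixture is simpler than a wrapped normal and
produces exactly the sector-like concentration the uniformity test is
meant to detect.  The cas-proximal array is placed adjacent to its operon
(50–2000 bp gap) at a model-drawn position, so clustered configurations
cluster the proximal arrays too.  Features are placed without overlap by
rejection sampling with a 200-retry cap; exhaustion raises an error
naming the replicon.

The proximal-size bias shrinks the *mean* of the proximal array's size
distribution by `(1 + bias)^(m−1)` on a replicon with m arrays (bias 0 is
an identity).  This is the generative mechanism behind the negative
multiplicity-size association; sweeping it produces a monotone decrease in
the largest-proximal proportion, verified over fixed seeds.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic non-independence between genomes
(heavily resequenced pathogens), spacer loss in blocks, correlation
between array size and replicon length, operon-array strand coupling, and
real CRISPRdb annotation noise.  Results on synthetic data validate the
*machinery*, not any biological claim.

## Numerical and interface choices

* All randomness flows from `numpy.random.default_rng` seeds; simulation,
  bootstraps, and the report are byte-reproducible per seed.  The report
  derives per-group bootstrap seeds from one root `SeedSequence`.
* Geometric p = 1 (all-zero sample) and Poisson λ = 0 are handled as
  exact point masses.
* The group hierarchy in reports is Class 1 → {Type I, Type III} →
  {I-B, I-C, I-E, I-F}; other Type I subtypes pool into "other" and are
  excluded from subtype-level tests.
* The command-line stages (`size-fit`, `location`, `multiplicity`,
  `report`) share one pipeline runner, so every stage command emits a
  consistent, complete output set; exit codes follow click's convention
  (2 usage, 1 data error).
* Reported problem sizes in `scripts/acceptance.py` (200 Monte-Carlo
  replicates for calibration, 50 for selection/recovery, 400-genome
  pipelines) were chosen as the smallest sizes at which the binomial or
  Monte-Carlo error of each quantity is comfortably below the property
  being demonstrated.

## Known limitations

* The uniformity test treats the circle as an anchored interval (see
  above); genuinely circular alternatives are out of scope.
* The bootstrap GOF p-value has resolution 1/(n_boot+1).
* Spearman variants at small curve sizes (few distinct array counts) rest
  on very few ranks; the per-genome variant is more stable and both are
  always reported.
* No negative-binomial or birth-death size models, no censoring or
  truncation corrections beyond the generator's explicit min-spacer
  truncation, and no origin-of-replication normalization.
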