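# Methods

## The analysis model

The unit of observation is one scored fin ray. Rays of a fin form an
ordered linear array indexed 1..K; adjacency means a ray-index difference
of exactly 1 within the same fin, never across fins or fish, with no
wraparound — a boundary ray has a single neighbor. All statistics in the
package are functions of this 1-D adjacency structure and of binary
regeneration calls; there is no 2-D fin geometry and no image-derived
quantity anywhere in the pipeline.

### Eligibility

Two filtered sets feed the statistics (`EligibilityConfig` defaults):

* **Non-injured analysis set** — rays with no experimental injury, not
  escapers, and with no immediate neighbor that is an escaper,
  re-amputated, or epidermally wounded. Excluding the flanks of injured
  rays keeps wound-induced bystander growth out of the "spontaneous"
  regeneration frequency. Skin wounds are *not* in the default adjacency
  exclusion set; in the experimental design they are inflicted in the
  skin distal to the ray, and the flanking rays were not excluded from
  the corresponding analysis — the set is configurable for other designs.
* **Bystander-quantification set** — additionally drops rays whose
  epidermis or bone was inadvertently damaged, and (by default) rays that
  themselves regenerated next to another regenerating ray. The protocol
  sentence defining this set is grammatically ambiguous about whether
  such rays are excluded or are the very objects being counted; we take
  the literal exclusion as the default and expose the alternative via
  `exclude_bystander_growers=False` rather than guessing intent.

Escapers — uninjured rays that grew when the regeneration blockade was
relieved, i.e. were never fully blocked — can be re-derived from any
boolean growth column with `flag_escapers`; injured rays are never
flagged.

### The isolated-regenerator statistic and its null

Regeneration over the non-injured analysis set is coded 1/0. A 1 is
*isolated* ("010") when every existing neighbor is 0; the isolated
frequency is isolated ones over total ones, and the bystander fraction
its complement. The permutation null re-arranges the observed multiset
of n₁ ones and n₀ zeros uniformly at random, N = 10 000 iterations by
default, and the one-sided p-value is P = (r+1)/(N+1) with r the number
of iterations whose isolated frequency is *strictly* below the observed
one. Ties do not enter r and are reported separately; this is the
conservative literal reading of the formula, and with frequencies that
are ratios of small integers exact ties do occur.

Two layout conventions interact here and both are configurable:

* the **observed** statistic respects fin boundaries by default
  (`observed_respect_blocks=True`) — biologically, a ray at the edge of
  a fin has one neighbor;
* the **null** pools all eligible rays into one flat list by default
  (`mode="pooled"`), which is the published shuffling procedure; a
  stratified mode shuffles within fins, preserving per-fin one-counts.

The default pairing (block-respecting observed, pooled null) makes the
test slightly conservative: a boundary 1 can only *gain* isolation when
blocks are respected, so the observed frequency is biased upward
relative to the pooled null and the measured type-I error sits below the
nominal level (0.02–0.03 at α = 0.05 in the simulations below). We keep
it because it errs against the clustering claim being tested.

The exact null expectation of the isolated frequency under uniform
pooled arrangement has the closed form

    E[freq] = n₀(n₀ + 1) / (n(n − 1)),  n = n₀ + n₁,

obtained by summing, over positions, the exchangeable probability that a
position holds a 1 with all existing neighbors 0 (ends:
n₁n₀/(n(n−1)); interior: n₁n₀(n₀−1)/(n(n−1)(n−2))) and dividing by n₁.
A single 1 with no zeros is isolated by convention (no neighbors exist).
This expectation is computed with exact rational arithmetic and serves
as an analytic cross-check on the permutation engine, never as a
substitute for it; the permutation distribution remains the inference.

The permutation engine draws each arrangement by ranking i.i.d. uniforms
(`argpartition` of one random matrix row per iteration), processed in
fixed-size batches from a single seeded `numpy` generator, so identical
seeds give bit-identical null distributions regardless of iteration
count splits.

### Group comparisons

Regeneration fractions per injury group are compared against the
eligible non-injured rays in 2×2 tables with the plain Pearson
chi-square (df = 1); Yates' correction is available but off by default
since the published comparisons state only a chi-square test. Tables
with a zero margin raise a degenerate-table error rather than returning
NaN. Fractions are kept at full precision; rounding happens only at the
reporting layer.

## The synthetic-data generator

`simulate_dataset` emulates the study design, not fin biology: per fish
one fin of `rays_per_fin` rays (default 18, a typical principal-ray
count); `injuries_per_fish` injuries (0–2, default 1) placed uniformly
at random and mutually non-adjacent when possible; injured rays
regenerate with `p_injured_regen` (default 0.74, the observed 7-d.p.i.
induction rate for epidermal wounds); uninjured rays regenerate
spontaneously with `p_spont` or, failing that, are escapers with
`p_escaper` (default 0.03). Escapers grow from day 0 and act as
contagion sources — that ordering is what makes the escaper-adjacency
control informative, since the question it answers is whether growth
per se, not covert injury, induces neighbors. Then `spread_rounds`
synchronous contagion passes (default 1, the minimal mechanism that
produces neighbor enrichment) convert each silent ray with at least one
regenerating neighbor with probability `p_bystander`. `regen_3dpi`
records the seed state, `regen_7dpi` the post-spread state, so bystander
conversion is a late call, as in the scoring timeline.

Calibration: with one round of spreading, defaults `p_spont = 0.11` and
`p_bystander = 0.80` put the marginal regeneration frequency of the
eligible non-injured set at 0.259 (measured once on a 2 000-fish
simulation) — matching the ~0.258 frequency of the study's pooled
non-injured list — with a bystander share of ~94–95% of regenerators,
matching the reported 95%. These defaults were fixed by that one-off
calibration and are not adjusted per analysis.

What the generator deliberately omits: longer-range induction (contagion
is strictly nearest-neighbor; the real spatial range of the wound signal
is unquantified), any mechanistic FGF/Wnt signalling dynamics,
fish-level heterogeneity in spontaneous rates, and inadvertent-injury
events (the flag exists in the data model but the generator leaves it
false). Passing tests therefore show that the pipeline is correct under
a homogeneous nearest-neighbor contagion world, not that real fins obey
that model.

## Operating characteristics

`sweep_power` simulates datasets over a parameter grid and reports the
fraction rejected at a threshold. At desk scale (20 fish, 1 000
permutation iterations, 200 replicates): with contagion off and the
spontaneous rate set to the study marginal, the rejection rate at
α = 0.05 is 0.02–0.03 — within the binomial band around the nominal
level, on the conservative side for the reason above; with
`p_bystander = 0.8` and the default seeding density the rejection rate
is 1.0. Replicates on which the statistic is undefined (no regenerating
eligible ray) count as non-rejections and are tallied separately. These
problem sizes (and the 10^5-shuffle enumeration checks on lists of
length ≤ 8) were chosen as the smallest scales at which the binomial and
Monte Carlo error bands are informative.

## Numerical conventions and degenerate inputs

* Statistics that are ratios (isolated frequency, bystander fraction,
  regeneration fraction, association rate) raise
  `UndefinedStatisticError` on empty denominators instead of returning
  NaN; callers that sweep simulations handle it explicitly.
* Booleans serialize as 0/1 and injury classes as fixed lower-case
  names, keeping tables locale-independent; unknown extra columns
  round-trip untouched (absent extras resurface as empty strings) but
  are invisible to the analysis.
* Ray indices are 1-based and must be contiguous per fin — a gap would
  make adjacency ambiguous, so it is a hard validation error, reported
  with the offending fin.
* All randomness flows from one seeded generator per operation;
  `sweep_power` spawns child seeds via `numpy.random.SeedSequence` so
  grid points are independent and reproducible.

## Known limitations

* The pooled default null ignores fin boundaries — faithful to the
  published procedure, but a simplification; the stratified mode exists
  precisely because of it, and the two agree closely when fins are long.
* The test is one-sided toward clustering; dispersion (fewer bystanders
  than chance) yields p near 1 by design.
* Only 2×2 contingency comparisons are provided; the published
  comparisons are pairwise and no multi-way or exact test is offered.
* The contingency comparisons and the permutation test treat rays as
  independent sampling units within groups, as the original analysis
  does; no fish-level random effect is modelled.
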