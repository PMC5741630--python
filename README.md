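# finray

Adjacency statistics and Monte Carlo permutation tests for zebrafish
fin-ray regeneration score tables.

## The problem

In fin regeneration experiments, each bony ray of a fin is scored as
regenerating or not at fixed timepoints. When regeneration of a fin is
experimentally blocked and individual rays are then re-injured,
neighboring *non-injured* rays often start growing too — *bystander
regeneration*, consistent with wound signals spreading locally along the
fin. The statistical question is whether regenerating non-injured rays
cluster next to each other more than chance placement would predict.

`finray` is for labs that produce per-ray score tables (one row per ray:
fish, fin, ordered ray position, injury class, escaper flag,
regeneration calls at 3 and 7 days post-injury) and want the complete
analysis pipeline: eligibility filtering, group comparisons, and the
spatial permutation test — plus a generative model to validate the test.

## The statistic and its null

Regeneration over the eligible non-injured rays is binary coded (1 =
growth). A 1 is an **isolated regenerator** ("010") when every existing
neighbor is 0; the **isolated frequency** is isolated ones / total ones,
and the **bystander fraction** is its complement. With the observed
multiset of `n₁` ones and `n₀` zeros, each of `N` Monte Carlo iterations
re-arranges the list uniformly at random and records the isolated
frequency. With `r` = number of iterations whose null frequency is
strictly below the observed one,

    P = (r + 1) / (N + 1).

Clustering drives the observed isolated frequency *below* the null, so
small `P` means more bystander structure than chance. The package also
provides the exact closed-form null expectation
`E[freq] = n₀(n₀+1) / (n(n−1))` (derived by exchangeability; used as an
analytic cross-check of the permutation engine), a stratified
(within-fin) null variant, per-group regeneration fractions, and 2×2
Pearson chi-square comparisons.

## Worked example

```python
import finray as fr

# simulate a study-like experiment: 61 fish, 18 rays per fin, one
# epidermal wound per fish, neighbor contagion switched on
dataset, truth = fr.simulate_dataset(fr.SimParams(seed=1))

model = fr.BystanderRegenerationTest(dataset)   # or .from_table("rays.tsv")
results = model.fit(iterations=10_000, seed=1)
print(results.summary())
```

```
Bystander regeneration analysis
================================================================
dataset label        : simulated
outcome field        : regen_7dpi
eligible non-injured : 865 rays, 241 regenerating (fraction 0.2786)

Group regeneration fractions
----------------------------------------------------------------
  non_injured_eligible      241/865  = 0.279
  epidermal_wound            47/61   = 0.770

Chi-square comparisons vs eligible non-injured rays
----------------------------------------------------------------
  epidermal_wound          chi2 =   64.337  df = 1  p = 1.05e-15

Monte Carlo permutation test of isolated-regenerator frequency
  null mode                 : pooled
  iterations (N)            : 10000
  observed isolated freq    : 0.0498
  implied bystander fraction: 0.9502
  null mean (s.d.)          : 0.5224 (0.0377)
  r (null < observed)       : 0   ties: 0
  p = (r+1)/(N+1)           : 9.999e-05
  closed-form null mean     : 0.5218
```

Reading the output: of 865 analyzable non-injured rays, 27.9%
regenerated, but only 5.0% of those regenerators were isolated — 95.0%
grew next to another regenerating ray. Under random placement the
isolated frequency would sit near 0.52, so no null iteration fell below
the observed value and the test returns its minimal p-value, 1/10 001:
strong evidence of spatial clustering. The wounded rays regenerated far
more often (77.0%) than non-injured ones, confirmed by the chi-square
comparison.

The same pipeline is scriptable:

```sh
finray simulate --n-fish 61 --seed 1 --out sim/
finray analyze --input sim/rays.tsv --iterations 10000 --seed 1 --out report/
finray mc-test --ones 142 --zeros 409 --observed 0.05 --iterations 10000 --seed 1
```

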