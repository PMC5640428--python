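# Methods

Statistical model, parameter defaults and design decisions for the
`baitprey` package. Notation: SpC = spectral counts (peptide-spectrum
matches) for one prey in one purification; bait/control channels are the
specific-antibody and control purifications of one replicate.

## Enrichment scoring

**Fold enrichment.** For prey *i*,
`fold = (SpC_bait + c) / (SpC_control + c)` with pseudocount `c = 1.0`
(default). The pseudocount bounds the ratio when the control count is zero
and shrinks ratios computed from very small counts. Totals are summed over
all purifications before the ratio is taken.

**NSAF.** Normalized spectral abundance factor,
`NSAF_i = (SpC_i / L_i) / Σ_j (SpC_j / L_j)`, with `L` the protein length.
NSAF values sum to 1 over the preys of a purification by construction; this
is tested as a property.

**MaxP.** Each replicate's bait-channel count `k` is modeled as a
two-component Poisson mixture: background `Poisson(λ_bg)` versus true
interaction `Poisson(f·λ_bg)` with enrichment factor `f > 1` and prior
`π = 0.5`. The posterior

```
P(true | k) = π·Pois(k; f·λ_bg) / [π·Pois(k; f·λ_bg) + (1−π)·Pois(k; λ_bg)]
```

is computed in log space for numerical stability, and **MaxP** is the
maximum posterior across replicates. λ_bg is estimated per prey as its mean
control-channel count per control purification, floored at 0.1 so preys
never seen in controls still receive a proper background rate. MaxP is
monotone non-decreasing in `k` (tested by property and used as an
acceptance invariant).

## Two-pass filtering

- **First pass:** admit preys with `unique_peptides ≥ 2` and
  `fold ≥ 1.5`.
- **Second pass (rescue), precedence a → b → c, first match recorded:**
  - (a) prey appears in the curated literature-partner list;
  - (b) prey's protein family contains a first-pass member. Families come
    from an explicit member→family map when supplied; otherwise a logged
    heuristic strips trailing digits from the gene symbol (ATP1A2 → ATP1A).
  - (c) *single-peptide* recurrence: `unique_peptides_max == 1` and the
    prey was seen in ≥ 2 antibody/age conditions or ≥ 2 replicates. The
    single-peptide gate is essential: without it, every background prey
    observed in two replicates would be rescued and the rescue stage would
    be vacuous. Rescue exists to save real single-peptide interactors, so
    the gate restricts criterion (c) to that population.
- **Contaminant removal:** preys in the contaminant list with occurrence
  frequency ≥ 0.5 (default threshold) are removed; a listed contaminant
  with no stated frequency is treated as frequency 1.0 (conservatively
  always removed).

**Tiers.** Platinum: replicate presence ≥ 2, fold ≥ 5 and MaxP ≥ 0.89.
Gold: fold ≥ 5 and MaxP ≥ 0.89 without the replicate evidence. Silver:
fold ∈ [3, 5) and MaxP ∈ [0.7, 0.89). Bronze: everything else admitted.
Literature-only members carry the tier `NA_LITERATURE`. The merge with the
31-member literature list deduplicates case-insensitively on
accession/symbol.

## Annotation mapping

Synapse category is EXCITATORY_ONLY / INHIBITORY_ONLY / BOTH / NEITHER,
resolved either from per-member ES/IS flags or from membership in named
excitatory/inhibitory proteome sets (union over sets; set naming is
irrelevant). Developmental category is P5_ONLY / P50_ONLY / SHARED from the
age flags; partitions are checked to be exhaustive and disjoint, and
percentage summaries must sum counts to the stated total.

## Network statistics

Built on `networkx`. The clustering statistic is the mean of local
Watts–Strogatz coefficients with degree-< 2 nodes counted as 0 and included
in the mean by default (`count_low_degree=False` excludes them). This
convention choice matters — published interactome clustering values often
use a different (e.g. Cytoscape) convention — which is why no exact
clustering value is an acceptance target; instead the implementation is
verified against O(k²) brute-force triangle enumeration on random graphs.
Self-loops are rejected; duplicate edges collapse to one undirected edge
whose `provenance` attribute is the union of sources.

## Electrophysiology statistics

**IV regression.** Ordinary least squares of peak IPSC amplitude on holding
potential (`scipy.stats.linregress`): the abscissa intercept `−b/m` is
E_GABA and the slope `m` the synaptic conductance. Signed amplitudes are
the default; an `use_absolute` flag fits |amplitude| for data reported as
magnitudes (meaningless when the points straddle the reversal, where
|amplitude| is V-shaped — tested). Zero slope raises `NoReversalError`.

**Pooled t from summaries.** Published comparisons report mean ± SEM and
n per group with df = n₁ + n₂ − 2, which identifies the pooled-variance
(Student) two-sample t-test. With `sd = sem·√n`:

```
s² = [(n₁−1)sd₁² + (n₂−1)sd₂²] / (n₁+n₂−2)
t  = (m₁ − m₂) / (s·√(1/n₁ + 1/n₂)),  two-sided p from t(df)
```

This reproduces the three packaged reference comparisons to within 2%
relative tolerance (the residual is rounding of the printed summaries) and
is exactly equal to `scipy.stats.ttest_ind(equal_var=True)` on raw data.

## Synthetic data generator

Seeded (`numpy.random.default_rng`) Poisson count simulator. Defaults:
50 true interactors, 200 background preys, 10 contaminants; 3 antibodies ×
2 ages × 3 replicates, each with a bait and a control purification;
`λ_bg = 3.0`, `enrichment_factor = 10`, true-prey detection probability
0.95, 10% of true preys forced single-peptide, contaminants at rate
`5·λ_bg` in *both* channels with listed frequency 0.8. Optional
negative-binomial overdispersion replaces the Poisson draws.

λ_bg = 3.0 was fixed analytically before any end-to-end testing: with the
default pseudocount, a background prey needs roughly 1.5× its expected
total to clear the first-pass fold threshold, and at λ_bg = 3 per channel
observation the probability of that fluctuation across the default design
is ≈ 1.9% (Monte-Carlo of the Poisson tail), comfortably inside the ≤ 5%
admission budget, whereas λ_bg = 2 sits at ≈ 4.7%, too close to the
boundary for a stochastic acceptance test. It was not tuned against
pipeline runs.

Ground truth records the planted id sets (disjoint by construction),
per-prey bait rates, the forced single-peptide ids, contaminant
frequencies, and a singleton family map (simulated preys have no family
structure, so family rescue is inert on synthetic data by design).

## Fixture caveat

The packaged partner table is a **verbatim transcription**: 2 bait rows
plus 149 prey rows. The source table's surrounding text claims 150
partners and a developmental split of 85/41/24 (sum 150), while the rows
themselves partition 83/42/24 (sum 149). The inconsistency is internal to
the source; no row was invented or edited to force agreement. The two
acceptance tests asserting the headline counts therefore fail, and the
acceptance script reports the transcribed values (149 partners, 180 after
the literature merge, 83/42/24).

## Limitations

- The MaxP model is a deliberately simple two-component Poisson mixture,
  not a full SAINT implementation (no abundance-dependent background, no
  Bayesian λ estimation).
- The literature list is mostly synthetic placeholder membership; only the
  merge arithmetic, not the biology, is meaningful.
- Synapse-proteome reference sets are not packaged; flag-based
  categorization on the fixture uses the table's own ES/IS columns.
- Network statistics depend on the stated clustering convention; values
  computed under other conventions will differ.
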