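# baitprey

Construction and statistical validation of a bait–prey interactome from
affinity-purification mass spectrometry (AP-MS) data, modeled on a
developmental screen for partners of the neuronal K⁺/Cl⁻ cotransporter KCC2.

## The scientific problem

AP-MS screens pull down a bait protein together with hundreds of candidate
prey proteins, most of which are background binders or recurrent
contaminants. Building a credible interactome therefore requires:

1. **Enrichment scoring** — per-prey fold enrichment of bait-channel versus
   control-channel spectral counts (with a pseudocount), NSAF abundance
   normalization, and a SAINT-style *MaxP* confidence score: the maximum
   across replicates of the posterior probability of true interaction under
   a two-component Poisson mixture (background rate λ versus an enriched
   rate *f*·λ).
2. **Two-pass filtering** — a first pass requiring ≥ 2 unique peptides and a
   minimum fold enrichment; a second pass that *rescues* single-peptide
   candidates that (a) are literature-validated partners, (b) share a
   protein family with a first-pass member, or (c) recur across ≥ 2
   antibody/age conditions or replicates; then removal of preys that appear
   at high frequency in a contaminant-repository list (CRAPome-style).
3. **Confidence tiering** — Platinum/Gold/Silver/Bronze from fold
   enrichment, MaxP and replicate presence; merge with a curated literature
   partner list.
4. **Annotation mapping** — partition of the interactome by excitatory- and
   inhibitory-synapse proteome membership, and by developmental stage
   (P5-only / P50-only / shared).
5. **Network statistics** — average local clustering coefficient and mean
   neighbor count of the interactome graph and induced subnetworks.
6. **Functional validation statistics** — E_GABA and synaptic conductance by
   linear regression of IV curves, and pooled two-sample t-tests computed
   directly from printed (mean ± SEM, n) summaries.
7. **Synthetic data** — a seeded Poisson count simulator with planted true
   interactors, background and contaminants, used to measure the pipeline's
   sensitivity and false-admission rate against known ground truth.

## Quick start

Run the full pipeline on simulated data from a YAML config:

```sh
cat > demo.yaml <<'EOF'
simulate:
  n_true_interactors: 20
  n_background: 100
  n_contaminants: 5
seed: 7
EOF
interactome run --config demo.yaml --out demo_out
```

Actual output:

```
              stage  n_in  n_out
         enrichment   125    125
         first_pass   125     19
        second_pass    19     21
contaminant_removal    21     21
   literature_merge    21     52
report bundle -> demo_out
```

`demo_out/` contains `interactome.tsv` (tiered members with provenance and
rescue reasons), `stage_counts.tsv`, partition summaries and `run.log`.
Here 20 of 20 planted true interactors are recovered (19 in the first pass,
1 single-peptide prey rescued by the multi-condition criterion), no
background or contaminant prey is admitted, and the literature merge adds
the 31 curated partners.

A t-test from printed summaries (the whole-cell E_GABA comparison):

```sh
$ interactome ttest --group1=-28.62,3.07,9 --group2=-37.86,1.73,11
t(18) = 2.747, p = 0.01325
```

Other subcommands: `interactome simulate`, `score`, `filter`, `map`,
`netstats`, `iv`. Each is a thin wrapper over the `baitprey` library; see
`interactome <cmd> --help`.

## Library example

```python
from baitprey import (
    FilterConfig, PipelineConfig, SimulationConfig, run_pipeline,
)

bundle = run_pipeline(PipelineConfig(simulate=SimulationConfig(), seed=1))
print(bundle.stage_counts)
print(bundle.tier_counts)
```

## Packaged fixtures

- `baitprey/data/table1_kcc2_partners.tsv` — a verbatim transcription of a
  published KCC2 partner table (2 bait rows + 149 prey rows) with fold
  ratios, MaxP scores and annotation flags. The source table's own headline
  counts are internally inconsistent with its rows; the transcription keeps
  the rows as printed (see `docs/methods.md`).
- `baitprey/data/literature_partners_synthetic.tsv` — a 31-member
  literature-partner list. Membership beyond a few well-known partners is
  synthetic and serves only to exercise the merge logic.

## Testing and reproducing the results

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

The suite holds unit, property-based (hypothesis) and acceptance tests.
Two acceptance tests (`test_criterion_1_fixture_counts`,
`test_criterion_2_developmental_partition`) fail **by design**: they assert
the published headline counts (150 partners; 85/41/24 developmental split),
which the published table's own rows do not reproduce (149 rows; 83/42/24).
The fixture is transcribed verbatim rather than edited to match.

The acceptance metrics script writes all headline numbers as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All simulation and scoring randomness flows from explicit seeds
(`numpy.random.default_rng`); identical seeds give byte-identical outputs.
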