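# Example run configuration for `phylolex infer` / `phylolex mlcompare`.
#
# Generate the matching input first:
#   phylolex simulate --seed 1 --n-concepts 40 --root-age 6 --out-prefix sim
# then copy the tip dates from sim.truth.yaml into data.tip_dates below
# (extinct languages must sit at their last-seen ages), and run
#   phylolex infer examples/run_config.yaml

seed: 1
output_dir: out

data:
  cognates_csv: sim.csv        # columns: language,concept,cognate_class,is_loan
  tip_dates: {}                # language -> age in ka BP (0 = extant)
  exclude: []                  # taxa dropped before curation

model:
  kind: m1p+CV                 # m1p | m1p+G4 | m1p+CV
  gain: 1.0                    # initial values; all rates are sampled
  loss: 1.0
  switch_on: 0.5
  switch_off: 0.5
  normalize: true              # unit expected substitution rate

ascertainment: false           # correct for unobservable all-absent columns

clock:
  kind: relaxed-lognormal      # strict | relaxed-lognormal
  clock_rate: 0.2              # substitutions per ka (initial value)
  mu: 1.0                      # real-space mean of branch multipliers
  sigma: 0.1                   # log-space stdev

fbd:
  birth: 0.8                   # lineage birth rate per ka (initial)
  death: 0.2
  psi: 0.1                     # serial sampling rate (extinct languages)
  rho: 0.8                     # extant sampling proportion (initial)

priors:
  transition_rate_mean: 10.0   # Exp prior mean on gain/loss
  clock_rate_mean: 1.0
  root_age_mean: 10.0          # Exp prior on the root age, in ka

calibrations:
  # extinct tips pinned at their last-seen dates
  # - {type: tip_date, taxon: Old_Chinese, age_ka: 2.2}
  # clades no younger than their earliest historical record
  # - {type: mrca_min_age, taxa: [Lang_A, Lang_B], min_age_ka: 1.3}
  []

constraints:
  # - {taxa: [Sinitic_1, Sinitic_2], outgroup: true}
  []

mcmc:
  chain_length: 200000
  burn_in: 40000
  sample_every: 400
  n_chains: 1

stepping_stone:                # used by `mlcompare`
  steps: 30
  shape: 0.3
  samples_per_step: 1000

clades: {}                     # named taxon sets for `summarize`
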