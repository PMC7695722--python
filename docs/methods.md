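# Methods

This note records the models implemented in `phylolex`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic-data experiments do and do not demonstrate.

## Data model and binarization

A `CognateDataset` maps (language, concept) to a set of cognate-class
labels; labels are scoped per concept, may be flagged as loans, and a pair
may be absent entirely (missing datum). Curation operations:

- `exclude_taxa` drops languages before analysis (duplicate names in the
  exclusion list are an error — they usually indicate a curation typo).
- `remove_loans` deletes loan-flagged classes. A cell whose only classes
  were loans becomes **missing**, not absent: the native word is unknown,
  and coding 0 would assert a loss that was never observed.
- `multistate_to_binary` emits one 0/1/? column per (concept, class)
  attested anywhere. A language missing a concept gets `?` in every column
  of that concept; downstream, `?` is a partial-likelihood vector of ones.
  Synonyms (two classes in one language) simply put 1 in two columns of
  the same concept. Column order is deterministic — concepts in input
  order, classes by first attestation — so NEXUS exports are reproducible.
  Singleton columns (classes attested by exactly one language) are
  retained; no frequency filter is applied.

Binarization is information-conserving for loan-free data: the set of
1-columns of a language within a concept equals its class set, which the
tests assert on simulated data.

## Substitution models

The two-state generator is Q = [[−a, a], [b, −b]] with stationary
frequencies (b, a)/(a+b). The binary covarion wraps it in a hidden on/off
switch (Tuffley–Steel form): states (0·on, 1·on, 0·off, 1·off), visible
changes at rates a, b only in the "on" block, switching at s₁ (off→on)
and s₂ (on→off) without visible change, and a frozen "off" block. The
root distribution is the full four-state stationary distribution
(product of the switch and visible stationaries). An alternative covarion
variant with separate hidden-frequency parameters exists in the
literature; the two-switch-rate form was chosen as the canonical
parameterization, and the switch rates are free parameters with Exp(1)
priors, so the stationary on-fraction is inferred.

**Normalization.** By default generators are rescaled so the expected
*visible* substitution rate at stationarity is 1 (m1p: 2ab/(a+b);
covarion: that times π_on = s₁/(s₁+s₂)). This makes the clock rate
interpretable in expected substitutions per ka and decouples it from the
overall scale of (a, b), which then matters only through its ratio. The
flag is exposed (`normalize=False`) because oracle tests compare against
unnormalized closed forms.

**Gamma heterogeneity** uses k = 4 equal-probability categories
represented by their category means under Gamma(α, α) (computed in closed
form from the regularized incomplete gamma function), renormalized to
mean exactly 1. Means, not medians, are the default convention; the exact
outer-category mean sits ~1.27/√α away from 1, which is the asymptotic the
degenerate-limit test asserts.

**Ascertainment.** Cognate collections cannot contain all-absent columns,
so a correction subtracting n_sites · log(1 − P(all-absent)) is
implemented, but it is **off by default**: whether the original analyses
of this kind corrected for ascertainment is generally unstated, and the
default mirrors the uncorrected likelihood. It is a config switch.

## Likelihood engine

Felsenstein pruning over compressed site patterns, all patterns
propagated simultaneously as (n_patterns, n_states) arrays. Transition
matrices come from a cached spectral decomposition: both generators are
reversible, so the symmetrized generator D^{1/2} Q D^{−1/2} is
diagonalized once per parameter setting with `eigh`, and P(t) needs two
small matrix products (negative round-off entries are floored at zero;
errors are ~1e−15 and the enumeration oracle agrees to 1e−10 or better).
Per-node rescaling is engaged only when the unscaled pass underflows
(detected at the root); desk-scale trees never trigger it, and a
1200-tip caterpillar test exercises the scaled path. Under gamma, the
per-pattern likelihood is the equal-weight average of category
likelihoods computed in log space.

## Tree prior

The FBD density uses the standard helper functions
c₁ = |√((λ−μ_d−ψ)² + 4λψ)|, c₂ = −(λ−μ_d−2λρ−ψ)/c₁ and
q(t) = 4e^{−c₁t}/(e^{−c₁t}(1−c₂) + (1+c₂))². Serial (ψ) sampling removes
the lineage — appropriate for a language observed at its last-seen date
and extinct thereafter — so there are no sampled ancestors. Conditioning
is on the root age with at least one sampled descendant on each side
(division by (1−p₀(root))²); origin-time conditioning is not implemented.
The edge-telescoping factorization gives, for n extant and m extinct
sampled tips,

log f = (n+m−2)·log λ + m·log ψ + n·log ρ + 2·log q(x₁)
      + Σ_internal log q(xᵢ) − Σ_extinct log q(yⱼ) − 2·log(1−p₀(x₁)),

which reduces exactly to the Yule density λ^{n−2} e^{−λL} when
μ_d = ψ = 0, ρ = 1 (a frozen oracle test), and is validated against
conditioned forward simulation by a Kolmogorov–Smirnov test on root ages.

**Root-age prior.** Conditioned on the root age, the FBD term alone
leaves the root-age marginal implicit. `PriorSpec` therefore carries an
explicit root-age prior (default Exp(mean 10 ka), settable to `None` for
a flat improper prior). This makes prior-only sampling a well-defined
target that forward simulation can match exactly — the sampler
correctness check draws the root age from the same prior on both sides.

**Hard calibrations.** Extinct-tip dates are fixed observations;
minimum-MRCA ages are indicator priors (the historical record gives
"no later than" statements, not distributions — soft calibration
densities are deliberately out of scope). Monophyly and outgroup
constraints are likewise indicators: proposals may violate them but score
−∞. Actual calibration values for any real analysis are user-supplied
through the config; synthetic fixtures carry their own.

Default hyperpriors where nothing else is specified: Exp(mean 10) on the
transition rates a, b; Exp(mean 1) on s₁, s₂, α, the clock rate, λ, μ_d
and ψ; ρ ~ Uniform[0, 1]. All means are config-overridable.

## MCMC

Metropolis–Hastings with a fixed operator suite: uniform node-age slides,
a root-age multiplier, narrow and wide exchanges (rooted-NNI-complete, so
topology space is connected), Wilson–Balding subtree transplants (the
re-rooting variant is omitted; root rearrangements come from exchanges at
the root), multiplier moves (log-uniform factor in [1/κ, κ], κ = 1.5
fixed, log Hastings ratio log f) on every positive scalar, a reflected
random walk on ρ, and single-branch rate-multiplier scales under the
relaxed clock. Default weights: topology ≈ 30%, node ages ≈ 30%,
clock/branch rates ≈ 20%, remaining scalars ≈ 20%. No adaptive tuning —
reproducibility over efficiency at desk scale.

Each chain uses one seeded generator; the chain index offsets the seed.
Moves touching only the tree prior's scalars (λ, μ_d, ψ, ρ) skip the
likelihood recomputation; a debug mode re-derives both cached terms every
N iterations and asserts agreement to 1e−8. Tip dates never move, so
tip-date calibrations are checked once at initialization and dropped from
the per-iteration prior. Burn-in is discarded during the run; chains are
pooled only after an R-hat check.

**Diagnostics.** ESS is n / (1 + 2Σρ_k) with the autocorrelation sum
truncated at the first nonpositive lag; constant series return n
(flagged), and anticorrelated series — whose raw estimator exceeds n —
are capped at n with a warning. R-hat is computed at chain level as
√((W+B)/W) with W the mean within-chain variance and B the variance of
chain means: identical chains give exactly 1, and there is no (n−1)/n
deflation, so R-hat ≥ 1 always. This chain-level form (rather than
split-R̂) was chosen so that duplicated chains are a fixed point; it will
not detect non-stationarity *within* a single chain, which the ESS and
the multi-chain protocol cover in practice.

## Marginal likelihoods

Stepping stone with β-values at Beta(0.3, 1) quantiles of k/K
(concentrating steps near the prior), estimator
log Z = Σ_k log[(1/n) Σᵢ L_i^{β_{k+1}−β_k}] with samples drawn at β_k,
all arithmetic in log space. Each phylogenetic step warm-starts from the
previous step's final state and discards 10% as burn-in. The per-step SE
uses the delta method and ignores autocorrelation, so it is an optimistic
lower bound for MCMC-based samplers (exact for the iid conjugate toy the
tests calibrate against). Bayes factors are reported as log BF = log Z₁ −
log Z₂ with the combined SE — always on the log scale, and labelled as
such, since raw-vs-log reporting is a recurring ambiguity in the
literature.

## Posterior summarization

Clades are keyed by tip sets. The MCC tree is the *sampled* tree
maximizing the sum of log clade frequencies (ties keep the first in
sample order, deterministically); each node is annotated with the clade's
posterior and the mean, median and 95% HPD of that clade's MRCA age
across all trees containing it (common-ancestor heights are not
implemented). Annotated node ages are set to the clade means, which can
in principle produce locally non-monotone ages on weakly supported
nestings — a known property of this annotation style. The HPD is the
shortest contiguous window containing ⌈mass·n⌉ sorted samples, ties
resolved toward the smallest lower bound. `root_split_support` asks
specifically whether a taxon set forms one child of the root — the
outgroup question — which is stricter than clade support.

## Synthetic data generator

`make_cognate_dataset` emulates the structure of a curated
basic-vocabulary dataset: a dated FBD tree (default λ = 0.78, μ_d = 0.2,
ψ = 0.05, ρ = 0.8, root 8 ka — rates chosen so an 8-ka family reaches
the ~131-language scale with a realistic minority of extinct tips), iid
lognormal branch rates, and per concept one ancestral class plus new
classes arising as a Poisson process along branches, each replacing the
carrier's class. Loans copy a donor's class to a non-sister recipient
and are always flagged (real datasets arrive with loans pre-identified —
no loan detection is attempted); synonyms add a second class to one
language (3% of cells by default); cells are blanked at a 5% missing
rate. With `target_classes_per_concept` set, the innovation rate is
scaled to the simulated tree's length (factor 1.08·(target−1)/L,
calibrated once by simulation) so that a 131-language, 110-concept run
yields ~1650 binary cognate sets, stable across seeds — the scale of
real curated datasets of this kind.

What the generator does **not** emulate: dialect-continuum or
wave-model borrowing (loans are tree-arbitrary), meaning shift across
concepts, coding disagreements between linguists, and any geographic
structure. Tests passing on this generator show the inference machinery
is correct and calibrated under the model's own assumptions; they do not
show the model is adequate for any particular real family.

## Validation experiments and problem sizes

All validation quantities are recomputed from scratch by
`phylolex.validation` (shared by the test suite and
`scripts/acceptance.py`):

- covarion pruning vs brute-force enumeration over hidden states, 50
  random 4-taxon dated trees with branch-rate variation (≤1e−10);
- closed forms: analytic two-state P(t), Yule limit of the FBD density,
  lognormal branch-rate prior (≤1e−12);
- prior-only MCMC vs conditioned forward FBD simulation, 5-tip trees,
  2000 samples a side, two-sample KS (this is the end-to-end check of
  every Hastings ratio);
- stepping stone on the Beta(1,1)–binomial(7/10) toy, K = 30 and 5000
  samples/step, against the exact marginal 1/11 (≤0.05 log units);
- root-age recovery: 20 replicates of 10-tip trees (2 extinct tips), 300
  covarion characters (a = b = 1, s₁ = s₂ = 0.5, clock 0.2/ka, strict
  clock, root 8 ka), 100k-iteration chains; the 95% HPD must cover the
  truth in ≥15/20 — the binomial band around nominal 95% coverage. The
  recovery harness uses a flat root-age prior: the true root age is a
  fixed value rather than a draw from the prior, and the extinct tip
  dates identify the time scale, so any decreasing root-age prior would
  bias the posterior downward and the coverage experiment would partly
  measure that prior rather than the sampler;
- MCC selection vs exhaustive clade-product scoring on random 6-tip
  samples, and the HPD window oracle on 1..100.

The replicate counts and chain lengths are the package's chosen
desk-scale study conditions: large enough for the binomial/KS bands to be
meaningful, small enough to run routinely.

## Known limitations

- No multistate (Mk) or stochastic-Dollo likelihoods; only the binarized
  matrix is analyzed.
- No sampled-ancestor trees, no origin-time conditioning, no coalescent
  or skyline priors.
- No soft calibration densities; no Metropolis-coupled chains, adaptive
  operators, or checkpointing beyond seed + iteration restart.
- The clock rate and covarion switch rates lie on a soft identifiability
  ridge at small data sizes (slow switching mimics rate variation); root
  ages remain well calibrated because extinct tips anchor the time
  scale, but per-parameter ESS can be low on short chains.
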