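# Methods

`nebench` is a simulation-and-benchmark toolkit for studying effective
population size (Ne) estimation in large, age-structured, migration-connected
populations — the setting typical of abundant marine fishes such as tunas,
where samples are a tiny fraction of Ne and drift signals are weak.  This
note records the models implemented, the parameters that matter, the
numerical choices, and what the test suite does and does not demonstrate.

## Demographic model

A population is described by per-age vital rates over ages `0..A`
(longevity `A = 15` by default): survival probabilities `s_x` (with
`s_0 = 1`: every newborn recruits to age 1) and relative fertility weights
`b_x` (zero below maturity `α = 4`, increasing linearly with age, as is
typical of teleost fecundity).  Sexes share one schedule and the sex ratio
is balanced.  At demographic equilibrium with a fixed annual cohort of `N0`
newborns the age structure is `N_x = N0 · l_x` with survivorship
`l_x = Π_{i<x} s_i`, giving the per-deme census `K = Σ N_x`.

**Theoretical Ne.**  The per-generation effective size follows the hybrid
Felsenstein–Hill approach for species with overlapping generations:

    Ne = 4 · N1 · T / (Vk + 2)

with `N1` the annual recruits reaching age 1, `T = Σ x·N_x·b_x / Σ N_x·b_x`
the mean parental age, and `Vk` the lifetime variance in reproductive
success of a newborn cohort implied by the rates under multinomial parent
assignment at constant size.  `Vk` is computed semi-analytically: per-step
offspring counts of an individual aged `x` are Poisson with mean
`f_x = 2·b_x / Σ l_y·b_y`, so conditioning on the age at death `D`
(`P(D = x) = l_x (1 − s_x)`),

    E[k] = E[F_D] = 2,   Vk = Var(F_D) + E[F_D],

where `F_x = Σ_{y≤x} f_y`.  A seeded Monte-Carlo cohort simulation
cross-checks this to well under 1%.  In the discrete-generation limit
(`α = A = 1`) the formula collapses to the Wright–Fisher census size.

**Reconstructed default rates.**  The packaged schedule
(`data/default_vital_rates.tsv`, `provenance=reconstructed`) is not a
transcribed life table: it is generated once by
`demography.reconstruct_vital_rates`, which fits a Gompertz hazard
`s_x = exp(−exp(a + c·x))` on ages 1..14 plus a linear fertility offset
`b_x = max(0, x − x0)` to three constraints of the reference population:
2 survivors at age 15 from cohorts of 5000, a stable per-deme census of
17,710, and a theoretical Ne of 3314 per generation.  The solved schedule
has near-flat adult survival (0.62 → 0.53) with mild senescence and
`T ≈ 5.83` years, `Vk ≈ 33.2`.  Any user schedule can be supplied through
the plain-text vital-rates config format, which round-trips bit-exactly.

## Forward simulation

Two demes of identical structure are simulated individual-by-individual.
Each time step applies, in a fixed, documented order: Bernoulli survival by
age; ageing; migration (probability `m` per individual per step, symmetric
deme swap); reproduction.  Each deme recruits **exactly** `N0` newborns per
step; every newborn draws its mother among the deme's mature females and
its father among the mature males, independently, with replacement, with
probability proportional to `b_age` (lottery polygamy; selfing impossible).
Variance in reproductive success therefore enters only through parent
assignment, which is what the theoretical `Vk` assumes.  A Poisson
recruitment option exists but is off by default.  Migration precedes
reproduction so migrants breed in their destination deme.  These orderings
are modelling choices made where the underlying description is silent.

Every individual ever alive is recorded in the pedigree (parents, sex,
birth/death steps, natal deme, migration events).  Serial sampling captures,
per deme, step and age class 1..A, `floor(rate · class abundance)` distinct
living individuals, never recapturing across steps; `floor` and the
no-recapture rule are conservative choices.

**Realized Ne** is computed per birth cohort: lifetime offspring counts
`k_i` (population variance `Vk`, cohort recruits `N1`) plugged into the same
`4·N1·T/(Vk+2)` formula, averaged over complete cohorts born in steps
`[2A, n_steps − A]` so lifetimes are fully observed at equilibrium.  A
per-step breeder count (`Nb`) diagnostic is emitted separately.  In this
implementation the realized value tracks the theoretical one closely
(≈3300 vs 3314 at full scale, the small deficit being demographic
stochasticity).  The reference study this package emulates reported a
markedly lower realized value (2772) than its own theoretical 3314 and
attributed the gap to unexplained stochastic behaviour of its simulator;
that gap is not reproducible from the model as specified, and the
corresponding acceptance check is expected to fail — the package reports
both numbers and takes no position on the cause.

## Genome simulation

Genetic data are produced only for sampled individuals, in two phases on
tskit tables.

*Gene dropping.*  Each meiosis on the path from a sampled haplotype to the
step-0 founders draws `Poisson(r·L)` crossovers at uniform positions.  All
transmissions among ancestors of the sample are recorded as node/edge
tables (one per chromosome) and simplified to the sample with founder roots
retained, preserving within-pedigree coalescence exactly.  Forward time
(years) is converted to generations by `T`; a pedigree branch spans the
parent's age at the birth in question over `T` — one generation in
expectation.

*Recapitation.*  Founder lineages still carrying sampled material coalesce
in a single panmictic ancestral population of diploid size `N_anc`
(pairwise rate `1/(2N_anc)` per generation) — the two demes merged, with
`N_anc` defaulting to twice the per-deme realized Ne.  Linked mode runs a
Hudson coalescent-with-recombination over the ancestral segments (full ARG,
not an SMC approximation; segment bookkeeping tracks per-interval sample
counts so simulation stops at each local MRCA).  Unlinked mode treats each
locus window as independent: per-locus Mendelian tracing through the
pedigree (one draw per ancestor haplotype and locus, so identity-by-descent
sharing is exact) followed by an independent Kingman tree per locus.  The
coalescent clock starts at the oldest founder birth, a simplification that
adds at most `A/T ≈ 2.6` generations against timescales of `2·N_anc`.

*Mutations.*  Infinite-sites biallelic mutations fall on every edge as
`Poisson(μ · span · branch length)` at uniform continuous positions with
known ancestral state, so unfolded spectra are available.  Two deliberate
approximations in unlinked mode: pedigree-phase internal merge heights are
collapsed to the founder polytomy, and mutations are not placed on the
pedigree-phase branches of merged lineages.  Both concern ≲ 0.3% of total
tree length (≤ 16 generations of pedigree against ≈ 2·5544 of coalescent)
and bias only the rarest frequency classes imperceptibly; the
linked/recorded path has neither approximation.

Default genome parameters (20 chromosomes × 5·10⁷ bp, `r = μ = 10⁻⁸`) are
explicit stand-ins — the reference parameter table is an external artifact —
and are configurable everywhere.

## Ne estimators

*LD (Burrows composite).*  For unphased diploids the composite
disequilibrium is `Δ̂ = mean(x·y)/2 − 2·p̂_A·p̂_B` on dosages, normalised by
`√(v_A v_B)` with `v = p(1−p) + (P_hom − p²)` (homozygote-excess
adjustment); no `n/(n−1)` scaling is applied, so identical columns give
exactly `r̂² = 1`.  Pairs use complete cases; aggregation weights pairs by
their sample size and reports the harmonic-mean `S`.  MAF screening
(default 0.05 — a flagged choice, since the reference workflow does not
print its filter) precedes pairing; policy `all` or `between-chrom`.  The
estimator inverts `E[r̂²] = 1/(3Ne) + 1/S` (random mating; monogamy doubles
the drift term).  A non-positive drift signal is reported as an infinite
estimate with the raw value attached — never clamped, because such outcomes
are a documented finding for large populations.  An opt-in `refined` mode
uses the published small-sample expectation `1/S + 3.19/S²` and its
quadratic inversion; note those constants were calibrated for the
`n/(n−1)`-scaled statistic, so the baseline is the package default and the
one used in all tests.  Empirically (ideal-population fixture, true
Ne = 200, S = 100, 2000 loci) the baseline recovers the truth to ~10% at
the median, and the uncorrected statistic's sampling bias is ≈ +1.1/S².

*Jackknife CIs.*  Delete-one (individual, or locus via exact aggregate
updates) jackknife on the weighted mean r̂², normal-theory bounds mapped
through the monotone inversion — so intervals respect positivity and an
upper r̂² bound at or below the sampling expectation yields an infinite
upper Ne bound.  Known to under-cover when `S ≪ Ne`; degenerate data return
NaN bounds.

*Physical-linkage correction.*  When all pairs are used, linked loci
inflate mean r̂² and bias Ne low.  The published regression of the bias
ratio on chromosome number, `ratio = a + b·ln(chromosomes)` with defaults
`(a, b) = (0.098, 0.219)` (genome size in Morgans accepted as an
alternative), divides the estimate; the ratio is capped at 1 and the
coefficients are configuration, not hard-coded truth.

*SFS.*  Unfolded/folded spectra and the two-deme joint SFS (deme at
sampling) are exact tallies.  The only in-package spectrum estimator is
Watterson's `θ_W = S / a_n`, `Ne = θ_W / (4μℓ)`, a constant-size
diagnostic; model-based inference is delegated to external tools via the
dadi text format (dimension header, row-major counts, mask line), which
round-trips bit-exactly.

## Benchmark design

The reference design crosses `m ∈ {0.01, 0.05, 0.10}` (3 replicate
simulations each) with locus counts {1000, 10,000, 30,000} × per-deme
sample sizes {14, 50, 56, 140} — 12 subsets per simulation, 108 in total,
36 at 30,000 loci; sample sizes are 0.5%, ~1.8%, 2% and 5% of the 2772
reference Ne.  Subsets draw individuals only from the final-step samples;
every subset is reproducible from a `(simulation seed, subset seed)` pair
derived from one base seed.  The orchestrator isolates per-subset failures
as flagged rows (infinite/negative estimates are results, not errors),
persists genepop intermediates and an incrementally written results table,
and resumes from it.  A `scale` parameter shrinks the cohort size for
desk-scale work; Ne scales linearly with cohort size under fixed rates, so
one-tenth scale targets Ne ≈ 277 per deme.

## What the synthetic data do and do not show

The generator reproduces the *structural* features that matter for Ne
estimation — overlapping generations, age-dependent vital rates, lifetime
RS variance, migration between demes, serial sampling, kin structure in
samples, physical linkage, and neutral long-term diversity via
recapitation.  It does not emulate genotyping error, missing-data patterns,
null alleles, allele dropout, selection, spatially continuous structure, or
non-equilibrium demographic history (the ancestral population is a single
constant-size merger).  Passing tests therefore demonstrate correctness of
the methods under the stated model, not robustness to the technical
artefacts of real datasets.

## Problem sizes used in the test suite

Deterministic demographic checks run at the full reference parameterisation
(cohort 5000, K = 17,710).  The realized-Ne check runs the full-scale
two-deme simulation for 3 seeds.  Stochastic genetic checks run at reduced,
stated scales chosen for desk-scale runtimes: recapitation-only spectra at
15,000 loci / 20 haplotypes; estimator recovery at 200 fixture replicates
(2000 loci, S = 100); Watterson recovery at 50 replicate locus sets; and
the migration sweep at one-tenth cohort scale with 1200-locus, 45-sample
subsets.  Statistical assertions use either Monte-Carlo standard errors
(4σ) or tolerances stated alongside each check.

## Known limitations

- The realized-vs-theoretical Ne gap of the reference study is not
  reproduced (see above); this package's simulator is internally consistent
  instead.
- Hudson recapitation is exact but not optimised for chromosome-scale
  ancestral recombination graphs at the full benchmark genome; full-scale
  linked-mode runs are compute-heavy and the benchmark defaults to unlinked
  loci, which is sufficient for the drift-LD and SFS estimators.
- The refined LD inversion constants apply to a slightly different
  normalisation of the statistic than the package computes (see above).
- Folded dadi files of odd haplotype count read back with an even-`n`
  convention (the text format does not encode parity).
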