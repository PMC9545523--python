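# Methods

This note documents the models implemented in `casfit`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Two-locus selection model

State: a probability vector over the nine genotypes formed by a biallelic
construct locus (EGFP/construct) and a biallelic idealized off-target locus
(uncut/cut), both autosomal and unlinked. Genotype frequencies are assumed
equal in the two sexes; mother and father roles are realized by enumerating
the same distribution twice. Generations are discrete and non-overlapping.

One generation, in order:

1. **Pair formation.** Pair weight is the product of parental frequencies;
   in the fecundity/mate-choice mode each parent's frequency is multiplied
   by its fitness (the same multiplier serves as maternal fecundity and
   paternal mating success) and renormalized.
2. **Gametes.** Mendelian transmission at both loci. A transmitted uncut
   off-target allele is converted to cut with probability `germline` iff
   the parent carries at least one construct allele. Cutting is applied per
   transmitted allele rather than pre-meiotically; for a single unlinked
   locus the two are marginally equivalent, and the per-gamete form is
   simpler to enumerate (they would differ only under linkage, which is out
   of scope).
3. **Embryo cutting.** Each uncut zygote allele (maternal and paternal) is
   independently converted with probability `embryo` iff the mother carries
   a construct allele. The independent-per-allele form matters only for
   `embryo < 1`; the canonical settings are 0 and 1.
4. **Viability selection** (viability mode only): offspring weights are
   multiplied by genotype fitness and renormalized.

Fitness is multiplicative per allele across loci:
`w = w_direct^construct_copies * w_offtarget^cut_copies`. All states are
renormalized after each step; normalization is checked to 1e-12.

The generation step is precomputed as a 9×9×9 tensor
`T[i, j, k] = P(offspring k | mother i, father j)` that depends only on the
cut rates, so it is cached across likelihood evaluations; selection enters
through parent weights or offspring weights at evaluation time.

## Likelihood and inference

Observations are per-generation counts of the three phenotype classes
(construct homozygote, heterozygote, EGFP homozygote); the off-target
dimension is latent. The ancestral state is built from the generation-0
class frequencies, with construct carriers assigned cut/cut when the
construct cuts (or for the initial-off-target model) and uncut/uncut
otherwise; EGFP homozygotes are always uncut/uncut. Heterozygotes present
at generation 0 are treated as cut/cut under that flag, since they were
reared by construct-carrying mothers.

Each transition contributes the multinomial drift kernel of size `Ne`
applied to the model's expected class frequencies, evaluated as a
**density over the class-frequency simplex**: the log-gamma multinomial
term at continuous pseudo-counts `f_c * Ne` plus the lattice-to-density
Jacobian `d * ln(Ne)`, where `d` is the number of classes with positive
expected mass minus one. Three numerical consequences motivated this form:

* A bare multinomial mass is monotonically decreasing in `Ne` (the count
  lattice refines), so `Ne` would always collapse to the search-box lower
  bound; the Jacobian restores the interior optimum, which balances drift
  variance against it (essentially the classic temporal-drift estimator).
  It also makes fitted log-likelihoods positive, on the order of a few
  nats per transition.
* Integer pseudo-counts (largest-remainder rounding) make the likelihood
  surface jagged in `Ne` (several nats of lattice jitter), which traps the
  optimizer and breaks profile bisection; the continuous log-gamma form is
  smooth and coincides with the ordinary mass at integers.
  `effective_counts` (largest-remainder at `round(Ne)`) remains the
  exported primitive for rendering frequencies as integer counts.
* Degenerate certain transitions (e.g. an all-EGFP cage) have `d = 0` and
  contribute exactly 0.

No additional sampling variance is added on top of drift, because whole
populations are phenotyped. Drift enters only through the observable
3-class kernel; the latent off-target composition propagates
deterministically and is **conditioned on each observation**: the observed
class frequencies replace the construct-locus marginal while the
conditional cut-copy distribution within each class is retained. This
anchors every transition to data, keeps the likelihood tractable, and
mirrors how one-locus frameworks of this kind chain observed frequencies.

Model variants: `full` frees (Ne, w_direct, w_offtarget); `construct`
fixes w_offtarget = 1; `off_target` and `initial_off_target` fix
w_direct = 1; `neutral` fixes both and disables selection. Cut rates
default to 1 for models with cutting during the experiment and 0 for
`initial_off_target` and `neutral`, overridable (e.g. to analyze constructs
that cannot cut, or to force cut rates to 1 as a robustness setting).

Optimization: bounded Nelder-Mead on (ln Ne in [ln 10, ln 5000], w in
[0.3, 2.0]) with 8 Latin-hypercube multi-starts and 1e-6 tolerance in lnL.
Replicates share all parameters, including Ne. 95% CIs are profile
likelihood: bisection (tolerance 1e-3 on the search coordinate; Ne profiled
on the log scale) to the 1.9207-nat drop, re-optimizing the other free
parameters warm-started at the MLE; bounds that hit the search box are
flagged as clipped. AICc uses the pooled transition count and is reported
as NaN when `n <= p + 1`. Rows excluded at ingestion (e.g. confounded
first generations) are dropped before transitions are counted.

## Synthetic cage generator

`cage_synth.simulate_cage` draws drift as one multinomial resampling of the
full nine-genotype vector per generation at size `round(Ne)`, then rescales
class frequencies to the reported census (largest remainder). This is
deliberately *richer* than the inference model, whose latent dynamics are
deterministic: the observable classes drift exactly as the likelihood
assumes, but the latent cut-copy composition drifts too. Recovery and
coverage studies therefore probe that mismatch; passing them shows the
inference tolerates latent drift at study scale, not that the likelihood is
exactly the generator's.

Default conditions emulate the study design: 7 replicate cages, 12
generations, census 3000 (median cage censuses were in the few-thousand
range), drift size Ne = 175, viability selection at (0.98, 0.84), cut
rates 1, ancestral construct carriers cut/cut. Starting construct
frequencies (0.2–0.6 across replicates) span the low-to-high range of the
cage experiments; the real starting frequencies are not printed, so these
are the package's choice, fixed once. The generator reports no observation
noise beyond drift (whole-population phenotyping). Sub-seeds for ensembles
and replicates are derived counter-style (`SeedSequence(master,
spawn_key=(i,))`), so results are independent of evaluation order.

Assay generators are plain binomial draws (mate choice; per-cross
heterozygous-offspring fractions) plus a negative-binomial egg-count
option (dispersion default 10) for overdispersed fecundity-like data; the
fecundity group-comparison analysis itself is out of scope.

What the generator does **not** emulate: overlapping ages, larval
competition and census bottlenecks, maternal effects beyond the ancestral
exclusion convention, sex-specific costs, linkage between construct and
off-target sites, or multiple off-target loci. Agreement of fits on these
synthetic data therefore validates the implementation and the statistical
machinery, not the biological adequacy of the two-locus idealization.

## Drive simulator

Diploid individuals carry a drive locus (W/D/R2; all resistance alleles
nonfunctional) and optionally `n_sites` unlinked off-target sites as cut
bits. Germline, per transmitted W allele of a drive-carrying parent:
conversion to D with probability 0.8 and to R2 with 0.1 by default —
interpreted as *absolute* outcome probabilities (the conditional-on-cut
parameterization is not distinguishable from the printed rates; the
absolute reading reproduces the published suppression equilibrium).
Maternally deposited Cas9 converts each zygote W allele to R2 with the
embryo rate (5% default). Off-target cutting occurs exclusively in the
germline of drive carriers: always for the single-site configuration,
at 5% per site for the 20-site configuration.

Off-target viability calibration: with homozygous-cut fitness `F`, the
per-cut-allele multiplier is `F^(1/2)` for one site and `F^(1/n_sites)`
for several, so a fully cut single-site genotype and a half-cut multi-site
genotype have identical fitness (identity holds to 1e-12). Direct drive
costs use the square root of the homozygote fitness per D allele. Fitness
acts on viability only. The default cost scenario `F = 0.7056 = 0.84²`
matches the cage-inference off-target estimate but is configurable — the
exact values used for the published drive figures are not printed.

Architecture rules: modification drives rescue an essential haplosufficient
target, so only R2/R2 individuals are nonviable; suppression drives target
a haplosufficient female-fertility gene, so females with any two drive/R2
alleles are sterile (males unaffected) and successful suppression ends in
extinction.

Reproduction: each fertile female mates one uniformly random male
(monogamous per generation, no Allee effect) and bears a Poisson number of
offspring with mean `2β / ((β − 1)·N/K + 1)` — replacement at carrying
capacity, `2β` per female at low density (β = 10 default). Offspring sex
is a fair coin; survival is Bernoulli with the viability weight. Default
carrying capacity is 20,000 (a desk-scale setting; the published scenario
value 200,000 is a flag away). The plateau frequency of a suppression
drive is capacity-insensitive — verified at both sizes — while time to
elimination is not. One master seed drives all draws in a fixed order.

## Assay statistics

The exact binomial test uses the small-mass two-sided convention (sum of
outcome probabilities not exceeding the observed one, with 1+1e-7 relative
tolerance against floating-point ties), the convention of standard
statistical environments; at `p0 = 0.5` it equals twice the one-sided
tail. The viability test is a standard one-sample t (zero-variance samples
are flagged degenerate, not raised). Drive-cross rates from pooled counts:
inheritance `i` = DsRed fraction, conversion `c = 2i − 1` (inverse of the
expected `(1+c)/2` transmission), embryo resistance = the fraction of
DsRed offspring whose paternal EGFP allele lost function; batch-aware
(GLMM) re-analysis is intentionally not implemented.

## Problem sizes in the test suite

The acceptance tests run at study scale chosen to keep the full suite in
the minutes range: 200 simulated experiments for CI coverage and 100 for
recovery bias (7 cages × 12 generations each), Monte-Carlo oracle checks
at 200,000 individuals × 20 parameter draws, and 20 replicate suppression
runs at K = 20,000. These sizes give binomial error bars comfortably
inside the asserted bands.

## Known limitations

* One latent off-target locus with codominant multiplicative costs; no
  linkage, dominance structure, or epistasis.
* Latent drift is ignored by the likelihood (deterministic propagation
  between observations); the generator's richer drift quantifies but does
  not eliminate this approximation.
* The AICc ranking compares five idealized scenarios; it cannot rule out
  selection models outside that set.
* Fitness parameters are bounded in [0.3, 2.0]; constructs with stronger
  effects would pin the profile bounds (flagged as clipped).
* The drive simulator is panmictic and non-spatial; chasing dynamics,
  functional (R1) resistance, haplolethal targets and somatic expression
  costs are out of scope.
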