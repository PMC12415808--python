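# Methods

## The amplification model

For a single species, PCR with per-cycle efficiency `a` (fraction of target
molecules copied per cycle) turns `c` template copies into
`A = c (1 + a)^N` amplicons after `N` cycles. Sequencing observes only the
*composition* of amplicons across species, so absolute efficiencies are
unidentifiable; we parameterize each species by its per-cycle log-ratio
efficiency relative to a named reference species,

    alpha_i = log(1 + a_i) − log(1 + a_ref),        alpha_ref ≡ 0,

and model expected read proportions as a softmax:

    pi_i = exp(log c_i + N·alpha_i) / Σ_j exp(log c_j + N·alpha_j).

Two invariances follow and are enforced to numerical precision: adding any
constant to all `alpha` (e.g. a mismatch penalty shared by every species in
the community) and rescaling all `c` leave `pi` unchanged. They are the
formal statement of two facts about metabarcoding: bias is relative, and a
primer defect common to all targets is invisible in composition. The flip
side of compositionality is coupling: a composition sums to one, so a
species depressed by low efficiency forces others to be over-represented.

Key assumption: `alpha_i` is constant across community compositions (no
saturation or interaction effects), so efficiencies measured on a mock
community transfer to field samples amplified under the *same marker-Taq
combination*. `calibrate_sample` refuses to mix combinations unless forced.

## Estimating efficiencies from mock communities

A mock community has known per-species amounts under one of two bases:
total genomic DNA mass (fluorometry) or amplifiable template copies
(ddPCR). Given replicate read counts `r` and expected amounts `c`:

- **point**: per replicate, `alpha_i = [log((r_i+κ)/(r_ref+κ)) −
  log(c_i/c_ref)] / N`, averaged over replicates, normal interval on the
  replicate mean. κ = 0.5 by default; κ = 0 requires all-positive counts.
- **bayes**: multinomial likelihood with `pi` from the forward model,
  `alpha` free except the reference, N(0, 0.5) prior, optimized to the MAP
  with an analytic gradient; intervals are Laplace (inverse observed
  information). Replicates factorize, so pooled counts are sufficient.
  MCMC is deliberately not used: at mock-community depths the posterior is
  close to Gaussian and the Laplace interval is accurate, fast, and
  deterministic.

The headline bias summary is mean |alpha| (± SD) per marker-Taq group,
reference species excluded: the further it is from zero, the further read
compositions sit from template compositions.

Calibration of an unknown sample inverts the forward map,
`log w_i = log(count_i + κ) − N·alpha_i`, renormalized; uncertainty is
propagated by sampling `alpha` from normal approximations to the interval.

## ddPCR quantification

Droplet digital PCR partitions a reaction into ~0.85 nL droplets; with
positive fraction `p`, occupancy is Poisson with mean λ = −ln(1 − p), and
concentration is λ/v × dilution. The CI is a Wilson score interval on `p`
pushed through the same transform (chosen for non-degenerate width at
p = 0). Saturated wells (p = 1) are rejected rather than truncated.
Positive calling from amplitudes uses a threshold of max(NTC) + margin.

Copies-per-ng convert to a mass fraction via one molecule's mass,
`L × 660 g/mol/bp / N_A`; both constants are module-level and auditable.
The per-species mitogenome length is a user input (default 16,500 bp). At
realistic rates (~2.8e3 copies/ng, 16.5 kb) the mitochondrial fraction of
an extract is ~5e-5 of total mass — and it varies widely across species,
which is exactly why the gDNA and template bases disagree.

## Attributing bias to template characteristics

Estimated efficiencies are regressed on reference-relative predictors:
mismatch count (forward + reverse), amplicon GC fraction, and insert length
(all minus the reference species' value for the same marker, mirroring the
log-ratio scale of `alpha`; a species with 3 mismatches against a reference
with 1 enters as 2). Mismatch and GC slopes interact with Taq polymerase;
length has a shared slope. There is no global intercept: the reference
species' all-zero row anchors the scale, and an intercept would absorb
reference miscalibration. Reference rows themselves (response and
predictors identically zero by construction) are excluded from the fit by
default — they carry no information and would deflate the residual
variance. Estimation is OLS with classical intervals; R² is reported as
1 − SS_res/SS_tot. Candidate formulas are ranked by small-sample-corrected
AIC, ties to fewer parameters. Efficiency-estimate uncertainty is ignored
in the default (two-stage) fit.

## Treatment effects on composition

Protocol effects (Taq, BSA, cycling regime) are estimated irrespective of
expected proportions with a multinomial-logit model: species `i` in a
sample with condition (j, k, l) has logit
`eta = g0_i + g1_ij + g2_ik + g3_il`, the reference species pinned at zero
(all effects are additive log-ratios against it) and reference condition
levels pinned at zero (effects are changes from the control protocol).
Counts enter the likelihood directly, so observed proportions of exactly 0
or 1 need no transformation; a Dirichlet-multinomial variant is available
for overdispersed replicates. Inference is MAP with a weak N(0, 10) prior
plus Laplace intervals; an effect is "influential" when its 95% interval
excludes zero — no p-values are computed. Aliased designs are rejected with
the offending terms named. Off-target taxa can be dropped first
(`subset_reads`), keeping counts raw and reporting the discarded fraction.

## In-silico PCR

Binding sites are found by semi-global alignment of the (possibly
degenerate) primer against the template: a primer base matches any template
base in its IUPAC expansion set; a template `N` matches only a primer `N`.
The search minimizes (mismatches, gaps) lexicographically with unit-cost
indels — an ungapped Hamming placement wins unless spending ≤ `max_gaps`
gaps strictly reduces mismatches, which reproduces the offset binding sites
caused by indels inside the binding region without a full aligner. Gaps
must be internal: the terminal primer bases always pair, so a terminal
substitution cannot be reinterpreted as a cheaper boundary gap. Ties break
to the leftmost start. Coordinates are 0-based half-open on the plus
strand; the reverse primer is reverse-complemented for the search and
reported on the minus strand. Both template orientations are scored and
the fewer-mismatch one kept (plus strand on ties). Templates whose best
placement exceeds the mismatch ceiling (default 8 per primer, above any
realistic binding-site divergence for these panels) are non-amplifiable —
a result, not an error. Insert GC is computed over unambiguous bases only.

## The synthetic-data generator

The generator emulates the statistical structure of a two-group marine
mock community so every stage is testable without sequence downloads:

- 12 "fish" + 14 "cetacean" species, gDNA mass split 91:9 between groups
  and equal within groups (total 100 ng);
- mitochondrial mass fractions log-normal across species, median 2e-5,
  log-SD 1.0 — the spread implied by observed template-copy proportions of
  extracts mixed at equal gDNA, roughly a 50-fold range between extremes —
  giving template copies = gDNA × fraction / mass-per-mitogenome;
- per-marker mismatch structure: two perfect-match panels, one
  fish-targeted panel whose off-target group carries 4 forward mismatches,
  and one panel whose 1+3 mismatches are shared by all species (and hence
  cancel from composition);
- amplicon GC 0.45–0.50 (fish) vs 0.35–0.40 (cetacean); 16S inserts 20 bp
  shorter in cetaceans;
- efficiencies generated linearly from the profiles with per-Taq mismatch
  slopes −0.0106…−0.0264, one small positive GC slope, length slope
  5.45e-4, residual SD 0.005 — realistic magnitudes for per-cycle
  log-ratio effects, used as fixture values only;
- reads multinomial (optionally Dirichlet-multinomial) at depth 50,000 ×
  3 technical replicates; droplets Poisson-partitioned.

Template sequences are assembled as flank + concretized forward site +
insert of prescribed GC/length + reverse-complemented reverse site + flank,
with mismatches planted at non-degenerate primer positions so counts are
unambiguous. Draws are rejection-sampled (still a pure function of the
seed) until the site search recovers the planted profile exactly, making
sequence → profile round trips exact by construction. All generators are
pure functions of (config, seed); independent purpose-keyed RNG streams
make each artifact invariant to which other generators ran first.

What the generator does not emulate — sequencing error, chimeras, index
hopping, tag jumps, ASV denoising artefacts, cross-contamination, and any
real phylogenetic structure in binding sites — bounds what passing tests
show: they validate the estimators under the stated observation model, not
robustness to upstream bioinformatic noise.

## Numerical choices and problem sizes

Softmaxes are max-subtracted; MAP fits use L-BFGS-B with analytic
gradients (tolerances 1e-13/1e-9) and analytic multinomial Hessians for
Laplace intervals (finite-difference only for the Dirichlet-multinomial
variant). Proportions are validated to sum to 1 within 1e-12 (inputs) and
1e-9 (outputs). The acceptance script uses 20-seed recovery studies,
50-seed basis contrasts, 200-seed droplet coverage runs and 500 site-search
fixtures — sizes chosen so the whole recomputation completes in well under
a minute while keeping Monte-Carlo error far from each decision boundary.

## Known limitations

- Mismatch position and identity are not modelled (a 3'-terminal mismatch
  counts the same as a 5' one); thermodynamic ΔG scoring is out of scope.
- One best site per primer per orientation: multiple/off-target amplicons
  are not enumerated.
- The attribution fit treats estimated `alpha` as data (two-stage); an
  interval-weighted fit is available but uncertainty is not propagated
  jointly.
- Replicates are pooled in the Bayesian estimators; replicate random
  effects are not modelled.
- DNA secondary structure, homopolymers and repeat content — real drivers
  of residual bias — are outside the model, so its R² on real data is
  expected to be well below 1.
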