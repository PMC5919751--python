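# Methods

## The statistic

The four-population test asks whether the tree (((H1,H2)H3)H4) — H4 an
outgroup — is compatible with the data, i.e. whether allele sharing between
H1 and H3 balances that between H2 and H3. For per-site focal-allele
frequencies q1..q4 each site contributes

    X_i = (q1 − q2)(q3 − q4)
    Y_i = (q1 + q2 − 2 q1 q2)(q3 + q4 − 2 q3 q4)

and the statistic is D = Σ X_i / Σ Y_i. X_i is identically the difference,
and Y_i the sum, of the BABA-like and ABBA-like pattern probabilities, so
D ∈ [−1, 1] and D > 0 means excess BABA (H1 shares with H3). Under the null
E[X_i] = 0 at every site; with blockwise-independent sites, D divided by its
block-jackknife standard error is approximately standard normal. The
conventional |Z| > 3 threshold corresponds to a two-tailed p ≈ 0.001; the
package reports Z and p and leaves rejection to the user.

Note the sign convention: the popular (nABBA − nBABA)/(nABBA + nBABA)
orientation is the negation of the equation above. The CLI exposes
`--sign-convention` (default `baba-abba`, matching the formula); the test is
two-tailed, so inference is unaffected.

## Frequencies from reads, without genotypes

Reads of individual l at a site are binomial draws given its allele
frequency, so the read proportion x̂_l is unbiased. The population estimate
is q̂ = Σ w_l x̂_l with w_l ∝ 2 n_l / (n_l + 1), n_l the individual's depth.
This is the variance-minimising weighting under diploid Hardy–Weinberg plus
binomial read sampling (the per-individual variance is proportional to
(n_l + 1) / 2 n_l, and the weights are its inverse, normalised); the test
suite verifies minimal variance against uniform weighting by simulation.
Individuals with no reads at a site get weight zero; the site is kept as
long as each of H1..H4 has at least one pooled read.

Three flavours of the statistic are implemented:

- `extended` — weighted all-read frequencies as above (the method of
  interest);
- `one_base` — the original low-depth approach: one individual per
  population (the first configured) and a single read sampled per site with
  probabilities given by that individual's read proportions;
- `genotype` — frequencies from known genotypes (simulation truth), the
  upper bound on achievable power.

In the full four-base representation each population carries a frequency
simplex vector f_j; the joint pattern probability factorises,
p(a1..a4) = Π_j f_j(a_j), and ABBA/BABA masses sum the 12 (x,y,y,x) and 12
(x,y,x,y) patterns. On di-allelic input this reproduces the scalar formula
exactly (tested to 1e-12). The pattern space is what makes error and
admixture corrections composable.

## Block jackknife

D is a ratio of block sums; the delete-m jackknife weights each block by
its count of usable sites (with equal counts it reduces to the textbook
delete-1 estimator, which the tests check against an independent
implementation). Site counts, not denominator mass, are the weights for a
non-obvious reason: after pattern-space corrections the per-block
denominator Y_b carries mean-zero noise whose sign matches the numerator
noise, so any weighting or block-selection rule based on the sign or
magnitude of Y_b selects on the noise and biases the corrected statistic
(we measured a +0.9σ shift before adopting site-count weights). For the
same reason, blocks are excluded only when genuinely empty — a corrected
block with small negative mass stays in. Blocks default to 5 Mb — large
enough that linkage between blocks is negligible in human-scale data.
All leave-one-out estimates identical ⇒ SE = 0 and Z undefined (NaN), as
is a single-block input.

## Type-specific error correction

A 4×4 row-stochastic matrix e, with e(a,b) the probability of reading b
when the truth is a, models type-specific errors (e.g. post-mortem
deamination). Estimation uses a trio ((T,R),O): conditional on the outgroup
base, T and R share the same true-base distribution, so the observed
conditional distributions satisfy P_T = P_R · e. We solve for e by least
squares constrained to the row-stochastic simplex (SLSQP started from the
projected unconstrained solution). Rows of the outgroup base with no data
are excluded with a warning; an ill-conditioned P_R raises an error
suggesting more sites.

Correction inverts the channel. Per individual: p_true = p_obs · e⁻¹ on the
4-vector of base frequencies. Per group: the 256-pattern operator
E = e1 ⊗ e2 ⊗ e3 ⊗ e4 (population-mean matrices) is applied through its
factors — E⁻¹ = e1⁻¹ ⊗ … ⊗ e4⁻¹ — to per-block pattern mass, before the
jackknife so the standard error reflects corrected quantities. The dense
256×256 matrix is only materialised on request; tests compare the factored
application against the dense oracle.

Two known approximations are kept deliberately: the group-level correction
uses unweighted population-mean matrices, so individuals that carry little
weight in the frequency estimate can be over-corrected; and inversion can
produce small negative pattern masses. For negatives, the *statistic*
pipeline propagates raw values (`policy="raw"`): the statistic is linear in
pattern mass, and clamping negative noise truncates it asymmetrically,
which biases corrected Z-scores upward. Clamp-and-rescale (with a logged
count of clamped mass) remains the default where an actual probability
vector is returned to the user.

## External-introgression correction and α estimation

If H5 contributed a fraction α of the admixed ingroup's genome (a single
pulse), every observed pattern probability of the tested tree is a mixture
p_1:4 = (1−α) p_un + α p_out, where p_out comes from the tree with H5
substituted for the admixed population and p_un belongs to the unadmixed
tree, which satisfies the null. Hence p_un = (p_1:4 − α p_out)/(1−α);
computing D from p_un removes the pulse. Both trees are evaluated over the
same usable sites.

When α is unknown it is estimated as the root of D_un(α) = 0. D_un is a
ratio of affine functions of α; its zero is the zero of the numerator
X_1:4 − α X_out, which is linear, so bisection on the numerator
(tolerance 1e-4 on α, search interval [0, 0.5]) is exact and immune to the
denominator pole that can sit inside the interval. Beyond α = 0.5 the
"minor contributor" reading of α inverts, hence the bound. The standard
error is a delete-one-block jackknife of the root itself (the root is
re-estimated on every leave-one-block-out dataset, unweighted delete-1
formula). Which ingroup is admixed is declared by the user, not inferred.
Order of corrections: error first, then admixture — the mixture identity
holds for error-free pattern probabilities.

Post-pulse drift of the admixed population, and drift between the admixing
branch and sampled H5, add noise but no bias to the root: both have zero
mean given the frequencies at the pulse and are independent of the other
branches, so E[X_un] = 0 still identifies the true α. The simulated
scenario deliberately includes such drift.

## The simulator

A frequency-drift generator replaces the coalescent at desk scale:

- ancestral derived-allele frequency per site from a 1/x density truncated
  to [1/(2Ne), 1 − 1/(2Ne)] (neutral-SFS-like), Ne = 10,000;
- Balding–Nichols drift along each branch with F = 1 − exp(−t/2Ne); times
  are written in units of 4Ne generations (F = 1 − exp(−2τ));
- pulses replace the target frequency by (1−α)·target + α·source;
- diploid genotypes ~ Binomial(2, freq); per-site depth ~ Poisson(λ);
  reads pass through per-individual error matrices;
- sites are unlinked; blocks are coordinate assignments (the jackknife's
  validity rests on block independence, which holds by construction).

All randomness flows from one master seed through named substreams, so
datasets are bit-reproducible. Presets mirror the published validation
scenarios: `fig2A` (migration H3→H1; the rescaled rate M = 4Ne·m maps to a
per-generation migrant fraction m, 280 ↔ 0.7%, applied as a pulse of total
fraction 1 − (1−m)^40 for the 40-generation window), `fig2B` (null tree
with an A→G error of 0.005 in H1 and H3), and `fig2C` (pulse of 0.1 from
H5 into H1, the admixing branch splitting from H5 at 0.2 and pulsing at
0.1).

What the generator does not emulate: linkage within blocks, recombination,
variable mutation rates, reference bias, and — because all variation
originates at the root of the frequency-drift process — polymorphism
arising on internal branches. Two consequences are documented design
choices rather than bugs:

1. *Deep outgroup branches are represented by bounded drift.* The
   published fig2C scenario places the H5 split at τ = 30; in a drift-only
   model that fixes every site in the whole quartet (verified: the
   denominator vanishes). The preset uses a root at τ = 1.25, keeping H5
   strongly diverged (F ≈ 0.97 along its path to the quartet) while
   within-quartet polymorphism survives.
2. *The error scenario preserves the signal-to-noise ratio, not the SNP
   density.* The bias a type-specific error induces grows linearly with
   the (overwhelmingly monomorphic) site count, while the statistic's
   sampling noise grows with the square root of the polymorphic count. A
   5-Mb block has ~5·10⁶ sites; a desk-scale replica with ~10⁵ sites per
   block must therefore lower the polymorphic fraction (5·10⁻⁵) to keep
   the uncorrected statistic as decisively biased as at full scale — the
   regime the correction is meant for. Power and calibration scenarios
   (`fig2A`, `fig2C`) use segregating sites only, as in the original
   pipeline.

Because sites are unlinked, power at a given number of segregating sites
is somewhat higher than for the same count in linked coalescent data; the
cross-check test suite simulates the same quartet with msprime (an
independent coalescent implementation) and verifies null calibration and
the direction of the gene-flow signal on that data too.

## Default study sizes

Calibration, power and introgression runs use 20 blocks per dataset (the
published analyses use 200 regions; 20 keeps a single replicate under a
second at 2× depth while the jackknife remains well-behaved) with 2,000
segregating sites per block (5,000 for α-recovery). 500 replicates
calibrate the null; 40 per grid point measure power.

The error-correction study uses 40 blocks of 100,000 mixed sites and, for
that scenario only, a usable-site rule of two pooled reads per population
instead of one. Both choices control desk-scale heavy tails: with ~10
informative polymorphic sites per block the jackknife needs more blocks,
and at depth 2× a population represented by a single erroneous read
contributes a full unit of spurious BABA mass — roughly 40 such
coincidences per dataset at full genomic scale (they average out), but
~0.1 at desk scale (pure skew). Requiring two reads bounds the per-site
pattern mass at 0.25 while the uncorrected statistic remains decisively
biased (mean |Z| ≈ 5.5).

## Numerical choices

- Frequencies are undefined (NaN) where a population has no reads; such
  sites are excluded before pattern aggregation.
- Major/minor and consensus base ties break in A<C<G<T order.
- ms-style fractional positions map to integers by floor(pos·L)+1,
  duplicates keep the first.
- Transition removal drops {A,G} and {C,T} allele pairs (equivalently, in
  pattern space, restricts ABBA/BABA masses to transversion pairs).
- The error-matrix fit runs SLSQP with analytic gradients, bounds [0,1]
  and row-sum equality constraints; condition numbers above 1e8 (fit) or
  1e10 (inversion) raise errors.
- Bisection tolerance for α is 1e-4; the reported curve samples 51 points.

## Known limitations

- Mapping quality cannot be enforced from pileup text (no per-read MQ);
  apply it upstream when generating the pileup.
- The population-structure caveat of the underlying model applies:
  structure predating the H1/H2 split can produce false positives.
- Error estimation assumes T and R are equidistant from O in substitution
  probability, and an outgroup sequenced (or consensus-called) without
  error.
- The real-data benchmark for α (the Neandertal-into-Han-Chinese analysis,
  α ≈ 0.03, SD 0.0042) requires whole genomes and is documented as an
  external benchmark only; it is not reproduced by the desk-scale suite.
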