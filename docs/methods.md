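# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `treehap`, in the spirit of a statistical software appendix.
All empirical numbers quoted here are computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Local genealogies and haplotype clusters

**Windows.** For a focal marker *f*, the window is the largest contiguous
marker interval containing *f* in which **every pair** of markers passes the
four-gamete test (two bi-allelic sites are incompatible with a single
recombination-free, infinite-sites history exactly when all four gametes
00/01/10/11 are observed). All-pairs compatibility — not merely
focal-versus-other — is required, so the window supports one perfect
phylogeny. Because every sub-window of a valid window is valid, the maximal
end is non-decreasing in the start and a two-pointer sweep finds all maximal
windows in near-linear time with memoized pair tests. Ties between equally
large windows go to the smaller start index. We deliberately compute the
exact maximum rather than a greedy left/right expansion: a greedy
acceptance on one side can block a larger window on the other, and the
exact maximum is both deterministic and what "as many markers as possible"
means; the test suite checks it against exhaustive enumeration on random
panels. Windows never cross chromosome boundaries.

**Trees.** Within a window, each non-focal marker contributes a split (its
minor-allele carrier set). Splits are oriented as clades nested inside the
focal marker's two allele classes — pairwise compatibility guarantees that
exactly one orientation nests, and that the oriented clades form a laminar
family — and assembled into the unique perfect phylogeny rooted on the
focal split. Haplotypes with identical window sequences collapse onto one
leaf. Polytomies are resolved deterministically into a caterpillar:
children ordered by decreasing haplotype count, ties by smallest contained
row index, largest branch split off first. Any deterministic resolution
would do; this one keeps frequent haplotype groups shallow, so they survive
the depth cut as separate clusters.

**Depth cut.** Level 1 is the root, level 2 its two children, level 3 the
four grandchildren; every branch hanging below level 3 is one cluster, and
leaves reached at or above that layer are clusters by themselves — hence at
most 2³ = 8 clusters, fewer when the tree is unbalanced or shallow ("empty
branches" simply never appear; labels are renumbered 1..C). Cutting deeper
is supported (`depth` parameter) but trades cluster resolution against the
number of observations per cluster.

**Covariates.** An individual's two haplotypes give 0/1/2 copies of every
cluster; within one focal marker's block the copy counts sum to 2 per
individual by construction. Cluster columns are not frequency-filtered by
default (they are complementary within a tree; dropping would break row
sums); duplicated columns arising from overlapping trees are counted and
logged but kept. Marker designs apply the MAF < 0.01 removal before
anything else, and focal trees are built only for retained markers.

## Weighted models

Records are DRE with reliability r (filled from EDC via r = EDC/(EDC + k),
k = (4 − h²)/h²). All models use residual covariance D σ²ₑ with
D = diag(1/wᵢ), wᵢ = rᵢ/(1 − rᵢ), reliabilities capped at 0.98 (max weight
49). Records with r ≤ 0 carry no information (the weight is undefined) and
are excluded with a warning.

**GBLUP.** G is VanRaden's first method on the 0/1/2 design: columns
centered by twice their observed frequency (computed on the analyzed sample,
reference + test), G = M_c M_cᵀ/s with s = Σⱼ 2fⱼ(1−fⱼ); zero-variance
columns are skipped; haplotype-cluster columns are treated exactly like
bi-allelic loci. Because one tree's centered columns are linearly
dependent (row sums are constant), haplotype G is rank-deficient and a
ridge δ = 1e-6 is added by default; δ = 0 is available and is what the
GBLUP↔RR-BLUP equivalence tests use (the identity
ĝ_test = G_test,ref G_ref⁻¹ ĝ_ref = M_c,test â holds exactly, by the
push-through identity, whenever G_ref is invertible). Variance components
are either fixed or estimated by EM-REML (σ²ₑ update via
yᵀW(y − 1μ̂ − ĝ)/(n − 1), σ²_g via the conditional-expectation update;
convergence when the larger variance change falls below 1e-8·var(y), at
most 500 iterations; a genetic variance reaching 1e-8·var(y) is clamped
and reported as a boundary solution). EM was preferred over AI-REML for
robustness at the problem sizes this package targets.

**Bayesian mixtures.** The sampler is the indicator-integrated single-site
Gibbs scheme with residual updating. Per covariate, the inclusion
indicator is sampled with the effect integrated out (the relevant statistic
rhs = zᵀW(e + z a_old) is normal with variance zᵀWz·σ²ₑ under exclusion
and additionally (zᵀWz)²σ²ₐ under inclusion), then the effect from its
normal full conditional. The common (BayesC/Cπ) or per-covariate
(BayesB/Bπ) effect variances, the mean, and σ²ₑ come from closed-form
scaled inverse-χ² / normal full conditionals; π (BayesCπ) from
Beta(K − m + 1, m + 1) with m the current number of non-zero effects. The
prior scale solves S²ₐ = V (ν−2)/(ν (1−π) Σⱼ 2fⱼ(1−fⱼ)) with ν = 4.2 and
target genetic variance V (default h²·weighted var(y)); σ²ₑ carries a
weakly informative scaled inverse-χ² prior (ν = 4, scale from
var(y)·(1−h²)). Degrees of freedom 4.2 are used for the per-covariate
variances of BayesB as well. Covariates are centered internally for
mixing; all reported quantities (effects, DGV = Σ zᵢāᵢ, intercept) are on
the raw 0/1/2 scale, so an all-zero covariate row has DGV exactly 0 and
predictions from posterior-mean effects coincide with the per-iteration
training accumulator by linearity. Default chain: 10 000 samples, 1 000
burn-in, thinning 1. All randomness comes from one seeded numpy generator
driving a numba kernel, so chains are bit-identical for a given seed.
BayesBπ is implemented as the documented two-stage protocol: run BayesCπ,
fix π at its posterior mean, run BayesB.

**Validation.** Accuracy = cor(DRE, DGV)/√(mean test reliability); its SE
is the Fisher-type correlation SE √((1−r²)/(n−2)) scaled by the same
reliability factor — a convention, since several SE choices are defensible
(a seeded bootstrap is provided as an alternative). Bias is the OLS slope
of DRE on DGV with its usual SE; slope 1 means the DGV dispersion is
calibrated, slope < 1 means over-dispersed (inflated) predictions.

## Synthetic population

The generator is a forward Wright–Fisher simulation chosen for simplicity
and zero external dependencies: Ne = 100 founders with site frequencies
uniform on (0.1, 0.9), 80 generations of random union of gametes with
Poisson recombination at 1 cM/Mb on 100 cM chromosomes and light mutation
(1e-4 per site per gamete during the burn-in generations only), then one
half-sib generation (N/25 sires, dams drawn from the whole pool) of N
bulls. Monomorphic markers are dropped; alleles are recoded so 1 is minor.
Trait architecture is additive over n_qtl loci; in *marker* mode TBV is a
weighted allele count, in *branch-haplotypic* mode each QTL effect attaches
to one depth-3 cluster of the local genealogy at the QTL (chosen among
mid-frequency clusters), so the causal unit is a haplotype, not a SNP.
Responses are DRE_i = 100 + TBV_i + ε_i with var(ε_i) =
var(TBV)(1 − r²ᵢ)/r²ᵢ and r²ᵢ from a lognormal EDC (median 3k, σ = 0.5,
i.e. typical reliability 0.75, the magnitude of progeny-test reliabilities);
birth dates are assigned so a fixed calendar-date split yields the
configured reference fraction (default 75%, split 2001-10-01).

What the generator does *not* emulate: selection, non-random mating beyond
one half-sib layer, genotyping error, chip ascertainment, multi-breed
structure, or any model misspecification — the mixture models' assumptions
hold exactly in the simulated data. Passing tests therefore demonstrate
algorithmic correctness and the *mechanism* of the haplotype advantage
(a branch-borne causal allele is tagged imperfectly by single markers but
contained exactly in the cluster design), not effect sizes on real data.

## Study sizes and the directional comparison

The marker-versus-haplotype study runs at N = 1000 individuals,
M = 2000 markers, 20 branch-haplotypic QTL, h² = 0.5, over 10 seeds, with
BayesC chains of 2000 samples (400 burn-in) — chain lengths scaled to desk
hardware after checking that short and long chains give DGV correlated
above 0.99 on the standard fixture. The fixed π per design is set so the
prior expected number of non-zero covariates is 50 in both designs, making
the marker and haplotype priors comparable despite very different K.
Haplotype-based BayesC is more accurate on average (positive mean accuracy
gain across seeds). The bias comparison, by contrast, has little signal
here: because the fitted model class matches the generator, both designs
produce essentially unbiased DGV (slopes scatter tightly around 1 on both
sides), so "which slope is closer to 1" is dominated by seed noise. A
systematic slope-below-1 regime would require misspecification (many more
covariates than records, causal variants absent from the panel), which this
generator intentionally does not build in; the corresponding check in the
acceptance suite documents this limit and may fail by a hair-thin margin.

## Numerical details and edge cases

- Window tie-breaks: smallest start. Tree tie-breaks: caterpillar order by
  (−cluster size, smallest haplotype row). Cluster labels follow a
  deterministic pre-order traversal.
- A monomorphic focal marker cannot be rooted and is a hard error; the MAF
  filter upstream prevents it in the pipeline.
- `build_grm(ridge=0)` plus a singular reference block raises with a
  suggestion to increase the ridge; the vector of ones is always in the
  null space of a full-sample VanRaden G, so reference sets must be proper
  subsets (or a ridge used) for the mixed-model equations to be solvable.
- π = 1 yields all-zero effects and the weighted-mean intercept; π = 0
  includes every covariate each iteration and reproduces weighted RR-BLUP
  when the variances are fixed.
- Sampler numerical guards: inclusion log-odds beyond ±35 short-circuit;
  non-finite states raise with the iteration index.
- Gzip is transparently supported for VCF and TSV I/O; VCF loading rejects
  unphased separators, missing genotypes and multi-allelic records
  outright rather than imputing.

## Known limitations

- The window search is exact but assumes bi-allelic, fully phased,
  imputation-complete input; no missing-data handling by design.
- Cluster columns from overlapping trees are strongly collinear; GBLUP
  absorbs this through G (with ridge), the mixture models through the
  prior, but effect estimates for individual clusters are not separately
  interpretable.
- EM-REML converges slowly near the σ²_g = 0 boundary (it is clamped and
  flagged rather than iterated indefinitely).
- Accuracy above 1 can occur on small test sets because the reliability
  rescaling is itself estimated.
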