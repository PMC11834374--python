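# Methods

This note documents the statistical machinery in `symnet`: the models,
their assumptions, the tunable parameters, and the numerical choices
that the code makes where conventions differ.

## Data model

The unit of observation is one sampled aphid individual, linking an
aphid species to up to three partners: the plant it was collected from,
the parasitoid that attacked it, and the symbiont strain it carried.
A screened-but-negative sample carries the sentinel `"No Association"`,
which is deliberately distinct from a missing value: the former is an
observation (the sample was tested and had no partner of that kind), the
latter is absent data. Counts of screened-but-negative samples can
therefore be reported, and each downstream analysis filters on presence
for its own partner kind only.

*Transient associations* — a single individual of a species collected
once from a plant that is not a recognised host — are removed by a
singleton rule: any (aphid, plant) pair observed exactly once is dropped
unless the plant appears in an optional recognised-host list supplied in
the configuration. The singleton rule is a design choice (no numeric
definition of "transient" exists in the field); the host list lets users
override it species by species. The partner-presence filter runs before
singleton detection so that the combined filter is idempotent: applying
it twice equals applying it once.

Community matrices count records per (aphid species, partner taxon).
Rows and columns are sorted lexicographically everywhere, making every
output byte-stable across runs. When several matrices feed one analysis,
`align_species` restricts all of them to the species with non-zero data
in every input (species lacking data for any partner kind would
otherwise inject structural zeros into the similarity matrices) and
requires at least 3 common species, the minimum that yields 3
off-diagonal pairs for matrix regression.

## Similarity and relatedness

Community dissimilarity between two species' partner count vectors is
Bray–Curtis, `BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`, reported as similarity `1 − BC`
(1 = identical partner communities, 0 = disjoint). By default BC runs on
raw counts, mirroring the default of the standard community-ecology
packages; a `normalize` flag first scales rows to relative abundances,
which removes differences in sampling effort and is the right choice
when effort varies strongly across species.

Host relatedness is summarised from one representative marker sequence
per species as the pairwise count of differing alignment positions
(gap/N sites dropped under pairwise deletion by default, or counted as
mismatches with `count_gaps`). This site count is *not* an
evolutionary-model distance: it saturates at high divergence and need
not satisfy the triangle inequality. It also *grows* with
unrelatedness, so the regression module accepts a transform:

- `raw_distance` (default): pass-through; a positive coefficient then
  refers to genetic distance, not relatedness;
- `one_minus_scaled`: `1 − D/max(D)`, a [0, 1] relatedness score;
- `negated_z`: `−(D − mean)/sd` over off-diagonal entries.

All three are monotone transforms of each other, so permutation
p-values are essentially unaffected; only the sign and scale of the
coefficient change. Every result records which mode produced it. The
pipeline's reporting convention uses `one_minus_scaled` so that the
printed coefficient is positive "relatedness".

## Multiple matrix regression with randomization (MMRR)

The dependent similarity matrix and each predictor matrix are unfolded
to their strictly-lower-triangle entries (fixed row-major order,
`n(n−1)/2` pairs), z-scored (mean 0, sd 1 with the n−1 denominator), and
fit by OLS with intercept. Coefficients are therefore standardized and
comparable across predictors. Because matrix entries that share a
species are not independent, parametric t/F p-values are invalid;
inference instead permutes the *species labels* of the dependent matrix
— rows and columns simultaneously — re-unfolds, re-fits, and compares
`|t|` (per coefficient) and `F` (whole model) against the permutation
distribution with the add-one correction
`p = (#{|t_perm| ≥ |t_obs|} + 1)/(nperm + 1)`; ties count as
exceedances (conservative). Only the dependent matrix is permuted, the
classic convention for multi-predictor matrix regression. The default
`nperm = 9999` resolves p-values to four decimals; the permutation
stream is seeded and the whole computation is vectorised (one gather and
one matrix product per batch of permutations), so 9999 permutations on a
22-species problem take well under a second.

Acceptance-grade checks: coefficients agree with a normal-equations
oracle to 1e-9; the single-predictor beta equals the Pearson correlation
of the unfolded vectors; on independent random distance matrices
(n = 20 species) the test rejects at 4–5% at nominal α = 0.05 over
hundreds of replicates.

## Diversity and rarefaction

Per species: richness (non-zero partner taxa), Shannon entropy
`−Σ pᵢ ln pᵢ` in nats, and Gini–Simpson `1 − Σ pᵢ²` (the "Simpson"
returned by the common ecology packages; the name is ambiguous in the
literature, so the choice is stated here). Because species differ in
sample size, indices are also computed on `reps` random subsamples of a
fixed depth drawn *without replacement* (multivariate hypergeometric;
default depth 7, 1000 replicates), reporting the mean per index.
Species with fewer individuals than the depth are excluded and flagged
rather than resampled with replacement. The Monte-Carlo mean richness is
checked against the closed form `E[S_d] = Σᵢ 1 − C(N−Nᵢ, d)/C(N, d)`.

The diversity screen regresses strain diversity on parasitoid (or
plant) diversity across species by one-predictor OLS and reports the
slope, adjusted `R² = 1 − (1−R²)(n−1)/(n−2)` (negative when the
predictor is uninformative), the F statistic and its p-value.

## H2′ and null-model standardised effect sizes

For an interaction count table with cell proportions `pᵢⱼ`, the
two-dimensional Shannon entropy is `H2 = −Σ pᵢⱼ ln pᵢⱼ`. H2 depends on
the marginals, so specialisation is read off only after rescaling
between the extreme entropies achievable by non-negative integer tables
with the observed row and column totals:
`H2′ = (H2max − H2)/(H2max − H2min)`, clamped to [0, 1]. H2′ = 0 means
partners are used in proportion to availability; H2′ = 1 means maximal
reciprocal specialisation.

Computing the exact integer entropy extremes is a combinatorial
problem. The entropy is concave over the transportation polytope, so
its maximum is near the independence table and its *minimum* sits at a
vertex, which greedy allocation does not always find. `symnet` uses:

- **small webs** (≤ 16 cells and total ≤ 16): exact extremes by
  enumerating every table with the given marginals — verified against
  an independent brute-force oracle over all 2×2…4×4 marginals with
  totals up to 12;
- **larger webs**: H2max from largest-remainder rounding of the
  independence expectation followed by coordinate ascent over 2×2
  cycle moves (along each cycle the entropy is concave in the transfer,
  so the step jumps straight to the integer optimum); H2min from two
  greedy concentration variants (largest allocation; exact row/column
  double-exhaustion preferred) refined by the same cycle moves,
  keeping the lower.

Bounds are computed from marginals once per analysis; they are
heuristic on large webs, but the *standardised effect size is exactly
invariant to them*: H2′ is an affine function of H2 given the
marginals, and the null model preserves the marginals, so
`SES = (H2′obs − null mean)/null sd` equals the (negated) SES of H2
itself.

The null model fixes both marginals (Patefield's algorithm, equivalent
to shuffling row-labelled against column-labelled interaction tokens);
1000 null tables by default, SES with the sample (n−1) standard
deviation. Degenerate cases (no entropy range; zero null sd) return
H2′ = 0 / SES undefined with warnings rather than NaNs.

The parasitoid × strain web is *generated*, not observed: each aphid
species' strain counts are assigned to the parasitoids attacking it
proportionally to attack frequency,
`B[p,s] = Σₐ S[a,s]·A[a,p]/Σₚ′A[a,p′]`. The projection conserves total
strain counts over the retained aphids (those with both parasitoid and
strain records) to floating-point precision. For H2′/SES scoring the
fractional projected weights are rounded to integers, since both the
entropy rescaling and the fixed-marginal null are defined on count
tables; at realistic totals (hundreds of interactions) the rounding
perturbs H2′ in the third decimal.

Pairwise sharing summaries count unordered species pairs with strain
similarity > 0 and, among them, pairs with partner similarity above a
threshold (default 0, i.e., any shared taxon; the similarity-highlight
threshold used for network figures, 0.1, is exposed as a parameter).
Species-level linkage asks whether each strain-sharing species also
shares at least one partner taxon with at least one of its
strain-sharing counterparts.

## Synthetic communities

The generator emulates the statistical structure of a field survey
without modelling mechanism:

- **Phylogeny and sequences**: a Yule (pure-birth) tree with
  unit-exponential waiting times; one marker sequence per species
  evolved from a random root by per-site substitution with probability
  `1 − exp(−μt)` per branch (μ = `mutation_rate`, default 0.02/site per
  unit branch length over 400 bp, giving realistic within-community
  divergence).
- **Attack profiles**: each species has a dominant parasitoid receiving
  `dominance` (default 0.8) of its attacks, remainder spread over 1–3
  minor parasitoids. Dominants are assigned in blocks of 1–3 species so
  that some parasitoids are shared; block assignment runs over an
  independently shuffled species order so parasitoid sharing is not
  confounded with phylogeny.
- **Strain profiles**: each parasitoid carries a signature strain; a
  species' strain profile mixes (λ_par) the signature strains of its
  parasitoids weighted by attack frequency, (λ_phy) its nearest
  relative's parasitoid-derived profile, (λ_pla) a strain pool attached
  to its dominant plant, and the remaining mass as Dirichlet noise
  (concentration `noise` = 0.5, giving the skewed few-dominant-strains
  profiles seen in real surveys). λ_par + λ_phy + λ_pla ≤ 1.
- **Plants**: one dominant plant per species (80% of records), blocks
  shuffled independently of the parasitoid blocks.
- **Records**: categorical draws from the per-species profiles
  (default 40 samples/species over 22 species); a configurable fraction
  (default 5%) is marked `"No Association"` for parasitoid/strain,
  emulating screened-but-negative samples.

Everything derives from one seed; the observation table is
byte-identical across reruns. Defaults mirror the scale of the
motivating field system: ~22 species entering the parasitoid analysis,
30 parasitoids, 25 strains, 20 plants, > 75% dominant-parasitoid share.

What the generator does *not* emulate: within-species symbiont
frequency dynamics, multi-year turnover, observation biases of
mummy-based sampling, phage-mediated protection, or spatial structure.
Passing recovery tests therefore show that the estimators detect the
encoded coupling at realistic sizes and calibrate correctly under the
null — not that field data satisfy the generator's independence
assumptions.

Simplifications worth knowing: phylogenetic coupling borrows the
nearest relative's profile rather than evolving strain profiles along
the tree (sufficient for recovery tests, no deep-time signal); strain
signatures are one-per-parasitoid (the sharpest version of
enemy-linked strain structure).

## Operating characteristics and problem sizes

The acceptance script (`scripts/acceptance.py`) reruns, from one seed:
one full study-condition analysis (22 species, λ_par = 0.8,
40 samples/species; MMRR with 9999 permutations, H2′/SES with 1000
nulls per web), the type-I error of the permutation test on independent
random matrices (200 replicates of 20 species, 999 permutations), and
the recovery rate of the parasitoid coupling (100 simulated surveys,
499 permutations). These replicate counts keep the whole script at
roughly half a minute on one core while leaving Monte-Carlo error on
the reported rates at the ~1.5–3 percentage-point level; the same
computations at larger replicate counts only tighten those errors.

## Known limitations

- H2min/H2max on large webs are heuristic; H2′ point values there carry
  a small downward/upward uncertainty (SES does not, see above).
- Greedy OTU clustering is order-dependent by construction; the
  (abundance, then id) processing order is pinned and documented, but a
  different order can split borderline chains differently.
- The site-count relatedness matrix ignores multiple substitutions; for
  deeply divergent communities a model-based distance would be
  preferable before regression.
- MMRR assumes a linear relation between unfolded similarities; strong
  nonlinearity would call for a rank-based variant, which is not
  implemented.
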