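# Methods

`domgen` analyses dominant molecular-marker data: band presence/absence
(0/1) matrices scored from ISSR, SCoT, EST-SSR or similar PCR assays, where
heterozygotes cannot be distinguished from dominant homozygotes. This note
records the models, the estimators and their assumptions, the numerical
conventions, and what the synthetic-data generator does and does not
emulate.

## Data model

A `BandMatrix` holds samples in rows and band loci in columns, each locus
annotated with its primer and marker type. Entries are 0, 1 or missing
(`NA`); every statistic is computed over non-missing entries
(pairwise-complete for pairwise quantities, column-complete for
frequencies). Real band scoring has failed lanes, so missingness is a
first-class state even though many published matrices are complete.

The MAF filter removes bands with presence frequency strictly below the
threshold (default 5 %), the usual pre-processing before LD and structure
analysis because rare bands have large sampling variances. One-sided
filtering is the default; a `two_sided` flag also removes near-fixed bands
(frequency > 1 − threshold), which is required before r² computation since
monomorphic columns have undefined correlations. The pipeline uses the
two-sided variant for its LD/structure input.

## Diversity statistics

Per scope (primer, marker type, overall) the package reports TNB (loci
scored), NPB (loci with both states observed), and PPB = 100·NPB/TNB.

Nei's gene diversity H = 2pq and Shannon's index I = −p ln p − q ln q need
allele frequencies, which dominant data do not expose directly. The default
estimator is the HWE square-root rule q̂ = √(1 − band frequency) — what
POPGENE applies to dominant data — with the Lynch–Milligan small-sample
correction available as an option (`method="lynch_milligan"`,
q̂ = √x / (1 − Var(x)/(8x²)) with x the null-phenotype frequency and
Var(x) = x(1−x)/n). Monomorphic loci are clamped so that q̂ lies in
[1/(2n), 1 − 1/(2n)], the standard finite-sample guard against log(0) and
degenerate H. Because published dominant-marker studies rarely state
whether indices were computed on allele or phenotype frequencies, a
`scale="phenotype"` mode computes both indices directly on band
frequencies; the two modes differ materially and neither is claimed to
reproduce any particular published H.

Per biallelic locus 0 ≤ H ≤ 0.5, 0 ≤ I ≤ ln 2 and I ≥ H; these are tested
as invariants.

## Marker efficiency

Band informativeness Ib = 1 − 2|0.5 − p| peaks at p = 0.5; Ib_av is the
mean of Ib over a marker system's bands. The sum runs over *all* scored
bands (monomorphic bands contribute 0) rather than polymorphic bands only —
the literal reading of the formula, and the one consistent with the
identity MI = EMR·Ib_av at the printed magnitudes; `ib_scope="polymorphic"`
exposes the alternative. EMR is the mean number of polymorphic bands per
primer, and MI = EMR·Ib_av. Table output rounds half-up to 2 decimals
(4.655 → 4.66); full precision is kept internally.

An aggregation-only path consumes a published per-primer TNB/NPB table —
the packaged `data/primer_band_counts.tsv` ships a 51-primer ISSR/SCoT/
EST-SSR reference table — and reproduces the survey aggregates without any
band matrix.

## Distances and ordination

Nei–Li similarity is the Dice coefficient S = 2a/(2a+b+c) on shared band
presences; the distance 1 − S feeds UPGMA. A pair with no presences at all
is defined to have S = 1 (identical absence profiles) with a warning rather
than crashing. The modified Rogers distance treats each 0/1 profile as an
allele-frequency vector under a two-alleles-per-locus convention and
reduces to √(Hamming/L); this individual-profile reading is documented here
because MRD is defined in the literature on population frequency vectors.
MRD is an L2 metric, so its matrices are Euclidean-embeddable.

PCoA follows Gower: B = −½ J (D∘D) J, eigendecomposition, coordinates =
eigenvectors scaled by √λ for positive eigenvalues. Negative eigenvalues
(non-Euclidean inputs) are reported in full and excluded from coordinate
scaling, never silently dropped. Two axes are the default, matching the
usual 2-D ordination plot.

## UPGMA and bootstrap

UPGMA merges the closest pair, averaging distances weighted by cluster
size; node height is half the merge distance, so trees are ultrametric.
Ties are broken deterministically: among tied pairs, the one whose pair of
smallest contained leaf labels sorts lexicographically first merges. The
resampling unit for Felsenstein bootstrap support is the band locus
(columns resampled with replacement), the standard choice for marker data;
support of an internal edge is the percentage of replicate trees containing
the same leaf bipartition. Newick export writes branch lengths and supports
as internal node labels and round-trips through the bundled reader.

## AMOVA

Two-level AMOVA on squared distances follows Excoffier's construction
(SS_total = Σd²/N over pairs; SS_within analogous per group; σ²_within =
MS_within; σ²_among = (MS_among − MS_within)/n₀ with n₀ the average group
size correction). Distances entering AMOVA are Euclidean on 0/1 profiles,
so squared distances are Hamming counts — the convention of the dominant-
marker AMOVA lineage. Negative among-group components are clamped to zero
and flagged; the zero-variance degenerate case defines percentages as
(0, 100) with a warning. Significance permutes group labels across all
samples: p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm).

## Admixture model

The clustering model is a Bernoulli-observation admixture model: cluster k
has band frequency p_kl, sample i has proportions q_i, and each band
observation picks a latent cluster z_il ~ Categorical(q_i) then
x_il ~ Bernoulli(p_{z_il,l}). This treats the dominant band phenotype as
the observed Bernoulli variable directly — a deliberate simplification of
STRUCTURE's recessive-genotype integration — and uses independent rather
than correlated cluster frequencies. The procedure's downstream logic
(LnP(D), Evanno ΔK, membership thresholds) is the standard one.

Gibbs sweeps sample z | q,p, then p | z from its Beta posterior (prior
Beta(1,1)) and q | z from its Dirichlet posterior (symmetric prior
α = 1). Model evidence is estimated as LnP(D) = mean(lnL) − var(lnL)/2
over the retained trace. ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K))
with the sample sd over replicate runs; its argmax over interior K
estimates the number of subpopulations. Samples with maximum membership
≥ 0.75 are assigned to that subpopulation (the boundary counts as
assigned); below the threshold they are labelled admixed. A threshold-free
maximum-membership assignment is always emitted alongside. Label switching
across replicate runs is resolved by greedy matching of Q columns against
the first run.

Sampler defaults are burn-in 2000 / 10 000 sweeps / thin 10. The pipeline
and the acceptance script run desk-scale chains (burn-in 200–300, 400–600
sweeps) on matrices of ~100–150 filtered loci; on data with clear two-group
structure the chain reaches its stationary band within tens of sweeps, and
the stationarity of the retained trace is itself tested. All run lengths
are configurable up to full-scale chains.

## Linkage disequilibrium

For band columns A, B: r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)),
the squared Pearson correlation of the binary columns, computed for all
unordered pairs (optionally restricted to inter-primer pairs). Significance
uses the allelic chi-square X² = n·r² on 1 df, with a seeded permutation
alternative. Headline counts apply no multiple-testing correction —
reporting raw P < 0.001 fractions is the field convention — but a
Bonferroni threshold is emitted for information. Stratified LD recomputes
band frequencies and the MAF filter within each stratum (e.g. per inferred
subpopulation) before computing r², since pooled frequencies would
manufacture spurious LD from structure alone.

## Synthetic data generator

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any external download:

- Locus layout: primers per marker type with band counts 1 + Poisson(mean −
  1); defaults 16/20/15 primers at means 13.75/22.25/8.53 bands per primer
  (≈ 793 loci from 51 primers).
- Differentiation: Balding–Nichols. Ancestral dominant-allele frequency
  p_anc ~ Beta(0.6, 0.6); subpopulation frequency p_k ~ Beta(p_anc(1−F)/F,
  (1−p_anc)(1−F)/F) with F the fst knob.
- Admixture: each sample has a subpopulation of origin (default sizes
  91 + 43 out of 134); its proportions are Dirichlet with a small symmetric
  concentration (0.15) plus weight 2.0 on its own subpopulation, giving
  mostly assignable samples with a realistic admixed minority. Setting the
  symmetric part to 0 yields hard, admixture-free membership for
  parameter-recovery tests.
- Dominance collapse: two allele copies per sample × locus, each drawn from
  a q-chosen subpopulation, presence with probability p_k; the band is
  present iff at least one copy carries the presence allele, so a locus
  with allele frequency p shows the band at 1 − (1−p)² under HWE.
- LD: mechanical block-copying — within blocks of `ld_block_size`, each
  non-anchor locus copies the anchor's diploid genotype column with
  probability `ld_copy_prob`, optionally only for samples of selected
  subpopulations (`ld_groups`), producing subpopulation-specific LD
  contrasts. This is not a recombination model; it exists to create the r²
  structure the LD module must detect, which coalescent machinery would
  buy at far higher cost.
- Metadata: the first 7 samples are labelled LL (lowland), the rest UL,
  mirroring a heavily unbalanced two-ecotype collection.

The default F = 0.35 was calibrated once so that AMOVA on the latent
subpopulations lands in the ~30 % among-group regime reported for
upland/lowland switchgrass collections; the calibration grid and choice
are fixed, not re-tuned per run.

What the generator does **not** emulate: real marker ascertainment (bands
are not length-sorted alleles of real primers), genotyping error and
band-comigration artefacts, isolation-by-distance or pedigree relatedness,
and LD decaying with physical distance (bands are anonymous and unmapped,
as in the motivating assays). Passing tests therefore demonstrate that the
estimators recover the structure they model, not that any particular field
dataset will show that structure.

## Numerical conventions

- Random state: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); the pipeline derives stage seeds from a
  master seed by fixed offsets.
- Beta draws in the sampler are clipped to [1e−9, 1 − 1e−9] before log
  terms; mixture weights are floored at 1e−12 before normalisation.
- UPGMA ties: exact float equality defines a tie; the lexicographic rule
  above resolves it.
- Permutation p-values use the add-one convention (1 + exceedances)/(1 +
  permutations), never reporting 0.
- Rounding for table parity is half-up via `decimal`, not banker's
  rounding.

## Known limitations

- The admixture sampler is a single-chain Gibbs scheme without tempering;
  for weakly structured data at large K, replicate runs (the default) are
  the guard against local modes.
- LnP(D)'s mean-minus-half-variance form is a rough evidence approximation;
  it is used inside ΔK, where only differences across K matter.
- AMOVA here is strictly two-level (among/within groups); nested designs
  are out of scope.
- The chi-square LD test is asymptotic; at the default problem sizes its
  type-I rate at α = 0.001 is calibrated by test, but for very small n the
  permutation method is preferable.
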