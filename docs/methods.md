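# Methods

This note documents the models, statistics and numerical choices behind
`songkin`, in the order the pipeline applies them, together with what the
synthetic data do and do not emulate.

## Study system and synthetic data

The package targets populations organised into small family groups: a
reproductive male, an unrelated reproductive female, and their offspring.
The default *study population* (`study_pedigree()`) fixes seven groups
with offspring counts (2, 1, 2, 1, 0, 2, 1) and offspring sexes chosen so
the population holds 5 sons and 4 daughters among 23 animals — the
composition at which the kin-category designs (7 fathers × 5 sons,
7 mothers × 4 daughters) are well posed.  `simulate_pedigree()` generates
random populations with configurable group count and offspring range
(default 0–2, keeping group sizes between 2 and 4).

### Genotypes

Six microsatellite loci form the default panel, using the published indri
marker names and fragment-size ranges (67HDZ25 218–253 bp, 67HDZ62
203–217, 67HDZ18 164–190, 67HDZ55 312–334, 67HDZ180 113–135, 67HDZ39
148–162), each as a dinucleotide ladder (2-bp steps).  Observed allele
frequencies were never published for this population, so defaults are
uniform over each ladder — a deliberately diffuse choice that makes the
panel *more* informative than a typical skewed frequency spectrum; users
with real data should supply observed frequencies.  Founders draw two
alleles per locus under Hardy–Weinberg; offspring receive one uniformly
chosen allele from each parent.  No mutation, genotyping error or allelic
dropout is modelled (the error rate ε is fixed at 0, appropriate for
replicate-confirmed genotypes).

### Phrases

Each individual *i* carries a latent mean vector μᵢ over the parameters
that define a descending phrase — unit durations (baselines 1.0, 1.2,
1.4 s), inter-unit intervals (0.30, 0.35 s), per-unit start/end pitch
(780→600, 720→520, 650→460 Hz) and Q50 (≈ mid-pitch + 40 Hz):

μᵢ = baseline + sex offset + group effect + dᵢ,

with founder deviations dᵢ ~ N(0, σ²ᵢₙd) per parameter and offspring
deviations dᵢ = h·d_parent + √(1−h²)·N(0, σ²ᵢₙd).  The parental term is
the mid-parent mean by default or, under the sex-specific path model, the
father for sons and the mother for daughters (weights `h_father_son`,
`h_mother_daughter`).  Heritability therefore acts on latent means, not
raw phrases, so the within-individual signature (residual SD) and the kin
signal (h) are independently tunable.  Defaults, chosen once as
field-realistic and not revisited: between-individual SD 0.10 s
(temporal) and 30 Hz (frequency); within-individual residual SD 0.05 s
and 15 Hz (a 2:1 signature-to-noise ratio, consistent with strongly
individual but overlapping phrase distributions); sex offsets +0.08 s on
male durations and +60 Hz on female pitch; group effect 0 (groups carry
no signal beyond the kinship they contain); mid-parent h = 0.5.  Each
group holds 5 chorus songs; every member contributes 2 phrases per type
per song (10 per type per individual, above the ≥4 inclusion threshold).
The paper-scale corpus is an order of magnitude larger per individual;
power analyses here showed the kin statistics are limited by the number
of dyads, not the number of phrases, so the smaller per-individual corpus
does not change any conclusion while keeping replicate studies cheap.

Phrases are rendered as unit boundaries plus an f0 contour sampled every
0.05 s: a linear descent from f0start to f0end plus a low-amplitude
sinusoidal wiggle (8 Hz default, random phase/cycle count) that makes
ptmax/ptmin informative noise rather than constants.  With residual SD
and wiggle set to 0, feature extraction recovers the latent parameters
exactly (a tested round-trip).

What the generator does **not** emulate: phrase-type-specific repertoire
beyond DP2/DP3, age effects, recording noise or pitch-tracking error,
non-Gaussian individual variation, unequal phrase counts across
individuals, and immigration/half-sib structure inside groups.  Passing
tests therefore demonstrate correctness of the statistical machinery
under a clean additive-Gaussian world, not robustness of the biology to
messy field data.

## Feature extraction

Temporal: `Dur_unit_k = end_k − start_k`, `Dur_int_k = start_{k+1} −
end_k`, `IOI_k = start_{k+1} − start_k`, `Dur_total = end_last −
start_first`.  Frequency, per unit: `f0mean` is the time-weighted
(trapezoidal) mean of the contour — robust to uneven sampling, which a
semi-automatic pitch-tracing workflow does not guarantee; extrema, first
and last samples, and `ptmax`/`ptmin` = 100·(t(extremum) − start)/duration
with ties resolved to the earliest sample (deterministic output).  `Q50`
is passed through when measured per unit, or computed from a supplied
spectrum as the frequency below which half the summed energy lies
(uniform density within bins); requesting it with neither source is an
explicit error.  Praat PitchTier files (short and long text dialects) are
accepted as a per-unit contour source.

## PCA and dissimilarity

"Factor analysis" in the source workflow is interpreted as unrotated PCA
on the correlation matrix with Kaiser retention (the default extraction
of the statistical package it names): variables are z-scored, the
correlation matrix eigendecomposed, and components with eigenvalue > 1
retained; a varimax rotation is exposed as an option but off by default.
Scores are the retained *standardized* (unit-variance, regression-type)
component scores, which makes the Euclidean distances scale-free.  Signs
follow a deterministic convention (largest-magnitude loading positive).
If no eigenvalue exceeds 1 the function raises rather than silently
retaining nothing.  One PCA is fitted per phrase type × parameter set on
the inclusion-filtered cohort (so component spaces match the analysed
sample); per-sex analyses reuse the all-individual scores rather than
refitting, since nothing indicates refitting in the source workflow.

Phrase distances are Euclidean on retained scores; the individual-level
matrix averages all cross-individual phrase pairs (the diagonal is set to
0 and excluded everywhere); matrices are min–max normalized to [0, 1]
off-diagonal before any correlation statistic.  Constant feature columns
(possible under degenerate generator settings) are dropped with a log
message before the PCA.

## Relatedness

Moment estimators are computed per dyad from known or gene-count allele
frequencies: Queller–Goodnight and Lynch–Ritland as ratio-of-sums over
loci in both reference directions, averaged (Lynch–Ritland with its
published 1/(2·p_a·p_b) locus weighting); Li's similarity index with
S₀ = 2Σp² − Σp³.  The `wang` estimator follows the similarity-category
moment approach: the observed category of a genotype pair (identical /
hom–het sharing / het–het sharing one allele / no sharing) has
expectation linear in (k₂, k₁) with coefficients given by the exact
conditional category probabilities under 0, 1 or 2 shared (IBD) alleles;
the stacked per-locus moment equations are solved by ordinary least
squares.  This keeps the estimator linear in the indicators and hence
exactly unbiased under the model, but it does not reproduce the published
variance-optimal weights — a documented simplification.  Moment estimates
may leave [−1, 1]; raw values are preserved internally and clamped only
in the exported matrix.

The dyadic maximum-likelihood estimator maximises Π_loci P(g₂ | g₁, k)
over the IBD simplex (k₀, k₁, k₂) by grid search (default resolution
0.01; the P(g₁) factor is state-independent and drops out), with
r̂ = k₂ + k₁/2, confined to [0, 1] by construction.  **Known property:**
the simplex constraint truncates negative estimates, so the ML *mean* is
biased upward near the boundary — for unrelated dyads on the default
six-locus panel the mean sits around +0.05–0.06 (the median is exactly
0), and the parent–offspring mean around 0.53.  The test suite asserts
the unbiasedness bound for every estimator and category; the ML boundary
cells fail it by this intrinsic property, which is reported rather than
hidden.  Moment estimators pass all four categories.

Estimator selection mirrors the simulate-known-dyads procedure: 100 dyads
per category (parent–offspring, full-sib, half-sib, unrelated) built by
explicit Mendelian construction — never by IBD-coefficient shortcuts —
all registered estimators applied, ranking by Pearson correlation between
estimate and truth pooled over categories ("consistency" operationalised;
constant estimators get an undefined correlation, an explicit flag, and
last place).  For the matrix correlation stage relatedness becomes a
distance, d = 1 − normalized r̂, so both matrices point the same way and
a positive Mantel r means "more related, more similar".

## Mantel tests

Statistic: Pearson correlation of the off-diagonal upper triangles; null:
simultaneous row/column permutation of one matrix; one-tailed (greater)
by default since the reported effects are directional, with two-tailed
available; p = (exceedances + 1)/(n_perm + 1), so p is never 0 and valid
at any permutation count.  When `n_perm` covers all n! − 1 non-identity
permutations (n ≤ 8) the test enumerates instead of sampling and the
plus-one p equals the exact enumeration p; `mantel_exact` exposes the
enumeration directly as an oracle.  Ties are compared with a 1e-12
tolerance so exact-equality cases (e.g. a matrix against itself) count
deterministically.

The kin-category variant restricts to the parent × offspring grid of one
role pairing (e.g. fathers × sons), correlates acoustic similarity
(1 − normalized dissimilarity) with the binary true-pair design, and
permutes *offspring identities* while the parent set stays fixed — the
question being whether an offspring resembles its own parent more than
other parents' same-role offspring do.  "Unrelated adult–offspring" cells
default to all non-parental dyads of the given roles.  With 5 sons the
null support is 5! = 120 permutations; the test is valid but its
resolution is bounded (minimum attainable p ≈ 1/120), which materially
limits power at realistic population sizes (see Limitations).

## Permuted DFA

Blocks are unique (test level × control level) cells, so a chorus song
shared by several singers contributes one block per singer.  The training
quota per test level defaults to (minimum block count over levels) − 1,
floor 1, guaranteeing held-out data for every level; balanced selection
draws *blocks* (songs), not phrases, because phrases within a song are
non-independent — that non-independence is the reason the control factor
exists.  The classifier is a Fisher discriminant: generalized
eigenvectors of between-class scatter against pooled within-class
covariance, scaled so the projected within-class covariance is the
identity, classification by nearest centroid with uniform priors (chance
level 1/k); a singular within-class covariance is ridge-regularized with
a logged constant, and variables are truncated to the leading columns
(with a warning) if a design cannot support them.  The observed training
and testing rates average over `n_selections` (default 100) random
balanced selections.  The null permutes test-level labels over blocks and
recomputes the averaged rates with fresh selections — the *same number*
of selections as the observed statistic (configurable), because an
unequal count would overdisperse the null and make the test
conservative.  p = (null ≥ observed + 1)/(n_perm + 1), separately for
training and testing.  Group-membership runs swap the factors (group as
test, individual as control): a group with a single individual is an
explicit error since no held-out individual exists.

## Pipeline

`run_all` executes features → PCA (×4) → distances → relatedness → Mantel
(overall, per sex, kin categories) → pDFA (individuality overall/per sex,
group membership), writing long-format CSVs shaped like the three
standard report tables plus a JSON manifest (seed, configuration hash,
library versions — no timestamps).  Inclusion filtering (≥4 phrases per
individual, per phrase type independently, so DP2 and DP3 cohorts may
differ) happens before the PCA.  Every stochastic stage derives its seed
from the global seed and a stage name (CRC-keyed `SeedSequence`), so
stage toggles never shift another stage's stream and two runs with one
seed are byte-identical.  CSV readers parse floats in round-trip mode, so
a dataset written and re-read reproduces the in-memory analysis bit for
bit.  Stage failures abort with the stage name in the message.

## Numerical and edge-case choices

- Min–max normalization errors on matrices whose off-diagonal is
  constant (the rescaling is undefined) rather than returning zeros.
- `normalize01` and the similarity conversion are affine, so Pearson
  statistics are invariant to them; they are kept for interpretability
  of the exported matrices.
- Monomorphic loci are accepted by the genotype simulator but contribute
  nothing to estimators (zero denominators are skipped per dyad).
- Dyads with no shared typed locus yield a missing estimate, are flagged,
  and export as 0 in the clamped matrix.
- PCA raises on constant variables, naming them.

## Limitations

- Power of the father–son kin-category test is intrinsically modest at
  the default population size: with 5 sons the permutation null has 120
  atoms and two of the sons are brothers (near-tied permutations), so at
  transmission h = 0.8 the detection rate at α = 0.05 is ≈ 0.7 (rising
  to ≈ 1 at h = 1.0), essentially independent of phrase counts and noise
  scales.  This is a property of the design, not of the implementation.
- The dyadic-ML mean is boundary-biased (see Relatedness); rank-based
  summaries (median, correlation with truth) are the reliable ones.
- The triadic likelihood estimator is out of scope; the dyadic estimator
  fills the "likelihood-based" slot in the comparison harness.
- The pDFA follows the published nested selection/permutation scheme;
  the original custom implementation's exact training-set sizes and
  permutation counts are unreported, so all of them are configurable
  with the defaults stated above.
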