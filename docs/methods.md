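# Methods

`genoscape` re-implements, as a tested pipeline over synthetic cohorts, an
energy-landscape approach to discovering genetic subtypes of a complex
disease from case-control genotype data. This note documents the models,
the numerical choices, what the synthetic cohorts do and do not emulate,
and the known limitations.

## The analysis pipeline

### Marker and sample quality control

Variants are filtered in a fixed, reported order: call rate (default
≥ 0.95), minor allele frequency (≥ 0.001), and a Hardy–Weinberg exact
test (p ≥ 0.001). The HWE test conditions on the observed allele counts
and sums the exact probabilities of every heterozygote count no more
probable than the observed one. By default it is computed **in controls
only** — the standard practice, since genuine case-only association
signal would otherwise be discarded as genotyping failure; a flag
switches to all subjects.

Samples are then filtered by per-subject missingness (≤ 0.05), the
method-of-moments inbreeding coefficient |F| ≤ 0.1 with
F = (E_het − O_het)/E_het and expectations 2p(1−p) summed over the
subject's non-missing variants, and pairwise relatedness PI_HAT =
P(IBD=1)/2 + P(IBD=2) ≤ 0.25. PI_HAT is method-of-moments on IBS counts;
the Hardy–Weinberg expectations use unbiased estimators of the
allele-frequency monomials (falling factorials of allele counts), which
matters at small sample sizes — with naive plug-in frequencies the
estimator is noticeably inflated. Of a flagged pair, the member with the
higher missingness is removed. For speed, PI_HAT is computed on at most
500 evenly thinned variants with complete calls preferred; at that panel
size the null sampling noise is ≲ 0.05, far from the 0.25 threshold.

LD pruning is the greedy windowed rule of `--indep-pairwise 50 5 0.1`: a
50-variant window slides in 5-variant steps; within a window the pair
with the highest squared dosage correlation above 0.1 repeatedly loses
one member until none violates. The removed member is the lower-MAF
variant, ties broken toward the later position (the reference tool's
internal tie rule is undocumented; this rule is fixed here and pinned by
tests). r² is computed over pairwise-complete subjects on dosages
(allele-count correlation), since phase is unavailable.

### Association scan

Each variant is tested with the covariate-adjusted logistic model

    logit P(case_i) = β0 + β1·age_i + β2·sex_i + β3·dosage_i

fit by damped Newton/IRLS on complete cases (subjects with a call at that
variant), convergence when the maximum absolute score drops below 1e-8,
at most 50 iterations. Sex (1=male, 2=female) enters centered, age in
years uncentered; the intercept is not interpreted. Wald statistics are
reported for β3 (matching the reference tool's `--logistic` semantics
rather than likelihood-ratio tests). Monomorphic dosages, perfect
separation (|β| > 12 on the logit scale) and non-convergence are flagged
per-row, never raised; flagged rows are excluded downstream. Variants
with p < 0.01 form the signal panel, each carrying its coefficient β3 as
a weight.

### Coefficient-weighted PCA and binarization

Signal-panel dosages are mean-imputed per variant, standardized,
multiplied by their coefficients, and decomposed by SVD. Each subject's
first N = 7 PC scores are binarized to a spin σ ∈ {−1, +1} at the
across-subject mean of that component's scores (σ = +1 when the score is
at or above the mean). This is the one consequential interpretation made
of the construction "binarized by the mean of the eigenvector values":
thresholding each subject's score at the across-subject component mean is
the only reading that yields one ±1 per subject per component. The
per-component thresholds, imputation means, scalings and loadings are
stored, so validation subjects are mapped with the training-time rule and
never re-thresholded. Whether genotypes should be standardized before
weighting is genuinely open; standardization is the default and is
exposed as a flag. Loading signs are fixed (largest-magnitude entry
positive) so results are reproducible across BLAS implementations.

### Pairwise maximum-entropy landscape

The empirical distribution of the 2^7 spin states is fit with the
pairwise maximum-entropy (Boltzmann/Ising) model

    P(V) ∝ exp(Σ_i h_i σ_i + Σ_{i<j} J_ij σ_i σ_j),
    E(V) = −Σ_i h_i σ_i − Σ_{i<j} J_ij σ_i σ_j,

by plain gradient ascent on the log-likelihood with **exact** model
moments from full state enumeration (no sampling; feasible to N ≈ 20):
h_i ← h_i + lr·(⟨σ_i⟩_emp − ⟨σ_i⟩_model) and likewise for J, learning
rate 0.1, stopping when every moment gap is below 1e-6, cap 1e5
iterations (exceeding the cap raises, carrying the final gap). Empirical
moments at exactly ±1 (a component constant in the data) are shrunk by
1e-6 toward zero so finite parameters exist.

State index ↔ spin convention: bit i of the index is set iff σ_{i+1} =
+1, component 1 being the least significant bit. All tie-breaks (minima,
descent, state ordering) are lexicographic by (energy, state index); they
are arbitrary but fixed and tested.

A state is a local minimum iff its energy is strictly below all N
single-flip neighbours (exact ties award the minimum to the lowest state
index on the plateau). Basins are steepest single-flip descent; the
disconnectivity tree is built by inserting states in (energy, index)
order into a union–find over the hypercube adjacency, recording a merge
node at the inserted state's energy whenever two components containing
minima first connect — internal-node heights then equal the minimax path
barriers, which the test suite verifies against exhaustive path search.
Cutting the tree at its root (the highest barrier) yields the two-group
split; group 1 contains the global minimum by convention. Landscape nodes
are **basins** (not raw occupied states); each node's case and control
occupancy gives case_frequency (fraction of all cases in that basin),
control_frequency, their difference, and the red/green/gray color by its
sign.

### Downstream statistics

Representative clusters are the nodes of each group where case and
control frequencies differ by more than 5% (strict inequality).
Within-cluster association re-runs the logistic scan restricted to the
basin subjects, Bonferroni-corrected over the variants actually tested in
that selection. The APOE4 allele-count comparison uses the 2×3
genotype-category table (0/1/2 alleles) with a two-sided
Fisher–Freeman–Halton exact test: the sum of conditional probabilities of
all margin-fixed tables no more probable than the observed one. 2×c
tables are enumerated with a vectorized inner column (the bundled
reference table, total n ≈ 4,000, runs in well under a second); larger
tables fall back to plain recursion, practical only for small margins.
Carrier percentages are 100·(n1+n2)/total to two decimals. Kendall's τ-b
(tie-corrected) correlates per-node case frequency with per-node carrier
frequency across occupied landscape nodes. Biomarker comparisons use the
two-sided Wilcoxon rank-sum test (exact enumeration when both arms have
n ≤ 10 without ties, else the normal approximation with tie and
continuity correction), with Benjamini–Hochberg q-values within the
five-kidney-marker family of each group; HbA1c is tested separately,
uncorrected. The eQTL analysis is OLS of expression on dosage adjusting
for age and sex, with a t-test on the dosage coefficient and an explicit
degenerate-predictor error when dosage has zero variance.

### Subtype predictor

A fully connected network regresses the N PC scores on standardized
dosages at the signal variants present in both cohorts. The reference
architecture is six hidden layers of 512 neurons with randomized leaky
rectifier activation (negative slopes uniform on [1/8, 1/3] during
training, their mean at evaluation), 50% inverted dropout, batch size 32,
checkpoints on an epoch grid 100..1500 in steps of 100. Since no deep
learning framework is a dependency, the network is a compact numpy
implementation (Adam, mean-squared error on standardized targets);
training is deterministic given the seed. The loss is MSE because the
task is score regression; the checkpoint kept is the one with the best
discovery-cohort node accuracy (model selection never touches the
validation cohort). At desk scale the pipeline uses a reduced
architecture (`NetConfig.small()`: two hidden layers of 64, epoch grid
20..100) purely for turnaround; the full architecture is the default of
`NetConfig`.

Predicted scores are binarized with the **stored** landscape thresholds,
each subject descends to a basin, and accuracy is node-based: a case
counts as correct iff its basin is red and (when a true group is defined)
of the subject's true group; a control iff green with the same condition;
gray basins never score. For validation subjects the "true group" is the
basin group of their directly binarized PCA projection, with variants
absent from the validation panel imputed at the training means — the
reference analysis does not define validation ground truth, and this is
the natural in-model surrogate. A 10-output mode (components 8–10
predicted but not binarized) exists because the source description of the
predictor mentions ten scores while the landscape uses seven; neither
reading is asserted as exact.

## The synthetic cohort generator

No genotype data are deposited for the motivating study, so the generator
is first-class, tested code that emulates the statistical structure the
analysis assumes. Defaults are desk-scale study conditions: a discovery
cohort of 941 cases / 1,059 controls (preserving the reference cohort's
case fraction at 2,000 subjects) by 5,000 variants, and a paired
validation cohort sharing 80% of variant identifiers;
`CohortConfig.discovery_scale()` / `validation_scale()` give the full
cohort sizes (1,947/2,192 and 847/2,298).

**Genotypes.** Variants live in LD blocks of five: each block opens with
an LD-independent seed variant followed by a copy-with-resampling chain
(entries redrawn from Binomial(2, MAF) with probability 0.15 per step),
so pairwise r² decays geometrically with distance and the pruning stage
has realistic work to do. Block MAFs are uniform on [0.05, 0.5]. A
coalescent simulator would be more realistic but is unnecessary to
exercise r² pruning.

**Latent subtypes.** Every subject carries a uniform latent subtype
(default two). Each subtype owns a disjoint causal set (12 variants,
chosen among common block seeds) and, within each subtype, subjects fall
into one of three latent genotype clusters — an idealization of
haplotype-group structure. On the causal panel a subject's latent value
is m0 (own-set variants, +; other-set, −) plus m1 times the cluster's ±1
profile plus unit Gaussian noise (defaults m0 = 0.75, m1 = 0.9; cluster
profiles share a subtype-level base pattern with 30% per-entry flips). A
probability integral transform through the exact pooled mixture CDF maps
latents to dosages, so every variant's pooled marginal is exactly
Hardy–Weinberg at its generating MAF: the subtype structure lives purely
in the cross-variant dependence, which is what keeps it (mostly) below
the HWE filter and the r² = 0.1 pruning threshold. A four-variant
APOE-region-like block, aligned with subtype 1 (separation 0.6), mimics a
strong shared risk region enriched in one subtype.

**Phenotypes.** Case status is drawn from the logistic liability

    logit P(case) = b0 + b_age·age + b_sex·female + Σ_g β_g·g

over the subject's own causal set (per-allele log-odds uniform on
[1.5, 2.2] — within the reference study's reported within-cluster
odds-ratio range — with set loads equalized across subtypes so neither
dominates the case quota) plus the shared block (effect 1.1 per allele,
plus log 2 for subtype-1 subjects). Ages are Gaussian and sex Bernoulli,
with b_age and b_sex derived from the configured case/control age means
(79.1 vs 70.8 years, SD 6.1) and female odds (2.13 vs 1.19), so the
adjustment model downstream is exactly well-specified. The intercept is
calibrated so the genetically unloaded background attains the population
prevalence (8% reduced to 5% under the default strong-effect regime);
exact case/control totals are then met by retrospective rejection
sampling of candidates, capped at 100× the requested total (beyond which
the generator errors rather than silently distorting prevalence). Cases
end up older, more often female, and enriched for risk alleles — the
selection the GWAS stage must then detect and adjust for.

**Biomarkers and expression.** Six routine blood measures are Gaussian
with clinically plausible means (albumin 4.2 ± 0.35 g/dL, hemoglobin
13.5 ± 1.5 g/dL, creatinine 0.8 ± 0.2 mg/dL, cystatin C 1.0 ± 0.25 mg/L,
eGFR 70 ± 15, HbA1c 5.8 ± 0.6%), truncated positive; albumin and
hemoglobin are depressed by 0.5 generative SD in subtype-2 cases only, so
biomarker effects attach to the latent subtype (not the inferred group)
and parameter-recovery tests are well-defined. One cis-eQTL pair is
simulated as expression = intercept + β·dosage + small age/sex nuisance
terms + Gaussian noise.

**What the generator does not emulate.** No imputation, phasing,
recombination maps, or population structure beyond what the subtype
mixture induces; no X chromosome; no genotyping batch effects; biomarkers
are independent Gaussians rather than correlated clinical measurements.
Passing tests on these cohorts demonstrate that the pipeline's machinery
is correct and that its statistical behavior matches theory at this
scale — not that the method would make the same discoveries on real
genotype data.

## Known limitations

The most important one is structural and affects the two-group subtype
recovery property. The weighted PCA concentrates the genotype footprint
of a single binary latent subtype into essentially one principal
component (orthogonal score columns cannot share a mean separation unless
eigenvalues are degenerate), so after binarization the subtype is encoded
in a single spin whose marginal is a balanced coin. A *pairwise*
maximum-entropy model assigns no energy structure to an uncoupled
balanced spin: basins and barriers are driven by whatever couplings
exist, and the root cut of the disconnectivity tree therefore does not
reliably select the subtype axis even when the subtype bit itself is
recovered almost perfectly (bit–subtype correlation 0.9+ across seeds at
the default settings). Couplings can be engineered onto the subtype bit
through the cluster and shared-block structure, but their strength is
capped by the r² < 0.1 pruning wall and the HWE filter, and across random
cohorts the resulting two-group split matches the latent subtype well in
only a minority of replicates (when it does, the case-ARI is 0.25–0.6;
otherwise near 0). The out-of-cohort prediction property is insensitive
to this alignment and holds consistently. At N = 7 the exact-enumeration
maxent fit is exact and fast; the implementation refuses N > 20.

Bonferroni counts, FDR families and the 5% representative-cluster cutoff
follow the reference analysis; the per-selection test count m is the
number of unflagged variants actually tested in that selection. The
Fisher–Freeman–Halton recursion is exponential in the table margins and
intended for demographic-scale tables only.
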