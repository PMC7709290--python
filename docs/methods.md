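# Methods

This note records the modelling assumptions, defaults and numerical
choices behind `stepblup`, and what the synthetic benchmark does and does
not demonstrate.

## Relationship matrices

**Pedigree A.** Built by the tabular method in topological order
(parents before offspring; ties broken by input order so results are
reproducible). Unknown parents are treated as unrelated, non-inbred
founders; no unknown-parent groups or metafounders. Inbreeding is
accounted for throughout: diag(A) = 1 + F with F from a Meuwissen–Luo
style accumulation, and Henderson's sparse A⁻¹ uses Mendelian sampling
variances 0.5 − 0.25(F_s + F_d) (both parents known), 0.75 − 0.25 F_p
(one), 1 (none). A flag disables the inbreeding adjustment for
comparison with software that ignores it; the default keeps it, matching
the long-standing default of the standard evaluation tool suites. A is
stored dense (the package targets up to a few thousand animals); A⁻¹ is
always sparse.

**Genomic G.** VanRaden's first method: G = MM′ / 2Σ pᵢ(1−pᵢ), with
dosages centered by 2pᵢ. Allele frequencies are those observed among the
post-QC genotyped animals; base-population frequencies are rarely
available in practice and are not estimated. A provided-frequency mode
exists (used by tests and simulations where the founder frequencies are
known). Monomorphic markers contribute zero to numerator and denominator
and trigger a warning, not an error. No rescaling of G toward A₂₂ means
is applied: the single-step combination below is exactly the stated
95/5 blend and nothing else.

**Single-step H⁻¹.** Assembled as A⁻¹ plus the genotyped-block
correction (w_g G + w_a A₂₂)⁻¹ − A₂₂⁻¹, default weights 0.95/0.05,
configurable. Inversions use Cholesky factorization of the
symmetric-positive-definite blocks; a non-PD blend or A₂₂ raises an
error carrying the condition number rather than silently adding ridge
beyond the blend. Two exact identities pin the implementation down and
are enforced in tests: with G := A₂₂ the correction vanishes (H⁻¹ = A⁻¹
for any weights), and with no genotyped animals H⁻¹ = A⁻¹.

## Genotype quality control

Filters run in a fixed order — animal missingness, then per SNP: unknown
map position, non-autosomal chromosome (default autosome labels 1–29,
cattle), call rate, minor allele frequency, heterozygosity departure
|obs_het − 2p(1−p)| — each step computed only on markers surviving the
previous ones, so the removal ledger is well defined. Inequalities are
strict on the failing side: an animal fails when missingness > 0.10, a
SNP fails when call rate < 0.98, MAF < 0.01, or departure > 0.15. The
`QCReport` enforces the accounting identity n_remaining(k) =
n_remaining(k−1) − n_removed(k) at every step.

**Parentage and identity checks.** Sire–offspring pairs from the
pedigree are screened by the opposing-homozygote rate (0 vs 2 among
jointly non-missing calls); pairs above 2% are flagged, and pairs with
no informative marker get a NaN sentinel and a review flag. Pedigree–
genomic conflicts are classified from the (G, A₂₂) coefficient pairs:
`missed_relative` when G ≥ 0.15 and A ≤ 0.05, `false_relative` when
A ≥ 0.15 and G ≤ 0.05 (recorded half-sibs that are genomically
unrelated), thresholds configurable. For duplicates the nominal rule
"G ≥ 0.9" is scaled by the pair's smaller diagonal when that diagonal is
below 1: a duplicated sample satisfies G_ij ≈ G_ii ≈ G_jj, and with
observed-frequency centering the self-relationship of a
low-heterozygosity animal legitimately sits below 0.9, so the unscaled
rule has structural false negatives. The default threshold itself stays
at 0.9.

**Imputation.** Missing post-QC dosages are replaced by the per-SNP mean
2p̂. At the ~2% missingness the pipeline targets, mean imputation
perturbs G negligibly; it is a deliberate, simple substitute for
haplotype-based imputation, which is out of scope. Imputed panels carry
real-valued dosages and are marked as such.

## Variance components (AI-REML)

The single-trait animal model y = Xb + Zu + e is fitted by restricted
maximum likelihood over (σ²ₐ, σ²ₑ). Numerically the likelihood is
evaluated in the eigenbasis of ZKZ′: one symmetric eigendecomposition
makes V = σ²ₐD + σ²ₑI diagonal, after which each iteration (score,
average-information matrix, REML log-likelihood) costs O(n p²). This is
exact, needs no sparse factorization machinery, and is comfortably fast
to n ≈ 5,000 records. Updates are average-information Newton steps with
monotone step-halving — a proposal that would leave the parameter space
or decrease the restricted likelihood is halved until acceptable — so
the log-likelihood is non-decreasing across iterations. Convergence is
declared at relative parameter change < 1e-8 (default, configurable);
σ²ₐ estimates at the positivity floor are flagged `boundary` rather than
raised, and a singular average-information matrix (e.g. K = I with one
record per animal, where only σ²ₐ + σ²ₑ is identifiable) stops the fit
with a warning and `converged=False`. Standard errors come from the
inverse AI matrix at convergence; the h² standard error uses the delta
method. Initialization is σ²ₐ = σ²ₑ = var(y)/2 unless supplied.

Fixed effects use reference-level dummy coding with levels in first-seen
order; columns aliased with earlier ones are dropped deterministically
(first-seen kept) by incremental Gram–Schmidt, and the dropped names are
reported.

## Prediction models

Phenotypes are adjusted once, on the full data, by OLS on the fixed
effects (y_adj = y − Xb̂); adjusted phenotypes then enter
y_adj = 1μ + Zu + e. Variance components estimated under the full animal
model are reused for all four prediction variants (per-fold
re-estimation is available but off by default: the evaluation design
adjusts first, predicts second). The mixed model equations are solved
directly; when only K is available (G, truncated A) the equivalent
u = Kα substitution avoids forming K⁻¹, and when K⁻¹ is the natural
object (A⁻¹, H⁻¹) the standard form is used — the two paths agree to
1e-8 on random instances and both match the closed-form GLS BLUP
u = σ²ₐKZ′V⁻¹(y_adj − 1μ̂). Every animal in the relationship structure
receives an EBV, including phenotype-masked ones.

PBLUP-G restricts both phenotypes and pedigree to genotyped animals,
with parents outside the genotyped set treated as unknown (the stricter
reading of "pedigree on genotyped animals only"); a flag switches to the
full-ancestry A₂₂ block instead, since the looser reading is also
defensible.

## Cross-validation

Genotyped animals are partitioned into k = 5 folds by k-means on the
rows of A₂₂ (Euclidean distance, 10 restarts, best inertia, fixed seed),
which minimizes training–validation relatedness and yields unequal fold
sizes by design. Per fold, validation phenotypes are masked, each model
is refit, and on the validation set: accuracy = cor(y_adj, EBV)/√h² with
h² the full-data REML estimate; slope = regression of y_adj on EBV;
RMSE = √mean((y_adj − EBV)²). Aggregation is the unweighted fold mean
with SE = sd/√k; a pooled-correlation accuracy across all validation
animals is also available, since fold-mean and pooled versions can
differ. Bias summaries (mean slope, mean |slope − 1| across traits) are
rounded to two decimals for reporting. The package bundles the ten
published per-trait dispersion slopes for the four models from the
Hanwoo body-measurement evaluation as `REFERENCE_SLOPES`, used as input
to these summaries and as a regression target for their arithmetic.

## Synthetic data

The generator emulates the data shape the pipeline consumes, at roughly
one tenth of the motivating study's scale. Defaults: 150 founders, 11
discrete generations, 25 sires × 5 dams per generation (~1,400 animals,
all phenotyped), the last two generations 60% genotyped (~150 animals),
3,500 independent biallelic SNPs with Beta(2,2) founder frequencies, 300
QTL, ten traits with heritabilities 0.40, 0.19, 0.20, 0.17, 0.11, 0.39,
0.11, 0.17, 0.16, 0.13, two categorical fixed effects (16 and 11
levels, effect sd 0.5 on a unit-phenotypic-variance scale), an age
covariate on 330–390 days with slope 0.02/day, and 2% random missing
genotypes. Phenotypic variance is normalized to 1 per trait, so
σ²ₐ = h².

Genotypes are gene-dropped: founders draw Binomial(2, pᵢ), offspring
receive one allele per parent by Mendelian segregation, no linkage.
Breeding values have two modes: pure-QTL (a centered-dosage × effect sum,
scaled to the nominal σ²ₐ in the base generation) and the default
QTL + polygenic mix (50/50 in variance), whose pedigree-polygenic term —
a Mendelian-sampling recursion down the true pedigree — gives
non-genotyped relatives genuine information and thus makes the
structural advantage of single-step evaluation visible. Planted defects
for QC testing: duplicate genotyped pairs (one row copied over another),
wrong-sire recordings among last-generation animals (the recorded sire
is a contemporary sire, the genotypes follow the true one), and
high-missingness animals.

What passing tests on this generator do **not** show: behaviour under
linkage disequilibrium and realistic MAF spectra, selection and
assortative mating across generations, genotype-by-environment effects,
heterogeneous variances, or the absolute accuracy levels of any real
population — the benchmark supports relative statements (model
rankings, parameter recovery, detector sensitivity), not transferable
accuracy values.

## Benchmark sizes and observed behaviour

The acceptance script and test suite use: 2,000-record populations ×
20 replicates for REML recovery (mean ĥ² within ±0.05 of 0.40 and 0.11);
20 replicate default-profile populations, two traits each, for the model
comparison, where ssGBLUP's fold-mean accuracy exceeds GBLUP's and
PBLUP-G's in ~19/20 replicates (one-sided sign test p < 0.05) and its
RMSE is the lowest — the qualitative pattern the single-step literature
reports. At this scale GBLUP trails full-pedigree PBLUP clearly (150
genotyped animals are a small reference), which is the expected
small-reference regime. These sizes were chosen to make the Monte-Carlo
error small relative to the tolerances while keeping a full run on one
desktop CPU in minutes.

## Known limitations

- Dense A and eigendecomposition-based REML cap practical problem size
  around ~10⁴ animals; APY-style approximations are out of scope.
- Single-trait models only; no maternal, permanent-environment, or
  dominance effects; no reliability/PEV reporting from the MME inverse.
- Mean imputation is inadequate above a few percent missingness; run the
  call-rate filter first (the panel-wide error for an all-missing SNP is
  deliberate).
- The conflict classifier's "close to" thresholds are heuristics;
  borderline relationships (e.g. true half-sibs with unusually low
  realized sharing) can be misclassified and should be reviewed, not
  auto-dropped.
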