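# Methods

This note records the models, conventions and design choices behind
`panelforge`, in the spirit of a statistical package's model documentation:
what each stage assumes, which defaults matter and why, what the synthetic
data do and do not emulate, and where the known limitations are.

## Data model and coordinate conventions

Genotypes live in a samples × markers matrix of diploid ALT-allele dosages
{0, 1, 2}, with −1 for missing. Coordinates are 1-based inclusive throughout
(VCF convention); BED output converts to 0-based half-open at the boundary and
that conversion is unit-tested. REF/ALT are taken verbatim from the source
file — no strand normalization at load time; cross-platform harmonization is
done explicitly (and logged) in the concordance stage. Phase is ignored: the
whole workflow is dosage-based. Indels and other non-SNP records are skipped
with a counted log entry; sites with more than two observed alleles are
excluded from the matrix but reported with per-allele carrier counts, so the
reader never silently drops a record.

## Synthetic data: what is emulated

The generator reproduces the statistical features of a multi-site wild rodent
study that the downstream stages are sensitive to:

* **Drift structure.** Population allele frequencies follow the
  Balding–Nichols model around ancestral frequencies drawn Uniform(0.05,
  0.95) (the range avoids a preponderance of monomorphic draws and is
  configurable): p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so E[p_k] = p and
  Var[p_k] = F·p(1−p). F = 0 short-circuits to p exactly; F = 1 is rejected.
  Populations drift independently from the ancestor ("star") by default; a
  "chain" option drifts each population from its neighbour to mimic isolation
  by distance. F defaults to 0.1, a farm-scale degree of differentiation that
  is strong enough to assign individuals yet weak enough that single markers
  are uninformative.
* **Local LD.** Markers in a block share one latent uniform per haplotype,
  re-drawn with probability `ld_leak` per marker; block members also share
  their ancestral frequency and their drift draw. This produces high r²
  within blocks while preserving per-marker allele frequencies and
  Hardy–Weinberg proportions — sufficient to exercise windowed r² pruning.
  It is *not* a coalescent: LD decays geometrically within fixed blocks
  rather than with recombination distance, and no LD crosses block
  boundaries. Block members are placed 150 bp apart, blocks 50 kb apart, on
  19 autosomes plus X.
* **Pedigrees.** Family units (parent–offspring, full-sib, half-sib,
  first-cousin, plus lone founders) are built from fresh founders per unit and
  gene-dropped: founder haplotypes are Bernoulli(p) draws, each child receives
  one uniformly chosen allele from each parent per marker, independently
  across markers. Expected kinships come from the standard pedigree recursion,
  so the truth table is exact: 0.25 (1st degree), 0.125 (2nd), 0.0625 (3rd),
  0 otherwise. Independence across markers means realized kinship concentrates
  tightly around the expectation — real linked genomes would show more
  dyad-to-dyad spread.
* **Genotyping artefacts.** Missingness is i.i.d. Bernoulli per call (default
  5%, the array-scale regime); errors perturb a call to one of the other two
  dosages uniformly. Sequencing depth is negative-binomial per genotype with
  mean 27.6× and size 11 — the size is matched by moments to a depth SD of
  ~9.84× — and DP = 0 forces a missing call. GQ is a deterministic capped ramp
  min(99, round(3·DP)): no published GQ model is being imitated; only the
  GQ ≥ 30 threshold matters downstream, and the slope is chosen so the
  ≥10× depth regime clears it.
* **Not emulated.** Sex-specific inheritance (the X is placed but inherited
  autosomally), mutation, selection, batch effects, allele-specific capture
  bias, and reference-strand ambiguity. Passing tests therefore demonstrate
  correctness of the estimators under clean population-genetic assumptions,
  not robustness to platform-specific artefacts.

All randomness flows through one `numpy` generator seeded from the config;
identical configs give byte-identical output files (hash-checked in tests).

## QC semantics

Filters run in a fixed, documented order — samples by missingness, then
markers by missingness, MAF, optional quality masking, then LD pruning — and
every removed marker is attributed to exactly the first rule that fired, so
stage reports reconcile exactly with the marker counts. Boundary conventions
are explicit: missingness *≥ threshold* removes (a sample at exactly 10%
missing is excluded); MAF retention is inclusive (*≥ 0.05* retained,
monomorphic always removed) since "MAF > 0.05" and "minimum MAF of 0.05"
coexist in common usage; the quality stage masks genotypes with GQ < 30, then
drops markers with mean depth < 10× or masked missingness > 10%.

LD pruning uses a base-pair window (1 kb) anchored at the left marker and
advanced by a marker-count step, never crossing chromosomes; a marker-count
window is available behind a flag. r² is the squared Pearson correlation of
dosages over pairwise-complete observations (no imputation inside QC; fewer
than two complete pairs or zero variance defines r² = 0). When a pair
violates the threshold, the member with higher missingness is removed, ties
broken by lower MAF, then larger position — keeping the more informative
marker, deterministically. The implementation guarantees, and an exhaustive
audit verifies, that no surviving same-chromosome pair within the window
exceeds the threshold.

## PCA and DAPC

Standardization centres by mean dosage and scales by the binomial SD
√(2p̂(1−p̂)) — the variance a marker would have under Hardy–Weinberg — with
plain SD and no-scaling options; zero-variance markers get divisor 1. Missing
dosages are mean-imputed for the eigendecomposition only (QC happens
earlier), and the imputation/centring/scaling parameters are stored in the
model: new samples are always projected with training parameters, never
refit, which makes `predict` on the training data reproduce the training
scores exactly (tested to 1e−10).

The discriminant step solves the symmetric-definite generalized eigenproblem
with the within-group scatter normalized to n−g and axes scaled so
aᵀWa = 1; the number of axes is min(g−1, K). A singular within-scatter (K too
large for the training size) raises an error advising fewer PCs. Posterior
membership uses an isotropic Gaussian with equal priors in discriminant
space — the simple centroid-distance model; assignment ties break by
population order.

Cross-validation draws stratified train fractions per population (default
90%), evaluates the whole PC grid on the same splits (the PCA at the largest
grid value is computed once per replicate; smaller grid values are exact
nested column subsets), and reports per-K mean success and
RMSE = √(mean (1−success)²). The chosen K minimizes RMSE, ties to the smaller
K — when mean-success and RMSE disagree, RMSE wins and both are reported. The
default grid is 10 evenly spaced values up to min(n−g, markers, 100).

A calibration subtlety: on label-permuted null data, centroid classifiers
show the well-known below-chance cross-validation bias at small n (a held-out
sample is negatively correlated with its own class's training mean), and any
single permutation retains a persistent chance alignment with the genotypes.
The null-calibration test therefore averages several independent permutations
at n = 160 and takes the Monte-Carlo SD across permutation means.

## Panel selection

"Loading" is interpreted as the normalized squared contribution (the quantity
that ranks discriminatory markers regardless of sign); an absolute-signed
option exists. Per axis, the threshold is the requested empirical percentile
(linear-interpolation quantile) and selection is inclusive (≥), so threshold
ties all enter; the panel is the union over the leading axes — with two
overlapping top-5% sets this yields between 5% and 10% of markers, matching
how such panels come out larger than a single axis's tail. A pooled-threshold
mode is available. Markers on excluded chromosomes (MT by default — a
mitochondrial probe would swamp an enriched library) are dropped *after*
selection, with a count.

Probes are fixed-length intervals centred on the SNP; for even lengths the
SNP sits at base L/2 + 1 (the 61st base of 120), i.e. [pos−60, pos+59]
1-based inclusive. Intervals running off the chromosome start are shifted to
start at 1 and flagged. Sequence QC is advisory only: probes containing N or
homopolymer runs ≥ 15 are flagged, not removed (vendor off-target screening
is out of scope).

## Concordance, coverage, off-target

Concordance classifies every shared-sample × harmonized-shared-site cell into
exactly one of five categories (identical, discordant, missing-in-A-only,
missing-in-B-only, missing-in-both); percentages use the full cell grid as
denominator, which is the convention under which printed workflow numbers
like "0.66% discordant" reconcile with their cell counts. Allele
harmonization handles identical and swapped REF/ALT pairs (dosage
complemented, logged); any other combination drops the site into the log. No
strand flipping: the platforms this workflow compares share a reference
orientation.

Coverage profiling consumes a plain samples × targets depth table (alignment
is out of scope; the synthetic module emits the table) and reports
proportion-of-targets-≥t curves, which are non-increasing by construction.
Off-target classification measures |pos − nearest same-chromosome target|
("within 150 bp" inclusive; no target on the chromosome means infinitely
far), and groups far SNPs into clusters when consecutive far SNPs are ≤ 10 kb
apart — a deliberate operationalization of the qualitative observation that
distant off-target SNPs arrive in clumps.

## Kinship

The estimator follows the individual-specific-frequency moment form given in
the README. Three choices matter:

* **Unrelated training subset (default).** Fitting the PCA and the per-marker
  regressions on all samples lets a principal component capture a large
  family, which deflates that family's kinship estimates (observed errors up
  to −0.2 on simulated cousin clans). The default therefore selects a
  mutually unrelated training subset with the KING-robust within-family
  estimator — structure-robust for relative detection precisely because
  diverged-population pairs come out negative — via greedy removal of the
  sample with most remaining relatives (deterministic), then fits the
  frequency model on that subset and predicts μ̂ for everyone. This is a
  single partition pass, not the full iterative refinement of the original
  method; `training="all"` gives the unpartitioned behaviour.
* **Clipping.** μ̂ is clipped to [0.01, 0.99] and clipped markers still
  contribute, keeping per-dyad marker counts stable; an exclusion mode is a
  flag. With 0 PCs the estimator reduces *exactly* (tested to 1e−10) to the
  classical frequency-standardized kinship computed from all-sample allele
  frequencies.
* **Degree thresholds.** The powers-of-two midpoints (2^(−5/2), 2^(−7/2),
  2^(−9/2)) ≈ (0.177, 0.088, 0.044) separate 1st/2nd/3rd degree from
  unrelated; they are configurable, as no single convention is universal.

Pairwise sums run over markers where both genotypes are called; no imputation
inside the estimator. The diagonal of the moment ratio estimates (1+f)/2,
giving the per-sample inbreeding estimate. Under the default two-population
pedigree simulation (5,000 markers, 2 PCs) the per-class mean error is below
0.01 and unrelated cross-population dyads average |φ̂| < 0.01, while the
unadjusted (0-PC) estimator pushes cross-population dyads strongly negative —
the structure-robustness property the adjustment exists for. Known
limitations: no iterative re-partitioning, no k0/k2 Cotterman coefficients,
and estimates from few hundred markers are noise-limited (the cross-panel
correlation in the worked example is bounded by panel size, not by bias).

Cross-panel comparison matches dyads by unordered id pair over shared
samples and reports Pearson r with t = r√(df)/√(1−r²), df = dyads − 2.

## Pipeline and problem sizes

`run_pipeline` sequences simulate → QC → cross-validated DAPC → panel
selection → simulated capture re-genotyping → concordance/coverage/off-target
→ kinship on both panels, writing every artifact plus a manifest of content
hashes; identical config and seed reproduce the run byte for byte (the VCF
writer embeds no timestamps). CLI flags override config-file values.

Test and demonstration problem sizes are chosen so the full suite runs in
about a minute on one CPU while staying in the regimes the statistics need:
the assignment-success check uses the two-population F = 0.1 regime at 150
diploids per population and 3,500 unlinked markers with 100 cross-validation
replicates; kinship recovery uses 5,000 markers; the array-scale
design-then-validate loop uses a 49k-marker chip yielding a ~2.3k-marker
panel. Larger sizes change runtimes, not conclusions.
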