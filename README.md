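# panelforge

**Reduced SNP panel design and evaluation for structured wild populations.**

Wildlife management and invasive-species research increasingly rely on
population-genetic analyses of SNP genotypes: assigning trapped animals to
their source population, screening known resistance loci, and inferring kin
structure within sites. Dense commercial genotyping arrays deliver the marker
discovery, but are expensive per sample and carry many markers that are
uninformative in wild populations. A practical alternative is a *chip-to-panel*
workflow: genotype a discovery cohort on the dense array, find the few thousand
SNPs that actually discriminate the study populations, and build a targeted
hybridization-capture sequencing panel from them for routine genotyping.

`panelforge` implements that workflow end to end for diploid biallelic SNP
data (wild house mice on neighbouring farms are the motivating system):

1. **QC** — sample/marker missingness filters (≥10% removes), minor-allele
   frequency filter (monomorphic always removed; retain iff MAF ≥ 0.05), optional
   per-genotype quality masking (GQ ≥ 30, mean depth ≥ 10×, marker missingness
   ≤ 10%), and sliding-window LD pruning (1 kb window, step 1 marker, r² > 0.5).
2. **Structure** — genotype PCA and discriminant analysis of principal
   components (DAPC) with a-priori population labels, including the repeated
   stratified 90/10 cross-validation used both to pick the number of retained
   PCs (lowest RMSE) and to measure assignment success.
3. **Panel design** — markers in the 95th percentile of the contribution
   distribution on the leading discriminant axes (union across axes) become
   120-nt capture-probe targets, with BED/FASTA outputs and per-chromosome
   summaries.
4. **Evaluation** — five-way genotype concordance between platforms on
   allele-harmonized shared sites, per-sample target coverage curves,
   off-target SNP classification (within 150 bp of a target vs. distant
   clusters), and genotype screens at named loci.
5. **Kinship** — structure-adjusted pairwise kinship (the PC-Relate
   estimator), relationship-degree classification, and cross-panel kinship
   comparison.

A first-class **synthetic-data module** simulates the whole study system —
populations drifted under the Balding–Nichols model, local LD, Mendelian
pedigrees with known kinship truth, missingness, and negative-binomial
sequencing depth with GQ annotations — so every stage runs and is tested
against known truth without any external data.

## The statistics at the core

**DAPC.** Genotype dosages are standardized (centred by mean dosage, scaled by
the binomial SD √(2p̂(1−p̂))) and reduced to K principal components. The
discriminant axes *a* solve the generalized eigenproblem **B**a = λ**W**a
(between/within-group scatter of the PC scores), scaled so aᵀ**W**a = 1. The
per-marker *contribution* to axis d is the normalized squared loading
c_{jd} = B²_{jd}/Σ_j B²_{jd} (summing to 1 per axis); panel selection
thresholds these contributions. New samples are standardized with the
*training* parameters, projected, and assigned by an isotropic Gaussian
posterior around the group centroids in discriminant space.

**PC-Relate.** For each marker s, dosage is regressed on [1, PC₁…PC_K] by OLS;
half the fitted value is the individual-specific allele frequency μ̂_is
(clipped to [0.01, 0.99]). Kinship is

    φ̂_ij = Σ_s (g_is − 2μ̂_is)(g_js − 2μ̂_js)
           ───────────────────────────────────────────────
           4 Σ_s √(μ̂_is(1−μ̂_is)) √(μ̂_js(1−μ̂_js))

over markers where both genotypes are called. The PCA and the regressions are
fitted on a mutually unrelated training subset (selected deterministically
with the KING-robust within-family estimator) so that family structure cannot
leak into the frequency model; with K = 0 the estimator reduces exactly to the
classical frequency-standardized kinship. Degrees are classified at the
powers-of-two midpoints 2^(−5/2), 2^(−7/2), 2^(−9/2).

## Worked example

```python
import numpy as np
import panelforge as pf

# a study-like system: two farm populations (F_ST = 0.1) with embedded
# pedigrees, genotyped on a 12k-marker "chip"
cfg = pf.SimConfig(n_pops=2, n_per_pop=1, n_markers=12_000, fst=0.1,
                   miss_rate=0.02, seed=1)
design = pf.PedigreeDesign(n_parent_offspring=2, n_full_sib=2, n_half_sib=4,
                           n_cousin=4, n_unrelated=40)
ds, freqs, truth = pf.sim_study(cfg, design)

ds_qc, reports = pf.run_qc(ds)                      # 12,000 -> 11,119 markers
xval = pf.crossvalidate_dapc(ds_qc, [2, 10, 20, 40], n_rep=50, seed=1)
dapc = pf.fit_dapc(ds_qc, xval.chosen_k)
print(dapc.summary())

panel = pf.select_panel(dapc, percentile=95, n_axes=1)  # top 5% of loadings
capture = ds.restrict_to_keys(panel.marker_keys())       # "re-genotype" panel
capture, depth = pf.sim_seq_artifacts(capture, cfg, np.random.default_rng(2))
capture, _ = pf.run_qc(capture, min_gq=30, min_mean_dp=10, skip_ld=True)

print(pf.coverage_profile(depth).summary())
r, t, df, n = pf.compare_kinship(pf.pcrelate(ds_qc, 2), pf.pcrelate(capture, 2))
print(f"cross-panel kinship: r = {r:.3f}, t({df}) = {t:.2f}")
```

Output (abridged):

```
DAPC results
============
samples:            212
markers:            11119
populations:        pop1, pop2
PCs retained:       2  (PC variance kept: 11.4%)
discriminant axes:  1
  LD1: eigenvalue 554.8585, 100.0% of between-group variance
training re-assignment: 100.0%

Target coverage profile
=======================
grand mean depth: 27.6 (S.D. = 9.84)
samples with >90% of targets at >=10x: 212 / 212

cross-panel kinship: r = 0.631, t(22364) = 121.75
```

Reading it: held-out assignment success is 100% at every grid point (two
populations at F = 0.1 with >10k markers are cleanly separable, so the
RMSE-optimal K is the smallest), the simulated capture reproduces the ~27.6×
target-depth regime, and kinship from the 556-marker panel correlates r = 0.63
with the full-chip estimates — panel-side sampling noise at a few hundred
markers is the limiting factor, and the correlation rises towards ~0.85 when
the discovery chip (and hence the panel) is ~4× larger, as the array-scale
test in `tests/test_pipeline.py` verifies.

The same workflow is scriptable end to end from one YAML config:

```bash
panelforge run --config run.yaml      # or: panelforge sim / qc / dapc /
                                      # select / concordance / coverage /
                                      # offtarget / screen / kinship ...
```

Every run writes a parameter echo and a manifest with content hashes; the same
config and seed reproduce every artifact byte for byte.

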