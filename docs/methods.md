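# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Scaling

Features are **autoscaled** (centered, divided by the sample SD with the
n−1 denominator) before any network computation, so high-abundance dynamic
metabolites cannot dominate the correlation structure; **Pareto scaling**
(centered, divided by √SD) is provided for PCA-style QC, where preserving
some of the magnitude structure is conventional. Zero-variance columns are
dropped and reported rather than propagated as NaNs. Technical replicates
are averaged to line level before scaling, since all downstream models are
per-line. The pipeline expects a gap-filled intensity matrix: missing values
are tolerated only in genotypes (mean-imputed per SNP for kinship and PCs;
per-SNP tests drop the affected lines pairwise).

## Network construction and module detection

The adjacency is `w_ij = |r_ij|^β` on Pearson correlations — an *unsigned*
network, chosen so that a module can contain both branches of an inversely
co-regulated pathway. The soft power β sharpens the contrast between strong
and weak correlations; `pick_soft_threshold` implements the usual
scale-free-topology criterion (fit index `−sign(slope)·R²` of `log p(k)` vs
`log k`, threshold 0.8, fallback β = 6) and is deterministic. β = 6 is the
conventional unsigned default and what the examples use.

Modules come from average-linkage hierarchical clustering on `1 − TOM`,
where `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` is the
topological overlap of the adjacency (a raw-adjacency dissimilarity is a
config switch). The tree is cut statically, but the **default cut height is
adaptive**: the midpoint of the largest gap in the sorted merge heights.
A fixed numeric cut cannot serve across soft powers, because raising β
compresses all dissimilarities toward 1 — module-internal merge heights sit
near 0.6 at β = 2 and near 0.93 at β = 6 — whereas the gap between the tight
within-module joins and the near-ceiling background joins survives the
compression. The adaptive cut recovers the planted partitions essentially
perfectly for β between 2 and 7 in the simulation tests; callers can always
pass an explicit `cut_height`. Clusters below `min_module_size` (default 10)
are left unassigned (**grey**).

Detected modules are labelled with the standard color palette strictly in
descending size order (largest = turquoise), ties broken by the
lexicographically smallest member id, so labels are reproducible run to run.

**Module eigenvalues** are the first-PC scores (SVD of the centered member
submatrix), rescaled to unit sample variance and signed to correlate
non-negatively with the module's mean member profile. The sign convention is
arbitrary for GWAS (Wald tests are sign-invariant) but fixing it keeps
output files byte-stable. The proportion of variance explained is reported
per module.

**Pruning** interprets "connectivity between nodes" as the pairwise edge
weight (not node degree): edges are retained when `w_ij` strictly exceeds
`mean + k·SD` over all off-diagonal weights (population SD, all pairs
including grey nodes). Statistics are computed on the β-powered weights by
default — the same matrix that defines the network — with a raw-|r| switch.
Because thresholds are nested in k, the retained edge sets are nested, and
modules may split into several connected components; isolated nodes are
removed and per-level node/edge/module/component counts are reported, with
the retained percentage printed to one decimal.

Guilt-by-association annotation transfers each annotated feature's label to
unannotated members of the same module, scored by the retained edge weight
between the pair (0 if pruning severed it), so the caller can rank
candidates by connection strength.

## Kinship, structure, and the mixed model

Relatedness uses the Loiselle marker estimator: with within-line allele
frequency `x_il = dosage/2` and panel frequency `p_l`,

    f_ij = Σ_l [ (x_il − p_l)(x_jl − p_l) + p_l(1−p_l)/(n−1) ] / Σ_l p_l(1−p_l).

Negative estimates are kept (a clamp switch exists); for the mixed model the
matrix is made positive semi-definite by flooring eigenvalues at 1e-8. For
an inbred panel the diagonal sits near 1, so `h² = σ²_g/(σ²_g+σ²_e)` is on
the usual scale.

Population structure enters as fixed effects: by default the top q = 3
principal components of the centered dosage matrix (an externally supplied
membership matrix is accepted instead). PCs need no external software and
are the standard stand-in for model-based ancestry fractions.

The null model `y = Xb + u + e` is fitted by REML through one
eigendecomposition of K: profiling out σ²_e leaves a one-dimensional
likelihood in the variance ratio λ = σ²_g/σ²_e, maximized by a log-spaced
grid (10⁻⁶..10⁶, 61 points) refined with bounded scalar minimization, with
an explicit boundary check at λ → 0 so pure-noise traits return σ²_g = 0
rather than a spurious interior optimum. The per-SNP scan reuses those
variance components (**P3D**): under fixed `V = σ²_g K + σ²_e I` each SNP is
a GLS Wald t-test, vectorized across all complete SNPs through the rotated,
whitened design; SNPs with missing calls are tested on their observed lines
against the corresponding submatrix of V. SNPs with minor-allele frequency
below 0.05 (inclusive floor: exactly 5% is kept) or with zero variance are
excluded before testing. When σ²_g = 0 the test reduces exactly to the OLS
F-test, which the suite verifies against a dense GLS oracle at small n.

FDR control is Benjamini–Hochberg step-up; significance is flagged at the
two conventional levels 0.001 (conservative) and 0.05 (generous), and the
stricter set always nests in the looser. Concordance between two scans
(e.g. a module eigenvalue and one of its member features) is plain SNP-id
intersection.

## Stepwise eigentrait regression

Mixed forward/backward selection on partial-F p-values, defaults
`p_enter = 0.05`, `p_leave = 0.10` (common fit-software defaults; both
configurable and logged). Ties break on the smaller p then the
lexicographic term id, so selection is invariant to candidate column order.
The reported table uses partial (Type-III) sums of squares: every candidate
is a 1-DF term, hence `F = t²` and partial SS = `F·MSE`, with the Error row
carrying the residual SS/DF and the Model row the corrected total (DF
n − 1) — under that convention adjusted R² equals
`1 − (SS_err/DF_err)/(SS_tot/DF_tot)` and the model F equals
`((SS_tot−SS_err)/(DF_tot−DF_err))/(SS_err/DF_err)`. Rows with missing
phenotype are dropped before fitting. An intercept-only outcome (nothing
passes entry) is a valid result, not an error.

With ~20 candidates at `p_enter = 0.01`, the minimum of the null candidates'
partial-F p-values dips below the threshold in roughly one replicate in six
(1 − 0.99^18), so occasional single false inclusions are expected behaviour
of the procedure itself, not a defect; the simulation tests assert certain
recovery of the true terms and a correspondingly small mean false-entry
count.

## Spectral reconstruction and mass conventions

idMS/MS reconstruction groups high collision-energy features within ±2 s of
the target feature's retention time and keeps those whose intensity profile
correlates with the target at Pearson r ≥ 0.5 across samples (the window
mirrors the acquisition's chromatographic peak width; the correlation
threshold is configurable). Peak intensity is the **median** across samples
— robust to single-injection spikes — renormalized so the base peak is
exactly 999, the NIST msp convention. The same grouping on the low-energy
channel reconstructs the MS spectrum. Empty reconstructions are flagged,
not fatal. Reconstruction is invariant to sample order and to global
intensity rescaling.

Charge states come from isotope spacing: `z = round(1.003355 / mean
spacing)` (the ¹³C−¹²C mass difference), with every individual spacing
required to agree with 1.003355/z within `2·tol_ppm·10⁻⁶·mz̄` Da, else the
cluster is rejected as irregular. Two mass constants are deliberately
distinct: multiply charged peptide envelopes are deconvolved with the
**hydrogen-atom mass 1.00794** per charge (`M = z·(m/z − 1.00794)`), the
convention that reproduces printed peptide molecular weights from observed
envelopes, while [M+H]+ adducts of small molecules add the **proton mass
1.007276**. Both are configurable. Elemental formulas (C,H,N,O,S,P) and
peptide sequences use standard monoisotopic tables via pyteomics; a
dehydration conjugate is `A + B − H₂O`, protonated. Cosine similarity pairs
peaks one-to-one within an m/z tolerance by maximum-weight assignment, so a
self-match scores exactly 1.

`.msp` records follow the NIST dialect (Name, PrecursorMZ, Num Peaks,
`mz intensity` lines, blank-line separated); reading validates the declared
peak count and inverts writing to the printed precision (4 decimals m/z,
1 decimal intensity).

## The synthetic cohort generator

The generator emulates a structured inbred diversity panel profiled by
dual-channel LC-MS:

- **Genotypes**: Balding–Nichols — ancestral frequencies Uniform(0.1, 0.9),
  subpopulation frequencies Beta with Fst parameterization (default 3
  subpopulations, Fst 0.2), inbred dosages in {0, 2} (heterozygosity rate
  configurable, default 0), 500 SNPs over 10 chromosomes, 200 lines.
- **Metabolome**: a factor model — each of 8 module latents is standard
  normal plus any configured QTL effects on standardized dosage; member
  features load 0.7–0.9 on their latent with feature noise SD 0.6; the
  remaining features are uncorrelated background (2,000 features total,
  module sizes 200…10). Intensities are an affine transform of the
  latent-scale values (floored at 0), so correlations are preserved exactly;
  m/z is drawn from the 50–1200 acquisition range, RT from 0–720 s. The
  default module-QTL effect (0.35 per dosage SD, ≈11% of latent variance) is
  a realistically large metabolite QTL.
- **Phenotype**: a weighted sum of the module latents plus noise scaled
  against the realized genetic variance to hit the target heritability
  (default 0.5). Note the distinction the tests respect: this h² is at the
  *latent* level; the kinship-attributable fraction of such a phenotype is
  much smaller unless many strong QTLs are configured, so mixed-model h²
  recovery is verified on a directly kinship-structured trait.
- **Spectra fixture**: each compound contributes an isotope cluster
  (spacing 1.003355/z) to the low-energy channel and fragment features to
  the high-energy channel, all within ±0.5 s of the precursor RT and
  sharing one lognormal per-sample abundance with 10% multiplicative noise
  — by construction the fragments pass the correlational filter (r ≈ 0.9).

All randomness flows from a single mandatory seed through spawned child
generators, so each stage is independently reproducible. What the generator
does **not** emulate: linkage disequilibrium beyond shared ancestry,
chromatographic drift, batch/injection-order effects, heteroscedastic or
heavy-tailed intensity noise, missing intensities, isotopologue overlap
between compounds, and adducts other than [M+H]+. Passing tests therefore
demonstrate statistical correctness of the procedures under the assumed
factor/mixed-model structure, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The simulation tests run at the package's reference conditions — 200 lines,
500 SNPs, 2,000 features for network recovery; 200 null phenotype
replicates for scan calibration; 50 replicates at n = 400 for h² recovery;
100 replicates for stepwise selection — sizes chosen to make the binomial
noise of the asserted rates small relative to the asserted bands while the
whole suite stays interactive. Degenerate inputs fail loudly and early:
constant traits, monomorphic-only panels, empty peptide sequences,
sub-minimum module sizes, rank-deficient designs, irregular isotope
clusters. Kinship PSD flooring (1e-8), the REML grid bounds, the strict
pruning inequality, and all tie-breaks (lexicographic ids) are fixed
conventions rather than tunables, so identical inputs give byte-identical
outputs everywhere, which the manifest-driven CLI relies on.

## Known limitations

- Module detection is a static (if adaptive) cut; branch-shape methods can
  separate adjacent modules that a flat cut merges.
- No block-wise network path: memory is quadratic in features, practical to
  a few tens of thousands of nodes.
- P3D fixes variance components at the null fit; per-SNP REML would give
  slightly different p-values for large-effect SNPs.
- The scan tests one SNP at a time; no multi-locus or epistatic models.
- Kinship compression, genomic prediction, signed networks and spectral
  database searching are out of scope; the package exports .msp libraries
  for external search engines instead.
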