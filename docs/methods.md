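# Methods

This note documents the models, defaults and design choices behind
`chemobiome`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Metabolomics measurement model and QC curation

An injection sequence is modelled as: solvent blank → leading pooled-QC
block (default 4 injections, kept in all statistics — the block exists to
equilibrate the column, not to be discarded) → a 3-point QC dilution series
(25-, 10-, 5-fold) → biological samples in randomised order with a pooled QC
every 6 injections and a closing QC.

Observed intensity = true concentration × drift(run order) × lognormal
noise. Drift is a per-feature cubic polynomial in normalised run order,
scaled so the maximum deviation is a draw in [½·A, A] with amplitude
A = 0.30 by default; it is strictly positive for A < 1.

**RSD filter.** RSD = sample SD (ddof = 1) / mean over all in-sequence QC
injections; features with RSD > 0.30 fail. The n−1 denominator matters at
the small QC counts involved (~15 per sequence). Features with fewer than 3
finite QC values auto-fail rather than aborting the batch. The acceptance
decision uses pre-correction intensities (drift correction is the final
step); a flag exists to recompute after correction.

**Linearity filter.** Squared Pearson correlation between concentration
(0 for the blank, 1/dilution otherwise) and abundance over the four points;
features with R² ≤ 0.8 fail, and a blank-dominated feature (flat response)
has undefined R² and fails. This one filter therefore removes both
detector-saturated and blank-contaminated features.

**LOESS drift correction.** A tricube-weighted local polynomial smoother
(default span 0.75, degree 1, both configurable) is fitted per feature to QC
intensity vs run order and evaluated at every injection's run order, clamped
to the first/last QC (boundary extrapolation returns the boundary fit).
Because the smoother matrix depends only on the QC run orders, it is shared
across features, making correction O(features) rather than
O(features × fits). Dividing by the fit converts all values to fold-changes
against the pooled QC; this is exactly division by the QC mean when drift is
flat. Dry-weight normalisation then scales each sample row by
(25 mg / sample dry weight); QC and blank rows are untouched.

## Community preparation

**Control filter.** An ASV is removed everywhere iff, in at least one
negative control, it has ≥ 25 reads *and* ≥ 0.5% of that control's reads.
The fraction is of the control's own total (decontamination convention), and
the read threshold is inclusive (≥ 25, configurable) as the more explicit of
the two possible readings. Removing only control-prominent ASVs avoids
purging ecologically valid sequences that merely cross-contaminate.

**Taxonomy filter.** Rank labels with bootstrap confidence < 0.80 are
truncated, and a failed rank blocks all deeper ranks (a lineage cannot skip
a rank). ASVs left with only a kingdom label are removed.

**Aggregation with rank fallback.** At a requested rank, ASVs sharing the
label are pooled by summation; ASVs unresolved at that rank are pooled under
their deepest reliable label with its UNITE prefix (`f__`, `o__`, …),
producing deliberately mixed-level taxa. Reads are conserved exactly at
every rank.

**Prevalence-filter optimisation.** Log-ratio transforms need mostly
non-zero data, so a grid of (min prevalence, min count) pairs is evaluated;
among candidates whose filtered matrix has a zero fraction < 0.5 the winner
maximises retained reads, then retained taxa. The default grid spans
prevalence 0–0.8 × count {1, 2, 5, 10, 25}; absent taxa are never counted as
retained. If no candidate qualifies the error names the best achieved
fraction.

**Zero replacement.** Geometric Bayesian-multiplicative style: with row
total n, uniform prior t = 1/D and prior strength s (default √n — weak in
deep samples, stronger in shallow ones), each zero becomes s·t/(n + s),
capped at 65% of the row's smallest observed proportion so an imputed part
can never exceed anything actually observed (without the cap the posterior
value can exceed 1/n in deep sparse rows). Observed parts are multiplied by
a common factor restoring the simplex, so their ratios are preserved
exactly.

**Log-ratio transforms.** clr is the log divided by the row geometric mean;
ilr uses the fixed Helmert-type sequential binary partition basis
(coordinate k contrasts the geometric mean of the first k parts with part
k + 1), which is orthonormal in clr space, so ilr distances equal Aitchison
distances and a D = 2 composition reduces to (1/√2)·ln(x/(1−x)). clr is
*not* subcompositionally coherent — dropping taxa changes the remaining clr
values — and the tests assert this rather than pretending otherwise.

## Diversity

Computed on the raw, non-pooled ASV matrix after the control and taxonomy
filters. Shannon H in nats; Dominance = Σp² (the Simpson concentration, so
high = few taxa dominate); Buzas–Gibson evenness e^H/S; ACE with the
standard rare/abundant split at 10 reads, coverage C = 1 − F₁/N_rare and the
rare-group squared coefficient of variation floored at 0 (no rare taxa →
ACE = S; all rare taxa singletons → undefined, reported missing with a
warning). Beta diversity: Bray–Curtis Σ|x−y|/Σ(x+y); pairwise Whittaker
turnover S_union/mean(S_a, S_b) − 1 on presence/absence; unweighted UniFrac
by explicit per-branch classification (unique branch length over spanned
branch length of the pair's union), vectorised over an edge × leaf incidence
matrix. PCoA uses Gower double-centering; axes with negative eigenvalues
(non-Euclidean input) are dropped, not Cailliez-corrected, and the full
spectrum is returned so the caller can see them. ANOSIM uses average ranks
of the condensed distances, R = (mean between − mean within rank)/(M/2), and
a one-sided permutation p with the +1 correction; the operation default is
9999 permutations, while the orchestrated pipeline uses 999 as its runtime
default (recorded in the run config). SIMPER splits each between-group
Bray–Curtis numerator by taxon, so contributions sum exactly to the mean
between-group dissimilarity. Kruskal–Wallis (tie-corrected, χ² p) comes from
scipy.

## Correlation mining

sPCA extracts components by rank-1 SVD with soft-thresholding of loadings to
a per-component variable budget, deflating between components; with sparsity
disabled (the default) the direct SVD path reproduces ordinary PCA exactly,
which is also how it is verified. Inputs are the ilr-transformed fungal
matrix (capped at 6 components) and the autoscaled chemistry (capped at 12);
components must explain > 2.5% of total variance to be tested further (the
variance-fraction reading of the gate; an SD-fraction option exists).

Spearman ρ is Pearson on average ranks with the t-approximation p-value;
scans are vectorised by rank-transforming columns once and computing the
cross-correlation block, which matches the per-pair path to 1e-12.
Confidence intervals are Fisher-z with the Fieller variance 1.06/(n−3) by
default; a 250-resample percentile bootstrap is available where the
bootstrap count matters.

Direct taxon–feature tests (`rawcordf`) are restricted to features that are
putatively annotated or have cross-sample RSD > 0.66 of their fold-change
values (in-sequence QC RSD is already capped at 0.30 by the acceptance
filter, so this is necessarily the biological-variability reading).
Diversity indices enter only the direct pairing. All p-values of a run —
correlations, PC ANOVAs, and any externally supplied diversity tests
(ANOSIM, Kruskal–Wallis) — form a single BH family whose size is logged, so
either pooling convention can be audited after the fact.

Effect sizes: the quartile effect size is |mean fungal value in the top
chemical quartile − bottom quartile| / SD of the fungal vector, computed on
the log-ratio (clr) fungal values (a config switch allows raw proportions);
quartile membership uses interpolated percentiles and keeps all tied
samples. The accession/year effect size of a feature is |max group mean −
min group mean| / SD of all values. Both are 0 by convention when the
denominator SD is 0.

## The synthetic study generator

The generator emulates the emulated field design's statistical structure:
n = 8 × 2 × 4 = 64 root samples measured in one LC-MS sequence (QC layout
above) and sequenced for ITS2. Defaults: 355 features; multiplicative
accession / year / residual biological effects on concentration with log-SDs
0.11 / 0.13 / 0.25, chosen so the accession and year effect-size medians of
the corrected chemistry land near 1.3 and 0.45 SD, the magnitudes typical of
this kind of field panel; 10 features are QC-unstable (measurement CV 0.6)
and 10 respond saturably to dilution (half with a 30% blank offset) so the
acceptance filters have known targets. Library sizes are lognormal with
median 26,000; one designated genus dominates each sample at a uniform
20–40% share; a handful of core background genera sit at mid prevalence and
the remaining genera get a presence probability solved to approach a 90%
genus-level zero fraction. Negative controls carry only contaminant ASVs,
one of which is deliberately below the discard thresholds (a true negative
for the filter); contaminants also seep into real samples at low abundance.
Soil samples draw from a disjoint genus pool. Taxonomy confidences include
genus-unresolved, order-only and kingdom-only ASVs.

Planted associations set a linked taxon's latent log-abundance to
intercept + slope × (autoscaled true feature concentration) + N(0, 1). The
default slope 1.45 was calibrated once by Monte-Carlo so the *realised*
|Spearman ρ| between the taxon's clr value and the corrected feature —
after counting noise, compositional closure and zero imputation — averages
≈ 0.7 at n = 64. Linked taxa are always present (an absent taxon cannot
carry a detectable monotone association), so heavily planted runs trade some
sparsity: the genus zero fraction drops from ≈ 0.91 (no links) to ≈ 0.83
with ten links.

What the generator does **not** emulate: chromatographic peak shapes and
co-elution, adduct/isotope structure (the input table is assumed
de-isotoped), DADA2's error model and chimera formation, phylogenetic signal
in the community (the UniFrac tree is random), batch-to-batch LC-MS
sequence merging, and ecological interactions among taxa beyond
compositional closure. Passing tests therefore demonstrate correctness of
the statistical machinery and honest error control under the assumed
generative structure — not robustness to every artefact of real field data.

## Numerical choices and degenerate inputs

* Zero-variance vectors: Spearman and the effect sizes return NaN / 0 with a
  warning rather than raising mid-scan.
* LOESS fits that dip non-positive (impossible under realistic drift) are
  floored at 1e-12 with a warning.
* sPCA sign convention: the largest-|loading| entry of each component is
  made positive, fixing the sign indeterminacy deterministically.
* BH is statsmodels' step-up implementation; pooled family size is logged.
* All randomness flows through `numpy.random.default_rng` seeded from the
  run seed; reports contain no timestamps, so a rerun with the same config
  and seed is byte-identical.

## Problem sizes used by the test suite

The error-control and power checks run 20 replicate end-to-end datasets
each: null runs use 50 genus-level taxa × 300 features at n = 64; power runs
use the default design with 10 planted links. The oracle-equivalence checks
use 200 random vectors (Spearman), 100 p-vectors (BH), 20 random matrices
(PCA), 20 random trees (UniFrac) and 10 datasets each for ANOSIM/SIMPER.
These sizes keep the whole suite under a few minutes on one CPU while
leaving the Monte-Carlo margins far from the asserted thresholds.

## Known limitations

* The exact prevalence-filter grid used on any real dataset is a config
  input; the default grid is a reasonable search space, not a reproduction
  of any specific supplementary table.
* The Fisher-z CI is approximate for Spearman under ties; the bootstrap
  option is the safer choice for heavily tied data.
* `p1cordf_f` tests fungal PCs against *all* features (the variability
  restriction applies only to the direct pairing), so its family share is
  large; the pooled-BH ledger makes this visible.
* ANOSIM p-values at 999 permutations have a resolution floor of 1e-3
  inside the pipeline; raise `anosim_permutations` where finer resolution
  matters.
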