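# chemobiome

Correlation mining between an untargeted root metabolome and an endophytic
fungal ITS2 community, implemented as a tested, fully synthetic-validatable
pipeline.

A recurring multi-omics question in plant–microbe ecology is whether root
chemistry (e.g. glucosinolates and their antifungal breakdown products in
Brassicaceae) shapes which fungal endophytes colonise the root. Answering it
from field data requires joining two noisy, structurally different datasets:

* an **LC-MS feature table** (injections × features) that must be curated by
  pooled-QC precision and dilution-series linearity filters, corrected for
  instrument sensitivity drift and normalised to extracted dry weight; and
* an **ASV count table** (samples × amplicon sequence variants) that is
  compositional, ~90% zeros at genus resolution, contaminated through
  extraction kits, and only partially resolved taxonomically.

`chemobiome` implements the whole chain: QC gating, LOESS drift correction,
negative-control and bootstrap-confidence ASV filtering, mixed-level
taxonomic pooling, prevalence-filter optimisation, Bayesian-multiplicative
zero replacement, clr/ilr log-ratio transforms, alpha/beta diversity with
ANOSIM/SIMPER, sparse-PCA score regression, four Spearman pairing schemes
with a single pooled Benjamini–Hochberg family, and quartile effect sizes —
plus a synthetic-study generator that reproduces the design (8 accessions ×
2 years × 4 replicates, QC every 6 injections, a 3-point dilution series,
planted taxon–metabolite associations) so every stage is testable without
any external download.

## The statistics at the core

* **Feature acceptance.** A feature survives if its in-sequence QC relative
  standard deviation RSD = s/x̄ ≤ 0.30 and the squared Pearson correlation
  between dilution-series abundance and concentration (1/dilution, blank at
  0) exceeds R² = 0.8.
* **Drift correction.** Per feature, a LOESS curve f̂(t) is fitted to QC
  intensity against run order t; every injection is divided by f̂(t), so all
  abundances become fold-changes against the pooled QC (QC ≈ 1.00).
* **Compositional preparation.** Counts pooled at phylum / order / genus
  (unresolved ASVs fall back to their deepest reliable rank, `f__`, `o__` …),
  a prevalence filter chosen by grid search to maximise retained reads and
  taxa subject to a post-filter zero fraction < 0.5, zeros replaced by
  posterior-expected proportions under a uniform Dirichlet prior
  (multiplicative adjustment of observed parts), then
  clr(x)ᵢ = ln xᵢ − (1/D)Σ ln xⱼ and ilr = clr projected on a Helmert-type
  orthonormal basis.
* **Correlation mining.** Spearman ρ between: taxa × features (`rawcordf`,
  restricted to annotated or highly variable features), fungal PCs × chemical
  PCs (`p2cordf`), fungal PCs × features (`p1cordf_f`) and taxa × chemical
  PCs (`p1cordf_c`); sPCA capped at 6 fungal / 12 chemical components, gated
  at > 2.5% variance explained, with component scores also tested by ANOVA
  against accession and year. Every p-value of a run forms **one pooled
  Benjamini–Hochberg family**; calls use adjusted p < 0.05.
* **Effect sizes.** For each significant taxon–feature pair,
  |mean clr abundance in the top chemical quartile − bottom quartile| / SD —
  an interpretable strength measure in standard-deviation units.

## Worked example

```bash
chemobiome run-all --seed 1 --out run1
```

or equivalently from Python:

```python
from chemobiome import RunConfig, run_pipeline
from chemobiome.synthetic import SynthDesign

report = run_pipeline(RunConfig(out_dir="run1", seed=1,
                                design=SynthDesign(seed=1, n_planted_links=10)))
print(report["feature_funnel"])
print(report["correlation"]["correlated_read_fraction"])
```

prints (seed 1, ten planted associations):

```
{'detected': 355, 'failed_rsd': 10, 'failed_linearity': 10, 'passed_qc': 335}
{'phylum': 1.0, 'order': 0.402, 'genus': 0.555}
```

Reading the run report: of 355 simulated chemical features, the QC filters
removed exactly the 10 built to be imprecise and the 10 built to respond
nonlinearly. The genus-level table entered the scan with an 82.7% zero
fraction; the optimised prevalence filter (present in ≥ 10% of samples)
kept 19 taxa holding 98.6% of reads at a 13.4% zero fraction. The scan ran
9,969 correlation tests pooled with 53 ANOVA/diversity tests into one BH
family of 10,022; 13 genus-level taxon–feature pairs were significant,
including all ten planted links, and taxa with at least one significant
association hold 55.5% of genus-level reads. The accession and year
effect-size medians of the chemistry were 1.31 and 0.40 SD.

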