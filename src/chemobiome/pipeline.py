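"""End-to-end orchestration: simulate -> qc -> community -> diversity -> correlate.

Every stage consumes only the artifacts of prior stages and writes its own
outputs under the run directory, so deleting outputs and re-running with the
same seed reproduces them exactly.  The final report aggregates the feature
funnel, the ASV funnel, diversity summaries, correlation-record counts, the
pooled-test ledger and the correlated-read fractions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .community import (aggregate_taxa, bayesian_multiplicative_replace, clr,
                        filter_control_asvs, filter_taxonomy, ilr,
                        optimize_prevalence_filter)
from .correlation import (correlated_read_fraction, group_effect_size,
                          run_correlation_scan)
from .diversity import (alpha_table, anosim, bray_curtis, kruskal_wallis,
                        simper, unweighted_unifrac, whittaker)
from .qc import accept_features, dry_weight_normalize, loess_correct
from .synthetic import SynthDesign, gen_community, gen_metabolome_batch, gen_tree

__all__ = ["RunConfig", "run_pipeline", "prepare_levels"]

log = logging.getLogger("chemobiome")

LEVELS = ("phylum", "order", "genus")


@dataclass
class RunConfig:
    """All thresholds of a run; defaults are the pipeline's standard constants."""

    out_dir: str = "run"
    seed: int = 0
    design: SynthDesign = None
    rsd_max: float = 0.30
    r2_min: float = 0.8
    loess_span: float = 0.75
    loess_degree: int = 1
    control_min_frac: float = 0.005
    control_min_reads: int = 25
    taxonomy_min_conf: float = 0.80
    prevalence_grid: list | None = None
    max_pcs_fungal: int = 6
    max_pcs_chem: int = 12
    pc_gate: float = 0.025
    q: float = 0.05
    rsd_restrict: float = 0.66
    anosim_permutations: int = 999

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = SynthDesign(seed=self.seed)
        for name, lo, hi in (("rsd_max", 0, 10), ("r2_min", 0, 1),
                             ("control_min_frac", 0, 1), ("taxonomy_min_conf", 0, 1),
                             ("pc_gate", 0, 1), ("q", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        design_cfg = raw.pop("design", None) or raw.pop("simulate", None)
        cfg = cls(**raw)
        if design_cfg:
            design_cfg.setdefault("seed", cfg.seed)
            if "dilution_factors" in design_cfg:
                design_cfg["dilution_factors"] = tuple(design_cfg["dilution_factors"])
            cfg.design = SynthDesign(**design_cfg)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # reports stay byte-identical across run dirs
        return d


def prepare_levels(asv_table, grid=None):
    """Aggregate a filtered ASV table at each level and log-ratio transform it.

    Returns ``(clr_by_level, ilr_by_level, counts_by_level, reports)`` where the
    transformed matrices cover the prevalence-optimized taxa only.
    """
    clr_by, ilr_by, counts_by, reports = {}, {}, {}, {}
    for level in LEVELS:
        agg = aggregate_taxa(asv_table, level)
        params, filtered, report = optimize_prevalence_filter(agg, grid)
        comp = bayesian_multiplicative_replace(filtered)
        clr_by[level] = clr(comp)
        ilr_by[level] = ilr(comp)
        counts_by[level] = filtered
        reports[level] = {
            "raw_taxa": int(agg.counts.shape[1]),
            "raw_zero_fraction": float((agg.counts.to_numpy() == 0).mean()),
            "chosen_min_prevalence": params[0],
            "chosen_min_count": params[1],
            "kept_taxa": int(filtered.shape[1]),
            "kept_read_fraction": float(filtered.to_numpy().sum()
                                        / max(agg.counts.to_numpy().sum(), 1)),
            "post_zero_fraction": float((filtered.to_numpy() == 0).mean()),
        }
    return clr_by, ilr_by, counts_by, reports


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated dataset and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_jsonable()}

    # ---- simulate ---------------------------------------------------------
    log.info("stage simulate: design n=%d, %d features", config.design.n_samples,
             config.design.n_features)
    metabo, truth = gen_metabolome_batch(config.design)
    asv_table, truth = gen_community(config.design, truth)
    tree = gen_tree(list(asv_table.counts.columns), seed=config.seed)
    cio.write_feature_table(metabo, out / "feature_table.tsv")
    cio.write_counts(asv_table.counts, out / "counts.tsv")
    cio.write_taxonomy(asv_table.taxonomy, out / "taxonomy.tsv")
    cio.write_sample_metadata(asv_table.samples, out / "sample_metadata.tsv")
    cio.write_newick(tree, out / "tree.nwk")
    cio.write_truth_json(truth, out / "truth.json")

    # ---- metabolomics QC --------------------------------------------------
    qa = accept_features(metabo, rsd_max=config.rsd_max, r2_min=config.r2_min)
    qa.table.to_csv(out / "qc_assessment.tsv", sep="\t")
    kept = metabo.subset_features(qa.passing)
    log.info("stage qc: rsd_max=%.2f r2_min=%.2f -> %d/%d features kept",
             config.rsd_max, config.r2_min, len(qa.passing), metabo.intensities.shape[1])
    corrected = loess_correct(kept, span=config.loess_span, degree=config.loess_degree)
    corrected = dry_weight_normalize(
        corrected, reference_mg=config.design.reference_dry_weight_mg)
    cio.write_feature_table(corrected, out / "corrected_features.tsv")
    report["feature_funnel"] = {
        "detected": int(metabo.intensities.shape[1]),
        "failed_rsd": qa.n_discarded_rsd,
        "failed_linearity": qa.n_discarded_linearity,
        "passed_qc": int(len(qa.passing)),
    }

    # ---- community filtering ---------------------------------------------
    filtered, discarded = filter_control_asvs(
        asv_table, min_frac=config.control_min_frac, min_reads=config.control_min_reads)
    filtered = filter_taxonomy(filtered, min_conf=config.taxonomy_min_conf)
    log.info("stage community: control filter (frac>=%.3f, reads>=%d) discarded %d ASVs; "
             "taxonomy filter (conf>=%.2f) kept %d",
             config.control_min_frac, config.control_min_reads, len(discarded),
             config.taxonomy_min_conf, filtered.counts.shape[1])
    report["asv_funnel"] = {
        "detected": int(asv_table.counts.shape[1]),
        "control_discarded": len(discarded),
        "after_taxonomy_filter": int(filtered.counts.shape[1]),
    }
    report["control_discarded_asvs"] = discarded

    bio = filtered.subset_samples(
        filtered.samples.index[filtered.samples["type"] != "negative_control"])
    accession_ids = [s for s in config.design.sample_ids() if s in bio.counts.index]
    accession_tbl = bio.subset_samples(accession_ids)

    clr_by, ilr_by, counts_by, prep_reports = prepare_levels(
        accession_tbl, config.prevalence_grid)
    report["community_prep"] = prep_reports
    for level in LEVELS:
        counts_by[level].rename_axis("sample_id").to_csv(
            out / f"aggregated_{level}.tsv", sep="\t")
        clr_by[level].rename_axis("sample_id").to_csv(
            out / f"transformed_{level}.tsv", sep="\t")
    cio.write_json(prep_reports, out / "imputation_report.json")

    # ---- diversity --------------------------------------------------------
    drop_empty = bio.counts.index[bio.counts.sum(axis=1) > 0]
    div_counts = bio.counts.loc[drop_empty]
    alpha = alpha_table(div_counts)
    alpha.rename_axis("sample_id").to_csv(out / "alpha_diversity.tsv", sep="\t")
    betas = {
        "bray_curtis": bray_curtis(div_counts),
        "whittaker": whittaker(div_counts),
        "unweighted_unifrac": unweighted_unifrac(div_counts, tree),
    }
    for name, dm in betas.items():
        dm.rename_axis("sample_id").to_csv(out / f"beta_{name}.tsv", sep="\t")

    extra_p = []
    div_report = {"anosim": {}, "kruskal_wallis": {}, "simper_top": {}}
    types = bio.samples.loc[div_counts.index, "type"]
    for name, dm in betas.items():
        if types.nunique() >= 2:
            R, p = anosim(dm, types, n_perm=config.anosim_permutations,
                          seed=config.seed)
            div_report["anosim"][f"type_{name}"] = {"R": R, "p": p}
            extra_p.append(p)
    acc_ids = [s for s in accession_ids if s in div_counts.index]
    acc_groups = bio.samples.loc[acc_ids, "accession"]
    for name, dm in betas.items():
        R, p = anosim(dm.loc[acc_ids, acc_ids], acc_groups,
                      n_perm=config.anosim_permutations, seed=config.seed)
        div_report["anosim"][f"accession_{name}"] = {"R": R, "p": p}
        extra_p.append(p)
    for index_name in alpha.columns:
        vals = alpha.loc[acc_ids, index_name]
        ok = vals.notna()
        if ok.sum() >= 8:
            H, p = kruskal_wallis(vals[ok], acc_groups[ok])
            div_report["kruskal_wallis"][f"accession_{index_name}"] = {"H": H, "p": p}
            extra_p.append(p)
    if types.nunique() == 2:
        sim = simper(div_counts, types)
        div_report["simper_top"]["type"] = {
            t: float(c) for t, c in sim["contribution"].head(10).items()}
    cio.write_json(div_report, out / "diversity_report.json")
    report["diversity"] = {
        "alpha_means": {c: float(alpha[c].mean()) for c in alpha.columns},
        "anosim": div_report["anosim"],
    }

    # ---- correlation scan -------------------------------------------------
    chem = corrected.intensities.loc[accession_ids]
    annotated = corrected.features["annotated"]
    factors = pd.DataFrame({
        "accession": accession_tbl.samples.loc[accession_ids, "accession"],
        "year": accession_tbl.samples.loc[accession_ids, "year"],
    })
    diversity_acc = alpha.loc[acc_ids].reindex(accession_ids)
    scan = run_correlation_scan(
        clr_by, ilr_by, chem, annotated=annotated,
        diversity=diversity_acc, factors=factors,
        max_pcs_fungal=config.max_pcs_fungal, max_pcs_chem=config.max_pcs_chem,
        pc_gate=config.pc_gate, q=config.q, rsd_restrict=config.rsd_restrict,
        seed=config.seed, extra_pvalues=extra_p,
    )
    scan.records.to_csv(out / "correlations.tsv", sep="\t", index=False)
    with open(out / "correlations.jsonl", "w", encoding="utf-8") as fh:
        for rec in scan.records.to_dict(orient="records"):
            fh.write(json.dumps(rec, sort_keys=True, default=float) + "\n")
    log.info("stage correlate: %d records, pooled BH family of %d tests",
             len(scan.records), scan.pooled_n)

    counts_summary = {}
    if len(scan.records):
        grp = scan.records.groupby(["approach", "fungal_level"]).agg(
            tested=("p", "size"), significant=("significant", "sum"))
        counts_summary = {f"{a}/{l}": {"tested": int(t), "significant": int(s)}
                          for (a, l), (t, s) in grp.iterrows()}
    read_frac = {level: correlated_read_fraction(scan.records, counts_by[level], level)
                 for level in LEVELS}
    effect_medians = {}
    for factor in ("accession", "year"):
        es = [group_effect_size(chem[c], factors[factor]) for c in chem.columns]
        effect_medians[factor] = float(np.median(es)) if es else float("nan")

    report["correlation"] = {
        "records": int(len(scan.records)),
        "per_approach_level": counts_summary,
        "pooled_tests": scan.pooled_n,
        "external_tests_in_family": scan.extra_n,
        "correlated_read_fraction": read_frac,
        "gated_components": {k: list(v) for k, v in scan.gated.items()},
    }
    report["chem_effect_size_median"] = effect_medians
    cio.write_json({"pooled_tests": scan.pooled_n,
                    "records": int(len(scan.records)),
                    "anova_tests": int(len(scan.anova)),
                    "external_tests": scan.extra_n},
                   out / "pooled_tests.json")
    cio.write_json(report, out / "report.json")
    return report
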