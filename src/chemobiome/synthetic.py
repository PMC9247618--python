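"""Synthetic multi-omics batches with the statistical structure the pipeline assumes.

The generator emulates a two-site field design: 8 accessions x 2 years x 4
replicates (n = 64) of root samples profiled by untargeted LC-MS (an
injection sequence with a leading pooled-QC block, a 3-point QC dilution
series and in-sequence QCs every few injections, smooth per-feature
sensitivity drift, and deliberately QC-unstable / nonlinear features to
exercise the acceptance filters) and by ITS2 amplicon sequencing (a sparse
genus-level community with one dominant taxon per sample at 20-40% of reads,
contaminated negative controls, a disjoint soil community, and optional
planted taxon-metabolite associations with known sign and strength for
parameter-recovery testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AsvTable, RANKS
from .qc import MetaboFeatureTable
from .trees import random_bifurcating_newick

__all__ = ["SynthDesign", "SyntheticTruth", "gen_metabolome_batch",
           "gen_community", "gen_tree"]

#: latent slope (per SD of chemical concentration, on the log-abundance scale)
#: calibrated by Monte-Carlo so a planted link realises |Spearman rho| ~ 0.7
#: at n = 64 after counting noise, compositional closure and zero imputation.
DEFAULT_LINK_SLOPE = 1.45


@dataclass
class SynthDesign:
    """Knobs of the simulated study; defaults mirror the emulated field design."""

    n_accessions: int = 8
    n_years: int = 2
    n_reps: int = 4
    n_features: int = 355
    n_taxa_genus: int = 60
    n_asvs: int = 300
    qc_block_leading: int = 4
    qc_interval: int = 6
    dilution_factors: tuple = (25.0, 10.0, 5.0)
    seed: int = 0

    # metabolome measurement model
    n_qc_unstable: int = 10          # features with true QC RSD ~ qc_unstable_cv
    n_nonlinear: int = 10            # features with saturating dilution response
    drift_amplitude: float = 0.30    # max fractional sensitivity drift over the run
    noise_cv: float = 0.08           # measurement CV of well-behaved features
    qc_unstable_cv: float = 0.60     # measurement CV of the unstable subset
    accession_sigma: float = 0.11    # log-SD of accession effects on concentration
    year_sigma: float = 0.13         # log-SD of year effects
    bio_sigma: float = 0.25          # residual biological log-SD
    frac_annotated: float = 0.40     # features flagged as putatively annotated
    reference_dry_weight_mg: float = 25.0

    # community model
    library_size_median: float = 26000.0
    library_size_sigma: float = 0.25
    dominant_frac_range: tuple = (0.2, 0.4)
    target_zero_fraction: float = 0.9
    n_core_background: int = 6       # mid-prevalence background genera
    core_prevalence: float = 0.75
    min_background_prevalence: float = 0.015
    n_negative_controls: int = 2
    control_total_reads: int = 3000
    n_contaminants: int = 5
    n_soil: int = 4
    n_soil_genera: int = 20
    n_soil_asvs: int = 60

    # planted taxon-metabolite links
    n_planted_links: int = 0
    link_slope: float = DEFAULT_LINK_SLOPE
    link_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_years", "n_reps", "n_features",
                     "n_taxa_genus", "n_asvs", "qc_block_leading", "qc_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(d <= 1 for d in self.dilution_factors):
            raise ValueError("dilution factors must be > 1")
        if self.n_qc_unstable + self.n_nonlinear > self.n_features:
            raise ValueError("more designed-to-fail features than features")
        if self.n_planted_links > self.n_taxa_genus - 1:
            raise ValueError("more planted links than available taxa")

    @property
    def n_samples(self) -> int:
        return self.n_accessions * self.n_years * self.n_reps

    def sample_ids(self) -> list[str]:
        accs = [chr(ord("A") + i) for i in range(self.n_accessions)]
        years = [2018 + y for y in range(self.n_years)]
        return [f"{a}{y % 100}_{r + 1}" for a in accs for y in years
                for r in range(self.n_reps)]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    planted_links: list = field(default_factory=list)  # (taxon, feature, sign, slope)
    drift_coefficients: dict = field(default_factory=dict)  # feature -> cubic coeffs
    contaminant_asvs: list = field(default_factory=list)
    expected_discarded_asvs: list = field(default_factory=list)
    true_concentration: pd.DataFrame | None = None
    accession_effects: pd.DataFrame | None = None
    year_effects: pd.DataFrame | None = None
    qc_unstable_features: list = field(default_factory=list)
    nonlinear_features: list = field(default_factory=list)
    annotated_features: list = field(default_factory=list)
    run_order_range: tuple = (0, 0)

    def drift_values(self, feature: str, run_orders) -> np.ndarray:
        """Evaluate the planted multiplicative drift curve of one feature."""
        lo, hi = self.run_order_range
        t = (np.asarray(run_orders, dtype=float) - lo) / max(hi - lo, 1)
        c = self.drift_coefficients.get(feature)
        if c is None:
            return np.ones_like(t)
        return 1.0 + c[0] * t + c[1] * t ** 2 + c[2] * t ** 3

    def to_jsonable(self) -> dict:
        d = {
            "planted_links": [list(l) for l in self.planted_links],
            "drift_coefficients": {k: list(v) for k, v in self.drift_coefficients.items()},
            "contaminant_asvs": self.contaminant_asvs,
            "expected_discarded_asvs": self.expected_discarded_asvs,
            "qc_unstable_features": self.qc_unstable_features,
            "nonlinear_features": self.nonlinear_features,
            "annotated_features": self.annotated_features,
            "run_order_range": list(self.run_order_range),
        }
        return d


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the requested CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(-sigma ** 2 / 2, sigma, size)


def gen_metabolome_batch(design: SynthDesign) -> tuple[MetaboFeatureTable, SyntheticTruth]:
    """Simulate one LC-MS sequence over the full biological sample set.

    The injection order is: solvent blank, a leading pooled-QC block, the QC
    dilution series, then the biological samples in randomized order with a
    pooled QC every ``qc_interval`` samples and a closing QC.  Observed
    intensity = true concentration x smooth per-feature drift x lognormal
    noise; the pooled QC's true value is the mean of all sample true values.
    A designed subset of features is QC-unstable (high measurement CV) and
    another responds nonlinearly to dilution (saturation, half of them with a
    blank-level offset), so the acceptance filters have known targets.
    """
    rng = np.random.default_rng(design.seed)
    truth = SyntheticTruth()
    sids = design.sample_ids()
    fids = [f"F{j + 1:04d}" for j in range(design.n_features)]

    accs = [chr(ord("A") + i) for i in range(design.n_accessions)]
    years = [2018 + y for y in range(design.n_years)]
    acc_of = {s: s[0] for s in sids}
    year_of = {s: 2000 + int(s.split("_")[0][1:]) for s in sids}

    base = 10 ** rng.uniform(4, 7, design.n_features)
    acc_eff = pd.DataFrame(
        rng.lognormal(0, design.accession_sigma, (len(accs), design.n_features)),
        index=accs, columns=fids)
    yr_eff = pd.DataFrame(
        rng.lognormal(0, design.year_sigma, (len(years), design.n_features)),
        index=years, columns=fids)
    bio = _lognormal_noise(rng, np.sqrt(np.expm1(design.bio_sigma ** 2)),
                           (len(sids), design.n_features))
    conc = pd.DataFrame(
        base * bio, index=sids, columns=fids)
    for s in sids:
        conc.loc[s] *= acc_eff.loc[acc_of[s]].to_numpy() * yr_eff.loc[year_of[s]].to_numpy()
    truth.true_concentration = conc
    truth.accession_effects = acc_eff
    truth.year_effects = yr_eff
    qc_truth = conc.mean(axis=0).to_numpy()

    # designed-to-fail subsets (disjoint)
    fail_pool = rng.permutation(design.n_features)
    unstable = sorted(fail_pool[:design.n_qc_unstable])
    nonlinear = sorted(fail_pool[design.n_qc_unstable:
                                 design.n_qc_unstable + design.n_nonlinear])
    truth.qc_unstable_features = [fids[i] for i in unstable]
    truth.nonlinear_features = [fids[i] for i in nonlinear]
    blank_offset = np.zeros(design.n_features)
    for k, i in enumerate(nonlinear):
        if k % 2 == 0:
            blank_offset[i] = 0.3  # also present in the blank at 30% of QC level
    sat_k = 0.005  # saturation constant on the relative-concentration scale

    annotated = np.zeros(design.n_features, dtype=bool)
    ok = [i for i in range(design.n_features) if i not in set(unstable) | set(nonlinear)]
    n_ann = min(int(round(design.frac_annotated * design.n_features)), len(ok))
    if n_ann:
        annotated[rng.choice(ok, size=n_ann, replace=False)] = True
    truth.annotated_features = [fids[i] for i in range(design.n_features) if annotated[i]]

    # injection sequence
    seq: list[tuple[str, str, float | None]] = [("blank_1", "blank", None)]
    seq += [(f"qc_{i + 1}", "qc", None) for i in range(design.qc_block_leading)]
    n_qc = design.qc_block_leading
    for k, d in enumerate(design.dilution_factors):
        seq.append((f"dil_{k + 1}", "qc_dilution", float(d)))
    order = rng.permutation(len(sids))
    for i, si in enumerate(order):
        seq.append((sids[si], "sample", None))
        if (i + 1) % design.qc_interval == 0:
            n_qc += 1
            seq.append((f"qc_{n_qc}", "qc", None))
    if seq[-1][1] != "qc":
        n_qc += 1
        seq.append((f"qc_{n_qc}", "qc", None))

    inj_ids = [s[0] for s in seq]
    roles = [s[1] for s in seq]
    dils = [s[2] for s in seq]
    run_order = np.arange(1, len(seq) + 1)
    truth.run_order_range = (int(run_order[0]), int(run_order[-1]))

    # per-feature cubic drift, scaled so the max |deviation| hits a draw in
    # [amplitude/2, amplitude]; strictly positive for amplitude < 1
    tgrid = np.linspace(0, 1, 101)
    for j, fid in enumerate(fids):
        c = rng.uniform(-1, 1, 3)
        dev = np.abs(c[0] * tgrid + c[1] * tgrid ** 2 + c[2] * tgrid ** 3)
        peak = dev.max()
        amp = design.drift_amplitude * rng.uniform(0.5, 1.0)
        scale = amp / peak if peak > 0 else 0.0
        truth.drift_coefficients[fid] = tuple(float(x) for x in c * scale)

    drift = np.column_stack([truth.drift_values(fid, run_order) for fid in fids])

    def response(rel_conc: np.ndarray) -> np.ndarray:
        """Instrument response per feature given concentration relative to QC."""
        out = np.empty_like(rel_conc)
        lin = np.ones(design.n_features, dtype=bool)
        lin[nonlinear] = False
        out[:, lin] = rel_conc[:, lin]
        if len(nonlinear):
            c = rel_conc[:, nonlinear]
            sat = (c / (c + sat_k)) / (1.0 / (1.0 + sat_k))
            b = blank_offset[nonlinear]
            out[:, nonlinear] = b + (1 - b) * sat
        return out

    rel = np.zeros((len(seq), design.n_features))
    for i, (iid, role, dil) in enumerate(seq):
        if role == "sample":
            rel[i] = conc.loc[iid].to_numpy() / qc_truth
        elif role == "qc":
            rel[i] = 1.0
        elif role == "qc_dilution":
            rel[i] = 1.0 / dil
        else:
            rel[i] = 0.0

    cv = np.full(design.n_features, design.noise_cv)
    cv[unstable] = design.qc_unstable_cv
    noise = np.column_stack([
        _lognormal_noise(rng, cv[j], len(seq)) for j in range(design.n_features)])
    intensities = qc_truth * response(rel) * drift * noise

    dry_w = np.clip(rng.normal(design.reference_dry_weight_mg, 2.0, len(sids)), 18, 32)
    dw_map = dict(zip(sids, dry_w))
    injections = pd.DataFrame({
        "run_order": run_order,
        "role": roles,
        "dilution_factor": [d if d is not None else np.nan for d in dils],
        "dry_weight_mg": [dw_map.get(i, np.nan) for i in inj_ids],
    }, index=pd.Index(inj_ids, name="injection_id"))
    features = pd.DataFrame({
        "mz": np.round(rng.uniform(100, 1200, design.n_features), 4),
        "rt": np.round(rng.uniform(1, 20, design.n_features), 2),
        "polarity": rng.choice(["positive", "negative"], design.n_features),
        "annotated": annotated,
    }, index=pd.Index(fids, name="feature_id"))
    table = MetaboFeatureTable(
        pd.DataFrame(intensities, index=injections.index, columns=fids),
        injections, features)
    return table, truth


def _taxonomy_frame(rng, asv_ids, genus_of, lineage, conf_profile) -> pd.DataFrame:
    rows = {}
    for asv in asv_ids:
        genus = genus_of[asv]
        lin = lineage[genus]
        row = {}
        profile = conf_profile.get(asv, "full")
        for rank in RANKS:
            label = lin[rank]
            conf = rng.uniform(0.85, 1.0)
            if profile == "family" and rank == "genus":
                conf = rng.uniform(0.3, 0.75)
            elif profile == "order" and rank in ("family", "genus"):
                conf = rng.uniform(0.3, 0.75)
            elif profile == "kingdom" and rank != "kingdom":
                conf = rng.uniform(0.1, 0.6)
            row[rank] = label
            row[f"conf_{rank}"] = round(float(conf), 3)
        rows[asv] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "asv_id"
    return out


def gen_community(design: SynthDesign,
                  chem_truth: SyntheticTruth) -> tuple[AsvTable, SyntheticTruth]:
    """Simulate the ITS2 community coupled (optionally) to the chemistry.

    Horseradish samples draw multinomial reads over logistic-normal genus
    proportions: one designated dominant genus holds 20-40% of reads, a few
    core background genera are at mid prevalence, the rest are rare with a
    presence probability solved so the genus-level zero fraction approaches
    the configured target.  Planted links force their taxon present and set
    its latent log-abundance to intercept + slope x autoscaled true feature
    concentration + noise.  Negative controls carry only contaminant ASVs
    (one deliberately below the control-filter threshold); contaminants also
    seep into real samples at low abundance.  Soil samples use a disjoint
    genus pool.  Taxonomy confidences include genus-unresolved and
    kingdom-only ASVs to exercise the bootstrap filter.
    """
    if chem_truth.true_concentration is None:
        raise ValueError("generate the metabolome batch first (links need chemistry)")
    rng = np.random.default_rng(design.seed + 1_000_003)
    truth = chem_truth
    conc = truth.true_concentration
    sids = list(conc.index)
    n = len(sids)

    # --- taxon pools -------------------------------------------------------
    genera = [f"Genus{i + 1:03d}" for i in range(design.n_taxa_genus)]
    phyla = ["Ascomycota", "Basidiomycota"]
    classes = [f"Class{i + 1:02d}" for i in range(6)]
    orders = [f"Order{i + 1:02d}" for i in range(12)]
    families = [f"Family{i + 1:02d}" for i in range(24)]

    def make_lineage(genus_list, tag=""):
        lin = {}
        for g in genus_list:
            fi = int(rng.integers(len(families)))
            lin[g] = {"kingdom": "Fungi",
                      "phylum": tag + phyla[fi % len(phyla)],
                      "class": tag + classes[fi % len(classes)],
                      "order": tag + orders[fi % len(orders)],
                      "family": tag + families[fi],
                      "genus": g}
        return lin

    lineage = make_lineage(genera)
    soil_genera = [f"SoilGenus{i + 1:03d}" for i in range(design.n_soil_genera)]
    lineage.update(make_lineage(soil_genera, tag="Soil"))
    contam_genera = [f"Contam{i + 1:02d}" for i in range(design.n_contaminants)]
    lineage.update(make_lineage(contam_genera))

    # ASVs per genus (each genus >= 1 ASV), fixed within-genus split
    asv_ids, genus_of = [], {}
    extra = rng.multinomial(design.n_asvs - design.n_taxa_genus,
                            np.full(design.n_taxa_genus, 1 / design.n_taxa_genus))
    k = 0
    for gi, g in enumerate(genera):
        for _ in range(1 + extra[gi]):
            k += 1
            aid = f"ASV{k:04d}"
            asv_ids.append(aid)
            genus_of[aid] = g
    soil_asvs = []
    extra_s = rng.multinomial(design.n_soil_asvs - design.n_soil_genera,
                              np.full(design.n_soil_genera, 1 / design.n_soil_genera))
    for gi, g in enumerate(soil_genera):
        for _ in range(1 + extra_s[gi]):
            k += 1
            aid = f"ASV{k:04d}"
            soil_asvs.append(aid)
            genus_of[aid] = g
    contam_asvs = []
    for g in contam_genera:
        k += 1
        aid = f"ASV{k:04d}"
        contam_asvs.append(aid)
        genus_of[aid] = g
    all_asvs = asv_ids + soil_asvs + contam_asvs
    truth.contaminant_asvs = list(contam_asvs)

    split = {}  # genus -> (asv list, Dirichlet weights)
    for g in genera + soil_genera:
        members = [a for a in all_asvs if genus_of[a] == g]
        w = rng.dirichlet(np.full(len(members), 2.0))
        split[g] = (members, w)

    # --- roles & planted links --------------------------------------------
    dominant = genera[0]
    link_genera = genera[1:1 + design.n_planted_links]
    # links target annotated, QC-passing features so the direct scan tests them
    bad = set(truth.qc_unstable_features) | set(truth.nonlinear_features)
    ann_pool = [f for f in (truth.annotated_features or conc.columns) if f not in bad]
    rng.shuffle(ann_pool)
    links = []
    for i, g in enumerate(link_genera):
        feat = ann_pool[i]
        sign = 1 if i % 2 == 0 else -1
        links.append((f"g__{g}", feat, sign, design.link_slope))
    truth.planted_links = links

    core = genera[1 + design.n_planted_links:
                  1 + design.n_planted_links + design.n_core_background]
    background = genera[1 + design.n_planted_links + design.n_core_background:]
    n_forced = 1 + len(link_genera) + len(core) * design.core_prevalence
    want_present = (1 - design.target_zero_fraction) * design.n_taxa_genus
    bg_prev = max((want_present - n_forced) / max(len(background), 1),
                  design.min_background_prevalence)
    bg_mu = rng.normal(-2.0, 1.0, len(background))

    # autoscaled true concentrations of the linked features
    zmat = {}
    for (_, feat, _, _) in links:
        v = conc[feat].to_numpy()
        zmat[feat] = (v - v.mean()) / v.std(ddof=1)

    lo, hi = design.dominant_frac_range
    depth = np.rint(rng.lognormal(np.log(design.library_size_median),
                                  design.library_size_sigma, n)).astype(int)

    genus_index = genera + soil_genera + contam_genera
    prop = np.zeros((n, len(genus_index)))
    gpos = {g: i for i, g in enumerate(genus_index)}
    for si, s in enumerate(sids):
        d = rng.uniform(lo, hi)
        w = np.zeros(len(genus_index))
        for gi, (taxon, feat, sign, slope) in enumerate(links):
            g = link_genera[gi]
            eta = -1.0 + sign * slope * zmat[feat][si] + rng.normal(0, design.link_noise_sd)
            w[gpos[g]] = np.exp(eta)
        for g in core:
            if rng.random() < design.core_prevalence:
                w[gpos[g]] = np.exp(rng.normal(-1.0, 0.8))
        for bi, g in enumerate(background):
            if rng.random() < bg_prev:
                w[gpos[g]] = np.exp(rng.normal(bg_mu[bi], 1.0))
        for g in contam_genera:
            if rng.random() < 0.4:
                w[gpos[g]] = np.exp(rng.normal(-7.0, 0.6))
        tot = w.sum()
        if tot == 0:
            w[gpos[core[0] if core else genera[-1]]] = 1.0
            tot = 1.0
        w *= (1 - d) / tot
        w[gpos[dominant]] = d
        prop[si] = w

    counts = np.zeros((n, len(all_asvs)), dtype=np.int64)
    apos = {a: i for i, a in enumerate(all_asvs)}
    for si in range(n):
        p_asv = np.zeros(len(all_asvs))
        for g in genus_index:
            pg = prop[si, gpos[g]]
            if pg <= 0:
                continue
            if g in split:
                members, wts = split[g]
                for a, wa in zip(members, wts):
                    p_asv[apos[a]] = pg * wa
            else:  # contaminant genera are single-ASV
                a = [x for x in contam_asvs if genus_of[x] == g][0]
                p_asv[apos[a]] = pg
        p_asv /= p_asv.sum()
        counts[si] = rng.multinomial(depth[si], p_asv)

    # --- soil samples ------------------------------------------------------
    soil_ids = [f"soil_{i + 1}" for i in range(design.n_soil)]
    soil_counts = np.zeros((design.n_soil, len(all_asvs)), dtype=np.int64)
    soil_mu = rng.normal(0, 1.0, design.n_soil_genera)
    for si in range(design.n_soil):
        w = np.zeros(len(all_asvs))
        for gi, g in enumerate(soil_genera):
            if rng.random() < 0.6:
                pg = np.exp(soil_mu[gi] + rng.normal(0, 0.8))
                members, wts = split[g]
                for a, wa in zip(members, wts):
                    w[apos[a]] = pg * wa
        w /= w.sum()
        soil_counts[si] = rng.multinomial(
            int(rng.lognormal(np.log(design.library_size_median), 0.25)), w)

    # --- negative controls: contaminants only ------------------------------
    ctrl_ids = [f"neg_{i + 1}" for i in range(design.n_negative_controls)]
    ctrl_counts = np.zeros((design.n_negative_controls, len(all_asvs)), dtype=np.int64)
    below = contam_asvs[-1]  # deliberately below the discard thresholds
    above = contam_asvs[:-1]
    for ci in range(design.n_negative_controls):
        main = rng.multinomial(design.control_total_reads - 10,
                               rng.dirichlet(np.full(len(above), 5.0)))
        for a, c in zip(above, main):
            ctrl_counts[ci, apos[a]] = c
        ctrl_counts[ci, apos[below]] = 10
    truth.expected_discarded_asvs = list(above)

    # --- assemble ----------------------------------------------------------
    all_counts = np.vstack([counts, soil_counts, ctrl_counts])
    index = sids + soil_ids + ctrl_ids
    counts_df = pd.DataFrame(all_counts, index=pd.Index(index, name="sample_id"),
                             columns=all_asvs)
    meta = pd.DataFrame({
        "type": (["horseradish_site1"] * n + ["soil"] * design.n_soil
                 + ["negative_control"] * design.n_negative_controls),
        "accession": [s[0] for s in sids] + [""] * (design.n_soil + design.n_negative_controls),
        "year": ([2000 + int(s.split("_")[0][1:]) for s in sids]
                 + [2018] * design.n_soil + [0] * design.n_negative_controls),
    }, index=counts_df.index)

    # confidence profiles: some genus-unresolved, some order-only, some kingdom-only
    conf_profile = {}
    protect = {a for a in all_asvs
               if genus_of[a] in set(link_genera) | {dominant} | set(contam_genera)}
    loose = [a for a in asv_ids if a not in protect]
    rng.shuffle(loose)
    n_fam = int(0.08 * len(loose))
    n_ord = int(0.04 * len(loose))
    n_kng = int(0.03 * len(loose))
    for a in loose[:n_fam]:
        conf_profile[a] = "family"
    for a in loose[n_fam:n_fam + n_ord]:
        conf_profile[a] = "order"
    for a in loose[n_fam + n_ord:n_fam + n_ord + n_kng]:
        conf_profile[a] = "kingdom"
    taxonomy = _taxonomy_frame(rng, all_asvs, genus_of, lineage, conf_profile)

    return AsvTable(counts_df, meta, taxonomy), truth


def gen_tree(asv_ids, seed: int = 0) -> str:
    """Random bifurcating newick over the given ASV ids (UniFrac input)."""
    return random_bifurcating_newick(asv_ids, seed)
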