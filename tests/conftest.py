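import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chemobiome.community import AsvTable, RANKS
from chemobiome.qc import MetaboFeatureTable
from chemobiome.synthetic import SynthDesign, gen_community, gen_metabolome_batch

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_design():
    return SynthDesign(seed=11)


@pytest.fixture(scope="session")
def metabolome(default_design):
    """One standard simulated LC-MS batch plus its ground truth."""
    return gen_metabolome_batch(default_design)


@pytest.fixture(scope="session")
def full_dataset():
    """A planted-link dataset shared by integration-level tests."""
    design = SynthDesign(seed=5, n_planted_links=10)
    table, truth = gen_metabolome_batch(design)
    asv, truth = gen_community(design, truth)
    return design, table, asv, truth


def make_feature_table(intensities, roles, run_order=None, dilution=None,
                       dry_weight=None, annotated=None):
    """Hand-build a small MetaboFeatureTable for unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    n, p = intensities.shape
    inj_ids = [f"inj{i}" for i in range(n)]
    fids = [f"f{j}" for j in range(p)]
    inj = pd.DataFrame({
        "run_order": run_order if run_order is not None else np.arange(1, n + 1),
        "role": roles,
        "dilution_factor": dilution if dilution is not None else [np.nan] * n,
        "dry_weight_mg": dry_weight if dry_weight is not None else [np.nan] * n,
    }, index=pd.Index(inj_ids, name="injection_id"))
    feats = pd.DataFrame({
        "mz": 100.0, "rt": 1.0, "polarity": "positive",
        "annotated": annotated if annotated is not None else False,
    }, index=pd.Index(fids, name="feature_id"))
    return MetaboFeatureTable(
        pd.DataFrame(intensities, index=inj.index, columns=fids), inj, feats)


def make_asv_table(counts, types, taxonomy=None, accession=None, year=None):
    """Hand-build a small AsvTable; default taxonomy is fully confident."""
    counts = pd.DataFrame(counts)
    counts.index = [f"s{i}" for i in range(counts.shape[0])]
    counts.columns = [f"asv{j}" for j in range(counts.shape[1])]
    counts = counts.astype(np.int64)
    samples = pd.DataFrame({
        "type": types,
        "accession": accession if accession is not None else [""] * len(counts),
        "year": year if year is not None else [2018] * len(counts),
    }, index=counts.index)
    if taxonomy is None:
        taxonomy = {}
        for j, a in enumerate(counts.columns):
            row = {}
            labels = {"kingdom": "Fungi", "phylum": "Ascomycota", "class": "C1",
                      "order": "O1", "family": "Fam1", "genus": f"Gen{j}"}
            for r in RANKS:
                row[r] = labels[r]
                row[f"conf_{r}"] = 0.99
            taxonomy[a] = row
        taxonomy = pd.DataFrame.from_dict(taxonomy, orient="index")
    return AsvTable(counts, samples, taxonomy)
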