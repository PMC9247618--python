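"""ASV filtering, taxonomic aggregation, zero imputation and log-ratio transforms.

Marker-gene count tables are compositional: only relative information is
carried, and log-ratio coordinates (clr / ilr) are required before ordinary
multivariate statistics apply.  Zeros block the logarithm, so counts are first
imputed with a Bayesian-multiplicative replacement after a prevalence filter
chosen to bring the zero fraction under one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "RANK_PREFIX",
    "AsvTable",
    "AggregatedCommunity",
    "filter_control_asvs",
    "filter_taxonomy",
    "aggregate_taxa",
    "default_prevalence_grid",
    "optimize_prevalence_filter",
    "bayesian_multiplicative_replace",
    "clr",
    "ilr_basis",
    "ilr",
    "ilr_inverse",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIX = {"kingdom": "k__", "phylum": "p__", "class": "c__",
               "order": "o__", "family": "f__", "genus": "g__"}

SAMPLE_TYPES = ("horseradish_site1", "horseradish_site2", "carrot", "soil",
                "negative_control", "qc_mix")


@dataclass
class AsvTable:
    """Samples x ASVs count matrix with sample metadata and per-rank taxonomy.

    ``samples`` carries ``type`` (one of :data:`SAMPLE_TYPES`), ``accession``
    and ``year``; ``taxonomy`` carries one label column per rank in
    :data:`RANKS` (empty string = unassigned) and a matching ``conf_<rank>``
    bootstrap-confidence column in [0, 1].
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.samples.index):
            raise ValueError("counts and sample metadata indexes differ")
        if not self.counts.columns.equals(pd.Index(self.taxonomy.index)):
            raise ValueError("count columns and taxonomy indexes differ")
        arr = self.counts.to_numpy()
        if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.integer)):
            raise ValueError("counts must be non-negative integers")
        bad = set(self.samples["type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValueError(f"unknown sample types: {sorted(bad)}")

    def subset_samples(self, ids) -> "AsvTable":
        ids = list(ids)
        return AsvTable(self.counts.loc[ids].copy(), self.samples.loc[ids].copy(),
                        self.taxonomy.copy())

    def subset_asvs(self, ids) -> "AsvTable":
        ids = list(ids)
        return AsvTable(self.counts[ids].copy(), self.samples.copy(),
                        self.taxonomy.loc[ids].copy())


@dataclass
class AggregatedCommunity:
    """Counts pooled at a (possibly mixed) taxonomic level, with provenance."""

    counts: pd.DataFrame
    rank: str
    provenance: dict[str, list[str]] = field(default_factory=dict)


def filter_control_asvs(
    table: AsvTable, min_frac: float = 0.005, min_reads: int = 25
) -> tuple[AsvTable, list[str]]:
    """Discard ASVs that are prominent in any negative-control sample.

    An ASV is removed from all samples iff in at least one negative control it
    has >= ``min_reads`` reads AND makes up >= ``min_frac`` of that control's
    total.  Rare cross-over into controls is tolerated, so ecologically valid
    sequences are not purged wholesale.  Returns the filtered table and the
    list of discarded ASV ids.
    """
    ctrl = table.counts.loc[table.samples["type"] == "negative_control"]
    if ctrl.shape[0] == 0:
        warnings.warn("no negative-control samples: control filter is a no-op")
        return table, []
    totals = ctrl.sum(axis=1)
    nonzero = totals > 0
    frac = ctrl.loc[nonzero].div(totals[nonzero], axis=0)
    hit = ((ctrl.loc[nonzero] >= min_reads) & (frac >= min_frac)).any(axis=0)
    discarded = sorted(hit.index[hit])
    keep = [a for a in table.counts.columns if a not in set(discarded)]
    return table.subset_asvs(keep), discarded


def filter_taxonomy(table: AsvTable, min_conf: float = 0.80) -> AsvTable:
    """Truncate low-confidence rank labels; drop ASVs resolved only to kingdom.

    A rank label survives iff its bootstrap confidence >= ``min_conf`` and no
    shallower rank already failed (lineages cannot skip ranks).  ASVs whose
    deepest surviving rank is kingdom, or that keep nothing, are removed.
    """
    tax = table.taxonomy.copy()
    keep_ids = []
    for asv, row in tax.iterrows():
        depth = -1
        for i, rank in enumerate(RANKS):
            label = row[rank]
            conf = row[f"conf_{rank}"]
            if label and pd.notna(conf) and conf >= min_conf:
                depth = i
            else:
                break
        for i, rank in enumerate(RANKS):
            if i > depth:
                tax.at[asv, rank] = ""
                tax.at[asv, f"conf_{rank}"] = np.nan
        if depth >= 1:  # deeper than kingdom
            keep_ids.append(asv)
    out = AsvTable(table.counts[keep_ids].copy(), table.samples.copy(),
                   tax.loc[keep_ids])
    return out


def _label_at(row: pd.Series, rank: str) -> str | None:
    """Deepest available label at or above ``rank``, with its UNITE prefix."""
    idx = RANKS.index(rank)
    for i in range(idx, -1, -1):
        label = row[RANKS[i]]
        if label:
            return RANK_PREFIX[RANKS[i]] + label
    return None


def aggregate_taxa(table: AsvTable, rank: str) -> AggregatedCommunity:
    """Pool ASVs sharing a taxonomic label at ``rank`` (genus/order/phylum).

    ASVs unresolved at the requested rank fall back to their deepest reliable
    label, prefixed with that rank's UNITE marker, yielding mixed-level taxa
    (e.g. ``f__Nectriaceae`` inside a genus-level table).  Reads are conserved:
    the pooled matrix has the same total as its member ASVs.
    """
    if rank not in ("phylum", "order", "genus"):
        raise ValueError(f"unsupported aggregation rank: {rank!r}")
    labels, provenance = {}, {}
    for asv, row in table.taxonomy.iterrows():
        lab = _label_at(row, rank)
        if lab is None:
            continue
        labels[asv] = lab
        provenance.setdefault(lab, []).append(asv)
    mapped = pd.Series(labels)
    counts = table.counts[mapped.index].T.groupby(mapped).sum().T
    counts = counts[sorted(counts.columns)]
    return AggregatedCommunity(counts, rank, {k: provenance[k] for k in sorted(provenance)})


def default_prevalence_grid() -> list[tuple[float, int]]:
    """Default (min_prevalence, min_count) search grid for the zero optimizer."""
    return [(p, c)
            for p in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
            for c in (1, 2, 5, 10, 25)]


def optimize_prevalence_filter(
    agg: AggregatedCommunity,
    grid: list[tuple[float, int]] | None = None,
    max_zero_fraction: float = 0.5,
) -> tuple[tuple[float, int], pd.DataFrame, pd.DataFrame]:
    """Grid-search the taxon prevalence filter that best prepares imputation.

    A taxon survives a grid point ``(min_prevalence, min_count)`` iff it holds
    >= ``min_count`` reads in >= ``min_prevalence`` of the samples.  Among
    grid points whose filtered matrix has a zero fraction below
    ``max_zero_fraction``, the winner maximises retained reads and then
    retained taxa.  Returns ``(chosen_params, filtered_counts, report)`` where
    the report lists every candidate evaluated.
    """
    if grid is None:
        grid = default_prevalence_grid()
    if not grid:
        raise ValueError("empty parameter grid")
    X = agg.counts
    n = X.shape[0]
    total_reads = X.to_numpy().sum()
    rows = []
    present = X.sum(axis=0) > 0  # absent taxa are never "retained"
    for prev, cnt in grid:
        keep = ((X >= cnt).sum(axis=0) / n >= prev) & present
        sub = X.loc[:, keep]
        nz = float((sub.to_numpy() == 0).mean()) if sub.size else 1.0
        rows.append({
            "min_prevalence": prev, "min_count": cnt,
            "taxa": int(keep.sum()), "reads": int(sub.to_numpy().sum()),
            "read_fraction": float(sub.to_numpy().sum() / total_reads) if total_reads else 0.0,
            "zero_fraction": nz,
            "eligible": bool(sub.size and nz < max_zero_fraction),
        })
    report = pd.DataFrame(rows)
    elig = report[report["eligible"]]
    if elig.empty:
        best = report["zero_fraction"].min()
        raise ValueError(
            f"no grid point reaches zero fraction < {max_zero_fraction} "
            f"(best achieved: {best:.3f})")
    winner = elig.sort_values(["reads", "taxa"], ascending=False).iloc[0]
    params = (float(winner["min_prevalence"]), int(winner["min_count"]))
    keep = ((X >= params[1]).sum(axis=0) / n >= params[0]) & present
    return params, X.loc[:, keep].copy(), report


def bayesian_multiplicative_replace(
    counts: pd.DataFrame, prior_strength=None
) -> pd.DataFrame:
    """Replace count zeros by posterior-expected proportions (Dirichlet prior).

    With a uniform prior of strength ``s`` (default: sqrt of the row total),
    each zero in a row with total ``n`` becomes ``(s/D) / (n + s)``, capped at
    65% of the row's smallest observed proportion so imputed parts always stay
    below anything actually seen; observed parts are shrunk by a common factor
    so the row returns to the simplex, preserving their ratios exactly.
    """
    X = counts.to_numpy(dtype=float)
    n_i = X.sum(axis=1)
    if (n_i <= 0).any():
        raise ValueError("all-zero sample row: nothing to impute")
    if (X.sum(axis=0) == 0).any():
        warnings.warn("taxon absent from every sample: imputation is prior-driven")
    D = X.shape[1]
    if prior_strength is None:
        s = np.sqrt(n_i)
    else:
        s = np.broadcast_to(np.asarray(prior_strength, dtype=float), n_i.shape).copy()
    P = X / n_i[:, None]
    out = np.empty_like(P)
    for i in range(X.shape[0]):
        zero = X[i] == 0
        if not zero.any():
            out[i] = P[i]
            continue
        repl = (s[i] / D) / (n_i[i] + s[i])
        cap = 0.65 * P[i][~zero].min()
        repl = min(repl, cap)
        out[i, zero] = repl
        mass = repl * zero.sum()
        out[i, ~zero] = P[i, ~zero] * (1.0 - mass)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def clr(composition) -> np.ndarray | pd.DataFrame:
    """Centered log-ratio transform: log(part / geometric mean), row-wise."""
    X = np.asarray(composition, dtype=float)
    if (X <= 0).any():
        raise ValueError("clr requires strictly positive parts")
    L = np.log(X)
    out = L - L.mean(axis=-1, keepdims=True)
    if isinstance(composition, pd.DataFrame):
        return pd.DataFrame(out, index=composition.index, columns=composition.columns)
    return out


def ilr_basis(D: int) -> np.ndarray:
    """Helmert-type orthonormal sequential-binary-partition basis, D x (D-1).

    Coordinate k contrasts the geometric mean of the first k parts against
    part k+1; columns are orthonormal and sum to zero, so ilr coordinates are
    an isometry of the clr (Aitchison) geometry.
    """
    V = np.zeros((D, D - 1))
    for k in range(1, D):
        V[:k, k - 1] = 1.0 / np.sqrt(k * (k + 1))
        V[k, k - 1] = -np.sqrt(k / (k + 1))
    return V


def ilr(composition, basis: np.ndarray | None = None):
    """Isometric log-ratio coordinates: clr projected on an orthonormal basis."""
    X = np.asarray(composition, dtype=float)
    D = X.shape[-1]
    if basis is None:
        basis = ilr_basis(D)
    if basis.shape != (D, D - 1):
        raise ValueError(f"basis must be {D} x {D - 1}, got {basis.shape}")
    Z = clr(X) @ basis
    if isinstance(composition, pd.DataFrame):
        cols = [f"ilr{k + 1}" for k in range(D - 1)]
        return pd.DataFrame(Z, index=composition.index, columns=cols)
    return Z


def ilr_inverse(coordinates, basis: np.ndarray | None = None) -> np.ndarray:
    """Map ilr coordinates back to the simplex (softmax of the clr preimage)."""
    Z = np.asarray(coordinates, dtype=float)
    D = Z.shape[-1] + 1
    if basis is None:
        basis = ilr_basis(D)
    C = Z @ basis.T
    E = np.exp(C - C.max(axis=-1, keepdims=True))
    return E / E.sum(axis=-1, keepdims=True)
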