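"""Microbiome-metabolome correlation mining with pooled FDR control.

The inference engine: sparse PCA with a variance gate, ANOVA of retained
component scores on design factors, four Spearman pairings between fungal and
chemical representations ("rawcordf": taxa x features; "p2cordf": PCs x PCs;
"p1cordf_f": fungal PCs x features; "p1cordf_c": taxa x chemical PCs), a
single Benjamini-Hochberg family pooled over every p-value produced in a run,
quartile effect sizes for the direct taxon-feature associations, and the
fraction of community reads belonging to taxa with at least one significant
association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .qc import autoscale

__all__ = [
    "SpcaResult",
    "ScanResult",
    "spca",
    "gate_pcs",
    "pc_anova",
    "spearman_test",
    "spearman_matrix",
    "quartile_effect_size",
    "group_effect_size",
    "bh_adjust",
    "run_correlation_scan",
    "correlated_read_fraction",
]

APPROACHES = ("rawcordf", "p2cordf", "p1cordf_f", "p1cordf_c")


# ---------------------------------------------------------------------------
# sparse PCA


@dataclass
class SpcaResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components, unit-norm columns
    variance_fraction: np.ndarray  # fraction of total variance per component
    keep_per_component: list      # sparsity setting actually applied


def _fix_sign(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Deterministic sign convention: largest-|loading| entry positive."""
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def _soft_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``v`` so only its ``keep`` largest-magnitude entries survive."""
    if keep >= v.size:
        return v
    lam = np.sort(np.abs(v))[::-1][keep]
    out = np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)
    return out


def spca(matrix, n_components: int, keep_per_component=None,
         max_iter: int = 500, tol: float = 1e-9) -> SpcaResult:
    """Sparse PCA by iterative rank-1 extraction with soft-thresholded loadings.

    ``keep_per_component`` limits how many variables load on each component
    (an int applies to all).  With sparsity disabled (None / all variables)
    the decomposition is computed by a direct SVD and equals ordinary PCA.
    The input is expected already centered/scaled (log-ratio fungal data or
    autoscaled chemistry); variance fractions are taken against the total
    variance of the input.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(dim)={min(n, p)}")
    if keep_per_component is None:
        keeps = [p] * n_components
    elif np.isscalar(keep_per_component):
        keeps = [int(keep_per_component)] * n_components
    else:
        keeps = [int(k) for k in keep_per_component]
        if len(keeps) != n_components:
            raise ValueError("keep_per_component length != n_components")
    total_var = (X ** 2).sum()
    if total_var == 0:
        raise ValueError("zero-variance input matrix")

    if all(k >= p for k in keeps):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        T = U[:, :n_components] * s[:n_components]
        V = Vt[:n_components].T
    else:
        R = X.copy()
        T = np.zeros((n, n_components))
        V = np.zeros((p, n_components))
        for h in range(n_components):
            _, s0, Vt0 = np.linalg.svd(R, full_matrices=False)
            v = Vt0[0]
            for _ in range(max_iter):
                t = R @ v
                v_new = _soft_keep(R.T @ t, keeps[h])
                nv = np.linalg.norm(v_new)
                if nv == 0:
                    v_new = v
                    break
                v_new /= nv
                if np.linalg.norm(v_new - v) < tol:
                    v = v_new
                    break
                v = v_new
            t = R @ v
            T[:, h], V[:, h] = t, v
            R = R - np.outer(t, v)
    _fix_sign(T, V)
    var_frac = (T ** 2).sum(axis=0) / total_var
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PC{h + 1}" for h in range(n_components)]
    vidx = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(p)
    return SpcaResult(
        pd.DataFrame(T, index=idx, columns=cols),
        pd.DataFrame(V, index=vidx, columns=cols),
        var_frac,
        keeps,
    )


def gate_pcs(result: SpcaResult, min_fraction: float = 0.025) -> list[str]:
    """Component labels whose variance-explained fraction exceeds the gate."""
    kept = [c for c, f in zip(result.scores.columns, result.variance_fraction)
            if f > min_fraction]
    if not kept:
        warnings.warn("no components pass the variance gate; downstream PC tests skipped")
    return kept


def pc_anova(scores_column, factor) -> tuple[float, float]:
    """One-way ANOVA of a component score on a design factor."""
    y = np.asarray(scores_column, dtype=float)
    f = np.asarray(factor)
    groups = [y[f == g] for g in pd.unique(f)]
    if len(groups) < 2:
        raise ValueError("factor has a single level")
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    F, p = scipy.stats.f_oneway(*groups)
    return float(F), float(p)


# ---------------------------------------------------------------------------
# Spearman machinery


def spearman_test(x, y, ci_method: str = "fisher", n_boot: int = 250,
                  seed: int = 0, alpha: float = 0.05):
    """Spearman rho with p-value and a confidence interval.

    rho is Pearson on average ranks; p uses the t approximation.  The CI is
    Fisher-z with the Fieller variance 1.06/(n-3) by default, or a
    percentile bootstrap over ``n_boot`` paired resamples.  Zero variance in
    either vector leaves rho undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), (float("nan"), float("nan"))
    rho, p = scipy.stats.spearmanr(x, y)
    zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
    if ci_method == "fisher":
        if n > 3 and abs(rho) < 1:
            se = np.sqrt(1.06 / (n - 3))
            z = np.arctanh(rho)
            ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
        else:
            ci = (rho, rho)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.std(x[idx]) == 0 or np.std(y[idx]) == 0:
                continue
            stats.append(scipy.stats.spearmanr(x[idx], y[idx]).statistic)
        if stats:
            lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            ci = (float(lo), float(hi))
        else:
            ci = (float("nan"), float("nan"))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return float(rho), float(p), ci


def spearman_matrix(X: pd.DataFrame, Y: pd.DataFrame):
    """All-pairs Spearman between columns of X and columns of Y (shared rows).

    Rank-transforms each column (average ranks), then computes the Pearson
    cross-correlation block and t-approximation p-values, matching
    :func:`spearman_test` pair by pair.  Columns of zero variance yield NaN.
    """
    n = X.shape[0]
    Rx = scipy.stats.rankdata(X.to_numpy(), axis=0)
    Ry = scipy.stats.rankdata(Y.to_numpy(), axis=0)

    def standardize(R):
        Z = R - R.mean(axis=0)
        sd = np.sqrt((Z ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(sd > 0, Z / sd, np.nan)
        return Z

    Zx, Zy = standardize(Rx), standardize(Ry)
    rho = np.clip(Zx.T @ Zy, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    rho_df = pd.DataFrame(rho, index=X.columns, columns=Y.columns)
    p_df = pd.DataFrame(p, index=X.columns, columns=Y.columns)
    return rho_df, p_df


# ---------------------------------------------------------------------------
# effect sizes


def quartile_effect_size(chem, fungal) -> float:
    """|mean fungal response in top chemical quartile - bottom quartile| in SD units.

    Quartile membership uses linearly interpolated percentiles; ties keep all
    tied samples.  The denominator is the sample SD of the fungal vector over
    all samples; a constant fungal vector gives 0 by convention.
    """
    chem = np.asarray(chem, dtype=float)
    fungal = np.asarray(fungal, dtype=float)
    if chem.size < 8:
        raise ValueError("need n >= 8 for a quartile split")
    sd = fungal.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return 0.0
    q1, q3 = np.percentile(chem, [25, 75])
    low = fungal[chem <= q1]
    high = fungal[chem >= q3]
    return float(abs(high.mean() - low.mean()) / sd)


def group_effect_size(values, groups) -> float:
    """|max group mean - min group mean| / sample SD of all values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    means = [values[groups == g].mean() for g in pd.unique(groups)]
    if len(means) < 2:
        raise ValueError("need >= 2 groups")
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return 0.0
    return float((max(means) - min(means)) / sd)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over one pooled family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the scan


@dataclass
class ScanResult:
    records: pd.DataFrame          # one row per tested pair
    anova: pd.DataFrame            # PC-on-factor ANOVA results
    fungal_pca: dict               # level -> SpcaResult
    chem_pca: "SpcaResult"
    gated: dict                    # block -> retained PC labels
    pooled_n: int = 0              # size of the pooled BH family
    extra_n: int = 0               # externally supplied tests in the family


def _record(approach, level, fid, cid, n, rho, p, ci, effect):
    return {"approach": approach, "fungal_level": level, "fungal_id": fid,
            "chem_id": cid, "n": n, "rho": rho, "p": p,
            "ci_low": ci[0], "ci_high": ci[1], "effect_size": effect}


def run_correlation_scan(
    fungal_clr: dict[str, pd.DataFrame],
    fungal_ilr: dict[str, pd.DataFrame],
    chem: pd.DataFrame,
    annotated: pd.Series | None = None,
    diversity: pd.DataFrame | None = None,
    factors: pd.DataFrame | None = None,
    *,
    max_pcs_fungal: int = 6,
    max_pcs_chem: int = 12,
    keep_fungal=None,
    keep_chem=None,
    pc_gate: float = 0.025,
    q: float = 0.05,
    rsd_restrict: float = 0.66,
    ci_method: str = "fisher",
    n_boot: int = 250,
    seed: int = 0,
    extra_pvalues=None,
) -> ScanResult:
    """Run the four Spearman pairings at every fungal level with pooled BH.

    ``fungal_clr`` / ``fungal_ilr`` map level name (phylum/order/genus) to
    log-ratio matrices over the same samples as ``chem`` (fold-change
    features).  Direct taxon-feature tests ("rawcordf") are restricted to
    features that are annotated or highly variable (cross-sample RSD >
    ``rsd_restrict``); diversity indices enter the rawcordf pairing only.
    Component scores come from sPCA capped at ``max_pcs_fungal`` /
    ``max_pcs_chem`` components and gated at ``pc_gate`` variance fraction;
    gated scores are also tested against the design ``factors`` by ANOVA.
    All p-values (plus any ``extra_pvalues`` from the caller, e.g. ANOSIM or
    Kruskal-Wallis) form a single BH family; records are flagged significant
    at adjusted p < ``q`` and rawcordf records carry quartile effect sizes.
    """
    sample_index = chem.index
    for lvl, M in fungal_clr.items():
        if not M.index.equals(sample_index):
            raise ValueError(f"sample ids misaligned between chem and fungal level {lvl}")
    n = len(sample_index)

    # feature restriction for direct tests
    mean = chem.mean(axis=0)
    sd = chem.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        feature_rsd = (sd / mean).where(mean > 0)
    eligible = feature_rsd > rsd_restrict
    if annotated is not None:
        eligible = eligible | annotated.reindex(chem.columns).fillna(False).astype(bool)
    chem_direct = chem.loc[:, eligible.fillna(False)]

    chem_scaled = autoscale(chem)
    chem_pca = spca(chem_scaled, min(max_pcs_chem, *chem_scaled.shape), keep_chem)
    gated: dict[str, list[str]] = {"chem": gate_pcs(chem_pca, pc_gate)}
    chem_scores = chem_pca.scores[gated["chem"]]

    records: list[dict] = []
    fungal_pcas: dict[str, SpcaResult] = {}

    def scan_block(approach, level, X, Y, with_effect):
        rho, p = spearman_matrix(X, Y)
        xa, ya = X.to_numpy(), Y.to_numpy()
        for i, fid in enumerate(X.columns):
            for j, cid in enumerate(Y.columns):
                r = rho.iat[i, j]
                if not np.isfinite(r):
                    warnings.warn(f"skipping zero-variance pair ({fid}, {cid})")
                    continue
                if abs(r) < 1 and n > 3:
                    se = np.sqrt(1.06 / (n - 3))
                    z = np.arctanh(r)
                    zc = scipy.stats.norm.ppf(0.975)
                    ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
                else:
                    ci = (r, r)
                eff = quartile_effect_size(ya[:, j], xa[:, i]) if with_effect else np.nan
                records.append(_record(approach, level, fid, cid, n, r, p.iat[i, j], ci, eff))

    for level, Xclr in fungal_clr.items():
        fpca = spca(fungal_ilr[level],
                    min(max_pcs_fungal, *fungal_ilr[level].shape), keep_fungal)
        fungal_pcas[level] = fpca
        gated[level] = gate_pcs(fpca, pc_gate)
        fscores = fpca.scores[gated[level]]
        if chem_direct.shape[1]:
            scan_block("rawcordf", level, Xclr, chem_direct, with_effect=True)
        if fscores.shape[1] and chem_scores.shape[1]:
            scan_block("p2cordf", level, fscores, chem_scores, with_effect=False)
        if fscores.shape[1]:
            scan_block("p1cordf_f", level, fscores, chem, with_effect=False)
        if chem_scores.shape[1]:
            scan_block("p1cordf_c", level, Xclr, chem_scores, with_effect=False)

    if diversity is not None and chem_direct.shape[1]:
        div = diversity.loc[sample_index].dropna(axis=1)
        scan_block("rawcordf", "diversity", div, chem_direct, with_effect=True)

    rec_df = pd.DataFrame(records)

    # PC-on-factor ANOVA, part of the same pooled family
    anova_rows = []
    if factors is not None:
        blocks = [("chem", None, chem_scores)] + [
            (lvl, lvl, fungal_pcas[lvl].scores[gated[lvl]]) for lvl in fungal_clr
        ]
        for name, _lvl, scores in blocks:
            for pc in scores.columns:
                for fac in factors.columns:
                    if factors[fac].nunique() < 2:
                        continue
                    F, p = pc_anova(scores[pc].loc[sample_index],
                                    factors[fac].loc[sample_index])
                    anova_rows.append({"block": name, "component": pc,
                                       "factor": fac, "F": F, "p": p})
    anova_df = pd.DataFrame(anova_rows)

    extra = np.asarray(extra_pvalues, dtype=float) if extra_pvalues is not None else np.array([])
    pool = np.concatenate([
        rec_df["p"].to_numpy() if len(rec_df) else np.array([]),
        anova_df["p"].to_numpy() if len(anova_df) else np.array([]),
        extra,
    ])
    adj = bh_adjust(pool) if pool.size else pool
    k = len(rec_df)
    m = len(anova_df)
    if k:
        rec_df["p_adj"] = adj[:k]
        rec_df["significant"] = rec_df["p_adj"] < q
    if m:
        anova_df["p_adj"] = adj[k:k + m]
        anova_df["significant"] = anova_df["p_adj"] < q

    return ScanResult(rec_df, anova_df, fungal_pcas, chem_pca, gated,
                      pooled_n=int(pool.size), extra_n=int(extra.size))


def correlated_read_fraction(records: pd.DataFrame, agg_counts: pd.DataFrame,
                             level: str) -> float:
    """Fraction of retained reads in taxa with >= 1 significant direct association."""
    if len(records):
        sig = records[(records["approach"] == "rawcordf")
                      & (records["fungal_level"] == level)
                      & records.get("significant", False)]
        taxa = sig["fungal_id"].unique().tolist()
    else:
        taxa = []
    missing = set(taxa) - set(agg_counts.columns)
    if missing:
        raise ValueError(f"taxa in records missing from counts: {sorted(missing)}")
    total = agg_counts.to_numpy().sum()
    if total == 0:
        return 0.0
    return float(agg_counts[taxa].to_numpy().sum() / total)
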