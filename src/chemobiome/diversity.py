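"""Alpha/beta diversity, ordination and group-difference tests for ASV counts.

All measures operate on the raw, non-pooled ASV matrix (diversity is computed
before any taxonomic pooling).  Shannon entropy is reported in nats,
Dominance is the Simpson concentration sum(p^2), evenness is Buzas-Gibson
e^H / S, and richness is extrapolated with the abundance-based coverage
estimator (ACE).  Beta diversity offers Bray-Curtis, pairwise Whittaker
turnover and unweighted UniFrac over a supplied phylogeny, with PCoA,
ANOSIM and SIMPER on top.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .trees import tree_edge_matrix

__all__ = [
    "alpha_profile",
    "alpha_table",
    "bray_curtis",
    "whittaker",
    "unweighted_unifrac",
    "pcoa",
    "anosim",
    "simper",
    "kruskal_wallis",
]


def alpha_profile(counts_row, rare_threshold: int = 10) -> dict:
    """Alpha-diversity summary of one sample: richness, ACE, Shannon, Dominance, evenness.

    ACE splits taxa at ``rare_threshold`` reads; the rare group estimates
    sample coverage C = 1 - F1/N_rare and the squared coefficient of
    variation of rare abundances (floored at 0).  With no rare taxa ACE
    equals observed richness; when every rare taxon is a singleton coverage
    is zero and ACE is undefined (returned as NaN with a warning).
    """
    x = np.asarray(counts_row, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty sample: no positive counts")
    n = x.sum()
    p = x / n
    shannon = float(-(p * np.log(p)).sum())
    dominance = float((p ** 2).sum())
    s_obs = int(x.size)
    evenness = float(np.exp(shannon) / s_obs)

    rare = x[x <= rare_threshold]
    s_rare = rare.size
    if s_rare == 0:
        ace = float(s_obs)
    else:
        s_abund = s_obs - s_rare
        n_rare = rare.sum()
        f1 = int((rare == 1).sum())
        c_ace = 1.0 - f1 / n_rare
        if c_ace == 0:
            warnings.warn("ACE undefined: all rare taxa are singletons")
            ace = float("nan")
        else:
            freqs = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)])
            i_arr = np.arange(1, rare_threshold + 1)
            gamma2 = (s_rare / c_ace) * (i_arr * (i_arr - 1) * freqs).sum() / (
                n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0
            gamma2 = max(gamma2, 0.0)
            ace = float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)
    return {"richness": s_obs, "ace": ace, "shannon": shannon,
            "dominance": dominance, "evenness": evenness}


def alpha_table(counts: pd.DataFrame, rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample alpha-diversity profile over a samples x taxa count matrix."""
    return pd.DataFrame(
        {sid: alpha_profile(counts.loc[sid], rare_threshold) for sid in counts.index}
    ).T


def _as_beta(dm: np.ndarray, ids, metric: str) -> pd.DataFrame:
    out = pd.DataFrame(dm, index=ids, columns=ids)
    out.attrs["metric"] = metric
    return out


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    X = counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    if (den == 0).any() and counts.shape[0] > 1:
        bad = np.argwhere((den == 0) & ~np.eye(X.shape[0], dtype=bool))
        if len(bad):
            raise ValueError("a pair of all-zero samples has undefined Bray-Curtis")
    dm = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(dm, 0.0)
    return _as_beta(dm, counts.index, "bray_curtis")


def whittaker(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Whittaker turnover S_union / mean(S_a, S_b) - 1 on presence/absence."""
    P = (counts.to_numpy() > 0)
    if P.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rich = P.sum(axis=1).astype(float)
    if (rich == 0).any():
        raise ValueError("empty sample has undefined Whittaker turnover")
    union = (P[:, None, :] | P[None, :, :]).sum(axis=2)
    mean_rich = (rich[:, None] + rich[None, :]) / 2.0
    dm = union / mean_rich - 1.0
    np.fill_diagonal(dm, 0.0)
    return _as_beta(dm, counts.index, "whittaker")


def unweighted_unifrac(counts: pd.DataFrame, newick: str) -> pd.DataFrame:
    """Unweighted UniFrac: unique branch length / spanned branch length.

    Every branch of the tree is classified per sample pair by whether its
    descendant leaves intersect each sample's presence set; the distance is
    the total length of branches leading only to one sample's taxa divided by
    the length spanned by their union.
    """
    E, lengths, leaves = tree_edge_matrix(newick)
    present_taxa = counts.columns[(counts.to_numpy() > 0).any(axis=0)]
    missing = set(present_taxa) - set(leaves)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]} ...")
    idx = {t: i for i, t in enumerate(leaves)}
    P = np.zeros((counts.shape[0], len(leaves)), dtype=bool)
    for j, taxon in enumerate(counts.columns):
        if taxon in idx:
            P[:, idx[taxon]] = counts.iloc[:, j].to_numpy() > 0
    reach = E @ P.T > 0  # (edges, samples): edge subtends >=1 present leaf
    n = counts.shape[0]
    dm = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            either = reach[:, a] | reach[:, b]
            unique = reach[:, a] ^ reach[:, b]
            span = lengths[either].sum()
            dm[a, b] = dm[b, a] = lengths[unique].sum() / span if span > 0 else 0.0
    return _as_beta(dm, counts.index, "unweighted_unifrac")


def pcoa(beta: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a dissimilarity matrix (Gower double-centering).

    Axes for negative eigenvalues (non-Euclidean input) are dropped, not
    corrected; the full eigenvalue spectrum is returned so callers can see
    them.  Coordinates are scaled by sqrt(eigenvalue).
    """
    D = beta.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("beta matrix must be square symmetric")
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-9 * max(abs(vals[0]), 1.0)
    if k > pos.sum():
        raise ValueError(f"k={k} exceeds the {int(pos.sum())} positive axes")
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=beta.index, columns=cols), vals


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(beta: pd.DataFrame, groups, n_perm: int = 9999, seed: int = 0,
           ) -> tuple[float, float]:
    """One-way ANOSIM: are between-group distances ranked above within-group ones?

    R = (mean between rank - mean within rank) / (M/2) with M the number of
    sample pairs; p is the one-sided permutation probability of an R at least
    as large.  Singleton groups are excluded with a warning.
    """
    groups = pd.Series(np.asarray(groups), index=beta.index)
    sizes = groups.value_counts()
    singletons = sizes.index[sizes < 2]
    if len(singletons):
        warnings.warn(f"excluding singleton groups: {list(singletons)}")
        keep = ~groups.isin(singletons)
        beta, groups = beta.loc[keep, keep], groups[keep]
    if groups.nunique() < 2:
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members")
    D = beta.to_numpy()
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = scipy.stats.rankdata(D[iu])
    labels = groups.to_numpy()
    within = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu[0]] == perm[iu[1]]) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return r_obs, float(p)


def simper(counts: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-taxon contribution to the average between-group Bray-Curtis dissimilarity.

    For every between-group sample pair the Bray-Curtis numerator is split by
    taxon; averaging over pairs decomposes the mean dissimilarity exactly.
    Returns contributions sorted descending with cumulative percentages.
    """
    groups = pd.Series(np.asarray(groups), index=counts.index)
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("SIMPER compares exactly 2 groups per call")
    A = counts.loc[groups == levels[0]].to_numpy(dtype=float)
    B = counts.loc[groups == levels[1]].to_numpy(dtype=float)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty group")
    diff = np.abs(A[:, None, :] - B[None, :, :])          # (na, nb, taxa)
    den = (A[:, None, :] + B[None, :, :]).sum(axis=2)     # (na, nb)
    contrib = (diff / den[:, :, None]).mean(axis=(0, 1))
    out = pd.DataFrame({"contribution": contrib}, index=counts.columns)
    out = out.sort_values("contribution", ascending=False)
    total = out["contribution"].sum()
    out["cumulative_pct"] = 100 * out["contribution"].cumsum() / total if total > 0 else 0.0
    out.attrs["mean_dissimilarity"] = float(contrib.sum())
    return out


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on g-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)
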