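"""Quality-control gating and drift correction for untargeted LC-MS feature tables.

An untargeted run yields an injections x features intensity matrix in which
pooled-QC injections recur throughout the sequence and a short dilution series
of the pooled QC probes response linearity.  This module implements the
acceptance funnel (precision filter on QC RSD, linearity filter on the
dilution series) and the downstream corrections (LOESS drift removal against
the QCs, dry-weight normalisation, autoscaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetaboFeatureTable",
    "QCAssessment",
    "compute_rsd",
    "linearity_r2",
    "accept_features",
    "loess_fit",
    "loess_correct",
    "dry_weight_normalize",
    "autoscale",
]

ROLES = ("sample", "qc", "qc_dilution", "blank")


@dataclass
class MetaboFeatureTable:
    """Injections x features intensity matrix with injection/feature metadata.

    ``intensities`` is indexed by injection id; ``injections`` carries
    ``run_order`` (unique, increasing ints), ``role`` (sample / qc /
    qc_dilution / blank), ``dilution_factor`` (qc_dilution rows only) and
    ``dry_weight_mg`` (sample rows only).  ``features`` carries ``mz``, ``rt``,
    ``polarity`` and the boolean ``annotated`` flag used by the correlation
    scan's feature restriction.
    """

    intensities: pd.DataFrame
    injections: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.injections.index):
            raise ValueError("intensities and injection metadata indexes differ")
        if not self.intensities.columns.equals(pd.Index(self.features.index)):
            raise ValueError("intensity columns and feature metadata indexes differ")
        ro = self.injections["run_order"]
        if ro.duplicated().any():
            raise ValueError("run_order values must be unique")
        bad = set(self.injections["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown injection roles: {sorted(bad)}")
        dil = self.injections.loc[self.injections["role"] == "qc_dilution", "dilution_factor"]
        if dil.isna().any() or (dil <= 0).any():
            raise ValueError("every qc_dilution injection needs a positive dilution_factor")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")

    @property
    def sample_ids(self) -> pd.Index:
        return self.injections.index[self.injections["role"] == "sample"]

    def role_matrix(self, role: str) -> pd.DataFrame:
        return self.intensities.loc[self.injections["role"] == role]

    def subset_features(self, keep) -> "MetaboFeatureTable":
        keep = list(keep)
        return MetaboFeatureTable(
            self.intensities[keep].copy(),
            self.injections.copy(),
            self.features.loc[keep].copy(),
        )


@dataclass
class QCAssessment:
    """Per-feature QC verdicts: ``rsd``, ``linearity_r2`` and pass flags."""

    table: pd.DataFrame
    rsd_max: float
    r2_min: float
    n_discarded_rsd: int = field(init=False)
    n_discarded_linearity: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_discarded_rsd = int((~self.table["pass_rsd"]).sum())
        self.n_discarded_linearity = int(
            (self.table["pass_rsd"] & ~self.table["pass_linearity"]).sum()
        )

    @property
    def passing(self) -> pd.Index:
        return self.table.index[self.table["pass"]]


def compute_rsd(qc_values) -> float:
    """Relative standard deviation (sample SD / mean) of in-sequence QC values.

    Returns ``nan`` for degenerate input (zero mean), which downstream code
    treats as a failed feature rather than an error.
    """
    v = np.asarray(qc_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def linearity_r2(dilution_factors, abundances, blank_abundance) -> float:
    """Squared Pearson correlation of abundance vs concentration (1/dilution).

    The blank enters as the concentration-0 point, so a feature whose signal
    is blank-dominated (flat response) has undefined r2 and fails the filter.
    """
    d = np.asarray(dilution_factors, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if d.shape != a.shape:
        raise ValueError("dilution_factors and abundances length mismatch")
    conc = np.concatenate([[0.0], 1.0 / d])
    resp = np.concatenate([[float(blank_abundance)], a])
    if np.std(resp) == 0 or np.std(conc) == 0:
        return float("nan")
    r = np.corrcoef(conc, resp)[0, 1]
    return float(r * r)


def accept_features(
    table: MetaboFeatureTable,
    rsd_max: float = 0.30,
    r2_min: float = 0.8,
    include_leading_qcs: bool = True,
) -> QCAssessment:
    """Apply the precision (RSD <= ``rsd_max``) and linearity (r2 > ``r2_min``) gates.

    RSD uses all in-sequence pooled-QC injections (the leading equilibration
    block included by default); linearity uses the dilution series plus the
    first blank.  Features with fewer than 3 finite QC values auto-fail.
    """
    qcs = table.role_matrix("qc")
    if qcs.shape[0] == 0:
        raise ValueError("no QC injections: table is not QC-correctable")
    if not include_leading_qcs:
        ro = table.injections.loc[qcs.index, "run_order"]
        first_sample = table.injections.loc[table.injections["role"] == "sample", "run_order"].min()
        qcs = qcs.loc[ro[ro > first_sample].index]

    dil_meta = table.injections[table.injections["role"] == "qc_dilution"]
    dil_rows = table.intensities.loc[dil_meta.index]
    blanks = table.role_matrix("blank")
    blank_row = blanks.iloc[0] if blanks.shape[0] else pd.Series(0.0, index=table.intensities.columns)

    recs = {}
    qarr = qcs.to_numpy()
    for j, fid in enumerate(table.intensities.columns):
        col = qarr[:, j]
        finite = np.isfinite(col)
        rsd = compute_rsd(col[finite]) if finite.sum() >= 3 else float("nan")
        pass_rsd = bool(np.isfinite(rsd) and rsd <= rsd_max)
        if dil_rows.shape[0] >= 3:
            r2 = linearity_r2(
                dil_meta["dilution_factor"].to_numpy(),
                dil_rows[fid].to_numpy(),
                blank_row[fid],
            )
        else:
            r2 = float("nan")
        pass_lin = bool(np.isfinite(r2) and r2 > r2_min)
        recs[fid] = (rsd, r2, pass_rsd, pass_lin, pass_rsd and pass_lin)
    tab = pd.DataFrame.from_dict(
        recs, orient="index", columns=["rsd", "linearity_r2", "pass_rsd", "pass_linearity", "pass"]
    )
    tab.index.name = "feature_id"
    return QCAssessment(tab, rsd_max, r2_min)


def loess_fit(x, y, x_eval, span: float = 0.75, degree: int = 1) -> np.ndarray:
    """Tricube-weighted local polynomial fit of ``y`` on ``x``, evaluated at ``x_eval``.

    Evaluation points are clamped to ``[min(x), max(x)]`` so extrapolation
    beyond the first/last anchor returns the boundary fitted value.  ``y`` may
    be 1-D or 2-D (observations x series); the smoother matrix depends only on
    ``x`` so all series share it.
    """
    x = np.asarray(x, dtype=float)
    y2 = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, n_series)
    if x.size != y2.shape[0]:
        raise ValueError("x and y length mismatch")
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} anchor points for degree {degree}")
    order = np.argsort(x)
    x, y2 = x[order], y2[order]
    xe = np.clip(np.asarray(x_eval, dtype=float), x[0], x[-1])
    k = max(int(np.ceil(span * x.size)), degree + 2)
    k = min(k, x.size)
    out = np.empty((xe.size, y2.shape[1]))
    for i, x0 in enumerate(xe):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1.0)
        w = np.clip(1 - (d / h) ** 3, 0, 1) ** 3
        w[d > h] = 0.0
        X = np.vander(x - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ y2, rcond=None)
        out[i] = beta[0]
    return out if np.ndim(y) > 1 else out[:, 0]


def loess_correct(
    table: MetaboFeatureTable,
    span: float = 0.75,
    degree: int = 1,
    include_leading_qcs: bool = True,
) -> MetaboFeatureTable:
    """Divide out per-feature instrument drift estimated from the QC injections.

    For every feature a LOESS curve is fitted to QC intensity vs run order and
    each injection's intensity is divided by the curve at its own run order.
    Output values are fold-changes against the pooled QC (QC rows land near
    1.00), which makes sequences comparable and the dilution series unitless.
    """
    qc_mask = table.injections["role"] == "qc"
    if not include_leading_qcs:
        first_sample = table.injections.loc[table.injections["role"] == "sample", "run_order"].min()
        qc_mask &= table.injections["run_order"] > first_sample
    xq = table.injections.loc[qc_mask, "run_order"].to_numpy(dtype=float)
    if xq.size < max(3, degree + 2):
        raise ValueError("need at least 3 QC injections spanning the run for drift correction")
    yq = table.intensities.loc[qc_mask].to_numpy()
    x_all = table.injections["run_order"].to_numpy(dtype=float)
    fitted = loess_fit(xq, yq, x_all, span=span, degree=degree)
    if (fitted <= 0).any():
        warnings.warn("non-positive LOESS fit encountered; flooring at tiny epsilon")
        fitted = np.maximum(fitted, 1e-12)
    corrected = table.intensities.to_numpy() / fitted
    return MetaboFeatureTable(
        pd.DataFrame(corrected, index=table.intensities.index, columns=table.intensities.columns),
        table.injections.copy(),
        table.features.copy(),
    )


def dry_weight_normalize(table: MetaboFeatureTable, reference_mg: float = 25.0) -> MetaboFeatureTable:
    """Scale each biological sample row by reference dry weight / its dry weight.

    QC, dilution and blank rows have no dry weight and pass through unchanged.
    """
    w = table.injections.loc[table.injections["role"] == "sample", "dry_weight_mg"]
    if w.isna().any() or (w <= 0).any():
        missing = w.index[w.isna() | (w <= 0)].tolist()
        raise ValueError(f"missing/non-positive dry weight for samples: {missing}")
    out = table.intensities.copy()
    out.loc[w.index] = out.loc[w.index].mul(reference_mg / w, axis=0)
    return MetaboFeatureTable(out, table.injections.copy(), table.features.copy())


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to unit sample SD (ddof=1).

    Zero-variance columns cannot be scaled and are dropped with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    sd = matrix.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance columns in autoscale")
        matrix = matrix.drop(columns=dead)
        sd = sd.drop(dead)
    return (matrix - matrix.mean(axis=0)) / sd
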