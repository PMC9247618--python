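"""Tab-separated I/O for every artifact the pipeline reads or writes.

One tabular dialect everywhere: UTF-8 TSV with '.' decimals, ids in the
first column.  Parse errors name the offending cell.  Newick files go
through dendropy.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import AsvTable, RANKS
from .qc import MetaboFeatureTable
from .trees import parse_newick

__all__ = [
    "write_feature_table", "read_feature_table",
    "write_counts", "read_counts",
    "write_taxonomy", "read_taxonomy",
    "write_sample_metadata", "read_sample_metadata",
    "read_asv_table",
    "write_newick", "read_newick",
    "write_truth_json", "write_json",
]


def _read_tsv(path, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing required column {index_col!r}")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    return df.set_index(index_col)


def _numeric(df: pd.DataFrame, path, allow_negative=True) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col] != "")
        if bad.any():
            row = bad.idxmax()
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                             f"{df.at[row, col]!r}")
        if not allow_negative and (vals < 0).any():
            row = (vals < 0).idxmax()
            raise ValueError(f"{path}: negative value at row {row!r}, column {col!r}")
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


# --- metabolomics feature table --------------------------------------------

_INJ_COLS = ["run_order", "role", "dilution_factor", "dry_weight_mg"]


def write_feature_table(table: MetaboFeatureTable, path) -> None:
    """Feature table TSV: injection metadata columns then one column per feature."""
    out = pd.concat([table.injections[_INJ_COLS], table.intensities], axis=1)
    out.index.name = "injection_id"
    out.to_csv(path, sep="\t")
    meta_path = Path(path).with_suffix(".features.tsv")
    table.features.to_csv(meta_path, sep="\t")


def read_feature_table(path) -> MetaboFeatureTable:
    df = _read_tsv(path, "injection_id")
    missing = [c for c in _INJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    inj = df[_INJ_COLS].copy()
    inj["run_order"] = pd.to_numeric(inj["run_order"]).astype(int)
    inj["dilution_factor"] = pd.to_numeric(inj["dilution_factor"], errors="coerce")
    inj["dry_weight_mg"] = pd.to_numeric(inj["dry_weight_mg"], errors="coerce")
    intens = _numeric(df.drop(columns=_INJ_COLS), path, allow_negative=False)
    meta_path = Path(path).with_suffix(".features.tsv")
    if meta_path.exists():
        feats = _read_tsv(meta_path, "feature_id")
        feats["mz"] = pd.to_numeric(feats["mz"])
        feats["rt"] = pd.to_numeric(feats["rt"])
        feats["annotated"] = feats["annotated"].isin(["True", "true", "1"])
        feats = feats.loc[intens.columns]
    else:
        feats = pd.DataFrame({"mz": np.nan, "rt": np.nan, "polarity": "",
                              "annotated": False},
                             index=pd.Index(intens.columns, name="feature_id"))
    return MetaboFeatureTable(intens, inj, feats)


# --- community tables -------------------------------------------------------


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = _numeric(_read_tsv(path, "sample_id"), path, allow_negative=False)
    return df.astype(np.int64)


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.rename_axis("asv_id").to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    df = _read_tsv(path, "asv_id")
    need = list(RANKS) + [f"conf_{r}" for r in RANKS]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing taxonomy columns {missing}")
    for r in RANKS:
        df[r] = df[r].fillna("")
        df[f"conf_{r}"] = pd.to_numeric(df[f"conf_{r}"], errors="coerce")
    return df


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path, "sample_id")
    if "type" not in df.columns:
        raise ValueError(f"{path}: missing required column 'type'")
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce").fillna(0).astype(int)
    df["accession"] = df.get("accession", pd.Series("", index=df.index)).fillna("")
    return df


def read_asv_table(counts_path, metadata_path, taxonomy_path) -> AsvTable:
    counts = read_counts(counts_path)
    meta = read_sample_metadata(metadata_path).loc[counts.index]
    tax = read_taxonomy(taxonomy_path).loc[counts.columns]
    return AsvTable(counts, meta, tax)


# --- newick and JSON --------------------------------------------------------


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.strip() + "\n", encoding="utf-8")


def read_newick(path) -> str:
    text = Path(path).read_text(encoding="utf-8").strip()
    parse_newick(text)  # validates; raises a precise dendropy error
    return text


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n",
        encoding="utf-8")


def write_truth_json(truth, path) -> None:
    write_json(truth.to_jsonable(), path)
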