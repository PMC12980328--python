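"""Readers and writers for expression matrices, metadata and result tables.

Formats are plain TSV/CSV (gzip by ``.gz`` suffix). Expression matrices are
feature x sample with a header row of sample ids and the feature id in the
first column; ``NA`` or an empty cell marks a missing value. Result tables
are long-format (one pair per row) with the run's effective configuration
echoed in ``#``-prefixed header lines, floats at 9 significant digits.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .partitioning import FeatureVector

__all__ = [
    "read_expression",
    "expression_to_features",
    "read_metadata",
    "metadata_to_features",
    "write_results",
    "read_results",
]

_NA_VALUES = ["NA", ""]


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample matrix; NaN marks missing entries.

    Raises on duplicate feature or sample ids and on non-numeric cells,
    naming the offending coordinates.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     na_values=_NA_VALUES, keep_default_na=False,
                     comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        out[col] = converted
    out.index.name = df.index.name or "feature_id"
    return out


def expression_to_features(expr: pd.DataFrame) -> list[FeatureVector]:
    """One numerical FeatureVector per matrix row."""
    return [
        FeatureVector.from_numerical(str(fid), expr.loc[fid].to_numpy(float))
        for fid in expr.index
    ]


def read_metadata(
    path: str | Path,
    type_overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a sample metadata table (first column = sample id).

    Columns whose non-missing values all parse as numbers are typed
    numerical, everything else categorical; ``type_overrides`` (variable ->
    "numerical" | "categorical") wins. The inferred type of each column is
    stored in ``DataFrame.attrs["types"]``.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     na_values=_NA_VALUES, keep_default_na=False)
    sample_col = df.columns[0]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    overrides = dict(type_overrides or {})
    types: dict[str, str] = {}
    for col in df.columns[1:]:
        if col in overrides:
            kind = overrides[col]
            if kind not in ("numerical", "categorical"):
                raise ValueError(f"invalid type override for {col!r}: {kind!r}")
        else:
            converted = pd.to_numeric(df[col], errors="coerce")
            parse_fail = converted.isna() & df[col].notna()
            kind = "categorical" if parse_fail.any() else "numerical"
        types[col] = kind
    df = df.set_index(sample_col)
    df.attrs["types"] = types
    return df


def metadata_to_features(
    metadata: pd.DataFrame, sample_ids: Sequence[str]
) -> list[FeatureVector]:
    """Align metadata to the expression sample order; build FeatureVectors.

    Samples absent from the metadata are treated as missing in every
    variable; zero overlap is an error.
    """
    overlap = [s for s in sample_ids if s in metadata.index]
    if not overlap:
        raise ValueError("no overlapping samples between expression and metadata")
    aligned = metadata.reindex(list(sample_ids))
    types = metadata.attrs.get("types", {})
    feats = []
    for col in metadata.columns:
        kind = types.get(col, "categorical")
        if kind == "numerical":
            feats.append(
                FeatureVector.from_numerical(
                    col, pd.to_numeric(aligned[col], errors="coerce").to_numpy(float)
                )
            )
        else:
            vals = [None if pd.isna(v) else v for v in aligned[col]]
            feats.append(FeatureVector.from_categorical(col, vals))
    return feats


def _format_float(v: object) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, float):
        return format(v, ".9g")
    return str(v)


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a long-format results TSV with ``#`` provenance header lines."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(table.columns) + "\n")
        for row in table.itertuples(index=False):
            fh.write("\t".join(_format_float(v) for v in row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table, skipping ``#`` header lines."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(_io.StringIO(text), sep="\t", na_values=_NA_VALUES,
                       keep_default_na=False)
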