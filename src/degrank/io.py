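"""Readers and writers for the plain-text formats used throughout.

Expression matrices are TSV with the probe ID in the first column; sample
metadata lives in a sidecar TSV (sample ID, type, site, platform).
Annotation maps are two-column TSV (probe ID, gene symbol).  Gene sets use
the GMT convention: name, description, then tab-separated member symbols.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError
from .matrix import ExpressionMatrix

PROBE_COLUMN = "probe_id"


def read_expression(
    path: str | Path,
    meta_path: str | Path | None = None,
    scale: str = "log2",
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns")
    samples = None
    if meta_path is not None:
        samples = read_sample_metadata(meta_path)
    return ExpressionMatrix(df, scale, samples)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = PROBE_COLUMN
    out.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"site": str})
    required = {"type", "site", "platform"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"{path}: metadata lacks columns {sorted(missing)}")
    return meta


def write_sample_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe-to-gene map; returns columns ``probe_id`` and ``gene``."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if ann.shape[1] < 2:
        raise DataError(f"{path}: annotation needs two columns")
    ann = ann.iloc[:, :2]
    ann.columns = [PROBE_COLUMN, "gene"]
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> tuple[dict[str, tuple[str, ...]], dict[str, str]]:
    """Parse GMT; returns (sets, descriptions)."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}: GMT line has fewer than 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in sets:
            raise DataError(f"{path}: duplicate gene-set name {name!r}")
        sets[name] = tuple(m for m in members if m)
        descriptions[name] = desc
    return sets, descriptions


def write_gmt(
    sets: dict[str, tuple[str, ...]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "is_deg" not in df.columns:
        raise DataError(f"{path}: truth table lacks 'is_deg' column")
    df["is_deg"] = df["is_deg"].astype(bool)
    return df


def write_truth_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
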