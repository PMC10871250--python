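"""Readers and writers for the package's on-disk formats.

Images travel as multi-page TIFF (one page per channel, 16-bit); tables
as TSV; gene sets as GMT; melt curves as two-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .enrich import GeneSet
from .simdata import MeltCurve, SyntheticField

__all__ = [
    "write_field_tiff", "read_field_tiff",
    "write_label_mask", "read_label_mask",
    "write_table", "read_table",
    "read_counts", "read_metadata",
    "read_gmt", "write_gmt",
    "read_melt_curve", "write_melt_curve",
]


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_field_tiff(path, field: SyntheticField) -> None:
    """Two-page TIFF: page 0 nuclear channel, page 1 reporter channel."""
    tifffile.imwrite(path, np.stack([_to_uint16(field.nuclear_channel),
                                     _to_uint16(field.reporter_channel)]))


def read_field_tiff(path):
    """Returns (nuclear, reporter) float arrays from a two-page TIFF."""
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] < 2:
        raise ValueError(f"{path}: expected a multi-page TIFF with >= 2 channels")
    return pages[0].astype(float), pages[1].astype(float)


def write_label_mask(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, _to_uint16(labels))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_table(path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (genes as row index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    mat = df.to_numpy()
    if np.any(mat < 0):
        raise ValueError(f"{path}: negative counts")
    return df.astype(np.int64)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample, assay, genotype, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "genotype", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df.set_index("sample")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT lines need id, description, >= 1 gene")
        sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g),
                            description=parts[1]))
    return sets


def write_gmt(path, sets) -> None:
    lines = ["\t".join([s.set_id, s.description or "na", *sorted(s.genes)])
             for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_melt_curve(path) -> MeltCurve:
    df = pd.read_csv(path, sep="\t")
    if not {"temperature", "fluorescence"} <= set(df.columns):
        raise ValueError(f"{path}: need columns temperature, fluorescence")
    return MeltCurve(df["temperature"].to_numpy(), df["fluorescence"].to_numpy())


def write_melt_curve(path, curve: MeltCurve) -> None:
    pd.DataFrame({"temperature": curve.temperature,
                  "fluorescence": curve.fluorescence}).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
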