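"""Stable file contracts: tab-separated tables, YAML config, JSON reports.

All tabular artifacts are TSV with a one-line header; floats are serialized
at six significant digits so that identical runs produce byte-identical
files.  The radial coordinate of an excluded cell is written as an empty
field and read back as NaN.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coordinates import NORMALIZED_COLUMNS
from .simulate import RAW_COLUMNS

__all__ = [
    "read_raw_table",
    "write_raw_table",
    "read_normalized_table",
    "write_normalized_table",
    "write_table",
    "write_matrix",
    "read_matrix",
    "write_zone_report",
    "read_config",
    "write_manifest",
    "read_loci_table",
]

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="")


def read_raw_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"raw table missing columns: {sorted(missing)}")
    return df[RAW_COLUMNS]


def write_raw_table(df: pd.DataFrame, path) -> None:
    write_table(df[RAW_COLUMNS], path)


def read_normalized_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(NORMALIZED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"normalized table missing columns: {sorted(missing)}")
    return df[NORMALIZED_COLUMNS]


def write_normalized_table(df: pd.DataFrame, path) -> None:
    write_table(df[NORMALIZED_COLUMNS], path)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Gene x gene matrix with the gene names as first column."""
    out = df.copy()
    out.insert(0, "gene", df.index)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene").rename_axis(index=None)


def write_zone_report(partition, path) -> None:
    Path(path).write_text(json.dumps(partition.to_dict(), indent=2) + "\n")


def read_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_manifest(path, seed: int, config: dict | None = None, **extra) -> None:
    from . import __version__

    manifest = {
        "seed": seed,
        "config_hash": None if config is None else config_hash(config),
        "version": __version__,
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_loci_table(path) -> dict[str, tuple[str, int, int, str]]:
    """Locus file: name, chrom, start, end, strand (TSV, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = ["name", "chrom", "start", "end", "strand"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"loci table missing columns: {sorted(missing)}")
    return {
        row.name_: (row.chrom, int(row.start), int(row.end), row.strand)
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    }


def write_loci_table(loci: dict[str, tuple[str, int, int, str]], path) -> None:
    rows = [(n, c, s, e, st) for n, (c, s, e, st) in sorted(loci.items())]
    write_table(
        pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"]), path
    )
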