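"""TSV / GMT / YAML readers and writers for every pipeline table.

All matrices are TSV with a header row and ids in the first column; writing
then reading a table returns an identical object. Regulatory networks use
the three-column (TR, target, mode) dialect of curated TR-target resources.
"""

from __future__ import annotations

from pathlib import Path
import warnings

import pandas as pd

from .types import IntensityTable

MODES = {"activation", "repression", "unknown"}


def read_matrix(path, index_name: str | None = None) -> pd.DataFrame:
    """Read a TSV matrix with first-column ids; rejects duplicate ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate row ids in {path}: {list(dups[:3])}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate column ids in {path}")
    if index_name:
        df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_series(path) -> pd.Series:
    df = read_matrix(path)
    return df.iloc[:, 0]


def write_series(s: pd.Series, path) -> None:
    write_matrix(s.to_frame(), path)


def read_regulatory_network(path) -> pd.DataFrame:
    """Read a (TR, target, mode) edge list.

    Mode tokens are case-insensitive ("Activation", "Repression", "Unknown").
    Duplicate (TR, target) pairs are collapsed; pairs listed with conflicting
    modes become "unknown" with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["tr", "target", "mode"], dtype=str)
    if df.isna().any().any():
        raise ValueError(f"malformed network file {path}: missing fields")
    df["mode"] = df["mode"].str.lower()
    bad = ~df["mode"].isin(MODES)
    if bad.any():
        raise ValueError(f"malformed mode tokens in {path}: {df['mode'][bad].unique()}")
    grouped = df.groupby(["tr", "target"], sort=False)["mode"].agg(set)
    conflicts = grouped[grouped.apply(len) > 1]
    if len(conflicts):
        warnings.warn(f"{len(conflicts)} TR-target pairs with conflicting modes set to 'unknown'")
    mode = grouped.apply(lambda s: next(iter(s)) if len(s) == 1 else "unknown")
    return mode.reset_index().rename(columns={0: "mode"})


def write_regulatory_network(network: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    network[["tr", "target", "mode"]].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT pathway sets: name <tab> description <tab> member ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def write_intensity_table(table: IntensityTable, prefix) -> None:
    """Write intensities and sample metadata side by side."""
    prefix = Path(prefix)
    write_matrix(table.intensity, prefix.with_suffix(".intensity.tsv"))
    write_matrix(table.sample_meta, prefix.with_suffix(".samples.tsv"))


def read_intensity_table(prefix) -> IntensityTable:
    prefix = Path(prefix)
    intensity = read_matrix(prefix.with_suffix(".intensity.tsv"))
    meta = read_matrix(prefix.with_suffix(".samples.tsv"))
    meta["cell_line"] = meta["cell_line"].astype(object).where(meta["cell_line"].notna(), None)
    if "pool_id" in meta:
        meta["pool_id"] = meta["pool_id"].fillna("")
    return IntensityTable(intensity, meta)
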