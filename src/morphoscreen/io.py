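"""Readers/writers for the pipeline's tabular artifacts.

Tables travel as delimited text (.csv/.tsv) or columnar binary (.parquet),
chosen by file suffix. Gene sets use the GMT convention (name, description,
members per tab-separated line); ranked lists use two-column RNK text.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".parquet":
        df.to_parquet(path, index=index)
    elif suffix == ".tsv":
        df.to_csv(path, sep="\t", index=index)
    elif suffix == ".csv":
        df.to_csv(path, index=index)
    else:
        raise ValueError(f"unsupported table format: {path.suffix!r}")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".parquet":
        return pd.read_parquet(path)
    if suffix == ".tsv":
        return pd.read_csv(path, sep="\t")
    if suffix == ".csv":
        return pd.read_csv(path)
    raise ValueError(f"unsupported table format: {path.suffix!r}")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_rnk(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "value"], comment="#")
    return df.set_index("gene")


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked.reset_index()[["gene", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_json(payload, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_fasta(library: pd.DataFrame, path) -> None:
    """Guide sequences as FASTA, one record per guide_id."""
    with open(path, "w") as fh:
        for _, row in library.iterrows():
            fh.write(f">{row['guide_id']} gene={row['gene']}\n{row['sequence']}\n")
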