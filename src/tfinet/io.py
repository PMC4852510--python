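"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED convention). Matrices
travel as TSV with a header row and the row identifier in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a TSV matrix (rows = features, columns = samples)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_bed(path) -> pd.DataFrame:
    """Read a 6-column BED file into a DataFrame (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int,
                            "name": str, "score": float, "strand": str})
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set file: term <tab> description <tab> member...

    Returns a mapping term -> (description, member set).
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        terms[fields[0]] = (fields[1], frozenset(fields[2:]))
    return terms


def write_gmt(terms: dict[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in terms.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
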