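"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is tab-separated text, GMT, MatrixMarket, or JSON so that runs
are diffable and fixtures stay human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format (name, description, members...)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write a gene x cell count matrix as matrix.mtx + genes.tsv + barcodes.tsv."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(counts.to_numpy())
    scipy.io.mmwrite(str(prefix / "matrix.mtx"), sparse)
    pd.Series(counts.index).to_csv(prefix / "genes.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(counts.columns).to_csv(prefix / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix / "matrix.mtx")).toarray()
    genes = pd.read_csv(prefix / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(prefix / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(mat, index=genes, columns=cells)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
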