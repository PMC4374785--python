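"""Minimal GCT v1.2 / v1.3 reader and writer.

GCT is the tab-delimited gene x sample matrix format used by landmark
profiling toolchains: a version line (``#1.2`` or ``#1.3``), a dimensions
line, a header row and then one row per gene.  v1.2 carries a single
``Description`` metadata column; v1.3 declares arbitrary row/column
metadata counts on the dimensions line.  The reader accepts both dialects
and returns the matrix as a float DataFrame (genes x samples); row
descriptions ride along in ``DataFrame.attrs['description']``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


class GctError(ValueError):
    """Malformed GCT file."""


def read_gct(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise GctError(f"{path.name}: unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if version == "#1.2":
            if len(dims) != 2:
                raise GctError(f"{path.name}: v1.2 dimensions line must have 2 fields")
            n_rows, n_cols = map(int, dims)
            n_rmeta, n_cmeta = 1, 0
        else:
            if len(dims) != 4:
                raise GctError(f"{path.name}: v1.3 dimensions line must have 4 fields")
            n_rows, n_cols, n_rmeta, n_cmeta = map(int, dims)
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1 + n_rmeta :]
        if len(sample_ids) != n_cols:
            raise GctError(
                f"{path.name}: header declares {len(sample_ids)} samples, expected {n_cols}"
            )
        for _ in range(n_cmeta):  # column metadata rows are tolerated, not modeled
            fh.readline()
        body = pd.read_csv(fh, sep="\t", header=None, nrows=n_rows)
    if body.shape != (n_rows, 1 + n_rmeta + n_cols):
        raise GctError(f"{path.name}: body shape {body.shape} does not match dimensions line")
    genes = body.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        raise GctError(f"{path.name}: duplicate gene ids")
    values = body.iloc[:, 1 + n_rmeta :]
    values.columns = sample_ids
    values.index = pd.Index(genes, name="gene")
    if values.isna().any().any():
        raise GctError(f"{path.name}: missing matrix cells")
    matrix = values.astype(float)
    if n_rmeta >= 1:
        matrix.attrs["description"] = body.iloc[:, 1].astype(str).tolist()
    return matrix


def write_gct(matrix: pd.DataFrame, path: str | Path, version: str = "1.2") -> None:
    if version not in ("1.2", "1.3"):
        raise GctError(f"unsupported GCT version {version!r}")
    n_rows, n_cols = matrix.shape
    desc = matrix.attrs.get("description") or ["na"] * n_rows
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#{version}\n")
        if version == "1.2":
            fh.write(f"{n_rows}\t{n_cols}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        else:
            fh.write(f"{n_rows}\t{n_cols}\t1\t0\n")
            fh.write("id\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for (gene, row), d in zip(matrix.iterrows(), desc):
            cells = "\t".join(format(v, ".10g") for v in row.to_numpy(float))
            fh.write(f"{gene}\t{d}\t{cells}\n")
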