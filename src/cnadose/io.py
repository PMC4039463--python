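"""Readers and writers for the pipeline's plain-text formats.

Everything on disk is TSV or BED; genomic intervals are 0-based half-open in
memory and in BED. Generator outputs carry ``# seed=<n>`` header comments;
expression matrices carry a ``# scale=linear|log2`` declaration.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _header_comments(path: Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                out[key.strip()] = val.strip()
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False,
              comments: dict[str, object] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, *, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_matrix(matrix: pd.DataFrame, path: str | Path, scale: str,
                 seed: int | None = None) -> None:
    comments: dict[str, object] = {"scale": scale}
    if seed is not None:
        comments["seed"] = seed
    write_tsv(matrix.rename_axis("gene_id"), path, index=True, comments=comments)


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a genes x samples matrix; returns (frame, declared scale)."""
    meta = _header_comments(Path(path))
    scale = meta.get("scale")
    if scale not in ("linear", "log2"):
        raise ValueError(f"{path}: missing or invalid scale declaration")
    return read_tsv(path, index_col=0), scale


def write_bed(genes: pd.DataFrame, path: str | Path,
              seed: int | None = None) -> None:
    """Gene annotation as BED: arm, start, end, gene_id."""
    bed = genes[["arm", "start", "end", "gene_id"]]
    comments = {"seed": seed} if seed is not None else None
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        bed.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["arm", "start", "end", "gene_id"])
    return df[["gene_id", "arm", "start", "end"]]


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
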