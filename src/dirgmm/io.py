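"""Readers and writers: TSV/CSV tables, newick trees, JSON artifacts.

All fitted artifacts are JSON (named fields, matrices as nested arrays) so
they diff cleanly and can be reused outside Python.  Every JSON document
written by the tool embeds provenance: tool version, the full config, the
seed, and SHA-256 checksums of its input files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from dirgmm.compositional import CountTable, TransformedData

__all__ = [
    "read_count_table",
    "read_transformed",
    "write_transformed",
    "read_tree",
    "write_json",
    "read_json",
    "file_checksum",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_count_table(path) -> CountTable:
    """Read a barcode x taxon table: first column barcode id, header taxa."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:
        raise ValueError(f"could not parse table {path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1))[0]) + 2  # header + 1-based
        raise ValueError(f"malformed row near line {bad} of {path}")
    return CountTable(
        barcode_ids=[str(i) for i in df.index],
        taxon_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(dtype=float),
    )


def read_transformed(path) -> TransformedData:
    """Read ILR coordinates: first column barcode id, header balance names."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.isna().any().any():
        raise ValueError(f"malformed rows in {path}")
    return TransformedData(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_transformed(data: TransformedData, path) -> None:
    df = pd.DataFrame(
        data.x,
        index=data.barcode_ids,
        columns=[f"balance{i}" for i in range(data.d)],
    )
    df.index.name = "barcode"
    df.to_csv(path, sep=_sep_for(path))


def read_tree(path) -> str:
    """Read a newick tree file and return its text."""
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise ValueError(f"{path} does not look like a newick file")
    return text


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(payload: dict, path, config: dict | None = None, seed=None, inputs=None) -> None:
    """Write a JSON artifact with an embedded provenance header."""
    from dirgmm import __version__

    doc = {
        "tool": "dirgmm",
        "version": __version__,
        "config": config or {},
        "seed": seed,
        "input_checksums": {str(p): file_checksum(p) for p in (inputs or [])},
        "payload": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
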