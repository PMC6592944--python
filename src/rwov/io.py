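"""Corpus file I/O.

A corpus lives in a delimited file (CSV/TSV) with a header of
``observation_id, text`` plus one label column per class, UTF-8 encoded.
JSON-lines records with the same keys are also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["read_corpus", "write_corpus"]

_REQUIRED = ("observation_id", "text")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"corpus file is missing columns: {missing}")
    df = df.copy()
    df["observation_id"] = df["observation_id"].astype(str)
    df["text"] = df["text"].fillna("").astype(str)
    return df


def read_corpus(path) -> pd.DataFrame:
    """Read a corpus from CSV/TSV (by extension) or JSON-lines."""
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson", ".json"}:
        with open(path, encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]
        return _validate(pd.DataFrame.from_records(records))
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    return _validate(pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False))


def write_corpus(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df = _validate(pd.DataFrame(df))
    if path.suffix in {".jsonl", ".ndjson"}:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
        return
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)
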