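"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular interchange is TSV with a header row; intervals are BED
(0-based half-open); reads are 4-line FASTQ plus a tagged-alignment TSV
that mirrors the FASTQ record-for-record with mapping coordinates.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

BED3_COLS = ["chrom", "start", "end"]
BED6_COLS = BED3_COLS + ["name", "score", "strand"]

#: columns of the tagged-alignment TSV emitted alongside synthetic FASTQ
ALIGNMENT_COLS = ["read_id", "chrom", "pos", "strand", "mapq", "fragment_length"]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    """Read a BED file into a DataFrame, naming up to six standard columns."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ValueError(f"malformed BED file {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ValueError(f"malformed BED file {path}: fewer than 3 columns")
    names = BED6_COLS[: min(df.shape[1], 6)]
    df.columns = names + [f"col{i}" for i in range(6, df.shape[1])]
    if n_cols is not None:
        df = df.iloc[:, :n_cols]
    bad = df.index[(df["end"] <= df["start"])]
    if len(bad):
        raise ValueError(f"malformed BED file {path}: end <= start at line {bad[0] + 1}")
    return df


def write_bed(df: pd.DataFrame, path, cols: list[str] | None = None) -> None:
    cols = cols or [c for c in BED6_COLS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (read_id, sequence, quality) triples as 4-line FASTQ records."""
    with _open(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_fastq(path):
    """Yield (read_id, sequence, quality) from a FASTQ file."""
    from Bio import SeqIO

    with _open(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), qual


def write_json(obj, path, indent: int = 2) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=indent, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=_json_default).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
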