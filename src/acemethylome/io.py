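"""Plain-text genomics I/O for the pipeline (FASTA, FASTQ, BED, TSV)."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd

BED_REPEAT_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                      "family", "class"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, list] = {}
    name = None
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            else:
                sequences[name].append(line)
    return {k: "".join(v) for k, v in sequences.items()}


def write_fastq(reads, path) -> None:
    """Write ``(read_id, seq, qual)`` triples as (optionally gzipped) FASTQ."""
    with _open(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    reads = []
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append((header.strip()[1:], seq, qual))
    return reads


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, columns=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = columns or (BED_REPEAT_COLUMNS if df.shape[1] >= 8 else BED6_COLUMNS)
    df.columns = cols + list(range(len(cols), df.shape[1]))
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
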