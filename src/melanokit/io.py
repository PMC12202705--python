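"""Readers and writers for the plain-text formats used across the pipeline.

Formats: survival CSV (``subject_id,group,time_weeks,event``), 4-line FASTQ,
MatrixMarket MTX with ``features.tsv``/``barcodes.tsv`` sidecars, GMT gene-set
files, and embeddings TSV with a cluster-label column.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from scipy import io as spio
from scipy import sparse

SURVIVAL_COLUMNS = ["subject_id", "group", "time_weeks", "event"]


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    """Read a right-censored survival table; validates schema and ranges."""
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival CSV {path} lacks required columns {missing}")
    if (df["time_weeks"] < 0).any():
        raise ValueError("negative times in survival table")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event column must be 0/1")
    return df[SURVIVAL_COLUMNS].copy()


def write_survival_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[SURVIVAL_COLUMNS].to_csv(path, index=False)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from FASTA or FASTQ, plain or gzipped."""
    from Bio import SeqIO

    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq)


def write_fastq(
    reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    """Write ``(read_id, sequence)`` pairs as 4-line FASTQ with constant quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for name, genes in sets.items():
            out.write("\t".join([name, name, *genes]) + "\n")


def read_mtx_bundle(
    mtx: str | Path, features: str | Path, barcodes: str | Path
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Read a genes x cells MTX with features/barcodes TSV sidecars."""
    x = sparse.csr_matrix(spio.mmread(mtx))
    genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    if x.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {x.shape} does not match {len(genes)} features x "
            f"{len(cells)} barcodes"
        )
    return x, genes, cells


def write_mtx_bundle(
    x: sparse.spmatrix,
    genes: Sequence[str],
    cells: Sequence[str],
    out_dir: str | Path,
) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / "matrix.mtx", sparse.coo_matrix(x))
    pd.Series(list(genes)).to_csv(out_dir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(list(cells)).to_csv(out_dir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_embedding_tsv(
    path: str | Path, label_column: str = "cluster"
) -> tuple[pd.DataFrame, pd.Series]:
    """Read an embeddings TSV; returns (coordinates, cluster labels)."""
    df = pd.read_csv(path, sep="\t")
    if label_column not in df.columns:
        raise ValueError(f"embedding TSV lacks label column {label_column!r}")
    labels = df[label_column].astype(str)
    coords = df.drop(columns=[label_column]).select_dtypes("number")
    if coords.shape[1] < 1:
        raise ValueError("embedding TSV has no numeric coordinate columns")
    return coords, labels
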