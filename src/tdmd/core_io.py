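"""Readers/writers, domain containers, configuration and logging.

Sequences are normalised to uppercase on input. Internally the toolkit works
in the DNA alphabet (printed constructs are DNA); RNA views are produced on
request with :meth:`SequenceRecord.as_rna`. Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("tdmd")

ALPHABET = set("ACGTUN")
FASTA_WRAP = 80  # fixed line-wrapping policy for writers


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending record."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (alphabet ACGTU, stored uppercase)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord requires a non-empty id")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def as_dna(self) -> "SequenceRecord":
        return replace(self, seq=self.seq.replace("U", "T"))

    def as_rna(self) -> "SequenceRecord":
        return replace(self, seq=self.seq.replace("T", "U"))


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTA file into SequenceRecords.

    Raises :class:`ParseError` on illegal characters or malformed headers,
    naming the offending record.
    """
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if first == "":
            return []
        if first != ">":
            raise ParseError(f"{path}: expected '>' on line 1, got {first!r}")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: record with empty header")
            try:
                records.append(
                    SequenceRecord(rec.id, str(rec.seq), rec.description)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records, path) -> None:
    """Write records wrapped at ``FASTA_WRAP`` columns."""
    with open(path, "wt") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), FASTA_WRAP):
                fh.write(rec.seq[i : i + FASTA_WRAP] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Lazily yield ``(id, seq, qual)`` from a 4-line FASTQ (optionally gzipped)."""
    with _open_maybe_gzip(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {n} ({title}): seq/qual length mismatch"
                    )
                yield title.split()[0], seq.upper(), qual
                n += 1
        except ValueError as exc:
            raise ParseError(f"{path}: record {n}: {exc}") from exc


def write_fastq(reads, path) -> None:
    with open(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative expression values (RPKM for genes, CPM for miRNAs).

    Thin validated wrapper around a pandas DataFrame with unique row
    (gene/miRNA) and column (condition) labels.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row labels: {dups}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate condition labels")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in matrix: {exc}") from exc
        if not np.isfinite(values).all():
            raise ValueError("matrix contains missing or non-finite values")
        if (values < 0).any():
            bad = df[(df < 0).any(axis=1)].index[0]
            raise ValueError(f"negative value in row {bad!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.df.columns)

    def __getitem__(self, key):
        return self.df[key]


def read_matrix(path) -> ExpressionMatrix:
    """Read a TSV matrix (header row + row labels) into an ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric cell at row {bad.index[0]!r}, column {col!r}"
            )
    if df.isna().any().any():
        row = df[df.isna().any(axis=1)].index[0]
        raise ParseError(f"{path}: missing cell in row {row!r}")
    try:
        return ExpressionMatrix(df.astype(float))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(matrix, path) -> None:
    df = matrix.df if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t")


def as_dataframe(matrix) -> pd.DataFrame:
    return matrix.df if isinstance(matrix, ExpressionMatrix) else matrix


@dataclass
class RunConfig:
    """Run-wide thresholds and options; defaults follow the published analysis.

    3C class boundaries: entry at -0.01, LOW/MID at -0.03, MID/HIGH at -0.05
    (boundary values fall into the more negative class). Expression cutoffs:
    genes expressed at >= 1 RPKM in at least one condition, miRNAs kept at
    strictly > 10 CPM. Duplex eligibility: high-affinity seed, >= 8 nt of
    contiguous 3' pairing, target-side central bulge of 1-7 nt ("strict"
    preset narrows the bulge to 3-4 nt).
    """

    seed: int = 0
    c3_entry: float = -0.01
    c3_low_mid: float = -0.03
    c3_mid_high: float = -0.05
    rpkm_min: float = 1.0
    cpm_min: float = 10.0
    min_3p: int = 8
    bulge_range: tuple[int, int] = (1, 7)
    eligibility_preset: str = "default"
    allow_wobble: bool = False
    log2fc_pseudocount: float = 0.1
    max_trim: int = 4
    max_tail: int = 4
    paths: dict = field(default_factory=dict)

    PRESETS = {"default": (1, 7), "strict": (3, 4)}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if "bulge_range" in known:
            cfg.bulge_range = tuple(known["bulge_range"])
        return cfg

    def with_preset(self, name: str) -> "RunConfig":
        if name not in self.PRESETS:
            raise ValueError(f"unknown eligibility preset {name!r}")
        cfg = replace(self)
        cfg.bulge_range = self.PRESETS[name]
        cfg.eligibility_preset = name
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bulge_range"] = list(self.bulge_range)
        return d

    def log(self) -> None:
        logger.info("resolved config: %s", self.to_dict())
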