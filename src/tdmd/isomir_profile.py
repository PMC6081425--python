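"""3' isomiR classification and tailing/trimming profiling.

Small-RNA reads already assigned to a mature miRNA are partitioned into
canonical reads, templated 3' extensions (the genomic sequence downstream of
the canonical end), non-templated 3' additions (tails: A-forms, U-forms, or
mixed), 3'-trimmed forms, and an OTHER bin. Mixed templated+non-templated
extensions are resolved conservatively: the longest templated prefix is
stripped before typing the tail. 5' isomiRs are out of scope and land in
OTHER.

Reads and references are compared in the DNA alphabet (sequencers emit T).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("tdmd")


class IsomiRClass(Enum):
    CANONICAL = "CANONICAL"
    TEMPLATED_3P = "TEMPLATED_3P"
    NT_A = "NT_A"
    NT_U = "NT_U"
    NT_MIXED = "NT_MIXED"
    TRIM = "TRIM"
    OTHER = "OTHER"


TAIL_CLASSES = {IsomiRClass.NT_A, IsomiRClass.NT_U, IsomiRClass.NT_MIXED}


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MiRNARefContext:
    """Canonical miRNA sequence plus >= 6 nt of downstream genomic context,
    needed to tell templated extensions from non-templated tails."""

    name: str
    canonical_seq: str
    downstream_genomic: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_seq", _dna(self.canonical_seq))
        object.__setattr__(self, "downstream_genomic", _dna(self.downstream_genomic))
        if len(self.downstream_genomic) < 6:
            raise ValueError(f"{self.name}: need >= 6 nt of downstream context")


@dataclass
class IsomiRProfile:
    """Per-miRNA isomiR composition (counts and percentages)."""

    mirna: str
    counts: dict
    n_reads: int
    percentages: dict
    pct_3nt: float
    pct_trim: float
    pct_a_forms: float
    pct_u_forms: float


def classify_read(
    read_seq: str,
    ref: MiRNARefContext,
    max_trim: int = 4,
    max_tail: int = 4,
) -> IsomiRClass:
    """Class of one read relative to its reference miRNA.

    The read must share the reference 5' end (assignment is by exact prefix;
    see :func:`assign_reads`); anything else is OTHER.
    """
    read = _dna(read_seq)
    canon = ref.canonical_seq
    if read == canon:
        return IsomiRClass.CANONICAL
    if read.startswith(canon):
        ext = read[len(canon):]
        # strip the longest templated prefix
        k = 0
        down = ref.downstream_genomic
        while k < len(ext) and k < len(down) and ext[k] == down[k]:
            k += 1
        tail = ext[k:]
        if not tail:
            return IsomiRClass.TEMPLATED_3P
        if len(tail) > max_tail:
            return IsomiRClass.OTHER
        if set(tail) == {"A"}:
            return IsomiRClass.NT_A
        if set(tail) == {"T"}:
            return IsomiRClass.NT_U
        return IsomiRClass.NT_MIXED
    if canon.startswith(read) and len(canon) - len(read) <= max_trim:
        return IsomiRClass.TRIM
    return IsomiRClass.OTHER


def assign_reads(
    reads: Iterable[tuple[str, str, str] | str],
    refs: Iterable[MiRNARefContext],
    max_trim: int = 4,
) -> dict[str, list[str]]:
    """Assign reads to references by exact prefix matching.

    A read belongs to a reference when it reproduces the canonical sequence
    up to the trimming window (the first ``len(canonical) - max_trim``
    nucleotides). Reads eligible for two references are ambiguous and go to
    the ``None`` pool, as do unmatched reads.
    """
    refs = list(refs)
    anchors = {r.name: r.canonical_seq[: len(r.canonical_seq) - max_trim] for r in refs}
    groups: dict[str, list[str]] = {r.name: [] for r in refs}
    groups[None] = []
    n_ambiguous = 0
    for item in reads:
        seq = _dna(item[1] if isinstance(item, tuple) else item)
        owners = [name for name, a in anchors.items() if seq.startswith(a)]
        if len(owners) == 1:
            groups[owners[0]].append(seq)
        else:
            if len(owners) > 1:
                n_ambiguous += 1
            groups[None].append(seq)
    if n_ambiguous:
        logger.info("%d ambiguous reads sent to the unassigned pool", n_ambiguous)
    return groups


def profile(
    groups: dict[str, list[str]],
    refs: Iterable[MiRNARefContext],
    max_trim: int = 4,
    max_tail: int = 4,
) -> dict[str, IsomiRProfile]:
    """IsomiR profile per miRNA; miRNAs with zero reads are omitted (logged)."""
    by_name = {r.name: r for r in refs}
    out: dict[str, IsomiRProfile] = {}
    for name, ref in by_name.items():
        reads = groups.get(name, [])
        if not reads:
            logger.info("miRNA %s has no assigned reads; profile omitted", name)
            continue
        counts = Counter(
            classify_read(seq, ref, max_trim, max_tail) for seq in reads
        )
        n = len(reads)
        pct = {cls: 100.0 * counts.get(cls, 0) / n for cls in IsomiRClass}
        out[name] = IsomiRProfile(
            mirna=name,
            counts={cls: counts.get(cls, 0) for cls in IsomiRClass},
            n_reads=n,
            percentages=pct,
            pct_3nt=sum(pct[c] for c in TAIL_CLASSES),
            pct_trim=pct[IsomiRClass.TRIM],
            pct_a_forms=pct[IsomiRClass.NT_A],
            pct_u_forms=pct[IsomiRClass.NT_U],
        )
    return out


def profiles_to_frame(profiles: dict[str, IsomiRProfile]) -> pd.DataFrame:
    rows = []
    for name, prof in profiles.items():
        row = {"mirna": name, "n_reads": prof.n_reads}
        row.update({f"n_{cls.value}": prof.counts[cls] for cls in IsomiRClass})
        row.update(
            {
                "pct_3NT": prof.pct_3nt,
                "pct_TRIM": prof.pct_trim,
                "pct_A_forms": prof.pct_a_forms,
                "pct_U_forms": prof.pct_u_forms,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def normalize(
    counts: pd.DataFrame,
    library_sizes: pd.Series | dict,
    amplification_factors: pd.Series | dict | float = 1.0,
) -> pd.DataFrame:
    """Reads-per-million normalisation with an optional per-condition
    correction for global RNA amplification (factors supplied externally).

    CPM = 1e6 * count / library_size, divided by the condition's factor.
    """
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("library sizes must be positive for every condition")
    if np.isscalar(amplification_factors):
        factors = pd.Series(float(amplification_factors), index=counts.columns)
    else:
        factors = pd.Series(amplification_factors, dtype=float).reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("amplification factors must be positive")
    return counts.div(sizes, axis=1).mul(1e6).div(factors, axis=1)
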