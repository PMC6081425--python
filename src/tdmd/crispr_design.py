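"""SpCas9 deletion design arithmetic.

Locates 20-nt protospacers (either strand, NGG PAM) in a supplied sequence,
places the blunt cut 3 bp 5' of the PAM (between protospacer positions 17
and 18), and characterises the interval excised by a guide pair, including
the miRNA response elements it removes. Coordinates are 0-based half-open on
the given (plus) strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import SequenceRecord
from .duplex_anatomy import DuplexAnatomy, MatureMiRNA, TargetSite, scan_utr

logger = logging.getLogger("tdmd")

_COMPL = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_COMPL)[::-1]


@dataclass(frozen=True)
class GuideMatch:
    guide: str
    strand: str  # "+" or "-"
    start: int   # protospacer interval on the plus strand, 0-based half-open
    end: int
    pam: str
    pam_valid: bool


@dataclass
class DeletionInterval:
    cut1: int
    cut2: int
    excised_seq: str
    retained_seq: str
    removed_sites: list[tuple[str, TargetSite, DuplexAnatomy]] = field(
        default_factory=list
    )

    @property
    def length(self) -> int:
        return self.cut2 - self.cut1


def strip_cloning_overhangs(oligo: str) -> str:
    """Protospacer from a printed cloning oligo.

    The published oligos carry lowercase cloning overhangs (caccg/aaac and a
    trailing base); the uppercase 20-mer is the protospacer. A leading
    lowercase g is a U6-transcription artefact, not part of the genomic
    match.
    """
    core = "".join(c for c in oligo if c.isupper())
    if core != oligo:
        logger.info("stripped cloning overhangs: %s -> %s", oligo, core)
    return core.replace("U", "T")


def find_protospacer(guide_seq: str, target: SequenceRecord | str) -> list[GuideMatch]:
    """Exact protospacer matches on both strands, with NGG PAM validation.

    Matches lacking a valid PAM are returned flagged (``pam_valid=False``).
    """
    guide = strip_cloning_overhangs(guide_seq)
    if len(guide) != 20:
        raise ValueError(f"protospacer must be 20 nt after stripping (got {len(guide)})")
    seq = (target.seq if isinstance(target, SequenceRecord) else target).upper()
    seq = seq.replace("U", "T")
    matches: list[GuideMatch] = []

    def scan(query: str, strand: str):
        pos = seq.find(query)
        while pos >= 0:
            if strand == "+":
                pam = seq[pos + 20 : pos + 23]
            else:
                pam = reverse_complement(seq[pos - 3 : pos])
            valid = len(pam) == 3 and pam[1:] == "GG"
            matches.append(GuideMatch(guide, strand, pos, pos + 20, pam, valid))
            pos = seq.find(query, pos + 1)

    scan(guide, "+")
    scan(reverse_complement(guide), "-")
    matches.sort(key=lambda m: m.start)
    return matches


def cut_site(match: GuideMatch) -> int:
    """Blunt SpCas9 cut position, 3 bp 5' of the PAM.

    Returned in plus-strand coordinates: between protospacer bases 17/18
    counted from the PAM-distal end, i.e. start+17 for a plus-strand guide
    and start+3 for a minus-strand guide.
    """
    if not match.pam_valid:
        raise ValueError(f"no valid NGG PAM for guide at [{match.start},{match.end})")
    return match.start + 17 if match.strand == "+" else match.start + 3


def unique_match(guide_seq: str, target) -> GuideMatch:
    """The single PAM-valid protospacer match, or a hard error listing hits."""
    hits = [m for m in find_protospacer(guide_seq, target) if m.pam_valid]
    if len(hits) != 1:
        positions = [(m.strand, m.start) for m in hits]
        raise ValueError(
            f"expected exactly one PAM-valid match, found {len(hits)}: {positions}"
        )
    return hits[0]


def deletion_interval(
    m1: GuideMatch,
    m2: GuideMatch,
    seq: SequenceRecord | str,
    mirna_panel: list[MatureMiRNA] | None = None,
) -> DeletionInterval:
    """Characterise the fragment excised by two cuts on one sequence.

    ``removed_sites`` lists, per panel miRNA, the seed-matched sites found in
    the excised interval with their duplex anatomy. Identical cut sites give
    a valid zero-length deletion.
    """
    full = (seq.seq if isinstance(seq, SequenceRecord) else seq).upper().replace("U", "T")
    c1, c2 = sorted((cut_site(m1), cut_site(m2)))
    excised = full[c1:c2]
    retained = full[:c1] + full[c2:]
    interval = DeletionInterval(c1, c2, excised, retained)
    for mirna in mirna_panel or []:
        for site, anatomy in scan_utr(mirna, excised):
            shifted = TargetSite(
                site.transcript_id, site.start + c1, site.end + c1, site.seq
            )
            interval.removed_sites.append((mirna.name, shifted, anatomy))
    return interval
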