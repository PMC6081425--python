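"""miRNA:target duplex anatomy and TDMD eligibility.

A target-directed degradation (TDMD) site pairs the miRNA seed at its 3' end
and, after a short unpaired loop (the central bulge), forms an extended
helix with the miRNA 3' region. This module classifies the seed match
(8mer > 7mer-m8 > 7mer-A1 > 6mer), finds the maximal contiguous
3'-supplementary helix, and applies the eligibility rules (high-affinity
seed, >= 8 nt of contiguous 3' pairing, target bulge within 1-7 nt by
default; the "strict" preset narrows the bulge to 3-4 nt).

Conventions: the miRNA is given 5'->3'; target sites are given 5'->3' on the
sense strand and indexed from their 3' end (t1 = the nucleotide opposite
miRNA position 1). Pairing is strict Watson-Crick by default; G:U wobble can
be enabled and is reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .core_io import RunConfig, SequenceRecord

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = _WC | {("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pairs(a: str, b: str, wobble: bool = False) -> bool:
    """True if nucleotides a and b form a base pair (U/T equivalent)."""
    table = _WOBBLE if wobble else _WC
    return (_rna(a), _rna(b)) in table


class SeedClass(Enum):
    EIGHT_MER = "8mer"
    SEVEN_MER_M8 = "7mer-m8"
    SEVEN_MER_A1 = "7mer-A1"
    SIX_MER = "6mer"
    NONE = "none"

    @property
    def rank(self) -> int:
        order = ["none", "6mer", "7mer-A1", "7mer-m8", "8mer"]
        return order.index(self.value)


HIGH_AFFINITY = {SeedClass.EIGHT_MER, SeedClass.SEVEN_MER_M8}


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3' (RNA); seed = positions 2-8 (1-based)."""

    name: str
    seq: str
    family: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _rna(self.seq))
        if len(self.seq) < 8:
            raise ValueError(f"{self.name}: miRNA shorter than 8 nt")

    @property
    def seed(self) -> str:
        return self.seq[1:8]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TargetSite:
    """A candidate site on a transcript; ``seq`` is the 5'->3' slice."""

    transcript_id: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("site end must exceed start")


@dataclass
class DuplexAnatomy:
    """Anatomy of one miRNA:site duplex.

    three_prime_len is the maximal contiguous Watson-Crick helix between the
    miRNA 3' region (past the seed helix) and the target 5' segment;
    bulge_target_len / bulge_mirna_len are the unpaired nucleotides between
    the two helices on each strand; mismatch_count_3p counts miRNA 3'-region
    bases left outside both helices towards the miRNA 3' end.
    """

    seed_class: SeedClass
    three_prime_len: int = 0
    bulge_target_len: int = 0
    bulge_mirna_len: int = 0
    mismatch_count_3p: int = 0
    eligible: bool = False
    reasons: list[str] = field(default_factory=list)
    wobble: bool = False


def classify_seed(mirna: MatureMiRNA, site: TargetSite | str) -> SeedClass:
    """Highest seed-match class at the site 3' end.

    Position t1 (opposite miRNA position 1) must be an A for the 8mer and
    7mer-A1 classes regardless of the miRNA position-1 identity.
    """
    seq = _rna(site.seq if isinstance(site, TargetSite) else site)
    if len(seq) < 6:
        return SeedClass.NONE
    t = seq[::-1]  # t[k-1] = target position k counted from the 3' end

    def helix(through: int) -> bool:
        # miRNA positions 2..through paired with t2..t_through
        if len(t) < through:
            return False
        return all(pairs(mirna.seq[i - 1], t[i - 1]) for i in range(2, through + 1))

    m8 = helix(8)
    m7 = helix(7)
    a1 = len(t) >= 7 and t[0] == "A"
    if m8 and a1:
        return SeedClass.EIGHT_MER
    if m8:
        return SeedClass.SEVEN_MER_M8
    if m7 and a1:
        return SeedClass.SEVEN_MER_A1
    if m7:
        return SeedClass.SIX_MER
    return SeedClass.NONE


def align_supplementary(
    mirna: MatureMiRNA,
    site: TargetSite | str,
    seed_class: SeedClass | None = None,
    wobble: bool = False,
) -> DuplexAnatomy:
    """Find the maximal 3'-supplementary helix given a seed-anchored duplex.

    The seed helix is anchored at the site 3' end (through miRNA position 8
    for 8mer/7mer-m8 sites, position 7 otherwise). All two-helix
    decompositions are enumerated: a target bulge of b nt and a miRNA bulge
    of b' nt, followed by a contiguous helix. Ties are broken by (1) longer
    helix, (2) smaller target bulge, (3) helix closest to the seed on the
    miRNA strand.
    """
    seq = _rna(site.seq if isinstance(site, TargetSite) else site)
    if seed_class is None:
        seed_class = classify_seed(mirna, seq)
    if seed_class is SeedClass.NONE:
        raise ValueError("cannot align supplementary region without a seed match")
    seed_end = 8 if seed_class in HIGH_AFFINITY else 7
    t = seq[::-1]
    m_rem = mirna.seq[seed_end:]          # miRNA positions seed_end+1 .. L
    t_rem = t[seed_end:]                  # target positions seed_end+1 .. (5' tail)

    best: tuple[int, int, int] | None = None  # (L, b_target, b_mirna)
    for b in range(len(t_rem)):
        for bp in range(len(m_rem)):
            run = 0
            while (
                b + run < len(t_rem)
                and bp + run < len(m_rem)
                and pairs(m_rem[bp + run], t_rem[b + run], wobble)
            ):
                run += 1
            if run == 0:
                continue
            if (
                best is None
                or run > best[0]
                or (run == best[0] and (b, bp) < (best[1], best[2]))
            ):
                best = (run, b, bp)

    anatomy = DuplexAnatomy(seed_class=seed_class, wobble=wobble)
    if best is not None:
        L, b, bp = best
        anatomy.three_prime_len = L
        anatomy.bulge_target_len = b
        anatomy.bulge_mirna_len = bp
        anatomy.mismatch_count_3p = len(m_rem) - bp - L
    else:
        anatomy.mismatch_count_3p = len(m_rem)
    return anatomy


def tdmd_eligible(
    anatomy: DuplexAnatomy, config: RunConfig | None = None
) -> tuple[bool, list[str]]:
    """Decide TDMD eligibility; reasons list every failed criterion."""
    cfg = config or RunConfig()
    reasons: list[str] = []
    if anatomy.seed_class not in HIGH_AFFINITY:
        reasons.append(
            f"seed class {anatomy.seed_class.value} below 7mer-m8"
        )
    if anatomy.three_prime_len < cfg.min_3p:
        reasons.append("3' pairing below minimum")
    lo, hi = cfg.bulge_range
    if not lo <= anatomy.bulge_target_len <= hi:
        reasons.append(
            f"target bulge {anatomy.bulge_target_len} nt outside {lo}-{hi}"
        )
    ok = not reasons
    anatomy.eligible = ok
    anatomy.reasons = reasons
    return ok, reasons


def scan_utr(
    mirna: MatureMiRNA,
    utr: SequenceRecord | str,
    wobble: bool = False,
    context: int = 7,
) -> list[tuple[TargetSite, DuplexAnatomy]]:
    """All seed-matched sites in a UTR, 5'->3', with their duplex anatomy.

    Each site window extends len(miRNA)+context nt upstream of the seed to
    accommodate the supplementary helix (clipped at the UTR start). Sites
    whose 8-nt seed regions overlap are resolved by keeping the higher seed
    class (ties: the 5'-most site).
    """
    if isinstance(utr, SequenceRecord):
        name, seq = utr.id, utr.seq
    else:
        name, seq = "utr", utr
    seq = _rna(seq)
    if len(seq) < 6:
        return []
    window = len(mirna) + context
    hits: list[tuple[TargetSite, DuplexAnatomy]] = []
    for end in range(6, len(seq) + 1):
        tail = seq[max(0, end - 8) : end]
        cls = classify_seed(mirna, tail)
        if cls is SeedClass.NONE:
            continue
        start = max(0, end - window)
        site = TargetSite(name, start, end, seq[start:end])
        hits.append((site, align_supplementary(mirna, site, cls, wobble)))

    # resolve seed-region overlaps, keeping the higher class
    kept: list[tuple[TargetSite, DuplexAnatomy]] = []
    for site, anatomy in hits:
        seed_lo = site.end - 8
        clash = None
        for k, (ks, ka) in enumerate(kept):
            if seed_lo < ks.end and site.end > ks.end - 8:
                clash = (k, ka)
                break
        if clash is None:
            kept.append((site, anatomy))
        elif anatomy.seed_class.rank > clash[1].seed_class.rank:
            kept[clash[0]] = (site, anatomy)
    kept.sort(key=lambda pair: pair[0].end)
    return kept
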