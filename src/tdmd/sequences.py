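"""Published sequence fixtures for the Serpine1:miR-30b/c TDMD system.

Mature miR-30 family sequences are the standard miRBase mouse entries
(all five 5p arms share the seed; only miR-30b/c carry the extended 3'
complementarity to the Serpine1 element). The adenoviral mCherry-Serpine1
3'UTR construct, the CRISPR sgRNA oligos, the MRE mutant oligos and the
four-repeat miR-30c sensor insert are the published construct sequences.
"""

from __future__ import annotations

from .core_io import SequenceRecord

# mature 5p arms of the mouse miR-30 family (RNA, 5'->3')
MIR30_FAMILY: dict[str, str] = {
    "mmu-miR-30a-5p": "UGUAAACAUCCUCGACUGGAAG",
    "mmu-miR-30b-5p": "UGUAAACAUCCUACACUCAGCU",
    "mmu-miR-30c-5p": "UGUAAACAUCCUACACUCUCAGC",
    "mmu-miR-30d-5p": "UGUAAACAUCCCCGACUGGAAG",
    "mmu-miR-30e-5p": "UGUAAACAUCCUUGACUGGAAG",
}

MIR30B = MIR30_FAMILY["mmu-miR-30b-5p"]
MIR30C = MIR30_FAMILY["mmu-miR-30c-5p"]

# mCherry-Serpine1 3'UTR adenoviral construct (DNA, 5'->3'); the miR-30 MRE
# lies between the MluI and SacI sites.
SERPINE1_UTR_CONSTRUCT = (
    "GGTACCCGCCACCATGGTGAGCAAGGGCGAGGAGGATAACATGGCCATCATCAAGGAGTTCATGCGCTTC"
    "AAGGTGCACATGGAGGGCTCCGTGAACGGCCACGAGTTCGAGATCGAGGGCGAGGGCGAGGGCCGCCCCT"
    "ACGAGGGCACCCAGACCGCCAAGCTGAAGGTGACCAAGGGTGGCCCCCTGCCCTTCGCCTGGGACATCCT"
    "GTCCCCTCAGTTCATGTACGGCTCCAAGGCCTACGTGAAGCACCCCGCCGACATCCCCGACTACTTGAAG"
    "CTGTCCTTCCCCGAGGGCTTCAAGTGGGAGCGCGTGATGAACTTCGAGGACGGCGGCGTGGTGACCGTGA"
    "CCCAGGACTCCTCCCTGCAGGACGGCGAGTTCATCTACAAGGTGAAGCTGCGCGGCACCAACTTCCCCTC"
    "CGACGGCCCCGTAATGCAGAAGAAGACCATGGGCTGGGAGGCCTCCTCCGAGCGGATGTACCCCGAGGAC"
    "GGCGCCCTGAAGGGCGAGATCAAGCAGAGGCTGAAGCTGAAGGACGGCGGCCACTACGACGCTGAGGTCA"
    "AGACCACCTACAAGGCCAAGAAGCCCGTGCAGCTGCCCGGCGCCTACAACGTCAACATCAAGTTGGACAT"
    "CACCTCCCACAACGAGGACTACACCATCGTGGAACAGTACGAACGCGCCGAGGGCCGCCACTCCACCGGC"
    "GGCATGGACGAGCTGTACAAGTAGCTCGAGCAGTGGGAAGAGACGCCTTCATTTGGGACGAAACTGGAGA"
    "TGTTATAAGCAGAAACTCTGAAGAAAAGGATTATTTAAAGGACTCTATGGGGAGAAAGAGAAGGCAACTC"
    "CTCCTTACCCCCCACACTGGTAATCTTTCCAACCAGCATCCCAGACCTCGGACTCTTGAAGGGAAAAGAG"
    "TCTAACTCCCTCCTCCCTAGGGATTCCTACCCCACAAAGGTCTCATGGACCATAGAACTCACAGTACCTG"
    "GATCTGCCCAGCATGCCCTTTGGACCCAGTTCCCACCGAGGCCCCAGCAGAGTGGAGGGCACAACACTTT"
    "CATTCAGCAAAATCGTTTGTGTTCCAGTCACACTGTGGGCACCTCTTGCATCGCCTGCCATTGCTGTGGA"
    "GGGTGGCCATGGGCCAAAGGAAAAAGCACTGTCCTATCTCAAGGTCCACTGTGGAAATGTCCACCTTGCC"
    "CACCTCCAAGGGGCAACGGATAGACAGATCAAATGGTGGCCCAATAGCGAGCCTTCTCCCTGCTCCCTCC"
    "CTTGACACAGCTTGCTTATGTTATTTCACGCGTAGAGTGTAGGTGACTTGTTTACAGAGCTCCAGCTTTT"
    "TTCGACCCACAAACTTTTTTCATTTGGAAAGGGTGTAAGAAAAGTCGGACGTGTGTGTGCCTGGCTCTTC"
    "GTCCCCAGTCTCCCAGTGGGGGGGCCCTGGGGAGATTCCAGGGGTGTGATTGAATATTTATCTCTTGCTC"
    "TTGTATGTTTGTTGGGGAGAAGAAGCACTTTTAAGGAAAATGCTTCTTATTTAAACCGTGGCATACGGCA"
    "TCCCATTTGGGGTCTGCATCCCTGTATGTCAGGGGTGCATCACTCCACAAACCTGCCCCTCTGGGTAGCC"
    "TCGTGATGGGGCTCACACTGCCGCCTAGTGGCAGCCGAACACACCCTTACCCGGTCCCTCCCTCCCTCCC"
    "CCCCCCCCCCCCCCCCCCCCGTGGCTCTTTTCCTTAGGGACCTTGCCAAGGTGATGCTTGGCAACCCACG"
    "TTAAAGGAAGGGGGGAAAAAAGATTAGATGGAAGAGAGAGAGATTTGAGAGAGGGCAAAGTGGTTTCAAA"
    "TTTTTCCAAGGCATTCAGAAGCAGAGAGGGAAAAGGGGCTGTGTGACCTAACAGGACAGAACTTTCTCCA"
    "ATTACTGGGTGAGTCAGAGCTGCACTGGTGACTCACTTCAATGTGTCATTTCCGGCTGCTGTATGTGAGC"
    "AGTGGACACGTGGGGGGGCGGGGGGGGGATGAAAGAGACAGCAGCTCCTGGTCAACCACCTTAGTTAGAT"
    "AATCTTTTTTGAAAGCTTCCTAGCTGGAGGTATGATCAGAAAACCAATTTACTGAAAAACTGCACAAGAA"
    "GGTACGGTGAATGTAATTTCCTAGCAGGCCACTCTGCATCTGTTATGTCTCCACCGGAAAAAAAATAATC"
    "ATGTTGGTGTTTTTGCTTTTCTCTCTCTCCCTCTTTCTCTCTGATTTTTTTTTCCTCTCTTTTCATTATG"
    "CACTGGACAGCCACACACCGTGTACCCATAGGGCCCCAAATGTGGGGTCACATGGTCTTGAATTTTGTTG"
    "GTTACATATGCCTTTTTGTTGTTGTTTGTCTTCACTTTTGATATATAAACAGGTAAATATGTTTTTTAAA"
    "AAATACTAAATATAGAGAATATGCAAACAAAAGCGGCCGC"
)

MLUI = "ACGCGT"
SACI = "GAGCTC"
KPNI = "GGTACC"
NOTI = "GCGGCCGC"

# sgRNA oligos as printed, lowercase cloning overhangs included
SGRNA1_SENSE_OLIGO = "caccgAAGCAAGCTGTGTCAAGGGA"  # targets the minus strand
SGRNA2_SENSE_OLIGO = "caccgTCTCCCAGTGGGGGGGCCCT"  # targets the plus strand

# MRE replacement oligos (subcloned between the MluI and SacI sites); the
# uppercase part is the site sequence that replaces the wild-type MRE
AD_RFP_SE1_MUT_FW = "cgcgtACTCTGAAAGTGAAAAGCCAATGgagct"
AD_RFP_SE1_SEED_FW = "cgcgtGATATTGTCCTGACTTGTTTACAgagct"

# four-repeat miR-30c-5p sensor insert (XbaI ... XmaI) and scrambled control
SENSOR_INSERT = (
    "TCTAGATAAGCTGAGAGTGTAGGATGTTTACACGATGCTGAGAGTGTAGGATGTTTACAACGCGTGTCGA"
    "CGCTGAGAGTGTAGGATGTTTACATCACGCTGAGAGTGTAGGATGTTTACACCCGGG"
)
CONTROL_SENSOR_FW = "TCTAGAGGAGCTCCACCGCGGTGGCATC"


def mre_site(construct: str = SERPINE1_UTR_CONSTRUCT) -> tuple[int, int, str]:
    """The miR-30 MRE: the segment between the MluI and SacI motifs.

    Returns ``(start, end, seq)`` with 0-based half-open coordinates on the
    construct.
    """
    i = construct.find(MLUI)
    j = construct.find(SACI, i + len(MLUI))
    if i < 0 or j < 0:
        raise ValueError("MluI/SacI motifs not found in construct")
    start = i + len(MLUI)
    return start, j, construct[start:j]


def oligo_site(oligo: str) -> str:
    """Uppercase site carried by a printed cloning oligo (overhangs lowercase)."""
    return "".join(c for c in oligo if c.isupper())


def serpine1_utr_record() -> SequenceRecord:
    return SequenceRecord("mCherry-Serpine1-3pUTR", SERPINE1_UTR_CONSTRUCT)


def sensor_record() -> SequenceRecord:
    return SequenceRecord("miR-30c-sensor-insert", SENSOR_INSERT)
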