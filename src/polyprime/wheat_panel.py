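"""Published genome-specific primer panels for the wheat Wx and SSII genes.

These are the published genome-specific primer sets for the three
homoeologous granule-bound starch synthase (Wx) genes (GenBank AB019622 =
Wx-7A, AB019623 = Wx-4A, AB019624 = Wx-7D) and starch synthase II (SSII)
genes (AB201445 = SSII-7A, AB201446 = SSII-7B, AB201447 = SSII-7D) of
allohexaploid wheat, with the reported product sizes on their own genome
(annealing at 60 degC).  They serve as regression inputs: re-scoring them
with this package's in-silico PCR model against the GenBank genomic
sequences should reproduce the reported sizes and genome assignments.

The waxy diagnostic subset (one pair per Wx locus) distinguishes wild-type
from partial-waxy lines carrying deletion-based null alleles; the
reference genotype table lists the classic line set with its published
presence/absence patterns and type codes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PublishedPair:
    name_fwd: str
    seq_fwd: str
    name_rev: str
    seq_rev: str
    annealing_C: float
    size_bp: int
    genome: str
    gene: str  # Wx | SSII


#: the published panel: 9 Wx pairs + 12 SSII pairs
PUBLISHED_PAIRS: list[PublishedPair] = [
    PublishedPair("Wx-7A-F1", "GTAAGCTTGCGCCACTGC", "Wx-7A-R1a", "GGATGCAGAATGCCACCTA", 60, 950, "7A", "Wx"),
    PublishedPair("Wx-7A-F2", "CGCTCTGCATATCAATTTTGC", "Wx-7A-R2a", "ATATGCAAAGGAGGTGAGGAAC", 60, 1038, "7A", "Wx"),
    PublishedPair("Wx-7A-F3", "CTGGTACGATCGACCGACAT", "Wx-7A-R3", "CGGCCCTTCACTCTTAGTTG", 60, 750, "7A", "Wx"),
    PublishedPair("Wx-4A-F1", "AGCTAGCACCACTGTCTTCTGA", "Wx-4A-R1", "GGCCGTCCTATAGATGCCAC", 60, 854, "4A", "Wx"),
    PublishedPair("Wx-4A-F2", "TCAACAACACCCAGCAGCTA", "Wx-4A-R2", "GGTTGGGGTCGATGACGTA", 60, 943, "4A", "Wx"),
    PublishedPair("Wx-4A-F3", "CCACACACCCACACAAAGAT", "Wx-4A-R3", "TTTACACAAGGGATCGACGAG", 60, 731, "4A", "Wx"),
    PublishedPair("Wx-7D-F1", "CCATGGCCGTAAGCTAGAC", "Wx-7D-R1", "CGCAAAATTGATATGCCTGTT", 60, 978, "7D", "Wx"),
    PublishedPair("Wx-7D-F2a", "AACTACCAGTCCAATGGCATCTAC", "Wx-7D-R2a", "GCTCGGGAATTTCTCCTCAAT", 60, 938, "7D", "Wx"),
    PublishedPair("Wx-7D-F3", "CCAGATCGTTCTCCTGGTACA", "Wx-7D-R3a", "CTCGCTCCCCTCGACA", 60, 861, "7D", "Wx"),
    PublishedPair("SSII-7A-F2", "CCCAGAACAGAGTACCAGTGAAC", "SSII-7A-R2", "CGGATCTACAGGGCAGGTAA", 60, 953, "7A", "SSII"),
    PublishedPair("SSII-7A-F3", "GCAGTCGGATTTCACAAATAAGG", "SSII-7A-R3a", "CCTGACGGTGTCGGAAGAT", 60, 883, "7A", "SSII"),
    PublishedPair("SSII-7A-F4a", "AGCGAAAATGCAATCAAAGG", "SSII-7A-R4a", "TTTGGGTATGAGGGGGAAAT", 60, 1657, "7A", "SSII"),
    PublishedPair("SSII-7A-F5a", "TGCACCATCGCTCGAAGT", "SSII-7A-R5", "CGTTGATGTGACACCATATCCT", 60, 983, "7A", "SSII"),
    PublishedPair("SSII-7B-F2", "CTGTCAGCGACGTGGAACT", "SSII-7B-R2", "TGCATTGAAATGAAAGCTTGAC", 60, 947, "7B", "SSII"),
    PublishedPair("SSII-7B-F3a", "GCAGTCGGATTTCACAAAGAAC", "SSII-7B-R3", "GGTCAGTAGGCCTTGGCTTG", 60, 973, "7B", "SSII"),
    PublishedPair("SSII-7B-F4a", "CATTGACGCTCCTCTCTTCC", "SSII-7B-R4a", "TACTCCCACTATGGTTAGCCTTACA", 60, 1596, "7B", "SSII"),
    PublishedPair("SSII-7B-F5", "ACAACTTCATGGGAACAAGGTT", "SSII-7B-R5", "CTCAGACCTGACGGAGATGG", 60, 949, "7B", "SSII"),
    PublishedPair("SSII-7D-F2a", "GTCAGCGACGTGGAACAA", "SSII-7D-R2a", "CGCGAAACTAGCTCCCAATC", 60, 1053, "7D", "SSII"),
    PublishedPair("SSII-7D-F3", "AGCCAGATTTCACAAAGAAGGA", "SSII-7D-R3", "AGTCAGTAGGCCTTGGCTTG", 60, 973, "7D", "SSII"),
    PublishedPair("SSII-7D-F4", "CTCTCTTCCGACACCGTCA", "SSII-7D-R4", "GGAGAAGGAGAGGAGAAGTTGG", 60, 1654, "7D", "SSII"),
    PublishedPair("SSII-7D-F5", "TGCGTCGCCTCATAGAGC", "SSII-7D-R5", "GCACAAGCAACTGACCTCAC", 60, 987, "7D", "SSII"),
]

#: GenBank accession -> (gene, genome, reported genomic length in bp)
REFERENCE_ACCESSIONS: dict[str, tuple[str, str, int | None]] = {
    "AB019622": ("Wx", "7A", 2781),
    "AB019623": ("Wx", "4A", None),  # length not reported
    "AB019624": ("Wx", "7D", 2862),
    "AB201445": ("SSII", "7A", None),
    "AB201446": ("SSII", "7B", 6566),
    "AB201447": ("SSII", "7D", 6775),
}

#: reported union-coverage of each gene by its published primer set (%)
REPORTED_COVERAGE_PCT: dict[tuple[str, str], float] = {
    ("Wx", "4A"): 72.6,
    ("Wx", "7A"): 82.9,
    ("Wx", "7D"): 87.0,
    ("SSII", "7B"): 59.5,
    ("SSII", "7D"): 60.3,
    ("SSII", "7A"): 61.6,
}

#: the waxy diagnostic panel: locus label -> published pair name
WAXY_DIAGNOSTIC_PAIRS = {
    "Wx-A1": ("Wx-7A-F1", "Wx-7A-R1a"),
    "Wx-B1": ("Wx-4A-F2", "Wx-4A-R2"),
    "Wx-D1": ("Wx-7D-F3", "Wx-7D-R3a"),
}

#: pattern -> (published allele label, type code) for the waxy panel;
#: the null alleles are named Wx-A1b / Wx-B1b / Wx-D1b.  Codes 5 and 6
#: (the double-null patterns not present in the classic line set) are
#: completed by analogy and marked inferred in the methods notes.
WAXY_CODE_MAP: dict[tuple[str, ...], tuple[str, str]] = {
    ("+", "+", "+"): ("Wild type", "1"),
    ("-", "+", "+"): ("null (Wx-A1b)", "2"),
    ("+", "-", "+"): ("null (Wx-B1b)", "3"),
    ("+", "+", "-"): ("null (Wx-D1b)", "4"),
    ("+", "-", "-"): ("null (Wx-B1b & D1b)", "5"),
    ("-", "+", "-"): ("null (Wx-A1b & D1b)", "6"),
    ("-", "-", "+"): ("null (Wx-A1b & B1b)", "7"),
    ("-", "-", "-"): ("Triple null alleles", "8"),
}

#: classic wild-type / partial-waxy line set: sample -> (pattern, label, code)
REFERENCE_GENOTYPES: dict[str, tuple[tuple[str, str, str], str, str]] = {
    "Chinese Spring": (("+", "+", "+"), "Wild type", "1"),
    "Sturdy": (("-", "+", "+"), "null (Wx-A1b)", "2"),
    "Fujimi Komugi": (("-", "+", "+"), "null (Wx-A1b)", "2"),
    "Gabo": (("+", "-", "+"), "null (Wx-B1b)", "3"),
    "Gamenya": (("+", "-", "+"), "null (Wx-B1b)", "3"),
    "Santanta": (("+", "-", "+"), "null (Wx-B1b)", "3"),
    "Bai Huo": (("+", "+", "-"), "null (Wx-D1b)", "4"),
    "Kanto 107": (("-", "-", "+"), "null (Wx-A1b & B1b)", "7"),
    "NSGC 8645": (("-", "-", "-"), "Triple null alleles", "8"),
    "NSGC 8646": (("-", "-", "-"), "Triple null alleles", "8"),
}


def published_primers() -> list[tuple[str, str]]:
    """All (name, sequence) primers of the published panel."""
    out = []
    for p in PUBLISHED_PAIRS:
        out.append((p.name_fwd, p.seq_fwd))
        out.append((p.name_rev, p.seq_rev))
    return out
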