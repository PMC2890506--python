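"""Enumeration and quality filtering of 3'-anchored genome-specific candidates.

Candidates place their 3'-terminal base on a discriminative site so that
off-target extension is blocked at the first cycle, then grow at the 5'
end until the melting temperature enters the target window.  Anchors in
introns and at exon/intron junctions are ranked above exon anchors
(homoeolog divergence concentrates in introns), but exon anchors are legal
when the caller asks for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from polyprime.alignment_core import (
    EXON,
    INTRON,
    JUNCTION,
    DiscriminativeSite,
    HomoeologAlignment,
)
from polyprime.thermo import ThermoParams, TmRejection, adjust_tm_by_5prime, melting_temperature

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class QualityParams:
    """Composition/structure filters applied to candidates.

    Thresholds mirror common primer-design defaults; all are configurable
    because none is uniquely dictated by the anchoring strategy.
    """

    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer: int = 5
    max_3prime_pentamer_selfcomp: int = 4  # reject only a fully pairing 3' pentamer
    max_self_dimer_seed: int = 7  # a perfect seed of 8+ bp rejects
    len_min: int = 16
    len_max: int = 25


@dataclass
class PrimerCandidate:
    """An oriented primer anchored on a discriminative site.

    ``template_interval`` is on the target genome's ungapped sequence
    (0-based half-open); ``sequence`` equals that substring for forward
    primers, or its reverse complement for reverse primers, so the
    3'-terminal base always maps to the anchor column.
    """

    genome_id: str
    orientation: str  # forward | reverse
    sequence: str
    template_interval: tuple[int, int]
    anchor_site: DiscriminativeSite
    tm_C: float
    region_label: str
    filter_status: str = "pass"
    duplex_profiles: dict = field(default_factory=dict)

    @property
    def anchor_pos(self) -> int:
        """Template position of the 3'-terminal base."""
        s, e = self.template_interval
        return e - 1 if self.orientation == "forward" else s

    @property
    def name(self) -> str:
        tag = "F" if self.orientation == "forward" else "R"
        return f"{self.genome_id}-{tag}{self.anchor_pos}"


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _three_prime_pentamer_selfcomp(seq: str) -> int:
    """Max complementary overlap of the 3' pentamer against the primer.

    Counts the longest stretch of the 3'-terminal 5-mer that pairs
    (antiparallel) with any window of the primer itself — a proxy for
    primer-dimer-prone 3' ends.
    """
    pent = seq[-5:]
    target = seq.translate(_COMPLEMENT)[::-1]  # the strand pent would pair with
    best = 0
    for w in range(len(pent), 0, -1):
        for s in range(len(pent) - w + 1):
            if pent[s : s + w] in target:
                return w
    return best


def longest_self_dimer_seed(seq: str) -> int:
    """Longest perfect complementary (antiparallel) stretch of seq with itself."""
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    best = 0
    # longest common substring of seq and its reverse complement
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seq[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def check_quality(seq: str, params: QualityParams | None = None) -> list[str]:
    """Machine-readable failure reasons for a primer sequence (empty = pass)."""
    if params is None:
        params = QualityParams()
    reasons = []
    gc = gc_fraction(seq)
    if not params.gc_min <= gc <= params.gc_max:
        reasons.append("gc_out_of_range")
    if max_homopolymer_run(seq) > params.max_homopolymer:
        reasons.append("homopolymer_run")
    if _three_prime_pentamer_selfcomp(seq) > params.max_3prime_pentamer_selfcomp:
        reasons.append("three_prime_selfcomp")
    if longest_self_dimer_seed(seq) > params.max_self_dimer_seed:
        reasons.append("self_dimer_seed")
    return reasons


def enumerate_anchored_candidates(
    aln: HomoeologAlignment,
    target_genome: str,
    sites: list[DiscriminativeSite],
    thermo_params: ThermoParams | None = None,
    quality_params: QualityParams | None = None,
) -> list[PrimerCandidate]:
    """Up to two Tm-adjusted, quality-filtered candidates per site.

    Partial sites are skipped (they do not discriminate against every
    off-target).  Candidates whose 5' extension would leave the template
    are skipped, as are those that cannot reach the Tm window at any legal
    length.  Results are sorted intron/junction first, then by column.
    """
    if thermo_params is None:
        thermo_params = ThermoParams()
    if quality_params is None:
        quality_params = QualityParams()
    gi = aln._genome_index(target_genome)
    template = aln.copies[gi].sequence
    out: list[PrimerCandidate] = []
    for site in sites:
        if site.partial:
            continue
        pos = aln.col_to_pos(target_genome, site.column)
        if pos < 0:
            continue
        for orientation in ("forward", "reverse"):
            got = adjust_tm_by_5prime(
                pos,
                orientation,
                template,
                thermo_params,
                quality_params.len_min,
                quality_params.len_max,
            )
            if isinstance(got, TmRejection):
                continue
            if check_quality(got, quality_params):
                continue
            L = len(got)
            interval = (
                (pos - L + 1, pos + 1) if orientation == "forward" else (pos, pos + L)
            )
            out.append(
                PrimerCandidate(
                    genome_id=target_genome,
                    orientation=orientation,
                    sequence=got,
                    template_interval=interval,
                    anchor_site=site,
                    tm_C=round(melting_temperature(got, thermo_params), 2),
                    region_label=site.region,
                )
            )
    rank = {INTRON: 0, JUNCTION: 0, EXON: 1}
    out.sort(key=lambda c: (rank.get(c.region_label, 2), c.anchor_site.column, c.orientation))
    return out


def filter_candidates(
    candidates: list[PrimerCandidate],
    quality_params: QualityParams | None = None,
) -> list[PrimerCandidate]:
    """Retain candidates passing the quality filters; annotate rejections.

    Idempotent: rejected candidates get ``filter_status`` set to the
    semicolon-joined reasons and are dropped from the returned list.
    """
    if quality_params is None:
        quality_params = QualityParams()
    kept = []
    for cand in candidates:
        reasons = check_quality(cand.sequence, quality_params)
        if not quality_params.len_min <= len(cand.sequence) <= quality_params.len_max:
            reasons.append("length_out_of_range")
        if reasons:
            cand.filter_status = ";".join(reasons)
        else:
            cand.filter_status = "pass"
            kept.append(cand)
    return kept
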