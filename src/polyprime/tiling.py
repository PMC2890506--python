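"""Pairing, specificity scoring and amplicon tiling with union coverage.

Sanger sequencing from both ends reads ~800 bp reliably, so amplicons of
800-1500 bp can be finished with one forward and one reverse read, and
80-100 bp overlaps between neighboring amplicons let the reads be
assembled into a single gene contig.  The tiler selects, per genome, a set
of genome-specific primer pairs maximizing the union of amplicon intervals
(then minimizing pair count, then maximizing specificity margin minus
size/overlap penalties).  Coverage is the union of amplicon intervals
divided by the full genomic length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from polyprime.alignment_core import GeneCopy
from polyprime.insilico_pcr import (
    STRONG,
    WEAK,
    InsilicoParams,
    PredictedAmplicon,
    SpecificityReport,
    scan_binding_sites,
)
from polyprime.primer_engine import PrimerCandidate


@dataclass
class TilingConstraints:
    """Amplicon size band and neighbor-overlap band.

    With ``hard_size_band`` False (default) sizes outside the band are
    penalized, not rejected — useful assays slightly outside the band are
    kept if nothing better covers the region.
    """

    amplicon_min_bp: int = 800
    amplicon_max_bp: int = 1500
    overlap_min_bp: int = 80
    overlap_max_bp: int = 100
    hard_size_band: bool = False
    #: soft-band slack: pairs with sizes inside [min - slack, max + slack]
    #: are admitted (with a penalty when outside the band proper)
    size_slack_bp: int = 300

    def __post_init__(self) -> None:
        if not 0 < self.amplicon_min_bp < self.amplicon_max_bp:
            raise ValueError("require 0 < amplicon_min < amplicon_max")
        if not 0 <= self.overlap_min_bp <= self.overlap_max_bp:
            raise ValueError("require 0 <= overlap_min <= overlap_max")


@dataclass
class ScoredPair:
    """A genome-specific forward/reverse pair with its target product."""

    fwd: PrimerCandidate
    rev: PrimerCandidate
    amplicon: PredictedAmplicon
    specificity_margin: int
    size_penalty: int
    report: SpecificityReport | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return self.amplicon.interval

    @property
    def size_bp(self) -> int:
        return self.amplicon.size_bp


@dataclass
class TilingSolution:
    genome_id: str
    chosen_pairs: list[ScoredPair]
    gene_length: int
    covered_bp: int = 0
    junction_overlaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chosen_pairs.sort(key=lambda p: p.interval)
        self.covered_bp = union_length([p.interval for p in self.chosen_pairs])
        self.junction_overlaps = [
            self.chosen_pairs[i].interval[1] - self.chosen_pairs[i + 1].interval[0]
            for i in range(len(self.chosen_pairs) - 1)
        ]

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bp / self.gene_length if self.gene_length else 0.0


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    total, last_end = 0, None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def _specificity_margin(
    fwd: str, rev: str, offtargets: dict[str, str], params: InsilicoParams
) -> int:
    """How safely the pair is blocked on its worst off-target.

    For each off-target, each primer's best (fewest-mismatch) binding site
    is found; the pair's safety there is the *better-blocked* primer (both
    primers are needed for a product).  The margin is the minimum over
    off-targets; sites beyond the scan cap count as max_mismatches + 1.
    """
    cap = params.max_mismatches + 1
    margins = []
    for oseq in offtargets.values():
        per_primer = []
        for p in (fwd, rev):
            hits = scan_binding_sites(p, oseq, params.max_mismatches)
            per_primer.append(min((h.total_mismatches for h in hits), default=cap))
        margins.append(max(per_primer))
    return min(margins, default=cap)


def _size_penalty(size: int, c: TilingConstraints) -> int:
    if size < c.amplicon_min_bp:
        return c.amplicon_min_bp - size
    if size > c.amplicon_max_bp:
        return size - c.amplicon_max_bp
    return 0


def enumerate_specific_pairs(
    candidates: list[PrimerCandidate],
    templates: dict[str, str],
    constraints: TilingConstraints | None = None,
    insilico_params: InsilicoParams | None = None,
) -> list[ScoredPair]:
    """All genome-specific forward/reverse combinations with scores.

    ``templates`` maps genome_id -> genomic sequence for the whole family;
    each candidate pair is validated with the in-silico PCR model against
    its own genome (target) and all others (off-targets).  With a soft size
    band, out-of-band sizes carry a penalty instead of being dropped.

    Binding-site scans are cached per (candidate, template), so each primer
    is scanned once per template regardless of how many pairs it joins;
    candidates that already amplify an off-target on their own best site
    with zero safety margin prune the pairing early.
    """
    if constraints is None:
        constraints = TilingConstraints()
    if insilico_params is None:
        insilico_params = InsilicoParams()
    from polyprime.insilico_pcr import pair_amplicons_from_hits

    hit_cache: dict[tuple[int, str], list] = {}

    def hits(cand: PrimerCandidate, tid: str):
        key = (id(cand), tid)
        if key not in hit_cache:
            hit_cache[key] = scan_binding_sites(
                cand.sequence, templates[tid], insilico_params.max_mismatches
            )
        return hit_cache[key]

    cap = insilico_params.max_mismatches + 1
    min_mm: dict[tuple[int, str], int] = {}

    def best_mm(cand: PrimerCandidate, tid: str) -> int:
        key = (id(cand), tid)
        if key not in min_mm:
            min_mm[key] = min(
                (h.total_mismatches for h in hits(cand, tid)), default=cap
            )
        return min_mm[key]

    out: list[ScoredPair] = []
    fwds = [c for c in candidates if c.orientation == "forward"]
    revs = [c for c in candidates if c.orientation == "reverse"]
    for fwd, rev in product(fwds, revs):
        if fwd.genome_id != rev.genome_id:
            continue
        size = rev.template_interval[1] - fwd.template_interval[0]
        if size < max(len(fwd.sequence), len(rev.sequence)):
            continue
        if size > insilico_params.max_product_bp:
            continue
        penalty = _size_penalty(size, constraints)
        slack = 0 if constraints.hard_size_band else constraints.size_slack_bp
        if penalty > slack:
            continue
        gid = fwd.genome_id
        off_ids = [t for t in templates if t != gid]
        min_size = max(len(fwd.sequence), len(rev.sequence))
        # target: require exactly one STRONG product
        on_target = pair_amplicons_from_hits(
            gid, hits(fwd, gid), hits(rev, gid), min_size, insilico_params
        )
        if sum(a.amp_class == STRONG for a in on_target) != 1:
            continue
        # off-targets: any STRONG or WEAK product disqualifies
        off_bad = False
        for tid in off_ids:
            amps = pair_amplicons_from_hits(
                tid, hits(fwd, tid), hits(rev, tid), min_size, insilico_params
            )
            if any(a.amp_class in (STRONG, WEAK) for a in amps):
                off_bad = True
                break
        if off_bad:
            continue
        margin = min(
            (max(best_mm(fwd, tid), best_mm(rev, tid)) for tid in off_ids),
            default=cap,
        )
        amp = next(a for a in on_target if a.amp_class == STRONG)
        out.append(
            ScoredPair(
                fwd=fwd,
                rev=rev,
                amplicon=amp,
                specificity_margin=margin,
                size_penalty=penalty,
            )
        )
    out.sort(key=lambda p: (p.interval, p.size_bp))
    return out


def _overlap_penalty(prev_end: int, start: int, end: int, c: TilingConstraints) -> int:
    """Penalty of adding an amplicon after coverage reaching ``prev_end``."""
    if prev_end <= 0 or start >= prev_end:
        # a coverage gap: penalize by the gap (disjoint tiling is legal
        # but contiguity is the design goal)
        return max(0, start - prev_end) if prev_end > 0 else 0
    overlap = min(prev_end, end) - start
    if overlap < c.overlap_min_bp:
        return c.overlap_min_bp - overlap
    if overlap > c.overlap_max_bp:
        return overlap - c.overlap_max_bp
    return 0


def tile_gene(
    pairs: list[ScoredPair],
    gene_length: int,
    constraints: TilingConstraints | None = None,
    genome_id: str | None = None,
) -> TilingSolution:
    """Exact search for the pair subset maximizing union coverage.

    Objective, lexicographic: (1) maximize covered_bp; (2) minimize the
    number of pairs; (3) maximize total specificity margin minus size and
    overlap penalties.  Amplicons are processed sorted by (start, end), and
    the search state is the rightmost covered position, which makes the
    memoized recursion exact for interval unions.
    """
    if constraints is None:
        constraints = TilingConstraints()
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    gid = genome_id or (pairs[0].fwd.genome_id if pairs else "NA")
    if not pairs:
        return TilingSolution(genome_id=gid, chosen_pairs=[], gene_length=gene_length)

    # iterate pairs sorted by (start, end); the only state the future needs
    # is the rightmost covered position, so keep the lexicographically best
    # (covered, -count, score, chosen) per distinct reach — an exact DP
    items = sorted(pairs, key=lambda p: (p.interval, p.size_bp))
    states: dict[int, tuple[int, int, int, tuple[int, ...]]] = {0: (0, 0, 0, ())}
    for idx, item in enumerate(items):
        s, e = item.interval
        updates: dict[int, tuple[int, int, int, tuple[int, ...]]] = {}
        for reach, (cov, ncnt, score, chosen) in states.items():
            gain = max(0, e - max(s, reach))
            sc = (
                item.specificity_margin
                - item.size_penalty
                - _overlap_penalty(reach, s, e, constraints)
            )
            new_reach = max(reach, e)
            cand = (cov + gain, ncnt - 1, score + sc, chosen + (idx,))
            if cand > updates.get(new_reach, (-1, 0, 0, ())):
                updates[new_reach] = cand
        for new_reach, cand in updates.items():
            if cand > states.get(new_reach, (-1, 0, 0, ())):
                states[new_reach] = cand

    _, _, _, chosen = max(states.values())
    return TilingSolution(
        genome_id=gid,
        chosen_pairs=[items[i] for i in chosen],
        gene_length=gene_length,
    )


def coverage_report(
    solutions: list[TilingSolution], copies: list[GeneCopy]
) -> pd.DataFrame:
    """Per-genome coverage table (coverage_pct reported to 0.1%)."""
    lengths = {c.genome_id: len(c) for c in copies}
    rows = []
    for sol in solutions:
        glen = lengths.get(sol.genome_id, sol.gene_length)
        rows.append(
            {
                "genome": sol.genome_id,
                "n_pairs": len(sol.chosen_pairs),
                "covered_bp": sol.covered_bp,
                "gene_length": glen,
                "coverage_pct": round(100.0 * sol.covered_bp / glen, 1) if glen else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["genome", "n_pairs", "covered_bp", "gene_length", "coverage_pct"])
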