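"""End-to-end design driver: sites -> candidates -> pairs -> tiling.

Used by the CLI and directly importable:

    copies = read_gene_family("family.fa", "family.gff3")
    result = design_family(copies)
    print(result.coverage)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from polyprime.alignment_core import (
    EXON,
    INTRON,
    JUNCTION,
    GeneCopy,
    HomoeologAlignment,
    build_alignment,
    find_discriminative_sites,
)
from polyprime.io_utils import RunConfig
from polyprime.primer_engine import enumerate_anchored_candidates, filter_candidates
from polyprime.tiling import (
    TilingSolution,
    coverage_report,
    enumerate_specific_pairs,
    tile_gene,
)

log = logging.getLogger("polyprime")


def _thin_sites(sites, spacing: int):
    """Keep at most one anchor site per ``spacing`` alignment columns.

    Sites a few columns apart produce near-identical primers; thinning
    keeps the pair search tractable without losing tiling options.
    """
    if spacing <= 1:
        return sites
    kept, last = [], None
    for s in sorted(sites, key=lambda s: s.column):
        if last is None or s.column - last >= spacing:
            kept.append(s)
            last = s.column
    return kept


@dataclass
class DesignResult:
    alignment: HomoeologAlignment
    solutions: list[TilingSolution]
    coverage: pd.DataFrame
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def design_family(
    copies: list[GeneCopy],
    config: RunConfig | None = None,
    precomputed_alignment: list[str] | None = None,
) -> DesignResult:
    """Design genome-specific tiling primer sets for every copy in a family."""
    if config is None:
        config = RunConfig()
    aln = build_alignment(copies, precomputed_alignment)
    templates = {c.genome_id: c.sequence for c in copies}
    regions = {INTRON, JUNCTION} | ({EXON} if config.allow_exon_anchors else set())

    solutions, counts = [], {}
    for copy in copies:
        gid = copy.genome_id
        sites = find_discriminative_sites(aln, gid, region_filter=regions)
        sites = _thin_sites(sites, config.min_anchor_spacing)
        cands = enumerate_anchored_candidates(
            aln, gid, sites, config.thermo, config.quality
        )
        cands = filter_candidates(cands, config.quality)
        pairs = enumerate_specific_pairs(
            cands, templates, config.tiling, config.insilico
        )
        sol = tile_gene(pairs, len(copy), config.tiling, genome_id=gid)
        solutions.append(sol)
        counts[gid] = {
            "sites": len(sites),
            "candidates": len(cands),
            "pairs": len(pairs),
            "tiled": len(sol.chosen_pairs),
        }
        log.info(
            "%s: %d sites -> %d candidates -> %d specific pairs -> %d tiled "
            "(%.1f%% coverage)",
            gid, len(sites), len(cands), len(pairs), len(sol.chosen_pairs),
            100 * sol.coverage_fraction,
        )
        if not sol.chosen_pairs:
            log.warning("%s: no genome-specific primer pairs found", gid)
    return DesignResult(
        alignment=aln,
        solutions=solutions,
        coverage=coverage_report(solutions, copies),
        stage_counts=counts,
    )
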