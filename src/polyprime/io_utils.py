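"""Readers/writers for the pipeline's table and track formats.

Conventions (also stated in file headers): BED output is 0-based
half-open; TSV coordinate columns are 1-based inclusive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from polyprime.alignment_core import GeneCopy
from polyprime.insilico_pcr import InsilicoParams, PredictedAmplicon
from polyprime.primer_engine import PrimerCandidate, QualityParams
from polyprime.thermo import ThermoParams
from polyprime.tiling import TilingConstraints, TilingSolution

_CLASS_SCORE = {"NONE": 0, "WEAK": 500, "STRONG": 1000}


@dataclass
class RunConfig:
    """All tunables of a design run; serializable to/from JSON."""

    thermo: ThermoParams = field(default_factory=ThermoParams)
    quality: QualityParams = field(default_factory=QualityParams)
    tiling: TilingConstraints = field(default_factory=TilingConstraints)
    insilico: InsilicoParams = field(default_factory=InsilicoParams)
    seed: int = 0
    allow_exon_anchors: bool = True
    #: minimum spacing (alignment columns) between anchor sites fed to the
    #: candidate enumerator; neighbouring sites give near-identical primers,
    #: so thinning trims redundancy without losing tiling options
    min_anchor_spacing: int = 30

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            thermo=ThermoParams(**raw.get("thermo", {})),
            quality=QualityParams(**raw.get("quality", {})),
            tiling=TilingConstraints(**raw.get("tiling", {})),
            insilico=InsilicoParams(**raw.get("insilico", {})),
            seed=raw.get("seed", 0),
            allow_exon_anchors=raw.get("allow_exon_anchors", True),
            min_anchor_spacing=raw.get("min_anchor_spacing", 30),
        )


def write_fasta(copies: list[GeneCopy], path) -> None:
    with open(path, "w") as fh:
        for c in copies:
            fh.write(f">{c.genome_id} {c.source_id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")


def write_gff3(copies: list[GeneCopy], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in copies:
            fh.write(
                f"{c.genome_id}\tpolyprime\tgene\t1\t{len(c)}\t.\t+\t.\t"
                f"ID=gene:{c.genome_id}\n"
            )
            for i, (a, b) in enumerate(c.exons, 1):
                fh.write(
                    f"{c.genome_id}\tpolyprime\texon\t{a + 1}\t{b}\t.\t+\t.\t"
                    f"ID=exon:{c.genome_id}.{i};Parent=gene:{c.genome_id}\n"
                )


def candidates_to_frame(candidates: list[PrimerCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        s, e = c.template_interval
        rows.append(
            {
                "genome": c.genome_id,
                "orientation": c.orientation,
                "sequence": c.sequence,
                "start_1based": s + 1,
                "end_1based": e,
                "tm_C": round(c.tm_C, 1),
                "anchor_kind": c.anchor_site.kind,
                "region": c.region_label,
                "filter_status": c.filter_status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome", "orientation", "sequence", "start_1based", "end_1based",
            "tm_C", "anchor_kind", "region", "filter_status",
        ],
    )


def pairs_to_frame(solutions: list[TilingSolution]) -> pd.DataFrame:
    """Chosen primer sets in the published-table layout.

    Columns: primer name, sequence 5'->3', annealing degC, product size bp,
    genome label.  Coordinates are 1-based inclusive.
    """
    rows = []
    for sol in solutions:
        for i, pair in enumerate(sol.chosen_pairs, 1):
            for cand, role in ((pair.fwd, "F"), (pair.rev, "R")):
                rows.append(
                    {
                        "primer_name": f"{sol.genome_id}-{role}{i}",
                        "sequence_5to3": cand.sequence,
                        "annealing_C": 60.0,
                        "size_bp": pair.size_bp,
                        "genome": sol.genome_id,
                        "start_1based": cand.template_interval[0] + 1,
                        "end_1based": cand.template_interval[1],
                        "tm_C": round(cand.tm_C, 1),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "primer_name", "sequence_5to3", "annealing_C", "size_bp",
            "genome", "start_1based", "end_1based", "tm_C",
        ],
    )


def amplicons_to_bed(amplicons: list[PredictedAmplicon], path) -> None:
    """BED6 (0-based half-open); score encodes class 0/500/1000."""
    with open(path, "w") as fh:
        fh.write('track name=amplicons description="predicted products (0-based half-open)"\n')
        for a in amplicons:
            s, e = a.interval
            fh.write(
                f"{a.template_id}\t{s}\t{e}\tamplicon_{a.size_bp}bp\t"
                f"{_CLASS_SCORE[a.amp_class]}\t+\n"
            )


def amplicons_to_frame(amplicons: list[PredictedAmplicon]) -> pd.DataFrame:
    rows = []
    for a in amplicons:
        s, e = a.interval
        rows.append(
            {
                "template": a.template_id,
                "start_1based": s + 1,
                "end_1based": e,
                "size_bp": a.size_bp,
                "class": a.amp_class,
                "fwd_mismatches": ",".join(map(str, a.fwd_profile.mismatch_positions_from_3prime)) or "-",
                "rev_mismatches": ",".join(map(str, a.rev_profile.mismatch_positions_from_3prime)) or "-",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["template", "start_1based", "end_1based", "size_bp", "class",
                 "fwd_mismatches", "rev_mismatches"],
    )


def read_primer_table(path) -> pd.DataFrame:
    """Primer TSV dialect: name, sequence 5'->3', annealing, size, genome.

    Consecutive rows pair up (forward then reverse), mirroring the
    published table layout.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"primer_name", "sequence_5to3", "genome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer table missing columns: {sorted(missing)}")
    if len(df) % 2:
        raise ValueError("primer table must contain an even number of rows (F/R pairs)")
    return df
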