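"""Homoeolog ingestion, multiple alignment, coordinate maps and site discovery.

The entry point is :func:`read_gene_family` (FASTA + GFF3 -> GeneCopy list),
followed by :func:`build_alignment` (MAFFT by default, or a user-supplied
aligned FASTA) and :func:`find_discriminative_sites`, which scans alignment
columns for positions where one genome's residue differs from the residue
of *every* other genome — the sites a genome-specific primer can anchor on.

Coordinates are 0-based half-open throughout; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import gzip
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

EXON = "EXON"
INTRON = "INTRON"
JUNCTION = "JUNCTION"

#: columns within this distance of an exon/intron boundary are labelled
#: JUNCTION — roughly the length of the 3'-proximal region that decides
#: whether a mismatched primer still extends
JUNCTION_WINDOW = 5

_VALID = set("ACGTN")


class StructuralError(ValueError):
    """Gene structure missing or inconsistent with the sequence data."""


def _clean_seq(seq: str) -> str:
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return s


@dataclass
class GeneCopy:
    """One genome's copy of the gene: sequence plus exon intervals.

    ``exons`` are 0-based half-open, sorted, non-overlapping; introns are
    the gaps between consecutive exons.  An empty sequence with no exons is
    permitted as the sentinel for a whole-locus deletion allele.
    """

    genome_id: str
    sequence: str
    exons: list[tuple[int, int]]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.sequence = str(self.sequence).upper().replace("U", "T")
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        if len(self.sequence) == 0:
            if self.exons:
                raise ValueError("empty sequence cannot carry exons")
            return
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.genome_id}: invalid characters {sorted(bad)}")
        prev_end = -1
        for a, b in self.exons:
            if not (0 <= a < b <= len(self.sequence)):
                raise ValueError(
                    f"{self.genome_id}: exon ({a},{b}) outside sequence of "
                    f"length {len(self.sequence)}"
                )
            if a < prev_end:
                raise ValueError(f"{self.genome_id}: exons overlap or are unsorted")
            if a == prev_end:
                raise ValueError(f"{self.genome_id}: zero-length intron between exons")
            prev_end = b

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons (0-based half-open)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def region_of(self, pos: int) -> str:
        """EXON or INTRON label of an ungapped position (ignores junctions)."""
        for a, b in self.exons:
            if a <= pos < b:
                return EXON
        return INTRON

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DiscriminativeSite:
    """An alignment column where the target genome differs from all others.

    ``kind`` is ``SNP`` (all genomes have a residue, the target's differs
    from every off-target) or ``INDEL_EDGE`` (the first/last target-ungapped
    column adjacent to an off-target gap run).  ``partial`` marks columns
    where the target differs from some but not all off-targets; these are
    excluded from anchoring by default because a genome-specific primer must
    discriminate against every homoeolog.
    """

    target_genome: str
    column: int
    kind: str  # SNP | INDEL_EDGE
    target_base: str
    offtarget_bases: dict[str, str]
    region: str = INTRON
    partial: bool = False


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_gff3_exons(gff3_path) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals per seqid from a GFF3 file, converted to 0-based half-open."""
    import gffutils

    with _open_text(gff3_path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("exon"):
        exons.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
    for seqid in exons:
        exons[seqid].sort()
    return exons


def read_gene_family(fasta_path, gff3_path) -> list[GeneCopy]:
    """Load one homoeolog family: one GeneCopy per FASTA record.

    FASTA record IDs must match GFF3 seqids carrying ``exon`` features.
    Sequences are uppercased and U is mapped to T.  Plain or gzipped files
    are accepted.
    """
    exon_map = _parse_gff3_exons(gff3_path)
    copies = []
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id not in exon_map:
                raise StructuralError(f"no exon features for record '{rec.id}' in GFF3")
            copies.append(
                GeneCopy(
                    genome_id=rec.id,
                    sequence=_clean_seq(rec.seq),
                    exons=exon_map[rec.id],
                    source_id=rec.description,
                )
            )
    if not copies:
        raise StructuralError(f"no records in {fasta_path}")
    return copies


@dataclass
class HomoeologAlignment:
    """Gapped multiple alignment of 2+ gene copies with coordinate maps.

    ``rows[g]`` degapped reproduces ``copies[g].sequence`` exactly.
    ``column_region[g][c]`` labels each column EXON / INTRON / JUNCTION for
    genome ``g`` (gap columns inherit the label of the next ungapped
    position to their right).
    """

    copies: list[GeneCopy]
    rows: list[str]
    _col_to_pos: list[np.ndarray] = field(repr=False, default_factory=list)
    _pos_to_col: list[np.ndarray] = field(repr=False, default_factory=list)
    column_region: list[list[str]] = field(repr=False, default_factory=list)
    junction_window: int = JUNCTION_WINDOW

    def __post_init__(self) -> None:
        if len(self.copies) < 2:
            raise ValueError("need at least two gene copies")
        n_cols = {len(r) for r in self.rows}
        if len(n_cols) != 1:
            raise ValueError("alignment rows differ in length")
        for copy, row in zip(self.copies, self.rows):
            if row.replace("-", "") != copy.sequence:
                raise ValueError(
                    f"row for {copy.genome_id} does not degap to its sequence"
                )
        if not self._col_to_pos:
            self._build_maps()
        if not self.column_region:
            self._build_regions()

    # -- coordinate maps -------------------------------------------------
    def _build_maps(self) -> None:
        for row in self.rows:
            arr = np.frombuffer(row.encode(), dtype="S1")
            ungapped = arr != b"-"
            # col -> pos: cumulative count of ungapped chars left of col; -1 on gaps
            cum = np.cumsum(ungapped) - 1
            col_to_pos = np.where(ungapped, cum, -1)
            pos_to_col = np.flatnonzero(ungapped)
            self._col_to_pos.append(col_to_pos.astype(np.int64))
            self._pos_to_col.append(pos_to_col.astype(np.int64))

    def _genome_index(self, genome_id: str) -> int:
        for i, c in enumerate(self.copies):
            if c.genome_id == genome_id:
                return i
        raise KeyError(f"unknown genome '{genome_id}'")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def genome_ids(self) -> list[str]:
        return [c.genome_id for c in self.copies]

    def col_to_pos(self, genome_id: str, col: int) -> int:
        """Ungapped position of column ``col`` in the genome (-1 on a gap)."""
        return int(self._col_to_pos[self._genome_index(genome_id)][col])

    def pos_to_col(self, genome_id: str, pos: int) -> int:
        return int(self._pos_to_col[self._genome_index(genome_id)][pos])

    # -- region labels ---------------------------------------------------
    def _build_regions(self) -> None:
        w = self.junction_window
        for g, copy in enumerate(self.copies):
            col_to_pos = self._col_to_pos[g]
            n = self.n_columns
            # per-position base labels, then project through the map;
            # gap columns take the label of the next ungapped position
            pos_labels = np.full(len(copy.sequence), INTRON, dtype=object)
            for a, b in copy.exons:
                pos_labels[a:b] = EXON
            # backward-fill: a gap column takes the next ungapped position
            eff = np.empty(n, dtype=np.int64)
            nxt = len(copy.sequence) - 1
            for c in range(n - 1, -1, -1):
                if col_to_pos[c] >= 0:
                    nxt = col_to_pos[c]
                eff[c] = nxt
            labels = [str(pos_labels[p]) for p in eff]
            # junction override: within w columns of a projected boundary
            boundaries = set()
            for a, b in copy.exons:
                for p in (a, b):
                    if 0 < p < len(copy.sequence):
                        boundaries.add(self._pos_to_col[g][p])
            is_junction = np.zeros(n, dtype=bool)
            for bc in boundaries:
                lo = max(0, bc - w)
                hi = min(n, bc + w + 1)
                is_junction[lo:hi] = True
            self.column_region.append(
                [JUNCTION if j else lab for j, lab in zip(is_junction, labels)]
            )

    def region_at(self, genome_id: str, col: int) -> str:
        return self.column_region[self._genome_index(genome_id)][col]


def _run_mafft(copies: list[GeneCopy]) -> list[str]:
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft not found on PATH; pass a precomputed alignment")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "family.fa"
        with open(fa, "w") as fh:
            for c in copies:
                fh.write(f">{c.genome_id}\n{c.sequence}\n")
        proc = subprocess.run(
            [mafft, "--auto", "--quiet", str(fa)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows = {}
    rec_id, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if rec_id is not None:
                rows[rec_id] = "".join(chunks)
            rec_id, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip().upper())
    if rec_id is not None:
        rows[rec_id] = "".join(chunks)
    return [rows[c.genome_id] for c in copies]


def build_alignment(
    copies: list[GeneCopy],
    precomputed_alignment: list[str] | None = None,
    junction_window: int = JUNCTION_WINDOW,
) -> HomoeologAlignment:
    """Build (via MAFFT) or ingest a multiple alignment of the gene copies.

    ``precomputed_alignment`` is a list of gapped rows in the same order as
    ``copies``; each row must degap to its copy's sequence exactly, else a
    ValueError is raised.
    """
    if len(copies) < 2:
        raise ValueError("need at least two gene copies to align")
    if precomputed_alignment is not None:
        rows = [r.upper() for r in precomputed_alignment]
    else:
        rows = _run_mafft(copies)
    return HomoeologAlignment(copies=copies, rows=rows, junction_window=junction_window)


def find_discriminative_sites(
    aln: HomoeologAlignment,
    target_genome: str,
    region_filter: set[str] | None = None,
    include_partial: bool = False,
) -> list[DiscriminativeSite]:
    """Columns where ``target_genome`` differs from every other genome.

    ``region_filter`` restricts sites by the target genome's region label
    at the column; the default {INTRON, JUNCTION} reflects that homoeolog
    divergence concentrates in introns (pass {EXON, INTRON, JUNCTION} to
    allow exon anchors).  Columns containing N never yield sites.  SNP sites
    require a residue in every genome; INDEL_EDGE sites are the first/last
    target-ungapped columns of a run where at least one off-target is
    gapped, and count as fully discriminative only when every off-target is
    gapped there.
    """
    if region_filter is None:
        region_filter = {INTRON, JUNCTION}
    ti = aln._genome_index(target_genome)
    others = [i for i in range(len(aln.copies)) if i != ti]
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in aln.rows])
    target = mat[ti]
    gap = b"-"
    n_col = aln.n_columns

    sites: list[DiscriminativeSite] = []

    has_n = (mat == b"N").any(axis=0)
    target_base = target != gap
    off = mat[others]
    off_gap = off == gap

    # SNP columns: everyone has a residue, target differs from each off-target
    all_residue = target_base & ~off_gap.all(axis=0) & (~off_gap).all(axis=0)
    diff = off != target[None, :]
    full_snp = all_residue & diff.all(axis=0) & ~has_n
    part_snp = all_residue & diff.any(axis=0) & ~diff.all(axis=0) & ~has_n

    def _mk(col: int, kind: str, partial: bool) -> DiscriminativeSite:
        return DiscriminativeSite(
            target_genome=target_genome,
            column=int(col),
            kind=kind,
            target_base=target[col].decode(),
            offtarget_bases={
                aln.copies[i].genome_id: mat[i, col].decode() for i in others
            },
            region=aln.region_at(target_genome, int(col)),
            partial=partial,
        )

    for col in np.flatnonzero(full_snp):
        sites.append(_mk(col, "SNP", partial=False))
    if include_partial:
        for col in np.flatnonzero(part_snp):
            sites.append(_mk(col, "SNP", partial=True))

    # INDEL_EDGE: maximal runs of columns where target has a residue and
    # >=1 off-target is gapped; emit the first and last column of each run
    in_run = target_base & off_gap.any(axis=0) & ~has_n
    col = 0
    while col < n_col:
        if in_run[col]:
            start = col
            while col < n_col and in_run[col]:
                col += 1
            for edge in {start, col - 1}:
                full = bool(off_gap[:, edge].all())
                if full or include_partial:
                    sites.append(_mk(edge, "INDEL_EDGE", partial=not full))
        else:
            col += 1

    sites = [s for s in sites if s.region in region_filter]
    sites.sort(key=lambda s: (s.column, s.kind))
    return sites
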