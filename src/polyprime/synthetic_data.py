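"""Simulation of homoeologous gene families and deletion-based null alleles.

The generator emulates the divergence structure of homoeologs in an
allopolyploid: an ancestral gene is sampled, and each genome copy then
accumulates substitutions at region-specific rates — low in exons (coding
identity stays above ~95%) and high in introns (identity in the high-60s
to low-80s percent) — plus intron-confined indels.  ``divergence`` values
are expected *pairwise* substitution fractions, so each copy receives half
that rate relative to the ancestor.

Because every copy is threaded through the ancestor's coordinates, the
true multiple alignment and the list of fully discriminative columns are
known exactly and returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from polyprime.alignment_core import GeneCopy, HomoeologAlignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationParams:
    """Family structure and divergence parameters.

    Defaults give a compact plant gene (8 exons of 150-300 bp, introns of
    100-600 bp, total roughly 3-6 kb) with 3% pairwise exon divergence,
    25% pairwise intron divergence and 0.02 indel events per intron bp —
    inside the empirically observed homoeolog bands (>95% exon identity,
    ~69-82% intron identity).
    """

    n_copies: int = 3
    n_exons: int = 8
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (100, 600)
    exon_lengths: list[int] | None = None
    intron_lengths: list[int] | None = None
    exon_divergence: float = 0.03
    intron_divergence: float = 0.25
    intron_indel_rate: float = 0.02
    indel_length_range: tuple[int, int] = (1, 30)
    genome_ids: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("need at least 2 copies")
        if self.n_exons < 1:
            raise ValueError("need at least one exon")
        for d in (self.exon_divergence, self.intron_divergence):
            if not 0.0 <= d <= 1.0:
                raise ValueError("divergences must be in [0, 1]")
        if self.genome_ids is None:
            self.genome_ids = [f"G{i + 1}" for i in range(self.n_copies)]
        if len(self.genome_ids) != self.n_copies:
            raise ValueError("genome_ids length must equal n_copies")


@dataclass
class SimulatedFamily:
    copies: list[GeneCopy]
    alignment: HomoeologAlignment
    #: fully discriminative columns per genome: {genome_id: [column, ...]}
    planted_sites: dict[str, list[int]]
    ancestor: str = ""


def _sample_structure(params: SimulationParams, rng: np.random.Generator):
    if params.exon_lengths is not None:
        exon_lens = list(params.exon_lengths)
    else:
        lo, hi = params.exon_length_range
        exon_lens = rng.integers(lo, hi + 1, size=params.n_exons).tolist()
    n_introns = params.n_exons - 1
    if params.intron_lengths is not None:
        intron_lens = list(params.intron_lengths)
    else:
        lo, hi = params.intron_length_range
        intron_lens = rng.integers(lo, hi + 1, size=n_introns).tolist()
    if len(exon_lens) != params.n_exons or len(intron_lens) != n_introns:
        raise ValueError("structure length lists inconsistent with n_exons")
    return exon_lens, intron_lens


def simulate_family(params: SimulationParams) -> SimulatedFamily:
    """Sample an ancestor and mutate each copy; return copies + ground truth.

    Substitutions are uniform over the three alternative bases (no
    transition bias); indels are deletions or insertions confined to intron
    interiors so the exon/intron structure projects cleanly onto every
    copy.  Identical params (including seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    exon_lens, intron_lens = _sample_structure(params, rng)

    anc_len = sum(exon_lens) + sum(intron_lens)
    ancestor = rng.choice(_BASES, size=anc_len)

    # ancestor exon intervals and per-position region mask
    exons_anc: list[tuple[int, int]] = []
    pos = 0
    in_intron = np.zeros(anc_len, dtype=bool)
    for i, el in enumerate(exon_lens):
        exons_anc.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            in_intron[pos : pos + intron_lens[i]] = True
            pos += intron_lens[i]

    # per-copy substitution masks (half the pairwise divergence each)
    copies_bases = []
    for _ in range(params.n_copies):
        bases = ancestor.copy()
        rate = np.where(in_intron, params.intron_divergence / 2.0, params.exon_divergence / 2.0)
        mut = rng.random(anc_len) < rate
        for p in np.flatnonzero(mut):
            choices = _BASES[_BASES != bases[p]]
            bases[p] = rng.choice(choices)
        copies_bases.append(bases)

    # intron-confined indels per copy: deletions mask ancestor positions,
    # insertions add a keyed block after an ancestor position
    deletions = [np.zeros(anc_len, dtype=bool) for _ in range(params.n_copies)]
    insertions: list[dict[int, np.ndarray]] = [dict() for _ in range(params.n_copies)]
    lo_i, hi_i = params.indel_length_range
    for ci in range(params.n_copies):
        for a, b in [(exons_anc[i][1], exons_anc[i + 1][0]) for i in range(len(exons_anc) - 1)]:
            intron_len = b - a
            n_events = rng.poisson(params.intron_indel_rate * intron_len)
            for _ in range(n_events):
                length = int(rng.integers(lo_i, hi_i + 1))
                if rng.random() < 0.5:
                    # deletion, clipped to the intron interior
                    start = int(rng.integers(a + 1, max(a + 2, b - 1)))
                    end = min(start + length, b - 1)
                    if end > start:
                        deletions[ci][start:end] = True
                else:
                    after = int(rng.integers(a, b - 1))
                    ins = rng.choice(_BASES, size=length)
                    prev = insertions[ci].get(after)
                    insertions[ci][after] = ins if prev is None else np.concatenate([prev, ins])

    # thread everything into one multiple alignment: columns are ancestor
    # positions plus per-copy insertion blocks (ordered by copy index)
    rows = [[] for _ in range(params.n_copies)]
    for p in range(anc_len):
        for ci in range(params.n_copies):
            rows[ci].append(b"-" if deletions[ci][p] else copies_bases[ci][p])
        for ci in range(params.n_copies):
            ins = insertions[ci].get(p)
            if ins is not None:
                for cj in range(params.n_copies):
                    rows[cj].extend(ins if cj == ci else [b"-"] * len(ins))
    row_strs = [b"".join(r).decode() for r in rows]

    # per-copy sequences and projected exon intervals
    copies = []
    for ci in range(params.n_copies):
        seq = row_strs[ci].replace("-", "")
        kept = ~deletions[ci]
        # ungapped position of each ancestor position in copy ci
        pos_of = np.full(anc_len, -1, dtype=np.int64)
        cur = 0
        for p in range(anc_len):
            if kept[p]:
                pos_of[p] = cur
                cur += 1
            ins = insertions[ci].get(p)
            if ins is not None:
                cur += len(ins)
        exons_ci = []
        for a, b in exons_anc:
            # exons contain no indels, so they stay contiguous
            exons_ci.append((int(pos_of[a]), int(pos_of[b - 1]) + 1))
        copies.append(
            GeneCopy(
                genome_id=params.genome_ids[ci],
                sequence=seq,
                exons=exons_ci,
                source_id=f"simulated seed={params.seed}",
            )
        )

    aln = HomoeologAlignment(copies=copies, rows=row_strs)

    # ground truth: fully discriminative SNP columns per genome
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in row_strs])
    planted: dict[str, list[int]] = {}
    for ci in range(params.n_copies):
        others = np.array([i for i in range(params.n_copies) if i != ci])
        residue = (mat != b"-").all(axis=0)
        diff = (mat[others] != mat[ci][None, :]).all(axis=0)
        planted[params.genome_ids[ci]] = np.flatnonzero(residue & diff).tolist()

    return SimulatedFamily(
        copies=copies,
        alignment=aln,
        planted_sites=planted,
        ancestor=ancestor.tobytes().decode(),
    )


def simulate_null_allele(copy: GeneCopy, mode: str, index: int | None = None) -> GeneCopy:
    """Derive a deletion-bearing null allele from a wild-type copy.

    ``mode`` is one of ``intron_deletion`` (drop intron ``index``, 1-based),
    ``exon_deletion`` (drop exon ``index``, 1-based) or
    ``whole_gene_deletion`` (empty-sequence sentinel).  Exon/intron
    intervals are re-indexed to the shortened sequence.
    """
    if mode == "whole_gene_deletion":
        return GeneCopy(
            genome_id=copy.genome_id,
            sequence="",
            exons=[],
            source_id=f"{copy.source_id} [whole-gene deletion]",
        )
    if mode == "intron_deletion":
        introns = copy.introns
        if index is None or not 1 <= index <= len(introns):
            raise ValueError(f"intron index {index} out of range 1..{len(introns)}")
        a, b = introns[index - 1]
    elif mode == "exon_deletion":
        if index is None or not 1 <= index <= len(copy.exons):
            raise ValueError(f"exon index {index} out of range 1..{len(copy.exons)}")
        a, b = copy.exons[index - 1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    removed = b - a
    seq = copy.sequence[:a] + copy.sequence[b:]
    new_exons = []
    for s, e in copy.exons:
        if mode == "exon_deletion" and (s, e) == (a, b):
            continue
        s2 = s - removed if s >= b else s
        e2 = e - removed if e > b else e
        new_exons.append((s2, e2))
    # deleting an intron fuses the flanking exons into one block
    if mode == "intron_deletion":
        fused = []
        for s, e in new_exons:
            if fused and s == fused[-1][1]:
                fused[-1] = (fused[-1][0], e)
            else:
                fused.append((s, e))
        new_exons = fused
    return GeneCopy(
        genome_id=copy.genome_id,
        sequence=seq,
        exons=new_exons,
        source_id=f"{copy.source_id} [{mode}({index})]",
    )
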