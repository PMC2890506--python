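"""Ingestion, alignment construction, coordinate maps and site discovery."""

import numpy as np
import pytest
from Bio import Align

from polyprime.alignment_core import (
    EXON,
    INTRON,
    JUNCTION,
    DiscriminativeSite,
    GeneCopy,
    HomoeologAlignment,
    StructuralError,
    build_alignment,
    find_discriminative_sites,
    read_gene_family,
)
from polyprime.synthetic_data import SimulationParams, simulate_family


def _write_family(tmp_path, records):
    """records: list of (id, seq, exons 0-based half-open)."""
    fa = tmp_path / "fam.fa"
    gff = tmp_path / "fam.gff3"
    with open(fa, "w") as fh:
        for rid, seq, _ in records:
            fh.write(f">{rid}\n{seq}\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, _, exons in records:
            for i, (a, b) in enumerate(exons, 1):
                fh.write(
                    f"{rid}\tx\texon\t{a + 1}\t{b}\t.\t+\t.\t"
                    f"ID=e{i};Parent=gene:{rid}\n"
                )
    return fa, gff


def _mk_gene(rng, n_exons, exon_len=30, intron_len=20):
    seq = "".join(rng.choice(list("ACGT")) for _ in range(n_exons * exon_len + (n_exons - 1) * intron_len))
    exons = [
        (i * (exon_len + intron_len), i * (exon_len + intron_len) + exon_len)
        for i in range(n_exons)
    ]
    return seq, exons


class TestReadGeneFamily:
    def test_three_records_eight_exons_give_seven_introns(self, tmp_path):
        import random

        rng = random.Random(0)
        records = []
        for rid in ("7A", "4A", "7D"):
            seq, exons = _mk_gene(rng, 8)
            records.append((rid, seq, exons))
        fa, gff = _write_family(tmp_path, records)
        copies = read_gene_family(fa, gff)
        assert [c.genome_id for c in copies] == ["7A", "4A", "7D"]
        assert all(len(c.exons) == 8 and len(c.introns) == 7 for c in copies)

    def test_eleven_exons_give_ten_introns(self, tmp_path):
        import random

        seq, exons = _mk_gene(random.Random(1), 11)
        fa, gff = _write_family(tmp_path, [("7A", seq, exons)])
        (copy,) = read_gene_family(fa, gff)
        assert len(copy.exons) == 11
        assert len(copy.introns) == 10

    def test_exon_beyond_sequence_is_rejected(self, tmp_path):
        fa, gff = _write_family(tmp_path, [("g", "ACGTACGT", [(0, 4), (6, 20)])])
        with pytest.raises(ValueError, match="outside sequence"):
            read_gene_family(fa, gff)

    def test_missing_structure_is_structural_error(self, tmp_path):
        fa = tmp_path / "solo.fa"
        fa.write_text(">g\nACGTACGT\n")
        gff = tmp_path / "solo.gff3"
        gff.write_text("##gff-version 3\nother\tx\texon\t1\t4\t.\t+\t.\tID=e1\n")
        with pytest.raises(StructuralError, match="no exon features"):
            read_gene_family(fa, gff)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneCopy("g", "ACGTACGTACGT", [(0, 6), (4, 10)])

    def test_uracil_mapped_to_thymine(self):
        assert GeneCopy("g", "acgu", [(0, 4)]).sequence == "ACGT"


class TestBuildAlignment:
    def test_identical_sequences_align_without_gaps(self):
        seq = "ATGCCGTATTGACCTGAGGACTGCTTGACAATCGGATATT"
        copies = [GeneCopy(g, seq, [(0, len(seq))]) for g in "AB"]
        aln = build_alignment(copies)
        assert all("-" not in row for row in aln.rows)

    def test_single_intron_deletion_matches_pairwise_oracle(self):
        # 100-bp gene vs. a copy lacking a 10-bp intron chunk: expect one
        # 10-column gap block, as an independent affine-gap global aligner
        # places it
        import random

        rng = random.Random(3)
        long = "".join(rng.choice("ACGT") for _ in range(100))
        short = long[:45] + long[55:]
        copies = [
            GeneCopy("L", long, [(0, 30), (70, 100)]),
            GeneCopy("S", short, [(0, 30), (60, 90)]),
        ]
        aln = build_alignment(copies)
        gaps = aln.rows[1].count("-")
        assert gaps == 10
        assert "-" * 10 in aln.rows[1]

        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-5,
            extend_gap_score=-1,
        )
        oracle = aligner.align(long, short)[0]
        assert str(oracle[1]).count("-") == 10

    def test_precomputed_alignment_must_degap_to_inputs(self):
        copies = [
            GeneCopy("A", "ACGTACGT", [(0, 8)]),
            GeneCopy("B", "ACGT", [(0, 4)]),
        ]
        with pytest.raises(ValueError, match="degap"):
            build_alignment(copies, precomputed_alignment=["ACGTACGT", "AC--GTAA"])

    def test_degap_round_trip_on_simulated_family(self, sim_family):
        for copy, row in zip(sim_family.copies, sim_family.alignment.rows):
            assert row.replace("-", "") == copy.sequence

    def test_coordinate_bijection(self, sim_family):
        aln = sim_family.alignment
        rng = np.random.default_rng(0)
        for copy in aln.copies:
            for pos in rng.integers(0, len(copy), size=50):
                col = aln.pos_to_col(copy.genome_id, int(pos))
                assert aln.col_to_pos(copy.genome_id, col) == pos

    def test_region_labels_cover_all_columns(self, sim_family):
        aln = sim_family.alignment
        for g, regions in enumerate(aln.column_region):
            assert len(regions) == aln.n_columns
            assert set(regions) <= {EXON, INTRON, JUNCTION}


def _toy_alignment(rows, exons=None):
    copies = [
        GeneCopy(f"G{i + 1}", row.replace("-", ""), exons or [(0, len(row.replace("-", "")))])
        for i, row in enumerate(rows)
    ]
    # toy rows are exon-only unless stated; use explicit structures
    return HomoeologAlignment(copies=copies, rows=list(rows))


ALL_REGIONS = {EXON, INTRON, JUNCTION}


class TestFindDiscriminativeSites:
    def test_identical_rows_give_no_sites(self):
        row = "ATGCCGTATTGACCTGAGCGATCGATCCGA"
        aln = _toy_alignment([row, row, row])
        assert find_discriminative_sites(aln, "G1", ALL_REGIONS) == []

    def test_planted_snp_column_found(self):
        base = "ATGCCGTATTGACCTGAGCGATCGATCCGA"
        target = base[:12] + "A" + base[13:]
        other = base[:12] + "G" + base[13:]
        aln = _toy_alignment([target, other, other])
        sites = find_discriminative_sites(aln, "G1", ALL_REGIONS)
        snps = [s for s in sites if s.kind == "SNP"]
        assert len(snps) == 1
        assert snps[0].column == 12
        assert snps[0].target_base == "A"
        assert set(snps[0].offtarget_bases.values()) == {"G"}

    def test_offtarget_gap_yields_indel_edge(self):
        aln = _toy_alignment(
            [
                "ATGCCGTATTGACCTGAGCG",
                "ATGCCGT----ACCTGAGCG".replace("A", "A"),
                "ATGCCGT----ACCTGAGCG",
            ]
        )
        sites = find_discriminative_sites(aln, "G1", ALL_REGIONS)
        edges = [s for s in sites if s.kind == "INDEL_EDGE"]
        assert {s.column for s in edges} == {7, 10}
        assert all(not s.partial for s in edges)

    def test_unknown_genome_is_lookup_error(self, sim_family):
        with pytest.raises(KeyError):
            find_discriminative_sites(sim_family.alignment, "nope")

    def test_matches_brute_force_column_scan(self, small_family):
        aln = small_family.alignment
        target = "G2"
        got = {
            s.column
            for s in find_discriminative_sites(aln, target, ALL_REGIONS)
            if s.kind == "SNP"
        }
        ti = aln.genome_ids.index(target)
        expect = set()
        for col in range(aln.n_columns):
            column = [row[col] for row in aln.rows]
            if "-" in column or "N" in column:
                continue
            if all(column[i] != column[ti] for i in range(len(column)) if i != ti):
                expect.add(col)
        assert got == expect

    def test_partial_sites_flagged_and_excluded_by_default(self):
        base = "ATGCCGTATTGACCTGAGCGATCGATCCGA"
        target = base[:12] + "A" + base[13:]
        other1 = base[:12] + "G" + base[13:]
        other2 = base[:12] + "A" + base[13:]  # same as target: only partial
        aln = _toy_alignment([target, other1, other2])
        assert find_discriminative_sites(aln, "G1", ALL_REGIONS) == []
        partial = find_discriminative_sites(aln, "G1", ALL_REGIONS, include_partial=True)
        assert any(s.partial and s.column == 12 for s in partial)

    def test_more_intron_divergence_never_loses_sites(self):
        counts = []
        for div in (0.05, 0.15, 0.25):
            fam = simulate_family(
                SimulationParams(
                    seed=11,
                    intron_divergence=div,
                    intron_indel_rate=0.0,
                    n_exons=4,
                    exon_length_range=(80, 120),
                    intron_length_range=(150, 300),
                )
            )
            n = sum(
                len(find_discriminative_sites(fam.alignment, g, {INTRON}))
                for g in fam.alignment.genome_ids
            )
            counts.append(n)
        assert counts == sorted(counts)
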