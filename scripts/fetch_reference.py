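#!/usr/bin/env python
"""Fetch the wheat Wx/SSII reference genomic sequences from GenBank.

Downloads the six accessions (AB019622-AB019624: Wx-7A/4A/7D;
AB201445-AB201447: SSII-7A/7B/7D) via NCBI efetch and writes, per gene
family, a FASTA and a GFF3 of exon features under tests/data/genbank/.
Requires network access; run once before executing the reference-based
acceptance tests.

Usage:  python scripts/fetch_reference.py [--out tests/data/genbank]
"""

from __future__ import annotations

import argparse
import io
import sys
import time
import urllib.request
from pathlib import Path

from Bio import SeqIO

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gb&retmode=text"
)

FAMILIES = {
    "Wx": ["AB019622", "AB019623", "AB019624"],
    "SSII": ["AB201445", "AB201446", "AB201447"],
}


def fetch_record(acc: str):
    with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as fh:
        text = fh.read().decode()
    return SeqIO.read(io.StringIO(text), "genbank")


def exon_intervals(record):
    """0-based half-open exon intervals from annotated exon features.

    Falls back to CDS sub-parts when no exon features are annotated.
    """
    exons = []
    for feat in record.features:
        if feat.type == "exon":
            exons.append((int(feat.location.start), int(feat.location.end)))
    if not exons:
        for feat in record.features:
            if feat.type == "CDS":
                for part in feat.location.parts:
                    exons.append((int(part.start), int(part.end)))
    return sorted(set(exons))


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="tests/data/genbank", type=Path)
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    for gene, accs in FAMILIES.items():
        fa_path = args.out / f"{gene}.fa"
        gff_path = args.out / f"{gene}.gff3"
        with open(fa_path, "w") as fa, open(gff_path, "w") as gff:
            gff.write("##gff-version 3\n")
            for acc in accs:
                rec = fetch_record(acc)
                seq = str(rec.seq).upper()
                fa.write(f">{acc} {rec.description}\n")
                for i in range(0, len(seq), 70):
                    fa.write(seq[i : i + 70] + "\n")
                exons = exon_intervals(rec)
                if not exons:
                    print(f"warning: no exon/CDS features for {acc}", file=sys.stderr)
                for i, (a, b) in enumerate(exons, 1):
                    gff.write(
                        f"{acc}\tgenbank\texon\t{a + 1}\t{b}\t.\t+\t.\t"
                        f"ID=exon:{acc}.{i};Parent=gene:{acc}\n"
                    )
                print(f"{acc}: {len(seq)} bp, {len(exons)} exons")
                time.sleep(0.5)
        print(f"wrote {fa_path} and {gff_path}")


if __name__ == "__main__":
    main()
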