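"""Presence/absence genotyping of deletion-based null alleles.

A diagnostic panel holds one genome-specific primer pair per locus (e.g.
the three wheat Wx loci on 7A, 4A and 7D).  A locus scores *present* when
the pair yields at least one STRONG in-silico product on the allele
sequence and *absent* otherwise — faint mismatch-primed products do not
count, matching how diagnostic gels are scored.  The joint +/- pattern
maps to a genotype code: wild type (1), the three single nulls (2-4), the
three double nulls (5-7) and the triple null (8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from polyprime.insilico_pcr import STRONG, InsilicoParams, insilico_pcr

PRESENT = "present"
ABSENT = "absent"


@dataclass
class PanelEntry:
    locus: str
    fwd: str
    rev: str
    expected_size_bp: int | None = None


@dataclass
class GenotypeRecord:
    sample: str
    presence: tuple[str, ...]  # '+' / '-' per locus
    null_loci: list[str]
    label: str
    type_code: str


def _default_code_map(loci: list[str]) -> dict[tuple[str, ...], tuple[str, str]]:
    """Pattern -> (label, code) for a three-locus null-allele panel.

    Codes follow the conventional waxy-line numbering: 1 wild type, 2-4
    single nulls in locus order, 7 the first+second double null, 8 triple
    null.  Codes 5 ((+,-,-)) and 6 ((-,+,-)) complete the scheme by
    analogy for the double-null patterns not observed in the classic line
    sets.
    """
    if len(loci) != 3:
        return {}
    a, b, d = loci
    return {
        ("+", "+", "+"): ("Wild type", "1"),
        ("-", "+", "+"): (f"null ({a})", "2"),
        ("+", "-", "+"): (f"null ({b})", "3"),
        ("+", "+", "-"): (f"null ({d})", "4"),
        ("+", "-", "-"): (f"null ({b} & {d})", "5"),
        ("-", "+", "-"): (f"null ({a} & {d})", "6"),
        ("-", "-", "+"): (f"null ({a} & {b})", "7"),
        ("-", "-", "-"): ("Triple null alleles", "8"),
    }


@dataclass
class DiagnosticPanel:
    """Ordered diagnostic loci plus the pattern -> genotype code map."""

    entries: list[PanelEntry]
    genotype_code_map: dict[tuple[str, ...], tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loci = [e.locus for e in self.entries]
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus labels in panel")
        if not self.genotype_code_map:
            self.genotype_code_map = _default_code_map(loci)

    @property
    def loci(self) -> list[str]:
        return [e.locus for e in self.entries]

    def validate_against_wild_type(
        self, wild_type: dict[str, str], params: InsilicoParams | None = None
    ) -> None:
        """Every panel entry must amplify its wild-type reference.

        ``wild_type`` maps locus -> reference allele sequence.  Raises if
        any diagnostic pair fails on its own reference (an invalid panel).
        """
        for e in self.entries:
            if predict_presence((e.fwd, e.rev), wild_type[e.locus], params) != PRESENT:
                raise ValueError(f"panel entry {e.locus} does not amplify wild type")


def predict_presence(
    pair: tuple[str, str],
    allele_sequence: str,
    params: InsilicoParams | None = None,
) -> str:
    """'present' iff the pair yields >= 1 STRONG product on the allele."""
    fwd, rev = pair
    if not allele_sequence:
        return ABSENT
    amps = insilico_pcr(fwd, rev, {"allele": allele_sequence}, params)
    return PRESENT if any(a.amp_class == STRONG for a in amps) else ABSENT


def classify_genotype(
    presence_pattern: tuple[str, ...] | list[str],
    panel: DiagnosticPanel,
    sample: str = "sample",
) -> GenotypeRecord:
    """Map a per-locus +/- pattern to allele calls and a type code.

    Patterns outside the panel's code map are typed 'other' with locus-wise
    null calls.
    """
    pattern = tuple(presence_pattern)
    if len(pattern) != len(panel.entries):
        raise ValueError(
            f"pattern length {len(pattern)} != panel size {len(panel.entries)}"
        )
    if set(pattern) - {"+", "-"}:
        raise ValueError("pattern entries must be '+' or '-'")
    null_loci = [e.locus for e, p in zip(panel.entries, pattern) if p == "-"]
    label, code = panel.genotype_code_map.get(
        pattern,
        ("null (" + " & ".join(null_loci) + ")" if null_loci else "Wild type", "other"),
    )
    return GenotypeRecord(
        sample=sample,
        presence=pattern,
        null_loci=null_loci,
        label=label,
        type_code=code,
    )


def type_alleles(
    panel: DiagnosticPanel,
    samples: dict[str, dict[str, str]],
    params: InsilicoParams | None = None,
) -> list[GenotypeRecord]:
    """Genotype each sample from its per-locus allele sequences.

    ``samples`` maps sample name -> {locus: allele sequence}; a missing
    locus counts as a whole-locus deletion (absent).
    """
    out = []
    for name in samples:
        pattern = []
        for e in panel.entries:
            seq = samples[name].get(e.locus, "")
            pattern.append("+" if predict_presence((e.fwd, e.rev), seq, params) == PRESENT else "-")
        out.append(classify_genotype(tuple(pattern), panel, sample=name))
    return out
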