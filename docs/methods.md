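# Methods

## Problem setting

Homoeologous gene copies in an allopolyploid are collinear over their full
genomic length, nearly identical in exons and substantially diverged in
introns. A genome-specific assay must amplify exactly one copy. The
package treats this as four coupled sub-problems: discriminative-site
discovery in a multiple alignment, 3′-anchored primer construction under
thermodynamic constraints, mismatch-aware amplification prediction, and
interval optimization for gene tiling.

## Alignment and site discovery

Copies are ingested from FASTA plus GFF3 exon features (gffutils; gzip
accepted, U→T, uppercase). The default multiple aligner is MAFFT
(`--auto`), chosen over an in-house progressive aligner because
homoeologs are globally collinear and MAFFT is the field-standard,
deterministic tool already on the PATH; a curated aligned FASTA can be
supplied instead and is validated by the degap-round-trip invariant
(every gapped row must reproduce its input sequence exactly). Coordinate
maps between alignment columns and per-genome positions are built once as
integer arrays; the bijection on ungapped positions is asserted in tests.

Each column is labelled per genome EXON or INTRON by projecting the exon
intervals through the coordinate map; gap columns take the label of the
next ungapped position to their right. Columns within W = 5 columns of an
exon/intron boundary are relabelled JUNCTION — 5 matches the length of
the 3′-proximal window that decides extension (below), and boundary
anchors behave differently enough from deep-intron anchors to deserve a
distinct label.

A *discriminative site* for target genome g is a column where g's residue
differs from the residue of **every** other genome (SNP), or the first or
last g-ungapped column of a run in which at least one other genome is
gapped (INDEL_EDGE). Sites where g differs from only some off-targets are
retained with a `partial` flag but never anchored by default, because a
genome-specific primer must discriminate against all homoeologs
simultaneously. Columns containing N are skipped. Site discovery defaults
to {INTRON, JUNCTION} — that is where divergence concentrates — but exon
sites can be requested, since usable exon anchors do occur in practice.

## Melting temperature and 5′ adjustment

Tm uses nearest-neighbor thermodynamics with the unified parameter set
(Biopython `Tm_NN`, table DNA_NN3) and a monovalent-equivalent salt
correction: free divalent cations contribute `120·sqrt([Mg²⁺]−[dNTP])` mM
of equivalent monovalent salt (von Ahsen approximation), applied through
the salt-entropy correction `ΔS + 0.368·(N−1)·ln[Na⁺]`. The annealing
concentration is CT/4 with CT = 0.6 µM (primers in excess,
non-self-complementary). Defaults mirror a standard Taq buffer: 50 mM
monovalent, 1.5 mM MgCl₂, 0.2 mM total dNTP.

The tests pin this model against an independently coded oracle built from
the published unified table; the two agree to well under 0.01 °C. The
model convention matters more than its absolute accuracy: all primers in
one design are ranked and windowed under the same convention.

Because the 3′ base is fixed by the anchor, the only free variable is the
5′ end: `adjust_tm_by_5prime` tries lengths from `len_min` upward and
returns the **shortest** primer whose Tm falls in [tm_min, tm_max]
(59–61 °C default) — shortest-first makes the choice deterministic and
biases toward tighter, more specific primers. If no length in 16–25 nt
reaches the window the anchor is rejected, with the nearest achievable Tm
reported. The published wheat panel contains one 16-mer, so the length
floor is 16 rather than the more common 17.

## Candidate quality filters

GC fraction in [0.30, 0.70]; no single-base run longer than 5; no perfect
antiparallel self-complementary stretch of 8+ bp (primer-dimer seed); and
the 3′-terminal pentamer may pair with the primer itself over at most 4
bases, i.e. only a fully self-complementary 3′ pentamer rejects. The
pentamer threshold is deliberately permissive: several bench-validated
primers of the published wheat panel carry a 4-base 3′ self-overlap, so a
stricter default would reject working assays. All thresholds are
config-exposed; every rejection carries a machine-readable reason.

## In-silico PCR model

Binding sites are all gapless alignments of a primer to either template
strand with at most `max_mismatches` (default 3) mismatches, recorded
with mismatch positions indexed from the 3′ end (1 = terminal). Extension
classes:

* `NONE` — mismatch at position 1, a gap within the 3′ hexamer, or more
  than 3 total mismatches;
* `WEAK` — 3′ terminus matched but a mismatch at positions 2–5;
* `STRONG` — all mismatches at positions ≥6.

The two empirical calibration points are: a single off-target mismatch at
position 5 from the 3′ end still yields a faint mismatch-primed product,
while the same polymorphism placed at the 3′-terminal base abolishes
amplification. The 2–5 window and the 3-mismatch cap generalize those two
observations in line with polymerase-extension biochemistry; both are
config-exposed because only the two endpoints are empirically pinned.

Products form between a +-strand hit and a −-strand hit facing each
other, sized 5′ end to 5′ end inclusive, capped at 3000 bp; the product
class is the weaker primer's class. A pair is **genome-specific** iff it
yields exactly one STRONG product on its target and no STRONG or WEAK
product on any off-target — a WEAK off-target product is disqualifying,
because a faint wrong-genome band already ruins a presence/absence assay.
Binding is gapless (no bulged duplexes): indel discrimination is captured
anyway, because a deletion in the off-target destroys or displaces the
binding site. This is the model's main simplification.

## Pairing and tiling

All forward×reverse combinations on the same genome are screened. The
target size band is 800–1500 bp (single-pass Sanger from both ends) with
a soft margin of 300 bp: sizes inside [500, 1800] are admitted with a
linear penalty outside the band, because bench-validated assays slightly
outside the band exist and hard rejection would lose them; `hard_size_band`
restores strict behavior. Each specific pair gets a *specificity margin*:
for every off-target, each primer's best (fewest-mismatch) binding site
is found and the better-blocked primer of the two taken (both primers are
needed for a product); the margin is the minimum over off-targets, with
absent sites counted as max_mismatches+1. Binding-site scans are cached
per primer/template, so enumeration is linear in candidates, not pairs.

The tiler selects a subset of pairs maximizing, lexicographically:
(1) union of amplicon intervals, (2) fewer pairs, (3) total margin minus
size- and overlap-band penalties (neighbor overlaps outside 80–100 bp are
penalized, not forbidden). Because amplicons are intervals, the only
state the future of a left-to-right scan needs is the rightmost covered
position; the dynamic program keeps the best value per distinct "reach"
and is exact — tests verify it against exhaustive subset enumeration.
Coverage is reported as union length divided by the *full* genomic
length, which is the convention under which the published panel's
per-gene percentages are reproducible.

Anchor sites closer than 30 alignment columns are thinned to one before
candidate enumeration (`min_anchor_spacing`): adjacent anchors yield
near-identical primers and only inflate the pair search. On default
simulations (~4 kb genes) the full pipeline runs in a few seconds.

## Null-allele genotyping

A diagnostic panel maps loci to genome-specific pairs. A locus is
*present* iff the pair yields ≥1 STRONG in-silico product on the allele
sequence — WEAK does not count, matching how faint mismatch products are
scored as absent on diagnostic gels. Panels are validated against
wild-type references (every entry must amplify its own reference). The
three-locus +/- pattern maps to type codes 1 (wild type), 2–4 (single
nulls in locus order), 7 (first+second double null), 8 (triple null);
codes 5 ((+,−,−)) and 6 ((−,+,−)) complete the scheme by analogy — they
are our inference, as the classic line set contains no such lines — and
non-three-locus panels fall back to locus-wise calls with code "other".
A whole-locus deletion is represented by an empty-sequence sentinel
allele, the one permitted exception to the nonempty-sequence invariant.

## Synthetic families

The simulator draws an ancestral gene (default 8 exons of 150–300 bp,
introns of 100–600 bp, so ~3–6 kb — a compact cereal-gene geometry),
then mutates each of 3 copies independently. Divergence parameters are
*expected pairwise* substitution fractions; each copy receives half the
rate relative to the ancestor, so defaults of 0.03 (exon) and 0.25
(intron) land realized pairwise identities near 97% and 75–78%, inside
the empirically observed homoeolog bands. Substitutions are uniform over
the three alternative bases (identity percentages, not spectra, are the
constraint being matched). Indels (0.02 events per intron bp, lengths
1–30) are confined to intron interiors, which keeps exon structure
projectable onto every copy and mirrors where usable indels occur in real
homoeologs. Because copies are threaded through ancestor coordinates, the
true alignment and all fully discriminative columns are returned as
ground truth; site discovery is tested to recover ≥95% of them.

What the simulator does *not* emulate: transition/transversion bias,
rate heterogeneity along introns, exonic indels, paralogs elsewhere in
the genome, and sequencing error. Passing tests therefore demonstrate
correctness of the algorithms under the stated divergence structure, not
performance on arbitrary real genomes — in particular there is no
genome-wide off-target background, so real designs should still be
screened against a genome assembly when one exists.

## Reference inputs and degenerate cases

The published wheat Wx/SSII primer panel, its reported product sizes and
coverage percentages, and the ten-line genotype reference table are
bundled as data (`wheat_panel.py`). The six GenBank genomic sequences are
not redistributed; `scripts/fetch_reference.py` downloads them once into
`tests/data/genbank/`, enabling the reference-based acceptance tests
(product sizes, coverage, size ranges, gene lengths). Without network
access those tests fail with an explanatory message rather than being
skipped.

Degenerate inputs behave conservatively: identical copies produce zero
sites, zero candidates and an empty design (exit 0 with a warning, not an
error); an empty pair list tiles to coverage 0; ambiguous bases are
rejected at Tm computation and never appear in emitted primers.
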