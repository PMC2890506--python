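"""Mismatch-position-aware in-silico PCR.

The central empirical fact this model encodes: a primer whose 3'-terminal
base mismatches the template is not extended by Taq (no product), while a
single mismatch a few bases in from the 3' end (positions 2-5) still
permits weak mismatch-primed amplification — e.g. a reverse primer with one
T/C mismatch at the fifth position from the 3' end produces a faint
off-target band, whereas moving the anchor so the mismatch sits at the
3'-terminal base abolishes it.  Binding sites are therefore classified

* ``NONE``   — 3'-terminal mismatch, a gap inside the 3' hexamer, or more
  than ``max_mismatches`` total mismatches;
* ``WEAK``   — 3' terminus matches but some mismatch lies at positions 2-5
  from the 3' end;
* ``STRONG`` — all mismatches (if any) at positions >= 6.

A primer pair is genome-specific iff it yields exactly one STRONG product
on its target and no STRONG or WEAK product on any off-target homoeolog
(a WEAK off-target product disqualifies the pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NONE = "NONE"
WEAK = "WEAK"
STRONG = "STRONG"
_CLASS_ORDER = {NONE: 0, WEAK: 1, STRONG: 2}

#: mismatches at positions 2..WEAK_WINDOW from the 3' end downgrade to WEAK
WEAK_WINDOW = 5


@dataclass
class InsilicoParams:
    """Binding/extension model parameters."""

    max_mismatches: int = 3
    weak_window: int = WEAK_WINDOW
    max_product_bp: int = 3000


@dataclass
class DuplexProfile:
    """One gapless primer/template duplex.

    ``template_interval`` is the 0-based half-open footprint on the + strand
    of the template; ``strand`` is the strand the primer anneals to (a
    ``+``-strand hit extends rightward, a ``-``-strand hit leftward).
    Mismatch positions are 1-based from the primer's 3' end (1 = terminal).
    """

    template_interval: tuple[int, int]
    strand: str
    mismatch_positions_from_3prime: list[int] = field(default_factory=list)
    gap_in_3prime_hexamer: bool = False

    @property
    def total_mismatches(self) -> int:
        return len(self.mismatch_positions_from_3prime)

    @property
    def five_prime_pos(self) -> int:
        """Template coordinate of the primer's 5'-terminal base."""
        s, e = self.template_interval
        return s if self.strand == "+" else e - 1

    @property
    def three_prime_pos(self) -> int:
        s, e = self.template_interval
        return e - 1 if self.strand == "+" else s


@dataclass
class PredictedAmplicon:
    """A predicted PCR product spanning the two primers' 5' ends."""

    template_id: str
    interval: tuple[int, int]  # 0-based half-open, fwd 5' end .. rev 5' end
    amp_class: str
    fwd_profile: DuplexProfile
    rev_profile: DuplexProfile

    @property
    def size_bp(self) -> int:
        return self.interval[1] - self.interval[0]


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def scan_binding_sites(
    primer: str,
    template: str,
    max_mismatches: int = 3,
) -> list[DuplexProfile]:
    """All gapless annealing sites of ``primer`` on either template strand.

    Every offset with at most ``max_mismatches`` mismatches is reported
    (overlapping hits included).  N in the template counts as a mismatch.
    Returns an empty list when the primer is longer than the template.
    """
    primer = primer.upper()
    template = template.upper()
    L, N = len(primer), len(template)
    if L == 0 or L > N:
        return []
    t = np.frombuffer(template.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(t, L)

    hits: list[DuplexProfile] = []
    for strand in "+-":
        if strand == "+":
            # primer anneals to - strand, reads along + strand left->right
            p = np.frombuffer(primer.encode(), dtype="S1")
        else:
            p = np.frombuffer(_revcomp(primer).encode(), dtype="S1")
        mism = windows != p[None, :]
        counts = mism.sum(axis=1)
        for off in np.flatnonzero(counts <= max_mismatches):
            idx = np.flatnonzero(mism[off])
            if strand == "+":
                # window index i -> distance from 3' end = L - i
                positions = sorted(int(L - i) for i in idx)
            else:
                positions = sorted(int(i + 1) for i in idx)
            hits.append(
                DuplexProfile(
                    template_interval=(int(off), int(off) + L),
                    strand=strand,
                    mismatch_positions_from_3prime=positions,
                )
            )
    hits.sort(key=lambda h: (h.template_interval, h.strand))
    return hits


def classify_primer_binding(
    profile: DuplexProfile, params: InsilicoParams | None = None
) -> str:
    """STRONG / WEAK / NONE extension class of one primer binding site."""
    if params is None:
        params = InsilicoParams()
    if profile.gap_in_3prime_hexamer:
        return NONE
    if profile.total_mismatches > params.max_mismatches:
        return NONE
    pos = profile.mismatch_positions_from_3prime
    if 1 in pos:
        return NONE
    if any(2 <= p <= params.weak_window for p in pos):
        return WEAK
    return STRONG


def _pair_class(fwd_cls: str, rev_cls: str) -> str:
    return fwd_cls if _CLASS_ORDER[fwd_cls] <= _CLASS_ORDER[rev_cls] else rev_cls


def pair_amplicons_from_hits(
    template_id: str,
    fwd_hits: list[DuplexProfile],
    rev_hits: list[DuplexProfile],
    min_size: int,
    params: InsilicoParams,
    include_none: bool = False,
) -> list[PredictedAmplicon]:
    """Pair precomputed binding sites of the two primers into products.

    Used by :func:`insilico_pcr` and by the pair enumerator, which caches
    the per-primer scans so each primer/template pair is scanned once.
    """
    out: list[PredictedAmplicon] = []
    for a_hits, b_hits, a_is_fwd in ((fwd_hits, rev_hits, True), (rev_hits, fwd_hits, False)):
        for ha in a_hits:
            if ha.strand != "+":
                continue
            for hb in b_hits:
                if hb.strand != "-":
                    continue
                start = ha.five_prime_pos
                end = hb.five_prime_pos + 1
                size = end - start
                if size < min_size or size > params.max_product_bp:
                    continue
                # primers must not run past each other
                if ha.three_prime_pos >= end or hb.three_prime_pos < start:
                    continue
                fwd_p, rev_p = (ha, hb) if a_is_fwd else (hb, ha)
                cls = _pair_class(
                    classify_primer_binding(fwd_p, params),
                    classify_primer_binding(rev_p, params),
                )
                if cls == NONE and not include_none:
                    continue
                out.append(
                    PredictedAmplicon(
                        template_id=template_id,
                        interval=(start, end),
                        amp_class=cls,
                        fwd_profile=fwd_p,
                        rev_profile=rev_p,
                    )
                )
    # deduplicate identical products found via both orientations (palindromic
    # corner cases) while keeping deterministic order
    seen = set()
    uniq = []
    for amp in sorted(out, key=lambda a: (a.template_id, a.interval)):
        key = (amp.template_id, amp.interval,
               amp.fwd_profile.template_interval, amp.rev_profile.template_interval)
        if key not in seen:
            seen.add(key)
            uniq.append(amp)
    return uniq


def insilico_pcr(
    fwd: str,
    rev: str,
    templates: dict[str, str],
    params: InsilicoParams | None = None,
    include_none: bool = False,
) -> list[PredictedAmplicon]:
    """Predicted products of a primer pair on each template.

    A product forms when one primer binds the + strand and the other the
    - strand, pointing toward each other, with the product (5' end to 5'
    end inclusive) no longer than ``max_product_bp``.  The product class is
    the weaker of the two primers' classes; class-NONE products are
    suppressed unless ``include_none``.
    """
    if params is None:
        params = InsilicoParams()
    out: list[PredictedAmplicon] = []
    for tid, template in templates.items():
        fwd_hits = scan_binding_sites(fwd, template, params.max_mismatches)
        rev_hits = scan_binding_sites(rev, template, params.max_mismatches)
        out.extend(
            pair_amplicons_from_hits(
                tid, fwd_hits, rev_hits, max(len(fwd), len(rev)), params, include_none
            )
        )
    return out


@dataclass
class SpecificityReport:
    """Outcome of the genome-specificity check for one primer pair."""

    specific: bool
    target_amplicons: list[PredictedAmplicon]
    offtarget_amplicons: dict[str, list[PredictedAmplicon]]

    @property
    def reasons(self) -> list[str]:
        msgs = []
        n_strong = sum(a.amp_class == STRONG for a in self.target_amplicons)
        if n_strong == 0:
            msgs.append("no_strong_target_product")
        elif n_strong > 1:
            msgs.append("multiple_target_products")
        for tid, amps in self.offtarget_amplicons.items():
            for a in amps:
                msgs.append(f"offtarget_{a.amp_class.lower()}_product:{tid}:{a.size_bp}bp")
        return msgs


def is_genome_specific(
    fwd: str,
    rev: str,
    target_template: tuple[str, str],
    offtarget_templates: dict[str, str],
    params: InsilicoParams | None = None,
) -> SpecificityReport:
    """True iff exactly one STRONG target product and no off-target product.

    ``target_template`` is (id, sequence).  Off-target WEAK products count
    against specificity: mismatch-primed amplification shows up as a faint
    band on a gel, which already defeats the purpose of a genome-specific
    assay.
    """
    if params is None:
        params = InsilicoParams()
    tid, tseq = target_template
    on_target = insilico_pcr(fwd, rev, {tid: tseq}, params)
    off: dict[str, list[PredictedAmplicon]] = {}
    for oid, oseq in offtarget_templates.items():
        amps = [
            a
            for a in insilico_pcr(fwd, rev, {oid: oseq}, params)
            if a.amp_class in (STRONG, WEAK)
        ]
        if amps:
            off[oid] = amps
    n_strong = sum(a.amp_class == STRONG for a in on_target)
    return SpecificityReport(
        specific=(n_strong == 1 and not off),
        target_amplicons=on_target,
        offtarget_amplicons=off,
    )
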