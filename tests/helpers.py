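"""Independent oracles shared by the test suite.

Each oracle re-derives an expected value by a route independent of the
implementation it checks: the NN melting temperature from the published
unified parameter table, binding sites by brute force over all offsets and
strands, interval unions by per-base bitmaps, and amplicon pairing by
direct enumeration.
"""

from __future__ import annotations

import math

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# unified nearest-neighbor table (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "TT": (-7.9, -22.2), "TG": (-8.5, -22.7), "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0), "TC": (-8.2, -22.2), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def nn_tm_oracle(seq: str, na_mM: float, duplex_nM: float) -> float:
    """Unified-table NN Tm with monovalent salt-entropy correction.

    ``duplex_nM`` is the effective annealing concentration (CT/4 for a
    non-self-complementary primer in excess).
    """
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    if seq == revcomp(seq):
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + 1.987 * math.log(duplex_nM * 1e-9)) - 273.15


# ---------------------------------------------------------------------------
def brute_force_binding_sites(primer: str, template: str, max_mm: int):
    """All (start, end, strand, mismatch-positions-from-3') by direct scan."""
    out = []
    L = len(primer)
    for strand in "+-":
        probe = primer if strand == "+" else revcomp(primer)
        for off in range(len(template) - L + 1):
            window = template[off : off + L]
            mm = []
            for i, (a, b) in enumerate(zip(probe, window)):
                if a != b:
                    mm.append(L - i if strand == "+" else i + 1)
            if len(mm) <= max_mm:
                out.append((off, off + L, strand, sorted(mm)))
    return sorted(out)


def bitmap_union(intervals, length: int) -> int:
    """Per-base union size of 0-based half-open intervals."""
    hit = bytearray(length)
    for s, e in intervals:
        for p in range(max(0, s), min(length, e)):
            hit[p] = 1
    return sum(hit)


def classify_oracle(mismatch_positions, gap_in_hexamer=False, max_mm=3, weak_window=5):
    """Rule-table classification, written out independently."""
    if gap_in_hexamer or len(mismatch_positions) > max_mm:
        return "NONE"
    if any(p == 1 for p in mismatch_positions):
        return "NONE"
    if any(2 <= p <= weak_window for p in mismatch_positions):
        return "WEAK"
    return "STRONG"


def brute_force_amplicons(fwd: str, rev: str, template: str, max_mm=3, max_product=3000):
    """All (start, end, class) products by direct enumeration of hit pairs."""
    order = {"NONE": 0, "WEAK": 1, "STRONG": 2}
    products = set()
    fh = brute_force_binding_sites(fwd, template, max_mm)
    rh = brute_force_binding_sites(rev, template, max_mm)
    min_size = max(len(fwd), len(rev))
    for ha, hb, a_is_fwd in [(a, b, True) for a in fh for b in rh] + [
        (a, b, False) for a in rh for b in fh
    ]:
        s1, e1, st1, mm1 = ha
        s2, e2, st2, mm2 = hb
        if st1 != "+" or st2 != "-":
            continue
        start, end = s1, e2
        size = end - start
        if size < min_size or size > max_product:
            continue
        if e1 - 1 >= end or s2 < start:
            continue
        c1 = classify_oracle(mm1, max_mm=max_mm)
        c2 = classify_oracle(mm2, max_mm=max_mm)
        cls = c1 if order[c1] <= order[c2] else c2
        if cls != "NONE":
            products.add((start, end, cls))
    return sorted(products)


def specificity_oracle(fwd, rev, target_seq, offtarget_seqs, max_mm=3, max_product=3000):
    """Direct re-derivation of the genome-specificity verdict."""
    on = brute_force_amplicons(fwd, rev, target_seq, max_mm, max_product)
    n_strong = sum(1 for *_, c in on if c == "STRONG")
    if n_strong != 1:
        return False
    for oseq in offtarget_seqs:
        if brute_force_amplicons(fwd, rev, oseq, max_mm, max_product):
            return False
    return True
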