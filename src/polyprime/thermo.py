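"""Melting temperature and 5'-end Tm adjustment.

Tm uses nearest-neighbor thermodynamics (unified parameter set) with a
monovalent-equivalent salt correction: divalent cations in excess of dNTPs
contribute ``120 * sqrt([Mg2+] - [dNTP])`` mM of equivalent monovalent salt
(von Ahsen's approximation, the convention PCR primer-design tools use).
Primer concentration enters as CT/4 (primers in excess, non-self-
complementary duplex).

A candidate's 3' end is fixed by its anchor site, so the only way to move
its Tm into the target window is to grow or trim the 5' end:
:func:`adjust_tm_by_5prime` returns the shortest primer in the length
window whose Tm lands in [tm_min, tm_max].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

MIN_PRIMER_LEN = 8


@dataclass
class ThermoParams:
    """Reaction conditions and the target Tm window.

    Defaults follow a standard Taq buffer (50 mM KCl, 1.5 mM MgCl2,
    0.2 mM each dNTP, 0.6 uM each primer) with a 59-61 degC Tm window and
    annealing at 60 degC.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.2
    primer_uM: float = 0.6
    tm_min_C: float = 59.0
    tm_max_C: float = 61.0
    annealing_C: float = 60.0

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "primer_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.tm_min_C < self.tm_max_C:
            raise ValueError("tm_min_C must be < tm_max_C")

    @property
    def monovalent_equivalent_mM(self) -> float:
        """Monovalent-equivalent salt: mono + 120*sqrt(max(Mg - dNTP, 0))."""
        free_mg = max(self.divalent_mM - self.dntp_mM, 0.0)
        return self.monovalent_mM + 120.0 * math.sqrt(free_mg)


def melting_temperature(primer_seq: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor Tm (degC) of a primer under the given conditions.

    Rejects primers shorter than 8 nt or containing ambiguous bases.
    """
    if params is None:
        params = ThermoParams()
    seq = str(primer_seq).upper()
    if len(seq) < MIN_PRIMER_LEN:
        raise ValueError(f"primer too short for NN Tm: {len(seq)} < {MIN_PRIMER_LEN}")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in primer: {primer_seq}")
    # CT/4: dnac1 = dnac2 = CT/2 nM makes Biopython's duplex term CT/4
    half_ct_nM = params.primer_uM * 1000.0 / 2.0
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=params.monovalent_equivalent_mM,
            K=0,
            Tris=0,
            Mg=0,
            dNTPs=0,
            saltcorr=5,
            dnac1=half_ct_nM,
            dnac2=half_ct_nM,
        )
    )


@dataclass
class TmRejection:
    """Returned when no length in the window reaches the Tm band."""

    reason: str
    nearest_tm_C: float | None
    nearest_length: int | None


def adjust_tm_by_5prime(
    anchor_pos: int,
    orientation: str,
    template: str,
    params: ThermoParams | None = None,
    len_min: int = 16,
    len_max: int = 25,
) -> str | TmRejection:
    """Shortest primer with its 3' end fixed at ``anchor_pos`` and Tm in window.

    ``anchor_pos`` is the 0-based template position of the primer's
    3'-terminal base.  A ``forward`` primer is the template substring ending
    at the anchor; a ``reverse`` primer is the reverse complement of the
    substring starting at the anchor.  Lengths are tried from ``len_min``
    upward; the first (shortest) length whose Tm falls in
    [tm_min, tm_max] wins, which makes the result deterministic.  If no
    length fits, a :class:`TmRejection` records the nearest achievable Tm.
    """
    if params is None:
        params = ThermoParams()
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse, got {orientation!r}")
    template = template.upper()
    if not 0 <= anchor_pos < len(template):
        raise ValueError("anchor_pos outside template")

    best_tm, best_len = None, None
    for length in range(len_min, len_max + 1):
        if orientation == "forward":
            start = anchor_pos - length + 1
            if start < 0:
                continue
            seq = template[start : anchor_pos + 1]
        else:
            end = anchor_pos + length
            if end > len(template):
                continue
            seq = str(Seq(template[anchor_pos:end]).reverse_complement())
        if "N" in seq:
            continue
        tm = melting_temperature(seq, params)
        if params.tm_min_C <= tm <= params.tm_max_C:
            return seq
        mid = (params.tm_min_C + params.tm_max_C) / 2.0
        if best_tm is None or abs(tm - mid) < abs(best_tm - mid):
            best_tm, best_len = tm, length
    if best_tm is None:
        return TmRejection("no_valid_length_in_template", None, None)
    return TmRejection("tm_window_unreachable", round(best_tm, 2), best_len)
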