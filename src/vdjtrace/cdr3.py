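"""CDR3 delimitation and productivity classification.

The CDR3 of a rearranged immunoglobulin chain spans the conserved V-region
cysteine codon through the conserved J-region tryptophan (IGH) or
phenylalanine (IGK) codon, inclusive. A rearrangement is productive when
both anchors are present, the CDR3 nucleotide length is a multiple of three
(the V and J reading frames are preserved across the junction) and no stop
codon interrupts the translated V-through-J region.

Failure reasons follow the precedence missing_anchor > out_of_frame >
stop_codon: the first rule that fails is recorded.
"""

from __future__ import annotations

from typing import NamedTuple

from Bio.Seq import Seq

from .germline import ANCHOR_RESIDUE

FAILURE_NONE = "none"
FAILURE_MISSING_ANCHOR = "missing_anchor"
FAILURE_OUT_OF_FRAME = "out_of_frame"
FAILURE_STOP_CODON = "stop_codon"


# standard-code codon table, materialized once (hot path in simulation)
_CODON = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
}


def translate_nt(nt: str) -> str:
    """Standard-code translation; trailing partial codon ignored."""
    usable = len(nt) - len(nt) % 3
    return "".join(_CODON[nt[i : i + 3]] for i in range(0, usable, 3))


class ProductivityCall(NamedTuple):
    productive: bool
    failure_reason: str
    cdr3_nt: str | None
    cdr3_aa: str | None


def classify_productivity(
    sequence_nt: str,
    chain: str,
    v_anchor_pos: int | None,
    j_anchor_pos: int | None,
    j_end: int | None = None,
) -> ProductivityCall:
    """Classify a rearranged sequence given anchor codon positions.

    ``v_anchor_pos``/``j_anchor_pos`` are 0-based offsets of the conserved
    V-Cys / J-Trp(Phe) codons in ``sequence_nt`` (``None`` when the anchor
    could not be located). ``j_end`` bounds the stop-codon scan (end of the
    J segment); defaults to the sequence end.
    """
    if (
        v_anchor_pos is None
        or j_anchor_pos is None
        or v_anchor_pos < 0
        or j_anchor_pos + 3 > len(sequence_nt)
        or j_anchor_pos < v_anchor_pos
    ):
        return ProductivityCall(False, FAILURE_MISSING_ANCHOR, None, None)

    v_codon = sequence_nt[v_anchor_pos : v_anchor_pos + 3]
    j_codon = sequence_nt[j_anchor_pos : j_anchor_pos + 3]
    if translate_nt(v_codon) != ANCHOR_RESIDUE[(chain, "V")] or translate_nt(
        j_codon
    ) != ANCHOR_RESIDUE[(chain, "J")]:
        return ProductivityCall(False, FAILURE_MISSING_ANCHOR, None, None)

    cdr3_nt = sequence_nt[v_anchor_pos : j_anchor_pos + 3]
    if len(cdr3_nt) % 3 != 0:
        return ProductivityCall(False, FAILURE_OUT_OF_FRAME, cdr3_nt, None)

    # stop-codon scan over the V-through-J region in the anchor frame
    if j_end is None:
        j_end = len(sequence_nt)
    frame_start = v_anchor_pos % 3
    region = sequence_nt[frame_start : frame_start + 3 * ((j_end - frame_start) // 3)]
    if "*" in translate_nt(region):
        return ProductivityCall(False, FAILURE_STOP_CODON, cdr3_nt, None)

    return ProductivityCall(True, FAILURE_NONE, cdr3_nt, translate_nt(cdr3_nt))
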