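"""Calling path: consensus, CDR3 extraction, productivity, clonotyping."""

import numpy as np
import pytest

from vdjtrace.caller import (
    CallerParams,
    ChainCall,
    build_consensus,
    call_sample,
    extract_cdr3,
    group_clonotypes,
)
from vdjtrace.cdr3 import (
    FAILURE_MISSING_ANCHOR,
    FAILURE_NONE,
    FAILURE_OUT_OF_FRAME,
    FAILURE_STOP_CODON,
    classify_productivity,
)
from vdjtrace.sim import FastqRead, SimConfig, simulate_reads

# minimal reverse codon choices for engineering CDR3s in fixtures
_AA2CODON = {
    "A": "GCT", "R": "CGT", "T": "ACT", "N": "AAT", "W": "TGG", "P": "CCT",
    "Y": "TAT", "F": "TTT", "D": "GAT", "H": "CAT", "C": "TGT",
}


def encode_aa(aa: str) -> str:
    return "".join(_AA2CODON[a] for a in aa)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def _reads(barcode, umi, seqs):
    return [FastqRead(f"{barcode}:{umi}:{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


def test_identical_reads_collapse_to_themselves(db):
    seq = db.get("IGHV1-18").sequence_nt
    res = build_consensus(_reads("B" * 16, "U" * 10, [seq] * 3), db, CallerParams(min_umis=1))
    assert len(res.chains) == 1
    assert res.chains[0].consensus_nt == seq
    assert res.chains[0].read_count == 3


def test_plurality_vote_corrects_a_single_read_error(db):
    seq = db.get("IGHV1-18").sequence_nt
    bad = "A" + seq[1:] if seq[0] != "A" else "C" + seq[1:]
    res = build_consensus(_reads("B" * 16, "U" * 10, [seq, bad, seq]), db, CallerParams(min_umis=1))
    assert res.chains[0].consensus_nt == seq


def test_single_umi_barcode_dropped_and_logged(db):
    seq = db.get("IGKV1-33").sequence_nt
    res = build_consensus(_reads("B" * 16, "U" * 10, [seq] * 3), db, CallerParams(min_umis=2))
    assert res.chains == []
    assert res.dropped == [("B" * 16, "IGK", 1)]


# ---------------------------------------------------------------------------
# CDR3 extraction and productivity
# ---------------------------------------------------------------------------


def _build_rearranged(db, cdr3_interior_aa):
    """V through its Cys codon + engineered interior + J from its anchor on."""
    v, j = db.get("IGHV1-18"), db.get("IGHJ4")
    return (
        v.sequence_nt[: v.anchor_index + 3]
        + encode_aa(cdr3_interior_aa)
        + j.sequence_nt[j.anchor_index :]
    )


def test_engineered_cdr3_recovered_exactly(db):
    """The published shared-clonotype CDR3 is recovered verbatim."""
    seq = _build_rearranged(db, "ARTNWPYYFDH")
    call = extract_cdr3(seq, "IGHV1-18", "IGHJ4", db)
    assert call.productive
    assert call.cdr3_aa == "CARTNWPYYFDHW"


def test_minimal_cdr3_is_cw(db):
    seq = _build_rearranged(db, "")
    call = extract_cdr3(seq, "IGHV1-18", "IGHJ4", db)
    assert call.cdr3_aa == "CW"


def test_simulated_productive_cdr3s_have_conserved_boundaries(db, small_sample):
    truth = small_sample["truth"]
    prod = truth[truth.productive]
    from vdjtrace.cdr3 import translate_nt

    for _, row in prod.iterrows():
        aa = translate_nt(row.cdr3_nt)
        assert aa.startswith("C")
        assert aa.endswith("W" if row.chain == "IGH" else "F")


def test_productivity_rules_and_precedence(db):
    v, j = db.get("IGHV1-18"), db.get("IGHJ4")
    ok = _build_rearranged(db, "ARY")
    va = v.anchor_index
    ja = va + 3 + 9  # after 3-codon interior
    jend = ja + (len(j.sequence_nt) - j.anchor_index)
    assert classify_productivity(ok, "IGH", va, ja, jend) == (True, FAILURE_NONE, ok[va : ja + 3], "CARYW")

    # single-nucleotide insert in the junction: frameshift
    shifted = ok[: va + 3] + "G" + ok[va + 3 :]
    res = classify_productivity(shifted, "IGH", va, ja + 1, jend + 1)
    assert (res.productive, res.failure_reason) == (False, FAILURE_OUT_OF_FRAME)

    # in-frame TAA inside the junction
    stopped = ok[: va + 3] + "TAA" + ok[va + 6 :]
    res = classify_productivity(stopped, "IGH", va, ja, jend)
    assert (res.productive, res.failure_reason) == (False, FAILURE_STOP_CODON)

    # missing anchor wins over everything
    res = classify_productivity(stopped, "IGH", None, ja, jend)
    assert (res.productive, res.failure_reason) == (False, FAILURE_MISSING_ANCHOR)

    # a mutated anchor codon is a missing anchor
    broken = "AAA" + ok[3:]
    res = classify_productivity(broken, "IGH", 0, ja, jend)
    assert res.failure_reason == FAILURE_MISSING_ANCHOR


# ---------------------------------------------------------------------------
# clonotype grouping
# ---------------------------------------------------------------------------


def _chain_call(barcode, chain, cdr3_nt, productive=True):
    return ChainCall(
        barcode=barcode, chain=chain, consensus_nt="ACGT", v_call="V", j_call="J",
        v_score=0, j_score=0, v_margin=99, ambiguous_v=False,
        cdr3_nt=cdr3_nt, cdr3_aa=None, productive=productive,
        failure_reason=FAILURE_NONE if productive else FAILURE_STOP_CODON,
        umi_count=2, read_count=6,
    )


def test_grouping_counts_and_frequencies():
    calls = [
        _chain_call("b1", "IGH", "TGTTGG"),
        _chain_call("b2", "IGH", "TGTTGG"),
        _chain_call("b3", "IGH", "TGTTGG"),
        _chain_call("b4", "IGH", "TGTAAATGG"),
    ]
    res = group_clonotypes(calls)
    assert [ct.n_cells for ct in res.clonotypes] == [3, 1]
    assert res.frequency_pct(res.clonotypes[0]) == 75.0
    assert res.frequency_pct(res.clonotypes[1]) == 25.0
    assert abs(sum(res.frequency_pct(ct) for ct in res.clonotypes) - 100.0) < 1e-9


def test_light_chain_only_clonotype_and_unproductive_exclusion():
    calls = [
        _chain_call("b1", "IGK", "TGTTTT"),
        _chain_call("b1", "IGH", "TGTTGG", productive=False),
        _chain_call("b2", "IGK", "TGTTTT"),
        _chain_call("b3", "IGH", "TGTCCC", productive=False),  # zero productive chains
    ]
    res = group_clonotypes(calls)
    assert res.n_cells == 2
    assert res.unproductive_barcodes == ["b3"]
    assert res.clonotypes[0].chain_keys == frozenset({("IGK", "TGTTTT")})


def test_empty_input_yields_empty_result():
    res = group_clonotypes([])
    assert res.clonotypes == []
    assert res.n_cells == 0


# ---------------------------------------------------------------------------
# end-to-end invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fraction", [0.5, 0.8, 0.99])
def test_clonal_fraction_recovery(db, fraction):
    """Dominant clonotype frequency within 3 percentage points of the
    simulated clonal fraction, CDR3 exactly equal to truth (n=500 cells)."""
    cfg = SimConfig(n_cells=500, clonal_fraction=fraction, seed=int(fraction * 1000))
    _, truth, reads = simulate_reads(db, cfg)
    _, clonos, _ = call_sample(reads, db)
    dom = clonos.clonotypes[0]
    freq = clonos.frequency_pct(dom)
    assert abs(freq - 100 * fraction) <= 3.0
    clonal = truth[(truth.clonotype_label == "clone") & (truth.chain == "IGH")]
    assert ("IGH", clonal.cdr3_nt.iloc[0]) in dom.chain_keys


def test_consensus_matches_truth_for_nearly_all_barcodes(db):
    """At 1% read error with 4 UMIs x 3 reads, >= 99% of barcode-chains
    reconstruct the exact simulated sequence."""
    cfg = SimConfig(n_cells=200, clonal_fraction=0.5, seed=17, seq_error_rate=0.01)
    cells, _, reads = simulate_reads(db, cfg)
    res = build_consensus(reads, db)
    true_seq = {
        (c.barcode, r.chain): r.sequence_nt
        for c in cells
        for _, r in c.rearrangements()
    }
    hits = sum(
        rec.consensus_nt == true_seq.get((rec.barcode, rec.chain)) for rec in res.chains
    )
    assert len(res.chains) >= 390  # nearly all 400 barcode-chains survive
    assert hits / len(res.chains) >= 0.99
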