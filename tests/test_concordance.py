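"""RNA/DNA concordance: matching, correlation, Venn, discordance attribution."""

import numpy as np
import pytest

from vdjtrace.caller import call_bulk_amplicons, call_sample
from vdjtrace.clonality import dominant_clonotype
from vdjtrace.concordance import (
    REASON_LIGHT_ONLY,
    REASON_NMD,
    REASON_PRIMER,
    REASON_UNKNOWN,
    ConcordanceError,
    MethodCall,
    attribute_discordance,
    cohort_concordance,
    fraction_correlation,
    match_clonotypes,
    table1_method_calls,
    venn_counts,
)
from vdjtrace.sim import (
    SimConfig,
    emit_reads,
    simulate_bulk_amplicon,
    simulate_sample,
    transcribe_with_nmd,
)


def _pairs_by_sample():
    return {rna.sample_id: (rna, dna) for rna, dna in table1_method_calls()}


def test_cdr3_match_with_and_without_v_gene_agreement():
    pairs = _pairs_by_sample()
    rec10 = match_clonotypes(*pairs["PLC-10"])
    assert rec10.status == "match" and rec10.v_gene_agreement  # IGHV5-51 vs IGHV5-51*01

    rec01 = match_clonotypes(*pairs["PLC-01"])
    assert rec01.status == "match" and not rec01.v_gene_agreement  # IGHV3-48 vs IGHV3-30*09

    rna, _ = pairs["PLC-10"]
    identical = match_clonotypes(rna, MethodCall(
        sample_id=rna.sample_id, method="bulkDNA", chain="IGH", v_call=rna.v_call,
        j_call=rna.j_call, cdr3_aa=rna.cdr3_aa, proportion_pct=50.0, productive=True,
    ))
    assert identical.status == "match" and identical.v_gene_agreement


def test_missing_cdr3_on_both_sides_is_discordant_unknown():
    a = MethodCall("s", "scRNA", "IGH", "IGHV1-18", "IGHJ4", None, 90.0, True)
    b = MethodCall("s", "bulkDNA", "IGH", "IGHV1-18", "IGHJ4", None, 50.0, True)
    rec = match_clonotypes(a, b)
    assert rec.status == "discordant"
    assert rec.discordance_reasons == (REASON_UNKNOWN,)


def test_pearson_correlation_values():
    on_line = [(float(i), 2.0 * i + 1) for i in range(5)]
    _, r2, _ = fraction_correlation(on_line)
    assert abs(r2 - 1.0) < 1e-12

    _, r2, n = fraction_correlation([(1, 2), (2, 1), (3, 3)])
    assert abs(r2 - 0.25) < 1e-12
    assert n == 3

    with pytest.raises(ConcordanceError, match="3 pairs"):
        fraction_correlation([(1, 2), (2, 1)])
    with pytest.raises(ConcordanceError, match="zero variance"):
        fraction_correlation([(1, 2), (1, 3), (1, 4)])


def test_pearson_equals_sigma_formula_oracle():
    rng = np.random.default_rng(55)
    for _ in range(25):
        n = int(rng.integers(3, 30))
        x = rng.uniform(1, 100, n)
        y = rng.uniform(1, 100, n) + 0.3 * x
        r, r2, _ = fraction_correlation(list(zip(x, y)))
        sx, sy = x.sum(), y.sum()
        num = n * (x * y).sum() - sx * sy
        den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
        assert abs(r - num / den) < 1e-12


def test_venn_counts():
    records = [match_clonotypes(r, d) for r, d in table1_method_calls()]
    assert venn_counts(records) == (17, 2, 2)

    matches = [rec for rec in records if rec.status == "match"]
    assert venn_counts(matches) == (17, 0, 0)
    assert venn_counts([]) == (0, 0, 0)


def test_fixture_discordance_attribution():
    pairs = _pairs_by_sample()
    assert REASON_NMD in attribute_discordance(*pairs["PLC-14"])
    assert attribute_discordance(*pairs["PLC-16"]) == (REASON_LIGHT_ONLY,)


def test_simulated_biallelic_clone_yields_both_mechanisms(db, panel):
    """Full reconstruction of the double-discordance: RNA sees only the
    productive primer-killed allele, DNA only the stop-codon allele, and
    attribution returns both the NMD and the misannealing reason."""
    from vdjtrace.sim import make_plc14_like_sample

    cfg = SimConfig(n_cells=60, clonal_fraction=0.9, seed=2014)
    cells, truth = make_plc14_like_sample(db, cfg)
    reads = emit_reads(transcribe_with_nmd(cells, cfg), cfg)
    calls, clonos, _ = call_sample(reads, db)
    rep = dominant_clonotype(clonos, "plc14-like")
    dom = clonos.clonotypes[0]
    heavy = next(c for c in calls if c.barcode in dom.barcodes and c.chain == "IGH")
    assert heavy.productive

    bulk = call_bulk_amplicons(simulate_bulk_amplicon(cells, panel, cfg), db)
    dna_dom = bulk[0]
    assert not dna_dom.productive and dna_dom.failure_reason == "stop_codon"
    # each method's clonotype is exclusive to it
    assert all(b.cdr3_aa != heavy.cdr3_aa for b in bulk)

    rna_call = MethodCall("s", "scRNA", "IGH", heavy.v_call, heavy.j_call,
                          heavy.cdr3_aa, rep.dominant_frequency_pct, True)
    dna_call = MethodCall("s", "bulkDNA", "IGH", dna_dom.v_call, dna_dom.j_call,
                          dna_dom.cdr3_aa, dna_dom.proportion_pct, False,
                          dna_dom.failure_reason)
    assert match_clonotypes(rna_call, dna_call).status == "discordant"
    clonal_seq = next(c for c in cells if c.is_clonal).heavy.sequence_nt
    reasons = attribute_discordance(rna_call, dna_call, rna_sequence_nt=clonal_seq, panel=panel)
    assert set(reasons) == {REASON_NMD, REASON_PRIMER}


def test_simulated_light_chain_only_clone_detected(db, panel):
    """Dominant clonotype keyed on IGK alone when no productive IGH exists;
    attribution returns the light-chain-only reason."""
    from vdjtrace.sim import make_plc16_like_sample

    cfg = SimConfig(n_cells=60, clonal_fraction=0.9, seed=2016)
    cells, _ = make_plc16_like_sample(db, cfg)
    reads = emit_reads(transcribe_with_nmd(cells, cfg), cfg)
    calls, clonos, _ = call_sample(reads, db)
    dom = clonos.clonotypes[0]
    assert {c for c, _ in dom.chain_keys} == {"IGK"}
    light = next(c for c in calls if c.barcode in dom.barcodes and c.chain == "IGK")

    bulk = call_bulk_amplicons(simulate_bulk_amplicon(cells, panel, cfg), db)
    dna_dom = bulk[0]
    assert not dna_dom.productive

    rna_call = MethodCall("s", "scRNA", "IGK", light.v_call, light.j_call,
                          light.cdr3_aa, 90.0, True)
    dna_call = MethodCall("s", "bulkDNA", "IGH", dna_dom.v_call, dna_dom.j_call,
                          dna_dom.cdr3_aa, dna_dom.proportion_pct, False,
                          dna_dom.failure_reason)
    assert attribute_discordance(rna_call, dna_call) == (REASON_LIGHT_ONLY,)


def test_matched_pipelines_agree_without_engineered_mechanisms(db, panel):
    """With no primer-killing mutations and no unproductive-only clones, the
    RNA and DNA dominant clonotypes match exactly."""
    for seed in (1, 2, 3):
        cfg = SimConfig(n_cells=60, clonal_fraction=0.7, seed=seed)
        cells, _ = simulate_sample(db, cfg)
        reads = emit_reads(transcribe_with_nmd(cells, cfg), cfg)
        calls, clonos, _ = call_sample(reads, db)
        dom = clonos.clonotypes[0]
        heavy = next(c for c in calls if c.barcode in dom.barcodes and c.chain == "IGH")
        bulk = call_bulk_amplicons(simulate_bulk_amplicon(cells, panel, cfg), db)
        rna_call = MethodCall("s", "scRNA", "IGH", heavy.v_call, heavy.j_call,
                              heavy.cdr3_aa, 70.0, True)
        dna_call = MethodCall("s", "bulkDNA", "IGH", bulk[0].v_call, bulk[0].j_call,
                              bulk[0].cdr3_aa, bulk[0].proportion_pct, bulk[0].productive)
        assert match_clonotypes(rna_call, dna_call).status == "match"


def test_cohort_concordance_summary_structure():
    summary = cohort_concordance(table1_method_calls())
    assert summary["venn"] == dict(shared=17, rna_only=2, dna_only=2)
    assert summary["n_matched"] == 17
    reasons = {
        r.sample_id: r.discordance_reasons
        for r in summary["records"]
        if r.status == "discordant"
    }
    assert REASON_NMD in reasons["PLC-14"]
    assert reasons["PLC-16"] == (REASON_LIGHT_ONLY,)
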