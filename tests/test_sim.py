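"""Repertoire simulator: junction model, SHM, NMD, reads, bulk amplicons."""

import numpy as np
import pytest

from vdjtrace.cdr3 import FAILURE_OUT_OF_FRAME, FAILURE_STOP_CODON
from vdjtrace.sim import (
    SimConfig,
    SimulatedCell,
    apply_shm,
    emit_reads,
    make_plc14_like_sample,
    recombine,
    simulate_bulk_amplicon,
    simulate_reads,
    simulate_sample,
    transcribe_with_nmd,
)


def test_zero_trim_zero_insert_is_pure_concatenation(db):
    v, d, j = db.get("IGHV1-18"), db.get("IGHD3-9"), db.get("IGHJ4")
    rng = np.random.default_rng(0)
    r = recombine(v, j, rng, d=d, max_trim=0, max_insert=0)
    assert r.sequence_nt == v.sequence_nt + d.sequence_nt + j.sequence_nt
    assert r.v_end == len(v)
    assert r.d_start == len(v)
    assert r.d_end == len(v) + len(d)
    assert r.j_start == len(v) + len(d)


def test_recombination_is_deterministic_under_a_seed(db):
    v, d, j = db.get("IGHV3-23"), db.get("IGHD2-2"), db.get("IGHJ5")
    r1 = recombine(v, j, np.random.default_rng(5), d=d)
    r2 = recombine(v, j, np.random.default_rng(5), d=d)
    assert r1 == r2


def test_insert_lengths_follow_uniform_model(db):
    """n1 lengths over many draws: all in [0, max_insert], mean within 3
    standard errors of the uniform mean."""
    v, d, j = db.get("IGHV1-18"), db.get("IGHD3-3"), db.get("IGHJ6")
    rng = np.random.default_rng(11)
    lengths = [
        len(recombine(v, j, rng, d=d, max_trim=0, max_insert=6).n1_insert)
        for _ in range(1000)
    ]
    assert min(lengths) >= 0 and max(lengths) <= 6
    mean = np.mean(lengths)
    se = np.sqrt(np.var([0, 1, 2, 3, 4, 5, 6], ddof=0) / 1000)
    assert abs(mean - 3.0) < 3 * se


def test_junction_coordinates_reconstruct_sequence(db):
    """The trimmed germline pieces plus inserts tile the full sequence."""
    rng = np.random.default_rng(2)
    for _ in range(50):
        v, d, j = db.get("IGHV4-39"), db.get("IGHD3-9"), db.get("IGHJ4")
        r = recombine(v, j, rng, d=d)
        v_part = r.sequence_nt[: r.v_end]
        assert v.sequence_nt.startswith(v_part)
        assert r.sequence_nt[r.v_end : r.d_start] == r.n1_insert
        assert r.sequence_nt[r.d_end : r.j_start] == r.n2_insert
        assert j.sequence_nt.endswith(r.sequence_nt[r.j_start :])


def test_shm_zero_rate_is_identity(db):
    r = recombine(db.get("IGHV1-18"), db.get("IGHJ4"), np.random.default_rng(0), d=db.get("IGHD2-2"))
    m = apply_shm(r, 0.0, np.random.default_rng(1))
    assert m.sequence_nt == r.sequence_nt
    assert m.shm_positions == ()


def test_shm_mutation_count_matches_binomial_oracle(db):
    """500 replicates at rate 0.05 on a ~400-nt sequence: mean count within
    3 standard errors of length x rate."""
    r = recombine(db.get("IGHV1-18"), db.get("IGHJ4"), np.random.default_rng(0),
                  d=db.get("IGHD3-9"), max_trim=0, max_insert=0)
    L = len(r.sequence_nt)
    rng = np.random.default_rng(21)
    counts = [len(apply_shm(r, 0.05, rng).shm_positions) for _ in range(500)]
    expected = L * 0.05
    se = np.sqrt(L * 0.05 * 0.95 / 500)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_shm_never_reproduces_original_base_and_respects_protection(db):
    r = recombine(db.get("IGHV3-43"), db.get("IGHJ5"), np.random.default_rng(0), d=db.get("IGHD3-3"))
    rng = np.random.default_rng(8)
    protected = frozenset(range(0, 50))
    m = apply_shm(r, 0.1, rng, protected=protected)
    for p in m.shm_positions:
        assert m.sequence_nt[p] != r.sequence_nt[p]
        assert p not in protected


def test_sample_structure_and_determinism(db):
    cfg = SimConfig(n_cells=100, clonal_fraction=0.8, seed=77)
    cells, truth = simulate_sample(db, cfg)
    labels = [c.clonotype_label for c in cells]
    assert labels.count("clone") == 80
    assert len({c.barcode for c in cells}) == 100
    # same seed twice -> identical truth
    _, truth2 = simulate_sample(db, cfg)
    assert truth.equals(truth2)
    # clonal heavy guaranteed productive, shared CDR3 nucleotides
    clonal = truth[(truth.clonotype_label == "clone") & (truth.chain == "IGH")]
    assert clonal.productive.all()
    assert clonal.cdr3_nt.nunique() == 1


def test_fully_polyclonal_sample_has_distinct_labels(db):
    cfg = SimConfig(n_cells=50, clonal_fraction=0.0, seed=5)
    cells, _ = simulate_sample(db, cfg)
    labels = [c.clonotype_label for c in cells]
    assert len(set(labels)) == len(labels)


def test_sub_single_cell_clonal_fraction_warns(db):
    cfg = SimConfig(n_cells=100, clonal_fraction=0.004, seed=5)
    with pytest.warns(UserWarning, match="no clonal cells"):
        cells, _ = simulate_sample(db, cfg)
    assert not any(c.is_clonal for c in cells)


def test_nmd_drops_stop_codon_transcripts_only(db):
    cfg = SimConfig(n_cells=10, clonal_fraction=1.0, seed=3)
    cells, _ = make_plc14_like_sample(db, cfg)
    cell = cells[0]
    assert cell.second_heavy_allele.failure_reason == FAILURE_STOP_CODON
    transcripts = transcribe_with_nmd(cells, cfg)
    alleles = {t.allele for t in transcripts if t.barcode == cell.barcode}
    assert alleles == {"heavy", "light"}  # the stop-codon allele is silenced

    # a cell carrying only a stop-codon rearrangement yields zero transcripts
    lone = SimulatedCell(
        barcode="A" * 16, clonotype_label="x", heavy=cell.second_heavy_allele,
        light=None, second_heavy_allele=None, is_clonal=False,
    )
    assert transcribe_with_nmd([lone], cfg) == []

    # probabilistic mode with p_nmd=0: everything survives
    import dataclasses
    cfg0 = dataclasses.replace(cfg, nmd_mode="probabilistic", p_nmd=0.0)
    assert len(transcribe_with_nmd([lone], cfg0)) == cfg.umis_per_cell


def test_out_of_frame_rearrangements_survive_nmd(db):
    """NMD recognizes premature stops, not frame: out-of-frame-without-stop
    transcripts are kept."""
    from vdjtrace.sim import make_plc16_like_sample

    cfg = SimConfig(n_cells=10, clonal_fraction=1.0, seed=13)
    cells, _ = make_plc16_like_sample(db, cfg)
    assert cells[0].heavy.failure_reason == FAILURE_OUT_OF_FRAME
    transcripts = transcribe_with_nmd(cells, cfg)
    assert any(t.allele == "heavy" for t in transcripts)


def test_read_emission_counting_and_error_oracle(db):
    cfg = SimConfig(n_cells=1, clonal_fraction=1.0, seed=9, umis_per_cell=4,
                    reads_per_umi=3, seq_error_rate=0.0)
    cells, truth = simulate_sample(db, cfg)
    transcripts = transcribe_with_nmd(cells, cfg)
    reads = emit_reads(transcripts, cfg)
    assert len(reads) == 2 * 4 * 3  # two chains x 4 UMIs x 3 reads
    assert len({r.name.split(":")[0] for r in reads}) == 1
    by_seq = {t.umi: t.sequence_nt for t in transcripts}
    for r in reads:
        umi = r.name.split(":")[1]
        assert by_seq[umi].startswith(r.sequence)  # error-free reads

    # error-rate oracle: observed mismatches within 3 SE of n x rate
    import dataclasses
    cfg_err = dataclasses.replace(cfg, seq_error_rate=0.01, seed=10)
    cells, _ = simulate_sample(db, cfg_err)
    transcripts = transcribe_with_nmd(cells, cfg_err)
    reads = emit_reads(transcripts, cfg_err)
    by_seq = {t.umi: t.sequence_nt for t in transcripts}
    total = mismatches = 0
    for r in reads:
        ref = by_seq[r.name.split(":")[1]][: len(r.sequence)]
        total += len(ref)
        mismatches += sum(a != b for a, b in zip(r.sequence, ref))
    se = np.sqrt(total * 0.01 * 0.99)
    assert abs(mismatches - total * 0.01) < 3 * se


def test_fastq_output_is_byte_identical_across_reruns(db, tmp_path):
    from vdjtrace.io import write_fastq

    cfg = SimConfig(n_cells=20, clonal_fraction=0.5, seed=123)
    paths = []
    for name in ("a.fastq", "b.fastq"):
        _, _, reads = simulate_reads(db, cfg)
        p = tmp_path / name
        write_fastq(reads, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_bulk_amplification_rules(db, panel):
    """DNA is blind to productivity; primer-killed clones vanish; intact
    productive clones amplify."""
    cfg = SimConfig(n_cells=20, clonal_fraction=1.0, seed=31)
    cells, _ = make_plc14_like_sample(db, cfg)
    amplicons = simulate_bulk_amplicon(cells, panel, cfg)
    cell = cells[0]
    seqs = [a.sequence_nt for a in amplicons]
    # stop-codon allele (unproductive) is amplified from DNA
    assert any(cell.second_heavy_allele.sequence_nt[60:90] in s for s in seqs)
    # the primer-killed productive allele yields zero amplicons
    assert not any(cell.heavy.cdr3_nt in s for s in seqs)

    # an unmutated productive clone amplifies
    plain, _ = simulate_sample(db, SimConfig(n_cells=5, clonal_fraction=1.0, seed=32))
    amp2 = simulate_bulk_amplicon(plain, panel, cfg)
    assert any(plain[0].heavy.cdr3_nt in a.sequence_nt for a in amp2)
    assert amp2[0].read_count == 5  # reads proportional to cell counts


def test_nmd_asymmetry_between_rna_and_dna(db, panel):
    """RNA-visible heavy rearrangements are exactly the non-stop ones; each is
    either amplifiable from DNA or carries a killed primer site."""
    from vdjtrace.germline import JC_INTRON
    from vdjtrace.primers import panel_screen

    cfg = SimConfig(n_cells=15, clonal_fraction=0.6, seed=41)
    cells, _ = make_plc14_like_sample(db, cfg)
    transcripts = transcribe_with_nmd(cells, cfg)
    rna_seqs = {t.sequence_nt for t in transcripts if t.chain == "IGH"}
    amplified = {a.sequence_nt for a in simulate_bulk_amplicon(cells, panel, cfg)}
    for cell in cells:
        for _, r in cell.rearrangements():
            if r.chain != "IGH":
                continue
            in_rna = r.sequence_nt in rna_seqs
            assert in_rna == (r.failure_reason != FAILURE_STOP_CODON)
            template = r.sequence_nt + JC_INTRON
            in_dna = any(template[60 : len(r.sequence_nt)] in a for a in amplified)
            killed = not panel_screen(panel, template).amplifiable
            assert in_dna != killed
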