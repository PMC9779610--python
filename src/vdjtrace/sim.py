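"""Synthetic plasma-cell repertoire generator.

Simulates the data-generating process of a 5' single-cell V(D)J experiment
on a plasma-cell dyscrasia sample, together with its bulk-DNA counterpart:

* V(D)J recombination with junctional trimming and untemplated N-nucleotide
  insertion (trim and insert lengths uniform, inserted bases uniform over
  ACGT — the simplest documented junction model);
* somatic hypermutation as independent per-base substitutions;
* one dominant clonotype at a configurable fraction of cells over a
  polyclonal background (every cell expresses a productive heavy and light
  chain by default, mirroring allelic exclusion in real plasma cells;
  unproductive rearrangements enter through the explicit second-allele
  machinery);
* nonsense-mediated decay (NMD): transcripts of stop-codon rearrangements
  are dropped (deterministically by default), while out-of-frame
  rearrangements without premature stops survive;
* barcoded/UMI-tagged reads with i.i.d. substitution errors;
* bulk-DNA amplicons under a consensus-primer PCR model, where templates are
  DNA (NMD does not apply) and amplification requires a forward V primer and
  at least one reverse J primer free of 3'-proximal mismatches.

Determinism: all randomness derives from ``SimConfig.seed``; identical
configs produce byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from . import cdr3 as _cdr3
from .germline import JC_INTRON, GermlineDatabase, GermlineSegment

BASES = "ACGT"

_STREAM_SAMPLE = 11
_STREAM_TRANSCRIBE = 23
_STREAM_READS = 37


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Rearrangement:
    """A recombined V(D)J sequence with junction records."""

    chain: str
    v_name: str
    d_name: str | None
    j_name: str
    sequence_nt: str
    v_end: int
    d_start: int
    d_end: int
    j_start: int
    n1_insert: str
    n2_insert: str
    shm_positions: tuple[int, ...]
    productive: bool
    failure_reason: str
    v_anchor_pos: int | None
    j_anchor_pos: int | None
    cdr3_nt: str | None
    cdr3_aa: str | None

    def __post_init__(self) -> None:
        if not (
            0 <= self.v_end <= self.d_start <= self.d_end <= self.j_start <= len(self.sequence_nt)
        ):
            raise SimulationError("inconsistent junction coordinates")
        if self.productive and self.failure_reason != _cdr3.FAILURE_NONE:
            raise SimulationError("productive rearrangement with failure reason")


class Transcript(NamedTuple):
    barcode: str
    chain: str
    allele: str
    umi: str
    sequence_nt: str


class FastqRead(NamedTuple):
    name: str  # "<barcode>:<umi>:<serial>" (+ ":trunc" when truncated)
    sequence: str
    quality: str


@dataclass(frozen=True)
class SimulatedCell:
    barcode: str
    clonotype_label: str
    heavy: Rearrangement | None
    light: Rearrangement | None
    second_heavy_allele: Rearrangement | None
    is_clonal: bool

    def __post_init__(self) -> None:
        if self.heavy is None and self.light is None:
            raise SimulationError("cell must carry at least one chain")

    def rearrangements(self) -> list[tuple[str, Rearrangement]]:
        out = []
        if self.heavy is not None:
            out.append(("heavy", self.heavy))
        if self.light is not None:
            out.append(("light", self.light))
        if self.second_heavy_allele is not None:
            out.append(("second_heavy", self.second_heavy_allele))
        return out


@dataclass
class SimConfig:
    """Study-condition knobs of the generator.

    Defaults encode a desk-scale rendering of the assay: 4 UMIs x 3 reads
    per chain, 0.5% per-base read error, 5% somatic hypermutation, and reads
    long enough to span a full V(D)J transcript (~370 nt), as the assembled
    contigs of the real assay do.
    """

    n_cells: int = 500
    clonal_fraction: float = 0.8
    shm_rate: float = 0.05
    max_trim: int = 6
    max_insert: int = 8
    reads_per_umi: int = 3
    umis_per_cell: int = 4
    seq_error_rate: float = 0.005
    read_length: int = 450
    nmd_mode: str = "deterministic"
    p_nmd: float = 1.0
    seed: int = 0
    polyclonal_productive_only: bool = True

    def validate(self) -> None:
        for name in ("clonal_fraction", "shm_rate", "seq_error_rate", "p_nmd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.shm_rate > 0.15:
            raise SimulationError("shm_rate above supported range [0, 0.15]")
        for name in ("n_cells", "reads_per_umi", "umis_per_cell", "read_length"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        if self.max_trim < 0 or self.max_insert < 0:
            raise SimulationError("max_trim/max_insert must be non-negative")
        if self.nmd_mode not in ("deterministic", "probabilistic"):
            raise SimulationError(f"unknown nmd_mode {self.nmd_mode!r}")


def _classify(
    chain: str,
    sequence: str,
    v: GermlineSegment,
    j: GermlineSegment,
    v_end: int,
    j_start: int,
    j_trim: int,
) -> tuple:
    v_anchor = v.anchor_index if v.anchor_index is not None and v_end >= v.anchor_index + 3 else None
    j_anchor = (
        j_start + j.anchor_index - j_trim
        if j.anchor_index is not None and j_trim <= j.anchor_index
        else None
    )
    call = _cdr3.classify_productivity(sequence, chain, v_anchor, j_anchor, j_end=len(sequence))
    return v_anchor, j_anchor, call


def recombine(
    v: GermlineSegment,
    j: GermlineSegment,
    rng: np.random.Generator,
    d: GermlineSegment | None = None,
    max_trim: int = 6,
    max_insert: int = 8,
) -> Rearrangement:
    """Assemble trimmed-V + N1 + trimmed-D + N2 + trimmed-J.

    IGK rearrangements omit D and N2. Trim lengths are uniform on
    [0, max_trim] per junction end, insert lengths uniform on [0, max_insert],
    inserted bases uniform over ACGT.
    """
    chains = {v.chain, j.chain} | ({d.chain} if d is not None else set())
    if len(chains) != 1:
        raise SimulationError(f"segments from different chains: {sorted(chains)}")
    chain = v.chain

    def trim(seg_len: int) -> int:
        t = int(rng.integers(0, max_trim + 1))
        if t > seg_len:
            raise SimulationError("trim exceeds segment length")
        return t

    def insert() -> str:
        n = int(rng.integers(0, max_insert + 1))
        return "".join(BASES[i] for i in rng.integers(0, 4, n))

    v_trim = trim(len(v))
    v_part = v.sequence_nt[: len(v) - v_trim]
    n1 = insert()
    if d is not None:
        d_trim5 = trim(len(d))
        d_trim3 = trim(len(d) - d_trim5)
        d_part = d.sequence_nt[d_trim5 : len(d) - d_trim3]
        n2 = insert()
    else:
        d_part, n2 = "", ""
    j_trim = trim(len(j))
    j_part = j.sequence_nt[j_trim:]

    seq = v_part + n1 + d_part + n2 + j_part
    v_end = len(v_part)
    d_start = v_end + len(n1)
    d_end = d_start + len(d_part)
    j_start = d_end + len(n2)

    v_anchor, j_anchor, call = _classify(chain, seq, v, j, v_end, j_start, j_trim)
    return Rearrangement(
        chain=chain,
        v_name=v.name,
        d_name=d.name if d is not None else None,
        j_name=j.name,
        sequence_nt=seq,
        v_end=v_end,
        d_start=d_start,
        d_end=d_end,
        j_start=j_start,
        n1_insert=n1,
        n2_insert=n2,
        shm_positions=(),
        productive=call.productive,
        failure_reason=call.failure_reason,
        v_anchor_pos=v_anchor,
        j_anchor_pos=j_anchor,
        cdr3_nt=call.cdr3_nt,
        cdr3_aa=call.cdr3_aa,
    )


def conserved_positions(r: Rearrangement, db: GermlineDatabase) -> frozenset[int]:
    """Sequence positions under selective constraint in real repertoires:
    anchor codons, the framework forward-primer block of the V gene, and the
    conserved 3' block of the J gene (consensus reverse-primer footprint)."""
    v = db.get(r.v_name)
    j = db.get(r.j_name)
    pos: set[int] = set()
    if r.v_anchor_pos is not None:
        pos.update(range(r.v_anchor_pos, r.v_anchor_pos + 3))
    if r.j_anchor_pos is not None:
        pos.update(range(r.j_anchor_pos, r.j_anchor_pos + 3))
    # framework primer block at V germline [60, 80)
    pos.update(p for p in range(60, 80) if p < r.v_end)
    # conserved J 3' block at J germline [len-14, len)
    j_trim = len(j) - (len(r.sequence_nt) - r.j_start)
    for g in range(len(j) - 14, len(j)):
        p = r.j_start + g - j_trim
        if r.j_start <= p < len(r.sequence_nt):
            pos.add(p)
    return frozenset(pos)


def apply_shm(
    r: Rearrangement,
    shm_rate: float,
    rng: np.random.Generator,
    db: GermlineDatabase | None = None,
    protected: Iterable[int] | None = None,
) -> Rearrangement:
    """Apply somatic hypermutation: independent per-base substitutions at
    ``shm_rate`` (never indels; a mutated base never equals the original).
    Positions in ``protected`` are exempt. Productivity is re-derived, since
    mutations can create stop codons or destroy anchor codons.
    """
    if not 0.0 <= shm_rate <= 0.15:
        raise SimulationError(f"shm_rate={shm_rate} outside [0, 0.15]")
    seq = list(r.sequence_nt)
    protected_set = frozenset(protected) if protected is not None else frozenset()
    hits = np.flatnonzero(rng.random(len(seq)) < shm_rate)
    mutated = []
    for p in hits:
        p = int(p)
        if p in protected_set:
            continue
        alternatives = [b for b in BASES if b != seq[p]]
        seq[p] = alternatives[int(rng.integers(0, 3))]
        mutated.append(p)
    new_seq = "".join(seq)

    call = _cdr3.classify_productivity(
        new_seq, r.chain, r.v_anchor_pos, r.j_anchor_pos, j_end=len(new_seq)
    )
    return replace(
        r,
        sequence_nt=new_seq,
        shm_positions=tuple(sorted(set(r.shm_positions) | set(mutated))),
        productive=call.productive,
        failure_reason=call.failure_reason,
        cdr3_nt=call.cdr3_nt,
        cdr3_aa=call.cdr3_aa,
    )


def point_mutation(r: Rearrangement, pos: int, new_base: str) -> Rearrangement:
    """Engineered single-base substitution (scenario construction)."""
    if not 0 <= pos < len(r.sequence_nt):
        raise SimulationError("mutation position out of range")
    if r.sequence_nt[pos] == new_base:
        raise SimulationError("substitution must change the base")
    seq = r.sequence_nt[:pos] + new_base + r.sequence_nt[pos + 1 :]
    call = _cdr3.classify_productivity(seq, r.chain, r.v_anchor_pos, r.j_anchor_pos, j_end=len(seq))
    return replace(
        r,
        sequence_nt=seq,
        shm_positions=tuple(sorted(set(r.shm_positions) | {pos})),
        productive=call.productive,
        failure_reason=call.failure_reason,
        cdr3_nt=call.cdr3_nt,
        cdr3_aa=call.cdr3_aa,
    )


def random_rearrangement(
    db: GermlineDatabase,
    chain: str,
    config: SimConfig,
    rng: np.random.Generator,
    require: str = "any",
    protect_conserved: bool = True,
    max_attempts: int = 500,
) -> Rearrangement:
    """Draw a hypermutated rearrangement, optionally resampling until a
    required outcome (``productive``, ``stop_codon``, ``out_of_frame``)."""
    vs = db.group(chain, "V")
    ds = db.group(chain, "D")
    js = db.group(chain, "J")
    for _ in range(max_attempts):
        v = vs[int(rng.integers(0, len(vs)))]
        j = js[int(rng.integers(0, len(js)))]
        d = ds[int(rng.integers(0, len(ds)))] if ds else None
        r = recombine(v, j, rng, d=d, max_trim=config.max_trim, max_insert=config.max_insert)
        if config.shm_rate > 0:
            prot = conserved_positions(r, db) if protect_conserved else None
            r = apply_shm(r, config.shm_rate, rng, protected=prot)
        if require == "any":
            return r
        if require == "productive" and r.productive:
            return r
        if require in (_cdr3.FAILURE_STOP_CODON, _cdr3.FAILURE_OUT_OF_FRAME) and (
            r.failure_reason == require
        ):
            return r
    raise SimulationError(f"could not draw a {require!r} {chain} rearrangement")


def _unique_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(BASES[i] for i in rng.integers(0, 4, 16))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def truth_table(cells: list[SimulatedCell]) -> pd.DataFrame:
    rows = []
    for cell in cells:
        for allele, r in cell.rearrangements():
            rows.append(
                dict(
                    barcode=cell.barcode,
                    clonotype_label=cell.clonotype_label,
                    allele=allele,
                    chain=r.chain,
                    v_name=r.v_name,
                    j_name=r.j_name,
                    cdr3_nt=r.cdr3_nt if r.cdr3_nt is not None else "",
                    productive=r.productive,
                    is_clonal=cell.is_clonal,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "clonotype_label",
            "allele",
            "chain",
            "v_name",
            "j_name",
            "cdr3_nt",
            "productive",
            "is_clonal",
        ],
    )


def simulate_sample(
    db: GermlineDatabase,
    config: SimConfig,
    clone_label: str = "clone",
) -> tuple[list[SimulatedCell], pd.DataFrame]:
    """Simulate one sample: a dominant clonotype over a polyclonal background.

    ``round(n_cells * clonal_fraction)`` cells share a single clonal
    heavy/light pair (identical CDR3 nucleotides); every remaining cell gets
    an independent random pair. Both clonal chains are resampled until
    productive — dominant myeloma clonotypes are productive rearrangements.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_SAMPLE)
    n_clonal = round(config.n_cells * config.clonal_fraction)
    if config.clonal_fraction > 0 and n_clonal < 1:
        warnings.warn("clonal_fraction x n_cells < 1: sample has no clonal cells")

    barcodes = _unique_barcodes(config.n_cells, rng)
    cells: list[SimulatedCell] = []
    if n_clonal > 0:
        clonal_heavy = random_rearrangement(db, "IGH", config, rng, require="productive")
        clonal_light = random_rearrangement(db, "IGK", config, rng, require="productive")
        for bc in barcodes[:n_clonal]:
            cells.append(
                SimulatedCell(
                    barcode=bc,
                    clonotype_label=clone_label,
                    heavy=clonal_heavy,
                    light=clonal_light,
                    second_heavy_allele=None,
                    is_clonal=True,
                )
            )
    require = "productive" if config.polyclonal_productive_only else "any"
    for i, bc in enumerate(barcodes[n_clonal:]):
        cells.append(
            SimulatedCell(
                barcode=bc,
                clonotype_label=f"poly-{i}",
                heavy=random_rearrangement(db, "IGH", config, rng, require=require),
                light=random_rearrangement(db, "IGK", config, rng, require=require),
                second_heavy_allele=None,
                is_clonal=False,
            )
        )
    return cells, truth_table(cells)


def transcribe_with_nmd(
    cells: list[SimulatedCell], config: SimConfig
) -> list[Transcript]:
    """Emit UMI-tagged transcripts per cell, applying NMD.

    Deterministic mode: rearrangements failing with a premature stop codon
    yield zero transcripts; out-of-frame rearrangements without stops are
    transcribed (NMD recognizes premature termination codons, not frame).
    Probabilistic mode drops each stop-codon transcript molecule with
    probability ``p_nmd``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TRANSCRIBE)
    out: list[Transcript] = []
    for cell in cells:
        for allele, r in cell.rearrangements():
            is_nmd_target = r.failure_reason == _cdr3.FAILURE_STOP_CODON
            if is_nmd_target and config.nmd_mode == "deterministic":
                continue
            for _ in range(config.umis_per_cell):
                if (
                    is_nmd_target
                    and config.nmd_mode == "probabilistic"
                    and rng.random() < config.p_nmd
                ):
                    continue
                umi = "".join(BASES[i] for i in rng.integers(0, 4, 10))
                out.append(Transcript(cell.barcode, r.chain, allele, umi, r.sequence_nt))
    return out


def emit_reads(transcripts: list[Transcript], config: SimConfig) -> list[FastqRead]:
    """Emit ``reads_per_umi`` reads per transcript molecule.

    Each read covers the transcript 5' end for ``read_length`` nt with i.i.d.
    substitution errors at ``seq_error_rate``; reads longer than their
    transcript are truncated to it and flagged in the read name.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_READS)
    reads: list[FastqRead] = []
    serial = 0
    for t in transcripts:
        truncated = config.read_length > len(t.sequence_nt)
        base = t.sequence_nt[: config.read_length]
        base_arr = np.frombuffer(base.encode(), dtype=np.uint8).copy()
        for _ in range(config.reads_per_umi):
            arr = base_arr.copy()
            n_err = rng.binomial(len(arr), config.seq_error_rate)
            if n_err:
                pos = rng.choice(len(arr), size=n_err, replace=False)
                for p in pos:
                    alternatives = [b for b in b"ACGT" if b != arr[p]]
                    arr[p] = alternatives[int(rng.integers(0, 3))]
            name = f"{t.barcode}:{t.umi}:{serial}"
            if truncated:
                name += ":trunc"
            reads.append(FastqRead(name, arr.tobytes().decode(), "I" * len(arr)))
            serial += 1
    return reads


def simulate_reads(
    db: GermlineDatabase, config: SimConfig, clone_label: str = "clone"
) -> tuple[list[SimulatedCell], pd.DataFrame, list[FastqRead]]:
    """Convenience: simulate_sample -> transcribe_with_nmd -> emit_reads."""
    cells, truth = simulate_sample(db, config, clone_label=clone_label)
    reads = emit_reads(transcribe_with_nmd(cells, config), config)
    return cells, truth, reads


# ---------------------------------------------------------------------------
# bulk-DNA amplicons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    sequence_nt: str
    read_count: int
    chain: str
    v_name: str
    j_name: str
    productive: bool
    failure_reason: str
    clonotype_labels: tuple[str, ...]


def simulate_bulk_amplicon(
    cells: list[SimulatedCell],
    panel,
    config: SimConfig,
    k: int = 3,
    max_total_mismatches: int = 6,
) -> list[Amplicon]:
    """First-step consensus PCR on genomic DNA of the same cells.

    The template is DNA: NMD does not apply and unproductive alleles are
    amplifiable. A rearrangement is amplified only if one forward V primer
    and at least one reverse J primer anneal without a 3'-window mismatch;
    amplified rearrangements contribute reads proportional to cell counts.
    Heavy-chain (IGH) templates only — the panel mimics an IGH V-J layout.
    """
    from .primers import panel_screen  # local import to avoid cycle

    config.validate()
    groups: dict[str, dict] = {}
    for cell in cells:
        for allele, r in cell.rearrangements():
            if r.chain != "IGH":
                continue
            g = groups.setdefault(
                r.sequence_nt, dict(rearrangement=r, n_cells=0, labels=set())
            )
            g["n_cells"] += 1
            g["labels"].add(cell.clonotype_label)

    out: list[Amplicon] = []
    for seq in sorted(groups):
        g = groups[seq]
        r: Rearrangement = g["rearrangement"]
        template = seq + JC_INTRON
        verdict = panel_screen(
            panel, template, template_kind="dna_rearrangement", k=k,
            max_total_mismatches=max_total_mismatches,
        )
        if not verdict.amplifiable:
            continue
        fwd = min(verdict.passing_forward, key=lambda rep: rep.offset)
        rev = max(verdict.passing_reverse, key=lambda rep: rep.end)
        out.append(
            Amplicon(
                sequence_nt=template[fwd.offset : rev.end],
                read_count=g["n_cells"],
                chain="IGH",
                v_name=r.v_name,
                j_name=r.j_name,
                productive=r.productive,
                failure_reason=r.failure_reason,
                clonotype_labels=tuple(sorted(g["labels"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# mechanism scenarios
# ---------------------------------------------------------------------------


def _kill_reverse_primers(r: Rearrangement, db: GermlineDatabase) -> Rearrangement:
    """Mutate the J gene under the shared 3'-terminal window of both reverse
    consensus primers (J germline position len-10), keeping the chain
    productive: the RNA-side clonotype is unaffected, but first-step PCR on
    DNA loses both reverse primers."""
    j = db.get(r.j_name)
    j_trim = len(j) - (len(r.sequence_nt) - r.j_start)
    pos = r.j_start + (len(j) - 10) - j_trim
    original = r.sequence_nt[pos]
    for new in BASES:
        if new == original:
            continue
        mutated = point_mutation(r, pos, new)
        if mutated.productive:
            return mutated
    raise SimulationError("no productivity-preserving substitution at primer site")


def make_plc14_like_sample(
    db: GermlineDatabase, config: SimConfig, clone_label: str = "clone"
) -> tuple[list[SimulatedCell], pd.DataFrame]:
    """Biallelic dominant clone reproducing the RNA/DNA double discordance:
    the expressed heavy chain carries a J mutation under the 3' end of both
    reverse primers (invisible to DNA-based PCR), while a second, stop-codon
    heavy allele is NMD-degraded in RNA but amplifiable from DNA."""
    cells, _ = simulate_sample(db, config, clone_label=clone_label)
    rng = _rng(config.seed, _STREAM_SAMPLE + 1)
    clonal = [c for c in cells if c.is_clonal]
    if not clonal:
        raise SimulationError("scenario requires clonal cells")
    heavy = _kill_reverse_primers(clonal[0].heavy, db)
    second = random_rearrangement(
        db, "IGH", config, rng, require=_cdr3.FAILURE_STOP_CODON
    )
    new_cells = [
        replace(c, heavy=heavy, second_heavy_allele=second) if c.is_clonal else c
        for c in cells
    ]
    return new_cells, truth_table(new_cells)


def make_plc16_like_sample(
    db: GermlineDatabase, config: SimConfig, clone_label: str = "clone"
) -> tuple[list[SimulatedCell], pd.DataFrame]:
    """Light-chain-only dominant clone: the clonal heavy allele is
    out-of-frame (no premature stop, so it survives NMD but contributes no
    productive clonotype key), and the clonal IGK chain defines the
    clonotype. Bulk heavy-chain screening finds only the unproductive
    rearrangement."""
    cells, _ = simulate_sample(db, config, clone_label=clone_label)
    rng = _rng(config.seed, _STREAM_SAMPLE + 2)
    heavy = random_rearrangement(
        db, "IGH", config, rng, require=_cdr3.FAILURE_OUT_OF_FRAME
    )
    new_cells = [replace(c, heavy=heavy) if c.is_clonal else c for c in cells]
    return new_cells, truth_table(new_cells)
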