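"""Per-cell chain calling from barcoded reads, and bulk-amplicon clonotyping.

The single-cell path mirrors the logic of a V(D)J assembly pipeline at desk
scale: reads are collapsed per UMI by per-position plurality vote, UMI
consensuses are collapsed per barcode and chain, V and J genes are assigned
by semi-global alignment against the germline database, the CDR3 is
delimited by mapping the conserved anchor codons through the alignment, and
cells are grouped into clonotypes by exact CDR3 nucleotide identity.

The bulk path is a deliberately simplified amplicon clonotyper (the real
assay runs a dedicated repertoire tool): amplicons are grouped by sequence,
annotated the same way, and reported with read proportions. D segments are
never assigned — they are too short for reliable assignment and live only in
simulation truth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cdr3 as _cdr3
from .align import (
    NO_COMPETITOR_MARGIN,
    _offset_batch,
    batch_scores,
    encode,
    pack_queries,
    rank_candidates,
)
from .germline import GermlineDatabase
from .sim import FastqRead

CHAINS = ("IGH", "IGK")


@dataclass
class CallerParams:
    """Tunable knobs of the calling path."""

    min_umis: int = 2
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    ambiguity_margin: int = 5
    kmer: int = 12  # word size of the chain-separation screen


@dataclass(frozen=True)
class ChainCall:
    barcode: str
    chain: str
    consensus_nt: str
    v_call: str
    j_call: str
    v_score: int
    j_score: int
    v_margin: int
    ambiguous_v: bool
    cdr3_nt: str | None
    cdr3_aa: str | None
    productive: bool
    failure_reason: str
    umi_count: int
    read_count: int


@dataclass(frozen=True)
class Clonotype:
    id: str
    chain_keys: frozenset[tuple[str, str]]  # (chain, cdr3_nt)
    barcodes: frozenset[str]

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def cdr3_aa_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((c, _cdr3.translate_nt(nt)) for c, nt in self.chain_keys)


def sorted_key(chain_keys: frozenset[tuple[str, str]]) -> tuple:
    return tuple(sorted(chain_keys))


# ---------------------------------------------------------------------------
# consensus building
# ---------------------------------------------------------------------------


def _plurality(seqs: list[str]) -> str:
    """Per-position plurality vote; unequal lengths vote over columns of the
    longest (absent bases abstain); ties pick the alphabetically first base."""
    if len(seqs) == 1:
        return seqs[0]
    if len(set(seqs)) == 1:
        return seqs[0]
    L = max(len(s) for s in seqs)
    counts = np.zeros((4, L), dtype=np.int32)
    for s in seqs:
        arr = encode(s)
        counts[arr, np.arange(len(s))] += 1
    best = counts.argmax(axis=0)  # argmax -> first max -> alphabetical tie-break
    return "".join("ACGT"[b] for b in best)


@dataclass(frozen=True)
class BarcodeChain:
    barcode: str
    chain: str
    consensus_nt: str
    umi_count: int
    read_count: int


@dataclass
class ConsensusResult:
    chains: list[BarcodeChain]
    dropped: list[tuple[str, str, int]] = field(default_factory=list)  # (barcode, chain, umis)


def _chain_kmer_index(db: GermlineDatabase, k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for chain in CHAINS:
        words: set[str] = set()
        for seg in db.group(chain, "V"):
            s = seg.sequence_nt
            words.update(s[i : i + k] for i in range(len(s) - k + 1))
        index[chain] = words
    return index


def _classify_chain(seq: str, index: dict[str, set[str]], k: int) -> str:
    """Chain of the best-scoring germline V set under a shared-word score."""
    words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    scores = {chain: len(words & wset) for chain, wset in index.items()}
    return max(sorted(scores), key=lambda c: scores[c])


def build_consensus(
    reads: list[FastqRead],
    db: GermlineDatabase,
    params: CallerParams | None = None,
) -> ConsensusResult:
    """Collapse reads to per-barcode, per-chain consensus sequences.

    Reads are grouped by (barcode, UMI) from the read-name convention
    ``barcode:umi:serial``; each UMI group is collapsed by plurality vote,
    UMI consensuses are assigned a chain and collapsed per barcode, and
    chains supported by fewer than ``min_umis`` UMIs are dropped (logged).
    """
    params = params or CallerParams()
    by_umi: dict[tuple[str, str], list[str]] = defaultdict(list)
    for r in reads:
        parts = r.name.split(":")
        if len(parts) < 3:
            raise ValueError(f"read name {r.name!r} lacks barcode:umi:serial structure")
        by_umi[(parts[0], parts[1])].append(r.sequence)

    index = _chain_kmer_index(db, params.kmer)
    per_barcode: dict[tuple[str, str], dict] = {}
    for (bc, umi), seqs in by_umi.items():
        cons = _plurality(seqs)
        chain = _classify_chain(cons, index, params.kmer)
        slot = per_barcode.setdefault((bc, chain), dict(umis=[], reads=0))
        slot["umis"].append(cons)
        slot["reads"] += len(seqs)

    chains: list[BarcodeChain] = []
    dropped: list[tuple[str, str, int]] = []
    for (bc, chain), slot in sorted(per_barcode.items()):
        n_umis = len(slot["umis"])
        if n_umis < params.min_umis:
            dropped.append((bc, chain, n_umis))
            continue
        chains.append(
            BarcodeChain(
                barcode=bc,
                chain=chain,
                consensus_nt=_plurality(slot["umis"]),
                umi_count=n_umis,
                read_count=slot["reads"],
            )
        )
    return ConsensusResult(chains=chains, dropped=dropped)


# ---------------------------------------------------------------------------
# segment assignment / CDR3 / chain calls
# ---------------------------------------------------------------------------


def extract_cdr3(
    consensus_nt: str,
    v_call: str,
    j_call: str,
    db: GermlineDatabase,
) -> _cdr3.ProductivityCall:
    """Delimit and classify the CDR3 of a single consensus (convenience
    wrapper over the batched path)."""
    v = db.get(v_call)
    j = db.get(j_call)
    Q, lens = pack_queries([consensus_nt])
    v_off, _ = _offset_batch(Q, lens, encode(v.sequence_nt), 2)
    j_off, _ = _offset_batch(Q, lens, encode(j.sequence_nt), 2)
    v_anchor = int(v_off[0]) + v.anchor_index
    j_anchor = int(j_off[0]) + j.anchor_index
    j_end = min(int(j_off[0]) + len(j.sequence_nt), len(consensus_nt))
    return _cdr3.classify_productivity(consensus_nt, v.chain, v_anchor, j_anchor, j_end=j_end)


classify_productivity = _cdr3.classify_productivity


def call_chains(
    consensus: ConsensusResult | list[BarcodeChain],
    db: GermlineDatabase,
    params: CallerParams | None = None,
) -> list[ChainCall]:
    """Assign V/J genes, extract CDR3s and classify productivity for every
    barcode-chain consensus (batched per chain for speed)."""
    params = params or CallerParams()
    records = consensus.chains if isinstance(consensus, ConsensusResult) else consensus
    calls: list[ChainCall] = []
    for chain in CHAINS:
        group = [r for r in records if r.chain == chain]
        if not group:
            continue
        vs = db.group(chain, "V")
        js = db.group(chain, "J")
        queries = [r.consensus_nt for r in group]
        v_scores = batch_scores(
            queries, [s.sequence_nt for s in vs], params.match, params.mismatch, params.gap
        )
        j_scores = batch_scores(
            queries, [s.sequence_nt for s in js], params.match, params.mismatch, params.gap
        )
        v_names = [s.name for s in vs]
        j_names = [s.name for s in js]

        v_assign = [
            rank_candidates(v_names, v_scores[i], params.ambiguity_margin)
            for i in range(len(group))
        ]
        j_assign = [
            rank_candidates(j_names, j_scores[i], params.ambiguity_margin)
            for i in range(len(group))
        ]

        # anchor mapping: batch the gapless placement per assigned segment
        Q, lens = pack_queries(queries)
        v_anchor = np.full(len(group), -1, dtype=np.int64)
        j_anchor = np.full(len(group), -1, dtype=np.int64)
        j_end = np.full(len(group), -1, dtype=np.int64)
        for seg_pool, assign, anchor_arr, end_arr in (
            (vs, v_assign, v_anchor, None),
            (js, j_assign, j_anchor, j_end),
        ):
            by_name = {s.name: s for s in seg_pool}
            chosen = np.array([a.name for a in assign])
            for name in sorted(set(chosen)):
                seg = by_name[name]
                idx = np.flatnonzero(chosen == name)
                offs, _ = _offset_batch(Q[idx], lens[idx], encode(seg.sequence_nt), 2)
                anchor_arr[idx] = offs + seg.anchor_index
                if end_arr is not None:
                    end_arr[idx] = np.minimum(offs + len(seg.sequence_nt), lens[idx])

        for i, rec in enumerate(group):
            call = _cdr3.classify_productivity(
                rec.consensus_nt,
                chain,
                int(v_anchor[i]),
                int(j_anchor[i]),
                j_end=int(j_end[i]),
            )
            calls.append(
                ChainCall(
                    barcode=rec.barcode,
                    chain=chain,
                    consensus_nt=rec.consensus_nt,
                    v_call=v_assign[i].name,
                    j_call=j_assign[i].name,
                    v_score=v_assign[i].score,
                    j_score=j_assign[i].score,
                    v_margin=v_assign[i].margin,
                    ambiguous_v=v_assign[i].ambiguous,
                    cdr3_nt=call.cdr3_nt,
                    cdr3_aa=call.cdr3_aa,
                    productive=call.productive,
                    failure_reason=call.failure_reason,
                    umi_count=rec.umi_count,
                    read_count=rec.read_count,
                )
            )
    calls.sort(key=lambda c: (c.barcode, c.chain))
    return calls


# ---------------------------------------------------------------------------
# clonotype grouping
# ---------------------------------------------------------------------------


@dataclass
class ClonotypeResult:
    clonotypes: list[Clonotype]
    n_cells: int  # denominator: cells with >= 1 productive chain
    unproductive_barcodes: list[str]

    def frequency_pct(self, ct: Clonotype) -> float:
        return 100.0 * ct.n_cells / self.n_cells if self.n_cells else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                clonotype_id=ct.id,
                chain_keys=";".join(f"{c}:{nt}" for c, nt in sorted_key(ct.chain_keys)),
                n_cells=ct.n_cells,
                frequency_pct=round(self.frequency_pct(ct), 2),
            )
            for ct in self.clonotypes
        ]
        return pd.DataFrame(
            rows, columns=["clonotype_id", "chain_keys", "n_cells", "frequency_pct"]
        )


def group_clonotypes(chain_calls: list[ChainCall]) -> ClonotypeResult:
    """Group cells by the set of their productive CDR3 nucleotide sequences.

    Paired IGH+IGK keys when both chains are productive; single-chain keys
    are allowed (supporting light-chain-only clonotypes). Cells with zero
    productive chains are excluded from the denominator and reported
    separately.
    """
    per_cell: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for call in chain_calls:
        if call.productive and call.cdr3_nt:
            per_cell.setdefault(call.barcode, set()).add((call.chain, call.cdr3_nt))
        else:
            per_cell.setdefault(call.barcode, set())

    groups: dict[frozenset, set[str]] = defaultdict(set)
    unproductive = []
    for bc, keys in per_cell.items():
        if keys:
            groups[frozenset(keys)].add(bc)
        else:
            unproductive.append(bc)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), sorted_key(kv[0])))
    clonotypes = [
        Clonotype(id=f"clonotype-{i + 1}", chain_keys=key, barcodes=frozenset(bcs))
        for i, (key, bcs) in enumerate(ordered)
    ]
    return ClonotypeResult(
        clonotypes=clonotypes,
        n_cells=sum(len(bcs) for _, bcs in ordered),
        unproductive_barcodes=sorted(unproductive),
    )


def call_sample(
    reads: list[FastqRead],
    db: GermlineDatabase,
    params: CallerParams | None = None,
) -> tuple[list[ChainCall], ClonotypeResult, ConsensusResult]:
    """Full single-cell calling path: consensus -> chain calls -> clonotypes."""
    consensus = build_consensus(reads, db, params)
    calls = call_chains(consensus, db, params)
    return calls, group_clonotypes(calls), consensus


# ---------------------------------------------------------------------------
# bulk amplicon clonotyping (simplified)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BulkClonotype:
    v_call: str
    j_call: str
    cdr3_nt: str | None
    cdr3_aa: str | None
    productive: bool
    failure_reason: str
    read_count: int
    proportion_pct: float


def call_bulk_amplicons(
    amplicons,
    db: GermlineDatabase,
    params: CallerParams | None = None,
) -> list[BulkClonotype]:
    """Annotate and rank bulk amplicons: group by CDR3 nucleotide sequence
    (unproductive amplicons without a CDR3 group by full sequence), with
    read proportions over all amplified reads. Sorted by abundance."""
    params = params or CallerParams()
    if not amplicons:
        return []
    records = [
        BarcodeChain(
            barcode=f"amplicon-{i}",
            chain=a.chain,
            consensus_nt=a.sequence_nt,
            umi_count=1,
            read_count=a.read_count,
        )
        for i, a in enumerate(amplicons)
    ]
    calls = call_chains(records, db, params)
    total = sum(a.read_count for a in amplicons)
    groups: dict = {}
    for call in calls:
        key = ("cdr3", call.chain, call.cdr3_nt) if call.cdr3_nt else ("seq", call.chain, call.consensus_nt)
        g = groups.setdefault(key, dict(call=call, reads=0))
        g["reads"] += call.read_count
    out = [
        BulkClonotype(
            v_call=g["call"].v_call,
            j_call=g["call"].j_call,
            cdr3_nt=g["call"].cdr3_nt,
            cdr3_aa=g["call"].cdr3_aa,
            productive=g["call"].productive,
            failure_reason=g["call"].failure_reason,
            read_count=g["reads"],
            proportion_pct=100.0 * g["reads"] / total,
        )
        for g in groups.values()
    ]
    out.sort(key=lambda b: (-b.read_count, b.v_call, b.j_call, b.cdr3_nt or ""))
    return out
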