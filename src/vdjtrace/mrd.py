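"""In silico minimal-residual-disease (MRD) dilution and detection.

A virtual post-therapy sample is built by spiking the reads of a handful of
known clonal cells into a large polyclonal background pooled from several
simulated samples, then running the standard calling path and looking for
the patient-specific clonotype by exact CDR3-nucleotide-key match. The
detector deliberately does not rely on dominance: background samples keep
their own dominant clonotypes, which outrank the spiked clone by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .caller import CallerParams, ClonotypeResult, call_sample, sorted_key
from .germline import GermlineDatabase
from .sim import BASES, FastqRead, SimConfig, simulate_reads


class MrdError(ValueError):
    pass


@dataclass(frozen=True)
class DilutionSpec:
    n_clonal_cells: int
    target_key: frozenset[tuple[str, str]]  # {(chain, cdr3_nt)}
    background_cells: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_clonal_cells < 1:
            raise MrdError("n_clonal_cells must be >= 1")
        if self.background_cells < 0:
            raise MrdError("background_cells must be >= 0")
        if not self.target_key:
            raise MrdError("empty target clonotype key")


@dataclass(frozen=True)
class MrdResult:
    detected_barcodes: frozenset[str]
    n_detected: int
    sensitivity: float
    false_positive_barcodes: frozenset[str]
    clonotype_rank: int | None

    def __post_init__(self) -> None:
        if self.detected_barcodes & self.false_positive_barcodes:
            raise MrdError("detected and false-positive sets overlap")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise MrdError("sensitivity outside [0, 1]")


def barcode_keys(truth: pd.DataFrame) -> dict[str, frozenset[tuple[str, str]]]:
    """Per-barcode clonotype key (productive chains only) from a truth table."""
    prod = truth[truth["productive"] & (truth["cdr3_nt"] != "")]
    keys: dict[str, set] = {bc: set() for bc in truth["barcode"].unique()}
    for _, row in prod.iterrows():
        keys[row["barcode"]].add((row["chain"], row["cdr3_nt"]))
    return {bc: frozenset(k) for bc, k in keys.items()}


def build_dilution(
    spec: DilutionSpec,
    clonal_reads: list[FastqRead],
    clonal_truth: pd.DataFrame,
    background_reads: list[FastqRead],
    background_truth: pd.DataFrame,
) -> tuple[list[FastqRead], pd.DataFrame, dict[str, str]]:
    """Concatenate reads of ``n_clonal_cells`` randomly chosen target-clonotype
    barcodes with all background reads.

    Spiked barcodes are chosen uniformly without replacement; a spiked
    barcode colliding with a background barcode is re-coded deterministically
    (seeded draw) and the re-coding returned. The combined truth table marks
    spiked barcodes.
    """
    rng = np.random.default_rng(spec.seed)
    keys = barcode_keys(clonal_truth)
    candidates = sorted(bc for bc, key in keys.items() if key == spec.target_key)
    if len(candidates) < spec.n_clonal_cells:
        raise MrdError(
            f"only {len(candidates)} target-clonotype barcodes available, "
            f"{spec.n_clonal_cells} requested"
        )
    chosen = sorted(
        np.asarray(candidates)[
            rng.choice(len(candidates), size=spec.n_clonal_cells, replace=False)
        ]
    )

    taken = set(background_truth["barcode"]) | set(chosen)
    recoded: dict[str, str] = {}
    for bc in chosen:
        if bc in set(background_truth["barcode"]):
            while True:
                new = "".join(BASES[i] for i in rng.integers(0, 4, 16))
                if new not in taken:
                    break
            recoded[bc] = new
            taken.add(new)

    def recode_read(r: FastqRead) -> FastqRead:
        bc, rest = r.name.split(":", 1)
        new = recoded.get(bc)
        return r if new is None else FastqRead(f"{new}:{rest}", r.sequence, r.quality)

    chosen_set = set(chosen)
    spike_reads = [
        recode_read(r) for r in clonal_reads if r.name.split(":", 1)[0] in chosen_set
    ]
    reads = spike_reads + list(background_reads)

    spike_truth = clonal_truth[clonal_truth["barcode"].isin(chosen_set)].copy()
    spike_truth["barcode"] = spike_truth["barcode"].map(lambda b: recoded.get(b, b))
    spike_truth["spiked"] = True
    spike_truth["origin"] = "spike"
    bg_truth = background_truth.copy()
    bg_truth["spiked"] = False
    bg_truth["origin"] = "background"
    truth = pd.concat([spike_truth, bg_truth], ignore_index=True)
    return reads, truth, recoded


def rank_clonotypes(result: ClonotypeResult, top: int | None = None) -> pd.DataFrame:
    """Abundance-ranked clonotype table (1-based ranks; stable sort by cell
    count descending, ties by lexicographic chain key)."""
    ordered = sorted(result.clonotypes, key=lambda ct: (-ct.n_cells, sorted_key(ct.chain_keys)))
    if top is not None:
        ordered = ordered[:top]
    return pd.DataFrame(
        dict(
            rank=range(1, len(ordered) + 1),
            clonotype_id=[ct.id for ct in ordered],
            chain_keys=[";".join(f"{c}:{nt}" for c, nt in sorted_key(ct.chain_keys)) for ct in ordered],
            n_cells=[ct.n_cells for ct in ordered],
        )
    )


def detect_mrd(
    result: ClonotypeResult,
    target_key: frozenset[tuple[str, str]],
    truth: pd.DataFrame,
) -> MrdResult:
    """Score target-clonotype recovery in a called dilution sample.

    Detection is an exact CDR3-nucleotide-key match against the known target;
    sensitivity and false positives are computed against the truth table's
    spiked flags, and the clonotype's abundance rank is reported.
    """
    truth_keys = set(barcode_keys(truth).values())
    if target_key not in truth_keys:
        raise MrdError("target key absent from the truth table")
    spiked = frozenset(truth.loc[truth["spiked"], "barcode"])

    detected: set[str] = set()
    for ct in result.clonotypes:
        if ct.chain_keys == target_key:
            detected |= ct.barcodes
    ranks = rank_clonotypes(result)
    key_str = ";".join(f"{c}:{nt}" for c, nt in sorted(target_key))
    hit = ranks[ranks["chain_keys"] == key_str]
    rank = int(hit["rank"].iloc[0]) if not hit.empty else None

    true_hits = frozenset(detected & spiked)
    return MrdResult(
        detected_barcodes=true_hits,
        n_detected=len(true_hits),
        sensitivity=len(true_hits) / len(spiked) if spiked else 0.0,
        false_positive_barcodes=frozenset(detected - spiked),
        clonotype_rank=rank,
    )


def run_dilution_experiment(
    db: GermlineDatabase,
    seed: int,
    n_spike: int = 5,
    total_background: int = 3180,
    n_background_samples: int = 13,
    background_clonal_fraction: float = 0.5,
    source_config: SimConfig | None = None,
    base_config: SimConfig | None = None,
    params: CallerParams | None = None,
) -> dict:
    """End-to-end MRD experiment: simulate backgrounds and a clonal source,
    build the dilution, call clonotypes, and score detection.

    Defaults render the published design: 5 spiked clonal cells against a
    3180-cell background pooled from 13 samples, each background sample
    keeping its own dominant clonotype.
    """
    seeder = np.random.default_rng(seed)
    sub = seeder.integers(0, 2**31 - 1, size=n_background_samples + 2)
    base = base_config or SimConfig()

    # clonal source sample (a diagnostic sample of the tracked patient)
    src_cfg = source_config or _dc_replace(base, n_cells=40, clonal_fraction=0.8, seed=int(sub[0]))
    _, src_truth, src_reads = simulate_reads(db, src_cfg, clone_label="target-clone")
    target_rows = src_truth[(src_truth["clonotype_label"] == "target-clone") & src_truth["productive"]]
    target_key = frozenset(
        (row["chain"], row["cdr3_nt"]) for _, row in target_rows.iterrows() if row["cdr3_nt"]
    )

    # pooled polyclonal background with per-sample dominant clonotypes
    base_n = total_background // n_background_samples
    rem = total_background % n_background_samples
    bg_reads: list[FastqRead] = []
    bg_truths = []
    for i in range(n_background_samples):
        cfg = _dc_replace(
            base,
            n_cells=base_n + (1 if i < rem else 0),
            clonal_fraction=background_clonal_fraction,
            seed=int(sub[i + 2]),
        )
        _, truth_i, reads_i = simulate_reads(db, cfg, clone_label=f"bg-{i}-clone")
        truth_i["clonotype_label"] = truth_i["clonotype_label"].map(lambda s, i=i: f"bg{i}:{s}")
        bg_reads.extend(reads_i)
        bg_truths.append(truth_i)
    bg_truth = pd.concat(bg_truths, ignore_index=True)

    spec = DilutionSpec(
        n_clonal_cells=n_spike,
        target_key=target_key,
        background_cells=total_background,
        seed=int(sub[1]),
    )
    reads, truth, recoded = build_dilution(spec, src_reads, src_truth, bg_reads, bg_truth)
    calls, clonotypes, _ = call_sample(reads, db, params)
    result = detect_mrd(clonotypes, target_key, truth)
    return dict(
        spec=spec,
        result=result,
        clonotypes=clonotypes,
        chain_calls=calls,
        truth=truth,
        recoded=recoded,
        n_barcodes=truth["barcode"].nunique(),
    )
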