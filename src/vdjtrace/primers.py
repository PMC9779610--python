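"""Consensus-primer annealing model and first-step PCR failure prediction.

Clinical marker identification amplifies rearranged IGH loci from genomic
DNA with consensus primers: per-V-family forward primers in the framework
region and a small set of reverse primers spanning the J 3' end and the
first bases of the J–C intron. A somatic mutation under a primer's
3'-terminal window abolishes priming — the mechanism by which a dominant
clonotype can disappear from DNA-based screening while remaining fully
visible in RNA.

The annealing model is ungapped: the primer (reverse primers are
reverse-complemented first) is placed at its best-scoring offset on the
template; mismatch positions are reported as offsets from the primer's 3'
terminus (0 = terminal base). On a mature-mRNA template the intronic tail of
a reverse primer has nothing to anneal to (the intron is spliced out), so
those bases are excluded from the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .germline import packaged_path

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TEMPLATE_KINDS = ("dna_rearrangement", "mature_mrna")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class Primer:
    """A consensus primer, sequence written 5'->3'."""

    name: str
    sequence_nt: str
    orientation: str  # forward | reverse
    target_region: str  # V | J
    intronic_tail_len: int = 0

    def __post_init__(self) -> None:
        if not self.sequence_nt:
            raise PrimerError(f"{self.name}: empty primer sequence")
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(f"{self.name}: orientation must be forward/reverse")
        if self.target_region not in ("V", "J"):
            raise PrimerError(f"{self.name}: target_region must be V/J")
        if not 0 <= self.intronic_tail_len < len(self.sequence_nt):
            raise PrimerError(f"{self.name}: intronic_tail_len out of range")


@dataclass(frozen=True)
class AnnealReport:
    primer_name: str
    aligned: bool
    mismatch_offsets: tuple[int, ...]  # from the primer 3' terminus, ascending
    three_prime_hit: bool
    predicted_amplification: bool
    offset: int  # template start of the primer footprint (plus strand)
    end: int  # template end of the footprint (half-open)

    def __post_init__(self) -> None:
        if self.predicted_amplification != (self.aligned and not self.three_prime_hit):
            raise PrimerError("inconsistent amplification prediction")


def _probe_and_exclusions(primer: Primer, template_kind: str) -> tuple[str, set[int], bool]:
    """Plus-strand probe sequence, excluded probe positions, and whether probe
    index i equals the 3'-offset (True for reverse primers)."""
    if primer.orientation == "reverse":
        probe = revcomp(primer.sequence_nt)
        # primer 5' tail (intronic) maps to the probe's right end
        excluded = (
            set(range(len(probe) - primer.intronic_tail_len, len(probe)))
            if template_kind == "mature_mrna"
            else set()
        )
        return probe, excluded, True
    probe = primer.sequence_nt
    excluded = set()  # forward primers carry no intronic tail
    return probe, excluded, False


def anneal_report(
    primer: Primer,
    template_nt: str,
    template_kind: str = "dna_rearrangement",
    k: int = 3,
    max_total_mismatches: int = 6,
) -> AnnealReport:
    """Predict whether a primer primes on a template.

    The probe is placed ungapped at the offset maximizing matches − mismatches
    over compared positions (probe bases beyond the template ends count as
    mismatches; intron-tail bases are excluded on mature mRNA). Priming fails
    when any mismatch falls within ``k`` bases of the primer 3' terminus or
    the total exceeds ``max_total_mismatches``.
    """
    if not template_nt:
        raise PrimerError("empty template")
    if k < 1:
        raise PrimerError("k must be >= 1")
    if template_kind not in TEMPLATE_KINDS:
        raise PrimerError(f"unknown template_kind {template_kind!r}")

    probe, excluded, probe_is_3prime_first = _probe_and_exclusions(primer, template_kind)
    n, m = len(template_nt), len(probe)
    compared = [i for i in range(m) if i not in excluded]

    best = None  # (score, offset, mismatches)
    for off in range(-m + 1, n):
        score = 0
        mismatches = []
        for i in compared:
            t = off + i
            if 0 <= t < n and template_nt[t] == probe[i]:
                score += 1
            else:
                score -= 1
                mismatches.append(i)
        if best is None or score > best[0]:
            best = (score, off, mismatches)
    assert best is not None
    _, off, mismatch_idx = best

    if probe_is_3prime_first:
        offsets = tuple(sorted(mismatch_idx))
    else:
        offsets = tuple(sorted(m - 1 - i for i in mismatch_idx))
    aligned = len(offsets) <= max_total_mismatches
    three_prime_hit = any(o < k for o in offsets)
    return AnnealReport(
        primer_name=primer.name,
        aligned=aligned,
        mismatch_offsets=offsets,
        three_prime_hit=three_prime_hit,
        predicted_amplification=aligned and not three_prime_hit,
        offset=max(off, 0),
        end=min(off + m, n),
    )


@dataclass(frozen=True)
class PanelVerdict:
    amplifiable: bool
    reports: tuple[AnnealReport, ...]
    passing_forward: tuple[AnnealReport, ...]
    passing_reverse: tuple[AnnealReport, ...]


def panel_screen(
    panel: list[Primer],
    template_nt: str,
    template_kind: str = "dna_rearrangement",
    k: int = 3,
    max_total_mismatches: int = 6,
) -> PanelVerdict:
    """First-step PCR verdict: amplifiable iff at least one forward AND one
    reverse primer are predicted to prime."""
    fwd = [p for p in panel if p.orientation == "forward"]
    rev = [p for p in panel if p.orientation == "reverse"]
    if not fwd or not rev:
        raise PrimerError("panel needs at least one forward and one reverse primer")
    reports = tuple(
        anneal_report(p, template_nt, template_kind, k, max_total_mismatches)
        for p in panel
    )
    by_name = {r.primer_name: r for r in reports}
    passing_f = tuple(by_name[p.name] for p in fwd if by_name[p.name].predicted_amplification)
    passing_r = tuple(by_name[p.name] for p in rev if by_name[p.name].predicted_amplification)
    return PanelVerdict(
        amplifiable=bool(passing_f) and bool(passing_r),
        reports=reports,
        passing_forward=passing_f,
        passing_reverse=passing_r,
    )


def render_annealing(primer: Primer, template_nt: str, report: AnnealReport) -> str:
    """Text rendering of a primer footprint over the template: primer line,
    match bars, template line, with mismatches marked ``*``."""
    probe, excluded, _ = _probe_and_exclusions(primer, "dna_rearrangement")
    off, end = report.offset, report.end
    start_in_probe = 0 if off > 0 or len(probe) <= end - off else len(probe) - (end - off)
    window = template_nt[off:end]
    probe_vis = probe[start_in_probe : start_in_probe + len(window)]
    bars = "".join(
        "|" if a == b else "*" for a, b in zip(probe_vis, window)
    )
    return "\n".join(
        [
            f"{report.primer_name} (plus-strand probe) @ {off}",
            f"primer   {probe_vis}",
            f"         {bars}",
            f"template {window}",
        ]
    )


def load_panel(path: str | Path) -> list[Primer]:
    """Load a primer panel TSV (name, sequence, orientation, target_region,
    intronic_tail_len)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "sequence", "orientation", "target_region", "intronic_tail_len"}
    missing = required - set(df.columns)
    if missing:
        raise PrimerError(f"panel missing columns: {sorted(missing)}")
    return [
        Primer(
            name=row["name"],
            sequence_nt=row["sequence"],
            orientation=row["orientation"],
            target_region=row["target_region"],
            intronic_tail_len=int(row["intronic_tail_len"]),
        )
        for _, row in df.iterrows()
    ]


def load_toy_panel() -> list[Primer]:
    """The packaged IGH V-J consensus panel matched to the toy germline set."""
    return load_panel(packaged_path("primer_panel.tsv"))
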