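"""RNA/DNA concordance of dominant clonotypes, and mechanistic attribution
of discordances.

A sample's single-cell-RNA dominant clonotype and its bulk-DNA amplicon
clonotype are matched on exact CDR3 amino-acid identity (the cross-method
comparison level); gene names are compared at gene level with allele
suffixes stripped, recorded in a separate agreement flag so that a V-gene
naming disagreement between annotation tools does not break a CDR3 match.

Discordances are attributed to the mechanisms that generate them:

* ``nmd_unproductive_absent_in_rna`` — the DNA-dominant rearrangement is
  unproductive with a premature stop codon; its transcript is degraded by
  nonsense-mediated decay and invisible to RNA.
* ``primer_misannealing_absent_in_dna`` — the RNA-dominant rearrangement
  fails the consensus-primer panel (3'-proximal mismatch under every usable
  primer pair) and cannot be amplified from DNA.
* ``light_chain_only_in_rna`` — the RNA-dominant clonotype is defined by a
  light chain only while heavy-chain DNA screening found no productive
  clonotype.

A discordant pair can exhibit several mechanisms at once (the biallelic
case: one allele NMD-degraded in RNA, the other refractory to PCR in DNA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from . import cdr3 as _cdr3
from .germline import packaged_path

REASON_NONE = "none"
REASON_NMD = "nmd_unproductive_absent_in_rna"
REASON_PRIMER = "primer_misannealing_absent_in_dna"
REASON_LIGHT_ONLY = "light_chain_only_in_rna"
REASON_UNKNOWN = "unknown"


class ConcordanceError(ValueError):
    pass


@dataclass(frozen=True)
class MethodCall:
    """Dominant-clonotype call of one method on one sample."""

    sample_id: str
    method: str  # scRNA | bulkDNA
    chain: str
    v_call: str
    j_call: str
    cdr3_aa: str | None
    proportion_pct: float
    productive: bool
    failure_reason: str = _cdr3.FAILURE_NONE

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion_pct <= 100.0:
            raise ConcordanceError(
                f"{self.sample_id}/{self.method}: proportion {self.proportion_pct} outside (0, 100]"
            )


@dataclass(frozen=True)
class ConcordanceRecord:
    sample_id: str
    status: str  # match | discordant
    cdr3_match: bool
    v_gene_agreement: bool
    discordance_reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.status == "match") != self.cdr3_match:
            raise ConcordanceError("status must mirror cdr3_match")


def strip_allele(gene: str) -> str:
    return gene.split("*")[0]


def match_clonotypes(rna: MethodCall, dna: MethodCall) -> ConcordanceRecord:
    """Compare the two methods' dominant clonotypes for one sample: CDR3
    match at exact amino-acid identity, V-gene agreement at gene level."""
    if rna.sample_id != dna.sample_id:
        raise ConcordanceError("calls belong to different samples")
    cdr3_match = bool(rna.cdr3_aa) and bool(dna.cdr3_aa) and rna.cdr3_aa == dna.cdr3_aa
    v_agree = strip_allele(rna.v_call) == strip_allele(dna.v_call)
    return ConcordanceRecord(
        sample_id=rna.sample_id,
        status="match" if cdr3_match else "discordant",
        cdr3_match=cdr3_match,
        v_gene_agreement=v_agree,
        discordance_reasons=() if cdr3_match else (REASON_UNKNOWN,),
    )


def attribute_discordance(
    rna: MethodCall,
    dna: MethodCall,
    rna_sequence_nt: str | None = None,
    panel=None,
    k: int = 3,
    max_total_mismatches: int = 6,
    intron_nt: str | None = None,
) -> tuple[str, ...]:
    """Attribute mechanisms to a discordant RNA/DNA pair (see module notes).

    ``rna_sequence_nt`` is the rearranged DNA sequence underlying the RNA
    dominant clonotype (simulation truth or assembled consensus); with a
    primer ``panel`` it enables the misannealing rule. All applicable
    reasons are returned, in rule order.
    """
    from .germline import JC_INTRON
    from .primers import panel_screen

    reasons: list[str] = []
    if not dna.productive and dna.failure_reason == _cdr3.FAILURE_STOP_CODON and (
        dna.cdr3_aa is None or dna.cdr3_aa != rna.cdr3_aa
    ):
        reasons.append(REASON_NMD)
    if rna.productive and rna.chain == "IGH" and rna_sequence_nt is not None and panel is not None:
        template = rna_sequence_nt + (intron_nt if intron_nt is not None else JC_INTRON)
        verdict = panel_screen(
            panel, template, template_kind="dna_rearrangement", k=k,
            max_total_mismatches=max_total_mismatches,
        )
        if not verdict.amplifiable:
            reasons.append(REASON_PRIMER)
    if rna.chain == "IGK" and not dna.productive:
        reasons.append(REASON_LIGHT_ONLY)
    return tuple(reasons) if reasons else (REASON_UNKNOWN,)


def fraction_correlation(pairs: list[tuple[float, float]]) -> tuple[float, float, int]:
    """Pearson product-moment correlation of paired clonal percentages.

    Returns (r, r_squared, n); requires n >= 3 and nonzero variance on both
    sides.
    """
    if len(pairs) < 3:
        raise ConcordanceError("need at least 3 pairs")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ConcordanceError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r, len(pairs)


def venn_counts(records: list[ConcordanceRecord]) -> tuple[int, int, int]:
    """(shared, RNA-only, DNA-only) counts over sample-level dominant
    clonotypes: each discordant sample contributes one method-exclusive
    clonotype to each side."""
    shared = sum(r.status == "match" for r in records)
    discordant = len(records) - shared
    return shared, discordant, discordant


# ---------------------------------------------------------------------------
# packaged cohort fixture
# ---------------------------------------------------------------------------


def load_table1() -> pd.DataFrame:
    """The packaged 19-sample cohort table: per-sample dominant-clonotype
    calls of both methods, shared CDR3s, and clonal proportions."""
    df = pd.read_csv(
        packaged_path("table1_fixture.csv"),
        dtype={"rna_pct": float, "dna_pct": float},
        keep_default_na=False,
    )
    for col in ("rna_productive", "dna_productive"):
        if df[col].dtype != bool:
            df[col] = df[col].map(lambda v: str(v).strip().lower() == "true")
    return df


def load_cohort_counts() -> dict:
    """Published pooled barcode counts of the cohort."""
    with open(packaged_path("cohort_counts.json")) as fh:
        return json.load(fh)


def table1_method_calls(df: pd.DataFrame | None = None) -> list[tuple[MethodCall, MethodCall]]:
    """Per-sample (scRNA, bulkDNA) call pairs from the packaged fixture."""
    df = load_table1() if df is None else df
    pairs = []
    for _, row in df.iterrows():
        cdr3 = row["common_cdr3_aa"] or None
        rna = MethodCall(
            sample_id=row["sample_id"],
            method="scRNA",
            chain=row["rna_chain"],
            v_call=row["rna_v"],
            j_call=row["rna_j"],
            cdr3_aa=cdr3,
            proportion_pct=row["rna_pct"],
            productive=row["rna_productive"],
        )
        dna = MethodCall(
            sample_id=row["sample_id"],
            method="bulkDNA",
            chain="IGH",
            v_call=row["dna_v"],
            j_call=row["dna_j"],
            cdr3_aa=cdr3 if row["dna_productive"] else None,
            proportion_pct=row["dna_pct"],
            productive=row["dna_productive"],
            failure_reason=row["dna_failure"] or _cdr3.FAILURE_NONE,
        )
        pairs.append((rna, dna))
    return pairs


def cohort_concordance(pairs: list[tuple[MethodCall, MethodCall]]) -> dict:
    """Cohort-level concordance summary: per-sample records, Venn counts,
    V-gene agreement among matches, and the matched-pair R^2."""
    records = [match_clonotypes(rna, dna) for rna, dna in pairs]
    attributed = []
    for (rna, dna), rec in zip(pairs, records):
        if rec.status == "discordant":
            reasons = attribute_discordance(rna, dna)
            rec = ConcordanceRecord(
                sample_id=rec.sample_id,
                status=rec.status,
                cdr3_match=rec.cdr3_match,
                v_gene_agreement=rec.v_gene_agreement,
                discordance_reasons=reasons,
            )
        attributed.append(rec)
    matched = [
        (rna.proportion_pct, dna.proportion_pct)
        for (rna, dna), rec in zip(pairs, attributed)
        if rec.status == "match"
    ]
    r, r2, n = fraction_correlation(matched)
    shared, rna_only, dna_only = venn_counts(attributed)
    return dict(
        records=attributed,
        venn=dict(shared=shared, rna_only=rna_only, dna_only=dna_only),
        n_v_gene_disagreements=sum(
            1 for rec in attributed if rec.status == "match" and not rec.v_gene_agreement
        ),
        pearson_r=r,
        r_squared=r2,
        n_matched=n,
    )
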