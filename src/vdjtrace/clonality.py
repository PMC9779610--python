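"""Per-sample and cohort clonality statistics: dominant clonotype,
pooled percentages, and V/J gene-usage tables.

Percentages are carried at full precision internally and rounded to two
decimals only in written outputs. Per-sample frequencies use cells with at
least one productive chain as the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .caller import ClonotypeResult, sorted_key


class ClonalityError(ValueError):
    pass


@dataclass(frozen=True)
class ClonalityReport:
    sample_id: str
    n_rearranged_cells: int
    dominant_clonotype_id: str
    dominant_frequency_pct: float
    tie_flag: bool
    other_clonotypes_pct: float


@dataclass(frozen=True)
class CohortSummary:
    per_sample_pct: dict[str, float]
    mean_pct: float
    min_pct: float
    max_pct: float
    pooled_pct: float | None


def dominant_clonotype(result: ClonotypeResult, sample_id: str = "sample") -> ClonalityReport:
    """The clonotype with the largest cell count; ties are broken by the
    lexicographically smallest chain key and flagged."""
    if not result.clonotypes:
        raise ClonalityError("no clonotypes in sample")
    best = min(result.clonotypes, key=lambda ct: (-ct.n_cells, sorted_key(ct.chain_keys)))
    tie = sum(ct.n_cells == best.n_cells for ct in result.clonotypes) > 1
    freq = result.frequency_pct(best)
    return ClonalityReport(
        sample_id=sample_id,
        n_rearranged_cells=result.n_cells,
        dominant_clonotype_id=best.id,
        dominant_frequency_pct=freq,
        tie_flag=tie,
        other_clonotypes_pct=100.0 - freq,
    )


def cohort_summary(
    reports: list[ClonalityReport],
    barcode_totals: dict[str, tuple[int, int]] | None = None,
    pooled_counts: tuple[int, int] | None = None,
) -> CohortSummary:
    """Summarize per-sample dominant fractions across a cohort.

    ``barcode_totals`` maps sample_id -> (dominant barcodes, total barcodes)
    and must cover exactly the reported samples; alternatively a pooled
    (dominant, total) pair may be given directly when only aggregate counts
    are known. The pooled percentage is 100 x sum(dominant) / sum(total).
    """
    if not reports:
        raise ClonalityError("no reports")
    per_sample = {r.sample_id: r.dominant_frequency_pct for r in reports}
    if len(per_sample) != len(reports):
        raise ClonalityError("duplicate sample ids in reports")

    pooled = None
    if barcode_totals is not None:
        if set(barcode_totals) != set(per_sample):
            raise ClonalityError("barcode_totals sample set does not match reports")
        dom = sum(d for d, _ in barcode_totals.values())
        tot = sum(t for _, t in barcode_totals.values())
        pooled = 100.0 * dom / tot
    elif pooled_counts is not None:
        dom, tot = pooled_counts
        pooled = 100.0 * dom / tot

    vals = list(per_sample.values())
    return CohortSummary(
        per_sample_pct=per_sample,
        mean_pct=sum(vals) / len(vals),
        min_pct=min(vals),
        max_pct=max(vals),
        pooled_pct=pooled,
    )


def reports_from_percentages(pcts: dict[str, float]) -> list[ClonalityReport]:
    """Minimal reports from published per-sample dominant percentages (used
    when only the printed proportions, not absolute counts, are available)."""
    return [
        ClonalityReport(
            sample_id=sid,
            n_rearranged_cells=0,
            dominant_clonotype_id="dominant",
            dominant_frequency_pct=pct,
            tie_flag=False,
            other_clonotypes_pct=100.0 - pct,
        )
        for sid, pct in pcts.items()
    ]


def report_from_frame(clonotypes: pd.DataFrame, sample_id: str = "sample") -> ClonalityReport:
    """Build a ClonalityReport from a written clonotype table
    (columns clonotype_id, chain_keys, n_cells, frequency_pct)."""
    if clonotypes.empty:
        raise ClonalityError("no clonotypes in sample")
    df = clonotypes.sort_values(["n_cells", "chain_keys"], ascending=[False, True], kind="stable")
    best = df.iloc[0]
    n_total = int(df["n_cells"].sum())
    freq = 100.0 * int(best["n_cells"]) / n_total
    return ClonalityReport(
        sample_id=sample_id,
        n_rearranged_cells=n_total,
        dominant_clonotype_id=str(best["clonotype_id"]),
        dominant_frequency_pct=freq,
        tie_flag=int((df["n_cells"] == best["n_cells"]).sum()) > 1,
        other_clonotypes_pct=100.0 - freq,
    )


def gene_family(gene_name: str) -> str:
    """Gene-name prefix before the first hyphen (IGHV3-30-3 -> IGHV3)."""
    return gene_name.split("-")[0]


def gene_usage(calls: pd.DataFrame) -> dict[str, pd.Series]:
    """V-gene, V-family and J-gene usage counts.

    ``calls`` needs columns ``v_call`` and ``j_call`` (one row per counted
    chain; pass clonotype-level or cell-level rows as appropriate).
    Unparseable gene names are counted under ``unknown`` with a warning.
    """
    for col in ("v_call", "j_call"):
        if col not in calls.columns:
            raise ClonalityError(f"missing column {col!r}")
    if calls.empty:
        empty = pd.Series(dtype="int64")
        return {"v_gene": empty, "v_family": empty.copy(), "j_gene": empty.copy()}

    def clean(series: pd.Series) -> pd.Series:
        bad = series.isna() | (series.astype(str).str.strip() == "")
        if bad.any():
            warnings.warn(f"{int(bad.sum())} unparseable gene names counted as 'unknown'")
        return series.astype(str).where(~bad, "unknown")

    v = clean(calls["v_call"])
    j = clean(calls["j_call"])
    fam = v.map(lambda g: "unknown" if g == "unknown" else gene_family(g))
    return {
        "v_gene": v.value_counts().sort_index().sort_values(ascending=False, kind="stable"),
        "v_family": fam.value_counts().sort_index().sort_values(ascending=False, kind="stable"),
        "j_gene": j.value_counts().sort_index().sort_values(ascending=False, kind="stable"),
    }
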