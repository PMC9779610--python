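"""File formats: FASTQ, AIRR-style rearrangement TSV, truth tables, configs.

All writers are deterministic: stable row ordering and fixed float formatting
(percentages to two decimals). Gzip is auto-detected by the ``.gz`` extension
on FASTQ paths.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import cdr3 as _cdr3
from .caller import ChainCall
from .sim import FastqRead


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _open(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads: list[FastqRead], path: str | Path) -> None:
    with _open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    with _open(path, "r") as fh:
        return [FastqRead(name, seq, qual) for name, seq, qual in FastqGeneralIterator(fh)]


# ---------------------------------------------------------------------------
# AIRR-style rearrangement table
# ---------------------------------------------------------------------------

AIRR_COLUMNS = [
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "consensus_count",
    "umi_count",
]


def chain_calls_to_airr(calls: list[ChainCall]) -> pd.DataFrame:
    rows = [
        dict(
            cell_id=c.barcode,
            locus=c.chain,
            v_call=c.v_call,
            j_call=c.j_call,
            junction=c.cdr3_nt or "",
            junction_aa=c.cdr3_aa or "",
            productive=c.productive,
            consensus_count=c.read_count,
            umi_count=c.umi_count,
        )
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    return df.sort_values(["cell_id", "locus"], kind="stable").reset_index(drop=True)


def write_airr(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column: {missing[0]}")
    df.to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str}, keep_default_na=False)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column: {missing[0]}")
    extra = [c for c in df.columns if c not in AIRR_COLUMNS]
    if extra:
        warnings.warn(f"unknown columns preserved: {extra}")
    if df["productive"].dtype == object:
        df["productive"] = df["productive"].map(
            lambda v: str(v).strip().lower() in ("true", "t", "1")
        )
    for _, row in df.iterrows():
        junction, aa = row["junction"], row["junction_aa"]
        if junction and aa and len(junction) % 3 == 0 and _cdr3.translate_nt(junction) != aa:
            warnings.warn(
                f"{row['cell_id']}/{row['locus']}: junction_aa inconsistent with junction translation"
            )
    return df


# ---------------------------------------------------------------------------
# truth tables, configs
# ---------------------------------------------------------------------------


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cdr3_nt": str}, keep_default_na=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping")
    return cfg


def format_pct(x: float) -> str:
    return f"{x:.2f}"
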