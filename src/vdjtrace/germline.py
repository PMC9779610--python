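"""Germline immunoglobulin segment database.

A small packaged repertoire of heavy-chain (IGH) and kappa light-chain (IGK)
V/D/J segments with conserved-anchor annotations. The anchors are the
clonotype-defining landmarks of the locus: the second conserved cysteine at
the 3' end of every V gene, the conserved tryptophan of heavy-chain J genes
and the conserved phenylalanine of kappa J genes. The CDR3 of a rearranged
receptor spans exactly from the V cysteine codon through the J
tryptophan/phenylalanine codon, so both the simulator and the caller are
driven by these coordinates.

The packaged set is a toy repertoire with realistic segment lengths, not a
mirror of the IMGT reference; it is large enough to express every mechanism
this package models (junctional diversity, hypermutation, ambiguous V
assignment between near-identical paralogs, consensus-primer annealing).

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

VALID_CHAINS = ("IGH", "IGK")
VALID_SEG_TYPES = ("V", "D", "J")

#: residue required at the conserved anchor codon, by (chain, seg_type)
ANCHOR_RESIDUE = {
    ("IGH", "V"): "C",
    ("IGK", "V"): "C",
    ("IGH", "J"): "W",
    ("IGK", "J"): "F",
}

#: Synthetic J–C intron shared by the toy IGHJ genes. In genomic DNA this
#: intron lies immediately 3' of the J exon and carries part of the footprint
#: of the consensus reverse J primers; it is spliced out of mature mRNA.
JC_INTRON = (
    "GTAAGAATGGCCACTCTAGGGCCTTTGTTTTCTGCTACTGCC"
    "TGTGGGGTTTCCTGAGCA"
)

_NT = set("ACGT")


class GermlineError(ValueError):
    """Malformed or inconsistent germline database input."""


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GermlineSegment:
    """One V, D or J gene with its conserved-anchor annotation."""

    name: str
    allele: str | None
    family: str
    chain: str
    seg_type: str
    sequence_nt: str
    anchor_index: int | None
    frame_offset: int

    def __post_init__(self) -> None:
        if self.chain not in VALID_CHAINS:
            raise GermlineError(f"{self.name}: unknown chain {self.chain!r}")
        if self.seg_type not in VALID_SEG_TYPES:
            raise GermlineError(f"{self.name}: unknown seg_type {self.seg_type!r}")
        if not self.sequence_nt or set(self.sequence_nt) - _NT:
            raise GermlineError(f"{self.name}: sequence must be non-empty over ACGT")
        if self.frame_offset not in (0, 1, 2):
            raise GermlineError(f"{self.name}: frame_offset must be in {{0,1,2}}")
        if self.seg_type == "D":
            if self.anchor_index is not None:
                raise GermlineError(f"{self.name}: D segments carry no anchor")
            return
        if self.anchor_index is None:
            raise GermlineError(f"{self.name}: {self.seg_type} segment requires an anchor")
        if self.anchor_index + 3 > len(self.sequence_nt):
            raise GermlineError(f"{self.name}: anchor codon exceeds sequence length")
        residue = translate_codon(self.anchor_codon)
        required = ANCHOR_RESIDUE[(self.chain, self.seg_type)]
        if residue != required:
            raise GermlineError(
                f"{self.name}: anchor codon {self.anchor_codon} translates to "
                f"{residue!r}, expected {required!r}"
            )

    @property
    def anchor_codon(self) -> str:
        assert self.anchor_index is not None
        return self.sequence_nt[self.anchor_index : self.anchor_index + 3]

    def __len__(self) -> int:
        return len(self.sequence_nt)


@dataclass
class GermlineDatabase:
    """Collection of germline segments indexed by name and by (chain, type)."""

    segments: list[GermlineSegment]
    _by_name: dict[str, GermlineSegment] = field(init=False, repr=False)
    _by_group: dict[tuple[str, str], list[GermlineSegment]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.name)
        self._by_name = {}
        self._by_group = {}
        for seg in self.segments:
            if seg.name in self._by_name:
                raise GermlineError(f"duplicate segment name {seg.name!r}")
            self._by_name[seg.name] = seg
            self._by_group.setdefault((seg.chain, seg.seg_type), []).append(seg)

    def __len__(self) -> int:
        return len(self.segments)

    def get(self, name: str) -> GermlineSegment:
        try:
            return self._by_name[name]
        except KeyError:
            raise GermlineError(f"unknown segment {name!r}") from None

    def group(self, chain: str, seg_type: str) -> list[GermlineSegment]:
        """Segments of one chain and type, sorted by name (may be empty)."""
        return list(self._by_group.get((chain, seg_type), []))

    def families(self, chain: str, seg_type: str) -> list[str]:
        return sorted({s.family for s in self.group(chain, seg_type)})


def _parse_header(header: str) -> dict:
    parts = header.split("|")
    if len(parts) != 6:
        raise GermlineError(
            f"malformed header {header!r}: expected "
            "name|allele|chain|seg_type|anchor_index|frame_offset"
        )
    name, allele, chain, seg_type, anchor, frame = parts
    try:
        anchor_index = None if anchor == "-" else int(anchor)
        frame_offset = int(frame)
    except ValueError:
        raise GermlineError(f"malformed header {header!r}: non-integer field") from None
    return dict(
        name=name,
        allele=None if allele == "-" else allele,
        family=name.split("-")[0],
        chain=chain,
        seg_type=seg_type,
        anchor_index=anchor_index,
        frame_offset=frame_offset,
    )


def load_germline_db(path: str | Path) -> GermlineDatabase:
    """Load a germline FASTA with pipe-delimited structured headers.

    Headers follow ``name|allele|chain|seg_type|anchor_index|frame_offset``
    with ``-`` for absent fields (allele, D-segment anchor).
    """
    segments = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        meta = _parse_header(header)
        seq = "".join(chunks).upper()
        segments.append(GermlineSegment(sequence_nt=seq, **meta))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        flush()
    if not segments:
        raise GermlineError(f"{path}: no FASTA records")
    return GermlineDatabase(segments)


def write_germline_db(db: GermlineDatabase, path: str | Path) -> None:
    """Write a canonical germline FASTA: records sorted by name, 60-column wrap."""
    with open(path, "w") as fh:
        for seg in db.segments:
            anchor = "-" if seg.anchor_index is None else str(seg.anchor_index)
            allele = "-" if seg.allele is None else seg.allele
            fh.write(
                f">{seg.name}|{allele}|{seg.chain}|{seg.seg_type}|{anchor}|{seg.frame_offset}\n"
            )
            for i in range(0, len(seg.sequence_nt), 60):
                fh.write(seg.sequence_nt[i : i + 60] + "\n")


def packaged_path(filename: str) -> Path:
    return Path(resources.files("vdjtrace").joinpath("data", filename))  # type: ignore[arg-type]


def load_toy_db() -> GermlineDatabase:
    """Load the packaged toy germline repertoire."""
    return load_germline_db(packaged_path("germline_toy.fasta"))
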