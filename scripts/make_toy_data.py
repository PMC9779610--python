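"""One-off generator for the packaged toy germline FASTA and primer panel.

Run from repo root:  python scripts/make_toy_data.py
Outputs are frozen into src/vdjtrace/data/ and committed as text.

Constraints encoded here:
- V genes: 296 nt (IGH) / 290 nt (IGK), reading frame 0, conserved Cys codon
  at index 288 / 282, no stop codons in frame, a family-specific 20-nt
  framework block at [60, 80) shared by all members of a family (forward
  consensus-primer site for IGH).
- IGHV3-9 is derived from IGHV3-43 by ~10% substitutions (>= 85% identity)
  to exercise ambiguous V assignment.
- J genes: IGHJ 48 nt with conserved Trp codon at index 12 and an identical
  3'-terminal 14-nt block across genes (reverse consensus-primer site);
  IGKJ 45 nt with conserved Phe codon at index 9. No stops in frame from the
  anchor onward.
- D genes: 16-24 nt, no anchor.
- Reverse J primers span the shared J 3' block plus the first bases of the
  synthetic J-C intron (intronic tail at the primer 5' end).
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from vdjtrace.germline import JC_INTRON, load_germline_db  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src" / "vdjtrace" / "data"

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP = [a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in STOPS]

rng = np.random.default_rng(20221210)


def codons(n):
    return "".join(NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n))


def rand_nt(n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_v(length, anchor, family_block):
    """Random stop-free V gene in frame 0 with family block at [60, 80)."""
    n_codons = length // 3
    seq = list(codons(n_codons) + rand_nt(length - 3 * n_codons))
    seq[60:80] = family_block
    # anchor = conserved Cys
    cys = "TGT" if rng.integers(0, 2) else "TGC"
    seq[anchor : anchor + 3] = cys
    s = "".join(seq)
    assert not has_stop(s, 0, anchor + 3)
    return s


def has_stop(seq, frame, upto=None):
    upto = len(seq) if upto is None else upto
    for i in range(frame, upto - 2, 3):
        if seq[i : i + 3] in STOPS:
            return True
    return False


def family_block():
    """20-nt codon-aligned stop-free framework block; last dinucleotide avoids
    starting a stop codon regardless of the following base."""
    while True:
        blk = codons(6) + rand_nt(2)
        if blk[18] != "T":
            return list(blk)


def mutate_paralog(seq, n_mut, protected):
    s = list(seq)
    mutated = 0
    while mutated < n_mut:
        pos = int(rng.integers(0, len(s)))
        if pos in protected:
            continue
        new = BASES[rng.integers(0, 4)]
        if new == s[pos]:
            continue
        old = s[pos]
        s[pos] = new
        cstart = 3 * (pos // 3)
        if "".join(s[cstart : cstart + 3]) in STOPS:
            s[pos] = old
            continue
        mutated += 1
    return "".join(s)


def make_ighj(shared_tail):
    """48-nt IGHJ: random 5' region, Trp anchor at 12, shared 3' 14-nt block."""
    while True:
        seq = list(rand_nt(12) + "TGG" + codons(11))
        seq[34:48] = shared_tail
        s = "".join(seq)
        if not has_stop(s, 12):
            return s


def make_igkj():
    """45-nt IGKJ: random 5' region, Phe anchor at 9."""
    while True:
        phe = "TTT" if rng.integers(0, 2) else "TTC"
        s = rand_nt(9) + phe + codons(11)
        if not has_stop(s, 9):
            return s


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def main():
    fam_blocks = {f: family_block() for f in ["IGHV1", "IGHV3", "IGHV4", "IGHV5"]}

    records = []  # (name, allele, chain, seg_type, anchor, frame, seq)

    def add(name, chain, seg_type, anchor, seq):
        records.append((name, "*01", chain, seg_type, anchor, 0, seq))

    # --- IGHV ---
    add("IGHV1-18", "IGH", "V", 288, make_v(296, 288, fam_blocks["IGHV1"]))
    v343 = make_v(296, 288, fam_blocks["IGHV3"])
    add("IGHV3-43", "IGH", "V", 288, v343)
    protected = set(range(60, 80)) | set(range(288, 291))
    v39 = mutate_paralog(v343, 30, protected)
    ident = sum(a == b for a, b in zip(v343, v39)) / len(v343)
    assert ident >= 0.85, ident
    add("IGHV3-9", "IGH", "V", 288, v39)
    add("IGHV3-23", "IGH", "V", 288, make_v(296, 288, fam_blocks["IGHV3"]))
    add("IGHV4-39", "IGH", "V", 288, make_v(296, 288, fam_blocks["IGHV4"]))
    add("IGHV5-51", "IGH", "V", 288, make_v(296, 288, fam_blocks["IGHV5"]))

    # --- IGHD ---
    add("IGHD2-2", "IGH", "D", None, rand_nt(16))
    add("IGHD3-3", "IGH", "D", None, rand_nt(20))
    add("IGHD3-9", "IGH", "D", None, rand_nt(24))

    # --- IGHJ (shared 3' block for consensus reverse primers) ---
    # The block occupies J positions [34, 48); in-frame codons start at block
    # offsets 2, 5, 8, 11. Stop codons all start with T, so banning T at those
    # offsets keeps every fully-shared codon stop-free.
    while True:
        tail = list(rand_nt(14))
        if all(tail[i] != "T" for i in (2, 5, 8, 11)):
            break
    j_genes = {}
    for name in ["IGHJ4", "IGHJ5", "IGHJ6"]:
        j_genes[name] = make_ighj(tail)
        add(name, "IGH", "J", 12, j_genes[name])
    tails = {s[34:] for s in j_genes.values()}
    assert len(tails) == 1

    # --- IGKV / IGKJ ---
    kblock = family_block()
    for name in ["IGKV1-33", "IGKV3-20", "IGKV4-1"]:
        add(name, "IGK", "V", 282, make_v(290, 282, kblock))
    for name in ["IGKJ1", "IGKJ3"]:
        add(name, "IGK", "J", 9, make_igkj())

    OUT.mkdir(parents=True, exist_ok=True)
    fa = OUT / "germline_toy.fasta"
    with open(fa, "w") as fh:
        for name, allele, chain, seg_type, anchor, frame, seq in sorted(records):
            a = "-" if anchor is None else anchor
            fh.write(f">{name}|{allele}|{chain}|{seg_type}|{a}|{frame}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    db = load_germline_db(fa)  # validates every invariant
    assert len(db.group("IGH", "V")) >= 5
    assert len(db.group("IGH", "D")) >= 3
    assert len(db.group("IGH", "J")) >= 3
    assert len(db.group("IGK", "V")) >= 3
    assert len(db.group("IGK", "J")) >= 2

    # --- primer panel: per-family forward primers + two reverse J primers ---
    jt = j_genes["IGHJ4"]  # 3' block shared across IGHJ genes
    rows = []
    for fam in ["IGHV1", "IGHV3", "IGHV4", "IGHV5"]:
        rows.append((f"{fam}-FR", "".join(fam_blocks[fam]), "forward", "V", 0))
    rows.append(("IGH-J-A-1", revcomp(jt[38:48] + JC_INTRON[:8]), "reverse", "J", 8))
    rows.append(("IGH-J-A-2", revcomp(jt[36:48] + JC_INTRON[:6]), "reverse", "J", 6))
    with open(OUT / "primer_panel.tsv", "w") as fh:
        fh.write("name\tsequence\torientation\ttarget_region\tintronic_tail_len\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")

    print("wrote", fa)
    print("IGHV3-43 / IGHV3-9 identity:", round(ident, 3))


if __name__ == "__main__":
    main()
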