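# vdjtrace

Single-cell V(D)J clonotype calling, bulk-amplicon concordance analysis and
in silico minimal-residual-disease (MRD) tracking for plasma-cell
dyscrasias.

Every multiple-myeloma patient's malignant plasma cells share one unique
rearranged immunoglobulin sequence: a V(D)J junction whose trimming,
untemplated N-nucleotides and somatic hypermutation make it effectively
clone-specific. That CDR3 sequence is the disease's molecular barcode.
`vdjtrace` implements, as a tested pipeline with its own synthetic-data
generator, the analysis that exploits it:

* **clonotype calling from barcoded reads** — UMI/barcode consensus
  building, V/J gene assignment by semi-global alignment, CDR3 delimitation
  between the conserved V-cysteine and J-tryptophan/phenylalanine anchors,
  productivity classification, and grouping of cells by exact CDR3
  nucleotide identity (paired heavy+light or single-chain keys);
* **clonality statistics** — dominant clonotype per sample, pooled cohort
  percentages, V/J gene-usage tables;
* **RNA/DNA concordance** — matching single-cell-RNA dominant clonotypes
  against bulk-DNA amplicon clonotypes on CDR3 amino acids, with mechanistic
  attribution of discordances: nonsense-mediated decay of stop-codon
  rearrangements (visible in DNA, absent from RNA), consensus-primer 3'
  misannealing (visible in RNA, refractory to PCR from DNA), and
  light-chain-only clonotypes;
* **primer screening** — an ungapped annealing model predicting first-step
  PCR failure from mismatches within the primer's 3'-terminal window;
* **MRD spike-in validation** — dilution of a few known clonal cells into a
  thousands-of-cells polyclonal background and recovery of the target
  clonotype by exact CDR3-key match.

The repertoire simulator is first-class, tested code: it generates clonal +
polyclonal samples (junctional diversity, somatic hypermutation,
unproductive alleles, NMD dropout in RNA, primer-killing mutations in DNA),
barcoded/UMI-tagged FASTQ reads, and bulk-DNA amplicons under a
consensus-primer PCR model. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
import vdjtrace as vt

db = vt.load_toy_db()                     # packaged toy germline repertoire
cfg = vt.SimConfig(n_cells=200, clonal_fraction=0.8, seed=11)
cells, truth, reads = vt.simulate_reads(db, cfg)
calls, clonotypes, _ = vt.call_sample(reads, db)
report = vt.dominant_clonotype(clonotypes, "demo")
print(f"cells called      : {clonotypes.n_cells}")
print(f"dominant clonotype: {report.dominant_clonotype_id} "
      f"at {report.dominant_frequency_pct:.2f}%")
dom = clonotypes.clonotypes[0]
heavy = next(c for c in calls if c.barcode in dom.barcodes and c.chain == "IGH")
print(f"heavy chain       : {heavy.v_call}/{heavy.j_call}  CDR3 {heavy.cdr3_aa}")

summary = vt.cohort_concordance(vt.table1_method_calls())
print(f"venn              : {summary['venn']}")
print(f"R^2 (17 pairs)    : {summary['r_squared']:.4f}")
```

prints

```
cells called      : 200
dominant clonotype: clonotype-1 at 80.00%
heavy chain       : IGHV5-51/IGHJ4  CDR3 CYRSIGFRISSW
venn              : {'shared': 17, 'rna_only': 2, 'dna_only': 2}
R^2 (17 pairs)    : 0.1934
```

The simulated sample's 160 clonal cells are recovered as a dominant
clonotype at exactly 80% of called cells, with the clone's heavy-chain gene
assignment and CDR3. The cohort summary comes from the packaged 19-sample
comparison table: 17 of 19 samples give identical dominant clonotypes by
both assays, each discordant sample contributes one method-exclusive
clonotype per side, and the clonal fractions of the 17 matched pairs
correlate only weakly between assays (R² ≈ 0.19) — single-cell fractions
run systematically higher than bulk read fractions.

A command-line surface wraps the same functions:

```bash
vdjtrace simulate --seed 7 --n-cells 200 --out-dir run/
vdjtrace call --fastq run/reads.fastq --out-dir run/
vdjtrace clonality --clonotypes run/clonotypes.csv --out run/report.csv
vdjtrace compare --fixture table1 --out run/concordance.json
vdjtrace dilute --seed 7 --out-dir run/mrd/
vdjtrace detect --fastq run/mrd/virtual.fastq --truth run/mrd/truth.tsv \
    --target-key run/mrd/target_key.json --out-dir run/mrd/
```

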