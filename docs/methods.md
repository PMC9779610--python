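# Methods

`vdjtrace` models the identification and tracking of patient-specific
immunoglobulin V(D)J rearrangements in plasma-cell dyscrasias, comparing a
single-cell RNA route (barcoded transcript reads → per-cell chain calls →
clonotypes) with a bulk-DNA route (consensus-primer PCR → amplicon
clonotypes), and validating clonotype tracking by in silico spike-in
dilution. This note records the models, the defaults and why, and what the
synthetic data does and does not represent.

## Germline model

The packaged repertoire is a toy stand-in for the IMGT reference: 6 IGHV,
3 IGHD, 3 IGHJ, 3 IGKV and 2 IGKJ segments with realistic lengths (V 290–296
nt, D 16–24 nt, J 45–48 nt). Each V carries its conserved second cysteine
codon near the 3' end; IGH J genes carry the conserved tryptophan codon and
IGK J genes the conserved phenylalanine. Coordinates are 0-based, half-open
throughout. Two design features exist specifically to exercise failure
modes observed in real cohorts:

* **Near-identical paralogs.** IGHV3-9 is derived from IGHV3-43 at 90%
  nucleotide identity, so that hypermutated queries can fall between the two
  and trigger ambiguous assignment — the situation in which two annotation
  tools report different best V genes for the same clonotype.
* **Conserved primer blocks.** All members of a V family share a 20-nt
  framework block (the forward consensus-primer site), and all IGHJ genes
  share their 3'-terminal 14 nt plus a synthetic 60-nt J–C intron (the
  reverse-primer site). The two packaged reverse primers overlap such that
  one J mutation at a shared 3'-window position abolishes both, reproducing
  the single-substitution PCR escape mechanism.

Alleles are carried as labels (`*01`) but all cross-method gene comparison is
done at gene level with allele suffixes stripped, since different annotation
pipelines resolve alleles differently.

## Rearrangement and mutation model

Rearrangements are assembled as trimmed-V + N1 + trimmed-D + N2 + trimmed-J
(IGK omits D and N2). Trim lengths are uniform on [0, `max_trim`=6] per
junction end, insert lengths uniform on [0, `max_insert`=8], inserted bases
uniform over ACGT. This is the simplest documented junction model; it is not
calibrated to empirical trim/insert distributions, but it produces
junction-unique CDR3s, which is the property everything downstream relies
on.

Somatic hypermutation is independent per-base substitution at `shm_rate`
(default 0.05, the order of magnitude seen in post-germinal-center myeloma
clones; supported range [0, 0.15]). Mutated bases never equal the original;
no indels. When the sample simulator draws rearrangements it exempts
conserved positions (anchor codons, the framework primer block, the J 3'
block) from mutation. This encodes purifying selection on frameworks rather
than SHM mechanism — uniform SHM would destroy a consensus-primer site in a
quarter of simulated samples, whereas the clinical observation this package
models is that such escapes are rare, single-sample events. Engineered
primer-site mutations are introduced explicitly by the scenario builders.
`apply_shm` called directly applies unprotected uniform mutation.

Productivity follows the standard definition: both anchors present and
intact, CDR3 nucleotide length divisible by three, and no stop codon in the
translated V-through-J region, with failure precedence
missing_anchor > out_of_frame > stop_codon.

**Expressed chains are productive by default.** Every simulated cell
resamples its expressed heavy and light rearrangement until productive,
mirroring allelic exclusion: a surviving plasma cell expresses a productive
receptor. Unproductive rearrangements enter through the explicit
second-allele machinery (biallelic scenario) or by disabling
`polyclonal_productive_only`. Without this choice the dominant-clonotype
denominator (cells with ≥1 productive chain) would systematically exclude
about half the polyclonal background and inflate clonality estimates by far
more than the ±3-percentage-point recovery tolerance the package tests.

## Transcription, NMD, and reads

In deterministic NMD mode (default) a rearrangement whose failure is a
premature stop codon yields zero transcripts; out-of-frame rearrangements
without stops are transcribed, because nonsense-mediated decay recognizes
premature termination codons, not reading frame. A probabilistic mode drops
each stop-codon transcript molecule with probability `p_nmd` for sensitivity
analysis. NMD efficiency is not quantified in the literature this package
follows; the deterministic default encodes the qualitative claim only.

Reads are single-end emulations of a 5' library: each of `umis_per_cell`=4
molecules per surviving chain yields `reads_per_umi`=3 reads of
`read_length`=450 nt starting at the transcript 5' end (i.e. spanning the
whole ~370-nt V(D)J transcript, as assembled contigs do; reads longer than
the transcript are truncated and flagged), with i.i.d. substitution errors
at `seq_error_rate`=0.005. Real sequencing depth (~15,000 reads/cell) is not
emulated; 4×3 is the smallest design that exercises both consensus stages.
Cell barcodes are 16-mers drawn without replacement, so barcode collisions
within a sample are impossible by construction. No PCR chimeras, GEM
doublets or ambient RNA are simulated.

All randomness derives from `SimConfig.seed` through fixed named streams;
identical configurations give byte-identical FASTQ.

## Calling path

Reads are collapsed per UMI by per-position plurality vote (ties to the
alphabetically first base), UMI consensuses are assigned to IGH or IGK by a
shared-12-mer word score against each chain's V set (the chains share no
12-mers in the toy repertoire), and per-barcode, per-chain consensuses are
voted the same way. Chains with fewer than `min_umis`=2 UMIs are dropped and
logged.

V and J genes are assigned by semi-global alignment — germline aligned
end-to-end, free end gaps on the consensus side only — under match +1,
mismatch −1, gap −2 (config-exposed). The scorer is a numba-compiled DP
kernel batched over all consensuses of a sample; a brute-force Python DP
serves as its oracle in the test suite. Ties break to the lexicographically
smallest gene name and are flagged; any winning margin below
`ambiguity_margin`=5 is flagged ambiguous. D segments are never assigned —
they are too short for reliable assignment — and exist only in simulation
truth.

CDR3s span the V cysteine codon through the J tryptophan/phenylalanine
codon inclusive, located by mapping germline anchor coordinates through a
gapless placement of the assigned segments on the consensus (SHM introduces
no indels, so anchor mapping is a gapless problem; the placement allows
overhang for truncated templates such as amplicons). A mutated or absent
anchor codon is classified `missing_anchor`.

Clonotypes group cells by the exact set of their productive CDR3
*nucleotide* sequences — paired IGH+IGK keys when both chains are
productive, single-chain keys otherwise, which is what makes light-chain-only
dominant clonotypes representable. Cells with zero productive chains are
excluded from the frequency denominator and reported separately.
Cross-method comparison, by contrast, is done on CDR3 *amino acids*, the
level at which the two assays' outputs are published side by side; exact
nucleotide matching is available as a strict option via the keys themselves.

## Bulk-DNA route

`simulate_bulk_amplicon` screens every heavy-chain rearrangement (DNA
template = rearrangement + J–C intron; NMD does not apply) against the
primer panel: amplifiable iff ≥1 forward and ≥1 reverse primer pass the
annealing model. The annealing model is ungapped placement at the
best-scoring offset; priming fails when any mismatch falls within `k`=3
bases of the primer 3' terminus (the standard PCR heuristic; the documented
escape case is the terminal base, inside any k ≥ 1) or when total mismatches
exceed 6. On mature-mRNA templates the reverse primers' intronic tail —
carried at the primer 5' end, annealing 3' of the J exon on the template —
is excluded from comparison, since the intron is spliced out. Indels under
a primer are treated as alignment failure; no melting-temperature or
multiplex-competition modeling.

Amplified rearrangements contribute reads proportional to their cell
counts, error-free: the mechanism under study is primer annealing, not bulk
sequencing noise. The bulk clonotyper annotates amplicons with the same
assignment/CDR3 machinery and reports read proportions — a deliberately
simplified stand-in for a dedicated repertoire analysis tool.

## MRD dilution design

The spike-in experiment draws 5 target-clonotype barcodes uniformly without
replacement from a simulated clonal source sample (40 cells, 80% clonal)
and concatenates their reads with a 3180-cell background pooled from 13
simulated samples (sizes 245/244). Background samples keep their own
dominant clonotypes (clonal fraction 0.5 each), so the target clone ranks
far below the top — the detector must match the exact CDR3 nucleotide key,
not rely on dominance. Spiked barcodes colliding with background barcodes
are re-coded deterministically and logged. Detection reports recovered
spiked barcodes, false positives (barcodes matching the key but not
spiked), sensitivity, and the target's abundance rank. Fuzzy (Hamming-1)
CDR3 rescue is deliberately absent from the default path.

The raw reads of each spiked barcode are diluted (not barcode-filtered
reads); with 2+ surviving UMIs per chain the consensus caller absorbs the
read-level noise.

## Cohort fixture

The packaged 19-sample table carries each sample's dominant-clonotype call
from both assays (V/J genes, shared CDR3 amino acids, clonal proportions),
including the two discordant samples: the biallelic case (RNA-productive
rearrangement at 98.08% vs DNA-only stop-codon rearrangement at 78%) and
the light-chain-only case (IGK clonotype at 79% vs unproductive IGH at
29.97%). One proportion is printed at low precision in the source (79%) and
is stored as 79.00. Per-sample absolute barcode counts were not published;
only the pooled counts (53,935 dominant / 61,022 total) are packaged, so
pooled clonality is computed from the aggregate pair.

## Numerical and formatting conventions

Percentages are stored as printed values (99.44 means 99.44%), never as
fractions, and written to two decimals while kept at full precision
internally. Clonotype and rank orderings are total (count descending, then
lexicographic key), so outputs are deterministic. Pearson correlation uses
`scipy.stats.pearsonr` and is reported with its square; zero-variance input
is an error rather than a NaN.

## Problem sizes and limitations

Default test-time problem sizes — 500-cell samples for parameter recovery,
the full 3185-barcode design for dilution — were chosen as the smallest
scales at which the tested properties are meaningful. The simulator's
simplifications (uniform junction model, uniform SHM outside protected
blocks, no doublets/chimeras/ambient RNA, toy germline set) mean that
passing tests demonstrate the correctness of the calling and comparison
logic under the modeled generative process, not performance on real
sequencing data; in particular, V-assignment ambiguity rates and absolute
barcode yields are properties of the real reference and depth and are not
reproduced here.
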