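# venomine

Transcriptome-to-proteome discovery of cysteine-rich venom toxins.

Spider venom glands express toxin precursors as large homologous families.
A single-pass cDNA (EST) library captures them as short reads; the toxins
themselves are small, disulfide-stabilized peptides whose hallmark is a
conserved arrangement of cysteines. `venomine` mines such reads for toxin
precursors, processes them into candidate mature peptides, organises the
peptides into cysteine families, and validates them against bottom-up
proteomics of the venom digested with up to four proteases.

## What it computes

**SRDA motif search.** Each translated read is reduced by single-residue
distribution analysis (SRDA) to its cysteine skeleton: `AACCAAC.` becomes
`2CC2C.` (spacer lengths, `C`s and the stop symbol `.`). Toxin frameworks
are found with formulas over that line, e.g. the 6-cysteine inhibitor-
cystine-knot motif

```
C6C*CC*C*C#.
```

where a digit is an exact spacer length, `#` one spacer of 1–9 residues (or
nothing right before the stop), `*` a gap absorbing any tokens, and `.` the
stop. Eight motifs (general, extended and partial variants) are applied in
precedence order; each read counts toward the first motif that matches any
of its six frames ("impact" accounting).

**Precursor processing.** Candidate ORFs are segmented into signal peptide
(built-in hydrophobicity heuristic, or ingested external predictions; the
initiator Met is the nearest one 20–27 residues upstream of the cleavage
site), a propeptide ending in an `XXKR`/`XXRR` quadruplet before the first
cysteine, and the mature chain. C-terminal processing is enumerated
exhaustively: carboxypeptidase trimming of up to two basic residues and
conversion of an exposed C-terminal Gly into an amide (−0.984 Da).

**Families and subfamilies.** Mature toxins are binned by cysteine count
(6C / 8C / 9C / 10C), clustered into subfamilies by single-linkage on
global-alignment identity (default ≥ 0.70), each subfamily's dominant
sequence is the unique transcript-count maximum, and per-position residue
frequency matrices with information content summarize family alignments.

**Proteomic validation.** The mature-variant database is digested in silico
with trypsin, Lys-C, Glu-C and Asp-N (≤ 4 missed cleavages, I/L collapsed);
PSM tables are filtered to 1% FDR by the target-decoy rule; a toxin is
unambiguously identified when at least one of its unique peptides is
observed; per-toxin coverage, isoform choice, five-way C-terminal amidation
evidence (confirmed by unique / by shared peptide, ambiguous, not amidated,
undefined) and protease-set Venn comparisons complete the report.

A ground-truth-labeled synthetic data generator (`venomine.synthetic`)
emulates the whole study — precursor-bearing EST reads with a realistic
length profile, family mix, processing cassettes and sequencing errors, plus
decoy-containing multi-protease PSM tables — so every stage is testable
without any external download.

## Worked example

```
$ venomine synth --seed 3 --out synth
300 reads, 42 toxins, 590 target + 295 decoy PSMs

$ venomine translate --fasta synth/reads.fasta --out tr
300 reads, median length 454 nt, 673 ORFs

$ venomine srda --fasta synth/reads.fasta --out sr
210 toxin-candidate reads of 300

$ venomine precursors --orfs tr/orfs.tsv --out pr
656 precursors, 505 unique CDS

$ venomine families --mature synth/mature_variants.fasta --out fam
42 toxins organised

$ venomine validate --db synth/mature_variants.fasta --psms synth/psms.tsv --out val
590/885 PSMs accepted at 1% FDR; 36/42 toxins uniquely identified; 0 unmatched PSMs
```

Reading the numbers: of 300 synthetic reads, 210 carry a cysteine framework
(the 165 planted toxin reads plus error reads still matching partial
motifs); the median read length tracks the configured 457 nt profile;
segmentation of every candidate ORF and deduplication of identical coding
sequences yield the unique precursor set; and validation accepts exactly the
high-scoring target PSMs (885 = 590 targets + 295 decoys) and uniquely
identifies the 36 toxins planted in the synthetic venom. Per-read, per-toxin
and per-peptide detail lands in the TSV files under each `--out` directory.

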