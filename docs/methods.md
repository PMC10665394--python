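# Methods

## Scope and model

`venomine` implements a transcriptome-to-proteome workflow for cysteine-rich
venom peptides. The underlying biological model: venom-gland transcripts
encode precursors of the form

```
Met — signal peptide — propeptide — mature chain [— GR/GKR cassette] — stop
```

where the propeptide (when present) ends in a quadruplet `XXKR` or `XXRR`
cleaved by the precursor-processing protease, and the mature chain is a
small peptide whose cysteines form a conserved framework (most commonly the
inhibitor cystine knot). After translation, carboxypeptidases may remove
C-terminal basic residues and peptidylglycine-alpha-amidating monooxygenase
may convert an exposed C-terminal Gly into an amide on the preceding
residue. Reads are treated as independent transcripts; no assembly is
performed, which preserves the per-transcript variant structure that family
and dominant-sequence analysis depends on.

## SRDA and the motif language

A protein segment maps to a token string: `C` per cysteine, one spacer
token per maximal non-Cys run (length attached; `X` counts as an ordinary
residue and never as Cys), and a terminal STOP for the stop symbol, which
is `.` in all internal amino-acid strings. Formulas are parsed into tokens
`C`, exact-spacer literals (multi-digit, so `C16C` never satisfies `C6C` —
matching is token-level, not substring-level), `#` (one spacer of 1–9, or
the empty tail directly before STOP: "digit 0" means no trailing residues),
`n … (n≠k)` (one spacer of any length except k) and `*`.

`*` is interpreted broadly: it may absorb any run of C/spacer tokens,
including extra cysteines. This is the reading under which the 8-Cys
formula is contained in the 6-Cys one (and the `n≠6` pair likewise), which
matches how the general motifs dominate classification counts; a narrow
single-spacer `*` is available as a switch (`star_spans_cys=False`).
Matching compiles patterns to regular expressions over an unambiguous token
serialization (`<n>` per spacer), with non-greedy quantifiers so reported
spans are leftmost-shortest; a backtracking window enumerator serves as the
test oracle for star-free patterns.

Classification applies the eight bundled motifs in table order to all six
frame translations of each read (frames are split at stops into
stop-terminated segments before encoding; no motif token can span a stop,
so this is equivalent to matching the full line). The first motif that
matches anywhere wins and the read counts once toward that motif's impact;
extended/partial hits are flagged as requiring external homology
verification but are not removed — homology search against reference
databases is out of scope.

## Precursor segmentation

The built-in signal predictor scores candidate cut sites 15–35 as
0.7 × (mean Kyte–Doolittle hydropathy of the 8 upstream residues, scaled to
[0,1]) + 0.15 per small residue (A, G, S, C, T) at −1 and −3, threshold 0.5.
It is a deliberately simple stand-in with the right qualitative behaviour
(hydrophobic core + small-residue cleavage context); externally produced
predictions can be ingested from TSV and take precedence. The initiator Met
is the nearest one 20–27 residues upstream of the cleavage site, falling
back to 15–35; with no Met in either window the sequence is partial. The
mature chain starts after the most C-terminal `XXKR`/`XXRR` quadruplet that
precedes the first downstream cysteine (processing sites precede the first
half-cystine in these peptides); `X` residues disqualify a quadruplet.

Variant enumeration emits the untrimmed mature chain, then up to two
successive carboxypeptidase removals of trailing K/R (a depth of two covers
the canonical `…G-K-R` amidation cassette while keeping the list small;
configurable), and an amidated variant (Gly dropped, flag set) for every
intermediate ending in Gly. Amidation is a boolean flag plus a −0.98402 Da
metadata constant, never a sequence character.

## Families, subfamilies, consensus

Families are defined purely by the mature chain's cysteine count (6C, 8C,
9C, 10C; everything else "other"; an odd count flags an unbound cysteine).
Subfamilies are single-linkage components at global pairwise identity ≥
0.70 — identity is matches / alignment length under match +1, mismatch 0,
gap −1, computed on mature chains only. The threshold is a tunable default:
no principled value exists for "highly homologous", and downstream subfamily
counts are calibration outputs of this knob, not fixed truths. The bundled
center-star aligner (center = highest summed identity; merge under
once-a-gap-always-a-gap) is intentionally modest — it feeds frequency
matrices, and progressive-alignment quality is a non-goal. Information
content per column is log2(20) − H − (19)/(2 ln 2 · n) bits (small-sample
corrected, clipped to [0, log2 20]); gaps are counted but carry no
information.

## Proteomic validation

Protease rules: trypsin C-terminal to K/R with the no-cut-before-P
exception on by default; Lys-C after K; Glu-C after E ({E,D} by config);
Asp-N before D. Digestion enumerates all peptides spanning ≤ 4 missed
cleavages; the 0-missed set partitions the protein. Peptides are pooled
across the variant database with I/L collapsed (mass-indistinguishable;
default on) and parents recorded at the toxin-group level, so isoforms of
one toxin do not destroy uniqueness. Uniqueness statistics use length ≥ 5
and 0 missed cleavages; observed peptides are accepted at any length.

The FDR filter accepts all target PSMs above the most permissive score
threshold t with (#decoys ≥ t)/(#targets ≥ t) ≤ α, ties included — the
threshold that maximizes accepted identifications while bounding the decoy
estimate, as is standard for target-decoy filtering.

Identification merges replicates and proteases by union. A toxin group is
`unique_identified` with ≥ 1 observed unique peptide, `group_evidence_only`
with shared peptides only. Coverage is the union of mapped peptide
intervals over the chosen isoform's length, computed for unique-only and
for all peptides. Isoform choice: unique evidence first, then highest
unique coverage, then highest overall coverage, then lexicographic id.

C-terminal peptides are indexed under both amidation states (amidation is a
variable modification in practice), and observed-peptide matching ignores
every modification except C-terminal amidation, which must agree. Evidence
for a toxin counts accepted PSMs of amidated and plain forms of all
C-terminal peptides mapping to its group: none observed → undefined; both
forms → ambiguous; amidated only → confirmed (via a unique peptide, or only
at group level via a shared one); plain only → not amidated. A peptide is
"C-terminal" if it ends any variant of the group — including trimmed
variants, so e.g. observing `…CNTG` plain is treated as C-terminal
(un-amidated) evidence.

## Synthetic data: what it emulates, what it does not

The generator plants complete ground truth and self-validates every
artifact against the pipeline stage it exercises before returning.

Study conditions (defaults, chosen once): 165 toxin + 90 non-toxin + 45
error reads = 300, following the observed partition of a venom-gland EST
library into framework-bearing, annotatable-other and erroneous reads;
log-normal read lengths with median 457 nt (σ = 0.25 in log space); family
mix proportional to 45 : 97 : 2 : 35 (6C : 8C : 9C : 10C); signal peptides
18–25 aa (Met + polar n-region + hydrophobic core + c-region with small
residues at −1/−3); propeptides 6–14 aa of polar residues ending in a
quadruplet; mature skeletons drawn to satisfy the family's general motif
with spacers 1–9 (tails 1–5, so a processing cassette never pushes the tail
spacer past the single-digit `#` token); cassette probabilities
none/GR/GKR = 0.60/0.15/0.25, assigned to subfamilies by largest-remainder
quota so the realized amidation-predicted fraction (≈ 0.2 of toxins,
matching the study scale this emulates) is stable at any size. Subfamilies
are point-substituted variants of a consensus (each member carries 1–2
private substitutions outside the shared C-terminal region), giving
within-subfamily identity ≥ 0.9, between ≪ 0.7, one dominant member with a
higher transcript count, and guaranteed per-member unique peptides.

PSM tables digest a sampled toxin subset (85%) with all four proteases,
emit replicate-1 peptides deterministically and replicate-2 with
probability 0.7, score targets ~ N(10, 1) and reversed-sequence decoys
~ N(10 − 6, 1) (the two-component Gaussian makes FDR behaviour analytically
checkable), and realize C-terminal amidation evidence per toxin. Amidation
categories are assigned per C-term-sharing cluster — toxins whose C-termini
can yield a common observable peptide must share a category, which mirrors
why real shared C-termini can only ever be confirmed at the group level —
with the five categories covered greedily across clusters.

Deliberate non-realism: uniform synonymous codons (no stage is
codon-aware); no chromatogram-style error model (one indel or premature
stop per error read); spacer residues are i.i.d. uniform, so between-family
sequence similarity is far below real venom paralog similarity; signal
peptides are rejection-sampled to be recoverable by the built-in heuristic,
so 100% segmentation recovery on synthetic data demonstrates the
segmentation logic, not the accuracy of the signal heuristic on real
precursors (reproducing real counts requires ingesting external
predictions); embeddings are redrawn when UTR junk in another frame would
steal motif precedence, so classification accuracy on synthetic reads
likewise validates precedence accounting, not robustness to adversarial
frames. Passing tests therefore certify the algorithms' correctness on data
satisfying the model's assumptions, not performance on real libraries.

## Numerical and degenerate-input choices

Frames are numbered 1–3 forward / 4–6 reverse-complement by offset; all
coordinates 0-based half-open. Codons containing N translate to `X`;
trailing partial codons are trimmed. ORF detection reports, per stop-bounded
segment, the ORF from the first Met (all nested starts by option), minimum
protein length 40 aa — below the ~100 aa of a full precursor because
partial reads must pass. Reads shorter than one codon, empty FASTA entries,
ragged alignments, and empty proteins raise; a too-short protein for signal
prediction returns "no signal" rather than raising. `dedup_cds` and
`cluster_subfamilies` order their output by (size, lexicographic id), so
results are independent of input order. Ties in transcript counts mean no
dominant sequence. With no feasible FDR threshold (or no targets) the
filter returns the empty set.

## Known limitations

The signal-peptide heuristic is not a trained predictor; external
predictions should be ingested for real data. The center-star aligner is
not suitable for divergent families. BLAST-style verification of
extended/partial motif hits, spectral searching, mass-tolerance matching
and disulfide-connectivity prediction are out of scope: the package
consumes post-search PSM tables and stops at sequence-level evidence.
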