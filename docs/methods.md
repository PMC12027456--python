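# Methods

## Coordinate and sequence conventions

All genomic intervals are 1-based inclusive (the GFF3/VCF convention);
BED output is 0-based half-open. Sequences are uppercased on input; `N` is
allowed everywhere except inside primers and protospacers. Analyses run on
the stored '+' orientation of the locus segment; the gene strand is
applied only at splice/translate time (a '-'-strand gene is spliced by
concatenating exons in genomic order and reverse-complementing the result
as a unit). A locus carries an `origin_offset`, the 1-based chromosome
position of its first base, so locus and chromosome coordinates
interconvert exactly.

Translation uses the standard genetic code, terminates at the first stop
codon (written `*`), renders codons containing non-ACGT characters as `X`,
and ignores a trailing partial codon with a warning.

## Synthetic data: what it emulates, and what it does not

The generator produces the inputs a locus-scale PAV study consumes, at a
reduced but structurally faithful scale:

- **Reference locus** — 120 kb of uniform random DNA carrying a centred
  two-exon gene (699 + 450 bp exons, 500 bp intron; spliced CDS = whole
  transcript, starts ATG, single terminal stop; intron boundaries GT..AG).
  The architecture mirrors a compact plant regulator with long conserved
  flanks.
- **Accession assemblies** — a configurable fraction of accessions
  (default 0.15) carry a compound SV: one 60 kb deletion centred on the
  gene plus one to three nested inversions (2–6 kb) or block substitutions
  (1–4 kb) in the flanks. Non-carriers differ from the reference only by
  scattered flank SNPs. Every event is recorded in both reference and
  accession coordinates; `gene_present` is false exactly when a deletion
  covers the full gene span.
- **Depth profiles** — per-base depth ~ Poisson(20) over present
  positions and Poisson(0.02 × 20) over deleted spans (off-target
  mapping); optional heterozygous carriers get Poisson(10) over the span.
  Coverage of the emulated short-read datasets is not published, so 20× is
  chosen as a typical resequencing depth.
- **SNP matrix** — 46 biallelic SNPs plus one InDel inside the gene span
  (matching the scale of variation reported for the motivating locus);
  8 distinct founder allele vectors with geometrically skewed carrier
  counts (every founder guaranteed at least one carrier); heterozygous and
  missing calls injected into disjoint sample sets sized
  `round(rate × n)`, never consuming a founder's last clean carrier (so
  the founder set remains recoverable after filtering — the filter's
  correctness, not its luck, is what tests should measure); subpopulation
  labels (XI/GJ/aus) correlated with founder, with a configurable
  confusion rate (default 0.1).

Determinism: one seed drives everything; per-accession streams are
derived by CRC-hashing the accession id, so enlarging a cohort never
perturbs existing accessions.

What the generator does **not** model: read-level artefacts (mapping
bias, GC bias, duplicates), repeat-rich sequence (the locus is random
DNA, so k-mer anchoring behaves near-ideally), population-genetic
structure beyond the founder-haplotype model, and linked phenotypes.
Perfect recovery on these cohorts therefore demonstrates correctness of
the algorithms under their stated model, not expected field performance
on repetitive or contaminated data.

A separate fixture, `ghd7_like_locus()`, is a **synthetic** stand-in for
the real heading-date gene: an 8 kb two-exon locus engineered so the
first AG downstream of the intron acceptor sits exactly 34 bp into exon 2
and a premature stop lies in the shifted frame, with a CCT-like domain
annotated near the protein's C terminus. It reproduces the documented
consequence of the natural splice-site allele (−34 bp, frameshift, CCT
loss) on sequence that ships with the package; it is not the real genomic
sequence, and results on it validate the predictor's mechanics only.

## Dot-plot SV inference

Anchors are maximal runs of consecutive shared k-mers (default k = 16),
computed forward and against the reverse complement; k-mers occurring
more than `max_occ` = 8 times in either sequence are skipped as repeats.
Anchors below `min_anchor` = 24 bp are ignored during classification
(between two ~100 kb random sequences a lone shared 16-mer is expected by
chance, a 24 bp exact match is not — at 24 bp the expected count over the
full comparison is ~1e-5); they remain in the dot-plot table.

The collinear backbone is the heaviest chain of forward anchors —
longest-increasing-subsequence on anchor midpoints weighted by anchor
length, ties toward the smaller reference coordinate. The deletion span
is the maximal anchor-free reference interval containing the entire gene
and flanked by backbone anchors on both sides; with exact matching its
boundaries are recovered to the base on planted SVs, and the test
tolerance of k−1 bp reflects the worst case in which a chance k-mer
spans a breakpoint. Inverted anchors within 200 bp of each other merge
into inversion segments. A backbone gap uncovered on **both** the
reference and accession sides (each ≥ `min_sub` = 50 bp) is a
substitution; a one-sided reference gap is reported as unaligned.
`gene_present` requires forward-anchor coverage of ≥ 90% of the gene
span. No anchors at all yields an "unalignable" report, not an error.

## Depth-interval PAV calling

Intervals: *a* is the 400 bp window ending 500 bp before the deletion
start, *c* the window starting 500 bp after its end, *b* the window
centred on the exon-2/intron junction (the junction's containment versus
centring is not specified by convention; centring is symmetric and keeps
the window inside the gene). The statistic is
r = mean(b) / ((mean(a) + mean(c)) / 2); positions absent from a depth
table count as depth 0.

Thresholds: absent below τ_abs = 0.15, present above τ_pres = 0.85.
The expectations are r ≈ 0 (homozygous deletion), ≈ 0.5 (heterozygous),
≈ 1 (intact); the mean of a 400 bp Poisson(20) window has standard error
≈ 0.11 in depth, i.e. ≈ 0.01 in r, so a present/ambiguous boundary at
0.5 itself would sit exactly on the heterozygous expectation and flip
half of those accessions by sampling noise alone. 0.85 keeps both the
0.5 and the 1.0 expectation ≳ 15 standard errors from the boundary at
20× coverage. Flank normalisation uses the mean of *a* and *c* (robust
to one-sided mismapping); a flank mean of 0 makes r undefined and the
call ambiguous with a low-confidence flag, as does flank depth below 5×.
Scale invariance (multiplying an accession's depths by a constant) and
monotonicity in τ_abs hold by construction and are property-tested.

## PCR assay

Primer acceptance: length 18–27 nt (default 20), GC 40–60%, Wallace-rule
Tm = 2(A+T) + 4(G+C) in 55–65 °C, pair ΔTm ≤ 3 °C, and locus-wide
uniqueness of the primer and its reverse complement. The Wallace rule is
chosen for transparency at these lengths; the Tm function is a single
swappable routine. G2 primers are searched outward from 500 bp beyond
each deletion breakpoint, with the forward search scanning toward the
breakpoint so the deleted-allele product stays small (~1 kb) while the
intact-allele distance (the 60 kb span) exceeds `max_product` = 3000 bp —
a typical Taq-amplifiable ceiling. In-silico PCR requires exact primer
matches by default; when mismatches are permitted the three 3'-terminal
bases must still match (3' mismatches abolish extension). Both template
orientations are searched, making amplification strand-symmetric.

## Haplotype typing

The filter drops every sample with at least one heterozygous or missing
genotype, and every sample already typed H0 (whole-gene deletion) by the
depth stage; each exclusion is logged with a single reason, in the fixed
order deletion > heterozygous > missing (the retained set is order-
independent; only the log wording depends on it). Identical allele
vectors collapse into haplotypes labelled H1, H2, … by descending carrier
count, ties broken by first-seen sample order — so sample-order
permutations can only relabel exact ties, never change the partition.
The single InDel rides as one more binary column. The NJ tree uses
Hamming distances between allele vectors (H0 has none and is excluded);
scikit-bio provides the neighbor-joining itself, and negative branch
lengths — an NJ artefact on non-additive matrices — are clamped to zero
with a warning. Fewer than three typable haplotypes yield a degenerate
newick with a warning rather than an error.

## Variant effects and cryptic splicing

Annotation order: canonical splice positions (the two intron bases at
each end, strand-aware) outrank coding consequences, which outrank
intron-interior and intergenic placement. Coding SNVs are evaluated by
rewriting the affected codon on the spliced coding-strand transcript;
a stop gained before the reference stop is `premature_stop`, a change in
the final stop codon is treated as nonsynonymous. Exonic indels are
`frameshift_indel`/`inframe_indel` by length mod 3. The annotator is
tested exhaustively against an independent mutate → re-splice → translate
oracle over every substitution of a toy gene, on both strands.

The cryptic-acceptor model: when the acceptor AG is destroyed, the
nearest AG downstream (scanning into the exon, at most `max_scan` =
200 bp) becomes the acceptor, and the exon start moves just past it.
Nearest-downstream-AG is the minimal mechanistic model consistent with a
shortened product; upstream (intron-side) candidates would lengthen the
transcript and are not scanned by default. Branch-point and
polypyrimidine-tract effects are out of scope. If no AG lies within
range the outcome is `exon_skip_unresolved` — no guess. The re-spliced
transcript is translated (any trailing partial codon dropped); the
frameshift verdict equals both `delta mod 3 ≠ 0` and the protein-length
comparison, and a domain is reported lost when translation terminates at
or before the domain's last residue.

## pegRNA / PE3 design

Nick convention: between protospacer positions 17 and 18 (3 nt 5' of the
NGG PAM), the standard SpCas9-H840A nickase geometry. The PBS is the
reverse complement of the `pbs_len` nicked-strand bases ending at the
nick; `pbs_len` defaults to 12, the value recovered by suffix-matching
published reagents for the motivating locus (the validator infers a PBS
length from a bare spacer + extension by finding the longest extension
suffix whose reverse complement is a protospacer suffix ending exactly at
the nick). The RT template is the reverse complement of the edited
strand from the nick, extended to cover the edit plus three downstream
bases and at least `rt_min` = 10 nt; the 3' extension is written 5'→3' as
RT template then PBS. Candidate protospacers must place the edit 1–16 nt
3' of the nick; the minimal nick-to-edit distance wins, ties toward the
smaller coordinate. The PE3 second nick is the opposite-strand candidate
whose nick distance falls in 40–90 bp, closest to the window midpoint;
its absence is a warning, not an error. Dimer/hairpin screening,
efficiency prediction and off-target scoring are out of scope.

## Problem sizes and runtimes

The shipped verification runs use: 20 independent 200-accession cohorts
(120 kb locus, 20×) for depth-PAV precision/recall; one 200-accession
heterozygous cohort; 50 compound-SV assemblies for dot-plot recovery;
200 assemblies for PCR concordance; a 200-sample, 8-founder SNP matrix
with 12 heterozygous and 9 missing-bearing samples; an exhaustive
substitution scan of a <1 kb toy gene; and 100 random pegRNA edits.
These sizes keep the full suite under a minute on one core while leaving
every per-accession statistic at its study scale. `scripts/acceptance.py`
recomputes all of them from a single command-line seed.

## Known limitations

- Exact k-mer anchoring presumes locus-scale, low-repeat sequence; real
  flanks with transposon content would need the repeat mask (`max_occ`)
  tuned and possibly gapped alignment.
- The depth caller assumes the deletion span is known (from the dot-plot
  stage or prior work) and does not segment novel CNVs.
- One transcript per gene; UTR-bearing models are not annotated
  specially (non-coding exon positions fall through to intergenic).
- The splice model is canonical-dinucleotide only, and the cryptic
  search is downstream-only by design.
- PCR simulation is sequence-exact; polymerase kinetics, secondary
  structure and multiplexing are not modelled.
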