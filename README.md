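# locuspav

Locus-centric discovery, genotyping and validation of gene
presence/absence variation (PAV), with downstream haplotype typing,
variant-effect interpretation and prime-editing reagent design.

## The problem

Large structural variants (SVs) that delete an entire gene are common in
crop genomes — the motivating case is the rice heading-date regulator
*Ghd7*, which is missing from a sizeable fraction of cultivated accessions
under a compound ~60 kb deletion — but they are hard to call reliably from
short reads alone. `locuspav` implements a desk-scale version of the
workflow a locus study uses end to end:

1. **Dot-plot SV characterisation** (`dotplot_sv`): exact k-mer anchors
   between an accession assembly and the reference locus, chained into a
   collinear backbone; the anchor-free reference interval containing the
   gene, flanked by chained anchors, is the deletion span; reverse-
   complement anchors mark inversions.
2. **Depth-interval PAV genotyping** (`depth_pav`): three 400 bp intervals
   — *a* and *c* in the conserved flanks outside the deletion span, *b* at
   the exon-2/intron junction of the gene — and the ratio

   r = d̄_b / ((d̄_a + d̄_c) / 2)

   with calls: absent for r < 0.15, present for r > 0.85, ambiguous
   between (heterozygous carriers sit at r ≈ 0.5).
3. **PCR assay design and simulation** (`insilico_pcr`): a gene-internal
   pair (G1) and a deletion-spanning pair (G2) whose bands are mutually
   exclusive; G1-only ⇒ gene present, G2-only ⇒ gene deleted.
4. **Haplotype typing** (`haplotype_typing`): samples with heterozygous or
   missing calls (and whole-gene-deletion carriers, class H0) are excluded;
   identical allele vectors collapse into haplotypes H1, H2, … by carrier
   count; subpopulation frequency tables and a neighbor-joining tree on
   Hamming distances summarise the diversity.
5. **Variant effects and cryptic splicing** (`variant_effects`):
   synonymous/nonsynonymous/splice/premature-stop annotation against the
   gene model, plus a cryptic-acceptor model — when a splice acceptor AG is
   destroyed, the nearest downstream AG in the exon takes over, shortening
   the cDNA and (if the loss is not a multiple of 3) shifting the frame.
6. **Prime-editing design** (`pegrna_design`): PE3 reagents for a
   single-base correction — 20 nt protospacer with NGG PAM, nick between
   protospacer positions 17/18, 3' extension written 5'→3' as RT template
   then PBS, and an opposite-strand second nick 40–90 bp away.

A `synthetic_data` module generates every input — reference locus with a
two-exon gene, accession assemblies with planted compound SVs, Poisson
depth profiles, SNP matrices with founder haplotypes — together with
machine-readable truth tables, so the whole pipeline is testable offline.

## Worked example

```python
import locuspav as lp
import locuspav.synthetic_data as sd
import locuspav.depth_pav as dpav

cfg = lp.SimConfig(seed=5, n_accessions=50, deletion_fraction=0.3)
locus = sd.simulate_reference(cfg)          # 120 kb locus, 2-exon gene
_, truth = sd.simulate_accessions(cfg, locus)
depths = sd.simulate_depth(cfg, locus, truth)   # 20x Poisson depth
iv = dpav.place_intervals(locus, truth.deletion_span)
calls, summary = dpav.cohort_scan(depths, iv)
print(summary)
```

prints

```
{'n': 50, 'present': 35, 'absent': 15, 'ambiguous': 0, 'errors': 0}
```

— 15 of 50 accessions carry the planted whole-gene deletion
(`round(50 × 0.3)`), and every call matches the generator's truth table.
The same cohort can be run through the shell front-end:

```bash
locuspav simulate --seed 5 --outdir sim
locuspav depth-call --locus sim/reference.fa --gff sim/gene.gff3 \
    --deletion-span "$(cat sim/deletion_span.txt)" \
    --manifest sim/manifest.tsv --outdir pav
```

The cryptic-splice predictor, run on the packaged synthetic locus that
mirrors the *Ghd7* splice architecture, reports a 34 bp cDNA deletion, a
frameshift, and loss of the CCT-like domain when the intron's acceptor A
is mutated to C — the documented failure mode of the natural H6 allele:

```python
import locuspav.variant_effects as ve
locus, cct = sd.ghd7_like_locus()
ie = locus.gene.introns[0][1]
out = ve.predict_cryptic_splice(locus, ve.Variant(ie - 1, "A", "C"),
                                domains=[cct])
print(out.cdna_delta_bp, out.frameshift, out.domains_lost)
# -34 True ['CCT']
```

## Scope

The package operates at locus scale (one gene plus ~50 kb flanks, one
transcript per gene). Genome-wide SV calling, read alignment, imputation,
phasing and editing-efficiency prediction are out of scope; depth is
consumed as (chrom, pos, depth) tables, which any aligner pileup can
produce. See `docs/methods.md` for models, parameter choices and
limitations.
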