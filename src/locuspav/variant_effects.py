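"""Variant-effect annotation against a single-transcript gene model.

Categories follow a fixed decision order: canonical splice-site positions
(the 2 intron bases at each end of an intron) outrank coding consequences,
which outrank intron-interior and intergenic placement.  Coding effects are
computed on the spliced coding-strand transcript, so '-'-strand genes are
handled by the same code path.

The cryptic-splice predictor models what happens when a splice acceptor is
destroyed: the spliceosome falls back to the nearest downstream AG inside
the exon, shortening the mature transcript.  A shortening that is not a
multiple of 3 shifts the reading frame, typically terminating translation
early and truncating any C-terminal domain — the mechanism by which a
single A>C acceptor mutation can abolish the function of a
CCT-domain-dependent regulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .locus_model import (
    CoordinateError,
    DomainAnnotation,
    GeneLocus,
    GeneModel,
    SequenceError,
    splice,
    translate,
    revcomp,
)

__all__ = [
    "Variant",
    "VariantEffect",
    "SpliceOutcome",
    "annotate",
    "predict_cryptic_splice",
    "classify_haplotype_function",
]

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Variant:
    """A locus-coordinate variant; multi-base ref/alt encode indels."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass(frozen=True)
class VariantEffect:
    variant: Variant
    category: str
    protein_change: str | None = None


@dataclass
class SpliceOutcome:
    """Consequence of acceptor loss resolved through a cryptic acceptor."""

    status: str  # "ok" | "exon_skip_unresolved"
    used_acceptor_pos: int | None  # locus coord of the redefined exon start
    cdna_delta_bp: int  # negative = mature cDNA shortened
    frameshift: bool
    truncated_protein: str
    domains_lost: list[str] = field(default_factory=list)


def _mirror(locus: GeneLocus) -> GeneLocus:
    """Reverse-complement view of the locus with the gene model remapped."""
    L = len(locus)
    g = locus.gene
    exons = tuple(sorted((L - e + 1, L - s + 1) for s, e in g.exons))
    model = GeneModel(gene_id=g.gene_id, strand="+", exons=exons, cds=g.cds)
    return GeneLocus(
        chrom_id=locus.chrom_id,
        sequence=revcomp(locus.sequence),
        gene=model,
        origin_offset=locus.origin_offset,
        flank_size=locus.flank_size,
    )


def _tx_position(model: GeneModel, pos: int) -> int | None:
    """Locus position -> 1-based spliced-transcript position (coding order)."""
    total = model.spliced_length
    offset = 0
    for s, e in model.exons:
        if s <= pos <= e:
            asc = offset + (pos - s) + 1
            return asc if model.strand == "+" else total - asc + 1
        offset += e - s + 1
    return None


def _splice_category(model: GeneModel, pos: int) -> str | None:
    """splice_donor / splice_acceptor if pos is an intron-edge dinucleotide."""
    for is_, ie in model.introns:
        if model.strand == "+":
            if pos in (is_, is_ + 1):
                return "splice_donor"
            if pos in (ie - 1, ie):
                return "splice_acceptor"
        else:
            if pos in (ie - 1, ie):
                return "splice_donor"
            if pos in (is_, is_ + 1):
                return "splice_acceptor"
    return None


def annotate(
    variant: Variant, locus: GeneLocus, model: GeneModel | None = None
) -> VariantEffect:
    """Categorise one variant against the gene model.

    Decision order: splice (2 bp intron edges) > coding > intronic >
    intergenic.  The ref allele must match the locus sequence at ``pos``.
    """
    model = model or locus.gene
    pos = variant.pos
    if not 1 <= pos <= len(locus):
        raise CoordinateError(f"variant position {pos} outside locus")
    observed = locus.subseq(pos, pos + len(variant.ref) - 1)
    if observed != variant.ref.upper():
        raise SequenceError(
            f"ref allele mismatch at {pos}: expected {observed}, got {variant.ref}"
        )

    cat = _splice_category(model, pos)
    if cat:
        return VariantEffect(variant, cat)

    t = _tx_position(model, pos)
    gs, ge = model.span
    if t is None:
        return VariantEffect(variant, "intronic" if gs <= pos <= ge else "intergenic")

    cs, ce = model.cds
    if not cs <= t <= ce:
        return VariantEffect(variant, "intergenic")  # non-coding exon sequence

    if not variant.is_snv:
        delta = len(variant.alt) - len(variant.ref)
        return VariantEffect(
            variant, "frameshift_indel" if delta % 3 else "inframe_indel"
        )

    cdna = splice(locus, model)
    c = t - cs + 1  # 1-based CDS position
    codon_index = (c - 1) // 3  # 0-based
    codon_start = cs - 1 + codon_index * 3
    ref_codon = cdna[codon_start : codon_start + 3]
    base = variant.alt.upper() if model.strand == "+" else _COMPL[variant.alt.upper()]
    within = (c - 1) % 3
    alt_codon = ref_codon[:within] + base + ref_codon[within + 1 :]
    ref_aa = translate(ref_codon + "TAA")[0] if len(ref_codon) == 3 else "X"
    alt_aa = translate(alt_codon + "TAA")[0]
    n_codons = (ce - cs + 1) // 3
    change = f"{ref_aa}{codon_index + 1}{alt_aa}"
    if alt_aa == ref_aa:
        return VariantEffect(variant, "synonymous", change)
    if alt_aa == "*" and codon_index + 1 < n_codons:
        return VariantEffect(variant, "premature_stop", change)
    return VariantEffect(variant, "nonsynonymous", change)


def predict_cryptic_splice(
    locus: GeneLocus,
    acceptor_variant: Variant | None,
    model: GeneModel | None = None,
    domains: Sequence[DomainAnnotation] = (),
    max_scan: int = 200,
) -> SpliceOutcome:
    """Resolve a destroyed splice acceptor through the nearest downstream AG.

    With ``acceptor_variant=None`` the canonical acceptor is used and the
    reference outcome (delta 0, reference protein) is returned.  Otherwise
    the variant must be a splice_acceptor change; the mutated acceptor is
    disabled and the closest AG dinucleotide downstream (scanning into the
    exon, at most ``max_scan`` bp) becomes the new acceptor.  No candidate
    within range yields status ``exon_skip_unresolved`` rather than a guess.

    Upstream (intron-side) cryptic acceptors would lengthen the transcript;
    they are not scanned because the modelled failure mode is a shortened
    product.
    """
    model = model or locus.gene
    if model.strand == "-":
        mirrored = _mirror(locus)
        mv = None
        if acceptor_variant is not None:
            L = len(locus)
            mv = Variant(
                pos=L - acceptor_variant.pos + 1,
                ref=_COMPL[acceptor_variant.ref.upper()],
                alt=_COMPL[acceptor_variant.alt.upper()],
            )
        out = predict_cryptic_splice(
            mirrored, mv, mirrored.gene, domains=domains, max_scan=max_scan
        )
        if out.used_acceptor_pos is not None:
            out.used_acceptor_pos = len(locus) - out.used_acceptor_pos + 1
        return out

    cs, ce = model.cds
    ref_cdna = splice(locus, model)
    ref_protein = translate(ref_cdna[cs - 1 :])

    if acceptor_variant is None:
        return SpliceOutcome(
            status="ok",
            used_acceptor_pos=None,
            cdna_delta_bp=0,
            frameshift=False,
            truncated_protein=ref_protein,
        )

    effect = annotate(acceptor_variant, locus, model)
    if effect.category != "splice_acceptor":
        raise ValueError(
            f"variant at {acceptor_variant.pos} is {effect.category}, "
            "not splice_acceptor"
        )

    # locate the affected intron and the exon it precedes (coding order '+')
    exon_start = None
    for (is_, ie), (s2, _) in zip(model.introns, [e for e in model.exons][1:]):
        if acceptor_variant.pos in (ie - 1, ie):
            exon_start = s2
            break
    if exon_start is None:
        raise CoordinateError("acceptor variant does not map to any intron end")

    seq = (
        locus.sequence[: acceptor_variant.pos - 1]
        + acceptor_variant.alt.upper()
        + locus.sequence[acceptor_variant.pos :]
    )
    new_start = None
    for t in range(exon_start + 1, exon_start + max_scan + 1):
        if seq[t - 3 : t - 1] == "AG":
            new_start = t
            break
    if new_start is None:
        return SpliceOutcome(
            status="exon_skip_unresolved",
            used_acceptor_pos=None,
            cdna_delta_bp=0,
            frameshift=False,
            truncated_protein="",
        )

    delta = -(new_start - exon_start)
    new_exons = tuple(
        (new_start, e) if s == exon_start else (s, e) for s, e in model.exons
    )
    new_model = GeneModel(
        gene_id=model.gene_id, strand="+", exons=new_exons, cds=(1, 1)
    )
    mutated = GeneLocus(
        chrom_id=locus.chrom_id, sequence=seq, gene=new_model,
        origin_offset=locus.origin_offset, flank_size=locus.flank_size,
    )
    new_cdna = splice(mutated, new_model)
    coding = new_cdna[cs - 1 :]
    coding = coding[: len(coding) - len(coding) % 3]  # drop partial codon
    aberrant = translate(coding)
    stop_aa = len(aberrant) if aberrant.endswith("*") else None
    lost = []
    for d in domains:
        effective_end = stop_aa if stop_aa is not None else len(aberrant) + 1
        if effective_end <= d.aa_end:
            lost.append(d.name)
    return SpliceOutcome(
        status="ok",
        used_acceptor_pos=new_start,
        cdna_delta_bp=delta,
        frameshift=delta % 3 != 0,
        truncated_protein=aberrant,
        domains_lost=lost,
    )


def classify_haplotype_function(
    effects: Sequence[VariantEffect], is_h0: bool = False
) -> str:
    """Functional class of a haplotype from its variant effects.

    deleted (H0) > splice_defective > truncated (premature stop or
    frameshift) > functional.
    """
    if is_h0:
        return "deleted"
    cats = {e.category for e in effects}
    if cats & {"splice_donor", "splice_acceptor"}:
        return "splice_defective"
    if cats & {"premature_stop", "frameshift_indel"}:
        return "truncated"
    return "functional"
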