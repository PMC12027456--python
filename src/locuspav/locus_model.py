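"""Shared domain model for locus-centric analyses.

A :class:`GeneLocus` is a reference chromosome segment carrying a single
gene plus flanking context — the coordinate frame every other stage of the
pipeline works in.  All genomic intervals are 1-based inclusive (GFF/VCF
convention); BED output, where emitted, is 0-based half-open.  Sequences are
uppercase-normalised on construction; per-locus analyses always operate on
the stored '+' orientation of the segment, and the gene strand is applied
only when splicing/translating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusError",
    "CoordinateError",
    "SequenceError",
    "GffParseError",
    "GeneModel",
    "GeneLocus",
    "DomainAnnotation",
    "revcomp",
    "translate",
    "splice",
    "cds_sequence",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
]


class LocusError(ValueError):
    """Base class for domain-model errors."""


class CoordinateError(LocusError):
    """An interval or position falls outside its coordinate frame."""


class SequenceError(LocusError):
    """A sequence contains characters outside the accepted alphabet."""


class GffParseError(LocusError):
    """Strict GFF3 validation failure; message carries the line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GFF3 line {lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

# Standard genetic code (DNA codons).  Kept explicit so translation behaviour
# (first-stop termination, 'X' for ambiguous codons) is fully local.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case-preserving).

    Raises :class:`SequenceError` on non-IUPAC characters.
    """
    bad = set(seq.upper()) - _IUPAC_DNA
    if bad:
        raise SequenceError(f"non-IUPAC DNA characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Translation stops at (and includes) the first stop codon, written ``*``.
    Codons containing non-ACGT characters yield ``X``.  A trailing partial
    codon is ignored with a warning.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise SequenceError(f"CDS shorter than one codon ({len(cds)} nt)")
    if len(cds) % 3:
        warnings.warn(
            f"trailing partial codon ({len(cds) % 3} nt) ignored", stacklevel=2
        )
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = GENETIC_CODE.get(cds[i : i + 3], "X")
        protein.append(aa)
        if aa == "*":
            break
    return "".join(protein)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model in locus coordinates.

    ``exons`` are 1-based inclusive intervals in ascending locus order;
    for '-'-strand genes the reverse complement is applied as a unit at
    splice time, so ascending storage serves both strands.  ``cds`` is the
    coding interval in spliced-transcript coordinates (1-based inclusive).
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise LocusError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise LocusError("gene model needs at least one exon")
        for s, e in exons:
            if s < 1 or e < s:
                raise CoordinateError(f"bad exon interval ({s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise CoordinateError("exons overlap or are unsorted")
            if s2 - e1 - 1 < 4:
                raise LocusError(
                    f"intron between {e1} and {s2} shorter than 4 bp"
                )
        cs, ce = self.cds
        if not (1 <= cs <= ce <= self.spliced_length):
            raise CoordinateError(f"CDS {self.cds} outside spliced transcript")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class GeneLocus:
    """A reference chromosome segment housing one gene.

    ``origin_offset`` is the 1-based position of the segment's first base on
    its source chromosome, so locus position *p* maps to chromosome position
    ``p + origin_offset - 1``.
    """

    chrom_id: str
    sequence: str
    gene: GeneModel
    origin_offset: int = 1
    flank_size: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _IUPAC_DNA
        if bad:
            raise SequenceError(f"non-IUPAC characters in locus: {sorted(bad)}")
        if self.origin_offset < 1:
            raise CoordinateError("origin_offset must be >= 1")
        gs, ge = self.gene.span
        if ge > len(self.sequence):
            raise CoordinateError(
                f"gene span ({gs},{ge}) exceeds locus length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice of the locus sequence."""
        if start < 1 or end > len(self.sequence) or end < start:
            raise CoordinateError(
                f"interval ({start},{end}) outside locus of length {len(self)}"
            )
        return self.sequence[start - 1 : end]

    def to_chrom(self, pos: int) -> int:
        """Locus position -> source-chromosome position."""
        if not 1 <= pos <= len(self):
            raise CoordinateError(f"position {pos} outside locus")
        return pos + self.origin_offset - 1

    def to_locus(self, chrom_pos: int) -> int:
        """Source-chromosome position -> locus position."""
        pos = chrom_pos - self.origin_offset + 1
        if not 1 <= pos <= len(self):
            raise CoordinateError(f"chromosome position {chrom_pos} outside locus")
        return pos


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain, 1-based inclusive amino-acid interval."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        if not 1 <= self.aa_start <= self.aa_end:
            raise CoordinateError(
                f"bad domain interval ({self.aa_start},{self.aa_end})"
            )


# ---------------------------------------------------------------------------
# gene-model operations
# ---------------------------------------------------------------------------


def splice(locus: GeneLocus, model: GeneModel | None = None) -> str:
    """Mature cDNA: exon substrings concatenated 5'->3'.

    Exons are concatenated in ascending locus order and the result is
    reverse-complemented as a unit for '-'-strand genes.
    """
    model = model or locus.gene
    parts = [locus.subseq(s, e) for s, e in model.exons]
    cdna = "".join(parts)
    return revcomp(cdna) if model.strand == "-" else cdna


def cds_sequence(locus: GeneLocus, model: GeneModel | None = None) -> str:
    """Coding sequence extracted from the spliced transcript."""
    model = model or locus.gene
    cdna = splice(locus, model)
    cs, ce = model.cds
    return cdna[cs - 1 : ce]


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, uppercase sequence), ...]``."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    seqrecs = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# strict GFF3 I/O (gene/mRNA/exon/CDS only, one transcript per gene)
# ---------------------------------------------------------------------------

_GFF_TYPES = {"gene", "mRNA", "exon", "CDS"}


def _gff_attributes(field9: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise GffParseError(lineno, f"malformed attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff3(path) -> tuple[str, GeneModel]:
    """Parse a single-gene GFF3 into ``(seqid, GeneModel)``.

    Only gene/mRNA/exon/CDS features are accepted; anything else, or a second
    transcript, is a validation error with the offending line number.
    """
    gene_id = None
    strand = None
    seqid = None
    mrna_count = 0
    exons: list[tuple[int, int]] = []
    cds_intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(lineno, f"expected 9 columns, got {len(cols)}")
            ftype = cols[2]
            if ftype not in _GFF_TYPES:
                raise GffParseError(lineno, f"unsupported feature type {ftype!r}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise GffParseError(lineno, "non-integer coordinates") from None
            if start < 1 or end < start:
                raise GffParseError(lineno, f"bad interval ({start},{end})")
            if cols[6] not in ("+", "-"):
                raise GffParseError(lineno, f"bad strand {cols[6]!r}")
            attrs = _gff_attributes(cols[8], lineno)
            if seqid is None:
                seqid = cols[0]
            elif cols[0] != seqid:
                raise GffParseError(lineno, "multiple seqids in single-gene GFF3")
            if ftype == "gene":
                if gene_id is not None:
                    raise GffParseError(lineno, "second gene feature")
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise GffParseError(lineno, "gene feature lacks ID attribute")
                strand = cols[6]
            elif ftype == "mRNA":
                mrna_count += 1
                if mrna_count > 1:
                    raise GffParseError(lineno, "multiple transcripts not supported")
            elif ftype == "exon":
                exons.append((start, end))
            else:  # CDS
                cds_intervals.append((start, end))
    if gene_id is None or not exons:
        raise GffParseError(0, "no gene/exon features found")
    exons.sort()
    if not cds_intervals:
        cds_intervals = list(exons)
    cds_intervals.sort()
    # map genomic CDS extent into spliced-transcript coordinates
    cds_tx = _cds_to_transcript(exons, cds_intervals, strand)
    model = GeneModel(gene_id=gene_id, strand=strand, exons=tuple(exons), cds=cds_tx)
    return seqid, model


def _cds_to_transcript(
    exons: list[tuple[int, int]],
    cds_intervals: list[tuple[int, int]],
    strand: str,
) -> tuple[int, int]:
    # cumulative transcript offsets in ascending genomic order
    offsets = []
    total = 0
    for s, e in exons:
        offsets.append(total)
        total += e - s + 1

    def tx_pos(gpos: int) -> int:
        for (s, e), off in zip(exons, offsets):
            if s <= gpos <= e:
                asc = off + (gpos - s) + 1
                return asc if strand == "+" else total - asc + 1
        raise GffParseError(0, f"CDS position {gpos} not inside any exon")

    positions = []
    for s, e in cds_intervals:
        positions.append(tx_pos(s))
        positions.append(tx_pos(e))
    return min(positions), max(positions)


def write_gff3(path, locus: GeneLocus) -> None:
    """Emit the locus gene model as a minimal single-transcript GFF3."""
    g = locus.gene
    gs, ge = g.span
    lines = ["##gff-version 3"]
    lines.append(
        "\t".join(
            [locus.chrom_id, "locuspav", "gene", str(gs), str(ge), ".", g.strand,
             ".", f"ID={g.gene_id}"]
        )
    )
    mrna_id = f"{g.gene_id}.1"
    lines.append(
        "\t".join(
            [locus.chrom_id, "locuspav", "mRNA", str(gs), str(ge), ".", g.strand,
             ".", f"ID={mrna_id};Parent={g.gene_id}"]
        )
    )
    for i, (s, e) in enumerate(g.exons, 1):
        lines.append(
            "\t".join(
                [locus.chrom_id, "locuspav", "exon", str(s), str(e), ".",
                 g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}"]
            )
        )
        lines.append(
            "\t".join(
                [locus.chrom_id, "locuspav", "CDS", str(s), str(e), ".",
                 g.strand, "0", f"ID={mrna_id}.cds;Parent={mrna_id}"]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
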