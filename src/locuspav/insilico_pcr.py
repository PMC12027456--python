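"""Deletion-assay primer design and in-silico PCR.

The assay uses two primer pairs.  G1 amplifies inside the gene and yields a
band only when the gene is present.  G2's primers sit in the conserved
flanks on either side of the deletion span: on the intact reference they
are too far apart to amplify (distance > ``max_product``), but on a deleted
allele the flanks are juxtaposed and G2 yields a band.  The two bands are
therefore mutually exclusive, which is what makes the assay interpretable:

    G1 band only  -> gene present
    G2 band only  -> gene deleted
    both / neither -> uninterpretable

Primer acceptance uses the Wallace rule Tm = 2(A+T) + 4(G+C) (transparent
and adequate for 18-27-mers; swappable if a nearest-neighbour model is
preferred), GC 40-60%, pair delta-Tm <= 3 C, and locus-wide uniqueness of
each primer and its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus_model import GeneLocus, revcomp

__all__ = [
    "Primer",
    "PrimerConstraints",
    "AssayDesign",
    "Amplicon",
    "DesignError",
    "wallace_tm",
    "design_assay",
    "simulate_pcr",
    "classify_pcr",
]


class DesignError(ValueError):
    """No primer pair satisfies the constraints; message names the reason."""


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) in Celsius."""
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3'
    tm: float
    gc: float

    def __post_init__(self):
        if not 18 <= len(self.sequence) <= 27:
            raise DesignError(f"primer length {len(self.sequence)} outside 18-27")
        if "N" in self.sequence.upper():
            raise DesignError("primer contains N")

    @classmethod
    def from_seq(cls, name: str, sequence: str) -> "Primer":
        sequence = sequence.upper()
        return cls(name, sequence, wallace_tm(sequence), gc_fraction(sequence))


@dataclass(frozen=True)
class PrimerConstraints:
    length: int = 20
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_min: float = 55.0
    tm_max: float = 65.0
    max_pair_delta_tm: float = 3.0


@dataclass(frozen=True)
class Amplicon:
    pair_name: str
    start: int  # 1-based on the template '+' strand
    end: int
    length: int
    sequence: str


@dataclass
class AssayDesign:
    g1_fwd: Primer
    g1_rev: Primer
    g1_product_len: int  # on the intact reference
    g2_fwd: Primer
    g2_rev: Primer
    g2_product_len: int  # on the deleted allele
    max_product: int


def _count_occurrences(hay: str, needle: str) -> int:
    n = 0
    i = hay.find(needle)
    while i != -1:
        n += 1
        i = hay.find(needle, i + 1)
    return n


def _is_unique(locus_seq: str, primer_seq: str) -> bool:
    """Primer (or its revcomp) occurs exactly once in the locus overall."""
    total = _count_occurrences(locus_seq, primer_seq) + _count_occurrences(
        locus_seq, revcomp(primer_seq)
    )
    return total == 1


def _find_primer(
    locus: GeneLocus,
    window: tuple[int, int],
    constraints: PrimerConstraints,
    name: str,
    reverse: bool,
    scan_backward: bool = False,
) -> tuple[Primer, int, int] | None:
    """First constraint-satisfying primer in a window.

    Returns (primer, start, end) in locus coordinates of the binding site;
    ``reverse`` primers are the revcomp of the '+'-strand site.
    ``scan_backward`` starts the search at the window's downstream edge
    (used to keep a primer as close as possible to a breakpoint).
    """
    L = constraints.length
    lo, hi = window
    seq = locus.sequence
    positions = range(hi - L + 1, lo - 1, -1) if scan_backward else range(lo, hi - L + 2)
    for s in positions:
        site = seq[s - 1 : s - 1 + L]
        if "N" in site:
            continue
        primer_seq = revcomp(site) if reverse else site
        if not constraints.gc_min <= gc_fraction(primer_seq) <= constraints.gc_max:
            continue
        tm = wallace_tm(primer_seq)
        if not constraints.tm_min <= tm <= constraints.tm_max:
            continue
        if not _is_unique(seq, primer_seq):
            continue
        return Primer.from_seq(name, primer_seq), s, s + L - 1
    return None


def design_assay(
    locus: GeneLocus,
    deletion_span: tuple[int, int],
    constraints: PrimerConstraints = PrimerConstraints(),
    max_product: int = 3000,
    flank_offset: int = 500,
    search_width: int = 2000,
) -> AssayDesign:
    """Design the G1 (gene-internal) and G2 (deletion-spanning) pairs.

    G2 primers are placed within ``flank_offset``..``flank_offset +
    search_width`` bp of the deletion breakpoints so the deleted-allele
    product stays well under ``max_product`` while the reference-allele
    distance (the whole deletion span) exceeds it.
    """
    ds, de = deletion_span
    gs, ge = locus.gene.span

    def paired(fwd_window, rev_window, prefix, fwd_backward=False,
               min_product=300) -> tuple[Primer, int, Primer, int]:
        fwd = _find_primer(locus, fwd_window, constraints, f"{prefix}-F",
                           reverse=False, scan_backward=fwd_backward)
        if fwd is None:
            raise DesignError(
                f"no forward primer in {fwd_window} meets GC/Tm/uniqueness constraints"
            )
        primer_f, fs, fe = fwd
        rev = None
        rev_lo = max(rev_window[0], fs + min_product - constraints.length)
        for attempt_start in range(rev_lo, rev_window[1], 50):
            cand = _find_primer(
                locus, (attempt_start, rev_window[1]), constraints,
                f"{prefix}-R", reverse=True,
            )
            if cand is None:
                break
            primer_r, rs, re_ = cand
            if abs(primer_r.tm - primer_f.tm) <= constraints.max_pair_delta_tm:
                rev = (primer_r, rs, re_)
                break
        if rev is None:
            raise DesignError(
                f"no reverse primer in {rev_window} within "
                f"delta-Tm {constraints.max_pair_delta_tm} of {primer_f.name}"
            )
        primer_r, rs, re_ = rev
        return primer_f, fs, primer_r, re_

    # G1: both primers inside the gene span
    g1_fwd, g1_fs, g1_rev, g1_re = paired(
        (gs, min(ge, gs + search_width)), (max(gs, ge - search_width), ge), "G1"
    )
    g1_len = g1_re - g1_fs + 1
    if g1_len > max_product:
        raise DesignError("gene too long for an internal product <= max_product")

    # G2: forward upstream of the deletion, reverse downstream
    g2_fwd, g2_fs, g2_rev, g2_re = paired(
        (max(1, ds - flank_offset - search_width), ds - flank_offset),
        (de + flank_offset, min(len(locus), de + flank_offset + search_width)),
        "G2",
        fwd_backward=True,  # hug the breakpoint: small deleted-allele product
    )
    ref_distance = g2_re - g2_fs + 1
    if ref_distance <= max_product:
        raise DesignError("G2 reference-allele distance not above max_product")
    g2_len = ref_distance - (de - ds + 1)
    if g2_len > max_product:
        raise DesignError("G2 deleted-allele product exceeds max_product")
    return AssayDesign(
        g1_fwd=g1_fwd, g1_rev=g1_rev, g1_product_len=g1_len,
        g2_fwd=g2_fwd, g2_rev=g2_rev, g2_product_len=g2_len,
        max_product=max_product,
    )


def _binding_sites(
    template: str, probe: str, max_mismatch: int, three_prime_at_start: bool = False
) -> list[int]:
    """0-based start positions where ``probe`` matches the template '+' strand.

    With ``max_mismatch`` > 0, mismatches are tolerated anywhere except the
    primer's three 3'-terminal bases (a 3' mismatch abolishes polymerase
    extension).  When the probe is a revcomp'd primer those bases sit at the
    *start* of the probe; ``three_prime_at_start`` selects that end.
    """
    if max_mismatch == 0:
        return _find_all(template, probe)
    sites = []
    m = len(probe)
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        mm = sum(1 for a, b in zip(window, probe) if a != b)
        anchored = (
            window[:3] == probe[:3] if three_prime_at_start
            else window[-3:] == probe[-3:]
        )
        if mm <= max_mismatch and anchored:
            sites.append(i)
    return sites


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def simulate_pcr(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_product: int = 3000,
    max_mismatch: int = 0,
    pair_name: str = "pair",
) -> list[Amplicon]:
    """Predict all amplicons of a primer pair on a template.

    An amplicon forms wherever the forward primer matches one strand and
    the reverse primer matches the other strand downstream of it within
    ``max_product``.  Both template orientations are searched, so the result
    is strand-symmetric.  No match yields an empty list, not an error.
    """
    template = template.upper()
    products: set[tuple[int, int]] = set()
    for left, right in ((fwd, rev), (rev, fwd)):
        left_sites = _binding_sites(template, left.sequence.upper(), max_mismatch)
        right_sites = _binding_sites(
            template, revcomp(right.sequence.upper()), max_mismatch,
            three_prime_at_start=True,
        )
        for ls in left_sites:
            for rs in right_sites:
                end = rs + len(right.sequence)  # 0-based exclusive
                if end - ls < max(len(left.sequence), len(right.sequence)):
                    continue
                if rs < ls + len(left.sequence) - 3:
                    continue  # primers overlap beyond annealing geometry
                length = end - ls
                if length <= max_product:
                    products.add((ls + 1, end))
    return sorted(
        (
            Amplicon(pair_name, s, e, e - s + 1, template[s - 1 : e])
            for s, e in products
        ),
        key=lambda a: (a.start, a.end),
    )


def classify_pcr(g1_products: list[Amplicon], g2_products: list[Amplicon]) -> str:
    """Interpret the two-band pattern.

    (>=1, 0) -> gene_present; (0, >=1) -> gene_deleted; anything else is
    uninterpretable (no template, or an unexpected double band).
    """
    has_g1 = len(g1_products) >= 1
    has_g2 = len(g2_products) >= 1
    if has_g1 and not has_g2:
        return "gene_present"
    if has_g2 and not has_g1:
        return "gene_deleted"
    return "uninterpretable"
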