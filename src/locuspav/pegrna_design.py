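"""Prime-editing (PE3) reagent design for a single-base correction.

A pegRNA is a Cas9 guide extended at its 3' end with a reverse-transcription
template (RT) encoding the desired edit followed by a primer-binding site
(PBS) complementary to the 3' end of the nicked strand.  SpCas9 H840A nicks
the protospacer-bearing strand between protospacer positions 17 and 18
(3 nt 5' of the NGG PAM); the freed 3' end anneals to the PBS and is
extended along the RT template, writing the edit into the genome.  PE3 adds
a second nick on the opposite strand, 40-90 bp away, to bias mismatch
repair toward the edited strand.

Conventions: the 3' extension is written 5'->3' as RT template then PBS;
``nick_pos`` is the locus coordinate of protospacer position 17 (the last
base 5' of the nick on the nicked strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .locus_model import GeneLocus, SequenceError, revcomp

__all__ = [
    "EditSpec",
    "ProtospacerSite",
    "PegRNADesign",
    "PegDesignError",
    "enumerate_protospacers",
    "design_pegrna",
    "validate_design",
]

NICK_OFFSET = 17  # nick between protospacer positions 17 and 18


class PegDesignError(ValueError):
    """No candidate protospacer places the edit inside the RT window."""


@dataclass(frozen=True)
class EditSpec:
    """Desired single-base change in locus coordinates ('+'-strand alleles)."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref.upper() == self.alt.upper():
            raise ValueError("ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base edits are supported")


@dataclass(frozen=True)
class ProtospacerSite:
    spacer: str  # 20 nt, 5'->3' on its strand
    pam: str  # 3 nt NGG
    strand: str  # "+" | "-"
    start: int  # locus coord of spacer 5' end on '+' frame (smallest coord)
    end: int
    nick_pos: int  # locus coord of protospacer position 17


@dataclass
class PegRNADesign:
    site: ProtospacerSite
    edit: EditSpec
    pbs: str
    rt_template: str
    pe3_site: ProtospacerSite | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def spacer(self) -> str:
        return self.site.spacer

    @property
    def extension(self) -> str:
        """3' extension, 5'->3': RT template then PBS."""
        return self.rt_template + self.pbs


def enumerate_protospacers(seq: str, offset: int = 1) -> list[ProtospacerSite]:
    """All 20-mer protospacers 5' of an NGG PAM, on both strands.

    ``offset`` is the locus coordinate of ``seq[0]``, letting callers scan a
    sub-window while keeping locus coordinates.
    """
    seq = seq.upper()
    sites: list[ProtospacerSite] = []
    # '+' strand: spacer at [i, i+19], PAM at [i+20, i+22] (0-based)
    for i in range(len(seq) - 22):
        if seq[i + 21 : i + 23] == "GG":
            start = offset + i
            sites.append(
                ProtospacerSite(
                    spacer=seq[i : i + 20],
                    pam=seq[i + 20 : i + 23],
                    strand="+",
                    start=start,
                    end=start + 19,
                    nick_pos=start + NICK_OFFSET - 1,
                )
            )
    # '-' strand: CCN at [j, j+2], spacer = revcomp of [j+3, j+22]
    for j in range(len(seq) - 22):
        if seq[j : j + 2] == "CC":
            start = offset + j + 3  # smallest locus coord of the spacer
            sites.append(
                ProtospacerSite(
                    spacer=revcomp(seq[j + 3 : j + 23]),
                    pam=revcomp(seq[j : j + 3]),
                    strand="-",
                    start=start,
                    end=start + 19,
                    nick_pos=start + (20 - NICK_OFFSET),  # position 17 on '-'
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _strand_base(base: str, strand: str) -> str:
    return base.upper() if strand == "+" else revcomp(base.upper())


def design_pegrna(
    locus,
    edit: EditSpec,
    pbs_len: int = 12,
    rt_min: int = 10,
    rt_max: int = 16,
    pe3_window: tuple[int, int] = (40, 90),
) -> PegRNADesign:
    """Design the pegRNA (and PE3 second nick) for a single-base edit.

    Among protospacers whose nick lies 1..``rt_max`` bases 5' of the edit on
    the nicked strand, the one minimising nick-to-edit distance wins (ties:
    smaller nick coordinate).  The PBS is the reverse complement of the
    ``pbs_len`` nicked-strand bases ending at the nick; the RT template is
    the reverse complement of the edited strand from the nick, long enough
    to cover the edit plus three downstream bases and at least ``rt_min``.
    A missing PE3 candidate downgrades to a warning, not an error.
    """
    seq = locus.sequence if isinstance(locus, GeneLocus) else str(locus).upper()
    if not seq[edit.pos - 1] == edit.ref.upper():
        raise SequenceError(
            f"edit ref mismatch at {edit.pos}: locus has {seq[edit.pos - 1]}"
        )
    sites = enumerate_protospacers(seq)

    def nick_to_edit(site: ProtospacerSite) -> int:
        # distance in 3' direction on the nicked strand; >0 means the edit
        # is downstream of the nick (reachable by the RT template)
        if site.strand == "+":
            return edit.pos - site.nick_pos
        return site.nick_pos - edit.pos

    candidates = [s for s in sites if 1 <= nick_to_edit(s) <= rt_max]
    if not candidates:
        raise PegDesignError(
            f"no protospacer places the edit within {rt_max} nt 3' of a nick"
        )
    best = min(candidates, key=lambda s: (nick_to_edit(s), s.nick_pos))
    d = nick_to_edit(best)

    if best.strand == "+":
        if best.nick_pos - pbs_len < 0:
            raise PegDesignError("not enough sequence 5' of the nick for the PBS")
        nicked_pbs = seq[best.nick_pos - pbs_len : best.nick_pos]
        rt_len = max(rt_min, d + 3)
        flap = list(seq[best.nick_pos : best.nick_pos + rt_len])
        flap[d - 1] = edit.alt.upper()
        rt_template = revcomp("".join(flap))
    else:
        nicked_pbs_plus = seq[best.nick_pos - 1 : best.nick_pos - 1 + pbs_len]
        nicked_pbs = revcomp(nicked_pbs_plus)
        rt_len = max(rt_min, d + 3)
        lo = best.nick_pos - 1 - rt_len
        if lo < 0:
            raise PegDesignError("not enough sequence for the RT template")
        flap_plus = list(seq[lo : best.nick_pos - 1])
        flap_plus[edit.pos - 1 - lo] = edit.alt.upper()
        rt_template = "".join(flap_plus)  # already the revcomp of the '-' flap
    pbs = revcomp(nicked_pbs)

    design = PegRNADesign(site=best, edit=edit, pbs=pbs, rt_template=rt_template)

    opposite = "-" if best.strand == "+" else "+"
    pe3_candidates = [
        s
        for s in sites
        if s.strand == opposite
        and pe3_window[0] <= abs(s.nick_pos - best.nick_pos) <= pe3_window[1]
    ]
    if pe3_candidates:
        mid = sum(pe3_window) / 2
        design.pe3_site = min(
            pe3_candidates,
            key=lambda s: (abs(abs(s.nick_pos - best.nick_pos) - mid), s.nick_pos),
        )
    else:
        design.warnings.append("no PE3 protospacer in the nick-distance window")
    return design


def validate_design(
    design: PegRNADesign | None = None,
    locus=None,
    spacer: str | None = None,
    extension: str | None = None,
) -> dict:
    """Check pegRNA internal consistency; also works on bare reagents.

    Full mode (``design`` + ``locus``): every structural invariant is
    checked against the locus sequence.  Inference mode (``spacer`` +
    ``extension`` only): the PBS length is inferred as the longest extension
    suffix whose reverse complement equals a protospacer suffix ending at
    the canonical 17/18 nick; the report carries the inferred split.
    Failures are report entries, never exceptions.
    """
    report: dict = {"checks": {}, "ok": True}

    def check(name: str, passed: bool, detail: str = ""):
        report["checks"][name] = {"passed": bool(passed), "detail": detail}
        if not passed:
            report["ok"] = False

    if design is None:
        if spacer is None or extension is None:
            raise ValueError("need either a design or spacer+extension")
        spacer = spacer.upper()
        extension = extension.upper()
        inferred = None
        for n in range(min(len(extension), NICK_OFFSET), 0, -1):
            if revcomp(extension[-n:]) == spacer[NICK_OFFSET - n : NICK_OFFSET]:
                inferred = n
                break
        check(
            "pbs_matches_spacer_suffix",
            inferred is not None,
            f"inferred pbs_len={inferred}" if inferred else
            "no extension suffix revcomp-matches a spacer suffix at the nick",
        )
        report["inferred_pbs_len"] = inferred
        if inferred:
            report["rt_template"] = extension[:-inferred]
            report["pbs"] = extension[-inferred:]
        return report

    seq = locus.sequence if isinstance(locus, GeneLocus) else str(locus).upper()
    site = design.site
    if site.strand == "+":
        nicked_end = seq[site.nick_pos - len(design.pbs) : site.nick_pos]
        flap_ref = seq[site.nick_pos : site.nick_pos + len(design.rt_template)]
        edited_flap = list(flap_ref)
        d = design.edit.pos - site.nick_pos
        if 1 <= d <= len(edited_flap):
            edited_flap[d - 1] = design.edit.alt.upper()
        check(
            "pbs_is_revcomp_of_nicked_strand",
            revcomp(design.pbs) == nicked_end,
        )
        check(
            "rt_template_is_revcomp_of_edited_strand",
            revcomp(design.rt_template) == "".join(edited_flap),
        )
    else:
        nicked_end_plus = seq[site.nick_pos - 1 : site.nick_pos - 1 + len(design.pbs)]
        check(
            "pbs_is_revcomp_of_nicked_strand",
            revcomp(design.pbs) == revcomp(nicked_end_plus),
        )
        lo = site.nick_pos - 1 - len(design.rt_template)
        flap_plus = list(seq[max(lo, 0) : site.nick_pos - 1])
        idx = design.edit.pos - 1 - lo
        if 0 <= idx < len(flap_plus):
            flap_plus[idx] = design.edit.alt.upper()
        check(
            "rt_template_is_revcomp_of_edited_strand",
            design.rt_template == "".join(flap_plus),
        )
    check(
        "edit_base_in_rt_template",
        _strand_base(design.edit.alt, "-" if site.strand == "+" else "+")
        in design.rt_template,
        "complemented edit base must appear in the RT template",
    )
    check(
        "extension_order_rt_then_pbs",
        design.extension == design.rt_template + design.pbs,
    )
    if design.pe3_site is not None:
        dist = abs(design.pe3_site.nick_pos - site.nick_pos)
        check("pe3_on_opposite_strand", design.pe3_site.strand != site.strand)
        report["pe3_nick_distance"] = dist
    return report
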