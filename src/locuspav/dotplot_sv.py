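"""Assembly-vs-reference comparison via exact k-mer anchors.

At locus scale (~100 kb) exact shared k-mers, merged into maximal diagonal
runs ("anchors"), are an adequate replacement for seeded alignment: forward
anchors trace the collinear backbone of a dot plot, reverse-complement
anchors mark inversions, and the anchor-free reference interval flanked by
chained anchors on both sides is the deletion span.  Repetitive k-mers
(occurring more than ``max_occ`` times in either sequence) are skipped.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .locus_model import GeneLocus, revcomp

__all__ = ["Anchor", "SvSegment", "SvReport", "kmer_anchors", "chain_and_classify",
           "dotplot_table"]


@dataclass(frozen=True)
class Anchor:
    """A maximal run of consecutive shared k-mers (1-based inclusive)."""

    ref_start: int
    ref_end: int
    acc_start: int
    acc_end: int
    orientation: str  # "forward" | "inverted"

    def __post_init__(self):
        if self.ref_end - self.ref_start != self.acc_end - self.acc_start:
            raise ValueError("anchor intervals differ in length")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class SvSegment:
    type: str  # collinear | inversion | substitution | unaligned
    ref_start: int
    ref_end: int
    acc_start: int
    acc_end: int


@dataclass
class SvReport:
    deletion_span: tuple[int, int] | None
    segments: list[SvSegment]
    gene_present: bool
    unalignable: bool = False


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _diagonal_runs(ref_index, skip, acc: str, k: int):
    """Yield (diagonal, [acc 0-based start positions]) maximal runs."""
    by_diag: dict[int, list[int]] = defaultdict(list)
    for j in range(len(acc) - k + 1):
        kmer = acc[j : j + k]
        if kmer in skip:
            continue
        for i in ref_index.get(kmer, ()):
            by_diag[i - j].append(j)
    for diag, js in by_diag.items():
        js.sort()
        run_start = js[0]
        prev = js[0]
        for j in js[1:]:
            if j == prev + 1:
                prev = j
                continue
            yield diag, run_start, prev
            run_start = prev = j
        yield diag, run_start, prev


def kmer_anchors(ref: str, acc: str, k: int = 16, max_occ: int = 8) -> list[Anchor]:
    """All maximal forward and reverse-complement k-mer anchors.

    Raises ``ValueError`` for k < 8 (spurious matches dominate below that).
    """
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    if not ref or not acc:
        raise ValueError("sequences must be nonempty")
    ref = ref.upper()
    acc = acc.upper()
    ref_index = _kmer_positions(ref, k)
    acc_counts = Counter(acc[j : j + k] for j in range(len(acc) - k + 1))
    rc_acc = revcomp(acc)
    rc_counts = Counter(rc_acc[j : j + k] for j in range(len(rc_acc) - k + 1))

    skip_fwd = {
        km for km, pos in ref_index.items()
        if len(pos) > max_occ or acc_counts.get(km, 0) > max_occ
    }
    skip_inv = {
        km for km, pos in ref_index.items()
        if len(pos) > max_occ or rc_counts.get(km, 0) > max_occ
    }

    anchors: list[Anchor] = []
    for diag, j0, j1 in _diagonal_runs(ref_index, skip_fwd, acc, k):
        i0 = diag + j0
        anchors.append(
            Anchor(i0 + 1, diag + j1 + k, j0 + 1, j1 + k, "forward")
        )
    L = len(acc)
    for diag, j0, j1 in _diagonal_runs(ref_index, skip_inv, rc_acc, k):
        i0 = diag + j0
        # map reverse-complement coordinates back to the accession frame
        acc_start = L - (j1 + k) + 1
        acc_end = L - j0
        anchors.append(Anchor(i0 + 1, diag + j1 + k, acc_start, acc_end, "inverted"))
    anchors.sort(key=lambda a: (a.ref_start, a.acc_start, a.orientation))
    return anchors


def _chain_forward(anchors: list[Anchor]) -> list[Anchor]:
    """Heaviest collinear chain: LIS on midpoints weighted by anchor length."""
    fwd = sorted(
        (a for a in anchors if a.orientation == "forward"),
        key=lambda a: ((a.ref_start + a.ref_end) / 2, (a.acc_start + a.acc_end) / 2),
    )
    n = len(fwd)
    if n == 0:
        return []
    best = [a.length for a in fwd]
    prev = [-1] * n
    for i in range(n):
        mi = (fwd[i].acc_start + fwd[i].acc_end) / 2
        for j in range(i):
            if (fwd[j].acc_start + fwd[j].acc_end) / 2 < mi and (
                best[j] + fwd[i].length > best[i]
            ):
                best[i] = best[j] + fwd[i].length
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(fwd[end])
        end = prev[end]
    return chain[::-1]


def _cluster_inverted(anchors: list[Anchor], join_dist: int = 200) -> list[SvSegment]:
    inv = sorted((a for a in anchors if a.orientation == "inverted"),
                 key=lambda a: a.ref_start)
    segments: list[SvSegment] = []
    for a in inv:
        if segments and a.ref_start <= segments[-1].ref_end + join_dist:
            s = segments[-1]
            segments[-1] = SvSegment(
                "inversion",
                s.ref_start,
                max(s.ref_end, a.ref_end),
                min(s.acc_start, a.acc_start),
                max(s.acc_end, a.acc_end),
            )
        else:
            segments.append(
                SvSegment("inversion", a.ref_start, a.ref_end, a.acc_start, a.acc_end)
            )
    return segments


def _covered(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def chain_and_classify(
    anchors: list[Anchor],
    locus: GeneLocus,
    min_gene_cov: float = 0.9,
    min_sub: int = 50,
    min_anchor: int = 24,
) -> SvReport:
    """Chain anchors and derive the structural-variant report.

    The deletion span is the maximal reference interval containing the whole
    gene that is covered by no anchor while flanked by chained anchors on
    both sides; inversions are clustered inverted anchors; a substitution is
    a backbone gap uncovered on both the reference and the accession side
    (both gaps >= ``min_sub``).  Anchors shorter than ``min_anchor`` are
    treated as dot-plot noise and ignored here (a lone shared k-mer between
    100 kb sequences is expected by chance; runs of several consecutive
    shared k-mers are not).
    """
    gs, ge = locus.gene.span
    anchors = [a for a in anchors if a.length >= min_anchor]
    if not anchors:
        return SvReport(None, [], gene_present=False, unalignable=True)

    backbone = _chain_forward(anchors)
    inv_segments = _cluster_inverted(anchors)

    # gene coverage by forward anchors
    gene_cov = 0
    for a in anchors:
        if a.orientation != "forward":
            continue
        lo, hi = max(a.ref_start, gs), min(a.ref_end, ge)
        if lo <= hi:
            gene_cov += hi - lo + 1  # forward anchors on one diagonal rarely overlap
    gene_present = gene_cov / (ge - gs + 1) >= min_gene_cov

    # anchor-free interval containing the gene
    cov = _covered([(a.ref_start, a.ref_end) for a in anchors])
    deletion = None
    for (s1, e1), (s2, e2) in zip(cov, cov[1:]):
        gap = (e1 + 1, s2 - 1)
        if gap[0] <= gs and ge <= gap[1]:
            left_ok = any(a.ref_end <= gap[0] - 1 for a in backbone)
            right_ok = any(a.ref_start >= gap[1] + 1 for a in backbone)
            if left_ok and right_ok:
                deletion = gap
            break

    segments: list[SvSegment] = []
    for a in backbone:
        segments.append(
            SvSegment("collinear", a.ref_start, a.ref_end, a.acc_start, a.acc_end)
        )
    segments.extend(inv_segments)
    inv_cov = _covered([(s.ref_start, s.ref_end) for s in inv_segments])
    for a, b in zip(backbone, backbone[1:]):
        ref_gap = b.ref_start - a.ref_end - 1
        acc_gap = b.acc_start - a.acc_end - 1
        iv = (a.ref_end + 1, b.ref_start - 1)
        if deletion and iv[0] <= deletion[0] and deletion[1] <= iv[1]:
            continue
        if any(s <= iv[1] and iv[0] <= e for s, e in inv_cov):
            continue
        if ref_gap >= min_sub and acc_gap >= min_sub:
            segments.append(
                SvSegment("substitution", iv[0], iv[1], a.acc_end + 1, b.acc_start - 1)
            )
        elif ref_gap >= min_sub:
            segments.append(
                SvSegment("unaligned", iv[0], iv[1], a.acc_end + 1, b.acc_start - 1)
            )
    segments.sort(key=lambda s: (s.ref_start, s.ref_end))
    return SvReport(deletion, segments, gene_present=gene_present)


def dotplot_table(anchors: list[Anchor]) -> pd.DataFrame:
    """Plot-ready anchor table; inverted anchors are flagged for red rendering."""
    return pd.DataFrame(
        [
            {
                "ref_start": a.ref_start,
                "ref_end": a.ref_end,
                "acc_start": a.acc_start,
                "acc_end": a.acc_end,
                "orientation": a.orientation,
            }
            for a in anchors
        ],
        columns=["ref_start", "ref_end", "acc_start", "acc_end", "orientation"],
    )
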