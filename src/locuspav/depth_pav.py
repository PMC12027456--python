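"""Presence/absence genotyping of a gene from short-read depth.

Three fixed-width reference intervals are defined: *a* in the conserved
flank upstream of the deletion span, *c* in the conserved flank downstream,
and *b* centred on the junction between the gene's second exon and its
intron.  Mean depth over *b* is compared with the mean of *a* and *c*:

    r = depth_b / ((depth_a + depth_c) / 2)

Homozygous deletion carriers have r near 0, intact accessions near 1, and
heterozygous carriers near 0.5.  The decision thresholds (absent below
``tau_abs`` = 0.15, present above ``tau_pres`` = 0.85, ambiguous between)
place the heterozygous case deep inside the ambiguous band: the mean of a
400 bp Poisson window has a relative standard error of a few percent, so a
present/ambiguous boundary at the heterozygous expectation itself (0.5)
would flip half of all heterozygous accessions by sampling noise alone.
0.85 leaves both the heterozygous (0.5) and the intact (1.0) expectation
many standard errors from the boundary at 20x coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locus_model import CoordinateError, GeneLocus

__all__ = [
    "DepthIntervals",
    "PavCall",
    "place_intervals",
    "load_depth_tsv",
    "mean_depth",
    "classify",
    "cohort_scan",
]


@dataclass(frozen=True)
class DepthIntervals:
    """The three diagnostic intervals (1-based inclusive, pairwise disjoint)."""

    a: tuple[int, int]
    b: tuple[int, int]
    c: tuple[int, int]

    def __post_init__(self):
        ivs = sorted([self.a, self.b, self.c])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise CoordinateError("depth intervals overlap")

    def to_bed(self) -> str:
        """BED (0-based half-open) representation of the three intervals."""
        rows = []
        for name, (s, e) in zip("abc", (self.a, self.b, self.c)):
            rows.append(f"{s - 1}\t{e}\t{name}")
        return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class PavCall:
    accession_id: str
    depth_a: float
    depth_b: float
    depth_c: float
    ratio: float | None
    call: str  # present | absent | ambiguous
    low_confidence: bool = False
    error: str | None = None


def place_intervals(
    locus: GeneLocus,
    deletion_span: tuple[int, int],
    interval_len: int = 400,
    margin: int = 500,
) -> DepthIntervals:
    """Place the a/b/c intervals relative to a known deletion span.

    *a* ends ``margin`` bp before the deletion start, *c* begins ``margin``
    bp after its end, and *b* is centred on the exon-2/intron junction.
    """
    ds, de = deletion_span
    gs, ge = locus.gene.span
    if not (ds <= gs and ge <= de):
        raise CoordinateError("deletion span does not cover the gene")
    a = (ds - margin - interval_len, ds - margin - 1)
    c = (de + margin + 1, de + margin + interval_len)
    if a[0] < 1:
        raise CoordinateError(
            f"insufficient upstream flank: interval a would start at {a[0]}"
        )
    if c[1] > len(locus):
        raise CoordinateError(
            f"insufficient downstream flank: interval c would end at {c[1]}"
        )
    if len(locus.gene.exons) < 2:
        raise CoordinateError("b interval needs a two-exon gene model")
    junction = locus.gene.exons[-1][0]  # last exon start = 3' end of the intron
    b = (junction - interval_len // 2, junction + interval_len // 2 - 1)
    if not (ds <= b[0] and b[1] <= de):
        raise CoordinateError("b interval falls outside the deletion span")
    return DepthIntervals(a=a, b=b, c=c)


def load_depth_tsv(path, locus_length: int) -> np.ndarray:
    """Read a (chrom, pos, depth) TSV into a dense per-base array.

    Positions absent from the table count as depth 0.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"pos": np.int64, "depth": np.float64},
    )
    depth = np.zeros(locus_length)
    pos = df["pos"].to_numpy()
    keep = (pos >= 1) & (pos <= locus_length)
    depth[pos[keep] - 1] = df["depth"].to_numpy()[keep]
    return depth


def mean_depth(depth: np.ndarray, interval: tuple[int, int]) -> float:
    """Arithmetic mean depth over a 1-based inclusive interval."""
    s, e = interval
    if s < 1 or e < s:
        raise CoordinateError(f"bad interval ({s},{e})")
    window = depth[s - 1 : e]
    if len(window) < e - s + 1:  # beyond table end: absent positions are 0
        window = np.concatenate([window, np.zeros(e - s + 1 - len(window))])
    return float(window.mean())


def classify(
    accession_id: str,
    depth_a: float,
    depth_b: float,
    depth_c: float,
    tau_abs: float = 0.15,
    tau_pres: float = 0.85,
    min_flank_depth: float = 5.0,
) -> PavCall:
    """Classify one accession from its three interval depths."""
    if tau_abs >= tau_pres:
        raise ValueError("tau_abs must be < tau_pres")
    if min(depth_a, depth_b, depth_c) < 0:
        raise ValueError("negative depth")
    flank = (depth_a + depth_c) / 2
    if flank == 0:
        return PavCall(
            accession_id, depth_a, depth_b, depth_c, None, "ambiguous",
            low_confidence=True,
        )
    r = depth_b / flank
    if r < tau_abs:
        call = "absent"
    elif r > tau_pres:
        call = "present"
    else:
        call = "ambiguous"
    return PavCall(
        accession_id, depth_a, depth_b, depth_c, r, call,
        low_confidence=flank < min_flank_depth,
    )


def cohort_scan(
    depth_tables,
    intervals: DepthIntervals,
    tau_abs: float = 0.15,
    tau_pres: float = 0.85,
    min_flank_depth: float = 5.0,
    locus_length: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scan a cohort of depth tables and tabulate presence/absence calls.

    ``depth_tables`` maps accession id to a per-base depth array or a TSV
    path (``locus_length`` required for paths).  A failing accession yields
    an error record; the scan continues.  Absent accessions correspond to
    the whole-gene-deletion haplotype class H0 downstream.
    """
    calls: list[PavCall] = []
    for acc, src in depth_tables.items():
        try:
            if isinstance(src, (str,)) or hasattr(src, "__fspath__"):
                if locus_length is None:
                    raise ValueError("locus_length required for TSV inputs")
                depth = load_depth_tsv(src, locus_length)
            else:
                depth = np.asarray(src, dtype=float)
            calls.append(
                classify(
                    acc,
                    mean_depth(depth, intervals.a),
                    mean_depth(depth, intervals.b),
                    mean_depth(depth, intervals.c),
                    tau_abs,
                    tau_pres,
                    min_flank_depth,
                )
            )
        except (OSError, ValueError, CoordinateError) as exc:
            calls.append(
                PavCall(acc, 0.0, 0.0, 0.0, None, "ambiguous",
                        low_confidence=True, error=str(exc))
            )
    table = pd.DataFrame(
        [
            {
                "accession_id": c.accession_id,
                "depth_a": c.depth_a,
                "depth_b": c.depth_b,
                "depth_c": c.depth_c,
                "ratio": c.ratio,
                "call": c.call,
                "low_confidence": c.low_confidence,
                "error": c.error,
            }
            for c in calls
        ],
        columns=["accession_id", "depth_a", "depth_b", "depth_c", "ratio",
                 "call", "low_confidence", "error"],
    )
    summary = {
        "n": len(calls),
        "present": int((table["call"] == "present").sum()),
        "absent": int((table["call"] == "absent").sum()),
        "ambiguous": int((table["call"] == "ambiguous").sum()),
        "errors": int(table["error"].notna().sum()),
    }
    return table, summary
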