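"""Synthetic inputs for every pipeline stage, with machine-readable truth.

The generator emulates the data situation around a rice heading-date locus:
a reference chromosome segment carrying a two-exon gene with conserved
flanks; accession assemblies in which a subset of accessions carry a
compound ~60 kb structural variant spanning the gene (one large deletion
plus nested inversions/substitutions in the flanks); Poisson short-read
depth profiles with near-zero off-target depth over deleted spans; and a
gene-region SNP matrix with clustered founder haplotypes, injected
heterozygous and missing calls, and subpopulation labels correlated with
haplotype.

Determinism: one seed in :class:`SimConfig` drives everything; per-accession
sub-streams are derived by stable hashing of the accession id, so adding
accessions never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .locus_model import GeneLocus, GeneModel, STOP_CODONS, revcomp

__all__ = [
    "SimConfig",
    "SvEvent",
    "AccessionTruth",
    "TruthTable",
    "simulate_reference",
    "simulate_accessions",
    "simulate_depth",
    "simulate_snp_matrix",
    "write_depth_tsv",
    "write_vcf",
    "ghd7_like_locus",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the locus architecture at reduced scale: a 120 kb
    segment with a two-exon gene (699 + 450 bp exons, 500 bp intron, CDS =
    whole transcript) and a 60 kb deletion centred on the gene in carrier
    accessions.  Depth defaults to 20x with off-target mapping depth inside
    deleted spans at 0.02x of the mean.
    """

    seed: int = 0
    locus_length: int = 120_000
    exon_lengths: tuple[int, int] = (699, 450)
    intron_length: int = 500
    gene_strand: str = "+"
    origin_offset: int = 1
    n_accessions: int = 200
    deletion_fraction: float = 0.15
    deletion_length: int = 60_000
    n_flank_svs: tuple[int, int] = (1, 3)
    inversion_size: tuple[int, int] = (2_000, 6_000)
    substitution_size: tuple[int, int] = (1_000, 4_000)
    mean_depth: float = 20.0
    depth_noise_factor: float = 0.02
    snp_count: int = 46
    include_indel: bool = True
    haplotype_count: int = 8
    het_rate: float = 0.05
    missing_rate: float = 0.05
    subpopulations: tuple[str, ...] = ("XI", "GJ", "aus")
    subpop_confusion: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.deletion_fraction <= 1.0:
            raise ConfigError("deletion_fraction must be in [0,1]")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.haplotype_count > self.n_accessions:
            raise ConfigError("haplotype_count cannot exceed n_accessions")
        gene_len = sum(self.exon_lengths) + self.intron_length
        if gene_len + 2_000 > self.locus_length:
            raise ConfigError("gene does not fit in locus_length with flanks")
        if sum(self.exon_lengths) % 3:
            raise ConfigError("spliced CDS length must be divisible by 3")

    @property
    def noise_depth(self) -> float:
        return self.depth_noise_factor * self.mean_depth


@dataclass(frozen=True)
class SvEvent:
    """One planted structural-variant event, in both coordinate frames."""

    type: str  # deletion | inversion | substitution | insertion
    ref_start: int
    ref_end: int
    acc_start: int
    acc_end: int


@dataclass
class AccessionTruth:
    accession_id: str
    gene_present: bool
    sv_events: list[SvEvent] = field(default_factory=list)
    haplotype_label: str | None = None
    genotype: list[int] | None = None


@dataclass
class TruthTable:
    """Per-accession ground truth written alongside every artefact."""

    records: dict[str, AccessionTruth]
    deletion_span: tuple[int, int] | None = None

    def carriers(self) -> list[str]:
        return [a for a, r in self.records.items() if not r.gene_present]

    def to_json(self, path) -> None:
        payload = {
            "deletion_span": self.deletion_span,
            "records": {
                a: {
                    "gene_present": r.gene_present,
                    "sv_events": [asdict(e) for e in r.sv_events],
                    "haplotype_label": r.haplotype_label,
                }
                for a, r in self.records.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-item RNG stream, stable under cohort growth."""
    return np.random.default_rng(
        (int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF)
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    if n_nt % 3 or n_nt < 9:
        raise ConfigError("CDS length must be a multiple of 3 and >= 9")
    n_internal = n_nt // 3 - 2
    sense = sorted(set(_all_codons()) - STOP_CODONS)
    codons = rng.choice(np.array(sense), size=n_internal)
    stop = rng.choice(np.array(sorted(STOP_CODONS)))
    return "ATG" + "".join(codons.tolist()) + str(stop)


def _all_codons():
    return {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}


# ---------------------------------------------------------------------------
# reference locus
# ---------------------------------------------------------------------------


def simulate_reference(cfg: SimConfig) -> GeneLocus:
    """Reference segment with a canonical two-exon gene at its centre.

    The intron begins GT and ends AG (canonical splice sites); the CDS spans
    the whole spliced transcript, starts ATG, ends with a stop codon, and
    contains no internal stop — all by construction.
    """
    rng = _substream(cfg.seed, "reference")
    e1, e2 = cfg.exon_lengths
    gene_len = e1 + cfg.intron_length + e2
    gene_start = (cfg.locus_length - gene_len) // 2 + 1
    backbone = list(_random_dna(rng, cfg.locus_length))

    cds = _random_cds(rng, e1 + e2)
    intron = list(_random_dna(rng, cfg.intron_length))
    intron[0:2] = "GT"
    intron[-2:] = "AG"
    gene_seq = cds[:e1] + "".join(intron) + cds[e1:]
    if cfg.gene_strand == "-":
        # coding strand is '-': the '+' frame carries the reverse complement,
        # so the genomic-first exon is the (shorter) coding-last one
        gene_seq = revcomp(gene_seq)
        e1, e2 = e2, e1
    backbone[gene_start - 1 : gene_start - 1 + gene_len] = gene_seq

    exon1 = (gene_start, gene_start + e1 - 1)
    intron_iv = (exon1[1] + 1, exon1[1] + cfg.intron_length)
    exon2 = (intron_iv[1] + 1, intron_iv[1] + e2)
    model = GeneModel(
        gene_id="geneA",
        strand=cfg.gene_strand,
        exons=(exon1, exon2),
        cds=(1, e1 + e2),
    )
    return GeneLocus(
        chrom_id="chrSim",
        sequence="".join(backbone),
        gene=model,
        origin_offset=cfg.origin_offset,
        flank_size=gene_start - 1,
    )


def deletion_span(cfg: SimConfig, locus: GeneLocus) -> tuple[int, int]:
    """The planted deletion interval: ``deletion_length`` bp centred on the gene."""
    gs, ge = locus.gene.span
    mid = (gs + ge) // 2
    start = max(2, mid - cfg.deletion_length // 2)
    end = min(len(locus) - 1, start + cfg.deletion_length - 1)
    if start > gs or end < ge:
        raise ConfigError("deletion_length does not cover the gene span")
    return start, end


# ---------------------------------------------------------------------------
# accession assemblies with planted compound SVs
# ---------------------------------------------------------------------------


def _apply_sv_plan(
    ref: str, plan: list[tuple[str, int, int, str | None]]
) -> tuple[str, list[SvEvent]]:
    """Rebuild an accession sequence from non-overlapping ref-ordered edits.

    ``plan`` entries are (type, ref_start, ref_end, payload); payload is the
    replacement sequence for substitutions/insertions, ignored otherwise.
    """
    plan = sorted(plan, key=lambda t: t[1])
    out: list[str] = []
    events: list[SvEvent] = []
    cursor = 1  # next unconsumed ref position
    acc_len = 0
    for typ, rs, re_, payload in plan:
        out.append(ref[cursor - 1 : rs - 1])
        acc_len += rs - cursor
        if typ == "deletion":
            events.append(SvEvent("deletion", rs, re_, acc_len + 1, acc_len))
        elif typ == "inversion":
            block = revcomp(ref[rs - 1 : re_])
            events.append(SvEvent("inversion", rs, re_, acc_len + 1, acc_len + len(block)))
            out.append(block)
            acc_len += len(block)
        elif typ == "substitution":
            events.append(
                SvEvent("substitution", rs, re_, acc_len + 1, acc_len + len(payload))
            )
            out.append(payload)
            acc_len += len(payload)
        elif typ == "insertion":
            # insertion after ref position rs (re_ == rs)
            out.append(ref[rs - 1 : re_])
            acc_len += re_ - rs + 1
            events.append(
                SvEvent("insertion", re_, re_, acc_len + 1, acc_len + len(payload))
            )
            out.append(payload)
            acc_len += len(payload)
        else:
            raise ConfigError(f"unknown SV type {typ!r}")
        cursor = re_ + 1
    out.append(ref[cursor - 1 :])
    return "".join(out), events


def _draw_interval(rng, lo: int, hi: int, size_range: tuple[int, int],
                   taken: list[tuple[int, int]]) -> tuple[int, int] | None:
    """A random interval of drawn size inside [lo,hi] avoiding ``taken``."""
    for _ in range(50):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if hi - lo + 1 < size:
            continue
        start = int(rng.integers(lo, hi - size + 2))
        iv = (start, start + size - 1)
        if all(iv[1] < s - 200 or iv[0] > e + 200 for s, e in taken):
            return iv
    return None


def simulate_accessions(
    cfg: SimConfig, locus: GeneLocus
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Accession assemblies: deletion carriers get a compound SV, others SNPs.

    Carriers receive the gene-spanning deletion plus 1–3 nested inversions /
    substitutions in the flanks; non-carriers receive only scattered flank
    SNPs.  Truth records every event in both reference and accession
    coordinates; ``gene_present`` is false exactly when a deletion event
    covers the full gene span.
    """
    rng = _substream(cfg.seed, "cohort")
    n = cfg.n_accessions
    ids = [f"ACC{i:04d}" for i in range(1, n + 1)]
    n_carriers = int(round(n * cfg.deletion_fraction))
    carrier_ids = set(rng.permutation(np.array(ids))[:n_carriers].tolist())
    span = deletion_span(cfg, locus)

    records: dict[str, AccessionTruth] = {}
    assemblies: list[tuple[str, str]] = []
    ref = locus.sequence
    for acc in ids:
        arng = _substream(cfg.seed, f"acc:{acc}")
        if acc in carrier_ids:
            plan: list = [("deletion", span[0], span[1], None)]
            taken = [span]
            n_extra = int(arng.integers(cfg.n_flank_svs[0], cfg.n_flank_svs[1] + 1))
            for _ in range(n_extra):
                typ = str(arng.choice(np.array(["inversion", "substitution"])))
                side_left = bool(arng.random() < 0.5)
                lo, hi = (500, span[0] - 500) if side_left else (span[1] + 500, len(ref) - 500)
                size_range = (
                    cfg.inversion_size if typ == "inversion" else cfg.substitution_size
                )
                iv = _draw_interval(arng, lo, hi, size_range, taken)
                if iv is None:
                    continue
                payload = (
                    _random_dna(arng, iv[1] - iv[0] + 1) if typ == "substitution" else None
                )
                plan.append((typ, iv[0], iv[1], payload))
                taken.append(iv)
            seq, events = _apply_sv_plan(ref, plan)
            records[acc] = AccessionTruth(acc, gene_present=False, sv_events=events)
        else:
            seq = list(ref)
            gs, ge = locus.gene.span
            n_snps = int(arng.integers(10, 40))
            for _ in range(n_snps):
                pos = int(arng.integers(1, len(ref) + 1))
                if gs <= pos <= ge:
                    continue
                cur = seq[pos - 1]
                seq[pos - 1] = str(
                    arng.choice(np.array([b for b in "ACGT" if b != cur]))
                )
            seq = "".join(seq)
            records[acc] = AccessionTruth(acc, gene_present=True)
        assemblies.append((acc, seq))
    return assemblies, TruthTable(records=records, deletion_span=span)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------


def simulate_depth(
    cfg: SimConfig,
    locus: GeneLocus,
    truth: TruthTable,
    heterozygous: Sequence[str] = (),
) -> dict[str, np.ndarray]:
    """Per-base read depth per accession over the reference frame.

    Depth is Poisson(mean_depth) over present positions and
    Poisson(noise_depth) over positions deleted in that accession; accessions
    listed in ``heterozygous`` carry the deletion on one haplotype only and
    get Poisson(mean_depth / 2) over the span instead.
    """
    het = set(heterozygous)
    out: dict[str, np.ndarray] = {}
    L = len(locus)
    for acc, rec in truth.records.items():
        arng = _substream(cfg.seed, f"depth:{acc}")
        lam = np.full(L, cfg.mean_depth)
        for ev in rec.sv_events:
            if ev.type == "deletion":
                level = cfg.mean_depth / 2 if acc in het else cfg.noise_depth
                lam[ev.ref_start - 1 : ev.ref_end] = level
        out[acc] = (
            arng.poisson(lam) if lam.max() > 0 else np.zeros(L, dtype=np.int64)
        )
    return out


def write_depth_tsv(path, chrom: str, depth: np.ndarray) -> None:
    """3-column depth table: chrom, 1-based position, depth."""
    df = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, len(depth) + 1), "depth": depth}
    )
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# SNP matrix / haplotype truth
# ---------------------------------------------------------------------------


def simulate_snp_matrix(cfg: SimConfig, locus: GeneLocus):
    """Gene-region variant matrix with founder haplotypes and injected noise.

    Returns ``(variants, samples, genotypes, metadata, truth)`` where
    ``genotypes`` is an (n_samples, n_variants) int matrix coded
    0=hom-ref, 1=hom-alt, 2=het, -1=missing; ``metadata`` maps samples to
    subpopulation labels; ``truth`` records each sample's founder haplotype
    and which samples a heterozygosity/missingness filter must exclude.
    Exactly ``round(het_rate * n)`` samples carry >=1 het call and
    ``round(missing_rate * n)`` further samples carry >=1 missing call.
    """
    rng = _substream(cfg.seed, "snps")
    gs, ge = locus.gene.span
    n_var = cfg.snp_count + (1 if cfg.include_indel else 0)
    positions = np.sort(
        rng.choice(np.arange(gs, ge + 1), size=n_var, replace=False)
    )
    variants = []
    for i, pos in enumerate(positions):
        ref = locus.sequence[pos - 1]
        is_indel = cfg.include_indel and i == n_var // 2
        if is_indel:
            alt = ref + str(rng.choice(_BASES).decode())
        else:
            alt = str(rng.choice(np.array([b for b in "ACGT" if b != ref])))
        variants.append(
            {"chrom": locus.chrom_id, "pos": int(pos), "ref": ref, "alt": alt,
             "is_indel": is_indel}
        )

    # distinct founder allele vectors, skewed carrier counts
    founders = set()
    while len(founders) < cfg.haplotype_count:
        founders.add(tuple(rng.integers(0, 2, size=n_var).tolist()))
    founders = [np.array(f) for f in sorted(founders)]
    rng.shuffle(founders)
    weights = np.array([2.0 ** -(i * 0.7) for i in range(cfg.haplotype_count)])
    weights /= weights.sum()

    n = cfg.n_accessions
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    # guarantee every founder appears at least once, rest drawn by weight
    assign = list(range(cfg.haplotype_count))
    assign += rng.choice(
        cfg.haplotype_count, size=n - cfg.haplotype_count, p=weights
    ).tolist()
    assign = np.array(assign)
    rng.shuffle(assign)

    geno = np.stack([founders[a].copy() for a in assign])

    # exact numbers of het-bearing / missing-bearing samples (disjoint sets);
    # never consume a founder's last clean carrier, so every founder haplotype
    # remains recoverable after filtering
    n_het = int(round(cfg.het_rate * n))
    n_miss = int(round(cfg.missing_rate * n))
    clean_count = {h: int((assign == h).sum()) for h in range(cfg.haplotype_count)}
    het_samples: set[int] = set()
    miss_samples: set[int] = set()
    for idx in rng.permutation(n).tolist():
        f = int(assign[idx])
        if clean_count[f] <= 1:
            continue
        if len(het_samples) < n_het:
            het_samples.add(idx)
        elif len(miss_samples) < n_miss:
            miss_samples.add(idx)
        else:
            break
        clean_count[f] -= 1
    for si in het_samples:
        for vi in rng.choice(n_var, size=int(rng.integers(1, 4)), replace=False):
            geno[si, vi] = 2
    for si in miss_samples:
        for vi in rng.choice(n_var, size=int(rng.integers(1, 4)), replace=False):
            geno[si, vi] = -1

    # subpopulation labels correlated with founder haplotype
    subpops = list(cfg.subpopulations)
    home = {h: subpops[h % len(subpops)] for h in range(cfg.haplotype_count)}
    labels = []
    for a in assign:
        if rng.random() < cfg.subpop_confusion:
            labels.append(str(rng.choice(np.array(subpops))))
        else:
            labels.append(home[int(a)])
    metadata = pd.DataFrame({"sample_id": samples, "subpopulation": labels})

    truth = {
        "founder_of": {s: int(a) for s, a in zip(samples, assign)},
        "founder_vectors": [f.tolist() for f in founders],
        "het_samples": sorted(samples[i] for i in het_samples),
        "missing_samples": sorted(samples[i] for i in miss_samples),
        "excluded": sorted(samples[i] for i in het_samples | miss_samples),
    }
    return variants, samples, geno, metadata, truth


def write_vcf(path, variants, samples, genotypes) -> None:
    """Minimal VCF 4.2 with GT fields, matching the generator's coding."""
    gt_map = {0: "0/0", 1: "1/1", 2: "0/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chrom = variants[0]["chrom"] if variants else "chrSim"
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for vi, v in enumerate(variants):
            gts = "\t".join(gt_map[int(g)] for g in genotypes[:, vi])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# synthetic stand-in for the real heading-date gene
# ---------------------------------------------------------------------------


def ghd7_like_locus(seed: int = 42):
    """SYNTHETIC stand-in locus mimicking the *Ghd7* splice architecture.

    This is not the real Nipponbare sequence: it is a generated two-exon
    locus engineered so that (i) the intron ends in a canonical AG acceptor,
    (ii) the first in-frame cryptic AG downstream sits exactly 34 bp into
    exon 2, and (iii) a CCT-like domain annotation occupies the C-terminal
    part of the protein.  Disabling the canonical acceptor therefore
    reproduces the documented failure mode of the H6 haplotype — a 34 bp
    cDNA deletion, a frameshift, and loss of the CCT domain — on sequence
    that ships with the package.

    Returns ``(locus, cct_domain)``.
    """
    from .locus_model import DomainAnnotation

    cfg = SimConfig(
        seed=seed, locus_length=8_000, exon_lengths=(699, 450), intron_length=500
    )
    locus = simulate_reference(cfg)
    seq = list(locus.sequence)
    e2s = locus.gene.exons[1][0]
    # Rewrite the first 14 codons of exon 2 deterministically: C/T-only codons
    # (never a stop, never an AG) up to offset 29, then CCA+GCC planting the
    # cryptic acceptor AG at offsets 32-33 (acceptor ends 33 bp in, so the
    # cryptic exon starts at +34), then two more C/T-only codons.
    block = (
        "CTCCTTTCCTTCCTCTCTCCTTTCTCCTCT"  # offsets 0-29
        + "CCA" + "GCC"                   # offsets 30-35, AG at 32/33
        + "TCCTCT"                        # offsets 36-41
        + "CTGA"                          # offsets 42-45: TGA stop in the
                                          # shifted frame, CTG/Axx in the
                                          # reference frame (no ref stop)
    )
    assert len(block) == 46 and "AG" not in block[:32]
    seq[e2s - 1 : e2s - 1 + 46] = block
    locus = GeneLocus(
        chrom_id="chrSynGhd7",
        sequence="".join(seq),
        gene=locus.gene,
        origin_offset=locus.origin_offset,
        flank_size=locus.flank_size,
    )
    prot_len = locus.gene.spliced_length // 3
    cct = DomainAnnotation("CCT", prot_len - 45, prot_len - 3)
    return locus, cct
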