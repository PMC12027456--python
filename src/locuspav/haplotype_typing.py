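"""Gene-region haplotype typing from a biallelic variant matrix.

Samples carrying any heterozygous or missing call — and samples already
typed as whole-gene deletion (H0) by the depth stage — are excluded, each
with a logged reason.  The retained samples' allele vectors are collapsed
into haplotypes labelled H1, H2, ... by descending carrier count (ties
broken by first-seen sample order); H0 is reserved for the deletion class
and carries no allele vector.  Haplotype relatedness is summarised by a
neighbor-joining tree on Hamming distances between allele vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpMatrix",
    "Haplotype",
    "read_vcf",
    "filter_samples",
    "collapse_haplotypes",
    "subpop_frequencies",
    "nj_tree",
]

# genotype codes
REF, ALT, HET, MISSING = 0, 1, 2, -1


@dataclass
class SnpMatrix:
    """Biallelic variants x samples with genotypes {0 ref, 1 alt, 2 het, -1 missing}."""

    variants: list[dict]  # chrom, pos, ref, alt, is_indel
    samples: list[str]
    genotypes: np.ndarray  # shape (n_samples, n_variants)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix shape mismatch")
        positions = [v["pos"] for v in self.variants]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("variant positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class Haplotype:
    """A distinct allele vector with its carriers; H0 = whole-gene deletion."""

    label: str
    alleles: tuple[int, ...] | None  # None for H0
    carriers: list[str]
    subpop_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def read_vcf(path) -> SnpMatrix:
    """Load a VCF 4.2 into a :class:`SnpMatrix` (biallelic records only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[dict] = []
    columns: list[np.ndarray] = []
    # gts012 coding: 0=HOM_REF, 1=HET, 2=HOM_ALT, 3=UNKNOWN
    remap = {0: REF, 1: HET, 2: ALT, 3: MISSING}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported"
            )
        variants.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "is_indel": len(rec.REF) != len(rec.ALT[0]),
            }
        )
        columns.append(np.array([remap[int(g)] for g in rec.gt_types]))
    vcf.close()
    geno = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), int)
    )
    return SnpMatrix(variants=variants, samples=samples, genotypes=geno)


def filter_samples(
    m: SnpMatrix, h0_carriers: Sequence[str] = ()
) -> tuple[SnpMatrix, pd.DataFrame]:
    """Drop samples with any het or missing call, and known H0 carriers.

    Returns the filtered matrix and an exclusion log (sample_id, reason).
    A sample matching several reasons is logged once with the first matching
    reason, in the order: whole-gene deletion, heterozygous call, missing call.
    """
    h0 = set(h0_carriers)
    keep: list[int] = []
    log: list[dict] = []
    for i, s in enumerate(m.samples):
        row = m.genotypes[i]
        if s in h0:
            log.append({"sample_id": s, "reason": "whole_gene_deletion"})
        elif (row == HET).any():
            log.append({"sample_id": s, "reason": "heterozygous_call"})
        elif (row == MISSING).any():
            log.append({"sample_id": s, "reason": "missing_call"})
        else:
            keep.append(i)
    filtered = SnpMatrix(
        variants=m.variants,
        samples=[m.samples[i] for i in keep],
        genotypes=m.genotypes[keep] if keep else np.empty((0, m.n_variants), int),
    )
    return filtered, pd.DataFrame(log, columns=["sample_id", "reason"])


def collapse_haplotypes(
    m: SnpMatrix, h0_carriers: Sequence[str] = ()
) -> list[Haplotype]:
    """Group identical allele vectors into labelled haplotypes.

    Labels H1, H2, ... are assigned by descending carrier count with ties
    broken by first-seen sample order; H0 (empty allele vector) is appended
    from ``h0_carriers`` when given.  Input must already be filtered: any
    residual het/missing code is an error.
    """
    if m.n_samples and ((m.genotypes == HET) | (m.genotypes == MISSING)).any():
        raise ValueError("collapse_haplotypes requires a filtered matrix")
    groups: dict[tuple[int, ...], list[str]] = {}
    order: dict[tuple[int, ...], int] = {}
    for i, s in enumerate(m.samples):
        key = tuple(int(g) for g in m.genotypes[i])
        groups.setdefault(key, []).append(s)
        order.setdefault(key, i)
    ranked = sorted(groups, key=lambda k: (-len(groups[k]), order[k]))
    haplotypes = [
        Haplotype(label=f"H{i}", alleles=k, carriers=groups[k])
        for i, k in enumerate(ranked, start=1)
    ]
    if h0_carriers:
        haplotypes.append(
            Haplotype(label="H0", alleles=None, carriers=list(h0_carriers))
        )
    return haplotypes


def subpop_frequencies(
    haplotypes: list[Haplotype], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Carrier counts and within-subpopulation proportions per haplotype.

    ``metadata`` needs columns sample_id and subpopulation.  Carriers absent
    from the metadata are tallied under an ``unassigned`` column rather than
    dropped.  Proportion columns (``p_<subpop>``) sum to 1 over haplotypes.
    """
    label_of = dict(
        zip(metadata["sample_id"].astype(str), metadata["subpopulation"].astype(str))
    )
    subpops = sorted(set(label_of.values()))
    rows = []
    for h in haplotypes:
        counts = {sp: 0 for sp in subpops}
        unassigned = 0
        for s in h.carriers:
            sp = label_of.get(s)
            if sp is None:
                unassigned += 1
            else:
                counts[sp] += 1
        h.subpop_counts = dict(counts)
        rows.append({"haplotype": h.label, **counts, "unassigned": unassigned})
    table = pd.DataFrame(
        rows, columns=["haplotype", *subpops, "unassigned"]
    )
    if len(table):
        for sp in subpops:
            total = table[sp].sum()
            table[f"p_{sp}"] = table[sp] / total if total else 0.0
    return table


def hamming_matrix(haplotypes: list[Haplotype]) -> tuple[list[str], np.ndarray]:
    """Pairwise Hamming distances between allele vectors (H0 excluded)."""
    with_vec = [h for h in haplotypes if h.alleles is not None]
    labels = [h.label for h in with_vec]
    vecs = np.array([h.alleles for h in with_vec])
    if len(vecs) == 0:
        return labels, np.zeros((0, 0))
    dm = (vecs[:, None, :] != vecs[None, :, :]).sum(axis=2).astype(float)
    return labels, dm


def nj_tree(haplotypes: list[Haplotype]) -> str:
    """Neighbor-joining tree of haplotype allele vectors, as newick.

    Distances are Hamming distances; H0 has no vector and is excluded.
    Negative branch lengths (a known NJ artefact on non-additive matrices)
    are clamped to zero with a warning.  Fewer than 3 typable haplotypes
    yield a degenerate tree with a warning rather than an error.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    labels, dm = hamming_matrix(haplotypes)
    if len(labels) < 3:
        warnings.warn(f"only {len(labels)} haplotypes; emitting degenerate tree")
        if not labels:
            return ";"
        if len(labels) == 1:
            return f"{labels[0]};"
        d = dm[0, 1]
        return f"({labels[0]}:{d / 2:g},{labels[1]}:{d / 2:g});"
    tree = nj(DistanceMatrix(dm, ids=labels))
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return str(tree).strip()
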