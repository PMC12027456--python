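"""Sample filtering, haplotype collapse, subpopulation tables, NJ tree."""

import io

import numpy as np
import pandas as pd
import pytest

import locuspav as lp
import locuspav.haplotype_typing as ht
import locuspav.synthetic_data as sd


def _matrix(rows, samples=None, positions=None):
    geno = np.array(rows)
    n_var = geno.shape[1]
    positions = positions or list(range(100, 100 + n_var))
    variants = [
        {"chrom": "chr", "pos": p, "ref": "A", "alt": "T", "is_indel": False}
        for p in positions
    ]
    samples = samples or [f"s{i}" for i in range(len(rows))]
    return ht.SnpMatrix(variants=variants, samples=samples, genotypes=geno)


class TestFilterSamples:
    def test_clean_matrix_is_identity(self):
        m = _matrix([[0, 1], [1, 0]])
        filt, log = ht.filter_samples(m)
        assert filt.samples == m.samples
        assert log.empty

    def test_het_missing_and_h0_reasons(self):
        m = _matrix([[0, 1], [2, 0], [0, -1], [1, 1]])
        filt, log = ht.filter_samples(m, h0_carriers=["s3"])
        assert filt.samples == ["s0"]
        reasons = dict(zip(log["sample_id"], log["reason"]))
        assert reasons == {
            "s1": "heterozygous_call",
            "s2": "missing_call",
            "s3": "whole_gene_deletion",
        }

    def test_all_excluded_no_exception(self):
        m = _matrix([[2, 0], [0, -1]])
        filt, log = ht.filter_samples(m)
        assert filt.samples == [] and len(log) == 2

    def test_generator_truth_exclusions(self):
        cfg = lp.SimConfig(seed=31, n_accessions=100, het_rate=0.12,
                           missing_rate=0.0)
        locus = sd.simulate_reference(cfg)
        variants, samples, geno, _, truth = sd.simulate_snp_matrix(cfg, locus)
        m = ht.SnpMatrix(variants=variants, samples=samples, genotypes=geno)
        _, log = ht.filter_samples(m)
        assert sorted(log["sample_id"]) == truth["het_samples"]
        assert len(log) == 12

    def test_conservation_of_samples(self):
        m = _matrix([[0, 1], [2, 0], [0, -1], [1, 1]])
        filt, log = ht.filter_samples(m)
        assert len(filt.samples) + len(log) == m.n_samples


class TestCollapseHaplotypes:
    def test_all_identical_single_haplotype(self):
        m = _matrix([[0, 1]] * 4)
        haps = ht.collapse_haplotypes(m)
        assert [h.label for h in haps] == ["H1"]
        assert haps[0].n_carriers == 4

    def test_counting_order_5_3_2(self):
        rows = [[0, 0]] * 5 + [[1, 0]] * 3 + [[0, 1]] * 2
        haps = ht.collapse_haplotypes(_matrix(rows))
        assert [(h.label, h.n_carriers) for h in haps] == [
            ("H1", 5), ("H2", 3), ("H3", 2)
        ]

    def test_h0_attached_with_no_vector(self):
        haps = ht.collapse_haplotypes(_matrix([[0, 1]]), h0_carriers=["d1", "d2"])
        h0 = [h for h in haps if h.label == "H0"][0]
        assert h0.alleles is None and h0.n_carriers == 2

    def test_generator_truth_partition(self):
        cfg = lp.SimConfig(seed=33, n_accessions=80, haplotype_count=8,
                           het_rate=0.0, missing_rate=0.0)
        locus = sd.simulate_reference(cfg)
        variants, samples, geno, _, truth = sd.simulate_snp_matrix(cfg, locus)
        m = ht.SnpMatrix(variants=variants, samples=samples, genotypes=geno)
        haps = ht.collapse_haplotypes(m)
        assert len(haps) == 8
        # partition matches founder assignment
        founder_of = truth["founder_of"]
        for h in haps:
            assert len({founder_of[s] for s in h.carriers}) == 1

    def test_label_stability_under_sample_permutation(self):
        rows = [[0, 0]] * 5 + [[1, 0]] * 3 + [[0, 1]] * 2
        m = _matrix(rows)
        rng = np.random.default_rng(2)
        perm = rng.permutation(m.n_samples)
        m2 = ht.SnpMatrix(
            variants=m.variants,
            samples=[m.samples[i] for i in perm],
            genotypes=m.genotypes[perm],
        )
        part1 = {frozenset(h.carriers) for h in ht.collapse_haplotypes(m)}
        part2 = {frozenset(h.carriers) for h in ht.collapse_haplotypes(m2)}
        assert part1 == part2

    def test_unfiltered_matrix_rejected(self):
        with pytest.raises(ValueError, match="filtered"):
            ht.collapse_haplotypes(_matrix([[2, 0]]))


class TestSubpopFrequencies:
    def _haps(self):
        m = _matrix([[0, 0], [0, 0], [1, 1]], samples=["a", "b", "c"])
        return ht.collapse_haplotypes(m)

    def test_single_subpop_equals_global(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "subpopulation": ["XI"] * 3}
        )
        table = ht.subpop_frequencies(self._haps(), meta)
        assert table["p_XI"].tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_proportions_sum_to_one(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "subpopulation": ["XI", "GJ", "GJ"]}
        )
        table = ht.subpop_frequencies(self._haps(), meta)
        assert table["p_XI"].sum() == pytest.approx(1.0)
        assert table["p_GJ"].sum() == pytest.approx(1.0)

    def test_missing_metadata_goes_to_unassigned(self):
        meta = pd.DataFrame({"sample_id": ["a"], "subpopulation": ["XI"]})
        table = ht.subpop_frequencies(self._haps(), meta).set_index("haplotype")
        assert table.loc["H1", "unassigned"] == 1
        assert table.loc["H2", "unassigned"] == 1

    def test_empty_haplotypes(self):
        meta = pd.DataFrame({"sample_id": [], "subpopulation": []})
        assert ht.subpop_frequencies([], meta).empty

    def test_planted_association_recovered(self):
        cfg = lp.SimConfig(seed=35, n_accessions=150, haplotype_count=3,
                           het_rate=0.0, missing_rate=0.0,
                           subpopulations=("XI", "GJ", "aus"),
                           subpop_confusion=0.0)
        locus = sd.simulate_reference(cfg)
        variants, samples, geno, meta, truth = sd.simulate_snp_matrix(cfg, locus)
        m = ht.SnpMatrix(variants=variants, samples=samples, genotypes=geno)
        haps = ht.collapse_haplotypes(m)
        table = ht.subpop_frequencies(haps, meta).set_index("haplotype")
        # zero confusion: every haplotype maps to exactly one subpopulation
        for h in haps:
            row = table.loc[h.label, ["XI", "GJ", "aus"]]
            assert (row > 0).sum() == 1


class TestNjTree:
    def test_three_taxon_closed_form(self):
        # d12=2, d13=4, d23=4 -> branches (d12+d13-d23)/2=1, 1, 3
        haps = [
            ht.Haplotype("H1", (0, 0, 0, 0), ["a"]),
            ht.Haplotype("H2", (1, 1, 0, 0), ["b"]),
            ht.Haplotype("H3", (0, 1, 1, 1), ["c"]),
        ]
        # Hamming: d12=2, d13=3... construct exact target instead
        haps = [
            ht.Haplotype("H1", (0, 0, 0, 0, 0, 0), ["a"]),
            ht.Haplotype("H2", (1, 1, 0, 0, 0, 0), ["b"]),
            ht.Haplotype("H3", (1, 0, 1, 1, 1, 0), ["c"]),
        ]
        labels, dm = ht.hamming_matrix(haps)
        assert dm[0, 1] == 2 and dm[0, 2] == 4 and dm[1, 2] == 4
        newick = ht.nj_tree(haps)
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(newick))
        lengths = {}
        for tip in tree.tips():
            lengths[tip.name] = tip.accumulate_to_ancestor(tree)
        assert lengths["H1"] == pytest.approx(1.0)
        assert lengths["H2"] == pytest.approx(1.0)
        assert lengths["H3"] == pytest.approx(3.0)

    def test_four_taxon_additive_topology(self):
        # generating tree: ((A,B),(C,D)) with edge weights realised as
        # disjoint coordinate blocks -> additive Hamming matrix
        A = (1,) + (0,) * 11
        B = (0,) + (1, 1) + (0,) * 9
        C = (0,) * 3 + (1, 1) + (0,) * 2 + (1, 1, 1) + (0,) * 2
        D = (0,) * 3 + (1, 1) + (0,) * 5 + (1, 1)
        haps = [
            ht.Haplotype("A", A, ["a"]),
            ht.Haplotype("B", B, ["b"]),
            ht.Haplotype("C", C, ["c"]),
            ht.Haplotype("D", D, ["d"]),
        ]
        newick = ht.nj_tree(haps)
        from skbio import TreeNode

        obs = TreeNode.read(io.StringIO(newick))
        exp = TreeNode.read(io.StringIO("((A:1,B:2):1,(C:3,D:2):1);"))
        rf = obs.compare_rfd(exp)
        assert rf == 0

    def test_degenerate_trees_warn(self):
        one = [ht.Haplotype("H1", (0, 1), ["a"])]
        with pytest.warns(UserWarning, match="degenerate"):
            assert ht.nj_tree(one) == "H1;"
        two = one + [ht.Haplotype("H2", (1, 0), ["b"])]
        with pytest.warns(UserWarning, match="degenerate"):
            newick = ht.nj_tree(two)
        assert newick.startswith("(H1:1")

    def test_h0_excluded_from_tree(self):
        haps = [
            ht.Haplotype("H1", (0, 0, 1), ["a"]),
            ht.Haplotype("H2", (1, 0, 0), ["b"]),
            ht.Haplotype("H3", (0, 1, 0), ["c"]),
            ht.Haplotype("H0", None, ["d"]),
        ]
        assert "H0" not in ht.nj_tree(haps)
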