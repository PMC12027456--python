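"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

import locuspav as lp
import locuspav.synthetic_data as sd


@pytest.fixture(scope="session")
def default_cfg():
    return lp.SimConfig(seed=101)


@pytest.fixture(scope="session")
def reference(default_cfg):
    return sd.simulate_reference(default_cfg)


@pytest.fixture(scope="session")
def planted_span(default_cfg, reference):
    return sd.deletion_span(default_cfg, reference)


@pytest.fixture(scope="session")
def small_cohort():
    """20 accessions, half deletion carriers: assemblies + truth."""
    cfg = lp.SimConfig(seed=7, n_accessions=20, deletion_fraction=0.5,
                       haplotype_count=4)
    locus = sd.simulate_reference(cfg)
    assemblies, truth = sd.simulate_accessions(cfg, locus)
    return cfg, locus, assemblies, truth


@pytest.fixture(scope="session")
def toy_gene():
    """A <1 kb two-exon gene in a 3 kb locus, for exhaustive scans."""
    cfg = lp.SimConfig(
        seed=13, locus_length=3000, exon_lengths=(300, 150), intron_length=50
    )
    return sd.simulate_reference(cfg)


@pytest.fixture(scope="session")
def ghd7_fixture():
    return sd.ghd7_like_locus()
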