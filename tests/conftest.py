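import datetime as dt

import pytest

from varaudit import GenePanel, VariantKey, gen_panel
from varaudit.burden import Cohort, Genotype
from varaudit.core import Gene


@pytest.fixture(scope="session")
def small_panel() -> GenePanel:
    """Two autosomal-recessive genes and one X-linked gene, fixed coordinates."""
    return GenePanel([
        Gene("GENE_A01", "chr1", 1000, 2000, "AR"),
        Gene("GENE_A02", "chr2", 1000, 2000, "AR"),
        Gene("GENE_X01", "chrX", 1000, 2000, "XL"),
    ])


def make_cohort(samples_spec, genotype_spec) -> Cohort:
    """Build an in-memory cohort.

    ``samples_spec``: list of (sample, sex, ancestry);
    ``genotype_spec``: {(sample, VariantKey): (alleles tuple, phased)}.
    Variants mentioned anywhere get reference genotypes for everyone else
    (haploid on chrX for males).
    """
    samples = [s for s, _, _ in samples_spec]
    sex = {s: x for s, x, _ in samples_spec}
    anc = {s: a for s, _, a in samples_spec}
    cohort = Cohort(samples=samples, sex=sex, ancestry=anc)
    variants = {v for _, v in genotype_spec}
    for v in variants:
        site = {}
        for s in samples:
            spec = genotype_spec.get((s, v))
            if spec is not None:
                alleles, phased = spec
                site[s] = Genotype(tuple(alleles), phased)
            elif v.chrom == "chrX" and sex[s] == "male":
                site[s] = Genotype((0,), False)
            else:
                site[s] = Genotype((0, 0), True)
        cohort.genotypes[v] = site
    return cohort


@pytest.fixture
def v_a1() -> VariantKey:
    return VariantKey("chr1", 1100, "A", "G")


@pytest.fixture
def v_a2() -> VariantKey:
    return VariantKey("chr1", 1500, "C", "T")


@pytest.fixture
def v_x() -> VariantKey:
    return VariantKey("chrX", 1200, "G", "A")
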