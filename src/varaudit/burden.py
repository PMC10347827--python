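"""Database-implied disease burden in a cohort.

Scans phased cohort genotypes for individuals whose genotype a variant set
classifies as pathogenic — homozygous, hemizygous (males, X-linked genes), or
compound heterozygous (two distinct variants in one gene on opposite
haplotypes) — then aggregates indicated-affected counts per snapshot date and
year and converts them into a false-positive rate per 1000 cataloged variants.
"""
from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from .core import AffectedCall, GenePanel, VariantKey

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Genotype:
    """One sample's alleles at one site; haploid genotypes have one allele."""

    alleles: tuple[int, ...]
    phased: bool

    @property
    def n_alt(self) -> int:
        return sum(1 for a in self.alleles if a and a > 0)

    @property
    def is_hom_alt(self) -> bool:
        return len(self.alleles) == 2 and all(a == 1 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.n_alt == 1


@dataclass
class Cohort:
    """In-memory phased cohort: sample metadata plus per-variant genotypes."""

    samples: list[str]
    sex: dict[str, str]       # "male" | "female"
    ancestry: dict[str, str]
    genotypes: dict[VariantKey, dict[str, Genotype]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.samples)

    def ancestry_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.samples:
            out[self.ancestry[s]] = out.get(self.ancestry[s], 0) + 1
        return out


def load_cohort(vcf_path, sample_sheet_path) -> Cohort:
    """Load a phased cohort VCF plus its sample sheet (sample, sex, ancestry)."""
    sex: dict[str, str] = {}
    ancestry: dict[str, str] = {}
    with open(sample_sheet_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for needed in ("sample", "sex", "ancestry"):
            if needed not in cols:
                raise ValueError(f"{sample_sheet_path}: missing column {needed!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sex[f[cols["sample"]]] = f[cols["sex"]]
            ancestry[f[cols["sample"]]] = f[cols["ancestry"]]

    cohort = Cohort(samples=[], sex=sex, ancestry=ancestry)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        cohort.samples = list(vcf.header.samples)
        missing = [s for s in cohort.samples if s not in sex]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing[:5]}")
        for rec in vcf:
            if not rec.alts or len(rec.alts) != 1:
                continue
            key = VariantKey(rec.chrom, rec.pos, rec.ref, rec.alts[0])
            site: dict[str, Genotype] = {}
            for s in cohort.samples:
                call = rec.samples[s]
                alleles = tuple(a for a in call["GT"] if a is not None)
                if not alleles:
                    alleles = (0,)
                site[s] = Genotype(alleles, bool(call.phased))
            cohort.genotypes[key] = site
    return cohort


# ---------------------------------------------------------------------------
# Affected detection
# ---------------------------------------------------------------------------

def detect_affected(
    cohort: Cohort,
    variant_set: Iterable[VariantKey],
    panel: GenePanel,
    date: dt.date,
    set_name: str,
    unphased_comphet: bool = False,
    unphased_policy: str = "skip",  # "skip" | "error"
) -> list[AffectedCall]:
    """Find indicated-affected individuals for one variant set at one date.

    Emits one call per (sample, gene, mechanism). Compound heterozygotes
    require phased genotypes with the two alt alleles on opposite haplotypes
    unless ``unphased_comphet`` presumes trans phase for any two hets in a
    gene. Unphased diploid genotypes encountered during phased compound-het
    pairing are skipped with a warning by default, or raise when
    ``unphased_policy="error"``.
    """
    present = [v for v in variant_set if v in cohort.genotypes]
    by_gene: dict[str, list[VariantKey]] = {}
    gene_of: dict[str, object] = {}
    for v in present:
        gene = panel.gene_at(v.chrom, v.pos)
        if gene is None:
            continue
        by_gene.setdefault(gene.name, []).append(v)
        gene_of[gene.name] = gene

    calls: list[AffectedCall] = []
    for gene_name in sorted(by_gene):
        gene = gene_of[gene_name]
        variants = sorted(by_gene[gene_name])
        for sample in cohort.samples:
            male = cohort.sex[sample] == "male"
            anc = cohort.ancestry[sample]
            hom_vs, hemi_vs, hets = [], [], []
            for v in variants:
                g = cohort.genotypes[v][sample]
                if gene.inheritance == "XL" and male:
                    if g.n_alt >= 1:
                        hemi_vs.append(v)
                elif g.is_hom_alt:
                    hom_vs.append(v)
                elif g.is_het:
                    hets.append((v, g))
            if hemi_vs:
                calls.append(AffectedCall(sample, gene_name, "hemi",
                                          (hemi_vs[0],), date, set_name, anc))
            if hom_vs:
                calls.append(AffectedCall(sample, gene_name, "hom",
                                          (hom_vs[0],), date, set_name, anc))
            pair = _comphet_pair(hets, sample, gene_name,
                                 unphased_comphet, unphased_policy)
            if pair is not None:
                calls.append(AffectedCall(sample, gene_name, "comphet",
                                          pair, date, set_name, anc))
    return calls


def _comphet_pair(
    hets: list[tuple[VariantKey, Genotype]],
    sample: str,
    gene_name: str,
    unphased_comphet: bool,
    unphased_policy: str,
) -> Optional[tuple[VariantKey, VariantKey]]:
    if len(hets) < 2:
        return None
    if unphased_comphet:
        pair = sorted(v for v, _ in hets[:2])
        return (pair[0], pair[1])
    usable = []
    for v, g in hets:
        if not g.phased:
            if unphased_policy == "error":
                raise ValueError(
                    f"unphased genotype at {v} for {sample} with compound-het "
                    f"detection enabled")
            log.warning("unphased genotype at %s for %s in %s skipped",
                        v, sample, gene_name)
            continue
        usable.append((v, g))
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            (v1, g1), (v2, g2) = usable[i], usable[j]
            if g1.alleles[0] != g2.alleles[0]:  # alt on opposite haplotypes
                pair = sorted((v1, v2))
                return (pair[0], pair[1])
    return None


def affected_individuals(calls: Iterable[AffectedCall]) -> set[str]:
    """Distinct indicated-affected individuals (a sample affected in several
    genes still counts once)."""
    return {c.sample for c in calls}


def yearly_max(calls_by_date: dict[dt.date, list[AffectedCall]]) -> dict[int, int]:
    """Per-year maximum of the distinct-individual count over the year's
    snapshots. Years with no snapshot are absent."""
    out: dict[int, int] = {}
    for date, calls in calls_by_date.items():
        n = len(affected_individuals(calls))
        y = date.year
        out[y] = max(out.get(y, 0), n)
    return out


def fp_rate(n_affected: int, n_variants: int) -> float:
    """Indicated-affected individuals per 1000 cataloged variants; NaN when
    the set is empty (no meaningful rate)."""
    if n_variants == 0:
        return math.nan
    return 1000.0 * n_affected / n_variants


def expected_affected(cohort_size: int, incidence: float) -> float:
    """Expected truly affected individuals in a random cohort at the given
    aggregate disorder incidence."""
    if not (0.0 < incidence < 1.0):
        raise ValueError("incidence must be in (0, 1)")
    return cohort_size * incidence


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurdenSummary:
    """One year's burden for one variant set."""

    year: int
    set_name: str
    n_affected: int
    n_variants: int
    fp_rate: float
    ancestry_counts: tuple[tuple[str, int], ...]


def summarize_burden(
    calls_by_date: dict[dt.date, list[AffectedCall]],
    set_sizes_by_date: dict[dt.date, int],
    set_name: str,
) -> list[BurdenSummary]:
    """Collapse per-snapshot calls into yearly summaries.

    For each year the affected count is the maximum distinct-individual count
    over the year's snapshots; the variant count and ancestry breakdown come
    from the latest snapshot attaining that maximum.
    """
    by_year: dict[int, list[dt.date]] = {}
    for date in calls_by_date:
        by_year.setdefault(date.year, []).append(date)
    out = []
    for year in sorted(by_year):
        dates = sorted(by_year[year])
        counts = {d: len(affected_individuals(calls_by_date[d])) for d in dates}
        peak = max(counts.values())
        peak_date = max(d for d in dates if counts[d] == peak)
        anc: dict[str, int] = {}
        for s in affected_individuals(calls_by_date[peak_date]):
            a = next(c.ancestry for c in calls_by_date[peak_date] if c.sample == s)
            anc[a] = anc.get(a, 0) + 1
        n_variants = set_sizes_by_date.get(peak_date, 0)
        out.append(BurdenSummary(
            year=year, set_name=set_name, n_affected=peak, n_variants=n_variants,
            fp_rate=fp_rate(peak, n_variants) if n_variants else math.nan,
            ancestry_counts=tuple(sorted(anc.items())),
        ))
    return out


def write_calls_tsv(calls: Iterable[AffectedCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tgene\tmechanism\tsample\tancestry\tdate\tset\n")
        for c in sorted(calls, key=lambda c: (c.date, c.set_name, c.gene, c.sample)):
            keys = ",".join(str(v) for v in c.variants)
            fh.write(f"{keys}\t{c.gene}\t{c.mechanism}\t{c.sample}\t"
                     f"{c.ancestry}\t{c.date.isoformat()}\t{c.set_name}\n")


def write_burden_tsv(summaries: Iterable[BurdenSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("year\tset\tn_affected\tn_variants\tfp_rate_per_1000\tancestry_counts\n")
        for s in sorted(summaries, key=lambda s: (s.set_name, s.year)):
            anc = ",".join(f"{a}:{n}" for a, n in s.ancestry_counts)
            rate = "" if math.isnan(s.fp_rate) else f"{s.fp_rate:.1f}"
            fh.write(f"{s.year}\t{s.set_name}\t{s.n_affected}\t{s.n_variants}\t"
                     f"{rate}\t{anc}\n")
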