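"""Synthetic study-condition generator with a machine-readable ground truth.

Emulates the inputs of the audit — a phased diploid cohort drawn from five
continental ancestries, dated classification snapshot series in the three
dialects, a screened-disorder gene panel, and population-stratified allele
frequency tables — while recording every planted signal (affected genotypes,
recategorizations, stand-alone-benign variants) in a ledger, so each
downstream stage can be tested against exact expected output.

Defaults mirror the real study conditions: the cohort composition is the
1000 Genomes phase-3 continental breakdown (661/347/504/503/489), frequency
tables use gnomAD v2.1 exome sample sizes, and non-planted samples receive
pathogenic-classified alleles only as isolated heterozygotes so that they can
never form a pathogenic genotype.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    ANCESTRIES,
    GNOMAD_V2_EXOME_N,
    KGP_COMPOSITION,
    STAR_CUTOVER,
    Gene,
    GenePanel,
    VariantKey,
    parse_date,
)
from .frequencies import FrequencyTable

log = logging.getLogger(__name__)

_BASES = "ACGT"

#: Default rate at which non-planted samples carry an isolated heterozygous
#: pathogenic-classified allele (per gene per sample).
BACKGROUND_HET_RATE = 0.01


# ---------------------------------------------------------------------------
# Ground truth ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedAffected:
    sample: str
    gene: str
    mechanism: str  # "hom" | "hemi" | "comphet"
    variants: tuple[str, ...]  # stringified VariantKeys
    ancestry: str


@dataclass(frozen=True)
class PlantedRecat:
    key: str
    date: str  # ISO date of the first snapshot showing the new category
    from_category: str
    to_category: str
    database: str  # "clinvar" | "hgmd"


@dataclass(frozen=True)
class PlantedBa1:
    key: str
    rule: str  # "2015" | "2018" | "both"


@dataclass
class GroundTruthLedger:
    """Everything the generators planted, for exact downstream verification."""

    planted_affected: list[PlantedAffected] = field(default_factory=list)
    planted_recats: list[PlantedRecat] = field(default_factory=list)
    planted_ba1: list[PlantedBa1] = field(default_factory=list)
    cohort_variants: dict[str, list[str]] = field(default_factory=dict)  # gene -> keys
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_affected": [asdict(p) for p in self.planted_affected],
            "planted_recats": [asdict(p) for p in self.planted_recats],
            "planted_ba1": [asdict(p) for p in self.planted_ba1],
            "cohort_variants": self.cohort_variants,
            "seeds": self.seeds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_affected=[
                PlantedAffected(**{**p, "variants": tuple(p["variants"])})
                for p in payload["planted_affected"]
            ],
            planted_recats=[PlantedRecat(**p) for p in payload["planted_recats"]],
            planted_ba1=[PlantedBa1(**p) for p in payload["planted_ba1"]],
            cohort_variants=payload["cohort_variants"],
            seeds=payload["seeds"],
        )

    def merge(self, other: "GroundTruthLedger") -> None:
        self.planted_affected.extend(other.planted_affected)
        self.planted_recats.extend(other.planted_recats)
        self.planted_ba1.extend(other.planted_ba1)
        for gene, keys in other.cohort_variants.items():
            self.cohort_variants.setdefault(gene, []).extend(keys)
        self.seeds.update(other.seeds)


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

def gen_panel(n_autosomal: int, n_xlinked: int, seed: int) -> GenePanel:
    """Generate a deterministic panel of non-overlapping gene intervals.

    Autosomal-recessive genes cycle over chr1..chr22; X-linked genes go on
    chrX. Coordinates are 1-based inclusive.
    """
    if n_autosomal < 0 or n_xlinked < 0:
        raise ValueError("gene counts must be non-negative")
    if n_autosomal == 0 and n_xlinked == 0:
        raise ValueError("empty panel")
    rng = np.random.default_rng(seed)
    cursors: dict[str, int] = {}
    genes: list[Gene] = []

    def place(chrom: str, name: str, inheritance: str) -> None:
        cursor = cursors.get(chrom, 1_000_000)
        start = cursor + int(rng.integers(10_000, 100_000))
        length = int(rng.integers(20_000, 60_000))
        genes.append(Gene(name, chrom, start, start + length, inheritance))
        cursors[chrom] = start + length + 1

    for i in range(n_autosomal):
        place(f"chr{i % 22 + 1}", f"GENE_A{i + 1:02d}", "AR")
    for i in range(n_xlinked):
        place("chrX", f"GENE_X{i + 1:02d}", "XL")
    return GenePanel(sorted(genes, key=lambda g: (g.chrom, g.start)))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    vcf_path: Path
    sample_sheet_path: Path
    ledger: GroundTruthLedger
    variants_by_gene: dict[str, list[VariantKey]]
    samples: list[str]

    @property
    def all_variants(self) -> list[VariantKey]:
        return [v for vs in self.variants_by_gene.values() for v in vs]


_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, 99), chrom)


def gen_cohort(
    panel: GenePanel,
    ancestry_sizes: dict[str, int],
    affected_spec: Sequence[tuple[str, str]],
    seed: int,
    out_dir,
    variants_per_gene: int = 6,
    background_het_rate: float = BACKGROUND_HET_RATE,
    male_fraction: float = 0.5,
) -> CohortResult:
    """Generate a phased diploid cohort VCF, a sample sheet, and a ledger.

    ``affected_spec`` is a list of (mechanism, ancestry) pairs; each plants one
    indicated-affected individual. Homozygous and compound-heterozygous
    genotypes are planted in autosomal-recessive genes; hemizygous genotypes
    require an X-linked gene and are planted in a male. All other samples
    carry at most one pathogenic-classified allele per gene, so no non-planted
    sample can form a pathogenic genotype. Male X genotypes are haploid.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for anc in ancestry_sizes:
        if anc not in ANCESTRIES:
            raise ValueError(f"unknown ancestry label: {anc!r}")
    rng = np.random.default_rng(seed)

    # variant sites per gene
    variants_by_gene: dict[str, list[VariantKey]] = {}
    for gene in panel:
        n = min(variants_per_gene, gene.end - gene.start + 1)
        positions = sorted(
            int(p) for p in rng.choice(
                np.arange(gene.start, gene.end + 1), size=n, replace=False)
        )
        sites = []
        for pos in positions:
            ref = _BASES[rng.integers(0, 4)]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            sites.append(VariantKey(gene.chrom, pos, ref, alt))
        variants_by_gene[gene.name] = sites

    # samples and sexes
    samples: list[str] = []
    ancestry_of: dict[str, str] = {}
    sex_of: dict[str, str] = {}
    for anc in sorted(ancestry_sizes):
        for i in range(ancestry_sizes[anc]):
            sid = f"{anc}{i + 1:04d}"
            samples.append(sid)
            ancestry_of[sid] = anc
            sex_of[sid] = "male" if rng.random() < male_fraction else "female"

    ledger = GroundTruthLedger(seeds={"cohort": seed})
    ledger.cohort_variants = {g: [str(v) for v in vs]
                              for g, vs in variants_by_gene.items()}

    # plant affected individuals
    genotypes: dict[tuple[str, VariantKey], tuple[int, ...]] = {}
    planted_samples: dict[str, set[str]] = {}  # sample -> genes with plants
    ar_genes = panel.autosomal
    xl_genes = panel.xlinked
    for idx, (mechanism, anc) in enumerate(affected_spec):
        pool = [s for s in samples if ancestry_of[s] == anc
                and s not in planted_samples]
        if not pool:
            raise ValueError(f"no free sample of ancestry {anc} to plant")
        sample = pool[int(rng.integers(0, len(pool)))]
        if mechanism == "hemi":
            if not xl_genes:
                raise ValueError("hemizygous plant requested but panel has no X-linked gene")
            gene = xl_genes[idx % len(xl_genes)]
            sex_of[sample] = "male"
            v = variants_by_gene[gene.name][int(rng.integers(0, variants_per_gene))]
            genotypes[(sample, v)] = (1,)
            planted = PlantedAffected(sample, gene.name, "hemi", (str(v),), anc)
        elif mechanism == "hom":
            if not ar_genes:
                raise ValueError("homozygous plant requires an autosomal gene")
            gene = ar_genes[idx % len(ar_genes)]
            v = variants_by_gene[gene.name][int(rng.integers(0, variants_per_gene))]
            genotypes[(sample, v)] = (1, 1)
            planted = PlantedAffected(sample, gene.name, "hom", (str(v),), anc)
        elif mechanism == "comphet":
            if not ar_genes:
                raise ValueError("compound-het plant requires an autosomal gene")
            gene = ar_genes[idx % len(ar_genes)]
            i1, i2 = rng.choice(len(variants_by_gene[gene.name]), size=2, replace=False)
            v1, v2 = (variants_by_gene[gene.name][int(i1)],
                      variants_by_gene[gene.name][int(i2)])
            genotypes[(sample, v1)] = (1, 0)
            genotypes[(sample, v2)] = (0, 1)
            planted = PlantedAffected(sample, gene.name, "comphet",
                                      tuple(sorted((str(v1), str(v2)))), anc)
        else:
            raise ValueError(f"unknown mechanism: {mechanism!r}")
        planted_samples.setdefault(sample, set()).add(gene.name)
        ledger.planted_affected.append(planted)

    # background sprinkle: isolated heterozygotes only, never in a planted
    # (sample, gene), never any alt for males in X-linked genes
    for sample in samples:
        for gene in panel:
            if gene.name in planted_samples.get(sample, set()):
                continue
            male = sex_of[sample] == "male"
            if gene.inheritance == "XL" and male:
                continue
            sites = variants_by_gene[gene.name]
            draws = rng.random(len(sites))
            hit = int(np.argmin(draws))
            if draws[hit] < background_het_rate:
                hap = int(rng.integers(0, 2))
                genotypes[(sample, sites[hit])] = (1, 0) if hap == 0 else (0, 1)

    # write VCF
    vcf_path = out_dir / "cohort.vcf"
    all_sites = sorted(
        (v for vs in variants_by_gene.values() for v in vs),
        key=lambda v: (_chrom_sort_key(v.chrom), v.pos),
    )
    contig_len: dict[str, int] = {}
    for g in panel:
        contig_len[g.chrom] = max(contig_len.get(g.chrom, 0), g.end + 10_000)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varaudit-synthetic\n")
        for chrom in sorted(contig_len, key=_chrom_sort_key):
            fh.write(f"##contig=<ID={chrom},length={contig_len[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in all_sites:
            on_x = v.chrom == "chrX"
            gts = []
            for sample in samples:
                g = genotypes.get((sample, v))
                if on_x and sex_of[sample] == "male":
                    gts.append(str(g[0]) if g else "0")
                else:
                    gts.append(f"{g[0]}|{g[1]}" if g else "0|0")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")

    sheet_path = out_dir / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("sample\tsex\tancestry\n")
        for sample in samples:
            fh.write(f"{sample}\t{sex_of[sample]}\t{ancestry_of[sample]}\n")

    return CohortResult(vcf_path, sheet_path, ledger, variants_by_gene, samples)


# ---------------------------------------------------------------------------
# Snapshot series
# ---------------------------------------------------------------------------

_ARCHIVE1_EMIT = {"P": "5", "LP": "4", "B": "2", "LB": "3", "VUS": "0",
                  "Conflicting": "5,0"}
_ARCHIVE2_EMIT = {
    "P": "Pathogenic",
    "LP": "Likely_pathogenic",
    "B": "Benign",
    "LB": "Likely_benign",
    "VUS": "Uncertain_significance",
    "Conflicting": "Conflicting_interpretations_of_pathogenicity",
}
_ARCHIVE1_REVSTAT = {0: "no_assertion_provided", 1: "single", 2: "mult"}
_ARCHIVE2_REVSTAT = {
    0: "no_assertion_criteria_provided",
    1: "criteria_provided,_single_submitter",
    2: "criteria_provided,_multiple_submitters,_no_conflicts",
}


def _parse_category(label: str) -> tuple[str, Optional[int]]:
    """Parse "P/LP 1*", "LP 0*", "VUS", "DM?" ... into (fine class, stars)."""
    parts = label.split(" ")
    base = parts[0]
    stars = int(parts[1].rstrip("*")) if len(parts) > 1 else None
    if base == "P/LP":
        base = "P"
    elif base == "B/LB":
        base = "B"
    return base, stars


@dataclass
class SnapshotSeries:
    files: list[tuple[dt.date, Path, str]]  # (date, path, dialect)
    ledger: GroundTruthLedger


def gen_snapshot_series(
    panel: GenePanel,
    dates: Sequence[dt.date],
    recat_spec: Sequence[tuple[str, str, str, str]],  # (key, iso-date, from, to)
    dialect: str,
    seed: int,
    out_dir,
    variant_categories: Optional[dict[VariantKey, str]] = None,
    n_background: int = 20,
    absence_spec: Sequence[tuple[str, str, str]] = (),  # (key, iso-from, iso-to)
    condition_map: Optional[dict[VariantKey, str]] = None,
    cutover: dt.date = STAR_CUTOVER,
) -> SnapshotSeries:
    """Generate a dated classification snapshot series with planted transitions.

    Each planted transition ``(key, date, from, to)`` makes the variant carry
    ``from`` at snapshots strictly before ``date`` and ``to`` from ``date``
    onward. Non-planted variants keep a constant category. ``absence_spec``
    removes a variant from snapshots within an inclusive date window, which
    lets re-entry rules be exercised end to end. Categories are ladder labels
    ("P/LP 1*", "VUS") or fine labels ("LP 0*"); HGMD dialect uses
    "DM"/"DM?"/"DFP"/"DP"/"R".
    """
    if dialect not in ("archive1", "archive2", "hgmd"):
        raise ValueError(f"unknown snapshot dialect: {dialect!r}")
    dates = sorted(dates)
    if len(set(dates)) != len(dates):
        raise ValueError("snapshot dates must be strictly increasing")
    if dialect == "archive1" and any(d >= cutover for d in dates):
        raise ValueError("archive-1 dialect only valid before the archive-2 cutover")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    categories: dict[VariantKey, str] = dict(variant_categories or {})
    if not categories:
        pool = (["P/LP 1*", "P/LP 0*", "VUS", "B/LB 1*", "Conflicting", "P/LP 2*"]
                if dialect != "hgmd" else ["DM", "DM?", "DFP", "DP"])
        genes = list(panel)
        for i in range(n_background):
            gene = genes[i % len(genes)]
            pos = int(rng.integers(gene.start, gene.end + 1))
            ref = _BASES[rng.integers(0, 4)]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            key = VariantKey(gene.chrom, pos, ref, alt)
            categories[key] = pool[int(rng.integers(0, len(pool)))]

    ledger = GroundTruthLedger(seeds={"snapshots": seed})
    transitions: dict[VariantKey, list[tuple[dt.date, str, str]]] = {}
    for key_s, date_s, from_cat, to_cat in recat_spec:
        key, date = VariantKey.parse(key_s), parse_date(date_s)
        if not (dates[0] < date <= dates[-1]):
            raise ValueError(f"transition for {key} dated {date} outside the series")
        transitions.setdefault(key, []).append((date, from_cat, to_cat))
        if key not in categories:
            categories[key] = from_cat
        db = "hgmd" if dialect == "hgmd" else "clinvar"
        effective = min(d for d in dates if d >= date)
        ledger.planted_recats.append(
            PlantedRecat(str(key), effective.isoformat(), from_cat, to_cat, db))
    for key in transitions:
        transitions[key].sort()

    absences: dict[VariantKey, list[tuple[dt.date, dt.date]]] = {}
    for key_s, a, b in absence_spec:
        absences.setdefault(VariantKey.parse(key_s), []).append(
            (parse_date(a), parse_date(b)))

    def category_at(key: VariantKey, date: dt.date) -> Optional[str]:
        for a, b in absences.get(key, []):
            if a <= date <= b:
                return None
        cat = categories[key]
        for t_date, from_cat, to_cat in transitions.get(key, []):
            if date >= t_date:
                cat = to_cat
            else:
                cat = from_cat  # earliest pending transition wins below
                break
        return cat

    conditions = condition_map or {}
    files: list[tuple[dt.date, Path, str]] = []
    sorted_keys = sorted(categories, key=lambda v: (_chrom_sort_key(v.chrom), v.pos))
    contig_len: dict[str, int] = {}
    for g in panel:
        contig_len[g.chrom] = max(contig_len.get(g.chrom, 0), g.end + 10_000)

    for date in dates:
        stamp = date.strftime("%Y%m%d")
        if dialect == "hgmd":
            path = out_dir / f"hgmd_{stamp}.tsv"
            with open(path, "w") as fh:
                fh.write("key\tlabel\tdate\n")
                for key in sorted_keys:
                    cat = category_at(key, date)
                    if cat is None:
                        continue
                    fh.write(f"{key}\t{cat}\t{date.isoformat()}\n")
        else:
            path = out_dir / f"clinvar_{stamp}.vcf"
            with open(path, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                fh.write(f"##fileDate={date.isoformat()}\n")
                for chrom in sorted(contig_len, key=_chrom_sort_key):
                    fh.write(f"##contig=<ID={chrom},length={contig_len[chrom]}>\n")
                for k, desc in (("CLNSIG", "Clinical significance"),
                                ("CLNREVSTAT", "Review status"),
                                ("CLNDN", "Condition"),
                                ("ORIGIN", "Allele origin")):
                    fh.write(f'##INFO=<ID={k},Number=.,Type=String,'
                             f'Description="{desc}">\n')
                fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
                for key in sorted_keys:
                    cat = category_at(key, date)
                    if cat is None:
                        continue
                    clazz, stars = _parse_category(cat)
                    if dialect == "archive1":
                        sig = _ARCHIVE1_EMIT[clazz]
                        revstat = _ARCHIVE1_REVSTAT[min(stars or 0, 2)]
                    else:
                        sig = _ARCHIVE2_EMIT[clazz]
                        revstat = _ARCHIVE2_REVSTAT[min(stars or 0, 2)]
                    cond = conditions.get(key, "not_provided").replace(" ", "_")
                    info = f"CLNSIG={sig};CLNREVSTAT={revstat};CLNDN={cond}"
                    fh.write(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}"
                             f"\t.\tPASS\t{info}\n")
        files.append((date, path, dialect))
    return SnapshotSeries(files, ledger)


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

def gen_frequency_table(
    variants: Sequence[VariantKey],
    populations: dict[str, int],
    common_spec: Sequence[tuple[str, str, float]],  # (key, ancestry, MAF)
    seed: int,
    rare_maf_scale: float = 5e-4,
    zero_fraction: float = 0.5,
    global_overrides: Optional[dict[str, dict[str, float]]] = None,
    population_dataset: str = "gnomad",
    global_datasets: tuple[str, ...] = ("1kgp", "esp"),
) -> tuple[FrequencyTable, GroundTruthLedger]:
    """Generate a population-stratified frequency table with planted commons.

    Background variants get sparse, rare population MAFs (zero with
    probability ``zero_fraction``, else exponential with mean
    ``rare_maf_scale``); ``common_spec`` plants an exact MAF for a variant in
    one population. The population dataset's global MAF is always the
    sample-size-weighted mean of its population MAFs; the global-only
    datasets default to that same value unless overridden. The returned
    ledger records which variants meet the 2015 and/or 2018 stand-alone-benign
    rules, computed arithmetically from the planted numbers.
    """
    for anc in populations:
        if anc not in ANCESTRIES:
            raise ValueError(f"unknown ancestry label: {anc!r}")
    for _, anc, maf in common_spec:
        if anc not in populations:
            raise ValueError(f"unknown ancestry label in common_spec: {anc!r}")
        if not (0.0 <= maf <= 1.0):
            raise ValueError(f"planted MAF out of range: {maf}")
    rng = np.random.default_rng(seed)
    overrides = global_overrides or {}
    table = FrequencyTable()
    ledger = GroundTruthLedger(seeds={"frequencies": seed})
    total_n = sum(populations.values())
    planted = {(VariantKey.parse(k), anc): maf for k, anc, maf in common_spec}

    for key in sorted(set(variants)):
        pop_mafs: dict[str, float] = {}
        for anc in sorted(populations):
            if (key, anc) in planted:
                maf = planted[(key, anc)]
            elif rng.random() < zero_fraction:
                maf = 0.0
            else:
                maf = min(0.5, float(rng.exponential(rare_maf_scale)))
            pop_mafs[anc] = maf
            table.set(key, population_dataset, anc, maf, populations[anc])
        global_maf = sum(pop_mafs[a] * populations[a] for a in pop_mafs) / total_n
        table.set(key, population_dataset, "ALL", global_maf)
        globals_by_ds = {population_dataset: global_maf}
        for ds in global_datasets:
            g = overrides.get(str(key), {}).get(ds, global_maf)
            table.set(key, ds, "ALL", g)
            globals_by_ds[ds] = g
        hits_2015 = any(g > 0.05 for g in globals_by_ds.values())
        hits_2018 = (any(globals_by_ds[ds] > 0.05 for ds in global_datasets)
                     or any(m > 0.05 for m in pop_mafs.values()))
        if hits_2015 and hits_2018:
            ledger.planted_ba1.append(PlantedBa1(str(key), "both"))
        elif hits_2015:
            ledger.planted_ba1.append(PlantedBa1(str(key), "2015"))
        elif hits_2018:
            ledger.planted_ba1.append(PlantedBa1(str(key), "2018"))
    return table, ledger


# ---------------------------------------------------------------------------
# End-to-end scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    panel_path: Path
    cohort: CohortResult
    clinvar: SnapshotSeries
    hgmd: SnapshotSeries
    frequency_path: Path
    ledger: GroundTruthLedger
    ledger_path: Path


def generate_scenario(
    out_dir,
    seed: int,
    ancestry_sizes: dict[str, int] = KGP_COMPOSITION,
    n_autosomal: int = 8,
    n_xlinked: int = 2,
    affected_spec: Sequence[tuple[str, str]] = (),
    clinvar_dates: Optional[Sequence[dt.date]] = None,
    hgmd_dates: Optional[Sequence[dt.date]] = None,
    recat_plan: Sequence[tuple[str, str, str]] = (),       # (from, to, iso-date)
    hgmd_recat_plan: Sequence[tuple[str, str, str]] = (),  # (from, to, iso-date)
    common_plan: Sequence[tuple[str, float]] = (),         # (ancestry, MAF)
    common_spec: Sequence[tuple[str, str, float]] = (),
    background_het_rate: float = BACKGROUND_HET_RATE,
    variants_per_gene: int = 6,
) -> Scenario:
    """Wire the four generators into one coherent synthetic study.

    Cohort variant sites become the classified variants of the snapshot
    series: variants contributing to planted affected genotypes enter as
    "P/LP 1*" (ClinVar) and "DM" (HGMD) so that every planted genotype is
    discoverable in every variant set; the remaining sites get constant
    background categories. ``recat_plan`` transitions are applied to
    background variants not involved in any planted genotype.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = {name: int(s) for name, s in zip(
        ("panel", "cohort", "clinvar", "hgmd", "freq"),
        rng.integers(1, 2**31 - 1, size=5))}

    panel = gen_panel(n_autosomal, n_xlinked, seeds["panel"])
    panel_path = out_dir / "panel.tsv"
    panel.write_tsv(panel_path)

    cohort = gen_cohort(panel, ancestry_sizes, affected_spec, seeds["cohort"],
                        out_dir, variants_per_gene=variants_per_gene,
                        background_het_rate=background_het_rate)

    planted_keys = {
        VariantKey.parse(v)
        for p in cohort.ledger.planted_affected for v in p.variants
    }
    if clinvar_dates is None:
        clinvar_dates = [dt.date(y, m, 15)
                         for y in (2016, 2017, 2018, 2019, 2020) for m in (3, 9)]
    if hgmd_dates is None:
        hgmd_dates = [dt.date(2016, 3, 1), dt.date(2018, 3, 1), dt.date(2020, 3, 1)]

    clinvar_pool = ["P/LP 2*", "P/LP 0*", "VUS", "B/LB 1*", "Conflicting", "LP 1*"]
    hgmd_pool = ["DM", "DM?", "DFP", "DP"]
    clinvar_cats: dict[VariantKey, str] = {}
    hgmd_cats: dict[VariantKey, str] = {}
    free: list[VariantKey] = []
    for v in cohort.all_variants:
        if v in planted_keys:
            clinvar_cats[v] = "P/LP 1*"
            hgmd_cats[v] = "DM"
        else:
            free.append(v)
            clinvar_cats[v] = clinvar_pool[int(rng.integers(0, len(clinvar_pool)))]
            hgmd_cats[v] = hgmd_pool[int(rng.integers(0, len(hgmd_pool)))]

    if len(free) < len(recat_plan) + len(hgmd_recat_plan) + len(common_plan):
        raise ValueError("not enough free variants for the requested plants")
    recat_spec = []
    for (from_cat, to_cat, date_s), v in zip(recat_plan, free):
        clinvar_cats[v] = from_cat
        recat_spec.append((str(v), date_s, from_cat, to_cat))
    hgmd_recat_spec = []
    for (from_cat, to_cat, date_s), v in zip(hgmd_recat_plan,
                                             free[len(recat_plan):]):
        hgmd_cats[v] = from_cat
        hgmd_recat_spec.append((str(v), date_s, from_cat, to_cat))

    clinvar = gen_snapshot_series(panel, clinvar_dates, recat_spec, "archive2",
                                  seeds["clinvar"], out_dir / "clinvar",
                                  variant_categories=clinvar_cats)
    hgmd = gen_snapshot_series(panel, hgmd_dates, hgmd_recat_spec, "hgmd",
                               seeds["hgmd"], out_dir / "hgmd",
                               variant_categories=hgmd_cats)

    common_spec = list(common_spec)
    offset = len(recat_plan) + len(hgmd_recat_plan)
    for (anc, maf), v in zip(common_plan, free[offset:]):
        common_spec.append((str(v), anc, maf))
    table, freq_ledger = gen_frequency_table(
        cohort.all_variants, dict(GNOMAD_V2_EXOME_N), common_spec, seeds["freq"])
    frequency_path = out_dir / "frequencies.tsv"
    table.write_tsv(frequency_path)

    ledger = cohort.ledger
    ledger.merge(clinvar.ledger)
    ledger.merge(hgmd.ledger)
    ledger.merge(freq_ledger)
    ledger.seeds["scenario"] = seed
    ledger_path = out_dir / "ledger.json"
    ledger.to_json(ledger_path)
    return Scenario(panel_path, cohort, clinvar, hgmd, frequency_path,
                    ledger, ledger_path)
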