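"""Population allele frequencies: BA1 stand-alone-benign filters and
principal-ancestry assignment.

The BA1 criterion declares a variant stand-alone benign when it is too common
to cause a rare disorder. The 2015 rule removes variants whose *global* minor
allele frequency exceeds 5% in any configured reference dataset; the 2018
revision additionally removes variants exceeding 5% in any single continental
population of the population-resolved dataset (subject to a minimum allele
count). Ancestry assignment gives each variant the continental population in
which its floored MAF is highest.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import VariantKey

log = logging.getLogger(__name__)

BA1_THRESHOLD = 0.05  # "MAF > 5%", strictly greater


@dataclass
class FrequencyTable:
    """Per-variant minor allele frequencies across datasets and populations.

    ``pop_maf[key][dataset][population]`` holds population-stratified MAFs;
    ``global_maf[key][dataset]`` holds dataset-wide MAFs; ``pop_n[dataset]``
    holds per-population diploid sample counts.
    """

    pop_maf: dict[VariantKey, dict[str, dict[str, float]]] = field(default_factory=dict)
    global_maf: dict[VariantKey, dict[str, float]] = field(default_factory=dict)
    pop_n: dict[str, dict[str, int]] = field(default_factory=dict)

    def set(self, key: VariantKey, dataset: str, population: str,
            maf: float, n: Optional[int] = None) -> None:
        if not (0.0 <= maf <= 1.0):
            raise ValueError(f"MAF out of range: {maf}")
        if population == "ALL":
            self.global_maf.setdefault(key, {})[dataset] = maf
        else:
            self.pop_maf.setdefault(key, {}).setdefault(dataset, {})[population] = maf
            if n is not None:
                self.pop_n.setdefault(dataset, {})[population] = n

    def variants(self) -> set[VariantKey]:
        return set(self.pop_maf) | set(self.global_maf)

    def get_global(self, key: VariantKey, dataset: str) -> Optional[float]:
        return self.global_maf.get(key, {}).get(dataset)

    def get_populations(self, key: VariantKey, dataset: str) -> dict[str, float]:
        return dict(self.pop_maf.get(key, {}).get(dataset, {}))

    # -- TSV round trip ----------------------------------------------------

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tdataset\tpopulation\tmaf\tn\n")
            for key in sorted(self.variants()):
                for dataset, pops in sorted(self.pop_maf.get(key, {}).items()):
                    for pop, maf in sorted(pops.items()):
                        n = self.pop_n.get(dataset, {}).get(pop, "")
                        fh.write(f"{key}\t{dataset}\t{pop}\t{maf:.10g}\t{n}\n")
                for dataset, maf in sorted(self.global_maf.get(key, {}).items()):
                    fh.write(f"{key}\t{dataset}\tALL\t{maf:.10g}\t\n")

    @classmethod
    def read_tsv(cls, path) -> "FrequencyTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("key\t"):
                raise ValueError(f"{path}: not a frequency TSV")
            for line in fh:
                key_s, dataset, pop, maf_s, n_s = line.rstrip("\n").split("\t")
                table.set(VariantKey.parse(key_s), dataset, pop, float(maf_s),
                          int(n_s) if n_s else None)
        return table


@dataclass(frozen=True)
class AncestryAssignment:
    key: VariantKey
    ancestry: Optional[str]  # None when all floored MAFs are zero


@dataclass(frozen=True)
class Ba1Removal:
    """One variant removed by a BA1 rule, with the offending frequency."""

    key: VariantKey
    rule_year: int
    maf: float
    dataset: str
    population: str  # "ALL" for global-MAF removals


# ---------------------------------------------------------------------------
# MAF flooring and ancestry assignment
# ---------------------------------------------------------------------------

def compute_maf_floor(population_n: dict[str, int]) -> float:
    """Smallest observable MAF across populations: 1 / (2 * min N).

    With gnomAD v2.1 exome sample sizes this is 1/(2*8128) = 6.152e-5, the
    smallest possible African-ancestry MAF.
    """
    if not population_n:
        raise ValueError("empty population size map")
    if any(n <= 0 for n in population_n.values()):
        raise ValueError("population sizes must be positive")
    return 1.0 / (2.0 * min(population_n.values()))


def floor_mafs(table: FrequencyTable, floor: float,
               dataset: Optional[str] = None) -> FrequencyTable:
    """Zero out population MAFs strictly below ``floor``.

    Only population-stratified MAFs are floored (global MAFs are untouched);
    ``dataset=None`` floors every dataset. Idempotent.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    out = FrequencyTable(pop_n={d: dict(p) for d, p in table.pop_n.items()},
                         global_maf={k: dict(v) for k, v in table.global_maf.items()})
    for key, by_dataset in table.pop_maf.items():
        for ds, pops in by_dataset.items():
            for pop, maf in pops.items():
                if (dataset is None or ds == dataset) and maf < floor:
                    maf = 0.0
                out.pop_maf.setdefault(key, {}).setdefault(ds, {})[pop] = maf
    return out


def assign_ancestry(table: FrequencyTable, dataset: str) -> dict[VariantKey, AncestryAssignment]:
    """Assign each variant the ancestry with the highest (floored) MAF.

    All-zero variants get ancestry ``None`` and are not considered further.
    Exact ties resolve to the lexicographically first ancestry label, logged.
    """
    out: dict[VariantKey, AncestryAssignment] = {}
    for key in sorted(table.pop_maf):
        pops = table.pop_maf[key].get(dataset, {})
        if not pops or all(m == 0.0 for m in pops.values()):
            out[key] = AncestryAssignment(key, None)
            continue
        best = max(pops.values())
        winners = sorted(p for p, m in pops.items() if m == best)
        if len(winners) > 1:
            log.info("ancestry tie for %s at MAF %g: %s -> %s",
                     key, best, winners, winners[0])
        out[key] = AncestryAssignment(key, winners[0])
    return out


# ---------------------------------------------------------------------------
# BA1 filters
# ---------------------------------------------------------------------------

def apply_ba1_2015(
    variants: Iterable[VariantKey],
    table: FrequencyTable,
    global_datasets: tuple[str, ...] = ("1kgp", "esp", "gnomad"),
) -> tuple[set[VariantKey], list[Ba1Removal]]:
    """2015 BA1: remove variants with a global MAF > 5% in any configured
    reference dataset. Datasets missing for a variant count as MAF 0."""
    kept: set[VariantKey] = set()
    removed: list[Ba1Removal] = []
    for key in sorted(set(variants)):
        hit = None
        for ds in global_datasets:
            maf = table.get_global(key, ds)
            if maf is None:
                log.debug("no global MAF for %s in %s; treated as 0", key, ds)
                continue
            if maf > BA1_THRESHOLD:
                hit = Ba1Removal(key, 2015, maf, ds, "ALL")
                break
        if hit is None:
            kept.add(key)
        else:
            removed.append(hit)
    return kept, removed


def apply_ba1_2018(
    variants: Iterable[VariantKey],
    table: FrequencyTable,
    global_datasets: tuple[str, ...] = ("1kgp", "esp"),
    population_dataset: str = "gnomad",
    min_alleles: int = 2000,
) -> tuple[set[VariantKey], list[Ba1Removal]]:
    """2018 BA1: remove variants with a global MAF > 5% in a global-role
    dataset, or a MAF > 5% in any continental population of the
    population-resolved dataset with at least ``min_alleles`` alleles."""
    kept: set[VariantKey] = set()
    removed: list[Ba1Removal] = []
    pop_n = table.pop_n.get(population_dataset, {})
    for key in sorted(set(variants)):
        hit = None
        for ds in global_datasets:
            maf = table.get_global(key, ds)
            if maf is not None and maf > BA1_THRESHOLD:
                hit = Ba1Removal(key, 2018, maf, ds, "ALL")
                break
        if hit is None:
            for pop, maf in sorted(table.get_populations(key, population_dataset).items()):
                n = pop_n.get(pop)
                if n is not None and 2 * n < min_alleles:
                    continue
                if maf > BA1_THRESHOLD:
                    hit = Ba1Removal(key, 2018, maf, population_dataset, pop)
                    break
        if hit is None:
            kept.add(key)
        else:
            removed.append(hit)
    return kept, removed


def write_removals_tsv(removals: list[Ba1Removal], path) -> None:
    """Removed-variant report (key, rule year, offending MAF, where)."""
    with open(path, "w") as fh:
        fh.write("key\trule_year\tmaf\tdataset\tpopulation\n")
        for r in sorted(removals, key=lambda r: (r.rule_year, r.key)):
            fh.write(f"{r.key}\t{r.rule_year}\t{r.maf:.10g}\t{r.dataset}\t{r.population}\n")


def weighted_global_maf(pop_mafs: dict[str, float], pop_n: dict[str, int]) -> float:
    """Sample-size-weighted mean of population MAFs."""
    total = sum(pop_n[p] for p in pop_mafs)
    if total == 0:
        raise ValueError("zero total sample size")
    return sum(pop_mafs[p] * pop_n[p] for p in pop_mafs) / total
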