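"""Shared vocabulary of the audit pipeline.

Variant identity, classification ladders, gene panels, and the small result
records the pipeline stages exchange. Everything here is plain data; the
behaviour lives in the stage modules.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

#: Continental ancestry labels, in canonical (lexicographic) order.
ANCESTRIES = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: 1000 Genomes phase-3 continental composition (individuals per ancestry).
KGP_COMPOSITION = {"AFR": 661, "AMR": 347, "EAS": 504, "EUR": 503, "SAS": 489}

#: gnomAD v2.1 exomes continental sample sizes (individuals per ancestry).
GNOMAD_V2_EXOME_N = {
    "AFR": 8128,
    "AMR": 17296,
    "EAS": 9197,
    "EUR": 56885,
    "SAS": 15308,
}

#: Review-star framework start: archive-1.0 stars before this date are unreliable
#: and ignored; reclassification events are only counted from this date onward.
STAR_CUTOVER = dt.date(2015, 6, 15)

#: Aggregate newborn-screened inborn-error-of-metabolism incidence (~1 in 3200).
IEM_INCIDENCE = 1.0 / 3200.0


# ---------------------------------------------------------------------------
# Variant identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized chrom/pos/ref/alt identity used to join databases, cohort
    genotypes and frequency tables.

    ``pos`` is 1-based. Instances are expected to already be in minimal,
    left-aligned representation (see :func:`varaudit.ingest.normalize_variant`).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


# ---------------------------------------------------------------------------
# Classification ladders
# ---------------------------------------------------------------------------

#: Fine ClinVar classes as harmonized from snapshots.
CLINVAR_CLASSES = ("B", "LB", "VUS", "Conflicting", "LP", "P")

#: Major ClinVar tiers used on the 10-level ladder.
TIER_BLB = "B/LB"
TIER_VUS = "VUS"
TIER_CONFLICTING = "Conflicting"
TIER_PLP = "P/LP"

#: The 10-level ClinVar category ladder, ordered from most benign to most
#: pathogenic. Stars order B/LB in decreasing confidence-of-benignity and
#: P/LP in increasing confidence-of-pathogenicity.
CLINVAR_LADDER = (
    "B/LB 3*",
    "B/LB 2*",
    "B/LB 1*",
    "B/LB 0*",
    "VUS",
    "Conflicting",
    "P/LP 0*",
    "P/LP 1*",
    "P/LP 2*",
    "P/LP 3*",
)

#: HGMD severity ladder, ordered from retired to disease-causing.
HGMD_LADDER = ("R", "DP", "DFP", "DM?", "DM")

_CLINVAR_INDEX = {label: i for i, label in enumerate(CLINVAR_LADDER)}
_HGMD_INDEX = {label: i for i, label in enumerate(HGMD_LADDER)}


def clinvar_tier(clazz: str) -> str:
    """Collapse a fine ClinVar class to its ladder tier."""
    if clazz in ("B", "LB"):
        return TIER_BLB
    if clazz in ("P", "LP"):
        return TIER_PLP
    if clazz in (TIER_VUS, TIER_CONFLICTING):
        return clazz
    raise ValueError(f"unknown ClinVar class: {clazz!r}")


def clinvar_major_tier(clazz_or_label: str) -> str:
    """Major tier used for the reclassification definition.

    The three major tiers are P/LP, VUS/Conflicting, and B/LB.
    """
    base = clazz_or_label.split(" ")[0]
    if base in ("B", "LB", "B/LB"):
        return TIER_BLB
    if base in ("P", "LP", "P/LP"):
        return TIER_PLP
    if base in (TIER_VUS, TIER_CONFLICTING):
        return "VUS/Conflicting"
    raise ValueError(f"unknown ClinVar class or label: {clazz_or_label!r}")


def ladder_label(clazz: str, stars: Optional[int]) -> str:
    """Build a 10-level ladder label from a fine class and star count.

    VUS and Conflicting carry no stars. Stars are clamped into 0-3; ``None``
    stars for a starred tier yields a label with unknown stars, which is not a
    ladder level and is rejected.
    """
    tier = clinvar_tier(clazz)
    if tier in (TIER_VUS, TIER_CONFLICTING):
        return tier
    if stars is None:
        raise ValueError(f"stars required for tier {tier}")
    stars = max(0, min(3, int(stars)))
    return f"{tier} {stars}*"


def ladder_index(label: str, database: str = "clinvar") -> int:
    """Position of a category on its ladder (benign end = 0)."""
    table = _CLINVAR_INDEX if database == "clinvar" else _HGMD_INDEX
    try:
        return table[label]
    except KeyError:
        raise ValueError(f"not a {database} ladder level: {label!r}") from None


def hgmd_severity(label: str) -> int:
    """HGMD severity rank under DM > DM? > DFP > DP > R."""
    return _HGMD_INDEX[label]


def most_severe_hgmd(labels: Sequence[str]) -> str:
    """Tie-break multiple HGMD labels by taking the most severe one."""
    known = [l for l in labels if l in _HGMD_INDEX]
    if not known:
        raise ValueError(f"no recognized HGMD label in {labels!r}")
    return max(known, key=hgmd_severity)


# ---------------------------------------------------------------------------
# Gene panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """One panel gene: a named 1-based inclusive interval with an
    inheritance mode (AR = autosomal recessive, XL = X-linked)."""

    name: str
    chrom: str
    start: int
    end: int
    inheritance: str  # "AR" | "XL"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")
        if self.inheritance not in ("AR", "XL"):
            raise ValueError(f"{self.name}: inheritance must be AR or XL")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GenePanel:
    """A screened-disorder gene panel: non-overlapping intervals per chromosome."""

    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping genes on {chrom}: {a.name}, {b.name}")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_at(self, chrom: str, pos: int) -> Optional[Gene]:
        for g in self.genes:
            if g.contains(chrom, pos):
                return g
        return None

    @property
    def xlinked(self) -> list[Gene]:
        return [g for g in self.genes if g.inheritance == "XL"]

    @property
    def autosomal(self) -> list[Gene]:
        return [g for g in self.genes if g.inheritance == "AR"]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tchrom\tstart\tend\tinheritance\n")
            for g in self.genes:
                fh.write(f"{g.name}\t{g.chrom}\t{g.start}\t{g.end}\t{g.inheritance}\n")

    @classmethod
    def read_tsv(cls, path) -> "GenePanel":
        genes = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("gene\t"):
                raise ValueError(f"{path}: not a panel TSV")
            for line in fh:
                name, chrom, start, end, inh = line.rstrip("\n").split("\t")
                genes.append(Gene(name, chrom, int(start), int(end), inh))
        return cls(genes)


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffectedCall:
    """One individual indicated affected in one gene by one mechanism."""

    sample: str
    gene: str
    mechanism: str  # "hom" | "hemi" | "comphet"
    variants: tuple[VariantKey, ...]
    date: dt.date
    set_name: str
    ancestry: str

    def __post_init__(self) -> None:
        if self.mechanism == "comphet":
            if len(self.variants) != 2 or self.variants[0] == self.variants[1]:
                raise ValueError("comphet call needs exactly 2 distinct variants")
        elif self.mechanism in ("hom", "hemi"):
            if len(self.variants) != 1:
                raise ValueError(f"{self.mechanism} call needs exactly 1 variant")
        else:
            raise ValueError(f"unknown mechanism: {self.mechanism}")


@dataclass(frozen=True)
class FisherResult:
    """Outcome of a contingency-table test."""

    p_value: float
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = "exact"  # "exact" | "chisq" | "montecarlo"


@dataclass(frozen=True)
class RateEstimate:
    """Reclassifications per variant-month with a Wald confidence interval."""

    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    n_variant_months: float


def parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text)


def month_of(date: dt.date) -> tuple[int, int]:
    return (date.year, date.month)


def months_between(start: dt.date, end: dt.date) -> list[tuple[int, int]]:
    """Inclusive list of (year, month) pairs covering [start, end]."""
    if end < start:
        return []
    out = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out
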