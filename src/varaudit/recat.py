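"""Recategorization and reclassification analysis.

Extracts category-change events from monthly-downsampled classification
timelines, computes variant-months exposure per ancestry and category, and
estimates ancestry-normalized reclassification rates with Wald confidence
intervals plus exact cross-ancestry comparisons.

A *recategorization* is any change of ladder level (including review-star
changes); a *reclassification* is a change between the three major tiers
(P/LP, VUS/Conflicting, B/LB). For the HGMD ladder every category change is
also a reclassification. Removal from ClinVar is not an event, but re-entry
under a new category is one; a variant removed from HGMD is treated as
retired (R).
"""
from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import (
    STAR_CUTOVER,
    FisherResult,
    RateEstimate,
    VariantKey,
    clinvar_major_tier,
    ladder_index,
)
from .exact import TestLedger, fisher_2x2, omnibus_rxc
from .ingest import ClassificationTimeline

log = logging.getLogger(__name__)

#: Default exposure window for variant-month accounting.
DEFAULT_WINDOW = (STAR_CUTOVER, dt.date(2020, 12, 31))


# ---------------------------------------------------------------------------
# Monthly downsampling
# ---------------------------------------------------------------------------

def downsample_monthly(dates: Sequence[dt.date], rule: str = "last") -> list[dt.date]:
    """Pick one representative snapshot per calendar month.

    ``rule`` selects the first snapshot of the month, the last (default), or
    the one nearest to the month's end. Months without a snapshot stay absent.
    """
    if rule not in ("first", "last", "nearest-to-month-end"):
        raise ValueError(f"unknown monthly rule: {rule!r}")
    by_month: dict[tuple[int, int], list[dt.date]] = {}
    for d in sorted(set(dates)):
        by_month.setdefault((d.year, d.month), []).append(d)
    out = []
    for (y, m), ds in sorted(by_month.items()):
        if rule == "first":
            out.append(ds[0])
        elif rule == "last":
            out.append(ds[-1])
        else:
            last_day = (dt.date(y + (m == 12), m % 12 + 1, 1) - dt.timedelta(days=1))
            out.append(min(ds, key=lambda d: (abs((last_day - d).days), d)))
    return out


# ---------------------------------------------------------------------------
# Monthly series per variant
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthlySeries:
    """One variant's ladder category at each monthly snapshot it appears in."""

    key: VariantKey
    database: str
    points: tuple[tuple[dt.date, str], ...]  # (snapshot date, ladder label)


def monthly_series(
    timeline: ClassificationTimeline,
    monthly_dates: Sequence[dt.date],
    hgmd_absent_as_retired: bool = True,
) -> MonthlySeries:
    """Restrict a timeline to the monthly snapshot grid.

    Entries that cannot be placed on the ladder (pre-cutover archive-1
    records with unassessed stars) are dropped. For HGMD, a variant missing
    from a snapshot after it first appeared is recorded as retired (R).
    """
    monthly = sorted(set(monthly_dates))
    points: list[tuple[dt.date, str]] = []
    seen = False
    for d in monthly:
        entry = timeline.at(d)
        if entry is None:
            if timeline.database == "hgmd" and seen and hgmd_absent_as_retired:
                points.append((d, "R"))
            continue
        try:
            label = entry.ladder(timeline.database)
        except ValueError:
            continue  # not placeable on the ladder; not considered
        seen = True
        points.append((d, label))
    return MonthlySeries(timeline.key, timeline.database, tuple(points))


def build_monthly_series(
    timelines: dict[VariantKey, ClassificationTimeline],
    rule: str = "last",
) -> dict[VariantKey, MonthlySeries]:
    all_dates = sorted({d for tl in timelines.values() for d in tl.dates})
    monthly = downsample_monthly(all_dates, rule)
    return {k: monthly_series(tl, monthly) for k, tl in timelines.items()}


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecategorizationEvent:
    key: VariantKey
    date: dt.date  # snapshot at which the new category first appears
    from_category: str
    to_category: str
    direction: str          # "toward_pathogenic" | "toward_benign"
    confidence_change: str  # "increasing" | "decreasing" | "neither"
    is_reclassification: bool


def _classify_event(key: VariantKey, date: dt.date, from_cat: str, to_cat: str,
                    database: str) -> RecategorizationEvent:
    i_from = ladder_index(from_cat, database)
    i_to = ladder_index(to_cat, database)
    direction = "toward_pathogenic" if i_to > i_from else "toward_benign"
    if database == "clinvar":
        mt_from = clinvar_major_tier(from_cat)
        mt_to = clinvar_major_tier(to_cat)
        is_reclass = mt_from != mt_to
        if mt_from == "VUS/Conflicting" and mt_to in ("P/LP", "B/LB"):
            confidence = "increasing"
        elif mt_from in ("P/LP", "B/LB") and mt_to == "VUS/Conflicting":
            confidence = "decreasing"
        else:
            confidence = "neither"
    else:
        is_reclass = True  # every HGMD category change crosses categories
        confidence = "neither"
    return RecategorizationEvent(key, date, from_cat, to_cat, direction,
                                 confidence, is_reclass)


def extract_events(
    series: MonthlySeries,
    clinvar_start: dt.date = STAR_CUTOVER,
) -> list[RecategorizationEvent]:
    """One event per adjacent category change in a monthly series.

    Removal emits nothing; re-entry under a different category emits a single
    event from the pre-removal category, dated at the re-entry snapshot.
    ClinVar events before ``clinvar_start`` are not considered.
    """
    events: list[RecategorizationEvent] = []
    prev_cat: Optional[str] = None
    for date, cat in series.points:
        if prev_cat is not None and cat != prev_cat:
            if series.database != "clinvar" or date >= clinvar_start:
                events.append(_classify_event(series.key, date, prev_cat, cat,
                                              series.database))
        prev_cat = cat
    return events


def extract_all_events(
    serieses: Iterable[MonthlySeries],
    clinvar_start: dt.date = STAR_CUTOVER,
) -> list[RecategorizationEvent]:
    out: list[RecategorizationEvent] = []
    for s in serieses:
        out.extend(extract_events(s, clinvar_start))
    return out


def first_last_transition(series: MonthlySeries) -> tuple[str, str]:
    """Chronologically first and last ladder categories (Sankey endpoints)."""
    if not series.points:
        raise ValueError(f"{series.key}: empty monthly series")
    return series.points[0][1], series.points[-1][1]


# ---------------------------------------------------------------------------
# Variant-months
# ---------------------------------------------------------------------------

def variant_months(
    serieses: Iterable[MonthlySeries],
    category_filter: set[str],
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
) -> int:
    """Total variant-months with category in ``category_filter`` inside the
    window: one variant in one monthly snapshot is one variant-month."""
    start, end = window
    total = 0
    for s in serieses:
        for date, cat in s.points:
            if start <= date <= end and cat in category_filter:
                total += 1
    return total


def variant_month_ledger(
    serieses: Iterable[MonthlySeries],
    ancestry_of: dict[VariantKey, Optional[str]],
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
) -> dict[tuple[str, str], int]:
    """(ancestry, category) -> variant-months. Variants without an assigned
    ancestry are not considered."""
    start, end = window
    cells: dict[tuple[str, str], int] = {}
    for s in serieses:
        anc = ancestry_of.get(s.key)
        if anc is None:
            continue
        for date, cat in s.points:
            if start <= date <= end:
                cells[(anc, cat)] = cells.get((anc, cat), 0) + 1
    return cells


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def reclass_rate(n_events: int, n_source_variant_months: int) -> RateEstimate:
    """Events per variant-month of the source category, with the Wald
    interval rate +/- 1.96*sqrt(rate*(1-rate)/n), lower bound clipped at 0."""
    if n_source_variant_months <= 0:
        return RateEstimate(math.nan, math.nan, math.nan, n_events, 0)
    p = n_events / n_source_variant_months
    half = 1.96 * math.sqrt(p * (1.0 - p) / n_source_variant_months)
    return RateEstimate(p, max(0.0, p - half), p + half,
                        n_events, n_source_variant_months)


@dataclass(frozen=True)
class AncestryRateComparison:
    rates: tuple[tuple[str, RateEstimate], ...]
    omnibus: FisherResult
    pairwise: tuple[tuple[str, str, float], ...]  # (higher?, other, one-sided p)


def compare_ancestry_rates(
    events_by_ancestry: dict[str, int],
    vm_by_ancestry: dict[str, int],
    ledger: Optional[TestLedger] = None,
    label: str = "",
) -> AncestryRateComparison:
    """Omnibus 5x2 test of (events, variant-months) homogeneity across
    ancestries plus all ordered-pair one-sided comparisons.

    Zero-exposure ancestries are excluded with a log line. The pairwise table
    for (A, B) is [[events_A, vm_A], [events_B, vm_B]] with alternative
    "greater" (A reclassified more often than B).
    """
    ancestries = sorted(a for a in vm_by_ancestry if vm_by_ancestry[a] > 0)
    dropped = sorted(set(vm_by_ancestry) - set(ancestries))
    if dropped:
        log.info("excluding zero-exposure ancestries: %s", dropped)
    rates = tuple(
        (a, reclass_rate(events_by_ancestry.get(a, 0), vm_by_ancestry[a]))
        for a in ancestries
    )
    if sum(events_by_ancestry.get(a, 0) for a in ancestries) == 0:
        # nothing reclassified anywhere: no comparison to make, no tests run
        return AncestryRateComparison(rates, FisherResult(p_value=1.0), ())
    tab = [[events_by_ancestry.get(a, 0), vm_by_ancestry[a]] for a in ancestries]
    omnibus = omnibus_rxc(tab)
    if ledger is not None:
        ledger.record(f"{label}:omnibus", omnibus.p_value)
    pairwise = []
    for a in ancestries:
        for b in ancestries:
            if a == b:
                continue
            t = [[events_by_ancestry.get(a, 0), vm_by_ancestry[a]],
                 [events_by_ancestry.get(b, 0), vm_by_ancestry[b]]]
            p = fisher_2x2(t, alternative="greater")
            pairwise.append((a, b, p))
            if ledger is not None:
                ledger.record(f"{label}:{a}>{b}", p)
    return AncestryRateComparison(rates, omnibus, tuple(pairwise))


# ---------------------------------------------------------------------------
# Cross-database comparability
# ---------------------------------------------------------------------------

def collapse_stars(series: MonthlySeries) -> MonthlySeries:
    """Collapse ClinVar star levels so that star-only changes vanish,
    leaving the major categories B/LB, VUS, Conflicting, P/LP."""
    if series.database != "clinvar":
        return series
    points = tuple((d, cat.split(" ")[0]) for d, cat in series.points)
    return MonthlySeries(series.key, series.database, points)


def restrict_dates(series: MonthlySeries, dates: set[dt.date]) -> MonthlySeries:
    """Keep only points at the given snapshot dates (HGMD-availability mode)."""
    return MonthlySeries(series.key, series.database,
                         tuple(p for p in series.points if p[0] in dates))


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def write_events_tsv(events: Iterable[RecategorizationEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tmonth\tfrom\tto\tdirection\tconfidence_change\t"
                 "is_reclassification\n")
        for e in sorted(events, key=lambda e: (e.date, e.key)):
            fh.write(f"{e.key}\t{e.date.isoformat()}\t{e.from_category}\t"
                     f"{e.to_category}\t{e.direction}\t{e.confidence_change}\t"
                     f"{int(e.is_reclassification)}\n")


def write_sankey_tsv(
    serieses: Iterable[MonthlySeries],
    ancestry_of: dict[VariantKey, Optional[str]],
    path,
) -> None:
    """First-to-last category link counts per ancestry, consumable by any
    flow-diagram tool."""
    links: dict[tuple[str, str, str], int] = {}
    for s in serieses:
        if not s.points:
            continue
        first, last = first_last_transition(s)
        anc = ancestry_of.get(s.key) or "unassigned"
        links[(first, last, anc)] = links.get((first, last, anc), 0) + 1
    with open(path, "w") as fh:
        fh.write("source\ttarget\tancestry\tcount\n")
        for (src, tgt, anc), n in sorted(links.items()):
            fh.write(f"{src}\t{tgt}\t{anc}\t{n}\n")


def write_rates_tsv(comparison: AncestryRateComparison, path) -> None:
    with open(path, "w") as fh:
        fh.write("ancestry\trate\tci_low\tci_high\tn_events\tn_variant_months\n")
        for anc, r in comparison.rates:
            fh.write(f"{anc}\t{r.rate:.6g}\t{r.ci_low:.6g}\t{r.ci_high:.6g}\t"
                     f"{r.n_events}\t{r.n_variant_months}\n")
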