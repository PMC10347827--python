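"""Snapshot ingestion and harmonization.

Reads dated classification snapshots in three dialects — archive-1.0-style
VCFs carrying numeric clinical-significance codes, archive-2.0-style VCFs
carrying aggregate string labels, and HGMD-style TSVs — normalizes variant
identities, maps raw labels onto the 10-level ClinVar ladder or the 5-level
HGMD ladder, and assembles per-variant classification timelines.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from .core import (
    STAR_CUTOVER,
    VariantKey,
    ladder_label,
    most_severe_hgmd,
    parse_date,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    context: str,
    context_start: int = 1,
) -> VariantKey:
    """Reduce a variant to its unique minimal, left-aligned representation.

    ``context`` is the reference sequence covering the locus; ``context_start``
    is the 1-based position of its first base. SNVs pass through unchanged and
    the operation is idempotent.

    The algorithm is the standard one: repeatedly truncate a shared trailing
    base (extending both alleles leftward from the reference whenever one
    allele would become empty), then truncate shared leading bases while both
    alleles retain at least two bases.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical; not a variant")
    lo = pos - context_start
    if lo < 0 or lo + len(ref) > len(context):
        raise ValueError("reference mismatch: context does not cover the variant")
    if context[lo : lo + len(ref)].upper() != ref.upper():
        raise ValueError("reference mismatch: ref allele disagrees with context")

    ref, alt = ref.upper(), alt.upper()
    # trim shared trailing bases; when that would empty an allele, rotate the
    # variant leftward by pulling in the preceding reference base
    while ref[-1] == alt[-1] and (
        (len(ref) > 1 and len(alt) > 1) or pos > context_start
    ):
        if len(ref) == 1 or len(alt) == 1:
            base = context[pos - 1 - context_start].upper()
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
        else:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Label maps
# ---------------------------------------------------------------------------

#: Archive-1.0 numeric clinical-significance codes.
_ARCHIVE1_CODES = {"0": "VUS", "2": "B", "3": "LB", "4": "LP", "5": "P"}

#: Archive-2.0 aggregate labels.
_ARCHIVE2_LABELS = {
    "Benign": "B",
    "Benign/Likely_benign": "B",
    "Likely_benign": "LB",
    "Uncertain_significance": "VUS",
    "Likely_pathogenic": "LP",
    "Pathogenic/Likely_pathogenic": "P",
    "Pathogenic": "P",
    "Conflicting_interpretations_of_pathogenicity": "Conflicting",
}


def map_archive1_class(code: str) -> Optional[str]:
    """Map an archive-1.0 numeric code to a fine class; unknown codes yield
    ``None`` (the record is skipped and logged, never fatal)."""
    clazz = _ARCHIVE1_CODES.get(code.strip())
    if clazz is None:
        log.info("unmapped archive-1.0 code %r; record skipped", code)
    return clazz


def map_archive2_class(label: str) -> Optional[str]:
    """Map an archive-2.0 aggregate label to a fine class.

    Comma-separated multi-labels resolve to the unique mapped component when
    exactly one component is in the recognized list (so "Pathogenic,_risk_factor"
    maps to P but "Pathogenic,Benign" is unmapped).
    """
    label = label.strip()
    if label in _ARCHIVE2_LABELS:
        return _ARCHIVE2_LABELS[label]
    parts = [p.strip().lstrip("_") for p in label.split(",")]
    hits = [_ARCHIVE2_LABELS[p] for p in parts if p in _ARCHIVE2_LABELS]
    if len(hits) == 1:
        return hits[0]
    log.info("unmapped archive-2.0 label %r; record skipped", label)
    return None


def infer_conflicting(classes: Iterable[str]) -> str:
    """Aggregate per-submission fine classes.

    Conflicting when two or more of the three groups {B, LB}, {VUS}, {P, LP}
    are represented; otherwise the single group's most severe member.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("no classes to aggregate")
    groups = set()
    if classes & {"B", "LB"}:
        groups.add("B/LB")
    if "VUS" in classes:
        groups.add("VUS")
    if classes & {"P", "LP"}:
        groups.add("P/LP")
    if "Conflicting" in classes:
        return "Conflicting"
    if len(groups) >= 2:
        return "Conflicting"
    # one group: most severe member (P > LP; B > LB is irrelevant, keep benign-most B)
    if "P/LP" in groups:
        return "P" if "P" in classes else "LP"
    if "VUS" in groups:
        return "VUS"
    return "B" if "B" in classes else "LB"


#: Review-status token groups per archive dialect. 2 stands for "2+".
_STAR_TOKENS = {
    1: {
        0: ("no_assertion_criteria_provided", "no_assertion_provided", "not",
            "no_criteria", "no_assertion"),
        1: ("criteria_provided", "conf", "single"),
        2: ("_multiple_submitters", "_no_conflicts", "mult"),
    },
    2: {
        0: ("no_assertion_criteria_provided", "no_assertion_provided",
            "no_interpretation_for_the_single_variant"),
        1: ("criteria_provided", "_single_submitter", "_conflicting_interpretations"),
        2: ("_multiple_submitters", "_no_conflicts", "reviewed_by_expert_panel"),
    },
}


def map_review_stars(status: str, archive: int) -> int:
    """Group a review-status string into 0, 1, or 2(+) stars.

    The most credible matching token group wins, so a status naming both
    criteria provision and multiple concordant submitters counts as 2+.
    Unknown statuses map to 0 stars with a warning.
    """
    if archive not in (1, 2):
        raise ValueError(f"archive must be 1 or 2, got {archive!r}")
    status_lower = status.strip().lower()
    for stars in (2, 1, 0):
        if any(tok in status_lower for tok in _STAR_TOKENS[archive][stars]):
            return stars
    log.warning("unknown review status %r; treated as 0 stars", status)
    return 0


def map_hgmd_class(labels: Sequence[str]) -> Optional[str]:
    """Resolve one or more HGMD labels to the most severe one
    (DM > DM? > DFP > DP > R); unrecognized-only input is skipped."""
    try:
        return most_severe_hgmd(labels)
    except ValueError:
        log.info("unmapped HGMD labels %r; record skipped", labels)
        return None


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnapshotEntry:
    """One variant's harmonized state in one dated snapshot."""

    clazz: str                 # fine ClinVar class or HGMD label
    stars: Optional[int] = None  # None = stars not assessed (pre-cutover archive 1)
    condition: str = "not provided"

    def ladder(self, database: str) -> str:
        if database == "hgmd":
            return self.clazz
        return ladder_label(self.clazz, self.stars)


@dataclass
class ClassificationTimeline:
    """Ordered (date, category) history of one variant in one database."""

    key: VariantKey
    database: str  # "clinvar" | "hgmd"
    entries: list[tuple[dt.date, SnapshotEntry]] = field(default_factory=list)

    def add(self, date: dt.date, entry: SnapshotEntry) -> None:
        if self.entries and date <= self.entries[-1][0]:
            raise ValueError(f"{self.key}: dates must be strictly increasing")
        self.entries.append((date, entry))

    @property
    def dates(self) -> list[dt.date]:
        return [d for d, _ in self.entries]

    def at(self, date: dt.date) -> Optional[SnapshotEntry]:
        for d, e in self.entries:
            if d == date:
                return e
        return None


def filter_condition(
    entries: dict[VariantKey, SnapshotEntry],
    allowlist: Optional[set[str]],
) -> dict[VariantKey, SnapshotEntry]:
    """Drop entries whose submitted condition is neither on the screened-disorder
    allowlist nor "not provided". ``allowlist=None`` disables the filter."""
    if allowlist is None:
        return dict(entries)
    return {
        k: e
        for k, e in entries.items()
        if e.condition == "not provided" or e.condition in allowlist
    }


# ---------------------------------------------------------------------------
# Snapshot readers
# ---------------------------------------------------------------------------

def _fetch_context(fasta: Optional[pysam.FastaFile], chrom: str, pos: int,
                   ref: str, pad: int = 50) -> tuple[str, int]:
    if fasta is None or chrom not in fasta.references:
        # no reference available: normalization degenerates to prefix/suffix trimming
        return ref, pos
    start = max(0, pos - 1 - pad)
    end = min(fasta.get_reference_length(chrom), pos - 1 + len(ref) + pad)
    return fasta.fetch(chrom, start, end), start + 1


def read_snapshot_vcf(
    path,
    date: dt.date,
    dialect: str,  # "archive1" | "archive2"
    fasta_path=None,
    clnsig_key: str = "CLNSIG",
    clnrevstat_key: str = "CLNREVSTAT",
    condition_key: str = "CLNDN",
    origin_key: str = "ORIGIN",
) -> dict[VariantKey, SnapshotEntry]:
    """Parse one dated classification snapshot VCF into harmonized entries.

    Multiallelic records are split into biallelic keys. Somatic-only records
    and records with null alt alleles are dropped. Unmapped labels are skipped
    with a log line, never raised.
    """
    if dialect not in ("archive1", "archive2"):
        raise ValueError(f"unknown VCF snapshot dialect: {dialect!r}")
    fasta = pysam.FastaFile(str(fasta_path)) if fasta_path else None
    out: dict[VariantKey, SnapshotEntry] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index else vcf:
            origin = _info_str(rec, origin_key)
            if origin is not None and origin.lower() == "somatic":
                continue
            if not rec.alts:
                continue
            sig = _info_str(rec, clnsig_key)
            if sig is None:
                continue
            revstat = _info_str(rec, clnrevstat_key)
            condition = _info_str(rec, condition_key) or "not provided"
            condition = condition.replace("_", " ")
            if dialect == "archive1":
                codes = [c for part in sig.split("|") for c in part.split(",")]
                mapped = [map_archive1_class(c) for c in codes]
                mapped = [m for m in mapped if m is not None]
                if not mapped:
                    continue
                clazz = infer_conflicting(mapped)
                if date < STAR_CUTOVER:
                    stars: Optional[int] = None
                elif revstat is not None:
                    stars = map_review_stars(revstat, archive=1)
                else:
                    stars = 0
            else:
                clazz = map_archive2_class(sig)
                if clazz is None:
                    continue
                stars = map_review_stars(revstat, archive=2) if revstat else 0
            for alt in rec.alts:
                if alt is None or alt in (".", "*", "<NON_REF>"):
                    continue
                context, ctx_start = _fetch_context(fasta, rec.chrom, rec.pos, rec.ref)
                key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt,
                                        context, ctx_start)
                out[key] = SnapshotEntry(clazz=clazz, stars=stars, condition=condition)
    if fasta is not None:
        fasta.close()
    return out


def read_snapshot_hgmd(path, date: dt.date) -> dict[VariantKey, SnapshotEntry]:
    """Parse an HGMD-dialect snapshot TSV (key, label, date).

    Rows whose date column disagrees with the requested snapshot date are
    ignored, so one file may carry a whole series.
    """
    out: dict[VariantKey, SnapshotEntry] = {}
    labels_by_key: dict[VariantKey, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for needed in ("key", "label", "date"):
            if needed not in cols:
                raise ValueError(f"{path}: HGMD snapshot TSV lacks column {needed!r}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if parse_date(fields[cols["date"]]) != date:
                continue
            key = VariantKey.parse(fields[cols["key"]])
            labels_by_key.setdefault(key, []).extend(
                fields[cols["label"]].split(","))
    for key, labels in labels_by_key.items():
        clazz = map_hgmd_class(labels)
        if clazz is not None:
            out[key] = SnapshotEntry(clazz=clazz)
    return out


def build_timelines(
    snapshots: Sequence[tuple[dt.date, dict[VariantKey, SnapshotEntry]]],
    database: str,
) -> dict[VariantKey, ClassificationTimeline]:
    """Assemble per-variant timelines from a dated series of snapshots.

    A variant absent from a snapshot simply has no entry at that date; removal
    and re-entry semantics are interpreted downstream.
    """
    ordered = sorted(snapshots, key=lambda x: x[0])
    timelines: dict[VariantKey, ClassificationTimeline] = {}
    for date, entries in ordered:
        for key, entry in entries.items():
            tl = timelines.setdefault(key, ClassificationTimeline(key, database))
            tl.add(date, entry)
    return timelines


# ---------------------------------------------------------------------------
# Variant sets
# ---------------------------------------------------------------------------

VARIANT_SETS = ("select_clinvar", "full_clinvar", "select_hgmd", "full_hgmd")


def select_variant_set(
    snapshot: dict[VariantKey, SnapshotEntry],
    set_name: str,
    star_overrides: Optional[dict[VariantKey, int]] = None,
) -> set[VariantKey]:
    """Resolve a date's snapshot into one of the four audited variant sets.

    select_clinvar: class P with >= 1 review star (aggregate Conflicting
    variants are by construction excluded); full_clinvar: class P or LP,
    Conflicting excluded; select_hgmd: DM; full_hgmd: DM or DM?.

    ``star_overrides`` supplies manually assessed stars for specific variants,
    taking precedence over the snapshot's own star annotation.
    """
    overrides = star_overrides or {}

    def stars_of(key: VariantKey, entry: SnapshotEntry) -> Optional[int]:
        return overrides.get(key, entry.stars)

    if set_name == "select_clinvar":
        return {
            k for k, e in snapshot.items()
            if e.clazz == "P" and (stars_of(k, e) or 0) >= 1
        }
    if set_name == "full_clinvar":
        return {k for k, e in snapshot.items() if e.clazz in ("P", "LP")}
    if set_name == "select_hgmd":
        return {k for k, e in snapshot.items() if e.clazz == "DM"}
    if set_name == "full_hgmd":
        return {k for k, e in snapshot.items() if e.clazz in ("DM", "DM?")}
    raise ValueError(f"unknown variant set: {set_name!r}")


def _info_str(rec, key: str) -> Optional[str]:
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, tuple):
        val = ",".join(str(v) for v in val if v is not None)
    return str(val) if val is not None else None


# ---------------------------------------------------------------------------
# Harmonized timeline TSV round-trip
# ---------------------------------------------------------------------------

def write_timelines_tsv(timelines: dict[VariantKey, ClassificationTimeline], path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tdatabase\tdate\tclass\tstars\tcondition\n")
        for key in sorted(timelines):
            tl = timelines[key]
            for date, e in tl.entries:
                stars = "" if e.stars is None else str(e.stars)
                fh.write(f"{key}\t{tl.database}\t{date.isoformat()}\t"
                         f"{e.clazz}\t{stars}\t{e.condition}\n")


def read_timelines_tsv(path) -> dict[VariantKey, ClassificationTimeline]:
    timelines: dict[VariantKey, ClassificationTimeline] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("key\t"):
            raise ValueError(f"{path}: not a harmonized timeline TSV")
        for line in fh:
            key_s, database, date_s, clazz, stars_s, condition = \
                line.rstrip("\n").split("\t")
            key = VariantKey.parse(key_s)
            tl = timelines.setdefault(key, ClassificationTimeline(key, database))
            stars = None if stars_s == "" else int(stars_s)
            tl.add(parse_date(date_s),
                   SnapshotEntry(clazz=clazz, stars=stars, condition=condition))
    return timelines
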