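"""End-to-end audit orchestration from a single declarative config.

Stages run in the method's order — ingest, allele-frequency filter, burden
detection, skew statistics, recategorization — each writing plain-text tables
into the output directory, with a JSON manifest recording input digests and
per-stage counts so every number in the bundle is auditable.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import burden as burden_mod
from . import exact as exact_mod
from . import frequencies as freq_mod
from . import ingest as ingest_mod
from . import recat as recat_mod
from .core import GenePanel, VariantKey, parse_date

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class SnapshotRef:
    date: dt.date
    path: Path
    dialect: str  # "archive1" | "archive2" | "hgmd"


@dataclass
class RunConfig:
    panel: Path
    cohort_vcf: Path
    sample_sheet: Path
    snapshots: dict[str, list[SnapshotRef]]  # database -> dated files
    frequency_table: Optional[Path]
    out_dir: Path
    variant_sets: list[str] = field(default_factory=lambda: list(ingest_mod.VARIANT_SETS))
    ba1: str = "none"  # "2015" | "2018" | "none"
    window_start: dt.date = dt.date(2015, 6, 15)
    window_end: dt.date = dt.date(2020, 12, 31)
    seed: int = 0
    unphased_comphet: bool = False
    monthly_rule: str = "last"
    hgmd_comparability: bool = False
    star_overrides: Optional[Path] = None
    condition_allowlist: Optional[list[str]] = None
    reference_fasta: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def p(value) -> Optional[Path]:
            if value is None:
                return None
            q = Path(value)
            return q if q.is_absolute() else base / q

        snapshots: dict[str, list[SnapshotRef]] = {}
        for db, refs in (raw.get("snapshots") or {}).items():
            snapshots[db] = [
                SnapshotRef(parse_date(str(r["date"])), p(r["path"]), r["dialect"])
                for r in refs
            ]
        opts = raw.get("options") or {}
        window = raw.get("window") or {}
        return cls(
            panel=p(raw["panel"]),
            cohort_vcf=p(raw["cohort_vcf"]),
            sample_sheet=p(raw["sample_sheet"]),
            snapshots=snapshots,
            frequency_table=p(raw.get("frequency_table")),
            out_dir=p(raw.get("out_dir", "audit_out")),
            variant_sets=list(raw.get("variant_sets", ingest_mod.VARIANT_SETS)),
            ba1=str(raw.get("ba1", "none")),
            window_start=parse_date(str(window.get("start", "2015-06-15"))),
            window_end=parse_date(str(window.get("end", "2020-12-31"))),
            seed=int(raw.get("seed", 0)),
            unphased_comphet=bool(opts.get("unphased_comphet", False)),
            monthly_rule=str(opts.get("monthly_rule", "last")),
            hgmd_comparability=bool(opts.get("hgmd_comparability", False)),
            star_overrides=p(opts.get("star_overrides")),
            condition_allowlist=opts.get("condition_allowlist"),
            reference_fasta=p(raw.get("reference_fasta")),
        )


def validate_config(config: RunConfig) -> list[str]:
    """Collect diagnostics ("ERROR: ..." / "WARNING: ...") without running."""
    diags: list[str] = []
    for name in ("panel", "cohort_vcf", "sample_sheet"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            diags.append(f"ERROR: {name} file missing: {path}")
    for db, refs in config.snapshots.items():
        for ref in refs:
            if not Path(ref.path).exists():
                diags.append(f"ERROR: {db} snapshot missing: {ref.path}")
            if ref.dialect == "archive1" and ref.date >= ingest_mod.STAR_CUTOVER:
                diags.append(
                    f"WARNING: archive-1 snapshot {ref.path} dated {ref.date} "
                    f"after the archive-2 cutover")
            if ref.dialect == "hgmd" and db != "hgmd":
                diags.append(f"WARNING: hgmd-dialect snapshot under database {db}")
    if config.ba1 not in ("2015", "2018", "none"):
        diags.append(f"ERROR: ba1 must be 2015, 2018, or none, got {config.ba1!r}")
    if config.ba1 != "none":
        if config.frequency_table is None:
            diags.append("ERROR: BA1 filtering enabled but no frequency table given")
        elif not Path(config.frequency_table).exists():
            diags.append(f"ERROR: frequency table missing: {config.frequency_table}")
    if config.monthly_rule not in ("first", "last", "nearest-to-month-end"):
        diags.append(f"ERROR: unknown monthly rule {config.monthly_rule!r}")
    for s in config.variant_sets:
        if s not in ingest_mod.VARIANT_SETS:
            diags.append(f"ERROR: unknown variant set {s!r}")
    return diags


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

@dataclass
class AuditResult:
    out_dir: Path
    burden: dict[str, list[burden_mod.BurdenSummary]]
    skew: dict[tuple[str, int], exact_mod.SkewResult]
    events: dict[str, list[recat_mod.RecategorizationEvent]]
    rates: dict[str, recat_mod.AncestryRateComparison]
    test_ledger: exact_mod.TestLedger
    manifest: dict


class Audit:
    """Composes the pipeline stages over one validated config."""

    def __init__(self, config: RunConfig):
        diags = [d for d in validate_config(config) if d.startswith("ERROR")]
        if diags:
            raise ValueError("invalid config:\n" + "\n".join(diags))
        self.config = config
        self.counts: dict[str, int] = {}
        self._snapshots: dict[str, list[tuple[dt.date, dict]]] = {}
        self._timelines: dict[str, dict] = {}
        self._removed_keys: set[VariantKey] = set()
        self._removals: list[freq_mod.Ba1Removal] = []

    # -- ingest ------------------------------------------------------------

    def stage_ingest(self) -> None:
        cfg = self.config
        self.panel = GenePanel.read_tsv(cfg.panel)
        self.cohort = burden_mod.load_cohort(cfg.cohort_vcf, cfg.sample_sheet)
        allow = set(cfg.condition_allowlist) if cfg.condition_allowlist else None
        for db, refs in cfg.snapshots.items():
            dated = []
            for ref in sorted(refs, key=lambda r: r.date):
                if ref.dialect == "hgmd":
                    entries = ingest_mod.read_snapshot_hgmd(ref.path, ref.date)
                else:
                    entries = ingest_mod.read_snapshot_vcf(
                        ref.path, ref.date, ref.dialect,
                        fasta_path=cfg.reference_fasta)
                n_raw = len(entries)
                if db == "clinvar":
                    entries = ingest_mod.filter_condition(entries, allow)
                entries = {
                    k: e for k, e in entries.items()
                    if self.panel.gene_at(k.chrom, k.pos) is not None
                }
                self.counts[f"ingest:{db}:{ref.date}:raw"] = n_raw
                self.counts[f"ingest:{db}:{ref.date}:kept"] = len(entries)
                dated.append((ref.date, entries))
            self._snapshots[db] = dated
            self._timelines[db] = ingest_mod.build_timelines(dated, db)

    # -- BA1 filter --------------------------------------------------------

    def stage_filter(self) -> None:
        cfg = self.config
        self._removed_keys = set()
        self._removals = []
        if cfg.ba1 == "none" or cfg.frequency_table is None:
            self.freq = (freq_mod.FrequencyTable.read_tsv(cfg.frequency_table)
                         if cfg.frequency_table else freq_mod.FrequencyTable())
            return
        self.freq = freq_mod.FrequencyTable.read_tsv(cfg.frequency_table)
        universe = {k for dated in self._snapshots.values()
                    for _, entries in dated for k in entries}
        if cfg.ba1 == "2015":
            kept, removed = freq_mod.apply_ba1_2015(universe, self.freq)
        else:
            kept, removed = freq_mod.apply_ba1_2018(universe, self.freq)
        self._removed_keys = universe - kept
        self._removals = removed
        self.counts["ba1:removed"] = len(removed)

    # -- burden ------------------------------------------------------------

    def stage_burden(self) -> None:
        cfg = self.config
        overrides = _read_star_overrides(cfg.star_overrides)
        self.calls_by_set: dict[str, dict[dt.date, list]] = {}
        self.set_sizes: dict[str, dict[dt.date, int]] = {}
        for set_name in cfg.variant_sets:
            db = "hgmd" if set_name.endswith("hgmd") else "clinvar"
            calls_by_date: dict[dt.date, list] = {}
            sizes: dict[dt.date, int] = {}
            for date, entries in self._snapshots.get(db, []):
                vset = ingest_mod.select_variant_set(entries, set_name, overrides)
                vset -= self._removed_keys
                sizes[date] = len(vset)
                calls_by_date[date] = burden_mod.detect_affected(
                    self.cohort, vset, self.panel, date, set_name,
                    unphased_comphet=cfg.unphased_comphet)
            self.calls_by_set[set_name] = calls_by_date
            self.set_sizes[set_name] = sizes
            self.counts[f"burden:{set_name}:calls"] = sum(
                len(v) for v in calls_by_date.values())
        self.burden_summaries = {
            s: burden_mod.summarize_burden(self.calls_by_set[s],
                                           self.set_sizes[s], s)
            for s in cfg.variant_sets
        }

    # -- statistics --------------------------------------------------------

    def stage_stats(self) -> None:
        self.test_ledger = exact_mod.TestLedger()
        cohort_comp = self.cohort.ancestry_counts()
        self.skew: dict[tuple[str, int], exact_mod.SkewResult] = {}
        for set_name, summaries in self.burden_summaries.items():
            for s in summaries:
                if s.n_affected == 0:
                    continue  # zero-height bars are not tested
                affected = dict(s.ancestry_counts)
                self.skew[(set_name, s.year)] = exact_mod.ancestry_skew(
                    affected, cohort_comp, ledger=self.test_ledger,
                    label=f"{set_name}:{s.year}")

    # -- recategorization --------------------------------------------------

    def stage_recat(self) -> None:
        cfg = self.config
        window = (cfg.window_start, cfg.window_end)
        self.series: dict[str, dict[VariantKey, recat_mod.MonthlySeries]] = {}
        self.events: dict[str, list] = {}
        for db, timelines in self._timelines.items():
            series = recat_mod.build_monthly_series(timelines, cfg.monthly_rule)
            self.series[db] = series
            self.events[db] = recat_mod.extract_all_events(series.values())
            self.counts[f"recat:{db}:events"] = len(self.events[db])

        if self.freq.pop_n.get("gnomad"):
            floor = freq_mod.compute_maf_floor(self.freq.pop_n["gnomad"])
            floored = freq_mod.floor_mafs(self.freq, floor, dataset="gnomad")
            assignments = freq_mod.assign_ancestry(floored, "gnomad")
            self.ancestry_of = {k: a.ancestry for k, a in assignments.items()}
        else:
            self.ancestry_of = {}

        self.rates: dict[str, recat_mod.AncestryRateComparison] = {}
        clinvar_series = self.series.get("clinvar", {})
        plp_blb = {"P/LP 0*", "P/LP 1*", "P/LP 2*", "P/LP 3*",
                   "B/LB 0*", "B/LB 1*", "B/LB 2*", "B/LB 3*"}
        vus_conf = {"VUS", "Conflicting"}
        for direction, source in (("decreasing", plp_blb), ("increasing", vus_conf)):
            events_by_anc: dict[str, int] = {}
            vm_by_anc: dict[str, int] = {}
            for key, s in clinvar_series.items():
                anc = self.ancestry_of.get(key)
                if anc is None:
                    continue
                n = sum(
                    1 for e in recat_mod.extract_events(s)
                    if e.confidence_change == direction
                    and cfg.window_start <= e.date <= cfg.window_end
                )
                events_by_anc[anc] = events_by_anc.get(anc, 0) + n
                vm_by_anc[anc] = vm_by_anc.get(anc, 0) + recat_mod.variant_months(
                    [s], source, window)
            if any(vm_by_anc.values()):
                self.rates[direction] = recat_mod.compare_ancestry_rates(
                    events_by_anc, vm_by_anc, ledger=self.test_ledger,
                    label=f"rate:{direction}")

    # -- outputs -----------------------------------------------------------

    def write_outputs(self) -> AuditResult:
        cfg = self.config
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        freq_mod.write_removals_tsv(self._removals, out / "ba1_removals.tsv")
        all_calls = [c for by_date in self.calls_by_set.values()
                     for calls in by_date.values() for c in calls]
        burden_mod.write_calls_tsv(all_calls, out / "affected_calls.tsv")
        burden_mod.write_burden_tsv(
            [s for ss in self.burden_summaries.values() for s in ss],
            out / "burden_summary.tsv")
        for db, events in self.events.items():
            recat_mod.write_events_tsv(events, out / f"events_{db}.tsv")
            recat_mod.write_sankey_tsv(self.series[db].values(),
                                       self.ancestry_of,
                                       out / f"sankey_{db}.tsv")
        for direction, comparison in self.rates.items():
            recat_mod.write_rates_tsv(comparison, out / f"rates_{direction}.tsv")
        _write_stats_tsv(self.skew, self.test_ledger, out / "skew_tests.tsv")

        manifest = {
            "inputs": {
                "panel": _digest(cfg.panel),
                "cohort_vcf": _digest(cfg.cohort_vcf),
                "sample_sheet": _digest(cfg.sample_sheet),
                "frequency_table": _digest(cfg.frequency_table),
            },
            "config": {
                "ba1": cfg.ba1,
                "variant_sets": cfg.variant_sets,
                "window": [cfg.window_start.isoformat(),
                           cfg.window_end.isoformat()],
                "seed": cfg.seed,
                "monthly_rule": cfg.monthly_rule,
            },
            "counts": self.counts,
            "n_tests": self.test_ledger.m,
            "bonferroni_threshold": self.test_ledger.threshold(0.05),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return AuditResult(out, self.burden_summaries, self.skew, self.events,
                           self.rates, self.test_ledger, manifest)

    def run(self) -> AuditResult:
        self.stage_ingest()
        self.stage_filter()
        self.stage_burden()
        self.stage_stats()
        self.stage_recat()
        return self.write_outputs()


def run_audit(config: RunConfig) -> AuditResult:
    """Run the full pipeline: ingest -> BA1 filter -> burden -> statistics ->
    recategorization; deterministic for a fixed config and inputs."""
    return Audit(config).run()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_star_overrides(path) -> Optional[dict[VariantKey, int]]:
    if path is None:
        return None
    out: dict[VariantKey, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            key_s, stars = line.rstrip("\n").split("\t")
            out[VariantKey.parse(key_s)] = int(stars)
    return out


def _digest(path) -> Optional[str]:
    if path is None:
        return None
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_stats_tsv(skew, ledger, path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tyear\tscope\tmethod\tp\todds_ratio\tci_low\tci_high\t"
                 "significant\n")
        threshold = ledger.threshold(0.05)
        for (set_name, year), res in sorted(skew.items()):
            om = res.omnibus
            fh.write(f"{set_name}\t{year}\tomnibus\t{om.method}\t"
                     f"{om.p_value:.6g}\t\t\t\t"
                     f"{int(om.p_value < threshold)}\n")
            for anc, fr in res.followups:
                orr = "inf" if math.isinf(fr.odds_ratio) else f"{fr.odds_ratio:.4g}"
                hi = "inf" if math.isinf(fr.ci_high) else f"{fr.ci_high:.4g}"
                fh.write(f"{set_name}\t{year}\t{anc}\t{fr.method}\t"
                         f"{fr.p_value:.6g}\t{orr}\t{fr.ci_low:.4g}\t{hi}\t"
                         f"{int(fr.p_value < threshold)}\n")
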