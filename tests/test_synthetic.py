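"""Generator contracts: determinism, planted ground truth, file dialects."""
import datetime as dt
import itertools

import pytest

from varaudit import (
    VariantKey,
    gen_cohort,
    gen_frequency_table,
    gen_panel,
    gen_snapshot_series,
)
from varaudit.core import GNOMAD_V2_EXOME_N, KGP_COMPOSITION
from varaudit.frequencies import apply_ba1_2018, assign_ancestry, floor_mafs, compute_maf_floor
from varaudit.ingest import build_timelines, read_snapshot_hgmd, read_snapshot_vcf
from varaudit.recat import build_monthly_series, extract_all_events

SIZES = {"AFR": 12, "AMR": 8, "EAS": 8, "EUR": 10, "SAS": 8}


class TestPanel:
    def test_count_conservation(self):
        panel = gen_panel(0, 1, seed=7)
        assert len(panel) == 1 and panel.genes[0].chrom == "chrX"
        panel = gen_panel(5, 2, seed=1)
        assert len(panel.autosomal) == 5 and len(panel.xlinked) == 2

    def test_seed_determinism_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        gen_panel(5, 2, seed=1).write_tsv(p1)
        gen_panel(5, 2, seed=1).write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_intervals_do_not_overlap(self):
        genes = list(gen_panel(3, 0, seed=3))
        assert len(genes) == 3
        for a, b in itertools.combinations(genes, 2):
            if a.chrom == b.chrom:
                assert a.end < b.start or b.end < a.start

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty panel"):
            gen_panel(0, 0, seed=1)


class TestCohort:
    def test_sample_sheet_matches_cohort_composition(self, tmp_path):
        panel = gen_panel(2, 1, seed=1)
        res = gen_cohort(panel, KGP_COMPOSITION, [], seed=2, out_dir=tmp_path,
                         variants_per_gene=2)
        rows = res.sample_sheet_path.read_text().splitlines()[1:]
        counts = {}
        for row in rows:
            anc = row.split("\t")[2]
            counts[anc] = counts.get(anc, 0) + 1
        assert counts == KGP_COMPOSITION  # 661/347/504/503/489 split

    def test_determinism(self, tmp_path):
        panel = gen_panel(2, 1, seed=1)
        r1 = gen_cohort(panel, SIZES, [("hom", "AFR")], seed=5,
                        out_dir=tmp_path / "a")
        r2 = gen_cohort(panel, SIZES, [("hom", "AFR")], seed=5,
                        out_dir=tmp_path / "b")
        assert r1.vcf_path.read_bytes() == r2.vcf_path.read_bytes()
        assert r1.sample_sheet_path.read_bytes() == r2.sample_sheet_path.read_bytes()

    def test_comphet_plant_found_by_haplotype_scan(self, tmp_path):
        """Brute-force scan of the emitted VCF text: exactly the planted
        sample carries two same-gene variants on opposite haplotypes."""
        panel = gen_panel(2, 1, seed=1)
        res = gen_cohort(panel, SIZES, [("comphet", "AFR")], seed=9,
                         out_dir=tmp_path)
        header, records = None, []
        for line in res.vcf_path.read_text().splitlines():
            if line.startswith("#CHROM"):
                header = line.split("\t")
            elif not line.startswith("#"):
                records.append(line.split("\t"))
        samples = header[9:]
        gene_of = {}
        for g in panel:
            for rec in records:
                if rec[0] == g.chrom and g.start <= int(rec[1]) <= g.end:
                    gene_of[(rec[0], rec[1])] = g.name
        comphet_samples = set()
        for si, sample in enumerate(samples):
            per_gene = {}
            for rec in records:
                gt = rec[9 + si]
                if "|" in gt:
                    a = tuple(int(x) for x in gt.split("|"))
                    if sum(a) == 1:
                        per_gene.setdefault(gene_of[(rec[0], rec[1])], []).append(a)
            for gene, hets in per_gene.items():
                if any(x[0] != y[0] for x, y in itertools.combinations(hets, 2)):
                    comphet_samples.add(sample)
        planted = res.ledger.planted_affected[0]
        assert planted.mechanism == "comphet"
        assert comphet_samples == {planted.sample}

    def test_hemi_plant_requires_xlinked_gene(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        with pytest.raises(ValueError, match="X-linked"):
            gen_cohort(panel, SIZES, [("hemi", "EUR")], seed=1,
                       out_dir=tmp_path)

    def test_hemi_plant_is_male_with_alt(self, tmp_path):
        panel = gen_panel(1, 1, seed=1)
        res = gen_cohort(panel, SIZES, [("hemi", "SAS")], seed=3,
                         out_dir=tmp_path)
        planted = res.ledger.planted_affected[0]
        sheet = {r.split("\t")[0]: r.split("\t")[1]
                 for r in res.sample_sheet_path.read_text().splitlines()[1:]}
        assert sheet[planted.sample] == "male"
        assert planted.gene.startswith("GENE_X")


class TestSnapshots:
    DATES = [dt.date(2016, 3, 1), dt.date(2017, 3, 1), dt.date(2018, 3, 1)]

    def _events(self, files, database):
        snaps = []
        for date, path, dialect in files:
            if dialect == "hgmd":
                snaps.append((date, read_snapshot_hgmd(path, date)))
            else:
                snaps.append((date, read_snapshot_vcf(path, date, dialect)))
        timelines = build_timelines(snaps, database)
        return extract_all_events(build_monthly_series(timelines).values())

    def test_no_planted_transitions_no_events(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        series = gen_snapshot_series(panel, self.DATES, [], "archive2", 4,
                                     tmp_path)
        assert self._events(series.files, "clinvar") == []

    def test_planted_clinvar_transition_recovered(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        key = "chr1:1060000:A:G"
        series = gen_snapshot_series(
            panel, self.DATES, [(key, "2017-01-01", "P/LP 1*", "Conflicting")],
            "archive2", 4, tmp_path)
        events = self._events(series.files, "clinvar")
        assert len(events) == 1
        e = events[0]
        assert str(e.key) == key
        assert (e.from_category, e.to_category) == ("P/LP 1*", "Conflicting")
        assert e.confidence_change == "decreasing"
        (ledgered,) = series.ledger.planted_recats
        assert ledgered.date == e.date.isoformat()

    def test_planted_hgmd_transition_recovered(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        key = "chr1:1060000:A:G"
        series = gen_snapshot_series(
            panel, self.DATES, [(key, "2017-01-01", "DM", "DM?")],
            "hgmd", 4, tmp_path)
        events = self._events(series.files, "hgmd")
        assert [(str(e.key), e.from_category, e.to_category, e.direction)
                for e in events] == [(key, "DM", "DM?", "toward_benign")]

    def test_transition_outside_series_rejected(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        with pytest.raises(ValueError, match="outside the series"):
            gen_snapshot_series(
                panel, self.DATES,
                [("chr1:1060000:A:G", "2021-01-01", "DM", "DM?")],
                "hgmd", 4, tmp_path)

    def test_archive1_after_cutover_rejected(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        with pytest.raises(ValueError, match="cutover"):
            gen_snapshot_series(panel, self.DATES, [], "archive1", 4, tmp_path)

    def test_determinism(self, tmp_path):
        panel = gen_panel(2, 0, seed=1)
        s1 = gen_snapshot_series(panel, self.DATES, [], "archive2", 4,
                                 tmp_path / "a")
        s2 = gen_snapshot_series(panel, self.DATES, [], "archive2", 4,
                                 tmp_path / "b")
        for (d1, p1, _), (d2, p2, _) in zip(s1.files, s2.files):
            assert p1.read_bytes() == p2.read_bytes()


class TestFrequencies:
    KEYS = [VariantKey("chr1", 1_050_000 + i, "A", "G") for i in range(30)]

    def test_global_is_weighted_mean(self):
        table, _ = gen_frequency_table(self.KEYS, dict(GNOMAD_V2_EXOME_N),
                                       [], seed=6)
        total = sum(GNOMAD_V2_EXOME_N.values())
        for key in self.KEYS:
            pops = table.get_populations(key, "gnomad")
            expected = sum(m * GNOMAD_V2_EXOME_N[a] for a, m in pops.items()) / total
            assert abs(table.get_global(key, "gnomad") - expected) < 1e-12

    def test_equal_population_maf_gives_global_maf(self):
        m = 0.013
        table, _ = gen_frequency_table(
            [self.KEYS[0]], dict(GNOMAD_V2_EXOME_N),
            [(str(self.KEYS[0]), a, m) for a in GNOMAD_V2_EXOME_N], seed=6)
        assert table.get_global(self.KEYS[0], "gnomad") == pytest.approx(m, abs=1e-15)

    def test_planted_common_removed_by_ba1_2018(self):
        key = self.KEYS[0]
        table, ledger = gen_frequency_table(
            self.KEYS, dict(GNOMAD_V2_EXOME_N),
            [(str(key), "AFR", 0.20)], seed=6)
        kept, removed = apply_ba1_2018(self.KEYS, table)
        assert key in {r.key for r in removed}
        assert str(key) in {p.key for p in ledger.planted_ba1}

    def test_all_zero_variant_gets_no_ancestry(self):
        key = self.KEYS[0]
        table, _ = gen_frequency_table(
            [key], dict(GNOMAD_V2_EXOME_N),
            [(str(key), a, 0.0) for a in GNOMAD_V2_EXOME_N], seed=6,
            zero_fraction=1.0)
        floored = floor_mafs(table, compute_maf_floor(GNOMAD_V2_EXOME_N))
        assert assign_ancestry(floored, "gnomad")[key].ancestry is None

    def test_unknown_ancestry_rejected(self):
        with pytest.raises(ValueError, match="ancestry"):
            gen_frequency_table(self.KEYS, {"MARS": 10}, [], seed=1)
        with pytest.raises(ValueError, match="ancestry"):
            gen_frequency_table(self.KEYS, dict(GNOMAD_V2_EXOME_N),
                                [(str(self.KEYS[0]), "MARS", 0.1)], seed=1)
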