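"""Snapshot harmonization: normalization, label maps, timelines, variant sets."""
import datetime as dt
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from oracle_utils import apply_variant, minimal_representation
from varaudit import (
    VariantKey,
    infer_conflicting,
    map_archive1_class,
    map_archive2_class,
    map_hgmd_class,
    map_review_stars,
    normalize_variant,
    select_variant_set,
)
from varaudit.ingest import (
    SnapshotEntry,
    read_snapshot_vcf,
    read_timelines_tsv,
    write_timelines_tsv,
    build_timelines,
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_snv_passthrough(self):
        key = normalize_variant("chr1", 100, "A", "G", "A", context_start=100)
        assert key == VariantKey("chr1", 100, "A", "G")

    def test_left_align_deletion(self):
        # context GCATTT at positions 1-6; deleting one T of the TT run at
        # position 5 left-aligns to the start of the homopolymer
        key = normalize_variant("chr1", 5, "TT", "T", "GCATTT", context_start=1)
        assert (key.pos, key.ref, key.alt) == (3, "AT", "A")

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="reference mismatch"):
            normalize_variant("chr1", 2, "GG", "G", "GCATTT", context_start=1)

    @given(
        context=st.text(alphabet="ACGT", min_size=8, max_size=16),
        pos0=st.integers(0, 7),
        ref_len=st.integers(1, 4),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_bruteforce_minimal_representation(self, context, pos0,
                                                       ref_len, alt, data):
        """The output equals the enumeration oracle's minimal representation."""
        if pos0 + ref_len > len(context):
            ref_len = len(context) - pos0
        ref = context[pos0:pos0 + ref_len]
        if ref == alt or not ref:
            return
        # anchor edits that would need left context beyond the window
        if pos0 == 0 and (ref[0] != alt[0] and (len(ref) > 1 or len(alt) > 1)):
            return
        key = normalize_variant("chr1", pos0 + 1, ref, alt, context)
        # same edit
        assert apply_variant(context, key.pos, key.ref, key.alt) \
            == apply_variant(context, pos0 + 1, ref, alt)
        # minimal and leftmost per the oracle
        exp_pos, exp_ref, exp_alt = minimal_representation(
            context, pos0 + 1, ref, alt)
        assert (key.pos, key.ref, key.alt) == (exp_pos, exp_ref, exp_alt)
        # idempotence
        again = normalize_variant("chr1", key.pos, key.ref, key.alt, context)
        assert again == key


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("code,expected", [
    ("5", "P"), ("4", "LP"), ("3", "LB"), ("2", "B"), ("0", "VUS"),
    ("9", None), ("x", None),
])
def test_archive1_codes(code, expected):
    assert map_archive1_class(code) == expected


@pytest.mark.parametrize("label,expected", [
    ("Pathogenic", "P"),
    ("Pathogenic/Likely_pathogenic", "P"),
    ("Likely_pathogenic", "LP"),
    ("Benign/Likely_benign", "B"),
    ("Conflicting_interpretations_of_pathogenicity", "Conflicting"),
    ("Pathogenic,_risk_factor", "P"),
    ("Uncertain_significance,_other", "VUS"),
    ("Pathogenic,Benign", None),      # two listed components
    ("risk_factor", None),
])
def test_archive2_labels(label, expected):
    assert map_archive2_class(label) == expected


def test_conflicting_inference_enumerated_against_rule():
    """All 15 non-empty subsets of {B, LB, VUS, LP, P} agree with the
    two-or-more-groups rule."""
    universe = ["B", "LB", "VUS", "LP", "P"]
    for r in range(1, 6):
        for subset in itertools.combinations(universe, r):
            groups = {g for g, members in
                      (("blb", {"B", "LB"}), ("vus", {"VUS"}), ("plp", {"P", "LP"}))
                      if set(subset) & members}
            got = infer_conflicting(set(subset))
            if len(groups) >= 2:
                assert got == "Conflicting", subset
            else:
                assert got in subset and got != "Conflicting", subset


def test_conflicting_empty_set_rejected():
    with pytest.raises(ValueError):
        infer_conflicting(set())


@pytest.mark.parametrize("status,archive,expected", [
    ("criteria_provided,_single_submitter", 2, 1),
    ("reviewed_by_expert_panel", 2, 2),
    ("criteria_provided,_multiple_submitters,_no_conflicts", 2, 2),
    ("criteria_provided,_conflicting_interpretations", 2, 1),
    ("no_assertion_provided", 1, 0),
    ("single", 1, 1),
    ("mult", 1, 2),
    ("gibberish_status", 2, 0),
])
def test_review_star_grouping(status, archive, expected):
    assert map_review_stars(status, archive) == expected


def test_hgmd_severity_tie_break_all_pairs():
    """Every pair resolves to the more severe label under DM > DM? > DFP > DP > R."""
    order = ["R", "DP", "DFP", "DM?", "DM"]
    for a, b in itertools.product(order, repeat=2):
        expected = a if order.index(a) >= order.index(b) else b
        assert map_hgmd_class([a, b]) == expected
    assert map_hgmd_class(["DM?"]) == "DM?"
    assert map_hgmd_class(["bogus"]) is None


# ---------------------------------------------------------------------------
# variant sets
# ---------------------------------------------------------------------------

def _entry(clazz, stars=None):
    return SnapshotEntry(clazz=clazz, stars=stars)


@pytest.fixture
def snapshot():
    keys = [VariantKey("chr1", 100 + i, "A", "G") for i in range(6)]
    return dict(zip(keys, [
        _entry("P", 1),            # select + full
        _entry("P", 0),            # full only (star threshold)
        _entry("LP", 2),           # full only (class is LP)
        _entry("Conflicting", None),  # excluded everywhere
        _entry("VUS", None),
        _entry("B", 2),
    ])), keys


def test_clinvar_set_definitions(snapshot):
    entries, keys = snapshot
    select = select_variant_set(entries, "select_clinvar")
    full = select_variant_set(entries, "full_clinvar")
    assert select == {keys[0]}
    assert full == {keys[0], keys[1], keys[2]}
    assert select <= full


def test_hgmd_set_definitions():
    keys = [VariantKey("chr1", 100 + i, "A", "G") for i in range(3)]
    entries = dict(zip(keys, [_entry("DM"), _entry("DM?"), _entry("DFP")]))
    select = select_variant_set(entries, "select_hgmd")
    full = select_variant_set(entries, "full_hgmd")
    assert select == {keys[0]}
    assert full == {keys[0], keys[1]}
    assert select <= full


def test_star_override_promotes_into_select(snapshot):
    entries, keys = snapshot
    select = select_variant_set(entries, "select_clinvar",
                                star_overrides={keys[1]: 1})
    assert keys[1] in select


def test_unknown_set_name(snapshot):
    with pytest.raises(ValueError):
        select_variant_set(snapshot[0], "all_of_them")


# ---------------------------------------------------------------------------
# snapshot VCF parsing
# ---------------------------------------------------------------------------

SNAPSHOT_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=CLNSIG,Number=.,Type=String,Description="sig">
##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="rev">
##INFO=<ID=CLNDN,Number=.,Type=String,Description="cond">
##INFO=<ID=ORIGIN,Number=.,Type=String,Description="origin">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\t.\tA\tG\t.\tPASS\tCLNSIG=Pathogenic;CLNREVSTAT=criteria_provided,_single_submitter;CLNDN=not_provided
chr1\t200\t.\tC\tT\t.\tPASS\tCLNSIG=Pathogenic;CLNREVSTAT=criteria_provided;ORIGIN=somatic
chr1\t300\t.\tG\t.\t.\tPASS\tCLNSIG=Benign
chr1\t400\t.\tT\tA,C\t.\tPASS\tCLNSIG=Uncertain_significance;CLNDN=schizophrenia
"""


def test_snapshot_vcf_parsing_drops_somatic_and_null_alt(tmp_path):
    path = tmp_path / "snap.vcf"
    path.write_text(SNAPSHOT_VCF)
    entries = read_snapshot_vcf(path, dt.date(2018, 1, 1), "archive2")
    keys = {str(k): e for k, e in entries.items()}
    assert "chr1:200:C:T" not in keys          # somatic-only
    assert not any(k.startswith("chr1:300") for k in keys)  # null alt
    assert keys["chr1:100:A:G"].clazz == "P"
    assert keys["chr1:100:A:G"].stars == 1
    # multiallelic split into biallelic keys
    assert "chr1:400:T:A" in keys and "chr1:400:T:C" in keys
    assert keys["chr1:400:T:A"].condition == "schizophrenia"


def test_timeline_roundtrip(tmp_path):
    d1, d2 = dt.date(2016, 1, 1), dt.date(2017, 1, 1)
    key = VariantKey("chr1", 100, "A", "G")
    snaps = [(d1, {key: _entry("P", 1)}), (d2, {key: _entry("Conflicting")})]
    timelines = build_timelines(snaps, "clinvar")
    path = tmp_path / "timelines.tsv"
    write_timelines_tsv(timelines, path)
    back = read_timelines_tsv(path)
    assert back.keys() == timelines.keys()
    assert back[key].entries == timelines[key].entries
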