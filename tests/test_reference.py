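"""Reference bundle: loading, spot queries, layering and the audit."""
import shutil
from collections import Counter

import pytest

from aphidkey import (Interval, load_reference, query_range, save_reference,
                      validate_dataset)
from aphidkey.reference import DATA_FILES, LoadError, LookupError_, \
    default_data_path


def test_profile_census_matches_the_printed_tables(ds):
    by_morph = Counter(p.morph for p in ds.profiles.values())
    canadensis = [p for p in ds.profiles.values() if p.taxon == "canadensis"]
    assert by_morph == {"fundatrix": 5, "aptera": 10, "alata": 7,
                       "ovipara": 6, "male": 6}
    assert len(canadensis) == 4  # its own table covers all four morphs


@pytest.mark.parametrize("taxon,morph,cid,expected", [
    ("oezdemirae", "ovipara", "PSEUDOSENSORIA", (61, 80)),
    ("canadensis", "male", "RHIN_ANT_III", (21, 21)),
    ("bucktoni", "fundatrix", "BL", (2.10, 2.60)),
    ("rosarum", "aptera", "URS", (0.047, 0.10)),
    ("turanica", "ovipara", "PSEUDOSENSORIA", (7, 20)),
    ("avariolosa", "aptera", "CAUDA_SETAE", (4, 4)),
])
def test_query_range_returns_printed_values(ds, taxon, morph, cid, expected):
    interval = query_range(ds, taxon, morph, cid)
    assert isinstance(interval, Interval)
    assert (interval.lo, interval.hi) == pytest.approx(expected)


def test_query_range_states_and_errors(ds):
    assert query_range(ds, "oezdemirae", "ovipara",
                       "TIBIA_III_SWELLING") == "swollen"
    with pytest.raises(LookupError_, match="no alata profile"):
        query_range(ds, "tuatayae", "alata", "BL")
    with pytest.raises(LookupError_, match="unknown taxon"):
        query_range(ds, "nonexistens", "aptera", "BL")
    with pytest.raises(LookupError_, match="unknown character"):
        query_range(ds, "rosarum", "aptera", "NOT_A_CHARACTER")
    with pytest.raises(LookupError_, match="not recorded"):
        query_range(ds, "rosarum", "fundatrix", "PSEUDOSENSORIA")


def test_missing_bundle_is_a_load_error(tmp_path):
    with pytest.raises(LoadError, match="not found"):
        load_reference(tmp_path / "nowhere")
    (tmp_path / "empty").mkdir()
    with pytest.raises(LoadError):
        load_reference(tmp_path / "empty")


def test_duplicate_profile_entry_is_named_in_the_load_error(tmp_path):
    bundle = tmp_path / "bundle"
    shutil.copytree(default_data_path(), bundle)
    with open(bundle / "table1.csv", "a") as fh:
        fh.write("bucktoni,fundatrix,BL,2.10,2.60,T1,2.10–2.60\n")
    with pytest.raises(LoadError, match="duplicate.*bucktoni.*BL"):
        load_reference(bundle)


def test_writer_loader_round_trip_is_byte_identical(ds, tmp_path):
    save_reference(ds, tmp_path)
    src = default_data_path()
    for name in DATA_FILES:
        assert (tmp_path / name).read_bytes() == (src / name).read_bytes(), name


def test_as_printed_strings_carry_the_printed_endpoints(ds_printed):
    # spot the verbatim anomalies with en-dash preserved
    p = ds_printed.profiles["tuatayae/aptera"]
    assert p.entries["ANT_IV"].as_printed == "0.08–1.10"
    assert ds_printed.profiles["bucktoni/aptera"].entries["GPW"].as_printed \
        == "0.3–0.20"


def test_audit_flags_the_printed_anomalies(ds_printed):
    findings = validate_dataset(ds_printed)
    errors = [f for f in findings if f.severity == "error"]
    assert len(errors) >= 2
    tagged = {(f.taxon, f.morph, f.character_id) for f in errors}
    assert ("tuatayae", "aptera", "ANT_IV") in tagged     # part > whole
    assert ("bucktoni", "aptera", "GPW") in tagged        # inverted interval
    # ordering is deterministic
    keys_seq = [(f.taxon, f.morph, f.character_id) for f in findings]
    assert keys_seq == sorted(keys_seq)


def test_curated_layer_audits_clean(ds):
    findings = validate_dataset(ds)
    assert [f for f in findings if f.severity == "error"] == []
    # the curated layer still flags every override it applied
    assert any("curated override" in f.message for f in findings)


def test_constructed_inverted_interval_is_an_error(ds):
    import copy
    broken = copy.deepcopy(ds)
    entry = broken.profiles["rosarum/aptera"].entries["BL"]
    broken.profiles["rosarum/aptera"].entries["BL"] = entry.model_copy(
        update={"lo": 2.0, "hi": 1.0})
    errors = [f for f in validate_dataset(broken) if f.severity == "error"]
    assert any(f.character_id == "BL" and f.taxon == "rosarum" for f in errors)
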