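"""Synthetic specimens: containment, ratio constraints, determinism,
corruption, and joint-satisfiability of the bundled profiles."""
import pytest

from aphidkey import (GeneratorConfig, Specimen, check_satisfiability,
                      corrupt, generate, ratio_closure)
from aphidkey.characters import CharacterKind
from aphidkey.simulate import GenerationError


def test_zero_specimens_requested(ds):
    cfg = GeneratorConfig(taxon="rosarum", morph="aptera", n=0, seed=1)
    specimens, report = generate(cfg, ds)
    assert specimens == []
    assert report.rejection_rate == 0.0


def test_table_only_values_are_fully_contained(ds):
    cfg = GeneratorConfig(taxon="rosarum", morph="aptera", n=100, seed=1,
                          mode="table_only")
    specimens, _ = generate(cfg, ds)
    profile = ds.profiles["rosarum/aptera"]
    assert len(specimens) == 100
    for spec in specimens:
        for cid, value in list(spec.linear.items()) + list(spec.counts.items()):
            if cid in profile.entries:
                entry = profile.entries[cid]
                assert entry.lo <= value <= entry.hi, (cid, value)
        for cid, value in spec.counts.items():
            assert value == int(value)
        assert spec.states.get("FRONTAL_TUBERCLE") == "quadrate"


def test_ratio_constrained_bucktoni_fundatrix_siph_cauda(ds):
    cfg = GeneratorConfig(taxon="bucktoni", morph="fundatrix", n=50, seed=3,
                          mode="ratio_constrained")
    specimens, _ = generate(cfg, ds)
    for spec in specimens:
        full = ratio_closure(spec, ds.registry)
        assert 1.43 <= full.derived["SIPH_CAUDA"] <= 1.51


def test_same_seed_means_identical_output(ds):
    cfg = GeneratorConfig(taxon="turanica", morph="ovipara", n=10, seed=9,
                          mode="ratio_constrained")
    a, _ = generate(cfg, ds)
    b, _ = generate(cfg, ds)
    assert [s.model_dump() for s in a] == [s.model_dump() for s in b]
    c, _ = generate(cfg.model_copy(update={"seed": 10}), ds)
    assert [s.model_dump() for s in a] != [s.model_dump() for s in c]


def test_truncated_normal_stays_inside_the_intervals(ds):
    cfg = GeneratorConfig(taxon="rosarum", morph="aptera", n=40, seed=5,
                          mode="table_only", distribution="truncated_normal",
                          sd_fraction=0.3)
    specimens, _ = generate(cfg, ds)
    profile = ds.profiles["rosarum/aptera"]
    for spec in specimens:
        for cid, value in spec.linear.items():
            if cid in profile.entries:
                e = profile.entries[cid]
                assert e.lo <= value <= e.hi


def test_every_bundled_profile_is_jointly_satisfiable(ds):
    # the dataset health check the generator exposes
    for profile in ds.profiles.values():
        ok, message = check_satisfiability(ds, profile.taxon, profile.morph,
                                           seed=1, n=3)
        assert ok, (profile.taxon, profile.morph, message)


def test_bd_iii_interval_is_derived_and_logged(ds):
    cfg = GeneratorConfig(taxon="tianshanica", morph="aptera", n=5, seed=2,
                          mode="ratio_constrained")
    specimens, report = generate(cfg, ds)
    assert "BD_III" in report.derived_intervals
    lo, hi = report.derived_intervals["BD_III"]
    assert 0 < lo < hi < 0.05
    for spec in specimens:
        # derived seta characters respect the printed ratio bands
        full = ratio_closure(spec, ds.registry)
        assert 3.40 <= full.derived["HLS_BD_III"] <= 3.63
        assert 0.54 <= full.derived["LS_III_BD_III"] <= 0.68


def test_unsatisfiable_constraints_report_the_binding_constraint(ds):
    import copy
    broken = copy.deepcopy(ds)
    prof = broken.profiles["rosarum/aptera"]
    prof.entries["SIPH_CAUDA"] = prof.entries["SIPH_CAUDA"].model_copy(
        update={"lo": 9.0, "hi": 9.5})
    cfg = GeneratorConfig(taxon="rosarum", morph="aptera", n=2, seed=1,
                          mode="ratio_constrained", max_rejections=50)
    with pytest.raises(GenerationError):
        generate(cfg, broken)


def _specimens(ds, n=5):
    cfg = GeneratorConfig(taxon="rosarum", morph="aptera", n=n, seed=21)
    return generate(cfg, ds)[0]


def test_corrupt_identity_and_total_masking(ds):
    specs = _specimens(ds)
    same = corrupt(specs, 0.0, 0.0, seed=1)
    assert [s.linear for s in same] == [s.linear for s in specs]
    assert [s.states for s in same] == [s.states for s in specs]
    gone = corrupt(specs, 1.0, 0.0, seed=1)
    for s in gone:
        assert not s.linear and not s.counts and not s.states


def test_corrupt_is_reproducible_and_seed_sensitive(ds):
    specs = _specimens(ds)
    a = corrupt(specs, 0.4, 0.3, seed=7)
    b = corrupt(specs, 0.4, 0.3, seed=7)
    c = corrupt(specs, 0.4, 0.3, seed=8)
    assert [s.model_dump() for s in a] == [s.model_dump() for s in b]
    assert [s.model_dump() for s in a] != [s.model_dump() for s in c]


def test_corrupt_rejects_bad_fractions(ds):
    with pytest.raises(ValueError):
        corrupt(_specimens(ds, 1), -0.1, 0.0, seed=1)
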