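"""Key engine: structure validation, lead evaluation, traversal, key audit."""
import pytest

from aphidkey import Specimen, audit_key, evaluate_lead, ratio_closure, traverse
from aphidkey.keys import (Couplet, Key, KeyDefinitionError, Lead, Predicate,
                           ScopeError, path_status, validate_key)


def pred(cid, **kw):
    return Predicate(character_id=cid, **kw)


def test_bundled_key_terminal_counts(keys):
    expected = {"fundatrix": 5, "apterae": 8, "alatae": 6, "oviparae": 5,
                "males": 5, "genera_222": 9}
    assert {k: len(key.terminals()) for k, key in keys.items()} == expected


def test_structural_validation_rejects_cycles_and_unreachables(ds):
    leaf = Lead(predicates=[pred("BL", op="in", lo=0, hi=1)], taxon="rosarum")
    back = Lead(predicates=[pred("BL", op="in", lo=1, hi=2)], next="1")
    cyclic = Key(id="k", name="k", morph="aptera", root="1",
                 couplets={"1": Couplet(a=leaf, b=back)})
    with pytest.raises(KeyDefinitionError, match="cycle"):
        validate_key(cyclic, ds.registry)
    orphan = Key(id="k", name="k", morph="aptera", root="1",
                 couplets={"1": Couplet(a=leaf, b=leaf),
                           "9": Couplet(a=leaf, b=leaf)})
    with pytest.raises(KeyDefinitionError, match="unreachable"):
        validate_key(orphan, ds.registry)
    bad_terminal = Key(id="k", name="k", morph="aptera", root="1",
                       couplets={"1": Couplet(a=leaf, b=Lead(
                           predicates=[pred("BL", op="in", lo=1, hi=2)],
                           taxon="martian"))})
    with pytest.raises(KeyDefinitionError, match="martian"):
        validate_key(bad_terminal, ds.registry, known_terminals={"rosarum"})
    with pytest.raises(KeyDefinitionError, match="unregistered"):
        validate_key(Key(id="k", name="k", morph="aptera", root="1",
                         couplets={"1": Couplet(a=Lead(
                             predicates=[pred("NOPE", op="ge", lo=1)],
                             taxon="rosarum"), b=leaf)}),
                     ds.registry)


def test_evaluate_lead_verdicts(ds, keys):
    lead3a = keys["apterae"].couplets["3"].a  # long pointed dorsal setae
    spec = ratio_closure(Specimen(id="x", morph="aptera",
                                  linear={"DORSAL_SETA_ABD": 0.07},
                                  states={"DORSAL_SETA_FORM": "long-pointed"}),
                         ds.registry)
    assert evaluate_lead(spec, lead3a) is True
    # missing SIPH -> SIPH/CAUDA unknown
    lead = Lead(predicates=[pred("SIPH_CAUDA", op="le", hi=1.96)],
                taxon="rosarum")
    spec2 = ratio_closure(Specimen(id="y", morph="fundatrix",
                                   linear={"CAUDA": 0.2}), ds.registry)
    assert evaluate_lead(spec2, lead) is None
    # outside an "or more" bound -> false
    lead_ge = Lead(predicates=[pred("PT_BASE", op="ge", lo=0.88)],
                   taxon="rosarum")
    spec3 = ratio_closure(Specimen(id="z", morph="fundatrix",
                                   linear={"PT": 0.04, "BASE": 0.08}),
                          ds.registry)
    assert evaluate_lead(spec3, lead_ge) is False
    # boundary value satisfies a closed predicate interval
    spec4 = ratio_closure(Specimen(id="w", morph="fundatrix",
                                   linear={"PT": 0.22, "BASE": 0.25}),
                          ds.registry)
    assert evaluate_lead(spec4, lead_ge) is True


def test_traversal_of_an_unambiguous_specimen(ds, keys):
    from aphidkey import midpoint_specimen
    mid = midpoint_specimen(ds.profiles["tianshanica/aptera"], ds)
    res = traverse(ratio_closure(mid, ds.registry), keys["apterae"])
    assert res.terminals == ["tianshanica"]
    assert ("1", "b") in res.trace and ("3", "a") in res.trace


def test_rhinaria_route_out_of_the_genus_key(ds, keys):
    spec = Specimen(id="g", morph="aptera", counts={"RHIN_ANT_III": 5})
    res = traverse(spec, keys["genera_222"])
    assert res.terminals == ["Hydaphias"]
    assert res.trace[0] == ("1", "a")


def test_total_ignorance_returns_every_terminal(ds, keys):
    empty = Specimen(id="e", morph="aptera")
    for kid in ("apterae", "genera_222"):
        res = traverse(empty, keys[kid])
        assert res.terminals == sorted(set(keys[kid].terminals()))
        assert all(v == "both" for _, v in res.trace)


def test_morph_scope_is_enforced(ds, keys):
    spec = Specimen(id="m", morph="male")
    with pytest.raises(ScopeError, match="male"):
        traverse(spec, keys["apterae"])
    traverse(spec, keys["apterae"], check_scope=False)  # flag disables it


def test_apterae_key_audit_tianshanica_path_fully_holds(ds, keys):
    assert set(path_status(keys["apterae"], ds, "tianshanica")) == {"holds"}


def test_genus_key_audit_richardsaphis_path_fully_holds(ds, keys):
    assert set(path_status(keys["genera_222"], ds, "Richardsaphis")) == {"holds"}


def test_fundatrix_key_about_band_vs_rezwanii_profile_is_partial(ds, keys):
    # "PT/BASE about 0.66" -> [0.627, 0.693]; the profile prints 0.66-0.83
    findings = audit_key(keys["fundatrix"], ds)
    assert any(f.taxon == "rezwanii" and f.character_id == "PT_BASE"
               and "partial" in f.message for f in findings)


def test_unsatisfiable_fixture_lead_fails_for_every_taxon(ds):
    key = Key(id="impossible", name="t", morph="aptera", root="1",
              couplets={"1": Couplet(
                  a=Lead(predicates=[pred("BL", op="in", lo=0, hi=0.01)],
                         taxon="rosarum"),
                  b=Lead(predicates=[pred("BL", op="in", lo=0, hi=0.01)],
                         taxon="turanica"))})
    findings = audit_key(key, ds)
    assert {f.taxon for f in findings if f.severity == "error"} \
        == {"rosarum", "turanica"}


def test_as_printed_alatae_key_contradicts_the_bucktoni_description(ds, keys):
    """Couplet 5 prints ANT IV/ANT III 1.00-1.45 for bucktoni although its
    own description (and couplet 4) give 0.33-0.46; the as-printed bounds
    must fail the audit while the curated override reconciles them."""
    printed = path_status(keys["alatae"], __import__("aphidkey").load_reference(
        layer="as_printed"), "bucktoni")
    assert "fails" in printed
    curated = path_status(keys["alatae"], ds, "bucktoni")
    assert "fails" not in curated
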