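"""Name matching, the misspelling/synonym review lists, and standardization."""

import pytest

from occurclean.datamodel import AuditLog, OccurrenceRecord, TaxonName
from occurclean.synth import FixtureSpec, make_backbone, make_fixture
from occurclean.taxonomy import (
    Backbone,
    BackboneEntry,
    ResolvedAction,
    Status,
    apply_standardization,
    build_misspelling_list,
    build_synonym_list,
    match_name,
    match_names,
)


@pytest.fixture(scope="module")
def backbone():
    return Backbone(
        [
            BackboneEntry("a1", "Acacia adenocalyx", "species", Status.accepted, "a1"),
            BackboneEntry("a2", "Acacia senegal", "species", Status.accepted, "a2"),
            BackboneEntry("s1", "Acacia circummarginata", "species", Status.synonym, "a1"),
            BackboneEntry("a3", "Albizia grandibracteata", "species", Status.accepted, "a3"),
        ]
    )


def edit_similarity_oracle(a: str, b: str) -> float:
    """Independent Wagner-Fischer edit distance, normalized."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return 1.0 - prev[n] / max(m, n)


def test_exact_match_scores_one(backbone):
    m = match_name("Acacia adenocalyx", backbone)
    assert m.overall_score == 1.0 and m.matched.name_id == "a1" and not m.partial


def test_single_edit_misspelling_scores_below_one(backbone):
    m = match_name("Acacia adenocalix", backbone)
    assert m.matched.name == "Acacia adenocalyx"
    assert m.overall_score < 1.0 and not m.partial
    # score consistent with an independent edit-distance computation:
    # length-weighted mean of genus (exact) and epithet similarities
    se = edit_similarity_oracle("adenocalix", "adenocalyx")
    expected = (6 * 1.0 + 10 * se) / 16
    assert m.overall_score == pytest.approx(expected, abs=1e-9)


def test_genus_only_hit_is_partial(backbone):
    m = match_name("Acacia nonexistens", backbone)
    assert m.partial


def test_empty_submitted_name_is_hard_error(backbone):
    with pytest.raises(ValueError):
        match_name("   ", backbone)


def test_synonym_link_validation_rejects_bad_backbones():
    with pytest.raises(ValueError):
        Backbone([BackboneEntry("s1", "A b", "species", Status.synonym, "missing")])
    with pytest.raises(ValueError):
        Backbone([BackboneEntry("a1", "A b", "species", Status.accepted, "other")])


# --- the two lists ----------------------------------------------------------


def test_misspelling_list_rules(backbone):
    matches = match_names(
        ["Acacia adenocalyx", "Acacia adenocalix", "Acacia nonexistens"], backbone
    )
    mis = {m.submitted for m in build_misspelling_list(matches)}
    assert mis == {"Acacia adenocalix"}  # exact excluded, partial excluded


def test_synonym_list_rules(backbone):
    matches = match_names(
        [
            "Acacia circummarginata",   # exact hit on a synonym -> rule (i)
            "Acacia circummarginatta",  # misspelt synonym -> rule (ii)
            "Acacia adenocalyx",        # accepted submitted exactly -> excluded
        ],
        backbone,
    )
    syn = {m.submitted for m in build_synonym_list(matches)}
    assert syn == {"Acacia circummarginata", "Acacia circummarginatta"}


def test_lists_disjoint_from_exact_accepted_set(small_fixture):
    names = sorted(set(small_fixture.truth.used_name))
    matches = match_names(names, small_fixture.backbone)
    exact_accepted = {
        m.submitted
        for m in matches
        if m.overall_score == 1.0 and m.matched.status is Status.accepted
    }
    mis = {m.submitted for m in build_misspelling_list(matches)}
    syn = {m.submitted for m in build_synonym_list(matches)}
    assert not mis & exact_accepted and not syn & exact_accepted


def test_planted_misspellings_and_synonyms_recovered(small_fixture):
    truth = small_fixture.truth
    names = sorted(set(truth.used_name))
    matches = match_names(names, small_fixture.backbone)
    assert {m.submitted for m in build_misspelling_list(matches)} == set(
        truth[truth.name_error == "misspelling"].used_name
    )
    assert {m.submitted for m in build_synonym_list(matches)} == set(
        truth[truth.name_error == "synonym_use"].used_name
    )


# --- standardization --------------------------------------------------------


def _rec(rid, name):
    genus, _, epithet = name.partition(" ")
    return OccurrenceRecord(rid, taxon=TaxonName(genus=genus, species_epithet=epithet))


def test_synonym_decision_substitutes_accepted_name(backbone):
    recs = [_rec("r1", "Acacia circummarginata")]
    matches = match_names(["Acacia circummarginata"], backbone)
    out = apply_standardization(
        recs, matches, {"Acacia circummarginata": ResolvedAction.map_to_synonym_target}, backbone
    )
    assert out[0].taxon.canonical == "Acacia adenocalyx"


def test_excluded_name_dropped_and_audited(backbone):
    recs = [_rec("r1", "Acacia adenocalix"), _rec("r2", "Acacia senegal")]
    matches = match_names(["Acacia adenocalix", "Acacia senegal"], backbone)
    audit = AuditLog()
    out = apply_standardization(
        recs, matches, {"Acacia adenocalix": ResolvedAction.exclude}, backbone, audit=audit
    )
    assert [r.record_id for r in out] == ["r2"]
    assert audit.discarded_ids() == {"r1"}


def test_decision_for_unknown_name_is_hard_error(backbone):
    with pytest.raises(ValueError, match="unknown name"):
        apply_standardization([], [], {"Nomen dubium": ResolvedAction.exclude}, backbone)


def test_standardization_is_idempotent(backbone):
    recs = [_rec("r1", "Acacia circummarginata"), _rec("r2", "Acacia adenocalix")]
    names = ["Acacia circummarginata", "Acacia adenocalix"]
    matches = match_names(names, backbone)
    decisions = {
        "Acacia circummarginata": ResolvedAction.map_to_synonym_target,
        "Acacia adenocalix": ResolvedAction.correct_spelling,
    }
    once = apply_standardization(recs, matches, decisions, backbone)
    twice = apply_standardization(once, matches, decisions, backbone)
    assert once == twice
    assert all(r.taxon.canonical == "Acacia adenocalyx" for r in once)


def test_fixture_ground_truth_fully_recovered(small_fixture):
    """Applying mechanical decisions recovers every planted true name."""
    from occurclean.pipeline import auto_decisions

    truth = small_fixture.truth
    records = small_fixture.records
    names = sorted({r.taxon.canonical for r in records})
    matches = match_names(names, small_fixture.backbone)
    out = apply_standardization(records, matches, auto_decisions(matches), small_fixture.backbone)
    by_id = {r.record_id: r for r in out}
    for rid, row in truth.iterrows():
        assert by_id[rid].taxon.canonical == row.true_species
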