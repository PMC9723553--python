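"""Registry fidelity: every transcribed checklist row resolves correctly."""

import pytest

from mixs_sa.errors import (
    IdSyntaxError,
    PackageNotFoundError,
    RegistryDuplicateIdError,
    TermNotFoundError,
)
from mixs_sa.registry import (
    ENVIRONMENTAL_PACKAGES_PRE_SA,
    load_registry,
    serialize_registry,
)

# Independently transcribed checklist rows: display name, MIXS ID,
# requirement level in the term's home package, category.
CHECKLIST_ROWS = [
    ("host dependence", "0001315", "M", "symbiont_specific"),
    ("type of symbiosis", "0001307", "C", "symbiont_specific"),
    ("symbiotic host organism life cycle type", "0001300", "M", "symbiont_specific"),
    ("host life stage", "0000251", "M", "symbiont_specific"),
    ("mode of transmission", "0001312", "C", "symbiont_specific"),
    ("route of transmission", "0001316", "O", "symbiont_specific"),
    ("host number individual", "0001305", "O", "symbiont_specific"),
    ("observed host symbionts", "0001309", "O", "shared"),
    ("host specificity", "0001308", "C", "symbiont_host_relationship"),
    ("host of the symbiont role", "0001303", "C", "symbiont_host_relationship"),
    ("host cellular location", "0001313", "C", "symbiont_host_relationship"),
    ("duration of association with the host", "0001299", "O", "symbiont_host_relationship"),
    ("observed coinfecting organisms in host of host", "0001310", "O", "symbiont_host_relationship"),
    ("host of the symbiotic host common name", "0001324", "O", "host_of_symbiont"),
    ("host of the symbiotic host local environmental context", "0001325", "O", "host_of_symbiont"),
    ("host of the symbiotic host environmental medium", "0001326", "O", "host_of_symbiont"),
    ("host of the symbiotic host taxon id", "0001306", "O", "host_of_symbiont"),
    ("host of the symbiotic host subject id", "0001327", "O", "host_of_symbiont"),
    ("relationship to other samples", "TBD", "C", "core"),
    ("biotic relationship", "0000028", "C", "core"),
]


@pytest.mark.parametrize("display,mixs_id,level,category", CHECKLIST_ROWS)
def test_every_row_resolves_by_display_name(registry, display, mixs_id, level, category):
    term = registry.get_term(display)
    assert term.display_name == display
    assert term.mixs_id == mixs_id
    assert term.category == category
    home = term.packages[0] if category != "shared" else "symbiont-associated"
    assert term.requirement(home) == level


def test_registry_census(registry):
    assert len(registry.terms) == 20  # 21 printed rows, one term duplicated
    assert len(registry.terms_for_package("symbiont-associated")) == 18
    assert registry.get_term("observed host symbionts").packages == (
        "symbiont-associated",
        "host-associated",
        "human-associated",
        "plant-associated",
        "human-vaginal",
        "human-skin",
        "human-oral",
        "human-gut",
    )


def test_id_bijection_excludes_provisional(registry):
    concrete = [t for t in registry.terms.values() if not t.is_provisional]
    ids = [t.mixs_id for t in concrete]
    assert len(ids) == len(set(ids))
    for term in concrete:
        assert registry.get_term_by_id(term.mixs_id) is term
    rel = registry.get_term("relationship to other samples")
    assert rel.is_provisional and rel.provisional_id == "SA-REL-0001"
    assert registry.get_term_by_id("SA-REL-0001") is rel


@pytest.mark.parametrize(
    "variant",
    ["host dependence", "HOST DEPENDENCE", "host_dependence", "Host-Dependence"],
)
def test_lookup_is_case_and_separator_insensitive(registry, variant):
    assert registry.get_term(variant).mixs_id == "0001315"


def test_alias_from_checklist_cross_reference(registry):
    # the route-of-transmission definition refers to "mode_transmission"
    assert registry.get_term("mode_transmission").canonical_name == "mode_of_transmission"


def test_unknown_term_reports_near_misses(registry):
    with pytest.raises(TermNotFoundError) as exc:
        registry.get_term("host dependance")
    assert "host_dependence" in exc.value.suggestions
    with pytest.raises(TermNotFoundError):
        registry.get_term("frobnicate")


def test_get_term_by_id_syntax(registry):
    assert registry.get_term_by_id("0000028").canonical_name == "biotic_relationship"
    with pytest.raises(IdSyntaxError):
        registry.get_term_by_id("28")
    with pytest.raises(TermNotFoundError):
        registry.get_term_by_id("9999999")


def test_terms_for_package_levels(registry):
    mandatory = [t.canonical_name for t in registry.terms_for_package("symbiont-associated", "M")]
    assert mandatory == [
        "host_dependence",
        "symbiotic_host_organism_life_cycle_type",
        "host_life_stage",
    ]
    with pytest.raises(PackageNotFoundError):
        registry.terms_for_package("atlantis")


def test_package_census(registry):
    pre = registry.list_packages("environmental", exclude_new=True)
    assert sorted(p.name for p in pre) == sorted(ENVIRONMENTAL_PACKAGES_PRE_SA)
    assert len(pre) == 17
    assert len(registry.list_packages("environmental")) == 18
    core = registry.list_packages("core")
    assert [p.name for p in core] == ["core"]
    assert core[0].terms == ["relationship_to_other_samples", "biotic_relationship"]


def test_new_term_accounting(registry):
    assert sorted(t.display_name for t in registry.new_terms()) == [
        "biotic relationship",
        "observed host symbionts",
        "relationship to other samples",
    ]


def test_serialize_round_trip(registry):
    doc = serialize_registry(registry)
    again = load_registry(doc)
    assert again.terms == registry.terms
    assert again.id_index == registry.id_index
    assert again.aliases == registry.aliases
    assert {n: p.terms for n, p in again.packages.items()} == {
        n: p.terms for n, p in registry.packages.items()
    }


def test_duplicate_id_rejected(registry):
    doc = serialize_registry(registry).replace("0001315", "0001307", 1)
    with pytest.raises(RegistryDuplicateIdError):
        load_registry(doc)
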