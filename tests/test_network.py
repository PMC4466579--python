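"""Structural tests of the generated species list and reaction network."""
import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vegftraffic as vt
from vegftraffic.network import (
    Compartment,
    MoleculeComposition,
    PhosphoState,
    Reaction,
    ReactionKind,
    Species,
    enumerate_reactions,
    enumerate_species,
    legal_compositions,
    validate_network,
)


def test_species_enumeration_counts(full_net):
    by_comp = Counter(s.compartment.value for s in full_net.species)
    assert len(full_net.species) == 97
    assert by_comp == {"ext": 3, "surf": 34, "rab45": 27, "rab11": 27, "degr": 6}


def test_every_r2_form_has_eight_phospho_variants(full_net):
    groups = Counter(
        (s.form, s.compartment)
        for s in full_net.species
        if s.composition.has_R2 and s.compartment is not Compartment.DEGRADED
    )
    assert groups and all(n == 8 for n in groups.values())


@settings(deadline=None, derandomize=True)
@given(st.tuples(*[st.booleans()] * 4))
def test_composition_rules(bits):
    """Any flag combination either builds a legal complex or raises; M+N1
    and VEGF-less bridges are always rejected."""
    has_v, has_m, has_r2, has_n1 = bits
    try:
        comp = MoleculeComposition(*bits)
    except ValueError:
        assert (
            not any(bits)
            or (has_m and has_n1)
            or (has_r2 and has_n1 and not has_v)
            or (has_m and has_r2 and not has_v)
        )
    else:
        assert not (comp.has_M and comp.has_N1)


def test_reaction_type_counts(full_net):
    assert full_net.binding_pair_count() == 15
    assert full_net.phospho_pair_count() == 120
    n_dephos = sum(
        1 for r in full_net.reactions if r.kind is ReactionKind.DEPHOSPHORYLATE
    )
    assert n_dephos == 120  # every phosphorylation step is reversible


def test_matrix_anchored_receptor_is_not_internalized(full_net):
    assert not any(
        r.kind is ReactionKind.INTERNALIZE and r.reactants[0].form == "M.V.R2"
        for r in full_net.reactions
    )
    # ... and M.V.R2 only ever lives on the surface
    assert all(
        s.compartment is Compartment.SURFACE
        for s in full_net.species
        if s.form == "M.V.R2"
    )


def test_degradation_routes_to_phospho_free_pool(full_net):
    degrades = [r for r in full_net.reactions if r.kind is ReactionKind.DEGRADE]
    assert degrades
    for r in degrades:
        assert r.products[0].compartment is Compartment.DEGRADED
        assert not r.products[0].phospho.any()
        assert r.reactants[0].compartment is Compartment.RAB45


def test_validation_passes_on_default_network(full_net):
    report = validate_network(full_net)
    assert report.ok, report.summary()
    # totals whose published decomposition is convention-dependent are
    # reported, not asserted
    assert "n_reactions_total" in report.info
    assert "n_trafficking_reaction_instances" in report.info


def _smuggle_species(composition, compartment, phospho=PhosphoState()):
    """Build a Species bypassing its invariant checks (negative controls)."""
    sp = object.__new__(Species)
    object.__setattr__(sp, "composition", composition)
    object.__setattr__(sp, "compartment", compartment)
    object.__setattr__(sp, "phospho", phospho)
    return sp


def test_validation_flags_injected_mn1_species(full_net):
    comp = object.__new__(MoleculeComposition)
    for f, v in zip(("has_V", "has_M", "has_R2", "has_N1"),
                    (True, True, False, True)):
        object.__setattr__(comp, f, v)
    bad = _smuggle_species(comp, Compartment.EXTRACELLULAR)
    net = vt.ReactionNetwork(
        species=full_net.species + [bad], reactions=full_net.reactions
    )
    report = validate_network(net, full_model=False)
    assert not report.ok
    assert any(c.name == "no_M_and_N1" for c in report.failures())


def test_validation_flags_phospho_preserving_degradation(full_net):
    src = next(
        s
        for s in full_net.species
        if s.form == "V.R2"
        and s.compartment is Compartment.RAB45
        and s.phospho.pY1175
    )
    bad_target = _smuggle_species(
        src.composition, Compartment.DEGRADED, src.phospho
    )
    bad_rx = Reaction(
        ReactionKind.DEGRADE, (src,), (bad_target,), "kdegr:V.R2"
    )
    net = vt.ReactionNetwork(
        species=full_net.species + [bad_target],
        reactions=full_net.reactions + [bad_rx],
    )
    report = validate_network(net, full_model=False)
    assert not report.ok
    names = {c.name for c in report.failures()}
    assert "degradation_clears_phospho" in names or (
        "degraded_pool_dephosphorylated" in names
    )


def test_trafficking_rates_are_phospho_uniform(full_net):
    refs = {}
    for r in full_net.reactions:
        if r.kind in (
            ReactionKind.INTERNALIZE,
            ReactionKind.RECYCLE_RAB4,
            ReactionKind.RECYCLE_RAB11,
            ReactionKind.TRANSFER_4TO11,
            ReactionKind.DEGRADE,
        ):
            refs.setdefault((r.kind, r.reactants[0].form), set()).add(r.rate_ref)
    assert all(len(v) == 1 for v in refs.values())


def test_binding_preserves_phospho_state(full_net):
    for r in full_net.reactions:
        if r.kind in (ReactionKind.BINDING_ON, ReactionKind.BINDING_OFF):
            ins = [s.phospho for s in r.reactants if s.composition.has_R2]
            outs = [s.phospho for s in r.products if s.composition.has_R2]
            assert ins == outs


def test_reduced_network_options():
    no_phos = enumerate_species(include_phospho=False)
    assert len(no_phos) == 27  # one variant per R2 form
    assert all(not s.phospho.any() for s in no_phos)
    minimal = enumerate_species(
        include_phospho=False, include_n1=False, include_m=False
    )
    forms = {(s.form, s.compartment.value) for s in minimal}
    assert ("V.N1.R2", "surf") not in forms and ("M.V.R2", "surf") not in forms
    net = enumerate_reactions(minimal)
    assert validate_network(net, full_model=False).ok


def test_dump_is_deterministic(full_net):
    net2 = vt.build_network()
    assert full_net.dump() == net2.dump()
    assert full_net.dump().startswith("# species\n")


def test_validation_flags_reaction_on_unknown_species(full_net):
    phantom = next(
        s for s in full_net.species if s.form == "V.N1.R2"
    )
    net = vt.ReactionNetwork(
        species=[s for s in full_net.species if s is not phantom],
        reactions=full_net.reactions,
    )
    report = validate_network(net, full_model=False)
    assert any(
        c.name == "reactions_reference_known_species" for c in report.failures()
    )


def test_free_internal_vegf_reachable_only_by_dissociation(full_net):
    producers = [
        r
        for r in full_net.reactions
        if any(
            p.form == "V" and p.compartment is Compartment.RAB11
            for p in r.products
        )
    ]
    assert producers
    assert all(r.kind is ReactionKind.BINDING_OFF for r in producers)
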