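"""Combinatorial enumeration of the VEGF-VEGFR2-NRP1 reaction network.

The model tracks complexes of four molecular entities -- the VEGF dimer (V),
a matrix/heparin binding site (M), the receptor tyrosine kinase VEGFR2 (R2)
and the co-receptor Neuropilin-1 (N1) -- across five compartments
(extracellular fluid, cell surface, Rab4/5 early endosomes, Rab11 recycling
endosomes, and a degraded pool).  Every VEGFR2-containing complex carries a
three-bit phosphorylation state for tyrosines Y951, Y1175 and Y1214.

The species list and reaction list are *generated* from composition rules
rather than hand-written, so that structural invariants (mutual exclusion of
M and N1 on one VEGF dimer, phospho-state preservation under trafficking,
phospho-clearing on degradation) hold by construction and can be audited by
:func:`validate_network`.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

RESIDUES: tuple[str, str, str] = ("Y951", "Y1175", "Y1214")

#: Ligated VEGFR2 forms: receptor in complex with VEGF, any phospho-state.
LIGATED_FORMS = ("V.R2", "M.V.R2", "V.N1.R2")


class Compartment(str, Enum):
    """The five model compartments."""

    EXTRACELLULAR = "ext"
    SURFACE = "surf"
    RAB45 = "rab45"
    RAB11 = "rab11"
    DEGRADED = "degr"


@dataclass(frozen=True, order=True)
class PhosphoState:
    """Phosphorylation pattern of the three modeled VEGFR2 tyrosines."""

    pY951: bool = False
    pY1175: bool = False
    pY1214: bool = False

    def has(self, residue: str) -> bool:
        return getattr(self, "p" + residue)

    def with_residue(self, residue: str, value: bool) -> "PhosphoState":
        return replace(self, **{"p" + residue: value})

    def any(self) -> bool:
        return self.pY951 or self.pY1175 or self.pY1214

    @staticmethod
    def all_states() -> list["PhosphoState"]:
        return [
            PhosphoState(*bits)
            for bits in itertools.product((False, True), repeat=3)
        ]

    def label(self) -> str:
        return "[p951=%d,p1175=%d,p1214=%d]" % (
            self.pY951,
            self.pY1175,
            self.pY1214,
        )


@dataclass(frozen=True, order=True)
class MoleculeComposition:
    """Membership of V, M, R2, N1 in one molecular complex.

    Raises ``ValueError`` for chemically impossible combinations: N1 and M
    compete for the same heparin-binding domain of the VEGF dimer, and R2
    can only be bridged to N1 or M through VEGF.
    """

    has_V: bool = False
    has_M: bool = False
    has_R2: bool = False
    has_N1: bool = False

    def __post_init__(self) -> None:
        if not (self.has_V or self.has_M or self.has_R2 or self.has_N1):
            raise ValueError("empty complex")
        if self.has_M and self.has_N1:
            raise ValueError("M and N1 cannot be present in the same complex")
        if self.has_R2 and self.has_N1 and not self.has_V:
            raise ValueError("R2-N1 complex requires VEGF")
        if self.has_M and self.has_R2 and not self.has_V:
            raise ValueError("M-R2 complex requires VEGF")

    @property
    def name(self) -> str:
        # conventional ordering: M.V.R2, V.M, V.N1.R2, V.N1, V.R2
        if self.has_M and self.has_V:
            return "M.V.R2" if self.has_R2 else "V.M"
        if self.has_V and self.has_N1:
            return "V.N1.R2" if self.has_R2 else "V.N1"
        if self.has_V and self.has_R2:
            return "V.R2"
        for flag, label in (("has_V", "V"), ("has_M", "M"),
                            ("has_R2", "R2"), ("has_N1", "N1")):
            if getattr(self, flag):
                return label
        raise AssertionError("empty complex")

    @staticmethod
    def from_name(name: str) -> "MoleculeComposition":
        parts = set(name.split("."))
        return MoleculeComposition(
            has_V="V" in parts,
            has_M="M" in parts,
            has_R2="R2" in parts,
            has_N1="N1" in parts,
        )


def legal_compositions() -> list[MoleculeComposition]:
    """All complexes permitted by the binding rules (9 of 15 combinations)."""
    out = []
    for bits in itertools.product((False, True), repeat=4):
        try:
            out.append(MoleculeComposition(*bits))
        except ValueError:
            continue
    return out


@dataclass(frozen=True, order=True)
class Species:
    composition: MoleculeComposition
    compartment: Compartment
    phospho: PhosphoState = PhosphoState()

    def __post_init__(self) -> None:
        if not self.composition.has_R2 and self.phospho.any():
            raise ValueError("phospho-state on a species lacking R2")
        if self.compartment is Compartment.DEGRADED and self.phospho.any():
            raise ValueError("degraded species must be dephosphorylated")
        if self.composition.has_M and self.compartment not in (
            Compartment.EXTRACELLULAR,
            Compartment.SURFACE,
        ):
            raise ValueError("matrix-bound species cannot be internal")
        if (
            self.composition.has_M
            and self.composition.has_R2
            and self.compartment is not Compartment.SURFACE
        ):
            raise ValueError("M.V.R2 is surface-only")

    @property
    def name(self) -> str:
        base = f"{self.compartment.value}:{self.composition.name}"
        if self.composition.has_R2:
            return base + self.phospho.label()
        return base

    @property
    def form(self) -> str:
        """Composition name, ignoring phospho-state and compartment."""
        return self.composition.name

    @property
    def is_ligated_r2(self) -> bool:
        return self.composition.has_R2 and self.composition.has_V


def _eligible(comp: MoleculeComposition, where: Compartment) -> bool:
    """Compartment-eligibility convention for the 97-species enumeration."""
    if where is Compartment.EXTRACELLULAR:
        return not comp.has_R2 and not comp.has_N1
    if where is Compartment.SURFACE:
        return comp.has_R2 or comp.has_N1
    if where in (Compartment.RAB45, Compartment.RAB11):
        if comp.has_M:
            return False
        # receptors, receptor complexes, and free VEGF released internally
        return comp.has_R2 or comp.has_N1 or comp.name == "V"
    if where is Compartment.DEGRADED:
        return not comp.has_M
    raise AssertionError(where)


def enumerate_species(
    include_phospho: bool = True,
    include_n1: bool = True,
    include_m: bool = True,
) -> list[Species]:
    """Generate the ordered species list.

    With all options on this yields the full 97-species model:
    3 extracellular + 34 surface + 27 Rab4/5 + 27 Rab11 + 6 degraded.
    ``include_phospho=False`` collapses each VEGFR2 form to its
    unphosphorylated representative (the trafficking-only reduced model);
    ``include_n1``/``include_m`` drop NRP1- or matrix-containing complexes.
    """
    comps = [
        c
        for c in legal_compositions()
        if (include_n1 or not c.has_N1) and (include_m or not c.has_M)
    ]
    comps.sort(key=lambda c: c.name)
    species: list[Species] = []
    order = (
        Compartment.EXTRACELLULAR,
        Compartment.SURFACE,
        Compartment.RAB45,
        Compartment.RAB11,
        Compartment.DEGRADED,
    )
    for where in order:
        for comp in comps:
            if not _eligible(comp, where):
                continue
            if (
                comp.has_R2
                and include_phospho
                and where is not Compartment.DEGRADED
            ):
                for ph in PhosphoState.all_states():
                    species.append(Species(comp, where, ph))
            else:
                species.append(Species(comp, where))
    return species


class ReactionKind(str, Enum):
    BINDING_ON = "binding_on"
    BINDING_OFF = "binding_off"
    INTERNALIZE = "internalize"
    RECYCLE_RAB4 = "recycle_rab4"
    RECYCLE_RAB11 = "recycle_rab11"
    TRANSFER_4TO11 = "transfer_4to11"
    DEGRADE = "degrade"
    PRODUCE = "produce"
    PHOSPHORYLATE = "phosphorylate"
    DEPHOSPHORYLATE = "dephosphorylate"


@dataclass(frozen=True)
class Reaction:
    kind: ReactionKind
    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate_ref: str
    residue: Optional[str] = None

    @property
    def name(self) -> str:
        lhs = " + ".join(s.name for s in self.reactants) or "0"
        rhs = " + ".join(s.name for s in self.products)
        return f"{self.kind.value}: {lhs} -> {rhs} [{self.rate_ref}]"


#: (pair id, compartment, reactant A form, reactant B form, product form)
#: The phospho-bearing participant (if any) is reactant B.
BINDING_RULES: list[tuple[str, Compartment, str, str, str]] = [
    ("V+M", Compartment.EXTRACELLULAR, "V", "M", "V.M"),
    ("V+R2", Compartment.SURFACE, "V", "R2", "V.R2"),
    ("V.M+R2", Compartment.SURFACE, "V.M", "R2", "M.V.R2"),
    ("M+V.R2", Compartment.SURFACE, "M", "V.R2", "M.V.R2"),
    ("V+N1", Compartment.SURFACE, "V", "N1", "V.N1"),
    ("N1+V.R2", Compartment.SURFACE, "N1", "V.R2", "V.N1.R2"),
    ("V.N1+R2", Compartment.SURFACE, "V.N1", "R2", "V.N1.R2"),
    ("V+R2", Compartment.RAB45, "V", "R2", "V.R2"),
    ("V+N1", Compartment.RAB45, "V", "N1", "V.N1"),
    ("N1+V.R2", Compartment.RAB45, "N1", "V.R2", "V.N1.R2"),
    ("V.N1+R2", Compartment.RAB45, "V.N1", "R2", "V.N1.R2"),
    ("V+R2", Compartment.RAB11, "V", "R2", "V.R2"),
    ("V+N1", Compartment.RAB11, "V", "N1", "V.N1"),
    ("N1+V.R2", Compartment.RAB11, "N1", "V.R2", "V.N1.R2"),
    ("V.N1+R2", Compartment.RAB11, "V.N1", "R2", "V.N1.R2"),
]

# For fluid-phase binding at the surface, the bulk (molar-unit) partner is
# the extracellular species; the receptor partner lives on the surface.
_BULK_FORMS = {"V", "M", "V.M"}

#: Trafficking rate rows that exist in the model (structural zeros such as
#: internalization of M.V.R2 or free V are omitted entirely -- those species
#: simply have no such reaction).
TRAFFIC_ROWS: dict[str, tuple[str, ...]] = {
    "int": ("R2", "V.R2", "N1", "V.N1", "V.N1.R2"),
    "rec4": ("R2", "V.R2", "N1", "V.N1", "V.N1.R2"),
    "rec11": ("R2", "V.R2", "N1", "V.N1", "V.N1.R2"),
    "4to11": ("R2", "V.R2", "N1", "V.N1", "V.N1.R2"),
    "degr": ("R2", "V.R2", "V", "N1", "V.N1", "V.N1.R2"),
}

#: The ten VEGFR2-containing (form, compartment) classes that carry
#: phosphorylation/dephosphorylation reactions.
PHOSPHO_FORMS: list[tuple[str, Compartment]] = [
    ("R2", Compartment.SURFACE),
    ("V.R2", Compartment.SURFACE),
    ("M.V.R2", Compartment.SURFACE),
    ("V.N1.R2", Compartment.SURFACE),
    ("R2", Compartment.RAB45),
    ("V.R2", Compartment.RAB45),
    ("V.N1.R2", Compartment.RAB45),
    ("R2", Compartment.RAB11),
    ("V.R2", Compartment.RAB11),
    ("V.N1.R2", Compartment.RAB11),
]


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    index: dict[Species, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {s: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise ValueError("duplicate species in network")

    def find(
        self, form: str, compartment: Compartment, phospho: PhosphoState = PhosphoState()
    ) -> Species:
        sp = Species(MoleculeComposition.from_name(form), compartment, phospho)
        if sp not in self.index:
            raise KeyError(sp.name)
        return sp

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def binding_pair_count(self) -> int:
        """Distinct reversible binding reaction types (phospho collapsed)."""
        pairs = {
            (r.rate_ref.split(":", 1)[1])
            for r in self.reactions
            if r.kind is ReactionKind.BINDING_ON
        }
        return len(pairs)

    def phospho_pair_count(self) -> int:
        """Reversible phosphorylation reactions (phospho-replicates counted)."""
        return sum(
            1 for r in self.reactions if r.kind is ReactionKind.PHOSPHORYLATE
        )

    def dump(self) -> str:
        """Deterministic plain-text listing of species and reactions."""
        lines = ["# species"]
        lines += self.species_names()
        lines.append("# reactions")
        lines += sorted(r.name for r in self.reactions)
        return "\n".join(lines) + "\n"

    def dump_json(self) -> str:
        payload = {
            "species": self.species_names(),
            "reactions": sorted(r.name for r in self.reactions),
        }
        return json.dumps(payload, indent=1)


def _phospho_states_of(species: Iterable[Species], comp_name: str,
                       where: Compartment) -> list[Species]:
    return sorted(
        s
        for s in species
        if s.form == comp_name and s.compartment is where
    )


def enumerate_reactions(species: list[Species]) -> ReactionNetwork:
    """Generate all reactions touching the given species list.

    Covers (a) reversible binding for every legal pair/compartment, replicated
    over phospho-states of any R2-containing participant, (b) trafficking per
    rate row, phospho-preserving except for degradation which clears the
    phospho-state, (c) phosphorylate/dephosphorylate pairs for each R2 form
    x residue x source state, and (d) zeroth-order receptor production.
    """
    have = set(species)
    index = {s: i for i, s in enumerate(species)}

    def get(form: str, where: Compartment,
            ph: PhosphoState = PhosphoState()) -> Optional[Species]:
        try:
            sp = Species(MoleculeComposition.from_name(form), where, ph)
        except ValueError:
            return None
        return sp if sp in have else None

    reactions: list[Reaction] = []

    def add(rx: Reaction) -> None:
        for s in rx.reactants + rx.products:
            if s not in have:
                raise ValueError(f"reaction references unknown species {s.name}")
        reactions.append(rx)

    # --- binding ---------------------------------------------------------
    for pair, where, fa, fb, fp in BINDING_RULES:
        comp_b = MoleculeComposition.from_name(fb)
        # reactant A never carries R2 under the rules above except none do
        where_a = (
            Compartment.EXTRACELLULAR
            if (where is Compartment.SURFACE and fa in _BULK_FORMS)
            else where
        )
        a = get(fa, where_a)
        if a is None:
            continue
        states = (
            PhosphoState.all_states()
            if comp_b.has_R2 and any(
                s.form == fb and s.compartment is where and s.phospho.any()
                for s in have
            )
            else [PhosphoState()]
        )
        for ph in states:
            b = get(fb, where, ph)
            p = get(fp, where, ph)
            if b is None or p is None:
                continue
            ref = f"{pair}@{where.value}"
            add(
                Reaction(
                    ReactionKind.BINDING_ON, (a, b), (p,), f"kon:{ref}"
                )
            )
            add(
                Reaction(
                    ReactionKind.BINDING_OFF, (p,), (a, b), f"koff:{ref}"
                )
            )

    # --- trafficking -----------------------------------------------------
    moves = {
        "int": (ReactionKind.INTERNALIZE, Compartment.SURFACE, Compartment.RAB45),
        "rec4": (ReactionKind.RECYCLE_RAB4, Compartment.RAB45, Compartment.SURFACE),
        "rec11": (ReactionKind.RECYCLE_RAB11, Compartment.RAB11, Compartment.SURFACE),
        "4to11": (ReactionKind.TRANSFER_4TO11, Compartment.RAB45, Compartment.RAB11),
        "degr": (ReactionKind.DEGRADE, Compartment.RAB45, Compartment.DEGRADED),
    }
    for process, forms in TRAFFIC_ROWS.items():
        kind, src, dst = moves[process]
        for form in forms:
            for s in _phospho_states_of(have, form, src):
                if kind is ReactionKind.DEGRADE:
                    d = get(form, dst)  # phospho cleared
                else:
                    d = get(form, dst, s.phospho)
                if d is None:
                    continue
                add(Reaction(kind, (s,), (d,), f"k{process}:{form}"))

    # --- production ------------------------------------------------------
    for form in ("R2", "N1"):
        p = get(form, Compartment.SURFACE)
        if p is not None:
            add(Reaction(ReactionKind.PRODUCE, (), (p,), f"s:{form}"))

    # --- phosphorylation -------------------------------------------------
    for form, where in PHOSPHO_FORMS:
        variants = _phospho_states_of(have, form, where)
        if len(variants) < 2:
            continue  # reduced (phospho-free) network
        for residue in RESIDUES:
            for s in variants:
                if s.phospho.has(residue):
                    continue
                tgt = get(form, where, s.phospho.with_residue(residue, True))
                if tgt is None:
                    continue
                ref = f"{residue}@{form}@{where.value}"
                add(
                    Reaction(
                        ReactionKind.PHOSPHORYLATE,
                        (s,),
                        (tgt,),
                        f"kp:{ref}",
                        residue=residue,
                    )
                )
                add(
                    Reaction(
                        ReactionKind.DEPHOSPHORYLATE,
                        (tgt,),
                        (s,),
                        f"kdp:{ref}",
                        residue=residue,
                    )
                )

    return ReactionNetwork(species=species, reactions=reactions, index=index)


def build_network(
    include_phospho: bool = True,
    include_n1: bool = True,
    include_m: bool = True,
) -> ReactionNetwork:
    return enumerate_reactions(
        enumerate_species(include_phospho, include_n1, include_m)
    )


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck]
    info: dict[str, int]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]

    def summary(self) -> str:
        lines = [
            f"{'PASS' if c.passed else 'FAIL'} {c.name}"
            + (f": {c.detail}" if c.detail else "")
            for c in self.checks
        ]
        lines += [f"info {k} = {v}" for k, v in sorted(self.info.items())]
        return "\n".join(lines)


def validate_network(net: ReactionNetwork, full_model: bool = True) -> ValidationReport:
    """Audit the structural invariants of a generated network.

    ``full_model`` enables the exact structural counts that hold only for the
    complete enumeration (97 species, 15 binding types, 120 reversible
    phosphorylation reactions).  Totals whose published decomposition is
    convention-dependent (grand total, trafficking family count) are reported
    in ``info`` without assertion.
    """
    checks: list[ValidationCheck] = []

    def check(name: str, passed: bool, detail: str = "") -> None:
        checks.append(ValidationCheck(name, bool(passed), detail))

    n_species = len(net.species)
    if full_model:
        check("species_count_97", n_species == 97, f"found {n_species}")
        nb = net.binding_pair_count()
        check("binding_types_15", nb == 15, f"found {nb}")
        np_ = net.phospho_pair_count()
        check("phospho_pairs_120", np_ == 120, f"found {np_}")

    # exclusion rule: never M and N1 together
    bad = [s.name for s in net.species
           if s.composition.has_M and s.composition.has_N1]
    check("no_M_and_N1", not bad, ", ".join(bad))

    # M-containing species compartment legality
    bad = [
        s.name
        for s in net.species
        if s.composition.has_M
        and (
            s.compartment not in (Compartment.EXTRACELLULAR, Compartment.SURFACE)
            or (s.composition.has_R2 and s.compartment is not Compartment.SURFACE)
        )
    ]
    check("matrix_compartment_legality", not bad, ", ".join(bad))

    # degraded species phospho-free; degrade reactions clear phospho
    bad = [
        s.name
        for s in net.species
        if s.compartment is Compartment.DEGRADED and s.phospho.any()
    ]
    check("degraded_pool_dephosphorylated", not bad, ", ".join(bad))
    bad = [
        r.name
        for r in net.reactions
        if r.kind is ReactionKind.DEGRADE and r.products[0].phospho.any()
    ]
    check("degradation_clears_phospho", not bad, "; ".join(bad))

    # every reaction references known species
    bad = [
        r.name
        for r in net.reactions
        for s in r.reactants + r.products
        if s not in net.index
    ]
    check("reactions_reference_known_species", not bad, "; ".join(bad[:3]))

    # non-degrade trafficking and binding preserve phospho-state
    preserve = {
        ReactionKind.BINDING_ON,
        ReactionKind.BINDING_OFF,
        ReactionKind.INTERNALIZE,
        ReactionKind.RECYCLE_RAB4,
        ReactionKind.RECYCLE_RAB11,
        ReactionKind.TRANSFER_4TO11,
    }
    bad = []
    for r in net.reactions:
        if r.kind not in preserve:
            continue
        ph_in = [s.phospho for s in r.reactants if s.composition.has_R2]
        ph_out = [s.phospho for s in r.products if s.composition.has_R2]
        if ph_in != ph_out:
            bad.append(r.name)
    check("trafficking_preserves_phospho", not bad, "; ".join(bad[:3]))

    # stoichiometry by kind
    bad = []
    for r in net.reactions:
        nr, np2 = len(r.reactants), len(r.products)
        ok = (
            (r.kind is ReactionKind.BINDING_ON and (nr, np2) == (2, 1))
            or (r.kind is ReactionKind.BINDING_OFF and (nr, np2) == (1, 2))
            or (r.kind is ReactionKind.PRODUCE and (nr, np2) == (0, 1))
            or (
                r.kind
                not in (
                    ReactionKind.BINDING_ON,
                    ReactionKind.BINDING_OFF,
                    ReactionKind.PRODUCE,
                )
                and (nr, np2) == (1, 1)
            )
        )
        if not ok:
            bad.append(r.name)
    check("mass_action_stoichiometry", not bad, "; ".join(bad[:3]))

    # phospho-uniform trafficking: one rate_ref per (process, form) family
    fam: dict[str, set[str]] = {}
    for r in net.reactions:
        if r.kind in preserve - {ReactionKind.BINDING_ON, ReactionKind.BINDING_OFF} or (
            r.kind is ReactionKind.DEGRADE
        ):
            fam.setdefault(
                f"{r.kind.value}:{r.reactants[0].form}", set()
            ).add(r.rate_ref)
    bad = [k for k, v in fam.items() if len(v) != 1]
    check("phospho_uniform_trafficking_rates", not bad, ", ".join(bad))

    # reachability: every non-degraded species reachable from the stimuli
    # {extracellular V, V.M} and the produced receptors.
    reach: set[Species] = set()
    seeds = []
    for form in ("V", "V.M", "M"):
        try:
            seeds.append(net.find(form, Compartment.EXTRACELLULAR))
        except KeyError:
            pass
    for r in net.reactions:
        if r.kind is ReactionKind.PRODUCE:
            seeds.append(r.products[0])
    reach.update(seeds)
    changed = True
    while changed:
        changed = False
        for r in net.reactions:
            if all(s in reach for s in r.reactants) and any(
                p not in reach for p in r.products
            ):
                reach.update(r.products)
                changed = True
    missing = [
        s.name
        for s in net.species
        if s not in reach and s.compartment is not Compartment.DEGRADED
    ]
    check("all_species_reachable", not missing, ", ".join(missing[:5]))

    n_traffic = sum(
        1
        for r in net.reactions
        if r.kind
        in (
            ReactionKind.INTERNALIZE,
            ReactionKind.RECYCLE_RAB4,
            ReactionKind.RECYCLE_RAB11,
            ReactionKind.TRANSFER_4TO11,
            ReactionKind.DEGRADE,
        )
    )
    info = {
        "n_species": n_species,
        "n_reactions_total": len(net.reactions),
        "n_trafficking_reaction_instances": n_traffic,
        "n_trafficking_reaction_families": len(fam),
        "n_binding_types": net.binding_pair_count(),
        "n_phospho_pairs": net.phospho_pair_count(),
    }
    return ValidationReport(checks=checks, info=info)
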