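"""Declarative constructors for the simulation scenarios and perturbations.

Each scenario wraps a study column (initial receptor numbers, VEGF/matrix
concentrations, geometry, study-specific rate overrides) into a runnable
:class:`~vegftraffic.simulate.Protocol`.  Perturbations are pure functions
on a :class:`~vegftraffic.parameters.ParameterSet` and compose in order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .network import Compartment, RESIDUES
from .parameters import (
    BindingEntry,
    ParameterSet,
    apply_study_config,
    default_parameters,
    get_study,
)
from .simulate import Protocol

SCENARIO_NAMES = (
    "trafficking_study",
    "trafficking_study_r2only",
    "presentation_2011",
    "presentation_2010",
    "other",
)

_SURFACE_LIGATED = ("V.R2", "M.V.R2", "V.N1.R2")
_INTERNAL_LIGATED = ("V.R2", "V.N1.R2")


@dataclass(frozen=True)
class Perturbation:
    """A named model perturbation with an optional magnitude."""

    kind: str
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("perturbation magnitude must be positive")


def make_scenario(
    name: str,
    mode: str = "soluble",
    vegf_ng_ml: Optional[float] = None,
    duration_s: float = 3600.0,
    n_grid: int = 241,
    perturbations: Sequence[Perturbation] = (),
    koff_vm: Optional[float] = None,
) -> Protocol:
    """Build the protocol for one study column.

    ``vegf_ng_ml`` overrides the study's printed [V]; ``koff_vm`` rescales
    the matrix off-rate with K_D co-varying at fixed k_on.  Perturbations
    are applied to the parameter set in the listed order.
    """
    study = get_study(name)
    if vegf_ng_ml is not None:
        study.vegf_ng_ml = vegf_ng_ml
    if koff_vm is not None:
        if koff_vm <= 0:
            raise ValueError("k_off,V.M must be positive")
        study.vm_koff = koff_vm
    params = apply_study_config(default_parameters(), study)
    for p in perturbations:
        params = apply_perturbation(params, p)
    label = f"{name}:{mode}:{study.vegf_ng_ml:g}ng/mL"
    return Protocol(
        params=params,
        mode=mode,
        vegf_ng_ml=study.vegf_ng_ml,
        duration_s=duration_s,
        n_grid=n_grid,
        label=label,
    )


def apply_perturbation(params: ParameterSet, p: Perturbation) -> ParameterSet:
    """Return a copy of ``params`` with one perturbation applied.

    Kinds
    -----
    nrp1_knockout
        NRP1 surface density zero and all VEGF-NRP1 association inert.
    v165b_ligand
        The ligand cannot bind NRP1 (VEGF165b): all V-N1 coupling k_on = 0;
        NRP1's own pools keep their VEGF-independent dynamics.
    veptp_sirna
        Surface dephosphorylation of Y951 and Y1175 on ligated receptor
        divided by ``magnitude`` (default experimental value: 5).
    tcptp_active
        Y951 and Y1214 dephosphorylation raised to the constitutive 30 s^-1
        in every compartment (ligated forms).
    surface_phosphatase
        Surface dephosphorylation of all three residues on ligated forms
        multiplied by ``magnitude``.
    rab11_kdp_equals_rab45
        Rab11 ligated dephosphorylation rates copied from Rab4/5.
    """
    ps = params.copy()
    S, R4, R11 = Compartment.SURFACE, Compartment.RAB45, Compartment.RAB11
    kdp = ps.phospho.kdp
    if p.kind == "nrp1_knockout":
        ps.study.n1_per_cell = 0.0
        _silence_n1_binding(ps)
    elif p.kind == "v165b_ligand":
        _silence_n1_binding(ps)
    elif p.kind == "veptp_sirna":
        f = p.magnitude
        for residue in ("Y951", "Y1175"):
            for form in _SURFACE_LIGATED:
                kdp[(residue, form, S)] = kdp[(residue, form, S)] / f
    elif p.kind == "tcptp_active":
        for residue in ("Y951", "Y1214"):
            for form in _SURFACE_LIGATED:
                kdp[(residue, form, S)] = 30.0
            for comp in (R4, R11):
                for form in _INTERNAL_LIGATED:
                    kdp[(residue, form, comp)] = 30.0
    elif p.kind == "surface_phosphatase":
        for residue in RESIDUES:
            for form in _SURFACE_LIGATED:
                kdp[(residue, form, S)] = kdp[(residue, form, S)] * p.magnitude
    elif p.kind == "rab11_kdp_equals_rab45":
        for residue in RESIDUES:
            for form in _INTERNAL_LIGATED:
                kdp[(residue, form, R11)] = kdp[(residue, form, R4)]
    else:
        raise ValueError(f"unknown perturbation kind {p.kind!r}")
    return ps


def _silence_n1_binding(ps: ParameterSet) -> None:
    """Zero every association step that couples VEGF to NRP1."""
    for (pair, comp), entry in ps.kinetics.entries.items():
        if pair in ("V+N1", "N1+V.R2", "V.N1+R2"):
            ps.kinetics.entries[(pair, comp)] = BindingEntry(
                0.0, entry.koff, entry.areal
            )


def koff_vm_sweep(
    values: Sequence[float],
    name: str = "other",
    vegf_ng_ml: Optional[float] = None,
    duration_s: float = 3600.0,
    n_grid: int = 241,
) -> list[Protocol]:
    """Immobilized-VEGF protocols differing only in k_off,V.M.

    K_D,V.M co-varies with the fixed study k_on.
    """
    if any(v <= 0 for v in values):
        raise ValueError("k_off values must be positive")
    return [
        make_scenario(
            name,
            mode="immobilized",
            vegf_ng_ml=vegf_ng_ml,
            duration_s=duration_s,
            n_grid=n_grid,
            koff_vm=v,
        )
        for v in values
    ]
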