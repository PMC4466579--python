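"""Model parameterization: kinetics, trafficking, phosphorylation, geometry.

Unit conventions
----------------
* Extracellular concentrations are molar at the user surface; internally the
  simulator stores every pool as molecules per cm^2 of total cell surface,
  converting bulk pools through ``N_A x (fluid volume per unit area)``.
* Fluid-phase association constants are given per-molar per-second and are
  converted per compartment; surface/endosomal receptor-receptor coupling
  constants are given per (mol/cm^2) per second.
* Trafficking and (de)phosphorylation rates are first-order, per second.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .network import (
    Compartment,
    PHOSPHO_FORMS,
    RESIDUES,
    TRAFFIC_ROWS,
)

AVOGADRO = 6.02214076e23  # molecules per mole

CM3_TO_L = 1e-3


@dataclass
class Geometry:
    """Cell-monolayer geometry and molecular weights.

    ``endosome_volume_per_area`` is the total volume of the named endosomal
    compartment per unit cell-surface area (cm^3 per cm^2).  ``fluid_depth_cm``
    is the media (or gel) depth over the monolayer, i.e. fluid volume per
    unit area in cm.
    """

    total_surface_area_cm2: float = 1.0
    fluid_depth_cm: float = 0.5
    endosome_volume_per_area: dict[str, float] = field(
        default_factory=lambda: {"rab45": 1.0e-7, "rab11": 1.0e-7}
    )
    cell_density_per_cm2: float = 1.0e5
    vegf_mw_g_per_mol: float = 45_000.0  # VEGF165 dimer
    matrix_site_mw_g_per_mol: float = 40_000.0

    def __post_init__(self) -> None:
        vals = [
            self.total_surface_area_cm2,
            self.fluid_depth_cm,
            self.cell_density_per_cm2,
            self.vegf_mw_g_per_mol,
            self.matrix_site_mw_g_per_mol,
            *self.endosome_volume_per_area.values(),
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("geometry parameters must be strictly positive")

    def fluid_volume_l_per_cm2(self) -> float:
        return self.fluid_depth_cm * CM3_TO_L

    def endosome_volume_l_per_cm2(self, compartment: Compartment | str) -> float:
        key = compartment.value if isinstance(compartment, Compartment) else compartment
        if key not in self.endosome_volume_per_area:
            raise ValueError(f"no endosome volume configured for {key!r}")
        return self.endosome_volume_per_area[key] * CM3_TO_L


@dataclass
class BindingEntry:
    """One reversible binding reaction's kinetics.

    ``areal`` marks receptor-receptor coupling constants given per areal
    density ((mol/cm^2)^-1 s^-1) rather than per molar.
    """

    kon: float
    koff: float
    areal: bool = False

    @property
    def kd(self) -> float:
        return self.koff / self.kon if self.kon else math.inf


@dataclass
class KineticParams:
    """Binding kinetics keyed by (pair id, compartment)."""

    entries: dict[tuple[str, Compartment], BindingEntry]

    def __getitem__(self, key: tuple[str, Compartment]) -> BindingEntry:
        return self.entries[key]


@dataclass
class TraffickingParams:
    """First-order trafficking rates keyed by (process, species form)."""

    rates: dict[tuple[str, str], float]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.rates[key]

    def __setitem__(self, key: tuple[str, str], value: float) -> None:
        if key not in self.rates:
            raise KeyError(key)
        self.rates[key] = value


@dataclass
class PhosphoParams:
    """Site-specific phosphorylation/dephosphorylation rates (s^-1).

    ``kp`` is keyed by (form, compartment); ``kdp`` by
    (residue, form, compartment), over the ten VEGFR2 form classes.
    """

    kp: dict[tuple[str, Compartment], float]
    kdp: dict[tuple[str, str, Compartment], float]


@dataclass
class StudyConfig:
    """Initial conditions and study-specific parameter overrides."""

    name: str
    cell_type: str
    vegf_ng_ml: float
    matrix_mg_ml: Optional[float]
    r2_per_cell: float
    n1_per_cell: float
    kdegr_scale: float = 1.0
    kint_rule: bool = True  # halve-by-six rule for [V] > 50 ng/mL
    vm_kon: float = 4.2e5  # M^-1 s^-1
    vm_koff: float = 1.0e-2  # s^-1
    total_surface_area_cm2: float = 1.0
    depth_soluble_cm: float = 0.5
    depth_bound_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.vegf_ng_ml < 0 or self.r2_per_cell < 0 or self.n1_per_cell < 0:
            raise ValueError("concentrations and receptor counts must be >= 0")

    @property
    def vm_kd(self) -> float:
        return self.vm_koff / self.vm_kon if self.vm_kon else math.inf


@dataclass
class ParameterSet:
    kinetics: KineticParams
    trafficking: TraffickingParams
    phospho: PhosphoParams
    geometry: Geometry
    study: Optional[StudyConfig] = None
    study_applied: bool = False

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- derived quantities ------------------------------------------------
    def surface_density(self, receptor: str) -> float:
        """Configured surface density (#/cm^2) of R2 or N1."""
        if self.study is None:
            raise ValueError("no study configured")
        count = {
            "R2": self.study.r2_per_cell,
            "N1": self.study.n1_per_cell,
        }[receptor]
        return receptors_per_cell_to_density(count, self.geometry)

    def production_rates(self) -> dict[str, float]:
        if self.study is None:
            return {"R2": 0.0, "N1": 0.0}
        targets = {r: self.surface_density(r) for r in ("R2", "N1")}
        return compute_production_rates(self.trafficking, targets)

    def rate_table(self) -> dict[str, float]:
        """Numeric value for every reaction ``rate_ref`` in the network.

        Bimolecular constants are pre-converted to the homogeneous internal
        unit system ((#/cm^2)^-1 s^-1) using the compartment volume in which
        the encounter happens.
        """
        geo = self.geometry
        table: dict[str, float] = {}
        na_vfluid = AVOGADRO * geo.fluid_volume_l_per_cm2()
        for (pair, comp), e in self.kinetics.entries.items():
            if e.areal:
                kon = e.kon / AVOGADRO
            elif comp in (Compartment.RAB45, Compartment.RAB11):
                kon = convert_bulk_to_internal_kon(e.kon, geo, comp)
            else:
                # bulk partner in the extracellular fluid column
                kon = e.kon / na_vfluid
            table[f"kon:{pair}@{comp.value}"] = kon
            table[f"koff:{pair}@{comp.value}"] = e.koff
        for (process, form), v in self.trafficking.rates.items():
            table[f"k{process}:{form}"] = v
        prod = self.production_rates()
        table["s:R2"] = prod["R2"]
        table["s:N1"] = prod["N1"]
        for (form, comp), v in self.phospho.kp.items():
            for residue in RESIDUES:
                table[f"kp:{residue}@{form}@{comp.value}"] = v
        for (residue, form, comp), v in self.phospho.kdp.items():
            table[f"kdp:{residue}@{form}@{comp.value}"] = v
        return table

    # -- fluid/bulk conversions -------------------------------------------
    def molar_to_density(self, conc_molar: float) -> float:
        """Extracellular molar concentration -> #/cm^2 equivalents."""
        return conc_molar * AVOGADRO * self.geometry.fluid_volume_l_per_cm2()

    def density_to_molar(self, density: float) -> float:
        return density / (AVOGADRO * self.geometry.fluid_volume_l_per_cm2())

    def vegf_ng_ml_to_molar(self, ng_ml: float) -> float:
        return ng_ml * 1e-6 / self.geometry.vegf_mw_g_per_mol  # g/L / (g/mol)

    def matrix_mg_ml_to_molar(self, mg_ml: float) -> float:
        return mg_ml / self.geometry.matrix_site_mw_g_per_mol


def _default_kinetics() -> KineticParams:
    E, S, R4, R11 = (
        Compartment.EXTRACELLULAR,
        Compartment.SURFACE,
        Compartment.RAB45,
        Compartment.RAB11,
    )
    entries: dict[tuple[str, Compartment], BindingEntry] = {
        ("V+M", E): BindingEntry(4.2e5, 1.0e-2),
        ("V+R2", S): BindingEntry(1.0e7, 1.0e-3),
        ("M+V.R2", S): BindingEntry(4.2e5, 1.0e-2),  # same as V+M
        ("V.M+R2", S): BindingEntry(1.0e7, 1.0e-3),  # same as V+R2
        ("V+N1", S): BindingEntry(4.8e4, 1.0e-4),
        ("N1+V.R2", S): BindingEntry(3.1e13, 1.0e-3, areal=True),
        ("V.N1+R2", S): BindingEntry(1.0e14, 1.0e-3, areal=True),
    }
    for comp in (R4, R11):
        entries[("V+R2", comp)] = BindingEntry(1.0e7, 1.0e-3)
        entries[("V+N1", comp)] = BindingEntry(4.8e4, 1.0e-4)
        entries[("N1+V.R2", comp)] = BindingEntry(3.1e13, 1.0e-3, areal=True)
        entries[("V.N1+R2", comp)] = BindingEntry(1.0e14, 1.0e-3, areal=True)
    return KineticParams(entries)


def _default_trafficking() -> TraffickingParams:
    rates = {
        ("int", "R2"): 2.6e-3,
        ("int", "V.R2"): 3.12e-2,
        ("int", "N1"): 2.6e-3,
        ("int", "V.N1"): 2.6e-3,
        ("int", "V.N1.R2"): 3.12e-2,
        ("rec4", "R2"): 3.8e-3,
        ("rec4", "V.R2"): 3.8e-3,
        ("rec4", "N1"): 3.8e-5,
        ("rec4", "V.N1"): 3.8e-5,
        ("rec4", "V.N1.R2"): 3.8e-5,
        ("rec11", "R2"): 1.4e-4,
        ("rec11", "V.R2"): 1.4e-4,
        ("rec11", "N1"): 1.4e-2,
        ("rec11", "V.N1"): 1.4e-2,
        ("rec11", "V.N1.R2"): 1.4e-2,
        ("4to11", "R2"): 1.0e-5,
        ("4to11", "V.R2"): 1.0e-5,
        ("4to11", "N1"): 1.9e-2,
        ("4to11", "V.N1"): 1.9e-2,
        ("4to11", "V.N1.R2"): 1.9e-2,
        ("degr", "R2"): 3.6e-6,
        ("degr", "V.R2"): 3.6e-5,
        ("degr", "V"): 1.2e-2,
        ("degr", "N1"): 1.6e-4,
        ("degr", "V.N1"): 1.6e-4,
        ("degr", "V.N1.R2"): 6.8e-4,
    }
    assert all(
        form in TRAFFIC_ROWS[process] for (process, form) in rates
    )
    return TraffickingParams(rates)


def _default_phospho() -> PhosphoParams:
    S, R4, R11 = Compartment.SURFACE, Compartment.RAB45, Compartment.RAB11
    kp: dict[tuple[str, Compartment], float] = {}
    for form, comp in PHOSPHO_FORMS:
        kp[(form, comp)] = 0.0 if form == "R2" else 1.0
    kdp: dict[tuple[str, str, Compartment], float] = {}
    # unligated VEGFR2: fast constitutive dephosphorylation everywhere
    for comp in (S, R4, R11):
        for residue in RESIDUES:
            kdp[(residue, "R2", comp)] = 30.0
    # ligated VEGFR2, per residue x compartment (fit values)
    vr2 = {
        S: {"Y951": 0.043, "Y1175": 4.98, "Y1214": 1.06},
        R4: {"Y951": 75.0, "Y1175": 0.00972, "Y1214": 0.0307},
        R11: {"Y951": 30.0, "Y1175": 30.0, "Y1214": 30.0},
    }
    vn1r2 = {
        S: {"Y951": 6.0, "Y1175": 5.0, "Y1214": 1.0},
        R4: {"Y951": 15.0, "Y1175": 0.01, "Y1214": 6.0},
        R11: {"Y951": 30.0, "Y1175": 30.0, "Y1214": 30.0},
    }
    for comp, row in vr2.items():
        for residue, v in row.items():
            kdp[(residue, "V.R2", comp)] = v
    for comp, row in vn1r2.items():
        for residue, v in row.items():
            kdp[(residue, "V.N1.R2", comp)] = v
    # matrix-anchored V.R2: intrinsic rates identical to soluble-ligated V.R2
    for residue in RESIDUES:
        kdp[(residue, "M.V.R2", S)] = kdp[(residue, "V.R2", S)]
    return PhosphoParams(kp=kp, kdp=kdp)


def default_parameters(study: Optional[StudyConfig] = None) -> ParameterSet:
    """The representative parameter set (published tables, no study scaling)."""
    return ParameterSet(
        kinetics=_default_kinetics(),
        trafficking=_default_trafficking(),
        phospho=_default_phospho(),
        geometry=Geometry(),
        study=study,
    )


def convert_bulk_to_internal_kon(
    kon_molar: float, geometry: Geometry, compartment: Compartment | str
) -> float:
    """Convert a per-molar association constant for use inside an endosome.

    The returned constant k' satisfies ``rate = k' * x * y`` with x, y in
    molecules per cm^2 of cell surface, reproducing the molar-unit flux for
    the configured endosomal volume per unit area.
    """
    v = geometry.endosome_volume_l_per_cm2(compartment)
    return kon_molar / (AVOGADRO * v)


def receptors_per_cell_to_density(count_per_cell: float, geometry: Geometry) -> float:
    """Receptors per cell -> molecules per cm^2 of monolayer."""
    if count_per_cell < 0:
        raise ValueError("receptor count must be >= 0")
    return count_per_cell * geometry.cell_density_per_cm2


def compute_production_rates(
    traffic: TraffickingParams, surface_targets: dict[str, float]
) -> dict[str, float]:
    """Receptor production rates holding the no-VEGF surface pools constant.

    For each unligated receptor the surface/Rab4/5/Rab11 subsystem is linear;
    the stationary endosomal pools are
    ``E45 = k_int*S/(k_rec4+k_4to11+k_degr)`` and
    ``E11 = k_4to11*E45/k_rec11``, and the production rate balancing
    degradation is ``s = k_int*S - k_rec4*E45 - k_rec11*E11 = k_degr*E45``.
    """
    out: dict[str, float] = {}
    for receptor, s_surface in surface_targets.items():
        kint = traffic[("int", receptor)]
        krec4 = traffic[("rec4", receptor)]
        krec11 = traffic[("rec11", receptor)]
        k4to11 = traffic[("4to11", receptor)]
        kdegr = traffic[("degr", receptor)]
        if kint == 0:
            out[receptor] = 0.0
            continue
        denom = krec4 + k4to11 + kdegr
        if denom == 0 or krec11 == 0:
            raise ZeroDivisionError(
                f"degenerate trafficking rates for {receptor}: no stationary state"
            )
        e45 = kint * s_surface / denom
        e11 = k4to11 * e45 / krec11
        out[receptor] = kint * s_surface - krec4 * e45 - krec11 * e11
    return out


def steady_state_pools(
    traffic: TraffickingParams, receptor: str, s_surface: float
) -> dict[str, float]:
    """Stationary unligated pools (surface, rab45, rab11) for one receptor."""
    kint = traffic[("int", receptor)]
    denom = (
        traffic[("rec4", receptor)]
        + traffic[("4to11", receptor)]
        + traffic[("degr", receptor)]
    )
    e45 = kint * s_surface / denom
    e11 = traffic[("4to11", receptor)] * e45 / traffic[("rec11", receptor)]
    return {"surf": s_surface, "rab45": e45, "rab11": e11}


# --- study registry -------------------------------------------------------

STUDIES: dict[str, StudyConfig] = {
    "trafficking_study": StudyConfig(
        name="trafficking_study",
        cell_type="PAEC",
        vegf_ng_ml=50.0,
        matrix_mg_ml=None,
        r2_per_cell=108_000.0,
        n1_per_cell=113_000.0,
        kdegr_scale=1.0,
        kint_rule=True,  # [V] = 50 ng/mL tie resolves to the original k_int
        vm_kon=4.2e5,
        vm_koff=1.0e-2,
        total_surface_area_cm2=1.0,
    ),
    "trafficking_study_r2only": StudyConfig(
        name="trafficking_study_r2only",
        cell_type="PAEC",
        vegf_ng_ml=50.0,
        matrix_mg_ml=None,
        r2_per_cell=37_400.0,
        n1_per_cell=0.0,
        kdegr_scale=1.0,
        vm_kon=4.2e5,
        vm_koff=1.0e-2,
        total_surface_area_cm2=1.0,
    ),
    "trafficking_study_n1only": StudyConfig(
        name="trafficking_study_n1only",
        cell_type="PAEC",
        vegf_ng_ml=50.0,
        matrix_mg_ml=None,
        r2_per_cell=0.0,
        n1_per_cell=113_000.0,
        kdegr_scale=1.0,
        vm_kon=4.2e5,
        vm_koff=1.0e-2,
        total_surface_area_cm2=1.0,
    ),
    "presentation_2011": StudyConfig(
        name="presentation_2011",
        cell_type="HUVEC",
        vegf_ng_ml=2.0,
        matrix_mg_ml=1.5e-3,  # 1500 ng/mL
        r2_per_cell=6_000.0,
        n1_per_cell=35_000.0,
        kdegr_scale=2.4,
        vm_kon=4.2e5,
        vm_koff=3.3e-3,  # electrostatic (Ve); covalent uses 1.1e-3
        total_surface_area_cm2=3.0,
        depth_soluble_cm=0.5,
        depth_bound_cm=0.05,
    ),
    "presentation_2010": StudyConfig(
        name="presentation_2010",
        cell_type="HUVEC",
        vegf_ng_ml=200.0,
        matrix_mg_ml=3.0,
        r2_per_cell=6_000.0,
        n1_per_cell=35_000.0,
        kdegr_scale=2.4,
        vm_kon=4.0e3,
        vm_koff=1.0e-2,
        total_surface_area_cm2=1.0,
    ),
    "other": StudyConfig(
        name="other",
        cell_type="HUVEC",
        vegf_ng_ml=20.0,
        matrix_mg_ml=3.0,
        r2_per_cell=6_000.0,
        n1_per_cell=35_000.0,
        kdegr_scale=2.4,
        vm_kon=4.0e3,
        vm_koff=1.0e-2,
        total_surface_area_cm2=1.0,
    ),
}


def get_study(name: str) -> StudyConfig:
    try:
        return replace(STUDIES[name])
    except KeyError:
        raise KeyError(
            f"unknown study {name!r}; choose from {sorted(STUDIES)}"
        ) from None


def apply_study_config(base: ParameterSet, study: StudyConfig) -> ParameterSet:
    """Install a study's initial conditions and parameter overrides.

    Returns a fresh ParameterSet; applying a study on top of an already
    study-scaled set is rejected to prevent compounding the degradation
    scale factor.
    """
    if base.study_applied:
        raise ValueError(
            "parameter set already carries study-specific scaling; "
            "start from default_parameters()"
        )
    ps = base.copy()
    ps.study = replace(study)
    ps.study_applied = True
    # (a) degradation scale factor
    for key in list(ps.trafficking.rates):
        if key[0] == "degr":
            ps.trafficking.rates[key] = base.trafficking.rates[key] * study.kdegr_scale
    # (b) internalization saturation rule at high VEGF
    if study.kint_rule and study.vegf_ng_ml > 50.0:
        for form in ("V.R2", "V.N1.R2"):
            ps.trafficking.rates[("int", form)] = (
                base.trafficking.rates[("int", form)] / 6.0
            )
    # (c) study V.M kinetics (also the matrix capture of surface V.R2)
    for key in (("V+M", Compartment.EXTRACELLULAR), ("M+V.R2", Compartment.SURFACE)):
        ps.kinetics.entries[key] = BindingEntry(study.vm_kon, study.vm_koff)
    # (d) geometry
    ps.geometry.total_surface_area_cm2 = study.total_surface_area_cm2
    ps.geometry.fluid_depth_cm = study.depth_soluble_cm
    return ps
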