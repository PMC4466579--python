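"""Derivative assembly, steady state, integration, conservation laws."""
import numpy as np
import pytest

import vegftraffic as vt
from vegftraffic.network import Compartment, PhosphoState, build_network
from vegftraffic.parameters import (
    AVOGADRO,
    default_parameters,
    get_study,
    steady_state_pools,
)
from vegftraffic.simulate import (
    Protocol,
    SolverOptions,
    assemble_rhs,
    initial_state,
    steady_state_no_vegf,
)


@pytest.fixture(scope="module")
def minimal_net():
    """VEGF + VEGFR2 only: no NRP1, no matrix, no phospho (12 species)."""
    return build_network(include_phospho=False, include_n1=False, include_m=False)


def _oracle_rhs(params, net):
    """Hand-coded balance equations for the minimal VEGF/VEGFR2 system,
    written independently of the generic assembler."""
    geo = params.geometry
    kon_f = 1.0e7 / (AVOGADRO * geo.fluid_volume_l_per_cm2())
    kon_45 = 1.0e7 / (AVOGADRO * geo.endosome_volume_l_per_cm2("rab45"))
    kon_11 = 1.0e7 / (AVOGADRO * geo.endosome_volume_l_per_cm2("rab11"))
    koff = 1.0e-3
    tr = params.trafficking
    ki, kiv = tr[("int", "R2")], tr[("int", "V.R2")]
    kr4, kr4v = tr[("rec4", "R2")], tr[("rec4", "V.R2")]
    kr11, kr11v = tr[("rec11", "R2")], tr[("rec11", "V.R2")]
    k41, k41v = tr[("4to11", "R2")], tr[("4to11", "V.R2")]
    kd, kdv, kdV = tr[("degr", "R2")], tr[("degr", "V.R2")], tr[("degr", "V")]
    s_r2 = params.production_rates()["R2"]
    ix = {s.name: i for i, s in enumerate(net.species)}
    iV = ix["ext:V"]
    iR = ix["surf:R2[p951=0,p1175=0,p1214=0]"]
    iVR = ix["surf:V.R2[p951=0,p1175=0,p1214=0]"]
    iR45 = ix["rab45:R2[p951=0,p1175=0,p1214=0]"]
    iV45 = ix["rab45:V"]
    iVR45 = ix["rab45:V.R2[p951=0,p1175=0,p1214=0]"]
    iR11 = ix["rab11:R2[p951=0,p1175=0,p1214=0]"]
    iV11 = ix["rab11:V"]
    iVR11 = ix["rab11:V.R2[p951=0,p1175=0,p1214=0]"]
    zero = "[p951=0,p1175=0,p1214=0]"
    iRd, iVd, iVRd = ix["degr:R2" + zero], ix["degr:V"], ix["degr:V.R2" + zero]

    def rhs(y):
        d = np.zeros_like(y)
        b_s = kon_f * y[iV] * y[iR] - koff * y[iVR]
        b_45 = kon_45 * y[iV45] * y[iR45] - koff * y[iVR45]
        b_11 = kon_11 * y[iV11] * y[iR11] - koff * y[iVR11]
        d[iV] = -b_s
        d[iR] = -b_s - ki * y[iR] + kr4 * y[iR45] + kr11 * y[iR11] + s_r2
        d[iVR] = b_s - kiv * y[iVR] + kr4v * y[iVR45] + kr11v * y[iVR11]
        d[iR45] = ki * y[iR] - (kr4 + k41 + kd) * y[iR45] - b_45
        d[iV45] = -b_45 - kdV * y[iV45]
        d[iVR45] = kiv * y[iVR] - (kr4v + k41v + kdv) * y[iVR45] + b_45
        d[iR11] = k41 * y[iR45] - kr11 * y[iR11] - b_11
        d[iV11] = -b_11
        d[iVR11] = k41v * y[iVR45] - kr11v * y[iVR11] + b_11
        d[iRd] = kd * y[iR45]
        d[iVd] = kdV * y[iV45]
        d[iVRd] = kdv * y[iVR45]
        return d

    return rhs


def test_assembled_rhs_matches_handcoded_oracle(minimal_net):
    params = default_parameters(study=get_study("other"))
    generic = assemble_rhs(minimal_net, params)
    oracle = _oracle_rhs(params, minimal_net)
    rng = np.random.default_rng(0)
    for _ in range(100):
        y = rng.uniform(0.0, 1.0, len(minimal_net.species)) * 1.0e8
        a, b = generic(0.0, y), oracle(y)
        scale = np.abs(b).max()
        assert np.abs(a - b).max() <= 1e-12 * scale


def test_zero_state_zero_production_gives_zero_derivative(full_net):
    study = get_study("other")
    study.r2_per_cell = 0.0
    study.n1_per_cell = 0.0
    params = default_parameters(study=study)
    rhs = assemble_rhs(full_net, params)
    y = np.zeros(len(full_net.species))
    assert np.all(rhs(0.0, y) == 0.0)


def test_single_term_binding_flux(full_net):
    params = default_parameters(study=get_study("other"))
    rhs = assemble_rhs(full_net, params)
    y = np.zeros(len(full_net.species))
    v, r2 = 2.0e10, 5.0e8
    y[full_net.index[full_net.find("V", Compartment.EXTRACELLULAR)]] = v
    y[full_net.index[full_net.find("R2", Compartment.SURFACE)]] = r2
    kon = 1.0e7 / (AVOGADRO * params.geometry.fluid_volume_l_per_cm2())
    i_vr2 = full_net.index[full_net.find("V.R2", Compartment.SURFACE)]
    d = rhs(0.0, y)
    # d[V.R2]/dt carries exactly the single association term
    assert d[i_vr2] == pytest.approx(kon * v * r2, rel=1e-12)


def test_steady_state_surface_fractions(full_net):
    params = default_parameters(study=get_study("trafficking_study"))
    y = steady_state_no_vegf(params, full_net)
    for receptor, expected in (("R2", 0.5779), ("N1", 0.7580)):
        pred = lambda s, r=receptor: (
            s.form == r and s.compartment is not Compartment.DEGRADED
        )
        mask = np.array([pred(s) for s in full_net.species])
        surf = y[full_net.index[full_net.find(receptor, Compartment.SURFACE)]]
        assert surf / y[mask].sum() == pytest.approx(expected, abs=2e-4)
    # NRP1: the Rab11 pool exceeds the Rab4/5 pool at steady state
    n45 = y[full_net.index[full_net.find("N1", Compartment.RAB45)]]
    n11 = y[full_net.index[full_net.find("N1", Compartment.RAB11)]]
    assert n11 > n45
    # residual of the live subsystem is at solver floor
    rhs = assemble_rhs(full_net, params)
    live = np.array(
        [s.compartment is not Compartment.DEGRADED for s in full_net.species]
    )
    assert np.abs(rhs(0.0, y)[live]).max() < 1e-9 * y.max()


def test_no_stimulus_protocol_stays_stationary(full_net):
    proto = vt.make_scenario("other", mode="soluble", vegf_ng_ml=0.0,
                             duration_s=3600.0, n_grid=25)
    tc = vt.simulate(proto, full_net)
    live = tc.species_mask(
        lambda s: s.compartment is not Compartment.DEGRADED
    )
    y0, yT = tc.states[0, live], tc.states[-1, live]
    scale = y0.max()
    assert np.abs(yT - y0).max() <= 1e-6 * scale


def test_total_receptor_decreases_after_stimulation(other_vs_tc):
    total = vt.total_r2_series(other_vs_tc).values
    assert total[0] == pytest.approx(100.0, abs=1e-6)
    assert np.all(np.diff(total) <= 1e-9)
    assert total[-1] < 99.0


def test_r2_mass_balance_closes_with_production(other_vb_tc):
    tc = other_vb_tc
    total_r2 = tc.group_series(lambda s: s.composition.has_R2)
    s_r2 = tc.params.production_rates()["R2"]
    expected = total_r2[0] + s_r2 * tc.times
    assert np.abs(total_r2 - expected).max() <= 1e-6 * total_r2[0]


def test_vegf_is_strictly_conserved(other_vb_tc):
    tc = other_vb_tc
    total_v = tc.group_series(lambda s: s.composition.has_V)
    assert np.abs(total_v - total_v[0]).max() <= 1e-6 * total_v[0]


def test_non_negativity(other_vb_tc, other_vs_tc):
    assert other_vb_tc.states.min() >= 0.0
    assert other_vs_tc.states.min() >= 0.0


def test_phospho_marginalization_matches_reduced_model(full_net, reduced_net):
    """Summing the 8 phospho-variants of each form must reproduce the
    phospho-free model exactly: trafficking and binding are phospho-blind."""
    tight = SolverOptions(rtol=1e-10, atol=1e-8)
    mk = lambda: vt.make_scenario("other", mode="soluble", vegf_ng_ml=20.0,
                                  duration_s=1800.0, n_grid=31)
    tc_full = vt.simulate(mk(), full_net, solver=tight)
    tc_red = vt.simulate(mk(), reduced_net, solver=tight)
    worst = 0.0
    for j, sp in enumerate(reduced_net.species):
        marg = tc_full.group_series(
            lambda s, sp=sp: s.form == sp.form and s.compartment is sp.compartment
        )
        ref = tc_red.states[:, j]
        scale = max(ref.max(), 1e-6 * tc_red.states.max())
        worst = max(worst, np.abs(marg - ref).max() / scale)
    assert worst <= 1e-8


def test_solver_tolerance_convergence(full_net):
    base = SolverOptions(rtol=1e-8, atol=1e-6)
    tighter = SolverOptions(rtol=5e-9, atol=5e-7)
    out = []
    for solver in (base, tighter):
        proto = vt.make_scenario("other", mode="immobilized", vegf_ng_ml=20.0,
                                 duration_s=600.0, n_grid=21)
        tc = vt.simulate(proto, full_net, solver=solver)
        out.append(vt.pR2_series(tc).values)
    a, b = out
    assert np.abs(a - b).max() <= 1e-3 * np.abs(a).max()


def test_immobilized_initialization_places_all_vegf_on_matrix(full_net):
    proto = vt.make_scenario("other", mode="immobilized", vegf_ng_ml=20.0)
    y0 = initial_state(proto, full_net)
    iv = full_net.index[full_net.find("V", Compartment.EXTRACELLULAR)]
    ivm = full_net.index[full_net.find("V.M", Compartment.EXTRACELLULAR)]
    assert y0[iv] == 0.0
    v_molar = proto.params.density_to_molar(y0[ivm])
    assert v_molar == pytest.approx(proto.params.vegf_ng_ml_to_molar(20.0),
                                    rel=1e-12)


def test_protocol_validation():
    with pytest.raises(ValueError):
        vt.make_scenario("other", mode="levitating")
    with pytest.raises(ValueError):
        vt.make_scenario("other", duration_s=-5.0)
    with pytest.raises(KeyError):
        vt.make_scenario("not_a_study")
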