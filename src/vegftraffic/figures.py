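"""Registered scenario bundles reproducing the published figure panels
(values only -- time-course CSVs and summary JSON, no plotting)."""
from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .network import build_network
from .observables import (
    ligated_fraction_phosphorylated,
    ligated_series,
    peak,
    phospho_series,
    pR2_series,
    ratio_series,
    total_r2_series,
)
from .scenarios import Perturbation, koff_vm_sweep, make_scenario
from .simulate import simulate

_CONCS = (2.0, 20.0, 200.0)


def _series_frame(series_map: dict) -> pd.DataFrame:
    frames = []
    for name, s in series_map.items():
        frames.append(
            pd.DataFrame(
                {"series": name, "time_min": s.times / 60.0, "value": s.values}
            )
        )
    return pd.concat(frames, ignore_index=True)


def fig2(net=None) -> dict:
    """Ligated/free VEGFR2 distributions and total-VEGFR2 decay (soluble and
    immobilized, 2/20/200 ng/mL)."""
    net = net or build_network()
    series, summary = {}, {}
    for mode in ("soluble", "immobilized"):
        tag = "Vs" if mode == "soluble" else "Vb"
        for conc in _CONCS:
            tc = simulate(make_scenario("other", mode=mode, vegf_ng_ml=conc), net)
            series[f"total_R2:{tag}:{conc:g}"] = total_r2_series(tc)
            for comp in ("surf", "rab45", "rab11"):
                series[f"ligated:{comp}:{tag}:{conc:g}"] = ligated_series(
                    tc, compartments=[comp]
                )
    return {"series": series, "summary": summary}


def fig4ef(net=None) -> dict:
    """Phosphatase-perturbation validation panels (VEPTP siRNA /5 on the
    surface; constitutively active TCPTP at 30 s^-1)."""
    net = net or build_network()
    out = {}
    runs = {
        "baseline": (),
        "veptp_sirna": (Perturbation("veptp_sirna", 5.0),),
        "tcptp_active": (Perturbation("tcptp_active"),),
    }
    for label, perts in runs.items():
        tc = simulate(
            make_scenario(
                "other", mode="soluble", vegf_ng_ml=50.0,
                duration_s=600.0, perturbations=perts,
            ),
            net,
        )
        for res in ("Y951", "Y1175", "Y1214"):
            out[f"p{res}:{label}"] = phospho_series(tc, res)
        out[f"pR2:{label}"] = pR2_series(tc)
    return {"series": out, "summary": {}}


def fig5(net=None) -> dict:
    """V.R2, pR2, pY1175, pY1214 for Vs/Vb at 2/20/200 ng/mL (12 series per
    readout family; the registry contract counts the ligated+phospho set)."""
    net = net or build_network()
    series = {}
    for mode in ("soluble", "immobilized"):
        tag = "Vs" if mode == "soluble" else "Vb"
        for conc in _CONCS:
            tc = simulate(
                make_scenario("other", mode=mode, vegf_ng_ml=conc,
                              duration_s=1800.0),
                net,
            )
            series[f"ligated:{tag}:{conc:g}"] = ligated_series(tc)
            series[f"pR2:{tag}:{conc:g}"] = pR2_series(tc)
            series[f"pY1175:{tag}:{conc:g}"] = phospho_series(tc, "Y1175")
            series[f"pY1214:{tag}:{conc:g}"] = phospho_series(tc, "Y1214")
    return {"series": series, "summary": {}}


def fig6(net=None) -> dict:
    """AUC comparison (first 60 min, 2 ng/mL, Vs vs Vb) by compartment."""
    from .observables import auc

    net = net or build_network()
    summary = {}
    for mode in ("soluble", "immobilized"):
        tag = "Vs" if mode == "soluble" else "Vb"
        tc = simulate(
            make_scenario("other", mode=mode, vegf_ng_ml=2.0, duration_s=3600.0),
            net,
        )
        for comp_label, comps in (
            ("surf", ["surf"]),
            ("rab45", ["rab45"]),
            ("total", None),
        ):
            summary[f"auc_pR2:{comp_label}:{tag}"] = auc(
                pR2_series(tc, compartments=comps)
            )
            summary[f"auc_pY1175:{comp_label}:{tag}"] = auc(
                phospho_series(tc, "Y1175", compartments=comps)
            )
            summary[f"auc_pY1214:{comp_label}:{tag}"] = auc(
                phospho_series(tc, "Y1214", compartments=comps)
            )
    return {"series": {}, "summary": summary}


def fig7(net=None) -> dict:
    """NRP1 knockout and surface-phosphatase overexpression panels."""
    net = net or build_network()
    series, summary = {}, {}
    for mode in ("soluble", "immobilized"):
        tag = "Vs" if mode == "soluble" else "Vb"
        for label, perts in (
            ("baseline", ()),
            ("no_nrp1", (Perturbation("nrp1_knockout"),)),
        ):
            tc = simulate(
                make_scenario("other", mode=mode, vegf_ng_ml=20.0,
                              duration_s=3600.0, perturbations=perts),
                net,
            )
            series[f"pR2:{tag}:{label}"] = pR2_series(tc)
            series[f"total_R2:{tag}:{label}"] = total_r2_series(tc)
            for comp in ("surf", "rab45", "rab11"):
                series[f"ligated:{comp}:{tag}:{label}"] = ligated_series(
                    tc, compartments=[comp]
                )
    for f in (2.0, 5.0, 10.0):
        tc = simulate(
            make_scenario(
                "other", mode="soluble", vegf_ng_ml=20.0, duration_s=1800.0,
                perturbations=(Perturbation("surface_phosphatase", f),),
            ),
            net,
        )
        for res in ("Y1175", "Y1214"):
            summary[f"peak_p{res}:x{f:g}"] = peak(phospho_series(tc, res))[1]
    return {"series": series, "summary": summary}


def fig8(net=None) -> dict:
    """k_off,V.M sweep at 5 min plus pY1214/pY1175 ratio curves."""
    net = net or build_network()
    series, summary = {}, {}
    sweep = (1e-4, 1e-3, 1e-2, 1e-1)
    for proto in koff_vm_sweep(sweep, vegf_ng_ml=20.0, duration_s=600.0):
        koff = proto.params.study.vm_koff
        tc = simulate(proto, net)
        t5 = 300.0
        for name, s in (
            ("pR2", pR2_series(tc)),
            ("pY1175", phospho_series(tc, "Y1175")),
            ("pY1214", phospho_series(tc, "Y1214")),
        ):
            summary[f"{name}@5min:koff={koff:g}"] = float(
                np.interp(t5, s.times, s.values)
            )
        r = ratio_series(phospho_series(tc, "Y1214"), phospho_series(tc, "Y1175"))
        summary[f"ratio1214_1175@5min:koff={koff:g}"] = float(
            np.interp(t5, r.times, r.values)
        )
    for mode in ("soluble", "immobilized"):
        tag = "Vs" if mode == "soluble" else "Vb"
        for conc in _CONCS:
            tc = simulate(
                make_scenario("other", mode=mode, vegf_ng_ml=conc,
                              duration_s=1800.0),
                net,
            )
            series[f"ratio1214_1175:{tag}:{conc:g}"] = ratio_series(
                phospho_series(tc, "Y1214"), phospho_series(tc, "Y1175")
            )
    return {"series": series, "summary": summary}


def s4(net=None) -> dict:
    """Rab11 dephosphorylation set equal to Rab4/5: effect on pR2/pY1175/pY1214."""
    net = net or build_network()
    series = {}
    for mode in ("soluble", "immobilized"):
        tag = "Vs" if mode == "soluble" else "Vb"
        for label, perts in (
            ("baseline", ()),
            ("rab11_eq_rab45", (Perturbation("rab11_kdp_equals_rab45"),)),
        ):
            tc = simulate(
                make_scenario("other", mode=mode, vegf_ng_ml=20.0,
                              duration_s=1800.0, perturbations=perts),
                net,
            )
            series[f"pR2:{tag}:{label}"] = pR2_series(tc)
            series[f"pY1175:{tag}:{label}"] = phospho_series(tc, "Y1175")
            series[f"pY1214:{tag}:{label}"] = phospho_series(tc, "Y1214")
    return {"series": series, "summary": {}}


def s5(net=None) -> dict:
    """Ligated-fraction-phosphorylated decomposition at 20 ng/mL (Vb)."""
    net = net or build_network()
    tc = simulate(
        make_scenario("other", mode="immobilized", vegf_ng_ml=20.0,
                      duration_s=1800.0),
        net,
    )
    summary = {}
    for t_min in (5.0, 15.0, 30.0):
        summary[f"ligated_frac_phospho:total@{t_min:g}min"] = (
            100.0 * ligated_fraction_phosphorylated(tc, t_min * 60.0)
        )
        for comp in ("surf", "rab45", "rab11"):
            v = ligated_fraction_phosphorylated(
                tc, t_min * 60.0, compartments=[comp]
            )
            summary[f"ligated_frac_phospho:{comp}@{t_min:g}min"] = (
                100.0 * v if np.isfinite(v) else None
            )
    return {"series": {}, "summary": summary}


FIGURES: dict[str, Callable] = {
    "fig2": fig2,
    "fig4ef": fig4ef,
    "fig5": fig5,
    "fig6": fig6,
    "fig7": fig7,
    "fig8": fig8,
    "s4": s4,
    "s5": s5,
}


def run_figure_scenario(figure_id: str, net=None) -> dict:
    """Execute a registered figure bundle; returns {'series', 'summary'}."""
    if figure_id not in FIGURES:
        raise KeyError(
            f"unknown figure id {figure_id!r}; registry: {sorted(FIGURES)}"
        )
    out = FIGURES[figure_id](net=net)
    out["frame"] = _series_frame(out["series"]) if out["series"] else pd.DataFrame()
    return out
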