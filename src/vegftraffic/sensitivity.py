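"""Local one-at-a-time sensitivity analysis.

Each selected parameter is doubled and halved; for every output in the
panel the absolute percent change from the unperturbed output is computed,
the two directions are averaged, and results can be aggregated over panel
subsets.  Tied parameter families (the published ratio relations between
species-specific trafficking rates) are perturbed as a unit so that the
published structure is preserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import FREE_TRAFFICKING, TRAFFICKING_TIES
from .network import Compartment, ReactionNetwork, build_network
from .observables import phospho_series, ratio_series
from .parameters import ParameterSet
from .scenarios import make_scenario
from .simulate import Protocol, SolverOptions, simulate

SENS_SOLVER = SolverOptions(method="BDF", rtol=1.0e-6, atol=1.0e-3)


@dataclass(frozen=True)
class PanelCondition:
    mode: str  # "soluble" | "immobilized"
    vegf_ng_ml: float

    @property
    def label(self) -> str:
        tag = "Vs" if self.mode == "soluble" else "Vb"
        return f"{tag}:{self.vegf_ng_ml:g}"


@dataclass(frozen=True)
class OutputSpec:
    observable: str  # "pY1175" | "pY1214" | "pY1214/pY1175"
    time_min: float

    @property
    def label(self) -> str:
        return f"{self.observable}@{self.time_min:g}min"


DEFAULT_OUTPUTS = tuple(
    OutputSpec(obs, t)
    for obs in ("pY1175", "pY1214", "pY1214/pY1175")
    for t in (5.0, 15.0, 30.0)
)
DEFAULT_CONDITIONS = tuple(
    PanelCondition(mode, v)
    for mode in ("soluble", "immobilized")
    for v in (2.0, 200.0)
)

#: Default parameter list: the directly-fit rate constants plus the initial
#: conditions called out in the results (receptor numbers and [V] are
#: covered through the panel conditions).
TRAFFICKING_PARAM_KEYS = tuple(
    f"traffic:{proc}:{form}" for proc, form in FREE_TRAFFICKING
) + ("traffic:int:R2", "traffic:int:V.R2")
DEPHOSPHO_PARAM_KEYS = tuple(
    f"kdp:{res}:{form}@{comp}"
    for res in ("Y951", "Y1175", "Y1214")
    for form in ("V.R2", "V.N1.R2")
    for comp in ("surf", "rab45")
)
INIT_PARAM_KEYS = ("init:R2", "init:N1")
DEFAULT_PARAM_KEYS = TRAFFICKING_PARAM_KEYS + DEPHOSPHO_PARAM_KEYS + INIT_PARAM_KEYS

#: The tied-children map for perturbing trafficking families as a unit.
_TIE_CHILDREN: dict[tuple[str, str], list[tuple[str, str]]] = {}
for child, (parent, _ratio) in TRAFFICKING_TIES.items():
    _TIE_CHILDREN.setdefault(parent, []).append(child)
_TIE_CHILDREN.setdefault(("int", "V.R2"), []).append(("int", "V.N1.R2"))
_TIE_CHILDREN.setdefault(("int", "R2"), []).extend(
    [("int", "N1"), ("int", "V.N1")]
)


def scale_parameter(params: ParameterSet, key: str, factor: float) -> ParameterSet:
    """Return a copy of ``params`` with one named parameter (and its tied
    family members) multiplied by ``factor``."""
    ps = params.copy()
    domain, _, rest = key.partition(":")
    if domain == "traffic":
        proc, form = rest.split(":")
        if (proc, form) not in ps.trafficking.rates:
            raise KeyError(key)
        family = [(proc, form)] + _TIE_CHILDREN.get((proc, form), [])
        for k in family:
            if k in ps.trafficking.rates:
                ps.trafficking.rates[k] *= factor
    elif domain == "kdp":
        res, _, loc = rest.partition(":")
        form, comp_name = loc.split("@")
        comp = Compartment(comp_name)
        k = (res, form, comp)
        ps.phospho.kdp[k] = ps.phospho.kdp[k] * factor
        if form == "V.R2" and comp is Compartment.SURFACE:
            # matrix-anchored receptor shares the surface V.R2 rates
            ps.phospho.kdp[(res, "M.V.R2", comp)] *= factor
    elif domain == "init":
        if rest == "R2":
            ps.study.r2_per_cell *= factor
        elif rest == "N1":
            ps.study.n1_per_cell *= factor
        elif rest == "V":
            ps.study.vegf_ng_ml *= factor
        else:
            raise KeyError(key)
    else:
        raise KeyError(key)
    return ps


@dataclass
class SensitivityResult:
    """Mean |percent change| per (parameter, condition x output)."""

    matrix: pd.DataFrame  # rows: parameter keys; columns: condition|output
    excluded: dict[str, int] = field(default_factory=dict)

    def mean_over(self, param_keys: Iterable[str],
                  columns: Optional[Iterable[str]] = None) -> float:
        sub = self.matrix.loc[list(param_keys)]
        if columns is not None:
            sub = sub[list(columns)]
        return float(np.nanmean(sub.to_numpy()))

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="parameter")


def _panel_outputs(
    params: ParameterSet,
    net: ReactionNetwork,
    condition: PanelCondition,
    outputs: Sequence[OutputSpec],
    duration_s: float,
) -> np.ndarray:
    proto = Protocol(
        params=params.copy(),
        mode=condition.mode,
        vegf_ng_ml=condition.vegf_ng_ml,
        duration_s=duration_s,
        n_grid=61,
    )
    tc = simulate(proto, net, solver=SENS_SOLVER)
    s1175 = phospho_series(tc, "Y1175")
    s1214 = phospho_series(tc, "Y1214")
    ratio = ratio_series(s1214, s1175)
    series = {"pY1175": s1175, "pY1214": s1214, "pY1214/pY1175": ratio}
    vals = []
    for spec in outputs:
        s = series[spec.observable]
        vals.append(float(np.interp(spec.time_min * 60.0, s.times, s.values)))
    return np.array(vals)


def local_sensitivity(
    base_params: Optional[ParameterSet] = None,
    param_keys: Sequence[str] = DEFAULT_PARAM_KEYS,
    conditions: Sequence[PanelCondition] = DEFAULT_CONDITIONS,
    outputs: Sequence[OutputSpec] = DEFAULT_OUTPUTS,
    factor: float = 2.0,
    net: Optional[ReactionNetwork] = None,
    scenario: str = "other",
    duration_s: float = 1800.0,
) -> SensitivityResult:
    """One-at-a-time +/- ``factor`` sensitivity over the output panel.

    Entries where the unperturbed output lies below 1e-3 % of baseline (the
    ratio floor) are excluded (NaN) and counted in ``excluded``.  A failed
    perturbed simulation flags the whole row for that condition (NaN) rather
    than being silently dropped.
    """
    net = net if net is not None else build_network()
    if base_params is None:
        base_params = make_scenario(scenario).params
    columns = [f"{c.label}|{o.label}" for c in conditions for o in outputs]
    mat = pd.DataFrame(
        np.nan, index=list(param_keys), columns=columns, dtype=float
    )
    excluded: dict[str, int] = {}
    base_vals: dict[PanelCondition, np.ndarray] = {}
    for cond in conditions:
        base_vals[cond] = _panel_outputs(
            base_params, net, cond, outputs, duration_s
        )
    for key in param_keys:
        for cond in conditions:
            base = base_vals[cond]
            changes = []
            for f in (factor, 1.0 / factor):
                try:
                    pert = _panel_outputs(
                        scale_parameter(base_params, key, f),
                        net,
                        cond,
                        outputs,
                        duration_s,
                    )
                except RuntimeError:
                    changes.append(np.full_like(base, np.nan))
                    continue
                with np.errstate(divide="ignore", invalid="ignore"):
                    pct = 100.0 * np.abs(pert - base) / np.abs(base)
                floor = np.abs(base) < 1.0e-3
                pct[floor] = np.nan
                excluded[key] = excluded.get(key, 0) + int(floor.sum())
                changes.append(pct)
            mean_change = np.nanmean(np.vstack(changes), axis=0)
            for o, v in zip(outputs, mean_change):
                mat.loc[key, f"{cond.label}|{o.label}"] = v
    return SensitivityResult(matrix=mat, excluded=excluded)
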