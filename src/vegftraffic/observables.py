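"""Model readouts computed from trajectories.

All phospho observables are normalized to the total VEGFR2 present in the
system at the pre-stimulus steady state (= 100%), the convention used for
every reported curve.  Compartment filters allow surface / Rab4/5 / Rab11
splits of each readout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .network import Compartment, LIGATED_FORMS, RESIDUES
from .simulate import TimeCourse

#: Compartments over which "total" receptor readouts are taken.
NON_DEGRADED = (Compartment.SURFACE, Compartment.RAB45, Compartment.RAB11)

#: Denominator floor for ratio observables, in % of baseline VEGFR2.
RATIO_FLOOR = 1.0e-3


@dataclass
class ObservableSeries:
    name: str
    times: np.ndarray  # seconds
    values: np.ndarray  # percent of baseline total VEGFR2 (or dimensionless)
    compartments: tuple[Compartment, ...] = NON_DEGRADED

    def resample(self, dt: float = 1.0, window: Optional[tuple] = None):
        lo, hi = (self.times[0], self.times[-1]) if window is None else window
        grid = np.arange(lo, hi + 0.5 * dt, dt)
        return grid, np.interp(grid, self.times, self.values)


def _norm(tc: TimeCourse) -> float:
    base = tc.baseline_total_r2
    if base <= 0:
        raise ValueError("baseline total VEGFR2 is zero; cannot normalize")
    return 100.0 / base


def _parse_compartments(
    compartments: Optional[Iterable[Compartment | str]],
) -> tuple[Compartment, ...]:
    if compartments is None:
        return NON_DEGRADED
    return tuple(Compartment(c) for c in compartments)


def total_r2_series(tc: TimeCourse, compartments=None) -> ObservableSeries:
    comps = _parse_compartments(compartments)
    vals = tc.group_series(
        lambda s: s.composition.has_R2 and s.compartment in comps
    )
    return ObservableSeries("total_R2", tc.times, vals * _norm(tc), comps)


def degraded_r2_series(tc: TimeCourse) -> ObservableSeries:
    vals = tc.group_series(
        lambda s: s.composition.has_R2 and s.compartment is Compartment.DEGRADED
    )
    return ObservableSeries(
        "degraded_R2", tc.times, vals * _norm(tc), (Compartment.DEGRADED,)
    )


def phospho_series(
    tc: TimeCourse, residue: str, compartments=None
) -> ObservableSeries:
    """VEGFR2 (ligated or free) phosphorylated on the given tyrosine."""
    if residue not in RESIDUES:
        raise ValueError(f"unknown residue {residue!r}; choose from {RESIDUES}")
    comps = _parse_compartments(compartments)
    vals = tc.group_series(
        lambda s: s.composition.has_R2
        and s.compartment in comps
        and s.phospho.has(residue)
    )
    return ObservableSeries(f"p{residue}", tc.times, vals * _norm(tc), comps)


def pR2_series(tc: TimeCourse, compartments=None) -> ObservableSeries:
    """VEGFR2 phosphorylated on at least one modeled tyrosine (union)."""
    comps = _parse_compartments(compartments)
    vals = tc.group_series(
        lambda s: s.composition.has_R2
        and s.compartment in comps
        and s.phospho.any()
    )
    return ObservableSeries("pR2", tc.times, vals * _norm(tc), comps)


def ligated_series(tc: TimeCourse, compartments=None) -> ObservableSeries:
    comps = _parse_compartments(compartments)
    vals = tc.group_series(
        lambda s: s.form in LIGATED_FORMS and s.compartment in comps
    )
    return ObservableSeries("ligated_R2", tc.times, vals * _norm(tc), comps)


def ligated_fraction_phosphorylated(
    tc: TimeCourse, t: float, compartments=None
) -> float:
    """Fraction of VEGF-bound VEGFR2 phosphorylated on >= 1 residue at time t.

    Returns ``nan`` when the ligated pool is below machine floor.
    """
    comps = _parse_compartments(compartments)
    lig = tc.value_at(
        t, lambda s: s.form in LIGATED_FORMS and s.compartment in comps
    )
    if lig < 1e-300 or lig < 1e-12 * tc.baseline_total_r2:
        return float("nan")
    phos = tc.value_at(
        t,
        lambda s: s.form in LIGATED_FORMS
        and s.compartment in comps
        and s.phospho.any(),
    )
    return phos / lig


def auc(
    series: ObservableSeries, window: tuple[float, float] = (0.0, 3600.0)
) -> float:
    """Trapezoidal area under the curve, in percent x minutes."""
    grid, vals = series.resample(dt=1.0, window=window)
    return float(np.trapezoid(vals, grid) / 60.0)


def ratio_series(a: ObservableSeries, b: ObservableSeries) -> ObservableSeries:
    """Pointwise a/b on a shared 1-s grid; undefined (nan) under the floor."""
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    grid = np.arange(lo, hi + 0.5, 1.0)
    va = np.interp(grid, a.times, a.values)
    vb = np.interp(grid, b.times, b.values)
    out = np.full_like(va, np.nan)
    ok = vb > RATIO_FLOOR
    out[ok] = va[ok] / vb[ok]
    return ObservableSeries(f"{a.name}/{b.name}", grid, out, a.compartments)


def peak(
    series: ObservableSeries, window: tuple[float, float] = (0.0, 3600.0)
) -> tuple[float, float]:
    """(t_peak, value) over a 1-s resampled grid within the window."""
    grid, vals = series.resample(dt=1.0, window=window)
    finite = np.isfinite(vals)
    if not finite.any():
        return float("nan"), float("nan")
    i = int(np.nanargmax(np.where(finite, vals, -np.inf)))
    return float(grid[i]), float(vals[i])


def summary(tc: TimeCourse) -> dict:
    """Peak/AUC digest of the standard readout panel for one trajectory."""
    out: dict = {}
    horizon = min(3600.0, float(tc.times[-1]))
    for name, series in (
        ("pR2", pR2_series(tc)),
        ("pY1175", phospho_series(tc, "Y1175")),
        ("pY1214", phospho_series(tc, "Y1214")),
        ("ligated_R2", ligated_series(tc)),
        ("total_R2", total_r2_series(tc)),
    ):
        t_pk, v_pk = peak(series, (0.0, horizon))
        out[name] = {
            "peak_t_min": t_pk / 60.0,
            "peak_pct": v_pk,
            "auc_pct_min": auc(series, (0.0, horizon)),
        }
    return out
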