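"""1-compartment comparator and PBPK-vs-1-compartment convergence analysis.

For a lipophilic solute whose metabolic time constant ``T_Cl = V / Cl``
is long compared with the adipose equilibration time constant, the late
plasma kinetics collapse onto the single exponential

    C(t) = (D / V) * exp(-t / T_Cl)

so the whole-body model is only needed for the initial distribution
transient.  ``convergence_analysis`` quantifies this: for a ladder of
``T_Cl`` values it measures the worst relative deviation between the PBPK
arterial concentration and the 1-compartment prediction after the adipose
transient has died out (t beyond ten slow-adipose time constants).  The
deviation shrinks monotonically as ``T_Cl`` grows, and "good prediction"
is operationalized as a late-time deviation of at most 10 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DoseRegimen, SoluteSpec, assemble_system, simulate
from .physiology import LIVER, PORTAL, BodyModel

__all__ = [
    "OneCompartment",
    "onecomp_concentration",
    "steady_state_volume",
    "adipose_transient_time",
    "convergence_analysis",
]


@dataclass(frozen=True)
class OneCompartment:
    """1-compartment model: dose ``D``, volume of distribution ``V`` (l),
    clearance ``Cl`` (l/min); ``t_cl = V / Cl`` is the elimination time
    constant in minutes."""

    dose: float
    volume_of_distribution: float
    clearance: float

    def __post_init__(self) -> None:
        for attr in ("dose", "volume_of_distribution", "clearance"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")

    @property
    def t_cl(self) -> float:
        return self.volume_of_distribution / self.clearance

    @classmethod
    def from_t_cl(cls, dose: float, volume_of_distribution: float, t_cl: float) -> "OneCompartment":
        return cls(dose, volume_of_distribution, volume_of_distribution / t_cl)


def onecomp_concentration(model: OneCompartment, t) -> np.ndarray | float:
    """``C(t) = (D / V) exp(-t / T_Cl)`` for ``t >= 0`` (min)."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    c = (model.dose / model.volume_of_distribution) * np.exp(-t / model.t_cl)
    return c if c.ndim else float(c)


def steady_state_volume(body: BodyModel, solute: SoluteSpec) -> float:
    """Whole-body steady-state distribution volume ``V_ss`` (l): the sum
    of all compartment capacities (partition-weighted tissue volumes plus
    the blood pools) of the assembled system."""
    clean = replace(solute, renal_clearance_fraction=0.0, hepatic_clearance_fraction=0.0)
    system = assemble_system(body, clean)
    return float(system.capacities.sum())


def adipose_transient_time(body: BodyModel, solute: SoluteSpec) -> float:
    """Slowest adipose equilibration time constant ``K / perfusion`` (min),
    the scale of the distribution transient for a lipophilic solute."""
    system = assemble_system(
        body, replace(solute, renal_clearance_fraction=0.0, hepatic_clearance_fraction=0.0)
    )
    taus = [
        system.partitions[name] / body.organ(name).perfusion
        for name in body.adipose_names
        if body.organ(name).perfusion > 0
    ]
    if not taus:
        raise ValueError("body has no perfused adipose compartment")
    return max(taus)


def convergence_analysis(
    body: BodyModel,
    solute: SoluteSpec,
    dose: DoseRegimen,
    t_cl_values: Sequence[float],
    *,
    late_factor: float = 10.0,
    horizon_factor: float = 2.0,
    n_points: int = 300,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Late-time divergence between the PBPK model and its matched
    1-compartment reduction, for each metabolic time constant.

    For each ``T_Cl`` (min) the hepatic clearance fraction is set so that
    the systemic clearance is ``Cl = V_ss / T_Cl``; a bolus is simulated
    and the maximum relative deviation
    ``|C_1c - C_pbpk| / C_pbpk`` is taken over the late window
    ``t in [late_factor * T_adipose, late_factor * T_adipose +
    horizon_factor * T_Cl]``.  Returns a DataFrame with columns
    ``t_cl_min``, ``max_rel_dev_late``, ``time_to_5pct`` (the earliest
    time from which the deviation stays below 5 %; NaN if never).
    """
    if solute.mode != "hls":
        raise ValueError("convergence_analysis is defined for HLS solutes")
    if dose.total_bolus <= 0:
        raise ValueError("convergence_analysis requires a bolus dose")

    v_ss = steady_state_volume(body, solute)
    t_adipose = adipose_transient_time(body, solute)
    liver_flow = body.organ(LIVER).blood_flow + body.organ(PORTAL).blood_flow

    rows = []
    for t_cl in t_cl_values:
        if t_cl <= 0:
            raise ValueError("t_cl values must be > 0")
        cl = v_ss / t_cl
        frac = cl / liver_flow
        if frac >= 1.0:
            raise ValueError(
                f"T_Cl = {t_cl} min requires clearance {cl:.3g} l/min, exceeding the "
                f"{liver_flow:.3g} l/min liver flow"
            )
        sol = replace(solute, hepatic_clearance_fraction=frac, renal_clearance_fraction=0.0)
        w0 = late_factor * t_adipose
        w1 = w0 + horizon_factor * t_cl
        grid = np.unique(
            np.concatenate([np.linspace(0.0, w0, 41), np.linspace(w0, w1, n_points)])
        )
        res = simulate(body, sol, dose, grid, rtol=rtol)
        comp = OneCompartment.from_t_cl(dose.total_bolus, v_ss, t_cl)
        c1 = onecomp_concentration(comp, res.times)
        window = res.times >= w0
        c_pbpk = res.arterial[window]
        if np.any(c_pbpk <= 0):
            raise RuntimeError("PBPK arterial concentration vanished inside the late window")
        dev = np.abs(c1[window] - c_pbpk) / c_pbpk
        below = dev <= 0.05
        # earliest time from which the deviation stays below 5 %
        tail_ok = np.flip(np.logical_and.accumulate(np.flip(below)))
        t5 = float(res.times[window][tail_ok][0]) if tail_ok.any() else math.nan
        rows.append(
            {
                "t_cl_min": float(t_cl),
                "max_rel_dev_late": float(dev.max()),
                "time_to_5pct": t5,
            }
        )
    return pd.DataFrame(rows)
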