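"""Circulation ODE assembly and integration.

Every compartment is well-stirred.  A flow-limited organ obeys

    V_i dC_i/dt = F_i (C_in - C_i)

where ``C_i`` is the venous (equilibrated) concentration leaving the organ
and ``V_i`` its effective distribution volume (partition coefficient times
anatomic volume).  The circulation closes vein -> lung -> artery ->
parallel tissues -> vein, with the portal bed's effluent perfusing the
liver.  For extracellular solutes the same equations run on plasma flows
and extracellular distribution volumes; a capillary-permeability-limited
organ exchanges only the single-pass extraction fraction ``fclr`` of its
plasma flow, its effluent being the flow-weighted mix
``(1 - fclr) C_arterial + fclr C_tissue``.  For volatile solutes the
state variables are partial pressures and an alveolar gas store with
continuous ventilation is inserted between vein and lung.

Clearance placement: renal clearance removes ``Cl_renal * C_arterial``
from the kidney's vein-bound effluent ("fraction of renal plasma
cleared"), which makes the steady-state infusion identity
``C_arterial = rate / clearance`` exact.  Hepatic clearance acts on the
well-mixed liver concentration (extraction on the combined hepatic-artery
plus portal outflow).

The assembled system is linear and time-invariant between dose events, but
spans rate constants from sub-minute (kidney, lung) to multi-day (slow
adipose), so it is integrated with a stiff implicit method (BDF) with the
exact constant Jacobian supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import physiology as phys
from .partition import EcsParams, HlsParams, ecs_partition, hls_partition
from .physiology import ARTERY, BRAIN, KIDNEY, LIVER, LUNG, PORTAL, VEIN, BodyModel, cardiac_output
from .volatile import VolatileParams, volatile_tissue_air_partition, volatile_tissue_blood_partition

__all__ = [
    "SoluteSpec",
    "DoseEvent",
    "DoseRegimen",
    "PbpkSystem",
    "SimResult",
    "SolverError",
    "Clearances",
    "compute_partitions",
    "compute_clearance",
    "assemble_system",
    "simulate",
    "total_amount",
]

ALVEOLAR = "alveolar"

MODES = ("hls", "ecs", "volatile")


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails; carries the solver diagnostic."""


@dataclass(frozen=True)
class SoluteSpec:
    """A solute: its class (mode) plus the matching parameter block and
    fractional clearances.

    ``renal_clearance_fraction`` is the fraction of renal plasma cleared
    per pass; ``hepatic_clearance_fraction`` the fractional extraction of
    the combined liver blood (or plasma) flow.
    """

    name: str
    mode: str
    hls: HlsParams | None = None
    ecs: EcsParams | None = None
    volatile: VolatileParams | None = None
    renal_clearance_fraction: float = 0.0
    hepatic_clearance_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got '{self.mode}'")
        blocks = {"hls": self.hls, "ecs": self.ecs, "volatile": self.volatile}
        populated = [m for m, b in blocks.items() if b is not None]
        if populated != [self.mode]:
            raise ValueError(
                f"exactly the '{self.mode}' parameter block must be populated, got {populated or 'none'}"
            )
        for attr in ("renal_clearance_fraction", "hepatic_clearance_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0,1], got {v}")

    @property
    def params(self):
        return {"hls": self.hls, "ecs": self.ecs, "volatile": self.volatile}[self.mode]


@dataclass(frozen=True)
class DoseEvent:
    """One dosing event.

    ``bolus``: ``amount`` delivered into the vein at ``start``.
    ``infusion``: constant ``rate`` (amount/min) into the vein over
    [``start``, ``stop``).  ``inhalation``: constant inspired partial
    pressure (fraction of 1 atm) over [``start``, ``stop``).
    """

    kind: str
    start: float
    amount: float | None = None
    rate: float | None = None
    stop: float | None = None
    inspired_partial_pressure: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "infusion", "inhalation"):
            raise ValueError(f"unknown dose kind '{self.kind}'")
        if self.start < 0:
            raise ValueError("event start must be >= 0")
        if self.kind == "bolus":
            if self.amount is None or self.amount < 0:
                raise ValueError("bolus requires amount >= 0")
        else:
            if self.stop is None or self.stop <= self.start:
                raise ValueError(f"{self.kind} requires stop > start")
            if self.kind == "infusion" and (self.rate is None or self.rate < 0):
                raise ValueError("infusion requires rate >= 0")
            if self.kind == "inhalation" and (
                self.inspired_partial_pressure is None or self.inspired_partial_pressure < 0
            ):
                raise ValueError("inhalation requires inspired_partial_pressure >= 0")


@dataclass(frozen=True)
class DoseRegimen:
    """Ordered collection of dose events on the time axis."""

    events: tuple[DoseEvent, ...] = ()

    def __post_init__(self) -> None:
        starts = [ev.start for ev in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("events must be ordered by start time")

    @classmethod
    def bolus(cls, amount: float, time: float = 0.0) -> "DoseRegimen":
        return cls((DoseEvent("bolus", start=time, amount=amount),))

    @classmethod
    def infusion(cls, rate: float, start: float, stop: float) -> "DoseRegimen":
        return cls((DoseEvent("infusion", start=start, stop=stop, rate=rate),))

    @classmethod
    def inhalation(cls, inspired_partial_pressure: float, start: float, stop: float) -> "DoseRegimen":
        return cls(
            (
                DoseEvent(
                    "inhalation",
                    start=start,
                    stop=stop,
                    inspired_partial_pressure=inspired_partial_pressure,
                ),
            )
        )

    @property
    def total_bolus(self) -> float:
        return sum(ev.amount for ev in self.events if ev.kind == "bolus")

    def breakpoints(self) -> list[float]:
        pts: set[float] = set()
        for ev in self.events:
            pts.add(ev.start)
            if ev.stop is not None:
                pts.add(ev.stop)
        return sorted(pts)

    def infusion_rate(self, t: float) -> float:
        return sum(
            ev.rate
            for ev in self.events
            if ev.kind == "infusion" and ev.start <= t < ev.stop
        )

    def inspired_pressure(self, t: float) -> float:
        return sum(
            ev.inspired_partial_pressure
            for ev in self.events
            if ev.kind == "inhalation" and ev.start <= t < ev.stop
        )


@dataclass(frozen=True)
class Clearances:
    """Absolute clearances, l/min (plasma-referenced for renal)."""

    renal: float
    hepatic: float

    @property
    def total(self) -> float:
        return self.renal + self.hepatic


def compute_partitions(body: BodyModel, solute: SoluteSpec) -> dict[str, float]:
    """Per-organ partition coefficients for every exchanging organ.

    HLS/volatile: tissue/blood partition from the organ lipid fraction.
    ECS: interstitial/plasma partition from the organ albumin ratio (the
    brain value is returned but acts on its zero interstitium).
    """
    if solute.params is None:
        raise ValueError(f"solute '{solute.name}' is missing its {solute.mode} parameter block")
    out: dict[str, float] = {}
    for organ in body.exchanging_organs():
        if solute.mode == "hls":
            out[organ.name] = hls_partition(
                solute.hls.p_lw, organ.lipid_fraction, solute.hls.effective_f_l_blood
            )
        elif solute.mode == "volatile":
            out[organ.name] = volatile_tissue_blood_partition(organ.lipid_fraction, solute.volatile)
        else:
            if organ.k_alb is None:
                continue
            out[organ.name] = ecs_partition(solute.ecs.f_p, organ.k_alb)
    return out


def compute_clearance(body: BodyModel, solute: SoluteSpec) -> Clearances:
    """Absolute renal and hepatic clearances in l/min.

    Renal: fraction x kidney plasma flow (weight x perfusion x (1 - Hct)).
    Hepatic: fraction x total liver flow (hepatic artery + portal
    outflow), on whole blood for HLS/volatile and on plasma for ECS.
    """
    kidney = body.organ(KIDNEY)
    renal = solute.renal_clearance_fraction * kidney.blood_flow * (1.0 - body.hematocrit)
    liver_flow = body.organ(LIVER).blood_flow + body.organ(PORTAL).blood_flow
    if solute.mode == "ecs":
        liver_flow *= 1.0 - body.hematocrit
    hepatic = solute.hepatic_clearance_fraction * liver_flow
    return Clearances(renal=renal, hepatic=hepatic)


@dataclass
class PbpkSystem:
    """Assembled linear circulation system ``dx/dt = A x + input``.

    ``capacities[i]`` is the effective volume (or gas capacity, for
    volatile partial-pressure states) of state ``i``: the stored amount is
    ``capacities @ x``.  ``clearance_vector @ x`` is the instantaneous
    cleared rate, including expired gas for volatile solutes.
    """

    body: BodyModel
    solute: SoluteSpec
    state_names: list[str]
    capacities: np.ndarray
    A: np.ndarray
    clearance_vector: np.ndarray
    partitions: dict[str, float]
    mode: str
    permeability_limited: bool
    flow_factor: float
    passthrough_organs: tuple[str, ...] = ()

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    @property
    def dose_index(self) -> int:
        return self.index(VEIN)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def slowest_time_constant(self) -> float:
        """Terminal time constant (min): -1 / (least-negative eigenvalue)."""
        lam = np.linalg.eigvals(self.A)
        re = lam.real[lam.real < -1e-300]
        if re.size == 0:
            return np.inf
        return float(-1.0 / re.max())


def _fclr_table(body: BodyModel, ecs: EcsParams) -> dict[str, float]:
    base = 1.0 if ecs.fclr_muscle is None else ecs.fclr_muscle
    ratios = dict(ecs.fclr_ratios or {})
    out = {}
    for organ in body.exchanging_organs():
        f = base * ratios.get(organ.name, 1.0)
        out[organ.name] = min(f, 1.0)
    return out


def assemble_system(
    body: BodyModel,
    solute: SoluteSpec,
    *,
    permeability_limited: bool | None = None,
) -> PbpkSystem:
    """Build the circulation matrix for a body/solute pair.

    ``permeability_limited`` selects the capillary-exchange code path for
    ECS solutes; by default it is enabled exactly when the solute carries
    a finite ``fclr_muscle``.  Inconsistent mode/parameter combinations
    fail here, not during integration.
    """
    mode = solute.mode
    partitions = compute_partitions(body, solute)
    clear = compute_clearance(body, solute)

    if permeability_limited is None:
        permeability_limited = mode == "ecs" and solute.ecs.fclr_muscle is not None
    if permeability_limited and mode != "ecs":
        raise ValueError("permeability-limited exchange applies to ECS solutes only")

    hct = body.hematocrit
    if mode == "hls":
        flow_factor = 1.0
    elif mode == "ecs":
        flow_factor = 1.0 - hct
    else:
        flow_factor = solute.volatile.k_blood_air

    co = cardiac_output(body) * flow_factor

    # --- states, in parameter-table order, plus the alveolar gas store ---
    names: list[str] = []
    caps: list[float] = []
    passthrough: list[str] = []
    for organ in body.organs:
        if organ.name in (VEIN, ARTERY):
            if mode == "hls":
                cap = organ.volume
            elif mode == "ecs":
                cap = organ.volume * (1.0 - hct)
            else:
                cap = organ.volume * solute.volatile.k_blood_air
            names.append(organ.name)
            caps.append(cap)
            continue
        if organ.perfusion == 0.0:
            continue  # inert mass (bone): weight only, no exchange
        if mode == "hls":
            cap = partitions[organ.name] * organ.volume
        elif mode == "ecs":
            if organ.name not in partitions:
                continue
            cap = partitions[organ.name] * organ.ecf_fraction * organ.volume
            if cap == 0.0:
                # no interstitium and no per-organ plasma pool: blood
                # transits unchanged (brain for ECS solutes)
                passthrough.append(organ.name)
                continue
        else:
            cap = volatile_tissue_air_partition(organ.lipid_fraction, solute.volatile) * organ.volume
        names.append(organ.name)
        caps.append(cap)
    if mode == "volatile":
        names.append(ALVEOLAR)
        caps.append(solute.volatile.alveolar_volume)

    n = len(names)
    idx = {name: i for i, name in enumerate(names)}
    cap = np.asarray(caps, float)
    A = np.zeros((n, n))
    cvec = np.zeros(n)

    fclr = _fclr_table(body, solute.ecs) if (mode == "ecs" and permeability_limited) else None

    def f_organ(name: str) -> float:
        o = body.organ(name)
        return o.weight * o.perfusion * flow_factor

    i_vein, i_art = idx[VEIN], idx[ARTERY]
    i_lung = idx.get(LUNG)
    i_liver, i_portal = idx.get(LIVER), idx.get(PORTAL)

    # --- parallel tissues -----------------------------------------------
    for organ in body.parallel_organs():
        name = organ.name
        if name in passthrough:
            # vein receives the arterial concentration unchanged
            A[i_vein, i_art] += f_organ(name) / cap[i_vein]
            continue
        i = idx[name]
        F = f_organ(name)
        e = 1.0 if fclr is None else fclr[name]
        if name == LIVER:
            continue  # handled below with the portal series path
        # uptake:  cap_i dC_i/dt = e * F * (C_art - C_i)
        A[i, i_art] += e * F / cap[i]
        A[i, i] -= e * F / cap[i]
        if name == PORTAL:
            # effluent feeds the liver, not the vein
            continue
        # effluent to vein: F * ((1 - e) C_art + e C_i)
        A[i_vein, i_art] += (1.0 - e) * F / cap[i_vein]
        A[i_vein, i] += e * F / cap[i_vein]

    # --- portal -> liver series path ------------------------------------
    if i_liver is not None:
        F_ha = f_organ(LIVER)
        F_po = f_organ(PORTAL)
        F_liv = F_ha + F_po
        e_l = 1.0 if fclr is None else fclr[LIVER]
        e_p = 1.0 if fclr is None else fclr[PORTAL]
        # liver inflow concentration is the flow-weighted mix of hepatic
        # artery blood and portal effluent (1 - e_p) C_art + e_p C_portal
        w_art = (F_ha + (1.0 - e_p) * F_po) / F_liv
        A[i_liver, i_art] += e_l * F_liv * w_art / cap[i_liver]
        A[i_liver, i_portal] += e_l * F_po * e_p / cap[i_liver]
        A[i_liver, i_liver] -= e_l * F_liv / cap[i_liver]
        # liver effluent to vein: F_liv ((1 - e_l) C_in + e_l C_liver)
        A[i_vein, i_art] += (1.0 - e_l) * F_liv * w_art / cap[i_vein]
        A[i_vein, i_portal] += (1.0 - e_l) * F_po * e_p / cap[i_vein]
        A[i_vein, i_liver] += e_l * F_liv / cap[i_vein]
        if clear.hepatic > 0.0:
            # extraction on the well-mixed liver concentration
            A[i_liver, i_liver] -= clear.hepatic / cap[i_liver]
            cvec[i_liver] += clear.hepatic

    # --- renal clearance: intercepts the kidney effluent, indexed to the
    # arterial (inflow) concentration ------------------------------------
    if clear.renal > 0.0:
        cl = clear.renal * (flow_factor if mode == "volatile" else 1.0)
        if mode == "hls":
            # blood-referenced approximation for lipophilic solutes
            cl = clear.renal
        A[i_vein, i_art] -= cl / cap[i_vein]
        cvec[i_art] += cl

    # --- vein outflow, lung, artery (and alveolar store) ----------------
    A[i_vein, i_vein] -= co / cap[i_vein]
    e_lung = 1.0 if fclr is None else fclr[LUNG]
    if mode == "volatile":
        i_alv = idx[ALVEOLAR]
        vent = solute.volatile.ventilation
        v_alv = solute.volatile.alveolar_volume
        # V_alv dP_alv/dt = Vent (P_insp - P_alv) + CO k_bair (P_vein - P_alv)
        A[i_alv, i_alv] -= (vent + co) / v_alv
        A[i_alv, i_vein] += co / v_alv
        cvec[i_alv] += vent  # expired gas
        upstream = i_alv
    else:
        upstream = i_vein
    if i_lung is not None:
        A[i_lung, upstream] += e_lung * co / cap[i_lung]
        A[i_lung, i_lung] -= e_lung * co / cap[i_lung]
        A[i_art, upstream] += (1.0 - e_lung) * co / cap[i_art]
        A[i_art, i_lung] += e_lung * co / cap[i_art]
    else:
        A[i_art, upstream] += co / cap[i_art]
    A[i_art, i_art] -= co / cap[i_art]

    return PbpkSystem(
        body=body,
        solute=solute,
        state_names=names,
        capacities=cap,
        A=A,
        clearance_vector=cvec,
        partitions=partitions,
        mode=mode,
        permeability_limited=bool(permeability_limited),
        flow_factor=flow_factor,
        passthrough_organs=tuple(passthrough),
    )


@dataclass
class SimResult:
    """Simulation output on the requested time grid.

    ``data`` holds one column per state (parameter-table order), plus
    ``cleared`` (cumulative amount removed) and ``dosed`` (cumulative
    amount delivered).  Volatile runs add ``p_inspired`` and
    ``expired_over_inspired``.  Concentration units follow the dose units
    per liter (partial pressure in atm for volatile).
    """

    times: np.ndarray
    data: pd.DataFrame
    system: PbpkSystem

    @property
    def mode(self) -> str:
        return self.system.mode

    @property
    def state_names(self) -> list[str]:
        return self.system.state_names

    @property
    def arterial(self) -> np.ndarray:
        return self.data[ARTERY].to_numpy()

    @property
    def venous(self) -> np.ndarray:
        return self.data[VEIN].to_numpy()

    @property
    def cleared(self) -> np.ndarray:
        return self.data["cleared"].to_numpy()

    @property
    def dosed(self) -> np.ndarray:
        return self.data["dosed"].to_numpy()

    def organ(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    @property
    def expired_over_inspired(self) -> np.ndarray:
        if self.mode != "volatile":
            raise ValueError("expired_over_inspired is defined for volatile runs only")
        return self.data["expired_over_inspired"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "time_min", self.times)
        out.to_csv(path, index=False)


def simulate(
    body: BodyModel,
    solute: SoluteSpec,
    dose: DoseRegimen,
    time_grid: Sequence[float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "BDF",
    permeability_limited: bool | None = None,
) -> SimResult:
    """Integrate the assembled circulation over ``time_grid``.

    Dose-event start/stop times are honored as integration breakpoints;
    boluses are applied as instantaneous jumps of the vein state.  Solver
    failure raises :class:`SolverError` with the integrator diagnostic.
    """
    system = assemble_system(body, solute, permeability_limited=permeability_limited)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("time_grid must be a strictly increasing 1-D array of length >= 2")
    for ev in dose.events:
        if system.mode == "volatile" and ev.kind != "inhalation":
            raise ValueError(f"volatile mode accepts inhalation events only, got '{ev.kind}'")
        if system.mode != "volatile" and ev.kind == "inhalation":
            raise ValueError(f"inhalation dosing requires volatile mode, not '{system.mode}'")
        if ev.start < t[0]:
            raise ValueError(f"dose event at t={ev.start} precedes the time grid start {t[0]}")

    n = system.n_states
    # augmented states: [concentrations, cumulative cleared, cumulative dosed]
    a_aug = np.zeros((n + 2, n + 2))
    a_aug[:n, :n] = system.A
    a_aug[n, :n] = system.clearance_vector

    breaks = sorted({t[0], t[-1], *(b for b in dose.breakpoints() if t[0] < b < t[-1])})
    boluses: dict[float, float] = {}
    for ev in dose.events:
        if ev.kind == "bolus" and ev.start <= t[-1]:
            boluses[ev.start] = boluses.get(ev.start, 0.0) + ev.amount
            if ev.start not in breaks:
                breaks.append(ev.start)
    breaks = sorted(breaks)

    x = np.zeros(n + 2)
    cap_vein = system.capacities[system.dose_index]
    out = np.empty((t.size, n + 2))
    filled = np.zeros(t.size, dtype=bool)

    def apply_bolus(time: float) -> None:
        if time in boluses:
            amt = boluses.pop(time)
            x[system.dose_index] += amt / cap_vein
            x[n + 1] += amt

    def jac(_t, _x):
        return a_aug

    for a, b in zip(breaks[:-1], breaks[1:]):
        apply_bolus(a)
        rate = dose.infusion_rate(0.5 * (a + b))
        u = np.zeros(n + 2)
        if system.mode == "volatile":
            pinsp = dose.inspired_pressure(0.5 * (a + b))
            vent = solute.volatile.ventilation
            u[system.index(ALVEOLAR)] = vent * pinsp / solute.volatile.alveolar_volume
            u[n + 1] = vent * pinsp
        else:
            u[system.dose_index] = rate / cap_vein
            u[n + 1] = rate

        def rhs(_t, y, _u=u):
            return a_aug @ y + _u

        # record grid points at the segment start (post-bolus)
        at_start = np.isclose(t, a, rtol=0.0, atol=1e-12)
        out[at_start] = x
        filled |= at_start

        inside = (t > a) & (t <= b) & ~filled
        t_eval = t[inside]
        sol = solve_ivp(
            rhs,
            (a, b),
            x,
            method=method,
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
            jac=jac,
        )
        if not sol.success:
            raise SolverError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        if t_eval.size:
            out[inside] = sol.y[:, : t_eval.size].T if sol.t.size == t_eval.size else sol.y.T
            filled |= inside
        x = sol.y[:, -1].copy()
    apply_bolus(t[-1])
    at_end = np.isclose(t, t[-1], rtol=0.0, atol=1e-12)
    out[at_end] = x

    data = pd.DataFrame(out[:, :n], columns=system.state_names)
    data["cleared"] = out[:, n]
    data["dosed"] = out[:, n + 1]
    if system.mode == "volatile":
        pinsp = np.array([dose.inspired_pressure(ti) for ti in t])
        data["p_inspired"] = pinsp
        p_alv = data[ALVEOLAR].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pinsp > 0, p_alv / np.where(pinsp > 0, pinsp, 1.0), np.nan)
        data["expired_over_inspired"] = ratio
    return SimResult(times=t, data=data, system=system)


def total_amount(result: SimResult) -> np.ndarray:
    """Total solute accounted for at each time: stored in compartments
    plus cumulatively cleared.  Constant (equal to the cumulative dose)
    once dosing has ended, to within solver tolerance, for any regimen."""
    states = result.data[result.state_names].to_numpy()
    return states @ result.system.capacities + result.cleared
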