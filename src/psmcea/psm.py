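"""Three-state partitioned survival model (PSM) with cost and QALY accrual.

State occupancy is read directly off the two survival curves each cycle:
progression-free = min(S_PFS, S_OS), progressed = S_OS - progression-free,
dead = 1 - S_OS.  Costs (drug acquisition, administration, follow-up,
adverse-event management, subsequent therapy) and utilities accrue per
42-day cycle with annual discounting, and strategies are compared via
the incremental cost-effectiveness ratio (ICER).

Dosing conventions
------------------
Drug doses are expressed per administration on one of three bases:
``per_m2`` (x body surface area), ``per_kg`` (x weight) or ``flat``.
Protocol schedules map onto the 42-day model cycle as 2 administrations
for every-3-week drugs, 3 for every-2-week drugs and 6 for weekly drugs.
First-line acquisition and administration costs accrue only on the
progression-free occupancy (treat to progression); per-drug caps on the
total number of administrations are honored by cycle index (e.g. 35
doses every 3 weeks exhausts in the middle of cycle 18).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .units import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "DrugComponent",
    "StrategySpec",
    "CohortTrace",
    "ArmOutcome",
    "CEResult",
    "discount_factor",
    "build_trace",
    "regimen_cost_per_admin",
    "ae_burden",
    "accrue_outcomes",
    "icer",
    "CEModel",
    "first_line_strategy",
    "subsequent_cycle_cost",
    "pap_cycle_cost",
]

AE_NAMES = ("diarrhoea", "anaemia", "hypokalaemia", "neutropenia")
SUBSEQUENT_CLASSES = ("pembrolizumab", "other_ici", "chemotherapy", "vegf", "egfr")


@dataclass
class ModelParams:
    """Complete parameter set of the decision model (Table-1 style)."""

    cycle_length_days: float = 42.0
    discount_rate: float = 0.05
    wtp: float = 38142.56
    horizon_threshold: float = 0.01  # stop when OS drops below this
    horizon_cap_years: float = 40.0
    bsa: float = 1.80  # m^2
    weight_kg: float = 65.0
    u_pfs: float = 0.7825
    u_pd: float = 0.64
    # AE incidence per arm; cost and disutility shared across arms
    ae_incidence: Dict[str, Dict[str, float]] = field(default_factory=dict)
    ae_cost: Dict[str, float] = field(default_factory=dict)
    ae_disutility: Dict[str, float] = field(default_factory=dict)  # negative
    prices: Dict[str, float] = field(default_factory=dict)  # USD per mg
    admin_cost: float = 310.16  # USD per attendance
    followup_cost: float = 31.33  # USD per cycle, while alive
    bsc_cost: float = 0.0  # USD per cycle (best supportive care)
    firstline_mix_C: Dict[str, float] = field(default_factory=dict)
    subsequent_mix: Dict[str, Dict[str, float]] = field(default_factory=dict)
    pap_enabled: bool = False
    pap_annual_cost: float = 11200.0
    pap_cap: float = 22400.0
    ici_cap_cycles: float = 2 * DAYS_PER_YEAR / 42.0  # ~17.4 cycles (2 years)
    integration: str = "trapezoid"  # or "end"

    def validate(self) -> None:
        if not 0 <= self.discount_rate <= 0.08:
            raise ValueError(f"discount_rate {self.discount_rate} outside [0, 0.08]")
        for nm in ("u_pfs", "u_pd"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm}={v} outside [0, 1]")
        for arm, entries in self.ae_incidence.items():
            for ae, inc in entries.items():
                if not 0 <= inc <= 1:
                    raise ValueError(f"ae_incidence.{arm}.{ae}={inc} outside [0, 1]")
        for nm, d in (("ae_cost", self.ae_cost), ("prices", self.prices)):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{nm}.{k}={v} negative")
        for mix_name, mix in [("firstline_mix_C", self.firstline_mix_C)] + [
            (f"subsequent_mix.{a}", m) for a, m in self.subsequent_mix.items()
        ]:
            if mix:
                tot = sum(mix.values())
                if abs(tot - 1.0) > 1e-6:
                    logger.info("renormalizing %s (weights summed to %.6f)",
                                mix_name, tot)
                    for k in mix:
                        mix[k] /= tot
        if self.ici_cap_cycles < 0:
            raise ValueError("ici_cap_cycles must be >= 0")

    def ae_set(self, arm: str) -> List[dict]:
        """(incidence, cost, disutility) triples for one arm."""
        out = []
        for ae in AE_NAMES:
            out.append(
                {
                    "name": ae,
                    "incidence": self.ae_incidence.get(arm, {}).get(ae, 0.0),
                    "cost": self.ae_cost.get(ae, 0.0),
                    "disutility": self.ae_disutility.get(ae, 0.0),
                }
            )
        return out

    # -- generic parameter addressing (used by sensitivity analyses) ------
    def set_value(self, pid: str, value: float) -> None:
        """Set the parameter addressed by ``pid`` in place."""
        parts = pid.split(".")
        head = parts[0]
        if head in {"discount_rate", "bsa", "weight_kg", "u_pfs", "u_pd",
                    "admin_cost", "followup_cost", "bsc_cost"}:
            setattr(self, head, value)
        elif head == "price":
            self.prices[parts[1]] = value
        elif head == "ae_incidence":
            self.ae_incidence[parts[1]][parts[2]] = value
        elif head == "ae_cost":
            self.ae_cost[parts[1]] = value
        elif head == "ae_disutility":
            self.ae_disutility[parts[1]] = value
        elif head == "subsequent_mix":
            self.subsequent_mix[parts[1]][parts[2]] = value
        else:
            raise KeyError(f"unknown parameter id {pid!r}")

    def with_value(self, pid: str, value: float) -> "ModelParams":
        """Return a copy with the parameter addressed by ``pid`` set."""
        new = copy.deepcopy(self)
        new.set_value(pid, value)
        return new

    def get_value(self, pid: str) -> float:
        parts = pid.split(".")
        head = parts[0]
        if head in {"discount_rate", "bsa", "weight_kg", "u_pfs", "u_pd",
                    "admin_cost", "followup_cost", "bsc_cost"}:
            return getattr(self, head)
        if head == "price":
            return self.prices[parts[1]]
        if head == "ae_incidence":
            return self.ae_incidence[parts[1]][parts[2]]
        if head == "ae_cost":
            return self.ae_cost[parts[1]]
        if head == "ae_disutility":
            return self.ae_disutility[parts[1]]
        if head == "subsequent_mix":
            return self.subsequent_mix[parts[1]][parts[2]]
        raise KeyError(f"unknown parameter id {pid!r}")


@dataclass(frozen=True)
class DrugComponent:
    """One drug within a regimen; dose in mg per basis unit per
    administration."""

    drug: str
    basis: str  # per_m2 | per_kg | flat
    dose: float
    admins_per_cycle: int
    max_admins: Optional[int] = None
    cycle1_extra_dose: float = 0.0  # loading, same basis, cycle 1 only


@dataclass(frozen=True)
class StrategySpec:
    arm: str
    components: Tuple[DrugComponent, ...]
    attendances_per_cycle: int


Mixture = Sequence[Tuple[float, StrategySpec]]

# Standard regimen building blocks (doses per administration).
_FOLFOX_BACKBONE = (
    DrugComponent("oxaliplatin", "per_m2", 85.0, 3),
    DrugComponent("leucovorin", "per_m2", 400.0, 3),
    DrugComponent("fluorouracil", "per_m2", 2800.0, 3),  # 400 bolus + 2400 infusion
)
_FOLFIRI_BACKBONE = (
    DrugComponent("irinotecan", "per_m2", 180.0, 3),
    DrugComponent("leucovorin", "per_m2", 400.0, 3),
    DrugComponent("fluorouracil", "per_m2", 2800.0, 3),
)
_BEV = DrugComponent("bevacizumab", "per_kg", 5.0, 3)
_CET = DrugComponent("cetuximab", "per_m2", 250.0, 6, cycle1_extra_dose=150.0)


def first_line_strategy(arm: str, params: ModelParams) -> Union[StrategySpec, Mixture]:
    """First-line treatment spec: pembrolizumab 200 mg q3w (max 35
    doses) for arm P; the six-regimen chemotherapy mixture for arm C."""
    if arm == "P":
        return StrategySpec(
            arm="P",
            components=(DrugComponent("pembrolizumab", "flat", 200.0, 2, max_admins=35),),
            attendances_per_cycle=2,
        )
    if arm == "C":
        mix = params.firstline_mix_C
        regs = {
            "mFOLFOX": StrategySpec("C", _FOLFOX_BACKBONE, 3),
            "mFOLFOX_bev": StrategySpec("C", _FOLFOX_BACKBONE + (_BEV,), 3),
            "mFOLFOX_cet": StrategySpec("C", _FOLFOX_BACKBONE + (_CET,), 9),
            "FOLFIRI": StrategySpec("C", _FOLFIRI_BACKBONE, 3),
            "FOLFIRI_bev": StrategySpec("C", _FOLFIRI_BACKBONE + (_BEV,), 3),
            "FOLFIRI_cet": StrategySpec("C", _FOLFIRI_BACKBONE + (_CET,), 9),
        }
        return [(mix[name], regs[name]) for name in regs]
    raise ValueError(f"unknown arm {arm!r}")


def discount_factor(time_days, annual_rate: float):
    """(1 + r)^(-t / 365.25); 1 at t=0 or r=0."""
    t = np.asarray(time_days, dtype=float)
    if np.any(t < 0) or annual_rate < 0:
        raise ValueError("time and rate must be >= 0")
    return (1.0 + annual_rate) ** (-t / DAYS_PER_YEAR)


def regimen_cost_per_admin(component: DrugComponent, prices: Dict[str, float],
                           bsa: float, weight: float) -> float:
    """USD for one administration of one component (no vial rounding)."""
    if component.drug not in prices:
        raise KeyError(f"no unit price for drug {component.drug!r}")
    if component.basis == "per_m2":
        mg = component.dose * bsa
    elif component.basis == "per_kg":
        mg = component.dose * weight
    elif component.basis == "flat":
        mg = component.dose
    else:
        raise ValueError(f"unknown dose basis {component.basis!r}")
    return mg * prices[component.drug]


def pap_cycle_cost(params: ModelParams, cycle: int) -> float:
    """Patient-assistance-program acquisition cost in model cycle
    ``cycle`` (1-based): the annual fee prorated per cycle, cumulative
    total capped."""
    rate = params.pap_annual_cost * params.cycle_length_days / DAYS_PER_YEAR
    spent = (cycle - 1) * rate
    return float(np.clip(params.pap_cap - spent, 0.0, rate))


def _component_cycle_cost(comp: DrugComponent, params: ModelParams,
                          cycle: int) -> float:
    per_admin = regimen_cost_per_admin(comp, params.prices, params.bsa,
                                       params.weight_kg)
    if comp.max_admins is None:
        n = comp.admins_per_cycle
    else:
        used = comp.admins_per_cycle * (cycle - 1)
        n = int(np.clip(comp.max_admins - used, 0, comp.admins_per_cycle))
    cost = per_admin * n
    if cycle == 1 and comp.cycle1_extra_dose:
        extra = DrugComponent(comp.drug, comp.basis, comp.cycle1_extra_dose, 1)
        cost += regimen_cost_per_admin(extra, params.prices, params.bsa,
                                       params.weight_kg)
    return cost


def _strategy_cycle_cost(strategy: Union[StrategySpec, Mixture],
                         params: ModelParams, cycle: int) -> Tuple[float, float]:
    """(acquisition USD, attendances) for model cycle ``cycle``."""
    if isinstance(strategy, StrategySpec):
        pairs = [(1.0, strategy)]
    else:
        pairs = list(strategy)
    cost = 0.0
    attend = 0.0
    for w, spec in pairs:
        for comp in spec.components:
            if spec.arm == "P" and comp.drug == "pembrolizumab" and params.pap_enabled:
                cost += w * pap_cycle_cost(params, cycle)
            else:
                cost += w * _component_cycle_cost(comp, params, cycle)
        attend += w * spec.attendances_per_cycle
    return cost, attend


def _ici_cap_factor(params: ModelParams, cycle: int) -> float:
    """Fraction of cycle ``cycle`` inside the ICI duration cap."""
    return float(np.clip(params.ici_cap_cycles - (cycle - 1), 0.0, 1.0))


def subsequent_cycle_cost(params: ModelParams, arm: str, cycle: int) -> float:
    """Mixture-weighted per-cycle drug cost of subsequent (post-
    progression) therapy.  Chemotherapy class = simple average of the
    CAPIRI / CAPOX / FOLFOX / FOLFIRI per-cycle costs; immune-checkpoint
    classes are zeroed beyond the configurable duration cap."""
    p, bsa, wt = params.prices, params.bsa, params.weight_kg

    def _cost(components, per_cycle_admins):
        return sum(
            regimen_cost_per_admin(c, p, bsa, wt) * n
            for c, n in zip(components, per_cycle_admins)
        )

    folfox = _cost(_FOLFOX_BACKBONE, (3, 3, 3))
    folfiri = _cost(_FOLFIRI_BACKBONE, (3, 3, 3))
    capox = _cost(
        (DrugComponent("capecitabine", "per_m2", 28000.0, 2),
         DrugComponent("oxaliplatin", "per_m2", 130.0, 2)), (2, 2))
    capiri = _cost(
        (DrugComponent("capecitabine", "per_m2", 28000.0, 2),
         DrugComponent("irinotecan", "per_m2", 200.0, 2)), (2, 2))
    chemo = (folfox + folfiri + capox + capiri) / 4.0

    cap = _ici_cap_factor(params, cycle)
    class_costs = {
        "pembrolizumab": 200.0 * p["pembrolizumab"] * 2 * cap,
        "other_ici": 240.0 * p["nivolumab"] * 3 * cap,
        "chemotherapy": chemo,
        "vegf": 5.0 * wt * p["bevacizumab"] * 3,
        "egfr": 250.0 * bsa * p["cetuximab"] * 6,
    }
    mix = params.subsequent_mix.get(arm, {})
    return sum(mix.get(k, 0.0) * v for k, v in class_costs.items())


@dataclass
class CohortTrace:
    """Cycle-indexed state occupancy with discount factors."""

    times: np.ndarray  # t_k = 42k days
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    df: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.times) - 1

    def occupancy_check(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.pfs + self.pd + self.dead - 1.0) <= tol))


def build_trace(s_pfs: Callable, s_os: Callable, params: ModelParams) -> CohortTrace:
    """Read state occupancy off the survival evaluators on the cycle
    grid.  PFS occupancy is clamped to OS (crossing curves give zero
    progressed occupancy there).  The trace runs until overall survival
    first drops below the horizon threshold (default: fewer than 1%
    survivors) or a hard cap in years."""
    cycle = params.cycle_length_days
    k_cap = int(math.ceil(params.horizon_cap_years * DAYS_PER_YEAR / cycle))
    times = [0.0]
    k = 1
    while True:
        t = k * cycle
        times.append(t)
        if float(s_os(t)) < params.horizon_threshold or k >= k_cap:
            break
        k += 1
    t_arr = np.asarray(times)
    sp = np.asarray([float(s_pfs(t)) for t in t_arr])
    so = np.asarray([float(s_os(t)) for t in t_arr])
    for name, arr in (("S_pfs", sp), ("S_os", so)):
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"{name} evaluator returned values outside [0, 1]")
    sp = np.clip(sp, 0.0, 1.0)
    so = np.clip(so, 0.0, 1.0)
    pfs = np.minimum(sp, so)
    pd_ = so - pfs
    dead = 1.0 - so
    df = discount_factor(t_arr, params.discount_rate)
    return CohortTrace(times=t_arr, pfs=pfs, pd=pd_, dead=dead, df=df)


@dataclass
class ArmOutcome:
    """Per-arm totals: (un)discounted life-years, QALYs, cost components."""

    arm: str
    ly: float
    ly_undiscounted: float
    qaly: float
    qaly_undiscounted: float
    costs: Dict[str, float]

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    def to_dict(self) -> dict:
        d = {
            "arm": self.arm,
            "ly": self.ly,
            "ly_undiscounted": self.ly_undiscounted,
            "qaly": self.qaly,
            "qaly_undiscounted": self.qaly_undiscounted,
            "total_cost": self.total_cost,
        }
        d.update({f"cost_{k}": v for k, v in self.costs.items()})
        return d


def ae_burden(ae_set: List[dict]) -> Tuple[float, float]:
    """One-off adverse-event burden: (expected cost, expected QALY
    loss) = sum of incidence x cost and incidence x |disutility|,
    applied once in the first cycle, undiscounted."""
    cost = sum(a["incidence"] * a["cost"] for a in ae_set)
    qaly_loss = sum(a["incidence"] * abs(a["disutility"]) for a in ae_set)
    return cost, qaly_loss


def accrue_outcomes(trace: CohortTrace, strategy: Union[StrategySpec, Mixture],
                    params: ModelParams, arm: Optional[str] = None) -> ArmOutcome:
    """Accrue life-years, QALYs and the five cost components over the
    trace.  Occupancy within a cycle is aggregated by the configured
    integration rule (trapezoid default, or end-of-cycle)."""
    if arm is None:
        arm = strategy.arm if isinstance(strategy, StrategySpec) else strategy[0][1].arm
    dt_years = params.cycle_length_days / DAYS_PER_YEAR
    alive = trace.pfs + trace.pd

    def cycle_weight(series, discounted=True):
        x = series * trace.df if discounted else series
        if params.integration == "trapezoid":
            return 0.5 * (x[:-1] + x[1:])
        if params.integration == "end":
            return x[1:]
        raise ValueError(f"unknown integration rule {params.integration!r}")

    w_alive = cycle_weight(alive)
    w_pfs = cycle_weight(trace.pfs)
    w_pd = cycle_weight(trace.pd)
    ly = float(np.sum(w_alive) * dt_years)
    qaly = float(np.sum(params.u_pfs * w_pfs + params.u_pd * w_pd) * dt_years)
    ly_u = float(np.sum(cycle_weight(alive, False)) * dt_years)
    qaly_u = float(
        np.sum(params.u_pfs * cycle_weight(trace.pfs, False)
               + params.u_pd * cycle_weight(trace.pd, False)) * dt_years
    )

    n_cycles = trace.n_cycles
    acq = np.empty(n_cycles)
    attend = np.empty(n_cycles)
    subs = np.empty(n_cycles)
    for k in range(1, n_cycles + 1):
        acq[k - 1], attend[k - 1] = _strategy_cycle_cost(strategy, params, k)
        subs[k - 1] = subsequent_cycle_cost(params, arm, k)
    acquisition = float(np.sum(w_pfs * acq))
    administration = float(np.sum(w_pfs * attend) * params.admin_cost)
    followup = float(np.sum(w_alive) * params.followup_cost)
    subsequent = float(np.sum(w_pd * subs) + np.sum(w_pd) * params.bsc_cost)
    ae_cost, ae_qaly = ae_burden(params.ae_set(arm))

    return ArmOutcome(
        arm=arm,
        ly=ly,
        ly_undiscounted=ly_u,
        qaly=qaly - ae_qaly,
        qaly_undiscounted=qaly_u - ae_qaly,
        costs={
            "acquisition": acquisition,
            "administration": administration,
            "followup": followup,
            "ae": ae_cost,
            "subsequent": subsequent,
        },
    )


@dataclass
class CEResult:
    """Incremental comparison (intervention minus comparator)."""

    d_cost: float
    d_ly: float
    d_qaly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    status: str  # interior | dominant | dominated | undefined

    def to_dict(self) -> dict:
        return {
            "d_cost": self.d_cost,
            "d_ly": self.d_ly,
            "d_qaly": self.d_qaly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "status": self.status,
        }


class CEModel:
    """Bind fitted survival evaluators to the engine: a callable that
    maps a parameter set to the incremental comparison P vs C.

    ``evaluators`` maps (arm, endpoint) -> callable t_days -> S(t),
    e.g. ``lambda t: survival_at(fit, t)`` for fitted models.
    """

    def __init__(self, evaluators: Dict[Tuple[str, str], Callable]):
        for arm in ("P", "C"):
            for ep in ("PFS", "OS"):
                if (arm, ep) not in evaluators:
                    raise ValueError(f"missing evaluator for arm {arm} endpoint {ep}")
        self.evaluators = evaluators

    def arm_outcome(self, arm: str, params: ModelParams) -> ArmOutcome:
        trace = build_trace(self.evaluators[(arm, "PFS")],
                            self.evaluators[(arm, "OS")], params)
        return accrue_outcomes(trace, first_line_strategy(arm, params), params, arm)

    def evaluate(self, params: ModelParams) -> CEResult:
        return icer(self.arm_outcome("P", params), self.arm_outcome("C", params))

    __call__ = evaluate


def icer(p: ArmOutcome, c: ArmOutcome) -> CEResult:
    """ICER of strategy ``p`` versus comparator ``c`` with dominance
    classification; no division when the QALY difference is zero."""
    d_cost = p.total_cost - c.total_cost
    d_ly = p.ly - c.ly
    d_qaly = p.qaly - c.qaly
    if d_qaly == 0:
        return CEResult(d_cost, d_ly, d_qaly, None, None, "undefined")
    if d_cost <= 0 and d_qaly > 0:
        status = "dominant"
        per_qaly = None
    elif d_cost >= 0 and d_qaly < 0:
        status = "dominated"
        per_qaly = None
    else:
        status = "interior"
        per_qaly = d_cost / d_qaly
    per_ly = d_cost / d_ly if (status == "interior" and d_ly != 0) else None
    return CEResult(d_cost, d_ly, d_qaly, per_qaly, per_ly, status)
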