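"""Synthetic two-arm oncology trial generator.

Emulates a KEYNOTE-177-like randomized trial — immunotherapy (arm ``P``)
versus chemotherapy (arm ``C``) in dMMR/MSI-H metastatic colorectal
cancer — at the level of statistical structure the downstream analysis
assumes: per-subject progression-free survival (PFS) drawn from a
parametric family per arm, overall survival (OS) as PFS plus an
exponential post-progression time, uniform accrual with administrative
cut-off, and exponential dropout.  Alongside the simulator it provides
the Kaplan-Meier estimator, a "digitizer" that mimics extracting curve
coordinates from a published figure (grid sampling plus jitter), and
number-at-risk table construction — everything needed to exercise the
pseudo-IPD reconstruction and fitting stages without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.isotonic import IsotonicRegression

from .families import get_family
from .units import months_to_days

__all__ = [
    "TrialSimConfig",
    "StepCurve",
    "DigitizedCurve",
    "RiskTable",
    "simulate_trial",
    "km_estimate",
    "digitize_curve",
    "make_risk_table",
    "select_ipd",
]

IPD_COLUMNS = ("subject_id", "arm", "endpoint", "time_days", "event")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class TrialSimConfig:
    """Generator settings; defaults emulate the trial conditions assumed
    by the analysis (median PFS about 16.5 vs 8.2 months, roughly 3.5
    years of follow-up, light dropout).

    ``pfs_params_*`` are natural-scale keyword dictionaries for the
    chosen family (see :mod:`psmcea.families`); times in days.
    """

    n_per_arm: int = 300
    pfs_family_P: str = "loglogistic"
    pfs_params_P: dict = field(
        default_factory=lambda: {"shape": 1.3, "scale": months_to_days(16.5)}
    )
    pfs_family_C: str = "lognormal"
    pfs_params_C: dict = field(
        default_factory=lambda: {"mu": math.log(months_to_days(8.2)), "sigma": 1.1}
    )
    post_progression_rate: float = 0.0243  # hazard per month (~28.5 mo median)
    accrual_months: float = 18.0
    admin_followup_months: float = 32.0
    dropout_rate: float = 0.004  # hazard per month
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ConfigurationError("n_per_arm must be >= 2")
        for name in ("post_progression_rate", "dropout_rate", "accrual_months",
                     "admin_followup_months"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for fam_field, par_field in (
            ("pfs_family_P", "pfs_params_P"),
            ("pfs_family_C", "pfs_params_C"),
        ):
            fam = get_family(getattr(self, fam_field))
            try:
                fam.pack(**getattr(self, par_field))
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(
                    f"{par_field} invalid for family {fam.name!r}: {exc}"
                ) from exc


@dataclass
class StepCurve:
    """Right-continuous Kaplan-Meier step function with n-at-risk."""

    times: np.ndarray  # includes 0
    survival: np.ndarray  # S at each time; S(0) = 1
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise ValueError("step curve must start at (0, 1)")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def evaluate(self, t) -> np.ndarray:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.times) - 1)]


@dataclass
class DigitizedCurve:
    """Point coordinates as read off a published curve."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "survival": self.survival})


@dataclass
class RiskTable:
    """Number-at-risk table at fixed landmark times."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times[0] != 0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("n-at-risk must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "n_at_risk": self.n_at_risk})


def simulate_trial(config: TrialSimConfig) -> pd.DataFrame:
    """Simulate subject-level PFS and OS records for both arms.

    Returns an IPD table (one PFS and one OS row per subject) with
    columns ``subject_id, arm, endpoint, time_days, event``.  OS event
    time = PFS event time + exponential post-progression time, so the
    OS record time is never below the PFS record time.  Censoring is
    the minimum of exponential dropout and the administrative cut
    (time from the subject's uniform accrual entry to trial end).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    day_rate_pp = config.post_progression_rate / months_to_days(1.0)
    day_rate_drop = config.dropout_rate / months_to_days(1.0)
    trial_end = months_to_days(config.accrual_months + config.admin_followup_months)

    rows = []
    sid = 0
    for arm, fam_name, fam_params in (
        ("P", config.pfs_family_P, config.pfs_params_P),
        ("C", config.pfs_family_C, config.pfs_params_C),
    ):
        fam = get_family(fam_name)
        theta = fam.pack(**fam_params)
        n = config.n_per_arm
        pfs_t = fam.rvs(theta, n, rng)
        if day_rate_pp > 0:
            post = rng.exponential(1.0 / day_rate_pp, size=n)
        else:
            post = np.full(n, np.inf)
        os_t = pfs_t + post
        entry = rng.uniform(0.0, months_to_days(config.accrual_months), size=n)
        admin = np.maximum(trial_end - entry, 1e-9)
        if day_rate_drop > 0:
            drop = rng.exponential(1.0 / day_rate_drop, size=n)
        else:
            drop = np.full(n, np.inf)
        cens = np.minimum(drop, admin)
        for i in range(n):
            sid += 1
            for endpoint, ev_t in (("PFS", pfs_t[i]), ("OS", os_t[i])):
                t = min(ev_t, cens[i])
                rows.append(
                    (sid, arm, endpoint, max(t, 1e-9), int(ev_t <= cens[i]))
                )
    ipd = pd.DataFrame(rows, columns=list(IPD_COLUMNS))
    return ipd


def select_ipd(ipd: pd.DataFrame, arm: Optional[str] = None,
               endpoint: Optional[str] = None) -> pd.DataFrame:
    """Filter an IPD table by arm and/or endpoint."""
    out = ipd
    if arm is not None:
        out = out[out["arm"] == arm]
    if endpoint is not None:
        out = out[out["endpoint"] == endpoint]
    return out


def km_estimate(ipd: pd.DataFrame, arm: Optional[str] = None,
                endpoint: Optional[str] = None) -> StepCurve:
    """Product-limit (Kaplan-Meier) estimate for one arm/endpoint.

    Ties at identical times are handled with events preceding
    censorings (subjects censored at t remain at risk for events at t),
    the standard convention.
    """
    sub = select_ipd(ipd, arm, endpoint)
    if len(sub) == 0:
        raise ValueError(f"no records for arm={arm!r} endpoint={endpoint!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_days"], event_observed=sub["event"])
    table = kmf.event_table
    times = np.asarray(table.index, dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    at_risk = table["at_risk"].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
        at_risk = np.concatenate([[float(len(sub))], at_risk])
    else:
        surv[0] = 1.0
    return StepCurve(times=times, survival=surv, n_at_risk=at_risk)


def digitize_curve(curve: StepCurve, grid_step: float, jitter_sd: float,
                   rng: Optional[np.random.Generator] = None) -> DigitizedCurve:
    """Mimic figure digitization: sample the step function on a regular
    grid plus all step locations, perturb with truncated Gaussian reading
    error, then restore monotonicity by isotonic regression.

    The output satisfies the digitized-curve invariants: starts at
    (0, 1), values in [0, 1], non-increasing.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    tmax = curve.times[-1]
    grid = np.arange(0.0, tmax + grid_step * 0.5, grid_step)
    times = np.unique(np.concatenate([grid, curve.times]))
    values = curve.evaluate(times)
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        values = np.clip(values + rng.normal(0.0, jitter_sd, size=len(values)), 0.0, 1.0)
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False)
        values = iso.fit_transform(times, values)
    values = np.clip(values, 0.0, 1.0)
    values[0] = 1.0
    return DigitizedCurve(times=times, survival=values)


def make_risk_table(ipd: pd.DataFrame, arm: Optional[str] = None,
                    endpoint: Optional[str] = None,
                    interval: float = 6 * 30.4375) -> RiskTable:
    """Number at risk at 0, interval, 2*interval, ... up to the last
    observed time: the count of subjects with follow-up >= boundary."""
    if interval <= 0:
        raise ValueError("interval must be > 0")
    sub = select_ipd(ipd, arm, endpoint)
    if len(sub) == 0:
        raise ValueError(f"no records for arm={arm!r} endpoint={endpoint!r}")
    t = sub["time_days"].to_numpy(dtype=float)
    boundaries = np.arange(0.0, t.max() + 1e-9, interval)
    counts = np.array([(t >= b).sum() for b in boundaries], dtype=int)
    return RiskTable(times=boundaries, n_at_risk=counts)
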