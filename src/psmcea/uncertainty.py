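"""Sensitivity analyses: one-way deterministic sweeps (tornado), Monte
Carlo probabilistic sensitivity analysis with method-of-moments beta and
gamma sampling, cost-effectiveness acceptability curves, and the
patient-assistance-program scenario.

Distribution conventions follow standard health-economic practice:
utilities, probabilities and mixture weights are beta distributed; costs
and prices are gamma distributed; adverse-event disutilities are sampled
as beta magnitudes and negated.  Mixture weights are renormalized to sum
to one after independent sampling.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .psm import CEResult, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "ParamDistribution",
    "PSADraw",
    "CEACPoint",
    "beta_from_moments",
    "gamma_from_moments",
    "dsa_bounds",
    "run_dsa",
    "run_psa",
    "ceac",
    "apply_scenario_pap",
]


def beta_from_moments(mean: float, se: float) -> tuple:
    """Method-of-moments beta parameters: nu = m(1-m)/se^2 - 1,
    alpha = m nu, beta = (1-m) nu."""
    if not 0 < mean < 1:
        raise ValueError(f"beta mean {mean} must lie in (0, 1)")
    if se <= 0:
        raise ValueError("se must be > 0")
    if se * se >= mean * (1 - mean):
        raise ValueError(
            f"beta moment condition violated: se^2={se*se:.3g} >= "
            f"mean(1-mean)={mean*(1-mean):.3g}"
        )
    nu = mean * (1 - mean) / (se * se) - 1.0
    return mean * nu, (1 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple:
    """Method-of-moments gamma (shape, scale) = ((m/se)^2, se^2/m)."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma moments require mean > 0 and se > 0")
    return (mean / se) ** 2, se * se / mean


def dsa_bounds(mean: float, frac: float = 0.2) -> tuple:
    """Default one-way range: baseline +/- 20% (ordered low, high)."""
    lo, hi = mean * (1 - frac), mean * (1 + frac)
    return (min(lo, hi), max(lo, hi))


@dataclass
class ParamDistribution:
    """One registry row: where a parameter lives, its one-way range and
    (for sampled parameters) its beta/gamma parameterization.

    When both explicit distribution parameters and (mean, se) moments
    are supplied, the explicit parameters win and any moment mismatch is
    logged — printed parameter tables are honored verbatim.
    """

    pid: str
    kind: str  # beta | gamma | fixed
    baseline: float
    dsa_low: float
    dsa_high: float
    mean: Optional[float] = None
    se: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None
    negate: bool = False  # sample magnitude, apply negated (disutilities)
    group: Optional[str] = None  # renormalization group (mixture weights)

    def __post_init__(self):
        if self.kind not in {"beta", "gamma", "fixed"}:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if self.alpha is None or self.beta is None:
                self.alpha, self.beta = beta_from_moments(self.mean, self.se)
            elif self.mean is not None and self.se is not None:
                a, b = beta_from_moments(self.mean, self.se)
                rel = max(abs(a - self.alpha) / self.alpha,
                          abs(b - self.beta) / self.beta)
                if rel > 0.01:
                    logger.info(
                        "%s: printed beta(%.3f, %.3f) differs from "
                        "moment-matched beta(%.3f, %.3f) by %.1f%%; "
                        "using printed parameters",
                        self.pid, self.alpha, self.beta, a, b, 100 * rel)
        elif self.kind == "gamma":
            if self.shape is None or self.scale is None:
                self.shape, self.scale = gamma_from_moments(self.mean, self.se)
            elif self.mean is not None and self.se is not None:
                s, sc = gamma_from_moments(self.mean, self.se)
                rel = max(abs(s - self.shape) / self.shape,
                          abs(sc - self.scale) / self.scale)
                if rel > 0.01:
                    logger.info(
                        "%s: printed gamma(%.3f, %.4f) differs from "
                        "moment-matched gamma(%.3f, %.4f) by %.1f%%; "
                        "using printed parameters",
                        self.pid, self.shape, self.scale, s, sc, 100 * rel)
        if self.dsa_low > self.dsa_high:
            self.dsa_low, self.dsa_high = self.dsa_high, self.dsa_low

    @property
    def dist_mean(self) -> Optional[float]:
        """Mean implied by the sampling distribution (None if fixed)."""
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta)
        if self.kind == "gamma":
            return self.shape * self.scale
        return None

    @property
    def dist_sd(self) -> Optional[float]:
        if self.kind == "beta":
            ab = self.alpha + self.beta
            return math.sqrt(self.alpha * self.beta / (ab * ab * (ab + 1.0)))
        if self.kind == "gamma":
            return self.scale * math.sqrt(self.shape)
        return None

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta))
        if self.kind == "gamma":
            return float(rng.gamma(self.shape, self.scale))
        return self.baseline


@dataclass
class PSADraw:
    iteration: int
    sampled: Dict[str, float]  # raw draws, before negation/renormalization
    d_cost: float
    d_qaly: float


@dataclass
class CEACPoint:
    wtp: float
    probability: float


def run_dsa(params: ModelParams, registry: Sequence[ParamDistribution],
            model: Callable[[ModelParams], CEResult]) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis.

    Every registry entry is swept to its low and high bound with all
    other parameters at baseline; the output (one row per entry, sorted
    by descending ICER bar width) backs a tornado diagram.  Bounds that
    make the model fail are flagged, not dropped.
    """
    base = model(params)
    rows = []
    for dist in registry:
        entry = {
            "param": dist.pid,
            "low": dist.dsa_low,
            "high": dist.dsa_high,
            "icer_base": base.icer_per_qaly,
            "failed": False,
        }
        icers = {}
        for side, bound in (("low", dist.dsa_low), ("high", dist.dsa_high)):
            try:
                res = model(params.with_value(dist.pid, bound))
                icers[side] = res.icer_per_qaly
            except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                logger.warning("DSA bound failed for %s=%s: %s", dist.pid, bound, exc)
                icers[side] = np.nan
                entry["failed"] = True
        entry["icer_low"] = icers["low"]
        entry["icer_high"] = icers["high"]
        vals = [v for v in icers.values() if v is not None and np.isfinite(v)]
        entry["width"] = (max(vals) - min(vals)) if len(vals) == 2 else np.nan
        rows.append(entry)
    out = pd.DataFrame(rows)
    return out.sort_values("width", ascending=False, na_position="last").reset_index(
        drop=True
    )


def run_psa(params: ModelParams, registry: Sequence[ParamDistribution],
            n_iter: int, seed: int,
            model: Callable[[ModelParams], CEResult]) -> List[PSADraw]:
    """Probabilistic sensitivity analysis: per iteration, sample every
    non-fixed parameter from its distribution, negate disutility
    magnitudes, renormalize each mixture-weight group to sum to one,
    evaluate the model, and record the incremental cost and QALYs.
    Bit-reproducible for a fixed seed."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for dist in registry:  # validate before sampling anything
        if dist.kind == "beta" and (dist.alpha is None or dist.beta is None):
            raise ValueError(f"{dist.pid}: beta distribution incomplete")
        if dist.kind == "gamma" and (dist.shape is None or dist.scale is None):
            raise ValueError(f"{dist.pid}: gamma distribution incomplete")
    rng = np.random.default_rng(seed)
    draws = []
    sampled_reg = [d for d in registry if d.kind != "fixed"]
    for it in range(1, n_iter + 1):
        raw = {d.pid: d.sample(rng) for d in sampled_reg}
        p = copy.deepcopy(params)
        # apply non-grouped values
        groups: Dict[str, List[ParamDistribution]] = {}
        for d in sampled_reg:
            if d.group:
                groups.setdefault(d.group, []).append(d)
            else:
                p.set_value(d.pid, -raw[d.pid] if d.negate else raw[d.pid])
        # renormalize each mixture group
        for members in groups.values():
            total = sum(raw[d.pid] for d in members)
            for d in members:
                p.set_value(d.pid, raw[d.pid] / total if total > 0 else 0.0)
        res = model(p)
        draws.append(PSADraw(iteration=it, sampled=raw,
                             d_cost=res.d_cost, d_qaly=res.d_qaly))
    return draws


def ceac(draws: Sequence[PSADraw], wtp_grid: Sequence[float]) -> List[CEACPoint]:
    """Probability of positive net monetary benefit lambda*dQALY - dCost
    at each willingness-to-pay value."""
    if len(draws) == 0:
        raise ValueError("need at least one PSA draw")
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid is empty")
    dq = np.array([d.d_qaly for d in draws])
    dc = np.array([d.d_cost for d in draws])
    points = []
    for lam in wtp_grid:
        prob = float(np.mean(lam * dq - dc > 0))
        points.append(CEACPoint(wtp=float(lam), probability=prob))
    return points


def default_wtp_grid(upper: float = 60000.0, step: float = 500.0) -> np.ndarray:
    return np.arange(0.0, upper + step / 2, step)


def apply_scenario_pap(params: ModelParams) -> ModelParams:
    """Enable the patient-assistance-program price scheme: first-line
    pembrolizumab acquisition replaced by a prorated annual fee with a
    lifetime cap; everything else untouched.  If no PAP configuration is
    present (annual cost unset), params are returned unchanged."""
    if params.pap_annual_cost is None:
        logger.info("PAP configuration absent; scenario is a no-op")
        return params
    new = copy.deepcopy(params)
    new.pap_enabled = True
    return new
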