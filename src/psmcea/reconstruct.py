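"""Pseudo individual-patient-data reconstruction from digitized
Kaplan-Meier coordinates and a number-at-risk table (Guyot algorithm).

Given the (time, survival) points read off a published KM curve and the
number at risk printed beneath it, the algorithm estimates, interval by
interval, how many subjects were censored (assumed uniformly spread
within each risk-table interval) and assigns integer event counts at
the curve steps so that (i) the KM estimate of the reconstructed data
tracks the input coordinates and (ii) the number at risk at each
landmark matches the printed table.  The result is an approximate
(time, event) dataset on which parametric models can be refit.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .trial_synth import IPD_COLUMNS, DigitizedCurve, RiskTable

logger = logging.getLogger(__name__)

__all__ = ["clean_curve", "reconstruct_ipd", "ReconstructionError"]


class ReconstructionError(ValueError):
    """Raised when curve/risk-table inputs are mutually infeasible."""


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-increasing fit (unit weights)."""
    y = np.asarray(y, dtype=float)
    # fit non-decreasing to the negated series
    vals = list(-y)
    blocks = [[v, 1] for v in vals]
    out = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            v2, w2 = out.pop()
            v1, w1 = out.pop()
            out.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    fitted = np.concatenate([[v] * w for v, w in out])
    return -fitted


def clean_curve(raw: DigitizedCurve) -> DigitizedCurve:
    """Normalize digitized coordinates to a valid survival curve.

    Sorts by time, clamps to [0, 1], enforces monotone non-increase by
    pool-adjacent-violators, deduplicates equal times keeping the lower
    survival, and anchors the curve at (0, 1).  Idempotent.
    """
    t = np.asarray(raw.times, dtype=float)
    s = np.asarray(raw.survival, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 digitized points")
    if np.any(t < 0):
        raise ValueError("digitized times must be non-negative")
    if np.allclose(t, t[0]):
        raise ValueError("all digitized points share one time; not a curve")
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    s = np.clip(s, 0.0, 1.0)
    s = _pava_decreasing(s)
    # deduplicate equal times keeping the lower (later) survival
    keep_t, keep_s = [], []
    for ti, si in zip(t, s):
        if keep_t and ti == keep_t[-1]:
            keep_s[-1] = min(keep_s[-1], si)
        else:
            keep_t.append(ti)
            keep_s.append(si)
    t = np.asarray(keep_t)
    s = np.asarray(keep_s)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    s[0] = 1.0
    return DigitizedCurve(times=t, survival=np.clip(s, 0.0, 1.0))


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: Optional[RiskTable] = None,
    total_events: Optional[int] = None,
    n_initial: Optional[int] = None,
    arm: str = "",
    endpoint: str = "",
) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from a cleaned curve and risk table.

    Parameters
    ----------
    curve
        Cleaned digitized coordinates (see :func:`clean_curve`).
    risk
        Number-at-risk table.  If omitted, the weakest defined
        assumption is used — no censoring before last follow-up — and
        ``n_initial`` must give the cohort size (a warning is logged).
    total_events
        If given, event counts in the final interval are adjusted so
        the total matches.
    n_initial
        Cohort size when no risk table is supplied.

    Returns
    -------
    pandas.DataFrame
        IPD rows ``subject_id, arm, endpoint, time_days, event``; the
        number of rows equals the risk table's first count.
    """
    t = np.asarray(curve.times, dtype=float)
    s = np.asarray(curve.survival, dtype=float)
    if t[0] != 0 or s[0] != 1.0:
        raise ValueError("curve must be cleaned (start at (0,1)); see clean_curve")
    assume_no_censoring = risk is None
    if risk is None:
        if n_initial is None:
            raise ValueError("risk table absent: n_initial is required")
        logger.warning(
            "no risk table supplied; assuming no censoring before last follow-up"
        )
        risk = RiskTable(times=np.array([0.0]), n_at_risk=np.array([int(n_initial)]))
    trisk = np.asarray(risk.times, dtype=float)
    nrisk = np.asarray(risk.n_at_risk, dtype=int)
    if nrisk[0] <= 0:
        raise ReconstructionError("risk table's first count must be > 0")
    if np.any(np.diff(nrisk) > 0):
        raise ReconstructionError("n-at-risk increases over time; infeasible table")
    # drop landmarks beyond the curve span (nothing to match there)
    keep = trisk <= t[-1] + 1e-9
    trisk, nrisk = trisk[keep], nrisk[keep]

    K = len(t)
    I = len(trisk)

    def _invert_interval(lo, hi, n_start, n_end, s_prev_in, t_start, t_end):
        """Exact within-interval allocation from KM drop ratios.

        Noise-free coordinates make every drop ratio rho = 1 - d/n with
        small integers d, n, so the at-risk set at each step can be
        recovered and censorings placed between the steps they actually
        separate.  Returns None when the coordinates are not consistent
        with any such allocation (noisy digitization), in which case the
        caller falls back to the uniform-censoring iteration.
        """
        d_loc = np.zeros(hi - lo + 1, dtype=int)
        events = []
        prev_s = s_prev_in
        for k in range(lo, hi + 1):
            if s[k] >= prev_s - 1e-12:
                prev_s = min(prev_s, s[k])
                continue
            if prev_s <= 0 or s[k] < 0:
                return None
            rho = s[k] / prev_s
            sol = None
            for d_try in range(1, int(n_start) + 1):
                nf = d_try / (1.0 - rho)
                nr = int(round(nf))
                if abs(nf - nr) < 1e-4 and nr >= d_try:
                    sol = (d_try, nr)
                    break
            if sol is None:
                return None
            events.append((k, sol[0], sol[1]))
            prev_s = s[k]
        cen_times = []
        avail = int(n_start)
        prev_time = t_start
        for k, d_ev, n_ev in events:
            c = avail - n_ev  # censored strictly before this event
            if c < 0:
                return None
            if c > 0:
                span = t[k] - prev_time
                cen_times.extend(
                    (prev_time + (np.arange(1, c + 1) / (c + 1)) * span).tolist()
                )
            d_loc[k - lo] = d_ev
            avail = n_ev - d_ev
            prev_time = t[k]
        if n_end is not None:
            c = avail - int(n_end)
            if c < 0:
                return None
            if c > 0:
                span = t_end - prev_time
                cen_times.extend(
                    (prev_time + (np.arange(1, c + 1) / (c + 1)) * span).tolist()
                )
        return d_loc, np.asarray(cen_times, dtype=float)

    # curve-point index ranges per risk interval
    lower = np.searchsorted(t, trisk, side="left")
    d = np.zeros(K, dtype=int)  # events at each curve point
    cen_all: list = []  # censoring times
    km_hat = np.ones(K)
    n_hat = np.zeros(K + 1)
    n_hat[lower[0]] = nrisk[0]
    last_km = 1.0  # KM value at the most recent event before the interval

    def _pass_interval(i, lo, hi, n_start, cen_times, last_in):
        """Assign events over curve indices [lo, hi] given censor times."""
        cen_counts = np.zeros(hi - lo + 1, dtype=int)
        if len(cen_times):
            edges = np.concatenate([t[lo : hi + 1], [np.inf]])
            cen_counts = np.histogram(cen_times, bins=edges)[0]
        n_hat[lo] = n_start
        last = last_in
        for k in range(lo, hi + 1):
            if t[k] == 0 or n_hat[k] <= 0:
                d[k] = 0
                km_hat[k] = last if n_hat[k] <= 0 else 1.0
            else:
                d[k] = int(round(n_hat[k] * (1.0 - s[k] / last)))
                d[k] = max(0, min(d[k], int(n_hat[k])))
                km_hat[k] = last * (1.0 - d[k] / n_hat[k])
            n_hat[k + 1] = n_hat[k] - d[k] - cen_counts[k - lo]
            if d[k] != 0:
                last = km_hat[k]
        return last

    for i in range(I):
        lo = lower[i]
        if i < I - 1:
            hi = lower[i + 1] - 1
            target = int(nrisk[i + 1])
        else:
            hi = K - 1
            target = None
        if hi < lo:
            # no curve point inside this interval
            if target is not None:
                n_hat[lower[i + 1]] = n_hat[lo]
            continue
        n_start_i = int(nrisk[i])
        s_prev_in = s[lo - 1] if lo > 0 else 1.0
        t_end_i = trisk[i + 1] if target is not None else t[-1]
        exact = None
        if not assume_no_censoring:
            exact = _invert_interval(lo, hi, n_start_i, target, s_prev_in,
                                     trisk[i], t_end_i)
        if exact is not None:
            d_loc, cen_times = exact
            d[lo : hi + 1] = d_loc
            cen_all.extend(cen_times.tolist())
            n_left = n_start_i - int(d_loc.sum()) - len(cen_times)
            n_hat[hi + 1] = n_left
            if target is not None:
                n_hat[lower[i + 1]] = target
            drops = s[lo : hi + 1][d_loc > 0]
            if len(drops):
                last_km = float(drops[-1])
            continue
        if target is not None:
            # iterate on the number censored in this interval
            denom = s[lo] if s[lo] > 0 else 1.0
            n_cen = int(round(n_hat[lo] * s[min(lower[i + 1], K - 1)] / denom)) - target
            n_cen = max(n_cen, 0)
            seen = set()
            for _ in range(200):
                span = trisk[i + 1] - t[lo]
                cen_times = (
                    t[lo] + (np.arange(1, n_cen + 1) / (n_cen + 1)) * span
                    if n_cen > 0
                    else np.array([])
                )
                _pass_interval(i, lo, hi, nrisk[i], cen_times, last_km)
                achieved = int(n_hat[hi + 1])
                diff = achieved - target
                if diff == 0 or n_cen in seen:
                    break
                seen.add(n_cen)
                n_cen += diff
                if n_cen < 0:
                    n_cen = 0
            last_km = _pass_interval(i, lo, hi, nrisk[i], cen_times, last_km)
            if abs(int(n_hat[hi + 1]) - target) > max(1, int(0.02 * nrisk[0])):
                raise ReconstructionError(
                    f"risk table infeasible at interval {i} "
                    f"[{trisk[i]:.1f}, {trisk[i+1]:.1f}): reconstructed "
                    f"{int(n_hat[hi + 1])} at risk vs table {target}"
                )
            cen_all.extend(cen_times.tolist())
            n_hat[lower[i + 1]] = n_hat[hi + 1]
        else:
            # final interval: no censoring until after the last curve point
            last_km = _pass_interval(i, lo, hi, int(n_hat[lo]), np.array([]), last_km)

    if total_events is not None:
        diff = int(total_events) - int(d.sum())
        # adjust events at the latest step times with capacity
        for k in range(K - 1, 0, -1):
            if diff == 0:
                break
            if diff > 0:
                room = int(n_hat[k]) - d[k]
                add = min(diff, max(room, 0))
                d[k] += add
                diff -= add
            else:
                sub = min(-diff, d[k])
                d[k] -= sub
                diff += sub
        if diff != 0:
            logger.warning("could not match total_events exactly; residual %d", diff)

    # residual subjects still at risk after the last curve point:
    # administratively censored at last follow-up
    n_resid = int(nrisk[0]) - int(d.sum()) - len(cen_all)
    times_out = []
    events_out = []
    for k in range(K):
        times_out.extend([t[k]] * d[k])
        events_out.extend([1] * d[k])
    times_out.extend(cen_all)
    events_out.extend([0] * len(cen_all))
    if n_resid > 0:
        times_out.extend([t[-1]] * n_resid)
        events_out.extend([0] * n_resid)
    elif n_resid < 0:
        raise ReconstructionError(
            "negative residual cohort after reconstruction; infeasible inputs"
        )
    order = np.argsort(times_out, kind="stable")
    times_arr = np.maximum(np.asarray(times_out, dtype=float)[order], 1e-9)
    events_arr = np.asarray(events_out, dtype=int)[order]
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, len(times_arr) + 1),
            "arm": arm,
            "endpoint": endpoint,
            "time_days": times_arr,
            "event": events_arr,
        },
        columns=list(IPD_COLUMNS),
    )
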