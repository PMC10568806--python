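"""Parametric survival families for censored maximum-likelihood fitting.

Six families are supported: exponential, Weibull, Gompertz, log-logistic,
log-normal and generalized gamma.  Each family exposes the log survival
function and log density on an *internal* parameter vector in which every
strictly positive parameter is stored on the natural-log scale, so that
optimizers can search an unconstrained space.

Parameterizations (t in days):

exponential   theta = [log lam],             S(t) = exp(-lam t)
weibull       theta = [log k, log s],        S(t) = exp(-(t/s)^k)
gompertz      theta = [a, log b],            S(t) = exp(-(b/a)(e^{a t} - 1))
loglogistic   theta = [log beta, log alpha], S(t) = 1 / (1 + (t/alpha)^beta)
lognormal     theta = [mu, log sigma],       S(t) = 1 - Phi((log t - mu)/sigma)
gengamma      theta = [mu, log sigma, q]     Prentice form, see below

The Gompertz shape ``a`` is unconstrained; ``a < 0`` gives an improper
survival function with plateau ``exp(b/a)`` (a fraction never experiencing
the event), which is legitimate for extrapolation but is surfaced as a
warning by the fitting layer.  For ``|a|`` below a small threshold the
exponential limit is used.

The generalized gamma uses the Prentice (mu, sigma, q) parameterization:
with w = (log t - mu)/sigma and gam = q^-2,

    f(t) = |q| gam^gam / (sigma t Gamma(gam)) * exp(gam (q w - e^{q w}))
    S(t) = Q(gam, gam e^{q w})        for q > 0
         = P(gam, gam e^{q w})        for q < 0

where P/Q are the regularized lower/upper incomplete gamma functions.
q -> 0 recovers the log-normal(mu, sigma) and q = 1 the Weibull; the
log-normal limit is taken analytically for |q| < 1e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np
from scipy import special

__all__ = ["Family", "get_family", "FAMILY_NAMES"]

_GG_Q_EPS = 1e-5  # |q| below this: analytic log-normal limit
_GOMP_A_EPS = 1e-10  # |a| below this: exponential limit


def _softplus(x):
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class Family:
    """A parametric survival family on the internal parameter scale."""

    name: str
    n_params: int
    param_names: tuple
    logsf: Callable  # (theta, t) -> log S(t)
    logpdf: Callable  # (theta, t) -> log f(t)
    median: Callable  # (theta) -> median time (may be inf)
    ppf_time: Callable  # (theta, u) -> t with S(t) = 1 - u (quantile of T)
    pack: Callable  # (**natural) -> internal theta
    unpack: Callable  # (theta) -> dict of natural parameters
    init: Callable  # (times, events) -> list of internal start vectors

    def sf(self, theta, t):
        return np.exp(self.logsf(theta, np.asarray(t, dtype=float)))

    def rvs(self, theta, size, rng: np.random.Generator):
        """Inverse-CDF sampling; may return +inf for improper survival."""
        u = rng.uniform(size=size)
        return self.ppf_time(theta, u)


# ----------------------------------------------------------------- exponential

def _exp_logsf(theta, t):
    lam = math.exp(theta[0])
    return -lam * t


def _exp_logpdf(theta, t):
    lam = math.exp(theta[0])
    return theta[0] - lam * t


def _exp_init(times, events):
    d = max(events.sum(), 1.0)
    lam = d / times.sum()
    base = np.array([math.log(lam)])
    return [base, base + 0.7, base - 0.7]


# --------------------------------------------------------------------- weibull

def _wei_logsf(theta, t):
    k, s = math.exp(theta[0]), math.exp(theta[1])
    return -((t / s) ** k)


def _wei_logpdf(theta, t):
    k, s = math.exp(theta[0]), math.exp(theta[1])
    lt = np.log(t)
    return theta[0] - theta[1] + (k - 1.0) * (lt - theta[1]) - (t / s) ** k


def _wei_init(times, events):
    lt = np.log(times[events == 1]) if events.sum() else np.log(times)
    s_log = lt.std() if len(lt) > 1 and lt.std() > 0 else 1.0
    base = np.array([math.log(max(1.0 / s_log, 0.05)), lt.mean()])
    return [base, base + np.array([0.5, 0.3]), base - np.array([0.5, 0.3])]


# -------------------------------------------------------------------- gompertz

def _gomp_logsf(theta, t):
    a, b = theta[0], math.exp(theta[1])
    if abs(a) < _GOMP_A_EPS:
        return -b * t
    with np.errstate(over="ignore"):
        return -(b / a) * np.expm1(a * t)


def _gomp_logpdf(theta, t):
    a, b = theta[0], math.exp(theta[1])
    # log hazard + log survival
    return theta[1] + a * t + _gomp_logsf(theta, t)


def _gomp_median(theta):
    a, b = theta[0], math.exp(theta[1])
    if abs(a) < _GOMP_A_EPS:
        return math.log(2.0) / b
    arg = 1.0 + a * math.log(2.0) / b
    if arg <= 0:  # plateau above 0.5: median never reached
        return math.inf
    return math.log(arg) / a


def _gomp_ppf(theta, u):
    a, b = theta[0], math.exp(theta[1])
    u = np.asarray(u, dtype=float)
    logs = np.log1p(-u)  # log of target survival
    if abs(a) < _GOMP_A_EPS:
        return -logs / b
    arg = 1.0 - (a / b) * logs
    out = np.full_like(arg, np.inf)
    ok = arg > 0
    out[ok] = np.log(arg[ok]) / a
    return out


def _gomp_init(times, events):
    d = max(events.sum(), 1.0)
    lb = math.log(d / times.sum())
    scale = 1.0 / times.mean()
    return [
        np.array([1e-6, lb]),
        np.array([0.2 * scale, lb]),
        np.array([-0.2 * scale, lb]),
    ]


# ----------------------------------------------------------------- loglogistic

def _llog_logsf(theta, t):
    beta = math.exp(theta[0])
    x = beta * (np.log(t) - theta[1])
    return -_softplus(x)


def _llog_logpdf(theta, t):
    beta = math.exp(theta[0])
    lt = np.log(t)
    x = beta * (lt - theta[1])
    return theta[0] - lt + x - 2.0 * _softplus(x)


def _llog_init(times, events):
    lt = np.log(times[events == 1]) if events.sum() else np.log(times)
    s = lt.std() if len(lt) > 1 and lt.std() > 0 else 1.0
    base = np.array([math.log(max(1.0 / s, 0.05)), lt.mean()])
    return [base, base + np.array([0.5, 0.3]), base - np.array([0.5, 0.3])]


# ------------------------------------------------------------------- lognormal

def _lnorm_logsf(theta, t):
    sigma = math.exp(theta[1])
    z = (np.log(t) - theta[0]) / sigma
    return special.log_ndtr(-z)


def _lnorm_logpdf(theta, t):
    sigma = math.exp(theta[1])
    lt = np.log(t)
    z = (lt - theta[0]) / sigma
    return -lt - theta[1] - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z


def _lnorm_init(times, events):
    lt = np.log(times[events == 1]) if events.sum() else np.log(times)
    s = lt.std() if len(lt) > 1 and lt.std() > 0 else 1.0
    base = np.array([lt.mean(), math.log(s)])
    return [base, base + np.array([0.3, 0.4]), base - np.array([0.3, 0.4])]


# ------------------------------------------------------- generalized gamma

def _gg_logsf(theta, t):
    mu, q = theta[0], theta[2]
    sigma = math.exp(theta[1])
    if abs(q) < _GG_Q_EPS:
        return _lnorm_logsf(theta[:2], t)
    gam = q ** -2
    w = (np.log(t) - mu) / sigma
    u = gam * np.exp(q * w)
    if q > 0:
        s = special.gammaincc(gam, u)
    else:
        s = special.gammainc(gam, u)
    with np.errstate(divide="ignore"):
        return np.log(s)


def _gg_logpdf(theta, t):
    mu, q = theta[0], theta[2]
    sigma = math.exp(theta[1])
    if abs(q) < _GG_Q_EPS:
        return _lnorm_logpdf(theta[:2], t)
    gam = q ** -2
    lt = np.log(t)
    w = (lt - mu) / sigma
    return (
        math.log(abs(q))
        - theta[1]
        - lt
        + gam * math.log(gam)
        - special.gammaln(gam)
        + gam * (q * w - np.exp(q * w))
    )


def _gg_median(theta):
    mu, q = theta[0], theta[2]
    sigma = math.exp(theta[1])
    if abs(q) < _GG_Q_EPS:
        return math.exp(mu)
    gam = q ** -2
    ustar = special.gammainccinv(gam, 0.5) if q > 0 else special.gammaincinv(gam, 0.5)
    w = math.log(ustar / gam) / q
    return math.exp(mu + sigma * w)


def _gg_ppf(theta, u):
    mu, q = theta[0], theta[2]
    sigma = math.exp(theta[1])
    u = np.asarray(u, dtype=float)
    if abs(q) < _GG_Q_EPS:
        return np.exp(mu + sigma * special.ndtri(u))
    gam = q ** -2
    surv = 1.0 - u
    if q > 0:
        x = special.gammainccinv(gam, surv)
    else:
        x = special.gammaincinv(gam, surv)
    w = np.log(x / gam) / q
    return np.exp(mu + sigma * w)


def _gg_init(times, events):
    lt = np.log(times[events == 1]) if events.sum() else np.log(times)
    s = lt.std() if len(lt) > 1 and lt.std() > 0 else 1.0
    m = lt.mean()
    ls = math.log(s)
    return [
        np.array([m, ls, 0.5]),
        np.array([m, ls, 1.0]),
        np.array([m, ls, -0.5]),
        np.array([m, ls, 1e-4]),
    ]


# ------------------------------------------------------------------- registry

FAMILIES: Dict[str, Family] = {
    "exponential": Family(
        name="exponential",
        n_params=1,
        param_names=("log_rate",),
        logsf=_exp_logsf,
        logpdf=_exp_logpdf,
        median=lambda th: math.log(2.0) / math.exp(th[0]),
        ppf_time=lambda th, u: -np.log1p(-np.asarray(u, float)) / math.exp(th[0]),
        pack=lambda rate: np.array([math.log(rate)]),
        unpack=lambda th: {"rate": math.exp(th[0])},
        init=_exp_init,
    ),
    "weibull": Family(
        name="weibull",
        n_params=2,
        param_names=("log_shape", "log_scale"),
        logsf=_wei_logsf,
        logpdf=_wei_logpdf,
        median=lambda th: math.exp(th[1]) * math.log(2.0) ** (1.0 / math.exp(th[0])),
        ppf_time=lambda th, u: math.exp(th[1])
        * (-np.log1p(-np.asarray(u, float))) ** (1.0 / math.exp(th[0])),
        pack=lambda shape, scale: np.array([math.log(shape), math.log(scale)]),
        unpack=lambda th: {"shape": math.exp(th[0]), "scale": math.exp(th[1])},
        init=_wei_init,
    ),
    "gompertz": Family(
        name="gompertz",
        n_params=2,
        param_names=("shape", "log_rate"),
        logsf=_gomp_logsf,
        logpdf=_gomp_logpdf,
        median=_gomp_median,
        ppf_time=_gomp_ppf,
        pack=lambda shape, rate: np.array([shape, math.log(rate)]),
        unpack=lambda th: {"shape": th[0], "rate": math.exp(th[1])},
        init=_gomp_init,
    ),
    "loglogistic": Family(
        name="loglogistic",
        n_params=2,
        param_names=("log_shape", "log_scale"),
        logsf=_llog_logsf,
        logpdf=_llog_logpdf,
        median=lambda th: math.exp(th[1]),
        ppf_time=lambda th, u: math.exp(th[1])
        * (np.asarray(u, float) / (1.0 - np.asarray(u, float)))
        ** (1.0 / math.exp(th[0])),
        pack=lambda shape, scale: np.array([math.log(shape), math.log(scale)]),
        unpack=lambda th: {"shape": math.exp(th[0]), "scale": math.exp(th[1])},
        init=_llog_init,
    ),
    "lognormal": Family(
        name="lognormal",
        n_params=2,
        param_names=("mu", "log_sigma"),
        logsf=_lnorm_logsf,
        logpdf=_lnorm_logpdf,
        median=lambda th: math.exp(th[0]),
        ppf_time=lambda th, u: np.exp(
            th[0] + math.exp(th[1]) * special.ndtri(np.asarray(u, float))
        ),
        pack=lambda mu, sigma: np.array([mu, math.log(sigma)]),
        unpack=lambda th: {"mu": th[0], "sigma": math.exp(th[1])},
        init=_lnorm_init,
    ),
    "gengamma": Family(
        name="gengamma",
        n_params=3,
        param_names=("mu", "log_sigma", "q"),
        logsf=_gg_logsf,
        logpdf=_gg_logpdf,
        median=_gg_median,
        ppf_time=_gg_ppf,
        pack=lambda mu, sigma, q: np.array([mu, math.log(sigma), q]),
        unpack=lambda th: {"mu": th[0], "sigma": math.exp(th[1]), "q": th[2]},
        init=_gg_init,
    ),
}

FAMILY_NAMES: Sequence[str] = tuple(FAMILIES)


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown survival family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
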