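"""Configuration loading and validation.

The parameter file is a YAML document mirroring the model's input table
column-for-column: every row carries its baseline, one-way (DSA) bounds
and, where sampled in the PSA, its beta or gamma parameterization.  The
loader builds a :class:`~psmcea.psm.ModelParams` plus the distribution
registry that drives the sensitivity analyses.  Missing optional fields
are defaulted with a logged warning; invariant violations raise with the
offending field named.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import List, Optional, Tuple, Union

import yaml

from .psm import AE_NAMES, SUBSEQUENT_CLASSES, ModelParams
from .uncertainty import ParamDistribution

logger = logging.getLogger(__name__)

__all__ = ["load_config", "baseline_config_path", "ConfigError"]


class ConfigError(ValueError):
    pass


def baseline_config_path() -> Path:
    """Path of the shipped baseline parameter fixture."""
    return Path(importlib.resources.files("psmcea") / "data" / "table1_baseline.yaml")


def _row(node, field: str, default=None, required=True) -> dict:
    """Normalize a scalar-or-mapping YAML node to a row dict."""
    if node is None:
        if required and default is None:
            raise ConfigError(f"missing required field {field!r}")
        logger.warning("field %s missing; defaulting to %s", field, default)
        node = default
    if not isinstance(node, dict):
        node = {"base": float(node)}
    if "base" not in node:
        raise ConfigError(f"field {field!r} has no baseline value")
    return node


def _registry_entry(pid: str, row: dict, group: Optional[str] = None
                    ) -> Optional[ParamDistribution]:
    kind = row.get("dist", "fixed")
    base = float(row["base"])
    low = float(row.get("low", base))
    high = float(row.get("high", base))
    if kind == "fixed" and low == high == base:
        return None  # nothing to vary or sample
    try:
        return ParamDistribution(
            pid=pid, kind=kind, baseline=base, dsa_low=low, dsa_high=high,
            mean=row.get("mean"), se=row.get("se"),
            alpha=row.get("alpha"), beta=row.get("beta"),
            shape=row.get("shape"), scale=row.get("scale"),
            negate=bool(row.get("negate", False)), group=group,
        )
    except ValueError as exc:
        raise ConfigError(f"field {pid!r}: {exc}") from exc


def load_config(path: Union[str, Path, None] = None
                ) -> Tuple[ModelParams, List[ParamDistribution]]:
    """Load a parameter file (the shipped baseline when ``path`` is
    None); returns the model parameters and the DSA/PSA registry."""
    if path is None:
        path = baseline_config_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a mapping")

    registry: List[ParamDistribution] = []
    model = doc.get("model", {})
    disc = _row(model.get("discount_rate"), "model.discount_rate", default=0.05)
    bsa = _row(model.get("bsa"), "model.bsa", default=1.80)
    params = ModelParams(
        cycle_length_days=float(model.get("cycle_days", 42)),
        discount_rate=float(disc["base"]),
        wtp=float(model.get("wtp", 38142.56)),
        horizon_threshold=float(model.get("horizon_threshold", 0.01)),
        horizon_cap_years=float(model.get("horizon_cap_years", 40)),
        bsa=float(bsa["base"]),
        weight_kg=float(model.get("weight_kg", 65)),
    )
    for pid, row in (("discount_rate", disc), ("bsa", bsa)):
        entry = _registry_entry(pid, row)
        if entry:
            registry.append(entry)

    util = doc.get("utilities", {})
    for pid in ("u_pfs", "u_pd"):
        row = _row(util.get(pid), f"utilities.{pid}")
        value = float(row["base"])
        if not 0 <= value <= 1:
            raise ConfigError(f"utilities.{pid}={value} outside [0, 1]")
        setattr(params, pid, value)
        entry = _registry_entry(pid, row)
        if entry:
            registry.append(entry)

    for arm in ("P", "C"):
        params.ae_incidence[arm] = {}
        for ae in AE_NAMES:
            row = _row(doc.get("ae_incidence", {}).get(arm, {}).get(ae),
                       f"ae_incidence.{arm}.{ae}", default=0.0)
            v = float(row["base"])
            if not 0 <= v <= 1:
                raise ConfigError(f"ae_incidence.{arm}.{ae}={v} outside [0, 1]")
            params.ae_incidence[arm][ae] = v
            entry = _registry_entry(f"ae_incidence.{arm}.{ae}", row)
            if entry:
                registry.append(entry)

    for section, target in (("ae_cost", params.ae_cost),
                            ("ae_disutility", params.ae_disutility)):
        for ae in AE_NAMES:
            row = _row(doc.get(section, {}).get(ae), f"{section}.{ae}", default=0.0)
            target[ae] = float(row["base"])
            entry = _registry_entry(f"{section}.{ae}", row)
            if entry:
                registry.append(entry)

    for drug, row in doc.get("prices", {}).items():
        row = _row(row, f"prices.{drug}")
        v = float(row["base"])
        if v < 0:
            raise ConfigError(f"prices.{drug}={v} negative")
        params.prices[drug] = v
        entry = _registry_entry(f"price.{drug}", row)
        if entry:
            registry.append(entry)

    costs = doc.get("costs", {})
    defaults = {"admin_cost": None, "followup_cost": None, "bsc_cost": 0.0}
    for pid, dflt in defaults.items():
        row = _row(costs.get(pid), f"costs.{pid}", default=dflt)
        setattr(params, pid, float(row["base"]))
        entry = _registry_entry(pid, row)
        if entry:
            registry.append(entry)

    mix = doc.get("firstline_mix_C")
    if mix is None:
        raise ConfigError("missing required field 'firstline_mix_C'")
    params.firstline_mix_C = {k: float(v) for k, v in mix.items()}

    for arm in ("P", "C"):
        params.subsequent_mix[arm] = {}
        arm_doc = doc.get("subsequent_mix", {}).get(arm)
        if arm_doc is None:
            raise ConfigError(f"missing required field 'subsequent_mix.{arm}'")
        for cls in SUBSEQUENT_CLASSES:
            row = _row(arm_doc.get(cls), f"subsequent_mix.{arm}.{cls}", default=0.0)
            params.subsequent_mix[arm][cls] = float(row["base"])
            entry = _registry_entry(f"subsequent_mix.{arm}.{cls}", row,
                                    group=f"subsequent_{arm}")
            if entry:
                registry.append(entry)

    pap = doc.get("pap", {}) or {}
    params.pap_enabled = bool(pap.get("enabled", False))
    params.pap_annual_cost = float(pap.get("annual_cost", 11200.0))
    params.pap_cap = float(pap.get("cap", 22400.0))

    try:
        params.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    if params.prices.get("pembrolizumab", 0) > 100:
        logger.info(
            "pembrolizumab unit price %.2f USD/mg implies ~%.0f USD per 200 mg "
            "dose; value used as configured",
            params.prices["pembrolizumab"], 200 * params.prices["pembrolizumab"])
    return params, registry
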