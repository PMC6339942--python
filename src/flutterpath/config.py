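"""Configuration loading, substrate presets, and run-config validation.

Substrate files are YAML/JSON mappings::

    bcl_range: [200, 1000]
    regions:
      default: {cv: {A: 700, B: 0, C: 150}, erp: {A: 250, B: 0, C: 150}, k: 1}
      slow:    {cv: {A: 500, B: 0, C: 150}, erp: {A: 250, B: 0, C: 150}, k: 1}

The shipped multi-region preset is ILLUSTRATIVE: its coefficients are chosen
to reproduce the qualitative regional ordering (ERP plateaus between roughly
256 and 332 ms, slow-conducting isthmus, fast anisotropic bundles), not any
measured dataset.  Scientific use requires an explicit substrate file.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import yaml

from .restitution import (
    DEFAULT_BCL_RANGE,
    RegionProperties,
    RestitutionParams,
    SubstrateConfig,
)

__all__ = [
    "load_substrate",
    "substrate_from_dict",
    "substrate_preset",
    "cv_ratio",
    "config_digest",
    "PRESET_NAMES",
]


def _params(d: dict, quantity: str) -> RestitutionParams:
    try:
        return RestitutionParams(float(d["A"]), float(d.get("B", 0.0)), float(d.get("C", 150.0)), quantity)
    except KeyError as exc:
        raise ValueError(f"restitution spec missing key {exc} (need A, optionally B, C)") from exc


def substrate_from_dict(data: dict[str, Any], name: str | None = None) -> SubstrateConfig:
    if "regions" not in data or not isinstance(data["regions"], dict):
        raise ValueError("substrate config must contain a 'regions' mapping")
    regions = {}
    for label, spec in data["regions"].items():
        for key in ("cv", "erp"):
            if key not in spec:
                raise ValueError(f"region {label!r} is missing its {key!r} curve")
        regions[str(label)] = RegionProperties(
            cv=_params(spec["cv"], "CV"),
            erp=_params(spec["erp"], "ERP"),
            k=float(spec.get("k", 1.0)),
        )
    bcl_range = tuple(data.get("bcl_range", DEFAULT_BCL_RANGE))
    return SubstrateConfig(regions, bcl_range=bcl_range, name=name or data.get("name"))


def load_substrate(path: str) -> SubstrateConfig:
    """Load a substrate config from a YAML (or JSON) file."""
    with open(path) as f:
        data = yaml.safe_load(f)
    return substrate_from_dict(data, name=str(path))


def _const(cv: float, erp: float, k: float = 1.0) -> RegionProperties:
    return RegionProperties(
        cv=RestitutionParams(cv, 0.0, 150.0, "CV"),
        erp=RestitutionParams(erp, 0.0, 150.0, "ERP"),
        k=k,
    )


def substrate_preset(name: str, **kwargs) -> SubstrateConfig:
    """Built-in substrate parameter sets.

    ``clinical_example``
        Homogeneous CV 650 mm/s, constant ERP 250 ms, isotropic.
    ``slow_zone``
        Surrounding tissue at 700 mm/s with a ``slow`` region whose CV is
        ``slow_cv`` (default 500 mm/s); constant ERP 250 ms.
    ``illustrative``
        Multi-region rate-dependent set (labeled illustrative, see module
        docstring).
    ``control``
        Homogeneous restitution with long-cycle CV 454 mm/s and long-cycle
        ERP 318 ms, anisotropic (k = 4).
    """
    if name == "clinical_example":
        return SubstrateConfig({"default": _const(650.0, 250.0)}, name=name)
    if name == "slow_zone":
        slow_cv = float(kwargs.get("slow_cv", 500.0))
        return SubstrateConfig(
            {"default": _const(700.0, 250.0), "slow": _const(slow_cv, 250.0)},
            name=name,
        )
    if name == "control":
        return SubstrateConfig(
            {
                "default": RegionProperties(
                    cv=RestitutionParams(454.0, 120.0, 180.0, "CV"),
                    erp=RestitutionParams(318.0, 90.0, 190.0, "ERP"),
                    k=float(kwargs.get("k", 4.0)),
                )
            },
            name=name,
        )
    if name == "illustrative":
        regions = {
            "default": RegionProperties(  # working myocardium (RA/LA)
                cv=RestitutionParams(700.0, 180.0, 170.0, "CV"),
                erp=RestitutionParams(300.0, 95.0, 190.0, "ERP"),
                k=float(kwargs.get("k", 3.0)),
            ),
            "crista_terminalis": RegionProperties(
                cv=RestitutionParams(900.0, 280.0, 160.0, "CV"),
                erp=RestitutionParams(332.0, 160.0, 150.0, "ERP"),
                k=9.0,
            ),
            "pectinate_muscles": RegionProperties(
                cv=RestitutionParams(750.0, 200.0, 170.0, "CV"),
                erp=RestitutionParams(300.0, 90.0, 190.0, "ERP"),
                k=6.0,
            ),
            "bachmann_bundle": RegionProperties(
                cv=RestitutionParams(950.0, 260.0, 160.0, "CV"),
                erp=RestitutionParams(330.0, 150.0, 150.0, "ERP"),
                k=9.0,
            ),
            "valve_ring": RegionProperties(
                cv=RestitutionParams(600.0, 160.0, 180.0, "CV"),
                erp=RestitutionParams(256.0, 60.0, 200.0, "ERP"),
                k=2.0,
            ),
            "inferior_isthmus": RegionProperties(
                cv=RestitutionParams(500.0, 150.0, 180.0, "CV"),
                erp=RestitutionParams(290.0, 80.0, 190.0, "ERP"),
                k=2.0,
            ),
        }
        return SubstrateConfig(regions, name=name)
    raise KeyError(f"unknown substrate preset {name!r}; known: {PRESET_NAMES}")


PRESET_NAMES = ("clinical_example", "slow_zone", "control", "illustrative")


def cv_ratio(cfg: SubstrateConfig, region_a: str, region_b: str, bcl: float | None = None) -> float:
    """Ratio CV(region_a)/CV(region_b), rounded to two decimals.

    Evaluated at ``bcl`` (default: the top of the validity range, i.e. the
    long-cycle plateau).
    """
    b = cfg.bcl_range[1] if bcl is None else bcl
    return round(cfg.cv(region_a, b) / cfg.cv(region_b, b), 2)


def config_digest(obj: Any) -> str:
    """Stable sha256 digest of a JSON-serializable configuration object."""

    def default(o):
        if isinstance(o, SubstrateConfig):
            return {
                "bcl_range": o.bcl_range,
                "regions": {
                    lbl: {
                        "cv": (p.cv.A, p.cv.B, p.cv.C),
                        "erp": (p.erp.A, p.erp.B, p.erp.C),
                        "k": p.k,
                    }
                    for lbl, p in sorted(o.regions.items())
                },
            }
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
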