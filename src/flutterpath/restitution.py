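"""Rate-dependent conduction-velocity and refractory-period restitution.

Both quantities follow a saturating exponential in the basic cycle length
(BCL, ms)::

    value(BCL) = A - B * exp(-BCL / C)

with A the long-cycle asymptote (mm/s for CV, ms for ERP), B the decay
amplitude and C the decay constant (ms).  BCL outside the declared validity
range is clamped: the curve is a fit and does not extrapolate meaningfully
toward BCL -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RestitutionParams",
    "RegionProperties",
    "SubstrateConfig",
    "NodeRateState",
    "cv_at",
    "erp_at",
    "wavelength_at",
    "fit_restitution",
    "FitError",
]

DEFAULT_BCL_RANGE = (200.0, 1000.0)


@dataclass(frozen=True)
class RestitutionParams:
    """Exponential restitution coefficients for one quantity (CV or ERP)."""

    A: float
    B: float
    C: float
    quantity: str = "CV"  # "CV" or "ERP"

    def __post_init__(self) -> None:
        if self.quantity not in ("CV", "ERP"):
            raise ValueError("quantity must be 'CV' or 'ERP'")
        if self.C <= 0:
            raise ValueError("decay constant C must be positive")
        if self.A <= 0:
            raise ValueError("asymptote A must be positive")

    def __call__(self, bcl: float, bcl_range: tuple[float, float] = DEFAULT_BCL_RANGE) -> float:
        return evaluate(self, bcl, bcl_range)


def evaluate(params: RestitutionParams, bcl, bcl_range=DEFAULT_BCL_RANGE):
    """Evaluate the restitution curve with BCL clamped to its validity range."""
    bcl = np.clip(bcl, bcl_range[0], bcl_range[1])
    if np.ndim(bcl) == 0:
        if not math.isfinite(float(bcl)):
            raise ValueError("bcl must be finite")
        return params.A - params.B * math.exp(-float(bcl) / params.C)
    bcl = np.asarray(bcl, dtype=float)
    if not np.isfinite(bcl).all():
        raise ValueError("bcl must be finite")
    return params.A - params.B * np.exp(-bcl / params.C)


def cv_at(params: RestitutionParams, bcl, bcl_range=DEFAULT_BCL_RANGE):
    """Conduction velocity in mm/s at the given BCL (ms)."""
    if params.quantity != "CV":
        raise ValueError("cv_at requires CV params")
    return evaluate(params, bcl, bcl_range)


def erp_at(params: RestitutionParams, bcl, bcl_range=DEFAULT_BCL_RANGE):
    """Effective refractory period in ms at the given BCL (ms)."""
    if params.quantity != "ERP":
        raise ValueError("erp_at requires ERP params")
    return evaluate(params, bcl, bcl_range)


@dataclass(frozen=True)
class RegionProperties:
    """Per-region substrate description: CV curve, ERP curve, anisotropy k."""

    cv: RestitutionParams
    erp: RestitutionParams
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1.0:
            raise ValueError("anisotropy ratio k must be >= 1")
        if self.cv.quantity != "CV" or self.erp.quantity != "ERP":
            raise ValueError("RegionProperties requires a CV curve and an ERP curve")


@dataclass
class NodeRateState:
    """Rate bookkeeping for one node."""

    last_activation_time: float
    bcl: float

    def __post_init__(self) -> None:
        if not self.bcl > 0:
            raise ValueError("bcl must be positive")


class SubstrateConfig:
    """Map of region label -> :class:`RegionProperties` with a default entry.

    The region named ``default`` (if present) backs any label the mesh uses
    that has no explicit entry.
    """

    def __init__(
        self,
        regions: dict[str, RegionProperties],
        bcl_range: tuple[float, float] = DEFAULT_BCL_RANGE,
        name: str | None = None,
    ):
        if not regions:
            raise ValueError("at least one region must be configured")
        if not bcl_range[1] > bcl_range[0] > 0:
            raise ValueError("invalid bcl validity range")
        self.regions = dict(regions)
        self.bcl_range = (float(bcl_range[0]), float(bcl_range[1]))
        self.name = name
        for label, props in self.regions.items():
            lo = self.bcl_range[0]
            for p in (props.cv, props.erp):
                if p.A - p.B * math.exp(-lo / p.C) <= 0:
                    raise ValueError(
                        f"region {label!r}: {p.quantity} curve is non-positive at BCLmin"
                    )

    def __contains__(self, label: str) -> bool:
        return label in self.regions or "default" in self.regions

    def properties(self, label: str) -> RegionProperties:
        if label in self.regions:
            return self.regions[label]
        if "default" in self.regions:
            return self.regions["default"]
        raise KeyError(f"unknown region {label!r} and no default configured")

    def cv(self, label: str, bcl) -> float:
        """CV in mm/s for the region at the given BCL."""
        return cv_at(self.properties(label).cv, bcl, self.bcl_range)

    def erp(self, label: str, bcl) -> float:
        """ERP in ms for the region at the given BCL."""
        return erp_at(self.properties(label).erp, bcl, self.bcl_range)

    def k(self, label: str) -> float:
        return self.properties(label).k

    def validate_mesh(self, mesh) -> None:
        missing = sorted({str(r) for r in mesh.region} - set(self.regions))
        if missing and "default" not in self.regions:
            raise ValueError(f"mesh regions without substrate entry: {missing}")

    def scaled_cv(self, factor: float) -> "SubstrateConfig":
        """New config with all CV curves scaled (A and B multiplied by factor)."""
        regions = {
            label: RegionProperties(
                cv=RestitutionParams(p.cv.A * factor, p.cv.B * factor, p.cv.C, "CV"),
                erp=p.erp,
                k=p.k,
            )
            for label, p in self.regions.items()
        }
        return SubstrateConfig(regions, self.bcl_range, name=self.name)


def wavelength_at(cfg: SubstrateConfig, region: str, bcl) -> float:
    """Wavelength WL = CV(bcl) * ERP(bcl) in mm (mm/ms x ms)."""
    if region not in cfg:
        raise KeyError(f"unknown region {region!r}")
    return cfg.cv(region, bcl) / 1000.0 * cfg.erp(region, bcl)


class FitError(RuntimeError):
    """Raised when restitution fitting cannot converge."""


def fit_restitution(samples, quantity: str = "CV") -> tuple[RestitutionParams, float]:
    """Least-squares fit of the exponential restitution curve.

    Parameters
    ----------
    samples : sequence of (bcl_ms, value) pairs
        At least 4 samples spanning a non-degenerate BCL range.

    Returns
    -------
    (params, residual_norm)
    """
    from scipy.optimize import curve_fit

    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 4:
        raise ValueError("need >= 4 (bcl, value) samples")
    bcl, val = arr[:, 0], arr[:, 1]
    span = bcl.max() - bcl.min()
    if span < 1e-9:
        raise FitError("degenerate samples: constant bcl")

    def model(x, A, B, C):
        return A - B * np.exp(-x / C)

    p0 = (float(val.max()), float(val.max() - val.min()), max(span / 3.0, 1.0))
    try:
        popt, _ = curve_fit(
            model,
            bcl,
            val,
            p0=p0,
            bounds=([1e-9, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - solver failure path
        raise FitError(f"restitution fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(model(bcl, *popt) - val))
    return RestitutionParams(float(popt[0]), float(popt[1]), float(popt[2]), quantity), resid


def bcl_grid(n: int = 50, lo: float = 200.0, hi: float = 1000.0) -> np.ndarray:
    """n BCLs distributed linearly in frequency (1/BCL) between lo and hi, ms."""
    freqs = np.linspace(1.0 / hi, 1.0 / lo, n)
    return np.sort(1.0 / freqs)
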