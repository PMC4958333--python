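"""Cylinder-body morphometry and the exponential-growth division-number estimator.

The mouse trunk is modelled as a cylinder of radius ``r`` (half the body width)
and height ``h`` (trunk length).  The dermis is the cylindrical shell between
the body surface and depth ``dd``, so its volume is

    dv = pi * r**2 * h  -  pi * (r - dd)**2 * h  =  pi * h * (2*r*dd - dd**2).

Under exponential cellular growth the number of divisions ``n`` between two
ages follows from the total-cell-number ratio, ``N / N0 = 2**n``, and total
cell number is proportional to dermis volume times areal fibroblast density,
``N ∝ dv * rho``.  Because the effective optical-section thickness behind the
areal density (cells per mm² of a fixed-thickness whole-mount section) is
constant, it cancels in every ratio; absolute values of ``dv * rho`` are
therefore reported in *relative units* only, and ``n`` is invariant to the
unit convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

Sex = Literal["male", "female", "pooled"]
LayerName = Literal["papillary", "reticular", "DWAT", "total"]

#: dermal compartments used in clone-size tables (DP = dermal papilla)
COMPARTMENTS = ("papillary", "reticular", "DWAT", "DP")

_REL_TOL = 1e-9


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value}")
    return value


@dataclass(frozen=True)
class BodyMeasurement:
    """Trunk morphometry of one animal at one age.

    length_cm is the trunk length h (scapulae to tail base), width_cm the body
    width at the widest point (so radius r = width/2) and dermis_depth_cm the
    dermis depth dd measured on back-skin sections.
    """

    age_days: int
    sex: Sex
    length_cm: float
    width_cm: float
    dermis_depth_cm: float

    def __post_init__(self) -> None:
        for field in ("length_cm", "width_cm", "dermis_depth_cm"):
            v = getattr(self, field)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{field} must be strictly positive, got {v}")
        if self.dermis_depth_cm >= self.width_cm / 2:
            raise ValueError(
                "dermis_depth_cm must be smaller than half the body width "
                f"(got dd={self.dermis_depth_cm}, width/2={self.width_cm / 2})"
            )
        if self.sex not in ("male", "female", "pooled"):
            raise ValueError(f"unknown sex {self.sex!r}")

    def geometry(self) -> "DermisGeometry":
        return body_geometry(self)


@dataclass(frozen=True)
class DermisGeometry:
    """Derived cylinder geometry: total body volume V and dermis shell volume dv."""

    radius_cm: float
    height_cm: float
    depth_cm: float
    total_volume_cm3: float
    dermis_volume_cm3: float

    def __post_init__(self) -> None:
        if self.dermis_volume_cm3 < 0 or self.total_volume_cm3 < 0:
            raise ValueError("volumes must be non-negative")
        if self.dermis_volume_cm3 > self.total_volume_cm3 * (1 + _REL_TOL):
            raise ValueError("dermis volume cannot exceed total volume")


@dataclass(frozen=True)
class DensitySample:
    """Areal fibroblast density (cells per mm² of section) for one dermal layer."""

    age_days: int
    layer: LayerName
    rho_per_mm2: float
    n_regions: int = 1

    def __post_init__(self) -> None:
        if self.rho_per_mm2 < 0:
            raise ValueError("rho_per_mm2 must be non-negative")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")


@dataclass(frozen=True)
class DivisionEstimate:
    """Output of the division-number estimator.

    n_divisions = log2(cell_ratio) where cell_ratio = N/N0; when the ratio is
    decomposed, cell_ratio = volume_ratio * density_ratio holds exactly up to
    floating tolerance.  Negative n (net cell loss) is permitted.
    """

    n_divisions: float
    cell_ratio: float
    volume_ratio: Optional[float] = None
    density_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cell_ratio <= 0:
            raise ValueError("cell_ratio must be strictly positive")
        if abs(self.n_divisions - math.log2(self.cell_ratio)) > 1e-6:
            raise ValueError("n_divisions must equal log2(cell_ratio)")
        if self.volume_ratio is not None and self.density_ratio is not None:
            prod = self.volume_ratio * self.density_ratio
            if abs(prod - self.cell_ratio) > _REL_TOL * max(1.0, abs(self.cell_ratio)):
                raise ValueError(
                    "cell_ratio must equal volume_ratio * density_ratio "
                    f"({self.cell_ratio} vs {prod})"
                )
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError("CI bounds must be ordered")


def cylinder_volume(radius_cm: float, height_cm: float) -> float:
    """Total body volume V = pi * r^2 * h (cm³)."""
    r = _require_finite_nonneg("radius_cm", radius_cm)
    h = _require_finite_nonneg("height_cm", height_cm)
    return math.pi * r * r * h


def dermis_volume(radius_cm: float, height_cm: float, depth_cm: float) -> float:
    """Dermis shell volume dv = pi*h*(2*r*dd - dd^2) (cm³).

    The shell between the body surface (radius r) and the inner cylinder of
    radius r - dd.  Requires 0 <= dd <= r.
    """
    r = _require_finite_nonneg("radius_cm", radius_cm)
    h = _require_finite_nonneg("height_cm", height_cm)
    dd = _require_finite_nonneg("depth_cm", depth_cm)
    if dd > r:
        raise ValueError(f"depth_cm ({dd}) cannot exceed radius_cm ({r})")
    return math.pi * h * (2.0 * r * dd - dd * dd)


def depth_for_volume(radius_cm: float, height_cm: float, dermis_volume_cm3: float) -> float:
    """Invert the shell formula: the depth dd giving the requested dermis volume."""
    r = _require_finite_nonneg("radius_cm", radius_cm)
    h = _require_finite_nonneg("height_cm", height_cm)
    dv = _require_finite_nonneg("dermis_volume_cm3", dermis_volume_cm3)
    if h == 0 or r == 0:
        if dv == 0:
            return 0.0
        raise ValueError("degenerate cylinder cannot hold a positive dermis volume")
    inner_sq = r * r - dv / (math.pi * h)
    if inner_sq < -_REL_TOL:
        raise ValueError("requested dermis volume exceeds the total cylinder volume")
    return r - math.sqrt(max(inner_sq, 0.0))


def body_geometry(measurement: BodyMeasurement) -> DermisGeometry:
    """Cylinder geometry for one animal: r = width/2, h = length."""
    r = measurement.width_cm / 2.0
    h = measurement.length_cm
    dd = measurement.dermis_depth_cm
    return DermisGeometry(
        radius_cm=r,
        height_cm=h,
        depth_cm=dd,
        total_volume_cm3=cylinder_volume(r, h),
        dermis_volume_cm3=dermis_volume(r, h, dd),
    )


def relative_cell_number(dermis_volume_cm3: float, rho_per_mm2: float) -> float:
    """Relative total fibroblast number N ∝ dv * rho.

    The product of a cm³ volume and a per-mm² areal density is proportional to
    the true cell number with a constant of proportionality set by the
    effective optical-section thickness; that constant cancels in all N/N0
    ratios, so the return value is in relative units only.
    """
    dv = _require_finite_nonneg("dermis_volume_cm3", dermis_volume_cm3)
    rho = _require_finite_nonneg("rho_per_mm2", rho_per_mm2)
    return dv * rho


def estimate_divisions(
    n0_relative: float,
    n_relative: float,
    volume_ratio: Optional[float] = None,
    density_ratio: Optional[float] = None,
) -> DivisionEstimate:
    """Division number n = log2(N / N0) under exponential growth.

    ``n0_relative`` and ``n_relative`` are the relative cell numbers at the
    earlier and later age.  Optional volume/density ratios are attached for
    provenance and checked against the cell ratio.
    """
    if not (math.isfinite(n0_relative) and n0_relative > 0):
        raise ValueError(f"N0 must be strictly positive, got {n0_relative}")
    if not (math.isfinite(n_relative) and n_relative > 0):
        raise ValueError(f"N must be strictly positive, got {n_relative}")
    ratio = n_relative / n0_relative
    return DivisionEstimate(
        n_divisions=math.log2(ratio),
        cell_ratio=ratio,
        volume_ratio=volume_ratio,
        density_ratio=density_ratio,
    )


def fold_change(value_t0: float, value_t1: float) -> float:
    """Ratio value_t1 / value_t0 (e.g. adult over neonatal dermal volume)."""
    if not (math.isfinite(value_t0) and value_t0 > 0):
        raise ValueError(f"baseline must be strictly positive, got {value_t0}")
    if not math.isfinite(value_t1):
        raise ValueError(f"value_t1 must be finite, got {value_t1}")
    return value_t1 / value_t0


def rounded_fold(value_t0: float, value_t1: float) -> int:
    """Companion integer-fold report (nearest integer; raw ratio via fold_change)."""
    return round(fold_change(value_t0, value_t1))
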