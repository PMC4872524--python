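"""Hydraulic resistance-network model of a trapping unit.

Fully developed laminar flow in a rectangular duct obeys

    Δp = fRe · L · ū · η / (2 Dh²),

where fRe, the product of the Darcy friction factor and the Reynolds
number, is a constant depending only on the duct aspect ratio
(Shah–London correlation), Dh = 4A/P is the hydraulic diameter, and ū the
mean velocity.  Writing Q = ū·A, each segment has a hydraulic resistance
R = Δp/Q = fRe·L·η/(2·Dh²·A), and the trapping path (Path 1, five segments
in series) competes with the bypass loop (Path 2) as two resistors in
parallel: Δp1 = Δp2, Q1/Q2 = R2/R1.

The design rule for a working trap is Q2/Q1 < 1: more flow must pass
through the empty trap than around it, so that an approaching cell is
pulled into the pocket.  Once the pocket is occupied (or the valve over
the middle chamber is closed) Path 1 is blocked and all flow diverts to
the bypass.

Units are SI internally; geometry interfaces are in μm and flow-rate
interfaces accept μl/h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import ChannelSegment, TrapUnitGeometry

UM = 1e-6                       # m per μm
UL_PER_H = 1e-9 / 3600.0        # m³/s per μl/h

#: Shah–London polynomial coefficients for fRe(α) in rectangular ducts.
_SHAH_LONDON = (-1.3553, 1.9467, -1.7012, 0.9564, -0.2537)


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid properties (default: water at room temperature)."""

    viscosity: float = 1.0e-3   # Pa·s
    density: float = 1.0e3      # kg/m³

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


WATER = FluidSpec()


@dataclass(frozen=True)
class FlowConditions:
    """Inlet drive: exactly one of mean velocity (m/s) or rate (m³/s)."""

    mean_velocity: Optional[float] = None
    volumetric_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.mean_velocity is None) == (self.volumetric_rate is None):
            raise ValueError("specify exactly one of mean_velocity or volumetric_rate")
        val = self.mean_velocity if self.mean_velocity is not None else self.volumetric_rate
        if not val > 0:
            raise ValueError("flow condition must be positive")

    @classmethod
    def from_ul_per_h(cls, rate_ul_h: float) -> "FlowConditions":
        return cls(volumetric_rate=rate_ul_h * UL_PER_H)

    def rate(self, inlet_area_m2: float) -> float:
        """Volumetric rate in m³/s given the inlet cross-section (Q = ū·A)."""
        if self.volumetric_rate is not None:
            return self.volumetric_rate
        return self.mean_velocity * inlet_area_m2


@dataclass(frozen=True)
class SegmentHydraulics:
    """Derived per-segment quantities (SI).

    For tapered segments A, P, Dh, aspect and fRe are evaluated at the
    mid-length width; R is the quadrature of the local resistance density
    along the taper.
    """

    A: float        # m²
    P: float        # m
    Dh: float       # m
    aspect: float
    fRe: float
    R: float        # Pa·s/m³


@dataclass(frozen=True)
class FlowSplit:
    Q1: float
    Q2: float
    ratio: float            # Q2/Q1 (inf if Q1 == 0)
    dp1: float
    dp2: float
    dp_regions: tuple[float, ...]
    R1: float
    R2: float


def hydraulic_diameter(segment: ChannelSegment) -> float:
    """Dh = 4A/P for the rectangular cross-section, in metres."""
    w = segment.width_start * UM
    h = segment.height * UM
    return 2.0 * w * h / (w + h)


def f_re(aspect: float) -> float:
    """Shah–London fRe for a rectangular duct of aspect ratio α ∈ (0, 1]."""
    if not 0 < aspect <= 1:
        raise ValueError(f"aspect ratio must be in (0, 1], got {aspect}")
    poly = 1.0 + sum(c * aspect ** (k + 1) for k, c in enumerate(_SHAH_LONDON))
    return 96.0 * poly


def reynolds_number(fluid: FluidSpec, mean_velocity: float, dh: float) -> float:
    """Re = ρ·ū·Dh/η (all SI)."""
    return fluid.density * mean_velocity * dh / fluid.viscosity


def _resistance_density(width_um: float, height_um: float, viscosity: float) -> float:
    """Local straight-duct resistance per unit length, Pa·s/m³ per m."""
    w = width_um * UM
    h = height_um * UM
    a = w * h
    dh = 2.0 * w * h / (w + h)
    alpha = min(w, h) / max(w, h)
    return f_re(alpha) * viscosity / (2.0 * dh**2 * a)


def segment_hydraulics(
    segment: ChannelSegment, fluid: FluidSpec = WATER, n_quad: int = 64
) -> SegmentHydraulics:
    """Per-segment derived quantities and hydraulic resistance.

    Straight segments use the closed form R = fRe·L·η/(2·Dh²·A).  Tapers
    integrate the local straight-duct resistance density along the length
    (composite Simpson, ``n_quad`` intervals).
    """
    w_mid = 0.5 * (segment.width_start + segment.width_end)
    w = w_mid * UM
    h = segment.height * UM
    A = w * h
    P = 2.0 * (w + h)
    Dh = 4.0 * A / P
    aspect = min(w, h) / max(w, h)
    fre = f_re(aspect)
    L = segment.length * UM

    if not segment.is_tapered:
        R = fre * L * fluid.viscosity / (2.0 * Dh**2 * A)
    else:
        n = n_quad + (n_quad % 2)
        s = np.linspace(0.0, segment.length, n + 1)
        dens = np.array([
            _resistance_density(wi, segment.height, fluid.viscosity)
            for wi in segment.width_at(s)
        ])
        wgt = np.ones(n + 1)
        wgt[1:-1:2] = 4.0
        wgt[2:-1:2] = 2.0
        R = float((segment.length * UM / n / 3.0) * np.sum(wgt * dens))
    return SegmentHydraulics(A=A, P=P, Dh=Dh, aspect=aspect, fRe=fre, R=R)


def segment_resistance(segment: ChannelSegment, fluid: FluidSpec = WATER) -> float:
    """Hydraulic resistance Δp/Q of one segment, Pa·s/m³."""
    return segment_hydraulics(segment, fluid).R


def path_resistances(
    unit: TrapUnitGeometry, fluid: FluidSpec = WATER, lump_pockets: bool = False
) -> tuple[np.ndarray, float]:
    """Per-region Path-1 resistances and the bypass resistance.

    With ``lump_pockets`` the pocket+gap pairs (regions i+ii and iv+v) are
    replaced by single straight gap segments of the combined length, a
    lumped variant for sensitivity analysis.
    """
    regions = unit.path1_regions
    if lump_pockets:
        gap = regions[1]
        lumped = ChannelSegment(
            gap.width_start, gap.width_start,
            regions[0].length + gap.length, gap.height,
        )
        r_lump = segment_resistance(lumped, fluid)
        r1 = np.array([r_lump, 0.0, segment_resistance(regions[2], fluid), 0.0, r_lump])
    else:
        r1 = np.array([segment_resistance(seg, fluid) for seg in regions])
    r2 = segment_resistance(unit.bypass, fluid)
    return r1, r2


def flow_split(
    unit: TrapUnitGeometry,
    fluid: FluidSpec = WATER,
    flow: FlowConditions = FlowConditions(mean_velocity=100e-6),
    valve_on: bool = False,
    trap_occupied: bool = False,
    lump_pockets: bool = False,
) -> FlowSplit:
    """Parallel-resistor flow split between Path 1 and the bypass.

    The inlet cross-section is the main channel (chamber width × height).
    A closed valve or an occupied trap blocks Path 1 entirely (Q1 = 0).
    """
    inlet_area = unit.entrance_width * UM * unit.height * UM
    q_total = flow.rate(inlet_area)
    r1_regions, r2 = path_resistances(unit, fluid, lump_pockets)
    r1 = float(r1_regions.sum())

    if valve_on or trap_occupied:
        q1, q2 = 0.0, q_total
        dp2 = q2 * r2
        return FlowSplit(
            Q1=0.0, Q2=q2, ratio=np.inf, dp1=dp2, dp2=dp2,
            dp_regions=tuple(0.0 for _ in r1_regions), R1=r1, R2=r2,
        )

    q1 = q_total * r2 / (r1 + r2)
    q2 = q_total * r1 / (r1 + r2)
    dp1 = q1 * r1
    return FlowSplit(
        Q1=q1, Q2=q2, ratio=q2 / q1, dp1=dp1, dp2=q2 * r2,
        dp_regions=tuple(q1 * r for r in r1_regions), R1=r1, R2=r2,
    )


@dataclass(frozen=True)
class CriterionReport:
    ratio: float
    passed: bool
    table: pd.DataFrame
    split: FlowSplit


def criterion_check(
    unit: TrapUnitGeometry,
    fluid: FluidSpec = WATER,
    flow: FlowConditions = FlowConditions(mean_velocity=100e-6),
) -> CriterionReport:
    """Evaluate the trapping design rule Q2/Q1 < 1 (valve off, trap empty).

    The report table lists, per region, the dimensions, hydraulic
    diameter, fRe, resistance and pressure drop.
    """
    split = flow_split(unit, fluid, flow, valve_on=False, trap_occupied=False)
    rows = []
    names = ["pocket_in", "gap_in", "chamber", "gap_out", "pocket_out"]
    for name, seg, dp in zip(names, unit.path1_regions, split.dp_regions):
        hyd = segment_hydraulics(seg, fluid)
        rows.append({
            "region": name,
            "W_um": 0.5 * (seg.width_start + seg.width_end),
            "L_um": seg.length,
            "Dh_um": hyd.Dh / UM,
            "fRe": hyd.fRe,
            "R_Pa_s_per_m3": hyd.R,
            "dp_Pa": dp,
        })
    hyd2 = segment_hydraulics(unit.bypass, fluid)
    rows.append({
        "region": "bypass",
        "W_um": unit.bypass.width_start,
        "L_um": unit.bypass.length,
        "Dh_um": hyd2.Dh / UM,
        "fRe": hyd2.fRe,
        "R_Pa_s_per_m3": hyd2.R,
        "dp_Pa": split.dp2,
    })
    table = pd.DataFrame(rows)
    return CriterionReport(ratio=split.ratio, passed=bool(split.ratio < 1.0), table=table, split=split)
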