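"""Plan-view geometry of hydrodynamic trap units.

A trapping unit consists of a short, straight trapping path (Path 1) in
parallel with a long bypass loop (Path 2) between two junctions A and B.
Path 1 is subdivided into five regions: a tapering trap pocket (i), a
narrow trapping gap (ii), a middle chamber (iii) that can be sealed by a
pneumatic valve, and the mirror-image gap (iv) and pocket (v).  A cell
larger than the gap is stopped in the pocket while fluid continues through
the gap, which is what makes the trap work.

Coordinate convention: 2-D plan view in micrometres, origin at junction A,
x along Path 1 toward junction B, bypass loop on the +y side.  Rasters are
cell-centred with half-open extents.

Two catalogue designs are provided (``preset_design``): design 1 has a
5 μm trapping gap and 25 μm wide channels, design 2 a 3 μm gap and 15 μm
channels; either can be fabricated at 15 or 25 μm channel height.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import ndimage
from skimage.morphology import disk


class ResolutionError(ValueError):
    """Raster spacing too coarse to resolve the trapping gap."""


@dataclass(frozen=True)
class ChannelSegment:
    """A straight or linearly tapering rectangular channel segment.

    Widths and lengths are in μm.  ``width_start == width_end`` denotes a
    straight segment; unequal widths a linear taper.  The height is the
    (uniform) channel depth.
    """

    width_start: float
    width_end: float
    length: float
    height: float

    def __post_init__(self) -> None:
        for name in ("width_start", "width_end", "length", "height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def is_tapered(self) -> bool:
        return self.width_start != self.width_end

    def width_at(self, s):
        """Local width at arc position ``s`` ∈ [0, length] along the segment."""
        frac = np.asarray(s, dtype=float) / self.length
        return self.width_start + (self.width_end - self.width_start) * frac


def straight(width: float, length: float, height: float) -> ChannelSegment:
    return ChannelSegment(width, width, length, height)


@dataclass(frozen=True)
class TrapUnitGeometry:
    """One trapping unit: five Path-1 regions plus the bypass loop.

    ``path1_regions`` is ordered pocket-gap-chamber-gap-pocket from
    junction A to junction B.  ``valve_region`` is the (x0, x1) span of the
    valve footprint over the middle chamber, full chamber width.
    """

    path1_regions: tuple[ChannelSegment, ...]
    bypass: ChannelSegment
    height: float
    valve_region: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.path1_regions) != 5:
            raise ValueError("Path 1 must have exactly five regions")
        heights = {seg.height for seg in self.path1_regions} | {self.bypass.height, self.height}
        if len(heights) != 1:
            raise ValueError("channel height must be uniform across the device")
        pocket_in, gap_in, chamber, gap_out, pocket_out = self.path1_regions
        if not (gap_in.width_end < chamber.width_start and gap_out.width_start < chamber.width_end):
            raise ValueError("trapping gaps must be narrower than the middle chamber")
        x0, x1 = self.valve_region
        c0 = pocket_in.length + gap_in.length
        c1 = c0 + chamber.length
        if not (c0 - 1e-9 <= x0 < x1 <= c1 + 1e-9):
            raise ValueError("valve region must lie within the middle chamber")

    # -- convenience accessors -------------------------------------------------
    @property
    def gap_width(self) -> float:
        return self.path1_regions[1].width_end

    @property
    def entrance_width(self) -> float:
        """Width of the channel at the trap entrance (= chamber width)."""
        return self.path1_regions[2].width_start

    @property
    def path1_length(self) -> float:
        return sum(seg.length for seg in self.path1_regions)

    @property
    def chamber_span(self) -> tuple[float, float]:
        x0 = self.path1_regions[0].length + self.path1_regions[1].length
        return x0, x0 + self.path1_regions[2].length

    @classmethod
    def from_dims(
        cls,
        *,
        L11: float,
        L12: float,
        W12: float,
        W13: float,
        L13: float,
        W2: float,
        L2: float,
        H: float,
        valve_width: float = 40.0,
    ) -> "TrapUnitGeometry":
        """Build a symmetric unit from catalogue-style dimensions (μm).

        The trap pockets (regions i and v) are modelled as linear tapers
        from the chamber width W13 down to the gap width W12 over lengths
        L11/L14 = L11: the pocket widths are not tabulated and the funnel
        shape leaves no free parameter.  The valve footprint is a
        ``valve_width`` long strip centred on the middle chamber.
        """
        regions = (
            ChannelSegment(W13, W12, L11, H),       # i: trap pocket (funnel in)
            ChannelSegment(W12, W12, L12, H),       # ii: trapping gap
            ChannelSegment(W13, W13, L13, H),       # iii: middle chamber
            ChannelSegment(W12, W12, L12, H),       # iv: trapping gap
            ChannelSegment(W12, W13, L11, H),       # v: trap pocket (funnel out)
        )
        c0 = L11 + L12
        vw = min(valve_width, L13)
        centre = c0 + L13 / 2.0
        return cls(
            path1_regions=regions,
            bypass=ChannelSegment(W2, W2, L2, H),
            height=H,
            valve_region=(centre - vw / 2.0, centre + vw / 2.0),
        )

    def to_dict(self) -> dict:
        p = self.path1_regions
        return {
            "L11": p[0].length, "L12": p[1].length, "W12": p[1].width_start,
            "W13": p[2].width_start, "L13": p[2].length,
            "W2": self.bypass.width_start, "L2": self.bypass.length,
            "H": self.height,
        }


@dataclass(frozen=True)
class DeviceLayout:
    """A serial array of identical trapping units."""

    n_units: int
    unit: TrapUnitGeometry
    valve_mode: str = "individual"  # "common" | "individual"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.valve_mode not in ("common", "individual"):
            raise ValueError(f"unknown valve_mode {self.valve_mode!r}")


# Catalogue dimensions (μm): gap width/length, chamber width/length, bypass.
_CATALOGUE = {
    1: dict(L11=10.0, L12=5.0, W12=5.0, W13=25.0, L13=50.0, W2=25.0, L2=805.0),
    2: dict(L11=6.0, L12=3.0, W12=3.0, W13=15.0, L13=48.0, W2=15.0, L2=761.0),
}
_HEIGHTS = (15.0, 25.0)


def preset_design(design_id: int, height: float) -> TrapUnitGeometry:
    """Return a catalogue trap-unit geometry.

    ``design_id`` 1 is the 5 μm-gap device, 2 the 3 μm-gap device; the
    channel height is 15 or 25 μm.
    """
    if design_id not in _CATALOGUE:
        raise ValueError(f"unknown design_id {design_id!r}; catalogue has {sorted(_CATALOGUE)}")
    if float(height) not in _HEIGHTS:
        raise ValueError(f"unknown height {height!r}; catalogue heights are {_HEIGHTS}")
    return TrapUnitGeometry.from_dims(H=float(height), **_CATALOGUE[design_id])


def load_geometry(path: str | Path) -> TrapUnitGeometry:
    """Read a key/value geometry config (YAML mapping, values in μm).

    Either ``design: 1|2`` plus ``height`` (catalogue lookup) or the full
    dimension set L11, L12, W12, W13, L13, W2, L2, H.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise ValueError("geometry config must be a key/value mapping")
    if "design" in data:
        return preset_design(int(data["design"]), float(data.get("height", 15.0)))
    keys = ("L11", "L12", "W12", "W13", "L13", "W2", "L2", "H")
    missing = [k for k in keys if k not in data]
    if missing:
        raise ValueError(f"geometry config missing keys: {missing}")
    return TrapUnitGeometry.from_dims(**{k: float(data[k]) for k in keys})


def save_geometry(unit: TrapUnitGeometry, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(unit.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass
class RasterDomain:
    """Cell-centred raster of one trapping unit.

    ``mask`` is the fluid mask (rows = y, cols = x); ``accessible`` is the
    mask eroded by the particle radius (equal to ``mask`` for point
    particles).  ``labels`` holds boolean region masks (inlet, outlet,
    valve, pockets).  Gates are line cuts used for flux integration and
    particle-fate assignment: ``trap_gate`` is the vertical cut
    (x, ylo, yhi) at the Path-1 entrance; ``bypass_gate`` the horizontal
    cut (y, xlo, xhi) across the first bypass arm.
    """

    dx: float
    x0: float
    y0: float
    mask: np.ndarray
    accessible: np.ndarray
    labels: dict[str, np.ndarray]
    trap_gate: tuple[float, float, float] | None
    bypass_gate: tuple[float, float, float] | None
    unit: TrapUnitGeometry | None
    height: float = 0.0
    particle_radius: float = 0.0
    lead_in: float = 40.0
    lead_out: float = 40.0

    def __post_init__(self) -> None:
        if self.height <= 0 and self.unit is not None:
            self.height = self.unit.height
        if self.height <= 0:
            raise ValueError("domain needs a positive channel height")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.mask.shape
        cx = self.x0 + (np.arange(nx) + 0.5) * self.dx
        cy = self.y0 + (np.arange(ny) + 0.5) * self.dx
        return cx, cy

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        i = np.floor((np.asarray(x) - self.x0) / self.dx).astype(int)
        j = np.floor((np.asarray(y) - self.y0) / self.dx).astype(int)
        return j, i

    def contains(self, x, y, eroded: bool = True) -> np.ndarray:
        """Whether points lie in the (eroded) fluid mask."""
        grid = self.accessible if eroded else self.mask
        ny, nx = grid.shape
        j, i = self.cell_index(x, y)
        ok = (i >= 0) & (i < nx) & (j >= 0) & (j < ny)
        out = np.zeros(np.shape(ok), dtype=bool)
        out[ok] = grid[j[ok], i[ok]]
        return out

    def fluid_area(self) -> float:
        return float(self.mask.sum()) * self.dx**2

    def to_pgm(self, path: str | Path) -> None:
        """Export the fluid mask as ASCII PGM with a JSON sidecar."""
        path = Path(path)
        ny, nx = self.mask.shape
        img = np.where(self.mask[::-1], 255, 0)  # top row = largest y
        lines = [f"P2\n{nx} {ny}\n255"]
        for row in img:
            lines.append(" ".join(map(str, row)))
        path.write_text("\n".join(lines) + "\n")
        sidecar = {
            "dx_um": self.dx,
            "origin_um": [self.x0, self.y0],
            "trap_gate": list(self.trap_gate),
            "bypass_gate": list(self.bypass_gate),
            "particle_radius_um": self.particle_radius,
            "labels": {k: int(v.sum()) for k, v in self.labels.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _layout(unit: TrapUnitGeometry, lead_in: float, lead_out: float) -> dict:
    """Plan-view layout constants for the rectangular-U bypass drawing.

    The loop arms (width W2) attach to the main channel immediately
    upstream of junction A and downstream of junction B; the arm length is
    set so the bypass centreline length equals L2.
    """
    W2 = unit.bypass.width_start
    L2 = unit.bypass.length
    Wm = unit.entrance_width
    L1 = unit.path1_length
    arm = (L2 - L1 - W2) / 2.0 - Wm / 2.0 - W2 / 2.0
    if arm <= 0:
        raise ValueError("bypass too short to draw as a rectangular U around Path 1")
    return dict(
        W2=W2, Wm=Wm, L1=L1, arm=arm,
        xmin=-W2 - lead_in, xmax=L1 + W2 + lead_out,
        ymin=-Wm / 2.0, ymax=Wm / 2.0 + arm + W2,
        arm1=(-W2, 0.0), arm2=(L1, L1 + W2),
        top=(Wm / 2.0 + arm, Wm / 2.0 + arm + W2),
    )


def rasterize(
    unit: TrapUnitGeometry,
    dx: float,
    particle_radius: float = 0.0,
    lead_in: float = 40.0,
    lead_out: float = 40.0,
) -> RasterDomain:
    """Rasterize a trap unit onto a cell-centred grid of spacing ``dx`` μm.

    The fluid mask reproduces the Path 1 + bypass loop topology.  If
    ``particle_radius`` > 0 the accessible mask is the fluid mask eroded by
    that radius (finite-size exclusion: a gap narrower than the particle
    diameter becomes impassable).
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if dx > unit.gap_width / 3.0:
        raise ResolutionError(
            f"dx={dx} μm too coarse: must be <= gap width / 3 = {unit.gap_width / 3.0:.3g} μm"
        )
    if particle_radius < 0:
        raise ValueError("particle_radius must be >= 0")

    lay = _layout(unit, lead_in, lead_out)
    nx = int(round((lay["xmax"] - lay["xmin"]) / dx))
    ny = int(round((lay["ymax"] - lay["ymin"]) / dx))
    x0, y0 = lay["xmin"], lay["ymin"]
    cx = x0 + (np.arange(nx) + 0.5) * dx
    cy = y0 + (np.arange(ny) + 0.5) * dx
    CX = cx[None, :]
    CY = cy[:, None]
    eps = 1e-9

    mask = np.zeros((ny, nx), dtype=bool)

    def paint(xa, xb, ya, yb):
        mask[((CX > xa + eps) & (CX < xb - eps) & (CY > ya + eps) & (CY < yb - eps))] = True

    Wm, W2, L1 = lay["Wm"], lay["W2"], lay["L1"]
    # main channel up to junction A and after junction B
    paint(lay["xmin"] - 1, 0.0, -Wm / 2, Wm / 2)
    paint(L1, lay["xmax"] + 1, -Wm / 2, Wm / 2)
    # bypass arms and top run
    for xa, xb in (lay["arm1"], lay["arm2"]):
        paint(xa, xb, Wm / 2 - dx, lay["top"][1])
    paint(lay["arm1"][0], lay["arm2"][1], lay["top"][0], lay["top"][1])
    # Path 1: piecewise width profile along x in [0, L1]
    xs = 0.0
    for seg in unit.path1_regions:
        in_seg = (CX > xs + eps) & (CX < xs + seg.length - eps)
        half = seg.width_at(np.clip(cx - xs, 0, seg.length)) / 2.0
        mask |= in_seg & (np.abs(CY) < half[None, :] - eps)
        xs += seg.length

    # labels
    labels: dict[str, np.ndarray] = {}
    labels["inlet"] = np.zeros_like(mask)
    labels["inlet"][:, 0] = mask[:, 0]
    labels["outlet"] = np.zeros_like(mask)
    labels["outlet"][:, -1] = mask[:, -1]
    v0, v1 = unit.valve_region
    labels["valve"] = mask & (CX > v0 + eps) & (CX < v1 - eps) & (np.abs(CY) < Wm / 2)
    p0 = unit.path1_regions[0]
    labels["pocket_in"] = mask & (CX > eps) & (CX < p0.length - eps) & (np.abs(CY) < Wm / 2)
    labels["pocket_out"] = mask & (CX > L1 - p0.length + eps) & (CX < L1 - eps) & (np.abs(CY) < Wm / 2)

    accessible = mask
    if particle_radius > 0:
        r_cells = int(round(particle_radius / dx))
        if r_cells > 0:
            # inlet/outlet columns are open boundaries, not walls: pad in x
            padded = np.pad(mask, ((0, 0), (r_cells, r_cells)), mode="edge")
            accessible = ndimage.binary_erosion(padded, structure=disk(r_cells))[:, r_cells:-r_cells]

    # gates: trap gate just inside the entrance pocket (still reachable after
    # erosion by realistic particle radii); bypass gate across arm 1
    trap_gate = (round(0.2 * p0.length / dx) * dx, -Wm / 2.0, Wm / 2.0)
    ygate = Wm / 2.0 + lay["arm"] / 2.0
    bypass_gate = (ygate, lay["arm1"][0], lay["arm1"][1])

    return RasterDomain(
        dx=dx, x0=x0, y0=y0, mask=mask, accessible=accessible, labels=labels,
        trap_gate=trap_gate, bypass_gate=bypass_gate, unit=unit,
        particle_radius=particle_radius, lead_in=lead_in, lead_out=lead_out,
    )


def channel_domain(width: float, length: float, height: float, dx: float,
                   particle_radius: float = 0.0) -> RasterDomain:
    """Raster of a plain straight channel (for validation and demos)."""
    nx = int(round(length / dx))
    ny = int(round(width / dx))
    mask = np.ones((ny, nx), dtype=bool)
    labels = {"inlet": np.zeros_like(mask), "outlet": np.zeros_like(mask)}
    labels["inlet"][:, 0] = True
    labels["outlet"][:, -1] = True
    accessible = mask
    r_cells = int(round(particle_radius / dx))
    if r_cells > 0:
        padded = np.pad(mask, ((0, 0), (r_cells, r_cells)), mode="edge")
        accessible = ndimage.binary_erosion(padded, structure=disk(r_cells))[:, r_cells:-r_cells]
    return RasterDomain(dx=dx, x0=0.0, y0=0.0, mask=mask, accessible=accessible,
                        labels=labels, trap_gate=None, bypass_gate=None,
                        unit=None, height=height, particle_radius=particle_radius)


def analytic_fluid_area(unit: TrapUnitGeometry, lead_in: float = 40.0, lead_out: float = 40.0) -> float:
    """Exact polygon area (μm²) of the plan-view fluid region."""
    lay = _layout(unit, lead_in, lead_out)
    Wm, W2, L1, arm = lay["Wm"], lay["W2"], lay["L1"], lay["arm"]
    main = (lead_in + W2 + lead_out + W2) * Wm
    path1 = sum(
        seg.length * (seg.width_start + seg.width_end) / 2.0 for seg in unit.path1_regions
    )
    # arms run from the main-channel top edge to the bottom of the top run
    arms = 2 * W2 * arm
    top = (L1 + 2 * W2) * W2
    return main + path1 + arms + top


def _connected(mask: np.ndarray, a: np.ndarray, b: np.ndarray) -> bool:
    lab, _ = ndimage.label(mask)
    la = np.unique(lab[a & mask])
    lb = np.unique(lab[b & mask])
    la = la[la > 0]
    lb = lb[lb > 0]
    return bool(np.intersect1d(la, lb).size)


def _gate_cells(domain: RasterDomain, gate: str) -> np.ndarray:
    ny, nx = domain.mask.shape
    cx, cy = domain.cell_centers()
    sel = np.zeros((ny, nx), dtype=bool)
    if gate == "trap":
        xg, ylo, yhi = domain.trap_gate
        i = int(np.floor((xg - domain.x0) / domain.dx))
        sel[:, i] = (cy > ylo) & (cy < yhi)
    else:
        yg, xlo, xhi = domain.bypass_gate
        j = int(np.floor((yg - domain.y0) / domain.dx))
        sel[j, :] = (cx > xlo) & (cx < xhi)
    return sel & domain.mask


def n_independent_paths(domain: RasterDomain, valve_on: bool = False) -> int:
    """Count independent inlet→outlet routes (0, 1 or 2).

    A route through Path 1 exists iff inlet and outlet stay connected when
    the bypass gate is blocked, and vice versa for the bypass route.
    """
    mask = domain.mask.copy()
    if valve_on:
        mask &= ~domain.labels["valve"]
    inlet, outlet = domain.labels["inlet"], domain.labels["outlet"]
    n = 0
    if _connected(mask & ~_gate_cells(domain, "bypass"), inlet, outlet):
        n += 1
    if _connected(mask & ~_gate_cells(domain, "trap"), inlet, outlet):
        n += 1
    return n
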