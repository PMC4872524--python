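"""Depth-averaged 2-D flow and Lagrangian particle tracing in a trap unit.

The 3-D creeping flow in a shallow channel network of uniform depth H is
reduced to its depth-averaged in-plane form (Brinkman equation):

    -η ∇²ū + (12η/H²) ū + ∇p = 0,   ∇·ū = 0,

with no-slip on the channel sidewalls.  The (12η/H²)ū drag term is the
out-of-plane Poiseuille friction of the Hele-Shaw limit; retaining the
in-plane viscous term gives no-slip sidewall boundary layers of thickness
H/√12, which carry the dominant resistance of gaps narrower than the
depth.  Segment resistances of this model agree with the Shah–London
rectangular-duct network to within a few percent over the aspect ratios
that occur here.

The equations are discretized on a MAC staggered grid over the rasterized
fluid mask (uniform-velocity inlet, zero-pressure outlet, no-slip walls)
and solved with a sparse direct factorization.  Tracer particles are then
advected through the interpolated velocity field (massless tracers; the
particle Stokes number at these Reynolds numbers is ≪ 1) until they cross
the Path-1 gate or the bypass gate, giving trap/bypass transmission
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .geometry import RasterDomain, TrapUnitGeometry, rasterize
from .hydraulics import WATER, FluidSpec

UM = 1e-6

FATE_PENDING, FATE_TRAP, FATE_BYPASS, FATE_OUTLET, FATE_STUCK = 0, 1, 2, 3, 4
FATE_NAMES = {FATE_PENDING: "pending", FATE_TRAP: "trap", FATE_BYPASS: "bypass",
              FATE_OUTLET: "outlet", FATE_STUCK: "stuck"}


class SolverError(RuntimeError):
    """Flow solve failed or did not conserve mass."""


class GeometryError(ValueError):
    """A gate does not form a closed cut of the domain."""


@dataclass
class FlowField:
    """Solved depth-averaged field on the raster.

    ``u``/``v`` are face-centred velocity arrays in μm/s (MAC layout:
    u on vertical faces, shape (ny, nx+1); v on horizontal faces,
    (ny+1, nx)); ``pressure`` is cell-centred in Pa (NaN outside the
    fluid).  ``mask`` is the fluid mask actually solved on (valve cells
    removed when the valve is on).
    """

    domain: RasterDomain
    mask: np.ndarray
    u: np.ndarray
    v: np.ndarray
    pressure: np.ndarray
    dx: float
    height: float
    inlet_velocity: float       # μm/s (mean over the inlet width)
    valve_on: bool
    residual: float             # max relative continuity residual

    # -- sampling ------------------------------------------------------------
    def velocity_at(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear MAC interpolation of (u, v) in μm/s at points (μm)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ny, nx = self.mask.shape
        dx = self.dx
        # u grid: nodes at x0 + i*dx, centres at y0 + (j+0.5)*dx
        fx = (x - self.domain.x0) / dx
        fy = (y - self.domain.y0) / dx - 0.5
        i0 = np.clip(np.floor(fx).astype(int), 0, nx - 1)
        j0 = np.clip(np.floor(fy).astype(int), 0, ny - 2)
        tx = np.clip(fx - i0, 0.0, 1.0)
        ty = np.clip(fy - j0, 0.0, 1.0)
        u = ((1 - tx) * (1 - ty) * self.u[j0, i0] + tx * (1 - ty) * self.u[j0, i0 + 1]
             + (1 - tx) * ty * self.u[j0 + 1, i0] + tx * ty * self.u[j0 + 1, i0 + 1])
        # v grid: nodes at y0 + j*dx, centres at x0 + (i+0.5)*dx
        gx = (x - self.domain.x0) / dx - 0.5
        gy = (y - self.domain.y0) / dx
        i1 = np.clip(np.floor(gx).astype(int), 0, nx - 2)
        j1 = np.clip(np.floor(gy).astype(int), 0, ny - 1)
        sx = np.clip(gx - i1, 0.0, 1.0)
        sy = np.clip(gy - j1, 0.0, 1.0)
        v = ((1 - sx) * (1 - sy) * self.v[j1, i1] + sx * (1 - sy) * self.v[j1, i1 + 1]
             + (1 - sx) * sy * self.v[j1 + 1, i1] + sx * sy * self.v[j1 + 1, i1 + 1])
        return u, v

    def speed(self) -> np.ndarray:
        """Cell-centred speed magnitude (μm/s), zero outside the fluid."""
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        s = np.hypot(uc, vc)
        s[~self.mask] = 0.0
        return s

    # -- fluxes ----------------------------------------------------------------
    def inlet_flux(self) -> float:
        """Net influx in μm³/s (depth-integrated)."""
        return float(self.u[:, 0].sum()) * self.dx * self.height

    def outlet_flux(self) -> float:
        return float(self.u[:, -1].sum()) * self.dx * self.height

    def cut_flux(self, x: float) -> float:
        """Net x-flux (μm³/s) through the vertical cut at ``x``."""
        i = int(round((x - self.domain.x0) / self.dx))
        i = np.clip(i, 0, self.mask.shape[1])
        return float(self.u[:, i].sum()) * self.dx * self.height

    def gate_fluxes(self) -> tuple[float, float]:
        """(Q1, Q2) in μm³/s through the trap gate and the bypass gate."""
        dom = self.domain
        if dom.trap_gate is None or dom.bypass_gate is None:
            raise GeometryError("domain has no gate definitions")
        cx, cy = dom.cell_centers()
        xg, ylo, yhi = dom.trap_gate
        ig = int(round((xg - dom.x0) / self.dx))
        rows = (cy > ylo) & (cy < yhi)
        q1 = float(self.u[rows, ig].sum()) * self.dx * self.height
        yg, xlo, xhi = dom.bypass_gate
        jg = int(round((yg - dom.y0) / self.dx))
        cols = (cx > xlo) & (cx < xhi)
        q2 = float(self.v[jg, cols].sum()) * self.dx * self.height
        return q1, q2

    def gap_speed_max(self) -> float:
        """Maximum speed (μm/s) in the trapping-gap throats.

        Probes the middle half of each gap segment: the end cells adjoin
        the pocket/chamber junctions and belong to those regions'
        transition zones rather than to the gap proper.
        """
        unit = self.domain.unit
        if unit is None:
            raise GeometryError("domain is not a trap unit")
        cx, cy = self.domain.cell_centers()
        p = unit.path1_regions
        lg = p[1].length
        g0a = p[0].length + 0.25 * lg
        g0b = p[0].length + 0.75 * lg
        g1a = p[0].length + lg + p[2].length + 0.25 * lg
        g1b = g1a + 0.5 * lg
        in_gap = ((cx[None, :] > g0a) & (cx[None, :] < g0b)) | \
                 ((cx[None, :] > g1a) & (cx[None, :] < g1b))
        in_gap = in_gap & (np.abs(cy[:, None]) < p[1].width_start / 2) & self.mask
        s = self.speed()
        return float(s[in_gap].max()) if in_gap.any() else 0.0

    def gap_flux(self) -> float:
        """Net through-flux (μm³/s) across the first gap throat."""
        unit = self.domain.unit
        if unit is None:
            raise GeometryError("domain is not a trap unit")
        p = unit.path1_regions
        xg = p[0].length + 0.5 * p[1].length
        i = int(round((xg - self.domain.x0) / self.dx))
        cy = self.domain.cell_centers()[1]
        rows = np.abs(cy) < p[1].width_start / 2
        return float(self.u[rows, i].sum()) * self.dx * self.height


def _brinkman_system(mask: np.ndarray, dx: float, height: float, ubar: float):
    """Assemble the MAC Brinkman saddle-point system (units μm, μm/s).

    Unknowns are interior u-faces plus open outlet faces, interior
    v-faces, and the reduced pressure q = p/η (1/s) per fluid cell.
    Returns (A_coo, rhs, uid, vid, pid, uval) where ``uval`` holds the
    prescribed inlet face velocities.
    """
    ny, nx = mask.shape
    c = 1.0 / dx**2
    sigma = 12.0 / height**2
    cp = 1.0 / dx

    left = np.zeros((ny, nx + 1), bool)
    left[:, 1:] = mask
    right = np.zeros((ny, nx + 1), bool)
    right[:, :nx] = mask
    um = left & right
    um[:, nx] |= mask[:, nx - 1]          # open outlet faces
    uval = np.zeros((ny, nx + 1))
    uval[:, 0][mask[:, 0]] = ubar         # prescribed plug inlet

    vm = np.zeros((ny + 1, nx), bool)
    vm[1:ny, :] = mask[:-1, :] & mask[1:, :]

    nu, nv, npp = int(um.sum()), int(vm.sum()), int(mask.sum())
    uid = np.full((ny, nx + 1), -1, np.int64)
    uid[um] = np.arange(nu)
    vid = np.full((ny + 1, nx), -1, np.int64)
    vid[vm] = np.arange(nv)
    pid = np.full((ny, nx), -1, np.int64)
    pid[mask] = np.arange(npp)
    off_v, off_p = nu, nu + nv
    ntot = nu + nv + npp

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(ntot)

    def add(r, cc, vv):
        rows.append(np.asarray(r, np.int64))
        cols.append(np.asarray(cc, np.int64))
        vals.append(np.asarray(vv, float))

    # ---------------- u momentum ----------------
    ju, iu = np.nonzero(um)
    ru = uid[ju, iu]
    dg = np.full(nu, sigma)

    # west (normal): always an existing face at iu-1
    nbu = um[ju, iu - 1]
    dg += c
    add(ru[nbu], uid[ju[nbu], iu[nbu] - 1], -c * np.ones(nbu.sum()))
    rhs[ru] += c * uval[ju, iu - 1] * (~nbu)

    # east (normal): interior faces only; outlet faces use zero-gradient
    interior = iu < nx
    ie = np.minimum(iu + 1, nx)
    nbu = interior & um[ju, ie]
    dg += c * interior
    add(ru[nbu], uid[ju[nbu], ie[nbu]], -c * np.ones(nbu.sum()))
    rhs[ru] += c * uval[ju, ie] * (interior & ~nbu)

    # tangential neighbours (north/south)
    for sgn in (+1, -1):
        jt = ju + sgn
        at_edge = (jt < 0) | (jt >= ny)
        jtc = np.clip(jt, 0, ny - 1)
        nb = ~at_edge & um[jtc, iu]
        wall = ~at_edge & ~nb & ~(left[jtc, iu] | right[jtc, iu])
        partial = ~at_edge & ~nb & ~wall
        dg += np.where(at_edge | wall, 2 * c, c)  # ghost u = -u across a wall plane
        add(ru[nb], uid[jtc[nb], iu[nb]], -c * np.ones(nb.sum()))
        rhs[ru] += c * uval[jtc, iu] * partial

    add(ru, ru, dg)
    # pressure gradient: (q_right - q_left)/dx; outlet ghost pressure = 0
    has_r = iu < nx
    add(ru[has_r], off_p + pid[ju[has_r], iu[has_r]], cp * np.ones(has_r.sum()))
    add(ru, off_p + pid[ju, iu - 1], -cp * np.ones(nu))

    # ---------------- v momentum ----------------
    jv, iv = np.nonzero(vm)
    rv = off_v + vid[jv, iv]
    dg = np.full(nv, sigma)
    below = np.zeros((ny + 1, nx), bool)
    below[1:, :] = mask
    above = np.zeros((ny + 1, nx), bool)
    above[:ny, :] = mask

    # south/north (normal): neighbour faces always exist in-range
    for sgn in (-1, +1):
        jn = jv + sgn
        nb = vm[jn, iv]
        dg += c
        add(rv[nb], off_v + vid[jn[nb], iv[nb]], -c * np.ones(nb.sum()))
        # non-unknown normal neighbours are wall faces with v = 0

    # tangential neighbours (west/east)
    for sgn in (-1, +1):
        it = iv + sgn
        at_w = it < 0            # inlet plane: v = 0 on the boundary
        at_e = it >= nx          # outlet plane: zero gradient
        itc = np.clip(it, 0, nx - 1)
        nb = ~at_w & ~at_e & vm[jv, itc]
        wall = ~at_w & ~at_e & ~nb & ~(below[jv, itc] | above[jv, itc])
        dg += np.where(at_w | wall, 2 * c, np.where(at_e, 0.0, c))
        add(rv[nb], off_v + vid[jv[nb], itc[nb]], -c * np.ones(nb.sum()))

    add(rv, rv, dg)
    add(rv, off_p + pid[jv, iv], cp * np.ones(nv))
    add(rv, off_p + pid[jv - 1, iv], -cp * np.ones(nv))

    # ---------------- continuity ----------------
    jp, ip = np.nonzero(mask)
    rp = off_p + pid[jp, ip]
    for darr, jj, ii, sign in (
        (uid, jp, ip + 1, +1.0), (uid, jp, ip, -1.0),
        (vid, jp + 1, ip, +1.0), (vid, jp, ip, -1.0),
    ):
        idx = darr[jj, ii]
        known = idx < 0
        add(rp[~known], idx[~known] + (off_v if darr is vid else 0), sign * cp * np.ones((~known).sum()))
        if darr is uid:
            rhs[rp[known]] -= sign * cp * uval[jj[known], ii[known]]

    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ntot, ntot),
    )
    return A, rhs, uid, vid, pid, uval


def solve_field(
    domain: RasterDomain,
    fluid: FluidSpec = WATER,
    inlet_velocity: float = 100e-6,
    valve_on: bool = False,
) -> FlowField:
    """Solve the depth-averaged flow on the rasterized unit.

    ``inlet_velocity`` is the mean inlet velocity in m/s (uniform inlet
    flux).  Outlet pressure is 0 Pa; walls are no-slip.  ``valve_on``
    removes the valve-chamber cells from the fluid mask, sealing Path 1.
    """
    mask = domain.mask.copy()
    if valve_on:
        if "valve" not in domain.labels:
            raise GeometryError("domain has no valve label")
        mask &= ~domain.labels["valve"]
    # keep only the component containing the inlet (guards singular blocks)
    lab, _ = ndimage.label(mask)
    inlet_labels = np.unique(lab[:, 0][mask[:, 0]])
    inlet_labels = inlet_labels[inlet_labels > 0]
    if inlet_labels.size != 1:
        raise SolverError("inlet is not a single connected strip")
    keep = lab == inlet_labels[0]
    if not keep[:, -1].any():
        raise SolverError("inlet not connected to outlet")
    mask = keep

    ubar = inlet_velocity * 1e6  # μm/s
    A, rhs, uid, vid, pid, uval = _brinkman_system(mask, domain.dx, domain.height, ubar)
    try:
        lu = splu(A.tocsc())
        sol = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise SolverError(f"sparse factorization failed: {exc}") from exc

    nu = int((uid >= 0).sum())
    nv = int((vid >= 0).sum())
    U = uval.copy()
    U[uid >= 0] = sol[:nu][uid[uid >= 0]]
    V = np.zeros_like(vid, dtype=float)
    V[vid >= 0] = sol[nu:nu + nv][vid[vid >= 0]]
    q = np.full(mask.shape, np.nan)
    q[pid >= 0] = sol[nu + nv:][pid[pid >= 0]]
    pressure = q * fluid.viscosity

    # continuity residual, relative to the inlet velocity scale
    div = (U[:, 1:] - U[:, :-1] + V[1:, :] - V[:-1, :]) / domain.dx
    res = float(np.abs(div[mask]).max()) * domain.dx / ubar if mask.any() else 0.0
    fld = FlowField(
        domain=domain, mask=mask, u=U, v=V, pressure=pressure, dx=domain.dx,
        height=domain.height, inlet_velocity=ubar, valve_on=valve_on, residual=res,
    )
    qin, qout = fld.inlet_flux(), fld.outlet_flux()
    if qin > 0 and abs(qin - qout) / qin > 1e-6:
        raise SolverError(f"mass imbalance: inlet {qin:g}, outlet {qout:g} μm³/s")
    return fld


# ---------------------------------------------------------------------------
# Particle ensembles and tracing
# ---------------------------------------------------------------------------

@dataclass
class ParticleEnsemble:
    """Tracer ensemble: seed positions, trajectories and fates."""

    positions: np.ndarray                     # (n, 2) current/end positions, μm
    diameter: float = 10.0                    # μm
    density: float = 1050.0                   # kg/m³ (informational; tracers are massless)
    seeds: np.ndarray | None = None           # (n, 2) initial positions
    fates: np.ndarray | None = None           # int codes, FATE_*
    times: np.ndarray | None = None           # s
    rng_seed: int | None = None
    trajectories: list[np.ndarray] | None = None

    @property
    def n(self) -> int:
        return len(self.positions)


def seed_particles(
    field: FlowField,
    n: int,
    diameter: float = 10.0,
    seeding: str = "uniform",
    rng_seed: int | None = None,
) -> ParticleEnsemble:
    """Seed ``n`` particles across the accessible inlet opening.

    ``uniform`` places them at equal spacing across the opening (the
    release line of the reference study); ``flux_weighted`` samples seed
    positions from the inlet velocity profile, so each seed carries equal
    flux and the trap fraction estimates the flux split directly.
    """
    dom = field.domain
    dx = field.dx
    acc = dom.accessible
    col = acc[:, 1]
    if not col.any():
        raise GeometryError("no accessible inlet cells (erosion closed the inlet)")
    jj = np.nonzero(col)[0]
    ylo = dom.y0 + jj.min() * dx
    yhi = dom.y0 + (jj.max() + 1) * dx
    x_seed = dom.x0 + 1.5 * dx
    if seeding == "uniform":
        ys = ylo + (np.arange(n) + 0.5) * (yhi - ylo) / n
    elif seeding == "flux_weighted":
        rng = np.random.default_rng(rng_seed)
        ycent = dom.y0 + (jj + 0.5) * dx
        w = np.maximum(field.velocity_at(np.full(jj.size, x_seed), ycent)[0], 0.0)
        if w.sum() <= 0:
            raise GeometryError("no positive inlet flux to weight seeds by")
        cdf = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
        u01 = rng.random(n)
        k = np.searchsorted(cdf, u01, side="right") - 1
        k = np.clip(k, 0, jj.size - 1)
        frac = (u01 - cdf[k]) / np.maximum(cdf[k + 1] - cdf[k], 1e-300)
        ys = dom.y0 + (jj[k] + frac) * dx
    else:
        raise ValueError(f"unknown seeding {seeding!r}")
    pos = np.column_stack([np.full(n, x_seed), ys])
    return ParticleEnsemble(
        positions=pos.copy(), diameter=diameter, seeds=pos.copy(),
        fates=np.full(n, FATE_PENDING, np.int8), times=np.zeros(n),
        rng_seed=rng_seed,
    )


def trace_particles(
    field: FlowField,
    ensemble: ParticleEnsemble,
    max_time: float = 240.0,
    cfl: float = 0.25,
    stall_speed_frac: float = 1e-3,
    stall_steps: int = 1000,
    max_steps: int = 200_000,
    store_trajectories: bool = False,
    store_every: int = 20,
) -> ParticleEnsemble:
    """Advect tracers until each crosses a gate (classic RK4, adaptive dt).

    Particle centres are confined to the eroded (accessible) mask.  A step
    that would leave it is retried at half length, then decomposed into
    axis-aligned sub-moves, which makes grazing trajectories slide along
    walls instead of pinning.  Fates: ``trap`` on crossing the Path-1
    gate, ``bypass`` on crossing the bypass gate, ``outlet`` on leaving
    through the outlet, ``stuck`` on stalling.
    """
    dom = field.domain
    dx = field.dx
    uref = field.inlet_velocity
    pos = ensemble.positions.copy()
    n = len(pos)
    fate = (ensemble.fates if ensemble.fates is not None
            else np.full(n, FATE_PENDING, np.int8)).copy()
    t = np.zeros(n)
    stall = np.zeros(n, dtype=int)
    x_out = dom.x0 + dom.mask.shape[1] * dx - 1.5 * dx
    xg, ylo, yhi = dom.trap_gate if dom.trap_gate is not None else (np.inf, 0, 0)
    yg, xlo, xhi = dom.bypass_gate if dom.bypass_gate is not None else (np.inf, 0, 0)
    traj: list[np.ndarray] = []

    def vel(p):
        u, v = field.velocity_at(p[:, 0], p[:, 1])
        return np.column_stack([u, v])

    # inward wall normals of the accessible region, for tangential sliding
    dist = ndimage.distance_transform_edt(dom.accessible)
    gy_wall, gx_wall = np.gradient(dist)

    active = fate == FATE_PENDING
    for step in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        k1 = vel(p)
        sp = np.hypot(k1[:, 0], k1[:, 1])
        dt = (cfl * dx / (sp + 1e-3 * uref))[:, None]
        k2 = vel(p + 0.5 * dt * k1)
        k3 = vel(p + 0.5 * dt * k2)
        k4 = vel(p + dt * k3)
        disp = dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        newp = p + disp

        ok = dom.contains(newp[:, 0], newp[:, 1])
        if not ok.all():
            bad = ~ok
            pb, db = p[bad], disp[bad]
            half = pb + 0.5 * db
            cand = np.where(dom.contains(half[:, 0], half[:, 1])[:, None], half, pb)
            # tangential slide: drop the wall-normal displacement component
            jj, ii = dom.cell_index(pb[:, 0], pb[:, 1])
            jj = np.clip(jj, 0, gy_wall.shape[0] - 1)
            ii = np.clip(ii, 0, gy_wall.shape[1] - 1)
            nvec = np.column_stack([gx_wall[jj, ii], gy_wall[jj, ii]])
            norm = np.hypot(nvec[:, 0], nvec[:, 1])
            nvec = nvec / np.maximum(norm, 1e-12)[:, None]
            dt_tan = db - (db * nvec).sum(axis=1)[:, None] * nvec
            for nudge in (0.0, 0.25 * dx):
                still = ~dom.contains(cand[:, 0], cand[:, 1]) | np.all(cand == pb, axis=1)
                trial = pb + dt_tan + nudge * nvec
                take = still & dom.contains(trial[:, 0], trial[:, 1])
                cand[take] = trial[take]
            newp[bad] = cand

        ai = np.nonzero(active)[0]
        t[ai] += dt[:, 0]
        # gate crossings
        crossed_trap = (p[:, 0] < xg) & (newp[:, 0] >= xg) & \
                       (newp[:, 1] > ylo) & (newp[:, 1] < yhi)
        crossed_byp = (p[:, 1] < yg) & (newp[:, 1] >= yg) & \
                      (newp[:, 0] > xlo) & (newp[:, 0] < xhi)
        crossed_out = newp[:, 0] >= x_out
        moved = np.hypot(*(newp - p).T) > 1e-3 * cfl * dx
        slow = (sp < stall_speed_frac * uref) | ~moved
        stall[ai] = np.where(slow, stall[ai] + 1, 0)
        timeout = (t[ai] > max_time) | (stall[ai] > stall_steps)

        fate[ai[crossed_trap]] = FATE_TRAP
        fate[ai[crossed_byp & ~crossed_trap]] = FATE_BYPASS
        fate[ai[crossed_out & ~crossed_trap & ~crossed_byp]] = FATE_OUTLET
        fate[ai[timeout & (fate[ai] == FATE_PENDING)]] = FATE_STUCK
        pos[ai] = newp
        if store_trajectories and step % store_every == 0:
            traj.append(pos.copy())
        active = fate == FATE_PENDING
    fate[fate == FATE_PENDING] = FATE_STUCK

    return ParticleEnsemble(
        positions=pos, diameter=ensemble.diameter, density=ensemble.density,
        seeds=ensemble.seeds, fates=fate, times=t, rng_seed=ensemble.rng_seed,
        trajectories=traj if store_trajectories else None,
    )


@dataclass(frozen=True)
class TransmissionResult:
    """Trap/bypass transmission probabilities of a traced ensemble."""

    n: int
    counts: dict
    p_trap: float
    p_bypass: float
    p_stuck: float
    rng_seed: int | None

    def as_dict(self) -> dict:
        return {
            "n": self.n, "counts": self.counts, "p_trap": self.p_trap,
            "p_bypass": self.p_bypass, "p_stuck": self.p_stuck,
            "rng_seed": self.rng_seed,
        }


def transmission(ensemble: ParticleEnsemble) -> TransmissionResult:
    """Fraction of the ensemble routed to the trap path vs the bypass."""
    if ensemble.fates is None or (ensemble.fates == FATE_PENDING).any():
        raise ValueError("ensemble has unresolved particle fates")
    n = ensemble.n
    counts = {name: int((ensemble.fates == code).sum())
              for code, name in FATE_NAMES.items() if code != FATE_PENDING}
    p_trap = counts["trap"] / n
    p_byp = counts["bypass"] / n
    return TransmissionResult(
        n=n, counts=counts, p_trap=p_trap, p_bypass=p_byp,
        p_stuck=1.0 - p_trap - p_byp, rng_seed=ensemble.rng_seed,
    )


@dataclass(frozen=True)
class FieldFlowSplit:
    Q1: float       # μm³/s through the trap gate
    Q2: float       # μm³/s through the bypass gate
    ratio: float    # Q2/Q1
    Q_in: float


def flux_split_from_field(field: FlowField) -> FieldFlowSplit:
    """Integrate the velocity across the two gates and report the split."""
    q1, q2 = field.gate_fluxes()
    qin = field.inlet_flux()
    if qin <= 0:
        raise GeometryError("no inlet flux")
    if abs(q1 + q2 - qin) / qin > 1e-3:
        raise GeometryError(
            f"gates are not a closed cut: Q1+Q2 = {q1 + q2:g} vs inlet {qin:g}"
        )
    ratio = q2 / q1 if q1 != 0 else np.inf
    return FieldFlowSplit(Q1=q1, Q2=q2, ratio=ratio, Q_in=qin)


def transmission_study(
    unit: TrapUnitGeometry,
    valve_on: bool = False,
    n_particles: int = 100,
    dx: float = 0.5,
    particle_diameter: float = 10.0,
    inlet_velocity: float = 100e-6,
    seeding: str = "uniform",
    rng_seed: int | None = None,
    fluid: FluidSpec = WATER,
    store_trajectories: bool = False,
):
    """Rasterize, solve and trace in one call; returns (field, ensemble, result)."""
    domain = rasterize(unit, dx=dx, particle_radius=particle_diameter / 2.0)
    fld = solve_field(domain, fluid=fluid, inlet_velocity=inlet_velocity, valve_on=valve_on)
    ens = seed_particles(fld, n_particles, diameter=particle_diameter,
                         seeding=seeding, rng_seed=rng_seed)
    ens = trace_particles(fld, ens, store_trajectories=store_trajectories)
    return fld, ens, transmission(ens)
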