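"""Fill, release and re-trap logic of a serial trap array.

Each trapping unit diverts an arriving particle into its pocket when the
pocket is empty and its valve is open (the differential-resistance rule:
more flow passes the short trapping path than the bypass).  An occupied
pocket blocks the trapping path, so the next particle rides the bypass to
the next unit — the array fills upstream-to-downstream.  Closing a unit's
valve blocks its trapping path too, which (a) prevents trapping, and
(b) ejects an already-held particle into the main flow, releasing it.
Because a released particle can be kept out of empty downstream traps by
closing their valves, traps can be emptied in any order — unlike
bubble-release schemes, which must release strictly upstream-first.

The simulation is event-based and replayable: every trap, bypass, release
and exit event is appended to a log from which the final state can be
reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .geometry import DeviceLayout, TrapUnitGeometry
from .hydraulics import FlowConditions, FluidSpec, WATER, flow_split


@dataclass(frozen=True)
class FitClass:
    """Occupancy classification of a particle/trap pairing.

    ``label`` is the dominant class; ``flags`` lists every applicable
    one.  Priority: passes_gap > blockage_risk > multiple_vertical >
    multiple_lateral > single.
    """

    label: str
    flags: tuple[str, ...]
    rationale: str

    @property
    def capacity(self) -> int:
        """Particles a single trap can plausibly hold."""
        k = 1
        if "multiple_vertical" in self.flags:
            k *= 2
        if "multiple_lateral" in self.flags:
            k *= 2
        return k


def classify_fit(
    particle_diameter: float,
    gap: float,
    entrance_width: float,
    height: float,
    blockage_fraction: float = 0.8,
) -> FitClass:
    """Classify how a particle of diameter ``d`` fits a trap (all μm).

    Rules distilled from bead-trapping observations: a particle no larger
    than the gap passes straight through; channel width or height at
    least twice the particle size admits multiple particles per trap
    (side by side or stacked); a particle close to the channel bore
    (``d ≥ blockage_fraction × min(width, height)``) risks clogging the
    device; otherwise the trap holds a single particle.
    """
    d = particle_diameter
    if min(d, gap, entrance_width, height) <= 0:
        raise ValueError("all dimensions must be positive")
    flags: list[str] = []
    if d <= gap:
        return FitClass("passes_gap", ("passes_gap",),
                        f"particle ({d} μm) fits through the {gap} μm trapping gap")
    if height >= 2 * d:
        flags.append("multiple_vertical")
    if entrance_width >= 2 * d:
        flags.append("multiple_lateral")
    if d >= blockage_fraction * min(entrance_width, height):
        flags.append("blockage_risk")
    if not flags:
        return FitClass("single", ("single",),
                        f"channel bore ({entrance_width}×{height} μm) holds one {d} μm particle")
    if "blockage_risk" in flags:
        label = "blockage_risk"
        why = f"particle ({d} μm) ≥ {blockage_fraction:g}× the narrowest bore dimension"
    elif "multiple_vertical" in flags:
        label = "multiple_vertical"
        why = f"channel height ({height} μm) ≥ twice the particle size ({d} μm)"
    else:
        label = "multiple_lateral"
        why = f"entrance width ({entrance_width} μm) ≥ twice the particle size ({d} μm)"
    return FitClass(label, tuple(flags), why)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Ordered valve actions: (time, unit index, action on|off)."""

    actions: tuple[tuple[float, int, str], ...]

    def __post_init__(self) -> None:
        for t, unit, action in self.actions:
            if action not in ("on", "off"):
                raise ValueError(f"unknown valve action {action!r}")
            if unit < 0:
                raise ValueError("unit index must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "ReleaseSchedule":
        df = pd.read_csv(path)
        return cls(tuple(
            (float(r.time), int(r.unit), str(r.action)) for r in df.itertuples()
        ))

    def validate(self, n_units: int) -> None:
        bad = [u for _, u, _ in self.actions if u >= n_units]
        if bad:
            raise ValueError(f"schedule references unknown units {bad}")


@dataclass
class TrapArrayState:
    """Occupancy, valve state and event log of a serial array."""

    layout: DeviceLayout
    occupancy: np.ndarray               # int count per unit
    valve_on: np.ndarray                # bool per unit
    holders: list[list[int]] = field(default_factory=list)  # particle ids per unit
    events: list[tuple] = field(default_factory=list)   # (time, particle, unit, event)
    fluid: FluidSpec = WATER
    flow: FlowConditions = FlowConditions(mean_velocity=100e-6)
    rng_seed: Optional[int] = None
    exited: list[int] = field(default_factory=list)
    _next_particle: int = 0
    time: float = 0.0

    @classmethod
    def empty(cls, layout: DeviceLayout, fluid: FluidSpec = WATER,
              flow: FlowConditions = FlowConditions(mean_velocity=100e-6),
              rng_seed: Optional[int] = None) -> "TrapArrayState":
        n = layout.n_units
        return cls(layout=layout, occupancy=np.zeros(n, dtype=int),
                   valve_on=np.zeros(n, dtype=bool),
                   holders=[[] for _ in range(n)], fluid=fluid, flow=flow,
                   rng_seed=rng_seed)

    # -- bookkeeping -----------------------------------------------------------
    def log(self, particle: int, unit: int, event: str) -> None:
        self.events.append((self.time, particle, unit, event))

    def unit_split(self, unit: int):
        """Flow split of one unit in its current state."""
        return flow_split(
            self.layout.unit, self.fluid, self.flow,
            valve_on=bool(self.valve_on[unit]),
            trap_occupied=bool(self.occupancy[unit] > 0),
        )

    def n_trapped(self) -> int:
        return int(self.occupancy.sum())

    def single_occupancy_fraction(self) -> float:
        return float((self.occupancy == 1).mean())

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time", "particle_id", "unit", "event"])


def route_particle(
    state: TrapArrayState,
    unit_index: int,
    mode: str = "deterministic",
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Decide whether a particle arriving at one unit is trapped or bypasses.

    An occupied or valve-closed unit always bypasses.  Otherwise the
    deterministic mode follows the larger branch flow; the stochastic
    mode draws trap with probability Q1/(Q1+Q2), the flux-weighted
    streamline fraction.
    """
    if state.occupancy[unit_index] > 0 or state.valve_on[unit_index]:
        return "bypass"
    split = state.unit_split(unit_index)
    p_trap = split.Q1 / (split.Q1 + split.Q2)
    if mode == "deterministic":
        return "trap" if split.Q1 >= split.Q2 else "bypass"
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic routing needs an rng")
        return "trap" if rng.random() < p_trap else "bypass"
    raise ValueError(f"unknown routing mode {mode!r}")


def _traverse(state: TrapArrayState, particle: int, start_unit: int,
              mode: str, rng, guard_downstream: bool = False,
              capacity: int = 1) -> None:
    """Carry one particle from ``start_unit`` downstream until trapped or out."""
    for u in range(start_unit, state.layout.n_units):
        guard = guard_downstream and state.occupancy[u] == 0
        if guard and not state.valve_on[u]:
            # empty downstream trap sealed for the passage to prevent re-trapping
            decision = "bypass"
        elif state.occupancy[u] >= capacity:
            decision = "bypass"
        else:
            decision = route_particle(state, u, mode, rng)
        if decision == "trap":
            state.occupancy[u] += 1
            state.holders[u].append(particle)
            state.log(particle, u, "trap")
            return
        state.log(particle, u, "bypass")
    state.exited.append(particle)
    state.log(particle, -1, "exit")


def fill_simulation(
    layout: DeviceLayout,
    n_particles: int,
    mode: str = "deterministic",
    rng_seed: Optional[int] = None,
    fluid: FluidSpec = WATER,
    flow: FlowConditions = FlowConditions(mean_velocity=100e-6),
    all_valves_on: bool = False,
    capacity: int = 1,
) -> TrapArrayState:
    """Inject particles one by one at the array head and fill the traps.

    Particles traverse the units in order, applying the routing rule at
    each; the return state carries the final occupancy and the full event
    log.  ``capacity`` > 1 lets a trap hold several particles (see
    ``classify_fit``).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    state = TrapArrayState.empty(layout, fluid, flow, rng_seed)
    if all_valves_on:
        state.valve_on[:] = True
    rng = np.random.default_rng(rng_seed)
    for p in range(n_particles):
        state.time = float(p)
        state.log(p, -1, "inject")
        _traverse(state, p, 0, mode, rng, capacity=capacity)
        state._next_particle = p + 1
    return state


def release(
    state: TrapArrayState,
    schedule: ReleaseSchedule,
    guard_downstream: bool = False,
    mode: str = "deterministic",
) -> TrapArrayState:
    """Apply a valve schedule, ejecting and re-routing trapped particles.

    Closing the valve of an occupied unit pushes its particle into the
    main flow; the particle then traverses the downstream units under the
    routing rule and can be re-trapped by an empty, open trap.  With
    ``guard_downstream`` the empty downstream traps are treated as sealed
    for the passage, so the released particle always leaves the array.
    Releasing an empty unit is a no-op (logged as a warning event).
    """
    schedule.validate(state.layout.n_units)
    rng = np.random.default_rng(state.rng_seed)
    for t, unit, action in sorted(schedule.actions, key=lambda a: a[0]):
        state.time = float(t)
        if action == "off":
            state.valve_on[unit] = False
            state.log(-1, unit, "valve_off")
            continue
        state.valve_on[unit] = True
        state.log(-1, unit, "valve_on")
        if state.occupancy[unit] == 0:
            state.log(-1, unit, "release_noop")
            continue
        while state.occupancy[unit] > 0:
            state.occupancy[unit] -= 1
            particle = state.holders[unit].pop()
            state.log(particle, unit, "release")
            _traverse(state, particle, unit + 1, mode, rng,
                      guard_downstream=guard_downstream)
    return state


def replay(events: Iterable[tuple], layout: DeviceLayout) -> np.ndarray:
    """Reconstruct the final occupancy from an event log."""
    occ = np.zeros(layout.n_units, dtype=int)
    for _, _, unit, event in events:
        if event == "trap":
            occ[unit] += 1
        elif event == "release":
            occ[unit] -= 1
    if (occ < 0).any():
        raise ValueError("event log releases more particles than were trapped")
    return occ
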