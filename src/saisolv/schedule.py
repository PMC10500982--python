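"""Serial-atom-insertion (SAI) annihilation schedules.

An absolute solvation free energy is computed here by *annihilation*: all
nonbonded interactions of the solute are turned off along a discrete ladder
of intermediate states, once in solution and once in vacuum.  The ladder is
built in three blocks:

1. charge block -- the partial charges of every solute atom are scaled
   uniformly (defaults 1.0, 0.6, 0.3, 0.0; the first state is the physical
   system), which keeps a neutral solute exactly neutral in every state;
2. hydrogen block -- the LJ parameters (both r_min and epsilon) of all
   hydrogens are scaled jointly in two steps (0.5, 0.0);
3. heavy-atom block -- heavy atoms are removed one per state in an order
   that keeps the still-interacting core connected, except the last heavy
   atom, which is faded out in two steps (0.5, 0.0).

A terminal all-zero bookkeeping state is appended by default, so a solute
with seven heavy atoms and its hydrogens yields 15 states.  Because no two
consecutive states differ by more than one vanishing atom (or a joint,
modest scaling step), no soft-core potential is needed anywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

from .chem_system import (SoluteTopology, SolvatedSystem, classify_atoms,
                          load_system, replace_system, write_system)
from .errors import ValidationError


@dataclass(frozen=True)
class ScheduleConfig:
    """Scaling-factor ladders for the three schedule blocks."""

    charge_factors: tuple[float, ...] = (1.0, 0.6, 0.3, 0.0)
    hydrogen_lj_factors: tuple[float, ...] = (0.5, 0.0)
    last_heavy_factors: tuple[float, ...] = (0.5, 0.0)
    emit_terminal_state: bool = True

    def __post_init__(self):
        object.__setattr__(self, "charge_factors", tuple(self.charge_factors))
        object.__setattr__(self, "hydrogen_lj_factors",
                           tuple(self.hydrogen_lj_factors))
        object.__setattr__(self, "last_heavy_factors",
                           tuple(self.last_heavy_factors))
        for name in ("charge_factors", "hydrogen_lj_factors",
                     "last_heavy_factors"):
            fs = getattr(self, name)
            if len(fs) == 0 or fs[-1] != 0.0:
                raise ValidationError(f"{name} must end at 0.0")
            if any(b >= a for a, b in zip(fs, fs[1:])):
                raise ValidationError(f"{name} must be strictly decreasing")
            if any(f < 0.0 or f > 1.0 for f in fs):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.charge_factors[0] != 1.0:
            raise ValidationError("charge_factors must begin at 1.0 "
                                  "(the physical state)")


@dataclass(frozen=True)
class StateSpec:
    """Per-atom coupling factors of one intermediate state (1-based index)."""

    index: int
    charge_scale: tuple[float, ...]
    lj_scale: tuple[float, ...]
    block: str  # charge | hydrogen_lj | heavy_lj | terminal

    def __post_init__(self):
        object.__setattr__(self, "charge_scale", tuple(self.charge_scale))
        object.__setattr__(self, "lj_scale", tuple(self.lj_scale))
        for f in (*self.charge_scale, *self.lj_scale):
            if f < 0.0 or f > 1.0:
                raise ValidationError("coupling factors must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"intst{self.index}"

    def is_physical(self) -> bool:
        return (all(f == 1.0 for f in self.charge_scale)
                and all(f == 1.0 for f in self.lj_scale))

    def is_decoupled(self) -> bool:
        return (all(f == 0.0 for f in self.charge_scale)
                and all(f == 0.0 for f in self.lj_scale))


@dataclass(frozen=True)
class Schedule:
    states: tuple[StateSpec, ...]
    heavy_order: tuple[int, ...]
    config: ScheduleConfig = field(default_factory=ScheduleConfig)
    solute_name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "heavy_order", tuple(self.heavy_order))
        for prev, cur in zip(self.states, self.states[1:]):
            if (np.any(np.array(cur.charge_scale) > np.array(prev.charge_scale))
                    or np.any(np.array(cur.lj_scale) > np.array(prev.lj_scale))):
                raise ValidationError(
                    f"coupling increases from {prev.label} to {cur.label}; "
                    "an interaction, once removed, may never reappear")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def table(self) -> str:
        """Human-readable schedule table (the primary provenance artifact)."""
        rows = [f"{'state':>8s}  {'block':<12s}  {'q-scale':>8s}  {'lj-off atoms':<s}"]
        for s in self.states:
            q = max(s.charge_scale) if s.charge_scale else 0.0
            off = [i for i, f in enumerate(s.lj_scale) if f < 1.0]
            rows.append(f"{s.label:>8s}  {s.block:<12s}  {q:8.3f}  "
                        f"{','.join(map(str, off)) if off else '-'}")
        return "\n".join(rows)


def heavy_atom_removal_order(topology: SoluteTopology) -> list[int]:
    """Order in which heavy atoms are turned into dummies, one per state.

    Peripheral atoms go first: an atom is eligible while it was terminal
    (degree <= 1) in the original heavy-atom graph, lowest index first.  When
    no such atom remains (rings), the lowest-index atom of minimal degree
    among the remaining heavy atoms is removed instead.  In either case an
    atom whose removal would disconnect the still-interacting heavy core is
    never chosen, so the remainder stays connected after every removal.
    """
    g = topology.heavy_graph()
    if g.number_of_nodes() == 0:
        raise ValidationError("solute has no heavy atoms")
    if not nx.is_connected(g):
        raise ValidationError("heavy-atom graph is disconnected")
    original_degree = dict(g.degree())
    remaining = g.copy()
    order: list[int] = []
    while remaining.number_of_nodes() > 0:
        if remaining.number_of_nodes() == 1:
            node = next(iter(remaining.nodes))
        else:
            cut = set(nx.articulation_points(remaining))
            candidates = [v for v in remaining.nodes if v not in cut]
            leaves = sorted(v for v in candidates if original_degree[v] <= 1)
            if leaves:
                node = leaves[0]
            else:
                node = min(candidates,
                           key=lambda v: (remaining.degree(v), v))
        order.append(node)
        remaining.remove_node(node)
    return order


def build_schedule(topology: SoluteTopology,
                   config: ScheduleConfig | None = None) -> Schedule:
    """Build the full SAI annihilation ladder for one solute.

    State count = |charge block| + |hydrogen block (if any H)| +
    (n_heavy - 1) + |last-heavy block| + 1 terminal state (if enabled).
    """
    config = config or ScheduleConfig()
    hydrogens, heavy = classify_atoms(topology)
    if not heavy:
        raise ValidationError("SAI requires at least one heavy atom")
    order = heavy_atom_removal_order(topology)

    n = topology.n_atoms
    q = np.ones(n)
    lj = np.ones(n)
    states: list[StateSpec] = []

    def emit(block):
        states.append(StateSpec(index=len(states) + 1,
                                charge_scale=tuple(q),
                                lj_scale=tuple(lj),
                                block=block))

    for f in config.charge_factors:
        q[:] = f
        emit("charge")
    if hydrogens:
        for f in config.hydrogen_lj_factors:
            lj[hydrogens] = f
            emit("hydrogen_lj")
    for atom in order[:-1]:
        lj[atom] = 0.0
        emit("heavy_lj")
    for f in config.last_heavy_factors:
        lj[order[-1]] = f
        emit("heavy_lj")
    if config.emit_terminal_state:
        emit("terminal")
    return Schedule(states=tuple(states), heavy_order=tuple(order),
                    config=config, solute_name=topology.name)


def expected_state_count(n_heavy: int, n_hydrogen: int,
                         config: ScheduleConfig | None = None) -> int:
    """Closed-form state count of :func:`build_schedule`."""
    config = config or ScheduleConfig()
    return (len(config.charge_factors)
            + (len(config.hydrogen_lj_factors) if n_hydrogen else 0)
            + (n_heavy - 1)
            + len(config.last_heavy_factors)
            + (1 if config.emit_terminal_state else 0))


def apply_state(system: SolvatedSystem, state: StateSpec) -> SolvatedSystem:
    """Return the system with one state's coupling factors folded into the
    solute parameters; the solvent is untouched."""
    if system.solute is None:
        raise ValidationError("system has no solute to scale")
    if len(state.charge_scale) != system.solute.n_atoms:
        raise ValidationError("state was built for a different solute")
    from dataclasses import replace as _replace
    atoms = tuple(
        _replace(a,
                 charge=a.charge * state.charge_scale[a.index],
                 r_min=a.r_min * state.lj_scale[a.index],
                 epsilon=a.epsilon * state.lj_scale[a.index])
        for a in system.solute.atoms)
    solute = _replace(system.solute, atoms=atoms)
    return replace_system(system, solute=solute)


# ---------------------------------------------------------------------------
# Self-contained per-state inputs
# ---------------------------------------------------------------------------

def write_state_inputs(schedule: Schedule, system: SolvatedSystem,
                       directory) -> list[str]:
    """Write one self-contained directory (intst1..intstK) per state.

    Each directory holds the *scaled* system file plus a metadata file with
    the raw coupling factors, so a state can be simulated or re-derived in
    isolation.  Re-running produces byte-identical files.
    """
    os.makedirs(directory, exist_ok=True)
    paths = []
    for state in schedule.states:
        subdir = os.path.join(directory, state.label)
        os.makedirs(subdir, exist_ok=True)
        write_system(apply_state(system, state),
                     os.path.join(subdir, "system.yaml"))
        meta = {
            "format": "saisolv-state/1",
            "index": state.index,
            "block": state.block,
            "solute_name": schedule.solute_name,
            "heavy_order": [int(i) for i in schedule.heavy_order],
            "charge_scale": [float(f) for f in state.charge_scale],
            "lj_scale": [float(f) for f in state.lj_scale],
        }
        with open(os.path.join(subdir, "state.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        paths.append(subdir)
    return paths


def read_state_input(subdir, r_off: float = 12.0
                     ) -> tuple[SolvatedSystem, StateSpec]:
    """Load one intstN directory back into a (system, state) pair.

    ``r_off`` is the cutoff used for the box-size guard of the system file.
    """
    system = load_system(os.path.join(subdir, "system.yaml"), r_off=r_off)
    with open(os.path.join(subdir, "state.yaml")) as fh:
        meta = yaml.safe_load(fh)
    state = StateSpec(index=int(meta["index"]),
                      charge_scale=tuple(meta["charge_scale"]),
                      lj_scale=tuple(meta["lj_scale"]),
                      block=str(meta["block"]))
    return system, state


def schedule_to_dict(schedule: Schedule) -> dict:
    return {
        "solute_name": schedule.solute_name,
        "heavy_order": [int(i) for i in schedule.heavy_order],
        "n_states": schedule.n_states,
        "states": [
            {"index": s.index, "block": s.block,
             "charge_scale": [float(f) for f in s.charge_scale],
             "lj_scale": [float(f) for f in s.lj_scale]}
            for s in schedule.states
        ],
    }
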