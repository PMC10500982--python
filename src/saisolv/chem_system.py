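"""Solutes and toy solvated systems with CHARMM-convention nonbonded parameters.

Parameters follow the CHARMM sign/unit conventions: partial charges in e,
Lennard-Jones well depth ``epsilon`` in kcal/mol (stored non-negative, the
pair energy at the minimum is ``-epsilon``), and ``r_min`` in Angstrom as the
*full* minimum-energy distance of the homo-pair, combined between unlike
atoms by the arithmetic mean (Lorentz) with the geometric mean for epsilon
(Berthelot).

Solvent is a rigid 3-site model water: one charged LJ oxygen site and two
charged hydrogen sites at fixed internal geometry.  The model is a toy --
deliberately *not* TIP3P -- because only the estimators built on top of it
are under test, not water thermodynamics.

Systems are (de)serialized to a documented YAML text format with an explicit
unit header, so that any intermediate state of an alchemical schedule can be
written out as a self-contained, diffable input file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import yaml

from .errors import ParseError, ValidationError

FORMAT_TAG = "saisolv-system/1"

#: Default cutoff (Angstrom) used for the load-time box-size guard; a periodic
#: box must be at least twice the cutoff for the minimum-image convention.
DEFAULT_R_OFF = 12.0


# ---------------------------------------------------------------------------
# Solute
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One solute atom: element, partial charge and LJ parameters."""

    index: int
    element: str
    charge: float  # e
    r_min: float   # Angstrom, full homo-pair minimum distance
    epsilon: float  # kcal/mol, >= 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValidationError(f"atom {self.index}: epsilon must be >= 0")
        if self.epsilon > 0 and self.r_min <= 0:
            raise ValidationError(
                f"atom {self.index}: r_min must be > 0 when epsilon > 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class SoluteTopology:
    """Atoms plus bond list; the alchemical region of a calculation."""

    name: str
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(
            self, "bonds",
            tuple((min(i, j), max(i, j)) for i, j in self.bonds))
        n = len(self.atoms)
        for k, atom in enumerate(self.atoms):
            if atom.index != k:
                raise ValidationError(
                    f"atom list not 0..{n - 1} contiguous at position {k}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValidationError(f"bond ({i}, {j}) has invalid indices")
        heavy = self.heavy_graph()
        if heavy.number_of_nodes() > 1 and not nx.is_connected(heavy):
            raise ValidationError(
                f"solute {self.name!r}: heavy-atom graph is disconnected")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(np.sum([a.charge for a in self.atoms]))

    def heavy_graph(self) -> nx.Graph:
        """Connectivity graph restricted to non-hydrogen atoms."""
        g = nx.Graph()
        g.add_nodes_from(a.index for a in self.atoms if not a.is_hydrogen)
        for i, j in self.bonds:
            if i in g and j in g:
                g.add_edge(i, j)
        return g

    def bonded_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g


def classify_atoms(topology: SoluteTopology) -> tuple[list[int], list[int]]:
    """Partition atom indices into (hydrogens, heavy atoms) by element."""
    hydrogens = [a.index for a in topology.atoms if a.is_hydrogen]
    heavy = [a.index for a in topology.atoms if not a.is_hydrogen]
    return hydrogens, heavy


def make_dummy_parameters(topology: SoluteTopology,
                          indices) -> dict[int, dict[str, float]]:
    """Overrides turning the listed atoms into non-interacting dummies.

    A dummy atom keeps its bonded terms but has charge = 0 and epsilon = 0,
    so it contributes nothing to any nonbonded pair sum.
    """
    overrides = {}
    for i in indices:
        if not (0 <= int(i) < topology.n_atoms):
            raise ValidationError(f"dummy index {i} out of range")
        overrides[int(i)] = {"charge": 0.0, "epsilon": 0.0}
    return overrides


def apply_overrides(topology: SoluteTopology,
                    overrides: dict[int, dict[str, float]]) -> SoluteTopology:
    """Return a new topology with per-atom parameter overrides applied."""
    atoms = list(topology.atoms)
    for i, fields in overrides.items():
        atoms[i] = replace(atoms[i], **fields)
    return replace(topology, atoms=tuple(atoms))


# ---------------------------------------------------------------------------
# Solvent model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterModel:
    """Rigid 3-site water: site order per monomer is (O, H1, H2)."""

    q_o: float = -0.80
    q_h: float = 0.40
    r_min_o: float = 3.54   # Angstrom
    eps_o: float = 0.152    # kcal/mol
    r_min_h: float = 0.45
    eps_h: float = 0.046
    r_oh: float = 0.9572    # Angstrom
    theta_deg: float = 104.52

    def __post_init__(self):
        if abs(self.q_o + 2 * self.q_h) > 1e-12:
            raise ValidationError("water model must be neutral")

    def site_charges(self) -> np.ndarray:
        return np.array([self.q_o, self.q_h, self.q_h])

    def site_r_min(self) -> np.ndarray:
        return np.array([self.r_min_o, self.r_min_h, self.r_min_h])

    def site_epsilon(self) -> np.ndarray:
        return np.array([self.eps_o, self.eps_h, self.eps_h])

    def canonical_sites(self) -> np.ndarray:
        """Site coordinates of one monomer with O at the origin, in the xy
        plane, bisector along +x."""
        half = math.radians(self.theta_deg) / 2.0
        h1 = self.r_oh * np.array([math.cos(half), math.sin(half), 0.0])
        h2 = self.r_oh * np.array([math.cos(half), -math.sin(half), 0.0])
        return np.array([[0.0, 0.0, 0.0], h1, h2])


# ---------------------------------------------------------------------------
# Solvated system
# ---------------------------------------------------------------------------

@dataclass
class SolvatedSystem:
    """A (possibly empty) solute in a bath of rigid model waters.

    ``solute_coords`` has shape (n_solute_atoms, 3); ``water_coords`` has
    shape (n_waters, 3, 3) with per-monomer site order (O, H1, H2).  A
    non-periodic system represents the vacuum leg; ``box_edge`` is ignored
    there.
    """

    solute: SoluteTopology | None
    solute_coords: np.ndarray
    water_coords: np.ndarray
    water_model: WaterModel = field(default_factory=WaterModel)
    box_edge: float = 0.0
    periodic: bool = True
    name: str = ""

    def __post_init__(self):
        self.solute_coords = np.asarray(self.solute_coords, dtype=float)
        self.water_coords = np.asarray(self.water_coords, dtype=float)
        if self.solute is None:
            self.solute_coords = self.solute_coords.reshape(0, 3)
        elif self.solute_coords.shape != (self.solute.n_atoms, 3):
            raise ValidationError(
                "solute coordinate array does not match atom count")
        if self.water_coords.size == 0:
            self.water_coords = self.water_coords.reshape(0, 3, 3)
        elif self.water_coords.ndim != 3 or self.water_coords.shape[1:] != (3, 3):
            raise ValidationError("water coordinates must have shape (n, 3, 3)")
        if self.periodic and self.box_edge <= 0:
            raise ValidationError("periodic system needs a positive box edge")

    def validate_box(self, r_off: float = DEFAULT_R_OFF):
        """Box-edge guard: a periodic box must accommodate the cutoff."""
        if self.periodic:
            if self.box_edge < 2.0 * r_off:
                raise ValidationError(
                    f"periodic box edge {self.box_edge:g} A is smaller than "
                    f"twice the cutoff ({2 * r_off:g} A); the minimum-image "
                    "convention would miss interactions")

    @property
    def n_waters(self) -> int:
        return self.water_coords.shape[0]

    @property
    def n_solute_atoms(self) -> int:
        return 0 if self.solute is None else self.solute.n_atoms

    @property
    def volume(self) -> float:
        return float(self.box_edge) ** 3

    def wrapped(self) -> "SolvatedSystem":
        """Return a copy with molecules wrapped into the primary box.

        Wrapping is molecule-wise (solute by centroid, each water by its O
        site) so rigid monomers are never split across the boundary.
        """
        if not self.periodic:
            return self.copy()
        box = self.box_edge
        sol = self.solute_coords.copy()
        if sol.size:
            shift = np.floor(sol.mean(axis=0) / box) * box
            sol -= shift
        wat = self.water_coords.copy()
        if wat.size:
            shifts = np.floor(wat[:, 0, :] / box) * box
            wat -= shifts[:, None, :]
        return replace_system(self, solute_coords=sol, water_coords=wat)

    def copy(self) -> "SolvatedSystem":
        return replace_system(self)

    def without_solute(self) -> "SolvatedSystem":
        """The matching pure-water box (same waters, same volume)."""
        return SolvatedSystem(
            solute=None,
            solute_coords=np.zeros((0, 3)),
            water_coords=self.water_coords.copy(),
            water_model=self.water_model,
            box_edge=self.box_edge,
            periodic=self.periodic,
            name=(self.name + "-waterbox").strip("-"),
        )


def replace_system(system: SolvatedSystem, **kw) -> SolvatedSystem:
    base = dict(
        solute=system.solute,
        solute_coords=system.solute_coords.copy(),
        water_coords=system.water_coords.copy(),
        water_model=system.water_model,
        box_edge=system.box_edge,
        periodic=system.periodic,
        name=system.name,
    )
    base.update(kw)
    return SolvatedSystem(**base)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def system_to_dict(system: SolvatedSystem) -> dict:
    wrapped = system.wrapped()
    doc: dict = {
        "format": FORMAT_TAG,
        "units": {"length": "angstrom", "energy": "kcal/mol", "charge": "e"},
        "combining_rules": "lorentz-berthelot on (r_min, epsilon)",
        "name": system.name,
        "periodic": bool(system.periodic),
        "box_edge": float(system.box_edge),
    }
    if system.solute is not None:
        doc["solute"] = {
            "name": system.solute.name,
            "atoms": [
                {
                    "index": a.index,
                    "element": a.element,
                    "charge": float(a.charge),
                    "r_min": float(a.r_min),
                    "epsilon": float(a.epsilon),
                    "xyz": [float(x) for x in wrapped.solute_coords[a.index]],
                }
                for a in system.solute.atoms
            ],
            "bonds": [[int(i), int(j)] for i, j in system.solute.bonds],
        }
    wm = system.water_model
    doc["water_model"] = {
        "q_o": wm.q_o, "q_h": wm.q_h,
        "r_min_o": wm.r_min_o, "eps_o": wm.eps_o,
        "r_min_h": wm.r_min_h, "eps_h": wm.eps_h,
        "r_oh": wm.r_oh, "theta_deg": wm.theta_deg,
    }
    doc["waters"] = [
        [[float(x) for x in site] for site in monomer]
        for monomer in wrapped.water_coords
    ]
    return doc


def write_system(system: SolvatedSystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False,
                       default_flow_style=None)


def system_from_dict(doc: dict) -> SolvatedSystem:
    if doc.get("format") != FORMAT_TAG:
        raise ParseError(f"unrecognized format tag {doc.get('format')!r}")
    solute = None
    solute_coords = np.zeros((0, 3))
    if "solute" in doc:
        atoms = []
        coords = []
        for rec in doc["solute"]["atoms"]:
            atoms.append(AtomRecord(
                index=int(rec["index"]), element=str(rec["element"]),
                charge=float(rec["charge"]), r_min=float(rec["r_min"]),
                epsilon=float(rec["epsilon"])))
            coords.append(rec["xyz"])
        solute = SoluteTopology(
            name=doc["solute"].get("name", ""),
            atoms=tuple(atoms),
            bonds=tuple((int(i), int(j)) for i, j in doc["solute"]["bonds"]))
        solute_coords = np.array(coords, dtype=float).reshape(len(atoms), 3)
    wm = WaterModel(**doc["water_model"]) if "water_model" in doc else WaterModel()
    waters = np.array(doc.get("waters", []), dtype=float)
    if waters.size == 0:
        waters = waters.reshape(0, 3, 3)
    return SolvatedSystem(
        solute=solute,
        solute_coords=solute_coords,
        water_coords=waters,
        water_model=wm,
        box_edge=float(doc.get("box_edge", 0.0)),
        periodic=bool(doc.get("periodic", True)),
        name=str(doc.get("name", "")),
    )


def load_system(path, r_off: float = DEFAULT_R_OFF) -> SolvatedSystem:
    """Load and validate a system file; parse errors carry line numbers.

    ``r_off`` is the cutoff against which the periodic-box-size guard is
    checked (default: the conventional 12 A CHARMM cutoff).
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            line = None
            mark = getattr(exc, "problem_mark", None)
            if mark is not None:
                line = mark.line + 1
            raise ParseError(str(exc).replace("\n", " "), line=line) from exc
    if not isinstance(doc, dict):
        raise ParseError("system file does not contain a mapping")
    try:
        system = system_from_dict(doc)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"missing or malformed field: {exc}") from exc
    system.validate_box(r_off=r_off)
    return system


def export_pdb(system: SolvatedSystem, path) -> None:
    """Coordinates-only PDB export for visualization (no parameters)."""
    lines = []
    serial = 1

    def record(name, resname, resseq, xyz, element):
        nonlocal serial
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{resname:<4s} {resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}")
        serial += 1

    if system.solute is not None:
        for a in system.solute.atoms:
            record(f"{a.element}{a.index}"[:4], "SOL", 1,
                   system.solute_coords[a.index], a.element)
    for w, monomer in enumerate(system.water_coords):
        for name, elem, xyz in zip(("O", "H1", "H2"), ("O", "H", "H"), monomer):
            record(name, "HOH", w + 2, xyz, elem)
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
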