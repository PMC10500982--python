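"""Synthetic toy solutes and water baths.

These generators make the whole pipeline testable without any external
input: neutral organic-like solutes (1-15 heavy atoms with explicit
hydrogens, chain / ring / star skeletons, plausible CHARMM-style LJ
parameters) and small periodic baths of the rigid 3-site toy water.  All
randomness is seeded and reproducible.

Partial charges are drawn on a dyadic grid (multiples of 1/4096 e) so that
their sum is *exactly* zero in floating point, mirroring the neutral small
molecules of hydration free energy benchmarks.
"""

from __future__ import annotations

import math

import numpy as np

from .chem_system import (AtomRecord, SoluteTopology, SolvatedSystem,
                          WaterModel)
from .errors import ValidationError

HEAVY_BOND = 1.5   # Angstrom
H_BOND = 1.1       # Angstrom
MAX_VALENCE = 4

#: unit directions tried when growing a 3-D embedding (icosahedron + axes)
_PHI = (1.0 + math.sqrt(5.0)) / 2.0
_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[a, b * _PHI, 0] for a in (1, -1) for b in (1, -1)]
    + [[0, a, b * _PHI] for a in (1, -1) for b in (1, -1)]
    + [[b * _PHI, 0, a] for a in (1, -1) for b in (1, -1)], dtype=float)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1)[:, None]


def _skeleton_bonds(n_heavy: int, kind: str) -> list[tuple[int, int]]:
    if kind == "chain":
        return [(i, i + 1) for i in range(n_heavy - 1)]
    if kind == "ring":
        if n_heavy < 3:
            raise ValidationError("a ring needs at least 3 heavy atoms")
        ring = min(n_heavy, 6)
        bonds = [(i, (i + 1) % ring) for i in range(ring)]
        # extra atoms become a substituent chain on atom 0 (e.g. 7 heavy
        # atoms -> six-ring plus methyl, the toluene-like skeleton)
        prev = 0
        for extra in range(ring, n_heavy):
            bonds.append((prev, extra))
            prev = extra
        return bonds
    if kind == "star":
        if n_heavy - 1 > MAX_VALENCE:
            raise ValidationError(
                f"star with {n_heavy} heavy atoms exceeds the center's "
                f"valence of {MAX_VALENCE}")
        return [(0, i) for i in range(1, n_heavy)]
    raise ValidationError(f"unknown topology kind {kind!r}")


def _dyadic_zero_sum_charges(n: int, rng) -> np.ndarray:
    """n charges on the 1/4096 e grid summing to exactly 0.0."""
    if n == 1:
        return np.zeros(1)
    for _ in range(1000):
        ticks = rng.integers(-1024, 1025, size=n)
        ticks[-1] = -int(ticks[:-1].sum())
        if abs(ticks[-1]) <= 2048:
            return ticks / 4096.0
    raise ValidationError("charge generation failed")  # pragma: no cover


def make_toy_solute(n_heavy: int, n_hydrogen: int,
                    topology_kind: str = "chain",
                    seed: int = 0) -> SoluteTopology:
    """Generate a neutral toy solute with a connected heavy-atom skeleton.

    Hydrogens are attached round-robin to heavy atoms with free valence;
    an impossible valence request raises.  LJ parameters fall in
    physically plausible ranges (epsilon 0.02-0.2 kcal/mol, r_min
    2.0-4.5 A).
    """
    if n_heavy < 1:
        raise ValidationError("need at least one heavy atom")
    rng = np.random.default_rng(seed)
    heavy_bonds = _skeleton_bonds(n_heavy, topology_kind)
    degree = np.zeros(n_heavy, dtype=int)
    for i, j in heavy_bonds:
        degree[i] += 1
        degree[j] += 1
    slots = np.maximum(MAX_VALENCE - degree, 0)
    if n_hydrogen > slots.sum():
        raise ValidationError(
            f"cannot attach {n_hydrogen} hydrogens: only {slots.sum()} free "
            "valence slots")
    h_parent = []
    free = slots.copy()
    cursor = 0
    for _ in range(n_hydrogen):
        while free[cursor % n_heavy] == 0:
            cursor += 1
        h_parent.append(cursor % n_heavy)
        free[cursor % n_heavy] -= 1
        cursor += 1

    n = n_heavy + n_hydrogen
    charges = _dyadic_zero_sum_charges(n, rng)
    atoms = []
    for i in range(n_heavy):
        atoms.append(AtomRecord(
            index=i, element="C", charge=float(charges[i]),
            r_min=float(rng.uniform(3.5, 4.5)),
            epsilon=float(rng.uniform(0.05, 0.2))))
    bonds = list(heavy_bonds)
    for k, parent in enumerate(h_parent):
        idx = n_heavy + k
        atoms.append(AtomRecord(
            index=idx, element="H", charge=float(charges[idx]),
            r_min=float(rng.uniform(2.0, 2.6)),
            epsilon=float(rng.uniform(0.02, 0.05))))
        bonds.append((parent, idx))
    return SoluteTopology(
        name=f"toy-{topology_kind}-{n_heavy}h{n_hydrogen}",
        atoms=tuple(atoms), bonds=tuple(bonds))


def embed_solute(topology: SoluteTopology, seed: int = 0) -> np.ndarray:
    """Deterministic 3-D coordinates for a toy topology.

    Atoms are grown breadth-first from atom 0; each new atom takes the
    first direction from a fixed icosahedral candidate set that keeps it
    at least 1.2 A (heavy) / 0.9 A (H) from everything already placed.
    Ring closures end up slightly strained, which is harmless: bonds are
    restrained to the *embedded* lengths, not to ideal ones.
    """
    import networkx as nx
    rng = np.random.default_rng(seed)
    g = topology.bonded_graph()
    n = topology.n_atoms
    coords = np.full((n, 3), np.nan)
    coords[0] = 0.0
    order = list(nx.bfs_edges(g, 0)) if n > 1 else []
    for parent, child in order:
        is_h = topology.atoms[child].is_hydrogen
        length = H_BOND if is_h else HEAVY_BOND
        min_sep = 1.5 if is_h else 2.0
        placed = coords[~np.isnan(coords[:, 0])]
        rot = _random_rotation_matrix(rng)
        for d in _DIRECTIONS @ rot.T:
            cand = coords[parent] + length * d
            others = placed[np.linalg.norm(placed - coords[parent],
                                           axis=1) > 1e-9]
            sep = (np.linalg.norm(others - cand, axis=1).min()
                   if others.size else np.inf)
            if sep > min_sep:
                coords[child] = cand
                break
        else:  # fall back: random direction, best effort
            d = rng.normal(size=3)
            coords[child] = coords[parent] + length * d / np.linalg.norm(d)
    if np.isnan(coords).any():
        raise ValidationError("topology has atoms unreachable from atom 0")
    return coords


def _random_rotation_matrix(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _place_waters(n_waters: int, box_edge: float, rng,
                  water_model: WaterModel,
                  avoid: np.ndarray | None = None,
                  min_dist: float = 2.0,
                  min_oo: float = 2.8,
                  max_tries: int = 2000) -> np.ndarray:
    """Clash-free random placement of rigid waters in a cubic box."""
    sites = water_model.canonical_sites()
    placed = np.zeros((0, 3, 3))
    for _ in range(n_waters):
        for attempt in range(max_tries):
            origin = rng.uniform(0.0, box_edge, size=3)
            rot = _random_rotation_matrix(rng)
            monomer = sites @ rot.T + origin
            ok = True
            if placed.size:
                d_oo = _min_image_dist(placed[:, 0, :], monomer[0:1],
                                       box_edge)
                if d_oo.min() < min_oo:
                    ok = False
                else:
                    d = _min_image_dist(placed.reshape(-1, 3), monomer,
                                        box_edge)
                    if d.min() < min_dist:
                        ok = False
            if ok and avoid is not None and avoid.size:
                if _min_image_dist(avoid, monomer, box_edge).min() < min_dist + 0.4:
                    ok = False
            if ok:
                placed = np.concatenate([placed, monomer[None]], axis=0)
                break
        else:
            raise ValidationError(
                f"could not place water {placed.shape[0] + 1} of {n_waters} "
                f"after {max_tries} tries (box too crowded)")
    return placed


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    disp = a[:, None, :] - b[None, :, :]
    disp -= box * np.round(disp / box)
    return np.sqrt((disp**2).sum(axis=2)).ravel()


def make_water_bath(n_waters: int, box_edge: float, seed: int = 0,
                    water_model: WaterModel | None = None) -> SolvatedSystem:
    """A periodic box of rigid toy waters with no solute.

    Placement guarantees no steric clash (all intermolecular site-site
    distances > 2 A, O-O > 2.8 A) and is reproducible by seed.
    """
    wm = water_model or WaterModel()
    rng = np.random.default_rng(seed)
    waters = _place_waters(n_waters, box_edge, rng, wm)
    return SolvatedSystem(solute=None, solute_coords=np.zeros((0, 3)),
                          water_coords=waters, water_model=wm,
                          box_edge=box_edge, periodic=True,
                          name=f"waterbath-{n_waters}")


def make_solvated_system(solute: SoluteTopology, n_waters: int,
                         box_edge: float, seed: int = 0,
                         water_model: WaterModel | None = None
                         ) -> SolvatedSystem:
    """Solute embedded at the box center in a clash-free water bath."""
    wm = water_model or WaterModel()
    rng = np.random.default_rng(seed)
    coords = embed_solute(solute, seed=seed)
    coords = coords - coords.mean(axis=0) + box_edge / 2.0
    waters = _place_waters(n_waters, box_edge, rng, wm, avoid=coords)
    return SolvatedSystem(solute=solute, solute_coords=coords,
                          water_coords=waters, water_model=wm,
                          box_edge=box_edge, periodic=True,
                          name=solute.name + "-aq")


def vacuum_system(solute: SoluteTopology, seed: int = 0,
                  coords: np.ndarray | None = None) -> SolvatedSystem:
    """The matching gas-phase (non-periodic) system for the vacuum leg."""
    if coords is None:
        coords = embed_solute(solute, seed=seed)
    return SolvatedSystem(solute=solute, solute_coords=coords,
                          water_coords=np.zeros((0, 3, 3)),
                          box_edge=0.0, periodic=False,
                          name=solute.name + "-vac")
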