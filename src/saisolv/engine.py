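"""Nonbonded energies, cutoff treatments, and Metropolis sampling of toy
solvated systems.

The engine evaluates minimum-image LJ + Coulomb pair sums for a solute in a
bath of rigid 3-site waters, under the cutoff treatments used in practice by
the big MD codes:

``OMM_VSWI``
    quintic smoothstep potential switch, S = 1 - 10x^3 + 15x^4 - 6x^5;
``VSWI``
    the classic quadratic-in-r^2 potential switch,
    S = (roff^2 - r^2)^2 (roff^2 + 2 r^2 - 3 ron^2) / (roff^2 - ron^2)^3;
``VFSW``
    the force-switch form (Steinbach & Brooks), which alters the potential
    itself so the *force* goes continuously to zero at the cutoff;
``NONE``
    hard truncation at ``r_off``.

Coulomb interactions in periodic systems are always tapered with the
quintic potential switch regardless of the LJ kind, so that comparisons of
LJ switch kinds differ only in the LJ treatment (the mesh-Ewald
electrostatics of production simulations are likewise common to all LJ
treatments).  Non-periodic (vacuum) systems are evaluated without any
truncation.

Sampling is plain Metropolis Monte Carlo: single-atom translations for the
solute, rigid translations + rotations for the waters, and optional
isotropic volume moves for constant-pressure runs.  Any correct Boltzmann
sampler suffices for the estimators downstream; molecular dynamics adds
nothing at desk scale.  Solute bonds are harmonic restraints to the input
geometry's bond lengths (the toy has no angle or torsion terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .chem_system import SolvatedSystem
from .errors import ValidationError
from .schedule import StateSpec

# Boltzmann constant, kcal/(mol K), CHARMM value
KB = 1.987204259e-3
#: 1 atm in kcal/(mol A^3)
ATM_TO_KCAL_PER_MOL_A3 = 101325.0 * 1e-30 * 6.02214076e23 / 4184.0

SWITCH_KINDS = ("VSWI", "OMM_VSWI", "VFSW", "NONE")
#: sentinel returned by switching_factor for the force-switch kind, which
#: has no multiplicative representation
FORCE_SWITCH_SENTINEL = float("nan")

#: harmonic bond force constant for toy solutes, kcal/(mol A^2)
BOND_K = 300.0


@dataclass(frozen=True)
class NonbondedSettings:
    """Cutoff scheme and thermodynamic state."""

    r_on: float = 10.0        # Angstrom
    r_off: float = 12.0       # Angstrom
    switch_kind: str = "OMM_VSWI"
    coulomb_constant: float = 332.0637  # kcal A / (mol e^2)
    temperature: float = 303.15  # K
    pressure: float = 1.0        # atm

    def __post_init__(self):
        if not (0.0 < self.r_on < self.r_off):
            raise ValidationError("need 0 < r_on < r_off")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.switch_kind not in SWITCH_KINDS:
            raise ValidationError(f"unknown switch kind {self.switch_kind!r}")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


# ---------------------------------------------------------------------------
# Pair potentials
# ---------------------------------------------------------------------------

def _smoothstep(r, r_on, r_off):
    x = np.clip((np.asarray(r, dtype=float) - r_on) / (r_off - r_on), 0.0, 1.0)
    return 1.0 - 10.0 * x**3 + 15.0 * x**4 - 6.0 * x**5


def _vswi(r, r_on, r_off):
    r = np.asarray(r, dtype=float)
    ron2, roff2 = r_on * r_on, r_off * r_off
    r2 = r * r
    s = ((roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2)
         / (roff2 - ron2) ** 3)
    return np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, s))


def switching_factor(r, settings: NonbondedSettings):
    """Unitless taper S(r) for the potential-switch kinds.

    Returns 1 below ``r_on`` and 0 above ``r_off``.  For ``VFSW`` the
    force-switch modifies the functional form of the potential rather than
    multiplying it, so a NaN sentinel is returned (see :func:`lj_energy`).
    ``NONE`` is a step function at the cutoff.
    """
    kind = settings.switch_kind
    if kind == "VFSW":
        return FORCE_SWITCH_SENTINEL
    r = np.asarray(r, dtype=float)
    if kind == "NONE":
        return np.where(r < settings.r_off, 1.0, 0.0)
    if kind == "OMM_VSWI":
        return np.where(r >= settings.r_off, 0.0,
                        _smoothstep(r, settings.r_on, settings.r_off))
    return _vswi(r, settings.r_on, settings.r_off)


def _lj_base(r, r_min, epsilon):
    t6 = (np.asarray(r_min, dtype=float) / r) ** 6
    return epsilon * (t6 * t6 - 2.0 * t6)


def _vfsw_energy(r, r_min, epsilon, r_on, r_off):
    """Force-switched LJ (Steinbach-Brooks): continuous force, zero at
    cutoff; the potential is constant-shifted inside ``r_on``."""
    r = np.asarray(r, dtype=float)
    a = epsilon * np.asarray(r_min, dtype=float) ** 12
    b = 2.0 * epsilon * np.asarray(r_min, dtype=float) ** 6
    ron3, roff3 = r_on**3, r_off**3
    ron6, roff6 = ron3 * ron3, roff3 * roff3
    k6 = roff3 / (roff3 - ron3)
    k12 = roff6 / (roff6 - ron6)
    dv6 = -1.0 / (roff3 * ron3)
    dv12 = -1.0 / (roff6 * ron6)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = a * (r**-12 + dv12) - b * (r**-6 + dv6)
        outer = (a * k12 * (r**-6 - 1.0 / roff6) ** 2
                 - b * k6 * (r**-3 - 1.0 / roff3) ** 2)
    return np.where(r >= r_off, 0.0, np.where(r <= r_on, inner, outer))


def lj_energy(r, r_min, epsilon, settings: NonbondedSettings | None = None):
    """LJ pair energy with the configured cutoff treatment, kcal/mol.

    The base form is U = eps [ (r_min/r)^12 - 2 (r_min/r)^6 ], so the well
    depth at r = r_min is exactly -eps.  ``settings=None`` means the bare,
    untruncated potential (vacuum legs).
    """
    if settings is None:
        return _lj_base(r, r_min, epsilon)
    kind = settings.switch_kind
    if kind == "VFSW":
        return _vfsw_energy(r, r_min, epsilon, settings.r_on, settings.r_off)
    return _lj_base(r, r_min, epsilon) * switching_factor(r, settings)


def lj_force(r, r_min, epsilon, settings: NonbondedSettings | None = None):
    """Analytic radial force -dU/dr, for continuity checks, kcal/(mol A)."""
    r = np.asarray(r, dtype=float)
    t6 = (np.asarray(r_min, dtype=float) / r) ** 6
    du_base = -12.0 * epsilon / r * (t6 * t6 - t6)  # dU/dr of the base form
    if settings is None:
        return -du_base
    kind = settings.switch_kind
    r_on, r_off = settings.r_on, settings.r_off
    if kind == "VFSW":
        a = epsilon * np.asarray(r_min, dtype=float) ** 12
        b = 2.0 * epsilon * np.asarray(r_min, dtype=float) ** 6
        ron3, roff3 = r_on**3, r_off**3
        ron6, roff6 = ron3 * ron3, roff3 * roff3
        k6 = roff3 / (roff3 - ron3)
        k12 = roff6 / (roff6 - ron6)
        with np.errstate(divide="ignore", invalid="ignore"):
            du_in = -12.0 * a * r**-13 + 6.0 * b * r**-7
            du_out = (a * k12 * 2.0 * (r**-6 - 1.0 / roff6) * (-6.0 * r**-7)
                      - b * k6 * 2.0 * (r**-3 - 1.0 / roff3) * (-3.0 * r**-4))
        du = np.where(r >= r_off, 0.0, np.where(r <= r_on, du_in, du_out))
        return -du
    if kind == "NONE":
        return np.where(r < r_off, -du_base, 0.0)
    # potential switch: d(U S)/dr = U' S + U S'
    h = 1e-7
    s = switching_factor(r, settings)
    ds = (switching_factor(r + h, settings)
          - switching_factor(r - h, settings)) / (2.0 * h)
    u = _lj_base(r, r_min, epsilon)
    return -(du_base * s + u * ds)


def softcore_lj_energy(r, lam, r_min, epsilon, alpha=5.0,
                       settings: NonbondedSettings | None = None):
    """Separation-shifted soft-core LJ used on the continuous-lambda path.

    U(r, lam) = lam * S(r) * U_LJ( sqrt(r^2 + alpha (1 - lam)) ), with the
    taper S evaluated at the true distance so the cutoff stays geometric.
    lam = 1 recovers the plain (switched) LJ energy; lam = 0 is identically
    zero.  ``alpha`` is in A^2.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lam must lie in [0, 1]")
    r = np.asarray(r, dtype=float)
    r_eff = np.sqrt(r * r + alpha * (1.0 - lam))
    u = _lj_base(r_eff, r_min, epsilon)
    if settings is None:
        return lam * u
    if settings.switch_kind == "VFSW":
        s = _smoothstep(np.where(r >= settings.r_off, settings.r_off, r),
                        settings.r_on, settings.r_off)
        s = np.where(r >= settings.r_off, 0.0, s)
    else:
        s = switching_factor(r, settings)
    return lam * s * u


def softcore_lj_dudl(r, lam, r_min, epsilon, alpha=5.0,
                     settings: NonbondedSettings | None = None):
    """Analytic d/d(lam) of :func:`softcore_lj_energy`."""
    r = np.asarray(r, dtype=float)
    r_eff = np.sqrt(r * r + alpha * (1.0 - lam))
    u = _lj_base(r_eff, r_min, epsilon)
    t6 = (np.asarray(r_min, dtype=float) / r_eff) ** 6
    du_dr = -12.0 * epsilon / r_eff * (t6 * t6 - t6)
    dr_dl = -alpha / (2.0 * r_eff)
    core = u + lam * du_dr * dr_dl
    if settings is None:
        return core
    if settings.switch_kind == "VFSW":
        s = np.where(np.asarray(r) >= settings.r_off, 0.0,
                     _smoothstep(r, settings.r_on, settings.r_off))
    else:
        s = switching_factor(r, settings)
    return s * core


def harmonic_reference(k, temperature):
    """Reduced free energy per degree of freedom of a 1-D harmonic well,
    f = (1/2) ln( k / (2 pi kB T) ); differences obey
    f(k2) - f(k1) = (1/2) ln(k2 / k1)."""
    if k <= 0:
        raise ValidationError("force constant must be positive")
    return 0.5 * math.log(k / (2.0 * math.pi * KB * temperature))


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Flattened per-site parameter arrays for one system.

    Site order: solute atoms first (topology order), then the waters, three
    sites each (O, H1, H2).  ``allowed`` is the boolean matrix of nonbonded
    pairs: self-pairs, intra-water pairs and solute 1-2/1-3 neighbors are
    excluded.
    """

    positions: np.ndarray       # (M, 3)
    charge: np.ndarray          # (M,)
    r_min: np.ndarray           # (M,)
    epsilon: np.ndarray         # (M,)
    is_solute: np.ndarray       # (M,) bool
    allowed: np.ndarray         # (M, M) bool
    bonds: np.ndarray           # (nb, 2) int, solute bonds
    bond_r0: np.ndarray         # (nb,)
    n_solute: int
    n_waters: int
    pair_i: np.ndarray = field(default=None, repr=False)
    pair_j: np.ndarray = field(default=None, repr=False)
    pair_kind: np.ndarray = field(default=None, repr=False)  # 0 uu, 1 uv, 2 vv

    def __post_init__(self):
        m = self.positions.shape[0]
        iu, ju = np.triu_indices(m, k=1)
        keep = self.allowed[iu, ju]
        self.pair_i, self.pair_j = iu[keep], ju[keep]
        n_sol = (self.is_solute[self.pair_i].astype(int)
                 + self.is_solute[self.pair_j].astype(int))
        self.pair_kind = 2 - n_sol  # 2 solute sites -> 0 (intra-solute)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]


def build_site_table(system: SolvatedSystem) -> SiteTable:
    ns = system.n_solute_atoms
    nw = system.n_waters
    m = ns + 3 * nw
    pos = np.zeros((m, 3))
    q = np.zeros(m)
    rmin = np.zeros(m)
    eps = np.zeros(m)
    is_sol = np.zeros(m, dtype=bool)
    if ns:
        pos[:ns] = system.solute_coords
        q[:ns] = [a.charge for a in system.solute.atoms]
        rmin[:ns] = [a.r_min for a in system.solute.atoms]
        eps[:ns] = [a.epsilon for a in system.solute.atoms]
        is_sol[:ns] = True
    wm = system.water_model
    if nw:
        pos[ns:] = system.water_coords.reshape(-1, 3)
        q[ns:] = np.tile(wm.site_charges(), nw)
        rmin[ns:] = np.tile(wm.site_r_min(), nw)
        eps[ns:] = np.tile(wm.site_epsilon(), nw)

    allowed = ~np.eye(m, dtype=bool)
    for w in range(nw):
        s = ns + 3 * w
        allowed[s:s + 3, s:s + 3] = False
    bonds = np.zeros((0, 2), dtype=int)
    bond_r0 = np.zeros(0)
    if ns:
        g = system.solute.bonded_graph()
        # exclude 1-2 and 1-3 bonded neighbors from intra-solute nonbonded
        lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
        for i in range(ns):
            for j, d in lengths[i].items():
                if d >= 1:
                    allowed[i, j] = allowed[j, i] = False
        bonds = np.array(system.solute.bonds, dtype=int).reshape(-1, 2)
        if bonds.size:
            d = system.solute_coords[bonds[:, 0]] - system.solute_coords[bonds[:, 1]]
            bond_r0 = np.linalg.norm(d, axis=1)
    return SiteTable(positions=pos, charge=q, r_min=rmin, epsilon=eps,
                     is_solute=is_sol, allowed=allowed, bonds=bonds,
                     bond_r0=bond_r0, n_solute=ns, n_waters=nw)


def state_scaled_arrays(table: SiteTable, state: StateSpec | None):
    """Per-site (charge, r_min, sqrt-epsilon) with a state's coupling
    factors folded in; solvent sites are untouched."""
    q = table.charge.copy()
    rmin = table.r_min.copy()
    eps = table.epsilon.copy()
    if state is not None:
        ns = table.n_solute
        if len(state.charge_scale) != ns:
            raise ValidationError("state does not match this solute")
        q[:ns] *= np.asarray(state.charge_scale)
        rmin[:ns] *= np.asarray(state.lj_scale)
        eps[:ns] *= np.asarray(state.lj_scale)
    return q, rmin, np.sqrt(eps)


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyBreakdown:
    solute_solvent: float
    intra_solute: float
    solvent_solvent: float
    bond: float

    @property
    def total(self) -> float:
        return (self.solute_solvent + self.intra_solute
                + self.solvent_solvent + self.bond)


def _min_image(disp, box):
    if box is not None:
        disp = disp - box * np.round(disp / box)
    return disp


def _pair_energies(r, qq, rmin_ij, eps_ij, settings, periodic):
    """LJ + Coulomb energy per pair (arrays).

    Non-periodic (vacuum) evaluation is untruncated; periodic evaluation
    applies the configured LJ cutoff treatment and the quintic potential
    switch to Coulomb.
    """
    if not periodic:
        return _lj_base(r, rmin_ij, eps_ij) + settings.coulomb_constant * qq / r
    if settings.switch_kind == "VFSW":
        lj = _vfsw_energy(r, rmin_ij, eps_ij, settings.r_on, settings.r_off)
    else:
        lj = _lj_base(r, rmin_ij, eps_ij) * switching_factor(r, settings)
    coul = (settings.coulomb_constant * qq / r
            * np.where(r >= settings.r_off, 0.0,
                       _smoothstep(r, settings.r_on, settings.r_off)))
    return lj + coul


def _bond_energy(pos, bonds, bond_r0):
    if bonds.size == 0:
        return 0.0
    d = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
    return float(BOND_K * np.sum((d - bond_r0) ** 2))


def total_energy(system: SolvatedSystem,
                 state: StateSpec | None = None,
                 settings: NonbondedSettings | None = None,
                 coords: np.ndarray | None = None,
                 box_edge: float | None = None) -> EnergyBreakdown:
    """Deterministic component-wise nonbonded + bond energy, kcal/mol.

    Components: solute-solvent, intra-solute (1-2/1-3 excluded),
    solvent-solvent, and the harmonic bond restraint term.
    """
    settings = settings or NonbondedSettings()
    table = build_site_table(system)
    box = box_edge if box_edge is not None else system.box_edge
    if system.periodic and box < 2.0 * settings.r_off:
        raise ValidationError("box too small for the cutoff")
    pos = table.positions if coords is None else np.asarray(coords, float)
    q, rmin, sqeps = state_scaled_arrays(table, state)
    i, j = table.pair_i, table.pair_j
    disp = _min_image(pos[i] - pos[j], box if system.periodic else None)
    r = np.linalg.norm(disp, axis=1)
    e = _pair_energies(r, q[i] * q[j], 0.5 * (rmin[i] + rmin[j]),
                       sqeps[i] * sqeps[j],
                       settings, system.periodic)
    kind = table.pair_kind
    return EnergyBreakdown(
        solute_solvent=float(e[kind == 1].sum()),
        intra_solute=float(e[kind == 0].sum()),
        solvent_solvent=float(e[kind == 2].sum()),
        bond=_bond_energy(pos, table.bonds, table.bond_r0),
    )


# switch-kind codes for the compiled kernels
_KIND_CODE = {"NONE": 0, "OMM_VSWI": 1, "VSWI": 2, "VFSW": 3}


@njit(cache=False)
def _nb_switch(r, ron, roff, kind):
    """Taper S(r) for the potential-switch kinds (scalar, compiled)."""
    if r >= roff:
        return 0.0
    if kind == 0:
        return 1.0
    if r <= ron:
        return 1.0
    if kind == 2:  # VSWI
        ron2 = ron * ron
        roff2 = roff * roff
        r2 = r * r
        return ((roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2)
                / (roff2 - ron2) ** 3)
    x = (r - ron) / (roff - ron)  # quintic smoothstep
    return 1.0 - 10.0 * x**3 + 15.0 * x**4 - 6.0 * x**5


@njit(cache=False)
def _nb_lj(r, rm, eps, ron, roff, kind, periodic):
    if eps == 0.0:
        return 0.0
    if not periodic:
        t6 = (rm / r) ** 6
        return eps * (t6 * t6 - 2.0 * t6)
    if r >= roff:
        return 0.0
    if kind == 3:  # force switch
        a = eps * rm**12
        b = 2.0 * eps * rm**6
        ron3 = ron**3
        roff3 = roff**3
        ron6 = ron3 * ron3
        roff6 = roff3 * roff3
        if r <= ron:
            return (a * (r**-12 - 1.0 / (roff6 * ron6))
                    - b * (r**-6 - 1.0 / (roff3 * ron3)))
        k6 = roff3 / (roff3 - ron3)
        k12 = roff6 / (roff6 - ron6)
        return (a * k12 * (r**-6 - 1.0 / roff6) ** 2
                - b * k6 * (r**-3 - 1.0 / roff3) ** 2)
    t6 = (rm / r) ** 6
    return eps * (t6 * t6 - 2.0 * t6) * _nb_switch(r, ron, roff, kind)


@njit(cache=False)
def _nb_group_energy(pos, box, periodic, sites, allowed, partners,
                     qq, rm_ij, eps_ij, ron, roff, kind):
    """Pair energy of the site group vs the partner mask (compiled)."""
    e = 0.0
    m = pos.shape[0]
    for gi in range(sites.shape[0]):
        a = sites[gi]
        for b in range(m):
            if not (partners[b] and allowed[a, b]):
                continue
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            if periodic:
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                dz -= box * round(dz / box)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            e += _nb_lj(r, rm_ij[a, b], eps_ij[a, b], ron, roff, kind,
                        periodic)
            q = qq[a, b]
            if q != 0.0:
                if periodic:
                    # Coulomb always uses the quintic potential switch
                    e += q / r * _nb_switch(r, ron, roff, 1)
                else:
                    e += q / r
    return e


@njit(cache=False)
def _nb_softcore_group_energy(pos, box, periodic, sites, allowed, partners,
                              qq, rm_ij, eps_ij, is_solute, lam, alpha,
                              ron, roff, kind):
    """Soft-core counterpart of :func:`_nb_group_energy` (compiled).

    Solute-involving LJ pairs use the separation-shifted soft core at
    coupling ``lam`` (taper evaluated at the true distance); the charges
    in ``qq`` already carry the lam scaling.
    """
    e = 0.0
    m = pos.shape[0]
    shift = alpha * (1.0 - lam)
    for gi in range(sites.shape[0]):
        a = sites[gi]
        for b in range(m):
            if not (partners[b] and allowed[a, b]):
                continue
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            if periodic:
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            r = math.sqrt(r2)
            if is_solute[a] or is_solute[b]:
                eps = eps_ij[a, b]
                if eps != 0.0 and lam > 0.0 and (not periodic or r < roff):
                    r_eff = math.sqrt(r2 + shift)
                    t6 = (rm_ij[a, b] / r_eff) ** 6
                    u = eps * (t6 * t6 - 2.0 * t6)
                    if periodic:
                        if kind == 3:
                            u *= _nb_switch(r, ron, roff, 1)
                        else:
                            u *= _nb_switch(r, ron, roff, kind)
                    e += lam * u
            else:
                e += _nb_lj(r, rm_ij[a, b], eps_ij[a, b], ron, roff, kind,
                            periodic)
            q = qq[a, b]
            if q != 0.0:
                if periodic:
                    e += q / r * _nb_switch(r, ron, roff, 1)
                else:
                    e += q / r
    return e


class StatePotential:
    """Nonbonded + bond potential of one SAI intermediate state, with the
    incremental-energy hooks the Monte Carlo kernel needs.

    Pairwise combined parameters are precomputed as M x M matrices and the
    group-energy inner loop is JIT-compiled; :meth:`total` goes through the
    plain vectorized pair sum, which doubles as an internal cross-check of
    the compiled path.
    """

    def __init__(self, system: SolvatedSystem, state: StateSpec | None,
                 settings: NonbondedSettings):
        self.table = build_site_table(system)
        self.settings = settings
        self.periodic = system.periodic
        self.q, self.rmin, self.sqeps = state_scaled_arrays(self.table, state)
        self.qq = np.outer(self.q, self.q) * settings.coulomb_constant
        self.rm_ij = 0.5 * (self.rmin[:, None] + self.rmin[None, :])
        self.eps_ij = np.outer(self.sqeps, self.sqeps)

    def _group_nonbonded(self, pos, box, sites, partners):
        """Sum of pair energies between ``sites`` (rows) and the partner
        mask (columns); masked-out pairs contribute exactly zero."""
        t = self.table
        mask = t.allowed[sites] & partners[None, :]
        disp = pos[sites][:, None, :] - pos[None, :, :]
        if self.periodic:
            disp -= box * np.round(disp / box)
        r2 = np.einsum("gmd,gmd->gm", disp, disp)
        r = np.sqrt(np.where(mask, r2, 1.0))
        qq = self.qq[sites]
        rm = self.rm_ij[sites]
        eps = self.eps_ij[sites]
        s = self.settings
        if not self.periodic:
            e = _lj_base(r, rm, eps) + qq / r
        else:
            if s.switch_kind == "VFSW":
                lj = _vfsw_energy(r, rm, eps, s.r_on, s.r_off)
            else:
                lj = _lj_base(r, rm, eps) * switching_factor(r, s)
            sw = np.where(r >= s.r_off, 0.0, _smoothstep(r, s.r_on, s.r_off))
            e = lj + qq / r * sw
        return float(np.sum(np.where(mask, e, 0.0)))

    def _group_bonds(self, pos, sites):
        t = self.table
        if t.bonds.size == 0:
            return 0.0
        touch = np.isin(t.bonds, sites).any(axis=1)
        if not touch.any():
            return 0.0
        b = t.bonds[touch]
        d = np.linalg.norm(pos[b[:, 0]] - pos[b[:, 1]], axis=1)
        return float(BOND_K * np.sum((d - t.bond_r0[touch]) ** 2))

    def group_energy(self, pos, box, sites) -> float:
        """Interaction energy of the site group with everything else, plus
        bond terms touching the group."""
        partners = np.ones(self.table.n_sites, dtype=bool)
        partners[sites] = False
        s = self.settings
        e = _nb_group_energy(
            pos, box if self.periodic else 0.0, self.periodic,
            np.asarray(sites, dtype=np.int64), self.table.allowed, partners,
            self.qq, self.rm_ij, self.eps_ij, s.r_on, s.r_off,
            _KIND_CODE[s.switch_kind])
        return e + self._group_bonds(pos, sites)

    def total(self, pos, box) -> float:
        t = self.table
        i, j = t.pair_i, t.pair_j
        disp = _min_image(pos[i] - pos[j], box if self.periodic else None)
        r = np.sqrt(np.einsum("ij,ij->i", disp, disp))
        e = float(np.sum(_pair_energies(
            r, self.q[i] * self.q[j], 0.5 * (self.rmin[i] + self.rmin[j]),
            self.sqeps[i] * self.sqeps[j],
            self.settings, self.periodic)))
        return e + _bond_energy(pos, t.bonds, t.bond_r0)


class SoftcorePotential:
    """Continuous-lambda annihilation Hamiltonian (the reference route).

    All solute-involving LJ pairs use the separation-shifted soft core at
    coupling ``lam``; solute charges are scaled linearly by ``lam`` (so
    solute-solvent Coulomb terms scale as lam and intra-solute ones as
    lam^2); the solvent-solvent terms are at full strength.  lam = 1 is the
    physical system and lam = 0 the fully decoupled solute, i.e. the same
    endpoints as the SAI ladder.
    """

    def __init__(self, system: SolvatedSystem, lam: float,
                 settings: NonbondedSettings, alpha: float = 5.0):
        if not (0.0 <= lam <= 1.0):
            raise ValidationError("lam must lie in [0, 1]")
        self.table = build_site_table(system)
        self.settings = settings
        self.periodic = system.periodic
        self.lam = float(lam)
        self.alpha = float(alpha)
        t = self.table
        self.q = t.charge.copy()
        self.q[:t.n_solute] *= self.lam
        self.sqeps = np.sqrt(t.epsilon)
        self.qq = np.outer(self.q, self.q) * settings.coulomb_constant
        self.rm_ij = 0.5 * (t.r_min[:, None] + t.r_min[None, :])
        self.eps_ij = np.outer(self.sqeps, self.sqeps)
        self.solute_pair = t.is_solute[:, None] | t.is_solute[None, :]

    def _energy_pairs(self, r, i, j, dudl=False):
        t, s = self.table, self.settings
        solute_pair = t.is_solute[i] | t.is_solute[j]
        rmin_ij = 0.5 * (t.r_min[i] + t.r_min[j])
        eps_ij = self.sqeps[i] * self.sqeps[j]
        per = self.settings if self.periodic else None
        # Coulomb (charges already scaled by lam on solute sites)
        if self.periodic:
            sw = np.where(r >= s.r_off, 0.0, _smoothstep(r, s.r_on, s.r_off))
        else:
            sw = 1.0
        coul = s.coulomb_constant * self.q[i] * self.q[j] / r * sw
        # LJ: soft core on solute-involving pairs, plain otherwise
        lj_plain = lj_energy(r, rmin_ij, eps_ij, per)
        lj_soft = softcore_lj_energy(r, self.lam, rmin_ij, eps_ij,
                                     self.alpha, per)
        e = np.where(solute_pair, lj_soft, lj_plain) + coul
        if not dudl:
            return e
        # dU_elec/dlam from unscaled charges (finite at lam = 0):
        # solute-solvent terms are linear in lam, intra-solute quadratic
        both_solute = t.is_solute[i] & t.is_solute[j]
        lam_power = np.where(both_solute, 2.0 * self.lam, 1.0)
        base_coul = s.coulomb_constant * t.charge[i] * t.charge[j] / r * sw
        dcoul = np.where(solute_pair, lam_power * base_coul, 0.0)
        dlj = np.where(solute_pair,
                       softcore_lj_dudl(r, self.lam, rmin_ij, eps_ij,
                                        self.alpha, per),
                       0.0)
        return e, dcoul + dlj

    def _group_nonbonded(self, pos, box, sites, partners):
        t, s = self.table, self.settings
        mask = t.allowed[sites] & partners[None, :]
        disp = pos[sites][:, None, :] - pos[None, :, :]
        if self.periodic:
            disp -= box * np.round(disp / box)
        r2 = np.einsum("gmd,gmd->gm", disp, disp)
        r = np.sqrt(np.where(mask, r2, 1.0))
        rm = self.rm_ij[sites]
        eps = self.eps_ij[sites]
        sol = self.solute_pair[sites]
        if self.periodic:
            sw = np.where(r >= s.r_off, 0.0, _smoothstep(r, s.r_on, s.r_off))
            sw_lj = (sw if s.switch_kind in ("OMM_VSWI", "VFSW")
                     else switching_factor(r, s))
        else:
            sw = sw_lj = 1.0
        coul = self.qq[sites] / r * sw
        r_eff = np.sqrt(r2 + self.alpha * (1.0 - self.lam))
        lj_soft = (self.lam * sw_lj
                   * _lj_base(np.where(mask, r_eff, 1.0), rm, eps))
        if self.periodic and s.switch_kind == "VFSW":
            lj_plain = _vfsw_energy(r, rm, eps, s.r_on, s.r_off)
        elif self.periodic:
            lj_plain = _lj_base(r, rm, eps) * switching_factor(r, s)
        else:
            lj_plain = _lj_base(r, rm, eps)
        e = np.where(sol, lj_soft, lj_plain) + coul
        return float(np.sum(np.where(mask, e, 0.0)))

    def group_energy(self, pos, box, sites) -> float:
        t, s = self.table, self.settings
        partners = np.ones(t.n_sites, dtype=bool)
        partners[sites] = False
        e = _nb_softcore_group_energy(
            pos, box if self.periodic else 0.0, self.periodic,
            np.asarray(sites, dtype=np.int64), t.allowed, partners,
            self.qq, self.rm_ij, self.eps_ij, t.is_solute,
            self.lam, self.alpha, s.r_on, s.r_off,
            _KIND_CODE[s.switch_kind])
        if t.bonds.size:
            touch = np.isin(t.bonds, sites).any(axis=1)
            if touch.any():
                b = t.bonds[touch]
                d = np.linalg.norm(pos[b[:, 0]] - pos[b[:, 1]], axis=1)
                e += float(BOND_K * np.sum((d - t.bond_r0[touch]) ** 2))
        return e

    def total(self, pos, box) -> float:
        t = self.table
        i, j = t.pair_i, t.pair_j
        disp = _min_image(pos[i] - pos[j], box if self.periodic else None)
        r = np.sqrt(np.einsum("ij,ij->i", disp, disp))
        e = float(np.sum(self._energy_pairs(r, i, j)))
        return e + _bond_energy(pos, t.bonds, t.bond_r0)

    def dudl(self, pos, box) -> float:
        """Instantaneous dU/d(lam) for one configuration."""
        t = self.table
        i, j = t.pair_i, t.pair_j
        keep = t.is_solute[i] | t.is_solute[j]
        i, j = i[keep], j[keep]
        disp = _min_image(pos[i] - pos[j], box if self.periodic else None)
        r = np.sqrt(np.einsum("ij,ij->i", disp, disp))
        _, de = self._energy_pairs(r, i, j, dudl=True)
        return float(np.sum(de))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Saved Monte Carlo frames of one intermediate state."""

    frames: np.ndarray        # (F, M, 3)
    box_edges: np.ndarray     # (F,)
    state_index: int
    seed: int
    periodic: bool = True
    npt: bool = False
    acceptance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.box_edges = np.asarray(self.box_edges, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must have shape (F, M, 3)")
        if self.box_edges.shape[0] != self.frames.shape[0]:
            raise ValidationError("one box edge per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def volumes(self) -> np.ndarray | None:
        """Per-frame box volumes in A^3 (None for non-periodic runs)."""
        if not self.periodic:
            return None
        return self.box_edges ** 3

    def sliced(self, start: int) -> "Trajectory":
        return Trajectory(frames=self.frames[start:],
                          box_edges=self.box_edges[start:],
                          state_index=self.state_index, seed=self.seed,
                          periodic=self.periodic, npt=self.npt,
                          acceptance=dict(self.acceptance))


def write_trajectory(traj: Trajectory, path, elements=None) -> None:
    """Multi-frame XYZ-style text with a box/volume comment line."""
    m = traj.frames.shape[1] if traj.n_frames else 0
    if elements is None:
        elements = ["X"] * m
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{m}\n")
            fh.write(f"box={traj.box_edges[f]:.10g} state={traj.state_index} "
                     f"seed={traj.seed} periodic={int(traj.periodic)} "
                     f"npt={int(traj.npt)}\n")
            for e, xyz in zip(elements, traj.frames[f]):
                fh.write(f"{e} {xyz[0]:.10g} {xyz[1]:.10g} {xyz[2]:.10g}\n")


def load_trajectory(path) -> Trajectory:
    frames, boxes = [], []
    meta = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        m = int(lines[k])
        meta = dict(tok.split("=") for tok in lines[k + 1].split())
        coords = [list(map(float, ln.split()[1:4]))
                  for ln in lines[k + 2:k + 2 + m]]
        frames.append(coords)
        boxes.append(float(meta["box"]))
        k += 2 + m
    return Trajectory(frames=np.array(frames), box_edges=np.array(boxes),
                      state_index=int(meta.get("state", 0)),
                      seed=int(meta.get("seed", 0)),
                      periodic=bool(int(meta.get("periodic", 1))),
                      npt=bool(int(meta.get("npt", 0))))


# ---------------------------------------------------------------------------
# Metropolis sampling
# ---------------------------------------------------------------------------

def _random_rotation(rng, max_angle):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return (np.eye(3) + math.sin(angle) * kx
            + (1.0 - math.cos(angle)) * (kx @ kx))


def _wrap_frame(pos, box, table: SiteTable):
    """Molecule-wise wrap of a frame into [0, box)."""
    out = pos.copy()
    ns = table.n_solute
    if ns:
        shift = np.floor(out[:ns].mean(axis=0) / box) * box
        out[:ns] -= shift
    for w in range(table.n_waters):
        s = ns + 3 * w
        shift = np.floor(out[s] / box) * box
        out[s:s + 3] -= shift
    return out


def mc_sample_potential(potential, initial_pos, box_edge, settings,
                        n_sweeps, seed, save_every=5, npt=False,
                        state_index=0, tune_fraction=0.2) -> Trajectory:
    """Metropolis MC over a generic potential (see :func:`mc_sample`)."""
    if n_sweeps <= 0:
        raise ValidationError("n_sweeps must be positive")
    rng = np.random.default_rng(seed)
    t = potential.table
    periodic = potential.periodic
    pos = np.array(initial_pos, dtype=float)
    box = float(box_edge) if periodic else None
    if periodic and box < 2.0 * settings.r_off:
        raise ValidationError("box too small for the cutoff")
    beta = settings.beta
    p_red = settings.pressure * ATM_TO_KCAL_PER_MOL_A3

    movers = [("atom", np.array([i])) for i in range(t.n_solute)]
    movers += [("water", np.arange(t.n_solute + 3 * w, t.n_solute + 3 * w + 3))
               for w in range(t.n_waters)]
    n_mol = t.n_solute + t.n_waters  # independently translated units

    steps = {"atom": 0.35, "water": 0.30, "rot": 0.35, "vol": 0.02}
    acc = {k: [0, 0] for k in ("atom", "water", "vol")}
    window = {k: [0, 0] for k in acc}
    tune_until = int(math.ceil(tune_fraction * n_sweeps))
    max_step = (box / 4.0) if periodic else 10.0

    def metropolis(d_e):
        if d_e <= 0.0:
            return True
        x = beta * d_e
        if x > 700.0:
            return False
        return rng.random() < math.exp(-x)

    frames, boxes = [], []

    for sweep in range(n_sweeps):
        for kind, sites in movers:
            e_old = potential.group_energy(pos, box, sites)
            old = pos[sites].copy()
            if kind == "atom":
                pos[sites] = old + rng.uniform(-steps["atom"], steps["atom"],
                                               size=3)
            else:
                rot = _random_rotation(rng, steps["rot"])
                center = old[0]  # rotate about the O site
                moved = (old - center) @ rot.T + center
                moved += rng.uniform(-steps["water"], steps["water"], size=3)
                pos[sites] = moved
            d_e = potential.group_energy(pos, box, sites) - e_old
            if metropolis(d_e):
                acc[kind][0] += 1
                window[kind][0] += 1
            else:
                pos[sites] = old
            acc[kind][1] += 1
            window[kind][1] += 1
        if npt and periodic:
            e_old = potential.total(pos, box)
            v_old = box**3
            v_new = v_old + rng.uniform(-steps["vol"], steps["vol"]) * v_old
            if v_new > (2.0 * settings.r_off) ** 3:
                s = (v_new / v_old) ** (1.0 / 3.0)
                new_pos = pos.copy()
                ns = t.n_solute
                if ns:
                    c = pos[:ns].mean(axis=0)
                    new_pos[:ns] = pos[:ns] + (s - 1.0) * c
                for w in range(t.n_waters):
                    a = ns + 3 * w
                    new_pos[a:a + 3] = pos[a:a + 3] + (s - 1.0) * pos[a]
                new_box = s * box
                d_e = potential.total(new_pos, new_box) - e_old
                arg = (-beta * (d_e + p_red * (v_new - v_old))
                       + n_mol * math.log(v_new / v_old))
                if arg >= 0.0 or (arg > -700.0 and rng.random() < math.exp(arg)):
                    pos, box = new_pos, new_box
                    acc["vol"][0] += 1
                    window["vol"][0] += 1
                acc["vol"][1] += 1
                window["vol"][1] += 1
        # step-size auto-tuning during the initial (discarded) phase
        if sweep < tune_until:
            for key, step_key in (("atom", "atom"), ("water", "water"),
                                  ("vol", "vol")):
                a, n = window[key]
                if n >= 25:
                    frac = a / n
                    if frac > 0.45:
                        steps[step_key] = min(steps[step_key] * 1.2, max_step)
                        if key == "water":
                            steps["rot"] = min(steps["rot"] * 1.2, math.pi)
                    elif frac < 0.30:
                        steps[step_key] *= 0.8
                        if key == "water":
                            steps["rot"] *= 0.8
                    window[key] = [0, 0]
        if (sweep + 1) % save_every == 0:
            frame = _wrap_frame(pos, box, t) if periodic else pos.copy()
            frames.append(frame)
            boxes.append(box if periodic else 0.0)

    rates = {k: (a / n if n else None) for k, (a, n) in acc.items()}
    return Trajectory(frames=np.array(frames), box_edges=np.array(boxes),
                      state_index=state_index, seed=seed, periodic=periodic,
                      npt=npt, acceptance=rates)


def mc_sample(system: SolvatedSystem, state: StateSpec | None,
              settings: NonbondedSettings, n_sweeps: int, seed: int,
              save_every: int = 5, npt: bool = False,
              initial_coords: np.ndarray | None = None) -> Trajectory:
    """Sample configurations of one intermediate state.

    One sweep attempts one move per solute atom and one rigid-body move per
    water (plus one volume move under ``npt``).  Step sizes are auto-tuned
    toward ~40% acceptance during the first 20% of the sweeps; a fixed seed
    gives a bit-identical trajectory.
    """
    pot = StatePotential(system, state, settings)
    pos = pot.table.positions if initial_coords is None else initial_coords
    return mc_sample_potential(
        pot, pos, system.box_edge, settings, n_sweeps, seed,
        save_every=save_every, npt=npt,
        state_index=state.index if state is not None else 1)
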