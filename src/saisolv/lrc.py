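"""Lennard-Jones long-range (dispersion) corrections.

Truncating LJ interactions at ``r_off`` omits the attractive tail beyond
the cutoff (and the part of the well suppressed by the switching function
inside it).  For an isotropic fluid the omitted energy is, per pair of atom
types a, b,

    E_LRC = (2 pi / V) sum_ab N_a N_b  Integral_0^inf [U_ab - U_ab^sw] r^2 dr,

which is evaluated here with the beyond-cutoff part in closed form (the
r^-6 tail contributes -2 eps r_min^6 / (3 r_off^3) per unit pair density,
plus the tiny r^-12 term) and the switch-deficit part inside the cutoff by
adaptive quadrature.

The correction to an absolute solvation free energy is the difference
between the correction of the fully interacting solute-solvent box and
that of the matching pure-water box.  For constant-volume systems the
difference is a constant; for constant-pressure trajectories it is
averaged a posteriori over snapshots (each frame's correction scales as
1/V), with the scatter over independently seeded repetitions as the error
bar.  The virial contribution of the tail is ignored throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .chem_system import SolvatedSystem
from .engine import NonbondedSettings, Trajectory, _lj_base, lj_energy
from .errors import ValidationError


@dataclass
class LRCResult:
    value: float                  # kcal/mol
    stderr: float                 # kcal/mol (SD over repetitions)
    method: str                   # analytic | a_posteriori
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stderr < 0:
            raise ValidationError("stderr must be >= 0")


def pair_tail_integral(r_min: float, epsilon: float,
                       settings: NonbondedSettings,
                       attractive_only: bool = False) -> float:
    """Integral_0^inf [U(r) - U_switched(r)] r^2 dr for one pair type,
    kcal/mol A^3.

    ``attractive_only`` keeps just the r^-6 tail beyond the cutoff (the
    textbook closed form); the default also includes the repulsive r^-12
    tail and the switch deficit inside [r_on, r_off].
    """
    if epsilon == 0.0:
        return 0.0
    r_off = settings.r_off
    r_on = settings.r_on
    tail_attr = -2.0 * epsilon * r_min**6 / (3.0 * r_off**3)
    if attractive_only:
        return tail_attr
    tail = tail_attr + epsilon * r_min**12 / (9.0 * r_off**9)
    deficit = 0.0
    if settings.switch_kind in ("VSWI", "OMM_VSWI", "VFSW"):
        def integrand(r):
            return ((_lj_base(r, r_min, epsilon)
                     - lj_energy(r, r_min, epsilon, settings)) * r * r)
        val, _ = quad(integrand, r_on, r_off, epsrel=1e-10, epsabs=1e-13,
                      limit=200)
        deficit += val
        if settings.switch_kind == "VFSW":
            # below r_on the force-switched potential is shifted by a constant
            a = epsilon * r_min**12
            b = 2.0 * epsilon * r_min**6
            shift = (a / (r_off**6 * r_on**6) - b / (r_off**3 * r_on**3))
            deficit += shift * r_on**3 / 3.0
    return tail + deficit


def _site_types(system: SolvatedSystem):
    """(count, r_min, epsilon) per atom type in the box."""
    types = []
    if system.solute is not None:
        for a in system.solute.atoms:
            types.append((1, a.r_min, a.epsilon))
    wm = system.water_model
    if system.n_waters:
        types.append((system.n_waters, wm.r_min_o, wm.eps_o))
        types.append((2 * system.n_waters, wm.r_min_h, wm.eps_h))
    return types


def analytic_tail(system: SolvatedSystem, settings: NonbondedSettings,
                  volume: float | None = None) -> float:
    """Analytic isotropic LRC of one periodic box, kcal/mol.

    Assumes a uniform (ideal-gas) pair distribution beyond the switching
    region, sums over all ordered type pairs, and is exact in the large-N
    homogeneous limit.  Negative whenever attraction dominates.
    """
    if not system.periodic:
        raise ValidationError("the isotropic LRC requires a periodic system")
    v = float(volume) if volume is not None else system.volume
    if v <= 0:
        raise ValidationError("volume must be positive")
    types = _site_types(system)
    cache: dict[tuple[float, float], float] = {}
    total = 0.0
    for a, (na, rma, epa) in enumerate(types):
        for b, (nb, rmb, epb) in enumerate(types):
            eps = math.sqrt(epa * epb)
            if eps == 0.0:
                continue
            # exact ordered distinct-pair counts: the self-density N^2
            # convention is only the large-N limit and is measurably wrong
            # for desk-sized boxes
            count = na * (na - 1) if a == b else na * nb
            if count == 0:
                continue
            rm = 0.5 * (rma + rmb)
            key = (rm, eps)
            if key not in cache:
                cache[key] = pair_tail_integral(rm, eps, settings)
            total += count * cache[key]
    return 2.0 * math.pi / v * total


def lrc_coefficient(system: SolvatedSystem,
                    settings: NonbondedSettings) -> float:
    """C such that the box's LRC at volume V is C / V (kcal/mol A^3)."""
    return analytic_tail(system, settings, volume=1.0)


def asfe_lrc_analytic(system: SolvatedSystem,
                      settings: NonbondedSettings) -> LRCResult:
    """Fixed-volume LRC contribution to the ASFE: full box minus the
    matching water box at the same volume."""
    full = analytic_tail(system, settings)
    water = analytic_tail(system.without_solute(), settings)
    return LRCResult(value=full - water, stderr=0.0, method="analytic",
                     components={"full": full, "water": water})


def a_posteriori_lrc(full_system: SolvatedSystem,
                     water_system: SolvatedSystem,
                     full_trajs: list[Trajectory],
                     water_trajs: list[Trajectory],
                     settings: NonbondedSettings,
                     discard_fraction: float = 1.0 / 3.0) -> LRCResult:
    """Constant-pressure LRC estimate from paired NPT trajectories.

    Per repetition: the first third of each trajectory is discarded, each
    retained frame contributes the analytic correction at its instantaneous
    volume, and the estimate is <dE_LRC_full> - <dE_LRC_water>.  The value
    is the mean over repetitions, the error bar their standard deviation.
    """
    if water_system.n_solute_atoms != 0:
        raise ValidationError("water_system must not contain a solute")
    if water_system.n_waters != full_system.n_waters:
        raise ValidationError(
            "water box must contain the same number of waters as the full "
            "system")
    if len(full_trajs) != len(water_trajs) or not full_trajs:
        raise ValidationError("need matched, non-empty trajectory lists")
    c_full = lrc_coefficient(full_system, settings)
    c_water = lrc_coefficient(water_system, settings)

    def mean_lrc(traj, coeff):
        vols = traj.volumes
        if vols is None:
            raise ValidationError("trajectory carries no volume data")
        drop = int(math.floor(discard_fraction * traj.n_frames))
        kept = vols[drop:]
        if kept.size == 0:
            raise ValidationError("no frames left after discard")
        return float(np.mean(coeff / kept))

    diffs, fulls, waters = [], [], []
    for tf, tw in zip(full_trajs, water_trajs):
        ef = mean_lrc(tf, c_full)
        ew = mean_lrc(tw, c_water)
        fulls.append(ef)
        waters.append(ew)
        diffs.append(ef - ew)
    diffs = np.asarray(diffs)
    stderr = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return LRCResult(value=float(diffs.mean()), stderr=stderr,
                     method="a_posteriori",
                     components={"full": float(np.mean(fulls)),
                                 "water": float(np.mean(waters)),
                                 "per_repetition": [float(d) for d in diffs]})
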