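"""Free energy estimation from per-state trajectories.

The production route is MBAR: every retained configuration from every
intermediate state is re-evaluated under every state's parameters, giving
the N x K reduced-potential matrix u(x, k) = beta U_k(x) (+ beta p V(x) for
constant-pressure frames), from which the self-consistent MBAR equations

    f_i = -ln sum_n  exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

yield the per-state reduced free energies (anchored at f_1 = 0).  The
solver iterates self-consistently with log-sum-exp stabilization and then
polishes with Newton steps on the convex MBAR objective; the asymptotic
covariance is available as a secondary diagnostic, while the headline
uncertainty is the standard deviation over independently seeded repeats.

The reference route is thermodynamic integration over a continuous
soft-core path: <dU/dlambda> at (by default 21) equidistant lambda values,
interpolated by a cubic spline that is integrated in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

from .chem_system import SolvatedSystem
from .engine import (NonbondedSettings, Trajectory, _bond_energy,
                     _min_image, _pair_energies, ATM_TO_KCAL_PER_MOL_A3,
                     build_site_table, state_scaled_arrays)
from .errors import ConvergenceError, OverlapWarning, ValidationError
from .schedule import Schedule

#: adjacent-state overlap below this triggers an OverlapWarning
OVERLAP_WARN_THRESHOLD = 0.03


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EnergyMatrix:
    """N x K reduced potentials with per-state sample counts."""

    u: np.ndarray          # (N, K), unitless
    n_k: np.ndarray        # (K,) samples contributed per state
    beta: float            # mol/kcal
    pressure_term: bool = False

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u.ndim != 2:
            raise ValidationError("u must be an N x K matrix")
        if int(self.n_k.sum()) != self.u.shape[0]:
            raise ValidationError("sum(N_k) must equal the number of rows")
        if not np.all(np.isfinite(self.u)):
            raise ValidationError("reduced potentials must be finite")

    @property
    def n_states(self) -> int:
        return self.u.shape[1]


@dataclass
class FreeEnergyResult:
    delta_g: float                 # kcal/mol
    stderr: float                  # kcal/mol, SD over repeats
    per_repeat: tuple[float, ...] = ()
    leg: str = ""                  # vacuum | aqueous
    method: str = "MBAR"
    solute: str = ""

    def __post_init__(self):
        if self.stderr < 0:
            raise ValidationError("stderr must be >= 0")


@dataclass
class TIProfile:
    """<dU/dlambda> per lambda on the soft-core path."""

    lambdas: np.ndarray
    dudl_means: np.ndarray      # kcal/mol
    dudl_stderr: np.ndarray | None = None

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dudl_means = np.asarray(self.dudl_means, dtype=float)
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValidationError("lambdas must be strictly increasing "
                                  "(duplicates not allowed)")
        if self.lambdas[0] != 0.0 or self.lambdas[-1] != 1.0:
            raise ValidationError("lambda endpoints must be 0 and 1")
        if self.dudl_stderr is not None:
            self.dudl_stderr = np.asarray(self.dudl_stderr, dtype=float)


@dataclass
class ASFEResult:
    """Combined absolute solvation free energy, kcal/mol."""

    value: float
    stderr: float
    vacuum: FreeEnergyResult
    aqueous: FreeEnergyResult
    lrc: float = 0.0
    lrc_stderr: float = 0.0


# ---------------------------------------------------------------------------
# Trajectory post-processing
# ---------------------------------------------------------------------------

def discard_equilibration(traj: Trajectory, fraction: float = 0.25) -> Trajectory:
    """Drop the first floor(fraction * n) frames as equilibration."""
    if not (0.0 <= fraction < 1.0):
        raise ValidationError("fraction must lie in [0, 1)")
    if traj.n_frames == 0:
        raise ValidationError("cannot discard from an empty trajectory")
    drop = int(math.floor(fraction * traj.n_frames))
    return traj.sliced(drop)


def state_energies(system: SolvatedSystem, schedule: Schedule,
                   settings: NonbondedSettings, frames: np.ndarray,
                   box_edges: np.ndarray) -> np.ndarray:
    """Potential energy of each frame under each state, shape (F, K).

    Solvent-solvent and bond terms are computed once per frame (they carry
    no alchemical scaling); solute-involving pair terms are re-evaluated
    for every state's coupling factors.
    """
    table = build_site_table(system)
    periodic = system.periodic
    scaled = [state_scaled_arrays(table, s) for s in schedule.states]
    i, j = table.pair_i, table.pair_j
    sol = table.pair_kind < 2
    i_s, j_s = i[sol], j[sol]
    i_w, j_w = i[~sol], j[~sol]
    out = np.zeros((frames.shape[0], len(scaled)))
    for f in range(frames.shape[0]):
        pos = frames[f]
        box = box_edges[f] if periodic else None
        disp = _min_image(pos[i_w] - pos[j_w], box)
        r_w = np.sqrt(np.einsum("ij,ij->i", disp, disp))
        e_ww = float(np.sum(_pair_energies(
            r_w, table.charge[i_w] * table.charge[j_w],
            0.5 * (table.r_min[i_w] + table.r_min[j_w]),
            np.sqrt(table.epsilon[i_w] * table.epsilon[j_w]),
            settings, periodic))) if i_w.size else 0.0
        e_bond = _bond_energy(pos, table.bonds, table.bond_r0)
        disp = _min_image(pos[i_s] - pos[j_s], box)
        r_s = np.sqrt(np.einsum("ij,ij->i", disp, disp))
        for k, (q, rmin, sqeps) in enumerate(scaled):
            e_sol = float(np.sum(_pair_energies(
                r_s, q[i_s] * q[j_s], 0.5 * (rmin[i_s] + rmin[j_s]),
                sqeps[i_s] * sqeps[j_s], settings, periodic))) if i_s.size else 0.0
            out[f, k] = e_sol + e_ww + e_bond
    return out


def reduced_potential_matrix(trajs: list[Trajectory], schedule: Schedule,
                             system: SolvatedSystem,
                             settings: NonbondedSettings) -> EnergyMatrix:
    """Re-evaluate every frame of every per-state trajectory under every
    state, returning the stacked N x K reduced-potential matrix.

    The beta p V term is included only for frames from constant-pressure
    trajectories (which carry instantaneous volumes); vacuum and NVT frames
    never get one.
    """
    if len(trajs) != schedule.n_states:
        raise ValidationError(
            f"need one trajectory per state: got {len(trajs)} trajectories "
            f"for {schedule.n_states} states")
    beta = settings.beta
    blocks = []
    n_k = []
    any_npt = False
    for traj in trajs:
        if traj.n_frames == 0:
            raise ValidationError(
                f"state {traj.state_index} contributed no frames")
        u = beta * state_energies(system, schedule, settings,
                                  traj.frames, traj.box_edges)
        if traj.npt and traj.periodic:
            pv = (settings.pressure * ATM_TO_KCAL_PER_MOL_A3
                  * traj.volumes)
            u = u + beta * pv[:, None]
            any_npt = True
        blocks.append(u)
        n_k.append(traj.n_frames)
    return EnergyMatrix(u=np.vstack(blocks), n_k=np.array(n_k), beta=beta,
                        pressure_term=any_npt)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _mbar_log_denominator(u, f, n_k):
    # log sum_k N_k exp(f_k - u_nk), per sample
    with np.errstate(divide="ignore"):
        log_nk = np.log(n_k.astype(float))
    return logsumexp(f[None, :] - u + log_nk[None, :], axis=1)


def _mbar_weights(u, f, n_k):
    """Normalized MBAR weights W (N, K): W_nk = exp(f_k - u_nk) / D_n."""
    log_d = _mbar_log_denominator(u, f, n_k)
    return np.exp(f[None, :] - u - log_d[:, None])


def _self_consistent_update(u, f, n_k):
    log_d = _mbar_log_denominator(u, f, n_k)
    f_new = -logsumexp(-u - log_d[:, None], axis=0)
    return f_new - f_new[0]


def mbar_solve(matrix: EnergyMatrix, tol: float = 1e-10,
               max_iter: int = 100000) -> np.ndarray:
    """Per-state reduced free energies f_k (f_1 anchored to 0).

    Self-consistent iteration with log-sum-exp stabilization, switching to
    Newton polishing once the iterate is close; raises
    :class:`ConvergenceError` carrying the overlap matrix on failure.
    """
    u = matrix.u
    n_k = matrix.n_k
    if np.any(n_k <= 0):
        raise ValidationError("every state must contribute samples")
    k_states = matrix.n_states
    f = np.zeros(k_states)
    iteration = 0
    # warm-up: plain self-consistent iteration
    while iteration < max_iter:
        f_new = _self_consistent_update(u, f, n_k)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        iteration += 1
        if delta < 1e-2 or iteration >= 200:
            break
    # Newton polish on the convex objective (gradient g, Hessian h)
    for _ in range(100):
        w = _mbar_weights(u, f, n_k)
        wn = w * n_k[None, :]
        g = wn.sum(axis=0) - n_k
        h = np.diag(wn.sum(axis=0)) - wn.T @ wn
        try:
            step = np.linalg.solve(h[1:, 1:] + 1e-12 * np.eye(k_states - 1),
                                   -g[1:])
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        if np.max(np.abs(step)) > 2.0:  # too far for Newton; fall back
            break
        f = f + np.concatenate([[0.0], step])
        if np.max(np.abs(step)) < 0.1 * tol:
            break
    # final self-consistent sweep(s) to certify the tolerance
    while iteration < max_iter:
        f_new = _self_consistent_update(u, f, n_k)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        iteration += 1
        if delta < tol:
            return f - f[0]
    raise ConvergenceError(
        f"MBAR did not converge within {max_iter} iterations "
        f"(last max |df| = {delta:.3e})",
        diagnostics=overlap_matrix(matrix, f=f, warn=False))


def overlap_matrix(matrix: EnergyMatrix, f: np.ndarray | None = None,
                   warn: bool = True) -> np.ndarray:
    """MBAR overlap matrix O_ij = sum_n W_ni W_nj N_j (row-stochastic).

    Low overlap between adjacent states signals an unreliable free energy
    difference; a warning is emitted below ``OVERLAP_WARN_THRESHOLD``.
    """
    if f is None:
        f = mbar_solve(matrix)
    w = _mbar_weights(matrix.u, f, matrix.n_k)
    o = w.T @ (w * matrix.n_k[None, :])
    if warn:
        adjacent = np.diag(o, k=1)
        bad = np.nonzero(adjacent < OVERLAP_WARN_THRESHOLD)[0]
        for i in bad:
            warnings.warn(
                f"overlap between adjacent states {i + 1} and {i + 2} is "
                f"{adjacent[i]:.4f} (< {OVERLAP_WARN_THRESHOLD})",
                OverlapWarning, stacklevel=2)
    return o


def mbar_covariance(matrix: EnergyMatrix, f: np.ndarray | None = None) -> np.ndarray:
    """Asymptotic covariance of the reduced free energies (diagnostic).

    Computed from the SVD of the weight matrix; the covariance of
    f_j - f_i is Theta_ii + Theta_jj - 2 Theta_ij.
    """
    if f is None:
        f = mbar_solve(matrix)
    w = _mbar_weights(matrix.u, f, matrix.n_k)
    u_svd, s, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    inner = (np.eye(len(s))
             - (s[:, None] * vt) @ (matrix.n_k[:, None] * v) * s[None, :])
    # the exact zero mode (overall shift of f) must be projected out
    theta = v @ (s[:, None] * np.linalg.pinv(inner, rcond=1e-10)
                 * s[None, :]) @ vt
    return theta


def mbar_delta_f(matrix: EnergyMatrix) -> tuple[float, float]:
    """(f_K - f_1, asymptotic SE) in reduced units."""
    f = mbar_solve(matrix)
    theta = mbar_covariance(matrix, f=f)
    var = theta[0, 0] + theta[-1, -1] - 2.0 * theta[0, -1]
    return float(f[-1] - f[0]), float(math.sqrt(max(var, 0.0)))


def free_energy_from_matrix(matrix: EnergyMatrix, leg: str = "",
                            method: str = "MBAR") -> FreeEnergyResult:
    """Annihilation free energy (physical -> decoupled) in kcal/mol."""
    df, se = mbar_delta_f(matrix)
    return FreeEnergyResult(delta_g=df / matrix.beta,
                            stderr=se / matrix.beta, leg=leg, method=method)


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------

def ti_estimate(profile: TIProfile, leg: str = "") -> FreeEnergyResult:
    """Closed-form integral of the cubic spline through <dU/dlambda>.

    Uses not-a-knot boundary conditions, which reproduce polynomials up to
    cubic order exactly; each segment's cubic is integrated analytically.
    The standard error propagates the per-lambda SEs through the (linear)
    spline quadrature weights.
    """
    lam = profile.lambdas
    if lam.size < 4:
        raise ValidationError("TI needs at least 4 lambda points")
    spline = CubicSpline(lam, profile.dudl_means)  # not-a-knot
    dg = float(spline.integrate(0.0, 1.0))
    se = 0.0
    if profile.dudl_stderr is not None:
        # quadrature weights: integral is linear in the ordinates
        weights = np.array([
            CubicSpline(lam, np.eye(lam.size)[i]).integrate(0.0, 1.0)
            for i in range(lam.size)])
        se = float(np.sqrt(np.sum((weights * profile.dudl_stderr) ** 2)))
    return FreeEnergyResult(delta_g=dg, stderr=se, leg=leg, method="TI")


# ---------------------------------------------------------------------------
# Combination & repeats
# ---------------------------------------------------------------------------

def aggregate_repeats(values) -> tuple[float, float]:
    """Sample mean and sample standard deviation (ddof = 1) over repeats."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 repeats")
    return float(values.mean()), float(values.std(ddof=1))


def combine_asfe(vac: FreeEnergyResult, aq: FreeEnergyResult,
                 lrc: float = 0.0, lrc_stderr: float = 0.0) -> ASFEResult:
    """ASFE = dG_vac - dG_aq + dG_LRC, both legs in annihilation direction
    (physical -> decoupled); uncertainties add in quadrature."""
    if vac.solute and aq.solute and vac.solute != aq.solute:
        raise ValidationError(
            f"legs belong to different solutes: {vac.solute!r} vs {aq.solute!r}")
    value = vac.delta_g - aq.delta_g + lrc
    stderr = math.sqrt(vac.stderr**2 + aq.stderr**2 + lrc_stderr**2)
    return ASFEResult(value=value, stderr=stderr, vacuum=vac, aqueous=aq,
                      lrc=lrc, lrc_stderr=lrc_stderr)


# ---------------------------------------------------------------------------
# Energy-matrix archive (delimited text)
# ---------------------------------------------------------------------------

def save_energy_matrix(matrix: EnergyMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# saisolv-energy-matrix/1\n")
        fh.write(f"# beta={matrix.beta!r} pressure_term={int(matrix.pressure_term)}\n")
        fh.write("# N_k=" + ",".join(str(int(n)) for n in matrix.n_k) + "\n")
        np.savetxt(fh, matrix.u, delimiter="\t")


def load_energy_matrix(path) -> EnergyMatrix:
    beta = None
    n_k = None
    pressure_term = False
    with open(path) as fh:
        header = [fh.readline() for _ in range(3)]
    for line in header:
        if line.startswith("# beta="):
            toks = dict(t.split("=") for t in line[2:].split())
            beta = float(toks["beta"])
            pressure_term = bool(int(toks.get("pressure_term", "0")))
        elif line.startswith("# N_k="):
            n_k = np.array([int(t) for t in line.split("=", 1)[1].split(",")])
    u = np.loadtxt(path, delimiter="\t", ndmin=2)
    return EnergyMatrix(u=u, n_k=n_k, beta=beta, pressure_term=pressure_term)
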