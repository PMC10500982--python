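"""End-to-end ASFE pipelines and run configuration.

The production pipeline mirrors the serial-atom-insertion workflow: build
the annihilation schedule, sample every intermediate state independently in
both legs (aqueous and vacuum), re-evaluate all retained frames under all
states, solve MBAR per leg, repeat with independent seeds for the error
bar, add the LJ long-range correction, and combine

    ASFE = dG_vac - dG_aq + dG_LRC.

A second, continuous soft-core lambda path with spline-integrated
thermodynamic integration is provided as an independent reference route to
the same endpoints.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .chem_system import SolvatedSystem
from .engine import (NonbondedSettings, SoftcorePotential, mc_sample,
                     mc_sample_potential)
from .errors import OverlapWarning, ValidationError
from .estimators import (ASFEResult, FreeEnergyResult, TIProfile,
                         aggregate_repeats, combine_asfe,
                         discard_equilibration, mbar_solve, overlap_matrix,
                         reduced_potential_matrix, ti_estimate)
from .fixtures import vacuum_system
from .lrc import asfe_lrc_analytic
from .schedule import Schedule, ScheduleConfig, build_schedule


@dataclass(frozen=True)
class SamplingConfig:
    """Per-state Monte Carlo budget."""

    n_sweeps: int = 600
    save_every: int = 3
    equilibration_fraction: float = 0.25
    repeats: int = 4
    base_seed: int = 2026

    def __post_init__(self):
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ValidationError("equilibration fraction must be in [0, 1)")


@dataclass(frozen=True)
class RunConfig:
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    nonbonded: NonbondedSettings = field(default_factory=NonbondedSettings)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    workspace: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        return cls(
            schedule=ScheduleConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in (doc.get("schedule") or {}).items()}),
            nonbonded=NonbondedSettings(**(doc.get("nonbonded") or {})),
            sampling=SamplingConfig(**(doc.get("sampling") or {})),
            workspace=doc.get("workspace"),
        )


def _leg_seed(base_seed: int, repeat: int, leg_id: int, state_index: int) -> int:
    """Repeat r uses the base seed + r; states and legs get disjoint
    streams below 2^31."""
    return ((base_seed + repeat) * 4096 + leg_id * 512 + state_index) % (2**31)


def _sample_leg(system: SolvatedSystem, schedule: Schedule,
                config: RunConfig, repeat: int, leg_id: int):
    trajs = []
    for state in schedule.states:
        seed = _leg_seed(config.sampling.base_seed, repeat, leg_id,
                         state.index)
        trajs.append(mc_sample(system, state, config.nonbonded,
                               n_sweeps=config.sampling.n_sweeps, seed=seed,
                               save_every=config.sampling.save_every))
    return trajs


def _leg_delta_g(system, schedule, trajs, config) -> tuple[float, np.ndarray]:
    kept = [discard_equilibration(t, config.sampling.equilibration_fraction)
            for t in trajs]
    matrix = reduced_potential_matrix(kept, schedule, system, config.nonbonded)
    f = mbar_solve(matrix)
    overlap = overlap_matrix(matrix, f=f)
    return float((f[-1] - f[0]) / matrix.beta), overlap


def run_asfe(config: RunConfig, system: SolvatedSystem) -> dict:
    """Full SAI/MBAR pipeline on one solvated system.

    Returns a machine-readable report: per-leg free energies with
    repeat-based errors, the LRC term, the combined ASFE, the schedule
    table, all seeds, and any overlap warnings.
    """
    if system.solute is None:
        raise ValidationError("system has no solute")
    schedule = build_schedule(system.solute, config.schedule)
    vac = vacuum_system(system.solute, coords=system.solute_coords.copy())

    captured: list[str] = []
    aq_vals, vac_vals = [], []
    for repeat in range(config.sampling.repeats):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", OverlapWarning)
            aq_trajs = _sample_leg(system, schedule, config, repeat, leg_id=0)
            dg_aq, _ = _leg_delta_g(system, schedule, aq_trajs, config)
            vac_trajs = _sample_leg(vac, schedule, config, repeat, leg_id=1)
            dg_vac, _ = _leg_delta_g(vac, schedule, vac_trajs, config)
        for w in caught:
            if issubclass(w.category, OverlapWarning):
                captured.append(f"repeat {repeat}: {w.message}")
        aq_vals.append(dg_aq)
        vac_vals.append(dg_vac)

    if config.sampling.repeats >= 2:
        aq_mean, aq_sd = aggregate_repeats(aq_vals)
        vac_mean, vac_sd = aggregate_repeats(vac_vals)
    else:
        aq_mean, aq_sd = aq_vals[0], 0.0
        vac_mean, vac_sd = vac_vals[0], 0.0
    aq_result = FreeEnergyResult(delta_g=aq_mean, stderr=aq_sd,
                                 per_repeat=tuple(aq_vals), leg="aqueous",
                                 method="MBAR", solute=system.solute.name)
    vac_result = FreeEnergyResult(delta_g=vac_mean, stderr=vac_sd,
                                  per_repeat=tuple(vac_vals), leg="vacuum",
                                  method="MBAR", solute=system.solute.name)
    lrc = asfe_lrc_analytic(system, config.nonbonded)
    asfe = combine_asfe(vac_result, aq_result, lrc=lrc.value,
                        lrc_stderr=lrc.stderr)
    return asfe_report(config, system, schedule, asfe, captured)


def asfe_report(config: RunConfig, system: SolvatedSystem,
                schedule: Schedule, asfe: ASFEResult,
                overlap_warnings: list[str]) -> dict:
    return {
        "solute": system.solute.name,
        "n_waters": system.n_waters,
        "box_edge": float(system.box_edge),
        "n_states": schedule.n_states,
        "schedule_table": schedule.table(),
        "config": yaml.safe_load(config.to_yaml()),
        "legs": {
            "vacuum": {"delta_g": asfe.vacuum.delta_g,
                       "stderr": asfe.vacuum.stderr,
                       "per_repeat": list(asfe.vacuum.per_repeat)},
            "aqueous": {"delta_g": asfe.aqueous.delta_g,
                        "stderr": asfe.aqueous.stderr,
                        "per_repeat": list(asfe.aqueous.per_repeat)},
        },
        "lrc": {"value": asfe.lrc, "stderr": asfe.lrc_stderr},
        "asfe": {"value": asfe.value, "stderr": asfe.stderr},
        "overlap_warnings": overlap_warnings,
    }


def report_to_yaml(report: dict) -> str:
    buf = io.StringIO()
    yaml.safe_dump(report, buf, sort_keys=False)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Reference route: soft-core lambda path + spline TI
# ---------------------------------------------------------------------------

def run_softcore_ti(system: SolvatedSystem, settings: NonbondedSettings,
                    n_lambdas: int = 21, n_sweeps: int = 600,
                    save_every: int = 3, repeats: int = 4,
                    base_seed: int = 2026, alpha: float = 5.0,
                    burn_in: float = 0.10) -> FreeEnergyResult:
    """Annihilation free energy of one leg over the continuous path.

    Samples (by default 21) equidistant lambda states of the soft-core
    Hamiltonian, discards the first 10% of each trajectory as burn-in,
    splines <dU/dlambda> over lambda and integrates analytically.  The
    returned dG is in the annihilation direction (physical at lambda = 1
    to decoupled at lambda = 0), i.e. the negated integral, so it is
    directly comparable with the SAI/MBAR result.
    """
    lambdas = np.linspace(0.0, 1.0, n_lambdas)
    per_repeat = []
    for repeat in range(repeats):
        means = np.zeros(n_lambdas)
        for i, lam in enumerate(lambdas):
            pot = SoftcorePotential(system, lam, settings, alpha=alpha)
            seed = _leg_seed(base_seed, repeat, leg_id=2, state_index=i)
            traj = mc_sample_potential(
                pot, pot.table.positions, system.box_edge, settings,
                n_sweeps=n_sweeps, seed=seed, save_every=save_every,
                state_index=i + 1)
            kept = discard_equilibration(traj, burn_in)
            vals = [pot.dudl(kept.frames[f], kept.box_edges[f]
                             if system.periodic else None)
                    for f in range(kept.n_frames)]
            means[i] = float(np.mean(vals))
        profile = TIProfile(lambdas=lambdas, dudl_means=means)
        est = ti_estimate(profile)
        per_repeat.append(-est.delta_g)  # annihilation direction
    if repeats >= 2:
        mean, sd = aggregate_repeats(per_repeat)
    else:
        mean, sd = per_repeat[0], 0.0
    return FreeEnergyResult(
        delta_g=mean, stderr=sd, per_repeat=tuple(per_repeat),
        leg="aqueous" if system.periodic else "vacuum", method="TI",
        solute=system.solute.name if system.solute else "")
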