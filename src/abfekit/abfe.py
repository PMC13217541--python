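"""Single-trajectory ΔG_bind assembly, snapshot schedules, replica statistics.

ΔG_bind is decomposed per snapshot as

    ΔG = ΔE_internal + ΔE_elec + ΔE_vdW + ΔG_polar + ΔG_nonpolar

with the configurational-entropy term deliberately excluded (end-point
ranking use).  Under the single-trajectory protocol (STP) the receptor and
ligand coordinates are slices of the complex frame, so ΔE_internal cancels
exactly and is reported as 0.  Two snapshot schedules mirror the two
production workflows: binding-affinity prediction averages equally spaced
snapshots over long trajectories (250 ns sampled every 200 ps → 1251
snapshots per replica), while pose rescoring evaluates only the final frame
of each short replica.  Replica means are combined into mean ± SEM, and a
one-sided Student-t test flags estimates that are negative at the 99%
significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gbsa import GBConfig, solvation_free_energy
from .mmenergy import EnergyBreakdown, interaction_energy
from .structio import MolecularSystem, ParameterSet, Trajectory

__all__ = [
    "SnapshotSchedule",
    "AbfeEstimate",
    "snapshot_schedule",
    "frame_delta_g",
    "mtp_delta_g",
    "trajectory_estimate",
    "replica_aggregate",
    "significance_filter",
]


class ScheduleError(ValueError):
    """Snapshot schedule incompatible with the trajectory layout."""


@dataclass
class SnapshotSchedule:
    mode: str  # "equally-spaced" | "final-only"
    spacing_ps: float
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ScheduleError("schedule must select at least one frame")
        if np.any(np.diff(self.indices) <= 0):
            raise ScheduleError("schedule indices must be strictly increasing")

    @property
    def n_snapshots(self) -> int:
        return self.indices.size


def snapshot_schedule(n_frames: int, frame_spacing_ps: float, mode: str,
                      target_spacing_ps: float | None = None) -> SnapshotSchedule:
    """Build the frame-selection schedule for one replica.

    equally-spaced: indices 0, s, 2s, … where s = target/frame spacing,
    which must divide evenly; includes frame 0 and — when the trajectory
    length is a multiple of the stride — the final frame.  A 250 ns
    trajectory sampled every 200 ps selected at 200 ps yields 1251 indices.
    final-only: the single last frame.
    """
    if n_frames < 1:
        raise ScheduleError("trajectory must contain at least one frame")
    if mode == "final-only":
        return SnapshotSchedule(mode, frame_spacing_ps, np.array([n_frames - 1]))
    if mode != "equally-spaced":
        raise ScheduleError(f"unknown schedule mode '{mode}'")
    if target_spacing_ps is None:
        target_spacing_ps = frame_spacing_ps
    stride = target_spacing_ps / frame_spacing_ps
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ScheduleError(
            f"target spacing {target_spacing_ps} ps is not an integer multiple "
            f"of frame spacing {frame_spacing_ps} ps")
    return SnapshotSchedule(mode, target_spacing_ps,
                            np.arange(0, n_frames, int(round(stride))))


@dataclass
class AbfeEstimate:
    """Replica-aggregated ABFE: mean ± SEM with mean component breakdown."""

    per_replica_means: list[float]
    mean: float
    sem: float | None  # None for a single replica
    n_replicas: int
    components: EnergyBreakdown | None = None
    significant_negative_99: bool | None = None

    def as_dict(self) -> dict:
        from .structio import KCAL_TO_KJ
        d = {
            "per_replica_means_kcal_mol": list(map(float, self.per_replica_means)),
            "mean_kcal_mol": float(self.mean),
            "mean_kj_mol": float(self.mean) * KCAL_TO_KJ,
            "sem_kcal_mol": None if self.sem is None else float(self.sem),
            "n_replicas": self.n_replicas,
            "significant_negative_99": self.significant_negative_99,
        }
        if self.components is not None:
            d["components_kcal_mol"] = self.components.as_dict()
        return d


def frame_delta_g(system: MolecularSystem, params: ParameterSet,
                  frame: np.ndarray, config: GBConfig | None = None,
                  protocol: str = "STP") -> EnergyBreakdown:
    """Per-snapshot ΔG_bind under the single-trajectory protocol.

    Receptor and ligand species are coordinate slices of the complex frame,
    so the bonded (internal) terms cancel and only cross nonbonded terms and
    solvation differences survive:

    ΔG = ΔE_elec(cross) + ΔE_vdW(cross)
         + [G_p(RL) − G_p(R) − G_p(L)] + [G_np(RL) − G_np(R) − G_np(L)]
    """
    if protocol != "STP":
        raise ValueError("only the single-trajectory protocol is implemented")
    config = config or GBConfig()
    if system.receptor_selection.size == 0 or system.ligand_selection.size == 0:
        raise ValueError("both receptor and ligand selections must be set")
    e_elec, e_vdw = interaction_energy(system, params, frame, config.eps_in)
    complex_sel = np.concatenate([system.receptor_selection,
                                  system.ligand_selection])
    gp_rl, gnp_rl = solvation_free_energy(system, params, frame, complex_sel, config)
    gp_r, gnp_r = solvation_free_energy(system, params, frame,
                                        system.receptor_selection, config)
    gp_l, gnp_l = solvation_free_energy(system, params, frame,
                                        system.ligand_selection, config)
    return EnergyBreakdown(
        e_internal=0.0,
        e_elec=e_elec,
        e_vdw=e_vdw,
        g_polar=gp_rl - gp_r - gp_l,
        g_nonpolar=gnp_rl - gnp_r - gnp_l,
    )


def mtp_delta_g(mean_g_complex: float, mean_g_receptor: float,
                mean_g_ligand: float) -> float:
    """Multiple-trajectory combination ⟨ΔG_bind⟩ = ⟨G_RL⟩ − ⟨G_R⟩ − ⟨G_L⟩."""
    values = (mean_g_complex, mean_g_receptor, mean_g_ligand)
    if not all(np.isfinite(values)):
        raise ValueError("species means must be finite")
    return float(mean_g_complex - mean_g_receptor - mean_g_ligand)


def trajectory_estimate(system: MolecularSystem, params: ParameterSet,
                        trajectory: Trajectory, schedule: SnapshotSchedule,
                        config: GBConfig | None = None
                        ) -> tuple[float, EnergyBreakdown]:
    """Unweighted mean ΔG (and mean components) over the scheduled frames.

    No Boltzmann reweighting between the simulation and post-processing
    Hamiltonians is applied.
    """
    trajectory.check_compatible(system)
    if schedule.indices[-1] >= trajectory.n_frames:
        raise ScheduleError("schedule index beyond trajectory length")
    sums = np.zeros(5)
    for idx in schedule.indices:
        try:
            bd = frame_delta_g(system, params, trajectory.frames[idx], config)
        except Exception as exc:
            raise RuntimeError(f"energy evaluation failed at frame {idx}: {exc}"
                               ) from exc
        sums += [bd.e_internal, bd.e_elec, bd.e_vdw, bd.g_polar, bd.g_nonpolar]
    sums /= schedule.n_snapshots
    mean_bd = EnergyBreakdown(*sums)
    return mean_bd.total, mean_bd


def replica_aggregate(per_replica_means: list[float],
                      components: EnergyBreakdown | None = None) -> AbfeEstimate:
    """Mean and standard error of the mean over replica estimates.

    SEM uses the n−1 sample standard deviation; with a single replica it is
    reported as unavailable (None).
    """
    values = np.asarray(per_replica_means, dtype=float)
    if values.size == 0:
        raise ValueError("at least one replica mean is required")
    mean = float(np.mean(values))
    sem = (float(np.std(values, ddof=1) / np.sqrt(values.size))
           if values.size >= 2 else None)
    return AbfeEstimate(per_replica_means=list(map(float, values)),
                        mean=mean, sem=sem, n_replicas=values.size,
                        components=components)


def significance_filter(estimate: AbfeEstimate, level: float = 0.99,
                        use_t: bool = True) -> bool:
    """True iff the estimate is negative at the given one-sided level.

    Student-t by default: mean + t_{level, n−1}·SEM < 0; a normal-quantile
    variant is available since the underlying test is a protocol choice.
    """
    if estimate.sem is None:
        raise ValueError("significance filter requires an available SEM")
    quantile = (stats.t.ppf(level, estimate.n_replicas - 1) if use_t
                else stats.norm.ppf(level))
    return bool(estimate.mean + quantile * estimate.sem < 0.0)
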