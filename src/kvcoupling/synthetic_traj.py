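"""Synthetic trajectories with known ground-truth statistical structure.

Stand-in for membrane MD runs of a homotetrameric channel: frames are a
fixed reference geometry plus zero-mean Gaussian residue displacements whose
inter-residue correlations are set exactly by construction, so every
downstream statistic (RMSF, DCCM, delta-DCCM, contact persistence) can be
checked against a known target.

Correlation blocks use a shared latent factor per block,

    x_i(t) = sqrt(|rho|) * s_i * z(t) + sqrt(1 - |rho|) * eps_i(t)

per Cartesian axis, with loading sign ``s_i`` = +1 on the first segment and
``sign(rho)`` on the second.  Cross-segment pairs then have correlation
exactly ``rho`` (pairs within one segment have ``|rho|``), and the implied
covariance is positive semi-definite by construction.  An optional AR(1)
filter (phi) adds temporal persistence without changing the stationary
correlation targets; an optional rigid-motion overlay adds per-frame global
rotation+translation that superposition must remove.

Defaults mirror the emulated study design: 30 ns runs sampled every 0.25 ns
(120 frames), five replicates with the ligand and three without.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .trajectory_io import (
    SegmentDefinition,
    TrajectoryEnsemble,
    TrajectoryError,
    selection_mask,
)

__all__ = [
    "SegmentJitter",
    "CorrelationBlock",
    "RigidMotionSchedule",
    "SyntheticTrajectoryConfig",
    "generate_reference_geometry",
    "generate_correlated_trajectory",
    "generate_condition_ensembles",
    "DEFAULT_N_FRAMES",
    "DEFAULT_DT_NS",
    "N_REPLICATES_WITH",
    "N_REPLICATES_WITHOUT",
]

DEFAULT_N_FRAMES = 120  # 30 ns sampled every 0.25 ns
DEFAULT_DT_NS = 0.25
N_REPLICATES_WITH = 5  # replicate counts of the emulated two-condition design
N_REPLICATES_WITHOUT = 3

LIGAND_CHAIN = "X"
LIGAND_RESNUM = 900
LIGAND_RESNAME = "LIG"
_CONTACT_OFFSET = 1.2  # Å from the target Cα when a contact is planted
_FAR_BASE = 1.0e3  # Å; parking position for out-of-contact ligand atoms


@dataclass
class SegmentJitter:
    """Per-segment isotropic displacement s.d. (Å per axis)."""

    segment: SegmentDefinition
    sigma: float


@dataclass
class CorrelationBlock:
    """Target displacement correlation between two residue segments."""

    segment_a: SegmentDefinition
    segment_b: SegmentDefinition
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise TrajectoryError(f"target correlation {self.rho} outside [-1, 1]")


@dataclass
class RigidMotionSchedule:
    """Per-frame random global rotation+translation overlay."""

    max_rotation_deg: float = 30.0
    max_translation: float = 10.0


@dataclass
class SyntheticTrajectoryConfig:
    n_frames: int = DEFAULT_N_FRAMES
    dt: float = DEFAULT_DT_NS
    seed: int = 0
    base_sigma: float = 0.5
    segment_sigmas: list[SegmentJitter] = field(default_factory=list)
    correlation_blocks: list[CorrelationBlock] = field(default_factory=list)
    temporal_ar1: float = 0.0
    rigid_motion: RigidMotionSchedule | None = None
    # planted per-residue contact schedules: {(chain, resnum): bool array}
    ligand_contact_schedule: Mapping[tuple[str, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise TrajectoryError("n_frames must be >= 1")
        if self.dt <= 0:
            raise TrajectoryError("dt must be positive")
        if not 0.0 <= self.temporal_ar1 < 1.0:
            raise TrajectoryError("AR(1) coefficient must lie in [0, 1)")
        if self.base_sigma < 0 or any(s.sigma < 0 for s in self.segment_sigmas):
            raise TrajectoryError("jitter sigma must be non-negative")

    def validate_blocks(self, traj: TrajectoryEnsemble) -> list[tuple[np.ndarray, np.ndarray, float]]:
        """Resolve blocks to atom indices and verify PSD-safety (disjointness)."""
        claimed: set[int] = set()
        resolved = []
        for block in self.correlation_blocks:
            ia = np.flatnonzero(selection_mask(traj, block.segment_a, None))
            ib = np.flatnonzero(selection_mask(traj, block.segment_b, None))
            if ia.size == 0 or ib.size == 0:
                raise TrajectoryError(
                    f"correlation block ({block.segment_a.name}, "
                    f"{block.segment_b.name}) resolves to no atoms"
                )
            members = set(ia) | set(ib)
            if claimed & members:
                raise TrajectoryError(
                    "correlation blocks overlap in residues; the implied "
                    "covariance is not guaranteed positive semi-definite"
                )
            claimed |= members
            resolved.append((ia, ib, block.rho))
        return resolved


def generate_reference_geometry(
    n_subunits: int = 4,
    residues_per_subunit: int = 20,
    first_residue: int = 1,
    ring_radius: float = 18.0,
) -> TrajectoryEnsemble:
    """Single-frame Cα-only geometry: one ideal helix per subunit.

    Subunits (chains A, B, …) are ideal α-helical traces (1.5 Å rise,
    100° twist, 2.3 Å radius) arranged on a ring — a deterministic,
    non-degenerate toy stand-in for a four-subunit channel.
    """
    if n_subunits < 1:
        raise TrajectoryError("need at least one subunit")
    if residues_per_subunit < 3:
        raise TrajectoryError("need >= 3 residues per subunit for superposition")
    rise, twist, helix_r = 1.5, np.deg2rad(100.0), 2.3
    records = []
    coords = []
    for c in range(n_subunits):
        chain = chr(ord("A") + c)
        angle = 2 * np.pi * c / n_subunits
        cx, cy = ring_radius * np.cos(angle), ring_radius * np.sin(angle)
        for i in range(residues_per_subunit):
            records.append(
                {
                    "chain_id": chain,
                    "residue_number": first_residue + i,
                    "residue_name": "ALA",
                    "atom_name": "CA",
                    "element": "C",
                    "hetero": False,
                }
            )
            coords.append(
                [
                    cx + helix_r * np.cos(i * twist),
                    cy + helix_r * np.sin(i * twist),
                    i * rise,
                ]
            )
    return TrajectoryEnsemble(
        atoms=pd.DataFrame(records),
        coords=np.asarray(coords, dtype=float)[None, :, :],
        timestamps=np.array([0.0]),
    )


def _ar1_filter(x: np.ndarray, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) along axis 0 from i.i.d. N(0,1) input."""
    if phi == 0.0:
        return x
    out = np.empty_like(x)
    out[0] = x[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, x.shape[0]):
        out[t] = phi * out[t - 1] + scale * x[t]
    return out


def generate_correlated_trajectory(
    ref: TrajectoryEnsemble,
    config: SyntheticTrajectoryConfig,
    condition: str = "",
    replicate_id: int = 0,
) -> TrajectoryEnsemble:
    """Frames = reference + correlated Gaussian displacements.

    Fully reproducible from ``config.seed``; validates the block structure
    before sampling.  With all sigmas zero every frame equals the reference.
    """
    blocks = config.validate_blocks(ref)
    rng = np.random.default_rng(config.seed)
    n_frames, n_atoms = config.n_frames, ref.n_atoms
    phi = config.temporal_ar1

    sigma = np.full(n_atoms, config.base_sigma)
    for sj in config.segment_sigmas:
        idx = np.flatnonzero(selection_mask(ref, sj.segment, None))
        if idx.size == 0:
            raise TrajectoryError(f"jitter segment {sj.segment.name!r} matches no atoms")
        sigma[idx] = sj.sigma

    eps = _ar1_filter(rng.standard_normal((n_frames, n_atoms, 3)), phi)
    x = eps.copy()
    for ia, ib, rho in blocks:
        if rho == 0.0:
            continue
        z = _ar1_filter(rng.standard_normal((n_frames, 3)), phi)
        load = np.sqrt(abs(rho))
        resid = np.sqrt(1.0 - abs(rho))
        x[:, ia, :] = load * z[:, None, :] + resid * eps[:, ia, :]
        sign = 1.0 if rho > 0 else -1.0
        x[:, ib, :] = sign * load * z[:, None, :] + resid * eps[:, ib, :]

    coords = ref.coords[0][None, :, :] + x * sigma[None, :, None]

    if config.rigid_motion is not None:
        sched = config.rigid_motion
        for k in range(n_frames):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(0.0, sched.max_rotation_deg))
            rot = Rotation.from_rotvec(angle * axis).as_matrix()
            shift = rng.uniform(-sched.max_translation, sched.max_translation, 3)
            coords[k] = coords[k] @ rot.T + shift

    atoms = ref.atoms.copy()
    if config.ligand_contact_schedule:
        coords, atoms = _plant_ligand(
            coords, atoms, config.ligand_contact_schedule, n_frames
        )

    timestamps = np.arange(1, n_frames + 1) * config.dt
    return TrajectoryEnsemble(
        atoms=atoms,
        coords=coords,
        timestamps=timestamps,
        condition=condition,
        replicate_id=replicate_id,
    )


def _plant_ligand(
    coords: np.ndarray,
    atoms: pd.DataFrame,
    schedule: Mapping[tuple[str, int], np.ndarray],
    n_frames: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Append one ligand pseudo-atom per scheduled residue.

    In frames where the residue's schedule is True the atom sits a fixed
    small offset from that residue's Cα (inside any sane contact cutoff);
    otherwise it is parked far outside the structure.  Schedules should
    target spatially separated residues so planted contacts stay independent.
    """
    new_rows = []
    lig_coords = []
    for j, ((chain, resnum), states) in enumerate(sorted(schedule.items())):
        states = np.asarray(states, dtype=bool)
        if states.shape != (n_frames,):
            raise TrajectoryError(
                f"contact schedule for {chain}:{resnum} must have one state "
                f"per frame ({n_frames})"
            )
        mask = (
            (atoms["chain_id"] == chain) & (atoms["residue_number"] == resnum)
        ).to_numpy()
        if not mask.any():
            raise TrajectoryError(f"scheduled residue {chain}:{resnum} not in geometry")
        target = np.flatnonzero(mask)[0]
        pos = np.where(
            states[:, None],
            coords[:, target, :] + np.array([_CONTACT_OFFSET, 0.0, 0.0]),
            np.array([_FAR_BASE + 50.0 * j, 0.0, 0.0]),
        )
        lig_coords.append(pos)
        new_rows.append(
            {
                "chain_id": LIGAND_CHAIN,
                "residue_number": LIGAND_RESNUM,
                "residue_name": LIGAND_RESNAME,
                "atom_name": f"C{j + 1}",
                "element": "C",
                "hetero": True,
            }
        )
    coords = np.concatenate([coords, np.stack(lig_coords, axis=1)], axis=1)
    atoms = pd.concat([atoms, pd.DataFrame(new_rows)], ignore_index=True)
    return coords, atoms


def generate_condition_ensembles(
    ref: TrajectoryEnsemble,
    config_with: SyntheticTrajectoryConfig,
    config_without: SyntheticTrajectoryConfig,
    n_with: int = N_REPLICATES_WITH,
    n_without: int = N_REPLICATES_WITHOUT,
    base_seed: int = 0,
    condition_with: str = "with_ligand",
    condition_without: str = "without_ligand",
) -> tuple[list[TrajectoryEnsemble], list[TrajectoryEnsemble]]:
    """Replicate ensembles for a two-condition design (default 5 vs 3).

    Replicate seeds are ``base_seed + i`` for the with-condition and
    ``base_seed + n_with + j`` for the without-condition, so reruns with the
    same base seed are bit-identical and no two replicates share a seed.
    """
    from dataclasses import replace as dc_replace

    if n_with < 1 or n_without < 1:
        raise TrajectoryError("need at least one replicate per condition")
    with_list = [
        generate_correlated_trajectory(
            ref,
            dc_replace(config_with, seed=base_seed + i),
            condition=condition_with,
            replicate_id=i,
        )
        for i in range(n_with)
    ]
    without_list = [
        generate_correlated_trajectory(
            ref,
            dc_replace(config_without, seed=base_seed + n_with + j),
            condition=condition_without,
            replicate_id=j,
        )
        for j in range(n_without)
    ]
    return with_list, without_list
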