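"""Ligand–residue contact detection and persistence fractions.

A frame is "in contact" when the chosen distance criterion between two atom
groups falls at or below a cutoff; persistence is the percentage of frames
in contact over the trajectory.  Default criteria follow common literature
conventions for hydrophobic (minimum heavy-atom distance <= 4.0 Å) and
aromatic (ring-centroid distance <= 5.5 Å, no angle term) interactions;
hydrogens are excluded by element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory_io import (
    SegmentDefinition,
    TrajectoryEnsemble,
    TrajectoryError,
)

__all__ = [
    "AtomGroup",
    "ContactSeries",
    "HYDROPHOBIC_CUTOFF",
    "AROMATIC_CENTROID_CUTOFF",
    "min_distance",
    "contact_series",
    "persistence_table",
    "residue_atom_group",
]

HYDROPHOBIC_CUTOFF = 4.0  # Å, minimum heavy-atom distance
AROMATIC_CENTROID_CUTOFF = 5.5  # Å, ring-centroid distance


@dataclass
class AtomGroup:
    """Named set of atoms given as (chain_id, residue_number, atom_name)."""

    name: str
    atoms: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise TrajectoryError(f"atom group {self.name!r} is empty")

    def resolve(self, traj: TrajectoryEnsemble, heavy_only: bool = True) -> np.ndarray:
        """Atom row indices of this group in the trajectory."""
        idx = []
        for chain, res, name in self.atoms:
            i = traj.atom_index(chain, res, name)
            if heavy_only and traj.atoms["element"].iloc[i].upper() == "H":
                continue
            idx.append(i)
        if not idx:
            raise TrajectoryError(
                f"atom group {self.name!r} resolves to no heavy atoms"
            )
        return np.asarray(idx, dtype=int)


@dataclass
class ContactSeries:
    pair: tuple[str, str]
    per_frame_state: np.ndarray
    cutoff: float
    criterion: str

    def __post_init__(self) -> None:
        self.per_frame_state = np.asarray(self.per_frame_state, dtype=bool)

    @property
    def persistence(self) -> float:
        """Percentage of frames in contact, in [0, 100]."""
        return 100.0 * float(self.per_frame_state.mean())


def residue_atom_group(traj: TrajectoryEnsemble, chain_id: str,
                       residue_number: int, heavy_only: bool = True) -> AtomGroup:
    """All atoms of one residue as an AtomGroup (heavy atoms by default)."""
    mask = (
        (traj.atoms["chain_id"] == chain_id)
        & (traj.atoms["residue_number"] == residue_number)
    )
    if heavy_only:
        mask &= traj.atoms["element"].str.upper() != "H"
    rows = traj.atoms[mask]
    if rows.empty:
        raise TrajectoryError(f"residue {chain_id}:{residue_number} not in trajectory")
    return AtomGroup(
        name=f"{chain_id}:{residue_number}",
        atoms=[(chain_id, residue_number, a) for a in rows["atom_name"]],
    )


def min_distance(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between two coordinate sets (Å)."""
    frame_a = np.atleast_2d(np.asarray(frame_a, dtype=float))
    frame_b = np.atleast_2d(np.asarray(frame_b, dtype=float))
    if frame_a.size == 0 or frame_b.size == 0:
        raise TrajectoryError("cannot compute distance for an empty group")
    return float(cdist(frame_a, frame_b).min())


def contact_series(
    traj: TrajectoryEnsemble,
    group_a: AtomGroup,
    group_b: AtomGroup,
    cutoff: float = HYDROPHOBIC_CUTOFF,
    criterion: str = "min-heavy-atom",
) -> ContactSeries:
    """Per-frame contact states between two atom groups.

    ``criterion`` is ``"min-heavy-atom"`` (default) or ``"centroid"``; the
    latter compares geometric centroids, the usual proxy for aromatic
    ring–ring interactions.
    """
    if cutoff < 0:
        raise TrajectoryError("cutoff must be non-negative")
    if criterion not in ("min-heavy-atom", "centroid"):
        raise TrajectoryError(f"unknown contact criterion {criterion!r}")
    ia = group_a.resolve(traj)
    ib = group_b.resolve(traj)
    states = np.empty(traj.n_frames, dtype=bool)
    for k in range(traj.n_frames):
        ca, cb = traj.coords[k][ia], traj.coords[k][ib]
        if criterion == "centroid":
            d = float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))
        else:
            d = min_distance(ca, cb)
        states[k] = d <= cutoff
    return ContactSeries(
        pair=(group_a.name, group_b.name),
        per_frame_state=states,
        cutoff=cutoff,
        criterion=criterion,
    )


def persistence_table(
    traj: TrajectoryEnsemble,
    ligand: AtomGroup,
    residues: Sequence[tuple[str, int]] | SegmentDefinition | Iterable[SegmentDefinition],
    cutoff: float = HYDROPHOBIC_CUTOFF,
    criterion: str = "min-heavy-atom",
) -> pd.DataFrame:
    """Contact persistence (%) of a ligand against a set of residues.

    ``residues`` may be explicit (chain, residue_number) pairs or segment
    definitions.  Rows are sorted by chain then residue number and carry the
    frame count and cutoff used.
    """
    if isinstance(residues, SegmentDefinition):
        pairs = residues.residues()
    else:
        residues = list(residues)
        if residues and isinstance(residues[0], SegmentDefinition):
            pairs = [rid for seg in residues for rid in seg.residues()]
        else:
            pairs = [(str(c), int(r)) for c, r in residues]
    if not pairs:
        raise TrajectoryError("no residues given")
    rows = []
    for chain, res in sorted(set(pairs)):
        group = residue_atom_group(traj, chain, res)
        series = contact_series(traj, ligand, group, cutoff, criterion)
        rows.append(
            {
                "chain_id": chain,
                "residue_number": res,
                "persistence_pct": series.persistence,
                "n_frames": traj.n_frames,
                "cutoff": cutoff,
                "criterion": criterion,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["chain_id", "residue_number"], ignore_index=True
    )
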