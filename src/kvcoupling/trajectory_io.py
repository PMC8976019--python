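"""Trajectory containers, multi-model PDB I/O, and rigid-body superposition.

A trajectory is a fixed atom list plus a ``(n_frames, n_atoms, 3)`` coordinate
array in Å.  Frames are snapshots written at a constant sampling interval
``dt`` (ns); the start structure is not stored, so frame ``k`` (1-based)
carries timestamp ``k * dt``.  A 30 ns run sampled every 0.25 ns therefore
holds 120 frames with timestamps 0.25 … 30.0 ns.

Chains follow the subunit convention of homotetrameric channel models
(chains A–D, one per subunit); residue numbering is the author numbering of
the source PDB, inclusive at both ends of any range.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "TrajectoryEnsemble",
    "SegmentDefinition",
    "SuperpositionResult",
    "TrajectoryError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_segment_config",
    "write_segment_config",
    "select_atoms",
    "kabsch_superpose",
    "apply_superposition_series",
]

ATOM_COLUMNS = ["chain_id", "residue_number", "residue_name", "atom_name", "element", "hetero"]


class TrajectoryError(ValueError):
    """Raised on malformed trajectories, selections, or degenerate geometry."""


class AtomRecord(NamedTuple):
    """One atom of the shared topology.

    ``(chain_id, residue_number, atom_name)`` is unique within a frame.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    hetero: bool = False


@dataclass
class SegmentDefinition:
    """A named, inclusive residue range on one chain.

    The unit of the coupling analysis: e.g. the lower S4 helix
    (chain B, residues 235–241) or the selectivity filter (chain A, 310–320).
    """

    name: str
    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise TrajectoryError(
                f"segment {self.name!r}: first_residue {self.first_residue} > "
                f"last_residue {self.last_residue}"
            )

    def __len__(self) -> int:
        return self.last_residue - self.first_residue + 1

    def residues(self) -> list[tuple[str, int]]:
        """All ``(chain_id, residue_number)`` pairs of the segment, in order."""
        return [
            (self.chain_id, r)
            for r in range(self.first_residue, self.last_residue + 1)
        ]


@dataclass
class TrajectoryEnsemble:
    """Time-ordered frames of labelled atom coordinates.

    Attributes
    ----------
    atoms : pandas.DataFrame
        One row per atom with columns ``chain_id, residue_number,
        residue_name, atom_name, element, hetero``; shared by all frames.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in Å.
    timestamps : ndarray, shape (n_frames,)
        Strictly increasing times in ns.
    replicate_id : int
        Index of the simulation replicate this trajectory belongs to.
    condition : str
        Free condition label, e.g. ``"with_ligand"`` / ``"without_ligand"``.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    timestamps: np.ndarray
    replicate_id: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must be (n_frames, n_atoms, 3); got {self.coords.shape}"
            )
        if self.coords.shape[0] != self.timestamps.shape[0]:
            raise TrajectoryError("one timestamp per frame required")
        if self.coords.shape[1] != len(self.atoms):
            raise TrajectoryError(
                f"coords hold {self.coords.shape[1]} atoms but atom table has "
                f"{len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coords contain non-finite values")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise TrajectoryError("timestamps must be strictly increasing")
        if "hetero" not in self.atoms.columns:
            self.atoms = self.atoms.assign(hetero=False)
        key = self.atoms[["chain_id", "residue_number", "atom_name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise TrajectoryError(
                f"duplicate atom (chain {dup.chain_id}, residue "
                f"{dup.residue_number}, atom {dup.atom_name})"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_records(self) -> list[AtomRecord]:
        return [AtomRecord(*row) for row in self.atoms[ATOM_COLUMNS].itertuples(index=False)]

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        mask = (
            (self.atoms["chain_id"] == chain_id)
            & (self.atoms["residue_number"] == residue_number)
            & (self.atoms["atom_name"] == atom_name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise TrajectoryError(
                f"atom (chain {chain_id}, residue {residue_number}, "
                f"{atom_name}) not in trajectory"
            )
        return int(idx[0])

    def take_atoms(self, indices: np.ndarray) -> "TrajectoryEnsemble":
        """Sub-ensemble restricted to the given atom rows (frame count unchanged)."""
        return TrajectoryEnsemble(
            atoms=self.atoms.iloc[indices].reset_index(drop=True),
            coords=self.coords[:, indices, :],
            timestamps=self.timestamps.copy(),
            replicate_id=self.replicate_id,
            condition=self.condition,
        )

    def take_frames(self, frame_mask: np.ndarray) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            atoms=self.atoms.copy(),
            coords=self.coords[frame_mask],
            timestamps=self.timestamps[frame_mask],
            replicate_id=self.replicate_id,
            condition=self.condition,
        )


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation of a mobile set onto a reference.

    ``transform(x) = x @ rotation.T + translation`` minimizes the RMSD to the
    reference; ``rotation`` always has determinant +1 (mirror images are never
    produced, even for planar/degenerate inputs).
    """

    rotation: np.ndarray
    translation: np.ndarray
    post_fit_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB I/O


def _scan_model_atom_identities(lines: Sequence[str]) -> list[tuple[int, list[str]]]:
    """Per-MODEL list of atom identity strings (name/chain/resnum columns).

    Returns ``[(model_serial, identities), ...]``; a file without MODEL
    records yields a single pseudo-model with serial 1.
    """
    models: list[tuple[int, list[str]]] = []
    current: list[str] | None = None
    serial = 0
    saw_model = False
    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model = True
            parts = line.split()
            serial = int(parts[1]) if len(parts) > 1 else len(models) + 1
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                current = []
                serial = 1
            # atom name, altloc, chain, resSeq identify the atom
            current.append(line[12:27])
        elif rec.startswith("ENDMDL"):
            if current is not None:
                models.append((serial, current))
            current = None
    if current is not None and (current or not saw_model):
        models.append((serial or 1, current))
    return models


def read_multimodel_pdb(path: str | Path, dt: float = 0.25,
                        condition: str = "", replicate_id: int = 0) -> TrajectoryEnsemble:
    """Read a MODEL/ENDMDL multi-model PDB file as a trajectory.

    Each MODEL becomes one frame; all models must contain the same atoms in
    the same order.  Timestamps are assigned as ``k * dt`` ns for frames
    ``k = 1..N`` (the start structure is not part of the file).

    Raises
    ------
    TrajectoryError
        If the file holds no atoms, or a model's atom set differs from the
        first model's (the error names the first offending MODEL).
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    models = _scan_model_atom_identities(pdb_file.lines)
    if not models or not models[0][1]:
        raise TrajectoryError(f"{path}: no atom records found")
    ref_serial, ref_ids = models[0]
    for serial, ids in models[1:]:
        if ids != ref_ids:
            raise TrajectoryError(
                f"{path}: MODEL {serial} atom set differs from MODEL "
                f"{ref_serial} ({len(ids)} vs {len(ref_ids)} atoms or "
                "mismatched identities)"
            )
    stack = pdb_file.get_structure(model=None)
    atoms = pd.DataFrame(
        {
            "chain_id": stack.chain_id,
            "residue_number": stack.res_id.astype(int),
            "residue_name": stack.res_name,
            "atom_name": stack.atom_name,
            "element": stack.element,
            "hetero": stack.hetero.astype(bool),
        }
    )
    n_frames = stack.stack_depth()
    timestamps = np.arange(1, n_frames + 1) * float(dt)
    return TrajectoryEnsemble(
        atoms=atoms,
        coords=np.asarray(stack.coord, dtype=float),
        timestamps=timestamps,
        condition=condition,
        replicate_id=replicate_id,
    )


def write_multimodel_pdb(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    n_atoms = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.chain_id = traj.atoms["chain_id"].to_numpy(dtype="U4")
    stack.res_id = traj.atoms["residue_number"].to_numpy(dtype=int)
    stack.res_name = traj.atoms["residue_name"].to_numpy(dtype="U5")
    stack.atom_name = traj.atoms["atom_name"].to_numpy(dtype="U6")
    stack.element = traj.atoms["element"].to_numpy(dtype="U2")
    stack.hetero = traj.atoms["hetero"].to_numpy(dtype=bool)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    out = pdbio.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Segment config


def read_segment_config(path: str | Path) -> dict[str, SegmentDefinition]:
    """Read named residue ranges from an INI-style key/value file.

    Each section defines one segment::

        [S4]
        chain = B
        first = 235
        last = 241
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    segments: dict[str, SegmentDefinition] = {}
    for name in parser.sections():
        sec = parser[name]
        segments[name] = SegmentDefinition(
            name=name,
            chain_id=sec["chain"].strip(),
            first_residue=int(sec["first"]),
            last_residue=int(sec["last"]),
        )
    return segments


def write_segment_config(segments: Iterable[SegmentDefinition], path: str | Path) -> None:
    parser = configparser.ConfigParser()
    for seg in segments:
        parser[seg.name] = {
            "chain": seg.chain_id,
            "first": str(seg.first_residue),
            "last": str(seg.last_residue),
        }
    with open(path, "w") as fh:
        parser.write(fh)


# ---------------------------------------------------------------------------
# Selection


def _as_segment_list(
    selection: SegmentDefinition | Iterable[SegmentDefinition],
) -> list[SegmentDefinition]:
    if isinstance(selection, SegmentDefinition):
        return [selection]
    return list(selection)


def selection_mask(
    traj: TrajectoryEnsemble,
    selection: SegmentDefinition | Iterable[SegmentDefinition] | None,
    atom_names: Iterable[str] | None = None,
) -> np.ndarray:
    """Boolean atom mask for a (possibly multi-segment) selection.

    ``selection=None`` keeps all chains/residues; an empty ``atom_names``
    (or ``None``) keeps all atom names.
    """
    atoms = traj.atoms
    if selection is None:
        mask = np.ones(len(atoms), dtype=bool)
    else:
        mask = np.zeros(len(atoms), dtype=bool)
        for seg in _as_segment_list(selection):
            mask |= (
                (atoms["chain_id"] == seg.chain_id)
                & (atoms["residue_number"] >= seg.first_residue)
                & (atoms["residue_number"] <= seg.last_residue)
            ).to_numpy()
    names = set(atom_names or [])
    if names:
        mask &= atoms["atom_name"].isin(names).to_numpy()
    return mask


def select_atoms(
    traj: TrajectoryEnsemble,
    selection: SegmentDefinition | Iterable[SegmentDefinition] | None,
    atom_names: Iterable[str] | None = None,
) -> TrajectoryEnsemble:
    """Sub-ensemble of the atoms matching segment ranges and atom names.

    Raises ``TrajectoryError`` listing the unmatched residues when nothing
    matches.
    """
    mask = selection_mask(traj, selection, atom_names)
    if not mask.any():
        missing: list[str] = []
        if selection is not None:
            present = set(
                zip(traj.atoms["chain_id"], traj.atoms["residue_number"])
            )
            for seg in _as_segment_list(selection):
                for chain, res in seg.residues():
                    if (chain, res) not in present:
                        missing.append(f"{chain}:{res}")
        detail = f"; residues absent from trajectory: {', '.join(missing)}" if missing else ""
        raise TrajectoryError(f"selection matched no atoms{detail}")
    return traj.take_atoms(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (Kabsch).

    Parameters are ``(n, 3)`` point sets with identical atom correspondence,
    ``n >= 3`` and a non-collinear reference.  The returned rotation always
    has determinant +1; for a mirror-image mobile set the best proper
    rotation is returned (nonzero residual) rather than an improper one.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise TrajectoryError(
            f"point sets must share shape (n, 3); got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise TrajectoryError("superposition requires at least 3 atoms")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    ref_c = reference - ref_mean
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise TrajectoryError("reference atoms are collinear; rotation is degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, rssd = Rotation.align_vectors(ref_c, mobile - mob_mean)
    rotation = rot.as_matrix()
    translation = ref_mean - rotation @ mob_mean
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        post_fit_rmsd=float(rssd / np.sqrt(n)),
    )


def apply_superposition_series(
    traj: TrajectoryEnsemble,
    fit_selection: SegmentDefinition | Iterable[SegmentDefinition] | None = None,
    atom_names: Iterable[str] | None = ("CA",),
    reference_frame: int = 0,
) -> TrajectoryEnsemble:
    """Superpose every frame onto a reference frame; transform all atoms.

    The fit uses the Cα atoms of ``fit_selection`` (whole structure by
    default); the resulting rigid transform of each frame is applied to the
    full atom set, removing global rotation/translation before RMSD, RMSF or
    cross-correlation analysis.
    """
    mask = selection_mask(traj, fit_selection, atom_names)
    if not mask.any():
        raise TrajectoryError("superposition fit selection matched no atoms")
    fit_idx = np.flatnonzero(mask)
    ref = traj.coords[reference_frame][fit_idx]
    out = np.empty_like(traj.coords)
    for k in range(traj.n_frames):
        fit = kabsch_superpose(traj.coords[k][fit_idx], ref)
        out[k] = fit.apply(traj.coords[k])
    return replace(traj, coords=out, atoms=traj.atoms.copy(),
                   timestamps=traj.timestamps.copy())
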