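"""RMSD, RMSF, and dynamic cross-correlation (DCCM) statistics.

The electro-mechanical coupling analysis: per-replicate residue×residue
correlation matrices of Cα displacement vectors, averaged within condition
(ligand bound / unbound) and differenced between conditions.  A positive
entry of the difference matrix marks a residue pair whose motions became
more correlated when the ligand is present; a negative entry marks a pair
whose coupling the ligand weakened or abolished.

Definitions
-----------
RMSD(t)   root-mean-square deviation of the selected atoms in frame t from
          the reference frame, after optional superposition.
RMSF_i    sqrt(<|r_i(t) - <r_i>|^2>_t), the stationary fluctuation of atom i
          about its time-mean position.
C_ij      <Δr_i · Δr_j> / sqrt(<|Δr_i|^2> <|Δr_j|^2>), with
          Δr_i(t) = r_i(t) - <r_i>: the scalar (3-D dot-product) correlation
          of mean-centred displacement vectors, in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import (
    SegmentDefinition,
    TrajectoryEnsemble,
    TrajectoryError,
    apply_superposition_series,
    select_atoms,
)

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "DCCMatrix",
    "DeltaDCCM",
    "SubmatrixSummary",
    "ZeroVarianceWarning",
    "rmsd_series",
    "rmsf_profile",
    "dccm",
    "average_dccm",
    "delta_dccm",
    "segment_pair_submatrix",
    "analysis_window",
]

_VAR_TOL = 1e-24  # Å²; below this a residue is treated as motionless


class ZeroVarianceWarning(UserWarning):
    """A residue with (numerically) zero displacement variance was flagged."""


@dataclass
class RmsdSeries:
    timestamps: np.ndarray
    values: np.ndarray
    selection_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


@dataclass
class RmsfProfile:
    residue_ids: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain_id": [c for c, _ in self.residue_ids],
                "residue_number": [r for _, r in self.residue_ids],
                "rmsf": self.values,
            }
        )


def _check_correlation_matrix(values: np.ndarray, what: str) -> None:
    filled = np.nan_to_num(values, nan=0.0)
    if not np.allclose(filled, filled.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    vmax = float(np.max(np.abs(filled)))
    if vmax > 1 + 1e-9:
        raise ValueError(f"{what} entries must lie in [-1, 1]; max |value| = {vmax}")


@dataclass
class DCCMatrix:
    """Residue×residue displacement cross-correlations for one trajectory.

    Residues with zero displacement variance carry NaN in their row/column
    (the correlation is undefined there, never silently zero).
    """

    residue_ids: list[tuple[str, int]]
    values: np.ndarray
    n_frames: int
    condition: str = ""
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} residue ids"
            )
        _check_correlation_matrix(self.values, "DCCM")
        diag = np.diag(self.values)
        ok = np.isfinite(diag)
        if ok.any() and not np.allclose(diag[ok], 1.0, atol=1e-9):
            raise ValueError("DCCM diagonal must be 1 for residues with motion")

    def labels(self) -> list[str]:
        return [f"{c}:{r}" for c, r in self.residue_ids]

    def to_frame(self) -> pd.DataFrame:
        lab = self.labels()
        return pd.DataFrame(self.values, index=lab, columns=lab)


@dataclass
class DeltaDCCM:
    """Condition-difference matrix: mean(with ligand) − mean(without)."""

    residue_ids: list[tuple[str, int]]
    values: np.ndarray
    n_replicates_with: int
    n_replicates_without: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.max(np.abs(finite)) > 2 + 1e-9:
            raise ValueError("delta-DCCM entries must lie in [-2, 2]")

    def labels(self) -> list[str]:
        return [f"{c}:{r}" for c, r in self.residue_ids]

    def to_frame(self) -> pd.DataFrame:
        lab = self.labels()
        return pd.DataFrame(self.values, index=lab, columns=lab)


@dataclass
class SubmatrixSummary:
    """A segment-pair block of a (delta-)DCCM with its summary statistics."""

    values: np.ndarray
    row_ids: list[tuple[str, int]]
    col_ids: list[tuple[str, int]]
    mean: float
    min: float
    max: float


# ---------------------------------------------------------------------------


def _maybe_superpose(
    traj: TrajectoryEnsemble,
    superpose: bool,
    fit_selection,
    reference_frame: int,
) -> TrajectoryEnsemble:
    if not superpose:
        return traj
    return apply_superposition_series(
        traj, fit_selection=fit_selection, reference_frame=reference_frame
    )


def rmsd_series(
    traj: TrajectoryEnsemble,
    selection: SegmentDefinition | Iterable[SegmentDefinition] | None = None,
    atom_names: Iterable[str] | None = None,
    superpose: bool = True,
    fit_selection=None,
    reference_frame: int = 0,
) -> RmsdSeries:
    """Per-frame RMSD of the selected atoms from the reference frame.

    With ``superpose=True`` each frame is first rigid-body fitted (Cα of
    ``fit_selection``, whole structure by default) onto the reference frame,
    so the series reports internal motion only.
    """
    if traj.n_frames < 1:
        raise TrajectoryError("need at least one frame")
    work = _maybe_superpose(traj, superpose, fit_selection, reference_frame)
    sub = select_atoms(work, selection, atom_names)
    ref = sub.coords[reference_frame]
    diff = sub.coords - ref[None, :, :]
    values = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    name = "all"
    if selection is not None:
        segs = [selection] if isinstance(selection, SegmentDefinition) else list(selection)
        name = "+".join(s.name for s in segs)
    return RmsdSeries(timestamps=sub.timestamps, values=values, selection_name=name)


def rmsf_profile(
    traj: TrajectoryEnsemble,
    selection: SegmentDefinition | Iterable[SegmentDefinition] | None = None,
    atom_names: Iterable[str] | None = ("CA",),
    superpose: bool = True,
    fit_selection=None,
    reference_frame: int = 0,
) -> RmsfProfile:
    """Per-residue RMSF about the time-mean atom positions.

    Residues contributing several selected atoms report the RMS of their
    atomic RMSF values.  Requires at least two frames.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("fluctuation undefined for a single frame")
    work = _maybe_superpose(traj, superpose, fit_selection, reference_frame)
    sub = select_atoms(work, selection, atom_names)
    disp = sub.coords - sub.coords.mean(axis=0, keepdims=True)
    atom_msf = np.mean(np.sum(disp**2, axis=2), axis=0)  # <|Δr|²> per atom
    keys = list(zip(sub.atoms["chain_id"], sub.atoms["residue_number"]))
    order: list[tuple[str, int]] = []
    grouped: dict[tuple[str, int], list[float]] = {}
    for key, msf in zip(keys, atom_msf):
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(msf)
    values = np.array([np.sqrt(np.mean(grouped[k])) for k in order])
    return RmsfProfile(residue_ids=order, values=values)


def dccm(
    traj: TrajectoryEnsemble,
    selection: SegmentDefinition | Iterable[SegmentDefinition] | None = None,
    atom_names: Iterable[str] | None = ("CA",),
    superpose: bool = True,
    fit_selection=None,
    reference_frame: int = 0,
) -> DCCMatrix:
    """Dynamic cross-correlation matrix over the full trajectory.

    One representative atom per residue (Cα by default) is required; a
    residue matching several selected atoms is an error, not an average.
    Zero-variance residues yield NaN rows/columns and a
    ``ZeroVarianceWarning``.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("correlation undefined for a single frame")
    work = _maybe_superpose(traj, superpose, fit_selection, reference_frame)
    sub = select_atoms(work, selection, atom_names)
    keys = list(zip(sub.atoms["chain_id"], sub.atoms["residue_number"]))
    if len(set(keys)) != len(keys):
        seen: set[tuple[str, int]] = set()
        for key in keys:
            if key in seen:
                raise TrajectoryError(
                    f"residue {key[0]}:{key[1]} matches more than one selected "
                    "atom; DCCM needs one representative atom per residue"
                )
            seen.add(key)
    disp = sub.coords - sub.coords.mean(axis=0, keepdims=True)
    n_frames = sub.n_frames
    cov = np.einsum("tia,tja->ij", disp, disp) / n_frames
    var = np.diag(cov).copy()
    zero = var <= _VAR_TOL
    if zero.any():
        flagged = [f"{c}:{r}" for (c, r), z in zip(keys, zero) if z]
        warnings.warn(
            "zero displacement variance; correlations undefined for "
            + ", ".join(flagged),
            ZeroVarianceWarning,
            stacklevel=2,
        )
        var[zero] = 1.0  # placeholder; rows overwritten with NaN below
    values = cov / np.sqrt(np.outer(var, var))
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    values[zero, :] = np.nan
    values[:, zero] = np.nan
    return DCCMatrix(
        residue_ids=keys,
        values=values,
        n_frames=n_frames,
        condition=traj.condition,
        replicate_id=traj.replicate_id,
    )


def average_dccm(matrices: Sequence[DCCMatrix], fisher_z: bool = False) -> DCCMatrix:
    """Entrywise mean of replicate DCCMs sharing one residue ordering.

    ``fisher_z=True`` averages on the arctanh scale instead of the plain
    arithmetic mean (the default mirrors straight replicate averaging).
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    ref_ids = matrices[0].residue_ids
    for m in matrices[1:]:
        if m.residue_ids != ref_ids:
            raise ValueError("residue orderings differ between matrices")
    stack = np.stack([m.values for m in matrices])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    conditions = {m.condition for m in matrices}
    return DCCMatrix(
        residue_ids=list(ref_ids),
        values=mean,
        n_frames=int(sum(m.n_frames for m in matrices)),
        condition=conditions.pop() if len(conditions) == 1 else "",
        replicate_id=None,
    )


def delta_dccm(mean_with: DCCMatrix, mean_without: DCCMatrix,
               n_replicates_with: int = 1, n_replicates_without: int = 1) -> DeltaDCCM:
    """Condition difference ``mean_with − mean_without`` (diagonal exactly 0)."""
    if mean_with.residue_ids != mean_without.residue_ids:
        raise ValueError("residue orderings differ between condition means")
    values = mean_with.values - mean_without.values
    np.fill_diagonal(values, 0.0)
    return DeltaDCCM(
        residue_ids=list(mean_with.residue_ids),
        values=values,
        n_replicates_with=n_replicates_with,
        n_replicates_without=n_replicates_without,
    )


def segment_pair_submatrix(
    matrix: DCCMatrix | DeltaDCCM,
    seg_a: SegmentDefinition,
    seg_b: SegmentDefinition,
) -> SubmatrixSummary:
    """Block of a (delta-)DCCM with rows from one segment, columns another.

    This is the panel structure of the coupling figures: e.g. S4 residues
    against selectivity-filter residues, summarized by block mean/min/max.
    """
    index = {rid: i for i, rid in enumerate(matrix.residue_ids)}

    def resolve(seg: SegmentDefinition) -> list[int]:
        rows = []
        for rid in seg.residues():
            if rid not in index:
                raise ValueError(
                    f"segment {seg.name!r}: residue {rid[0]}:{rid[1]} not in matrix"
                )
            rows.append(index[rid])
        return rows

    ri = resolve(seg_a)
    ci = resolve(seg_b)
    block = matrix.values[np.ix_(ri, ci)]
    finite = block[np.isfinite(block)]
    if finite.size == 0:
        mean = mn = mx = float("nan")
    else:
        mean, mn, mx = float(finite.mean()), float(finite.min()), float(finite.max())
    return SubmatrixSummary(
        values=block,
        row_ids=[matrix.residue_ids[i] for i in ri],
        col_ids=[matrix.residue_ids[i] for i in ci],
        mean=mean,
        min=mn,
        max=mx,
    )


def analysis_window(
    traj: TrajectoryEnsemble, t_start: float, t_end: float
) -> TrajectoryEnsemble:
    """Frames with ``t_start <= t <= t_end`` (both endpoints inclusive).

    A 120-frame run sampled every 0.25 ns windowed to [10, 30] ns keeps 81
    frames (the snapshot bookkeeping behind pooled per-frame statistics).
    """
    if not t_start < t_end:
        raise TrajectoryError(f"empty window: t_start {t_start} >= t_end {t_end}")
    eps = 1e-9
    mask = (traj.timestamps >= t_start - eps) & (traj.timestamps <= t_end + eps)
    if not mask.any():
        raise TrajectoryError(
            f"window [{t_start}, {t_end}] ns contains no frames "
            f"(trajectory spans [{traj.timestamps[0]}, {traj.timestamps[-1]}] ns)"
        )
    return traj.take_frames(mask)
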