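"""End-to-end two-condition comparison pipeline.

Orchestrates: read replicate trajectories → superpose → (optional analysis
window) → RMSD/RMSF/DCCM per replicate → average per condition → condition
difference → segment-pair summaries → ligand contact table, writing every
artifact with provenance (config hash, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contacts import AtomGroup, persistence_table
from .coupling_stats import (
    DCCMatrix,
    DeltaDCCM,
    RmsdSeries,
    RmsfProfile,
    SubmatrixSummary,
    analysis_window,
    average_dccm,
    dccm,
    delta_dccm,
    rmsd_series,
    rmsf_profile,
    segment_pair_submatrix,
)
from .ephys_fits import (
    PAPER_PROTOCOL,
    VoltageProtocol,
    biexp_fit,
    boltzmann_fit,
    gv_from_tails,
    read_trace,
)
from .synthetic_traj import (
    SyntheticTrajectoryConfig,
    generate_condition_ensembles,
    generate_reference_geometry,
)
from .trajectory_io import (
    SegmentDefinition,
    TrajectoryEnsemble,
    read_multimodel_pdb,
    write_multimodel_pdb,
)

logger = logging.getLogger("kvcoupling")

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "PipelineError",
    "run_compare",
    "run_simulate",
    "run_ephys",
    "analyze_replicate",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and replicate."""


@dataclass
class RunConfig:
    """Configuration of a two-condition comparison run.

    ``replicate_files`` maps exactly two condition labels to lists of
    multi-model PDB paths; the condition difference is computed as
    first label minus second label.
    """

    replicate_files: Mapping[str, Sequence[str | Path]]
    segments: Mapping[str, SegmentDefinition] = field(default_factory=dict)
    atom_names: tuple[str, ...] = ("CA",)
    superpose: bool = True
    reference_frame: int = 0
    dt: float = 0.25  # ns between stored frames
    window: tuple[float, float] | None = None
    contact_cutoff: float = 4.0
    ligand: AtomGroup | None = None
    contact_residues: Sequence[tuple[str, int]] | None = None
    seed: int = 0
    outdir: str | Path | None = None

    def condition_labels(self) -> tuple[str, str]:
        labels = list(self.replicate_files)
        if len(labels) != 2:
            raise PipelineError(
                f"exactly two conditions required, got {len(labels)}: {labels}"
            )
        return labels[0], labels[1]

    def config_hash(self) -> str:
        payload = {
            "replicate_files": {
                k: [str(p) for p in v] for k, v in self.replicate_files.items()
            },
            "segments": {
                k: dataclasses.asdict(s) for k, s in sorted(self.segments.items())
            },
            "atom_names": list(self.atom_names),
            "superpose": self.superpose,
            "reference_frame": self.reference_frame,
            "dt": self.dt,
            "window": self.window,
            "contact_cutoff": self.contact_cutoff,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ComparisonReport:
    replicate_dccms: dict[str, list[DCCMatrix]]
    mean_dccms: dict[str, DCCMatrix]
    delta: DeltaDCCM
    rmsd: dict[str, list[RmsdSeries]]
    rmsf: dict[str, list[RmsfProfile]]
    segment_summaries: dict[str, SubmatrixSummary]
    contact_table: pd.DataFrame | None
    provenance: dict[str, Any]


def analyze_replicate(
    traj: TrajectoryEnsemble, config: RunConfig
) -> tuple[DCCMatrix, RmsdSeries, RmsfProfile]:
    """Windowed RMSD/RMSF/DCCM for one replicate trajectory."""
    if config.window is not None:
        traj = analysis_window(traj, *config.window)
    kwargs = dict(
        atom_names=config.atom_names,
        superpose=config.superpose,
        reference_frame=config.reference_frame,
    )
    return (
        dccm(traj, **kwargs),
        rmsd_series(traj, **kwargs),
        rmsf_profile(traj, **kwargs),
    )


def _write_matrix(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6f")


def run_compare(config: RunConfig) -> ComparisonReport:
    """Execute the full two-condition coupling comparison."""
    label_with, label_without = config.condition_labels()
    replicate_dccms: dict[str, list[DCCMatrix]] = {}
    rmsd: dict[str, list[RmsdSeries]] = {}
    rmsf: dict[str, list[RmsfProfile]] = {}
    contact_frames: list[pd.DataFrame] = []

    for label in (label_with, label_without):
        files = list(config.replicate_files[label])
        if not files:
            raise PipelineError(f"condition {label!r} has no replicate files")
        replicate_dccms[label], rmsd[label], rmsf[label] = [], [], []
        for rid, path in enumerate(files):
            path = Path(path)
            if not path.exists():
                raise PipelineError(
                    f"stage read, condition {label!r}, replicate {rid}: "
                    f"missing file {path}"
                )
            try:
                traj = read_multimodel_pdb(
                    path, dt=config.dt, condition=label, replicate_id=rid
                )
            except Exception as err:
                raise PipelineError(
                    f"stage read, condition {label!r}, replicate {rid}: {err}"
                ) from err
            try:
                matrix, rs, rf = analyze_replicate(traj, config)
            except Exception as err:
                raise PipelineError(
                    f"stage statistics, condition {label!r}, replicate {rid}: {err}"
                ) from err
            replicate_dccms[label].append(matrix)
            rmsd[label].append(rs)
            rmsf[label].append(rf)
            if config.ligand is not None and config.contact_residues:
                try:
                    table = persistence_table(
                        traj,
                        config.ligand,
                        config.contact_residues,
                        cutoff=config.contact_cutoff,
                    )
                    table["condition"] = label
                    table["replicate_id"] = rid
                    contact_frames.append(table)
                except Exception:
                    logger.info(
                        "ligand not resolvable in condition %r replicate %d; "
                        "skipping contact table", label, rid,
                    )
            logger.info("analyzed condition %r replicate %d (%s)", label, rid, path)

    mean_dccms = {
        label: average_dccm(mats) for label, mats in replicate_dccms.items()
    }
    delta = delta_dccm(
        mean_dccms[label_with],
        mean_dccms[label_without],
        n_replicates_with=len(replicate_dccms[label_with]),
        n_replicates_without=len(replicate_dccms[label_without]),
    )
    segment_summaries: dict[str, SubmatrixSummary] = {}
    names = sorted(config.segments)
    for i, a in enumerate(names):
        for b in names[i:]:
            try:
                segment_summaries[f"{a}|{b}"] = segment_pair_submatrix(
                    delta, config.segments[a], config.segments[b]
                )
            except ValueError as err:
                raise PipelineError(f"stage segment summary ({a},{b}): {err}") from err

    contact_table = (
        pd.concat(contact_frames, ignore_index=True) if contact_frames else None
    )
    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "conditions": {
            label_with: len(replicate_dccms[label_with]),
            label_without: len(replicate_dccms[label_without]),
        },
        "n_frames_per_replicate": {
            label: [m.n_frames for m in mats]
            for label, mats in replicate_dccms.items()
        },
    }
    report = ComparisonReport(
        replicate_dccms=replicate_dccms,
        mean_dccms=mean_dccms,
        delta=delta,
        rmsd=rmsd,
        rmsf=rmsf,
        segment_summaries=segment_summaries,
        contact_table=contact_table,
        provenance=provenance,
    )
    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: ComparisonReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for label, mats in report.replicate_dccms.items():
        for matrix in mats:
            _write_matrix(
                matrix.to_frame(), outdir / f"dccm_{label}_rep{matrix.replicate_id}.tsv"
            )
    for label, matrix in report.mean_dccms.items():
        _write_matrix(matrix.to_frame(), outdir / f"dccm_mean_{label}.tsv")
    _write_matrix(report.delta.to_frame(), outdir / "delta_dccm.tsv")
    for label, profiles in report.rmsf.items():
        merged = profiles[0].as_frame()[["chain_id", "residue_number"]].copy()
        for i, prof in enumerate(profiles):
            merged[f"rmsf_rep{i}"] = prof.values
        merged.to_csv(outdir / f"rmsf_{label}.tsv", sep="\t", index=False)
    if report.contact_table is not None:
        report.contact_table.to_csv(
            outdir / "contact_persistence.tsv", sep="\t", index=False
        )
    summary = {
        "provenance": report.provenance,
        "segment_pair_delta": {
            key: {"mean": s.mean, "min": s.min, "max": s.max}
            for key, s in report.segment_summaries.items()
        },
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Simulation driver


def run_simulate(
    outdir: str | Path,
    config_with: SyntheticTrajectoryConfig,
    config_without: SyntheticTrajectoryConfig,
    n_with: int = 5,
    n_without: int = 3,
    base_seed: int = 0,
    n_subunits: int = 4,
    residues_per_subunit: int = 20,
    first_residue: int = 1,
) -> dict[str, Any]:
    """Generate a two-condition replicate set and write it as PDB files.

    Returns (and writes) a manifest listing the file of every replicate and
    the seed it was generated from.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = generate_reference_geometry(
        n_subunits=n_subunits,
        residues_per_subunit=residues_per_subunit,
        first_residue=first_residue,
    )
    with_list, without_list = generate_condition_ensembles(
        ref, config_with, config_without,
        n_with=n_with, n_without=n_without, base_seed=base_seed,
    )
    manifest: dict[str, Any] = {
        "base_seed": base_seed,
        "n_frames": config_with.n_frames,
        "dt_ns": config_with.dt,
        "replicates": [],
    }
    for traj in with_list + without_list:
        name = f"{traj.condition}_rep{traj.replicate_id}.pdb"
        write_multimodel_pdb(traj, outdir / name)
        offset = traj.replicate_id if traj.condition == with_list[0].condition else (
            n_with + traj.replicate_id
        )
        manifest["replicates"].append(
            {
                "file": name,
                "condition": traj.condition,
                "replicate_id": traj.replicate_id,
                "seed": base_seed + offset,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Electrophysiology driver


def run_ephys(
    trace_files: Sequence[str | Path],
    protocol: VoltageProtocol = PAPER_PROTOCOL,
    reference_potential: float = 40.0,
    amplitude: str = "fixed",
    blank_s: float = 0.005,
) -> dict[str, Any]:
    """Fit a directory's worth of current traces.

    Per-file biexponential activation/deactivation fits, then a G–V
    Boltzmann fit from the pooled tail currents.  Per-file failures are
    collected and reported; the run continues.
    """
    trace_files = [Path(p) for p in trace_files]
    if not trace_files:
        raise PipelineError("no trace files given")
    traces, failures = [], []
    per_trace = []
    for path in trace_files:
        try:
            trace = read_trace(path)
        except Exception as err:
            failures.append({"file": str(path), "stage": "read", "error": str(err)})
            continue
        traces.append(trace)
        entry: dict[str, Any] = {"file": str(path), "test_potential_mV": trace.test_potential}
        try:
            act = biexp_fit(trace, "activation", window=(0.0, protocol.test_duration))
            entry["activation"] = {
                "tau_fast_s": act.tau_fast,
                "tau_slow_s": act.tau_slow,
                "degenerate": act.degenerate,
            }
        except Exception as err:
            failures.append({"file": str(path), "stage": "activation_fit", "error": str(err)})
        try:
            # skip the capacitive step instant: the sample at the exact end of
            # the test pulse still belongs to the activation phase
            deact = biexp_fit(
                trace,
                "deactivation",
                window=(
                    protocol.test_duration + blank_s,
                    protocol.test_duration + protocol.tail_duration,
                ),
            )
            entry["deactivation"] = {
                "tau_fast_s": deact.tau_fast,
                "tau_slow_s": deact.tau_slow,
                "degenerate": deact.degenerate,
            }
        except Exception as err:
            failures.append({"file": str(path), "stage": "deactivation_fit", "error": str(err)})
        per_trace.append(entry)
    report: dict[str, Any] = {"traces": per_trace, "failures": failures}
    try:
        volts, g_norm = gv_from_tails(traces, protocol, reference_potential)
        fit = boltzmann_fit(volts, g_norm, amplitude=amplitude)
        report["gv"] = {
            "V_mV": volts.tolist(),
            "G_norm": g_norm.tolist(),
            "v_half_mV": fit.v_half,
            "slope_k_mV": fit.slope_k,
            "residual": fit.residual,
        }
    except Exception as err:
        failures.append({"file": None, "stage": "gv_fit", "error": str(err)})
    report["ok"] = not failures
    return report
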