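# Methods

## Scope

`kvcoupling` quantifies how a small-molecule modulator changes the
electro-mechanical coupling of a voltage-gated potassium channel, from two
directions:

1. **Trajectory statistics** — per-replicate RMSD/RMSF and dynamic
   cross-correlation matrices (DCCMs) of Cα displacements, averaged within a
   ligand-bound and a ligand-free condition and differenced between them
   (delta-DCCM), plus ligand–residue contact persistence.
2. **Electrophysiology fits** — Boltzmann activation curves from tail
   currents, two-component exponential activation/deactivation kinetics, and
   Hill dose–response fits, with a protocol-aware synthetic trace generator.

MD engines and oocyte recordings are replaced by synthetic generators with
known ground truth, so every statistic is testable end to end.

## Trajectory model and conventions

A trajectory is a fixed atom list plus frames of coordinates in Å. Frames
are snapshots at a constant interval `dt` (default 0.25 ns); frame `k`
(1-based) carries timestamp `k·dt` and the start structure is not stored.
This is the only convention under which a 30 ns run sampled every 0.25 ns
holds 120 frames and an inclusive 10–30 ns production window holds 81 of
them (405 pooled snapshots over five replicates, 243 over three — the
replicate design the generator emulates).

Residue ranges are inclusive at both ends in author numbering; chains A–D
map to the four subunits of a homotetrameric channel. Missing atoms in a
selection are a hard error, never a silent skip, because correlation
matrices need a fixed residue index.

**Superposition.** Rigid-body motion is removed by a Kabsch fit (proper
rotation guaranteed; implemented via SVD with determinant sign correction,
through `scipy.spatial.transform.Rotation.align_vectors`) of each frame's
Cα atoms onto the first frame; the whole-structure Cα set is the default
fit selection and both reference frame and fit selection are configurable.
Superposition is idempotent and removes any per-frame global
rotation+translation exactly.

**DCCM.** `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)` with
`Δr_i(t) = r_i(t) − ⟨r_i⟩`, i.e. the scalar (3-D dot-product) correlation
of mean-centred displacement vectors, one representative atom (Cα) per
residue, computed over the complete trajectory. Residues with zero
displacement variance get NaN rows/columns and a warning — coercing them to
0 would fake "no correlation". Replicate averaging is the plain entrywise
arithmetic mean (a Fisher-z option exists but is off by default); the
condition difference subtracts the two means and zeroes the diagonal.

A caveat that matters for calibration work: mean-removal by superposition
absorbs part of any displacement component shared by many atoms. When a
large fraction of the fit selection carries a common latent motion (as in
the synthetic correlation blocks), superposing against that same selection
shrinks the apparent correlation toward zero. Recovery checks of the
generator's targets therefore run with superposition disabled — those
trajectories contain no rigid-body motion, so nothing needs removing — while
invariance checks (identical statistics with and without a rigid overlay)
run with superposition enabled on both sides. On real data with a stable
core, the standard whole-protein Cα fit is appropriate.

**Contacts.** A frame is in contact when the criterion distance is at or
below the cutoff: minimum heavy-atom distance ≤ 4.0 Å for hydrophobic
contacts, geometric ring-centroid distance ≤ 5.5 Å (no angle term) for
aromatic ones. Both values follow common literature conventions and are
exposed in the API; hydrogens are excluded by element. Persistence is the
percentage of in-contact frames and is invariant to frame order and global
rigid motion.

## Synthetic trajectory generator

Frames are `reference + displacement`, with displacements drawn from a
zero-mean Gaussian whose inter-residue correlation is set exactly by a
shared-latent-factor construction per block:

    x_i(t) = √|ρ|·s_i·z(t) + √(1−|ρ|)·ε_i(t)   (per Cartesian axis)

with loading sign `s_i = +1` on the first segment and `sign(ρ)` on the
second. Cross-segment pairs then have correlation exactly `ρ`; pairs within
one segment have `|ρ|`. Blocks must be residue-disjoint (validated), which
keeps the implied covariance positive semi-definite by construction.
Optional components: an AR(1) filter (`0 ≤ φ < 1`, normalized to unit
stationary variance, so it changes effective sample size but not the
stationary correlation targets), a per-frame random rigid-motion overlay
(what superposition must remove), and planted per-residue ligand contact
schedules (one ligand pseudo-atom per scheduled residue, placed 1.2 Å from
the target Cα when in contact and parked ~1000 Å away otherwise; schedules
should target spatially separated residues so plants stay independent).

Defaults are the emulated study conditions: 120 frames at 0.25 ns, base
jitter σ = 0.5 Å per axis (a typical equilibrated backbone fluctuation
scale), five replicates in the ligand-bound condition and three in the
ligand-free one. Replicate seeds derive deterministically from a base seed
(`base_seed + i` for the first condition, `base_seed + n_with + j` for the
second) so reruns are bit-identical and no replicate shares a seed.

What the generator does *not* model: physical dynamics (no force field,
thermostat, or membrane), anharmonicity, state transitions, and
time-irreversible relaxation. Passing recovery tests therefore demonstrates
estimator correctness, not fidelity of any MD engine; conclusions about
real trajectories still depend on sampling quality of those trajectories.

## Electrophysiology model

The trace generator emulates a two-electrode voltage-clamp step protocol
(defaults: holding −80 mV; 7 s test pulses −100…+60 mV in 20 mV increments;
3 s tail at −120 mV). Per test potential `V`:

- activation: `I(t) = g_max·P(V)·[f·(1−e^(−t/τ_fa)) + (1−f)·(1−e^(−t/τ_sa))]`
  with open probability `P(V) = 1/(1+exp((V_half−V)/k))`;
- tail: a two-exponential decay whose initial amplitude is proportional to
  the open probability reached at the end of the test pulse (inward at
  −120 mV, hence negative).

Voltage-independent time constants are a deliberate simplification: they
make the activation-completion factor identical across potentials, so
normalized tail peaks trace the Boltzmann exactly. Default gating values
(`V_half = −20 mV`, `k = 12 mV`, `τ_fast/τ_slow` activation 0.5/3.0 s,
deactivation 0.15/1.2 s) are typical for a slowly activating cardiac
potassium current.

Fitting choices:

- **Tail peaks** are the maximum |I| in the tail window after a 5 ms
  blanking interval (capacitive transient; also excludes the last
  test-pulse sample sitting exactly on the step). Normalization is to the
  +40 mV reference, as is conventional — not to the asymptote. The
  Boltzmann fit pins the amplitude at 1 by default; a free-amplitude option
  absorbs the known `1/P(+40)` scale that reference normalization leaves,
  which is what makes the noiseless simulate→fit round trip exact.
  Sign convention: `k > 0` for depolarization-activated channels.
- **Biexponential fits** multi-start the two time constants on a log-spaced
  grid over `[T/100, T]` (T = window length, all ordered pairs of 4 grid
  points), keep the best residual, and relabel post-fit so
  `τ_fast < τ_slow`. Time is measured from the window start, so amplitudes
  are referenced to it. Flat traces return a flagged degenerate fit with
  zero amplitudes instead of an error, so batch runs continue.
- **Dose–response** uses a Hill curve with the coefficient fixed at 1 by
  default (only EC50 and maximal effect are reported for this compound
  class); an all-zero effect is returned as unidentifiable rather than
  fitted.
- **Fluorescence–voltage (dF/F) relations** run through the identical
  Boltzmann code path as G–V; no photobleach correction is applied (known
  limitation). No leak subtraction or series-resistance correction either —
  synthetic traces do not need them, and real traces should be
  pre-processed upstream.

## Pipeline

`run_compare` executes read → superpose → (window) → RMSD/RMSF/DCCM per
replicate → condition means → delta → segment-pair block summaries →
contact table, writes all matrices as labelled TSV, and stamps every report
with a config hash, the seed, and the package version, so identical inputs
give byte-identical artifacts. Exactly two conditions per run; any stage
error aborts naming the stage and replicate. The `kvcoupling` CLI exposes
`simulate`, `analyze`, `compare`, and `ephys-fit` subcommands (exit codes
0/1/2 = ok / user error / stage failure).

## Problem sizes and numerical tolerances

Statistical checks use sizes where Monte-Carlo error is well inside the
asserted tolerances: correlation-target recovery at 2,000 frames (±0.05),
the null condition-difference bound at 2,000 frames (|Δ| < 0.1), the
isotropic RMSF closed form `σ√3` at 10,000 frames (±2%), and the noisy
`V_half` recovery over 50 seeds (median error < 1 mV at 1% current noise).
Exact checks: DCCM equals a literal double-loop evaluation to 1e−12;
rigid-overlay invariance holds to 1e−6; the noiseless ephys round trip
recovers parameters to 1e−4 relative. Degenerate inputs (collinear
reference geometry, single-frame fluctuations, zero-variance residues,
zero control currents) raise or flag; they are never silently coerced.
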