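"""Two-electrode voltage-clamp analysis: Boltzmann G–V, biexponential
kinetics, dose–response, and a protocol-aware synthetic trace generator.

The analysis chain mirrors standard oocyte work on slowly activating
potassium channels: a family of depolarizing test pulses from a holding
potential, each followed by a fixed hyperpolarized tail pulse.  Peak tail
currents report the open probability reached during the test pulse; plotted
against test potential and normalized to a reference potential they give the
activation (G–V) curve

    G(V) = 1 / (1 + exp((V_half - V) / k)),

with half-activation voltage ``V_half`` (mV) and slope factor ``k`` (mV,
positive for depolarization-activated channels).  Activation and
deactivation time courses are fitted with two-component exponentials
(tau_fast < tau_slow enforced by relabelling), and drug dose–response data
with a Hill curve (coefficient fixed at 1 by default, since only EC50 and
maximal effect are reported for this compound class).

Fluorescence–voltage (dF/F) relations from voltage-clamp fluorometry are
normalized sigmoids too and run through the identical Boltzmann code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from lmfit import Model

__all__ = [
    "VoltageProtocol",
    "CurrentTrace",
    "BoltzmannFit",
    "BiexpFit",
    "DoseResponseFit",
    "GatingParams",
    "FitError",
    "PAPER_PROTOCOL",
    "percent_activation",
    "gv_from_tails",
    "boltzmann_fit",
    "fit_gv_curve",
    "fit_fv_curve",
    "biexp_fit",
    "dose_response_fit",
    "simulate_traces",
    "write_trace",
    "read_trace",
]


class FitError(RuntimeError):
    """A fit failed to converge; carries the best iterate when available."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class VoltageProtocol:
    """Step protocol: test pulses from holding, each followed by a tail pulse."""

    holding: float = -80.0  # mV
    test_potentials: tuple[float, ...] = tuple(np.arange(-100.0, 61.0, 20.0))
    test_duration: float = 7.0  # s
    tail_potential: float = -120.0  # mV
    tail_duration: float = 3.0  # s

    def __post_init__(self) -> None:
        if self.test_duration <= 0 or self.tail_duration <= 0:
            raise ValueError("pulse durations must be positive")
        if len(self.test_potentials) == 0:
            raise ValueError("protocol needs at least one test potential")


#: 7 s test pulses −100…+60 mV in 20 mV steps, 3 s tail at −120 mV,
#: holding −80 mV — the standard protocol emulated by `simulate_traces`.
PAPER_PROTOCOL = VoltageProtocol()


@dataclass
class CurrentTrace:
    time: np.ndarray  # s
    current: np.ndarray  # µA
    test_potential: float  # mV
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class BoltzmannFit:
    v_half: float  # mV
    slope_k: float  # mV
    residual: float
    amplitude: float = 1.0

    def predict(self, v: np.ndarray) -> np.ndarray:
        return _boltzmann(np.asarray(v, dtype=float), self.v_half, self.slope_k,
                          self.amplitude)


@dataclass
class BiexpFit:
    tau_fast: float  # s
    tau_slow: float  # s
    amp_fast: float  # µA
    amp_slow: float  # µA
    offset: float  # µA
    residual: float
    phase: str = "activation"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (0 < self.tau_fast <= self.tau_slow):
            raise ValueError("time constants must be positive with tau_fast <= tau_slow")


@dataclass
class DoseResponseFit:
    ec50: float  # µM
    e_max: float  # % activation
    hill_h: float = 1.0
    residual: float = 0.0
    identifiable: bool = True


@dataclass
class GatingParams:
    """Ground truth for the synthetic trace generator."""

    v_half: float = -20.0  # mV
    slope_k: float = 12.0  # mV
    g_max: float = 2.0  # µA at full activation (driving force folded in)
    tau_fast_act: float = 0.5  # s
    tau_slow_act: float = 3.0  # s
    frac_fast_act: float = 0.6
    tau_fast_deact: float = 0.15  # s
    tau_slow_deact: float = 1.2  # s
    frac_fast_deact: float = 0.55
    tail_amp: float = -1.0  # µA scale of the (inward) tail at full open probability


# ---------------------------------------------------------------------------
# Elementary statistics


def percent_activation(i_drug: float, i_ctrl: float) -> float:
    """Percent change in current: ``100 * (I_drug - I_ctrl) / I_ctrl``."""
    if i_ctrl == 0:
        raise ValueError("control current is zero; percent change undefined")
    return 100.0 * (i_drug - i_ctrl) / i_ctrl


# ---------------------------------------------------------------------------
# G–V from tail currents


def gv_from_tails(
    traces: Sequence[CurrentTrace],
    protocol: VoltageProtocol,
    reference_potential: float = 40.0,
    blank_s: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized activation curve from peak tail currents.

    For each test potential the peak |I| inside the tail window (skipping a
    short capacitive blanking interval after the step) is taken; values are
    normalized to the reference potential's peak.

    Returns sorted ``(V, G_norm)`` arrays.
    """
    by_potential = {t.test_potential: t for t in traces}
    missing = [v for v in protocol.test_potentials if v not in by_potential]
    if missing:
        raise FitError(f"no trace for test potentials {missing}")
    if reference_potential not in by_potential:
        raise FitError(f"reference potential {reference_potential} mV has no trace")
    t0 = protocol.test_duration + blank_s
    t1 = protocol.test_duration + protocol.tail_duration
    peaks = {}
    for v, trace in by_potential.items():
        sel = (trace.time >= t0) & (trace.time <= t1)
        if not sel.any():
            raise FitError(f"trace at {v} mV does not cover the tail window")
        peaks[v] = float(np.max(np.abs(trace.current[sel])))
    ref_peak = peaks[reference_potential]
    if ref_peak == 0:
        raise FitError("all-zero tail at the reference potential; no peak to normalize to")
    volts = np.array(sorted(peaks))
    g_norm = np.array([peaks[v] / ref_peak for v in volts])
    return volts, g_norm


# ---------------------------------------------------------------------------
# Boltzmann


def _boltzmann(v, v_half, k, amplitude=1.0):
    return amplitude / (1.0 + np.exp((v_half - v) / k))


def boltzmann_fit(
    v: Iterable[float],
    g_norm: Iterable[float],
    amplitude: str = "fixed",
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized activation curve.

    ``amplitude="fixed"`` pins the asymptote at 1 (normalized data);
    ``"free"`` floats it, appropriate when the data are normalized to a
    finite reference potential rather than to the asymptote.
    """
    v = np.asarray(list(v), dtype=float)
    g = np.asarray(list(g_norm), dtype=float)
    if v.size < 4:
        raise FitError("need at least 4 points spanning the transition")
    model = Model(_boltzmann)
    half = 0.5 * (g.min() + g.max())
    v0 = float(v[np.argmin(np.abs(g - half))])
    params = model.make_params(
        v_half=v0,
        k=max((v.max() - v.min()) / 4.0, 1.0),
        amplitude=1.0,
    )
    params["k"].set(min=1e-6)
    params["amplitude"].set(vary=(amplitude == "free"), min=1e-6)
    result = model.fit(g, params, v=v)
    if not result.success:
        raise FitError(f"Boltzmann fit did not converge: {result.message}", best=result)
    return BoltzmannFit(
        v_half=float(result.params["v_half"].value),
        slope_k=float(result.params["k"].value),
        amplitude=float(result.params["amplitude"].value),
        residual=float(np.sqrt(np.mean(result.residual**2))),
    )


def fit_gv_curve(v, g_norm, amplitude: str = "fixed") -> BoltzmannFit:
    """Boltzmann fit of normalized conductance (G/Gmax) vs voltage."""
    return boltzmann_fit(v, g_norm, amplitude=amplitude)


def fit_fv_curve(v, df_f_norm, amplitude: str = "fixed") -> BoltzmannFit:
    """Boltzmann fit of normalized fluorescence (dF/F) vs voltage.

    Identical machinery to the G–V fit: a voltage-sensor fluorescence curve
    is a normalized sigmoid like the conductance curve.
    """
    return boltzmann_fit(v, df_f_norm, amplitude=amplitude)


# ---------------------------------------------------------------------------
# Biexponential kinetics


def _biexp_activation(t, amp_fast, tau_fast, amp_slow, tau_slow, offset):
    return (
        amp_fast * (1.0 - np.exp(-t / tau_fast))
        + amp_slow * (1.0 - np.exp(-t / tau_slow))
        + offset
    )


def _biexp_decay(t, amp_fast, tau_fast, amp_slow, tau_slow, offset):
    return amp_fast * np.exp(-t / tau_fast) + amp_slow * np.exp(-t / tau_slow) + offset


def biexp_fit(
    trace: CurrentTrace,
    phase: str = "activation",
    window: tuple[float, float] | None = None,
) -> BiexpFit:
    """Two-component exponential fit of an activation or deactivation phase.

    Time constants are multi-started on a log-spaced grid over the window
    length and relabelled post-fit so that ``tau_fast < tau_slow``.  Time is
    measured from the window start, so amplitudes are referenced to it.  A
    flat trace returns a flagged degenerate fit with zero amplitudes.
    """
    if phase not in ("activation", "deactivation"):
        raise ValueError(f"unknown phase {phase!r}")
    if window is None:
        window = (float(trace.time[0]), float(trace.time[-1]))
    t0, t1 = window
    sel = (trace.time >= t0) & (trace.time <= t1)
    if sel.sum() < 20:
        raise FitError(f"window [{t0}, {t1}] s holds {int(sel.sum())} samples; need >= 20")
    t = trace.time[sel] - t0
    y = trace.current[sel]
    span = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * scale:
        return BiexpFit(
            tau_fast=np.nan, tau_slow=np.nan, amp_fast=0.0, amp_slow=0.0,
            offset=float(y.mean()), residual=float(np.std(y)), phase=phase,
            degenerate=True,
        )
    func = _biexp_activation if phase == "activation" else _biexp_decay
    model = Model(func)
    total = float(y[-1] - y[0]) if phase == "activation" else float(y[0] - y[-1])
    duration = float(t[-1])
    grid = np.geomspace(duration / 100.0, duration, 4)
    starts = [(grid[i], grid[j]) for i in range(len(grid)) for j in range(i + 1, len(grid))]
    best = None
    tried = []
    for tf0, ts0 in starts:
        tried.append((tf0, ts0))
        params = model.make_params(
            amp_fast=0.6 * total if phase == "activation" else 0.6 * (y[0] - y[-1]),
            amp_slow=0.4 * total if phase == "activation" else 0.4 * (y[0] - y[-1]),
            tau_fast=tf0,
            tau_slow=ts0,
            offset=float(y[0]) if phase == "activation" else float(y[-1]),
        )
        params["tau_fast"].set(min=duration * 1e-4)
        params["tau_slow"].set(min=duration * 1e-4)
        try:
            result = model.fit(y, params, t=t)
        except Exception:
            continue
        if not result.success:
            continue
        if best is None or result.chisqr < best.chisqr:
            best = result
    if best is None:
        raise FitError(
            f"biexponential fit failed for all {len(tried)} starts: {tried}"
        )
    p = best.params
    tf, ts = float(p["tau_fast"].value), float(p["tau_slow"].value)
    af, as_ = float(p["amp_fast"].value), float(p["amp_slow"].value)
    if tf > ts:  # relabel so the fast component really is the fast one
        tf, ts, af, as_ = ts, tf, as_, af
    return BiexpFit(
        tau_fast=tf,
        tau_slow=ts,
        amp_fast=af,
        amp_slow=as_,
        offset=float(p["offset"].value),
        residual=float(np.sqrt(np.mean(best.residual**2))),
        phase=phase,
    )


# ---------------------------------------------------------------------------
# Dose–response


def _hill(c, e_max, ec50, h):
    c = np.asarray(c, dtype=float)
    return e_max * c**h / (ec50**h + c**h)


def dose_response_fit(
    conc: Iterable[float],
    effect: Iterable[float],
    fix_hill: bool = True,
) -> DoseResponseFit:
    """Hill fit of percent effect vs concentration (µM).

    With ``fix_hill=True`` (default) the coefficient is pinned at 1.  An
    all-zero effect returns a flagged, unidentifiable fit (EC50 NaN) rather
    than an arbitrary number.
    """
    c = np.asarray(list(conc), dtype=float)
    e = np.asarray(list(effect), dtype=float)
    if c.size < 3:
        raise FitError("need at least 3 concentrations")
    if np.any(c <= 0):
        raise FitError("concentrations must be positive")
    if np.max(np.abs(e)) < 1e-12:
        return DoseResponseFit(ec50=np.nan, e_max=0.0, residual=0.0, identifiable=False)
    model = Model(_hill)
    params = model.make_params(
        e_max=float(e[np.argmax(np.abs(e))]),
        ec50=float(np.median(c)),
        h=1.0,
    )
    params["ec50"].set(min=1e-9)
    params["h"].set(vary=not fix_hill, min=0.1, max=10.0)
    result = model.fit(e, params, c=c)
    if not result.success:
        raise FitError(f"dose-response fit did not converge: {result.message}", best=result)
    return DoseResponseFit(
        ec50=float(result.params["ec50"].value),
        e_max=float(result.params["e_max"].value),
        hill_h=float(result.params["h"].value),
        residual=float(np.sqrt(np.mean(result.residual**2))),
    )


# ---------------------------------------------------------------------------
# Synthetic traces


def simulate_traces(
    params: GatingParams,
    protocol: VoltageProtocol = PAPER_PROTOCOL,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_sample: float = 0.01,
) -> list[CurrentTrace]:
    """Synthetic current family for a step protocol.

    Per test potential V: biexponential activation toward a steady state
    scaled by the Boltzmann open probability P(V), then a biexponential
    (inward) tail at the tail potential whose initial amplitude is
    proportional to the open probability reached at the end of the test
    pulse.  Additive Gaussian noise, reproducible from ``seed``.
    """
    if dt_sample <= 0:
        raise ValueError("dt_sample must be positive")
    rng = np.random.default_rng(seed)
    t_test = np.arange(dt_sample, protocol.test_duration + dt_sample / 2, dt_sample)
    t_tail = np.arange(dt_sample, protocol.tail_duration + dt_sample / 2, dt_sample)
    ff, fs = params.frac_fast_act, 1.0 - params.frac_fast_act
    fd, sd_ = params.frac_fast_deact, 1.0 - params.frac_fast_deact
    act_shape = ff * (1.0 - np.exp(-t_test / params.tau_fast_act)) + fs * (
        1.0 - np.exp(-t_test / params.tau_slow_act)
    )
    act_end = float(act_shape[-1])
    tail_shape = fd * np.exp(-t_tail / params.tau_fast_deact) + sd_ * np.exp(
        -t_tail / params.tau_slow_deact
    )
    traces = []
    for v in protocol.test_potentials:
        p_open = float(_boltzmann(v, params.v_half, params.slope_k))
        i_test = params.g_max * p_open * act_shape
        i_tail = params.tail_amp * p_open * act_end * tail_shape
        time = np.concatenate([t_test, protocol.test_duration + t_tail])
        current = np.concatenate([i_test, i_tail])
        if noise_sd > 0:
            current = current + rng.normal(0.0, noise_sd, current.shape)
        traces.append(CurrentTrace(time=time, current=current, test_potential=float(v)))
    return traces


# ---------------------------------------------------------------------------
# Trace I/O (2-column delimited text)


def write_trace(trace: CurrentTrace, path) -> None:
    """Write time (s) / current (µA) as tab-separated text with a header."""
    header = f"# test_potential_mV = {trace.test_potential}\n# time_s\tcurrent_uA"
    np.savetxt(
        path,
        np.column_stack([trace.time, trace.current]),
        delimiter="\t",
        header=header,
        comments="",
    )


def read_trace(path, test_potential: float | None = None) -> CurrentTrace:
    v = test_potential
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            if "test_potential_mV" in line and v is None:
                v = float(line.split("=")[1])
            continue
        if line.strip() and not line.lstrip()[0].isalpha():
            data_lines.append(line)
    if v is None:
        raise FitError(f"{path}: no test potential in header and none given")
    data = np.loadtxt(data_lines, delimiter="\t", ndmin=2)
    return CurrentTrace(time=data[:, 0], current=data[:, 1], test_potential=v)
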