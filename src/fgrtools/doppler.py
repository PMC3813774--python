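"""Umbilical Doppler velocimetry: cycle detection, PSV/MDV/MV, and the
pulsatility index PI = (PSV − MDV)/MV.

PSV is the peak systolic velocity, MDV the minimum (end) diastolic velocity
— the two names are used interchangeably for the waveform minimum — and MV
the time-averaged velocity over the cycle.  Measures are taken per cardiac
cycle, require at least 3 cycles to be reportable, and are averaged across
cycles before the PI is formed (the mean of per-cycle PIs is reported
alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic import VelocityTrace

logger = logging.getLogger("fgrtools")

DEFAULT_PROMINENCE = 0.2  # fraction of trace amplitude
MIN_CYCLES = 3


class TooFewCyclesError(ValueError):
    """Raised when a trace does not contain enough cardiac cycles."""


@dataclass
class CycleMeasures:
    """Cycle-averaged velocimetry for one trace."""

    trace_id: str
    psv: float  # mm/s, mean of per-cycle maxima
    mdv: float  # mm/s, mean of per-cycle minima
    mv: float  # mm/s, mean of per-cycle time-averages
    pi: float  # (psv - mdv) / mv from the cycle-averaged values
    pi_per_cycle_mean: float  # mean of per-cycle PIs (alternative order)
    n_cycles: int


def find_cycle_peaks(
    trace: VelocityTrace, prominence: float = DEFAULT_PROMINENCE
) -> np.ndarray:
    """Indices of systolic peaks, prominence-filtered at ``prominence`` of
    the trace amplitude.  Shift-invariant by construction."""
    v = np.asarray(trace.velocities, dtype=float)
    amplitude = float(np.ptp(v))
    if amplitude <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(v, prominence=prominence * amplitude)
    return peaks


def detect_cycles(
    trace: VelocityTrace,
    prominence: float = DEFAULT_PROMINENCE,
    min_cycles: int = MIN_CYCLES,
) -> list[slice]:
    """Peak-to-peak cycle segments (n_peaks − 1 full segments).

    Raises :class:`TooFewCyclesError` when fewer than ``min_cycles`` full
    segments are found — such a trace is unreportable.
    """
    peaks = find_cycle_peaks(trace, prominence)
    segments = [
        slice(int(a), int(b) + 1) for a, b in zip(peaks[:-1], peaks[1:])
    ]
    if len(segments) < min_cycles:
        raise TooFewCyclesError(
            f"{trace.trace_id}: {len(segments)} full cycle(s) detected, "
            f"need at least {min_cycles}"
        )
    return segments


def cycle_measures(
    times: np.ndarray, velocities: np.ndarray
) -> tuple[float, float, float]:
    """(psv, mdv, mv) for one cycle segment: max, min, and trapezoidal
    time-average."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if len(v) < 4:
        raise ValueError("cycle segment needs at least 4 samples")
    mv = float(np.trapezoid(v, t) / (t[-1] - t[0]))
    return float(v.max()), float(v.min()), mv


def pulsatility_index(psv: float, mdv: float, mv: float) -> float:
    """PI = (PSV − MDV)/MV; dimensionless, invariant under rescaling all
    three velocities."""
    if mv <= 0:
        raise ValueError("mean velocity must be > 0 (non-physiological trace)")
    return (psv - mdv) / mv


def aggregate_trace(
    trace: VelocityTrace,
    prominence: float = DEFAULT_PROMINENCE,
    min_cycles: int = MIN_CYCLES,
) -> CycleMeasures:
    """Average per-cycle PSV/MDV/MV across cycles and compute PI from the
    averages; the alternative order (mean of per-cycle PIs) is reported
    alongside for comparison."""
    segments = detect_cycles(trace, prominence, min_cycles)
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.velocities, dtype=float)
    per_cycle = np.array(
        [cycle_measures(t[s], v[s]) for s in segments]
    )  # columns: psv, mdv, mv
    psv, mdv, mv = per_cycle.mean(axis=0)
    pis = [(p - d) / m for p, d, m in per_cycle]
    return CycleMeasures(
        trace_id=trace.trace_id,
        psv=float(psv),
        mdv=float(mdv),
        mv=float(mv),
        pi=pulsatility_index(psv, mdv, mv),
        pi_per_cycle_mean=float(np.mean(pis)),
        n_cycles=len(segments),
    )
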