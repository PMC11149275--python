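"""Partition a ramp-hold-unload indentation record into protocol phases.

The detector classifies the smoothed displacement rate against the protocol
ramp rate (within +/-40% of +v for loading, |rate| < 10% of v for hold,
within +/-40% of -v for unloading, all configurable), then refines each
boundary to the intersection of the fitted ramp line with the adjacent
displacement plateau.  On noise-free protocol curves the refined boundaries
are exact to the sample.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .curves import IndentationCurve, ProtocolSpec
from .errors import SegmentationError, ValidationError


class Phase(enum.Enum):
    PRELOAD = "preload"
    LOADING = "loading"
    HOLD = "hold"
    UNLOADING = "unloading"


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open index ranges partitioning one curve into the four phases."""

    loading_start: int
    loading_end: int
    hold_end: int
    n_samples: int

    def __post_init__(self):
        if not (0 < self.loading_start < self.loading_end < self.hold_end < self.n_samples):
            raise ValidationError(
                f"phase boundaries not ordered/non-empty: "
                f"0 < {self.loading_start} < {self.loading_end} < "
                f"{self.hold_end} < {self.n_samples}")

    @property
    def preload(self) -> tuple[int, int]:
        return (0, self.loading_start)

    @property
    def loading(self) -> tuple[int, int]:
        return (self.loading_start, self.loading_end)

    @property
    def hold(self) -> tuple[int, int]:
        return (self.loading_end, self.hold_end)

    @property
    def unloading(self) -> tuple[int, int]:
        return (self.hold_end, self.n_samples)

    def range_of(self, phase: Phase) -> tuple[int, int]:
        return getattr(self, phase.value)

    def to_json(self, curve: IndentationCurve | None = None) -> str:
        d = {p.value: list(self.range_of(p)) for p in Phase}
        if curve is not None:
            t = curve.time
            for p in Phase:
                a, b = self.range_of(p)
                d[p.value + "_duration_s"] = float(t[b - 1] - t[a])
        return json.dumps(d, indent=2)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs (half-open)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _nearest_index(t: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(t - value)))


def segment_phases(curve: IndentationCurve, protocol: ProtocolSpec | None = None,
                   rate_tolerance: float = 0.40, hold_rate_fraction: float = 0.10,
                   median_window: int = 5, rate_smooth_s: float = 0.09,
                   min_hold_fraction: float = 0.5) -> PhaseSegmentation:
    """Locate preload / loading / hold / unloading ranges in a curve.

    Raises :class:`SegmentationError` ("protocol mismatch") when no region
    matches the ramp signature, or when the detected hold is shorter than
    ``min_hold_fraction`` of the protocol hold duration.
    """
    if protocol is None:
        protocol = ProtocolSpec()
    t, x = curve.time, curve.displacement
    fs = curve.sampling_rate
    if fs < 20.0:
        raise SegmentationError(
            f"sampling rate {fs:.1f} Hz too low (need >= 20 Hz)")
    v = protocol.ramp_rate_um_per_s

    xs = median_filter(x, size=median_window, mode="nearest")
    w = max(3, int(round(rate_smooth_s * fs)) | 1)
    xs = uniform_filter1d(xs, size=w, mode="nearest")
    rate = np.gradient(xs, t)

    lo, hi = (1.0 - rate_tolerance) * v, (1.0 + rate_tolerance) * v
    load_runs = [r for r in _runs((rate >= lo) & (rate <= hi))
                 if x[min(r[1], len(x) - 1)] - x[r[0]] > 0.3 * protocol.ramp_depth_um]
    if not load_runs:
        raise SegmentationError("protocol mismatch: no loading-ramp signature found")
    L0r, L1r = max(load_runs, key=lambda r: x[min(r[1], len(x) - 1)] - x[r[0]])

    unload_runs = [r for r in _runs((rate <= -lo) & (rate >= -hi)) if r[0] >= L1r]
    if not unload_runs:
        raise SegmentationError("protocol mismatch: no unloading-ramp signature found")
    U0r, U1r = unload_runs[0]

    if L0r < 1:
        raise SegmentationError("protocol mismatch: no preload region before ramp")

    # refine corners: intersect fitted ramp lines with adjacent plateaus
    pre_level = float(np.median(xs[max(0, L0r - int(fs)):L0r]))
    hold_level = float(np.median(xs[L1r:U0r])) if U0r > L1r else float(xs[L1r])

    def _line(a: int, b: int):
        span = b - a
        aa, bb = a + span // 5, b - span // 5
        coef = np.polyfit(t[aa:bb], x[aa:bb], 1)
        return coef  # slope, intercept

    m_l, b_l = _line(L0r, L1r)
    if m_l <= 0:
        raise SegmentationError("protocol mismatch: loading ramp has no positive slope")
    t_load0 = (pre_level - b_l) / m_l
    t_load1 = (hold_level - b_l) / m_l
    m_u, b_u = _line(U0r, U1r)
    t_unload0 = (hold_level - b_u) / m_u

    L0 = _nearest_index(t, t_load0)
    L1 = _nearest_index(t, t_load1)
    H1 = _nearest_index(t, t_unload0)
    seg = PhaseSegmentation(loading_start=L0, loading_end=L1, hold_end=H1,
                            n_samples=len(curve))

    rise = x[L1] - x[L0]
    if abs(rise - protocol.ramp_depth_um) > 0.3 * protocol.ramp_depth_um:
        raise SegmentationError(
            f"protocol mismatch: ramp rise {rise:.1f} um vs expected "
            f"{protocol.ramp_depth_um} um")
    hold_dur = t[H1 - 1] - t[L1]
    if hold_dur < min_hold_fraction * protocol.hold_duration_s:
        raise SegmentationError(
            f"hold phase {hold_dur:.2f} s shorter than "
            f"{min_hold_fraction} x {protocol.hold_duration_s} s")
    return seg


def extract_phase(curve: IndentationCurve, seg: PhaseSegmentation, phase: Phase,
                  rezero: bool = True, rezero_load: bool = True) -> IndentationCurve:
    """Slice one phase out of a curve.

    Time is re-zeroed to the phase start.  Displacement (and, by default,
    load) are re-zeroed to the end-of-preload state, so the ramp runs
    0 -> ramp_depth and moduli are incremental above the preload.
    """
    a, b = seg.range_of(phase)
    if b - a <= 0:
        raise SegmentationError(f"phase {phase.value} is empty")
    t = curve.time[a:b] - curve.time[a]
    x = curve.displacement[a:b].copy()
    p = curve.load[a:b].copy()
    if rezero:
        i0 = seg.loading_start
        j = max(0, i0 - 5)
        x -= float(np.median(curve.displacement[j:i0]))
        if rezero_load:
            p -= float(np.median(curve.load[j:i0]))
    return IndentationCurve(time=t, displacement=x, load=p,
                            sample_id=f"{curve.sample_id}:{phase.value}",
                            sampling_rate_hint=curve.sampling_rate_hint,
                            min_samples=5)
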