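"""Fluorescence recovery after photobleaching (FRAP) analysis.

Traces are integrated intensities of the bleached region, already
background-subtracted (background measured from a neighbouring region).
Normalization maps the prebleach plateau to 1 and the post-bleach floor to
0:

    I_norm(t) = (I(t) - I(0)) / (I(prebleach) - I(0))

where I(prebleach) is the average over the prebleach window and I(0) is the
single first post-bleach sample.  Negative normalized values are permitted
and never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class FRAPTrace:
    """A bleach-recovery time series.

    ``bleach_index`` is the index of the first post-bleach sample; samples
    before it form the prebleach window (must be non-empty).
    """

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time_s and intensity must have the same shape")
        if self.bleach_index < 1 or self.bleach_index >= self.time_s.size:
            raise ValueError("prebleach window must be non-empty and bleach within the trace")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    def post_times_s(self) -> np.ndarray:
        """Times relative to the bleach (t = 0 at the first post-bleach sample)."""
        return self.time_s - self.time_s[self.bleach_index]


def normalize(trace: FRAPTrace, prebleach_window: int | None = None) -> FRAPTrace:
    """Normalize a trace to prebleach = 1, post-bleach floor = 0.

    ``prebleach_window`` limits the prebleach average to the last N
    prebleach samples (all of them by default).  Rejects traces with zero
    bleach depth (prebleach average equal to the first post-bleach sample),
    for which the normalization is undefined.
    """
    i0 = trace.intensity[trace.bleach_index]
    pre = trace.intensity[: trace.bleach_index]
    if prebleach_window is not None:
        pre = pre[-prebleach_window:]
    i_pre = float(np.mean(pre))
    denom = i_pre - i0
    if denom == 0:
        raise ValueError("zero bleach depth: prebleach equals first post-bleach sample")
    return replace(trace, intensity=(trace.intensity - i0) / denom, normalized=True)


def recovery_stats(trace: FRAPTrace, horizon_s: float) -> tuple[float, float]:
    """Maximum post-bleach recovery and recovery at ``horizon_s``, in percent.

    ``horizon_s`` is measured from the bleach; the trace must extend to it.
    """
    if not trace.normalized:
        trace = normalize(trace)
    t = trace.post_times_s()
    post = trace.intensity[trace.bleach_index :]
    t_post = t[trace.bleach_index :]
    if horizon_s > t_post[-1]:
        raise ValueError(f"horizon {horizon_s} s beyond trace end at {t_post[-1]} s")
    max_recovery = 100.0 * float(np.max(post))
    at = int(np.argmin(np.abs(t_post - horizon_s)))
    return max_recovery, 100.0 * float(post[at])


def average_traces(traces: list[FRAPTrace]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and SD over normalized traces, bleach-aligned.

    Traces are aligned so t = 0 at the first post-bleach sample; traces on
    differing grids are resampled onto the first trace's grid by linear
    interpolation.  Returns ``(time_s, mean, sd)`` with SD computed with
    one delta degree of freedom.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces to average")
    traces = [t if t.normalized else normalize(t) for t in traces]
    grid = traces[0].post_times_s()
    stack = [traces[0].intensity]
    for tr in traces[1:]:
        t = tr.post_times_s()
        if t.shape == grid.shape and np.allclose(t, grid):
            stack.append(tr.intensity)
        else:
            stack.append(np.interp(grid, t, tr.intensity))
    arr = np.vstack(stack)
    return grid, arr.mean(axis=0), arr.std(axis=0, ddof=1)
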