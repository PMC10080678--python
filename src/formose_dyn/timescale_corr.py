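"""Multi-timescale windowed-differential correlation of traces to the input.

For each window width w (default 30, 60, 90, 120, 150 s) the time axis
is tiled with consecutive non-overlapping windows; the per-window mean
of each signal is differenced between consecutive windows, the
differential vector is standardised (mean 0, population SD 1), and the
Pearson correlation between the standardised input and output
differentials is reported per compound per width.  A positive entry
means the compound's concentration moves with the input on that
timescale, a negative one means it moves against it.

A partial trailing window (span not divisible by the width) is dropped;
trailing windows that contain no sample (a tiling artifact at the very
end of the record) are dropped too, while an *interior* empty window is
an error, since silently skipping it would misalign the differentials.
An overlapping-stride mode is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .crn_sim import TraceSet
from .flow_program import StepSignal

__all__ = [
    "TimescaleError",
    "DifferentialVector",
    "NormalizedDifferential",
    "CorrelationMap",
    "resample_to",
    "windowed_differential",
    "normalize_differential",
    "timescale_correlations",
    "correlate_traces_to_input",
    "DEFAULT_WINDOWS",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOWS = (30.0, 60.0, 90.0, 120.0, 150.0)


class TimescaleError(ValueError):
    """Invalid windowing or correlation parameters."""


@dataclass
class DifferentialVector:
    window_width: float
    values: np.ndarray  # consecutive differences of window means
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise TimescaleError("differential vector contains non-finite values")


@dataclass
class NormalizedDifferential:
    window_width: float
    values: np.ndarray  # z-scores (population SD)
    source_id: str = ""


@dataclass
class CorrelationMap:
    """Compounds x window-widths matrix of Pearson r to the input."""

    compound_ids: list[str]
    window_widths: list[float]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.compound_ids), len(self.window_widths)):
            raise TimescaleError("correlation map shape mismatch")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise TimescaleError("Pearson r out of [-1, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.r, index=self.compound_ids,
                            columns=[f"{w:g}" for w in self.window_widths])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="compound_id")


def resample_to(signal, target_times: np.ndarray) -> np.ndarray:
    """Linearly interpolate a signal onto a target time axis.

    ``signal`` is either a ``StepSignal`` (its step knots are the
    interpolation nodes) or a ``(times, values)`` pair.  Requests
    outside the signal's span raise, rather than extrapolating.
    """
    if isinstance(signal, StepSignal):
        # step-start knots, plus a final hold point so the last step is covered
        times = np.append(signal.step_times, signal.end_time)
        values = np.append(signal.values, signal.values[-1])
    else:
        times, values = signal
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
    target = np.asarray(target_times, dtype=float)
    if target.min() < times[0] - 1e-9 or target.max() > times[-1] + 1e-9:
        raise TimescaleError(
            f"resampling target [{target.min():g}, {target.max():g}] s exceeds "
            f"signal span [{times[0]:g}, {times[-1]:g}] s"
        )
    return np.interp(target, times, values)


def windowed_differential(
    trace: np.ndarray,
    times: np.ndarray,
    window_width: float,
    source_id: str = "",
    stride: float | None = None,
) -> DifferentialVector:
    """First differences of consecutive window means of a sampled signal.

    Windows are ``[t0 + i*stride, t0 + i*stride + w)`` with
    ``stride = w`` by default (consecutive tiling).  The number of
    windows is ``floor(total_span / stride)`` where the total span
    counts one sample spacing beyond the last sample.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape or trace.ndim != 1:
        raise TimescaleError("trace and times must be 1-D and of equal length")
    if window_width <= 0:
        raise TimescaleError("window width must be positive")
    stride = window_width if stride is None else float(stride)
    if not 0 < stride <= window_width:
        raise TimescaleError("stride must be in (0, window_width]")
    dt = float(np.median(np.diff(times))) if times.size > 1 else window_width
    span = times[-1] - times[0] + dt
    if span < 2 * window_width:
        raise TimescaleError("trace span must cover at least two windows")
    n_win = int(np.floor((span - window_width) / stride)) + 1
    t0 = times[0]
    means = np.empty(n_win)
    counts = np.empty(n_win, dtype=int)
    for i in range(n_win):
        lo = t0 + i * stride
        mask = (times >= lo - 1e-9) & (times < lo + window_width - 1e-9)
        counts[i] = mask.sum()
        means[i] = trace[mask].mean() if counts[i] else np.nan
    # trailing empty windows are tiling artifacts; interior ones are errors
    while n_win and counts[-1] == 0:
        n_win -= 1
        means, counts = means[:-1], counts[:-1]
        log.info("dropped empty trailing window for %s at w=%gs", source_id, window_width)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise TimescaleError(
            f"window {empty[0]} (w={window_width:g}s) of {source_id or 'trace'} "
            "contains no samples"
        )
    if n_win < 2:
        raise TimescaleError("fewer than two non-empty windows")
    return DifferentialVector(window_width=window_width,
                              values=np.diff(means), source_id=source_id)


def normalize_differential(x: DifferentialVector) -> NormalizedDifferential:
    """Standardise a differential vector (mean 0, population SD 1)."""
    sd = float(np.std(x.values))
    if sd == 0.0:
        raise TimescaleError(
            f"constant differential for {x.source_id or 'trace'}; normalisation undefined"
        )
    return NormalizedDifferential(
        window_width=x.window_width,
        values=(x.values - x.values.mean()) / sd,
        source_id=x.source_id,
    )


def timescale_correlations(
    input_trace: np.ndarray,
    traces: TraceSet,
    window_widths=DEFAULT_WINDOWS,
    stride: float | None = None,
) -> CorrelationMap:
    """Pearson r between input and compound windowed differentials per width.

    ``input_trace`` must already share the trace time axis (use
    :func:`resample_to` or :func:`correlate_traces_to_input`).
    """
    input_trace = np.asarray(input_trace, dtype=float)
    if input_trace.shape != traces.times.shape:
        raise TimescaleError("input trace must share the trace time axis")
    widths = [float(w) for w in window_widths]
    r = np.empty((traces.n_compounds, len(widths)))
    for j, w in enumerate(widths):
        try:
            v_in = normalize_differential(
                windowed_differential(input_trace, traces.times, w,
                                      source_id="input", stride=stride))
        except TimescaleError as err:
            raise TimescaleError(f"input at w={w:g}s: {err}") from err
        for i, cid in enumerate(traces.compound_ids):
            try:
                v_out = normalize_differential(
                    windowed_differential(traces.concentrations[i], traces.times,
                                          w, source_id=cid, stride=stride))
            except TimescaleError as err:
                raise TimescaleError(f"{cid} at w={w:g}s: {err}") from err
            r[i, j] = sps.pearsonr(v_in.values, v_out.values).statistic
    return CorrelationMap(compound_ids=list(traces.compound_ids),
                          window_widths=widths, r=r)


def correlate_traces_to_input(
    input_signal: StepSignal,
    traces: TraceSet,
    window_widths=DEFAULT_WINDOWS,
    stride: float | None = None,
) -> CorrelationMap:
    """Resample a step input onto the trace time axis, then correlate."""
    resampled = resample_to(input_signal, traces.times)
    return timescale_correlations(resampled, traces, window_widths, stride=stride)
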