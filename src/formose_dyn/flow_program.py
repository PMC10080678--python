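"""Dynamic Ca(OH)2 input programs for a CSTR and their flow-schedule realisation.

The environmental "input" applied to the reactor is a stepwise-constant
CaCl2 inlet concentration whose step values are drawn from a Gaussian
(mean 15 mM by default), with NaOH co-varied to hold a 1:2 Ca2+:HO-
ratio and a water channel balancing the total flow so the residence
time stays constant.  Multi-timescale inputs are built by superimposing
several independently drawn step signals and affinely rescaling the sum
back to a target mean and standard deviation.

Conventions
-----------
* Step signals are piecewise constant, left-closed / right-open, with
  times in seconds from the program start.
* Concentrations are in mM, volumes in uL, flows in uL/s.
* Negative Gaussian draws are clipped to zero (physical concentration);
  the number of clipped steps is recorded on the returned signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowProgramError",
    "StepSignal",
    "InletSpec",
    "ReactorSpec",
    "FlowProgram",
    "sample_step_signal",
    "superimpose_signals",
    "program_flows",
]

#: Relative tolerance on the constant-total-flow invariant.
FLOW_RTOL = 1e-9


class FlowProgramError(ValueError):
    """Invalid parameters or infeasible inlet targets."""


@dataclass
class StepSignal:
    """Piecewise-constant concentration-versus-time program for one inlet.

    Attributes
    ----------
    step_times : array of float
        Left edges of the steps, seconds; strictly increasing, uniformly
        spaced by ``step_interval``.
    values : array of float
        Concentration held during each step, mM (``>= 0``).
    step_interval : float
        Step duration, seconds.
    mean_target, sigma_target : float
        Parameters of the generating distribution (book-keeping).
    n_clipped : int
        Number of draws clipped at zero (or at a feasibility ceiling).
    raw_values : array or None
        The unclipped draws, kept so pre-clipping statistics can be
        reported.
    """

    step_times: np.ndarray
    values: np.ndarray
    step_interval: float
    mean_target: float = np.nan
    sigma_target: float = np.nan
    n_clipped: int = 0
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.step_times.ndim != 1 or self.step_times.size == 0:
            raise FlowProgramError("step_times must be a non-empty 1-D array")
        if self.values.shape != self.step_times.shape:
            raise FlowProgramError("values and step_times must have equal length")
        if self.step_interval <= 0:
            raise FlowProgramError("step_interval must be positive")
        if self.step_times.size > 1:
            dt = np.diff(self.step_times)
            if np.any(dt <= 0):
                raise FlowProgramError("step_times must be strictly increasing")
            if not np.allclose(dt, self.step_interval, rtol=1e-9, atol=1e-9):
                raise FlowProgramError("step_times must be uniformly spaced by step_interval")
        if np.any(self.values < 0):
            raise FlowProgramError("step values must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Total covered time span in seconds."""
        return float(self.step_times[-1] + self.step_interval - self.step_times[0])

    @property
    def end_time(self) -> float:
        return float(self.step_times[-1] + self.step_interval)

    def __call__(self, t):
        """Evaluate the signal at time(s) ``t`` (left-closed steps)."""
        t = np.asarray(t, dtype=float)
        t0, t1 = self.step_times[0], self.end_time
        if np.any(t < t0) or np.any(t >= t1):
            raise FlowProgramError(
                f"evaluation time outside program span [{t0}, {t1})"
            )
        idx = np.searchsorted(self.step_times, t, side="right") - 1
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def boundaries(self) -> np.ndarray:
        """All step edges including the final right edge."""
        return np.append(self.step_times, self.end_time)


@dataclass
class InletSpec:
    """Stock solutions and target inlet concentrations for the five channels.

    ``ca_to_oh_ratio`` is the fixed Ca2+:HO- ratio of 1:2, stored as 0.5.
    """

    stock_formaldehyde: float = 198.0
    stock_dha: float = 198.0
    stock_naoh: float = 240.0
    stock_cacl2: float = 120.0
    formaldehyde_in: float = 50.0
    dha_in: float = 50.0
    ca_in_mean: float = 15.0
    ca_to_oh_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.ca_to_oh_ratio != 0.5:
            raise FlowProgramError("ca_to_oh_ratio is fixed at 1:2 (0.5)")
        pairs = [
            ("formaldehyde", self.formaldehyde_in, self.stock_formaldehyde),
            ("DHA", self.dha_in, self.stock_dha),
            ("CaCl2", self.ca_in_mean, self.stock_cacl2),
            ("NaOH", self.ca_in_mean / self.ca_to_oh_ratio, self.stock_naoh),
        ]
        for name, target, stock in pairs:
            if stock <= 0:
                raise FlowProgramError(f"{name} stock must be positive")
            if target < 0:
                raise FlowProgramError(f"{name} inlet target must be non-negative")
            if target > stock:
                raise FlowProgramError(
                    f"{name} inlet target {target} mM exceeds stock {stock} mM"
                )


@dataclass
class ReactorSpec:
    """CSTR geometry and hydrodynamics; temperature is metadata only."""

    volume_uL: float = 411.0
    residence_time_s: float = 120.0
    temperature_C: float = 21.0

    def __post_init__(self) -> None:
        if self.volume_uL <= 0 or self.residence_time_s <= 0:
            raise FlowProgramError("volume and residence time must be positive")

    @property
    def total_flow(self) -> float:
        """Implied constant total flow V / tau in uL/s."""
        return self.volume_uL / self.residence_time_s


CHANNELS = ("formaldehyde", "dha", "naoh", "cacl2", "water")


@dataclass
class FlowProgram:
    """Per-channel volumetric flow schedules realising an inlet program."""

    flow_schedules: dict[str, StepSignal]
    reactor: ReactorSpec
    inlet: InletSpec
    ca_inlet: StepSignal = None  # implied (post-clipping) CaCl2 inlet, mM
    n_clipped: int = 0

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.flow_schedules)

    @property
    def step_times(self) -> np.ndarray:
        return self.ca_inlet.step_times

    def implied_inlet(self, channel: str) -> np.ndarray:
        """Per-step implied inlet concentration (mM) of a solute channel."""
        if channel == "water":
            raise FlowProgramError("water carries no solute")
        stock = {
            "formaldehyde": self.inlet.stock_formaldehyde,
            "dha": self.inlet.stock_dha,
            "naoh": self.inlet.stock_naoh,
            "cacl2": self.inlet.stock_cacl2,
        }[channel]
        flows = self.flow_schedules[channel].values
        return flows * stock / self.reactor.total_flow

    def inlet_concentration_signal(self, channel: str) -> StepSignal:
        """The implied inlet concentration of a solute as a StepSignal."""
        ca = self.ca_inlet
        return StepSignal(
            step_times=ca.step_times.copy(),
            values=self.implied_inlet(channel),
            step_interval=ca.step_interval,
        )

    def to_frame(self):
        """Tabular view: flows per channel plus implied inlet concentrations."""
        import pandas as pd

        data = {"time_s": self.step_times}
        for ch in CHANNELS:
            data[f"F_{ch}"] = self.flow_schedules[ch].values
        for ch in ("formaldehyde", "dha", "naoh", "cacl2"):
            data[f"c_in_{ch}"] = self.implied_inlet(ch)
        return pd.DataFrame(data)


def sample_step_signal(
    mean: float,
    sigma: float,
    step_interval: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> StepSignal:
    """Draw a stepwise-Gaussian inlet concentration program.

    ``floor(duration / step_interval)`` independent draws from
    ``N(mean, sigma^2)``, truncated at zero from below.  Deterministic
    for a given integer seed.
    """
    if sigma < 0:
        raise FlowProgramError("sigma must be non-negative")
    if step_interval <= 0:
        raise FlowProgramError("step_interval must be positive")
    if duration < step_interval:
        raise FlowProgramError("duration must cover at least one step")
    n = int(np.floor(duration / step_interval))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = mean + sigma * rng.standard_normal(n) if sigma > 0 else np.full(n, float(mean))
    values = np.maximum(raw, 0.0)
    n_clipped = int(np.count_nonzero(raw < 0))
    return StepSignal(
        step_times=np.arange(n) * float(step_interval),
        values=values,
        step_interval=float(step_interval),
        mean_target=float(mean),
        sigma_target=float(sigma),
        n_clipped=n_clipped,
        raw_values=raw,
    )


def superimpose_signals(
    components: list[StepSignal],
    target_sigma: float,
    target_mean: float,
    weights: list[float] | None = None,
) -> StepSignal:
    """Combine step signals on the finest common grid and rescale.

    The weighted sum (equal weights by default) is evaluated on the grid
    of the component with the smallest step interval, then affinely
    rescaled so its mean equals ``target_mean`` and its population SD
    equals ``target_sigma`` over the overlapping duration.  Values are
    clipped at zero afterwards (count recorded).
    """
    if len(components) < 2:
        raise FlowProgramError("need at least two components to superimpose")
    if target_sigma < 0:
        raise FlowProgramError("target_sigma must be non-negative")
    if weights is None:
        weights = [1.0 / len(components)] * len(components)
    if len(weights) != len(components):
        raise FlowProgramError("one weight per component required")

    interval = min(c.step_interval for c in components)
    start = max(c.step_times[0] for c in components)
    end = min(c.end_time for c in components)
    if end - start < interval:
        raise FlowProgramError("components do not overlap in time")
    grid = start + np.arange(int(np.floor((end - start) / interval))) * interval
    combined = sum(w * c(grid) for w, c in zip(weights, components))

    sd = float(np.std(combined))
    if target_sigma == 0.0:
        rescaled = np.full_like(combined, float(target_mean))
    elif sd == 0.0:
        raise FlowProgramError("combined signal has zero variance; cannot rescale")
    else:
        rescaled = (combined - combined.mean()) * (target_sigma / sd) + target_mean
    values = np.maximum(rescaled, 0.0)
    return StepSignal(
        step_times=grid,
        values=values,
        step_interval=float(interval),
        mean_target=float(target_mean),
        sigma_target=float(target_sigma),
        n_clipped=int(np.count_nonzero(rescaled < 0)),
        raw_values=rescaled,
    )


def program_flows(
    ca_signal: StepSignal,
    inlet: InletSpec | None = None,
    reactor: ReactorSpec | None = None,
) -> FlowProgram:
    """Convert a CaCl2 inlet concentration program into balanced channel flows.

    Per step: the formaldehyde and DHA channels run at fixed fractions of
    the total flow, the CaCl2 channel tracks the signal, NaOH is slaved
    to twice the Ca inlet concentration, and water absorbs the remainder
    so that the total equals ``V / tau`` exactly.  Steps whose Ca draw
    would drive the water flow negative are clipped jointly (Ca and NaOH
    reduced together, preserving the 1:2 ratio) to the feasibility
    ceiling; the number of clipped steps is recorded.
    """
    inlet = inlet or InletSpec()
    reactor = reactor or ReactorSpec()
    f_total = reactor.total_flow

    frac_fa = inlet.formaldehyde_in / inlet.stock_formaldehyde
    frac_dha = inlet.dha_in / inlet.stock_dha
    fixed = frac_fa + frac_dha
    # concentration ceiling at which the water channel reaches zero flow
    ca_max = (1.0 - fixed) / (1.0 / inlet.stock_cacl2 + 2.0 / inlet.stock_naoh)

    mean_frac = fixed + inlet.ca_in_mean / inlet.stock_cacl2 \
        + 2.0 * inlet.ca_in_mean / inlet.stock_naoh
    if mean_frac > 1.0:
        raise FlowProgramError(
            f"inlet targets infeasible at the signal mean (flow fraction {mean_frac:.3f} > 1)"
        )

    ca = np.minimum(ca_signal.values, ca_max)
    n_clipped = int(np.count_nonzero(ca_signal.values > ca_max))

    f_fa = np.full_like(ca, f_total * frac_fa)
    f_dha = np.full_like(ca, f_total * frac_dha)
    f_ca = f_total * ca / inlet.stock_cacl2
    f_oh = f_total * 2.0 * ca / inlet.stock_naoh
    f_water = f_total - (f_fa + f_dha + f_ca + f_oh)
    # exact balance up to floating point; guard against tiny negatives
    f_water = np.where(np.abs(f_water) < f_total * FLOW_RTOL, 0.0, f_water)
    if np.any(f_water < 0):
        raise FlowProgramError("internal error: negative water flow after clipping")

    times = ca_signal.step_times
    interval = ca_signal.step_interval

    def sig(v: np.ndarray) -> StepSignal:
        return StepSignal(step_times=times.copy(), values=v, step_interval=interval)

    schedules = {
        "formaldehyde": sig(f_fa),
        "dha": sig(f_dha),
        "naoh": sig(f_oh),
        "cacl2": sig(f_ca),
        "water": sig(f_water),
    }
    ca_inlet = StepSignal(
        step_times=times.copy(),
        values=ca,
        step_interval=interval,
        mean_target=ca_signal.mean_target,
        sigma_target=ca_signal.sigma_target,
    )
    return FlowProgram(
        flow_schedules=schedules,
        reactor=reactor,
        inlet=inlet,
        ca_inlet=ca_inlet,
        n_clipped=n_clipped,
    )
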