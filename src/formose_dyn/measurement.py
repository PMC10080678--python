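"""GC-MS-style quantification rules: quadratic calibration, averaged
fallback curves, and largest-of-two-peaks selection.

A calibration curve maps a chromatographic peak integral A to a
concentration ``c = a*A**2 + b*A + c0`` (mM) and must be monotone
increasing over its declared working range.  Compounds without their
own calibration use the coefficient-wise mean of the curves for
compounds of similar molecular weight (grouped by carbon count).  The
module also provides the forward direction — synthesising peak tables
from concentration traces by inverting the quadratic — so the whole
pipeline can be exercised end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crn_sim import TraceSet

__all__ = [
    "MeasurementError",
    "CalibrationCurve",
    "PeakTable",
    "quantify",
    "averaged_curve",
    "synthesize_peaks",
    "default_curves",
    "load_curves",
    "save_curves",
]

log = logging.getLogger(__name__)


class MeasurementError(ValueError):
    """Calibration or quantification failure."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic peak-integral -> concentration calibration."""

    compound_id: str
    a: float
    b: float
    c: float
    area_max: float = 1e4  # declared working range [0, area_max]
    mw_class: int = 0      # carbon-count class used for averaging
    averaged: bool = False

    def __post_init__(self):
        if self.area_max <= 0:
            raise MeasurementError(f"{self.compound_id}: empty working range")
        # monotone increasing over [0, area_max]: derivative 2aA + b > 0
        lo = self.b
        hi = 2 * self.a * self.area_max + self.b
        if lo <= 0 or hi <= 0:
            raise MeasurementError(
                f"{self.compound_id}: calibration not monotone increasing on "
                f"[0, {self.area_max:g}]"
            )

    def concentration(self, area) -> np.ndarray:
        area = np.asarray(area, dtype=float)
        return self.a * area ** 2 + self.b * area + self.c

    def area(self, conc) -> np.ndarray:
        """Invert the quadratic on the monotone working range."""
        conc = np.asarray(conc, dtype=float)
        if self.a == 0.0:
            area = (conc - self.c) / self.b
        else:
            disc = self.b ** 2 - 4.0 * self.a * (self.c - conc)
            if np.any(disc < 0):
                raise MeasurementError(
                    f"{self.compound_id}: concentration outside invertible range"
                )
            area = (-self.b + np.sqrt(disc)) / (2.0 * self.a)
        if np.any(area < -1e-9) or np.any(area > self.area_max * (1 + 1e-9)):
            raise MeasurementError(
                f"{self.compound_id}: concentration maps outside the working range"
            )
        return area


@dataclass
class PeakTable:
    """Integrated peaks of one sample: (compound_id, peak_integral, peak_index)."""

    sample_id: str
    rows: pd.DataFrame  # columns compound_id, peak_integral, peak_index

    def __post_init__(self):
        required = {"compound_id", "peak_integral", "peak_index"}
        if not required.issubset(self.rows.columns):
            raise MeasurementError(f"peak table needs columns {sorted(required)}")
        if (self.rows["peak_integral"] < 0).any():
            raise MeasurementError("peak integrals must be non-negative")


def averaged_curve(curves: list[CalibrationCurve],
                   compound_id: str = "averaged") -> CalibrationCurve:
    """Coefficient-wise mean of calibrations for similar-weight compounds."""
    if len(curves) < 2:
        raise MeasurementError("averaging requires at least two curves")
    return CalibrationCurve(
        compound_id=compound_id,
        a=float(np.mean([c.a for c in curves])),
        b=float(np.mean([c.b for c in curves])),
        c=float(np.mean([c.c for c in curves])),
        area_max=float(min(c.area_max for c in curves)),
        mw_class=curves[0].mw_class,
        averaged=True,
    )


def _resolve_curve(cid: str, curves: dict[str, CalibrationCurve],
                   mw_classes: dict[str, int] | None) -> CalibrationCurve:
    if cid in curves:
        return curves[cid]
    if mw_classes is None or cid not in mw_classes:
        raise MeasurementError(f"no calibration for {cid!r} and no fallback class")
    peers = [c for c in curves.values() if c.mw_class == mw_classes[cid]]
    if len(peers) < 2:
        raise MeasurementError(
            f"no calibration for {cid!r}; fewer than two curves in weight class "
            f"{mw_classes[cid]}"
        )
    return averaged_curve(peers, compound_id=cid)


def quantify(
    peaks: PeakTable,
    curves: dict[str, CalibrationCurve],
    mw_classes: dict[str, int] | None = None,
) -> pd.Series:
    """Peak integrals -> concentrations (mM) for one sample.

    Compounds reporting several peaks are quantified from the largest
    integral only.  Negative results are floored at zero with a warning.
    """
    out = {}
    for cid, grp in peaks.rows.groupby("compound_id", sort=False):
        area = float(grp["peak_integral"].max())
        curve = _resolve_curve(str(cid), curves, mw_classes)
        conc = float(curve.concentration(area))
        if conc < 0:
            log.warning("%s/%s: negative concentration %.3g mM floored at 0",
                        peaks.sample_id, cid, conc)
            conc = 0.0
        out[str(cid)] = conc
    return pd.Series(out, name=peaks.sample_id)


def synthesize_peaks(
    traces: TraceSet,
    curves: dict[str, CalibrationCurve],
    mw_classes: dict[str, int] | None = None,
    seed: int | np.random.Generator | None = None,
    minor_peak_fraction: float = 0.0,
) -> list[PeakTable]:
    """Forward model: concentration traces -> per-timepoint peak tables.

    Each timepoint becomes one sample whose peak integrals invert the
    calibration quadratics, so ``quantify(synthesize_peaks(T)) == T`` on
    noiseless data.  With ``minor_peak_fraction > 0`` a random subset of
    compounds additionally reports a smaller second peak (as derivatised
    sugars often do), exercising the largest-peak rule.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = []
    for j, t in enumerate(traces.times):
        recs = []
        for i, cid in enumerate(traces.compound_ids):
            curve = _resolve_curve(cid, curves, mw_classes)
            area = float(curve.area(traces.concentrations[i, j]))
            recs.append((cid, area, 0))
            if minor_peak_fraction > 0 and rng.random() < minor_peak_fraction:
                recs.append((cid, area * rng.uniform(0.1, 0.9), 1))
        tables.append(PeakTable(
            sample_id=f"t{t:.1f}",
            rows=pd.DataFrame(recs, columns=["compound_id", "peak_integral",
                                             "peak_index"]),
        ))
    return tables


def quantify_traceset(
    tables: list[PeakTable],
    times: np.ndarray,
    curves: dict[str, CalibrationCurve],
    mw_classes: dict[str, int] | None = None,
) -> TraceSet:
    """Quantify a sequence of per-timepoint peak tables back into a TraceSet."""
    series = [quantify(t, curves, mw_classes) for t in tables]
    df = pd.DataFrame(series)
    return TraceSet(times=np.asarray(times, dtype=float),
                    concentrations=df.to_numpy().T,
                    compound_ids=list(df.columns))


def default_curves(
    compound_ids: list[str],
    carbon_counts: dict[str, int],
    uncalibrated: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
) -> tuple[dict[str, CalibrationCurve], dict[str, int]]:
    """Synthetic fixture calibrations (the real calibration table is not
    published); curves pass through the origin with mild quadratic
    curvature and per-compound response factors.

    Returns the curve dictionary (omitting ``uncalibrated`` compounds)
    and the carbon-class map used for the averaged-curve fallback.
    """
    rng = np.random.default_rng(seed)
    curves = {}
    for cid in compound_ids:
        b = 10 ** rng.uniform(-2.3, -1.7)     # mM per area unit
        a = b * 10 ** rng.uniform(-6.0, -5.0)  # mild positive curvature
        if cid not in uncalibrated:
            curves[cid] = CalibrationCurve(
                compound_id=cid, a=a, b=b, c=0.0, area_max=1e4,
                mw_class=carbon_counts[cid],
            )
    classes = {cid: carbon_counts[cid] for cid in compound_ids}
    return curves, classes


def save_curves(curves: dict[str, CalibrationCurve], path) -> None:
    pd.DataFrame(
        [(c.compound_id, c.a, c.b, c.c, c.area_max, c.mw_class)
         for c in curves.values()],
        columns=["compound_id", "a", "b", "c", "area_max", "mw_class"],
    ).to_csv(path, index=False)


def load_curves(path) -> dict[str, CalibrationCurve]:
    df = pd.read_csv(path)
    return {
        str(r.compound_id): CalibrationCurve(
            compound_id=str(r.compound_id), a=float(r.a), b=float(r.b),
            c=float(r.c), area_max=float(r.area_max), mw_class=int(r.mw_class),
        )
        for r in df.itertuples()
    }
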