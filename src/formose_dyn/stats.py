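"""Distribution comparison across experimental conditions.

Compound concentration distributions (the sampled outlet timepoints of
a condition) are compared pairwise between conditions with a two-sided
Welch unequal-variance t test by default (Mann-Whitney available), and
annotated with the significance-star bins

    ns    5e-2 < p <= 1
    *     1e-2 < p <= 5e-2
    **    1e-3 < p <= 1e-2
    ***   1e-4 < p <= 1e-3
    ****  p <= 1e-4

No multiple-testing correction is applied by default (each comparison
is annotated on its own); a Benjamini-Hochberg option exists for users
who pool many compounds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crn_sim import TraceSet

__all__ = [
    "StatsError",
    "DistributionSummary",
    "SignificanceResult",
    "compare_means",
    "star_annotation",
    "condition_report",
    "STAR_BINS",
]

log = logging.getLogger(__name__)

P_FLOOR = 1e-300

#: (upper bound, label); bins are left-open/right-closed on (0, 1]
STAR_BINS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
    (1.0, "ns"),
)


class StatsError(ValueError):
    """Invalid samples or p-values."""


@dataclass(frozen=True)
class DistributionSummary:
    compound_id: str
    condition_id: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise StatsError("summary requires n >= 2")
        if self.sd < 0:
            raise StatsError("sd must be non-negative")


@dataclass(frozen=True)
class SignificanceResult:
    compound_id: str
    condition_a: str
    condition_b: str
    p_value: float
    stars: str


def compare_means(a, b, test: str = "welch") -> float:
    """Two-sided p-value for a difference in means between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise StatsError("each sample needs n >= 3")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            log.info("both samples constant and equal; p = 1 by convention")
            return 1.0
        return P_FLOOR
    if test == "welch":
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "mannwhitney":
        p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise StatsError(f"unknown test {test!r}")
    return float(min(max(p, P_FLOOR), 1.0))


def star_annotation(p: float) -> str:
    """Map a p-value to its significance-star bin."""
    if not 0.0 < p <= 1.0:
        raise StatsError(f"p-value {p!r} outside (0, 1]")
    for bound, label in STAR_BINS:
        if p <= bound:
            return label
    raise AssertionError("unreachable: bins cover (0, 1]")


def condition_report(
    tracesets: dict[str, TraceSet],
    test: str = "welch",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """All pairwise condition comparisons per compound, with stars.

    Rows: one per (compound, condition pair), ordered by compound then
    by condition pair; columns follow the report CSV convention
    (compound_id, condition_a, condition_b, mean_a, sd_a, mean_b, sd_b,
    n_a, n_b, p_value, stars).
    """
    if len(tracesets) < 2:
        raise StatsError("need at least two conditions")
    conditions = list(tracesets)
    ref = tracesets[conditions[0]].compound_ids
    for cond in conditions[1:]:
        other = tracesets[cond].compound_ids
        if set(other) != set(ref):
            diff = sorted(set(ref) ^ set(other))
            raise StatsError(f"conditions disagree on compounds: {diff}")

    rows = []
    for cid in ref:
        for ca, cb in itertools.combinations(conditions, 2):
            xa, xb = tracesets[ca].trace(cid), tracesets[cb].trace(cid)
            p = compare_means(xa, xb, test=test)
            rows.append({
                "compound_id": cid, "condition_a": ca, "condition_b": cb,
                "mean_a": xa.mean(), "sd_a": xa.std(ddof=1),
                "mean_b": xb.mean(), "sd_b": xb.std(ddof=1),
                "n_a": xa.size, "n_b": xb.size, "p_value": p,
            })
    df = pd.DataFrame(rows)
    if bh_correct:
        df["p_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
    df["stars"] = [star_annotation(p) for p in df["p_value"]]
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.clip(adj, P_FLOOR, 1.0)
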