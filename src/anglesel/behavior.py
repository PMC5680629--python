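"""Boldness metrics from PIT detection logs, and their consistency.

Three per-fish measures, following the pond protocol: mean visits/hr/day at
the close and the distant feeding spot (raw reads debounced into visits) and
mean minutes/hr/day spent sheltering (reads merged into presence intervals).
Between-period consistency is quantified by Spearman rank correlation and by
ANOVA-based repeatability (intraclass correlation, Lessells & Boag form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "summarize_behavior",
    "spearman_consistency",
    "lessells_boag_repeatability",
    "capture_summary",
    "ConsistencyResult",
    "RepeatabilityResult",
    "CaptureSummary",
]

_DAY_S = 86400.0


def _count_visits(t: np.ndarray, debounce_s: float) -> int:
    """Number of visits in a sorted read-time vector (gaps >= debounce split)."""
    if t.size == 0:
        return 0
    return 1 + int(np.count_nonzero(np.diff(t) >= debounce_s))


def _shelter_seconds(t: np.ndarray, debounce_s: float) -> float:
    """Total presence seconds from sorted shelter reads.

    Consecutive reads closer than the debounce window belong to one stay whose
    duration is last-read minus first-read; an isolated single read counts as
    half a debounce window (midpoint convention).
    """
    if t.size == 0:
        return 0.0
    breaks = np.nonzero(np.diff(t) >= debounce_s)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    dur = t[ends] - t[starts]
    dur[dur == 0] = debounce_s / 2.0
    return float(dur.sum())


def summarize_behavior(
    detections: pd.DataFrame,
    period: tuple,
    debounce_s: float = 60.0,
    roster=None,
) -> pd.DataFrame:
    """Per-fish boldness measures over an observation period.

    ``period`` is a (start, end) pair of timestamps spanning a whole number of
    days (end exclusive).  Returns one row per roster fish with columns
    ``bp_close``, ``bp_distant`` (mean visits/hr/day) and ``sp`` (mean
    sheltering minutes/hr/day); fish with no reads get zeros.  Events outside
    the period are ignored with a logged count; detections of fish missing
    from the roster are an error.
    """
    if debounce_s <= 0:
        raise ValueError("debounce_s must be > 0")
    start, end = (pd.Timestamp(p) for p in period)
    span = (end - start).total_seconds()
    if span <= 0:
        raise ValueError("period must be nonempty")
    n_days = span / _DAY_S
    if abs(n_days - round(n_days)) > 1e-9:
        raise ValueError("period must span a whole number of days")
    n_days = round(n_days)

    if roster is None:
        roster_ids = pd.unique(detections["fish_id"])
    else:
        roster_ids = roster["fish_id"].to_numpy() if isinstance(roster, pd.DataFrame) else np.asarray(list(roster))
    unknown = set(detections["fish_id"].unique()) - set(roster_ids)
    if unknown:
        raise ValueError(f"detections contain fish not in roster: {sorted(unknown)}")

    t = (pd.to_datetime(detections["timestamp"]) - start).dt.total_seconds().to_numpy()
    inside = (t >= 0) & (t < span)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("summarize_behavior: ignoring %d events outside the period", n_out)
    df = detections.loc[inside, ["fish_id", "antenna"]].copy()
    df["t"] = t[inside]
    df = df.sort_values("t", kind="mergesort")

    hours = n_days * 24.0
    out = pd.DataFrame({"fish_id": roster_ids, "bp_close": 0.0, "bp_distant": 0.0, "sp": 0.0})
    out = out.set_index("fish_id")
    for (fish, antenna), grp in df.groupby(["fish_id", "antenna"], sort=False):
        tt = grp["t"].to_numpy()
        if antenna == "close_spot":
            out.at[fish, "bp_close"] = _count_visits(tt, debounce_s) / hours
        elif antenna == "distant_spot":
            out.at[fish, "bp_distant"] = _count_visits(tt, debounce_s) / hours
        elif antenna == "shelter":
            out.at[fish, "sp"] = min(_shelter_seconds(tt, debounce_s) / 60.0 / hours, 60.0)
    return out.reset_index()


@dataclass
class ConsistencyResult:
    spearman_rho: float
    p_value: float
    n: int


def spearman_consistency(x, y) -> ConsistencyResult:
    """Spearman rank correlation between paired period values (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return ConsistencyResult(float(rho), float(p), len(x))


@dataclass
class RepeatabilityResult:
    """One-way ANOVA repeatability (intraclass correlation) components."""

    ms_among: float
    ms_within: float
    n0: float
    s2_among: float
    s2_within: float
    r: float
    F: float
    p_value: float
    n_groups: int
    n_obs: int


def lessells_boag_repeatability(measures) -> RepeatabilityResult:
    """Repeatability from per-fish sequences of period values.

    ``measures`` may be a mapping fish -> sequence, a wide DataFrame (one row
    per fish, one column per period), or a list of sequences.  Individuals are
    the ANOVA groups; the variance components use the effective group size
    ``n0 = (N - sum(n_i^2)/N) / (a - 1)``.  Negative estimates are reported
    as computed, never clamped.
    """
    if isinstance(measures, pd.DataFrame):
        groups = [row.to_numpy(dtype=float) for _, row in measures.iterrows()]
        names = list(measures.index)
    elif isinstance(measures, dict):
        names = list(measures)
        groups = [np.asarray(measures[k], dtype=float) for k in names]
    else:
        groups = [np.asarray(g, dtype=float) for g in measures]
        names = list(range(len(groups)))
    if len(groups) < 2:
        raise ValueError("repeatability needs at least 2 individuals")
    for name, g in zip(names, groups):
        if len(g) < 2:
            raise ValueError(f"individual {name!r} has fewer than 2 period values")

    sizes = np.array([len(g) for g in groups], dtype=float)
    a, N = len(groups), sizes.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_a = float((sizes * (means - grand) ** 2).sum())
    ss_w = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ms_a = ss_a / (a - 1)
    ms_w = ss_w / (N - a)
    n0 = (N - (sizes**2).sum() / N) / (a - 1)
    s2_a = (ms_a - ms_w) / n0
    denom = ms_w + s2_a
    r = s2_a / denom if denom != 0 else np.nan
    if ms_w > 0:
        F = ms_a / ms_w
        p = float(stats.f.sf(F, a - 1, N - a))
    else:
        F = np.inf if ms_a > 0 else np.nan
        p = 0.0 if ms_a > 0 else np.nan
    if r < 0:
        logger.warning("negative repeatability estimate r=%.3f (reported as computed)", r)
    return RepeatabilityResult(ms_a, ms_w, float(n0), float(s2_a), ms_w, float(r),
                               float(F), p, a, int(N))


@dataclass
class CaptureSummary:
    horizon_days: int
    captured: int
    population: int
    fraction: float
    rod_hours: float
    cpue: float


def capture_summary(
    captures: pd.DataFrame,
    horizon_days: int,
    population: int,
    rod_hours_per_day: float = 4.0,
    n_ponds: int = 3,
) -> CaptureSummary:
    """Distinct fish first-captured within the horizon, plus CPUE.

    CPUE divides by pond-summed rod hours (horizon x rod-hours/day x ponds).
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if len(captures):
        first = captures.groupby("fish_id")["day"].min()
        captured = int((first <= horizon_days).sum())
    else:
        captured = 0
    rod_hours = horizon_days * rod_hours_per_day * n_ponds
    return CaptureSummary(
        horizon_days=horizon_days,
        captured=captured,
        population=int(population),
        fraction=captured / population,
        rod_hours=rod_hours,
        cpue=captured / rod_hours if rod_hours > 0 else np.nan,
    )
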