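"""RNase H2 cleavage quantification by rNMP position class.

Gel band intensities (cleaved and uncleaved) per timepoint are converted to
percent cleavage, cleaved / (cleaved + uncleaved); replicates are aggregated
as mean +/- sample SD; constructs are grouped by the structural class of
their ribonucleotide position (G1/G2/G3/loop) to expose the positional
pattern of ribonucleotide-excision-repair initiation, and potassium vs
sodium conditions are compared descriptively.

A replicate mean below the detection threshold (default 0.1%) is reported as
not detected (N.D.), mirroring gel assays where no product band is visible;
class means treat N.D. as zero by default, since excluding an undetectable
product would bias the class upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .sequences import PositionClass, SubstitutionSite

__all__ = [
    "CleavageMeasurement",
    "CleavageTimecourse",
    "ClassSummary",
    "percent_cleaved",
    "summarize_timecourse",
    "group_by_position_class",
    "fit_first_order",
    "compare_cations",
    "DETECTION_THRESHOLD_PCT",
]

#: replicate means below this (percent) are reported as not detected
DETECTION_THRESHOLD_PCT = 0.1


@dataclass(frozen=True)
class CleavageMeasurement:
    """One gel lane: band intensities at one timepoint (arbitrary units)."""

    time: float  # minutes
    intensity_cleaved: float
    intensity_uncleaved: float

    def __post_init__(self):
        if self.intensity_cleaved < 0 or self.intensity_uncleaved < 0:
            raise ValueError("band intensities must be nonnegative")

    @property
    def percent(self) -> float:
        return 100.0 * percent_cleaved(self)


def percent_cleaved(m: CleavageMeasurement) -> float:
    """Cleaved fraction: cleaved / (cleaved + uncleaved)."""
    total = m.intensity_cleaved + m.intensity_uncleaved
    if total <= 0:
        raise ValueError(f"zero total band intensity at t={m.time} min")
    return m.intensity_cleaved / total


@dataclass(frozen=True)
class CleavageTimecourse:
    """One replicate's measurements, ordered by strictly increasing time."""

    construct: str
    cation: str  # 'K' or 'Na'
    replicate: int
    measurements: tuple[CleavageMeasurement, ...]

    def __post_init__(self):
        if self.cation not in ("K", "Na"):
            raise ValueError(f"cation must be 'K' or 'Na', got {self.cation!r}")
        times = [m.time for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("measurement times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements])

    @property
    def percents(self) -> np.ndarray:
        return np.array([m.percent for m in self.measurements])


def summarize_timecourse(
    replicates: Sequence[CleavageTimecourse],
    detection_threshold_pct: float = DETECTION_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Per-timepoint mean +/- sample SD (n-1) of percent cleavage.

    Columns: time_min, mean_pct, sd_pct, n, detected.  ``detected`` is False
    when the replicate mean falls below the detection threshold (an N.D.
    entry); mean/sd are still carried numerically so the N.D. policy can be
    applied downstream.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    grid = replicates[0].times
    for r in replicates[1:]:
        if r.times.shape != grid.shape or not np.allclose(r.times, grid):
            raise ValueError(
                f"replicate {r.replicate} of {r.construct} has a different time grid"
            )
    values = np.vstack([r.percents for r in replicates])  # replicates x time
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.full(grid.size, np.nan)
    return pd.DataFrame(
        {
            "time_min": grid,
            "mean_pct": mean,
            "sd_pct": sd,
            "n": values.shape[0],
            "detected": mean >= detection_threshold_pct,
        }
    )


@dataclass(frozen=True)
class ClassSummary:
    """Cleavage aggregated over the constructs of one position class."""

    position_class: PositionClass
    cation: str
    table: pd.DataFrame  # time_min, mean_pct, sd_pct, n_constructs
    nd_as_zero: bool


def group_by_position_class(
    summaries: Mapping[str, pd.DataFrame],
    sites: Mapping[str, SubstitutionSite],
    cation: str = "K",
    nd_as_zero: bool = True,
) -> list[ClassSummary]:
    """Group per-construct cleavage summaries by rNMP position class.

    ``summaries`` maps construct name to a table with columns time_min,
    mean_pct, detected (the output of :func:`summarize_timecourse`, or a
    table of published values).  N.D. timepoints (detected=False) enter the
    class mean as 0 when ``nd_as_zero``, and are excluded otherwise.
    """
    for construct in summaries:
        if construct not in sites:
            raise ValueError(f"construct {construct!r} has no classified substitution site")
    members: dict[PositionClass, list[str]] = {}
    for construct in summaries:
        members.setdefault(sites[construct].position_class, []).append(construct)

    out = []
    for pclass in sorted(members, key=lambda c: c.value):
        tables = []
        for construct in members[pclass]:
            t = summaries[construct][["time_min", "mean_pct", "detected"]].copy()
            t["construct"] = construct
            tables.append(t)
        long = pd.concat(tables, ignore_index=True)
        if nd_as_zero:
            long.loc[~long["detected"], "mean_pct"] = 0.0
        else:
            long = long[long["detected"]]
        grouped = (
            long.groupby("time_min")["mean_pct"]
            .agg(mean_pct="mean", sd_pct=lambda v: v.std(ddof=1), n_constructs="count")
            .reset_index()
        )
        out.append(ClassSummary(position_class=pclass, cation=cation, table=grouped,
                                nd_as_zero=nd_as_zero))
    return out


def _saturating(t, k, plateau, burst):
    return burst + (plateau - burst) * (1.0 - np.exp(-k * t))


def fit_first_order(
    times: np.ndarray,
    fractions: np.ndarray,
) -> tuple[float, float, float]:
    """Descriptive first-order fit F(t) = burst + (plateau-burst)(1-exp(-kt)).

    ``fractions`` are cleaved fractions in [0, 1].  Returns (rate per minute,
    plateau, burst) with fractions bounded to [0, 1] and rate >= 0.  A flat
    series is returned as rate 0 with burst = plateau = the constant level.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 timepoints")
    if np.ptp(f) < 1e-12:
        level = float(f.mean())
        return 0.0, level, level
    k0 = 1.0 / max(float(t.mean()), 1e-9)
    p0 = (k0, float(np.clip(f.max(), 0.0, 1.0)), float(np.clip(f[0], 0.0, 1.0)))
    try:
        popt, _ = optimize.curve_fit(
            _saturating, t, f, p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, 1.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"first-order cleavage fit did not converge: {exc}") from exc
    k, plateau, burst = popt
    return float(k), float(plateau), float(burst)


def compare_cations(
    k_summaries: Sequence[ClassSummary],
    na_summaries: Sequence[ClassSummary],
) -> pd.DataFrame:
    """Descriptive Na+ minus K+ class-mean difference per timepoint.

    Columns: position_class, time_min, k_mean_pct, na_mean_pct, diff_pct.
    """
    if not k_summaries or not na_summaries:
        raise ValueError("empty class summary set")
    k_by = {s.position_class: s for s in k_summaries}
    na_by = {s.position_class: s for s in na_summaries}
    if set(k_by) != set(na_by):
        missing = set(k_by) ^ set(na_by)
        raise ValueError(f"position classes missing a counterpart: {sorted(c.value for c in missing)}")
    rows = []
    for pclass in sorted(k_by, key=lambda c: c.value):
        kt = k_by[pclass].table.set_index("time_min")["mean_pct"]
        nt = na_by[pclass].table.set_index("time_min")["mean_pct"]
        if not kt.index.equals(nt.index):
            raise ValueError(f"class {pclass.value}: time grids differ between cations")
        for t in kt.index:
            rows.append(
                {
                    "position_class": pclass.value,
                    "time_min": float(t),
                    "k_mean_pct": float(kt[t]),
                    "na_mean_pct": float(nt[t]),
                    "diff_pct": float(nt[t] - kt[t]),
                }
            )
    return pd.DataFrame(rows)
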