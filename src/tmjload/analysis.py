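"""Load-asymmetry analysis: window means, baseline-relative percentage
tables, sweep summaries and cut-off detection.

The analysis windows follow the reporting convention of the study design:
jaw-closed window 180-189.9 ms, jaw-open window 270-279.9 ms.  Percentages
are 100 * force / baseline force of the same side and phase, rounded
half-up to one decimal.  A "cut-off" is any consecutive shortening pair
across which the windowed force drops by at least the threshold (default
50%); the separate 10% threshold flags changes worth attention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhaseWindow",
    "CLOSED_WINDOW",
    "OPEN_WINDOW",
    "LoadSummary",
    "SweepResult",
    "window_mean",
    "summarize_run",
    "relative_load_table",
    "percent_change",
    "flag_significant",
    "detect_cutoff",
    "round_half_up",
]

SIDES = ("right", "left")
PHASES = ("closed", "open")


@dataclass(frozen=True)
class PhaseWindow:
    """Analysis window over the force trace, in ms."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start must precede end, got [{self.start}, {self.end}]")


CLOSED_WINDOW = PhaseWindow("closed", 180.0, 189.9)
OPEN_WINDOW = PhaseWindow("open", 270.0, 279.9)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to the given decimals (table reporting style)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def window_mean(time_ms: np.ndarray, trace: np.ndarray, window: PhaseWindow) -> float:
    """Arithmetic mean of trace samples with start <= t <= end (ms)."""
    time_ms = np.asarray(time_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    mask = (time_ms >= window.start) & (time_ms <= window.end)
    if not np.any(mask):
        raise ValueError(
            f"trace (span {time_ms.min():.1f}-{time_ms.max():.1f} ms) does not cover "
            f"window [{window.start}, {window.end}] ms"
        )
    return float(trace[mask].mean())


@dataclass
class LoadSummary:
    """Window-mean joint forces per side and phase for one run.

    ``forces[(side, phase)]`` in N; ``percent[(side, phase)]`` is filled by
    :func:`relative_load_table` (100.0 for the baseline itself).
    """

    label: str
    forces: dict = field(default_factory=dict)
    percent: dict = field(default_factory=dict)
    shortening_mm: float = 0.0


def summarize_run(
    time_ms, mean_force: dict, label: str = "", shortening_mm: float = 0.0,
    closed: PhaseWindow = CLOSED_WINDOW, open_: PhaseWindow = OPEN_WINDOW,
) -> LoadSummary:
    """Window means of the per-side joint mean-force traces."""
    forces = {}
    for side in SIDES:
        forces[(side, "closed")] = window_mean(time_ms, mean_force[side], closed)
        forces[(side, "open")] = window_mean(time_ms, mean_force[side], open_)
    return LoadSummary(label=label, forces=forces, shortening_mm=shortening_mm)


def relative_load_table(baseline: LoadSummary, runs: list[LoadSummary]) -> pd.DataFrame:
    """Forces (N) and percent-of-baseline per cell, to one decimal.

    Normalization is always same side, same phase.  A zero baseline force
    makes the percentage undefined: reported as NaN with a warning.
    """
    import warnings

    rows = []
    for summ in [baseline] + list(runs):
        missing = set(baseline.forces) - set(summ.forces)
        if missing:
            raise ValueError(f"run {summ.label!r} missing cells {sorted(missing)}")
        for side in SIDES:
            row = {"run": summ.label, "shortening_mm": summ.shortening_mm, "side": side}
            for phase in PHASES:
                f = summ.forces[(side, phase)]
                base = baseline.forces[(side, phase)]
                if base <= 0:
                    warnings.warn(
                        f"zero baseline force for ({side}, {phase}); percentage undefined",
                        stacklevel=2)
                    pct = float("nan")
                else:
                    pct = round_half_up(100.0 * f / base)
                summ.percent[(side, phase)] = pct
                row[f"{phase}_N"] = round_half_up(f)
                row[f"{phase}_pct"] = pct
            rows.append(row)
    return pd.DataFrame(rows)


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before; before must be positive."""
    if before <= 0:
        raise ValueError(f"'before' must be > 0, got {before}")
    return 100.0 * (after - before) / before


def flag_significant(change: float, threshold: float = 10.0) -> bool:
    """True iff |change| strictly exceeds the attention threshold (%)."""
    if not np.isfinite(change):
        raise ValueError(f"change must be finite, got {change}")
    return abs(change) > threshold


def detect_cutoff(
    shortenings, forces, drop_threshold: float = 50.0
) -> list[tuple[float, float]]:
    """Consecutive shortening intervals with a drop of at least the threshold.

    Returns every pair (d_i, d_{i+1}) whose percent change is
    <= -drop_threshold.  Invariant under uniform rescaling of the forces.
    """
    shortenings = list(shortenings)
    forces = list(forces)
    if len(shortenings) != len(forces):
        raise ValueError("shortenings and forces must have equal length")
    if len(shortenings) < 2:
        raise ValueError("need at least two points to detect a cut-off")
    if any(b <= a for a, b in zip(shortenings, shortenings[1:])):
        raise ValueError(f"shortenings must be strictly increasing, got {shortenings}")
    out = []
    for (d0, f0), (d1, f1) in zip(zip(shortenings, forces), zip(shortenings[1:], forces[1:])):
        if f0 <= 0:
            continue    # already fully unloaded; no further drop to detect
        if percent_change(f0, f1) <= -drop_threshold:
            out.append((d0, d1))
    return out


@dataclass
class SweepResult:
    """Load summaries across the shortening sweep, with derived measures."""

    shortenings: list            # mm, strictly increasing, baseline first (0)
    summaries: list              # LoadSummary per shortening
    table: pd.DataFrame
    consecutive_changes: dict    # (side, phase) -> list of % changes between runs
    significant: dict            # (side, phase) -> list of bool flags
    cutoffs: dict                # (side, phase) -> list of (mm, mm) intervals

    @classmethod
    def from_summaries(cls, baseline: LoadSummary, runs: list[LoadSummary],
                       drop_threshold: float = 50.0,
                       attention_threshold: float = 10.0) -> "SweepResult":
        all_runs = [baseline] + list(runs)
        shortenings = [s.shortening_mm for s in all_runs]
        if any(b <= a for a, b in zip(shortenings, shortenings[1:])):
            raise ValueError(f"shortenings must be strictly increasing, got {shortenings}")
        table = relative_load_table(baseline, list(runs))
        changes, signif, cutoffs = {}, {}, {}
        for side in SIDES:
            for phase in PHASES:
                series = [s.forces[(side, phase)] for s in all_runs]
                ch = [percent_change(a, b) if a > 0 else float("nan")
                      for a, b in zip(series, series[1:])]
                changes[(side, phase)] = ch
                signif[(side, phase)] = [flag_significant(c, attention_threshold)
                                         if np.isfinite(c) else False for c in ch]
                cutoffs[(side, phase)] = (
                    detect_cutoff(shortenings, series, drop_threshold)
                    if len(series) >= 2 else [])
        return cls(shortenings=shortenings, summaries=all_runs, table=table,
                   consecutive_changes=changes, significant=signif, cutoffs=cutoffs)

    def to_json_dict(self) -> dict:
        return {
            "shortenings_mm": [float(s) for s in self.shortenings],
            "window_means_N": {
                f"{side}_{phase}": [float(s.forces[(side, phase)]) for s in self.summaries]
                for side in SIDES for phase in PHASES
            },
            "percent_of_baseline": {
                f"{side}_{phase}": [
                    None if not np.isfinite(s.percent.get((side, phase), float("nan")))
                    else float(s.percent[(side, phase)])
                    for s in self.summaries
                ]
                for side in SIDES for phase in PHASES
            },
            "consecutive_changes_pct": {
                f"{k[0]}_{k[1]}": [float(c) for c in v]
                for k, v in self.consecutive_changes.items()
            },
            "significant": {f"{k[0]}_{k[1]}": v for k, v in self.significant.items()},
            "cutoff_intervals_mm": {
                f"{k[0]}_{k[1]}": [[float(a), float(b)] for a, b in v]
                for k, v in self.cutoffs.items()
            },
        }
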