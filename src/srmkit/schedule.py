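"""Retention-time-scheduled SRM acquisition planning.

Calibrates dimensionless iRT scores to chromatographic retention time by
ordinary least squares, centres a fixed-width acquisition window on each
transition's predicted RT (light and heavy twins share one window — they
co-elute by construction), and checks dwell-time/cycle-time feasibility:
the effective cycle time is the worst-case number of concurrently
scheduled transitions times the per-transition dwell (plus any interscan
overhead), and must not exceed the configured maximum cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ProteinPanel, TransitionAssay

__all__ = [
    "RtCalibration",
    "ScheduleConfig",
    "ScheduledEntry",
    "ScheduledMethod",
    "fit_rt_calibration",
    "assign_windows",
    "max_concurrency",
    "check_feasibility",
    "write_scheduled_method",
    "count_transitions",
]


class ScheduleError(ValueError):
    """Invalid input to a scheduling operation."""


@dataclass(frozen=True)
class RtCalibration:
    """Linear iRT -> RT map fitted from calibration peptides."""

    slope: float  # min per iRT unit
    intercept: float  # min
    residual_sd: float  # min
    n_points: int

    def predict(self, irt: float) -> float:
        return self.slope * irt + self.intercept


@dataclass(frozen=True)
class ScheduleConfig:
    """Scheduled-acquisition parameters.

    Defaults reproduce the published method: 4-min RT windows, 10-ms
    dwell, 1.7-s maximum cycle time, 30-min gradient.
    """

    window_width: float = 4.0  # min
    dwell_time: float = 0.010  # s per transition
    max_cycle_time: float = 1.7  # s
    interscan_overhead: float = 0.0  # s per transition
    gradient_length: float = 30.0  # min

    def __post_init__(self) -> None:
        if min(self.window_width, self.dwell_time, self.max_cycle_time,
               self.gradient_length) <= 0:
            raise ScheduleError("schedule parameters must be positive")
        if self.interscan_overhead < 0:
            raise ScheduleError("interscan_overhead must be >= 0")
        if self.window_width > self.gradient_length:
            raise ScheduleError("window wider than the gradient")


@dataclass(frozen=True)
class ScheduledEntry:
    assay: TransitionAssay
    window_start: float  # min
    window_end: float  # min


@dataclass
class ScheduledMethod:
    entries: list[ScheduledEntry]
    max_concurrency: int = 0
    effective_cycle_time: float = 0.0  # s
    feasible: bool = True

    @property
    def n_light(self) -> int:
        return sum(1 for e in self.entries if e.assay.label_state == "light")

    @property
    def n_heavy(self) -> int:
        return sum(1 for e in self.entries if e.assay.label_state == "heavy")

    @property
    def n_total(self) -> int:
        return len(self.entries)


def fit_rt_calibration(
    points: Sequence[tuple[float, float]]
) -> RtCalibration:
    """OLS fit of observed RT (min) against iRT score."""
    if len(points) < 2:
        raise ScheduleError("need >= 2 calibration points")
    irt = np.asarray([p[0] for p in points], dtype=float)
    rt = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(irt).size < 2:
        raise ScheduleError("need >= 2 distinct iRT values")
    fit = stats.linregress(irt, rt)
    resid = rt - (fit.slope * irt + fit.intercept)
    dof = len(points) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return RtCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=residual_sd,
        n_points=len(points),
    )


def assign_windows(
    panel: ProteinPanel,
    cal: RtCalibration,
    config: ScheduleConfig | None = None,
) -> ScheduledMethod:
    """Centre an acquisition window on each transition's predicted RT.

    Windows are clipped (not shifted) at the gradient boundaries, so
    early/late eluters keep their centre ordering. Light and heavy twins
    inherit the same window because they share the peptide's iRT.
    """
    config = config or ScheduleConfig()
    missing = sorted(
        {
            e.peptide.sequence
            for e in panel.all_transitions()
            if e.peptide.irt is None
        }
    )
    if missing:
        raise ScheduleError(f"peptides without iRT: {missing}")
    half = config.window_width / 2.0
    entries = []
    for assay in panel.all_transitions():
        centre = cal.predict(assay.peptide.irt)
        start = max(0.0, centre - half)
        end = min(config.gradient_length, centre + half)
        entries.append(ScheduledEntry(assay=assay, window_start=start, window_end=end))
    method = ScheduledMethod(entries=entries)
    return check_feasibility(method, config)


def max_concurrency(method: ScheduledMethod) -> int:
    """Maximum number of overlapping windows, by endpoint sweep.

    Windows are treated as half-open [start, end): at a shared endpoint
    the closing window no longer counts, so touching windows do not
    overlap.
    """
    events: list[tuple[float, int]] = []
    for e in method.entries:
        if e.window_end > e.window_start:
            events.append((e.window_start, 1))
            events.append((e.window_end, -1))
    # at equal time, process window closings (-1) before openings (+1)
    events.sort(key=lambda ev: (ev[0], ev[1]))
    running = best = 0
    for _, delta in events:
        running += delta
        best = max(best, running)
    return best


def check_feasibility(
    method: ScheduledMethod, config: ScheduleConfig | None = None
) -> ScheduledMethod:
    """Set concurrency, effective cycle time, and the feasibility flag."""
    config = config or ScheduleConfig()
    conc = max_concurrency(method)
    cycle = conc * (config.dwell_time + config.interscan_overhead)
    method.max_concurrency = conc
    method.effective_cycle_time = cycle
    method.feasible = cycle <= config.max_cycle_time
    return method


# ---------------------------------------------------------------------------
# External interfaces


def method_to_frame(method: ScheduledMethod) -> pd.DataFrame:
    rows = []
    for e in method.entries:
        t = e.assay
        rows.append(
            {
                "protein": t.peptide.protein_id,
                "peptide_sequence": t.peptide.sequence,
                "label": t.label_state,
                "precursor_mz": round(t.precursor_mz, 4),
                "precursor_charge": t.precursor_charge,
                "fragment": t.fragment,
                "fragment_charge": t.fragment_charge,
                "product_mz": round(t.product_mz, 4),
                "irt": t.peptide.irt,
                "rank": t.rank,
                "window_start": round(e.window_start, 2),
                "window_end": round(e.window_end, 2),
            }
        )
    return pd.DataFrame(rows)


def write_scheduled_method(method: ScheduledMethod, path: str | Path) -> pd.DataFrame:
    frame = method_to_frame(method)
    frame.to_csv(path, index=False, float_format="%.4f")
    return frame


def count_transitions(path: str | Path) -> dict[str, int]:
    """Report light/heavy/total transition counts of an exported method.

    Whether a published transition total counts heavy twins varies, so
    all three numbers are reported.
    """
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ScheduleError("method file has no 'label' column")
    n_light = int((frame["label"] == "light").sum())
    n_heavy = int((frame["label"] == "heavy").sum())
    return {"light": n_light, "heavy": n_heavy, "total": len(frame)}
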