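"""Analytical speed model of the mixed workflow versus pure glocal search.

With T_local the total local-scan time over the M local-build models,
T_realign the glocal re-alignment time over the K hit models, and T_glocal
the time a glocal scan of those same M models would take, the predicted
speed-up of the mixed workflow over pure glocal search is

    f = T_glocal / (T_local + T_realign),

bounded above by T_glocal / T_local (the T_realign = 0 limit) and strictly
decreasing in T_realign.  Wall-clock aggregates are reported, never
asserted: they are hardware-dependent.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

__all__ = ["SpeedInputs", "predicted_speedup", "speedup_upper_bound", "measure_run_times"]


@dataclasses.dataclass
class SpeedInputs:
    """Per-stage wall-clock aggregates (seconds) and per-model breakdowns."""

    T_local: float
    T_glocal: float
    T_realign: float
    t_local_by_model: dict[str, float]
    t_glocal_by_model: dict[str, float]
    t_realign_by_model: dict[str, float]

    def __post_init__(self) -> None:
        if min(self.T_local, self.T_glocal, self.T_realign) < 0:
            raise ValueError("times must be non-negative")


def predicted_speedup(T_glocal: float, T_local: float, T_realign: float) -> float:
    """f = T_glocal / (T_local + T_realign)."""
    denom = T_local + T_realign
    if denom <= 0:
        raise ZeroDivisionError("T_local + T_realign must be positive")
    return T_glocal / denom


def speedup_upper_bound(T_glocal: float, T_local: float) -> float:
    """The T_realign = 0 limit T_glocal / T_local bounding the achievable
    speed-up."""
    if T_local <= 0:
        raise ZeroDivisionError("T_local must be positive")
    return T_glocal / T_local


def measure_run_times(run_summary: Mapping) -> SpeedInputs:
    """Aggregate a pipeline run summary's stage timings into SpeedInputs.

    T_glocal comes from the optional reference glocal scan of the local
    sub-library (``measure_reference=True``); without it, T_glocal is 0 and
    only the T_local / T_realign terms are meaningful.
    """
    timings = run_summary["timings"]
    t_local = dict(timings.get("t_local_by_model", {}))
    t_realign = dict(timings.get("t_realign_by_model", {}))
    t_glocal = dict(timings.get("t_reference_glocal_by_model", {}))
    return SpeedInputs(
        T_local=sum(t_local.values()),
        T_glocal=sum(t_glocal.values()),
        T_realign=sum(t_realign.values()),
        t_local_by_model=t_local,
        t_glocal_by_model=t_glocal,
        t_realign_by_model=t_realign,
    )
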