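"""Per-model build selection by normalized partial-AUC differences.

For a fixed false-positive count x, the partial AUC of a build is the area
under its ROC staircase over FPR in [0, x/N_neg] (right-continuous step
integration; if fewer negatives were detected the staircase extends flat).
The normalized difference

    diff(x) = (AUC_glocal - AUC_local) / (x / norm_n)

is evaluated over an ordered FP set A; count_y is the number of x in A with
diff(x) > 0.  A model selects its glocal build only when count_y = |A|, its
local build when count_y = 0, and is otherwise undetermined (its sensitivity
ranking fluctuates with x).  Undetermined models run as local builds in the
downstream workflow.  Library totals over the three labels always partition
the library; totals are also reported for every suffix of A (dropping the
smallest x values first), which can only move models out of the undetermined
class.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, ModelCalibration

__all__ = [
    "DEFAULT_FP_SET",
    "FPSet",
    "SelectionResult",
    "partial_auc",
    "normalized_auc_diff",
    "count_and_select",
    "select_library",
    "selection_report",
]

#: default FP evaluation set A = {1, 5, 10, 20, ..., 100}
DEFAULT_FP_SET: tuple[int, ...] = (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)

GLOCAL, LOCAL, UNDETERMINED = "glocal", "local", "undetermined"


@dataclasses.dataclass(frozen=True)
class FPSet:
    """Ordered set of positive FP evaluation points."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("FP set must be non-empty")
        if any(x <= 0 for x in self.values):
            raise ValueError("FP values must be positive")
        if list(self.values) != sorted(set(self.values)):
            raise ValueError("FP values must be distinct and ascending")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def suffixes(self) -> list["FPSet"]:
        """A, then A minus its smallest element, and so on."""
        return [FPSet(self.values[i:]) for i in range(len(self.values))]


@dataclasses.dataclass
class SelectionResult:
    model_id: str
    auc_diff_by_x: dict[int, float]
    count_y: int
    chosen_build: str  # glocal | local | undetermined


def partial_auc(table: CalibrationTable, fp_limit: int) -> float:
    """Area under the ROC staircase for FPR in [0, fp_limit/n_neg].

    The staircase is right-continuous: on [k/n_neg, (k+1)/n_neg) the height
    is the best TPR reachable with at most k false positives; beyond the
    detected negatives the TPR extends flat.
    """
    if fp_limit < 1:
        raise ValueError("fp_limit must be >= 1")
    heights = [table.tpr_below_fp(k) for k in range(fp_limit)]
    return float(np.sum(heights)) / table.n_neg


def normalized_auc_diff(
    table_glocal: CalibrationTable,
    table_local: CalibrationTable,
    x: int,
    norm_n: int | None = None,
) -> float:
    """(partial AUC glocal - partial AUC local) / (x / norm_n).

    ``norm_n`` defaults to the library size n_neg + 1; the sign of the
    difference is invariant to this normalization.
    """
    if x == 0:
        raise ValueError("x must be positive")
    if table_glocal.model_id != table_local.model_id:
        raise ValueError("tables must describe the same model")
    if norm_n is None:
        norm_n = table_glocal.n_neg + 1
    diff = partial_auc(table_glocal, x) - partial_auc(table_local, x)
    return diff / (x / norm_n)


def count_and_select(
    auc_diff_by_x: Mapping[int, float],
    A: FPSet | Sequence[int],
    literal_printed_mapping: bool = False,
) -> SelectionResult:
    """Count FP points where the glocal build is strictly more sensitive and
    map the count to a build label.

    count_y = #{x in A : diff(x) > 0}; count_y = |A| selects the glocal
    build, count_y = 0 the local build, anything between is undetermined.
    ``literal_printed_mapping`` swaps the local/undetermined labels (the
    alternative pairing some reports print); the default follows the
    criterion's own prose, under which only a zero count means the local
    build wins at every FP point.
    """
    A = A if isinstance(A, FPSet) else FPSet(tuple(A))
    missing = [x for x in A if x not in auc_diff_by_x]
    if missing:
        raise KeyError(f"missing AUC differences for FP values {missing}")
    count_y = sum(1 for x in A if auc_diff_by_x[x] > 0.0)
    if count_y == len(A):
        chosen = GLOCAL
    elif count_y == 0:
        chosen = UNDETERMINED if literal_printed_mapping else LOCAL
    else:
        chosen = LOCAL if literal_printed_mapping else UNDETERMINED
    return SelectionResult(
        model_id="", auc_diff_by_x=dict(auc_diff_by_x), count_y=count_y, chosen_build=chosen
    )


def _totals(results: Sequence[SelectionResult]) -> dict[str, int]:
    t = {GLOCAL: 0, LOCAL: 0, UNDETERMINED: 0}
    for r in results:
        t[r.chosen_build] += 1
    return t


def select_library(
    calibrations: Mapping[str, ModelCalibration],
    A: FPSet | Sequence[int] = DEFAULT_FP_SET,
    norm_n: int | None = None,
    literal_printed_mapping: bool = False,
) -> tuple[dict[str, SelectionResult], dict[str, int], pd.DataFrame]:
    """Select the build of every model and report library totals.

    Returns per-model results, totals over {glocal, local, undetermined}
    (always summing to the library size), and a sweep table with totals for
    every suffix FP set obtained by dropping the smallest x values.
    """
    A = A if isinstance(A, FPSet) else FPSet(tuple(A))
    results: dict[str, SelectionResult] = {}
    for model_id, cal in calibrations.items():
        diffs = {
            x: normalized_auc_diff(cal.tables["glocal"], cal.tables["local"], x, norm_n)
            for x in A
        }
        res = count_and_select(diffs, A, literal_printed_mapping)
        res.model_id = model_id
        results[model_id] = res

    totals = _totals(list(results.values()))

    sweep_rows = []
    for sub in A.suffixes():
        sub_results = [
            count_and_select(
                {x: results[mid].auc_diff_by_x[x] for x in sub}, sub, literal_printed_mapping
            )
            for mid in results
        ]
        t = _totals(sub_results)
        sweep_rows.append(
            {
                "fp_set": ",".join(str(x) for x in sub),
                "min_fp": sub.values[0],
                GLOCAL: t[GLOCAL],
                LOCAL: t[LOCAL],
                UNDETERMINED: t[UNDETERMINED],
            }
        )
    sweep = pd.DataFrame(sweep_rows)
    return results, totals, sweep


def selection_report(results: Mapping[str, SelectionResult], A: FPSet | Sequence[int]) -> pd.DataFrame:
    """Tab-friendly report: model, count_y, chosen build, diff at each x."""
    A = A if isinstance(A, FPSet) else FPSet(tuple(A))
    rows = []
    for model_id, r in results.items():
        row = {"model_id": model_id, "count_y": r.count_y, "chosen_build": r.chosen_build}
        for x in A:
            row[f"diff_fp{x}"] = r.auc_diff_by_x[x]
        rows.append(row)
    return pd.DataFrame(rows)
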