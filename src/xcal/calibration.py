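"""Per-model cross-build calibration via false-positive ranks.

For every domain model the two builds are made comparable on a common scale
by searching the same model-specific query set with both engines:

* positives — the model's own alpha seed sequences (gaps stripped);
* negatives — the consensus sequences of every *other* model in the library.

Hits are stratified into paired (same query, overlapping model spans) and
orphaned sets.  Each paired glocal hit is reconstructed over its local
counterpart's model-span window, re-deriving a windowed bit score and a new
E-value under the glocal build's own Gumbel parameters, so both builds are
scored on comparable alignment extents.  Sorting the negative E-values
ascending assigns each its rank — the false-positive count FP — and
FPR = FP / N_neg with N_neg = N_total - 1.  Sweeping thresholds over the
observed E-values yields the ROC and precision-recall staircases and the
E-value boundary at every sampled FP grid point.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    DomainHit,
    EVDParams,
    ScoredAlignment,
    calibrate_evd,
    evalue,
    search_model_vs_seqdb,
)
from .library import DomainLibrary, DomainModel

__all__ = [
    "DEFAULT_FP_GRID",
    "CalibrationQuerySet",
    "StratifiedHits",
    "CalibrationTable",
    "ModelCalibration",
    "make_query_set",
    "stratify_hits",
    "reconstruct_glocal_to_local",
    "build_calibration_table",
    "fpr_of_fp",
    "coverage_per_model",
    "library_fpr_evalue_profile",
    "calibrate_model",
    "calibrate_library",
    "write_calibration",
    "read_calibration",
]

#: FP grid bounding the assignment intervals of the annotation workflow
DEFAULT_FP_GRID: tuple[int, ...] = (1, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100)

BUILDS = ("glocal", "local")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CalibrationQuerySet:
    """Positives (seed sequences) and negatives (other models' consensus)."""

    target_model_id: str
    positives: list[tuple[str, str]]  # (query_id, sequence)
    negatives: list[tuple[str, str]]

    @property
    def alpha(self) -> int:
        return len(self.positives)

    def all_queries(self) -> list[tuple[str, str]]:
        return self.positives + self.negatives


@dataclasses.dataclass
class StratifiedHits:
    """Hit strata for one model: each hit appears in exactly one stratum and
    pairing happens only within the same query."""

    paired: list[tuple[DomainHit, DomainHit]]  # (glocal, local)
    orphaned_glocal: list[DomainHit]
    orphaned_local: list[DomainHit]


@dataclasses.dataclass
class CalibrationTable:
    """Per model and build: ranked negative E-values, positive E-values and
    the derived ROC / PR staircases.

    ``pos_evalues`` records non-detections as +inf; ``neg_evalues_sorted``
    holds only detected negatives, ascending, so index k-1 is the FP=k rank
    boundary.  ``fp_grid_boundaries`` maps each sampled FP to that order
    statistic (absent when fewer negatives were detected).
    """

    model_id: str
    build: str
    alpha: int
    n_neg: int
    pos_evalues: np.ndarray
    neg_evalues_sorted: np.ndarray
    fp_grid: tuple[int, ...]
    fp_grid_boundaries: dict[int, float]
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]

    def tp_below_fp(self, fp: int) -> int:
        """Largest TP achievable at a threshold admitting at most ``fp``
        false positives (right-continuous staircase height at FPR=fp/n_neg)."""
        pos = np.sort(self.pos_evalues[np.isfinite(self.pos_evalues)])
        if fp >= len(self.neg_evalues_sorted):
            return int(len(pos))
        return int(np.searchsorted(pos, self.neg_evalues_sorted[fp], side="left"))

    def tpr_below_fp(self, fp: int) -> float:
        return self.tp_below_fp(fp) / self.alpha

    def fpr_of_evalue(self, e: float) -> float:
        """FPR at threshold e: (#negatives <= e) / n_neg."""
        return float(np.searchsorted(self.neg_evalues_sorted, e, side="right")) / self.n_neg


@dataclasses.dataclass
class ModelCalibration:
    """Both builds' tables plus the strata they were derived from."""

    model_id: str
    tables: dict[str, CalibrationTable]
    strata: StratifiedHits | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def make_query_set(library: DomainLibrary, target_model_id: str) -> CalibrationQuerySet:
    """Build the model-specific query set: alpha seed rows (degapped) as
    positives, every other model's consensus as a negative."""
    if target_model_id not in library:
        raise KeyError(f"model {target_model_id!r} not in library")
    target = library[target_model_id]
    positives = [
        (f"{target_model_id}/seed{i + 1}", seq)
        for i, seq in enumerate(target.seed.ungapped_rows())
    ]
    if not positives:
        raise ValueError("target model has no seed sequences")
    negatives = [(m.model_id, m.consensus) for m in library if m.model_id != target_model_id]
    return CalibrationQuerySet(target_model_id, positives, negatives)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def stratify_hits(
    glocal_hits: Sequence[DomainHit], local_hits: Sequence[DomainHit]
) -> StratifiedHits:
    """Pair hits of the two builds per query by model-span overlap.

    Among a query's local hits that overlap its glocal hit by at least one
    model position, the one with maximal overlap is paired (ties to the
    smaller model start); all remaining hits are orphaned.
    """
    models = {h.model_id for h in glocal_hits} | {h.model_id for h in local_hits}
    if len(models) > 1:
        raise ValueError("stratify_hits expects hits of a single target model")
    local_by_query: dict[str, list[DomainHit]] = {}
    for h in local_hits:
        local_by_query.setdefault(h.query_id, []).append(h)

    paired: list[tuple[DomainHit, DomainHit]] = []
    orphaned_glocal: list[DomainHit] = []
    used: set[int] = set()
    for g in glocal_hits:
        candidates = [
            l
            for l in local_by_query.get(g.query_id, [])
            if _overlap(g.alignment.model_span, l.alignment.model_span) >= 1
        ]
        if not candidates:
            orphaned_glocal.append(g)
            continue
        best = max(
            candidates,
            key=lambda l: (
                _overlap(g.alignment.model_span, l.alignment.model_span),
                -l.alignment.model_span[0],
            ),
        )
        paired.append((g, best))
        used.add(id(best))
    orphaned_local = [h for h in local_hits if id(h) not in used]
    return StratifiedHits(paired, orphaned_glocal, orphaned_local)


def reconstruct_glocal_to_local(
    glocal: ScoredAlignment,
    local_model_span: tuple[int, int],
    evd_glocal: EVDParams,
    Z: int,
) -> tuple[float, float]:
    """Windowed re-score of a glocal alignment over its local counterpart's
    model span; the new E-value keeps the glocal build's Gumbel parameters.

    The identity window [1, L] reproduces the original score and E-value.
    """
    L = len(glocal.per_position_scores)
    a = max(1, local_model_span[0])
    b = min(L, local_model_span[1])
    if a > b:
        raise ValueError(f"window {local_model_span} does not overlap model positions 1..{L}")
    score = float(glocal.per_position_scores[a - 1 : b].sum())
    return score, evalue(score, evd_glocal, Z)


def build_calibration_table(
    pos_evalues: Sequence[float],
    neg_evalues: Sequence[float],
    alpha: int,
    n_neg: int,
    fp_grid: Sequence[int] = DEFAULT_FP_GRID,
    model_id: str = "",
    build: str = "",
) -> CalibrationTable:
    """Construct the ROC/PR staircases and FP-grid boundaries.

    Thresholds sweep the distinct observed finite E-values; at threshold e,
    FP = #(neg <= e), TP = #(pos <= e), FPR = FP/n_neg, TPR = TP/alpha and
    precision = TP/(TP+FP).  Non-detections enter as +inf and never count as
    detected.
    """
    if alpha < 1 or n_neg < 1:
        raise ValueError("alpha and n_neg must be >= 1")
    pos = np.asarray(list(pos_evalues), dtype=float)
    neg = np.asarray(list(neg_evalues), dtype=float)
    if len(pos) < alpha:  # undetected positives may simply be omitted by callers
        pos = np.concatenate([pos, np.full(alpha - len(pos), np.inf)])
    neg_sorted = np.sort(neg[np.isfinite(neg)])
    pos_sorted = np.sort(pos)

    thresholds = np.unique(np.concatenate([pos_sorted[np.isfinite(pos_sorted)], neg_sorted]))
    roc: list[tuple[float, float]] = []
    pr: list[tuple[float, float]] = []
    for e in thresholds:
        fp = int(np.searchsorted(neg_sorted, e, side="right"))
        tp = int(np.searchsorted(pos_sorted, e, side="right"))
        roc.append((fp / n_neg, tp / alpha))
        if tp + fp > 0:
            pr.append((tp / alpha, tp / (tp + fp)))

    boundaries = {
        int(k): float(neg_sorted[k - 1]) for k in fp_grid if 1 <= k <= len(neg_sorted)
    }
    return CalibrationTable(
        model_id=model_id,
        build=build,
        alpha=int(alpha),
        n_neg=int(n_neg),
        pos_evalues=pos,
        neg_evalues_sorted=neg_sorted,
        fp_grid=tuple(int(k) for k in fp_grid),
        fp_grid_boundaries=boundaries,
        roc_points=roc,
        pr_points=pr,
    )


def fpr_of_fp(fp: int, n_neg: int) -> float:
    """False-positive rate of rank fp among n_neg negatives: fp / n_neg."""
    if n_neg < 1:
        raise ValueError("n_neg must be >= 1")
    if fp < 0 or fp > n_neg:
        raise ValueError(f"fp must be in [0, {n_neg}], got {fp}")
    return fp / n_neg


def coverage_per_model(
    positive_hits: Sequence[DomainHit],
    model_length: int,
    fpr_threshold: float,
    table: CalibrationTable,
) -> float:
    """Mean fractional model coverage of the detected positive hits.

    A positive hit is detected at the threshold when its E-value's FPR
    (negatives at or below it, over n_neg) does not exceed ``fpr_threshold``.
    Full-length alignments give coverage 1.  Returns NaN when no positive hit
    is detected (undefined, never zero).
    """
    if model_length < 1:
        raise ValueError("model_length must be >= 1")
    fractions = [
        h.alignment.model_span_length / model_length
        for h in positive_hits
        if math.isfinite(h.evalue) and table.fpr_of_evalue(h.evalue) <= fpr_threshold
    ]
    if not fractions:
        return math.nan
    return float(np.mean(fractions))


def library_fpr_evalue_profile(
    tables: Iterable[CalibrationTable], fp_grid: Sequence[int] = DEFAULT_FP_GRID
) -> pd.DataFrame:
    """Library-level FPR-to-E-value profile: per build and FP grid point, the
    median and IQR of the boundary E-values across models (models lacking a
    boundary at that FP are skipped for that row)."""
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one calibration table")
    rows = []
    for build in sorted({t.build for t in tables}):
        sub = [t for t in tables if t.build == build]
        n_neg = sub[0].n_neg
        for fp in fp_grid:
            vals = [t.fp_grid_boundaries[fp] for t in sub if fp in t.fp_grid_boundaries]
            if not vals:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "build": build,
                    "fp": int(fp),
                    "fpr": fpr_of_fp(int(fp), n_neg),
                    "median_evalue": float(med),
                    "iqr_evalue": float(q3 - q1),
                    "n_models": len(vals),
                }
            )
    return pd.DataFrame(rows, columns=["build", "fp", "fpr", "median_evalue", "iqr_evalue", "n_models"])


# ---------------------------------------------------------------------------
# Calibration driver
# ---------------------------------------------------------------------------


def _derived_seed(rng_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=rng_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def ensure_calibrated(
    model: DomainModel, model_index: int, rng_seed: int, n_null: int = 200
) -> None:
    """Fit Gumbel nulls for both builds if not already present."""
    if model.evd_glocal is None:
        model.evd_glocal = calibrate_evd(
            model.glocal_build, n_samples=n_null, rng_seed=_derived_seed(rng_seed, model_index, 0)
        )
    if model.evd_local is None:
        model.evd_local = calibrate_evd(
            model.local_build, n_samples=n_null, rng_seed=_derived_seed(rng_seed, model_index, 1)
        )


def calibrate_model(
    library: DomainLibrary,
    target_model_id: str,
    rng_seed: int = 0,
    Z: int | None = None,
    e_cutoff: float = 1000.0,
    n_null: int = 200,
    fp_grid: Sequence[int] = DEFAULT_FP_GRID,
    keep_strata: bool = True,
) -> ModelCalibration:
    """Run the full per-model calibration: dual-build searches over the
    model-specific query set, stratification, glocal reconstruction, and
    ROC table construction for both builds."""
    if Z is None:
        Z = library.n_total
    target = library[target_model_id]
    model_index = [m.model_id for m in library].index(target_model_id)
    ensure_calibrated(target, model_index, rng_seed, n_null)

    qs = make_query_set(library, target_model_id)
    queries = qs.all_queries()
    glocal_hits = search_model_vs_seqdb(target, "glocal", queries, Z, e_cutoff)
    local_hits = search_model_vs_seqdb(target, "local", queries, Z, e_cutoff)
    strata = stratify_hits(glocal_hits, local_hits)

    # per-query E-value for the glocal build: reconstructed for paired hits,
    # original for orphans; for the local build: best domain E-value
    e_glocal: dict[str, float] = {}
    for g, l in strata.paired:
        _, e_new = reconstruct_glocal_to_local(
            g.alignment, l.alignment.model_span, target.evd("glocal"), Z
        )
        e_glocal[g.query_id] = min(e_glocal.get(g.query_id, np.inf), e_new)
    for g in strata.orphaned_glocal:
        e_glocal[g.query_id] = min(e_glocal.get(g.query_id, np.inf), g.evalue)
    e_local: dict[str, float] = {}
    for h in local_hits:
        e_local[h.query_id] = min(e_local.get(h.query_id, np.inf), h.evalue)

    pos_ids = [qid for qid, _ in qs.positives]
    neg_ids = [qid for qid, _ in qs.negatives]
    tables: dict[str, CalibrationTable] = {}
    for build, e_by_query in (("glocal", e_glocal), ("local", e_local)):
        pos = [e_by_query.get(q, np.inf) for q in pos_ids]
        neg = [e_by_query.get(q, np.inf) for q in neg_ids]
        tables[build] = build_calibration_table(
            pos, neg, qs.alpha, len(neg_ids), fp_grid, model_id=target_model_id, build=build
        )
    return ModelCalibration(target_model_id, tables, strata if keep_strata else None)


def calibrate_library(
    library: DomainLibrary,
    rng_seed: int = 0,
    Z: int | None = None,
    e_cutoff: float = 1000.0,
    n_null: int = 200,
    fp_grid: Sequence[int] = DEFAULT_FP_GRID,
    keep_strata: bool = False,
) -> dict[str, ModelCalibration]:
    """Calibrate every model in the library; deterministic given rng_seed."""
    return {
        m.model_id: calibrate_model(
            library, m.model_id, rng_seed, Z, e_cutoff, n_null, fp_grid, keep_strata
        )
        for m in library
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_calibration(
    calibrations: Mapping[str, ModelCalibration],
    library: DomainLibrary,
    out_dir: str | Path,
) -> None:
    """Write per model+build E-value tables (TSV) plus a JSON summary with
    Gumbel parameters and FP-grid boundaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}
    for model_id, cal in calibrations.items():
        model = library[model_id]
        entry: dict = {"builds": {}}
        for build, table in cal.tables.items():
            rows = [("pos", e) for e in table.pos_evalues] + [
                ("neg", e) for e in table.neg_evalues_sorted
            ]
            df = pd.DataFrame(rows, columns=["label", "evalue"])
            df.to_csv(out / f"{model_id}.{build}.tsv", sep="\t", index=False)
            evd = model.evd(build)
            entry["builds"][build] = {
                "mu": evd.mu,
                "lambda": evd.lam,
                "n_samples": evd.n_samples,
                "rng_seed": evd.rng_seed,
                "alpha": table.alpha,
                "n_neg": table.n_neg,
                "fp_grid": list(table.fp_grid),
                "boundaries": {str(k): v for k, v in table.fp_grid_boundaries.items()},
            }
        summary[model_id] = entry
    (out / "summary.json").write_text(json.dumps(summary, indent=1))


def read_calibration(calib_dir: str | Path) -> dict[str, ModelCalibration]:
    """Rebuild calibration tables (and EVD params in ``.evds``) from disk."""
    calib_dir = Path(calib_dir)
    summary = json.loads((calib_dir / "summary.json").read_text())
    out: dict[str, ModelCalibration] = {}
    for model_id, entry in summary.items():
        tables: dict[str, CalibrationTable] = {}
        evds: dict[str, EVDParams] = {}
        for build, meta in entry["builds"].items():
            df = pd.read_csv(calib_dir / f"{model_id}.{build}.tsv", sep="\t")
            pos = df.loc[df["label"] == "pos", "evalue"].to_numpy(float)
            neg = df.loc[df["label"] == "neg", "evalue"].to_numpy(float)
            tables[build] = build_calibration_table(
                pos, neg, meta["alpha"], meta["n_neg"], meta["fp_grid"], model_id, build
            )
            evds[build] = EVDParams(
                mu=meta["mu"],
                lam=meta["lambda"],
                n_samples=meta["n_samples"],
                rng_seed=meta["rng_seed"],
            )
        cal = ModelCalibration(model_id, tables)
        cal.evds = evds  # type: ignore[attr-defined]
        out[model_id] = cal
    return out
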