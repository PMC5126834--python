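"""Three-stage annotation workflow with FP(FPR) assignment and concordance.

Stage 1 scans each query against two sub-libraries: the N models whose
glocal build was selected as more sensitive (permissive E-value cutoff 24)
and the M remaining models through their fast local build (cutoff 0.1); the
cutoffs correspond to the largest sampled FP ranks of the two builds'
library-wide calibration.  Stage 2 re-aligns every local hit's (query, model)
pair with the glocal engine so that every final annotation spans the full
model.  Stage 3 assigns each hit a false-positive count by locating its
E-value within the calibrated FP-grid boundary intervals and taking the
nearer margin in log10-E; E-values below the FP=1 boundary get the "FP<1"
sentinel and E-values beyond the last sampled boundary "beyond-grid".

The concordance screen compares the FP assigned under each build for the
same hit: |FP_glocal - FP_local| <= 4 is concordant, and hits with
FP_glocal - FP_local < -4 (the local build's FPR estimate is markedly worse)
are flagged for scrutiny.
"""

from __future__ import annotations

import dataclasses
import math
import time
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DEFAULT_FP_GRID, CalibrationTable, ModelCalibration, fpr_of_fp
from .engine import DomainHit, ScoredAlignment, evalue, viterbi_glocal, viterbi_local_multihit
from .library import DomainLibrary
from .selection import GLOCAL, LOCAL, SelectionResult

__all__ = [
    "FP_BELOW_GRID",
    "FP_BEYOND_GRID",
    "WorkflowConfig",
    "AnnotationRecord",
    "builds_from_selection",
    "run_stage1",
    "run_stage2",
    "assign_fpr",
    "run_pipeline",
    "concordance_screen",
    "annotation_table",
]

FP_BELOW_GRID = "FP<1"
FP_BEYOND_GRID = "beyond-grid"


@dataclasses.dataclass
class WorkflowConfig:
    """Run configuration; the E-value cutoffs default to the calibrated
    upper limits of the two builds (0.1 local, 24 glocal)."""

    Z: int
    e_cutoff_local: float = 0.1
    e_cutoff_glocal: float = 24.0
    fp_grid: tuple[int, ...] = DEFAULT_FP_GRID
    top_n_override: int | None = None
    measure_reference: bool = False  # also time a glocal scan of the local sub-library

    def __post_init__(self) -> None:
        if self.e_cutoff_local <= 0 or self.e_cutoff_glocal <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if list(self.fp_grid) != sorted(self.fp_grid):
            raise ValueError("fp_grid must be ascending")


@dataclasses.dataclass
class AnnotationRecord:
    """Final annotation: always a full-model glocal alignment.

    ``fp``/``fpr`` are the assignment under the build that detected the hit;
    ``fp_glocal`` (always present) and ``fp_local`` (present for local-build
    detections) keep the per-build assignments for the concordance screen.
    """

    query_id: str
    model_id: str
    alignment: ScoredAlignment
    evalue_glocal: float
    evalue_local: float | None
    fp: "int | str"
    fpr: float
    fp_glocal: "int | str"
    fpr_glocal: float
    fp_local: "int | str | None" = None
    fpr_local: float | None = None
    source_build: str = GLOCAL


def builds_from_selection(
    selection: Mapping[str, SelectionResult], top_n_override: int | None = None
) -> dict[str, str]:
    """Map every model to the build the workflow runs it with.

    Undetermined models run as local builds.  With ``top_n_override``, only
    the top-n glocal-selected models (ranked by count_y, then mean normalized
    AUC difference, descending) keep the glocal build.
    """
    builds = {
        mid: (GLOCAL if r.chosen_build == GLOCAL else LOCAL) for mid, r in selection.items()
    }
    if top_n_override is not None:
        glocal_ids = [mid for mid, b in builds.items() if b == GLOCAL]
        ranked = sorted(
            glocal_ids,
            key=lambda mid: (
                -selection[mid].count_y,
                -float(np.mean(list(selection[mid].auc_diff_by_x.values()))),
                mid,
            ),
        )
        keep = set(ranked[: max(0, top_n_override)])
        for mid in glocal_ids:
            if mid not in keep:
                builds[mid] = LOCAL
    return builds


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_stage1(
    queries: Sequence[tuple[str, str]],
    library: DomainLibrary,
    builds: Mapping[str, str],
    config: WorkflowConfig,
) -> tuple[list[DomainHit], list[DomainHit], dict[str, set[str]], dict[str, float], dict[str, float]]:
    """Split-library scan.

    Returns (local_hits, glocal_hits, models_to_realign_by_query,
    per-model local scan times, per-model glocal scan times).
    """
    missing = [m.model_id for m in library if m.model_id not in builds]
    if missing:
        raise ValueError(f"selection does not cover models: {missing[:5]}")
    local_hits: list[DomainHit] = []
    glocal_hits: list[DomainHit] = []
    k_models: dict[str, set[str]] = {qid: set() for qid, _ in queries}
    t_local: dict[str, float] = {}
    t_glocal: dict[str, float] = {}
    for model in library:
        build = builds[model.model_id]
        evd = model.evd(build)
        t0 = time.perf_counter()
        if build == LOCAL:
            for qid, seq in queries:
                if not seq:
                    continue
                for aln in viterbi_local_multihit(model.local_build, seq, qid):
                    e = evalue(aln.bit_score, evd, config.Z)
                    if e <= config.e_cutoff_local:
                        local_hits.append(DomainHit(qid, model.model_id, "local", aln, e))
                        k_models[qid].add(model.model_id)
            t_local[model.model_id] = time.perf_counter() - t0
        else:
            for qid, seq in queries:
                aln = viterbi_glocal(model.glocal_build, seq, qid)
                e = evalue(aln.bit_score, evd, config.Z)
                if e <= config.e_cutoff_glocal:
                    glocal_hits.append(DomainHit(qid, model.model_id, "glocal", aln, e))
            t_glocal[model.model_id] = time.perf_counter() - t0
    return local_hits, glocal_hits, k_models, t_local, t_glocal


def run_stage2(
    local_hits: Sequence[DomainHit],
    library: DomainLibrary,
    queries: Mapping[str, str],
    config: WorkflowConfig,
) -> tuple[dict[tuple[str, str], tuple[ScoredAlignment, float]], dict[str, float]]:
    """Glocal full-domain re-alignment of every (query, model) pair with a
    local hit; one re-alignment per pair, E-value under the glocal Gumbel."""
    pairs: list[tuple[str, str]] = []
    seen = set()
    for h in local_hits:
        key = (h.query_id, h.model_id)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    out: dict[tuple[str, str], tuple[ScoredAlignment, float]] = {}
    t_realign: dict[str, float] = {}
    for qid, mid in pairs:
        model = library[mid]
        t0 = time.perf_counter()
        aln = viterbi_glocal(model.glocal_build, queries[qid], qid)
        e = evalue(aln.bit_score, model.evd("glocal"), config.Z)
        t_realign[mid] = t_realign.get(mid, 0.0) + (time.perf_counter() - t0)
        out[(qid, mid)] = (aln, e)
    return out, t_realign


def assign_fpr(
    hit_evalue: float,
    table: CalibrationTable,
    fp_grid: Sequence[int] | None = None,
) -> tuple["int | str", float]:
    """Assign a hit to the nearer margin of its FP-grid E-value interval.

    Distance is measured in log10 E-value; an exact midpoint goes to the
    less significant (larger-FP) margin.  Returns (fp, fpr) with fpr = NaN
    for the two sentinels.
    """
    boundaries = table.fp_grid_boundaries
    if fp_grid is not None:
        boundaries = {k: v for k, v in boundaries.items() if k in set(fp_grid)}
    if not boundaries:
        raise ValueError("calibration table has no FP-grid boundaries")
    fps = sorted(boundaries)
    evals = [boundaries[k] for k in fps]
    if hit_evalue < evals[0]:
        return FP_BELOW_GRID, math.nan
    if hit_evalue > evals[-1]:
        return FP_BEYOND_GRID, math.nan
    # locate the containing interval [E(fp_i), E(fp_{i+1})]
    idx = int(np.searchsorted(evals, hit_evalue, side="left"))
    if math.isclose(hit_evalue, evals[idx], rel_tol=0.0, abs_tol=0.0) or hit_evalue == evals[idx]:
        fp = fps[idx]
        return fp, fpr_of_fp(fp, table.n_neg)
    lo, hi = idx - 1, idx
    d_lo = math.log10(hit_evalue) - math.log10(evals[lo])
    d_hi = math.log10(evals[hi]) - math.log10(hit_evalue)
    fp = fps[lo] if d_lo < d_hi else fps[hi]  # midpoint tie -> larger FP
    return fp, fpr_of_fp(fp, table.n_neg)


def run_pipeline(
    queries: Sequence[tuple[str, str]],
    library: DomainLibrary,
    calibrations: Mapping[str, ModelCalibration],
    builds: Mapping[str, str],
    config: WorkflowConfig,
) -> tuple[list[AnnotationRecord], dict]:
    """Run all three stages and return annotation records plus a run summary
    with the speed-model bookkeeping terms."""
    qmap = dict(queries)
    local_hits, glocal_hits, k_models, t_local, t_glocal_native = run_stage1(
        queries, library, builds, config
    )
    realigned, t_realign = run_stage2(local_hits, library, qmap, config)

    # best local E-value per (query, model)
    best_local: dict[tuple[str, str], float] = {}
    for h in local_hits:
        key = (h.query_id, h.model_id)
        best_local[key] = min(best_local.get(key, math.inf), h.evalue)

    records: list[AnnotationRecord] = []
    for h in glocal_hits:
        fp, fpr = assign_fpr(h.evalue, calibrations[h.model_id].tables["glocal"], config.fp_grid)
        records.append(
            AnnotationRecord(
                query_id=h.query_id,
                model_id=h.model_id,
                alignment=h.alignment,
                evalue_glocal=h.evalue,
                evalue_local=None,
                fp=fp,
                fpr=fpr,
                fp_glocal=fp,
                fpr_glocal=fpr,
                source_build=GLOCAL,
            )
        )
    for (qid, mid), (aln, e_glocal) in realigned.items():
        e_local = best_local[(qid, mid)]
        fp_l, fpr_l = assign_fpr(e_local, calibrations[mid].tables["local"], config.fp_grid)
        fp_g, fpr_g = assign_fpr(e_glocal, calibrations[mid].tables["glocal"], config.fp_grid)
        records.append(
            AnnotationRecord(
                query_id=qid,
                model_id=mid,
                alignment=aln,
                evalue_glocal=e_glocal,
                evalue_local=e_local,
                fp=fp_l,
                fpr=fpr_l,
                fp_glocal=fp_g,
                fpr_glocal=fpr_g,
                fp_local=fp_l,
                fpr_local=fpr_l,
                source_build=LOCAL,
            )
        )
    records.sort(key=lambda r: (r.query_id, r.model_id))

    n_glocal_models = sum(1 for b in builds.values() if b == GLOCAL)
    n_local_models = len(builds) - n_glocal_models
    summary = {
        "N": n_glocal_models,
        "M": n_local_models,
        "K_total": len(realigned),
        "K_by_query": {q: sorted(ms) for q, ms in k_models.items()},
        "L_total": len(glocal_hits),
        "n_records": len(records),
        "timings": {
            "t_local_by_model": t_local,
            "t_glocal_native_by_model": t_glocal_native,
            "t_realign_by_model": t_realign,
        },
    }
    if config.measure_reference and n_local_models:
        # reference glocal scan over the local sub-library, for the speed model
        t_ref: dict[str, float] = {}
        for model in library:
            if builds[model.model_id] != LOCAL:
                continue
            evd = model.evd("glocal")
            t0 = time.perf_counter()
            for qid, seq in queries:
                aln = viterbi_glocal(model.glocal_build, seq, qid)
                evalue(aln.bit_score, evd, config.Z)
            t_ref[model.model_id] = time.perf_counter() - t0
        summary["timings"]["t_reference_glocal_by_model"] = t_ref
    return records, summary


def concordance_screen(
    records: Sequence[AnnotationRecord], tolerance: int = 4
) -> tuple[pd.DataFrame, list[AnnotationRecord], list[AnnotationRecord]]:
    """Compare the per-build FP assignments of dual-assigned records.

    Records with a sentinel FP on either side are excluded from the
    difference histogram and returned separately.  A record is concordant
    when |FP_glocal - FP_local| <= tolerance and flagged when
    FP_glocal - FP_local < -tolerance.
    """
    rows = []
    flagged: list[AnnotationRecord] = []
    excluded: list[AnnotationRecord] = []
    for r in records:
        if r.fp_local is None:
            continue  # glocal-native record: nothing to compare
        if not (isinstance(r.fp_glocal, int) and isinstance(r.fp_local, int)):
            excluded.append(r)
            continue
        diff = r.fp_glocal - r.fp_local
        concordant = abs(diff) <= tolerance
        if diff < -tolerance:
            flagged.append(r)
        rows.append(
            {
                "query_id": r.query_id,
                "model_id": r.model_id,
                "fp_glocal": r.fp_glocal,
                "fp_local": r.fp_local,
                "fp_diff": diff,
                "concordant": concordant,
            }
        )
    df = pd.DataFrame(
        rows, columns=["query_id", "model_id", "fp_glocal", "fp_local", "fp_diff", "concordant"]
    )
    return df, flagged, excluded


def annotation_table(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Tab-separated-friendly annotation table with sentinel FPs rendered
    as "FP<1" / ">grid"."""

    def _fp(v):
        if v == FP_BEYOND_GRID:
            return ">grid"
        return v

    rows = [
        {
            "query_id": r.query_id,
            "model_id": r.model_id,
            "hmm_from": r.alignment.model_span[0],
            "hmm_to": r.alignment.model_span[1],
            "seq_from": r.alignment.seq_span[0],
            "seq_to": r.alignment.seq_span[1],
            "evalue_glocal": r.evalue_glocal,
            "evalue_local": r.evalue_local if r.evalue_local is not None else "",
            "fp": _fp(r.fp),
            "fpr": r.fpr,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "model_id",
            "hmm_from",
            "hmm_to",
            "seq_from",
            "seq_to",
            "evalue_glocal",
            "evalue_local",
            "fp",
            "fpr",
        ],
    )
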