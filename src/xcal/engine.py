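"""Alignment engines, score statistics and library search drivers.

Two Viterbi engines score a query sequence against a profile HMM in log2-odds
("bit") space against a background residue model:

* ``viterbi_glocal`` — global over the model, local over the sequence: the
  single best path that traverses match/delete positions 1..L exactly once,
  with flanking sequence residues scored as background (zero bits).
* ``viterbi_local_multihit`` — fragmented alignment: entry at any match
  position (probability 1/L), free exit after any match position, and a
  restart loop (probability 0.5, i.e. one bit per additional domain) that
  permits several non-overlapping domain instances on one query.

Score significance is assessed with a Gumbel (extreme-value) null fitted by
maximum likelihood to Viterbi scores of background-sampled sequences, giving
E-values E = Z * (1 - exp(-exp(-lambda * (s - mu)))) for a database of Z
sequences.

All dynamic programming is in log2 space with deterministic tie-breaking, so
identical inputs and seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import AMINO_ACIDS, AA_INDEX, DomainLibrary, DomainModel, ProfileHMM

__all__ = [
    "ScoredAlignment",
    "EVDParams",
    "DomainHit",
    "encode_sequence",
    "viterbi_glocal",
    "viterbi_local_multihit",
    "best_viterbi_score",
    "fit_gumbel",
    "calibrate_evd",
    "evalue",
    "scan_sequence",
    "search_model_vs_seqdb",
    "write_hit_table",
    "read_hit_table",
    "read_domtblout_table",
]

NEG_INF = -np.inf
_TB_ATOL = 1e-9  # traceback predecessor matching tolerance

#: bits charged per additional domain in the multihit parse (restart prob 0.5)
MULTIHIT_RESTART_BITS = 1.0

HIT_TABLE_COLUMNS = [
    "query_id",
    "model_id",
    "build",
    "seq_from",
    "seq_to",
    "hmm_from",
    "hmm_to",
    "bit_score",
    "evalue",
]


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ScoredAlignment:
    """One sequence-to-model alignment with its score decomposition.

    Coordinates are 1-based inclusive.  ``per_position_scores[i]`` is the bit
    contribution attributed to model position ``model_span[0] + i``: its
    emission (zero for a delete), any insert block that follows it, the
    transition to the next position, and — at the first position — the entry
    term.  The contributions sum to ``bit_score`` exactly.
    """

    query_id: str
    model_id: str
    mode: str  # "glocal" | "local"
    seq_span: tuple[int, int]
    model_span: tuple[int, int]
    state_path: list[tuple[str, int, int | None]]
    bit_score: float
    per_position_scores: np.ndarray

    @property
    def model_span_length(self) -> int:
        return self.model_span[1] - self.model_span[0] + 1


@dataclasses.dataclass(frozen=True)
class EVDParams:
    """Gumbel null parameters for one model build: location mu (bits) and
    scale lambda (1/bits), plus provenance of the fit."""

    mu: float
    lam: float
    n_samples: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be positive")


@dataclasses.dataclass
class DomainHit:
    """A scored sequence-to-model hit; FP/FPR fields stay unset until the
    annotation workflow's assignment stage."""

    query_id: str
    model_id: str
    build: str  # "glocal" | "local"
    alignment: ScoredAlignment
    evalue: float
    assigned_fp: "int | str | None" = None  # count, "FP<1" or "beyond-grid"
    assigned_fpr: float | None = None


# ---------------------------------------------------------------------------
# Model compilation (probabilities -> bit scores)
# ---------------------------------------------------------------------------


class _CompiledModel:
    """Log2-space score tables for one ProfileHMM."""

    def __init__(self, model: ProfileHMM) -> None:
        model.validate()
        L = model.length
        bg = model.background
        # column 20 is the ambiguity/background column (zero log-odds)
        self.em = np.zeros((L, 21))
        self.em[:, :20] = np.log2(model.match_emissions / bg)
        self.ib = np.zeros((L, 21))
        self.ib[:, :20] = np.log2(model.insert_emissions / bg)
        with np.errstate(divide="ignore"):
            self.bmm = np.log2(model.t_mm)
            self.bmi = np.log2(model.t_mi)
            self.bmd = np.log2(model.t_md)
            self.bim = np.log2(model.t_im)
            self.bii = np.log2(model.t_ii)
            self.bdm = np.log2(model.t_dm)
            self.bdd = np.log2(model.t_dd)
            self.b_bm = float(np.log2(model.begin_to_match))
            self.b_bd = float(np.log2(model.begin_to_delete))
        self.ent_local = -math.log2(L)
        self.L = L
        # prefix sums of delete-chain costs: S[k] = sum(bdd[0..k-1])
        self.dd_prefix = np.concatenate(([0.0], np.cumsum(self.bdd[: L - 1]))) if L > 1 else np.zeros(1)


def _compiled(model: ProfileHMM) -> _CompiledModel:
    cm = model.__dict__.get("_compiled")
    if cm is None:
        cm = _CompiledModel(model)
        model.__dict__["_compiled"] = cm
    return cm


def encode_sequence(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; ambiguity codes map to the
    zero-log-odds background column."""
    return np.array([AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# Dynamic programming
# ---------------------------------------------------------------------------


def _delete_row(ent: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Best delete-state values along one DP row.

    ``ent[a]`` is the score upon entering delete column ``a`` directly (from
    the begin state or from match ``a-1``); chains extend with per-column
    costs whose prefix sums are ``S``.  Returns
    ``D[k] = max_{a<=k} ent[a] + S[k] - S[a]``.
    """
    return S + np.maximum.accumulate(ent - S)


def _glocal_matrices(cm: _CompiledModel, enc: np.ndarray):
    n, L = len(enc), cm.L
    M = np.full((n + 1, L), NEG_INF)
    I = np.full((n + 1, L), NEG_INF)
    D = np.full((n + 1, L), NEG_INF)

    ent = np.full(L, NEG_INF)
    ent[0] = cm.b_bd
    D[0] = _delete_row(ent, cm.dd_prefix)
    for j in range(1, n + 1):
        x = enc[j - 1]
        pm, pi, pd = M[j - 1], I[j - 1], D[j - 1]
        best_in = np.maximum(np.maximum(pm + cm.bmm, pi + cm.bim), pd + cm.bdm)
        M[j, 0] = cm.em[0, x] + cm.b_bm
        if L > 1:
            M[j, 1:] = cm.em[1:, x] + best_in[:-1]
            I[j, : L - 1] = cm.ib[: L - 1, x] + np.maximum(
                pm[: L - 1] + cm.bmi[: L - 1], pi[: L - 1] + cm.bii[: L - 1]
            )
        ent = np.full(L, NEG_INF)
        ent[0] = cm.b_bd
        if L > 1:
            ent[1:] = M[j, :-1] + cm.bmd[:-1]
        D[j] = _delete_row(ent, cm.dd_prefix)
    return M, I, D


def _local_matrices(cm: _CompiledModel, enc: np.ndarray, multihit: bool):
    """Local-mode DP; ``base[j]`` is the best completed-parse score available
    before starting a domain after j consumed residues (0 for the first
    domain, XJ[j]-restart for later ones)."""
    n, L = len(enc), cm.L
    M = np.full((n + 1, L), NEG_INF)
    I = np.full((n + 1, L), NEG_INF)
    D = np.full((n + 1, L), NEG_INF)
    XJ = np.full(n + 1, NEG_INF)
    base = np.zeros(n + 1)

    for j in range(1, n + 1):
        x = enc[j - 1]
        pm, pi, pd = M[j - 1], I[j - 1], D[j - 1]
        entry = base[j - 1] + cm.ent_local
        best_in = np.maximum(np.maximum(pm + cm.bmm, pi + cm.bim), pd + cm.bdm)
        M[j, 0] = cm.em[0, x] + entry
        if L > 1:
            M[j, 1:] = cm.em[1:, x] + np.maximum(best_in[:-1], entry)
            I[j, : L - 1] = cm.ib[: L - 1, x] + np.maximum(
                pm[: L - 1] + cm.bmi[: L - 1], pi[: L - 1] + cm.bii[: L - 1]
            )
        ent = np.full(L, NEG_INF)
        if L > 1:
            ent[1:] = M[j, :-1] + cm.bmd[:-1]
        D[j] = _delete_row(ent, cm.dd_prefix)
        e_j = float(np.max(M[j]))  # free exit from any match state
        XJ[j] = max(XJ[j - 1], e_j)
        if multihit:
            base[j] = max(0.0, XJ[j] - MULTIHIT_RESTART_BITS)
    return M, I, D, XJ, base


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_TB_ATOL, abs_tol=_TB_ATOL)


def _traceback(
    cm: _CompiledModel,
    enc: np.ndarray,
    M: np.ndarray,
    I: np.ndarray,
    D: np.ndarray,
    j: int,
    k: int,
    state: str,
    entry_base,  # callable(j) -> entry-score base at row j, or None if impossible
    glocal: bool,
):
    """Walk one domain path back to its entry; returns (steps, j_entry, k_entry,
    entry_kind) with steps in forward order."""
    steps: list[tuple[str, int, int | None]] = []
    while True:
        if state == "M":
            steps.append(("M", k + 1, j))
            x = enc[j - 1]
            v = M[j, k] - cm.em[k, x]
            if k == 0:
                if glocal:
                    return steps[::-1], j, k, "BM"
                return steps[::-1], j, k, "ENTRY"
            # predecessor priority: match, insert, delete, then local entry
            if _close(v, M[j - 1, k - 1] + cm.bmm[k - 1]):
                j, k, state = j - 1, k - 1, "M"
            elif _close(v, I[j - 1, k - 1] + cm.bim[k - 1]):
                j, k, state = j - 1, k - 1, "I"
            elif _close(v, D[j - 1, k - 1] + cm.bdm[k - 1]):
                j, k, state = j - 1, k - 1, "D"
            elif not glocal and entry_base is not None and _close(v, entry_base(j - 1) + cm.ent_local):
                return steps[::-1], j, k, "ENTRY"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed at match state")
        elif state == "I":
            steps.append(("I", k + 1, j))
            x = enc[j - 1]
            v = I[j, k] - cm.ib[k, x]
            if _close(v, M[j - 1, k] + cm.bmi[k]):
                j, state = j - 1, "M"
            elif _close(v, I[j - 1, k] + cm.bii[k]):
                j, state = j - 1, "I"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed at insert state")
        else:  # delete
            steps.append(("D", k + 1, None))
            v = D[j, k]
            if k == 0:
                if glocal and _close(v, cm.b_bd):
                    return steps[::-1], j, k, "BD"
                raise RuntimeError("traceback failed at delete entry")  # pragma: no cover
            if _close(v, M[j, k - 1] + cm.bmd[k - 1]):
                k, state = k - 1, "M"
            elif _close(v, D[j, k - 1] + cm.bdd[k - 1]):
                k, state = k - 1, "D"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed at delete state")


def _per_position_scores(
    cm: _CompiledModel,
    enc: np.ndarray,
    steps: list[tuple[str, int, int | None]],
    entry_bits: float,
    k_first: int,
    k_last: int,
) -> np.ndarray:
    """Attribute the path's bits to model positions k_first..k_last (0-based).

    Position k collects its emission, the insert block following it and the
    transition leaving it; the entry term goes to the first position.
    """
    width = k_last - k_first + 1
    c = np.zeros(width)
    c[0] += entry_bits
    prev: tuple[str, int] | None = None
    for state, pos1, j in steps:
        k = pos1 - 1
        if state == "M":
            c[k - k_first] += cm.em[k, enc[j - 1]]
        elif state == "I":
            c[k - k_first] += cm.ib[k, enc[j - 1]]
        if prev is not None:
            ps, pk = prev
            if ps == "M" and state == "M":
                c[pk - k_first] += cm.bmm[pk]
            elif ps == "M" and state == "I":
                c[pk - k_first] += cm.bmi[pk]
            elif ps == "M" and state == "D":
                c[pk - k_first] += cm.bmd[pk]
            elif ps == "I" and state == "M":
                c[pk - k_first] += cm.bim[pk]
            elif ps == "I" and state == "I":
                c[pk - k_first] += cm.bii[pk]
            elif ps == "D" and state == "M":
                c[pk - k_first] += cm.bdm[pk]
            elif ps == "D" and state == "D":
                c[pk - k_first] += cm.bdd[pk]
        prev = (state, k)
    return c


def _seq_span(steps: list[tuple[str, int, int | None]]) -> tuple[int, int]:
    consumed = [j for _, _, j in steps if j is not None]
    if not consumed:
        return (1, 0)  # empty span sentinel (all-delete path)
    return (min(consumed), max(consumed))


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------


def viterbi_glocal(model: ProfileHMM, seq: str, query_id: str = "query") -> ScoredAlignment:
    """Best glocal alignment: the model is traversed completely (positions
    1..L via match or delete states); sequence flanks score zero bits.

    The empty sequence is allowed and yields the all-delete path.
    """
    if model.mode != "glocal":
        raise ValueError("viterbi_glocal requires a glocal-mode model")
    cm = _compiled(model)
    enc = encode_sequence(seq)
    M, I, D = _glocal_matrices(cm, enc)
    L = cm.L
    endM, endD = M[:, L - 1], D[:, L - 1]
    jM, jD = int(np.argmax(endM)), int(np.argmax(endD))
    if endM[jM] >= endD[jD]:
        j_end, end_state = jM, "M"
    else:
        j_end, end_state = jD, "D"
    steps, _, _, entry_kind = _traceback(cm, enc, M, I, D, j_end, L - 1, end_state, None, glocal=True)
    entry_bits = cm.b_bm if entry_kind == "BM" else cm.b_bd
    pps = _per_position_scores(cm, enc, steps, entry_bits, 0, L - 1)
    return ScoredAlignment(
        query_id=query_id,
        model_id=model.model_id,
        mode="glocal",
        seq_span=_seq_span(steps),
        model_span=(1, L),
        state_path=steps,
        bit_score=float(pps.sum()),
        per_position_scores=pps,
    )


def viterbi_local_multihit(model: ProfileHMM, seq: str, query_id: str = "query") -> list[ScoredAlignment]:
    """Multihit local alignment: zero or more non-overlapping domains.

    The optimal parse is reported; when the best parse contains no domain of
    positive score, the single best-scoring domain is still returned (weak
    hits are filtered later by E-value cutoffs, not by the engine), so a
    non-empty sequence always yields at least one domain.  Domains are
    ordered by their sequence span.
    """
    if model.mode != "local":
        raise ValueError("viterbi_local_multihit requires a local-mode model")
    cm = _compiled(model)
    enc = encode_sequence(seq)
    n = len(enc)
    if n == 0:
        return []
    M, I, D, XJ, base = _local_matrices(cm, enc, multihit=True)

    domains: list[ScoredAlignment] = []
    j = n
    # earliest row achieving the final parse score
    while j > 1 and XJ[j - 1] == XJ[j]:
        j -= 1
    while j >= 1 and np.isfinite(XJ[j]):
        row = M[j]
        k = int(np.argmax(row))
        if not _close(float(row[k]), float(XJ[j])):  # pragma: no cover - defensive
            raise RuntimeError("multihit traceback lost the exit row")
        steps, j_entry, k_entry, _ = _traceback(
            cm, enc, M, I, D, j, k, "M", lambda jj: base[jj], glocal=False
        )
        pps = _per_position_scores(cm, enc, steps, cm.ent_local, k_entry, k)
        domains.append(
            ScoredAlignment(
                query_id=query_id,
                model_id=model.model_id,
                mode="local",
                seq_span=_seq_span(steps),
                model_span=(k_entry + 1, k + 1),
                state_path=steps,
                bit_score=float(pps.sum()),
                per_position_scores=pps,
            )
        )
        # continue with the parse preceding this domain's entry; the entry
        # used base[j] = max(0, XJ[j] - restart), so earlier domains exist
        # only when the restart strictly paid off
        j = j_entry - 1
        if not (j >= 1 and np.isfinite(XJ[j]) and XJ[j] - MULTIHIT_RESTART_BITS > 0.0):
            break
        while j > 1 and XJ[j - 1] == XJ[j]:
            j -= 1
    return domains[::-1]


def best_viterbi_score(model: ProfileHMM, seq: str) -> float:
    """Score-only statistic used for null calibration: the glocal score, or
    the best single-domain local score (which may be negative)."""
    cm = _compiled(model)
    enc = encode_sequence(seq)
    if model.mode == "glocal":
        M, I, D = _glocal_matrices(cm, enc)
        return float(max(np.max(M[:, cm.L - 1]), np.max(D[:, cm.L - 1])))
    if len(enc) == 0:
        raise ValueError("cannot score an empty sequence in local mode")
    M, _, _, _, _ = _local_matrices(cm, enc, multihit=False)
    return float(np.max(M[1:]))


# ---------------------------------------------------------------------------
# Gumbel calibration and E-values
# ---------------------------------------------------------------------------


def fit_gumbel(scores: Sequence[float]) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda)."""
    from scipy import stats

    arr = np.asarray(scores, dtype=float)
    if arr.size < 2 or float(np.std(arr)) == 0.0:
        raise ValueError("degenerate score sample: cannot fit a Gumbel")
    loc, scale = stats.gumbel_r.fit(arr)
    return float(loc), float(1.0 / scale)


def calibrate_evd(
    model: ProfileHMM,
    n_samples: int = 200,
    length_range: tuple[int, int] | None = None,
    rng_seed: int = 0,
) -> EVDParams:
    """Fit the Gumbel null of a model build from Viterbi scores of i.i.d.
    background-sampled sequences.

    Null sequence lengths are uniform over [0.5 L, 2 L] by default, bracketing
    typical query envelopes.  Deterministic given ``rng_seed``.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    L = model.length
    if length_range is None:
        length_range = (max(1, L // 2), 2 * L)
    rng = np.random.default_rng(rng_seed)
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n_samples)
    bg = model.background
    scores = np.empty(n_samples)
    for i, n in enumerate(lengths):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(n), p=bg))
        scores[i] = best_viterbi_score(model, seq)
    mu, lam = fit_gumbel(scores)
    return EVDParams(mu=mu, lam=lam, n_samples=n_samples, rng_seed=rng_seed)


def evalue(bit_score: float, evd: EVDParams, Z: int) -> float:
    """E = Z * (1 - exp(-exp(-lambda (s - mu)))): expected chance hits at
    least as strong in a database of Z sequences."""
    if Z < 1:
        raise ValueError("Z must be >= 1")
    return float(Z * -np.expm1(-np.exp(-evd.lam * (bit_score - evd.mu))))


# ---------------------------------------------------------------------------
# Search drivers
# ---------------------------------------------------------------------------


def _hits_for_pair(
    model: DomainModel, build: str, query_id: str, seq: str, Z: int, e_cutoff: float
) -> list[DomainHit]:
    evd = model.evd(build)
    hits: list[DomainHit] = []
    if build == "glocal":
        aln = viterbi_glocal(model.glocal_build, seq, query_id)
        e = evalue(aln.bit_score, evd, Z)
        if e <= e_cutoff:
            hits.append(DomainHit(query_id, model.model_id, "glocal", aln, e))
    else:
        for aln in viterbi_local_multihit(model.local_build, seq, query_id):
            e = evalue(aln.bit_score, evd, Z)
            if e <= e_cutoff:
                hits.append(DomainHit(query_id, model.model_id, "local", aln, e))
    return hits


def scan_sequence(
    library: DomainLibrary,
    selected_builds: dict[str, str],
    seq: str,
    Z: int,
    e_cutoffs: dict[str, float],
    query_id: str = "query",
) -> list[DomainHit]:
    """Scan one query against the library, each model through its selected
    build's engine and E-value cutoff; hits sorted by E-value."""
    hits: list[DomainHit] = []
    for model in library:
        build = selected_builds.get(model.model_id)
        if build is None:
            continue
        if build not in ("glocal", "local"):
            raise KeyError(f"unknown build {build!r}")
        hits.extend(_hits_for_pair(model, build, query_id, seq, Z, e_cutoffs[build]))
    hits.sort(key=lambda h: (h.evalue, h.model_id, h.alignment.seq_span))
    return hits


def search_model_vs_seqdb(
    model: DomainModel,
    build: str,
    seq_set: Sequence[tuple[str, str]],
    Z: int,
    e_cutoff: float = 1000.0,
) -> list[DomainHit]:
    """One model against many sequences (the calibration direction), with a
    permissive default cutoff to capture as many hits as possible."""
    hits: list[DomainHit] = []
    if build not in ("glocal", "local"):
        raise KeyError(f"unknown build {build!r}")
    for query_id, seq in seq_set:
        if build == "local" and len(seq) == 0:
            continue
        hits.extend(_hits_for_pair(model, build, query_id, seq, Z, e_cutoff))
    return hits


# ---------------------------------------------------------------------------
# Hit-table I/O (1-based inclusive coordinates)
# ---------------------------------------------------------------------------


def hits_to_frame(hits: Sequence[DomainHit]) -> pd.DataFrame:
    rows = [
        {
            "query_id": h.query_id,
            "model_id": h.model_id,
            "build": h.build,
            "seq_from": h.alignment.seq_span[0],
            "seq_to": h.alignment.seq_span[1],
            "hmm_from": h.alignment.model_span[0],
            "hmm_to": h.alignment.model_span[1],
            "bit_score": h.alignment.bit_score,
            "evalue": h.evalue,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def write_hit_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_domtblout_table(path: str | Path) -> list[DomainHit]:
    """Adapter for externally produced per-domain tables in the whitespace
    layout of hmmscan/hmmsearch ``--domtblout`` output.  I/O only: records
    carry spans, scores and E-values but no state path."""
    hits: list[DomainHit] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 22:
            raise ValueError(f"domtblout line has {len(f)} fields, expected >= 22")
        model_id, query_id = f[0], f[3]
        aln = ScoredAlignment(
            query_id=query_id,
            model_id=model_id,
            mode="local",
            seq_span=(int(f[17]), int(f[18])),
            model_span=(int(f[15]), int(f[16])),
            state_path=[],
            bit_score=float(f[13]),
            per_position_scores=np.zeros(0),
        )
        hits.append(DomainHit(query_id, model_id, "local", aln, float(f[12])))
    return hits
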