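"""Independent brute-force alignment oracles for tiny problem instances.

These enumerate every legal state path recursively, scoring straight from
the profile's probability arrays with math.log2 — no shared code with the
dynamic-programming engines beyond the model definition itself.
"""

from __future__ import annotations

import math
from functools import lru_cache

from xcal.library import AA_INDEX, ProfileHMM

NEG_INF = float("-inf")


def _lg(p: float) -> float:
    return NEG_INF if p <= 0.0 else math.log2(p)


def brute_force_glocal(hmm: ProfileHMM, seq: str) -> float:
    """Best glocal path score: model positions 1..L traversed exactly once,
    sequence flanks free."""
    L = hmm.length
    x = [AA_INDEX[c] for c in seq]
    n = len(x)

    def em(k: int, j: int) -> float:
        return math.log2(hmm.match_emissions[k][x[j]] / hmm.background[x[j]])

    def ib(k: int, j: int) -> float:
        return math.log2(hmm.insert_emissions[k][x[j]] / hmm.background[x[j]])

    @lru_cache(maxsize=None)
    def after_M(k: int, j: int) -> float:
        if k == L - 1:
            return 0.0  # exit; trailing flank free
        best = _lg(hmm.t_md[k]) + after_D(k + 1, j)
        if j < n:
            best = max(best, _lg(hmm.t_mm[k]) + em(k + 1, j) + after_M(k + 1, j + 1))
            best = max(best, _lg(hmm.t_mi[k]) + ib(k, j) + after_I(k, j + 1))
        return best

    @lru_cache(maxsize=None)
    def after_I(k: int, j: int) -> float:
        best = NEG_INF
        if j < n:
            best = max(best, _lg(hmm.t_im[k]) + em(k + 1, j) + after_M(k + 1, j + 1))
            best = max(best, _lg(hmm.t_ii[k]) + ib(k, j) + after_I(k, j + 1))
        return best

    @lru_cache(maxsize=None)
    def after_D(k: int, j: int) -> float:
        if k == L - 1:
            return 0.0
        best = _lg(hmm.t_dd[k]) + after_D(k + 1, j)
        if j < n:
            best = max(best, _lg(hmm.t_dm[k]) + em(k + 1, j) + after_M(k + 1, j + 1))
        return best

    best = NEG_INF
    for s in range(n + 1):  # entry after s free flank residues
        best = max(best, _lg(hmm.begin_to_delete) + after_D(0, s))
        if s < n:
            best = max(best, _lg(hmm.begin_to_match) + em(0, s) + after_M(0, s + 1))
    return best


def _enumerate_domains(hmm: ProfileHMM, seq: str) -> dict[tuple[int, int], float]:
    """Best single-domain score per half-open sequence interval [s, e):
    uniform 1/L entry at any match state, free exit after any match state."""
    L = hmm.length
    x = [AA_INDEX[c] for c in seq]
    n = len(x)
    ent = -math.log2(L)

    def em(k: int, j: int) -> float:
        return math.log2(hmm.match_emissions[k][x[j]] / hmm.background[x[j]])

    def ib(k: int, j: int) -> float:
        return math.log2(hmm.insert_emissions[k][x[j]] / hmm.background[x[j]])

    best: dict[tuple[int, int], float] = {}

    def record(s: int, e: int, score: float) -> None:
        key = (s, e)
        if score > best.get(key, NEG_INF):
            best[key] = score

    def walk_M(k: int, j: int, s: int, score: float) -> None:
        record(s, j, score)  # free exit from any match state
        if j < n and k < L - 1:
            walk_M(k + 1, j + 1, s, score + _lg(hmm.t_mm[k]) + em(k + 1, j))
            walk_I(k, j + 1, s, score + _lg(hmm.t_mi[k]) + ib(k, j))
        if k < L - 1:
            walk_D(k + 1, j, s, score + _lg(hmm.t_md[k]))

    def walk_I(k: int, j: int, s: int, score: float) -> None:
        if j < n:
            walk_M(k + 1, j + 1, s, score + _lg(hmm.t_im[k]) + em(k + 1, j))
            walk_I(k, j + 1, s, score + _lg(hmm.t_ii[k]) + ib(k, j))

    def walk_D(k: int, j: int, s: int, score: float) -> None:
        if j < n and k < L - 1:
            walk_M(k + 1, j + 1, s, score + _lg(hmm.t_dm[k]) + em(k + 1, j))
        if k < L - 1:
            walk_D(k + 1, j, s, score + _lg(hmm.t_dd[k]))

    for s in range(n):
        for k0 in range(L):
            walk_M(k0, s + 1, s, ent + em(k0, s))
    return best


def brute_force_local_multihit(hmm: ProfileHMM, seq: str, restart_bits: float = 1.0) -> float:
    """Best multihit parse score (>=1 domain): ordered non-overlapping
    domains, each extra domain charged ``restart_bits``."""
    n = len(seq)
    dom = _enumerate_domains(hmm, seq)
    Q = [NEG_INF] * (n + 1)  # best non-empty parse within prefix j
    for j in range(1, n + 1):
        Q[j] = Q[j - 1]
        for s in range(j):
            d = dom.get((s, j))
            if d is None:
                continue
            prior = max(0.0, Q[s] - restart_bits) if Q[s] > NEG_INF else 0.0
            Q[j] = max(Q[j], d + prior)
    return Q[n]
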