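"""Domain-library data model: seed alignments, profile HMMs, consensus sequences.

A domain family is represented by its curated seed multiple sequence
alignment.  From the seed, two profile HMMs are estimated that share every
emission parameter and differ only in alignment-mode topology:

* a *glocal* build — global over the model (entry only at position 1, exit
  only at position L, through match or delete chains), local over the
  sequence; and
* a *local multihit* build — entry/exit mass at every match position, with a
  restart loop allowing several domain instances per query.

Every alignment column becomes a match position, so the model length L always
equals the number of alignment columns.  Emission and transition
probabilities are add-pseudocount estimates over the 20-letter amino-acid
alphabet; ambiguity codes ('X' etc.) are excluded from counts and score as
background downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "AA_INDEX",
    "GAP_CHARS",
    "SeedAlignment",
    "ProfileHMM",
    "DomainModel",
    "DomainLibrary",
    "read_seed_alignment",
    "read_library_manifest",
    "build_profile",
    "build_domain_model",
    "consensus_sequence",
    "uniform_background",
]

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS: frozenset[str] = frozenset("-.")

_PROB_TOL = 1e-9


def uniform_background() -> np.ndarray:
    """Uniform background distribution over the 20 amino acids."""
    return np.full(20, 1.0 / 20.0)


class FormatError(ValueError):
    """Raised for unparseable or ragged alignment input."""


class EmptyInputError(ValueError):
    """Raised for empty files or zero-column alignments."""


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SeedAlignment:
    """A seed multiple sequence alignment for one domain family.

    ``rows`` are aligned residue strings of equal length with ``-``/``.`` as
    gap characters; residues are upper-cased on ingestion.  The row count
    alpha is the number of calibration positives for this family.
    """

    model_id: str
    rows: tuple[str, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError(f"{self.model_id}: alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"{self.model_id}: ragged rows with lengths {sorted(lengths)}")
        if self.n_columns == 0:
            raise EmptyInputError(f"{self.model_id}: alignment has zero columns")
        allowed = set(AMINO_ACIDS) | GAP_CHARS | {"X"}
        for row in self.rows:
            bad = set(row) - allowed
            if bad:
                raise FormatError(f"{self.model_id}: illegal characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def alpha(self) -> int:
        """Number of seed sequences (calibration positives)."""
        return len(self.rows)

    def ungapped_rows(self) -> list[str]:
        """Seed sequences with gap columns stripped (the positive queries)."""
        return ["".join(c for c in row if c not in GAP_CHARS) for row in self.rows]


@dataclasses.dataclass
class ProfileHMM:
    """Profile HMM for one domain family in one alignment-mode configuration.

    Arrays are indexed by 0-based match position k (model position k+1):

    match_emissions, insert_emissions : (L, 20) probability rows
    t_mm, t_mi, t_md : from match k+1 (used for k = 0..L-2)
    t_im, t_ii       : from insert k+1 (used for k = 0..L-2)
    t_dm, t_dd       : from delete k+1 (used for k = 0..L-2)
    begin_to_match, begin_to_delete : glocal entry split at model position 1

    The glocal build enters only at position 1 and exits only after position
    L; the local build enters any match position with probability 1/L and
    exits freely after any match position (the documented uniform
    entry / free-exit convention), with a multihit restart probability of
    0.5 charged per additional domain.
    """

    model_id: str
    mode: str  # "glocal" | "local"
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    begin_to_match: float
    begin_to_delete: float
    background: np.ndarray = dataclasses.field(default_factory=uniform_background)

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.length
        if L < 1:
            raise ValueError("model must have at least one match position")
        if self.mode not in ("glocal", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("match_emissions", "insert_emissions"):
            arr = getattr(self, name)
            if arr.shape != (L, 20):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(L, 20)}")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=_PROB_TOL):
                raise ValueError(f"{name} rows do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=_PROB_TOL):
            raise ValueError("background does not sum to 1")
        if L > 1:
            interior = slice(0, L - 1)
            if not np.allclose(
                self.t_mm[interior] + self.t_mi[interior] + self.t_md[interior], 1.0, atol=_PROB_TOL
            ):
                raise ValueError("match transition rows do not sum to 1")
            if not np.allclose(self.t_im[interior] + self.t_ii[interior], 1.0, atol=_PROB_TOL):
                raise ValueError("insert transition rows do not sum to 1")
            if not np.allclose(self.t_dm[interior] + self.t_dd[interior], 1.0, atol=_PROB_TOL):
                raise ValueError("delete transition rows do not sum to 1")
        if not np.isclose(self.begin_to_match + self.begin_to_delete, 1.0, atol=_PROB_TOL):
            raise ValueError("begin-state transitions do not sum to 1")


@dataclasses.dataclass
class DomainModel:
    """A named family: seed, both builds, consensus, per-build Gumbel fits."""

    model_id: str
    seed: SeedAlignment
    glocal_build: ProfileHMM
    local_build: ProfileHMM
    consensus: str
    evd_glocal: "object | None" = None  # EVDParams, set by calibration
    evd_local: "object | None" = None

    @property
    def length(self) -> int:
        return self.glocal_build.length

    def build(self, which: str) -> ProfileHMM:
        if which == "glocal":
            return self.glocal_build
        if which == "local":
            return self.local_build
        raise KeyError(f"unknown build {which!r}")

    def evd(self, which: str):
        if which not in ("glocal", "local"):
            raise KeyError(f"unknown build {which!r}")
        evd = self.evd_glocal if which == "glocal" else self.evd_local
        if evd is None:
            raise ValueError(f"{self.model_id}: {which} build is not calibrated")
        return evd


@dataclasses.dataclass
class DomainLibrary:
    """Ordered collection of domain models with unique identifiers."""

    models: list[DomainModel]

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate model_ids in library")
        if len(self.models) < 2:
            raise ValueError("library needs at least 2 models")
        self._by_id = {m.model_id: m for m in self.models}

    @property
    def n_total(self) -> int:
        return len(self.models)

    @property
    def n_negatives(self) -> int:
        """Negative-set size for any one model's calibration: N_total - 1."""
        return self.n_total - 1

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, model_id: str) -> DomainModel:
        return self._by_id[model_id]

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._by_id


# ---------------------------------------------------------------------------
# Seed-alignment ingestion
# ---------------------------------------------------------------------------


def read_seed_alignment(path: str | Path, fmt: str = "stockholm", model_id: str | None = None) -> SeedAlignment:
    """Read a seed alignment from Stockholm or aligned FASTA.

    Annotation lines (``#=GF``/``#=GC``/``#=GS``/``#=GR``) are ignored;
    residues are upper-cased and ``.`` gaps preserved as gap characters.
    """
    from Bio import AlignIO

    path = Path(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path}: empty file")
    bio_fmt = {"stockholm": "stockholm", "aligned-fasta": "fasta", "fasta": "fasta"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), bio_fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows = tuple(str(rec.seq).upper() for rec in msa)
    names = tuple(rec.id for rec in msa)
    return SeedAlignment(model_id=model_id or path.stem, rows=rows, names=names)


def read_library_manifest(path: str | Path) -> list[tuple[str, Path, str, Path | None]]:
    """Read a library manifest.

    One ``model_id<TAB>seed_path[<TAB>format[<TAB>local_seed_path]]`` per
    line; the optional fourth column points at an alternative alignment used
    only for the local build.  Relative paths resolve against the manifest.
    """
    path = Path(path)
    entries: list[tuple[str, Path, str, Path | None]] = []

    def _resolve(p: str) -> Path:
        sp = Path(p)
        return sp if sp.is_absolute() else path.parent / sp

    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: manifest line needs model_id<TAB>path: {line!r}")
        fmt = parts[2] if len(parts) > 2 else "stockholm"
        local_path = _resolve(parts[3]) if len(parts) > 3 else None
        entries.append((parts[0], _resolve(parts[1]), fmt, local_path))
    if not entries:
        raise EmptyInputError(f"{path}: empty manifest")
    return entries


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------


def _column_states(row: str) -> np.ndarray:
    """Per-column state of one aligned row: True = match (residue), False = delete."""
    return np.array([c not in GAP_CHARS for c in row], dtype=bool)


def build_profile(
    seed: SeedAlignment,
    mode: str,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Every column is a match position.  Match emissions are
    ``(count + pseudocount) / (depth + 20 * pseudocount)`` with depth the
    number of counted residues in the column ('X' excluded).  A gap in a row
    routes that row through the delete state at that column, contributing to
    the match/delete transition counts; transition probabilities are
    pseudocounted and renormalised per source state.  Insert states are never
    observed in a seed (all columns are matches), so insert emissions default
    to background and insert transitions to the pseudocount prior.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if background is None:
        background = uniform_background()
    L = seed.n_columns
    c = float(pseudocount)

    counts = np.zeros((L, 20))
    for row in seed.rows:
        for k, ch in enumerate(row):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[k, idx] += 1.0
    depth = counts.sum(axis=1, keepdims=True)
    match_emissions = (counts + c) / (depth + 20.0 * c)

    insert_emissions = np.tile(background, (L, 1))

    # Transition counts along each row's match/delete column path.
    n_mm = np.zeros(L)
    n_md = np.zeros(L)
    n_dm = np.zeros(L)
    n_dd = np.zeros(L)
    n_bm = 0.0
    n_bd = 0.0
    for row in seed.rows:
        states = _column_states(row)
        if states[0]:
            n_bm += 1.0
        else:
            n_bd += 1.0
        for k in range(L - 1):
            if states[k] and states[k + 1]:
                n_mm[k] += 1.0
            elif states[k] and not states[k + 1]:
                n_md[k] += 1.0
            elif not states[k] and states[k + 1]:
                n_dm[k] += 1.0
            else:
                n_dd[k] += 1.0

    denom_m = n_mm + n_md + 3.0 * c  # outcomes {M->M, M->I, M->D}
    t_mm = (n_mm + c) / denom_m
    t_mi = np.full(L, c) / denom_m
    t_md = (n_md + c) / denom_m
    denom_d = n_dm + n_dd + 2.0 * c
    t_dm = (n_dm + c) / denom_d
    t_dd = (n_dd + c) / denom_d
    t_im = np.full(L, 0.5)  # unobserved: pseudocount prior over {I->M, I->I}
    t_ii = np.full(L, 0.5)

    n_rows = float(seed.alpha)
    begin_to_match = (n_bm + c) / (n_rows + 2.0 * c)
    begin_to_delete = (n_bd + c) / (n_rows + 2.0 * c)

    hmm = ProfileHMM(
        model_id=seed.model_id,
        mode=mode,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        begin_to_match=begin_to_match,
        begin_to_delete=begin_to_delete,
        background=background,
    )
    hmm.validate()
    return hmm


def consensus_sequence(model: ProfileHMM) -> str:
    """Per-position argmax residue string; emission ties break alphabetically."""
    model.validate()
    # argmax over columns sorted alphabetically == AMINO_ACIDS order, and
    # np.argmax returns the first maximum, i.e. the alphabetically smallest.
    idx = np.argmax(model.match_emissions, axis=1)
    return "".join(AMINO_ACIDS[i] for i in idx)


def build_domain_model(
    seed: SeedAlignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    local_seed: SeedAlignment | None = None,
) -> DomainModel:
    """Build both alignment-mode configurations for one family.

    ``local_seed`` lets callers estimate the local build from a different
    alignment of the same columns (used by the synthetic weakened-local
    fixtures); by default both builds come from the same seed and share all
    emissions.
    """
    glocal = build_profile(seed, "glocal", pseudocount, background)
    local_src = local_seed if local_seed is not None else seed
    if local_src.n_columns != seed.n_columns:
        raise ValueError("local_seed must have the same number of columns")
    local = build_profile(local_src, "local", pseudocount, background)
    return DomainModel(
        model_id=seed.model_id,
        seed=seed,
        glocal_build=glocal,
        local_build=local,
        consensus=consensus_sequence(glocal),
    )
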