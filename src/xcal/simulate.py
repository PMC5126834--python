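"""Deterministic synthetic domain libraries and query sets.

The generator emulates, at desk scale, the ingredients of a domain-library
calibration study: a library of protein families (each a seed alignment of
alpha sequences around a hidden consensus), and query sequences carrying
noisy implanted domain copies between background linkers, plus implant-free
decoys.  Background residues are uniform over the 20 amino acids, matching
the engines' default null model so implant log-odds are
calibration-consistent.

A family's seed rows copy the consensus per column with probability p
(conservation) and substitute a uniform residue otherwise, so the expected
per-column identity is p + (1-p)/20.  The ``weakened_local`` set marks
models whose *local* build is estimated from an extra-noised copy of the
seed, degrading only that build's positive/negative separation — these
models should be selected for their glocal build by the calibration.

Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .library import (
    AMINO_ACIDS,
    DomainLibrary,
    DomainModel,
    SeedAlignment,
    build_domain_model,
    read_library_manifest,
    read_seed_alignment,
)

__all__ = [
    "FixtureSpec",
    "generate_domain_family",
    "generate_mini_library",
    "generate_query_set",
    "write_library_files",
    "load_library",
]

_AA = np.array(list(AMINO_ACIDS))


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic library + query set."""

    n_models: int = 30
    length_range: tuple[int, int] = (60, 90)
    alpha: int = 8
    conservation: float = 0.95
    substitution_rate: float = 0.05  # implant noise off the consensus
    n_queries: int = 30
    implants_per_query: int = 1
    linker_range: tuple[int, int] = (5, 20)
    decoy_fraction: float = 0.2
    rng_seed: int = 0
    weakened_local: frozenset[str] = frozenset()
    # Per-column substitution probability applied to the seed copy the
    # *local* build of a weakened model is estimated from.  The value must
    # leave the noised profile essentially uninformative about the family:
    # positives then interleave with negatives under that build while the
    # clean glocal build still separates them, which is the condition for a
    # uniform glocal advantage over the whole FP set.  At 0.5 roughly half
    # the columns still carry full signal and separation stays perfect, so
    # the weakening is a no-op; 0.9 (keep probability 0.1) reduces the
    # expected per-column log-odds to near zero.
    weaken_noise: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.conservation <= 1.0):
            raise ValueError("conservation must be in (0, 1]")
        if self.n_models < 1 or self.alpha < 1 or self.n_queries < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ValueError("decoy_fraction must be in [0, 1]")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n))


def _noisy_copy(rng: np.random.Generator, template: str, keep_prob: float) -> str:
    keep = rng.random(len(template)) < keep_prob
    subs = rng.choice(_AA, size=len(template))
    return "".join(t if k else s for t, k, s in zip(template, keep, subs))


def generate_domain_family(
    length: int,
    alpha: int,
    conservation: float,
    rng_seed: int | np.random.Generator,
    model_id: str = "model",
) -> tuple[SeedAlignment, str]:
    """One family: uniform-random consensus plus alpha per-column noisy rows."""
    if not (0.0 < conservation <= 1.0):
        raise ValueError("conservation must be in (0, 1]")
    if length < 1 or alpha < 1:
        raise ValueError("length and alpha must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    consensus = _random_seq(rng, length)
    rows = tuple(_noisy_copy(rng, consensus, conservation) for _ in range(alpha))
    names = tuple(f"{model_id}/row{i + 1}" for i in range(alpha))
    return SeedAlignment(model_id=model_id, rows=rows, names=names), consensus


def generate_mini_library(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[DomainLibrary, Path | None]:
    """A library of n_models families with mutually distinct consensus
    sequences; optionally written to disk as Stockholm seeds + manifest."""
    rng = np.random.default_rng(spec.rng_seed)
    models: list[DomainModel] = []
    seen_consensus: set[str] = set()
    local_seeds: dict[str, SeedAlignment] = {}
    for i in range(spec.n_models):
        model_id = f"fam{i + 1:03d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        for attempt in range(100):
            seed, consensus = generate_domain_family(
                length, spec.alpha, spec.conservation, rng, model_id
            )
            if consensus not in seen_consensus:
                break
        else:
            raise RuntimeError(f"{model_id}: duplicate consensus after 100 redraws")
        seen_consensus.add(consensus)
        local_seed = None
        if model_id in spec.weakened_local:
            noised = tuple(
                _noisy_copy(rng, row, 1.0 - spec.weaken_noise) for row in seed.rows
            )
            local_seed = SeedAlignment(model_id=model_id, rows=noised, names=seed.names)
            local_seeds[model_id] = local_seed
        models.append(build_domain_model(seed, local_seed=local_seed))
    library = DomainLibrary(models)
    manifest = None
    if out_dir is not None:
        manifest = write_library_files(library, out_dir, local_seeds)
    return library, manifest


def write_library_files(
    library: DomainLibrary,
    out_dir: str | Path,
    local_seeds: dict[str, SeedAlignment] | None = None,
) -> Path:
    """Write Stockholm seed files and a tab-separated manifest; weakened
    local-build seeds go into sibling ``<model>.local.sto`` files referenced
    by the manifest's fourth column."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    local_seeds = local_seeds or {}
    lines = []
    for model in library:
        path = out / f"{model.model_id}.sto"
        _write_stockholm(model.seed, path)
        fields = [model.model_id, path.name, "stockholm"]
        if model.model_id in local_seeds:
            lpath = out / f"{model.model_id}.local.sto"
            _write_stockholm(local_seeds[model.model_id], lpath)
            fields.append(lpath.name)
        lines.append("\t".join(fields))
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def _write_stockholm(seed: SeedAlignment, path: Path) -> None:
    names = seed.names or tuple(f"row{i + 1}" for i in range(seed.alpha))
    width = max(len(n) for n in names)
    body = "\n".join(f"{n.ljust(width)}  {row}" for n, row in zip(names, seed.rows))
    path.write_text(f"# STOCKHOLM 1.0\n{body}\n//\n")


def load_library(manifest_path: str | Path, pseudocount: float = 1.0) -> DomainLibrary:
    """Rebuild a DomainLibrary from a manifest written by
    ``write_library_files`` (or hand-rolled in the same layout)."""
    entries = read_library_manifest(manifest_path)
    models = []
    for model_id, path, fmt, local_path in entries:
        seed = read_seed_alignment(path, fmt, model_id)
        local_seed = (
            read_seed_alignment(local_path, fmt, model_id) if local_path is not None else None
        )
        models.append(build_domain_model(seed, pseudocount=pseudocount, local_seed=local_seed))
    return DomainLibrary(models)


def generate_query_set(
    library: DomainLibrary, spec: FixtureSpec
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Queries with implanted noisy domain copies plus implant-free decoys.

    Returns (queries, truth) where truth rows are
    (query_id, model_id, seq_from, seq_to), 1-based inclusive.
    """
    if library.n_total < 1:
        raise ValueError("library is empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(1,)))
    n_decoys = int(round(spec.n_queries * spec.decoy_fraction))
    n_implanted = spec.n_queries - n_decoys
    model_ids = [m.model_id for m in library]
    queries: list[tuple[str, str]] = []
    truth_rows = []
    lo, hi = spec.linker_range
    for i in range(n_implanted):
        qid = f"query{i + 1:03d}"
        parts = [_random_seq(rng, int(rng.integers(lo, hi + 1)))]
        pos = len(parts[0])
        for _ in range(spec.implants_per_query):
            mid = model_ids[int(rng.integers(len(model_ids)))]
            implant = _noisy_copy(rng, library[mid].consensus, 1.0 - spec.substitution_rate)
            truth_rows.append(
                {
                    "query_id": qid,
                    "model_id": mid,
                    "seq_from": pos + 1,
                    "seq_to": pos + len(implant),
                }
            )
            linker = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            parts.extend([implant, linker])
            pos += len(implant) + len(linker)
        queries.append((qid, "".join(parts)))
    typical_len = int(np.mean([len(s) for _, s in queries])) if queries else 100
    for i in range(n_decoys):
        qid = f"decoy{i + 1:03d}"
        queries.append((qid, _random_seq(rng, typical_len)))
    truth = pd.DataFrame(truth_rows, columns=["query_id", "model_id", "seq_from", "seq_to"])
    return queries, truth
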