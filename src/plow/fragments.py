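"""Trimer fragment-configuration library.

Fragment assembly discretises the conformational space: new conformations
are built by splicing 6-torsion configurations of three consecutive residues
(trimers), excised from known backbone structures, into the chain.  The
library stores, for every trimer start position ``p`` in ``[1, n-2]`` of the
target chain, a non-empty ordered list of candidate configurations.

Construction policy: configurations whose source 3-mer sequence exactly
matches the target 3-mer at ``p`` are collected first; positions with no
sequence match anywhere fall back to the pool of all excised trimers.  Each
position's list is truncated to ``per_position_cap`` entries (default 200).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .chain import Chain, Conformation, extended_conformation, set_trimer, wrap_angle

__all__ = [
    "TrimerConfig",
    "FragmentLibrary",
    "build_library",
    "sample_config",
    "random_assembly",
    "save_library",
    "load_library",
]

DEFAULT_PER_POSITION_CAP = 200


class LibraryError(ValueError):
    """Library construction or parsing failure."""


@dataclass(frozen=True)
class TrimerConfig:
    """One library entry: six torsions (phi, psi for three consecutive
    residues, degrees) plus provenance."""

    angles: tuple
    source_id: str = ""
    source_seq: str = "XXX"

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        if len(angles) != 6:
            raise LibraryError(f"trimer config needs 6 angles, got {len(angles)}")
        for a in angles:
            if not (-180.0 < a <= 180.0):
                raise LibraryError(f"angle {a} outside (-180, 180]")
        object.__setattr__(self, "angles", angles)

    def as_array(self) -> np.ndarray:
        return np.array(self.angles, dtype=float)


@dataclass
class FragmentLibrary:
    """Per-position trimer configurations for one target chain."""

    target_chain: Chain
    configs: Dict[int, List[TrimerConfig]]

    def __post_init__(self) -> None:
        n = self.target_chain.n
        for p in range(1, n - 1):
            if not self.configs.get(p):
                raise LibraryError(f"position {p} has no configurations")
        extra = set(self.configs) - set(range(1, n - 1))
        if extra:
            raise LibraryError(f"positions outside [1, {n - 2}]: {sorted(extra)}")

    @property
    def positions(self) -> range:
        return range(1, self.target_chain.n - 1)

    def __getitem__(self, position: int) -> List[TrimerConfig]:
        if position not in self.configs:
            raise LibraryError(
                f"position {position} out of range [1, {self.target_chain.n - 2}]"
            )
        return self.configs[position]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentLibrary):
            return NotImplemented
        return (
            self.target_chain == other.target_chain
            and self.configs == other.configs
        )


def _excise_all(structures) -> List[TrimerConfig]:
    pool: List[TrimerConfig] = []
    for s in structures:
        dihedrals = s.dihedrals()
        for p in range(1, s.n - 1):
            lo = 2 * (p - 1)
            angles = tuple(wrap_angle(a) for a in dihedrals[lo : lo + 6])
            pool.append(
                TrimerConfig(
                    angles=angles,
                    source_id=f"{s.structure_id}:{p}",
                    source_seq=s.sequence[p - 1 : p + 2],
                )
            )
    return pool


def build_library(
    structures: Sequence,
    target: Chain,
    per_position_cap: int = DEFAULT_PER_POSITION_CAP,
) -> FragmentLibrary:
    """Excise every trimer from the source structures and index the results
    by the target's 3-mer sequences.

    Deterministic: source order and excision order fix the library exactly.
    """
    structures = list(structures)
    if not structures:
        raise LibraryError("empty structure set")
    if per_position_cap < 1:
        raise LibraryError("per_position_cap must be >= 1")
    pool = _excise_all(structures)
    by_seq: Dict[str, List[TrimerConfig]] = {}
    for cfg in pool:
        by_seq.setdefault(cfg.source_seq, []).append(cfg)
    configs: Dict[int, List[TrimerConfig]] = {}
    for p in range(1, target.n - 1):
        trimer_seq = target.sequence[p - 1 : p + 2]
        matches = by_seq.get(trimer_seq, [])
        chosen = matches if matches else pool  # fallback: all excised trimers
        if not chosen:
            raise LibraryError(f"position {p}: no configurations available")
        configs[p] = list(chosen[:per_position_cap])
    return FragmentLibrary(target_chain=target, configs=configs)


def sample_config(
    lib: FragmentLibrary, position: int, rng: np.random.Generator
) -> TrimerConfig:
    """Uniform draw over the configurations stored for ``position``."""
    options = lib[position]
    return options[int(rng.integers(len(options)))]


def random_assembly(lib: FragmentLibrary, rng: np.random.Generator) -> Conformation:
    """Assemble a uniformly random conformation by fragment assembly.

    Starts from the fully extended conformation and applies one uniformly
    sampled configuration at every trimer position in a fixed left-to-right
    sweep; overlapping windows overwrite earlier writes.
    """
    conf = extended_conformation(lib.target_chain)
    for p in lib.positions:
        conf = set_trimer(conf, p, sample_config(lib, p, rng))
    return conf


_TSV_HEADER = [
    "position",
    "source_id",
    "source_seq",
    "phi1",
    "psi1",
    "phi2",
    "psi2",
    "phi3",
    "psi3",
]


def save_library(lib: FragmentLibrary, path) -> None:
    """Write the library in the canonical TSV dialect (angles at 6 decimals).

    The first line carries the target sequence as a comment; then a header
    line and one row per configuration.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# target={lib.target_chain.sequence}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for p in lib.positions:
            for cfg in lib[p]:
                writer.writerow(
                    [p, cfg.source_id, cfg.source_seq]
                    + [f"{a:.6f}" for a in cfg.angles]
                )


def load_library(path) -> FragmentLibrary:
    """Load a library written by :func:`save_library`; malformed rows raise a
    parse error naming the offending line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# target="):
        raise LibraryError(f"{path}: line 1: missing '# target=' header")
    target = Chain(lines[0].split("=", 1)[1].strip())
    if len(lines) < 2 or lines[1].split("\t") != _TSV_HEADER:
        raise LibraryError(f"{path}: line 2: bad or missing column header")
    configs: Dict[int, List[TrimerConfig]] = {}
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_TSV_HEADER):
            raise LibraryError(
                f"{path}: line {lineno}: expected {len(_TSV_HEADER)} "
                f"tab-separated columns, got {len(fields)}"
            )
        try:
            p = int(fields[0])
            angles = tuple(wrap_angle(float(a)) for a in fields[3:9])
        except ValueError as exc:
            raise LibraryError(f"{path}: line {lineno}: {exc}") from exc
        configs.setdefault(p, []).append(
            TrimerConfig(angles=angles, source_id=fields[1], source_seq=fields[2])
        )
    return FragmentLibrary(target_chain=target, configs=configs)
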