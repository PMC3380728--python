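"""Synthetic inputs: toy chains, synthetic fragment libraries, enumerable
toy landscapes and pseudo-native structures.

Everything here is generated programmatically and is reproducible bit-for-bit
from its seed; no external structure files are required to build or test the
full stack.

The toy landscape realises a discrete, exactly enumerable energy surface
over the fragment-replacement move graph.  One *identity* torsion is
designated in every block of three residues (the phi of residues 2, 5, 8,
...), giving ``L = n_residues // 3`` coordinates; each takes one of ``m``
tag values.  Every trimer window covers exactly one identity torsion (or
none, near a ragged C-terminus), and its library configurations write one of
the ``m`` tags there and the base angle (180) everywhere else.  Fragment
replacement therefore moves the chain on the Hamming graph over ``m**L``
decodable states: one move sets one coordinate to any tag.

The energy is a *staircase of basins*: the binary coordinates are split into
blocks, and within each block the planted minima are the even-length 1-prefix
patterns ``1^t 0^(L_b - t)``.  Odd prefix lengths carry an energy barrier,
stray 1s beyond the prefix ("junk") are penalised, and the prefix length
ramps the energy down linearly, so the planted minima are graded across
``basin_depth_range`` with the deepest at the full prefix.  The number of
planted minima is exactly the product over blocks of the even-level counts,
arranged to equal ``n_basins``.

This organises the surface the way a rugged funnel is organised.  A random
fragment assembly scatters 1s everywhere; greedy descent mostly cleans them
up and lands in a shallow, short-prefix basin — deep basins need many
coordinated bits and are exponentially rare from random restarts.  A
perturbation of a minimum, in contrast, can flip the single bit at the end
of a prefix, leaving a barrier state one move from the *next* minimum of the
staircase: local minima are locally connected, and a trajectory that keeps
deeper minima under Metropolis acceptance ratchets down the staircase.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .chain import Chain, Conformation, extended_conformation, set_trimer, wrap_angle
from .energy import ToyLandscapeModel
from .fragments import FragmentLibrary, TrimerConfig, sample_config

__all__ = [
    "FixtureSpec",
    "make_polyala",
    "make_synthetic_library",
    "make_toy_landscape",
    "make_pseudo_native",
]

HELIX = (-57.0, -47.0)
STRAND = (-120.0, 120.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic fixtures.

    ``basin_depth_range`` is the (lowest, highest) planted basin energy in
    kcal/mol; the deepest basin sits exactly at the lower bound.
    """

    n_residues: int = 20
    configs_per_position: int = 5
    n_basins: int = 2
    basin_depth_range: Tuple[float, float] = (-100.0, -20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.configs_per_position < 1 or self.n_basins < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.basin_depth_range
        if not lo <= hi:
            raise ValueError("basin_depth_range must be (low, high)")


def make_polyala(n: int) -> Chain:
    """An n-residue poly-alanine chain (n >= 3)."""
    return Chain("A" * n)


def make_synthetic_library(
    spec: FixtureSpec,
    mixture: Tuple[float, float, float] = (0.4, 0.4, 0.2),
) -> FragmentLibrary:
    """A synthetic trimer library over a poly-alanine target.

    Each stored configuration is an ideal helix (phi=-57, psi=-47), an ideal
    strand (phi=-120, psi=120) or six uniform-random torsions, drawn with the
    given mixture weights; deterministic per seed.
    """
    chain = make_polyala(spec.n_residues)
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(mixture, dtype=float)
    weights = weights / weights.sum()
    configs: Dict[int, list] = {}
    for p in range(1, chain.n - 1):
        entries = []
        for c in range(spec.configs_per_position):
            kind = rng.choice(3, p=weights)
            if kind == 0:
                angles = HELIX * 3
            elif kind == 1:
                angles = STRAND * 3
            else:
                angles = tuple(wrap_angle(a) for a in rng.uniform(-180.0, 180.0, 6))
            entries.append(
                TrimerConfig(angles=angles, source_id=f"synthetic:{p}:{c}", source_seq="AAA")
            )
        configs[p] = entries
    return FragmentLibrary(target_chain=chain, configs=configs)


def _identity_tags(m: int) -> Tuple[float, ...]:
    # m distinct torsion tags in (-180, 180]; tag 0 is 180, the extended base.
    return tuple(wrap_angle(180.0 - t * 360.0 / (m + 1)) for t in range(m))


TAG_ON = -60.0  # torsion value of an "on" identity bit (off = 180, the base)


def _factor_blocks(n_basins: int) -> list:
    """Decompose n_basins into small factors; each factor K becomes a block
    with K planted levels (even prefixes of a 2(K-1)-bit block)."""
    factors = []
    rest = n_basins
    for f in (2, 3, 5, 7):
        while rest % f == 0:
            factors.append(f)
            rest //= f
    if rest > 1:
        factors.append(rest)
    return sorted(factors, reverse=True)


def make_toy_landscape(
    spec: FixtureSpec,
    max_nodes: int = 10**6,
) -> Tuple[ToyLandscapeModel, FragmentLibrary, Dict[Tuple[int, ...], float]]:
    """Build the enumerable staircase landscape described in the module
    docstring.

    Returns the model, the matching fragment library, and the catalogue of
    planted minima ``{bit-tuple: energy}``.  The identity coordinates are
    binary regardless of ``configs_per_position`` (which sizes the synthetic
    torsion library, not the toy move graph).  Raises if the required state
    space exceeds ``max_nodes`` or the chain is too short to host the
    identity torsions.
    """
    n = spec.n_residues
    nb = spec.n_basins
    if nb == 1:
        blocks = [(2, (2,))]  # one 2-bit block, single planted level t=2
    else:
        blocks = []
        for K in _factor_blocks(nb):
            L_b = 2 * (K - 1)
            blocks.append((L_b, tuple(range(0, L_b + 1, 2))))
    n_coords = sum(L_b for L_b, _ in blocks)
    if 2**n_coords > max_nodes:
        raise ValueError(
            f"state space ~{2**n_coords} nodes exceeds limit {max_nodes}"
        )
    if n < 3 * n_coords:
        raise ValueError(
            f"{nb} basins need {n_coords} identity torsions: "
            f"n_residues must be >= {3 * n_coords}, got {n}"
        )
    chain = make_polyala(n)
    tags = (180.0, TAG_ON)
    identity_residues = [3 * l + 2 for l in range(n_coords)]  # 2, 5, 8, ...
    base6 = (180.0,) * 6

    configs: Dict[int, list] = {}
    for p in range(1, n - 1):
        covered = [r for r in identity_residues if p <= r <= p + 2]
        if covered:
            r = covered[0]  # identity residues are >= 3 apart: at most one
            offset = 2 * (r - p)  # phi of residue r inside the 6-angle window
            configs[p] = [
                TrimerConfig(
                    angles=base6[:offset] + (tags[t],) + base6[offset + 1 :],
                    source_id=f"toy:{p}:{t}",
                    source_seq="AAA",
                )
                for t in range(2)
            ]
        else:
            configs[p] = [
                TrimerConfig(angles=base6, source_id=f"toy:base:{p}", source_seq="AAA")
            ]
    lib = FragmentLibrary(target_chain=chain, configs=configs)

    lo, hi = spec.basin_depth_range
    total_levels = max(sum(L_b for L_b, _ in blocks), 1)
    ramp = (hi - lo) / total_levels  # energy gained per prefix level
    barrier = 1.5 * ramp  # odd prefix levels sit above both even neighbours
    junkpen = 0.75 * ramp  # stray 1 beyond the prefix

    def node_energy(node: Tuple[int, ...]) -> float:
        e = hi
        offset = 0
        for L_b, planted_levels in blocks:
            bits = node[offset : offset + L_b]
            offset += L_b
            t = 0
            while t < L_b and bits[t] == 1:
                t += 1
            junk = sum(bits) - t
            e += -ramp * t + junkpen * junk
            if t not in planted_levels:
                e += barrier
        return e

    table: Dict[Tuple[int, ...], float] = {}
    for node in itertools.product((0, 1), repeat=n_coords):
        table[node] = node_energy(node)

    identity_slots = [(2 * (r - 1), tags) for r in identity_residues]
    model = ToyLandscapeModel(chain, identity_slots, table)

    catalogue: Dict[Tuple[int, ...], float] = {}
    for combo in itertools.product(*(planted for _, planted in blocks)):
        node = []
        for (L_b, _), t in zip(blocks, combo):
            node.extend([1] * t + [0] * (L_b - t))
        node = tuple(node)
        catalogue[node] = table[node]
    return model, lib, catalogue


def make_pseudo_native(
    lib: FragmentLibrary, rng: np.random.Generator
) -> Conformation:
    """Assemble a conformation from one designated "native" configuration per
    position (drawn with ``rng``), giving a ground-truth reference for lRMSD
    and probe tests."""
    conf = extended_conformation(lib.target_chain)
    for p in lib.positions:
        conf = set_trimer(conf, p, sample_config(lib, p, rng))
    return conf
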