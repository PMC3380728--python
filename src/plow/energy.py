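"""Energy models with exact evaluation-budget accounting.

Three pieces live here:

* :class:`EnergyModel` — the evaluation contract.  Every call to
  :meth:`EnergyModel.evaluate` increments a counter by exactly one and raises
  :class:`BudgetExhaustedError` once the counter has reached the configured
  budget; search code treats that signal as normal termination.  Evaluation
  is a pure function of a conformation's dihedrals.

* :class:`AMWStyleModel` — a coarse-grained backbone energy in the spirit of
  associative-memory-with-water potentials: the sum of six non-local terms
  (Lennard-Jones, hydrogen bond, contact, water, burial, radius-of-gyration
  penalty).  Local terms are omitted because fragment-assembled backbones
  already carry near-ideal local geometry.  All constants sit in one
  parameter block (:class:`AMWParams`) and the model is pluggable, so a
  different parameterisation can replace it without touching search code.

* :class:`ToyLandscapeModel` — a tabulated energy over a small discrete move
  graph (one node per choice of trimer configuration at each "active"
  position), enumerable exactly.  This is the verification currency for the
  local-minimum semantics of the greedy search: on a toy landscape,
  :func:`enumerate_minima` lists every true local minimum of the fragment-
  replacement move graph.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .chain import Chain, Conformation, set_trimer

__all__ = [
    "BudgetExhaustedError",
    "EnergyModel",
    "AMWParams",
    "AMWStyleModel",
    "ToyLandscapeModel",
    "enumerate_minima",
]


class BudgetExhaustedError(RuntimeError):
    """Raised when an evaluation is requested after the budget is spent."""


class EnergyModel:
    """Base evaluation contract: counting, budget, purity.

    Subclasses implement ``_energy(conf) -> float`` as a deterministic
    function of the conformation's dihedral angles.
    """

    def __init__(self, budget: Optional[int] = None):
        if budget is not None and budget < 1:
            raise ValueError("budget must be a positive integer or None")
        self.budget = budget
        self.evaluation_count = 0

    def evaluate(self, conf: Conformation) -> float:
        if self.budget is not None and self.evaluation_count >= self.budget:
            raise BudgetExhaustedError(
                f"energy budget of {self.budget} evaluations exhausted"
            )
        self.evaluation_count += 1
        e = float(self._energy(conf))
        conf.energy = e
        return e

    def _energy(self, conf: Conformation) -> float:  # pragma: no cover
        raise NotImplementedError


# Kyte-Doolittle hydrophobicity, rescaled to [0, 1] (1 = most hydrophobic).
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
HYDROPHOBICITY = {aa: (v + 4.5) / 9.0 for aa, v in _KD.items()}


@dataclass(frozen=True)
class AMWParams:
    """Weights, well depths and geometric cutoffs of the AMW-style model.

    Weights are dimensionless multipliers on each term; distances in
    Angstroms, energies in kcal/mol.
    """

    w_lj: float = 1.0
    w_hb: float = 1.0
    w_contact: float = 1.0
    w_water: float = 1.0
    w_burial: float = 1.0
    w_rg: float = 1.0
    # 12-6 Lennard-Jones on backbone atoms; sigma_ij = r_i + r_j.
    lj_epsilon: float = 0.05
    lj_cutoff: float = 8.0
    atom_radii: Tuple[float, float, float, float] = (1.55, 1.70, 1.70, 1.50)
    # backbone H-bond: N...O distance well, gated by the C=O...N angle.
    hb_depth: float = 2.0
    hb_d0: float = 2.9
    hb_sigma: float = 0.3
    hb_cutoff: float = 4.5
    hb_min_angle: float = 100.0
    # CA-CA contact well and the contact-number used by water/burial.
    contact_depth: float = 0.5
    contact_cutoff: float = 6.5
    # water: reward interface-density residues; burial: reward buried
    # hydrophobics (two density regimes of the contact number).
    water_depth: float = 0.3
    water_rho0: float = 2.6
    water_sigma: float = 1.5
    burial_depth: float = 1.0
    burial_rho0: float = 4.5
    burial_slope: float = 1.0
    # quadratic penalty above the target radius of gyration 2.2 * n**0.38.
    rg_coeff: float = 2.2
    rg_exponent: float = 0.38
    # minimum sequence separation for any pairwise interaction.
    min_separation: int = 3


class AMWStyleModel(EnergyModel):
    """Coarse-grained six-term backbone energy (see module docstring).

    The total is the exact sum of the six term values; every pairwise term
    only involves residue pairs at sequence separation >= ``min_separation``,
    so the model is purely non-local.
    """

    name = "amw_style"

    def __init__(self, params: AMWParams = AMWParams(), budget: Optional[int] = None):
        super().__init__(budget=budget)
        self.params = params
        self._pair_cache: Dict[int, dict] = {}

    # -- geometry bookkeeping -------------------------------------------------

    def _pairs(self, n: int) -> dict:
        """Precomputed index arrays for an n-residue chain (cached)."""
        if n in self._pair_cache:
            return self._pair_cache[n]
        sep = self.params.min_separation
        res_of_atom = np.repeat(np.arange(n), 4)
        type_of_atom = np.tile(np.arange(4), n)
        ai, aj = np.triu_indices(4 * n, k=1)
        keep = np.abs(res_of_atom[ai] - res_of_atom[aj]) >= sep
        ai, aj = ai[keep], aj[keep]
        radii = np.asarray(self.params.atom_radii)
        sigma = radii[type_of_atom[ai]] + radii[type_of_atom[aj]]
        ri, rj = np.triu_indices(n, k=1)
        ca_keep = (rj - ri) >= sep
        # H-bond donor/acceptor residue pairs, both orientations.
        hi, hj = np.nonzero(
            np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) >= sep
        )
        cache = {
            "atom_i": ai,
            "atom_j": aj,
            "sigma": sigma,
            "ca_i": ri[ca_keep],
            "ca_j": rj[ca_keep],
            "hb_n": hi,
            "hb_o": hj,
        }
        self._pair_cache[n] = cache
        return cache

    def _geometry(self, conf: Conformation) -> dict:
        """Distances shared by several terms, computed once per evaluation."""
        c = self._pairs(conf.n)
        xyz = conf.coords.reshape(-1, 3)
        ca = conf.coords[:, 1]
        diff = xyz[c["atom_i"]] - xyz[c["atom_j"]]
        atom_d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        cdiff = ca[c["ca_i"]] - ca[c["ca_j"]]
        ca_d = np.sqrt(np.einsum("ij,ij->i", cdiff, cdiff))
        return {"pairs": c, "atom_d": atom_d, "ca_d": ca_d}

    # -- individual terms -----------------------------------------------------

    def term_lennard_jones(self, conf: Conformation, _geom: dict | None = None) -> float:
        p = self.params
        c = self._pairs(conf.n)
        if _geom is None:
            xyz = conf.coords.reshape(-1, 3)
            d = np.linalg.norm(xyz[c["atom_i"]] - xyz[c["atom_j"]], axis=1)
        else:
            d = _geom["atom_d"]
        mask = d < p.lj_cutoff
        if not mask.any():
            return 0.0
        sr6 = (c["sigma"][mask] / d[mask]) ** 6
        return float(p.w_lj * 4.0 * p.lj_epsilon * np.sum(sr6 * sr6 - sr6))

    def term_hbond(self, conf: Conformation) -> float:
        p = self.params
        c = self._pairs(conf.n)
        coords = conf.coords
        n_xyz = coords[c["hb_n"], 0]
        o_xyz = coords[c["hb_o"], 3]
        c_xyz = coords[c["hb_o"], 2]
        d = np.linalg.norm(n_xyz - o_xyz, axis=1)
        mask = d < p.hb_cutoff
        if not mask.any():
            return 0.0
        v1 = c_xyz[mask] - o_xyz[mask]
        v2 = n_xyz[mask] - o_xyz[mask]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        gate = ang >= p.hb_min_angle
        if not gate.any():
            return 0.0
        dd = (d[mask][gate] - p.hb_d0) / p.hb_sigma
        return float(-p.w_hb * p.hb_depth * np.sum(np.exp(-dd * dd)))

    def _ca_distances(self, conf: Conformation, _geom: dict | None = None) -> np.ndarray:
        if _geom is not None:
            return _geom["ca_d"]
        c = self._pairs(conf.n)
        ca = conf.coords[:, 1]
        return np.linalg.norm(ca[c["ca_i"]] - ca[c["ca_j"]], axis=1)

    def _contact_numbers(self, conf: Conformation, _geom: dict | None = None) -> np.ndarray:
        p = self.params
        c = self._pairs(conf.n)
        touching = self._ca_distances(conf, _geom) <= p.contact_cutoff
        rho = np.zeros(conf.n)
        np.add.at(rho, c["ca_i"][touching], 1.0)
        np.add.at(rho, c["ca_j"][touching], 1.0)
        return rho

    def term_contact(self, conf: Conformation, _geom: dict | None = None) -> float:
        p = self.params
        n_contacts = int(np.sum(self._ca_distances(conf, _geom) <= p.contact_cutoff))
        return float(-p.w_contact * p.contact_depth * n_contacts)

    def term_water(self, conf: Conformation, _geom: dict | None = None) -> float:
        p = self.params
        rho = self._contact_numbers(conf, _geom)
        z = (rho - p.water_rho0) / p.water_sigma
        return float(-p.w_water * p.water_depth * np.sum(np.exp(-z * z)))

    def term_burial(self, conf: Conformation, _geom: dict | None = None) -> float:
        p = self.params
        rho = self._contact_numbers(conf, _geom)
        h = np.array([HYDROPHOBICITY[a] for a in conf.chain.sequence])
        s = 1.0 / (1.0 + np.exp(-(rho - p.burial_rho0) / p.burial_slope))
        return float(-p.w_burial * p.burial_depth * np.sum(h * s))

    def radius_of_gyration(self, conf: Conformation) -> float:
        ca = conf.coords[:, 1]
        centered = ca - ca.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(centered * centered, axis=1))))

    def target_rg(self, n: int) -> float:
        return self.params.rg_coeff * n ** self.params.rg_exponent

    def term_rg(self, conf: Conformation) -> float:
        p = self.params
        excess = self.radius_of_gyration(conf) - self.target_rg(conf.n)
        if excess <= 0.0:
            return 0.0
        return float(p.w_rg * excess * excess)

    TERMS = (
        "term_lennard_jones",
        "term_hbond",
        "term_contact",
        "term_water",
        "term_burial",
        "term_rg",
    )

    def term_values(self, conf: Conformation) -> Dict[str, float]:
        return {t: getattr(self, t)(conf) for t in self.TERMS}

    def _energy(self, conf: Conformation) -> float:
        geom = self._geometry(conf)
        return (
            self.term_lennard_jones(conf, geom)
            + self.term_hbond(conf)
            + self.term_contact(conf, geom)
            + self.term_water(conf, geom)
            + self.term_burial(conf, geom)
            + self.term_rg(conf)
        )


class ToyDecodeError(ValueError):
    """A conformation does not correspond to any toy-landscape node."""


class ToyLandscapeModel(EnergyModel):
    """Tabulated energy over a discrete fragment-replacement move graph.

    The model designates a set of *identity slots* in the dihedral vector,
    each carrying one of a finite set of tag angles; a node of the move graph
    is the tuple of tag indices, one per identity slot.  Library
    configurations write only valid tags on identity slots and the shared
    base angle everywhere else, so every conformation reachable by fragment
    replacement decodes to exactly one table entry.
    """

    name = "toy"

    def __init__(
        self,
        chain: Chain,
        identity_slots,  # sequence of (angle-slot index, tuple of tag values)
        table: Dict[Tuple[int, ...], float],
        base_angle: float = 180.0,
        budget: Optional[int] = None,
    ):
        super().__init__(budget=budget)
        self.chain = chain
        self.identity_slots = [
            (int(slot), tuple(float(v) for v in values))
            for slot, values in identity_slots
        ]
        self.table = dict(table)
        self.base_angle = base_angle
        expected = self.shape
        for node in self.table:
            if len(node) != len(expected) or any(
                not 0 <= idx < m for idx, m in zip(node, expected)
            ):
                raise ValueError(f"table node {node} inconsistent with identity slots")

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(len(values) for _, values in self.identity_slots)

    def n_nodes(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1

    def nodes(self):
        return itertools.product(*(range(m) for m in self.shape))

    def decode_angles(self, angles: np.ndarray) -> Tuple[int, ...]:
        node = []
        for slot, values in self.identity_slots:
            a = angles[slot]
            diffs = [abs(((a - v + 180.0) % 360.0) - 180.0) for v in values]
            idx = int(np.argmin(diffs))
            # tags are tens of degrees apart; the loose tolerance absorbs
            # PDB-format quantisation of round-tripped conformations
            if diffs[idx] > 0.5:
                raise ToyDecodeError(
                    f"angle {a} at slot {slot} matches no configuration tag"
                )
            node.append(idx)
        return tuple(node)

    def decode(self, conf: Conformation) -> Tuple[int, ...]:
        return self.decode_angles(conf.angles)

    def node_angles(self, node: Tuple[int, ...]) -> np.ndarray:
        angles = np.full(2 * self.chain.n, self.base_angle)
        for (slot, values), idx in zip(self.identity_slots, node):
            angles[slot] = values[idx]
        return angles

    def node_conformation(self, node: Tuple[int, ...]) -> Conformation:
        return Conformation(self.chain, self.node_angles(node))

    def node_energy(self, node: Tuple[int, ...]) -> float:
        return self.table[node]

    def _energy(self, conf: Conformation) -> float:
        return self.table[self.decode(conf)]

    # -- serialisation (TSV with a JSON metadata comment line) ---------------

    def save(self, path) -> None:
        meta = {
            "sequence": self.chain.sequence,
            "base_angle": self.base_angle,
            "identity_slots": [
                {"slot": slot, "values": list(values)}
                for slot, values in self.identity_slots
            ],
        }
        with Path(path).open("w", newline="") as fh:
            fh.write("# toy_landscape " + json.dumps(meta) + "\n")
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["node", "energy"])
            for node in sorted(self.table):
                writer.writerow([",".join(map(str, node)), f"{self.table[node]:.10g}"])

    @classmethod
    def load(cls, path, budget: Optional[int] = None) -> "ToyLandscapeModel":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("# toy_landscape "):
            raise ValueError(f"{path}: not a toy landscape file")
        meta = json.loads(lines[0][len("# toy_landscape "):])
        identity_slots = [
            (int(spec["slot"]), tuple(float(v) for v in spec["values"]))
            for spec in meta["identity_slots"]
        ]
        table = {}
        for lineno, line in enumerate(lines[2:], start=3):
            if not line.strip():
                continue
            key, energy = line.split("\t")
            table[tuple(int(x) for x in key.split(","))] = float(energy)
        return cls(
            Chain(meta["sequence"]),
            identity_slots,
            table,
            base_angle=float(meta["base_angle"]),
            budget=budget,
        )


def enumerate_minima(
    model: ToyLandscapeModel, lib, max_nodes: int = 10**6
) -> set:
    """Exhaustively list every local minimum of the discrete move graph.

    A node is a local minimum iff no single trimer replacement available in
    the library reaches a strictly lower-energy node.  Refuses graphs larger
    than ``max_nodes``.
    """
    total = model.n_nodes()
    if total > max_nodes:
        raise ValueError(
            f"move graph too large to enumerate: ~{total} nodes > {max_nodes}"
        )
    minima = set()
    for node in model.nodes():
        e = model.table[node]
        conf = model.node_conformation(node)
        is_min = True
        for pos in lib.positions:
            for cfg in lib[pos]:
                succ = model.decode(set_trimer(conf, pos, cfg))
                if model.table[succ] < e:
                    is_min = False
                    break
            if not is_min:
                break
        if is_min:
            minima.add(node)
    return minima
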