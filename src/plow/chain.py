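"""Coarse-grained backbone chain model.

A conformation of an ``n``-residue chain is parameterised by its 2n backbone
dihedral angles, laid out ``[phi_1, psi_1, phi_2, psi_2, ..., phi_n, psi_n]``
in degrees.  Bond lengths and bond angles are held at fixed ideal values and
the peptide bond is kept trans (omega = 180 deg), so the torsions are the only
degrees of freedom.  Cartesian backbone coordinates (N, CA, C, O per residue)
are derived deterministically from the torsions by sequential internal-to-
Cartesian (NeRF-style) placement, with the first residue anchored in a
canonical frame.

Conventions used throughout the package:

* residues are 1-based in user-facing indices; a trimer window starting at
  residue ``p`` covers residues ``p .. p+2`` and the six angle slots
  ``2(p-1) .. 2(p-1)+5`` (0-based) of the dihedral vector;
* angles live in the half-open interval (-180, 180];
* the terminal torsions phi_1 and psi_n are geometrically inert for N..C'
  placement but are kept in the 2n vector (psi_n still orients the terminal
  carbonyl oxygen); ``measure_dihedrals`` reports both as 180.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Chain",
    "Conformation",
    "build_coordinates",
    "measure_dihedrals",
    "set_trimer",
    "extended_conformation",
    "wrap_angle",
    "IDEAL_GEOMETRY",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Ideal backbone geometry (Engh–Huber-style values); Angstroms and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

IDEAL_GEOMETRY = {
    "bond_n_ca": BOND_N_CA,
    "bond_ca_c": BOND_CA_C,
    "bond_c_n": BOND_C_N,
    "bond_c_o": BOND_C_O,
    "angle_n_ca_c": ANGLE_N_CA_C,
    "angle_ca_c_n": ANGLE_CA_C_N,
    "angle_c_n_ca": ANGLE_C_N_CA,
    "angle_ca_c_o": ANGLE_CA_C_O,
    "omega": OMEGA,
}

ATOM_NAMES = ("N", "CA", "C", "O")


class ChainError(ValueError):
    """Invalid chain or dihedral input."""


class GeometryError(ValueError):
    """Degenerate geometry (e.g. collinear atoms) encountered."""


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into the interval (-180, 180]."""
    r = math.fmod(a + 180.0, 360.0)
    if r <= 0.0:
        r += 360.0
    return r - 180.0


@dataclass(frozen=True)
class Chain:
    """An amino-acid chain, the static identity of a conformation.

    Parameters
    ----------
    sequence
        One-letter amino-acid string; at least three residues (a trimer must
        fit) and only the 20 canonical codes.
    """

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ChainError(
                f"chain needs >= 3 residues, got {len(self.sequence)}"
            )
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ChainError(f"non-canonical residue codes: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def n_trimer_positions(self) -> int:
        return self.n - 2


def _check_angles(chain: Chain, angles: np.ndarray) -> np.ndarray:
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (2 * chain.n,):
        raise ChainError(
            f"dihedral vector must have length {2 * chain.n}, "
            f"got shape {angles.shape}"
        )
    if not np.all(np.isfinite(angles)):
        raise ChainError("dihedral vector contains non-finite entries")
    return angles


def _place(a, b, c, bond: float, theta_deg: float, chi_deg: float):
    """NeRF placement: position atom d with |cd| = bond, angle(b,c,d) = theta
    and torsion(a,b,c,d) = chi.  Plain-float implementation: this sits in the
    innermost loop of every energy evaluation."""
    th = math.radians(theta_deg)
    ch = math.radians(chi_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nbc, bcy / nbc, bcz / nbc
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    # n = unit(ab x bc)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise GeometryError("collinear atoms in placement frame")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(th)
    s = bond * math.sin(th)
    d1 = s * math.cos(ch)
    d2 = -s * math.sin(ch)  # sign fixes the IUPAC torsion handedness
    return (
        c[0] + d0 * bcx + d1 * mx + d2 * nx,
        c[1] + d0 * bcy + d1 * my + d2 * ny,
        c[2] + d0 * bcz + d1 * mz + d2 * nz,
    )


def build_coordinates(chain: Chain, dihedrals: np.ndarray) -> np.ndarray:
    """Build backbone Cartesian coordinates from a dihedral vector.

    Returns an array of shape ``(n, 4, 3)`` holding N, CA, C, O positions per
    residue (Angstroms).  The first residue is anchored canonically: N at the
    origin, CA on +x, C in the xy-plane; phi_1 therefore rotates nothing.
    Deterministic: identical inputs give bitwise-identical output.
    """
    angles = _check_angles(chain, dihedrals)
    n = chain.n
    N = [(0.0, 0.0, 0.0)]
    CA = [(BOND_N_CA, 0.0, 0.0)]
    th = math.radians(ANGLE_N_CA_C)
    C = [(BOND_N_CA - BOND_CA_C * math.cos(th), BOND_CA_C * math.sin(th), 0.0)]
    for i in range(1, n):
        psi_prev = angles[2 * (i - 1) + 1]
        phi = angles[2 * i]
        n_i = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place(CA[i - 1], C[i - 1], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place(C[i - 1], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        N.append(n_i)
        CA.append(ca_i)
        C.append(c_i)
    coords = np.empty((n, 4, 3), dtype=float)
    for i in range(n):
        coords[i, 0] = N[i]
        coords[i, 1] = CA[i]
        coords[i, 2] = C[i]
        # carbonyl oxygen, anti to the next amide nitrogen: torsion
        # N-CA-C-O = psi_i + 180 (psi_n orients the C-terminal oxygen).
        psi = angles[2 * i + 1]
        coords[i, 3] = _place(
            N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
    return coords


def _torsion(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-9 or n2n < 1e-9 or b1n < 1e-12:
        raise GeometryError("collinear atom triplet in torsion computation")
    m1 = np.cross(n1, b1 / b1n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def measure_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Measure the 2n dihedral vector from backbone coordinates.

    Standard IUPAC torsions: phi_i = C'(i-1)-N(i)-CA(i)-C'(i) and
    psi_i = N(i)-CA(i)-C'(i)-N(i+1), in (-180, 180].  The undefined terminal
    torsions phi_1 and psi_n are reported as 180.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1] != 4 or coords.shape[2] != 3:
        raise ChainError(f"expected (n, 4, 3) coordinates, got {coords.shape}")
    n = coords.shape[0]
    if n < 3:
        raise ChainError("need >= 3 residues to measure dihedrals")
    if not np.all(np.isfinite(coords)):
        raise ChainError("coordinates contain non-finite entries")
    angles = np.full(2 * n, 180.0)
    for i in range(n):
        if i > 0:
            angles[2 * i] = _torsion(
                coords[i - 1, 2], coords[i, 0], coords[i, 1], coords[i, 2]
            )
        if i < n - 1:
            angles[2 * i + 1] = _torsion(
                coords[i, 0], coords[i, 1], coords[i, 2], coords[i + 1, 0]
            )
    return angles


@dataclass
class Conformation:
    """A chain plus its 2n dihedral angles, with lazily derived coordinates
    and a cached energy.

    ``coords`` is always consistent with ``angles`` (it is rebuilt on demand
    and never mutated in place); ``energy`` is whatever the last energy-model
    evaluation assigned, or ``None``.
    """

    chain: Chain
    angles: np.ndarray
    energy: Optional[float] = None
    _coords: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.angles = _check_angles(self.chain, self.angles)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = build_coordinates(self.chain, self.angles)
        return self._coords

    @property
    def n(self) -> int:
        return self.chain.n

    def copy(self) -> "Conformation":
        return Conformation(self.chain, self.angles.copy(), self.energy, self._coords)

    def trimer_angles(self, position: int) -> np.ndarray:
        """The six angles of the trimer window starting at residue
        ``position`` (1-based)."""
        _check_position(self.chain, position)
        lo = 2 * (position - 1)
        return self.angles[lo : lo + 6].copy()


def _check_position(chain: Chain, position: int) -> None:
    if not 1 <= position <= chain.n - 2:
        raise ChainError(
            f"trimer position {position} out of range [1, {chain.n - 2}]"
        )


def set_trimer(conf: Conformation, position: int, cfg) -> Conformation:
    """Return a new conformation with the six angles of the trimer window at
    ``position`` (1-based) replaced by ``cfg``'s angles.

    All other angle slots are untouched; cached coordinates and energy are
    invalidated on the result.
    """
    _check_position(conf.chain, position)
    new_angles = conf.angles.copy()
    lo = 2 * (position - 1)
    cfg_angles = np.asarray(getattr(cfg, "angles", cfg), dtype=float)
    if cfg_angles.shape != (6,):
        raise ChainError(f"trimer config must have 6 angles, got {cfg_angles.shape}")
    new_angles[lo : lo + 6] = cfg_angles
    return Conformation(conf.chain, new_angles)


def extended_conformation(chain: Chain) -> Conformation:
    """The fully extended conformation: all phi = psi = 180 degrees."""
    conf = Conformation(chain, np.full(2 * chain.n, 180.0))
    conf.coords  # build eagerly; the extended state is a common anchor
    return conf
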