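"""Optimal rigid-body superposition (Kabsch) and backbone lRMSD.

lRMSD between two conformations is the root-mean-square deviation over all
4n backbone atoms (N, CA, C, O) after the optimal proper-rotation
superposition.  Weights are uniform by default; a per-atom weight vector is
accepted as a hook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuperpositionResult", "kabsch", "lrmsd"]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping the mobile set onto the reference, plus the
    residual RMSD.  ``rotation`` is a proper rotation (det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    lrmsd: float


def _as_points(x) -> np.ndarray:
    p = np.asarray(getattr(x, "coords", x), dtype=float)
    return p.reshape(-1, 3)


def kabsch(mobile, reference, weights=None) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    Both inputs are (m, 3) point sets (or anything with a ``.coords``
    attribute reshapeable to one).  Reflections are corrected so the returned
    rotation is always proper.  ``mobile @ R.T + t`` best matches
    ``reference`` in the (weighted) least-squares sense.
    """
    P = _as_points(mobile)
    Q = _as_points(reference)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if weights is None:
        w = np.full(len(P), 1.0 / len(P))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(P),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, matching length")
        w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    resid = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum()))
    return SuperpositionResult(rotation=R, translation=t, lrmsd=rmsd)


def lrmsd(a, b, weights=None) -> float:
    """Least RMSD (Angstroms) between two same-length conformations over all
    backbone atoms, after optimal rigid superposition."""
    P = _as_points(a)
    Q = _as_points(b)
    if P.shape != Q.shape:
        raise ValueError(
            f"conformations differ in atom count: {P.shape[0]} vs {Q.shape[0]}"
        )
    return kabsch(P, Q, weights=weights).lrmsd
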