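"""Analysis instruments for sampled minima ensembles.

* lRMSD summaries of ensembles against a native reference (lowest lRMSD per
  run, aggregated min/mean across runs);
* the native-minimum probe: repeated fixed-length greedy descents started
  from the native structure, measuring how far the nearest reachable local
  minimum of the energy model lies from the native;
* perturbation statistics: how far the perturbation move jumps (lRMSD from
  each minimum to its perturbed copy), the fraction of jumps under 1 A
  (deemed an insignificant change), and the mean distance between
  consecutive accepted minima;
* Pearson correlation, used to relate mean perturbation distance to the
  lowest lRMSD reached per target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chain import Conformation
from .energy import BudgetExhaustedError, EnergyModel
from .fragments import FragmentLibrary, sample_config
from .search import MinimaEnsemble
from .superpose import lrmsd

__all__ = [
    "EnsembleSummary",
    "PerturbationStats",
    "native_minimum_probe",
    "ensemble_summary",
    "perturbation_stats",
    "pearson_correlation",
    "export_energy_vs_lrmsd",
]

INSIGNIFICANT_PERTURB_A = 1.0  # below this lRMSD a kick is deemed not to escape


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleSummary:
    """Lowest lRMSD to the native per run, aggregated across runs."""

    lowest_lrmsd_per_run: tuple
    min_lowest: float
    avg_lowest: float
    best_energy: float


@dataclass(frozen=True)
class PerturbationStats:
    """Perturbation-move statistics of one PLOW run."""

    mean_perturb_distance: float
    frac_below_1A: float
    mean_consecutive_minima_distance: float
    n_perturbations: int


class ProbeBudgetError(RuntimeError):
    """The native-minimum probe ran out of energy evaluations."""


def native_minimum_probe(
    native: Conformation,
    model: EnergyModel,
    lib: FragmentLibrary,
    n_restarts: int,
    iterations: int,
    rng: np.random.Generator,
) -> float:
    """Distance (lRMSD, Angstroms) from the native structure to the nearest
    local minimum found by repeated greedy descents started at the native.

    Each restart performs exactly ``iterations`` attempted modifications
    (accepted + rejected), a fixed-length descent rather than the k-failure
    rule; the minimum over restarts of lrmsd(native, found minimum) is
    returned.  The probe needs its own evaluation budget: exhaustion raises
    :class:`ProbeBudgetError`.
    """
    if n_restarts < 1 or iterations < 1:
        raise AnalysisError("n_restarts and iterations must be >= 1")
    n_positions = native.chain.n_trimer_positions
    best = np.inf
    try:
        for _ in range(n_restarts):
            current = native.copy()
            current.energy = None
            current_e = model.evaluate(current)
            for _ in range(iterations):
                pos = int(rng.integers(n_positions)) + 1
                cfg = sample_config(lib, pos, rng)
                from .chain import set_trimer

                candidate = set_trimer(current, pos, cfg)
                e = model.evaluate(candidate)
                if e < current_e:
                    current, current_e = candidate, e
            best = min(best, lrmsd(native, current))
    except BudgetExhaustedError as exc:
        raise ProbeBudgetError(
            "energy budget exhausted during the native-minimum probe"
        ) from exc
    return float(best)


def ensemble_summary(
    ensembles: Sequence[MinimaEnsemble], native: Conformation
) -> EnsembleSummary:
    """Per run, the lowest lRMSD to the native over all recorded minima;
    aggregated as the min and mean across runs."""
    ensembles = list(ensembles)
    if not ensembles:
        raise AnalysisError("need at least one ensemble")
    lowests = []
    best_energy = np.inf
    for ens in ensembles:
        if not ens.records:
            raise AnalysisError("empty ensemble")
        lowests.append(min(lrmsd(native, r.conformation) for r in ens.records))
        best_energy = min(best_energy, ens.best_energy)
    return EnsembleSummary(
        lowest_lrmsd_per_run=tuple(lowests),
        min_lowest=float(min(lowests)),
        avg_lowest=float(np.mean(lowests)),
        best_energy=float(best_energy),
    )


def perturbation_stats(ensemble: MinimaEnsemble) -> PerturbationStats:
    """Perturbation statistics for a PLOW ensemble.

    Mean lRMSD of every C_i -> C_i(perturb) jump, the fraction of jumps
    below 1 A, and the mean lRMSD between consecutive accepted minima
    (recomputed from the stored conformations of the accepted trajectory).
    """
    if ensemble.method_tag != "plow":
        raise AnalysisError(
            "perturbation statistics are only defined for PLOW ensembles "
            "(naive runs have no perturbation moves)"
        )
    dists = [
        r.perturb_distance for r in ensemble.records if r.perturb_distance is not None
    ]
    if not dists:
        raise AnalysisError("ensemble records no perturbation events")
    dists = np.array(dists)
    accepted = [r.conformation for r in ensemble.records if r.accepted]
    if len(accepted) >= 2:
        consec = float(
            np.mean([lrmsd(a, b) for a, b in zip(accepted[:-1], accepted[1:])])
        )
    else:
        consec = 0.0
    return PerturbationStats(
        mean_perturb_distance=float(dists.mean()),
        frac_below_1A=float(np.mean(dists < INSIGNIFICANT_PERTURB_A)),
        mean_consecutive_minima_distance=consec,
        n_perturbations=len(dists),
    )


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Standard Pearson r; raises on zero variance or length mismatch."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise AnalysisError("inputs must be 1-D and of equal length")
    if len(xs) < 3:
        raise AnalysisError("need at least 3 points")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise AnalysisError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(xs, ys).statistic)


def export_energy_vs_lrmsd(
    ensembles: Sequence[MinimaEnsemble], native: Conformation, path
) -> pd.DataFrame:
    """Write a scatter table (method_tag, run, step_index, energy, lrmsd) of
    every recorded minimum against the native; one row per record."""
    rows = []
    for run_idx, ens in enumerate(ensembles):
        for r in ens.records:
            rows.append(
                {
                    "method_tag": ens.method_tag,
                    "run": run_idx,
                    "step_index": r.step_index,
                    "energy": r.energy,
                    "lrmsd": lrmsd(native, r.conformation),
                }
            )
    df = pd.DataFrame(rows, columns=["method_tag", "run", "step_index", "energy", "lrmsd"])
    df.to_csv(path, sep="\t", index=False)
    return df
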