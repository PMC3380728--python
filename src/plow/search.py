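"""Iterated local search over the subspace of local minima (PLOW), and the
naive random-restart baseline.

The Protein Local Optima Walk alternates three ingredients:

* **greedy search** — repeated random single-trimer replacements, keeping a
  change only when it strictly lowers the energy; the descent stops when
  ``k`` consecutive modifications fail, the working definition of having
  reached a local minimum.  ``k`` defaults to the chain length.

* **perturbation** — one random trimer replacement applied to the current
  minimum, with no energy test: enough of a kick to leave the basin while
  preserving most local structure.

* **Metropolis acceptance** — a downhill minimum is always accepted as the
  new trajectory state; an uphill one with probability ``exp(-dE * beta)``.
  The default ``beta = ln(10)/10 kcal^-1 mol`` makes a 10 kcal/mol increase
  acceptable with probability 0.1.

The naive baseline instead restarts every descent from an independent random
fragment assembly, with no coupling between iterations.  Both samplers run
under a shared energy-evaluation budget (default 10,000,000 evaluations) and
record *every* sampled minimum, accepted or not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .chain import Chain, Conformation, extended_conformation, set_trimer
from .energy import BudgetExhaustedError, EnergyModel
from .fragments import FragmentLibrary, sample_config
from .superpose import lrmsd

__all__ = [
    "DEFAULT_BUDGET",
    "DEFAULT_BETA",
    "SearchConfig",
    "GreedyResult",
    "MinimumRecord",
    "MinimaEnsemble",
    "greedy_search",
    "perturb",
    "metropolis_accept",
    "plow_run",
    "naive_run",
]

DEFAULT_BUDGET = 10_000_000
# Calibrated so a 10 kcal/mol increase is accepted with probability 0.1.
DEFAULT_BETA = math.log(10.0) / 10.0


@dataclass(frozen=True)
class SearchConfig:
    """Run parameters.

    ``k`` is the greedy failure threshold (defaults to the chain length when
    left as None), ``budget`` the total number of energy evaluations,
    ``beta`` the Metropolis scaling in kcal^-1 mol.
    """

    k: Optional[int] = None
    budget: int = DEFAULT_BUDGET
    beta: float = DEFAULT_BETA
    seed: int = 0
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def resolve_k(self, chain: Chain) -> int:
        return self.k if self.k is not None else chain.n


@dataclass
class GreedyResult:
    """Outcome of one greedy descent."""

    conformation: Conformation
    energy: float
    n_attempts: int  # attempted modifications (accepted + rejected)
    truncated: bool  # True if the budget ran out mid-descent


@dataclass
class MinimumRecord:
    """One sampled local minimum with its trajectory bookkeeping."""

    conformation: Conformation
    energy: float
    step_index: int
    accepted: bool
    greedy_length: int
    perturb_distance: Optional[float] = None  # lRMSD C_i -> C_i(perturb)
    consecutive_distance: Optional[float] = None  # lRMSD C_i -> C_{i+1}
    truncated: bool = False


@dataclass
class MinimaEnsemble:
    """Ordered record of the minima sampled by one run."""

    records: List[MinimumRecord]
    config: SearchConfig
    evaluations_used: int
    method_tag: str  # "plow" | "naive"

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    @property
    def best_energy(self) -> float:
        return float(self.energies.min())

    def __len__(self) -> int:
        return len(self.records)


def metropolis_accept(
    e_new: float, e_old: float, beta: float, rng: np.random.Generator
) -> bool:
    """Metropolis criterion: always accept downhill; accept an uphill move of
    size dE with probability ``exp(-dE * beta)`` via one uniform draw."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    de = e_new - e_old
    if de <= 0:
        return True
    return rng.random() < math.exp(-de * beta)


def _ensure_energy(conf: Conformation, model: EnergyModel) -> float:
    if conf.energy is None:
        return model.evaluate(conf)
    return conf.energy


def greedy_search(
    start: Conformation,
    model: EnergyModel,
    lib: FragmentLibrary,
    k: int,
    rng: np.random.Generator,
) -> GreedyResult:
    """Map ``start`` to a nearby local minimum by greedy fragment replacement.

    Draws a uniformly random trimer position and configuration, applies the
    replacement and keeps it iff the energy strictly decreases (resetting the
    failure counter); a tie or increase counts as a failure.  Stops after
    ``k`` consecutive failures, or when the budget runs out (returning the
    best-so-far, flagged truncated).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_positions = start.chain.n_trimer_positions
    try:
        current_e = _ensure_energy(start, model)
    except BudgetExhaustedError:
        return GreedyResult(start, math.inf, 0, truncated=True)
    current = start
    failures = 0
    attempts = 0
    while failures < k:
        pos = int(rng.integers(n_positions)) + 1
        cfg = sample_config(lib, pos, rng)
        candidate = set_trimer(current, pos, cfg)
        try:
            e = model.evaluate(candidate)
        except BudgetExhaustedError:
            return GreedyResult(current, current_e, attempts, truncated=True)
        attempts += 1
        if e < current_e:
            current, current_e = candidate, e
            failures = 0
        else:
            failures += 1
    return GreedyResult(current, current_e, attempts, truncated=False)


def perturb(
    minimum: Conformation, lib: FragmentLibrary, rng: np.random.Generator
) -> Conformation:
    """Jump out of a local minimum: replace one uniformly chosen trimer with
    a uniformly sampled configuration, with no energy test."""
    pos = int(rng.integers(minimum.chain.n_trimer_positions)) + 1
    cfg = sample_config(lib, pos, rng)
    return set_trimer(minimum, pos, cfg)


def plow_run(
    chain: Chain,
    model: EnergyModel,
    lib: FragmentLibrary,
    config: SearchConfig,
) -> MinimaEnsemble:
    """One PLOW trajectory under the configured evaluation budget.

    Starts by mapping the fully extended conformation to a first minimum,
    then iterates perturbation -> greedy descent -> Metropolis decision until
    the budget is exhausted.  Every sampled minimum is recorded (with its
    perturbation distance and acceptance flag); the trajectory state advances
    only on acceptance.  Fully deterministic given the seed.
    """
    k = config.resolve_k(chain)
    rng = np.random.default_rng(config.seed)
    model.budget = config.budget
    start_count = model.evaluation_count
    records: List[MinimumRecord] = []

    first = greedy_search(extended_conformation(chain), model, lib, k, rng)
    records.append(
        MinimumRecord(
            conformation=first.conformation,
            energy=first.energy,
            step_index=0,
            accepted=True,
            greedy_length=first.n_attempts,
            truncated=first.truncated,
        )
    )
    current = first.conformation
    current_e = first.energy
    step = 1
    while not records[-1].truncated:
        kicked = perturb(current, lib, rng)
        perturb_distance = lrmsd(current, kicked)
        result = greedy_search(kicked, model, lib, k, rng)
        if result.truncated and result.n_attempts == 0 and result.energy == math.inf:
            break  # budget died before the perturbed state was even scored
        accepted = metropolis_accept(result.energy, current_e, config.beta, rng)
        records.append(
            MinimumRecord(
                conformation=result.conformation,
                energy=result.energy,
                step_index=step,
                accepted=accepted,
                greedy_length=result.n_attempts,
                perturb_distance=perturb_distance,
                consecutive_distance=lrmsd(current, result.conformation),
                truncated=result.truncated,
            )
        )
        if accepted:
            current, current_e = result.conformation, result.energy
        step += 1
    return MinimaEnsemble(
        records=records,
        config=config,
        evaluations_used=model.evaluation_count - start_count,
        method_tag="plow",
    )


def naive_run(
    chain: Chain,
    model: EnergyModel,
    lib: FragmentLibrary,
    config: SearchConfig,
) -> MinimaEnsemble:
    """Naive random-restart sampling of local minima at the same budget:
    repeat {random fragment assembly -> greedy descent -> record} until the
    budget is exhausted.  Iterations are independent beyond the RNG stream;
    there is no acceptance step."""
    from .fragments import random_assembly

    k = config.resolve_k(chain)
    rng = np.random.default_rng(config.seed)
    model.budget = config.budget
    start_count = model.evaluation_count
    records: List[MinimumRecord] = []
    step = 0
    while True:
        start = random_assembly(lib, rng)
        result = greedy_search(start, model, lib, k, rng)
        if result.truncated and result.n_attempts == 0 and result.energy == math.inf:
            break
        records.append(
            MinimumRecord(
                conformation=result.conformation,
                energy=result.energy,
                step_index=step,
                accepted=True,
                greedy_length=result.n_attempts,
                truncated=result.truncated,
            )
        )
        step += 1
        if result.truncated:
            break
    return MinimaEnsemble(
        records=records,
        config=config,
        evaluations_used=model.evaluation_count - start_count,
        method_tag="naive",
    )
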