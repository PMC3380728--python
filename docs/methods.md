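# Methods

This note documents the models and procedures implemented in `plow`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic fixtures do and do not emulate.

## Representation and geometry

A chain of *n* amino acids is parameterised by 2*n* backbone dihedrals
`[φ₁, ψ₁, …, φₙ, ψₙ]` in degrees, each in (−180, 180].  All bonded geometry
is ideal and fixed (Engh–Huber-style values): N–Cα 1.458 Å, Cα–C′ 1.525 Å,
C′–N 1.329 Å, C′=O 1.231 Å; angles N–Cα–C′ 111.2°, Cα–C′–N 116.2°,
C′–N–Cα 121.7°, Cα–C′=O 120.5°; ω fixed trans (180°).  Torsions are the
only degrees of freedom, so any built structure has exactly these bonded
distances and angles.

Coordinates (N, Cα, C′, O per residue) are derived by sequential
internal-to-Cartesian placement (NeRF-style), with residue 1 anchored in a
canonical frame (N at the origin, Cα on +x, C′ in the xy-plane).
Consequences of this convention:

* φ₁ rotates nothing and ψₙ orients only the C-terminal carbonyl oxygen;
  both slots are kept in the 2*n* vector (they participate in fragment
  replacement unchanged) and are *reported* as 180° by dihedral
  measurement, which follows IUPAC definitions.  A consequence is that the
  C-terminal oxygen orientation is not recovered when a structure is
  re-imported from a backbone PDB file.
* "Fully extended" is defined as all φ = ψ = 180°, the maximal-extension
  conformation under trans geometry.
* Residues and trimer positions are 1-based in user-facing interfaces
  (window *p* covers residues *p*..*p*+2); angle-vector slots are 0-based
  internally.

The internal→Cartesian and Cartesian→internal maps are mutually inverse on
interior torsions to well below 1e−6° (the test suite bounds the round-trip
error over random conformations).

## Fragment library

Trimer configurations (six torsions) are excised from source backbone
structures by dihedral measurement and indexed by the 3-mer sequence of
their source window.  For a target chain, each position *p* receives the
configurations whose source 3-mer exactly matches the target 3-mer at *p*;
positions with no match anywhere fall back to the pool of all excised
trimers, so every position is guaranteed non-empty.  Lists are truncated to
`per_position_cap` (default 200, in the tradition of capped per-position
fragment candidate lists; it bounds memory and sampling cost).  Sampling at
a position is uniform.  Random assembly applies one sampled configuration
at every position in a fixed left-to-right sweep (overlapping windows
overwrite), which makes the operation deterministic given the RNG stream.

The interchange format is a TSV (position, source id, source 3-mer, six
angles at six decimals); reloading is lossless to ~5e−7°.

## Energy models

`EnergyModel` is a contract: `evaluate` is a pure function of the dihedral
vector, increments a counter by exactly one per call, and raises a
budget-exhausted signal once the counter reaches the configured budget.
Search code treats that signal as normal termination, so budget accounting
is exact under any interleaving of descents and perturbations.

### AMW-style coarse-grained model

The bundled model is the sum of six non-local terms; every pairwise term
involves only residue pairs at sequence separation ≥ 3 (local interactions
are near-ideal by construction in fragment-assembled backbones and are not
modelled).  All constants live in one parameter block (`AMWParams`); the
model is pluggable so a different parameterisation can replace it without
touching search code.  Defaults, with distances in Å and energies in
kcal/mol:

| term | form | key defaults |
|---|---|---|
| Lennard-Jones | 4ε[(σ/r)¹² − (σ/r)⁶] over backbone-atom pairs, σᵢⱼ = rᵢ+rⱼ | ε 0.05, radii N 1.55 / Cα 1.70 / C′ 1.70 / O 1.50, cutoff 8 |
| H-bond | −ε·exp(−((d−d₀)/s)²) for N···O pairs, gated by C=O···N angle | ε 2.0, d₀ 2.9, s 0.3, cutoff 4.5, angle ≥ 100° |
| contact | −ε per Cα–Cα pair within cutoff | ε 0.5, cutoff 6.5 |
| water | −ε·exp(−((ρᵢ−ρ₀)/s)²) per residue (interface density regime) | ε 0.3, ρ₀ 2.6, s 1.5 |
| burial | −ε·hᵢ·sigmoid((ρᵢ−ρ₀)/s) per residue (buried regime, hᵢ = scaled Kyte–Doolittle hydrophobicity) | ε 1.0, ρ₀ 4.5, s 1.0 |
| Rg | w·max(0, Rg − Rg₀)², Rg over Cα | Rg₀ = 2.2·n^0.38 |

ρᵢ is the residue contact number (Cα neighbours within the contact cutoff
at separation ≥ 3).  The total is the exact sum of the six terms, and the
model is rigid-motion invariant to 1e−9.  These constants were chosen once
to give a physically sensible balance (repulsion dominates clashes,
compactness is rewarded, helical/compact states score below extended ones);
no claim is made that they reproduce any published parameterisation —
absolute energies from this model are not comparable to other
implementations.

### Toy landscapes

`ToyLandscapeModel` tabulates energies over a discrete fragment-replacement
move graph so that "local minimum" is *exactly decidable* — the
verification currency for the k-failure descent.  One identity torsion is
designated per block of three residues (φ of residues 2, 5, 8, …); every
trimer window covers at most one of them, and its library configurations
write one of two tag angles there (180° or −60°) and the base angle
everywhere else.  Reachable conformations therefore decode uniquely to bit
tuples, and single fragment replacements are single-coordinate moves on a
Hamming graph.  Decoding tolerates 0.5° so that conformations re-imported
from quantised PDB files still decode.

The planted energy is a *staircase*: coordinates are split into blocks, and
within a block the strict minima are the even-length 1-prefix patterns,
with odd prefix lengths raised by a barrier (1.5× the per-level energy
gain) and stray 1s beyond the prefix penalised (0.75× per bit).  The prefix
length ramps the energy down linearly, so planted minima are graded across
`basin_depth_range` with the deepest at the full prefix, and the number of
minima is exactly the product over blocks of their even-level counts
(blocks are sized by factorising `n_basins`).  Exhaustive enumeration over
the move graph confirms that the planted catalogue is exactly the set of
local minima.

This construction emulates the one structural feature of protein energy
surfaces that the walk-vs-restart comparison depends on: deep minima
require many coordinated degrees of freedom (so they are exponentially rare
targets for uniform random assembly) but lie a short move sequence away
from neighbouring minima (so a trajectory that keeps deeper minima under
Metropolis acceptance ratchets towards them).  Two earlier candidate
designs (a flat plateau with planted wells, and value-aligned minima on a
Hamming grid) were discarded during fixture design because any deep
minimum was a single move away from a large slice of state space, which
makes random restarts as good as the walk — a geometry real funnels do not
have.  What the toy landscapes do *not* emulate: continuous torsion space,
energetic ruggedness within a basin, chain-length scaling of the move set,
or any actual protein physics; passing toy-landscape tests validates the
search semantics, not predictive accuracy on real proteins.

## Search

* **Greedy descent**: uniformly random (position, configuration) proposals;
  a proposal is kept iff it *strictly* lowers the energy.  Ties count as
  failures — this reads "fails to lower" strictly and prevents unbounded
  plateau drift.  The descent stops at `k` consecutive failures (default:
  chain length) or at budget exhaustion (returning best-so-far, flagged
  truncated).
* **Perturbation** replaces one uniformly chosen trimer with a uniformly
  sampled configuration; re-drawing the identical configuration is allowed
  (the move then fails to escape, which the under-1-Å fraction statistic
  tolerates by design).
* **Metropolis acceptance** with β = ln(10)/10 kcal⁻¹·mol ≈ 0.230, the
  constant implied by calibrating a +10 kcal/mol step to acceptance 0.1.
* **PLOW run**: first minimum from the fully extended conformation, then
  perturb → descend → accept/reject until the budget is spent.  All minima
  (accepted and rejected) are recorded; the trajectory state advances only
  on acceptance.  One shared RNG stream per run, seeded from the run
  configuration, makes every run bit-reproducible.
* **Naive run**: independent `random assembly → descent` restarts at the
  same budget, no acceptance step.

The default budget is 10⁷ evaluations, matching the regime the framework is
designed for; tests and the acceptance script use 10³–5×10⁴ so that suites
complete in minutes — these sizes are stated with each test and were chosen
as the smallest at which the measured effects are stable.

## Analysis

* **lRMSD**: Kabsch superposition with reflection correction (proper
  rotations only), uniform weights over all 4*n* backbone atoms; a per-atom
  weight vector is accepted as a hook.  "Weighted" variants in the
  literature are not standardised; uniform is the field default.  The
  implementation is verified against a grid-plus-refinement brute-force
  minimiser to 1e−3 Å.
* **Native-minimum probe**: repeated greedy descents from a reference
  structure, each running a *fixed* number of attempted modifications
  (accepted + rejected — the count bounds work, not successes), reporting
  the minimum over restarts of the lRMSD from the reference to the found
  minimum.  The probe requires its own budget; exhaustion is an error, not
  a truncation.
* **Ensemble summary**: per run the lowest lRMSD to the reference over all
  recorded minima; aggregated as min and mean across runs.
* **Perturbation statistics**: mean lRMSD of every minimum→perturbed jump,
  the fraction below 1 Å (deemed an insignificant change), and the mean
  lRMSD between consecutive *accepted* minima, recomputed from the stored
  conformations rather than trusted from bookkeeping.
* **Pearson correlation** (scipy) relates per-target mean perturbation
  distance to the lowest lRMSD reached; zero-variance input is an error.

## Degenerate inputs and numerical choices

Chains must have ≥ 3 residues and canonical one-letter codes; dihedral
vectors must be finite and of length 2*n*; collinear atom triplets make
torsions undefined and raise a geometry error.  Angles are always wrapped
to (−180, 180] (−180 maps to +180).  Backbone PDB input requires all four
backbone atoms per residue — Cα-only traces are rejected rather than
guessed at.  Library TSV parsing reports the offending line number.
Budgets are "exactly m evaluations": the (m+1)-th call raises.

## Limitations

Side chains, cis-prolines, non-canonical residues and multi-chain systems
are out of scope.  The bundled energy model is a documented surrogate, not
a validated force field; results on real proteins depend on supplying a
real fragment library (from PDB files via `plow build-lib`) and, ideally, a
better energy model behind the same interface.  The synthetic landscapes
validate search semantics only.  Sampling statistics at the default 10⁷
budget take CPU-days for realistic chain lengths, as expected for this
class of method.
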