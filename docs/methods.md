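# Methods

This note records the model, the algorithmic choices, the defaults and their
rationale, what the synthetic data emulate, and the known limitations.

## Model and procedure

The electronic Hamiltonian is defined by a core energy, one-electron
integrals `h_ij` and two-electron integrals `g_ij,kl` (chemist's notation,
8-fold permutation symmetric, Hartree throughout), read from or written to
FCIDUMP text files (1-based indices on disk, 0-based in memory; both `&END`
and `/` header terminators accepted; `ORBSYM`/`ISYM` ignored since all
calculations are C1).

Determinants are bit masks per spin channel.  All fermionic phases derive
from one interleaved spin-orbital convention (`2p` = alpha of spatial
orbital p, `2p+1` = beta, creation operators ordered by ascending index);
Slater–Condon elements, S² ladder operators and sampled-excitation signs use
the same parity helper, and the test suite checks the whole matrix against
an independent brute-force second-quantized oracle.

A GAS model is an ordered list of disjoint orbital subspaces with local or
cumulative occupation bounds.  Compositions and supergroups are indexed
1-based in decreasing lexicographic order.  Local constraints are generally
*stronger* than any cumulative set on three or more subspaces;
`GASPartition.to_cumulative()` derives the tightest cumulative bounds, which
provably coincide with the local set for two subspaces and for the worked
three-electron example, but in general only over-approximate it (the
derived supergroup set is a superset).  DDCI spaces are encoded as the
supergroups `[2n_o − n_h, N_a + (n_h − m_p), m_p]`; following the prose
classification the hole/particle classes are `(n_h, m_p) ∈ {0,1,2}²`
without the pure `(2,2)` class at level 3, and levels nest.

SplitGAS designates the supergroups satisfying a second, tighter constraint
set as P; the effective Hamiltonian keeps PP/PQ/QP intact and zeroes QQ
off-diagonals.  Equivalently, the second-order Löwdin downfolding
`H̃(E) = H_PP + H_PQ (E − D_Q)^{-1} H_QP` is exact for this effective
matrix: every effective eigenvalue with nonzero P projection solves the
downfolded self-consistency.  The unfolded (effective) form is preferred:
it needs no trial energy and one run treats all states; the downfolded
solver exists for analysis and cross-checks.

## Stochastic solver

Walker dynamics with real signed weights: spawning via PCHB proposals,
deterministic death on real weights, keyed-merge annihilation, stochastic
rounding to unit magnitude below weight 1 (both for spawns and for occupied
determinants), iteration in canonical determinant order so seeded runs are
bit-reproducible.

PCHB weights: doubles `|g_AIBJ − g_AJBI|` (same spin) / `|g_AIBJ|`
(opposite spin) over unordered spin-orbital pairs; singles
`|h_AI| + Σ_R |g_AIRR − g_ARRI|`.  Weights below 1e-8 are truncated (the
FCIDUMP writer keeps 1e-12 — storage keeps more precision than sampling).
Per supergroup, entries whose subspace move is GAS-forbidden, or whose
OR-gate `iP' ∨ iP` is false, are zeroed; a supergroup with no outgoing
weight at all is flagged isolated (direct sampling raises; the dynamics
falls back to the death term alone, which is the exact propagation of a
diagonal Hamiltonian).  Sampling draws the single/double branch
proportionally to the summed table weights with a 0.05 floor when both are
nonzero, then a uniform occupied hole (pair), then the particle (pair) from
a Vose alias table over the nonzero support of the category, dense and
sparse storage giving bit-identical streams.  Invalid draws (occupied
particle) are explicit null moves, never resampled, so `p_gen` is exact and
the per-target proposal masses plus rejections sum to 1 to 1e-12.

Defaults, with units and why:

- `dtau` (1/Hartree): automatic `min(0.1, 1/(diagonal span + 1))`, reduced
  by 5% per bloom during equilibration; a fixed user value overrides.
- shift update `S ← S − ζ/(AΔτ) ln(N_w/N_w')` with ζ = 0.05, A = 5
  (standard population-control scheme); the shift is seeded with the
  instantaneous projected-energy estimate when the target population is
  first reached, which avoids a large overshoot.
- initiator threshold `n_add = 3` walkers: spawns onto unoccupied
  determinants from weaker parents are discarded (core parents exempt).
- semistochastic core: the `core_size` lowest-diagonal determinants (always
  containing the reference) propagated exactly with the OR-gate-masked core
  Hamiltonian; core→core stochastic spawns are suppressed and core entries
  are never purged.  With the core equal to the whole space the dynamics is
  deterministic power iteration.
- reference: lowest-diagonal allowed determinant (lowest-diagonal P
  determinant in SplitGAS mode), ties broken canonically; `E_ref` is its
  diagonal and the shift estimates `E − E_ref`.

Estimators: projected energy `⟨ref|H|Ψ⟩/⟨ref|Ψ⟩` (flagged NaN when the
reference empties) and the mean shift, both with blocking
(Flyvbjerg–Petersen pairwise averaging; plateau = first level whose
estimate is within one estimated-error of the next, last level as
fallback).  Efficiency is `η = 1/(Var(E_proj)·t)` with the plateau variance.
Wavefunction RMSE L2-normalizes both vectors and aligns the global sign by
maximal overlap (the comparisons use instantaneous coefficients).

## Spin adaptation

Spin-adapted bases are built by explicit S² diagonalization inside each
spatial-occupation block (no GUGA graph machinery): orthonormal eigenvectors
at `S(S+1)` within 1e-10, signs fixed positive on the largest-magnitude
entry.  Zeroing QQ off-diagonals *after* this transformation keeps the
perturbative correction spin-pure; doing it in the determinant basis does
not.  One subtlety: with a closed-shell single-determinant P in a CAS(2,2),
the SD effective Hamiltonian's ground vector is still exactly spin-pure
(the P determinant couples only to the singlet combination of the open
shells), and the basis dependence appears in the energy through the
denominators; genuine ⟨S²⟩ contamination of the SD solution needs several
open-shell perturbers per spatial occupation, which the CAS(4,4) fixture
provides (measured deviations of order 1e-5–1e-3).

## Synthetic data and what the tests show

Fixture generators: Hubbard chains (known closed forms; note that a
density-density interaction has *zero* double-excitation heat-bath weights,
so those dynamics move by hopping singles alone) and random Hermitian
integral sets with exact 8-fold symmetry, ascending one-electron diagonal
(so a single Hartree product dominates the ground state and spectra are
bounded), and tunable off-diagonal scale/sparsity.  These reproduce the
*structural* features the algorithms depend on — symmetry, sparsity,
supergroup structure, P-dominated ground states — but not real molecular
integral decay, near-degeneracy patterns, or sign-problem severity; passing
tests therefore validate correctness and calibration of the machinery, not
chemical accuracy on any specific molecule.

Problem sizes: stochastic validation runs use a Hubbard dimer, a random
CAS(4,4) (36 determinants) and a three-subspace CAS(6,6)-style SplitGAS
model (400 determinants, 16-determinant P space) at 5·10⁴ walkers with
1500–4000 steps; deterministic property checks use 100–200 random instances
of dimension ≤ 12–100.  These sizes give 3σ-resolvable energies in minutes
on one CPU.

## Numerical choices and degenerate inputs

- Downfolding denominators `|E − H_αα|` below a guard (default 1e-10,
  configurable) raise a singularity error naming the perturber; the
  downfolded matrix is inherently ill-conditioned near such collisions.
- The self-consistent ground root uses bracketed Brent on
  `λ_min(H̃(E)) − E`, which is monotone below the perturber diagonals;
  excited roots use damped fixed-point iteration following the eigenvector
  of maximal overlap (the root-matching rule for partially-P-projected
  degenerate roots is our choice; no prescription exists).
- A ground state living entirely (or almost entirely) in Q is invisible to
  the P-rooted self-consistency but found by the effective-Hamiltonian
  diagonalization — one more reason the unfolded form is the default.
- Eigenvector signs are fixed positive on the largest-magnitude entry;
  supergroup orderings are the single canonical decreasing-lexicographic
  order everywhere.

## Limitations

- Desk-scale only: spaces are enumerated (guard 2·10⁵) for audits and
  reference selection; the sampler and tables would scale further, but no
  distributed or compressed population storage is provided.
- No GUGA coupling coefficients: spin adaptation is exact S² projection,
  practical only for small spaces; stochastic runs use the determinant
  basis.
- No adaptive shift, no RDM sampling, no multi-state orthogonalized
  dynamics, no point-group symmetry, third- and higher-order Löwdin terms
  out of scope.
- The sparse PCHB storage is a simple keyed-rows fallback chosen for
  correctness (bit-identical streams), not a memory-optimal data structure.
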