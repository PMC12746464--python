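"""P/Q partitioning, the effective SplitGAS Hamiltonian and Lowdin downfolding.

The configuration space T is split into a principal space P (the supergroups
satisfying a second, tighter GAS constraint set) and the perturber space
Q = T \\ P.  Lowdin's partitioning maps the eigenproblem onto an
energy-dependent matrix of dimension dim(P),

    H~_ij(E) = H_ij + sum_{a in Q} H_ia H_aj / (E - H_aa),

the second-order truncation of the exact downfolding.  Solving this
self-consistency is equivalent to diagonalizing the full-dimension
*effective* Hamiltonian in which every off-diagonal element of the QQ block
is set to zero -- the object the stochastic dynamics explores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .basis import (
    CISpace,
    Determinant,
    build_dense_hamiltonian,
    determinant_occupations,
    excitation_rank,
    slater_condon_element,
)
from .gas import GASPartition, SupergroupTable, enumerate_supergroups, supergroup_of
from .integrals import IntegralSet

__all__ = [
    "SplitPartitioning",
    "EffectiveHamiltonian",
    "DownfoldedHamiltonian",
    "build_ip_vector",
    "or_gate",
    "build_effective_hamiltonian",
    "downfold",
    "solve_self_consistent_downfold",
    "solve_exact",
]

_DENSE_LIMIT = 1500
_DIM_GUARD = 200_000


@dataclass
class SplitPartitioning:
    """Disjoint P/Q supergroup sets over a total space T with its {iP} vector."""

    table_T: SupergroupTable
    p_supergroups: frozenset[int]  # i_sg indices (1-based, T numbering)
    p_constraints: GASPartition | None = None

    @property
    def ip_vector(self) -> list[bool]:
        """Truth value per T supergroup, ordered by i_sg."""
        return [i + 1 in self.p_supergroups for i in range(self.table_T.n_supergroups)]

    def is_p(self, i_sg: int) -> bool:
        return i_sg in self.p_supergroups

    def supergroup_of_det(self, det: Determinant) -> int | None:
        occ = determinant_occupations(det, self.table_T.partition)
        return supergroup_of(occ, self.table_T)


def build_ip_vector(
    table_T: SupergroupTable,
    p_constraints: GASPartition | None = None,
    p_supergroups: list[int] | None = None,
) -> SplitPartitioning:
    """Classify every T supergroup as P (true) or Q (false).

    P is normally defined by a second constraint set over the same subspaces;
    an explicit ``p_supergroups`` index list overrides it.  P supergroups not
    contained in T are an error; an empty P is too.
    """
    if p_supergroups is not None:
        bad = [i for i in p_supergroups if not 1 <= i <= table_T.n_supergroups]
        if bad:
            raise ValueError(f"P supergroup indices outside T: {bad}")
        p_set = frozenset(p_supergroups)
    else:
        if p_constraints is None:
            raise ValueError("give either p_constraints or p_supergroups")
        p_comps = [x for x in table_T.compositions if p_constraints.allows(x)]
        missing = [x for x in p_comps if x not in table_T.sg_index]
        if missing:
            raise ValueError(f"P supergroups not contained in T: {missing}")
        p_set = frozenset(table_T.sg_index[x] for x in p_comps)
    if not p_set:
        raise ValueError("P space is empty")
    return SplitPartitioning(table_T, p_set, p_constraints)


def or_gate(i_sg_target: int, i_sg_source: int, part: SplitPartitioning) -> bool:
    """Spawn permission iP' v iP: false exactly for Q <- Q events."""
    return part.is_p(i_sg_target) or part.is_p(i_sg_source)


@dataclass
class EffectiveHamiltonian:
    """Full-dimension Hamiltonian with the QQ block stripped to its diagonal.

    The space is ordered P-first; ``n_p`` counts the P determinants.  The PP,
    PQ and QP blocks equal the exact Hamiltonian; for distinct a, b in Q the
    entry (a, b) is zero.
    """

    space: CISpace
    matrix: sp.csr_matrix
    n_p: int
    is_p: np.ndarray  # bool per determinant in the ordered space

    @property
    def q_diagonal(self) -> np.ndarray:
        return self.matrix.diagonal()[self.n_p :]

    @classmethod
    def from_dense(cls, h: np.ndarray, is_p: np.ndarray, space: CISpace | None = None) -> "EffectiveHamiltonian":
        """Mask a dense symmetric matrix: zero QQ off-diagonals, reorder P-first."""
        is_p = np.asarray(is_p, dtype=bool)
        order = np.concatenate([np.flatnonzero(is_p), np.flatnonzero(~is_p)])
        h = np.asarray(h, dtype=float)[np.ix_(order, order)]
        n_p = int(is_p.sum())
        masked = h.copy()
        q = slice(n_p, None)
        qq = masked[q, q].copy()
        masked[q, q] = np.diag(np.diag(qq))
        if space is not None:
            dets = [space.determinants[i] for i in order]
            space = CISpace(dets, space.n_orb)
        else:
            space = CISpace([Determinant(1 << i, 0) for i in range(h.shape[0])], h.shape[0])
        return cls(space, sp.csr_matrix(masked), n_p, np.arange(h.shape[0]) < n_p)


def build_effective_hamiltonian(
    space: CISpace, ints: IntegralSet, part: SplitPartitioning
) -> EffectiveHamiltonian:
    """Assemble the sparse effective Hamiltonian over a T-constrained space.

    Off-diagonal entries are stored iff the Slater-Condon value is nonzero
    and the OR-gate permits the supergroup pair; all diagonals are stored.
    """
    sgs = []
    for det in space.determinants:
        i_sg = part.supergroup_of_det(det)
        if i_sg is None:
            raise ValueError(f"determinant {det} violates the T constraints")
        sgs.append(i_sg)

    order = sorted(range(len(space)), key=lambda i: (not part.is_p(sgs[i]), i))
    dets = [space.determinants[i] for i in order]
    sgs = [sgs[i] for i in order]
    ordered = CISpace(dets, space.n_orb)
    n = len(dets)
    n_p = sum(part.is_p(s) for s in sgs)

    rows, cols, vals = [], [], []
    for i in range(n):
        rows.append(i)
        cols.append(i)
        vals.append(slater_condon_element(dets[i], dets[i], ints))
        for j in range(i + 1, n):
            if excitation_rank(dets[i], dets[j]) > 2:
                continue
            if not or_gate(sgs[i], sgs[j], part):
                continue
            v = slater_condon_element(dets[i], dets[j], ints)
            if v != 0.0:
                rows.extend((i, j))
                cols.extend((j, i))
                vals.extend((v, v))
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return EffectiveHamiltonian(ordered, mat, n_p, np.arange(n) < n_p)


@dataclass
class DownfoldedHamiltonian:
    """dim(P) x dim(P) energy-dependent matrix H~(E)."""

    trial_energy: float
    matrix: np.ndarray


def downfold(
    eff: EffectiveHamiltonian, trial_energy: float, denom_tol: float = 1e-10
) -> DownfoldedHamiltonian:
    """Second-order Lowdin downfolding at a trial energy E.

    Only the QQ diagonal enters; a denominator |E - H_aa| below ``denom_tol``
    is a singularity error naming the offending perturber.
    """
    h = eff.matrix.toarray() if sp.issparse(eff.matrix) else np.asarray(eff.matrix)
    n_p = eff.n_p
    h_pp = h[:n_p, :n_p]
    h_pq = h[:n_p, n_p:]
    q_diag = np.diag(h[n_p:, n_p:])
    denom = trial_energy - q_diag
    if denom.size:
        worst = int(np.argmin(np.abs(denom)))
        if abs(denom[worst]) < denom_tol:
            raise ZeroDivisionError(
                f"trial energy {trial_energy} collides with perturber diagonal "
                f"H_aa={q_diag[worst]} (Q index {worst})"
            )
    tilde = h_pp + (h_pq / denom) @ h_pq.T
    return DownfoldedHamiltonian(trial_energy, tilde)


def solve_self_consistent_downfold(
    eff: EffectiveHamiltonian,
    root: int = 0,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[float, np.ndarray]:
    """Self-consistent energy E* with E* an eigenvalue of H~(E*).

    Starts from the P-only eigenvalue of the requested root.  For the ground
    root the map ``E -> lambda_min(H~(E))`` is monotonically decreasing below
    the perturber diagonals (its derivative is a negative sum of squared
    couplings), so ``f(E) = lambda_min(H~(E)) - E`` has a unique bracketable
    zero at or below the P-only energy; that zero is found by Brent's method.
    Excited roots fall back to damped fixed-point iteration following the
    eigenvector of maximal overlap with the previous iterate (avoids root
    flipping).  Returns the converged energy and the P-space eigenvector.
    """
    n_p = eff.n_p
    h = eff.matrix.toarray() if sp.issparse(eff.matrix) else np.asarray(eff.matrix)
    vals0, vecs0 = np.linalg.eigh(h[:n_p, :n_p])
    if len(h) == n_p:  # Q empty: one iteration, P eigenpair
        return float(vals0[root]), vecs0[:, root]
    energy = float(vals0[root])
    q_min = float(np.min(np.diag(h[n_p:, n_p:])))

    if root == 0 and energy < q_min:
        from scipy.optimize import brentq

        def f(e: float) -> float:
            return float(np.linalg.eigvalsh(downfold(eff, e).matrix)[0]) - e

        hi = energy
        if f(hi) > 0.0:  # uncoupled Q: P eigenpair already self-consistent
            return energy, vecs0[:, 0]
        span = max(1.0, abs(energy))
        lo = hi - span
        for _ in range(max_iter):
            if f(lo) > 0.0:
                break
            span *= 2.0
            lo = hi - span
        else:
            raise RuntimeError("could not bracket the downfolded ground root")
        e_star = float(brentq(f, lo, hi, xtol=tol, maxiter=max_iter))
        vals, vecs = np.linalg.eigh(downfold(eff, e_star).matrix)
        return float(vals[0]), vecs[:, 0]

    vec = vecs0[:, root]
    damping = 0.0
    trace = [energy]
    for _ in range(max_iter):
        tilde = downfold(eff, energy).matrix
        vals, vecs = np.linalg.eigh(tilde)
        k = int(np.argmax(np.abs(vecs.T @ vec)))
        new_energy = float(vals[k])
        vec = vecs[:, k]
        step = new_energy - energy
        if abs(step) < tol:
            return new_energy, vec
        if len(trace) >= 2 and (new_energy - energy) * (energy - trace[-2]) < 0:
            damping = 0.5  # oscillation detected
        energy = energy + (1.0 - damping) * step
        trace.append(energy)
    raise RuntimeError(f"downfolding not converged in {max_iter} iterations; trace={trace}")


def solve_exact(matrix, n_roots: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Lowest eigenpairs of a (sparse or dense) symmetric matrix.

    Dense solve below 1500 rows, sparse Lanczos up to the 2e5-row guard.
    Eigenvectors are normalized with the largest-magnitude entry positive.
    """
    n = matrix.shape[0]
    if n > _DIM_GUARD:
        raise ValueError(f"dimension {n} exceeds the solver guard {_DIM_GUARD}")
    if n <= _DENSE_LIMIT or not sp.issparse(matrix):
        dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
        vals, vecs = np.linalg.eigh(dense)
        vals, vecs = vals[:n_roots], vecs[:, :n_roots]
    else:
        k = min(n_roots, n - 2)
        vals, vecs = spla.eigsh(matrix, k=k, which="SA")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    vecs = vecs.copy()
    for j in range(vecs.shape[1]):
        lead = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[lead, j] < 0:
            vecs[:, j] *= -1.0
    return vals, vecs


# ---------------------------------------------------------------------------
# deterministic SplitGAS drivers (SD and spin-adapted bases)


@dataclass
class SplitGASResult:
    """Deterministic SplitGAS solution in one many-electron basis."""

    energy: float
    coefficients: np.ndarray  # in the determinant basis of `space`
    space: CISpace
    basis: str  # 'sd' or 'csf'
    s_squared: float


def solve_splitgas_deterministic(
    ints: IntegralSet,
    gas_T: GASPartition,
    p_constraints: GASPartition,
    basis: str = "sd",
    s_target: float | None = None,
    n_alpha: int | None = None,
    n_beta: int | None = None,
) -> SplitGASResult:
    """Diagonalize the effective SplitGAS Hamiltonian in an SD or CSF basis.

    In the CSF basis the QQ off-diagonals are zeroed *after* spin adaptation
    (S^2 projection of each spatial-occupation block), so the perturbative
    correction cannot mix spin sectors; in the SD basis it can, which is the
    source of spin contamination of the downfolded solution.
    """
    from .basis import enumerate_space, s_squared_expectation, spin_adapted_basis, spin_adapted_transform

    table = enumerate_supergroups(gas_T)
    part = build_ip_vector(table, p_constraints)
    space = enumerate_space(ints, n_alpha, n_beta, gas_T, table)

    if basis == "sd":
        eff = build_effective_hamiltonian(space, ints, part)
        vals, vecs = solve_exact(eff.matrix, n_roots=1)
        coeffs = vecs[:, 0]
        return SplitGASResult(
            float(vals[0]), coeffs, eff.space, "sd", s_squared_expectation(coeffs, eff.space)
        )
    if basis != "csf":
        raise ValueError("basis must be 'sd' or 'csf'")
    if s_target is None:
        d0 = space.determinants[0]
        s_target = 0.5 * abs(d0.n_alpha - d0.n_beta)
    blocks = spin_adapted_basis(space, s_target)
    if not blocks:
        raise ValueError(f"no spin-adapted functions with S={s_target}")
    trans = spin_adapted_transform(space, blocks)
    h_sd = build_dense_hamiltonian(space, ints)
    h_csf = trans.T @ h_sd @ trans
    csf_is_p = []
    for b in blocks:
        det = space.determinants[b.det_indices[0]]
        i_sg = part.supergroup_of_det(det)
        csf_is_p.extend([part.is_p(i_sg)] * b.transform.shape[1])
    is_p = np.asarray(csf_is_p, dtype=bool)
    order = np.concatenate([np.flatnonzero(is_p), np.flatnonzero(~is_p)])
    eff_csf = EffectiveHamiltonian.from_dense(h_csf, is_p)
    vals, vecs = solve_exact(eff_csf.matrix, n_roots=1)
    coeffs_csf = np.zeros(trans.shape[1])
    coeffs_csf[order] = vecs[:, 0]
    coeffs_sd = trans @ coeffs_csf
    return SplitGASResult(
        float(vals[0]), coeffs_sd, space, "csf", s_squared_expectation(coeffs_sd, space)
    )
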