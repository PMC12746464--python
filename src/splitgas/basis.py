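"""Slater determinants, Slater-Condon matrix elements, CI spaces and spin.

Determinants are encoded as one integer bit mask per spin channel.  For
fermionic phases a single *interleaved* spin-orbital convention is used
throughout: spin orbital ``2p`` is the alpha component of spatial orbital
``p`` and ``2p + 1`` its beta component, with creation operators ordered by
ascending spin-orbital index.  Every sign in the package (Slater-Condon
elements, S^2 ladder operators, sampled excitations) derives from parity
counts in this one convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np

from .gas import GASPartition, SupergroupTable, enumerate_supergroups
from .integrals import IntegralSet

__all__ = [
    "Determinant",
    "CISpace",
    "SpinAdaptedBlock",
    "enumerate_space",
    "slater_condon_element",
    "spin_adapted_basis",
    "s_squared_expectation",
    "build_dense_hamiltonian",
]


class Determinant(NamedTuple):
    """Occupation of spin orbitals, one bit mask per spin channel."""

    alpha: int
    beta: int

    @classmethod
    def from_occ(cls, alpha_occ, beta_occ) -> "Determinant":
        a = b = 0
        for p in alpha_occ:
            a |= 1 << int(p)
        for p in beta_occ:
            b |= 1 << int(p)
        return cls(a, b)

    @property
    def alpha_occ(self) -> tuple[int, ...]:
        return _bits(self.alpha)

    @property
    def beta_occ(self) -> tuple[int, ...]:
        return _bits(self.beta)

    @property
    def n_alpha(self) -> int:
        return self.alpha.bit_count()

    @property
    def n_beta(self) -> int:
        return self.beta.bit_count()

    def interleaved(self) -> int:
        """Single mask over spin orbitals ``2p`` (alpha) / ``2p+1`` (beta)."""
        return _interleave(self.alpha) | (_interleave(self.beta) << 1)

    def spin_orbitals(self) -> tuple[int, ...]:
        return _bits(self.interleaved())

    def label(self, n_orb: int) -> str:
        """Occupation string, one character per spatial orbital: 2/a/b/0."""
        chars = []
        for p in range(n_orb):
            occ_a = bool(self.alpha >> p & 1)
            occ_b = bool(self.beta >> p & 1)
            chars.append("2" if occ_a and occ_b else "a" if occ_a else "b" if occ_b else "0")
        return "".join(chars)


def _bits(mask: int) -> tuple[int, ...]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return tuple(out)


def _interleave(mask: int) -> int:
    """Spread the bits of ``mask`` to even positions (p -> 2p)."""
    out = 0
    while mask:
        low = mask & -mask
        p = low.bit_length() - 1
        out |= 1 << (2 * p)
        mask ^= low
    return out


def from_interleaved(full: int) -> Determinant:
    a = b = 0
    while full:
        low = full & -full
        s = low.bit_length() - 1
        if s % 2 == 0:
            a |= 1 << (s // 2)
        else:
            b |= 1 << (s // 2)
        full ^= low
    return Determinant(a, b)


def excitation_rank(d_i: Determinant, d_j: Determinant) -> int:
    return ((d_i.alpha ^ d_j.alpha).bit_count() + (d_i.beta ^ d_j.beta).bit_count()) // 2


def annihilate(full: int, s: int) -> tuple[int, int] | None:
    """Apply ``a_s`` to an interleaved mask; returns (new mask, sign) or None."""
    if not full >> s & 1:
        return None
    sign = -1 if (full & ((1 << s) - 1)).bit_count() & 1 else 1
    return full ^ (1 << s), sign


def create(full: int, s: int) -> tuple[int, int] | None:
    """Apply ``a^dagger_s`` to an interleaved mask."""
    if full >> s & 1:
        return None
    sign = -1 if (full & ((1 << s) - 1)).bit_count() & 1 else 1
    return full | (1 << s), sign


def excitation_sign(full: int, holes: tuple[int, ...], particles: tuple[int, ...]) -> int:
    """Phase of ``a^dag_{p1} a^dag_{p2} a_{h2} a_{h1}`` applied to ``full``.

    Holes and particles are interleaved spin-orbital indices in ascending
    order; the caller guarantees the operator string does not vanish.
    """
    sign = 1
    for h in holes:
        full, s = annihilate(full, h)  # type: ignore[misc]
        sign *= s
    for p in reversed(particles):
        full, s = create(full, p)  # type: ignore[misc]
        sign *= s
    return sign


def _spatial_spin(s: int) -> tuple[int, int]:
    return s >> 1, s & 1


def diagonal_element(det: Determinant, ints: IntegralSet) -> float:
    """<D|H|D> including the core energy."""
    h, g = ints.h, ints.g
    occ = det.spin_orbitals()
    e = ints.e_core
    for s in occ:
        e += h[s >> 1, s >> 1]
    for a, b in combinations(occ, 2):
        pa, sa = _spatial_spin(a)
        pb, sb = _spatial_spin(b)
        e += g[pa, pa, pb, pb]
        if sa == sb:
            e -= g[pa, pb, pb, pa]
    return e


def slater_condon_element(d_i: Determinant, d_j: Determinant, ints: IntegralSet) -> float:
    """<D_j|H|D_i> by the Slater-Condon rules, with the fermionic phase.

    Zero for excitation rank above two; the diagonal includes ``e_core``.
    """
    if d_i == d_j:
        return diagonal_element(d_i, ints)
    fi, fj = d_i.interleaved(), d_j.interleaved()
    diff = fi ^ fj
    rank = diff.bit_count() // 2
    if rank > 2:
        return 0.0
    holes = _bits(diff & fi)
    particles = _bits(diff & fj)
    h, g = ints.h, ints.g
    if rank == 1:
        (hole,), (part,) = holes, particles
        ph, sh = _spatial_spin(hole)
        pp, sp = _spatial_spin(part)
        if sh != sp:
            return 0.0
        value = h[pp, ph]
        for s in _bits(fi & ~diff):
            pr, sr = _spatial_spin(s)
            value += g[pp, ph, pr, pr]
            if sr == sh:
                value -= g[pp, pr, pr, ph]
        return excitation_sign(fi, holes, particles) * value

    (h1, h2), (p1, p2) = holes, particles
    q1, s1 = _spatial_spin(h1)
    q2, s2 = _spatial_spin(h2)
    r1, t1 = _spatial_spin(p1)
    r2, t2 = _spatial_spin(p2)
    value = 0.0
    if t1 == s1 and t2 == s2:
        value += g[r1, q1, r2, q2]
    if t1 == s2 and t2 == s1:
        value -= g[r1, q2, r2, q1]
    if value == 0.0:
        return 0.0
    return excitation_sign(fi, holes, particles) * value


@dataclass
class CISpace:
    """Deterministically ordered list of determinants with O(1) lookup."""

    determinants: list[Determinant]
    n_orb: int
    lookup: dict[Determinant, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lookup:
            self.lookup = {d: i for i, d in enumerate(self.determinants)}

    def __len__(self) -> int:
        return len(self.determinants)

    def index(self, det: Determinant) -> int:
        return self.lookup[det]

    def __contains__(self, det: Determinant) -> bool:
        return det in self.lookup


def determinant_occupations(det: Determinant, gas: GASPartition) -> tuple[int, ...]:
    """Electron count of ``det`` in each GAS subspace."""
    occ = []
    for sub in gas.subspaces:
        mask = 0
        for o in sub:
            mask |= 1 << o
        occ.append((det.alpha & mask).bit_count() + (det.beta & mask).bit_count())
    return tuple(occ)


def enumerate_space(
    ints: IntegralSet,
    n_alpha: int | None = None,
    n_beta: int | None = None,
    gas: GASPartition | None = None,
    table: SupergroupTable | None = None,
) -> CISpace:
    """All determinants with the given electron counts and GAS constraints.

    Default counts follow ``ints.n_elec``/``ints.ms2``.  With a GAS model only
    determinants whose subspace occupation vector is an allowed supergroup are
    kept; ordering is lexicographic on the (alpha, beta) mask encoding.
    """
    if n_alpha is None or n_beta is None:
        n_alpha = (ints.n_elec + ints.ms2) // 2
        n_beta = ints.n_elec - n_alpha
    if min(n_alpha, n_beta) < 0 or max(n_alpha, n_beta) > ints.n_orb:
        raise ValueError("infeasible electron counts")

    sg_lookup = None
    if gas is not None:
        if table is None:
            table = enumerate_supergroups(gas)
        sg_lookup = table.sg_index

    dets = []
    orbitals = range(ints.n_orb)
    for aocc in combinations(orbitals, n_alpha):
        for bocc in combinations(orbitals, n_beta):
            det = Determinant.from_occ(aocc, bocc)
            if sg_lookup is not None:
                if determinant_occupations(det, gas) not in sg_lookup:
                    continue
            dets.append(det)
    if not dets:
        raise ValueError("constraints admit no determinant")
    dets.sort(key=lambda d: (d.alpha, d.beta))
    return CISpace(dets, ints.n_orb)


def build_dense_hamiltonian(space: CISpace, ints: IntegralSet) -> np.ndarray:
    """Dense Hamiltonian over an enumerated space (small spaces only)."""
    n = len(space)
    mat = np.zeros((n, n))
    dets = space.determinants
    for i in range(n):
        mat[i, i] = diagonal_element(dets[i], ints)
        for j in range(i + 1, n):
            if excitation_rank(dets[i], dets[j]) > 2:
                continue
            val = slater_condon_element(dets[i], dets[j], ints)
            mat[i, j] = mat[j, i] = val
    return mat


# ---------------------------------------------------------------------------
# spin


def apply_s_plus(det: Determinant) -> list[tuple[Determinant, int]]:
    """``S_+ |D>`` as a signed determinant sum (beta -> alpha flips)."""
    out = []
    full = det.interleaved()
    for p in _bits(det.beta & ~det.alpha):
        new, s1 = annihilate(full, 2 * p + 1)  # type: ignore[misc]
        new, s2 = create(new, 2 * p)  # type: ignore[misc]
        out.append((from_interleaved(new), s1 * s2))
    return out


def apply_s_minus(det: Determinant) -> list[tuple[Determinant, int]]:
    out = []
    full = det.interleaved()
    for p in _bits(det.alpha & ~det.beta):
        new, s1 = annihilate(full, 2 * p)  # type: ignore[misc]
        new, s2 = create(new, 2 * p + 1)  # type: ignore[misc]
        out.append((from_interleaved(new), s1 * s2))
    return out


def s_squared_expectation(coeffs: np.ndarray, space: CISpace) -> float:
    """``<Psi|S^2|Psi>`` with ``S^2 = S_- S_+ + S_z (S_z + 1)``.

    The vector is normalized defensively; a zero vector is an error.
    """
    c = np.asarray(coeffs, dtype=float)
    norm = np.linalg.norm(c)
    if norm == 0.0:
        raise ValueError("zero coefficient vector")
    c = c / norm
    d0 = space.determinants[0]
    ms = 0.5 * (d0.n_alpha - d0.n_beta)
    # <Psi|S_- S_+|Psi> = |S_+ Psi|^2
    raised: dict[Determinant, float] = {}
    for ci, det in zip(c, space.determinants):
        if ci == 0.0:
            continue
        for new, sign in apply_s_plus(det):
            raised[new] = raised.get(new, 0.0) + sign * ci
    return float(sum(v * v for v in raised.values()) + ms * (ms + 1.0))


@dataclass
class SpinAdaptedBlock:
    """Orthonormal S^2 eigenvectors over one spatial-occupation sub-basis."""

    spatial_occupation: tuple[int, ...]  # per spatial orbital: 0, 1 or 2
    det_indices: list[int]  # positions of the sub-basis determinants in the space
    transform: np.ndarray  # (len(det_indices), n_csf)
    s_value: float


def _spatial_occ(det: Determinant, n_orb: int) -> tuple[int, ...]:
    return tuple((det.alpha >> p & 1) + (det.beta >> p & 1) for p in range(n_orb))


def spin_adapted_basis(
    space: CISpace, s_target: float, tol: float = 1e-8
) -> list[SpinAdaptedBlock]:
    """Per spatial occupation, the S^2 eigenvectors with eigenvalue S(S+1).

    Realized by explicit diagonalization of S^2 within each spatial-occupation
    block.  Blocks with no eigenvector at the target spin are omitted.
    Degenerate eigenvectors are canonicalized by the eigensolver ordering with
    the sign fixed positive on the largest-magnitude entry.
    """
    blocks: dict[tuple[int, ...], list[int]] = {}
    for i, det in enumerate(space.determinants):
        blocks.setdefault(_spatial_occ(det, space.n_orb), []).append(i)

    target = s_target * (s_target + 1.0)
    out = []
    for occ in sorted(blocks):
        idx = blocks[occ]
        sub = [space.determinants[i] for i in idx]
        pos = {d: r for r, d in enumerate(sub)}
        m = len(sub)
        s2 = np.zeros((m, m))
        d0 = sub[0]
        ms = 0.5 * (d0.n_alpha - d0.n_beta)
        for r, det in enumerate(sub):
            # S_- S_+ within the block: raising then lowering stays in it
            for mid, sgn1 in apply_s_plus(det):
                for fin, sgn2 in apply_s_minus(mid):
                    s2[pos[fin], r] += sgn1 * sgn2
            s2[r, r] += ms * (ms + 1.0)
        vals, vecs = np.linalg.eigh(s2)
        cols = [k for k, v in enumerate(vals) if abs(v - target) < tol]
        if not cols:
            continue
        transform = vecs[:, cols].copy()
        for k in range(transform.shape[1]):
            lead = np.argmax(np.abs(transform[:, k]))
            if transform[lead, k] < 0:
                transform[:, k] *= -1.0
        out.append(SpinAdaptedBlock(occ, list(idx), transform, s_target))
    return out


def spin_adapted_transform(space: CISpace, blocks: list[SpinAdaptedBlock]) -> np.ndarray:
    """Assemble the (n_det, n_csf) matrix mapping CSF to determinant basis."""
    n_csf = sum(b.transform.shape[1] for b in blocks)
    mat = np.zeros((len(space), n_csf))
    col = 0
    for b in blocks:
        k = b.transform.shape[1]
        mat[np.asarray(b.det_indices), col : col + k] = b.transform
        col += k
    return mat
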