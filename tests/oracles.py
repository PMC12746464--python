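"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's Slater-Condon fast path: the
Hamiltonian is assembled by symbolically applying second-quantized creation
and annihilation operators to bit-encoded determinants, so any sign or
index-convention error in the implementation shows up as a mismatch.
"""

from __future__ import annotations

import numpy as np

from splitgas.basis import CISpace, annihilate, create, from_interleaved
from splitgas.integrals import IntegralSet


def brute_hamiltonian(space: CISpace, ints: IntegralSet) -> np.ndarray:
    """H = e_core + sum h_pq a+_ps a_qs + 1/2 sum g_pq,rs a+_ps a+_rt a_st a_qs."""
    dets = space.determinants
    n = len(dets)
    lookup = {d: i for i, d in enumerate(dets)}
    mat = np.zeros((n, n))
    no = ints.n_orb
    for j, d in enumerate(dets):
        f0 = d.interleaved()
        for p in range(no):
            for q in range(no):
                if ints.h[p, q] == 0.0:
                    continue
                for spin in (0, 1):
                    r = annihilate(f0, 2 * q + spin)
                    if r is None:
                        continue
                    f1, s1 = r
                    r = create(f1, 2 * p + spin)
                    if r is None:
                        continue
                    f2, s2 = r
                    dd = from_interleaved(f2)
                    if dd in lookup:
                        mat[lookup[dd], j] += ints.h[p, q] * s1 * s2
        for p in range(no):
            for q in range(no):
                for r_ in range(no):
                    for s_ in range(no):
                        gval = ints.g[p, q, r_, s_]
                        if gval == 0.0:
                            continue
                        for sp1 in (0, 1):
                            for sp2 in (0, 1):
                                x = annihilate(f0, 2 * q + sp1)
                                if x is None:
                                    continue
                                f1, g1 = x
                                x = annihilate(f1, 2 * s_ + sp2)
                                if x is None:
                                    continue
                                f2, g2 = x
                                x = create(f2, 2 * r_ + sp2)
                                if x is None:
                                    continue
                                f3, g3 = x
                                x = create(f3, 2 * p + sp1)
                                if x is None:
                                    continue
                                f4, g4 = x
                                dd = from_interleaved(f4)
                                if dd in lookup:
                                    mat[lookup[dd], j] += 0.5 * gval * g1 * g2 * g3 * g4
        mat[j, j] += ints.e_core
    return mat


def hubbard_dimer_energy(t: float, u: float) -> float:
    """Closed-form singlet ground energy (u - sqrt(u^2 + 16 t^2)) / 2."""
    return 0.5 * (u - np.sqrt(u * u + 16.0 * t * t))


def masked_effective_dense(h: np.ndarray, is_p: np.ndarray) -> np.ndarray:
    """Reference construction: zero QQ off-diagonals of a dense matrix."""
    is_p = np.asarray(is_p, dtype=bool)
    out = h.copy()
    q = np.flatnonzero(~is_p)
    for a in q:
        for b in q:
            if a != b:
                out[a, b] = 0.0
    return out
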