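"""Precomputed heat-bath (PCHB) excitation generation with GAS/SplitGAS masks.

Double excitations ``AB <- IJ`` between Slater determinants have a matrix
element magnitude ``|g_AIBJ - g_AJBI|`` that depends only on the four spin
orbitals, not on the determinants; singles get the robust surrogate
``S_I^A = |h_AI| + sum_R |g_AIRR - g_ARRI|``.  These determinant-independent
weights are precomputed once per *supergroup*, with entries representing
GAS-forbidden moves -- and, in SplitGAS mode, moves failing the OR-gate
(both endpoints in the perturber space Q) -- set to zero.  Sampling is O(1)
per draw through alias tables; because the weights are only approximately
the true (determinant-dependent) probabilities, a drawn particle orbital may
already be occupied, in which case the move is returned as an explicit
rejection rather than resampled, keeping the generation probability exact.

Spin orbitals use the interleaved convention of :mod:`splitgas.basis`:
``s = 2p + sigma`` with sigma = 0 (alpha) / 1 (beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import Determinant, determinant_occupations
from .core import SplitPartitioning, or_gate
from .gas import SupergroupTable, classify_excitation, supergroup_of
from .integrals import IntegralSet

__all__ = [
    "PCHBTables",
    "SampledMove",
    "build_double_weights",
    "build_single_weights",
    "constrain_tables",
    "sample_excitation",
    "sample_many",
    "p_gen_of",
    "connecting_elements",
]

WEIGHT_TRUNCATION = 1e-8  # integral magnitudes below this carry zero weight
BRANCH_FLOOR = 0.05


def _pair_index(s1: np.ndarray | int, s2: np.ndarray | int):
    """Index of the unordered spin-orbital pair s1 < s2."""
    return s2 * (s2 - 1) // 2 + s1


def _pair_arrays(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode arrays: pair index -> (s1, s2) with s1 < s2."""
    s2, s1 = np.triu_indices(m, k=1)[::-1]
    # triu_indices gives row<col; we want s1<s2 ordered by pair index
    n_pair = m * (m - 1) // 2
    a = np.empty(n_pair, dtype=np.int64)
    b = np.empty(n_pair, dtype=np.int64)
    for x, y in zip(s1, s2):
        idx = _pair_index(min(x, y), max(x, y))
        a[idx] = min(x, y)
        b[idx] = max(x, y)
    return a, b


def build_double_weights(ints: IntegralSet, truncation: float = WEIGHT_TRUNCATION) -> np.ndarray:
    """Raw heat-bath weights W[holes, particles] over spin-orbital pairs.

    Same-spin pairs carry ``|g_AIBJ - g_AJBI|``, opposite-spin pairs
    ``|g_AIBJ|`` (spin channels matched alpha-alpha / beta-beta); pairs that
    share a spin orbital or break spin conservation carry zero.
    """
    m = 2 * ints.n_orb
    p1, p2 = _pair_arrays(m)
    n_pair = len(p1)
    spat1, spin1 = p1 >> 1, p1 & 1
    spat2, spin2 = p2 >> 1, p2 & 1
    g = ints.g

    w = np.zeros((n_pair, n_pair))
    for hp in range(n_pair):
        i1, i2 = p1[hp], p2[hp]
        qi1, si1 = i1 >> 1, i1 & 1
        qi2, si2 = i2 >> 1, i2 & 1
        overlap = (p1 == i1) | (p1 == i2) | (p2 == i1) | (p2 == i2)
        if si1 == si2:  # same-spin holes: particles must share that spin
            ok = (spin1 == si1) & (spin2 == si1) & ~overlap
            vals = np.abs(g[spat1, qi1, spat2, qi2] - g[spat1, qi2, spat2, qi1])
        else:  # opposite-spin holes: particle pair must be opposite-spin too
            ok = (spin1 != spin2) & ~overlap
            # match alpha particle with alpha hole; with s1<s2 interleaved the
            # smaller index of an opposite-spin pair need not be the alpha one
            a_alpha = np.where(spin1 == 0, spat1, spat2)
            a_beta = np.where(spin1 == 0, spat2, spat1)
            h_alpha, h_beta = (qi1, qi2) if si1 == 0 else (qi2, qi1)
            vals = np.abs(g[a_alpha, h_alpha, a_beta, h_beta])
        row = np.where(ok, vals, 0.0)
        row[row < truncation] = 0.0
        w[hp] = row
    return w


def build_single_weights(ints: IntegralSet, truncation: float = WEIGHT_TRUNCATION) -> np.ndarray:
    """Raw single-excitation weights S[I, A] over spin orbitals (same spin).

    ``S_I^A = |h_AI| + sum_R |g_AIRR - g_ARRI|`` with the sum over spatial
    orbitals R; ``S_I^I = 0`` and cross-spin entries are zero.
    """
    n = ints.n_orb
    spat = np.abs(ints.h).copy()
    for a in range(n):
        for i in range(n):
            if a == i:
                continue
            spat[a, i] += np.sum(np.abs(ints.g[a, i].diagonal() - ints.g[a, :, :, i].diagonal()))
    np.fill_diagonal(spat, 0.0)
    spat[spat < truncation] = 0.0

    m = 2 * n
    s = np.zeros((m, m))
    for spin in (0, 1):
        idx = np.arange(n) * 2 + spin
        s[np.ix_(idx, idx)] = spat.T  # S[I, A] = spat[a_spatial, i_spatial]
    return s


@dataclass
class SampledMove:
    """One proposed excitation with its exact generation probability."""

    target: Determinant | None  # None when the draw was rejected
    p_gen: float
    kind: str  # 'single' | 'double'
    reason: str = ""  # rejection reason when target is None


class PCHBTables:
    """Supergroup-resolved PCHB weights with alias-table samplers.

    ``storage_mode='dense'`` keeps one full weight array per supergroup;
    ``'sparse'`` keeps only the nonzero rows keyed by (supergroup, category).
    Both modes build alias structures over the ascending nonzero support of a
    row, so sampling streams are bit-identical for identical seeds.
    """

    def __init__(
        self,
        table_T: SupergroupTable,
        part: SplitPartitioning | None,
        doubles: dict[int, np.ndarray],
        singles: dict[int, np.ndarray],
        n_orb: int,
        storage_mode: str = "dense",
    ) -> None:
        self.table_T = table_T
        self.part = part
        self.n_orb = n_orb
        self.m = 2 * n_orb
        self.pair_s1, self.pair_s2 = _pair_arrays(self.m)
        self.storage_mode = storage_mode
        self.double_rowsum = {sg: w.sum(axis=1) for sg, w in doubles.items()}
        self.single_rowsum = {sg: s.sum(axis=1) for sg, s in singles.items()}
        self.isolated: list[int] = []
        self.p_single: dict[int, float] = {}
        self.zero_fraction: dict[int, float] = {}
        for sg in doubles:
            w_tot = float(self.double_rowsum[sg].sum())
            s_tot = float(self.single_rowsum[sg].sum())
            self.zero_fraction[sg] = float(np.mean(doubles[sg] == 0.0))
            if w_tot == 0.0 and s_tot == 0.0:
                self.isolated.append(sg)
                self.p_single[sg] = np.nan
            elif w_tot == 0.0:
                self.p_single[sg] = 1.0
            elif s_tot == 0.0:
                self.p_single[sg] = 0.0
            else:
                self.p_single[sg] = float(
                    np.clip(s_tot / (s_tot + w_tot), BRANCH_FLOOR, 1.0 - BRANCH_FLOOR)
                )
        if storage_mode == "dense":
            self._doubles = doubles
            self._singles = singles
        elif storage_mode == "sparse":
            self._doubles = {
                sg: {
                    int(r): (np.flatnonzero(w[r]), w[r, np.flatnonzero(w[r])])
                    for r in np.flatnonzero(self.double_rowsum[sg] > 0)
                }
                for sg, w in doubles.items()
            }
            self._singles = {
                sg: {
                    int(r): (np.flatnonzero(s[r]), s[r, np.flatnonzero(s[r])])
                    for r in np.flatnonzero(self.single_rowsum[sg] > 0)
                }
                for sg, s in singles.items()
            }
        else:
            raise ValueError("storage_mode must be 'dense' or 'sparse'")
        self._alias_cache: dict[tuple, tuple] = {}

    # -- row access ---------------------------------------------------------
    def _row(self, kind: str, sg: int, row: int) -> tuple[np.ndarray, np.ndarray]:
        """Nonzero (support, weights) of one categorical row."""
        store = self._doubles if kind == "d" else self._singles
        if self.storage_mode == "dense":
            vec = store[sg][row]
            support = np.flatnonzero(vec)
            return support, vec[support]
        return store[sg].get(row, (np.empty(0, dtype=np.int64), np.empty(0)))

    def double_weight(self, sg: int, hole_pair: int, part_pair: int) -> float:
        support, w = self._row("d", sg, hole_pair)
        k = np.searchsorted(support, part_pair)
        if k < len(support) and support[k] == part_pair:
            return float(w[k])
        return 0.0

    def single_weight(self, sg: int, hole: int, particle: int) -> float:
        support, w = self._row("s", sg, hole)
        k = np.searchsorted(support, particle)
        if k < len(support) and support[k] == particle:
            return float(w[k])
        return 0.0

    def alias(self, kind: str, sg: int, row: int):
        """(prob, alias, support, p_norm) alias structure for one category.

        ``p_norm`` is the normalized weight vector over the support, i.e. the
        exact categorical probability of each slot.
        """
        key = (kind, sg, row)
        hit = self._alias_cache.get(key)
        if hit is None:
            support, w = self._row(kind, sg, row)
            p_norm = w / w.sum() if len(w) else w
            hit = (*_build_alias(w), support, p_norm)
            self._alias_cache[key] = hit
        return hit

    def stacked(self, kind: str, sg: int):
        """Row-padded alias arrays over all categories of one supergroup.

        Returns dict with 2D arrays ``prob``, ``alias``, ``support``,
        ``p_norm`` (rows = hole category, columns = padded support slots) and
        the per-row support length ``length``; enables one vectorized draw
        across mixed hole categories.
        """
        key = ("stack", kind, sg)
        hit = self._alias_cache.get(key)
        if hit is None:
            n_rows = self.m * (self.m - 1) // 2 if kind == "d" else self.m
            rows = [self.alias(kind, sg, r) for r in range(n_rows)]
            width = max((len(r[2]) for r in rows), default=0)
            prob = np.zeros((n_rows, max(width, 1)))
            alias = np.zeros((n_rows, max(width, 1)), dtype=np.int64)
            support = np.zeros((n_rows, max(width, 1)), dtype=np.int64)
            p_norm = np.zeros((n_rows, max(width, 1)))
            length = np.zeros(n_rows, dtype=np.int64)
            for r, (pr, al, su, pn) in enumerate(rows):
                k = len(su)
                length[r] = k
                if k:
                    prob[r, :k] = pr
                    alias[r, :k] = al
                    support[r, :k] = su
                    p_norm[r, :k] = pn
            hit = {"prob": prob, "alias": alias, "support": support, "p_norm": p_norm, "length": length}
            self._alias_cache[key] = hit
        return hit

    def supergroup_of_det(self, det: Determinant) -> int:
        occ = determinant_occupations(det, self.table_T.partition)
        sg = supergroup_of(occ, self.table_T)
        if sg is None:
            raise ValueError(f"determinant {det} violates the GAS constraints")
        return sg


def _build_alias(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vose alias construction: (prob, alias) arrays over ``len(w)`` slots."""
    k = len(w)
    if k == 0 or w.sum() == 0.0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    p = w * (k / w.sum())
    prob = np.zeros(k)
    alias = np.zeros(k, dtype=np.int64)
    small = [i for i in range(k) if p[i] < 1.0]
    large = [i for i in range(k) if p[i] >= 1.0]
    p = p.copy()
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = p[s]
        alias[s] = l
        p[l] = (p[l] + p[s]) - 1.0
        (small if p[l] < 1.0 else large).append(l)
    for rest in large + small:
        prob[rest] = 1.0
        alias[rest] = rest
    return prob, alias


def constrain_tables(
    raw_doubles: np.ndarray,
    raw_singles: np.ndarray,
    table_T: SupergroupTable,
    part: SplitPartitioning | None = None,
    storage_mode: str = "dense",
) -> PCHBTables:
    """Zero GAS-forbidden (and, with a partitioning, Q<-Q) weights per supergroup.

    An entry survives iff the subspace move is a valid supergroup transition
    from the source supergroup and, in SplitGAS mode, the OR-gate on the
    (source, target) pair is true.
    """
    gas = table_T.partition
    n_orb = max(max(sub) for sub in gas.subspaces) + 1
    sub_of_orb = np.full(n_orb, -1, dtype=np.int64)
    for si, sub in enumerate(gas.subspaces):
        for o in sub:
            sub_of_orb[o] = si
    m = 2 * n_orb
    p1, p2 = _pair_arrays(m)
    sub1 = sub_of_orb[p1 >> 1]
    sub2 = sub_of_orb[p2 >> 1]
    k = gas.k
    pair_cat = np.minimum(sub1, sub2) * k + np.maximum(sub1, sub2)
    orb_cat = sub_of_orb[np.arange(m) >> 1]

    doubles: dict[int, np.ndarray] = {}
    singles: dict[int, np.ndarray] = {}
    for sg in range(1, table_T.n_supergroups + 1):
        allowed_d = np.zeros((k * k, k * k), dtype=bool)
        for hu in range(k):
            for hv in range(hu, k):
                for pu in range(k):
                    for pv in range(pu, k):
                        tgt = classify_excitation(sg, (hu, hv), (pu, pv), table_T)
                        ok = tgt is not None and (part is None or or_gate(tgt, sg, part))
                        allowed_d[hu * k + hv, pu * k + pv] = ok
        allowed_s = np.zeros((k, k), dtype=bool)
        for hu in range(k):
            for pu in range(k):
                tgt = classify_excitation(sg, (hu,), (pu,), table_T)
                allowed_s[hu, pu] = tgt is not None and (
                    part is None or or_gate(tgt, sg, part)
                )
        doubles[sg] = raw_doubles * allowed_d[pair_cat[:, None], pair_cat[None, :]]
        singles[sg] = raw_singles * allowed_s[orb_cat[:, None], orb_cat[None, :]]
    return PCHBTables(table_T, part, doubles, singles, n_orb, storage_mode)


# ---------------------------------------------------------------------------
# sampling


def _occ_pairs(occ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(len(occ), k=1)
    return occ[i], occ[j]


def sample_many(
    parent: Determinant,
    i_sg: int,
    tables: PCHBTables,
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw ``n`` excitations from one parent; vectorized alias sampling.

    Returns arrays: ``kind`` (0 single / 1 double), ``valid`` flags, target
    ``alpha``/``beta`` masks, ``p_gen``, and the hole/particle spin orbitals
    (-1 padding for singles).  Invalid draws (occupied particle orbital, or a
    hole category with zero total weight) are explicit null moves.
    """
    p_single = tables.p_single.get(i_sg)
    if p_single is None or np.isnan(p_single):
        raise ValueError(f"supergroup {i_sg} has no outgoing weight (isolated)")
    occ = np.array(parent.spin_orbitals(), dtype=np.int64)
    n_e = len(occ)
    full = parent.interleaved()

    kind = (rng.random(n) >= p_single).astype(np.int64)  # 1 = double
    valid = np.zeros(n, dtype=bool)
    p_gen = np.zeros(n)
    holes = np.full((n, 2), -1, dtype=np.int64)
    parts = np.full((n, 2), -1, dtype=np.int64)

    # --- doubles
    d_idx = np.flatnonzero(kind == 1)
    if d_idx.size and n_e >= 2:
        h1_all, h2_all = _occ_pairs(occ)
        n_hp = len(h1_all)
        pick = rng.integers(0, n_hp, d_idx.size)
        rows = _pair_index(h1_all[pick], h2_all[pick])
        holes[d_idx, 0] = h1_all[pick]
        holes[d_idx, 1] = h2_all[pick]
        p_hole = (1.0 - p_single) / n_hp
        st = tables.stacked("d", i_sg)
        length = st["length"][rows]
        live = length > 0  # zero-weight hole pair stays invalid
        k_draw = (rng.random(d_idx.size) * length).astype(np.int64)
        u = rng.random(d_idx.size)
        k_draw = np.where(live, k_draw, 0)
        accept = u < st["prob"][rows, k_draw]
        slot = np.where(accept, k_draw, st["alias"][rows, k_draw])
        pp = st["support"][rows, slot]
        a1 = tables.pair_s1[pp]
        a2 = tables.pair_s2[pp]
        sel = d_idx[live]
        parts[sel, 0] = a1[live]
        parts[sel, 1] = a2[live]
        p_gen[sel] = p_hole * st["p_norm"][rows, slot][live]
        free = ((full >> a1) & 1 == 0) & ((full >> a2) & 1 == 0)
        valid[sel] = free[live]

    # --- singles
    s_idx = np.flatnonzero(kind == 0)
    if s_idx.size and n_e >= 1:
        pick = rng.integers(0, n_e, s_idx.size)
        hole = occ[pick]
        holes[s_idx, 0] = hole
        p_hole = p_single / n_e
        st = tables.stacked("s", i_sg)
        length = st["length"][hole]
        live = length > 0
        k_draw = (rng.random(s_idx.size) * length).astype(np.int64)
        u = rng.random(s_idx.size)
        k_draw = np.where(live, k_draw, 0)
        accept = u < st["prob"][hole, k_draw]
        slot = np.where(accept, k_draw, st["alias"][hole, k_draw])
        a = st["support"][hole, slot]
        sel = s_idx[live]
        parts[sel, 0] = a[live]
        p_gen[sel] = p_hole * st["p_norm"][hole, slot][live]
        valid[sel] = ((full >> a) & 1 == 0)[live]

    # --- assemble target masks for valid draws
    alpha = np.full(n, parent.alpha, dtype=np.int64)
    beta = np.full(n, parent.beta, dtype=np.int64)
    for col in range(2):
        h = holes[:, col]
        p = parts[:, col]
        act = valid & (h >= 0)
        ha = act & (h & 1 == 0)
        hb = act & (h & 1 == 1)
        alpha[ha] ^= np.int64(1) << (h[ha] >> 1)
        beta[hb] ^= np.int64(1) << (h[hb] >> 1)
        pa = act & (p & 1 == 0)
        pb = act & (p & 1 == 1)
        alpha[pa] |= np.int64(1) << (p[pa] >> 1)
        beta[pb] |= np.int64(1) << (p[pb] >> 1)
    return {
        "kind": kind,
        "valid": valid,
        "alpha": alpha,
        "beta": beta,
        "p_gen": p_gen,
        "holes": holes,
        "parts": parts,
    }


def sample_excitation(
    parent: Determinant, i_sg: int, tables: PCHBTables, rng: np.random.Generator
) -> SampledMove:
    """Draw one excitation; rejections come back as explicit null moves."""
    d = sample_many(parent, i_sg, tables, 1, rng)
    kind = "double" if d["kind"][0] else "single"
    if not d["valid"][0]:
        reason = "zero-weight category" if d["parts"][0, 0] < 0 else "particle occupied"
        return SampledMove(None, float(d["p_gen"][0]), kind, reason)
    return SampledMove(
        Determinant(int(d["alpha"][0]), int(d["beta"][0])), float(d["p_gen"][0]), kind
    )


def p_gen_of(
    parent: Determinant,
    target: Determinant,
    tables: PCHBTables,
    i_sg: int | None = None,
) -> float:
    """Exact probability that the sampler proposes ``target`` from ``parent``."""
    if i_sg is None:
        i_sg = tables.supergroup_of_det(parent)
    fi = parent.interleaved()
    fj = target.interleaved()
    diff = fi ^ fj
    rank = diff.bit_count() // 2
    if rank not in (1, 2):
        return 0.0
    hole_bits = diff & fi
    part_bits = diff & fj
    occ = parent.spin_orbitals()
    n_e = len(occ)
    p_single = tables.p_single[i_sg]
    if rank == 1:
        h = hole_bits.bit_length() - 1
        a = part_bits.bit_length() - 1
        rowsum = tables.single_rowsum[i_sg][h]
        if rowsum == 0.0:
            return 0.0
        return p_single / n_e * tables.single_weight(i_sg, h, a) / rowsum
    if n_e < 2:
        return 0.0
    h1, h2 = sorted(_bits_of(hole_bits))
    a1, a2 = sorted(_bits_of(part_bits))
    hp = _pair_index(h1, h2)
    pp = _pair_index(a1, a2)
    rowsum = tables.double_rowsum[i_sg][hp]
    if rowsum == 0.0:
        return 0.0
    n_hp = n_e * (n_e - 1) // 2
    return (1.0 - p_single) / n_hp * tables.double_weight(i_sg, hp, pp) / rowsum


def _bits_of(mask: int) -> list[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return out


# ---------------------------------------------------------------------------
# vectorized matrix elements for sampled moves


def _popcount(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x.astype(np.uint64)).astype(np.int64)


def _apply_parity(full: np.ndarray, pos: np.ndarray, sign: np.ndarray) -> np.ndarray:
    below = (np.int64(1) << pos) - np.int64(1)
    odd = _popcount(full & below) & 1
    sign *= np.where(odd == 1, -1, 1)
    return sign


def connecting_elements(
    ints: IntegralSet,
    parent: Determinant,
    kind: np.ndarray,
    holes: np.ndarray,
    parts: np.ndarray,
) -> np.ndarray:
    """Signed <target|H|parent> for arrays of sampled moves (rank 1 and 2).

    Mirrors the scalar Slater-Condon path, vectorized over draws with the
    interleaved-mask phase convention.
    """
    n = len(kind)
    out = np.zeros(n)
    full0 = np.int64(parent.interleaved())
    h_mat, g = ints.h, ints.g
    occ = np.array(parent.spin_orbitals(), dtype=np.int64)

    d = np.flatnonzero(kind == 1)
    if d.size:
        h1, h2 = holes[d, 0], holes[d, 1]
        a1, a2 = parts[d, 0], parts[d, 1]
        q1, s1 = h1 >> 1, h1 & 1
        q2, s2 = h2 >> 1, h2 & 1
        r1, t1 = a1 >> 1, a1 & 1
        r2, t2 = a2 >> 1, a2 & 1
        val = np.where((t1 == s1) & (t2 == s2), g[r1, q1, r2, q2], 0.0)
        val -= np.where((t1 == s2) & (t2 == s1), g[r1, q2, r2, q1], 0.0)
        sign = np.ones(d.size, dtype=np.int64)
        full = np.full(d.size, full0)
        sign = _apply_parity(full, h1, sign)
        full ^= np.int64(1) << h1
        sign = _apply_parity(full, h2, sign)
        full ^= np.int64(1) << h2
        sign = _apply_parity(full, a2, sign)
        full |= np.int64(1) << a2
        sign = _apply_parity(full, a1, sign)
        out[d] = sign * val

    s_rows = np.flatnonzero(kind == 0)
    if s_rows.size:
        h1 = holes[s_rows, 0]
        a1 = parts[s_rows, 0]
        q, sq = h1 >> 1, h1 & 1
        r, _ = a1 >> 1, a1 & 1
        val = h_mat[r, q].copy()
        for s in occ:
            pr, sr = int(s) >> 1, int(s) & 1
            keep = (s != h1)
            val += np.where(keep, g[r, q, pr, pr], 0.0)
            val -= np.where(keep & (sr == sq), g[r, np.full_like(q, pr), np.full_like(q, pr), q], 0.0)
        sign = np.ones(s_rows.size, dtype=np.int64)
        full = np.full(s_rows.size, full0)
        sign = _apply_parity(full, h1, sign)
        full ^= np.int64(1) << h1
        sign = _apply_parity(full, a1, sign)
        out[s_rows] = sign * val
    return out
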