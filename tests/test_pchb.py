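"""Heat-bath weights, supergroup masking, alias sampling, p_gen evaluation."""

from itertools import combinations

import numpy as np
import pytest

from splitgas.basis import Determinant, enumerate_space, slater_condon_element
from splitgas.core import build_ip_vector, or_gate
from splitgas.gas import GASPartition, classify_excitation, enumerate_supergroups
from splitgas.integrals import IntegralSet, make_hubbard, make_random_integrals
from splitgas.pchb import (
    PCHBTables,
    _build_alias,
    _pair_arrays,
    _pair_index,
    build_double_weights,
    build_single_weights,
    connecting_elements,
    constrain_tables,
    p_gen_of,
    sample_excitation,
    sample_many,
)


def _cas_tables(ints, sizes=None, n_min=None, n_max=None, part_bounds=None, mode="dense"):
    sizes = sizes or [ints.n_orb]
    n_min = n_min if n_min is not None else [ints.n_elec]
    n_max = n_max if n_max is not None else [ints.n_elec]
    gas = GASPartition.from_sizes(sizes, n_min, n_max, "local", ints.n_elec)
    table = enumerate_supergroups(gas)
    part = None
    if part_bounds is not None:
        gas_p = GASPartition.from_sizes(sizes, *part_bounds, "local", ints.n_elec)
        part = build_ip_vector(table, gas_p)
    tables = constrain_tables(
        build_double_weights(ints), build_single_weights(ints), table, part, storage_mode=mode
    )
    return gas, table, part, tables


class TestRawWeights:
    def test_hubbard_dimer_doubles_vanish_singles_carry_hopping(self):
        """A density-density interaction has zero double-excitation matrix
        elements (g_AIBJ needs A=I to touch g_iiii, which collides with the
        hole), so the dimer moves only through hopping singles of weight t."""
        ints = make_hubbard(2, 1.0, 4.0)
        assert not build_double_weights(ints).any()
        s = build_single_weights(ints)
        assert s[0, 2] == pytest.approx(1.0)  # site 0 -> 1, alpha channel
        assert s[3, 1] == pytest.approx(1.0)  # site 1 -> 0, beta channel

    def test_zero_g_means_zero_double_weights(self):
        ints = IntegralSet(n_orb=3, n_elec=2)
        ints.h[0, 1] = ints.h[1, 0] = 0.5
        assert not build_double_weights(ints).any()

    def test_double_weight_values_match_loop_oracle(self):
        ints = make_random_integrals(3, 4, seed=8)
        w = build_double_weights(ints)
        p1, p2 = _pair_arrays(6)
        for hp in range(len(p1)):
            for pp in range(len(p1)):
                i1, i2, a1, a2 = p1[hp], p2[hp], p1[pp], p2[pp]
                if {i1, i2} & {a1, a2} or sorted((i1 & 1, i2 & 1)) != sorted((a1 & 1, a2 & 1)):
                    assert w[hp, pp] == 0.0
                    continue
                # oracle: determinant-independent |<j|H|i>| via Slater-Condon
                # on a two-electron pair with no spectators
                d_i = Determinant.from_occ(
                    [s >> 1 for s in (i1, i2) if s % 2 == 0],
                    [s >> 1 for s in (i1, i2) if s % 2 == 1],
                )
                d_j = Determinant.from_occ(
                    [s >> 1 for s in (a1, a2) if s % 2 == 0],
                    [s >> 1 for s in (a1, a2) if s % 2 == 1],
                )
                expected = abs(slater_condon_element(d_i, d_j, ints))
                if expected < 1e-8:
                    expected = 0.0
                assert w[hp, pp] == pytest.approx(expected, abs=1e-12)

    def test_single_weights_eq_formula(self):
        # bare hopping: S_1^2 = |h_12|
        ints = IntegralSet(n_orb=2, n_elec=2)
        ints.h[0, 1] = ints.h[1, 0] = 0.3
        s = build_single_weights(ints)
        assert s[0, 2] == pytest.approx(0.3)  # alpha channel
        assert s[1, 3] == pytest.approx(0.3)  # beta channel
        assert s[0, 1] == 0.0  # cross spin
        assert np.diag(s).sum() == 0.0

    def test_single_weights_match_summation_oracle(self):
        ints = make_random_integrals(4, 4, seed=4)
        s = build_single_weights(ints)
        for i_orb in range(4):
            for a_orb in range(4):
                if i_orb == a_orb:
                    continue
                expected = abs(ints.h[a_orb, i_orb]) + sum(
                    abs(ints.g[a_orb, i_orb, r, r] - ints.g[a_orb, r, r, i_orb])
                    for r in range(4)
                )
                assert s[2 * i_orb, 2 * a_orb] == pytest.approx(expected, abs=1e-12)

    def test_diagonal_only_integrals_give_zero_single_weights(self):
        ints = make_random_integrals(3, 4, seed=0, sparsity=1.0)
        assert not build_single_weights(ints).any()


class TestConstrainedTables:
    def test_zeroing_is_exactly_the_constraint_mask(self, table1_partition):
        """weight(i_sg, move) = 0 iff GAS-forbidden or OR-gate false,
        exhaustively over every supergroup and spin-orbital move."""
        ints = make_random_integrals(6, 3, seed=6)
        table = enumerate_supergroups(table1_partition)
        part = build_ip_vector(table, p_supergroups=[2, 4])
        raw_d = build_double_weights(ints)
        raw_s = build_single_weights(ints)
        tables = constrain_tables(raw_d, raw_s, table, part)
        sub_of = table1_partition.subspace_of_orbital()
        p1, p2 = _pair_arrays(12)
        for sg in range(1, table.n_supergroups + 1):
            for hp in range(0, len(p1), 7):  # stride keeps the loop affordable
                for pp in range(0, len(p1), 7):
                    holes = (sub_of[p1[hp] >> 1], sub_of[p2[hp] >> 1])
                    parts = (sub_of[p1[pp] >> 1], sub_of[p2[pp] >> 1])
                    tgt = classify_excitation(sg, holes, parts, table)
                    allowed = tgt is not None and or_gate(tgt, sg, part)
                    got = tables.double_weight(sg, hp, pp)
                    if not allowed:
                        assert got == 0.0
                    else:
                        assert got == raw_d[hp, pp]

    def test_worked_example_third_electron_into_g1(self, table1_partition):
        """From [1,1,1] any double placing two particles in G1 is zeroed;
        from [0,1,2] the same orbital move retains its raw weight."""
        ints = make_random_integrals(6, 3, seed=2)
        table = enumerate_supergroups(table1_partition)
        raw_d = build_double_weights(ints)
        tables = constrain_tables(raw_d, build_single_weights(ints), table)
        from splitgas.gas import supergroup_of

        sg_111 = supergroup_of((1, 1, 1), table)
        sg_012 = supergroup_of((0, 1, 2), table)
        # holes: one G2 orbital (orb 2) one G3 orbital (orb 4); particles in G1
        hp = _pair_index(2 * 2, 2 * 4)  # alpha spin orbitals of orbitals 2, 4
        pp = _pair_index(2 * 0, 2 * 1)  # alpha particles on orbitals 0, 1
        assert tables.double_weight(sg_111, hp, pp) == 0.0
        if raw_d[hp, pp] > 0:
            assert tables.double_weight(sg_012, hp, pp) == raw_d[hp, pp]

    def test_q_only_connected_supergroup_has_empty_double_table(self):
        """A Q supergroup whose doubles all land in Q carries an all-zero
        double table (the fourth spawn case is excluded at generation)."""
        # two subspaces, P = everything with G2 empty; the supergroup with
        # G2 = 4 can only reach G2 in {2, 3, 4} by a double -> all Q
        ints = make_random_integrals(4, 4, seed=3)
        gas = GASPartition.from_sizes([2, 2], [0, 0], [4, 4], "local", 4)
        table = enumerate_supergroups(gas)
        gas_p = GASPartition.from_sizes([2, 2], [4, 0], [4, 0], "local", 4)
        part = build_ip_vector(table, gas_p)
        tables = constrain_tables(
            build_double_weights(ints), build_single_weights(ints), table, part
        )
        from splitgas.gas import supergroup_of

        sg_q = supergroup_of((0, 4), table)
        assert tables.double_rowsum[sg_q].sum() == 0.0

    def test_single_supergroup_tables_equal_raw(self):
        ints = make_random_integrals(3, 4, seed=1)
        _, _, _, tables = _cas_tables(ints)
        assert np.array_equal(tables._doubles[1], build_double_weights(ints))
        assert np.array_equal(tables._singles[1], build_single_weights(ints))


class TestAlias:
    def test_alias_reproduces_weight_vector(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = rng.random(rng.integers(1, 40))
            w[rng.random(len(w)) < 0.3] = 0.0
            if w.sum() == 0.0:
                continue
            support = np.flatnonzero(w)
            prob, alias = _build_alias(w[support])
            k = len(support)
            induced = prob.copy()
            for s in range(k):
                if alias[s] != s:
                    induced[alias[s]] += 1.0 - prob[s]
            assert np.allclose(induced / k, w[support] / w.sum(), atol=1e-12)

    def test_dense_and_sparse_streams_identical(self):
        ints = make_random_integrals(4, 4, seed=9)
        _, _, _, dense = _cas_tables(ints, mode="dense")
        _, _, _, sparse = _cas_tables(ints, mode="sparse")
        parent = Determinant.from_occ([0, 1], [0, 1])
        a = sample_many(parent, 1, dense, 5000, np.random.default_rng(42))
        b = sample_many(parent, 1, sparse, 5000, np.random.default_rng(42))
        for key in ("kind", "valid", "alpha", "beta", "holes", "parts"):
            assert np.array_equal(a[key], b[key])
        assert np.allclose(a["p_gen"], b["p_gen"], atol=0.0)


class TestSampling:
    def test_accepted_moves_satisfy_constraints(self, splitgas_cas66):
        """10^4 draws: every accepted target passes GAS and OR-gate checks."""
        ints, gas_t, gas_p = splitgas_cas66
        gas, table, part, tables = _cas_tables(
            ints, [2, 2, 2], [0, 0, 0], [4, 4, 4], part_bounds=([2, 0, 0], [4, 4, 0])
        )
        space = enumerate_space(ints, 3, 3, gas, table)
        rng = np.random.default_rng(7)
        from splitgas.basis import determinant_occupations
        from splitgas.gas import supergroup_of

        for parent in space.determinants[::40]:
            i_sg = tables.supergroup_of_det(parent)
            draws = sample_many(parent, i_sg, tables, 2000, rng)
            for j in np.flatnonzero(draws["valid"]):
                target = Determinant(int(draws["alpha"][j]), int(draws["beta"][j]))
                occ = determinant_occupations(target, gas)
                t_sg = supergroup_of(occ, table)
                assert t_sg is not None
                assert or_gate(t_sg, i_sg, part)

    def test_single_orbital_system_cannot_move(self):
        ints = IntegralSet(n_orb=1, n_elec=2)
        ints.g[0, 0, 0, 0] = 4.0
        _, _, _, tables = _cas_tables(ints)
        assert tables.isolated == [1]
        parent = Determinant.from_occ([0], [0])
        with pytest.raises(ValueError, match="isolated"):
            sample_excitation(parent, 1, tables, np.random.default_rng(0))

    def test_rejected_moves_are_explicit(self):
        ints = make_hubbard(2, 1.0, 4.0)
        _, _, _, tables = _cas_tables(ints)
        parent = Determinant.from_occ([0], [0])
        rng = np.random.default_rng(1)
        seen_rejection = seen_move = False
        for _ in range(200):
            move = sample_excitation(parent, 1, tables, rng)
            assert 0.0 <= move.p_gen <= 1.0
            if move.target is None:
                seen_rejection = True
            else:
                seen_move = True
                assert move.p_gen > 0.0
        assert seen_move  # the dimer has valid double moves from |2,0>

    def test_expected_spawn_matches_matrix_element(self):
        """Monte Carlo unbiasedness: mean of K_ij/p_gen restricted to draws
        hitting j equals K_ij times the number of draws, within 4 sigma."""
        ints = make_random_integrals(3, 4, seed=12)
        gas, table, _, tables = _cas_tables(ints)
        space = enumerate_space(ints, 2, 2)
        parent = space.determinants[0]
        rng = np.random.default_rng(3)
        n = 200_000
        draws = sample_many(parent, 1, tables, n, rng)
        idx = np.flatnonzero(draws["valid"])
        kv = connecting_elements(ints, parent, draws["kind"][idx], draws["holes"][idx], draws["parts"][idx])
        counts: dict[tuple[int, int], int] = {}
        ratio: dict[tuple[int, int], float] = {}
        for j, k in zip(idx, kv):
            key = (int(draws["alpha"][j]), int(draws["beta"][j]))
            counts[key] = counts.get(key, 0) + 1
            ratio[key] = k / draws["p_gen"][j]
        checked = 0
        for (a, b), c in counts.items():
            if c < 50:
                continue
            target = Determinant(a, b)
            p = p_gen_of(parent, target, tables)
            k_exact = slater_condon_element(parent, target, ints)
            # mean spawned weight per draw: (c/n) * K/p_gen, expected K
            mean = c / n * ratio[(a, b)]
            sigma = abs(ratio[(a, b)]) * np.sqrt(p * (1.0 - p) / n)
            assert abs(mean - k_exact) < 4.0 * sigma + 1e-12
            checked += 1
        assert checked >= 3


class TestPGen:
    def test_total_probability_mass_is_one(self):
        """Moves + rejections + dead categories exhaust the sample space
        exactly (6-orbital system, exhaustive enumeration)."""
        ints = make_random_integrals(3, 4, seed=2)
        gas, table, _, tables = _cas_tables(ints, [2, 1], [1, 0], [4, 2])
        space = enumerate_space(ints, 2, 2, gas, table)
        for parent in space.determinants[:6]:
            i_sg = tables.supergroup_of_det(parent)
            occ = parent.spin_orbitals()
            n_e = len(occ)
            ps = tables.p_single[i_sg]
            full = parent.interleaved()
            mass = 0.0
            n_hp = n_e * (n_e - 1) // 2
            for h1, h2 in combinations(occ, 2):
                row = _pair_index(h1, h2)
                _, _, support, p_norm = tables.alias("d", i_sg, int(row))
                if len(support) == 0:
                    mass += (1.0 - ps) / n_hp  # dead category
                else:
                    mass += (1.0 - ps) / n_hp * p_norm.sum()
            for h in occ:
                _, _, support, p_norm = tables.alias("s", i_sg, int(h))
                if len(support) == 0:
                    mass += ps / n_e
                else:
                    mass += ps / n_e * p_norm.sum()
            assert mass == pytest.approx(1.0, abs=1e-12)

    def test_p_gen_of_agrees_with_path_enumeration(self):
        """p_gen_of equals the summed probability of every sampler path that
        produces the pair, and valid-target masses plus rejections total 1."""
        ints = make_random_integrals(3, 4, seed=2)
        gas, table, _, tables = _cas_tables(ints, [2, 1], [1, 0], [4, 2])
        space = enumerate_space(ints, 2, 2, gas, table)
        parent = space.determinants[0]
        i_sg = tables.supergroup_of_det(parent)
        occ = parent.spin_orbitals()
        n_e = len(occ)
        ps = tables.p_single[i_sg]
        full = parent.interleaved()
        p1, p2 = tables.pair_s1, tables.pair_s2
        path_mass: dict[Determinant, float] = {}
        rejection = 0.0
        n_hp = n_e * (n_e - 1) // 2
        for h1, h2 in combinations(occ, 2):
            row = _pair_index(h1, h2)
            _, _, support, p_norm = tables.alias("d", i_sg, int(row))
            for slot, pp in enumerate(support):
                a1, a2 = int(p1[pp]), int(p2[pp])
                p_path = (1.0 - ps) / n_hp * p_norm[slot]
                if (full >> a1) & 1 or (full >> a2) & 1:
                    rejection += p_path
                    continue
                new = (full ^ (1 << h1) ^ (1 << h2)) | (1 << a1) | (1 << a2)
                from splitgas.basis import from_interleaved

                det = from_interleaved(new)
                path_mass[det] = path_mass.get(det, 0.0) + p_path
        for h in occ:
            _, _, support, p_norm = tables.alias("s", i_sg, int(h))
            for slot, a in enumerate(support):
                p_path = ps / n_e * p_norm[slot]
                if (full >> int(a)) & 1:
                    rejection += p_path
                    continue
                from splitgas.basis import from_interleaved

                det = from_interleaved((full ^ (1 << h)) | (1 << int(a)))
                path_mass[det] = path_mass.get(det, 0.0) + p_path
        for det, mass in path_mass.items():
            assert p_gen_of(parent, det, tables) == pytest.approx(mass, abs=1e-14)

    def test_forbidden_and_distant_pairs_have_zero_p_gen(self, table1_partition):
        ints = make_random_integrals(6, 3, seed=1)
        table = enumerate_supergroups(table1_partition)
        tables = constrain_tables(
            build_double_weights(ints), build_single_weights(ints), table
        )
        # parent in supergroup [1,1,1]: orbital 0 (G1), 2 (G2), 4 (G3)
        parent = Determinant.from_occ([0, 2], [4])
        # a double moving both G2/G3 electrons into G1 -> [3,0,0], forbidden
        target = Determinant.from_occ([0, 1], [1])
        assert p_gen_of(parent, target, tables) == 0.0
        # rank-3 move
        far = Determinant.from_occ([1, 3], [5])
        assert p_gen_of(parent, far, tables) == 0.0
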