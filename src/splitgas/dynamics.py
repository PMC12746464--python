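"""FCIQMC walker dynamics over full, GAS-constrained or SplitGAS Hamiltonians.

The CI vector is carried by a signed real-weighted walker population
n_i(tau); one imaginary-time step applies, per Delta c_j = -Delta tau
(sum_i K_ij c_i + (K_jj - S) c_j) with K = H - E_ref I,

  (i)   excitation generation through the supergroup-resolved PCHB sampler,
  (ii)  spawning with probability Delta tau |K_ij| / p_gen and sign
        -sign(K_ij) sign(n_i),
  (iii) death/cloning by the diagonal factor Delta tau (K_jj - S),
  (iv)  annihilation by keyed merge of signed weights.

The shift S acts as population control and, at stationarity, estimates the
correlation energy.  An optional semistochastic core propagates the most
important configurations deterministically (OR-gate-masked core Hamiltonian
in SplitGAS mode); the initiator rule discards spawns onto unoccupied
configurations from weakly populated parents.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import CISpace, Determinant, diagonal_element, enumerate_space, excitation_rank, slater_condon_element
from .core import SplitPartitioning, build_ip_vector, or_gate
from .gas import GASPartition, enumerate_supergroups
from .integrals import IntegralSet
from .pchb import PCHBTables, build_double_weights, build_single_weights, connecting_elements, constrain_tables, sample_many

__all__ = ["RunConfig", "WalkerPopulation", "RunStats", "FCIQMCRun", "run"]


@dataclass
class RunConfig:
    """Parameters of one FCIQMC dynamics."""

    n_steps: int = 2000
    dtau: float | None = None  # inverse Hartree; None = automatic
    target_walkers: float = 5.0e4
    shift_damping: float = 0.05  # zeta
    shift_period: int = 5  # A steps between shift updates
    initiator_threshold: float = 3.0  # n_add
    seed: int = 0
    core_size: int = 0
    mode: str = "full"  # full | gas | splitgas
    initial_walkers: float = 100.0
    bloom_cap: float = 3.0  # spawns above this magnitude are logged as blooms
    storage_mode: str = "dense"

    def __post_init__(self) -> None:
        if self.dtau is not None and self.dtau <= 0:
            raise ValueError("dtau must be positive")
        if self.initiator_threshold < 0 or self.target_walkers <= 0:
            raise ValueError("thresholds must be non-negative")
        if self.mode not in ("full", "gas", "splitgas"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class WalkerPopulation:
    """Signed real walker weights keyed by determinant."""

    weights: dict[Determinant, float]
    reference: Determinant
    e_ref: float

    @property
    def total_weight(self) -> float:
        return float(sum(abs(w) for w in self.weights.values()))

    @property
    def n_occupied(self) -> int:
        return len(self.weights)

    def as_vector(self, space: CISpace) -> np.ndarray:
        """Instantaneous CI coefficients over an enumerated space."""
        v = np.zeros(len(space))
        for det, w in self.weights.items():
            v[space.index(det)] = w
        return v


@dataclass
class RunStats:
    """Per-step records of the dynamics plus run-level audit counters."""

    records: list[dict] = field(default_factory=list)
    wallclock: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    def series(self, key: str, burn_in: int = 0) -> np.ndarray:
        return self.to_frame()[key].to_numpy()[burn_in:]

    @property
    def qq_spawn_events(self) -> int:
        return int(sum(r["qq_events"] for r in self.records))

    @property
    def forbidden_spawn_events(self) -> int:
        return int(sum(r["forbidden_events"] for r in self.records))


def _single_supergroup_partition(n_orb: int, n_elec: int) -> GASPartition:
    return GASPartition.from_sizes([n_orb], [n_elec], [n_elec], "local", n_elec)


class FCIQMCRun:
    """One prepared dynamics: spaces, PCHB tables, semistochastic core, state.

    ``gas_T`` defaults to a single fully connected subspace (plain FCIQMC).
    In ``splitgas`` mode the reference is the lowest-diagonal P determinant
    and all spawning uses the OR-gate-masked tables, so the dynamics solves
    the effective Hamiltonian rather than the bare one.
    """

    def __init__(
        self,
        ints: IntegralSet,
        config: RunConfig,
        gas_T: GASPartition | None = None,
        p_constraints: GASPartition | None = None,
        n_alpha: int | None = None,
        n_beta: int | None = None,
    ) -> None:
        self.ints = ints
        self.config = config
        if gas_T is None:
            gas_T = _single_supergroup_partition(ints.n_orb, ints.n_elec)
        self.gas_T = gas_T
        self.table_T = enumerate_supergroups(gas_T)
        self.part: SplitPartitioning | None = None
        if config.mode == "splitgas":
            if p_constraints is None:
                raise ValueError("splitgas mode needs p_constraints")
            self.part = build_ip_vector(self.table_T, p_constraints)
        self.tables: PCHBTables = constrain_tables(
            build_double_weights(ints),
            build_single_weights(ints),
            self.table_T,
            self.part,
            storage_mode=config.storage_mode,
        )
        self.space = enumerate_space(ints, n_alpha, n_beta, gas_T, self.table_T)
        self.rng = np.random.default_rng(config.seed)

        self._sg_cache: dict[Determinant, int] = {}
        self._diag_cache: dict[Determinant, float] = {}
        self._ref_row_cache: dict[Determinant, float] = {}

        self.pop = self._init_population()
        self.e_ref = self.pop.e_ref
        self._setup_core()
        self._setup_sg_codes()
        self.dtau = config.dtau if config.dtau is not None else self._auto_dtau()
        self.shift = 0.0
        self.shift_engaged = False
        self._nw_at_update = None
        self.stats = RunStats()

    # -- setup --------------------------------------------------------------
    def _sg_of(self, det: Determinant) -> int:
        sg = self._sg_cache.get(det)
        if sg is None:
            sg = self.tables.supergroup_of_det(det)
            self._sg_cache[det] = sg
        return sg

    def _diag(self, det: Determinant) -> float:
        d = self._diag_cache.get(det)
        if d is None:
            d = diagonal_element(det, self.ints)
            self._diag_cache[det] = d
        return d

    def _init_population(self) -> WalkerPopulation:
        """All initial weight on the lowest-diagonal allowed determinant (in P
        for SplitGAS mode); ties broken by the canonical determinant order."""
        candidates = self.space.determinants
        if self.part is not None:
            candidates = [d for d in candidates if self.part.is_p(self._sg_of(d))]
            if not candidates:
                raise ValueError("P constraints admit no determinant")
        ref = min(candidates, key=lambda d: (self._diag(d), d.alpha, d.beta))
        e_ref = self._diag(ref)
        return WalkerPopulation({ref: self.config.initial_walkers}, ref, e_ref)

    def _setup_core(self) -> None:
        size = min(self.config.core_size, len(self.space))
        self.core: list[Determinant] = []
        self.core_set: set[Determinant] = set()
        self.core_h = None
        if size <= 0:
            self.core_is_full = False
            return
        order = sorted(self.space.determinants, key=lambda d: (self._diag(d), d.alpha, d.beta))
        self.core = order[:size]
        if self.pop.reference not in self.core:
            self.core[-1] = self.pop.reference
        self.core_set = set(self.core)
        self.core_index = {d: i for i, d in enumerate(self.core)}
        h = np.zeros((size, size))
        for i, di in enumerate(self.core):
            h[i, i] = self._diag(di)
            for j in range(i + 1, size):
                dj = self.core[j]
                if excitation_rank(di, dj) > 2:
                    continue
                if self.part is not None and not or_gate(
                    self._sg_of(di), self._sg_of(dj), self.part
                ):
                    continue  # OR-gate-masked core Hamiltonian
                h[i, j] = h[j, i] = slater_condon_element(di, dj, self.ints)
        self.core_h = h
        self.core_is_full = size >= len(self.space)

    def _setup_sg_codes(self) -> None:
        """Dense lookup from subspace-occupation codes to supergroup indices.

        The occupation vector of a determinant is encoded as an integer in a
        mixed radix; one array lookup then yields supergroup index (0 =
        GAS-forbidden) and P membership for whole spawn batches at once.
        """
        gas = self.gas_T
        k = gas.k
        self._sub_masks = np.array(
            [sum(1 << o for o in sub) for sub in gas.subspaces], dtype=np.int64
        )
        base = 2 * self.ints.n_orb + 1
        self._sg_base = np.array([base**i for i in range(k)], dtype=np.int64)
        code_to_sg = np.zeros(base**k, dtype=np.int64)
        code_to_isp = np.zeros(base**k, dtype=bool)
        for comp, i_sg in self.table_T.sg_index.items():
            code = int(np.dot(np.array(comp, dtype=np.int64), self._sg_base))
            code_to_sg[code] = i_sg
            if self.part is not None:
                code_to_isp[code] = self.part.is_p(i_sg)
        self._code_to_sg = code_to_sg
        self._code_to_isp = code_to_isp

    def _sg_codes(self, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
        occ_code = np.zeros(len(alpha), dtype=np.int64)
        for i, mask in enumerate(self._sub_masks):
            occ = np.bitwise_count((alpha & mask).astype(np.uint64)).astype(np.int64)
            occ += np.bitwise_count((beta & mask).astype(np.uint64)).astype(np.int64)
            occ_code += occ * self._sg_base[i]
        return occ_code

    def _auto_dtau(self) -> float:
        diags = [self._diag(d) for d in self.space.determinants]
        span = max(diags) - min(diags)
        return min(0.1, 1.0 / (span + 1.0))

    # -- per-step pieces ----------------------------------------------------
    def _ref_coupling(self, det: Determinant) -> float:
        v = self._ref_row_cache.get(det)
        if v is None:
            if excitation_rank(self.pop.reference, det) > 2:
                v = 0.0
            else:
                v = slater_condon_element(self.pop.reference, det, self.ints)
            self._ref_row_cache[det] = v
        return v

    def projected_energy(self) -> float:
        """<ref|H|Psi> / <ref|Psi>; NaN when the reference is unoccupied."""
        n_ref = self.pop.weights.get(self.pop.reference, 0.0)
        if n_ref == 0.0:
            return float("nan")
        e = self._diag(self.pop.reference)
        for det, w in self.pop.weights.items():
            if det is self.pop.reference or det == self.pop.reference:
                continue
            c = self._ref_coupling(det)
            if c != 0.0:
                e += c * w / n_ref
        return e

    def _stochastic_round(self, values: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Round magnitudes below 1 to 0/1 stochastically, keeping the sign."""
        mag = np.abs(values)
        small = mag < 1.0
        out = values.copy()
        out[small] = np.where(u[small] < mag[small], np.sign(values[small]), 0.0)
        return out

    def step(self) -> dict:
        cfg = self.config
        rng = self.rng
        dtau = self.dtau
        spawns: dict[Determinant, float] = {}
        attempts_total = accepted = blooms = 0
        qq_events = forbidden_events = initiator_discards = 0

        items = sorted(self.pop.weights.items(), key=lambda kv: (kv[0].alpha, kv[0].beta))
        for det, w in items:
            if self.core_is_full:
                break  # fully deterministic propagation
            mag = abs(w)
            attempts = int(mag) + (1 if rng.random() < mag - int(mag) else 0)
            if attempts == 0:
                continue
            in_core = det in self.core_set
            i_sg = self._sg_of(det)
            if i_sg in self.tables.isolated:
                continue  # no outgoing weight anywhere: death term only
            draws = sample_many(det, i_sg, self.tables, attempts, rng)
            attempts_total += attempts
            valid = draws["valid"]
            if not valid.any():
                continue
            idx = np.flatnonzero(valid)
            k_vals = connecting_elements(
                self.ints, det, draws["kind"][idx], draws["holes"][idx], draws["parts"][idx]
            )
            child = -dtau * k_vals / draws["p_gen"][idx] * np.sign(w)
            child = self._stochastic_round(child, rng.random(len(child)))
            live = child != 0.0
            n_blooms = int(np.count_nonzero(np.abs(child) > cfg.bloom_cap))
            if n_blooms:
                blooms += n_blooms
                if not self.shift_engaged and cfg.dtau is None:
                    self.dtau *= 0.95**n_blooms  # equilibration time-step search
            if not live.any():
                continue
            jj = idx[live]
            child = child[live]
            t_alpha = draws["alpha"][jj]
            t_beta = draws["beta"][jj]
            # audits: GAS closure and QQ suppression must hold by construction
            t_sg = self._code_to_sg[self._sg_codes(t_alpha, t_beta)]
            bad = t_sg == 0
            forbidden_events += int(bad.sum())
            if self.part is not None and not self.part.is_p(i_sg):
                t_isp = self._code_to_isp[self._sg_codes(t_alpha, t_beta)]
                qq = ~bad & ~t_isp
                qq_events += int(qq.sum())
                bad |= qq
            keep = ~bad
            if not keep.any():
                continue
            # merge children by target before the per-target bookkeeping
            code = (t_alpha[keep].astype(np.uint64) << np.uint64(32)) | t_beta[keep].astype(
                np.uint64
            )
            uniq, first, inverse, counts = np.unique(
                code, return_index=True, return_inverse=True, return_counts=True
            )
            sums = np.bincount(inverse, weights=child[keep])
            parent_strong = mag >= cfg.initiator_threshold or in_core
            ka = t_alpha[keep]
            kb = t_beta[keep]
            for u in range(len(uniq)):
                target = Determinant(int(ka[first[u]]), int(kb[first[u]]))
                if in_core and target in self.core_set:
                    continue  # core-to-core handled deterministically
                if (
                    not parent_strong
                    and target not in self.pop.weights
                    and target not in self.core_set
                ):
                    initiator_discards += int(counts[u])
                    continue
                spawns[target] = spawns.get(target, 0.0) + float(sums[u])
                accepted += int(counts[u])

        # death / cloning (deterministic on real weights) + core propagation
        new_weights: dict[Determinant, float] = {}
        e0 = self.e_ref + self.shift
        if self.core_h is not None:
            vec = np.array([self.pop.weights.get(d, 0.0) for d in self.core])
            k_core = self.core_h - e0 * np.eye(len(self.core))
            vec = vec - dtau * (k_core @ vec)
            for d, v in zip(self.core, vec):
                new_weights[d] = float(v)
        for det, w in self.pop.weights.items():
            if det in self.core_set:
                continue
            new_weights[det] = w * (1.0 - dtau * (self._diag(det) - e0))

        # annihilation: signed keyed merge
        for det, w in spawns.items():
            new_weights[det] = new_weights.get(det, 0.0) + w

        # stochastic rounding of sub-unit occupied weights (non-core)
        keys = sorted(new_weights, key=lambda d: (d.alpha, d.beta))
        final: dict[Determinant, float] = {}
        for det in keys:
            w = new_weights[det]
            if det in self.core_set:
                final[det] = w
                continue
            mag = abs(w)
            if mag == 0.0:
                continue
            if mag < 1.0:
                if rng.random() < mag:
                    final[det] = float(np.sign(w))
            else:
                final[det] = w
        self.pop.weights = final

        n_w = self.pop.total_weight
        if not self.shift_engaged and n_w >= self.config.target_walkers:
            self.shift_engaged = True
            # seed the shift with the current energy estimate so population
            # control starts near stationarity instead of chasing the growth
            e_proj = self.projected_energy()
            if np.isfinite(e_proj):
                self.shift = e_proj - self.e_ref
            self._nw_at_update = n_w
            self._steps_since_update = 0
        elif self.shift_engaged:
            self._steps_since_update += 1
            if self._steps_since_update >= self.config.shift_period:
                self.update_shift(n_w)
                self._steps_since_update = 0

        rec = {
            "step": len(self.stats.records),
            "shift": self.shift,
            "e_proj": self.projected_energy(),
            "n_walkers": n_w,
            "n_occupied": self.pop.n_occupied,
            "ref_weight": self.pop.weights.get(self.pop.reference, 0.0),
            "attempts": attempts_total,
            "accepted": accepted,
            "acceptance_ratio": accepted / attempts_total if attempts_total else 0.0,
            "qq_events": qq_events,
            "forbidden_events": forbidden_events,
            "initiator_discards": initiator_discards,
            "blooms": blooms,
            "dtau": self.dtau,
        }
        self.stats.records.append(rec)
        return rec

    def update_shift(self, n_w: float) -> None:
        """S <- S - zeta/(A dtau) ln(N_w / N_w_prev)."""
        cfg = self.config
        if self._nw_at_update and n_w > 0:
            self.shift -= (
                cfg.shift_damping
                / (cfg.shift_period * self.dtau)
                * np.log(n_w / self._nw_at_update)
            )
        self._nw_at_update = n_w

    def run(self) -> RunStats:
        t0 = time.perf_counter()
        for _ in range(self.config.n_steps):
            self.step()
            if self.pop.total_weight == 0.0:
                raise RuntimeError("walker population died out")
        self.stats.wallclock = time.perf_counter() - t0
        return self.stats

    # -- estimators ---------------------------------------------------------
    def energy_estimates(self, burn_in: int | None = None) -> dict[str, float]:
        """Mean projected energy and mean total energy from the shift.

        The shift estimates the correlation energy relative to ``e_ref``, so
        ``e_ref + <S>`` is directly comparable to ``<E_proj>``.
        """
        if burn_in is None:
            burn_in = self.config.n_steps // 2
        frame = self.stats.to_frame().iloc[burn_in:]
        e_proj = frame["e_proj"].to_numpy()
        e_proj = e_proj[np.isfinite(e_proj)]
        return {
            "e_proj_mean": float(np.mean(e_proj)),
            "shift_energy_mean": float(self.e_ref + frame["shift"].mean()),
        }


def run(
    config: RunConfig,
    ints: IntegralSet,
    gas_T: GASPartition | None = None,
    p_constraints: GASPartition | None = None,
) -> tuple[RunStats, WalkerPopulation, FCIQMCRun]:
    """Prepare and execute one dynamics; reproducible per config.seed."""
    driver = FCIQMCRun(ints, config, gas_T, p_constraints)
    stats = driver.run()
    return stats, driver.pop, driver
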