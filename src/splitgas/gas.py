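"""Generalized active space (GAS) partitions, compositions and supergroups.

A GAS model splits the active orbitals into ``k`` disjoint subspaces and
restricts how many electrons each may hold, either through *local* bounds
``N_i^min <= x_i <= N_i^max`` or *cumulative* bounds on the running sums
``sum_{j<=i} x_j``.  A distribution of ``N`` electrons over the subspaces is a
*composition*; compositions satisfying the constraints are *supergroups*.
Both are indexed (1-based, ``i_C`` and ``i_sg``) in decreasing lexicographic
order.  The supergroup of a configuration is the only information an
excitation generator needs to enforce GAS rules with zero runtime overhead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

__all__ = [
    "GASPartition",
    "SupergroupTable",
    "enumerate_compositions",
    "enumerate_supergroups",
    "supergroup_of",
    "classify_excitation",
    "ddci_supergroups",
]

Composition = tuple[int, ...]


@dataclass(frozen=True)
class GASPartition:
    """Disjoint orbital subspaces with occupation constraints.

    ``subspaces`` holds 0-based orbital indices.  ``n_min``/``n_max`` are the
    per-subspace bounds for ``flavor='local'`` or the bounds on cumulative
    sums for ``flavor='cumulative'``.
    """

    subspaces: tuple[tuple[int, ...], ...]
    n_min: tuple[int, ...]
    n_max: tuple[int, ...]
    flavor: str = "local"
    n_elec_active: int | None = None

    def __post_init__(self) -> None:
        k = len(self.subspaces)
        object.__setattr__(self, "subspaces", tuple(tuple(sorted(s)) for s in self.subspaces))
        object.__setattr__(self, "n_min", tuple(self.n_min))
        object.__setattr__(self, "n_max", tuple(self.n_max))
        if self.flavor not in ("local", "cumulative"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if not (len(self.n_min) == len(self.n_max) == k):
            raise ValueError("n_min/n_max length must match number of subspaces")
        seen: set[int] = set()
        for sub in self.subspaces:
            if seen.intersection(sub):
                raise ValueError("GAS subspaces must be disjoint")
            seen.update(sub)
        if self.n_elec_active is None:
            if self.flavor == "cumulative":
                object.__setattr__(self, "n_elec_active", self.n_max[-1])
            else:
                raise ValueError("n_elec_active required for local constraints")
        sizes = self.sizes
        if self.flavor == "local":
            for i in range(k):
                if not 0 <= self.n_min[i] <= self.n_max[i] <= 2 * sizes[i]:
                    raise ValueError(f"invalid local bounds for subspace {i}")
        else:
            if list(self.n_min) != sorted(self.n_min) or list(self.n_max) != sorted(self.n_max):
                raise ValueError("cumulative bounds must be non-decreasing")
            if self.n_min[-1] != self.n_elec_active or self.n_max[-1] != self.n_elec_active:
                raise ValueError("final cumulative bound must equal n_elec_active")

    @classmethod
    def from_sizes(
        cls,
        sizes: list[int],
        n_min: list[int],
        n_max: list[int],
        flavor: str = "local",
        n_elec_active: int | None = None,
        first_orbital: int = 0,
    ) -> "GASPartition":
        """Build a partition over consecutive orbital blocks of given sizes."""
        subspaces, start = [], first_orbital
        for size in sizes:
            subspaces.append(tuple(range(start, start + size)))
            start += size
        return cls(tuple(subspaces), tuple(n_min), tuple(n_max), flavor, n_elec_active)

    @property
    def k(self) -> int:
        return len(self.subspaces)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.subspaces)

    @property
    def orbitals(self) -> tuple[int, ...]:
        return tuple(o for sub in self.subspaces for o in sub)

    def subspace_of_orbital(self) -> dict[int, int]:
        return {o: i for i, sub in enumerate(self.subspaces) for o in sub}

    def allows(self, x: Composition) -> bool:
        """Constraint test for one composition, including orbital capacity."""
        if len(x) != self.k or any(xi < 0 for xi in x):
            return False
        if any(xi > 2 * size for xi, size in zip(x, self.sizes)):
            return False
        if self.flavor == "local":
            return all(lo <= xi <= hi for xi, lo, hi in zip(x, self.n_min, self.n_max))
        running = 0
        for xi, lo, hi in zip(x, self.n_min, self.n_max):
            running += xi
            if not lo <= running <= hi:
                return False
        return True

    def to_cumulative(self) -> "GASPartition":
        """Derive the equivalent cumulative constraint set from local bounds.

        The cumulative minimum at level ``i`` is the total minus the maximal
        occupation the remaining subspaces can absorb; the maximum is the sum
        of the leading local maxima (both clipped to feasibility).
        """
        if self.flavor == "cumulative":
            return self
        n = self.n_elec_active
        k = self.k
        caps = [min(self.n_max[i], 2 * self.sizes[i]) for i in range(k)]
        cum_min, cum_max = [], []
        for i in range(k):
            tail_cap = sum(caps[i + 1 :])
            head_cap = sum(caps[: i + 1])
            head_min = sum(self.n_min[: i + 1])
            cum_min.append(max(head_min, n - tail_cap))
            cum_max.append(min(head_cap, n - sum(self.n_min[i + 1 :])))
        cum_min[-1] = cum_max[-1] = n
        return GASPartition(self.subspaces, tuple(cum_min), tuple(cum_max), "cumulative", n)


def enumerate_compositions(n: int, k: int) -> list[Composition]:
    """All compositions ``x_1 + ... + x_k = n`` in decreasing lexicographic order.

    The list has ``C(n + k - 1, k - 1)`` entries; ``i_C`` is the 1-based
    position in this ordering.
    """
    if n < 0 or k < 1:
        raise ValueError("need n >= 0 and k >= 1")
    out: list[Composition] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(tuple(prefix + [remaining]))
            return
        for x in range(remaining, -1, -1):
            rec(prefix + [x], remaining - x, slots - 1)

    rec([], n, k)
    assert len(out) == comb(n + k - 1, k - 1)
    return out


@dataclass
class SupergroupTable:
    """Compositions and constraint-satisfying supergroups with index maps."""

    partition: GASPartition
    compositions: list[Composition]
    supergroups: list[Composition]
    comp_index: dict[Composition, int] = field(default_factory=dict)  # 1-based i_C
    sg_index: dict[Composition, int] = field(default_factory=dict)  # 1-based i_sg

    def __post_init__(self) -> None:
        if not self.comp_index:
            self.comp_index = {x: i + 1 for i, x in enumerate(self.compositions)}
        if not self.sg_index:
            self.sg_index = {x: i + 1 for i, x in enumerate(self.supergroups)}

    @property
    def n_supergroups(self) -> int:
        return len(self.supergroups)

    def composition_of_sg(self, i_sg: int) -> Composition:
        return self.supergroups[i_sg - 1]


def enumerate_supergroups(gas: GASPartition) -> SupergroupTable:
    """Filter the compositions of the partition down to its supergroups."""
    comps = enumerate_compositions(gas.n_elec_active, gas.k)
    sgs = [x for x in comps if gas.allows(x)]
    if not sgs:
        raise ValueError("GAS constraints admit no supergroup (infeasible model)")
    return SupergroupTable(gas, comps, sgs)


def supergroup_of(occupations: Composition, table: SupergroupTable) -> int | None:
    """Supergroup index of an occupation vector, or None if forbidden."""
    x = tuple(occupations)
    if sum(x) != table.partition.n_elec_active:
        raise ValueError(
            f"occupations sum to {sum(x)}, expected {table.partition.n_elec_active}"
        )
    return table.sg_index.get(x)


def classify_excitation(
    i_sg: int,
    holes: tuple[int, ...],
    particles: tuple[int, ...],
    table: SupergroupTable,
) -> int | None:
    """Target supergroup after moving electrons between subspaces, or None.

    ``holes``/``particles`` are subspace indices (one or two of each).  A
    target occupation that is negative, exceeds a subspace capacity, or fails
    the GAS constraints is forbidden (returns None), not an error.
    """
    if not 1 <= len(holes) <= 2 or len(holes) != len(particles):
        raise ValueError("need 1 or 2 holes and equally many particles")
    x = list(table.composition_of_sg(i_sg))
    for h in holes:
        x[h] -= 1
    for p in particles:
        x[p] += 1
    sizes = table.partition.sizes
    if any(xi < 0 or xi > 2 * s for xi, s in zip(x, sizes)):
        return None
    return table.sg_index.get(tuple(x))


_DDCI_CLASSES = {
    1: [(0, 0), (1, 0), (0, 1), (1, 1)],
    2: [(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2)],
    3: [(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (1, 2), (2, 1)],
}


def ddci_supergroups(n_o: int, n_a: int, n_elec_a: int, n_v: int, level: int = 3) -> SupergroupTable:
    """Difference-dedicated CI space encoded as supergroups.

    GAS1 holds ``n_o`` doubly occupied orbitals, GAS2 a valence CAS of
    ``n_elec_a`` electrons in ``n_a`` orbitals, GAS3 ``n_v`` virtuals.  The
    supergroups are ``[2 n_o - n_h, N_a + (n_h - m_p), m_p]`` for the hole /
    particle classes of the requested level; DDCI3 keeps everything up to
    2h+1p / 1h+2p but excludes the pure 2h+2p class.
    """
    if level not in _DDCI_CLASSES:
        raise ValueError("level must be 1, 2 or 3")
    if min(n_o, n_a, n_elec_a, n_v) < 0:
        raise ValueError("counts must be non-negative")
    n_total = 2 * n_o + n_elec_a
    gas = GASPartition.from_sizes(
        [n_o, n_a, n_v],
        [0, 0, 0],
        [2 * n_o, 2 * n_a, 2 * n_v],
        "local",
        n_total,
    )
    comps = enumerate_compositions(n_total, 3)
    wanted: set[Composition] = set()
    for n_h, m_p in _DDCI_CLASSES[level]:
        x = (2 * n_o - n_h, n_elec_a + (n_h - m_p), m_p)
        if all(0 <= xi <= 2 * s for xi, s in zip(x, gas.sizes)):
            wanted.add(x)
    sgs = [x for x in comps if x in wanted]
    return SupergroupTable(gas, comps, sgs)
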