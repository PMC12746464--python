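"""Molecular integral containers, FCIDUMP I/O, and synthetic generators.

The electronic Hamiltonian is defined by a scalar core energy ``e_core``,
one-electron integrals ``h[i, j]`` and two-electron integrals ``g[i, j, k, l]``
in chemist's notation, ``(ij|kl)``, all in Hartree.  ``g`` carries the 8-fold
real-orbital permutation symmetry (i<->j, k<->l, ij<->kl).

Orbital indices are 1-based in FCIDUMP files and 0-based everywhere in memory;
the conversion happens only inside :func:`read_fcidump` / :func:`write_fcidump`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

__all__ = [
    "IntegralSet",
    "read_fcidump",
    "write_fcidump",
    "make_hubbard",
    "make_random_integrals",
]


@dataclass
class IntegralSet:
    """One- and two-electron integrals of a molecular Hamiltonian.

    Attributes
    ----------
    n_orb, n_elec, ms2
        Spatial orbital count, electron count and twice the spin projection.
    e_core
        Scalar energy offset (nuclear repulsion + frozen core), Hartree.
    h
        ``(n_orb, n_orb)`` symmetric one-electron matrix, Hartree.
    g
        ``(n_orb,) * 4`` two-electron tensor in chemist's notation, Hartree,
        with 8-fold permutation symmetry.
    """

    n_orb: int
    n_elec: int
    ms2: int = 0
    e_core: float = 0.0
    h: np.ndarray = field(default=None)  # type: ignore[assignment]
    g: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_orb
        if self.h is None:
            self.h = np.zeros((n, n))
        if self.g is None:
            self.g = np.zeros((n, n, n, n))
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.h.shape != (n, n):
            raise ValueError(f"h has shape {self.h.shape}, expected {(n, n)}")
        if self.g.shape != (n, n, n, n):
            raise ValueError(f"g has shape {self.g.shape}, expected {(n,) * 4}")

    def validate(self, atol: float = 1e-12) -> None:
        """Raise if the symmetry or finiteness invariants are violated."""
        if not (np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.g))):
            raise ValueError("non-finite integral values")
        if not np.allclose(self.h, self.h.T, atol=atol):
            raise ValueError("h is not symmetric")
        g = self.g
        for perm in (
            g.transpose(1, 0, 2, 3),
            g.transpose(0, 1, 3, 2),
            g.transpose(2, 3, 0, 1),
        ):
            if not np.allclose(g, perm, atol=atol):
                raise ValueError("g violates 8-fold permutation symmetry")

    def allclose(self, other: "IntegralSet", atol: float = 0.0) -> bool:
        return (
            self.n_orb == other.n_orb
            and self.n_elec == other.n_elec
            and self.ms2 == other.ms2
            and abs(self.e_core - other.e_core) <= atol
            and np.allclose(self.h, other.h, rtol=0.0, atol=atol)
            and np.allclose(self.g, other.g, rtol=0.0, atol=atol)
        )


class FCIDumpError(ValueError):
    """Malformed FCIDUMP content; the message names the offending line."""


def _set_g(g: np.ndarray, i: int, j: int, k: int, l: int, value: float) -> None:
    """Store ``value`` under all 8 index permutations of ``(ij|kl)``."""
    for a, b in ((i, j), (j, i)):
        for c, d in ((k, l), (l, k)):
            g[a, b, c, d] = value
            g[c, d, a, b] = value


_HEADER_INT = re.compile(r"(NORB|NELEC|MS2)\s*=\s*([-+]?\d+)", re.IGNORECASE)


def read_fcidump(path: str | Path) -> IntegralSet:
    """Read an FCIDUMP file into an :class:`IntegralSet`.

    Accepts both ``&END`` and ``/`` as header terminators and ignores
    ``ORBSYM``/``ISYM`` (all calculations here are C1).  Records populate all
    8 permutations of each two-electron entry; unlisted entries are zero.
    """
    lines = Path(path).read_text().splitlines()
    header_lines: list[str] = []
    body_start = None
    for lineno, line in enumerate(lines):
        header_lines.append(line)
        stripped = line.strip().upper()
        if stripped.endswith("&END") or stripped == "/" or stripped.endswith("/"):
            body_start = lineno + 1
            break
    if body_start is None:
        raise FCIDumpError("no header terminator (&END or /) found")

    header = " ".join(header_lines)
    fields = {m.group(1).upper(): int(m.group(2)) for m in _HEADER_INT.finditer(header)}
    for key in ("NORB", "NELEC"):
        if key not in fields:
            raise FCIDumpError(f"header missing {key}")
    n_orb = fields["NORB"]
    if n_orb < 1:
        raise FCIDumpError(f"NORB={n_orb} must be positive")
    ints = IntegralSet(n_orb=n_orb, n_elec=fields["NELEC"], ms2=fields.get("MS2", 0))

    for lineno in range(body_start, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FCIDumpError(f"line {lineno + 1}: expected 'value i j k l', got {line!r}")
        try:
            value = float(parts[0].replace("D", "E").replace("d", "e"))
            i, j, k, l = (int(p) for p in parts[1:])
        except ValueError as exc:
            raise FCIDumpError(f"line {lineno + 1}: non-numeric field in {line!r}") from exc
        for idx in (i, j, k, l):
            if idx < 0 or idx > n_orb:
                raise FCIDumpError(f"line {lineno + 1}: orbital index {idx} outside [0, {n_orb}]")
        if i == j == k == l == 0:
            ints.e_core = value
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise FCIDumpError(f"line {lineno + 1}: one-electron record with a zero index")
            ints.h[i - 1, j - 1] = value
            ints.h[j - 1, i - 1] = value
        else:
            if 0 in (i, j, k, l):
                raise FCIDumpError(f"line {lineno + 1}: two-electron record with a zero index")
            _set_g(ints.g, i - 1, j - 1, k - 1, l - 1, value)
    return ints


def write_fcidump(ints: IntegralSet, path: str | Path, threshold: float = 1e-12) -> None:
    """Write an FCIDUMP file with one canonical record per permutation class.

    Entries with magnitude below ``threshold`` are omitted (the core energy is
    always written).
    """
    n = ints.n_orb
    out = [
        f"&FCI NORB={n},NELEC={ints.n_elec},MS2={ints.ms2},",
        " ORBSYM=" + ",".join(["1"] * n) + ",",
        " ISYM=1,",
        "&END",
    ]

    def rec(value: float, i: int, j: int, k: int, l: int) -> str:
        return f"{value: .16E} {i:4d} {j:4d} {k:4d} {l:4d}"

    # canonical two-electron representative: i>=j, k>=l, (i,j) >= (k,l)
    for i in range(n):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    v = ints.g[i, j, k, l]
                    if abs(v) >= threshold:
                        out.append(rec(v, i + 1, j + 1, k + 1, l + 1))
    for i in range(n):
        for j in range(i + 1):
            if abs(ints.h[i, j]) >= threshold:
                out.append(rec(ints.h[i, j], i + 1, j + 1, 0, 0))
    out.append(rec(ints.e_core, 0, 0, 0, 0))
    Path(path).write_text("\n".join(out) + "\n")


def make_hubbard(n_sites: int, t: float = 1.0, u: float = 4.0, periodic: bool = False) -> IntegralSet:
    """Half-filled Hubbard chain: hopping ``-t`` on bonds, on-site repulsion ``u``.

    ``n_elec = n_sites``; ``ms2`` is 0 for even chains and 1 for odd ones.
    The dimer (t=1, u) has the closed-form singlet ground energy
    ``(u - sqrt(u**2 + 16 t**2)) / 2``, used as an exact oracle in tests.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    ints = IntegralSet(n_orb=n_sites, n_elec=n_sites, ms2=n_sites % 2)
    for i in range(n_sites - 1):
        ints.h[i, i + 1] = ints.h[i + 1, i] = -t
    if periodic and n_sites > 2:
        ints.h[0, n_sites - 1] = ints.h[n_sites - 1, 0] = -t
    for i in range(n_sites):
        ints.g[i, i, i, i] = u
    return ints


def make_random_integrals(
    n_orb: int,
    n_elec: int,
    seed: int = 0,
    scale: float = 0.1,
    sparsity: float = 0.0,
    diag_spread: float = 1.0,
) -> IntegralSet:
    """Random Hermitian integral set with the 8-fold symmetry built in.

    The one-electron diagonal is spread over ``[0, diag_spread * n_orb]`` so
    the lowest Hartree product dominates the ground state and spectra stay
    bounded; off-diagonal magnitudes scale with ``scale``.  ``sparsity`` is the
    fraction of off-diagonal permutation classes zeroed at random; at 1 only
    the diagonal ``h`` and ``g[i,i,i,i]`` survive.
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ints = IntegralSet(n_orb=n_orb, n_elec=n_elec, ms2=n_elec % 2)

    h = scale * rng.standard_normal((n_orb, n_orb))
    h = 0.5 * (h + h.T)
    np.fill_diagonal(h, diag_spread * np.arange(n_orb) + scale * rng.standard_normal(n_orb))
    keep_h = rng.random((n_orb, n_orb)) >= sparsity
    keep_h &= keep_h.T  # symmetric keep mask
    off = ~np.eye(n_orb, dtype=bool)
    h[off & ~keep_h] = 0.0
    ints.h = h

    g = np.zeros((n_orb,) * 4)
    for i, j, k, l in product(range(n_orb), repeat=4):
        if not (i >= j and k >= l and (i, j) >= (k, l)):
            continue  # canonical representative only
        value = scale * rng.standard_normal()
        is_diag = i == j == k == l
        if is_diag:
            value = abs(value) + 0.1 * scale  # repulsive on-site terms
        elif rng.random() < sparsity:
            value = 0.0
        _set_g(g, i, j, k, l, value)
    ints.g = g
    ints.validate()
    return ints
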