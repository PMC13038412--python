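"""Symmetry-orbit combinatorics of peroxiredoxin decamer rings.

Typical 2-Cys peroxiredoxins assemble as (alpha2)5 toroids: five head-to-tail
dimers (B-type interface inside each dimer) closed into a ring through A-type
dimer-dimer interfaces.  When the ten subunit positions can be occupied by
monomers of ``m`` distinguishable types (or redox / PTM states), two labelled
rings describe the same physical particle when one is carried onto the other
by a rotation about the fivefold axis or a flip about one of the five twofold
axes lying in the ring plane.  This module constructs that dihedral action on
ring positions, counts the orbits with Burnside's lemma, and enumerates one
canonical representative per orbit.

Conventions
-----------
Positions ``0 .. 2d-1`` run around the ring; positions ``(2i, 2i+1)`` form
dimer ``i``.  Rotations shift by even offsets (a one-position shift is not a
symmetry of the dimer-of-dimers assembly).  The twofold axes pass through
interface midpoints, so every reflection is a fixed-point-free product of
``d`` transpositions; this is the convention under which two monomer types
yield 120 distinct decamers (axes through monomers would give 136).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: refuse exhaustive enumeration above this many labelings
ENUMERATION_GUARD = 2_000_000


@dataclass(frozen=True)
class DecamerConfiguration:
    """One labelled ring of ``2d`` monomer positions grouped into ``d`` dimers.

    ``labels[2i]`` and ``labels[2i+1]`` are the two subunits of dimer ``i``.
    """

    labels: tuple[int, ...]
    d: int = 5

    def __post_init__(self) -> None:
        if self.d < 1:
            raise InvalidParameterError(f"d must be >= 1, got {self.d}")
        if len(self.labels) != 2 * self.d:
            raise InvalidParameterError(
                f"expected {2 * self.d} labels for d={self.d}, got {len(self.labels)}"
            )
        if any(l < 0 for l in self.labels):
            raise InvalidParameterError("labels must be non-negative integers")

    @property
    def composition(self) -> tuple[int, ...]:
        """Counts of each label value up to max(labels)."""
        m = max(self.labels) + 1
        return tuple(self.labels.count(t) for t in range(m))


@dataclass(frozen=True)
class SymmetryGroup:
    """The order-``2d`` dihedral action on ring positions.

    Each permutation ``p`` acts on a labelling by ``labels[p[i]] -> position i``.
    """

    d: int
    rotations: tuple[tuple[int, ...], ...]
    reflections: tuple[tuple[int, ...], ...]

    @property
    def permutations(self) -> tuple[tuple[int, ...], ...]:
        return self.rotations + self.reflections

    @property
    def order(self) -> int:
        return 2 * self.d

    def apply(self, perm: tuple[int, ...], labels: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(labels[j] for j in perm)


@dataclass
class OrbitCensus:
    """Orbit counts, total and broken down by subunit composition."""

    m: int
    d: int
    total_distinct: int
    by_composition: dict = field(default_factory=dict)
    representatives: list[DecamerConfiguration] | None = None

    def combined_ratios(self) -> dict[tuple[int, int], int]:
        """Pairs (k, 2d-k) with their combined orbit counts (m=2 only)."""
        if self.m != 2:
            raise InvalidParameterError("combined ratios are defined for m=2")
        n = 2 * self.d
        out: dict[tuple[int, int], int] = {}
        for k in range(n // 2 + 1):
            c = self.by_composition.get(k, 0)
            if k != n - k:
                c += self.by_composition.get(n - k, 0)
            out[(k, n - k)] = c
        return out


def build_symmetry_group(d: int) -> SymmetryGroup:
    """Construct the dihedral group of the ``d``-dimer ring.

    ``d`` rotations (cyclic shifts by even offsets) plus ``d`` fixed-point-free
    reflections through interface midpoints (``i -> (c - i) mod 2d`` with ``c``
    odd).  The result is verified closed under composition.
    """
    if not isinstance(d, (int, np.integer)) or d < 1:
        raise InvalidParameterError(f"dimer count d must be a positive integer, got {d!r}")
    n = 2 * d
    rotations = tuple(tuple((i + 2 * r) % n for i in range(n)) for r in range(d))
    reflections = tuple(tuple((c - i) % n for i in range(n)) for c in range(1, n, 2))
    group = SymmetryGroup(d=d, rotations=rotations, reflections=reflections)
    perms = set(group.permutations)
    assert len(perms) == 2 * d
    for p, q in itertools.product(group.permutations, repeat=2):
        if tuple(p[j] for j in q) not in perms:  # pragma: no cover - construction bug
            raise AssertionError("symmetry group not closed under composition")
    for refl in reflections:
        if any(refl[i] == i for i in range(n)):  # pragma: no cover
            raise AssertionError("reflection is not fixed-point-free")
    return group


def _check_md(m: int, d: int) -> None:
    for name, v in (("m", m), ("d", d)):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
            raise InvalidParameterError(f"{name} must be a positive integer, got {v!r}")


def _cycle_count(perm: tuple[int, ...]) -> int:
    seen = [False] * len(perm)
    cycles = 0
    for i in range(len(perm)):
        if not seen[i]:
            cycles += 1
            j = i
            while not seen[j]:
                seen[j] = True
                j = perm[j]
    return cycles


def burnside_count(m: int, d: int) -> int:
    """Number of orbits of ``m``-colorings of the ring under the dihedral action.

    Burnside's lemma: the orbit count is the group average of ``m**cycles(g)``.
    Exact integer arithmetic; no size guard is needed.
    """
    _check_md(m, d)
    group = build_symmetry_group(d)
    total = sum(int(m) ** _cycle_count(p) for p in group.permutations)
    q, r = divmod(total, group.order)
    assert r == 0
    return q


def canonical_form(
    config: DecamerConfiguration, group: SymmetryGroup | None = None
) -> DecamerConfiguration:
    """Lexicographically smallest image of ``config`` under the group."""
    if group is None:
        group = build_symmetry_group(config.d)
    best = min(group.apply(p, config.labels) for p in group.permutations)
    return DecamerConfiguration(labels=best, d=config.d)


def enumerate_orbits(m: int, d: int, representatives: bool = True) -> OrbitCensus:
    """Exhaustively enumerate symmetry-distinct ring labellings.

    Every one of the ``m**(2d)`` labellings is reduced to its canonical form
    (minimum over the group's images); unique canonical forms are the orbit
    representatives.  Refuses when the state space exceeds the guard threshold.
    """
    _check_md(m, d)
    n = 2 * d
    n_states = m**n
    if n_states > ENUMERATION_GUARD:
        raise InvalidParameterError(
            f"state space m**(2d) = {n_states} exceeds enumeration guard "
            f"{ENUMERATION_GUARD}; use burnside_count for counting"
        )
    group = build_symmetry_group(d)

    # all labelings as base-m digit rows, most significant digit at position 0
    codes = np.arange(n_states, dtype=np.int64)
    digits = np.empty((n_states, n), dtype=np.int64)
    rem = codes
    for pos in range(n - 1, -1, -1):
        digits[:, pos] = rem % m
        rem = rem // m
    weights = m ** np.arange(n - 1, -1, -1, dtype=np.int64)

    canon = codes.copy()
    for p in group.permutations:
        img = digits[:, list(p)] @ weights
        np.minimum(canon, img, out=canon)

    uniq = np.unique(canon)
    total = int(uniq.size)

    reps: list[DecamerConfiguration] | None = None
    rep_digits = digits[uniq]
    if representatives:
        reps = [DecamerConfiguration(labels=tuple(int(x) for x in row), d=d) for row in rep_digits]

    by_comp: dict = {}
    if m == 2:
        ones = rep_digits.sum(axis=1)
        ks, counts = np.unique(ones, return_counts=True)
        by_comp = {int(k): int(c) for k, c in zip(ks, counts)}
    else:
        for row in rep_digits:
            key = tuple(int((row == t).sum()) for t in range(m))
            by_comp[key] = by_comp.get(key, 0) + 1

    return OrbitCensus(
        m=m, d=d, total_distinct=total, by_composition=by_comp, representatives=reps
    )


def composition_census(d: int) -> OrbitCensus:
    """Orbit counts of two-type rings broken down by subunit stoichiometry.

    Returns the ``m=2`` census whose ``by_composition[k]`` is the number of
    distinct decamers containing exactly ``k`` type-1 subunits; the combined
    ``k : 2d-k`` ratios are available via :meth:`OrbitCensus.combined_ratios`.
    """
    _check_md(2, d)
    return enumerate_orbits(2, d, representatives=False)


def orbit_sizes(m: int, d: int) -> list[int]:
    """Sizes of all orbits (they partition the m**(2d) labellings)."""
    _check_md(m, d)
    n = 2 * d
    if m**n > ENUMERATION_GUARD:
        raise InvalidParameterError("state space exceeds enumeration guard")
    group = build_symmetry_group(d)
    sizes: dict[tuple[int, ...], int] = {}
    for labels in itertools.product(range(m), repeat=n):
        canon = min(group.apply(p, labels) for p in group.permutations)
        sizes[canon] = sizes.get(canon, 0) + 1
    assert sum(sizes.values()) == m**n
    return sorted(sizes.values())
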