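"""Ring combinatorics: dihedral group construction, Burnside counts, orbit census."""

import itertools

import numpy as np
import pytest

from prxkit import (
    DecamerConfiguration,
    build_symmetry_group,
    burnside_count,
    canonical_form,
    composition_census,
    enumerate_orbits,
)
from prxkit.errors import InvalidParameterError
from prxkit.ring import orbit_sizes


def oracle_orbit_count(m: int, d: int) -> int:
    """Independent brute-force orbit count by explicit list manipulation.

    Builds the ring symmetries directly as label-sequence operations
    (slicing for rotations, index reversal around odd centers for flips)
    and groups all m**(2d) labelings by their orbit minimum.
    """
    n = 2 * d

    def images(labels):
        out = []
        for r in range(d):
            rot = labels[2 * r:] + labels[:2 * r]
            out.append(rot)
            for c in range(1, n, 2):
                out.append(tuple(labels[(c - i) % n] for i in range(n)))
        return out

    seen = set()
    for labels in itertools.product(range(m), repeat=n):
        seen.add(min(images(labels)))
    return len(seen)


class TestSymmetryGroup:
    def test_order_and_reflection_structure(self):
        g = build_symmetry_group(5)
        assert g.order == 10
        assert len(g.rotations) == 5 and len(g.reflections) == 5
        for refl in g.reflections:
            assert all(refl[i] != i for i in range(10)), "reflection has a fixed point"
            # involution built from 5 transpositions
            assert all(refl[refl[i]] == i for i in range(10))

    def test_rotations_are_even_shifts(self):
        g = build_symmetry_group(5)
        shifts = sorted(p[0] for p in g.rotations)
        assert shifts == [0, 2, 4, 6, 8]

    def test_two_reflections_compose_to_rotation(self):
        g = build_symmetry_group(5)
        rotset = set(g.rotations)
        for p, q in itertools.product(g.reflections, repeat=2):
            composed = tuple(p[j] for j in q)
            assert composed in rotset

    def test_reflections_map_dimers_to_dimers(self):
        g = build_symmetry_group(5)
        dimers = [{2 * i, 2 * i + 1} for i in range(5)]
        for perm in g.permutations:
            for dim in dimers:
                assert {perm[i] for i in dim} in dimers

    def test_minimal_ring(self):
        g = build_symmetry_group(1)
        assert g.order == 2
        assert set(g.permutations) == {(0, 1), (1, 0)}

    def test_invalid_dimer_count(self):
        with pytest.raises(InvalidParameterError):
            build_symmetry_group(0)


class TestBurnside:
    @pytest.mark.parametrize(
        "m,d,expected",
        [(2, 5, 120), (1, 5, 1), (1, 3, 1), (3, 5, 6030), (2, 1, 3)],
    )
    def test_known_counts(self, m, d, expected):
        assert burnside_count(m, d) == expected

    @pytest.mark.parametrize("m", range(1, 7))
    def test_closed_form_d5(self, m):
        # cycle index of the constructed group at d=5: five rotations
        # contribute m^10 + 4 m^2, five fixed-point-free flips 5 m^5
        assert burnside_count(m, 5) == (m**10 + 4 * m**2 + 5 * m**5) // 10

    @pytest.mark.parametrize("m,d", [(m, d) for m in (1, 2, 3) for d in (1, 2, 3)])
    def test_matches_independent_brute_force(self, m, d):
        assert burnside_count(m, d) == oracle_orbit_count(m, d)

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            burnside_count(bad, 5)
        with pytest.raises(InvalidParameterError):
            burnside_count(2, bad)


class TestEnumeration:
    def test_two_types_five_dimers(self):
        census = enumerate_orbits(2, 5)
        assert census.total_distinct == 120
        assert len(census.representatives) == 120
        assert sum(census.by_composition.values()) == 120

    def test_single_type_single_orbit(self):
        census = enumerate_orbits(1, 5)
        assert census.total_distinct == 1
        assert census.representatives[0].labels == (0,) * 10

    def test_orbit_sizes_partition_state_space(self):
        sizes = orbit_sizes(2, 5)
        assert sum(sizes) == 2**10
        assert len(sizes) == 120

    @pytest.mark.parametrize("m,d", [(2, 2), (2, 4), (3, 3), (4, 4)])
    def test_enumeration_agrees_with_burnside(self, m, d):
        assert enumerate_orbits(m, d, representatives=False).total_distinct == burnside_count(m, d)

    def test_guard_refuses_huge_state_space(self):
        with pytest.raises(InvalidParameterError, match="guard"):
            enumerate_orbits(5, 5)  # 5**10 labelings

    def test_representatives_are_canonical_and_distinct(self):
        census = enumerate_orbits(2, 3)
        group = build_symmetry_group(3)
        seen = set()
        for rep in census.representatives:
            assert canonical_form(rep, group).labels == rep.labels
            seen.add(rep.labels)
        assert len(seen) == census.total_distinct


class TestCompositionCensus:
    def test_published_breakdown(self):
        census = composition_census(5)
        combined = census.combined_ratios()
        assert combined[(0, 10)] == 2  # the two homodecamers
        assert combined[(1, 9)] == 2
        assert combined[(2, 8)] == 14
        assert combined[(3, 7)] == 24
        assert combined[(4, 6)] == 52
        assert combined[(5, 5)] == 26
        assert census.by_composition[0] == 1
        assert census.by_composition[5] == 26

    @pytest.mark.parametrize("d", [1, 2, 3, 4, 5, 6])
    def test_relabeling_symmetry_and_total(self, d):
        census = composition_census(d)
        for k in range(2 * d + 1):
            assert census.by_composition.get(k, 0) == census.by_composition.get(2 * d - k, 0)
        assert sum(census.by_composition.values()) == burnside_count(2, d)


class TestCanonicalForm:
    def test_invariant_under_group_action(self, rng):
        group = build_symmetry_group(5)
        for _ in range(50):
            labels = tuple(int(x) for x in rng.integers(0, 3, size=10))
            config = DecamerConfiguration(labels)
            canon = canonical_form(config, group)
            for perm in group.permutations:
                moved = DecamerConfiguration(group.apply(perm, labels))
                assert canonical_form(moved, group).labels == canon.labels

    def test_label_length_validation(self):
        with pytest.raises(InvalidParameterError):
            DecamerConfiguration((0, 1, 0), d=5)
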