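"""Shared fixtures: tiny hand-built systems and seeded clusters."""

import pytest

from fragmbe.clusters import generate_cluster
from fragmbe.contract import DecomposedEnergy, EnergyBackend, LevelTag, RegionSpec
from fragmbe.molsys import FragmentedSystem, Site
from fragmbe.surrogate import PolarizableBackend


@pytest.fixture
def backend():
    return PolarizableBackend()


@pytest.fixture
def two_unit_charges():
    """Two unit point charges 1 Bohr apart, one fragment each (no α, B, C)."""
    return FragmentedSystem(
        sites=(
            Site("X", (0.0, 0.0, 0.0), charge=1.0),
            Site("X", (1.0, 0.0, 0.0), charge=1.0),
        ),
        fragment_of=(0, 1),
        fragment_labels=("A", "B"),
    )


@pytest.fixture
def charge_and_polarizable():
    """Unit charge at origin; neutral polarizable site (α = 1) at 2 Bohr."""
    return FragmentedSystem(
        sites=(
            Site("X", (0.0, 0.0, 0.0), charge=1.0),
            Site("Y", (2.0, 0.0, 0.0), polarizability=1.0),
        ),
        fragment_of=(0, 1),
        fragment_labels=("A", "B"),
    )


@pytest.fixture
def cluster5():
    """Seeded polarizable 5-fragment pseudo-water cluster."""
    return generate_cluster(5, seed=3)


def make_nonpolarizable(system: FragmentedSystem) -> FragmentedSystem:
    """Copy of a system with all polarizabilities zeroed (strictly pairwise
    additive under the classical backend)."""
    from dataclasses import replace

    return replace(
        system, sites=tuple(replace(s, polarizability=0.0) for s in system.sites)
    )


class TableBackend(EnergyBackend):
    """Test backend serving prescribed subset energies.

    ``energies`` maps frozensets of fragment indices (the HIGH, non-ABSENT
    set of the region) to total energies; the decomposition puts everything
    in the first fragment's intra entry (exact by construction).
    """

    correlation_channel = None

    def __init__(self, energies):
        self.energies = {frozenset(k): v for k, v in energies.items()}
        self.calls = 0

    def compute(self, system, region: RegionSpec) -> DecomposedEnergy:
        self.calls += 1
        present = frozenset(
            f for f, l in region.level_of.items() if l.tag is not LevelTag.ABSENT
        )
        e = self.energies[present]
        first = min(present)
        intra = {f: (e if f == first else 0.0) for f in sorted(present)}
        inter = {
            (x, y): 0.0
            for i, x in enumerate(sorted(present))
            for y in sorted(present)[i + 1 :]
        }
        return DecomposedEnergy(total=e, intra=intra, inter=inter)


def vacuum_dimer_decompositions(system, backend):
    """All n(n-1)/2 vacuum dimer decompositions of a system."""
    from fragmbe.mbe import vacuum_region

    n = system.n_fragments
    return {
        (x, y): backend.compute(system, vacuum_region(frozenset({x, y}), n))
        for x in range(n)
        for y in range(x + 1, n)
    }
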