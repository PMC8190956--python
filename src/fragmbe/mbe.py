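"""General-order many-body expansion of a cluster energy.

The supersystem energy of N fragments is rewritten exactly as

    E_tot = Σ_X E_X + Σ_{X<Y} ΔE_XY + Σ_{X<Y<Z} ΔE_XYZ + ...

where the increment Δε(S) of a fragment subset S is the part of E(S) not
attributable to any proper sub-subset, obtained here by inclusion–exclusion
(Möbius inversion):

    Δε(S) = Σ_{T ⊆ S} (−1)^{|S|−|T|} E(T),   E(∅) = 0.

Truncating at order k keeps subsets of size ≤ k.  The binding energy is
ΔE = E(full) − Σ_X E_X; its two-body part ΔE² is the sum of pair increments;
the cooperativity ΔE_coop = ΔE − ΔE² collects everything of order ≥ 3.

All accumulation is in Hartree; kcal/mol appears only at the reporting
boundary (:class:`BindingSummary`).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

from .contract import (
    ABSENT,
    HIGH,
    BackendError,
    EnergyBackend,
    RegionSpec,
    extract_subsystem,
)
from .molsys import FragmentedSystem, ValidationError
from .units import HARTREE_TO_KCAL

_log = logging.getLogger(__name__)


class EvaluationCache:
    """Memo store for backend evaluations, keyed by region fingerprint.

    Embedded and vacuum evaluations of the same subset carry different
    fingerprints, so they never collide.  Shared between the MBE engine and
    the embedding drivers so monomer energies are computed once.
    """

    def __init__(self):
        self._store: dict[tuple, "DecomposedEnergy"] = {}
        self.n_evaluations = 0

    def decomposition(
        self,
        system: FragmentedSystem,
        backend: EnergyBackend,
        region: RegionSpec,
        subset: frozenset[int] | None = None,
    ):
        """Memoized ``backend.compute``; ``subset`` only labels errors."""
        key = (system.fingerprint(), region.fingerprint())
        if key not in self._store:
            t0 = time.perf_counter()
            try:
                self._store[key] = backend.compute(system, region)
            except BackendError as exc:
                what = f"subset {sorted(subset)}" if subset is not None else "region"
                raise BackendError(f"backend failed on {what}: {exc}", region) from exc
            self.n_evaluations += 1
            _log.debug(
                "evaluation %d: subset=%s region=%s energy=%.12f Eh wall=%.3f ms",
                self.n_evaluations,
                sorted(subset) if subset is not None else "all",
                region.fingerprint(),
                self._store[key].total,
                1e3 * (time.perf_counter() - t0),
            )
        return self._store[key]

    def energy(
        self,
        system: FragmentedSystem,
        backend: EnergyBackend,
        subset: frozenset[int],
        region: RegionSpec,
    ) -> float:
        """Subsystem-restricted energy of ``subset`` under ``region``."""
        d = self.decomposition(system, backend, region, subset)
        _, _, e = extract_subsystem(d, subset)
        return e


def vacuum_region(subset: frozenset[int], n_fragments: int) -> RegionSpec:
    """Subset fragments HIGH, everything else removed."""
    return RegionSpec(
        {f: (HIGH if f in subset else ABSENT) for f in range(n_fragments)}
    )


def embedded_region(
    subset: frozenset[int], template: RegionSpec
) -> RegionSpec:
    """Subset fragments HIGH, everything else at the template's level."""
    return RegionSpec(
        {
            f: (HIGH if f in subset else template.level(f))
            for f in template.level_of
        }
    )


@dataclass
class MBETermSet:
    """Memoized subset energies and increments (Hartree) up to ``max_order``."""

    n_fragments: int
    max_order: int
    subset_energy: dict[frozenset, float] = field(default_factory=dict)
    increment: dict[frozenset, float] = field(default_factory=dict)
    n_evaluations: int = 0

    def order_sum(self, k: int) -> float:
        """Sum of all increments of order exactly k."""
        return sum(v for s, v in self.increment.items() if len(s) == k)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "n_fragments": self.n_fragments,
                "max_order": self.max_order,
                "n_evaluations": self.n_evaluations,
                "subset_energy": {
                    json.dumps(sorted(s)): v for s, v in sorted(
                        self.subset_energy.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                    )
                },
                "increment": {
                    json.dumps(sorted(s)): v for s, v in sorted(
                        self.increment.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                    )
                },
            },
            **kw,
        )


def build_mbe(
    system: FragmentedSystem,
    backend: EnergyBackend,
    order: int,
    region_template: RegionSpec | None = None,
    cache: EvaluationCache | None = None,
) -> MBETermSet:
    """Evaluate all subset energies up to ``order`` and their increments.

    ``region_template=None`` means vacuum subsets (non-subset fragments
    ABSENT); a template puts non-subset fragments at the template's level and
    restricts each evaluation to the subset (embedded subset energies).
    The full-fragment set is always evaluated when ``order == n_fragments``.
    Evaluation order is deterministic: subsets by size, then lexicographic.
    """
    n = system.n_fragments
    if not 1 <= order <= n:
        raise ValidationError(f"MBE order must be in 1..{n}, got {order}")
    cache = cache or EvaluationCache()
    terms = MBETermSet(n_fragments=n, max_order=order)

    n0 = cache.n_evaluations
    for k in range(1, order + 1):
        for subset in combinations(range(n), k):
            fs = frozenset(subset)
            region = (
                vacuum_region(fs, n)
                if region_template is None
                else embedded_region(fs, region_template)
            )
            terms.subset_energy[fs] = cache.energy(system, backend, fs, region)
    terms.n_evaluations = cache.n_evaluations - n0

    # inclusion–exclusion increments
    for fs, _ in sorted(terms.subset_energy.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        inc = 0.0
        for k in range(1, len(fs) + 1):
            sign = (-1) ** (len(fs) - k)
            inc += sign * sum(
                terms.subset_energy[frozenset(t)] for t in combinations(sorted(fs), k)
            )
        terms.increment[fs] = inc
    return terms


def truncated_total(terms: MBETermSet, k: int) -> float:
    """Σ of all increments of order ≤ k (Hartree)."""
    if k > terms.max_order:
        raise ValidationError(f"k={k} exceeds max_order={terms.max_order}")
    return sum(terms.order_sum(j) for j in range(1, k + 1))


@dataclass(frozen=True)
class BindingSummary:
    """Binding energy and its many-body breakdown, in kcal/mol."""

    delta_E: float        # E(full) − Σ E_X
    delta_E2: float       # sum of pair increments
    delta_E_coop: float   # delta_E − delta_E2: everything of order ≥ 3
    per_order: Mapping[int, float]


def binding_energy(
    terms: MBETermSet, monomer_energies: Mapping[int, float]
) -> BindingSummary:
    """Assemble the binding summary from a complete term set.

    ``monomer_energies`` are the isolated-monomer energies (Hartree); under
    the rigid-fragment surrogate convention these are 0.
    """
    n = terms.n_fragments
    missing = set(range(n)) - set(monomer_energies)
    if missing:
        raise ValidationError(f"missing monomer energies for fragments {sorted(missing)}")
    full = frozenset(range(n))
    if full not in terms.subset_energy:
        raise ValidationError(
            "full-set energy not available; rebuild the MBE with order = n_fragments"
        )
    e_monomers = sum(monomer_energies[f] for f in range(n))
    dE = (terms.subset_energy[full] - e_monomers) * HARTREE_TO_KCAL
    dE2 = terms.order_sum(2) * HARTREE_TO_KCAL
    per_order = {
        1: (terms.order_sum(1) - e_monomers) * HARTREE_TO_KCAL,
    }
    for k in range(2, terms.max_order + 1):
        per_order[k] = terms.order_sum(k) * HARTREE_TO_KCAL
    return BindingSummary(
        delta_E=dE, delta_E2=dE2, delta_E_coop=dE - dE2, per_order=per_order
    )
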