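"""Embedded two-body drivers: limits, discard correctness, assembly identities."""

import pytest

from fragmbe.clusters import generate_cluster
from fragmbe.contract import (
    DecomposedEnergy,
    LevelTag,
    RegionSpec,
)
from fragmbe.embedding import (
    EmbeddingSpec,
    Scheme,
    binding_energy_embedded,
    common_reference_total,
    run_embedded_mbe,
    total_energy,
)
from fragmbe.mbe import binding_energy, build_mbe, truncated_total
from fragmbe.molsys import ValidationError
from fragmbe.surrogate import PolarizableBackend
from fragmbe.units import HARTREE_TO_KCAL

from conftest import make_nonpolarizable


def _exact(system, backend):
    return backend.compute(system, RegionSpec.uniform(system.n_fragments)).total


class TestEmbeddingLimits:
    def test_zero_alpha_equals_vacuum_terms_bitwise(self):
        system = generate_cluster(4, seed=41)
        backend = PolarizableBackend()
        ee0 = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.EE1, alpha=0.0))
        vac = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.NONE))
        assert ee0.monomer_vacuum == vac.monomer_vacuum
        assert ee0.monomer_embedded_intra == vac.monomer_embedded_intra
        assert ee0.dimer_embedded_intra == vac.dimer_embedded_intra
        assert ee0.dimer_embedded_inter == vac.dimer_embedded_inter

    def test_zero_alpha_reproduces_two_body_mbe(self):
        system = generate_cluster(4, seed=41)
        backend = PolarizableBackend()
        ee0 = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.EE1, alpha=0.0))
        terms = build_mbe(system, backend, order=4)
        summary = binding_energy(terms, {f: 0.0 for f in range(4)})
        assert binding_energy_embedded(ee0) == pytest.approx(summary.delta_E2, abs=1e-9)

    def test_nonpolarizable_embedding_is_inert(self):
        system = make_nonpolarizable(generate_cluster(4, seed=42))
        backend = PolarizableBackend()
        for spec in (
            EmbeddingSpec(scheme=Scheme.HF_LIKE),
            EmbeddingSpec(scheme=Scheme.EE2, alpha=1.25),
        ):
            terms = run_embedded_mbe(system, backend, spec)
            assert all(v == pytest.approx(0.0, abs=1e-12) for v in terms.elprep1.values())
            assert all(v == pytest.approx(0.0, abs=1e-12) for v in terms.elprep2.values())
            vac = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.NONE))
            for p, v in vac.dimer_embedded_inter.items():
                assert terms.dimer_embedded_inter[p] == pytest.approx(v, abs=1e-12)
            # a pairwise-additive system is reproduced exactly by the 2-body sum
            assert total_energy(terms) == pytest.approx(_exact(system, backend), abs=1e-10)

    def test_embedded_pair_interactions_closer_to_supersystem(self):
        system = generate_cluster(4, seed=43)
        backend = PolarizableBackend()
        full = backend.compute(system, RegionSpec.uniform(4))
        hf = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        vac = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.NONE))
        better, total_pairs = 0, 0
        for p, ref in full.inter.items():
            total_pairs += 1
            if abs(hf.dimer_embedded_inter[p] - ref) <= abs(vac.dimer_embedded_inter[p] - ref):
                better += 1
        assert better == total_pairs


class TestTotalEnergy:
    def test_two_fragments_equal_vacuum_dimer(self):
        system = generate_cluster(2, seed=44)
        backend = PolarizableBackend()
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        assert total_energy(terms) == pytest.approx(_exact(system, backend), abs=1e-12)

    @pytest.mark.parametrize("seed", [45, 46])
    def test_embedding_beats_vacuum_two_body(self, seed):
        system = generate_cluster(5, seed=seed)
        backend = PolarizableBackend()
        exact = _exact(system, backend)
        hf = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        terms = build_mbe(system, backend, order=2)
        e2 = truncated_total(terms, 2)
        assert abs(total_energy(hf) - exact) < abs(e2 - exact)

    def test_binding_total_relation(self):
        system = generate_cluster(4, seed=47)
        backend = PolarizableBackend()
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.EE1, alpha=1.2))
        lhs = binding_energy_embedded(terms) / HARTREE_TO_KCAL
        rhs = total_energy(terms) - sum(terms.monomer_vacuum.values())
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_missing_pair_rejected(self):
        system = generate_cluster(3, seed=48)
        backend = PolarizableBackend()
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        del terms.dimer_embedded_inter[(0, 1)]
        with pytest.raises(ValidationError, match="pair"):
            total_energy(terms)


class TestDiscardCorrectness:
    def test_environment_terms_never_reach_totals(self):
        """Poison every environment intra/inter entry; driver output must be
        unchanged — the discard step is explicit, not backend magic."""

        class PoisonedBackend(PolarizableBackend):
            def compute(self, system, region):
                d = super().compute(system, region)
                high = {
                    f for f, l in region.level_of.items() if l.tag is LevelTag.HIGH
                }
                intra = {
                    f: (v if f in high else v + 1000.0) for f, v in d.intra.items()
                }
                inter = {
                    p: (v if p[0] in high and p[1] in high else v - 500.0)
                    for p, v in d.inter.items()
                }
                return DecomposedEnergy(
                    total=sum(intra.values()) + sum(inter.values()),
                    intra=intra,
                    inter=inter,
                    channels=None,
                    reference_energy=d.reference_energy,
                    correlation_part=d.correlation_part,
                )

        system = generate_cluster(4, seed=49)
        spec = EmbeddingSpec(scheme=Scheme.HF_LIKE)
        clean = run_embedded_mbe(system, PolarizableBackend(), spec)
        poisoned = run_embedded_mbe(system, PoisonedBackend(), spec)
        assert total_energy(poisoned) == pytest.approx(total_energy(clean), abs=1e-12)
        assert poisoned.dimer_embedded_inter == clean.dimer_embedded_inter


class TestChargeSchemes:
    def test_ee1_and_ee2_coincide_for_fixed_site_charges(self):
        system = generate_cluster(4, seed=50)
        backend = PolarizableBackend()
        e1 = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.EE1, alpha=1.16))
        e2 = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.EE2, alpha=1.16))
        assert e1.dimer_embedded_inter == e2.dimer_embedded_inter
        assert total_energy(e1) == total_energy(e2)

    def test_alpha_sweep_alpha0_matches_vacuum(self):
        system = generate_cluster(3, seed=51)
        backend = PolarizableBackend()
        results = {
            alpha: binding_energy_embedded(
                run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.EE2, alpha=alpha))
            )
            for alpha in (0.0, 0.5, 1.0)
        }
        terms = build_mbe(system, backend, order=3)
        dE2 = binding_energy(terms, {f: 0.0 for f in range(3)}).delta_E2
        assert results[0.0] == pytest.approx(dE2, abs=1e-9)
        assert len(set(results.values())) == 3  # sweep actually changes things

    def test_unknown_charge_source_rejected(self):
        system = generate_cluster(3, seed=51)
        from fragmbe.contract import BackendError

        with pytest.raises(BackendError, match="charges"):
            run_embedded_mbe(
                system,
                PolarizableBackend(),
                EmbeddingSpec(scheme=Scheme.EE1, alpha=1.0, charge_source="NPA"),
            )

    def test_spec_validation(self):
        with pytest.raises(ValidationError, match="alpha"):
            EmbeddingSpec(scheme=Scheme.EE1)
        with pytest.raises(ValidationError, match="alpha"):
            EmbeddingSpec(scheme=Scheme.HF_LIKE, alpha=1.0)


class TestCommonReference:
    def test_two_fragments_degenerate_case(self):
        system = generate_cluster(2, seed=52)
        backend = PolarizableBackend()
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        d = backend.compute(system, RegionSpec.uniform(2))
        e_ref = d.reference_energy
        shared_route = common_reference_total(terms, e_ref)
        assert shared_route == pytest.approx(e_ref + sum(terms.dimer_corr.values()), abs=1e-14)
        assert shared_route == pytest.approx(total_energy(terms), abs=1e-10)

    @pytest.mark.parametrize("n,seed", [(4, 53), (5, 54)])
    def test_shared_reference_route_equals_assembled_route(self, n, seed):
        system = generate_cluster(n, seed=seed)
        backend = PolarizableBackend()
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        # reference = mean-field (dispersion-free) full-system energy
        e_ref = backend.compute(system, RegionSpec.uniform(n)).reference_energy
        assert common_reference_total(terms, e_ref) == pytest.approx(
            total_energy(terms), abs=1e-9
        )

    def test_zero_correlation_parts_give_reference(self):
        system = make_nonpolarizable(generate_cluster(3, seed=55))
        backend = PolarizableBackend()
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        zeros_m = {x: 0.0 for x in range(3)}
        zeros_d = {p: 0.0 for p in terms.dimer_embedded_inter}
        assert common_reference_total(terms, -1.25, zeros_m, zeros_d) == -1.25

    def test_point_charge_environment_rejected(self):
        system = generate_cluster(3, seed=56)
        terms = run_embedded_mbe(
            system, PolarizableBackend(), EmbeddingSpec(scheme=Scheme.EE1, alpha=1.0)
        )
        with pytest.raises(ValidationError, match="mean-field"):
            common_reference_total(terms, 0.0)

    def test_mismatched_basis_fingerprint_rejected(self):
        from fragmbe.contract import Level, LevelTag

        system = generate_cluster(3, seed=56)
        spec = EmbeddingSpec(
            scheme=Scheme.HF_LIKE,
            env_level=Level(LevelTag.LOW, basis_tag="aDZ"),
            subsystem_basis="aTZ",
        )
        terms = run_embedded_mbe(system, PolarizableBackend(), spec)
        with pytest.raises(ValidationError, match="mismatched reference"):
            common_reference_total(terms, 0.0)
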