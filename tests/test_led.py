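"""Interaction maps: conservation identities and comparison statistics."""

import numpy as np
import pytest

from fragmbe.clusters import generate_cluster
from fragmbe.contract import RegionSpec
from fragmbe.led import (
    LEDMap,
    MapFlavor,
    led_channels,
    led_cooperativity,
    led_embedded,
    led_full,
    led_two_body,
    mae,
    max_abs_dev,
    round_half_up,
)
from fragmbe.mbe import binding_energy, build_mbe
from fragmbe.molsys import FragmentedSystem, Site, ValidationError
from fragmbe.surrogate import PolarizableBackend
from fragmbe.units import HARTREE_TO_KCAL

from conftest import make_nonpolarizable, vacuum_dimer_decompositions


def _maps(system, backend):
    n = system.n_fragments
    mono = {f: 0.0 for f in range(n)}
    full = led_full(backend.compute(system, RegionSpec.uniform(n)), mono)
    two = led_two_body(vacuum_dimer_decompositions(system, backend), mono)
    return full, two, led_cooperativity(full, two)


class TestLedFull:
    def test_nonpolarizable_diagonal_is_zero(self, backend):
        system = make_nonpolarizable(generate_cluster(4, seed=61))
        m = led_full(backend.compute(system, RegionSpec.uniform(4)), {f: 0.0 for f in range(4)})
        assert np.allclose(np.diag(m.matrix), 0.0)

    def test_total_is_binding_energy(self, backend):
        system = generate_cluster(4, seed=62)
        full, _, _ = _maps(system, backend)
        terms = build_mbe(system, backend, order=4)
        s = binding_energy(terms, {f: 0.0 for f in range(4)})
        assert full.total == pytest.approx(s.delta_E, abs=1e-9)

    def test_offdiagonals_match_site_pair_sums(self, backend):
        """Three bare charges, one per fragment: each off-diagonal element
        must equal the hand-computed Coulomb term of that pair."""
        system = FragmentedSystem(
            sites=(
                Site("X", (0.0, 0.0, 0.0), charge=1.0),
                Site("X", (2.0, 0.0, 0.0), charge=-0.5),
                Site("X", (0.0, 3.0, 0.0), charge=0.25),
            ),
            fragment_of=(0, 1, 2),
            fragment_labels=("A", "B", "C"),
        )
        m = led_full(
            PolarizableBackend().compute(system, RegionSpec.uniform(3)),
            {0: 0.0, 1: 0.0, 2: 0.0},
        )
        assert m.matrix[0, 1] == pytest.approx(1.0 * -0.5 / 2.0 * HARTREE_TO_KCAL)
        assert m.matrix[0, 2] == pytest.approx(1.0 * 0.25 / 3.0 * HARTREE_TO_KCAL)
        r12 = np.sqrt(2.0**2 + 3.0**2)
        assert m.matrix[1, 2] == pytest.approx(-0.5 * 0.25 / r12 * HARTREE_TO_KCAL)

    def test_missing_monomer_energy_rejected(self, backend):
        system = generate_cluster(2, seed=63)
        d = backend.compute(system, RegionSpec.uniform(2))
        with pytest.raises(ValidationError, match="monomer"):
            led_full(d, {0: 0.0})


class TestLedTwoBody:
    def test_two_fragments_equals_full(self, backend):
        system = generate_cluster(2, seed=64)
        full, two, _ = _maps(system, backend)
        assert np.allclose(full.matrix, two.matrix, atol=1e-12)

    def test_additive_system_two_body_is_exact(self, backend):
        system = make_nonpolarizable(generate_cluster(4, seed=65))
        full, two, coop = _maps(system, backend)
        assert np.allclose(full.matrix, two.matrix, atol=1e-10)
        assert np.allclose(coop.matrix, 0.0, atol=1e-10)

    def test_total_is_two_body_binding(self, backend):
        system = generate_cluster(3, seed=66)
        _, two, _ = _maps(system, backend)
        terms = build_mbe(system, backend, order=3)
        s = binding_energy(terms, {f: 0.0 for f in range(3)})
        assert two.total == pytest.approx(s.delta_E2, abs=1e-9)

    def test_missing_dimer_named(self, backend):
        system = generate_cluster(3, seed=66)
        dimers = vacuum_dimer_decompositions(system, backend)
        del dimers[(0, 2)]
        with pytest.raises(ValidationError, match=r"\(0, 2\)"):
            led_two_body(dimers, {f: 0.0 for f in range(3)})


class TestCooperativity:
    def test_dimer_cooperativity_map_is_zero(self, backend):
        system = generate_cluster(2, seed=67)
        _, _, coop = _maps(system, backend)
        assert np.allclose(coop.matrix, 0.0, atol=1e-12)

    def test_total_matches_independent_coop(self, backend):
        system = generate_cluster(4, seed=68)
        _, _, coop = _maps(system, backend)
        terms = build_mbe(system, backend, order=4)
        s = binding_energy(terms, {f: 0.0 for f in range(4)})
        assert coop.total == pytest.approx(s.delta_E_coop, abs=1e-9)

    def test_label_mismatch_rejected(self):
        a = LEDMap(("A", "B"), np.zeros((2, 2)), MapFlavor.FULL)
        b = LEDMap(("A", "C"), np.zeros((2, 2)), MapFlavor.TWO_BODY)
        with pytest.raises(ValidationError, match="label"):
            led_cooperativity(a, b)


class TestEmbeddedMap:
    def test_embedded_map_total_is_embedded_binding(self, backend):
        from fragmbe.embedding import (
            EmbeddingSpec,
            Scheme,
            binding_energy_embedded,
            run_embedded_mbe,
        )

        system = generate_cluster(4, seed=69)
        terms = run_embedded_mbe(system, backend, EmbeddingSpec(scheme=Scheme.HF_LIKE))
        m = led_embedded(terms)
        assert m.flavor is MapFlavor.EMBEDDED
        assert m.total == pytest.approx(binding_energy_embedded(terms), abs=1e-9)


class TestChannels:
    def test_channel_maps_sum_to_main_map(self, backend):
        system = generate_cluster(3, seed=70)
        d = backend.compute(system, RegionSpec.uniform(3))
        main = led_full(d, {f: 0.0 for f in range(3)})
        chans = led_channels(d)
        stacked = sum(m.matrix for m in chans.values())
        assert np.allclose(stacked, main.matrix, atol=1e-9)


class TestStatistics:
    def test_mae_hand_arithmetic(self):
        assert mae([(0, 1), (2, 0)]) == pytest.approx(1.5)

    def test_mae_identical_columns(self):
        assert mae([(1.0, 1.0), (-2.0, -2.0)]) == 0.0

    def test_mae_empty_rejected(self):
        with pytest.raises(ValidationError):
            mae([])

    def test_max_abs_dev(self):
        assert max_abs_dev([(0.0, -3.0)]) == 3.0
        assert max_abs_dev([(1.0, 1.0)]) == 0.0

    def test_half_up_rounding(self):
        # banker's rounding would give 0.32; report parity needs 0.33
        assert round_half_up(0.325, 2) == 0.33
        assert round_half_up(0.3267, 1) == 0.3

    def test_map_serialization_roundtrip(self, backend, tmp_path):
        import json

        system = generate_cluster(3, seed=71)
        m = led_full(
            backend.compute(system, RegionSpec.uniform(3)),
            {f: 0.0 for f in range(3)},
            labels=system.fragment_labels,
        )
        payload = json.loads(m.to_json())
        assert payload["total"] == pytest.approx(m.total)
        out = tmp_path / "map.csv"
        m.to_csv(out)
        text = out.read_text()
        assert "TOTAL" in text and "W0" in text
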