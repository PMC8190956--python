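"""Seeded generator of rigid pseudo-water clusters.

Emulates compact clusters of small rigid polar molecules: each fragment is a
3-site "pseudo-water" (one O-like site carrying negative charge,
polarizability and the repulsion/dispersion coefficients; two H-like sites
with positive charge and a small polarizability) with the internal geometry
of a water monomer.  Fragments are placed with uniformly random centers and
orientations inside a cubic box, rejecting placements that bring any two
sites of different fragments closer than ``min_sep``.  Deterministic per
seed; same seed → bitwise-identical geometry.
"""

from __future__ import annotations

import numpy as np

from .molsys import DEFAULT_PARAMETER_TABLE, FragmentedSystem, Site
from .units import ANGSTROM_TO_BOHR


class PlacementError(RuntimeError):
    """Could not place all fragments; try a larger box or smaller min_sep."""


#: Rigid pseudo-water internal geometry (Bohr): O at origin, H's in the
#: xz-plane at the experimental water monomer geometry.
_R_OH = 0.9572 * ANGSTROM_TO_BOHR
_HOH = np.deg2rad(104.52)
PSEUDO_WATER_TEMPLATE: tuple[tuple[str, np.ndarray], ...] = (
    ("O", np.zeros(3)),
    ("H", _R_OH * np.array([np.sin(_HOH / 2), 0.0, np.cos(_HOH / 2)])),
    ("H", _R_OH * np.array([-np.sin(_HOH / 2), 0.0, np.cos(_HOH / 2)])),
)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_cluster(
    n_fragments: int,
    seed: int,
    box: float = 12.0,
    min_sep: float = 4.0,
    parameter_table=None,
    max_attempts: int = 10_000,
) -> FragmentedSystem:
    """Place ``n_fragments`` rigid pseudo-water fragments in a cubic box.

    Parameters
    ----------
    box
        Edge length of the placement cube for fragment centers, Bohr.
    min_sep
        Minimum allowed distance between sites of different fragments, Bohr.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if min_sep <= 0:
        raise ValueError("min_sep must be > 0")
    table = parameter_table if parameter_table is not None else DEFAULT_PARAMETER_TABLE
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []  # (3,3) site coordinates per fragment
    for _ in range(n_fragments):
        for attempt in range(max_attempts):
            center = rng.uniform(-box / 2, box / 2, size=3)
            R = _random_rotation(rng)
            coords = np.array([center + R @ local for _, local in PSEUDO_WATER_TEMPLATE])
            ok = all(
                np.min(
                    np.linalg.norm(coords[:, None, :] - other[None, :, :], axis=-1)
                )
                >= min_sep
                for other in placed
            )
            if ok:
                placed.append(coords)
                break
        else:
            raise PlacementError(
                f"failed to place fragment {len(placed)} after {max_attempts} "
                f"attempts; try a larger box (current {box} Bohr)"
            )

    sites, frag_of = [], []
    for f, coords in enumerate(placed):
        for (el, _), xyz in zip(PSEUDO_WATER_TEMPLATE, coords):
            p = table.get(el, {})
            sites.append(
                Site(
                    element=el,
                    position=tuple(xyz),
                    charge=p.get("charge", 0.0),
                    polarizability=p.get("polarizability", 0.0),
                    repulsion_coeff=p.get("repulsion_coeff", 0.0),
                    dispersion_coeff=p.get("dispersion_coeff", 0.0),
                )
            )
            frag_of.append(f)
    return FragmentedSystem(
        sites=tuple(sites),
        fragment_of=tuple(frag_of),
        fragment_labels=tuple(f"W{f}" for f in range(n_fragments)),
    )
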