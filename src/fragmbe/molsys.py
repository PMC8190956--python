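"""Molecular systems, fragmentation, point-charge sets, and file I/O.

A :class:`FragmentedSystem` is the universe every calculation runs on: an
ordered list of sites (atoms, or classical interaction sites) grouped into
named fragments.  Coordinates are stored in Bohr; XYZ I/O is in Ångström.

Sites carry classical parameters (charge, polarizability, repulsion and
dispersion coefficients) used by the built-in polarizable backend; quantum
backends are free to ignore them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM


class ValidationError(ValueError):
    """Invalid fragmentation, region, or argument."""


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


#: Default classical parameters for "pseudo-water" fragments.
#:
#: Charges/polarizabilities give a polar, polarizable 3-site fragment
#: (net neutral).  Repulsion/dispersion live on the heavy site only and are
#: chosen so that the O···O pair potential B/r^12 − C/r^6 has its minimum at
#: r_m = 5.7 Bohr with well depth eps = 2e-3 Hartree (B = eps·r_m^12,
#: C = 2·eps·r_m^6).  Override per element via ``parameter_table``.
_RM = 5.7
_EPS = 2.0e-3
DEFAULT_PARAMETER_TABLE: dict[str, dict[str, float]] = {
    "O": {
        "charge": -0.8,
        "polarizability": 1.2,
        "repulsion_coeff": _EPS * _RM**12,
        "dispersion_coeff": 2.0 * _EPS * _RM**6,
    },
    "H": {
        "charge": +0.4,
        "polarizability": 0.3,
        "repulsion_coeff": 0.0,
        "dispersion_coeff": 0.0,
    },
}


@dataclass(frozen=True)
class Site:
    """One interaction site: element label, position (Bohr), classical params."""

    element: str
    position: tuple[float, float, float]
    charge: float = 0.0
    polarizability: float = 0.0
    repulsion_coeff: float = 0.0
    dispersion_coeff: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"non-finite position for site {self.element}")
        if self.polarizability < 0:
            raise ValidationError("polarizability must be >= 0")
        if self.repulsion_coeff < 0 or self.dispersion_coeff < 0:
            raise ValidationError("repulsion/dispersion coefficients must be >= 0")


@dataclass(frozen=True)
class PointCharge:
    """A bare point charge (position in Bohr)."""

    position: tuple[float, float, float]
    charge: float
    source_fragment: int | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValidationError("non-finite point-charge position")


@dataclass(frozen=True)
class FragmentedSystem:
    """Sites partitioned into contiguously indexed, named fragments.

    ``fragment_of[i]`` is the fragment index of site ``i``.  Site order is
    identity: systems are never re-centered or rotated, so decomposition
    bookkeeping can rely on stable indices.
    """

    sites: tuple[Site, ...]
    fragment_of: tuple[int, ...]
    fragment_labels: tuple[str, ...]
    clash_distance: float = field(default=0.5, compare=False)

    def __post_init__(self):
        n = len(self.sites)
        if len(self.fragment_of) != n:
            raise ValidationError("fragment_of must assign every site exactly once")
        nfrag = len(self.fragment_labels)
        seen = set(self.fragment_of)
        if seen != set(range(nfrag)):
            raise ValidationError(
                f"fragment indices must be contiguous 0..{nfrag - 1}; got {sorted(seen)}"
            )
        pos = self.positions
        if n > 1 and self.clash_distance > 0:
            d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.min(d2) < self.clash_distance**2:
                i, j = np.unravel_index(np.argmin(d2), d2.shape)
                raise ValidationError(
                    f"sites {i} and {j} are {np.sqrt(d2[i, j]):.3f} Bohr apart "
                    f"(< clash distance {self.clash_distance} Bohr)"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_labels)

    @property
    def positions(self) -> np.ndarray:
        """(n_sites, 3) array of positions in Bohr."""
        return np.array([s.position for s in self.sites], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites], dtype=float)

    def fingerprint(self) -> int:
        """Cheap identity hash over geometry, charges and fragmentation
        (used in memoization keys so distinct systems never collide)."""
        return hash(
            (
                self.positions.tobytes(),
                self.charges.tobytes(),
                self.fragment_of,
                tuple(s.element for s in self.sites),
            )
        )

    def fragments(self) -> list[list[int]]:
        """Site indices of each fragment, in site order."""
        out: list[list[int]] = [[] for _ in range(self.n_fragments)]
        for i, f in enumerate(self.fragment_of):
            out[f].append(i)
        return out

    def sites_of(self, fragment: int) -> list[int]:
        if not 0 <= fragment < self.n_fragments:
            raise ValidationError(f"unknown fragment index {fragment}")
        return [i for i, f in enumerate(self.fragment_of) if f == fragment]


def parse_fragment_ranges(text: str, n_sites: int) -> list[int]:
    """Parse a range spec like ``"0-2,3-5,6-8"`` into a per-site fragment map.

    Each comma-separated token is an inclusive site-index range (or single
    index) defining one fragment, in order.  The ranges must cover all sites
    exactly once.
    """
    assignment = [-1] * n_sites
    for frag, token in enumerate(t.strip() for t in text.split(",")):
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", token)
        if not m:
            raise ValidationError(f"bad fragment range token {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo or hi >= n_sites:
            raise ValidationError(f"fragment range {token!r} out of bounds (n_sites={n_sites})")
        for i in range(lo, hi + 1):
            if assignment[i] != -1:
                raise ValidationError(f"site {i} assigned to more than one fragment")
            assignment[i] = frag
    if -1 in assignment:
        missing = [i for i, a in enumerate(assignment) if a == -1]
        raise ValidationError(f"fragment map incomplete: sites {missing} unassigned")
    return assignment


def read_fragment_labels(path: str | Path, n_sites: int) -> tuple[list[int], list[str]]:
    """Read a sidecar label file: one fragment label per atom line."""
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(labels) != n_sites:
        raise ValidationError(
            f"fragment label file has {len(labels)} entries for {n_sites} sites"
        )
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    return [order.index(lab) for lab in labels], order


def read_xyz(
    path: str | Path,
    fragment_map: str | Sequence[int] | Path | None = None,
    parameter_table: Mapping[str, Mapping[str, float]] | None = None,
    clash_distance: float = 0.5,
) -> FragmentedSystem:
    """Read a standard XYZ file (Å) into a :class:`FragmentedSystem`.

    Parameters
    ----------
    fragment_map
        Either a range string ``"0-2,3-5"``, an explicit per-site fragment
        index sequence, a path to a sidecar label file (one label per atom
        line), or ``None`` for a single fragment.
    parameter_table
        element → classical parameters; defaults to the pseudo-water table.
        Elements absent from the table get all-zero classical parameters.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected atom count, got {lines[0]!r}") from None
    if len(lines) < natoms + 2:
        raise ParseError(f"{path}: {natoms} atoms declared but only {len(lines)} lines")
    table = parameter_table if parameter_table is not None else DEFAULT_PARAMETER_TABLE
    sites = []
    for k in range(natoms):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {lineno}: expected 'element x y z', got {lines[k + 2]!r}")
        el = parts[0]
        try:
            xyz_ang = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}, line {lineno}: non-numeric coordinate in {lines[k + 2]!r}") from None
        params = table.get(el, {})
        sites.append(
            Site(
                element=el,
                position=tuple(v * ANGSTROM_TO_BOHR for v in xyz_ang),
                charge=params.get("charge", 0.0),
                polarizability=params.get("polarizability", 0.0),
                repulsion_coeff=params.get("repulsion_coeff", 0.0),
                dispersion_coeff=params.get("dispersion_coeff", 0.0),
            )
        )

    if fragment_map is None:
        fragment_of = [0] * natoms
        labels = ["frag0"]
    elif isinstance(fragment_map, (str, Path)) and Path(str(fragment_map)).is_file():
        fragment_of, labels = read_fragment_labels(fragment_map, natoms)
    elif isinstance(fragment_map, str):
        fragment_of = parse_fragment_ranges(fragment_map, natoms)
        labels = [f"frag{i}" for i in range(max(fragment_of) + 1)]
    else:
        fragment_of = list(fragment_map)
        if len(fragment_of) != natoms:
            raise ValidationError("explicit fragment map length does not match atom count")
        labels = [f"frag{i}" for i in range(max(fragment_of) + 1)]

    return FragmentedSystem(
        sites=tuple(sites),
        fragment_of=tuple(fragment_of),
        fragment_labels=tuple(labels),
        clash_distance=clash_distance,
    )


def write_xyz(system: FragmentedSystem, path: str | Path, comment: str = "") -> None:
    """Write a standard XYZ file (coordinates converted Bohr → Å)."""
    with open(path, "w") as fh:
        fh.write(f"{system.n_sites}\n{comment}\n")
        for s in system.sites:
            x, y, z = (v * BOHR_TO_ANGSTROM for v in s.position)
            fh.write(f"{s.element} {x:.10f} {y:.10f} {z:.10f}\n")


def write_charges(
    system: FragmentedSystem, fragments: Iterable[int], scale: float
) -> list[PointCharge]:
    """Turn selected fragments into scaled point charges (charge = q·scale)."""
    frag_set = sorted(set(fragments))
    if not frag_set:
        raise ValidationError("fragment selection must be nonempty")
    if not np.isfinite(scale):
        raise ValidationError("charge scale must be finite")
    for f in frag_set:
        if not 0 <= f < system.n_fragments:
            raise ValidationError(f"unknown fragment index {f}")
    out = []
    for f in frag_set:
        for i in system.sites_of(f):
            s = system.sites[i]
            out.append(PointCharge(position=s.position, charge=s.charge * scale, source_fragment=f))
    return out


def write_pc_file(charges: Sequence[PointCharge], path: str | Path) -> None:
    """Write point charges as ``q x y z`` per line, coordinates in Å."""
    with open(path, "w") as fh:
        for pc in charges:
            x, y, z = (v * BOHR_TO_ANGSTROM for v in pc.position)
            fh.write(f"{pc.charge:.10f} {x:.10f} {y:.10f} {z:.10f}\n")


def subsystem(
    system: FragmentedSystem, keep: Iterable[int]
) -> tuple[FragmentedSystem, dict[int, int]]:
    """Extract the fragments in ``keep``; fragment indices are relabeled
    contiguously.  Returns the sub-system and the old→new fragment map."""
    keep_set = sorted(set(keep))
    if not keep_set:
        raise ValidationError("keep set must be nonempty")
    for f in keep_set:
        if not 0 <= f < system.n_fragments:
            raise ValidationError(f"unknown fragment index {f}")
    old_to_new = {old: new for new, old in enumerate(keep_set)}
    sites, frag_of = [], []
    for i, s in enumerate(system.sites):
        f = system.fragment_of[i]
        if f in old_to_new:
            sites.append(s)
            frag_of.append(old_to_new[f])
    return (
        FragmentedSystem(
            sites=tuple(sites),
            fragment_of=tuple(frag_of),
            fragment_labels=tuple(system.fragment_labels[f] for f in keep_set),
            clash_distance=system.clash_distance,
        ),
        old_to_new,
    )
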