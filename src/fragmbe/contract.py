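"""Treatment levels, the decomposed-energy contract, and subsystem extraction.

Every energy backend maps a (system, region) pair to a
:class:`DecomposedEnergy`: a total energy partitioned exactly into
per-fragment *intra* terms (the energy of a fragment with its internal
degrees of freedom distorted by the surroundings) and unordered
fragment-pair *inter* terms.  The partition is exact:

    total = Σ_X intra[X] + Σ_{X<Y} inter[(X,Y)]

Backends must report *all* terms, including those involving environment
fragments — the embedding drivers discard environment terms explicitly via
:func:`extract_subsystem`, so what is "neglected" is a visible, testable step
rather than backend magic.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .molsys import FragmentedSystem, ValidationError

#: Sum-identity tolerance for the analytic surrogate backend (Hartree).
SUM_IDENTITY_TOL = 1e-9


class LevelTag(str, Enum):
    HIGH = "HIGH"        # full treatment (coupled-cluster analog)
    LOW = "LOW"          # mean-field analog: HIGH minus the correlation channel
    CHARGES = "CHARGES"  # fragment replaced by its fixed, scaled point charges
    ABSENT = "ABSENT"    # fragment removed entirely


@dataclass(frozen=True)
class Level:
    """Treatment level of one fragment.

    ``charge_scale`` is meaningful only for CHARGES (the α of a scaled
    point-charge embedding); ``basis_tag`` is advisory and interpreted by the
    backend (the classical surrogate ignores it).
    """

    tag: LevelTag
    basis_tag: str = ""
    charge_scale: float | None = None

    def __post_init__(self):
        if self.tag is LevelTag.CHARGES and self.charge_scale is None:
            raise ValidationError("CHARGES level requires charge_scale")
        if self.tag is not LevelTag.CHARGES and self.charge_scale is not None:
            raise ValidationError("charge_scale only valid for CHARGES level")


HIGH = Level(LevelTag.HIGH)
LOW = Level(LevelTag.LOW)
ABSENT = Level(LevelTag.ABSENT)


def charges(scale: float, basis_tag: str = "") -> Level:
    return Level(LevelTag.CHARGES, basis_tag=basis_tag, charge_scale=scale)


@dataclass(frozen=True)
class RegionSpec:
    """Per-fragment treatment assignment; at least one fragment must be HIGH."""

    level_of: Mapping[int, Level]

    def __post_init__(self):
        object.__setattr__(self, "level_of", dict(self.level_of))
        if not any(l.tag is LevelTag.HIGH for l in self.level_of.values()):
            raise ValidationError("RegionSpec needs at least one HIGH fragment")

    def level(self, fragment: int) -> Level:
        try:
            return self.level_of[fragment]
        except KeyError:
            raise ValidationError(f"fragment {fragment} has no level assigned") from None

    def fragments_with(self, *tags: LevelTag) -> list[int]:
        return sorted(f for f, l in self.level_of.items() if l.tag in tags)

    def fingerprint(self) -> tuple:
        """Hashable identity of the region, for memoization keys."""
        return tuple(
            (f, l.tag.value, l.basis_tag, l.charge_scale)
            for f, l in sorted(self.level_of.items())
        )

    @staticmethod
    def uniform(n_fragments: int, level: Level = HIGH) -> "RegionSpec":
        return RegionSpec({f: level for f in range(n_fragments)})


def pair_key(x: int, y: int) -> tuple[int, int]:
    if x == y:
        raise ValidationError("pair key requires two distinct fragments")
    return (x, y) if x < y else (y, x)


@dataclass(frozen=True)
class DecomposedEnergy:
    """Exact fragment-pairwise partition of a total energy (Hartree).

    ``channels`` optionally carries a per-channel split (e.g. electrostatic /
    repulsion / dispersion / induction) whose pieces sum entry-wise to the
    main intra/inter maps.  ``reference_energy`` and ``correlation_part``
    carry the mean-field/correlation split when the backend defines one
    (for the surrogate: correlation ≡ dispersion channel).
    """

    total: float
    intra: Mapping[int, float]
    inter: Mapping[tuple[int, int], float]
    channels: Mapping[str, tuple[Mapping[int, float], Mapping[tuple[int, int], float]]] | None = None
    reference_energy: float | None = None
    correlation_part: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "intra", dict(self.intra))
        object.__setattr__(self, "inter", dict(self.inter))
        for (x, y) in self.inter:
            if not x < y:
                raise ValidationError(f"inter key ({x},{y}) must use X<Y ordering")
        if self.channels is not None:
            object.__setattr__(
                self,
                "channels",
                {k: (dict(a), dict(b)) for k, (a, b) in self.channels.items()},
            )

    @property
    def fragments(self) -> list[int]:
        return sorted(self.intra)

    def validate(self, tol: float = SUM_IDENTITY_TOL) -> None:
        """Assert the exact-partition identity (and per-channel closure)."""
        s = sum(self.intra.values()) + sum(self.inter.values())
        if abs(s - self.total) > tol:
            raise ValidationError(
                f"decomposition sum {s!r} differs from total {self.total!r} by {s - self.total:.3e}"
            )
        if self.channels:
            for f in self.intra:
                part = sum(ch[0].get(f, 0.0) for ch in self.channels.values())
                if abs(part - self.intra[f]) > tol:
                    raise ValidationError(f"channel intra terms do not close for fragment {f}")
            for p in self.inter:
                part = sum(ch[1].get(p, 0.0) for ch in self.channels.values())
                if abs(part - self.inter[p]) > tol:
                    raise ValidationError(f"channel inter terms do not close for pair {p}")

    # -- JSON layout: documented ingestion format for external decompositions --

    def to_json_dict(self, labels: list[str] | None = None) -> dict:
        lab = labels or [str(f) for f in self.fragments]
        d = {
            "total": self.total,
            "fragment_labels": lab,
            "intra": {str(f): v for f, v in sorted(self.intra.items())},
            "inter": {f"{x}:{y}": v for (x, y), v in sorted(self.inter.items())},
            "reference_energy": self.reference_energy,
            "correlation_part": self.correlation_part,
        }
        if self.channels is not None:
            d["channels"] = {
                name: {
                    "intra": {str(f): v for f, v in sorted(ch[0].items())},
                    "inter": {f"{x}:{y}": v for (x, y), v in sorted(ch[1].items())},
                }
                for name, ch in self.channels.items()
            }
        return d

    def to_json(self, labels: list[str] | None = None, **kw) -> str:
        return json.dumps(self.to_json_dict(labels), **kw)

    @staticmethod
    def from_json_dict(d: dict) -> "DecomposedEnergy":
        def _pair(k: str) -> tuple[int, int]:
            x, y = (int(v) for v in k.split(":"))
            return pair_key(x, y)

        channels = None
        if "channels" in d and d["channels"] is not None:
            channels = {
                name: (
                    {int(f): v for f, v in ch["intra"].items()},
                    {_pair(k): v for k, v in ch["inter"].items()},
                )
                for name, ch in d["channels"].items()
            }
        return DecomposedEnergy(
            total=d["total"],
            intra={int(f): v for f, v in d["intra"].items()},
            inter={_pair(k): v for k, v in d["inter"].items()},
            channels=channels,
            reference_energy=d.get("reference_energy"),
            correlation_part=d.get("correlation_part"),
        )


class BackendError(RuntimeError):
    """Backend failure; carries the region that failed."""

    def __init__(self, message: str, region: RegionSpec | None = None):
        super().__init__(message)
        self.region = region


class EnergyBackend(ABC):
    """Contract every energy backend satisfies.

    ``compute`` must be deterministic for fixed inputs; ABSENT fragments
    contribute nothing; CHARGES fragments act only through their scaled fixed
    charges.  LOW must equal HIGH minus the backend's correlation channel.
    """

    #: name of the channel playing the role of the correlation energy
    correlation_channel: str | None = None

    @abstractmethod
    def compute(self, system: FragmentedSystem, region: RegionSpec) -> DecomposedEnergy:
        ...

    def site_charges(self, system: FragmentedSystem, source: str = "site"):
        """Charge provider hook for electrostatic embedding (per-site charges).

        The base implementation serves fixed site charges (``source="site"``);
        quantum adapters override to provide population-analysis charges.
        """
        if source != "site":
            raise BackendError(f"backend cannot supply charges of type {source!r}")
        return system.charges


def extract_subsystem(
    d: DecomposedEnergy, sub: set[int] | list[int]
) -> tuple[dict[int, float], dict[tuple[int, int], float], float]:
    """Keep only the intra terms of ``sub`` and inter terms internal to ``sub``.

    This is the explicit "neglect the environment and its interaction with
    the subsystem" step of the embedding drivers.  Returns (intra, inter,
    energy = their sum).
    """
    sub_set = set(sub)
    unknown = sub_set - set(d.intra)
    if unknown:
        raise ValidationError(f"unknown fragments in subsystem selection: {sorted(unknown)}")
    intra = {f: d.intra[f] for f in sorted(sub_set)}
    inter = {p: v for p, v in d.inter.items() if p[0] in sub_set and p[1] in sub_set}
    return intra, inter, sum(intra.values()) + sum(inter.values())


def extract_channel_subsystem(
    d: DecomposedEnergy, channel: str, sub: set[int] | list[int]
) -> float:
    """Subsystem-restricted sum of one channel (0 if the channel is absent)."""
    if not d.channels or channel not in d.channels:
        return 0.0
    intra_ch, inter_ch = d.channels[channel]
    sub_set = set(sub)
    return sum(v for f, v in intra_ch.items() if f in sub_set) + sum(
        v for p, v in inter_ch.items() if p[0] in sub_set and p[1] in sub_set
    )
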