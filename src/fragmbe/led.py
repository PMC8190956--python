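"""Fragment-pairwise interaction maps and comparison statistics.

An interaction map is a symmetric fragment×fragment matrix in kcal/mol:
diagonal elements are electronic preparation energies (the cost of
distorting each monomer for interaction), off-diagonal elements are pair
interaction energies.  Three flavors:

* FULL        — from the supersystem decomposition; sums to the binding
                energy ΔE,
* TWO_BODY    — from all vacuum dimer decompositions; sums to the two-body
                part ΔE²,
* COOPERATIVITY — their element-wise difference; sums to ΔE_coop = ΔE − ΔE²,
* EMBEDDED    — from an embedded two-body run.

The "map total" is Σ diagonal + Σ upper-triangle off-diagonal, and each
flavor's conservation identity (total = ΔE, ΔE², ΔE_coop) is exact up to
floating-point resummation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contract import DecomposedEnergy, pair_key
from .molsys import ValidationError
from .units import HARTREE_TO_KCAL


class MapFlavor(str, Enum):
    FULL = "FULL"
    TWO_BODY = "TWO_BODY"
    COOPERATIVITY = "COOPERATIVITY"
    EMBEDDED = "EMBEDDED"


@dataclass(frozen=True)
class LEDMap:
    """Symmetric interaction map (kcal/mol) with fragment labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    flavor: MapFlavor

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12, rtol=0.0):
            raise ValidationError("interaction map must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def total(self) -> float:
        """Σ diagonal + Σ upper-triangle off-diagonal (kcal/mol)."""
        return float(np.trace(self.matrix) + np.sum(np.triu(self.matrix, k=1)))

    def to_dataframe(self, decimals: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))
        return df.round(decimals) if decimals is not None else df

    def to_csv(self, path) -> None:
        """Canonical artifact: label header, symmetric body, trailing TOTAL."""
        df = self.to_dataframe()
        df.loc["TOTAL"] = [""] * len(self.labels)
        df.iloc[-1, 0] = self.total
        df.to_csv(path)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "flavor": self.flavor.value,
                "labels": list(self.labels),
                "matrix": self.matrix.tolist(),
                "total": self.total,
            },
            **kw,
        )

    def plot(self, ax=None, cmap: str = "coolwarm_r"):
        """Render as a heat plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lim = np.max(np.abs(self.matrix)) or 1.0
        im = ax.imshow(self.matrix, cmap=cmap, vmin=-lim, vmax=lim)
        ax.set_xticks(range(len(self.labels)), self.labels, rotation=45, ha="right")
        ax.set_yticks(range(len(self.labels)), self.labels)
        for i in range(len(self.labels)):
            for j in range(len(self.labels)):
                ax.text(j, i, f"{self.matrix[i, j]:.2f}", ha="center", va="center", fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="kcal/mol")
        ax.set_title(self.flavor.value)
        return ax


def _labels(n: int, labels: Sequence[str] | None) -> tuple[str, ...]:
    return tuple(labels) if labels is not None else tuple(f"frag{i}" for i in range(n))


def led_full(
    decomposition: DecomposedEnergy,
    monomer_energies: Mapping[int, float],
    labels: Sequence[str] | None = None,
) -> LEDMap:
    """Supersystem map: diagonal = E_X^intra − E_X, off-diagonal = E_XY^int."""
    frags = decomposition.fragments
    missing = set(frags) - set(monomer_energies)
    if missing:
        raise ValidationError(f"missing monomer energies for fragments {sorted(missing)}")
    n = len(frags)
    pos = {f: i for i, f in enumerate(frags)}
    m = np.zeros((n, n))
    for i, f in enumerate(frags):
        m[i, i] = (decomposition.intra[f] - monomer_energies[f]) * HARTREE_TO_KCAL
    for (x, y), v in decomposition.inter.items():
        m[pos[x], pos[y]] = m[pos[y], pos[x]] = v * HARTREE_TO_KCAL
    return LEDMap(_labels(n, labels), m, MapFlavor.FULL)


def led_two_body(
    dimer_decompositions: Mapping[tuple[int, int], DecomposedEnergy],
    monomer_energies: Mapping[int, float],
    labels: Sequence[str] | None = None,
) -> LEDMap:
    """Two-body map from all vacuum dimers.

    diagonal[X] = Σ_Y (E_X(XY)^intra,2 − E_X); off-diagonal = E_XY^int,2.
    """
    n = len(monomer_energies)
    expected = {(x, y) for x in range(n) for y in range(x + 1, n)}
    missing = expected - {pair_key(*p) for p in dimer_decompositions}
    if missing:
        raise ValidationError(f"missing dimer decompositions for pairs {sorted(missing)}")
    m = np.zeros((n, n))
    for p, d in dimer_decompositions.items():
        x, y = pair_key(*p)
        m[x, x] += (d.intra[x] - monomer_energies[x]) * HARTREE_TO_KCAL
        m[y, y] += (d.intra[y] - monomer_energies[y]) * HARTREE_TO_KCAL
        m[x, y] = m[y, x] = d.inter[(x, y)] * HARTREE_TO_KCAL
    return LEDMap(_labels(n, labels), m, MapFlavor.TWO_BODY)


def led_embedded(terms, labels: Sequence[str] | None = None) -> LEDMap:
    """Map of an embedded two-body run: diagonal = ΔE_X^el-prep,2(S),
    off-diagonal = E_XY^int,2(S).  Sums to the embedded binding energy."""
    n = terms.n_fragments
    m = np.zeros((n, n))
    for x, v in terms.elprep2.items():
        m[x, x] = v * HARTREE_TO_KCAL
    for (x, y), v in terms.dimer_embedded_inter.items():
        m[x, y] = m[y, x] = v * HARTREE_TO_KCAL
    return LEDMap(_labels(n, labels), m, MapFlavor.EMBEDDED)


def led_cooperativity(full: LEDMap, two_body: LEDMap) -> LEDMap:
    """Element-wise ``full − two_body``; sums to ΔE_coop."""
    if full.labels != two_body.labels:
        raise ValidationError("label mismatch between full and two-body maps")
    return LEDMap(full.labels, full.matrix - two_body.matrix, MapFlavor.COOPERATIVITY)


def led_channels(
    decomposition: DecomposedEnergy, labels: Sequence[str] | None = None
) -> dict[str, LEDMap]:
    """One raw map per backend channel; they sum element-wise to the main
    decomposition map (taken with zero monomer references)."""
    if not decomposition.channels:
        return {}
    frags = decomposition.fragments
    n = len(frags)
    pos = {f: i for i, f in enumerate(frags)}
    out = {}
    for name, (intra_ch, inter_ch) in decomposition.channels.items():
        m = np.zeros((n, n))
        for f, v in intra_ch.items():
            m[pos[f], pos[f]] = v * HARTREE_TO_KCAL
        for (x, y), v in inter_ch.items():
            m[pos[x], pos[y]] = m[pos[y], pos[x]] = v * HARTREE_TO_KCAL
        out[name] = LEDMap(_labels(n, labels), m, MapFlavor.FULL)
    return out


# ------------------------------------------------------------- statistics

def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero at the given decimal (report parity:
    a computed 0.327 prints as 0.33 at two decimals and 0.3 at one)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def mae(
    pairs: Iterable[tuple[float, float]], decimals: int | None = None
) -> float:
    """Mean absolute deviation of (test, reference) pairs, kcal/mol."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("mae requires a nonempty list of pairs")
    value = float(np.mean([abs(t - r) for t, r in pairs]))
    return round_half_up(value, decimals) if decimals is not None else value


def max_abs_dev(
    pairs: Iterable[tuple[float, float]], decimals: int | None = None
) -> float:
    """Maximum absolute deviation of (test, reference) pairs, kcal/mol."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("max_abs_dev requires a nonempty list of pairs")
    value = float(np.max([abs(t - r) for t, r in pairs]))
    return round_half_up(value, decimals) if decimals is not None else value
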