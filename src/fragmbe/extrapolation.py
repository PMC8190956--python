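"""PNO-space and complete-basis-set extrapolation utilities.

Both are linear in the input energies, hence commute with any linear
combination — extrapolating absolute energies and then taking a binding
energy gives the same result as extrapolating the binding energies.

* PNO ("6/7") extrapolation: correlation energies computed at two
  pair-natural-orbital truncation thresholds (10⁻⁶ = loose, 10⁻⁷ = tight)
  are extrapolated toward the complete-PNO limit as
  ``E = E_loose + F · (E_tight − E_loose)`` with F = 1.5 by default.
* Two-point CBS extrapolation over basis cardinal numbers (X, X+1):
  mean-field part via ``E(X) = E_CBS + A·exp(−α·√X)`` (α = 5.46 for the
  3/4 pair), correlation part via the inverse-power form
  ``E_CBS = (X^β·E_X − Y^β·E_Y) / (X^β − Y^β)`` with β = 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .molsys import ValidationError


@dataclass(frozen=True)
class ExtrapolationSpec:
    """Extrapolation parameters (conventional defaults for the 3/4 pair)."""

    pno_F: float = 1.5
    cbs_alpha: float = 5.46
    cbs_beta: float = 3.0
    cardinal_X: int = 3
    cardinal_Y: int = 4

    def __post_init__(self):
        if self.pno_F <= 0:
            raise ValidationError("F must be > 0")
        if self.cardinal_Y != self.cardinal_X + 1:
            raise ValidationError("cardinal_Y must be cardinal_X + 1")


def pno_extrapolate(e_loose: float, e_tight: float, F: float = 1.5) -> float:
    """Complete-PNO-limit estimate ``E = E_loose + F·(E_tight − E_loose)``."""
    if not (math.isfinite(e_loose) and math.isfinite(e_tight) and math.isfinite(F)):
        raise ValidationError("pno_extrapolate requires finite inputs")
    return e_loose + F * (e_tight - e_loose)


def cbs_extrapolate(
    e_ref_X: float,
    e_ref_Y: float,
    e_corr_X: float,
    e_corr_Y: float,
    spec: ExtrapolationSpec = ExtrapolationSpec(),
) -> tuple[float, float]:
    """Two-point CBS limits of the reference and correlation energies.

    Returns ``(reference_CBS, correlation_CBS)``.
    """
    X, Y = spec.cardinal_X, spec.cardinal_Y
    if X == Y:
        raise ValidationError("cardinal numbers must differ")
    fX = math.exp(-spec.cbs_alpha * math.sqrt(X))
    fY = math.exp(-spec.cbs_alpha * math.sqrt(Y))
    ref = (e_ref_X * fY - e_ref_Y * fX) / (fY - fX)
    xb, yb = X**spec.cbs_beta, Y**spec.cbs_beta
    corr = (xb * e_corr_X - yb * e_corr_Y) / (xb - yb)
    return ref, corr
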