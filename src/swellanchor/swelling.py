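"""Hygroscopic swelling of the co-polymeric anchor material.

Moisture uptake of the MMA/AA co-polymer produces a stress-free volumetric
eigenstrain, linear in the absorbed moisture::

    eps_hs = beta_h * (alpha_m - alpha_m_ref)

with the swelling coefficient ``beta_h`` (m^3/kg) and the moisture
concentration change ``delta_alpha`` (kg/m^3); their product is the
dimensionless linear swelling strain.  Swelling is applied as a steady-state
eigenstrain scaled by a ``saturation`` fraction (1 = fully swollen); the
uptake transient is not modeled, since swelling completes fast relative to
bone remodeling.  The swelling tensor is used isotropically throughout.

The registry holds the three measured MMA/AA compositions.  Unconstrained
isotropic linear swelling changes every length by the same relative amount,
which gives the closed-form free-swelling prediction used as a patch test
for the finite element solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SwellingComposition",
    "COMPOSITIONS",
    "get_composition",
    "eigenstrain",
    "linear_swelling_strain",
    "free_swelling_prediction",
]


@dataclass(frozen=True)
class SwellingComposition:
    """Measured swelling parameters of one MMA/AA co-polymer ratio."""

    label: str
    beta_h: float  # swelling coefficient, m^3/kg (isotropic scalar)
    delta_alpha: float  # moisture concentration change, kg/m^3

    def __post_init__(self):
        if self.beta_h < 0:
            raise ValueError("beta_h must be non-negative")
        if self.delta_alpha < 0:
            raise ValueError("delta_alpha must be non-negative")


#: Measured free-swelling parameters for the three MMA/AA ratios.
COMPOSITIONS = {
    "80/20": SwellingComposition("80/20", beta_h=1.2287, delta_alpha=0.1881),
    "85/15": SwellingComposition("85/15", beta_h=0.9920, delta_alpha=0.08672),
    "90/10": SwellingComposition("90/10", beta_h=0.9032, delta_alpha=0.0487),
}


def get_composition(label: str) -> SwellingComposition:
    try:
        return COMPOSITIONS[label]
    except KeyError:
        valid = ", ".join(sorted(COMPOSITIONS))
        raise KeyError(f"unknown composition {label!r}; valid labels: {valid}") from None


def linear_swelling_strain(comp: SwellingComposition, saturation: float = 1.0) -> float:
    """Scalar linear eigenstrain beta_h * delta_alpha * saturation."""
    if saturation < 0:
        raise ValueError("saturation must be non-negative")
    if saturation > 1:
        raise ValueError("saturation must not exceed 1 (fully swollen)")
    return comp.beta_h * comp.delta_alpha * saturation


def eigenstrain(comp: SwellingComposition, saturation: float = 1.0, dim: int = 3) -> np.ndarray:
    """Isotropic hygroscopic strain tensor (dim x dim, zero shear)."""
    return linear_swelling_strain(comp, saturation) * np.eye(dim)


def free_swelling_prediction(diameter0: float, length0: float, comp: SwellingComposition,
                             saturation: float = 1.0):
    """Closed-form (Delta d, Delta L) for an unconstrained swelling cylinder.

    Under unconstrained isotropic linear swelling every length scales by the
    same strain, so ``Delta d = d0 * beta_h * delta_alpha`` and likewise for
    the length.  A free-swelling FE run must reproduce this to machine
    precision (patch test).
    """
    if diameter0 <= 0 or length0 <= 0:
        raise ValueError("dimensions must be positive")
    e = linear_swelling_strain(comp, saturation)
    return diameter0 * e, length0 * e
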