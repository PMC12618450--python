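"""HU -> apparent density -> elastic modulus calibration and material binning.

The empirical calibration is linear in both steps::

    rho [g/m^3] = density_intercept + density_slope * HU
    E   [Pa]    = modulus_intercept + modulus_slope * rho [g/m^3]

The package's canonical unit system is mm / N / MPa / g cm^-3, in which
strain energy density (mJ mm^-3 = J cm^-3) divided by apparent density
(g cm^-3) is numerically J/g with no hidden factors, so the remodeling
reference stimulus k = 0.004 J/g can be used directly.  The calibration's
g/m^3 and Pa are converted at this boundary (1 g/cm^3 = 1e6 g/m^3,
1 MPa = 1e6 Pa).

Densities are clamped to the remodeling bounds [0.01, 2.0] g/cm^3 at mapping
time so that the initial and remodeled states share one invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationConstants",
    "MaterialState",
    "RHO_MIN_DEFAULT",
    "RHO_MAX_DEFAULT",
    "hu_to_density",
    "density_to_modulus",
    "density_to_hu",
    "bin_materials",
]

RHO_MIN_DEFAULT = 0.01  # g/cm^3
RHO_MAX_DEFAULT = 2.0  # g/cm^3

G_PER_M3_TO_G_PER_CM3 = 1e-6
PA_TO_MPA = 1e-6


@dataclass(frozen=True)
class CalibrationConstants:
    """Linear HU->density and density->modulus calibration coefficients.

    ``density_intercept``/``density_slope`` are in g/m^3 (per HU);
    ``modulus_intercept`` is in Pa and ``modulus_slope`` in Pa per (g/m^3).
    """

    density_intercept: float = 1041395.0
    density_slope: float = 1017.0
    modulus_intercept: float = -388.8
    modulus_slope: float = 5925.0

    def __post_init__(self):
        if not self.density_slope > 0:
            raise ValueError("density_slope must be positive")
        if not self.modulus_slope > 0:
            raise ValueError("modulus_slope must be positive")


def hu_to_density(
    hu,
    cal: CalibrationConstants = CalibrationConstants(),
    rho_min: float = RHO_MIN_DEFAULT,
    rho_max: float = RHO_MAX_DEFAULT,
):
    """Apparent density (g/cm^3) from HU, clamped to the remodeling bounds."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    rho = (cal.density_intercept + cal.density_slope * hu) * G_PER_M3_TO_G_PER_CM3
    rho = np.clip(rho, rho_min, rho_max)
    return rho if rho.ndim else float(rho)


def density_to_modulus(density, cal: CalibrationConstants = CalibrationConstants()):
    """Young's modulus (MPa) from apparent density (g/cm^3).

    Raises if the affine map yields a non-positive modulus, which can only
    happen below the density floor and therefore signals corrupted state.
    """
    rho = np.asarray(density, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    modulus = (cal.modulus_intercept + cal.modulus_slope * rho / G_PER_M3_TO_G_PER_CM3) * PA_TO_MPA
    if np.any(modulus <= 0):
        raise ValueError("calibration produced a non-positive modulus: corrupted density state")
    return modulus if modulus.ndim else float(modulus)


def density_to_hu(density, cal: CalibrationConstants = CalibrationConstants()):
    """Invert the HU->density map (affine inverse, no clamping)."""
    rho = np.asarray(density, dtype=float)
    hu = (rho / G_PER_M3_TO_G_PER_CM3 - cal.density_intercept) / cal.density_slope
    return hu if hu.ndim else float(hu)


@dataclass
class MaterialState:
    """Per-element apparent density, modulus, Poisson ratio and material bin.

    ``density`` (g/cm^3) is the remodeling state variable; ``modulus`` (MPa)
    is kept consistent with it through the calibration except on anchor
    elements, whose modulus is fixed.
    """

    density: np.ndarray
    modulus: np.ndarray
    poisson: np.ndarray
    bin_index: np.ndarray = None
    rho_min: float = RHO_MIN_DEFAULT
    rho_max: float = RHO_MAX_DEFAULT

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        self.modulus = np.asarray(self.modulus, dtype=float)
        self.poisson = np.broadcast_to(np.asarray(self.poisson, dtype=float), self.density.shape).copy()
        self.validate()

    def validate(self) -> None:
        eps = 1e-12
        if np.any(self.density < self.rho_min - eps) or np.any(self.density > self.rho_max + eps):
            raise ValueError("density outside [rho_min, rho_max]")
        if np.any(self.modulus <= 0):
            raise ValueError("modulus must be positive for every element")

    def copy(self) -> "MaterialState":
        return MaterialState(
            self.density.copy(), self.modulus.copy(), self.poisson.copy(),
            None if self.bin_index is None else self.bin_index.copy(),
            self.rho_min, self.rho_max,
        )

    @classmethod
    def from_hu(
        cls,
        hu,
        anchor_mask=None,
        anchor_modulus: float = 2500.0,
        poisson: float = 0.3,
        cal: CalibrationConstants = CalibrationConstants(),
        rho_min: float = RHO_MIN_DEFAULT,
        rho_max: float = RHO_MAX_DEFAULT,
    ) -> "MaterialState":
        """Initial material state from per-element HU values.

        Anchor elements (where ``anchor_mask``) keep a fixed polymer modulus
        and a nominal density of 1 g/cm^3 (they never remodel).
        """
        hu = np.asarray(hu, dtype=float)
        rho = np.asarray(hu_to_density(hu, cal, rho_min, rho_max))
        E = np.asarray(density_to_modulus(rho, cal))
        if anchor_mask is not None:
            anchor_mask = np.asarray(anchor_mask, dtype=bool)
            rho = rho.copy()
            E = E.copy()
            rho[anchor_mask] = 1.0
            E[anchor_mask] = anchor_modulus
        return cls(rho, E, poisson, rho_min=rho_min, rho_max=rho_max)

    def to_frame(self) -> pd.DataFrame:
        """Per-element material table (CSV-exportable)."""
        frame = pd.DataFrame({
            "density_g_cm3": self.density,
            "modulus_MPa": self.modulus,
            "poisson": self.poisson,
        })
        if self.bin_index is not None:
            frame["bin_index"] = self.bin_index
        return frame


def bin_materials(densities, n_bins: int = 10, cal: CalibrationConstants = CalibrationConstants()):
    """Bin a density field into discrete material types (equal-width bins).

    Returns ``(bin_index, table)`` where ``table`` has one row per bin with
    the representative (midpoint) density and its calibrated modulus.  A
    constant field occupies a single bin regardless of ``n_bins``.  Binning is
    optional in the pipeline: continuous per-element properties are the
    default, and this reproduces the discrete 10-type workflow.
    """
    rho = np.asarray(densities, dtype=float).ravel()
    if rho.size == 0:
        raise ValueError("empty density list")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(rho.min()), float(rho.max())
    if hi == lo:
        idx = np.zeros(rho.shape, dtype=int)
        mids = np.array([lo])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.digitize(rho, edges[1:-1]), 0, n_bins - 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
    table = pd.DataFrame({
        "bin_index": np.arange(mids.size),
        "density_g_cm3": mids,
        "modulus_MPa": [density_to_modulus(m, cal) for m in mids],
    })
    return idx, table
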