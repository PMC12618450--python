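"""Strain-energy-density-driven bone remodeling with overload resorption.

The apparent density rho of each bone element evolves with the mechanical
stimulus S = U / rho (J/g) relative to a reference stimulus k, with a dead
("lazy") zone of half-width delta*k and a quadratic overload term::

    drho/dt = B (S - (1+delta) k) - D (S - (1+delta) k)^2    if S > (1+delta) k
            = 0                                              inside the lazy zone
            = B (S - (1-delta) k)                            if S < (1-delta) k

Setting D = 0 recovers the classical linear apposition law.  The rate is
integrated by forward Euler with clamping to [rho_min, rho_max]; lazy-zone
boundaries are inclusive (zero rate exactly at (1 +/- delta) k).

The coupled simulation alternates FE solves with blocks of Euler steps: the
stimulus is frozen over a window of ``resolve_every`` steps, densities are
updated, element stiffness is re-mapped from density, and convergence is
declared when the largest relative density change over a window drops below
``convergence_tol`` (or every element sits at a bound or in the lazy zone).
Time is the dimensionless unit implied by the remodeling constants; no claim
of physiological weeks is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem
from .materials import MaterialState, CalibrationConstants, density_to_modulus

__all__ = [
    "RemodelingParams",
    "RemodelingHistory",
    "density_rate",
    "rate_curve_landmarks",
    "step_density",
    "equilibrate_constant_stimulus",
    "equilibrate_frozen_energy",
    "run_remodeling",
    "classify_elements",
]


@dataclass(frozen=True)
class RemodelingParams:
    """Remodeling constants; defaults are the values for human bone used
    throughout the adaptive-remodeling literature.

    B: remodeling rate, (g/cm^3)^2 (MPa * time-unit)^-1.
    D: overload-resorption constant, (g/cm^3)^3 MPa^-2 (time-unit)^-1;
       D = 0 disables the quadratic overload branch.
    k: reference stimulus (J/g); delta: lazy-zone half-width fraction.
    dt: Euler time increment; resolve_every: Euler steps per FE re-solve.
    """

    B: float = 1.0
    D: float = 60.0
    k: float = 0.004
    delta: float = 0.10
    dt: float = 0.01
    rho_min: float = 0.01
    rho_max: float = 2.0
    convergence_tol: float = 0.02
    resolve_every: int = 100
    max_steps: int = 1_000_000

    def __post_init__(self):
        if self.B <= 0 or self.k <= 0 or self.dt <= 0:
            raise ValueError("B, k and dt must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")
        if not self.rho_min < self.rho_max:
            raise ValueError("rho_min must be below rho_max")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.resolve_every < 1:
            raise ValueError("resolve_every must be >= 1")

    @property
    def lazy_low(self) -> float:
        return (1.0 - self.delta) * self.k

    @property
    def lazy_high(self) -> float:
        return (1.0 + self.delta) * self.k


def density_rate(S, p: RemodelingParams):
    """Density rate drho/dt (g/cm^3 per time unit) for stimulus S (J/g)."""
    S = np.asarray(S, dtype=float)
    hi, lo = p.lazy_high, p.lazy_low
    over = S - hi
    under = S - lo
    rate = np.where(S > hi, p.B * over - p.D * over * over,
                    np.where(S < lo, p.B * under, 0.0))
    return rate if rate.ndim else float(rate)


def rate_curve_landmarks(p: RemodelingParams):
    """Closed-form landmarks of the overload rate curve.

    Returns ``(S_peak, rate_peak, S_zero_cross)``: the stimulus of maximum
    apposition rate ``(1+delta) k + B / (2 D)`` with rate ``B^2 / (4 D)``, and
    the overload zero-crossing ``(1+delta) k + B / D`` beyond which net
    resorption occurs.
    """
    if p.D <= 0:
        raise ValueError("landmarks require D > 0 (overload branch enabled)")
    s_peak = p.lazy_high + p.B / (2.0 * p.D)
    rate_peak = p.B ** 2 / (4.0 * p.D)
    s_zero = p.lazy_high + p.B / p.D
    return s_peak, rate_peak, s_zero


def step_density(rho, S, p: RemodelingParams):
    """One forward-Euler update with clamping to [rho_min, rho_max]."""
    out = np.clip(np.asarray(rho, dtype=float) + p.dt * density_rate(S, p),
                  p.rho_min, p.rho_max)
    return out if out.ndim else float(out)


def equilibrate_constant_stimulus(rho0: float, S: float, p: RemodelingParams):
    """Iterate a single element under a frozen stimulus until the density
    stops changing (a bound is hit or the rate is zero).

    Returns ``(rho_final, steps)``.
    """
    rho = float(rho0)
    for step in range(1, p.max_steps + 1):
        new = step_density(rho, S, p)
        if new == rho:
            return rho, step - 1
        rho = new
    return rho, p.max_steps


def equilibrate_frozen_energy(rho0: float, U: float, p: RemodelingParams,
                              rho_tol: float = 1e-12):
    """Single-element loop with frozen strain energy U (J/cm^3) and the
    stimulus recomputed as S = U / rho every step.

    Remodeling ceases when the stimulus enters the lazy zone (rate zero) or
    the per-step density change falls below ``rho_tol``.  Returns
    ``(rho_final, S_final, steps)``.  The fixed point, when inside the
    density bounds, is rho = U / ((1 + delta) k) approached from below (or
    rho = U / ((1 - delta) k) from above).
    """
    rho = float(rho0)
    for step in range(1, p.max_steps + 1):
        S = U / rho
        new = step_density(rho, S, p)
        if abs(new - rho) <= rho_tol:
            return new, U / new, step
        rho = new
    return rho, U / rho, p.max_steps


@dataclass
class RemodelingHistory:
    """Checkpointed densities and per-checkpoint summaries of one run."""

    snapshots: list = field(default_factory=list)  # density arrays per checkpoint
    summary: pd.DataFrame = None
    converged: bool = False
    steps: int = 0  # total Euler steps taken

    @property
    def n_checkpoints(self) -> int:
        if self.summary is not None:
            return len(self.summary)
        return len(self.snapshots)


def _summary_row(checkpoint, rho_bone, max_rel_change, p: RemodelingParams):
    return {
        "checkpoint": checkpoint,
        "mean_density": float(rho_bone.mean()),
        "max_density": float(rho_bone.max()),
        "min_density": float(rho_bone.min()),
        "n_at_floor": int(np.sum(rho_bone <= p.rho_min * (1 + 1e-9))),
        "n_at_cap": int(np.sum(rho_bone >= p.rho_max * (1 - 1e-9))),
        "max_rel_change": float(max_rel_change),
    }


def run_remodeling(mesh: fem.VoxelMesh, mat: MaterialState, eig,
                   bc: fem.BoundaryConditions, p: RemodelingParams,
                   cal: CalibrationConstants = CalibrationConstants(),
                   keep_snapshots: bool = True):
    """Coupled FE / remodeling loop.

    Each checkpoint performs one FE solve, freezes the per-element stimulus,
    advances every bone element by ``resolve_every`` Euler steps with
    clamping, re-maps element moduli from the new densities, and records a
    summary.  Anchor elements never remodel and keep their modulus.

    Returns ``(history, final_material, final_field_state)``; the run is
    deterministic given its inputs.  When ``max_steps`` is exhausted the
    partial history is returned with ``converged=False``.
    """
    mat = mat.copy()
    bone = mesh.region == fem.REGION_BONE
    rows = []
    history = RemodelingHistory()
    state = None
    max_checkpoints = max(1, p.max_steps // p.resolve_every)
    total_steps = 0
    for checkpoint in range(max_checkpoints):
        state = fem.solve_hygroelastic(mesh, mat, eig, bc)
        S = fem.stimulus_field(state, mat, mesh)

        rho_old = mat.density[bone].copy()
        rho = rho_old.copy()
        S_bone = S[bone]
        for _ in range(p.resolve_every):
            rho = step_density(rho, S_bone, p)
        total_steps += p.resolve_every

        max_rel = float(np.max(np.abs(rho - rho_old) / rho_old)) if rho.size else 0.0
        mat.density[bone] = rho
        mat.modulus[bone] = density_to_modulus(rho, cal)
        mat.validate()

        if keep_snapshots:
            history.snapshots.append(mat.density.copy())
        rows.append(_summary_row(checkpoint, rho, max_rel, p))

        at_bound = (rho <= p.rho_min * (1 + 1e-9)) | (rho >= p.rho_max * (1 - 1e-9))
        lazy = density_rate(S_bone, p) == 0.0
        if max_rel < p.convergence_tol or np.all(at_bound | lazy):
            history.converged = True
            break
    history.summary = pd.DataFrame(rows)
    history.steps = total_steps
    # final state consistent with the converged material
    state = fem.solve_hygroelastic(mesh, mat, eig, bc)
    return history, mat, state


REGIME_LABELS = ("apposed", "lazy", "disuse-resorbed", "overload-resorbed",
                 "capped", "floored")


def classify_elements(mat: MaterialState, S: np.ndarray, mesh: fem.VoxelMesh,
                      p: RemodelingParams, interface_mask=None):
    """Label each bone element's remodeling regime from its final state.

    Bound hits take precedence (``capped``/``floored``); otherwise the final
    stimulus is placed against the lazy zone and, when the overload branch is
    enabled, its zero-crossing.  Returns ``(labels, table)`` where the table
    counts regimes and reports mean density, split by an optional interface
    mask (interface shell vs far field).
    """
    labels = np.full(mesh.n_elements, "", dtype=object)
    bone = mesh.region == fem.REGION_BONE
    rho = mat.density
    s_zero = rate_curve_landmarks(p)[2] if p.D > 0 else np.inf

    capped = bone & (rho >= p.rho_max * (1 - 1e-9))
    floored = bone & (rho <= p.rho_min * (1 + 1e-9))
    rest = bone & ~capped & ~floored
    labels[capped] = "capped"
    labels[floored] = "floored"
    labels[rest & (S > s_zero)] = "overload-resorbed"
    labels[rest & (S > p.lazy_high) & (S <= s_zero)] = "apposed"
    labels[rest & (S >= p.lazy_low) & (S <= p.lazy_high)] = "lazy"
    labels[rest & (S < p.lazy_low)] = "disuse-resorbed"

    if interface_mask is None:
        groups = {"all": bone}
    else:
        interface_mask = np.asarray(interface_mask, dtype=bool)
        groups = {"interface": bone & interface_mask, "far": bone & ~interface_mask}
    rows = []
    for name, sel in groups.items():
        row = {"region": name, "n_elements": int(sel.sum()),
               "mean_density": float(rho[sel].mean()) if sel.any() else np.nan}
        for lab in REGIME_LABELS:
            row[f"n_{lab.replace('-', '_')}"] = int(np.sum(labels[sel] == lab))
        rows.append(row)
    return labels, pd.DataFrame(rows)
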