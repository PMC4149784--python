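"""Titration isotherm modelling and metal-quantification arithmetic.

A bidentate ionophore L binding a metal M as an ML_n complex (n ligands per
metal; n = 2 for a bis-chelate) obeys the mass balances

    M_total = [M] + [ML_n]
    L_total = [L] + n [ML_n]
    [ML_n]  = beta_n [M] [L]^n

with beta_n the overall formation constant (M^-n).  The observable is an
absorbance proportional to the complex concentration,
A = epsilon [ML_n] + baseline.  In the tight-binding limit (beta_n -> inf)
the complex concentration is simply min(M_total, L_total / n), producing a
sharp saturation breakpoint at 1/n metal equivalents: a 2:1 ligand:metal
complex saturates at 0.5 equivalents of added metal.

This module solves the finite-beta mass balance, fits the saturation
breakpoint of a measured isotherm by continuous two-segment least squares,
and performs the per-cell / per-volume metal accumulation arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import brentq

__all__ = [
    "BindingModel",
    "TitrationCurve",
    "BreakpointFit",
    "MetalQuant",
    "solve_complex",
    "simulate_isotherm",
    "fit_breakpoint",
    "quantify_metal",
]


@dataclass(frozen=True)
class BindingModel:
    """Overall-formation-constant model of an ML_n complex.

    Parameters
    ----------
    n : ligands per metal (2 for a bis-chelate).
    beta : overall formation constant in M^-n; ``math.inf`` selects the
        tight-binding limit.
    epsilon : response coefficient, absorbance per uM complex.
    baseline : additive absorbance offset.
    """

    n: int = 2
    beta: float = math.inf
    epsilon: float = 0.01
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"stoichiometry n must be a positive integer, got {self.n}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass
class TitrationCurve:
    """(added metal, absorbance) points for a ligand solution of known total."""

    l_total: float  # uM
    added: np.ndarray  # uM metal added
    absorbance: np.ndarray
    epsilon: float | None = None

    def __post_init__(self) -> None:
        self.added = np.asarray(self.added, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.l_total <= 0:
            raise ValueError("l_total must be positive")
        if self.added.size != self.absorbance.size:
            raise ValueError("added and absorbance must have the same length")
        if np.any(self.added < 0):
            raise ValueError("added metal concentrations must be non-negative")
        if np.any(np.diff(self.added) <= 0):
            raise ValueError("added metal concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")

    @property
    def equivalents(self) -> np.ndarray:
        """Added metal expressed in metal:ligand equivalents."""
        return self.added / self.l_total


def solve_complex(model: BindingModel, l_total: float, m_total: float,
                  rtol: float = 1e-12) -> float:
    """Equilibrium [ML_n] (uM) for total ligand/metal concentrations in uM.

    Finite beta: monotone bracketing (Brent) on free ligand.  Infinite beta:
    the min-rule ``min(M_total, L_total/n)``.
    """
    if l_total < 0 or m_total < 0:
        raise ValueError("concentrations must be non-negative")
    n = model.n
    if m_total == 0 or l_total == 0:
        return 0.0
    if math.isinf(model.beta):
        return min(m_total, l_total / n)

    # work in molar so beta keeps its customary units
    L = l_total * 1e-6
    M = m_total * 1e-6
    beta = model.beta

    def residual(free_l: float) -> float:
        complex_c = (L - free_l) / n
        free_m = M - complex_c
        return beta * free_m * free_l ** n - complex_c

    # residual(0) = -L/n < 0 ; residual(L) = beta*M*L^n > 0.  The root in
    # free ligand is located to machine precision; the raw residual can
    # stay large at extreme beta (cancellation in M - [ML_n]) even though
    # the concentrations are exact to round-off, so convergence is judged
    # on the bracket, not the residual.
    free_l, info = brentq(residual, 0.0, L, xtol=1e-30, rtol=8.9e-16,
                          maxiter=300, full_output=True)
    if not info.converged:
        raise RuntimeError("mass-balance solver did not converge")
    complex_c = (L - free_l) / n
    # guard against round-off pushing outside the physical box
    complex_c = min(max(complex_c, 0.0), M, L / n)
    return complex_c * 1e6


def simulate_isotherm(model: BindingModel, l_total: float,
                      additions: Sequence[float]) -> TitrationCurve:
    """Simulate a noise-free titration curve A(M_added) for the given model."""
    added = np.asarray(additions, dtype=float)
    if np.any(added < 0):
        raise ValueError("additions must be non-negative")
    if added.size > 1 and np.any(np.diff(added) <= 0):
        raise ValueError("additions must be strictly increasing")
    complex_uM = np.array([solve_complex(model, l_total, m) for m in added])
    absorbance = model.epsilon * complex_uM + model.baseline
    return TitrationCurve(l_total=l_total, added=added, absorbance=absorbance,
                          epsilon=model.epsilon)


@dataclass
class BreakpointFit:
    """Two-segment fit of a saturation isotherm.

    ``x_break`` is in metal:ligand equivalents, so the inferred
    ligand:metal stoichiometry is ``1 / x_break``.
    """

    x_break: float
    stoichiometry: float
    stoichiometry_rounded: float  # nearest half-integer
    intercept: float
    slope_rise: float
    slope_plateau: float
    residual_ss: float
    n_points: int


def _segment_ss(x: np.ndarray, y: np.ndarray, xb: float):
    """Least-squares continuous two-segment fit at fixed breakpoint."""
    design = np.column_stack([np.ones_like(x), np.minimum(x, xb),
                              np.maximum(x - xb, 0.0)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if coef[2] < 0.0:  # plateau slope constrained >= 0
        design = design[:, :2]
        coef2, *_ = np.linalg.lstsq(design, y, rcond=None)
        coef = np.array([coef2[0], coef2[1], 0.0])
        resid = y - design @ coef2
    else:
        resid = y - np.column_stack([np.ones_like(x), np.minimum(x, xb),
                                     np.maximum(x - xb, 0.0)]) @ coef
    return float(resid @ resid), coef


def fit_breakpoint(curve: TitrationCurve, coarse: int = 60,
                   refinements: int = 4) -> BreakpointFit:
    """Locate the saturation breakpoint of a titration curve.

    Continuous two-segment linear least squares; the breakpoint is chosen on
    a coarse-to-fine grid over the interior of the data range, minimising the
    total sum of squares, with the smallest breakpoint winning ties.  The
    second-segment (plateau) slope is constrained to be non-negative.
    """
    x = curve.equivalents
    y = curve.absorbance
    if x.size < 5:
        raise ValueError("need at least 5 titration points spanning the breakpoint")
    lo, hi = x[1], x[-2]
    if not lo < hi:
        raise ValueError("titration points do not bracket an interior breakpoint")

    best_xb, best_ss, best_coef = None, np.inf, None
    width = hi - lo
    centre = 0.5 * (lo + hi)
    for _ in range(refinements + 1):
        grid = np.linspace(max(lo, centre - width / 2),
                           min(hi, centre + width / 2), coarse)
        for xb in grid:  # ascending, so ties resolve to the smallest xb
            ss, coef = _segment_ss(x, y, xb)
            if best_xb is None or ss < best_ss - 1e-15 * (1 + ss):
                best_xb, best_ss, best_coef = xb, ss, coef
        centre = best_xb
        width = width * 2.0 / (coarse - 1) * 4  # keep a few grid cells of slack

    stoich = 1.0 / best_xb
    return BreakpointFit(
        x_break=float(best_xb),
        stoichiometry=float(stoich),
        stoichiometry_rounded=round(stoich * 2) / 2,
        intercept=float(best_coef[0]),
        slope_rise=float(best_coef[1]),
        slope_plateau=float(best_coef[2]),
        residual_ss=float(best_ss),
        n_points=int(x.size),
    )


@dataclass
class MetalQuant:
    """Per-culture metal accumulation summary.

    ``atoms_per_total_volume`` is atoms per fL of aggregate cell volume;
    ``cu_bpq_ratio`` is accumulated metal atoms over ionophore molecules
    added, assuming complete ionophore uptake.
    """

    mol_metal: float
    cells: float | None = None
    total_volume_fl: float | None = None
    mean_cell_volume_fl: float | None = None
    atoms_total: float = field(init=False)
    atoms_per_cell: float | None = None
    atoms_per_total_volume: float | None = None
    cu_bpq_ratio: float | None = None
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        if self.mol_metal < 0:
            raise ValueError("mol_metal must be non-negative")
        self.atoms_total = self.mol_metal * Avogadro


def quantify_metal(mol_metal: float, cells: float | None = None,
                   total_volume_fl: float | None = None,
                   mean_cell_volume_fl: float | None = None,
                   bpq_added_mol: float | None = None,
                   baseline_mol_metal: float | None = None) -> MetalQuant:
    """Metal-accumulation arithmetic: atoms per cell, per volume, metal:ionophore.

    The metal:ionophore ratio assumes every added ionophore molecule was
    accumulated by the cells; when no untreated baseline is supplied the
    treated total is used unsubtracted and ``baseline_subtracted`` is False.
    """
    q = MetalQuant(mol_metal=mol_metal, cells=cells,
                   total_volume_fl=total_volume_fl,
                   mean_cell_volume_fl=mean_cell_volume_fl)
    if cells is not None:
        if cells <= 0:
            raise ValueError("cell count must be positive for per-cell output")
        q.atoms_per_cell = q.atoms_total / cells
    if total_volume_fl is not None:
        if total_volume_fl <= 0:
            raise ValueError("total cell volume must be positive for per-volume output")
        q.atoms_per_total_volume = q.atoms_total / total_volume_fl
    if bpq_added_mol is not None:
        if bpq_added_mol <= 0:
            raise ValueError("bpq_added_mol must be positive")
        atoms = q.atoms_total
        if baseline_mol_metal is not None:
            atoms = atoms - baseline_mol_metal * Avogadro
            q.baseline_subtracted = True
        q.cu_bpq_ratio = atoms / (bpq_added_mol * Avogadro)
    return q
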