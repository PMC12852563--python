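"""Vesicle self-assembly physics: packing parameter, Helfrich bending energy,
and a Gibbs free-energy model of the equilibrium vesicle size.

The critical packing parameter CPP = V / (a0 · lc) — chain volume over
headgroup area times maximum chain length — predicts the preferred aggregate
morphology of an amphiphile: cones (CPP below ~1/3) pack into spherical
micelles, truncated cones into curved bilayers that close into vesicles,
cylinders (CPP ≈ 1) into planar bilayers, and inverted cones (CPP > 1) into
inverse phases.

Membrane shape energetics follow the Helfrich Hamiltonian: the areal bending
energy of a patch with principal curvatures c1, c2 is

    E_bend = ½ κ (c1 + c2 − c0)² + κ̄ c1 c2

with bending rigidity κ, Gaussian modulus κ̄ and spontaneous curvature c0.
For a closed sphere of radius R this integrates to
2πκ(2 − c0 R)² + 4πκ̄ — independent of R when c0 = 0 (the classical
8πκ + 4πκ̄ result).

The Gibbs model ΔG(R) = ΔH(R) − TΔS(R) takes the enthalpic cost as the
sphere's bending energy and models the entropy gain of closing the bilayer
(release of edge-constrained lipids and water) as a saturating function
s·(1 − exp(−R/R_sat)): once the bilayer is closed, growing further yields
little additional entropy. This functional form is a documented construction
for exploring the size optimum, not a fitted thermodynamic model; with the
shipped calibration (c0 = 2/60 nm⁻¹) the minimum sits at a vesicle diameter
of ~120 nm. Energies are in units of kT; line tension γ is carried in the
parameters because it is why open membrane disks close into vesicles at all,
but open-edge geometries are not modelled here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .data import FormulationError


@dataclass(frozen=True)
class LipidGeometry:
    """Molecular shape of one amphiphile: V (nm³), a0 (nm²), lc (nm)."""

    v_chain: float
    a0: float
    lc: float

    def __post_init__(self) -> None:
        if min(self.v_chain, self.a0, self.lc) <= 0:
            raise FormulationError("all geometry parameters must be positive")


@dataclass(frozen=True)
class MembraneParams:
    """Continuum membrane parameters (energies in kT)."""

    kappa: float = 20.0  # bending rigidity κ, kT
    kappa_bar: float = -15.0  # Gaussian modulus κ̄, kT
    c0: float = 2.0 / 60.0  # spontaneous curvature, 1/nm
    gamma: float = 10.0  # line tension, kT/nm (documentation of edge cost)
    temperature: float = 310.0  # K
    entropy_s: float = 1.0  # saturating entropy amplitude s, kT
    r_sat: float = 20.0  # entropy saturation radius, nm

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.temperature <= 0:
            raise FormulationError("kappa and temperature must be positive")


class MorphologyClass(enum.Enum):
    SPHERICAL_MICELLE = "spherical_micelle"
    CURVED_BILAYER_VESICLE = "curved_bilayer_vesicle"
    PLANAR_BILAYER = "planar_bilayer"
    INVERSE_MICELLE = "inverse_micelle"


#: half-width of the "CPP ≈ 1" planar-bilayer band
PLANAR_BAND_EPS = 0.05

#: lower micelle/vesicle boundary per threshold set
_MICELLE_BOUND = {"theoretical": 1.0 / 3.0, "empirical": 0.5}


def critical_packing_parameter(g: LipidGeometry) -> float:
    """CPP = V / (a0 · lc), dimensionless."""
    return g.v_chain / (g.a0 * g.lc)


def classify_morphology(
    cpp: float, threshold_set: str = "theoretical", eps: float = PLANAR_BAND_EPS
) -> MorphologyClass:
    """Map a packing parameter to its preferred aggregate morphology.

    Theoretical boundaries {1/3, 1±eps}; empirical (formulation-screen)
    boundaries {0.5, 1±eps}. Values on a boundary belong to the lower class.
    """
    if cpp <= 0:
        raise FormulationError("cpp must be positive")
    if threshold_set not in _MICELLE_BOUND:
        raise FormulationError("threshold_set must be 'theoretical' or 'empirical'")
    lo = _MICELLE_BOUND[threshold_set]
    if cpp <= lo:
        return MorphologyClass.SPHERICAL_MICELLE
    if cpp <= 1.0 - eps:
        return MorphologyClass.CURVED_BILAYER_VESICLE
    if cpp <= 1.0 + eps:
        return MorphologyClass.PLANAR_BILAYER
    return MorphologyClass.INVERSE_MICELLE


def bending_energy_density(c1: float, c2: float, p: MembraneParams):
    """Helfrich areal bending energy at principal curvatures c1, c2 (1/nm)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    return 0.5 * p.kappa * (c1 + c2 - p.c0) ** 2 + p.kappa_bar * c1 * c2


def sphere_bending_energy(radius: float, p: MembraneParams):
    """Total Helfrich energy of a closed sphere: 2πκ(2 − c0 R)² + 4πκ̄."""
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise FormulationError("radius must be positive")
    return 2.0 * np.pi * p.kappa * (2.0 - p.c0 * radius) ** 2 + 4.0 * np.pi * p.kappa_bar


def gibbs_free_energy(radius: float, p: MembraneParams):
    """ΔG(R) = ΔH(R) − TΔS(R) with ΔH the sphere bending energy and the
    entropy term s·(1 − exp(−R/R_sat)) saturating once the bilayer closes."""
    radius = np.asarray(radius, dtype=float)
    enthalpy = sphere_bending_energy(radius, p)
    t_delta_s = p.entropy_s * (1.0 - np.exp(-radius / p.r_sat))
    return enthalpy - t_delta_s


@dataclass(frozen=True)
class EquilibriumRadius:
    radius_nm: float
    diameter_nm: float
    gibbs: float
    at_boundary: bool


def equilibrium_radius(
    p: MembraneParams, r_min: float = 10.0, r_max: float = 300.0, tol: float = 0.01
) -> EquilibriumRadius:
    """Radius minimizing ΔG over [r_min, r_max] (grid scan + bounded refine).

    Returns the boundary value with ``at_boundary`` set when the minimum is
    not interior. Tolerance 0.01 nm.
    """
    if not r_min < r_max:
        raise FormulationError("need r_min < r_max")
    grid = np.linspace(r_min, r_max, 512)
    vals = gibbs_free_energy(grid, p)
    if not np.all(np.isfinite(vals)):
        raise FormulationError("non-finite free energy in the search range")
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda r: float(gibbs_free_energy(r, p)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol / 10},
    )
    r_star = float(res.x)
    g_star = float(res.fun)
    # golden-section can sit a hair inside the bracket; snap to true boundary
    at_boundary = r_star - r_min <= tol or r_max - r_star <= tol
    if at_boundary:
        r_star = r_min if (r_star - r_min <= tol) else r_max
        g_star = float(gibbs_free_energy(r_star, p))
    return EquilibriumRadius(r_star, 2.0 * r_star, g_star, at_boundary)


def energy_radius_sweep(
    p: MembraneParams, r_min: float = 10.0, r_max: float = 300.0, n: int = 200
):
    """(radius, ΔG) table for plotting the free-energy landscape."""
    import pandas as pd

    radii = np.linspace(r_min, r_max, n)
    return pd.DataFrame(
        {"radius_nm": radii, "gibbs_kt": gibbs_free_energy(radii, p),
         "bending_kt": sphere_bending_energy(radii, p)}
    )
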