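"""Methane solubility and equilibrium hydrate partitioning.

Hydrate formation/dissolution is assumed to be much faster than microbial
kinetics (local thermodynamic equilibrium): after every reaction and
diffusion step, each node is projected onto the equilibrium manifold —
either no hydrate and dissolved methane below the local solubility, or
hydrate present and dissolved methane pinned exactly at solubility.

The solubility curve C_eq(depth) rises with burial depth (pressure and
temperature increase along the local geotherm). Small mud pores raise the
local solubility (capillary effect), captured by an optional multiplier
on mud nodes; below the base of the gas hydrate stability zone hydrate is
forbidden outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import SAND

#: Structure-I hydrate defaults: density (g/cm3) and hydration number.
HYDRATE_DENSITY = 0.912
HYDRATION_NUMBER = 5.75

_CH4_MOLAR_MASS = 16.043
_H2O_MOLAR_MASS = 18.0153


def hydrate_carbon_density(hydrate_density: float = HYDRATE_DENSITY,
                           hydration_number: float = HYDRATION_NUMBER) -> float:
    """Carbon molarity of the pure hydrate phase, mM CH4 per liter hydrate.

    ``CH4 . n H2O`` with density rho packs ``rho / (16.043 + n * 18.0153)``
    mol of methane per cm3.
    """
    if hydrate_density <= 0 or hydration_number <= 0:
        raise ValueError("hydrate density and hydration number must be positive")
    molar_mass = _CH4_MOLAR_MASS + hydration_number * _H2O_MOLAR_MASS
    return hydrate_density / molar_mass * 1.0e6


@dataclass(frozen=True)
class HydrateConstants:
    """Constants of the hydrate phase (mostly its carbon molarity)."""

    c_h: float = hydrate_carbon_density()

    def __post_init__(self) -> None:
        if self.c_h <= 1000.0:
            raise ValueError("hydrate carbon molarity must far exceed aqueous C_eq")


@dataclass(frozen=True)
class SolubilityModel:
    """Depth-dependent dissolved-methane solubility C_eq(d).

    Attributes
    ----------
    form : str
        ``"linear"``: ``c_ref * (1 + (d - d_ref)/d_scale)``;
        ``"exponential"``: ``c_ref * exp((d - d_ref)/d_scale)``;
        ``"table"``: linear interpolation of a user (depth, C_eq) table.
    c_ref : float
        Solubility at the reference depth, mM.
    d_ref : float
        Reference depth, m below seafloor.
    d_scale : float
        Linear slope scale or exponential e-folding scale, m.
    mud_multiplier : float
        Factor (>= 1) applied to C_eq on mud nodes: small pores raise the
        solubility and inhibit hydrate formation there.
    bghsz_depth : float
        Base of the gas hydrate stability zone, m; below it hydrate is
        disallowed (C_eq treated as infinite).
    table : tuple of (depth, ceq) pairs, optional
        Required for ``form="table"``; depths strictly increasing.
    """

    form: str = "linear"
    c_ref: float = 60.0
    d_ref: float = 0.0
    d_scale: float = 500.0
    mud_multiplier: float = 1.0
    bghsz_depth: float = np.inf
    table: tuple = ()

    def __post_init__(self) -> None:
        if self.form not in ("linear", "exponential", "table"):
            raise ValueError(f"unknown solubility form {self.form!r}")
        if self.form != "table" and (self.c_ref <= 0 or self.d_scale <= 0):
            raise ValueError("c_ref and d_scale must be positive")
        if self.mud_multiplier < 1.0:
            raise ValueError("mud_multiplier must be >= 1")
        if self.form == "table":
            if len(self.table) < 2:
                raise ValueError("table form needs at least two (depth, ceq) rows")
            d = np.array([row[0] for row in self.table])
            if np.any(np.diff(d) <= 0):
                raise ValueError("table depths must be strictly increasing")

    def base_curve(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.form == "linear":
            c = self.c_ref * (1.0 + (d - self.d_ref) / self.d_scale)
        elif self.form == "exponential":
            c = self.c_ref * np.exp((d - self.d_ref) / self.d_scale)
        else:
            dd = np.array([row[0] for row in self.table])
            cc = np.array([row[1] for row in self.table])
            c = np.interp(d, dd, cc)
        return c


def load_solubility_table(path, **kwargs) -> SolubilityModel:
    """Build a table-form model from two-column delimited text (depth_m, ceq_mM)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("solubility table must have two columns: depth_m, ceq_mM")
    return SolubilityModel(form="table", table=tuple(map(tuple, data)), **kwargs)


def ceq(d, lith, sm: SolubilityModel) -> np.ndarray:
    """Local methane solubility at absolute depth(s) d for given lithology.

    Mud nodes get the pore-size multiplier; depths below the BGHSZ return
    ``inf`` (hydrate forbidden, any methane load stays dissolved).
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    lith = np.atleast_1d(np.asarray(lith))
    mult = np.where(lith == SAND, 1.0, sm.mud_multiplier)
    c = sm.base_curve(d) * mult
    c = np.where(d > sm.bghsz_depth, np.inf, c)
    return c


def partition(M, S, ceq_local, hc: HydrateConstants, occupancy: bool = True):
    """Project (dissolved methane, hydrate saturation) onto equilibrium.

    Conserves the node methane carbon ``T = M * (1 - S) + c_h * S``
    (or ``T = M + c_h * S`` without pore-occupancy accounting) exactly in
    every branch. Where the total load exceeds what the fluid can hold at
    solubility, the excess freezes: ``M' = C_eq`` and ``S'`` solves the
    conservation equation; where the implied saturation is negative,
    hydrate dissolves (down to ``S' = 0``, in which case all methane is
    dissolved below solubility). Saturations reaching 1 are unphysical
    and raise.

    Accepts scalars or arrays; returns ``(M', S')`` (scalars in ->
    python floats out).
    """
    scalar = np.isscalar(M)
    M = np.atleast_1d(np.asarray(M, dtype=float))
    S = np.atleast_1d(np.asarray(S, dtype=float))
    ce = np.atleast_1d(np.asarray(ceq_local, dtype=float))
    if np.any(M < 0):
        raise ValueError("dissolved methane must be non-negative")
    if np.any((S < 0) | (S >= 1)):
        raise ValueError("hydrate saturation must lie in [0, 1)")
    if np.any(ce[np.isfinite(ce)] >= hc.c_h):
        raise ValueError(
            "solubility reaches the hydrate carbon density; the equilibrium "
            "partition is undefined there (use an infinite C_eq to forbid "
            "hydrate instead)")

    if occupancy:
        T = M * (1.0 - S) + hc.c_h * S
        denom = hc.c_h - ce
    else:
        T = M + hc.c_h * S
        denom = np.full_like(ce, hc.c_h)
    finite = np.isfinite(ce)
    with np.errstate(invalid="ignore"):
        S_new = np.where(finite, (T - ce) / denom, 0.0)
    S_new = np.maximum(S_new, 0.0)
    if np.any(S_new >= 1.0):
        raise RuntimeError(
            "equilibrium saturation reached 1: methane load exceeds what the "
            "pore can hold as hydrate (check rate constants / solubility)")
    M_new = np.where(S_new > 0.0, ce, T)
    if scalar:
        return float(M_new[0]), float(S_new[0])
    return M_new, S_new
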