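"""Shared data model for the sediment-column reactive transport model.

The model tracks six carbon pools in a one-dimensional sediment interval
that is buried below the seafloor in a Lagrangian frame (the grid is fixed
to the sediment, which sinks at the sedimentation rate):

* ``P`` — particulate organic carbon (POC), solid, immobile;
* ``H`` — high-molecular-weight dissolved organic carbon (HMW-DOC);
* ``L`` — low-molecular-weight dissolved organic carbon (LMW-DOC);
* ``E`` — extracellular enzymes, treated as a dissolved carbon pool;
* ``M`` — dissolved methane;
* ``S`` — methane hydrate, expressed as pore-volume saturation.

All dissolved concentrations (and POC, after conversion from weight
percent) are stored as mM of carbon per liter of pore fluid, so that the
rate laws in :mod:`sandhydrate.kinetics` share a single unit system.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("sandhydrate")

#: Seconds per (Julian) year; used for every yr <-> s conversion.
SECONDS_PER_YEAR = 3.15576e7

#: Molar mass of carbon, g/mol.
CARBON_MOLAR_MASS = 12.011

MUD = "mud"
SAND = "sand"


def convert_poc(wt_percent: float, grain_density: float = 2.65,
                porosity: float = 0.5) -> float:
    """Convert a POC grain mass fraction to mM carbon per pore-fluid volume.

    Parameters
    ----------
    wt_percent : float
        Organic carbon content as a percentage of sediment grain mass.
    grain_density : float
        Grain density in g/cm3 (default 2.65, typical marine sediment).
    porosity : float
        Sediment porosity (fraction of bulk volume that is pore fluid).

    Returns
    -------
    float
        Carbon molarity referenced to the pore-fluid volume, in mM.

    Notes
    -----
    carbon mass per cm3 of bulk sediment is ``(wt/100) * rho_g * (1-phi)``;
    dividing by the pore-fluid volume fraction ``phi`` and the molar mass
    of carbon, then rescaling to mmol per liter, gives

    ``mM = (wt/100) * rho_g * (1-phi)/phi / 12.011 * 1e6``.
    """
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must lie strictly in (0, 1); got {porosity}")
    if grain_density <= 0:
        raise ValueError(f"grain density must be positive; got {grain_density}")
    if wt_percent < 0 or wt_percent >= 100:
        raise ValueError(f"wt_percent must lie in [0, 100); got {wt_percent}")
    grams_per_cm3_fluid = (wt_percent / 100.0) * grain_density * (1.0 - porosity) / porosity
    return grams_per_cm3_fluid / CARBON_MOLAR_MASS * 1e6


def invert_poc(conc_mM: float, grain_density: float = 2.65,
               porosity: float = 0.5) -> float:
    """Inverse of :func:`convert_poc`: mM carbon back to grain wt%."""
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must lie strictly in (0, 1); got {porosity}")
    return conc_mM * CARBON_MOLAR_MASS / 1e6 * porosity / ((1.0 - porosity) * grain_density) * 100.0


@dataclass(frozen=True)
class BurialTrajectory:
    """Linear burial history of the modeled interval.

    Attributes
    ----------
    sed_rate : float
        Sedimentation rate in mm/yr.
    d0 : float
        Burial depth (m below seafloor) of the interval top at t = 0.
    """

    sed_rate: float
    d0: float = 0.0

    def __post_init__(self) -> None:
        if self.sed_rate <= 0:
            raise ValueError(f"sed_rate must be positive; got {self.sed_rate}")
        if self.d0 < 0:
            raise ValueError(f"d0 must be non-negative; got {self.d0}")


def burial_depth(traj: BurialTrajectory, t_yr: float) -> float:
    """Depth (mbsf) of the interval top after ``t_yr`` years of burial."""
    t = np.asarray(t_yr, dtype=float)
    if np.any(t < 0):
        raise ValueError("burial time must be non-negative")
    return traj.d0 + traj.sed_rate * 1e-3 * t


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the POC degradation network.

    Attributes
    ----------
    K_eh : float
        Enzyme-driven POC hydrolysis constant, per mM enzyme per second.
    K_fm : float
        Fermentation constant, per second per (cell per liter pore fluid).
    K_m : float
        Methanogenesis constant, same units as ``K_fm``. Equal to ``K_fm``
        in both site presets (the published simplification).
    beta : float
        Small dimensionless factor in the background hydrolysis constant.
    E0 : float
        Reference extracellular enzyme concentration, mM.
    lambda_half : float
        Extracellular enzyme half-life, years. ``inf`` disables decay.
    epsilon : float
        Fraction of fermented carbon routed to new extracellular enzymes
        (much less than one).
    gamma_ch4 : float
        Fraction of methanogenesis carbon emitted as methane; the
        remainder is CO2 (0.5 corresponds to 2 CH2O -> CH4 + CO2).
    """

    K_eh: float
    K_fm: float
    K_m: float
    beta: float = 0.01
    E0: float = 0.5
    lambda_half: float = 1.0e4
    epsilon: float = 0.01
    gamma_ch4: float = 0.5

    def __post_init__(self) -> None:
        for name in ("K_eh", "K_fm", "K_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.epsilon < 1:
            raise ValueError(f"epsilon must lie in (0, 1); got {self.epsilon}")
        if not 0 < self.gamma_ch4 <= 1:
            raise ValueError(f"gamma_ch4 must lie in (0, 1]; got {self.gamma_ch4}")
        if self.lambda_half <= 0:
            raise ValueError("lambda_half must be positive (inf disables decay)")

    @property
    def K_o(self) -> float:
        """Background hydrolysis constant, per second: beta * E0 * K_eh."""
        return self.beta * self.E0 * self.K_eh

    @property
    def K_ed(self) -> float:
        """Enzyme decay constant, per second: ln(2) / half-life."""
        if np.isinf(self.lambda_half):
            return 0.0
        return np.log(2.0) / (self.lambda_half * SECONDS_PER_YEAR)


@dataclass(frozen=True)
class TransportParams:
    """Effective sediment diffusivities of the four solutes, m2/s.

    Defaults are free-solution values at ~4 degC scaled by a tortuosity
    factor of about one half, size-ordered (larger molecules diffuse
    more slowly).
    """

    D_hmw: float = 5.0e-11
    D_lmw: float = 2.5e-10
    D_enz: float = 2.5e-11
    D_ch4: float = 4.4e-10

    def __post_init__(self) -> None:
        vals = (self.D_enz, self.D_hmw, self.D_lmw, self.D_ch4)
        if any(v < 0 for v in vals):
            raise ValueError("diffusivities must be non-negative")
        if not (self.D_enz <= self.D_hmw <= self.D_lmw <= self.D_ch4):
            raise ValueError(
                "diffusivities must be size-ordered: D_enz <= D_hmw <= D_lmw <= D_ch4")


@dataclass(frozen=True)
class MicrobialProfile:
    """Optional depth decay of the mud cell census.

    When enabled, mud cell density decays exponentially with absolute
    burial depth from ``n_surface`` to the lithology plateau value,
    emulating pore-space collapse during early compaction. OFF by
    default: the presets use the two published plateau densities.
    """

    enabled: bool = False
    n_surface: float = 1.0e9
    efold_depth_m: float = 30.0


@dataclass(frozen=True)
class SedimentColumn:
    """Static description of the modeled sediment interval.

    Attributes
    ----------
    node_depths : ndarray
        Coordinate of each node within the interval (m from interval top),
        uniformly spaced.
    lithology : ndarray of str
        Per-node label, ``"mud"`` or ``"sand"``.
    n_cells : ndarray
        Per-node microbial density, cells per cm3 of bulk sediment.
        Fermenters and methanogens share this census (one count, two
        functional groups); see :func:`sandhydrate.kinetics.reaction_rates`
        for how separate densities can be supplied.
    poc_init : ndarray
        Initial POC, mM carbon per pore-fluid volume (zero on sand).
    porosity : float
        Constant porosity shared by both lithologies.
    microbial_profile : MicrobialProfile
        Optional depth-dependent mud census (disabled by default).
    """

    node_depths: np.ndarray
    lithology: np.ndarray
    n_cells: np.ndarray
    poc_init: np.ndarray
    porosity: float
    microbial_profile: MicrobialProfile = field(default_factory=MicrobialProfile)

    def __post_init__(self) -> None:
        n = len(self.node_depths)
        if n < 3:
            raise ValueError("column needs at least 3 nodes")
        dz = np.diff(self.node_depths)
        if not np.allclose(dz, dz[0], rtol=1e-9, atol=0.0):
            raise ValueError("node spacing must be uniform")
        for name in ("lithology", "n_cells", "poc_init"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match node count")
        if np.any(self.poc_init[self.lithology == SAND] != 0):
            raise ValueError("sand nodes must carry zero initial POC")
        if np.any(self.n_cells <= 0):
            raise ValueError("cell densities must be positive everywhere")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie strictly in (0, 1)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_depths)

    @property
    def dz(self) -> float:
        return float(self.node_depths[1] - self.node_depths[0])

    @property
    def length(self) -> float:
        """Interval length in m (node span plus one cell)."""
        return float(self.node_depths[-1] - self.node_depths[0])

    @property
    def is_sand(self) -> np.ndarray:
        return self.lithology == SAND

    @property
    def is_mud(self) -> np.ndarray:
        return self.lithology == MUD

    def cells_at_depth(self, burial_depth_m: float) -> np.ndarray:
        """Per-node cell census when the interval top sits at the given depth.

        Constant per lithology unless the optional mud depth-decay profile
        is enabled, in which case mud follows
        ``max(plateau, n_surface * exp(-d / efold))`` with ``d`` the
        absolute node depth below the seafloor.
        """
        prof = self.microbial_profile
        if not prof.enabled:
            return self.n_cells
        d_abs = burial_depth_m + self.node_depths
        decayed = prof.n_surface * np.exp(-d_abs / prof.efold_depth_m)
        n = np.where(self.is_mud, np.maximum(self.n_cells, decayed), self.n_cells)
        return n


def build_column(domain_length: float, sand_thickness: float, dz: float,
                 n_sand: float = 1.0e9, n_mud: float = 1.0e6,
                 poc_mud_wt: float = 0.5, porosity: float = 0.5,
                 grain_density: float = 2.65,
                 microbial_profile: MicrobialProfile | None = None) -> SedimentColumn:
    """Construct a mud column with a single centered sand bed.

    Nodes are cell centers: node i sits at ``(i + 1/2) * dz`` so that
    ``n_nodes * dz == domain_length`` and the discrete pore volume
    matches the physical interval exactly. A node is sand when its
    center falls inside the centered bed
    ``[(Ld - Ls)/2, (Ld + Ls)/2]``.

    ``sand_thickness == 0`` produces a valid all-mud column.
    """
    if domain_length <= 0 or dz <= 0:
        raise ValueError("domain_length and dz must be positive")
    if sand_thickness < 0 or sand_thickness >= domain_length:
        raise ValueError("sand bed must be thinner than the domain")
    if sand_thickness > 0 and dz >= sand_thickness:
        raise ValueError(
            f"dz={dz} m cannot resolve a {sand_thickness} m sand bed")

    n_nodes = int(round(domain_length / dz))
    if abs(n_nodes * dz - domain_length) > 1e-9 * domain_length:
        warnings.warn(
            f"dz={dz} does not divide domain_length={domain_length}; "
            f"snapping to {n_nodes} nodes ({n_nodes * dz:.6g} m)")
    node_depths = (np.arange(n_nodes) + 0.5) * dz

    top = 0.5 * (domain_length - sand_thickness)
    bot = 0.5 * (domain_length + sand_thickness)
    is_sand = (node_depths > top) & (node_depths < bot)
    if sand_thickness > 0:
        n_sand_nodes = int(is_sand.sum())
        want = int(round(sand_thickness / dz))
        if n_sand_nodes != want:
            warnings.warn(
                f"sand bed resolved by {n_sand_nodes} nodes "
                f"(nominal {want}); thickness snapped to grid")

    lith = np.where(is_sand, SAND, MUD)
    cells = np.where(is_sand, n_sand, n_mud).astype(float)
    poc = np.where(is_sand, 0.0, convert_poc(poc_mud_wt, grain_density, porosity))
    return SedimentColumn(
        node_depths=node_depths, lithology=lith, n_cells=cells,
        poc_init=poc, porosity=porosity,
        microbial_profile=microbial_profile or MicrobialProfile())


@dataclass
class ColumnState:
    """Time-dependent state of the column: one array per carbon pool.

    ``G`` is a cumulative CO2 ledger and ``E_dead`` a cumulative
    decayed-enzyme ledger; neither is transported nor reacts further —
    they exist so the closed-system carbon balance closes exactly.
    """

    t: float
    P: np.ndarray
    H: np.ndarray
    L: np.ndarray
    E: np.ndarray
    M: np.ndarray
    S: np.ndarray
    G: np.ndarray
    E_dead: np.ndarray

    @classmethod
    def initial(cls, column: SedimentColumn) -> "ColumnState":
        """Initial condition: all solutes and hydrate zero, POC in mud."""
        z = np.zeros(column.n_nodes)
        return cls(t=0.0, P=column.poc_init.copy(), H=z.copy(), L=z.copy(),
                   E=z.copy(), M=z.copy(), S=z.copy(), G=z.copy(),
                   E_dead=z.copy())

    def copy(self) -> "ColumnState":
        return ColumnState(
            t=self.t, P=self.P.copy(), H=self.H.copy(), L=self.L.copy(),
            E=self.E.copy(), M=self.M.copy(), S=self.S.copy(),
            G=self.G.copy(), E_dead=self.E_dead.copy())

    def validate(self) -> None:
        for name in ("P", "H", "L", "E", "M", "G", "E_dead"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ValueError(f"negative concentration in pool {name}")
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"non-finite value in pool {name}")
        if np.any(self.S < 0) or np.any(self.S >= 1):
            raise ValueError("hydrate saturation must lie in [0, 1)")


def total_carbon(state: ColumnState, column: SedimentColumn,
                 hydrate_carbon_mM: float, occupancy: bool = True) -> float:
    """Total tracked carbon in the closed interval (phi * mmol per m2).

    With pore-occupancy accounting (default) the dissolved pools occupy
    the hydrate-free fluid fraction ``1 - S`` while POC, the cumulative
    ledgers and the hydrate phase reference the full pore volume; with it
    off, every pool references the full pore volume. Uniform node weights
    are exact because nodes are cell centers (each node owns one full
    cell of width dz).
    """
    fluid = state.H + state.L + state.E + state.M
    w = (1.0 - state.S) if occupancy else 1.0
    per_node = (state.P + state.G + state.E_dead + w * fluid
                + hydrate_carbon_mM * state.S)
    return float(column.porosity * column.dz * per_node.sum())


# --- snapshot I/O -----------------------------------------------------------

SNAPSHOT_COLUMNS = ("depth", "lithology", "P", "H", "L", "E", "M", "S", "G")


def write_snapshot(path, state: ColumnState, column: SedimentColumn) -> None:
    """Write a per-node state snapshot as delimited text."""
    import pandas as pd

    df = pd.DataFrame({
        "depth": column.node_depths, "lithology": column.lithology,
        "P": state.P, "H": state.H, "L": state.L, "E": state.E,
        "M": state.M, "S": state.S, "G": state.G,
    })
    with open(path, "w") as fh:
        fh.write(f"# t_yr = {state.t!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_snapshot(path):
    """Read a snapshot written by :func:`write_snapshot`.

    Returns ``(t_yr, DataFrame)``.
    """
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        t = float(header.split("=")[1])
        df = pd.read_csv(fh, sep="\t")
    return t, df
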