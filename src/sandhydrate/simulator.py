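"""Scenario definition, the split-step time loop, and result summaries.

One time step of size dt is the three-fractional-step scheme:

1. implicit diffusion of the four solutes over dt/2;
2. reaction integration over the full dt, followed by projection of every
   node onto the hydrate equilibrium manifold;
3. diffusion over another dt/2, followed by a second (cheap, conservative)
   equilibrium projection so emitted states always satisfy the
   dichotomy: either S = 0 and M <= C_eq, or S > 0 and M = C_eq.

Both half-steps and the reaction step are individually second-order, and
the symmetric arrangement keeps the splitting second-order overall.

The interval is closed (zero-flux walls, no advection): total tracked
carbon — POC, the three dissolved organic pools, dissolved methane in the
hydrate-free fluid fraction, hydrate, and the cumulative CO2 and
decayed-enzyme ledgers — is monitored every few steps and a drift beyond
tolerance aborts the run with a diagnostic dump.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np

from . import kinetics, transport
from .hydrate_equilibrium import (HydrateConstants, SolubilityModel, ceq,
                                  hydrate_carbon_density)
from .model_core import (BurialTrajectory, ColumnState, MicrobialProfile,
                         RateConstants, SedimentColumn, TransportParams,
                         build_column, burial_depth, logger, total_carbon)

LEDGER_TOL = 1.0e-3  # relative closed-system carbon drift that aborts a run


@dataclass(frozen=True)
class ColumnSpec:
    """Geometry/lithology inputs consumed by ``build_column``."""

    domain_length: float
    sand_thickness: float
    dz: float
    n_sand: float = 1.0e9
    n_mud: float = 1.0e6
    poc_mud_wt: float = 0.5
    porosity: float = 0.5
    grain_density: float = 2.65
    microbial_profile: MicrobialProfile = field(default_factory=MicrobialProfile)

    def build(self) -> SedimentColumn:
        return build_column(
            self.domain_length, self.sand_thickness, self.dz,
            n_sand=self.n_sand, n_mud=self.n_mud, poc_mud_wt=self.poc_mud_wt,
            porosity=self.porosity, grain_density=self.grain_density,
            microbial_profile=self.microbial_profile)


@dataclass(frozen=True)
class Scenario:
    """Everything needed to run one site simulation."""

    column: ColumnSpec
    rates: RateConstants
    transport: TransportParams
    burial: BurialTrajectory
    solubility: SolubilityModel
    name: str = "custom"
    hydrate: HydrateConstants = field(default_factory=HydrateConstants)
    dt: float = 10.0                      # yr
    t_end: float = 3.0e5                  # yr
    snapshot_times: tuple = ()            # yr
    series_interval: float = 1000.0       # yr
    occupancy: bool = True
    theta: float = 0.5                    # 0.5 = Crank-Nicolson
    s_hfz: float = 0.01                   # hydrate-free-zone threshold on S
    s_top: float = 0.05                   # hydrate-onset threshold on S

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")

    def with_(self, **kw) -> "Scenario":
        """Return a copy with the given fields replaced (nested keys via
        dotted names are not supported; replace whole sub-objects)."""
        return dataclasses.replace(self, **kw)


@dataclass
class RunResult:
    """Output of :func:`run_scenario`."""

    scenario: Scenario
    column: SedimentColumn
    snapshots: list          # of ColumnState
    series: dict             # name -> ndarray, aligned on series["t_yr"]
    final_state: ColumnState

    @property
    def ledger_drift(self) -> float:
        c = self.series["total_carbon"]
        if c[0] == 0.0:
            return float(np.max(np.abs(c)))
        return float(np.max(np.abs(c - c[0])) / c[0])


def _series_record(series, state, column, scn, c_h):
    doc = state.H + state.L
    sand = column.is_sand
    mud = column.is_mud
    series["t_yr"].append(state.t)
    series["burial_m"].append(burial_depth(scn.burial, state.t))
    series["max_doc"].append(float(doc.max()))
    series["max_doc_mud"].append(float(doc[mud].max()) if mud.any() else np.nan)
    series["max_doc_sand"].append(float(doc[sand].max()) if sand.any() else np.nan)
    series["max_S_sand"].append(float(state.S[sand].max()) if sand.any() else np.nan)
    series["max_S_mud"].append(float(state.S[mud].max()) if mud.any() else np.nan)
    series["max_S"].append(float(state.S.max()))
    above, below = hfz_thicknesses(state, column, scn.s_hfz)
    series["hfz_above_m"].append(above)
    series["hfz_below_m"].append(below)
    series["total_carbon"].append(total_carbon(state, column, c_h, scn.occupancy))


def _half_step_kernel(scn: Scenario, col: SedimentColumn, S: np.ndarray,
                      static_kernel: transport.DiffusionKernel | None):
    """Pick the diffusion kernel for the current hydrate field.

    While the column is hydrate-free the prebuilt storage-free kernel is
    reused; once S > 0 anywhere (occupancy mode) the kernel is rebuilt
    with the fluid-fraction storage 1 - S so diffusion conserves the
    occupancy-weighted solute mass.
    """
    if scn.occupancy and np.any(S > 0):
        return transport.DiffusionKernel(col.n_nodes, col.dz, scn.dt / 2.0,
                                         scn.transport, scn.theta, 1.0 - S)
    if static_kernel is not None:
        return static_kernel
    return transport.DiffusionKernel(col.n_nodes, col.dz, scn.dt / 2.0,
                                     scn.transport, scn.theta)


def step(state: ColumnState, scenario: Scenario,
         column: SedimentColumn | None = None,
         kernel: transport.DiffusionKernel | None = None) -> ColumnState:
    """Advance one full time step of the three-fractional-step scheme.

    ``kernel`` is the prebuilt storage-free (S = 0) kernel; it is only
    used while the column is hydrate-free.
    """
    scn = scenario
    col = column if column is not None else scn.column.build()
    d_top = burial_depth(scn.burial, state.t + scn.dt)
    ce = ceq(d_top + col.node_depths, col.lithology, scn.solubility)
    n_cells = col.cells_at_depth(burial_depth(scn.burial, state.t))

    k1 = _half_step_kernel(scn, col, state.S, kernel)
    s = transport.diffuse_all(state, scn.transport, col.dz, scn.dt / 2.0,
                              kernel=k1, theta=scn.theta)
    _clamp_solutes(s)
    s = kinetics.integrate_reactions(s, col, scn.rates, scn.dt,
                                     n_ferm=n_cells, n_meth=n_cells,
                                     occupancy=scn.occupancy)
    _project(s, ce, scn)
    k2 = _half_step_kernel(scn, col, s.S, kernel)
    s = transport.diffuse_all(s, scn.transport, col.dz, scn.dt / 2.0,
                              kernel=k2, theta=scn.theta)
    _clamp_solutes(s)
    _project(s, ce, scn)
    s.t = state.t + scn.dt
    return s


_CLAMP_REL = 2.0e-2  # of the field maximum; larger negatives are a failure
_CLAMP_ABS = 1.0e-2  # mM; spikes below this are clamped regardless (grid-
                     # scale deltas arise at sand edges during the burst)


def _clamp_solutes(s: ColumnState) -> None:
    """Zero the small negative undershoot that Crank-Nicolson leaves on
    sharp near-zero profiles (round-off plus bounded CN oscillation at
    the sand edges); raise if a negative exceeds that scale. The mass
    added by clamping is bounded by the same small fraction and is
    watched by the global carbon ledger."""
    for name in ("H", "L", "E", "M"):
        arr = getattr(s, name)
        lo = arr.min(initial=0.0)
        if lo < 0.0:
            if lo < -max(_CLAMP_REL * float(arr.max(initial=0.0)), _CLAMP_ABS):
                raise RuntimeError(
                    f"diffusion produced negative {name} = {lo:g} "
                    f"(beyond undershoot scale); reduce dt or use theta=1")
            np.maximum(arr, 0.0, out=arr)


def _project(s: ColumnState, ce, scn: Scenario) -> None:
    """In-place equilibrium projection; concentrates/dilutes the other
    solutes into the changed fluid fraction so their carbon is conserved."""
    from .hydrate_equilibrium import partition

    S_old = s.S
    M_new, S_new = partition(s.M, s.S, ce, scn.hydrate, scn.occupancy)
    if scn.occupancy:
        changed = S_new != S_old
        if np.any(changed):
            ratio = np.where(changed, (1.0 - S_old) / (1.0 - S_new), 1.0)
            s.H = s.H * ratio
            s.L = s.L * ratio
            s.E = s.E * ratio
    s.M, s.S = M_new, S_new


def run_scenario(scenario: Scenario, progress: bool = False) -> RunResult:
    """Run the full time loop and collect snapshots, series and the ledger."""
    scn = scenario
    col = scn.column.build()
    kernel = transport.DiffusionKernel(col.n_nodes, col.dz, scn.dt / 2.0,
                                       scn.transport, scn.theta)
    state = ColumnState.initial(col)
    c_h = scn.hydrate.c_h

    n_steps = int(round(scn.t_end / scn.dt))
    if abs(n_steps * scn.dt - scn.t_end) > 1e-9 * scn.t_end:
        n_steps = int(math.ceil(scn.t_end / scn.dt))
        logger.warning("t_end=%g yr is not a multiple of dt=%g yr; "
                       "running %d steps to %g yr",
                       scn.t_end, scn.dt, n_steps, n_steps * scn.dt)
    series_stride = max(1, int(round(scn.series_interval / scn.dt)))
    snap_steps = sorted({min(n_steps, max(0, int(round(t / scn.dt))))
                         for t in scn.snapshot_times})

    series = {k: [] for k in (
        "t_yr", "burial_m", "max_doc", "max_doc_mud", "max_doc_sand",
        "max_S_sand", "max_S_mud", "max_S", "hfz_above_m", "hfz_below_m",
        "total_carbon")}
    snapshots = []
    _series_record(series, state, col, scn, c_h)
    if 0 in snap_steps:
        snapshots.append(state.copy())

    c0 = series["total_carbon"][0]
    it = range(1, n_steps + 1)
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(it, desc=scn.name)
        except ImportError:
            pass
    for i in it:
        state = step(state, scn, column=col, kernel=kernel)
        if i % series_stride == 0 or i == n_steps:
            _series_record(series, state, col, scn, c_h)
            ct = series["total_carbon"][-1]
            drift = abs(ct - c0) / c0 if c0 > 0 else abs(ct)
            if drift > LEDGER_TOL:
                raise RuntimeError(
                    f"carbon ledger drift {drift:.2e} exceeded {LEDGER_TOL:g} "
                    f"at t={state.t:g} yr in scenario {scn.name!r}; state "
                    f"max per pool: P={state.P.max():.3g} H={state.H.max():.3g} "
                    f"L={state.L.max():.3g} E={state.E.max():.3g} "
                    f"M={state.M.max():.3g} S={state.S.max():.3g}")
        if i in snap_steps:
            snapshots.append(state.copy())

    series = {k: np.asarray(v) for k, v in series.items()}
    return RunResult(scenario=scn, column=col, snapshots=snapshots,
                     series=series, final_state=state)


# --- diagnostics ------------------------------------------------------------

def hfz_thicknesses(state: ColumnState, column: SedimentColumn,
                    s_hfz: float = 0.01):
    """Thickness (m) of the hydrate-free mud zones above and below the sand.

    Counts contiguous mud nodes with S < s_hfz outward from each sand
    boundary until a hydrate-bearing node or the domain edge. NaN when
    the column has no sand bed.
    """
    sand_idx = np.flatnonzero(column.is_sand)
    if sand_idx.size == 0:
        return float("nan"), float("nan")
    dz = column.dz
    i0, i1 = sand_idx[0], sand_idx[-1]

    above = 0
    for i in range(i0 - 1, -1, -1):
        if state.S[i] < s_hfz:
            above += 1
        else:
            break
    below = 0
    for i in range(i1 + 1, column.n_nodes):
        if state.S[i] < s_hfz:
            below += 1
        else:
            break
    return above * dz, below * dz


def mud_saturation_beyond_hfz(state: ColumnState, column: SedimentColumn,
                              s_hfz: float = 0.01) -> float:
    """Peak hydrate saturation on mud nodes beyond the hydrate-free zones.

    NaN when the mud beyond the HFZs carries no hydrate at all (the HFZ
    extends to the domain edge on both sides).
    """
    sand_idx = np.flatnonzero(column.is_sand)
    if sand_idx.size == 0:
        return float("nan")
    above, below = hfz_thicknesses(state, column, s_hfz)
    dz = column.dz
    i0, i1 = sand_idx[0], sand_idx[-1]
    n_above = int(round(above / dz))
    n_below = int(round(below / dz))
    vals = np.concatenate([state.S[:i0 - n_above], state.S[i1 + 1 + n_below:]])
    if vals.size == 0:
        return float("nan")
    return float(vals.max())


def generation_rate_profiles(state: ColumnState, column: SedimentColumn,
                             rc: RateConstants, burial_depth_m: float = 0.0):
    """Per-node DOC and methane generation rates, mM per kyr.

    DOC generation is the gross hydrolysis rate (POC -> HMW-DOC); methane
    generation is the methane-carbon fraction of methanogenesis.
    """
    n = column.cells_at_depth(burial_depth_m)
    rr = kinetics.reaction_rates(state.P, state.H, state.L, state.E, rc,
                                 n, n, column.porosity)
    to_mM_per_kyr = kinetics.SECONDS_PER_YEAR * 1.0e3
    return rr.r_hyd * to_mM_per_kyr, rc.gamma_ch4 * rr.r_m * to_mM_per_kyr


def summarize(result: RunResult, snapshot_burial_m: float | None = None) -> dict:
    """Scalar metrics of a run (the quantities the site figures report).

    ``snapshot_burial_m`` selects the snapshot nearest that burial depth
    for the mud-saturation metric; defaults to the final state. Metrics
    that need hydrate are NaN when none ever formed.
    """
    scn, col = result.scenario, result.column
    se = result.series
    i_peak = int(np.argmax(se["max_doc"]))

    def first_time(mask):
        idx = np.flatnonzero(mask)
        return float(se["t_yr"][idx[0]]) if idx.size else float("nan")

    onset_t = first_time(se["max_S"] >= scn.s_top)
    with np.errstate(invalid="ignore"):
        onset_sand_t = first_time(np.nan_to_num(se["max_S_sand"]) >= scn.s_top)
    onset_burial = (burial_depth(scn.burial, onset_sand_t)
                    if np.isfinite(onset_sand_t) else float("nan"))

    if snapshot_burial_m is not None and result.snapshots:
        burials = np.array([burial_depth(scn.burial, s.t) for s in result.snapshots])
        snap = result.snapshots[int(np.argmin(np.abs(burials - snapshot_burial_m)))]
    else:
        snap = result.final_state
    above, below = hfz_thicknesses(result.final_state, col, scn.s_hfz)

    sand = col.is_sand
    final = result.final_state
    return {
        "max_doc": float(se["max_doc"][i_peak]),
        "t_max_doc_kyr": float(se["t_yr"][i_peak]) / 1e3,
        "max_sh_sand_final": float(final.S[sand].max()) if sand.any() else float("nan"),
        "max_sh_sand_overall": float(np.nanmax(se["max_S_sand"])) if sand.any() else float("nan"),
        "max_sh_mud_overall": float(np.nanmax(se["max_S_mud"])),
        "onset_time_kyr": onset_t / 1e3 if np.isfinite(onset_t) else float("nan"),
        "onset_burial_m": onset_burial,
        "hfz_above_m": above,
        "hfz_below_m": below,
        "mud_sh_beyond_hfz": mud_saturation_beyond_hfz(snap, col, scn.s_hfz),
        "top_hydrate_depth_m": top_hydrate_depth(result),
        "snapshot_t_kyr": snap.t / 1e3,
        "ledger_drift": result.ledger_drift,
    }


def top_hydrate_depth(result: RunResult, s_top: float | None = None) -> float:
    """Burial depth (mbsf) of the top of the sand hydrate at its onset.

    Onset is the first output time at which any sand node exceeds the
    ``s_top`` saturation threshold (the scenario's by default); the
    reported depth is the interval burial depth at that time. NaN when
    sand hydrate never reaches the threshold.
    """
    scn, col = result.scenario, result.column
    if s_top is None:
        s_top = scn.s_top
    se = result.series
    with np.errstate(invalid="ignore"):
        idx = np.flatnonzero(np.nan_to_num(se["max_S_sand"]) >= s_top)
    if idx.size == 0 or not col.is_sand.any():
        return float("nan")
    return burial_depth(scn.burial, float(se["t_yr"][idx[0]]))


def doc_max_after(result: RunResult, t_after_yr: float) -> float:
    """Largest DOC concentration at any node/time later than ``t_after_yr``."""
    se = result.series
    mask = se["t_yr"] > t_after_yr
    return float(se["max_doc"][mask].max()) if mask.any() else float("nan")


# --- scenario config files --------------------------------------------------

_CONFIG_SCHEMA = {
    # key: (section of Scenario, attribute path, type)
    "name": ("scenario", "name", str),
    "domain_length_m": ("column", "domain_length", float),
    "sand_thickness_m": ("column", "sand_thickness", float),
    "dz_m": ("column", "dz", float),
    "n_sand_cells_cm3": ("column", "n_sand", float),
    "n_mud_cells_cm3": ("column", "n_mud", float),
    "poc_mud_wt_pct": ("column", "poc_mud_wt", float),
    "porosity": ("column", "porosity", float),
    "grain_density_g_cm3": ("column", "grain_density", float),
    "mud_profile_enabled": ("profile", "enabled", bool),
    "mud_profile_n_surface_cells_cm3": ("profile", "n_surface", float),
    "mud_profile_efold_m": ("profile", "efold_depth_m", float),
    "K_eh_per_mM_s": ("rates", "K_eh", float),
    "K_fm_per_cell_s": ("rates", "K_fm", float),
    "K_m_per_cell_s": ("rates", "K_m", float),
    "beta": ("rates", "beta", float),
    "E0_mM": ("rates", "E0", float),
    "lambda_half_yr": ("rates", "lambda_half", float),
    "epsilon": ("rates", "epsilon", float),
    "gamma_ch4": ("rates", "gamma_ch4", float),
    "D_hmw_m2_s": ("transport", "D_hmw", float),
    "D_lmw_m2_s": ("transport", "D_lmw", float),
    "D_enz_m2_s": ("transport", "D_enz", float),
    "D_ch4_m2_s": ("transport", "D_ch4", float),
    "sed_rate_mm_yr": ("burial", "sed_rate", float),
    "d0_m": ("burial", "d0", float),
    "sol_form": ("solubility", "form", str),
    "sol_c_ref_mM": ("solubility", "c_ref", float),
    "sol_d_ref_m": ("solubility", "d_ref", float),
    "sol_d_scale_m": ("solubility", "d_scale", float),
    "sol_mud_multiplier": ("solubility", "mud_multiplier", float),
    "bghsz_depth_m": ("solubility", "bghsz_depth", float),
    "hydrate_density_g_cm3": ("hydrate", "_density", float),
    "hydration_number": ("hydrate", "_number", float),
    "dt_yr": ("scenario", "dt", float),
    "t_end_yr": ("scenario", "t_end", float),
    "snapshot_times_yr": ("scenario", "snapshot_times", "floatlist"),
    "series_interval_yr": ("scenario", "series_interval", float),
    "occupancy": ("scenario", "occupancy", bool),
    "theta": ("scenario", "theta", float),
    "s_hfz": ("scenario", "s_hfz", float),
    "s_top": ("scenario", "s_top", float),
}


def _parse_value(raw: str, typ):
    raw = raw.strip()
    if typ is bool:
        if raw.lower() in ("true", "yes", "on", "1"):
            return True
        if raw.lower() in ("false", "no", "off", "0"):
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if typ == "floatlist":
        if not raw:
            return ()
        return tuple(float(x) for x in raw.split(","))
    if typ is float:
        return float(raw)
    return raw


def scenario_from_config(source) -> Scenario:
    """Build a Scenario from a flat ``key = value`` text file or a dict.

    Lines starting with ``#`` and inline ``# ...`` trailers are comments.
    Unknown keys raise (typos should not pass silently).
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        raw = {}
        with open(source) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {lineno}: expected 'key = value'")
                key, val = (x.strip() for x in line.split("=", 1))
                raw[key] = val

    groups: dict = {"scenario": {}, "column": {}, "profile": {}, "rates": {},
                    "transport": {}, "burial": {}, "solubility": {},
                    "hydrate": {}}
    for key, val in raw.items():
        if key not in _CONFIG_SCHEMA:
            raise KeyError(f"unknown config key {key!r}")
        group, attr, typ = _CONFIG_SCHEMA[key]
        groups[group][attr] = _parse_value(val, typ) if isinstance(val, str) else val

    hyd = groups["hydrate"]
    hc = HydrateConstants(c_h=hydrate_carbon_density(
        hyd.get("_density", 0.912), hyd.get("_number", 5.75)))
    prof = MicrobialProfile(**groups["profile"]) if groups["profile"] else MicrobialProfile()
    return Scenario(
        column=ColumnSpec(microbial_profile=prof, **groups["column"]),
        rates=RateConstants(**groups["rates"]),
        transport=TransportParams(**groups["transport"]),
        burial=BurialTrajectory(**groups["burial"]),
        solubility=SolubilityModel(**groups["solubility"]),
        hydrate=hc,
        **groups["scenario"],
    )


def scenario_to_config(scn: Scenario) -> str:
    """Serialize a Scenario back to the flat config format (fully resolved)."""
    lines = [f"# sandhydrate scenario: {scn.name}"]
    col, rc, tp, tr, sm = scn.column, scn.rates, scn.transport, scn.burial, scn.solubility
    prof = col.microbial_profile
    vals = {
        "name": scn.name,
        "domain_length_m": col.domain_length, "sand_thickness_m": col.sand_thickness,
        "dz_m": col.dz, "n_sand_cells_cm3": col.n_sand, "n_mud_cells_cm3": col.n_mud,
        "poc_mud_wt_pct": col.poc_mud_wt, "porosity": col.porosity,
        "grain_density_g_cm3": col.grain_density,
        "mud_profile_enabled": prof.enabled,
        "mud_profile_n_surface_cells_cm3": prof.n_surface,
        "mud_profile_efold_m": prof.efold_depth_m,
        "K_eh_per_mM_s": rc.K_eh, "K_fm_per_cell_s": rc.K_fm,
        "K_m_per_cell_s": rc.K_m, "beta": rc.beta, "E0_mM": rc.E0,
        "lambda_half_yr": rc.lambda_half, "epsilon": rc.epsilon,
        "gamma_ch4": rc.gamma_ch4,
        "D_hmw_m2_s": tp.D_hmw, "D_lmw_m2_s": tp.D_lmw,
        "D_enz_m2_s": tp.D_enz, "D_ch4_m2_s": tp.D_ch4,
        "sed_rate_mm_yr": tr.sed_rate, "d0_m": tr.d0,
        "sol_form": sm.form, "sol_c_ref_mM": sm.c_ref, "sol_d_ref_m": sm.d_ref,
        "sol_d_scale_m": sm.d_scale, "sol_mud_multiplier": sm.mud_multiplier,
        "bghsz_depth_m": sm.bghsz_depth,
        "dt_yr": scn.dt, "t_end_yr": scn.t_end,
        "snapshot_times_yr": ",".join(f"{t:g}" for t in scn.snapshot_times),
        "series_interval_yr": scn.series_interval,
        "occupancy": scn.occupancy, "theta": scn.theta,
        "s_hfz": scn.s_hfz, "s_top": scn.s_top,
    }
    for key, val in vals.items():
        lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


PRESET_NAMES = ("wr313h", "u1325")


def preset(name: str) -> Scenario:
    """Load one of the shipped, frozen site presets (``wr313h``/``u1325``)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    ref = importlib.resources.files("sandhydrate.presets") / f"{name}.cfg"
    with importlib.resources.as_file(ref) as path:
        return scenario_from_config(path)
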