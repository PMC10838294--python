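"""Reaction network and the full-time-step reaction integrator.

The degradation chain is

* hydrolysis:      POC -> HMW-DOC at rate ``(K_o + K_eh * E) * P``, where
  ``K_o = beta * E0 * K_eh`` is the slow background rate that kick-starts
  the chain from a sterile initial state;
* fermentation:    HMW-DOC -> LMW-DOC (fraction ``1 - eps``) plus new
  extracellular enzymes (fraction ``eps``), at ``K_fm * n_ferm * H``;
* methanogenesis:  LMW-DOC -> CH4 (fraction ``gamma``) + CO2
  (fraction ``1 - gamma``), at ``K_m * n_meth * L``;
* enzyme decay:    first order with rate constant ``K_ed = ln 2 / lambda``.

Cell densities enter the rate laws as cells per cubic meter of pore
fluid (``n_sediment * 1e6 / porosity``), pairing the per-cell rate
constants with a fluid-referenced census. Hydrolysis does not scale with
the census: enzymes are extracellular and act cell-free.

Two integrators are provided and selected automatically:

* explicit midpoint (RK2) with a substep guard, used while the fastest
  effective rate constant satisfies ``k_max * dt`` below a few — the
  plainly non-stiff regime;
* an exact-flow Strang splitting for the stiff regime (fermentation in
  a dense sand bed can reach ``k * dt`` in the hundreds): a half step of
  hydrolysis with enzymes frozen (exact exponential depletion of POC),
  a full step of the linear decay chain H -> L/E -> M/G/E_dead solved in
  closed form with constant per-node coefficients, then the second
  hydrolysis half step. Product pools are filled from conservation
  identities (carbon out of a pool = inflow + initial - remaining), so
  per-node carbon conservation is exact to round-off, and the symmetric
  composition keeps the step second-order in dt while being
  unconditionally stable in the fast rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (SECONDS_PER_YEAR, ColumnState, RateConstants,
                         SedimentColumn)

def cells_per_fluid_m3(n_cells_cm3, porosity: float):
    """cells/cm3 bulk sediment -> cells per m3 of pore fluid (n * 1e6 / phi).

    This is the census normalization under which the published star rate
    constants reproduce the published pore-water DOC scale (a few mM in
    quasi-steady state); see the methods note for the calibration of this
    convention against the site behavior.
    """
    return np.asarray(n_cells_cm3, dtype=float) * 1.0e6 / porosity


@dataclass
class ReactionRates:
    """Instantaneous reaction rates, mM carbon per second (all >= 0)."""

    r_hyd: np.ndarray
    r_fm: np.ndarray
    r_m: np.ndarray
    r_ed: np.ndarray


def enzyme_decay_constant(lambda_half_yr: float) -> float:
    """First-order enzyme decay constant (1/s) from a half-life in years.

    ``inf`` disables decay and returns 0.
    """
    if np.isinf(lambda_half_yr):
        return 0.0
    if lambda_half_yr <= 0:
        raise ValueError("enzyme half-life must be positive")
    return float(np.log(2.0) / (lambda_half_yr * SECONDS_PER_YEAR))


def reaction_rates(P, H, L, E, rc: RateConstants, n_ferm, n_meth,
                   porosity: float) -> ReactionRates:
    """Evaluate the four rate laws at one or many nodes.

    ``n_ferm`` / ``n_meth`` are cell densities in cells per cm3 of bulk
    sediment; they are converted to per-m3-pore-fluid inside.
    Negative state components raise (they signal an upstream bug).
    """
    P, H, L, E = (np.asarray(x, dtype=float) for x in (P, H, L, E))
    for name, arr in (("P", P), ("H", H), ("L", L), ("E", E)):
        if np.any(arr < 0):
            raise ValueError(f"negative {name} passed to reaction_rates")
    nf = cells_per_fluid_m3(n_ferm, porosity)
    nm = cells_per_fluid_m3(n_meth, porosity)
    return ReactionRates(
        r_hyd=(rc.K_o + rc.K_eh * E) * P,
        r_fm=rc.K_fm * nf * H,
        r_m=rc.K_m * nm * L,
        r_ed=rc.K_ed * E,
    )


def _rhs(P, H, L, E, rc: RateConstants, nf_L, nm_L, w):
    """Time derivatives of (P, H, L, E, M, G, E_dead); nf_L/nm_L in cells/m3 fluid.

    ``w`` is the local fluid fraction ``1 - S`` (or scalar 1 when
    pore-occupancy accounting is off). Dissolved pools are referenced to
    the remaining fluid volume, so their per-fluid derivatives carry no
    ``w``; the solid pool P and the cumulative ledgers G / E_dead are
    referenced to the full pore volume and exchange carbon with the fluid
    at rates scaled by ``w``. This makes the weighted per-node carbon sum
    ``P + w*(H+L+E+M) + G + E_dead`` exactly conserved by the network.
    """
    r_hyd = (rc.K_o + rc.K_eh * E) * P
    r_fm = rc.K_fm * nf_L * H
    r_m = rc.K_m * nm_L * L
    r_ed = rc.K_ed * E
    eps, g = rc.epsilon, rc.gamma_ch4
    return (-w * r_hyd,
            r_hyd - r_fm,
            (1.0 - eps) * r_fm - r_m,
            eps * r_fm - r_ed,
            g * r_m,
            w * (1.0 - g) * r_m,
            w * r_ed)


def max_rate_constant(state: ColumnState, rc: RateConstants, nf_L, nm_L) -> float:
    """Largest effective first-order rate constant anywhere (1/s)."""
    k_hyd = rc.K_o + rc.K_eh * float(state.E.max(initial=0.0))
    k_fm = rc.K_fm * float(np.max(nf_L))
    k_m = rc.K_m * float(np.max(nm_L))
    return max(k_hyd, k_fm, k_m, rc.K_ed)


_NEG_CLAMP_REL = 1e-12

#: RK2 is used below this ``k_max * dt``; the exact-flow splitting above.
_STIFF_SWITCH = 2.0


def _phi(d):
    """(1 - exp(-d)) / d, stable for all d >= 0 including d = 0."""
    d = np.asarray(d, dtype=float)
    safe = np.where(d == 0.0, 1.0, d)
    return np.where(d == 0.0, 1.0, -np.expm1(-safe) / safe)


def _decay_transfer(k_src, k_dst, h):
    """``integral_0^h exp(-k_src t) exp(-k_dst (h-t)) dt``.

    The response at time h of a pool decaying at ``k_dst`` to a unit
    source decaying at ``k_src``; stable when the two rates coincide.
    """
    d = (k_src - k_dst) * h
    return h * np.exp(-k_dst * h) * _phi(d)


def _hydrolysis_half(y, rc: RateConstants, w, h):
    """Exact flow of hydrolysis alone over h seconds (E frozen)."""
    P, H = y[0], y[1]
    a = rc.K_o + rc.K_eh * y[3]
    decayed = -np.expm1(-w * a * h)        # 1 - exp(..), >= 0
    dP = P * decayed
    y[0] = P - dP
    y[1] = H + dP / w


def _chain_full(y, rc: RateConstants, kf, km, w, h):
    """Exact flow of the linear decay chain over h seconds.

    H decays at kf into L (1-eps) and E (eps); L decays at km into
    M (gamma, per fluid volume) and G (1-gamma, full pore volume);
    E decays at K_ed into E_dead. Product increments come from
    conservation identities, so the weighted per-node carbon sum is
    preserved exactly.
    """
    P, H, L, E, M, G, Ed = y
    kd = rc.K_ed
    eps, g = rc.epsilon, rc.gamma_ch4

    H1 = H * np.exp(-kf * h)
    fermented = H - H1
    L1 = L * np.exp(-km * h) + (1.0 - eps) * kf * H * _decay_transfer(kf, km, h)
    E1 = E * np.exp(-kd * h) + eps * kf * H * _decay_transfer(kf, kd, h)
    methanized = L + (1.0 - eps) * fermented - L1
    decayed = E + eps * fermented - E1

    y[1] = H1
    y[2] = L1
    y[3] = E1
    y[4] = M + g * methanized
    y[5] = G + w * (1.0 - g) * methanized
    y[6] = Ed + w * decayed


def _integrate_exact(y, rc: RateConstants, nf_L, nm_L, w, dt_s,
                     guard: float) -> None:
    """Strang composition hydrolysis(h/2) o chain(h) o hydrolysis(h/2).

    Substeps are set by the slow rates only (hydrolysis and enzyme
    decay); the fast chain rates are handled exactly.
    """
    kf = rc.K_fm * nf_L
    km = rc.K_m * nm_L
    a_max = rc.K_o + rc.K_eh * float(y[3].max(initial=0.0))
    k_slow = max(a_max, rc.K_ed)
    n_sub = max(1, int(np.ceil(k_slow * dt_s / min(guard, 0.05))))
    h = dt_s / n_sub
    for _ in range(n_sub):
        _hydrolysis_half(y, rc, w, 0.5 * h)
        _chain_full(y, rc, kf, km, w, h)
        _hydrolysis_half(y, rc, w, 0.5 * h)


def integrate_reactions(state: ColumnState, col: SedimentColumn,
                        rc: RateConstants, dt_yr: float,
                        n_ferm=None, n_meth=None,
                        guard: float = 0.5,
                        occupancy: bool = True,
                        method: str = "auto") -> ColumnState:
    """Advance the reaction ODEs over a full time step.

    Parameters
    ----------
    state : ColumnState
        Input state (not modified).
    col : SedimentColumn
        Supplies cell census and porosity.
    rc : RateConstants
        Kinetic parameters.
    dt_yr : float
        Full time step, years.
    n_ferm, n_meth : ndarray, optional
        Per-node cell densities (cells/cm3 sediment) overriding the
        column census, e.g. for a depth-decaying profile or distinct
        functional-group counts.
    guard : float
        Maximum allowed ``k_eff * dt`` per internal substep; the step is
        subdivided as needed so accuracy never degrades with large dt.
    occupancy : bool
        When True (default), hydrate occupies pore volume: reaction
        exchange between the fluid pools and the full-pore-volume pools
        (P, G, E_dead) is scaled by the local fluid fraction ``1 - S``.
    method : str
        ``"rk2"`` (explicit midpoint with substep guard), ``"exact"``
        (exact-flow Strang splitting, unconditionally stable in the fast
        chain rates), or ``"auto"`` (default): RK2 while ``k_max * dt``
        is small, exact-flow otherwise.

    Tiny negative round-off values are clamped to zero; anything beyond
    ``1e-12`` of the local scale raises.
    """
    if dt_yr <= 0:
        raise ValueError("dt must be positive")
    if method not in ("auto", "rk2", "exact"):
        raise ValueError(f"unknown reaction integrator {method!r}")
    nf = col.n_cells if n_ferm is None else np.asarray(n_ferm, dtype=float)
    nm = col.n_cells if n_meth is None else np.asarray(n_meth, dtype=float)
    nf_L = cells_per_fluid_m3(nf, col.porosity)
    nm_L = cells_per_fluid_m3(nm, col.porosity)
    w = (1.0 - state.S) if occupancy else 1.0

    dt_s = dt_yr * SECONDS_PER_YEAR
    kmax = max_rate_constant(state, rc, nf_L, nm_L)
    if method == "auto":
        method = "rk2" if kmax * dt_s <= _STIFF_SWITCH else "exact"

    y = [state.P.copy(), state.H.copy(), state.L.copy(), state.E.copy(),
         state.M.copy(), state.G.copy(), state.E_dead.copy()]
    if method == "exact":
        _integrate_exact(y, rc, nf_L, nm_L, w, dt_s, guard)
    else:
        n_sub = max(1, int(np.ceil(kmax * dt_s / guard)))
        h = dt_s / n_sub
        for _ in range(n_sub):
            k1 = _rhs(y[0], y[1], y[2], y[3], rc, nf_L, nm_L, w)
            mid = [yi + 0.5 * h * ki for yi, ki in zip(y, k1)]
            # midpoint can only undershoot by O(h^2); clamp before re-evaluating
            for i in range(4):
                np.maximum(mid[i], 0.0, out=mid[i])
            k2 = _rhs(mid[0], mid[1], mid[2], mid[3], rc, nf_L, nm_L, w)
            y = [yi + h * ki for yi, ki in zip(y, k2)]

    scale = max(float(state.P.max(initial=0.0)),
                float(state.H.max(initial=0.0)), 1.0)
    for i, arr in enumerate(y):
        neg = arr < 0
        if np.any(neg):
            worst = float(arr[neg].min())
            if worst < -_NEG_CLAMP_REL * scale:
                raise RuntimeError(
                    f"reaction integrator produced negative value {worst:g} "
                    f"(pool index {i}); reduce dt")
            np.maximum(arr, 0.0, out=arr)

    out = state.copy()
    out.P, out.H, out.L, out.E, out.M, out.G, out.E_dead = y
    out.t = state.t + dt_yr
    return out
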