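"""Implicit solute diffusion: the first and third fractional steps.

The four solutes (HMW-DOC, LMW-DOC, enzymes, methane) diffuse over a half
time step with a Crank-Nicolson discretization. The closed-system
zero-gradient (Neumann) boundaries are imposed by mirrored ghost nodes:
on the cell-centered grid the mirror image of the first node coincides
with the node itself, so the boundary row reduces to the exact zero-flux
finite-volume form. That keeps the scheme second-order at the walls and
conserves the discrete mass exactly. POC, hydrate and the cumulative
ledgers are immobile solid phases and are never diffused.

When hydrate occupies part of the pore space, solutes are stored in and
fluxed through the remaining fluid fraction ``A = 1 - S``:

    A dC/dt = d/dz [ D A dC/dz ]

discretized in conservative (finite-volume) form with arithmetic-mean
face coefficients; the conserved discrete mass is then ``sum(A*C)*dz``.
With ``A = 1`` everywhere this reduces to the ordinary heat equation and
mass ``sum(C)*dz``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_core import SECONDS_PER_YEAR, ColumnState, TransportParams


@dataclass
class TridiagonalSystem:
    """Banded linear system ``A x = rhs`` with three diagonals.

    ``lower[0]`` and ``upper[-1]`` are unused padding so that all four
    arrays share the node count.
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    rhs: np.ndarray


def solve_tridiagonal(sys: TridiagonalSystem) -> np.ndarray:
    """Solve a tridiagonal system (Thomas-algorithm contract).

    Delegates to LAPACK via :func:`scipy.linalg.solve_banded`; raises on a
    singular pivot.
    """
    n = len(sys.diag)
    if n < 1:
        raise ValueError("system dimension must be >= 1")
    if n == 1:
        if sys.diag[0] == 0:
            raise np.linalg.LinAlgError("zero pivot in 1x1 system")
        return np.array([sys.rhs[0] / sys.diag[0]])
    ab = np.zeros((3, n))
    ab[0, 1:] = sys.upper[:-1]
    ab[1, :] = sys.diag
    ab[2, :-1] = sys.lower[1:]
    return scipy.linalg.solve_banded((1, 1), ab, sys.rhs)


def _flux_bands(n: int, storage: np.ndarray | None):
    """Bands of the conservative flux operator ``d/dz [A d/dz]`` (1/dz^2
    factored out) with zero-flux walls.

    ``storage`` is the per-node fluid fraction A (None means 1). Face
    coefficients are arithmetic means of the adjacent nodes; the wall
    faces carry zero flux, which makes every column sum to zero — the
    discrete conservation property.
    """
    if storage is None:
        a_face = np.ones(n - 1)
    else:
        a_face = 0.5 * (storage[:-1] + storage[1:])
    lower = np.zeros(n)
    upper = np.zeros(n)
    diag = np.zeros(n)
    lower[1:] = a_face
    upper[:-1] = a_face
    diag[:-1] -= a_face
    diag[1:] -= a_face
    return lower, diag, upper


def _tridiag_matvec(lower, diag, upper, x):
    y = diag * x
    y[:-1] += upper[:-1] * x[1:]
    y[1:] += lower[1:] * x[:-1]
    return y


def diffuse_half_step(field: np.ndarray, D: float, dz: float,
                      dt_half_yr: float, theta: float = 0.5,
                      storage: np.ndarray | None = None) -> np.ndarray:
    """Advance one solute over a half time step of diffusion.

    Parameters
    ----------
    field : ndarray
        Per-node concentration, mM (per fluid volume).
    D : float
        Effective sediment diffusivity, m2/s.
    dz : float
        Node spacing, m.
    dt_half_yr : float
        Half time step, years.
    theta : float
        Implicitness: 0.5 is Crank-Nicolson (default), 1.0 backward Euler
        (first-order fallback for monotonicity-sensitive runs).
    storage : ndarray, optional
        Per-node fluid fraction ``1 - S`` (strictly positive). Omitted
        means a fully open pore.
    """
    field = np.asarray(field, dtype=float)
    if np.any(~np.isfinite(field)):
        raise ValueError("non-finite value in diffused field")
    if D < 0:
        raise ValueError("diffusivity must be non-negative")
    if D == 0.0 or dt_half_yr == 0.0:
        return field.copy()
    n = len(field)
    A = np.ones(n) if storage is None else np.asarray(storage, dtype=float)
    if np.any(A <= 0):
        raise ValueError("storage (fluid fraction) must be strictly positive")
    r = D * dt_half_yr * SECONDS_PER_YEAR / dz**2
    lo, di, up = _flux_bands(n, storage)
    rhs = _tridiag_matvec((1 - theta) * r * lo,
                          A + (1 - theta) * r * di,
                          (1 - theta) * r * up, field)
    return solve_tridiagonal(TridiagonalSystem(
        lower=-theta * r * lo, diag=A - theta * r * di,
        upper=-theta * r * up, rhs=rhs))


def solute_mass(field: np.ndarray, dz: float,
                storage: np.ndarray | None = None) -> float:
    """Discrete solute mass, the diffusion invariant.

    ``sum(field) * dz`` for an open pore; ``sum(storage * field) * dz``
    when a fluid-fraction storage array is in effect.
    """
    if storage is None:
        return float(dz * field.sum())
    return float(dz * (storage * field).sum())


class DiffusionKernel:
    """Assembled Crank-Nicolson half-step for the four solutes at once.

    The four tridiagonal systems are stacked into one block-diagonal
    banded system (the off-diagonal entries joining blocks are zero), so
    each half step costs a single LAPACK banded solve. The kernel is
    cheap to assemble and is rebuilt by the simulator whenever the
    hydrate storage field changes.
    """

    SOLUTES = ("H", "L", "E", "M")

    def __init__(self, n: int, dz: float, dt_half_yr: float,
                 tp: TransportParams, theta: float = 0.5,
                 storage: np.ndarray | None = None):
        self.n = n
        ds = {"H": tp.D_hmw, "L": tp.D_lmw, "E": tp.D_enz, "M": tp.D_ch4}
        A = np.ones(n) if storage is None else np.asarray(storage, dtype=float)
        lo, di, up = _flux_bands(n, storage)
        N = 4 * n
        a_lo = np.zeros(N); a_di = np.zeros(N); a_up = np.zeros(N)
        b_lo = np.zeros(N); b_di = np.zeros(N); b_up = np.zeros(N)
        for k, sol in enumerate(self.SOLUTES):
            r = ds[sol] * dt_half_yr * SECONDS_PER_YEAR / dz**2
            sl = slice(k * n, (k + 1) * n)
            a_lo[sl] = -theta * r * lo
            a_di[sl] = A - theta * r * di
            a_up[sl] = -theta * r * up
            b_lo[sl] = (1 - theta) * r * lo
            b_di[sl] = A + (1 - theta) * r * di
            b_up[sl] = (1 - theta) * r * up
        # block boundaries are already decoupled (_flux_bands zeroes the
        # first lower / last upper entries), but make it explicit
        for k in range(1, 4):
            a_lo[k * n] = a_up[k * n - 1] = 0.0
            b_lo[k * n] = b_up[k * n - 1] = 0.0
        self._ab = np.zeros((3, N))
        self._ab[0, 1:] = a_up[:-1]
        self._ab[1, :] = a_di
        self._ab[2, :-1] = a_lo[1:]
        self._b = (b_lo, b_di, b_up)

    def apply(self, H, L, E, M):
        """Return the four solute fields advanced by one half step."""
        x = np.concatenate([H, L, E, M])
        rhs = _tridiag_matvec(*self._b, x)
        out = scipy.linalg.solve_banded((1, 1), self._ab, rhs,
                                        overwrite_ab=False, overwrite_b=True,
                                        check_finite=False)
        n = self.n
        return out[:n], out[n:2 * n], out[2 * n:3 * n], out[3 * n:]


def diffuse_all(state: ColumnState, tp: TransportParams, dz: float,
                dt_half_yr: float, kernel: DiffusionKernel | None = None,
                theta: float = 0.5, occupancy: bool = True) -> ColumnState:
    """Diffuse the four solutes of a column state over a half time step.

    POC, hydrate saturation and the cumulative ledgers are immobile.
    With ``occupancy`` (default) the solutes are stored in and fluxed
    through the hydrate-free fluid fraction. A prebuilt
    :class:`DiffusionKernel` (with matching storage!) may be passed to
    avoid matrix reassembly inside the time loop.
    """
    out = state.copy()
    if kernel is None:
        storage = (1.0 - state.S) if occupancy and np.any(state.S > 0) else None
        kernel = DiffusionKernel(len(state.S), dz, dt_half_yr, tp, theta,
                                 storage)
    out.H, out.L, out.E, out.M = kernel.apply(state.H, state.L,
                                              state.E, state.M)
    return out
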