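"""Rate-constant grid sweeps and constraint-region extraction.

The two POC hydrolysis / fermentation rate constants are not
independently known; following the calibration approach behind the site
presets, a scenario is re-run on a log10 grid of (K_eh, K_fm) with
K_m tied to K_fm, each grid point is reduced to summary metrics, and
named constraint predicates on those metrics carve out the admissible
region of parameter space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import logger
from .simulator import Scenario, doc_max_after, run_scenario, summarize

#: metric keys available to constraint predicates (see ``point_metrics``).
METRIC_KEYS = ("max_doc", "max_sh_sand_final", "max_sh_sand_overall",
               "onset_burial_m", "onset_time_kyr", "max_sh_mud_overall",
               "hfz_above_m", "hfz_below_m", "top_hydrate_depth_m")


@dataclass(frozen=True)
class Constraint:
    """Named comparison on a metric key: ``metric op value``."""

    name: str
    metric: str
    op: str          # one of <, <=, >, >=, between
    value: float
    value_hi: float = float("nan")

    def holds(self, metrics: dict) -> bool:
        x = metrics.get(self.metric, float("nan"))
        if not np.isfinite(x):
            return False
        if self.op == "<":
            return x < self.value
        if self.op == "<=":
            return x <= self.value
        if self.op == ">":
            return x > self.value
        if self.op == ">=":
            return x >= self.value
        if self.op == "between":
            return self.value <= x <= self.value_hi
        raise ValueError(f"unknown constraint op {self.op!r}")


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a (K_eh, K_fm) sweep.

    Grids are in log10 of the rate constants. ``fast`` runs grid points
    at halved resolution (dz and dt doubled) for speed; the star point —
    if it coincides with a grid point — is re-run at full fidelity.
    """

    base: Scenario
    log10_keh: tuple          # (min, max, n)
    log10_kfm: tuple          # (min, max, n)
    constraints: tuple = ()
    star: tuple | None = None  # (log10_keh, log10_kfm) annotation
    fast: bool = True

    def axes(self):
        amin, amax, an = self.log10_keh
        bmin, bmax, bn = self.log10_kfm
        return (np.linspace(amin, amax, int(an)),
                np.linspace(bmin, bmax, int(bn)))


@dataclass
class SweepResult:
    """Metrics table, constraint mask and provenance of one sweep."""

    spec: SweepSpec
    table: pd.DataFrame       # one row per grid point
    mask: np.ndarray          # (n_keh, n_kfm) boolean
    failures: list = field(default_factory=list)

    def metric_grid(self, key: str) -> np.ndarray:
        keh_ax, kfm_ax = self.spec.axes()
        return self.table[key].to_numpy().reshape(len(keh_ax), len(kfm_ax))


def point_metrics(scn: Scenario) -> dict:
    """Run one scenario and reduce it to the sweep metric set."""
    res = run_scenario(scn)
    m = summarize(res)
    m["doc_after_400kyr"] = doc_max_after(res, 4.0e5)
    return m


def _fast_variant(scn: Scenario) -> Scenario:
    col = dataclasses.replace(scn.column, dz=2.0 * scn.column.dz)
    return scn.with_(column=col, dt=2.0 * scn.dt)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the full grid; individual failures are recorded, not fatal."""
    keh_ax, kfm_ax = spec.axes()
    rows, failures = [], []
    for a in keh_ax:
        for b in kfm_ax:
            rc = dataclasses.replace(spec.base.rates, K_eh=10.0**a,
                                     K_fm=10.0**b, K_m=10.0**b)
            is_star = (spec.star is not None
                       and np.isclose(a, spec.star[0])
                       and np.isclose(b, spec.star[1]))
            scn = spec.base.with_(rates=rc)
            if spec.fast and not is_star:
                scn = _fast_variant(scn)
            row = {"log10_keh": a, "log10_kfm": b, "star": is_star,
                   "fidelity": "full" if (is_star or not spec.fast) else "fast"}
            try:
                row.update(point_metrics(scn))
                row["ok"] = True
            except Exception as exc:  # keep sweeping
                logger.warning("sweep point (%g, %g) failed: %s", a, b, exc)
                failures.append((a, b, str(exc)))
                row["ok"] = False
            rows.append(row)
    table = pd.DataFrame(rows)
    mask = np.array([
        bool(r.get("ok")) and all(c.holds(r) for c in spec.constraints)
        for r in rows]).reshape(len(keh_ax), len(kfm_ax))
    return SweepResult(spec=spec, table=table, mask=mask, failures=failures)


def constraint_region(result: SweepResult, constraints=None):
    """Boolean mask plus its boundary traced on the grid.

    Returns ``(mask, boundary)``. The boundary is a list of
    ``(log10_keh, log10_kfm)`` grid points that satisfy the constraints
    but have at least one non-satisfying (or off-grid) 4-neighbor —
    a marching-squares-style outline on the sample lattice. The result
    also notes whether the region touches the high-K_fm grid edge (the
    admissible region is then open in that direction).
    """
    spec = result.spec
    cons = tuple(constraints) if constraints is not None else spec.constraints
    keh_ax, kfm_ax = spec.axes()
    if constraints is None:
        mask = result.mask
    else:
        rows = result.table.to_dict("records")
        mask = np.array([bool(r.get("ok")) and all(c.holds(r) for c in cons)
                         for r in rows]).reshape(len(keh_ax), len(kfm_ax))

    boundary = []
    ni, nj = mask.shape
    for i in range(ni):
        for j in range(nj):
            if not mask[i, j]:
                continue
            edge = (i == 0 or i == ni - 1 or j == 0 or j == nj - 1
                    or not mask[i - 1, j] or not mask[i + 1, j]
                    or not mask[i, j - 1] or not mask[i, j + 1])
            if edge:
                boundary.append((keh_ax[i], kfm_ax[j]))
    if not boundary:
        logger.warning("constraint region is empty")
    open_high_kfm = bool(mask[:, -1].any())
    return mask, {"boundary": boundary, "open_high_kfm": open_high_kfm}
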