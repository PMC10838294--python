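"""Shared fixtures: cached preset runs and a fast synthetic scenario."""

import pytest
from hypothesis import HealthCheck, settings

from sandhydrate import (BurialTrajectory, ColumnSpec, RateConstants, Scenario,
                         SolubilityModel, TransportParams, preset,
                         run_scenario, summarize)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_mini(**overrides) -> Scenario:
    """Small, fast scenario (~0.3 s): 2 m of mud around a 0.6 m sand bed.

    The solubility anchor is set high enough that no hydrate ever forms,
    so the default mini run stays in the smooth hydrate-free regime;
    tests that need hydrate lower ``solubility`` explicitly.
    """
    kw = dict(
        column=ColumnSpec(domain_length=2.0, sand_thickness=0.6, dz=0.1,
                          n_sand=1.0e9, n_mud=1.0e6, poc_mud_wt=0.5),
        rates=RateConstants(K_eh=10**-12.6, K_fm=10**-21.5, K_m=10**-21.5,
                            epsilon=0.04),
        transport=TransportParams(D_hmw=5.0e-11, D_lmw=1.0e-10,
                                  D_enz=2.5e-11, D_ch4=1.0e-10),
        burial=BurialTrajectory(sed_rate=1.0),
        solubility=SolubilityModel(c_ref=5000.0, d_scale=500.0),
        name="mini", dt=50.0, t_end=5.0e4, series_interval=500.0)
    kw.update(overrides)
    return Scenario(**kw)


@pytest.fixture(scope="session")
def wr_result():
    return run_scenario(preset("wr313h"))


@pytest.fixture(scope="session")
def u1325_result():
    return run_scenario(preset("u1325"))


@pytest.fixture(scope="session")
def wr_metrics(wr_result):
    return summarize(wr_result)


@pytest.fixture(scope="session")
def wr_metrics_290(wr_result):
    """Metrics with the mud-saturation snapshot taken near 290 m burial."""
    return summarize(wr_result, snapshot_burial_m=290.0)


@pytest.fixture(scope="session")
def u1325_metrics(u1325_result):
    return summarize(u1325_result)
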