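"""Shared fixtures: a small simulated panel, kernels and a balanced design.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

import gxeblup as gx


@pytest.fixture(scope="session")
def small_design():
    return gx.complete_design(30, countries=["Norway", "Sweden", "Denmark"],
                              years=[2015, 2016])


@pytest.fixture(scope="session")
def small_panel(small_design):
    depths, truth, subpop = gx.simulate_population(
        n_accessions=30, n_markers=400, n_subpops=3, divergence=0.03,
        depth_mean=40, seed=11, accession_labels=small_design.accessions)
    freq = gx.estimate_frequencies(depths)
    filtered, _ = gx.filter_markers(depths, freq)
    complete = gx.impute_missing(filtered)
    return {"depths": depths, "freq": complete, "truth": truth,
            "subpop": subpop}


@pytest.fixture(scope="session")
def kernels(small_panel, small_design):
    freq = small_panel["freq"]
    G_A = gx.additive_kernel(freq)
    G_D = gx.dominance_kernel(freq)
    weather = gx.simulate_weather(small_design, seed=12)
    windows = gx.build_windows("TDM3", 2016)
    harvest_years = {c.name: small_design.years for c in small_design.countries}
    rn = gx.rn_features(weather, windows, harvest_years,
                        ["tmean", "tmin", "tmax", "precipitation", "radiation"])
    E = gx.env_kernel(rn)
    return {"G_A": G_A, "G_D": G_D, "E": E, "rn": rn, "weather": weather,
            "windows": windows, "harvest_years": harvest_years}


@pytest.fixture(scope="session")
def stage2_data(small_design, kernels):
    y, index, truth = gx.simulate_stage2(
        small_design, "TDM3", kernels["G_A"], kernels["E"], kernels["G_D"],
        varcomp={"A": 0.35, "Env": 0.02, "AxEnv": 0.18, "D": 0.15,
                 "DxEnv": 0.17, "residual": 0.15},
        seed=13)
    return {"y": y, "index": index, "truth": truth}
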