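"""Shared fixtures: small synthetic worlds and simulations, generated at test time."""

import numpy as np
import pandas as pd
import pytest

import sealforage as sf


@pytest.fixture(scope="session")
def small_seascape():
    return sf.make_seascape(sf.SeascapeParams(extent_km=60, cell_km=2, n_haulouts=2), seed=3)


@pytest.fixture(scope="session")
def small_sim(small_seascape):
    pref = sf.TruePreference(beta_bathy=-0.05, haulout_decay_km=20.0, phi=0.5)
    return sf.simulate_seals(small_seascape, pref, n_seals=3, n_trips_per_seal=3, seed=11)


@pytest.fixture(scope="session")
def classified_sim(small_seascape):
    """Larger simulation with scored + classified + located dives attached."""
    pref = sf.TruePreference(beta_bathy=-0.08, haulout_decay_km=20.0, phi=0.4)
    sim = sf.simulate_seals(small_seascape, pref, n_seals=4, n_trips_per_seal=6, seed=29,
                            config=sf.SimConfig(mean_dives_per_trip=30))
    scored = sf.score_dives(sf.prefilter(sim.dives))
    classified = sf.classify_all(scored)
    located = sf.interpolate_dive_locations(classified, sim.fixes)
    return sim, located


@pytest.fixture(scope="session")
def ua_table(small_seascape, classified_sim):
    """Use-availability table built through the geospatial stages."""
    sc = small_seascape
    sim, located = classified_sim
    graph = sf.SeaGraph(sc)
    foraging = located.loc[located["foraging"]].rename(columns={"seal": "individual"})
    hull = sf.mcp(located[["x", "y"]].to_numpy())
    region = sf.availability_region(hull, sc.shelf_polygon, sc.land_polygon)
    absences = sf.sample_pseudo_absences(region, foraging.groupby("individual").size(), seed=5)
    fcov = sf.extract_covariates(foraging[["individual", "dive_id", "x", "y"]], sc, graph)
    acov = sf.extract_covariates(absences, sc, graph)
    return sf.build_table(fcov, acov)


def make_dive(seal="S00", start="2010-03-05T00:00:00", duration_s=300.0, max_depth_m=50.0,
              times=None, depths=None, dive_id="D0"):
    """One dive-table row; default profile is a square dive."""
    if times is None:
        times = np.linspace(duration_s * 0.1, duration_s * 0.9, 9)
    if depths is None:
        depths = np.full(9, max_depth_m)
    row = {"seal": seal, "dive_id": dive_id, "start": pd.Timestamp(start),
           "end": pd.Timestamp(start) + pd.Timedelta(seconds=duration_s),
           "duration_s": duration_s, "max_depth_m": max_depth_m}
    row.update({f"t{i+1}": times[i] for i in range(9)})
    row.update({f"d{i+1}": depths[i] for i in range(9)})
    return row


def random_profiles(rng, n, v_max=2.0):
    """Random valid scorable dive profiles (duration 60-1200 s, depth 5-200 m)."""
    rows = []
    for i in range(n):
        T = rng.uniform(60, 1200)
        D = rng.uniform(5, min(200.0, v_max * T / 2 - 1.0))
        ts = np.sort(rng.uniform(1e-3 * T, T * (1 - 1e-3), 9))
        while np.any(np.diff(ts) <= 0):
            ts = np.sort(rng.uniform(1e-3 * T, T * (1 - 1e-3), 9))
        ds = rng.uniform(0, D, 9)
        ds[rng.integers(9)] = D
        rows.append(make_dive(duration_s=T, max_depth_m=D, times=ts, depths=ds,
                              dive_id=f"R{i}"))
    return pd.DataFrame(rows)
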