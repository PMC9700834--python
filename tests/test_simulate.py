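"""The synthetic-data generator: grid geometry, exact ICAR sampling,
dataset generation and the descriptive-margins fixture."""

import warnings

import numpy as np
import pytest

from carmap.cohort import descriptive_table, tabulate_counts
from carmap.geo import queen_adjacency
from carmap.simulate import (SimulationParams, make_grid_geometry,
                             sample_icar_field, simulate_dataset)
from carmap.table1 import PERIOD_TOTALS, TABLE1_MARGINS, table1_fixture


# ------------------------------------------------------------- geometry
def test_2x2_grid_queen_complete():
    A = queen_adjacency(make_grid_geometry(2, 2))
    assert int(A.weights.sum()) // 2 == 6  # complete graph K4


def test_8x9_grid_edge_count():
    A = queen_adjacency(make_grid_geometry(8, 9))
    assert A.n == 72
    assert int(A.weights.sum()) // 2 == 8 * 8 + 9 * 7 + 2 * 7 * 8  # 239


def test_1x1_grid_single_island():
    with pytest.warns(UserWarning):
        A = queen_adjacency(make_grid_geometry(1, 1))
    assert A.islands == {"Z_0_0"}


# ----------------------------------------------------------- ICAR draws
def test_icar_draw_sums_to_zero():
    A = queen_adjacency(make_grid_geometry(4, 4))
    rng = np.random.default_rng(0)
    for _ in range(10):
        u = sample_icar_field(A, 0.7, rng)
        assert abs(u.sum()) < 1e-10


def test_icar_zero_scale_gives_zero_field():
    A = queen_adjacency(make_grid_geometry(3, 3))
    u = sample_icar_field(A, 0.0, np.random.default_rng(1))
    assert (u == 0).all()


def test_icar_disconnected_requires_flag():
    zones = make_grid_geometry(1, 2) + make_grid_geometry(1, 1)
    for i, z in enumerate(zones):
        z.zone_id = f"A{i}"
    zones[2].geometry = zones[2].geometry.buffer(0)  # keep as-is
    from shapely import affinity

    zones[2] = type(zones[2])("A2", affinity.translate(zones[2].geometry, 10, 10))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A = queen_adjacency(zones)
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="component"):
        sample_icar_field(A, 0.5, rng)
    u = sample_icar_field(A, 0.5, rng, per_component=True)
    assert abs(u[:2].sum()) < 1e-10  # each component centred


def test_icar_covariance_matches_pseudoinverse_on_path():
    """Empirical covariance of exact draws vs sigma^2 * Laplacian
    pseudoinverse (the constrained ICAR covariance)."""
    # a 1 x 5 path has rook = queen contiguity: a path graph
    zones = make_grid_geometry(1, 5)
    A = queen_adjacency(zones)
    sigma = 0.8
    rng = np.random.default_rng(3)
    draws = np.array([sample_icar_field(A, sigma, rng) for _ in range(10000)])
    W = A.weights.astype(float)
    L = np.diag(W.sum(axis=1)) - W
    target = sigma ** 2 * np.linalg.pinv(L)
    emp = np.cov(draws.T)
    scale = np.abs(target).max()
    assert np.abs(emp - target).max() < 0.1 * scale


# -------------------------------------------------------------- datasets
def test_simulation_deterministic():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = simulate_dataset(SimulationParams(rows=3, cols=3, seed=5))
        b = simulate_dataset(SimulationParams(rows=3, cols=3, seed=5))
    assert a.records.equals(b.records)
    assert np.array_equal(a.counts.O, b.counts.O)
    assert a.truth["beta"] == b.truth["beta"]


def test_null_simulation_recovers_baseline_rate():
    params = SimulationParams(rows=4, cols=4, alpha=0.0, beta1=0.0,
                              beta={k: 0.0 for k in SimulationParams().beta},
                              sigma_u=0.0, sigma_v=0.0, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate_dataset(params)
    rate = sim.counts.O.sum() / sim.counts.n.sum()
    n_tot = sim.counts.n.sum()
    se = np.sqrt(0.55 * 0.45 / n_tot)
    assert abs(rate - 0.55) < 4 * se


def test_positive_trend_raises_late_period_rate():
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(8):
            # covariate effects zeroed to isolate the time trend (a steep
            # trend on top of the default effects would be infeasible)
            sim = simulate_dataset(SimulationParams(
                rows=4, cols=4, beta1=0.2,
                beta={k: 0.0 for k in SimulationParams().beta}, seed=seed))
            r1 = sim.counts.O[:, 0].sum() / sim.counts.n[:, 0].sum()
            r3 = sim.counts.O[:, 2].sum() / sim.counts.n[:, 2].sum()
            hits += r3 > r1
    assert hits == 8


def test_records_round_trip_through_tabulation(small_sim):
    sim = small_sim
    C = tabulate_counts(sim.records, [z.zone_id for z in sim.zones],
                        list(sim.counts.periods))
    assert np.array_equal(C.O, sim.counts.O)
    assert np.array_equal(C.n, sim.counts.n)


def test_infeasible_parameters_rejected():
    big = {k: 1.5 for k in SimulationParams().beta}
    with pytest.raises(ValueError, match="rate above 1"):
        simulate_dataset(SimulationParams(rows=3, cols=3, beta=big,
                                          baseline_rate=0.9, seed=0))


def test_truth_manifest_complete(small_sim):
    truth = small_sim.truth
    for key in ("alpha", "alpha_uncentred", "beta1", "beta", "u", "v",
                "sigma_u", "sigma_v", "seed"):
        assert key in truth
    assert abs(np.sum(truth["u"])) < 1e-8


def test_write_outputs_round_trip(tmp_path, small_sim):
    from carmap.geo import read_geojson

    paths = small_sim.write(tmp_path)
    zones = read_geojson(paths["geojson"])
    assert [z.zone_id for z in zones] == [z.zone_id for z in small_sim.zones]
    import pandas as pd

    recs = pd.read_csv(paths["records"])
    assert len(recs) == len(small_sim.records)


# ------------------------------------------------------- table-1 fixture
def test_fixture_period_totals():
    recs = table1_fixture()
    assert len(recs) == 18939
    counts = recs.groupby("survey_year").size()
    for per, tot in PERIOD_TOTALS.items():
        assert counts[per] == tot


def test_fixture_margins_match_printed_counts_cell_by_cell():
    recs = table1_fixture()
    tab = descriptive_table(recs)
    for var, cats in TABLE1_MARGINS.items():
        for cat, per_counts in cats.items():
            for per, expected in zip((2005, 2011, 2016), per_counts):
                got = tab[(tab["variable"] == var) & (tab["category"] == cat)
                          & (tab["period"] == per)]["count"].iloc[0]
                assert got == expected, (var, cat, per)


def test_fixture_anemic_total():
    recs = table1_fixture()
    anemic = recs["anemia_level"].isin(["severe", "moderate", "mild"]).sum()
    assert anemic == 10393


def test_fixture_2005_anemia_severity_counts():
    recs = table1_fixture()
    y05 = recs[recs["survey_year"] == 2005]["anemia_level"].value_counts()
    assert y05["severe"] == 150 and y05["moderate"] == 943 and y05["mild"] == 723


def test_fixture_tabulates_over_74_zones():
    recs = table1_fixture()
    zones = sorted(recs["zone_id"].unique())
    assert len(zones) == 74
    C = tabulate_counts(recs, zones, [2005, 2011, 2016])
    assert C.O.sum() == 10393
    assert C.n.sum() == 18939
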