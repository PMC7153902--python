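"""FES estimation: KDE, reweighting, checkpoints, basins, barriers."""

import math

import numpy as np
import pytest
from scipy.special import erf

from hingedyn.fes import (
    DisconnectedBasinsError,
    FreeEnergySurface,
    barrier_between,
    basin_errors,
    density_to_fes,
    fes_checkpoints,
    find_minimum,
    grid_edges,
    kde_histogram,
    reweight_biased,
    write_fes_dat,
)
from hingedyn.hinge_model import KB, HingeParams, langevin_run, potential_grid
from hingedyn.model_io import CVSeries


def _series(values, names=("x",), units=("nm",), bias=None):
    values = np.asarray(values, dtype=float).reshape(len(values), -1)
    if bias is not None:
        values = np.column_stack([values, bias])
        names = list(names) + ["bias"]
        units = list(units) + ["kJ/mol"]
    return CVSeries(names=list(names), units=list(units),
                    times=np.arange(len(values), dtype=float),
                    values=values)


# ---------------------------------------------------------------------------
# kde_histogram
# ---------------------------------------------------------------------------

def test_kde_single_point_normalized():
    s = _series([[1.0]])
    edges = [np.linspace(0, 2, 51)]
    for bw in (0.01, 0.1, 0.5):
        dens = kde_histogram(s, edges=edges, bandwidth=bw)
        assert dens.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dens >= 0)


def test_kde_weights_equal_duplication():
    """Duplicating points equals doubling their weights."""
    pts = [[0.5], [1.0], [1.5]]
    edges = [np.linspace(0, 2, 41)]
    dup = kde_histogram(_series(pts + pts), edges=edges)
    weighted = kde_histogram(_series(pts), weights=np.full(3, 2.0),
                             edges=edges)
    np.testing.assert_allclose(dup, weighted, atol=1e-12)


def test_kde_grid_mean_matches_sample_moment(rng):
    x = rng.normal(1.2, 0.2, size=1000)
    s = _series(x[:, None])
    edges = [np.linspace(0, 2.4, 241)]
    dens = kde_histogram(s, edges=edges, bandwidth=0.01)
    centers = 0.5 * (edges[0][1:] + edges[0][:-1])
    grid_mean = float((dens * centers).sum())
    se = 0.2 / math.sqrt(1000)
    assert abs(grid_mean - 1.2) < 3 * se


def test_kde_empty_series_error():
    s = CVSeries(names=["x"], units=["nm"], times=np.empty(0),
                 values=np.empty((0, 1)))
    with pytest.raises(ValueError):
        kde_histogram(s, edges=[np.linspace(0, 1, 11)])


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------

def test_zero_bias_gives_unit_weights():
    s = _series([[0.5], [1.0], [1.5]], bias=[0.0, 0.0, 0.0])
    res = reweight_biased(s, 300.0, mode="instantaneous")
    np.testing.assert_array_equal(res.weights, np.ones(3))
    assert res.n_eff == pytest.approx(3.0)


def test_bias_difference_of_kbt_gives_weight_ratio_e():
    kt = KB * 300.0
    s = _series([[0.5], [1.0]], bias=[0.0, kt])
    res = reweight_biased(s, 300.0, mode="instantaneous")
    assert res.weights[1] / res.weights[0] == pytest.approx(math.e,
                                                            rel=1e-12)


def test_umbrella_reweighting_recovers_unbiased_minimum():
    """A static linear umbrella on w shifts sampling; reweighting undoes it."""

    class LinearUmbrella:
        slope = 4.0  # kJ/mol/nm

        def grad(self, theta, w):
            return 0.0, self.slope

        def value(self, theta, w):
            return self.slope * w

    p = HingeParams(n_steps=400_000, stride=10, dt=0.001, seed=13)
    s = langevin_run(p, bias=LinearUmbrella())
    w = s.column("ww")
    res = reweight_biased(s, p.temperature, mode="instantaneous")
    # biased mean is shifted by -slope/k_w; the reweighted mean is not
    shift = LinearUmbrella.slope / p.twist_k
    assert abs(np.mean(w) - (p.twist_center - shift)) < 0.05
    rw_mean = float(np.sum(res.weights * w) / np.sum(res.weights))
    blocks = np.array_split(np.arange(len(w)), 20)
    bmeans = [np.sum(res.weights[b] * w[b]) / np.sum(res.weights[b])
              for b in blocks]
    se = np.std(bmeans, ddof=1) / math.sqrt(len(blocks))
    assert abs(rw_mean - p.twist_center) < 3 * se


def test_reweighting_missing_bias_errors():
    s = _series([[0.5]])
    with pytest.raises(KeyError):
        reweight_biased(s, 300.0, mode="instantaneous")
    with pytest.raises(ValueError):
        reweight_biased(s, 300.0, mode="final-bias")


# ---------------------------------------------------------------------------
# density -> FES
# ---------------------------------------------------------------------------

def test_uniform_density_flat_fes():
    dens = np.full(20, 1.0 / 20)
    fes = density_to_fes(dens, [np.linspace(0, 1, 21)], 300.0)
    np.testing.assert_allclose(fes.values, 0.0, atol=1e-12)


def test_density_ratio_e_gives_kbt():
    dens = np.array([math.e, 1.0])
    dens = dens / dens.sum()
    fes = density_to_fes(dens, [np.linspace(0, 1, 3)], 300.0)
    assert fes.values[0] == 0.0
    assert fes.values[1] == pytest.approx(KB * 300.0, rel=1e-12)


def test_unvisited_cells_masked_not_zero():
    dens = np.array([0.5, 0.5, 0.0])
    fes = density_to_fes(dens, [np.linspace(0, 1, 4)], 300.0)
    assert fes.mask[2]
    assert np.isnan(fes.values[2])


def test_boltzmann_samples_recover_hinge_potential():
    """Unbiased run: F(theta, w) matches min-shifted U in the well regions."""
    # ~400 ns: thousands of barrier crossings, so the well occupancies are
    # equilibrated and the histogram noise is well below the tolerance
    p = HingeParams(n_steps=40_000_000, stride=50, seed=42, barrier=2.0)
    s = langevin_run(p)
    edges = grid_edges([(40.0, 130.0), (0.6, 2.4)], 60)
    dens = kde_histogram(s, edges=edges, bandwidth=[1.5, 0.03],
                         cv_names=["theta", "ww"])
    fes = density_to_fes(dens, edges, p.temperature,
                         names=["theta", "ww"], units=["deg", "nm"])
    ct = fes.centers(0)
    cw = fes.centers(1)
    tt, wwg = np.meshgrid(ct, cw, indexing="ij")
    u = potential_grid(tt, wwg, p)
    u = u - u.min()
    # compare where the reference is low (well regions, good statistics)
    sel = (u < 4.0) & ~fes.mask
    assert sel.sum() > 100
    dev = np.abs(fes.values[sel] - u[sel])
    assert np.quantile(dev, 0.95) < 0.5


def test_reweighting_consistency_identity():
    """Unbiased series + reweighting equals the plain histogram exactly."""
    rng = np.random.default_rng(3)
    x = rng.normal(1.0, 0.3, size=500)
    edges = [np.linspace(0, 2, 41)]
    plain = _series(x[:, None])
    biased = _series(x[:, None], bias=np.zeros(500))
    res = reweight_biased(biased, 300.0, mode="instantaneous")
    d1 = kde_histogram(plain, edges=edges)
    d2 = kde_histogram(biased, weights=res.weights, edges=edges,
                       cv_names=["x"])
    np.testing.assert_allclose(d1, d2, atol=1e-12)
    f1 = density_to_fes(d1, edges, 300.0)
    f2 = density_to_fes(d2, edges, 300.0)
    np.testing.assert_allclose(f1.values[~f1.mask], f2.values[~f2.mask],
                               atol=1e-12)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _builder(edges):
    def build(sub):
        dens = kde_histogram(sub, edges=edges, cv_names=["x"])
        return density_to_fes(dens, edges, 300.0)
    return build


def test_identical_checkpoints_zero_deviation(rng):
    x = rng.normal(1.0, 0.2, size=400)
    s = _series(x[:, None])
    edges = [np.linspace(0, 2, 21)]
    # both checkpoints truncate beyond the data: identical surfaces
    surfaces, dev = fes_checkpoints(s, [400.0, 401.0], _builder(edges))
    assert dev[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_single_checkpoint_no_deviation(rng):
    s = _series(rng.normal(1.0, 0.2, size=100)[:, None])
    surfaces, dev = fes_checkpoints(s, [50.0], _builder(
        [np.linspace(0, 2, 21)]))
    assert len(surfaces) == 1
    assert dev is None


def test_longer_checkpoints_converge_more(rng):
    """For stationary data, late-vs-late deviation < early-vs-early."""
    x = rng.normal(1.0, 0.2, size=20_000)
    s = _series(x[:, None])
    edges = [np.linspace(0.2, 1.8, 33)]
    surfaces, dev = fes_checkpoints(
        s, [500.0, 1000.0, 16_000.0, 20_000.0], _builder(edges))
    assert dev[2, 3] < dev[0, 1]


def test_checkpoint_before_first_sample_errors(rng):
    s = _series(rng.normal(size=10)[:, None])
    with pytest.raises(ValueError):
        fes_checkpoints(s, [-5.0], _builder([np.linspace(-3, 3, 11)]))


# ---------------------------------------------------------------------------
# basin errors
# ---------------------------------------------------------------------------

def test_whole_domain_basin_zero_free_energy(rng):
    x = rng.normal(1.0, 0.2, size=100)
    s = _series(x[:, None])
    out = basin_errors(s, None, {"all": [(-10.0, 10.0)]}, n_blocks=5,
                       temperature=300.0)
    est = out["all"]
    assert est.free_energy == pytest.approx(0.0, abs=1e-12)
    assert est.error == pytest.approx(0.0, abs=1e-12)
    assert est.n_blocks_used == 5


def test_duplicated_series_zero_error(rng):
    x = rng.normal(1.0, 0.2, size=50)
    s = _series(np.concatenate([x, x])[:, None])
    out = basin_errors(s, None, {"left": [(-10.0, 1.0)]}, n_blocks=2,
                       temperature=300.0)
    assert out["left"].error == pytest.approx(0.0, abs=1e-12)


def test_half_domain_occupancy_matches_gaussian_tail():
    """Harmonic-well occupancy of w > w0 + d equals the erf tail mass."""
    p = HingeParams(n_steps=2_000_000, stride=20, dt=0.001, seed=33)
    s = langevin_run(p)
    sd = math.sqrt(KB * p.temperature / p.twist_k)
    d = 0.5 * sd
    basin = {"tail": [(0.0, 180.0), (p.twist_center + d, 10.0)]}
    out = basin_errors(s, None, basin, n_blocks=10,
                       temperature=p.temperature,
                       cv_names=["theta", "ww"])
    est = out["tail"]
    tail_mass = 0.5 * (1.0 - erf(d / (sd * math.sqrt(2.0))))
    expected_f = -KB * p.temperature * math.log(tail_mass)
    assert abs(est.free_energy - expected_f) < 3 * max(est.error, 1e-3)


# ---------------------------------------------------------------------------
# barriers
# ---------------------------------------------------------------------------

def _fes_1d(values, lo=0.0, hi=1.0, mask=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    return FreeEnergySurface(names=["x"], units=["nm"],
                             edges=[np.linspace(lo, hi, n + 1)],
                             values=values, temperature=300.0, mask=mask)


def test_flat_surface_zero_barrier():
    fes = _fes_1d(np.zeros(50))
    assert barrier_between(fes, [(0.0, 0.2)], [(0.8, 1.0)]) == 0.0


def test_double_well_barrier_closed_form():
    x = np.linspace(-1.5, 1.5, 601)
    centers = 0.5 * (x[1:] + x[:-1])
    b_true = 5.0
    profile = b_true * (centers ** 2 - 1.0) ** 2
    fes = FreeEnergySurface(names=["u"], units=["dimensionless"],
                            edges=[x], values=profile, temperature=300.0,
                            mask=np.zeros(len(centers), dtype=bool))
    est = barrier_between(fes, [(-1.2, -0.8)], [(0.8, 1.2)])
    cell = abs(profile[300] - profile[299]) + 1e-6
    assert abs(est - b_true) < max(0.05, 10 * cell)


def test_barrier_gauge_invariance():
    rng = np.random.default_rng(5)
    prof = rng.uniform(0, 3, size=100)
    prof[10] = 0.0
    a, b = [(0.05, 0.15)], [(0.85, 0.95)]
    f1 = _fes_1d(prof)
    f2 = _fes_1d(prof + 7.3)  # min-shift removes the constant again
    assert barrier_between(f1, a, b) == pytest.approx(
        barrier_between(f2, a, b), abs=1e-12)


def test_disconnected_basins_error():
    prof = np.zeros(30)
    mask = np.zeros(30, dtype=bool)
    mask[14:16] = True
    fes = _fes_1d(prof, mask=mask)
    with pytest.raises(DisconnectedBasinsError):
        barrier_between(fes, [(0.0, 0.2)], [(0.8, 1.0)])


def test_2d_minimax_path_goes_through_saddle():
    edges = grid_edges([(0.0, 1.0), (0.0, 1.0)], 41)
    cx = 0.5 * (edges[0][1:] + edges[0][:-1])
    cy = 0.5 * (edges[1][1:] + edges[1][:-1])
    xx, yy = np.meshgrid(cx, cy, indexing="ij")
    # two wells at (0.2, 0.5) and (0.8, 0.5); ridge at x=0.5 with a dip
    vals = 10.0 * (1.0 - np.exp(-((xx - 0.2) ** 2 + (yy - 0.5) ** 2) / 0.02)
                   - np.exp(-((xx - 0.8) ** 2 + (yy - 0.5) ** 2) / 0.02))
    vals += 5.0 * np.exp(-((xx - 0.5) ** 2) / 0.005) \
        * (1.0 - 0.8 * np.exp(-((yy - 0.3) ** 2) / 0.01))
    fes = FreeEnergySurface(names=["x", "y"], units=["nm", "nm"],
                            edges=edges, values=vals, temperature=300.0,
                            mask=np.zeros_like(vals, dtype=bool))
    barrier = barrier_between(fes, [(0.15, 0.25), (0.45, 0.55)],
                              [(0.75, 0.85), (0.45, 0.55)])
    # the minimax path must exploit the dip in the ridge at y ~ 0.3
    ridge_idx = np.argmin(np.abs(cx - 0.5))
    dip = vals[ridge_idx].min() - vals.min()
    full_ridge = vals[ridge_idx, np.argmin(np.abs(cy - 0.5))] - vals.min()
    assert barrier <= dip + 1.0
    assert barrier < full_ridge - 1.0


def test_find_minimum_windowed():
    fes = _fes_1d(np.array([3.0, 1.0, 0.0, 2.0, 0.5]))
    (loc,), val = find_minimum(fes)
    assert val == 0.0
    (loc,), val = find_minimum(fes, [(0.6, 1.0)])
    assert val == pytest.approx(0.5)


def test_write_fes_dat_round_trip_values(tmp_path):
    fes = _fes_1d(np.array([0.0, 1.0, 2.0]))
    path = tmp_path / "fes.dat"
    write_fes_dat(fes, str(path))
    data = np.loadtxt(path, comments="#")
    np.testing.assert_allclose(data[:, 1], [0.0, 1.0, 2.0], atol=1e-9)
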