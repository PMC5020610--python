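"""Reaction coordinates, free-energy surfaces, diagnostics, ladders."""

import numpy as np
import pytest

from dimerscope.ensemble_stats import (R_KCAL, LadderSpec, fes2d, find_basins,
                                       radius_of_gyration, replica_traversal,
                                       rg_series, split_half_convergence,
                                       temperature_ladder)
from dimerscope.model import Conformation


def test_rg_of_known_configuration():
    # two unit-mass points 2 apart about the origin: Rg = 1
    conf = Conformation(np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
    assert radius_of_gyration(conf, np.array([1.0, 1.0])) == pytest.approx(1.0)
    # unequal masses shift the centre: Rg = sqrt(m1 d1^2 + m2 d2^2 / M)
    rg = radius_of_gyration(conf, np.array([3.0, 1.0]))
    assert rg == pytest.approx(np.sqrt((3 * 0.5 ** 2 + 1 * 1.5 ** 2) / 4))
    with pytest.raises(ValueError):
        radius_of_gyration(conf, np.array([1.0, 1.0]), selection=np.array([], dtype=int))


def test_rg_series_matches_per_frame(small_dimer_ensemble):
    vals = rg_series(small_dimer_ensemble)
    masses = small_dimer_ensemble.topology.masses()
    direct = [radius_of_gyration(f, masses) for f in small_dimer_ensemble.frames]
    assert np.allclose(vals, direct)


def test_fes_masks_empty_bins_and_min_is_zero():
    rng = np.random.default_rng(0)
    samples = rng.normal(size=(500, 2))
    grid = fes2d(samples, bins=12, temperature_K=310.0)
    assert float(grid.G.min()) == pytest.approx(0.0, abs=1e-12)
    assert grid.G.mask.sum() > 0  # corners of a Gaussian histogram are empty
    # re-exponentiation returns the histogram probabilities
    assert np.allclose(grid.reprobability(), grid.probability, atol=1e-12)


def test_fes_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fes2d(np.zeros((0, 2)), bins=5)
    with pytest.raises(ValueError):
        # explicit zero-width bin edges
        fes2d(np.zeros((10, 2)),
              bins=(np.array([0.0, 0.0]), np.array([-0.5, 0.5])))


def test_basin_detection_two_well_surface():
    rng = np.random.default_rng(1)
    a = rng.normal([-2.0, 0.0], 0.3, size=(4000, 2))
    b = rng.normal([2.0, 0.0], 0.3, size=(2000, 2))
    grid = fes2d(np.vstack([a, b]), bins=30)
    basins = find_basins(grid, depth_threshold=0.5)
    assert len(basins) == 2
    # deepest first; well positions recovered
    assert basins[0][2] <= basins[1][2]
    xs = sorted(bx for bx, _, _ in basins)
    assert xs[0] == pytest.approx(-2.0, abs=0.4)
    assert xs[1] == pytest.approx(2.0, abs=0.4)


def test_single_well_has_one_basin():
    rng = np.random.default_rng(2)
    grid = fes2d(rng.normal(size=(3000, 2)), bins=20)
    assert len(find_basins(grid, depth_threshold=0.5)) == 1


def test_split_half_convergence_bounds(small_dimer_ensemble):
    out = split_half_convergence(small_dimer_ensemble, {"rg": rg_series})
    assert 0.0 <= out["rg"] <= 1.0
    broken = split_half_convergence(
        small_dimer_ensemble, {"bad": lambda e: 1 / 0})
    assert np.isnan(broken["bad"])


def test_identical_halves_have_zero_distance(small_dimer_ensemble):
    ens = small_dimer_ensemble
    doubled = ens.subset(list(range(ens.n_frames)) + list(range(ens.n_frames)))
    out = split_half_convergence(doubled, {"rg": rg_series})
    assert out["rg"] == pytest.approx(0.0, abs=1e-12)


def test_replica_traversal_counts_round_trips():
    # replica walks 0 -> top -> 0 twice, second replica never leaves middle
    s = np.array([[0, 1, 2, 3, 2, 1, 0, 1, 2, 3, 3, 2, 1, 0],
                  [1, 1, 2, 2, 1, 1, 2, 1, 1, 2, 1, 1, 2, 1]])
    trips = replica_traversal(s, n_replicas=4)
    assert list(trips) == [2, 0]
    with pytest.raises(ValueError):
        replica_traversal(np.array([[0, 4]]), n_replicas=4)


def test_temperature_ladder_constant_ratio_and_endpoints():
    T = temperature_ladder(LadderSpec(306.0, 409.0, 48))
    assert T[0] == 306.0 and T[-1] == 409.0
    ratios = T[1:] / T[:-1]
    assert np.allclose(ratios, ratios[0], rtol=1e-12)
    assert np.all(np.diff(T) > 0)
    with pytest.raises(ValueError):
        LadderSpec(400.0, 300.0, 8)
    with pytest.raises(ValueError):
        LadderSpec(300.0, 400.0, 1)


def test_fes_temperature_scaling():
    # doubling T doubles every free-energy difference
    samples = np.array([[0.0, 0.0]] * 3 + [[1.0, 0.0]])
    bins = (np.array([-0.5, 0.5, 1.5]), np.array([-0.5, 0.5]))
    g1 = fes2d(samples, bins=bins, temperature_K=300.0)
    g2 = fes2d(samples, bins=bins, temperature_K=600.0)
    d1 = float(g1.G[1, 0] - g1.G[0, 0])
    d2 = float(g2.G[1, 0] - g2.G[0, 0])
    assert d2 == pytest.approx(2 * d1)
    assert d1 == pytest.approx(R_KCAL * 300.0 * np.log(3.0))
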