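"""Superposition and clustering properties."""

import numpy as np
import pytest

from dimerscope.cluster import (ClusterResult, chain_independent_rmsd,
                                cluster_summary, daura_cluster,
                                kabsch_superpose, rmsd_matrix, superposed_rmsd)
from dimerscope.geometry import random_rotation


def _cloud(rng, n=40):
    return rng.normal(size=(n, 3))


def test_kabsch_identity_and_translation():
    rng = np.random.default_rng(1)
    X = _cloud(rng)
    R, t, rmsd = kabsch_superpose(X, X)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(R, np.eye(3), atol=1e-9)
    _, t2, rmsd2 = kabsch_superpose(X, X + [1.0, -2.0, 0.5])
    assert rmsd2 == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(t2, [1.0, -2.0, 0.5], atol=1e-9)


def test_kabsch_never_returns_reflection():
    rng = np.random.default_rng(2)
    X = _cloud(rng)
    Y = X.copy()
    Y[:, 0] = -Y[:, 0]  # mirror image: best proper rotation cannot reach 0
    R, _, rmsd = kabsch_superpose(Y, X)
    assert np.linalg.det(R) == pytest.approx(1.0)
    assert rmsd > 0.1


def test_kabsch_weighted_ignores_zero_weight_atoms():
    rng = np.random.default_rng(3)
    X = _cloud(rng)
    Y = X.copy()
    Y[-1] += 5.0  # outlier
    w = np.ones(len(X))
    w[-1] = 0.0
    assert superposed_rmsd(Y, X, w) == pytest.approx(0.0, abs=1e-12)


def test_kabsch_input_validation():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
    with pytest.raises(ValueError):
        kabsch_superpose(np.ones((4, 3)), np.ones((4, 3)), np.zeros(4))


def test_rmsd_is_a_pseudometric_on_frames(small_dimer_ensemble):
    M = rmsd_matrix(small_dimer_ensemble)
    n = len(M)
    assert np.allclose(M, M.T)
    assert np.all(np.diag(M) < 1e-9)
    assert np.all(M >= 0)
    # triangle inequality on all frame triples
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert M[i, j] <= M[i, k] + M[k, j] + 1e-9


def test_chain_swap_leaves_rmsd_unchanged(small_dimer_ensemble):
    ens = small_dimer_ensemble
    f0, f1 = ens.frames[0], ens.frames[1]
    d = chain_independent_rmsd(f0, f1, ens.topology)
    # permuting chain blocks of one frame must not change the distance
    top = ens.topology
    nA = top.chains[0].n_atoms
    swapped = f1.coords.copy()
    swapped[:nA], swapped[nA:] = f1.coords[nA:].copy(), f1.coords[:nA].copy()
    from dimerscope.model import Conformation
    d_sw = chain_independent_rmsd(f0, Conformation(swapped), ens.topology)
    assert d_sw == pytest.approx(d, abs=1e-9)


def test_daura_hand_worked_example():
    # 5 frames: {0,1,2} mutually close, {3,4} close, no cross links
    D = np.array([
        [0.0, 0.1, 0.2, 2.0, 2.0],
        [0.1, 0.0, 0.1, 2.0, 2.0],
        [0.2, 0.1, 0.0, 2.0, 2.0],
        [2.0, 2.0, 2.0, 0.0, 0.3],
        [2.0, 2.0, 2.0, 0.3, 0.0],
    ])
    res = daura_cluster(D, cutoff=0.35)
    assert res.n_clusters == 2
    # frames 0, 1, 2 all see {0,1,2}: ties resolve to the lowest index
    assert res.clusters[0][0] == 0
    assert sorted(res.clusters[0][1]) == [0, 1, 2]
    assert sorted(res.clusters[1][1]) == [3, 4]
    assert np.allclose(res.populations, [0.6, 0.4])
    assert list(res.labels()) == [0, 0, 0, 1, 1]


def test_daura_validates_matrix():
    with pytest.raises(ValueError):
        daura_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        daura_cluster(np.zeros((3, 3)), cutoff=-1.0)


def test_cluster_summary_table(small_dimer_ensemble):
    M = rmsd_matrix(small_dimer_ensemble)
    res = daura_cluster(M, cutoff=1.0)
    rows, centers = cluster_summary(res, small_dimer_ensemble,
                                    min(2, res.n_clusters))
    assert rows[0]["cluster"] == 1
    assert rows[-1]["cumulative"] == pytest.approx(
        sum(r["population"] for r in rows))
    assert centers.n_frames == len(rows)
    with pytest.raises(ValueError):
        cluster_summary(res, small_dimer_ensemble, res.n_clusters + 1)
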