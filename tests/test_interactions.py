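"""Contacts, hydrogen bonds, stacking and ring geometry."""

import numpy as np
import pytest

from dimerscope.geometry import random_rotation
from dimerscope.interactions import (cation_pi_distances, classify_stacking,
                                     contact_probability, hbond_count,
                                     ligand_residue_contacts, plane_angle,
                                     ring_geometry, ring_pair_torsion,
                                     stacking_statistics)
from dimerscope.model import Conformation, Ensemble
from dimerscope.synth import (HIAPP_SEQUENCE, attach_ligand, build_backbone,
                              egcg_like_ligand, helix_dihedrals,
                              place_ligand_ring)


def _rigidly_moved(ens, seed):
    rng = np.random.default_rng(seed)
    frames = []
    for f in ens.frames:
        g = f.transformed(rotation=random_rotation(rng),
                          translation=rng.normal(0.0, 2.0, size=3))
        g.frame_index = f.frame_index
        frames.append(g)
    return Ensemble(ens.topology, frames, weights=ens.weights,
                    temperature_K=ens.temperature_K)


def test_contact_maps_are_rigid_motion_invariant(small_dimer_ensemble):
    for mode in ("MC-MC", "SC-SC"):
        for scope in ("inter", "intra"):
            a = contact_probability(small_dimer_ensemble, mode, scope)
            b = contact_probability(_rigidly_moved(small_dimer_ensemble, 9),
                                    mode, scope)
            assert np.allclose(a.matrix, b.matrix, atol=1e-12)


def test_homodimer_inter_map_is_symmetric(small_dimer_ensemble):
    cm = contact_probability(small_dimer_ensemble, "MC-MC", "inter")
    assert np.allclose(cm.matrix, cm.matrix.T)
    assert cm.matrix.min() >= 0 and cm.matrix.max() <= 1


def test_intra_map_has_zero_diagonal(small_dimer_ensemble):
    cm = contact_probability(small_dimer_ensemble, "MC-MC", "intra")
    assert np.all(np.diag(cm.matrix) == 0)


def test_contact_validation(small_dimer_ensemble):
    with pytest.raises(ValueError):
        contact_probability(small_dimer_ensemble, "XX", "inter")
    with pytest.raises(ValueError):
        contact_probability(small_dimer_ensemble, "MC-MC", "inter", cutoff=0.0)


def test_ideal_helix_hydrogen_bond_count(helix12):
    """An ideal 12-residue alpha helix has the 8 canonical i->i-4 bonds."""
    conf, top = helix12
    assert hbond_count(Ensemble(top, [conf]))[0] == 8


def test_hbond_count_is_rigid_motion_invariant(small_dimer_ensemble):
    a = hbond_count(small_dimer_ensemble)
    b = hbond_count(_rigidly_moved(small_dimer_ensemble, 4))
    assert np.array_equal(a, b)


def test_stacking_classification_thresholds():
    assert classify_stacking(0.40, 10.0) == "parallel"
    assert classify_stacking(0.56, 10.0) == "none"       # just beyond distance
    assert classify_stacking(0.40, 31.0) == "none"       # just beyond angle
    assert classify_stacking(0.60, 85.0) == "perpendicular"
    assert classify_stacking(0.76, 85.0) == "none"
    assert classify_stacking(0.60, 45.0) == "none"       # intermediate angle


def test_plane_angle_folds_to_90():
    n = np.array([0.0, 0.0, 1.0])
    assert plane_angle(n, n) == pytest.approx(0.0)
    assert plane_angle(n, -n) == pytest.approx(0.0)
    assert plane_angle(n, np.array([1.0, 0.0, 0.0])) == pytest.approx(90.0)


def test_ring_geometry_normal_and_residual():
    from dimerscope.synth import hexagon_ring
    pts = hexagon_ring((1.0, 2.0, 3.0), (0.0, 0.0, 1.0))
    g = ring_geometry(Conformation(pts), np.arange(6))
    assert np.allclose(g.centroid, [1.0, 2.0, 3.0], atol=1e-12)
    assert abs(abs(g.normal[2]) - 1.0) < 1e-9
    assert g.residual < 1e-12
    with pytest.raises(ValueError, match="collinear"):
        line = np.outer(np.arange(6.0), [1.0, 0.0, 0.0])
        ring_geometry(Conformation(line), np.arange(6))


@pytest.fixture(scope="module")
def ligand_system():
    pep, ptop = build_backbone(HIAPP_SEQUENCE, helix_dihedrals(37))
    span = pep.coords.max(0) - pep.coords.min(0)
    conf, top = attach_ligand((pep, ptop), egcg_like_ligand(), translation=span + 3.0)
    return conf, top


def test_stacking_statistics_sees_planted_contact(ligand_system):
    conf, top = ligand_system
    target = sorted(n for n in top.ring_groups()
                    if top.atoms[top.ring_groups()[n][0]].atom_class == "side_chain")[0]
    placed = place_ligand_ring((conf, top), "ring1", target, 0.42, 5.0, seed=1)
    events, summary = stacking_statistics(Ensemble(top, [placed]))
    classes = {(e.residue_ring, e.ligand_ring): e.stacking_class
               for e in events[0]}
    assert classes[(target, "ring1")] == "parallel"
    assert summary["parallel"] == pytest.approx(1.0)


def test_ligand_contacts_report_near_residues(ligand_system):
    conf, top = ligand_system
    target = sorted(n for n in top.ring_groups()
                    if top.atoms[top.ring_groups()[n][0]].atom_class == "side_chain")[0]
    placed = place_ligand_ring((conf, top), "ring1", target, 0.40, 0.0, seed=2)
    per_res, per_ring = ligand_residue_contacts(Ensemble(top, [placed]))
    target_res_global = int(top.atom_residue[top.ring_groups()[target][0]])
    assert per_res[target_res_global] == pytest.approx(1.0)
    assert per_ring["ring1"]["total"] == per_ring["ring1"]["MC"] + per_ring["ring1"]["SC"]
    assert per_ring["ring1"]["total"] > 0


def test_cation_pi_distance_to_planted_ring(ligand_system):
    conf, top = ligand_system
    cation = next(iter(top.charged_groups().values()))
    cpos = conf.coords[cation].mean(axis=0)
    # move the whole ligand so ring1's centroid sits 0.43 nm from the cation
    ring1 = top.ring_groups()["ring1"]
    shift = cpos + np.array([0.43, 0.0, 0.0]) - conf.coords[ring1].mean(axis=0)
    moved = conf.coords.copy()
    lig = top.select(atom_class="ligand")
    moved[lig] += shift
    d = cation_pi_distances(Ensemble(top, [Conformation(moved)]))
    assert np.any(np.isclose(d, 0.43, atol=1e-9))


def test_ring_pair_torsion_matches_construction():
    conf, top = egcg_like_ligand(torsion_12_deg=50.0, torsion_23_deg=135.0)
    t12 = ring_pair_torsion(conf, top, "ring1", "ring2")
    t23 = ring_pair_torsion(conf, top, "ring2", "ring3")
    # unfolded angle: accepts the value or its supplement (normal orientation)
    assert min(abs(t12 - 50.0), abs(t12 - 130.0)) < 1e-6
    assert min(abs(t23 - 135.0), abs(t23 - 45.0)) < 1e-6
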