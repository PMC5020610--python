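"""Generator post-conditions: built structures have the declared geometry."""

import numpy as np
import pytest
from dimerscope.model import Ensemble
from dimerscope.secstruct import assign_ss
from dimerscope.synth import (HIAPP_SEQUENCE, MixtureSpec, attach_ligand,
                              build_backbone, build_dimer, build_hairpin,
                              coil_dihedrals, egcg_like_ligand,
                              generate_mixture, helix_dihedrals,
                              place_ligand_ring, strand_dihedrals)
from dimerscope.interactions import plane_angle, ring_geometry
from conftest import HAIRPIN_RANGES


def _ss_string(conf, top):
    return "".join(assign_ss(Ensemble(top, [conf])).classes[0])


def test_ideal_helix_assigns_helical():
    conf, top = build_backbone("A" * 16, helix_dihedrals(16))
    ss = _ss_string(conf, top)
    frac = sum(c in "HGI" for c in ss) / len(ss)
    assert frac >= 0.6


def test_isolated_strand_has_no_sheet():
    conf, top = build_backbone("A" * 15, strand_dihedrals(15))
    assert "E" not in _ss_string(conf, top)


def test_hairpin_forms_antiparallel_sheet():
    conf, top = build_hairpin(HIAPP_SEQUENCE, *HAIRPIN_RANGES)
    ss = _ss_string(conf, top)
    assert sum(c == "E" for c in ss) / len(ss) >= 0.4
    # both strand segments participate
    assert "E" in ss[7:16] and "E" in ss[24:33]


def test_hairpin_rejects_bad_ranges():
    with pytest.raises(ValueError):
        build_hairpin("A" * 20, (1, 8), (7, 10), (11, 20))  # overlapping
    with pytest.raises(ValueError):
        build_hairpin("A" * 20, (1, 8), (9, 12), (13, 25))  # beyond sequence


def test_built_chain_has_ideal_bond_lengths():
    rng = np.random.default_rng(0)
    conf, top = build_backbone(HIAPP_SEQUENCE, coil_dihedrals(37, rng))
    for g in range(top.n_residues):
        res = top.residues[g]
        base = top.residue_atom_indices(g)[0]
        n = conf.coords[base + res.atom_index("N")]
        ca = conf.coords[base + res.atom_index("CA")]
        c = conf.coords[base + res.atom_index("C")]
        assert np.linalg.norm(ca - n) == pytest.approx(0.1458, abs=1e-9)
        assert np.linalg.norm(c - ca) == pytest.approx(0.1525, abs=1e-9)


def test_dimer_is_homodimer_and_clash_checked():
    c1, t1 = build_backbone(HIAPP_SEQUENCE, helix_dihedrals(37))
    c2, t2 = build_backbone(HIAPP_SEQUENCE, helix_dihedrals(37))
    conf, top = build_dimer((c1, t1), (c2, t2), translation=(1.5, 0.0, 0.0))
    assert top.homodimer
    assert [c.chain_id for c in top.chains] == ["A", "B"]
    # ring/charged group names are per-chain
    assert any(n.startswith("B") for n in top.ring_groups())
    with pytest.raises(ValueError, match="clash"):
        build_dimer((c1, t1), (c2, t2), translation=(0.0, 0.0, 0.0))


def test_ligand_torsions_equal_ring_plane_angles():
    for t12, t23 in ((30.0, 80.0), (55.0, 10.0), (90.0, 90.0)):
        conf, top = egcg_like_ligand(t12, t23)
        rings = top.ring_groups()
        g1 = ring_geometry(conf, rings["ring1"])
        g2 = ring_geometry(conf, rings["ring2"])
        g3 = ring_geometry(conf, rings["ring3"])
        assert plane_angle(g1.normal, g2.normal) == pytest.approx(min(t12, 180 - t12), abs=1e-6)
        assert plane_angle(g2.normal, g3.normal) == pytest.approx(min(t23, 180 - t23), abs=1e-6)


def test_place_ligand_ring_hits_requested_geometry():
    pep, ptop = build_backbone(HIAPP_SEQUENCE, helix_dihedrals(37))
    lig = egcg_like_ligand()
    span = pep.coords.max(0) - pep.coords.min(0)
    conf, top = attach_ligand((pep, ptop), lig, translation=span + 3.0)
    target = sorted(n for n in top.ring_groups()
                    if top.atoms[top.ring_groups()[n][0]].atom_class == "side_chain")[0]
    for d, a in ((0.40, 5.0), (0.60, 85.0), (0.95, 45.0)):
        placed = place_ligand_ring((conf, top), "ring1", target, d, a, seed=4)
        rings = top.ring_groups()
        gl = ring_geometry(placed, rings["ring1"])
        gt = ring_geometry(placed, rings[target])
        assert np.linalg.norm(gl.centroid - gt.centroid) == pytest.approx(d, abs=1e-9)
        assert plane_angle(gl.normal, gt.normal) == pytest.approx(a, abs=1e-6)
    with pytest.raises(ValueError):
        place_ligand_ring((conf, top), "ring1", target, 0.2, 0.0, seed=4)


def test_mixture_is_seed_reproducible_with_true_labels():
    spec = MixtureSpec([("helix", {"sequence": "A" * 10}, 0.7),
                        ("coil", {"sequence": "A" * 10}, 0.3)],
                       n_frames=20, seed=42)
    e1, l1 = generate_mixture(spec)
    e2, l2 = generate_mixture(spec)
    assert np.array_equal(l1, l2)
    assert np.allclose(e1.coordinates(), e2.coordinates())
    assert set(np.unique(l1)) <= {0, 1}


def test_mixture_rejects_inconsistent_components():
    spec = MixtureSpec([("helix", {"sequence": "A" * 10}, 0.5),
                        ("coil", {"sequence": "A" * 12}, 0.5)],
                       n_frames=30, seed=0)
    with pytest.raises(ValueError, match="topology"):
        generate_mixture(spec)


def test_mixture_rejects_unknown_generator_and_bad_weights():
    with pytest.raises(KeyError):
        MixtureSpec([("nope", {}, 1.0)], n_frames=5, seed=0)
    with pytest.raises(ValueError):
        MixtureSpec([("helix", {"sequence": "AA"}, 0.0)], n_frames=5, seed=0)
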