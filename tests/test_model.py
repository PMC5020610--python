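"""Topology/conformation/ensemble data-model invariants."""

import numpy as np
import pytest

from dimerscope.model import Atom, Chain, Conformation, Ensemble, Residue, Topology
from dimerscope.synth import HIAPP_SEQUENCE, peptide_topology


def test_duplicate_atom_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        Residue(1, "ALA", (Atom("CA", "C", "main_chain"),
                           Atom("CA", "C", "main_chain")))


def test_unknown_atom_class_rejected():
    with pytest.raises(ValueError, match="atom class"):
        Atom("X", "C", "bogus")


def test_duplicate_chain_ids_rejected():
    res = Residue(1, "ALA", (Atom("CA", "C", "main_chain"),))
    with pytest.raises(ValueError, match="duplicate chain"):
        Topology([Chain("A", (res,)), Chain("A", (res,))])


def test_homodimer_signature_mismatch_rejected():
    a = Residue(1, "ALA", (Atom("CA", "C", "main_chain"),))
    g = Residue(1, "GLY", (Atom("CA", "C", "main_chain"),))
    with pytest.raises(ValueError, match="homodimer"):
        Topology([Chain("A", (a,)), Chain("B", (g,))], homodimer=True)


def test_select_by_class_and_chain():
    top = peptide_topology(HIAPP_SEQUENCE)
    mc = top.select(atom_class="main_chain")
    assert all(top.atoms[i].atom_class == "main_chain" for i in mc)
    sc = top.select(atom_class="side_chain", heavy_only=True)
    assert all(top.atoms[i].element != "H" for i in sc)
    assert len(top.select(chain="A")) == top.n_atoms
    with pytest.raises(ValueError, match="unknown chain"):
        top.select(chain="Z")


def test_ring_and_charged_groups_present_for_aromatic_and_basic_residues():
    top = peptide_topology(HIAPP_SEQUENCE)
    rings = top.ring_groups()
    # two PHE and one TYR aromatic ring in this sequence
    assert len(rings) == 3
    for idx in rings.values():
        assert len(idx) >= 6
    charged = top.charged_groups()
    assert any("guanidinium" in n for n in charged)
    assert any("ammonium" in n for n in charged)


def test_find_atom_addresses_unique_atom():
    top = peptide_topology(HIAPP_SEQUENCE)
    i = top.find_atom("A", 2, "CA")
    assert top.atoms[i].name == "CA"
    assert top.residues[top.atom_residue[i]].index == 2
    with pytest.raises(KeyError):
        top.find_atom("A", 99, "CA")


def test_conformation_rejects_nonfinite_and_bad_shape():
    with pytest.raises(ValueError):
        Conformation(np.array([[0.0, 0.0]]))
    with pytest.raises(ValueError, match="finite"):
        Conformation(np.array([[np.nan, 0.0, 0.0]]))


def test_ensemble_weight_normalisation_and_subset():
    top = peptide_topology("AAA")
    n = top.n_atoms
    frames = [Conformation(np.random.default_rng(k).normal(size=(n, 3)),
                           frame_index=k) for k in range(4)]
    ens = Ensemble(top, frames, weights=np.array([2.0, 1.0, 1.0, 0.0]))
    assert ens.weights.sum() == pytest.approx(1.0)
    assert ens.weights[0] == pytest.approx(0.5)
    sub = ens.subset([0, 1])
    assert sub.n_frames == 2
    assert sub.weights.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ens.subset([])


def test_ensemble_frame_atom_count_checked():
    top = peptide_topology("AAA")
    with pytest.raises(ValueError, match="coords"):
        Ensemble(top, [Conformation(np.zeros((3, 3)))])
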