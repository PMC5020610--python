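"""Kabsch-Sander secondary-structure machinery (beyond the oracle test)."""

import numpy as np
import pytest

from dimerscope.model import Ensemble
from dimerscope.secstruct import (COLLAPSED_CLASSES, SS_CLASSES, assign_ss,
                                  backbone_hbond_energy, hbond_energy_matrix,
                                  ss_profile, strand_length_pdf)
from dimerscope.synth import build_backbone, build_hairpin, helix_dihedrals
from conftest import HAIRPIN_RANGES, HIAPP_SEQUENCE


def test_helix_hbond_energies_favour_i_to_i_minus_4(helix12):
    conf, top = helix12
    E = hbond_energy_matrix(conf, top)
    for i in range(4, 12):
        assert E[i, i - 4] < -0.5          # the canonical helical bond
    assert backbone_hbond_energy(5, 1, conf, top) == pytest.approx(E[5, 1])
    # neighbours and self are excluded
    assert E[5, 5] == 0.0 and E[5, 4] == 0.0 and E[5, 6] == 0.0


def test_assignment_classes_are_legal(small_dimer_ensemble):
    a = assign_ss(small_dimer_ensemble)
    assert a.classes.shape == (small_dimer_ensemble.n_frames, 74)
    assert set(np.unique(a.classes)) <= set(SS_CLASSES)


def test_profile_rows_sum_to_one(small_dimer_ensemble):
    prof = ss_profile(assign_ss(small_dimer_ensemble),
                      small_dimer_ensemble.weights)
    assert prof.per_residue.shape == (74, len(COLLAPSED_CLASSES))
    assert np.allclose(prof.per_residue.sum(axis=1), 1.0, atol=1e-9)
    assert prof.ensemble_mean.sum() == pytest.approx(1.0, abs=1e-9)


def test_interchain_sheet_detected_between_paired_strands():
    """Two chains paired edge-on (a strand and its translated copy along
    the amide N-H direction) must yield E through inter-chain bridges;
    neither chain forms a sheet on its own."""
    from dimerscope.synth import build_dimer, strand_dihedrals
    c1, t1 = build_backbone("A" * 10, strand_dihedrals(10))
    c2, t2 = build_backbone("A" * 10, strand_dihedrals(10))
    g = 4
    res = t1.residues[g]
    base = t1.residue_atom_indices(g)[0]
    n = c1.coords[base + res.atom_index("N")]
    h = c1.coords[base + res.atom_index("H")]
    u = (h - n) / np.linalg.norm(h - n)
    best = 0.0
    for d in np.arange(0.28, 0.42, 0.01):
        try:
            conf, top = build_dimer((c1, t1), (c2, t2), d * u)
        except ValueError:
            continue
        ss = assign_ss(Ensemble(top, [conf])).classes[0]
        best = max(best, float((ss == "E").mean()))
    assert best > 0.3, f"best inter-chain sheet fraction: {best}"


def test_strand_length_distribution_of_hairpin():
    conf, top = build_hairpin(HIAPP_SEQUENCE, *HAIRPIN_RANGES)
    pdf = strand_length_pdf(assign_ss(Ensemble(top, [conf])))
    assert pdf.probabilities
    assert sum(pdf.probabilities.values()) > 0
    assert all(L >= 1 for L in pdf.probabilities)
    # the dominant strand length matches the built strand span
    dominant = max(pdf.probabilities, key=pdf.probabilities.get)
    assert dominant >= 5


def test_helix_ends_are_not_helical(helix12):
    conf, top = helix12
    ss = assign_ss(Ensemble(top, [conf])).classes[0]
    assert ss[0] not in "HGI"  # first residue cannot complete a turn pattern
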