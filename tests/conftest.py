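"""Shared fixtures: small built structures and an mdtraj bridge.

mdtraj serves strictly as an independent reference implementation
(DSSP assignment) in tests; the package itself never imports it.
"""

from __future__ import annotations

import numpy as np
import pytest

from dimerscope.model import Ensemble
from dimerscope.synth import (HIAPP_SEQUENCE, build_backbone, build_dimer,
                              build_hairpin, coil_dihedrals, helix_dihedrals)


#: hairpin segmentation used throughout the tests (1-based residue ranges)
HAIRPIN_RANGES = ((8, 16), (17, 24), (25, 33))


def to_mdtraj(conf, top):
    """Convert a (Conformation, Topology) pair to a 1-frame mdtraj Trajectory."""
    import mdtraj as md
    t = md.Topology()
    for chain in top.chains:
        ch = t.add_chain()
        for res in chain.residues:
            r = t.add_residue(res.name, ch, resSeq=res.index)
            for a in res.atoms:
                elem = md.element.get_by_symbol(a.element.capitalize())
                t.add_atom(a.name, elem, r)
    return md.Trajectory(conf.coords[None, :, :], t)


@pytest.fixture(scope="session")
def helix12():
    return build_backbone("A" * 12, helix_dihedrals(12))


@pytest.fixture(scope="session")
def hairpin37():
    return build_hairpin(HIAPP_SEQUENCE, *HAIRPIN_RANGES)


@pytest.fixture(scope="session")
def coil_dimer_frame():
    rng = np.random.default_rng(5)
    s1, t1 = build_backbone(HIAPP_SEQUENCE, coil_dihedrals(37, rng))
    s2, t2 = build_backbone(HIAPP_SEQUENCE, coil_dihedrals(37, rng))
    return build_dimer((s1, t1), (s2, t2), translation=(2.5, 0.0, 0.0))


@pytest.fixture(scope="session")
def small_dimer_ensemble(coil_dimer_frame):
    """Eight-frame coil-dimer ensemble, rigid per-frame noise only."""
    conf, top = coil_dimer_frame
    rng = np.random.default_rng(17)
    frames = []
    for f in range(8):
        jitter = rng.normal(0.0, 0.02, size=conf.coords.shape)
        c = conf.transformed(translation=rng.normal(0.0, 0.5, size=3))
        c.coords = c.coords + jitter
        c.frame_index = f
        frames.append(c)
    return Ensemble(top, frames)
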