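"""Rigid ligand templates and controlled-geometry ring placement.

The ligand scaffold is a simplified three-ring polyphenol: two benzene
rings joined through a one-carbon linker plus a third (gallate-ester-like)
ring on a second linker, with the two inter-ring torsions as the only
conformational degrees of freedom.  It carries just enough geometry to
exercise stacking classification, per-ring contact counting and
inter-ring torsion analysis; it makes no attempt at real polyphenol
chemistry.
"""

from __future__ import annotations

import numpy as np

from ..geometry import perpendicular_vector, rotation_about_axis, unit
from ..model import Atom, Chain, Conformation, Residue, Topology
from .backbone import RING_CC, A2NM

RING_OVERLAP_NM = 0.1
LINKER_CC = 1.50  # angstrom


def hexagon_ring(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0),
                 first_vertex_dir=None, bond_length_A: float = RING_CC) -> np.ndarray:
    """Ideal hexagon vertex coordinates (6, 3) in nm."""
    c = np.asarray(center, dtype=float)
    nrm = unit(np.asarray(normal, dtype=float))
    u = (perpendicular_vector(nrm) if first_vertex_dir is None
         else unit(np.asarray(first_vertex_dir, dtype=float)))
    v = np.cross(nrm, u)
    r = bond_length_A * A2NM
    pts = [c + r * (np.cos(np.deg2rad(60 * k)) * u + np.sin(np.deg2rad(60 * k)) * v)
           for k in range(6)]
    return np.asarray(pts)


def _ligand_topology(chain_id: str, residue_index: int = 1) -> Topology:
    atoms: list[Atom] = []
    for ring in (1, 2, 3):
        for k in range(1, 7):
            atoms.append(Atom(f"C{ring}{k}", "C", "ligand", ring_group=f"ring{ring}"))
        if ring < 3:
            atoms.append(Atom(f"CL{ring}", "C", "ligand"))
    res = Residue(residue_index, "EGC", tuple(atoms))
    return Topology([Chain(chain_id, (res,))])


def egcg_like_ligand(torsion_12_deg: float = 50.0, torsion_23_deg: float = 90.0,
                     chain_id: str = "L") -> tuple[Conformation, Topology]:
    """Build the rigid three-ring ligand with the given inter-ring torsions.

    ``torsion_12_deg`` rotates ring 2 about its linker bond relative to
    ring 1, and equals the ring1-ring2 plane angle; likewise
    ``torsion_23_deg`` for ring 3 relative to ring 2.
    """
    x = np.array([1.0, 0.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    r_hex = RING_CC * A2NM
    link = LINKER_CC * A2NM

    coords: list[np.ndarray] = []
    # ring 1 centred at origin in the xy-plane, first vertex toward +x
    ring1 = hexagon_ring((0, 0, 0), z, x)
    coords.extend(ring1)
    a1 = ring1[0]                       # attachment vertex
    l1 = a1 + link * x                  # linker CL1

    # ring 2: attached through CL1 along +x, then twisted about the bond axis
    c2 = l1 + (link + r_hex) * x
    ring2 = hexagon_ring(c2, z, -x)     # vertex 0 faces back toward CL1
    R12 = rotation_about_axis(x, torsion_12_deg)
    ring2 = (ring2 - l1) @ R12.T + l1
    c2 = (c2 - l1) @ R12.T + l1
    coords.extend(ring2)
    coords.append(l1)

    # ring 3 off ring 2's far vertex, with its own torsion
    n2 = unit(np.cross(ring2[1] - ring2[0], ring2[2] - ring2[0]))
    a2 = ring2[3]                       # vertex opposite the attachment
    out_dir = unit(a2 - c2)
    l2 = a2 + link * out_dir
    c3 = l2 + (link + r_hex) * out_dir
    ring3 = hexagon_ring(c3, n2, -out_dir)
    R23 = rotation_about_axis(out_dir, torsion_23_deg)
    ring3 = (ring3 - l2) @ R23.T + l2
    coords.extend(ring3)
    coords.append(l2)

    top = _ligand_topology(chain_id)
    return Conformation(np.asarray(coords)), top


def attach_ligand(base: tuple[Conformation, Topology],
                  ligand: tuple[Conformation, Topology],
                  translation=(0.0, 0.0, 0.0), rotation=None,
                  min_distance_nm: float = 0.15) -> tuple[Conformation, Topology]:
    """Append a rigidly transformed ligand chain to a peptide system.

    The ligand chain id is made unique if it collides with an existing
    chain.  Raises on heavy-atom contact below ``min_distance_nm``.
    """
    conf, top = base
    lconf, ltop = ligand
    if len(ltop.chains) != 1:
        raise ValueError("ligand must be a single chain")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    lcoords = lconf.coords @ R.T + np.asarray(translation, dtype=float)

    from scipy.spatial.distance import cdist
    heavy = top.select(heavy_only=True)
    lheavy = ltop.select(heavy_only=True)
    d = cdist(conf.coords[heavy], lcoords[lheavy])
    if d.min() < min_distance_nm:
        raise ValueError(f"ligand clashes with base: min distance {d.min():.3f} nm")

    existing = {c.chain_id for c in top.chains}
    cid = ltop.chains[0].chain_id
    while cid in existing:
        cid = chr(ord(cid) + 1)
    lig_chain = Chain(cid, ltop.chains[0].residues)
    new_top = Topology(list(top.chains) + [lig_chain], homodimer=top.homodimer)
    return Conformation(np.vstack([conf.coords, lcoords])), new_top


def place_ligand_ring(system: tuple[Conformation, Topology],
                      ligand_ring: str, target_ring: str,
                      centroid_distance_nm: float, plane_angle_deg: float,
                      seed: int) -> Conformation:
    """Rigidly move the ligand so one of its rings stacks on a target ring.

    The named ligand ring's centroid lands exactly ``centroid_distance_nm``
    along the target ring's normal, with the requested angle between the
    two ring planes; the azimuthal tilt direction and the spin of the
    ligand about its own ring normal are drawn from ``seed``.  Raises if
    any ligand-ring atom would come within 0.1 nm of a target-ring atom.
    """
    if centroid_distance_nm < 0.3:
        raise ValueError("centroid distance must be >= 0.3 nm")
    if not 0.0 <= plane_angle_deg <= 90.0:
        raise ValueError("plane angle must lie in [0, 90] degrees")
    conf, top = system
    rings = top.ring_groups()
    for name in (ligand_ring, target_ring):
        if name not in rings:
            raise KeyError(f"no ring group {name!r} in topology")
    lig_idx = rings[ligand_ring]
    tgt_idx = rings[target_ring]
    lig_chain = top.atom_chain[lig_idx[0]]
    move = np.flatnonzero(top.atom_chain == lig_chain)

    rng = np.random.default_rng(seed)

    def ring_frame(idx):
        pts = conf.coords[idx]
        c = pts.mean(axis=0)
        centered = pts - c
        _, _, vt = np.linalg.svd(centered)
        return c, vt[2]

    ct, nt = ring_frame(tgt_idx)
    cl, nl = ring_frame(lig_idx)

    azimuth = rng.uniform(0.0, 360.0)
    u = perpendicular_vector(nt)
    u = rotation_about_axis(nt, azimuth) @ u
    theta = np.deg2rad(plane_angle_deg)
    target_normal = np.cos(theta) * nt + np.sin(theta) * u

    # rotate ligand normal onto the requested normal, add a seeded spin
    axis = np.cross(nl, target_normal)
    if np.linalg.norm(axis) < 1e-12:
        R1 = np.eye(3) if np.dot(nl, target_normal) > 0 else \
            rotation_about_axis(perpendicular_vector(nl), 180.0)
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(nl, target_normal), -1, 1)))
        R1 = rotation_about_axis(axis, ang)
    R2 = rotation_about_axis(target_normal, rng.uniform(0.0, 360.0))
    R = R2 @ R1

    p = ct + centroid_distance_nm * nt
    new = conf.coords.copy()
    new[move] = (conf.coords[move] - cl) @ R.T + p

    from scipy.spatial.distance import cdist
    d = cdist(new[lig_idx], new[tgt_idx])
    if d.min() < RING_OVERLAP_NM:
        raise ValueError(
            f"requested geometry overlaps rings: min atom distance "
            f"{d.min():.3f} nm < {RING_OVERLAP_NM} nm")
    return Conformation(new, conf.frame_index, conf.box)
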