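"""Ideal-geometry peptide builders.

Backbones are constructed from internal coordinates (bond lengths and
angles fixed at ideal values, per-residue phi/psi/omega supplied by the
caller) using natural-extension placement.  Side chains are minimal: a
beta carbon for every non-glycine residue, a rigid ideal six-ring for
PHE/TYR, and short cationic stubs for ARG/LYS — enough chemistry for
contact, stacking and cation-pi analyses without rotamer libraries.

All builder output is in nm.  Builders are deterministic: the same
sequence and dihedral spec always yield identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry import place_atom, dihedral, perpendicular_vector, unit
from ..model import Atom, Chain, Conformation, Residue, Topology

#: hIAPP (amylin) sequence, residues K1..Y37, as one-letter codes.
HIAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# Ideal backbone internal coordinates (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.000
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
BOND_CA_CB = 1.521
ANGLE_C_CA_CB = 110.6
TORSION_N_C_CA_CB = 122.6  # L-amino-acid improper
RING_CC = 1.39

A2NM = 0.1

# canonical dihedral presets (phi, psi) in degrees
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def normalize_sequence(sequence) -> list[str]:
    """Accept a one-letter string or a list of 3-letter names."""
    if isinstance(sequence, str):
        return [ONE_TO_THREE[c.upper()] for c in sequence]
    return [s.upper() for s in sequence]


@dataclass
class DihedralSpec:
    """Per-residue (phi, psi, omega) in degrees; boundary angles of the
    first/last residue are used only where geometrically defined."""

    angles: np.ndarray  # (n_res, 3)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ValueError("angles must have shape (n_res, 3)")
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValueError("dihedral angles must lie in (-180, 180]")

    def __len__(self):
        return self.angles.shape[0]

    @classmethod
    def uniform(cls, n_res: int, phi: float, psi: float, omega: float = 180.0):
        return cls(np.tile([phi, psi, omega], (n_res, 1)))


def helix_dihedrals(n_res: int) -> DihedralSpec:
    return DihedralSpec.uniform(n_res, *HELIX_PHI_PSI)


def strand_dihedrals(n_res: int) -> DihedralSpec:
    return DihedralSpec.uniform(n_res, *STRAND_PHI_PSI)


#: Broad Ramachandran-permitted (phi, psi) boxes sampled by the coil
#: generator: (phi_lo, phi_hi, psi_lo, psi_hi, weight)
RAMACHANDRAN_BOXES = (
    (-160.0, -60.0, 90.0, 175.0, 0.45),    # beta / PPII region
    (-160.0, -60.0, -60.0, -20.0, 0.35),   # alpha region
    (45.0, 75.0, 15.0, 70.0, 0.20),        # left-handed alpha
)


def coil_dihedrals(n_res: int, rng: np.random.Generator) -> DihedralSpec:
    """Seeded random-coil dihedrals from broad Ramachandran boxes."""
    weights = np.array([b[4] for b in RAMACHANDRAN_BOXES])
    weights = weights / weights.sum()
    angles = np.empty((n_res, 3))
    for i in range(n_res):
        lo1, hi1, lo2, hi2, _ = RAMACHANDRAN_BOXES[rng.choice(len(weights), p=weights)]
        angles[i] = (rng.uniform(lo1, hi1), rng.uniform(lo2, hi2), 180.0)
    return DihedralSpec(angles)


# ---------------------------------------------------------------------------
# topology template for the minimal side-chain model
# ---------------------------------------------------------------------------

def _residue_atoms(resname: str, is_first: bool, chain_id: str, index: int) -> list[Atom]:
    atoms = [Atom("N", "N", "main_chain"),
             Atom("CA", "C", "main_chain"),
             Atom("C", "C", "main_chain"),
             Atom("O", "O", "main_chain")]
    if not is_first and resname != "PRO":
        atoms.insert(1, Atom("H", "H", "hydrogen"))
    if resname != "GLY":
        atoms.append(Atom("CB", "C", "side_chain"))
    tag = f"{chain_id}{index}"
    if resname in ("PHE", "TYR"):
        ring = f"{tag}-ring"
        for name in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"):
            atoms.append(Atom(name, "C", "side_chain", ring_group=ring))
        if resname == "TYR":
            atoms.append(Atom("OH", "O", "side_chain"))
    elif resname == "ARG":
        grp = f"{tag}-guanidinium"
        atoms.append(Atom("CZ", "C", "side_chain"))
        for name in ("NE", "NH1", "NH2"):
            atoms.append(Atom(name, "N", "side_chain", charged_group=grp))
    elif resname == "LYS":
        atoms.append(Atom("NZ", "N", "side_chain", charged_group=f"{tag}-ammonium"))
    return atoms


def peptide_topology(sequence, chain_id: str = "A", start_index: int = 1) -> Topology:
    """Single-chain topology for the minimal side-chain peptide model."""
    names = normalize_sequence(sequence)
    residues = []
    for i, resname in enumerate(names):
        idx = start_index + i
        atoms = tuple(_residue_atoms(resname, i == 0, chain_id, idx))
        residues.append(Residue(idx, resname, atoms))
    return Topology([Chain(chain_id, tuple(residues))])


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def build_backbone(sequence, dihedrals: DihedralSpec, chain_id: str = "A"
                   ) -> tuple[Conformation, Topology]:
    """Build a peptide chain from per-residue dihedrals.

    Returns the conformation (nm) and matching minimal-side-chain
    topology.  Raises on an empty sequence or a length mismatch.
    """
    names = normalize_sequence(sequence)
    if not names:
        raise ValueError("empty sequence")
    if len(dihedrals) != len(names):
        raise ValueError("one (phi, psi, omega) triple per residue required")
    n_res = len(names)
    ang = dihedrals.angles

    # backbone trace in angstrom; converted to nm at the end
    N = np.empty((n_res, 3)); CA = np.empty((n_res, 3)); C = np.empty((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    th = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(1, n_res):
        psi_prev = ang[i - 1, 1]
        omega_i = ang[i, 2]
        phi_i = ang[i, 0]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega_i)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i)

    O = np.empty((n_res, 3))
    for i in range(n_res):
        # carbonyl O in the peptide plane, anti to the next amide N
        psi = ang[i, 1]
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)

    coords: list[np.ndarray] = []
    for i, resname in enumerate(names):
        coords.append(N[i])
        if i > 0 and resname != "PRO":
            coords.append(N[i] + BOND_N_H * unit(C[i - 1] - O[i - 1]))
        coords.append(CA[i])
        coords.append(C[i])
        coords.append(O[i])
        if resname != "GLY":
            CB = place_atom(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB,
                            TORSION_N_C_CA_CB)
            coords.append(CB)
            coords.extend(_side_chain_coords(resname, CA[i], CB))

    top = peptide_topology(names, chain_id=chain_id)
    xyz = np.asarray(coords) * A2NM
    if xyz.shape[0] != top.n_atoms:
        raise AssertionError("builder/topology atom count mismatch")
    return Conformation(xyz), top


def _side_chain_coords(resname: str, ca: np.ndarray, cb: np.ndarray) -> list[np.ndarray]:
    axis = unit(cb - ca)
    v = perpendicular_vector(axis)
    out: list[np.ndarray] = []
    if resname in ("PHE", "TYR"):
        cg = cb + 1.50 * axis
        center = cg + RING_CC * axis
        for k in range(6):  # path CG-CD1-CE1-CZ-CE2-CD2 around the hexagon
            t = np.deg2rad(60.0 * k)
            out.append(center + RING_CC * (-np.cos(t) * axis + np.sin(t) * v))
        if resname == "TYR":
            out.append(center + (RING_CC + 1.36) * axis)
    elif resname == "ARG":
        cz = cb + 2.40 * axis
        out.append(cz)
        for k in range(3):
            t = np.deg2rad(120.0 * k)
            out.append(cz + 1.33 * (np.cos(t) * axis + np.sin(t) * v))
    elif resname == "LYS":
        out.append(cb + 3.00 * axis)
    return out


def measure_dihedrals(conf: Conformation, top: Topology, chain: int | str = 0
                      ) -> np.ndarray:
    """Back-compute (phi, psi, omega) per residue from built coordinates.

    Boundary angles that are geometrically undefined (phi of the first
    residue, psi/omega at the termini) are returned as NaN.
    """
    ci = chain if isinstance(chain, int) else top.chain_index(chain)
    res_idx = top.chain_residue_indices(ci)
    n = len(res_idx)

    def atom(i, name):
        g = res_idx[i]
        res = top.residues[g]
        return conf.coords[top.residue_atom_indices(g)[res.atom_index(name)]]

    out = np.full((n, 3), np.nan)
    for i in range(n):
        if i > 0:
            out[i, 0] = dihedral(atom(i - 1, "C"), atom(i, "N"), atom(i, "CA"), atom(i, "C"))
            out[i, 2] = dihedral(atom(i - 1, "CA"), atom(i - 1, "C"), atom(i, "N"), atom(i, "CA"))
        if i < n - 1:
            out[i, 1] = dihedral(atom(i, "N"), atom(i, "CA"), atom(i, "C"), atom(i + 1, "N"))
    return out


# ---------------------------------------------------------------------------
# hairpin builder
# ---------------------------------------------------------------------------

#: Hairpin dihedral template.  Strand and flanking-turn residues use a
#: slightly under-twisted antiparallel-sheet geometry, and the two turn
#: centre residues a type-II' beta-turn: with ideal bond geometry this
#: combination closes the hairpin into a hydrogen-bonded antiparallel
#: ladder across a wide range of strand and turn lengths, which the
#: textbook (-139, 135) strand values do not reliably do.
HAIRPIN_STRAND_PHI_PSI = (-130.0, 128.0)
TURN_CENTER_PHI_PSI = ((60.0, -120.0), (-80.0, 0.0))
TURN_FLANK_PHI_PSI = (-130.0, 128.0)


def _check_ranges(n_res: int, *ranges):
    prev_end = 0
    for lo, hi in ranges:
        if not (1 <= lo <= hi <= n_res):
            raise ValueError(f"range {lo}-{hi} outside 1..{n_res}")
        if lo <= prev_end:
            raise ValueError("hairpin ranges overlap or are out of order")
        prev_end = hi


def build_hairpin(sequence, strand1: tuple[int, int], turn: tuple[int, int],
                  strand2: tuple[int, int], chain_id: str = "A"
                  ) -> tuple[Conformation, Topology]:
    """Build a beta-hairpin: two antiparallel strands joined by a turn.

    ``strand1``/``turn``/``strand2`` are inclusive 1-based residue ranges,
    in order and non-overlapping.  Residues use the hairpin dihedral
    template above; the turn centre is a two-residue type-II' beta turn,
    which closes the hairpin into an antiparallel hydrogen-bonded ladder.
    """
    names = normalize_sequence(sequence)
    n_res = len(names)
    _check_ranges(n_res, strand1, turn, strand2)

    angles = np.tile([*HAIRPIN_STRAND_PHI_PSI, 180.0], (n_res, 1))
    t_lo, t_hi = turn
    turn_len = t_hi - t_lo + 1
    if turn_len >= 2:
        c0 = t_lo + (turn_len - 2) // 2  # centre the 2-residue template
        for j in range(t_lo, t_hi + 1):
            if j == c0:
                phi, psi = TURN_CENTER_PHI_PSI[0]
            elif j == c0 + 1:
                phi, psi = TURN_CENTER_PHI_PSI[1]
            else:
                phi, psi = TURN_FLANK_PHI_PSI
            angles[j - 1, 0] = phi
            angles[j - 1, 1] = psi
    else:  # single-residue turn: just the first template position
        angles[t_lo - 1, :2] = TURN_CENTER_PHI_PSI[0]
    return build_backbone(names, DihedralSpec(angles), chain_id=chain_id)


# ---------------------------------------------------------------------------
# dimer assembly
# ---------------------------------------------------------------------------

CLASH_DISTANCE_NM = 0.15


def build_dimer(chainA: tuple[Conformation, Topology],
                chainB: tuple[Conformation, Topology],
                translation, rotation=None) -> tuple[Conformation, Topology]:
    """Rigidly place chain B (rotated then translated) next to chain A.

    The combined topology re-labels chain B and declares a homodimer when
    the two chains have identical residue and atom naming.  Raises if any
    inter-chain heavy-atom pair comes closer than 0.15 nm, naming the
    worst pair.
    """
    confA, topA = chainA
    confB, topB = chainB
    if len(topA.chains) != 1 or len(topB.chains) != 1:
        raise ValueError("build_dimer expects single-chain inputs")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be orthonormal")
    t = np.asarray(translation, dtype=float)

    coordsB = confB.coords @ R.T + t

    heavyA = topA.select(heavy_only=True)
    heavyB = topB.select(heavy_only=True)
    from scipy.spatial.distance import cdist
    d = cdist(confA.coords[heavyA], coordsB[heavyB])
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] < CLASH_DISTANCE_NM:
        a = topA.atoms[heavyA[i]]
        b = topB.atoms[heavyB[j]]
        raise ValueError(
            f"steric clash: {a.name}/{b.name} at {d[i, j]:.3f} nm "
            f"(< {CLASH_DISTANCE_NM} nm)")

    idA = topA.chains[0].chain_id
    idB = "B" if idA != "B" else "C"
    chainB_rec = Chain(idB, topB.chains[0].residues)
    # ring/charged group names embed the chain id; rebuild chain B's atoms
    chainB_rec = _relabel_groups(chainB_rec, topB.chains[0].chain_id, idB)
    sig = lambda c: [(r.name, tuple(a.name for a in r.atoms)) for r in c.residues]
    homodimer = sig(topA.chains[0]) == sig(chainB_rec)
    top = Topology([topA.chains[0], chainB_rec], homodimer=homodimer)
    coords = np.vstack([confA.coords, coordsB])
    return Conformation(coords), top


def _relabel_groups(chain: Chain, old_id: str, new_id: str) -> Chain:
    def relabel(name: str | None) -> str | None:
        if name is not None and name.startswith(old_id):
            return new_id + name[len(old_id):]
        return name

    residues = []
    for res in chain.residues:
        atoms = tuple(Atom(a.name, a.element, a.atom_class,
                           relabel(a.ring_group), relabel(a.charged_group))
                      for a in res.atoms)
        residues.append(Residue(res.index, res.name, atoms))
    return Chain(chain.chain_id, tuple(residues))
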