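"""Contacts, hydrogen bonds, aromatic stacking and cation-pi geometry.

Contact criterion: a residue pair is in contact in a frame when the
minimum distance between their selected heavy atoms is at or below the
cutoff (default 0.50 nm; an alternative two-tier carbon-aware preset is
available).  Stacking between a residue ring and a ligand ring is
classified from the ring-centroid distance d and the angle theta between
the ring-plane normals (folded to [0, 90] degrees):

* parallel       d <= 0.55 nm and theta <= 30 deg
* perpendicular  d <= 0.75 nm and theta >= 60 deg
* none           otherwise

These thresholds bracket the canonical parallel (~0.4 nm, small angle)
and T-shaped (~0.6 nm, near-90 deg) stacking geometries and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model import Conformation, Ensemble, Topology

DEFAULT_CONTACT_CUTOFF_NM = 0.50
#: two-tier preset common in the aggregation literature: C-C pairs 0.54 nm,
#: any pair involving a non-carbon atom 0.46 nm
TWO_TIER_CUTOFFS_NM = (0.54, 0.46)

HBOND_DISTANCE_NM = 0.35
HBOND_ANGLE_DEG = 30.0

PARALLEL_MAX_ANGLE_DEG = 30.0
PERPENDICULAR_MIN_ANGLE_DEG = 60.0
PARALLEL_MAX_DIST_NM = 0.55
PERPENDICULAR_MAX_DIST_NM = 0.75


# ---------------------------------------------------------------------------
# residue-residue contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Residue-pair contact probabilities.

    ``matrix[i, j]`` is the probability that residue i of one chain and
    residue j of the other (scope "inter") or of the same chain (scope
    "intra") are in contact.  Rows/columns follow per-chain residue
    order.  Inter-chain homodimer maps are symmetrised over the two
    chain assignments.
    """

    matrix: np.ndarray
    mode: str       # "MC-MC" or "SC-SC"
    scope: str      # "inter" or "intra"
    cutoff_nm: float

    def __post_init__(self):
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError("contact probabilities must lie in [0, 1]")


_MODE_CLASS = {"MC-MC": "main_chain", "SC-SC": "side_chain"}


def _residue_atom_lists(top: Topology, chain: int, atom_class: str
                        ) -> list[np.ndarray]:
    """Per-residue heavy-atom index lists of one class for one chain."""
    out = []
    for g in top.chain_residue_indices(chain):
        idx = top.residue_atom_indices(g)
        keep = [i for i in idx
                if top.atoms[i].atom_class == atom_class
                and top.atoms[i].element.upper() != "H"]
        out.append(np.asarray(keep, dtype=int))
    return out


def _pair_contact(frame_xyz, lists_a, lists_b, cutoff) -> np.ndarray:
    na, nb = len(lists_a), len(lists_b)
    hit = np.zeros((na, nb), dtype=bool)
    for i, ia in enumerate(lists_a):
        if len(ia) == 0:
            continue
        for j, ib in enumerate(lists_b):
            if len(ib) == 0:
                continue
            if cdist(frame_xyz[ia], frame_xyz[ib]).min() <= cutoff:
                hit[i, j] = True
    return hit


def contact_probability(ensemble: Ensemble, mode: str = "MC-MC",
                        scope: str = "inter",
                        cutoff: float = DEFAULT_CONTACT_CUTOFF_NM) -> ContactMap:
    """Weighted residue-residue contact probability map.

    ``mode`` selects main-chain-main-chain or side-chain-side-chain heavy
    atoms; ``scope`` selects inter-chain (between the first two peptide
    chains) or intra-chain (within each peptide chain, averaged over
    chains) pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in _MODE_CLASS:
        raise ValueError(f"mode must be one of {sorted(_MODE_CLASS)}")
    if scope not in ("inter", "intra"):
        raise ValueError('scope must be "inter" or "intra"')
    top = ensemble.topology
    pep = top.peptide_chain_indices()
    cls = _MODE_CLASS[mode]

    if scope == "inter":
        if len(pep) < 2:
            raise ValueError("inter-chain map requires two peptide chains")
        la = _residue_atom_lists(top, pep[0], cls)
        lb = _residue_atom_lists(top, pep[1], cls)
        acc = np.zeros((len(la), len(lb)))
        for w, frame in zip(ensemble.weights, ensemble.frames):
            acc += w * _pair_contact(frame.coords, la, lb, cutoff)
        if top.homodimer and len(la) == len(lb):
            acc = 0.5 * (acc + acc.T)
        return ContactMap(acc, mode, scope, cutoff)

    per_chain = []
    for c in pep:
        la = _residue_atom_lists(top, c, cls)
        acc = np.zeros((len(la), len(la)))
        for w, frame in zip(ensemble.weights, ensemble.frames):
            acc += w * _pair_contact(frame.coords, la, la, cutoff)
        np.fill_diagonal(acc, 0.0)
        per_chain.append(acc)
    mat = np.mean(per_chain, axis=0)
    mat = 0.5 * (mat + mat.T)
    return ContactMap(mat, mode, scope, cutoff)


# ---------------------------------------------------------------------------
# ligand-residue contacts
# ---------------------------------------------------------------------------

def ligand_residue_contacts(ensemble: Ensemble,
                            cutoff: float = DEFAULT_CONTACT_CUTOFF_NM):
    """Ligand binding statistics per residue and per ligand ring.

    Returns ``(per_residue, per_ring)``:

    * ``per_residue``: probability (weighted frame fraction) that any
      ligand heavy atom lies within ``cutoff`` of any heavy atom of the
      residue, per peptide residue in topology order;
    * ``per_ring``: dict ring-name -> mean number of peptide heavy atoms
      within ``cutoff`` of any atom of that ring, split into
      ``{"MC": ..., "SC": ..., "total": ...}`` (total = MC + SC).
    """
    top = ensemble.topology
    lig_atoms = top.select(atom_class="ligand", heavy_only=True)
    if len(lig_atoms) == 0:
        raise ValueError("no ligand atoms declared in topology")
    pep_chains = top.peptide_chain_indices()
    pep_res = np.concatenate([top.chain_residue_indices(c) for c in pep_chains])
    res_atoms = []
    for g in pep_res:
        idx = top.residue_atom_indices(g)
        res_atoms.append(np.asarray(
            [i for i in idx if top.atoms[i].atom_class in ("main_chain", "side_chain")
             and top.atoms[i].element.upper() != "H"]))
    pep_heavy = np.concatenate(res_atoms)
    pep_is_mc = np.array([top.atoms[i].atom_class == "main_chain" for i in pep_heavy])

    lig_ring_groups = {name: idx for name, idx in top.ring_groups().items()
                       if top.atoms[idx[0]].atom_class == "ligand"}

    per_res = np.zeros(len(pep_res))
    ring_mc = {r: 0.0 for r in lig_ring_groups}
    ring_sc = {r: 0.0 for r in lig_ring_groups}
    for w, frame in zip(ensemble.weights, ensemble.frames):
        xyz = frame.coords
        d_res = cdist(xyz[pep_heavy], xyz[lig_atoms])
        near_any = (d_res <= cutoff).any(axis=1)
        pos = 0
        for k, ra in enumerate(res_atoms):
            if near_any[pos:pos + len(ra)].any():
                per_res[k] += w
            pos += len(ra)
        for rname, ridx in lig_ring_groups.items():
            d = cdist(xyz[pep_heavy], xyz[ridx])
            near = (d <= cutoff).any(axis=1)
            ring_mc[rname] += w * float(near[pep_is_mc].sum())
            ring_sc[rname] += w * float(near[~pep_is_mc].sum())

    per_ring = {r: {"MC": ring_mc[r], "SC": ring_sc[r],
                    "total": ring_mc[r] + ring_sc[r]} for r in lig_ring_groups}
    return per_res, per_ring


# ---------------------------------------------------------------------------
# hydrogen-bond counting (geometric criterion)
# ---------------------------------------------------------------------------

def hbond_count(ensemble: Ensemble, include_ligand: bool = False) -> np.ndarray:
    """Per-frame hydrogen-bond count by the geometric criterion.

    Donors are amide N-H pairs (declared H atoms bonded to backbone N;
    the builder's topology declares them) plus, when ``include_ligand``
    is set, any ligand O-H.  Acceptors are carbonyl/carboxyl O atoms.  A
    bond is counted when the donor-acceptor heavy-atom distance is at
    most 0.35 nm and the H-donor-acceptor angle at most 30 degrees.
    """
    top = ensemble.topology
    donors: list[tuple[int, int]] = []  # (heavy N/O index, H index)
    acceptors: list[int] = []
    for g in range(top.n_residues):
        idx = top.residue_atom_indices(g)
        names = {top.atoms[i].name: i for i in idx}
        is_ligand = top.atoms[idx[0]].atom_class == "ligand"
        if is_ligand and not include_ligand:
            continue
        if not is_ligand:
            if "N" in names and "H" in names:
                donors.append((names["N"], names["H"]))
            if "O" in names:
                acceptors.append(names["O"])
        else:
            for i in idx:
                if top.atoms[i].element.upper() == "O":
                    acceptors.append(i)

    counts = np.zeros(ensemble.n_frames, dtype=int)
    if not donors or not acceptors:
        return counts
    acc = np.asarray(acceptors)
    for f, frame in enumerate(ensemble.frames):
        xyz = frame.coords
        c = 0
        for d_heavy, d_h in donors:
            vec = xyz[acc] - xyz[d_heavy]
            dist = np.linalg.norm(vec, axis=1)
            ok = dist <= HBOND_DISTANCE_NM
            if not ok.any():
                continue
            hvec = xyz[d_h] - xyz[d_heavy]
            cosang = (vec[ok] @ hvec) / (dist[ok] * np.linalg.norm(hvec))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            # exclude the donor's own carbonyl (same-residue trivial pair)
            c += int(np.count_nonzero(ang <= HBOND_ANGLE_DEG))
        counts[f] = c
    return counts


# ---------------------------------------------------------------------------
# ring geometry and stacking
# ---------------------------------------------------------------------------

@dataclass
class RingGeometry:
    """Least-squares ring plane: centroid (nm), unit normal, RMS residual."""

    centroid: np.ndarray
    normal: np.ndarray
    residual: float

    def __post_init__(self):
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("normal must be unit length")
        if self.residual < 0:
            raise ValueError("residual must be nonnegative")


def ring_geometry(frame: Conformation, ring_atoms: np.ndarray) -> RingGeometry:
    """Centroid + least-squares plane normal of a ring atom group.

    The normal's sign follows the right-hand rule of the declared atom
    ordering; the residual is the RMS out-of-plane distance.
    """
    pts = frame.coords[np.asarray(ring_atoms)]
    if pts.shape[0] < 3:
        raise ValueError("ring needs at least 3 atoms")
    c = pts.mean(axis=0)
    centered = pts - c
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise ValueError("ring atoms are collinear")
    normal = vt[2]
    # orient along the ordered-atom circulation (right-hand rule)
    circ = np.cross(centered[0], centered[1])
    for k in range(1, len(centered) - 1):
        circ = circ + np.cross(centered[k], centered[k + 1])
    if np.dot(normal, circ) < 0:
        normal = -normal
    residual = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingGeometry(c, normal / np.linalg.norm(normal), residual)


@dataclass
class StackingEvent:
    """One residue-ring / ligand-ring geometry with its classification."""

    residue_ring: str
    ligand_ring: str
    distance_nm: float
    angle_deg: float
    stacking_class: str

    def __post_init__(self):
        if not 0.0 <= self.angle_deg <= 90.0 + 1e-9:
            raise ValueError("plane angle must lie in [0, 90]")
        if self.stacking_class not in ("parallel", "perpendicular", "none"):
            raise ValueError(f"bad class {self.stacking_class!r}")


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes, folded to [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def classify_stacking(distance_nm: float, angle_deg: float,
                      d_par: float = PARALLEL_MAX_DIST_NM,
                      d_perp: float = PERPENDICULAR_MAX_DIST_NM,
                      a_par: float = PARALLEL_MAX_ANGLE_DEG,
                      a_perp: float = PERPENDICULAR_MIN_ANGLE_DEG) -> str:
    if distance_nm <= d_par and angle_deg <= a_par:
        return "parallel"
    if distance_nm <= d_perp and angle_deg >= a_perp:
        return "perpendicular"
    return "none"


def stacking_classify(res_ring: RingGeometry, lig_ring: RingGeometry,
                      residue_ring_name: str = "", ligand_ring_name: str = "",
                      **thresholds) -> StackingEvent:
    d = float(np.linalg.norm(res_ring.centroid - lig_ring.centroid))
    theta = plane_angle(res_ring.normal, lig_ring.normal)
    cls = classify_stacking(d, theta, **thresholds)
    return StackingEvent(residue_ring_name, ligand_ring_name, d, theta, cls)


def stacking_statistics(ensemble: Ensemble, **thresholds):
    """Per-frame stacking events between residue rings and ligand rings.

    Returns ``(events, summary)``: ``events`` is a list (one per frame)
    of lists of :class:`StackingEvent`; ``summary`` maps
    ``"parallel"``/``"perpendicular"``/``"both"`` to the weighted
    probability that a frame contains at least one event of that class
    ("both" = parallel or perpendicular).  An ensemble without ligand
    rings yields empty events and zero probabilities.
    """
    top = ensemble.topology
    rings = top.ring_groups()
    res_rings = {n: i for n, i in rings.items()
                 if top.atoms[i[0]].atom_class == "side_chain"}
    lig_rings = {n: i for n, i in rings.items()
                 if top.atoms[i[0]].atom_class == "ligand"}
    events: list[list[StackingEvent]] = []
    p_par = p_perp = p_both = 0.0
    for w, frame in zip(ensemble.weights, ensemble.frames):
        fr_events = []
        for rname, ridx in res_rings.items():
            rg = ring_geometry(frame, ridx)
            for lname, lidx in lig_rings.items():
                lg = ring_geometry(frame, lidx)
                fr_events.append(stacking_classify(rg, lg, rname, lname, **thresholds))
        events.append(fr_events)
        classes = {e.stacking_class for e in fr_events}
        if "parallel" in classes:
            p_par += w
        if "perpendicular" in classes:
            p_perp += w
        if classes & {"parallel", "perpendicular"}:
            p_both += w
    summary = {"parallel": p_par, "perpendicular": p_perp, "both": p_both}
    return events, summary


def stacking_samples(events) -> np.ndarray:
    """(distance, angle) sample array from stacking events, for FES input."""
    rows = [(e.distance_nm, e.angle_deg) for fr in events for e in fr]
    return np.asarray(rows).reshape(-1, 2)


# ---------------------------------------------------------------------------
# cation-pi and ring-pair torsion distributions
# ---------------------------------------------------------------------------

def cation_pi_distances(ensemble: Ensemble) -> np.ndarray:
    """All cation-centre to ligand-ring-centroid distances (nm).

    The cation centre of a charged group is the mean position of its
    declared atoms (e.g. the three guanidinium nitrogens of Arg).
    """
    top = ensemble.topology
    cations = top.charged_groups()
    lig_rings = {n: i for n, i in top.ring_groups().items()
                 if top.atoms[i[0]].atom_class == "ligand"}
    if not cations:
        raise ValueError("no charged groups declared in topology")
    out = []
    for frame in ensemble.frames:
        for cidx in cations.values():
            cpos = frame.coords[cidx].mean(axis=0)
            for ridx in lig_rings.values():
                out.append(np.linalg.norm(frame.coords[ridx].mean(axis=0) - cpos))
    return np.asarray(out)


def cation_pi_pdf(ensemble: Ensemble, bins=50, range_nm=(0.2, 2.0)):
    """Unit-area PDF of cation-to-ring-centroid distances.

    Returns ``(bin_centers, density)``; both empty when the topology has
    no ligand rings.
    """
    d = cation_pi_distances(ensemble)
    if len(d) == 0:
        return np.array([]), np.array([])
    density, edges = np.histogram(d, bins=bins, range=range_nm, density=True)
    return 0.5 * (edges[:-1] + edges[1:]), density


def ring_pair_torsion(frame: Conformation, top: Topology,
                      ringA: str, ringB: str) -> float:
    """Angle between two rings of one ligand molecule, in [0, 180] deg.

    Uses the oriented normals fixed by the declared atom ordering, so
    unlike the stacking plane angle this does not fold at 90 degrees.
    """
    rings = top.ring_groups()
    ia, ib = rings[ringA], rings[ringB]
    if top.atom_chain[ia[0]] != top.atom_chain[ib[0]]:
        raise ValueError("rings belong to different molecules")
    ga = ring_geometry(frame, ia)
    gb = ring_geometry(frame, ib)
    c = float(np.dot(ga.normal, gb.normal))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def ring_pair_torsion_pdf(ensemble: Ensemble, ringA: str, ringB: str,
                          bins=36):
    """Unit-area PDF of the inter-ring angle over [0, 180] degrees."""
    vals = [ring_pair_torsion(f, ensemble.topology, ringA, ringB)
            for f in ensemble.frames]
    density, edges = np.histogram(vals, bins=bins, range=(0.0, 180.0),
                                  density=True, weights=ensemble.weights)
    return 0.5 * (edges[:-1] + edges[1:]), density
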