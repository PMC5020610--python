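"""Hydrogen-bond-based secondary-structure assignment (Kabsch-Sander).

Implements the classic eight-state assignment from backbone hydrogen
bonds: the electrostatic H-bond energy model, n-turns and helices
(G/H/I), parallel and antiparallel bridges and ladders (B/E, including
bulge-linked ladders and inter-chain bridges), hydrogen-bonded turns (T)
and bends (S).  Everything else is coil (C).

Derived ensemble statistics live here too: per-residue class
probabilities with the six-class collapse used for reporting
(helix = {H,G,I}, sheet = {E}, bridge = {B}, turn = {T}, bend = {S},
coil = {C}), and the beta-strand run-length distribution.

Amide hydrogens are reconstructed when the topology does not declare
them: H sits 1.0 angstrom from N, anti to the preceding carbonyl C=O.
The first residue of a chain and every proline are never donors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model import Conformation, Ensemble, Topology

# Kabsch-Sander electrostatic model constants
KS_COUPLING = 27.888          # kcal/mol * angstrom (q1*q2*332)
HBOND_ENERGY_CUTOFF = -0.5    # kcal/mol
BEND_KAPPA_DEG = 70.0
NM_TO_A = 10.0

SS_CLASSES = ("H", "G", "I", "E", "B", "T", "S", "C")

#: collapse of the 8-state alphabet to the six reported classes
COLLAPSE_MAP = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "bridge", "T": "turn", "S": "bend", "C": "coil",
}
COLLAPSED_CLASSES = ("helix", "sheet", "bridge", "turn", "bend", "coil")


# ---------------------------------------------------------------------------
# backbone extraction
# ---------------------------------------------------------------------------

@dataclass
class _Backbone:
    """Per-peptide-residue backbone atom indices for one topology."""

    res_global: np.ndarray      # global residue index per backbone residue
    chain: np.ndarray           # chain index per backbone residue
    n_idx: np.ndarray
    ca_idx: np.ndarray
    c_idx: np.ndarray
    o_idx: np.ndarray
    h_idx: np.ndarray           # -1 where H must be reconstructed / absent
    is_pro: np.ndarray          # bool

    def __len__(self):
        return len(self.res_global)


def _extract_backbone(top: Topology) -> _Backbone:
    res_g, chain, n_i, ca_i, c_i, o_i, h_i, pro = [], [], [], [], [], [], [], []
    for g, res in enumerate(top.residues):
        atoms = {a.name: k for k, a in enumerate(res.atoms)}
        if not {"N", "CA", "C", "O"} <= atoms.keys():
            # skip non-peptide residues (ligands); partial backbones are errors
            if any(top.atoms[i].atom_class == "main_chain"
                   for i in top.residue_atom_indices(g)):
                missing = {"N", "CA", "C", "O"} - atoms.keys()
                raise ValueError(
                    f"residue {res.name}{res.index}: missing backbone "
                    f"atom(s) {sorted(missing)}")
            continue
        base = top.residue_atom_indices(g)[0]
        res_g.append(g)
        chain.append(int(top.residue_chain[g]))
        n_i.append(base + atoms["N"])
        ca_i.append(base + atoms["CA"])
        c_i.append(base + atoms["C"])
        o_i.append(base + atoms["O"])
        h_i.append(base + atoms["H"] if "H" in atoms else -1)
        pro.append(res.name == "PRO")
    if not res_g:
        raise ValueError("topology has no peptide residues")
    return _Backbone(*(np.asarray(x) for x in (res_g, chain, n_i, ca_i, c_i,
                                               o_i, h_i)), np.asarray(pro))


def _amide_hydrogens(bb: _Backbone, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Amide H positions (angstrom) + donor-capability mask."""
    n = len(bb)
    H = np.zeros((n, 3))
    can_donate = np.zeros(n, dtype=bool)
    N = xyz[bb.n_idx] * NM_TO_A
    C = xyz[bb.c_idx] * NM_TO_A
    O = xyz[bb.o_idx] * NM_TO_A
    for i in range(n):
        if bb.is_pro[i]:
            continue
        if bb.h_idx[i] >= 0:
            H[i] = xyz[bb.h_idx[i]] * NM_TO_A
            can_donate[i] = True
        elif i > 0 and bb.chain[i - 1] == bb.chain[i]:
            d = C[i - 1] - O[i - 1]
            H[i] = N[i] + d / np.linalg.norm(d)
            can_donate[i] = True
        # chain-start residue without declared H: no donor
    return H, can_donate


# ---------------------------------------------------------------------------
# hydrogen-bond energies
# ---------------------------------------------------------------------------

def hbond_energy_matrix(frame: Conformation, top: Topology) -> np.ndarray:
    """Kabsch-Sander energies E[donor, acceptor] in kcal/mol.

    ``E[i, j]`` is the energy of the hydrogen bond donated by the amide
    N-H of backbone residue i to the carbonyl C=O of residue j.
    Self-bonds and same-chain neighbours (|i - j| < 2) are excluded and
    reported as 0 (no bond), as are incapable donors (prolines,
    chain-start residues without a declared H).
    """
    bb = _extract_backbone(top)
    return _energies(bb, frame.coords)


def _energies(bb: _Backbone, xyz: np.ndarray) -> np.ndarray:
    N = xyz[bb.n_idx] * NM_TO_A
    C = xyz[bb.c_idx] * NM_TO_A
    O = xyz[bb.o_idx] * NM_TO_A
    H, can_donate = _amide_hydrogens(bb, xyz)

    # distances clamped below at 0.5 A to keep the 1/r model finite
    def inv(a, b):
        return 1.0 / np.maximum(cdist(a, b), 0.5)

    E = KS_COUPLING * (inv(N, O) + inv(H, C) - inv(H, O) - inv(N, C))
    E[~can_donate, :] = 0.0
    n = len(bb)
    same_chain = bb.chain[:, None] == bb.chain[None, :]
    near = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) < 2
    E[same_chain & near] = 0.0
    return E


def backbone_hbond_energy(donor: int, acceptor: int, frame: Conformation,
                          top: Topology) -> float:
    """Energy (kcal/mol) of the single H-bond donor N-H -> acceptor C=O.

    Indices address backbone residues in topology order.  Excluded pairs
    (self, same-chain neighbours, incapable donors) return 0.
    """
    return float(hbond_energy_matrix(frame, top)[donor, acceptor])


# ---------------------------------------------------------------------------
# per-frame pattern assignment
# ---------------------------------------------------------------------------

def _assign_frame(bb: _Backbone, xyz: np.ndarray) -> np.ndarray:
    n = len(bb)
    E = _energies(bb, xyz)
    hbond = E < HBOND_ENERGY_CUTOFF  # hbond[donor, acceptor]

    def consecutive(i, j):
        return j == i + 1 and bb.chain[i] == bb.chain[j]

    # n-turns: acceptor i, donor i+n within one chain
    turn = {}
    for m in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - m):
            if bb.chain[i] == bb.chain[i + m] and hbond[i + m, i]:
                t[i] = True
        turn[m] = t

    # bridges
    def hb(d, a):
        return 0 <= d < n and 0 <= a < n and hbond[d, a]

    def valid_triple(i):
        return (0 < i < n - 1 and bb.chain[i - 1] == bb.chain[i] == bb.chain[i + 1])

    par = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        if not valid_triple(i):
            continue
        for j in range(i + 1, n - 1):
            if not valid_triple(j):
                continue
            if bb.chain[i] == bb.chain[j] and j < i + 3:
                continue
            if (hb(j, i - 1) and hb(i + 1, j)) or (hb(i, j - 1) and hb(j + 1, i)):
                par[i, j] = par[j, i] = True
            if (hb(j, i) and hb(i, j)) or (hb(j + 1, i - 1) and hb(i + 1, j - 1)):
                anti[i, j] = anti[j, i] = True

    is_E, is_B = _ladders(bb, par, anti)

    # minimal helices: two consecutive n-turns at i-1 and i
    helix = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(1, n - m):
            if turn[m][i - 1] and turn[m][i] and bb.chain[i - 1] == bb.chain[i + m - 1]:
                helix[m][i:i + m] = True

    # T: interior residues of any single n-turn
    is_T = np.zeros(n, dtype=bool)
    for m in (3, 4, 5):
        for i in np.flatnonzero(turn[m]):
            is_T[i + 1:i + m] = True

    # S: CA-pseudo-angle kappa > 70 degrees
    CA = xyz[bb.ca_idx] * NM_TO_A
    is_S = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if bb.chain[i - 2] != bb.chain[i] or bb.chain[i] != bb.chain[i + 2]:
            continue
        u = CA[i] - CA[i - 2]
        v = CA[i + 2] - CA[i]
        cosk = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosk, -1, 1))) > BEND_KAPPA_DEG:
            is_S[i] = True

    ss = np.full(n, "C", dtype="U1")
    ss[is_S] = "S"
    ss[is_T] = "T"
    ss[helix[5]] = "I"
    ss[helix[3]] = "G"
    ss[is_B] = "B"
    ss[is_E] = "E"
    ss[helix[4]] = "H"
    return ss


def _ladders(bb: _Backbone, par: np.ndarray, anti: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Extended-strand (E) and isolated-bridge (B) flags from bridges.

    Consecutive bridges of one type form ladders; ladders separated by a
    short bulge (at most one residue on one strand and four on the
    other) are merged, with the bulge residues themselves marked E.
    """
    n = par.shape[0]
    ladders: list[dict] = []  # {type, i_lo, i_hi, j_lo, j_hi, dir}
    for kind, mat, step in (("p", par, +1), ("a", anti, -1)):
        seen = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                if not mat[i, j] or seen[i, j] or j < i:
                    continue
                ii, jj = i, j
                pairs = [(ii, jj)]
                while (ii + 1 < n and 0 <= jj + step < n
                       and mat[ii + 1, jj + step]
                       and bb.chain[ii + 1] == bb.chain[ii]
                       and bb.chain[jj + step] == bb.chain[jj]):
                    ii, jj = ii + 1, jj + step
                    pairs.append((ii, jj))
                for a, b in pairs:
                    seen[a, b] = seen[b, a] = True
                iis = [p[0] for p in pairs]
                jjs = [p[1] for p in pairs]
                ladders.append({"type": kind, "pairs": pairs,
                                "i_lo": min(iis), "i_hi": max(iis),
                                "j_lo": min(jjs), "j_hi": max(jjs)})

    # bulge merging
    merged = True
    while merged:
        merged = False
        for a in range(len(ladders)):
            for b in range(a + 1, len(ladders)):
                la, lb = ladders[a], ladders[b]
                if la["type"] != lb["type"]:
                    continue
                if _bulge_linked(bb, la, lb):
                    la["pairs"] = la["pairs"] + lb["pairs"]
                    la["i_lo"] = min(la["i_lo"], lb["i_lo"])
                    la["i_hi"] = max(la["i_hi"], lb["i_hi"])
                    la["j_lo"] = min(la["j_lo"], lb["j_lo"])
                    la["j_hi"] = max(la["j_hi"], lb["j_hi"])
                    del ladders[b]
                    merged = True
                    break
            if merged:
                break

    is_E = np.zeros(n, dtype=bool)
    is_B = np.zeros(n, dtype=bool)
    for lad in ladders:
        if len(lad["pairs"]) == 1:
            i, j = lad["pairs"][0]
            is_B[i] = is_B[j] = True
        else:
            is_E[lad["i_lo"]:lad["i_hi"] + 1] = True
            is_E[lad["j_lo"]:lad["j_hi"] + 1] = True
    is_B &= ~is_E
    return is_E, is_B


def _bulge_linked(bb: _Backbone, la: dict, lb: dict) -> bool:
    # ladders must sit on the same chain pair, in order, with a short gap
    if la["i_lo"] > lb["i_lo"]:
        la, lb = lb, la
    gap_i = lb["i_lo"] - la["i_hi"] - 1
    if gap_i < 0 or gap_i > 4:
        return False
    if bb.chain[la["i_hi"]] != bb.chain[lb["i_lo"]]:
        return False
    if lb["j_lo"] > la["j_hi"]:
        gap_j = lb["j_lo"] - la["j_hi"] - 1
        cj = (bb.chain[la["j_hi"]], bb.chain[lb["j_lo"]])
    else:
        gap_j = la["j_lo"] - lb["j_hi"] - 1
        cj = (bb.chain[lb["j_hi"]], bb.chain[la["j_lo"]])
    if gap_j < 0 or gap_j > 4 or cj[0] != cj[1]:
        return False
    return min(gap_i, gap_j) <= 1 and max(gap_i, gap_j) <= 4


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class SSAssignment:
    """Per-frame, per-backbone-residue class labels.

    ``classes`` has shape (n_frames, n_residues) over the topology's
    peptide residues, in topology order; ``res_global`` / ``res_chain``
    map columns back to global residue and chain indices.
    """

    classes: np.ndarray
    res_global: np.ndarray
    res_chain: np.ndarray

    def __post_init__(self):
        bad = set(np.unique(self.classes)) - set(SS_CLASSES)
        if bad:
            raise ValueError(f"unknown SS classes {sorted(bad)}")

    @property
    def n_frames(self):
        return self.classes.shape[0]

    @property
    def n_residues(self):
        return self.classes.shape[1]


def assign_ss(ensemble: Ensemble) -> SSAssignment:
    """Assign eight-state secondary structure to every frame."""
    bb = _extract_backbone(ensemble.topology)
    out = np.empty((ensemble.n_frames, len(bb)), dtype="U1")
    for f, frame in enumerate(ensemble.frames):
        out[f] = _assign_frame(bb, frame.coords)
    return SSAssignment(out, bb.res_global, bb.chain)


@dataclass
class SSProfile:
    """Per-residue probabilities over the six collapsed classes, plus
    ensemble means.  Rows of ``per_residue`` follow the assignment's
    residue order; columns follow :data:`COLLAPSED_CLASSES`."""

    per_residue: np.ndarray
    ensemble_mean: np.ndarray
    res_global: np.ndarray

    def __post_init__(self):
        sums = self.per_residue.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-residue probabilities must sum to 1")

    def mean_of(self, collapsed_class: str) -> float:
        return float(self.ensemble_mean[COLLAPSED_CLASSES.index(collapsed_class)])


def ss_profile(assign: SSAssignment, weights: np.ndarray | None = None) -> SSProfile:
    """Weight-averaged collapsed-class probabilities per residue."""
    nf, nr = assign.classes.shape
    w = np.full(nf, 1.0 / nf) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    per_res = np.zeros((nr, len(COLLAPSED_CLASSES)))
    for ci, cls8 in enumerate(SS_CLASSES):
        col = COLLAPSED_CLASSES.index(COLLAPSE_MAP[cls8])
        mask = assign.classes == cls8
        per_res[:, col] += (w[:, None] * mask).sum(axis=0)
    mean = per_res.mean(axis=0)
    return SSProfile(per_res, mean, assign.res_global)


@dataclass
class StrandLengthPDF:
    """Probability of maximal beta-strand (E) runs by length.

    Normalised per frame x chain: probability(L) = runs of length L
    divided by (n_frames * n_chains), so values need not sum to 1.
    """

    probabilities: dict[int, float]

    def __post_init__(self):
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be nonnegative")


def strand_length_pdf(assign: SSAssignment,
                      normalization: str = "per_frame_chain") -> StrandLengthPDF:
    """Distribution of maximal consecutive-E run lengths.

    ``normalization`` is ``"per_frame_chain"`` (default, counts divided by
    n_frames * n_chains) or ``"fraction"`` (counts divided by the total
    number of runs).
    """
    chains = np.unique(assign.res_chain)
    counts: dict[int, int] = {}
    total_runs = 0
    for f in range(assign.n_frames):
        for c in chains:
            labels = assign.classes[f, assign.res_chain == c]
            run = 0
            for lab in list(labels) + ["*"]:
                if lab == "E":
                    run += 1
                else:
                    if run > 0:
                        counts[run] = counts.get(run, 0) + 1
                        total_runs += 1
                    run = 0
    if normalization == "per_frame_chain":
        denom = assign.n_frames * len(chains)
    elif normalization == "fraction":
        denom = max(total_runs, 1)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return StrandLengthPDF({L: c / denom for L, c in sorted(counts.items())})
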