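"""Superposition, chain-independent RMSD and Daura clustering.

The clustering follows the greedy neighbour-count rule: the frame with
the most neighbours within the RMSD cutoff seeds a cluster, the seed and
its neighbours are removed, and the rule repeats until no frames remain.
For a homodimer the pairwise RMSD ignores the chain labels: both chain
assignments (A-A/B-B and A-B/B-A) are superposed and the smaller RMSD is
used, since the two chains are topologically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Conformation, Ensemble, Topology

DEFAULT_CUTOFF_NM = 0.35
MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    (det = +1; reflections disallowed) and translation minimising the
    weighted RMSD of ``mobile @ R.T + t`` against ``reference``.  RMSD is
    in the input length unit (nm throughout this package).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 atoms required")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0):
        raise ValueError("weights must be nonnegative, one per atom")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")
    w = w / wsum

    mu_m = w @ mobile
    mu_r = w @ reference
    X = mobile - mu_m
    Y = reference - mu_r
    C = (X * w[:, None]).T @ Y
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    diff = X @ R.T - Y
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    return kabsch_superpose(mobile, reference, weights)[2]


# ---------------------------------------------------------------------------
# chain-independent main-chain RMSD
# ---------------------------------------------------------------------------

def main_chain_indices(top: Topology, atom_names=MAIN_CHAIN_ATOMS
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Main-chain atom indices for the two chains of a homodimer.

    Returns ``(idx_A, idx_B)`` in matching per-chain order, so that
    swapping the two blocks realises the chain-label permutation.
    """
    if not top.homodimer:
        raise ValueError("chain-independent RMSD requires a declared homodimer")
    out = []
    for ci in (0, 1):
        chain = top.chains[ci]
        idx = []
        for g in top.chain_residue_indices(ci):
            res = top.residues[g]
            base = top.residue_atom_indices(g)[0]
            for name in atom_names:
                try:
                    idx.append(base + res.atom_index(name))
                except KeyError:
                    continue
        out.append(np.asarray(idx))
    if len(out[0]) != len(out[1]):
        raise ValueError("homodimer chains yield different main-chain selections")
    return out[0], out[1]


def chain_independent_rmsd(frameA: Conformation, frameB: Conformation,
                           top: Topology, atom_names=MAIN_CHAIN_ATOMS) -> float:
    """Main-chain RMSD (nm) minimised over the two chain-label assignments."""
    ia, ib = main_chain_indices(top, atom_names)
    ref = np.vstack([frameA.coords[ia], frameA.coords[ib]])
    direct = np.vstack([frameB.coords[ia], frameB.coords[ib]])
    swapped = np.vstack([frameB.coords[ib], frameB.coords[ia]])
    return min(superposed_rmsd(direct, ref), superposed_rmsd(swapped, ref))


def rmsd_matrix(ensemble: Ensemble, atom_names=MAIN_CHAIN_ATOMS,
                stride: int = 1) -> np.ndarray:
    """Full pairwise chain-independent main-chain RMSD matrix (nm).

    ``stride`` subsamples frames for large ensembles (the matrix is then
    over frames 0, stride, 2*stride, ...).
    """
    frames = ensemble.frames[::stride]
    n = len(frames)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = chain_independent_rmsd(
                frames[i], frames[j], ensemble.topology, atom_names)
    return M


# ---------------------------------------------------------------------------
# Daura clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Greedy neighbour-count clustering output.

    ``clusters`` is ordered by decreasing size (ties: lower centre frame
    index); each entry is ``(center, members)`` with the centre included
    among its members.  ``populations`` are member fractions.
    """

    clusters: list[tuple[int, np.ndarray]]
    populations: np.ndarray
    cutoff_nm: float

    def __post_init__(self):
        total = sum(len(m) for _, m in self.clusters)
        all_members = np.concatenate([m for _, m in self.clusters])
        if len(np.unique(all_members)) != total:
            raise ValueError("clusters must partition the frames")
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")

    @property
    def n_clusters(self):
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        n = sum(len(m) for _, m in self.clusters)
        lab = np.empty(n, dtype=int)
        for k, (_, members) in enumerate(self.clusters):
            lab[members] = k
        return lab


def daura_cluster(matrix: np.ndarray, cutoff: float = DEFAULT_CUTOFF_NM
                  ) -> ClusterResult:
    """Greedy neighbour-count clustering of a pairwise RMSD matrix.

    Repeatedly takes the unassigned frame with the most unassigned
    neighbours within ``cutoff`` (ties: lowest frame index) as a centre
    and removes it with its neighbours.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-9) or np.any(np.diag(M) > 1e-12):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = M.shape[0]
    neighbor = M <= cutoff
    np.fill_diagonal(neighbor, True)

    remaining = np.ones(n, dtype=bool)
    raw: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes lowest index on ties
        members = np.flatnonzero(neighbor[center] & remaining)
        raw.append((center, members))
        remaining[members] = False

    raw.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    pops = np.array([len(m) for _, m in raw], dtype=float) / n
    return ClusterResult(raw, pops, cutoff)


def cluster_ensemble(ensemble: Ensemble, cutoff: float = DEFAULT_CUTOFF_NM,
                     atom_names=MAIN_CHAIN_ATOMS) -> ClusterResult:
    """Convenience: RMSD matrix + Daura clustering in one call."""
    return daura_cluster(rmsd_matrix(ensemble, atom_names), cutoff)


def cluster_summary(result: ClusterResult, ensemble: Ensemble, k: int):
    """Top-k cluster table and centre conformations.

    Returns ``(table, centers)`` where ``table`` is a list of dicts
    (cluster rank, centre frame, size, population, cumulative fraction)
    and ``centers`` the centre frames as an :class:`Ensemble` suitable
    for writing as a multi-model PDB.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > result.n_clusters:
        raise ValueError(f"k={k} exceeds {result.n_clusters} clusters")
    rows = []
    cum = 0.0
    for rank in range(k):
        center, members = result.clusters[rank]
        pop = float(result.populations[rank])
        cum += pop
        rows.append({"cluster": rank + 1, "center_frame": center,
                     "size": len(members), "population": pop,
                     "cumulative": cum})
    centers = ensemble.subset([result.clusters[r][0] for r in range(k)])
    return rows, centers
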